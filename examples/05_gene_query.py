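"""Query one gene and one protein across a synthetic cell-line panel.

The gene query joins screen rank, hit status, expression and copy number
for a single gene in every cell line; the protein query returns the RPPA
panel rank-ordered by normalised linear expression.
"""

from screenomics import ProteinRecord, gene_query, protein_query
from screenomics.simulate import simulate_omics

store, truth = simulate_omics(n_lines=4, n_genes=30, n_drivers=2, seed=13)
gene = truth.drivers[next(iter(truth.drivers))][0]

rows = gene_query(gene, store)
print(f"gene query for {gene}:")
print(rows.to_string(index=False))

proteins = [
    ProteinRecord(line, "AR", value)
    for line, value in zip(sorted(truth.drivers), (4.2, 1.1, 9.7, 2.0))
]
print("\nprotein query for AR (rank-ordered, descending):")
print(protein_query("AR", proteins).to_string(index=False))
# Rows are one per cell line, sorted by screen rank (missing layers shown
# as NaN); the protein table descends from the highest-expressing line.
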