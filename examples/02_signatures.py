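"""Derive oncogene and druggable signatures for a synthetic cell line.

The generator plants three driver genes that are simultaneously
genomically altered (amplified or carrying a recurrent COSMIC mutation),
annotated oncogenes, overexpressed and screen hits.  The candidate
signature (altered ∩ oncogenes) may include non-essential oncogenes; the
overall signature (altered ∩ hits) may include non-oncogenes; their
synthesis — the functional signature — recovers exactly the planted
drivers.  The druggable signature lists every hit with a mapped drug.
"""

from screenomics import (
    candidate_signature,
    druggable_signature,
    functional_signature,
    overall_signature,
)
from screenomics.simulate import simulate_omics

store, truth = simulate_omics(n_lines=1, n_genes=40, n_drivers=3, seed=5)
line = next(iter(truth.drivers))

cand = candidate_signature(line, store)
over = overall_signature(line, store)
func = functional_signature(line, store)
drug = druggable_signature(line, store)

print(f"cell line {line}; planted drivers: {', '.join(truth.drivers[line])}")
print(f"candidate signature ({len(cand)} genes): "
      f"{', '.join(r.gene for r in cand)}")
print(f"overall signature ({len(over)} genes): "
      f"{', '.join(r.gene for r in over)}")
print(f"functional signature ({len(func)} genes): "
      f"{', '.join(r.gene for r in func)}")
print("druggable signature (rank, gene, drugs):")
for r in drug[:5]:
    print(f"  {r.rank:>3}  {r.gene}  {', '.join(r.drugs)}")
# The functional signature equals candidate ∩ overall and matches the
# planted drivers; druggable rows are ordered by screen rank (most
# essential first).
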