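"""Oncogene and druggable signatures by orthogonal set logic.

For one cell line:

* Candidate signature  = {genomically altered} ∩ {annotated oncogenes}
* Overall signature    = {genomically altered} ∩ {screen hits}
* Functional signature = {altered} ∩ {oncogenes} ∩ {hits}
                       = candidate ∩ overall
* Druggable signature  = {screen hits} ∩ {genes with ≥ 1 mapped drug}

"Genomically altered" means amplified (log2 copy ratio at or above the
amplification cut) or carrying a point mutation retained by the COSMIC
occurrence filter.  Every field of a signature row is taken verbatim from
the store — nothing is recomputed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import ConfigurationError
from .store import OmicsStore, filter_mutations


@dataclass(frozen=True)
class SignatureRow:
    gene: str
    quant_log: float | None
    rank: int | None
    is_hit: bool | None
    expression_lfc: float | None
    dna_amp: float | None
    mutation: str
    cosmic_occurrences: int | None
    drugs: tuple[str, ...]


def _require(store: OmicsStore, cell_line: str, *, oncogenes=False, hits=False,
             drugs=False) -> None:
    if store.cna is None and not store.mutations:
        raise ConfigurationError(
            "signature needs a copy-number or mutation layer"
        )
    if oncogenes and store.oncogenes is None:
        raise ConfigurationError("signature needs oncogene annotations")
    if hits and cell_line not in store.hits:
        raise ConfigurationError(f"no screen results loaded for {cell_line!r}")
    if drugs and store.drugs is None:
        raise ConfigurationError("druggable signature needs a drug map")


def _build_row(store: OmicsStore, cell_line: str, gene: str,
               min_occurrences: int, hotspot_mode: bool) -> SignatureRow:
    quant_log = rank = is_hit = None
    if cell_line in store.hits:
        for h in store.hits[cell_line]:
            if h.gene == gene:
                quant_log, rank, is_hit = h.quant_log, h.rank, h.is_hit
                break
    lfc = (
        store.expression_lfc(cell_line, gene)
        if store.expression is not None
        else None
    )
    amp = store.dna_amp(cell_line, gene) if store.cna is not None else None
    retained = filter_mutations(
        store.mutations_for(cell_line, gene),
        min_occurrences=min_occurrences,
        hotspot_mode=hotspot_mode,
    )
    mutation = ", ".join(m.protein_change for m in retained)
    occurrences = max((m.cosmic_occurrences for m in retained), default=None)
    drugs = store.drugs_for(gene) if store.drugs is not None else ()
    return SignatureRow(
        gene=gene, quant_log=quant_log, rank=rank, is_hit=is_hit,
        expression_lfc=lfc, dna_amp=amp, mutation=mutation,
        cosmic_occurrences=occurrences, drugs=drugs,
    )


def _rows_for(genes: Iterable[str], store: OmicsStore, cell_line: str,
              min_occurrences: int, hotspot_mode: bool) -> list[SignatureRow]:
    rows = [
        _build_row(store, cell_line, g, min_occurrences, hotspot_mode)
        for g in genes
    ]
    # Published signature tables are ordered by expression descending.
    rows.sort(
        key=lambda r: (
            -(r.expression_lfc if r.expression_lfc is not None else float("-inf")),
            r.gene,
        )
    )
    return rows


def candidate_signature(
    cell_line: str,
    store: OmicsStore,
    amp_threshold: float = 0.8,
    min_occurrences: int = 5,
    hotspot_mode: bool = False,
) -> list[SignatureRow]:
    """Genomically altered genes that are annotated oncogenes, regardless of
    screen-hit status (the hit column shows how essential each one is)."""
    _require(store, cell_line, oncogenes=True)
    altered = store.altered_genes(
        cell_line, amp_threshold=amp_threshold,
        min_occurrences=min_occurrences, hotspot_mode=hotspot_mode,
    )
    genes = altered & set(store.oncogenes)
    return _rows_for(genes, store, cell_line, min_occurrences, hotspot_mode)


def overall_signature(
    cell_line: str,
    store: OmicsStore,
    amp_threshold: float = 0.8,
    min_occurrences: int = 5,
    hotspot_mode: bool = False,
) -> list[SignatureRow]:
    """Genomically altered genes that were screen hits, oncogene or not."""
    _require(store, cell_line, hits=True)
    altered = store.altered_genes(
        cell_line, amp_threshold=amp_threshold,
        min_occurrences=min_occurrences, hotspot_mode=hotspot_mode,
    )
    hit_genes = {h.gene for h in store.hits_for(cell_line) if h.is_hit}
    return _rows_for(
        altered & hit_genes, store, cell_line, min_occurrences, hotspot_mode
    )


def functional_signature(
    cell_line: str,
    store: OmicsStore,
    amp_threshold: float = 0.8,
    min_occurrences: int = 5,
    hotspot_mode: bool = False,
) -> list[SignatureRow]:
    """The synthesis of candidate and overall: altered, bona fide oncogene,
    and a hit in the functional screen."""
    _require(store, cell_line, oncogenes=True, hits=True)
    altered = store.altered_genes(
        cell_line, amp_threshold=amp_threshold,
        min_occurrences=min_occurrences, hotspot_mode=hotspot_mode,
    )
    hit_genes = {h.gene for h in store.hits_for(cell_line) if h.is_hit}
    genes = altered & set(store.oncogenes) & hit_genes
    return _rows_for(genes, store, cell_line, min_occurrences, hotspot_mode)


def druggable_signature(
    cell_line: str,
    store: OmicsStore,
    min_occurrences: int = 5,
    hotspot_mode: bool = False,
) -> list[SignatureRow]:
    """Screen hits with at least one mapped targeted drug, ordered by screen
    rank ascending (most essential first)."""
    _require(store, cell_line, hits=True, drugs=True)
    rows = [
        _build_row(store, cell_line, h.gene, min_occurrences, hotspot_mode)
        for h in store.hits_for(cell_line)
        if h.is_hit and store.drugs_for(h.gene)
    ]
    rows.sort(key=lambda r: (r.rank if r.rank is not None else 1 << 30, r.gene))
    return rows
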