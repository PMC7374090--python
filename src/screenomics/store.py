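"""Per-cell-line omics store: copy number, expression, mutations, screen
results, oncogene annotations, drugs and RPPA protein data, joined on
(cell line, gene symbol).

Gene identity is the case-preserved symbol string, matched case-sensitively.
Expression values come in two dialects — log2 ratio versus normal cells, or
median-centred across a cell-line panel — recorded at store level and never
mixed within one store.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AbsentLayerError, FormatError, NotFoundError
from .screen import HitCall

EXPRESSION_DIALECTS = ("vs_normal", "median_centered")


@dataclass(frozen=True)
class MutationRecord:
    """One retained point mutation, e.g. protein_change 'PIK3CAp.H1047R'."""

    cell_line: str
    gene: str
    protein_change: str
    cosmic_occurrences: int
    hotspot: bool = False


@dataclass(frozen=True)
class ProteinRecord:
    """Normalised linear RPPA value for a protein or phospho-protein."""

    cell_line: str
    protein: str
    value: float


@dataclass
class OmicsStore:
    """In-memory join of all omics layers for a panel of cell lines.

    Layers are optional; querying an absent layer raises AbsentLayerError.
    Frames are indexed by plain columns:
      cna: cell_line, gene, dna_amp (log2 ratio vs normal)
      expression: cell_line, gene, expression_lfc
      mutations: list of MutationRecord
      hits: cell_line -> list of HitCall
      oncogenes: set of gene symbols flagged by the annotation source
      drugs: gene -> tuple of drug names
      proteins: list of ProteinRecord
    """

    cna: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    expression_dialect: str | None = None
    mutations: list[MutationRecord] = field(default_factory=list)
    hits: dict[str, list[HitCall]] = field(default_factory=dict)
    oncogenes: frozenset[str] | None = None
    drugs: dict[str, tuple[str, ...]] | None = None
    proteins: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("cna", "expression"):
            frame = getattr(self, name)
            if frame is None:
                continue
            dup = frame.duplicated(subset=["cell_line", "gene"])
            if dup.any():
                row = frame[dup].iloc[0]
                raise FormatError(
                    f"duplicate ({row['cell_line']}, {row['gene']}) row in the "
                    f"{name} layer"
                )
        if self.expression is not None and self.expression_dialect not in EXPRESSION_DIALECTS:
            raise FormatError(
                f"expression dialect must be one of {EXPRESSION_DIALECTS}, "
                f"got {self.expression_dialect!r}"
            )

    # -- layer access -------------------------------------------------------

    def _layer(self, name: str):
        value = getattr(self, name)
        if value is None:
            raise AbsentLayerError(f"omics layer {name!r} was not loaded")
        return value

    def cell_lines(self) -> list[str]:
        lines: set[str] = set(self.hits)
        for frame in (self.cna, self.expression):
            if frame is not None:
                lines.update(frame["cell_line"])
        lines.update(m.cell_line for m in self.mutations)
        return sorted(lines)

    def dna_amp(self, cell_line: str, gene: str) -> float | None:
        frame = self._layer("cna")
        sel = frame[(frame["cell_line"] == cell_line) & (frame["gene"] == gene)]
        return None if sel.empty else float(sel["dna_amp"].iloc[0])

    def expression_lfc(self, cell_line: str, gene: str) -> float | None:
        frame = self._layer("expression")
        sel = frame[(frame["cell_line"] == cell_line) & (frame["gene"] == gene)]
        return None if sel.empty else float(sel["expression_lfc"].iloc[0])

    def mutations_for(self, cell_line: str, gene: str | None = None) -> list[MutationRecord]:
        out = [m for m in self.mutations if m.cell_line == cell_line]
        if gene is not None:
            out = [m for m in out if m.gene == gene]
        return out

    def hits_for(self, cell_line: str) -> list[HitCall]:
        if cell_line not in self.hits:
            raise AbsentLayerError(f"no screen results loaded for {cell_line!r}")
        return self.hits[cell_line]

    def drugs_for(self, gene: str) -> tuple[str, ...]:
        drugs = self._layer("drugs")
        return drugs.get(gene, ())

    def is_oncogene(self, gene: str) -> bool:
        return gene in self._layer("oncogenes")

    # -- derived per-line gene sets ----------------------------------------

    def amplified_genes(self, cell_line: str, threshold: float = 0.8) -> set[str]:
        if self.cna is None:
            return set()
        sel = self.cna[self.cna["cell_line"] == cell_line]
        return call_amplifications(
            dict(zip(sel["gene"], sel["dna_amp"])), threshold=threshold
        )

    def mutated_genes(
        self,
        cell_line: str,
        min_occurrences: int = 5,
        hotspot_mode: bool = False,
    ) -> set[str]:
        kept = filter_mutations(
            self.mutations_for(cell_line),
            min_occurrences=min_occurrences,
            hotspot_mode=hotspot_mode,
        )
        return {m.gene for m in kept}

    def altered_genes(
        self,
        cell_line: str,
        amp_threshold: float = 0.8,
        min_occurrences: int = 5,
        hotspot_mode: bool = False,
    ) -> set[str]:
        """Genomically altered = amplified OR carrying a retained mutation.

        Deletions are deliberately excluded: the signature definitions rest
        on activation by gene amplification or point mutation.
        """
        return self.amplified_genes(cell_line, threshold=amp_threshold) | (
            self.mutated_genes(
                cell_line, min_occurrences=min_occurrences, hotspot_mode=hotspot_mode
            )
        )


# -- operations -------------------------------------------------------------


def median_center_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centre each gene row at its median across cell lines.

    Missing cells are ignored in the median and stay missing; an entirely
    missing row is left untouched.  Applying the operation twice equals
    applying it once.
    """
    medians = matrix.median(axis=1, skipna=True)
    return matrix.sub(medians.fillna(0.0), axis=0)


def filter_mutations(
    records: Iterable[MutationRecord],
    min_occurrences: int = 5,
    hotspot_mode: bool = False,
) -> list[MutationRecord]:
    """Retain mutations seen in COSMIC strictly more than ``min_occurrences``
    times; in hotspot mode retain only mutations flagged as COSMIC hot spots
    (the rule used for DepMap-sourced lines)."""
    out = []
    for rec in records:
        if rec.cosmic_occurrences < 0:
            raise ValueError(
                f"negative COSMIC occurrence count for {rec.gene} "
                f"{rec.protein_change}"
            )
        keep = rec.hotspot if hotspot_mode else rec.cosmic_occurrences > min_occurrences
        if keep:
            out.append(rec)
    return out


def call_amplifications(
    cna: Mapping[str, float], threshold: float = 0.8
) -> set[str]:
    """Genes whose log2 copy-number ratio is at or above the threshold."""
    out = set()
    for gene, val in cna.items():
        if not np.isfinite(val):
            raise ValueError(f"non-finite copy-number value for gene {gene!r}")
        if val >= threshold:
            out.add(gene)
    return out


def gene_query(gene: str, store: OmicsStore) -> pd.DataFrame:
    """Cross-panel view of one gene: screen rank, hit flag, expression and
    copy number for every cell line in the store, sorted by rank ascending
    (lines without screen data last, then alphabetical)."""
    lines = store.cell_lines()
    known = False
    rows = []
    for line in lines:
        rank = is_hit = None
        if line in store.hits:
            for h in store.hits[line]:
                if h.gene == gene:
                    rank, is_hit, known = h.rank, int(h.is_hit), True
                    break
        lfc = amp = None
        if store.expression is not None:
            lfc = store.expression_lfc(line, gene)
            known = known or lfc is not None
        if store.cna is not None:
            amp = store.dna_amp(line, gene)
            known = known or amp is not None
        if store.mutations_for(line, gene):
            known = True
        rows.append(
            {"cell_line": line, "rank": rank, "is_hit": is_hit,
             "expression_lfc": lfc, "dna_amp": amp}
        )
    if not known:
        raise NotFoundError(f"gene {gene!r} is unknown to every loaded layer")
    frame = pd.DataFrame(rows)
    frame = frame.sort_values(
        by=["rank", "cell_line"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return frame


def protein_query(name: str, proteins: Sequence[ProteinRecord]) -> pd.DataFrame:
    """All cell lines' normalised linear values for one RPPA protein or
    phospho-protein, rank-ordered by expression descending (ties broken by
    cell-line name)."""
    sel = [p for p in proteins if p.protein == name]
    if not sel:
        raise NotFoundError(f"protein {name!r} was not measured")
    sel.sort(key=lambda p: (-p.value, p.cell_line))
    return pd.DataFrame(
        {"cell_line": [p.cell_line for p in sel], "value": [p.value for p in sel]}
    )
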