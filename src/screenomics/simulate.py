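"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters including the seed,
so downstream expectations (planted essential genes, planted drivers,
requested pathway topologies, true IC50s) can be asserted exactly.  Read
counts are negative-binomial because pooled-screen counts are
overdispersed; essential genes have the depletion effect applied to all
of their hairpins, with an optional per-hairpin efficacy jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .screen import GeneScore, HitCall, ShRNACountRecord
from .store import MutationRecord, OmicsStore, ProteinRecord
from .pathways import PathwayGraph, build_pathway_graph


@dataclass(frozen=True)
class ScreenTruth:
    essential_genes: frozenset[str]
    effect_log2: float
    n_genes: int
    shrnas_per_gene: int
    depth: float
    dispersion: float
    seed: int


@dataclass(frozen=True)
class OmicsTruth:
    """Planted per-line gene sets; functional signature should recover
    exactly ``drivers`` for each line."""

    drivers: dict[str, tuple[str, ...]]
    altered: dict[str, frozenset[str]]
    hits: dict[str, frozenset[str]]
    oncogenes: frozenset[str]
    drug_map: dict[str, tuple[str, ...]]
    seed: int


@dataclass(frozen=True)
class DoseResponseTruth:
    ic50: float
    hill: float
    top: float
    floor: float
    noise_sd: float
    seed: int


def _neg_binomial(rng: np.random.Generator, mean, dispersion: float, size):
    """NB with var = m + dispersion * m^2; dispersion 0 degrades to Poisson."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if dispersion == 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def simulate_screen(
    n_genes: int = 15000,
    shrnas_per_gene: int = 5,
    frac_essential: float = 0.02,
    effect_log2: float = 4.0,
    depth: float = 500.0,
    dispersion: float = 0.05,
    efficacy_jitter_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[ShRNACountRecord], ScreenTruth]:
    """Pooled dropout screen: reference counts at transduction, final counts
    after outgrowth, with essential genes' hairpins depleted 2**effect_log2
    fold in expectation."""
    if not 0 <= frac_essential < 1:
        raise ValueError("frac_essential must be in [0, 1)")
    if effect_log2 < 0:
        raise ValueError("effect_log2 must be non-negative")
    if n_genes < 1 or shrnas_per_gene < 1:
        raise ValueError("n_genes and shrnas_per_gene must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_ess = int(round(frac_essential * n_genes))
    essential = rng.choice(n_genes, size=n_ess, replace=False)
    is_ess = np.zeros(n_genes, dtype=bool)
    is_ess[essential] = True

    shape = (n_genes, shrnas_per_gene)
    ref = _neg_binomial(rng, depth, dispersion, shape)
    effect = np.where(is_ess[:, None], effect_log2, 0.0)
    if efficacy_jitter_sd > 0:
        jitter = np.clip(
            1.0 + rng.normal(0.0, efficacy_jitter_sd, shape), 0.0, None
        )
        effect = effect * jitter
    final_mean = depth / 2.0**effect
    fin = _neg_binomial(rng, final_mean, dispersion, shape)

    records = [
        ShRNACountRecord(
            shrna_id=f"{genes[g]}_sh{j}",
            gene=genes[g],
            count_ref=int(ref[g, j]),
            count_final=int(fin[g, j]),
        )
        for g in range(n_genes)
        for j in range(shrnas_per_gene)
    ]
    truth = ScreenTruth(
        essential_genes=frozenset(genes[i] for i in essential),
        effect_log2=effect_log2,
        n_genes=n_genes,
        shrnas_per_gene=shrnas_per_gene,
        depth=depth,
        dispersion=dispersion,
        seed=seed,
    )
    return records, truth


def simulate_omics(
    n_lines: int = 1,
    n_genes: int = 60,
    n_drivers: int = 3,
    seed: int = 0,
    out_dir=None,
    line_names: Sequence[str] | None = None,
) -> tuple[OmicsStore, OmicsTruth]:
    """Omics store with planted drivers per line.

    Each planted driver is amplified (or carries a high-occurrence COSMIC
    mutation), annotated as an oncogene, overexpressed, drug-mapped and a
    screen hit, so the functional signature recovers exactly the planted
    set.  Background genes are assigned at most two of the three
    predicates (altered / oncogene / hit) so no background gene can leak
    into the functional signature.
    """
    if n_drivers > n_genes:
        raise ValueError("planted drivers cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    lines = (
        list(line_names)
        if line_names is not None
        else [f"LINE{i:02d}" for i in range(n_lines)]
    )

    # Oncogene annotations are a property of the gene, not the cell line, so
    # the set is fixed globally; per-line drivers are drawn from it.  A
    # non-driver oncogene is never both altered and a hit in the same line,
    # which guarantees the functional signature equals the planted drivers.
    n_onco = max(n_drivers, int(round(0.3 * n_genes)))
    oncogenes: set[str] = {
        genes[i] for i in rng.choice(n_genes, size=n_onco, replace=False)
    }
    onco_pool = sorted(oncogenes)
    drug_map: dict[str, tuple[str, ...]] = {}
    cna_rows, expr_rows, mut_rows = [], [], []
    hits: dict[str, list[HitCall]] = {}
    truth_drivers: dict[str, tuple[str, ...]] = {}
    truth_altered: dict[str, frozenset[str]] = {}
    truth_hits: dict[str, frozenset[str]] = {}

    onco_classes = ("none", "alt", "hit")
    other_classes = ("none", "alt", "hit", "alt+hit")

    for line in lines:
        driver_genes = tuple(
            sorted(rng.choice(onco_pool, size=n_drivers, replace=False))
        )
        truth_drivers[line] = driver_genes
        altered: set[str] = set()
        hit_genes: set[str] = set()
        line_scores: dict[str, float] = {}

        for g in driver_genes:
            altered.add(g)
            hit_genes.add(g)
            if rng.random() < 0.5:
                cna_rows.append((line, g, float(rng.uniform(1.0, 4.5))))
            else:
                cna_rows.append((line, g, float(rng.uniform(-0.2, 0.2))))
                mut_rows.append(
                    MutationRecord(
                        cell_line=line, gene=g,
                        protein_change=f"{g}p.H{int(rng.integers(100, 999))}R",
                        cosmic_occurrences=int(rng.integers(10, 2000)),
                        hotspot=True,
                    )
                )
            expr_rows.append((line, g, float(rng.uniform(1.0, 3.0))))
            line_scores[g] = float(rng.uniform(2.5, 6.0))
            if g not in drug_map:
                n_drugs = int(rng.integers(1, 4))
                drug_map[g] = tuple(f"DRUG-{g}-{k}" for k in range(n_drugs))

        for gi in range(n_genes):
            g = genes[gi]
            if g in driver_genes:
                continue
            classes = onco_classes if g in oncogenes else other_classes
            cls = classes[int(rng.integers(0, len(classes)))]
            amp = "alt" in cls and rng.random() < 0.7
            mut = "alt" in cls and not amp
            cna_rows.append(
                (line, g,
                 float(rng.uniform(1.0, 3.0)) if amp
                 else float(rng.uniform(-0.4, 0.4)))
            )
            if mut:
                mut_rows.append(
                    MutationRecord(
                        cell_line=line, gene=g,
                        protein_change=f"{g}p.G{int(rng.integers(10, 99))}D",
                        cosmic_occurrences=int(rng.integers(6, 500)),
                        hotspot=bool(rng.random() < 0.5),
                    )
                )
            if "alt" in cls:
                altered.add(g)
            if "hit" in cls:
                hit_genes.add(g)
                line_scores[g] = float(rng.uniform(1.5, 2.4))
                if g not in drug_map and rng.random() < 0.5:
                    drug_map[g] = (f"DRUG-{g}-0",)
            else:
                line_scores[g] = float(rng.normal(0.0, 0.4))
            expr_rows.append((line, g, float(rng.normal(0.0, 0.5))))

        order = sorted(line_scores, key=lambda g: (-line_scores[g], g))
        hits[line] = [
            HitCall(gene=g, quant_log=line_scores[g], rank=r,
                    is_hit=g in hit_genes)
            for r, g in enumerate(order, start=1)
        ]
        truth_altered[line] = frozenset(altered)
        truth_hits[line] = frozenset(hit_genes)

    store = OmicsStore(
        cna=pd.DataFrame(cna_rows, columns=["cell_line", "gene", "dna_amp"]),
        expression=pd.DataFrame(
            expr_rows, columns=["cell_line", "gene", "expression_lfc"]
        ),
        expression_dialect="vs_normal",
        mutations=mut_rows,
        hits=hits,
        oncogenes=frozenset(oncogenes),
        drugs=drug_map,
        proteins=[],
    )
    truth = OmicsTruth(
        drivers=truth_drivers,
        altered=truth_altered,
        hits=truth_hits,
        oncogenes=frozenset(oncogenes),
        drug_map=dict(drug_map),
        seed=seed,
    )
    if out_dir is not None:
        from .io import write_store

        write_store(store, out_dir)
    return store, truth


def make_toy_kgml(
    out_path,
    n_nodes: int = 10,
    edges: Sequence[tuple[str, str]] | None = None,
    density: float | None = None,
    multi_gene_entry_fraction: float = 0.0,
    seed: int = 0,
    pathway_id: str = "path:toy00001",
    title: str = "Toy pathway",
    gene_prefix: str = "PW",
) -> tuple[Path, PathwayGraph]:
    """Write a valid KGML file and return it with the expected gene graph.

    Gene symbols are PW0000, PW0001, ...  With
    ``multi_gene_entry_fraction`` > 0 some entries carry several gene ids,
    and relations touching them expand to all their genes (the expected
    graph returned accounts for the expansion).  Edges may be given as
    symbol pairs; otherwise they are sampled at the requested density.
    """
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    symbols = [f"{gene_prefix}{i:04d}" for i in range(n_nodes)]

    # Assign genes to entries.
    entries: list[list[str]] = []
    i = 0
    while i < n_nodes:
        if multi_gene_entry_fraction > 0 and rng.random() < multi_gene_entry_fraction:
            size = int(min(rng.integers(2, 4), n_nodes - i))
        else:
            size = 1
        entries.append(symbols[i : i + size])
        i += size
    entry_of = {g: idx for idx, group in enumerate(entries) for g in group}

    if edges is None:
        edges = []
        if density:
            for a in range(n_nodes):
                for b in range(a + 1, n_nodes):
                    if rng.random() < density:
                        edges.append((symbols[a], symbols[b]))

    # Relations connect entries; expected edges expand entry-by-entry.
    relations: set[tuple[int, int]] = set()
    for u, v in edges:
        e1, e2 = entry_of[u], entry_of[v]
        if e1 != e2:
            relations.add((min(e1, e2), max(e1, e2)))
    expected_edges = [
        (g1, g2)
        for e1, e2 in sorted(relations)
        for g1 in entries[e1]
        for g2 in entries[e2]
    ]

    lines = [
        '<?xml version="1.0"?>',
        f'<pathway name="{pathway_id}" org="hsa" number="1" title="{title}">',
    ]
    for idx, group in enumerate(entries, start=1):
        names = " ".join(f"hsa:{g}" for g in group)
        lines.append(
            f'  <entry id="{idx}" name="{names}" type="gene">'
            f'<graphics name="{group[0]}" type="rectangle"/></entry>'
        )
    for e1, e2 in sorted(relations):
        lines.append(
            f'  <relation entry1="{e1 + 1}" entry2="{e2 + 1}" type="PPrel">'
            '<subtype name="activation" value="--&gt;"/></relation>'
        )
    lines.append("</pathway>")
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    expected = build_pathway_graph(pathway_id, title, symbols, expected_edges)
    return out_path, expected


def simulate_dose_response(
    ic50: float = 1.0,
    hill: float = 1.0,
    top: float = 1.0,
    floor: float = 0.0,
    noise_sd: float = 0.0,
    concentrations: Sequence[float] | None = None,
    seed: int = 0,
):
    """Four-parameter-logistic dose-response with optional Gaussian noise
    (truncated at zero).  Default concentrations: 9 log-spaced points over
    0.01-100 µM."""
    from .doseresponse import DoseResponse

    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if concentrations is None:
        concentrations = np.logspace(-2, 2, 9)
    c = np.asarray(concentrations, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    y = floor + (top - floor) / (1.0 + (c / ic50) ** hill)
    if noise_sd > 0:
        y = np.clip(y + rng.normal(0.0, noise_sd, c.shape), 0.0, None)
    dr = DoseResponse(
        concentrations=tuple(float(v) for v in c),
        surviving_fraction=tuple(float(v) for v in y),
    )
    truth = DoseResponseTruth(
        ic50=ic50, hill=hill, top=top, floor=floor, noise_sd=noise_sd, seed=seed
    )
    return dr, truth
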