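"""Gene-level essentiality scoring for pooled shRNA dropout screens.

The pipeline turns per-hairpin read counts at two time points into
fold-depletion scores, summarises each gene by an upper quantile of its
log-scale depletion scores, fits a robust normal null to the population of
gene scores (median for the centre, inter-quantile range for the spread)
and calls hits above the null's 95th percentile.  A companion rule flags
hits in CRISPR gene-effect tables (CERES scores).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateNullError

#: Standard-normal 95th percentile, pinned to 4 decimals for reproducibility.
Z95 = 1.6449

#: Default quantile level for the per-gene score (the "QuantLog" statistic).
GENE_QUANTILE = 0.80

#: Default per-gene quantile convention.  The discrete lower order statistic
#: guarantees that a gene's score never exceeds its 2nd-largest hairpin
#: score, hence every called hit is supported by at least two hairpins above
#: the cut.  Linear interpolation ("linear") is available as an alternative.
QUANTILE_METHOD = "lower"


@dataclass(frozen=True)
class ShRNACountRecord:
    """Read counts for one hairpin at the reference and final time points."""

    shrna_id: str
    gene: str
    count_ref: int
    count_final: int


@dataclass(frozen=True)
class DepletionScore:
    shrna_id: str
    gene: str
    fold_depletion: float
    log_depletion: float


@dataclass(frozen=True)
class GeneScore:
    gene: str
    quant_log: float
    n_shrnas: int
    rank: int


@dataclass(frozen=True)
class NullModel:
    """Robust normal null for the gene-score population.

    mu is the median of all gene scores; sigma is (q97.5 - q2.5) / 4, the
    inter-quantile range matched to +/- 2 standard deviations of a normal;
    threshold is the null's 95th percentile, mu + 1.6449 * sigma.
    """

    mu: float
    sigma: float
    threshold: float


@dataclass(frozen=True)
class HitCall:
    gene: str
    quant_log: float
    rank: int
    is_hit: bool


@dataclass(frozen=True)
class CeresRecord:
    gene: str
    ceres: float
    is_hit: bool


def compute_depletion_scores(
    counts: Iterable[ShRNACountRecord], pseudocount: float = 1.0
) -> list[DepletionScore]:
    """Fold depletion (count_ref + c) / (count_final + c) and its log2.

    A hairpin that drops out has a large fold depletion.  The pseudocount
    guards hairpins whose final count is zero; with pseudocount 0 such a
    hairpin raises a ValueError naming the shRNA.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    out = []
    for rec in counts:
        if rec.count_final + pseudocount == 0:
            raise ValueError(
                f"shRNA {rec.shrna_id!r}: count_final is 0 and pseudocount is 0"
            )
        fold = (rec.count_ref + pseudocount) / (rec.count_final + pseudocount)
        out.append(
            DepletionScore(
                shrna_id=rec.shrna_id,
                gene=rec.gene,
                fold_depletion=fold,
                log_depletion=math.log2(fold),
            )
        )
    return out


def gene_quantile_scores(
    depletions: Iterable[DepletionScore],
    min_shrnas: int = 2,
    quantile: float = GENE_QUANTILE,
    quantile_method: str = QUANTILE_METHOD,
) -> tuple[list[GeneScore], list[str]]:
    """Summarise each gene by an upper quantile of its log depletion scores.

    Using a quantile rather than the mean avoids bias from the varying
    number of hairpins per gene and is robust to the skew of the empirical
    distributions.  Genes with fewer than ``min_shrnas`` scores are not
    scored; they are returned in the second element (skipped list).  Ranks
    are 1-based, descending by score, ties broken lexicographically by gene
    symbol.
    """
    per_gene: dict[str, list[float]] = defaultdict(list)
    for d in depletions:
        per_gene[d.gene].append(d.log_depletion)
    if not per_gene:
        raise ValueError("no depletion scores supplied")

    skipped = sorted(g for g, v in per_gene.items() if len(v) < min_shrnas)
    scored = {
        g: float(np.quantile(np.asarray(v), quantile, method=quantile_method))
        for g, v in per_gene.items()
        if len(v) >= min_shrnas
    }
    order = sorted(scored, key=lambda g: (-scored[g], g))
    scores = [
        GeneScore(gene=g, quant_log=scored[g], n_shrnas=len(per_gene[g]), rank=i)
        for i, g in enumerate(order, start=1)
    ]
    return scores, skipped


def fit_null_model(
    scores: Sequence[GeneScore] | Sequence[float],
    lower_q: float = 0.025,
    upper_q: float = 0.975,
    min_scores: int = 40,
) -> NullModel:
    """Fit the robust normal null to the gene-score population.

    Assumes the large majority (>95%) of genes are not depleted, so the bulk
    of scores is normal: the median estimates the mean, and the 97.5th minus
    the 2.5th quantile divided by 4 estimates the standard deviation (95% of
    a normal lies within +/- 2 sd).  Both quantiles use linear interpolation.
    """
    vals = np.asarray(
        [s.quant_log if isinstance(s, GeneScore) else float(s) for s in scores],
        dtype=float,
    )
    if vals.size < min_scores:
        raise ValueError(
            f"need >= {min_scores} gene scores to fit the null, got {vals.size}"
        )
    mu = float(np.median(vals))
    sigma = float(
        (np.quantile(vals, upper_q) - np.quantile(vals, lower_q)) / 4.0
    )
    if sigma == 0.0:
        raise DegenerateNullError("all gene scores are equal; null sd is zero")
    return NullModel(mu=mu, sigma=sigma, threshold=mu + Z95 * sigma)


def call_hits(scores: Sequence[GeneScore], null: NullModel) -> list[HitCall]:
    """Flag genes whose score strictly exceeds the null's 95th percentile."""
    return [
        HitCall(gene=s.gene, quant_log=s.quant_log, rank=s.rank,
                is_hit=s.quant_log > null.threshold)
        for s in sorted(scores, key=lambda s: s.rank)
    ]


def score_screen(
    counts: Iterable[ShRNACountRecord],
    pseudocount: float = 1.0,
    min_shrnas: int = 2,
    quantile: float = GENE_QUANTILE,
    quantile_method: str = QUANTILE_METHOD,
) -> tuple[list[HitCall], NullModel, list[str]]:
    """Full pipeline: counts -> depletion -> gene scores -> null -> hit calls."""
    deps = compute_depletion_scores(counts, pseudocount=pseudocount)
    scores, skipped = gene_quantile_scores(
        deps, min_shrnas=min_shrnas, quantile=quantile,
        quantile_method=quantile_method,
    )
    null = fit_null_model(scores)
    return call_hits(scores, null), null, skipped


def hit_shrna_support(
    hits: Sequence[HitCall],
    depletions: Iterable[DepletionScore],
    null: NullModel,
) -> dict[str, int]:
    """Diagnostic: for each called hit, how many of its hairpins individually
    exceed the hit threshold.

    Under the default lower-order-statistic gene quantile every called hit
    with >= 2 hairpins is guaranteed a count of at least 2, since its gene
    score cannot exceed its 2nd-largest hairpin score.
    """
    per_gene: dict[str, int] = defaultdict(int)
    for d in depletions:
        if d.log_depletion > null.threshold:
            per_gene[d.gene] += 1
    return {h.gene: per_gene.get(h.gene, 0) for h in hits if h.is_hit}


def ceres_hits(
    records: Mapping[str, float], threshold: float = -0.5
) -> list[CeresRecord]:
    """Apply the CRISPR gene-effect hit rule: CERES score <= threshold.

    The comparison is inclusive: a score exactly at the threshold is a hit.
    More negative CERES scores indicate stronger essentiality.
    """
    out = []
    for gene in sorted(records):
        val = float(records[gene])
        if not math.isfinite(val):
            raise ValueError(f"non-finite CERES score for gene {gene!r}")
        out.append(CeresRecord(gene=gene, ceres=val, is_hit=val <= threshold))
    return out
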