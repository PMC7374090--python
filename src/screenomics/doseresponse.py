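"""Dose-response IC50 estimation and panel drug-sensitivity Z-scores.

IC50s come from a four-parameter logistic (4PL) least-squares fit on log10
concentration; when the response is too flat or non-sigmoid for that fit,
a LOESS fallback (local linear regression, tricube weights, span as a
fraction of the data) traces the curve and the IC50 is read off where the
fit crosses a surviving fraction of 0.5, with the error obtained by
inverting the 95% prediction interval at the crossing.

A cell line's sensitivity to a drug is summarised as a Z-score of its log
IC50 against the panel's geometric-mean IC50; Z <= -1.5 flags high
sensitivity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import NoCrossingError, NonSigmoidError
from .screen import CeresRecord, HitCall

SENSITIVITY_CUT = -1.5
LOESS_GRID_POINTS = 1000


@dataclass(frozen=True)
class DoseResponse:
    """Endpoint summary of one drug on one cell line: surviving fraction
    (viable cells at endpoint over cells before treatment) at each tested
    concentration in µM."""

    concentrations: tuple[float, ...]
    surviving_fraction: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.surviving_fraction, dtype=float)
        if c.shape != y.shape:
            raise ValueError("concentration and response lengths differ")
        if np.any(c <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.any(y < 0):
            raise ValueError("surviving fractions must be non-negative")

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.surviving_fraction, dtype=float)
        order = np.argsort(c)
        return c[order], y[order]


@dataclass(frozen=True)
class IC50Estimate:
    ic50: float
    error: float
    method: str  # "sigmoid-fit" | "loess-inversion"


@dataclass(frozen=True)
class PanelStats:
    """Externally supplied panel statistics on the natural-log IC50 scale
    (mean_log is the log of the geometric mean)."""

    mean_log: float
    sd_log: float


@dataclass(frozen=True)
class DrugZScore:
    cell_line: str
    drug: str
    ic50: float
    z: float
    sensitive: bool


def _four_pl(x, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (x - log_ic50)))


def fit_sigmoid_ic50(dr: DoseResponse) -> IC50Estimate:
    """Four-parameter logistic fit on log10 concentration.

    The IC50 is the fitted midpoint; the error is the standard error of
    the midpoint propagated to concentration units.  Raises
    NonSigmoidError when the response never approaches half-maximum or
    the optimiser fails; callers should then fall back to loess_ic50.
    """
    c, y = dr.arrays()
    if len(np.unique(c)) < 4:
        raise NonSigmoidError("need >= 4 distinct concentrations")
    top, bottom = float(y.max()), float(y.min())
    if top - bottom < 1e-9 or bottom > 0.5 * top:
        raise NonSigmoidError("response does not span the half-maximal level")
    x = np.log10(c)
    mid = (top + bottom) / 2.0
    x0 = float(x[np.argmin(np.abs(y - mid))])
    try:
        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            # noiseless data gives an exactly singular covariance; the SE
            # then degrades to 0 below rather than warning
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                _four_pl, x, y, p0=[top, bottom, x0, 1.0], maxfev=20000
            )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise NonSigmoidError(f"4PL fit failed to converge: {exc}") from exc
    top_f, bottom_f, log_ic50, hill = popt
    if not np.isfinite(log_ic50) or abs(top_f - bottom_f) < 1e-9:
        raise NonSigmoidError("degenerate 4PL fit")
    ic50 = float(10.0 ** log_ic50)
    var = pcov[2, 2] if np.all(np.isfinite(pcov)) else np.nan
    se_log = math.sqrt(var) if np.isfinite(var) and var >= 0 else 0.0
    return IC50Estimate(
        ic50=ic50, error=math.log(10.0) * ic50 * se_log, method="sigmoid-fit"
    )


def _loess_weights(x: np.ndarray, x0: float, k: int) -> np.ndarray:
    """Tricube weights over the k nearest neighbours of x0 (zero elsewhere)."""
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    if h == 0:
        return (d == 0).astype(float)
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    if w.sum() == 0:
        w = (d <= h).astype(float)
    return w


def _loess_l_vector(x: np.ndarray, x0: float, k: int) -> np.ndarray:
    """Linear-smoother vector l with fitted value l @ y at x0
    (weighted local linear fit; falls back to a weighted mean when the
    design is singular, e.g. all neighbours at the same x)."""
    w = _loess_weights(x, x0, k)
    xc = x - x0
    s0, s1, s2 = w.sum(), (w * xc).sum(), (w * xc * xc).sum()
    det = s0 * s2 - s1 * s1
    if det <= 1e-12 * max(s0 * s2, 1e-300):
        return w / w.sum()
    return (s2 - s1 * xc) * w / det


def loess_ic50(
    dr: DoseResponse,
    span: float = 1.0,
    grid_points: int = LOESS_GRID_POINTS,
    level: float = 0.95,
) -> IC50Estimate:
    """LOESS-traced IC50 with prediction-interval inversion.

    Fits a local linear regression (tricube weights; the span is the
    fraction of points in each local window) of surviving fraction on
    log10 concentration, evaluates it on a log-spaced grid across the
    tested range, and takes the first grid concentration where the curve
    crosses 0.5.  The error is half the width, in concentration units, of
    the inverted prediction interval at the crossing (t quantile on n - 2
    degrees of freedom, residual variance from the in-sample fit).
    """
    c, y = dr.arrays()
    n = len(c)
    if n < 4:
        raise NonSigmoidError("need >= 4 concentrations for LOESS")
    x = np.log10(c)
    k = min(n, max(2, math.ceil(span * n)))
    grid = np.linspace(x.min(), x.max(), grid_points)

    l_vectors = np.array([_loess_l_vector(x, g, k) for g in grid])
    fitted_grid = l_vectors @ y
    in_sample = np.array([_loess_l_vector(x, xi, k) @ y for xi in x])
    dof = max(1, n - 2)
    s2 = float(((y - in_sample) ** 2).sum() / dof)
    t_mult = stats.t.ppf(0.5 + level / 2.0, dof)
    half_width = t_mult * np.sqrt(s2 * (1.0 + (l_vectors**2).sum(axis=1)))

    def first_crossing(curve: np.ndarray) -> int | None:
        below = curve <= 0.5
        if below[0] or not below.any():
            return None
        return int(np.argmax(below))

    idx = first_crossing(fitted_grid)
    if idx is None:
        raise NoCrossingError(
            "LOESS curve does not cross surviving fraction 0.5 within the "
            "tested concentration range"
        )
    ic50 = float(10.0 ** grid[idx])

    lo_idx = first_crossing(fitted_grid - half_width)
    hi_idx = first_crossing(fitted_grid + half_width)
    c_lo = float(10.0 ** grid[lo_idx]) if lo_idx is not None else float(c.min())
    c_hi = float(10.0 ** grid[hi_idx]) if hi_idx is not None else float(c.max())
    return IC50Estimate(
        ic50=ic50, error=abs(c_hi - c_lo) / 2.0, method="loess-inversion"
    )


def estimate_ic50(dr: DoseResponse, method: str = "auto", span: float = 1.0) -> IC50Estimate:
    """Dispatch: 'sigmoid', 'loess', or 'auto' (sigmoid with LOESS fallback)."""
    if method == "sigmoid":
        return fit_sigmoid_ic50(dr)
    if method == "loess":
        return loess_ic50(dr, span=span)
    if method != "auto":
        raise ValueError(f"unknown IC50 method {method!r}")
    try:
        return fit_sigmoid_ic50(dr)
    except NonSigmoidError:
        return loess_ic50(dr, span=span)


def drug_zscores(
    ic50s: Mapping[str, float],
    drug: str = "",
    panel_stats: PanelStats | None = None,
    cut: float = SENSITIVITY_CUT,
    log_scale: bool = True,
) -> list[DrugZScore]:
    """Standardise each cell line's IC50 against the panel.

    Default (log_scale=True): z = (ln IC50 - ln geometric-mean IC50) / sd
    of the panel's natural-log IC50s (sample sd, n - 1); this makes z
    invariant to rescaling every IC50 by a positive constant.  The
    raw-scale alternative (z = (IC50 - geometric mean) / sd of raw IC50s)
    is kept behind log_scale=False.  Panel statistics default to the
    supplied map itself but can be given externally (e.g. a large
    reference panel).  Sensitivity is inclusive: z <= cut.
    """
    lines = sorted(ic50s)
    vals = np.array([float(ic50s[line]) for line in lines])
    if np.any(vals <= 0):
        bad = lines[int(np.argmax(vals <= 0))]
        raise ValueError(f"non-positive IC50 for cell line {bad!r}")
    logs = np.log(vals)
    if panel_stats is None:
        if len(vals) < 2:
            raise ValueError("need >= 2 cell lines without external panel stats")
        mean_log = float(logs.mean())
        sd_log = float(logs.std(ddof=1))
    else:
        mean_log, sd_log = panel_stats.mean_log, panel_stats.sd_log
    if log_scale:
        if sd_log == 0:
            z = np.zeros_like(logs)
        else:
            z = (logs - mean_log) / sd_log
    else:
        gm = math.exp(mean_log)
        sd_raw = float(vals.std(ddof=1)) if panel_stats is None else sd_log
        z = np.zeros_like(vals) if sd_raw == 0 else (vals - gm) / sd_raw
    return [
        DrugZScore(
            cell_line=line, drug=drug, ic50=float(v), z=float(zi),
            sensitive=bool(zi <= cut),
        )
        for line, v, zi in zip(lines, vals, z)
    ]


def essentiality_vs_sensitivity(
    zscores: Sequence[DrugZScore],
    gene_effects: Mapping[str, CeresRecord | HitCall],
) -> tuple[list[dict], int]:
    """Join drug sensitivity with gene essentiality per cell line.

    ``gene_effects`` maps cell line to that line's effect record for the
    gene of interest (a CERES record or an shRNA hit call).  Returns the
    inner-joined rows and the concordance count — the number of lines
    where the hit flag agrees with the sensitivity flag.
    """
    z_by_line = {z.cell_line: z for z in zscores}
    shared = sorted(set(z_by_line) & set(gene_effects))
    if not shared:
        raise ValueError("no cell lines shared between z-scores and gene effects")
    rows = []
    n_concordant = 0
    for line in shared:
        z = z_by_line[line]
        eff = gene_effects[line]
        score = eff.ceres if isinstance(eff, CeresRecord) else eff.quant_log
        concordant = eff.is_hit == z.sensitive
        n_concordant += concordant
        rows.append(
            {
                "cell_line": line, "z": z.z, "effect": score,
                "is_hit": eff.is_hit, "sensitive": z.sensitive,
                "concordant": concordant,
            }
        )
    return rows, n_concordant
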