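"""Statistics used to technically validate the database.

Includes fixed-width histograms and their intersection similarity, subsample
stability checks, extinction-coefficient range/percentile flagging, the
empirical oscillator-strength -> extinction conversion, MAE, OLS regression
with a mean-response confidence band, Tukey quartile summaries, Spearman rank
correlation and solvent normalization/tallying.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "Histogram",
    "SummaryStats",
    "EpsilonFlagSet",
    "RegressionResult",
    "QuartileSummary",
    "SolventTally",
    "EPSILON_RANGE",
    "SOLVENT_DIELECTRICS",
    "SOLVENT_ALIASES",
    "build_histogram",
    "histogram_intersection",
    "summary_stats",
    "subsample_stability",
    "epsilon_flags",
    "epsilon_from_oscillator",
    "mae",
    "regression_with_ci",
    "quartile_summary",
    "spearman_corr",
    "solvent_tally",
]

#: Physically plausible extinction-coefficient range, L mol-1 cm-1 (inclusive).
EPSILON_RANGE = (1e3, 5e5)

#: Empirical conversion constant between oscillator strength and extinction.
OSCILLATOR_TO_EPSILON = 2.699e4

#: Static dielectric constants of the ten common spectroscopy solvents.
SOLVENT_DIELECTRICS = {
    "toluene": 2.38,
    "chloroform": 4.81,
    "tetrahydrofuran": 7.58,
    "dichloromethane": 8.93,
    "acetone": 20.7,
    "ethanol": 24.5,
    "methanol": 32.7,
    "acetonitrile": 37.5,
    "dimethylformamide": 38.3,
    "dimethyl sulfoxide": 46.7,
}

#: Spelling variants found in the literature, lower-cased.
SOLVENT_ALIASES = {
    "etoh": "ethanol",
    "meoh": "methanol",
    "mecn": "acetonitrile",
    "acn": "acetonitrile",
    "ch3cn": "acetonitrile",
    "dcm": "dichloromethane",
    "ch2cl2": "dichloromethane",
    "methylene chloride": "dichloromethane",
    "chcl3": "chloroform",
    "thf": "tetrahydrofuran",
    "dmso": "dimethyl sulfoxide",
    "dimethylsulfoxide": "dimethyl sulfoxide",
    "dimethyl sulphoxide": "dimethyl sulfoxide",
    "dmf": "dimethylformamide",
    "n,n-dimethylformamide": "dimethylformamide",
    "phme": "toluene",
    "me2co": "acetone",
}


class EmptySampleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


@dataclass
class Histogram:
    """Counts over left-closed right-open bins [origin + k*w, origin + (k+1)*w)."""

    origin: float
    bin_width: float
    counts: list[int]
    n_total: int

    def proportions(self) -> np.ndarray:
        if self.n_total == 0:
            raise EmptySampleError("empty histogram has no proportions")
        return np.asarray(self.counts, dtype=float) / self.n_total

    def edges(self) -> np.ndarray:
        return self.origin + self.bin_width * np.arange(len(self.counts) + 1)


def build_histogram(values: Sequence[float], origin: float, bin_width: float) -> Histogram:
    """Bin ``values`` with the half-open convention; values below ``origin``
    are rejected."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return Histogram(origin=origin, bin_width=bin_width, counts=[], n_total=0)
    if np.any(arr < origin):
        raise ValueError("values below the histogram origin")
    idx = np.floor((arr - origin) / bin_width).astype(int)
    counts = np.bincount(idx).tolist()
    return Histogram(origin=origin, bin_width=bin_width, counts=counts, n_total=int(arr.size))


def histogram_intersection(h1: Histogram, h2: Histogram) -> float:
    """Sum of bin-wise minima of the two normalized histograms, in [0, 1].

    Proportions (not raw counts) are compared so unequal sample sizes are
    treated fairly; the histograms must share origin and bin width.
    """
    if h1.n_total == 0 or h2.n_total == 0:
        raise EmptySampleError("histogram intersection undefined for empty histograms")
    if h1.origin != h2.origin or h1.bin_width != h2.bin_width:
        raise ValueError("histograms differ in origin/bin width; rebin first")
    p1 = h1.proportions()
    p2 = h2.proportions()
    n = max(p1.size, p2.size)
    p1 = np.pad(p1, (0, n - p1.size))
    p2 = np.pad(p2, (0, n - p2.size))
    return float(np.minimum(p1, p2).sum())


# ---------------------------------------------------------------------------
# Summary statistics and subsample stability
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    mean: float
    std: float
    median: float
    skew: float
    n: int


def summary_stats(values: Sequence[float]) -> SummaryStats:
    """Mean, sample std, median and the adjusted Fisher-Pearson coefficient
    of skewness (bias-corrected third standardized moment)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise EmptySampleError("summary statistics need at least 2 values")
    return SummaryStats(
        mean=float(arr.mean()),
        std=float(arr.std(ddof=1)),
        median=float(np.median(arr)),
        skew=float(sps.skew(arr, bias=False)),
        n=int(arr.size),
    )


def subsample_stability(
    values: Sequence[float], fractions: Iterable[float], seed: int
) -> dict[float, SummaryStats]:
    """Summary statistics of seeded simple random subsamples (without
    replacement) at each fraction; fraction 1.0 is the full sample exactly."""
    arr = np.asarray(list(values), dtype=float)
    rng = np.random.default_rng(seed)
    out: dict[float, SummaryStats] = {}
    for frac in fractions:
        if not 0 < frac <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {frac}")
        if frac == 1.0:
            out[frac] = summary_stats(arr)
            continue
        k = int(round(frac * arr.size))
        if k < 2:
            raise EmptySampleError(f"fraction {frac} yields fewer than 2 values")
        idx = rng.choice(arr.size, size=k, replace=False)
        out[frac] = summary_stats(arr[idx])
    return out


# ---------------------------------------------------------------------------
# Extinction-coefficient checks
# ---------------------------------------------------------------------------

FLAG_OK = "ok"
FLAG_LOW = "low_percentile"
FLAG_HIGH = "high_percentile"
FLAG_OUT = "out_of_range"


@dataclass
class EpsilonFlagSet:
    """Per-value plausibility flags for extinction coefficients.

    Values outside the physical range are excluded from the percentile
    computation; among retained values, midrank percentiles below 20 or above
    90 are flagged as suspect exponents.
    """

    values: list[float]
    flags: list[str]
    low_threshold: float = 20.0
    high_threshold: float = 90.0

    def retained(self) -> list[float]:
        return [v for v, f in zip(self.values, self.flags) if f != FLAG_OUT]

    def flagged(self) -> list[int]:
        """Indices of all non-ok values."""
        return [i for i, f in enumerate(self.flags) if f != FLAG_OK]


def epsilon_flags(
    values: Sequence[float],
    low: float = 20.0,
    high: float = 90.0,
    value_range: tuple[float, float] = EPSILON_RANGE,
) -> EpsilonFlagSet:
    vals = [float(v) for v in values]
    lo, hi = value_range
    in_range = [lo <= v <= hi for v in vals]
    retained = np.asarray([v for v, ok in zip(vals, in_range) if ok])
    flags = [FLAG_OK if ok else FLAG_OUT for ok in in_range]
    if retained.size:
        # midrank percentile: ties get their average rank
        ranks = sps.rankdata(retained)
        pct = 100.0 * (ranks - 0.5) / retained.size
        it = iter(pct)
        for i, ok in enumerate(in_range):
            if not ok:
                continue
            p = next(it)
            if p < low:
                flags[i] = FLAG_LOW
            elif p > high:
                flags[i] = FLAG_HIGH
    return EpsilonFlagSet(values=vals, flags=flags, low_threshold=low, high_threshold=high)


def epsilon_from_oscillator(f: float, b: float) -> float:
    """Empirical conversion eps = f * 2.699e4 / b, with line width ``b``."""
    if b <= 0:
        raise ValueError(f"line width b must be > 0, got {b}")
    if f < 0:
        raise ValueError(f"oscillator strength must be >= 0, got {f}")
    return f * OSCILLATOR_TO_EPSILON / b


# ---------------------------------------------------------------------------
# Paired comparison statistics
# ---------------------------------------------------------------------------


def mae(pred: Sequence[float], obs: Sequence[float]) -> float:
    p = np.asarray(list(pred), dtype=float)
    o = np.asarray(list(obs), dtype=float)
    if p.size != o.size:
        raise ValueError(f"length mismatch: {p.size} vs {o.size}")
    if p.size == 0:
        raise EmptySampleError("MAE undefined for empty samples")
    return float(np.mean(np.abs(p - o)))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    conf_level: float
    x: np.ndarray
    mean_lower: np.ndarray
    mean_upper: np.ndarray


def regression_with_ci(
    x: Sequence[float], y: Sequence[float], conf: float = 0.98
) -> RegressionResult:
    """Ordinary least squares with a pointwise confidence band for the mean
    response at the observed x, at confidence level ``conf``."""
    import statsmodels.api as sm

    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.var(xa) == 0:
        raise ValueError("degenerate x: zero variance")
    design = sm.add_constant(xa)
    fit = sm.OLS(ya, design).fit()
    band = fit.get_prediction(design).conf_int(alpha=1 - conf)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        conf_level=conf,
        x=xa,
        mean_lower=band[:, 0],
        mean_upper=band[:, 1],
    )


@dataclass
class QuartileSummary:
    """Tukey box summary: quartiles, whiskers at the most extreme points
    within 1.5 IQR, everything beyond is an outlier."""

    lower_quartile: float
    median: float
    upper_quartile: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]


def quartile_summary(values: Sequence[float]) -> QuartileSummary:
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise EmptySampleError("quartile summary needs at least 4 values")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return QuartileSummary(
        lower_quartile=float(q1),
        median=float(med),
        upper_quartile=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=sorted(float(v) for v in outliers),
    )


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.var(sps.rankdata(xa)) == 0 or np.var(sps.rankdata(ya)) == 0:
        raise ValueError("zero rank variance")
    return float(sps.spearmanr(xa, ya).statistic)


# ---------------------------------------------------------------------------
# Solvents
# ---------------------------------------------------------------------------


@dataclass
class SolventTally:
    """Per-compound solvent counts ordered by increasing dielectric constant."""

    entries: list[tuple[str, int, float]] = field(default_factory=list)
    unrecognized: dict[str, int] = field(default_factory=dict)


def canonical_solvent(
    name: str, aliases: dict[str, str] | None = None
) -> str | None:
    """Map a printed solvent name onto its canonical spelling, or None."""
    table = dict(SOLVENT_ALIASES)
    if aliases:
        table.update({k.lower(): v for k, v in aliases.items()})
    low = name.strip().lower()
    if low in SOLVENT_DIELECTRICS:
        return low
    return table.get(low)


def solvent_tally(
    records,
    min_count: int = 100,
    aliases: dict[str, str] | None = None,
    dielectrics: dict[str, float] | None = None,
) -> SolventTally:
    """Count solvents across deduplicated records, once per compound,
    after normalizing spelling variants; order by dielectric constant."""
    eps_table = dict(SOLVENT_DIELECTRICS)
    if dielectrics:
        eps_table.update(dielectrics)
    counts: Counter[str] = Counter()
    unrecognized: Counter[str] = Counter()
    for record in records:
        seen: set[str] = set()
        raw_seen: set[str] = set()
        for entry in record.uvvis:
            if entry.solvent is None:
                continue
            canon = canonical_solvent(entry.solvent, aliases)
            if canon is None:
                raw_seen.add(entry.solvent.strip().lower())
            elif canon in eps_table:
                seen.add(canon)
            else:
                raw_seen.add(canon)
        counts.update(seen)
        unrecognized.update(raw_seen)
    entries = [
        (name, counts[name], eps_table[name])
        for name in counts
        if counts[name] >= min_count
    ]
    entries.sort(key=lambda t: t[2])
    return SolventTally(entries=entries, unrecognized=dict(unrecognized))


def _folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ N(mu, sigma^2); the expected MAE of a biased, noisy
    predictor.  Exposed for test oracles and reporting."""
    if sigma == 0:
        return abs(mu)
    return sigma * math.sqrt(2 / math.pi) * math.exp(-(mu**2) / (2 * sigma**2)) + mu * (
        1 - 2 * sps.norm.cdf(-mu / sigma)
    )
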