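"""Elongation-rate estimation from wave-call series.

The headline rate is the slope (bp/min) of an ordinary least-squares
regression of wave distance on time, pooled over every (gene, timepoint)
call that survived the series filter; the intercept is included (a
configurable through-origin toggle exists, but forcing the origin biases
the slope whenever the wave has a positional offset).

Two uncertainty procedures accompany the point estimate: a bootstrap that
resamples 10% of the called genes with replacement 1000 times and refits
the pooled slope, and a more conservative gene-by-gene distribution of
per-gene OLS slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hmm import WaveCall

__all__ = ["RateEstimate", "fit_rate", "bootstrap_rate", "per_gene_rates", "compare_rates"]


@dataclass
class RateEstimate:
    slope: float  # bp/min
    intercept: float  # bp
    r_squared: float
    n_points: int
    n_genes: int
    per_gene_slopes: dict[str, float] = field(default_factory=dict)
    bootstrap_slopes: np.ndarray | None = None
    bootstrap_fraction: float = 0.10
    bootstrap_reps: int = 1000
    bootstrap_seed: int | None = None

    @property
    def gene_slope_mean(self) -> float:
        return float(np.mean(list(self.per_gene_slopes.values())))

    @property
    def gene_slope_sd(self) -> float:
        return float(np.std(list(self.per_gene_slopes.values()), ddof=1))

    def bootstrap_interval(self, level: float = 0.95) -> tuple[float, float]:
        if self.bootstrap_slopes is None:
            raise ValueError("no bootstrap distribution attached")
        a = (1 - level) / 2
        lo, hi = np.quantile(self.bootstrap_slopes, [a, 1 - a])
        return float(lo), float(hi)


def _points(calls_by_gene: dict[str, list[WaveCall]]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    t, d, gid = [], [], []
    for g, calls in calls_by_gene.items():
        for c in calls:
            t.append(c.timepoint)
            d.append(c.distance_bp)
            gid.append(g)
    return np.asarray(t, float), np.asarray(d, float), gid


def _ols(t: np.ndarray, d: np.ndarray, through_origin: bool) -> tuple[float, float, float]:
    if through_origin:
        slope = float((t * d).sum() / (t * t).sum())
        pred = slope * t
        inter = 0.0
    else:
        res = stats.linregress(t, d)
        slope, inter = float(res.slope), float(res.intercept)
        pred = slope * t + inter
    ss_res = float(((d - pred) ** 2).sum())
    ss_tot = float(((d - d.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, inter, r2


def fit_rate(
    calls_by_gene: dict[str, list[WaveCall]], through_origin: bool = False
) -> RateEstimate:
    """Pooled OLS of distance (bp) on time (min) over all gene x timepoint calls."""
    t, d, gid = _points(calls_by_gene)
    if np.unique(t).size < 2:
        raise ValueError("need calls at >= 2 distinct timepoints to fit a rate")
    slope, inter, r2 = _ols(t, d, through_origin)
    est = RateEstimate(slope, inter, r2, len(t), len(calls_by_gene))
    est.per_gene_slopes = per_gene_rates(calls_by_gene)
    return est


def per_gene_rates(calls_by_gene: dict[str, list[WaveCall]]) -> dict[str, float]:
    """Per-gene OLS slopes; genes with fewer than 2 timepoints are skipped."""
    slopes = {}
    skipped = 0
    for gid, calls in calls_by_gene.items():
        t = np.array([c.timepoint for c in calls], float)
        d = np.array([c.distance_bp for c in calls], float)
        if np.unique(t).size < 2:
            skipped += 1
            continue
        slopes[gid] = _ols(t, d, through_origin=False)[0]
    if skipped:
        import warnings

        warnings.warn(f"{skipped} genes skipped in per-gene rates (< 2 timepoints)")
    return slopes


def bootstrap_rate(
    calls_by_gene: dict[str, list[WaveCall]],
    fraction: float = 0.10,
    reps: int = 1000,
    seed: int | None = None,
    through_origin: bool = False,
) -> np.ndarray:
    """Distribution of pooled slopes over gene resamples.

    Each replicate draws ``ceil(fraction * n_genes)`` genes with
    replacement and refits the pooled regression on their calls.
    """
    genes = sorted(calls_by_gene)
    n = len(genes)
    if n < 10:
        raise ValueError(f"bootstrap needs >= 10 genes, got {n}")
    k = int(np.ceil(fraction * n))
    if k < 2:
        raise ValueError(f"fraction {fraction} yields {k} gene(s) per replicate; need >= 2")
    rng = np.random.default_rng(seed)
    slopes = np.empty(reps)
    for r in range(reps):
        pick = rng.choice(genes, size=k, replace=True)
        t, d = [], []
        for g in pick:
            for c in calls_by_gene[g]:
                t.append(c.timepoint)
                d.append(c.distance_bp)
        slopes[r] = _ols(np.asarray(t), np.asarray(d), through_origin)[0]
    return slopes


def compare_rates(advancing: RateEstimate, clearing: RateEstimate) -> dict[str, float]:
    """Compare two wave populations' rates.

    Reports the pooled-slope difference, a Welch t-test on the per-gene
    slope distributions, and (when both carry bootstrap draws) a
    bootstrap overlap p: twice the smaller tail fraction of
    pairwise differences crossing zero.
    """
    a = np.array(list(advancing.per_gene_slopes.values()))
    c = np.array(list(clearing.per_gene_slopes.values()))
    if a.size == 0 or c.size == 0:
        raise ValueError("both estimates need per-gene slopes")
    t = stats.ttest_ind(c, a, equal_var=False)
    out = {
        "difference": clearing.slope - advancing.slope,
        "welch_t": float(t.statistic),
        "welch_p": float(t.pvalue),
    }
    if advancing.bootstrap_slopes is not None and clearing.bootstrap_slopes is not None:
        diff = clearing.bootstrap_slopes[:, None] - advancing.bootstrap_slopes[None, :]
        frac = float((diff <= 0).mean())
        out["bootstrap_overlap_p"] = 2 * min(frac, 1 - frac)
    return out
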