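"""Three-state left-to-right HMMs for calling Pol II advancing and clearing waves.

The observation sequence for a gene is the treated-minus-untreated
normalized PRO-seq signal summed in 50-bp windows along the gene strand.
A left-to-right HMM with states 1 -> 2 -> 3 (no backward transitions, no
skipping, initial state fixed to 1) segments that sequence:

* advancing variant: state 1 models the upstream region (-500..TSS) with a
  normal emission; states 2 (the wave of elevated difference) and 3 (the
  unaffected remainder) carry gamma emissions.  The wave front is the
  downstream edge of the last state-2 window, in bp from the TSS.
* clearing variant: all three states carry gamma emissions; state 1 is
  initialized from the first 1000 nt downstream of the TSS, state 2 models
  the cleared trough between the two waves and state 3 the signal ahead of
  the fast population.  The clearing-wave position is the boundary between
  states 2 and 3.  Observations are first clamped at ``tsmooth`` standard
  scores to restrain outlying windows.

Because differences can be negative, gamma emissions are evaluated on
values affinely shifted by the sequence minimum minus a small margin; the
shift is fixed before fitting and recorded, so it is invertible.

Fitting is Baum-Welch EM with exact weighted-MLE M-steps (so the data
log-likelihood is non-decreasing every iteration), followed by Viterbi
decoding with ties broken toward the earliest state transitions
(conservative, shorter wave distances).  Call quality requires a
Kullback-Leibler divergence > 1 between the fitted state-2 and state-3
emissions, and EM convergence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special, stats

from .tracks import Gene, SignalTrack, gene_profile

__all__ = [
    "Emission",
    "WindowedDiff",
    "WaveCall",
    "HmmFit",
    "LeftRightHMM",
    "windowed_difference",
    "fit_advancing_hmm",
    "fit_clearing_hmm",
    "kl_divergence",
    "filter_wave_series",
    "viterbi_bruteforce",
    "call_wave_cohort",
    "suggest_init_distance",
]

VAR_FLOOR = 1e-8
SHAPE_BOUNDS = (1e-3, 1e6)


# ---------------------------------------------------------------------------
# Emission distributions


@dataclass
class Emission:
    """A state emission: normal on the raw scale, or gamma on a shifted scale."""

    family: str  # "normal" | "gamma"
    params: tuple[float, float]  # normal: (mu, sigma); gamma: (shape, scale)
    shift: float = 0.0  # gamma densities are evaluated at x - shift

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        if self.family == "normal":
            mu, sigma = self.params
            return stats.norm.logpdf(x, mu, sigma)
        if self.family == "gamma":
            shape, scale = self.params
            return stats.gamma.logpdf(x - self.shift, shape, scale=scale)
        raise ValueError(f"unknown emission family {self.family!r}")

    @property
    def mean(self) -> float:
        if self.family == "normal":
            return self.params[0]
        return self.params[0] * self.params[1] + self.shift

    @property
    def variance(self) -> float:
        if self.family == "normal":
            return self.params[1] ** 2
        return self.params[0] * self.params[1] ** 2


def _weighted_normal_mle(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    wsum = w.sum()
    mu = float((w * x).sum() / wsum)
    var = float((w * (x - mu) ** 2).sum() / wsum)
    return mu, math.sqrt(max(var, VAR_FLOOR))


def _solve_gamma_shape(s: float) -> float:
    """Solve log(k) - digamma(k) = s for the gamma shape k (s > 0)."""
    if s <= 0:
        return SHAPE_BOUNDS[1]
    k = (3 - s + math.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)  # Minka's starting point
    k = min(max(k, SHAPE_BOUNDS[0]), SHAPE_BOUNDS[1])
    for _ in range(60):
        f = math.log(k) - special.digamma(k) - s
        fp = 1.0 / k - special.polygamma(1, k)
        step = f / fp
        k_new = k - step
        if not (SHAPE_BOUNDS[0] <= k_new <= SHAPE_BOUNDS[1]):
            k_new = min(max(k_new, SHAPE_BOUNDS[0]), SHAPE_BOUNDS[1])
        if abs(k_new - k) < 1e-12 * max(1.0, k):
            k = k_new
            break
        k = k_new
    return k


def _weighted_gamma_mle(x: np.ndarray, w: np.ndarray, shift: float) -> tuple[float, float]:
    y = np.maximum(x - shift, 1e-12)
    wsum = w.sum()
    ybar = float((w * y).sum() / wsum)
    logbar = float((w * np.log(y)).sum() / wsum)
    s = math.log(ybar) - logbar
    shape = _solve_gamma_shape(s)
    scale = ybar / shape
    if shape * scale**2 < VAR_FLOOR:  # degenerate segment: enforce a variance floor
        scale = math.sqrt(VAR_FLOOR / shape)
    return shape, scale


def _moment_emission(family: str, x: np.ndarray, shift: float) -> Emission:
    """Moment-matched initial emission for a segment of observations."""
    if family == "normal":
        mu = float(x.mean())
        sd = math.sqrt(max(float(x.var()), VAR_FLOOR))
        return Emission("normal", (mu, sd))
    y = np.maximum(x - shift, 1e-12)
    m, v = float(y.mean()), max(float(y.var()), VAR_FLOOR)
    shape = min(max(m * m / v, SHAPE_BOUNDS[0]), SHAPE_BOUNDS[1])
    return Emission("gamma", (shape, m / shape), shift)


# ---------------------------------------------------------------------------
# Windowed difference signal


@dataclass
class WindowedDiff:
    """Treated-minus-untreated normalized signal per 50-bp window along a gene."""

    gene_id: str
    timepoint: float
    window: int
    upstream: int  # bp of upstream extension included before the TSS
    values: np.ndarray
    gene_length: int

    @property
    def n_upstream(self) -> int:
        return self.upstream // self.window


def windowed_difference(
    treated: SignalTrack,
    untreated: SignalTrack,
    gene: Gene,
    window: int = 50,
    upstream: int = 500,
    timepoint: float | None = None,
) -> WindowedDiff:
    """Per-window difference in normalized signal from -upstream to the gene end.

    Windows tile from ``upstream`` bp before the TSS through the CPS; a
    partial final window is dropped.
    """
    if upstream % window:
        raise ValueError(f"upstream extension {upstream} not divisible by window {window}")
    span = upstream + gene.length
    n_win = span // window
    if n_win - upstream // window < 3:
        raise ValueError(
            f"gene {gene.gene_id} too short for wave calling: needs >= 3 gene-body "
            f"windows of {window} bp, has {n_win - upstream // window}"
        )
    hi = -upstream + n_win * window
    pt = gene_profile(treated, gene, "tss", -upstream, hi, normalized=True)
    pu = gene_profile(untreated, gene, "tss", -upstream, hi, normalized=True)
    diff = np.nan_to_num(pt, nan=0.0) - np.nan_to_num(pu, nan=0.0)
    values = diff.reshape(n_win, window).sum(axis=1)
    tp = timepoint if timepoint is not None else (treated.timepoint or 0.0)
    return WindowedDiff(gene.gene_id, float(tp), window, upstream, values, gene.length)


def tsmooth_clamp(values: np.ndarray, tsmooth: float) -> np.ndarray:
    """Clamp standardized window values at |z| <= tsmooth, then de-standardize."""
    sd = values.std()
    if sd == 0:
        return values.copy()
    mu = values.mean()
    z = np.clip((values - mu) / sd, -tsmooth, tsmooth)
    return mu + z * sd


# ---------------------------------------------------------------------------
# The HMM itself


@dataclass
class HmmFit:
    emissions: list[Emission]
    trans: np.ndarray
    log_likelihoods: list[float]
    converged: bool
    n_iter: int
    path: np.ndarray  # Viterbi state per window, values 0/1/2
    flags: list[str] = field(default_factory=list)


@dataclass
class WaveCall:
    gene_id: str
    timepoint: float
    distance_bp: float
    kl: float
    converged: bool
    quality_pass: bool
    init_distance: float
    variant: str


class LeftRightHMM:
    """3-state strictly left-to-right HMM (1 -> 2 -> 3, no skips), initial state 1."""

    def __init__(self, emissions: list[Emission], trans: np.ndarray | None = None):
        if len(emissions) != 3:
            raise ValueError("exactly three states required")
        self.emissions = emissions
        if trans is None:
            trans = np.array([[0.9, 0.1, 0.0], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]])
        self.trans = np.asarray(trans, dtype=float)
        self._check_trans()

    def _check_trans(self) -> None:
        A = self.trans
        if A.shape != (3, 3) or not np.allclose(A.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if A[1, 0] or A[2, 0] or A[2, 1] or A[0, 2]:
            raise ValueError("left-to-right topology violated (backward/skip transition)")

    def _log_b(self, obs: np.ndarray) -> np.ndarray:
        return np.column_stack([e.logpdf(obs) for e in self.emissions])

    def _scaled_b(self, obs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Emission likelihoods shifted per window to avoid underflow."""
        logb = self._log_b(obs)
        shift = logb.max(axis=1)
        return np.exp(logb - shift[:, None]), shift

    def log_likelihood(self, obs: np.ndarray) -> float:
        b, shift = self._scaled_b(obs)
        return self._forward(b)[1] + float(shift.sum())

    def _forward(self, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Scaled forward pass: returns (alpha_hat, scale c, log-lik sans shift)."""
        n = b.shape[0]
        A = self.trans
        alpha = np.zeros((n, 3))
        c = np.empty(n)
        a = np.array([b[0, 0], 0.0, 0.0])  # initial state fixed to 1
        c[0] = a.sum()
        alpha[0] = a / c[0]
        for t in range(1, n):
            a = (alpha[t - 1] @ A) * b[t]
            c[t] = a.sum()
            alpha[t] = a / c[t]
        return alpha, c, float(np.log(c).sum())

    def _backward(self, b: np.ndarray, c: np.ndarray) -> np.ndarray:
        n = b.shape[0]
        A = self.trans
        beta = np.ones((n, 3))
        for t in range(n - 2, -1, -1):
            beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
        return beta

    def viterbi(self, obs: np.ndarray) -> np.ndarray:
        """Most probable state path; ties broken toward the earliest transitions.

        At every tie the larger predecessor state (and larger final state)
        is preferred, which makes each 1->2 and 2->3 transition happen as
        early as the optimum allows -- the conservative, shorter wave call.
        """
        logb = self._log_b(obs)
        n = logb.shape[0]
        with np.errstate(divide="ignore"):
            logA = np.log(self.trans)
        delta = np.array([logb[0, 0], -np.inf, -np.inf])
        ptr = np.zeros((n, 3), dtype=int)
        for t in range(1, n):
            cand = delta[:, None] + logA  # cand[i, j]
            best = 2 - np.argmax((cand == cand.max(axis=0)[None, :])[::-1], axis=0)
            delta = cand[best, np.arange(3)] + logb[t]
            ptr[t] = best
        last = int(np.flatnonzero(delta == delta.max())[-1])
        path = np.empty(n, dtype=int)
        path[-1] = last
        for t in range(n - 1, 0, -1):
            path[t - 1] = ptr[t, path[t]]
        return path

    def fit(
        self, obs: np.ndarray, max_iter: int = 200, tol: float = 1e-6
    ) -> tuple[list[float], bool, list[str]]:
        """Baum-Welch EM in place; returns (log-likelihoods, converged, flags)."""
        flags: list[str] = []
        lls: list[float] = []
        prev = -np.inf
        converged = False
        for _ in range(max_iter):
            b, shift = self._scaled_b(obs)
            alpha, c, ll0 = self._forward(b)
            ll = ll0 + float(shift.sum())
            beta = self._backward(b, c)
            lls.append(ll)
            if ll - prev < tol * max(1.0, abs(ll)) and len(lls) > 1:
                converged = True
                break
            prev = ll
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            A = self.trans
            bb = b[1:] * beta[1:]  # (n-1, 3)
            xi = np.einsum("ti,ij,tj->ij", alpha[:-1], A, bb / c[1:, None])
            # M-step: transitions (row 3 is absorbing)
            A = np.array(self.trans)
            for i in (0, 1):
                row = xi[i]
                tot = row.sum()
                if tot > 1e-12:
                    A[i] = row / tot
                    A[i][A[i] < 1e-10] = 0.0
                    A[i] /= A[i].sum()
            self.trans = A
            # M-step: emissions (weighted MLE; skip states with ~no mass)
            for j, emi in enumerate(self.emissions):
                w = gamma[:, j]
                if w.sum() < 1e-8:
                    flags.append(f"state {j + 1} unoccupied; emission frozen")
                    continue
                if emi.family == "normal":
                    emi.params = _weighted_normal_mle(obs, w)
                else:
                    emi.params = _weighted_gamma_mle(obs, w, emi.shift)
        else:
            flags.append("EM reached max_iter without convergence")
        if not converged and "EM reached max_iter without convergence" not in flags:
            flags.append("EM reached max_iter without convergence")
        return lls, converged, flags


# ---------------------------------------------------------------------------
# KL divergence between emissions


def kl_divergence(a: Emission, b: Emission) -> float:
    """KL(a || b) in nats; closed form within a family, quadrature across.

    Cross-family KL is evaluated by adaptive quadrature of
    p(x) log(p(x)/q(x)) over the support of ``a``; a support mismatch
    (mass of ``a`` where ``b`` has none) raises.
    """
    if a.family == b.family == "normal":
        mu1, s1 = a.params
        mu2, s2 = b.params
        return math.log(s2 / s1) + (s1**2 + (mu1 - mu2) ** 2) / (2 * s2**2) - 0.5
    if a.family == b.family == "gamma":
        if abs(a.shift - b.shift) > 1e-9:
            raise ValueError("gamma emissions with different shifts: support mismatch")
        k1, t1 = a.params
        k2, t2 = b.params
        return float(
            (k1 - k2) * special.digamma(k1)
            - special.gammaln(k1)
            + special.gammaln(k2)
            + k2 * math.log(t2 / t1)
            + k1 * (t1 - t2) / t2
        )
    # cross-family: quadrature on a's effective support
    if a.family == "gamma":
        lo, hi = a.shift + 1e-9, a.shift + stats.gamma.ppf(1 - 1e-10, a.params[0], scale=a.params[1])
    else:
        mu, s = a.params
        lo, hi = mu - 10 * s, mu + 10 * s
        if b.family == "gamma" and lo < b.shift:
            raise ValueError("support mismatch: normal mass below the gamma shift")

    def integrand(x):
        lp = a.logpdf(np.array([x]))[0]
        lq = b.logpdf(np.array([x]))[0]
        p = math.exp(lp)
        return p * (lp - lq) if p > 0 else 0.0

    val, _ = integrate.quad(integrand, lo, hi, limit=200)
    return float(val)


# ---------------------------------------------------------------------------
# Wave calling


def _segments(n: int, bounds: list[int]) -> list[np.ndarray]:
    idx = np.arange(n)
    b1, b2 = bounds
    return [idx[:b1], idx[b1:b2], idx[b2:]]


def _init_bounds(n: int, b1: int, b2: int) -> tuple[int, int]:
    """Clamp segment boundaries so every state starts with >= 1 window."""
    b1 = min(max(b1, 1), n - 2)
    b2 = min(max(b2, b1 + 1), n - 1)
    return b1, b2


def _gamma_shift(values: np.ndarray) -> float:
    span = float(values.max() - values.min())
    return float(values.min()) - max(0.05 * span, 1e-3)


def _fit_variant(
    wdiff: WindowedDiff,
    init_distance: float,
    variant: str,
    tsmooth: float | None,
    state1_bp: int | None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[HmmFit, WaveCall]:
    w = wdiff.window
    obs = wdiff.values.astype(float)
    if tsmooth is not None:
        obs = tsmooth_clamp(obs, tsmooth)
    n = obs.size
    n_up = wdiff.n_upstream
    shift = _gamma_shift(obs)
    if variant == "advancing":
        b1 = n_up if n_up >= 1 else 1
        b2 = b1 + max(int(init_distance) // w, 1)
        families = ["normal", "gamma", "gamma"]
    else:
        b1 = max((state1_bp or 1000) // w, 1)
        b2 = int(init_distance) // w
        families = ["gamma", "gamma", "gamma"]
    b1, b2 = _init_bounds(n, b1, b2)
    segs = _segments(n, [b1, b2])
    emissions = [
        _moment_emission(fam, obs[seg] if seg.size else obs, shift)
        for fam, seg in zip(families, segs)
    ]
    trans = np.array(
        [
            [1 - 1 / (segs[0].size + 1), 1 / (segs[0].size + 1), 0.0],
            [0.0, 1 - 1 / (segs[1].size + 1), 1 / (segs[1].size + 1)],
            [0.0, 0.0, 1.0],
        ]
    )
    model = LeftRightHMM(emissions, trans)
    lls, converged, flags = model.fit(obs, max_iter=max_iter, tol=tol)
    path = model.viterbi(obs)
    if variant == "advancing":
        in2 = np.flatnonzero(path == 1)
        # downstream edge of the last state-2 window, bp from the TSS
        distance = (int(in2[-1]) + 1 - n_up) * w if in2.size else 0.0
    else:
        in3 = np.flatnonzero(path == 2)
        distance = (int(in3[0]) - n_up) * w if in3.size else float(n - n_up) * w
    distance = float(min(max(distance, 0.0), wdiff.gene_length))
    try:
        kl = kl_divergence(model.emissions[1], model.emissions[2])
    except ValueError:
        kl = float("nan")
        flags.append("KL undefined between fitted states 2 and 3")
    fit = HmmFit(model.emissions, model.trans, lls, converged, len(lls), path, flags)
    call = WaveCall(
        gene_id=wdiff.gene_id,
        timepoint=wdiff.timepoint,
        distance_bp=distance,
        kl=float(kl),
        converged=converged,
        quality_pass=bool(converged and np.isfinite(kl) and kl > 1.0),
        init_distance=float(init_distance),
        variant=variant,
    )
    return fit, call


def fit_advancing_hmm(
    wdiff: WindowedDiff, init_distance: float, max_iter: int = 200, tol: float = 1e-6
) -> tuple[HmmFit, WaveCall]:
    """Fit the advancing-wave HMM (normal upstream state, gamma wave/body states).

    ``init_distance`` is the approximate wave distance used to split the
    gene for emission initialization; state 1 is initialized from the
    upstream (-500..TSS) windows.
    """
    if wdiff.n_upstream < 1:
        warnings.warn(
            f"gene {wdiff.gene_id}: no upstream windows; state 1 initialized "
            "from the first gene-body window"
        )
    return _fit_variant(wdiff, init_distance, "advancing", tsmooth=None, state1_bp=None,
                        max_iter=max_iter, tol=tol)


def fit_clearing_hmm(
    wdiff: WindowedDiff,
    init_distance: float,
    tsmooth: float = 5.0,
    state1_bp: int = 1000,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> tuple[HmmFit, WaveCall]:
    """Fit the clearing-wave HMM (all-gamma emissions, TSmooth clamping).

    State 1 is initialized from the first ``state1_bp`` nt downstream of
    the TSS; ``init_distance`` approximates the start of the clearing wave
    (the state-2/3 boundary reported as the call).
    """
    return _fit_variant(wdiff, init_distance, "clearing", tsmooth=tsmooth,
                        state1_bp=state1_bp, max_iter=max_iter, tol=tol)


def filter_wave_series(calls_by_gene: dict[str, list[WaveCall]]) -> dict[str, list[WaveCall]]:
    """Keep genes with quality-passing calls at every timepoint that never recede.

    ``calls_by_gene`` maps gene id to its calls over the timepoint grid;
    a gene is retained only if every call passes quality and the distance
    series is non-decreasing in time.
    """
    kept = {}
    for gid, calls in calls_by_gene.items():
        calls = sorted(calls, key=lambda c: c.timepoint)
        if not calls or not all(c.quality_pass for c in calls):
            continue
        d = [c.distance_bp for c in calls]
        if all(b >= a for a, b in zip(d, d[1:])):
            kept[gid] = calls
    return kept


def viterbi_bruteforce(obs: np.ndarray, model: LeftRightHMM) -> np.ndarray:
    """Exhaustive best-path search over all legal left-to-right paths.

    Test oracle: enumerates every (t1, t2) segmentation with states
    1 on [0, t1), 2 on [t1, t2), 3 on [t2, n); the initial state is 1, so
    t1 >= 1.  Ties resolve toward the earliest transitions (smallest t1,
    then t2), matching the main decoder.  Refuses > 14 windows.
    """
    n = len(obs)
    if n > 14:
        raise ValueError(f"brute-force Viterbi limited to 14 windows, got {n}")
    logb = model._log_b(np.asarray(obs, dtype=float))
    with np.errstate(divide="ignore"):
        logA = np.log(model.trans)
    best_lp = -np.inf
    best = None
    for t1 in range(1, n + 1):
        for t2 in range(t1, n + 1):
            if t1 == n and t2 < n:
                continue
            path = np.concatenate(
                [np.zeros(t1, int), np.ones(t2 - t1, int), np.full(n - t2, 2, int)]
            )
            lp = logb[0, path[0]] if path[0] == 0 else -np.inf
            for t in range(1, n):
                lp += logA[path[t - 1], path[t]] + logb[t, path[t]]
            if lp > best_lp:
                best_lp, best = lp, path
    return best


def call_wave_cohort(
    treated_by_timepoint: dict[float, SignalTrack],
    untreated: SignalTrack,
    genes: list[Gene],
    variant: str,
    window: int = 50,
    upstream: int = 500,
    tsmooth: float = 5.0,
    state1_bp: int = 1000,
    min_length: int | None = None,
    init_distances: dict[float, float] | None = None,
) -> dict[str, list[WaveCall]]:
    """Call waves for a cohort across a time course (one variant).

    Genes shorter than ``min_length`` (4 kb advancing, 6 kb clearing by
    default) are dropped.  When ``init_distances`` is omitted, the
    cohort-level changepoint scan supplies the per-timepoint init.
    """
    if min_length is None:
        min_length = 4000 if variant == "advancing" else 6000
    up = upstream if variant == "advancing" else 0
    cohort = [g for g in genes if g.length > min_length]
    calls: dict[str, list[WaveCall]] = {g.gene_id: [] for g in cohort}
    for t in sorted(treated_by_timepoint):
        if t <= 0:
            continue
        treated = treated_by_timepoint[t]
        wdiffs = [windowed_difference(treated, untreated, g, window, up, t) for g in cohort]
        if init_distances is not None and float(t) in init_distances:
            init = init_distances[float(t)]
        else:
            init = suggest_init_distance(wdiffs, variant, state1_bp)
        for g, wd in zip(cohort, wdiffs):
            if variant == "advancing":
                _, call = fit_advancing_hmm(wd, init)
            else:
                _, call = fit_clearing_hmm(wd, init, tsmooth, state1_bp)
            calls[g.gene_id].append(call)
    return calls


def suggest_init_distance(
    wdiffs: list[WindowedDiff], variant: str, state1_bp: int = 1000
) -> float:
    """Cohort-level approximate wave distance from a least-squares changepoint scan.

    The in-silico analog of eyeballing fold-change heat maps: for every
    gene the best piecewise-constant segmentation of its gene-body windows
    (two segments for advancing, three for clearing) is found by exact
    SSE minimization, and the cohort median of the relevant boundary is
    returned in bp from the TSS.
    """
    picks = []
    for wd in wdiffs:
        x = wd.values[wd.n_upstream :].astype(float)
        n = x.size
        if n < 3:
            continue
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        c2 = np.concatenate([[0.0], np.cumsum(x**2)])

        def sse(i, j):  # SSE of constant fit on x[i:j]
            if j <= i:
                return 0.0
            s, s2 = c1[j] - c1[i], c2[j] - c2[i]
            return s2 - s * s / (j - i)

        if variant == "advancing":
            errs = [(sse(0, b) + sse(b, n), b) for b in range(1, n)]
            b = min(errs)[1]
            picks.append(b * wd.window)
        else:
            b1_lo = max(1, state1_bp // wd.window)
            best = (np.inf, None)
            for b1 in range(b1_lo, n - 1):
                for b2 in range(b1 + 1, n):
                    e = sse(0, b1) + sse(b1, b2) + sse(b2, n)
                    if e < best[0]:
                        best = (e, b2)
            if best[1] is not None:
                picks.append(best[1] * wd.window)
    if not picks:
        raise ValueError("no usable genes for init-distance suggestion")
    return float(np.median(picks))
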