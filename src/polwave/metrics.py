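"""Pausing indices, composite profiles, fold-change matrices, termination zones.

The pausing index (PI) of a gene is the ratio of normalized PRO-seq
density in the promoter-proximal window (TSS to +100) to density in the
gene body; the body is taken as +100 through the CPS, the non-overlapping
complement of the promoter window.  PI is scale-free: multiplying a track
by any positive constant leaves it unchanged.

Composite (metagene) profiles average normalized signal within fixed-width
bins anchored at the TSS or CPS, first within bins along each gene and
then unweighted across genes, so every gene contributes equally.

Fold-change matrices hold log2((treated + eps) / (untreated + eps)) of
normalized signal in 10-bp bins spanning -250..+4000 from the TSS, rows
sorted by increasing gene length, with bins past a gene's CPS masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import Gene, SignalTrack, gene_profile, region_signal

__all__ = [
    "PausingRecord",
    "CompositeProfile",
    "pausing_index",
    "pausing_table",
    "pi_quartiles",
    "pi_cdf_compare",
    "composite_profile",
    "foldchange_matrix",
    "termination_zone_metrics",
]

PROMOTER_WINDOW = (0, 100)  # TSS..+100, bp downstream of the TSS


@dataclass
class PausingRecord:
    gene_id: str
    promoter_density: float
    body_density: float
    pausing_index: float


def pausing_index(track: SignalTrack, gene: Gene,
                  promoter: tuple[int, int] = PROMOTER_WINDOW) -> PausingRecord | None:
    """Pausing index of one gene, or None if it cannot be computed.

    Genes shorter than twice the promoter window (no room for a body) or
    with zero body density are excluded; the caller tallies the reasons.
    """
    body_start = promoter[1]
    if gene.length < 2 * body_start:
        return None
    _, prom = region_signal(track, gene, "tss", *promoter, normalized=True)
    _, body = region_signal(track, gene, "tss", body_start, gene.length, normalized=True)
    if body <= 0:
        return None
    return PausingRecord(gene.gene_id, prom, body, prom / body)


def pausing_table(track: SignalTrack, genes: list[Gene]) -> pd.DataFrame:
    """Pausing records for a filtered gene set, with exclusion reasons."""
    rows, excluded = [], []
    for g in genes:
        rec = pausing_index(track, g)
        if rec is None:
            excluded.append(g.gene_id)
            continue
        rows.append(vars(rec))
    df = pd.DataFrame(rows, columns=["gene_id", "promoter_density", "body_density", "pausing_index"])
    df.attrs["excluded"] = excluded
    return df


def pi_quartiles(table: pd.DataFrame) -> pd.Series:
    """Rank-based PI quartiles (1 = lowest PI), sizes differing by at most 1.

    Ties in PI are broken by gene id so the assignment is deterministic.
    """
    if len(table) < 4:
        raise ValueError(f"need at least 4 genes for quartiles, got {len(table)}")
    order = table.sort_values(["pausing_index", "gene_id"]).index
    ranks = pd.Series(np.arange(len(order)), index=order)
    quart = (ranks * 4 // len(order)) + 1
    return quart.reindex(table.index).astype(int).rename("quartile")


def pi_cdf_compare(
    treated: pd.DataFrame, untreated: pd.DataFrame, n_grid: int = 512
) -> dict[str, object]:
    """Empirical CDFs of log10 PI on a shared grid plus a two-sample KS test.

    Non-positive PIs are excluded (counted in the result); the KS statistic
    quantifies the global shift between the treated and untreated
    distributions.
    """
    out = {}
    vals = {}
    for name, df in (("treated", treated), ("untreated", untreated)):
        pi = df["pausing_index"].to_numpy(dtype=float)
        good = pi > 0
        out[f"n_excluded_{name}"] = int((~good).sum())
        if good.sum() == 0:
            raise ValueError(f"no positive pausing indices in {name} set")
        vals[name] = np.log10(pi[good])
    lo = min(v.min() for v in vals.values())
    hi = max(v.max() for v in vals.values())
    grid = np.linspace(lo, hi, n_grid)
    for name, v in vals.items():
        out[f"cdf_{name}"] = np.searchsorted(np.sort(v), grid, side="right") / v.size
    ks = stats.ks_2samp(vals["treated"], vals["untreated"])
    out.update(grid=grid, ks_statistic=float(ks.statistic), ks_p=float(ks.pvalue),
               median_shift=float(np.median(vals["treated"]) - np.median(vals["untreated"])))
    return out


@dataclass
class CompositeProfile:
    anchor: str
    bin_size: int
    window: tuple[int, int]
    values: np.ndarray  # per-bin mean normalized signal across genes
    n_genes: int

    @property
    def bin_centers(self) -> np.ndarray:
        lo, _ = self.window
        return lo + (np.arange(self.values.size) + 0.5) * self.bin_size


def composite_profile(
    track: SignalTrack,
    genes: list[Gene],
    anchor: str = "tss",
    window: tuple[int, int] = (-250, 4000),
    bin_size: int = 10,
) -> CompositeProfile:
    """Anchored composite: per-bin mean within each gene, then across genes.

    Bases beyond a gene's annotated extent still contribute (composites
    show termination read-through on purpose); bases off the chromosome
    are masked per gene.
    """
    if not genes:
        raise ValueError("composite_profile needs a non-empty gene set")
    lo, hi = window
    if (hi - lo) % bin_size:
        raise ValueError(f"window {window} not divisible by bin {bin_size}")
    n_bins = (hi - lo) // bin_size
    acc = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    for g in genes:
        prof = gene_profile(track, g, anchor, lo, hi, normalized=True)
        binned = prof.reshape(n_bins, bin_size)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(binned, axis=1)
        ok = ~np.isnan(means)
        acc[ok] += means[ok]
        cnt[ok] += 1
    values = np.divide(acc, cnt, out=np.full(n_bins, np.nan), where=cnt > 0)
    return CompositeProfile(anchor, bin_size, window, values, len(genes))


def foldchange_matrix(
    treated: SignalTrack,
    untreated: SignalTrack,
    genes: list[Gene],
    window: tuple[int, int] = (-250, 4000),
    bin_size: int = 10,
    eps: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2 fold change of normalized signal in fixed TSS-anchored bins.

    Rows are sorted by increasing gene length; entries past a gene's CPS
    are NaN.  ``eps`` (normalized reads per bin) stabilizes sparse bins;
    with treated and untreated swapped every finite entry changes sign.
    """
    lo, hi = window
    n_bins = (hi - lo) // bin_size
    edges = lo + np.arange(n_bins + 1) * bin_size
    rows = {}
    lengths = {}
    for g in genes:
        pt = gene_profile(treated, g, "tss", lo, hi, normalized=True)
        pu = gene_profile(untreated, g, "tss", lo, hi, normalized=True)
        st = np.nansum(pt.reshape(n_bins, bin_size), axis=1)
        su = np.nansum(pu.reshape(n_bins, bin_size), axis=1)
        lfc = np.log2((st + eps) / (su + eps))
        past_cps = edges[:-1] >= gene_rel_cps(g)
        lfc[past_cps] = np.nan
        rows[g.gene_id] = lfc
        lengths[g.gene_id] = g.length
    order = sorted(rows, key=lambda gid: (lengths[gid], gid))
    df = pd.DataFrame([rows[gid] for gid in order], index=order,
                      columns=edges[:-1])
    df.attrs["gene_length"] = [lengths[gid] for gid in order]
    return df


def gene_rel_cps(gene: Gene) -> int:
    """CPS position in TSS-relative coordinates (bp downstream)."""
    return gene.length - 1


def termination_zone_metrics(
    track: SignalTrack,
    genes: list[Gene],
    post_cps_window: int = 1000,
    fraction: float = 0.25,
    bin_size: int = 10,
    reference_bp: int = 50,
) -> dict[str, float | np.ndarray]:
    """Post-CPS termination-zone width and total signal.

    Builds the composite decay profile downstream of the CPS, takes the
    mean of the first ``reference_bp`` bases as the CPS-proximal level,
    and reports the distance at which the composite first falls below
    ``fraction`` of that level (for a clean exponential of scale s this is
    s * ln(1/fraction)).  Genes are eligible only when no annotated
    neighbour starts within the window.
    """
    eligible = [g for g in genes if _clear_downstream(g, genes, post_cps_window, track)]
    if not eligible:
        raise ValueError("no genes with a clear post-CPS window")
    comp = composite_profile(track, eligible, anchor="cps",
                             window=(0, post_cps_window), bin_size=bin_size)
    prof = comp.values
    ref_bins = max(1, reference_bp // bin_size)
    level = float(np.nanmean(prof[:ref_bins]))
    width = 0.0
    if level > 0:
        below = np.flatnonzero(prof < fraction * level)
        width = float(below[0] * bin_size) if below.size else float(post_cps_window)
    total = 0.0
    for g in eligible:
        s, _ = region_signal(track, g, "cps", 1, post_cps_window + 1, normalized=True)
        total += s
    return {
        "profile": prof,
        "zone_width_bp": width,
        "cps_level": level,
        "total_post_cps_signal": total,
        "n_genes": len(eligible),
    }


def _clear_downstream(gene: Gene, genes: list[Gene], window: int, track: SignalTrack) -> bool:
    lo, hi = (gene.end, gene.end + window) if gene.strand == "+" else (gene.start - window, gene.start)
    if lo < 0 or hi > track.chrom_sizes[gene.chrom]:
        return False
    for other in genes:
        if other.gene_id == gene.gene_id or other.chrom != gene.chrom:
            continue
        if other.start < hi and other.end > lo:
            return False
    return True
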