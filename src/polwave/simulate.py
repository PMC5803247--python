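"""Synthetic PRO-seq/PRO-cap data with a two-population Pol II kinematic model.

The generator builds a toy genome (a few chromosomes, non-overlapping
stranded genes), then emits single-base 3'-end count tracks whose expected
per-base density follows a conveyor-belt picture of transcription: at a
constant initiation rate r and elongation speed v the steady-state
polymerase density is rho = r / v, so PRO-seq density is inversely
proportional to speed.

Untreated profile (per gene, distances d from the TSS):

* gene body plateau at ``initiation_density``
* an additive promoter-proximal pause peak of height
  ``pause_peak_height x initiation_density`` over the first
  ``pause_peak_width`` bases
* exponential termination decay past the CPS with e-folding length
  ``termination_decay_bp``
* ``background_density`` everywhere else (intergenic, both strands).

Under simulated kinase inhibition at time t the gene body splits into the
two populations of the checkpoint model, with a checkpoint at distance c
from the TSS:

* ``[0, v_slow*t)``           slow post-inhibition Pol II, density elevated
                              to ``initiation_density * v_ref / v_slow``
* ``[v_slow*t, c + v_slow*t)`` pre-inhibition density (polymerases that had
                              passed the TSS but not the checkpoint)
* ``[c + v_slow*t, c + v_fast*t)`` cleared zone at background density (fast
                              pre-inhibition Pol II has run ahead)
* ``[c + v_fast*t, CPS]``     unaffected density ahead of the clearing wave

with segments truncated at the gene end; the pause peak persists
additively and the post-CPS decay scales with the density reaching the
CPS, so the t = 0 profile equals the untreated one exactly.

Counts are Poisson-sampled per base (optionally negative-binomial via a
gamma-Poisson mixture) and scaled by each library's spike-in normalization
factor, so *normalized* signal is comparable across libraries by
construction.  A single master seed drives deterministic per-sample
streams.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .tracks import Gene, SignalTrack, write_bedgraph, write_genes_bed6

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_toy_genome",
    "expected_density",
    "simulate_untreated",
    "simulate_inhibition_timecourse",
    "simulate_procap",
    "write_fixture_set",
]


@dataclass
class SimulationConfig:
    """Parameters of the toy genome and the two-population kinematic model.

    Defaults are the cohort used throughout for parameter recovery: 40
    long genes (6-8 kb), slow/fast rates of 400 and 1200 bp/min, a 500 bp
    checkpoint, a five-point inhibition time course, and two replicate
    libraries at matched spike-in depth.
    """

    n_chromosomes: int = 2
    chrom_length: int = 250_000
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (6_000, 8_000)
    v_slow: float = 400.0       # bp/min, post-inhibition population
    v_fast: float = 1200.0      # bp/min, pre-inhibition population
    v_ref: float = 2000.0       # bp/min, pre-inhibition effective rate (sets 5' elevation)
    checkpoint_distance: int = 500   # bp from TSS where the two populations split
    initiation_density: float = 0.25  # expected reads/bp in gene body
    pause_peak_height: float = 10.0   # multiplier over body density
    pause_peak_width: int = 50        # bp
    background_density: float = 0.01  # expected reads/bp intergenic
    termination_decay_bp: float = 300.0
    timepoints: tuple[float, ...] = (0.0, 0.5, 1.0, 2.5, 5.0)  # minutes
    n_replicates: int = 2
    spike_reads_per_library: tuple[int, ...] | int = 100_000
    procap_peak_reads: float = 100.0  # expected PRO-cap reads at the true TSS
    noise_model: str = "poisson"      # "poisson" or "nb"
    nb_dispersion: float = 0.1        # used only when noise_model == "nb"
    seed: int = 0

    def validate(self) -> None:
        if not (self.v_fast > self.v_slow > 0):
            raise ValueError(f"need v_fast > v_slow > 0, got {self.v_fast}, {self.v_slow}")
        if self.checkpoint_distance < 0:
            raise ValueError("checkpoint_distance must be >= 0")
        if self.background_density >= self.initiation_density:
            raise ValueError("background_density must be below initiation_density")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"bad gene_length_range {self.gene_length_range}")
        if min(self.n_chromosomes, self.chrom_length, self.n_genes) <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.noise_model not in ("poisson", "nb"):
            raise ValueError(f"noise_model must be 'poisson' or 'nb', got {self.noise_model!r}")
        if 0.0 not in self.timepoints:
            raise ValueError("timepoints must include 0")

    def spike_reads(self, library_index: int) -> int:
        if isinstance(self.spike_reads_per_library, int):
            return self.spike_reads_per_library
        seq = self.spike_reads_per_library
        return int(seq[library_index % len(seq)])


@dataclass
class GroundTruth:
    """Truth channel for recovery tests: per-gene TSS and wave positions.

    Wave-front distance at time t is ``min(v_slow*t, L)`` and the clearing
    start (downstream edge of the cleared zone) is
    ``min(checkpoint + v_fast*t, L)``; both are non-decreasing in t.
    """

    true_tss: dict[str, int]
    gene_length: dict[str, int]
    front_bp: dict[str, dict[float, float]]
    clearing_bp: dict[str, dict[float, float]]
    v_slow: float
    v_fast: float
    checkpoint_distance: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid in self.true_tss:
            for t in self.front_bp[gid]:
                rows.append(
                    {
                        "gene_id": gid,
                        "timepoint": t,
                        "true_tss": self.true_tss[gid],
                        "gene_length": self.gene_length[gid],
                        "front_bp": self.front_bp[gid][t],
                        "clearing_bp": self.clearing_bp[gid][t],
                    }
                )
        return pd.DataFrame(rows)


def make_toy_genome(config: SimulationConfig) -> tuple[list[Gene], dict[str, int]]:
    """Place non-overlapping stranded genes on a toy genome.

    Deterministic for a fixed seed.  At least 10% of genes are guaranteed
    to be >= 6 kb whenever the configured length range allows it, so
    long-gene analyses always have a cohort to work on.  Genes are
    separated by >= 1.5 kb so upstream windows and intergenic background
    regions never touch a neighbour.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0xA11CE]))
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    if hi >= 6000:
        need = max(0, math.ceil(0.1 * config.n_genes) - int((lengths >= 6000).sum()))
        if need:
            idx = rng.choice(np.flatnonzero(lengths < 6000), size=need, replace=False)
            lengths[idx] = rng.integers(max(lo, 6000), hi + 1, size=need)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    chrom_sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    margin = 1000
    min_gap, max_gap = 1500, 2500
    genes: list[Gene] = []
    chroms = list(chrom_sizes)
    ci, cursor = 0, margin
    for k in range(config.n_genes):
        length = int(lengths[k])
        gap = int(rng.integers(min_gap, max_gap + 1))
        while ci < len(chroms) and cursor + length + margin > chrom_sizes[chroms[ci]]:
            ci += 1
            cursor = margin
        if ci >= len(chroms):
            raise ValueError(
                f"cannot place {config.n_genes} genes of length {lo}..{hi} on "
                f"{config.n_chromosomes} x {config.chrom_length} bp chromosomes "
                f"(failed at gene {k})"
            )
        genes.append(
            Gene(
                gene_id=f"g{k + 1:03d}",
                chrom=chroms[ci],
                start=cursor,
                end=cursor + length,
                strand=str(strands[k]),
            )
        )
        cursor += length + gap
    return genes, chrom_sizes


# ---------------------------------------------------------------------------
# Expected-density model


def _gene_body_density(config: SimulationConfig, length: int, timepoint: float | None) -> np.ndarray:
    """Expected reads/bp along a gene (index = distance from TSS)."""
    d = np.arange(length, dtype=float)
    rho = np.full(length, config.initiation_density)
    if timepoint is not None and timepoint > 0:
        t = timepoint
        front = config.v_slow * t
        cl_start = config.checkpoint_distance + config.v_slow * t
        cl_end = config.checkpoint_distance + config.v_fast * t
        rho[d < front] = config.initiation_density * config.v_ref / config.v_slow
        rho[(d >= cl_start) & (d < cl_end)] = config.background_density
    # promoter-proximal pause peak persists in all conditions
    rho[: config.pause_peak_width] += config.pause_peak_height * config.initiation_density
    return rho


def expected_density(
    config: SimulationConfig,
    genes: list[Gene],
    chrom_sizes: dict[str, int],
    timepoint: float | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Expected per-base PRO-seq density (reads/bp at unit normalization).

    ``timepoint=None`` gives the untreated profile; a number gives the
    profile after that many minutes of inhibition.
    """
    dens = {
        chrom: {"+": np.full(size, config.background_density),
                "-": np.full(size, config.background_density)}
        for chrom, size in chrom_sizes.items()
    }
    decay_span = int(6 * config.termination_decay_bp)
    for gene in genes:
        body = _gene_body_density(config, gene.length, timepoint)
        arr = dens[gene.chrom][gene.strand]
        if gene.strand == "+":
            arr[gene.start : gene.end] = body
        else:
            arr[gene.start : gene.end] = body[::-1]
        # termination zone: exponential decay from the density reaching the CPS
        cps_level = body[-1]
        span = np.arange(1, decay_span + 1, dtype=float)
        tail = cps_level * np.exp(-span / config.termination_decay_bp)
        if gene.strand == "+":
            hi = min(gene.end + decay_span, chrom_sizes[gene.chrom])
            arr[gene.end : hi] += tail[: hi - gene.end]
        else:
            lo = max(gene.start - decay_span, 0)
            arr[lo : gene.start] += tail[: gene.start - lo][::-1]
    return dens


def _sample_rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), *map(int, stream)]))


def _sample_counts(
    config: SimulationConfig, lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    if config.noise_model == "nb":
        # gamma-Poisson mixture: var = mu + dispersion * mu^2
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, lam / shape)
    return rng.poisson(lam).astype(float)


def _render_track(
    config: SimulationConfig,
    dens: dict[str, dict[str, np.ndarray]],
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    spike_reads: int,
    **meta,
) -> SignalTrack:
    track = SignalTrack(chrom_sizes=dict(chrom_sizes), spike_mapped_reads=spike_reads, **meta)
    factor = track.normalization_factor
    for chrom in dens:
        for strand in ("+", "-"):
            track.data[chrom][strand] = _sample_counts(config, dens[chrom][strand] * factor, rng)
    return track


_UNTREATED_STREAM = 1
_TREATED_STREAM = 2
_PROCAP_STREAM = 3


def simulate_untreated(
    config: SimulationConfig,
    genes: list[Gene],
    chrom_sizes: dict[str, int],
    replicate: int = 0,
    library_index: int = 0,
) -> SignalTrack:
    """One untreated PRO-seq library (Poisson counts around the steady profile)."""
    config.validate()
    dens = expected_density(config, genes, chrom_sizes, timepoint=None)
    rng = _sample_rng(config, _UNTREATED_STREAM, replicate)
    return _render_track(
        config, dens, chrom_sizes, rng, config.spike_reads(library_index),
        sample_id=f"untreated_rep{replicate + 1}", timepoint=0.0, treatment="untreated",
    )


def simulate_inhibition_timecourse(
    config: SimulationConfig,
    genes: list[Gene],
    chrom_sizes: dict[str, int],
) -> tuple[dict[float, list[SignalTrack]], GroundTruth]:
    """Treated libraries for every timepoint (replicates each), plus ground truth."""
    config.validate()
    out: dict[float, list[SignalTrack]] = {}
    lib = 0
    for ti, t in enumerate(config.timepoints):
        dens = expected_density(config, genes, chrom_sizes, timepoint=t)
        reps = []
        for rep in range(config.n_replicates):
            rng = _sample_rng(config, _TREATED_STREAM, ti, rep)
            reps.append(
                _render_track(
                    config, dens, chrom_sizes, rng, config.spike_reads(lib),
                    sample_id=f"treated_t{t:g}_rep{rep + 1}", timepoint=float(t),
                    treatment="treated",
                )
            )
            lib += 1
        out[float(t)] = reps
    truth = GroundTruth(
        true_tss={g.gene_id: g.tss for g in genes},
        gene_length={g.gene_id: g.length for g in genes},
        front_bp={
            g.gene_id: {float(t): min(config.v_slow * t, g.length) for t in config.timepoints}
            for g in genes
        },
        clearing_bp={
            g.gene_id: {
                float(t): min(config.checkpoint_distance + config.v_fast * t, g.length)
                for t in config.timepoints
            }
            for g in genes
        },
        v_slow=config.v_slow,
        v_fast=config.v_fast,
        checkpoint_distance=config.checkpoint_distance,
    )
    return out, truth


def simulate_procap(
    config: SimulationConfig,
    genes: list[Gene],
    chrom_sizes: dict[str, int],
    library_index: int = 0,
) -> SignalTrack:
    """A PRO-cap 5'-end library: a sharp peak at each true TSS over background.

    The full expected peak mass sits on the TSS base itself, so well over
    90% of a gene's 5' signal falls within +/-2 bp of the truth.
    """
    config.validate()
    dens = {
        chrom: {"+": np.full(size, config.background_density),
                "-": np.full(size, config.background_density)}
        for chrom, size in chrom_sizes.items()
    }
    for gene in genes:
        dens[gene.chrom][gene.strand][gene.tss] += config.procap_peak_reads
    rng = _sample_rng(config, _PROCAP_STREAM)
    return _render_track(
        config, dens, chrom_sizes, rng, config.spike_reads(library_index),
        sample_id="procap", treatment="procap",
    )


def write_fixture_set(config: SimulationConfig, outdir) -> dict[str, object]:
    """Materialize a complete fixture set on disk.

    Emits per-sample plus/minus bedGraphs, the gene annotation (BED6),
    chrom.sizes, a sample sheet (sample id, timepoint, treatment,
    replicate, spike-in reads, file paths), the ground-truth table, and the
    config as YAML.  Everything round-trips through the track readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, chrom_sizes = make_toy_genome(config)
    if not genes:
        warnings.warn("empty gene list: writing an empty annotation")
    write_genes_bed6(genes, outdir / "genes.bed")
    with open(outdir / "chrom.sizes", "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    rows = []

    def _emit(track: SignalTrack) -> None:
        plus = outdir / f"{track.sample_id}_plus.bedgraph"
        minus = outdir / f"{track.sample_id}_minus.bedgraph"
        write_bedgraph(track, plus, minus)
        rows.append(
            {
                "sample_id": track.sample_id,
                "timepoint": track.timepoint if track.timepoint is not None else "",
                "treatment": track.treatment,
                "spike_reads": int(track.spike_mapped_reads),
                "plus_bedgraph": plus.name,
                "minus_bedgraph": minus.name,
            }
        )

    tracks: dict[str, SignalTrack] = {}
    for rep in range(config.n_replicates):
        tr = simulate_untreated(config, genes, chrom_sizes, replicate=rep, library_index=rep)
        _emit(tr)
        tracks[tr.sample_id] = tr
    timecourse, truth = simulate_inhibition_timecourse(config, genes, chrom_sizes)
    for t in sorted(timecourse):
        for tr in timecourse[t]:
            _emit(tr)
            tracks[tr.sample_id] = tr
    procap = simulate_procap(config, genes, chrom_sizes)
    _emit(procap)
    tracks[procap.sample_id] = procap

    pd.DataFrame(rows).to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    cfg = asdict(config)
    cfg["gene_length_range"] = list(config.gene_length_range)
    cfg["timepoints"] = list(config.timepoints)
    if not isinstance(cfg["spike_reads_per_library"], int):
        cfg["spike_reads_per_library"] = list(cfg["spike_reads_per_library"])
    with open(outdir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return {
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "tracks": tracks,
        "timecourse": timecourse,
        "truth": truth,
        "outdir": outdir,
    }
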