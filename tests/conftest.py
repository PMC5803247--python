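"""Shared fixtures: small synthetic genomes and the default recovery cohort."""

import numpy as np
import pytest

from polwave import simulate, tracks


@pytest.fixture(scope="session")
def default_config():
    """The default study conditions: 40 long genes, v_slow=400, v_fast=1200."""
    return simulate.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Toy genome + untreated/treated tracks for the default conditions.

    Combined-replicate tracks mirror how the analysis pools libraries.
    """
    cfg = default_config
    genes, chrom_sizes = simulate.make_toy_genome(cfg)
    timecourse, truth = simulate.simulate_inhibition_timecourse(cfg, genes, chrom_sizes)
    untreated_reps = [
        simulate.simulate_untreated(cfg, genes, chrom_sizes, replicate=r)
        for r in range(cfg.n_replicates)
    ]
    return {
        "config": cfg,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "timecourse": timecourse,
        "truth": truth,
        "untreated_reps": untreated_reps,
        "untreated": tracks.combine_tracks(untreated_reps),
        "treated": {t: tracks.combine_tracks(reps) for t, reps in timecourse.items()},
        "procap": simulate.simulate_procap(cfg, genes, chrom_sizes),
    }


@pytest.fixture(scope="session")
def mixed_cohort():
    """A genome-like length mix (1-6.5 kb): most genes short, a long-gene tail.

    Genome-wide signatures (PI shift, region change patterns) depend on the
    length mix, so they are checked here rather than on the long-gene
    rate-recovery cohort.
    """
    cfg = simulate.SimulationConfig(
        seed=21, n_genes=48, gene_length_range=(1000, 6500)
    )
    genes, chrom_sizes = simulate.make_toy_genome(cfg)
    timecourse, truth = simulate.simulate_inhibition_timecourse(cfg, genes, chrom_sizes)
    untreated_reps = [
        simulate.simulate_untreated(cfg, genes, chrom_sizes, replicate=r)
        for r in range(cfg.n_replicates)
    ]
    return {
        "config": cfg,
        "genes": genes,
        "chrom_sizes": chrom_sizes,
        "timecourse": timecourse,
        "truth": truth,
        "untreated_reps": untreated_reps,
        "untreated": tracks.combine_tracks(untreated_reps),
        "treated": {t: tracks.combine_tracks(reps) for t, reps in timecourse.items()},
        "procap": simulate.simulate_procap(cfg, genes, chrom_sizes),
    }


@pytest.fixture()
def flat_track():
    """Single 10 kb chromosome, uniform 1.0 on both strands."""
    cs = {"chr1": 10_000}
    tr = tracks.SignalTrack(chrom_sizes=cs, spike_mapped_reads=100_000)
    for strand in "+-":
        tr.data["chr1"][strand][:] = 1.0
    return tr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
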