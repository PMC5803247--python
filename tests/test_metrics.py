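"""Pausing index, quartiles, composites, fold changes, termination zones."""

import numpy as np
import pandas as pd
import pytest

from polwave import metrics, simulate, tracks
from polwave.tracks import Gene, SignalTrack


def _uniform_track(value=1.0, size=20_000, spike=100_000):
    tr = SignalTrack(chrom_sizes={"c": size}, spike_mapped_reads=spike)
    for strand in "+-":
        tr.data["c"][strand][:] = value
    return tr


class TestPausingIndex:
    def test_uniform_density_gives_pi_one(self):
        g = Gene("g", "c", 1000, 5000, "+")
        rec = metrics.pausing_index(_uniform_track(), g)
        assert rec.pausing_index == pytest.approx(1.0)

    def test_ratio_of_densities(self):
        g = Gene("g", "c", 1000, 5000, "+")
        tr = _uniform_track()
        tr.data["c"]["+"][1000:1100] = 5.0
        rec = metrics.pausing_index(tr, g)
        assert rec.pausing_index == pytest.approx(5.0)

    def test_short_gene_excluded(self):
        g = Gene("g", "c", 1000, 1150, "+")
        assert metrics.pausing_index(_uniform_track(), g) is None

    def test_zero_body_excluded_and_reported(self):
        g = Gene("g", "c", 1000, 5000, "+")
        tr = _uniform_track(0.0)
        tr.data["c"]["+"][1000:1100] = 1.0
        table = metrics.pausing_table(tr, [g])
        assert table.empty and table.attrs["excluded"] == ["g"]

    def test_scale_invariance(self, cohort):
        """PI is unchanged when the track is multiplied by a positive scalar."""
        g = cohort["genes"][0]
        tr = cohort["untreated"]
        pi1 = metrics.pausing_index(tr, g).pausing_index
        scaled = SignalTrack(
            chrom_sizes=tr.chrom_sizes,
            data={c: {s: 7.3 * a for s, a in d.items()} for c, d in tr.data.items()},
            spike_mapped_reads=tr.spike_mapped_reads,
        )
        assert metrics.pausing_index(scaled, g).pausing_index == pytest.approx(pi1)

    def test_median_pi_increases_with_peak_height(self):
        medians = []
        for h in (0.0, 5.0, 20.0):
            cfg = simulate.SimulationConfig(
                seed=11, pause_peak_height=h, n_genes=15,
                gene_length_range=(2000, 3000),
            )
            genes, cs = simulate.make_toy_genome(cfg)
            tr = simulate.simulate_untreated(cfg, genes, cs)
            table = metrics.pausing_table(tr, genes)
            medians.append(table["pausing_index"].median())
        assert medians[0] < medians[1] < medians[2]


class TestQuartiles:
    def test_eight_genes_split_in_twos(self):
        df = pd.DataFrame(
            {"gene_id": list("abcdefgh"), "pausing_index": np.arange(1.0, 9.0)}
        )
        q = metrics.pi_quartiles(df)
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_sizes_near_equal(self):
        df = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(3364)],
             "pausing_index": np.random.default_rng(0).lognormal(size=3364)}
        )
        counts = metrics.pi_quartiles(df).value_counts()
        assert set(counts) == {841}  # 3364 genes -> 841 per quartile

    def test_all_equal_pis_deterministic_by_id(self):
        df = pd.DataFrame({"gene_id": list("dcba"), "pausing_index": [1.0] * 4})
        q = metrics.pi_quartiles(df)
        assert list(q) == [4, 3, 2, 1]  # alphabetical ids a<b<c<d get 1..4

    def test_too_few_genes_rejected(self):
        df = pd.DataFrame({"gene_id": list("abc"), "pausing_index": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            metrics.pi_quartiles(df)


class TestCdfCompare:
    def _table(self, pis):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(len(pis))], "pausing_index": pis}
        )

    def test_identical_sets_ks_zero(self):
        t = self._table(np.linspace(0.5, 5, 50))
        out = metrics.pi_cdf_compare(t, t)
        assert out["ks_statistic"] == 0.0

    def test_twofold_shift_moves_cdf_by_log10_two(self, rng):
        base = rng.lognormal(0, 0.5, 200)
        out = metrics.pi_cdf_compare(self._table(base / 2), self._table(base))
        assert out["median_shift"] == pytest.approx(-np.log10(2), abs=1e-9)

    def test_inhibition_shifts_pi_down(self, mixed_cohort):
        """After 5 min of inhibition the PI CDF sits left of untreated.

        On a genome-like length mix the slow post-inhibition wave spans
        most of a typical gene body, raising the body denominator far more
        than the promoter window, so pausing indices drop genome-wide.
        """
        genes = mixed_cohort["genes"]
        t_u = metrics.pausing_table(mixed_cohort["untreated"], genes)
        t_t = metrics.pausing_table(mixed_cohort["treated"][5.0], genes)
        out = metrics.pi_cdf_compare(t_t, t_u)
        assert out["median_shift"] < 0
        assert out["ks_p"] < 0.01


class TestComposite:
    def test_single_uniform_gene_flat_profile(self):
        g = Gene("g", "c", 1000, 5000, "+")
        comp = metrics.composite_profile(_uniform_track(2.0), [g], "tss", (0, 1000), 10)
        assert np.allclose(comp.values, 2.0)

    def test_two_genes_average(self):
        tr = _uniform_track(0.0)
        tr.data["c"]["+"][1000:3000] = 1.0
        tr.data["c"]["-"][5000:7000] = 3.0
        g1 = Gene("a", "c", 1000, 3000, "+")
        g2 = Gene("b", "c", 5000, 7000, "-")
        comp = metrics.composite_profile(tr, [g1, g2], "tss", (0, 1000), 10)
        assert np.allclose(comp.values, 2.0)

    def test_identical_genes_equal_single_gene_profile(self, cohort):
        g = cohort["genes"][0]
        tr = cohort["untreated"]
        single = metrics.composite_profile(tr, [g], "tss", (0, 2000), 10)
        triple = metrics.composite_profile(tr, [g, g, g], "tss", (0, 2000), 10)
        np.testing.assert_allclose(triple.values, single.values)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            metrics.composite_profile(_uniform_track(), [], "tss", (0, 100), 10)

    def test_timecourse_shape(self, cohort):
        """Early inhibition elevates 5' bins and depletes mid-gene bins."""
        genes = [g for g in cohort["genes"] if g.length > 6000]
        u = metrics.composite_profile(cohort["untreated"], genes, "tss", (0, 4000), 50)
        t1 = metrics.composite_profile(cohort["treated"][1.0], genes, "tss", (0, 4000), 50)
        five_prime = slice(2, 8)  # 100-400 bp: inside the slow wave at 1 min
        mid = slice(20, 30)  # 1-1.5 kb: inside the cleared zone at 1 min
        assert t1.values[five_prime].mean() > 1.5 * u.values[five_prime].mean()
        assert t1.values[mid].mean() < 0.5 * u.values[mid].mean()


class TestFoldChange:
    def test_identical_tracks_zero_matrix(self, cohort):
        tr = cohort["untreated"]
        fc = metrics.foldchange_matrix(tr, tr, cohort["genes"][:5])
        vals = fc.to_numpy()
        assert np.nanmax(np.abs(vals)) == 0.0

    def test_doubled_signal_constant_plus_one(self):
        g = Gene("g", "c", 1000, 6000, "+")
        u = _uniform_track(1.0)
        t = _uniform_track(2.0)
        fc = metrics.foldchange_matrix(t, u, [g], window=(0, 4000), bin_size=10, eps=0.0)
        assert np.allclose(fc.to_numpy(), 1.0, equal_nan=False)

    def test_antisymmetry_under_swap(self, cohort):
        genes = cohort["genes"][:8]
        t, u = cohort["treated"][2.5], cohort["untreated"]
        a = metrics.foldchange_matrix(t, u, genes).to_numpy()
        b = metrics.foldchange_matrix(u, t, genes).to_numpy()
        np.testing.assert_allclose(a, -b, equal_nan=True)

    def test_rows_sorted_by_length_and_cps_masked(self, cohort):
        genes = cohort["genes"]
        fc = metrics.foldchange_matrix(cohort["treated"][1.0], cohort["untreated"], genes)
        lengths = fc.attrs["gene_length"]
        assert lengths == sorted(lengths)
        # a 2 kb gene should have NaN past its CPS in a -250..+4000 window
        short_cfg = simulate.SimulationConfig(
            seed=12, n_genes=5, gene_length_range=(2000, 2000)
        )
        sg, scs = simulate.make_toy_genome(short_cfg)
        st = simulate.simulate_untreated(short_cfg, sg, scs)
        sfc = metrics.foldchange_matrix(st, st, sg)
        row = sfc.iloc[0]
        assert row[row.index >= 2000].isna().all()

    def test_advancing_band_right_edge_moves_with_time(self, cohort):
        """The positive fold-change band extends further at later timepoints."""
        genes = [g for g in cohort["genes"] if g.length > 6000]
        edges = []
        for t in (0.5, 1.0, 2.5):
            fc = metrics.foldchange_matrix(cohort["treated"][t], cohort["untreated"], genes)
            mean_prof = fc.mean(axis=0)
            bins = mean_prof.index.to_numpy()
            positive = (mean_prof.to_numpy() > 0.5) & (bins >= 0)
            edges.append(bins[positive].max())
        assert edges[0] < edges[1] < edges[2]


class TestTerminationZone:
    def test_width_matches_exponential_closed_form(self):
        """Decay scale 300 bp at f=0.25 -> width near 300*ln(4) = 416 bp."""
        tr = _uniform_track(0.0, size=20_000)
        g = Gene("g", "c", 1000, 5000, "+")
        d = np.arange(1, 3001)
        tr.data["c"]["+"][5000:8000] = np.exp(-d / 300.0)
        out = metrics.termination_zone_metrics(tr, [g], post_cps_window=2000)
        assert out["zone_width_bp"] == pytest.approx(300 * np.log(4), rel=0.10)

    def test_zero_post_cps_signal_width_zero(self):
        tr = _uniform_track(0.0)
        g = Gene("g", "c", 1000, 5000, "+")
        out = metrics.termination_zone_metrics(tr, [g])
        assert out["zone_width_bp"] == 0.0

    def test_shorter_decay_narrows_zone(self):
        g = Gene("g", "c", 1000, 5000, "+")
        widths = {}
        for label, scale in (("untreated", 300.0), ("treated", 120.0)):
            tr = _uniform_track(0.0, size=20_000)
            d = np.arange(1, 3001)
            tr.data["c"]["+"][5000:8000] = np.exp(-d / scale)
            widths[label] = metrics.termination_zone_metrics(
                tr, [g], post_cps_window=2000
            )["zone_width_bp"]
        assert widths["treated"] < widths["untreated"]

    def test_no_eligible_genes_rejected(self):
        tr = _uniform_track(1.0, size=3000)
        g = Gene("g", "c", 500, 2500, "+")  # < 1 kb clearance to chromosome end
        with pytest.raises(ValueError):
            metrics.termination_zone_metrics(tr, [g])
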