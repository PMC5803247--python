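"""Wave HMM: decoder vs exhaustive oracle, EM monotonicity, wave calls, KL."""

import math

import numpy as np
import pytest
from scipy import stats

from polwave import hmm, tracks
from polwave.hmm import Emission, LeftRightHMM, WaveCall, WindowedDiff
from polwave.tracks import Gene, SignalTrack


def _wdiff(values, window=50, upstream=0, gene_length=None, tp=1.0):
    values = np.asarray(values, dtype=float)
    if gene_length is None:
        gene_length = (values.size - upstream // window) * window
    return WindowedDiff("g", tp, window, upstream, values, gene_length)


class TestWindowedDifference:
    def _tracks(self, size=20_000):
        t = SignalTrack(chrom_sizes={"c": size}, spike_mapped_reads=100_000)
        u = SignalTrack(chrom_sizes={"c": size}, spike_mapped_reads=100_000)
        return t, u

    def test_identical_tracks_all_zero(self):
        t, u = self._tracks()
        t.data["c"]["+"][:] = u.data["c"]["+"][:] = 2.0
        g = Gene("g", "c", 1000, 4000, "+")
        wd = hmm.windowed_difference(t, u, g, 50, 500)
        assert np.all(wd.values == 0.0)
        assert wd.values.size == (500 + 3000) // 50

    def test_added_signal_appears_in_first_windows(self):
        t, u = self._tracks()
        g = Gene("g", "c", 1000, 4000, "+")
        t.data["c"]["+"][1000:1500] = 1.0
        wd = hmm.windowed_difference(t, u, g, 50, 0)
        assert np.all(wd.values[:10] == 50.0)
        assert np.all(wd.values[10:] == 0.0)

    def test_too_short_gene_rejected(self):
        t, u = self._tracks()
        g = Gene("g", "c", 1000, 1100, "+")
        with pytest.raises(ValueError, match="too short"):
            hmm.windowed_difference(t, u, g, 50, 0)

    def test_difference_normalized_by_spike(self):
        t, u = self._tracks()
        t.spike_mapped_reads = 200_000  # factor 2
        g = Gene("g", "c", 1000, 4000, "+")
        t.data["c"]["+"][1000:1050] = 4.0
        wd = hmm.windowed_difference(t, u, g, 50, 0)
        assert wd.values[0] == pytest.approx(100.0)  # 4*50 raw / factor 2


def _random_model(rng, families):
    shift = -5.0
    emis = []
    for fam in families:
        if fam == "normal":
            emis.append(Emission("normal", (rng.normal(0, 2), 0.5 + rng.random())))
        else:
            emis.append(
                Emission("gamma", (0.5 + 3 * rng.random(), 0.3 + rng.random()), shift)
            )
    a01, a12 = 0.05 + 0.4 * rng.random(2)
    trans = np.array([[1 - a01, a01, 0.0], [0.0, 1 - a12, a12], [0.0, 0.0, 1.0]])
    return LeftRightHMM(emis, trans)


class TestViterbiOracle:
    @pytest.mark.parametrize("families", [
        ("normal", "gamma", "gamma"),
        ("gamma", "gamma", "gamma"),
    ])
    def test_decoder_equals_exhaustive_enumeration(self, families):
        """200 random instances per emission variant, <= 12 windows each."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            model = _random_model(rng, families)
            n = int(rng.integers(2, 13))
            obs = rng.normal(0, 3, n)
            obs = np.clip(obs, -4.5, None)  # inside the gamma support (shift -5)
            fast = model.viterbi(obs)
            slow = hmm.viterbi_bruteforce(obs, model)
            np.testing.assert_array_equal(fast, slow)

    def test_single_window_path_is_state_one(self):
        model = _random_model(np.random.default_rng(0), ("normal", "gamma", "gamma"))
        assert list(hmm.viterbi_bruteforce(np.array([0.3]), model)) == [0]

    def test_tie_breaks_toward_earliest_transition(self):
        """With all states emitting identically, both decoders pick the path
        that leaves each state as early as possible."""
        emis = [Emission("normal", (0.0, 1.0)) for _ in range(3)]
        trans = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.0, 0.0, 1.0]])
        model = LeftRightHMM(emis, trans)
        obs = np.zeros(5)
        expected = [0, 1, 2, 2, 2]
        assert list(model.viterbi(obs)) == expected
        assert list(hmm.viterbi_bruteforce(obs, model)) == expected

    def test_oracle_refuses_large_inputs(self):
        model = _random_model(np.random.default_rng(1), ("gamma", "gamma", "gamma"))
        with pytest.raises(ValueError, match="14"):
            hmm.viterbi_bruteforce(np.zeros(15), model)


class TestEmFitting:
    def test_log_likelihood_monotone(self, cohort):
        """EM never decreases the data log-likelihood on cohort fixtures."""
        g = next(g for g in cohort["genes"] if g.length > 6000)
        t, u = cohort["treated"][2.5], cohort["untreated"]
        for variant, upstream in (("advancing", 500), ("clearing", 0)):
            wd = hmm.windowed_difference(t, u, g, 50, upstream, 2.5)
            if variant == "advancing":
                fit, _ = hmm.fit_advancing_hmm(wd, 1000)
            else:
                fit, _ = hmm.fit_clearing_hmm(wd, 3500)
            diffs = np.diff(fit.log_likelihoods)
            assert (diffs >= -1e-6 * np.abs(fit.log_likelihoods[:-1])).all()
            assert fit.converged

    def test_step_signal_front_at_window_twenty(self, rng):
        """10 upstream + 20 elevated + 40 background windows -> front at 1000 bp."""
        obs = np.concatenate([
            rng.normal(0, 1, 10),         # upstream
            rng.normal(40, 3, 20),        # wave
            rng.normal(0, 1, 40),         # quiet body
        ])
        wd = _wdiff(obs, upstream=500, gene_length=3000)
        _, call = hmm.fit_advancing_hmm(wd, 1000)
        assert call.distance_bp == 1000.0
        assert call.quality_pass

    def test_shift_equivariance(self, rng):
        """Moving the step by k windows moves the called front by exactly k."""
        fronts = {}
        noise = rng.normal(0, 0.5, 70)
        for k in (12, 18, 26):
            obs = noise.copy()
            obs[10 : 10 + k] += 50.0
            wd = _wdiff(obs, upstream=500, gene_length=3000)
            _, call = hmm.fit_advancing_hmm(wd, 800)
            fronts[k] = call.distance_bp
        assert fronts[18] - fronts[12] == 6 * 50
        assert fronts[26] - fronts[18] == 8 * 50

    def test_all_zero_difference_fails_quality(self):
        wd = _wdiff(np.zeros(40), upstream=500, gene_length=1500)
        _, call = hmm.fit_advancing_hmm(wd, 500)
        assert not call.quality_pass

    def test_clearing_three_level_boundary_at_trough_end(self, rng):
        """High / near-zero trough / moderate levels: the 2-3 boundary falls
        at the trough's downstream edge."""
        obs = np.concatenate([
            rng.normal(30, 2, 20),    # elevated head (first 1000 nt)
            rng.normal(-12, 1, 30),   # cleared trough
            rng.normal(0, 1, 50),     # unaffected tail
        ])
        wd = _wdiff(obs, gene_length=5000)
        _, call = hmm.fit_clearing_hmm(wd, 2000)
        assert call.distance_bp == 50 * 50.0  # window 50 edge
        assert call.quality_pass

    def test_two_level_signal_fails_kl_gate(self, rng):
        """Without a distinct trough the 2/3 emissions collapse and KL <= 1."""
        obs = np.concatenate([rng.normal(30, 2, 20), rng.normal(0, 1, 80)])
        wd = _wdiff(obs, gene_length=5000)
        _, call = hmm.fit_clearing_hmm(wd, 2500)
        assert not call.quality_pass


class TestKlDivergence:
    def test_identical_distributions_zero(self):
        e = Emission("gamma", (2.0, 1.5), -1.0)
        assert hmm.kl_divergence(e, e) == pytest.approx(0.0, abs=1e-12)

    def test_normal_closed_form(self):
        a = Emission("normal", (0.0, 1.0))
        b = Emission("normal", (1.0, 1.0))
        assert hmm.kl_divergence(a, b) == pytest.approx(0.5)

    def test_gamma_closed_form_matches_quadrature(self):
        from scipy import integrate

        a = Emission("gamma", (2.0, 1.0))
        b = Emission("gamma", (2.0, 2.0))
        closed = hmm.kl_divergence(a, b)

        def integrand(x):
            pa = stats.gamma.pdf(x, 2.0, scale=1.0)
            return pa * (stats.gamma.logpdf(x, 2.0, scale=1.0)
                         - stats.gamma.logpdf(x, 2.0, scale=2.0)) if pa > 0 else 0.0

        quad, _ = integrate.quad(integrand, 1e-12, 60)
        assert closed == pytest.approx(quad, abs=1e-6)

    def test_support_mismatch_rejected(self):
        a = Emission("gamma", (2.0, 1.0), shift=0.0)
        b = Emission("gamma", (2.0, 1.0), shift=3.0)
        with pytest.raises(ValueError, match="shift"):
            hmm.kl_divergence(a, b)


class TestFilterWaveSeries:
    def _call(self, gid, t, d, ok=True):
        return WaveCall(gid, t, d, 2.0 if ok else 0.5, True, ok, 1000, "advancing")

    def test_receding_series_rejected(self):
        calls = {"g": [self._call("g", t, d) for t, d in
                       zip((0.5, 1, 2.5, 5), (500, 400, 900, 1800))]}
        assert hmm.filter_wave_series(calls) == {}

    def test_single_quality_fail_rejects_gene(self):
        calls = {"g": [self._call("g", 0.5, 200), self._call("g", 1, 400, ok=False),
                       self._call("g", 2.5, 1000)]}
        assert hmm.filter_wave_series(calls) == {}

    def test_monotone_passing_series_kept(self):
        calls = {"g": [self._call("g", t, 400 * t) for t in (0.5, 1, 2.5)]}
        assert set(hmm.filter_wave_series(calls)) == {"g"}

    def test_cohort_retention_at_default_noise(self, cohort):
        """>= 90% of simulated genes survive the series filter."""
        genes = cohort["genes"]
        u = cohort["untreated"]
        calls = {g.gene_id: [] for g in genes}
        for t in (0.5, 1.0, 2.5, 5.0):
            tr = cohort["treated"][t]
            wds = [hmm.windowed_difference(tr, u, g, 50, 500, t) for g in genes]
            init = hmm.suggest_init_distance(wds, "advancing")
            for g, wd in zip(genes, wds):
                calls[g.gene_id].append(hmm.fit_advancing_hmm(wd, init)[1])
        kept = hmm.filter_wave_series(calls)
        assert len(kept) >= 0.9 * len(genes)


class TestFrontRecovery:
    def test_mean_absolute_front_error_within_one_window(self, cohort):
        """Across the cohort the called front tracks the kinematic truth."""
        genes = cohort["genes"]
        u = cohort["untreated"]
        truth = cohort["truth"]
        errors = []
        for t in (1.0, 2.5):
            tr = cohort["treated"][t]
            wds = [hmm.windowed_difference(tr, u, g, 50, 500, t) for g in genes]
            init = hmm.suggest_init_distance(wds, "advancing")
            for g, wd in zip(genes, wds):
                _, call = hmm.fit_advancing_hmm(wd, init)
                errors.append(abs(call.distance_bp - truth.front_bp[g.gene_id][t]))
        assert np.mean(errors) <= 50.0
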