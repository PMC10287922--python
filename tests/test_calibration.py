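import numpy as np
import pytest

from ledseq import calibration as cal
from ledseq.types import NormalizedTrack, ReferenceStructure, TranscriptRecord


class TestClassifySite:
    def test_ca_dinucleotide(self):
        assert cal.classify_site("GCAU", 2) == "CA"

    def test_non_ca(self):
        assert cal.classify_site("GCAU", 1) == "other"

    def test_transcript_end_is_not_a_site(self):
        with pytest.raises(ValueError):
            cal.classify_site("GCAU", 4)

    def test_site_classes_vector(self):
        classes = cal.site_classes("CACA")
        assert list(classes) == ["CA", "other", "CA", "other"]


class TestBinSignals:
    def test_single_bin_phat(self):
        values = np.full(40, 0.5)
        labels = np.array([True] * 30 + [False] * 10)
        bins = cal.bin_signals(values, labels, edges=(0.0, 1.0), min_bin_count=20)
        (b,) = bins
        assert b.n == 40 and b.n_u == 30 and b.p_hat == pytest.approx(0.75)

    def test_small_bin_gets_nan_phat(self):
        bins = cal.bin_signals(
            np.array([0.5, 0.6, 0.7]), np.array([True, True, False]),
            edges=(0.0, 1.0), min_bin_count=20,
        )
        assert len(bins) == 1 and np.isnan(bins[0].p_hat)

    def test_counts_match_bruteforce_tally(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 7, size=500)
        labels = rng.random(500) < 0.4
        edges = cal.DEFAULT_EDGES_1D
        bins = cal.bin_signals(values, labels, edges, min_bin_count=1)
        # brute-force position-by-position tally
        expected = {}
        for v, u in zip(values, labels):
            for k in range(len(edges) - 1):
                hi_ok = v < edges[k + 1] or (k == len(edges) - 2 and v <= edges[-1])
                if edges[k] <= v and hi_ok:
                    n, nu = expected.get(k, (0, 0))
                    expected[k] = (n + 1, nu + int(u))
                    break
        assert sum(b.n for b in bins) == 500
        assert sorted((b.n, b.n_u) for b in bins) == sorted(expected.values())

    def test_bin_totals_and_prior(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 7, size=2000)
        labels = rng.random(2000) < 0.42
        bins = cal.bin_signals(values, labels, min_bin_count=1)
        assert sum(b.n for b in bins) == 2000
        assert sum(b.n_u for b in bins) <= sum(b.n for b in bins)
        weighted = sum(b.p_hat * b.n for b in bins) / sum(b.n for b in bins)
        assert weighted == pytest.approx(labels.mean())


def _bins_from_function(params, centers, n=1000):
    a, b, c = params
    return [
        cal.CalibrationBin((s,), 0, n, float(1 / (1 + np.exp(-a * s + b)) + c))
        for s in centers
    ]


class TestFitSigmoid:
    def test_noiseless_parameter_recovery(self):
        centers = np.linspace(0.05, 6.5, 12)
        bins = _bins_from_function((2.0, 3.0, 0.10), centers)
        model = cal.fit_sigmoid(bins, "oneD")
        assert model.params == pytest.approx((2.0, 3.0, 0.10), abs=1e-6)

    def test_constant_phat_yields_flat_curve(self):
        bins = [
            cal.CalibrationBin((s,), 0, 100, 0.42) for s in np.linspace(0.1, 6.5, 8)
        ]
        model = cal.fit_sigmoid(bins, "oneD")
        pred = model.predict(np.linspace(0, 7, 200))
        assert np.all(np.abs(pred - 0.42) < 0.02)

    def test_monotone_data_gives_positive_slope(self):
        centers = np.linspace(0.1, 6.0, 8)
        bins = [
            cal.CalibrationBin((s,), 0, 100, p)
            for s, p in zip(centers, np.linspace(0.1, 0.9, 8))
        ]
        model = cal.fit_sigmoid(bins, "oneD")
        assert model.params[0] > 0

    def test_too_few_bins_raises(self):
        bins = _bins_from_function((2.0, 3.0, 0.1), [0.5, 1.5, 3.0])
        with pytest.raises(cal.CalibrationError, match="insufficient"):
            cal.fit_sigmoid(bins, "oneD")

    def test_2d_noiseless_recovery(self):
        a1, a2, b, c = 1.5, 2.5, 3.0, 0.05
        rng = np.random.default_rng(2)
        bins = []
        for _ in range(20):
            s1, s2 = rng.uniform(0, 3, size=2)
            p = 1 / (1 + np.exp(-a1 * s1 - a2 * s2 + b)) + c
            bins.append(cal.CalibrationBin((float(s1), float(s2)), 0, 100, float(p)))
        model = cal.fit_sigmoid(bins, "twoD")
        assert model.params == pytest.approx((a1, a2, b, c), abs=1e-5)


class TestStochasticRecovery:
    """Data simulated from a known response curve must be recovered."""

    A, B, C = 2.0, 3.0, 0.10

    def _simulate(self, n, rng):
        s = rng.uniform(0, 2.5, size=n)  # below the p==1 saturation point
        p = 1 / (1 + np.exp(-self.A * s + self.B)) + self.C
        labels = rng.random(n) < np.clip(p, 0, 1)
        return s, labels

    def test_parameters_recovered_within_ten_percent(self):
        rng = np.random.default_rng(42)
        s, labels = self._simulate(100_000, rng)
        bins = cal.bin_signals(s, labels)
        model = cal.fit_sigmoid(bins, "oneD")
        for got, want in zip(model.params, (self.A, self.B, self.C)):
            assert abs(got - want) / abs(want) < 0.10

    def test_shuffled_labels_flatten_the_curve(self):
        rng = np.random.default_rng(42)
        s, labels = self._simulate(100_000, rng)
        _, flat = cal.randomization_control(s, labels, seed=7)
        assert flat < 0.05
        unshuffled = cal.fit_sigmoid(cal.bin_signals(s, labels), "oneD")
        assert cal.flatness_statistic(unshuffled, s) > 0.2

    def test_randomization_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        s, labels = self._simulate(5000, rng)
        groups = np.repeat(np.arange(10), 500)
        m1, f1 = cal.randomization_control(s, labels, groups, seed=3)
        m2, f2 = cal.randomization_control(s, labels, groups, seed=3)
        assert m1.params == m2.params and f1 == f2


def _model_set():
    mk = cal.SigmoidModel
    models = {
        ("twoD", None, "other"): mk("twoD", "other", None, (1.0, 1.0, 1.0, 0.0)),
        ("twoD", None, "CA"): mk("twoD", "CA", None, (0.5, 1.5, 1.0, 0.0)),
        ("oneD", "cP", "other"): mk("oneD", "other", "cP", (2.0, 1.0, 0.0)),
        ("oneD", "cP", "CA"): mk("oneD", "CA", "cP", (1.0, 1.0, 0.0)),
        ("oneD", "OH", "other"): mk("oneD", "other", "OH", (2.0, 1.0, 0.0)),
        ("oneD", "OH", "CA"): mk("oneD", "CA", "OH", (1.0, 1.0, 0.0)),
    }
    return cal.CalibrationModelSet(models=models, p0=0.42)


class TestPredictUnpaired:
    def _tracks(self, length=40):
        t = TranscriptRecord("t1", "ACGU" * (length // 4))
        s_cp = np.full(length, 0.5)
        s_cp[:11] = np.nan  # cP blind 5' end
        s_oh = np.full(length, 0.5)
        s_oh[-12:] = np.nan  # OH blind 3' end
        cp = NormalizedTrack("t1", "cP", s_cp, 1.0)
        oh = NormalizedTrack("t1", "OH", s_oh, 1.0)
        return t, cp, oh

    def test_sources_follow_blind_end_fallback(self):
        t, cp, oh = self._tracks()
        profile = cal.predict_unpaired(_model_set(), cp, oh, t)
        assert list(profile.source[:11]) == ["OH_only"] * 11
        assert list(profile.source[-12:]) == ["cP_only"] * 12
        assert set(profile.source[11:-12]) == {"twoD"}
        assert np.all(np.isfinite(profile.q))

    def test_double_nan_yields_none_source(self):
        t, cp, oh = self._tracks()
        cp.values[20] = np.nan
        oh.values[20] = np.nan
        profile = cal.predict_unpaired(_model_set(), cp, oh, t)
        assert profile.source[20] == "none" and np.isnan(profile.q[20])

    def test_monotone_in_each_signal(self):
        t, cp, oh = self._tracks()
        base = cal.predict_unpaired(_model_set(), cp, oh, t)
        cp_hi = NormalizedTrack("t1", "cP", cp.values + 0.5, 1.0)
        up = cal.predict_unpaired(_model_set(), cp_hi, oh, t)
        interior = slice(11, -12)
        assert np.all(up.q[interior] >= base.q[interior])

    def test_ca_site_without_2d_ca_model_uses_oh_only(self):
        models = _model_set()
        del models.models[("twoD", None, "CA")]
        t = TranscriptRecord("t1", "CA" * 20)
        cp = NormalizedTrack("t1", "cP", np.full(40, 3.0), 1.0)
        oh = NormalizedTrack("t1", "OH", np.full(40, 0.1), 1.0)
        profile = cal.predict_unpaired(models, cp, oh, t)
        ca_positions = [i for i in range(39) if t.sequence[i : i + 2] == "CA"]
        assert all(profile.source[i] == "OH_only" for i in ca_positions)


class TestModelSerialization:
    def test_json_round_trip(self, tmp_path):
        models = _model_set()
        path = tmp_path / "model.json"
        models.to_json(path)
        back = cal.CalibrationModelSet.from_json(path)
        assert back.p0 == models.p0
        assert set(back.models) == set(models.models)
        for key in models.models:
            assert back.models[key].params == models.models[key].params


class TestCalibrationTable:
    def test_table_prior_and_fit_on_synthetic_structures(self):
        length = 400
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGU"), size=length))
        db = "." * length  # all unpaired
        struct = ReferenceStructure("t1", db)
        t = TranscriptRecord("t1", seq)
        cp = NormalizedTrack("t1", "cP", rng.uniform(0, 7, length), 1.0)
        oh = NormalizedTrack("t1", "OH", rng.uniform(0, 7, length), 1.0)
        table = cal.assemble_calibration_table([cp], [oh], [struct], [t])
        assert len(table) == length
        assert cal.prior_unpaired(table) == 1.0
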