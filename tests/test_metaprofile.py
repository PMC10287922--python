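import numpy as np
import pandas as pd
import pytest

from ledseq import metaprofile as mp
from ledseq.types import CoverageReport, NormalizedTrack


def annotation_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "start", "end", "strand", "kind", "cds_start"]
    )


def passing(tid):
    return CoverageReport(tid, 1.0, 10.0, True)


def failing(tid):
    return CoverageReport(tid, 0.5, 1.0, False)


class TestSelectMrnas:
    def test_upstream_overlap_excludes(self):
        ann = annotation_frame([
            ("m1", 1000, 1500, "+", "mRNA", 1100),
            ("trna", 1040, 1060, "+", "other", 0),  # inside m1's upstream window
            ("m2", 3000, 3500, "+", "mRNA", 3100),
        ])
        cov = {"m1": passing("m1"), "m2": passing("m2")}
        assert mp.select_mrnas(ann, cov) == ["m2"]

    def test_coverage_failure_excludes(self):
        ann = annotation_frame([
            ("m1", 1000, 1500, "+", "mRNA", 1100),
            ("m2", 3000, 3500, "+", "mRNA", 3100),
        ])
        cov = {"m1": passing("m1"), "m2": failing("m2")}
        assert mp.select_mrnas(ann, cov) == ["m1"]

    def test_passing_both_conditions_included(self):
        ann = annotation_frame([("m1", 1000, 1500, "+", "mRNA", 1100)])
        assert mp.select_mrnas(ann, {"m1": passing("m1")}) == ["m1"]


def constant_track(tid, length, value, library="cP"):
    return NormalizedTrack(tid, library, np.full(length, float(value)), 1.0)


ANN2 = annotation_frame([
    ("m1", 1, 400, "+", "mRNA", 101),
    ("m2", 1001, 1400, "+", "mRNA", 1101),
])


class TestBuildProfile:
    def test_mean_of_constant_signals(self):
        tracks = {
            "m1": constant_track("m1", 400, 0.4),
            "m2": constant_track("m2", 400, 0.6),
        }
        profile = mp.build_profile(tracks, ANN2, ["m1", "m2"], "cP")
        assert profile.values.shape == (2, 228)
        assert np.allclose(profile.mean, 0.5)
        assert np.all(profile.n_transcripts == 2)
        assert 0 not in profile.positions

    def test_single_coverage_position(self):
        t1 = constant_track("m1", 400, 0.4)
        t1.values[:] = np.nan
        idx = 100 + 5 - 1  # transcript position of meta +5 (cds_tx=101)
        t1.values[idx] = 0.9
        tracks = {"m1": t1, "m2": constant_track("m2", 400, 0.3)}
        profile = mp.build_profile(tracks, ANN2, ["m1", "m2"], "cP")
        c = profile.position_index(5)
        assert profile.n_transcripts[c] == 2
        assert profile.mean[c] == pytest.approx((0.9 + 0.3) / 2)
        other = profile.position_index(6)
        assert profile.n_transcripts[other] == 1
        assert profile.mean[other] == pytest.approx(0.3)

    def test_blind_end_positions_excluded(self):
        # cP blind end (transcript positions 1..11) lands in the meta window
        # when the UTR is short: annotate cds_start near the transcript start
        ann = annotation_frame([("m1", 1, 400, "+", "mRNA", 31)])
        t1 = constant_track("m1", 400, 0.5)
        t1.values[:11] = np.nan  # as normalize() produces
        profile = mp.build_profile({"m1": t1}, ann, ["m1"], "cP")
        # meta -30..-20 correspond to transcript 1..11
        for m in range(-30, -19):
            assert profile.n_transcripts[profile.position_index(m)] == 0
        assert profile.n_transcripts[profile.position_index(-19)] == 1

    def test_transcript_order_invariance_and_all_nan_transcript(self):
        tracks = {
            "m1": constant_track("m1", 400, 0.4),
            "m2": constant_track("m2", 400, 0.6),
        }
        p12 = mp.build_profile(tracks, ANN2, ["m1", "m2"], "cP")
        p21 = mp.build_profile(tracks, ANN2, ["m2", "m1"], "cP")
        assert np.allclose(p12.mean, p21.mean)
        nan_track = constant_track("m2", 400, 0.0)
        nan_track.values[:] = np.nan
        ann3 = annotation_frame([
            ("m1", 1, 400, "+", "mRNA", 101),
            ("m2", 1001, 1400, "+", "mRNA", 1101),
        ])
        p_with_nan = mp.build_profile(
            {"m1": tracks["m1"], "m2": nan_track}, ann3, ["m1", "m2"], "cP"
        )
        assert np.allclose(p_with_nan.mean, 0.4)

    def test_empty_eligible_raises(self):
        with pytest.raises(ValueError):
            mp.build_profile({}, ANN2, [], "cP")


def profile_from_matrix(values):
    return mp.MetaProfile("cP", mp.META_POSITIONS, np.asarray(values, dtype=float),
                          [f"m{i}" for i in range(len(values))])


class TestRegionStats:
    def test_identical_regions_not_significant(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0.4, 0.05, size=(30, 228))
        out = mp.region_stats(profile_from_matrix(values))
        assert out["tests"]["UTR_vs_CDS_1_60"]["pvalue"] > 0.01
        assert abs(out["means"]["UTR"] - out["means"]["CDS_1_60"]) < 0.02

    def test_shifted_cds_detected(self):
        rng = np.random.default_rng(1)
        values = rng.normal(0.4, 0.1, size=(500, 228))
        cds_cols = [i for i, m in enumerate(mp.META_POSITIONS) if 1 <= m <= 60]
        values[:, cds_cols] += 0.1
        out = mp.region_stats(profile_from_matrix(values))
        test = out["tests"]["UTR_vs_CDS_1_60"]
        assert test["pvalue"] < 1e-6
        assert out["means"]["CDS_1_60"] - out["means"]["UTR"] == pytest.approx(0.1, abs=0.02)
        assert test["statistic"] < 0  # UTR mean below CDS mean

    def test_constant_profile_equal_means(self):
        out = mp.region_stats(profile_from_matrix(np.full((5, 228), 0.37)))
        for value in out["means"].values():
            assert value == pytest.approx(0.37)

    def test_pooled_and_per_position_region_means_agree_on_full_coverage(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.5, 0.1, size=(40, 228))
        profile = profile_from_matrix(values)
        out = mp.region_stats(profile)
        for region, (lo, hi) in mp.REGIONS.items():
            cols = [i for i, m in enumerate(mp.META_POSITIONS) if lo <= m <= hi]
            pooled = values[:, cols].mean()
            assert out["means"][region] == pytest.approx(pooled, abs=1e-12)

    def test_by_transcript_mode(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0.4, 0.05, size=(60, 228))
        out = mp.region_stats(profile_from_matrix(values), by_transcript=True)
        assert np.isfinite(out["tests"]["UTR_vs_CDS_1_60"]["pvalue"])


class TestCodonPeriodicity:
    def test_exact_period_three_pattern(self):
        values = np.zeros((3, 228))
        pattern = {1: 0.3, 2: 0.4, 3: 0.5}
        for i, m in enumerate(mp.META_POSITIONS):
            if m >= 1:
                values[:, i] = pattern[(m - 1) % 3 + 1]
            else:
                values[:, i] = 0.4
        out = mp.codon_periodicity(profile_from_matrix(values))
        for f in (1, 2, 3):
            assert out["CDS"]["frame_means"][f] == pytest.approx(pattern[f])
        assert out["CDS"]["tests"]["1_vs_3"]["pvalue"] < 1e-10

    def test_aperiodic_constant_signal(self):
        out = mp.codon_periodicity(profile_from_matrix(np.full((4, 228), 0.4)))
        means = out["CDS"]["frame_means"]
        assert means[1] == means[2] == means[3] == pytest.approx(0.4)

    def test_utr_pseudo_frame_flat_when_only_cds_periodic(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0.4, 0.02, size=(50, 228))
        for i, m in enumerate(mp.META_POSITIONS):
            if m >= 1 and (m - 1) % 3 == 2:
                values[:, i] += 0.15
        out = mp.codon_periodicity(profile_from_matrix(values))
        assert out["CDS"]["frame_means"][3] > out["CDS"]["frame_means"][1]
        assert out["CDS"]["tests"]["1_vs_3"]["pvalue"] < 1e-6
        assert out["UTR"]["tests"]["1_vs_3"]["pvalue"] > 0.01


class TestEndToEndMrnaAnalysis:
    def test_simulated_third_position_boost_is_recovered(self):
        from ledseq import workflow as wf
        from ledseq.simulate import MrnaSimConfig, SimulationConfig, make_mrna_dataset
        from ledseq.cleavage_signal import coverage_filter

        transcripts, annotation, fragments, _ = make_mrna_dataset(
            n_mrnas=25, seed=2,
            config=MrnaSimConfig(cleavage=SimulationConfig(n_replicates=2)),
        )
        counts = wf.count_all(fragments, transcripts, ["r1", "r2"])
        per_rep, averaged = wf.normalize_and_average(counts)
        coverage = {
            tid: coverage_filter(counts[(tid, "cP", "r1")])
            for tid in [t.id for t in transcripts]
        }
        eligible = mp.select_mrnas(annotation, coverage)
        assert len(eligible) >= 20
        tracks = {tid: tr for (tid, lib), tr in averaged.items() if lib == "cP"}
        profile = mp.build_profile(tracks, annotation, eligible, "cP")
        out = mp.codon_periodicity(profile)
        assert out["CDS"]["frame_means"][3] > out["CDS"]["frame_means"][1]
        regions = mp.region_stats(profile)
        # simulated ordering: early CDS most open, late CDS least
        assert regions["means"]["CDS_1_60"] > regions["means"]["UTR"]
        assert regions["means"]["CDS_1_60"] > regions["means"]["CDS_61_180"]
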