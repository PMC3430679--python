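"""Insert model, discordant clustering, dropout segmentation, evidence
merging and exact junction-read breakpoint refinement."""

import numpy as np
import pandas as pd
import pytest

from lethalscan import sv_calling as sv
from lethalscan import synthetic_data as sd
from lethalscan.errors import DataError


def pairs_frame(distances, start=1000):
    n = len(distances)
    pos1 = np.arange(n) * 10 + start
    d = np.asarray(distances)
    return pd.DataFrame(
        {
            "pair_id": [f"p{i}" for i in range(n)],
            "chrom": "ref",
            "pos1": pos1,
            "end1": pos1 + 76,
            "pos2": pos1 + d - 76,
            "end2": pos1 + d,
            "orientation": "FR",
            "mapped_distance": d,
        }
    )


class TestInsertModel:
    def test_degenerate_constant_library(self):
        model = sv.fit_insert_model(pairs_frame([4250] * 200))
        assert model.mean == 4250 and model.sd == 0
        assert model.threshold > model.mean

    def test_uniform_sample_mean(self):
        rng = np.random.default_rng(3)
        model = sv.fit_insert_model(pairs_frame(rng.integers(4000, 4501, size=5000)))
        assert model.mean == pytest.approx(4250, abs=50)

    def test_robust_to_contamination(self):
        rng = np.random.default_rng(4)
        d = rng.integers(4000, 4501, size=5000)
        d[:50] = 8000  # 1% deletion-spanning pairs
        model = sv.fit_insert_model(pairs_frame(d), trim_quantile=0.05)
        assert model.mean == pytest.approx(4250, abs=50)

    def test_too_few_pairs(self):
        with pytest.raises(DataError):
            sv.fit_insert_model(pairs_frame([4250] * 99))


class TestClusterDiscordant:
    def test_no_discordant_pairs(self):
        model = sv.InsertModel(4250, 100, 4650, 200)
        assert sv.cluster_discordant(pairs_frame([4200] * 200), model) == []

    def test_simulated_deletion_size_estimate(self, dd_reads, wt_reads):
        model = sv.fit_insert_model(wt_reads.pairs)
        clusters = sv.cluster_discordant(dd_reads.pairs, model)
        assert len(clusters) == 1
        assert clusters[0].size_estimate == pytest.approx(3329, abs=300)
        assert clusters[0].n_pairs > 100

    def test_two_planted_deletions_two_clusters(self):
        model = sv.InsertModel(4250, 100, 4650, 200)
        rng = np.random.default_rng(5)
        a = pairs_frame(rng.integers(7500, 7700, size=30), start=10_000)
        b = pairs_frame(rng.integers(7500, 7700, size=30), start=80_000)
        both = pd.concat([a, b], ignore_index=True)
        clusters = sv.cluster_discordant(both, model, max_gap=1000)
        assert len(clusters) == 2

    def test_size_estimate_unbiased_over_seeds(self):
        # mean of the pre-refinement size estimate over many simulations
        model = None
        ests = []
        for seed in range(100):
            rs = sd.simulate_matepairs(
                sd.ReadSimConfig(seed=500 + seed, coverage=8.0), "D/D"
            )
            if model is None:
                wt = sd.simulate_matepairs(sd.ReadSimConfig(seed=499, coverage=8.0), "+/+")
                model = sv.fit_insert_model(wt.pairs)
            clusters = sv.cluster_discordant(rs.pairs, model)
            assert len(clusters) == 1
            ests.append(clusters[0].size_estimate)
        assert np.mean(ests) == pytest.approx(3329, rel=0.02)


class TestDetectDropout:
    def test_uniform_track_yields_nothing(self):
        assert sv.detect_dropout(np.full(20_000, 30.0)) == []

    def test_all_zero_track_rejected(self):
        with pytest.raises(DataError, match="flanking"):
            sv.detect_dropout(np.zeros(10_000))

    def test_deep_coverage_exact_interval(self, dd_reads):
        intervals = sv.detect_dropout(dd_reads.depth)
        assert intervals == [dd_reads.truth_interval]

    def test_sparse_coverage_still_detected(self):
        rs = sd.simulate_matepairs(sd.ReadSimConfig(seed=21, coverage=1.7), "D/D")
        intervals = sv.detect_dropout(rs.depth, window=500)
        ds, de = rs.truth_interval
        hits = [iv for iv in intervals if iv[0] <= ds and iv[1] >= de]
        assert len(hits) == 1
        assert hits[0][0] >= ds - 500 and hits[0][1] <= de + 500

    def test_het_mode_finds_half_depth_band(self):
        rs = sd.simulate_matepairs(sd.ReadSimConfig(seed=22), "D/+")
        intervals = sv.detect_dropout(rs.depth, window=500, mode="het")
        ds, de = rs.truth_interval
        assert any(iv[0] <= ds + 500 and iv[1] >= de - 500 for iv in intervals)


class TestMergeEvidence:
    def test_cluster_only(self):
        cl = sv.DeletionCandidate("ref", 100, 600, 480.0, 12)
        calls = sv.merge_evidence([cl], [])
        assert calls[0].evidence == "pair-only"

    def test_merged_tier_one(self, dd_reads, wt_reads):
        model = sv.fit_insert_model(wt_reads.pairs)
        clusters = sv.cluster_discordant(dd_reads.pairs, model)
        dropouts = sv.detect_dropout(dd_reads.depth)
        calls = sv.merge_evidence(clusters, dropouts)
        assert len(calls) == 1
        assert calls[0].evidence == "pair+dropout"
        assert (calls[0].start, calls[0].end) == dd_reads.truth_interval

    def test_disjoint_evidence_stays_separate(self):
        cl = sv.DeletionCandidate("ref", 100, 600, 480.0, 12)
        calls = sv.merge_evidence([cl], [(50_000, 53_000)])
        assert len(calls) == 2
        assert {c.evidence for c in calls} == {"pair-only", "dropout-only"}

    def test_no_false_tier_one_on_wildtype(self):
        wt0 = sd.simulate_matepairs(sd.ReadSimConfig(seed=998), "+/+")
        model = sv.fit_insert_model(wt0.pairs)
        for seed in range(50):
            rs = sd.simulate_matepairs(sd.ReadSimConfig(seed=700 + seed), "+/+")
            clusters = sv.cluster_discordant(rs.pairs, model)
            dropouts = sv.detect_dropout(rs.depth)
            calls = sv.merge_evidence(clusters, dropouts)
            assert not any(c.evidence == "pair+dropout" for c in calls)


class TestRefineBreakpoints:
    @pytest.mark.parametrize("size", [500, 3329, 10_000])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_size_recovery(self, size, seed):
        cfg = sd.ReadSimConfig(
            reference_length=80_000,
            deletion_start=40_000,
            deletion_end=40_000 + size,
            coverage=20.0,
            seed=seed,
        )
        rs = sd.simulate_matepairs(cfg, "D/D")
        assert len(rs.junction_reads) >= 1
        call = sv.DeletionCall("ref", 39_000, 41_000 + size, 0, "dropout-only")
        refined = sv.refine_breakpoints(call, rs.junction_reads, rs.reference)
        assert refined.refined
        assert refined.size == size

    def test_engineered_microhomology(self):
        rng = np.random.default_rng(77)
        ref = list(sd.random_dna(10_000, rng))
        ds, de = 4000, 6000
        ref[de : de + 5] = ref[ds : ds + 5]  # 5 bp identical after both breakpoints
        ref[de + 5] = "A" if ref[ds + 5] != "A" else "C"  # stop the match at 5
        ref[ds - 1] = "A"
        ref[de - 1] = "C" if ref[ds - 1] == "A" else "A"  # no left-side homology
        ref = "".join(ref)
        read = ref[ds - 40 : ds] + ref[de : de + 40]
        call = sv.DeletionCall("ref", ds - 100, de + 100, 0, "dropout-only")
        refined = sv.refine_breakpoints(call, [read], ref)
        assert refined.refined
        assert refined.size == de - ds
        assert refined.microhomology == 5

    def test_random_breakpoints_low_microhomology(self):
        mhs = []
        for seed in range(20):
            rs = sd.simulate_matepairs(sd.ReadSimConfig(seed=900 + seed, coverage=5.0), "D/D")
            if len(rs.junction_reads) == 0:
                continue
            call = sv.DeletionCall("ref", 29_000, 34_500, 0, "dropout-only")
            refined = sv.refine_breakpoints(call, rs.junction_reads, rs.reference)
            if refined.refined:
                mhs.append(refined.microhomology)
        assert len(mhs) >= 10
        assert np.median(mhs) <= 3

    def test_unrefined_without_junction_reads(self):
        ref = sd.random_dna(5000, np.random.default_rng(1))
        call = sv.DeletionCall("ref", 1000, 2000, 3, "pair-only")
        out = sv.refine_breakpoints(call, [], ref)
        assert not out.refined and out.size == 1000
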