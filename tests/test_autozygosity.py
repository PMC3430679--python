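"""ROH detection, shared-segment maximality (vs brute force) and the
Monte-Carlo genome-wide sharing statistic."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lethalscan import autozygosity as az
from lethalscan import synthetic_data as sd
from lethalscan.errors import ConfigurationError, DataError

from conftest import tiny_genotype_matrix


def brute_force_roh(geno, min_markers, max_het):
    """All maximal intervals with <= max_het hets, no missing, >= min_markers."""
    m = len(geno)
    valid = []
    for s in range(m):
        for e in range(s + 1, m + 1):
            win = geno[s:e]
            if (win < 0).any() or (win == 1).sum() > max_het:
                continue
            valid.append((s, e))
    maximal = [
        (s, e)
        for s, e in valid
        if not any((s2 <= s and e <= e2) and (s2, e2) != (s, e) for s2, e2 in valid)
    ]
    return sorted((s, e) for s, e in maximal if e - s >= min_markers)


def brute_force_shared(case_rows, marker_index):
    """Maximal interval around marker_index where all cases are identical-homozygous."""
    G = np.asarray(case_rows)
    ok = lambda j: set(G[:, j]) <= {0} or set(G[:, j]) <= {2}
    if not ok(marker_index):
        return None
    s = marker_index
    while s > 0 and ok(s - 1):
        s -= 1
    e = marker_index + 1
    while e < G.shape[1] and ok(e):
        e += 1
    return (s, e)


class TestDetectROH:
    def test_fully_heterozygous_yields_nothing(self):
        gm = tiny_genotype_matrix([[1] * 10, [1] * 10])
        assert az.detect_roh(gm, "case_0", min_markers=1, max_het=0) == []

    def test_single_het_within_budget(self):
        gm = tiny_genotype_matrix([[2, 2, 1, 2, 2], [0] * 5])
        runs = az.detect_roh(gm, "case_0", min_markers=1, max_het=1)
        assert [(r.start_idx, r.end_idx) for r in runs] == [(0, 5)]

    def test_all_missing_individual(self):
        gm = tiny_genotype_matrix([[-1] * 8, [0] * 8])
        assert az.detect_roh(gm, "case_0", min_markers=1) == []

    @pytest.mark.parametrize("max_het", [0, 1, 2])
    def test_matches_brute_force(self, max_het):
        rng = np.random.default_rng(17)
        for _ in range(25):
            geno = rng.choice([0, 1, 2, -1], size=15, p=[0.35, 0.2, 0.35, 0.1])
            gm = tiny_genotype_matrix([geno, [0] * 15])
            got = sorted(
                (r.start_idx, r.end_idx)
                for r in az.detect_roh(gm, "case_0", min_markers=2, max_het=max_het)
            )
            assert got == brute_force_roh(geno, 2, max_het), (geno.tolist(), max_het)

    def test_planted_interval_recovered_in_case(self, planted_genotypes):
        gm = planted_genotypes
        idx = gm.markers.interval_markers(*gm.truth_interval)
        runs = az.detect_roh(gm, "case_0", min_markers=10, max_het=0)
        covering = [r for r in runs if r.start_idx <= idx[0] and r.end_idx >= idx[-1] + 1]
        assert len(covering) == 1


class TestSharedSegment:
    def test_none_when_any_case_het_at_query(self):
        gm = tiny_genotype_matrix([[2, 2, 2], [2, 1, 2]])
        assert az.shared_segment_at(gm, gm.case_ids, 1) is None

    def test_out_of_range_rejected(self):
        gm = tiny_genotype_matrix([[2, 2], [2, 2]])
        with pytest.raises(DataError):
            az.shared_segment_at(gm, gm.case_ids, 5)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(40):
            G = rng.choice([0, 1, 2], size=(4, 18), p=[0.4, 0.2, 0.4])
            gm = tiny_genotype_matrix(G)
            q = int(rng.integers(0, 18))
            seg = az.shared_segment_at(gm, gm.case_ids, q)
            expected = brute_force_shared(G, q)
            got = None if seg is None else (seg.start_idx, seg.end_idx)
            assert got == expected, (G.tolist(), q)

    def test_contains_planted_interval(self, planted_genotypes):
        gm = planted_genotypes
        idx = gm.markers.interval_markers(*gm.truth_interval)
        seg = az.shared_segment_at(gm, gm.case_ids, int(idx[len(idx) // 2]))
        assert seg is not None
        assert seg.start_idx <= idx[0] and seg.end_idx >= idx[-1] + 1


class TestSharingStatistic:
    def _segment(self, alleles, n_cases=6):
        return az.SharedSegment(
            chrom="1", start_idx=0, end_idx=len(alleles), start_bp=1,
            end_bp=len(alleles), alleles=np.array(alleles, dtype=np.int8),
            n_cases=n_cases,
        )

    def test_fixed_haplotype_limits_to_one(self):
        seg = self._segment([1, 1, 1])
        haps = np.ones((200, 3), dtype=np.int8)
        p = az.sharing_statistic(seg, haps, pseudocount=1e-9)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_half_frequency_closed_form(self):
        seg = self._segment([1])
        haps = np.array([[1]] * 99 + [[0]] * 99, dtype=np.int8)
        p = az.sharing_statistic(seg, haps, pseudocount=1.0)
        assert p == pytest.approx(0.5**12)

    def test_zero_matches_pseudocount_floor(self):
        seg = self._segment([1, 0, 1])
        haps = np.zeros((200, 3), dtype=np.int8)
        p = az.sharing_statistic(seg, haps, pseudocount=1.0)
        assert p == pytest.approx((1 / 202) ** 12)
        assert seg.control_matches == 0

    def test_monotone_in_matches(self):
        haps = np.zeros((200, 2), dtype=np.int8)
        last = 0.0
        for k in (0, 5, 50, 200):
            h = haps.copy()
            h[:k] = 1
            seg = self._segment([1, 1])
            p = az.sharing_statistic(seg, h)
            assert p > last
            last = p

    def test_no_controls_rejected(self):
        with pytest.raises(DataError):
            az.sharing_statistic(self._segment([1]), np.empty((0, 1)))


class TestGenomewideScan:
    @staticmethod
    def _min_hits_planted(scan, gm):
        """Does any marker attaining the minimum p lie inside the planted interval?

        p is constant across a shared segment, so the minimum is tied along
        the whole segment (which may extend a marker or two past the planted
        boundary through chance homozygosity)."""
        chrom, start, end = gm.truth_interval
        m = gm.markers
        at_min = np.flatnonzero(scan.p_point == scan.observed_min_p)
        return any(
            m.chrom[j] == chrom and start < m.pos[j] <= end for j in at_min
        )

    def test_planted_haplotype_genomewide_significant(self, planted_genotypes):
        scan = az.genomewide_scan(planted_genotypes, n_reps=1000, seed=5)
        assert scan.min_segment.p_genomewide <= 0.001
        assert self._min_hits_planted(scan, planted_genotypes)

    def test_minimum_localises_inside_planted_interval(self, marker_map):
        hits = 0
        for seed in range(10):
            gm = sd.simulate_genotypes(
                sd.PopulationConfig(seed=100 + seed, carrier_freq=0.05), marker_map
            )
            scan = az.genomewide_scan(gm, n_reps=100, seed=seed)
            hits += self._min_hits_planted(scan, gm)
        assert hits == 10

    def test_null_calibration_when_cases_come_from_pool(self, marker_map):
        # pseudo-cases drawn from the control pool itself: the planted-interval
        # statistic should rarely look significant
        significant = 0
        n_trials = 40
        for seed in range(n_trials):
            gm = sd.simulate_genotypes(
                sd.PopulationConfig(seed=200 + seed, carrier_freq=0.2, n_cases=6),
                marker_map,
            )
            rng = np.random.default_rng(seed)
            pool = gm.control_haplotypes
            idx = rng.integers(0, pool.shape[0], size=12)
            pseudo = pool[idx[0::2]] + pool[idx[1::2]]
            gm2 = sd.GenotypeMatrix(
                markers=gm.markers,
                sample_ids=[f"case_{i}" for i in range(6)] + gm.control_ids,
                case_ids=[f"case_{i}" for i in range(6)],
                genotypes=np.vstack([pseudo, pool[0::2] + pool[1::2]]).astype(np.int8),
                control_haplotypes=pool,
            )
            scan = az.genomewide_scan(gm2, n_reps=150, seed=1000 + seed)
            if scan.p_genomewide <= 0.05:
                significant += 1
        assert significant <= 4  # ~5% expected under a calibrated null

    def test_add_one_floor(self, planted_genotypes):
        scan = az.genomewide_scan(planted_genotypes, n_reps=100, seed=2)
        assert scan.p_genomewide == pytest.approx(1 / 101)

    def test_invariant_to_control_order(self, marker_map):
        gm = sd.simulate_genotypes(sd.PopulationConfig(seed=31, carrier_freq=0.1), marker_map)
        scan_a = az.genomewide_scan(gm, n_reps=120, seed=9)
        perm = np.random.default_rng(0).permutation(gm.control_haplotypes.shape[0] // 2)
        haps = gm.control_haplotypes.reshape(-1, 2, gm.markers.n_markers)[perm].reshape(
            -1, gm.markers.n_markers
        )
        gm_perm = sd.GenotypeMatrix(
            markers=gm.markers,
            sample_ids=gm.sample_ids,
            case_ids=gm.case_ids,
            genotypes=gm.genotypes,
            control_haplotypes=haps,
        )
        scan_b = az.genomewide_scan(gm_perm, n_reps=120, seed=9)
        assert scan_a.p_genomewide == scan_b.p_genomewide
        np.testing.assert_array_equal(scan_a.null_min_p, scan_b.null_min_p)

    def test_too_few_reps_rejected(self, planted_genotypes):
        with pytest.raises(ConfigurationError):
            az.genomewide_scan(planted_genotypes, n_reps=10)

    def test_unphased_controls_rejected(self, planted_genotypes):
        gm = planted_genotypes
        bare = sd.GenotypeMatrix(
            markers=gm.markers,
            sample_ids=gm.sample_ids,
            case_ids=gm.case_ids,
            genotypes=gm.genotypes,
            control_haplotypes=None,
        )
        with pytest.raises(DataError, match="phased"):
            az.genomewide_scan(bare)
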