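"""Autozygosity mapping: shared homozygous haplotypes and their significance.

Affected individuals from a recessive defect that traces back to one common
ancestor are expected to be homozygous for a single shared (autozygous)
haplotype around the causal mutation. This module scans case genotypes for

* runs of homozygosity (ROH) per individual,
* the maximal interval at which *all* cases are homozygous for one identical
  haplotype (the shared segment), and
* a genome-wide chance-sharing probability for that segment.

The point statistic for a shared segment s is p(s) = f^(2n), the probability
that 2n chromosomes drawn at random from the population all carry the case
haplotype, with f estimated from phased control haplotypes using an add-one
pseudocount: f = (matches + 1) / (2 N_controls + 2). Genome-wide significance
comes from a Monte-Carlo null: in each replicate 2n chromosomes are redrawn
with replacement from the control pool, the identical scan is run, and the
genome-wide minimum p is recorded; the reported P_gw is the add-one estimator
(1 + #{null minima <= observed p}) / (n_reps + 1).

Cases are typically related, which makes the null anti-conservative; this is
a property of the design (shared ancestry is precisely the signal), not
corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError
from .synthetic_data import GenotypeMatrix

__all__ = [
    "ROHSegment",
    "SharedSegment",
    "ScanResult",
    "detect_roh",
    "shared_segment_at",
    "sharing_statistic",
    "genomewide_scan",
]


@dataclass(frozen=True)
class ROHSegment:
    """Maximal run of homozygosity; marker indices are 0-based half-open."""

    chrom: str
    start_idx: int
    end_idx: int
    start_bp: int
    end_bp: int
    n_markers: int
    n_het: int


@dataclass(eq=False)
class SharedSegment:
    """Maximal interval where every case is homozygous for one identical haplotype."""

    chrom: str
    start_idx: int
    end_idx: int  # half-open marker indices (global)
    start_bp: int
    end_bp: int
    alleles: np.ndarray  # shared haplotype (0/1 alt dosage per marker)
    n_cases: int
    control_matches: int | None = None
    p_point: float | None = None
    p_genomewide: float | None = None

    @property
    def n_markers(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(eq=False)
class ScanResult:
    """Per-marker point statistic and genome-wide calibrated segments."""

    p_point: np.ndarray  # per-marker p(s); 1.0 where no shared segment
    segments: list[SharedSegment]
    observed_min_p: float
    null_min_p: np.ndarray
    n_reps: int

    @property
    def min_segment(self) -> SharedSegment | None:
        if not self.segments:
            return None
        return min(self.segments, key=lambda s: s.p_point)

    @property
    def p_genomewide(self) -> float:
        return _add_one(self.null_min_p, self.observed_min_p, self.n_reps)


def _add_one(null_min: np.ndarray, observed: float, n_reps: int) -> float:
    return (1.0 + int((null_min <= observed).sum())) / (n_reps + 1.0)


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return []
    d = np.diff(m.astype(np.int8))
    starts = (np.flatnonzero(d == 1) + 1).tolist()
    ends = (np.flatnonzero(d == -1) + 1).tolist()
    if m[0]:
        starts = [0] + starts
    if m[-1]:
        ends = ends + [m.size]
    return list(zip(starts, ends))


def detect_roh(
    genotypes: GenotypeMatrix,
    individual: str,
    min_markers: int = 20,
    max_het: int = 0,
) -> list[ROHSegment]:
    """Maximal runs with >= min_markers markers and <= max_het heterozygous calls.

    Missing genotypes always break a run (conservative: a gap is never
    assumed homozygous). With max_het > 0, reported runs are maximal in the
    sense that extending them by one marker on either side would exceed the
    heterozygote budget (or leave the chromosome / hit a missing call).
    """
    g = genotypes.genotypes_of(individual)
    markers = genotypes.markers
    out: list[ROHSegment] = []
    for chrom in markers.chromosomes:
        lo, hi = markers.chrom_block(chrom)
        gc = g[lo:hi]
        for bs, be in _true_runs(gc >= 0):  # split at missing
            het = np.flatnonzero(gc[bs:be] == 1) + bs
            out.extend(
                _maximal_budget_runs(chrom, markers, lo, bs, be, het, max_het, min_markers)
            )
    return out


def _maximal_budget_runs(chrom, markers, block_off, bs, be, het_idx, max_het, min_markers):
    """Maximal sub-intervals of [bs, be) containing at most max_het of het_idx."""
    segs = []
    h = het_idx.tolist()
    if len(h) <= max_het:
        candidates = [(bs, be, len(h))]
    else:
        bounds = [bs - 1] + h + [be]
        candidates = []
        # a maximal window contains exactly max_het hets, bounded by the
        # neighbouring hets just outside the budget
        for t in range(len(h) - max_het + 1):
            start = bounds[t] + 1
            end = bounds[t + max_het + 1]
            candidates.append((start, end, max_het))
    for start, end, nh in candidates:
        if end - start >= min_markers:
            segs.append(
                ROHSegment(
                    chrom=chrom,
                    start_idx=block_off + start,
                    end_idx=block_off + end,
                    start_bp=int(markers.pos[block_off + start]),
                    end_bp=int(markers.pos[block_off + end - 1]),
                    n_markers=end - start,
                    n_het=nh,
                )
            )
    return segs


def _shared_mask(case_geno: np.ndarray) -> np.ndarray:
    """True where all cases are homozygous and pairwise identical."""
    hom = ((case_geno == 0) | (case_geno == 2)).all(axis=0)
    same = (case_geno == case_geno[0]).all(axis=0)
    return hom & same


def shared_segment_at(
    genotypes: GenotypeMatrix, case_ids: list[str], marker_index: int
) -> SharedSegment | None:
    """Maximal shared homozygous-identical segment containing one marker.

    Returns None when any case is heterozygous or missing at the query
    marker, or when the cases are not identical there.
    """
    if len(case_ids) < 2:
        raise DataError("need >= 2 cases to define a shared segment")
    markers = genotypes.markers
    if not 0 <= marker_index < markers.n_markers:
        raise DataError(f"marker index {marker_index} out of range")
    case_geno = np.vstack([genotypes.genotypes_of(s) for s in case_ids])
    chrom = markers.chrom[marker_index]
    lo, hi = markers.chrom_block(chrom)
    mask = _shared_mask(case_geno[:, lo:hi])
    k = marker_index - lo
    if not mask[k]:
        return None
    start = k
    while start > 0 and mask[start - 1]:
        start -= 1
    end = k + 1
    while end < mask.size and mask[end]:
        end += 1
    return _make_segment(genotypes, case_geno, chrom, lo + start, lo + end, len(case_ids))


def _make_segment(genotypes, case_geno, chrom, start, end, n_cases) -> SharedSegment:
    markers = genotypes.markers
    return SharedSegment(
        chrom=chrom,
        start_idx=start,
        end_idx=end,
        start_bp=int(markers.pos[start]),
        end_bp=int(markers.pos[end - 1]),
        alleles=(case_geno[0, start:end] // 2).astype(np.int8),
        n_cases=n_cases,
    )


def sharing_statistic(
    segment: SharedSegment,
    control_haplotypes: np.ndarray,
    pseudocount: float = 1.0,
) -> float:
    """Point probability p(s) = f^(2n) of chance sharing of a segment.

    f is the add-one frequency of the case haplotype among phased control
    haplotypes over the segment's markers. Monotone increasing in the number
    of matching controls.
    """
    if control_haplotypes is None or len(control_haplotypes) == 0:
        raise DataError("no control haplotypes supplied")
    haps = np.asarray(control_haplotypes)
    seg = haps[:, segment.start_idx : segment.end_idx]
    matches = int((seg == segment.alleles).all(axis=1).sum())
    n_haps = haps.shape[0]
    f = (matches + pseudocount) / (n_haps + 2.0 * pseudocount)
    segment.control_matches = matches
    segment.p_point = float(f ** (2 * segment.n_cases))
    return segment.p_point


def _scan_once(
    hap_rows: np.ndarray,
    pool: np.ndarray,
    chrom_blocks: list[tuple[str, int, int]],
    pseudocount: float,
) -> tuple[float, list[tuple[str, int, int, int, float]]]:
    """Scan 2n chromosomes for identical runs; score against the pool.

    Returns the genome-wide minimum p and the list of scored runs as
    (chrom, start, end, matches, p).
    """
    two_n = hap_rows.shape[0]
    n_haps = pool.shape[0]
    identical = (hap_rows == hap_rows[0]).all(axis=0)
    best = 1.0
    runs_out = []
    for chrom, lo, hi in chrom_blocks:
        for s, e in _true_runs(identical[lo:hi]):
            a, b = lo + s, lo + e
            vec = hap_rows[0, a:b]
            matches = int((pool[:, a:b] == vec).all(axis=1).sum())
            f = (matches + pseudocount) / (n_haps + 2.0 * pseudocount)
            p = float(f**two_n)
            runs_out.append((chrom, a, b, matches, p))
            best = min(best, p)
    return best, runs_out


def genomewide_scan(
    genotypes: GenotypeMatrix,
    case_ids: list[str] | None = None,
    n_reps: int = 1000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> ScanResult:
    """Genome-wide scan with a resampled-chromosome Monte-Carlo null.

    Observed shared segments are the maximal intervals where all cases are
    homozygous-identical; each is scored with p(s) = f^(2n). Under the null,
    each replicate draws 2n chromosomes with replacement from the phased
    control pool and records the genome-wide minimum p of the same scan.
    The control pool is put in a canonical (lexicographic) row order before
    resampling, so the result is invariant to the order in which control
    individuals are supplied.
    """
    if n_reps < 100:
        raise ConfigurationError("n_reps must be >= 100")
    if genotypes.control_haplotypes is None:
        raise DataError("controls must be supplied phased")
    case_ids = case_ids if case_ids is not None else genotypes.case_ids
    n = len(case_ids)
    if n < 2:
        raise DataError("need >= 2 cases")
    markers = genotypes.markers
    chrom_blocks = [(c, *markers.chrom_block(c)) for c in markers.chromosomes]

    pool = np.asarray(genotypes.control_haplotypes)
    order = np.lexsort(pool.T[::-1])
    pool = np.ascontiguousarray(pool[order])
    n_haps = pool.shape[0]

    # observed scan: case haplotype rows are the doubled shared genotype where
    # defined; we scan the genotype-level shared mask directly
    case_geno = np.vstack([genotypes.genotypes_of(s) for s in case_ids])
    mask = _shared_mask(case_geno)
    p_point = np.ones(markers.n_markers)
    segments: list[SharedSegment] = []
    for chrom, lo, hi in chrom_blocks:
        for s, e in _true_runs(mask[lo:hi]):
            seg = _make_segment(genotypes, case_geno, chrom, lo + s, lo + e, n)
            sharing_statistic(seg, pool, pseudocount)
            p_point[seg.start_idx : seg.end_idx] = seg.p_point
            segments.append(seg)
    observed_min = float(p_point.min())

    rng = np.random.default_rng(seed)
    null_min = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.integers(0, n_haps, size=2 * n)
        null_min[r], _ = _scan_once(pool[idx], pool, chrom_blocks, pseudocount)

    for seg in segments:
        seg.p_genomewide = _add_one(null_min, seg.p_point, n_reps)
    return ScanResult(
        p_point=p_point,
        segments=segments,
        observed_min_p=observed_min,
        null_min_p=null_min,
        n_reps=n_reps,
    )
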