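"""Deletion calling from discordant mate pairs, coverage dropout and junctions.

A multi-kb deletion leaves three footprints in mate-pair data:

1. pairs whose fragment spans the deletion map "too far apart" on the
   reference — their mapped distance is the library insert plus the deletion
   length — and cluster at the breakpoints;
2. read depth drops to zero (homozygous) or about half (heterozygous) inside
   the deleted interval;
3. reads crossing the novel junction carry the concatenated breakpoint
   sequence and pin the breakpoints to the base.

This module fits an insert-size model from concordant pairs, clusters
discordant pairs into candidate deletions, segments the depth track for
dropout intervals, merges the two evidence types, and refines breakpoints by
split-aligning junction reads (exact-match seed and extend; simulator reads
are error-free). Junction microhomology — identical sequence flanking both
breakpoints, which makes the exact breakpoint placement ambiguous — is
measured and reported; calls are left-aligned.

Coordinates are 0-based half-open throughout; VCF output is 1-based with a
symbolic <DEL> allele.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = [
    "InsertModel",
    "DeletionCandidate",
    "DeletionCall",
    "fit_insert_model",
    "cluster_discordant",
    "detect_dropout",
    "merge_evidence",
    "refine_breakpoints",
]


@dataclass(frozen=True)
class InsertModel:
    """Concordant mapped-distance model and the discordance threshold."""

    mean: float
    sd: float
    threshold: float
    n_pairs: int


@dataclass(frozen=True)
class DeletionCandidate:
    """Discordant-pair cluster: interval bounds compatible with every pair."""

    chrom: str
    start: int
    end: int
    size_estimate: float
    n_pairs: int


@dataclass(frozen=True)
class DeletionCall:
    """A called deletion with its evidence tier.

    Tier "pair+dropout" means a discordant cluster and a dropout interval
    reciprocally overlap by >= 0.5; "pair-only" / "dropout-only" calls carry a
    single evidence type. Refined calls have base-exact breakpoints from
    junction reads and a measured microhomology length (0 is a valid value —
    the study's breakpoints showed no obvious sequence similarity).
    """

    chrom: str
    start: int
    end: int
    n_discordant_pairs: int
    evidence: str
    dropout: tuple[int, int] | None = None
    refined: bool = False
    n_junction_reads: int = 0
    microhomology: int | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


def fit_insert_model(
    pairs: pd.DataFrame,
    trim_quantile: float = 0.05,
    k: float = 4.0,
) -> InsertModel:
    """Robust insert-size model from mapped distances of (mostly) concordant pairs.

    Mean and sd are computed on the central quantiles [trim, 1-trim], which
    discards a small admixture of deletion-spanning pairs. The discordance
    threshold is mean + k*sd (k = 4 by default), floored one bp above the
    mean so that the threshold strictly exceeds it even for degenerate
    zero-variance libraries.
    """
    d = np.asarray(pairs["mapped_distance"], dtype=float)
    if d.size < 100:
        raise DataError(f"need >= 100 pairs to fit an insert model, got {d.size}")
    lo, hi = np.quantile(d, [trim_quantile, 1.0 - trim_quantile])
    trimmed = d[(d >= lo) & (d <= hi)]
    mean = float(trimmed.mean())
    sd = float(trimmed.std(ddof=1))
    return InsertModel(mean=mean, sd=sd, threshold=mean + max(k * sd, 1.0), n_pairs=d.size)


def cluster_discordant(
    pairs: pd.DataFrame,
    model: InsertModel,
    max_gap: int = 1000,
) -> list[DeletionCandidate]:
    """Group discordant pairs into candidate deletions.

    Only pairs in the expected relative orientation enter clustering. The
    breakpoint-compatible interval of a pair is (end of read 1, start of
    read 2): the deletion must lie strictly between the two reads. Pairs are
    chained into one cluster while their intervals overlap within max_gap;
    the candidate interval is the intersection of the member intervals
    (which contains the deletion and tightens as support grows) and the size
    estimate is mean(cluster distance) - model mean.
    """
    disc = pairs[
        (pairs["mapped_distance"] > model.threshold) & (pairs["orientation"] == "FR")
    ]
    out: list[DeletionCandidate] = []
    for chrom, grp in disc.groupby("chrom", sort=True):
        grp = grp.sort_values(["end1", "pos2"], kind="mergesort")
        inner_l = grp["end1"].to_numpy()
        inner_r = grp["pos2"].to_numpy()
        dist = grp["mapped_distance"].to_numpy(dtype=float)
        members: list[int] = []
        reach = None
        for i in range(len(grp)):
            if members and inner_l[i] > reach + max_gap:
                out.append(_make_candidate(chrom, inner_l, inner_r, dist, members, model))
                members = []
                reach = None
            members.append(i)
            reach = inner_r[i] if reach is None else max(reach, inner_r[i])
        if members:
            out.append(_make_candidate(chrom, inner_l, inner_r, dist, members, model))
    return out


def _make_candidate(chrom, inner_l, inner_r, dist, members, model) -> DeletionCandidate:
    sel = np.array(members)
    lo = int(inner_l[sel].max())
    hi = int(inner_r[sel].min())
    if hi <= lo:  # inconsistent cluster: fall back to the union bounds
        lo = int(inner_l[sel].min())
        hi = int(inner_r[sel].max())
    return DeletionCandidate(
        chrom=str(chrom),
        start=lo,
        end=hi,
        size_estimate=float(dist[sel].mean() - model.mean),
        n_pairs=len(members),
    )


def detect_dropout(
    depth: np.ndarray,
    window: int = 500,
    min_flank_depth: float = 0.5,
    mode: str = "hom",
) -> list[tuple[int, int]]:
    """Maximal depth-dropout intervals flanked by covered sequence.

    In "hom" mode, a dropout is a maximal run of zero depth at least
    ``window`` bp long; in "het" mode, a maximal run of ``window``-bp bins
    whose mean depth sits in a 0.5x +/- 0.2x band of the track median. Both
    require the flanking ``window`` bp on each side to average at least
    ``min_flank_depth`` (so intervals at the track edges are not called).
    """
    d = np.asarray(depth, dtype=float)
    if d.size == 0 or not np.any(d > 0):
        raise DataError("no flanking coverage: depth track is empty or all zero")
    if mode == "hom":
        runs = _zero_runs(d, window)
    elif mode == "het":
        runs = _half_runs(d, window)
    else:
        raise DataError(f"unknown dropout mode {mode!r}")
    out = []
    for s, e in runs:
        if s < window or e > d.size - window:
            continue
        if d[s - window : s].mean() >= min_flank_depth and d[e : e + window].mean() >= min_flank_depth:
            out.append((int(s), int(e)))
    return out


def _zero_runs(d: np.ndarray, window: int) -> list[tuple[int, int]]:
    zero = d == 0
    dz = np.diff(zero.astype(np.int8))
    starts = (np.flatnonzero(dz == 1) + 1).tolist()
    ends = (np.flatnonzero(dz == -1) + 1).tolist()
    if zero[0]:
        starts = [0] + starts
    if zero[-1]:
        ends = ends + [d.size]
    return [(s, e) for s, e in zip(starts, ends) if e - s >= window]


def _half_runs(d: np.ndarray, window: int) -> list[tuple[int, int]]:
    n_bins = d.size // window
    if n_bins == 0:
        return []
    binned = d[: n_bins * window].reshape(n_bins, window).mean(axis=1)
    med = np.median(d[d >= 0])
    in_band = (binned >= 0.3 * med) & (binned <= 0.7 * med)
    runs = []
    s = None
    for i, flag in enumerate(in_band):
        if flag and s is None:
            s = i
        elif not flag and s is not None:
            runs.append((s * window, i * window))
            s = None
    if s is not None:
        runs.append((s * window, n_bins * window))
    return runs


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def merge_evidence(
    clusters: list[DeletionCandidate],
    dropouts: list[tuple[int, int]],
    chrom: str = "ref",
    min_reciprocal_overlap: float = 0.5,
) -> list[DeletionCall]:
    """Combine discordant-pair and dropout evidence into ranked calls.

    A cluster and a dropout interval merge when they reciprocally overlap by
    at least ``min_reciprocal_overlap``; merged calls take the dropout's
    base-resolution coordinates and rank first. Unmerged evidence is kept as
    lower-tier single-evidence calls.
    """
    used = set()
    calls: list[DeletionCall] = []
    for cl in clusters:
        best_j, best_ov = None, 0.0
        for j, dv in enumerate(dropouts):
            if j in used:
                continue
            ov = _reciprocal_overlap((cl.start, cl.end), dv)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j is not None and best_ov >= min_reciprocal_overlap:
            dv = dropouts[best_j]
            used.add(best_j)
            calls.append(
                DeletionCall(
                    chrom=cl.chrom,
                    start=dv[0],
                    end=dv[1],
                    n_discordant_pairs=cl.n_pairs,
                    evidence="pair+dropout",
                    dropout=dv,
                )
            )
        else:
            calls.append(
                DeletionCall(
                    chrom=cl.chrom,
                    start=cl.start,
                    end=cl.end,
                    n_discordant_pairs=cl.n_pairs,
                    evidence="pair-only",
                )
            )
    for j, dv in enumerate(dropouts):
        if j not in used:
            calls.append(
                DeletionCall(
                    chrom=chrom,
                    start=dv[0],
                    end=dv[1],
                    n_discordant_pairs=0,
                    evidence="dropout-only",
                    dropout=dv,
                )
            )
    tier = {"pair+dropout": 0, "pair-only": 1, "dropout-only": 1}
    calls.sort(key=lambda c: (tier[c.evidence], -c.n_discordant_pairs))
    return calls


def refine_breakpoints(
    call: DeletionCall,
    junction_reads,
    reference: str,
    seed_len: int = 20,
    search_slack: int = 2000,
) -> DeletionCall:
    """Fix exact breakpoints by split-aligning junction reads.

    Each junction read is anchored by an exact ``seed_len``-mer near the
    call's left breakpoint, its prefix is extended base by base as far as it
    matches the reference, and the remaining suffix is anchored near the
    right breakpoint. The greedy prefix extension right-aligns the junction
    through any microhomology; the final call is left-aligned and the total
    microhomology (identical sequence immediately left of both breakpoints
    plus immediately right of both) is reported. If no read aligns on both
    sides, the call is returned unrefined.
    """
    seqs = (
        list(junction_reads["sequence"])
        if isinstance(junction_reads, pd.DataFrame)
        else list(junction_reads)
    )
    votes: dict[tuple[int, int], int] = {}
    for seq in seqs:
        bp = _split_align(seq, reference, call, seed_len, search_slack)
        if bp is not None:
            votes[bp] = votes.get(bp, 0) + 1
    if not votes:
        return call
    (start, end), support = max(votes.items(), key=lambda kv: kv[1])
    # left-align through microhomology
    while start > 0 and reference[start - 1] == reference[end - 1]:
        start -= 1
        end -= 1
    mh_left = 0
    while start - 1 - mh_left >= 0 and reference[start - 1 - mh_left] == reference[end - 1 - mh_left]:
        mh_left += 1
    mh_right = 0
    while end + mh_right < len(reference) and reference[start + mh_right] == reference[end + mh_right]:
        mh_right += 1
    return replace(
        call,
        start=start,
        end=end,
        refined=True,
        n_junction_reads=support,
        microhomology=mh_left + mh_right,
    )


def _split_align(seq: str, ref: str, call: DeletionCall, seed_len: int, slack: int):
    if len(seq) < 2 * seed_len:
        return None
    left_win_start = max(0, call.start - slack)
    left_win = ref[left_win_start : call.start + slack]
    a = left_win.find(seq[:seed_len])
    if a < 0 or left_win.find(seq[:seed_len], a + 1) >= 0:
        return None
    a += left_win_start
    n = len(seq)
    ext = seed_len
    while ext < n and a + ext < len(ref) and ref[a + ext] == seq[ext]:
        ext += 1
    if ext == n:  # read fully matches the reference: not a junction read
        return None
    left_bp = a + ext
    rest = seq[ext:]
    if len(rest) < seed_len:
        return None
    right_win_start = max(left_bp + 1, call.end - slack)
    right_win = ref[right_win_start : call.end + slack + len(rest)]
    b = right_win.find(rest[:seed_len])
    if b < 0 or right_win.find(rest[:seed_len], b + 1) >= 0:
        return None
    b += right_win_start
    if ref[b : b + len(rest)] != rest:
        return None
    if b <= left_bp:
        return None
    return (left_bp, b)
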