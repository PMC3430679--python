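"""Synthetic inputs for every stage of the recessive-lethal mapping pipeline.

The real study data (50K SNP genotypes of affected calves, mate-pair
sequencing reads, and AI insemination records) are not publicly deposited, so
every downstream module is exercised on simulated data that reproduces the
statistical structure the analysis relies on:

* diploid SNP genotypes in which all cases are homozygous for one planted
  identical-by-descent haplotype across a contiguous interval, against
  phased unrelated controls carrying that haplotype at a configurable
  population frequency;
* mate-pair alignment records (4-4.5 kb inserts, 2x76 bp reads) over a
  reference window in which one haplotype carries a multi-kb deletion, plus
  the per-base depth track — pairs whose fragment spans the deletion map
  "too far apart" by exactly the deletion length, and no read maps inside a
  homozygously deleted segment;
* artificial-insemination mating records for the four sire-class x
  dam's-sire-class combinations with return-to-oestrus outcomes at 56, 90
  and 270 days, under a baseline failure level plus stage-specific mortality
  of homozygous-mutant conceptuses.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import popgen
from .errors import ConfigurationError
from ._seeds import child_seed

__all__ = [
    "MarkerMap",
    "PopulationConfig",
    "ReadSimConfig",
    "MatingSimConfig",
    "GenotypeMatrix",
    "SimulatedReadSet",
    "MATING_CLASSES",
    "random_marker_map",
    "simulate_genotypes",
    "simulate_matepairs",
    "simulate_matings",
    "simulate_deletion_sample",
    "random_dna",
]

_BASES = np.array(list("ACGT"))

#: Mating classes as (dam's-sire class, sire class); sire genotype is known
#: with certainty (AI bulls are genotyped), the dam is only known through
#: her sire.
MATING_CLASSES = ("NCxNC", "CxNC", "NCxC", "CxC")


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random nucleotide string (no repeat structure is simulated)."""
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# marker maps and genotypes
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class MarkerMap:
    """Ordered SNP map: chromosome, physical position (bp, 1-based), id, alleles."""

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ids) == len(self.ref) == len(self.alt) == n):
            raise ConfigurationError("marker map columns have unequal lengths")
        for c in self.chromosomes:
            sel = self.chrom == c
            if sel.sum() < 2:
                raise ConfigurationError(f"chromosome {c} has fewer than 2 markers")
            p = self.pos[sel]
            if not np.all(np.diff(p) > 0):
                raise ConfigurationError(f"positions not strictly increasing on {c}")

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_block(self, chrom: str) -> tuple[int, int]:
        """Half-open marker-index range of one chromosome (markers are grouped)."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            raise ConfigurationError(f"no markers on chromosome {chrom}")
        return int(idx[0]), int(idx[-1]) + 1

    def interval_markers(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Marker indices whose 0-based position falls in [start, end)."""
        zero_based = self.pos - 1
        return np.flatnonzero((self.chrom == chrom) & (zero_based >= start) & (zero_based < end))


def random_marker_map(
    n_chrom: int = 5,
    markers_per_chrom: int = 300,
    chrom_length: int = 60_000_000,
    seed: int = 0,
) -> MarkerMap:
    """Evenly spaced-ish SNP map with random A/B-style alleles."""
    rng = np.random.default_rng(seed)
    chroms, pos, ids = [], [], []
    spacing = chrom_length // (markers_per_chrom + 1)
    for c in range(1, n_chrom + 1):
        base = np.arange(1, markers_per_chrom + 1) * spacing
        jitter = rng.integers(-spacing // 4, spacing // 4 + 1, size=markers_per_chrom)
        p = np.sort(base + jitter)
        # enforce strict increase after jitter
        p = np.maximum.accumulate(p + np.arange(markers_per_chrom))
        chroms.extend([str(c)] * markers_per_chrom)
        pos.extend(p.tolist())
        ids.extend(f"snp{c}_{i}" for i in range(markers_per_chrom))
    n = len(pos)
    ref = _BASES[rng.integers(0, 4, size=n)].astype(object)
    alt = np.array([_BASES[(list(_BASES).index(r) + 1) % 4] for r in ref], dtype=object)
    return MarkerMap(np.array(chroms, dtype=object), np.array(pos), np.array(ids, dtype=object), ref, alt)


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the case/control genotype simulation.

    ``carrier_freq`` is the population frequency of carrier *animals* (the
    quantity the study reports, 7.4% in Holstein); internally control
    haplotypes carry the planted haplotype at the HWE allele frequency q
    solving 2q(1-q) = c. The planted interval is 0-based half-open in bp.
    """

    n_cases: int = 6
    n_controls: int = 100
    carrier_freq: float = 0.074
    planted_chrom: str = "3"
    planted_start: int = 20_000_000
    planted_end: int = 22_460_000
    allele_freqs: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ConfigurationError("carrier_freq outside [0, 1]")
        if self.n_cases < 1 or self.n_controls < 0:
            raise ConfigurationError("need >=1 case and >=0 controls")
        if self.planted_end <= self.planted_start:
            raise ConfigurationError("planted interval is empty")


@dataclass(eq=False)
class GenotypeMatrix:
    """Biallelic genotypes (alt-allele dosage 0/1/2, -1 missing) over a map.

    Control phase is retained (``control_haplotypes`` has two rows per
    control, alleles 0/1); case genotypes are unphased. ``truth_interval`` is
    the planted IBD interval as (chrom, start, end), 0-based half-open.
    """

    markers: MarkerMap
    sample_ids: list[str]
    case_ids: list[str]
    genotypes: np.ndarray  # (n_samples, n_markers) int8
    control_haplotypes: np.ndarray | None = None  # (2*n_controls, n_markers) int8
    truth_interval: tuple[str, int, int] | None = None
    planted_haplotype: np.ndarray | None = None  # alleles over planted-interval markers

    @property
    def control_ids(self) -> list[str]:
        case = set(self.case_ids)
        return [s for s in self.sample_ids if s not in case]

    def genotypes_of(self, sample_id: str) -> np.ndarray:
        try:
            row = self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise ConfigurationError(f"sample {sample_id!r} not present") from exc
        return self.genotypes[row]

    def case_genotypes(self) -> np.ndarray:
        return np.vstack([self.genotypes_of(s) for s in self.case_ids])


def simulate_genotypes(config: PopulationConfig, markers: MarkerMap) -> GenotypeMatrix:
    """Plant one IBD haplotype homozygous in all cases; draw phased controls.

    Cases are homozygous for a single shared haplotype across every marker of
    the planted interval and random elsewhere. Each control haplotype is the
    planted haplotype (over the interval markers) with probability q solving
    2q(1-q) = carrier_freq, and random otherwise; controls homozygous for the
    planted haplotype may arise naturally, as the homozygote-deficit test
    requires the unconstrained model.
    """
    interval_idx = markers.interval_markers(
        config.planted_chrom, config.planted_start, config.planted_end
    )
    if interval_idx.size < 10:
        raise ConfigurationError(
            f"planted interval covered by {interval_idx.size} markers; >=10 required"
        )
    rng = np.random.default_rng(config.seed)
    m = markers.n_markers
    if config.allele_freqs is not None:
        p = np.asarray(config.allele_freqs, dtype=float)
        if p.shape != (m,):
            raise ConfigurationError("allele_freqs length does not match marker map")
    else:
        p = rng.uniform(0.1, 0.9, size=m)

    planted_hap = (rng.random(interval_idx.size) < p[interval_idx]).astype(np.int8)
    q = popgen.allele_freq_from_carrier(min(config.carrier_freq, 0.5))

    def _random_haps(k: int) -> np.ndarray:
        return (rng.random((k, m)) < p).astype(np.int8)

    # cases: both haplotypes carry the planted segment
    case_haps = _random_haps(2 * config.n_cases)
    case_haps[:, interval_idx] = planted_hap
    case_geno = case_haps[0::2] + case_haps[1::2]

    ctrl_haps = _random_haps(2 * config.n_controls)
    if config.n_controls:
        is_carrier = rng.random(2 * config.n_controls) < q
        ctrl_haps[np.ix_(is_carrier, interval_idx)] = planted_hap
    ctrl_geno = ctrl_haps[0::2] + ctrl_haps[1::2]

    case_ids = [f"case_{i}" for i in range(config.n_cases)]
    ctrl_ids = [f"control_{i}" for i in range(config.n_controls)]
    return GenotypeMatrix(
        markers=markers,
        sample_ids=case_ids + ctrl_ids,
        case_ids=case_ids,
        genotypes=np.vstack([case_geno, ctrl_geno]).astype(np.int8),
        control_haplotypes=ctrl_haps,
        truth_interval=(config.planted_chrom, config.planted_start, config.planted_end),
        planted_haplotype=planted_hap,
    )


def simulate_deletion_sample(n: int, carrier_freq: float, seed: int) -> popgen.GenotypeCounts:
    """Genotype a simulated random sample of n animals at the deletion locus.

    Each animal draws two deletion alleles at the HWE frequency q solving
    2q(1-q) = carrier_freq; emulates the diagnostic-assay screen of a random
    population sample.
    """
    if n < 1:
        raise ConfigurationError("sample size must be >= 1")
    q = popgen.allele_freq_from_carrier(carrier_freq)
    rng = np.random.default_rng(seed)
    dosage = (rng.random((n, 2)) < q).sum(axis=1)
    return popgen.GenotypeCounts(
        n_wildtype=int((dosage == 0).sum()),
        n_carrier=int((dosage == 1).sum()),
        n_homozygous=int((dosage == 2).sum()),
    )


# ---------------------------------------------------------------------------
# mate pairs and depth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadSimConfig:
    """Mate-pair simulation over one reference window.

    Inserts (fragment outer length) default to uniform 4,000-4,500 bp, the
    library's fragment size; ``insert_dist`` may be ``("uniform", low, high)``
    or ``("normal", mean, sd)``. Coverage is sequence coverage in x of the
    reference window. The deletion interval is 0-based half-open.
    """

    reference_length: int = 60_000
    deletion_start: int = 30_000
    deletion_end: int = 33_329
    insert_dist: tuple = ("uniform", 4000, 4500)
    read_length: int = 76
    coverage: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ConfigurationError("coverage must be > 0")
        if not 0 <= self.deletion_start < self.deletion_end <= self.reference_length:
            raise ConfigurationError("deletion interval not inside reference")
        kind = self.insert_dist[0]
        if kind not in ("uniform", "normal"):
            raise ConfigurationError(f"unknown insert distribution {kind!r}")
        low = self.insert_dist[1] if kind == "uniform" else self.insert_dist[1] - 4 * self.insert_dist[2]
        if low <= 2 * self.read_length:
            raise ConfigurationError("insert must exceed twice the read length")

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start


@dataclass(eq=False)
class SimulatedReadSet:
    """Mapped mate pairs, junction reads, per-base depth and the reference."""

    pairs: pd.DataFrame  # pair_id, chrom, pos1, end1, pos2, end2, orientation, mapped_distance
    depth: np.ndarray  # per-base depth over the reference window
    junction_reads: pd.DataFrame  # read_id, sequence, left_ref_start
    reference: str
    genotype: str
    truth_interval: tuple[int, int]
    config: ReadSimConfig


def _sample_inserts(config: ReadSimConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    kind = config.insert_dist[0]
    if kind == "uniform":
        low, high = config.insert_dist[1], config.insert_dist[2]
        ins = rng.integers(int(low), int(high) + 1, size=k)
    else:
        mean, sd = config.insert_dist[1], config.insert_dist[2]
        ins = np.rint(rng.normal(mean, sd, size=k)).astype(np.int64)
    return np.maximum(ins, 2 * config.read_length + 1)


def simulate_matepairs(config: ReadSimConfig, genotype: str = "D/D") -> SimulatedReadSet:
    """Simulate mapped mate pairs for one individual of a deletion genotype.

    Fragments are drawn uniformly from the sample genome of the chosen
    haplotype (the deleted haplotype is the reference with the deletion
    excised), and their reads are mapped back to reference coordinates.
    Consequences of the construction:

    * no read of a deleted haplotype overlaps the deleted reference interval;
    * a pair whose fragment spans the junction maps at distance
      insert + deletion length (the discordant-cluster signal);
    * a read crossing the junction carries the concatenated breakpoint
      sequence and is emitted separately as a junction read.

    Genotypes: ``"+/+"`` both haplotypes intact, ``"D/D"`` both deleted,
    ``"D/+"`` a 1:1 mix per fragment. The number of pairs is exactly
    round(coverage * reference_length / (2 * read_length)).
    """
    if genotype not in ("+/+", "D/+", "D/D"):
        raise ConfigurationError(f"unknown deletion genotype {genotype!r}")
    rng = np.random.default_rng(config.seed)
    ref = random_dna(config.reference_length, rng)
    rl = config.read_length
    ds, de = config.deletion_start, config.deletion_end
    dlen = config.deletion_length
    n_pairs = int(round(config.coverage * config.reference_length / (2 * rl)))

    if genotype == "+/+":
        deleted = np.zeros(n_pairs, dtype=bool)
    elif genotype == "D/D":
        deleted = np.ones(n_pairs, dtype=bool)
    else:
        deleted = rng.random(n_pairs) < 0.5

    inserts = _sample_inserts(config, rng, n_pairs)
    glen = np.where(deleted, config.reference_length - dlen, config.reference_length)
    inserts = np.minimum(inserts, glen - 1)
    starts = (rng.random(n_pairs) * (glen - inserts)).astype(np.int64)

    rows = []
    junction_rows = []
    depth_diff = np.zeros(config.reference_length + 1, dtype=np.int64)

    def _map(p: np.ndarray | int, is_del: bool):
        return p + dlen if is_del and p >= ds else p

    for i in range(n_pairs):
        s = int(starts[i])
        ins = int(inserts[i])
        is_del = bool(deleted[i])
        r1 = (s, s + rl)  # sample coordinates, forward read
        r2 = (s + ins - rl, s + ins)  # reverse read
        segments = []
        bridge = False
        for rs, re_ in (r1, r2):
            if is_del and rs < ds < re_:
                # junction read: concatenated breakpoint sequence
                left_len = ds - rs
                seq = ref[rs:ds] + ref[de : de + (rl - left_len)]
                junction_rows.append((f"jr_{i}", seq, rs))
                segments.append((rs, ds))
                segments.append((de, de + (rl - left_len)))
                bridge = True
            else:
                a = _map(rs, is_del)
                b = _map(re_ - 1, is_del) + 1
                segments.append((a, b))
        for a, b in segments:
            depth_diff[a] += 1
            depth_diff[min(b, config.reference_length)] -= 1
        if bridge:
            continue  # a junction read does not map contiguously; pair omitted from table
        p1 = _map(r1[0], is_del)
        p2 = _map(r2[0], is_del)
        e1, e2 = p1 + rl, p2 + rl
        rows.append((f"mp_{i}", "ref", p1, e1, p2, e2, "FR", e2 - p1))

    pairs = pd.DataFrame(
        rows,
        columns=["pair_id", "chrom", "pos1", "end1", "pos2", "end2", "orientation", "mapped_distance"],
    )
    junction = pd.DataFrame(junction_rows, columns=["read_id", "sequence", "left_ref_start"])
    depth = np.cumsum(depth_diff[:-1])
    return SimulatedReadSet(
        pairs=pairs,
        depth=depth,
        junction_reads=junction,
        reference=ref,
        genotype=genotype,
        truth_interval=(ds, de),
        config=config,
    )


# ---------------------------------------------------------------------------
# matings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MatingSimConfig:
    """AI mating simulation across the four sire x dam's-sire classes.

    ``baseline`` are the cumulative pregnancy-failure probabilities at 56, 90
    and 270 days for a viable conceptus (the published per-class tables are
    supplementary-only; these stand-in defaults are configurable and cancel
    in the class contrasts). ``mortality`` is the cumulative probability
    m(t) that a homozygous-mutant conceptus has died by day t; the default
    reaches 0.52 by day 270 with more than half of the loss before day 56.
    """

    n_per_class: int = 100_000
    baseline: tuple[float, float, float] = (0.35, 0.40, 0.45)
    mortality: tuple[float, float, float] = (0.30, 0.40, 0.52)
    carrier_freq: float = 0.074
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ConfigurationError("n_per_class must be >= 1")
        for name, vec in (("baseline", self.baseline), ("mortality", self.mortality)):
            if len(vec) != 3:
                raise ConfigurationError(f"{name} must have one value per stage (56/90/270 d)")
            if any(not 0.0 <= v <= 1.0 for v in vec):
                raise ConfigurationError(f"{name} probabilities outside [0, 1]")
            if not (vec[0] <= vec[1] <= vec[2]):
                raise ConfigurationError(f"{name} must be non-decreasing over stages")
        if not 0.0 <= self.carrier_freq <= 1.0:
            raise ConfigurationError("carrier_freq outside [0, 1]")


def simulate_matings(config: MatingSimConfig) -> pd.DataFrame:
    """Simulate insemination outcomes for the four mating classes.

    The dam's carrier status is Bernoulli(0.5 + c/2) when her sire is a
    genotyped carrier and Bernoulli(c/2) otherwise (the ungenotyped granddam
    contributes c/2 either way). The conceptus is D/D when both parents are
    carriers and both transmit (probability 1/4 given two carriers).

    Failure by day t is coupled additively: with a single uniform u per
    mating, failure(t) = u < baseline(t) + 1{D/D} * m(t) (capped at 1). A
    dead conceptus therefore always produces a return to oestrus, and the
    expected class contrast equals P_hom * m(t) exactly — the additive
    arithmetic the mortality estimator inverts. Failure indicators are
    monotone across stages within a record by construction.
    """
    rng = np.random.default_rng(config.seed)
    c = config.carrier_freq
    b = np.array(config.baseline)
    m = np.array(config.mortality)
    frames = []
    for label in MATING_CLASSES:
        dam_sire_class, sire_class = label.split("x")
        n = config.n_per_class
        p_dam = 0.5 + c / 2.0 if dam_sire_class == "C" else c / 2.0
        dam_carrier = rng.random(n) < p_dam
        sire_transmits = (rng.random(n) < 0.5) & (sire_class == "C")
        dam_transmits = (rng.random(n) < 0.5) & dam_carrier
        dosage = sire_transmits.astype(int) + dam_transmits.astype(int)
        dd = dosage == 2
        u = rng.random(n)
        fails = {}
        for stage, bt, mt in zip((56, 90, 270), b, m):
            thr = np.minimum(bt + np.where(dd, mt, 0.0), 1.0)
            fails[f"fail{stage}"] = (u < thr).astype(np.int8)
        conceptus = pd.Categorical.from_codes(dosage, categories=["+/+", "D/+", "D/D"])
        offset = MATING_CLASSES.index(label) * n
        mating_id = np.arange(offset, offset + n, dtype=np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "mating_id": mating_id,
                    "sire_class": pd.Categorical([sire_class]).repeat(n),
                    "dam_sire_class": pd.Categorical([dam_sire_class]).repeat(n),
                    "mating_class": pd.Categorical([label]).repeat(n),
                    **fails,
                    "truth_dam_carrier": dam_carrier.astype(np.int8),
                    "truth_conceptus": conceptus,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def spawn(config, stage: str):
    """Copy a config with its seed replaced by a named child seed."""
    return replace(config, seed=child_seed(config.seed, stage))


# ---------------------------------------------------------------------------
# synthetic FANCI-like gene case
# ---------------------------------------------------------------------------


@dataclass(eq=False)
class GeneCase:
    """A synthetic gene, genome and deletion mirroring the study's geometry.

    The real bovine FANCI exon coordinates and primer sequences are not
    printed in the study text, so this is a synthetic stand-in built to
    satisfy the published identities: a 37-exon gene whose coding sequence
    encodes a 1,328-residue protein; a 3,329 bp genomic deletion removing
    exons 25-27 (361 coding bp, not a multiple of 3); residues 1-877 intact
    in the mutant, a 26-residue novel peptide, and a premature stop in exon
    28; cDNA primers in exons 24/28 giving 457 bp (wild-type) and 96 bp
    (mutant) products; and a junction-spanning genomic pair giving a 409 bp
    deletion-specific product.
    """

    genome: str
    gene: "object"  # consequence.GeneModel
    deletion: tuple[int, int]
    primers: dict  # name -> (fwd, rev)


def fanci_like_case(seed: int = 0, novel_peptide: int = 26) -> GeneCase:
    """Deterministically construct the FANCI-like synthetic gene case.

    Exon transcript lengths are fixed (23x110 + 101 | 120,121,120 | 9x100 +
    95 = 3,987 nt = 1,329 codons including the stop); the coding sequence is
    drawn codon-wise without internal stops, and the post-junction region is
    redrawn (seeded rejection search) until the frame-shifted mutant reading
    yields exactly ``novel_peptide`` novel residues before its stop.
    """
    from .consequence import GeneModel, delete_interval, _translate_to_stop

    rng = np.random.default_rng(seed)
    exon_lens = [110] * 23 + [101] + [120, 121, 120] + [100] * 9 + [95]
    assert sum(exon_lens) == 3987 and len(exon_lens) == 37
    junction_nt = sum(exon_lens[:24])  # 2631 = 877 codons
    deleted_nt = sum(exon_lens[24:27])  # 361

    codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    non_stop = np.array([c for c in codons if c not in ("TAA", "TAG", "TGA")])

    head = "ATG" + "".join(rng.choice(non_stop, size=876))  # codons 1..877
    block25_27 = "".join(rng.choice(non_stop, size=(junction_nt + deleted_nt) // 3 - 877))
    # one codon straddles the exon27/28 boundary offset; keep codon-aligned
    # drawing and redraw the tail until the shifted frame behaves
    n_tail_codons = (3987 - len(head) - len(block25_27) - 3) // 3
    for _ in range(50_000):
        tail = "".join(rng.choice(non_stop, size=n_tail_codons))
        cds = head + block25_27 + tail + "TAA"
        assert len(cds) == 3987
        mut_cds = cds[:junction_nt] + cds[junction_nt + deleted_nt :]
        mut_body, has_stop = _translate_to_stop(mut_cds)
        if not has_stop or len(mut_body) != 877 + novel_peptide:
            continue
        wt_body, wt_stop = _translate_to_stop(cds)
        if wt_stop and len(wt_body) == 1328 and mut_body[877 - 1] == wt_body[877 - 1] and (
            len(mut_body) == 877 or mut_body[877] != wt_body[877]
        ):
            break
    else:  # pragma: no cover - the search space is ample
        raise ConfigurationError("could not engineer the mutant reading frame")

    intron = 1000
    flank = 1500
    exons = []
    pos = flank
    tx_off = 0
    for L in exon_lens:
        exons.append((pos, pos + L))
        pos += L + intron
        tx_off += L
    genome_len = pos - intron + flank
    genome_arr = list(random_dna(genome_len, rng))
    tx_off = 0
    for (s, e), L in zip(exons, exon_lens):
        genome_arr[s:e] = cds[tx_off : tx_off + L]
        tx_off += L
    genome = "".join(genome_arr)

    gene = GeneModel(
        chrom="geneA",
        strand="+",
        exons=tuple(exons),
        cds_start=0,
        cds_end=3987,
        name="fanci_like",
    )

    # deletion removing exons 25-27 only, total genomic span 3,329 bp
    e25s = exons[24][0]
    e27e = exons[26][1]
    span_core = e27e - e25s  # 120+1000+121+1000+120 = 2361
    left_pad = 500
    right_pad = 3329 - span_core - left_pad  # 468
    deletion = (e25s - left_pad, e27e + right_pad)
    assert deletion[1] - deletion[0] == 3329

    tx = gene.transcript_sequence(genome)

    def rc(s: str) -> str:
        comp = str.maketrans("ACGT", "TGCA")
        return s.translate(comp)[::-1]

    # cDNA primers: forward ends 30 nt before the exon24/25 junction (5' end
    # 50 nt before it), reverse 5' end 46 nt into exon 28 -> 457 / 96 bp
    cdna_fwd = tx[junction_nt - 50 : junction_nt - 30]
    cdna_rev = rc(tx[junction_nt + deleted_nt + 26 : junction_nt + deleted_nt + 46])
    # genomic junction-spanning pair: 409 bp product on the deleted allele
    ds, de = deletion
    gdna_fwd = genome[ds - 200 : ds - 180]
    gdna_rev = rc(genome[de + 189 : de + 209])
    # pair internal to the deletion: product on + allele only
    int_fwd = genome[ds + 600 : ds + 620]
    int_rev = rc(genome[ds + 800 : ds + 820])

    return GeneCase(
        genome=genome,
        gene=gene,
        deletion=deletion,
        primers={
            "cdna_ex24_ex28": (cdna_fwd, cdna_rev),
            "junction_spanning": (gdna_fwd, gdna_rev),
            "internal": (int_fwd, int_rev),
        },
    )
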