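"""Transcript and protein consequences of a genomic deletion on a gene model.

Given a gene model and a deletion that removes whole exons, this module
predicts the mutant transcript (juxtaposition of the flanking exons), the
protein-level effect (frameshift position, novel C-terminal peptide,
truncated residues), whether the resulting premature termination codon (PTC)
triggers nonsense-mediated decay (the 50-nt rule: a PTC at least 50 nt
upstream of the final exon-exon junction), and the behaviour of validation
amplicons (deletion-spanning, deletion-internal, and cDNA primer pairs).
A generic variant-triage filter removes known polymorphisms and non-coding
variants from a candidate list.

Only deletions removing complete exons are supported; a deletion splitting
an exon raises. Strand is handled by projecting into transcript coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import Seq

from .errors import AmbiguousPrimerError, ModelError, UnsupportedDeletionError

__all__ = [
    "GeneModel",
    "TranscriptEffect",
    "AmpliconResult",
    "apply_deletion",
    "delete_interval",
    "protein_effect",
    "predict_nmd",
    "predict_amplicons",
    "filter_candidate_variants",
]


@dataclass(frozen=True)
class GeneModel:
    """A transcript model: ordered exons on a genome plus CDS bounds.

    ``exons`` are 0-based half-open genomic intervals sorted in ascending
    genomic order; for strand "-" the transcript reads them in reverse with
    reverse-complemented sequence. ``cds_start``/``cds_end`` are 0-based
    half-open *transcript* coordinates.
    """

    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    name: str = "gene"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        prev = None
        for s, e in self.exons:
            if e <= s:
                raise ModelError(f"empty exon ({s}, {e})")
            if prev is not None and s < prev:
                raise ModelError("exons overlap or are unsorted")
            prev = e
        if not 0 <= self.cds_start < self.cds_end <= self.transcript_length:
            raise ModelError("CDS not within transcript")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> list[int]:
        lens = [e - s for s, e in self.exons]
        return lens[::-1] if self.strand == "-" else lens

    @property
    def transcript_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate_cds(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ModelError("CDS length not divisible by 3")

    def transcript_sequence(self, genome: str) -> str:
        parts = [genome[s:e] for s, e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq

    def cds_sequence(self, genome: str) -> str:
        return self.transcript_sequence(genome)[self.cds_start : self.cds_end]

    def exon_transcript_spans(self) -> list[tuple[int, int]]:
        """Transcript-coordinate span of each exon, in transcript order."""
        spans = []
        off = 0
        for length in self.exon_lengths:
            spans.append((off, off + length))
            off += length
        return spans

    def last_junction_pos(self) -> int | None:
        """Transcript coordinate of the final exon-exon junction (None if single-exon)."""
        if self.n_exons < 2:
            return None
        return self.transcript_length - self.exon_lengths[-1]

    def cds_genomic_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals covered by the CDS (plus-strand coordinates)."""
        out = []
        spans = self.exon_transcript_spans()
        exons_tx_order = self.exons[::-1] if self.strand == "-" else self.exons
        for (ts, te), (gs, ge) in zip(spans, exons_tx_order):
            lo = max(ts, self.cds_start)
            hi = min(te, self.cds_end)
            if lo >= hi:
                continue
            if self.strand == "+":
                out.append((gs + (lo - ts), gs + (hi - ts)))
            else:
                out.append((ge - (hi - ts), ge - (lo - ts)))
        return out


@dataclass(frozen=True)
class TranscriptEffect:
    """Protein-level consequence of an exon-deleting genomic deletion."""

    deleted_exons: tuple[int, ...]  # 0-based indices in transcript order
    deleted_cds_length: int
    frameshift: bool
    divergence_position: int | None  # first divergent residue, 1-based; None if silent
    novel_peptide_length: int
    truncated_residues: int
    wt_protein_length: int
    mutant_protein_length: int
    ptc_transcript_pos: int | None  # 0-based transcript position of the new stop
    ptc_exon_index: int | None  # exon holding the PTC, 0-based wild-type numbering
    nmd_predicted: bool


def delete_interval(seq: str, deletion: tuple[int, int]) -> str:
    """Genome sequence with a 0-based half-open interval excised."""
    s, e = deletion
    return seq[:s] + seq[e:]


def apply_deletion(model: GeneModel, deletion: tuple[int, int]) -> GeneModel:
    """Gene model after a whole-exon deletion, in mutant-genome coordinates.

    Exons entirely inside the deletion are removed; exons downstream shift
    left by the deletion length; remaining exon order is preserved. A
    deletion overlapping but not containing an exon is rejected. The mutant
    CDS keeps its start (the deletion must not remove the CDS start) and is
    left open-ended at the transcript end — the new reading frame decides
    where translation actually stops.
    """
    ds, de = deletion
    if de < ds:
        raise UnsupportedDeletionError("deletion end before start")
    if de == ds:
        return model
    dlen = de - ds
    kept = []
    removed_tx: list[int] = []
    spans = model.exon_transcript_spans()
    exons_tx_order = model.exons[::-1] if model.strand == "-" else model.exons
    for tx_i, (s, e) in enumerate(exons_tx_order):
        if s >= ds and e <= de:
            removed_tx.append(tx_i)
            continue
        if s < de and e > ds:
            raise UnsupportedDeletionError(
                f"deletion ({ds}, {de}) splits exon ({s}, {e}); only whole-exon deletions supported"
            )
        shift = dlen if s >= de else 0
        kept.append((s - shift, e - shift))
    kept.sort()
    removed_cds_upstream = sum(
        max(0, min(spans[i][1], model.cds_start) - spans[i][0]) for i in removed_tx
    )
    if any(spans[i][0] <= model.cds_start < spans[i][1] for i in removed_tx):
        raise UnsupportedDeletionError("deletion removes the CDS start")
    new_tlen = model.transcript_length - sum(spans[i][1] - spans[i][0] for i in removed_tx)
    return GeneModel(
        chrom=model.chrom,
        strand=model.strand,
        exons=tuple(kept),
        cds_start=model.cds_start - removed_cds_upstream,
        cds_end=new_tlen,
        name=model.name,
    )


def _translate_to_stop(cds: str) -> tuple[str, bool]:
    """Translate from the first codon to the first stop; flag whether a stop was found."""
    prot = []
    for i in range(0, len(cds) - 2, 3):
        aa = str(Seq(cds[i : i + 3]).translate())
        if aa == "*":
            return "".join(prot), True
        prot.append(aa)
    return "".join(prot), False


def protein_effect(
    model: GeneModel,
    mutant: GeneModel,
    genome: str,
    deletion: tuple[int, int],
) -> TranscriptEffect:
    """Compare wild-type and mutant translations of a whole-exon deletion.

    The wild-type CDS must start with ATG, contain no internal stop, and end
    with a stop codon. The mutant CDS is translated from the (preserved) ATG
    to its first stop. A frameshift occurs iff the summed deleted coding
    length is not a multiple of 3. The divergence position is the first
    residue at which the two proteins differ; the novel peptide runs from
    there to the mutant stop, and the truncated-residue count is
    wild-type length - (divergence - 1).
    """
    model.validate_cds()
    wt_cds = model.cds_sequence(genome)
    if not wt_cds.startswith("ATG"):
        raise ModelError("wild-type CDS does not start with ATG")
    wt_body, found = _translate_to_stop(wt_cds)
    if not found or 3 * (len(wt_body) + 1) != len(wt_cds):
        raise ModelError("wild-type CDS has an internal stop or lacks a terminal stop")

    mut_genome = delete_interval(genome, deletion)
    mut_tx = mutant.transcript_sequence(mut_genome)
    mut_cds = mut_tx[mutant.cds_start :]
    mut_body, mut_has_stop = _translate_to_stop(mut_cds)

    spans = model.exon_transcript_spans()
    exons_tx = model.exons[::-1] if model.strand == "-" else model.exons
    deleted = tuple(
        i for i, (s, e) in enumerate(exons_tx) if s >= deletion[0] and e <= deletion[1]
    )
    deleted_cds = sum(
        max(0, min(spans[i][1], model.cds_end) - max(spans[i][0], model.cds_start))
        for i in deleted
    )
    frameshift = deleted_cds % 3 != 0

    div = None
    for i in range(min(len(wt_body), len(mut_body))):
        if wt_body[i] != mut_body[i]:
            div = i + 1
            break
    if div is None and len(wt_body) != len(mut_body):
        div = min(len(wt_body), len(mut_body)) + 1

    if div is None:
        novel = 0
        truncated = 0
    elif frameshift:
        novel = max(0, len(mut_body) - (div - 1))
        truncated = len(wt_body) - (div - 1)
    else:
        novel = 0
        truncated = len(wt_body) - (div - 1)

    ptc_pos = mutant.cds_start + 3 * len(mut_body) if mut_has_stop else None
    ptc_exon = None
    if ptc_pos is not None:
        kept_wt_indices = [i for i in range(model.n_exons) if i not in deleted]
        for i, (s, e) in enumerate(mutant.exon_transcript_spans()):
            if s <= ptc_pos < e:
                ptc_exon = kept_wt_indices[i]  # wild-type exon numbering
                break
    nmd = predict_nmd(mutant, ptc_pos) if ptc_pos is not None else False
    return TranscriptEffect(
        deleted_exons=deleted,
        deleted_cds_length=deleted_cds,
        frameshift=frameshift,
        divergence_position=div,
        novel_peptide_length=novel,
        truncated_residues=truncated,
        wt_protein_length=len(wt_body),
        mutant_protein_length=len(mut_body),
        ptc_transcript_pos=ptc_pos,
        ptc_exon_index=ptc_exon,
        nmd_predicted=nmd,
    )


def predict_nmd(mutant: GeneModel, ptc_transcript_pos: int, rule_nt: int = 50) -> bool:
    """50-nt rule: NMD is predicted iff the PTC sits >= rule_nt nucleotides
    upstream of the final exon-exon junction (inclusive at the boundary).
    Single-exon transcripts are never NMD substrates."""
    junction = mutant.last_junction_pos()
    if junction is None:
        return False
    if not 0 <= ptc_transcript_pos < mutant.transcript_length:
        raise ModelError("PTC outside the mutant transcript")
    return junction - ptc_transcript_pos >= rule_nt


@dataclass(frozen=True)
class AmpliconResult:
    """Predicted PCR product size per allele (None = no product)."""

    wt_product: int | None
    mut_product: int | None


def _unique_site(template: str, probe: str, label: str) -> int | None:
    i = template.find(probe)
    if i < 0:
        return None
    if template.find(probe, i + 1) >= 0:
        raise AmbiguousPrimerError(f"{label} primer matches template more than once")
    return i


def predict_amplicons(
    primer_pair: tuple[str, str],
    wt_seq: str,
    mut_seq: str,
    max_amplicon: int = 5000,
) -> AmpliconResult:
    """Predict per-allele product size for one primer pair.

    The forward primer must match the top strand, the reverse primer the
    bottom strand (its reverse complement is searched on the top strand),
    each at most once per allele. Product size is the distance between the
    two primer 5' ends, inclusive; no product is reported when a site is
    missing, the primers do not converge, or the span exceeds
    ``max_amplicon``.
    """
    fwd, rev = primer_pair
    rc = str(Seq(rev).reverse_complement())

    def product(template: str) -> int | None:
        f = _unique_site(template, fwd, "forward")
        r = _unique_site(template, rc, "reverse")
        if f is None or r is None:
            return None
        size = (r + len(rc)) - f
        if size < len(fwd) + len(rev) or size > max_amplicon:
            return None
        return size

    return AmpliconResult(wt_product=product(wt_seq), mut_product=product(mut_seq))


def filter_candidate_variants(
    variants: pd.DataFrame,
    known_variants: set[tuple],
    gene_models: list[GeneModel],
    coding_only: bool = True,
) -> pd.DataFrame:
    """Triage candidate causative variants.

    Removes exact matches (chrom, pos, ref, alt) to the known-polymorphism
    set, annotates the remainder as coding/non-coding against the CDS
    footprint of the supplied gene models, and by default retains only
    coding variants. ``pos`` is 1-based (VCF convention).
    """
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(variants.columns):
        raise ModelError(f"variant table must have columns {sorted(required)}")
    cds: dict[str, list[tuple[int, int]]] = {}
    for gm in gene_models:
        cds.setdefault(gm.chrom, []).extend(gm.cds_genomic_intervals())

    def is_known(row) -> bool:
        return (row["chrom"], int(row["pos"]), row["ref"], row["alt"]) in known_variants

    def is_coding(row) -> bool:
        p = int(row["pos"]) - 1
        return any(s <= p < e for s, e in cds.get(row["chrom"], []))

    out = variants.loc[[not is_known(r) for _, r in variants.iterrows()]].copy()
    out["coding"] = [is_coding(r) for _, r in out.iterrows()]
    if coding_only:
        out = out[out["coding"]]
    return out.reset_index(drop=True)
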