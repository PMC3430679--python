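"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF v4.2 (1-based; controls phased with '|') or as a
PED/MAP dialect; truth intervals as BED (0-based half-open); mate pairs,
depth tracks and mating records as TSV; references as FASTA; deletions as
symbolic <DEL> VCF records. Reading of VCF uses cyvcf2 and of gene models
gffutils; the writers emit the minimal dialects the pipeline itself
consumes.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic_data import GenotypeMatrix, MarkerMap


# --- genotypes -------------------------------------------------------------


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """VCF v4.2; case genotypes unphased, control genotypes phased from truth."""
    m = gm.markers
    ctrl_ids = gm.control_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lethalscan\n")
        for c in m.chromosomes:
            lo, hi = m.chrom_block(c)
            fh.write(f"##contig=<ID={c},length={int(m.pos[hi - 1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        n_cases = len(gm.case_ids)
        unphased = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for j in range(m.n_markers):
            fields = [
                str(m.chrom[j]),
                str(int(m.pos[j])),
                str(m.ids[j]),
                str(m.ref[j]),
                str(m.alt[j]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for i, sid in enumerate(gm.sample_ids):
                g = int(gm.genotypes[i, j])
                if i >= n_cases and gm.control_haplotypes is not None:
                    k = i - n_cases
                    a, b = gm.control_haplotypes[2 * k, j], gm.control_haplotypes[2 * k + 1, j]
                    fields.append(f"{a}|{b}")
                else:
                    fields.append(unphased[g])
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str, case_ids: list[str]) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix; phased samples feed the control pool."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, pos, ids, ref, alt = [], [], [], [], []
    geno_rows, hap_rows = [], []
    phased_ctrl = [s for s in samples if s not in set(case_ids)]
    for var in vcf:
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else "N")
        g = var.genotypes  # [allele1, allele2, phased]
        geno_rows.append(
            [a + b if a >= 0 and b >= 0 else -1 for a, b, *_ in g]
        )
        hap_rows.append([(gt[0], gt[1]) for gt in g])
    markers = MarkerMap(
        np.array(chroms, dtype=object),
        np.array(pos, dtype=np.int64),
        np.array(ids, dtype=object),
        np.array(ref, dtype=object),
        np.array(alt, dtype=object),
    )
    geno = np.array(geno_rows, dtype=np.int8).T  # (samples, markers)
    ctrl_idx = [samples.index(s) for s in phased_ctrl]
    haps = np.empty((2 * len(ctrl_idx), markers.n_markers), dtype=np.int8)
    for k, si in enumerate(ctrl_idx):
        for j in range(markers.n_markers):
            haps[2 * k, j], haps[2 * k + 1, j] = hap_rows[j][si]
    order = [s for s in case_ids if s in samples] + phased_ctrl
    rows = [samples.index(s) for s in order]
    return GenotypeMatrix(
        markers=markers,
        sample_ids=order,
        case_ids=[s for s in case_ids if s in samples],
        genotypes=geno[rows],
        control_haplotypes=haps,
    )


def write_ped_map(gm: GenotypeMatrix, prefix: str) -> None:
    """PLINK-style PED/MAP pair (alleles as REF/ALT letters, 0 = missing)."""
    m = gm.markers
    with open(prefix + ".map", "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chrom[j]}\t{m.ids[j]}\t0\t{int(m.pos[j])}\n")
    with open(prefix + ".ped", "w") as fh:
        case = set(gm.case_ids)
        for i, sid in enumerate(gm.sample_ids):
            pheno = "2" if sid in case else "1"
            row = [sid, sid, "0", "0", "0", pheno]
            for j in range(m.n_markers):
                g = int(gm.genotypes[i, j])
                r, a = str(m.ref[j]), str(m.alt[j])
                row.extend({0: (r, r), 1: (r, a), 2: (a, a)}.get(g, ("0", "0")))
            fh.write("\t".join(row) + "\n")


# --- intervals and tables --------------------------------------------------


def write_bed(intervals: list[tuple[str, int, int]], path: str, names=None) -> None:
    with open(path, "w") as fh:
        for k, (chrom, start, end) in enumerate(intervals):
            name = names[k] if names else f"region_{k}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_pairs_tsv(pairs: pd.DataFrame, path: str) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"pair_id", "pos1", "pos2", "orientation", "mapped_distance"} - set(df.columns)
    if missing:
        raise DataError(f"mate-pair table missing columns {sorted(missing)}")
    return df


def write_depth_tsv(depth: np.ndarray, path: str) -> None:
    pd.DataFrame({"pos": np.arange(len(depth)), "depth": depth}).to_csv(
        path, sep="\t", index=False
    )


def read_depth_tsv(path: str) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if not {"pos", "depth"}.issubset(df.columns):
        raise DataError("depth table needs 'pos' and 'depth' columns")
    depth = np.zeros(int(df["pos"].max()) + 1)
    depth[df["pos"].to_numpy()] = df["depth"].to_numpy()
    return depth


def write_matings_tsv(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_matings_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"sire_class", "dam_sire_class", "fail56", "fail90", "fail270"}
    if not needed.issubset(df.columns):
        raise DataError(f"mating table missing columns {sorted(needed - set(df.columns))}")
    return df


def write_junction_reads(junction: pd.DataFrame, path: str) -> None:
    junction.to_csv(path, sep="\t", index=False)


def read_junction_reads(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- sequences and SV calls ------------------------------------------------


def write_fasta(seq: str, path: str, name: str = "ref") -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], path, "fasta")


def read_fasta(path: str) -> str:
    from Bio import SeqIO

    return str(next(SeqIO.parse(path, "fasta")).seq)


def write_deletion_vcf(calls, path: str, chrom_lengths: dict | None = None) -> None:
    """Symbolic <DEL> records; POS is the base before the deleted segment (1-based)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lethalscan-callsv\n")
        fh.write('##ALT=<ID=DEL,Description="Deletion">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="End of deletion">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Deletion length">\n')
        fh.write('##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Discordant pairs">\n')
        fh.write('##INFO=<ID=EVIDENCE,Number=1,Type=String,Description="Evidence tier">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k, call in enumerate(calls):
            info = (
                f"END={call.end};SVLEN=-{call.size};SUPPORT={call.n_discordant_pairs};"
                f"EVIDENCE={call.evidence.replace('+', '_')}"
            )
            fh.write(
                f"{call.chrom}\t{call.start}\tdel_{k}\tN\t<DEL>\t.\tPASS\t{info}\n"
            )


def read_gene_model_gff3(path: str, name: str | None = None):
    """Load one transcript's exons and CDS bounds from a GFF3 file."""
    import gffutils

    from .consequence import GeneModel

    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique", force=True)
    exons, cds = [], []
    chrom = strand = None
    for f in db.all_features(order_by="start"):
        if f.featuretype == "exon":
            exons.append((f.start - 1, f.end))
            chrom, strand = f.seqid, f.strand
        elif f.featuretype == "CDS":
            cds.append((f.start - 1, f.end))
    if not exons:
        raise DataError("no exon features in GFF3")
    exons.sort()
    if not cds:
        cds_start, cds_end = 0, sum(e - s for s, e in exons)
    else:
        cds.sort()
        tmp = GeneModel(chrom=chrom, strand=strand, exons=tuple(exons), cds_start=0,
                        cds_end=sum(e - s for s, e in exons), name=name or "gff_gene")
        offsets = _genomic_to_transcript_offsets(tmp, cds)
        cds_start, cds_end = offsets
    return GeneModel(
        chrom=chrom,
        strand=strand,
        exons=tuple(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        name=name or "gff_gene",
    )


def _genomic_to_transcript_offsets(model, cds_intervals):
    spans = model.exon_transcript_spans()
    exons_tx = model.exons[::-1] if model.strand == "-" else model.exons
    lo, hi = None, None
    g_lo = min(s for s, _ in cds_intervals)
    g_hi = max(e for _, e in cds_intervals)
    for (ts, te), (gs, ge) in zip(spans, exons_tx):
        for g, which in ((g_lo, "lo"), (g_hi - 1, "hi")):
            if gs <= g < ge:
                t = ts + (g - gs) if model.strand == "+" else ts + (ge - 1 - g)
                if which == "lo":
                    lo = t
                else:
                    hi = t
    if lo is None or hi is None:
        raise DataError("CDS bounds fall outside exons")
    if model.strand == "-":
        lo, hi = hi, lo
    return lo, hi + 1
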