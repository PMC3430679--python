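"""Generate the synthetic study and write it to disk.

The cohort emulates the study's three data sources: 50K-style SNP
genotypes of 6 affected calves sharing a planted 2.46 Mb autozygous
haplotype plus 100 phased controls; 4-4.5 kb-insert mate pairs of a
homozygous-deletion case and a wild-type control over a window carrying a
3,329 bp deletion; and 4 x 1,000,000 AI mating records with return-to-
oestrus outcomes at 56/90/270 days. Raw files go to scratch/ (bulky);
a summary table goes to results/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _config as cfg

from lethalscan import io

out = cfg.scratch_dir("01_cohort")
res = cfg.results_dir("01_cohort")

genotypes = cfg.cohort_genotypes()
io.write_vcf(genotypes, os.path.join(out, "genotypes.vcf"))
io.write_bed(
    [genotypes.truth_interval], os.path.join(res, "truth_interval.bed"),
    names=["planted_ibd"],
)

case_reads = cfg.cohort_reads("D/D")
ctrl_reads = cfg.cohort_reads("+/+")
io.write_pairs_tsv(case_reads.pairs, os.path.join(out, "case_pairs.tsv"))
io.write_depth_tsv(case_reads.depth, os.path.join(out, "case_depth.tsv"))
io.write_pairs_tsv(ctrl_reads.pairs, os.path.join(out, "control_pairs.tsv"))
io.write_junction_reads(
    case_reads.junction_reads, os.path.join(out, "case_junction_reads.tsv")
)
io.write_fasta(case_reads.reference, os.path.join(out, "reference.fa"))

matings = cfg.cohort_matings()
io.write_matings_tsv(matings, os.path.join(out, "matings.tsv"))

with open(os.path.join(res, "cohort_summary.tsv"), "w") as fh:
    fh.write("item\tvalue\n")
    fh.write(f"n_cases\t{len(genotypes.case_ids)}\n")
    fh.write(f"n_controls\t{len(genotypes.control_ids)}\n")
    fh.write(f"n_markers\t{genotypes.markers.n_markers}\n")
    fh.write(f"planted_interval\t{genotypes.truth_interval}\n")
    fh.write(f"n_case_mate_pairs\t{len(case_reads.pairs)}\n")
    fh.write(f"n_junction_reads\t{case_reads.junction_reads['read_id'].nunique()}\n")
    fh.write(f"n_matings\t{len(matings)}\n")

print(f"cohort raw files -> {out}")
print(f"  {len(genotypes.case_ids)} cases / {len(genotypes.control_ids)} phased controls "
      f"over {genotypes.markers.n_markers} markers; planted IBD interval "
      f"{genotypes.truth_interval}")
print(f"  {len(case_reads.pairs)} case mate pairs, "
      f"{case_reads.junction_reads['read_id'].nunique()} junction reads")
print(f"  {len(matings):,} mating records")
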