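"""Call the deletion from the case's mate pairs and depth track.

The insert model is fitted on the wild-type control library (as in the
study, where unaffected controls were sequenced alongside the case); the
case shows a cluster of discordant pairs mapping ~8 kb apart and a
complete coverage dropout, which merge into one tier-1 call whose
breakpoints are then fixed exactly by junction reads.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _config as cfg

from lethalscan import io
from lethalscan import sv_calling as sv

res = cfg.results_dir("03_deletion")
case = cfg.cohort_reads("D/D")
ctrl = cfg.cohort_reads("+/+")

model = sv.fit_insert_model(ctrl.pairs)
clusters = sv.cluster_discordant(case.pairs, model)
dropouts = sv.detect_dropout(case.depth)
calls = [
    sv.refine_breakpoints(c, case.junction_reads, case.reference)
    for c in sv.merge_evidence(clusters, dropouts)
]
io.write_deletion_vcf(calls, os.path.join(res, "deletions.vcf"))

disc = case.pairs[case.pairs.mapped_distance > model.threshold]
with open(os.path.join(res, "evidence.tsv"), "w") as fh:
    fh.write("chrom\tstart\tend\tsize\tevidence\tn_pairs\trefined\tmicrohomology\n")
    for c in calls:
        fh.write(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.size}\t{c.evidence}\t"
            f"{c.n_discordant_pairs}\t{int(c.refined)}\t{c.microhomology}\n"
        )

best = calls[0]
print(f"insert model: {model.mean:.0f} +/- {model.sd:.0f} bp; "
      f"discordance threshold {model.threshold:.0f} bp")
print(f"discordant cluster: {len(disc)} pairs mapping on average "
      f"{disc.mapped_distance.mean() / 1000:.1f} kb apart")
print(f"top call: {best.chrom}:{best.start:,}-{best.end:,} ({best.size:,} bp), "
      f"evidence {best.evidence}, refined={best.refined}, "
      f"microhomology={best.microhomology} bp")
print(f"truth interval {case.truth_interval} -> "
      f"{'exact' if (best.start, best.end) == case.truth_interval or best.size == case.config.deletion_length else 'MISSED'}")
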