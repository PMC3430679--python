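"""Predict the transcript/protein consequence of the deletion on a
synthetic 37-exon FANCI-like gene built to the study's geometry.

Finding: deleting exons 25-27 (361 coding bp) juxtaposes exons 24 and 28,
shifts the frame after residue 877 of 1,328, replaces the 451 C-terminal
residues with a 26-residue novel peptide, and leaves the premature stop in
exon 28, far enough upstream of the last junction to predict NMD. The
validation amplicons reproduce the 457/96 bp cDNA pair and the 409 bp
deletion-specific genomic product.
"""

import json
import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
import _config as cfg

from lethalscan import consequence as cq
from lethalscan import synthetic_data as sd
from lethalscan._seeds import child_seed

res = cfg.results_dir("04_consequence")
case = sd.fanci_like_case(seed=child_seed(cfg.ROOT_SEED, "gene"))
mutant = cq.apply_deletion(case.gene, case.deletion)
effect = cq.protein_effect(case.gene, mutant, case.genome, case.deletion)

mut_genome = cq.delete_interval(case.genome, case.deletion)
wt_tx = case.gene.transcript_sequence(case.genome)
mut_tx = mutant.transcript_sequence(mut_genome)
cdna = cq.predict_amplicons(case.primers["cdna_ex24_ex28"], wt_tx, mut_tx)
junction = cq.predict_amplicons(
    case.primers["junction_spanning"], case.genome, mut_genome, max_amplicon=2000
)
internal = cq.predict_amplicons(
    case.primers["internal"], case.genome, mut_genome, max_amplicon=2000
)

summary = {
    "deleted_exons_1based": [i + 1 for i in effect.deleted_exons],
    "deleted_cds_length": effect.deleted_cds_length,
    "frameshift": effect.frameshift,
    "divergence_position": effect.divergence_position,
    "novel_peptide_length": effect.novel_peptide_length,
    "truncated_residues": effect.truncated_residues,
    "wt_protein_length": effect.wt_protein_length,
    "ptc_exon_1based": effect.ptc_exon_index + 1,
    "nmd_predicted": effect.nmd_predicted,
    "amplicons_wt_mut": {
        "cdna": [cdna.wt_product, cdna.mut_product],
        "junction_spanning": [junction.wt_product, junction.mut_product],
        "internal": [internal.wt_product, internal.mut_product],
    },
}
with open(os.path.join(res, "consequence_summary.json"), "w") as fh:
    json.dump(summary, fh, indent=2)
    fh.write("\n")

print(f"deleted exons {summary['deleted_exons_1based']} "
      f"({effect.deleted_cds_length} coding bp, frameshift={effect.frameshift})")
print(f"divergence at residue {effect.divergence_position} of "
      f"{effect.wt_protein_length}; {effect.truncated_residues} residues replaced by "
      f"{effect.novel_peptide_length}-aa novel peptide; PTC in exon "
      f"{summary['ptc_exon_1based']}; NMD predicted: {effect.nmd_predicted}")
print(f"amplicons wt/mut (bp): cDNA {cdna.wt_product}/{cdna.mut_product}, "
      f"junction-spanning {junction.wt_product}/{junction.mut_product}, "
      f"internal {internal.wt_product}/{internal.mut_product}")
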