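"""Whole-exon deletion effects: juxtaposition, reading frame, NMD rule,
amplicon arithmetic and candidate-variant triage."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings, strategies as st

from lethalscan import consequence as cq
from lethalscan import synthetic_data as sd
from lethalscan.errors import AmbiguousPrimerError, ModelError, UnsupportedDeletionError


def make_gene(exon_lens, intron=200, flank=300, seed=0, cds=None):
    """Single-strand '+' gene with the given exon transcript lengths."""
    rng = np.random.default_rng(seed)
    tlen = sum(exon_lens)
    if cds is None:
        codons = [c for c in (a + b + d for a in "ACGT" for b in "ACGT" for d in "ACGT")
                  if c not in ("TAA", "TAG", "TGA")]
        body = "".join(rng.choice(codons, size=tlen // 3 - 1))
        cds = ("ATG" + body)[: tlen - 3] + "TAA"
    assert len(cds) == tlen
    exons = []
    pos = flank
    for L in exon_lens:
        exons.append((pos, pos + L))
        pos += L + intron
    genome = list(sd.random_dna(pos - intron + flank, rng))
    off = 0
    for (s, e), L in zip(exons, exon_lens):
        genome[s:e] = cds[off : off + L]
        off += L
    model = cq.GeneModel(
        chrom="g", strand="+", exons=tuple(exons), cds_start=0, cds_end=tlen
    )
    return model, "".join(genome)


class TestApplyDeletion:
    def test_zero_length_roundtrip(self):
        model, genome = make_gene([30, 30, 30])
        assert cq.apply_deletion(model, (100, 100)) is model

    def test_intronic_deletion_preserves_transcript(self):
        model, genome = make_gene([30, 30, 30])
        s = model.exons[0][1] + 10
        mutant = cq.apply_deletion(model, (s, s + 50))
        mut_genome = cq.delete_interval(genome, (s, s + 50))
        assert mutant.transcript_sequence(mut_genome) == model.transcript_sequence(genome)

    def test_internal_exon_block_removed(self):
        model, genome = make_gene([30] * 10)
        ds = model.exons[4][0] - 5
        de = model.exons[5][1] + 5
        mutant = cq.apply_deletion(model, (ds, de))
        assert mutant.n_exons == 8
        # exons 4 and 7 (0-based 3 and 6) are now adjacent in the transcript
        spans = mutant.exon_transcript_spans()
        assert spans[3][1] == spans[4][0]

    def test_exon_splitting_rejected(self):
        model, genome = make_gene([30, 30, 30])
        mid = model.exons[1][0] + 10
        with pytest.raises(UnsupportedDeletionError):
            cq.apply_deletion(model, (mid, mid + 100))

    def test_thirtyseven_exon_case_structure(self, fanci_case):
        mutant = cq.apply_deletion(fanci_case.gene, fanci_case.deletion)
        assert fanci_case.gene.n_exons == 37
        assert mutant.n_exons == 34


class TestProteinEffect:
    def test_in_frame_deletion_no_novel_peptide(self):
        model, genome = make_gene([60, 60, 60, 60, 60])
        ds, de = model.exons[2][0] - 5, model.exons[2][1] + 5  # 60 nt, in frame
        mutant = cq.apply_deletion(model, (ds, de))
        eff = cq.protein_effect(model, mutant, genome, (ds, de))
        assert not eff.frameshift
        assert eff.novel_peptide_length == 0
        assert eff.deleted_cds_length == 60

    def test_frameshift_iff_deleted_length_not_multiple_of_three(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            lens = [int(rng.integers(20, 70)) for _ in range(6)]
            lens = [L + (3 - sum(lens) % 3) % 3 if i == 5 else L for i, L in enumerate(lens)]
            model, genome = make_gene(lens, seed=int(rng.integers(1 << 30)))
            k = int(rng.integers(1, 5))
            ds, de = model.exons[k][0] - 3, model.exons[k][1] + 3
            mutant = cq.apply_deletion(model, (ds, de))
            eff = cq.protein_effect(model, mutant, genome, (ds, de))
            assert eff.frameshift == (lens[k] % 3 != 0)
            # direct-translation oracle: compare proteins by hand
            wt_prot = str(Seq(model.cds_sequence(genome)).translate(to_stop=True))
            mut_tx = mutant.transcript_sequence(cq.delete_interval(genome, (ds, de)))
            mut_prot = str(Seq(mut_tx[: 3 * (len(mut_tx) // 3)]).translate(to_stop=True))
            assert eff.wt_protein_length == len(wt_prot)
            assert eff.mutant_protein_length == len(mut_prot)

    def test_study_scaled_divergence_and_truncation(self, fanci_case):
        mutant = cq.apply_deletion(fanci_case.gene, fanci_case.deletion)
        eff = cq.protein_effect(fanci_case.gene, mutant, fanci_case.genome, fanci_case.deletion)
        assert eff.wt_protein_length == 1328
        assert eff.divergence_position == 878
        assert eff.truncated_residues == 451
        assert eff.novel_peptide_length == 26
        assert eff.frameshift and eff.deleted_cds_length == 361
        assert eff.ptc_exon_index == 27  # exon 28, wild-type numbering
        assert eff.nmd_predicted

    def test_invalid_wildtype_rejected(self):
        model, genome = make_gene([30, 30, 30])
        bad = genome[: model.exons[0][0]] + "CCC" + genome[model.exons[0][0] + 3 :]
        mutant = cq.apply_deletion(model, (model.exons[1][0] - 2, model.exons[1][1] + 2))
        with pytest.raises(ModelError, match="ATG"):
            cq.protein_effect(model, mutant, bad, (model.exons[1][0] - 2, model.exons[1][1] + 2))


class TestPredictNMD:
    def _model(self, exon_lens):
        model, _ = make_gene(exon_lens)
        return model

    def test_ptc_in_last_exon_escapes(self):
        m = self._model([120, 120, 120])
        assert not cq.predict_nmd(m, 300)

    def test_ptc_far_upstream_triggers(self):
        m = self._model([300, 120, 120])
        junction = m.transcript_length - 120
        assert cq.predict_nmd(m, junction - 200)

    def test_boundary_inclusive_at_fifty(self):
        m = self._model([300, 120, 120])
        junction = m.transcript_length - 120
        assert cq.predict_nmd(m, junction - 50)
        assert not cq.predict_nmd(m, junction - 49)

    def test_single_exon_never(self):
        model, _ = make_gene([300])
        assert not cq.predict_nmd(model, 10)


class TestPredictAmplicons:
    def test_internal_pair_allele_specific(self, fanci_case):
        mut_genome = cq.delete_interval(fanci_case.genome, fanci_case.deletion)
        res = cq.predict_amplicons(
            fanci_case.primers["internal"], fanci_case.genome, mut_genome, max_amplicon=2000
        )
        assert res.wt_product is not None and res.mut_product is None

    def test_junction_pair_deletion_specific(self, fanci_case):
        mut_genome = cq.delete_interval(fanci_case.genome, fanci_case.deletion)
        res = cq.predict_amplicons(
            fanci_case.primers["junction_spanning"], fanci_case.genome, mut_genome,
            max_amplicon=2000,
        )
        assert res.wt_product is None  # wild-type span exceeds max_amplicon
        assert res.mut_product == 409

    def test_cdna_products_and_identity(self, fanci_case):
        mutant = cq.apply_deletion(fanci_case.gene, fanci_case.deletion)
        mut_genome = cq.delete_interval(fanci_case.genome, fanci_case.deletion)
        wt_tx = fanci_case.gene.transcript_sequence(fanci_case.genome)
        mut_tx = mutant.transcript_sequence(mut_genome)
        res = cq.predict_amplicons(fanci_case.primers["cdna_ex24_ex28"], wt_tx, mut_tx)
        assert (res.wt_product, res.mut_product) == (457, 96)
        assert res.wt_product - res.mut_product == 361  # summed deleted exon lengths

    @given(st.integers(0, 1_000_000))
    @settings(deadline=None, max_examples=15)
    def test_cdna_identity_on_random_genes(self, seed):
        rng = np.random.default_rng(seed)
        lens = [int(rng.integers(60, 120)) for _ in range(6)]
        lens[-1] += (3 - sum(lens) % 3) % 3
        model, genome = make_gene(lens, seed=seed)
        k = int(rng.integers(1, 5))
        ds, de = model.exons[k][0] - 2, model.exons[k][1] + 2
        mutant = cq.apply_deletion(model, (ds, de))
        mut_genome = cq.delete_interval(genome, (ds, de))
        wt_tx = model.transcript_sequence(genome)
        mut_tx = mutant.transcript_sequence(mut_genome)
        spans = model.exon_transcript_spans()
        fs, fe = spans[k - 1]
        ns, ne = spans[k + 1]
        fwd = wt_tx[fe - 25 : fe - 5]
        rev = str(Seq(wt_tx[ns + 5 : ns + 25]).reverse_complement())
        res = cq.predict_amplicons((fwd, rev), wt_tx, mut_tx)
        assert res.wt_product is not None and res.mut_product is not None
        assert res.wt_product - res.mut_product == lens[k]

    def test_ambiguous_primer_rejected(self):
        seq = "ACGTACGTAAACCCGGGTTT" * 2
        with pytest.raises(AmbiguousPrimerError):
            cq.predict_amplicons((seq[:12], "AAAA"), seq, seq)


class TestVariantTriage:
    def test_known_and_noncoding_removed(self):
        model, _ = make_gene([30, 30, 30])
        e0 = model.exons[0]
        variants = pd.DataFrame(
            {
                "chrom": ["g", "g", "g"],
                "pos": [e0[0] + 5, e0[1] + 50, e0[0] + 8],  # coding, intronic, coding
                "ref": ["A", "A", "A"],
                "alt": ["G", "G", "T"],
            }
        )
        known = {("g", e0[0] + 5, "A", "G")}
        kept = cq.filter_candidate_variants(variants, known, [model])
        assert len(kept) == 1
        assert kept.iloc[0]["pos"] == e0[0] + 8

    def test_coding_only_flag(self):
        model, _ = make_gene([30, 30, 30])
        variants = pd.DataFrame(
            {"chrom": ["g"], "pos": [model.exons[0][1] + 50], "ref": ["A"], "alt": ["G"]}
        )
        kept = cq.filter_candidate_variants(variants, set(), [model], coding_only=False)
        assert len(kept) == 1 and not kept.iloc[0]["coding"]
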