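"""One-config orchestration of the full synthetic analysis.

Stages run in the order of the study's inference chain:

    simulate -> map -> callsv -> consequence -> popgen -> fertility

Every stage draws its randomness from a child seed derived from the single
root seed and the stage name, so stages are independently rerunnable and a
rerun with the same config is bit-identical. A run manifest records the
child seeds and a SHA-256 digest of every output file (no wall-clock
information, so manifests of identical runs are themselves identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__, autozygosity, consequence, fertility, io, popgen, sv_calling
from . import synthetic_data as sd
from ._seeds import child_seed
from .errors import ConfigurationError, LethalscanError

log = logging.getLogger("lethalscan")

STAGE_ORDER = ("simulate", "map", "callsv", "consequence", "popgen", "fertility")


@dataclass
class RunConfig:
    """Root seed, output directory, stage switches and per-stage parameters."""

    seed: int
    outdir: str
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    genotypes: dict = field(default_factory=dict)
    reads: dict = field(default_factory=dict)
    matings: dict = field(default_factory=dict)
    map_params: dict = field(default_factory=lambda: {"n_reps": 1000})
    popgen_params: dict = field(default_factory=lambda: {"sample_size": 3038})

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ConfigurationError("config must set a seed")
        if "outdir" not in raw:
            raise ConfigurationError("config must set an output directory")
        cfg = cls(seed=int(raw["seed"]), outdir=str(raw["outdir"]))
        stages = dict(cfg.stages)
        stages.update(raw.get("stages", {}))
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ConfigurationError(f"unknown stages in config: {sorted(unknown)}")
        cfg.stages = stages
        for block in ("genotypes", "reads", "matings", "map_params", "popgen_params"):
            getattr(cfg, block).update(raw.get(block, {}))
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; return the manifest (also written to disk).

    A stage failure aborts the run with the failing stage named; outputs of
    completed stages are retained and a ``<stage>.partial`` marker is left
    for the failed one.
    """
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "root_seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    ctx: dict = {}
    for stage in STAGE_ORDER:
        if not config.stages.get(stage, True):
            continue
        stage_dir = os.path.join(config.outdir, stage)
        os.makedirs(stage_dir, exist_ok=True)
        seed = child_seed(config.seed, stage)
        log.info("stage %s (seed %d)", stage, seed)
        marker = os.path.join(config.outdir, f"{stage}.partial")
        open(marker, "w").close()
        try:
            outputs = _STAGE_FUNCS[stage](config, stage_dir, seed, ctx)
        except Exception as exc:
            raise LethalscanError(f"stage {stage!r} failed: {exc}") from exc
        os.remove(marker)
        manifest["stages"].append({"name": stage, "seed": seed})
        for path in outputs:
            rel = os.path.relpath(path, config.outdir)
            manifest["outputs"][rel] = _sha256(path)
    _write_json(manifest, os.path.join(config.outdir, "manifest.json"))
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    gcfg = sd.PopulationConfig(**{"seed": child_seed(seed, "genotypes"), **config.genotypes})
    markers = sd.random_marker_map(seed=child_seed(seed, "markers"))
    gm = sd.simulate_genotypes(gcfg, markers)
    rcfg = sd.ReadSimConfig(**{"seed": child_seed(seed, "reads"), **config.reads})
    case_reads = sd.simulate_matepairs(rcfg, "D/D")
    ctrl_reads = sd.simulate_matepairs(
        sd.ReadSimConfig(**{**asdict(rcfg), "seed": child_seed(seed, "control_reads")}), "+/+"
    )
    mcfg = sd.MatingSimConfig(**{"seed": child_seed(seed, "matings"), **config.matings})
    matings = sd.simulate_matings(mcfg)
    ctx.update(
        genotypes=gm,
        case_reads=case_reads,
        ctrl_reads=ctrl_reads,
        matings=matings,
        mating_config=mcfg,
        genotype_config=gcfg,
    )
    p = lambda name: os.path.join(outdir, name)
    io.write_vcf(gm, p("genotypes.vcf"))
    io.write_bed([gm.truth_interval], p("truth_interval.bed"), names=["planted_ibd"])
    io.write_pairs_tsv(case_reads.pairs, p("case_pairs.tsv"))
    io.write_depth_tsv(case_reads.depth, p("case_depth.tsv"))
    io.write_pairs_tsv(ctrl_reads.pairs, p("control_pairs.tsv"))
    io.write_junction_reads(case_reads.junction_reads, p("case_junction_reads.tsv"))
    io.write_fasta(case_reads.reference, p("reference.fa"))
    io.write_matings_tsv(matings, p("matings.tsv"))
    _write_json(
        {
            "n_cases": gcfg.n_cases,
            "n_controls": gcfg.n_controls,
            "carrier_freq": gcfg.carrier_freq,
            "planted_interval": list(gm.truth_interval),
            "n_mate_pairs": int(len(case_reads.pairs) + case_reads.junction_reads["read_id"].nunique()),
            "n_matings": int(len(matings)),
        },
        p("simulate_summary.json"),
    )
    return [
        p(n)
        for n in (
            "genotypes.vcf",
            "truth_interval.bed",
            "case_pairs.tsv",
            "case_depth.tsv",
            "control_pairs.tsv",
            "case_junction_reads.tsv",
            "reference.fa",
            "matings.tsv",
            "simulate_summary.json",
        )
    ]


def _stage_map(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    gm = ctx["genotypes"]
    scan = autozygosity.genomewide_scan(
        gm, n_reps=int(config.map_params.get("n_reps", 1000)), seed=seed
    )
    ctx["scan"] = scan
    markers = gm.markers
    p = os.path.join(outdir, "scan_statistic.tsv")
    with open(p, "w") as fh:
        fh.write("marker\tchrom\tpos\tp_point\tneg_log10\n")
        for j in range(markers.n_markers):
            pj = scan.p_point[j]
            fh.write(
                f"{markers.ids[j]}\t{markers.chrom[j]}\t{int(markers.pos[j])}\t"
                f"{pj:.6g}\t{-np.log10(pj):.4f}\n"
            )
    seg = scan.min_segment
    bed = os.path.join(outdir, "candidate_interval.bed")
    io.write_bed(
        [(seg.chrom, seg.start_bp - 1, seg.end_bp)], bed, names=["shared_autozygous_segment"]
    )
    summary = {
        "chrom": seg.chrom,
        "start_bp": int(seg.start_bp),
        "end_bp": int(seg.end_bp),
        "span_mb": (seg.end_bp - seg.start_bp) / 1e6,
        "n_markers": seg.n_markers,
        "p_point": seg.p_point,
        "p_genomewide": seg.p_genomewide,
        "n_reps": scan.n_reps,
    }
    sj = os.path.join(outdir, "map_summary.json")
    _write_json(summary, sj)
    return [p, bed, sj]


def _stage_callsv(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    case = ctx["case_reads"]
    ctrl = ctx["ctrl_reads"]
    model = sv_calling.fit_insert_model(ctrl.pairs)
    clusters = sv_calling.cluster_discordant(case.pairs, model)
    dropouts = sv_calling.detect_dropout(case.depth)
    calls = sv_calling.merge_evidence(clusters, dropouts)
    refined = []
    for call in calls:
        refined.append(
            sv_calling.refine_breakpoints(call, case.junction_reads, case.reference)
        )
    ctx["deletion_calls"] = refined
    vcf = os.path.join(outdir, "deletions.vcf")
    io.write_deletion_vcf(refined, vcf)
    ev = os.path.join(outdir, "evidence.tsv")
    with open(ev, "w") as fh:
        fh.write("chrom\tstart\tend\tsize\tevidence\tn_pairs\trefined\tn_junction_reads\tmicrohomology\n")
        for c in refined:
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.size}\t{c.evidence}\t"
                f"{c.n_discordant_pairs}\t{int(c.refined)}\t{c.n_junction_reads}\t"
                f"{'' if c.microhomology is None else c.microhomology}\n"
            )
    best = refined[0] if refined else None
    summary = {
        "insert_mean": model.mean,
        "insert_sd": model.sd,
        "discordance_threshold": model.threshold,
        "n_calls": len(refined),
        "truth_interval": list(case.truth_interval),
    }
    if best is not None:
        summary.update(
            best_call={
                "start": best.start,
                "end": best.end,
                "size": best.size,
                "evidence": best.evidence,
                "n_discordant_pairs": best.n_discordant_pairs,
                "refined": best.refined,
                "microhomology": best.microhomology,
            }
        )
    sj = os.path.join(outdir, "callsv_summary.json")
    _write_json(summary, sj)
    return [vcf, ev, sj]


def _stage_consequence(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    case = sd.fanci_like_case(seed=child_seed(seed, "gene"))
    mutant = consequence.apply_deletion(case.gene, case.deletion)
    effect = consequence.protein_effect(case.gene, mutant, case.genome, case.deletion)
    mut_genome = consequence.delete_interval(case.genome, case.deletion)
    wt_tx = case.gene.transcript_sequence(case.genome)
    mut_tx = mutant.transcript_sequence(mut_genome)
    cdna = consequence.predict_amplicons(case.primers["cdna_ex24_ex28"], wt_tx, mut_tx, max_amplicon=5000)
    junction = consequence.predict_amplicons(
        case.primers["junction_spanning"], case.genome, mut_genome, max_amplicon=2000
    )
    internal = consequence.predict_amplicons(
        case.primers["internal"], case.genome, mut_genome, max_amplicon=2000
    )
    summary = {
        "deleted_exons_1based": [i + 1 for i in effect.deleted_exons],
        "n_exons_wt": case.gene.n_exons,
        "n_exons_mut": mutant.n_exons,
        "deletion_size": case.deletion[1] - case.deletion[0],
        "frameshift": effect.frameshift,
        "divergence_position": effect.divergence_position,
        "novel_peptide_length": effect.novel_peptide_length,
        "truncated_residues": effect.truncated_residues,
        "wt_protein_length": effect.wt_protein_length,
        "ptc_exon_1based": None if effect.ptc_exon_index is None else effect.ptc_exon_index + 1,
        "nmd_predicted": effect.nmd_predicted,
        "amplicons": {
            "cdna": [cdna.wt_product, cdna.mut_product],
            "junction_spanning": [junction.wt_product, junction.mut_product],
            "internal": [internal.wt_product, internal.mut_product],
        },
    }
    ctx["effect_summary"] = summary
    sj = os.path.join(outdir, "consequence_summary.json")
    _write_json(summary, sj)
    txt = os.path.join(outdir, "effect_report.txt")
    with open(txt, "w") as fh:
        fh.write(
            "Deletion of exons {exs} ({sz} bp genomic) juxtaposes the flanking exons.\n"
            "Frameshift: {fs}; first divergent residue {dv} of {wt}; novel peptide {nv} aa; "
            "{tr} C-terminal residues replaced.\nPTC in exon {ptc}; NMD predicted: {nmd}.\n"
            "Amplicons (wt/mut bp): cDNA {c0}/{c1}; junction-spanning {j0}/{j1}; internal {i0}/{i1}.\n".format(
                exs=summary["deleted_exons_1based"],
                sz=summary["deletion_size"],
                fs=effect.frameshift,
                dv=effect.divergence_position,
                wt=effect.wt_protein_length,
                nv=effect.novel_peptide_length,
                tr=effect.truncated_residues,
                ptc=summary["ptc_exon_1based"],
                nmd=effect.nmd_predicted,
                c0=cdna.wt_product, c1=cdna.mut_product,
                j0=junction.wt_product, j1=junction.mut_product,
                i0=internal.wt_product, i1=internal.mut_product,
            )
        )
    return [sj, txt]


def _stage_popgen(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    n = int(config.popgen_params.get("sample_size", 3038))
    true_c = ctx.get("genotype_config", sd.PopulationConfig()).carrier_freq
    counts = sd.simulate_deletion_sample(n, true_c, seed)
    est = popgen.carrier_frequency(counts)
    q = popgen.allele_freq_from_carrier(est.estimate)
    inc, recip = popgen.expected_incidence(est.estimate)
    p0 = popgen.prob_zero_homozygotes(q, counts.total)
    raw_adj, adj = popgen.survival_adjusted_incidence(est.estimate, 0.5)
    summary = {
        "sample_size": counts.total,
        "n_carrier": counts.n_carrier,
        "n_homozygous": counts.n_homozygous,
        "carrier_freq_hat": est.estimate,
        "carrier_freq_ci": [est.ci_low, est.ci_high],
        "allele_freq_q": q,
        "expected_incidence": inc,
        "incidence_reciprocal": recip,
        "prob_zero_homozygotes": p0,
        "survival50_incidence_reciprocal": adj,
    }
    ctx["popgen_summary"] = summary
    sj = os.path.join(outdir, "popgen_summary.json")
    _write_json(summary, sj)
    return [sj]


def _stage_fertility(config: RunConfig, outdir: str, seed: int, ctx: dict) -> list[str]:
    mcfg = ctx.get("mating_config")
    if "matings" in ctx:
        records = ctx["matings"]
    else:
        mcfg = sd.MatingSimConfig(**{"seed": seed, **config.matings})
        records = sd.simulate_matings(mcfg)
    contrast = fertility.class_contrasts(records)
    fit = fertility.estimate_mortality(
        contrast, mcfg.carrier_freq, n_boot=200, seed=child_seed(seed, "boot")
    )
    cls = os.path.join(outdir, "class_summary.tsv")
    with open(cls, "w") as fh:
        fh.write("class\tn\tfail56\tfail90\tfail270\trate56\trate90\trate270\n")
        for label, s in contrast.summaries.items():
            r = s.rates
            fh.write(
                f"{label}\t{s.n}\t{s.failures[0]}\t{s.failures[1]}\t{s.failures[2]}\t"
                f"{r[0]:.5f}\t{r[1]:.5f}\t{r[2]:.5f}\n"
            )
    summary = {
        "truth_mortality": list(mcfg.mortality),
        "carrier_freq": mcfg.carrier_freq,
        "p_hom_cxc": fit.p_hom,
        "excess": contrast.excess.loc["CxC"].tolist(),
        "m_hat": fit.m_hat.tolist(),
        "ci_delta": fit.ci_delta.tolist(),
        "ci_boot": None if fit.ci_boot is None else fit.ci_boot.tolist(),
        "p_values": fit.p_values.tolist(),
        "excess_cdam_ncsire": contrast.excess.loc["CxNC"].tolist(),
    }
    ctx["fertility_summary"] = summary
    sj = os.path.join(outdir, "fertility_summary.json")
    _write_json(summary, sj)
    return [cls, sj]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "map": _stage_map,
    "callsv": _stage_callsv,
    "consequence": _stage_consequence,
    "popgen": _stage_popgen,
    "fertility": _stage_fertility,
}


# --- report ----------------------------------------------------------------


def make_report(run_dir: str) -> str:
    """Assemble a run report from stage summaries; returns the document text.

    Mirrors the inference chain: candidate interval -> deletion call ->
    transcript consequence -> population frequencies -> lethality. Missing
    stages are marked absent rather than failing.
    """
    manifest_path = os.path.join(run_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise LethalscanError(f"no manifest in {run_dir!r}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)

    def load(stage, name):
        path = os.path.join(run_dir, stage, name)
        if not os.path.exists(path):
            return None
        with open(path) as fh:
            return json.load(fh)

    lines = [
        "# lethalscan run report",
        "",
        f"Package version {manifest['package_version']}, root seed {manifest['root_seed']}.",
        "",
    ]
    m = load("map", "map_summary.json")
    lines.append("## Candidate interval (autozygosity mapping)")
    if m is None:
        lines.append("_section absent_")
    else:
        lines.append(
            f"Shared autozygous segment on chromosome {m['chrom']}: "
            f"{m['start_bp']:,}-{m['end_bp']:,} ({m['span_mb']:.2f} Mb, {m['n_markers']} markers); "
            f"point p = {m['p_point']:.3g}, genome-wide Monte-Carlo P = {m['p_genomewide']:.4g} "
            f"({m['n_reps']} replicates)."
        )
    lines.append("")
    c = load("callsv", "callsv_summary.json")
    lines.append("## Deletion call (mate pairs + depth)")
    if c is None or "best_call" not in c:
        lines.append("_section absent_")
    else:
        b = c["best_call"]
        lines.append(
            f"Insert model {c['insert_mean']:.0f} +/- {c['insert_sd']:.0f} bp "
            f"(discordance > {c['discordance_threshold']:.0f} bp). Top call: "
            f"{b['start']:,}-{b['end']:,} ({b['size']:,} bp), evidence {b['evidence']}, "
            f"{b['n_discordant_pairs']} discordant pairs, refined={b['refined']}, "
            f"microhomology={b['microhomology']} bp."
        )
    lines.append("")
    q = load("consequence", "consequence_summary.json")
    lines.append("## Transcript consequence")
    if q is None:
        lines.append("_section absent_")
    else:
        amp = q["amplicons"]
        lines.append(
            f"Deletion removes exons {q['deleted_exons_1based']} of {q['n_exons_wt']}; "
            f"frameshift={q['frameshift']} diverging at residue {q['divergence_position']} "
            f"of {q['wt_protein_length']}; {q['truncated_residues']} residues replaced by a "
            f"{q['novel_peptide_length']}-residue novel peptide; PTC in exon {q['ptc_exon_1based']}; "
            f"NMD predicted: {q['nmd_predicted']}. Amplicons wt/mut (bp): cDNA {amp['cdna']}, "
            f"junction-spanning {amp['junction_spanning']}, internal {amp['internal']}."
        )
    lines.append("")
    pg = load("popgen", "popgen_summary.json")
    lines.append("## Population genetics")
    if pg is None:
        lines.append("_section absent_")
    else:
        lines.append(
            f"Carrier frequency {100 * pg['carrier_freq_hat']:.1f}% "
            f"({pg['n_carrier']}/{pg['sample_size']}; Wilson 95% CI "
            f"{100 * pg['carrier_freq_ci'][0]:.1f}-{100 * pg['carrier_freq_ci'][1]:.1f}%), "
            f"allele frequency q = {pg['allele_freq_q']:.4f}; expected incidence "
            f"1/{pg['incidence_reciprocal']}; P(no homozygote in {pg['sample_size']}) = "
            f"{pg['prob_zero_homozygotes']:.3f}; with 50% in-utero survival, one affected birth per "
            f"{pg['survival50_incidence_reciprocal']} calvings."
        )
    lines.append("")
    ft = load("fertility", "fertility_summary.json")
    lines.append("## Lethality (mating-class contrasts)")
    if ft is None:
        lines.append("_section absent_")
    else:
        ex = ft["excess"]
        mh = ft["m_hat"]
        lines.append(
            f"Excess failure CxC - NCxNC at 56/90/270 d: "
            f"{100 * ex[0]:.2f}/{100 * ex[1]:.2f}/{100 * ex[2]:.2f} pp; expected homozygote "
            f"fraction {100 * ft['p_hom_cxc']:.1f}%; estimated cumulative mortality "
            f"{100 * mh[0]:.0f}%/{100 * mh[1]:.0f}%/{100 * mh[2]:.0f}% "
            f"(truth {ft['truth_mortality']})."
        )
        ex_cnc = ft["excess_cdam_ncsire"]
        lines.append(
            f"Model-misfit diagnostic — excess in carrier-dam x non-carrier-sire matings "
            f"(expected ~0 under the recessive-lethal model): "
            f"{100 * ex_cnc[0]:.2f}/{100 * ex_cnc[1]:.2f}/{100 * ex_cnc[2]:.2f} pp."
        )
    text = "\n".join(lines) + "\n"
    with open(os.path.join(run_dir, "report.md"), "w") as fh:
        fh.write(text)
    return text
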