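"""End-to-end orchestration and the run manifest.

Stages run in dependency order: synth -> exprmodel -> {rdd, ase} ->
protdb -> methylcorr. Each executed stage contributes exactly one summary
block to the manifest; a failure in one branch is recorded and does not
abort independent branches. On synthetic runs the manifest also carries a
truth-based evaluation (planted-edit recall/precision, artifact flagging,
informer precision/recall) computed against the truth table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ase as ase_mod
from . import exprmodel, io, methylcorr, protdb, rdd, synth
from .models import Annotation


class ConfigurationError(ValueError):
    """A requested stage is missing a required input."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    @property
    def ok(self) -> bool:
        return not self.errors


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] if isinstance(obj, set) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    return obj


def run_pipeline(
    config: synth.SimulationConfig,
    outdir: str | Path | None = None,
    fpkm_per_copy: float = 73.0,
) -> tuple[RunManifest, dict]:
    """Simulate-and-analyse run returning (manifest, in-memory outputs)."""
    config.validate()
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    outputs: dict = {}

    # --- synth --------------------------------------------------------------
    genome, annotation, truth = synth.generate_genome(config)
    pileup = synth.simulate_rna_pileup(genome, annotation, truth, config)
    fpkm, ibaq, mirna = synth.simulate_expression_tables(
        annotation, config, truth=truth
    )
    probes, panel_expr = synth.simulate_methylation_panel(
        annotation, config, truth=truth
    )
    outputs.update(
        genome=genome,
        annotation=annotation,
        truth=truth,
        pileup=pileup,
        fpkm=fpkm,
        ibaq=ibaq,
        mirna=mirna,
        probes=probes,
        panel_expr=panel_expr,
    )
    manifest.stages["synth"] = {
        "n_chromosomes": len(genome),
        "genome_length": sum(len(s) for s in genome.values()),
        "n_transcripts": len(annotation),
        "n_variants": len(truth.planted_variants),
        "n_edits": len(truth.planted_edits),
        "n_artifact_pairs": len(truth.planted_artifacts),
        "n_ase_genes": len(truth.planted_ase_genes),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(genome, outdir / "genome.fa")
        io.write_gtf(annotation, outdir / "annotation.gtf")
        io.write_vcf(truth.planted_variants, outdir / "variants.vcf")
        io.write_pileup(pileup, outdir / "pileup.tsv")
        io.write_table(fpkm, outdir / "fpkm.tsv")
        io.write_table(ibaq, outdir / "ibaq.tsv")
        io.write_table(mirna, outdir / "mirna.tsv")
        io.write_table(probes, outdir / "methylation.tsv")
        io.write_table(panel_expr, outdir / "panel_expression.tsv")
        for name in (
            "genome.fa",
            "annotation.gtf",
            "variants.vcf",
            "pileup.tsv",
            "fpkm.tsv",
        ):
            manifest.input_checksums[name] = _checksum(outdir / name)

    # --- exprmodel ----------------------------------------------------------
    try:
        fit = exprmodel.fit_expression_mixture(fpkm["fpkm"], seed=config.seed)
        classified = exprmodel.classify_transcripts(fpkm, fit)
        _, mirna_summary = exprmodel.mirna_copies_per_cell(mirna, fpkm_per_copy)
        outputs["mixture_fit"] = fit
        outputs["fpkm_classified"] = classified
        manifest.stages["exprmodel"] = _jsonable(
            {
                "fit": fit.to_dict(),
                **classified.attrs["summary"],
                "mirna": mirna_summary,
            }
        )
    except Exception as exc:  # independent branches continue
        manifest.errors["exprmodel"] = str(exc)

    # --- rdd ----------------------------------------------------------------
    try:
        candidates, summary = rdd.run_rdd_pipeline(
            pileup, genome, truth.planted_variants, annotation
        )
        outputs["rdd_candidates"] = candidates
        outputs["rdd_summary"] = summary
        evaluation = evaluate_rdd(candidates, truth)
        manifest.stages["rdd"] = _jsonable(
            {**summary.to_dict(), "evaluation": evaluation}
        )
    except Exception as exc:
        manifest.errors["rdd"] = str(exc)

    # --- ase ----------------------------------------------------------------
    try:
        sites = ase_mod.tally_het_sites(pileup, truth.planted_variants, annotation)
        calls = ase_mod.call_ase(sites)
        outputs["ase_calls"] = calls
        manifest.stages["ase"] = _jsonable(ase_mod.ase_summary(calls))
    except Exception as exc:
        manifest.errors["ase"] = str(exc)

    # --- protdb -------------------------------------------------------------
    try:
        params = protdb.DigestParams()
        dbs = {
            "six_frame": protdb.translate_six_frame(genome),
            "three_frame": protdb.translate_transcripts_three_frame(
                annotation, genome
            ),
            "variant": protdb.build_variant_db(
                annotation, genome, truth.planted_variants, params
            ),
            "alt_start": protdb.build_alt_start_db(annotation, genome, 50, params),
            "junction": protdb.build_junction_db(annotation, genome),
        }
        outputs["protein_databases"] = dbs
        manifest.stages["protdb"] = {
            f"n_{name}": len(entries) for name, entries in dbs.items()
        }
    except Exception as exc:
        manifest.errors["protdb"] = str(exc)

    # --- methylcorr ---------------------------------------------------------
    try:
        _, fractions = methylcorr.classify_beta(probes["naive"])
        assigned = methylcorr.assign_regions(probes, annotation)
        corr = methylcorr.correlate_methylation_expression(assigned, fpkm, ibaq)
        sample_cols = [c for c in probes.columns if c.startswith("S")]
        informers, pair_table = methylcorr.select_informer_sites(
            probes, panel_expr, sample_cols
        )
        deltas = methylcorr.differential_methylation(probes, panel_expr)
        methylcorr.score_informer_sites(informers, deltas)
        outputs["informer_sites"] = informers
        outputs["informer_table"] = pair_table
        outputs["methyl_deltas"] = deltas
        planted = truth.inverse_cpgs
        selected = {(s.probe_id, s.gene_id) for s in informers}
        tp = len(planted & selected)
        manifest.stages["methylcorr"] = _jsonable(
            {
                "beta_fractions": fractions,
                "correlations": corr,
                "n_informer_sites": len(informers),
                "informer_precision": tp / len(selected) if selected else None,
                "informer_recall": tp / len(planted) if planted else None,
            }
        )
    except Exception as exc:
        manifest.errors["methylcorr"] = str(exc)

    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    return manifest, outputs


def evaluate_rdd(
    candidates: list[rdd.RddCandidate], truth: synth.TruthTable
) -> dict:
    """Score the RDD cascade against the planted truth."""
    edit_sites = truth.edit_sites()
    snp_sites = truth.snp_sites()
    artifact_sites = set(truth.planted_artifact_sites)
    passing = {
        (c.chrom, c.pos) for c in candidates if c.filter_status == "pass"
    }
    called = {(c.chrom, c.pos) for c in candidates}
    recovered = edit_sites & passing
    recall = len(recovered) / len(edit_sites) if edit_sites else None
    precision = len(recovered) / len(passing) if passing else None
    flagged_artifacts = {
        (c.chrom, c.pos)
        for c in candidates
        if c.filter_status == "alignment_artifact"
    }
    return {
        "edit_recall": recall,
        "pass_precision": precision,
        "n_vcf_sites_passing": len(snp_sites & passing),
        "n_artifact_sites_candidate": len(artifact_sites & called),
        "n_artifact_sites_flagged": len(artifact_sites & flagged_artifacts),
    }


# ---------------------------------------------------------------------------
# File-driven entry (user-supplied data)

STAGE_INPUTS = {
    "rdd": ["pileup", "vcf", "gtf", "fasta"],
    "ase": ["pileup", "vcf", "gtf"],
    "expr": ["fpkm"],
    "methyl": ["methylation", "fpkm", "gtf"],
}


def check_stage_inputs(stage: str, inputs: dict[str, str | None]) -> None:
    missing = [k for k in STAGE_INPUTS.get(stage, []) if not inputs.get(k)]
    if missing:
        raise ConfigurationError(
            f"stage {stage!r} requires inputs: {', '.join(missing)}"
        )


# ---------------------------------------------------------------------------
# Report rendering


def _matrix_md(mat: dict) -> str:
    bases = list("ACGT")
    lines = ["| ref\\obs | " + " | ".join(bases) + " |",
             "|---" * 5 + "|"]
    for r in bases:
        row = [str(mat.get(c, {}).get(r, 0)) for c in bases]
        lines.append(f"| {r} | " + " | ".join(row) + " |")
    return "\n".join(lines)


def render_report(manifest: RunManifest) -> str:
    """Human-readable Markdown summary of a run."""
    out = [f"# omicloom run report", "",
           f"seed: {manifest.seed}", ""]
    all_stages = ["synth", "exprmodel", "rdd", "ase", "protdb", "methylcorr"]
    for stage in all_stages:
        out.append(f"## {stage}")
        if stage in manifest.errors:
            out.append(f"FAILED: {manifest.errors[stage]}")
            out.append("")
            continue
        block = manifest.stages.get(stage)
        if block is None:
            out.append("not run")
            out.append("")
            continue
        if stage == "rdd":
            out.append(
                f"filter waterfall: {block['n_candidates']} candidates -> "
                f"{block['n_genomic_variant']} genomic variants, "
                f"{block['n_alignment_artifact']} alignment artifacts, "
                f"{block['n_pass']} pass"
            )
            out.append("")
            out.append("substitution matrix (rows ref, columns observed):")
            out.append(_matrix_md(block["substitution_matrix"]))
            out.append("")
            out.append(f"region distribution of passing sites: "
                       f"{block['region_distribution']}")
            ev = block.get("evaluation")
            if ev:
                out.append(f"planted-edit recall: {ev['edit_recall']}")
        elif stage == "exprmodel":
            out.append(
                f"expression cutoff: {block['cutoff_fpkm']:.3f} FPKM "
                f"(bimodal: {block['bimodal']}); "
                f"{block['n_transcripts_expressed']} transcripts expressed"
            )
        elif stage == "ase":
            out.append(
                f"genes: {block['n_genes']} with het sites; "
                f"{block['monoallelic']} monoallelic, "
                f"{block['allele_specific']} allele-specific, "
                f"{block['biallelic']} biallelic"
            )
        elif stage == "protdb":
            out.append(
                "database entries: "
                + ", ".join(f"{k[2:]}={v}" for k, v in sorted(block.items()))
            )
        elif stage == "methylcorr":
            out.append(f"beta fractions: {block['beta_fractions']}")
            out.append(f"informer sites selected: {block['n_informer_sites']}")
        else:
            out.append(json.dumps(block, sort_keys=True))
        out.append("")
    return "\n".join(out)
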