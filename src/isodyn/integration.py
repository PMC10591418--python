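"""Set-logic integration, over-representation analysis and wet-lab formulas.

This module combines the upstream results the way the study design intends:
breed-specific axis contributors are intersected with the stage-wise
upregulated DET set, optionally reduced to genes annotated to
muscle-development-like terms, and finally crossed with the switch-event
genes in a three-set Venn whose triple intersection is the headline
candidate list.  It also provides generic hypergeometric gene-set
over-representation with BH correction, the relative-protein-content
formula for the cell assays, the 2^-ddCT relative-expression formula, and
the end-to-end pipeline driver.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .core import (POSTHATCH_STAGES, SampleMetadata, TranscriptAnnotation,
                   ValidationError, average_replicates, compute_fpkm,
                   filter_expressed, read_gtf, read_matrix, ExpressionMatrix)
from .devaxis import (axis_curve, breed_specific_contributors, decompose,
                      top_contributors, variance_report)
from .diffexpr import det_per_stage
from .dominance import call_dominant_all, classify_switches, within_breed_switches
from .timecourse import TimecourseModel, build_design

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Candidate sets
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Transcripts surviving an integration step, with provenance."""

    transcripts: set[str]
    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    stage_tag: str = ""


def intersect_axis_det(specific: set[str], det_up,
                       ann: TranscriptAnnotation,
                       stage_tag: str = "post-hatching") -> CandidateSet:
    """Transcripts that are both breed-specific axis contributors and
    upregulated DET; genes resolved through the annotation."""
    if isinstance(det_up, pd.DataFrame):
        det_ids = set(det_up["transcript_id"])
    else:
        det_ids = set(det_up)
    transcripts = set(specific) & det_ids
    genes = ann.genes_for(transcripts) if transcripts else set()
    provenance = {t: {"axis-specific", "det-up"} for t in transcripts}
    return CandidateSet(transcripts, genes, provenance, stage_tag)


def filter_by_terms(candidates: CandidateSet, term_map: pd.DataFrame | dict,
                    keep_terms, ann: TranscriptAnnotation) -> CandidateSet:
    """Keep only candidate genes annotated to at least one ``keep_term``.

    Genes absent from the term map count as unannotated and are dropped
    (logged).  Transcripts of dropped genes are removed.
    """
    if isinstance(term_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for r in term_map.itertuples():
            mapping.setdefault(r.gene_id, set()).add(r.term)
    else:
        mapping = {g: set(ts) for g, ts in term_map.items()}
    keep_terms = set(keep_terms)
    kept_genes = {g for g in candidates.genes if mapping.get(g, set()) & keep_terms}
    unannotated = [g for g in candidates.genes if g not in mapping]
    if unannotated:
        logger.info("%d candidate genes unannotated in term map; dropped",
                    len(unannotated))
    gene_of = ann.gene_of
    transcripts = {t for t in candidates.transcripts if gene_of[t] in kept_genes}
    provenance = {t: candidates.provenance.get(t, set()) | {"term-filter"}
                  for t in transcripts}
    return CandidateSet(transcripts, kept_genes, provenance, candidates.stage_tag)


def venn_integration(det_genes: set[str], switch_genes: set[str],
                     candidate_genes: set[str]) -> tuple[dict[str, int], set[str]]:
    """Exact three-set region sizes plus the triple intersection."""
    a, b, c = set(det_genes), set(switch_genes), set(candidate_genes)
    regions = {
        "det_only": len(a - b - c),
        "switch_only": len(b - a - c),
        "candidate_only": len(c - a - b),
        "det_switch": len((a & b) - c),
        "det_candidate": len((a & c) - b),
        "switch_candidate": len((b & c) - a),
        "triple": len(a & b & c),
    }
    return regions, a & b & c


# ---------------------------------------------------------------------------
# Over-representation
# ---------------------------------------------------------------------------

def hypergeometric_enrichment(query: set[str], universe: set[str],
                              term_map: pd.DataFrame | dict) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per term, BH-adjusted.

    ``p = P(X >= overlap)`` drawing ``|query|`` genes from ``|universe|``
    with the term's genes as successes.  The query must be a subset of the
    universe.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        raise ValidationError("query gene set must be a subset of the universe")
    if isinstance(term_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for r in term_map.itertuples():
            mapping.setdefault(r.term, set()).add(r.gene_id)
    else:
        mapping = {t: set(gs) for t, gs in term_map.items()}
    m_pop, n_query = len(universe), len(query)
    rows = []
    for term in sorted(mapping):
        members = mapping[term] & universe
        overlap = sorted(members & query)
        k = len(overlap)
        p = 1.0 if len(members) == 0 else float(
            stats.hypergeom.sf(k - 1, m_pop, len(members), n_query))
        rows.append({"term_id": term, "term_size": len(members),
                     "overlap": k, "p_value": min(p, 1.0),
                     "members": ",".join(overlap)})
    out = pd.DataFrame(rows)
    if len(out):
        from .diffexpr import bh_adjust
        out["q_value"] = np.maximum(bh_adjust(out["p_value"]), out["p_value"])
    return out


# ---------------------------------------------------------------------------
# Wet-lab formula utilities
# ---------------------------------------------------------------------------

def relative_protein_content(corrected, control_mean: float):
    """Per-well relative protein content ``2**-(corrected - control_mean)``
    and its group mean.

    ``corrected`` is the protein/DNA ratio per well; ``control_mean`` is the
    arithmetic mean of the control group's corrected values.
    """
    corrected = np.asarray(corrected, dtype=float)
    per_well = 2.0 ** (-(corrected - control_mean))
    return per_well, float(per_well.mean())


def ddct_relative_expression(ct_target: float, ct_reference: float,
                             ct_target_cal: float, ct_reference_cal: float) -> float:
    """Comparative threshold cycle: ``2**-ddCT`` with
    ``ddCT = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)``."""
    ddct = (ct_target - ct_reference) - (ct_target_cal - ct_reference_cal)
    return float(2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


DEFAULT_CONFIG = {
    "reference_breed": "LS",
    "expression_threshold": 1.0,
    "timecourse": {"alpha_fdr": 0.05, "r2_threshold": 0.6, "k": 9},
    "axis": {"n_pcs": 4, "fraction": 0.10, "center_rows": True},
    "det": {"fc_threshold": 1.0, "q_threshold": 0.05,
            "stages": list(POSTHATCH_STAGES)},
    "candidate_terms": ["muscle_development"],
}


@dataclass
class PipelineResult:
    manifest: dict
    candidate_genes: set[str]
    triple: set[str]
    out_dir: Path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config, out_dir=None) -> PipelineResult:
    """Execute normalize -> timecourse -> axis (per breed) -> det (per stage)
    -> dominance/switches -> integration, writing TSV outputs and a JSON
    manifest.  Fully deterministic for fixed inputs and parameters."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    for key in ("timecourse", "axis", "det"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(config.get(key) or {})}
    out = Path(out_dir or cfg.get("out_dir", "pipeline_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"package": "isodyn", "version": __version__,
                      "parameters": {k: v for k, v in cfg.items()
                                     if k != "inputs"},
                      "counts": {}}

    @_stage("normalize")
    def normalize():
        inputs = cfg["inputs"]
        for key in ("counts", "gtf", "meta"):
            if key not in inputs or not Path(inputs[key]).exists():
                raise FileNotFoundError(f"missing input file for {key!r}")
        ann = read_gtf(inputs["gtf"])
        meta = SampleMetadata.read_tsv(inputs["meta"])
        counts = read_matrix(inputs["counts"], "counts", ann, meta)
        fpkm = compute_fpkm(counts, ann, meta)
        fpkm.write_tsv(out / "fpkm.tsv")
        transcripts, genes = filter_expressed(fpkm, ann,
                                              cfg["expression_threshold"])
        keep = sorted(transcripts)
        fpkm_f = ExpressionMatrix(fpkm.values.loc[keep], "fpkm")
        counts_f = ExpressionMatrix(counts.values.loc[keep], "counts")
        manifest["counts"]["expressed_transcripts"] = len(transcripts)
        manifest["counts"]["expressed_genes"] = len(genes)
        return ann, meta, counts_f, fpkm_f, genes

    ann, meta, counts, fpkm, expressed_genes = normalize()
    reference = cfg["reference_breed"]
    experimental = next(b for b in meta.breeds if b != reference)

    @_stage("timecourse")
    def timecourse():
        design = build_design(meta, reference_group=reference)
        results = TimecourseModel.from_fpkm(fpkm, design).fit(
            alpha_fdr=cfg["timecourse"]["alpha_fdr"])
        step = results.stepwise(r2_threshold=cfg["timecourse"]["r2_threshold"])
        results.table.to_csv(out / "timecourse_fits.tsv", sep="\t")
        step.table.to_csv(out / "timecourse_selected.tsv", sep="\t")
        manifest["counts"]["timecourse_significant"] = int(
            results.table["significant"].sum())
        manifest["counts"]["timecourse_retained"] = len(step.retained_ids)
        k = cfg["timecourse"]["k"]
        if len(step.retained_ids) >= k:
            clusters = step.cluster_profiles(k=k)
            clusters.membership.to_csv(out / "clusters.tsv", sep="\t")
            manifest["counts"]["clusters"] = int(clusters.k)
        else:
            manifest["counts"]["clusters"] = 0
        return step

    timecourse()

    @_stage("axis")
    def axis():
        specific_sets = {}
        for breed in (experimental, reference):
            samples = meta.samples_for(breed)
            dec = decompose(fpkm, meta, samples,
                            center_rows=cfg["axis"]["center_rows"])
            n_pcs = min(cfg["axis"]["n_pcs"], dec.n_components)
            sets = [top_contributors(dec, pc, cfg["axis"]["fraction"])
                    for pc in range(1, n_pcs + 1)]
            specific_sets[breed] = sets
            dec.feature_vectors.iloc[:, :n_pcs].to_csv(
                out / f"axis_loadings_{breed}.tsv", sep="\t")
            curves = pd.concat([axis_curve(dec, meta, pc).to_frame()
                                .assign(pc_index=pc)
                                for pc in range(1, n_pcs + 1)])
            curves.to_csv(out / f"axis_curves_{breed}.tsv", sep="\t",
                          index=False)
            manifest["counts"][f"variance_top{n_pcs}_{breed}"] = round(
                variance_report(dec, n_pcs), 6)
        specific = breed_specific_contributors(
            specific_sets[experimental], specific_sets[reference])
        pd.DataFrame({"transcript_id": sorted(specific)}).to_csv(
            out / "axis_specific_transcripts.tsv", sep="\t", index=False)
        manifest["counts"]["axis_specific_transcripts"] = len(specific)
        return specific

    specific = axis()

    @_stage("det")
    def det():
        table = det_per_stage(counts, meta, stages=cfg["det"]["stages"],
                              reference=reference,
                              fc_threshold=cfg["det"]["fc_threshold"],
                              q_threshold=cfg["det"]["q_threshold"])
        table.to_csv(out / "det.tsv", sep="\t", index=False)
        up = table[table["direction"] == "up"]
        manifest["counts"]["det_up"] = int(len(up))
        manifest["counts"]["det_down"] = int(
            (table["direction"] == "down").sum())
        return up

    det_up = det()

    @_stage("dominance")
    def dominance():
        calls = call_dominant_all(fpkm, counts, ann, meta)
        calls.to_csv(out / "dominance.tsv", sep="\t", index=False)
        events = []
        for breed in meta.breeds:
            events.append(within_breed_switches(
                calls[calls["breed"] == breed], breed,
                stages=list(meta.stages)))
        calls_a = calls[calls["breed"] == experimental]
        calls_b = calls[calls["breed"] == reference]
        cross = classify_switches(calls_a, calls_b)
        cross.insert(2, "breed", "")
        switches = pd.concat(events + [cross], ignore_index=True)
        switches.to_csv(out / "switches.tsv", sep="\t", index=False)
        manifest["counts"]["class_I_genes"] = int(
            (cross["switch_class"] == "I").sum())
        manifest["counts"]["class_II_genes"] = int(
            (cross["switch_class"] == "II").sum())
        manifest["counts"]["within_breed_genes"] = int(
            sum(len(e) for e in events))
        return set(cross["gene_id"])

    switch_genes = dominance()

    @_stage("integration")
    def integrate():
        cand = intersect_axis_det(specific, det_up, ann)
        go_path = cfg["inputs"].get("go_map")
        if go_path and cfg.get("candidate_terms"):
            term_map = pd.read_csv(go_path, sep="\t")
            cand = filter_by_terms(cand, term_map, cfg["candidate_terms"], ann)
            universe = expressed_genes
            enrich = hypergeometric_enrichment(
                cand.genes & universe, universe, term_map)
            enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        det_genes = ann.genes_for(set(det_up["transcript_id"])) \
            if len(det_up) else set()
        regions, triple = venn_integration(det_genes, switch_genes, cand.genes)
        pd.DataFrame({"gene_id": sorted(cand.genes)}).to_csv(
            out / "candidate_genes.tsv", sep="\t", index=False)
        pd.DataFrame({"gene_id": sorted(triple)}).to_csv(
            out / "triple_intersection.tsv", sep="\t", index=False)
        (out / "venn.json").write_text(json.dumps(regions, indent=2,
                                                  sort_keys=True))
        manifest["counts"]["candidate_genes"] = len(cand.genes)
        manifest["counts"]["triple_intersection"] = len(triple)
        return cand, triple

    cand, triple = integrate()
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(manifest, cand.genes, triple, out)
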