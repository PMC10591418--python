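"""Dominant-isoform calling and switch-event classification.

Within a multi-isoform gene at one breed x stage, the candidate dominant
isoform is the one with the highest mean FPKM over the replicates.  It is
called *dominant* when either

* every sibling isoform has mean FPKM exactly 0 while the candidate is
  positive (the zero rule), or
* the candidate beats *every* sibling in a pairwise negative-binomial test
  with ``log2FC > 1`` and ``q < 0.05`` (strict), where q-values are
  Benjamini-Hochberg-adjusted across all pairwise tests in that
  breed x stage family.

The pairwise test runs on counts with ``log(library_size x length)``
offsets, so the tested fold change is on the FPKM scale and agrees with the
candidate selection.  At most one isoform per (gene, breed, stage) can be
dominant; single-isoform genes are never called.

Cross-breed switch events:

* class I  — the breeds' defined dominant isoforms disagree at the same
  stage;
* class II — no same-stage disagreement exists, but defined dominants
  disagree across two different stages (class I takes precedence; the two
  classes are mutually exclusive per gene);
* within-breed — one breed has two or more distinct defined dominants
  across the stages.

Undefined calls (no dominant) never count as disagreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (ExpressionMatrix, SampleMetadata, TranscriptAnnotation,
                   ValidationError)
from .diffexpr import DispersionEstimate, bh_adjust, estimate_dispersion, nb_lrt


def call_dominant(fpkm: ExpressionMatrix, counts: ExpressionMatrix,
                  ann: TranscriptAnnotation, meta: SampleMetadata,
                  breed: str, stage: str,
                  dispersion: DispersionEstimate | float | None = None,
                  fc_threshold: float = 1.0,
                  q_threshold: float = 0.05,
                  zero_rule_min_fpkm: float = 1.0) -> pd.DataFrame:
    """Dominance verdict for every multi-isoform gene at one breed x stage.

    Returns one row per gene: ``dominant_transcript`` (empty when none),
    ``basis`` in {``pairwise-test``, ``zero-rule``, ``none``}, and the
    candidate's weakest pairwise statistics (``min_log2fc``, ``max_q``).

    The zero rule only fires when the candidate itself is expressed
    (``mean FPKM >= zero_rule_min_fpkm``); without this floor, a single
    stray read in an otherwise silent gene would be declared dominant.
    """
    fpkm.require_layer("fpkm")
    counts.require_layer("counts")
    samples = list(meta.samples_for(breed, stage))
    if len(samples) < 2:
        raise ValidationError(f"need >= 2 replicates at ({breed}, {stage})")
    fpkm.validate_against(ann=ann)
    counts.validate_against(ann=ann)

    libs = meta.library_sizes[samples].to_numpy(dtype=float)
    lengths = ann.lengths
    mean_fpkm = fpkm.values[samples].mean(axis=1)

    if dispersion is None:
        sub = ExpressionMatrix(counts.values[samples], "counts")
        dispersion = estimate_dispersion(
            sub, pd.Series(breed, index=samples), meta.library_sizes[samples])
    if isinstance(dispersion, DispersionEstimate):
        phi_of = dispersion.phi
    else:
        phi_of = pd.Series(float(dispersion), index=counts.transcript_ids)

    # Dominance is assessed over the *quantified* isoforms: transcripts not
    # present in the expression matrix (e.g. removed by the expression
    # filter) do not take part, and genes with < 2 quantified isoforms are
    # not multi-isoform here.
    quantified = set(fpkm.transcript_ids)
    tx_of = {g: [t for t in ts if t in quantified]
             for g, ts in ann.transcripts_of_gene().items()}
    genes = sorted(g for g, ts in tx_of.items() if len(ts) >= 2)

    # First pass: candidate per gene, zero-rule shortcuts, pairwise batch.
    rows = []
    pair_meta: list[tuple[str, str, str]] = []   # (gene, candidate, sibling)
    y_a, y_b, off_a, off_b, phis = [], [], [], [], []
    for gid in genes:
        tids = sorted(tx_of[gid])
        means = mean_fpkm[tids]
        top = means.max()
        if top <= 0:
            rows.append({"gene_id": gid, "breed": breed, "stage": stage,
                         "dominant_transcript": "", "basis": "none",
                         "min_log2fc": np.nan, "max_q": np.nan})
            continue
        cand = means[means == top].index.min()  # lexicographic tie-break
        siblings = [t for t in tids if t != cand]
        if all(means[t] == 0.0 for t in siblings):
            if top >= zero_rule_min_fpkm:
                rows.append({"gene_id": gid, "breed": breed, "stage": stage,
                             "dominant_transcript": cand, "basis": "zero-rule",
                             "min_log2fc": np.inf, "max_q": 0.0})
            else:
                rows.append({"gene_id": gid, "breed": breed, "stage": stage,
                             "dominant_transcript": "", "basis": "none",
                             "min_log2fc": np.nan, "max_q": np.nan})
            continue
        for sib in siblings:
            pair_meta.append((gid, cand, sib))
            y_a.append(counts.values.loc[cand, samples].to_numpy(dtype=float))
            y_b.append(counts.values.loc[sib, samples].to_numpy(dtype=float))
            off_a.append(np.log(libs / 1e6 * lengths[cand] / 1e3))
            off_b.append(np.log(libs / 1e6 * lengths[sib] / 1e3))
            phis.append(0.5 * (phi_of.get(cand, 0.0) + phi_of.get(sib, 0.0)))
        rows.append({"gene_id": gid, "breed": breed, "stage": stage,
                     "dominant_transcript": cand, "basis": "pending",
                     "min_log2fc": np.nan, "max_q": np.nan})

    if pair_meta:
        res = nb_lrt(np.vstack(y_a), np.vstack(y_b),
                     np.vstack(off_a), np.vstack(off_b), np.array(phis))
        res["q_value"] = bh_adjust(res["p_value"])
        res["gene_id"] = [p[0] for p in pair_meta]
        verdict = {}
        for gid, sub in res.groupby("gene_id"):
            ok = ((sub["log2fc"] > fc_threshold)
                  & (sub["q_value"] < q_threshold)).all()
            verdict[gid] = (bool(ok), float(sub["log2fc"].min()),
                            float(sub["q_value"].max()))
        for row in rows:
            if row["basis"] != "pending":
                continue
            ok, min_lfc, max_q = verdict[row["gene_id"]]
            row["min_log2fc"], row["max_q"] = min_lfc, max_q
            if ok:
                row["basis"] = "pairwise-test"
            else:
                row["basis"] = "none"
                row["dominant_transcript"] = ""
    return pd.DataFrame(rows, columns=["gene_id", "breed", "stage",
                                       "dominant_transcript", "basis",
                                       "min_log2fc", "max_q"])


def call_dominant_all(fpkm: ExpressionMatrix, counts: ExpressionMatrix,
                      ann: TranscriptAnnotation, meta: SampleMetadata,
                      dispersion: DispersionEstimate | float | None = None,
                      fc_threshold: float = 1.0,
                      q_threshold: float = 0.05,
                      zero_rule_min_fpkm: float = 1.0) -> pd.DataFrame:
    """Dominance calls over every observed breed x stage cell."""
    frames = []
    for breed in meta.breeds:
        for stage in meta.stages:
            if len(meta.samples_for(breed, stage)) == 0:
                continue
            frames.append(call_dominant(fpkm, counts, ann, meta, breed, stage,
                                        dispersion, fc_threshold, q_threshold,
                                        zero_rule_min_fpkm))
    return pd.concat(frames, ignore_index=True)


def call_dominant_per_sample(fpkm: ExpressionMatrix, ann: TranscriptAnnotation,
                             sample_id: str, fold: float = 2.0) -> pd.DataFrame:
    """Optional single-sample mode: dominance = highest FPKM exceeding every
    sibling by more than ``fold`` (no statistical test)."""
    fpkm.require_layer("fpkm")
    values = fpkm.values[sample_id]
    tx_of = ann.transcripts_of_gene()
    rows = []
    for gid in ann.multi_isoform_genes():
        tids = sorted(tx_of[gid])
        v = values[tids]
        top = v.max()
        cand = v[v == top].index.min()
        siblings = v.drop(cand)
        if top > 0 and (top > fold * siblings).all():
            rows.append({"gene_id": gid, "sample_id": sample_id,
                         "dominant_transcript": cand})
        else:
            rows.append({"gene_id": gid, "sample_id": sample_id,
                         "dominant_transcript": ""})
    return pd.DataFrame(rows)


def _dominance_lookup(calls: pd.DataFrame) -> dict[tuple[str, str, str], str]:
    lookup = {}
    for r in calls.itertuples():
        if r.dominant_transcript:
            lookup[(r.gene_id, r.breed, r.stage)] = r.dominant_transcript
    return lookup


def within_breed_switches(calls: pd.DataFrame, breed: str,
                          stages=None) -> pd.DataFrame:
    """Genes whose defined dominant isoform changes across stages in one breed.

    Stages with no call are skipped, never treated as disagreement; a gene
    with a single defined dominant emits nothing.
    """
    sub = calls[(calls["breed"] == breed) & (calls["dominant_transcript"] != "")]
    if stages is None:
        stages = list(dict.fromkeys(calls["stage"]))
    rows = []
    for gid, grp in sub.groupby("gene_id"):
        by_stage = dict(zip(grp["stage"], grp["dominant_transcript"]))
        ordered = [(s, by_stage[s]) for s in stages if s in by_stage]
        distinct = {t for _, t in ordered}
        if len(distinct) >= 2:
            rows.append({
                "gene_id": gid, "switch_class": "within-breed", "breed": breed,
                "stages": ",".join(s for s, _ in ordered),
                "transcripts": ",".join(sorted(distinct)),
            })
    return pd.DataFrame(rows, columns=["gene_id", "switch_class", "breed",
                                       "stages", "transcripts"])


def classify_switches(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-breed switch classification; class I takes precedence.

    ``calls_a`` and ``calls_b`` are the two breeds' dominance calls on the
    same stage grid.  Per gene: class I when any same-stage defined pair
    disagrees; otherwise class II when any cross-stage defined pair
    disagrees; identical dominance everywhere emits nothing.
    """
    stages_a = list(dict.fromkeys(calls_a["stage"]))
    stages_b = list(dict.fromkeys(calls_b["stage"]))
    if stages_a != stages_b:
        raise ValidationError("the two breeds were called on different stage grids")
    stages = stages_a
    dom_a = _dominance_lookup(calls_a)
    dom_b = _dominance_lookup(calls_b)
    breed_a = calls_a["breed"].iloc[0] if len(calls_a) else "A"
    breed_b = calls_b["breed"].iloc[0] if len(calls_b) else "B"
    genes = sorted(set(calls_a["gene_id"]) | set(calls_b["gene_id"]))
    rows = []
    for gid in genes:
        a = {s: dom_a.get((gid, breed_a, s)) for s in stages}
        b = {s: dom_b.get((gid, breed_b, s)) for s in stages}
        same = [s for s in stages
                if a[s] is not None and b[s] is not None and a[s] != b[s]]
        if same:
            involved = sorted({a[s] for s in same} | {b[s] for s in same})
            rows.append({"gene_id": gid, "switch_class": "I",
                         "stages": ",".join(same),
                         "transcripts": ",".join(involved)})
            continue
        cross = [(s1, s2) for s1 in stages for s2 in stages
                 if a[s1] is not None and b[s2] is not None and a[s1] != b[s2]]
        if cross:
            involved = sorted({a[s1] for s1, _ in cross}
                              | {b[s2] for _, s2 in cross})
            stages_txt = ";".join(f"{s1}|{s2}" for s1, s2 in cross[:3])
            rows.append({"gene_id": gid, "switch_class": "II",
                         "stages": stages_txt,
                         "transcripts": ",".join(involved)})
    return pd.DataFrame(rows, columns=["gene_id", "switch_class", "stages",
                                       "transcripts"])
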