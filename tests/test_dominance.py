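"""Dominant-isoform calling and switch classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from isodyn.core import (ExpressionMatrix, TranscriptAnnotation,
                         ValidationError, compute_fpkm)
from isodyn.dominance import (call_dominant, call_dominant_all,
                              classify_switches, within_breed_switches)
from isodyn.simulate import SimulationConfig, simulate_dataset
from conftest import make_metadata

LIB = 1_000_000  # unit library: FPKM == counts/length_kb


def _annotation(iso_per_gene, length=1000):
    rows, exons = [], {}
    for g, m in enumerate(iso_per_gene):
        for j in range(m):
            tid = f"G{g:03d}.T{j + 1}"
            rows.append((tid, f"G{g:03d}", length))
            exons[tid] = [(1, length)]
    frame = pd.DataFrame(rows, columns=["transcript_id", "gene_id",
                                        "length_bp"]).set_index("transcript_id")
    return TranscriptAnnotation(frame, exons)


def _dataset(iso_per_gene, counts_rows, n_replicates=3):
    """counts_rows: per transcript, identical across replicates unless a
    tuple of per-replicate values is given."""
    meta = make_metadata(breeds=("AA",), stages=("E10",),
                         n_replicates=n_replicates, library_size=LIB)
    ann = _annotation(iso_per_gene)
    data = []
    for v in counts_rows:
        row = list(v) if isinstance(v, (tuple, list)) else [v] * n_replicates
        data.append(row)
    counts = ExpressionMatrix(
        pd.DataFrame(np.asarray(data, dtype=float),
                     index=ann.transcript_ids, columns=meta.sample_ids),
        "counts")
    fpkm = compute_fpkm(counts, ann, meta)
    return fpkm, counts, ann, meta


class TestCallDominant:
    def test_zero_rule(self):
        fpkm, counts, ann, meta = _dataset([3], [10000, 0, 0])
        calls = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                              dispersion=0.05)
        row = calls.iloc[0]
        assert row["dominant_transcript"] == "G000.T1"
        assert row["basis"] == "zero-rule"

    def test_zero_rule_needs_real_expression(self):
        # a single stray read must not be declared dominant
        fpkm, counts, ann, meta = _dataset([2], [(1, 0, 0), 0])
        calls = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                              dispersion=0.05)
        assert calls.iloc[0]["basis"] == "none"
        assert calls.iloc[0]["dominant_transcript"] == ""

    def test_clear_fourfold_separation_is_dominant(self):
        fpkm, counts, ann, meta = _dataset([2], [8000, 2000])
        calls = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                              dispersion=0.01)
        row = calls.iloc[0]
        assert row["dominant_transcript"] == "G000.T1"
        assert row["basis"] == "pairwise-test"
        assert row["min_log2fc"] == pytest.approx(2.0, abs=0.01)

    def test_small_fold_change_not_dominant(self):
        # log2(8/5) ~ 0.678 < 1, however significant the difference
        fpkm, counts, ann, meta = _dataset([2], [80000, 50000])
        calls = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                              dispersion=0.001)
        assert calls.iloc[0]["basis"] == "none"
        assert calls.iloc[0]["dominant_transcript"] == ""

    def test_single_isoform_genes_never_called(self):
        fpkm, counts, ann, meta = _dataset([1, 2], [5000, 4000, 100])
        calls = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                              dispersion=0.05)
        assert set(calls["gene_id"]) == {"G001"}

    def test_uniqueness_and_strictly_greatest_mean(self):
        ds = simulate_dataset(SimulationConfig(seed=30, n_genes=80,
                                               n_classI=3, n_classII=3,
                                               n_within_breed_switches=2,
                                               n_candidates=1))
        fpkm = compute_fpkm(ds.counts, ds.annotation, ds.metadata)
        calls = call_dominant(fpkm, ds.counts, ds.annotation, ds.metadata,
                              "AA", "W1")
        assert calls["gene_id"].is_unique
        samples = list(ds.metadata.samples_for("AA", "W1"))
        means = fpkm.values[samples].mean(axis=1)
        for r in calls.itertuples():
            if r.dominant_transcript:
                sibs = [t for t in
                        ds.annotation.transcripts_of_gene()[r.gene_id]
                        if t != r.dominant_transcript]
                assert (means[r.dominant_transcript] > means[sibs]).all()

    def test_isoform_order_permutation_invariant(self):
        fpkm, counts, ann, meta = _dataset([3, 2], [9000, 1000, 500,
                                                    300, 7000])
        base = call_dominant(fpkm, counts, ann, meta, "AA", "E10",
                             dispersion=0.05)
        perm = list(fpkm.transcript_ids)[::-1]
        fpkm2 = ExpressionMatrix(fpkm.values.loc[perm], "fpkm")
        counts2 = ExpressionMatrix(counts.values.loc[perm], "counts")
        again = call_dominant(fpkm2, counts2, ann, meta, "AA", "E10",
                              dispersion=0.05)
        pd.testing.assert_frame_equal(base, again)

    def test_fold_threshold_monotone(self):
        ds = simulate_dataset(SimulationConfig(seed=31, n_genes=60,
                                               n_classI=3, n_classII=3,
                                               n_within_breed_switches=2,
                                               n_candidates=1))
        fpkm = compute_fpkm(ds.counts, ds.annotation, ds.metadata)
        loose = call_dominant(fpkm, ds.counts, ds.annotation, ds.metadata,
                              "AA", "D1", fc_threshold=1.0)
        strict = call_dominant(fpkm, ds.counts, ds.annotation, ds.metadata,
                               "AA", "D1", fc_threshold=2.0)
        dom = lambda c: {(r.gene_id, r.dominant_transcript)
                         for r in c.itertuples() if r.dominant_transcript}
        assert dom(strict) <= dom(loose)


# ---------------------------------------------------------------------------
# Independent brute-force oracle (scalar likelihood optimization + own BH)
# ---------------------------------------------------------------------------

def _oracle_nb_fit(y, offs, phi):
    def nll(beta):
        mu = np.exp(beta + offs)
        if phi > 0:
            r = 1.0 / phi
            return -(special.xlogy(y, mu) - (y + r) * np.log1p(phi * mu)).sum()
        return -(special.xlogy(y, mu) - mu).sum()
    res = optimize.minimize_scalar(nll, bounds=(-30, 30), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x, -nll(res.x)


def _oracle_pair_test(ya, yb, offa, offb, phi):
    ba, la = _oracle_nb_fit(ya, offa, phi)
    bb, lb = _oracle_nb_fit(yb, offb, phi)
    _, l0 = _oracle_nb_fit(np.concatenate([ya, yb]),
                           np.concatenate([offa, offb]), phi)
    lrt = max(0.0, 2.0 * (la + lb - l0))
    return (ba - bb) / np.log(2.0), stats.chi2.sf(lrt, 1)


def _oracle_calls(fpkm, counts, ann, meta, breed, stage, phi,
                  zero_rule_min_fpkm=1.0):
    samples = list(meta.samples_for(breed, stage))
    libs = meta.library_sizes[samples].to_numpy(float)
    means = fpkm.values[samples].mean(axis=1)
    pairs, rows = [], {}
    for gid in ann.multi_isoform_genes():
        tids = sorted(ann.transcripts_of_gene()[gid])
        sub = means[tids].sort_values(kind="stable")
        top = sub.max()
        if top <= 0:
            rows[gid] = ("", "none")
            continue
        cand = min(t for t in tids if means[t] == top)
        sibs = [t for t in tids if t != cand]
        if all(means[s] == 0 for s in sibs):
            rows[gid] = (cand, "zero-rule") if top >= zero_rule_min_fpkm \
                else ("", "none")
            continue
        for s in sibs:
            lfc, p = _oracle_pair_test(
                counts.values.loc[cand, samples].to_numpy(float),
                counts.values.loc[s, samples].to_numpy(float),
                np.log(libs / 1e6 * ann.lengths[cand] / 1e3),
                np.log(libs / 1e6 * ann.lengths[s] / 1e3), phi)
            pairs.append((gid, lfc, p))
        rows[gid] = (cand, "pending")
    if pairs:
        from test_diffexpr import bh_oracle
        qs = bh_oracle([p for _, _, p in pairs])
        verdict = {}
        for (gid, lfc, _), q in zip(pairs, qs):
            ok, lo = verdict.get(gid, (True, np.inf))
            verdict[gid] = (ok and lfc > 1.0 and q < 0.05, min(lo, lfc))
        for gid, (cand, basis) in rows.items():
            if basis == "pending":
                rows[gid] = (cand, "pairwise-test") if verdict[gid][0] \
                    else ("", "none")
    return rows


def test_calls_match_exhaustive_pairwise_oracle():
    """A 20-gene fixture including zero-rule and single-isoform genes."""
    ds = simulate_dataset(SimulationConfig(
        seed=33, n_genes=20, n_classI=2, n_classII=2,
        n_within_breed_switches=1, n_candidates=1))
    fpkm = compute_fpkm(ds.counts, ds.annotation, ds.metadata)
    phi = 0.05
    calls = call_dominant(fpkm, ds.counts, ds.annotation, ds.metadata,
                          "AA", "W3", dispersion=phi)
    oracle = _oracle_calls(fpkm, ds.counts, ds.annotation, ds.metadata,
                           "AA", "W3", phi)
    assert len(calls) == len(oracle)
    for r in calls.itertuples():
        o_tid, o_basis = oracle[r.gene_id]
        assert (r.dominant_transcript, r.basis) == (o_tid, o_basis), r.gene_id


# ---------------------------------------------------------------------------
# Switch classification
# ---------------------------------------------------------------------------

def _calls(breed, mapping):
    """mapping: stage -> dominant transcript ('' = undefined)."""
    return pd.DataFrame([
        {"gene_id": "G", "breed": breed, "stage": s,
         "dominant_transcript": t, "basis": "pairwise-test",
         "min_log2fc": 2.0, "max_q": 0.01}
        for s, t in mapping.items()])


STAGES7 = ("E10", "E14", "E18", "D1", "W1", "W3", "W5")


class TestWithinBreedSwitches:
    def test_change_of_dominant_is_an_event(self):
        calls = _calls("LS", {"D1": "T1", "W1": "T2"})
        events = within_breed_switches(calls, "LS", stages=["D1", "W1"])
        assert len(events) == 1
        assert events.iloc[0]["transcripts"] == "T1,T2"

    def test_constant_dominant_is_no_event(self):
        calls = _calls("LS", {s: "T1" for s in STAGES7})
        assert within_breed_switches(calls, "LS", stages=list(STAGES7)).empty

    def test_single_defined_stage_is_no_event(self):
        calls = _calls("LS", dict.fromkeys(STAGES7, ""))
        calls.loc[calls["stage"] == "W1", "dominant_transcript"] = "T1"
        assert within_breed_switches(calls, "LS", stages=list(STAGES7)).empty


class TestClassifySwitches:
    def test_same_stage_disagreement_is_class_one(self):
        a = _calls("AA", {**dict.fromkeys(STAGES7, "X1"), "W1": "X2"})
        b = _calls("LS", dict.fromkeys(STAGES7, "X1"))
        events = classify_switches(a, b)
        assert list(events["switch_class"]) == ["I"]
        assert "W1" in events.iloc[0]["stages"]

    def test_identical_dominance_no_event(self):
        a = _calls("AA", dict.fromkeys(STAGES7, "T1"))
        b = _calls("LS", dict.fromkeys(STAGES7, "T1"))
        assert classify_switches(a, b).empty

    def test_shared_timing_change_is_class_two(self):
        pattern = {s: ("T1" if i < 3 else "T2")
                   for i, s in enumerate(STAGES7)}
        a, b = _calls("AA", pattern), _calls("LS", pattern)
        events = classify_switches(a, b)
        assert list(events["switch_class"]) == ["II"]
        # ... and both breeds have within-breed events
        assert len(within_breed_switches(a, "AA", stages=list(STAGES7))) == 1
        assert len(within_breed_switches(b, "LS", stages=list(STAGES7))) == 1

    def test_undefined_calls_do_not_create_class_one(self):
        # A undefined at W1, so B's W1 switch cannot be a same-stage clash;
        # the disagreement only survives as cross-stage (class II)
        a = _calls("AA", {**dict.fromkeys(STAGES7, "T1"), "W1": ""})
        b = _calls("LS", {**dict.fromkeys(STAGES7, "T1"), "W1": "T2"})
        events = classify_switches(a, b)
        assert list(events["switch_class"]) == ["II"]
        a_blank = _calls("AA", dict.fromkeys(STAGES7, ""))
        assert classify_switches(a_blank, b).empty

    def test_mismatched_stage_grids_rejected(self):
        a = _calls("AA", dict.fromkeys(STAGES7, "T1"))
        b = _calls("LS", dict.fromkeys(STAGES7[:5], "T1"))
        with pytest.raises(ValidationError, match="stage grids"):
            classify_switches(a, b)
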