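"""Seeded generator of two-breed, seven-stage transcript count data.

The generator emulates the study design the package targets: 2 breeds
(fast-growing ``AA``, slow-growing ``LS``) x 7 developmental stages (E10,
E14, E18, D1, W1, W3, W5) x 3 biological replicates of transcript-level
quantifications over multi-isoform genes, with:

* gene-level expected FPKM following ``exp(b0 + b1*tau + b2*tau**2)`` over
  scaled developmental time ``tau`` (the quadratic trajectory family the
  time-course model assumes);
* negative-binomial count noise (``variance = mu + phi*mu**2``), expected
  count = isoform usage x gene FPKM x length/1e3 x library/1e6;
* planted breed x stage differential expression (default 4-fold);
* planted dominant isoforms (one isoform carries a fixed heavy usage share,
  default 0.85) and planted switch events:

  - class I: the two breeds disagree on the dominant isoform at the same
    stage (one breed's heavy isoform changes at a switch stage, the other's
    does not);
  - class II: both breeds share an identical dominance pattern that changes
    at one stage, so dominants disagree across stages but never at the same
    stage;
  - within-breed only: one breed switches its heavy isoform while the other
    breed's usage is balanced (no dominant anywhere), so no cross-breed
    event arises;

* a small set of planted "candidate" genes drawn from the class I pool that
  are additionally upregulated in AA at the post-hatching stages, carry a
  strong AA-specific trajectory (so they load on AA's leading axes but not
  LS's), and are annotated to a synthetic muscle-development term in the
  emitted gene->term map.

Machine-readable truth tables record every planted effect; cross-breed and
within-breed switch truth is *derived* from the planted dominance pattern by
directly applying the operational class definitions, so recovery tests
compare like with like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (STAGES, STAGE_DAYS, POSTHATCH_STAGES, ExpressionMatrix,
                   SampleMetadata, TranscriptAnnotation, ValidationError, write_gtf)

MUSCLE_TERM = "muscle_development"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    n_genes: int = 500
    #: probability of a gene having 1..4 isoforms
    isoform_count_probs: tuple[float, ...] = (0.35, 0.35, 0.20, 0.10)
    n_replicates: int = 3
    stages: tuple[str, ...] = STAGES
    breeds: tuple[str, str] = ("AA", "LS")
    seed: int = 0
    #: natural-log gene FPKM baseline
    baseline_log_mean: float = 3.0
    baseline_log_sd: float = 1.0
    #: SD of the linear / quadratic trajectory coefficients on scaled time
    trajectory_beta_sd: tuple[float, float] = (2.0, 2.0)
    breed_effect_log2fc: float = 2.0
    det_fraction: float = 0.10
    dominance_proportion: float = 0.85
    #: fraction of non-switch multi-isoform genes given a stable planted dominant
    planted_dominance_fraction: float = 0.6
    n_classI: int = 15
    n_classII: int = 15
    n_within_breed_switches: int = 10
    n_candidates: int = 6
    dispersion: float = 0.05
    library_size_mean: int = 20_000_000
    min_length: int = 800
    max_length: int = 2000

    def __post_init__(self) -> None:
        if abs(sum(self.isoform_count_probs) - 1.0) > 1e-9:
            raise ValidationError("isoform_count_probs must sum to 1")
        if not (0.5 < self.dominance_proportion < 1.0):
            raise ValidationError("dominance_proportion must lie in (0.5, 1)")
        if self.n_candidates > self.n_classI:
            raise ValidationError("n_candidates must not exceed n_classI")


@dataclass
class TruthTables:
    """Planted ground truth of one simulated dataset."""

    det: pd.DataFrame          # transcript_id, stage, direction (up = higher in AA)
    dominance: pd.DataFrame    # gene_id, breed, stage, dominant_transcript
    switches: pd.DataFrame     # gene_id, switch_class, breed (within-breed only)
    candidates: set[str]       # planted candidate gene ids
    go_map: pd.DataFrame       # gene_id, term

    def dominance_map(self) -> dict[tuple[str, str, str], str]:
        return {(r.gene_id, r.breed, r.stage): r.dominant_transcript
                for r in self.dominance.itertuples()}

    def switch_genes(self, switch_class: str) -> set[str]:
        sub = self.switches[self.switches["switch_class"] == switch_class]
        return set(sub["gene_id"])


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: TranscriptAnnotation
    metadata: SampleMetadata
    counts: ExpressionMatrix
    truth: TruthTables
    #: expected (noise-free) FPKM per transcript x (breed, stage)
    expected_fpkm: pd.DataFrame = field(repr=False, default=None)


def _derive_switch_truth(dominance: pd.DataFrame, breeds, stages) -> pd.DataFrame:
    """Apply the operational switch definitions to the planted dominance map."""
    dom = {(r.gene_id, r.breed, r.stage): r.dominant_transcript
           for r in dominance.itertuples()}
    genes = sorted(dominance["gene_id"].unique())
    rows = []
    b_a, b_b = breeds
    for gene in genes:
        calls = {(b, s): dom.get((gene, b, s)) for b in breeds for s in stages}
        # within-breed: >= 2 distinct defined dominants across stages
        for b in breeds:
            defined = {calls[(b, s)] for s in stages if calls[(b, s)] is not None}
            if len(defined) >= 2:
                rows.append({"gene_id": gene, "switch_class": "within-breed",
                             "breed": b})
        same_stage = any(
            calls[(b_a, s)] is not None and calls[(b_b, s)] is not None
            and calls[(b_a, s)] != calls[(b_b, s)] for s in stages)
        cross_stage = any(
            calls[(b_a, s1)] is not None and calls[(b_b, s2)] is not None
            and calls[(b_a, s1)] != calls[(b_b, s2)]
            for s1 in stages for s2 in stages)
        if same_stage:
            rows.append({"gene_id": gene, "switch_class": "I", "breed": ""})
        elif cross_stage:
            rows.append({"gene_id": gene, "switch_class": "II", "breed": ""})
    return pd.DataFrame(rows, columns=["gene_id", "switch_class", "breed"])


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate annotation, metadata, counts and truth tables from a config.

    Identical configs (including seed) produce identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    stages = list(cfg.stages)
    n_stages = len(stages)
    tau = np.array([(STAGE_DAYS[s] - STAGE_DAYS[stages[0]])
                    / (STAGE_DAYS[stages[-1]] - STAGE_DAYS[stages[0]])
                    for s in stages])
    breed_a, breed_b = cfg.breeds  # experimental (AA), reference (LS)

    # --- gene / transcript scaffold -------------------------------------
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    iso_counts = rng.choice(np.arange(1, len(cfg.isoform_count_probs) + 1),
                            size=cfg.n_genes, p=cfg.isoform_count_probs)
    transcripts: list[tuple[str, str, int]] = []
    for gid, m in zip(gene_ids, iso_counts):
        for j in range(m):
            tid = f"{gid}.T{j + 1}"
            length = int(rng.integers(cfg.min_length, cfg.max_length + 1))
            transcripts.append((tid, gid, length))
    ann_frame = pd.DataFrame(transcripts,
                             columns=["transcript_id", "gene_id", "length_bp"]
                             ).set_index("transcript_id")
    # simple exon structures: 1-3 exons per transcript on a per-gene locus
    exons: dict[str, list[tuple[int, int]]] = {}
    offset = 1000
    for tid, gid, length in transcripts:
        n_ex = int(rng.integers(1, 4))
        cuts = np.sort(rng.choice(np.arange(1, length), size=n_ex - 1,
                                  replace=False)) if n_ex > 1 else np.array([], int)
        widths = np.diff(np.concatenate([[0], cuts, [length]]))
        ivs, pos = [], offset
        for w in widths:
            ivs.append((pos, pos + int(w) - 1))
            pos += int(w) + 500  # intron gap
        exons[tid] = ivs
        offset = pos + 5000
    annotation = TranscriptAnnotation(ann_frame, exons)

    multi = annotation.multi_isoform_genes()
    n_events = cfg.n_classI + cfg.n_classII + cfg.n_within_breed_switches
    if n_events > len(multi):
        raise ValidationError(
            f"{n_events} planted events exceed {len(multi)} multi-isoform genes")

    # --- role assignment -------------------------------------------------
    shuffled = [str(g) for g in rng.permutation(multi)]
    class_i = shuffled[:cfg.n_classI]
    class_ii = shuffled[cfg.n_classI:cfg.n_classI + cfg.n_classII]
    within = shuffled[cfg.n_classI + cfg.n_classII:n_events]
    candidates = set(class_i[:cfg.n_candidates])
    rest_multi = shuffled[n_events:]
    n_dom = int(round(cfg.planted_dominance_fraction * len(rest_multi)))
    stable_dom = rest_multi[:n_dom]
    background_multi = rest_multi[n_dom:]

    switch_roles = set(class_i) | set(class_ii) | set(within)
    det_pool = [g for g in gene_ids if g not in switch_roles and g not in candidates]
    n_det = int(round(cfg.det_fraction * cfg.n_genes))
    det_genes = [str(g) for g in rng.choice(det_pool,
                                            size=min(n_det, len(det_pool)),
                                            replace=False)]

    # --- gene-level trajectories -----------------------------------------
    b1_sd, b2_sd = cfg.trajectory_beta_sd
    gene_fpkm = {}  # gid -> (n_breeds=2, n_stages) expected FPKM, rows (AA, LS)
    det_rows = []
    for gid in gene_ids:
        planted = gid in switch_roles or gid in candidates
        b0 = rng.normal(cfg.baseline_log_mean + (1.0 if planted else 0.0),
                        0.5 if planted else cfg.baseline_log_sd)
        if gid in candidates:
            b1 = b2 = 0.0  # flat in LS; AA gets its own strong trend below
        else:
            b1 = rng.normal(0.0, b1_sd if not planted else 1.0)
            b2 = rng.normal(0.0, b2_sd if not planted else 1.0)
        base = np.exp(b0 + b1 * tau + b2 * tau ** 2)
        fa, fb = base.copy(), base.copy()
        if gid in candidates:
            fa = fa * np.exp(4.0 * tau)  # strong AA-specific developmental trend
            for s in POSTHATCH_STAGES:
                if s in stages:
                    fa[stages.index(s)] *= 2.0 ** cfg.breed_effect_log2fc
                    for tid in annotation.transcripts_of_gene()[gid]:
                        det_rows.append({"transcript_id": tid, "stage": s,
                                         "direction": "up"})
        elif gid in det_genes:
            s_idx = int(rng.integers(0, n_stages))
            direction = "up" if rng.random() < 0.5 else "down"
            factor = 2.0 ** cfg.breed_effect_log2fc
            fa[s_idx] *= factor if direction == "up" else 1.0 / factor
            for tid in annotation.transcripts_of_gene()[gid]:
                det_rows.append({"transcript_id": tid, "stage": stages[s_idx],
                                 "direction": direction})
        gene_fpkm[gid] = np.vstack([fa, fb])

    # --- isoform usage ----------------------------------------------------
    tx_of = annotation.transcripts_of_gene()
    p = cfg.dominance_proportion
    usage = {}  # tid -> (2, n_stages) usage share
    dominance_rows = []

    def heavy_usage(tids, heavy_idx_per_cell):
        """usage shares from a (2, n_stages) array of heavy isoform indices
        (-1 = balanced, no heavy isoform)."""
        m = len(tids)
        arr = {tid: np.zeros((2, n_stages)) for tid in tids}
        for b in range(2):
            for s in range(n_stages):
                h = heavy_idx_per_cell[b, s]
                if h < 0:
                    for tid in tids:
                        arr[tid][b, s] = 1.0 / m
                else:
                    for j, tid in enumerate(tids):
                        arr[tid][b, s] = p if j == h else (1.0 - p) / (m - 1)
        return arr

    def record_dominance(gid, tids, heavy_idx_per_cell):
        for b_i, breed in enumerate((breed_a, breed_b)):
            for s_i, stage in enumerate(stages):
                h = heavy_idx_per_cell[b_i, s_i]
                if h >= 0:
                    dominance_rows.append({
                        "gene_id": gid, "breed": breed, "stage": stage,
                        "dominant_transcript": tids[h]})

    for gid in gene_ids:
        tids = tx_of[gid]
        m = len(tids)
        if m == 1:
            usage[tids[0]] = np.ones((2, n_stages))
            continue
        heavy = np.full((2, n_stages), -1, dtype=int)
        if gid in class_i or gid in candidates:
            j1, j2 = rng.choice(m, size=2, replace=False)
            s_star = int(rng.integers(1, n_stages))  # needs a 'before'
            heavy[0, :] = np.where(np.arange(n_stages) < s_star, j1, j2)  # AA switches
            heavy[1, :] = j1                                              # LS stable
        elif gid in class_ii:
            j1, j2 = rng.choice(m, size=2, replace=False)
            s_star = int(rng.integers(1, n_stages))
            pattern = np.where(np.arange(n_stages) < s_star, j1, j2)
            heavy[0, :] = pattern
            heavy[1, :] = pattern  # identical in both breeds: no same-stage clash
        elif gid in within:
            j1, j2 = rng.choice(m, size=2, replace=False)
            s_star = int(rng.integers(1, n_stages))
            b_switch = int(rng.integers(0, 2))
            heavy[b_switch, :] = np.where(np.arange(n_stages) < s_star, j1, j2)
            # other breed stays balanced (-1): no dominant, no cross-breed event
        elif gid in stable_dom:
            j1 = int(rng.integers(0, m))
            heavy[:, :] = j1
        else:  # background: one Dirichlet draw shared across breeds and stages
            shares = rng.dirichlet(np.full(m, 2.0))
            for j, tid in enumerate(tids):
                usage[tid] = np.full((2, n_stages), shares[j])
            order = np.sort(shares)[::-1]
            if order[0] > 2.0 * order[1]:  # expected-FPKM dominance by the rule
                j1 = int(np.argmax(shares))
                heavy_bg = np.full((2, n_stages), j1, dtype=int)
                record_dominance(gid, tids, heavy_bg)
            continue
        arr = heavy_usage(tids, heavy)
        for tid in tids:
            usage[tid] = arr[tid]
        record_dominance(gid, tids, heavy)

    # --- samples and counts ----------------------------------------------
    sample_rows = []
    for breed in (breed_a, breed_b):
        for stage in stages:
            for rep in range(1, cfg.n_replicates + 1):
                lib = int(cfg.library_size_mean
                          * np.exp(rng.normal(0.0, 0.05)))
                sample_rows.append({"sample_id": f"{breed}_{stage}_{rep}",
                                    "breed": breed, "stage": stage,
                                    "replicate": rep, "library_size": lib})
    meta_frame = pd.DataFrame(sample_rows).set_index("sample_id")
    metadata = SampleMetadata(meta_frame, stages=tuple(stages))

    tids_all = list(annotation.transcript_ids)
    lengths = annotation.lengths
    expected_cols = {}
    mu = np.zeros((len(tids_all), len(meta_frame)))
    for j, (sid, row) in enumerate(meta_frame.iterrows()):
        b_i = 0 if row["breed"] == breed_a else 1
        s_i = stages.index(str(row["stage"]))
        lib = row["library_size"]
        for i, tid in enumerate(tids_all):
            gid = ann_frame.loc[tid, "gene_id"]
            fpkm = usage[tid][b_i, s_i] * gene_fpkm[gid][b_i, s_i]
            mu[i, j] = fpkm * (lengths[tid] / 1e3) * (lib / 1e6)
    for b_i, breed in enumerate((breed_a, breed_b)):
        for s_i, stage in enumerate(stages):
            expected_cols[(breed, stage)] = [
                usage[tid][b_i, s_i]
                * gene_fpkm[ann_frame.loc[tid, "gene_id"]][b_i, s_i]
                for tid in tids_all]
    expected_fpkm = pd.DataFrame(expected_cols, index=tids_all)
    expected_fpkm.columns = pd.MultiIndex.from_tuples(
        expected_fpkm.columns, names=["breed", "stage"])

    if cfg.dispersion > 0:
        lam = rng.gamma(shape=1.0 / cfg.dispersion,
                        scale=cfg.dispersion * np.maximum(mu, 1e-12))
        counts_arr = rng.poisson(lam)
    else:
        counts_arr = rng.poisson(mu)
    counts = ExpressionMatrix(
        pd.DataFrame(counts_arr.astype(float), index=tids_all,
                     columns=meta_frame.index), "counts")

    dominance = pd.DataFrame(
        dominance_rows,
        columns=["gene_id", "breed", "stage", "dominant_transcript"])
    truth = TruthTables(
        det=pd.DataFrame(det_rows,
                         columns=["transcript_id", "stage", "direction"]),
        dominance=dominance,
        switches=_derive_switch_truth(dominance, (breed_a, breed_b), stages),
        candidates=candidates,
        go_map=_make_go_map(rng, gene_ids, candidates),
    )
    return SimulatedDataset(cfg, annotation, metadata, counts, truth,
                            expected_fpkm)


def _make_go_map(rng, gene_ids, candidates) -> pd.DataFrame:
    """Synthetic gene->term annotation; candidates carry the muscle term."""
    terms = [f"SYN:{i:04d}" for i in range(1, 21)]
    rows = []
    for gid in gene_ids:
        for term in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            rows.append({"gene_id": gid, "term": term})
        if gid in candidates:
            rows.append({"gene_id": gid, "term": MUSCLE_TERM})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def write_fixture(dataset: SimulatedDataset, out_dir) -> dict[str, str]:
    """Emit the dataset as plain-text files consumable by the core readers."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "meta": out / "meta.tsv",
        "gtf": out / "ann.gtf",
        "truth_det": out / "truth_det.tsv",
        "truth_dominance": out / "truth_dominance.tsv",
        "truth_switches": out / "truth_switches.tsv",
        "truth_candidates": out / "truth_candidates.tsv",
        "go_map": out / "go_map.tsv",
    }
    dataset.counts.write_tsv(paths["counts"])
    dataset.metadata.write_tsv(paths["meta"])
    write_gtf(dataset.annotation, paths["gtf"])
    dataset.truth.det.to_csv(paths["truth_det"], sep="\t", index=False)
    dataset.truth.dominance.to_csv(paths["truth_dominance"], sep="\t", index=False)
    dataset.truth.switches.to_csv(paths["truth_switches"], sep="\t", index=False)
    pd.DataFrame({"gene_id": sorted(dataset.truth.candidates)}).to_csv(
        paths["truth_candidates"], sep="\t", index=False)
    dataset.truth.go_map.to_csv(paths["go_map"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}
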