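"""Negative-binomial two-group tests for stage-wise differential expression.

Transcripts are compared between the two breeds at one developmental stage
using a negative-binomial (NB2) generalized linear model with a log link and a
log library-size offset, at fixed per-transcript dispersion ``phi``
(``variance = mu + phi * mu**2``).  The null model shares one mean across both
groups; the alternative gives each group its own mean.  Significance comes
from the 1-df likelihood-ratio test against chi-square; q-values are
Benjamini-Hochberg within each stage's family of tests.

A transcript is called a DET (differentially expressed transcript) when
``|log2FC| > 1`` and ``q < 0.05``, both strict.

The module is written in the statsmodels idiom: :class:`NBTwoGroupModel` is
built from data and ``fit()`` returns a result table; the underlying
vectorized fitting kernels (:func:`fit_nb_mean`, :func:`nb_lrt`) are exposed
for reuse (the dominant-isoform caller runs the same test between sibling
isoforms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, SampleMetadata, ValidationError

_LOG2 = np.log(2.0)
_BETA_FLOOR = -30.0
_MAX_ITER = 100
_TOL = 1e-12


# ---------------------------------------------------------------------------
# Vectorized NB fitting kernels
# ---------------------------------------------------------------------------

def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over the last axis, dropping terms constant
    in ``mu`` (they cancel in likelihood ratios).  ``phi = 0`` is the Poisson
    limit."""
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(mu, y.shape)
    phi = np.broadcast_to(np.asarray(phi, dtype=float)[..., None], y.shape)
    t1 = special.xlogy(y, mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 1.0 / phi
        nb = t1 - (y + r) * np.log1p(phi * mu)
    pois = t1 - mu
    return np.where(phi > 0, nb, pois).sum(axis=-1)


def fit_nb_mean(y: np.ndarray, offsets: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Maximum-likelihood intercept of ``mu = exp(beta + offset)`` per row.

    ``y`` is (n, k); ``offsets`` broadcastable to it; ``phi`` is (n,).
    Fisher scoring on the single parameter; rows that are all zero converge to
    the floored intercept.
    """
    y = np.asarray(y, dtype=float)
    offsets = np.broadcast_to(offsets, y.shape)
    phi = np.asarray(phi, dtype=float)[:, None]
    exp_off = np.exp(offsets)
    beta = np.log((y.sum(axis=1) + 0.1) / exp_off.sum(axis=1))[:, None]
    for _ in range(_MAX_ITER):
        mu = np.exp(beta + offsets)
        denom = 1.0 + phi * mu
        score = ((y - mu) / denom).sum(axis=1, keepdims=True)
        info = (mu / denom).sum(axis=1, keepdims=True)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        beta = np.maximum(beta + step, _BETA_FLOOR)
        if np.max(np.abs(step)) < _TOL:
            break
    return beta[:, 0]


def nb_lrt(y_a: np.ndarray, y_b: np.ndarray, off_a: np.ndarray, off_b: np.ndarray,
           phi: np.ndarray) -> pd.DataFrame:
    """Two-group NB likelihood-ratio test, vectorized over rows.

    Returns a DataFrame with ``log2fc`` (group A over group B on the
    offset-normalized scale), ``lrt``, ``p_value`` and the fitted group means
    (offset-normalized).  Rows that are all zero in both groups get
    ``p_value = 1`` and ``log2fc = 0`` and are flagged ``tested = False``.
    """
    y_a = np.atleast_2d(np.asarray(y_a, dtype=float))
    y_b = np.atleast_2d(np.asarray(y_b, dtype=float))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y_a.shape[0],))
    off_a = np.broadcast_to(off_a, y_a.shape)
    off_b = np.broadcast_to(off_b, y_b.shape)

    beta_a = fit_nb_mean(y_a, off_a, phi)
    beta_b = fit_nb_mean(y_b, off_b, phi)
    y_all = np.concatenate([y_a, y_b], axis=1)
    off_all = np.concatenate([off_a, off_b], axis=1)
    beta0 = fit_nb_mean(y_all, off_all, phi)

    ll_alt = (nb_loglik(y_a, np.exp(beta_a[:, None] + off_a), phi)
              + nb_loglik(y_b, np.exp(beta_b[:, None] + off_b), phi))
    ll_null = nb_loglik(y_all, np.exp(beta0[:, None] + off_all), phi)
    lrt = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    p = stats.chi2.sf(lrt, df=1)

    tested = (y_all.sum(axis=1) > 0)
    log2fc = (beta_a - beta_b) / _LOG2
    log2fc = np.where(tested, log2fc, 0.0)
    p = np.where(tested, p, 1.0)
    return pd.DataFrame({
        "log2fc": log2fc,
        "lrt": np.where(tested, lrt, 0.0),
        "p_value": p,
        "mean_a": np.exp(beta_a),
        "mean_b": np.exp(beta_b),
        "tested": tested,
    })


# ---------------------------------------------------------------------------
# Dispersion estimation
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    """Per-transcript NB dispersion (``variance = mu + phi * mu**2``).

    ``table`` carries ``tagwise`` (method-of-moments), ``common`` (trimmed
    mean across transcripts) and ``shrunk`` (weighted average of the two)
    columns indexed by transcript id; ``method`` names the column served by
    :attr:`phi`.
    """

    table: pd.DataFrame
    method: str = "shrunk"

    @property
    def phi(self) -> pd.Series:
        return self.table[self.method]


def estimate_dispersion(counts: ExpressionMatrix, groups: pd.Series,
                        library_sizes: pd.Series | None = None,
                        shrink_weight: float = 0.5,
                        trim: float = 0.1) -> DispersionEstimate:
    """Method-of-moments dispersion on library-size-normalized counts.

    Within each group, a per-transcript sample mean and variance are computed
    on counts rescaled to a common library size, then pooled across groups:
    ``phi_tagwise = max(0, (s2 - m) / m**2)``.  The common dispersion is a
    trimmed mean of tagwise values over transcripts with positive means; the
    shrunk value is ``w * common + (1 - w) * tagwise``.

    Every group must have at least two replicates.
    """
    counts.require_layer("counts")
    groups = groups.reindex(counts.sample_ids)
    if groups.isna().any():
        raise ValidationError("group labels missing for some samples")
    if library_sizes is None:
        library_sizes = counts.values.sum(axis=0)
    library_sizes = pd.Series(library_sizes).reindex(counts.sample_ids)
    norm = counts.values * (library_sizes.mean() / library_sizes)

    means, variances = [], []
    for _, sample_ids in groups.groupby(groups, observed=True).groups.items():
        sub = norm[list(sample_ids)]
        if sub.shape[1] < 2:
            raise ValidationError("each group needs >= 2 replicates for dispersion")
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
    m = pd.concat(means, axis=1).mean(axis=1)
    s2 = pd.concat(variances, axis=1).mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        tagwise = np.maximum(0.0, (s2 - m) / (m ** 2))
    tagwise = tagwise.where(m > 0, 0.0)
    positive = tagwise[m > 0]
    common = float(stats.trim_mean(positive, trim)) if len(positive) else 0.0
    shrunk = shrink_weight * common + (1.0 - shrink_weight) * tagwise
    table = pd.DataFrame({"tagwise": tagwise, "common": common, "shrunk": shrunk})
    return DispersionEstimate(table)


# ---------------------------------------------------------------------------
# Model / results surface
# ---------------------------------------------------------------------------

class NBTwoGroupModel:
    """NB GLM comparing the two breeds at one developmental stage.

    Parameters
    ----------
    counts : ExpressionMatrix (counts layer)
    meta : SampleMetadata
    stage : str
        Stage at which to compare.
    reference : str
        The reference breed (denominator of the fold change); the slow-growing
        indigenous breed ``LS`` by default.
    dispersion : DispersionEstimate or float, optional
        Fixed per-transcript (or scalar) dispersion.  When omitted it is
        estimated from the replicates at this stage.
    """

    def __init__(self, counts: ExpressionMatrix, meta: SampleMetadata, stage: str,
                 reference: str = "LS",
                 dispersion: DispersionEstimate | float | None = None):
        counts.require_layer("counts")
        self.counts = counts
        self.meta = meta
        self.stage = stage
        breeds = meta.breeds
        if reference not in breeds:
            raise ValidationError(f"reference breed {reference!r} not in metadata")
        if len(breeds) != 2:
            raise ValidationError("exactly two breeds are supported")
        self.reference = reference
        self.experimental = next(b for b in breeds if b != reference)
        self.samples_exp = meta.samples_for(self.experimental, stage)
        self.samples_ref = meta.samples_for(reference, stage)
        if len(self.samples_exp) == 0 or len(self.samples_ref) == 0:
            raise ValidationError(f"both breeds must be sampled at stage {stage!r}")
        if dispersion is None:
            stage_samples = list(self.samples_exp) + list(self.samples_ref)
            sub = ExpressionMatrix(counts.values[stage_samples], "counts")
            dispersion = estimate_dispersion(
                sub, meta.frame.loc[stage_samples, "breed"],
                meta.library_sizes[stage_samples])
        self.dispersion = dispersion

    def fit(self) -> pd.DataFrame:
        """Run the per-transcript LRT; returns a tidy result table."""
        ids = self.counts.transcript_ids
        if isinstance(self.dispersion, DispersionEstimate):
            phi = self.dispersion.phi.reindex(ids).fillna(0.0).to_numpy()
        else:
            phi = np.full(len(ids), float(self.dispersion))
        y_a = self.counts.values[list(self.samples_exp)].to_numpy()
        y_b = self.counts.values[list(self.samples_ref)].to_numpy()
        off_a = np.log(self.meta.library_sizes[self.samples_exp].to_numpy() / 1e6)
        off_b = np.log(self.meta.library_sizes[self.samples_ref].to_numpy() / 1e6)
        res = nb_lrt(y_a, y_b, off_a, off_b, phi)
        res.insert(0, "transcript_id", ids)
        res.insert(1, "stage", self.stage)
        res = res.rename(columns={
            "mean_a": f"mean_{self.experimental}", "mean_b": f"mean_{self.reference}"})
        return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg linear step-up q-values (order-preserving, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_det(results: pd.DataFrame, fc_threshold: float = 1.0,
             q_threshold: float = 0.05) -> pd.DataFrame:
    """Attach stage-wise BH q-values and up/down/ns direction calls.

    ``direction`` is ``up`` when ``log2fc > fc_threshold`` and
    ``q < q_threshold`` (strict), ``down`` symmetric, else ``ns``.  Untested
    (all-zero) transcripts are always ``ns``.  The BH family is the set of
    tested transcripts within each stage.
    """
    out = results.copy()
    out["q_value"] = 1.0
    for _, idx in out.groupby("stage", observed=True).groups.items():
        tested = out.loc[idx, "tested"]
        tested_idx = idx[tested.to_numpy()]
        if len(tested_idx):
            out.loc[tested_idx, "q_value"] = bh_adjust(out.loc[tested_idx, "p_value"])
    sig = (out["q_value"] < q_threshold) & out["tested"]
    out["direction"] = "ns"
    out.loc[sig & (out["log2fc"] > fc_threshold), "direction"] = "up"
    out.loc[sig & (out["log2fc"] < -fc_threshold), "direction"] = "down"
    return out


def det_per_stage(counts: ExpressionMatrix, meta: SampleMetadata,
                  stages=None, reference: str = "LS",
                  dispersion: DispersionEstimate | float | None = None,
                  fc_threshold: float = 1.0, q_threshold: float = 0.05) -> pd.DataFrame:
    """Convenience driver: NB test plus DET calling for each stage."""
    if stages is None:
        stages = [s for s in meta.stages
                  if len(meta.samples_for(stage=s))]
    frames = []
    for stage in stages:
        model = NBTwoGroupModel(counts, meta, stage, reference=reference,
                                dispersion=dispersion)
        frames.append(model.fit())
    results = pd.concat(frames, ignore_index=True)
    return call_det(results, fc_threshold, q_threshold)
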