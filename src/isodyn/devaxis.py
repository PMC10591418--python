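"""Developmental-axis construction by singular value decomposition.

For one breed, the ``log2(FPKM + 1)`` expression matrix ``X`` (transcripts x
samples, optionally row-centered) is decomposed as ``X = sum_a lambda_a *
feature_a (x) axis_a``: the length-s right singular vectors are the
*developmental axes* (sample-space trajectories), the length-g left singular
vectors are per-transcript *feature vectors* (loadings), and
``lambda_a^2 / sum(lambda^2)`` is each component's variance fraction.  Axes
are smoothed over the ordered stages with a local-quadratic LOESS, and the
transcripts with the largest absolute loadings (top 10% by default) are each
component's contributors, signed up/down by the loading.

Breed-specific contributor sets are the union of one breed's per-component
contributors minus the union of the other breed's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import STAGE_DAYS, ExpressionMatrix, SampleMetadata, ValidationError, log2p1


@dataclass
class AxisDecomposition:
    """SVD factors of one breed's transformed expression matrix.

    ``axis_vectors`` (samples x components) are the developmental axes;
    ``feature_vectors`` (transcripts x components) the transcript loadings.
    Components are ordered by decreasing singular value and oriented so each
    axis correlates non-negatively with numeric time.
    """

    x: pd.DataFrame                 # transcripts x samples, transformed input
    lambdas: np.ndarray             # singular values, descending
    axis_vectors: pd.DataFrame      # samples x PCs
    feature_vectors: pd.DataFrame   # transcripts x PCs
    centered: bool

    @property
    def variance_fraction(self) -> np.ndarray:
        lam2 = self.lambdas ** 2
        return lam2 / lam2.sum()

    @property
    def n_components(self) -> int:
        return len(self.lambdas)

    def reconstruction(self) -> np.ndarray:
        """``U diag(lambda) V^T`` on the (centered) input scale."""
        return (self.feature_vectors.to_numpy()
                * self.lambdas) @ self.axis_vectors.to_numpy().T


def decompose(fpkm: ExpressionMatrix, meta: SampleMetadata,
              samples=None, center_rows: bool = True,
              time_encoding: dict[str, float] | None = None) -> AxisDecomposition:
    """SVD of ``log2(FPKM + 1)`` over one breed's samples.

    ``samples`` selects the columns (typically one breed's 21 samples); rows
    are mean-centered by default so variance fractions have their PCA
    meaning.  Each axis is oriented so that its Pearson correlation with
    numeric time is non-negative (fallback for time-orthogonal axes: first
    nonzero axis entry made positive).
    """
    fpkm.require_layer("fpkm")
    if samples is None:
        samples = fpkm.sample_ids
    samples = list(samples)
    if len(samples) < 2:
        raise ValidationError("need at least two samples for a decomposition")
    if time_encoding is None:
        time_encoding = dict(STAGE_DAYS)

    x = log2p1(fpkm)[samples]
    values = x.to_numpy(dtype=float)
    if center_rows:
        values = values - values.mean(axis=1, keepdims=True)
    if not np.isfinite(values).any() or np.allclose(values, 0.0):
        raise ValidationError("matrix is identically zero after transform/centering")

    u, s, vt = np.linalg.svd(values, full_matrices=False)
    # Orientation: axis correlates non-negatively with developmental time.
    t = meta.frame.loc[samples, "stage"].astype(str).map(time_encoding).to_numpy(float)
    for a in range(len(s)):
        axis = vt[a]
        if np.std(axis) > 0 and np.std(t) > 0:
            corr = float(np.corrcoef(axis, t)[0, 1])
        else:
            corr = 0.0
        if corr < 0:
            flip = True
        elif corr > 0:
            flip = False
        else:
            nz = axis[np.nonzero(axis)[0]] if np.any(axis) else np.array([1.0])
            flip = nz[0] < 0
        if flip:
            vt[a] = -vt[a]
            u[:, a] = -u[:, a]

    pcs = [f"PC{i + 1}" for i in range(len(s))]
    return AxisDecomposition(
        x=pd.DataFrame(values, index=x.index, columns=samples),
        lambdas=s,
        axis_vectors=pd.DataFrame(vt.T, index=samples, columns=pcs),
        feature_vectors=pd.DataFrame(u, index=x.index, columns=pcs),
        centered=center_rows,
    )


# ---------------------------------------------------------------------------
# LOESS axis curves
# ---------------------------------------------------------------------------

def loess_quadratic(x: np.ndarray, y: np.ndarray, x_out: np.ndarray,
                    span: float = 0.75) -> np.ndarray:
    """Local quadratic regression with tricube weights.

    At each output point the ``ceil(span * n)`` nearest observations are fit
    by weighted degree-2 least squares.  Exactly reproduces polynomials up to
    degree 2.  Requires at least four points in each window.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    q = int(np.ceil(span * n))
    if q < 4:
        min_span = 4.0 / n
        raise ValidationError(
            f"span {span} leaves {q} points per window; need >= 4 "
            f"(minimum feasible span {min_span:.3f})")
    out = np.empty(len(x_out))
    for j, x0 in enumerate(np.asarray(x_out, dtype=float)):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[j] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        xc = x[idx] - x0
        design = np.column_stack([np.ones_like(xc), xc, xc ** 2])
        wsqrt = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * wsqrt[:, None], y[idx] * wsqrt, rcond=None)
        out[j] = beta[0]
    return out


@dataclass
class AxisCurve:
    """One component's developmental axis over the stage grid."""

    pc_index: int
    stages: tuple[str, ...]
    times: np.ndarray
    raw_means: np.ndarray       # per-stage replicate means of the axis vector
    smoothed: np.ndarray        # LOESS values at the observed stage times
    span: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "stage": self.stages, "time": self.times,
            "raw_mean": self.raw_means, "smoothed": self.smoothed,
        })

    def plot(self, ax=None, label: str | None = None):
        """Plot raw per-stage means and the LOESS curve (needs matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.smoothed, "-", label=label)
        ax.plot(self.times, self.raw_means, "o", alpha=0.5)
        ax.set_xlabel("developmental time (days)")
        ax.set_ylabel(f"axis value (PC{self.pc_index})")
        if label:
            ax.legend()
        return ax


def axis_curve(dec: AxisDecomposition, meta: SampleMetadata, pc_index: int,
               span: float = 0.75,
               time_encoding: dict[str, float] | None = None) -> AxisCurve:
    """LOESS-smoothed developmental axis for one component."""
    if pc_index < 1 or pc_index > dec.n_components:
        raise ValidationError(f"pc_index {pc_index} outside 1..{dec.n_components}")
    if time_encoding is None:
        time_encoding = dict(STAGE_DAYS)
    samples = dec.axis_vectors.index
    stage_of = meta.frame.loc[samples, "stage"].astype(str)
    axis = dec.axis_vectors[f"PC{pc_index}"]
    observed = [s for s in meta.stages if (stage_of == s).any()]
    times = np.array([time_encoding[s] for s in observed], dtype=float)
    raw = np.array([axis[stage_of == s].mean() for s in observed])
    t_all = stage_of.map(time_encoding).to_numpy(dtype=float)
    smoothed = loess_quadratic(t_all, axis.to_numpy(), times, span=span)
    return AxisCurve(pc_index, tuple(observed), times, raw, smoothed, span)


# ---------------------------------------------------------------------------
# Contributors
# ---------------------------------------------------------------------------

@dataclass
class ContributorSet:
    """Top transcripts of one component, ranked by absolute loading."""

    pc_index: int
    table: pd.DataFrame  # index transcript_id; columns loading, rank, direction

    @property
    def transcript_ids(self) -> set[str]:
        return set(self.table.index)


def top_contributors(dec: AxisDecomposition, pc_index: int,
                     fraction: float = 0.10) -> ContributorSet:
    """The ``ceil(fraction * g)`` transcripts with the largest |loading|.

    Direction is ``up`` for positive loadings, ``down`` for negative; ties in
    |loading| break lexicographically by transcript id.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValidationError("fraction must lie in (0, 1]")
    if pc_index < 1 or pc_index > dec.n_components:
        raise ValidationError(f"pc_index {pc_index} outside 1..{dec.n_components}")
    loadings = dec.feature_vectors[f"PC{pc_index}"]
    order = pd.DataFrame({"abs": loadings.abs(), "tid": loadings.index})
    order = order.sort_values(["abs", "tid"], ascending=[False, True])
    n_top = int(np.ceil(fraction * len(loadings)))
    chosen = order.index[:n_top]
    table = pd.DataFrame({
        "loading": loadings[chosen],
        "rank": np.arange(1, n_top + 1),
        "direction": np.where(loadings[chosen] >= 0, "up", "down"),
    })
    return ContributorSet(pc_index, table)


def breed_specific_contributors(a_sets: list[ContributorSet],
                                b_sets: list[ContributorSet]) -> set[str]:
    """Union of A's contributors minus union of B's."""
    if not a_sets or not b_sets:
        raise ValidationError("both contributor lists must be nonempty")
    a_union = set().union(*(s.transcript_ids for s in a_sets))
    b_union = set().union(*(s.transcript_ids for s in b_sets))
    return a_union - b_union


def variance_report(dec: AxisDecomposition, top_k: int = 4) -> float:
    """Cumulative variance fraction of the leading ``top_k`` components."""
    if top_k > dec.n_components:
        raise ValidationError(f"top_k {top_k} exceeds {dec.n_components} components")
    return float(dec.variance_fraction[:top_k].sum())
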