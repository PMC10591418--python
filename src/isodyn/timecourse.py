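"""Two-group polynomial time-course model of expression profiles.

For a design with T time points and two groups, each transcript's response
``y`` (here ``log2(FPKM + 1)``) is modelled by quadratic polynomial
regression with group dummies:

    y_i = b0 + b1*t_i + b2*t_i^2 + b3*z_i + b4*t_i*z_i + b5*t_i^2*z_i + e_i

where ``z`` is the binary indicator distinguishing the experimental group
from the reference group (``z = 0`` for the reference).  Transcripts whose
profile differs from flatness are flagged by the global F-test of the full
model against the intercept-only model, with Benjamini-Hochberg FDR across
transcripts.  Significant transcripts then undergo backward elimination of
non-significant terms and are retained when the selected model's R-squared
clears a threshold (default 0.6); retained profiles are grouped by
agglomerative hierarchical clustering (1 - Pearson correlation, average
linkage) into k characteristic patterns (default 9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core import STAGE_DAYS, ExpressionMatrix, SampleMetadata, ValidationError, log2p1
from .diffexpr import bh_adjust

#: Design column order: intercept then the five candidate terms.
DESIGN_COLUMNS = ("intercept", "t", "t2", "z1", "t_z1", "t2_z1")
CANDIDATE_TERMS = DESIGN_COLUMNS[1:]


@dataclass
class TimecourseDesign:
    """Design matrix for the two-group quadratic model.

    ``matrix`` is samples x 6 in the order of :data:`DESIGN_COLUMNS`;
    ``z = 0`` marks the reference group.
    """

    matrix: pd.DataFrame
    meta: SampleMetadata
    reference_group: str
    time_encoding: dict[str, float] = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def t(self) -> np.ndarray:
        return self.matrix["t"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.matrix["z1"].to_numpy()


def build_design(meta: SampleMetadata, reference_group: str = "LS",
                 time_encoding: dict[str, float] | None = None) -> TimecourseDesign:
    """Build the samples x 6 design; stages are encoded as numeric time.

    The default encoding is days since onset of incubation
    (:data:`isodyn.core.STAGE_DAYS`).  More than two groups is unsupported.
    """
    if time_encoding is None:
        time_encoding = dict(STAGE_DAYS)
    groups = meta.breeds
    if len(groups) > 2:
        raise ValidationError("designs with more than two groups are unsupported")
    if reference_group not in groups:
        raise ValidationError(f"reference group {reference_group!r} not in metadata")
    unmapped = set(meta.frame["stage"].astype(str)) - set(time_encoding)
    if unmapped:
        raise ValidationError(f"stages lacking a time encoding: {sorted(unmapped)}")
    t = meta.frame["stage"].astype(str).map(time_encoding).to_numpy(dtype=float)
    z = (meta.frame["breed"] != reference_group).to_numpy(dtype=float)
    matrix = pd.DataFrame(
        np.column_stack([np.ones_like(t), t, t ** 2, z, t * z, t ** 2 * z]),
        index=meta.sample_ids, columns=list(DESIGN_COLUMNS))
    return TimecourseDesign(matrix, meta, reference_group, time_encoding)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least squares of each row of ``y`` on columns of ``x``.

    Returns (coefficients, residual sum of squares per row)."""
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    return beta.T, (resid ** 2).sum(axis=1)


class TimecourseModel:
    """Per-transcript quadratic time-course regression.

    Build from a response matrix (transcripts x samples) and a design, or
    directly from an FPKM matrix via :meth:`from_fpkm` (which applies the
    package's ``log2(FPKM + 1)`` transform).
    """

    def __init__(self, responses: pd.DataFrame, design: TimecourseDesign):
        missing = design.sample_ids.difference(responses.columns)
        if len(missing):
            raise ValidationError(f"responses missing samples: {list(missing)[:5]}")
        if responses.isna().any().any():
            raise ValidationError("responses contain missing values")
        self.responses = responses[design.sample_ids]
        self.design = design

    @classmethod
    def from_fpkm(cls, fpkm: ExpressionMatrix, design: TimecourseDesign) -> "TimecourseModel":
        return cls(log2p1(fpkm), design)

    def fit(self, alpha_fdr: float = 0.05) -> "TimecourseResults":
        """OLS of the full 6-term model; global F-test against intercept-only.

        Constant responses have an undefined F and are reported with
        ``p = 1`` (never significant).
        """
        x = self.design.matrix.to_numpy()
        y = self.responses.to_numpy(dtype=float)
        n, p = x.shape
        beta, rss1 = _ols(y, x)
        rss0 = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)

        df1, df2 = p - 1, n - p
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ((rss0 - rss1) / df1) / (rss1 / df2)
            r2 = 1.0 - rss1 / rss0
        constant = rss0 <= 1e-300
        perfect = (rss1 <= 1e-12 * np.maximum(rss0, 1.0)) & ~constant
        p_values = np.where(constant, 1.0,
                            np.where(perfect, 0.0, stats.f.sf(f_stat, df1, df2)))
        r2 = np.where(constant, 0.0, np.clip(r2, 0.0, 1.0))
        q_values = bh_adjust(p_values)

        table = pd.DataFrame(beta, index=self.responses.index,
                             columns=[f"beta{i}" for i in range(p)])
        table["p_value"] = p_values
        table["q_value"] = q_values
        table["r_squared"] = r2
        table["significant"] = (q_values < alpha_fdr) & ~constant
        return TimecourseResults(self, table)


@dataclass
class TimecourseResults:
    """Full-model fits plus downstream selection and clustering."""

    model: TimecourseModel
    table: pd.DataFrame

    @property
    def significant_ids(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def summary(self) -> str:
        n = len(self.table)
        k = int(self.table["significant"].sum())
        lines = [
            "Two-group quadratic time-course model",
            f"  transcripts fitted:      {n}",
            f"  significant (BH q<0.05): {k}",
            f"  median full-model R2:    {self.table['r_squared'].median():.3f}",
        ]
        return "\n".join(lines)

    # -- stepwise term selection ------------------------------------------

    def stepwise(self, r2_threshold: float = 0.6,
                 alpha_in: float = 0.05) -> "StepwiseResults":
        """Backward elimination on the significant set.

        From the full model, iteratively drop the least-significant candidate
        term (largest t-test p-value above ``alpha_in``); the intercept is
        always kept.  A transcript is retained when the selected model's
        R-squared is at least ``r2_threshold``.
        """
        x_full = self.model.design.matrix.to_numpy()
        n = x_full.shape[0]
        y_all = self.model.responses
        rows = []
        profiles = {}
        for tid in self.significant_ids:
            y = y_all.loc[tid].to_numpy(dtype=float)
            rss0 = float(((y - y.mean()) ** 2).sum())
            cols = list(range(x_full.shape[1]))  # intercept + 5 candidates
            while len(cols) > 1:
                x = x_full[:, cols]
                beta, *_ = np.linalg.lstsq(x, y, rcond=None)
                resid = y - x @ beta
                rss = float(resid @ resid)
                dof = n - len(cols)
                s2 = rss / dof if dof > 0 else 0.0
                xtx_inv = np.linalg.pinv(x.T @ x)
                se = np.sqrt(np.maximum(np.diag(xtx_inv) * s2, 0.0))
                with np.errstate(divide="ignore", invalid="ignore"):
                    tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta + 1e-300))
                pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
                cand = [(pvals[i], i) for i in range(1, len(cols))]
                worst_p, worst_i = max(cand)
                if worst_p > alpha_in:
                    cols.pop(worst_i)
                else:
                    break
            x = x_full[:, cols]
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
            rss = float(resid @ resid)
            r2 = 0.0 if rss0 <= 0 else max(0.0, 1.0 - rss / rss0)
            selected = tuple(DESIGN_COLUMNS[c] for c in cols[1:])
            rows.append({
                "transcript_id": tid,
                "selected_terms": ",".join(selected),
                "r_squared": r2,
                "retained": r2 >= r2_threshold,
            })
            profiles[tid] = x @ beta
        table = pd.DataFrame(rows).set_index("transcript_id") if rows else pd.DataFrame(
            columns=["selected_terms", "r_squared", "retained"])
        fitted = pd.DataFrame(profiles, index=self.model.responses.columns).T
        return StepwiseResults(self, table, fitted)


@dataclass
class StepwiseResults:
    """Selected models for significant transcripts and their fitted values."""

    parent: TimecourseResults
    table: pd.DataFrame
    fitted: pd.DataFrame  # transcripts x samples, selected-model fitted values

    @property
    def retained_ids(self) -> pd.Index:
        return self.table.index[self.table["retained"]]

    def fitted_profiles(self) -> pd.DataFrame:
        """Mean fitted value per (breed, stage) for retained transcripts."""
        meta = self.parent.model.design.meta
        cols = {}
        for breed in meta.breeds:
            for stage in meta.stages:
                samples = meta.samples_for(breed, stage)
                if len(samples) == 0:
                    continue
                cols[(breed, stage)] = self.fitted.loc[self.retained_ids,
                                                       list(samples)].mean(axis=1)
        out = pd.DataFrame(cols)
        out.columns = pd.MultiIndex.from_tuples(out.columns, names=["breed", "stage"])
        return out

    def cluster_profiles(self, k: int = 9) -> "ProfileClusters":
        """Cluster retained transcripts into k characteristic patterns.

        Profiles (mean fitted value per breed x stage) are z-scored per
        transcript; distance is 1 - Pearson correlation; linkage is average.
        Transcripts are processed in lexicographic id order so ties resolve
        deterministically.
        """
        profiles = self.fitted_profiles().sort_index()
        if len(profiles) < k:
            raise ValidationError(
                f"only {len(profiles)} retained transcripts; choose k <= that")
        values = profiles.to_numpy(dtype=float)
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        zed = np.where(sd > 0, (values - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        corr = np.corrcoef(zed)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        link = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
        membership = pd.Series(labels, index=profiles.index, name="cluster_id")
        means = profiles.groupby(membership).mean()
        return ProfileClusters(membership, means)


@dataclass
class ProfileClusters:
    """Partition of retained transcripts into characteristic patterns."""

    membership: pd.Series  # transcript_id -> cluster_id (1..k)
    mean_profiles: pd.DataFrame  # cluster_id x (breed, stage)

    @property
    def k(self) -> int:
        return int(self.membership.max()) if len(self.membership) else 0

    def members(self, cluster_id: int) -> list[str]:
        return sorted(self.membership.index[self.membership == cluster_id])
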