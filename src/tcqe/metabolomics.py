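"""Metabolomics feature-table processing and the differential screen.

Stages, in pipeline order:

1. ``qc_rsd_filter`` — drop features whose relative standard deviation
   across the pooled-QC injections exceeds the threshold (default 30%,
   strict; a feature at exactly the threshold is kept).
2. ``loess_drift_correct`` — QC-anchored locally weighted regression of
   intensity against injection order, per feature; every sample is
   divided by the interpolated drift and rescaled so the QC median is
   unchanged.  This removes smooth instrument-sensitivity drift without
   touching between-group differences.
3. ``pca`` — mean-centred (optionally unit-variance or pareto scaled)
   principal components via SVD with a deterministic sign convention.
4. OPLS-DA, VIP and the permutation test live in :mod:`tcqe.oplsda`.
5. ``volcano`` / ``screen_differential`` — per-feature log2 fold change
   and Welch t-test; a feature is differential iff p < 0.05 (strict)
   and VIP > 1 (strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ValidationError

log = logging.getLogger("tcqe")


@dataclass
class FeatureTable:
    """Features x samples intensity matrix with sample metadata.

    ``intensities``: DataFrame, rows = feature ids, columns = sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``group``
    (str), ``is_qc`` (bool) and ``injection_order`` (int, unique).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in intensity matrix")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples missing metadata: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.intensities.columns)]
        order = self.samples["injection_order"]
        if order.duplicated().any():
            raise ValidationError("injection_order values must be unique")
        if (self.intensities.to_numpy(dtype=float) < 0).any():
            raise ValidationError("intensities must be nonnegative")

    @property
    def qc_columns(self) -> list[str]:
        return list(self.samples.index[self.samples["is_qc"].astype(bool)])

    @property
    def biological_columns(self) -> list[str]:
        return list(self.samples.index[~self.samples["is_qc"].astype(bool)])

    def groups(self) -> pd.Series:
        return self.samples.loc[self.biological_columns, "group"]

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.intensities.loc[list(feature_ids)], self.samples.copy())


def qc_rsd_filter(table: FeatureTable, qc_rsd_max: float = 30.0) -> FeatureTable:
    """Drop features with QC RSD strictly above ``qc_rsd_max`` percent.

    RSD = sample SD / mean x 100 over the QC injections; features whose
    QC mean is zero are dropped as unquantifiable.
    """
    qc = table.qc_columns
    if len(qc) < 2:
        raise ValidationError(f"QC RSD filter needs >= 2 QC samples, got {len(qc)}")
    X = table.intensities[qc].to_numpy(dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean * 100.0, np.inf)
    keep = rsd <= qc_rsd_max
    out = table.intensities.loc[keep]
    log.info(
        "qc_rsd_filter: %d -> %d features (QC RSD <= %g%%)",
        len(table.intensities), len(out), qc_rsd_max,
    )
    return FeatureTable(out, table.samples.copy())


def qc_rsd(table: FeatureTable) -> pd.Series:
    """Per-feature QC relative standard deviation, in percent."""
    qc = table.qc_columns
    X = table.intensities[qc].to_numpy(dtype=float)
    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, sd / mean * 100.0, np.inf)
    return pd.Series(rsd, index=table.intensities.index, name="qc_rsd")


def loess_drift_correct(
    table: FeatureTable, span: float = 0.75
) -> tuple[FeatureTable, list[str]]:
    """QC-anchored LOESS signal-drift correction.

    Per feature: a locally weighted linear regression (tricube weights,
    degree 1, fraction ``span``) of QC intensity on injection order is
    evaluated at every sample's injection order by linear interpolation
    (flat beyond the QC range); each intensity is divided by the local
    drift and rescaled so the feature's QC median is exactly preserved.
    Features whose fitted drift is nonpositive anywhere are left
    uncorrected and returned in the flagged list.

    Returns the corrected table and the list of flagged feature ids.
    """
    qc = table.qc_columns
    if len(qc) < 4:
        raise ValidationError(
            f"LOESS drift correction needs >= 4 QC samples, got {len(qc)}"
        )
    if int(np.ceil(span * len(qc))) < 2:
        raise ValidationError(
            f"span {span} covers fewer than 2 of {len(qc)} QC points; "
            "increase span"
        )
    order = table.samples["injection_order"].astype(float)
    x_qc = order[qc].to_numpy()
    qc_sorted = np.argsort(x_qc)
    x_all = order[table.intensities.columns].to_numpy()

    corrected = table.intensities.copy().astype(float)
    flagged: list[str] = []
    for fid, row in table.intensities.iterrows():
        y_qc = row[qc].to_numpy(dtype=float)
        fit = lowess(
            y_qc[qc_sorted], x_qc[qc_sorted], frac=span, it=0, return_sorted=False
        )
        drift = np.interp(x_all, x_qc[qc_sorted], fit)
        if (drift <= 0).any():
            flagged.append(fid)
            continue
        ratio = row.to_numpy(dtype=float) / drift
        qc_ratio = y_qc / np.interp(x_qc, x_qc[qc_sorted], fit)
        scale = np.median(y_qc) / np.median(qc_ratio)
        corrected.loc[fid] = ratio * scale
    if flagged:
        log.warning(
            "loess_drift_correct: %d feature(s) with nonpositive fitted drift "
            "left uncorrected", len(flagged),
        )
    return FeatureTable(corrected, table.samples.copy()), flagged


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # features x components
    explained_variance_ratio: np.ndarray
    dropped_features: list[str] = field(default_factory=list)


def pca(
    table: FeatureTable | pd.DataFrame,
    scaling: str = "uv",
    n_components: int | None = None,
    include_qc: bool = False,
) -> PcaResult:
    """Principal component analysis of samples (observations = samples).

    Always mean-centred; ``scaling`` is ``"uv"`` (unit variance, default),
    ``"pareto"`` or ``"none"``.  Zero-variance features are dropped with a
    warning under uv scaling.  Component signs follow the convention that
    the largest-magnitude loading of each component is positive.
    """
    if isinstance(table, FeatureTable):
        cols = list(table.intensities.columns) if include_qc else table.biological_columns
        mat = table.intensities[cols]
    else:
        mat = table
    X = mat.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    feature_ids = list(mat.index)
    sd = X.std(axis=0, ddof=1)
    dropped: list[str] = []
    if scaling == "uv":
        keep = sd > 0
        if not keep.all():
            dropped = [f for f, k in zip(feature_ids, keep) if not k]
            log.warning("pca: dropped %d zero-variance feature(s)", len(dropped))
            X = X[:, keep]
            sd = sd[keep]
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        Xs = (X - X.mean(axis=0)) / sd
    elif scaling == "pareto":
        div = np.where(sd > 0, np.sqrt(sd), 1.0)
        Xs = (X - X.mean(axis=0)) / div
    elif scaling == "none":
        Xs = X - X.mean(axis=0)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")

    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    k = min(n_components or len(s), len(s))
    # deterministic signs: largest-|loading| entry positive per component
    for j in range(k):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u[:, :k] * s[:k]
    total_var = float(np.sum(Xs**2))
    evr = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=mat.columns, columns=comp_names),
        loadings=pd.DataFrame(vt[:k].T, index=feature_ids, columns=comp_names),
        explained_variance_ratio=evr,
        dropped_features=dropped,
    )


def volcano(
    table: FeatureTable,
    group_a: str,
    group_b: str,
    vip: pd.Series,
    p_threshold: float = 0.05,
    vip_threshold: float = 1.0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Per-feature fold change, Welch t-test and up/down/ns status.

    ``log2_fc`` is log2(mean(group_b) / mean(group_a)) on raw intensities
    — orientation B vs A, with B the comparison arm (model vs control, or
    treated vs model).  The p-value is a two-sample Welch t-test, on
    log-transformed intensities by default.  Features with a nonpositive
    group mean are excluded from the fold change (NaN, status ``ns``).

    Status is ``up`` iff log2_fc > 0, p < p_threshold and
    vip > vip_threshold; symmetric for ``down``; otherwise ``ns``.
    """
    groups = table.groups()
    a_cols = list(groups.index[groups == group_a])
    b_cols = list(groups.index[groups == group_b])
    if not a_cols or not b_cols:
        raise ValidationError(f"groups {group_a!r}/{group_b!r} not found")
    A = table.intensities[a_cols].to_numpy(dtype=float)
    B = table.intensities[b_cols].to_numpy(dtype=float)
    mean_a, mean_b = A.mean(axis=1), B.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.where(
            (mean_a > 0) & (mean_b > 0), np.log2(mean_b / mean_a), np.nan
        )
    n_excluded = int(np.isnan(log2_fc).sum())
    if n_excluded:
        log.warning("volcano: %d feature(s) with nonpositive group mean excluded "
                    "from fold change", n_excluded)
    if log_transform:
        with np.errstate(divide="ignore"):
            A = np.log(np.where(A > 0, A, np.nan))
            B = np.log(np.where(B > 0, B, np.nan))
    t_p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit").pvalue
    t_p = np.asarray(t_p, dtype=float)

    v = vip.reindex(table.intensities.index).to_numpy(dtype=float)
    sig = (t_p < p_threshold) & (v > vip_threshold) & ~np.isnan(log2_fc)
    status = np.where(
        sig & (log2_fc > 0), "up", np.where(sig & (log2_fc < 0), "down", "ns")
    )
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(t_p)
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p_value": t_p,
            "neg_log10_p": neg_log10_p,
            "vip": v,
            "status": status,
        },
        index=table.intensities.index,
    )


def screen_differential(volcano_records: pd.DataFrame) -> pd.DataFrame:
    """Differential features: p < 0.05 (strict) and VIP > 1 (strict).

    Thresholds are the ones already applied by :func:`volcano`; this
    simply selects the rows with status up or down, keeping the split.
    """
    out = volcano_records[volcano_records["status"].isin(["up", "down"])]
    log.info(
        "screen_differential: %d features -> %d differential (%d up, %d down)",
        len(volcano_records), len(out),
        int((out["status"] == "up").sum()), int((out["status"] == "down").sum()),
    )
    return out.copy()
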