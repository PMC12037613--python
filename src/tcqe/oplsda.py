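"""Orthogonal projections to latent structures discriminant analysis (OPLS-DA).

Two-class O-PLS with a single predictive component: orthogonal-variation
components (variation in X uncorrelated with the class vector y) are
stripped first, then one PLS component is fitted to the filtered matrix.
For a single response the algorithm is the classical orthogonal-signal-
correction sequence:

    w  = X'y / ||X'y||                      (predictive weight)
    repeat n_orthogonal times:
        t      = X w
        p      = X't / t't
        w_o    = p - (w'p) w ;  w_o /= ||w_o||
        t_o    = X w_o
        p_o    = X't_o / t_o't_o
        X     <- X - t_o p_o'
    t = X w ;  p = X't / t't ;  q = y't / t't

The predictive scores are orthogonal to every orthogonal score exactly
(t_o' (Xw - t_o p_o'w) = 0 by construction of p_o).

Model quality: R2X and R2Y on the full fit; Q2 by k-fold cross-validation
with venetian-blind fold assignment (samples ordered by injection within
each class, fold = rank mod k) so consecutive injections never share a
fold.  VIP is computed over the predictive component; with one component
VIP_j = sqrt(n_features) |w_j| / ||w||, so mean(VIP^2) = 1 identically.

Class labels are encoded +1/-1; X is mean-centred and unit-variance
scaled by default (pareto and no scaling available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


def _scale_matrix(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centre and scale columns; returns (Xs, mean, divisor)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        div = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        div = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "none":
        div = np.ones_like(sd)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    return (X - mean) / div, mean, div


def _opls_core(
    X: np.ndarray, y: np.ndarray, n_orthogonal: int
) -> dict[str, np.ndarray]:
    """Run the O-PLS sequence on preprocessed X, centred y."""
    w = X.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValidationError("OPLS: X carries no covariance with y")
    w = w / norm

    Xres = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orthogonal):
        t = Xres @ w
        p = Xres.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / n_o
        t_o = Xres @ w_o
        p_o = Xres.T @ t_o / (t_o @ t_o)
        Xres = Xres - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)

    t = Xres @ w
    p = Xres.T @ t / (t @ t)
    q = float(y @ t / (t @ t))
    return {
        "w": w,
        "t": t,
        "p": p,
        "q": q,
        "W_o": np.array(W_o),
        "T_o": np.array(T_o).T if T_o else np.empty((len(y), 0)),
        "P_o": np.array(P_o),
    }


@dataclass
class OplsdaModel:
    """Fitted two-class O-PLS model."""

    scores: np.ndarray            # predictive scores t, one per sample
    loadings: np.ndarray          # predictive loadings p
    weights: np.ndarray           # predictive weights w (unit norm)
    q: float                      # y-loading of the predictive component
    orthogonal_scores: np.ndarray    # (n_samples, n_orthogonal)
    orthogonal_loadings: np.ndarray  # (n_orthogonal, n_features)
    orthogonal_weights: np.ndarray
    r2x: float
    r2y: float
    q2: float
    vip: np.ndarray
    classes: tuple[str, str]      # labels encoded (-1, +1)
    feature_ids: list[str]
    x_mean: np.ndarray = field(repr=False, default=None)
    x_div: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0

    @property
    def n_orthogonal(self) -> int:
        return self.orthogonal_scores.shape[1]


def _encode_classes(groups: pd.Series) -> tuple[np.ndarray, tuple[str, str]]:
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValidationError(f"OPLS-DA needs exactly 2 groups, got {labels}")
    y = np.where(groups.to_numpy() == labels[1], 1.0, -1.0)
    return y, (labels[0], labels[1])


def _venetian_blind_folds(
    groups: np.ndarray, order: np.ndarray, k: int
) -> np.ndarray:
    """Fold ids: within each class, samples sorted by injection order get
    folds 0,1,...,k-1,0,1,... (venetian blind, stratified)."""
    folds = np.empty(len(groups), dtype=int)
    for g in np.unique(groups):
        idx = np.where(groups == g)[0]
        ranked = idx[np.argsort(order[idx], kind="stable")]
        folds[ranked] = np.arange(len(ranked)) % k
    return folds


def _q2_cv(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    order: np.ndarray,
    n_orthogonal: int,
    cv_folds: int,
    scaling: str,
) -> float:
    folds = _venetian_blind_folds(groups, order, cv_folds)
    press = 0.0
    y_centred = y - y.mean()
    for f in np.unique(folds):
        train, test = folds != f, folds == f
        Xtr, mean, div = _scale_matrix(X[train], scaling)
        ytr = y[train]
        ym = ytr.mean()
        core = _opls_core(Xtr, ytr - ym, n_orthogonal)
        Xte = (X[test] - mean) / div
        # strip orthogonal variation from the held-out rows
        for w_o, p_o in zip(core["W_o"], core["P_o"]):
            t_o = Xte @ w_o
            Xte = Xte - np.outer(t_o, p_o)
        y_hat = Xte @ core["w"] * core["q"] + ym
        press += float(np.sum((y[test] - y_hat) ** 2))
    ssy = float(np.sum(y_centred**2))
    return 1.0 - press / ssy


def fit_oplsda(
    table: pd.DataFrame,
    groups: pd.Series,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    scaling: str = "uv",
    injection_order: pd.Series | None = None,
    compute_q2: bool = True,
) -> OplsdaModel:
    """Fit OPLS-DA on a features x samples table for a two-class contrast.

    Parameters
    ----------
    table
        Intensity matrix, features in rows, samples in columns.
    groups
        Class label per sample (index must match the table columns);
        exactly two distinct labels, each with >= 3 samples.
    injection_order
        Used only for venetian-blind fold assignment; defaults to the
        column order of ``table``.
    """
    samples = list(table.columns)
    groups = groups.reindex(samples)
    if groups.isna().any():
        raise ValidationError("group label missing for some samples")
    y, classes = _encode_classes(groups)
    counts = pd.Series(groups).value_counts()
    if (counts < 3).any():
        raise ValidationError(
            f"each group needs >= 3 samples for cross-validation, got {dict(counts)}"
        )
    X = table.to_numpy(dtype=float).T  # samples x features
    Xs, mean, div = _scale_matrix(X, scaling)
    ym = float(y.mean())
    yc = y - ym
    core = _opls_core(Xs, yc, n_orthogonal)

    t, p, q = core["t"], core["p"], core["q"]
    ssx = float(np.sum(Xs**2))
    ssy = float(np.sum(yc**2))
    explained_x = float(t @ t) * float(p @ p)
    for j in range(core["T_o"].shape[1]):
        t_o = core["T_o"][:, j]
        p_o = core["P_o"][j]
        explained_x += float(t_o @ t_o) * float(p_o @ p_o)
    r2x = explained_x / ssx
    y_hat = t * q
    r2y = 1.0 - float(np.sum((yc - y_hat) ** 2)) / ssy

    if injection_order is None:
        order = np.arange(len(samples), dtype=float)
    else:
        order = injection_order.reindex(samples).to_numpy(dtype=float)
    q2 = (
        _q2_cv(X, y, groups.to_numpy(), order, n_orthogonal, cv_folds, scaling)
        if compute_q2
        else np.nan
    )

    w = core["w"]
    n_feat = Xs.shape[1]
    vip = np.sqrt(n_feat) * np.abs(w) / np.linalg.norm(w)

    return OplsdaModel(
        scores=t,
        loadings=p,
        weights=w,
        q=q,
        orthogonal_scores=core["T_o"],
        orthogonal_loadings=core["P_o"] if core["P_o"].size else np.empty((0, n_feat)),
        orthogonal_weights=core["W_o"] if core["W_o"].size else np.empty((0, n_feat)),
        r2x=r2x,
        r2y=r2y,
        q2=q2,
        vip=vip,
        classes=classes,
        feature_ids=list(table.index),
        x_mean=mean,
        x_div=div,
        y_mean=ym,
    )


def vip(model: OplsdaModel) -> pd.Series:
    """Per-feature variable importance in projection (predictive component).

    With a single predictive component the weighted sum over components
    collapses and VIP_j = sqrt(n_features) |w_j| / ||w||; the mean of
    VIP^2 over features is exactly 1.
    """
    return pd.Series(model.vip, index=model.feature_ids, name="vip")


@dataclass
class PermutationReport:
    n_permutations: int
    r2y_observed: float
    q2_observed: float
    r2y_permuted: np.ndarray
    q2_permuted: np.ndarray
    q2_max_permuted: float
    p_empirical: float
    q2_intercept: float
    passed: bool                 # max permuted Q2 < observed Q2


def permutation_test(
    table: pd.DataFrame,
    groups: pd.Series,
    n_permutations: int = 200,
    seed: int = 0,
    n_orthogonal: int = 1,
    cv_folds: int = 7,
    scaling: str = "uv",
    injection_order: pd.Series | None = None,
) -> PermutationReport:
    """Label-permutation test of OPLS-DA model validity.

    The class vector is shuffled ``n_permutations`` times (seeded); the
    model is refitted each time and R2Y/Q2 recorded.  The empirical p for
    Q2 is (1 + #{Q2_perm >= Q2_obs}) / (1 + n_permutations).  The pass
    flag is the max criterion (every permuted Q2 below the observed one);
    the regression intercept of permuted Q2 against the label-vector
    correlation is also reported as the classical intercept diagnostic.
    """
    rng = np.random.default_rng(seed)
    observed = fit_oplsda(
        table, groups, n_orthogonal, cv_folds, scaling, injection_order
    )
    samples = list(table.columns)
    labels = groups.reindex(samples).to_numpy()
    y_true = np.where(labels == sorted(set(labels))[1], 1.0, -1.0)

    r2y_perm = np.empty(n_permutations)
    q2_perm = np.empty(n_permutations)
    corr = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(labels))
        shuffled = pd.Series(labels[perm], index=samples)
        try:
            m = fit_oplsda(
                table, shuffled, n_orthogonal, cv_folds, scaling, injection_order
            )
            r2y_perm[i], q2_perm[i] = m.r2y, m.q2
        except ValidationError:
            r2y_perm[i], q2_perm[i] = np.nan, np.nan
        y_p = np.where(labels[perm] == sorted(set(labels))[1], 1.0, -1.0)
        corr[i] = abs(float(np.corrcoef(y_true, y_p)[0, 1]))

    ok = ~np.isnan(q2_perm)
    q2_ok = q2_perm[ok]
    q2_max = float(np.max(q2_ok)) if q2_ok.size else np.nan
    p_emp = (1.0 + int(np.sum(q2_ok >= observed.q2))) / (1.0 + int(ok.sum()))
    # intercept of the permuted-Q2 vs label-correlation regression at corr=0,
    # anchored through the observed point at corr=1
    xs = np.concatenate([corr[ok], [1.0]])
    ys = np.concatenate([q2_ok, [observed.q2]])
    slope, intercept = np.polyfit(xs, ys, 1)
    return PermutationReport(
        n_permutations=n_permutations,
        r2y_observed=observed.r2y,
        q2_observed=observed.q2,
        r2y_permuted=r2y_perm,
        q2_permuted=q2_perm,
        q2_max_permuted=q2_max,
        p_empirical=p_emp,
        q2_intercept=float(intercept),
        passed=bool(q2_max < observed.q2),
    )
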