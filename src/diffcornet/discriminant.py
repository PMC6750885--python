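"""OPLS-DA, VIP, S-plot, univariate screening and regression association.

Orthogonal projections to latent structures discriminant analysis (OPLS-DA)
separates class-predictive variation from class-orthogonal variation.  The
implementation is the standard single-response NIPALS formulation: the
predictive weight vector ``w ∝ Xᵀu`` (u the centred class indicator) is
computed once; each orthogonal component is extracted from the loading of
the current predictive score and deflated from X; the predictive component
is then fit on the filtered matrix.  With zero orthogonal components the
model coincides with a one-component PLS-DA fit.

VIP (variable importance in projection) is computed on the predictive
component; with a single component it reduces to ``sqrt(m) * |w_j|`` for
the unit-norm weight vector, so the mean squared VIP is exactly 1.

Q² is the cross-validated explained variation of the class response,
``1 - PRESS/TSS``, over stratified folds.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigurationError, DataError


def _encode_classes(y) -> tuple[np.ndarray, list]:
    y = np.asarray(y)
    classes = sorted(pd.unique(y).tolist())
    if len(classes) != 2:
        raise DataError(f"OPLS-DA requires exactly two classes, got {classes}")
    return (y == classes[1]).astype(float), classes


@dataclasses.dataclass
class OplsdaModel:
    """Fitted OPLS-DA model (one predictive, ``n_orth`` orthogonal components)."""

    metabolites: list[str]
    classes: list
    weights: np.ndarray            # predictive weight vector, unit norm
    scores: np.ndarray             # predictive scores t
    loadings: np.ndarray           # predictive loadings p
    coef: float                    # inner-relation coefficient c (y ≈ t·c)
    y_mean: float
    orth_weights: np.ndarray       # (n_orth, m)
    orth_scores: np.ndarray        # (n, n_orth)
    orth_loadings: np.ndarray      # (n_orth, m)
    r2x: float
    r2y: float

    @property
    def n_orth(self) -> int:
        return self.orth_scores.shape[1]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new observations after orthogonal filtering."""
        X = np.array(X, dtype=float)
        for k in range(self.n_orth):
            t_o = X @ self.orth_weights[k]
            X = X - np.outer(t_o, self.orth_loadings[k])
        return X @ self.weights

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted (continuous) class response for new observations."""
        return self.transform(X) * self.coef + self.y_mean


def fit_oplsda(X, y, n_orth: int = 1, metabolites: list[str] | None = None) -> OplsdaModel:
    """Fit OPLS-DA on a column-standardized matrix and binary labels.

    Deterministic (fixed deflation order, no randomness).  ``n_orth = 0``
    reduces to a one-component PLS-DA fit.
    """
    X = np.array(X, dtype=float)
    if X.ndim != 2:
        raise DataError("X must be a 2-D samples x metabolites matrix")
    n, m = X.shape
    if n_orth < 0:
        raise ConfigurationError("n_orth must be non-negative")
    if n < n_orth + 2:
        raise DataError(f"need at least n_orth + 2 = {n_orth + 2} samples, got {n}")
    u, classes = _encode_classes(y)
    if metabolites is None:
        metabolites = [f"X{k}" for k in range(m)]
    y_mean = float(u.mean())
    u = u - y_mean

    ssx_total = float((X * X).sum())
    w = X.T @ u
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DataError("class response is orthogonal to every metabolite")
    w = w / norm

    Xr = X.copy()
    orth_w, orth_t, orth_p = [], [], []
    for _ in range(n_orth):
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        w_o_norm = np.linalg.norm(w_o)
        if w_o_norm < 1e-12:
            raise DataError("n_orth too large for the rank of X")
        w_o = w_o / w_o_norm
        t_o = Xr @ w_o
        p_o = Xr.T @ t_o / (t_o @ t_o)
        Xr = Xr - np.outer(t_o, p_o)
        orth_w.append(w_o)
        orth_t.append(t_o)
        orth_p.append(p_o)

    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    c = float((u @ t) / (t @ t))
    r2x = float((t @ t) * (p @ p) / ssx_total)
    ssy = float(u @ u)
    r2y = float(1.0 - ((u - t * c) @ (u - t * c)) / ssy) if ssy > 0 else 0.0

    return OplsdaModel(
        metabolites=list(metabolites),
        classes=classes,
        weights=w,
        scores=t,
        loadings=p,
        coef=c,
        y_mean=y_mean,
        orth_weights=np.array(orth_w).reshape(n_orth, m),
        orth_scores=np.column_stack(orth_t) if orth_t else np.empty((n, 0)),
        orth_loadings=np.array(orth_p).reshape(n_orth, m),
        r2x=r2x,
        r2y=r2y,
    )


def vip_scores(model: OplsdaModel) -> pd.Series:
    """VIP on the predictive component; the mean squared VIP is exactly 1."""
    m = len(model.metabolites)
    vip = math.sqrt(m) * np.abs(model.weights)
    return pd.Series(vip, index=model.metabolites, name="vip")


def splot(model: OplsdaModel, X) -> pd.DataFrame:
    """S-plot coordinates: covariance and correlation of each column with t.

    Columns orthogonal to the predictive score map to (0, 0); the two
    coordinates always share their sign.
    """
    X = np.asarray(X, dtype=float)
    t = model.scores
    tc = t - t.mean()
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    cov = Xc.T @ tc / (n - 1)
    denom = Xc.std(axis=0, ddof=1) * tc.std(ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.DataFrame(
        {"covariance": cov, "correlation": corr}, index=model.metabolites
    )


def cross_validated_q2(
    X, y, folds: int = 7, seed: int = 0, n_orth: int = 1
) -> float:
    """Stratified k-fold cross-validated Q² = 1 − PRESS/TSS.

    Folds are stratified by class with seeded assignment so that both
    classes appear in every training split; per fold, columns are re-centred
    and re-scaled with training statistics before fitting.
    """
    X = np.asarray(X, dtype=float)
    u, _ = _encode_classes(y)
    if folds < 2:
        raise ConfigurationError("folds must be at least 2")
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(u == cls)
        if len(idx) < folds:
            raise DataError("each class needs at least `folds` samples for stratification")
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % folds
    press = 0.0
    tss = 0.0
    for k in range(folds):
        test = fold_of == k
        train = ~test
        if len(np.unique(u[train])) < 2:
            raise DataError(f"fold {k} lost a class; check stratification inputs")
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (X[train] - mu) / sd
        Xte = (X[test] - mu) / sd
        model = fit_oplsda(Xtr, u[train], n_orth=n_orth)
        pred = model.predict(Xte)
        press += float(((u[test] - pred) ** 2).sum())
        tss += float(((u[test] - u[train].mean()) ** 2).sum())
    return 1.0 - press / tss


def truncate_sigfigs(x: float, digits: int = 2) -> float:
    """Truncate (not round) to the leading significant digits.

    ``truncate_sigfigs(0.05/168, 2)`` is ``2.9e-4`` — the conventional way
    a Bonferroni threshold is displayed.
    """
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - digits + 1)
    return math.trunc(x / scale) * scale


@dataclasses.dataclass
class ScreenResult:
    """Joint VIP/univariate screen over the panel."""

    table: pd.DataFrame            # per metabolite: vip, p_value, passed
    alpha: float
    threshold_exact: float         # alpha / m
    threshold_printed: float       # truncated to 2 significant digits

    @property
    def passing(self) -> list[str]:
        return self.table.index[self.table["passed"]].tolist()


def screen_metabolites(
    X, y, model: OplsdaModel, alpha: float = 0.05, vip_threshold: float = 1.0
) -> ScreenResult:
    """Joint criterion: VIP > 1 and Welch-t p below the Bonferroni threshold.

    Both inequalities are strict; the per-test threshold is ``alpha / m``
    for the m metabolites screened (reported exactly and truncated to two
    significant digits, the form in which such thresholds are printed).
    """
    X = np.asarray(X, dtype=float)
    u, _ = _encode_classes(y)
    m = X.shape[1]
    threshold = alpha / m
    vip = vip_scores(model)
    p_values = stats.ttest_ind(X[u == 0], X[u == 1], equal_var=False).pvalue
    table = pd.DataFrame(
        {
            "vip": vip.to_numpy(),
            "p_value": p_values,
        },
        index=model.metabolites,
    )
    table["passed"] = (table["vip"] > vip_threshold) & (table["p_value"] < threshold)
    return ScreenResult(
        table=table,
        alpha=alpha,
        threshold_exact=threshold,
        threshold_printed=truncate_sigfigs(threshold, 2),
    )


def associate(adjusted_X: pd.DataFrame, y, candidates: list[str]) -> pd.DataFrame:
    """OLS of each covariate-adjusted candidate on the binary group indicator.

    The slope equals the between-group difference of means of the adjusted
    values; the two-sided slope p-value is reported.
    """
    u, classes = _encode_classes(y)
    absent = [c for c in candidates if c not in adjusted_X.columns]
    if absent:
        raise DataError(f"candidates not present in the adjusted matrix: {absent}")
    design = sm.add_constant(u)
    rows = {}
    for name in candidates:
        fit = sm.OLS(adjusted_X[name].to_numpy(float), design).fit()
        rows[name] = {"slope": float(fit.params[1]), "p_value": float(fit.pvalues[1])}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.attrs["reference_class"] = classes[0]
    return frame
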