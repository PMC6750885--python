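"""Preprocessing chain for two-group targeted metabolomics panels.

Fixed pipeline order (mirroring the standard targeted-panel workflow this
package implements):

1. :func:`filter_metabolites` — keep metabolites quantified in at least 80%
   of samples;
2. :func:`impute_below_lod` — replace below-LOD entries by half the minimum
   quantified concentration of that metabolite (both groups pooled);
3. :func:`adjust_covariates` — replace each metabolite by the residuals of
   an OLS regression on the covariates (fit on both groups pooled);
4. :func:`impute_missing` — fill missing entries (rate below 5% per
   metabolite) with the all-sample mean; drop metabolites at/above 5%;
5. :func:`normalize` — z-score each metabolite to mean 0, SD 1.

:func:`run_preprocessing` applies the chain and returns a machine-readable
report of what was dropped, imputed and fitted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .tables import (
    BELOW_LOD,
    COVARIATE_COLUMNS,
    GROUP_POST,
    GROUP_PRE,
    IMPUTED_LOD,
    IMPUTED_MEAN,
    MISSING,
    QUANTIFIED,
    SampleTable,
)

logger = logging.getLogger(__name__)

#: absolute tolerance for exactness claims (zero-mean residuals, unit SD)
ATOL = 1e-8


def filter_metabolites(table: SampleTable, min_fraction: float = 0.8) -> SampleTable:
    """Keep metabolites measurable (quantified) in ``>= min_fraction`` of samples.

    The boundary is inclusive: a metabolite quantified in exactly 80 of 100
    samples is retained at the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise DataError("min_fraction must lie in (0, 1]")
    frac = table.measurable_fraction()
    keep = frac[frac >= min_fraction].index
    dropped = [c for c in table.metabolites if c not in set(keep)]
    if len(keep) == 0:
        raise DataError(
            "all metabolites fall below the measurability threshold; "
            "review min_fraction or the input panel"
        )
    if dropped:
        logger.info("filter_metabolites dropped %d metabolites: %s", len(dropped), dropped)
    return SampleTable(table.metadata.copy(), table.values[keep].copy(), table.status[keep].copy())


def impute_below_lod(table: SampleTable) -> SampleTable:
    """Replace below-LOD entries by half the minimum quantified level.

    The minimum is taken over quantified entries of both groups pooled.  A
    metabolite whose entries are all below LOD has no quantified minimum and
    raises :class:`DataError`.
    """
    out = table.copy()
    for col in out.metabolites:
        lod_mask = out.status[col] == BELOW_LOD
        if not lod_mask.any():
            continue
        quantified = out.values[col][out.status[col] == QUANTIFIED]
        if quantified.empty:
            raise DataError(
                f"metabolite {col!r} is entirely below LOD: no minimum quantified level"
            )
        fill = 0.5 * float(quantified.min())
        out.values.loc[lod_mask, col] = fill
        out.status.loc[lod_mask, col] = IMPUTED_LOD
    return out


def adjust_covariates(
    table: SampleTable, covariates: list[str] | None = None
) -> SampleTable:
    """Replace metabolite values by residuals of OLS on the covariates.

    The fit uses an intercept plus the requested covariates, on both groups
    pooled; entries that are still missing are excluded from the fit and
    remain missing.  Residuals have zero sample correlation with every
    covariate (to numerical tolerance) by OLS orthogonality.
    """
    covariates = list(COVARIATE_COLUMNS) if covariates is None else list(covariates)
    absent = [c for c in covariates if c not in table.metadata.columns]
    if absent:
        raise DataError(f"covariates not present in metadata: {absent}")
    design = np.column_stack(
        [np.ones(table.n_samples)] + [table.metadata[c].to_numpy(float) for c in covariates]
    )
    p = design.shape[1]
    if np.linalg.matrix_rank(design) < p:
        collinear = _collinear_columns(design, covariates)
        raise DataError(f"rank-deficient covariate design; collinear covariates: {collinear}")
    if table.n_samples < p:
        raise DataError("fewer samples than regression parameters")

    out = table.copy()
    for col in out.metabolites:
        y = out.values[col].to_numpy(float)
        mask = ~np.isnan(y)
        if mask.sum() < p:
            raise DataError(f"metabolite {col!r}: fewer observed samples than parameters")
        beta, *_ = np.linalg.lstsq(design[mask], y[mask], rcond=None)
        resid = y.copy()
        resid[mask] = y[mask] - design[mask] @ beta
        out.values[col] = resid
    return out


def impute_missing(table: SampleTable, max_missing: float = 0.05) -> SampleTable:
    """Mean-impute missing entries; drop metabolites missing at/above 5%.

    Metabolites with a missing fraction below ``max_missing`` have missing
    entries replaced by the all-sample mean of that metabolite; metabolites
    at or above the threshold are dropped with a logged warning.
    """
    out = table.copy()
    missing_frac = (out.status == MISSING).mean(axis=0)
    drop = list(missing_frac[missing_frac >= max_missing].index)
    if drop:
        logger.warning(
            "impute_missing dropping %d metabolites at >= %.0f%% missing: %s",
            len(drop), 100 * max_missing, drop,
        )
        keep = [c for c in out.metabolites if c not in set(drop)]
        out = SampleTable(out.metadata, out.values[keep].copy(), out.status[keep].copy())
    for col in out.metabolites:
        miss = out.status[col] == MISSING
        if not miss.any():
            continue
        fill = float(out.values[col].mean(skipna=True))
        out.values.loc[miss, col] = fill
        out.status.loc[miss, col] = IMPUTED_MEAN
    return out


def normalize(table: SampleTable) -> SampleTable:
    """Standardize each metabolite to mean 0 and unit SD over all samples."""
    out = table.copy()
    vals = out.values
    if vals.isna().any().any():
        raise DataError("normalize requires a table with no missing entries")
    sd = vals.std(axis=0, ddof=1)
    zero_var = list(sd[sd == 0].index)
    if zero_var:
        raise DataError(f"zero-variance metabolites cannot be normalized: {zero_var}")
    out.values = (vals - vals.mean(axis=0)) / sd
    return out


def summarize_cohort(table: SampleTable) -> pd.DataFrame:
    """Per-covariate group means ± SD and a Welch two-sample t-test p-value.

    Descriptive only; returns a DataFrame indexed by covariate with columns
    ``mean_pre, sd_pre, mean_post, sd_post, p_value`` plus the group counts
    in ``.attrs["n_pre"]`` / ``.attrs["n_post"]``.
    """
    sizes = table.group_sizes()
    if min(sizes.values()) < 2:
        raise DataError("each group needs at least 2 samples to summarize (SD undefined)")
    pre = table.metadata.loc[table.group_mask(GROUP_PRE)]
    post = table.metadata.loc[table.group_mask(GROUP_POST)]
    rows = {}
    for cov in COVARIATE_COLUMNS:
        a, b = pre[cov].to_numpy(float), post[cov].to_numpy(float)
        t = stats.ttest_ind(a, b, equal_var=False)
        rows[cov] = {
            "mean_pre": a.mean(), "sd_pre": a.std(ddof=1),
            "mean_post": b.mean(), "sd_post": b.std(ddof=1),
            "p_value": float(t.pvalue),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.attrs["n_pre"] = sizes[GROUP_PRE]
    summary.attrs["n_post"] = sizes[GROUP_POST]
    return summary


def run_preprocessing(
    table: SampleTable,
    min_fraction: float = 0.8,
    covariates: list[str] | None = None,
    max_missing: float = 0.05,
) -> tuple[SampleTable, dict]:
    """Apply the full fixed-order chain and report what happened."""
    report: dict = {"order": [
        "filter_metabolites", "impute_below_lod", "adjust_covariates",
        "impute_missing", "normalize",
    ]}
    before = set(table.metabolites)
    filtered = filter_metabolites(table, min_fraction=min_fraction)
    report["dropped_low_measurability"] = sorted(before - set(filtered.metabolites))
    report["n_below_lod_imputed"] = int((filtered.status == BELOW_LOD).to_numpy().sum())
    lod_filled = impute_below_lod(filtered)
    adjusted = adjust_covariates(lod_filled, covariates=covariates)
    report["covariates"] = list(COVARIATE_COLUMNS) if covariates is None else list(covariates)
    report["n_missing_imputed"] = int((adjusted.status == MISSING).to_numpy().sum())
    imputed = impute_missing(adjusted, max_missing=max_missing)
    report["dropped_high_missingness"] = sorted(
        set(adjusted.metabolites) - set(imputed.metabolites)
    )
    normalized = normalize(imputed)
    report["n_metabolites_retained"] = normalized.n_metabolites
    report["n_samples"] = normalized.n_samples
    report["group_sizes"] = normalized.group_sizes()
    return normalized, report


def _collinear_columns(design: np.ndarray, covariates: list[str]) -> list[str]:
    """Name covariates involved in exact collinearity (best effort)."""
    names = []
    for k in range(1, design.shape[1]):
        reduced = np.delete(design, k, axis=1)
        if np.linalg.matrix_rank(reduced) == np.linalg.matrix_rank(design):
            names.append(covariates[k - 1])
    return names or covariates
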