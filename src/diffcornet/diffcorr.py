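"""Differential correlation statistics with a permutation null.

For metabolites *i*, *j* with within-group Pearson correlations
``r_pre(i,j)`` and ``r_post(i,j)``, the differential correlation is the
weighted difference of Fisher z-transforms

    r_diff(i,j) = sqrt((n_pre - 3)/2) * z_pre(i,j)
                - sqrt((n_post - 3)/2) * z_post(i,j)

where ``z = atanh(r)``.  Since ``z`` has sampling variance ``1/(n-3)``,
each weighted term has variance 1/2 under independent sampling and
``r_diff`` is approximately standard normal under the no-difference null
for any pair of group sizes.  Significance is assessed with a two-sided
group-label permutation test that preserves group sizes and reuses one
shared set of permutations across all pairs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .tables import GROUP_PRE, SampleTable

logger = logging.getLogger(__name__)

Direction = Literal["pre_minus_post", "post_minus_pre"]


def fisher_z(r):
    """Fisher z-transformation ``z = 0.5 * ln((1+r)/(1-r))``.

    Odd function of ``r``; raises on ``|r| >= 1`` (no silent clamping —
    callers must handle degenerate perfect correlation explicitly).
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise DataError("fisher_z requires |r| < 1 (perfect correlation is degenerate)")
    out = np.arctanh(r)
    return out.item() if out.ndim == 0 else out


def differential_correlation(
    r_pre, r_post, n_pre: int, n_post: int, direction: Direction = "pre_minus_post"
):
    """Weighted Fisher-z difference of two group correlations.

    ``direction`` flips the reported sign; the default subtracts the
    post-group term from the pre-group term.
    """
    if n_pre <= 3 or n_post <= 3:
        raise DataError("differential correlation requires n > 3 in each group")
    w_pre = np.sqrt((n_pre - 3) / 2.0)
    w_post = np.sqrt((n_post - 3) / 2.0)
    d = w_pre * fisher_z(r_pre) - w_post * fisher_z(r_post)
    return -d if direction == "post_minus_pre" else d


@dataclasses.dataclass
class GroupCorrelation:
    """Within-group Pearson correlation matrix with per-pair test p-values."""

    group: str
    n: int
    r: pd.DataFrame
    p: pd.DataFrame

    def pair_count(self) -> int:
        m = self.r.shape[0]
        return m * (m - 1) // 2


@dataclasses.dataclass
class DifferentialEdge:
    """One metabolite pair's differential-correlation record."""

    met_i: str
    met_j: str
    r_pre: float
    r_post: float
    z_pre: float
    z_post: float
    r_diff: float
    p_perm: float

    @property
    def sign(self) -> str:
        return "negative" if self.r_diff < 0 else "positive"

    @property
    def pair(self) -> tuple[str, str]:
        return (self.met_i, self.met_j)


@dataclasses.dataclass
class PermutationPlan:
    """Group-label permutation scheme.

    ``n_permutations`` draws (default 1000) of a relabeling with exactly the
    observed group sizes; the same permutations are reused across all pairs.
    Explicit ``permutations`` (one row per permutation, each a permutation
    of ``range(n)``, with the first ``n_pre`` positions assigned to the pre
    group) override seeded generation — used for oracle fixtures.
    """

    n_permutations: int = 1000
    seed: int = 0
    permutations: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.permutations is None and self.n_permutations < 1:
            raise ConfigurationError("need at least one permutation")

    def realize(self, n: int) -> np.ndarray:
        """Materialize the permutation index matrix (B x n)."""
        if self.permutations is not None:
            perms = np.asarray(self.permutations)
            if perms.ndim != 2 or perms.shape[1] != n:
                raise ConfigurationError("explicit permutations must have shape (B, n)")
            expected = np.arange(n)
            for row in perms:
                if not np.array_equal(np.sort(row), expected):
                    raise ConfigurationError("each row must be a permutation of range(n)")
            return perms
        rng = np.random.default_rng(self.seed)
        return np.array([rng.permutation(n) for _ in range(self.n_permutations)])


def _group_matrix(table: SampleTable, group: str) -> np.ndarray:
    X = table.values_for(group).to_numpy(float)
    if X.shape[0] <= 3:
        raise DataError(f"group {group!r} needs more than 3 samples")
    if np.isnan(X).any():
        raise DataError("correlation analysis requires a fully imputed table")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [table.metabolites[k] for k in np.flatnonzero(sd == 0)]
        raise DataError(f"zero variance within group {group!r}: {bad}")
    return X


def pairwise_correlations(table: SampleTable, group: str) -> GroupCorrelation:
    """Full symmetric Pearson matrix plus two-sided test p-values for a group.

    For *m* metabolites the unordered pair count is ``m(m-1)/2``.
    """
    X = _group_matrix(table, group)
    n = X.shape[0]
    names = table.metabolites
    r = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, np.nan)
    return GroupCorrelation(
        group=group,
        n=n,
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names),
    )


def significant_pairs(corr: GroupCorrelation, alpha: float = 0.05) -> set[tuple[str, str]]:
    """Bonferroni-screened correlated pairs: raw p < alpha / (full pair count).

    The divisor is the full ``m(m-1)/2`` pair count of the matrix; the
    inequality is strict.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must lie in (0, 1)")
    names = list(corr.r.columns)
    m = len(names)
    threshold = alpha / (m * (m - 1) / 2)
    p = corr.p.to_numpy()
    iu = np.triu_indices(m, k=1)
    hits = np.flatnonzero(p[iu] < threshold)
    return {
        tuple(sorted((names[iu[0][k]], names[iu[1][k]]))) for k in hits
    }


def overlap_fraction(
    pre_set: Iterable[tuple[str, str]], post_set: Iterable[tuple[str, str]]
) -> float:
    """Fraction of pre-group correlated pairs also correlated in the post group."""
    pre_set, post_set = set(pre_set), set(post_set)
    if not pre_set:
        logger.info("overlap_fraction: empty pre-group pair set; returning 0.0")
        return 0.0
    return len(pre_set & post_set) / len(pre_set)


def _rdiff_upper(
    X: np.ndarray, pre_idx: np.ndarray, post_idx: np.ndarray, iu, w_pre: float, w_post: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle r_pre, r_post and weighted z-difference for one labeling."""
    r_pre = np.corrcoef(X[pre_idx], rowvar=False)[iu]
    r_post = np.corrcoef(X[post_idx], rowvar=False)[iu]
    if np.any(np.abs(r_pre) >= 1) or np.any(np.abs(r_post) >= 1):
        raise DataError("perfect within-group correlation encountered; data degenerate")
    return r_pre, r_post, w_pre * np.arctanh(r_pre) - w_post * np.arctanh(r_post)


def permutation_test(
    table: SampleTable,
    plan: PermutationPlan | None = None,
    direction: Direction = "pre_minus_post",
) -> list[DifferentialEdge]:
    """Observed r_diff for every pair plus a two-sided permutation p-value.

    ``p_perm = (1 + #{b : |r_diff_b| >= |r_diff_obs|}) / (B + 1)`` over B
    group-size-preserving label permutations (add-one estimator, never
    zero).  One shared permutation set serves all pairs; seeded runs are
    bit-reproducible.
    """
    plan = PermutationPlan() if plan is None else plan
    X = table.values.to_numpy(float)
    if np.isnan(X).any():
        raise DataError("permutation test requires a fully imputed table")
    names = table.metabolites
    m = len(names)
    pre_mask = table.group_mask(GROUP_PRE)
    n_pre = int(pre_mask.sum())
    n_post = int((~pre_mask).sum())
    if n_pre <= 3 or n_post <= 3:
        raise DataError("both groups need more than 3 samples")
    w_pre = np.sqrt((n_pre - 3) / 2.0)
    w_post = np.sqrt((n_post - 3) / 2.0)
    iu = np.triu_indices(m, k=1)

    obs_pre_idx = np.flatnonzero(pre_mask)
    obs_post_idx = np.flatnonzero(~pre_mask)
    r_pre, r_post, d_obs = _rdiff_upper(X, obs_pre_idx, obs_post_idx, iu, w_pre, w_post)

    perms = plan.realize(X.shape[0])
    exceed = np.zeros(d_obs.shape[0], dtype=np.int64)
    abs_obs = np.abs(d_obs)
    for row in perms:
        _, _, d_b = _rdiff_upper(X, row[:n_pre], row[n_pre:], iu, w_pre, w_post)
        exceed += np.abs(d_b) >= abs_obs
    B = perms.shape[0]
    p_perm = (1.0 + exceed) / (B + 1.0)

    sign_flip = -1.0 if direction == "post_minus_pre" else 1.0
    edges = []
    for k in range(d_obs.shape[0]):
        i, j = int(iu[0][k]), int(iu[1][k])
        met_i, met_j = sorted((names[i], names[j]))
        edges.append(
            DifferentialEdge(
                met_i=met_i,
                met_j=met_j,
                r_pre=float(r_pre[k]),
                r_post=float(r_post[k]),
                z_pre=float(np.arctanh(r_pre[k])),
                z_post=float(np.arctanh(r_post[k])),
                r_diff=float(sign_flip * d_obs[k]),
                p_perm=float(p_perm[k]),
            )
        )
    return edges


def select_edges(
    edges: list[DifferentialEdge], p_threshold: float = 0.01
) -> list[DifferentialEdge]:
    """Edges with ``p_perm <= p_threshold`` (inclusive), ranked by |r_diff|.

    Ties are broken by the (met_i, met_j) name pair.
    """
    if not 0 < p_threshold <= 1:
        raise ConfigurationError("p_threshold must lie in (0, 1]")
    selected = [e for e in edges if e.p_perm <= p_threshold]
    return sorted(selected, key=lambda e: (-abs(e.r_diff), e.met_i, e.met_j))


def edges_to_frame(edges: list[DifferentialEdge]) -> pd.DataFrame:
    """Tabulate edges (met_i, met_j, r_pre, r_post, z_pre, z_post, r_diff, p_perm)."""
    cols = ["met_i", "met_j", "r_pre", "r_post", "z_pre", "z_post", "r_diff", "p_perm"]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} | {"sign": e.sign} for e in edges],
        columns=cols + ["sign"],
    )


def write_edges(edges: list[DifferentialEdge], path: str | Path) -> None:
    """Write the full per-pair results table as CSV."""
    edges_to_frame(edges).to_csv(path, index=False)
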