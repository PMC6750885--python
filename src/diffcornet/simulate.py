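"""Two-group synthetic metabolomics panels with known differential structure.

The generator emulates a targeted plasma panel of the Biocrates-p180 kind:
positive, right-skewed concentrations for ~170 metabolites measured in two
groups of women (pre- and post-menopausal), with

* shared "housekeeping" correlation blocks present in both groups,
* a configurable set of planted group-specific (differentially correlated)
  metabolite pairs,
* covariates (age differs by group; BMI, physical-activity score and age of
  menarche are group-invariant by default) that can optionally confound
  metabolite levels through linear effects,
* below-LOD censoring of the lowest quantile of each metabolite, and
* a small fraction of missing entries.

Concentrations are generated on a log scale and exponentiated, so planted
correlations live on the latent (log) scale; because the mapping from
latent values to log-concentrations is affine per metabolite, the Pearson
correlation of log concentrations equals the latent correlation exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .tables import (
    BELOW_LOD,
    GROUP_POST,
    GROUP_PRE,
    MISSING,
    QUANTIFIED,
    SampleTable,
)

# Cohort parameters of the emulated study: group sizes and age structure of
# pre- vs post-menopausal women, plus panel-wide covariate distributions.
DEFAULT_N_PRE = 55
DEFAULT_N_POST = 64
AGE_PRE = (39.4, 9.1)
AGE_POST = (57.2, 8.5)
BMI = (29.2, 5.6)
ACTIVITY = (7.8, 1.6)
MENARCHE = (12.8, 1.8)

#: default housekeeping blocks: (size, within-block correlation)
DEFAULT_SHARED_BLOCKS: tuple[tuple[int, float], ...] = ((10, 0.6), (8, 0.5), (6, 0.4))


@dataclasses.dataclass
class DifferentialPair:
    """A planted pair with group-specific target correlations."""

    i: int
    j: int
    r_pre: float
    r_post: float

    @property
    def delta(self) -> float:
        return self.r_pre - self.r_post


@dataclasses.dataclass
class SimulationConfig:
    """Configuration of a simulated two-group study.

    ``differential_pairs`` entries are ``(i, j, r_pre, r_post)`` with
    metabolite column indices ``i < j`` and target latent correlations in
    (−1, 1).  ``covariate_effects`` maps a covariate name to a linear slope
    (scalar, applied to every metabolite, or one slope per metabolite) on the
    log-concentration scale per unit of the centred covariate.
    """

    n_pre: int = DEFAULT_N_PRE
    n_post: int = DEFAULT_N_POST
    n_metabolites: int = 168
    shared_blocks: Sequence[tuple[int, float]] = DEFAULT_SHARED_BLOCKS
    differential_pairs: Sequence[tuple[int, int, float, float]] = ()
    covariate_effects: Mapping[str, float | Sequence[float]] = dataclasses.field(
        default_factory=dict
    )
    lod_quantile: float = 0.02
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pre < 4 or self.n_post < 4:
            raise ConfigurationError(
                "each group needs at least 4 samples (Fisher weights require n > 3)"
            )
        if self.n_metabolites < 2:
            raise ConfigurationError("need at least 2 metabolites")
        if sum(size for size, _ in self.shared_blocks) > self.n_metabolites:
            raise ConfigurationError("shared block sizes exceed the panel size")
        for size, rho in self.shared_blocks:
            if size < 2 or not -1 < rho < 1:
                raise ConfigurationError(f"invalid shared block ({size}, {rho})")
        for i, j, r_pre, r_post in self.differential_pairs:
            if not (0 <= i < j < self.n_metabolites):
                raise ConfigurationError(f"planted pair ({i}, {j}) out of range")
            if not (-1 < r_pre < 1 and -1 < r_post < 1):
                raise ConfigurationError(
                    f"planted correlations for pair ({i}, {j}) must lie in (-1, 1)"
                )
        if not 0 <= self.lod_quantile < 1:
            raise ConfigurationError("lod_quantile must lie in [0, 1)")
        if not 0 <= self.missing_rate < 0.05:
            raise ConfigurationError("missing_rate must lie in [0, 0.05)")

    @property
    def planted(self) -> list[DifferentialPair]:
        return [DifferentialPair(*p) for p in self.differential_pairs]

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "shared_blocks" in d:
            d["shared_blocks"] = [tuple(b) for b in d["shared_blocks"]]
        if "differential_pairs" in d:
            d["differential_pairs"] = [tuple(p) for p in d["differential_pairs"]]
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a configuration from a YAML or JSON file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


@dataclasses.dataclass
class SimulatedStudy:
    """A generated table plus the generative ground truth."""

    table: SampleTable
    truth: list[DifferentialPair]
    repaired: dict[str, bool]

    def latent_log_values(self) -> pd.DataFrame:
        """Log concentrations (the scale on which correlations were planted).

        Only defined where a numeric value exists; censored/missing are NaN.
        """
        return np.log(self.table.values)


def nearest_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Repair a symmetric target correlation matrix by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to it, the matrix is reassembled
    and re-normalised to unit diagonal.  Returns the repaired matrix and a
    flag indicating whether any clipping occurred.
    """
    vals, vecs = np.linalg.eigh(corr)
    repaired = bool(vals.min() < floor)
    if repaired:
        vals = np.clip(vals, floor, None)
        corr = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        np.fill_diagonal(corr, 1.0)
    return corr, repaired


def _target_correlation(config: SimulationConfig, group: str) -> np.ndarray:
    m = config.n_metabolites
    corr = np.eye(m)
    offset = 0
    for size, rho in config.shared_blocks:
        block = slice(offset, offset + size)
        corr[block, block] = rho
        offset += size
    np.fill_diagonal(corr, 1.0)
    for pair in config.planted:
        r = pair.r_pre if group == GROUP_PRE else pair.r_post
        corr[pair.i, pair.j] = corr[pair.j, pair.i] = r
    return corr


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a two-group study with the configured correlation structure.

    Per group, latent values are drawn from a multivariate normal with the
    assembled (block + planted pair) correlation matrix, repaired to the
    nearest positive-definite correlation matrix if needed.  Covariates are
    added as linear shifts on the log scale, values are exponentiated to
    positive concentrations, the lowest ``lod_quantile`` of each metabolite
    is censored below-LOD, and ``missing_rate`` of entries per metabolite is
    flagged missing.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    n = config.n_pre + config.n_post

    chol = {}
    repaired = {}
    for group in (GROUP_PRE, GROUP_POST):
        target = _target_correlation(config, group)
        fixed, was_repaired = nearest_positive_definite(target)
        repaired[group] = was_repaired
        try:
            chol[group] = np.linalg.cholesky(fixed)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - repair guards this
            raise ConfigurationError(
                f"correlation structure for group {group!r} is not positive definite "
                "and could not be repaired; check shared_blocks/differential_pairs"
            ) from exc

    # per-metabolite log-normal baselines, shared by both groups (µM scale)
    log_mean = rng.uniform(np.log(0.5), np.log(50.0), size=m)
    log_sd = rng.uniform(0.2, 0.4, size=m)

    # covariates: age differs by group, the rest are group-invariant
    age = np.concatenate(
        [
            rng.normal(*AGE_PRE, size=config.n_pre),
            rng.normal(*AGE_POST, size=config.n_post),
        ]
    )
    covariates = pd.DataFrame(
        {
            "age": age,
            "bmi": rng.normal(*BMI, size=n),
            "activity": rng.normal(*ACTIVITY, size=n),
            "menarche_age": rng.normal(*MENARCHE, size=n),
        }
    )
    centres = {
        "age": (config.n_pre * AGE_PRE[0] + config.n_post * AGE_POST[0]) / n,
        "bmi": BMI[0],
        "activity": ACTIVITY[0],
        "menarche_age": MENARCHE[0],
    }

    latent = np.empty((n, m))
    z_pre = rng.standard_normal((config.n_pre, m))
    z_post = rng.standard_normal((config.n_post, m))
    latent[: config.n_pre] = z_pre @ chol[GROUP_PRE].T
    latent[config.n_pre :] = z_post @ chol[GROUP_POST].T

    log_conc = log_mean + log_sd * latent
    for name, beta in config.covariate_effects.items():
        if name not in covariates.columns:
            raise ConfigurationError(f"unknown covariate {name!r} in covariate_effects")
        slope = np.broadcast_to(np.asarray(beta, dtype=float), (m,))
        centred = covariates[name].to_numpy() - centres[name]
        log_conc = log_conc + np.outer(centred, slope)
    conc = np.exp(log_conc)

    names = [f"M{k + 1:03d}" for k in range(m)]
    sample_ids = [f"S{k + 1:03d}" for k in range(n)]
    groups = [GROUP_PRE] * config.n_pre + [GROUP_POST] * config.n_post
    metadata = pd.DataFrame({"group": groups}, index=pd.Index(sample_ids, name="sample_id"))
    metadata[["age", "bmi", "activity", "menarche_age"]] = covariates.to_numpy()

    values = pd.DataFrame(conc, index=metadata.index, columns=names)
    status = pd.DataFrame(QUANTIFIED, index=metadata.index, columns=names)

    # below-LOD: censor the k lowest concentrations of each metabolite
    k_lod = int(round(config.lod_quantile * n))
    if k_lod > 0:
        order = np.argsort(conc, axis=0)
        for col in range(m):
            rows = order[:k_lod, col]
            status.iloc[rows, col] = BELOW_LOD
            values.iloc[rows, col] = np.nan

    # missing entries, allocated per metabolite so no metabolite crosses the
    # 5% drop rule at the default rate
    k_miss = int(round(config.missing_rate * n))
    if k_miss > 0:
        for col in range(m):
            eligible = np.flatnonzero((status.iloc[:, col] == QUANTIFIED).to_numpy())
            rows = rng.choice(eligible, size=min(k_miss, len(eligible)), replace=False)
            status.iloc[rows, col] = MISSING
            values.iloc[rows, col] = np.nan

    table = SampleTable(metadata, values, status)
    truth = [
        DifferentialPair(p.i, p.j, p.r_pre, p.r_post) for p in config.planted
    ]
    return SimulatedStudy(table=table, truth=truth, repaired=repaired)


def write_truth(study: SimulatedStudy, path: str | Path) -> None:
    """Write the planted ground truth as CSV (met_i, met_j, r_pre, r_post)."""
    names = study.table.metabolites
    rows = [
        {"met_i": names[p.i], "met_j": names[p.j], "r_pre": p.r_pre, "r_post": p.r_post}
        for p in study.truth
    ]
    pd.DataFrame(rows, columns=["met_i", "met_j", "r_pre", "r_post"]).to_csv(path, index=False)
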