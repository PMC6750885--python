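"""End-to-end pipeline: simulate/load -> preprocess -> differential
correlation -> network -> discriminant analysis, with machine-readable
reports.

All stages run in a fixed order from a single :class:`PipelineConfig`;
every source of randomness is derived from the one configured seed, so an
identical config produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping

import yaml

from . import diffcorr, discriminant, network, preprocess
from .errors import ConfigurationError
from .simulate import SimulationConfig, generate_study, write_truth
from .tables import GROUP_POST, GROUP_PRE, SampleTable, read_sample_table, write_sample_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and inputs of the full analysis.

    Exactly one of ``input_path`` (a sample-table CSV) or ``simulation``
    must be provided.
    """

    input_path: str | None = None
    simulation: SimulationConfig | None = None
    min_fraction: float = 0.8
    corr_alpha: float = 0.05
    edge_p: float = 0.01
    screen_alpha: float = 0.05
    vip_threshold: float = 1.0
    n_permutations: int = 1000
    n_orth: int = 1
    q2_folds: int = 7
    direction: str = "pre_minus_post"
    seed: int = 0
    outdir: str = "diffcornet_out"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise ConfigurationError("provide exactly one of input_path or simulation")
        for name in ("min_fraction", "corr_alpha", "edge_p", "screen_alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1], got {v}")
        if self.n_permutations < 1:
            raise ConfigurationError("n_permutations must be at least 1")
        if self.direction not in ("pre_minus_post", "post_minus_pre"):
            raise ConfigurationError(f"unknown direction {self.direction!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown pipeline keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigurationError(f"pipeline config {path} must be a mapping")
        return cls.from_dict(data)


def _load_table(config: PipelineConfig, outdir: Path) -> SampleTable:
    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.simulation.seed or config.seed)
        study = generate_study(sim)
        write_sample_table(study.table, outdir / "simulated_table.csv")
        write_truth(study, outdir / "simulated_truth.csv")
        return study.table
    return read_sample_table(config.input_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write stage outputs under ``config.outdir``,
    and return the top-level report (also written as ``report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    table = _load_table(config, outdir)
    logger.info("pipeline thresholds: %s", dataclasses.asdict(config) | {"simulation": None})

    clean, prep_report = preprocess.run_preprocessing(table, min_fraction=config.min_fraction)
    write_sample_table(clean, outdir / "preprocessed_table.csv")
    (outdir / "preprocess_report.json").write_text(
        json.dumps(prep_report, indent=2, sort_keys=True)
    )

    summary = preprocess.summarize_cohort(table)
    summary.to_csv(outdir / "cohort_summary.csv")

    corr_pre = diffcorr.pairwise_correlations(clean, GROUP_PRE)
    corr_post = diffcorr.pairwise_correlations(clean, GROUP_POST)
    sig_pre = diffcorr.significant_pairs(corr_pre, alpha=config.corr_alpha)
    sig_post = diffcorr.significant_pairs(corr_post, alpha=config.corr_alpha)
    overlap = diffcorr.overlap_fraction(sig_pre, sig_post)

    plan = diffcorr.PermutationPlan(n_permutations=config.n_permutations, seed=config.seed)
    edges = diffcorr.permutation_test(clean, plan, direction=config.direction)
    diffcorr.write_edges(edges, outdir / "differential_edges.csv")
    selected = diffcorr.select_edges(edges, p_threshold=config.edge_p)

    graph = network.build_network(selected)
    network.export_network(graph, outdir / "network.graphml", fmt="graphml")
    network.export_network(graph, outdir / "network_edges.csv", fmt="csv")
    topo = network.topology_report(graph)
    (outdir / "topology.json").write_text(json.dumps(topo, indent=2, sort_keys=True))

    X = clean.values.to_numpy(float)
    y = clean.metadata["group"].to_numpy()
    model = discriminant.fit_oplsda(X, y, n_orth=config.n_orth, metabolites=clean.metabolites)
    q2 = discriminant.cross_validated_q2(
        X, y, folds=config.q2_folds, seed=config.seed, n_orth=config.n_orth
    )
    screen = discriminant.screen_metabolites(
        X, y, model, alpha=config.screen_alpha, vip_threshold=config.vip_threshold
    )
    screen.table.to_csv(outdir / "screen.csv")
    splot = discriminant.splot(model, X)
    splot.to_csv(outdir / "splot.csv")
    association = (
        discriminant.associate(clean.values, y, screen.passing) if screen.passing else None
    )
    if association is not None:
        association.to_csv(outdir / "association.csv")
    # candidates x samples matrix of normalized values, for external heatmaps
    clean.values[screen.passing].T.to_csv(outdir / "screen_matrix.tsv", sep="\t")
    (outdir / "oplsda.json").write_text(json.dumps(
        {"r2x": model.r2x, "r2y": model.r2y, "q2": q2, "n_orth": model.n_orth},
        indent=2, sort_keys=True,
    ))

    report = {
        "seed": config.seed,
        "direction": config.direction,
        "preprocess": prep_report,
        "pairs_tested": corr_pre.pair_count(),
        "significant_pairs_pre": len(sig_pre),
        "significant_pairs_post": len(sig_post),
        "overlap_fraction": overlap,
        "n_edges_p_le_0.05": sum(e.p_perm <= 0.05 for e in edges),
        "n_edges_selected": len(selected),
        "edge_p_threshold": config.edge_p,
        "network": topo,
        "oplsda": {"r2x": model.r2x, "r2y": model.r2y, "q2": q2, "n_orth": model.n_orth},
        "screen": {
            "alpha": screen.alpha,
            "threshold_exact": screen.threshold_exact,
            "threshold_printed": screen.threshold_printed,
            "n_passing": len(screen.passing),
            "passing": screen.passing,
        },
        "association": (
            {name: row["p_value"] for name, row in association.iterrows()}
            if association is not None else {}
        ),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
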