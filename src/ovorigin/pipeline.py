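"""End-to-end pipeline configuration and orchestration.

``run_pipeline`` chains filter -> pairwise DE -> signatures -> scores ->
(optional) cohort application on top of :class:`CellOfOriginModel`, writing
all interchange files to an output directory. With no input paths configured
it runs on synthetic data generated from the configured seed, so the whole
pipeline is reproducible from a config file alone; all outputs are stamped
with the config hash and seed via ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ovio
from .datatypes import CohortData, CountMatrix, OrthologyTable, ValidationError
from .model import DEFAULT_CONTRASTS, CellOfOriginModel, CellOfOriginResults, CohortResults
from .signatures import DEFAULT_SIZES
from .simulate import GroundTruth, SimulationConfig, generate_orthology_table, simulate_cohort, simulate_mouse_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline end to end."""

    seed: int = 0
    alpha: float = 0.05
    sizes: tuple[int, ...] = DEFAULT_SIZES
    prior_count: float = 0.5
    out_dir: str = "ovorigin_out"
    # input paths; all None -> simulate
    counts: str | None = None
    annotation: str | None = None
    orthology: str | None = None
    cohort_expression: str | None = None
    cohort_subtype: str | None = None
    cohort_ipl: str | None = None
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS
    top_n: int = 50
    score_size: int | None = None  # cohort scoring size; smallest by default
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if any(int(k) <= 0 for k in self.sizes):
            raise ValidationError("signature sizes must be positive integers")
        self.sizes = tuple(int(k) for k in self.sizes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        if "sizes" in raw:
            raw["sizes"] = tuple(raw["sizes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


@dataclass
class PipelineOutput:
    """Return bundle of :func:`run_pipeline`."""

    results: CellOfOriginResults
    cohort_results: CohortResults | None
    truth: GroundTruth | None  # only for simulated runs
    paths: dict[str, Path]


def _load_inputs(
    config: PipelineConfig, out_dir: Path
) -> tuple[CountMatrix, OrthologyTable | None, CohortData | None, GroundTruth | None]:
    if config.counts is None:
        sim_cfg = config.simulation_config()
        logger.info("no counts path configured; simulating with seed %d", config.seed)
        matrix, truth = simulate_mouse_experiment(sim_cfg)
        orthology = generate_orthology_table(sim_cfg, truth)
        cohort, truth = simulate_cohort(sim_cfg, truth, orthology)
        return matrix, orthology, cohort, truth

    if config.annotation is None:
        raise ValidationError("counts path given without an annotation path")
    matrix = ovio.read_count_matrix(config.counts, config.annotation)
    orthology = (
        ovio.read_orthology_table(config.orthology) if config.orthology else None
    )
    cohort = None
    if config.cohort_expression is not None:
        if config.cohort_subtype is None:
            raise ValidationError("cohort expression given without subtype labels")
        expr = ovio.read_expression_matrix(config.cohort_expression)
        subtype_frame = pd.read_csv(config.cohort_subtype, sep="\t", dtype=str)
        subtype = subtype_frame.set_index("sample_id")["subtype"]
        ipl = (
            ovio.read_expression_matrix(config.cohort_ipl)
            if config.cohort_ipl
            else None
        )
        cohort = CohortData(expr, subtype, ipl)
    return matrix, orthology, cohort, None


def run_pipeline(config: PipelineConfig) -> PipelineOutput:
    """Execute the configured stages and write all outputs to ``out_dir``.

    Stage errors propagate wrapped with the stage name. Outputs are
    deterministic for a fixed config (bytes included), so two runs with the
    same seed produce identical score tables.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _stage(name: str):
        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with _stage("input"):
        matrix, orthology, cohort, truth = _load_inputs(config, out_dir)

    with _stage("fit"):
        model = CellOfOriginModel(
            matrix, orthology=orthology, prior_count=config.prior_count
        )
        results = model.fit(sizes=config.sizes, alpha=config.alpha)

    with _stage("write-de"):
        for (b, a), table in results.pairwise.tables.items():
            path = out_dir / f"de_{b}_vs_{a}.tsv"
            ovio.write_de_table(table, path)
            paths[f"de_{b}_vs_{a}"] = path

    with _stage("write-signatures"):
        paths["signatures"] = out_dir / "signatures.gmt"
        ovio.write_signatures_gmt(results.signatures, paths["signatures"])

    with _stage("write-scores"):
        for k in results.sizes:
            path = out_dir / f"scores_mouse_k{k}.tsv"
            ovio.write_scores(results.score_table(k), path)
            paths[f"scores_mouse_k{k}"] = path

    with _stage("write-venn"):
        paths["venn"] = out_dir / "venn.json"
        venn_payload = {
            "alpha": results.venn.alpha,
            "counts": results.venn.counts,
            "pairwise_intersections": {
                " & ".join(combo): n
                for combo, n in results.venn.intersection_counts(order=2).items()
            },
        }
        paths["venn"].write_text(json.dumps(venn_payload, indent=2, sort_keys=True))

    with _stage("clustering"):
        clustering = results.cluster_samples()
        paths["dendrogram"] = out_dir / "dendrogram.newick"
        paths["dendrogram"].write_text(clustering.newick + "\n")

    cohort_results: CohortResults | None = None
    if cohort is not None:
        with _stage("cohort"):
            cohort_results = results.apply_to_cohort(
                cohort,
                k=config.score_size,
                contrasts=config.contrasts,
                top_n=config.top_n,
            )
            paths["cohort_scores"] = out_dir / f"scores_cohort_k{cohort_results.k}.tsv"
            ovio.write_scores(cohort_results.scores, paths["cohort_scores"])
            paths["subtype_tests"] = out_dir / "subtype_tests.tsv"
            cohort_results.subtype_tests.to_csv(
                paths["subtype_tests"], sep="\t", index=False
            )
            if cohort_results.ipl_table is not None:
                paths["ipl_correlations"] = out_dir / "ipl_correlations.tsv"
                cohort_results.ipl_table.to_csv(
                    paths["ipl_correlations"], sep="\t", index=False
                )
    else:
        logger.info("no cohort configured; cohort stage skipped")

    with _stage("manifest"):
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash,
            "config": config.to_dict(),
            "outputs": {k: str(v) for k, v in sorted(paths.items())},
        }
        paths["manifest"] = out_dir / "manifest.json"
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineOutput(
        results=results, cohort_results=cohort_results, truth=truth, paths=paths
    )
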