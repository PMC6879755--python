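"""Synthetic data with known ground truth for the four-group design.

Two generators: a mouse-like RNA-seq experiment (negative-binomial counts for
the groups N-FT, N-O, T-FT, T-O with planted tissue-marker and tumor
expression programs) and a human-like tumor cohort whose samples mix the two
tumor programs through a latent origin coefficient alpha in [0, 1], with
subtype labels and pathway-activity (IPL) features tied to alpha. Every
downstream stage is testable against the planted truth without external data.

Seeding: all stages derive child generators from one master seed via
``numpy.random.SeedSequence([seed, stage])`` with stage ids 0 (mouse counts),
1 (orthology), 2 (cohort); partial reruns of a stage are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import (
    CohortData,
    CountMatrix,
    OrthologyTable,
    SampleAnnotation,
    ValidationError,
)

#: Program names, in gene-assignment order.
PROGRAMS = ("ft_marker", "o_marker", "shared_tumor", "ft_tumor", "o_tumor")

_STAGE_MOUSE, _STAGE_ORTHOLOGY, _STAGE_COHORT = 0, 1, 2


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment and cohort.

    Defaults reflect the four-group design being emulated: five FTE-derived
    tumors compared with three OSE-derived tumors and three normal samples of
    each tissue; tissue-marker programs larger than the tumor programs so
    tissue identity dominates the transcriptome; NB counts with variance
    mu + phi * mu**2.
    """

    seed: int = 0
    n_genes: int = 2000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"T-FT": 5, "T-O": 3, "N-FT": 3, "N-O": 3}
    )
    # planted genes per program
    n_ft_marker: int = 100
    n_o_marker: int = 100
    n_shared_tumor: int = 50
    n_ft_tumor: int = 50
    n_o_tumor: int = 50
    effect_size: float = 2.0  # log2 fold change of every planted program
    dispersion: float = 0.1  # NB phi, shared across genes
    baseline_mean: float = 100.0  # median of the log-normal baseline
    baseline_log_sd: float = 1.0  # sd of ln(baseline)
    libsize_range: tuple[float, float] = (0.7, 1.3)  # size-factor range
    # orthology / gene universe (background genes only; planted genes are
    # always protein-coding with an ortholog so the truth is in-universe)
    frac_protein_coding: float = 0.95
    frac_orphan: float = 0.05  # mapped to "no ortholog", n_databases = 0
    frac_multi_mapping: float = 0.0  # extra lower-support symbol per gene
    # cohort
    n_cohort: int = 100
    alpha_beta: tuple[float, float] | None = None  # Beta(a, b); None = uniform
    alpha_fixed: float | None = None  # degenerate alpha for null checks
    subtype_quantiles: tuple[float, float] = (0.3, 0.7)
    cohort_noise_sd: float = 0.5  # gaussian noise on log-scale expression
    n_ipl_features: int = 200
    n_informative_ipl: int = 10
    ipl_slope: float = 1.0
    ipl_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        planted = self.n_planted
        if self.n_genes <= 0 or planted > self.n_genes:
            raise ValidationError(
                f"n_genes={self.n_genes} must exceed planted genes ({planted})"
            )
        for name, size in self.group_sizes.items():
            if size < 2:
                raise ValidationError(
                    f"group {name!r} has {size} samples; differential expression "
                    "requires at least 2 replicates per group"
                )
        if not (0 <= self.frac_orphan <= 1 and 0 <= self.frac_protein_coding <= 1):
            raise ValidationError("fractions must lie in [0, 1]")
        if self.libsize_range[0] <= 0 or self.libsize_range[1] < self.libsize_range[0]:
            raise ValidationError("libsize_range must be positive and ordered")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be non-negative")
        if self.alpha_fixed is not None and not 0 <= self.alpha_fixed <= 1:
            raise ValidationError("alpha_fixed must lie in [0, 1]")
        lo, hi = self.subtype_quantiles
        if not 0 <= lo <= hi <= 1:
            raise ValidationError("subtype_quantiles must be ordered within [0, 1]")
        if self.n_informative_ipl > self.n_ipl_features:
            raise ValidationError("more informative IPL features than features")

    @property
    def n_planted(self) -> int:
        return (
            self.n_ft_marker
            + self.n_o_marker
            + self.n_shared_tumor
            + self.n_ft_tumor
            + self.n_o_tumor
        )

    def child_rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class GroundTruth:
    """Planted structure the generators guarantee.

    ``programs`` maps program name -> member gene ids; ``profiles`` holds the
    expected log2 expression of the two tumor groups (genes x {T-FT, T-O}),
    used as the endpoints of the cohort mixture; ``alpha`` and
    ``informative_features`` are filled by :func:`simulate_cohort`.
    """

    programs: dict[str, list[str]]
    profiles: pd.DataFrame | None = None
    alpha: pd.Series | None = None
    informative_features: list[str] | None = None


def _program_delta(cfg: SimulationConfig) -> dict[str, dict[str, float]]:
    """log2 offsets per program and group."""
    e = cfg.effect_size
    return {
        "ft_marker": {"N-FT": e, "T-FT": e},
        "o_marker": {"N-O": e, "T-O": e},
        "shared_tumor": {"T-FT": e, "T-O": e},
        "ft_tumor": {"T-FT": e},
        "o_tumor": {"T-O": e},
    }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"Gene{i:0{width}d}" for i in range(1, n + 1)]


def nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Draw NB counts with ``var = mean + dispersion * mean**2`` (Poisson if 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_mouse_experiment(
    cfg: SimulationConfig,
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the four-group mouse count matrix with planted programs.

    Counts are NB with mean ``baseline_g * sf_i * 2**delta(g, group_i)``;
    baselines are log-normal, size factors uniform in ``libsize_range``,
    and delta encodes program membership (tissue markers high in both samples
    of their tissue, tumor programs high in the corresponding tumor group(s)).
    """
    rng = cfg.child_rng(_STAGE_MOUSE)
    genes = _gene_ids(cfg.n_genes)

    # random program placement so gene order carries no information
    order = rng.permutation(cfg.n_genes)
    sizes = [
        cfg.n_ft_marker,
        cfg.n_o_marker,
        cfg.n_shared_tumor,
        cfg.n_ft_tumor,
        cfg.n_o_tumor,
    ]
    programs: dict[str, list[str]] = {}
    start = 0
    for name, size in zip(PROGRAMS, sizes):
        members = sorted(genes[i] for i in order[start : start + size])
        programs[name] = members
        start += size

    baseline = rng.lognormal(np.log(cfg.baseline_mean), cfg.baseline_log_sd, cfg.n_genes)
    groups = list(cfg.group_sizes)
    deltas = _program_delta(cfg)
    delta = pd.DataFrame(0.0, index=genes, columns=groups)
    for prog, members in programs.items():
        for grp, off in deltas[prog].items():
            if grp in delta.columns:
                delta.loc[members, grp] += off

    sample_ids: list[str] = []
    sample_groups: list[str] = []
    columns = []
    for grp in groups:
        n = cfg.group_sizes[grp]
        sf = rng.uniform(*cfg.libsize_range, size=n)
        mu = baseline[:, None] * sf[None, :] * 2.0 ** delta[grp].to_numpy()[:, None]
        columns.append(nb_sample(rng, mu, cfg.dispersion))
        sample_ids += [f"{grp}_{i + 1}" for i in range(n)]
        sample_groups += [grp] * n

    counts = pd.DataFrame(np.hstack(columns), index=genes, columns=sample_ids)
    annotation = SampleAnnotation(
        pd.DataFrame({"group": sample_groups}, index=pd.Index(sample_ids, name="sample_id"))
    )
    matrix = CountMatrix(counts, annotation)

    # expected log2 expression per tumor group: the cohort mixture endpoints
    profiles = pd.DataFrame(
        {
            grp: np.log2(baseline) + delta[grp].to_numpy()
            for grp in ("T-FT", "T-O")
            if grp in delta.columns
        },
        index=genes,
    )
    return matrix, GroundTruth(programs=programs, profiles=profiles)


def generate_orthology_table(
    cfg: SimulationConfig, truth: GroundTruth | None = None
) -> OrthologyTable:
    """Simulate an HCOP-like orthology/biotype table over the gene universe.

    Background genes are protein-coding with probability
    ``frac_protein_coding`` and orphaned (no human symbol, zero supporting
    databases) with probability ``frac_orphan``; planted program genes (from
    ``truth``) are always protein-coding with an ortholog so the ground truth
    survives the universe filter. With ``frac_multi_mapping`` > 0 a second,
    lower-support human symbol is emitted for a random subset of genes.
    """
    rng = cfg.child_rng(_STAGE_ORTHOLOGY)
    genes = _gene_ids(cfg.n_genes)
    planted: set[str] = set()
    if truth is not None:
        for members in truth.programs.values():
            planted.update(members)

    rows = []
    for gene in genes:
        is_planted = gene in planted
        coding = is_planted or rng.random() < cfg.frac_protein_coding
        orphan = (not is_planted) and rng.random() < cfg.frac_orphan
        biotype = "protein_coding" if coding else "lncRNA"
        if orphan:
            rows.append((gene, "", 0, biotype))
            continue
        n_db = int(rng.integers(1, 15))
        symbol = gene.upper()
        rows.append((gene, symbol, n_db, biotype))
        if rng.random() < cfg.frac_multi_mapping:
            alt_db = int(rng.integers(1, max(2, n_db)))
            rows.append((gene, f"{symbol}B", alt_db, biotype))

    table = pd.DataFrame(
        rows, columns=["source_gene_id", "human_symbol", "n_databases", "biotype"]
    )
    return OrthologyTable(table)


def simulate_cohort(
    cfg: SimulationConfig,
    truth: GroundTruth,
    orthology: OrthologyTable | None = None,
) -> tuple[CohortData, GroundTruth]:
    """Simulate a human-like cohort mixing the two tumor programs.

    Per sample, a latent origin coefficient alpha in [0, 1] is drawn and the
    log-scale expression mean is ``alpha * T-FT profile + (1 - alpha) * T-O
    profile`` on the human-symbol namespace (via ``orthology``), plus
    Gaussian noise. Subtype labels are "mesenchymal-like" above the upper
    alpha quantile, "proliferative-like" below the lower one, else "other".
    Of the IPL features the informative subset equals ``slope * alpha +
    noise``; the rest are standard-normal noise.
    """
    if truth.profiles is None:
        raise ValidationError("truth lacks tumor profiles; run the mouse simulation first")
    if cfg.n_cohort < 4:
        raise ValidationError("cohort needs at least 4 samples")
    if orthology is None:
        orthology = generate_orthology_table(cfg, truth)
    rng = cfg.child_rng(_STAGE_COHORT)

    n = cfg.n_cohort
    if cfg.alpha_fixed is not None:
        alpha = np.full(n, cfg.alpha_fixed)
    elif cfg.alpha_beta is not None:
        alpha = rng.beta(*cfg.alpha_beta, size=n)
    else:
        alpha = rng.uniform(0.0, 1.0, size=n)
    samples = [f"TCGA_{i + 1:03d}" for i in range(n)]

    # best-supported symbol per mouse gene (ties by symbol name)
    mapped = orthology.mapped().sort_values(
        ["source_gene_id", "n_databases", "human_symbol"],
        ascending=[True, False, True],
    )
    best = mapped.drop_duplicates("source_gene_id").set_index("source_gene_id")[
        "human_symbol"
    ]
    keep = [g for g in truth.profiles.index if g in best.index]
    profiles = truth.profiles.loc[keep]
    symbols = best.loc[keep]
    # if two mouse genes share a symbol, keep the first occurrence
    unique = ~symbols.duplicated()
    profiles, symbols = profiles[unique.to_numpy()], symbols[unique]

    mean = np.outer(profiles["T-FT"], alpha) + np.outer(profiles["T-O"], 1.0 - alpha)
    expr = mean + rng.normal(0.0, cfg.cohort_noise_sd, size=mean.shape)
    expression = pd.DataFrame(expr, index=list(symbols), columns=samples)

    lo_q, hi_q = np.quantile(alpha, cfg.subtype_quantiles)
    labels = np.where(
        alpha > hi_q,
        "mesenchymal-like",
        np.where(alpha < lo_q, "proliferative-like", "other"),
    )
    subtype = pd.Series(labels, index=samples, name="subtype")

    width = max(4, len(str(cfg.n_ipl_features)))
    features = [f"IPL_{i + 1:0{width}d}" for i in range(cfg.n_ipl_features)]
    informative = features[: cfg.n_informative_ipl]
    ipl = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(cfg.n_ipl_features, n)),
        index=features,
        columns=samples,
    )
    for feat in informative:
        ipl.loc[feat] = cfg.ipl_slope * alpha + rng.normal(0.0, cfg.ipl_noise_sd, n)

    new_truth = replace(
        truth,
        alpha=pd.Series(alpha, index=samples, name="alpha"),
        informative_features=list(informative),
    )
    return CohortData(expression, subtype, ipl), new_truth
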