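"""Regulon-structured synthetic RNA-seq study generator.

Emulates a six-population bacterial tolerance study design — stationary
phase, untreated outgrowth, ampicillin-treated outgrowth (3 h and 6 h),
proteolytic queueing, and queueing plus ampicillin — with three biological
replicates per condition. The generator plants *regulator activity*: every
sign-consistent target of an active regulator shifts its mean expression by
``effect_fold`` in that condition, and the full ground truth (active
regulators, affected genes, directions, folds, baselines, dispersions,
library-size factors) is recorded for recovery testing.

Counts are negative binomial with gene-wise dispersion,
``Var(K) = m + alpha * m**2`` for mean ``m``, matching the error model the
downstream DESeq-style test assumes; per-sample library-size factors
exercise median-of-ratios normalization.

Randomness: one integer seed; each stage consumes an independent substream
derived from it (network -> annotation -> counts), so any stage can be
regenerated alone and stays identical when the others are reconfigured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .formats import COG_LEGEND, COGAnnotation, CountMatrix, RegulatoryNetwork

#: The six populations of the emulated study design.
DEFAULT_CONDITIONS = (
    "stationary",
    "untreated",
    "amp_3h",
    "amp_6h",
    "queueing",
    "queueing_amp",
)


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    Defaults reproduce the emulated design: 2000 genes, 5 sigma factors,
    30 TFs, six conditions x 3 replicates, four-fold planted effects.
    """

    n_genes: int = 2000
    n_sigma: int = 5
    n_tf: int = 30
    regulon_size_range: tuple[int, int] = (5, 100)
    mode_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)  # activator/repressor/dual
    conditions: Sequence[str] = DEFAULT_CONDITIONS
    n_replicates: int = 3
    active_regulators: Mapping[str, frozenset[str]] = field(default_factory=dict)
    effect_fold: float = 4.0
    baseline_mean_log10_range: tuple[float, float] = (0.5, 3.5)
    dispersion_range: tuple[float, float] = (0.05, 0.3)
    libsize_factor_range: tuple[float, float] = (0.7, 1.3)
    multi_sigma_prob: float = 0.2
    unannotated_prob: float = 0.15
    multi_cog_prob: float = 0.10
    dual_direction: str = "up"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sigma < 0 or self.n_tf < 0:
            raise ConfigurationError("n_genes must be >= 1; n_sigma/n_tf >= 0")
        if self.n_replicates < 2:
            raise ConfigurationError("n_replicates must be >= 2")
        if abs(sum(self.mode_probs) - 1.0) > 1e-9:
            raise ConfigurationError("mode_probs must sum to 1")
        for name in (
            "regulon_size_range",
            "baseline_mean_log10_range",
            "dispersion_range",
            "libsize_factor_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} must be ordered low <= high")
        if self.n_tf > 0 and self.regulon_size_range[1] > self.n_genes:
            raise ConfigurationError(
                "regulon_size_range upper bound exceeds n_genes"
            )
        if self.effect_fold <= 0:
            raise ConfigurationError("effect_fold must be positive")
        if self.dual_direction not in ("up", "down"):
            raise ConfigurationError("dual_direction must be 'up' or 'down'")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        self.active_regulators = {
            cond: frozenset(regs) for cond, regs in dict(self.active_regulators).items()
        }
        unknown = set(self.active_regulators) - set(self.conditions)
        if unknown:
            raise ConfigurationError(
                f"active_regulators references unknown condition(s) {sorted(unknown)}"
            )

    @property
    def reference_condition(self) -> str:
        return self.conditions[0]


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study.

    ``de_genes`` maps contrast labels ``"B:A"`` (condition B vs the
    reference A) to the planted differential genes as
    ``(gene, direction, true_fold)`` triples, with fold > 1 for "up" and
    fold < 1 for "down".
    """

    active_regulators: dict[str, frozenset[str]]
    de_genes: dict[str, frozenset[tuple[str, str, float]]]
    gene_baseline_mean: dict[str, float]
    gene_dispersion: dict[str, float]
    sample_libsize_factor: dict[str, float]


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def gene_ids(config: SimConfig) -> list[str]:
    width = max(4, len(str(config.n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def generate_network(config: SimConfig) -> RegulatoryNetwork:
    """Draw a regulon-structured network.

    Every gene receives at least one sigma-class regulator (sigma edges are
    always activators — sigma factors initiate transcription) and, with
    probability ``multi_sigma_prob``, a second one; TF regulons are drawn
    uniformly in ``regulon_size_range`` with per-edge modes from
    ``mode_probs``. Regulon overlap is unrestricted.
    """
    rng = _rng(config, 0)
    genes = gene_ids(config)
    rows: list[tuple[str, str, str, str]] = []
    if config.n_sigma > 0:
        sigmas = [f"sigma{i + 1:02d}" for i in range(config.n_sigma)]
        primary = rng.integers(0, config.n_sigma, size=config.n_genes)
        extra = rng.random(config.n_genes) < config.multi_sigma_prob
        for g, gene in enumerate(genes):
            rows.append((sigmas[primary[g]], "sigma", gene, "activator"))
            if extra[g] and config.n_sigma > 1:
                second = int(rng.integers(0, config.n_sigma - 1))
                if second >= primary[g]:
                    second += 1
                rows.append((sigmas[second], "sigma", gene, "activator"))
    modes = np.array(["activator", "repressor", "dual"])
    for t in range(config.n_tf):
        tf = f"TF{t + 1:02d}"
        size = int(
            rng.integers(config.regulon_size_range[0], config.regulon_size_range[1] + 1)
        )
        targets = rng.choice(config.n_genes, size=size, replace=False)
        edge_modes = rng.choice(modes, size=size, p=list(config.mode_probs))
        for idx, mode in zip(np.sort(targets), edge_modes):
            rows.append((tf, "TF", genes[idx], str(mode)))
    edges = pd.DataFrame(rows, columns=["regulator", "reg_class", "target", "mode"])
    return RegulatoryNetwork(edges)


def generate_cog_annotation(
    network: RegulatoryNetwork, config: SimConfig
) -> COGAnnotation:
    """Assign 0, 1 or 2 one-letter COG categories per gene.

    Marginal fractions: ``unannotated_prob`` genes carry no category and
    ``multi_cog_prob`` carry two distinct ones; the rest carry one.
    """
    if network.edges.empty:
        raise ConfigurationError("cannot annotate an empty network")
    rng = _rng(config, 1)
    codes = np.array(list(COG_LEGEND))
    p1 = 1.0 - config.unannotated_prob - config.multi_cog_prob
    if p1 < 0:
        raise ConfigurationError("unannotated_prob + multi_cog_prob must be <= 1")
    mapping: dict[str, frozenset[str]] = {}
    for gene in sorted(network.genes):
        k = int(rng.choice(3, p=[config.unannotated_prob, p1, config.multi_cog_prob]))
        mapping[gene] = frozenset(rng.choice(codes, size=k, replace=False))
    return COGAnnotation(mapping)


def _condition_fold(
    config: SimConfig, network: RegulatoryNetwork, condition: str
) -> dict[str, float]:
    """Per-gene mean multiplier in one condition.

    A gene is up-shifted by ``effect_fold`` when any active regulator
    reaches it through an activator edge (or a dual edge, by default);
    down-shifted by ``1/effect_fold`` when its only active-regulator edges
    are repressing. Up-shifts take precedence over down-shifts when both
    apply.
    """
    active = config.active_regulators.get(condition, frozenset())
    if not active:
        return {}
    missing = active - set(network.regulators)
    if missing:
        raise ConfigurationError(
            f"active regulator(s) not in network: {sorted(missing)}"
        )
    up_modes = {"activator", "dual"} if config.dual_direction == "up" else {"activator"}
    down_modes = {"repressor"} if config.dual_direction == "up" else {"repressor", "dual"}
    sub = network.edges[network.edges["regulator"].isin(active)]
    up_genes = set(sub.loc[sub["mode"].isin(up_modes), "target"])
    down_genes = set(sub.loc[sub["mode"].isin(down_modes), "target"]) - up_genes
    folds = {g: config.effect_fold for g in up_genes}
    folds.update({g: 1.0 / config.effect_fold for g in down_genes})
    return folds


def generate_counts(
    network: RegulatoryNetwork, config: SimConfig
) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw the count matrix and record the full ground truth.

    Counts are NB with mean ``s_j * mu_g * fold_gc`` and variance
    ``m + alpha_g * m**2``; baselines are log10-uniform in
    ``baseline_mean_log10_range``, dispersions log-uniform in
    ``dispersion_range``, library-size factors uniform in
    ``libsize_factor_range``.
    """
    rng = _rng(config, 2)
    genes = gene_ids(config)
    mu = 10.0 ** rng.uniform(*config.baseline_mean_log10_range, size=config.n_genes)
    log_disp = rng.uniform(
        np.log(config.dispersion_range[0]),
        np.log(config.dispersion_range[1]),
        size=config.n_genes,
    )
    alpha = np.exp(log_disp)
    samples = [
        f"{cond}_r{k + 1}" for cond in config.conditions for k in range(config.n_replicates)
    ]
    libsize = rng.uniform(*config.libsize_factor_range, size=len(samples))

    fold_by_condition = {
        cond: _condition_fold(config, network, cond) for cond in config.conditions
    }
    gene_pos = {g: i for i, g in enumerate(genes)}
    mean_mat = np.empty((config.n_genes, len(samples)))
    for j, sample in enumerate(samples):
        cond = sample.rsplit("_r", 1)[0]
        fold = np.ones(config.n_genes)
        for g, f in fold_by_condition[cond].items():
            fold[gene_pos[g]] = f
        mean_mat[:, j] = libsize[j] * mu * fold
    n_param = 1.0 / alpha[:, None]
    counts = rng.negative_binomial(n_param, n_param / (n_param + mean_mat))

    design = pd.DataFrame(
        {
            "condition": [s.rsplit("_r", 1)[0] for s in samples],
            "replicate": [s.rsplit("_r", 1)[1] for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        design,
    )

    ref = config.reference_condition
    de_genes: dict[str, frozenset[tuple[str, str, float]]] = {}
    for cond in config.conditions:
        if cond == ref:
            continue
        ref_fold = fold_by_condition[ref]
        cond_fold = fold_by_condition[cond]
        triples = set()
        for g in set(ref_fold) | set(cond_fold):
            ratio = cond_fold.get(g, 1.0) / ref_fold.get(g, 1.0)
            if ratio > 1.0:
                triples.add((g, "up", ratio))
            elif ratio < 1.0:
                triples.add((g, "down", ratio))
        de_genes[f"{cond}:{ref}"] = frozenset(triples)

    truth = SyntheticTruth(
        active_regulators={c: frozenset(r) for c, r in config.active_regulators.items()},
        de_genes=de_genes,
        gene_baseline_mean=dict(zip(genes, mu.tolist())),
        gene_dispersion=dict(zip(genes, alpha.tolist())),
        sample_libsize_factor=dict(zip(samples, libsize.tolist())),
    )
    return matrix, truth


def simulate_study(
    config: SimConfig,
) -> tuple[RegulatoryNetwork, COGAnnotation, CountMatrix, SyntheticTruth]:
    """Network, annotation, counts and truth for one config, in stage order."""
    network = generate_network(config)
    annotation = generate_cog_annotation(network, config)
    matrix, truth = generate_counts(network, config)
    return network, annotation, matrix, truth
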