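"""Synthetic uEV-like count data with known ground truth.

Counts follow a negative-binomial model: for gene g and sample j,

    count_gj ~ NB(mean = L_j * pi_g * e_gj,  Var = mu + phi_g * mu^2)

where L_j is the sample's nominal library size (log-normal), pi_g the gene's
normalized baseline abundance (heavy-tailed log-normal over mean abundance
mu_g), phi_g a gene-specific dispersion (gamma), and e_gj a condition effect:

* degraded storage (e.g. urine frozen at -20 degC): e = s * mu_g / (mu_g + K)
  with global retention s and half-constant K — low-abundance genes are
  suppressed disproportionately and their zeros emerge from the count model,
  while high-abundance genes shrink but survive;
* attenuated isolation workflow: e = 1 - a_g with a_g drawn from a fractional
  attenuation range on a chosen feature subset;
* phenotype group 2: e = fold_g on a planted set of group-discriminating
  features (half up-, half down-regulated).

A planted set of stable genes shares its abundance and a small dispersion in
every sample (and, in multi-dataset scenarios, across datasets), giving the
reference-gene search a recoverable target. The generator is deterministic
under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import ConfigurationError, CountMatrix, SampleAnnotation

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_dataset",
    "scenario_storage",
    "scenario_multidataset",
    "scenario_groups",
]


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the count simulator; defaults emulate a small uEV study."""

    n_genes: int = 2000
    groups: tuple[tuple[str, int], ...] = (("a", 4), ("b", 4))
    # baseline abundance mu_g ~ LogNormal(location, scale)
    mu_log_location: float = 3.0
    mu_log_scale: float = 2.0
    # dispersion phi_g ~ Gamma(shape, scale); Var = mu + phi mu^2
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.25
    # nominal library size L_j ~ LogNormal(location, scale); ~2M reads typical
    library_log_location: float = math.log(2e6)
    library_log_scale: float = 0.4
    # planted stable genes: shared abundance, low dispersion everywhere
    n_stable: int = 40
    stable_dispersion: float = 0.02
    stable_mu_log_location: float = 7.0
    stable_mu_log_scale: float = 0.5
    # degraded condition: e = retention * mu / (mu + half_constant)
    retention: float = 0.1
    half_constant: float = 500.0
    degraded_groups: tuple[str, ...] = ()
    # workflow attenuation on a feature subset
    n_attenuated: int = 18
    attenuation_range: tuple[float, float] = (0.03, 0.58)
    attenuated_groups: tuple[str, ...] = ()
    # group-discriminating (differentially expressed) features
    n_de: int = 20
    fold_range: tuple[float, float] = (2.0, 8.0)
    de_groups: tuple[str, ...] = ()
    # optional SampleAnnotation field overrides per group
    group_annotations: tuple[tuple[str, tuple[tuple[str, str], ...]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.groups or any(n < 1 for _, n in self.groups):
            raise ConfigurationError("every group needs at least one sample")
        for name in ("mu_log_scale", "dispersion_shape", "dispersion_scale", "library_log_scale"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0 < self.retention <= 1):
            raise ConfigurationError("retention must lie in (0, 1]")
        if self.half_constant < 0:
            raise ConfigurationError("half_constant must be >= 0")
        if self.n_stable + self.n_de + self.n_attenuated > self.n_genes:
            raise ConfigurationError("planted sets exceed n_genes")
        group_names = {name for name, _ in self.groups}
        for attr in ("degraded_groups", "attenuated_groups", "de_groups"):
            unknown = set(getattr(self, attr)) - group_names
            if unknown:
                raise ConfigurationError(f"{attr} references unknown groups {sorted(unknown)}")
        lo, hi = self.attenuation_range
        if not (0 <= lo <= hi < 1):
            raise ConfigurationError("attenuation_range must satisfy 0 <= lo <= hi < 1")
        lo, hi = self.fold_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("fold_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted structure of one simulated dataset."""

    planted_stable: tuple[str, ...]
    forced_zero: tuple[str, ...]  # certainly lost in the degraded condition
    suppressed: tuple[str, ...]  # outer bound: expected degraded count < 0.5 per sample
    attenuated: Mapping[str, float]  # gene -> attenuation fraction a_g
    de: Mapping[str, float]  # gene -> fold multiplier applied in the DE groups
    mu: pd.Series
    phi: pd.Series
    library_sizes: pd.Series
    sample_groups: pd.Series


@dataclass(frozen=True)
class SimulatedDataset:
    counts: CountMatrix
    annotations: tuple[SampleAnnotation, ...]
    truth: SimulationTruth
    config: SimulationConfig


# Operational thresholds for the degraded-condition ground truth. A gene is
# recorded as forced to zero only when its *total* expected count across the
# degraded samples is below _FORCED_ZERO_TOTAL (so the probability of any
# nonzero draw is tiny under the count model) while its total expected count
# in the remaining samples is at least _CONTROL_PRESENT_TOTAL (so it is
# reliably observable where degradation is absent). The outer "suppressed"
# bound uses the per-sample expectation < 0.5.
_FORCED_ZERO_TOTAL = 0.1
_CONTROL_PRESENT_TOTAL = 8.0
_SUPPRESSED_PER_SAMPLE = 0.5


def _annotation_for(sample_id: str, group: str, config: SimulationConfig, dataset_id: str) -> SampleAnnotation:
    overrides = dict(dict(config.group_annotations).get(group, ()))
    return SampleAnnotation(sample_id=sample_id, dataset_id=dataset_id, **overrides)


def simulate_dataset(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    dataset_id: str = "sim",
    shared_stable: tuple[tuple[str, ...], np.ndarray] | None = None,
) -> SimulatedDataset:
    """Draw one dataset from the model; identical seed gives identical output.

    ``shared_stable`` (ids, mu values) lets multi-dataset scenarios plant the
    same stable genes with the same abundances in every dataset.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n)])
    perm = rng.permutation(n)
    stable_idx = perm[: config.n_stable]
    de_idx = perm[config.n_stable : config.n_stable + config.n_de]
    att_idx = perm[config.n_stable + config.n_de : config.n_stable + config.n_de + config.n_attenuated]

    mu = rng.lognormal(config.mu_log_location, config.mu_log_scale, size=n)
    stable_mu = rng.lognormal(config.stable_mu_log_location, config.stable_mu_log_scale, size=config.n_stable)
    if shared_stable is not None:
        shared_ids, shared_mu = shared_stable
        if len(shared_ids) != config.n_stable:
            raise ConfigurationError("shared stable set does not match n_stable")
        stable_idx = np.array([int(np.where(gene_ids == g)[0][0]) for g in shared_ids])
        stable_mu = np.asarray(shared_mu, dtype=float)
    mu[stable_idx] = stable_mu

    phi = rng.gamma(config.dispersion_shape, config.dispersion_scale, size=n)
    phi[stable_idx] = config.stable_dispersion

    sample_ids: list[str] = []
    group_of: list[str] = []
    for group, count in config.groups:
        for i in range(count):
            sample_ids.append(f"{dataset_id}_{group}_{i + 1}")
            group_of.append(group)
    n_samples = len(sample_ids)
    lib = rng.lognormal(config.library_log_location, config.library_log_scale, size=n_samples)

    attenuation = rng.uniform(*config.attenuation_range, size=config.n_attenuated)
    folds = rng.uniform(*config.fold_range, size=config.n_de)
    down = rng.random(config.n_de) < 0.5
    fold_mult = np.where(down, 1.0 / folds, folds)

    pi = mu / mu.sum()
    effect = np.ones((n, n_samples))
    degraded = np.array([g in config.degraded_groups for g in group_of])
    if degraded.any():
        retention_g = config.retention * mu / (mu + config.half_constant)
        effect[:, degraded] *= retention_g[:, None]
    attenuated_samples = np.array([g in config.attenuated_groups for g in group_of])
    if attenuated_samples.any() and len(att_idx):
        effect[np.ix_(att_idx, np.flatnonzero(attenuated_samples))] *= (1.0 - attenuation)[:, None]
    de_samples = np.array([g in config.de_groups for g in group_of])
    if de_samples.any() and len(de_idx):
        effect[np.ix_(de_idx, np.flatnonzero(de_samples))] *= fold_mult[:, None]

    mean = lib[None, :] * pi[:, None] * effect
    size = 1.0 / phi  # NB "number of successes" parameter
    p = size[:, None] / (size[:, None] + mean)
    counts = rng.negative_binomial(size[:, None], p)

    frame = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    matrix = CountMatrix(frame)

    if degraded.any():
        deg_mean = mean[:, degraded]
        ctrl_mean = mean[:, ~degraded]
        total_deg = deg_mean.sum(axis=1)
        total_ctrl = ctrl_mean.sum(axis=1)
        forced_zero = gene_ids[(total_deg < _FORCED_ZERO_TOTAL) & (total_ctrl >= _CONTROL_PRESENT_TOTAL)]
        suppressed = gene_ids[deg_mean.max(axis=1) < _SUPPRESSED_PER_SAMPLE]
    else:
        forced_zero = np.array([], dtype=object)
        suppressed = np.array([], dtype=object)

    truth = SimulationTruth(
        planted_stable=tuple(gene_ids[stable_idx]),
        forced_zero=tuple(forced_zero),
        suppressed=tuple(suppressed),
        attenuated=dict(zip(gene_ids[att_idx], attenuation)),
        de=dict(zip(gene_ids[de_idx], fold_mult)),
        mu=pd.Series(mu, index=gene_ids),
        phi=pd.Series(phi, index=gene_ids),
        library_sizes=pd.Series(lib, index=sample_ids),
        sample_groups=pd.Series(group_of, index=sample_ids),
    )
    annotations = tuple(
        _annotation_for(s, g, config, dataset_id) for s, g in zip(sample_ids, group_of)
    )
    return SimulatedDataset(counts=matrix, annotations=annotations, truth=truth, config=config)


def scenario_storage(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Paired-aliquot storage scenario: -80 degC controls vs -20 degC degraded.

    Both conditions share every gene's baseline abundance; the degraded
    condition applies the retention model. The truth records which genes are
    certainly forced to zero (and the outer suppressed bound).
    """
    if config is None:
        config = SimulationConfig(
            groups=(("minus80", 4), ("minus20", 4)),
            degraded_groups=("minus20",),
            n_de=0,
            n_attenuated=0,
            group_annotations=(
                ("minus80", (("storage_temp", "minus80"),)),
                ("minus20", (("storage_temp", "minus20"),)),
            ),
        )
    if not config.degraded_groups:
        raise ConfigurationError("storage scenario needs at least one degraded group")
    if seed is not None:
        config = replace(config, seed=seed)
    return simulate_dataset(config, dataset_id="storage")


def scenario_groups(
    config: SimulationConfig | None = None, seed: int | None = None
) -> SimulatedDataset:
    """Two-phenotype scenario with planted group-discriminating features."""
    if config is None:
        config = SimulationConfig(
            groups=(("healthy", 5), ("macro", 5)),
            de_groups=("macro",),
            n_stable=0,
            n_attenuated=0,
            group_annotations=(
                ("healthy", (("disease_group", "healthy"),)),
                ("macro", (("disease_group", "macro"),)),
            ),
        )
    if not config.de_groups:
        raise ConfigurationError("group scenario needs a DE group")
    if seed is not None:
        config = replace(config, seed=seed)
    return simulate_dataset(config, dataset_id="dkd")


def scenario_multidataset(configs: Sequence[SimulationConfig]) -> list[SimulatedDataset]:
    """Independent datasets sharing one planted stable-gene set.

    Library sizes, nuisance abundances and dispersions are redrawn per
    dataset; the planted stable genes keep the same identities, abundances
    and low dispersion everywhere. Configs must agree on the planted-set
    parameters (and gene count, which fixes the identifier namespace).
    """
    if not configs:
        raise ConfigurationError("need at least one dataset config")
    head = configs[0]
    for cfg in configs[1:]:
        same = (
            cfg.n_genes == head.n_genes
            and cfg.n_stable == head.n_stable
            and cfg.stable_dispersion == head.stable_dispersion
            and cfg.stable_mu_log_location == head.stable_mu_log_location
            and cfg.stable_mu_log_scale == head.stable_mu_log_scale
        )
        if not same:
            raise ConfigurationError("planted stable-gene settings differ between configs")
    master = np.random.SeedSequence(head.seed)
    children = master.spawn(len(configs) + 1)
    setup_rng = np.random.default_rng(children[0])
    gene_ids = np.array([f"G{i:05d}" for i in range(head.n_genes)])
    stable_ids = tuple(gene_ids[setup_rng.permutation(head.n_genes)[: head.n_stable]])
    stable_mu = setup_rng.lognormal(
        head.stable_mu_log_location, head.stable_mu_log_scale, size=head.n_stable
    )
    datasets = []
    for i, cfg in enumerate(configs):
        rng = np.random.default_rng(children[i + 1])
        shared = (stable_ids, stable_mu) if head.n_stable else None
        datasets.append(
            simulate_dataset(cfg, rng=rng, dataset_id=f"ds{i + 1}", shared_stable=shared)
        )
    return datasets
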