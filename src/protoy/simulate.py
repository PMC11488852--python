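"""Synthetic data generators for the proto-Y trans-regulation pipeline.

Every pipeline input can be generated here with known ground truth:
negative-binomial RNA-seq counts with planted co-expression modules, batch
effects and genotype log2 fold-changes; diagnostic-SNP allele read depths
with configurable III^M bias; and mating trials (competitive outcomes and
right-censored copulation latencies) with planted genotype/temperature
effects.

All randomness flows from a single integer seed through a counter-based
Philox stream, so a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GroundTruth",
    "MatingEffects",
    "TrialTable",
    "simulate_counts",
    "simulate_allele_depths",
    "simulate_mating_trials",
]

#: natural-log <-> log2 conversion for variance bookkeeping
_LN2_SQ = math.log(2.0) ** 2


@dataclass
class SimConfig:
    """Configuration for :func:`simulate_counts`.

    Defaults emulate a bulk head RNA-seq comparison of Y^M and III^M males:
    two genotype groups across a handful of strain-by-experiment batches,
    negative-binomial counts with log-normally distributed gene means, and
    optional planted co-expression modules and differential expression.

    Parameters
    ----------
    n_genes, n_samples, n_batches
        Matrix dimensions and number of multiplicative batch groups.
    genotype_labels
        Pair of genotype category names; the second label is the one whose
        planted fold-changes are positive (fold-change orientation is
        ``genotype_labels[1] - genotype_labels[0]``, i.e. III^M minus Y^M).
    n_per_genotype
        Sample counts per genotype; ``None`` splits ``n_samples`` evenly
        (remainder to the second genotype, mirroring the 9 vs 15 imbalance
        of the motivating data sets).
    module_spec
        ``(size, latent_correlation)`` per planted module.  Module genes
        share a latent Gaussian factor scaled so their realized pairwise
        correlation approximates ``latent_correlation``.
    de_spec
        ``(gene_index, log2_fold_change)`` pairs planted on the genotype
        contrast.
    nb_dispersion
        Negative-binomial dispersion alpha (var = mu + alpha * mu^2).
    bio_log2_sd
        Per-gene biological log2 standard deviation across replicates.
    batch_log2_sd
        Standard deviation of per-(gene, batch) multiplicative log2 shifts.
    library_size_range
        Inclusive range of per-sample library sizes (total counts, in
        expectation).
    """

    n_genes: int = 2000
    n_samples: int = 24
    n_batches: int = 3
    genotype_labels: tuple[str, str] = ("YM", "IIIM")
    n_per_genotype: tuple[int, int] | None = None
    module_spec: Sequence[tuple[int, float]] = ()
    de_spec: Sequence[tuple[int, float]] = ()
    nb_dispersion: float = 0.05
    bio_log2_sd: float = 0.35
    batch_log2_sd: float = 0.3
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.5
    library_size_range: tuple[int, int] = (8_000_000, 12_000_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ValueError("library sizes must be positive and ordered")
        sizes = [s for s, _ in self.module_spec]
        if any(s < 1 for s in sizes):
            raise ValueError("module sizes must be positive")
        if sum(sizes) > self.n_genes:
            raise ValueError("module sizes exceed n_genes")
        for _, rho in self.module_spec:
            if not 0.0 <= rho <= 1.0:
                raise ValueError("latent_correlation must lie in [0, 1]")
        for idx, _ in self.de_spec:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"de_spec gene index {idx} out of range")
        n0, n1 = self._genotype_counts()
        if min(n0, n1) < 2:
            raise ValueError("need at least 2 samples per genotype")

    def _genotype_counts(self) -> tuple[int, int]:
        if self.n_per_genotype is not None:
            return tuple(self.n_per_genotype)  # type: ignore[return-value]
        half = self.n_samples // 2
        return half, self.n_samples - half


@dataclass
class GroundTruth:
    """Planted quantities, recorded exactly once, for recovery tests."""

    module_membership: list[int] = field(default_factory=list)
    true_log2_fc: list[float] = field(default_factory=list)
    allele_bias: dict[str, float] = field(default_factory=dict)
    hazard_ratios: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a gene-by-sample count matrix with planted structure.

    Counts are negative binomial with gene-wise means drawn log-normally.
    Planted modules share a per-sample latent Gaussian factor added on the
    log2-mean scale, scaled so realized pairwise correlations approximate
    the requested latent correlation.  Planted fold-changes multiply the
    genotype means by ``2^(+F/2)`` / ``2^(-F/2)``; batch shifts act
    multiplicatively.

    Returns ``(counts, metadata, truth)`` where ``counts`` is an integer
    DataFrame (genes x samples), ``metadata`` has one row per sample
    (genotype, batch, strain, temperature) and ``truth`` records the
    planted module membership and fold-changes.
    """
    config.validate()
    rng = np.random.Generator(np.random.Philox(config.seed))
    g, n = config.n_genes, config.n_samples
    n0, n1 = config._genotype_counts()
    lab0, lab1 = config.genotype_labels

    genotype = np.array([lab0] * n0 + [lab1] * n1)
    batch = np.array([f"b{i % config.n_batches + 1}" for i in range(n)])
    meta = pd.DataFrame(
        {
            "sample": [f"s{i + 1:02d}" for i in range(n)],
            "genotype": genotype,
            "batch": batch,
            "strain": np.where(genotype == lab1, "CS", "IsoCS"),
            "temperature": 22.0,
        }
    ).set_index("sample")

    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=g)
    log2_mu = np.tile(base[:, None], (1, n)).astype(float)

    # genotype contrast: planted F is (second label) minus (first label)
    x = np.where(genotype == lab1, 0.5, -0.5)
    true_fc = np.zeros(g)
    for idx, fc in config.de_spec:
        true_fc[idx] += fc
    log2_mu += true_fc[:, None] * x[None, :]

    # idiosyncratic biological noise plus shared module factors
    sigma = config.bio_log2_sd
    log2_mu += rng.normal(0.0, sigma, size=(g, n))
    # count-level (shot + overdispersion) noise on the log2 scale, used to
    # de-attenuate the latent factor so realized r ~ latent_correlation
    mu_typical = 2.0 ** config.base_log2_mean
    nu_count = (1.0 / mu_typical + config.nb_dispersion) / _LN2_SQ
    nu_total = sigma**2 + nu_count

    membership = np.zeros(g, dtype=int)
    start = 0
    for m, (size, rho) in enumerate(config.module_spec, start=1):
        members = np.arange(start, start + size)
        start += size
        membership[members] = m
        if rho > 0:
            scale = math.sqrt(rho / max(1.0 - rho, 1e-12) * nu_total)
            z = rng.normal(0.0, 1.0, size=n)
            loading = rng.choice([1.0, -1.0], size=size)  # unsigned network
            log2_mu[members, :] += scale * loading[:, None] * z[None, :]

    # multiplicative batch shifts, gene-by-batch
    batch_levels = sorted(set(batch))
    shifts = rng.normal(0.0, config.batch_log2_sd, size=(g, len(batch_levels)))
    for j, b in enumerate(batch_levels):
        log2_mu[:, batch == b] += shifts[:, [j]]

    mu = 2.0**log2_mu
    libs = rng.integers(config.library_size_range[0], config.library_size_range[1] + 1, size=n)
    mu *= libs[None, :] / mu.sum(axis=0, keepdims=True)

    # gamma-Poisson mixture = negative binomial with dispersion alpha
    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(
        counts,
        index=pd.Index([f"gene{i + 1:05d}" for i in range(g)], name="gene"),
        columns=meta.index,
    )
    truth = GroundTruth(
        module_membership=membership.tolist(),
        true_log2_fc=true_fc.tolist(),
    )
    return counts_df, meta, truth


def simulate_allele_depths(
    n_sites: int,
    bias_spec: Sequence[float] | float,
    seed: int = 0,
    groups: Sequence[tuple[str, str]] | None = None,
    site_depth: float | Sequence[float] = 50.0,
    library_size_range: tuple[int, int] = (8_000_000, 12_000_000),
    allow_any_groups: bool = False,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate per-site allele read depths at diagnostic SNPs.

    In III^M (heterozygous) groups the III^M-allele depth is binomial with
    the per-site bias fraction; Y^M groups are homozygous for the standard
    III allele and contribute III rows only.  ``groups`` is a list of
    ``(group_label, genotype)`` pairs and defaults to the study layout of
    4 III^M plus 4 Y^M strain-by-batch combinations.

    Returns a tidy table (scaffold, pos, allele, group, genotype, depth,
    library_size) and the planted bias per site.
    """
    if groups is None:
        groups = [(f"IIIM_{i}", "IIIM") for i in range(1, 5)] + [
            (f"YM_{i}", "YM") for i in range(1, 5)
        ]
    if len(groups) != 8 and not allow_any_groups:
        raise ValueError("expected 8 groups (4 IIIM + 4 YM); pass allow_any_groups=True to override")
    bias = np.broadcast_to(np.asarray(bias_spec, dtype=float), (n_sites,)).copy()
    if np.any((bias < 0) | (bias > 1)):
        raise ValueError("bias fractions must lie in [0, 1]")
    depth = np.broadcast_to(np.asarray(site_depth, dtype=float), (n_sites,)).copy()
    lo, hi = library_size_range
    if lo <= 0:
        raise ValueError("library sizes must be positive")

    rng = np.random.Generator(np.random.Philox(seed))
    libs = {grp: int(rng.integers(lo, hi + 1)) for grp, _ in groups}
    rows = []
    for s in range(n_sites):
        scaffold, pos = "scaffold_1", 1000 + 100 * s
        total = rng.poisson(depth[s], size=len(groups))
        for (grp, gt), tot in zip(groups, total):
            if gt == "IIIM":
                d_m = rng.binomial(int(tot), bias[s])
                rows.append((scaffold, pos, "IIIM", grp, gt, int(d_m), libs[grp]))
                rows.append((scaffold, pos, "III", grp, gt, int(tot - d_m), libs[grp]))
            else:
                rows.append((scaffold, pos, "III", grp, gt, int(tot), libs[grp]))
    table = pd.DataFrame(
        rows,
        columns=["scaffold", "pos", "allele", "group", "genotype", "depth", "library_size"],
    )
    truth = GroundTruth(allele_bias={f"scaffold_1:{1000 + 100 * s}": float(bias[s]) for s in range(n_sites)})
    return table, truth


@dataclass
class MatingEffects:
    """Planted effects for :func:`simulate_mating_trials`.

    Latency defaults reproduce the single-choice study conditions: a Y^M
    baseline mating hazard at 22 deg C of ~0.00139 events/min (so ~28% of
    males mate within the 4 hr window), a III^M hazard ratio of 2.92, and
    strongly reduced mating at 29 deg C.
    """

    baseline_rate: float = 0.00139
    genotype_hr: float = 2.92
    temperature_hr: float = 0.25
    interaction_hr: float = 1.0
    batch_sd: float = 0.0
    n_batches: int = 5
    comp_intercept: float = 0.0
    comp_genotype_beta: float = 1.0
    comp_temperature_beta: float = 0.0
    comp_interaction_beta: float = 0.0


@dataclass
class TrialTable:
    """Mating-trial outputs: latency records plus competitive outcomes."""

    latency: pd.DataFrame
    competitive: pd.DataFrame


def simulate_mating_trials(
    n_trials: int,
    effects: MatingEffects | None = None,
    censor_minutes: float = 240.0,
    seed: int = 0,
    temperatures: tuple[float, float] = (22.0, 29.0),
) -> tuple[TrialTable, GroundTruth]:
    """Simulate single-choice latency records and competitive outcomes.

    Latencies are exponential with group-specific hazards, observed on a
    10-minute grid (values rounded up to the next grid point, matching an
    every-10-min observation protocol); latencies beyond ``censor_minutes``
    are right-censored at the bound.  Competitive winners are drawn from a
    logistic model on the blue male's genotype, temperature and their
    interaction, with batch shifts on the log-odds scale.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be positive")
    if censor_minutes < 0:
        raise ValueError("censor_minutes must be non-negative")
    eff = effects or MatingEffects()
    if min(eff.genotype_hr, eff.temperature_hr, eff.interaction_hr) <= 0:
        raise ValueError("hazard ratios must be positive")
    rng = np.random.Generator(np.random.Philox(seed))

    idx = np.arange(n_trials)
    genotype = np.where(idx % 2 == 0, "YM", "IIIM")
    temperature = np.where((idx // 2) % 2 == 0, temperatures[0], temperatures[1])
    batch = np.array([f"b{i % eff.n_batches + 1}" for i in idx])
    strain = np.where(genotype == "IIIM", "CS", "IsoCS")
    batch_eff = {f"b{i + 1}": rng.normal(0.0, eff.batch_sd) for i in range(eff.n_batches)}

    is_m = (genotype == "IIIM").astype(float)
    is_hot = (temperature == temperatures[1]).astype(float)
    rate = (
        eff.baseline_rate
        * eff.genotype_hr**is_m
        * eff.temperature_hr**is_hot
        * eff.interaction_hr ** (is_m * is_hot)
        * np.exp([batch_eff[b] for b in batch])
    )
    raw = rng.exponential(1.0 / rate)
    grid = np.ceil(raw / 10.0) * 10.0
    censored = grid > censor_minutes
    latency = np.where(censored, censor_minutes, grid)
    lat = pd.DataFrame(
        {
            "latency_min": latency,
            "censored": censored,
            "genotype": genotype,
            "temperature": temperature,
            "strain": strain,
            "batch": batch,
        }
    )

    blue_genotype = np.where(idx % 2 == 0, "IIIM", "YM")  # color alternates every trial
    gb = np.where(blue_genotype == "IIIM", 0.5, -0.5)
    t = np.where(temperature == temperatures[1], 0.5, -0.5)
    logit = (
        eff.comp_intercept
        + eff.comp_genotype_beta * gb
        + eff.comp_temperature_beta * t
        + eff.comp_interaction_beta * gb * t
        + np.array([batch_eff[b] for b in batch])
    )
    p_blue = 1.0 / (1.0 + np.exp(-logit))
    blue_wins = rng.random(n_trials) < p_blue
    winner = np.where(blue_wins, blue_genotype, np.where(blue_genotype == "IIIM", "YM", "IIIM"))
    comp = pd.DataFrame(
        {
            "winner": winner,
            "blue_genotype": blue_genotype,
            "temperature": temperature,
            "batch": batch,
        }
    )
    truth = GroundTruth(
        hazard_ratios={
            "genotype": eff.genotype_hr,
            "temperature": eff.temperature_hr,
            "interaction": eff.interaction_hr,
        }
    )
    return TrialTable(latency=lat, competitive=comp), truth
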