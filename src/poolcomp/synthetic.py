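"""Synthetic score/count report generator.

Emulates the study design the analysis stages assume: several divergent
accessions (Balding–Nichols drift around ancestral frequencies), partial
inbreeding within accessions, marker-level missingness in the score data,
and nested tissue pools (20 ⊂ 30 ⊂ 40 ⊂ 50 ⊂ 60 members) sequenced as two
tissue replicates x two library depth classes each.

Pooling acts on *tissue*, before genotyping: pool read counts are drawn
from the members' true genotypes, so score-level missingness never
propagates into the pools. Pool missingness arises only from zero
coverage at a marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import CountMatrix, PoolDesign, PoolSample, ScoreMatrix

#: marker count at which the library depth classes (in Mr) are calibrated;
#: per-marker mean coverage = depth_class * 1e6 / REFERENCE_MARKER_COUNT,
#: so scaled-down runs keep the real-scale coverage geometry.
REFERENCE_MARKER_COUNT = 130_000

#: concentration of the Beta distribution for per-marker missing rates
#: (alpha + beta). Kept small so the marker-level missingness is strongly
#: overdispersed (most markers near-complete, a heavy tail of bad ones),
#: matching how reduced-representation genotyping data behave; a sizeable
#: marker fraction must survive a 10% missing-data cut even when the
#: overall rate is ~30%.
MD_BETA_CONCENTRATION = 2.0

#: negative-binomial shape (overdispersion) parameter for per-marker coverage.
COVERAGE_NB_SHAPE = 5.0


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset."""

    n_accessions: int = 5
    n_markers: int = 2000
    n_individuals_per_accession: int = 60
    divergence_theta: float = 0.15
    #: optional per-accession drift parameters (one per accession); when
    #: set they override divergence_theta and give heterogeneous pairwise
    #: divergence (realistic F_ST ranges rather than exchangeable pairs).
    accession_thetas: tuple[float, ...] | None = None
    fis: float = 0.2
    ancestral_freq_range: tuple[float, float] = (0.02, 0.98)
    md_target: float = 0.29
    pool_sizes: tuple[int, ...] = (20, 30, 40, 50, 60)
    tissue_replicates: int = 2
    library_depth_classes: tuple[float, ...] = (0.9, 1.5)  # Mr per library
    contribution_cv: float = 0.3
    error_rate: float = 0.15
    #: shape of the symmetric Beta spectrum for ancestral frequencies inside
    #: ancestral_freq_range; None = uniform, values < 1 give the U-shaped,
    #: rare-allele-heavy spectrum typical of de-novo-called marker panels.
    ancestral_beta: float | None = 0.6
    #: Gamma shape of the per-marker representation factor (mean 1) that
    #: scales pool coverage; None = all markers equally represented. The
    #: factor is coupled to the marker's score missing rate (bad markers
    #: are bad in both report types), which is what makes pool missingness
    #: and the Representativity-vs-MD trend realistic.
    marker_weight_shape: float | None = 0.8
    #: multiplier on the per-marker mean coverage of every library; the
    #: depth-class labels (and hence the 1.8/3.0/4.8 merge semantics) are
    #: unchanged. Values >> 1 give the near-noise-free sequencing regime.
    coverage_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 1 or self.n_markers < 1:
            raise ValueError("n_accessions and n_markers must be >= 1")
        if not 0.0 < self.divergence_theta < 1.0:
            raise ValueError(
                f"divergence_theta must lie in (0, 1), got {self.divergence_theta}"
            )
        if self.accession_thetas is not None:
            if len(self.accession_thetas) != self.n_accessions:
                raise ValueError("need one accession_theta per accession")
            if any(not 0.0 < t < 1.0 for t in self.accession_thetas):
                raise ValueError("accession_thetas must lie in (0, 1)")
        if not 0.0 <= self.fis <= 1.0:
            raise ValueError(f"fis must lie in [0, 1], got {self.fis}")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("ancestral_freq_range must satisfy 0 < lo < hi < 1")
        if not 0.0 <= self.md_target < 1.0:
            raise ValueError(f"md_target must lie in [0, 1), got {self.md_target}")
        if list(self.pool_sizes) != sorted(set(self.pool_sizes)):
            raise ValueError("pool_sizes must be strictly increasing")
        if max(self.pool_sizes) > self.n_individuals_per_accession:
            raise ValueError("largest pool size exceeds individuals per accession")
        if self.tissue_replicates < 1:
            raise ValueError("tissue_replicates must be >= 1")
        if any(d <= 0 for d in self.library_depth_classes):
            raise ValueError("library depth classes must be positive")
        if self.contribution_cv < 0:
            raise ValueError("contribution_cv must be >= 0")
        if self.ancestral_beta is not None and self.ancestral_beta <= 0:
            raise ValueError("ancestral_beta must be positive (or None for uniform)")
        if self.marker_weight_shape is not None and self.marker_weight_shape <= 0:
            raise ValueError("marker_weight_shape must be positive (or None)")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must lie in [0, 0.5), got {self.error_rate}")
        if self.coverage_scale <= 0:
            raise ValueError("coverage_scale must be positive")

    @property
    def accession_labels(self) -> tuple[str, ...]:
        return tuple(f"A{i + 1}" for i in range(self.n_accessions))

    def library_reads(self, depth_class: float) -> float:
        """Total reads of one library at desk scale (proportional rescale)."""
        return (
            depth_class * 1e6 * self.n_markers / REFERENCE_MARKER_COUNT
            * self.coverage_scale
        )

    def mean_coverage(self, depth_class: float) -> float:
        return self.library_reads(depth_class) / self.n_markers


@dataclass
class TrueFrequencies:
    """Latent per-marker major-allele frequencies (simulation truth)."""

    ancestral_p: np.ndarray
    accession_p: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ancestral_p = np.asarray(self.ancestral_p, dtype=float)
        for label, p in self.accession_p.items():
            p = np.asarray(p, dtype=float)
            if p.shape != self.ancestral_p.shape:
                raise ValueError(f"accession {label!r} frequency shape mismatch")
            if ((p < 0) | (p > 1)).any():
                raise ValueError(f"accession {label!r} frequencies outside [0, 1]")
            self.accession_p[label] = p


def simulate_metapopulation(config: SimConfig) -> TrueFrequencies:
    """Draw ancestral and per-accession allele frequencies.

    Each accession's frequency at a marker with ancestral frequency ``p``
    is Beta-distributed with mean ``p`` and variance ``theta * p * (1-p)``
    (Balding–Nichols), i.e. Beta(p (1-theta)/theta, (1-p)(1-theta)/theta).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.ancestral_freq_range
    if config.ancestral_beta is None:
        ancestral = rng.uniform(lo, hi, size=config.n_markers)
    else:
        b = config.ancestral_beta
        ancestral = lo + (hi - lo) * rng.beta(b, b, size=config.n_markers)
    thetas = config.accession_thetas or (config.divergence_theta,) * config.n_accessions
    accession_p = {}
    for label, theta in zip(config.accession_labels, thetas):
        scale = (1.0 - theta) / theta
        accession_p[label] = rng.beta(ancestral * scale, (1.0 - ancestral) * scale)
    return TrueFrequencies(ancestral_p=ancestral, accession_p=accession_p)


def simulate_genotypes(
    truth: TrueFrequencies,
    accession: str,
    n: int,
    fis: float,
    seed: int,
    sample_prefix: str | None = None,
) -> ScoreMatrix:
    """Draw ``n`` diploid genotypes for one accession.

    Genotype probabilities follow inbreeding-adjusted Hardy–Weinberg:
    P(AA) = p^2 + F p q, P(Aa) = 2 p q (1 - F), P(aa) = q^2 + F p q.
    """
    if accession not in truth.accession_p:
        raise KeyError(f"unknown accession {accession!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= fis <= 1.0:
        raise ValueError(f"fis must lie in [0, 1], got {fis}")
    rng = np.random.default_rng(seed)
    p = truth.accession_p[accession][:, None]
    q = 1.0 - p
    p_aa_major = p * p + fis * p * q
    p_het = 2.0 * p * q * (1.0 - fis)
    u = rng.random((len(truth.ancestral_p), n))
    genotypes = np.full(u.shape, 2, dtype=np.int8)  # hom-minor unless overridden
    genotypes[u < p_aa_major + p_het] = 1
    genotypes[u < p_aa_major] = 0
    prefix = sample_prefix or accession
    width = len(str(n))
    sample_ids = np.array([f"{prefix}_{i + 1:0{width}d}" for i in range(n)], dtype=object)
    marker_ids = np.array([f"M{i + 1}" for i in range(len(truth.ancestral_p))], dtype=object)
    return ScoreMatrix(
        marker_ids=marker_ids,
        sample_ids=sample_ids,
        genotypes=genotypes,
        accession_of_sample={s: accession for s in sample_ids},
    )


def simulate_all_genotypes(truth: TrueFrequencies, config: SimConfig) -> ScoreMatrix:
    """Genotypes for every accession, concatenated into one score matrix."""
    rng = np.random.default_rng(config.seed + 1)
    parts = []
    accession_of_sample: dict[str, str] = {}
    for label in config.accession_labels:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        part = simulate_genotypes(
            truth, label, config.n_individuals_per_accession, config.fis, sub_seed
        )
        parts.append(part)
        accession_of_sample.update(part.accession_of_sample)
    return ScoreMatrix(
        marker_ids=parts[0].marker_ids,
        sample_ids=np.concatenate([p.sample_ids for p in parts]),
        genotypes=np.concatenate([p.genotypes for p in parts], axis=1),
        accession_of_sample=accession_of_sample,
    )


def apply_missingness(
    scores: ScoreMatrix,
    md_target: float,
    seed: int,
    concentration: float = MD_BETA_CONCENTRATION,
    marker_quantiles: np.ndarray | None = None,
) -> ScoreMatrix:
    """Mask entries at a per-marker Beta-Bernoulli missing rate.

    Per-marker rates are Beta with mean ``md_target`` and concentration
    :data:`MD_BETA_CONCENTRATION`; entries are masked independently given
    the marker rate. ``md_target=0`` returns an unmodified copy.

    ``marker_quantiles`` (uniform in (0,1), one per marker) optionally fix
    each marker's position in the rate distribution, so a shared quality
    variable can couple score missingness to pool representation.
    """
    if not 0.0 <= md_target < 1.0:
        raise ValueError(f"md_target must lie in [0, 1), got {md_target}")
    genotypes = scores.genotypes.copy()
    if md_target > 0.0:
        from scipy.stats import beta as beta_dist

        rng = np.random.default_rng(seed)
        a = md_target * concentration
        b = (1.0 - md_target) * concentration
        if marker_quantiles is None:
            rates = rng.beta(a, b, size=scores.n_markers)
        else:
            if len(marker_quantiles) != scores.n_markers:
                raise ValueError("need one quantile per marker")
            rates = beta_dist.ppf(marker_quantiles, a, b)
        mask = rng.random(genotypes.shape) < rates[:, None]
        genotypes[mask] = -1
    return ScoreMatrix(
        marker_ids=scores.marker_ids.copy(),
        sample_ids=scores.sample_ids.copy(),
        genotypes=genotypes,
        accession_of_sample=dict(scores.accession_of_sample),
    )


def build_pool_design(config: SimConfig, membership_seed: int) -> PoolDesign:
    """Nested random pool membership plus the replicate/library layout.

    For each accession a random subset of ``pool_sizes[0]`` individuals is
    drawn, then grown by random additions to each larger size, so the
    member sets are strictly nested. Every (accession, size) combination
    yields ``tissue_replicates x len(library_depth_classes)`` pool-library
    samples sharing that membership.
    """
    rng = np.random.default_rng(membership_seed)
    n = config.n_individuals_per_accession
    width = len(str(n))
    pools: list[PoolSample] = []
    for label in config.accession_labels:
        sample_ids = [f"{label}_{i + 1:0{width}d}" for i in range(n)]
        order = rng.permutation(n)
        for size in config.pool_sizes:
            members = tuple(sorted(sample_ids[i] for i in order[:size]))
            for rep in range(1, config.tissue_replicates + 1):
                for depth in config.library_depth_classes:
                    pools.append(
                        PoolSample(
                            pool_sample_id=f"{label}_s{size}_r{rep}_{depth}Mr",
                            accession=label,
                            size=size,
                            tissue_rep=rep,
                            depth_class=depth,
                            member_ids=members,
                        )
                    )
    return PoolDesign(pools=pools)


def marker_representation(
    config: SimConfig, marker_quantiles: np.ndarray
) -> np.ndarray:
    """Per-marker coverage multipliers (mean ~1) from quality quantiles.

    Low-quality markers (high missing-rate quantile) get small factors:
    the Gamma(:attr:`SimConfig.marker_weight_shape`) factor is evaluated
    at ``1 - quantile``, making representation comonotone with call rate.
    """
    if config.marker_weight_shape is None:
        return np.ones(len(marker_quantiles))
    from scipy.stats import gamma as gamma_dist

    k = config.marker_weight_shape
    return gamma_dist.ppf(1.0 - marker_quantiles, k, scale=1.0 / k)


def simulate_pool_counts(
    scores: ScoreMatrix,
    design: PoolDesign,
    config: SimConfig,
    seed: int,
    marker_weights: np.ndarray | None = None,
) -> CountMatrix:
    """Draw read counts for every pool-library sample in the design.

    ``scores`` must be the *true* (pre-missingness) genotypes: tissue is
    pooled before genotyping, so every member contributes regardless of
    whether its individual score was later masked.

    Per tissue replicate, member weights are i.i.d. Gamma with coefficient
    of variation ``contribution_cv`` (equal weights when 0), normalized to
    sum to 1; both libraries of a replicate share its weights. Per-marker
    coverage is negative-binomial with mean ``library_reads / n_markers``;
    major-allele reads are Binomial(coverage, f(1-e) + (1-f)e) where ``f``
    is the weighted major-allele dose fraction of the pool.

    ``marker_weights`` optionally scales each marker's expected coverage
    (mean ~1 across markers), modelling unequal marker representation in
    the sequencing libraries.
    """
    if (scores.genotypes < 0).any():
        raise ValueError("simulate_pool_counts requires true genotypes (no missing)")
    rng = np.random.default_rng(seed)
    n_markers = scores.n_markers
    if marker_weights is None:
        marker_weights = np.ones(n_markers)
    elif len(marker_weights) != n_markers:
        raise ValueError("need one coverage weight per marker")
    # weights are a property of the tissue replicate, shared by its libraries
    weights_of_rep: dict[tuple[str, int, int], np.ndarray] = {}
    for pool in design:
        key = (pool.accession, pool.size, pool.tissue_rep)
        if key not in weights_of_rep:
            k = len(pool.member_ids)
            if config.contribution_cv > 0:
                shape = 1.0 / config.contribution_cv**2
                w = rng.gamma(shape, 1.0 / shape, size=k)
            else:
                w = np.ones(k)
            weights_of_rep[key] = w / w.sum()
    major = np.zeros((n_markers, len(design)), dtype=np.int64)
    minor = np.zeros_like(major)
    for col, pool in enumerate(design):
        idx = scores.sample_indices(pool.member_ids)
        dose = (2 - scores.genotypes[:, idx]).astype(float)  # major-allele dose
        w = weights_of_rep[(pool.accession, pool.size, pool.tissue_rep)]
        f = dose @ w / 2.0
        mu = config.mean_coverage(pool.depth_class) * marker_weights
        r = COVERAGE_NB_SHAPE
        coverage = rng.negative_binomial(r, r / (r + mu))
        e = config.error_rate
        p_read = np.clip(f * (1.0 - e) + (1.0 - f) * e, 0.0, 1.0)
        n_a = rng.binomial(coverage, p_read)
        major[:, col] = n_a
        minor[:, col] = coverage - n_a
    return CountMatrix(
        marker_ids=scores.marker_ids.copy(),
        pool_sample_ids=np.array([p.pool_sample_id for p in design], dtype=object),
        major=major,
        minor=minor,
    )


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimConfig
    truth: TrueFrequencies
    true_scores: ScoreMatrix  # pre-missingness genotypes (pooled tissue)
    scores: ScoreMatrix  # observed score report (with missingness)
    design: PoolDesign
    counts: CountMatrix


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the whole generator with seeds derived from ``config.seed``."""
    truth = simulate_metapopulation(config)
    true_scores = simulate_all_genotypes(truth, config)
    # one quality quantile per marker couples score missingness (high
    # quantile = high missing rate) to pool representation (low coverage)
    quality = np.random.default_rng(config.seed + 5).random(config.n_markers)
    scores = apply_missingness(
        true_scores, config.md_target, config.seed + 2, marker_quantiles=quality
    )
    design = build_pool_design(config, config.seed + 3)
    counts = simulate_pool_counts(
        true_scores, design, config, config.seed + 4,
        marker_weights=marker_representation(config, quality),
    )
    return SimulatedDataset(
        config=config,
        truth=truth,
        true_scores=true_scores,
        scores=scores,
        design=design,
        counts=counts,
    )
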