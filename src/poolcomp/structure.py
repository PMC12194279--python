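"""Between-accession structure statistics.

Distances (Nei 1972 standard distance, Rogers distance), Weir–Cockerham
F_ST, distance-based AMOVA with a permutation test, classical (Torgerson)
multidimensional scaling, and the Mantel matrix-correlation test.

Units for individual-level analyses are individuals encoded as
within-individual major-allele frequencies (0, 1/2, 1, NaN for missing);
units for pool-level analyses are pool-samples encoded as major-allele
frequency vectors. Missing entries are handled pairwise-complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import FrequencyTable, ScoreMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    metric: str  # "nei" | "rogers" | "fst"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite]):
            raise ValueError("distance matrix must be symmetric")

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class AmovaResult:
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    sigma2_between: float
    sigma2_within: float
    pct_between: float
    pct_within: float
    p_value: float | None
    n_permutations: int


@dataclass
class MdsResult:
    labels: list[str]
    coordinates: np.ndarray  # units x dims
    eigenvalues: np.ndarray  # all, descending
    explained: np.ndarray  # fraction of positive-eigenvalue mass, per kept dim


# ---------------------------------------------------------------------------
# distances


def nei_distance(freq_a: FrequencyTable, freq_b: FrequencyTable) -> float:
    """Nei (1972) standard genetic distance between two accessions.

    D = -ln( J_ab / sqrt(J_a J_b) ) with identities summed over shared
    loci and both alleles (ratio-of-sums aggregation). Returns ``inf``
    when the inter-population identity is zero.
    """
    shared = [m for m in freq_a.marker_ids if m in set(freq_b.marker_ids)]
    if not shared:
        raise ValueError("no shared loci")
    pa = np.array([freq_a.freq_of()[m] for m in shared])
    pb = np.array([freq_b.freq_of()[m] for m in shared])
    qa, qb = 1.0 - pa, 1.0 - pb
    j_a = float(np.sum(pa * pa + qa * qa))
    j_b = float(np.sum(pb * pb + qb * qb))
    j_ab = float(np.sum(pa * pb + qa * qb))
    if j_ab == 0.0:
        return float("inf")
    return float(-np.log(j_ab / np.sqrt(j_a * j_b)))


def nei_matrix(tables: Sequence[FrequencyTable]) -> DistanceMatrix:
    n = len(tables)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = nei_distance(tables[i], tables[j])
    return DistanceMatrix(labels=[t.accession for t in tables], metric="nei", values=values)


def rogers_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Rogers distance between two aligned major-allele frequency vectors.

    Mean over loci of sqrt(1/2 * sum over alleles of (x_u - y_u)^2); for
    biallelic loci this reduces to the mean absolute frequency difference.
    Missing entries (NaN) are dropped pairwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must be aligned")
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError("no shared loci")
    return float(np.abs(x[ok] - y[ok]).mean())


def rogers_matrix(encodings: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    """Pairwise Rogers distances between unit rows (pairwise-complete loci)."""
    X = np.asarray(encodings, dtype=float)
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = rogers_distance(X[i], X[j])
    return DistanceMatrix(labels=list(labels), metric="rogers", values=values)


def genotype_frequency_encoding(
    scores: ScoreMatrix,
    sample_ids: Sequence[str],
    marker_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Individuals as rows of within-individual major-allele frequencies.

    Codes map 0 -> 1.0, 1 -> 0.5, 2 -> 0.0, missing -> NaN.
    """
    idx = scores.sample_indices(list(sample_ids))
    g = scores.genotypes[:, idx].astype(float)
    if marker_ids is not None:
        pos = {m: i for i, m in enumerate(scores.marker_ids)}
        g = g[np.array([pos[m] for m in marker_ids], dtype=np.intp)]
    enc = (2.0 - g) / 2.0
    enc[g < 0] = np.nan
    return enc.T  # units x loci


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST


def _wc_components(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components a, b, c.

    ``n``, ``p``, ``h``: (loci x populations) sample sizes (individuals),
    major-allele frequencies and observed heterozygote fractions.
    """
    r = n.shape[1]
    n_bar = n.mean(axis=1)
    n_c = (r * n_bar - (n**2).sum(axis=1) / (r * n_bar)) / (r - 1)
    p_bar = (n * p).sum(axis=1) / (r * n_bar)
    s2 = (n * (p - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
    h_bar = (n * h).sum(axis=1) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2
        - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def weir_cockerham_fst(
    scores: ScoreMatrix,
    accessions: Sequence[str],
    subsets: dict[str, Sequence[str]] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> float:
    """Multi-population Weir–Cockerham theta, ratio-of-sums over loci.

    Loci where any population has fewer than two non-missing individuals
    are dropped. ``subsets`` optionally restricts each accession to the
    given samples (defaults to all of its samples).
    """
    if len(accessions) < 2:
        raise ValueError("need at least two populations")
    cols = []
    for acc in accessions:
        samples = list(subsets[acc]) if subsets else scores.samples_of_accession(acc)
        if len(samples) < 2:
            raise ValueError(f"accession {acc!r}: need at least two individuals")
        cols.append(scores.sample_indices(samples))
    if marker_ids is not None:
        pos = {m: i for i, m in enumerate(scores.marker_ids)}
        rows = np.array([pos[m] for m in marker_ids], dtype=np.intp)
    else:
        rows = np.arange(scores.n_markers)
    n = np.zeros((len(rows), len(accessions)))
    p = np.zeros_like(n)
    h = np.zeros_like(n)
    for k, idx in enumerate(cols):
        g = scores.genotypes[np.ix_(rows, idx)]
        obs = g != -1
        n_k = obs.sum(axis=1)
        n[:, k] = n_k
        with np.errstate(invalid="ignore"):
            p[:, k] = np.where(n_k > 0, np.where(obs, 2 - g, 0).sum(axis=1) / (2 * np.maximum(n_k, 1)), np.nan)
            h[:, k] = np.where(n_k > 0, (g == 1).sum(axis=1) / np.maximum(n_k, 1), np.nan)
    usable = (n >= 2).all(axis=1)
    if not usable.any():
        raise ValueError("no locus with at least two individuals in every population")
    a, b, c = _wc_components(n[usable], p[usable], h[usable])
    denom = float((a + b + c).sum())
    if denom == 0.0:
        raise ValueError("F_ST undefined: zero total variance")
    return float(a.sum() / denom)


def pairwise_fst(
    scores: ScoreMatrix,
    accession_a: str,
    accession_b: str,
    subsets: dict[str, Sequence[str]] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> float:
    """Two-population Weir–Cockerham theta."""
    return weir_cockerham_fst(scores, [accession_a, accession_b], subsets, marker_ids)


def fst_matrix(
    scores: ScoreMatrix,
    accessions: Sequence[str],
    subsets: dict[str, Sequence[str]] | None = None,
    marker_ids: Sequence[str] | None = None,
) -> DistanceMatrix:
    n = len(accessions)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pairwise_fst(
                scores, accessions[i], accessions[j], subsets, marker_ids
            )
    return DistanceMatrix(labels=list(accessions), metric="fst", values=values)


# ---------------------------------------------------------------------------
# AMOVA


def _ss_decomposition(d2: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """(SS_between, SS_within) from squared distances and group labels."""
    n = len(groups)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for grp in np.unique(groups):
        members = np.flatnonzero(groups == grp)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    return ss_total - ss_within, ss_within


def amova(
    encodings: np.ndarray,
    groups: Sequence[str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> AmovaResult:
    """Distance-based AMOVA on Rogers-distance squared deviations.

    ``encodings`` holds one frequency vector per unit (individuals coded
    0/0.5/1 or pool-samples coded by allele frequency; NaN = missing,
    handled pairwise-complete). Groups are shuffled across units for the
    permutation p-value of the between-group component; the reported p is
    ``(1 + #{perm >= observed}) / (1 + n_permutations)``.
    """
    groups = np.asarray(groups)
    X = np.asarray(encodings, dtype=float)
    if X.shape[0] != len(groups):
        raise ValueError("one group label per unit row is required")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("every group needs at least two units")
    n = len(groups)
    k = len(labels)
    dist = rogers_matrix(X, [str(i) for i in range(n)]).values
    d2 = dist**2
    ss_between, ss_within = _ss_decomposition(d2, groups)
    df_between, df_within = k - 1, n - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    n0 = (n - (counts**2).sum() / n) / (k - 1)
    sigma2_within = ms_within
    sigma2_between = (ms_between - ms_within) / n0
    total = sigma2_between + sigma2_within
    if total == 0.0:  # all units identical: no variance to apportion
        pct_between, pct_within = 0.0, 100.0
    else:
        pct_between = 100.0 * sigma2_between / total
        pct_within = 100.0 * sigma2_within / total
    p_value = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(groups)
            ss_b, _ = _ss_decomposition(d2, perm)
            if ss_b >= ss_between - 1e-12:
                hits += 1
        p_value = (1 + hits) / (1 + n_permutations)
    return AmovaResult(
        df_between=df_between,
        df_within=df_within,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
        sigma2_between=float(sigma2_between),
        sigma2_within=float(sigma2_within),
        pct_between=pct_between,
        pct_within=pct_within,
        p_value=p_value,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# MDS and Mantel


def classical_mds(dist: DistanceMatrix, n_dims: int = 2) -> MdsResult:
    """Torgerson metric MDS: double-center -D^2/2, eigendecompose, scale.

    Coordinates use the ``n_dims`` largest positive eigenvalues (fewer if
    fewer are positive); explained fractions are relative to the positive
    eigenvalue mass.
    """
    D = dist.values
    if not np.isfinite(D).all():
        raise ValueError("MDS requires finite distances")
    if np.allclose(D, 0.0):
        raise ValueError("all-zero distance matrix")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12, 1e-9 * abs(eigval[0]))
    n_keep = min(n_dims, int(positive.sum()))
    coords = eigvec[:, :n_keep] * np.sqrt(eigval[:n_keep])
    explained = eigval[:n_keep] / eigval[positive].sum()
    return MdsResult(
        labels=list(dist.labels),
        coordinates=coords,
        eigenvalues=eigval,
        explained=explained,
    )


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation of two distance matrices over the same labels.

    Pearson r over upper-triangle entries; p from simultaneous row/column
    permutations of the second matrix, one-sided against the "positively
    correlated" alternative (the convention of the ecology packages this
    mirrors), so a strongly negative r yields p near 1.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels in the same order")
    n = len(d1.labels)
    if n < 3:
        raise ValueError("need at least three units")
    iu = np.triu_indices(n, k=1)
    x = d1.values[iu]
    M2 = d2.values
    y = M2[iu]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant distance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        y_perm = M2[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(x, y_perm)[0, 1])
        if r_perm >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return r_obs, p
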