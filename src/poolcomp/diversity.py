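"""Within-accession diversity statistics and the ind/pool H_E comparison.

Individual data yield observed heterozygosity, expected heterozygosity,
the inbreeding coefficient and rarefaction allelic richness; pool data
yield expected heterozygosity and the effective number of alleles. The
two "allele number" summaries are computed differently by construction
and are labelled distinctly (``ar_rarefaction`` vs ``ae_effective``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .datatypes import FrequencyTable, ScoreMatrix


@dataclass
class DiversityRecord:
    """Summary statistics of one accession-dataset."""

    accession: str
    source: str  # "ind" or "pool"
    size: int
    depth: float | None
    n_snps: int  # polymorphic retained markers
    h_obs: float | None  # ind only
    h_exp: float
    fis: float | None  # ind only
    ae: float  # rarefaction richness (ind) or effective alleles (pool)
    ae_kind: str  # "ar_rarefaction" | "ae_effective"


@dataclass
class DeltaHeRecord:
    accession: str
    size: int
    depth: float
    h_exp_ind: float
    h_exp_pool: float
    delta: float


def observed_heterozygosity(
    scores: ScoreMatrix,
    accession: str,
    subset: Sequence[str],
    marker_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Per-locus and mean fraction of heterozygous calls among non-missing.

    ``marker_ids`` restricts the computation to retained markers; loci
    with no non-missing calls are excluded from the mean.
    """
    idx = scores.sample_indices(list(subset))
    g = scores.genotypes[:, idx]
    if marker_ids is not None:
        pos = {m: i for i, m in enumerate(scores.marker_ids)}
        rows = np.array([pos[m] for m in marker_ids], dtype=np.intp)
        g = g[rows]
    observed = g != -1
    n_obs = observed.sum(axis=1)
    if (n_obs == 0).all():
        raise ValueError("no locus with any non-missing genotype")
    with np.errstate(invalid="ignore"):
        per_locus = np.where(n_obs > 0, (g == 1).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    return per_locus, float(np.nanmean(per_locus))


def expected_heterozygosity(table: FrequencyTable) -> tuple[np.ndarray, float]:
    """Per-locus and mean H_E = 1 - p^2 - q^2 (same formula for ind and pool)."""
    per_locus = 1.0 - table.p**2 - table.q**2
    if len(per_locus) == 0:
        raise ValueError("empty frequency table")
    return per_locus, float(per_locus.mean())


def inbreeding_coefficient(
    h_obs: float | np.ndarray, h_exp: float | np.ndarray, per_locus: bool = False
) -> float | np.ndarray:
    """F_IS = 1 - H_O / H_E.

    Default convention: ratio of accession means (scalar in, scalar out).
    With ``per_locus=True`` accepts aligned per-locus arrays and returns
    per-locus values (NaN where H_E is 0).
    """
    if per_locus:
        h_obs = np.asarray(h_obs, dtype=float)
        h_exp = np.asarray(h_exp, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(h_exp > 0, 1.0 - h_obs / np.where(h_exp > 0, h_exp, 1.0), np.nan)
    if h_exp <= 0:
        raise ValueError("F_IS undefined: mean expected heterozygosity is zero")
    return 1.0 - float(h_obs) / float(h_exp)


def _rarefaction_locus(allele_counts: np.ndarray, g: int) -> float:
    """Expected number of distinct alleles in a subsample of g gene copies.

    AR(g) = sum over alleles of 1 - C(N - N_a, g) / C(N, g), evaluated in
    log space for numerical stability.
    """
    n_total = int(allele_counts.sum())
    if g > n_total:
        raise ValueError(f"g={g} exceeds the {n_total} available gene copies")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    total = 0.0
    for count in allele_counts:
        count = int(count)
        if count == 0:
            continue
        if n_total - count < g:
            total += 1.0
        else:
            total += 1.0 - np.exp(log_comb(n_total - count, g) - log_comb(n_total, g))
    return total


def allelic_richness_rarefaction(
    scores: ScoreMatrix,
    accession: str,
    subset: Sequence[str],
    g: int | None = None,
    marker_ids: Sequence[str] | None = None,
) -> tuple[np.ndarray, float, int]:
    """Rarefaction allelic richness per locus and its mean.

    ``g`` is the standardized number of gene copies; it defaults to the
    minimum non-missing gene-copy count over the loci considered (i.e.
    2 x the smallest per-locus sample), so every locus can be rarefied.
    Loci with fewer than ``g`` copies are excluded. Returns
    ``(per_locus, mean, g_used)``.
    """
    idx = scores.sample_indices(list(subset))
    geno = scores.genotypes[:, idx]
    if marker_ids is not None:
        pos = {m: i for i, m in enumerate(scores.marker_ids)}
        rows = np.array([pos[m] for m in marker_ids], dtype=np.intp)
        geno = geno[rows]
    observed = geno != -1
    n_copies = 2 * observed.sum(axis=1)
    if (n_copies == 0).all():
        raise ValueError("no locus with data")
    if g is None:
        g = int(n_copies[n_copies > 0].min())
    if g < 2:
        raise ValueError(f"g must be >= 2, got {g}")
    major_copies = np.where(observed, 2 - geno, 0).sum(axis=1)
    per_locus = np.full(len(n_copies), np.nan)
    for i in range(len(n_copies)):
        if n_copies[i] < g:
            continue  # excluded: fewer copies than the rarefaction size
        counts = np.array([major_copies[i], n_copies[i] - major_copies[i]])
        per_locus[i] = _rarefaction_locus(counts, g)
    if np.isnan(per_locus).all():
        raise ValueError(f"no locus has at least g={g} gene copies")
    return per_locus, float(np.nanmean(per_locus)), g


def effective_alleles_pool(table: FrequencyTable) -> tuple[np.ndarray, float]:
    """Effective number of alleles per locus, Ae = 1 / (p^2 + q^2)."""
    per_locus = 1.0 / (table.p**2 + table.q**2)
    if len(per_locus) == 0:
        raise ValueError("empty frequency table")
    return per_locus, float(per_locus.mean())


def polymorphic_count(table: FrequencyTable) -> int:
    """Retained markers with both alleles observed in this dataset."""
    return int(((table.p > 0.0) & (table.p < 1.0)).sum())


def ind_diversity(
    scores: ScoreMatrix,
    table: FrequencyTable,
    subset: Sequence[str],
    g: int | None = None,
) -> DiversityRecord:
    """Diversity summary of one accession from individual genotypes.

    ``table`` must be the filtered frequency table of the same subset;
    all statistics are computed over its retained markers.
    """
    markers = list(table.marker_ids)
    _, ho = observed_heterozygosity(scores, table.accession, subset, markers)
    _, he = expected_heterozygosity(table)
    _, ar, _ = allelic_richness_rarefaction(scores, table.accession, subset, g, markers)
    return DiversityRecord(
        accession=table.accession,
        source="ind",
        size=table.size,
        depth=None,
        n_snps=polymorphic_count(table),
        h_obs=ho,
        h_exp=he,
        fis=inbreeding_coefficient(ho, he),
        ae=ar,
        ae_kind="ar_rarefaction",
    )


def pool_diversity(table: FrequencyTable) -> DiversityRecord:
    """Diversity summary of one accession from pooled read counts."""
    _, he = expected_heterozygosity(table)
    _, ae = effective_alleles_pool(table)
    return DiversityRecord(
        accession=table.accession,
        source="pool",
        size=table.size,
        depth=table.depth,
        n_snps=polymorphic_count(table),
        h_obs=None,
        h_exp=he,
        fis=None,
        ae=ae,
        ae_kind="ae_effective",
    )


def delta_he(
    ind_records: Sequence[DiversityRecord], pool_records: Sequence[DiversityRecord]
) -> pd.DataFrame:
    """H_E(pool, a, s, j) - H_E(ind, a, s) for every matching cell.

    Pool cells without a matching individual cell are flagged in the
    ``flag`` column rather than dropped.
    """
    ind_he = {(r.accession, r.size): r.h_exp for r in ind_records if r.source == "ind"}
    rows = []
    for r in pool_records:
        if r.source != "pool":
            continue
        key = (r.accession, r.size)
        matched = key in ind_he
        rows.append(
            {
                "accession": r.accession,
                "size": r.size,
                "depth": r.depth,
                "h_exp_ind": ind_he.get(key, float("nan")),
                "h_exp_pool": r.h_exp,
                "delta": r.h_exp - ind_he[key] if matched else float("nan"),
                "flag": "" if matched else "no matching ind cell",
            }
        )
    return pd.DataFrame(rows)
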