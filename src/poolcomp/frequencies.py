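"""Allele-frequency estimation, replicate/depth merging and MD/MAF filtering.

Frequencies are always major-allele frequencies under the polarity fixed
by the report writer. Individual-sample estimates use genotype counts
(p = (AA + Aa/2) / (AA + Aa + aa) over non-missing subset members); pool
estimates use read counts (p = n_major / (n_major + n_minor)).

Filtering is applied per accession-dataset: a marker is retained iff its
missing fraction in that dataset's samples is strictly below ``md_max``
and its minor-allele frequency is strictly above ``maf_min``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .datatypes import (
    DEPTH_MERGES,
    CountMatrix,
    FilterSettings,
    FrequencyTable,
    PoolDesign,
    PoolcompError,
    ScoreMatrix,
)


def score_missing_fraction(scores: ScoreMatrix, group_samples: Sequence[str]) -> np.ndarray:
    """Per-marker fraction of the given samples with a missing genotype."""
    if len(group_samples) == 0:
        raise ValueError("group must be nonempty")
    idx = scores.sample_indices(group_samples)
    return (scores.genotypes[:, idx] == -1).mean(axis=1)


def count_missing_fraction(counts: CountMatrix, group_pools: Sequence[str]) -> np.ndarray:
    """Per-marker fraction of the given pool-samples with (0, 0) counts."""
    if len(group_pools) == 0:
        raise ValueError("group must be nonempty")
    idx = counts.pool_indices(group_pools)
    return counts.missing_mask()[:, idx].mean(axis=1)


def ind_allele_frequencies(
    scores: ScoreMatrix, accession: str, sample_subset: Sequence[str]
) -> FrequencyTable:
    """Unfiltered major-allele frequencies from individual genotypes.

    Markers at which every subset member is missing are excluded from the
    table, with the exclusion reason recorded.
    """
    members = set(scores.samples_of_accession(accession))
    subset = list(sample_subset)
    if not subset:
        raise ValueError("sample subset must be nonempty")
    outside = [s for s in subset if s not in members]
    if outside:
        raise ValueError(
            f"samples not in accession {accession!r}: {outside[:5]}"
        )
    idx = scores.sample_indices(subset)
    g = scores.genotypes[:, idx]
    observed = g != -1
    n_obs = observed.sum(axis=1)
    # major-allele count = 2*AA + Aa = sum over observed of (2 - code)
    major_copies = np.where(observed, 2 - g, 0).sum(axis=1)
    keep = n_obs > 0
    with np.errstate(invalid="ignore"):
        p = np.where(keep, major_copies / np.maximum(2 * n_obs, 1), np.nan)
    excluded = {str(m): "all samples missing" for m in scores.marker_ids[~keep]}
    return FrequencyTable(
        accession=accession,
        source="ind",
        size=len(subset),
        marker_ids=scores.marker_ids[keep],
        p=p[keep],
        n_used=n_obs[keep],
        excluded=excluded,
    )


def merge_pool_replicates(
    counts: CountMatrix,
    design: PoolDesign,
    accession: str,
    size: int,
    depth_level: float,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Elementwise-sum the libraries that make up one analysis depth.

    Depth 1.8 merges the two 0.9-class libraries (one per tissue
    replicate), 3.0 the two 1.5-class libraries, and 4.8 all four.
    Returns ``(major, minor, pool_sample_ids)`` of the merged libraries.
    """
    if depth_level not in DEPTH_MERGES:
        raise ValueError(
            f"depth_level must be one of {sorted(DEPTH_MERGES)}, got {depth_level}"
        )
    wanted_classes = DEPTH_MERGES[depth_level]
    pools: list[str] = []
    for cls in sorted(set(wanted_classes)):
        n_needed = wanted_classes.count(cls)
        found = design.select(accession=accession, size=size, depth_class=cls)
        if len(found) != n_needed:
            raise PoolcompError(
                f"accession {accession!r} size {size}: need {n_needed} libraries of "
                f"depth class {cls} Mr for the {depth_level} Mr merge, found {len(found)}"
            )
        pools.extend(p.pool_sample_id for p in found)
    idx = counts.pool_indices(pools)
    return counts.major[:, idx].sum(axis=1), counts.minor[:, idx].sum(axis=1), pools


def pool_allele_frequencies(
    major: np.ndarray,
    minor: np.ndarray,
    marker_ids: np.ndarray,
    accession: str,
    size: int,
    depth: float,
) -> FrequencyTable:
    """Unfiltered major-allele frequencies from merged read counts.

    Markers with zero total reads are excluded as missing.
    """
    total = major + minor
    keep = total > 0
    with np.errstate(invalid="ignore"):
        p = np.where(keep, major / np.maximum(total, 1), np.nan)
    excluded = {str(m): "zero coverage" for m in np.asarray(marker_ids)[~keep]}
    return FrequencyTable(
        accession=accession,
        source="pool",
        size=size,
        depth=depth,
        marker_ids=np.asarray(marker_ids, dtype=object)[keep],
        p=p[keep],
        n_used=total[keep],
        excluded=excluded,
    )


def apply_filters(
    table: FrequencyTable,
    missing_fractions: np.ndarray,
    marker_ids: np.ndarray,
    settings: FilterSettings,
) -> FrequencyTable:
    """Retain markers with MD strictly < ``md_max`` and MAF strictly > ``maf_min``.

    ``missing_fractions`` are per-marker fractions aligned with
    ``marker_ids`` (typically the full report's marker list), computed on
    the same sample group as the table. The returned table records how
    many markers each rule dropped.
    """
    md_of = dict(zip(np.asarray(marker_ids), np.asarray(missing_fractions, dtype=float)))
    try:
        md = np.array([md_of[m] for m in table.marker_ids], dtype=float)
    except KeyError as exc:
        raise ValueError(f"no missing fraction for marker {exc.args[0]!r}") from None
    maf = np.minimum(table.p, 1.0 - table.p)
    pass_md = md < settings.md_max
    # strict inequality with float-roundoff guard: MAF equal to the
    # threshold (e.g. 1 - 0.95 in binary floating point) is discarded
    pass_maf = maf > settings.maf_min + 1e-9
    keep = pass_md & pass_maf
    return FrequencyTable(
        accession=table.accession,
        source=table.source,
        size=table.size,
        depth=table.depth,
        filters=settings,
        marker_ids=table.marker_ids[keep],
        p=table.p[keep],
        n_used=table.n_used[keep],
        excluded=dict(table.excluded),
        drop_counts={
            "md": int((~pass_md).sum()),
            "maf": int((~pass_maf).sum()),
            "either": int((~keep).sum()),
        },
    )


def ind_frequency_table(
    scores: ScoreMatrix,
    accession: str,
    sample_subset: Sequence[str],
    settings: FilterSettings,
) -> FrequencyTable:
    """Convenience: estimate + filter individual frequencies in one call."""
    table = ind_allele_frequencies(scores, accession, sample_subset)
    md = score_missing_fraction(scores, list(sample_subset))
    return apply_filters(table, md, scores.marker_ids, settings)


def pool_frequency_table(
    counts: CountMatrix,
    design: PoolDesign,
    accession: str,
    size: int,
    depth: float,
    settings: FilterSettings,
) -> FrequencyTable:
    """Convenience: merge + estimate + filter pool frequencies in one call.

    The missing fraction of a marker is the fraction of the merged
    libraries in which it has (0, 0) counts.
    """
    major, minor, pools = merge_pool_replicates(counts, design, accession, size, depth)
    table = pool_allele_frequencies(major, minor, counts.marker_ids, accession, size, depth)
    md = count_missing_fraction(counts, pools)
    return apply_filters(table, md, counts.marker_ids, settings)
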