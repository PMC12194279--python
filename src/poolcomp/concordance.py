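"""Shared-SNP accounting, Representativity and Lin's concordance coefficient.

The sweep walks the full factor grid — accession ``a``, sample size ``s``,
missing-data threshold ``m``, pool analysis depth ``j`` and pool MAF
threshold ``k`` (individual MAF fixed at 0.05) — building the filtered
individual and pool frequency tables for each cell, intersecting their
marker sets and scoring agreement on the shared markers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, FilterSettings, FrequencyTable, PoolDesign, ScoreMatrix
from .frequencies import (
    apply_filters,
    ind_allele_frequencies,
    pool_frequency_table,
    score_missing_fraction,
)

DEFAULT_MD_GRID = (0.10, 0.20, 0.30, 0.40, 0.50, 0.60)
DEFAULT_DEPTHS = (1.8, 3.0, 4.8)
DEFAULT_POOL_MAFS = (0.01, 0.05)
IND_MAF = 0.05


@dataclass
class ConcordanceRecord:
    """One cell of the a x s x m x j x k factor grid."""

    accession: str
    size: int
    md_max: float
    depth: float
    pool_maf: float
    n_ind_snps: int
    n_pool_snps: int
    n_shared: int
    representativity: float  # percent; NaN when undefined
    ccc: float  # NaN when undefined
    ccc_ci_low: float = float("nan")
    ccc_ci_high: float = float("nan")
    flag: str = ""


def shared_snps(ind_table: FrequencyTable, pool_table: FrequencyTable) -> list[str]:
    """Marker ids retained by both tables (set intersection, ind order)."""
    if ind_table.accession != pool_table.accession:
        raise ValueError(
            f"accession mismatch: {ind_table.accession!r} vs {pool_table.accession!r}"
        )
    if ind_table.size != pool_table.size:
        raise ValueError(f"sample size mismatch: {ind_table.size} vs {pool_table.size}")
    pool_set = set(pool_table.marker_ids)
    return [m for m in ind_table.marker_ids if m in pool_set]


def representativity(n_shared: int, n_ind_snps: int) -> float:
    """Percentage of individually-detected SNPs recovered by the pool."""
    if n_ind_snps <= 0:
        raise ValueError("representativity undefined when no individual SNPs remain")
    return 100.0 * n_shared / n_ind_snps


def concordance_correlation(
    x: Sequence[float], y: Sequence[float], ci: bool = False, alpha: float = 0.05
) -> float | tuple[float, tuple[float, float]]:
    """Lin's concordance correlation coefficient of two aligned series.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2), with
    population (N-denominator) moments. With ``ci=True`` also returns a
    confidence interval from the inverse-hyperbolic-tangent (Fisher z)
    transformation with Lin's asymptotic variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-d series")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    mx, my = x.mean(), y.mean()
    vx = np.mean((x - mx) ** 2)
    vy = np.mean((y - my) ** 2)
    sxy = np.mean((x - mx) * (y - my))
    denom = vx + vy + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: both series constant and equal")
    ccc = 2.0 * sxy / denom
    if not ci:
        return ccc
    interval = _lin_ci(ccc, x, y, vx, vy, sxy, mx, my, n, alpha)
    return ccc, interval


def _lin_ci(ccc, x, y, vx, vy, sxy, mx, my, n, alpha) -> tuple[float, float]:
    from scipy import stats

    if vx == 0.0 or vy == 0.0 or abs(ccc) >= 1.0:
        return (float("nan"), float("nan"))
    r = sxy / np.sqrt(vx * vy)
    if r == 0.0:
        return (float("nan"), float("nan"))
    u = (mx - my) / (vx * vy) ** 0.25
    c2 = ccc * ccc
    var_z = (
        (1.0 - r * r) * c2 / ((1.0 - c2) * r * r)
        + 4.0 * ccc**3 * (1.0 - ccc) * u * u / (r * (1.0 - c2) ** 2)
        - 2.0 * c2 * c2 * u**4 / (r * r * (1.0 - c2) ** 2)
    ) / (n - 2)
    if not np.isfinite(var_z) or var_z < 0:
        return (float("nan"), float("nan"))
    z = np.arctanh(ccc)
    half = stats.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(var_z)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def concordance_cell(
    ind_table: FrequencyTable, pool_table: FrequencyTable, ci: bool = False
) -> ConcordanceRecord:
    """Score one grid cell from its two filtered frequency tables."""
    shared = shared_snps(ind_table, pool_table)
    n_ind = ind_table.n_markers
    n_pool = pool_table.n_markers
    rec = ConcordanceRecord(
        accession=ind_table.accession,
        size=ind_table.size,
        md_max=ind_table.filters.md_max if ind_table.filters else float("nan"),
        depth=pool_table.depth if pool_table.depth is not None else float("nan"),
        pool_maf=pool_table.filters.maf_min if pool_table.filters else float("nan"),
        n_ind_snps=n_ind,
        n_pool_snps=n_pool,
        n_shared=len(shared),
        representativity=float("nan"),
        ccc=float("nan"),
    )
    if n_ind == 0:
        rec.flag = "no individual SNPs"
        return rec
    rec.representativity = representativity(len(shared), n_ind)
    if len(shared) < 3:
        rec.flag = "fewer than 3 shared SNPs"
        return rec
    ind_p = ind_table.freq_of()
    pool_p = pool_table.freq_of()
    x = np.array([ind_p[m] for m in shared])
    y = np.array([pool_p[m] for m in shared])
    try:
        if ci:
            rec.ccc, (rec.ccc_ci_low, rec.ccc_ci_high) = concordance_correlation(
                x, y, ci=True
            )
        else:
            rec.ccc = concordance_correlation(x, y)
    except ValueError:
        rec.flag = "CCC undefined (constant series)"
    return rec


def concordance_sweep(
    scores: ScoreMatrix,
    counts: CountMatrix,
    design: PoolDesign,
    sizes: Sequence[int] | None = None,
    md_grid: Sequence[float] = DEFAULT_MD_GRID,
    depths: Sequence[float] = DEFAULT_DEPTHS,
    pool_mafs: Sequence[float] = DEFAULT_POOL_MAFS,
    ind_maf: float = IND_MAF,
    ci: bool = False,
) -> pd.DataFrame:
    """Run the full a x s x m x j x k grid and return a tidy record table.

    The individual subset for each (accession, size) cell is the pool's
    recorded membership, so both sources describe the same plants. Cells
    that end up without shared markers are flagged, never dropped.
    """
    from .frequencies import (
        count_missing_fraction,
        merge_pool_replicates,
        pool_allele_frequencies,
    )

    sizes = list(sizes) if sizes is not None else design.sizes()
    records: list[ConcordanceRecord] = []
    for accession in design.accessions():
        for size in sizes:
            subset = list(design.members(accession, size))
            base_ind = ind_allele_frequencies(scores, accession, subset)
            ind_md = score_missing_fraction(scores, subset)
            ind_tables = {
                md_max: apply_filters(
                    base_ind, ind_md, scores.marker_ids,
                    FilterSettings(md_max=md_max, maf_min=ind_maf),
                )
                for md_max in md_grid
            }
            for depth in depths:
                major, minor, pools = merge_pool_replicates(
                    counts, design, accession, size, depth
                )
                base_pool = pool_allele_frequencies(
                    major, minor, counts.marker_ids, accession, size, depth
                )
                pool_md = count_missing_fraction(counts, pools)
                for pool_maf in pool_mafs:
                    for md_max in md_grid:
                        pool_table = apply_filters(
                            base_pool, pool_md, counts.marker_ids,
                            FilterSettings(md_max=md_max, maf_min=pool_maf),
                        )
                        records.append(
                            concordance_cell(ind_tables[md_max], pool_table, ci=ci)
                        )
    return pd.DataFrame([vars(r) for r in records])
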