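"""Core data containers shared by every pipeline stage.

Genotypes are diploid-coded biallelic scores stored as ``int8``:

* ``0`` — homozygous for the major allele (AA)
* ``1`` — heterozygous (Aa)
* ``2`` — homozygous for the minor allele (aa)
* ``-1`` — missing

Major/minor polarity is fixed per marker when the reports are generated
(or called) and is shared between score and count reports, so individual-
and pool-derived frequencies always refer to the same allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
HOM_MAJOR = np.int8(0)
HET = np.int8(1)
HOM_MINOR = np.int8(2)

#: analysis depth (Mr) -> library depth classes (Mr) merged to reach it
DEPTH_MERGES: dict[float, tuple[float, ...]] = {
    1.8: (0.9, 0.9),
    3.0: (1.5, 1.5),
    4.8: (0.9, 0.9, 1.5, 1.5),
}


class PoolcompError(Exception):
    """Base class for errors raised by this package."""


class FormatError(PoolcompError):
    """Malformed input file."""


@dataclass
class ScoreMatrix:
    """Markers x individual samples genotype matrix.

    Parameters
    ----------
    marker_ids : sequence of str
        Unique marker identifiers (row labels).
    sample_ids : sequence of str
        Unique individual sample identifiers (column labels).
    genotypes : ndarray of int8, shape (n_markers, n_samples)
        Codes 0/1/2/-1 as documented in the module docstring.
    accession_of_sample : mapping, optional
        Sample id -> accession label. Every sample must map to exactly
        one accession when provided.
    """

    marker_ids: np.ndarray
    sample_ids: np.ndarray
    genotypes: np.ndarray
    accession_of_sample: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.marker_ids), len(self.sample_ids)):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.marker_ids)} markers x {len(self.sample_ids)} samples"
            )
        for name, ids in (("marker", self.marker_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        bad = ~np.isin(self.genotypes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        if self.accession_of_sample:
            unknown = [s for s in self.sample_ids if s not in self.accession_of_sample]
            if unknown:
                raise ValueError(f"samples without accession: {unknown[:5]}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def accessions(self) -> list[str]:
        """Accession labels in first-appearance order of the samples."""
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.accession_of_sample[s], None)
        return list(seen)

    def samples_of_accession(self, accession: str) -> list[str]:
        out = [s for s in self.sample_ids if self.accession_of_sample.get(s) == accession]
        if not out:
            raise KeyError(f"unknown accession {accession!r}")
        return out


@dataclass
class CountMatrix:
    """Markers x pool-library samples of (major, minor) allele read counts.

    ``(0, 0)`` at a marker/pool cell means the marker is missing there.
    """

    marker_ids: np.ndarray
    pool_sample_ids: np.ndarray
    major: np.ndarray  # (n_markers, n_pools) nonnegative ints
    minor: np.ndarray

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.pool_sample_ids = np.asarray(self.pool_sample_ids, dtype=object)
        self.major = np.asarray(self.major, dtype=np.int64)
        self.minor = np.asarray(self.minor, dtype=np.int64)
        shape = (len(self.marker_ids), len(self.pool_sample_ids))
        if self.major.shape != shape or self.minor.shape != shape:
            raise ValueError("count matrix shapes inconsistent with labels")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if len(set(self.pool_sample_ids)) != len(self.pool_sample_ids):
            raise ValueError("duplicate pool sample ids")
        if (self.major < 0).any() or (self.minor < 0).any():
            raise ValueError("allele counts must be nonnegative")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def pool_indices(self, pool_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.pool_sample_ids)}
        try:
            return np.array([pos[s] for s in pool_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown pool sample id {exc.args[0]!r}") from None

    def missing_mask(self) -> np.ndarray:
        """Boolean (markers x pools) mask of (0, 0) cells."""
        return (self.major == 0) & (self.minor == 0)


@dataclass(frozen=True)
class PoolSample:
    """One pool-library sample: a sequencing library of one tissue pool."""

    pool_sample_id: str
    accession: str
    size: int
    tissue_rep: int
    depth_class: float  # Mr per library, e.g. 0.9 or 1.5
    member_ids: tuple[str, ...]


@dataclass
class PoolDesign:
    """Nested pooling layout: which individuals entered which pool library."""

    pools: list[PoolSample]

    def __post_init__(self) -> None:
        ids = [p.pool_sample_id for p in self.pools]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate pool sample ids in design")

    def __iter__(self):
        return iter(self.pools)

    def __len__(self) -> int:
        return len(self.pools)

    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.pools:
            seen.setdefault(p.accession, None)
        return list(seen)

    def sizes(self) -> list[int]:
        return sorted({p.size for p in self.pools})

    def select(
        self,
        accession: str | None = None,
        size: int | None = None,
        tissue_rep: int | None = None,
        depth_class: float | None = None,
    ) -> list[PoolSample]:
        out = []
        for p in self.pools:
            if accession is not None and p.accession != accession:
                continue
            if size is not None and p.size != size:
                continue
            if tissue_rep is not None and p.tissue_rep != tissue_rep:
                continue
            if depth_class is not None and not np.isclose(p.depth_class, depth_class):
                continue
            out.append(p)
        return out

    def members(self, accession: str, size: int) -> tuple[str, ...]:
        pools = self.select(accession=accession, size=size)
        if not pools:
            raise KeyError(f"no pool for accession {accession!r} size {size}")
        members = {p.member_ids for p in pools}
        if len(members) != 1:
            raise ValueError(
                f"inconsistent membership for accession {accession!r} size {size}"
            )
        return pools[0].member_ids


@dataclass(frozen=True)
class FilterSettings:
    """Marker retention thresholds.

    A marker is retained iff its missing fraction is strictly below
    ``md_max`` and its minor-allele frequency strictly above ``maf_min``
    (a MAF equal to the threshold is discarded).
    """

    md_max: float
    maf_min: float

    def __post_init__(self) -> None:
        if not 0.0 < self.md_max <= 1.0:
            raise ValueError(f"md_max must be in (0, 1], got {self.md_max}")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5), got {self.maf_min}")


@dataclass
class FrequencyTable:
    """Per-accession major-allele frequencies for one data source.

    ``n_used`` is the number of non-missing samples (ind) or total reads
    (pool) behind each estimate. ``excluded`` records marker -> reason for
    markers dropped before/while building the table (e.g. all-missing).
    """

    accession: str
    source: str  # "ind" or "pool"
    size: int
    marker_ids: np.ndarray
    p: np.ndarray
    n_used: np.ndarray
    depth: float | None = None  # pool only: analysis depth in Mr
    filters: FilterSettings | None = None
    excluded: dict[str, str] = field(default_factory=dict)
    drop_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.p = np.asarray(self.p, dtype=float)
        self.n_used = np.asarray(self.n_used)
        if self.source not in ("ind", "pool"):
            raise ValueError(f"source must be 'ind' or 'pool', got {self.source!r}")
        if not (len(self.marker_ids) == len(self.p) == len(self.n_used)):
            raise ValueError("marker_ids, p and n_used must have equal length")
        if len(self.p) and ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def q(self) -> np.ndarray:
        return 1.0 - self.p

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_ids, "p": self.p, "q": self.q, "n_used": self.n_used}
        )

    def freq_of(self) -> Mapping[str, float]:
        return dict(zip(self.marker_ids, self.p))
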