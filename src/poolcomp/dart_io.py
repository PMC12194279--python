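"""Readers and writers for the SNP report dialects used by the pipeline.

Three plain-CSV artifacts travel between stages:

* **score report** — one row per marker, header row of sample ids, cells
  in ``{0, 1, 2, "-"}`` (0 = homozygous major, 1 = het, 2 = homozygous
  minor, ``-`` = missing).
* **count report** — two rows per marker, tagged ``Ref`` (major-allele
  reads) and ``Alt`` (minor-allele reads), integer cells.
* **design map** — one row per pool-library sample with its accession,
  pool size, tissue replicate, library depth class and member ids.

All readers reject malformed input instead of coercing it. Metadata
columns other than the ones documented here are not produced; extra
columns in third-party score reports are ignored on read only if their
header does not collide with a sample id.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np

from .datatypes import (
    CountMatrix,
    FormatError,
    PoolDesign,
    PoolSample,
    ScoreMatrix,
)

_SCORE_TOKENS = {"0": 0, "1": 1, "2": 2, "-": -1}
_TOKEN_OF_CODE = {0: "0", 1: "1", 2: "2", -1: "-"}


# ---------------------------------------------------------------------------
# score reports


def write_score_report(matrix: ScoreMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker_id", *matrix.sample_ids])
        for i, marker in enumerate(matrix.marker_ids):
            w.writerow([marker, *(_TOKEN_OF_CODE[int(g)] for g in matrix.genotypes[i])])


def read_score_report(
    path: str | Path, accession_of_sample: dict[str, str] | None = None
) -> ScoreMatrix:
    """Parse a score report CSV.

    Parameters
    ----------
    path : path to the CSV file.
    accession_of_sample : optional sample id -> accession mapping (e.g.
        from :func:`read_sample_map`); attached to the returned matrix.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty score report") from None
        if not header or header[0] != "marker_id":
            raise FormatError(f"{path}: first header cell must be 'marker_id'")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicate sample ids in header")
        marker_ids: list[str] = []
        seen: set[str] = set()
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            marker = row[0]
            if marker in seen:
                raise FormatError(f"{path}: duplicate marker id {marker!r}")
            seen.add(marker)
            if len(row) - 1 != len(sample_ids):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(sample_ids)} cells, "
                    f"got {len(row) - 1}"
                )
            codes = []
            for j, tok in enumerate(row[1:]):
                try:
                    codes.append(_SCORE_TOKENS[tok])
                except KeyError:
                    raise FormatError(
                        f"{path}: unknown genotype token {tok!r} at marker "
                        f"{marker!r}, sample {sample_ids[j]!r}"
                    ) from None
            marker_ids.append(marker)
            rows.append(codes)
    genotypes = np.array(rows, dtype=np.int8).reshape(len(marker_ids), len(sample_ids))
    return ScoreMatrix(
        marker_ids=np.array(marker_ids, dtype=object),
        sample_ids=np.array(sample_ids, dtype=object),
        genotypes=genotypes,
        accession_of_sample=dict(accession_of_sample or {}),
    )


# ---------------------------------------------------------------------------
# count reports


def write_count_report(matrix: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["marker_id", "allele", *matrix.pool_sample_ids])
        for i, marker in enumerate(matrix.marker_ids):
            w.writerow([marker, "Ref", *matrix.major[i].tolist()])
            w.writerow([marker, "Alt", *matrix.minor[i].tolist()])


def read_count_report(path: str | Path) -> CountMatrix:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty count report") from None
        if header[:2] != ["marker_id", "allele"]:
            raise FormatError(f"{path}: header must start with 'marker_id,allele'")
        pool_ids = header[2:]
        rows = [row for row in reader if row]
    if len(rows) % 2 != 0:
        raise FormatError(f"{path}: odd number of count rows (one row missing a pair)")
    marker_ids: list[str] = []
    seen: set[str] = set()
    major_rows: list[list[int]] = []
    minor_rows: list[list[int]] = []
    for ref_row, alt_row in zip(rows[0::2], rows[1::2]):
        marker = ref_row[0]
        if alt_row[0] != marker:
            raise FormatError(
                f"{path}: marker {marker!r} Ref row is not followed by its Alt row"
            )
        if ref_row[1] != "Ref" or alt_row[1] != "Alt":
            raise FormatError(f"{path}: marker {marker!r}: rows must be tagged Ref then Alt")
        if marker in seen:
            raise FormatError(f"{path}: duplicate marker id {marker!r}")
        seen.add(marker)
        if len(ref_row) - 2 != len(pool_ids) or len(alt_row) - 2 != len(pool_ids):
            raise FormatError(f"{path}: marker {marker!r}: wrong number of count cells")
        try:
            ref = [int(x) for x in ref_row[2:]]
            alt = [int(x) for x in alt_row[2:]]
        except ValueError as exc:
            raise FormatError(f"{path}: marker {marker!r}: non-integer count ({exc})") from None
        if min(ref, default=0) < 0 or min(alt, default=0) < 0:
            raise FormatError(f"{path}: marker {marker!r}: negative count")
        marker_ids.append(marker)
        major_rows.append(ref)
        minor_rows.append(alt)
    shape = (len(marker_ids), len(pool_ids))
    return CountMatrix(
        marker_ids=np.array(marker_ids, dtype=object),
        pool_sample_ids=np.array(pool_ids, dtype=object),
        major=np.array(major_rows, dtype=np.int64).reshape(shape),
        minor=np.array(minor_rows, dtype=np.int64).reshape(shape),
    )


# ---------------------------------------------------------------------------
# design and sample maps

_DESIGN_COLUMNS = [
    "pool_sample_id",
    "accession",
    "size",
    "tissue_rep",
    "depth_class",
    "member_ids",
]


def write_design_map(design: PoolDesign, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_DESIGN_COLUMNS)
        for p in design:
            w.writerow(
                [
                    p.pool_sample_id,
                    p.accession,
                    p.size,
                    p.tissue_rep,
                    p.depth_class,
                    ";".join(p.member_ids),
                ]
            )


def read_design_map(path: str | Path) -> PoolDesign:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _DESIGN_COLUMNS:
            raise FormatError(f"{path}: design map header must be {_DESIGN_COLUMNS}")
        pools = []
        for row in reader:
            if not row:
                continue
            if len(row) != len(_DESIGN_COLUMNS):
                raise FormatError(f"{path}: malformed design row {row!r}")
            pools.append(
                PoolSample(
                    pool_sample_id=row[0],
                    accession=row[1],
                    size=int(row[2]),
                    tissue_rep=int(row[3]),
                    depth_class=float(row[4]),
                    member_ids=tuple(row[5].split(";")) if row[5] else (),
                )
            )
    return PoolDesign(pools=pools)


def write_sample_map(accession_of_sample: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "accession"])
        for sample, accession in accession_of_sample.items():
            w.writerow([sample, accession])


def read_sample_map(path: str | Path) -> dict[str, str]:
    path = Path(path)
    out: dict[str, str] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["sample_id", "accession"]:
            raise FormatError(f"{path}: sample map header must be sample_id,accession")
        for row in reader:
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{path}: malformed sample map row {row!r}")
            if row[0] in out:
                raise FormatError(f"{path}: duplicate sample id {row[0]!r}")
            out[row[0]] = row[1]
    return out
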