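"""Factorial experiment orchestration and group-comparison statistics.

The statistics here (one-way and two-way ANOVA, Tukey's HSD with a
compact letter display, Brown–Forsythe Levene test) operate on the sweep
and diversity summary tables, treating accessions as replicates.

:func:`run_full_experiment` chains the whole pipeline on one synthetic
dataset — simulate, write reports, concordance sweep, diversity, delta
H_E, structure, factorial statistics — and writes every table as CSV
plus a JSON run manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import dart_io
from .concordance import concordance_sweep
from .datatypes import FilterSettings
from .diversity import delta_he, ind_diversity, pool_diversity
from .frequencies import ind_frequency_table, pool_frequency_table
from .structure import (
    amova,
    classical_mds,
    fst_matrix,
    genotype_frequency_encoding,
    mantel_test,
    nei_matrix,
)
from .synthetic import SimConfig, simulate_dataset


@dataclass
class AnovaTable:
    model: str  # "one-way" | "two-way"
    response: str
    factors: list[str]
    terms: pd.DataFrame  # term, df, ss, ms, F, p

    def term(self, name: str) -> pd.Series:
        rows = self.terms[self.terms["term"] == name]
        if rows.empty:
            raise KeyError(f"no term {name!r}")
        return rows.iloc[0]


@dataclass
class TukeyTable:
    alpha: float
    ms_within: float
    df_within: int
    pairs: pd.DataFrame  # level_a, level_b, diff, q, p, ci_low, ci_high
    letters: dict[str, str] = field(default_factory=dict)


def _group_arrays(values: Sequence[float], groups: Sequence) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must be aligned")
    return {g: values[groups == g] for g in pd.unique(groups)}


def one_way_anova(
    values: Sequence[float], groups: Sequence, response: str = "y", factor: str = "group"
) -> AnovaTable:
    """Between/within decomposition with an F test."""
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) < 1 for v in by_group.values()):
        raise ValueError("every group needs at least one observation")
    y = np.asarray(values, dtype=float)
    n = len(y)
    k = len(by_group)
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = y.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in by_group.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    df_b, df_w = k - 1, n - k
    ms_b, ms_w = ss_between / df_b, ss_within / df_w
    if ms_w == 0.0:
        f_stat = 0.0 if ms_b == 0.0 else float("inf")
    else:
        f_stat = ms_b / ms_w
    p = float(sps.f.sf(f_stat, df_b, df_w)) if np.isfinite(f_stat) else 0.0
    terms = pd.DataFrame(
        [
            {"term": factor, "df": df_b, "ss": ss_between, "ms": ms_b, "F": f_stat, "p": p},
            {"term": "residual", "df": df_w, "ss": ss_within, "ms": ms_w,
             "F": float("nan"), "p": float("nan")},
        ]
    )
    return AnovaTable(model="one-way", response=response, factors=[factor], terms=terms)


def two_way_anova(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    response: str = "y",
    factor_names: tuple[str, str] = ("A", "B"),
) -> AnovaTable:
    """Balanced-design main effects + interaction decomposition.

    Every factor-level combination must be observed; empty cells raise an
    error naming the cell. When each cell holds a single observation the
    interaction cannot be separated from error and is used as the
    residual (additive model).
    """
    y = np.asarray(values, dtype=float)
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(y) == len(fa) == len(fb)):
        raise ValueError("values and factors must be aligned")
    levels_a = pd.unique(fa)
    levels_b = pd.unique(fb)
    cells = {}
    for la in levels_a:
        for lb in levels_b:
            cell = y[(fa == la) & (fb == lb)]
            if len(cell) == 0:
                raise ValueError(f"empty design cell ({la}, {lb})")
            cells[(la, lb)] = cell
    n = len(y)
    a, b = len(levels_a), len(levels_b)
    grand = y.mean()
    ss_a = sum(
        (fa == la).sum() * (y[fa == la].mean() - grand) ** 2 for la in levels_a
    )
    ss_b = sum(
        (fb == lb).sum() * (y[fb == lb].mean() - grand) ** 2 for lb in levels_b
    )
    ss_cells = sum(len(c) * (c.mean() - grand) ** 2 for c in cells.values())
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(((c - c.mean()) ** 2).sum() for c in cells.values())
    df_a, df_b_ = a - 1, b - 1
    df_ab = df_a * df_b_
    df_err = n - a * b
    rows = []
    if df_err == 0:
        # one observation per cell: interaction becomes the residual
        df_err, ss_err = df_ab, ss_ab
        df_ab = 0
    ms_err = ss_err / df_err if df_err > 0 else float("nan")

    def add(term, df, ss):
        ms = ss / df if df > 0 else float("nan")
        if df > 0 and df_err > 0 and ms_err > 0:
            f_stat = ms / ms_err
            p = float(sps.f.sf(f_stat, df, df_err))
        else:
            f_stat, p = float("nan"), float("nan")
        rows.append({"term": term, "df": df, "ss": ss, "ms": ms, "F": f_stat, "p": p})

    add(factor_names[0], df_a, ss_a)
    add(factor_names[1], df_b_, ss_b)
    if df_ab > 0:
        add(f"{factor_names[0]}:{factor_names[1]}", df_ab, ss_ab)
    rows.append({"term": "residual", "df": df_err, "ss": ss_err, "ms": ms_err,
                 "F": float("nan"), "p": float("nan")})
    return AnovaTable(
        model="two-way",
        response=response,
        factors=list(factor_names),
        terms=pd.DataFrame(rows),
    )


def _compact_letters(levels: list, significant: set[tuple]) -> dict:
    """Insert-and-absorb compact letter display.

    ``levels`` are ordered (typically by descending mean); ``significant``
    holds unordered level pairs that differ at alpha.
    """
    groups: list[set] = [set(levels)]
    for pair in significant:
        i, j = pair
        for g in list(groups):
            if i in g and j in g:
                groups.remove(g)
                groups.extend([g - {i}, g - {j}])
        # absorb sets contained in others, keep unique
        groups = [g for g in groups if g and not any(g < h for h in groups)]
        unique = []
        for g in groups:
            if g not in unique:
                unique.append(g)
        groups = unique
    order = {lvl: pos for pos, lvl in enumerate(levels)}
    groups.sort(key=lambda g: min(order[lvl] for lvl in g))
    letters = {lvl: "" for lvl in levels}
    for letter, g in zip("abcdefghijklmnopqrstuvwxyz", groups):
        for lvl in g:
            letters[lvl] += letter
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def tukey_hsd(
    values: Sequence[float], groups: Sequence, alpha: float = 0.05
) -> TukeyTable:
    """Tukey(-Kramer) HSD with studentized-range adjusted p-values."""
    by_group = _group_arrays(values, groups)
    k = len(by_group)
    if k < 2:
        raise ValueError("need at least two groups")
    n = sum(len(v) for v in by_group.values())
    df_w = n - k
    if df_w <= 0:
        raise ValueError("no within-group degrees of freedom")
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in by_group.values())
    ms_w = ss_within / df_w
    levels = sorted(by_group, key=lambda g: -by_group[g].mean())
    q_crit = float(sps.studentized_range.ppf(1 - alpha, k, df_w))
    rows = []
    significant = set()
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            a_, b_ = levels[i], levels[j]
            va, vb = by_group[a_], by_group[b_]
            diff = va.mean() - vb.mean()
            se = np.sqrt(ms_w / 2.0 * (1.0 / len(va) + 1.0 / len(vb)))
            if se == 0.0:
                q = 0.0 if diff == 0 else float("inf")
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
            ci_half = q_crit * se
            rows.append(
                {"level_a": a_, "level_b": b_, "diff": diff, "q": q, "p": p,
                 "ci_low": diff - ci_half, "ci_high": diff + ci_half}
            )
            if p < alpha:
                significant.add((a_, b_))
    letters = _compact_letters(levels, significant)
    return TukeyTable(
        alpha=alpha,
        ms_within=float(ms_w),
        df_within=df_w,
        pairs=pd.DataFrame(rows),
        letters=letters,
    )


def levene_test(
    values: Sequence[float], groups: Sequence, center: str = "median"
) -> tuple[float, float]:
    """Levene's homoscedasticity test (Brown–Forsythe by default).

    One-way ANOVA on absolute deviations from each group's center
    (``median`` or ``mean``). Returns ``(W, p)``.
    """
    if center not in ("median", "mean"):
        raise ValueError("center must be 'median' or 'mean'")
    by_group = _group_arrays(values, groups)
    if any(len(v) < 2 for v in by_group.values()):
        raise ValueError("every group needs at least two observations")
    z_parts, labels = [], []
    for g, v in by_group.items():
        c = np.median(v) if center == "median" else v.mean()
        z_parts.append(np.abs(v - c))
        labels.extend([g] * len(v))
    z = np.concatenate(z_parts)
    table = one_way_anova(z, labels, response="|deviation|")
    w = float(table.term(table.factors[0])["F"])
    p = float(table.term(table.factors[0])["p"])
    if not np.isfinite(w):  # all deviations identical
        w, p = 0.0, 1.0
    return w, p


# ---------------------------------------------------------------------------
# orchestration


def aggregate_sweep(
    sweep: pd.DataFrame, response: str, factor: str
) -> pd.DataFrame:
    """Average a sweep response per (accession, factor level).

    Accessions then serve as replicates for the factorial statistics; all
    factors other than ``factor`` are averaged over.
    """
    out = (
        sweep.groupby(["accession", factor], sort=False)[response]
        .mean()
        .reset_index()
    )
    return out.dropna(subset=[response])


def read_config(path: str | Path) -> SimConfig:
    """Parse a ``key = value`` text config into a :class:`SimConfig`."""
    tuple_fields = {"pool_sizes", "library_depth_classes", "ancestral_freq_range"}
    int_fields = {"n_accessions", "n_markers", "n_individuals_per_accession",
                  "tissue_replicates", "seed"}
    kwargs: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key in tuple_fields:
            parts = [x.strip() for x in raw.split(",") if x.strip()]
            value = tuple(int(x) if key == "pool_sizes" else float(x) for x in parts)
        elif key in int_fields:
            value = int(raw)
        else:
            value = float(raw)
        kwargs[key] = value
    return SimConfig(**kwargs)


def run_full_experiment(
    config: SimConfig,
    outdir: str | Path,
    reference_size: int = 50,
    reference_depth: float = 4.8,
    ind_filters: FilterSettings = FilterSettings(md_max=0.10, maf_min=0.05),
    pool_filters: FilterSettings = FilterSettings(md_max=0.10, maf_min=0.01),
    amova_permutations: int = 999,
    mantel_permutations: int = 999,
) -> dict:
    """Simulate one dataset and run every analysis stage on it.

    Writes the score/count/design reports, the concordance sweep, the
    diversity and delta-H_E tables, structure results at the reference
    sample size, the factorial statistics, and a JSON manifest. Returns
    the bundle as a dict of DataFrames / result objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "simulate"
    try:
        data = simulate_dataset(config)
        dart_io.write_score_report(data.scores, outdir / "score_report.csv")
        dart_io.write_count_report(data.counts, outdir / "count_report.csv")
        dart_io.write_design_map(data.design, outdir / "design_map.csv")
        dart_io.write_sample_map(data.scores.accession_of_sample, outdir / "sample_map.csv")
        truth = pd.DataFrame({"marker_id": data.scores.marker_ids,
                              "ancestral_p": data.truth.ancestral_p})
        for label, p in data.truth.accession_p.items():
            truth[f"p_{label}"] = p
        truth.to_csv(outdir / "truth.csv", index=False)

        stage = "sweep"
        sweep = concordance_sweep(data.scores, data.counts, data.design)
        sweep.to_csv(outdir / "sweep.csv", index=False)

        stage = "diversity"
        accessions = data.design.accessions()
        sizes = data.design.sizes()
        ind_records, pool_records = [], []
        for acc in accessions:
            for size in sizes:
                subset = list(data.design.members(acc, size))
                itab = ind_frequency_table(data.scores, acc, subset, ind_filters)
                if itab.n_markers:
                    ind_records.append(ind_diversity(data.scores, itab, subset))
                for depth in (1.8, 3.0, 4.8):
                    ptab = pool_frequency_table(
                        data.counts, data.design, acc, size, depth, pool_filters
                    )
                    if ptab.n_markers:
                        pool_records.append(pool_diversity(ptab))
        diversity_df = pd.DataFrame([asdict(r) for r in ind_records + pool_records])
        diversity_df.to_csv(outdir / "diversity.csv", index=False)

        stage = "delta_he"
        delta = delta_he(ind_records, pool_records)
        delta.to_csv(outdir / "delta_he.csv", index=False)

        stage = "structure"
        structure = _structure_stage(
            data, accessions, reference_size, reference_depth,
            ind_filters, pool_filters, amova_permutations, mantel_permutations,
            config.seed, outdir,
        )

        stage = "stats"
        stats_tables = _stats_stage(sweep, delta, outdir)

        stage = "manifest"
        manifest = {
            "config": asdict(config),
            "reference_size": reference_size,
            "reference_depth": reference_depth,
            "ind_filters": asdict(ind_filters),
            "pool_filters": asdict(pool_filters),
            "amova_permutations": amova_permutations,
            "mantel_permutations": mantel_permutations,
            "outputs": sorted(p.name for p in outdir.glob("*.csv")),
            "elapsed_s": round(time.time() - t0, 2),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception as exc:
        raise RuntimeError(f"experiment stage {stage!r} failed: {exc}") from exc
    return {
        "data": data,
        "sweep": sweep,
        "diversity": diversity_df,
        "delta_he": delta,
        "structure": structure,
        "stats": stats_tables,
        "manifest": manifest,
    }


def _structure_stage(
    data, accessions, size, depth, ind_filters, pool_filters,
    amova_permutations, mantel_permutations, seed, outdir: Path,
) -> dict:
    ind_tables, subsets = {}, {}
    for acc in accessions:
        subset = list(data.design.members(acc, size))
        subsets[acc] = subset
        ind_tables[acc] = ind_frequency_table(data.scores, acc, subset, ind_filters)
    pool_tables = {
        acc: pool_frequency_table(data.counts, data.design, acc, size, depth, pool_filters)
        for acc in accessions
    }
    nei_ind = nei_matrix([ind_tables[a] for a in accessions])
    nei_pool = nei_matrix([pool_tables[a] for a in accessions])
    shared_loci = sorted(
        set.intersection(*(set(ind_tables[a].marker_ids) for a in accessions))
    )
    fst = fst_matrix(data.scores, accessions, subsets, shared_loci)
    mantel_r, mantel_p = mantel_test(
        nei_ind, nei_pool, n_permutations=mantel_permutations, seed=seed
    )
    # AMOVA, ind: individuals as units on the jointly retained loci
    enc_rows, labels = [], []
    for acc in accessions:
        enc = genotype_frequency_encoding(data.scores, subsets[acc], shared_loci)
        enc_rows.append(enc)
        labels.extend([acc] * len(subsets[acc]))
    amova_ind = amova(
        np.vstack(enc_rows), labels, n_permutations=amova_permutations, seed=seed
    )
    # AMOVA, pool: the reference-size pool libraries as units
    pool_samples = [p for p in data.design.select(size=size)]
    pool_loci = sorted(set.intersection(*(set(t.marker_ids) for t in pool_tables.values())))
    pos = {m: i for i, m in enumerate(data.counts.marker_ids)}
    rows = np.array([pos[m] for m in pool_loci], dtype=np.intp)
    enc_pool, pool_labels = [], []
    idx = data.counts.pool_indices([p.pool_sample_id for p in pool_samples])
    major = data.counts.major[np.ix_(rows, idx)].astype(float)
    minor = data.counts.minor[np.ix_(rows, idx)].astype(float)
    total = major + minor
    with np.errstate(invalid="ignore"):
        freq = np.where(total > 0, major / np.maximum(total, 1), np.nan)
    enc_pool = freq.T
    pool_labels = [p.accession for p in pool_samples]
    amova_pool = amova(enc_pool, pool_labels,
                       n_permutations=amova_permutations, seed=seed + 1)
    mds_ind = classical_mds(nei_ind)
    mds_pool = classical_mds(nei_pool)
    for name, dm in (("nei_ind", nei_ind), ("nei_pool", nei_pool), ("fst_ind", fst)):
        pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels).to_csv(
            outdir / f"structure_{name}.csv"
        )
    summary = {
        "mantel_r": mantel_r,
        "mantel_p": mantel_p,
        "amova_ind": asdict(amova_ind),
        "amova_pool": asdict(amova_pool),
        "mds_ind_explained": mds_ind.explained.tolist(),
        "mds_pool_explained": mds_pool.explained.tolist(),
    }
    (outdir / "structure_summary.json").write_text(json.dumps(summary, indent=2))
    return {
        "nei_ind": nei_ind, "nei_pool": nei_pool, "fst_ind": fst,
        "amova_ind": amova_ind, "amova_pool": amova_pool,
        "mantel": (mantel_r, mantel_p),
        "mds_ind": mds_ind, "mds_pool": mds_pool,
    }


def _stats_stage(sweep: pd.DataFrame, delta: pd.DataFrame, outdir: Path) -> dict:
    tables = {}
    rows = []
    for response in ("representativity", "ccc"):
        for factor in ("size", "md_max", "depth", "pool_maf"):
            agg = aggregate_sweep(sweep, response, factor)
            if agg[factor].nunique() < 2:
                continue
            table = one_way_anova(agg[response], agg[factor],
                                  response=response, factor=factor)
            top = table.term(factor)
            levene_w, levene_p = levene_test(agg[response], agg[factor])
            tukey = tukey_hsd(agg[response], agg[factor])
            tables[(response, factor)] = {"anova": table, "tukey": tukey}
            rows.append(
                {"response": response, "factor": factor,
                 "df_factor": top["df"], "df_residual": table.term("residual")["df"],
                 "F": top["F"], "p": top["p"],
                 "levene_W": levene_w, "levene_p": levene_p,
                 "letters": json.dumps({str(k): v for k, v in tukey.letters.items()})}
            )
    ok = delta.dropna(subset=["delta"])
    if ok["size"].nunique() >= 2 and ok["depth"].nunique() >= 2:
        table2 = two_way_anova(
            ok["delta"], ok["size"], ok["depth"],
            response="delta_he", factor_names=("size", "depth"),
        )
        tables[("delta_he", "size_x_depth")] = {"anova": table2}
        table2.terms.assign(response="delta_he").to_csv(
            outdir / "stats_delta_he_two_way.csv", index=False
        )
    pd.DataFrame(rows).to_csv(outdir / "stats_one_way.csv", index=False)
    return tables
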