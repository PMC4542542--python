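"""End-to-end analyses: spatial, temporal, modern-vs-core comparison, lake summaries.

The three analyses mirror the study design:

* spatial — over lakes: NMDS of samples on Bray–Curtis presence/absence,
  RDA of lineage occurrence on transect and on vegetation dummies, and
  dbRDA of lineage patristic distances on transect-affinity and on
  vegetation-affinity columns, each with forward selection (p < alpha);
* temporal — over core horizons: Larix pollen affinity per lineage, then
  dbRDA of patristic distances on that single affinity column;
* comparison — partition two lineage sets (same fragment) into shared /
  exclusive lineages and list near-matches within a mismatch budget.

Each report carries the seed and settings used; results tables use the
columns ``data  explanatory_set  selected  R2  adjR2  P`` with R²/adjusted
R² in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .affinity import category_affinity, larix_affinity
from .errors import DegenerateInputError, InvalidArgumentError
from .ordination import (
    ForwardSelectionResult,
    NmdsResult,
    bray_curtis,
    dummy_code,
    forward_select,
    nmds,
)
from .phylo import patristic_distances
from .seqproc import LineageSet, MatchedPair, match_lineage_sets


def _binarize(occurrence: pd.DataFrame) -> pd.DataFrame:
    return (occurrence.astype(float) > 0).astype(int)


def _selection_row(
    sel: ForwardSelectionResult, data: str, explanatory_set: str
) -> dict:
    """Table row for a forward-selection outcome.

    If nothing was selected the best single candidate's diagnostics are
    shown with selected='(none)'.
    """
    res = sel.final if sel.final is not None else sel.best_single
    row = res.row(data, explanatory_set)
    if sel.final is None:
        row["selected"] = "(none)"
    else:
        row["selected"] = ", ".join(sel.selected)
    return row


@dataclass
class SpatialReport:
    nmds: NmdsResult
    results: pd.DataFrame
    excluded_lineages: list[str]
    selections: dict[str, ForwardSelectionResult]
    seed: int | None
    settings: dict


@dataclass
class TemporalReport:
    results: pd.DataFrame
    larix_affinity: pd.Series
    horizon_table: pd.DataFrame
    selections: dict[str, ForwardSelectionResult]
    seed: int | None
    settings: dict


@dataclass
class ComparisonReport:
    shared: list[MatchedPair]
    only_a: list[str]
    only_b: list[str]
    near_matches: list[MatchedPair]
    context: pd.DataFrame | None = None


def run_spatial(
    occurrence: pd.DataFrame,
    lake_table: pd.DataFrame,
    tree: TreeNode,
    n_perm: int = 999,
    alpha: float = 0.1,
    seed: int | None = None,
    negative_policy: str = "drop",
    transect_column: str = "transect",
    vegetation_column: str = "vegetation",
) -> SpatialReport:
    """Spatial analysis over lakes: does relatedness track vegetation or transect?"""
    if occurrence.size == 0 or int(occurrence.to_numpy().sum()) == 0:
        raise InvalidArgumentError("empty occurrence matrix")
    occ = _binarize(occurrence)
    tips = {t.name for t in tree.tips()}
    excluded = sorted(set(occ.index) - tips)
    if excluded:
        warnings.warn(f"lineages not in tree excluded: {excluded}", stacklevel=2)
        occ = occ.drop(index=excluded)
    never_seen = list(occ.index[occ.sum(axis=1) == 0])
    if never_seen:
        warnings.warn(f"lineages never observed excluded: {never_seen}", stacklevel=2)
        occ = occ.drop(index=never_seen)
        excluded = excluded + never_seen
    table = lake_table.set_index("sample") if "sample" in lake_table.columns else lake_table
    samples_by_lineage = occ.T  # samples × lineages

    seed_seq = np.random.SeedSequence(seed if seed is not None else 0)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in seed_seq.spawn(6)]

    # (i) NMDS of samples
    bc = bray_curtis(samples_by_lineage, presence_absence=True)
    nmds_result = nmds(bc, k=2, seed=seeds[0])

    rows = []
    selections: dict[str, ForwardSelectionResult] = {}

    # (ii) RDA of occurrence vs transect / vegetation dummies
    for label, column, s in (
        ("transect dummies", transect_column, seeds[1]),
        ("vegetation dummies", vegetation_column, seeds[2]),
    ):
        dummies = dummy_code(table.loc[samples_by_lineage.index], column)
        sel = forward_select(
            samples_by_lineage, dummies, alpha=alpha, n_perm=n_perm, seed=s
        )
        selections[f"rda:{label}"] = sel
        rows.append(_selection_row(sel, "lineage occurrence (RDA)", label))

    # (iii) dbRDA of patristic distances vs affinity columns
    patristic = patristic_distances(tree, tips=list(occ.index))
    for label, column, s in (
        ("transect affinity", transect_column, seeds[3]),
        ("vegetation affinity", vegetation_column, seeds[4]),
    ):
        aff = category_affinity(occ, table, column)
        sel = forward_select(
            patristic,
            aff,
            alpha=alpha,
            n_perm=n_perm,
            seed=s,
            negative_policy=negative_policy,
        )
        selections[f"dbrda:{label}"] = sel
        rows.append(_selection_row(sel, "patristic distance (dbRDA)", label))

    results = pd.DataFrame(rows, columns=["data", "explanatory_set", "selected", "R2", "adjR2", "P"])
    return SpatialReport(
        nmds=nmds_result,
        results=results,
        excluded_lineages=excluded,
        selections=selections,
        seed=seed,
        settings={"n_perm": n_perm, "alpha": alpha, "negative_policy": negative_policy},
    )


def run_temporal(
    core_occurrence: pd.DataFrame,
    core_table: pd.DataFrame,
    tree: TreeNode,
    n_perm: int = 999,
    alpha: float = 0.1,
    seed: int | None = None,
    negative_policy: str = "drop",
    larix_column: str = "larix_pct",
) -> TemporalReport:
    """Temporal analysis over core horizons: relatedness vs Larix pollen affinity."""
    table = core_table.set_index("sample") if "sample" in core_table.columns else core_table
    missing = table[larix_column].isna()
    if missing.any():
        warnings.warn(
            f"horizons with missing Larix % excluded: {list(table.index[missing])}",
            stacklevel=2,
        )
        table = table[~missing]
    occ = _binarize(core_occurrence)[list(table.index)]
    occ = occ[occ.sum(axis=1) > 0]
    if len(occ) < 3:
        raise InvalidArgumentError(
            f"temporal dbRDA needs at least 3 observed lineages, got {len(occ)}"
        )
    la = larix_affinity(occ, table, larix_column)
    if float(np.var(la.to_numpy())) <= 1e-12:
        raise DegenerateInputError(
            "Larix affinity has zero variance (constant Larix % across occupied horizons)"
        )
    tips = {t.name for t in tree.tips()}
    absent = sorted(set(la.index) - tips)
    if absent:
        warnings.warn(f"lineages not in tree excluded: {absent}", stacklevel=2)
        la = la.drop(index=absent)
    patristic = patristic_distances(tree, tips=list(la.index))
    seed_int = None if seed is None else int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    sel = forward_select(
        patristic,
        la.to_frame(),
        alpha=alpha,
        n_perm=n_perm,
        seed=seed_int,
        negative_policy=negative_policy,
    )
    rows = [_selection_row(sel, "patristic distance (dbRDA)", "Larix pollen affinity")]
    horizon_table = table.copy()
    horizon_table["n_lineages_present"] = occ.sum(axis=0)
    presence = occ.T.add_prefix("present:")
    horizon_table = horizon_table.join(presence)
    return TemporalReport(
        results=pd.DataFrame(rows, columns=["data", "explanatory_set", "selected", "R2", "adjR2", "P"]),
        larix_affinity=la,
        horizon_table=horizon_table.reset_index(),
        selections={"dbrda:larix affinity": sel},
        seed=seed,
        settings={"n_perm": n_perm, "alpha": alpha, "negative_policy": negative_policy},
    )


def run_comparison(
    modern: LineageSet,
    core: LineageSet,
    max_mismatch: int = 2,
    modern_affinity: pd.DataFrame | None = None,
    core_larix_affinity: pd.Series | None = None,
) -> ComparisonReport:
    """Partition modern vs core lineage sets and list near-matching pairs.

    Shared lineages are exact sequence matches (distance 0); near-matches
    are cross-set pairs within ``max_mismatch`` differences.  If affinity
    context is supplied, each near-match row shows the modern lineage's
    preferred category (argmax vegetation affinity) beside the core
    lineage's Larix affinity.
    """
    pairs = match_lineage_sets(modern, core, max_mismatch=max_mismatch)
    shared = [p for p in pairs if p.identical]
    near = [p for p in pairs if not p.identical]
    shared_a = {p.id_a for p in shared}
    shared_b = {p.id_b for p in shared}
    only_a = [i for i in modern.ids if i not in shared_a]
    only_b = [i for i in core.ids if i not in shared_b]
    context = None
    if modern_affinity is not None or core_larix_affinity is not None:
        rows = []
        for p in near:
            row = {"modern": p.id_a, "core": p.id_b, "distance": p.distance}
            if modern_affinity is not None and p.id_a in modern_affinity.index:
                row["modern_preferred_category"] = str(
                    modern_affinity.loc[p.id_a].idxmax()
                )
            if core_larix_affinity is not None and p.id_b in core_larix_affinity.index:
                row["core_larix_affinity"] = float(core_larix_affinity[p.id_b])
            rows.append(row)
        context = pd.DataFrame(rows)
    return ComparisonReport(
        shared=shared, only_a=only_a, only_b=only_b, near_matches=near, context=context
    )


def summarize_lakes(
    sample_table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Median and quartiles per numeric lake variable.

    Quantiles use linear interpolation on the sorted values (position
    1 + p·(n−1)), the convention under which the published lake-table
    summary rows reproduce exactly.  Returns a frame with rows ``median``,
    ``q1``, ``q3``.
    """
    if columns is None:
        columns = [
            c
            for c in sample_table.columns
            if pd.api.types.is_numeric_dtype(sample_table[c])
        ]
    if not columns:
        raise InvalidArgumentError("no numeric columns to summarize")
    out = {}
    for c in columns:
        col = pd.to_numeric(sample_table[c], errors="coerce")
        if col.isna().any():
            bad = sample_table.index[col.isna()][0]
            raise InvalidArgumentError(f"non-numeric value in column {c!r} at row {bad!r}")
        v = col.to_numpy(dtype=float)
        out[c] = [
            float(np.quantile(v, 0.5)),
            float(np.quantile(v, 0.25)),
            float(np.quantile(v, 0.75)),
        ]
    return pd.DataFrame(out, index=["median", "q1", "q3"])
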