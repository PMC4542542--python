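"""Per-lineage environmental and geographic affinity statistics.

Affinity quantifies where a lineage occurs, on presence/absence data only:

* category affinity (per transect or vegetation type): the lineage's
  occupancy proportion within each category — presences in the category
  divided by the number of samples in that category.  Dividing by category
  size corrects for unequal numbers of lakes per category.
* Larix pollen affinity: the mean Larix pollen percentage over the samples
  a lineage occurs in — a scalar preference along the past-vegetation axis,
  defined only for lineages observed at least once.

Pairwise distances in affinity space (Euclidean for vectors, absolute
difference for scalars) are offered as a diagnostic companion to using the
affinity columns directly as explanatory variables.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .errors import InvalidArgumentError


def _check_alignment(occurrence: pd.DataFrame, sample_table: pd.DataFrame) -> pd.DataFrame:
    table = sample_table.set_index("sample") if "sample" in sample_table.columns else sample_table
    missing = set(occurrence.columns) - set(table.index)
    if missing:
        raise InvalidArgumentError(f"samples absent from sample table: {sorted(missing)}")
    return table.loc[list(occurrence.columns)]


def category_affinity(
    occurrence: pd.DataFrame,
    sample_table: pd.DataFrame,
    category_column: str,
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Occupancy proportion of each lineage in each category.

    ``occurrence`` is a binary lineages × samples matrix; ``sample_table``
    maps each sample to exactly one category.  Value (i, c) = number of
    category-c samples where lineage i is present, divided by the number of
    category-c samples.  With ``normalize_rows`` the rows are rescaled to
    sum 1 (all-zero rows stay zero, with a warning).
    """
    table = _check_alignment(occurrence, sample_table)
    if category_column not in table.columns:
        raise InvalidArgumentError(f"no column {category_column!r} in sample table")
    cats = pd.unique(table[category_column])
    occ = (occurrence.astype(float) > 0).astype(float)
    out = {}
    for c in cats:
        members = table.index[table[category_column] == c]
        if len(members) == 0:
            raise InvalidArgumentError(f"category {c!r} has no samples")
        out[c] = occ[members].sum(axis=1) / len(members)
    result = pd.DataFrame(out, index=occurrence.index)
    zero = result.sum(axis=1) == 0
    if zero.any():
        warnings.warn(
            f"lineages never observed: {list(result.index[zero])}", stacklevel=2
        )
    if normalize_rows:
        sums = result.sum(axis=1)
        result = result.div(sums.where(sums > 0, 1.0), axis=0)
    return result


def larix_affinity(
    occurrence: pd.DataFrame,
    sample_table: pd.DataFrame,
    larix_column: str = "larix_pct",
) -> pd.Series:
    """Mean Larix pollen percentage of the samples each lineage occurs in.

    Lineages with no occurrences have no defined affinity and are excluded
    (with a warning) rather than set to zero.
    """
    table = _check_alignment(occurrence, sample_table)
    if larix_column not in table.columns:
        raise InvalidArgumentError(f"no column {larix_column!r} in sample table")
    p = table[larix_column].astype(float).to_numpy()
    x = (occurrence.astype(float).to_numpy() > 0).astype(float)
    totals = x.sum(axis=1)
    absent = totals == 0
    if absent.any():
        warnings.warn(
            "lineages never observed excluded from Larix affinity: "
            f"{list(occurrence.index[absent])}",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        values = (x @ p) / totals
    return pd.Series(values[~absent], index=occurrence.index[~absent], name="larix_affinity")


def affinity_distance(affinities, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between lineages in affinity space.

    Accepts a category-affinity table (one vector per lineage; Euclidean or
    Manhattan distance) or a scalar affinity Series (absolute difference).
    """
    if metric not in ("euclidean", "cityblock"):
        raise InvalidArgumentError(f"unsupported metric {metric!r}")
    if isinstance(affinities, pd.Series):
        vals = affinities.to_numpy(dtype=float)[:, None]
        ids = list(affinities.index)
    elif isinstance(affinities, pd.DataFrame):
        vals = affinities.to_numpy(dtype=float)
        ids = list(affinities.index)
    else:
        raise InvalidArgumentError("affinities must be a pandas Series or DataFrame")
    if len(ids) < 2:
        raise InvalidArgumentError("need at least 2 lineages")
    return DistanceMatrix(squareform(pdist(vals, metric=metric)), ids=ids)
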