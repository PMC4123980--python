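"""Species-by-region composition, chi-square heterogeneity, range shifts.

Composition tables report the percentage of specimens per species within
each region (or overall); specimens without a species assignment appear in
an ``unresolved`` row and are excluded from the percentage denominator.
Heterogeneity between regions is tested with the Pearson chi-square
statistic (no continuity correction).  Range comparison contrasts two
surveys' species-by-region presence sets, classifying each cell as gained,
lost or stable — the data statement behind "the species expanded south".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "CompositionTable",
    "ChiSquareResult",
    "composition",
    "chi_square",
    "range_comparison",
    "export_coordinates",
]

UNRESOLVED = "unresolved"


@dataclass
class CompositionTable:
    counts: pd.DataFrame  # species x region counts (incl. unresolved row)
    percents: pd.DataFrame  # species x region percents (unresolved excluded)


def composition(
    assignments: Mapping[str, str],
    metadata: pd.DataFrame,
    level: str | None = None,
) -> CompositionTable:
    """Species composition per region at the requested metadata level.

    ``level`` names a metadata column (e.g. ``country`` or ``province``);
    None pools everything into one ``all`` column.  Every specimen must
    carry a region at the requested level.  Percentages are per column and
    sum to 100 over assigned species.
    """
    meta = metadata.set_index("id")
    rows = []
    missing_region = []
    for sid in meta.index:
        if level is None:
            region = "all"
        else:
            if level not in meta.columns:
                raise ValueError(f"metadata lacks column {level!r}")
            region = meta.loc[sid, level]
            if not region:
                missing_region.append(sid)
                continue
        species = assignments.get(sid, UNRESOLVED) or UNRESOLVED
        rows.append({"species": species, "region": region})
    if missing_region:
        raise ValueError(
            f"specimens without a {level!r} value: {missing_region[:5]}"
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["species", "region"]).size().unstack(fill_value=0).sort_index()
    )
    assigned = counts.drop(index=UNRESOLVED, errors="ignore")
    col_sums = assigned.sum(axis=0)
    if (col_sums == 0).any():
        empty = list(col_sums.index[col_sums == 0])
        raise ValueError(f"no assigned specimens in region(s) {empty}")
    percents = 100.0 * assigned / col_sums
    return CompositionTable(counts=counts, percents=percents)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    expected: np.ndarray


def chi_square(table) -> ChiSquareResult:
    """Pearson chi-square test of heterogeneity on a contingency table.

    Requires at least a 2x2 table with no empty row or column margin;
    zero margins are reported by label.  No continuity correction is
    applied, matching the plain sum((O-E)^2/E) statistic.
    """
    if isinstance(table, pd.DataFrame):
        arr = table.to_numpy(dtype=float)
        row_labels, col_labels = list(table.index), list(table.columns)
    else:
        arr = np.asarray(table, dtype=float)
        row_labels = [f"row{i}" for i in range(arr.shape[0])]
        col_labels = [f"col{j}" for j in range(arr.shape[1])]
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    zero_rows = [row_labels[i] for i in np.flatnonzero(arr.sum(axis=1) == 0)]
    zero_cols = [col_labels[j] for j in np.flatnonzero(arr.sum(axis=0) == 0)]
    if zero_rows or zero_cols:
        raise ValueError(
            f"empty margins: rows {zero_rows or 'none'}, columns {zero_cols or 'none'}"
        )
    stat, p, df, expected = chi2_contingency(arr, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p), expected)


def _presence(survey) -> set:
    """Normalize a survey to a set of (species, region) pairs."""
    if isinstance(survey, pd.DataFrame):
        return set(zip(survey["species"], survey["region"]))
    return {(s, r) for s, r in survey}


def range_comparison(survey_t1, survey_t2, regions: Iterable[str] | None = None) -> pd.DataFrame:
    """Per species x region presence change between two surveys.

    Surveys are DataFrames with ``species``/``region`` columns or iterables
    of (species, region) pairs.  When ``regions`` is given it is the shared
    vocabulary, and a survey region outside it is an error listing the
    unmatched names.  Status values: ``gained`` (absent -> present),
    ``lost`` (present -> absent), ``stable_present``, ``stable_absent``.
    """
    p1, p2 = _presence(survey_t1), _presence(survey_t2)
    seen_regions = {r for _, r in p1 | p2}
    if regions is None:
        vocab = sorted(seen_regions)
    else:
        vocab = sorted(regions)
        unmatched = sorted(seen_regions - set(vocab))
        if unmatched:
            raise ValueError(f"regions not in the shared vocabulary: {unmatched}")
    species = sorted({s for s, _ in p1 | p2})
    rows = []
    for sp in species:
        for region in vocab:
            before, after = (sp, region) in p1, (sp, region) in p2
            if before and after:
                status = "stable_present"
            elif before:
                status = "lost"
            elif after:
                status = "gained"
            else:
                status = "stable_absent"
            rows.append({"species": sp, "region": region, "status": status})
    return pd.DataFrame(rows)


def export_coordinates(metadata: pd.DataFrame, assignments: Mapping[str, str], path) -> None:
    """TSV of (species, lat, lon, region) ready for any mapping tool."""
    if not {"lat", "lon"}.issubset(metadata.columns):
        raise ValueError("metadata lacks lat/lon columns")
    rows = []
    for _, row in metadata.iterrows():
        rows.append(
            {
                "species": assignments.get(row["id"], UNRESOLVED),
                "lat": row["lat"],
                "lon": row["lon"],
                "region": row.get("region", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")
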