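"""Tabulation and chi-square comparisons of simulated screw outcomes.

Produces the two standard summaries of a simulation run: the full 90-cell
table of injury-potential percentages per (level, trajectory rule, diameter),
and one-way marginal tables per variable.  Group comparisons use the Pearson
chi-square test on flagged/not-flagged contingency tables; homogeneous
subsets are annotated with a compact letter display built from all pairwise
2x2 chi-square tests with Bonferroni adjustment (the SPSS column-proportions
convention; categories sharing a letter are not significantly different).
Percentages are kept at full precision internally and rounded only for
display (one decimal, half-up).
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulation import SimulationRecord, records_to_frame

CELL_KEYS = ["level_cm", "angle_rule", "diameter_mm"]

#: Marginal axis name -> cell-table column.
AXES: dict[str, str] = {
    "level": "level_cm",
    "angle_rule": "angle_rule",
    "diameter": "diameter_mm",
}


class TableError(ValueError):
    """Malformed cell/marginal table or fixture input."""


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class LetterGroups:
    """Compact letter display over ordered categories.

    ``letters[c]`` is the (sorted) string of letters for category ``c``; two
    categories share at least one letter exactly when their Bonferroni-adjusted
    pairwise chi-square comparison is non-significant at ``alpha``.
    """

    letters: dict[object, str]
    alpha: float
    adjustment: str = "bonferroni"


def cell_table(records: Sequence[SimulationRecord] | pd.DataFrame) -> pd.DataFrame:
    """Count flags per (level, rule, diameter) cell; exact counting, full-
    precision percentages."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if frame.empty:
        raise TableError("no simulation records to tabulate")
    grouped = (
        frame.groupby(CELL_KEYS, sort=True)["injury_flag"]
        .agg(n_total="size", n_flagged="sum")
        .reset_index()
    )
    grouped["n_flagged"] = grouped["n_flagged"].astype(int)
    grouped["pct"] = 100.0 * grouped["n_flagged"] / grouped["n_total"]
    return grouped


def marginals(cells: pd.DataFrame, axis: str) -> pd.DataFrame:
    """Collapse the cell table onto one variable (level, angle_rule or
    diameter); conserves flagged and total counts."""
    if axis not in AXES:
        raise TableError(f"unknown axis {axis!r}; expected one of {sorted(AXES)}")
    col = AXES[axis]
    out = (
        cells.groupby(col, sort=True)[["n_total", "n_flagged"]]
        .sum()
        .reset_index()
        .rename(columns={col: "category"})
    )
    out.insert(0, "axis", axis)
    out["pct"] = 100.0 * out["n_flagged"] / out["n_total"]
    assert out["n_flagged"].sum() == cells["n_flagged"].sum()
    assert out["n_total"].sum() == cells["n_total"].sum()
    return out


def _as_count_pairs(
    counts: pd.DataFrame | Sequence[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Normalise to a list of (n_flagged, n_total) pairs in category order."""
    if isinstance(counts, pd.DataFrame):
        return [
            (int(f), int(t))
            for f, t in zip(counts["n_flagged"], counts["n_total"])
        ]
    return [(int(f), int(t)) for f, t in counts]


def pearson_chi_square(
    counts: pd.DataFrame | Sequence[tuple[int, int]],
) -> ChiSquareResult:
    """Pearson chi-square test on a k x 2 flagged/not-flagged table.

    ``counts`` holds (n_flagged, n_total) per category.  df = k - 1; p from
    the upper tail.  Expected counts below 5 raise a warning but the result
    is still returned; a category with zero total is a validation error.
    """
    pairs = _as_count_pairs(counts)
    if len(pairs) < 2:
        raise TableError("chi-square needs at least two categories")
    for f, t in pairs:
        if t <= 0:
            raise TableError("every category needs n_total > 0")
        if not 0 <= f <= t:
            raise TableError(f"invalid counts (flagged={f}, total={t})")
    observed = np.array([[f, t - f] for f, t in pairs], dtype=float)
    df = len(pairs) - 1
    col_sums = observed.sum(axis=0)
    if (col_sums == 0).any():
        # Degenerate table (e.g. no category flags anything): proportions are
        # identical by construction, the statistic is 0.
        return ChiSquareResult(statistic=0.0, df=df, p_value=1.0)
    expected = np.outer(observed.sum(axis=1), col_sums) / observed.sum()
    if (expected < 5).any():
        warnings.warn(
            "chi-square expected cell count below 5; the asymptotic p-value "
            "may be inaccurate",
            stacklevel=2,
        )
    stat, p, dof, _ = sps.chi2_contingency(observed, correction=False)
    assert dof == df
    return ChiSquareResult(statistic=float(stat), df=int(dof), p_value=float(p))


def letter_groups(
    counts: pd.DataFrame | Sequence[tuple[int, int]],
    alpha: float = 0.05,
    adjustment: str = "bonferroni",
    categories: Sequence | None = None,
) -> LetterGroups:
    """Compact letter display from all pairwise 2x2 Pearson chi-square tests.

    With Bonferroni adjustment each pairwise p-value is multiplied by the
    number of pairs; a pair is non-significant when the adjusted p is >=
    ``alpha``.  Letters are the maximal cliques of the non-significance
    graph, lettered in order of their first category.
    """
    if adjustment not in ("bonferroni", "none"):
        raise TableError(f"unknown adjustment {adjustment!r}")
    pairs = _as_count_pairs(counts)
    k = len(pairs)
    if k < 2:
        raise TableError("letter grouping needs at least two categories")
    if categories is None:
        if isinstance(counts, pd.DataFrame) and "category" in counts.columns:
            categories = list(counts["category"])
        else:
            categories = list(range(k))
    n_pairs = k * (k - 1) // 2

    graph = nx.Graph()
    graph.add_nodes_from(range(k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small expected counts in pairwise 2x2s
        for i in range(k):
            for j in range(i + 1, k):
                p = pearson_chi_square([pairs[i], pairs[j]]).p_value
                if adjustment == "bonferroni":
                    p = min(1.0, p * n_pairs)
                if p >= alpha:
                    graph.add_edge(i, j)

    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    cliques.sort()
    if len(cliques) > len(string.ascii_lowercase):
        raise TableError("more homogeneous subsets than available letters")
    letters: dict[object, list[str]] = {c: [] for c in categories}
    for letter, clique in zip(string.ascii_lowercase, cliques):
        for idx in clique:
            letters[categories[idx]].append(letter)
    return LetterGroups(
        letters={c: "".join(sorted(ls)) for c, ls in letters.items()},
        alpha=alpha,
        adjustment=adjustment,
    )


# ---------------------------------------------------------------------------
# Published-table fixture
# ---------------------------------------------------------------------------

_EXPECTED_CELLS = 90


def ingest_table1_fixture(source) -> pd.DataFrame:
    """Load a transcribed 90-cell published table (level, rule, diameter ->
    injury percentage over n=100 ankles) into a cell table.

    Percentages must be exact integers in [0, 100]; each cell becomes
    n_total=100, n_flagged=pct.  Accepts a CSV path/buffer or a DataFrame.
    """
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        frame = pd.read_csv(source, comment="#")
    required = {"level_cm", "angle_rule", "diameter_mm", "pct"}
    missing = required - set(frame.columns)
    if missing:
        raise TableError(f"fixture missing columns {sorted(missing)}")
    if len(frame) != _EXPECTED_CELLS:
        raise TableError(f"fixture must have {_EXPECTED_CELLS} rows, got {len(frame)}")
    if frame.duplicated(CELL_KEYS).any():
        raise TableError("fixture has duplicate (level, rule, diameter) cells")
    pct = frame["pct"].astype(float)
    if ((pct < 0) | (pct > 100)).any():
        raise TableError("fixture percentages must lie in [0, 100]")
    if (pct != pct.round()).any():
        raise TableError("fixture percentages must be exact integers")
    cells = frame[CELL_KEYS].copy()
    cells["n_total"] = 100
    cells["n_flagged"] = pct.round().astype(int)
    cells["pct"] = 100.0 * cells["n_flagged"] / cells["n_total"]
    return cells.sort_values(CELL_KEYS, ignore_index=True)


def load_packaged_table1() -> pd.DataFrame:
    """The packaged transcription of the published 90-cell injury table."""
    ref = resources.files("synfix.data").joinpath("table1_injury_pct.csv")
    with ref.open("r", encoding="utf-8") as fh:
        return ingest_table1_fixture(fh)


def format_pct(x: float) -> str:
    """Display rounding: one decimal, half-up (65.25 -> '65.3')."""
    import decimal

    return str(
        decimal.Decimal(repr(float(x))).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def stats_report(
    cells: pd.DataFrame, alpha: float = 0.05, adjustment: str = "bonferroni"
) -> dict:
    """Chi-square and letter-group summary for each marginal axis."""
    report: dict = {"alpha": alpha, "adjustment": adjustment, "axes": {}}
    total_flagged = int(cells["n_flagged"].sum())
    total = int(cells["n_total"].sum())
    report["overall"] = {
        "n_total": total,
        "n_flagged": total_flagged,
        "pct": 100.0 * total_flagged / total,
    }
    for axis in AXES:
        marg = marginals(cells, axis)
        chi = pearson_chi_square(marg)
        groups = letter_groups(marg, alpha=alpha, adjustment=adjustment)
        report["axes"][axis] = {
            "categories": [
                {
                    "category": cat.item() if isinstance(cat, np.generic) else cat,
                    "n_total": int(t),
                    "n_flagged": int(f),
                    "pct": 100.0 * f / t,
                    "letters": groups.letters[cat],
                }
                for cat, t, f in zip(marg["category"], marg["n_total"], marg["n_flagged"])
            ],
            "chi_square": {
                "statistic": chi.statistic,
                "df": chi.df,
                "p_value": chi.p_value,
            },
        }
    return report
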