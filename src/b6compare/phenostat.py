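"""Per parameter/center/sex strain comparison and heat-map cell encoding.

Strain comparisons are made within, never between, centers.  Numeric
parameters use the two-sided Mann-Whitney U test — exact enumeration when
both groups are small (min n ≤ 8) and tie-free, otherwise the
tie-corrected normal approximation with continuity correction.
Categorical parameters use Fisher's exact test (2×2) or Pearson's χ²
(larger tables).  Time courses are first averaged into one scalar per
animal.  Each result becomes a colored heat-map cell: red when N > J,
green when J > N, blue for an unordered categorical difference, with the
shade darkening at p < 0.05, 0.01, 0.001.

No multiple-testing correction is applied across parameters; multiplicity
is handled downstream by the cross-center randomization null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DIRECTIONS = ("N_gt_J", "J_gt_N", "none", "unordered")
HUES = ("red", "green", "blue", "null")
DEFAULT_SHADE_THRESHOLDS = (0.05, 0.01, 0.001)

#: largest per-group size for which the tie-free exact Mann-Whitney
#: enumeration is used
EXACT_MW_MAX_N = 8


@dataclass(frozen=True)
class GroupOption:
    """One candidate comparison group (a metadata-compatible subset)."""

    group_key: str
    n_N: int
    n_J: int

    def __post_init__(self) -> None:
        if self.n_N < 0 or self.n_J < 0:
            raise ValueError("group sizes must be non-negative")


@dataclass(frozen=True)
class StatCell:
    """One parameter × center × sex test result."""

    parameter: str
    center: str
    sex: str
    test: str  # mann_whitney | fisher | chi2
    p_value: float
    direction: str
    effect: float  # mean difference (numeric) or proportion difference
    rank_biserial: float | None
    n_N: int
    n_J: int


@dataclass(frozen=True)
class CellColor:
    hue: str
    shade: int

    def __post_init__(self) -> None:
        if self.hue not in HUES:
            raise ValueError(f"unknown hue {self.hue!r}")
        if self.shade not in (0, 1, 2, 3):
            raise ValueError("shade must be 0..3")
        if (self.hue == "null") != (self.shade == 0):
            raise ValueError("null hue exactly when shade is 0")


def select_comparison_group(options: Sequence[GroupOption]) -> GroupOption:
    """Pick the comparison group with the largest minimum group size.

    Ties break by larger combined size, then by position in the list.
    """
    if not options:
        raise ValueError("no comparison groups offered")
    best = options[0]
    for opt in options[1:]:
        key = (min(opt.n_N, opt.n_J), opt.n_N + opt.n_J)
        if key > (min(best.n_N, best.n_J), best.n_N + best.n_J):
            best = opt
    return best


def collapse_timecourse(
    series_by_animal: Mapping[str, Sequence[float]]
) -> dict[str, float]:
    """Average each animal's time course into a single scalar.

    Missing (NaN) points are skipped; an animal with no valid points is
    dropped with a warning.
    """
    out = {}
    for animal, series in series_by_animal.items():
        arr = np.asarray(list(series), dtype=float)
        valid = arr[~np.isnan(arr)]
        if valid.size == 0:
            warnings.warn(f"animal {animal}: all time points missing, dropped")
            continue
        out[animal] = float(valid.mean())
    return out


def _direction_from_effect(effect: float) -> str:
    if effect > 0:
        return "N_gt_J"
    if effect < 0:
        return "J_gt_N"
    return "none"


def compare_numeric(
    values_N: Sequence[float], values_J: Sequence[float]
) -> StatCell:
    """Two-sided Mann-Whitney comparison of one numeric parameter.

    Exact p-value by enumeration when min(n) ≤ 8 with no ties across the
    pooled sample, else the tie-corrected normal approximation with
    continuity correction.  Direction follows the sign of
    mean(N) − mean(J); the rank-biserial correlation is reported as a
    robust effect size alongside the mean difference.
    """
    x = np.asarray(values_N, dtype=float)
    y = np.asarray(values_J, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    u_n = float(res.statistic)  # U for the N sample
    effect = float(x.mean() - y.mean())
    return StatCell(
        parameter="", center="", sex="",
        test="mann_whitney",
        p_value=float(min(res.pvalue, 1.0)),
        direction=_direction_from_effect(effect),
        effect=effect,
        rank_biserial=float(2.0 * u_n / (x.size * y.size) - 1.0),
        n_N=int(x.size), n_J=int(y.size),
    )


def compare_categorical(
    table: Sequence[Sequence[int]], affected_index: int | None = 0
) -> StatCell:
    """Compare a strain × level contingency table (row 0 = N, row 1 = J).

    2×2 tables use Fisher's exact test (two-sided: sum of hypergeometric
    probabilities no larger than the observed table's); larger tables use
    Pearson's χ² with (r−1)(c−1) degrees of freedom.  For binary levels
    the direction orders the strains by the proportion of the designated
    affected level (column ``affected_index``); otherwise the result is
    unordered.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("table must be 2 strains x >=2 levels")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    n_N, n_J = int(t[0].sum()), int(t[1].sum())
    if t.shape[1] == 2:
        test = "fisher"
        _, p = stats.fisher_exact(t, alternative="two-sided")
    else:
        test = "chi2"
        if (t == t[0]).all():  # identical rows: no association by definition
            p = 1.0
        else:
            p = float(stats.chi2_contingency(t, correction=False).pvalue)
    if t.shape[1] == 2 and affected_index is not None:
        prop_N = t[0, affected_index] / n_N if n_N else 0.0
        prop_J = t[1, affected_index] / n_J if n_J else 0.0
        effect = float(prop_N - prop_J)
        direction = _direction_from_effect(effect)
    else:
        effect = 0.0
        direction = "unordered"
    return StatCell(
        parameter="", center="", sex="", test=test,
        p_value=float(min(p, 1.0)), direction=direction, effect=effect,
        rank_biserial=None, n_N=n_N, n_J=n_J,
    )


def encode_cell(
    cell: StatCell,
    thresholds: tuple[float, float, float] = DEFAULT_SHADE_THRESHOLDS,
) -> CellColor:
    """Map a test result to its heat-map color.

    p at or above the outermost threshold → null (no call); otherwise the
    shade counts how many thresholds the p-value falls below, and the hue
    encodes the direction (red N > J, green J > N, blue unordered).  A
    significant result with no direction (exactly equal means) is not
    interpretable as a strain difference and is encoded null.
    """
    if not all(a > b for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if cell.p_value >= thresholds[0] or cell.direction == "none":
        return CellColor("null", 0)
    shade = sum(cell.p_value < t for t in thresholds)
    hue = {"N_gt_J": "red", "J_gt_N": "green", "unordered": "blue"}[cell.direction]
    return CellColor(hue, shade)


# ---------------------------------------------------------------------------
# study-table driver


def _options_for(df: pd.DataFrame) -> list[GroupOption]:
    opts = []
    for key, sub in df.groupby("group_key", sort=True):
        n_n = sub.loc[sub.strain == "B6N", "animal_id"].nunique()
        n_j = sub.loc[sub.strain == "B6J", "animal_id"].nunique()
        opts.append(GroupOption(str(key), n_n, n_j))
    return opts


def cells_from_study(
    df: pd.DataFrame,
    affected_levels: Mapping[str, str] | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_SHADE_THRESHOLDS,
) -> list[tuple[StatCell, CellColor]]:
    """Run every parameter × center × sex comparison in a phenotype table.

    When a (parameter, center) stratum offers several metadata groups, the
    one with the largest minimum group size is compared.  *affected_levels*
    names the affected level per categorical parameter (defaults to
    ``affected``).
    """
    affected_levels = affected_levels or {}
    results = []
    for (param, center), stratum in df.groupby(["parameter", "center"], sort=True):
        chosen = select_comparison_group(_options_for(stratum)).group_key
        stratum = stratum[stratum.group_key.astype(str) == chosen]
        kind = stratum["kind"].iloc[0]
        for sex, sub in stratum.groupby("sex", sort=True):
            vals = {}
            for strain in ("B6N", "B6J"):
                grp = sub[sub.strain == strain]
                if kind == "timecourse":
                    series = {
                        r.animal_id: [float(x) for x in str(r.value).split(",")]
                        for r in grp.itertuples()
                    }
                    vals[strain] = list(collapse_timecourse(series).values())
                elif kind == "numeric":
                    vals[strain] = grp["value"].astype(float).tolist()
                else:
                    vals[strain] = grp["value"].tolist()
            if not vals["B6N"] or not vals["B6J"]:
                continue
            if kind == "categorical":
                affected = affected_levels.get(param, "affected")
                tab = [
                    [sum(v == affected for v in vals[s]),
                     sum(v != affected for v in vals[s])]
                    for s in ("B6N", "B6J")
                ]
                cell = compare_categorical(tab)
            else:
                cell = compare_numeric(vals["B6N"], vals["B6J"])
            cell = replace(cell, parameter=str(param), center=str(center), sex=str(sex))
            results.append((cell, encode_cell(cell, thresholds)))
    return results


def cells_to_frame(cells: Sequence[tuple[StatCell, CellColor]]) -> pd.DataFrame:
    rows = [
        {
            "parameter": c.parameter, "center": c.center, "sex": c.sex,
            "test": c.test, "p": c.p_value, "direction": c.direction,
            "effect": c.effect, "rank_biserial": c.rank_biserial,
            "n_N": c.n_N, "n_J": c.n_J, "hue": col.hue, "shade": col.shade,
        }
        for c, col in cells
    ]
    return pd.DataFrame(rows)
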