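"""Cross-center concordance classes and the square-randomization null.

Replicating a strain comparison at several centers gives power without a
cross-center model: a parameter whose heat-map row shows the same color in
three or more centers is unlikely to do so by chance.  That chance level is
estimated by randomizing all heat-map squares — permuting the observed
color multiset over the cell positions — and counting how often a
parameter still shows ≥ k same-colored squares within a sex, divided by
the number of parameters and repeats.  For small maps an exhaustive
enumeration over all distinct color assignments provides the exact value.

Concordance is counted on hue only (shade ignored); null cells never match
each other, and blue (unordered) cells can concord only with blue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import factorial
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sympy.utilities.iterables import multiset_permutations

from .phenostat import CellColor, StatCell, encode_cell

CLASSES = ("concordant_3plus", "concordant_2", "contradictory", "no_difference")
_HUE_CODE = {"null": 0, "red": 1, "green": 2, "blue": 3}
_OPPOSITE = {"red": "green", "green": "red"}

#: cap on the number of distinct color assignments the exhaustive oracle
#: will enumerate
EXHAUSTIVE_LIMIT = 500_000


@dataclass
class HeatMap:
    """Parameter × center × sex color matrix.

    Every combination is present; combinations with no underlying data are
    encoded (null, 0) and flagged in ``absent``.
    """

    parameters: list[str]
    centers: list[str]
    sexes: list[str]
    cells: dict[tuple[str, str, str], CellColor] = field(default_factory=dict)
    absent: set[tuple[str, str, str]] = field(default_factory=set)

    def color(self, parameter: str, center: str, sex: str) -> CellColor:
        return self.cells[(parameter, center, sex)]

    def present_keys(self) -> list[tuple[str, str, str]]:
        return [k for k in self.cells if k not in self.absent]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parameter": p, "center": c, "sex": s,
             "hue": self.cells[(p, c, s)].hue,
             "shade": self.cells[(p, c, s)].shade,
             "absent": (p, c, s) in self.absent}
            for p in self.parameters for c in self.centers for s in self.sexes
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HeatMap":
        hm = cls(
            parameters=list(dict.fromkeys(df["parameter"])),
            centers=list(dict.fromkeys(df["center"])),
            sexes=list(dict.fromkeys(df["sex"])),
        )
        for r in df.itertuples():
            key = (r.parameter, r.center, r.sex)
            hm.cells[key] = CellColor(r.hue, int(r.shade))
            if getattr(r, "absent", False):
                hm.absent.add(key)
        return hm


def build_heatmap(
    cells: Sequence[tuple[StatCell, CellColor]] | Sequence[StatCell],
) -> HeatMap:
    """Assemble encoded cells into a rectangular heat map.

    Accepts (StatCell, CellColor) pairs or bare StatCells (encoded with
    default thresholds).  Duplicate (parameter, center, sex) entries are an
    error; combinations missing from the input are filled with null color
    and flagged absent.
    """
    entries = []
    for item in cells:
        if isinstance(item, StatCell):
            entries.append((item, encode_cell(item)))
        else:
            entries.append(item)
    parameters = list(dict.fromkeys(c.parameter for c, _ in entries))
    centers = list(dict.fromkeys(c.center for c, _ in entries))
    sexes = list(dict.fromkeys(c.sex for c, _ in entries))
    hm = HeatMap(parameters=parameters, centers=centers, sexes=sexes)
    for cell, color in entries:
        key = (cell.parameter, cell.center, cell.sex)
        if key in hm.cells:
            raise ValueError(f"duplicate heat-map cell {key}")
        hm.cells[key] = color
    for p in parameters:
        for c in centers:
            for s in sexes:
                if (p, c, s) not in hm.cells:
                    hm.cells[(p, c, s)] = CellColor("null", 0)
                    hm.absent.add((p, c, s))
    return hm


def _sex_hues(hm: HeatMap, parameter: str, sex: str) -> list[str]:
    return [hm.color(parameter, c, sex).hue for c in hm.centers]


def classify_parameter(hm: HeatMap, parameter: str) -> str:
    """Assign a parameter's cross-center concordance class.

    Evaluated per sex over the non-null hues of its centers, then
    aggregated across sexes with precedence contradictory >
    concordant_3plus > concordant_2 > no_difference:

    - contradictory: some sex shows one ordered hue in ≥ 2 centers and the
      opposite ordered hue in ≥ 1 center;
    - concordant_3plus: some sex shows the same hue in ≥ 3 centers;
    - concordant_2: some sex shows the same hue in exactly 2 centers with
      every other center null;
    - no_difference: anything else.
    """
    if parameter not in hm.parameters:
        raise KeyError(f"unknown parameter {parameter!r}")
    found = set()
    for sex in hm.sexes:
        hues = _sex_hues(hm, parameter, sex)
        counts = {h: hues.count(h) for h in set(hues) if h != "null"}
        for hue, n in counts.items():
            opp = _OPPOSITE.get(hue)
            if n >= 2 and opp and counts.get(opp, 0) >= 1:
                found.add("contradictory")
            if n >= 3:
                found.add("concordant_3plus")
            if n == 2 and sum(counts.values()) == 2:
                found.add("concordant_2")
    for cls in ("contradictory", "concordant_3plus", "concordant_2"):
        if cls in found:
            return cls
    return "no_difference"


def _concordant_at(hues_by_sex: Iterable[Sequence[int]], k: int) -> bool:
    """≥ k centers share one non-null hue within some sex (integer codes)."""
    for hues in hues_by_sex:
        counts = np.bincount([h for h in hues if h != 0], minlength=4)
        if counts.max(initial=0) >= k:
            return True
    return False


def observed_concordance_rate(hm: HeatMap, k: int = 3) -> float:
    """Fraction of parameters showing ≥ k same-hue centers within a sex.

    This is the same counting rule the randomization null uses, so the two
    are directly comparable.
    """
    hits = 0
    for p in hm.parameters:
        rows = [
            [_HUE_CODE[h] for h in _sex_hues(hm, p, s)] for s in hm.sexes
        ]
        hits += _concordant_at(rows, k)
    return hits / len(hm.parameters) if hm.parameters else 0.0


@dataclass(frozen=True)
class NullEstimate:
    k: int
    n_reps: int
    probability: float
    observed: float
    seed: int | None
    standard_error: float = 0.0


def _cell_layout(hm: HeatMap) -> tuple[np.ndarray, list[list[list[int]]]]:
    """Hue codes of present cells plus, per parameter and sex, the indices
    of that row's present cells in the flat array."""
    keys = hm.present_keys()
    index = {key: i for i, key in enumerate(keys)}
    hues = np.array([_HUE_CODE[hm.cells[key].hue] for key in keys], dtype=np.int8)
    layout = [
        [
            [index[(p, c, s)] for c in hm.centers if (p, c, s) in index]
            for s in hm.sexes
        ]
        for p in hm.parameters
    ]
    return hues, layout


def randomize_null(
    hm: HeatMap,
    k: int = 3,
    n_reps: int = 10_000,
    seed: int = 0,
    with_replacement: bool = False,
) -> NullEstimate:
    """Estimate the chance rate of ≥ k-center concordance by randomization.

    Each repeat redistributes the observed hue multiset (nulls included)
    over all present cell positions — a permutation without replacement by
    default, preserving the color composition; ``with_replacement``
    resamples hues independently instead.  The estimate is the total count
    of concordant parameters over repeats divided by (parameters ×
    repeats); deterministic under ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(hm.centers) < k:
        raise ValueError(f"map has fewer than k={k} centers")
    rng = np.random.default_rng(seed)
    hues, layout = _cell_layout(hm)
    n_cells, n_params = hues.size, len(hm.parameters)
    per_rep = np.empty(n_reps, dtype=np.int32)
    chunk = max(1, min(n_reps, 20_000))
    done = 0
    while done < n_reps:
        r = min(chunk, n_reps - done)
        if with_replacement:
            shuffled = rng.choice(hues, size=(r, n_cells), replace=True)
        else:
            order = rng.random((r, n_cells)).argsort(axis=1)
            shuffled = hues[order]
        counts = np.zeros(r, dtype=np.int32)
        for rows in layout:
            hit = np.zeros(r, dtype=bool)
            for idx in rows:
                if not idx:
                    continue
                sub = shuffled[:, idx]
                for hue in (1, 2, 3):
                    hit |= (sub == hue).sum(axis=1) >= k
            counts += hit
        per_rep[done : done + r] = counts
        done += r
    frac = per_rep / n_params
    return NullEstimate(
        k=k,
        n_reps=n_reps,
        probability=float(frac.mean()),
        observed=observed_concordance_rate(hm, k),
        seed=seed,
        standard_error=float(frac.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0,
    )


def exhaustive_null(hm: HeatMap, k: int = 3) -> float:
    """Exact expectation of the concordant-parameter fraction over all
    distinct assignments of the observed hue multiset to the cells.

    Only feasible for small maps (≤ 16 cells and a bounded number of
    distinct arrangements); larger maps should use :func:`randomize_null`.
    """
    hues, layout = _cell_layout(hm)
    if hues.size > 16:
        raise ValueError("map too large for exhaustive enumeration; "
                         "use randomize_null")
    counts = np.bincount(hues, minlength=4)
    n_arrangements = factorial(int(hues.size))
    for c in counts:
        n_arrangements //= factorial(int(c))
    if n_arrangements > EXHAUSTIVE_LIMIT:
        raise ValueError("too many distinct assignments; use randomize_null")
    n_params = len(hm.parameters)
    total = 0
    n_seen = 0
    for arrangement in multiset_permutations(hues.tolist()):
        n_seen += 1
        arr = arrangement
        for rows in layout:
            if _concordant_at([[arr[i] for i in idx] for idx in rows], k):
                total += 1
    return total / (n_params * n_seen)


def concordance_report(
    hm: HeatMap, n_reps: int = 1000, seed: int = 0, k: int = 3
) -> dict:
    """Class roster plus observed-versus-randomized rates per class.

    For each of the four concordance classes the report gives the observed
    rate, the rate in color-randomized maps (mean over ``n_reps``
    permutations, with its Monte-Carlo standard error), and their ratio.
    """
    roster = {p: classify_parameter(hm, p) for p in hm.parameters}
    n_params = len(hm.parameters)
    observed_rates = {
        cls: sum(1 for v in roster.values() if v == cls) / n_params
        for cls in CLASSES
    }

    rng = np.random.default_rng(seed)
    hues, _ = _cell_layout(hm)
    keys = hm.present_keys()
    rand_counts = {cls: np.zeros(n_reps) for cls in CLASSES}
    shuffled_map = HeatMap(
        parameters=hm.parameters, centers=hm.centers, sexes=hm.sexes,
        cells=dict(hm.cells), absent=set(hm.absent),
    )
    inv_code = {v: k for k, v in _HUE_CODE.items()}
    for rep in range(n_reps):
        perm = rng.permutation(hues)
        for key, code in zip(keys, perm):
            hue = inv_code[int(code)]
            shuffled_map.cells[key] = CellColor(hue, 0 if hue == "null" else 1)
        for p in hm.parameters:
            rand_counts[classify_parameter(shuffled_map, p)][rep] += 1
    report = {
        "k": k,
        "n_reps": n_reps,
        "seed": seed,
        "n_parameters": n_params,
        "roster": roster,
        "observed_rate_at_k": observed_concordance_rate(hm, k),
        "null_rate_at_k": randomize_null(hm, k=k, n_reps=n_reps, seed=seed).probability,
        "classes": {},
    }
    for cls in CLASSES:
        rates = rand_counts[cls] / n_params
        null_rate = float(rates.mean())
        se = float(rates.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else 0.0
        obs = observed_rates[cls]
        report["classes"][cls] = {
            "observed": obs,
            "randomized": null_rate,
            "ratio": obs / null_rate if null_rate > 0 else float("inf"),
            "mc_se": se,
        }
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
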