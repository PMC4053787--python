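import pytest

from b6compare.concordance import HeatMap, build_heatmap
from b6compare.phenostat import CellColor, StatCell


def make_cell(parameter, center, sex="male", p=0.01, direction="N_gt_J",
              test="mann_whitney"):
    return StatCell(parameter=parameter, center=center, sex=sex, test=test,
                    p_value=p, direction=direction, effect=1.0,
                    rank_biserial=0.5, n_N=10, n_J=10)


def heatmap_from_hues(rows, centers=None, sexes=("male",)):
    """Build a HeatMap from {parameter: {sex: [hue per center]}}."""
    params = list(rows)
    any_row = next(iter(rows.values()))
    n_centers = len(next(iter(any_row.values())))
    centers = centers or [f"c{i}" for i in range(n_centers)]
    hm = HeatMap(parameters=params, centers=list(centers), sexes=list(sexes))
    for p, by_sex in rows.items():
        for s in sexes:
            for c, hue in zip(centers, by_sex[s]):
                shade = 0 if hue == "null" else 1
                hm.cells[(p, c, s)] = CellColor(hue, shade)
    return hm


@pytest.fixture
def small_null_map():
    """2 parameters x 3 centers, one sex, multiset {red x3, green x3}."""
    return heatmap_from_hues({
        "p1": {"male": ["red", "red", "red"]},
        "p2": {"male": ["green", "green", "green"]},
    })
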