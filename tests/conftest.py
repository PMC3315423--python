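import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from morphrel import TableSimParams, make_table, simulate_morphometry


@pytest.fixture
def toy_csv(tmp_path):
    """1 subject x 1 centre x 2 visits x 2 hemispheres of GM volume."""
    path = tmp_path / "toy.csv"
    path.write_text(
        "subject,centre,visit,hemisphere,measure,sulcus,algorithm,value\n"
        "S01,A,1,left,gm_volume,,,250.0\n"
        "S01,A,1,right,gm_volume,,,252.0\n"
        "S01,A,2,left,gm_volume,,,249.0\n"
        "S01,A,2,right,gm_volume,,,251.0\n"
    )
    return path


def tidy_frame(values, subjects, centres, visits, hemis, measure="gm_volume"):
    """Long frame from a (s, c, v, h) value array."""
    rows = []
    arr = np.asarray(values, dtype=float)
    for i, s in enumerate(subjects):
        for j, c in enumerate(centres):
            for k, v in enumerate(visits):
                for l, h in enumerate(hemis):
                    rows.append(
                        dict(subject=s, centre=c, visit=v, hemisphere=h,
                             measure=measure, sulcus="", algorithm="",
                             value=arr[i, j, k, l])
                    )
    return pd.DataFrame(rows)


@pytest.fixture
def tiny_crossed_frame():
    """3 subjects x 2 centres x 2 visits x 2 hemispheres, fixed values."""
    rng = np.random.default_rng(42)
    vals = 100 + 3 * rng.standard_normal((3, 1, 1, 1)) + rng.standard_normal((3, 2, 2, 2))
    return tidy_frame(vals, ["S1", "S2", "S3"], ["A", "B"], [1, 2], ["left", "right"])


@pytest.fixture
def default_sim_table():
    table, truth = simulate_morphometry(TableSimParams(seed=123))
    return table, truth
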