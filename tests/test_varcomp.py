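import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphrel import (
    TableSimParams,
    analytic_reliability,
    classify_reliability,
    estimate_variance_components,
    reliability,
    simulate_morphometry,
    sulcal_reliability_summary,
)
from morphrel.errors import (
    DegenerateDesignError,
    UnbalancedDesignError,
    UndefinedReliabilityError,
)
from morphrel.varcomp import TERMS, VarianceComponents

from conftest import tidy_frame


def naive_ems(arr):
    """Independent moment estimator: explicit-loop mean squares and the
    textbook EMS table for the fully random a x b x c design with n
    replicates, solved with numpy.  No code shared with the package path.
    """
    a, b, c, n = arr.shape
    gm = arr.mean()
    ss = {k: 0.0 for k in
          ["A", "B", "C", "AB", "AC", "BC", "ABC", "E"]}
    mA = [arr[i].mean() for i in range(a)]
    mB = [arr[:, j].mean() for j in range(b)]
    mC = [arr[:, :, k].mean() for k in range(c)]
    for i in range(a):
        ss["A"] += b * c * n * (mA[i] - gm) ** 2
    for j in range(b):
        ss["B"] += a * c * n * (mB[j] - gm) ** 2
    for k in range(c):
        ss["C"] += a * b * n * (mC[k] - gm) ** 2
    for i in range(a):
        for j in range(b):
            ss["AB"] += c * n * (arr[i, j].mean() - mA[i] - mB[j] + gm) ** 2
    for i in range(a):
        for k in range(c):
            ss["AC"] += b * n * (arr[i, :, k].mean() - mA[i] - mC[k] + gm) ** 2
    for j in range(b):
        for k in range(c):
            ss["BC"] += a * n * (arr[:, j, k].mean() - mB[j] - mC[k] + gm) ** 2
    for i in range(a):
        for j in range(b):
            for k in range(c):
                cell = arr[i, j, k].mean()
                eff = (cell - arr[i, j].mean() - arr[i, :, k].mean()
                       - arr[:, j, k].mean() + mA[i] + mB[j] + mC[k] - gm)
                ss["ABC"] += n * eff ** 2
                for l in range(n):
                    ss["E"] += (arr[i, j, k, l] - cell) ** 2
    df = {"A": a - 1, "B": b - 1, "C": c - 1,
          "AB": (a - 1) * (b - 1), "AC": (a - 1) * (c - 1),
          "BC": (b - 1) * (c - 1), "ABC": (a - 1) * (b - 1) * (c - 1),
          "E": a * b * c * (n - 1)}
    ms = {k: ss[k] / df[k] for k in ss}
    # textbook EMS table, written out literally
    M = np.array([
        # sA      sB     sC     sAB   sAC   sBC   sABC  sE
        [b*c*n,   0,     0,     c*n,  b*n,  0,    n,    1],  # MS_A
        [0,       a*c*n, 0,     c*n,  0,    a*n,  n,    1],  # MS_B
        [0,       0,     a*b*n, 0,    b*n,  a*n,  n,    1],  # MS_C
        [0,       0,     0,     c*n,  0,    0,    n,    1],  # MS_AB
        [0,       0,     0,     0,    b*n,  0,    n,    1],  # MS_AC
        [0,       0,     0,     0,    0,    a*n,  n,    1],  # MS_BC
        [0,       0,     0,     0,    0,    0,    n,    1],  # MS_ABC
        [0,       0,     0,     0,    0,    0,    0,    1],  # MS_E
    ], dtype=float)
    rhs = np.array([ms[k] for k in ["A", "B", "C", "AB", "AC", "BC", "ABC", "E"]])
    sol = np.linalg.solve(M, rhs)
    names = ["subject", "centre", "visit", "subject:centre", "subject:visit",
             "centre:visit", "subject:centre:visit", "residual"]
    return dict(zip(names, sol))


class TestEMSEstimator:
    def test_matches_independent_oracle(self, tiny_crossed_frame):
        """3x2x2x2 fixture: package estimates equal the hand-coded EMS
        solution to 1e-10."""
        arr = (
            tiny_crossed_frame.sort_values(
                ["subject", "centre", "visit", "hemisphere"]
            )["value"].to_numpy().reshape(3, 2, 2, 2)
        )
        expected = naive_ems(arr)
        comp = estimate_variance_components(tiny_crossed_frame)
        for term in TERMS:
            assert comp.raw[term] == pytest.approx(expected[term], abs=1e-10)

    def test_noise_free_subject_only(self):
        """Pure between-subject signal: only sigma2_subject is positive."""
        offsets = np.array([0.0, 5.0, -3.0, 9.0])
        vals = 100.0 + offsets[:, None, None, None] * np.ones((4, 2, 2, 2))
        frame = tidy_frame(vals, ["S1", "S2", "S3", "S4"], ["A", "B"], [1, 2],
                           ["left", "right"])
        comp = estimate_variance_components(frame)
        assert comp.components["subject"] > 0
        for term in TERMS:
            if term != "subject":
                assert comp.raw[term] <= 1e-18
                assert comp.components[term] == 0.0

    def test_unbalanced_raises(self, tiny_crossed_frame):
        frame = tiny_crossed_frame.iloc[:-1]
        with pytest.raises(UnbalancedDesignError, match="reml"):
            estimate_variance_components(frame)

    def test_single_level_raises(self, tiny_crossed_frame):
        frame = tiny_crossed_frame[tiny_crossed_frame["centre"] == "A"]
        with pytest.raises(DegenerateDesignError):
            estimate_variance_components(frame)

    def test_shift_invariance(self, tiny_crossed_frame):
        comp = estimate_variance_components(tiny_crossed_frame)
        shifted = tiny_crossed_frame.assign(value=tiny_crossed_frame["value"] + 1234.5)
        comp2 = estimate_variance_components(shifted)
        for term in TERMS:
            assert comp2.raw[term] == pytest.approx(comp.raw[term], abs=1e-8)

    def test_scale_equivariance_of_components(self, tiny_crossed_frame):
        comp = estimate_variance_components(tiny_crossed_frame)
        scaled = tiny_crossed_frame.assign(value=tiny_crossed_frame["value"] * 3.0)
        comp2 = estimate_variance_components(scaled)
        for term in TERMS:
            assert comp2.raw[term] == pytest.approx(9.0 * comp.raw[term], rel=1e-8)

    def test_single_observation_per_cell_confounds_threeway(self):
        table, _ = simulate_morphometry(TableSimParams(seed=3, n_hemispheres=1))
        comp = estimate_variance_components(table.analysis_frame("gm_volume"))
        assert "subject:centre:visit" not in comp.raw
        assert "residual" in comp.raw
        assert comp.design[3] == 1


class TestReliability:
    def test_reliability_ratio_arithmetic(self):
        comp = VarianceComponents(
            components={"subject": 3.0, "centre": 1.0, "visit": 0.0,
                        "subject:centre": 0.0, "subject:visit": 0.0,
                        "centre:visit": 0.0, "residual": 1.0},
            raw={}, design=(3, 2, 2, 1),
        )
        r = reliability(comp, "centre")
        assert r.value == pytest.approx(0.8, abs=1e-12)
        assert set(r.components_used) == {"centre", "subject:centre", "centre:visit"}

    @pytest.mark.parametrize("factor,expected", [("centre", 1.0), ("visit", 0.0)])
    def test_boundaries(self, factor, expected):
        comp = VarianceComponents(
            components={"subject": 0.0, "centre": 0.0, "visit": 2.0,
                        "subject:centre": 0.0, "subject:visit": 1.0,
                        "centre:visit": 0.0, "residual": 0.0},
            raw={}, design=(3, 2, 2, 1),
        )
        assert reliability(comp, factor).value == expected

    def test_zero_total_variance_undefined(self):
        comp = VarianceComponents(
            components={t: 0.0 for t in TERMS}, raw={}, design=(3, 2, 2, 2)
        )
        with pytest.raises(UndefinedReliabilityError):
            reliability(comp, "centre")

    @given(
        st.dictionaries(
            st.sampled_from(TERMS),
            st.floats(min_value=0.0, max_value=1e6),
            min_size=1,
        ).filter(lambda d: sum(d.values()) > 0)
    )
    def test_reliability_identity_property(self, comps):
        """reliability + V_factor/V_total == 1 to 1e-12, for both factors."""
        vc = VarianceComponents(components=dict(comps), raw={}, design=(2, 2, 2, 2))
        total = vc.total
        for factor in ("centre", "visit"):
            v_f = sum(v for t, v in comps.items()
                      if factor in t.split(":") and t != "residual")
            r = reliability(vc, factor)
            assert r.value + v_f / total == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= r.value <= 1.0

    def test_estimated_reliability_scale_invariant(self, tiny_crossed_frame):
        comp = estimate_variance_components(tiny_crossed_frame)
        scaled = estimate_variance_components(
            tiny_crossed_frame.assign(value=tiny_crossed_frame["value"] * 7.0)
        )
        for factor in ("centre", "visit"):
            assert reliability(scaled, factor).value == pytest.approx(
                reliability(comp, factor).value, abs=1e-10
            )


class TestGrading:
    @pytest.mark.parametrize(
        "value,grade",
        [
            (0.92, "excellent"), (0.90, "excellent"), (1.0, "excellent"),
            (0.89, "good"), (0.75, "good"), (0.70, "good"),
            (0.69, "moderate"), (0.50, "moderate"),
            (0.49, "poor"), (0.13, "poor"), (0.0, "poor"),
        ],
    )
    def test_cut_points(self, value, grade):
        assert classify_reliability(value) == grade

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            classify_reliability(bad)


class TestRecovery:
    def test_parameter_recovery_means(self):
        """Means of component estimates over 200 draws of the 13x3x2x2
        design recover the generating components."""
        comps = {"subject": 9.0, "centre": 1.0, "visit": 0.25,
                 "subject:centre": 0.5, "residual": 1.0}
        sums = {t: 0.0 for t in TERMS}
        n_rep = 200
        for s in range(n_rep):
            table, _ = simulate_morphometry(
                TableSimParams(seed=s, components=comps)
            )
            est = estimate_variance_components(table.analysis_frame("gm_volume"))
            for t in TERMS:
                sums[t] += est.raw[t]
        full = dict.fromkeys(TERMS, 0.0) | comps
        for t in ("subject", "centre", "visit", "subject:centre", "residual"):
            mean = sums[t] / n_rep
            truth = full[t]
            tol = max(0.10 * truth, 0.12)  # MC error floor for small truths
            assert abs(mean - truth) < tol, (t, mean, truth)

    def test_analytic_reliability_identity(self):
        comps = {"subject": 9.0, "centre": 1.0, "visit": 0.25,
                 "subject:centre": 0.5, "subject:visit": 0.0,
                 "centre:visit": 0.0, "subject:centre:visit": 0.0,
                 "residual": 1.0}
        total = sum(comps.values())
        assert analytic_reliability(comps, "centre") == pytest.approx(
            (total - 1.5) / total
        )
        assert analytic_reliability(comps, "visit") == pytest.approx(
            (total - 0.25) / total
        )


@pytest.fixture(scope="module")
def sulcal_table():
    table, truth = simulate_morphometry(
        TableSimParams(
            seed=5, measure="sulcal_surface", n_sulci=8,
            grand_mean=900.0, algorithm="markovian",
            components={"subject": 9.0, "centre": 1.0, "visit": 0.25,
                        "subject:centre": 0.5, "residual": 1.0},
        )
    )
    return table, truth


class TestSulcal:
    def test_counts_and_summary(self, sulcal_table):
        table, truth = sulcal_table
        res = sulcal_reliability_summary(table, "sulcal_surface", "markovian")
        # 8 sulci x 2 hemispheres
        assert len(res.per_sulcus) == 16
        assert res.skipped == ()
        # unweighted means match the column means
        assert res.mean_centre == pytest.approx(
            res.per_sulcus["centre_reliability"].mean()
        )
        # scatter around the analytic truth
        truth_c = truth["analytic_reliability"]["centre"]
        assert abs(res.mean_centre - truth_c) < 0.15

    def test_reduced_subject_flagged(self, sulcal_table):
        table, _ = sulcal_table
        df = table.records
        drop = (
            (df["sulcus"] == "SULC01") & (df["subject"] == "S01")
            & (df["hemisphere"] == "left") & (df["centre"] == "A")
        )
        table2 = type(table)(records=df[~drop].reset_index(drop=True))
        res = sulcal_reliability_summary(table2, "sulcal_surface", "markovian")
        row = res.per_sulcus.set_index(["hemisphere", "sulcus"]).loc[("left", "SULC01")]
        assert row["reduced_subjects"]
        assert row["n_subjects"] == 12
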