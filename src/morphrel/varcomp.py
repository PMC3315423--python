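"""Crossed random-effects variance components and scanner reliability.

The measurement model for one morphometric measure is the fully crossed
random-effects ANOVA

    y_scvh = mu + A_s + B_c + C_v + AB_sc + AC_sv + BC_cv + ABC_scv + e_scvh

with s = subject, c = centre, v = visit and h indexing within-cell
replicates (the two hemispheres, by default).  All effects are mutually
independent zero-mean random variables; the quantities of interest are
their variances sigma^2_T.

For a balanced design the components are estimated by the method of
moments: the classical ANOVA mean squares are computed and the expected
mean squares (EMS) equations of the fully random model are solved
exactly.  Raw solutions can be negative; they are truncated at zero
before any reliability is formed (the raw values are retained for
inspection).  REML estimation (via statsmodels MixedLM with crossed
variance components) is available as an alternative and as an
independent cross-check; it is the only option for unbalanced data.

The reliability of a factor F (centre or visit) is

    reliability(F) = (V_total - V_F) / V_total

where V_total is the sum of all (truncated) components and V_F is the
sum of the components of F and every interaction containing F (the
centre:visit and, when estimable, three-way components therefore count
against both factors).  The value lies in [0, 1]: 1 means the factor
contributes nothing, 0 means it is the only source of variance.  Grades
follow the conventional rule of thumb: < 0.50 poor, 0.50-0.70 moderate,
0.70-0.90 good, >= 0.90 excellent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MorphometryTable, validate_design
from .errors import (
    DegenerateDesignError,
    UnbalancedDesignError,
    UndefinedReliabilityError,
)

FACTORS = ("subject", "centre", "visit")

#: Random terms of the crossed model, in canonical order.
TERMS = (
    "subject",
    "centre",
    "visit",
    "subject:centre",
    "subject:visit",
    "centre:visit",
    "subject:centre:visit",
    "residual",
)

GRADE_BOUNDS = ((0.50, "poor"), (0.70, "moderate"), (0.90, "good"), (np.inf, "excellent"))


@dataclass
class VarianceComponents:
    """Variance-component estimates for the crossed random model.

    ``raw`` holds the unconstrained method-of-moments (or REML) solutions;
    ``components`` holds the nonnegative (truncated) estimates used for
    reliabilities.  ``design`` is (n_subjects, n_centres, n_visits,
    n_replicates).
    """

    components: dict[str, float]
    raw: dict[str, float]
    design: tuple[int, int, int, int]
    method: str = "ems"
    residualized: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return float(sum(self.components.values()))

    def factor_variance(self, factor: str) -> float:
        return float(
            sum(v for t, v in self.components.items() if factor in t.split(":"))
        )


@dataclass(frozen=True)
class ReliabilityEstimate:
    """Between-centre or between-visit reliability with its grade."""

    factor: str
    value: float
    grade: str
    components_used: tuple[str, ...]


def _balanced_array(frame: pd.DataFrame) -> np.ndarray:
    """Reshape a tidy frame into a (subject, centre, visit, replicate) array.

    Raises if any cell is missing or cells have unequal replicate counts.
    """
    subjects = sorted(frame["subject"].unique())
    centres = sorted(frame["centre"].unique())
    visits = sorted(frame["visit"].unique())
    counts = frame.groupby(["subject", "centre", "visit"]).size()
    if len(counts) != len(subjects) * len(centres) * len(visits) or counts.nunique() != 1:
        raise UnbalancedDesignError(
            "design is not balanced over subject x centre x visit; "
            "use method='reml' for unbalanced data"
        )
    n_rep = int(counts.iloc[0])
    idx = {
        "subject": {s: i for i, s in enumerate(subjects)},
        "centre": {c: i for i, c in enumerate(centres)},
        "visit": {v: i for i, v in enumerate(visits)},
    }
    arr = np.empty((len(subjects), len(centres), len(visits), n_rep))
    order = frame.sort_values(["subject", "centre", "visit", "hemisphere"])
    filled = np.zeros(arr.shape[:3], dtype=int)
    for row in order.itertuples(index=False):
        i = idx["subject"][row.subject]
        j = idx["centre"][row.centre]
        k = idx["visit"][row.visit]
        arr[i, j, k, filled[i, j, k]] = row.value
        filled[i, j, k] += 1
    return arr


def anova_mean_squares(arr: np.ndarray) -> dict[str, tuple[float, int]]:
    """Balanced three-way ANOVA sums of squares via the means decomposition.

    ``arr`` has shape (a, b, c, n).  Returns term -> (SS, df); the
    within-cell term is reported as 'residual' (absent when n == 1).
    """
    a, b, c, n = arr.shape
    mean = arr.mean()
    m_a = arr.mean(axis=(1, 2, 3))
    m_b = arr.mean(axis=(0, 2, 3))
    m_c = arr.mean(axis=(0, 1, 3))
    m_ab = arr.mean(axis=(2, 3))
    m_ac = arr.mean(axis=(1, 3))
    m_bc = arr.mean(axis=(0, 3))
    m_abc = arr.mean(axis=3)

    out: dict[str, tuple[float, int]] = {}
    out["subject"] = (b * c * n * float(np.sum((m_a - mean) ** 2)), a - 1)
    out["centre"] = (a * c * n * float(np.sum((m_b - mean) ** 2)), b - 1)
    out["visit"] = (a * b * n * float(np.sum((m_c - mean) ** 2)), c - 1)
    eff_ab = m_ab - m_a[:, None] - m_b[None, :] + mean
    out["subject:centre"] = (c * n * float(np.sum(eff_ab**2)), (a - 1) * (b - 1))
    eff_ac = m_ac - m_a[:, None] - m_c[None, :] + mean
    out["subject:visit"] = (b * n * float(np.sum(eff_ac**2)), (a - 1) * (c - 1))
    eff_bc = m_bc - m_b[:, None] - m_c[None, :] + mean
    out["centre:visit"] = (a * n * float(np.sum(eff_bc**2)), (b - 1) * (c - 1))
    eff_abc = (
        m_abc
        - m_ab[:, :, None]
        - m_ac[:, None, :]
        - m_bc[None, :, :]
        + m_a[:, None, None]
        + m_b[None, :, None]
        + m_c[None, None, :]
        - mean
    )
    out["subject:centre:visit"] = (
        n * float(np.sum(eff_abc**2)),
        (a - 1) * (b - 1) * (c - 1),
    )
    if n > 1:
        out["residual"] = (
            float(np.sum((arr - m_abc[..., None]) ** 2)),
            a * b * c * (n - 1),
        )
    return out


def _ems_matrix(a: int, b: int, c: int, n: int, terms: Sequence[str]) -> np.ndarray:
    """EMS coefficients: E[MS_S] = sum_T coef(S, T) * sigma^2_T.

    For the fully random balanced model, sigma^2_T enters E[MS_S] iff the
    factor set of T contains that of S, with coefficient equal to the
    number of observations sharing one level combination of T (replicates
    times the levels of every factor absent from T); the residual always
    enters with coefficient 1.
    """
    levels = {"subject": a, "centre": b, "visit": c}
    sets = {t: frozenset(t.split(":")) for t in terms if t != "residual"}
    M = np.zeros((len(terms), len(terms)))
    for i, s in enumerate(terms):
        for j, t in enumerate(terms):
            if t == "residual":
                M[i, j] = 1.0
            elif s != "residual" and sets[t] >= sets[s]:
                absent = set(FACTORS) - sets[t]
                M[i, j] = n * int(np.prod([levels[f] for f in absent] or [1]))
    return M


def estimate_variance_components(
    frame: pd.DataFrame,
    *,
    method: str = "ems",
    covariates: Sequence[str] = (),
) -> VarianceComponents:
    """Estimate the crossed-model variance components from a tidy frame.

    ``frame`` needs columns subject, centre, visit, hemisphere, value (plus
    any covariate columns).  When ``covariates`` are given the values are
    first residualized against them (pooled OLS, slopes only — the grand
    mean is retained), then decomposed; the adjustment is recorded in the
    result's metadata.

    With replicates (both hemispheres per cell) all seven random terms are
    estimable; with one observation per cell the three-way interaction is
    confounded with the residual and reported under 'residual'.
    """
    frame = frame.copy()
    if covariates:
        frame["value"] = residualize(frame, covariates)
    for f in FACTORS:
        if frame[f].nunique() < 2:
            raise DegenerateDesignError(f"factor {f!r} has fewer than 2 levels")
    arr = _balanced_array(frame)
    a, b, c, n = arr.shape
    if method == "reml":
        raw = _reml_components(frame, with_threeway=n > 1, start=_ems_start(arr))
    elif method == "ems":
        ms = anova_mean_squares(arr)
        terms = list(ms)
        if n == 1:
            # three-way MS is the error stratum; relabel
            terms = [t for t in terms if t != "subject:centre:visit"] + ["residual"]
            ms["residual"] = ms.pop("subject:centre:visit")
        M = _ems_matrix(a, b, c, n, terms)
        rhs = np.array([ms[t][0] / ms[t][1] for t in terms])
        sol = np.linalg.solve(M, rhs)
        raw = dict(zip(terms, sol))
    else:
        raise ValueError(f"unknown method {method!r}")
    components = {t: max(v, 0.0) for t, v in raw.items()}
    return VarianceComponents(
        components=components,
        raw=raw,
        design=(a, b, c, n),
        method=method,
        residualized=tuple(covariates),
    )


def residualize(frame: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    """Remove pooled linear covariate effects, keeping the grand mean."""
    y = frame["value"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones_like(y)]
        + [frame[c].to_numpy(dtype=float) - frame[c].mean() for c in covariates]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted_slopes = X[:, 1:] @ beta[1:]
    return y - fitted_slopes


def _ems_start(arr: np.ndarray) -> dict[str, float]:
    """Truncated moment estimates, used to warm-start the REML optimizer."""
    a, b, c, n = arr.shape
    ms = anova_mean_squares(arr)
    terms = list(ms)
    if n == 1:
        terms = [t for t in terms if t != "subject:centre:visit"] + ["residual"]
        ms["residual"] = ms.pop("subject:centre:visit")
    M = _ems_matrix(a, b, c, n, terms)
    sol = np.linalg.solve(M, np.array([ms[t][0] / ms[t][1] for t in terms]))
    return {t: max(float(v), 0.0) for t, v in zip(terms, sol)}


def _reml_components(
    frame: pd.DataFrame,
    *,
    with_threeway: bool,
    start: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """REML estimates via a crossed variance-components mixed model.

    The whole sample forms a single group and every random term enters as
    a crossed variance component.  The optimizer is warm-started at the
    (truncated) moment solution when one is available; for a balanced
    design with an admissible moment solution REML reproduces it exactly.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    df = frame.copy()
    df["visit"] = df["visit"].astype(str)
    vc = {
        "subject": "0 + C(subject)",
        "centre": "0 + C(centre)",
        "visit": "0 + C(visit)",
        "subject:centre": "0 + C(subject):C(centre)",
        "subject:visit": "0 + C(subject):C(visit)",
        "centre:visit": "0 + C(centre):C(visit)",
    }
    if with_threeway:
        vc["subject:centre:visit"] = "0 + C(subject):C(centre):C(visit)"
    df["_one"] = 1
    model = MixedLM.from_formula(
        "value ~ 1", groups="_one", vc_formula=vc, re_formula="0", data=df
    )
    names = model.exog_vc.names
    start_params = None
    if start is not None:
        scale0 = max(start.get("residual", 1.0), 1e-3)
        v0 = np.array([max(start.get(nm, 0.0), 1e-3) / scale0 for nm in names])
        start_params = MixedLMParams.from_components(
            fe_params=np.array([df["value"].mean()]),
            cov_re=np.empty((0, 0)),
            vcomp=v0,
        )
    best = None
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    for opt in ("lbfgs", "cg", "powell"):
        try:
            with _warnings.catch_warnings():
                # near-boundary fits routinely trip the optimizer's own
                # diagnostics; the best-criterion fallback handles them
                _warnings.simplefilter("ignore", ConvergenceWarning)
                fit = model.fit(
                    reml=True, method=opt, maxiter=2000, start_params=start_params
                )
        except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
            continue
        if best is None or fit.llf > best.llf:
            best = fit
        if getattr(fit, "converged", True):
            break
    if best is None:  # pragma: no cover
        raise RuntimeError("REML optimization failed with all optimizers")
    out = {name: float(v) for name, v in zip(names, best.vcomp)}
    out["residual"] = float(best.scale)
    return out


def classify_reliability(value: float) -> str:
    """Grade a reliability in [0, 1] as poor/moderate/good/excellent.

    Intervals are left-closed: [0, 0.50) poor, [0.50, 0.70) moderate,
    [0.70, 0.90) good, [0.90, 1] excellent.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"reliability {value} outside [0, 1]")
    for bound, grade in GRADE_BOUNDS:
        if value < bound:
            return grade
    return "excellent"  # pragma: no cover


def reliability(components: VarianceComponents, factor: str) -> ReliabilityEstimate:
    """Reliability of 'centre' or 'visit' from estimated components.

    V_factor sums the factor's own component and every interaction
    containing it; the value is (V_total - V_factor) / V_total.
    """
    if factor not in ("centre", "visit"):
        raise ValueError("factor must be 'centre' or 'visit'")
    total = components.total
    if total <= 0:
        raise UndefinedReliabilityError("total variance is zero")
    used = tuple(
        t for t in components.components if factor in t.split(":") and t != "residual"
    )
    v_factor = sum(components.components[t] for t in used)
    value = (total - v_factor) / total
    value = min(max(value, 0.0), 1.0)
    return ReliabilityEstimate(
        factor=factor,
        value=value,
        grade=classify_reliability(value),
        components_used=used,
    )


def analytic_reliability(components: Mapping[str, float], factor: str) -> float:
    """Reliability implied exactly by known (true) variance components."""
    total = sum(components.values())
    if total <= 0:
        raise UndefinedReliabilityError("total variance is zero")
    v_factor = sum(
        v for t, v in components.items() if factor in t.split(":") and t != "residual"
    )
    return (total - v_factor) / total


@dataclass
class SulcalReliabilitySummary:
    """Per-sulcus reliabilities and their unweighted across-sulcus means."""

    per_sulcus: pd.DataFrame
    mean_centre: float
    mean_visit: float
    skipped: tuple[tuple[str, str, str], ...]  # (hemisphere, sulcus, reason)


def sulcal_reliability_summary(
    table: MorphometryTable,
    measure: str,
    algorithm: str,
    *,
    covariates: Sequence[str] = (),
    method: str = "ems",
) -> SulcalReliabilitySummary:
    """Reliability pair for every sulcus label, per hemisphere.

    Each sulcus piece is analysed independently (its sizes differ too much
    across sulci for pooling): the crossed model is fitted on the subjects
    with complete centre x visit data for that sulcus and hemisphere, with
    one observation per cell.  Sulci that cannot be analysed (too few
    complete subjects, degenerate variance) are listed as skipped.  The
    summary means are unweighted across analysed sulci.
    """
    from .errors import EmptyDesignError, MorphrelError

    df = table.records
    mask = (df["measure"] == measure) & (df["algorithm"] == algorithm)
    sub = df.loc[mask]
    if sub.empty:
        raise EmptyDesignError(f"no {measure!r} records for algorithm {algorithm!r}")
    rows = []
    skipped: list[tuple[str, str, str]] = []
    for (hemi, sulcus), grp in sub.groupby(["hemisphere", "sulcus"], sort=True):
        centres = sorted(grp["centre"].unique())
        visits = sorted(grp["visit"].unique())
        expected = len(centres) * len(visits)
        counts = grp.groupby("subject").size()
        complete = counts.index[counts == expected]
        reduced = grp[grp["subject"].isin(complete)]
        flagged = len(complete) < counts.size
        try:
            if covariates:
                reduced = _merge_covariates(table, reduced, covariates)
            comp = estimate_variance_components(
                reduced, method=method, covariates=covariates
            )
            rc = reliability(comp, "centre")
            rv = reliability(comp, "visit")
        except MorphrelError as exc:
            skipped.append((hemi, str(sulcus), str(exc)))
            continue
        rows.append(
            {
                "hemisphere": hemi,
                "sulcus": sulcus,
                "n_subjects": len(complete),
                "reduced_subjects": flagged,
                "centre_reliability": rc.value,
                "centre_grade": rc.grade,
                "visit_reliability": rv.value,
                "visit_grade": rv.grade,
            }
        )
    if not rows:
        raise EmptyDesignError("no sulcus passed design validation")
    per = pd.DataFrame(rows)
    return SulcalReliabilitySummary(
        per_sulcus=per,
        mean_centre=float(per["centre_reliability"].mean()),
        mean_visit=float(per["visit_reliability"].mean()),
        skipped=tuple(skipped),
    )


def _merge_covariates(
    table: MorphometryTable, frame: pd.DataFrame, covariates: Sequence[str]
) -> pd.DataFrame:
    keys = ["subject", "centre", "visit", "hemisphere"]
    out = frame
    for cov in covariates:
        cdf = table.view(cov)[keys + ["value"]].rename(columns={"value": cov})
        out = out.merge(cdf, on=keys, how="inner")
    return out
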