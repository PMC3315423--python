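"""Fixed-effects ANCOVA engine for scanner-effect tests.

For each morphometric measure the model is

    value ~ subject + centre + visit + centre:visit [+ covariates]

with all factors fixed and the covariates (cerebral hemisphere volume;
plus GSI for sulcal measures) entered additively after mean-centering.
The F tests for centre, visit and their interaction use the full-model
residual mean square as denominator.  Two sum-of-squares conventions are
supported: ``adjusted`` (drop-one from the full model, each term adjusted
for all others) and ``sequential`` (incremental in listed order).  On a
balanced design with no covariates the two coincide.

Factors are encoded with sum-to-zero contrasts so that drop-one tests of
main effects remain meaningful in the presence of the interaction.
p-values are reported unadjusted for multiple testing and should be read
as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats

from .errors import (
    AliasingError,
    InsufficientDataError,
    SaturatedModelError,
)

TESTED_EFFECTS = ("centre", "visit", "centre:visit")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the ANCOVA for one measure.

    ``covariates`` are column names of the analysis frame (typically
    ``hemisphere_volume`` and, for sulcal measures, ``gsi``).
    """

    response: str = "value"
    covariates: tuple[str, ...] = ()
    ss_type: str = "adjusted"  # or "sequential"
    alpha: float = 0.05

    def __post_init__(self):
        if self.ss_type not in ("adjusted", "sequential"):
            raise ValueError(f"unknown ss_type {self.ss_type!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class OLSFit:
    """Least-squares fit: coefficients, residual SS and residual df."""

    params: np.ndarray
    rss: float
    df_resid: int
    rank: int


def _formula(spec: ModelSpec) -> str:
    terms = [
        "C(subject, Sum)",
        "C(centre, Sum)",
        "C(visit, Sum)",
        "C(centre, Sum):C(visit, Sum)",
    ]
    terms += [f"center({c})" for c in spec.covariates]
    return f"{spec.response} ~ " + " + ".join(terms)


def build_design_matrix(frame: pd.DataFrame, spec: ModelSpec):
    """Encode the ANCOVA design.

    Returns ``(y, X, term_slices)`` where ``term_slices`` maps each model
    term (including ``Intercept``) to its column slice in ``X``.  Factors
    use sum-to-zero coding; covariates are mean-centered.

    Raises :class:`AliasingError` if the encoded matrix is rank deficient
    (e.g. a constant covariate, collinear with the intercept).
    """
    y, X = patsy.dmatrices(_formula(spec), frame, return_type="dataframe")
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise AliasingError(
            "design matrix is rank deficient; check for constant or "
            "collinear covariates/factors"
        )
    slices = dict(X.design_info.term_name_slices)
    return y.to_numpy(dtype=float).ravel(), Xm, slices


def fit_ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Ordinary least squares via QR (numpy lstsq)."""
    n, p = X.shape
    if n < p:
        raise InsufficientDataError(f"{n} observations for {p} parameters")
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ params
    return OLSFit(params=params, rss=float(resid @ resid), df_resid=n - rank, rank=rank)


def _term_name(effect: str) -> str:
    parts = effect.split(":")
    return ":".join(f"C({p}, Sum)" for p in parts)


def f_test_effects(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """F tests for centre, visit and centre:visit.

    Returns an effect table indexed by effect name with columns
    ``F``, ``df_num``, ``df_den``, ``p_value`` and ``significant`` (at
    ``spec.alpha``).  The denominator is always the full-model residual
    mean square.
    """
    y, X, slices = build_design_matrix(frame, spec)
    full = fit_ols(X, y)
    if full.df_resid <= 0:
        raise SaturatedModelError("no residual degrees of freedom")
    mse = full.rss / full.df_resid
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if mse <= 1e-12 * max(total_ss, 1.0) / max(full.df_resid, 1):
        raise SaturatedModelError("residual variance is (numerically) zero")

    tested = {e: _term_name(e) for e in TESTED_EFFECTS}
    rows = []
    if spec.ss_type == "adjusted":
        for effect, term in tested.items():
            sl = slices[term]
            keep = np.ones(X.shape[1], dtype=bool)
            keep[sl] = False
            reduced = fit_ols(X[:, keep], y)
            delta_ss = reduced.rss - full.rss
            delta_df = sl.stop - sl.start
            rows.append((effect, delta_ss, delta_df))
    else:  # sequential, in formula order
        order = [t for t in slices if t != "Intercept"]
        cols = slices["Intercept"]
        current = list(range(cols.start, cols.stop))
        prev = fit_ols(X[:, current], y)
        seq = {}
        for term in order:
            sl = slices[term]
            current += list(range(sl.start, sl.stop))
            nxt = fit_ols(X[:, current], y)
            seq[term] = (prev.rss - nxt.rss, sl.stop - sl.start)
            prev = nxt
        for effect, term in tested.items():
            rows.append((effect, *seq[term]))

    out = []
    for effect, delta_ss, delta_df in rows:
        delta_ss = max(delta_ss, 0.0)
        F = (delta_ss / delta_df) / mse
        p = float(stats.f.sf(F, delta_df, full.df_resid))
        out.append(
            {
                "effect": effect,
                "F": F,
                "df_num": delta_df,
                "df_den": full.df_resid,
                "p_value": p,
                "significant": p < spec.alpha,
            }
        )
    return pd.DataFrame(out).set_index("effect")


def format_p(p: float) -> str:
    """Report-style p-value formatting: '< 0.001' below 0.001, else 3 dp."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"
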