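"""Synthetic data with known ground truth for the whole pipeline.

Two generators:

* :func:`simulate_morphometry` draws long-format morphometry tables from
  the additive crossed random-effects model (subject, centre, visit and
  all their interactions, Gaussian throughout) with user-specified
  variance components, optional fixed per-centre shifts, and an optional
  linear covariate (brain-volume) dependence.  The default design mirrors
  a multi-site test-retest study: 13 subjects x 3 centres x 2 visits x
  2 hemispheres (an 11 x 5 x 2 x 2 variant for a five-centre 3 T cohort
  is one parameter change away).  Ground truth — every drawn effect and
  the analytic reliabilities implied by the components — is returned
  alongside the table.

* :func:`simulate_phantom` builds a 3-D head-like phantom of nested
  tissue regions (WM core, GM shell, CSF shell) with per-tissue mean
  grey levels, additive Gaussian noise and a smooth multiplicative bias
  field 1 + alpha * g(x) with g a separable low-frequency profile in
  [-1, 1].  Tissue masks are deterministic functions of the geometry,
  so voxel counts are seed-independent.

One seed governs a draw; per-term sub-streams are derived from it so
that enlarging the design leaves shared draws unchanged.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import MorphometryTable, make_table
from .errors import GeometryError
from .varcomp import TERMS, analytic_reliability

#: Variance components used by default: dominant between-subject variance,
#: a real centre effect, a small visit effect and a subject-by-centre
#: interaction over unit residual noise.
DEFAULT_COMPONENTS = {
    "subject": 9.0,
    "centre": 1.0,
    "visit": 0.25,
    "subject:centre": 0.5,
    "subject:visit": 0.0,
    "centre:visit": 0.0,
    "subject:centre:visit": 0.0,
    "residual": 1.0,
}


@dataclass(frozen=True)
class CovariateModel:
    """Linear dependence of the response on a brain-size covariate.

    The covariate has a per-subject component (``sd``, the between-subject
    spread of e.g. hemisphere volume) plus per-scan measurement variation
    (``noise_sd``) — without the latter it would be confounded with the
    subject factor in any within-subject model.
    """

    name: str = "hemisphere_volume"
    mean: float = 642.0
    sd: float = 40.0
    noise_sd: float = 5.0
    slope: float = 0.0


@dataclass
class TableSimParams:
    """Parameters of the crossed-design table simulator."""

    n_subjects: int = 13
    n_centres: int = 3
    n_visits: int = 2
    n_hemispheres: int = 2
    grand_mean: float = 259.0
    measure: str = "gm_volume"
    components: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENTS)
    )
    fixed_centre_shifts: Sequence[float] | None = None
    covariate: CovariateModel | None = None
    n_sulci: int | None = None
    sulcus_mean: float = 900.0
    sulcus_mean_sd: float = 400.0
    algorithm: str = "global"
    seed: int = 0

    def __post_init__(self):
        comp = dict(DEFAULT_COMPONENTS)
        comp.update(self.components)
        unknown = set(comp) - set(TERMS)
        if unknown:
            raise ValueError(f"unknown variance terms: {sorted(unknown)}")
        if any(v < 0 for v in comp.values()):
            raise ValueError("variance components must be >= 0")
        if min(self.n_subjects, self.n_centres, self.n_visits, self.n_hemispheres) < 1:
            raise ValueError("design sizes must be >= 1")
        if self.n_hemispheres > 2:
            raise ValueError("at most 2 hemispheres (left, right)")
        self.components = comp


def _term_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-term stream independent of other terms.

    The label is hashed (stable across runs) into the spawn key so that
    streams for different terms — or for different sulci — never collide.
    """
    digest = hashlib.sha256(label.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _draw_effects(params: TableSimParams, seed_offset: str = "") -> dict[str, np.ndarray]:
    a, b, c = params.n_subjects, params.n_centres, params.n_visits
    shapes = {
        "subject": (a, 1, 1, 1),
        "centre": (1, b, 1, 1),
        "visit": (1, 1, c, 1),
        "subject:centre": (a, b, 1, 1),
        "subject:visit": (a, 1, c, 1),
        "centre:visit": (1, b, c, 1),
        "subject:centre:visit": (a, b, c, 1),
    }
    effects = {}
    for term, shape in shapes.items():
        sd = np.sqrt(params.components[term])
        rng = _term_rng(params.seed, term + seed_offset)
        effects[term] = sd * rng.standard_normal(shape)
    return effects


def _cell_values(params: TableSimParams, seed_offset: str = "") -> np.ndarray:
    a, b, c, n = (
        params.n_subjects,
        params.n_centres,
        params.n_visits,
        params.n_hemispheres,
    )
    effects = _draw_effects(params, seed_offset)
    rng = _term_rng(params.seed, "residual" + seed_offset)
    noise = np.sqrt(params.components["residual"]) * rng.standard_normal((a, b, c, n))
    values = params.grand_mean + noise
    for eff in effects.values():
        values = values + eff
    if params.fixed_centre_shifts is not None:
        shifts = np.asarray(params.fixed_centre_shifts, dtype=float)
        if shifts.shape != (b,):
            raise ValueError(f"fixed_centre_shifts must have length {b}")
        values = values + shifts[None, :, None, None]
    return values


def _long_frame(values: np.ndarray, params: TableSimParams, measure, sulcus, algorithm):
    a, b, c, n = values.shape
    subjects = [f"S{i + 1:02d}" for i in range(a)]
    centres = [chr(ord("A") + j) for j in range(b)]
    visits = list(range(1, c + 1))
    hemis = ["left", "right"][:n]
    idx = pd.MultiIndex.from_product(
        [subjects, centres, visits, hemis],
        names=["subject", "centre", "visit", "hemisphere"],
    )
    df = pd.DataFrame({"value": values.ravel()}, index=idx).reset_index()
    df["measure"] = measure
    df["sulcus"] = sulcus
    df["algorithm"] = algorithm
    return df


def simulate_morphometry(params: TableSimParams) -> tuple[MorphometryTable, dict]:
    """Draw one table from the crossed random-effects model.

    Returns the validated table and a ground-truth record holding the
    generating components, the analytic between-centre/between-visit
    reliabilities they imply, and the drawn random effects.
    """
    frames = []
    truth: dict = {
        "components": dict(params.components),
        "grand_mean": params.grand_mean,
        "design": [
            params.n_subjects,
            params.n_centres,
            params.n_visits,
            params.n_hemispheres,
        ],
        "analytic_reliability": {
            factor: (
                analytic_reliability(params.components, factor)
                if sum(params.components.values()) > 0
                else None  # all variances zero: the ratio is undefined
            )
            for factor in ("centre", "visit")
        },
        "seed": params.seed,
    }
    if params.n_sulci:
        rng = _term_rng(params.seed, "sulcus_means")
        means = np.abs(
            rng.normal(params.sulcus_mean, params.sulcus_mean_sd, params.n_sulci)
        ) + 1.0
        truth["sulcus_means"] = means.tolist()
        for s in range(params.n_sulci):
            label = f"SULC{s + 1:02d}"
            sp = TableSimParams(**{**params.__dict__, "n_sulci": None,
                                   "grand_mean": float(means[s])})
            vals = _cell_values(sp, seed_offset=f"|{label}")
            frames.append(
                _long_frame(vals, params, params.measure, label, params.algorithm)
            )
    else:
        vals = _cell_values(params)
        effects = _draw_effects(params)
        truth["effects"] = {t: e.ravel().tolist() for t, e in effects.items()}
        cov = params.covariate
        if cov is not None and cov.slope != 0.0:
            rng = _term_rng(params.seed, "covariate")
            base = cov.sd * rng.standard_normal(params.n_subjects)
            scan = cov.noise_sd * rng.standard_normal(vals.shape)
            cov_arr = cov.mean + base[:, None, None, None] + scan
            vals = vals + cov.slope * (cov_arr - cov.mean)
            frames.append(_long_frame(cov_arr, params, cov.name, "", ""))
            truth["covariate_values"] = cov_arr.ravel().tolist()
        sulcal = params.measure in ("sulcal_surface", "sulcal_depth")
        frames.insert(
            0,
            _long_frame(
                vals,
                params,
                params.measure,
                "SULC01" if sulcal else "",
                params.algorithm if sulcal else "",
            ),
        )
    df = pd.concat(frames, ignore_index=True)
    table = make_table(df, max_visits=params.n_visits)
    return table, truth


@dataclass
class PhantomParams:
    """Parameters of the nested-sphere tissue phantom."""

    shape: tuple[int, int, int] = (48, 48, 48)
    tissue_means: Mapping[str, float] = field(
        default_factory=lambda: {"wm": 150.0, "gm": 100.0, "csf": 40.0}
    )
    noise_sd: float = 5.0
    bias_amplitude: float = 0.0
    bias_frequency: float = 1.0
    radii: tuple[float, float, float] = (0.30, 0.55, 0.75)  # fractions of half-extent
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if any(m <= 0 for m in self.tissue_means.values()):
            raise ValueError("tissue means must be > 0")
        if not 0 < self.radii[0] < self.radii[1] < self.radii[2] <= 1.0:
            raise GeometryError("radii must be strictly increasing fractions in (0, 1]")


def _bias_field(shape, amplitude: float, frequency: float) -> np.ndarray:
    """Smooth separable multiplicative field 1 + amplitude * g(x), g in [-1, 1].

    Per-axis half-cosine profiles with an off-centre phase, so the field
    has a strong gradient across the middle of the volume (a centred
    profile would be nearly flat over central tissue regions and barely
    perturb them).
    """
    axes = [np.linspace(-0.5, 0.5, n) for n in shape]
    profiles = [np.cos(np.pi * frequency * (ax - 0.2)) for ax in axes]
    g = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
    lo, hi = g.min(), g.max()
    g = 2.0 * (g - lo) / (hi - lo) - 1.0 if hi > lo else np.zeros(shape)
    return 1.0 + amplitude * g


def simulate_phantom(params: PhantomParams):
    """Build the phantom volume, its tissue masks and the truth record.

    Voxel value = tissue_mean * bias_field(x) + Gaussian noise; outside
    the outermost (CSF) shell the volume is zero plus noise.  Masks are
    deterministic given the geometry.
    """
    from .image_metrics import ImageVolume, Mask

    shape = params.shape
    grids = np.meshgrid(
        *[np.linspace(-1.0, 1.0, n) for n in shape], indexing="ij"
    )
    r = np.sqrt(sum(g**2 for g in grids))
    r_wm, r_gm, r_csf = params.radii
    masks = {
        "wm": r <= r_wm,
        "gm": (r > r_wm) & (r <= r_gm),
        "csf": (r > r_gm) & (r <= r_csf),
    }
    for name, m in masks.items():
        if not m.any():
            raise GeometryError(f"tissue region {name!r} is empty at shape {shape}")

    bias = _bias_field(shape, params.bias_amplitude, params.bias_frequency)
    clean = np.zeros(shape)
    for name, m in masks.items():
        clean[m] = params.tissue_means[name]
    data = clean * bias
    if params.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(params.seed))
        data = data + params.noise_sd * rng.standard_normal(shape)

    truth = {
        "tissue_means": dict(params.tissue_means),
        "noise_sd": params.noise_sd,
        "bias_amplitude": params.bias_amplitude,
        "noiseless_contrast": params.tissue_means["wm"] / params.tissue_means["gm"],
        "voxel_counts": {k: int(m.sum()) for k, m in masks.items()},
    }
    volume = ImageVolume(data, voxel_size=params.voxel_size)
    return volume, {k: Mask(m) for k, m in masks.items()}, truth
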