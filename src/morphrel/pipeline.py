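"""End-to-end reliability report generation.

Given one morphometry table per study group (e.g. a 1.5 T and a 3 T
cohort, analysed fully independently), the pipeline produces for each
group:

* ``effects.csv`` — centre / visit / centre:visit p-values per measure
  from the fixed-effects ANCOVA ("< 0.001" below 0.001, else 3 dp);
* ``reliability_global.csv`` — between-visit and between-centre
  reliabilities (2 dp) with grades for the global measures;
* ``reliability_sulcal_<algorithm>.csv`` — across-sulcus mean
  reliabilities per algorithm, when sulcal measures are configured;
* ``components.json`` — raw and truncated variance components per
  measure, for transparency about truncation and covariate adjustment;

plus a ``manifest.json`` (config echo, package version, SHA-256 input
digests) so a report can be traced to its exact inputs.  All numeric
output is produced by the public module functions; the pipeline only
orchestrates and formats.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    GLOBAL_MEASURES,
    SULCAL_MEASURES,
    MorphometryTable,
    complete_view,
    load_morphometry_table,
)
from .errors import ConfigError, MorphrelError
from .linear_model import ModelSpec, f_test_effects, format_p
from .varcomp import (
    estimate_variance_components,
    reliability,
    sulcal_reliability_summary,
)

log = logging.getLogger("morphrel")

#: Default covariate assignment: brain (hemisphere) volume for segmented
#: volumes and GSI; brain volume plus GSI for sulcal measures.
DEFAULT_COVARIATES = {
    "gm_volume": ("hemisphere_volume",),
    "wm_volume": ("hemisphere_volume",),
    "csf_volume": ("hemisphere_volume",),
    "hemisphere_volume": (),
    "gsi": ("hemisphere_volume",),
    "sulcal_surface": ("hemisphere_volume", "gsi"),
    "sulcal_depth": ("hemisphere_volume", "gsi"),
}


@dataclass
class PipelineConfig:
    """Configuration of a full reliability analysis.

    ``inputs`` maps a group name (e.g. ``"1p5T"``) to its table path;
    groups are analysed independently.
    """

    inputs: Mapping[str, str]
    measures: Sequence[str] = tuple(GLOBAL_MEASURES)
    sulcal_measures: Sequence[str] = ()
    algorithms: Sequence[str] = ()
    covariates: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    ss_type: str = "adjusted"
    alpha: float = 0.05
    varcomp_method: str = "ems"
    residualize_covariates: bool = True
    output_dir: str = "morphrel_report"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        if "inputs" not in raw:
            raise ConfigError("config must define 'inputs' (group -> table path)")
        cov = dict(DEFAULT_COVARIATES)
        cov.update(raw.pop("covariates", {}))
        return cls(covariates=cov, **raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _check_config(config: PipelineConfig, table: MorphometryTable, group: str) -> None:
    available = set(table.measures())
    for m in list(config.measures) + list(config.sulcal_measures):
        if m not in available:
            raise ConfigError(
                f"group {group!r}: configured measure {m!r} absent from input"
            )
        for cov in config.covariates.get(m, ()):
            if cov not in available:
                raise ConfigError(
                    f"group {group!r}: covariate {cov!r} for measure {m!r} "
                    "absent from input"
                )


def _group_report(config: PipelineConfig, group: str, path: Path, outdir: Path) -> None:
    table = load_morphometry_table(path)
    _check_config(config, table, group)

    effect_rows, rel_rows, comp_json = [], [], {}
    for measure in config.measures:
        covs = tuple(config.covariates.get(measure, ()))
        frame, summary = _complete_frame(table, measure, covs)
        spec = ModelSpec(covariates=covs, ss_type=config.ss_type, alpha=config.alpha)
        effects = f_test_effects(frame, spec)
        effect_rows.append(
            {
                "measure": measure,
                "centre": format_p(effects.loc["centre", "p_value"]),
                "visit": format_p(effects.loc["visit", "p_value"]),
                "centre_x_visit": format_p(effects.loc["centre:visit", "p_value"]),
            }
        )
        comp = estimate_variance_components(
            frame,
            method=config.varcomp_method,
            covariates=covs if config.residualize_covariates else (),
        )
        rc, rv = reliability(comp, "centre"), reliability(comp, "visit")
        for t, v in comp.raw.items():
            if v < 0:
                log.warning(
                    "%s/%s: negative raw component %s = %.4g truncated to 0",
                    group, measure, t, v,
                )
        rel_rows.append(
            {
                "measure": measure,
                "between_visit": f"{rv.value:.2f}",
                "visit_grade": rv.grade,
                "between_centre": f"{rc.value:.2f}",
                "centre_grade": rc.grade,
            }
        )
        comp_json[measure] = {
            "raw": comp.raw,
            "truncated": comp.components,
            "residualized_covariates": list(comp.residualized),
            "excluded_subjects": list(summary.excluded_subjects),
        }

    pd.DataFrame(effect_rows).to_csv(outdir / "effects.csv", index=False)
    pd.DataFrame(rel_rows).to_csv(outdir / "reliability_global.csv", index=False)
    with open(outdir / "components.json", "w") as fh:
        json.dump(comp_json, fh, indent=2, sort_keys=True)

    for algorithm in config.algorithms:
        rows = []
        for measure in config.sulcal_measures:
            covs = tuple(config.covariates.get(measure, ()))
            res = sulcal_reliability_summary(
                table, measure, algorithm,
                covariates=covs if config.residualize_covariates else (),
                method=config.varcomp_method,
            )
            for hemi, sulc, reason in res.skipped:
                log.warning("%s/%s/%s: skipped sulcus %s/%s (%s)",
                            group, measure, algorithm, hemi, sulc, reason)
            rows.append(
                {
                    "measure": measure,
                    "algorithm": algorithm,
                    "n_sulci": len(res.per_sulcus),
                    "mean_between_visit": f"{res.mean_visit:.2f}",
                    "mean_between_centre": f"{res.mean_centre:.2f}",
                }
            )
        if rows:
            pd.DataFrame(rows).to_csv(
                outdir / f"reliability_sulcal_{algorithm}.csv", index=False
            )


def _complete_frame(table: MorphometryTable, measure: str, covariates):
    df, summary = complete_view(table, measure)
    keys = ["subject", "centre", "visit", "hemisphere"]
    for cov in covariates:
        cdf = table.view(cov)[keys + ["value"]].rename(columns={"value": cov})
        df = df.merge(cdf, on=keys, how="inner")
    return df.reset_index(drop=True), summary


def run_reliability_report(config: PipelineConfig) -> Path:
    """Run the full analysis and write the report bundle.

    Returns the output directory.  On a stage failure, partial outputs
    are moved to ``<output_dir>/quarantine`` and the error re-raised with
    the failing group named.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "morphrel",
        "version": __version__,
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else list(v) if isinstance(v, (tuple, list)) else v)
            for k, v in config.__dict__.items()
        },
        "inputs": {},
    }
    try:
        for group, path in config.inputs.items():
            path = Path(path)
            if not path.exists():
                raise ConfigError(f"input for group {group!r} not found: {path}")
            manifest["inputs"][group] = {
                "path": str(path),
                "sha256": _sha256(path),
            }
            gdir = outdir / group
            gdir.mkdir(parents=True, exist_ok=True)
            log.info("analysing group %s", group)
            _group_report(config, group, path, gdir)
    except MorphrelError:
        quarantine = outdir / "quarantine"
        if quarantine.exists():
            shutil.rmtree(quarantine)
        quarantine.mkdir()
        for item in list(outdir.iterdir()):
            if item.name != "quarantine":
                item.rename(quarantine / item.name)
        raise
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
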