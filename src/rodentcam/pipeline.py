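"""End-to-end pipeline: triggers -> events -> occupancy -> habitat -> GLMs.

``run_pipeline`` executes the full analysis from a config describing the
input tables and conventions, writing every summary surface as CSV/JSON
plus a run manifest recording versions, seed and the conventions in force.
The stages are the library functions; each stage failure is re-raised as a
``PipelineError`` naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rodentcam import events as ev
from rodentcam import habitat as hab
from rodentcam import model_selection as msel
from rodentcam import occupancy as occ

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    """Inputs and conventions for a full pipeline run."""

    triggers: str
    deployments: str
    pcq: str
    poles: str
    covers: str
    out_dir: str = "rodentcam_run"
    #: analysis species -> candidate-set key; other species appear only in
    #: the occurrence table
    analysis_species: Mapping[str, str] = field(
        default_factory=lambda: {
            "black rat": "black_rat",
            "house mouse": "house_mouse",
        }
    )
    species_aliases: Mapping[str, str] = field(default_factory=dict)
    bin_anchor: str = "clock"
    nights_mode: str = "fractional"
    criterion: str = "aicc"
    averaging_threshold: float = 0.9
    confidence_level: float = 0.95
    standardize_covariates: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError("confidence_level must be in (0, 1)")
        for name in ("triggers", "deployments", "pcq", "poles", "covers"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")


def occurrence_percent(n_present: int, n_total: int) -> float:
    """Percent of sites occupied, rounded half-up to the nearest integer
    (values below 0.5% keep one decimal so rare species do not round to 0)."""
    if n_total <= 0:
        raise ValueError("total site count must be positive")
    pct = 100.0 * n_present / n_total
    if 0.0 < pct < 0.5:
        return round(pct, 1)
    return float(np.floor(pct + 0.5))


def species_occurrence_table(
    events_table: pd.DataFrame, deployments: pd.DataFrame
) -> pd.DataFrame:
    """Per-species site occurrence and event totals.

    Columns: species, sites_present, pct_sites (integer-rounded),
    proportion (raw), n_events; sorted by event count descending.
    """
    n_total = deployments["site_id"].nunique()
    if n_total == 0:
        raise ValueError("deployment log lists no sites")
    grp = events_table.groupby("species")
    out = pd.DataFrame(
        {
            "sites_present": grp["site_id"].nunique(),
            "n_events": grp.size(),
        }
    ).reset_index()
    out["proportion"] = out["sites_present"] / n_total
    out["pct_sites"] = out["sites_present"].map(
        lambda s: occurrence_percent(int(s), n_total)
    )
    out = out.sort_values("n_events", ascending=False, kind="mergesort")
    return out[
        ["species", "sites_present", "pct_sites", "proportion", "n_events"]
    ].reset_index(drop=True)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, e) from e

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle to
    ``config.out_dir``.

    Returns a dict of the in-memory result tables.  Deterministic given
    identical inputs and config.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    @_stage("events")
    def stage_events():
        triggers = ev.load_trigger_records(
            config.triggers, aliases=config.species_aliases
        )
        deployments = ev.load_deployments(config.deployments)
        with_nights = ev.assign_survey_nights(
            triggers, deployments, bin_anchor=config.bin_anchor
        )
        events_table = ev.discretize_events(with_nights)
        activity = ev.activity_index(
            events_table, deployments, nights_mode=config.nights_mode
        )
        return triggers, deployments, events_table, activity

    triggers, deployments, events_table, activity = stage_events()
    events_table.to_csv(out_dir / "events.csv", index=False)
    activity.to_csv(out_dir / "activity.csv", index=False)
    occurrence = species_occurrence_table(events_table, deployments)
    occurrence.to_csv(out_dir / "species_occurrence.csv", index=False)
    results.update(
        events=events_table, activity=activity, occurrence=occurrence
    )

    @_stage("occupancy")
    def stage_occupancy(species: str):
        hist = ev.detection_histories(events_table, deployments, species)
        fits = [
            occ.fit_occupancy(hist, occ.CONSTANT, seed=config.seed),
            occ.fit_occupancy(hist, occ.BY_NIGHT, seed=config.seed),
        ]
        table = occ.compare_detection_models(fits, criterion="aic")
        best = next(f for f in fits if f.name == table["Model"].iloc[0])
        curve = occ.cumulative_detection(
            best.p_full(),
            best.p_ci[:, 0] if best.p_ci.ndim == 2 and not best.boundary else None,
            best.p_ci[:, 1] if best.p_ci.ndim == 2 and not best.boundary else None,
        )
        ntc = occ.nights_to_confidence(
            best.p_full(), level=config.confidence_level
        )
        return hist, fits, table, best, curve, ntc

    results["occupancy"] = {}
    for species in config.analysis_species:
        hist, fits, table, best, curve, ntc = stage_occupancy(species)
        tag = species.replace(" ", "_")
        hist.to_csv(out_dir / f"histories_{tag}.csv")
        table.to_csv(out_dir / f"detection_models_{tag}.csv", index=False)
        curve.to_csv(out_dir / f"detection_curve_{tag}.csv", index=False)
        with open(out_dir / f"occupancy_{tag}.json", "w") as fh:
            json.dump(
                {f.name: f.to_dict() for f in fits}
                | {
                    "nights_to_confidence": ntc.nights,
                    "confidence_level": ntc.level,
                    "achieved": ntc.achieved,
                },
                fh, indent=2,
            )
        results["occupancy"][species] = {
            "histories": hist, "fits": fits, "table": table,
            "best": best, "curve": curve, "nights_to_confidence": ntc,
        }

    @_stage("habitat")
    def stage_habitat():
        pcq = pd.read_csv(config.pcq, dtype={"site_id": str})
        poles = pd.read_csv(config.poles, dtype={"site_id": str})
        covers = pd.read_csv(config.covers, dtype={"site_id": str})
        cov = hab.assemble_covariates(
            pcq, poles, covers, standardize=config.standardize_covariates
        )
        max_r, flagged = hab.correlation_screen(cov)
        return cov, max_r, flagged

    covariates, max_r, flagged = stage_habitat()
    covariates.to_csv(out_dir / "covariates.csv", index=False)
    flagged.to_csv(out_dir / "collinear_pairs.csv", index=False)
    results.update(covariates=covariates, max_abs_correlation=max_r)

    @_stage("model_selection")
    def stage_glm(species: str, set_key: str):
        act = activity[activity["species"] == species].set_index("site_id")
        cov = covariates.set_index("site_id").loc[act.index].reset_index()
        # black-rat activity as a covariate for the mouse candidate set
        rat = activity[activity["species"] == "black rat"].set_index("site_id")
        cov = cov.assign(RR=rat["index"].reindex(cov["site_id"]).to_numpy())
        response = act["events_total"].to_numpy()
        offset = np.log(act["nights_observed"].to_numpy())
        fits = [
            msel.fit_nb_glm(spec, response, cov, offset=offset)
            for spec in msel.candidate_sets(set_key)
        ]
        table = msel.ic_table(fits, n=len(response), criterion=config.criterion)
        averaged = None
        if msel.selection_uncertain(table, config.averaging_threshold):
            averaged = msel.model_average(table, fits)
        return fits, table, averaged

    results["glm"] = {}
    for species, set_key in config.analysis_species.items():
        fits, table, averaged = stage_glm(species, set_key)
        tag = species.replace(" ", "_")
        table.to_csv(out_dir / f"activity_models_{tag}.csv", index=False)
        if averaged is not None:
            averaged.to_csv(
                out_dir / f"averaged_coefficients_{tag}.csv", index=False
            )
        results["glm"][species] = {
            "fits": fits, "table": table, "averaged": averaged,
        }

    manifest = {
        "versions": _versions(),
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in asdict(config).items()
        },
        "conventions": {
            "survey_night": "noon-to-noon local time",
            "bin_anchor": config.bin_anchor,
            "nights_mode": config.nights_mode,
            "pcq_estimator": covariates.attrs.get("pcq_method", "cottam"),
            "pcq_empty_quadrant_rule": covariates.attrs.get(
                "pcq_empty_quadrant_rule", ""
            ),
            "criterion": config.criterion,
            "averaging": "full (shrinkage)",
            "averaging_threshold": config.averaging_threshold,
        },
        "n_excluded_triggers": triggers.attrs.get("n_excluded", 0),
        "max_abs_covariate_correlation": max_r,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import scipy
    import statsmodels

    import rodentcam

    return {
        "rodentcam": rodentcam.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
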