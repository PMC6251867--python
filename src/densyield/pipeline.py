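"""End-to-end analysis pipeline and run manifest.

``run_pipeline`` ties the stages together: (optionally) simulate a trial,
normalise raw yields to the reference density, fit the candidate catalog
per variety, screen and select the plausible model, rank varieties by
density resistance, and (optionally) verify against a standard plot and
summarise traits.  Every report is written as delimited text next to a
JSON manifest recording inputs, seed, package versions and the screening
decisions, so that two runs with the same config and seed produce
identical bundles.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import POPULATION_FAMILIES, SINGLE_PLANT_FAMILIES
from .errors import ValidationError
from .fitting import FitOptions, FitResult, fit_catalog, fit_report
from .io import read_trial_table, write_table
from .plausibility import (
    SelectionResult,
    screen_population,
    screen_single_plant,
    select_model,
)
from .resistance import (
    normalize,
    resistance_ranking,
    resistance_report_frame,
    verify_against_standard,
)
from .synthetic import TRAIT_CORR_COLUMNS, default_truth, simulate_gradient_trial
from .traits import double_ear_profile, pearson_matrix

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_KNOWN_MODEL_SETS = {"population": POPULATION_FAMILIES,
                     "single_plant": SINGLE_PLANT_FAMILIES}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration.

    ``input`` may be a CSV path or ``None`` to simulate a default-truth
    gradient trial.  ``model_set`` is ``"population"``, ``"single_plant"``
    or an explicit list of family ids.  All randomness flows from ``seed``.
    """

    input: str | None = None
    role: str = "population"
    reference_density: str | float = "min"
    model_set: str | Sequence[str] = "population"
    seed: int = 0
    output_dir: str = "densyield_out"
    verification_input: str | None = None
    trait_input: str | None = None
    n_starts: int = 16
    use_means: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        allowed = set(cls.__dataclass_fields__)
        unknown = set(raw) - allowed
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.role not in ("population", "single_plant"):
            raise ValidationError(
                f"config field 'role' must be population|single_plant, "
                f"got {self.role!r}"
            )
        if not isinstance(self.seed, int):
            raise ValidationError("config field 'seed' must be an integer")
        if isinstance(self.model_set, str):
            if self.model_set not in _KNOWN_MODEL_SETS:
                raise ValidationError(
                    f"config field 'model_set' must be one of "
                    f"{sorted(_KNOWN_MODEL_SETS)} or a list of family ids"
                )
        for key in ("input", "verification_input", "trait_input"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise ValidationError(f"config field {key!r}: "
                                      f"path {val} does not exist")
        if isinstance(self.reference_density, str) and \
                self.reference_density != "min" and \
                not self.reference_density.startswith("fixed:"):
            raise ValidationError(
                "config field 'reference_density' must be 'min', "
                "'fixed:<density>' or a number"
            )

    def model_ids(self) -> tuple[str, ...]:
        if isinstance(self.model_set, str):
            return _KNOWN_MODEL_SETS[self.model_set]
        return tuple(self.model_set)


@dataclass
class PipelineResult:
    """Everything one pipeline run produced."""

    manifest: dict[str, Any]
    fits: dict[str, list[FitResult]]
    selections: dict[str, SelectionResult]
    resistance: pd.DataFrame | None
    verification: Any | None
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute simulate → normalize → fit → screen/select → resist
    (→ verify → traits) and write the report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package": "densyield",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in config.__dict__.items()},
        "stages": [],
        "decisions": [],
    }

    trait_table: pd.DataFrame | None = None
    if config.input is None:
        truth = default_truth(seed=config.seed)
        trial, traits_df = simulate_gradient_trial(truth, seed=config.seed)
        trial = trial[trial["role"] == config.role].reset_index(drop=True)
        trait_table = traits_df
        write_table(trial, out / "simulated_trial.csv")
        write_table(traits_df, out / "simulated_traits.csv")
        manifest["stages"].append({"stage": "simulate",
                                   "records": int(len(trial))})
    else:
        trial = read_trial_table(config.input, role=config.role
                                 if "role" in pd.read_csv(
                                     config.input, nrows=0).columns else None)
        manifest["stages"].append({"stage": "load", "path": config.input,
                                   "records": int(len(trial))})

    normalized = normalize(trial, reference=config.reference_density)
    manifest["stages"].append({"stage": "normalize",
                               "reference": str(config.reference_density)})

    screen = (screen_population if config.role == "population"
              else screen_single_plant)
    opts = FitOptions(n_starts=config.n_starts, seed=config.seed,
                      use_means=config.use_means)
    fits: dict[str, list[FitResult]] = {}
    selections: dict[str, SelectionResult] = {}
    report_frames = []
    for variety, group in normalized.groupby("variety", sort=False):
        ranked = fit_catalog(group, config.model_ids(), opts,
                             label=str(variety))
        fits[str(variety)] = ranked
        sel = select_model(ranked, screen)
        selections[str(variety)] = sel
        frame = fit_report(ranked)
        rejected_map = {rf.model_id: v for rf, v in sel.rejected}
        def _verdict_str(f: FitResult) -> str:
            if sel.selected is not None and f.model_id == sel.selected.model_id:
                return "yes"
            if f.model_id in rejected_map:
                return "no: " + "; ".join(rejected_map[f.model_id].reasons)
            return "not screened"
        frame["plausible"] = [_verdict_str(f) for f in ranked]
        report_frames.append(frame)
        manifest["decisions"].append({
            "variety": str(variety),
            "selected": sel.selected.model_id if sel.selected else None,
            "rejected_above": [
                {"model": rf.model_id, "reasons": list(v.reasons)}
                for rf, v in sel.rejected
            ],
        })
    write_table(pd.concat(report_frames, ignore_index=True),
                out / "fit_report.csv")
    manifest["stages"].append({
        "stage": "fit+select",
        "families_per_variety": len(config.model_ids()),
        "varieties": sorted(fits),
    })

    resistance_frame = None
    if config.role == "population":
        hoerl_fits = [s.selected for s in selections.values()
                      if s.selected is not None
                      and s.selected.model_id == "hoerl"]
        if hoerl_fits:
            reports = resistance_ranking(hoerl_fits)
            resistance_frame = resistance_report_frame(reports)
            write_table(resistance_frame, out / "resistance.csv")
            manifest["stages"].append({
                "stage": "resist",
                "order": [r.label for r in reports],
            })

    verification = None
    if config.verification_input is not None:
        std = read_trial_table(config.verification_input)
        any_sel = next((s.selected for s in selections.values()
                        if s.selected is not None), None)
        if any_sel is not None:
            verification = verify_against_standard(any_sel, std)
            write_table(pd.DataFrame(
                [{"density": d, "deviation_pct": p}
                 for d, p in verification.deviations]
            ).assign(slope=verification.slope,
                     intercept=verification.intercept,
                     accuracy=verification.accuracy),
                out / "verification.csv")
            manifest["stages"].append({
                "stage": "verify",
                "accuracy": verification.accuracy,
            })

    if config.trait_input is not None:
        trait_table = pd.read_csv(config.trait_input)
    if trait_table is not None:
        cols = [c for c in TRAIT_CORR_COLUMNS if c in trait_table.columns]
        if len(cols) >= 2:
            r, stars = pearson_matrix(trait_table, cols)
            write_table(r.round(4).reset_index(names="trait"),
                        out / "trait_correlations.csv")
            write_table(stars.reset_index(names="trait"),
                        out / "trait_significance.csv")
        if "double_ear" in trait_table.columns:
            write_table(double_ear_profile(trait_table).round(2)
                        .reset_index(),
                        out / "double_ear_rates.csv")
        manifest["stages"].append({"stage": "traits",
                                   "records": int(len(trait_table))})

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(manifest=manifest, fits=fits,
                          selections=selections,
                          resistance=resistance_frame,
                          verification=verification, output_dir=out)
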