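"""End-to-end orchestration: profiles -> fits -> traits -> ANN -> meta.

``run_pipeline`` runs every stage for each strain profile and pools the
fitted monomolecular parameters across strains, returning a
:class:`ReportBundle` of plain DataFrames plus a manifest (package version,
seed, config hash) so that every exported cell can be re-derived by calling
the owning module with the logged inputs.  ``export_tables`` writes the
bundle as CSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .ann import MLPGrowthRegressor
from .bioenergetics import DEFAULT_ME_TO_NE_FACTOR, EfficiencyMode, derive_traits
from .criteria import criteria
from .datasets import meta_input_from_frame
from .meta import MetaResult, dl_pool, forest_table, single_study_result
from .monomolecular import MonomolecularRegressor, N_PARAMS
from .profiles import (
    ScalingMode,
    StrainProfile,
    observations_to_arrays,
    scale_observations,
)

logger = logging.getLogger("pulletgrowth")

META_PARAMETERS = ("a", "b", "c")


@dataclass(frozen=True)
class PipelineConfig:
    scaling_mode: ScalingMode = "interval_mean"
    efficiency_mode: EfficiencyMode = "chord"
    me_to_ne_factor: float = DEFAULT_ME_TO_NE_FACTOR
    validation_fraction: float = 0.33
    learning_rate: float = 0.05
    max_epochs: int = 20000
    patience: int = 200
    seed: int = 0
    float_digits: int = 4

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    scaled: pd.DataFrame
    fits: pd.DataFrame
    traits: pd.DataFrame
    criteria: pd.DataFrame
    meta: pd.DataFrame
    forest: dict[str, pd.DataFrame]
    meta_results: dict[str, MetaResult]
    manifest: dict


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage and strain for the log."""

    def __init__(self, stage: str, strain: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for strain {strain!r}: {cause}")
        self.stage = stage
        self.strain = strain
        self.cause = cause


def run_pipeline(
    profiles: Sequence[StrainProfile],
    config: PipelineConfig = PipelineConfig(),
) -> ReportBundle:
    """Full per-strain analysis plus cross-strain meta-analysis."""
    if not profiles:
        raise ValueError("need at least one strain profile")
    scaled_rows, fit_rows, trait_rows, crit_rows = [], [], [], []

    for idx, profile in enumerate(profiles):
        strain = profile.strain_name
        stage = "scale"
        try:
            obs = scale_observations(profile, mode=config.scaling_mode)
            x, y = observations_to_arrays(obs)
            for o in obs:
                scaled_rows.append(
                    {"strain": strain, "week": o.week, "x": o.x, "y": o.y,
                     "bw_mean_g": o.bw_mean_g, "days": o.days}
                )

            stage = "fit"
            reg = MonomolecularRegressor().fit(x, y)
            params = reg.params_
            mono_crit = criteria(y, reg.predict(x), n_params=N_PARAMS)
            fit_rows.append(
                {"strain": strain, "a": params.a, "b": params.b, "c": params.c,
                 "se_a": params.se_a, "se_b": params.se_b, "se_c": params.se_c,
                 "rss": params.rss, "n_obs": params.n_obs,
                 "r2_adj": mono_crit.r2_adj}
            )

            stage = "derive"
            traits = derive_traits(
                params, mode=config.efficiency_mode,
                me_to_ne_factor=config.me_to_ne_factor, with_se=True,
            )
            trait_rows.append(
                {"strain": strain,
                 "MEm_kcal_per_kg": traits.me_maintenance,
                 "NEg_kcal_per_g": traits.ne_growth,
                 **{f"kg{m}": traits.kg_at[m] for m in (1, 2, 3, 4)},
                 "mode": traits.mode, "me_to_ne_factor": traits.me_to_ne_factor}
            )
            crit_rows.append(
                {"strain": strain, "model": "monomolecular", "split": "all",
                 **mono_crit.as_dict()}
            )

            stage = "ann"
            ann = MLPGrowthRegressor(
                validation_fraction=config.validation_fraction,
                learning_rate=config.learning_rate,
                max_epochs=config.max_epochs,
                patience=config.patience,
                random_state=config.seed + idx,
            ).fit(x, y)
            for split, crit in (
                ("training", ann.training_criteria_),
                ("validation", ann.validation_criteria_),
            ):
                crit_rows.append(
                    {"strain": strain, "model": "ann", "split": split,
                     **crit.as_dict()}
                )
        except Exception as exc:  # noqa: BLE001 - rethrown with stage context
            logger.error("stage %s failed for strain %s: %s", stage, strain, exc)
            raise StageError(stage, strain, exc) from exc

    fits = pd.DataFrame(fit_rows)
    meta_df, forest, meta_results = meta_stage(fits)

    manifest = {
        "package_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "n_strains": len(profiles),
    }
    return ReportBundle(
        scaled=pd.DataFrame(scaled_rows),
        fits=fits,
        traits=pd.DataFrame(trait_rows),
        criteria=pd.DataFrame(crit_rows),
        meta=meta_df,
        forest=forest,
        meta_results=meta_results,
        manifest=manifest,
    )


def meta_stage(
    fits: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, MetaResult]]:
    """Pool each monomolecular parameter across the fitted strains.

    Accepts either a per-strain fits frame (columns strain, a..se_c) or a
    long frame with columns parameter,strain,estimate,se.
    """
    if "parameter" in fits.columns:
        long = fits
    else:
        long = pd.concat(
            [
                pd.DataFrame(
                    {"parameter": p, "strain": fits["strain"],
                     "estimate": fits[p], "se": fits[f"se_{p}"]}
                )
                for p in META_PARAMETERS
            ],
            ignore_index=True,
        )
    meta_rows, forest, results = [], {}, {}
    for p in META_PARAMETERS:
        meta_input = meta_input_from_frame(long, p)
        if meta_input.k == 0:
            continue
        res = dl_pool(meta_input) if meta_input.k >= 2 else single_study_result(meta_input)
        results[p] = res
        forest[p] = forest_table(res, meta_input)
        meta_rows.append(
            {"parameter": p, "point_estimate": res.pooled,
             "standard_error": res.se_pooled, "ci_low": res.ci_low,
             "ci_high": res.ci_high, "p_value": res.p_value, "q": res.q,
             "q_p_value": res.q_p_value, "i_squared": res.i_squared,
             "tau_squared": res.tau_squared,
             "heterogeneity": res.heterogeneity_label}
        )
    return pd.DataFrame(meta_rows), forest, results


TABLE_FILES = {
    "scaled": "scaled.csv",
    "fits": "fits.csv",
    "traits": "traits.csv",
    "criteria": "criteria.csv",
    "meta": "meta.csv",
}


def export_tables(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the bundle's tables, forest CSVs and manifest; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in TABLE_FILES.items():
        path = outdir / fname
        getattr(bundle, attr).to_csv(path, index=False)
        written.append(path)
    for p, table in bundle.forest.items():
        path = outdir / f"forest_{p}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(bundle.manifest, indent=1, sort_keys=True))
    written.append(manifest_path)
    return written
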