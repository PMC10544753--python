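"""End-to-end analysis pipeline.

One call runs: load or simulate a cohort → apply eligibility exclusions →
derive features and score every subject → estimate crude, weighted, and
age-standardized NASH prevalence under each of the five classification
schemes (three single scores, all-three-positive, at-least-one-positive) →
compose published net sensitivities/specificities → fit survey-weighted
multinomial models of the three-class outcome on the configured
covariates → write everything as CSV/TSV/JSON plus a run manifest.

Identical configuration and seed give byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import read_cohort
from .eligibility import DEFAULT_REQUIRED_FIELDS, apply_exclusions
from .scoring import ScoreConfig, SCHEMES, classify_cohort, derive_features
from .screening import PUBLISHED_PERFORMANCE, net_parallel, net_serial, performance_table
from .survey import (
    STD_US_1990,
    STD_US_2000,
    SurveyDesign,
    direct_standardize,
    odds_ratio_table,
    weighted_prevalence,
)
from .synth import SyntheticCohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

STANDARDS = {"us2000": STD_US_2000, "us1990": STD_US_1990}

#: Reference levels mirroring the published regression's reference groups.
DEFAULT_REFERENCES = {
    "race_ethnicity": "white",
    "sex": "male",
    "urbanization": "urban",
    "education": "hs",
    "smoking": "never",
    "alcohol_status": "never",
    "activity_level": "meets_guidelines",
    "whr_risk": "healthy",
    "c_peptide_cat": "normal",
    "chol_cat": "normal",
    "crp_cat": "normal",
    "hei_cat": "good",
}

DEFAULT_COVARIATES = [
    "race_ethnicity",
    "sex",
    "whr_risk",
    "smoking",
    "c_peptide_cat",
    "chol_cat",
    "crp_cat",
]


class RunConfig(BaseModel):
    """Declarative configuration of one pipeline run."""

    input_path: str | None = None
    synthetic: SyntheticCohortConfig | None = None
    required_fields: list[str] = Field(default_factory=lambda: list(DEFAULT_REQUIRED_FIELDS))
    standard_population: str = "us2000"
    covariates: list[str] = Field(default_factory=lambda: list(DEFAULT_COVARIATES))
    run_regression: bool = True
    out_dir: str = "nashscreen_out"
    seed: int = 0

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_path or synthetic must be set")
        if self.standard_population not in STANDARDS:
            raise ValueError(f"unknown standard population {self.standard_population!r}")
        return self


def _prevalence_rows(panel, features, design, std):
    rows = []
    age_groups = sorted(std.proportions)
    for scheme in SCHEMES:
        flag = panel[f"{scheme}_nash"].to_numpy(dtype=bool)
        crude = float(flag.mean())
        wp = weighted_prevalence(flag, design)
        by_age = {}
        for g in age_groups:
            in_g = (features["age_group"] == g).to_numpy()
            if in_g.sum() == 0:
                by_age[g] = 0.0
                continue
            w = design.weight[in_g]
            by_age[g] = float(np.sum(w * flag[in_g]) / w.sum())
        std_prev = direct_standardize(by_age, std)
        rows.append(
            {
                "scheme": scheme,
                "n_nash": int(flag.sum()),
                "crude": crude,
                "weighted": wp.estimate,
                "weighted_se": wp.se,
                "weighted_ci_low": wp.ci_low,
                "weighted_ci_high": wp.ci_high,
                "age_standardized": std_prev,
            }
        )
    return pd.DataFrame(rows)


def _check_scheme_ordering(prev: pd.DataFrame) -> None:
    p = prev.set_index("scheme")["weighted"]
    singles = [p["hair"], p["gholam"], p["lfs"]]
    if not (p["all3"] <= min(singles) + 1e-12 and max(singles) <= p["any1"] + 1e-12):
        raise AssertionError(
            "scheme ordering violated: expected all3 <= each single method <= any1"
        )


def run_pipeline(config: RunConfig, score_config: ScoreConfig | None = None) -> dict:
    """Execute the full analysis; returns the result bundle.

    The bundle maps stage names to in-memory objects (DataFrames, tallies,
    dicts); everything is also written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    score_config = score_config or ScoreConfig()

    if config.synthetic is not None:
        synth_cfg = config.synthetic.model_copy(update={"seed": config.seed})
        cohort, latent = generate_cohort(synth_cfg)
    else:
        cohort = read_cohort(config.input_path)
        latent = None

    analysis, tally = apply_exclusions(cohort, tuple(config.required_fields))
    (out / "exclusion_tally.json").write_text(tally.to_json())
    (out / "flow_report.txt").write_text(tally.flow_report() + "\n")

    features = derive_features(analysis, score_config)
    panel = classify_cohort(analysis, features, score_config)
    panel_out = pd.concat([analysis[["subject_id"]], panel], axis=1)
    panel_out.to_csv(out / "score_panel.csv", index=False)

    design = SurveyDesign.from_cohort(analysis)
    std = STANDARDS[config.standard_population]
    prev = _prevalence_rows(panel, features, design, std)
    _check_scheme_ordering(prev)
    prev.to_csv(out / "prevalence.tsv", sep="\t", index=False)

    serial = net_serial(
        [PUBLISHED_PERFORMANCE["hair"], PUBLISHED_PERFORMANCE["gholam"],
         PUBLISHED_PERFORMANCE["lfs_finnish"]]
    )
    parallel = net_parallel(
        [PUBLISHED_PERFORMANCE["hair"], PUBLISHED_PERFORMANCE["gholam"],
         PUBLISHED_PERFORMANCE["lfs_finnish"]]
    )
    perf_tsv = performance_table(
        list(PUBLISHED_PERFORMANCE.values()) + [serial, parallel]
    )
    (out / "net_performance.tsv").write_text(perf_tsv)

    regressions = {}
    if config.run_regression:
        reg_data = pd.concat([analysis.reset_index(drop=True),
                              features.reset_index(drop=True)], axis=1)
        for scheme in SCHEMES:
            reg_data[f"label_{scheme}"] = panel[f"label_{scheme}"].to_numpy()
            table = odds_ratio_table(
                reg_data, f"label_{scheme}", config.covariates,
                SurveyDesign.from_cohort(reg_data), DEFAULT_REFERENCES,
            )
            table.to_csv(out / f"regression_{scheme}.tsv", sep="\t", index=False)
            regressions[scheme] = table

    cfg_json = config.model_dump_json()
    manifest = {
        "package": "nashscreen",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_input": tally.n_input,
        "n_analysis": tally.n_retained,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "cohort": cohort,
        "latent": latent,
        "analysis": analysis,
        "tally": tally,
        "features": features,
        "panel": panel,
        "prevalence": prev,
        "net_serial": serial,
        "net_parallel": parallel,
        "regressions": regressions,
        "manifest": manifest,
    }
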