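"""The hemophilia A prophylaxis study configuration.

Bundles the concrete study objects: the four treatment attributes and their
levels, the published mixed-logit coefficient table used as the generative
truth for simulation and as input to the benefit-risk statistics, the
respondent covariate mix, and the six standard attribute improvements whose
maximum acceptable risk is reported.
"""

from __future__ import annotations

import numpy as np

from .attributes import ASC_COLUMN, Attribute, AttributeSet
from .design import Design, augment_tasks, block_design, generate_design
from .simulate import (
    ChoiceDataset,
    PreferenceParameters,
    generate_covariates,
    inject_contamination,
    sample_individual_betas,
    simulate_choices,
)
from .tradeoff import AttributeChange

__all__ = [
    "hemophilia_attributes",
    "study_parameters",
    "study_covariate_proportions",
    "standard_changes",
    "build_study_design",
    "simulate_study",
    "RISK_ATTRIBUTE",
]

#: Name of the risk attribute used as the MAR denominator.
RISK_ATTRIBUTE = "inhibitor_risk"


def hemophilia_attributes() -> AttributeSet:
    """The four prophylaxis attributes, three levels each.

    Annual bleeding times, dosing frequency and dosing mode are benefits;
    the risk of developing inhibitors (neutralizing anti-FVIII antibodies)
    is the risk attribute, coded continuously in percentage points.
    """
    return AttributeSet(
        (
            Attribute(
                name="annual_bleeds",
                coding="categorical",
                levels=(0, 6, 12),
                reference=12,
                unit="times/year",
                direction_hint="lower_better",
            ),
            Attribute(
                name=RISK_ATTRIBUTE,
                coding="continuous",
                levels=(0.0, 2.0, 4.0),
                unit="% points",
                direction_hint="lower_better",
            ),
            Attribute(
                name="dosing_freq",
                coding="categorical",
                levels=(1, 2, 3),
                reference=3,
                unit="times/week",
                direction_hint="lower_better",
            ),
            Attribute(
                name="dosing_mode",
                coding="categorical",
                # declared worst -> best for the dominance diagnostics
                levels=("drip", "push", "subcutaneous"),
                reference="drip",
                direction_hint="higher_better",
            ),
        )
    )


def study_parameters() -> PreferenceParameters:
    """Published population preference parameters (means and heterogeneity SDs).

    Utility weights are relative to the reference levels (12 bleeds/year,
    3 doses/week, intravenous drip); the inhibitor-risk weight is per
    percentage point; ASC is the status-quo constant.
    """
    means = {
        ASC_COLUMN: 0.72,
        "annual_bleeds[0]": 3.64,
        "annual_bleeds[6]": 1.80,
        "inhibitor_risk": -0.79,
        "dosing_freq[1]": 1.58,
        "dosing_freq[2]": 1.20,
        "dosing_mode[push]": 0.74,
        "dosing_mode[subcutaneous]": 1.35,
    }
    sds = {
        ASC_COLUMN: 3.80,
        "annual_bleeds[0]": 1.49,
        "annual_bleeds[6]": 0.00,
        "inhibitor_risk": 0.54,
        "dosing_freq[1]": 0.01,
        "dosing_freq[2]": 0.05,
        "dosing_mode[push]": 0.07,
        "dosing_mode[subcutaneous]": 1.95,
    }
    return PreferenceParameters(mean=means, sd=sds)


def study_covariate_proportions() -> dict[str, dict[str, float]]:
    """Covariate category proportions among the analysed respondents."""
    return {
        "education": {"middle_school_or_below": 0.471, "high_school_or_above": 0.529},
        "location": {"urban": 0.353, "rural": 0.647},
        "treatment_type": {
            "on_demand": 0.549,
            "prophylaxis": 0.402,
            "nonstandard_prophylaxis": 0.049,
        },
    }


def build_study_design(seed: int | None = 0, n_restarts: int = 5,
                       n_tasks: int = 18, n_blocks: int = 2,
                       practice_task: bool = False) -> Design:
    """The study's instrument: a D-efficient two-alternative design of
    ``n_tasks`` tasks split into ``n_blocks`` balanced blocks, every task
    augmented with the status-quo alternative and each block with one
    repeated validation task."""
    aset = hemophilia_attributes()
    d = generate_design(aset, n_tasks=n_tasks, n_alternatives=2,
                        seed=seed, n_restarts=n_restarts)
    d = block_design(d, n_blocks=n_blocks, seed=seed)
    return augment_tasks(d, repeat_per_block=True, practice_task=practice_task,
                         seed=seed)


def simulate_study(
    n_respondents: int = 102,
    params: PreferenceParameters | None = None,
    design: Design | None = None,
    seed: int | None = None,
    copy_repeats: bool = False,
    n_inconsistent: int = 0,
    n_position_biased: int = 0,
    dominant_spec: dict[str, int] | None = None,
) -> ChoiceDataset:
    """Simulate one survey wave under the study conditions.

    Defaults mirror the study: 102 respondents with covariates at the
    published proportions, taste heterogeneity at the published means/SDs,
    two blocks of 9 scored tasks plus a repeated task each, a status-quo
    alternative per task. Contamination is off unless requested.
    """
    params = params or study_parameters()
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))
    design = design or build_study_design(seed=sub())
    betas = sample_individual_betas(params, n_respondents, seed=sub())
    cov = generate_covariates(n_respondents, study_covariate_proportions(), seed=sub())
    ds = simulate_choices(design, betas, seed=sub(), copy_repeats=copy_repeats)
    ds.covariates = cov
    ds.provenance["true_parameters"] = {"mean": dict(params.mean), "sd": dict(params.sd)}
    if n_inconsistent or n_position_biased or dominant_spec:
        ds = inject_contamination(
            ds, n_inconsistent=n_inconsistent, n_position_biased=n_position_biased,
            dominant_spec=dominant_spec, seed=sub(),
        )
    return ds


def standard_changes() -> list[AttributeChange]:
    """The six attribute improvements whose MAR the study reports."""
    return [
        AttributeChange("annual_bleeds", 12, 0),
        AttributeChange("annual_bleeds", 12, 6),
        AttributeChange("dosing_freq", 3, 1),
        AttributeChange("dosing_freq", 3, 2),
        AttributeChange("dosing_mode", "drip", "subcutaneous"),
        AttributeChange("dosing_mode", "drip", "push"),
    ]
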