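"""Respondent quality control and dominance diagnostics.

Implements the exclusion rules applied before estimation — the repeated-task
consistency screen and the position-bias screen — plus the risk-comprehension
item and the two dominant-preference diagnostics (a nonparametric choice
pattern test and a parametric full-versus-single-attribute model comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    ConditionalLogit,
    ModelSpec,
    NonIdentifiableModelError,
)
from .simulate import ChoiceDataset

__all__ = [
    "QCReport",
    "consistency_check",
    "position_bias_check",
    "comprehension_check",
    "apply_exclusions",
    "dominance_nonparametric",
    "dominance_parametric",
    "DominanceTestReport",
]


def _chosen_positions(dataset: ChoiceDataset) -> pd.DataFrame:
    """Per respondent x task: chosen position (1-based alt_id) and task flags."""
    df = dataset.data
    chosen = df[df["chosen"] == 1][
        ["respondent_id", "task_id", "alt_id", "is_repeat_of", "is_practice"]
    ].rename(columns={"alt_id": "chosen_position"})
    return chosen.reset_index(drop=True)


def consistency_check(dataset: ChoiceDataset, compare: str = "position") -> pd.Series:
    """Flag respondents whose repeated-task answer differs from the original.

    Returns a nullable boolean Series indexed by respondent id: ``True`` =
    fail, ``False`` = pass, ``NA`` = not evaluable (no repeated task seen).
    ``compare`` is ``"position"`` (alternative slot, default) or
    ``"identity"`` (same in this package's designs, where repeats preserve
    the alternative order).
    """
    if compare not in ("position", "identity"):
        raise ValueError(f"unknown compare mode {compare!r}")
    chosen = _chosen_positions(dataset)
    repeats = chosen[chosen["is_repeat_of"].notna() & (chosen["is_practice"] == 0)]
    originals = chosen.set_index(["respondent_id", "task_id"])["chosen_position"]
    flags = pd.Series(pd.NA, index=pd.Index(dataset.respondent_ids, name="respondent_id"),
                      dtype="boolean")
    for _, row in repeats.iterrows():
        key = (row["respondent_id"], int(row["is_repeat_of"]))
        if key not in originals.index:
            raise ValueError(f"repeat references missing task {key}")
        differs = row["chosen_position"] != originals.loc[key]
        rid = row["respondent_id"]
        prev = flags.loc[rid]
        flags.loc[rid] = bool(differs) if pd.isna(prev) else bool(prev or differs)
    return flags


def position_bias_check(dataset: ChoiceDataset) -> pd.Series:
    """Flag respondents choosing the same alternative position in every
    scored (non-practice) task."""
    chosen = _chosen_positions(dataset)
    scored = chosen[chosen["is_practice"] == 0]
    counts = scored.groupby("respondent_id")["chosen_position"].agg(["nunique", "size"])
    if (counts["size"] < 2).any():
        raise ValueError("position-bias check needs >=2 scored tasks per respondent")
    flags = counts["nunique"] == 1
    flags.name = "position_bias"
    return flags.reindex(dataset.respondent_ids).astype(bool)


def comprehension_check(stated_risk_percent: float, answer_out_of_100: float) -> bool:
    """Risk-numeracy item: "x% of 100 patients" must be answered with x."""
    if not 0 <= stated_risk_percent <= 100:
        raise ValueError("stated risk must lie in [0, 100]")
    if answer_out_of_100 < 0:
        raise ValueError("negative answer")
    return float(answer_out_of_100) == float(stated_risk_percent)


@dataclass
class QCReport:
    """Per-respondent exclusion flags and reconciled counts."""

    flags: pd.DataFrame  # columns: consistency_fail, position_bias, comprehension_fail
    n_input: int
    n_excluded: int
    n_retained: int
    rules: dict = field(default_factory=dict)
    dominance: pd.DataFrame | None = None

    def __post_init__(self):
        union = self.flags.fillna(False).any(axis=1).sum()
        assert self.n_excluded == int(union), "exclusion counts must reconcile (set union)"
        assert self.n_retained == self.n_input - self.n_excluded

    def to_json_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_excluded": self.n_excluded,
            "n_retained": self.n_retained,
            "rules": self.rules,
            "excluded_respondents": sorted(
                int(r) for r in self.flags.index[self.flags.fillna(False).any(axis=1)]
            ),
        }

    def __str__(self) -> str:
        lines = [
            f"respondents in: {self.n_input}",
            f"  consistency failures: {int(self.flags['consistency_fail'].fillna(False).sum())}",
            f"  position bias:        {int(self.flags['position_bias'].fillna(False).sum())}",
            f"  comprehension fail:   {int(self.flags['comprehension_fail'].fillna(False).sum())}"
            f" (exclusion {'on' if self.rules.get('comprehension') else 'off'})",
            f"excluded (union): {self.n_excluded}",
            f"retained: {self.n_retained}",
        ]
        return "\n".join(lines)


def apply_exclusions(
    dataset: ChoiceDataset,
    consistency: bool = True,
    position_bias: bool = True,
    comprehension: bool = False,
    comprehension_answers: Mapping[int, tuple[float, float]] | None = None,
    consistency_compare: str = "position",
) -> tuple[ChoiceDataset, QCReport]:
    """Remove flagged respondents and reconcile the counts.

    The comprehension item is recorded but, mirroring its use as a gate
    before the tasks rather than an analysis exclusion, does not exclude by
    default. A respondent failing several rules is counted once (set union).
    """
    ids = pd.Index(dataset.respondent_ids, name="respondent_id")
    flags = pd.DataFrame(index=ids)
    cons = consistency_check(dataset, compare=consistency_compare)
    flags["consistency_fail"] = cons.astype("boolean")
    flags["position_bias"] = position_bias_check(dataset)
    comp = pd.Series(False, index=ids, dtype="boolean")
    if comprehension_answers:
        for rid, (statedr, answer) in comprehension_answers.items():
            comp.loc[rid] = not comprehension_check(statedr, answer)
    flags["comprehension_fail"] = comp

    exclude = pd.Series(False, index=ids)
    if consistency:
        exclude |= flags["consistency_fail"].fillna(False).astype(bool)
    if position_bias:
        exclude |= flags["position_bias"].fillna(False).astype(bool)
    if comprehension:
        exclude |= flags["comprehension_fail"].fillna(False).astype(bool)

    active = flags.copy()
    for col, on in (("consistency_fail", consistency), ("position_bias", position_bias),
                    ("comprehension_fail", comprehension)):
        if not on:
            active[col] = False
    report = QCReport(
        flags=active,
        n_input=len(ids),
        n_excluded=int(exclude.sum()),
        n_retained=int((~exclude).sum()),
        rules={"consistency": consistency, "position_bias": position_bias,
               "comprehension": comprehension,
               "consistency_compare": consistency_compare},
    )
    if report.n_retained == 0:
        raise ValueError("all respondents excluded: empty estimation set")
    filtered = dataset.subset(ids[~exclude])
    return filtered, report


# ---------------------------------------------------------------------------
# dominant preference diagnostics
# ---------------------------------------------------------------------------

def dominance_nonparametric(dataset: ChoiceDataset, attribute: str) -> pd.Series:
    """Flag respondents whose every evaluable choice follows one attribute.

    A task is evaluable when the two designed alternatives differ on the
    attribute; a respondent is flagged when, in every evaluable task, they
    chose the designed alternative with the better level (per the attribute's
    ``direction_hint``) — choosing the status quo in an evaluable task breaks
    the pattern. ``NA`` = no evaluable task.
    """
    attr = dataset.attribute_set[attribute]
    if attr.direction_hint == "none":
        raise ValueError(f"attribute {attribute!r} has no direction_hint")
    df = dataset.data
    scored = df[(df["is_practice"] == 0)]
    flags = pd.Series(pd.NA, index=pd.Index(dataset.respondent_ids, name="respondent_id"),
                      dtype="boolean")
    for rid, resp_rows in scored.groupby("respondent_id"):
        verdict: bool | None = None
        for tid, task_rows in resp_rows.groupby("task_id"):
            designed = task_rows[task_rows["is_status_quo"] == 0]
            levels = designed[attribute].tolist()
            if len(levels) != 2:
                continue
            better = attr.better_level(levels[0], levels[1])
            if better is None:
                continue  # tied: not evaluable
            chosen_row = task_rows[task_rows["chosen"] == 1]
            followed = (
                int(chosen_row["is_status_quo"].iat[0]) == 0
                and chosen_row[attribute].iat[0] == better
            )
            verdict = followed if verdict is None else (verdict and followed)
            if verdict is False:
                break
        if verdict is not None:
            flags.loc[rid] = verdict
    return flags


@dataclass
class DominanceTestReport:
    """Full-versus-reduced coefficient comparison for one attribute."""

    attribute: str
    shared_columns: list[str]
    full_coefs: pd.Series
    reduced_coefs: pd.Series
    difference: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    pvalues_bonferroni: pd.Series
    alpha: float
    dominance_suspected: bool
    dominance_suspected_raw: bool


def dominance_parametric(
    dataset: ChoiceDataset,
    attribute: str,
    alpha: float = 0.05,
    **fit_kwargs,
) -> DominanceTestReport:
    """Compare full-model and single-attribute-model coefficients.

    Fits the full conditional logit and a reduced one containing only the
    named attribute's columns (plus the ASC when a status quo is present),
    then z-tests each shared column's coefficient difference with
    conservatively pooled variances (var_full + var_reduced). Dominance is
    suspected when any Bonferroni-adjusted difference is significant at
    ``alpha``; the unadjusted verdict is reported alongside.
    """
    aset = dataset.attribute_set
    has_sq = bool((dataset.data["is_status_quo"] == 1).any())
    full_spec = ModelSpec(attribute_set=aset, asc=has_sq)
    reduced_spec = ModelSpec(
        attribute_set=aset, asc=has_sq,
        keep_columns=tuple(aset[attribute].design_columns),
    )
    full = ConditionalLogit(dataset, full_spec).fit(**fit_kwargs)
    try:
        reduced = ConditionalLogit(dataset, reduced_spec).fit(**fit_kwargs)
    except NonIdentifiableModelError as err:
        raise NonIdentifiableModelError(
            f"reduced model on {attribute!r} is not identifiable: {err}"
        ) from err

    shared = [c for c in aset[attribute].design_columns]
    diff = full.params[shared] - reduced.params[shared]
    pooled_se = np.sqrt(full.bse[shared] ** 2 + reduced.bse[shared] ** 2)
    z = diff / pooled_se
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)
    p_bonf = (p * len(shared)).clip(upper=1.0)
    return DominanceTestReport(
        attribute=attribute,
        shared_columns=shared,
        full_coefs=full.params[shared],
        reduced_coefs=reduced.params[shared],
        difference=diff,
        zvalues=z,
        pvalues=p,
        pvalues_bonferroni=p_bonf,
        alpha=alpha,
        dominance_suspected=bool((p_bonf < alpha).any()),
        dominance_suspected_raw=bool((p < alpha).any()),
    )
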