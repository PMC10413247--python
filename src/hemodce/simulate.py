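"""Synthetic respondents and choice data.

Generates choice datasets with the statistical structure the estimators
assume: each respondent carries an individual utility-weight vector drawn
from independent normal taste distributions, and answers every task of their
block by a multinomial draw from the conditional-logit probabilities
``P(j) = exp(V_j) / sum_k exp(V_k)`` with ``V_j`` the model-matrix row times
the individual weights. Repeated validation tasks are answered from fresh
utility draws by default, so honest respondents can fail the consistency
screen by chance; a copy mode answers them identically to the original task.

Controlled contamination (inconsistent, position-biased and single-attribute
dominant respondents) is injected on top, with the contaminated respondent
ids recorded in the dataset provenance so QC tests have an exact oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import AttributeSet
from .design import Design

__all__ = [
    "PreferenceParameters",
    "ChoiceDataset",
    "sample_individual_betas",
    "generate_covariates",
    "assign_blocks",
    "simulate_choices",
    "inject_contamination",
]


@dataclass(frozen=True)
class PreferenceParameters:
    """Population preference distribution: per-column mean and normal SD.

    The generative truth for simulation and the estimand of the mixed logit.
    """

    mean: Mapping[str, float]
    sd: Mapping[str, float]
    distribution: str = "normal"

    def __post_init__(self):
        object.__setattr__(self, "mean", dict(self.mean))
        object.__setattr__(self, "sd", dict(self.sd))
        if self.distribution != "normal":
            raise ValueError("only normal taste heterogeneity is supported")
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd must cover the same model columns")
        neg = [c for c, v in self.sd.items() if v < 0]
        if neg:
            raise ValueError(f"negative heterogeneity SD for columns {neg}")

    @property
    def columns(self) -> list[str]:
        return list(self.mean)

    def with_sd_zero(self) -> "PreferenceParameters":
        return PreferenceParameters(self.mean, {c: 0.0 for c in self.sd})


@dataclass
class ChoiceDataset:
    """Long-format choice records plus covariates and provenance.

    ``data`` has one row per respondent x task x alternative with columns
    ``respondent_id, task_id, block_id, alt_id, is_status_quo, is_repeat_of,
    is_practice, chosen`` and one column per attribute (status-quo rows carry
    the status-quo levels if the design states them, else missing values).
    """

    data: pd.DataFrame
    attribute_set: AttributeSet
    covariates: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        per_task = self.data.groupby(["respondent_id", "task_id"])["chosen"].sum()
        if not (per_task == 1).all():
            bad = per_task[per_task != 1].index[:5].tolist()
            raise ValueError(f"not exactly one chosen alternative per task: {bad}")
        blocks = self.data.groupby("respondent_id")["block_id"].nunique()
        if not (blocks == 1).all():
            raise ValueError("a respondent sees tasks from more than one block")

    @property
    def respondent_ids(self) -> np.ndarray:
        return self.data["respondent_id"].unique()

    @property
    def n_respondents(self) -> int:
        return self.data["respondent_id"].nunique()

    def subset(self, respondent_ids) -> "ChoiceDataset":
        keep = set(respondent_ids)
        data = self.data[self.data["respondent_id"].isin(keep)].reset_index(drop=True)
        cov = None
        if self.covariates is not None:
            cov = self.covariates[
                self.covariates["respondent_id"].isin(keep)
            ].reset_index(drop=True)
        return ChoiceDataset(data, self.attribute_set, cov, dict(self.provenance))

    def copy(self) -> "ChoiceDataset":
        return ChoiceDataset(
            self.data.copy(),
            self.attribute_set,
            None if self.covariates is None else self.covariates.copy(),
            json.loads(json.dumps(self.provenance)),
        )

    # ---- I/O ---------------------------------------------------------------

    def write(self, stem) -> None:
        stem = Path(stem)
        self.data.to_csv(stem.with_suffix(".csv"), index=False)
        if self.covariates is not None:
            self.covariates.to_csv(
                stem.with_name(stem.name + ".covariates.csv"), index=False
            )
        with open(stem.with_name(stem.name + ".provenance.json"), "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=float)

    @classmethod
    def read(cls, stem, attribute_set: AttributeSet) -> "ChoiceDataset":
        stem = Path(stem)
        data = pd.read_csv(stem.with_suffix(".csv"))
        cov_path = stem.with_name(stem.name + ".covariates.csv")
        cov = pd.read_csv(cov_path) if cov_path.exists() else None
        prov_path = stem.with_name(stem.name + ".provenance.json")
        prov = {}
        if prov_path.exists():
            with open(prov_path) as fh:
                prov = json.load(fh)
        return cls(data, attribute_set, cov, prov)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def sample_individual_betas(
    params: PreferenceParameters, n_respondents: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw individual utility-weight vectors, one row per respondent.

    Each column is drawn independently Normal(mean, sd).
    """
    if n_respondents < 1:
        raise ValueError("need at least one respondent")
    rng = np.random.default_rng(seed)
    cols = params.columns
    mean = np.array([params.mean[c] for c in cols])
    sd = np.array([params.sd[c] for c in cols])
    draws = mean + sd * rng.standard_normal((n_respondents, len(cols)))
    out = pd.DataFrame(draws, columns=cols)
    out.insert(0, "respondent_id", np.arange(1, n_respondents + 1))
    return out


def generate_covariates(
    n_respondents: int,
    proportions: Mapping[str, Mapping[str, float]],
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw categorical respondent covariates at the stated proportions."""
    rng = np.random.default_rng(seed)
    out = {"respondent_id": np.arange(1, n_respondents + 1)}
    for name, cats in proportions.items():
        labels = list(cats)
        probs = np.array([cats[c] for c in labels], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions for {name!r} sum to {probs.sum()}, not 1")
        out[name] = rng.choice(labels, size=n_respondents, p=probs)
    return pd.DataFrame(out)


def assign_blocks(n_respondents: int, n_blocks: int, seed: int | None = None) -> np.ndarray:
    """Balanced random block assignment (1-based block ids)."""
    rng = np.random.default_rng(seed)
    base = np.tile(np.arange(1, n_blocks + 1), n_respondents // n_blocks + 1)
    return rng.permutation(base[:n_respondents])


def simulate_choices(
    design: Design,
    individual_betas: pd.DataFrame,
    seed: int | None = None,
    block_assignment: Sequence[int] | None = None,
    copy_repeats: bool = False,
) -> ChoiceDataset:
    """Simulate every respondent's answers to their block's tasks.

    ``individual_betas`` must carry a ``respondent_id`` column plus one column
    per model column of the design (attribute columns, and ``ASC`` when the
    design has a status-quo alternative).
    """
    rng = np.random.default_rng(seed)
    cols = design.model_columns
    missing = [c for c in cols if c not in individual_betas.columns]
    if missing:
        raise ValueError(f"individual_betas missing model columns {missing}")
    resp_ids = individual_betas["respondent_id"].to_numpy()
    betas = individual_betas[cols].to_numpy(dtype=float)
    n = len(resp_ids)

    if block_assignment is None:
        block_assignment = assign_blocks(n, design.n_blocks, rng.integers(2**31))
    blocks = np.asarray(block_assignment)
    if blocks.shape != (n,):
        raise ValueError("one block assignment per respondent is required")

    base_frame = design.to_frame()
    frames = []
    for b in range(1, design.n_blocks + 1):
        in_block = blocks == b
        if not in_block.any():
            continue
        r_ids = resp_ids[in_block]
        r_betas = betas[in_block]
        tasks = design.block(b)
        chosen_by_task: dict[int, np.ndarray] = {}
        for task in tasks:
            rows = design.task_rows(task)  # (J, K)
            if copy_repeats and task.is_repeat_of is not None:
                choice = chosen_by_task[task.is_repeat_of]
            else:
                v = r_betas @ rows.T
                v -= v.max(axis=1, keepdims=True)
                p = np.exp(v)
                p /= p.sum(axis=1, keepdims=True)
                u = rng.random((len(r_ids), 1))
                choice = (p.cumsum(axis=1) < u).sum(axis=1)
            chosen_by_task[task.task_id] = choice
        tmpl = base_frame[base_frame["block_id"] == b].reset_index(drop=True)
        n_rows = len(tmpl)
        block_frame = pd.concat([tmpl] * len(r_ids), ignore_index=True)
        block_frame.insert(0, "respondent_id", np.repeat(r_ids, n_rows))
        chosen = np.zeros(len(block_frame), dtype=int)
        alt_of_row = block_frame["alt_id"].to_numpy()
        task_of_row = block_frame["task_id"].to_numpy()
        for i, rid in enumerate(r_ids):
            off = i * n_rows
            for task in tasks:
                sel = off + np.flatnonzero(task_of_row[:n_rows] == task.task_id)
                chosen[sel[chosen_by_task[task.task_id][i]]] = 1
        block_frame["chosen"] = chosen
        frames.append(block_frame)

    data = pd.concat(frames, ignore_index=True)
    data = data.sort_values(["respondent_id", "block_id", "task_id", "alt_id"]).reset_index(
        drop=True
    )
    ds = ChoiceDataset(
        data=data,
        attribute_set=design.attribute_set,
        provenance={
            "seed": None if seed is None else int(seed),
            "copy_repeats": bool(copy_repeats),
            "contamination": {"inconsistent": [], "position_biased": [], "dominant": {}},
        },
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# contamination
# ---------------------------------------------------------------------------

def _set_choice(data: pd.DataFrame, idx: np.ndarray, position: int) -> None:
    """Within the rows ``idx`` of one respondent-task, choose ``position`` (0-based)."""
    data.loc[idx, "chosen"] = 0
    data.loc[idx[position], "chosen"] = 1


def inject_contamination(
    dataset: ChoiceDataset,
    n_inconsistent: int = 0,
    n_position_biased: int = 0,
    dominant_spec: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> ChoiceDataset:
    """Overwrite selected respondents' answers with pathological patterns.

    - *inconsistent*: each repeated task is answered at a different position
      than its original task;
    - *position biased*: one fixed position chosen in every task;
    - *dominant* (per attribute): always the designed alternative with the
      strictly better level of that attribute, original answer kept on ties.

    Contaminated respondents are disjoint; their ids are stored under
    ``provenance["contamination"]``.
    """
    dominant_spec = dict(dominant_spec or {})
    rng = np.random.default_rng(seed)
    total = n_inconsistent + n_position_biased + sum(dominant_spec.values())
    ids = dataset.respondent_ids
    if total > len(ids):
        raise ValueError(
            f"requested {total} contaminated respondents but dataset has {len(ids)}"
        )
    if total == 0:
        return dataset.copy()

    picked = rng.choice(ids, size=total, replace=False)
    cursor = 0
    inconsistent = picked[cursor:cursor + n_inconsistent]; cursor += n_inconsistent
    biased = picked[cursor:cursor + n_position_biased]; cursor += n_position_biased
    dominant: dict[str, np.ndarray] = {}
    for attr, count in dominant_spec.items():
        dominant[attr] = picked[cursor:cursor + count]; cursor += count

    out = dataset.copy()
    data = out.data
    grouped = data.groupby(["respondent_id", "task_id"], sort=False).indices

    def task_rows(rid, tid) -> np.ndarray:
        return np.sort(grouped[(rid, tid)])

    task_meta = data.drop_duplicates(["respondent_id", "task_id"]).set_index(
        ["respondent_id", "task_id"]
    )

    for rid in inconsistent:
        tasks = task_meta.loc[rid]
        for tid, row in tasks.iterrows():
            rep_of = row["is_repeat_of"]
            if pd.isna(rep_of):
                continue
            orig_idx = task_rows(rid, int(rep_of))
            rep_idx = task_rows(rid, tid)
            orig_pos = int(np.flatnonzero(data.loc[orig_idx, "chosen"].to_numpy())[0])
            others = [p for p in range(len(rep_idx)) if p != orig_pos]
            _set_choice(data, rep_idx, int(rng.choice(others)))

    for rid in biased:
        tasks = task_meta.loc[rid]
        n_alts = min(len(task_rows(rid, tid)) for tid in tasks.index)
        pos = int(rng.integers(n_alts))
        for tid in tasks.index:
            _set_choice(data, task_rows(rid, tid), pos)

    for attr, rids in dominant.items():
        attribute = dataset.attribute_set[attr]
        for rid in rids:
            tasks = task_meta.loc[rid]
            for tid in tasks.index:
                idx = task_rows(rid, tid)
                rows = data.loc[idx]
                designed = rows[rows["is_status_quo"] == 0]
                levels = designed[attr].tolist()
                if len(levels) != 2:
                    raise ValueError("dominant injection expects two designed alternatives")
                better = attribute.better_level(levels[0], levels[1])
                if better is None:
                    continue  # tie: keep the original answer
                designed_pos = np.flatnonzero(rows["is_status_quo"].to_numpy() == 0)
                pos = int(designed_pos[0 if levels[0] == better else 1])
                _set_choice(data, idx, pos)

    cont = out.provenance.setdefault(
        "contamination", {"inconsistent": [], "position_biased": [], "dominant": {}}
    )
    cont["inconsistent"] = sorted(int(r) for r in inconsistent)
    cont["position_biased"] = sorted(int(r) for r in biased)
    cont["dominant"] = {a: sorted(int(r) for r in rids) for a, rids in dominant.items()}
    out.validate()
    return out
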