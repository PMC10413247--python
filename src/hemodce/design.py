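"""Experimental design for the choice tasks.

Generates the candidate profile set, searches for a D-efficient set of choice
tasks with a modified Fedorov exchange algorithm, splits tasks into blocks
balanced on level frequencies, and augments the blocked design with the
status-quo alternative, the repeated internal-consistency task and an
optional practice task.

The efficiency criterion is the D-error of the conditional-logit information
matrix: ``det(I(beta))**(-1/K)`` for ``K`` model columns, evaluated at prior
coefficients (zeros by default, i.e. a utility-neutral design). Lower is
better.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import ASC_COLUMN, AttributeSet, Profile

__all__ = [
    "ChoiceTask",
    "Design",
    "NonIdentifiableDesignError",
    "InfeasibleDesignError",
    "full_factorial",
    "d_error",
    "generate_design",
    "block_design",
    "augment_tasks",
    "write_design",
    "read_design",
]


class NonIdentifiableDesignError(ValueError):
    """The design's information matrix is singular: coefficients are not identified."""


class InfeasibleDesignError(ValueError):
    """Too few tasks for the number of model columns."""


@dataclass(frozen=True)
class ChoiceTask:
    """One choice set: the designed alternatives, plus flags.

    The status-quo alternative, when present, is an implicit extra alternative
    shown last; its coding is decided at the design level
    (:attr:`Design.status_quo_profile`).
    """

    task_id: int
    profiles: tuple[Profile, ...]
    block_id: int = 1
    has_status_quo: bool = False
    is_repeat_of: int | None = None
    is_practice: bool = False

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        if len(self.profiles) + int(self.has_status_quo) < 2:
            raise ValueError("a choice task needs at least 2 alternatives")

    @property
    def n_alternatives(self) -> int:
        return len(self.profiles) + int(self.has_status_quo)


@dataclass(frozen=True)
class Design:
    """A full experimental design: tasks grouped into blocks."""

    attribute_set: AttributeSet
    tasks: tuple[ChoiceTask, ...]
    n_blocks: int = 1
    #: Levels shown for the status-quo alternative; ``None`` means the
    #: ASC-only coding (all attribute columns zero).
    status_quo_profile: Profile | None = None

    def __post_init__(self):
        object.__setattr__(self, "tasks", tuple(self.tasks))
        blocks = {t.block_id for t in self.tasks}
        if self.tasks and blocks != set(range(1, self.n_blocks + 1)):
            raise ValueError("tasks do not partition into the declared blocks")
        for t in self.tasks:
            if len(set(t.profiles)) != len(t.profiles):
                raise ValueError(f"task {t.task_id} contains two identical profiles")

    @property
    def has_status_quo(self) -> bool:
        return any(t.has_status_quo for t in self.tasks)

    @property
    def model_columns(self) -> list[str]:
        cols = list(self.attribute_set.design_columns)
        if self.has_status_quo:
            cols.append(ASC_COLUMN)
        return cols

    def block(self, block_id: int) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.block_id == block_id]

    def task(self, task_id: int) -> ChoiceTask:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)

    def task_rows(self, task: ChoiceTask) -> np.ndarray:
        """Model-matrix rows of one task (designed alternatives, then status quo)."""
        cols = self.model_columns
        asc = self.has_status_quo
        rows = []
        for p in task.profiles:
            r = self.attribute_set.encode_profile_array(p)
            rows.append(np.append(r, 0.0) if asc else r)
        if task.has_status_quo:
            if self.status_quo_profile is not None:
                r = self.attribute_set.encode_profile_array(self.status_quo_profile)
            else:
                r = np.zeros(len(self.attribute_set.design_columns))
            rows.append(np.append(r, 1.0))
        return np.asarray(rows, dtype=float)

    def d_error(self, priors: Mapping[str, float] | Sequence[float] | None = None) -> float:
        return d_error(self, priors)

    def to_frame(self) -> pd.DataFrame:
        """Long layout: one row per task x alternative."""
        records = []
        for t in sorted(self.tasks, key=lambda t: (t.block_id, t.task_id)):
            alts: list[tuple[Profile | None, bool]] = [(p, False) for p in t.profiles]
            if t.has_status_quo:
                alts.append((self.status_quo_profile, True))
            for alt_id, (profile, is_sq) in enumerate(alts, start=1):
                rec = {
                    "task_id": t.task_id,
                    "block_id": t.block_id,
                    "alt_id": alt_id,
                    "is_status_quo": int(is_sq),
                    "is_repeat_of": t.is_repeat_of,
                    "is_practice": int(t.is_practice),
                }
                for name in self.attribute_set.names:
                    rec[name] = profile.levels[name] if profile is not None else None
                records.append(rec)
        return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# candidate set and efficiency
# ---------------------------------------------------------------------------

def full_factorial(attribute_set: AttributeSet) -> list[Profile]:
    """All level combinations, lexicographic over the declared attribute and
    level order."""
    names = attribute_set.names
    grids = [a.levels for a in attribute_set]
    return [
        Profile(dict(zip(names, combo))) for combo in itertools.product(*grids)
    ]


def _resolve_priors(design: Design, priors) -> np.ndarray:
    cols = design.model_columns
    if priors is None:
        return np.zeros(len(cols))
    if isinstance(priors, Mapping):
        return np.array([float(priors.get(c, 0.0)) for c in cols])
    arr = np.asarray(priors, dtype=float)
    if arr.shape != (len(cols),):
        raise ValueError(f"priors must have length {len(cols)}")
    return arr


def _task_information(rows: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Conditional-logit information contribution of one choice set."""
    v = rows @ beta
    v = v - v.max()
    p = np.exp(v)
    p /= p.sum()
    xbar = p @ rows
    centered = rows - xbar
    return (centered * p[:, None]).T @ centered


def information_matrix(design: Design, priors=None) -> np.ndarray:
    beta = _resolve_priors(design, priors)
    k = len(design.model_columns)
    info = np.zeros((k, k))
    for t in design.tasks:
        if t.is_practice:
            continue
        info += _task_information(design.task_rows(t), beta)
    return info


def d_error(design: Design, priors=None) -> float:
    """D-error of the design under prior coefficients; lower is better.

    Raises :class:`NonIdentifiableDesignError` when the information matrix is
    singular (e.g. identical alternatives in every task).
    """
    if not design.tasks:
        raise ValueError("design has no tasks")
    info = information_matrix(design, priors)
    k = info.shape[0]
    eigvals = np.linalg.eigvalsh(info)
    if eigvals[0] <= 1e-10 * max(1.0, eigvals[-1]):
        raise NonIdentifiableDesignError(
            "singular information matrix: design does not identify all coefficients"
        )
    sign, logdet = np.linalg.slogdet(info)
    return float(np.exp(-logdet / k))


# ---------------------------------------------------------------------------
# D-efficient search (modified Fedorov exchange)
# ---------------------------------------------------------------------------

def _logdet_psd(info: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(info)
    return logdet if sign > 0 else -np.inf


def generate_design(
    attribute_set: AttributeSet,
    n_tasks: int,
    n_alternatives: int = 2,
    priors: Mapping[str, float] | None = None,
    seed: int | None = None,
    n_restarts: int = 20,
    max_passes: int = 10,
) -> Design:
    """Search for a D-efficient design by modified Fedorov exchange.

    From each random start, every alternative slot is repeatedly offered every
    candidate profile from the full factorial; an exchange is kept when it
    lowers the D-error. The best design over ``n_restarts`` starts is
    returned. Deterministic given ``seed``.
    """
    candidates = full_factorial(attribute_set)
    cand_rows = np.array(
        [attribute_set.encode_profile_array(p) for p in candidates]
    )
    k = len(attribute_set.design_columns)
    if n_tasks * (n_alternatives - 1) < k:
        raise InfeasibleDesignError(
            f"{n_tasks} tasks with {n_alternatives} alternatives cannot identify "
            f"{k} model columns"
        )
    rng = np.random.default_rng(seed)
    beta = np.zeros(k) if priors is None else np.array(
        [float(priors.get(c, 0.0)) for c in attribute_set.design_columns]
    )

    best_logdet = -np.inf
    best_assign: np.ndarray | None = None

    n_cand = len(candidates)
    for _ in range(max(1, n_restarts)):
        # random start: distinct profiles within each task
        assign = np.empty((n_tasks, n_alternatives), dtype=int)
        for t in range(n_tasks):
            assign[t] = rng.choice(n_cand, size=n_alternatives, replace=False)
        contribs = np.array(
            [_task_information(cand_rows[assign[t]], beta) for t in range(n_tasks)]
        )
        info = contribs.sum(axis=0)
        cur = _logdet_psd(info)

        for _ in range(max_passes):
            improved = False
            for t in range(n_tasks):
                for slot in range(n_alternatives):
                    others = np.delete(assign[t], slot)
                    base = info - contribs[t]
                    best_c, best_val, best_contrib = None, cur, None
                    for c in range(n_cand):
                        if c in others or c == assign[t, slot]:
                            continue
                        trial = assign[t].copy()
                        trial[slot] = c
                        contrib = _task_information(cand_rows[trial], beta)
                        val = _logdet_psd(base + contrib)
                        if val > best_val + 1e-12:
                            best_c, best_val, best_contrib = c, val, contrib
                    if best_c is not None:
                        assign[t, slot] = best_c
                        contribs[t] = best_contrib
                        info = base + best_contrib
                        cur = best_val
                        improved = True
            if not improved:
                break
        if cur > best_logdet:
            best_logdet = cur
            best_assign = assign.copy()

    if best_assign is None or not np.isfinite(best_logdet):
        raise NonIdentifiableDesignError(
            "no identifiable design found; increase n_tasks or n_restarts"
        )
    tasks = tuple(
        ChoiceTask(task_id=t + 1, profiles=tuple(candidates[c] for c in best_assign[t]))
        for t in range(n_tasks)
    )
    return Design(attribute_set=attribute_set, tasks=tasks, n_blocks=1)


# ---------------------------------------------------------------------------
# blocking and augmentation
# ---------------------------------------------------------------------------

def _level_counts(design: Design, tasks: Sequence[ChoiceTask]) -> dict:
    counts: dict = {}
    for t in tasks:
        for p in t.profiles:
            for name, level in p.levels.items():
                counts[(name, level)] = counts.get((name, level), 0) + 1
    return counts


def block_design(design: Design, n_blocks: int, seed: int | None = None,
                 n_restarts: int = 200) -> Design:
    """Split tasks into equal blocks balanced on attribute-level frequencies.

    Over random equal-size partitions, picks the one minimizing the maximum
    across levels of the spread (max minus min) of that level's frequency
    across blocks. ``n_blocks=1`` returns the design unchanged.
    """
    n = len(design.tasks)
    if n % n_blocks:
        raise ValueError(f"{n} tasks cannot be split into {n_blocks} equal blocks")
    if n_blocks == 1:
        return design
    rng = np.random.default_rng(seed)
    size = n // n_blocks
    all_levels = [
        (a.name, lv) for a in design.attribute_set for lv in a.levels
    ]

    def score(perm: np.ndarray) -> int:
        worst = 0
        per_block = []
        for b in range(n_blocks):
            tasks = [design.tasks[i] for i in perm[b * size:(b + 1) * size]]
            per_block.append(_level_counts(design, tasks))
        for key in all_levels:
            vals = [c.get(key, 0) for c in per_block]
            worst = max(worst, max(vals) - min(vals))
        return worst

    best_perm, best_score = None, None
    for _ in range(max(1, n_restarts)):
        perm = rng.permutation(n)
        s = score(perm)
        if best_score is None or s < best_score:
            best_perm, best_score = perm, s
            if s == 0:
                break
    new_tasks = []
    for b in range(n_blocks):
        for i in sorted(best_perm[b * size:(b + 1) * size]):
            new_tasks.append(replace(design.tasks[i], block_id=b + 1))
    return replace(design, tasks=tuple(new_tasks), n_blocks=n_blocks)


def augment_tasks(
    design: Design,
    status_quo_profile: Profile | None = None,
    repeat_per_block: bool = True,
    practice_task: bool = False,
    seed: int | None = None,
) -> Design:
    """Add the status-quo alternative to every task and, per block, one
    repeated validation task (and optionally one practice task).

    The repeated task is drawn uniformly from the block's scored tasks and
    flagged ``is_repeat_of``; the practice task duplicates a random task and
    is excluded from estimation.
    """
    rng = np.random.default_rng(seed)
    tasks = [replace(t, has_status_quo=True) for t in design.tasks]
    next_id = max(t.task_id for t in tasks) + 1
    extra: list[ChoiceTask] = []
    for b in range(1, design.n_blocks + 1):
        block = [t for t in tasks if t.block_id == b]
        if practice_task:
            src = block[rng.integers(len(block))]
            extra.append(
                replace(src, task_id=next_id, is_practice=True, is_repeat_of=None)
            )
            next_id += 1
        if repeat_per_block:
            src = block[rng.integers(len(block))]
            extra.append(
                replace(src, task_id=next_id, is_repeat_of=src.task_id)
            )
            next_id += 1
    ordered = sorted(tasks + extra, key=lambda t: (t.block_id, t.is_repeat_of is not None, t.task_id))
    return replace(
        design,
        tasks=tuple(ordered),
        status_quo_profile=status_quo_profile,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_design(design: Design, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, attribute_set: AttributeSet) -> Design:
    df = pd.read_csv(path)
    tasks = []
    sq_profile = None
    for (task_id, block_id), grp in df.groupby(["task_id", "block_id"], sort=True):
        profiles = []
        has_sq = False
        for _, row in grp.sort_values("alt_id").iterrows():
            if row["is_status_quo"]:
                has_sq = True
                if not pd.isna(row[attribute_set.names[0]]):
                    sq_profile = Profile(
                        {n: _parse_level(attribute_set, n, row[n]) for n in attribute_set.names}
                    )
                continue
            profiles.append(
                Profile({n: _parse_level(attribute_set, n, row[n]) for n in attribute_set.names})
            )
        rep = row["is_repeat_of"]
        tasks.append(
            ChoiceTask(
                task_id=int(task_id),
                block_id=int(block_id),
                profiles=tuple(profiles),
                has_status_quo=has_sq,
                is_repeat_of=None if pd.isna(rep) else int(rep),
                is_practice=bool(row["is_practice"]),
            )
        )
    n_blocks = df["block_id"].nunique()
    return Design(
        attribute_set=attribute_set,
        tasks=tuple(tasks),
        n_blocks=n_blocks,
        status_quo_profile=sq_profile,
    )


def _parse_level(attribute_set: AttributeSet, name: str, value):
    attr = attribute_set[name]
    for lv in attr.levels:
        if lv == value or str(lv) == str(value):
            return lv
        try:
            if float(lv) == float(value):
                return lv
        except (TypeError, ValueError):
            pass
    raise ValueError(f"{value!r} is not a level of {name!r}")
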