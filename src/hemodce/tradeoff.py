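"""Benefit-risk statistics from fitted preference weights.

Attribute relative importance (ARI) rescales each attribute's part-worth
utility range so the widest-range attribute scores 100; maximum acceptable
risk (MAR) converts the utility gain of a stated improvement into the
inhibitor-risk increase (in percentage points) that leaves total utility
unchanged:

    MAR(change) = [U(to_level) - U(from_level)] / |beta_risk per % point|.

Both are ratios of coefficients, so any common rescaling of the utilities
leaves them unchanged. Inputs may be a fitted results object or a plain
coefficient mapping (e.g. a published table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attributes import AttributeSet

__all__ = [
    "AttributeChange",
    "TradeoffReport",
    "attribute_ranges",
    "relative_importance",
    "mar",
    "mar_uncertainty",
    "tradeoff_report",
    "subgroup_compare",
    "sensitivity_analysis",
    "SensitivityReport",
    "plot_mar",
]


@dataclass(frozen=True)
class AttributeChange:
    """A stated improvement: one attribute moved between two of its levels."""

    attribute: str
    from_level: object
    to_level: object

    def __post_init__(self):
        if self.from_level == self.to_level:
            raise ValueError("from_level and to_level must differ")

    def label(self) -> str:
        return f"{self.attribute}: {self.from_level} -> {self.to_level}"


def _coefs(source) -> Mapping[str, float]:
    if isinstance(source, Mapping):
        return source
    if hasattr(source, "mean_params"):  # MixedLogitResults
        return source.mean_params.to_dict()
    if hasattr(source, "params"):
        return source.params.to_dict()
    raise TypeError("expected a results object or a coefficient mapping")


def attribute_ranges(source, attribute_set: AttributeSet) -> dict[str, float]:
    """Part-worth utility range per attribute.

    Categorical: max minus min over level utilities (reference at 0);
    continuous: |coefficient| times the level span.
    """
    coefs = _coefs(source)
    missing = [c for c in attribute_set.design_columns if c not in coefs]
    if missing:
        raise KeyError(f"coefficients missing for columns {missing}")
    ranges: dict[str, float] = {}
    for a in attribute_set:
        if a.coding == "continuous":
            span = float(max(a.levels)) - float(min(a.levels))
            ranges[a.name] = abs(coefs[a.name]) * span
        else:
            utils = [a.level_utility(lv, coefs) for lv in a.levels]
            ranges[a.name] = max(utils) - min(utils)
    return ranges


def relative_importance(source, attribute_set: AttributeSet):
    """ARI scores (max = 100) and raw importance shares.

    Returns ``(ari, ari_raw, shares)``: integer-rounded scores, unrounded
    scores, and range shares summing to 1.
    """
    ranges = attribute_ranges(source, attribute_set)
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all attribute ranges are zero")
    positive = [r for r in ranges.values() if r > 0]
    if len(positive) < 2:
        raise ValueError("need >=2 attributes with positive range")
    total = sum(ranges.values())
    ari_raw = {a: 100.0 * r / max_range for a, r in ranges.items()}
    ari = {a: int(round(v)) for a, v in ari_raw.items()}
    shares = {a: r / total for a, r in ranges.items()}
    return ari, ari_raw, shares


def mar(source, attribute_set: AttributeSet, change: AttributeChange,
        risk_attribute: str = "inhibitor_risk") -> float:
    """Maximum acceptable risk for one attribute change, in percentage points
    of the risk attribute (unrounded)."""
    coefs = _coefs(source)
    if change.attribute == risk_attribute:
        raise ValueError("MAR is undefined for changes of the risk attribute itself")
    risk_attr = attribute_set[risk_attribute]
    if risk_attr.coding != "continuous":
        raise ValueError("risk attribute must be continuous (per percentage point)")
    beta_risk = coefs[risk_attribute]
    if beta_risk == 0:
        raise ValueError("zero risk coefficient: MAR undefined")
    attr = attribute_set[change.attribute]
    for lv in (change.from_level, change.to_level):
        if lv not in attr.levels:
            raise ValueError(f"{lv!r} is not a level of {change.attribute!r}")
    du = attr.level_utility(change.to_level, coefs) - attr.level_utility(
        change.from_level, coefs
    )
    return du / abs(beta_risk)


@dataclass
class TradeoffReport:
    """Utility ranges, ARI scores and MARs from one coefficient source."""

    ranges: dict[str, float]
    ari: dict[str, int]
    ari_raw: dict[str, float]
    shares: dict[str, float]
    mars: dict[str, float]  # label -> rounded to 1 decimal
    mars_raw: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "ranges": self.ranges, "ari": self.ari, "ari_raw": self.ari_raw,
            "shares": self.shares, "mar": self.mars, "mar_raw": self.mars_raw,
            "provenance": self.provenance,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "range": self.ranges,
            "ari": self.ari,
            "share": self.shares,
        })


def tradeoff_report(source, attribute_set: AttributeSet,
                    changes: Sequence[AttributeChange] = (),
                    risk_attribute: str = "inhibitor_risk") -> TradeoffReport:
    """Compute the full benefit-risk report: ranges, ARIs and the MAR of each
    requested change (MAR rounded to one decimal, ARI to integer; raw values
    retained)."""
    ranges = attribute_ranges(source, attribute_set)
    ari, ari_raw, shares = relative_importance(source, attribute_set)
    mars_raw = {
        c.label(): mar(source, attribute_set, c, risk_attribute) for c in changes
    }
    mars = {k: round(v, 1) for k, v in mars_raw.items()}
    prov = {}
    if hasattr(source, "fingerprint"):
        prov["result_fingerprint"] = source.fingerprint
    return TradeoffReport(ranges=ranges, ari=ari, ari_raw=ari_raw, shares=shares,
                          mars=mars, mars_raw=mars_raw, provenance=prov)


def mar_uncertainty(result, attribute_set: AttributeSet, change: AttributeChange,
                    n_sim: int = 10000, seed: int | None = None,
                    risk_attribute: str = "inhibitor_risk",
                    level: float = 0.95) -> tuple[float, float]:
    """Krinsky-Robb percentile interval for one MAR.

    Draws coefficient vectors from the multivariate normal at the estimates
    with the fitted variance-covariance matrix (repaired by eigenvalue
    clipping if not positive semidefinite) and recomputes the MAR per draw.
    """
    coefs = _coefs(result)
    names = list(coefs)
    mu = np.array([coefs[c] for c in names])
    cov_df = result.cov_params()
    cov = cov_df.reindex(index=names, columns=names).fillna(0.0).to_numpy()
    eigval, eigvec = np.linalg.eigh(0.5 * (cov + cov.T))
    if eigval.min() < 0:
        import warnings

        warnings.warn("covariance not PSD; clipping negative eigenvalues")
        eigval = np.clip(eigval, 0.0, None)
    root = eigvec * np.sqrt(eigval)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_sim, len(names)))
    draws = mu + z @ root.T
    vals = np.empty(n_sim)
    for i in range(n_sim):
        d = dict(zip(names, draws[i]))
        try:
            vals[i] = mar(d, attribute_set, change, risk_attribute)
        except ValueError:  # zero risk coefficient draw
            vals[i] = np.nan
    vals = vals[np.isfinite(vals)]
    lo, hi = np.percentile(vals, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# subgroups and sensitivity
# ---------------------------------------------------------------------------

def subgroup_compare(
    dataset,
    result,
    grouping_covariate: str,
    mode: str = "individual_level",
    changes: Sequence[AttributeChange] = (),
    min_group_size: int = 30,
    risk_attribute: str = "inhibitor_risk",
    **fit_kwargs,
) -> dict[str, TradeoffReport]:
    """Per-group benefit-risk reports.

    ``individual_level`` (default): average the mixed logit's conditional
    individual coefficients within each covariate group and derive each
    group's ARIs from those averages. ``refit``: estimate a separate mixed
    logit per group (each group must reach ``min_group_size``).
    """
    if dataset.covariates is None or grouping_covariate not in dataset.covariates:
        raise ValueError(f"covariate {grouping_covariate!r} not available")
    cov = dataset.covariates.set_index("respondent_id")[grouping_covariate]
    aset = dataset.attribute_set
    reports: dict[str, TradeoffReport] = {}
    if mode == "individual_level":
        indiv = result.individual_params()
        indiv = indiv.set_index("respondent_id")
        groups = cov.reindex(indiv.index)
        for g, sub in indiv.groupby(groups):
            coefs = sub.mean(axis=0).to_dict()
            reports[str(g)] = tradeoff_report(coefs, aset, changes, risk_attribute)
    elif mode == "refit":
        from .models import MixedLogit

        for g in cov.unique():
            ids = cov.index[cov == g]
            if len(ids) < min_group_size:
                raise ValueError(
                    f"group {g!r} has {len(ids)} respondents (< {min_group_size})"
                )
            sub = dataset.subset(ids)
            res = MixedLogit(sub, result.model.spec).fit(**fit_kwargs)
            reports[str(g)] = tradeoff_report(res, aset, changes, risk_attribute)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reports


@dataclass
class SensitivityReport:
    """Side-by-side coefficients from the all-respondents and filtered fits."""

    table: pd.DataFrame  # coef_all, se_all, coef_filtered, se_filtered, z, p, sign_agrees
    n_all: int
    n_filtered: int
    any_significant: bool
    alpha: float

    def __str__(self) -> str:
        return (
            f"sensitivity check: {self.n_all} vs {self.n_filtered} respondents; "
            f"{'some' if self.any_significant else 'no'} significant coefficient "
            f"differences at alpha={self.alpha}\n"
            + self.table.to_string(float_format=lambda x: f"{x: .4f}")
        )


def sensitivity_analysis(dataset_all, dataset_filtered, spec, alpha: float = 0.05,
                         model: str = "mixl", **fit_kwargs) -> SensitivityReport:
    """Fit the model on the full and the filtered datasets and z-test each
    coefficient difference (pooled variances)."""
    ids_all = set(map(int, dataset_all.respondent_ids))
    ids_f = set(map(int, dataset_filtered.respondent_ids))
    key = ["respondent_id", "task_id", "alt_id"]
    rows_all = dataset_all.data[dataset_all.data["respondent_id"].isin(ids_f)]
    rows_all = rows_all.sort_values(key).reset_index(drop=True)
    rows_f = dataset_filtered.data.sort_values(key).reset_index(drop=True)
    if not ids_f <= ids_all or len(rows_all) != len(rows_f) \
            or not (rows_all["chosen"].to_numpy() == rows_f["chosen"].to_numpy()).all():
        raise ValueError("filtered dataset is not a subset of the full dataset")
    if ids_f == ids_all:
        import warnings

        warnings.warn("datasets are identical; sensitivity comparison is trivial")

    from .models import ConditionalLogit, MixedLogit

    cls = MixedLogit if model == "mixl" else ConditionalLogit
    res_all = cls(dataset_all, spec).fit(**fit_kwargs)
    res_f = cls(dataset_filtered, spec).fit(**fit_kwargs)

    names = [c for c in res_all.params.index if c in res_f.params.index]
    diff = res_all.params[names] - res_f.params[names]
    pooled = np.sqrt(res_all.bse[names] ** 2 + res_f.bse[names] ** 2)
    from scipy import stats

    z = diff / pooled
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=z.index)
    table = pd.DataFrame({
        "coef_all": res_all.params[names], "se_all": res_all.bse[names],
        "coef_filtered": res_f.params[names], "se_filtered": res_f.bse[names],
        "z": z, "p": p,
        "sign_agrees": np.sign(res_all.params[names]) == np.sign(res_f.params[names]),
    })
    return SensitivityReport(
        table=table,
        n_all=res_all.n_respondents,
        n_filtered=res_f.n_respondents,
        any_significant=bool((p < alpha).any()),
        alpha=alpha,
    )


def plot_mar(report: TradeoffReport, path=None, ax=None):
    """Horizontal bar chart of the MARs (percentage points of inhibitor risk)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.6 * max(len(report.mars), 2) + 1))
    labels = list(report.mars)
    vals = [report.mars[k] for k in labels]
    ax.barh(labels, vals, color="#4878a8")
    for y, v in enumerate(vals):
        ax.text(v, y, f" {v:.1f}%", va="center")
    ax.set_xlabel("maximum acceptable increase in inhibitor risk (% points)")
    ax.invert_yaxis()
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
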