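"""Conditional logit and mixed logit estimation.

Statsmodels-style modelling objects: :class:`ConditionalLogit` (the
homogeneous-coefficient multinomial logit of McFadden) and
:class:`MixedLogit` (normally distributed taste heterogeneity, estimated by
simulated maximum likelihood over Halton or pseudo-random draws, with the
panel product of task probabilities taken within respondent). Both are built
from a :class:`~hemodce.simulate.ChoiceDataset` plus a :class:`ModelSpec`
and their ``fit()`` returns a results object carrying estimates, standard
errors, p-values, log-likelihood, AIC/BIC, the variance-covariance matrix
and a ``summary()`` table.

The simulated log-likelihood is

    SLL = sum_i ln[ (1/R) sum_r prod_t P(y_it | beta_ir) ],
    beta_ir = mean + sd * draw_ir   (elementwise, random columns only),

maximized by quasi-Newton (BFGS) with an analytic gradient and a final
Newton polish using a finite-difference Hessian of the gradient; standard
errors come from the inverse Hessian (cluster-robust by respondent
optionally). Reported heterogeneity SDs are absolute values of the raw
parameters (the likelihood is invariant to their sign).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from scipy.stats import qmc

from .attributes import ASC_COLUMN, AttributeSet
from .simulate import ChoiceDataset

__all__ = [
    "ModelSpec",
    "DrawConfig",
    "ModelData",
    "build_model_matrix",
    "make_draws",
    "ConditionalLogit",
    "MixedLogit",
    "ConditionalLogitResults",
    "MixedLogitResults",
    "fit_mnl",
    "fit_mixl",
    "lr_test",
    "LRTestResult",
    "backward_select_interactions",
    "InteractionSelection",
    "posterior_individual_betas",
    "NonIdentifiableModelError",
]

_NEG_INF = -1e30


class NonIdentifiableModelError(ValueError):
    """Model matrix (or reduced model) does not identify all coefficients."""


@dataclass(frozen=True)
class ModelSpec:
    """What enters the utility function and how.

    Attribute columns follow the :class:`AttributeSet` coding (dummy columns
    against reference levels, risk continuous in percentage points). ``asc``
    adds the status-quo constant. ``interactions`` are (covariate, column)
    pairs, each expanding to one dummy per non-reference covariate category
    multiplied by the model column (``"ASC"`` allowed). ``random_columns``
    get normally distributed heterogeneity in the mixed logit.
    """

    attribute_set: AttributeSet
    asc: bool = True
    random_columns: tuple[str, ...] = ()
    interactions: tuple[tuple[str, str], ...] = ()
    include_repeats: bool = False
    covariate_references: Mapping[str, str] = field(default_factory=dict)
    keep_columns: tuple[str, ...] | None = None  # restrict attribute columns (reduced models)

    def __post_init__(self):
        object.__setattr__(self, "random_columns", tuple(self.random_columns))
        object.__setattr__(self, "interactions", tuple(tuple(t) for t in self.interactions))
        object.__setattr__(self, "covariate_references", dict(self.covariate_references))
        if len(set(self.interactions)) != len(self.interactions):
            raise ValueError("duplicated interaction terms")

    def base_columns(self) -> list[str]:
        cols = list(self.attribute_set.design_columns)
        if self.keep_columns is not None:
            keep = set(self.keep_columns)
            unknown = keep - set(cols)
            if unknown:
                raise ValueError(f"unknown model columns {sorted(unknown)}")
            cols = [c for c in cols if c in keep]
        if self.asc:
            cols.append(ASC_COLUMN)
        return cols


@dataclass(frozen=True)
class DrawConfig:
    """Simulation-draw schedule for the mixed logit.

    ``schedule`` is the increasing list of draw counts tried in turn;
    estimation is declared stable at the first point where the maximum
    relative change of every mean and |SD| against the previous point falls
    below ``tolerance``.
    """

    draw_type: str = "halton"
    schedule: tuple[int, ...] = (50, 500, 1000, 1500, 2000, 2500)
    tolerance: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "schedule", tuple(int(r) for r in self.schedule))
        if self.draw_type not in ("halton", "pseudo_random"):
            raise ValueError(f"unknown draw_type {self.draw_type!r}")
        if any(b <= a for a, b in zip(self.schedule, self.schedule[1:])) or not self.schedule:
            raise ValueError("draw schedule must be strictly increasing and non-empty")
        if self.tolerance <= 0:
            raise ValueError("stability tolerance must be positive")


# ---------------------------------------------------------------------------
# model matrix
# ---------------------------------------------------------------------------

@dataclass
class ModelData:
    """Padded per-situation arrays feeding both likelihoods.

    ``X`` is (situations, max alternatives, columns); ``alt_mask`` marks real
    alternatives; ``chosen`` is the chosen alternative's index within the
    situation; ``resp_codes`` maps situations to respondents.
    """

    X: np.ndarray
    alt_mask: np.ndarray
    chosen: np.ndarray
    resp_codes: np.ndarray
    resp_ids: np.ndarray
    columns: list[str]
    fingerprint: str

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_respondents(self) -> int:
        return len(self.resp_ids)


def _encode_rows(dataset: ChoiceDataset, spec: ModelSpec, df: pd.DataFrame) -> np.ndarray:
    """Encode the long rows into attribute (+ASC, +interaction) columns."""
    aset = spec.attribute_set
    base = spec.base_columns()
    n = len(df)
    X = np.zeros((n, len(base)))
    col_idx = {c: i for i, c in enumerate(base)}
    is_sq = df["is_status_quo"].to_numpy().astype(bool)

    for a in aset:
        vals = df[a.name]
        known_rows = ~(is_sq & vals.isna().to_numpy())
        for i in np.flatnonzero(known_rows):
            enc = a.encode(_coerce_level(a, vals.iat[i]))
            for c, v in enc.items():
                if c in col_idx:
                    X[i, col_idx[c]] = v
    if spec.asc:
        X[:, col_idx[ASC_COLUMN]] = is_sq.astype(float)

    columns = list(base)
    if spec.interactions:
        if dataset.covariates is None:
            raise ValueError("interactions requested but dataset has no covariates")
        cov = dataset.covariates.set_index("respondent_id")
        rows_cov = cov.reindex(df["respondent_id"])
        inter_cols = []
        for covariate, col in spec.interactions:
            if col not in col_idx:
                raise ValueError(f"interaction on unknown model column {col!r}")
            cats = sorted(cov[covariate].astype(str).unique())
            ref = str(spec.covariate_references.get(covariate, cats[0]))
            for cat in cats:
                if cat == ref:
                    continue
                dummy = (rows_cov[covariate].astype(str).to_numpy() == cat).astype(float)
                inter_cols.append((f"{col}:{covariate}[{cat}]", X[:, col_idx[col]] * dummy))
        if inter_cols:
            X = np.column_stack([X] + [v for _, v in inter_cols])
            columns += [name for name, _ in inter_cols]
    return X, columns


def _coerce_level(attribute, value):
    for lv in attribute.levels:
        if lv == value:
            return lv
        try:
            if float(lv) == float(value):
                return lv
        except (TypeError, ValueError):
            pass
    if str(value) in map(str, attribute.levels):
        return next(lv for lv in attribute.levels if str(lv) == str(value))
    raise ValueError(f"{value!r} is not a level of attribute {attribute.name!r}")


def build_model_matrix(dataset: ChoiceDataset, spec: ModelSpec) -> ModelData:
    """Build the padded per-situation arrays for estimation.

    Practice tasks are always excluded; repeated validation tasks are
    excluded unless ``spec.include_repeats`` (they duplicate a choice
    situation).
    """
    df = dataset.data
    keep = df["is_practice"] == 0
    if not spec.include_repeats:
        keep &= df["is_repeat_of"].isna()
    df = df[keep].sort_values(["respondent_id", "task_id", "alt_id"]).reset_index(drop=True)
    if df.empty:
        raise ValueError("no scored observations after filtering")

    X, columns = _encode_rows(dataset, spec, df)
    sit_keys, sit_codes = np.unique(
        df[["respondent_id", "task_id"]].to_numpy(), axis=0, return_inverse=True
    )
    order = np.argsort(sit_codes, kind="stable")
    sit_codes = sit_codes[order]
    X = X[order]
    chosen_flag = df["chosen"].to_numpy()[order]
    resp_of_sit = sit_keys[:, 0]

    counts = np.bincount(sit_codes)
    if counts.min() < 2:
        raise ValueError("every choice situation needs at least 2 alternatives")
    S, J, K = len(counts), counts.max(), X.shape[1]
    X3 = np.zeros((S, J, K))
    mask = np.zeros((S, J), dtype=bool)
    chosen = np.zeros(S, dtype=int)
    pos = np.zeros(S, dtype=int)
    starts = np.concatenate([[0], np.cumsum(counts)])
    for s in range(S):
        lo, hi = starts[s], starts[s + 1]
        X3[s, : hi - lo] = X[lo:hi]
        mask[s, : hi - lo] = True
        ch = np.flatnonzero(chosen_flag[lo:hi])
        if len(ch) != 1:
            raise ValueError("not exactly one chosen alternative in a situation")
        chosen[s] = ch[0]

    resp_ids, resp_codes = np.unique(resp_of_sit, return_inverse=True)
    # fingerprint identifies the choice data (situations and outcomes), not
    # the spec's column selection, so nested fits compare as "same data"
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(sit_keys).tobytes())
    h.update(chosen.tobytes())
    h.update(counts.tobytes())
    return ModelData(
        X=X3, alt_mask=mask, chosen=chosen, resp_codes=resp_codes,
        resp_ids=resp_ids, columns=columns, fingerprint=h.hexdigest(),
    )


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

def make_draws(
    n_respondents: int,
    n_draws: int,
    n_dims: int,
    draw_type: str = "halton",
    seed: int | None = None,
    burn_in: int = 10,
) -> np.ndarray:
    """Standard-normal simulation draws, shape (respondents, draws, dims).

    Halton: one prime base per dimension, ``burn_in`` initial points dropped,
    consecutive blocks of ``n_draws`` points per respondent, inverse-normal
    transformed. Pseudo-random: seeded normals.
    """
    if n_respondents < 1 or n_draws < 1 or n_dims < 1:
        raise ValueError("counts must be >= 1")
    if draw_type == "halton":
        sampler = qmc.Halton(d=n_dims, scramble=False)
        sampler.fast_forward(burn_in)
        u = sampler.random(n_respondents * n_draws)
        z = stats.norm.ppf(u)
        return z.reshape(n_respondents, n_draws, n_dims)
    if draw_type == "pseudo_random":
        rng = np.random.default_rng(seed)
        return rng.standard_normal((n_respondents, n_draws, n_dims))
    raise ValueError(f"unknown draw_type {draw_type!r}")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

class ChoiceModelResultsBase:
    """Shared surface of the estimation results."""

    def __init__(self, model, params: pd.Series, cov: np.ndarray, llf: float,
                 converged: bool, diagnostics: dict):
        self.model = model
        self.params = params
        self._cov = cov
        self.llf = float(llf)
        self.converged = bool(converged)
        self.diagnostics = diagnostics

    # -- inference -----------------------------------------------------------

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._cov, index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.clip(np.diag(self._cov), 0, None)),
                         index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    # -- fit statistics ------------------------------------------------------

    @property
    def df_model(self) -> int:
        return len(self.params)

    @property
    def n_obs(self) -> int:
        return self.model.data.n_obs

    @property
    def n_respondents(self) -> int:
        return self.model.data.n_respondents

    @property
    def aic(self) -> float:
        return 2 * self.df_model - 2 * self.llf

    @property
    def bic(self) -> float:
        return self.df_model * np.log(self.n_obs) - 2 * self.llf

    @property
    def fingerprint(self) -> str:
        return self.model.data.fingerprint

    # -- reporting -----------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "z": self.zvalues, "p": self.pvalues}
        )

    def summary(self) -> str:
        head = (
            f"{type(self).__name__.replace('Results', '')}"
            f"  LL={self.llf:.3f}  AIC={self.aic:.2f}  BIC={self.bic:.2f}\n"
            f"situations={self.n_obs}  respondents={self.n_respondents}"
            f"  converged={self.converged}\n"
        )
        tbl = self.coefficient_table()
        return head + tbl.to_string(float_format=lambda x: f"{x: .4f}") + "\n"

    def to_json_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "llf": self.llf,
            "aic": self.aic,
            "bic": self.bic,
            "n_obs": self.n_obs,
            "n_respondents": self.n_respondents,
            "converged": self.converged,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if isinstance(v, (int, float, str, bool, type(None)))},
        }


class ConditionalLogitResults(ChoiceModelResultsBase):
    pass


class MixedLogitResults(ChoiceModelResultsBase):
    """Adds the heterogeneity-SD block and draw diagnostics.

    ``params`` holds the means under the column names and the |SD|s under
    ``sd.<column>``.
    """

    def __init__(self, model, params, cov, llf, converged, diagnostics,
                 draw_state: dict):
        super().__init__(model, params, cov, llf, converged, diagnostics)
        self.draw_state = draw_state  # n_draws, draw_type, seed, fixed sds
        self.schedule_trace: list[dict] = []
        self.stable_at: int | None = None

    @property
    def mean_params(self) -> pd.Series:
        return self.params[[c for c in self.params.index if not c.startswith("sd.")]]

    @property
    def sd_params(self) -> pd.Series:
        sds = self.params[[c for c in self.params.index if c.startswith("sd.")]]
        return sds.abs()

    def coefficient_table(self) -> pd.DataFrame:
        """Mean | p | SE | SD | p | SE layout, one row per model column."""
        rows = {}
        for col in self.mean_params.index:
            rows[col] = {
                "mean": self.params[col], "p_mean": self.pvalues[col],
                "se_mean": self.bse[col],
            }
            sd_name = f"sd.{col}"
            if sd_name in self.params.index:
                rows[col].update({
                    "sd": abs(self.params[sd_name]),
                    "p_sd": self.pvalues[sd_name],
                    "se_sd": self.bse[sd_name],
                })
        fixed = self.draw_state.get("fix_sds") or {}
        for col, v in fixed.items():
            if col in rows:
                rows[col]["sd"] = abs(v)
        return pd.DataFrame.from_dict(rows, orient="index")

    def individual_params(self, n_draws: int | None = None, seed: int | None = None
                          ) -> pd.DataFrame:
        """Posterior (conditional) mean coefficients per respondent."""
        means = self.mean_params.to_dict()
        sds = {c[3:]: abs(v) for c, v in
               self.params[[i for i in self.params.index if i.startswith("sd.")]].items()}
        for col, v in (self.draw_state.get("fix_sds") or {}).items():
            sds[col] = abs(v)
        return posterior_individual_betas(
            self.model, means, sds,
            n_draws=n_draws or self.draw_state["n_draws"],
            draw_type=self.draw_state["draw_type"],
            seed=self.draw_state["seed"] if seed is None else seed,
        )


# ---------------------------------------------------------------------------
# conditional logit
# ---------------------------------------------------------------------------

class ConditionalLogit:
    """McFadden conditional logit on long-format choice data."""

    results_class = ConditionalLogitResults

    def __init__(self, dataset: ChoiceDataset, spec: ModelSpec | None = None):
        if spec is None:
            spec = ModelSpec(attribute_set=dataset.attribute_set,
                             asc=bool((dataset.data["is_status_quo"] == 1).any()))
        self.dataset = dataset
        self.spec = spec
        self.data = build_model_matrix(dataset, spec)
        self._check_identification()

    @classmethod
    def from_dataset(cls, dataset: ChoiceDataset, **spec_kwargs) -> "ConditionalLogit":
        return cls(dataset, ModelSpec(attribute_set=dataset.attribute_set, **spec_kwargs))

    def _check_identification(self):
        d = self.data
        p0 = np.where(d.alt_mask, 1.0, 0.0)
        p0 /= p0.sum(axis=1, keepdims=True)
        xbar = np.einsum("sj,sjk->sk", p0, d.X)
        centered = d.X - xbar[:, None, :]
        info = np.einsum("sj,sjk,sjl->kl", p0 * d.alt_mask, centered, centered)
        eig = np.linalg.eigvalsh(info)
        if eig[0] <= 1e-9 * max(1.0, eig[-1]):
            raise NonIdentifiableModelError(
                "model matrix has no within-task variation for some column(s)"
            )

    # -- likelihood ----------------------------------------------------------

    def _utilities(self, beta: np.ndarray) -> np.ndarray:
        u = self.data.X @ beta
        return np.where(self.data.alt_mask, u, _NEG_INF)

    def _case_logprobs(self, beta: np.ndarray):
        u = self._utilities(beta)
        lse = logsumexp(u, axis=1)
        p = np.exp(u - lse[:, None])
        # normalization sanity: within-task probabilities must sum to 1
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-8)
        ll_case = u[np.arange(len(u)), self.data.chosen] - lse
        return ll_case, p

    def loglike(self, beta: np.ndarray) -> float:
        ll_case, _ = self._case_logprobs(np.asarray(beta, dtype=float))
        return float(ll_case.sum())

    def score_obs(self, beta: np.ndarray) -> np.ndarray:
        """Per-situation score vectors."""
        _, p = self._case_logprobs(np.asarray(beta, dtype=float))
        d = self.data
        xch = d.X[np.arange(d.n_obs), d.chosen]
        xbar = np.einsum("sj,sjk->sk", p, d.X)
        return xch - xbar

    def score(self, beta: np.ndarray) -> np.ndarray:
        return self.score_obs(beta).sum(axis=0)

    def hessian(self, beta: np.ndarray) -> np.ndarray:
        _, p = self._case_logprobs(np.asarray(beta, dtype=float))
        d = self.data
        xbar = np.einsum("sj,sjk->sk", p, d.X)
        h = np.einsum("sj,sjk,sjl->kl", p, d.X, d.X) - np.einsum("sk,sl->kl", xbar, xbar)
        return -h

    # -- fitting -------------------------------------------------------------

    def fit(self, start: Sequence[float] | None = None, maxiter: int = 500,
            gtol: float = 1e-6, cov_type: str = "hessian") -> ConditionalLogitResults:
        k = len(self.data.columns)
        x0 = np.zeros(k) if start is None else np.asarray(start, dtype=float)

        res = optimize.minimize(
            lambda b: -self.loglike(b), x0, jac=lambda b: -self.score(b),
            method="BFGS", options={"gtol": gtol, "maxiter": maxiter},
        )
        beta = res.x
        # Newton polish: the MNL log-likelihood is concave, so a few Newton
        # steps push the gradient norm well below the quasi-Newton tolerance.
        for _ in range(25):
            g = self.score(beta)
            if np.max(np.abs(g)) < 1e-10:
                break
            H = self.hessian(beta)
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                break
            new = beta + step
            if self.loglike(new) >= self.loglike(beta):
                beta = new
            else:
                break

        g = self.score(beta)
        gnorm = float(np.max(np.abs(g)))
        converged = gnorm <= gtol
        diagnostics = {"grad_max_norm": gnorm, "optimizer_message": res.message,
                       "n_iter": int(res.nit)}
        H = self.hessian(beta)
        cov, notes = _covariance(H, cov_type, self._cluster_scores(beta))
        diagnostics.update(notes)
        if np.max(np.abs(beta)) > 30:
            converged = False
            diagnostics["separation_suspected"] = True
        params = pd.Series(beta, index=self.data.columns)
        return self.results_class(self, params, cov, self.loglike(beta), converged,
                                  diagnostics)

    def _cluster_scores(self, beta: np.ndarray) -> np.ndarray:
        obs = self.score_obs(beta)
        out = np.zeros((self.data.n_respondents, obs.shape[1]))
        np.add.at(out, self.data.resp_codes, obs)
        return out


def _covariance(H: np.ndarray, cov_type: str, cluster_scores: np.ndarray | None):
    """Covariance from the Hessian of the log-likelihood (negative definite)."""
    notes: dict = {}
    negH = -H
    try:
        bread = np.linalg.inv(negH)
        if not np.all(np.isfinite(bread)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(negH)
        notes["singular_hessian"] = True
    if cov_type == "hessian" or cluster_scores is None:
        return bread, notes
    if cov_type == "cluster":
        meat = cluster_scores.T @ cluster_scores
        g = cluster_scores.shape[0]
        corr = g / max(g - 1, 1)
        return corr * bread @ meat @ bread, notes
    raise ValueError(f"unknown cov_type {cov_type!r}")


# ---------------------------------------------------------------------------
# mixed logit
# ---------------------------------------------------------------------------

class MixedLogit(ConditionalLogit):
    """Mixed logit with independent normal random coefficients (panel SMLE)."""

    results_class = MixedLogitResults

    def __init__(self, dataset: ChoiceDataset, spec: ModelSpec):
        if not spec.random_columns:
            raise ValueError("MixedLogit needs at least one random column")
        super().__init__(dataset, spec)
        unknown = set(spec.random_columns) - set(self.data.columns)
        if unknown:
            raise ValueError(f"random columns not in model: {sorted(unknown)}")
        self._build_panel()

    def _build_panel(self):
        d = self.data
        order = np.argsort(d.resp_codes, kind="stable")
        counts = np.bincount(d.resp_codes)
        if counts.min() < 1:
            raise ValueError("empty respondent panel")
        N, T = len(counts), counts.max()
        S, J, K = d.X.shape
        Xp = np.zeros((N, T, J, K))
        task_mask = np.zeros((N, T), dtype=bool)
        alt_mask = np.zeros((N, T, J), dtype=bool)
        chosen = np.zeros((N, T), dtype=int)
        starts = np.concatenate([[0], np.cumsum(counts)])
        for i in range(N):
            sel = order[starts[i]:starts[i + 1]]
            t = len(sel)
            Xp[i, :t] = d.X[sel]
            alt_mask[i, :t] = d.alt_mask[sel]
            task_mask[i, :t] = True
            chosen[i, :t] = d.chosen[sel]
        self._panel = (Xp, task_mask, alt_mask, chosen)
        self._rand_idx = np.array(
            [self.data.columns.index(c) for c in self.spec.random_columns]
        )

    # -- simulated likelihood ------------------------------------------------

    def _respondent_logw(self, mean: np.ndarray, sd_full: np.ndarray,
                         draws: np.ndarray, chunk: int = 128,
                         want_grad: bool = False):
        """Per-respondent per-draw log panel probabilities (and gradients)."""
        Xp, task_mask, alt_mask, chosen = self._panel
        N, T, J, K = Xp.shape
        R = draws.shape[1]
        D = len(self._rand_idx)
        sll = 0.0
        ll_n = np.empty(N)
        dmean = np.zeros(K)
        dsd = np.zeros(D)
        resp_scores = np.empty((N, K + D)) if want_grad else None
        Xflat = Xp.reshape(N, T * J, K)
        for lo in range(0, N, chunk):
            hi = min(lo + chunk, N)
            n_c = hi - lo
            beta = np.broadcast_to(mean, (n_c, R, K)).copy()
            beta[:, :, self._rand_idx] += draws[lo:hi] * sd_full[self._rand_idx]
            # batched GEMM: utilities for every draw, task and alternative
            U = (Xflat[lo:hi] @ beta.transpose(0, 2, 1))  # (n_c, T*J, R)
            U = U.transpose(0, 2, 1).reshape(n_c, R, T, J)
            U = np.where(alt_mask[lo:hi, None, :, :], U, _NEG_INF)
            u_max = U.max(axis=3, keepdims=True)
            eU = np.exp(U - u_max)
            sums = eU.sum(axis=3)
            lse = u_max[..., 0] + np.log(sums)
            ch = chosen[lo:hi][:, None, :, None]
            u_ch = np.take_along_axis(U, np.broadcast_to(ch, U.shape[:3] + (1,)), axis=3)[..., 0]
            logp = (u_ch - lse) * task_mask[lo:hi, None, :]
            logw = logp.sum(axis=2)  # (n_c, R)
            a = logw.max(axis=1, keepdims=True)
            wrel = np.exp(logw - a)
            ssum = wrel.sum(axis=1)
            ll_chunk = a[:, 0] + np.log(ssum) - np.log(R)
            ll_n[lo:hi] = ll_chunk
            sll += ll_chunk.sum()
            if want_grad:
                wtil = wrel / ssum[:, None]
                p = eU / sums[..., None]
                # within-task probabilities must sum to one on real tasks
                assert np.allclose(
                    p.sum(axis=3)[:, 0, :][task_mask[lo:hi]], 1.0, atol=1e-8
                )
                # score: chosen-row sum minus probability-weighted row sum,
                # with the t and j sums collapsed into one batched GEMM
                xch = np.take_along_axis(
                    Xp[lo:hi], chosen[lo:hi][:, :, None, None].repeat(K, 3), axis=2
                )[:, :, 0, :]
                xch_sum = (xch * task_mask[lo:hi, :, None]).sum(axis=1)  # (n_c, K)
                xbar_sum = p.reshape(n_c, R, T * J) @ Xflat[lo:hi]  # (n_c, R, K)
                s = xch_sum[:, None, :] - xbar_sum
                dmean += np.einsum("nr,nrk->k", wtil, s)
                s_rand = s[:, :, self._rand_idx] * draws[lo:hi]
                dsd += np.einsum("nr,nrd->d", wtil, s_rand)
                resp_scores[lo:hi, :K] = np.einsum("nr,nrk->nk", wtil, s)
                resp_scores[lo:hi, K:] = np.einsum("nr,nrd->nd", wtil, s_rand)
        return sll, ll_n, dmean, dsd, resp_scores

    def simulated_loglike(self, mean, sds: Mapping[str, float], draws: np.ndarray) -> float:
        """Simulated log-likelihood at given means and SDs (sign-invariant in SDs)."""
        mean = np.asarray(mean, dtype=float)
        sd_full = np.zeros(len(self.data.columns))
        for c, v in sds.items():
            sd_full[self.data.columns.index(c)] = v
        sll, *_ = self._respondent_logw(mean, sd_full, draws)
        return float(sll)

    def fit(self, n_draws: int = 500, draw_type: str = "halton",
            seed: int | None = None, start: Mapping[str, float] | None = None,
            fix_sds: Mapping[str, float] | None = None, maxiter: int = 500,
            gtol: float = 1e-6, cov_type: str = "hessian",
            start_sd: float = 0.1) -> MixedLogitResults:
        """Estimate by simulated maximum likelihood with ``n_draws`` per respondent.

        ``fix_sds`` pins selected heterogeneity SDs (e.g. all zero recovers the
        conditional logit exactly); fixed SDs are excluded from the parameter
        vector.
        """
        fix_sds = dict(fix_sds or {})
        unknown = set(fix_sds) - set(self.spec.random_columns)
        if unknown:
            raise ValueError(f"fix_sds for non-random columns {sorted(unknown)}")
        free_rand = [c for c in self.spec.random_columns if c not in fix_sds]
        K = len(self.data.columns)
        D = len(self._rand_idx)
        draws = make_draws(self.data.n_respondents, n_draws, D, draw_type, seed)

        fixed_full = np.zeros(K)
        for c, v in fix_sds.items():
            fixed_full[self.data.columns.index(c)] = v
        free_idx = np.array([self.data.columns.index(c) for c in free_rand], dtype=int)
        rand_pos = {int(ci): j for j, ci in enumerate(self._rand_idx)}

        def unpack(theta):
            mean = theta[:K]
            sd_full = fixed_full.copy()
            if len(free_idx):
                sd_full[free_idx] = theta[K:]
            return mean, sd_full

        def negloglike_and_grad(theta):
            mean, sd_full = unpack(theta)
            sll, _, dmean, dsd, _ = self._respondent_logw(
                mean, sd_full, draws, want_grad=True
            )
            grad = np.concatenate([dmean, [dsd[rand_pos[int(ci)]] for ci in free_idx]])
            return -sll, -grad

        if start is None:
            mnl = ConditionalLogit(self.dataset, replace(self.spec, random_columns=()))
            mnl_res = mnl.fit(gtol=max(gtol, 1e-5))
            mean0 = mnl_res.params.reindex(self.data.columns).fillna(0.0).to_numpy()
        else:
            mean0 = np.array([start.get(c, 0.0) for c in self.data.columns])
        sd0 = np.array([start.get(f"sd.{c}", start_sd) if start else start_sd
                        for c in free_rand])
        x0 = np.concatenate([mean0, sd0])

        res = optimize.minimize(
            negloglike_and_grad, x0, jac=True, method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        theta = res.x

        grad_fn = lambda t: negloglike_and_grad(t)[1]
        H = _fd_jacobian(grad_fn, theta)
        H = 0.5 * (H + H.T)  # Hessian of the negative SLL
        try:
            step = np.linalg.solve(H, -grad_fn(theta))
            cand = theta + step
            if negloglike_and_grad(cand)[0] <= res.fun + 1e-9:
                theta = cand
                H = _fd_jacobian(grad_fn, theta)
                H = 0.5 * (H + H.T)
        except np.linalg.LinAlgError:
            pass

        nll, ngrad = negloglike_and_grad(theta)
        gnorm = float(np.max(np.abs(ngrad)))
        converged = gnorm <= max(gtol, 1e-4)
        mean, sd_full = unpack(theta)
        names = list(self.data.columns) + [f"sd.{c}" for c in free_rand]
        # report |sd|: the SLL is symmetric in each sd's sign
        vals = np.concatenate([mean, np.abs(theta[K:])])
        params = pd.Series(vals, index=names)

        cov, notes = _covariance(-H, cov_type,
                                 self._mixl_cluster_scores(theta, draws, unpack,
                                                           rand_pos, free_idx)
                                 if cov_type == "cluster" else None)
        diagnostics = {
            "grad_max_norm": gnorm, "optimizer_message": res.message,
            "n_iter": int(res.nit), **notes,
        }
        if n_draws < 30:
            diagnostics["low_draw_warning"] = (
                f"only {n_draws} draws: simulated LL is noisy and biased upward"
            )
        result = MixedLogitResults(
            self, params, cov, -nll, converged, diagnostics,
            draw_state={"n_draws": n_draws, "draw_type": draw_type, "seed": seed,
                        "fix_sds": fix_sds},
        )
        return result

    def _mixl_cluster_scores(self, theta, draws, unpack, rand_pos, free_idx):
        mean, sd_full = unpack(theta)
        _, _, _, _, resp_scores = self._respondent_logw(
            mean, sd_full, draws, want_grad=True
        )
        K = len(self.data.columns)
        cols = list(range(K)) + [K + rand_pos[int(ci)] for ci in free_idx]
        return resp_scores[:, cols]

    def fit_schedule(self, draw_config: DrawConfig | None = None,
                     **fit_kwargs) -> MixedLogitResults:
        """Run the increasing-draw schedule until coefficient stability.

        Fits at each draw count in turn (warm-starting from the previous
        point) and stops at the first point where the maximum relative change
        of every reported parameter versus the previous point is below the
        configured tolerance; that fit is returned, annotated with the trace.
        """
        cfg = draw_config or DrawConfig()
        prev: MixedLogitResults | None = None
        trace: list[dict] = []
        result = None
        stable_at = None
        for r in cfg.schedule:
            start = None
            if prev is not None:
                start = {**prev.mean_params.to_dict(),
                         **{f"sd.{c[3:]}": v for c, v in
                            prev.params[[i for i in prev.params.index
                                         if i.startswith("sd.")]].items()}}
            result = self.fit(n_draws=r, draw_type=cfg.draw_type, seed=cfg.seed,
                              start=start, **fit_kwargs)
            rec = {"n_draws": r, "llf": result.llf,
                   "params": result.params.to_dict(), "max_rel_change": None}
            if prev is not None:
                denom = np.maximum(np.abs(prev.params.to_numpy()), 1e-8)
                rec["max_rel_change"] = float(
                    np.max(np.abs(result.params.to_numpy() - prev.params.to_numpy())
                           / denom)
                )
            trace.append(rec)
            if rec["max_rel_change"] is not None and rec["max_rel_change"] < cfg.tolerance:
                stable_at = r
                break
            prev = result
        result.schedule_trace = trace
        result.stable_at = stable_at
        return result


def _fd_jacobian(grad_fn, theta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of a gradient function."""
    k = len(theta)
    J = np.empty((k, k))
    for i in range(k):
        h = eps * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        J[:, i] = (grad_fn(up) - grad_fn(dn)) / (2 * h)
    return J


# ---------------------------------------------------------------------------
# convenience fitters
# ---------------------------------------------------------------------------

def fit_mnl(dataset: ChoiceDataset, spec: ModelSpec | None = None,
            **fit_kwargs) -> ConditionalLogitResults:
    return ConditionalLogit(dataset, spec).fit(**fit_kwargs)


def fit_mixl(dataset: ChoiceDataset, spec: ModelSpec, **fit_kwargs) -> MixedLogitResults:
    return MixedLogit(dataset, spec).fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# inference across models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    pvalue: float


def lr_test(result_full: ChoiceModelResultsBase,
            result_reduced: ChoiceModelResultsBase) -> LRTestResult:
    """Likelihood-ratio test of nested specifications on the same data."""
    if result_full.fingerprint != result_reduced.fingerprint \
            or result_full.n_obs != result_reduced.n_obs:
        raise ValueError("models were fitted on different data")
    full_cols = set(result_full.params.index)
    red_cols = set(result_reduced.params.index)
    if not red_cols <= full_cols:
        raise ValueError("reduced model is not nested in the full model")
    df = result_full.df_model - result_reduced.df_model
    if df < 0:
        raise ValueError("full model has fewer parameters than the reduced model")
    stat = 2 * (result_full.llf - result_reduced.llf)
    stat = max(stat, 0.0)
    p = 1.0 if df == 0 and stat == 0.0 else float(stats.chi2.sf(stat, max(df, 1)))
    if df == 0:
        p = 1.0 if stat <= 1e-10 else 0.0
    return LRTestResult(float(stat), df, p)


@dataclass
class InteractionSelection:
    selected: list[tuple[str, str]]
    trace: list[dict]
    final: ConditionalLogitResults
    dropped_aliased: list[tuple[str, str]] = field(default_factory=list)


def backward_select_interactions(
    dataset: ChoiceDataset,
    covariates: Sequence[str],
    alpha: float = 0.05,
    spec: ModelSpec | None = None,
    include_asc: bool = True,
    **fit_kwargs,
) -> InteractionSelection:
    """Backward selection of covariate x attribute interaction terms (MNL).

    Starts from all (covariate, model column) interactions; repeatedly drops
    the term with the largest single-term LR-test p-value above ``alpha``
    until every remaining term is significant. Terms whose columns are
    aliased (non-identifiable full model) are dropped upfront with a note.
    """
    base_spec = spec or ModelSpec(
        attribute_set=dataset.attribute_set,
        asc=bool((dataset.data["is_status_quo"] == 1).any()),
    )
    cols = list(base_spec.base_columns())
    if not include_asc and ASC_COLUMN in cols:
        cols.remove(ASC_COLUMN)
    terms = [(cov, col) for cov in covariates for col in cols]

    dropped_aliased: list[tuple[str, str]] = []

    def fit_with(term_list):
        s = replace(base_spec, interactions=tuple(term_list))
        return ConditionalLogit(dataset, s).fit(**fit_kwargs)

    while True:
        try:
            full = fit_with(terms)
            break
        except NonIdentifiableModelError:
            dropped_aliased.append(terms.pop())
            if not terms:
                full = fit_with(terms)
                break

    trace: list[dict] = []
    while terms:
        pvals = []
        for term in terms:
            reduced = fit_with([t for t in terms if t != term])
            test = lr_test(full, reduced)
            pvals.append((test.pvalue, term, reduced, test))
        pvals.sort(key=lambda x: (-x[0], x[1]))
        worst_p, worst_term, reduced, test = pvals[0]
        if worst_p > alpha:
            trace.append({"removed": worst_term, "statistic": test.statistic,
                          "df": test.df, "pvalue": worst_p})
            terms = [t for t in terms if t != worst_term]
            full = reduced
        else:
            break
    return InteractionSelection(selected=list(terms), trace=trace, final=full,
                                dropped_aliased=dropped_aliased)


# ---------------------------------------------------------------------------
# individual-level (conditional) coefficients
# ---------------------------------------------------------------------------

def posterior_individual_betas(
    model: MixedLogit,
    means: Mapping[str, float],
    sds: Mapping[str, float],
    n_draws: int = 500,
    draw_type: str = "halton",
    seed: int | None = None,
) -> pd.DataFrame:
    """Conditional mean coefficients per respondent.

    ``E[beta_i | choices] = sum_r beta_ir w_ir / sum_r w_ir`` with
    ``w_ir`` the panel probability of the respondent's observed choices under
    draw ``r``; computed in log space so underflowing weights renormalize
    safely.
    """
    cols = model.data.columns
    mean = np.array([means[c] for c in cols])
    sd_full = np.zeros(len(cols))
    for c, v in sds.items():
        sd_full[cols.index(c)] = v
    D = len(model._rand_idx)
    draws = make_draws(model.data.n_respondents, n_draws, D, draw_type, seed)

    Xp, task_mask, alt_mask, chosen = model._panel
    N = Xp.shape[0]
    out = np.tile(mean, (N, 1))
    chunk = 128
    R = n_draws
    for lo in range(0, N, chunk):
        hi = min(lo + chunk, N)
        n_c = hi - lo
        beta = np.broadcast_to(mean, (n_c, R, len(cols))).copy()
        beta[:, :, model._rand_idx] += draws[lo:hi] * sd_full[model._rand_idx]
        U = np.einsum("ntjk,nrk->nrtj", Xp[lo:hi], beta)
        U = np.where(alt_mask[lo:hi, None, :, :], U, _NEG_INF)
        lse = logsumexp(U, axis=3)
        ch = chosen[lo:hi][:, None, :, None]
        u_ch = np.take_along_axis(U, np.broadcast_to(ch, U.shape[:3] + (1,)), axis=3)[..., 0]
        logw = ((u_ch - lse) * task_mask[lo:hi, None, :]).sum(axis=2)
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        out[lo:hi] = np.einsum("nr,nrk->nk", w, beta)
    df = pd.DataFrame(out, columns=cols)
    df.insert(0, "respondent_id", model.data.resp_ids)
    return df
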