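"""Group x timepoint inference for recall accuracy, organization scores and
lag-CRP values.

Three model families mirror the analysis design of the clinical free-recall
study this package supports:

* **recall accuracy** — logistic regression (logit link) on per-item binary
  recall outcomes, group x timepoint with full interactions;
* **temporal organization scores** — linear model on per-unit scores, group x
  timepoint, optionally adding grand-mean-centered percent recall as a
  covariate; one-sample t tests compare scores to the chance level of .5;
* **lag-CRP values** — a two-part zero-inflated beta regression: a logistic
  part for P(CRP = 0) and a beta part (mean link logit by default, log
  selectable; constant precision phi) for positive CRPs, both on group x
  timepoint x |lag| x direction.

Within-participant dependence is handled by fixed-effects maximum likelihood
plus a participant-cluster nonparametric bootstrap for standard errors
(resampling participants with replacement, keeping all their rows), rather
than random-effect estimation.  Dummy coding uses a declared reference level
per factor; ``recode_reference`` re-bases a factor so simple effects at other
levels can be read off a refit, which leaves the likelihood and fitted values
unchanged.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
from scipy import optimize, special, stats

from .core_metrics import DEFAULT_MAX_LAG, StudyList, sequence_metrics
from .io import (
    RunConfig,
    TIMEPOINT_ORDER,
    config_hash,
    item_outcomes,
    sequences_from_frame,
)

CHANCE_LEVEL = 0.5


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation in a logistic fit."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge."""


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FactorSpec:
    """A categorical predictor: ordered levels and the dummy-coding
    reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if self.reference not in self.levels:
            raise ValueError(
                f"reference {self.reference!r} not among levels of {self.name!r}"
            )


@dataclass(frozen=True)
class ModelSpec:
    """Formula descriptor: response, fully-crossed terms, additive covariates.

    ``factors`` and ``numeric`` enter a full-factorial interaction;
    ``covariates`` are additive (e.g. grand-mean-centered percent recall).
    """

    response: str
    factors: tuple[FactorSpec, ...] = ()
    numeric: tuple[str, ...] = ()
    covariates: tuple[str, ...] = ()

    def rhs(self) -> str:
        terms = [
            f"C({f.name}, Treatment(reference={f.reference!r}))" for f in self.factors
        ]
        terms += list(self.numeric)
        if not terms:
            rhs = "1"
        else:
            rhs = " * ".join(terms)
        for cov in self.covariates:
            rhs += f" + {cov}"
        return rhs

    def formula(self) -> str:
        return f"{self.response} ~ {self.rhs()}"


def recode_reference(spec: ModelSpec, factor: str, new_reference: str) -> ModelSpec:
    """Return ``spec`` with ``factor`` re-based to ``new_reference``.

    Refitting the recoded spec reproduces the same model (identical
    log-likelihood and fitted values) with coefficients re-expressed as
    simple effects at the new reference level.
    """
    for i, f in enumerate(spec.factors):
        if f.name == factor:
            if new_reference not in f.levels:
                raise ValueError(
                    f"unknown level {new_reference!r} for factor {factor!r}; "
                    f"levels are {f.levels}"
                )
            if new_reference == f.reference:
                return spec
            new_factors = (
                spec.factors[:i]
                + (replace(f, reference=new_reference),)
                + spec.factors[i + 1 :]
            )
            return replace(spec, factors=new_factors)
    raise KeyError(f"no factor named {factor!r} in spec")


_TREATMENT_RE = re.compile(r"C\((\w+), Treatment\(reference=[^)]*\)\)")


def _clean_term(term: str) -> str:
    return _TREATMENT_RE.sub(r"\1", term)


# ---------------------------------------------------------------------------
# fitted-model container
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Tidy coefficient table plus fit metadata for any inference model."""

    model_kind: str  # binomial | linear | zib
    formula: str
    coefficients: pd.DataFrame  # part, term, estimate, se, stat, p, ci_lo, ci_hi
    llf: float
    converged: bool
    n_obs: int
    n_boot: int = 0
    meta: dict = field(default_factory=dict)

    def coef(self, term: str, part: str = "mean") -> pd.Series:
        """Look up one coefficient row by (cleaned) term name."""
        df = self.coefficients
        hit = df[(df["term"] == term) & (df["part"] == part)]
        if hit.empty:
            raise KeyError(f"no term {term!r} in part {part!r}")
        return hit.iloc[0]

    def terms(self, part: str = "mean") -> list[str]:
        df = self.coefficients
        return df.loc[df["part"] == part, "term"].tolist()


class OneSampleT(NamedTuple):
    t: float
    df: int
    p: float
    mean: float
    sd: float


def one_sample_t(scores, mu0: float = CHANCE_LEVEL) -> OneSampleT:
    """Classical one-sample t test of a score collection against ``mu0``
    (two-sided); NaNs are dropped first.  Used to compare temporal
    organization scores to the chance level of .5."""
    arr = np.asarray(list(scores), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 defined scores")
    sd = float(arr.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(float(arr.mean()))):
        raise ValueError("degenerate sample: zero standard deviation")
    res = stats.ttest_1samp(arr, mu0)
    return OneSampleT(
        t=float(res.statistic),
        df=arr.size - 1,
        p=float(res.pvalue),
        mean=float(arr.mean()),
        sd=sd,
    )


# ---------------------------------------------------------------------------
# design-matrix plumbing
# ---------------------------------------------------------------------------

def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = data.copy()
    for f in spec.factors:
        if f.name not in df.columns:
            raise ValueError(f"factor column {f.name!r} missing from data")
        col = pd.Categorical(df[f.name].astype(str), categories=f.levels)
        if col.isna().any() and not pd.isna(df[f.name]).any():
            bad = sorted(set(df[f.name].astype(str)) - set(f.levels))
            raise ValueError(f"unknown level(s) {bad} in factor {f.name!r}")
        observed = set(col.dropna())
        missing = [lv for lv in f.levels if lv not in observed]
        if missing:
            raise ValueError(
                f"factor {f.name!r} has no rows for level(s) {missing}"
            )
        df[f.name] = col
    return df


def _design(df: pd.DataFrame, spec: ModelSpec):
    y, X = patsy.dmatrices(spec.formula(), df, return_type="dataframe")
    terms = [_clean_term(c) for c in X.columns]
    return np.asarray(y).ravel(), np.asarray(X), terms, X.index


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = sorted(terms[j] for j in piv[diag < tol])
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _cluster_indices(cluster: pd.Series) -> dict:
    groups: dict = {}
    codes, uniques = pd.factorize(cluster.to_numpy())
    for i, c in enumerate(codes):
        groups.setdefault(c, []).append(i)
    return {uniques[c]: np.asarray(ix) for c, ix in groups.items()}


def _fit_point(kind: str, y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, object]:
    if kind == "linear":
        res = sm.OLS(y, X).fit()
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return np.asarray(res.params), res


def _cluster_bootstrap(
    kind: str,
    y: np.ndarray,
    X: np.ndarray,
    cluster: pd.Series,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    groups = _cluster_indices(cluster)
    ids = list(groups)
    draws = np.empty((B, X.shape[1]))
    n_fail = 0
    for b in range(B):
        pick = rng.integers(0, len(ids), size=len(ids))
        idx = np.concatenate([groups[ids[i]] for i in pick])
        try:
            draws[b], _ = _fit_point(kind, y[idx], X[idx])
        except Exception:
            draws[b] = np.nan
            n_fail += 1
    if n_fail > B // 10:
        raise ConvergenceError(f"{n_fail}/{B} bootstrap refits failed")
    return draws


def _coef_table(
    terms: list[str],
    est: np.ndarray,
    boot: np.ndarray | None,
    model_se: np.ndarray,
    model_stat: np.ndarray,
    model_p: np.ndarray,
    model_ci: np.ndarray,
    part: str = "mean",
) -> pd.DataFrame:
    if boot is not None:
        se = np.nanstd(boot, axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, est / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(stat))
        ci_lo = np.nanpercentile(boot, 2.5, axis=0)
        ci_hi = np.nanpercentile(boot, 97.5, axis=0)
    else:
        se, stat, p = model_se, model_stat, model_p
        ci_lo, ci_hi = model_ci[:, 0], model_ci[:, 1]
    return pd.DataFrame(
        {
            "part": part,
            "term": terms,
            "estimate": est,
            "se": se,
            "stat": stat,
            "p": p,
            "ci_lo": ci_lo,
            "ci_hi": ci_hi,
        }
    )


# ---------------------------------------------------------------------------
# recall-accuracy and score models
# ---------------------------------------------------------------------------

def fit_recall_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    bootstrap: int = 1000,
    seed: int = 0,
    cluster: str = "participant_id",
) -> ModelFit:
    """Logistic fixed-effects fit of per-item recall outcomes.

    SEs come from a participant-cluster nonparametric bootstrap (``bootstrap``
    replicates; 0 falls back to model-based SEs).  Complete separation raises
    :class:`SeparationError` naming the offending term.
    """
    df = _prepare(data, spec)
    vals = pd.unique(df[spec.response].dropna())
    if not set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}:
        raise ValueError("recall outcomes must be binary 0/1")
    if len(vals) < 2:
        raise SeparationError(
            f"response {spec.response!r} is constant; the intercept separates perfectly"
        )
    y, X, terms, index = _design(df, spec)
    _check_rank(X, terms)
    est, res = _fit_point("binomial", y, X)
    bad = [t for t, b in zip(terms, est) if abs(b) > 12]
    if bad:
        raise SeparationError(f"separation suspected for term(s): {bad}")
    boot = None
    if bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
        boot = _cluster_bootstrap(
            "binomial", y, X, df.loc[index, cluster], bootstrap, rng
        )
    table = _coef_table(
        terms,
        est,
        boot,
        np.asarray(res.bse),
        np.asarray(res.tvalues),
        np.asarray(res.pvalues),
        np.asarray(res.conf_int()),
    )
    return ModelFit(
        model_kind="binomial",
        formula=spec.formula(),
        coefficients=table,
        llf=float(res.llf),
        converged=bool(res.converged) if hasattr(res, "converged") else True,
        n_obs=int(res.nobs),
        n_boot=bootstrap,
    )


def fit_score_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    percent_recall: bool = False,
    bootstrap: int = 1000,
    seed: int = 0,
    cluster: str = "participant_id",
) -> ModelFit:
    """OLS fixed-effects fit of temporal organization scores.

    Rows with undefined (NaN) scores are dropped.  With
    ``percent_recall=True`` the grand-mean-centered percent-recall covariate
    is added additively (``percent_recall_c``).
    """
    df = _prepare(data, spec)
    df = df[~df[spec.response].isna()]
    if percent_recall:
        if "percent_recall" not in df.columns:
            raise ValueError("percent_recall column required for the covariate model")
        df = df.copy()
        df["percent_recall_c"] = df["percent_recall"] - df["percent_recall"].mean()
        if "percent_recall_c" not in spec.covariates:
            spec = replace(spec, covariates=spec.covariates + ("percent_recall_c",))
    y, X, terms, index = _design(df, spec)
    _check_rank(X, terms)
    est, res = _fit_point("linear", y, X)
    boot = None
    if bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence((seed, 202)))
        boot = _cluster_bootstrap("linear", y, X, df.loc[index, cluster], bootstrap, rng)
    table = _coef_table(
        terms,
        est,
        boot,
        np.asarray(res.bse),
        np.asarray(res.tvalues),
        np.asarray(res.pvalues),
        np.asarray(res.conf_int()),
    )
    return ModelFit(
        model_kind="linear",
        formula=spec.formula(),
        coefficients=table,
        llf=float(res.llf),
        converged=True,
        n_obs=int(res.nobs),
        n_boot=bootstrap,
    )


# ---------------------------------------------------------------------------
# zero-inflated beta regression
# ---------------------------------------------------------------------------

ONE_ADJUST = 0.999


def adjust_ones(y, value: float = ONE_ADJUST) -> np.ndarray:
    """Replace CRP values of exactly 1 with ``value`` (default .999) so the
    beta component's open-interval support holds."""
    arr = np.asarray(y, dtype=float).copy()
    arr[arr == 1.0] = value
    return arr


def make_zib_data(crp_frame: pd.DataFrame, adjust: float | None = ONE_ADJUST) -> pd.DataFrame:
    """Prepare a long lag-CRP frame for the two-part model.

    Structurally impossible cells (``possible == 0``, CRP undefined) are
    excluded — they are not observed zeros.  CRPs of exactly 1 are adjusted
    to ``adjust`` unless ``adjust`` is None.
    """
    df = crp_frame[crp_frame["possible"] > 0].copy()
    if adjust is not None:
        df["crp"] = adjust_ones(df["crp"].to_numpy(), adjust)
    if "direction" not in df.columns:
        df["direction"] = np.where(df["lag"] > 0, 0.5, -0.5)
    if "abs_lag" not in df.columns:
        df["abs_lag"] = df["lag"].abs()
    return df.reset_index(drop=True)


def _logistic_irls(X: np.ndarray, z: np.ndarray, tol: float = 1e-10, maxit: int = 100):
    beta = np.zeros(X.shape[1])
    converged = False
    H = np.eye(X.shape[1])
    for _ in range(maxit):
        mu = np.clip(special.expit(X @ beta), 1e-12, 1 - 1e-12)
        grad = X.T @ (z - mu)
        w = mu * (1 - mu)
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = np.clip(special.expit(X @ beta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(z * np.log(mu) + (1 - z) * np.log1p(-mu)))
    grad_norm = float(np.max(np.abs(X.T @ (z - mu))))
    if not converged:
        raise ConvergenceError(
            f"zero part did not converge (max |gradient| = {grad_norm:.3g})"
        )
    cov = np.linalg.pinv(H)
    return beta, cov, ll


def _beta_part_nll(params, Xp, ly, l1y, ystar, link):
    b, lphi = params[:-1], params[-1]
    phi = math.exp(min(lphi, 30.0))
    eta = Xp @ b
    if link == "logit":
        mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-9)
        dmu = mu * (1 - mu)
    else:  # log link; clamp keeps mu inside the unit interval
        mu = np.clip(np.exp(np.clip(eta, -30, 0.0)), 1e-12, 1 - 1e-9)
        dmu = mu
    a = mu * phi
    c = (1 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(c)
        + (a - 1) * ly
        + (c - 1) * l1y
    )
    mustar = special.digamma(a) - special.digamma(c)
    gb = Xp.T @ (phi * (ystar - mustar) * dmu)
    glphi = phi * np.sum(
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1 - mu) * special.digamma(c)
        + mu * ly
        + (1 - mu) * l1y
    )
    return -ll, -np.concatenate([gb, [glphi]])


def _hessian_from_grad(grad_fn, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Observed information via central differences of the analytic gradient
    (2p gradient evaluations instead of O(p^2) function evaluations)."""
    p = x.size
    H = np.empty((p, p))
    for j in range(p):
        step = eps * max(1.0, abs(x[j]))
        dx = np.zeros(p)
        dx[j] = step
        H[:, j] = (grad_fn(x + dx) - grad_fn(x - dx)) / (2 * step)
    return (H + H.T) / 2.0


def fit_zib(
    data: pd.DataFrame,
    spec: ModelSpec,
    *,
    link: str = "logit",
    seed: int = 0,
) -> ModelFit:
    """Two-part zero-inflated beta regression by maximum likelihood.

    Part ``zero``: logit model for P(y = 0).  Part ``beta``: for y > 0,
    y ~ Beta(mu*phi, (1-mu)*phi) with ``link`` on mu (``logit`` default,
    ``log`` selectable) and constant precision phi.  The factorized
    likelihood is maximized part-by-part; the reported log-likelihood is the
    sum.  Inputs must satisfy 0 <= y < 1 — apply the .999 one-adjustment
    (:func:`adjust_ones` / :func:`make_zib_data`) first.
    """
    if link not in ("logit", "log"):
        raise ValueError("link must be 'logit' or 'log'")
    df = _prepare(data, spec)
    y_raw = df[spec.response].to_numpy(dtype=float)
    if np.isnan(y_raw).any():
        raise ValueError(
            "undefined CRP values present; drop possible == 0 cells first "
            "(make_zib_data)"
        )
    if (y_raw >= 1).any():
        raise ValueError(
            "response contains values of exactly 1; adjust them to .999 "
            "(adjust_ones / make_zib_data) before fitting"
        )
    if (y_raw < 0).any():
        raise ValueError("response values must lie in [0, 1)")
    _, X, terms, _ = _design(df, spec)
    _check_rank(X, terms)
    y = y_raw

    # zero part
    z = (y == 0).astype(float)
    if z.min() == z.max():
        raise SeparationError("zero indicator is constant; zero part is degenerate")
    beta0, cov0, ll0 = _logistic_irls(X, z)
    se0 = np.sqrt(np.diag(cov0))

    # beta part on positives
    pos = y > 0
    Xp = X[pos]
    yp = y[pos]
    if yp.size <= X.shape[1] + 1:
        raise ValueError("too few positive observations for the beta part")
    ly = np.log(yp)
    l1y = np.log1p(-yp)
    ystar = ly - l1y
    mean_pos = float(yp.mean())
    eta0 = (
        math.log(mean_pos / (1 - mean_pos)) if link == "logit" else math.log(mean_pos)
    )
    var_pos = float(yp.var()) or 1e-4
    phi0 = np.clip(mean_pos * (1 - mean_pos) / var_pos - 1, 0.5, 500.0)
    x0 = np.zeros(X.shape[1] + 1)
    x0[0] = eta0
    x0[-1] = math.log(phi0)
    # phi is bounded above so that a degenerate zero-variance positive part
    # (phi -> inf) terminates at the bound instead of diverging
    lphi_max = math.log(1e6)
    bounds = [(None, None)] * X.shape[1] + [(math.log(1e-2), lphi_max)]
    res = optimize.minimize(
        _beta_part_nll,
        x0,
        args=(Xp, ly, l1y, ystar, link),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "maxfun": 5000},
    )
    grad = np.asarray(res.jac, dtype=float).copy()
    if res.x[-1] >= lphi_max - 1e-6 and grad[-1] < 0:
        grad[-1] = 0.0  # pressing against the phi bound, not a failure
    grad_norm = float(np.max(np.abs(grad)))
    if not res.success and grad_norm > 1e-3 * (1 + abs(res.fun)):
        raise ConvergenceError(
            f"beta part did not converge (max |gradient| = {grad_norm:.3g})"
        )
    hess = _hessian_from_grad(
        lambda p: _beta_part_nll(p, Xp, ly, l1y, ystar, link)[1], res.x
    )
    try:
        covb = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        covb = np.linalg.pinv(hess)
    seb = np.sqrt(np.clip(np.diag(covb), 0, None))
    bhat = res.x[:-1]
    phi_hat = math.exp(res.x[-1])
    ll_beta = -float(res.fun)

    def _rows(part, terms_, est, se):
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(se > 0, est / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(stat))
        return pd.DataFrame(
            {
                "part": part,
                "term": terms_,
                "estimate": est,
                "se": se,
                "stat": stat,
                "p": p,
                "ci_lo": est - 1.959963984540054 * se,
                "ci_hi": est + 1.959963984540054 * se,
            }
        )

    table = pd.concat(
        [
            _rows("zero", terms, beta0, se0),
            _rows("beta", terms, bhat, seb[:-1]),
            _rows("precision", ["(phi)"], np.array([phi_hat]), np.array([phi_hat * seb[-1]])),
        ],
        ignore_index=True,
    )
    return ModelFit(
        model_kind="zib",
        formula=f"{spec.formula()} [zero ~ logit; beta mean link {link}]",
        coefficients=table,
        llf=ll0 + ll_beta,
        converged=True,
        n_obs=int(y.size),
        n_boot=0,
        meta={"phi": phi_hat, "link": link, "n_zero": int(z.sum()), "n_pos": int(pos.sum())},
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _timepoint_reference(task: str, levels: tuple[str, ...]) -> str:
    if task == "narrative" and "No Delay" in levels:
        return "No Delay"
    if task == "wordlist" and "Trial 5" in levels:
        return "Trial 5"
    return levels[0]


def _ordered_timepoints(task: str, observed) -> tuple[str, ...]:
    canonical = TIMEPOINT_ORDER.get(task)
    observed = list(dict.fromkeys(observed))
    if canonical:
        ordered = [tp for tp in canonical if tp in observed]
        ordered += [tp for tp in observed if tp not in ordered]
        return tuple(ordered)
    return tuple(observed)


def run_full_analysis(
    dataset,
    config: RunConfig | None = None,
    *,
    expected_groups: tuple[str, ...] = ("NC", "TBI"),
    group_reference: str = "NC",
    percent_recall_models: bool = True,
) -> dict:
    """Run the whole analysis chain on a dataset and return a report bundle.

    ``dataset`` is anything with ``recalls`` and ``manifest`` DataFrames (a
    SyntheticDataset) or a ``(recalls, manifest)`` tuple.  Stages: chance
    t tests by group and by timepoint, recall-accuracy logistic models,
    score models with and without the percent-recall covariate, and the
    zero-inflated beta model of lag-CRP values — each per task.  The bundle
    holds ``scores``, ``crp``, ``fits`` DataFrames, the fitted ``models`` and
    a ``manifest`` dict (seed, config hash, counts).
    """
    config = config or RunConfig()
    if hasattr(dataset, "recalls"):
        recalls, manifest = dataset.recalls, dataset.manifest
    else:
        recalls, manifest = dataset
    studies = {
        str(r.unit_id): StudyList(unit_id=str(r.unit_id), n_items=int(r.n_items))
        for r in manifest.itertuples()
    }
    present = set(recalls["group"].astype(str))
    for g in expected_groups:
        if g not in present:
            raise ValueError(f"no data for group {g!r}")
    seqs, report = sequences_from_frame(
        recalls, studies, repeat_policy=config.repeat_policy
    )

    all_scores: list[pd.DataFrame] = []
    all_crp: list[pd.DataFrame] = []
    fit_rows: list[pd.DataFrame] = []
    models: dict[str, ModelFit] = {}
    chance_rows: list[dict] = []

    tasks = sorted({s.task for s in seqs})
    for task in tasks:
        task_seqs = [s for s in seqs if s.task == task]
        tps = _ordered_timepoints(task, (s.timepoint for s in task_seqs))
        tp_ref = _timepoint_reference(task, tps)
        scores_df, crp_df = sequence_metrics(task_seqs, studies, config.max_lag)
        all_scores.append(scores_df)
        all_crp.append(crp_df)

        # chance tests by group and by timepoint
        for by in ("group", "timepoint"):
            order = expected_groups if by == "group" else tps
            for level in order:
                sub = scores_df.loc[scores_df[by] == level, "score"].dropna()
                if len(sub) < 2 or float(sub.std(ddof=1)) == 0:
                    continue
                res = one_sample_t(sub)
                chance_rows.append(
                    {
                        "model": "chance_t",
                        "task": task,
                        "part": by,
                        "term": level,
                        "estimate": res.mean,
                        "se": res.sd / math.sqrt(res.df + 1),
                        "stat": res.t,
                        "p": res.p,
                        "ci_lo": np.nan,
                        "ci_hi": np.nan,
                    }
                )

        group_factor = FactorSpec("group", tuple(expected_groups), group_reference)
        tp_factor = FactorSpec("timepoint", tps, tp_ref)

        items = item_outcomes(
            recalls[recalls["task"].astype(str) == task],
            manifest[manifest["unit_id"].astype(str).isin({s.unit_id for s in task_seqs})]
            if "unit_id" in manifest
            else manifest,
        )
        recall_fit = fit_recall_model(
            items,
            ModelSpec("recalled", (group_factor, tp_factor)),
            bootstrap=config.bootstrap_B,
            seed=config.seed,
        )
        models[f"recall_{task}"] = recall_fit

        score_spec = ModelSpec("score", (group_factor, tp_factor))
        score_fit = fit_score_model(
            scores_df,
            score_spec,
            bootstrap=config.bootstrap_B,
            seed=config.seed,
        )
        models[f"score_{task}"] = score_fit
        if percent_recall_models:
            models[f"score_{task}_pr"] = fit_score_model(
                scores_df,
                score_spec,
                percent_recall=True,
                bootstrap=config.bootstrap_B,
                seed=config.seed,
            )

        zib_data = make_zib_data(crp_df)
        zib_spec = ModelSpec(
            "crp", (group_factor, tp_factor), numeric=("abs_lag", "direction")
        )
        models[f"zib_{task}"] = fit_zib(
            zib_data, zib_spec, link=config.beta_link, seed=config.seed
        )

    for name, fit in models.items():
        tbl = fit.coefficients.copy()
        tbl.insert(0, "model", name)
        tbl.insert(1, "task", name.split("_", 1)[1].replace("_pr", ""))
        fit_rows.append(tbl)
    fits = pd.concat(
        [pd.DataFrame(chance_rows, columns=[
            "model", "task", "part", "term", "estimate", "se", "stat", "p",
            "ci_lo", "ci_hi",
        ])] + fit_rows,
        ignore_index=True,
    )

    import contiguity

    cfg_dict = {
        "max_lag": config.max_lag,
        "repeat_policy": config.repeat_policy,
        "beta_link": config.beta_link,
        "bootstrap_B": config.bootstrap_B,
        "seed": config.seed,
    }
    bundle = {
        "scores": pd.concat(all_scores, ignore_index=True),
        "crp": pd.concat(all_crp, ignore_index=True),
        "fits": fits,
        "models": models,
        "manifest": {
            "seed": config.seed,
            "config": cfg_dict,
            "config_hash": config_hash(cfg_dict),
            "versions": {
                "contiguity": contiguity.__version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
                "statsmodels": __import__("statsmodels").__version__,
            },
            "input": report,
            "models": {
                name: {
                    "llf": float(fit.llf),
                    "converged": bool(fit.converged),
                    "n_obs": int(fit.n_obs),
                    "n_boot": int(fit.n_boot),
                }
                for name, fit in models.items()
            },
        },
    }
    return bundle
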