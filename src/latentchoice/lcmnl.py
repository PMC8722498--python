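"""Latent class multinomial logit (MNL) estimation for choice-task data.

The model is a finite mixture of conditional logits.  Respondent ``i`` belongs
to latent class ``c`` with probability ``pi_c``; within class ``c`` the
probability of picking option ``j`` in a task is the softmax of the option
utilities ``x_j' beta_c``, where ``x_j`` effects-codes the profile's attribute
levels (the last level of each attribute is the implied reference whose
coefficient is the negative sum of the others) and the opt-out option carries
a single alternative-specific constant per class.

Estimation alternates an E-step (posterior class-membership probabilities from
current parameters) with an M-step (per-class conditional logits weighted by
the posterior columns, and mixing shares set to the posterior means), run from
several random starting points with the highest-likelihood replication kept.
The M-step maximizes each weighted log-likelihood by damped Newton iteration
with analytic gradient and Hessian, warm-started from the previous EM
iteration, so the mixture log-likelihood is non-decreasing across iterations.

The estimator :class:`LatentClassMNL` follows scikit-learn conventions
(``fit`` / ``predict_proba`` / ``get_params``; fitted attributes end in an
underscore) and accepts either a long-format ``pandas.DataFrame`` or a
:class:`ChoiceData`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .design import NONE_LABEL, AttributeSpec, Design, DesignConfig, DesignError

__all__ = [
    "ChoiceData",
    "EMConfig",
    "WeightedMNLFit",
    "fit_weighted_mnl",
    "e_step",
    "em_fit",
    "sweep_classes",
    "LatentClassMNL",
    "match_classes",
]


class ConvergenceError(RuntimeError):
    """Raised when an optimization cannot reach the requested tolerance."""


# ---------------------------------------------------------------------------
# data container


class ChoiceData:
    """Vectorized choice observations: effects-coded design tensor plus choices.

    Attributes
    ----------
    X : (n_tasks, 3, n_features) effects-coded option features; options are
        (alternative 1, alternative 2, NONE), the last feature is the opt-out
        indicator.
    chosen : (n_tasks,) index in {0, 1, 2} of the chosen option.
    resp_idx : (n_tasks,) 0-based respondent index.
    """

    def __init__(
        self,
        attributes: Sequence[AttributeSpec],
        codes: np.ndarray,
        chosen: np.ndarray,
        resp_idx: np.ndarray,
        respondent_ids: np.ndarray,
    ) -> None:
        self.attributes = list(attributes)
        self.codes = np.asarray(codes, dtype=np.int64)
        self.chosen = np.asarray(chosen, dtype=np.int64)
        self.resp_idx = np.asarray(resp_idx, dtype=np.int64)
        self.respondent_ids = np.asarray(respondent_ids)
        if self.chosen.min() < 0 or self.chosen.max() > 2:
            raise ValueError("chosen option index must be 0, 1, or 2")
        self.n_tasks = self.codes.shape[0]
        self.n_respondents = len(self.respondent_ids)
        self.X = _effects_tensor(self.codes, self.attributes)
        self.n_features = self.X.shape[2]
        # flattened views used by the likelihood kernels
        self._X2d = self.X.reshape(self.n_tasks * 3, self.n_features)
        self._rows = np.arange(self.n_tasks)

    @classmethod
    def from_design(
        cls, design: Design, chosen: np.ndarray
    ) -> "ChoiceData":
        return cls(
            design.attributes,
            design.codes,
            chosen,
            design.respondent_ids - design.respondent_ids.min(),
            np.unique(design.respondent_ids),
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        attributes: Sequence[AttributeSpec] | None = None,
    ) -> "ChoiceData":
        """Build from a long-format table (respondent_id, task, alternative,
        chosen, one column per attribute)."""
        if attributes is None:
            attributes = DesignConfig().attributes
        required = {"respondent_id", "task", "alternative", "chosen"}
        missing = required - set(frame.columns)
        if missing:
            raise DesignError(f"missing columns: {sorted(missing)}")
        frame = frame.copy()
        frame["alternative"] = frame["alternative"].astype(str)
        alt_order = {"1": 0, "2": 1, NONE_LABEL: 2}
        if not frame["alternative"].isin(alt_order).all():
            bad = sorted(set(frame["alternative"]) - set(alt_order))
            raise DesignError(f"unknown alternative labels: {bad}")
        frame["_opt"] = frame["alternative"].map(alt_order)
        frame = frame.sort_values(["respondent_id", "task", "_opt"], kind="stable")
        n_rows = len(frame)
        if n_rows % 3:
            raise DesignError("each task must have exactly 3 option rows (1, 2, NONE)")
        n_tasks = n_rows // 3
        opts = frame["_opt"].to_numpy().reshape(n_tasks, 3)
        if not (opts == np.array([0, 1, 2])).all():
            raise DesignError("each task must have exactly the option rows 1, 2, NONE")

        codes = np.empty((n_tasks, 2, len(attributes)), dtype=np.int64)
        for j, attr in enumerate(attributes):
            labels = frame[attr.name].to_numpy(dtype=object).reshape(n_tasks, 3)[:, :2]
            lut = {lvl: k for k, lvl in enumerate(attr.levels)}
            try:
                codes[:, :, j] = np.vectorize(lut.__getitem__, otypes=[np.int64])(labels)
            except KeyError as err:
                raise DesignError(
                    f"unknown level {err.args[0]!r} for attribute {attr.name!r}"
                ) from None
        chosen_mat = frame["chosen"].to_numpy(dtype=np.int64).reshape(n_tasks, 3)
        if not (chosen_mat.sum(axis=1) == 1).all():
            raise DesignError("each task must have exactly one chosen option")
        chosen = chosen_mat.argmax(axis=1)
        resp = frame["respondent_id"].to_numpy().reshape(n_tasks, 3)[:, 0]
        respondent_ids, resp_idx = np.unique(resp, return_inverse=True)
        return cls(attributes, codes, chosen, resp_idx, respondent_ids)

    def subset(self, keep_respondents: np.ndarray) -> "ChoiceData":
        """Restrict to a boolean mask (or id list) over respondents."""
        keep = np.asarray(keep_respondents)
        if keep.dtype != bool:
            keep = np.isin(self.respondent_ids, keep)
        task_mask = keep[self.resp_idx]
        ids = self.respondent_ids[keep]
        return ChoiceData(
            self.attributes,
            self.codes[task_mask],
            self.chosen[task_mask],
            np.searchsorted(np.flatnonzero(keep), self.resp_idx[task_mask]),
            ids,
        )


def _effects_tensor(codes: np.ndarray, attributes: Sequence[AttributeSpec]) -> np.ndarray:
    """Effects-coded feature tensor (n_tasks, 3, sum(L-1) + 1)."""
    n_tasks = codes.shape[0]
    n_free = sum(a.n_levels - 1 for a in attributes)
    X = np.zeros((n_tasks, 3, n_free + 1))
    offset = 0
    for j, attr in enumerate(attributes):
        L = attr.n_levels
        for alt in (0, 1):
            c = codes[:, alt, j]
            rows = np.arange(n_tasks)
            free = c < L - 1
            X[rows[free], alt, offset + c[free]] = 1.0
            X[rows[~free], alt, offset : offset + L - 1] = -1.0
        offset += L - 1
    X[:, 2, -1] = 1.0  # opt-out constant
    return X


def expand_coefficients(
    beta: np.ndarray, attributes: Sequence[AttributeSpec]
) -> tuple[np.ndarray, float]:
    """Expand free effects-coded coefficients to full zero-centered level
    utilities; returns (level utilities in design order, opt-out constant)."""
    beta = np.asarray(beta, dtype=float)
    out = []
    offset = 0
    for attr in attributes:
        free = beta[offset : offset + attr.n_levels - 1]
        out.append(np.concatenate([free, [-free.sum()]]))
        offset += attr.n_levels - 1
    return np.concatenate(out), float(beta[-1])


# ---------------------------------------------------------------------------
# weighted conditional logit (M-step kernel)


@dataclass
class WeightedMNLFit:
    """Result of one weighted conditional-logit maximization."""

    beta: np.ndarray
    loglik: float
    se: np.ndarray
    n_iter: int
    converged: bool
    grad_norm: float


def _loglik_parts(
    data: ChoiceData, beta: np.ndarray, w_task: np.ndarray, order: int
):
    """Weighted conditional-logit log-likelihood and derivatives.

    order 0: ll only; 1: +gradient; 2: +Hessian (of the log-likelihood, so the
    Hessian is negative definite).
    """
    U = (data._X2d @ beta).reshape(data.n_tasks, 3)
    m = U.max(axis=1, keepdims=True)
    E = np.exp(U - m)
    S = E.sum(axis=1)
    ll = float(np.sum(w_task * (U[data._rows, data.chosen] - m[:, 0] - np.log(S))))
    if order == 0:
        return ll, None, None
    P = E / S[:, None]
    R = P.copy()
    R[data._rows, data.chosen] -= 1.0  # d(-ll)/dU
    g = -((w_task[:, None] * R).reshape(1, -1) @ data._X2d).ravel()
    if order == 1:
        return ll, g, None
    # H = X' diag(wP) X - sum_t w_t mu_t mu_t',  mu_t = sum_j P_tj x_tj
    wp = (w_task[:, None] * P).ravel()
    H = data._X2d.T @ (wp[:, None] * data._X2d)
    mu = np.einsum("tj,tjf->tf", P, data.X)
    H -= (w_task[:, None] * mu).T @ mu
    return ll, g, -H


def fit_weighted_mnl(
    data: ChoiceData,
    weights: np.ndarray | None = None,
    beta0: np.ndarray | None = None,
    gtol_scale: float = 1e-7,
    max_iter: int = 100,
    compute_se: bool = True,
) -> WeightedMNLFit:
    """Maximize the respondent-weighted conditional-logit log-likelihood.

    Damped Newton iteration with analytic gradient/Hessian.  Standard errors
    come from the inverse observed information at the optimum.

    Raises :class:`ConvergenceError` with diagnostics on non-convergence
    (e.g. quasi-separation driving coefficients to infinity).
    """
    if weights is None:
        weights = np.ones(data.n_respondents)
    weights = np.asarray(weights, dtype=float)
    if weights.min() < 0 or weights.max() <= 0:
        raise ValueError("weights must be >= 0 with at least one positive")
    w_task = weights[data.resp_idx]
    beta = np.zeros(data.n_features) if beta0 is None else np.array(beta0, dtype=float)
    gtol = gtol_scale * max(1.0, float(w_task.sum()))

    ll, g, H = _loglik_parts(data, beta, w_task, order=2)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.abs(g).max())
        if gnorm < gtol:
            converged = True
            break
        A = -H
        A[np.diag_indices_from(A)] += 1e-10 * (1.0 + np.trace(A) / A.shape[0])
        try:
            step = cho_solve(cho_factor(A), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(A, g, rcond=None)[0]
        lam = 1.0
        while lam > 1e-10:
            cand = beta + lam * step
            ll_new, _, _ = _loglik_parts(data, cand, w_task, order=0)
            if ll_new >= ll - 1e-12:
                break
            lam *= 0.5
        else:
            break  # no ascent direction left; report at current point
        if not np.isfinite(ll_new):
            raise ConvergenceError(
                f"weighted MNL diverged (non-finite log-likelihood at iteration {it}); "
                "possible separation in the choice data"
            )
        beta = cand
        ll, g, H = _loglik_parts(data, beta, w_task, order=2)
        if ll_new < ll - 1e-6:  # pragma: no cover - defensive
            break

    gnorm = float(np.abs(g).max())
    converged = converged or gnorm < gtol
    if compute_se:
        A = -H
        A[np.diag_indices_from(A)] += 1e-12 * (1.0 + np.trace(A) / A.shape[0])
        try:
            cov = np.linalg.inv(A)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:  # pragma: no cover
            se = np.full(data.n_features, np.nan)
    else:
        se = np.full(data.n_features, np.nan)
    return WeightedMNLFit(beta=beta, loglik=ll, se=se, n_iter=it, converged=converged, grad_norm=gnorm)


# ---------------------------------------------------------------------------
# E-step and EM


def _respondent_class_loglik(
    data: ChoiceData, betas: np.ndarray
) -> np.ndarray:
    """(n_respondents, K) log-likelihood of each respondent's choices per class."""
    K = betas.shape[0]
    out = np.empty((data.n_respondents, K))
    for c in range(K):
        U = (data._X2d @ betas[c]).reshape(data.n_tasks, 3)
        m = U.max(axis=1)
        lp = U[data._rows, data.chosen] - m - np.log(np.exp(U - m[:, None]).sum(axis=1))
        out[:, c] = np.bincount(data.resp_idx, weights=lp, minlength=data.n_respondents)
    return out


def e_step(
    data: ChoiceData, shares: np.ndarray, betas: np.ndarray
) -> tuple[np.ndarray, float]:
    """Posterior class memberships and the mixture log-likelihood.

    posterior(i, c) is proportional to ``pi_c`` times the product over
    respondent i's tasks of the class-c probability of the observed choice;
    accumulation is done in the log domain.
    """
    shares = np.asarray(shares, dtype=float)
    log_joint = _respondent_class_loglik(data, np.asarray(betas)) + np.log(shares)[None, :]
    lse = logsumexp(log_joint, axis=1)
    post = np.exp(log_joint - lse[:, None])
    return post, float(lse.sum())


@dataclass
class EMConfig:
    """EM estimation settings: class count, restarts, convergence rule."""

    n_classes: int = 5
    max_iter: int = 100
    n_replications: int = 5
    tol: float = 1e-6
    random_state: int | None = 0
    collapse_tol: float = 1e-6
    max_restarts: int = 10
    newton_max_iter: int = 40

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.max_iter < 1 or self.tol <= 0:
            raise ValueError("invalid EM configuration")


@dataclass
class FittedModel:
    """A fitted latent class MNL (internal result record)."""

    attributes: list[AttributeSpec]
    shares: np.ndarray  # (K,)
    betas: np.ndarray  # (K, n_features)
    loglik: float
    n_parameters: int
    aic: float
    bic: float
    posteriors: np.ndarray  # (n_respondents, K)
    respondent_ids: np.ndarray
    convergence: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(self.shares)

    def expanded_utilities(self) -> tuple[np.ndarray, np.ndarray]:
        """Zero-centered level utilities (K, total_levels) and opt-out constants (K,)."""
        rows, none = [], []
        for beta in self.betas:
            u, c = expand_coefficients(beta, self.attributes)
            rows.append(u)
            none.append(c)
        return np.stack(rows), np.asarray(none)


class _Collapse(Exception):
    pass


def _em_once(
    data: ChoiceData, config: EMConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, dict]:
    rng = np.random.default_rng(seed)
    K = config.n_classes
    post = rng.dirichlet(np.ones(K), size=data.n_respondents)
    betas = np.zeros((K, data.n_features))
    ll_prev = -np.inf
    ll = -np.inf
    trace = []
    for it in range(1, config.max_iter + 1):
        shares = post.mean(axis=0)
        if shares.min() < config.collapse_tol:
            raise _Collapse(f"class share collapsed to {shares.min():.2e} at iteration {it}")
        for c in range(K):
            fit = fit_weighted_mnl(
                data, post[:, c], beta0=betas[c],
                max_iter=config.newton_max_iter, compute_se=False,
            )
            betas[c] = fit.beta
        post, ll = e_step(data, shares, betas)
        trace.append(ll)
        if ll - ll_prev < config.tol and it > 1:
            break
        ll_prev = ll
    delta = trace[-1] - trace[-2] if len(trace) > 1 else np.inf
    info = {"iterations": len(trace), "final_delta": delta, "seed": seed, "ll_trace": trace}
    return shares, betas, ll, post, info


def em_fit(data: ChoiceData, config: EMConfig) -> FittedModel:
    """Fit the latent class MNL by EM with random restarts.

    Each replication starts from a random Dirichlet posterior assignment; the
    replication with the highest mixture log-likelihood is returned.  A
    replication whose smallest mixing share collapses below ``collapse_tol``
    is restarted from a fresh seed (bounded by ``max_restarts``), and the
    restart is recorded in the convergence log.
    """
    if data.n_respondents < config.n_classes:
        raise ValueError("need at least one respondent per class")
    root = np.random.default_rng(config.random_state)
    best = None
    replication_log = []
    for rep in range(config.n_replications):
        restarts = 0
        while True:
            seed = int(root.integers(0, 2**31 - 1))
            try:
                shares, betas, ll, post, info = _em_once(data, config, seed)
                break
            except _Collapse as err:
                restarts += 1
                replication_log.append({"replication": rep, "seed": seed, "collapsed": str(err)})
                if restarts > config.max_restarts:
                    raise ConvergenceError(
                        f"replication {rep}: class collapse persisted over "
                        f"{config.max_restarts} restarts"
                    ) from err
        info.update(replication=rep, restarts=restarts)
        replication_log.append({k: v for k, v in info.items() if k != "ll_trace"})
        if best is None or ll > best[2]:
            best = (shares, betas, ll, post, info)
    shares, betas, ll, post, info = best

    # report classes ordered by descending mixing share
    order = np.argsort(-shares, kind="stable")
    shares, betas, post = shares[order], betas[order], post[:, order]

    k_params = config.n_classes * data.n_features + (config.n_classes - 1)
    n = data.n_respondents
    model = FittedModel(
        attributes=data.attributes,
        shares=shares,
        betas=betas,
        loglik=ll,
        n_parameters=k_params,
        aic=-2.0 * ll + 2.0 * k_params,
        bic=-2.0 * ll + k_params * np.log(n),
        posteriors=post,
        respondent_ids=data.respondent_ids,
        convergence={"best": info, "replications": replication_log},
    )
    return model


def sweep_classes(
    data: ChoiceData,
    k_values: Sequence[int] = tuple(range(2, 11)),
    config: EMConfig | None = None,
) -> pd.DataFrame:
    """Model-selection sweep over class counts.

    One row per K: log-likelihood, parameter count, AIC = -2LL + 2k,
    BIC = -2LL + k ln(n_respondents), and the smallest class share.  A K whose
    fit fails is reported with NaNs rather than aborting the sweep.
    """
    base = config or EMConfig()
    rows = []
    for k in k_values:
        cfg = EMConfig(
            n_classes=k,
            max_iter=base.max_iter,
            n_replications=base.n_replications,
            tol=base.tol,
            random_state=base.random_state,
            collapse_tol=base.collapse_tol,
            max_restarts=base.max_restarts,
            newton_max_iter=base.newton_max_iter,
        )
        try:
            model = em_fit(data, cfg)
            rows.append(
                {
                    "n_classes": k,
                    "loglik": model.loglik,
                    "n_parameters": model.n_parameters,
                    "aic": model.aic,
                    "bic": model.bic,
                    "min_class_share": float(model.shares.min()),
                    "error": "",
                }
            )
        except Exception as err:  # propagate per-K without aborting
            rows.append(
                {
                    "n_classes": k,
                    "loglik": np.nan,
                    "n_parameters": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "min_class_share": np.nan,
                    "error": f"{type(err).__name__}: {err}",
                }
            )
    return pd.DataFrame(rows)


def match_classes(
    estimated: np.ndarray, truth: np.ndarray
) -> np.ndarray:
    """Match estimated classes to reference classes by utility correlation.

    Hungarian assignment on negative Pearson correlation between flattened
    utility vectors; returns ``perm`` with ``perm[est_class] = true_class``.
    """
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(truth, dtype=float)
    ez = (est - est.mean(axis=1, keepdims=True)) / est.std(axis=1, keepdims=True)
    rz = (ref - ref.mean(axis=1, keepdims=True)) / ref.std(axis=1, keepdims=True)
    corr = ez @ rz.T / est.shape[1]
    rows, cols = linear_sum_assignment(-corr)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return perm


# ---------------------------------------------------------------------------
# scikit-learn estimator


class LatentClassMNL(BaseEstimator):
    """Latent class multinomial logit estimator (scikit-learn style).

    Parameters
    ----------
    n_classes : number of latent classes K.
    n_replications : random EM restarts; the best log-likelihood wins.
    max_iter : EM iteration cap per replication.
    tol : stop when the log-likelihood improves by less than this.
    random_state : seed for the replication starting points.

    Fitted attributes
    -----------------
    class_shares_ : (K,) mixing proportions, descending.
    coefficients_ : (K, n_features) free effects-coded coefficients per class
        (last entry of each row is the opt-out constant).
    utilities_ : (K, total_levels) zero-centered level utilities.
    none_utilities_ : (K,) opt-out constants.
    posteriors_ : (n_respondents, K) posterior memberships.
    log_likelihood_, aic_, bic_, n_parameters_, n_iter_, convergence_.
    """

    def __init__(
        self,
        n_classes: int = 5,
        n_replications: int = 5,
        max_iter: int = 100,
        tol: float = 1e-6,
        random_state: int | None = 0,
    ) -> None:
        self.n_classes = n_classes
        self.n_replications = n_replications
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def _as_data(self, X) -> ChoiceData:
        if isinstance(X, ChoiceData):
            return X
        if isinstance(X, pd.DataFrame):
            return ChoiceData.from_frame(X)
        raise TypeError("X must be a ChoiceData or a long-format DataFrame")

    def fit(self, X, y=None) -> "LatentClassMNL":
        data = self._as_data(X)
        config = EMConfig(
            n_classes=self.n_classes,
            max_iter=self.max_iter,
            n_replications=self.n_replications,
            tol=self.tol,
            random_state=self.random_state,
        )
        model = em_fit(data, config)
        self.model_ = model
        self.attributes_ = model.attributes
        self.class_shares_ = model.shares
        self.coefficients_ = model.betas
        self.utilities_, self.none_utilities_ = model.expanded_utilities()
        self.posteriors_ = model.posteriors
        self.respondent_ids_ = model.respondent_ids
        self.log_likelihood_ = model.loglik
        self.aic_ = model.aic
        self.bic_ = model.bic
        self.n_parameters_ = model.n_parameters
        self.n_iter_ = model.convergence["best"]["iterations"]
        self.convergence_ = model.convergence
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Posterior class memberships for (possibly new) respondents."""
        check_is_fitted(self, "model_")
        data = self._as_data(X)
        post, _ = e_step(data, self.class_shares_, self.coefficients_)
        return post

    def predict(self, X) -> np.ndarray:
        """Max-posterior class index per respondent (ties toward lower index)."""
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X, y=None) -> float:
        """Mean mixture log-likelihood per respondent."""
        check_is_fitted(self, "model_")
        data = self._as_data(X)
        _, ll = e_step(data, self.class_shares_, self.coefficients_)
        return ll / data.n_respondents

    def part_worths(self) -> pd.DataFrame:
        """Tidy per-class zero-centered utilities (one row per class x level,
        plus the opt-out constant rows)."""
        check_is_fitted(self, "model_")
        rows = []
        for c in range(len(self.class_shares_)):
            offset = 0
            for attr in self.attributes_:
                for lvl in attr.levels:
                    rows.append(
                        {
                            "class": c,
                            "attribute": attr.name,
                            "level": lvl,
                            "utility": self.utilities_[c, offset],
                        }
                    )
                    offset += 1
            rows.append(
                {
                    "class": c,
                    "attribute": NONE_LABEL,
                    "level": NONE_LABEL,
                    "utility": self.none_utilities_[c],
                }
            )
        return pd.DataFrame(rows)
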