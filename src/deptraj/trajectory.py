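"""Latent-class trajectory models on fractional-polynomial bases.

Two model families are provided, both finite mixtures of Gaussian
regressions of the repeated symptom score on a fractional-polynomial
function of age:

* group-based trajectory model (GBTM): within a class, occasions are
  independent around the class curve (no random effects);
* growth mixture model (GMM) with a subject-level random intercept whose
  variance is either common across classes or scaled per class by a
  proportionality multiplier (reference class fixed at 1).

For subject i with observed score vector y_i and design X_i, the marginal
log-likelihood is

    l = sum_i log sum_g pi_g N(y_i; X_i beta_g, V_ig),
    V_ig = omega_g^2 tau^2 11' + sigma^2 I   (GBTM: tau = 0)

Mixing proportions pi are softmax-parameterised.  Estimation is maximum
likelihood with a multistart scheme: many short runs from randomly
perturbed single-class starts, then the best start is run to convergence.
GBTM uses EM with closed-form M-steps (the likelihood is monitored and an
EM decrease is an error); the random-intercept variants optimise the
marginal likelihood directly by quasi-Newton with variance components
log-parameterised.  Classes are reported in descending order of pi.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .basis import FPBasis, build_fp_basis

logger = logging.getLogger(__name__)

RANDOM_EFFECT_STRUCTURES = ("none", "common_intercept", "class_proportional_intercept")

_LOG2PI = float(np.log(2.0 * np.pi))


class FitValidationError(ValueError):
    """The data or model specification is unusable for fitting."""


class EMMonotonicityError(RuntimeError):
    """The EM objective decreased beyond numerical tolerance."""


@dataclass
class PosteriorMatrix:
    """Posterior class-membership probabilities for N subjects.

    ``probabilities`` is N x G with rows summing to 1; ``modal_class`` is
    the row argmax (1-based, ties broken toward the lowest index);
    ``prior_fallback`` flags subjects with no usable occasions, whose row
    is the prior mixing proportion.
    """

    subject_ids: np.ndarray
    probabilities: np.ndarray
    prior_fallback: np.ndarray

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    @property
    def modal_class(self) -> np.ndarray:
        return np.argmax(self.probabilities, axis=1) + 1

    @property
    def modal_probability(self) -> np.ndarray:
        return np.max(self.probabilities, axis=1)

    def to_frame(self) -> pd.DataFrame:
        g = self.n_classes
        out = pd.DataFrame(
            self.probabilities, columns=[f"p_{k+1}" for k in range(g)]
        )
        out.insert(0, "subject_id", self.subject_ids)
        out["modal_class"] = self.modal_class
        out["modal_probability"] = self.modal_probability
        out["prior_fallback"] = self.prior_fallback
        return out


def _group_long(data: pd.DataFrame):
    """Sort long data by subject and return (ids, starts, counts, y, ages).

    Rows with missing scores are dropped (row deletion, no imputation);
    subjects left with zero rows are excluded with a logged count.
    """
    for col in ("subject_id", "age", "score"):
        if col not in data.columns:
            raise FitValidationError(f"data lacks required column {col!r}")
    df = data.dropna(subset=["score"]).sort_values(
        ["subject_id", "age"], kind="mergesort"
    )
    n_dropped = data["subject_id"].nunique() - df["subject_id"].nunique()
    if n_dropped:
        logger.info("excluded %d subjects with zero non-missing occasions", n_dropped)
    ids, starts, counts = np.unique(
        df["subject_id"].to_numpy(), return_index=True, return_counts=True
    )
    order = np.argsort(starts)
    ids, starts, counts = ids[order], starts[order], counts[order]
    return ids, starts, counts, df["score"].to_numpy(float), df["age"].to_numpy(float)


def _class_loglik(y, X, starts, counts, coef, sigma2, tau2, omega):
    """Per-subject per-class Gaussian log-density, N x G.

    Uses the Sherman-Morrison closed form for V = sigma^2 I + a 11' with
    a = omega_g^2 tau^2 (a = 0 recovers the independence/GBTM case).
    """
    G = coef.shape[0]
    resid = y[:, None] - X @ coef.T  # rows x G
    ss = np.add.reduceat(resid * resid, starts, axis=0)
    nvec = counts[:, None].astype(float)
    if tau2 <= 0.0:
        return -0.5 * (nvec * (_LOG2PI + np.log(sigma2)) + ss / sigma2)
    a = (np.asarray(omega, float) ** 2) * tau2  # (G,)
    s1 = np.add.reduceat(resid, starts, axis=0)
    denom = sigma2 + nvec * a[None, :]
    logdet = (nvec - 1.0) * np.log(sigma2) + np.log(denom)
    quad = ss / sigma2 - a[None, :] * s1**2 / (sigma2 * denom)
    return -0.5 * (nvec * _LOG2PI + logdet + quad)


def marginal_loglik(
    data: pd.DataFrame,
    coef: np.ndarray,
    mixing: np.ndarray,
    sigma2: float,
    tau2: float = 0.0,
    omega: np.ndarray | None = None,
    basis: FPBasis = FPBasis(),
) -> float:
    """Marginal mixture log-likelihood at the given parameters.

    ``coef`` is G x p on the basis (intercept first); ``mixing`` the
    simplex of class proportions; ``omega`` the per-class random-intercept
    multipliers (defaults to ones).  Missing scores are handled by row
    deletion.
    """
    coef = np.atleast_2d(np.asarray(coef, float))
    mixing = np.asarray(mixing, float)
    G = coef.shape[0]
    if omega is None:
        omega = np.ones(G)
    ids, starts, counts, y, ages = _group_long(data)
    if len(ids) == 0:
        raise FitValidationError("no subjects with non-missing scores")
    X = build_fp_basis(ages, basis)
    lg = _class_loglik(y, X, starts, counts, coef, sigma2, tau2, omega)
    return float(np.sum(logsumexp(np.log(mixing)[None, :] + lg, axis=1)))


def _softmax(logits_free: np.ndarray) -> np.ndarray:
    """Mixing proportions from G-1 free logits (reference class logit 0)."""
    z = np.concatenate([[0.0], logits_free])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class TrajectoryModel:
    """Latent-class trajectory mixture estimator (sklearn-style).

    Parameters
    ----------
    n_classes
        Number of latent classes G >= 1.
    basis
        Fractional-polynomial basis of age; the default quadratic
        FP(1,2) on age/10 matches the conventional starting model.
    random_effects
        "none" (GBTM), "common_intercept", or
        "class_proportional_intercept" (reference multiplier fixed at 1).
    n_starts, burn_iters, final_iters
        Multistart schedule: ``n_starts`` random starts each run for
        ``burn_iters`` iterations, then the best continues for up to
        ``final_iters``.
    tol
        Relative log-likelihood change declaring convergence.
    random_state
        Seed for the random starts (mandatory determinism contract).

    Attributes (after fit)
    ----------------------
    mixing_ : (G,) class proportions, descending.
    coef_ : (G, p) class trajectory coefficients on the basis.
    sigma2_, tau2_, omega_ : variance components (tau2_ = 0, omega_ = 1
        for GBTM; omega_[0] = 1 for the class-proportional structure).
    loglik_, n_parameters_, n_subjects_, converged_, multistart_trace_.
    """

    def __init__(
        self,
        n_classes: int = 4,
        basis: FPBasis = FPBasis(),
        random_effects: str = "none",
        n_starts: int = 50,
        burn_iters: int = 10,
        final_iters: int = 500,
        tol: float = 1e-6,
        random_state: int | None = 0,
        start_scale: float | None = None,
        start_method: str = "exemplar",
    ):
        self.n_classes = n_classes
        self.basis = basis
        self.random_effects = random_effects
        self.n_starts = n_starts
        self.burn_iters = burn_iters
        self.final_iters = final_iters
        self.tol = tol
        self.random_state = random_state
        self.start_scale = start_scale
        self.start_method = start_method

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_classes": self.n_classes,
            "basis": self.basis,
            "random_effects": self.random_effects,
            "n_starts": self.n_starts,
            "burn_iters": self.burn_iters,
            "final_iters": self.final_iters,
            "tol": self.tol,
            "random_state": self.random_state,
            "start_scale": self.start_scale,
            "start_method": self.start_method,
        }

    def set_params(self, **params) -> "TrajectoryModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"TrajectoryModel(n_classes={self.n_classes}, "
            f"basis={self.basis.label()}, random_effects={self.random_effects!r})"
        )

    # -- fitting -----------------------------------------------------------
    def fit(self, data: pd.DataFrame) -> "TrajectoryModel":
        """Fit by maximum likelihood on long-format (subject_id, age, score)."""
        if self.random_effects not in RANDOM_EFFECT_STRUCTURES:
            raise FitValidationError(
                f"random_effects must be one of {RANDOM_EFFECT_STRUCTURES}"
            )
        if self.n_classes < 1:
            raise FitValidationError("n_classes must be >= 1")
        if self.random_state is None:
            raise FitValidationError("random_state (seed) is mandatory")
        ids, starts, counts, y, ages = _group_long(data)
        N = len(ids)
        if N == 0:
            raise FitValidationError("empty data")
        if self.n_classes > N:
            raise FitValidationError(
                f"G={self.n_classes} exceeds the number of subjects ({N})"
            )
        X = build_fp_basis(ages, self.basis)
        p = X.shape[1]
        G = self.n_classes
        rng = np.random.default_rng(self.random_state)

        # single-class OLS anchor for start generation
        beta0, res0, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = max(len(y) - p, 1)
        sigma2_0 = float(np.sum((y - X @ beta0) ** 2) / dof)
        XtX_inv = np.linalg.pinv(X.T @ X)
        se0 = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2_0, 1e-12))
        scale = self.start_scale if self.start_scale is not None else 2.0 * np.sqrt(N)

        # precompute per-subject ridge-stabilised OLS curves for exemplar starts
        if self.start_method == "exemplar" and G > 1:
            exemplar_beta = np.empty((N, p))
            lam = 1e-3 * np.eye(p)
            for i in range(N):
                sl = slice(starts[i], starts[i] + counts[i])
                Xi, yi = X[sl], y[sl]
                exemplar_beta[i] = np.linalg.solve(Xi.T @ Xi + lam, Xi.T @ yi)
        else:
            exemplar_beta = None

        gbtm = self.random_effects == "none"
        trace = []
        best = None
        for s in range(self.n_starts):
            if exemplar_beta is not None:
                picks = rng.choice(N, size=G, replace=False)
                beta_s = exemplar_beta[picks].copy()
            else:
                beta_s = (
                    beta0[None, :] + rng.normal(size=(G, p)) * se0[None, :] * scale
                )
            if gbtm:
                state = self._em_gbtm(
                    y, X, starts, counts, beta_s, sigma2_0, self.burn_iters
                )
            else:
                state = self._qn_gmm(
                    y, X, starts, counts, beta_s, sigma2_0, self.burn_iters
                )
            trace.append(state["loglik"])
            if best is None or state["loglik"] > best["loglik"]:
                best = state
        if gbtm:
            final = self._em_gbtm(
                y,
                X,
                starts,
                counts,
                best["coef"],
                best["sigma2"],
                self.final_iters,
                pi=best["pi"],
                tol=self.tol,
            )
        else:
            final = self._qn_gmm(
                y,
                X,
                starts,
                counts,
                best["coef"],
                best["sigma2"],
                self.final_iters,
                init=best,
                tol=self.tol,
            )

        order = np.argsort(-final["pi"], kind="mergesort")
        self.mixing_ = final["pi"][order]
        self.coef_ = final["coef"][order]
        self.sigma2_ = float(final["sigma2"])
        omega = final.get("omega", np.ones(G))[order]
        tau2 = float(final.get("tau2", 0.0))
        if self.random_effects == "class_proportional_intercept" and omega[0] > 0:
            # renormalise so the (new) reference class multiplier is 1
            tau2 = tau2 * float(omega[0]) ** 2
            omega = omega / omega[0]
        elif self.random_effects == "common_intercept":
            omega = np.ones(G)
        self.omega_ = omega
        self.tau2_ = tau2
        self.loglik_ = float(final["loglik"])
        self.converged_ = bool(final["converged"])
        self.multistart_trace_ = [float(v) for v in trace]
        self.n_subjects_ = N
        self.n_observations_ = len(y)
        self.n_parameters_ = self._count_parameters(G, p)
        self.subject_ids_ = ids
        return self

    def _count_parameters(self, G: int, p: int) -> int:
        k = (G - 1) + G * p + 1  # mixing + curves + sigma2
        if self.random_effects == "common_intercept":
            k += 1
        elif self.random_effects == "class_proportional_intercept":
            k += 1 + (G - 1)
        return k

    # EM for GBTM: closed-form M-steps, monotone likelihood monitored.
    def _em_gbtm(
        self, y, X, starts, counts, coef, sigma2, max_iter, pi=None, tol=None
    ):
        G = coef.shape[0]
        N = len(starts)
        pi = np.full(G, 1.0 / G) if pi is None else np.asarray(pi, float)
        coef = np.array(coef, float)
        sigma2 = float(sigma2)
        row_of = np.repeat(np.arange(N), counts)
        prev = -np.inf
        converged = False
        loglik = -np.inf
        for it in range(max_iter):
            lg = _class_loglik(y, X, starts, counts, coef, sigma2, 0.0, None)
            joint = np.log(np.maximum(pi, 1e-300))[None, :] + lg
            lse = logsumexp(joint, axis=1)
            loglik = float(lse.sum())
            if loglik < prev - 1e-8 * max(1.0, abs(prev)):
                raise EMMonotonicityError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{prev:.8f} -> {loglik:.8f}"
                )
            if tol is not None and np.isfinite(prev):
                if abs(loglik - prev) < tol * max(1.0, abs(prev)):
                    converged = True
                    prev = loglik
                    break
            prev = loglik
            r = np.exp(joint - lse[:, None])  # N x G responsibilities
            pi = r.mean(axis=0)
            w_rows = r[row_of]  # rows x G
            sse = 0.0
            for g in range(G):
                w = w_rows[:, g]
                Xw = X * w[:, None]
                A = X.T @ Xw
                b = Xw.T @ y
                coef[g] = np.linalg.solve(A + 1e-10 * np.eye(A.shape[0]), b)
                resid = y - X @ coef[g]
                sse += float(w @ (resid * resid))
            sigma2 = max(sse / len(y), 1e-8)
        return {
            "pi": pi,
            "coef": coef,
            "sigma2": sigma2,
            "loglik": loglik if np.isfinite(loglik) else prev,
            "converged": converged,
        }

    # quasi-Newton on the marginal likelihood for random-intercept GMMs
    def _qn_gmm(self, y, X, starts, counts, coef, sigma2, max_iter, init=None, tol=None):
        G, p = coef.shape
        prop = self.random_effects == "class_proportional_intercept"

        def unpack(theta):
            i = 0
            logits = theta[i : i + G - 1]
            i += G - 1
            B = theta[i : i + G * p].reshape(G, p)
            i += G * p
            log_tau2 = theta[i]
            i += 1
            if prop:
                log_omega = np.concatenate([[0.0], theta[i : i + G - 1]])
                i += G - 1
            else:
                log_omega = np.zeros(G)
            log_sigma2 = theta[i]
            return logits, B, log_tau2, log_omega, log_sigma2

        def negloglik(theta):
            logits, B, lt, lo, ls = unpack(theta)
            pi = _softmax(logits)
            lg = _class_loglik(
                y, X, starts, counts, B, np.exp(ls), np.exp(lt), np.exp(lo / 2.0)
            )
            joint = np.log(np.maximum(pi, 1e-300))[None, :] + lg
            return -float(logsumexp(joint, axis=1).sum())

        if init is not None and "theta" in init:
            theta0 = init["theta"]
        else:
            parts = [np.zeros(G - 1), np.ravel(coef)]
            parts.append([np.log(max(0.25 * sigma2, 1e-4))])
            if prop:
                parts.append(np.zeros(G - 1))
            parts.append([np.log(max(0.75 * sigma2, 1e-4))])
            theta0 = np.concatenate([np.atleast_1d(np.asarray(q, float)) for q in parts])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = minimize(
                negloglik,
                theta0,
                method="L-BFGS-B",
                options={
                    "maxiter": max_iter,
                    "ftol": (tol if tol is not None else 1e-4) * 1e-2,
                },
            )
        logits, B, lt, lo, ls = unpack(res.x)
        return {
            "pi": _softmax(logits),
            "coef": B,
            "sigma2": float(np.exp(ls)),
            "tau2": float(np.exp(lt)),
            "omega": np.exp(lo / 2.0),
            "loglik": -float(res.fun),
            "converged": bool(res.success) or (tol is None),
            "theta": res.x,
        }

    # -- posterior inference ----------------------------------------------
    def _check_fitted(self, override: bool = False):
        if not hasattr(self, "loglik_"):
            raise FitValidationError("model is not fitted")
        if not self.converged_ and not override:
            warnings.warn(
                "model did not converge; posteriors computed from the last iterate",
                RuntimeWarning,
            )

    def predict_proba(
        self, data: pd.DataFrame, allow_unconverged: bool = True
    ) -> PosteriorMatrix:
        """Posterior class probabilities for every subject in ``data``.

        Subjects whose occasions are all missing receive the prior mixing
        proportions and are flagged via ``prior_fallback``.  Applies the
        same computation to fitting-sample and new subjects, so it also
        serves out-of-sample class prediction (subjects with as little as
        one scored occasion).
        """
        self._check_fitted(allow_unconverged)
        all_ids = pd.unique(data["subject_id"])
        usable = data.dropna(subset=["score"])
        ids, starts, counts, y, ages = _group_long(usable)
        G = len(self.mixing_)
        prob = np.tile(self.mixing_, (len(all_ids), 1))
        fallback = np.ones(len(all_ids), dtype=bool)
        if len(ids):
            X = build_fp_basis(ages, self.basis)
            lg = _class_loglik(
                y, X, starts, counts, self.coef_, self.sigma2_, self.tau2_, self.omega_
            )
            joint = np.log(np.maximum(self.mixing_, 1e-300))[None, :] + lg
            post = np.exp(joint - logsumexp(joint, axis=1)[:, None])
            post /= post.sum(axis=1, keepdims=True)
            pos = {sid: k for k, sid in enumerate(all_ids)}
            for j, sid in enumerate(ids):
                prob[pos[sid]] = post[j]
                fallback[pos[sid]] = False
        return PosteriorMatrix(
            subject_ids=np.asarray(all_ids),
            probabilities=prob,
            prior_fallback=fallback,
        )

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Modal class labels (1-based, classes ordered by descending pi)."""
        return self.predict_proba(data).modal_class

    def score(self, data: pd.DataFrame) -> float:
        """Marginal log-likelihood of ``data`` under the fitted parameters."""
        self._check_fitted(True)
        return marginal_loglik(
            data,
            self.coef_,
            self.mixing_,
            self.sigma2_,
            self.tau2_,
            self.omega_,
            self.basis,
        )

    def class_curves(self, age_grid: np.ndarray) -> pd.DataFrame:
        """Predicted mean trajectory per class over ``age_grid``."""
        self._check_fitted(True)
        Xg = build_fp_basis(np.asarray(age_grid, float), self.basis)
        rows = []
        for g in range(len(self.mixing_)):
            mean = Xg @ self.coef_[g]
            for a, m in zip(age_grid, mean):
                rows.append({"class": g + 1, "age": float(a), "mean": float(m)})
        return pd.DataFrame(rows)

    # -- persistence --------------------------------------------------------
    def to_json(self) -> str:
        self._check_fitted(True)
        payload = {
            "n_classes": self.n_classes,
            "basis": {
                "powers": list(self.basis.powers),
                "offset": self.basis.offset,
                "divisor": self.basis.divisor,
            },
            "random_effects": self.random_effects,
            "mixing": self.mixing_.tolist(),
            "coef": self.coef_.tolist(),
            "sigma2": self.sigma2_,
            "tau2": self.tau2_,
            "omega": self.omega_.tolist(),
            "loglik": self.loglik_,
            "n_parameters": self.n_parameters_,
            "n_subjects": self.n_subjects_,
            "converged": self.converged_,
            "multistart_trace": self.multistart_trace_,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "TrajectoryModel":
        d = json.loads(text)
        model = cls(
            n_classes=d["n_classes"],
            basis=FPBasis(
                powers=tuple(d["basis"]["powers"]),
                offset=d["basis"]["offset"],
                divisor=d["basis"]["divisor"],
            ),
            random_effects=d["random_effects"],
        )
        model.mixing_ = np.asarray(d["mixing"], float)
        model.coef_ = np.asarray(d["coef"], float)
        model.sigma2_ = float(d["sigma2"])
        model.tau2_ = float(d["tau2"])
        model.omega_ = np.asarray(d["omega"], float)
        model.loglik_ = float(d["loglik"])
        model.n_parameters_ = int(d["n_parameters"])
        model.n_subjects_ = int(d["n_subjects"])
        model.converged_ = bool(d["converged"])
        model.multistart_trace_ = list(d["multistart_trace"])
        return model


# -- thin functional wrappers ---------------------------------------------


def fit(
    data: pd.DataFrame,
    n_classes: int = 4,
    basis: FPBasis = FPBasis(),
    random_effects: str = "none",
    n_starts: int = 50,
    burn_iters: int = 10,
    final_iters: int = 500,
    seed: int = 0,
) -> TrajectoryModel:
    """Fit a latent-class trajectory model; see :class:`TrajectoryModel`."""
    return TrajectoryModel(
        n_classes=n_classes,
        basis=basis,
        random_effects=random_effects,
        n_starts=n_starts,
        burn_iters=burn_iters,
        final_iters=final_iters,
        random_state=seed,
    ).fit(data)


def posterior_probs(model: TrajectoryModel, data: pd.DataFrame) -> PosteriorMatrix:
    """Posterior class membership for the given data under ``model``."""
    return model.predict_proba(data)


def predict_class(model: TrajectoryModel, new_data: pd.DataFrame) -> PosteriorMatrix:
    """Out-of-sample class prediction (same computation as posterior_probs)."""
    return model.predict_proba(new_data)
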