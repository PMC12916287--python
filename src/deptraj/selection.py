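"""Model-selection framework for latent-class trajectory models.

A four-step procedure: (1) sweep the number of classes under a chosen
model structure, ranking by BIC/ICL/relative entropy among candidates
that converged and keep every class above a minimum share; (2) compare
random-effect structures at the chosen number of classes under adequacy
gates (average posterior probability per class and odds of correct
classification); (3) refine the fractional-polynomial shape at fixed
class count and structure by BIC.  Visual inspection is supported through
emitted class-curve tables/plots, never as an automated rule.

Fit indices:

* BIC = -2 l + k log N with N the number of subjects;
* relative entropy = 1 - EN / (N log G) with
  EN = sum_i sum_g -p_ig log p_ig (1 for a 1-class model, by convention);
* ICL (ICL-BIC convention) = BIC + 2 EN;
* APP_g = mean posterior probability of class g among its modal members;
* OCC_g = [APP_g/(1-APP_g)] / [pi_g/(1-pi_g)].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .basis import FPBasis, enumerate_fp_specs  # noqa: F401  (re-export)
from .trajectory import PosteriorMatrix, TrajectoryModel


def bic(loglik: float, n_parameters: int, n_subjects: int) -> float:
    """Bayesian information criterion; N counts subjects, not observations."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    return -2.0 * loglik + n_parameters * np.log(n_subjects)


def _entropy_nats(probabilities: np.ndarray) -> float:
    p = np.asarray(probabilities, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return float(-plogp.sum())


def relative_entropy(posteriors: PosteriorMatrix | np.ndarray) -> float:
    """Normalised classification certainty in [0, 1] (1 = crisp).

    Defined as 1 - EN/(N log G); a one-class model is perfectly assigned,
    so G=1 returns 1.0 with a warning.
    """
    p = (
        posteriors.probabilities
        if isinstance(posteriors, PosteriorMatrix)
        else np.asarray(posteriors, float)
    )
    n, g = p.shape
    if g < 2:
        warnings.warn("relative entropy is undefined for G=1; returning 1.0")
        return 1.0
    return 1.0 - _entropy_nats(p) / (n * np.log(g))


def icl(
    bic_value: float,
    posteriors: PosteriorMatrix | np.ndarray,
    hard_assignment: bool = False,
) -> float:
    """Integrated completed likelihood, ICL-BIC convention (BIC + 2 EN).

    With ``hard_assignment=True`` the entropy term uses the modal
    assignment only, EN = sum_i -log max_g p_ig (the completed-data
    variant); the default soft version is used everywhere else.
    """
    p = (
        posteriors.probabilities
        if isinstance(posteriors, PosteriorMatrix)
        else np.asarray(posteriors, float)
    )
    if hard_assignment:
        en = float(-np.log(np.maximum(p.max(axis=1), 1e-300)).sum())
    else:
        en = _entropy_nats(p)
    return float(bic_value + 2.0 * en)


def average_posterior_prob(posteriors: PosteriorMatrix | np.ndarray) -> np.ndarray:
    """Per-class APP: mean p_ig over subjects modally assigned to g.

    Classes with no assigned member get NaN (adequacy gate fails there).
    """
    p = (
        posteriors.probabilities
        if isinstance(posteriors, PosteriorMatrix)
        else np.asarray(posteriors, float)
    )
    modal = np.argmax(p, axis=1)
    g = p.shape[1]
    app = np.full(g, np.nan)
    for k in range(g):
        members = modal == k
        if members.any():
            app[k] = p[members, k].mean()
    return app


def odds_correct_classification(app_g: float, pi_hat_g: float) -> float:
    """OCC_g = assignment odds over prior odds for class g.

    APP_g = 1 gives +inf; degenerate mixing proportions are an error.
    """
    if not 0.0 < pi_hat_g < 1.0:
        raise ValueError(f"mixing proportion must be in (0,1), got {pi_hat_g}")
    if np.isnan(app_g):
        return np.nan
    if app_g >= 1.0:
        return np.inf
    return (app_g / (1.0 - app_g)) / (pi_hat_g / (1.0 - pi_hat_g))


@dataclass(frozen=True)
class SelectionGates:
    """Adequacy and class-size gates used across the selection steps."""

    min_class_share: float = 0.05
    min_app: float = 0.7
    min_occ: float = 5.0


@dataclass
class CandidateSummary:
    """One fitted candidate with its fit and adequacy indices."""

    label: str
    n_classes: int
    structure: str
    basis_label: str
    loglik: float
    n_parameters: int
    n_subjects: int
    converged: bool
    bic: float
    icl: float
    relative_entropy: float
    smallest_class_share: float
    app: list
    occ: list
    model: TrajectoryModel | None = None

    def passes_share(self, gates: SelectionGates) -> bool:
        return self.smallest_class_share >= gates.min_class_share

    def passes_adequacy(self, gates: SelectionGates) -> bool:
        if self.n_classes == 1:
            return True
        app = np.asarray(self.app, float)
        occ = np.asarray(self.occ, float)
        if np.isnan(app).any() or np.isnan(occ).any():
            return False
        return bool((app >= gates.min_app).all() and (occ >= gates.min_occ).all())

    def to_record(self) -> dict:
        d = {
            "label": self.label,
            "n_classes": self.n_classes,
            "structure": self.structure,
            "basis": self.basis_label,
            "loglik": self.loglik,
            "n_parameters": self.n_parameters,
            "n_subjects": self.n_subjects,
            "converged": self.converged,
            "BIC": self.bic,
            "ICL": self.icl,
            "relative_entropy": self.relative_entropy,
            "smallest_class_share": self.smallest_class_share,
        }
        for k, (a, o) in enumerate(zip(self.app, self.occ)):
            d[f"APP_{k+1}"] = a
            d[f"OCC_{k+1}"] = o
        return d


def summarise_candidate(model: TrajectoryModel, data: pd.DataFrame) -> CandidateSummary:
    """Compute all selection indices for a fitted model on its data."""
    post = model.predict_proba(data)
    b = bic(model.loglik_, model.n_parameters_, model.n_subjects_)
    app = average_posterior_prob(post)
    occ = [
        odds_correct_classification(a, p) if 0 < p < 1 else np.nan
        for a, p in zip(app, model.mixing_)
    ]
    if model.n_classes == 1:
        occ = [np.inf]
    return CandidateSummary(
        label=f"G={model.n_classes}|{model.random_effects}|{model.basis.label()}",
        n_classes=model.n_classes,
        structure=model.random_effects,
        basis_label=model.basis.label(),
        loglik=model.loglik_,
        n_parameters=model.n_parameters_,
        n_subjects=model.n_subjects_,
        converged=model.converged_,
        bic=b,
        icl=icl(b, post),
        relative_entropy=relative_entropy(post)
        if model.n_classes > 1
        else 1.0,
        smallest_class_share=float(np.min(model.mixing_)),
        app=list(app),
        occ=list(occ),
        model=model,
    )


@dataclass
class ModelSelectionReport:
    """Outcome of the staged selection with a full decision trail."""

    candidates: list
    decision_trail: list
    chosen: CandidateSummary | None

    def to_json(self) -> str:
        return json.dumps(
            {
                "candidates": [c.to_record() for c in self.candidates],
                "decision_trail": self.decision_trail,
                "chosen": self.chosen.label if self.chosen else None,
            },
            indent=2,
            default=float,
        )

    def fit_index_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_record() for c in self.candidates])


def _best_by_bic(cands: list) -> CandidateSummary:
    return min(cands, key=lambda c: (c.bic, c.n_classes, c.label))


def select_model(
    candidates: list,
    gates: SelectionGates = SelectionGates(),
    sweep_structure: str | None = None,
) -> ModelSelectionReport:
    """Apply the staged selection rules to a list of CandidateSummary.

    Pure function of its candidate list: (i) choose the class count by
    BIC within ``sweep_structure`` among converged candidates passing the
    class-share gate; (ii) at that class count compare structures under
    the adequacy gates (relaxed, with a recorded reason, if none pass);
    (iii) refine the basis at fixed count and structure by BIC.  When BIC
    and ICL disagree at any stage, BIC decides and the disagreement is
    logged in the decision trail.
    """
    if not candidates:
        return ModelSelectionReport([], [{"step": 0, "note": "no candidates"}], None)
    trail: list[dict] = []
    converged = [c for c in candidates if c.converged]
    if not converged:
        trail.append({"step": 1, "note": "no converged candidates; selection aborted"})
        return ModelSelectionReport(candidates, trail, None)

    if sweep_structure is None:
        structs = [c.structure for c in converged]
        sweep_structure = max(set(structs), key=structs.count)

    # step 1: class-number sweep
    sweep = [c for c in converged if c.structure == sweep_structure]
    eligible = [c for c in sweep if c.passes_share(gates)]
    trail.append(
        {
            "step": 1,
            "rule": f"class sweep on structure {sweep_structure!r}; "
            f"convergence and smallest class share >= {gates.min_class_share}",
            "eligible": [c.label for c in eligible],
            "rejected": [c.label for c in sweep if c not in eligible],
        }
    )
    if not eligible:
        trail.append({"step": 1, "note": "no candidate passes the share gate"})
        return ModelSelectionReport(candidates, trail, None)
    by_bic = _best_by_bic(eligible)
    by_icl = min(eligible, key=lambda c: (c.icl, c.n_classes, c.label))
    if by_icl.label != by_bic.label:
        trail.append(
            {
                "step": 1,
                "note": f"BIC and ICL disagree ({by_bic.label} vs {by_icl.label}); "
                "BIC decides",
            }
        )
    k = by_bic.n_classes
    trail.append({"step": 1, "chosen_n_classes": k, "by": "BIC", "label": by_bic.label})

    # step 2: structure comparison at fixed k with adequacy gates
    at_k = [c for c in converged if c.n_classes == k and c.passes_share(gates)]
    adequate = [c for c in at_k if c.passes_adequacy(gates)]
    relaxed = False
    if not adequate:
        adequate = at_k
        relaxed = True
    trail.append(
        {
            "step": 2,
            "rule": f"structure comparison at k={k}; APP >= {gates.min_app}, "
            f"OCC >= {gates.min_occ} for all classes",
            "eligible": [c.label for c in adequate],
            "gates_relaxed": relaxed,
            **(
                {"note": "no structure passed adequacy gates; best BIC kept with "
                 "gates relaxed"}
                if relaxed
                else {}
            ),
        }
    )
    if not adequate:
        return ModelSelectionReport(candidates, trail, None)
    structure_choice = _best_by_bic(adequate)
    structure = structure_choice.structure
    trail.append({"step": 2, "chosen_structure": structure,
                  "label": structure_choice.label})

    # step 3: fractional-polynomial refinement at fixed k and structure
    fp_pool = [
        c
        for c in converged
        if c.n_classes == k and c.structure == structure and c.passes_share(gates)
    ]
    chosen = _best_by_bic(fp_pool) if fp_pool else structure_choice
    trail.append(
        {
            "step": 3,
            "rule": "fractional-polynomial refinement by BIC",
            "eligible": [c.label for c in fp_pool],
            "chosen": chosen.label,
        }
    )
    return ModelSelectionReport(candidates, trail, chosen)


def fit_candidate_grid(
    data: pd.DataFrame,
    n_classes_range=range(1, 7),
    structures=("none",),
    bases=(FPBasis(),),
    seed: int = 0,
    n_starts: int = 50,
    burn_iters: int = 10,
    final_iters: int = 500,
) -> list:
    """Fit and summarise every (G, structure, basis) combination."""
    out = []
    for G in n_classes_range:
        for structure in structures:
            for basis in bases:
                model = TrajectoryModel(
                    n_classes=G,
                    basis=basis,
                    random_effects=structure,
                    n_starts=n_starts,
                    burn_iters=burn_iters,
                    final_iters=final_iters,
                    random_state=seed,
                ).fit(data)
                out.append(summarise_candidate(model, data))
    return out


def class_curve_table(
    model: TrajectoryModel,
    data: pd.DataFrame,
    age_grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted class mean curves with approximate 95% bands.

    Bands use the within-class weighted-OLS covariance evaluated at the
    posterior responsibilities (an approximation; the full information
    matrix is not assembled).
    """
    from .basis import build_fp_basis
    from .trajectory import _group_long

    if age_grid is None:
        lo, hi = data["age"].min(), data["age"].max()
        age_grid = np.linspace(lo, hi, 61)
    ids, starts, counts, y, ages = _group_long(data)
    X = build_fp_basis(ages, model.basis)
    post = model.predict_proba(data)
    pos = {sid: k for k, sid in enumerate(post.subject_ids)}
    resp = post.probabilities[[pos[sid] for sid in ids]]
    row_weights = np.repeat(resp, counts, axis=0)
    Xg = build_fp_basis(np.asarray(age_grid, float), model.basis)
    rows = []
    for g in range(len(model.mixing_)):
        w = row_weights[:, g]
        A = X.T @ (X * w[:, None]) + 1e-10 * np.eye(X.shape[1])
        cov = model.sigma2_ * np.linalg.inv(A)
        mean = Xg @ model.coef_[g]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, cov, Xg), 0.0))
        for a, mu, s in zip(age_grid, mean, se):
            rows.append(
                {
                    "class": g + 1,
                    "age": float(a),
                    "mean": float(mu),
                    "ci_low": float(mu - 1.96 * s),
                    "ci_high": float(mu + 1.96 * s),
                }
            )
    return pd.DataFrame(rows)
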