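"""Associations of assigned trajectory class with clinical outcomes.

Binary outcomes are analysed with modified Poisson regression (log-link
Poisson on a binary response with a robust sandwich variance), which
targets the risk ratio directly; continuous outcomes with ordinary least
squares.  The reference class is the largest trajectory class.  Two
covariate sets are supported: the basic set (sex, maternal education,
maternal occupational social class) and the adjusted set which adds BMI
at age 10.  All models run on complete cases.  Two sensitivity modes
mirror the class-assignment-uncertainty checks: restricting to subjects
with modal posterior probability >= 0.7, and replacing the class factor
with the posterior-probability columns themselves.  Multiplicity is
handled with Benjamini-Hochberg FDR flags at q = 0.1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

BASIC_COVARIATES = ("sex", "maternal_education", "maternal_social_class")
ADJUSTED_COVARIATES = BASIC_COVARIATES + ("bmi_age10",)

SENSITIVITY_MODES = ("none", "modal_p_ge_0.7", "posterior_terms")


class DesignError(ValueError):
    """The design matrix is unusable (collinear or missing columns)."""


@dataclass
class AssociationResult:
    """Effect of one non-reference class on one outcome."""

    outcome: str
    contrast_class: str
    effect: float  # RR for binary outcomes, mean difference for continuous
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # "basic" or "adjusted"
    n_complete: int
    effect_type: str  # "risk_ratio" or "coefficient"
    sensitivity_mode: str = "none"
    degenerate: bool = False
    degenerate_reason: str | None = None
    fdr_significant: bool | None = None


def _check_collinearity(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, R, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[j] for j in piv[len(diag):]]
        raise DesignError(f"collinear design; aliased columns: {aliased}")


def build_design(
    df: pd.DataFrame,
    class_col: str = "trajectory_class",
    covariates=ADJUSTED_COVARIATES,
    reference=None,
    posterior_cols=None,
) -> tuple[pd.DataFrame, list, object]:
    """Intercept + class dummies (largest class = reference) + covariates.

    Categorical covariates are dummy-encoded dropping the first level;
    numeric covariates enter linearly.  When ``posterior_cols`` is given,
    the class factor is replaced by those columns (posterior-terms
    sensitivity analysis; the reference class column is omitted).
    Returns (design, class term names, reference label).
    """
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    if posterior_cols is not None:
        class_terms = list(posterior_cols)
        for c in class_terms:
            X[c] = df[c].astype(float)
    else:
        counts = df[class_col].value_counts()
        if reference is None:
            reference = counts.index[counts.argmax()]
        levels = [lvl for lvl in counts.index if lvl != reference]
        class_terms = []
        for lvl in sorted(levels, key=str):
            name = f"{class_col}[{lvl}]"
            X[name] = (df[class_col] == lvl).astype(float)
            class_terms.append(name)
    for cov in covariates:
        if cov not in df.columns:
            raise DesignError(f"covariate column {cov!r} missing from data")
        col = df[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique(), key=str)
            for lvl in levels[1:]:
                X[f"{cov}[{lvl}]"] = (col == lvl).astype(float)
        else:
            X[cov] = col.astype(float)
    _check_collinearity(X)
    return X, class_terms, reference


def apply_sensitivity(
    mode: str,
    df: pd.DataFrame,
    posteriors: pd.DataFrame | None = None,
    threshold: float = 0.7,
):
    """Restrict or augment the model inputs per the sensitivity mode.

    Returns (df, posterior_term_columns or None, flags).  Mode
    "modal_p_ge_0.7" filters rows by modal posterior probability;
    "posterior_terms" merges the posterior columns (reference class
    omitted) for use in place of the class factor.
    """
    if mode not in SENSITIVITY_MODES:
        raise ValueError(f"unknown sensitivity mode {mode!r}")
    flags: dict = {}
    if mode == "none":
        return df, None, flags
    if posteriors is None:
        raise ValueError(f"sensitivity mode {mode!r} requires a posterior matrix")
    merged = df.merge(posteriors, on="subject_id", how="inner")
    if mode == "modal_p_ge_0.7":
        kept = merged[merged["modal_probability"] >= threshold]
        flags["n_dropped"] = len(merged) - len(kept)
        if "modal_class" in kept.columns:
            empty = set(merged["modal_class"].unique()) - set(
                kept["modal_class"].unique()
            )
            if empty:
                flags["empty_classes"] = sorted(int(c) for c in empty)
        if len(kept) == 0:
            flags["empty"] = True
        return kept.reset_index(drop=True), None, flags
    p_cols = sorted(
        [c for c in posteriors.columns if c.startswith("p_")],
        key=lambda c: int(c.split("_")[1]),
    )
    shares = merged[p_cols].mean()
    reference_col = shares.idxmax()  # largest class by average posterior
    terms = [c for c in p_cols if c != reference_col]
    flags["reference_posterior_column"] = reference_col
    return merged, terms, flags


def _result_from_glm(
    fit, class_terms, outcome, model_label, n, sensitivity, effect_type
) -> list:
    out = []
    params = fit.params
    bse = fit.bse
    pvals = fit.pvalues
    for term in class_terms:
        est, se, p = params[term], bse[term], pvals[term]
        if effect_type == "risk_ratio":
            out.append(
                AssociationResult(
                    outcome=outcome,
                    contrast_class=term,
                    effect=float(np.exp(est)),
                    se=float(se),
                    ci_low=float(np.exp(est - 1.96 * se)),
                    ci_high=float(np.exp(est + 1.96 * se)),
                    p_value=float(p),
                    model=model_label,
                    n_complete=n,
                    effect_type=effect_type,
                    sensitivity_mode=sensitivity,
                )
            )
        else:
            out.append(
                AssociationResult(
                    outcome=outcome,
                    contrast_class=term,
                    effect=float(est),
                    se=float(se),
                    ci_low=float(est - 1.96 * se),
                    ci_high=float(est + 1.96 * se),
                    p_value=float(p),
                    model=model_label,
                    n_complete=n,
                    effect_type=effect_type,
                    sensitivity_mode=sensitivity,
                )
            )
    return out


def _degenerate(outcome, class_terms, model_label, n, sensitivity, effect_type, reason):
    return [
        AssociationResult(
            outcome=outcome,
            contrast_class=term,
            effect=np.nan,
            se=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            p_value=np.nan,
            model=model_label,
            n_complete=n,
            effect_type=effect_type,
            sensitivity_mode=sensitivity,
            degenerate=True,
            degenerate_reason=reason,
        )
        for term in class_terms
    ]


def fit_binary_outcome(
    df: pd.DataFrame,
    outcome: str,
    class_col: str = "trajectory_class",
    model: str = "adjusted",
    reference=None,
    sensitivity: str = "none",
    posteriors: pd.DataFrame | None = None,
    covariates_override=None,
) -> list:
    """Adjusted risk ratios per non-reference class via modified Poisson.

    Complete-case log-link Poisson GLM on the binary outcome with an HC0
    sandwich variance; 95% CIs are exp(logRR +/- 1.96 robust SE).  A class
    with zero events yields flagged degenerate results (no exception).
    ``covariates_override`` replaces the standard covariate set (an empty
    tuple gives the crude model).
    """
    covariates = ADJUSTED_COVARIATES if model == "adjusted" else BASIC_COVARIATES
    if covariates_override is not None:
        covariates = tuple(covariates_override)
    df, posterior_terms, flags = apply_sensitivity(sensitivity, df, posteriors)
    cols = [outcome, *covariates]
    if posterior_terms is None:
        cols.append(class_col)
    else:
        cols.extend(posterior_terms)
    cc = df.dropna(subset=[c for c in cols if c in df.columns]).reset_index(drop=True)
    X, class_terms, reference = build_design(
        cc, class_col, covariates, reference, posterior_terms
    )
    y = cc[outcome].astype(float)
    n = len(cc)
    if flags.get("empty") or n == 0:
        return _degenerate(
            outcome, class_terms or ["<none>"], model, n, sensitivity,
            "risk_ratio", "no rows after sensitivity restriction",
        )
    if y.nunique() < 2:
        return _degenerate(
            outcome, class_terms, model, n, sensitivity, "risk_ratio",
            f"outcome is constant (value {y.iloc[0]!r})",
        )
    if posterior_terms is None:
        events = cc.groupby(class_col)[outcome].sum()
        zero_classes = events.index[events == 0].tolist()
        if zero_classes:
            return _degenerate(
                outcome, class_terms, model, n, sensitivity, "risk_ratio",
                f"zero events in class(es) {zero_classes}; separation",
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit(cov_type="HC0")
    return _result_from_glm(
        fit, class_terms, outcome, model, n, sensitivity, "risk_ratio"
    )


def fit_continuous_outcome(
    df: pd.DataFrame,
    outcome: str,
    class_col: str = "trajectory_class",
    model: str = "adjusted",
    reference=None,
    sensitivity: str = "none",
    posteriors: pd.DataFrame | None = None,
    covariates_override=None,
) -> list:
    """Unstandardised mean differences per class via complete-case OLS."""
    covariates = ADJUSTED_COVARIATES if model == "adjusted" else BASIC_COVARIATES
    if covariates_override is not None:
        covariates = tuple(covariates_override)
    df, posterior_terms, flags = apply_sensitivity(sensitivity, df, posteriors)
    cols = [outcome, *covariates]
    if posterior_terms is None:
        cols.append(class_col)
    else:
        cols.extend(posterior_terms)
    cc = df.dropna(subset=[c for c in cols if c in df.columns]).reset_index(drop=True)
    X, class_terms, reference = build_design(
        cc, class_col, covariates, reference, posterior_terms
    )
    y = cc[outcome].astype(float)
    n = len(cc)
    if flags.get("empty") or n == 0:
        return _degenerate(
            outcome, class_terms or ["<none>"], model, n, sensitivity,
            "coefficient", "no rows after sensitivity restriction",
        )
    if y.nunique() < 2:
        return _degenerate(
            outcome, class_terms, model, n, sensitivity, "coefficient",
            "outcome is constant",
        )
    fit = sm.OLS(y, X).fit()
    return _result_from_glm(
        fit, class_terms, outcome, model, n, sensitivity, "coefficient"
    )


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``.

    NaN p-values are never flagged and are excluded from the ranking.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    flags = np.zeros(p.shape, dtype=bool)
    ok = ~np.isnan(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return flags


def association_table(results: list, q: float = 0.1) -> pd.DataFrame:
    """Tidy results table with FDR flags pooled across the given set."""
    df = pd.DataFrame([vars(r) for r in results])
    if len(df):
        df["fdr_significant"] = bh_fdr(df["p_value"].to_numpy(), q)
    return df


def estimate_rr_gcomputation(
    df: pd.DataFrame,
    outcome: str,
    class_col: str = "trajectory_class",
    model: str = "adjusted",
    reference=None,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal risk ratios by g-computation over a logistic model.

    Fits a logistic regression, predicts each subject's risk under every
    counterfactual class assignment, and ratios the average predicted
    risks against the reference class.  Optional percentile bootstrap CI.
    Provided as a parity check for the modified-Poisson estimator.
    """
    covariates = ADJUSTED_COVARIATES if model == "adjusted" else BASIC_COVARIATES
    cc = df.dropna(subset=[outcome, class_col, *covariates]).reset_index(drop=True)

    def _estimate(data: pd.DataFrame) -> dict:
        X, class_terms, ref = build_design(data, class_col, covariates, reference)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(
                data[outcome].astype(float), X, family=sm.families.Binomial()
            ).fit()
        risks = {}
        for lvl in data[class_col].unique():
            Xc = X.copy()
            for term in class_terms:
                Xc[term] = 1.0 if term == f"{class_col}[{lvl}]" else 0.0
            risks[lvl] = float(fit.predict(Xc).mean())
        return {lvl: risks[lvl] / risks[ref] for lvl in risks if lvl != ref}

    point = _estimate(cc)
    rows = [{"contrast_class": lvl, "rr": rr} for lvl, rr in sorted(point.items(), key=lambda kv: str(kv[0]))]
    out = pd.DataFrame(rows)
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = {lvl: [] for lvl in point}
        for _ in range(n_boot):
            sample = cc.sample(frac=1.0, replace=True, random_state=rng.integers(2**31))
            try:
                est = _estimate(sample)
            except Exception:
                continue
            for lvl in point:
                if lvl in est:
                    boot[lvl].append(est[lvl])
        out["ci_low"] = [np.percentile(boot[r["contrast_class"]], 2.5) for _, r in out.iterrows()]
        out["ci_high"] = [np.percentile(boot[r["contrast_class"]], 97.5) for _, r in out.iterrows()]
    return out
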