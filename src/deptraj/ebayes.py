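"""Per-analyte linear models with empirical-Bayes variance moderation.

High-dimensional biomarker panels (inflammation proteins on a log2
NPX-like scale, NMR metabolomic features, blood count / clinical
chemistry measures) are regressed analyte-by-analyte on trajectory class
and covariates over a shared design matrix.  Residual variances are
shrunk toward a pooled prior estimated by the method of moments on the
log residual variances: with e_g = log s_g^2 - psi(d_g/2) + log(d_g/2),

    psi'(d0/2) = max{0, var(e) - mean psi'(d_g/2)}
    s0^2       = exp(mean(e) + psi(d0/2) - log(d0/2))
    s~_g^2     = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)

(d0 = +inf when the variance term vanishes, in which case every s~_g^2 =
s0^2 = exp(mean e)).  Moderated t statistics use d0 + d_g degrees of
freedom (a normal reference when d0 is infinite).  Planned contrasts of
each intermediary trajectory against the largest (reference) class are
reported with Benjamini-Hochberg FDR flags at q = 0.1 per contrast set.

Panel filtering follows the delivery conventions: proteins with >= 50%
of values below the limit of detection are excluded, and lipoprotein
subclass measures are dropped from the metabolomic feature set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

from .associations import (
    ADJUSTED_COVARIATES,
    BASIC_COVARIATES,
    DesignError,
    bh_fdr,
    build_design,
)
from .simulate import BiomarkerPanel

KNOWN_CATEGORIES = {
    "cholesterol",
    "apolipoproteins_lipids",
    "particle_size",
    "fatty_acids",
    "glycolysis",
    "amino_acids",
    "ketone_bodies",
    "fluid_balance",
    "inflammation",
    "lipoprotein_subclass",
    "inflammation_protein",
    "blood_count_chemistry",
}


def lod_filter(
    panel: BiomarkerPanel,
    max_below_lod: float = 0.5,
    substitute_half_lod: bool = False,
) -> BiomarkerPanel:
    """Drop protein analytes with a below-LOD fraction >= ``max_below_lod``.

    The threshold is inclusive (a fraction of exactly 0.5 excludes the
    analyte).  Non-protein families pass through untouched.  Retained
    values below the LOD are kept as delivered by default;
    ``substitute_half_lod=True`` replaces them with LOD/2 instead.
    """
    meta = panel.metadata
    frac = meta.get("below_lod_fraction")
    if frac is None:
        return panel
    drop = (meta["family"] == "protein") & (frac >= max_below_lod)
    keep = meta.loc[~drop, "analyte"].tolist()
    out = panel.subset(keep)
    if substitute_half_lod and "lod" in out.metadata.columns:
        lods = out.metadata.set_index("analyte")["lod"]
        for analyte in out.analytes:
            mask = out.censored[analyte]
            if mask.any() and np.isfinite(lods[analyte]):
                out.values.loc[mask, analyte] = lods[analyte] / 2.0
    return out


def select_metabolomic_features(panel: BiomarkerPanel) -> BiomarkerPanel:
    """Drop lipoprotein-subclass features from the metabolomic family.

    With the packaged catalogue this leaves the 57-feature analysis set.
    An empty result (a subclass-only panel) is returned flagged via an
    empty values frame rather than raising.
    """
    meta = panel.metadata
    unknown = set(meta["category"]) - KNOWN_CATEGORIES
    if unknown:
        raise ValueError(f"unknown analyte categories: {sorted(unknown)}")
    drop = (meta["family"] == "metabolomic") & (
        meta["category"] == "lipoprotein_subclass"
    )
    keep = meta.loc[~drop, "analyte"].tolist()
    return panel.subset(keep)


@dataclass
class AnalyteFits:
    """Per-analyte OLS results over a shared design.

    ``coef`` is (analytes x design columns); ``s2`` the residual
    variances with ``df_resid`` degrees of freedom each;
    ``xtx_inv`` the shared unscaled covariance of the coefficients.
    Zero-variance analytes are recorded in ``excluded`` and dropped.
    """

    analytes: list
    design_columns: list
    class_terms: list
    coef: np.ndarray
    s2: np.ndarray
    df_resid: int
    xtx_inv: np.ndarray
    n: int
    excluded: list = field(default_factory=list)


def fit_analyte_models(
    values: pd.DataFrame,
    sample_data: pd.DataFrame,
    class_col: str = "trajectory_class",
    model: str = "adjusted",
    reference=None,
) -> AnalyteFits:
    """Fit one OLS per analyte on the shared class + covariate design.

    ``values`` is subjects x analytes indexed by subject_id;
    ``sample_data`` carries subject_id, the class column and covariates.
    Complete cases on the covariate set; rows missing an analyte are not
    allowed (panel values are assumed complete after filtering).
    """
    covariates = ADJUSTED_COVARIATES if model == "adjusted" else BASIC_COVARIATES
    df = sample_data.dropna(subset=[class_col, *covariates]).reset_index(drop=True)
    df = df[df["subject_id"].isin(values.index)]
    Y = values.loc[df["subject_id"]].to_numpy(float)
    X, class_terms, _ = build_design(df, class_col, covariates, reference)
    Xm = X.to_numpy(float)
    n, p = Xm.shape
    if n <= p:
        raise DesignError(f"too few complete cases ({n}) for {p} parameters")
    coef, *_ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ coef
    dfr = n - np.linalg.matrix_rank(Xm)
    s2 = (resid**2).sum(axis=0) / dfr
    names = list(values.columns)
    # a flat analyte leaves only rounding residue; treat it as zero-variance
    keep = (s2 > 0) & (Y.var(axis=0) > 0)
    excluded = [names[j] for j in np.flatnonzero(~keep)]
    return AnalyteFits(
        analytes=[names[j] for j in np.flatnonzero(keep)],
        design_columns=list(X.columns),
        class_terms=class_terms,
        coef=coef.T[keep],
        s2=s2[keep],
        df_resid=int(dfr),
        xtx_inv=np.linalg.pinv(Xm.T @ Xm),
        n=n,
        excluded=excluded,
    )


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y > 0 (Newton iteration on the log scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def ebayes_moderate(s2, df, prior_df: float | None = None):
    """Moment-matched variance shrinkage: returns (d0, s0^2, s~^2).

    ``s2`` are per-analyte residual variances on ``df`` residual degrees
    of freedom (scalar or per-analyte).  ``prior_df`` overrides the
    estimated d0 (0 disables moderation exactly; inf shrinks fully).
    All-equal variances legitimately give d0 = +inf.
    """
    s2 = np.asarray(s2, float)
    if np.any(s2 <= 0):
        raise ValueError("residual variances must be strictly positive")
    d = np.broadcast_to(np.asarray(df, float), s2.shape)
    if s2.size < 2 and prior_df is None:
        raise ValueError("need >= 2 analytes to estimate the prior")
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0.0:
            return 0.0, np.nan, s2.copy()
        if np.isinf(d0):
            s02 = float(np.exp(e.mean()))
            return d0, s02, np.full_like(s2, s02)
        s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        evar = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
        rhs = evar - float(np.mean(polygamma(1, d / 2.0)))
        if rhs > 0:
            d0 = 2.0 * _trigamma_inverse(rhs)
            s02 = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s02 = float(np.exp(e.mean()))
            return d0, s02, np.full_like(s2, s02)
    s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
    return float(d0), s02, s2_tilde


@dataclass
class EBayesFit:
    """Moderated contrast results: one row per analyte per contrast."""

    table: pd.DataFrame
    d0: float
    s02: float
    s2_tilde: np.ndarray


def planned_contrasts(
    fits: AnalyteFits,
    contrasts: list | None = None,
    moderate: bool = True,
    prior_df: float | None = None,
    q: float = 0.1,
) -> EBayesFit:
    """Moderated t-tests of planned class contrasts vs the reference.

    ``contrasts`` selects class-term design columns (default: all of
    them, i.e. each non-reference trajectory against the reference);
    entries may also be explicit contrast vectors over the design
    columns.  BH-FDR flags are computed within each contrast set at
    level ``q``.  ``moderate=False`` (or ``prior_df=0``) gives ordinary
    per-analyte t-tests.
    """
    if contrasts is None:
        contrasts = list(fits.class_terms)
    if moderate:
        d0, s02, s2t = ebayes_moderate(fits.s2, fits.df_resid, prior_df=prior_df)
    else:
        d0, s02, s2t = 0.0, np.nan, fits.s2.copy()
    df_total = fits.df_resid + (0.0 if d0 == 0.0 else d0)
    rows = []
    cols = fits.design_columns
    for contrast in contrasts:
        if isinstance(contrast, str):
            if contrast not in cols:
                raise ValueError(f"contrast column {contrast!r} not in design")
            cvec = np.zeros(len(cols))
            cvec[cols.index(contrast)] = 1.0
            label = contrast
        else:
            cvec = np.asarray(contrast, float)
            if cvec.shape != (len(cols),):
                raise ValueError("contrast vector length must match the design")
            label = "custom:" + ",".join(f"{v:g}" for v in cvec)
        var_unscaled = float(cvec @ fits.xtx_inv @ cvec)
        if np.allclose(cvec, 0.0):
            # e.g. a class contrasted against itself: difference is exactly 0
            est = np.zeros(len(fits.analytes))
            se = np.zeros_like(est)
            tstat = np.zeros_like(est)
            p = np.ones_like(est)
        elif var_unscaled <= 0:
            raise ValueError(f"contrast {label!r} is not estimable")
        else:
            est = fits.coef @ cvec
            se = np.sqrt(s2t * var_unscaled)
            with np.errstate(divide="ignore", invalid="ignore"):
                tstat = np.where(se > 0, est / se, 0.0)
            if np.isinf(df_total):
                p = 2.0 * norm.sf(np.abs(tstat))
            else:
                p = 2.0 * t_dist.sf(np.abs(tstat), df_total)
        flags = bh_fdr(p, q)
        for j, analyte in enumerate(fits.analytes):
            rows.append(
                {
                    "analyte": analyte,
                    "contrast": label,
                    "estimate": float(est[j]),
                    "se": float(se[j]),
                    "t": float(tstat[j]),
                    "df": float(df_total),
                    "p_value": float(p[j]),
                    "neg_log10_p": float(-np.log10(max(p[j], 1e-300))),
                    "fdr_significant": bool(flags[j]),
                }
            )
    table = pd.DataFrame(rows)
    return EBayesFit(table=table, d0=d0, s02=s02, s2_tilde=s2t)


def standardise_metabolomics(values: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform strictly positive features, then scale to SD 1.

    Features that are not strictly positive (e.g. already-log or ratio
    features spanning zero) are standardised without the log step.
    """
    out = values.copy()
    for col in out.columns:
        v = out[col].astype(float)
        if (v > 0).all():
            v = np.log(v)
        sd = v.std(ddof=1)
        out[col] = (v - v.mean()) / (sd if sd > 0 else 1.0)
    return out


def log_transform_blood_measures(values: pd.DataFrame) -> pd.DataFrame:
    """Natural-log scale for blood count / chemistry measures.

    Exponentiated coefficients from models on this scale are reported as
    multiplicative (percentage) differences between trajectories.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = values.astype(float)
        if (v <= 0).any().any():
            raise ValueError("blood measures must be strictly positive to log")
        return np.log(v)
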