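"""Synthetic longitudinal cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
birth cohort with repeated 13-item questionnaire measurements on ten
occasions between ages 10 and 25, four latent trajectory classes with
known mixing proportions, occasion-level missingness that grows with age
(attrition), subject covariates, biomarker panels with below-LOD
censoring, and binary/continuous outcomes with planted class effects.

Item-level generation: the latent occasion value (class curve + subject
random intercept + Gaussian residual) is truncated to [0, 26] and rounded
half-up to the intended sum score; the sum is then spread over the 13
items (values in {0,1,2}) in a random order.  Scoring the items therefore
reproduces the latent sum exactly, so any mechanism-level detail beyond
the sum-score distribution is intentionally unmodelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import FPBasis, build_fp_basis
from .catalogues import metabolomic_catalogue, protein_catalogue
from .smfq import ITEM_COLUMNS, MAX_SCORE

CLASS_NAMES = (
    "low-stable",
    "adolescent-limited",
    "adolescent-persistent",
    "adulthood-onset",
)

#: the cohort's questionnaire schedule (years)
DEFAULT_AGES: tuple[float, ...] = (10, 12, 13, 16, 17, 18, 21, 22, 23, 25)

#: reported class shares (69.6, 13.3, 7.0, 10.0)% normalised onto the simplex
DEFAULT_PROPORTIONS: tuple[float, ...] = tuple(
    p / 0.999 for p in (0.696, 0.133, 0.070, 0.100)
)

#: per-occasion response probabilities declining with age (cohort attrition)
DEFAULT_RESPONSE_RATES: tuple[float, ...] = (
    0.95, 0.92, 0.90, 0.80, 0.75, 0.72, 0.62, 0.58, 0.55, 0.50
)

_TRAJECTORY_BASIS = FPBasis(powers=(1.0, 2.0))

# anchor points (age: mean score) sketching the four qualitative shapes:
# flat-low; rise-then-fall peaking mid-adolescence; early rise then
# sustained high; low until ~17 then rising.  Quadratic coefficients are
# fitted to these anchors once at import.
_ANCHORS: dict[str, dict[float, float]] = {
    "low-stable": {10: 2.2, 13: 2.0, 17: 1.8, 21: 2.0, 25: 2.3},
    "adolescent-limited": {10: 5.5, 13: 8.0, 16: 8.5, 18: 7.5, 21: 5.5, 25: 3.5},
    "adolescent-persistent": {10: 6.0, 13: 9.5, 16: 11.5, 18: 12.0, 21: 12.5, 25: 12.0},
    "adulthood-onset": {10: 2.5, 13: 2.0, 16: 2.5, 18: 4.0, 21: 7.5, 25: 11.5},
}


def _fit_anchor_coefficients() -> np.ndarray:
    coefs = []
    for name in CLASS_NAMES:
        ages = np.array(sorted(_ANCHORS[name]))
        vals = np.array([_ANCHORS[name][a] for a in ages])
        X = build_fp_basis(ages, _TRAJECTORY_BASIS)
        beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
        coefs.append(beta)
    return np.vstack(coefs)


DEFAULT_CLASS_TRAJECTORIES: np.ndarray = _fit_anchor_coefficients()


class ConfigurationError(ValueError):
    """The generator configuration violates an invariant."""


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions for the subject covariates."""

    p_female: float = 0.5
    education_levels: tuple[str, ...] = (
        "CSE/none", "Vocational", "O-level", "A-level", "Degree"
    )
    education_probs: tuple[float, ...] = (0.15, 0.09, 0.35, 0.26, 0.15)
    social_class_levels: tuple[str, ...] = (
        "I", "II", "III non-manual", "III manual", "IV/V"
    )
    social_class_probs: tuple[float, ...] = (0.07, 0.34, 0.42, 0.07, 0.10)
    bmi_log_mean: float = float(np.log(17.2))
    bmi_log_sd: float = 0.15  # right-skewed childhood BMI


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults encode the emulated study design: n=2000 subjects, the
    ten-occasion age schedule, four classes at the reported shares,
    quadratic trajectory shapes, residual SD 2.5 score units with no
    subject random intercept (the default cohort is group-based-trajectory
    data, matching the model family the analysis selects; set
    ``random_intercept_sd`` > 0 for growth-mixture data), and MCAR
    per-occasion missingness declining with age.  Noise defaults are set
    so that the floor effect at score 0 (the Gaussian-then-truncate
    mechanism) leaves planted class proportions recoverable.
    """

    n_subjects: int = 2000
    occasion_ages: tuple[float, ...] = DEFAULT_AGES
    class_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    class_trajectories: np.ndarray | None = None  # G x p basis coefficients
    trajectory_basis: FPBasis = _TRAJECTORY_BASIS
    random_intercept_sd: float = 0.0
    class_variance_multipliers: tuple[float, ...] | None = None
    residual_sd: float = 2.5
    response_rates: tuple[float, ...] | float = DEFAULT_RESPONSE_RATES
    dropout_hazard: float = 0.0
    class_response_odds: tuple[float, ...] | None = None  # MAR-on-class, off
    covariate_model: CovariateModel = field(default_factory=CovariateModel)
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        p = np.asarray(self.class_proportions, float)
        if np.any(p <= 0):
            raise ConfigurationError("class proportions must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"class_proportions must sum to 1 within 1e-12 (got {p.sum()!r})"
            )
        ages = np.asarray(self.occasion_ages, float)
        if np.any(np.diff(ages) <= 0):
            raise ConfigurationError("occasion_ages must be strictly increasing")
        if self.residual_sd < 0 or self.random_intercept_sd < 0:
            raise ConfigurationError("noise SDs must be nonnegative")
        mult = self.class_variance_multipliers
        if mult is not None:
            m = np.asarray(mult, float)
            if len(m) != len(p) or np.any(m <= 0):
                raise ConfigurationError(
                    "class_variance_multipliers must be positive, one per class"
                )
        traj = self.class_trajectories
        if traj is not None and np.asarray(traj).shape[0] != len(p):
            raise ConfigurationError("one trajectory coefficient vector per class")
        rr = self.response_rates
        rates = np.full(len(ages), float(rr)) if np.isscalar(rr) else np.asarray(rr, float)
        if len(rates) != len(ages) or np.any((rates < 0) | (rates > 1)):
            raise ConfigurationError(
                "response_rates must lie in [0,1], one per occasion"
            )

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    def trajectories(self) -> np.ndarray:
        if self.class_trajectories is not None:
            return np.asarray(self.class_trajectories, float)
        if self.n_classes == len(CLASS_NAMES):
            return DEFAULT_CLASS_TRAJECTORIES.copy()
        raise ConfigurationError(
            "class_trajectories must be given when n_classes != 4"
        )

    def resolved_response_rates(self) -> np.ndarray:
        rr = self.response_rates
        if np.isscalar(rr):
            return np.full(len(self.occasion_ages), float(rr))
        return np.asarray(rr, float)


@dataclass
class LongitudinalCohort:
    """A generated cohort: subject covariates plus long-format occasions.

    ``covariates`` has one row per subject (subject_id, true_class, sex,
    maternal_education, maternal_social_class, bmi_age10,
    family_adversity, imd_quintile); ``occasions`` is long format
    (subject_id, age, item01..item13) with missing occasions removed.
    """

    covariates: pd.DataFrame
    occasions: pd.DataFrame

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    @property
    def true_class(self) -> pd.Series:
        return self.covariates.set_index("subject_id")["true_class"]


def generate_cohort(config: GeneratorConfig) -> LongitudinalCohort:
    """Draw a cohort under ``config``; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    G = config.n_classes
    ages = np.asarray(config.occasion_ages, float)
    T = len(ages)
    props = np.asarray(config.class_proportions, float)
    mult = (
        np.ones(G)
        if config.class_variance_multipliers is None
        else np.asarray(config.class_variance_multipliers, float)
    )

    true_class = rng.choice(G, size=n, p=props) + 1
    intercepts = rng.normal(0.0, config.random_intercept_sd, size=n) * mult[
        true_class - 1
    ]

    X = build_fp_basis(ages, config.trajectory_basis)  # T x p
    curves = X @ config.trajectories().T  # T x G
    latent = (
        curves.T[true_class - 1]  # n x T
        + intercepts[:, None]
        + rng.normal(0.0, config.residual_sd, size=(n, T))
    )
    sums = np.clip(np.floor(latent + 0.5), 0, MAX_SCORE).astype(int)

    # spread each sum over 13 items in {0,1,2}, random order per occasion
    q, r = np.divmod(sums.ravel(), 2)
    ranks = np.argsort(rng.random((n * T, 13)), axis=1)
    items = np.where(ranks < q[:, None], 2, np.where(ranks == q[:, None], r[:, None], 0))
    items = items.reshape(n, T, 13)

    rates = config.resolved_response_rates()
    if config.class_response_odds is not None:
        odds_mult = np.asarray(config.class_response_odds, float)[true_class - 1]
        odds = rates[None, :] / (1.0 - rates[None, :] + 1e-12) * odds_mult[:, None]
        p_resp = odds / (1.0 + odds)
    else:
        p_resp = np.broadcast_to(rates[None, :], (n, T))
    responded = rng.random((n, T)) < p_resp
    if config.dropout_hazard > 0:
        alive = np.cumprod(rng.random((n, T)) >= config.dropout_hazard, axis=1) > 0
        responded &= alive

    subject_ids = np.array([f"S{i:06d}" for i in range(1, n + 1)])
    cm = config.covariate_model
    covariates = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "true_class": true_class,
            "sex": np.where(rng.random(n) < cm.p_female, "female", "male"),
            "maternal_education": rng.choice(
                cm.education_levels, size=n, p=cm.education_probs
            ),
            "maternal_social_class": rng.choice(
                cm.social_class_levels, size=n, p=cm.social_class_probs
            ),
            "bmi_age10": np.exp(rng.normal(cm.bmi_log_mean, cm.bmi_log_sd, size=n)),
            "family_adversity": np.minimum(rng.poisson(1.2, size=n), 10),
            "imd_quintile": rng.choice(
                [1, 2, 3, 4, 5], size=n, p=(0.33, 0.20, 0.18, 0.15, 0.14)
            ),
        }
    )

    subj_idx, occ_idx = np.nonzero(responded)
    occasions = pd.DataFrame(
        items[subj_idx, occ_idx], columns=ITEM_COLUMNS
    )
    occasions.insert(0, "age", ages[occ_idx])
    occasions.insert(0, "subject_id", subject_ids[subj_idx])
    return LongitudinalCohort(covariates=covariates, occasions=occasions)


# ---------------------------------------------------------------------------
# biomarker panels


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a synthetic analyte panel.

    ``metadata`` carries analyte/family/category; ``class_shifts`` maps
    analyte -> {class index (1-based) -> additive shift on the analysis
    (log) scale}; ``below_lod_fractions`` maps analyte -> target fraction
    of values left-censored at the analyte's limit of detection.
    """

    metadata: pd.DataFrame
    class_shifts: dict = field(default_factory=dict)
    below_lod_fractions: dict = field(default_factory=dict)
    analyte_sd: float = 1.0

    def __post_init__(self):
        if self.metadata["analyte"].duplicated().any():
            raise ConfigurationError("duplicate analyte names in panel metadata")
        for frac in self.below_lod_fractions.values():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("below-LOD fractions must be in [0,1]")


@dataclass
class BiomarkerPanel:
    """Subjects x analytes values with metadata and censoring flags.

    ``values`` is indexed by subject_id; ``censored`` is the same shape
    (True where the delivered value was below the LOD and left-censored
    at it); ``metadata`` has one row per analyte with family, category,
    lod and below_lod_fraction.
    """

    values: pd.DataFrame
    censored: pd.DataFrame
    metadata: pd.DataFrame

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, analytes: list[str]) -> "BiomarkerPanel":
        meta = self.metadata[self.metadata["analyte"].isin(analytes)].reset_index(
            drop=True
        )
        return BiomarkerPanel(
            values=self.values[analytes].copy(),
            censored=self.censored[analytes].copy(),
            metadata=meta,
        )


def default_protein_panel_spec(
    n_high_lod: int = 25, high_fraction: float = 0.7, low_fraction: float = 0.1
) -> PanelSpec:
    """The default 92-protein panel: ``n_high_lod`` analytes are given a
    below-LOD fraction above the 50% exclusion threshold (so the standard
    filter retains 92 - ``n_high_lod``), the remainder a low fraction."""
    meta = protein_catalogue()
    fractions = {}
    for i, name in enumerate(meta["analyte"]):
        fractions[name] = high_fraction if i < n_high_lod else low_fraction
    return PanelSpec(metadata=meta, below_lod_fractions=fractions)


def default_metabolomic_panel_spec() -> PanelSpec:
    """Metabolomic panel including the lipoprotein-subclass block."""
    return PanelSpec(metadata=metabolomic_catalogue(include_subclasses=True))


def generate_biomarker_panel(
    cohort: LongitudinalCohort, panel_spec: PanelSpec, seed: int
) -> BiomarkerPanel:
    """Draw log-scale analyte values with class shifts and LOD censoring.

    Values are class-shifted Gaussians on the analysis (log) scale; for
    each analyte the LOD is placed at the empirical quantile matching its
    configured below-LOD fraction, and values below it are flagged and
    left-censored at the LOD.
    """
    rng = np.random.default_rng(seed)
    meta = panel_spec.metadata.reset_index(drop=True).copy()
    names = list(meta["analyte"])
    classes = cohort.covariates["true_class"].to_numpy()
    G = int(classes.max())
    n, m = len(classes), len(names)

    shift_matrix = np.zeros((G, m))
    for analyte, shifts in panel_spec.class_shifts.items():
        if analyte not in names:
            raise ConfigurationError(f"class shift for unknown analyte {analyte!r}")
        j = names.index(analyte)
        for cls, delta in shifts.items():
            if not 1 <= int(cls) <= G:
                raise ConfigurationError(
                    f"class shift for unknown class {cls!r} on {analyte!r}"
                )
            shift_matrix[int(cls) - 1, j] = float(delta)

    values = rng.normal(0.0, panel_spec.analyte_sd, size=(n, m))
    values += shift_matrix[classes - 1]

    lods = np.full(m, -np.inf)
    censored = np.zeros((n, m), dtype=bool)
    for j, name in enumerate(names):
        frac = float(panel_spec.below_lod_fractions.get(name, 0.0))
        if frac <= 0.0:
            continue
        if frac >= 1.0:
            lods[j] = values[:, j].max() + 1.0
            censored[:, j] = True
        else:
            lods[j] = np.quantile(values[:, j], frac)
            censored[:, j] = values[:, j] < lods[j]
        values[censored[:, j], j] = lods[j]

    meta["lod"] = lods
    meta["below_lod_fraction"] = censored.mean(axis=0)
    ids = cohort.covariates["subject_id"]
    return BiomarkerPanel(
        values=pd.DataFrame(values, columns=names, index=ids),
        censored=pd.DataFrame(censored, columns=names, index=ids),
        metadata=meta,
    )


# ---------------------------------------------------------------------------
# outcomes

#: default covariate effects on the log-risk scale (applied to the derived
#: numeric columns female/educ_level/bmi_c)
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "female": 0.35,
    "educ_level": -0.06,
    "bmi_c": 0.02,
}


@dataclass(frozen=True)
class OutcomeEffectConfig:
    """A binary outcome with planted class risk ratios.

    ``class_risk_ratios`` maps non-reference class index (1-based; the
    reference is class 1) to its risk ratio; ``covariate_effects`` are
    log-scale coefficients on the derived numeric covariate columns.
    """

    outcome_name: str
    baseline_risk: float
    class_risk_ratios: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.baseline_risk <= 1.0:
            raise ConfigurationError("baseline_risk must be a probability")
        for cls, rr in self.class_risk_ratios.items():
            if rr <= 0:
                raise ConfigurationError(f"risk ratio for class {cls} must be positive")
        max_rr = max(self.class_risk_ratios.values(), default=1.0)
        if self.baseline_risk * max(max_rr, 1.0) > 1.0:
            raise ConfigurationError(
                "baseline_risk x max class risk ratio exceeds 1"
            )


@dataclass(frozen=True)
class ContinuousOutcomeConfig:
    """A continuous outcome with planted class mean differences."""

    outcome_name: str
    reference_mean: float = 0.0
    class_shifts: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)
    sd: float = 1.0


def covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate columns used by planted outcome effects."""
    cm = CovariateModel()
    return pd.DataFrame(
        {
            "female": (covariates["sex"] == "female").astype(float),
            "educ_level": covariates["maternal_education"]
            .map({lvl: i for i, lvl in enumerate(cm.education_levels)})
            .astype(float),
            "social_level": covariates["maternal_social_class"]
            .map({lvl: i for i, lvl in enumerate(cm.social_class_levels)})
            .astype(float),
            "bmi_c": covariates["bmi_age10"].astype(float) - 17.5,
        },
        index=covariates.index,
    )


def generate_outcomes(
    cohort: LongitudinalCohort,
    effect_configs,
    seed: int,
) -> pd.DataFrame:
    """Draw outcomes per subject from true class + covariates.

    ``effect_configs`` is one config or a list of
    :class:`OutcomeEffectConfig` / :class:`ContinuousOutcomeConfig`.
    Binary risks are baseline x RR(class) x exp(covariate terms); a risk
    above 1 is a configuration error reporting the offending count.
    """
    if not isinstance(effect_configs, (list, tuple)):
        effect_configs = [effect_configs]
    rng = np.random.default_rng(seed)
    cov = cohort.covariates
    if "true_class" not in cov.columns or cov["true_class"].isna().any():
        raise ConfigurationError("cohort lacks true_class")
    classes = cov["true_class"].to_numpy()
    design = covariate_design(cov)
    out = pd.DataFrame({"subject_id": cov["subject_id"]})

    for cfg in effect_configs:
        lin = np.zeros(len(cov))
        for col, coefficient in cfg.covariate_effects.items():
            if col not in design.columns:
                raise ConfigurationError(f"unknown covariate effect column {col!r}")
            lin += coefficient * design[col].to_numpy()
        if isinstance(cfg, OutcomeEffectConfig):
            rr = np.ones(int(classes.max()))
            for cls, value in cfg.class_risk_ratios.items():
                if not 1 <= int(cls) <= len(rr):
                    raise ConfigurationError(f"risk ratio for unknown class {cls!r}")
                rr[int(cls) - 1] = value
            risk = cfg.baseline_risk * rr[classes - 1] * np.exp(lin)
            n_bad = int((risk > 1.0).sum())
            if n_bad:
                raise ConfigurationError(
                    f"outcome {cfg.outcome_name!r}: {n_bad} subjects have risk > 1 "
                    "after covariate effects"
                )
            out[cfg.outcome_name] = (rng.random(len(cov)) < risk).astype(int)
        elif isinstance(cfg, ContinuousOutcomeConfig):
            shift = np.zeros(int(classes.max()))
            for cls, value in cfg.class_shifts.items():
                shift[int(cls) - 1] = value
            mean = cfg.reference_mean + shift[classes - 1] + lin
            out[cfg.outcome_name] = mean + rng.normal(0.0, cfg.sd, size=len(cov))
        else:
            raise ConfigurationError(f"unknown outcome config type {type(cfg)!r}")
    return out


#: Table-2-style planted risk ratios for the depression-diagnosis outcome:
#: adolescent-limited 3.65, adolescent-persistent 13.11, adulthood-onset 6.25
#: versus the low-stable reference, baseline risk 0.02.
DEFAULT_DEPRESSION_OUTCOME = OutcomeEffectConfig(
    outcome_name="icd10_depressive_episode",
    baseline_risk=0.02,
    class_risk_ratios={2: 3.65, 3: 13.11, 4: 6.25},
    covariate_effects=dict(DEFAULT_COVARIATE_EFFECTS),
)
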