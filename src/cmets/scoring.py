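"""Continuous metabolic syndrome (cMetS) score.

The score is built per component — waist circumference (``wc``), mean
arterial pressure (``map``), HDL-cholesterol (``hdl``), triglycerides
(``tg``) and fasting glucose (``fbg``) — by regressing the component on
age and sex with ordinary least squares, standardizing the residuals by
the residual SD (n − p denominator), flipping the sign of the HDL
z-score (HDL is inversely related to metabolic risk), and summing the
five z-scores.  A higher cMetS indicates a less favorable metabolic
profile.  On the fitting sample each z-score has mean 0 and, under the
n − p convention, SD exactly 1, so the cMetS mean is 0 by construction.

The standardization is internal to the analysis sample: the score is
sample-specific and fitted models applied to a different cohort emit a
warning rather than an error.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, TransformerMixin

from cmets.derived import add_derived_measures

logger = logging.getLogger(__name__)

__all__ = [
    "SCORE_COMPONENTS",
    "ZScoreModel",
    "CMetSScorer",
    "fit_zscore_model",
    "compute_cmets",
    "models_to_json",
    "models_from_json",
]

#: the five score components, in summation order
SCORE_COMPONENTS = ("wc", "map", "hdl", "tg", "fbg")

_SPECS = ("pooled_age_sex", "by_sex_age", "pooled_age_sex_interaction")


@dataclass
class ZScoreModel:
    """Age/sex regression of one component, used to standardize residuals.

    ``coefficients`` maps coefficient names to values for the pooled
    specs (``intercept``, ``age``, ``sex_male`` and optionally
    ``age:sex_male``); for ``by_sex_age`` it maps each sex to its own
    ``{intercept, age}`` dict and ``residual_sd`` is likewise per sex.
    """

    component: str
    covariate_spec: str
    coefficients: dict
    residual_sd: float | dict
    n_fit: int
    log_scale: bool = False

    def __post_init__(self):
        if self.covariate_spec not in _SPECS:
            raise ValueError(f"unknown covariate_spec {self.covariate_spec!r}")
        sds = (
            self.residual_sd.values()
            if isinstance(self.residual_sd, dict)
            else [self.residual_sd]
        )
        if any(sd <= 0 for sd in sds):
            raise ValueError(
                f"degenerate fit for {self.component}: residual SD must be > 0"
            )

    # -- prediction ------------------------------------------------------
    def predict(self, age, sex):
        age = np.asarray(age, dtype=float)
        male = (np.asarray(sex) == "male").astype(float)
        if self.covariate_spec == "by_sex_age":
            out = np.empty(age.shape)
            for s, ind in (("male", male == 1), ("female", male == 0)):
                c = self.coefficients[s]
                out[ind] = c["intercept"] + c["age"] * age[ind]
            return out
        c = self.coefficients
        out = c["intercept"] + c["age"] * age + c["sex_male"] * male
        if self.covariate_spec == "pooled_age_sex_interaction":
            out = out + c["age:sex_male"] * age * male
        return out

    def _sd_for(self, sex):
        if isinstance(self.residual_sd, dict):
            return np.array([self.residual_sd[s] for s in np.asarray(sex)])
        return self.residual_sd

    def standardize(self, value, age, sex):
        """z = (observed − predicted) / residual SD (log scale if fitted so)."""
        v = np.asarray(value, dtype=float)
        if self.log_scale:
            v = np.log(v)
        return (v - self.predict(age, sex)) / self._sd_for(sex)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "covariate_spec": self.covariate_spec,
            "coefficients": self.coefficients,
            "residual_sd": self.residual_sd,
            "n_fit": self.n_fit,
            "log_scale": self.log_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreModel":
        return cls(**d)


def _ols(y: np.ndarray, X: np.ndarray, names: list[str], n_min: int):
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"insufficient n for OLS fit: n={n}, p={p}")
    res = sm.OLS(y, X).fit()
    rsd = float(np.sqrt(res.ssr / (n - p)))
    # scale-relative: a constant response leaves ~1e-15 numerical residue
    if not np.isfinite(rsd) or rsd <= 1e-8 * max(1.0, float(np.abs(y).mean())):
        raise ValueError("degenerate fit: zero residual variance")
    return dict(zip(names, (float(b) for b in res.params))), rsd


def fit_zscore_model(
    cohort: pd.DataFrame,
    component: str,
    covariate_spec: str = "pooled_age_sex",
    log_scale: bool = False,
) -> ZScoreModel:
    """OLS fit of one component on the age/sex design.

    Rows with missing values in the component, age or sex are dropped
    (logged).  The residual SD uses the n − p denominator.  A constant
    component (zero residual variance) is an error, not a silent model.
    """
    if covariate_spec not in _SPECS:
        raise ValueError(f"unknown covariate_spec {covariate_spec!r}")
    needed = cohort[[component, "age", "sex"]].dropna()
    n_drop = len(cohort) - len(needed)
    if n_drop:
        logger.info("%s fit: dropped %d incomplete rows", component, n_drop)
    y = needed[component].to_numpy(dtype=float)
    if log_scale:
        if np.any(y <= 0):
            raise ValueError(f"log-scale fit of {component} needs positive values")
        y = np.log(y)
    age = needed["age"].to_numpy(dtype=float)
    male = (needed["sex"] == "male").to_numpy(dtype=float)

    if covariate_spec == "by_sex_age":
        coefs, sds = {}, {}
        for s, ind in (("male", male == 1), ("female", male == 0)):
            X = np.column_stack([np.ones(ind.sum()), age[ind]])
            coefs[s], sds[s] = _ols(y[ind], X, ["intercept", "age"], 4)
        return ZScoreModel(component, covariate_spec, coefs, sds, len(needed), log_scale)

    cols = [np.ones(len(y)), age, male]
    names = ["intercept", "age", "sex_male"]
    if covariate_spec == "pooled_age_sex_interaction":
        cols.append(age * male)
        names.append("age:sex_male")
    coefs, rsd = _ols(y, np.column_stack(cols), names, len(names) + 2)
    return ZScoreModel(component, covariate_spec, coefs, rsd, len(y), log_scale)


def compute_cmets(cohort: pd.DataFrame, models: dict[str, ZScoreModel]) -> pd.DataFrame:
    """Per-subject z-scores and their signed sum.

    ``models`` must contain one fitted model per score component.  The
    HDL z-score is multiplied by −1 before summation.  Subjects missing
    any component value get NaN scores and are counted in the log.
    """
    missing = set(SCORE_COMPONENTS) - set(models)
    if missing:
        raise ValueError(f"missing models for components: {sorted(missing)}")
    df = cohort if "map" in cohort.columns else add_derived_measures(cohort)
    needed = ["age", "sex", *SCORE_COMPONENTS]
    ok = df[needed].notna().all(axis=1).to_numpy()
    if (~ok).sum():
        logger.info("cMetS: %d subjects excluded for missing values", (~ok).sum())
    out = pd.DataFrame(index=df.index)
    sub = df.loc[ok]
    total = np.zeros(ok.sum())
    for comp in SCORE_COMPONENTS:
        z = models[comp].standardize(
            sub[comp].to_numpy(), sub["age"].to_numpy(), sub["sex"].to_numpy()
        )
        signed = -z if comp == "hdl" else z
        col = np.full(len(df), np.nan)
        col[ok] = signed
        out[f"z_{comp}"] = col
        total += signed
    cm = np.full(len(df), np.nan)
    cm[ok] = total
    out["cmets"] = cm
    return out


class CMetSScorer(BaseEstimator, TransformerMixin):
    """Fit the five age/sex regressions and score a cohort.

    scikit-learn-style transformer: ``fit`` runs the per-component OLS
    fits, ``transform`` appends ``z_wc … z_fbg`` (HDL sign-flipped) and
    their sum ``cmets``.  MAP is derived from SBP/DBP on the fly when
    absent.

    Parameters
    ----------
    covariate_spec : {'pooled_age_sex', 'by_sex_age', 'pooled_age_sex_interaction'}
        Design of the adjustment regressions (default pooled intercept +
        age + sex indicator).
    log_tg : bool
        Standardize triglycerides on the log scale (sensitivity option).

    Attributes
    ----------
    models_ : dict of component -> ZScoreModel
    n_fit_ : int

    Notes
    -----
    The score is sample-specific: calling ``transform`` on data that do
    not look like the fitting sample triggers a ``UserWarning``.
    """

    def __init__(self, covariate_spec: str = "pooled_age_sex", log_tg: bool = False):
        self.covariate_spec = covariate_spec
        self.log_tg = log_tg

    def fit(self, X: pd.DataFrame, y=None) -> "CMetSScorer":
        df = X if "map" in X.columns else add_derived_measures(X)
        self.models_ = {
            comp: fit_zscore_model(
                df, comp, self.covariate_spec,
                log_scale=(self.log_tg and comp == "tg"),
            )
            for comp in SCORE_COMPONENTS
        }
        self.n_fit_ = len(df)
        self._fit_fingerprint_ = _fingerprint(df)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise RuntimeError("CMetSScorer is not fitted")
        df = X if "map" in X.columns else add_derived_measures(X)
        if _fingerprint(df) != self._fit_fingerprint_:
            warnings.warn(
                "scoring a cohort different from the fitting sample: the cMetS "
                "score is sample-specific and its scale does not transfer "
                "across populations without revalidation",
                UserWarning,
                stacklevel=2,
            )
        scores = compute_cmets(df, self.models_)
        out = df.copy()
        for c in scores.columns:
            out[c] = scores[c].to_numpy()
        return out

    def fit_transform(self, X: pd.DataFrame, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)


def _fingerprint(df: pd.DataFrame):
    cols = [c for c in ("age", *SCORE_COMPONENTS) if c in df.columns]
    sums = tuple(round(float(df[c].sum()), 6) for c in cols)
    return (len(df), sums)


def models_to_json(models: dict[str, ZScoreModel], path) -> None:
    """Serialize fitted z-score models to a JSON file."""
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=2)


def models_from_json(path) -> dict[str, ZScoreModel]:
    with open(path) as fh:
        raw = json.load(fh)
    return {k: ZScoreModel.from_dict(d) for k, d in raw.items()}
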