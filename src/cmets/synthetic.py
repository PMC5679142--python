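"""Synthetic pediatric cohort generator with a latent-severity factor.

Generates subject-level tables of anthropometric and biochemical
measurements for 7–18-year-olds whose per-stratum (sex × age band) means
and SDs match a set of published national summary statistics embedded as
:func:`load_table1_defaults`.  Clustering of cardiometabolic
abnormalities is induced by a single latent severity factor per subject:
each component is

    value = stratum_mean + age_slope * (age - band_midpoint)
            + loading * sigma * L + noise,      L ~ N(0, 1)

with the loading expressed as a fraction of the stratum SD (negative for
HDL-C, which moves opposite to metabolic risk) and the independent-noise
SD chosen so the configured stratum SD is reproduced exactly.
Triglycerides and weight are generated on the log scale (both
right-skewed in practice) and moment-matched to the configured mean/SD
on the natural scale.
Physiologic floors (all values positive, SBP > DBP + 5 mmHg) are enforced
by rejection resampling, which preserves smooth distributions; systolic
and diastolic noise share a common component so the SBP/DBP constraint
almost never binds and the calibrated moments are undisturbed.

Column schema of a generated cohort (one row per subject):

==========  =====================================================
column      meaning / unit
==========  =====================================================
id          integer subject id, 1..n
age         age in years, continuous, uniform within band
sex         ``male`` or ``female``
weight      body weight, kg
height      standing height, cm
wc          waist circumference, cm
sbp, dbp    systolic / diastolic blood pressure, mmHg
fbg         fasting blood glucose, mg/dL
tg          triglycerides, mg/dL
tc          total cholesterol, mg/dL
hdl         HDL cholesterol, mg/dL
ldl         LDL cholesterol, mg/dL
latent      the latent severity factor L (generator bookkeeping,
            dropped by :func:`write_cohort`)
==========  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AGE_BANDS",
    "COMPONENTS",
    "StratumParams",
    "GeneratorConfig",
    "load_table1_defaults",
    "table1_bp_summary",
    "generate_cohort",
    "summarize_cohort",
    "write_cohort",
    "read_cohort",
    "age_band_of",
]

#: age bands in years; half-open intervals covering [7, 19)
AGE_BANDS: dict[str, tuple[float, float]] = {
    "7-10": (7.0, 11.0),
    "11-14": (11.0, 15.0),
    "15-18": (15.0, 19.0),
}

#: measured components generated per subject (derived MAP/BMI/WHtR excluded)
COMPONENTS = ["weight", "height", "wc", "sbp", "dbp", "fbg", "tg", "tc", "hdl", "ldl"]

SUBJECT_COLUMNS = ["id", "age", "sex"] + COMPONENTS

_SEXES = ("male", "female")


@dataclass(frozen=True)
class StratumParams:
    """Mean/SD of each measured component in one sex × age-band stratum."""

    sex: str
    age_band: str
    means: dict[str, float]
    sds: dict[str, float]

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(f"unknown age band {self.age_band!r}")
        for c in COMPONENTS:
            if c not in self.means or c not in self.sds:
                raise ValueError(f"stratum ({self.sex}, {self.age_band}) missing {c}")
            if self.means[c] <= 0:
                raise ValueError(f"mean of {c} must be > 0")
            if self.sds[c] <= 0:
                raise ValueError(f"SD of {c} must be > 0")


# Published per-stratum means (SDs) of the measured components for a
# national school-based sample of 7-18-year-olds; the calibration target
# of the generator.  Units as in the cohort schema.
_TABLE1 = {
    ("male", "7-10"): {
        "weight": (28.36, 9.56),
        "height": (130.87, 10.50),
        "wc": (60.03, 9.54),
        "sbp": (93.85, 12.69),
        "dbp": (60.63, 10.31),
        "fbg": (92.31, 17.26),
        "tg": (86.78, 49.06),
        "tc": (155.43, 29.37),
        "hdl": (47.59, 10.80),
        "ldl": (90.48, 23.46),
    },
    ("female", "7-10"): {
        "weight": (27.06, 7.95),
        "height": (129.27, 9.75),
        "wc": (59.09, 8.53),
        "sbp": (94.12, 12.74),
        "dbp": (61.00, 10.39),
        "fbg": (91.05, 9.83),
        "tg": (87.45, 42.09),
        "tc": (154.03, 29.06),
        "hdl": (46.59, 10.38),
        "ldl": (89.95, 24.75),
    },
    ("male", "11-14"): {
        "weight": (41.43, 13.60),
        "height": (148.43, 12.25),
        "wc": (67.68, 11.25),
        "sbp": (99.16, 12.61),
        "dbp": (63.93, 10.20),
        "fbg": (92.18, 10.45),
        "tg": (85.67, 41.60),
        "tc": (153.29, 27.21),
        "hdl": (46.59, 10.06),
        "ldl": (89.56, 22.72),
    },
    ("female", "11-14"): {
        "weight": (42.68, 12.56),
        "height": (149.28, 11.28),
        "wc": (67.25, 11.11),
        "sbp": (99.71, 12.03),
        "dbp": (63.95, 9.74),
        "fbg": (91.33, 12.16),
        "tg": (89.96, 47.01),
        "tc": (154.89, 25.30),
        "hdl": (45.46, 9.38),
        "ldl": (91.43, 20.53),
    },
    ("male", "15-18"): {
        "weight": (59.75, 16.83),
        "height": (167.71, 13.54),
        "wc": (76.38, 12.76),
        "sbp": (106.55, 12.09),
        "dbp": (68.21, 10.38),
        "fbg": (91.66, 11.17),
        "tg": (89.59, 47.29),
        "tc": (150.18, 27.78),
        "hdl": (44.39, 9.45),
        "ldl": (87.87, 22.56),
    },
    ("female", "15-18"): {
        "weight": (55.31, 13.27),
        "height": (159.80, 8.93),
        "wc": (72.68, 10.00),
        "sbp": (103.76, 11.47),
        "dbp": (66.57, 9.48),
        "fbg": (91.14, 10.82),
        "tg": (89.38, 44.07),
        "tc": (155.75, 25.82),
        "hdl": (46.86, 9.49),
        "ldl": (91.02, 21.84),
    },
}

# Printed mean SBP/DBP/MAP for every row of the same summary table
# (band x sex group, plus totals); used for the MAP linear-identity
# checks, since MAP is linear and the mean MAP equals MAP of the means.
_TABLE1_BP_ROWS = {
    ("7-10", "total"): (93.99, 60.82, 71.88),
    ("7-10", "male"): (93.85, 60.63, 71.70),
    ("7-10", "female"): (94.12, 61.00, 72.04),
    ("11-14", "total"): (99.43, 63.94, 75.77),
    ("11-14", "male"): (99.16, 63.93, 75.68),
    ("11-14", "female"): (99.71, 63.95, 75.87),
    ("15-18", "total"): (105.25, 67.44, 80.05),
    ("15-18", "male"): (106.55, 68.21, 80.98),
    ("15-18", "female"): (103.76, 66.57, 78.98),
    ("total", "total"): (99.17, 63.83, 75.61),
    ("total", "male"): (99.55, 64.08, 75.91),
    ("total", "female"): (98.77, 63.57, 75.31),
}


def load_table1_defaults() -> list[StratumParams]:
    """The six embedded calibration strata (2 sexes × 3 age bands)."""
    return [
        StratumParams(
            sex=sex,
            age_band=band,
            means={c: v[0] for c, v in vals.items()},
            sds={c: v[1] for c, v in vals.items()},
        )
        for (sex, band), vals in _TABLE1.items()
    ]


def table1_bp_summary() -> pd.DataFrame:
    """Printed mean SBP, DBP and MAP per summary-table row.

    Indexed by (age_band, group) where group is ``male``, ``female`` or
    ``total`` and age_band may also be ``total``.  Because MAP is linear
    in (SBP, DBP), applying the MAP formula to the printed mean pressures
    must reproduce the printed mean MAP up to display rounding.
    """
    rows = [
        {"age_band": b, "group": g, "sbp": s, "dbp": d, "map": m}
        for (b, g), (s, d, m) in _TABLE1_BP_ROWS.items()
    ]
    return pd.DataFrame(rows).set_index(["age_band", "group"])


# Fraction of each component's within-age SD carried by the latent
# severity factor.  Calibrated once so that, with the embedded stratum
# moments and the percentile-based abdominal/BP rules, MetS prevalence
# lands near 5% and all component pairs cluster in the expected
# directions.  HDL loads negatively (higher severity -> lower HDL).
DEFAULT_LOADINGS = {
    "weight": 0.40,
    "height": 0.0,
    "wc": 0.32,
    "sbp": 0.22,
    "dbp": 0.22,
    "fbg": 0.10,
    "tg": 0.15,
    "tc": 0.12,
    "hdl": -0.18,
    "ldl": 0.12,
}

# physiologic floors for rejection resampling
_FLOORS = {
    "weight": 5.0,
    "height": 50.0,
    "wc": 20.0,
    "sbp": 50.0,
    "dbp": 25.0,
    "fbg": 40.0,
    "tg": 1.0,
    "tc": 50.0,
    "hdl": 10.0,
    "ldl": 20.0,
}
_MIN_PULSE_PRESSURE = 5.0  # mmHg; SBP must exceed DBP by at least this

# components generated on the log scale (right-skewed in children; also
# keeps the positivity floor from truncating the lower tail, which would
# deflate the calibrated SD for the youngest boys' weight)
_LOGNORMAL = frozenset({"tg", "weight"})


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    n : int
        Number of subjects.
    seed : int
        Seed for the single PRNG stream; fixed seed gives a
        bit-identical cohort.
    stratum_params : list of StratumParams, optional
        Per-stratum calibration moments; defaults to the embedded table.
    male_fraction : float
        Probability a subject is male (default 0.523, the source
        cohort's sex ratio).
    band_weights : tuple of 3 floats
        Sampling probabilities of the 7-10 / 11-14 / 15-18 bands.
    loadings : dict, optional
        Per-component latent-factor loading as a fraction of the
        within-age stratum SD; HDL must load negatively.
    age_slopes : dict, optional
        ``(sex, component) -> units per year`` within-band slopes; by
        default derived from the stratum means as the 7-10 to 15-18
        band-midpoint gradient, ``(mean_15_18 - mean_7_10) / 8``.
    noise_scale : dict, optional
        Per-component fraction of the within-age SD left as independent
        noise.  Derived as ``sqrt(1 - loading**2)`` when omitted; if
        supplied it must satisfy ``loading**2 + noise_scale**2 = 1``
        within 1% so the configured SDs are reproduced.
    bp_noise_corr : float
        Correlation between the idiosyncratic noise of SBP and DBP
        (default 0.85; keeps pulse pressure physiologic — so the
        rejection step almost never binds and the calibrated moments
        survive — and makes the systolic and diastolic percentile flags
        overlap the way they do in survey data).
    target_mets_prevalence_band : (low, high)
        The prevalence range the shipped defaults are calibrated to.
    """

    n: int
    seed: int
    stratum_params: list[StratumParams] | None = None
    male_fraction: float = 0.523
    band_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    loadings: dict[str, float] | None = None
    age_slopes: dict[tuple[str, str], float] | None = None
    noise_scale: dict[str, float] | None = None
    bp_noise_corr: float = 0.85
    target_mets_prevalence_band: tuple[float, float] = (0.03, 0.08)

    def __post_init__(self):
        if not isinstance(self.n, (int, np.integer)) or self.n < 0:
            raise ValueError("n must be a non-negative integer")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError("seed must be a non-negative integer")
        if self.stratum_params is None:
            self.stratum_params = load_table1_defaults()
        keys = {(p.sex, p.age_band) for p in self.stratum_params}
        expected = {(s, b) for s in _SEXES for b in AGE_BANDS}
        if keys != expected:
            raise ValueError("stratum_params must cover exactly the 6 sex x band strata")
        if not 0 < self.male_fraction < 1:
            raise ValueError("male_fraction must be in (0, 1)")
        bw = np.asarray(self.band_weights, dtype=float)
        if bw.shape != (3,) or np.any(bw <= 0) or not np.isclose(bw.sum(), 1.0):
            raise ValueError("band_weights must be 3 positive numbers summing to 1")
        if self.loadings is None:
            self.loadings = dict(DEFAULT_LOADINGS)
        for c in COMPONENTS:
            l = self.loadings.get(c, 0.0)
            if abs(l) >= 1:
                raise ValueError(f"loading for {c} must lie in (-1, 1)")
        if self.loadings.get("hdl", 0.0) >= 0:
            raise ValueError("HDL loading must be negative (inverse risk relation)")
        if self.noise_scale is not None:
            for c in COMPONENTS:
                l = self.loadings.get(c, 0.0)
                ns = self.noise_scale.get(c)
                if ns is None or ns <= 0 or ns > 1:
                    raise ValueError("noise_scale entries must lie in (0, 1]")
                if abs(l * l + ns * ns - 1.0) > 0.01:
                    raise ValueError(
                        f"loading^2 + noise_scale^2 for {c} must reproduce the "
                        f"configured SD within 1% (got {l * l + ns * ns:.4f})"
                    )
        if not 0 <= self.bp_noise_corr < 1:
            raise ValueError("bp_noise_corr must be in [0, 1)")
        lo, hi = self.target_mets_prevalence_band
        if not (0 < lo < hi < 1):
            raise ValueError("target_mets_prevalence_band must be within (0, 1)")

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["stratum_params"] = [asdict(p) for p in self.stratum_params]
        if d["age_slopes"] is not None:
            d["age_slopes"] = {f"{s}:{c}": v for (s, c), v in d["age_slopes"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("stratum_params") is not None:
            d["stratum_params"] = [StratumParams(**p) for p in d["stratum_params"]]
        if d.get("age_slopes") is not None:
            d["age_slopes"] = {
                tuple(k.split(":", 1)): v for k, v in d["age_slopes"].items()
            }
        if d.get("band_weights") is not None:
            d["band_weights"] = tuple(d["band_weights"])
        if d.get("target_mets_prevalence_band") is not None:
            d["target_mets_prevalence_band"] = tuple(d["target_mets_prevalence_band"])
        return cls(**d)


def _default_age_slopes(strata: dict[tuple[str, str], StratumParams]):
    """Per-year gradients from the 7-10 to 15-18 band midpoints (8 years apart)."""
    slopes = {}
    for sex in _SEXES:
        lo = strata[(sex, "7-10")].means
        hi = strata[(sex, "15-18")].means
        for c in COMPONENTS:
            slopes[(sex, c)] = (hi[c] - lo[c]) / 8.0
    return slopes


def _band_midpoint(band: str) -> float:
    lo, hi = AGE_BANDS[band]
    return 0.5 * (lo + hi)


def age_band_of(age) -> np.ndarray:
    """Map continuous ages in [7, 19) to band labels."""
    age_a = np.atleast_1d(np.asarray(age, dtype=float))
    if np.any((age_a < 7) | (age_a >= 19)):
        raise ValueError("ages must lie in [7, 19)")
    labels = np.where(age_a < 11, "7-10", np.where(age_a < 15, "11-14", "15-18"))
    return labels if np.ndim(age) else labels.item()


def _draw_components(rng, strata, cfg, sex, band, age, latent):
    """One vectorized draw of all measured components for the given subjects."""
    n = len(age)
    var_age = 16.0 / 12.0  # variance of U(-2, 2), the within-band age offset
    out = {}
    eps = {c: rng.standard_normal(n) for c in COMPONENTS}
    # shared idiosyncratic noise between the two pressures
    rho = cfg.bp_noise_corr
    eps["dbp"] = rho * eps["sbp"] + np.sqrt(1.0 - rho * rho) * eps["dbp"]

    slopes = cfg.age_slopes
    for c in COMPONENTS:
        mu = np.empty(n)
        sd = np.empty(n)
        slope = np.empty(n)
        mid = np.empty(n)
        for (s, b), p in strata.items():
            m = (sex == s) & (band == b)
            if not m.any():
                continue
            mu[m] = p.means[c]
            sd[m] = p.sds[c]
            slope[m] = slopes[(s, c)]
            mid[m] = _band_midpoint(b)
        sigma_a_sq = sd * sd - slope * slope * var_age
        if np.any(sigma_a_sq <= 0):
            raise ValueError(f"age slope of {c} leaves no within-age variance")
        sigma_a = np.sqrt(sigma_a_sq)
        l = cfg.loadings.get(c, 0.0)
        noise_frac = np.sqrt(1.0 - l * l)
        age_term = slope * (age - mid)
        if c in _LOGNORMAL:
            # lognormal latent, moment-matched to (mu, sigma_a) on the
            # natural scale; the additive age term is mean-zero
            s_log = np.sqrt(np.log1p(sigma_a_sq / (mu * mu)))
            m_log = np.log(mu) - 0.5 * s_log * s_log
            g = l * latent + noise_frac * eps[c]
            out[c] = np.exp(m_log + s_log * g) + age_term
        else:
            out[c] = mu + age_term + sigma_a * (l * latent + noise_frac * eps[c])
    return out


def _violations(vals: dict[str, np.ndarray]) -> np.ndarray:
    bad = np.zeros(len(vals["sbp"]), dtype=bool)
    for c, floor in _FLOORS.items():
        bad |= vals[c] <= floor
    bad |= vals["sbp"] <= vals["dbp"] + _MIN_PULSE_PRESSURE
    return bad


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a subject table under the latent-severity model.

    Returns a DataFrame with the documented cohort schema plus a
    ``latent`` bookkeeping column.  Deterministic under a fixed seed.
    Rows violating physiologic floors or the SBP > DBP + 5 constraint are
    redrawn (conditioning, not clipping, so no point masses appear).
    """
    cfg = config
    strata = {(p.sex, p.age_band): p for p in cfg.stratum_params}
    if cfg.age_slopes is None:
        cfg = GeneratorConfig(**{**asdict_shallow(cfg), "age_slopes": _default_age_slopes(strata)})

    if cfg.n == 0:
        return pd.DataFrame(columns=SUBJECT_COLUMNS + ["latent"])

    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    bands = np.array(list(AGE_BANDS))
    band = bands[rng.choice(3, size=n, p=np.asarray(cfg.band_weights, dtype=float))]
    lo = np.array([AGE_BANDS[b][0] for b in band])
    age = lo + rng.random(n) * 4.0
    latent = rng.standard_normal(n)

    vals = _draw_components(rng, strata, cfg, sex, band, age, latent)
    bad = _violations(vals)
    n_iter = 0
    while bad.any():
        n_iter += 1
        if n_iter > 1000:
            raise RuntimeError("rejection resampling failed to converge")
        redraw = _draw_components(
            rng, strata, cfg, sex[bad], band[bad], age[bad], latent[bad]
        )
        for c in COMPONENTS:
            vals[c][bad] = redraw[c]
        bad_idx = np.flatnonzero(bad)
        still = _violations({c: vals[c][bad_idx] for c in COMPONENTS})
        bad = np.zeros(n, dtype=bool)
        bad[bad_idx[still]] = True

    df = pd.DataFrame({"id": np.arange(1, n + 1), "age": age, "sex": sex})
    for c in COMPONENTS:
        df[c] = vals[c]
    df["latent"] = latent
    return df


def asdict_shallow(cfg: GeneratorConfig) -> dict:
    """Field dict without dataclass deep-copy (StratumParams stay intact)."""
    return {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}


def summarize_cohort(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-stratum mean/SD summary in the layout of the calibration table.

    Rows: (age_band, group) for group in male/female/total, plus an
    overall ``total`` band.  Columns: a two-level (variable, statistic)
    index with mean, sd and n.  SD is reported as NaN for single-subject
    cells (flagged rather than fabricated).  Raises on an empty table.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    variables = list(variables) if variables is not None else [
        c for c in cohort.columns
        if c in COMPONENTS or c in ("map", "bmi", "whtr", "cmets")
    ]
    band = age_band_of(cohort["age"].to_numpy())
    rows = []
    band_keys = list(AGE_BANDS) + ["total"]
    for b in band_keys:
        sel_b = np.ones(len(cohort), dtype=bool) if b == "total" else band == b
        for g in ("male", "female", "total"):
            sel = sel_b if g == "total" else sel_b & (cohort["sex"].to_numpy() == g)
            sub = cohort.loc[sel, variables]
            if len(sub) == 0:
                continue
            row = {"age_band": b, "group": g}
            for v in variables:
                row[(v, "mean")] = sub[v].mean()
                row[(v, "sd")] = sub[v].std(ddof=1) if len(sub) > 1 else np.nan
            row[("n", "")] = len(sub)
            rows.append(row)
    out = pd.DataFrame(rows).set_index(["age_band", "group"])
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort as CSV with exactly the documented subject columns."""
    cols = [c for c in SUBJECT_COLUMNS if c in cohort.columns]
    cohort[cols].to_csv(path, index=False, float_format="%.6f")


def read_cohort(path) -> pd.DataFrame:
    """Read a subject CSV, validating the required columns."""
    df = pd.read_csv(path)
    missing = set(SUBJECT_COLUMNS) - {"id"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(1, len(df) + 1))
    return df
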