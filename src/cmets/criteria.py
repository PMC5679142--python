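"""Pediatric metabolic-syndrome components under modified ATP-III criteria.

Two named threshold presets are shipped and are deliberately not
reconciled, because the normative definition and the summary-table
footnotes of the source survey state different cutoffs:

``methods_text`` (default)
    TG >= 150 mg/dL; HDL-C <= 40 mg/dL; FBG >= 100 mg/dL; abdominal
    obesity as waist-to-height ratio > 0.5; SBP or DBP above the 90th
    percentile for age, sex and height.

``table_footnote``
    TG > 100 mg/dL; HDL-C < 40 mg/dL (boys 15-18 y: < 45 mg/dL);
    FBG > 100 mg/dL; abdominal obesity as WC above the sex/age 90th
    percentile; blood pressure as above.

MetS is at least ``mets_min_components`` (default 3) of the five flags.

Percentile thresholds (BP 90th, WC 90th, BMI 85th/95th) resolve either
empirically within the analysis cohort — sex × integer-age bins, with a
within-bin height tertile for BP, linear-interpolation percentiles —
or from an external normative CSV for blood pressure.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from cmets.derived import add_derived_measures
from cmets.synthetic import age_band_of

logger = logging.getLogger(__name__)

__all__ = [
    "CriteriaConfig",
    "ComponentFlags",
    "preset",
    "interpolated_percentile",
    "EmpiricalPercentiles",
    "fit_empirical_percentiles",
    "MetSClassifier",
    "flag_components",
    "secondary_flags",
]

_CMP = {">": operator.gt, ">=": operator.ge, "<": operator.lt, "<=": operator.le}

#: columns a subject row must provide for the five component flags
REQUIRED_FIELDS = ["age", "sex", "height", "wc", "sbp", "dbp", "fbg", "tg", "hdl"]

FLAG_COLUMNS = ["high_tg", "low_hdl", "high_fbg", "abdominal_obesity", "elevated_bp"]


@dataclass
class CriteriaConfig:
    """One resolvable set of component thresholds.

    Comparators are stored explicitly (strict vs inclusive matters at the
    printed cutoffs and differs between the two presets).
    ``hdl_overrides`` maps (sex, age_band) to a replacement HDL
    threshold.
    """

    preset_name: str
    tg_cmp: str
    tg_threshold: float
    hdl_cmp: str
    hdl_threshold: float
    fbg_cmp: str
    fbg_threshold: float
    abdominal_rule: str  # 'whtr_gt_0.5' | 'wc_gt_90th_pct'
    bp_percentile: float = 90.0
    mets_min_components: int = 3
    hdl_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        for cmp_ in (self.tg_cmp, self.hdl_cmp, self.fbg_cmp):
            if cmp_ not in _CMP:
                raise ValueError(f"unknown comparator {cmp_!r}")
        for thr in (self.tg_threshold, self.hdl_threshold, self.fbg_threshold):
            if thr <= 0:
                raise ValueError("thresholds must be positive")
        if self.abdominal_rule not in ("whtr_gt_0.5", "wc_gt_90th_pct"):
            raise ValueError(f"unknown abdominal rule {self.abdominal_rule!r}")
        if not 0 < self.bp_percentile < 100:
            raise ValueError("bp_percentile must be in (0, 100)")
        if not 1 <= self.mets_min_components <= 5:
            raise ValueError("mets_min_components must be in 1..5")

    def hdl_threshold_for(self, sex: str, age_band: str) -> float:
        return self.hdl_overrides.get((sex, age_band), self.hdl_threshold)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["hdl_overrides"] = {f"{s}:{b}": v for (s, b), v in self.hdl_overrides.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CriteriaConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["hdl_overrides"] = {
            tuple(k.split(":", 1)): v for k, v in (d.get("hdl_overrides") or {}).items()
        }
        return cls(**d)


@dataclass(frozen=True)
class ComponentFlags:
    """Per-subject component flags and the binary MetS label."""

    high_tg: bool
    low_hdl: bool
    high_fbg: bool
    abdominal_obesity: bool
    elevated_bp: bool
    n_components: int
    mets: bool


_PRESETS = {
    "methods_text": dict(
        preset_name="methods_text",
        tg_cmp=">=", tg_threshold=150.0,
        hdl_cmp="<=", hdl_threshold=40.0,
        fbg_cmp=">=", fbg_threshold=100.0,
        abdominal_rule="whtr_gt_0.5",
    ),
    "table_footnote": dict(
        preset_name="table_footnote",
        tg_cmp=">", tg_threshold=100.0,
        hdl_cmp="<", hdl_threshold=40.0,
        fbg_cmp=">", fbg_threshold=100.0,
        abdominal_rule="wc_gt_90th_pct",
        hdl_overrides={("male", "15-18"): 45.0},
    ),
}


def preset(name: str) -> CriteriaConfig:
    """Return one of the two named criteria presets (see module docstring)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return CriteriaConfig(**_PRESETS[name])


def interpolated_percentile(values, level: float):
    """Linear-interpolation (Hyndman–Fan type 7) percentile of a sample."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    if not 0 <= level <= 100:
        raise ValueError("level must be in [0, 100]")
    return float(np.quantile(v, level / 100.0, method="linear"))


class EmpiricalPercentiles:
    """Within-cohort percentile reference for BP, WC and BMI thresholds.

    Bins subjects by sex × integer age; age bins with fewer than
    ``min_bin`` subjects are merged with the adjacent age.  Blood
    pressure is additionally adjusted for height through within-bin
    height tertiles.  Percentiles use linear interpolation (type 7).

    An external normative blood-pressure table may be supplied instead
    (``mode='external'``) as a DataFrame or CSV path with columns
    ``sex, age_year, height_percentile_band, sbp_p90, dbp_p90`` where the
    band is written ``lo-hi`` in percent (e.g. ``0-33.3``); the subject's
    height percentile is still resolved empirically within sex × age.
    """

    def __init__(self, level: float = 90.0, min_bin: int = 20, external_bp=None):
        self.level = level
        self.min_bin = min_bin
        if isinstance(external_bp, (str, bytes)) or hasattr(external_bp, "__fspath__"):
            external_bp = pd.read_csv(external_bp)
        self.external_bp = external_bp
        self.mode = "external" if external_bp is not None else "empirical"

    # -- fitting ---------------------------------------------------------
    def fit(self, cohort: pd.DataFrame) -> "EmpiricalPercentiles":
        df = cohort
        if "bmi" not in df.columns or "whtr" not in df.columns:
            df = add_derived_measures(df)
        age_year = np.floor(df["age"].to_numpy()).astype(int)
        sex = df["sex"].to_numpy()

        self.age_bin_map_ = {}
        for s in ("male", "female"):
            mask = sex == s
            if mask.sum() < self.min_bin:
                raise ValueError(
                    f"too few {s} subjects ({mask.sum()}) for percentile bins"
                )
            counts = pd.Series(age_year[mask]).value_counts().sort_index()
            self.age_bin_map_[s] = _merge_small_bins(counts, self.min_bin)

        bin_id = np.array(
            [self.age_bin_map_[s][a] for s, a in zip(sex, age_year)], dtype=int
        )

        lvl = self.level
        self.wc_p90_ = {}
        self.bmi_bands_ = {}
        self.height_tertiles_ = {}
        self.bp_table_ = {}
        for (s, b), idx in pd.DataFrame({"s": sex, "b": bin_id}).groupby(
            ["s", "b"]
        ).groups.items():
            sub = df.loc[df.index[list(idx)]]
            self.wc_p90_[(s, b)] = interpolated_percentile(sub["wc"], lvl)
            self.bmi_bands_[(s, b)] = (
                interpolated_percentile(sub["bmi"], 85.0),
                interpolated_percentile(sub["bmi"], 95.0),
            )
            h = sub["height"].to_numpy()
            t1 = interpolated_percentile(h, 100.0 / 3.0)
            t2 = interpolated_percentile(h, 200.0 / 3.0)
            self.height_tertiles_[(s, b)] = (t1, t2)
            for ter in range(3):
                tm = (h <= t1) if ter == 0 else ((h > t1) & (h <= t2)) if ter == 1 else (h > t2)
                if tm.sum() == 0:  # fully tied heights: fall back to the bin
                    tm = np.ones(len(sub), dtype=bool)
                self.bp_table_[(s, b, ter)] = (
                    interpolated_percentile(sub["sbp"].to_numpy()[tm], lvl),
                    interpolated_percentile(sub["dbp"].to_numpy()[tm], lvl),
                )
        if self.mode == "external":
            self._external_bands = _parse_external_bp(self.external_bp)
        return self

    def _check_fitted(self):
        if not hasattr(self, "age_bin_map_"):
            raise RuntimeError("percentile reference is not fitted")

    def _bins(self, sex, age):
        self._check_fitted()
        age_year = np.floor(np.asarray(age, dtype=float)).astype(int)
        sex = np.asarray(sex)
        out = np.empty(len(sex), dtype=int)
        for i, (s, a) in enumerate(zip(sex, age_year)):
            m = self.age_bin_map_[s]
            if a not in m:  # age outside fitted range: nearest fitted year
                a = min(max(a, min(m)), max(m))
            out[i] = m[a]
        return sex, age_year, out

    # -- lookups (vectorized) -------------------------------------------
    def wc_p90(self, sex, age):
        sex, _, b = self._bins(sex, age)
        return np.array([self.wc_p90_[(s, bb)] for s, bb in zip(sex, b)])

    def bmi_p85_p95(self, sex, age):
        sex, _, b = self._bins(sex, age)
        arr = np.array([self.bmi_bands_[(s, bb)] for s, bb in zip(sex, b)])
        return arr[:, 0], arr[:, 1]

    def bp_p90(self, sex, age, height):
        sex, age_year, b = self._bins(sex, age)
        height = np.asarray(height, dtype=float)
        if self.mode == "external":
            return self._external_bp_lookup(sex, age_year, b, height)
        ter = np.empty(len(sex), dtype=int)
        for i, (s, bb) in enumerate(zip(sex, b)):
            t1, t2 = self.height_tertiles_[(s, bb)]
            ter[i] = 0 if height[i] <= t1 else 1 if height[i] <= t2 else 2
        arr = np.array([self.bp_table_[(s, bb, t)] for s, bb, t in zip(sex, b, ter)])
        return arr[:, 0], arr[:, 1]

    def _external_bp_lookup(self, sex, age_year, bin_id, height):
        # height percentile resolved empirically within the fitted bins
        sbp90 = np.empty(len(sex))
        dbp90 = np.empty(len(sex))
        for i, (s, a) in enumerate(zip(sex, age_year)):
            t1, t2 = self.height_tertiles_[(s, bin_id[i])]
            pct = 100.0 / 6 if height[i] <= t1 else 50.0 if height[i] <= t2 else 500.0 / 6
            key = (s, int(a))
            if key not in self._external_bands:
                raise ValueError(f"external BP table has no row for sex={s}, age={a}")
            for (lo, hi), (s90, d90) in self._external_bands[key]:
                if lo <= pct <= hi:
                    sbp90[i], dbp90[i] = s90, d90
                    break
            else:
                raise ValueError(
                    f"external BP table bands for sex={s}, age={a} do not cover "
                    f"height percentile {pct:.1f}"
                )
        return sbp90, dbp90


def _merge_small_bins(counts: pd.Series, min_bin: int) -> dict[int, int]:
    """Map integer ages to merged bin ids so every bin holds >= min_bin."""
    ages = list(counts.index)
    sizes = list(counts.to_numpy())
    groups = [[a] for a in ages]
    i = 0
    while i < len(groups):
        if sizes[i] >= min_bin:
            i += 1
            continue
        if i + 1 < len(groups):  # merge forward
            groups[i] = groups[i] + groups[i + 1]
            sizes[i] = sizes[i] + sizes[i + 1]
            del groups[i + 1], sizes[i + 1]
        elif i > 0:  # trailing small bin: merge backward
            groups[i - 1] = groups[i - 1] + groups[i]
            sizes[i - 1] = sizes[i - 1] + sizes[i]
            del groups[i], sizes[i]
            i -= 1
        else:
            raise ValueError("too few subjects for percentile bins even after merging")
    mapping = {}
    for gid, grp in enumerate(groups):
        for a in grp:
            mapping[a] = gid
    return mapping


def _parse_external_bp(table: pd.DataFrame):
    required = {"sex", "age_year", "height_percentile_band", "sbp_p90", "dbp_p90"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"external BP table missing columns: {sorted(missing)}")
    if (table["sbp_p90"] <= table["dbp_p90"]).any():
        raise ValueError("external BP table must have sbp_p90 > dbp_p90")
    bands: dict[tuple[str, int], list] = {}
    for _, row in table.iterrows():
        lo, hi = (float(x) for x in str(row["height_percentile_band"]).split("-"))
        bands.setdefault((row["sex"], int(row["age_year"])), []).append(
            ((lo, hi), (float(row["sbp_p90"]), float(row["dbp_p90"])))
        )
    return bands


def fit_empirical_percentiles(
    cohort: pd.DataFrame, level: float = 90.0, min_bin: int = 20
) -> EmpiricalPercentiles:
    """Fit the within-cohort percentile reference (thin functional wrapper)."""
    return EmpiricalPercentiles(level=level, min_bin=min_bin).fit(cohort)


class MetSClassifier(BaseEstimator, TransformerMixin):
    """Flag the five MetS components and the binary MetS label.

    scikit-learn-style transformer over a cohort DataFrame.  ``fit``
    resolves the criteria preset and fits the percentile reference on the
    cohort (or loads the external BP table); ``transform`` appends the
    boolean flag columns, ``n_components`` and ``mets``.

    Parameters
    ----------
    criteria : str or CriteriaConfig
        ``'methods_text'`` (default), ``'table_footnote'`` or an explicit
        config.
    percentile_mode : {'empirical', 'external'}
        How BP (and, in the footnote preset, WC) 90th percentiles are
        resolved.  External mode needs ``external_bp``.
    external_bp : DataFrame, path or None
        Normative BP table for external mode.
    min_bin : int
        Minimum subjects per sex × age bin before merging.

    Attributes
    ----------
    criteria_ : CriteriaConfig
    reference_ : EmpiricalPercentiles
    n_excluded_ : int
        Rows of the last ``transform`` left unevaluable by missing data.
    """

    def __init__(self, criteria="methods_text", percentile_mode="empirical",
                 external_bp=None, min_bin=20):
        self.criteria = criteria
        self.percentile_mode = percentile_mode
        self.external_bp = external_bp
        self.min_bin = min_bin

    def fit(self, X: pd.DataFrame, y=None) -> "MetSClassifier":
        if self.percentile_mode not in ("empirical", "external"):
            raise ValueError("percentile_mode must be 'empirical' or 'external'")
        if self.percentile_mode == "external" and self.external_bp is None:
            raise ValueError("external percentile mode requires external_bp")
        self.criteria_ = (
            self.criteria if isinstance(self.criteria, CriteriaConfig)
            else preset(self.criteria)
        )
        ext = self.external_bp if self.percentile_mode == "external" else None
        self.reference_ = EmpiricalPercentiles(
            level=self.criteria_.bp_percentile, min_bin=self.min_bin, external_bp=ext
        ).fit(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "criteria_"):
            raise RuntimeError("MetSClassifier is not fitted")
        df = X if {"whtr", "bmi", "map"} <= set(X.columns) else add_derived_measures(X)
        crit = self.criteria_
        ref = self.reference_

        ok = df[REQUIRED_FIELDS].notna().all(axis=1).to_numpy()
        self.n_excluded_ = int((~ok).sum())
        if self.n_excluded_:
            logger.info(
                "%d of %d records unevaluable for MetS flags (missing data)",
                self.n_excluded_, len(df),
            )
        sub = df.loc[ok]
        sex = sub["sex"].to_numpy()
        age = sub["age"].to_numpy()

        high_tg = _CMP[crit.tg_cmp](sub["tg"].to_numpy(), crit.tg_threshold)
        hdl_thr = np.array(
            [crit.hdl_threshold_for(s, b) for s, b in zip(sex, age_band_of(age))]
        )
        low_hdl = _CMP[crit.hdl_cmp](sub["hdl"].to_numpy(), hdl_thr)
        high_fbg = _CMP[crit.fbg_cmp](sub["fbg"].to_numpy(), crit.fbg_threshold)
        if crit.abdominal_rule == "whtr_gt_0.5":
            abdominal = sub["whtr"].to_numpy() > 0.5
        else:
            abdominal = sub["wc"].to_numpy() > ref.wc_p90(sex, age)
        sbp90, dbp90 = ref.bp_p90(sex, age, sub["height"].to_numpy())
        elev_sbp = sub["sbp"].to_numpy() > sbp90
        elev_dbp = sub["dbp"].to_numpy() > dbp90
        elevated_bp = elev_sbp | elev_dbp

        out = df.copy()
        flags = {
            "high_tg": high_tg,
            "low_hdl": low_hdl,
            "high_fbg": high_fbg,
            "abdominal_obesity": abdominal,
            "elevated_sbp": elev_sbp,
            "elevated_dbp": elev_dbp,
            "elevated_bp": elevated_bp,
        }
        for name, arr in flags.items():
            col = pd.array(np.full(len(df), pd.NA, dtype=object), dtype="boolean")
            col[ok] = arr
            out[name] = col
        n_comp = (
            high_tg.astype(int) + low_hdl.astype(int) + high_fbg.astype(int)
            + abdominal.astype(int) + elevated_bp.astype(int)
        )
        nc = pd.array(np.full(len(df), pd.NA, dtype=object), dtype="Int64")
        nc[ok] = n_comp
        out["n_components"] = nc
        mets = pd.array(np.full(len(df), pd.NA, dtype=object), dtype="boolean")
        mets[ok] = n_comp >= crit.mets_min_components
        out["mets"] = mets
        return out


def flag_components(subject, criteria: CriteriaConfig,
                    ref: EmpiricalPercentiles) -> ComponentFlags:
    """Component flags for a single subject (mapping or Series).

    The subject must carry the raw measurement fields; derived WHtR is
    computed on the fly.  Percentile thresholds come from the supplied
    fitted reference.
    """
    row = pd.DataFrame([dict(subject)])
    clf = MetSClassifier(criteria=criteria)
    clf.criteria_ = criteria
    clf.reference_ = ref
    res = clf.transform(row).iloc[0]
    if pd.isna(res["mets"]):
        raise ValueError("subject has missing measurements; flags unevaluable")
    return ComponentFlags(
        high_tg=bool(res["high_tg"]),
        low_hdl=bool(res["low_hdl"]),
        high_fbg=bool(res["high_fbg"]),
        abdominal_obesity=bool(res["abdominal_obesity"]),
        elevated_bp=bool(res["elevated_bp"]),
        n_components=int(res["n_components"]),
        mets=bool(res["mets"]),
    )


def secondary_flags(X: pd.DataFrame, ref: EmpiricalPercentiles) -> pd.DataFrame:
    """Overweight/obesity and lipid flags for the prevalence table.

    overweight: BMI between the sex/age 85th and 95th percentiles;
    obese: BMI above the 95th percentile (mutually exclusive);
    high_ldl: LDL > 110 mg/dL; high_tc: TC > 200 mg/dL (both strict).
    Rows with missing inputs get NA flags.
    """
    df = X if "bmi" in X.columns else add_derived_measures(X)
    needed = ["age", "sex", "bmi", "ldl", "tc"]
    ok = df[needed].notna().all(axis=1).to_numpy()
    sub = df.loc[ok]
    p85, p95 = ref.bmi_p85_p95(sub["sex"].to_numpy(), sub["age"].to_numpy())
    bmi_v = sub["bmi"].to_numpy()
    obese = bmi_v > p95
    overweight = (bmi_v > p85) & ~obese
    vals = {
        "overweight": overweight,
        "obese": obese,
        "high_ldl": sub["ldl"].to_numpy() > 110.0,
        "high_tc": sub["tc"].to_numpy() > 200.0,
    }
    out = pd.DataFrame(index=df.index)
    for name, arr in vals.items():
        col = pd.array(np.full(len(df), pd.NA, dtype=object), dtype="boolean")
        col[ok] = arr
        out[name] = col
    return out
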