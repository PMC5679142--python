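"""End-to-end orchestration: generate/load → derive → classify → score → validate.

Produces the four report tables of a cMetS validation study:

* table 1 — descriptives (mean/SD) per variable × age band, split by sex,
  with between-sex equal-variance t-test p-values;
* table 2 — prevalence (count, %) of the component and secondary flags
  per age band and sex, with chi-square p-values (denominators reported
  explicitly, since evaluable subsets can differ by flag);
* table 3 — mean ± SD cMetS by MetS status and by component-count group
  (0, 1, 2, ≥3) per sex group, with t-test / ANOVA p-values;
* table 4 — ROC cutoff results per sex × age-band stratum plus overall.

The run is a pure function of (config, seeds): tables re-written from the
same config are byte-identical.  Raw p-values are kept in CSVs; display
flooring (``< 0.001``) happens only in the rendered text report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

import cmets
from cmets.criteria import FLAG_COLUMNS, MetSClassifier, secondary_flags
from cmets.derived import add_derived_measures
from cmets.roc import (
    DEFAULT_BOOTSTRAP_B,
    DEFAULT_BOOTSTRAP_SEED,
    CutoffResult,
    stratified_validation,
)
from cmets.scoring import CMetSScorer, models_to_json
from cmets.synthetic import (
    AGE_BANDS,
    GeneratorConfig,
    age_band_of,
    generate_cohort,
    read_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "descriptive_tests",
    "two_sample_t",
    "chi_square",
    "one_way_anova",
    "render_report",
]

_T1_VARIABLES = ["weight", "height", "wc", "sbp", "dbp", "fbg", "tg", "tc",
                 "hdl", "map", "bmi", "whtr", "ldl"]
_T2_FLAGS = ["abdominal_obesity", "overweight", "obese", "high_fbg", "high_tg",
             "high_ldl", "high_tc", "low_hdl", "elevated_sbp", "elevated_dbp",
             "elevated_bp", "mets"]


# -- elementary tests (delegated to standard routines) -------------------

def two_sample_t(a, b) -> tuple[float, float]:
    """Equal-variance two-sample t test; NaN (flagged) if both groups constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return (np.nan, np.nan)
    if np.var(a) == 0 and np.var(b) == 0:
        logger.warning("zero-variance groups in t test; statistic undefined")
        return (np.nan, np.nan)
    stat, p = stats.ttest_ind(a, b, equal_var=True)
    return float(stat), float(p)


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square on a contingency table, no continuity correction."""
    stat, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(stat), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA F test across two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.var(g) == 0 for g in arrays) and len({g[0] for g in arrays if len(g)}) == 1:
        return (0.0, 1.0)
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def descriptive_tests(cohort: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Between-sex t-test p-values per variable and age band (plus totals)."""
    df = cohort if "map" in cohort.columns else add_derived_measures(cohort)
    variables = variables or [v for v in _T1_VARIABLES if v in df.columns]
    band = age_band_of(df["age"].to_numpy())
    rows = []
    for b in list(AGE_BANDS) + ["total"]:
        sel = np.ones(len(df), dtype=bool) if b == "total" else band == b
        boys = df.loc[sel & (df["sex"] == "male").to_numpy()]
        girls = df.loc[sel & (df["sex"] == "female").to_numpy()]
        for v in variables:
            t, p = two_sample_t(boys[v].dropna(), girls[v].dropna())
            rows.append({"age_band": b, "variable": v, "t_stat": t, "p_value": p})
    return pd.DataFrame(rows)


# -- configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Exactly one input mode: ``synthetic`` (uses ``n``/``seed`` and the
    calibrated generator defaults) or ``csv`` (subject table at
    ``csv_path``).
    """

    input_mode: str = "synthetic"
    n: int = 5000
    seed: int = 1
    csv_path: str | None = None
    criteria: str = "methods_text"
    percentile_mode: str = "empirical"
    external_bp: str | None = None
    covariate_spec: str = "pooled_age_sex"
    log_tg: bool = False
    bootstrap_B: int = DEFAULT_BOOTSTRAP_B
    bootstrap_seed: int = DEFAULT_BOOTSTRAP_SEED
    min_bin: int = 20
    outdir: str = "cmets_run"
    generator: GeneratorConfig | None = None

    def __post_init__(self):
        if self.input_mode not in ("synthetic", "csv"):
            raise ValueError("input_mode must be 'synthetic' or 'csv'")
        if self.input_mode == "csv" and not self.csv_path:
            raise ValueError("csv input mode requires csv_path")
        if self.input_mode == "synthetic" and self.csv_path:
            raise ValueError("exactly one input mode: drop csv_path for synthetic")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)

    def metadata(self) -> dict:
        d = asdict(self)
        d.pop("generator")
        d["ci_methods"] = {
            "sensitivity_specificity": "wald",
            "auc": "delong",
            "cutoff": f"percentile_bootstrap(B={self.bootstrap_B})",
        }
        d["positivity_rule"] = "score >= threshold"
        d["version"] = cmets.__version__
        return d


@dataclass
class ReportBundle:
    """The four report tables plus run metadata and raw cutoff results."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    cutoffs: list[CutoffResult]
    metadata: dict
    cohort: pd.DataFrame = field(repr=False, default=None)


class PipelineError(RuntimeError):
    """Stage failure with the stage name and record counts attached."""

    def __init__(self, stage: str, message: str, n_records: int | None = None):
        self.stage = stage
        self.n_records = n_records
        super().__init__(f"[{stage}] {message}" + (
            f" (records: {n_records})" if n_records is not None else ""))


# -- table builders ------------------------------------------------------

def _groups(df: pd.DataFrame):
    band = age_band_of(df["age"].to_numpy())
    for b in list(AGE_BANDS) + ["total"]:
        sel_b = np.ones(len(df), dtype=bool) if b == "total" else band == b
        yield b, sel_b


def build_table1(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    male = (df["sex"] == "male").to_numpy()
    for b, sel in _groups(df):
        if sel.sum() == 0:
            continue
        for v in [v for v in _T1_VARIABLES if v in df.columns]:
            boys = df.loc[sel & male, v].dropna()
            girls = df.loc[sel & ~male, v].dropna()
            allv = df.loc[sel, v].dropna()
            _, p = two_sample_t(boys, girls)
            rows.append({
                "age_band": b, "variable": v,
                "total_mean": allv.mean(), "total_sd": allv.std(ddof=1),
                "male_mean": boys.mean(), "male_sd": boys.std(ddof=1),
                "female_mean": girls.mean(), "female_sd": girls.std(ddof=1),
                "p_value": p,
            })
    return pd.DataFrame(rows)


def build_table2(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    male = (df["sex"] == "male").to_numpy()
    flags = [f for f in _T2_FLAGS if f in df.columns]
    for b, sel in _groups(df):
        if sel.sum() == 0:
            continue
        for f in flags:
            col = df[f]
            known = col.notna().to_numpy()
            for label, gsel in (("total", sel), ("male", sel & male),
                                ("female", sel & ~male)):
                g = gsel & known
                n = int(g.sum())
                k = int(col[g].sum()) if n else 0
                rows.append({
                    "age_band": b, "flag": f, "group": label,
                    "count": k, "denominator": n,
                    "percent": 100.0 * k / n if n else np.nan,
                })
            bm = sel & known & male
            bf = sel & known & ~male
            tab = [
                [int(col[bm].sum()), int(bm.sum() - col[bm].sum())],
                [int(col[bf].sum()), int(bf.sum() - col[bf].sum())],
            ]
            if min(bm.sum(), bf.sum()) > 0 and all(sum(r) for r in tab):
                try:
                    _, p = chi_square(tab)
                except ValueError:  # a flag absent in both sexes
                    p = np.nan
            else:
                p = np.nan
            rows[-3]["p_value"] = p  # attach to the 'total' row of this flag
    long = pd.DataFrame(rows)
    # n_components distribution rows
    nc = df["n_components"]
    known = nc.notna().to_numpy()
    for b, sel in _groups(df):
        if sel.sum() == 0:
            continue
        for grp_label, gsel in (("total", sel), ("male", sel & male),
                                ("female", sel & ~male)):
            g = gsel & known
            n = int(g.sum())
            vals = nc[g].astype(int)
            for cat, cnt in (("0", (vals == 0).sum()), ("1", (vals == 1).sum()),
                             ("2", (vals == 2).sum()), ("3+", (vals >= 3).sum())):
                long.loc[len(long)] = {
                    "age_band": b, "flag": f"n_components_{cat}",
                    "group": grp_label, "count": int(cnt), "denominator": n,
                    "percent": 100.0 * cnt / n if n else np.nan, "p_value": np.nan,
                }
    return long


def build_table3(df: pd.DataFrame) -> pd.DataFrame:
    sub = df.dropna(subset=["cmets", "mets", "n_components"])
    band = age_band_of(sub["age"].to_numpy())
    male = (sub["sex"] == "male").to_numpy()
    rows = []
    for b in list(AGE_BANDS) + ["total"]:
        sel_b = np.ones(len(sub), dtype=bool) if b == "total" else band == b
        for g, sel_g in (("total", sel_b), ("male", sel_b & male),
                         ("female", sel_b & ~male)):
            grp = sub.loc[sel_g]
            if len(grp) == 0:
                continue
            mets_yes = grp.loc[grp["mets"].astype(bool), "cmets"]
            mets_no = grp.loc[~grp["mets"].astype(bool), "cmets"]
            t_p = two_sample_t(mets_yes, mets_no)[1] if min(len(mets_yes), len(mets_no)) > 1 else np.nan
            nc = grp["n_components"].astype(int)
            count_groups = [grp.loc[nc == 0, "cmets"], grp.loc[nc == 1, "cmets"],
                            grp.loc[nc == 2, "cmets"], grp.loc[nc >= 3, "cmets"]]
            nonempty = [g_ for g_ in count_groups if len(g_) > 1]
            anova_p = one_way_anova(*nonempty)[1] if len(nonempty) > 1 else np.nan
            cats = [("mets_yes", mets_yes), ("mets_no", mets_no),
                    ("components_0", count_groups[0]), ("components_1", count_groups[1]),
                    ("components_2", count_groups[2]), ("components_3plus", count_groups[3]),
                    ("all", grp["cmets"])]
            for cat, vals in cats:
                rows.append({
                    "age_band": b, "group": g, "category": cat, "n": len(vals),
                    "cmets_mean": vals.mean() if len(vals) else np.nan,
                    "cmets_sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "p_mets_ttest": t_p, "p_components_anova": anova_p,
                })
    return pd.DataFrame(rows)


def build_table4(cutoffs: list[CutoffResult]) -> pd.DataFrame:
    return pd.DataFrame([c.as_row() for c in cutoffs])


# -- the pipeline --------------------------------------------------------

def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute all stages in order and (optionally) write every output.

    Outputs under ``config.outdir``: ``cohort_scored.csv`` (augmented
    subject table), ``table1.csv`` … ``table4.csv``, ``zscore_models.json``,
    ``metadata.json`` and ``run.log``.  Deterministic given the seeds in
    the config.  Any stage error propagates as :class:`PipelineError`
    with the stage name; nothing is written on failure.
    """
    cfg = config
    # stage 1: input
    if cfg.input_mode == "synthetic":
        gen = cfg.generator or GeneratorConfig(n=cfg.n, seed=cfg.seed)
        cohort = generate_cohort(gen)
    else:
        try:
            cohort = read_cohort(cfg.csv_path)
        except (OSError, ValueError) as e:
            raise PipelineError("input", str(e)) from e
    if len(cohort) == 0:
        raise PipelineError("input", "empty cohort", 0)
    logger.info("input: %d records", len(cohort))

    # stage 2: derived measures
    try:
        derived = add_derived_measures(cohort)
    except ValueError as e:
        raise PipelineError("derive", str(e), len(cohort)) from e

    # stage 3: classification
    try:
        clf = MetSClassifier(
            criteria=cfg.criteria, percentile_mode=cfg.percentile_mode,
            external_bp=cfg.external_bp, min_bin=cfg.min_bin,
        ).fit(derived)
        classified = clf.transform(derived)
        sec = secondary_flags(classified, clf.reference_)
        classified = pd.concat([classified, sec], axis=1)
    except (ValueError, RuntimeError) as e:
        raise PipelineError("classify", str(e), len(derived)) from e
    logger.info("classify: %d records in, %d unevaluable",
                len(derived), clf.n_excluded_)

    # stage 4: scoring
    try:
        scorer = CMetSScorer(covariate_spec=cfg.covariate_spec, log_tg=cfg.log_tg)
        scored = scorer.fit_transform(classified)
    except ValueError as e:
        raise PipelineError("score", str(e), len(classified)) from e

    # stage 5: ROC validation
    try:
        cutoffs = stratified_validation(scored, B=cfg.bootstrap_B,
                                        seed=cfg.bootstrap_seed)
    except ValueError as e:
        raise PipelineError("validate", str(e), len(scored)) from e

    meta = cfg.metadata()
    meta["n_input"] = int(len(cohort))
    meta["n_unevaluable_flags"] = int(clf.n_excluded_)
    meta["n_scored"] = int(scored["cmets"].notna().sum())
    bundle = ReportBundle(
        table1=build_table1(scored),
        table2=build_table2(scored),
        table3=build_table3(scored),
        table4=build_table4(cutoffs),
        cutoffs=cutoffs,
        metadata=meta,
        cohort=scored,
    )
    if write:
        _write_outputs(bundle, scorer, cfg)
    return bundle


def _write_outputs(bundle: ReportBundle, scorer: CMetSScorer, cfg: RunConfig):
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out / "cohort_scored.csv", index=False, float_format="%.6f")
    for name in ("table1", "table2", "table3", "table4"):
        getattr(bundle, name).to_csv(out / f"{name}.csv", index=False,
                                     float_format="%.6f")
    models_to_json(scorer.models_, out / "zscore_models.json")
    with open(out / "metadata.json", "w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(
            "records_in={n_input} unevaluable_flags={n_unevaluable_flags} "
            "scored={n_scored}\n".format(**bundle.metadata)
        )
    logger.info("outputs written to %s", out)


# -- rendered report -----------------------------------------------------

def format_p(p: float) -> str:
    """Display rule for p-values: floor at < 0.001, else 3 decimals."""
    if np.isnan(p):
        return "NA"
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def render_report(bundle: ReportBundle) -> str:
    """Plain-text rendering of the four tables (2-dp display rounding)."""
    lines = ["== Descriptives (mean (SD)) =="]
    for b, grp in bundle.table1.groupby("age_band", sort=False):
        lines.append(f"-- {b} --")
        for _, r in grp.iterrows():
            lines.append(
                f"  {r['variable']:<8} total {r['total_mean']:.2f} ({r['total_sd']:.2f})  "
                f"boys {r['male_mean']:.2f} ({r['male_sd']:.2f})  "
                f"girls {r['female_mean']:.2f} ({r['female_sd']:.2f})  "
                f"p {format_p(r['p_value'])}"
            )
    lines.append("== Prevalence ==")
    t2 = bundle.table2[bundle.table2["group"] == "total"]
    for b, grp in t2.groupby("age_band", sort=False):
        lines.append(f"-- {b} --")
        for _, r in grp.iterrows():
            pct = "NA" if np.isnan(r["percent"]) else f"{r['percent']:.1f}%"
            lines.append(f"  {r['flag']:<18} {int(r['count'])}/{int(r['denominator'])} ({pct})")
    lines.append("== cMetS by MetS status and component count ==")
    for (b, g), grp in bundle.table3.groupby(["age_band", "group"], sort=False):
        if g != "total":
            continue
        lines.append(f"-- {b} --")
        for _, r in grp.iterrows():
            if r["n"] == 0:
                continue
            lines.append(
                f"  {r['category']:<17} {r['cmets_mean']:+.2f} ± {r['cmets_sd']:.2f} "
                f"(n={int(r['n'])})"
            )
    lines.append("== ROC cutoffs (AUC as %) ==")
    for _, r in bundle.table4.iterrows():
        if np.isnan(r["auc"]):
            lines.append(f"  {r['stratum']:<14} single-class stratum, no estimates")
            continue
        lines.append(
            f"  {r['stratum']:<14} cutoff {r['cutoff']:.2f} "
            f"({r['cutoff_ci_low']:.2f}-{r['cutoff_ci_high']:.2f})  "
            f"sens {100 * r['sensitivity']:.0f} spec {100 * r['specificity']:.0f}  "
            f"AUC {100 * r['auc']:.0f} "
            f"({100 * r['auc_ci_low']:.0f}-{100 * r['auc_ci_high']:.0f})"
        )
    return "\n".join(lines)
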