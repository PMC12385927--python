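"""Paired cohort statistics for aganglionic vs. ganglionic measurements.

Each patient contributes both an aganglionic and a ganglionic specimen and
serves as their own control, so layer-thickness comparisons are paired
t-tests on within-patient differences (aganglionic − ganglionic).  The
module also provides confidence intervals recomputable from printed summary
statistics, Pearson correlations of full-wall thickness against clinical
covariates, the cohort inclusion/exclusion flow, and descriptive summaries.

Statistics are computed at full floating-point precision; rounding to three
decimals happens only in the reporting layer (:mod:`hdmorph.io`).  No
multiple-testing correction is applied across the per-layer rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ALL_LAYERS, SpecimenMeasurement

__all__ = [
    "FEATURES",
    "EXCLUSION_CRITERIA",
    "PairedPatientRecord",
    "PairedTestResult",
    "paired_t",
    "paired_t_from_summary",
    "ci_from_summary",
    "pearson",
    "cohort_feature_frame",
    "cohort_table",
    "correlate_fullwall",
    "apply_inclusion_criteria",
    "cohort_descriptives",
]

#: Cohort-table rows, in reporting order (muscle coats and their ratio first).
FEATURES = (
    "muscularis_externa",
    "muscularis_interna",
    "mi_me_ratio",
    "myenteric",
    "submucosa",
    "mucosa",
    "full_wall",
    "folding_ratio",
)


@dataclass
class PairedPatientRecord:
    """One patient's paired specimens plus clinical covariates."""

    patient_id: str
    aganglionic: SpecimenMeasurement
    ganglionic: SpecimenMeasurement
    age_days: float | None = None
    weight_kg: float | None = None
    aganglionosis_cm: float | None = None
    prior_stoma: bool = False
    primary_surgery: bool = True
    image_quality_ok: bool = True


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test summary for one layer or derived feature."""

    feature: str
    n: int
    mean_diff: float  # aganglionic − ganglionic
    sd_diff: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    n_ganglionic_greater: int | None = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("paired test needs n >= 2")
        if not (self.ci_low <= self.mean_diff <= self.ci_high):
            raise ValueError("confidence interval must contain the mean difference")


def _t_core(mean: float, sd: float, n: int, level: float) -> tuple[float, float, float, float]:
    """(t, p, ci_low, ci_high) for a one-sample t on a mean difference."""
    if not (0.0 < level < 1.0):
        raise ValueError("confidence level must be in (0, 1)")
    se = sd / np.sqrt(n)
    t = mean / se
    df = n - 1
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.5 * (1.0 + level), df) * se
    return float(t), float(p), float(mean - half), float(mean + half)


def paired_t(
    differences: Sequence[float] | np.ndarray,
    level: float = 0.95,
    feature: str = "",
) -> PairedTestResult:
    """Two-sided paired t-test on a vector of within-patient differences.

    t = d̄ / (s/√n) with n−1 degrees of freedom; the confidence interval is
    d̄ ± t_{n−1,(1+level)/2} · s/√n.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need a 1-D difference vector with n >= 2")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance: degenerate (identical) paired differences")
    mean = float(d.mean())
    t, p, lo, hi = _t_core(mean, sd, len(d), level)
    return PairedTestResult(
        feature=feature, n=len(d), mean_diff=mean, sd_diff=sd,
        ci_low=lo, ci_high=hi, t=t, p=p, level=level,
    )


def paired_t_from_summary(
    mean_diff: float, sd: float, n: int, level: float = 0.95, feature: str = ""
) -> PairedTestResult:
    """Paired t-test recomputed from printed summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("need sd > 0")
    t, p, lo, hi = _t_core(mean_diff, sd, n, level)
    return PairedTestResult(
        feature=feature, n=n, mean_diff=mean_diff, sd_diff=sd,
        ci_low=lo, ci_high=hi, t=t, p=p, level=level,
    )


def ci_from_summary(
    mean_diff: float, sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval recomputed from printed summary statistics."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("need sd > 0")
    _, _, lo, hi = _t_core(mean_diff, sd, n, level)
    return lo, hi


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------


def cohort_feature_frame(cohort: Iterable[PairedPatientRecord]) -> pd.DataFrame:
    """Tidy per-specimen feature table (one row per patient-segment)."""
    rows = []
    for rec in cohort:
        for seg, meas in (("aganglionic", rec.aganglionic), ("ganglionic", rec.ganglionic)):
            row: dict = {"patient_id": rec.patient_id, "segment": seg}
            row.update(meas.to_features())
            rows.append(row)
    return pd.DataFrame(rows)


def cohort_table(
    cohort: Iterable[PairedPatientRecord] | pd.DataFrame,
    level: float = 0.95,
    shapiro: bool = True,
) -> pd.DataFrame:
    """Paired comparison of every feature across the cohort.

    One row per layer/feature with the per-segment mean (SD) across patients,
    the paired-difference statistics (difference = aganglionic − ganglionic),
    confidence interval, p-value, and the count of patients in whom the
    ganglionic value is the greater one.  Patients missing a feature in
    either segment are dropped from that row only; rows with fewer than two
    complete pairs, or identical pairs throughout, are flagged not-computable
    / degenerate.  An informational Shapiro–Wilk normality p-value of the
    differences is included when ``shapiro`` is set.
    """
    if isinstance(cohort, pd.DataFrame):
        frame = cohort
    else:
        frame = cohort_feature_frame(cohort)
    wide_a = frame[frame["segment"] == "aganglionic"].set_index("patient_id")
    wide_g = frame[frame["segment"] == "ganglionic"].set_index("patient_id")
    common = wide_a.index.intersection(wide_g.index)

    rows = []
    for feat in FEATURES:
        if feat not in frame.columns:
            rows.append({"feature": feat, "n": 0, "status": "not_computable"})
            continue
        a = pd.to_numeric(wide_a.loc[common, feat], errors="coerce")
        g = pd.to_numeric(wide_g.loc[common, feat], errors="coerce")
        ok = a.notna() & g.notna()
        a, g = a[ok].to_numpy(), g[ok].to_numpy()
        n = len(a)
        row: dict = {
            "feature": feat,
            "n": n,
            "aganglionic_mean": float(a.mean()) if n else np.nan,
            "aganglionic_sd": float(a.std(ddof=1)) if n > 1 else np.nan,
            "ganglionic_mean": float(g.mean()) if n else np.nan,
            "ganglionic_sd": float(g.std(ddof=1)) if n > 1 else np.nan,
        }
        if n < 2:
            row["status"] = "not_computable"
            rows.append(row)
            continue
        d = a - g
        row["n_ganglionic_greater"] = int((g > a).sum())
        if d.std(ddof=1) == 0.0:
            row["status"] = "degenerate"
            row["mean_diff"] = float(d.mean())
            rows.append(row)
            continue
        res = paired_t(d, level=level, feature=feat)
        row.update(
            status="ok",
            mean_diff=res.mean_diff,
            sd_diff=res.sd_diff,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            t=res.t,
            p=res.p,
        )
        if shapiro and n >= 3:
            row["shapiro_p"] = float(stats.shapiro(d).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_fullwall(
    cohort: Iterable[PairedPatientRecord],
    covariate: str,
) -> dict[str, tuple[float, float]]:
    """Pearson (r, p) of full-wall mean thickness vs. a clinical covariate.

    ``covariate`` is ``"weight"`` (kg at surgery) or ``"age"`` (days at
    surgery); one correlation per segment.
    """
    attr = {"weight": "weight_kg", "age": "age_days"}.get(covariate)
    if attr is None:
        raise ValueError("covariate must be 'weight' or 'age'")
    cohort = list(cohort)
    out: dict[str, tuple[float, float]] = {}
    for seg in ("aganglionic", "ganglionic"):
        xs, ys = [], []
        for rec in cohort:
            meas = getattr(rec, seg)
            fw = meas.layers.get("full_wall")
            cov = getattr(rec, attr)
            if fw is not None and cov is not None:
                xs.append(fw.mean_thickness)
                ys.append(float(cov))
        out[seg] = pearson(xs, ys)
    return out


# ---------------------------------------------------------------------------
# inclusion/exclusion flow
# ---------------------------------------------------------------------------

#: (name, required field, predicate returning True when the record PASSES),
#: applied in order; an excluded record is tallied under its first failure.
EXCLUSION_CRITERIA = (
    ("age_over_1_year", "age_days", lambda r: r["age_days"] <= 365),
    ("prior_stoma", "prior_stoma", lambda r: not r["prior_stoma"]),
    ("not_primary_surgery", "primary_surgery", lambda r: bool(r["primary_surgery"])),
    ("aganglionosis_over_25cm", "aganglionosis_cm", lambda r: r["aganglionosis_cm"] <= 25.0),
    ("poor_image_quality", "image_quality_ok", lambda r: bool(r["image_quality_ok"])),
)


def apply_inclusion_criteria(
    registry: pd.DataFrame | Iterable[Mapping],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a patient registry and tally exclusions.

    Inclusion requires: age at surgery ≤ 1 year, no prior stoma, primary
    surgery, aganglionic segment ≤ 25 cm, and adequate image quality.  A
    record failing several criteria is counted once, under the first failing
    criterion in that order.  Returns the included records and an ordered
    exclusion tally.
    """
    if not isinstance(registry, pd.DataFrame):
        registry = pd.DataFrame(list(registry))
    tally = {name: 0 for name, _, _ in EXCLUSION_CRITERIA}
    if registry.empty:
        return registry.copy(), tally

    keep = []
    for _, rec in registry.iterrows():
        excluded = False
        for name, fld, passes in EXCLUSION_CRITERIA:
            if fld not in rec.index or pd.isna(rec[fld]):
                pid = rec.get("patient_id", "<unknown>")
                raise ValueError(f"record {pid!r} is missing criterion field {fld!r}")
            if not passes(rec):
                tally[name] += 1
                excluded = True
                break
        keep.append(not excluded)
    return registry[np.array(keep, dtype=bool)].reset_index(drop=True), tally


def cohort_descriptives(registry: pd.DataFrame) -> pd.DataFrame:
    """Median / mean / IQR descriptives of the clinical covariates."""
    rows = []
    for col, label in (
        ("age_days", "age_at_surgery_days"),
        ("weight_kg", "weight_at_surgery_kg"),
        ("aganglionosis_cm", "aganglionosis_length_cm"),
    ):
        if col not in registry.columns:
            continue
        v = pd.to_numeric(registry[col], errors="coerce").dropna()
        rows.append(
            {
                "variable": label,
                "n": len(v),
                "median": float(v.median()),
                "mean": float(v.mean()),
                "q1": float(v.quantile(0.25)),
                "q3": float(v.quantile(0.75)),
            }
        )
    return pd.DataFrame(rows)
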