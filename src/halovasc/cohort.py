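"""Per-sample and cohort-level statistics for treatment comparisons.

For every caliber class the pipeline yields a percent volume (V%, vessel
voxels as a percentage of the stack) and a dispersion value (nHv) per
sample. Cohorts are summarized by medians with 25–75% interquartile
ranges (nHv departs from normality, so medians are preferred to means),
compared pairwise with Welch's unequal-variance t-test on V% and the
unpaired Wilcoxon rank-sum test on nHv, and each sample's V%–nHv
relationship across classes is captured by a least-squares 2nd-degree
polynomial with its coefficient of determination R².
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SampleMetrics",
    "CohortSummary",
    "percent_volume",
    "summarize",
    "welch_t",
    "wilcoxon_rank",
    "significance_stars",
    "quadratic_fit",
    "build_significance_table",
    "read_metrics_workbook",
    "fit_per_sample",
]


def percent_volume(vol) -> float:
    """V%: foreground voxels as a percentage of all voxels in the stack."""
    if vol.voxels.size == 0:
        raise ValueError("empty stack has no percent volume")
    return 100.0 * vol.foreground_count / vol.voxels.size


def summarize(values) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles (linear interpolation between
    order statistics)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q25, med, q75 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q25), float(q75)


def welch_t(a, b) -> float:
    """Two-tailed Welch unequal-variance t-test p-value.

    Uses the Welch–Satterthwaite degrees of freedom; requires at least two
    values per sample and a nonzero variance in at least one of them.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch's t-test needs >= 2 values per sample")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def _rank_sum(a, b) -> tuple[float, str]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        raise ValueError("all pooled values identical: rank test undefined")
    has_ties = np.unique(pooled).size < pooled.size
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue), method


def wilcoxon_rank(a, b) -> float:
    """Two-sided unpaired Wilcoxon rank-sum (Mann–Whitney) p-value.

    Exact null distribution for combined n ≤ 20 without ties; otherwise
    the tie-corrected normal approximation.
    """
    return _rank_sum(a, b)[0]


def significance_stars(p: float) -> str:
    """Star coding with strict thresholds: *** p<0.001, ** p<0.01, * p<0.05."""
    if np.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def quadratic_fit(v_pct, nhv) -> tuple[float, float, float, float]:
    """Least-squares fit nHv = a·V%² + b·V% + c, returning (a, b, c, R²)."""
    x = np.asarray(v_pct, dtype=float)
    y = np.asarray(nhv, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3 or np.unique(x).size < 3:
        raise ValueError("quadratic fit needs >= 3 points with >= 3 distinct V% values")
    coeffs = np.polyfit(x, y, 2)
    pred = np.polyval(coeffs, x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 1.0 if ss_res < 1e-12 else float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    a, b, c = (float(v) for v in coeffs)
    return a, b, c, r2


@dataclass
class SampleMetrics:
    """Per-class metrics for one sample (one stack)."""

    sample: str
    treatment: str
    v_pct: np.ndarray  # (K,) percent volume per caliber class
    nhv: np.ndarray  # (K,) normalized Halo index per class (NaN if class absent)
    wall_counts: np.ndarray | None = None
    skeleton_counts: np.ndarray | None = None
    lumen_counts: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.v_pct)

    def to_frame(self) -> pd.DataFrame:
        k = self.n_classes
        df = pd.DataFrame(
            {
                "sample": [self.sample] * k,
                "treatment": [self.treatment] * k,
                "class": np.arange(1, k + 1),
                "v_pct": self.v_pct,
                "nhv": self.nhv,
            }
        )
        for name, arr in (
            ("wall", self.wall_counts),
            ("skeleton", self.skeleton_counts),
            ("lumen", self.lumen_counts),
        ):
            if arr is not None:
                df[name] = arr
        return df


@dataclass
class CohortSummary:
    """Cohort medians/IQRs, the pairwise significance grid and per-sample fits."""

    medians: pd.DataFrame  # treatment × class medians + IQR for V% and nHv
    pairwise: pd.DataFrame  # class × treatment-pair p-values and stars
    fits: pd.DataFrame  # per-sample quadratic coefficients + R²


def _collect(cohorts: dict[str, list[SampleMetrics]]) -> pd.DataFrame:
    frames = [m.to_frame() for ms in cohorts.values() for m in ms]
    return pd.concat(frames, ignore_index=True)


def build_significance_table(cohorts: dict[str, list[SampleMetrics]]) -> CohortSummary:
    """Medians/IQR per treatment × class, pairwise tests and quadratic fits.

    For every caliber class and every unordered treatment pair, V% is
    compared with Welch's t-test and nHv with the Wilcoxon rank-sum test;
    p-values carry star codes. Cells with too little data (an absent class
    after treatment, degenerate samples) are flagged NaN/"na", never
    fabricated. Per-sample quadratic fits of nHv on V% span all classes
    present in that sample.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least two treatments to compare")
    sizes = {t: len(ms) for t, ms in cohorts.items()}
    if any(n == 0 for n in sizes.values()):
        raise ValueError(f"empty cohort(s): {sizes}")
    long = _collect(cohorts)

    med_rows = []
    for (treat, klass), grp in long.groupby(["treatment", "class"], sort=True):
        row = {"treatment": treat, "class": klass}
        for var in ("v_pct", "nhv"):
            vals = grp[var].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            if vals.size:
                med, q25, q75 = summarize(vals)
            else:
                med = q25 = q75 = float("nan")
            row.update({f"{var}_median": med, f"{var}_q25": q25, f"{var}_q75": q75})
        med_rows.append(row)
    medians = pd.DataFrame(med_rows)

    pair_rows = []
    classes = sorted(long["class"].unique())
    for klass in classes:
        sub = long[long["class"] == klass]
        for ta, tb in combinations(sorted(cohorts), 2):
            va = sub.loc[sub["treatment"] == ta, "v_pct"].dropna().to_numpy()
            vb = sub.loc[sub["treatment"] == tb, "v_pct"].dropna().to_numpy()
            ha = sub.loc[sub["treatment"] == ta, "nhv"].dropna().to_numpy()
            hb = sub.loc[sub["treatment"] == tb, "nhv"].dropna().to_numpy()
            try:
                p_v = welch_t(va, vb)
            except ValueError:
                p_v = float("nan")
            try:
                p_h, method = _rank_sum(ha, hb) if (len(ha) >= 4 and len(hb) >= 4) else (float("nan"), "na")
            except ValueError:
                p_h, method = float("nan"), "na"
            pair_rows.append(
                {
                    "class": klass,
                    "treatment_a": ta,
                    "treatment_b": tb,
                    "p_vpct_welch": p_v,
                    "stars_vpct": significance_stars(p_v),
                    "p_nhv_wilcoxon": p_h,
                    "stars_nhv": significance_stars(p_h),
                    "wilcoxon_method": method,
                }
            )
    pairwise = pd.DataFrame(pair_rows)

    fit_rows = []
    for treat, ms in cohorts.items():
        for m in ms:
            try:
                a, b, c, r2 = quadratic_fit(m.v_pct, m.nhv)
            except ValueError:
                a = b = c = r2 = float("nan")
            fit_rows.append(
                {"sample": m.sample, "treatment": treat, "a": a, "b": b, "c": c, "r2": r2}
            )
    fits = pd.DataFrame(fit_rows)
    return CohortSummary(medians=medians, pairwise=pairwise, fits=fits)


def read_metrics_workbook(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Read a per-sample, per-class metrics spreadsheet (xlsx).

    Expects columns (case-insensitive) ``sample``, ``treatment`` (optional),
    ``class``, ``v_pct`` and ``nhv`` — the layout used for cohort metric
    exports. Returns a tidy DataFrame with those canonical column names.
    """
    df = pd.read_excel(Path(path), sheet_name=sheet)
    rename = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("%", "pct").replace(" ", "_")
        if key in {"v_pct", "vpct", "vol_pct", "volpct"}:
            rename[col] = "v_pct"
        elif key in {"nhv", "nhv_90", "nhv90"}:
            rename[col] = "nhv"
        elif key in {"sample", "treatment", "class"}:
            rename[col] = key
    df = df.rename(columns=rename)
    missing = {"sample", "class", "v_pct", "nhv"} - set(df.columns)
    if missing:
        raise ValueError(f"workbook lacks required columns: {sorted(missing)}")
    if "treatment" not in df.columns:
        df["treatment"] = "all"
    return df[["sample", "treatment", "class", "v_pct", "nhv"]]


def fit_per_sample(metrics: pd.DataFrame) -> pd.DataFrame:
    """Quadratic nHv-on-V% fit per sample of a tidy metrics table.

    Returns one row per sample with coefficients (a, b, c) and R².
    """
    rows = []
    for (sample, treat), grp in metrics.groupby(["sample", "treatment"], sort=True):
        a, b, c, r2 = quadratic_fit(grp["v_pct"].to_numpy(), grp["nhv"].to_numpy())
        rows.append({"sample": sample, "treatment": treat, "a": a, "b": b, "c": c, "r2": r2})
    return pd.DataFrame(rows)
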