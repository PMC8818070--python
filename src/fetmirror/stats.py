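"""Reader-variability statistics: coefficient of variation and ICC(2,1).

Measurements live in a long-format table ("reader table") with one row per
(patient, reader, repeat, method) holding the background reference mean SUV
and the biological tumour volume.  Two families of summaries are computed:

* **Coefficient of variation** (CoV = 100 x sd / mean, sample sd with n-1
  denominator).  Intra-reader CoV is computed per (patient, reader) cell over
  that reader's repeats; inter-reader CoV is computed per patient over the
  reader means (each reader first averaged over their repeats).  Summaries
  report median and range per reader and pooled over all readers.

* **ICC(2,1)** — intraclass correlation, two-way random-effects,
  absolute-agreement, single-measurement form — with 95% confidence
  intervals from the McGraw–Wong F-based construction, and the conventional
  reliability bands (poor < 0.5 <= moderate < 0.75 <= good < 0.9 < excellent).

Paired method comparisons (two-tailed Wilcoxon signed-rank per reader or per
patient, Mann–Whitney U for the pooled groups, alpha = 0.05) are delegated to
scipy.stats; this module validates their inputs and surfaces the p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import FetMirrorError

__all__ = [
    "READER_TABLE_COLUMNS",
    "PARAMETERS",
    "cov_percent",
    "validate_reader_table",
    "read_reader_table",
    "write_reader_table",
    "intra_reader_cov",
    "inter_reader_cov",
    "summarise_cov",
    "ICCResult",
    "icc_2_1",
    "icc_from_reader_table",
    "compare_methods",
    "reliability_report",
]

READER_TABLE_COLUMNS = [
    "patient_id",
    "reader_id",
    "repeat",
    "method",
    "ctrl_suv_mean",
    "btv_cm3",
]
PARAMETERS = ("ctrl_suv_mean", "btv_cm3")
METHODS = ("MI", "gCS")


def cov_percent(values) -> float:
    """Coefficient of variation in percent: 100 x sd(values) / mean(values).

    Sample standard deviation (n-1 denominator).  Requires at least two
    values and a strictly positive mean.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError(f"CoV needs at least 2 values, got {arr.size}")
    mean = arr.mean()
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"CoV undefined for non-positive mean {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# Reader table
# ---------------------------------------------------------------------------

def validate_reader_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format measurement table and return it unchanged."""
    missing = [c for c in READER_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"reader table missing columns: {missing}")
    if table.empty:
        raise ValueError("reader table is empty")
    for col in PARAMETERS:
        vals = table[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError(f"column {col} must be finite and non-negative")
    dup = table.duplicated(subset=["patient_id", "reader_id", "method", "repeat"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValueError(
            "duplicate repeat index for cell "
            f"(patient={row.patient_id}, reader={row.reader_id}, method={row.method})"
        )
    return table


def read_reader_table(path) -> pd.DataFrame:
    return validate_reader_table(pd.read_csv(path))


def write_reader_table(table: pd.DataFrame, path) -> None:
    validate_reader_table(table)[READER_TABLE_COLUMNS].to_csv(path, index=False)


def _method_slice(table: pd.DataFrame, parameter: str, method: str) -> pd.DataFrame:
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}, expected one of {PARAMETERS}")
    sub = table[table["method"] == method]
    if sub.empty:
        raise ValueError(f"no rows for method {method!r}")
    return sub


def intra_reader_cov(table: pd.DataFrame, parameter: str, method: str) -> pd.DataFrame:
    """Per-(patient, reader) CoV of ``parameter`` over that cell's repeats.

    Every cell must carry the full repeat set (the largest repeat count seen
    for the method); an incomplete cell is an error naming the cell.
    """
    validate_reader_table(table)
    sub = _method_slice(table, parameter, method)
    counts = sub.groupby(["patient_id", "reader_id"], sort=True).size()
    n_rep = int(counts.max())
    rows = []
    for (pat, rdr), grp in sub.groupby(["patient_id", "reader_id"], sort=True):
        if len(grp) != n_rep:
            raise ValueError(
                f"incomplete repeat set for cell (patient={pat}, reader={rdr}, "
                f"method={method}): {len(grp)} of {n_rep} repeats"
            )
        rows.append({"patient_id": pat, "reader_id": rdr, "cov": cov_percent(grp[parameter])})
    return pd.DataFrame(rows)


def inter_reader_cov(table: pd.DataFrame, parameter: str, method: str) -> pd.DataFrame:
    """Per-patient CoV across reader means (each reader averaged over repeats)."""
    validate_reader_table(table)
    sub = _method_slice(table, parameter, method)
    rows = []
    for pat, grp in sub.groupby("patient_id", sort=True):
        reader_means = grp.groupby("reader_id")[parameter].mean()
        if len(reader_means) < 2:
            raise ValueError(
                f"inter-reader CoV needs >= 2 readers for patient {pat}, got {len(reader_means)}"
            )
        rows.append({"patient_id": pat, "cov": cov_percent(reader_means)})
    return pd.DataFrame(rows)


def summarise_cov(cell_covs: pd.DataFrame, by: str | None = "reader_id") -> dict:
    """Median (range) per group plus the pooled overall group, in percent."""
    def _summary(vals: pd.Series) -> dict:
        return {
            "median": float(vals.median()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "n": int(vals.size),
        }

    out: dict = {"overall": _summary(cell_covs["cov"])}
    if by is not None and by in cell_covs.columns:
        out["per_" + by.replace("_id", "")] = {
            str(key): _summary(grp["cov"]) for key, grp in cell_covs.groupby(by, sort=True)
        }
    return out


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_targets: int
    n_raters: int
    interpretation: str


def _interpret(icc: float) -> str:
    if icc < 0.5:
        return "poor"
    if icc < 0.75:
        return "moderate"
    if icc < 0.9:
        return "good"
    return "excellent"


def icc_2_1(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measurement.

    ``matrix`` is an (n targets x k raters) array of ratings with no missing
    cells.  The point estimate is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the two-way ANOVA mean squares for rows (targets),
    columns (raters) and residual.  Confidence bounds use the McGraw–Wong
    F-based construction with Satterthwaite degrees of freedom.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2D targets x raters matrix, got {X.ndim}D")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"ICC needs >= 2 targets and >= 2 raters, got {n} x {k}")
    if not np.all(np.isfinite(X)):
        raise ValueError("ICC matrix has missing or non-finite cells")
    if np.ptp(X) == 0:
        raise FetMirrorError("ICC undefined for constant data")

    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise FetMirrorError("ICC undefined for constant data")
    icc = float((msr - mse) / denom)

    if mse == 0 and msc == 0:
        # raters agree exactly on every target: degenerate perfect agreement
        ci_low = ci_high = 1.0
    else:
        a = (k * icc) / (n * (1 - icc)) if icc < 1 else np.inf
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc < 1 else np.inf
        if np.isinf(a):
            ci_low = ci_high = icc
        else:
            v_num = (a * msc + b * mse) ** 2
            v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = v_num / v_den
            f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
            ci_low = float(
                n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            ci_high = float(
                n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
            )

    return ICCResult(
        icc=icc,
        ci_low=ci_low,
        ci_high=ci_high,
        n_targets=n,
        n_raters=k,
        interpretation=_interpret(icc),
    )


def icc_from_reader_table(table: pd.DataFrame, parameter: str, method: str) -> ICCResult:
    """ICC(2,1) on the patients x readers matrix of repeat means."""
    validate_reader_table(table)
    sub = _method_slice(table, parameter, method)
    pivot = sub.groupby(["patient_id", "reader_id"])[parameter].mean().unstack()
    if pivot.isna().any().any():
        raise ValueError("ICC needs every reader to cover every patient")
    return icc_2_1(pivot.to_numpy())


# ---------------------------------------------------------------------------
# Method comparisons (standard tests, invoked not implemented)
# ---------------------------------------------------------------------------

def _safe_wilcoxon(a, b) -> dict:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 1:
        raise ValueError("paired comparison needs equal-length non-empty samples")
    if np.all(a == b):
        return {"p_value": None, "note": "all paired differences are zero"}
    try:
        stat = sps.wilcoxon(a, b, alternative="two-sided")
        return {"p_value": float(stat.pvalue)}
    except ValueError as err:  # e.g. too few nonzero differences
        return {"p_value": None, "note": str(err)}


def compare_methods(table: pd.DataFrame, parameter: str, alpha: float = 0.05) -> dict:
    """MI vs gCS variability comparison for one parameter.

    Per reader: two-tailed matched-pairs Wilcoxon signed-rank between the
    reader's per-patient intra-reader CoV under the two methods.  Overall
    group: two-tailed Mann–Whitney U on the pooled CoV values.  Inter-reader:
    matched-pairs Wilcoxon across patients.
    """
    intra = {m: intra_reader_cov(table, parameter, m) for m in METHODS}
    inter = {m: inter_reader_cov(table, parameter, m) for m in METHODS}

    per_reader = {}
    readers = sorted(set(intra["MI"]["reader_id"]) & set(intra["gCS"]["reader_id"]))
    for rdr in readers:
        a = intra["MI"][intra["MI"]["reader_id"] == rdr].sort_values("patient_id")["cov"]
        b = intra["gCS"][intra["gCS"]["reader_id"] == rdr].sort_values("patient_id")["cov"]
        per_reader[str(rdr)] = _safe_wilcoxon(a, b)

    pooled_mi = intra["MI"]["cov"].to_numpy()
    pooled_gcs = intra["gCS"]["cov"].to_numpy()
    if np.ptp(np.concatenate([pooled_mi, pooled_gcs])) == 0:
        overall = {"p_value": None, "note": "no variability in either group"}
    else:
        overall = {"p_value": float(sps.mannwhitneyu(pooled_mi, pooled_gcs).pvalue)}

    a = inter["MI"].sort_values("patient_id")["cov"]
    b = inter["gCS"].sort_values("patient_id")["cov"]
    return {
        "alpha": alpha,
        "intra_reader": {"per_reader": per_reader, "overall_group": overall},
        "inter_reader": _safe_wilcoxon(a, b),
    }


def reliability_report(table: pd.DataFrame, icc_targets: str = "patients") -> dict:
    """Full variability report for both parameters and both methods.

    Layout mirrors the usual reader-study tables: per-reader and overall
    median (range) of intra-reader CoV, overall inter-reader CoV, ICC(2,1)
    on patients x readers repeat means, and the paired method comparisons.
    """
    validate_reader_table(table)
    methods = [m for m in METHODS if (table["method"] == m).any()]
    report: dict = {}
    for parameter in PARAMETERS:
        block: dict = {}
        for method in methods:
            entry = {
                "intra_reader": summarise_cov(intra_reader_cov(table, parameter, method)),
                "inter_reader": summarise_cov(
                    inter_reader_cov(table, parameter, method), by=None
                ),
            }
            try:
                entry["icc"] = vars(icc_from_reader_table(table, parameter, method))
            except (FetMirrorError, ValueError) as err:
                entry["icc"] = {"error": str(err)}
            block[method] = entry
        if set(methods) == set(METHODS):
            block["comparison"] = compare_methods(table, parameter)
        report[parameter] = block
    return report
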