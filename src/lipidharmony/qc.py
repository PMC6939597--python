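"""Data-filtering QC: reproducibility, blank contamination, dilution linearity.

A lipid is quantifiable only if it
(1) is reproducibly detected — CoV over the replicate QC (long-term reference)
    injections below 20%,
(2) is absent from blank extractions — mean blank signal below 10% of the QC
    mean, and
(3) responds to dilution — OLS R² above 0.9 over the 50–200% portion of the
    dilution series.
All three cuts are strict inequalities; a lipid sitting exactly on a
threshold fails.  CoV and R² are computed on internal-standard-normalized
ratios (what the dilution design varies); the blank criterion uses raw
intensities, since blanks contain IS but no analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import LipidSpecies
from .quantify import InternalStandardMap, resolve_internal_standard
from .tables import MeasurementTable, Role

__all__ = ["QCThresholds", "QCReport", "cov", "linearity_r2", "apply_qc"]


@dataclass(frozen=True)
class QCThresholds:
    cov_max: float = 0.20
    blank_ratio_max: float = 0.10
    r2_min: float = 0.90
    linearity_range: tuple[float, float] = (0.5, 2.0)
    blank_aggregation: str = "mean"  # or "max" for a stricter variant
    missing_role_policy: str = "fail"  # or "skip": unevaluable criterion passes

    def __post_init__(self) -> None:
        if not (0 < self.cov_max <= 1 and 0 < self.blank_ratio_max <= 1 and 0 < self.r2_min <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        lo, hi = self.linearity_range
        if not (0 < lo < hi):
            raise ValueError("linearity range endpoints must be positive and ordered")
        if self.blank_aggregation not in ("mean", "max"):
            raise ValueError("blank_aggregation must be 'mean' or 'max'")
        if self.missing_role_policy not in ("fail", "skip"):
            raise ValueError("missing_role_policy must be 'fail' or 'skip'")


def cov(values) -> float:
    """Coefficient of variation: sample SD (n−1) over mean.

    Undefined (NaN) for fewer than two non-missing values or non-positive mean.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size < 2:
        return float("nan")
    mean = arr.mean()
    if mean <= 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def linearity_r2(
    fractions, responses, fit_range: tuple[float, float] = (0.5, 2.0)
) -> float:
    """R² of OLS (with intercept) of response on dilution fraction.

    Only points with fraction inside ``fit_range`` (inclusive) enter the fit;
    fewer than three such points → NaN.
    """
    f = np.asarray(fractions, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = (f >= fit_range[0]) & (f <= fit_range[1]) & np.isfinite(y) & np.isfinite(f)
    f, y = f[keep], y[keep]
    if f.size < 3:
        return float("nan")
    if np.allclose(y, y[0]):
        return 0.0  # flat response explains nothing
    result = stats.linregress(f, y)
    return float(result.rvalue**2)


@dataclass(frozen=True)
class QCReport:
    """Per-lipid filter statistics and verdicts.

    ``table`` has one row per lipid with columns cov, blank_ratio, r2,
    pass_cov, pass_blank, pass_r2, pass_overall and the evaluated-injection
    counts n_qc, n_blank, n_dilution.
    """

    table: pd.DataFrame
    thresholds: QCThresholds

    @property
    def survivors(self) -> list[str]:
        return list(self.table.index[self.table["pass_overall"]])

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index_label="lipid")


def _verdict(stat: float, passes_when_defined: bool, policy: str, evaluable: bool) -> bool:
    if not evaluable:
        return policy == "skip"
    if np.isnan(stat):
        return False  # conservative: missing statistic fails
    return passes_when_defined


def apply_qc(
    table: MeasurementTable,
    species_index: Mapping[str, LipidSpecies],
    is_map: InternalStandardMap,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Evaluate the three filters for every mapped lipid feature."""
    qc_cols = table.columns_with_role(Role.QC_LTR)
    blank_cols = table.columns_with_role(Role.BLANK)
    dil_cols = table.columns_with_role(Role.DILUTION)
    dil_fracs = table.injections.loc[dil_cols, "dilution_fraction"].astype(float)

    rows = []
    for feature, species in species_index.items():
        if species.is_internal_standard or feature not in table.intensities.index:
            continue
        is_feature, _ = resolve_internal_standard(species, is_map)
        intens = table.intensities.loc[feature]
        is_intens = table.intensities.loc[is_feature]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = intens / is_intens

        cov_stat = cov(ratios[qc_cols]) if qc_cols else float("nan")

        if qc_cols and blank_cols:
            qc_mean = np.nanmean(intens[qc_cols].to_numpy(dtype=float))
            blank_vals = intens[blank_cols].fillna(0.0).to_numpy(dtype=float)
            agg = np.mean if thresholds.blank_aggregation == "mean" else np.max
            blank_stat = float(agg(blank_vals) / qc_mean) if qc_mean > 0 else float("nan")
        else:
            blank_stat = float("nan")

        r2_stat = (
            linearity_r2(dil_fracs.to_numpy(), ratios[dil_cols].to_numpy(),
                         thresholds.linearity_range)
            if dil_cols else float("nan")
        )

        policy = thresholds.missing_role_policy
        pass_cov = _verdict(cov_stat, cov_stat < thresholds.cov_max, policy, bool(qc_cols))
        pass_blank = _verdict(
            blank_stat, blank_stat < thresholds.blank_ratio_max, policy, bool(blank_cols)
        )
        pass_r2 = _verdict(r2_stat, r2_stat > thresholds.r2_min, policy, bool(dil_cols))

        lo, hi = thresholds.linearity_range
        rows.append({
            "lipid": species.name,
            "cov": cov_stat,
            "blank_ratio": blank_stat,
            "r2": r2_stat,
            "pass_cov": pass_cov,
            "pass_blank": pass_blank,
            "pass_r2": pass_r2,
            "pass_overall": pass_cov and pass_blank and pass_r2,
            "n_qc": len(qc_cols),
            "n_blank": len(blank_cols),
            "n_dilution": int(((dil_fracs >= lo) & (dil_fracs <= hi)).sum()),
        })
    report = pd.DataFrame(rows).set_index("lipid") if rows else pd.DataFrame(
        columns=["cov", "blank_ratio", "r2", "pass_cov", "pass_blank",
                 "pass_r2", "pass_overall", "n_qc", "n_blank", "n_dilution"]
    )
    return QCReport(report, thresholds)
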