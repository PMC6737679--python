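"""Cohort statistics: Pearson correlation with band classification,
repeat-measurement coefficient of variation, and the summary report.

The correlation bands follow the convention used in clinical elastography
studies: |r| < 0.3 none, 0.3 <= |r| < 0.5 weak, 0.5 <= |r| < 0.7 moderate,
|r| >= 0.7 strong. Bands are applied to the magnitude of r so that strong
negative associations are classified symmetrically with positive ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationResult",
    "pearson",
    "classify_correlation",
    "coefficient_of_variation",
    "cohort_report",
]

#: Columns every cohort table must carry.
COHORT_COLUMNS = [
    "subject_id",
    "age",
    "breast_volume",
    "fgt_volume",
    "whole_percent_density",
    "local_percent_density",
    "stiffness",
    "stiffness_repeats",
    "roi_depth",
    "roi_window",
]


@dataclass(frozen=True)
class CorrelationResult:
    pair: str
    r: float
    n: int
    band: str


def pearson(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length samples.

    Raises ``ValueError`` on length mismatch, n < 3, or a constant input
    (where r is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return float(np.clip(r, -1.0, 1.0))


def classify_correlation(r: float) -> str:
    """Band a correlation coefficient by its magnitude."""
    r = float(r)
    if abs(r) > 1.0:
        raise ValueError(f"|r| must be <= 1, got {r}")
    a = abs(r)
    if a < 0.3:
        return "none"
    if a < 0.5:
        return "weak"
    if a < 0.7:
        return "moderate"
    return "strong"


def coefficient_of_variation(repeats) -> float:
    """Percent coefficient of variation of repeated measurements.

    100 * sample SD (n-1 denominator) / mean. Requires >= 2 repeats and a
    strictly positive mean.
    """
    repeats = np.asarray(repeats, dtype=float)
    if repeats.size < 2:
        raise ValueError("need at least 2 repeats")
    mean = repeats.mean()
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    return float(100.0 * repeats.std(ddof=1) / mean)


def _parse_repeats(value) -> np.ndarray:
    """Stiffness repeats are stored in CSV as a ';'-joined string."""
    if isinstance(value, str):
        return np.array([float(v) for v in value.split(";") if v != ""])
    return np.asarray(value, dtype=float)


_SUMMARY_VARS = {
    "stiffness": "m/s",
    "breast_volume": "cm3",
    "fgt_volume": "cm3",
    "whole_percent_density": "%",
    "local_percent_density": "%",
    "roi_depth": "cm",
}

_CORRELATION_PAIRS = [
    ("stiffness", "age"),
    ("stiffness", "breast_volume"),
    ("stiffness", "whole_percent_density"),
    ("stiffness", "local_percent_density"),
    ("whole_percent_density", "age"),
]


def cohort_report(cohort: pd.DataFrame) -> dict:
    """Summary statistics, correlations, and reproducibility for a cohort.

    Emits mean/SD/range per variable, the five stiffness/density/age
    Pearson correlations with bands, and per-subject CV of stiffness
    repeats with its <10% / 10-20% / >20% bin counts.
    """
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    n = len(cohort)
    report: dict = {"n": n, "summary": {}, "correlations": [], "reproducibility": {}}

    for var, units in _SUMMARY_VARS.items():
        vals = cohort[var].to_numpy(dtype=float)
        entry = {
            "mean": float(vals.mean()) if n else float("nan"),
            "sd": float(vals.std(ddof=1)) if n > 1 else None,
            "min": float(vals.min()) if n else float("nan"),
            "max": float(vals.max()) if n else float("nan"),
            "units": units,
        }
        if n == 1:
            entry["sd_undefined"] = True
        report["summary"][var] = entry

    if n >= 3:
        for a, b in _CORRELATION_PAIRS:
            r = pearson(cohort[a], cohort[b])
            report["correlations"].append(
                asdict(CorrelationResult(f"{a}~{b}", r, n, classify_correlation(r)))
            )

    cvs = np.array(
        [coefficient_of_variation(_parse_repeats(v)) for v in cohort["stiffness_repeats"]]
    ) if n else np.array([])
    report["reproducibility"] = {
        "per_subject_cv": [float(c) for c in cvs],
        "mean_cv": float(cvs.mean()) if n else float("nan"),
        "cv_range": [float(cvs.min()), float(cvs.max())] if n else None,
        "bins": {
            "lt_10": int((cvs < 10).sum()),
            "10_to_20": int(((cvs >= 10) & (cvs <= 20)).sum()),
            "gt_20": int((cvs > 20).sum()),
        },
    }
    return report


def write_report(report: dict, json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=2)
    if csv_path is not None:
        rows = [
            {"variable": k, **{kk: vv for kk, vv in v.items()}}
            for k, v in report["summary"].items()
        ]
        pd.DataFrame(rows).to_csv(csv_path, index=False)
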