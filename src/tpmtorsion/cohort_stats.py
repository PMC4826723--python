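"""Cohort-level statistics for torsion biomarkers.

Covers the statistical machinery used when comparing torsion parameters
between subject groups: normality-gated two-sample tests (Welch t-test for
normal samples, Wilcoxon rank-sum otherwise), Pearson correlation, and
Bland–Altman agreement with limits of agreement and a relative-error
summary.  Subgroup labels follow the clinical conventions: ejection
fraction >= 50% is "preserved" (EF+), a wall-motion study is WM+ if any of
the 16 segments is graded above 1 (scale 0-5), and LGE+/- flags the presence
of late gadolinium enhancement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectRecord",
    "ComparisonResult",
    "AgreementResult",
    "REFERENCE_GROUP_MEANS",
    "assign_subgroups",
    "compare_groups",
    "pearson_corr",
    "bland_altman",
]

EF_PRESERVED_THRESHOLD_PCT = 50.0
WM_ABNORMAL_GRADE = 1  # any segment graded above this is abnormal
N_AHA_SEGMENTS = 16

#: Published cohort-level summary means (deg/mm) for the torsion biomarkers,
#: kept for validation of derived ratio statistics.  Keys: subject group ->
#: biomarker -> mean.
REFERENCE_GROUP_MEANS: dict[str, dict[str, float]] = {
    "control": {"T_max": 0.36, "dT_max": 0.16, "T_max_endo": 0.46, "T_max_epi": 0.30},
    "wm_abnormal_preserved_ef": {"T_max": 0.23, "dT_max": 0.08},
    "ef_preserved": {"T_max": 0.41, "dT_max": 0.22, "T_max_endo": 0.56, "T_max_epi": 0.34},
    "ef_reduced": {"T_max": 0.21, "dT_max": 0.06},
}


@dataclass
class SubjectRecord:
    """One subject's torsion summary joined with clinical metadata."""

    subject_id: str
    group: str  # "patient" or "volunteer"
    ef_pct: float | None = None
    age_years: float | None = None
    sex: str | None = None
    ef_label: str | None = None  # "EF+" / "EF-"
    wm_label: str | None = None  # "WM+" / "WM-"
    lge_label: str | None = None  # "LGE+" / "LGE-"
    T_max: float | None = None
    T_max_endo: float | None = None
    T_max_epi: float | None = None
    dT_max: float | None = None
    dPctT_max: float | None = None


@dataclass
class ComparisonResult:
    """Two-sample comparison with the test actually used and its p-value."""

    groups: tuple[str, str]
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    test_used: str  # "welch_t" or "wilcoxon"
    p_value: float


@dataclass
class AgreementResult:
    """Bland–Altman agreement summary for paired measurements."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    relative_error_pct: float


def assign_subgroups(
    records: pd.DataFrame,
    wm_grades: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach EF+/-, WM+/- labels to a cohort table.

    Parameters
    ----------
    records : DataFrame with at least ``subject_id`` and ``ef_pct`` columns.
    wm_grades : DataFrame indexed by subject_id with 16 per-segment wall-motion
        scores in {0..5}; a subject is WM+ iff any segment is graded > 1.

    Records without an ejection fraction are dropped with a warning.
    """
    out = records.copy()
    missing = out["ef_pct"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} record(s) without ejection fraction",
            stacklevel=2,
        )
        out = out[~missing].copy()
    out["ef_label"] = np.where(
        out["ef_pct"] >= EF_PRESERVED_THRESHOLD_PCT, "EF+", "EF-"
    )
    if wm_grades is not None:
        grades = wm_grades.to_numpy()
        if grades.shape[1] != N_AHA_SEGMENTS:
            raise ValueError(f"expected {N_AHA_SEGMENTS} segment grades per subject")
        if ((grades < 0) | (grades > 5)).any():
            raise ValueError("wall-motion grades must be in 0..5")
        wm_pos = pd.Series(
            (grades > WM_ABNORMAL_GRADE).any(axis=1), index=wm_grades.index
        )
        out["wm_label"] = out["subject_id"].map(
            wm_pos.map({True: "WM+", False: "WM-"})
        )
    return out


def _is_normal(sample: np.ndarray, alpha: float) -> bool:
    if np.ptp(sample) == 0:
        return False  # Shapiro-Wilk is undefined for constant samples
    return stats.shapiro(sample).pvalue > alpha


def compare_groups(
    a: np.ndarray,
    b: np.ndarray,
    alpha_normality: float = 0.05,
    names: tuple[str, str] = ("a", "b"),
) -> ComparisonResult:
    """Two-sample comparison with a normality-gated choice of test.

    Shapiro–Wilk is applied to each sample; if both are compatible with
    normality the Welch (unequal-variance) t-test is used, otherwise the
    Wilcoxon rank-sum test.  Two-sided p-values throughout.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("both samples have zero variance; no test is meaningful")
    if _is_normal(a, alpha_normality) and _is_normal(b, alpha_normality):
        test, p = "welch_t", stats.ttest_ind(a, b, equal_var=False).pvalue
    else:
        test, p = "wilcoxon", stats.ranksums(a, b).pvalue
    return ComparisonResult(
        groups=names,
        n_a=len(a), n_b=len(b),
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        test_used=test, p_value=float(p),
    )


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation coefficient and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(
    x: np.ndarray,
    y: np.ndarray,
    relative_error: str = "pairwise",
) -> AgreementResult:
    """Bland–Altman agreement between paired measurements.

    Differences are x - y; limits of agreement are mean ± 1.96 × SD of the
    differences (SD with n-1 denominator).  The relative error is, by
    default, the mean over pairs of |difference| / pair mean in percent
    (pairs with zero mean are excluded with a warning); with
    ``relative_error="grand_mean"`` it is |mean difference| over the grand
    mean of all measurements.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    pair_means = (x + y) / 2.0
    if relative_error == "pairwise":
        ok = pair_means != 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} pair(s) with zero mean from the "
                "relative error", stacklevel=2,
            )
        rel = float(np.mean(np.abs(d[ok]) / np.abs(pair_means[ok])) * 100) if ok.any() else float("nan")
    elif relative_error == "grand_mean":
        grand = float(np.concatenate([x, y]).mean())
        rel = float(abs(mean_diff) / abs(grand) * 100) if grand != 0 else float("nan")
    else:
        raise ValueError(f"unknown relative_error mode {relative_error!r}")
    return AgreementResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
        relative_error_pct=rel,
    )
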