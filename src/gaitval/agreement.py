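"""Method-agreement statistics between the wearable and the optical reference.

Implements the full validation battery: absolute-error quartile tables,
ICC(2,k) (two-way random effects, absolute agreement, average measures, with
the F-based 95% confidence interval), Bland–Altman analysis with a mean +- SD
band, the two-sided Mann–Whitney U test for left/right error symmetry, and
detection-rate / distance summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import DetectionCounts, MatchedStridePair

FEATURES = ("length", "velocity")


def _diffs(pairs: list[MatchedStridePair], feature: str) -> np.ndarray:
    if feature == "length":
        return np.array([p.signed_diff_length for p in pairs])
    if feature == "velocity":
        return np.array([p.signed_diff_velocity for p in pairs])
    raise ValueError(f"unknown feature {feature!r}")


def _values(pairs: list[MatchedStridePair], feature: str) -> tuple[np.ndarray, np.ndarray]:
    if feature == "length":
        return (np.array([p.imu_length for p in pairs]),
                np.array([p.mocap_length for p in pairs]))
    if feature == "velocity":
        return (np.array([p.imu_velocity for p in pairs]),
                np.array([p.mocap_velocity for p in pairs]))
    raise ValueError(f"unknown feature {feature!r}")


def pairs_frame(pairs: list[MatchedStridePair]) -> pd.DataFrame:
    """Flat table of matched pairs with signed differences."""
    return pd.DataFrame({
        "subject": [p.subject for p in pairs],
        "exercise": [p.exercise for p in pairs],
        "foot": [p.foot for p in pairs],
        "imu_length_m": [p.imu_length for p in pairs],
        "mocap_length_m": [p.mocap_length for p in pairs],
        "imu_velocity_mps": [p.imu_velocity for p in pairs],
        "mocap_velocity_mps": [p.mocap_velocity for p in pairs],
        "diff_length_m": [p.signed_diff_length for p in pairs],
        "diff_velocity_mps": [p.signed_diff_velocity for p in pairs],
        "imu_midpoint_s": [p.imu_midpoint for p in pairs],
        "mocap_midpoint_s": [p.mocap_midpoint for p in pairs],
    })


def absolute_error_quartiles(pairs: list[MatchedStridePair],
                             feature: str = "length") -> pd.DataFrame:
    """Q1/median/Q3 of |wearable - mocap| per (exercise, side) and overall.

    Quantiles use the linear-interpolation convention. Rows: one per
    (exercise, side) group plus per-exercise "overall" sides, plus a global
    "overall"/"overall" row. Units are SI (m or m/s).
    """
    if not pairs:
        raise ValueError("no matched pairs")
    df = pairs_frame(pairs)
    col = "diff_length_m" if feature == "length" else "diff_velocity_mps"
    df["abs_err"] = df[col].abs()

    rows = []

    def quartile_row(exercise: str, side: str, values: np.ndarray) -> None:
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
        rows.append((exercise, side, float(q1), float(med), float(q3), len(values)))

    exercises = sorted(df["exercise"].unique())
    for ex in exercises:
        sub = df[df["exercise"] == ex]
        for side in sorted(sub["foot"].unique()):
            quartile_row(ex, side, sub.loc[sub["foot"] == side, "abs_err"].to_numpy())
        quartile_row(ex, "overall", sub["abs_err"].to_numpy())
    for side in sorted(df["foot"].unique()):
        quartile_row("overall", side, df.loc[df["foot"] == side, "abs_err"].to_numpy())
    quartile_row("overall", "overall", df["abs_err"].to_numpy())
    return pd.DataFrame(rows, columns=["exercise", "side", "q1", "median", "q3", "n"])


@dataclass
class IccResult:
    icc2k: float
    ci95: tuple[float, float]
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_targets: int
    k_raters: int
    icc2_single: float = float("nan")

    def __post_init__(self) -> None:
        if self.icc2k > 1:
            raise ValueError("ICC cannot exceed 1")


def icc2k(x: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> IccResult:
    """ICC(2,k): two-way random effects, absolute agreement, average measures.

    ``x`` and ``y`` are the two systems' measurements of the same n targets
    (k = 2 raters). Point estimate from the two-way ANOVA mean squares::

        ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

    The 95% CI is the standard F-based interval for the single-measure form,
    stepped up with the Spearman-Brown relation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 targets")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    # guard against tiny negative residuals from catastrophic cancellation
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if mse == 0.0 and msc <= 1e-30 * max(msr, 1.0):
        if msr <= 0:
            raise ValueError("degenerate variance structure; ICC undefined")
        # the two raters agree exactly on every target
        return IccResult(icc2k=1.0, ci95=(1.0, 1.0), ms_rows=float(msr),
                         ms_cols=0.0, ms_error=0.0, n_targets=n, k_raters=k,
                         icc2_single=1.0)

    denom_k = msr + (msc - mse) / n
    denom_1 = msr + (k - 1) * mse + k * (msc - mse) / n
    if abs(denom_k) < 1e-30 or abs(denom_1) < 1e-30:
        raise ValueError("degenerate variance structure; ICC undefined")
    icc_k = (msr - mse) / denom_k
    icc_1 = (msr - mse) / denom_1

    # F-based CI (Shrout & Fleiss / McGraw & Wong) for ICC(2,1), then
    # Spearman-Brown step-up to the average-measures form.
    fj = msc / mse if mse > 0 else np.inf
    vn = (k - 1) * (n - 1) * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1)
                              - k * icc_1) ** 2
    vd = ((n - 1) * k ** 2 * icc_1 ** 2 * fj ** 2
          + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_u = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)

    def step_up(r: float) -> float:
        return k * r / (1 + (k - 1) * r)

    lo, hi = sorted((step_up(lo1), step_up(hi1)))
    lo = min(lo, icc_k)
    hi = max(hi, icc_k)
    return IccResult(icc2k=float(icc_k), ci95=(float(lo), float(hi)),
                     ms_rows=float(msr), ms_cols=float(msc), ms_error=float(mse),
                     n_targets=n, k_raters=k, icc2_single=float(icc_1))


def icc2k_for_feature(pairs: list[MatchedStridePair],
                      feature: str = "length") -> IccResult:
    x, y = _values(pairs, feature)
    return icc2k(x, y)


@dataclass
class BlandAltmanResult:
    bias: float  # mean signed difference
    sd: float  # sample SD (ddof=1) of the differences
    band: tuple[float, float]  # bias -+ band_multiplier * sd
    points: pd.DataFrame = field(repr=False)  # columns mean, difference, group
    fraction_outside: float = float("nan")
    band_multiplier: float = 1.0

    def __post_init__(self) -> None:
        width = self.band[1] - self.band[0]
        if abs(width - 2 * self.band_multiplier * self.sd) > 1e-9:
            raise ValueError("band width must equal 2 * multiplier * sd")


def bland_altman(pairs: list[MatchedStridePair], feature: str = "length",
                 group_by: str | None = None,
                 band_multiplier: float = 1.0) -> BlandAltmanResult:
    """Bland–Altman agreement with a mean +- SD error band.

    The band is ``bias +- band_multiplier * sd``; the default multiplier of 1
    reports the mu +- sigma band, pass 1.96 for conventional limits of
    agreement. ``group_by`` labels points by "foot", "subject" or "exercise".
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    a, b = _values(pairs, feature)
    diffs = a - b
    means = 0.5 * (a + b)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    band = (bias - band_multiplier * sd, bias + band_multiplier * sd)
    groups = ([getattr(p, group_by) for p in pairs] if group_by
              else [""] * len(pairs))
    points = pd.DataFrame({"mean": means, "difference": diffs, "group": groups})
    outside = float(np.mean((diffs < band[0]) | (diffs > band[1]))) if sd > 0 else 0.0
    return BlandAltmanResult(bias=bias, sd=sd, band=band, points=points,
                             fraction_outside=outside,
                             band_multiplier=band_multiplier)


@dataclass
class MannWhitneyResult:
    u_statistic: float
    p_value: float
    n_left: int
    n_right: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value out of range")
        if self.u_statistic > self.n_left * self.n_right:
            raise ValueError("U exceeds n1*n2")


def mann_whitney_two_sided(x, y) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test of two independent samples.

    Uses exact enumeration for small tie-free samples (both n <= 8) and the
    tie-corrected normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return MannWhitneyResult(u_statistic=float(res.statistic),
                             p_value=float(res.pvalue),
                             n_left=len(x), n_right=len(y))


def left_right_tests(pairs: list[MatchedStridePair]) -> pd.DataFrame:
    """Left-vs-right signed-error Mann–Whitney tests, per exercise and globally."""
    df = pairs_frame(pairs)
    rows = []
    scopes = [("all", df)] + [(ex, df[df["exercise"] == ex])
                              for ex in sorted(df["exercise"].unique()) if ex]
    for scope, sub in scopes:
        left = sub[sub["foot"] == "left"]
        right = sub[sub["foot"] == "right"]
        for feature, col in (("length", "diff_length_m"),
                             ("velocity", "diff_velocity_mps")):
            if left.empty or right.empty:
                continue
            res = mann_whitney_two_sided(left[col].to_numpy(), right[col].to_numpy())
            rows.append((scope, feature, res.u_statistic, res.p_value,
                         res.n_left, res.n_right))
    return pd.DataFrame(rows, columns=["scope", "feature", "u_statistic",
                                       "p_value", "n_left", "n_right"])


def detection_summary(counts: dict[tuple[str, str], DetectionCounts]) -> pd.DataFrame:
    """True-positive rates and totals per (exercise, side), plus aggregate.

    A group with no truth strides gets a flagged, undefined rate.
    """
    rows = []
    total = DetectionCounts(0, 0, 0)
    for (exercise, side), c in sorted(counts.items()):
        rate = c.true_positive_rate
        rows.append((exercise, side, c.tp, c.fp, c.fn, c.detected_total,
                     c.truth_total, rate if rate is not None else np.nan,
                     rate is None))
        total = total + c
    rate = total.true_positive_rate
    rows.append(("all", "all", total.tp, total.fp, total.fn, total.detected_total,
                 total.truth_total, rate if rate is not None else np.nan,
                 rate is None))
    return pd.DataFrame(rows, columns=["exercise", "side", "tp", "fp", "fn",
                                       "detected_total", "truth_total",
                                       "true_positive_rate", "rate_undefined"])


def distance_summary(features_by_system: pd.DataFrame) -> pd.DataFrame:
    """Total measured distance per subject, exercise, side and system.

    Input: long table with columns subject, exercise, foot, system, length_m.
    """
    return (features_by_system
            .groupby(["subject", "exercise", "foot", "system"], as_index=False)
            .agg(total_distance_m=("length_m", "sum"),
                 n_strides=("length_m", "size")))


def plot_bland_altman(result: BlandAltmanResult, path) -> None:
    """Scatter of per-pair difference vs mean with bias and band lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in result.points.groupby("group"):
        ax.scatter(grp["mean"], grp["difference"], s=8, alpha=0.6,
                   label=str(name) if name else None)
    ax.axhline(result.bias, color="k", lw=1)
    for b in result.band:
        ax.axhline(b, color="k", lw=1, ls="--")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("difference (wearable - mocap)")
    if result.points["group"].nunique() > 1:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
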