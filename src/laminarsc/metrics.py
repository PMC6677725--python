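"""Per-channel epoch statistics and depth-profile population analyses.

The visuomotor index VMI = (M - V)/(M + V) contrasts the baseline-corrected
mean rate in the visual epoch ([0, 100] ms after visual burst onset, V)
against the peri-saccadic epoch ([-25, 25] ms re saccade onset, M): -1 is a
purely visual unit, +1 purely motor.  Channels are categorized as
visual-only / visuo-movement / movement-only from per-epoch significance
(rank-sum P < 0.001 vs baseline plus a 10 spk/s floor on the corrected
mean).  Depth trends of any per-channel quantity are summarized by a cubic
fit over aligned channel index with a permutation P value, and session
profiles are aggregated with 1000-resample bootstrap confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "VMIRecord",
    "UnitCategory",
    "CubicFit",
    "PopulationProfile",
    "vmi",
    "categorize_unit",
    "last_visual_peak",
    "delay_bins",
    "cubic_fit_permutation",
    "burst_peak_scaling",
    "population_aggregate",
    "compare_groups",
]

RANKSUM_ALPHA = 0.001
RATE_GATE_SPK_S = 10.0
DELAY_BIN_MS = 50.0


@dataclass
class VMIRecord:
    V: float
    M: float
    vmi: float | None

    @property
    def defined(self) -> bool:
        return self.vmi is not None


@dataclass
class UnitCategory:
    visual_significant: bool
    movement_significant: bool

    @property
    def category(self) -> str:
        if self.visual_significant and self.movement_significant:
            return "visuo-movement"
        if self.visual_significant:
            return "visual-only"
        if self.movement_significant:
            return "movement-only"
        return "none"


@dataclass
class CubicFit:
    coefficients: np.ndarray      # a, b, c, d for a x^3 + b x^2 + c x + d
    r_squared: float
    p_perm: float | None = None
    n_perm: int = 0

    def predict(self, x) -> np.ndarray:
        return np.polyval(self.coefficients, np.asarray(x, float))

    @property
    def significant(self) -> bool:
        return self.p_perm is not None and self.p_perm < 0.05


@dataclass
class PopulationProfile:
    """Session-averaged quantity vs aligned channel index with bootstrap CI."""

    quantity: str
    table: pd.DataFrame           # aligned_index, n_sessions, mean, ci_lo, ci_hi

    def mean_at(self, index: int) -> float:
        row = self.table[self.table["aligned_index"] == index]
        return float(row["mean"].iloc[0])


def vmi(V: float, M: float) -> VMIRecord:
    """Visuomotor index (M - V)/(M + V); undefined when V + M == 0."""
    total = V + M
    if total == 0:
        return VMIRecord(V=V, M=M, vmi=None)
    return VMIRecord(V=V, M=M, vmi=(M - V) / total)


def categorize_unit(
    visual_trials: np.ndarray,
    visual_baseline_trials: np.ndarray,
    movement_trials: np.ndarray,
    movement_baseline_trials: np.ndarray,
    *,
    alpha: float = RANKSUM_ALPHA,
    rate_gate: float = RATE_GATE_SPK_S,
) -> UnitCategory:
    """Classify a channel from per-trial (non-corrected) epoch means.

    An epoch is significant iff the across-trial rank-sum test against its
    baseline gives P < 0.001 AND the baseline-corrected trial-averaged rate
    is at least 10 spk/s.
    """
    if min(len(visual_trials), len(movement_trials)) < 5:
        raise ValueError("need at least 5 trials per epoch")

    def significant(epoch, base) -> bool:
        p = stats.ranksums(epoch, base).pvalue
        corrected = float(np.mean(epoch) - np.mean(base))
        return bool(p < alpha and corrected >= rate_gate)

    return UnitCategory(
        visual_significant=significant(visual_trials, visual_baseline_trials),
        movement_significant=significant(movement_trials, movement_baseline_trials),
    )


def last_visual_peak(
    time: np.ndarray,
    values: np.ndarray,
    *,
    window: tuple[float, float] = (0.0, 150.0),
    rel_height: float = 0.5,
) -> float:
    """Final local maximum of the visual burst (often the second of two).

    Peaks are local maxima inside ``window`` whose amplitude exceeds
    ``rel_height`` of the window maximum; the latest qualifying peak time is
    returned (the window maximum itself when none qualifies).
    """
    m = (time >= window[0]) & (time <= window[1])
    seg, tseg = values[m], time[m]
    idx, _ = signal.find_peaks(seg, height=rel_height * seg.max())
    if idx.size == 0:
        return float(tseg[np.argmax(seg)])
    return float(tseg[idx[-1]])


def delay_bins(
    time: np.ndarray,
    values: np.ndarray,
    start: float,
    stop: float,
    *,
    bin_ms: float = DELAY_BIN_MS,
) -> np.ndarray:
    """Baseline-corrected means in non-overlapping 50 ms bins over the delay.

    ``values`` must already be baseline-corrected in the visual frame;
    ``start`` is the last visual-burst peak and ``stop`` the end of the
    shortest delay period.  Returns ``floor((stop-start)/50)`` bin means
    (possibly zero bins).
    """
    n_bins = int((stop - start) // bin_ms)
    out = np.empty(n_bins)
    for i in range(n_bins):
        m = (time >= start + i * bin_ms) & (time < start + (i + 1) * bin_ms)
        out[i] = values[m].mean()
    return out


def cubic_fit_permutation(
    x: np.ndarray,
    y: np.ndarray,
    *,
    n_perm: int = 1000,
    seed: int = 0,
) -> CubicFit:
    """Least-squares cubic over depth index with a permutation P value.

    The null is built by shuffling the depth indices: P equals the fraction
    of shuffles whose cubic R² is greater than or equal to the observed R²
    (degenerate constant data get R² = 0 and are never significant).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 5:
        raise ValueError("need at least 5 points for a cubic depth fit")
    X = np.vander(x, 4)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return CubicFit(coefficients=coef, r_squared=0.0, p_perm=1.0,
                        n_perm=n_perm)
    sse = float(((y - X @ coef) ** 2).sum())
    r2 = 1.0 - sse / sst

    rng = np.random.default_rng(seed)
    # shuffling the depth index is equivalent to permuting y against fixed x
    Y = np.empty((x.size, n_perm))
    for j in range(n_perm):
        Y[:, j] = y[rng.permutation(x.size)]
    Q, _ = np.linalg.qr(X)
    sse_perm = (Y**2).sum(axis=0) - ((Q.T @ Y) ** 2).sum(axis=0)
    r2_perm = 1.0 - sse_perm / sst
    p = float(np.mean(r2_perm >= r2 - 1e-12))
    return CubicFit(coefficients=coef, r_squared=float(r2), p_perm=p,
                    n_perm=n_perm)


def burst_peak_scaling(
    burst_fit: CubicFit,
    peak_fit: CubicFit,
    index_range: tuple[float, float],
    *,
    n_grid: int = 1001,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Scaling factor between the fitted Burst-onset and peak rate profiles.

    The factor is the ratio of the two cubic fits' maxima over the shared
    aligned-index range; the rescaled burst curve is returned for visual
    comparison with the peak curve.
    """
    grid = np.linspace(index_range[0], index_range[1], n_grid)
    burst_max = float(burst_fit.predict(grid).max())
    if burst_max <= 0:
        raise ValueError("burst fit maximum must be positive")
    factor = float(peak_fit.predict(grid).max()) / burst_max
    return factor, grid, factor * burst_fit.predict(grid)


def population_aggregate(
    table: pd.DataFrame,
    value_col: str,
    *,
    quantity: str | None = None,
    index_col: str = "aligned_index",
    n_boot: int = 1000,
    seed: int = 0,
) -> PopulationProfile:
    """Per-aligned-index mean over sessions with a 95% bootstrap CI.

    Indices observed in a single session are reported with a degenerate
    (mean, mean) interval.  NaN values are dropped per index.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for idx, grp in table.groupby(index_col):
        vals = grp[value_col].to_numpy(float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        mean = float(vals.mean())
        if vals.size >= 2:
            draws = rng.integers(0, vals.size, size=(n_boot, vals.size))
            boots = vals[draws].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
        else:
            lo = hi = mean
        rows.append(
            {
                index_col: idx, "n_sessions": int(vals.size), "mean": mean,
                "ci_lo": float(lo), "ci_hi": float(hi),
                "single_session": vals.size < 2,
            }
        )
    return PopulationProfile(
        quantity=quantity or value_col,
        table=pd.DataFrame(rows).sort_values(index_col).reset_index(drop=True),
    )


def compare_groups(a: np.ndarray, b: np.ndarray, *, alpha_norm: float = 0.05):
    """Two-tailed VG-vs-MG style comparison with KS-gated test choice.

    Each sample is standardized and checked against normality with a
    Kolmogorov-Smirnov test; a t test is used when neither sample rejects
    normality, a Wilcoxon rank-sum test otherwise.  Returns
    ``(test_name, p_value)``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def normal(x) -> bool:
        if x.size < 3 or x.std(ddof=1) == 0:
            return False
        z = (x - x.mean()) / x.std(ddof=1)
        return stats.kstest(z, "norm").pvalue >= alpha_norm

    if normal(a) and normal(b):
        return "t", float(stats.ttest_ind(a, b).pvalue)
    return "ranksum", float(stats.ranksums(a, b).pvalue)
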