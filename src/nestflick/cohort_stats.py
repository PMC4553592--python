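"""Rate/intensity statistics of flickering cohorts.

Per test square the pipeline reports a flickering rate (events per second)
and a flickering intensity fI = sum of event Δlum per reference time t_ref.
Squares are split into trigger-site (ts) and non-trigger-site (nts) cohorts,
rates are binned into 30 contiguous classes of width 0.03 Hz, and per-class
intensity means +/- SEM are compared between cohorts: the per-class
difference d_fI = fI_ts - fI_nts is sorted by sign and the positive/negative
counts tested against equal expectation with a df=1 chi-square.  Class-mean
rate-intensity curves are summarised by log-linear exponential fits
y = a * exp(b * x), and the rate-intensity association by a Spearman rank
correlation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .flicker_events import FlickerEvent
from .trigger_map import CohortPartition

Square = Tuple[int, int]

RATE_CLASS_WIDTH = 0.03  # Hz
N_RATE_CLASSES = 30


@dataclass(frozen=True)
class RelFSummary:
    """Fractions of nest squares that are flickering-active, split by cohort.

    ``relF_total = relF_ts + relF_nts`` holds exactly (disjoint cohorts).
    """

    relf_total: float
    relf_ts: float
    relf_nts: float

    def __post_init__(self) -> None:
        for v in (self.relf_total, self.relf_ts, self.relf_nts):
            if not 0 <= v <= 1 + 1e-12:
                raise ValueError("relF values must lie in [0, 1]")


@dataclass(frozen=True)
class ExpFit:
    """Log-linear least-squares fit of y = a * exp(b * x).

    ``r_squared`` is the coefficient of determination of the regression of
    ln(y) on x (the fitted scale); ``n_dropped`` counts non-positive y values
    excluded from the fit.
    """

    a: float
    b: float
    r_squared: float
    n_points: int
    n_dropped: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class CohortComparison:
    """Sign-sorted per-class intensity differences d_fI = fI_ts - fI_nts."""

    deltas: pd.DataFrame  # columns: class_index, delta_fi
    n_positive: int
    n_negative: int
    chi2: float
    p_value: float


def square_rate(events: Sequence[FlickerEvent] | int, observed_s: float) -> float:
    """Flickering rate in Hz: events per second of observation."""
    if observed_s <= 0:
        raise ValueError("observed_s must be positive")
    n = events if isinstance(events, int) else len(list(events))
    if n < 0:
        raise ValueError("event count must be >= 0")
    return n / observed_s


def square_intensity(events: Sequence[FlickerEvent] | Sequence[float],
                     t_ref: float) -> float:
    """Flickering intensity fI = (sum of event Δlum) / t_ref."""
    if t_ref <= 0:
        raise ValueError("t_ref must be positive")
    total = 0.0
    for ev in events:
        total += ev.sum_dlum if isinstance(ev, FlickerEvent) else float(ev)
    return total / t_ref


def build_rate_intensity_table(events: Iterable[FlickerEvent],
                               partition: CohortPartition,
                               t_ref: float,
                               phase_label: str = "all") -> pd.DataFrame:
    """Per-square rate (Hz) and intensity fI for every active square.

    Squares outside the partition (masked) are skipped.  Squares without any
    event appear with rate = fI = 0, so occupancy (relF) and rate-class 0
    bookkeeping stay consistent.
    """
    if t_ref <= 0:
        raise ValueError("t_ref must be positive")
    by_square: Dict[Square, List[FlickerEvent]] = {}
    for ev in events:
        sq = tuple(ev.square)
        if partition.cohort_of(sq) is None:
            continue
        by_square.setdefault(sq, []).append(ev)
    rows = []
    for cohort, squares in (("ts", partition.ts_squares), ("nts", partition.nts_squares)):
        for sq in sorted(squares):
            evs = by_square.get(sq, [])
            rows.append({
                "square_row": sq[0], "square_col": sq[1], "cohort": cohort,
                "n_events": len(evs),
                "rate_hz": square_rate(len(evs), t_ref),
                "intensity_fi": square_intensity(evs, t_ref),
                "phase": phase_label,
            })
    return pd.DataFrame(rows, columns=["square_row", "square_col", "cohort",
                                       "n_events", "rate_hz", "intensity_fi",
                                       "phase"])


def relf_metrics(active_flicker_squares: Iterable[Square],
                 partition: CohortPartition,
                 nest_squares: int) -> RelFSummary:
    """relF occupancy: fraction of nest squares with >= 1 flicker, by cohort.

    ``nest_squares`` is the 100% denominator -- the number of test squares
    covering the nest area.
    """
    if nest_squares <= 0:
        raise ValueError("nest_squares must be positive")
    flicking = {tuple(sq) for sq in active_flicker_squares}
    n_ts = len(flicking & partition.ts_squares)
    n_nts = len(flicking & partition.nts_squares)
    outside = flicking - partition.ts_squares - partition.nts_squares
    if outside:
        raise ValueError(f"flickering squares outside the partition: {sorted(outside)[:5]}")
    return RelFSummary(relf_total=(n_ts + n_nts) / nest_squares,
                       relf_ts=n_ts / nest_squares,
                       relf_nts=n_nts / nest_squares)


def rate_class_index(rate_hz: float, width: float = RATE_CLASS_WIDTH,
                     n_classes: int = N_RATE_CLASSES) -> int:
    """Half-open class [k*width, (k+1)*width); overflow capped into the top class."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    return min(int(math.floor(rate_hz / width)), n_classes - 1)


def bin_rate_classes(records: pd.DataFrame, width: float = RATE_CLASS_WIDTH,
                     n_classes: int = N_RATE_CLASSES,
                     include_zero_rate: bool = False) -> pd.DataFrame:
    """Compile per-class, per-cohort intensity means and SEMs.

    Returns one row per (class_index, cohort) with columns ``n``, ``mean_fi``,
    ``sem_fi`` (sample sd / sqrt(n); 0 for n = 1) and the class bounds.
    By default squares with zero rate (no events) are excluded from the
    compilation -- they carry no flickering -- unless ``include_zero_rate``.
    Rates >= ``n_classes * width`` are capped into the top class with a warning.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    df = records.copy()
    if not include_zero_rate:
        df = df[df["rate_hz"] > 0]
    if (df["rate_hz"] >= n_classes * width).any():
        warnings.warn("rates beyond the top class were capped", stacklevel=2)
    df = df.assign(class_index=[rate_class_index(r, width, n_classes)
                                for r in df["rate_hz"]])
    rows = []
    for (k, cohort), grp in df.groupby(["class_index", "cohort"], sort=True):
        vals = grp["intensity_fi"].to_numpy(dtype=float)
        n = len(vals)
        sem = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append({"class_index": int(k), "cohort": cohort,
                     "class_low_hz": k * width, "class_high_hz": (k + 1) * width,
                     "n": n, "mean_fi": float(vals.mean()), "sem_fi": sem})
    return pd.DataFrame(rows, columns=["class_index", "cohort", "class_low_hz",
                                       "class_high_hz", "n", "mean_fi", "sem_fi"])


def class_midpoints(table: pd.DataFrame) -> np.ndarray:
    return ((table["class_low_hz"] + table["class_high_hz"]) / 2).to_numpy()


def fit_exponential(x: Sequence[float], y: Sequence[float]) -> ExpFit:
    """Least-squares fit of y = a * exp(b * x) on the log-linear scale.

    Ordinary least squares of ln(y) on x; returns a = exp(intercept),
    b = slope, and the R² of that regression.  Points with y <= 0 are
    dropped with a warning; at least two positive points are required.
    Noiseless curve data is recovered exactly (R² = 1); a constant y gives
    b = 0, a = y, R² = 1 (zero total variance means a perfect fit).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} non-positive y values from exponential fit",
                      stacklevel=2)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("need at least two points with y > 0")
    ln_y = np.log(y)
    slope, intercept = np.polyfit(x, ln_y, 1)
    resid = ln_y - (intercept + slope * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ExpFit(a=float(np.exp(intercept)), b=float(slope),
                  r_squared=float(min(max(r2, 0.0), 1.0)),
                  n_points=int(x.size), n_dropped=n_dropped)


def spearman_rate_intensity(rates: Sequence[float],
                            intensities: Sequence[float]) -> Tuple[float, float]:
    """Spearman rank correlation (mid-rank ties, two-sided P) of rate vs fI."""
    rates = np.asarray(rates, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if rates.size != intensities.size or rates.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(rates == rates[0]) or np.all(intensities == intensities[0]):
        raise ValueError("rank correlation undefined for constant input")
    rho, p = _stats.spearmanr(rates, intensities)
    return float(rho), float(p)


def chi_square_sign_test(n_pos: int, n_neg: int) -> Tuple[float, float]:
    """df = 1 goodness-of-fit of positive vs negative counts against 50:50.

    chi2 = (n_pos - n_neg)^2 / (n_pos + n_neg), no continuity correction.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("counts must be >= 0")
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("sign test undefined for zero counts")
    chi2 = (n_pos - n_neg) ** 2 / total
    p = float(_stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def cohort_difference(table: pd.DataFrame) -> CohortComparison:
    """Per-class d_fI = mean fI_ts - mean fI_nts, sign-sorted and chi2-tested.

    Classes missing either cohort are excluded; classes with d_fI == 0 are
    excluded from both sign groups.
    """
    pivot = table.pivot_table(index="class_index", columns="cohort",
                              values="mean_fi", aggfunc="first")
    if "ts" not in pivot.columns or "nts" not in pivot.columns:
        raise ValueError("table must contain both ts and nts cohorts")
    both = pivot.dropna(subset=["ts", "nts"])
    deltas = pd.DataFrame({
        "class_index": both.index.to_numpy(),
        "delta_fi": (both["ts"] - both["nts"]).to_numpy(),
    })
    n_pos = int((deltas["delta_fi"] > 0).sum())
    n_neg = int((deltas["delta_fi"] < 0).sum())
    if n_pos + n_neg > 0:
        chi2, p = chi_square_sign_test(n_pos, n_neg)
    else:
        chi2, p = 0.0, 1.0
    return CohortComparison(deltas=deltas, n_positive=n_pos, n_negative=n_neg,
                            chi2=chi2, p_value=p)
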