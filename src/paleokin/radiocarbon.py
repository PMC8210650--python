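"""Radiocarbon combination, calibration, and death-order probabilities.

Replicate conventional radiocarbon ages for one sample are combined by an
inverse-variance weighted mean after a chi-square homogeneity test (Ward &
Wilson): T = sum((x_i - xbar)^2 / sigma_i^2) against the 5% critical value
at n - 1 degrees of freedom.

Calibration uses the probability method on a calibration-curve table (the
standard IntCal layout: cal BP grid, curve mean BP, curve sigma): posterior
mass per grid year proportional to the normal density of the measured age
about the curve mean with variance sigma_meas^2 + sigma_curve^2.  95%
ranges are built by descending-probability inclusion, merged into
contiguous runs, and rounded outward to 5 years.  Internally everything is
cal BP; reporting converts to cal BCE as cal BCE = cal BP - 1949.

Death order between two individuals treats their calibrated posteriors as
independent: P(A died first) = P(t_A earlier than t_B), with ties at the
grid resolution split evenly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import RadiocarbonSample


class RadiocarbonError(ValueError):
    pass


@dataclass
class WardWilsonResult:
    weighted_mean: float
    sigma: float
    t_statistic: float
    df: int
    critical_5pct: float
    consistent: bool


def ward_wilson(measurements: list[RadiocarbonSample]) -> WardWilsonResult:
    """Combine replicate ages; chi-square homogeneity test at the 5% level."""
    if len(measurements) < 2:
        raise RadiocarbonError("need >= 2 measurements to combine")
    x = np.array([m.age_bp for m in measurements], dtype=float)
    s = np.array([m.sigma for m in measurements], dtype=float)
    if np.any(s <= 0):
        raise RadiocarbonError("sigma must be positive")
    w = 1.0 / s ** 2
    mean = float(np.sum(w * x) / np.sum(w))
    sigma = float(1.0 / np.sqrt(np.sum(w)))
    t = float(np.sum((x - mean) ** 2 / s ** 2))
    df = len(x) - 1
    crit = float(stats.chi2.ppf(0.95, df))
    return WardWilsonResult(weighted_mean=mean, sigma=sigma, t_statistic=t,
                            df=df, critical_5pct=crit, consistent=t <= crit)


@dataclass
class CalibrationCurve:
    """Calendar grid (cal BP), curve mean (BP) and curve sigma per point."""

    cal_bp: np.ndarray
    mean_bp: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.mean_bp = np.asarray(self.mean_bp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        d = np.diff(self.cal_bp)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise RadiocarbonError("calendar grid must be strictly monotone")
        if np.any(self.sigma <= 0):
            raise RadiocarbonError("curve sigma must be positive")
        if self.cal_bp[0] > self.cal_bp[-1]:     # store ascending
            self.cal_bp = self.cal_bp[::-1]
            self.mean_bp = self.mean_bp[::-1]
            self.sigma = self.sigma[::-1]

    @classmethod
    def from_table(cls, path) -> "CalibrationCurve":
        """Read a 3+-column whitespace/comma table (cal BP, mean BP, sigma)."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(),
                   df.iloc[:, 2].to_numpy())

    def resample(self, step: float) -> "CalibrationCurve":
        grid = np.arange(self.cal_bp[0], self.cal_bp[-1] + step / 2, step)
        return CalibrationCurve(grid, np.interp(grid, self.cal_bp, self.mean_bp),
                                np.interp(grid, self.cal_bp, self.sigma))

    def curve_age(self, cal_bp: float) -> float:
        return float(np.interp(cal_bp, self.cal_bp, self.mean_bp))


def linear_curve(cal_lo: float, cal_hi: float, slope: float = 1.0,
                 intercept: float = 0.0, sigma: float = 1e-6,
                 step: float = 1.0) -> CalibrationCurve:
    """Strictly linear synthetic curve: mean BP = intercept + slope * cal BP."""
    grid = np.arange(cal_lo, cal_hi + step / 2, step)
    return CalibrationCurve(grid, intercept + slope * grid,
                            np.full(grid.size, sigma))


@dataclass
class CalibratedDate:
    cal_bp: np.ndarray
    probability: np.ndarray
    ranges_95: list[tuple[float, float]]    # cal BP, rounded outward to 5 yr

    @property
    def mode_cal_bp(self) -> float:
        return float(self.cal_bp[np.argmax(self.probability)])

    def ranges_bce(self) -> list[tuple[float, float]]:
        """95% ranges in cal BCE (cal BCE = cal BP - 1949), older bound first."""
        return [(hi - 1949.0, lo - 1949.0) for lo, hi in self.ranges_95]

    def format_bce(self) -> str:
        parts = [f"{int(older)}–{int(younger)}" for older, younger in
                 sorted(self.ranges_bce(), reverse=True)]
        return ", ".join(parts) + " cal BCE (95%)"


def calibrate(measurement: RadiocarbonSample, curve: CalibrationCurve,
              level: float = 0.95, round_to: int = 5) -> CalibratedDate:
    """Probability-method calibration of one conventional age.

    Posterior mass per grid year is proportional to the normal density of
    (age - curve mean) with variance sigma_meas^2 + sigma_curve^2; the
    ``level`` ranges are the smallest set of grid years by descending
    probability, merged into contiguous runs and rounded outward.
    """
    var = measurement.sigma ** 2 + curve.sigma ** 2
    logdens = -0.5 * (measurement.age_bp - curve.mean_bp) ** 2 / var - 0.5 * np.log(var)
    logdens -= logdens.max()
    mass = np.exp(logdens)
    total = mass.sum()
    if total <= 0 or mass[0] + mass[-1] > 0.01 * total:
        raise RadiocarbonError("curve does not cover the plausible range")
    prob = mass / total

    order = np.argsort(prob)[::-1]
    csum = np.cumsum(prob[order])
    n_keep = int(np.searchsorted(csum, level) + 1)
    keep = np.zeros(prob.size, dtype=bool)
    keep[order[:n_keep]] = True

    ranges: list[tuple[float, float]] = []
    grid = curve.cal_bp
    step = float(np.median(np.diff(grid)))
    in_run = False
    for i, flag in enumerate(keep):
        if flag and not in_run:
            start = grid[i]
            in_run = True
        elif not flag and in_run:
            ranges.append((start, grid[i - 1]))
            in_run = False
    if in_run:
        ranges.append((start, grid[-1]))
    rounded = [(_floor_to(lo, round_to), _ceil_to(hi, round_to))
               for lo, hi in ranges]
    return CalibratedDate(cal_bp=grid, probability=prob, ranges_95=rounded)


def _floor_to(x: float, q: int) -> float:
    return float(np.floor(x / q) * q)


def _ceil_to(x: float, q: int) -> float:
    return float(np.ceil(x / q) * q)


def death_order_probability(cal_a: CalibratedDate, cal_b: CalibratedDate) -> float:
    """P(A died before B) under independent calibrated posteriors.

    'Earlier' means a larger cal BP.  Ties at the shared grid resolution
    contribute half weight, which makes
    P(A first) + P(B first) = 1 exactly.
    """
    pa, pb, grid = _align(cal_a, cal_b)
    # pa/pb are indexed in chronological order (earliest first); A dies first
    # when B's death falls strictly later, i.e. at a higher index
    tail_b_after = 1.0 - np.cumsum(pb)
    p = float(np.sum(pa * tail_b_after) + 0.5 * np.sum(pa * pb))
    return p


def _align(cal_a: CalibratedDate, cal_b: CalibratedDate):
    if (cal_a.cal_bp.size == cal_b.cal_bp.size
            and np.allclose(cal_a.cal_bp, cal_b.cal_bp)):
        # ascending cal BP = later->earlier; order descending (earlier first)
        return cal_a.probability[::-1], cal_b.probability[::-1], cal_a.cal_bp[::-1]
    lo = min(cal_a.cal_bp.min(), cal_b.cal_bp.min())
    hi = max(cal_a.cal_bp.max(), cal_b.cal_bp.max())
    step_a = float(np.median(np.diff(cal_a.cal_bp)))
    step_b = float(np.median(np.diff(cal_b.cal_bp)))
    step = min(step_a, step_b)
    grid = np.arange(lo, hi + step / 2, step)

    def regrid(cal: CalibratedDate) -> np.ndarray:
        p = np.zeros(grid.size)
        idx = np.clip(np.round((cal.cal_bp - lo) / step).astype(int), 0, grid.size - 1)
        np.add.at(p, idx, cal.probability)
        return p

    return regrid(cal_a)[::-1], regrid(cal_b)[::-1], grid[::-1]
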