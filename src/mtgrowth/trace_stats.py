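"""Growth rate and growth-fluctuation estimation from tip-position traces.

The estimator separates the mean growth rate from fluctuations around it by
window downsampling.  A trace sampled at exposure ``t_exp`` is averaged over
non-overlapping blocks of ``n`` frames at each of the ``n - 1`` possible
phase offsets, frame-to-frame displacements are pooled across phases, and the
mean and variance of the pooled displacement distribution are recorded per
lag ``dt = n * t_exp``.  The mean displacement grows linearly with lag
(slope = growth rate), while the displacement variance is biphasic:

    ``var(dt) = 2 D dt + sigma_i^2 / dt^f``

with a diffusion-like growth variance ``D`` dominating at long lags and a
per-frame measurement-noise term ``sigma_i`` that averages out as roughly
``1/dt`` at short lags.  ``D`` is fitted on the linear regime (lags >= 10 s
by default) and ``sigma_i`` on the short-lag decay with ``f`` fixed at 1.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .params import STATIC_SEED_NOISE_OFFSET
from .sim import Trajectory

DEFAULT_T_EXP = 0.1      # s, 10 frames/s acquisition
MIN_EPISODE_S = 90.0     # inclusion rule for growth episodes


@dataclasses.dataclass
class TipTrace:
    """Time series of microtubule end position on a regular frame grid."""

    times: np.ndarray      # s
    lengths: np.ndarray    # nm
    concentration: Optional[float] = None   # uM, episode metadata
    source: Optional[str] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.size != self.lengths.size:
            raise ValueError("times and lengths differ in size")
        if self.times.size < 2:
            raise ValueError("trace needs at least two frames")
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("trace is not regularly sampled")

    @property
    def t_exp(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    @classmethod
    def from_trajectory(cls, traj: Trajectory,
                        concentration: Optional[float] = None) -> "TipTrace":
        conc = concentration
        if conc is None and traj.params is not None:
            conc = traj.params.tubulin_conc
        return cls(times=traj.times, lengths=traj.mean_length,
                   concentration=conc, source="simulation")

    def to_file(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "length_nm": self.lengths}).to_csv(
            path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_file(cls, path, concentration: Optional[float] = None) -> "TipTrace":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower(): c for c in df.columns}
        tcol = cols.get("time_s", df.columns[0])
        lcol = cols.get("length_nm", cols.get("mean_length_nm", df.columns[1]))
        return cls(times=df[tcol].to_numpy(), lengths=df[lcol].to_numpy(),
                   concentration=concentration, source=str(path))


@dataclasses.dataclass
class DisplacementStats:
    n: int            # downsampling window (frames)
    dt: float         # lag, n * t_exp (s)
    mean: float       # nm
    variance: float   # nm^2
    count: int        # pooled displacements


@dataclasses.dataclass
class FluctuationResult:
    growth_rate: float          # nm/s
    growth_variance: float      # D, nm^2/s
    sigma_i: float              # nm
    f: float = 1.0
    r_squared: float = np.nan   # of the linear-regime fit
    lag_range: tuple = (np.nan, np.nan)
    clipped: bool = False       # fitted D was negative and clipped to zero
    concentration: Optional[float] = None

    def variance_with_noise_offset(self,
                                   offset: float = STATIC_SEED_NOISE_OFFSET) -> float:
        """Growth variance plus the imaging noise floor, for comparison with
        experimental values."""
        return self.growth_variance + offset


def downsample_trace(trace: TipTrace, n: int) -> List[np.ndarray]:
    """The ``n - 1`` phase-offset block-mean traces for window ``n``.

    ``n = 1`` bypasses averaging and returns the raw trace.
    """
    x = trace.lengths
    if n == 1:
        return [x.copy()]
    if n < 1:
        raise ValueError("window must be >= 1")
    if x.size < 2 * n:
        raise ValueError("trace shorter than two windows")
    out = []
    for p in range(n - 1):
        k = (x.size - p) // n
        out.append(x[p:p + k * n].reshape(k, n).mean(axis=1))
    return out


def _pooled_moments(x: np.ndarray, n: int):
    """Pooled mean/variance/count of phase-block-mean displacements, O(N)."""
    N = x.size
    if n == 1:
        d = np.diff(x)
    else:
        S = np.concatenate(([0.0], np.cumsum(x)))
        K = (N - (n - 2)) // n          # blocks valid for every phase
        if K < 2:
            return np.nan, np.nan, 0
        p = np.arange(n - 1)[:, None]
        i = p + n * np.arange(K)[None, :]
        B = (S[i + n] - S[i]) / n       # (n-1, K) block means
        d = np.diff(B, axis=1).ravel()
    if d.size < 2:
        return np.nan, np.nan, 0
    return float(d.mean()), float(d.var(ddof=1)), int(d.size)


def displacement_stats(trace: TipTrace, n: int) -> DisplacementStats:
    """Mean and variance of the pooled displacement distribution at window n.

    The normal fit to the displacement histogram is taken as the sample mean
    and variance (the maximum-likelihood normal parameters); the ``n - 1``
    phase traces are pooled into one distribution.
    """
    mean, var, count = _pooled_moments(trace.lengths, n)
    if count < 10:
        raise ValueError(f"fewer than 10 pooled displacements at window n={n}")
    return DisplacementStats(n=n, dt=n * trace.t_exp, mean=mean,
                             variance=var, count=count)


def fluctuation_curve(trace: TipTrace, n_values: Optional[Sequence[int]] = None,
                      min_count: int = 10) -> pd.DataFrame:
    """Displacement mean/variance vs lag for windows ``n`` (default 2..300)."""
    if n_values is None:
        n_values = range(2, 301)
    rows = []
    for n in n_values:
        if trace.lengths.size < 2 * n:
            break
        mean, var, count = _pooled_moments(trace.lengths, n)
        if count < min_count:
            continue
        rows.append((n, n * trace.t_exp, mean, var, count))
    if not rows:
        raise ValueError("no usable lags for this trace")
    return pd.DataFrame(rows, columns=["n", "dt", "mean", "variance", "count"])


def fit_growth_rate(curve: pd.DataFrame) -> float:
    """Growth rate (nm/s): slope of mean displacement vs lag through the origin."""
    if len(curve) < 5:
        raise ValueError("need at least 5 lags to fit a growth rate")
    dt = curve["dt"].to_numpy()
    mu = curve["mean"].to_numpy()
    if np.ptp(dt) == 0:
        raise ValueError("degenerate lag range")
    return float(np.sum(mu * dt) / np.sum(dt * dt))


def fit_growth_variance(curve: pd.DataFrame, min_lag: float = 10.0,
                        noise_max_lag: float = 2.0, f: float = 1.0
                        ) -> FluctuationResult:
    """Biphasic fit of displacement variance vs lag.

    ``D`` is half the slope of a straight line fitted to the variance at lags
    >= ``min_lag`` (where measurement noise has averaged out); the noise
    amplitude ``A`` of the residual short-lag decay ``A / dt^f`` is fitted at
    lags <= ``noise_max_lag`` and reported as the per-frame noise SD
    ``sigma_i = sqrt(A / (2 t_exp^f))`` (for iid frame noise of SD s the
    raw-lag displacement variance is ``2 s^2 = A / t_exp^f``).  A negative
    fitted D is clipped to zero and flagged.
    """
    dt = curve["dt"].to_numpy()
    t_exp = float(dt[0] / curve["n"].to_numpy()[0])
    var = curve["variance"].to_numpy()
    lin = dt >= min_lag
    if lin.sum() < 3:
        raise ValueError("fewer than 3 lags in the linear regime")
    slope, icept = np.polyfit(dt[lin], var[lin], 1)
    pred = slope * dt[lin] + icept
    ss_res = np.sum((var[lin] - pred) ** 2)
    ss_tot = np.sum((var[lin] - var[lin].mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    D = slope / 2.0
    clipped = D < 0
    if clipped:
        D = 0.0
    short = dt <= noise_max_lag
    if short.any():
        g = dt[short] ** (-f)
        resid = var[short] - 2.0 * D * dt[short]
        amp = float(np.sum(resid * g) / np.sum(g * g))   # A in var = A / dt^f
        sigma_i = float(np.sqrt(max(amp, 0.0) / (2.0 * t_exp ** f)))
    else:
        sigma_i = np.nan
    return FluctuationResult(growth_rate=np.nan, growth_variance=float(D),
                             sigma_i=sigma_i, f=f, r_squared=float(r2),
                             lag_range=(float(dt.min()), float(dt.max())),
                             clipped=clipped)


def analyze_trace(trace: TipTrace, n_values: Optional[Sequence[int]] = None,
                  min_duration: float = MIN_EPISODE_S, min_lag: float = 10.0,
                  noise_max_lag: float = 2.0, f: float = 1.0
                  ) -> FluctuationResult:
    """Full per-episode analysis: downsample, pool displacements, fit both
    the growth rate and the biphasic variance curve."""
    if trace.duration < min_duration:
        raise ValueError(f"episode shorter than {min_duration} s")
    curve = fluctuation_curve(trace, n_values)
    res = fit_growth_variance(curve, min_lag=min_lag,
                              noise_max_lag=noise_max_lag, f=f)
    res.growth_rate = fit_growth_rate(curve)
    res.concentration = trace.concentration
    return res


def analyze_batch(traces: Iterable[TipTrace], **kwargs) -> pd.DataFrame:
    """Per-episode results as a table; episodes failing the inclusion rule
    are skipped."""
    rows = []
    for i, tr in enumerate(traces):
        try:
            r = analyze_trace(tr, **kwargs)
        except ValueError:
            continue
        rows.append({"episode": i, "concentration": r.concentration,
                     "growth_rate": r.growth_rate,
                     "growth_variance": r.growth_variance,
                     "sigma_i": r.sigma_i, "r_squared": r.r_squared,
                     "clipped": r.clipped})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class SeriesFit:
    slope: float            # per-uM slope
    x_intercept: float      # uM
    y_intercept: float
    weighted: bool          # False when a zero SEM forced the unweighted fallback
    summary: pd.DataFrame   # per-concentration mean/SD/SEM/n
    slope_se: float = np.nan
    x_intercept_se: float = np.nan


def summarize_by_concentration(table: pd.DataFrame,
                               value: str = "growth_rate") -> pd.DataFrame:
    g = table.groupby("concentration")[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out


def concentration_series_fit(table: pd.DataFrame, value: str = "growth_rate"
                             ) -> SeriesFit:
    """Weighted linear fit of per-concentration means vs concentration.

    Weights are 1/SEM (the convention used for the experimental series
    fits), i.e. residuals are divided by sqrt(SEM).  Falls back to an
    unweighted fit when any SEM is zero or undefined.
    """
    s = summarize_by_concentration(table, value=value)
    if len(s) < 3:
        raise ValueError("need at least 3 concentrations")
    x = s["concentration"].to_numpy(dtype=float)
    y = s["mean"].to_numpy(dtype=float)
    sem = s["sem"].to_numpy(dtype=float)
    weighted = bool(np.all(np.isfinite(sem)) and np.all(sem > 0))
    w = 1.0 / sem if weighted else np.ones_like(y)
    # minimize sum w * (y - a - b x)^2
    sw = np.sqrt(w)
    A = np.stack([np.ones_like(x), x], axis=1) * sw[:, None]
    coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
    a, b = coef
    # parameter covariance from the weighted residual scatter
    dof = max(len(x) - 2, 1)
    resid = y * sw - A @ coef
    s2 = float(resid @ resid) / dof
    cov = np.linalg.inv(A.T @ A) * s2
    slope_se = float(np.sqrt(cov[1, 1]))
    xi = -a / b
    var_xi = (xi ** 2) * (cov[0, 0] / a**2 + cov[1, 1] / b**2
                          - 2 * cov[0, 1] / (a * b))
    return SeriesFit(slope=float(b), x_intercept=float(xi),
                     y_intercept=float(a), weighted=weighted, summary=s,
                     slope_se=slope_se,
                     x_intercept_se=float(np.sqrt(max(var_xi, 0.0))))
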