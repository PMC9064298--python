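"""Synthetic tip-position traces with known growth statistics.

Generates the statistical structure of experimental recordings — steady
drift at velocity ``v``, Brownian growth fluctuations with diffusion-like
variance ``D`` (increment variance ``2 D dt``), iid per-frame measurement
noise of SD ``sigma_i``, and optional rigid stage drift — so that every
stage of the analysis pipeline can be exercised against known ground truth.
Measurement noise is iid per frame; its pooled displacement variance then
decays as 1/lag under block averaging, exactly the short-lag phase of the
biphasic variance fit.
"""
from __future__ import annotations

import dataclasses
import pathlib
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .trace_stats import TipTrace

_SEED_MOD = 2**31 - 1


@dataclasses.dataclass
class DriftModel:
    """Rigid stage drift: linear component plus one sinusoid (nm)."""
    linear_nm_per_s: float = 0.0
    amplitude_nm: float = 0.0
    period_s: float = 60.0
    phase: float = 0.0

    def path(self, times: np.ndarray) -> np.ndarray:
        out = self.linear_nm_per_s * times
        if self.amplitude_nm:
            out = out + self.amplitude_nm * np.sin(
                2 * np.pi * times / self.period_s + self.phase)
        return out


@dataclasses.dataclass
class TraceGenSpec:
    """Parameters of one synthetic growth episode."""
    v: float = 5.0              # nm/s growth velocity
    D: float = 10.0             # nm^2/s growth variance (Brownian)
    sigma_i: float = 3.5        # nm per-frame measurement noise SD
    frame_rate: float = 10.0    # frames/s
    duration: float = 900.0     # s
    seed: int = 0
    drift: Optional[DriftModel] = None

    def __post_init__(self) -> None:
        if self.v < 0 or self.D < 0 or self.sigma_i < 0:
            raise ValueError("v, D and sigma_i must be non-negative")
        if self.duration < 90.0:
            raise ValueError("episodes shorter than 90 s are not analyzable")


def gen_trace(spec: TraceGenSpec, concentration: Optional[float] = None
              ) -> TipTrace:
    """One synthetic episode: ``L(t) = v t + W(t) + eps`` with ``Var W = 2 D t``."""
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.frame_rate
    n = int(round(spec.duration * spec.frame_rate)) + 1
    t = np.arange(n) * dt
    w = np.zeros(n)
    if spec.D > 0:
        w[1:] = np.cumsum(rng.normal(0.0, np.sqrt(2.0 * spec.D * dt), n - 1))
    eps = rng.normal(0.0, spec.sigma_i, n) if spec.sigma_i > 0 else 0.0
    L = spec.v * t + w + eps
    if spec.drift is not None:
        L = L + spec.drift.path(t)
    return TipTrace(times=t, lengths=L, concentration=concentration,
                    source="synthetic")


@dataclasses.dataclass
class FiduciaryTrack:
    """Per-frame positions of stationary fiduciary marks and their average."""
    times: np.ndarray
    marks: np.ndarray        # (n_marks, n_frames) positions (nm, one axis)
    average: np.ndarray      # (n_frames,) mean across marks


def gen_fiduciaries(drift: DriftModel, n_frames: int, frame_rate: float = 10.0,
                    n_marks: int = 10, noise_sd: float = 5.0,
                    seed: int = 0) -> FiduciaryTrack:
    """Noisy copies of a common stage-drift path, plus their average.

    Averaging ``n`` marks with iid tracking noise SD ``s`` leaves the common
    drift untouched and shrinks the noise to ``s / sqrt(n)``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    base = drift.path(t)
    marks = base[None, :] + rng.normal(0.0, noise_sd, (n_marks, n_frames))
    if noise_sd == 0:
        marks = np.broadcast_to(base, (n_marks, n_frames)).copy()
    return FiduciaryTrack(times=t, marks=marks, average=marks.mean(axis=0))


def linear_law(slope: float, intercept_x: float = 0.0) -> Callable[[float], float]:
    """Rate/variance law ``f(c) = slope * (c - intercept_x)``."""
    return lambda c: slope * (c - intercept_x)


def affine_law(a: float, b: float) -> Callable[[float], float]:
    """Law ``f(c) = a * c + b``."""
    return lambda c: a * c + b


def gen_bundle(concentrations: Sequence[float],
               rate_law: Callable[[float], float],
               variance_law: Callable[[float], float],
               episodes_per_point: int = 50,
               sigma_i: float = 3.5,
               duration: float = 900.0,
               frame_rate: float = 10.0,
               seed: int = 0,
               out_dir=None) -> Tuple[pd.DataFrame, List[TipTrace]]:
    """A complete synthetic concentration-series 'experiment'.

    Returns a manifest (concentration, episode, seed, true v/D/sigma_i) and
    the traces; optionally writes trace tables plus ``manifest.tsv`` to
    ``out_dir`` for the end-to-end file pipeline.
    """
    rows = []
    traces = []
    k = 0
    for c in concentrations:
        v = rate_law(c)
        D = variance_law(c)
        if v < 0 or D < 0:
            raise ValueError(f"law produced a negative value at {c} uM")
        for e in range(episodes_per_point):
            ep_seed = (seed + 1000 * k) % _SEED_MOD
            spec = TraceGenSpec(v=v, D=D, sigma_i=sigma_i,
                                frame_rate=frame_rate, duration=duration,
                                seed=ep_seed)
            traces.append(gen_trace(spec, concentration=c))
            rows.append({"concentration": c, "episode": e, "seed": ep_seed,
                         "true_v": v, "true_D": D, "true_sigma_i": sigma_i,
                         "file": f"trace_{k:04d}.tsv"})
            k += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for row, tr in zip(rows, traces):
            tr.to_file(out / row["file"])
        manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest, traces
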