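"""High-level simulation drivers: sampled trajectories and shrinkage rates."""
from __future__ import annotations

import dataclasses
import math
from typing import List, Optional

import numpy as np
import pandas as pd

from . import kernel
from .lattice import FrozenSystemError, init_state
from .params import ModelParams

_SEED_MOD = 2**31 - 1


@dataclasses.dataclass
class Trajectory:
    """Regularly sampled output of one kinetic Monte Carlo run.

    ``mean_length`` is the mean polymer length above the seed
    (total non-seed dimers / n_pf * dimer_length, nm); ``terminal_gdp`` is
    the number of protofilaments whose exposed terminal interface is GDP.
    """

    times: np.ndarray            # s
    mean_length: np.ndarray      # nm
    terminal_gdp: np.ndarray     # count per sample
    per_pf: Optional[np.ndarray] = None   # (n_samples, n_pf) dimers incl. seed
    params: Optional[ModelParams] = None
    seed: Optional[int] = None
    stripped: bool = False       # lattice reached the bare seed during the run

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times,
                             "mean_length_nm": self.mean_length,
                             "terminal_gdp_count": self.terminal_gdp})

    def to_file(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _capacity_guess(params: ModelParams, t_total: float, base: int) -> int:
    kon_max = params.k_on * (params.kon_ratio_long_corner
                             if params.site_dependent_kon else 1.0)
    return base + int(kon_max * params.tubulin_conc * t_total * 1.25) + 64


def simulate(params: ModelParams, t_total: float = 600.0, sample_dt: float = 0.1,
             seed: int = 0, seed_layers: int = 10, record_pf: bool = False,
             all_gdp: bool = False, extra_layers: int = 0) -> Trajectory:
    """Run one kinetic Monte Carlo growth episode.

    The trajectory is sampled on a regular grid (default 0.1 s, matching
    10 frames/s acquisition) and is reproducible for a fixed ``seed``.
    ``all_gdp``/``extra_layers`` set up an all-GDP lattice above the seed for
    depolymerization runs.
    """
    if t_total <= 0 or sample_dt <= 0:
        raise ValueError("t_total and sample_dt must be positive")
    n_samples = int(round(t_total / sample_dt)) + 1
    cap = _capacity_guess(params, t_total, seed_layers + extra_layers)
    for _attempt in range(8):
        state = init_state(params, seed_layers, capacity=cap,
                           all_gdp=all_gdp, extra_layers=extra_layers)
        out_sub = np.zeros(n_samples, dtype=np.int64)
        out_gdp = np.zeros(n_samples, dtype=np.int64)
        out_pf = (np.zeros((n_samples, params.n_pf), dtype=np.int64)
                  if record_pf else np.zeros((1, params.n_pf), dtype=np.int64))
        status = kernel.kmc_sample(
            state.heights, state.nuc, state.seed_len, sample_dt, n_samples,
            params.tubulin_conc, params.k_on, params.K_D_long,
            params.lateral_ratio, params.gdp_factor_X, params.k_GTPase,
            params.site_dependent_kon, params.kon_ratio_long_corner,
            params.kon_ratio_corner_bucket, params.seam_offset,
            int(seed) % _SEED_MOD,
            out_sub, out_gdp, out_pf, record_pf)
        if status == kernel.OK:
            break
        cap *= 2
    else:
        raise RuntimeError("lattice capacity overflow not resolved")
    if params.tubulin_conc == 0 and params.k_GTPase == 0 and extra_layers == 0:
        raise FrozenSystemError("bare immutable seed at zero tubulin cannot react")
    times = np.arange(n_samples) * sample_dt
    mean_len = out_sub / params.n_pf * params.dimer_length
    return Trajectory(times=times, mean_length=mean_len, terminal_gdp=out_gdp,
                      per_pf=out_pf if record_pf else None, params=params,
                      seed=seed, stripped=bool(out_sub.min() == 0 and extra_layers > 0))


def simulate_batch(params: ModelParams, n_replicates: int, t_total: float = 600.0,
                   sample_dt: float = 0.1, base_seed: int = 0,
                   **kwargs) -> List[Trajectory]:
    """Independent replicate episodes; replicate ``r`` uses seed ``base+r``."""
    return [simulate(params, t_total=t_total, sample_dt=sample_dt,
                     seed=(base_seed + r) % _SEED_MOD, **kwargs)
            for r in range(n_replicates)]


@dataclasses.dataclass
class ShrinkResult:
    rate: float          # nm/s length loss (positive)
    span_s: float        # time span the rate was fitted over
    stripped: bool       # lattice fully depolymerized to the seed
    short_episode: bool  # fitted span shorter than requested minimum


def shrink_rate(params: ModelParams, seed: int = 0, initial_layers: int = 400,
                t_total: float = 30.0, sample_dt: float = 0.01,
                min_span: float = 0.5) -> ShrinkResult:
    """Mean depolymerization speed of an all-GDP lattice (nm/s).

    Starts from ``initial_layers`` GDP dimers per protofilament above the
    seed at zero free tubulin and fits a line to mean length vs time over
    the episode (truncated where the lattice approaches the bare seed).
    """
    p0 = params.replace(tubulin_conc=0.0, k_GTPase=0.0)
    traj = simulate(p0, t_total=t_total, sample_dt=sample_dt, seed=seed,
                    all_gdp=True, extra_layers=initial_layers)
    L = traj.mean_length
    L0 = L[0]
    # fit only while some polymer remains (avoid the flat stripped tail)
    alive = np.nonzero(L > 0.02 * L0)[0]
    stop = int(alive[-1]) + 1 if alive.size else 2
    stop = max(stop, 2)
    t, y = traj.times[:stop], L[:stop]
    slope = np.polyfit(t, y, 1)[0]
    span = float(t[-1] - t[0])
    return ShrinkResult(rate=max(-slope, 0.0), span_s=span,
                        stripped=bool(L[-1] <= 0.02 * L0),
                        short_episode=span < min_span)
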