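"""Model convolution: synthetic microscope images of microtubule ends.

Renders interference-reflection-like images of microtubules with defined
protofilament-length tapers.  Each tubulin dimer is placed at its lattice
position (13 protofilaments on a 25-nm-radius cylinder, 8.2-nm dimer rise,
3-start-helix stagger), projected to the image plane, blurred with the
measured Gaussian point-spread function, scaled so a fully formed backbone
cross-section has the calibrated contrast, and superimposed on the
back-reflection background with additive Gaussian noise matched to the
measured background SD.  The microtubule appears dark on a bright
background, as in the raw recordings; the experimental post-processing
(invert, convert to 8-bit) is available as a utility.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import tip_tracking
from .params import DIMER_LENGTH_NM, N_PF

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))   # 1/2.355


@dataclasses.dataclass
class OpticsSpec:
    """Optical and noise calibration of the imaging system."""
    image_px: int = 1024
    pixel_nm: float = 58.0            # 59.4 um over 1024 px
    psf_fwhm_nm: float = 250.0
    signal_amplitude: float = 1160.0  # peak backbone contrast, 16-bit units
    background: float = 22300.0       # back-reflection level, 16-bit units
    noise_sd: float = 181.0           # background SD, 16-bit units
    full_scale: int = 65535

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm <= self.pixel_nm:
            raise ValueError("PSF FWHM must exceed the pixel size")
        if min(self.signal_amplitude, self.background, self.noise_sd) <= 0:
            raise ValueError("intensity calibration values must be positive")

    @property
    def psf_sigma_nm(self) -> float:
        return self.psf_fwhm_nm * FWHM_TO_SIGMA

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_nm

    @property
    def contrast(self) -> float:
        """Fractional backbone contrast (5.2% at the printed calibration)."""
        return self.signal_amplitude / self.background


@dataclasses.dataclass
class MicrotubuleSpec:
    """Geometry of one rendered microtubule."""
    pf_lengths_nm: np.ndarray          # (13,) length of each protofilament
    position_nm: Tuple[float, float] = (0.0, 0.0)   # minus end, image plane
    angle: float = 0.0                 # rad, in-plane
    radius_nm: float = 25.0
    dimer_nm: float = DIMER_LENGTH_NM

    @classmethod
    def from_taper(cls, mean_length_nm: float = 6500.0, taper_nm: float = 0.0,
                   **kwargs) -> "MicrotubuleSpec":
        return cls(pf_lengths_nm=make_taper(taper_nm, mean_length_nm), **kwargs)

    @property
    def taper_nm(self) -> float:
        return float(self.pf_lengths_nm.max() - self.pf_lengths_nm.min())

    @property
    def tip_nm(self) -> float:
        """Mean protofilament end position along the axis (the tracked tip)."""
        return float(self.pf_lengths_nm.mean())


def make_taper(taper_nm: float, mean_length_nm: float = 6500.0,
               n_pf: int = N_PF, dimer_nm: float = DIMER_LENGTH_NM
               ) -> np.ndarray:
    """Protofilament lengths with a linear end taper (nm).

    Lengths increase stepwise and linearly from the 1st and 13th
    protofilament toward the center one, which is the unique maximum;
    max - min equals ``taper_nm`` rounded to whole dimers.
    """
    if taper_nm < 0:
        raise ValueError("taper must be non-negative")
    center = (n_pf - 1) // 2
    frac = 1.0 - np.abs(np.arange(n_pf) - center) / center
    taper_dimers = round(taper_nm / dimer_nm)
    offsets = np.round(frac * taper_dimers)
    base = round(mean_length_nm / dimer_nm) - offsets.mean()
    lengths = (np.floor(base) + offsets) * dimer_nm
    return lengths


def _subunit_xy(mt: MicrotubuleSpec) -> np.ndarray:
    """Image-plane (x, y) positions (nm) of every dimer in the lattice."""
    n_pf = mt.pf_lengths_nm.size
    rise = 1.5 * mt.dimer_nm / n_pf          # 3-start helix rise per protofilament
    xs, ys = [], []
    for p in range(n_pf):
        n_dimers = int(round(mt.pf_lengths_nm[p] / mt.dimer_nm))
        ax = np.arange(n_dimers) * mt.dimer_nm + p * rise
        lat = mt.radius_nm * np.sin(2.0 * np.pi * p / n_pf)
        xs.append(ax)
        ys.append(np.full(n_dimers, lat))
    ax = np.concatenate(xs)
    lat = np.concatenate(ys)
    ca, sa = np.cos(mt.angle), np.sin(mt.angle)
    x = mt.position_nm[0] + ca * ax - sa * lat
    y = mt.position_nm[1] + sa * ax + ca * lat
    return np.stack([x, y], axis=1)


def _deposit(points_px: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    """Bilinear deposition of unit weights onto the pixel grid."""
    img = np.zeros(shape)
    x = points_px[:, 0]
    y = points_px[:, 1]
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    for dy, dx, w in ((0, 0, (1 - fx) * (1 - fy)), (0, 1, fx * (1 - fy)),
                      (1, 0, (1 - fx) * fy), (1, 1, fx * fy)):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < shape[0]) & (xx >= 0) & (xx < shape[1])
        np.add.at(img, (yy[ok], xx[ok]), w[ok])
    return img


def subunit_amplitude(optics: OpticsSpec) -> float:
    """Per-dimer intensity budget (16-bit units summed over pixels).

    Back-computed so the blurred cross-section of a long, fully formed
    backbone peaks at ``signal_amplitude`` above background.
    """
    # long blunt microtubule rendered at unit budget, away from edges
    mt = MicrotubuleSpec.from_taper(mean_length_nm=4000.0, taper_nm=0.0,
                                    position_nm=(500.0, 64 * optics.pixel_nm))
    pts = _subunit_xy(mt) / optics.pixel_nm
    img = _deposit(pts, (128, 128))
    img = gaussian_filter(img, optics.psf_sigma_px, mode="constant")
    mid = img[:, 30:50]
    return float(optics.signal_amplitude / mid.max())


def render_frame(mt: MicrotubuleSpec, optics: OpticsSpec,
                 seed: Optional[int] = 0, noiseless: bool = False,
                 image_px: Optional[int] = None,
                 _amp: Optional[float] = None) -> np.ndarray:
    """Render one 16-bit frame (dark microtubule on bright background)."""
    n = image_px or optics.image_px
    shape = (n, n)
    pts = _subunit_xy(mt)
    # the minus end routinely extends past the left edge; warn only when the
    # plus end or the lattice leaves the frame on the tracked side
    if pts.size and (pts[:, 0].max() / optics.pixel_nm > n
                     or pts[:, 1].max() / optics.pixel_nm > n
                     or pts[:, 1].min() < 0):
        import warnings
        warnings.warn("microtubule extends beyond the frame; clipping")
    img = _deposit(pts / optics.pixel_nm, shape)
    img = gaussian_filter(img, optics.psf_sigma_px, mode="constant")
    amp = subunit_amplitude(optics) if _amp is None else _amp
    signal = amp * img
    out = optics.background - signal
    if not noiseless:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, optics.noise_sd, shape)
    return np.clip(np.round(out), 0, optics.full_scale).astype(np.uint16)


def render_movie(pf_lengths_nm: np.ndarray, optics: OpticsSpec,
                 position_nm: Tuple[float, float] = (580.0, 0.0),
                 angle: float = 0.0, seed: int = 0,
                 image_px: Optional[int] = None
                 ) -> Tuple[np.ndarray, pd.DataFrame]:
    """Render one frame per row of ``pf_lengths_nm`` ((n_frames, 13), nm).

    Returns the 16-bit stack and a ground-truth sidecar table (frame, true
    mean-tip position and taper).  Deterministic for a fixed seed.
    """
    pf = np.atleast_2d(np.asarray(pf_lengths_nm, dtype=float))
    n = image_px or optics.image_px
    amp = subunit_amplitude(optics)
    stack = np.empty((pf.shape[0], n, n), dtype=np.uint16)
    rows = []
    for i in range(pf.shape[0]):
        mt = MicrotubuleSpec(pf_lengths_nm=pf[i], position_nm=position_nm,
                             angle=angle)
        stack[i] = render_frame(mt, optics, seed=seed + i, image_px=n, _amp=amp)
        rows.append({"frame": i,
                     "true_tip_nm": position_nm[0] + mt.tip_nm * np.cos(angle),
                     "true_taper_nm": mt.taper_nm})
    return stack, pd.DataFrame(rows)


def invert_to_8bit(stack: np.ndarray) -> np.ndarray:
    """Experimental post-processing: invert and min-max scale to 8 bits.

    Makes the microtubule bright on a dark background, as the tracker
    expects; scaling is per stack.
    """
    inv = stack.max() - stack.astype(float)
    lo, hi = inv.min(), inv.max()
    if hi <= lo:
        return np.zeros_like(stack, dtype=np.uint8)
    return np.round((inv - lo) / (hi - lo) * 255).astype(np.uint8)


def write_stack(path, stack: np.ndarray) -> None:
    import tifffile
    tifffile.imwrite(path, stack)


def read_stack(path) -> np.ndarray:
    import tifffile
    return tifffile.imread(path)


@dataclasses.dataclass
class TaperCalibration:
    tapers: np.ndarray        # nm, grid (includes 0)
    mean_sigma: np.ndarray    # nm, mean fitted sigma_MT per taper
    sd_sigma: np.ndarray      # nm
    threshold_nm: float       # minimal distinguishable taper
    monotone: bool
    n_replicates: int


def calibrate_taper(optics: OpticsSpec, tapers: Sequence[float],
                    replicates: int = 30, seed: int = 0,
                    image_px: int = 256, mt_length_nm: float = 6500.0,
                    ) -> TaperCalibration:
    """Map fitted tip spread ``sigma_MT`` to true taper length.

    Renders ``replicates`` noisy images per taper (random sub-pixel
    placement), runs the full backbone + erfc tip fit on the post-processed
    (inverted 8-bit) images, and reports the mean and SD of ``sigma_MT`` per
    taper.  The detection threshold is where the mean curve crosses the
    blunt-end mean + 2 blunt SD (linearly interpolated between grid points).
    """
    tapers = np.asarray(sorted(tapers), dtype=float)
    if tapers[0] != 0:
        raise ValueError("the taper grid must include 0 (blunt reference)")
    rng = np.random.default_rng(seed)
    amp = subunit_amplitude(optics)
    # plus end placed ~56 px from the right edge: a long backbone plateau on
    # the left, ample room for the intensity falloff on the right
    tip_target = (image_px - 56) * optics.pixel_nm
    means, sds = [], []
    for taper in tapers:
        sig = []
        for r in range(replicates):
            jitter = rng.uniform(0, optics.pixel_nm, 2)
            y0 = image_px // 2 * optics.pixel_nm + jitter[1]
            mt = MicrotubuleSpec.from_taper(mean_length_nm=mt_length_nm,
                                            taper_nm=taper, position_nm=(0, y0))
            x0 = tip_target - mt.tip_nm + jitter[0]
            mt.position_nm = (x0, y0)
            frame = render_frame(mt, optics, seed=int(rng.integers(2**31)),
                                 image_px=image_px, _amp=amp)
            img8 = invert_to_8bit(frame[None])[0]
            tip_px = (x0 + mt.tip_nm) / optics.pixel_nm
            bb_px = max(tip_px - 80, x0 / optics.pixel_nm + 5, 2)
            try:
                bb = tip_tracking.fit_backbone(
                    img8, (bb_px, y0 / optics.pixel_nm),
                    (tip_px, y0 / optics.pixel_nm),
                    pixel_nm=optics.pixel_nm, pad_past_tip=40,
                    column_stride=3)
                tf = tip_tracking.fit_tip(bb.x_arc, bb.profile, backbone=bb,
                                          pixel_nm=optics.pixel_nm)
            except tip_tracking.TrackingError:
                continue
            sig.append(tf.sigma)
        if len(sig) < max(3, replicates // 2):
            raise RuntimeError(f"too many failed fits at taper {taper} nm")
        means.append(np.mean(sig))
        sds.append(np.std(sig, ddof=1))
    means = np.asarray(means)
    sds = np.asarray(sds)
    monotone = bool(np.all(np.diff(means) > -sds[:-1]))
    crit = means[0] + 2.0 * sds[0]
    above = np.nonzero(means > crit)[0]
    if above.size == 0:
        threshold = float("inf")
    else:
        j = int(above[0])
        if j == 0:
            threshold = 0.0
        else:
            f = (crit - means[j - 1]) / (means[j] - means[j - 1])
            threshold = float(tapers[j - 1] + f * (tapers[j] - tapers[j - 1]))
    return TaperCalibration(tapers=tapers, mean_sigma=means, sd_sigma=sds,
                            threshold_nm=threshold, monotone=monotone,
                            n_replicates=replicates)
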