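"""Sub-pixel microtubule tip localization and drift correction.

Per frame, the microtubule backbone is located by fitting a Gaussian to the
intensity cross-section of every image column inside a region of interest
(centered on the line fitted in the previous frame), a straight line through
the per-column centers defines the backbone axis, and the intensity profile
along that axis — each sample the average of the five pixels nearest the
backbone in y — is fitted with a Gaussian survival function

    ``I(x) = 0.5 * I_MT * erfc((x - mu_MT) / (sqrt(2) sigma_MT)) + I_bg``

whose midpoint ``mu_MT`` is the sub-pixel tip position and whose spread
``sigma_MT`` reflects the point-spread function broadened by any
protofilament-length taper at the end.  Sub-pixel stage drift measured from
averaged fiduciary-mark tracks is removed from the tip-to-backbone length:

    ``dLx = mu_x - B_x - Fid_x``
    ``dLy = mu_y - B_y - sin(theta) * Fid_x``
    ``dL  = sqrt(dLx^2 + dLy^2)``

(the backbone y is re-fitted every frame, so only the x drift needs the
fiduciary; the angle term propagates x drift into the backbone's y).
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erfc

from .trace_stats import TipTrace

PIXEL_NM = 58.0          # image pixel size


class TrackingError(RuntimeError):
    pass


def _gauss(y, bg, amp, mu, sigma):
    return bg + amp * np.exp(-((y - mu) ** 2) / (2.0 * sigma ** 2))


def _erfc_profile(x, bg, amp, mu, sigma):
    return bg + 0.5 * amp * erfc((x - mu) / (np.sqrt(2.0) * sigma))


@dataclasses.dataclass
class BackboneModel:
    columns: np.ndarray        # px, columns with a valid Gaussian fit
    y_centers: np.ndarray      # px, sub-pixel backbone center per column
    amplitudes: np.ndarray
    sigmas: np.ndarray         # px
    background: float
    line: Tuple[float, float]  # y = a + b * x (px)
    theta: float               # rad, backbone angle to the x axis
    x_arc: np.ndarray          # nm, 1-D arclength coordinate of profile samples
    profile: np.ndarray        # averaged 5-pixel intensity along the backbone
    origin_px: Tuple[float, float]  # arclength origin in image coordinates

    def arc_to_xy(self, arc_nm: float, pixel_nm: float = PIXEL_NM
                  ) -> Tuple[float, float]:
        """Map an arclength position (nm) back to image-plane nm coordinates."""
        x0, y0 = self.origin_px
        x = x0 * pixel_nm + arc_nm * np.cos(self.theta)
        y = y0 * pixel_nm + arc_nm * np.sin(self.theta)
        return x, y


@dataclasses.dataclass
class TipFit:
    mu_arc: float        # nm along the backbone axis
    sigma: float         # nm, spread of the survival function
    amplitude: float
    background: float
    xy_nm: Tuple[float, float]   # image-plane position


def fit_backbone(frame: np.ndarray, seed_backbone: Sequence[float],
                 seed_tip: Sequence[float], pixel_nm: float = PIXEL_NM,
                 half_width: int = 5, pad_past_tip: int = 15,
                 min_columns: int = 5, column_stride: int = 1) -> BackboneModel:
    """Locate the backbone of a near-horizontal microtubule.

    ``seed_backbone`` and ``seed_tip`` are (x, y) pixel positions, one on the
    lattice and one near the growing end; the region of interest spans the
    columns between them (extended ``pad_past_tip`` columns beyond the tip so
    the intensity falloff is covered) with a +-``half_width`` pixel window
    around the expected backbone row.
    """
    frame = np.asarray(frame, dtype=float)
    x0, y0 = float(seed_backbone[0]), float(seed_backbone[1])
    x1, y1 = float(seed_tip[0]), float(seed_tip[1])
    if x1 < x0:
        raise TrackingError("tip seed must lie at larger x than the backbone seed")
    c_lo = max(int(round(x0)), 0)
    c_hi = min(int(round(x1)) + pad_past_tip, frame.shape[1] - 1)
    cols = np.arange(c_lo, c_hi + 1)
    slope0 = (y1 - y0) / max(x1 - x0, 1.0)

    ys, amps, sigmas, ok_cols, bgs = [], [], [], [], []
    for c in cols[::max(column_stride, 1)]:
        yc = y0 + slope0 * (c - x0)
        r_lo = max(int(round(yc)) - half_width, 0)
        r_hi = min(int(round(yc)) + half_width, frame.shape[0] - 1)
        win = frame[r_lo:r_hi + 1, c]
        rows = np.arange(r_lo, r_hi + 1, dtype=float)
        bg0 = float(win.min())
        amp0 = float(win.max() - win.min())
        mu0 = float(rows[np.argmax(win)])
        try:
            popt, _ = curve_fit(_gauss, rows, win,
                                p0=(bg0, amp0, mu0, 2.0),
                                bounds=([-np.inf, 0.0, r_lo - 1, 0.4],
                                        [np.inf, np.inf, r_hi + 1, 10.0]),
                                maxfev=400)
        except (RuntimeError, ValueError):
            continue
        bgs.append(popt[0]); amps.append(popt[1]); ys.append(popt[2])
        sigmas.append(popt[3]); ok_cols.append(c)
    if len(ok_cols) < min_columns:
        raise TrackingError("fewer than %d valid backbone columns" % min_columns)
    ok_cols = np.asarray(ok_cols); ys = np.asarray(ys)
    amps = np.asarray(amps); sigmas = np.asarray(sigmas)

    # restrict the line fit to columns clearly on the lattice (not past the tip)
    ref_amp = np.median(amps[: max(len(amps) // 2, 1)])
    on_mt = amps > 0.3 * ref_amp
    if on_mt.sum() < min_columns:
        raise TrackingError("too few on-lattice columns for the line fit")
    b, a = np.polyfit(ok_cols[on_mt], ys[on_mt], 1)   # slope, intercept
    theta = float(np.arctan(b))

    # intensity profile along the backbone: average of the 5 nearest pixels in y
    prof = np.empty(cols.size)
    for k, c in enumerate(cols):
        yc = a + b * c
        r = int(round(yc))
        r_lo = max(r - 2, 0)
        r_hi = min(r + 2, frame.shape[0] - 1)
        prof[k] = frame[r_lo:r_hi + 1, c].mean()
    x_arc = (cols - x0) * pixel_nm / max(np.cos(theta), 1e-6)

    return BackboneModel(columns=ok_cols, y_centers=ys, amplitudes=amps,
                         sigmas=sigmas, background=float(np.median(bgs)),
                         line=(float(a), float(b)), theta=theta,
                         x_arc=x_arc, profile=prof, origin_px=(x0, a + b * x0))


def fit_tip(x_arc: np.ndarray, profile: np.ndarray,
            backbone: Optional[BackboneModel] = None,
            pixel_nm: float = PIXEL_NM, sigma0: float = 120.0) -> TipFit:
    """Fit the Gaussian survival function to the axial intensity profile."""
    x_arc = np.asarray(x_arc, dtype=float)
    profile = np.asarray(profile, dtype=float)
    # robust initialization: quantile plateau levels, last above-half crossing
    bg0 = float(np.quantile(profile, 0.1))
    amp0 = max(float(np.quantile(profile, 0.9) - bg0), 1e-6)
    smooth = np.convolve(profile, np.ones(3) / 3.0, mode="same")
    above = np.nonzero(smooth > bg0 + 0.5 * amp0)[0]
    mu0 = float(x_arc[above[-1]]) if above.size else float(x_arc[profile.size // 2])
    span = float(x_arc[-1] - x_arc[0])
    try:
        popt, _ = curve_fit(
            _erfc_profile, x_arc, profile, p0=(bg0, amp0, mu0, sigma0),
            bounds=([-np.inf, 0.0, x_arc[0] - span, 5.0],
                    [np.inf, np.inf, x_arc[-1] + span, span]),
            xtol=1e-10, maxfev=2000)
    except (RuntimeError, ValueError) as exc:
        raise TrackingError("tip fit did not converge") from exc
    bg, amp, mu, sigma = popt
    xy = backbone.arc_to_xy(mu, pixel_nm) if backbone is not None else (np.nan, np.nan)
    return TipFit(mu_arc=float(mu), sigma=float(sigma), amplitude=float(amp),
                  background=float(bg), xy_nm=xy)


def correct_drift(tip_xy_nm: np.ndarray, backbone_xy_nm: Sequence[float],
                  fid_x_nm: np.ndarray, theta: float,
                  frame_interval: float = 0.1,
                  concentration: Optional[float] = None) -> TipTrace:
    """Drift-corrected microtubule length series.

    ``tip_xy_nm`` is (n_frames, 2); ``backbone_xy_nm`` the fixed reference
    position on the backbone (defined in the first frame); ``fid_x_nm`` the
    averaged fiduciary x track relative to its initial position (NaN frames
    are linearly interpolated).
    """
    tip = np.asarray(tip_xy_nm, dtype=float)
    fid = np.asarray(fid_x_nm, dtype=float).copy()
    if fid.shape[0] != tip.shape[0]:
        raise ValueError("fiduciary track must cover every frame")
    bad = ~np.isfinite(fid)
    if bad.any():
        idx = np.arange(fid.size)
        fid[bad] = np.interp(idx[bad], idx[~bad], fid[~bad])
    dLx = tip[:, 0] - backbone_xy_nm[0] - fid
    dLy = tip[:, 1] - backbone_xy_nm[1] - np.sin(theta) * fid
    dL = np.hypot(dLx, dLy)
    t = np.arange(tip.shape[0]) * frame_interval
    return TipTrace(times=t, lengths=dL, concentration=concentration,
                    source="tracking")


@dataclasses.dataclass
class TrackResult:
    trace: TipTrace
    sigma_mt: np.ndarray       # nm per frame (NaN where flagged)
    theta: np.ndarray          # rad per frame
    flagged: np.ndarray        # bool per frame
    tip_xy_nm: np.ndarray


def track_movie(stack: np.ndarray, seed_backbone: Sequence[float],
                seed_tip: Sequence[float], fid_x_nm: Optional[np.ndarray] = None,
                pixel_nm: float = PIXEL_NM, frame_interval: float = 0.1,
                max_flagged_frac: float = 0.05, **bb_kwargs) -> TrackResult:
    """Track a movie end to end: backbone fit, tip fit, drift correction.

    The region of interest follows the previous frame's tip; an episode with
    more than ``max_flagged_frac`` failed frames is rejected.
    """
    n_frames = stack.shape[0]
    tip_xy = np.full((n_frames, 2), np.nan)
    sig = np.full(n_frames, np.nan)
    th = np.full(n_frames, np.nan)
    flagged = np.zeros(n_frames, dtype=bool)
    b_ref = None
    cur_tip = np.asarray(seed_tip, dtype=float)
    for i in range(n_frames):
        try:
            bb = fit_backbone(stack[i], seed_backbone, cur_tip,
                              pixel_nm=pixel_nm, **bb_kwargs)
            tf = fit_tip(bb.x_arc, bb.profile, backbone=bb, pixel_nm=pixel_nm)
        except TrackingError:
            flagged[i] = True
            continue
        tip_xy[i] = tf.xy_nm
        sig[i] = tf.sigma
        th[i] = bb.theta
        if b_ref is None:
            x0, y0 = bb.origin_px
            b_ref = (x0 * pixel_nm, y0 * pixel_nm)
        # follow the tip with the region of interest
        cur_tip = np.array([tf.xy_nm[0] / pixel_nm,
                            (bb.line[0] + bb.line[1] * tf.xy_nm[0] / pixel_nm)])
    if flagged.mean() > max_flagged_frac:
        raise TrackingError(f"{flagged.sum()} of {n_frames} frames flagged")
    if b_ref is None:
        raise TrackingError("no frame tracked successfully")
    good = ~flagged
    # flagged frames: carry tip through by interpolation before drift correction
    idx = np.arange(n_frames)
    for d in range(2):
        tip_xy[flagged, d] = np.interp(idx[flagged], idx[good], tip_xy[good, d])
    theta0 = float(np.nanmedian(th))
    fid = np.zeros(n_frames) if fid_x_nm is None else np.asarray(fid_x_nm, float)
    fid = fid - fid[np.isfinite(fid)][0]
    trace = correct_drift(tip_xy, b_ref, fid, theta0,
                          frame_interval=frame_interval)
    return TrackResult(trace=trace, sigma_mt=sig, theta=th, flagged=flagged,
                       tip_xy_nm=tip_xy)


def taper_estimate(sigma_mt: float, calibration) -> Optional[float]:
    """Invert a taper calibration curve for one fitted ``sigma_MT`` (nm).

    Returns the taper length in nm, or ``None`` ("below detection") when
    ``sigma_mt`` lies within the blunt-end confidence band (mean + 2 SD of
    blunt-end fits).  Raises for values outside the calibrated range.
    """
    tapers = np.asarray(calibration.tapers, dtype=float)
    means = np.asarray(calibration.mean_sigma, dtype=float)
    blunt = means[0] + 2.0 * float(calibration.sd_sigma[0])
    if sigma_mt <= blunt:
        return None
    if sigma_mt > means.max():
        raise ValueError("sigma_MT outside the calibrated range")
    return float(np.interp(sigma_mt, means, tapers))
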