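"""BOLD preprocessing: volume discarding, nuisance regression, band-pass.

The stage order is fixed: discard initial volumes, regress out the
Friston-24 motion expansion plus white-matter / CSF / global signals,
then band-pass filter (default 0.01-0.1 Hz). The filter is an ideal
DFT-domain mask applied to the linearly detrended series: bins with
frequency f satisfying low <= f <= high pass with unit gain, all other
bins (including DC) are zeroed.
"""

from __future__ import annotations

import logging
import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np

from .types import BoldRun, MotionTrace, NuisanceDesign

logger = logging.getLogger(__name__)

DEFAULT_N_DISCARD = 5
DEFAULT_BAND_HZ = (0.01, 0.1)


def discard_initial(run: BoldRun, n_discard: int = DEFAULT_N_DISCARD) -> BoldRun:
    """Drop the first ``n_discard`` volumes (magnetization equilibration).

    The caller must trim the motion trace identically
    (:meth:`MotionTrace.discard_initial`).
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if n_discard >= run.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {run.n_volumes} volumes"
        )
    if n_discard == 0:
        return run
    return dataclasses.replace(run, data=run.data[..., n_discard:])


def friston24(motion: MotionTrace) -> np.ndarray:
    """Friston 24-parameter motion expansion: [R, R^2, R_-1, R_-1^2].

    R is the t x 6 rigid-body trace and R_-1 its one-volume lag with the
    first row zero-padded (the autoregressive form of the expansion).
    Returns a t x 24 array with the four blocks in that order.
    """
    r = motion.params
    r_lag = np.vstack([np.zeros((1, 6)), r[:-1]])
    return np.hstack([r, r ** 2, r_lag, r_lag ** 2])


def extract_nuisance_signals(
    run: BoldRun, wm_mask: np.ndarray, csf_mask: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-centered (wm, csf, global) mean time courses.

    Each is the spatial mean over its mask; the global signal uses the
    run's own brain mask.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    csf_mask = np.asarray(csf_mask, dtype=bool)
    for name, m in (("wm", wm_mask), ("csf", csf_mask), ("global", run.mask)):
        if m.shape != run.spatial_shape:
            raise ValueError(f"{name} mask shape does not match BOLD volume")
        if not m.any():
            raise ValueError(f"{name} mask is empty")
    out = []
    for m in (wm_mask, csf_mask, run.mask):
        sig = run.data[m].mean(axis=0)
        out.append(sig - sig.mean())
    return tuple(out)  # type: ignore[return-value]


def build_design(
    motion: MotionTrace,
    wm: Optional[np.ndarray] = None,
    csf: Optional[np.ndarray] = None,
    global_sig: Optional[np.ndarray] = None,
) -> NuisanceDesign:
    """Assemble the nuisance design: Friston-24 [+ wm, csf, global] + intercept."""
    cols = [friston24(motion)]
    names = [f"friston_{i + 1}" for i in range(24)]
    for name, sig in (("wm", wm), ("csf", csf), ("global", global_sig)):
        if sig is not None:
            sig = np.asarray(sig, dtype=np.float64)
            if sig.shape != (motion.n_volumes,):
                raise ValueError(f"{name} signal length does not match motion rows")
            cols.append(sig[:, None])
            names.append(name)
    cols.append(np.ones((motion.n_volumes, 1)))
    names.append("intercept")
    return NuisanceDesign(np.hstack(cols), tuple(names))


def _drop_collinear(design: NuisanceDesign) -> NuisanceDesign:
    """Remove exactly-collinear columns (keeping the first of each set)."""
    x = design.matrix
    keep: list[int] = []
    for j in range(x.shape[1]):
        cand = x[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
    if len(keep) < x.shape[1]:
        dropped = [design.column_names[j] for j in range(x.shape[1]) if j not in keep]
        logger.warning("dropping collinear nuisance columns: %s", dropped)
        return NuisanceDesign(x[:, keep], tuple(design.column_names[j] for j in keep))
    return design


def regress_out(run: BoldRun, design: NuisanceDesign) -> BoldRun:
    """Replace each in-mask voxel series by its OLS residual vs the design.

    Out-of-mask voxels are set to 0. Exactly collinear design columns are
    dropped with a logged warning.
    """
    if design.matrix.shape[0] != run.n_volumes:
        raise ValueError(
            f"design has {design.matrix.shape[0]} rows but run has "
            f"{run.n_volumes} volumes"
        )
    design = _drop_collinear(design)
    x = design.matrix
    y = run.data[run.mask].T  # t x V
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    out = np.zeros_like(run.data)
    out[run.mask] = resid.T
    return dataclasses.replace(run, data=out)


def bandpass(
    run: BoldRun,
    low_hz: float = DEFAULT_BAND_HZ[0],
    high_hz: float = DEFAULT_BAND_HZ[1],
) -> BoldRun:
    """Ideal DFT band-pass of every in-mask voxel series.

    The series is linearly detrended, transformed with the real FFT, and
    all bins with frequency outside [low_hz, high_hz] are zeroed (unit
    gain inside the band). Since low_hz > 0 removes DC, a constant series
    maps to zero.
    """
    nyquist = 1.0 / (2.0 * run.tr_seconds)
    if not 0 <= low_hz < high_hz:
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz > nyquist + 1e-12:
        raise ValueError(f"high_hz {high_hz} exceeds Nyquist {nyquist:.4f} Hz")
    nt = run.n_volumes
    y = run.data[run.mask]  # V x t
    # linear detrend
    t = np.arange(nt, dtype=np.float64)
    t_c = t - t.mean()
    slope = (y @ t_c) / (t_c @ t_c)
    y = y - y.mean(axis=1, keepdims=True) - slope[:, None] * t_c[None, :]
    freqs = np.fft.rfftfreq(nt, d=run.tr_seconds)
    spec = np.fft.rfft(y, axis=1)
    spec[:, (freqs < low_hz) | (freqs > high_hz)] = 0.0
    filt = np.fft.irfft(spec, n=nt, axis=1)
    out = np.zeros_like(run.data)
    out[run.mask] = filt
    return dataclasses.replace(run, data=out)


def preprocess_run(
    run: BoldRun,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    n_discard: int = DEFAULT_N_DISCARD,
    band_hz: Tuple[float, float] = DEFAULT_BAND_HZ,
    global_signal_regression: bool = True,
) -> BoldRun:
    """Full preprocessing chain: discard -> nuisance regression -> band-pass."""
    if motion.n_volumes != run.n_volumes:
        raise ValueError("motion trace and BOLD run differ in volume count")
    run = discard_initial(run, n_discard)
    motion = motion.discard_initial(n_discard) if n_discard else motion
    wm, csf, glob = extract_nuisance_signals(run, wm_mask, csf_mask)
    design = build_design(
        motion, wm=wm, csf=csf, global_sig=glob if global_signal_regression else None
    )
    run = regress_out(run, design)
    return bandpass(run, *band_hz)
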