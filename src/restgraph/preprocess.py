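"""Temporal denoising of node time series.

The resting pipeline applies, in this fixed order: (1) a 0.01-0.08 Hz
bandpass realized as FFT-domain masking with a one-bin soft edge, then
(2) joint least-squares removal of nuisance confounds (mean white-matter and
ventricle time courses plus the six rigid-body motion parameters, all
band-passed into the same frequency space).  The global mean signal is never
used as a regressor: removing it shifts the correlation distribution and
makes the sign of correlations ambiguous.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "bandpass",
    "extract_confounds",
    "regress_nuisance",
    "preprocess_run",
]

CONFOUND_COLUMNS = ["wm_mean", "vent_mean"] + [f"motion_{i}" for i in range(1, 7)]


def bandpass(
    series: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Bandpass node x time series by FFT-domain masking.

    The passband mask is 1 inside [low_hz, high_hz], 0 outside, with a
    one-bin raised edge (neighbouring bins averaged) so the transition is
    soft.  The DC component (mean) is always removed.  Exactly zero phase
    shift; output length equals input length.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    if n < 20:
        raise ValueError(f"need at least 20 volumes, got {n}")
    nyq = 1.0 / (2.0 * tr_s)
    if not (0.0 < low_hz < high_hz):
        raise ValueError("require 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyq} = 1/(2*TR) for TR={tr_s}s"
        )
    freqs = np.fft.rfftfreq(n, d=tr_s)
    w = ((freqs >= low_hz) & (freqs <= high_hz)).astype(float)
    # one-bin soft edges: average each bin with its neighbours
    w = np.convolve(w, [0.25, 0.5, 0.25], mode="same")
    w[0] = 0.0  # DC always removed
    spec = np.fft.rfft(x - x.mean(axis=1, keepdims=True), axis=1)
    out = np.fft.irfft(spec * w, n=n, axis=1)
    return out if np.ndim(series) == 2 else out[0]


def extract_confounds(
    volume_series: np.ndarray,
    wm_mask: np.ndarray,
    vent_mask: np.ndarray,
    motion_params: np.ndarray,
) -> pd.DataFrame:
    """Build the confound matrix from a full-volume voxel x time array.

    ``wm_mean`` / ``vent_mean`` are spatial means over the mask voxels per
    volume; the six motion parameters are passed through unchanged.
    """
    vol = np.asarray(volume_series, dtype=float)
    wm_mask = np.asarray(wm_mask, dtype=bool)
    vent_mask = np.asarray(vent_mask, dtype=bool)
    if wm_mask.sum() == 0:
        raise ValueError("white-matter mask is empty")
    if vent_mask.sum() == 0:
        raise ValueError("ventricle mask is empty")
    motion = np.asarray(motion_params, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion_params must be n_vols x 6")
    n_vols = vol.shape[1]
    if motion.shape[0] != n_vols:
        raise ValueError(
            f"motion has {motion.shape[0]} rows but run has {n_vols} volumes"
        )
    data = {
        "wm_mean": vol[wm_mask].mean(axis=0),
        "vent_mean": vol[vent_mask].mean(axis=0),
    }
    for i in range(6):
        data[f"motion_{i + 1}"] = motion[:, i]
    return pd.DataFrame(data)


def _collinear_columns(x: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal does not reduce the rank (the redundant set)."""
    full = np.linalg.matrix_rank(x)
    out = []
    for j in range(x.shape[1]):
        reduced = np.delete(x, j, axis=1)
        if np.linalg.matrix_rank(reduced) == full:
            out.append(names[j])
    return out


def regress_nuisance(
    series: np.ndarray,
    confounds: pd.DataFrame | np.ndarray,
) -> np.ndarray:
    """Residualize node x time series against the confounds plus an intercept.

    Residuals are orthogonal to every confound column.  The global mean
    signal is deliberately never added here.
    """
    y = np.atleast_2d(np.asarray(series, dtype=float))
    if isinstance(confounds, pd.DataFrame):
        names = list(confounds.columns)
        c = confounds.to_numpy(dtype=float)
    else:
        c = np.asarray(confounds, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        names = [f"confound_{j}" for j in range(c.shape[1])]
    n_vols = y.shape[1]
    if c.shape[0] != n_vols:
        raise ValueError("confound length does not match run length")
    if n_vols <= c.shape[1] + 1:
        raise ValueError("need n_vols > n_confounds + 1")
    x = np.column_stack([np.ones(n_vols), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        bad = _collinear_columns(x, ["intercept"] + names)
        raise ValueError(f"confound matrix is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y - (x @ beta).T
    return resid if np.ndim(series) == 2 else resid[0]


def preprocess_run(
    volume_series: np.ndarray,
    gray_mask: np.ndarray,
    wm_mask: np.ndarray,
    vent_mask: np.ndarray,
    motion_params: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> np.ndarray:
    """Full denoising of one rest run: bandpass, then confound regression.

    Returns the denoised gray-matter node x time matrix.  Confound columns
    are band-passed with the same filter before regression; columns left with
    (numerically) zero variance by the filter are dropped with a warning.
    """
    conf = extract_confounds(volume_series, wm_mask, vent_mask, motion_params)
    conf_bp = pd.DataFrame(
        bandpass(conf.to_numpy().T, tr_s, low_hz, high_hz).T, columns=conf.columns
    )
    keep = conf_bp.std(axis=0) > 1e-10
    if not keep.all():
        dropped = list(conf_bp.columns[~keep])
        warnings.warn(
            f"confound columns with no in-band variance dropped: {dropped}",
            stacklevel=2,
        )
        conf_bp = conf_bp.loc[:, keep]
    nodes = bandpass(np.asarray(volume_series, dtype=float)[np.asarray(gray_mask, bool)],
                     tr_s, low_hz, high_hz)
    return regress_nuisance(nodes, conf_bp)
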