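"""Band-limited power envelopes of multichannel time-courses.

The connectivity pipeline characterises slow co-modulation of oscillatory
amplitude: each channel is band-pass filtered, its instantaneous amplitude
taken as the magnitude of the analytic (Hilbert) signal, and that envelope
low-pass filtered to 0.5 Hz and re-sampled at 1 Hz.  All filtering is
zero-phase (forward-backward Butterworth) so that the zero-lag structure
the leakage correction relies on is preserved.

Region collapsing is also provided: :func:`roi_timecourse` reduces a
multi-voxel region to the scores of the first principal component of its
weighted voxel time-courses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "EnvelopeMatrix",
    "bandpass",
    "hilbert_envelope",
    "downsample_envelope",
    "roi_timecourse",
    "envelope_pipeline",
]

#: Butterworth design order used for every filter in the pipeline.
FILTER_ORDER = 4

#: Seconds trimmed from each end of the envelope before downsampling, to
#: discard the bounded transient of the analytic transform and filters.
DEFAULT_TRIM = 1.0


@dataclass
class EnvelopeMatrix:
    """Down-sampled power envelopes, envelope samples × nodes.

    Attributes
    ----------
    values : ndarray
        Envelope samples × nodes; nonnegative before any standardisation.
    envelope_rate : float
        Output sampling rate in Hz (default 1 Hz).
    source_band : tuple of float
        (low, high) Hz band the envelopes were computed from, if known.
    """

    values: np.ndarray
    envelope_rate: float = 1.0
    source_band: tuple[float, float] | None = None

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


def _check_matrix(values) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if not np.all(np.isfinite(values)):
        raise DegenerateInputError("input contains non-finite values")
    return values


def bandpass(values, sampling_rate: float, band) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter along axis 0.

    Parameters
    ----------
    values : array-like, samples × nodes
    sampling_rate : float, Hz
    band : (low, high) in Hz, ``0 < low < high < sampling_rate / 2``.
    """
    values = _check_matrix(values)
    low, high = float(band[0]), float(band[1])
    nyq = sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ParameterError(
            f"band ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = scipy.signal.butter(FILTER_ORDER, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    return scipy.signal.sosfiltfilt(sos, values, axis=0)


def hilbert_envelope(values) -> np.ndarray:
    """Magnitude of the analytic signal, column-wise.

    The analytic transform is computed by FFT, so the input is padded to
    the next fast length and cropped back; the envelope is exact in the
    interior and shows a bounded edge transient that the downsampling
    stage trims.
    """
    values = _check_matrix(values)
    m = values.shape[0]
    if m < 16:
        raise ParameterError(f"need at least 16 samples for a stable envelope, got {m}")
    nfft = scipy.fft.next_fast_len(m)
    analytic = scipy.signal.hilbert(values, N=nfft, axis=0)[:m]
    return np.abs(analytic)


def downsample_envelope(
    values,
    sampling_rate: float,
    lowpass: float = 0.5,
    out_rate: float = 1.0,
    trim: float = DEFAULT_TRIM,
    source_band=None,
) -> EnvelopeMatrix:
    """Low-pass filter an envelope and re-sample it at a slow rate.

    Applies a zero-phase Butterworth low-pass at ``lowpass`` Hz, trims
    ``trim`` seconds from each end, and decimates to ``out_rate``.  Output
    length is ``floor(duration × out_rate) − 2·trim·out_rate`` samples.
    """
    values = _check_matrix(values)
    if not (sampling_rate > 2.0 * lowpass):
        raise ParameterError(
            f"envelope rate {sampling_rate} Hz must exceed twice the low-pass ({lowpass} Hz)"
        )
    if not (out_rate >= 2.0 * lowpass):
        raise ParameterError(
            f"output rate {out_rate} Hz must be at least twice the low-pass ({lowpass} Hz)"
        )
    sos = scipy.signal.butter(FILTER_ORDER, lowpass, btype="lowpass", fs=sampling_rate, output="sos")
    smooth = scipy.signal.sosfiltfilt(sos, values, axis=0)

    step = sampling_rate / out_rate
    n_trim = int(round(trim * sampling_rate))
    if 2 * n_trim >= values.shape[0]:
        raise ParameterError("trim exceeds the available duration")
    # sample on a regular grid at out_rate inside the trimmed span
    idx = np.arange(n_trim, values.shape[0] - n_trim, step)
    picks = np.round(idx).astype(int)
    out = smooth[picks]
    return EnvelopeMatrix(values=out, envelope_rate=out_rate, source_band=source_band)


def envelope_pipeline(
    values,
    sampling_rate: float,
    band=None,
    lowpass: float = 0.5,
    out_rate: float = 1.0,
    trim: float = DEFAULT_TRIM,
) -> EnvelopeMatrix:
    """Band-pass (optional) → Hilbert envelope → low-pass → downsample."""
    values = _check_matrix(values)
    if band is not None:
        values = bandpass(values, sampling_rate, band)
    env = hilbert_envelope(values)
    return downsample_envelope(
        env, sampling_rate, lowpass=lowpass, out_rate=out_rate, trim=trim,
        source_band=tuple(band) if band is not None else None,
    )


def roi_timecourse(voxels, weights) -> np.ndarray:
    """Collapse a multi-voxel region to a single representative series.

    The voxel series (samples × voxels) are scaled by their nonnegative
    spatial-map weights — first normalised to a positive peak of unity —
    and the scores of the first principal component of the weighted set
    are returned.  The sign is fixed so the result correlates nonnegatively
    with the weighted mean time-course.
    """
    voxels = _check_matrix(voxels)
    weights = np.asarray(weights, dtype=float).ravel()
    if weights.size != voxels.shape[1]:
        raise ParameterError(
            f"weight count {weights.size} does not match voxel count {voxels.shape[1]}"
        )
    if np.any(weights < 0):
        raise ParameterError("weights must be nonnegative")
    peak = weights.max()
    if peak == 0:
        raise ParameterError("weights must not be all zero")
    weights = weights / peak

    weighted = voxels * weights
    if not np.any(weighted):
        raise DegenerateInputError("all-zero voxel data")

    centred = weighted - weighted.mean(axis=0)
    # first left singular vector scaled by its singular value = PC1 scores
    U, s, _ = np.linalg.svd(centred, full_matrices=False)
    scores = U[:, 0] * s[0]
    reference = weighted.mean(axis=1)
    ref_c = reference - reference.mean()
    if np.dot(scores, ref_c) < 0:
        scores = -scores
    return scores


def explained_variance_ratio(voxels, weights) -> float:
    """Fraction of weighted-voxel variance captured by the first PC."""
    voxels = _check_matrix(voxels)
    weights = np.asarray(weights, dtype=float).ravel()
    weights = weights / weights.max()
    weighted = voxels * weights
    centred = weighted - weighted.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    power = s**2
    return float(power[0] / power.sum())
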