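"""Directional traveling-wave power by sliding-window 2D-FFT.

Each trial's 7 x n_samples axis stack is cut into 500 ms segments advancing
in 100 ms steps.  A segment, viewed as an image (channels x time), carries a
tilted planar wave as energy concentrated off the spatial-frequency midline
of its 2-D Fourier power spectrum; the quadrant sign of the tilt encodes
propagation direction.  For a temporal frequency f and a direction, the raw
directional power is the maximum over the three nonzero spatial-frequency
bins of the matching sign at column f.  It is normalized by ``FFT_f``, the
1-D temporal power at f averaged over the seven channels of the *same*
segment:

    FW_dB = 10 log10(FW_{f,max} / FFT_f),   BW_dB likewise.

0 dB therefore means directional power at parity with the segment's mean
temporal power (a perfectly coherent on-bin plane wave); band values are
the arithmetic mean of per-bin dB over bins inside the closed band.

Conventions fixed here (and pinned by tests): zero spatial frequency
(standing waves) and zero temporal frequency (DC) are excluded; no
detrending, tapering, or zero-padding unless explicitly enabled; the 2-D
power is scaled by 1/n_channels**2 so the 0 dB baseline is meaningful.
With the measurement's sign conventions, a forward wave (posterior leads)
puts its positive-temporal-frequency energy at negative spatial
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axes import N_VIRTUAL_CHANNELS, AxisStack

__all__ = [
    "WindowSpec",
    "BANDS",
    "slide_windows",
    "window_centers",
    "segment_power_2d",
    "directional_power",
    "mean_temporal_power",
    "normalize_db",
    "directional_db",
    "band_average",
    "band_bins",
    "stationary_band_power",
    "wave_power_table",
]

#: Canonical frequency bands (Hz, closed intervals on bin centers).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
}

# spatial-frequency FFT indices for a 7-row stack (unshifted layout
# [0, 1, 2, 3, -3, -2, -1]); the forward quadrant is the negative side.
_FORWARD_SPATIAL = np.array([4, 5, 6])
_BACKWARD_SPATIAL = np.array([1, 2, 3])


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window; defaults are 500 ms length, 100 ms step."""

    length: float = 0.5
    step: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0 or self.step <= 0:
            raise ValueError("window length and step must be positive")

    def in_samples(self, fs: float) -> tuple[int, int]:
        """(length, step) in samples; both must be integer at ``fs``."""
        out = []
        for name, sec in (("length", self.length), ("step", self.step)):
            n = sec * fs
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"window {name} {sec} s is not an integer "
                                 f"number of samples at {fs} Hz")
            out.append(int(round(n)))
        return out[0], out[1]

    def freq_bins(self, fs: float) -> np.ndarray:
        """Positive temporal-frequency bin centers (Hz), DC excluded."""
        n_len, _ = self.in_samples(fs)
        return np.arange(1, n_len // 2 + 1) / self.length


def slide_windows(stack: AxisStack, w: WindowSpec) -> np.ndarray:
    """Cut a stack into fully contained segments.

    Returns ``(n_trials, n_windows, 7, n_len)``; windows start at the epoch
    start and advance by the step.
    """
    n_len, n_step = w.in_samples(stack.fs)
    n_samples = stack.data.shape[-1]
    if n_len > n_samples:
        raise ValueError(
            f"window of {n_len} samples longer than epoch ({n_samples} samples)"
        )
    view = np.lib.stride_tricks.sliding_window_view(stack.data, n_len, axis=-1)
    # view: (trials, 7, n_positions, n_len) -> subsample starts, move window axis
    segs = np.moveaxis(view[:, :, ::n_step, :], 1, 2)
    return np.ascontiguousarray(segs)


def window_centers(stack: AxisStack, w: WindowSpec) -> np.ndarray:
    """Center time (s) of each emitted window."""
    n_len, n_step = w.in_samples(stack.fs)
    n_samples = stack.data.shape[-1]
    starts = np.arange(0, n_samples - n_len + 1, n_step)
    return stack.times[0] + (starts + n_len / 2.0) / stack.fs


def segment_power_2d(segments: np.ndarray) -> np.ndarray:
    """2-D DFT power of ``(..., 7, n_len)`` segments, scaled by 1/7**2.

    Output has the unshifted FFT layout on both axes (spatial axis -2,
    temporal axis -1).
    """
    n_ch = segments.shape[-2]
    F = np.fft.fft2(segments, axes=(-2, -1))
    return (F.real**2 + F.imag**2) / n_ch**2


def _temporal_bin(f: float, n_len: int, fs: float) -> int:
    k = f * n_len / fs
    if abs(k - round(k)) > 1e-9 or not 0 < round(k) <= n_len // 2:
        grid = fs / n_len
        raise ValueError(
            f"{f} Hz is not a positive temporal bin (grid {grid} Hz, "
            f"Nyquist {fs / 2} Hz)"
        )
    return int(round(k))


def directional_power(segment: np.ndarray, direction: str, f: float,
                      fs: float) -> float | np.ndarray:
    """Raw directional power at temporal frequency ``f`` for one direction.

    Maximum of the 2-D power over the three nonzero spatial frequencies of
    the quadrant mapped to ``direction`` ("forward" or "backward") in the
    positive-temporal-frequency half; by conjugate symmetry the mirrored
    quadrant gives the identical value.  Accepts a single ``7 x n`` segment
    or any batch ``(..., 7, n)``.
    """
    segment = np.asarray(segment, dtype=np.float64)
    if segment.shape[-2] != N_VIRTUAL_CHANNELS:
        raise ValueError(f"segment must have {N_VIRTUAL_CHANNELS} channel rows")
    k = _temporal_bin(f, segment.shape[-1], fs)
    P = segment_power_2d(segment)
    return _quadrant_max(P, direction, k)


def _quadrant_max(P: np.ndarray, direction: str, k: int) -> np.ndarray:
    if direction == "forward":
        rows = _FORWARD_SPATIAL
    elif direction == "backward":
        rows = _BACKWARD_SPATIAL
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    return P[..., rows, k].max(axis=-1)


def mean_temporal_power(segment: np.ndarray, f: float, fs: float) -> float | np.ndarray:
    """``FFT_f``: 1-D temporal power at ``f`` averaged over the 7 channels."""
    segment = np.asarray(segment, dtype=np.float64)
    k = _temporal_bin(f, segment.shape[-1], fs)
    F = np.fft.fft(segment, axis=-1)[..., k]
    return (F.real**2 + F.imag**2).mean(axis=-1)


def normalize_db(raw, fft_f):
    """dB of raw directional power against the segment's ``FFT_f``.

    An all-zero segment (``FFT_f == 0``) is degenerate and rejected; a zero
    *numerator* against positive ``FFT_f`` maps to -inf dB.
    """
    raw = np.asarray(raw, dtype=np.float64)
    fft_f = np.asarray(fft_f, dtype=np.float64)
    if np.any(fft_f <= 0):
        raise ValueError("degenerate segment: zero mean temporal power at f")
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(raw / fft_f)


def directional_db(segments: np.ndarray, fs: float,
                   freqs: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-segment, per-bin FW/BW dB for a batch ``(..., 7, n_len)``.

    Returns ``(freqs, fw_db, bw_db)`` with the frequency axis appended to
    the batch shape.  ``freqs`` defaults to the full positive bin grid
    (DC and upper bins included up to Nyquist).
    """
    segments = np.asarray(segments, dtype=np.float64)
    n_len = segments.shape[-1]
    if freqs is None:
        freqs = np.arange(1, n_len // 2 + 1) * fs / n_len
    ks = np.array([_temporal_bin(f, n_len, fs) for f in np.atleast_1d(freqs)])
    P = segment_power_2d(segments)
    fw = P[..., _FORWARD_SPATIAL[:, None], ks].max(axis=-2)
    bw = P[..., _BACKWARD_SPATIAL[:, None], ks].max(axis=-2)
    F = np.fft.fft(segments, axis=-1)[..., ks]
    fft_f = (F.real**2 + F.imag**2).mean(axis=-2)
    return np.atleast_1d(freqs), normalize_db(fw, fft_f), normalize_db(bw, fft_f)


def band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    """Indices of bin centers inside the closed band; empty band rejected."""
    lo, hi = band
    mask = (freqs >= lo) & (freqs <= hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}] Hz contains no frequency bin "
                         f"(grid: {freqs[:4]}... Hz)")
    return np.flatnonzero(mask)


def band_average(db_values: np.ndarray, freqs: np.ndarray,
                 band: tuple[float, float]) -> np.ndarray:
    """Arithmetic mean of per-bin dB over the closed band (last axis)."""
    idx = band_bins(np.asarray(freqs), band)
    return np.asarray(db_values)[..., idx].mean(axis=-1)


def stationary_band_power(stack: AxisStack, w: WindowSpec,
                          band: tuple[float, float]) -> np.ndarray:
    """Conventional band-limited amplitude power, same windowing as waves.

    Per window: one-sided per-bin signal power (2 |X_k|^2 / n^2) summed over
    band bins and averaged over the seven channels.  For an amplitude-a
    sinusoid on a bin this is a^2/2; for white noise it approximates
    (band width / Nyquist) x total power (Parseval).
    """
    segs = slide_windows(stack, w)
    n_len = segs.shape[-1]
    freqs = w.freq_bins(stack.fs)
    idx = band_bins(freqs, band) + 1  # +1: freq_bins starts at bin 1
    F = np.fft.fft(segs, axis=-1)[..., idx]
    per_bin = 2.0 * (F.real**2 + F.imag**2) / n_len**2
    return per_bin.sum(axis=-1).mean(axis=-1)  # sum bins, average channels


def wave_power_table(
    stack: AxisStack,
    w: WindowSpec | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    trial_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format per-trial wave power for one axis.

    Columns: trial, axis, window_time, band, direction, db.  Per-bin dB is
    computed first, then averaged within each band (per-frequency
    normalization before band averaging).
    """
    w = w or WindowSpec()
    bands = bands or {"alpha": BANDS["alpha"]}
    segs = slide_windows(stack, w)
    centers = window_centers(stack, w)
    freqs, fw, bw = directional_db(segs, stack.fs)  # (trials, windows, bins)
    if trial_ids is None:
        trial_ids = np.arange(stack.n_trials)
    frames = []
    n_t, n_w = fw.shape[:2]
    for band_name, band in bands.items():
        fw_b = band_average(fw, freqs, band)
        bw_b = band_average(bw, freqs, band)
        for direction, vals in (("forward", fw_b), ("backward", bw_b)):
            frames.append(pd.DataFrame({
                "trial": np.repeat(trial_ids, n_w),
                "axis": stack.axis_name,
                "window_time": np.tile(centers, n_t),
                "band": band_name,
                "direction": direction,
                "db": vals.ravel(),
            }))
    return pd.concat(frames, ignore_index=True)
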