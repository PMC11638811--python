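"""Synthetic epoched EEG with known traveling-wave content.

The generator produces the two study layouts the pipeline targets: a
distractor-load design ("DS1": 32-channel 10/10 montage, loads 2/4/6 with
the lateralized cluster being either the targets or the distractors) and a
set-size design ("DS2": 20-channel montage, set sizes 1/3/6, targets always
lateral).  Plane waves with a controlled temporal frequency and a monotonic
phase shift across channels are injected directly onto the channels of each
analysis axis (no volume-conduction model), on top of 1/f background noise.
A positive ``phase_step`` means the most posterior channel leads, i.e. the
wave travels posterior -> anterior ("forward").

Condition effects are expressed as extra :class:`WaveSpec` components per
condition level and per axis role, so every downstream measurement has a
known monotone ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .recording import MONTAGE_TEMPLATES, EpochedRecording
from .axes import builtin_axes

__all__ = [
    "WaveSpec",
    "NoiseSpec",
    "DesignSpec",
    "make_plane_wave",
    "make_noise",
    "simulate_participant",
    "simulate_dataset",
]


@dataclass(frozen=True)
class WaveSpec:
    """A planar traveling-wave component.

    ``phase_step`` is the phase lag added per channel step (radians); its
    sign encodes direction (positive = posterior leads = forward).
    ``onset``/``offset`` delimit the active interval in epoch time (seconds);
    ``None`` spans the whole epoch.  ``phase0 = None`` means a fresh uniform
    random initial phase per trial.
    """

    temporal_frequency: float
    phase_step: float
    amplitude: float = 1.0
    onset: float | None = None
    offset: float | None = None
    phase0: float | None = None

    def __post_init__(self) -> None:
        if self.temporal_frequency <= 0:
            raise ValueError("temporal_frequency must be positive")
        if not abs(self.phase_step) < np.pi:
            raise ValueError("|phase_step| must be < pi (spatial aliasing)")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.onset is not None and self.offset is not None and not self.onset < self.offset:
            raise ValueError("onset must precede offset")

    def scaled(self, factor: float) -> "WaveSpec":
        return WaveSpec(self.temporal_frequency, self.phase_step,
                        self.amplitude * factor, self.onset, self.offset, self.phase0)


@dataclass(frozen=True)
class NoiseSpec:
    """1/f^beta background noise; ``scale`` is the per-channel sample SD."""

    exponent: float = 1.0
    scale: float = 1.0
    spatially_coherent: bool = False

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ValueError("exponent must be >= 0")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")


#: role -> wave components; roles are axis names ("midline"/"left"/"right")
#: or lateral roles ("contra"/"ipsi") resolved per trial against the side of
#: the lateralized cluster.
WaveMap = Mapping[str, Sequence[WaveSpec]]


@dataclass(frozen=True)
class DesignSpec:
    """A full simulated study.

    ``effect_map`` gives, per condition level (distractor load or set size),
    the wave components added on top of ``base_waves``; every level must
    have an entry (an empty sequence is an explicit null effect).
    """

    dataset_template: str = "DS1"
    n_participants: int = 10
    n_trials_per_condition: int = 20
    levels: tuple[int, ...] = (2, 4, 6)
    sides: tuple[str, ...] = ("left", "right")
    arrangements: tuple[str, ...] = ("targets lateral", "distractors lateral")
    base_waves: WaveMap = field(default_factory=dict)
    effect_map: Mapping[int, WaveMap] = field(default_factory=dict)
    noise: NoiseSpec = NoiseSpec()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset_template not in MONTAGE_TEMPLATES:
            raise ValueError(
                f"unknown dataset template {self.dataset_template!r}; "
                f"known: {sorted(MONTAGE_TEMPLATES)}"
            )
        if min(self.n_participants, self.n_trials_per_condition, len(self.levels)) < 1:
            raise ValueError("all design counts must be >= 1")
        missing = [lv for lv in self.levels if lv not in self.effect_map]
        if missing:
            raise ValueError(
                f"effect_map lacks entries for levels {missing}; "
                "use an empty sequence for a null effect"
            )

    @property
    def level_name(self) -> str:
        return "load" if self.dataset_template == "DS1" else "set_size"


def make_plane_wave(
    spec: WaveSpec,
    n_channels: int,
    n_samples: int,
    fs: float,
    tmin: float = 0.0,
    phase0: float | None = None,
) -> np.ndarray:
    """Render a plane wave as a ``channels x samples`` matrix.

    Channel ``c``, sample ``t`` holds
    ``amplitude * sin(2 pi f t / fs - c * phase_step + phase0)`` inside the
    active interval and 0 outside.  Channel index 0 is the most posterior.
    """
    if fs <= 2 * spec.temporal_frequency:
        raise ValueError(
            f"temporal frequency {spec.temporal_frequency} Hz at or above "
            f"Nyquist ({fs / 2} Hz)"
        )
    if phase0 is None:
        phase0 = spec.phase0 if spec.phase0 is not None else 0.0
    t = np.arange(n_samples)
    phase = (2 * np.pi * spec.temporal_frequency * t / fs)[np.newaxis, :] \
        - (np.arange(n_channels) * spec.phase_step)[:, np.newaxis] + phase0
    wave = spec.amplitude * np.sin(phase)
    times = tmin + t / fs
    lo = times[0] if spec.onset is None else spec.onset
    hi = times[-1] if spec.offset is None else spec.offset
    wave *= ((times >= lo) & (times <= hi))[np.newaxis, :]
    return wave


def make_noise(
    spec: NoiseSpec,
    n_channels: int,
    n_samples: int,
    fs: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Zero-mean 1/f^beta noise, one row per channel.

    Spectral shaping in the frequency domain: white Gaussian noise is
    filtered so the expected power spectral density is proportional to
    ``f**-exponent`` (DC removed), then each channel is rescaled to sample
    SD ``spec.scale``.  With ``spatially_coherent`` one realization is
    shared by all channels.
    """
    if spec.scale == 0.0:
        return np.zeros((n_channels, n_samples))
    n_real = 1 if spec.spatially_coherent else n_channels
    white = rng.standard_normal((n_real, n_samples))
    spectrum = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-spec.exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    shaped = spec.scale * shaped / sd
    if spec.spatially_coherent:
        shaped = np.broadcast_to(shaped, (n_channels, n_samples)).copy()
    return shaped


def _trial_table(design: DesignSpec) -> pd.DataFrame:
    """Fully crossed, deterministic trial order (condition-blocked)."""
    rows = []
    arrangements = design.arrangements if design.dataset_template == "DS1" \
        else ("targets lateral",)
    for level in design.levels:
        for side in design.sides:
            for arr in arrangements:
                for rep in range(design.n_trials_per_condition):
                    rows.append({design.level_name: level, "side": side,
                                 "arrangement": arr, "rep": rep})
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def _resolve_role(role: str, side: str) -> str:
    """Map a lateral role to a concrete axis name for a trial.

    "contra"/"ipsi" are relative to the side of the lateralized cluster.
    """
    if role in ("midline", "left", "right"):
        return role
    if role == "contra":
        return "right" if side == "left" else "left"
    if role == "ipsi":
        return side
    raise ValueError(f"unknown axis role {role!r}")


def _merge_components(components: list[tuple[str, WaveSpec]]) -> list[tuple[str, WaveSpec]]:
    """Coherently merge same-shaped wave components by summing amplitudes.

    An effect-map entry that repeats a base component's frequency, phase
    step, interval and phase policy is an *amplitude adjustment* of that
    component, not an independent oscillation: two same-frequency waves
    with independent random phases would add with zero median log-power
    gain, destroying the monotone ground truth the effect map promises.
    """
    amplitudes: dict[tuple, float] = {}
    for axis_name, s in components:
        key = (axis_name, s.temporal_frequency, s.phase_step, s.onset,
               s.offset, s.phase0)
        amplitudes[key] = amplitudes.get(key, 0.0) + s.amplitude
    return [
        (key[0], WaveSpec(key[1], key[2], amp, key[3], key[4], key[5]))
        for key, amp in amplitudes.items() if amp > 0
    ]


def simulate_participant(design: DesignSpec, participant: str,
                         rng: np.random.Generator) -> EpochedRecording:
    """One participant's epochs under the design, using the supplied rng."""
    tpl = MONTAGE_TEMPLATES[design.dataset_template]
    fs, tmin, n_samples = tpl["fs"], tpl["tmin"], tpl["n_samples"]
    ch_names = tpl["ch_names"]
    axes = builtin_axes(design.dataset_template)
    trials = _trial_table(design)
    n_trials = len(trials)
    data = np.empty((n_trials, len(ch_names), n_samples))
    ch_index = {name: i for i, name in enumerate(ch_names)}

    for t_i, row in enumerate(trials.itertuples(index=False)):
        level = getattr(row, design.level_name)
        epoch = make_noise(design.noise, len(ch_names), n_samples, fs, rng)
        components: list[tuple[str, WaveSpec]] = []
        for wave_map in (design.base_waves, design.effect_map[level]):
            for role, specs in wave_map.items():
                axis_name = _resolve_role(role, row.side)
                components.extend((axis_name, s) for s in specs)
        for axis_name, wspec in _merge_components(components):
            axis = axes[axis_name]
            phase0 = wspec.phase0
            if phase0 is None:
                phase0 = rng.uniform(0.0, 2 * np.pi)
            wave = make_plane_wave(wspec, len(axis), n_samples, fs,
                                   tmin=tmin, phase0=phase0)
            for c, ch in enumerate(axis.channels):
                epoch[ch_index[ch]] += wave[c]
        data[t_i] = epoch

    return EpochedRecording(
        data=data, ch_names=ch_names, fs=fs, tmin=tmin, trials=trials,
        participant=participant, template=design.dataset_template,
    )


def simulate_dataset(design: DesignSpec) -> list[EpochedRecording]:
    """All participants of a design; reproducible under ``design.rng_seed``."""
    seeds = np.random.SeedSequence(design.rng_seed).spawn(design.n_participants)
    return [
        simulate_participant(design, f"p{i:02d}", np.random.default_rng(seeds[i]))
        for i in range(design.n_participants)
    ]
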