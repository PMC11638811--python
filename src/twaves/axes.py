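"""Electrode axes: definition, extraction and posterior->anterior stacking.

An *axis* is an ordered run of electrodes from the back of the head to the
front (midline, left hemisphere, right hemisphere).  Each axis is linearly
interpolated to seven virtual channels so that all axes have the same
spatial sampling; a trial's ``7 x n_samples`` matrix is the unit the wave
quantification operates on.  The interpolation abscissa is channel *rank*
along the axis (equally spaced), not 3-D scalp distance.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

from .recording import EpochedRecording

__all__ = [
    "N_VIRTUAL_CHANNELS",
    "ElectrodeAxis",
    "AxisStack",
    "builtin_axes",
    "load_axes",
    "interpolation_matrix",
    "build_axis_stack",
    "items_side",
    "assign_roles",
]

#: All axes are resampled to this many virtual channels.
N_VIRTUAL_CHANNELS = 7


@dataclass(frozen=True)
class ElectrodeAxis:
    """An ordered electrode run, most posterior channel first."""

    name: str
    channels: tuple[str, ...]
    template: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) < 3:
            raise ValueError(f"axis {self.name!r} needs >= 3 channels")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError(f"axis {self.name!r} has duplicate channel labels")

    def __len__(self) -> int:
        return len(self.channels)

    def reversed(self) -> "ElectrodeAxis":
        return ElectrodeAxis(self.name, self.channels[::-1], self.template)


@dataclass
class AxisStack:
    """Per-trial interpolated axis data: ``(n_trials, 7, n_samples)``.

    Row 0 of each trial matrix is the most posterior virtual channel.
    """

    axis_name: str
    data: np.ndarray
    fs: float
    times: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 2:
            self.data = self.data[np.newaxis]
        if self.data.shape[1] != N_VIRTUAL_CHANNELS:
            raise ValueError(
                f"axis stack must have {N_VIRTUAL_CHANNELS} rows, got {self.data.shape[1]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("axis stack contains non-finite values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def load_axes(path) -> dict[str, dict[str, ElectrodeAxis]]:
    """Load axis definitions from a YAML file (template -> name -> channels)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, dict[str, ElectrodeAxis]] = {}
    for template, axes in raw.items():
        out[template] = {
            name: ElectrodeAxis(name, tuple(chs), template)
            for name, chs in axes.items()
        }
    return out


def builtin_axes(template: str) -> dict[str, ElectrodeAxis]:
    """Built-in axis definitions for a montage template ("DS1" or "DS2")."""
    ref = importlib.resources.files("twaves.data") / "axes.yaml"
    with importlib.resources.as_file(ref) as path:
        table = load_axes(path)
    if template not in table:
        raise KeyError(
            f"no built-in axes for template {template!r}; available: {sorted(table)}"
        )
    return table[template]


def interpolation_matrix(n_in: int, n_out: int = N_VIRTUAL_CHANNELS) -> np.ndarray:
    """Linear-interpolation weights ``W`` with ``out = W @ in``.

    Input channels sit at equally spaced ranks rescaled to [0, 1]; output
    row ``j`` samples the piecewise-linear profile at position ``j/(n_out-1)``.
    For ``n_in == n_out`` this is the identity.
    """
    if n_in < 2:
        raise ValueError("need at least 2 input channels to interpolate")
    xp = np.linspace(0.0, 1.0, n_in)
    xq = np.linspace(0.0, 1.0, n_out)
    W = np.zeros((n_out, n_in))
    # each query point lies in segment [i, i+1]; weights are the two hat values
    seg = np.clip(np.searchsorted(xp, xq, side="right") - 1, 0, n_in - 2)
    frac = (xq - xp[seg]) / (xp[seg + 1] - xp[seg])
    W[np.arange(n_out), seg] = 1.0 - frac
    W[np.arange(n_out), seg + 1] = frac
    return W


def build_axis_stack(rec: EpochedRecording, axis: ElectrodeAxis) -> AxisStack:
    """Extract an axis from a recording and interpolate to 7 virtual channels.

    Raises ``KeyError`` naming the label if an axis channel is missing from
    the recording.
    """
    picked = rec.pick(list(axis.channels))  # (trials, k, samples)
    W = interpolation_matrix(len(axis))
    data = np.einsum("jk,tks->tjs", W, picked)
    return AxisStack(axis.name, data, rec.fs, rec.times)


def items_side(lateral_side: str, lateral_items: str, items_of_interest: str) -> str:
    """Side of the items of interest given which cluster was lateralized.

    ``lateral_side`` is the hemifield of the lateralized cluster;
    ``lateral_items`` says what that cluster was ("targets" or "distractors",
    the two arrangements of the distractor-load design; set-size designs are
    always "targets").  When the items of interest are the non-lateral
    cluster, they sit in the opposite hemifield.
    """
    for arg, val in (("lateral_side", lateral_side), ("items_of_interest", items_of_interest)):
        if val not in _SIDE_VOCAB[arg]:
            raise ValueError(f"unknown {arg} {val!r}")
    if lateral_items not in ("targets", "distractors"):
        raise ValueError(f"unknown lateral_items {lateral_items!r}")
    if items_of_interest == lateral_items:
        return lateral_side
    return "right" if lateral_side == "left" else "left"


_SIDE_VOCAB = {
    "lateral_side": ("left", "right"),
    "items_of_interest": ("targets", "distractors"),
}


def assign_roles(
    axis_values: dict[str, object], side: str, items_of_interest: str = "targets",
    lateral_items: str = "targets",
) -> dict[str, object]:
    """Relabel hemisphere axes as contralateral/ipsilateral to the items.

    ``axis_values`` maps axis names ("left"/"right", optionally "midline")
    to any payload; the returned dict maps roles ("contra"/"ipsi", midline
    passed through).  Visual input projects contralaterally, so items in the
    left hemifield make the *right* axis contralateral.
    """
    ref_side = items_side(side, lateral_items, items_of_interest)
    out: dict[str, object] = {}
    for name, val in axis_values.items():
        if name == "midline":
            out["midline"] = val
        elif name in ("left", "right"):
            out["contra" if name != ref_side else "ipsi"] = val
        else:
            raise ValueError(f"axis {name!r} has no lateral role")
    return out
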