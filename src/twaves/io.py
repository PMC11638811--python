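"""Readers/writers and run configuration.

The *fixture container* is the package's documented epoch format: a
directory with ``data.npy`` (trials x channels x samples), ``trials.csv``
(the condition table) and ``meta.json`` (channel names, sampling rate,
epoch start, identifiers).  FIF and EEGLAB ``.set`` epochs are read through
mne when available.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .quant import BANDS, WindowSpec
from .recording import MONTAGE_TEMPLATES, EpochedRecording

logger = logging.getLogger("twaves")

__all__ = ["write_fixture", "read_epochs", "PipelineConfig", "SimulationParams",
           "load_config"]


def write_fixture(rec: EpochedRecording, path: str | Path) -> Path:
    """Write a recording to the fixture container (directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", rec.data)
    rec.trials.to_csv(path / "trials.csv", index=False)
    meta = {
        "ch_names": list(rec.ch_names),
        "fs": rec.fs,
        "tmin": rec.tmin,
        "shape": list(rec.data.shape),
        "participant": rec.participant,
        "template": rec.template,
        "experiment": rec.experiment,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def _read_fixture(path: Path) -> EpochedRecording:
    for required in ("meta.json", "data.npy", "trials.csv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"fixture container {path} is missing {required}")
    meta = json.loads((path / "meta.json").read_text())
    for key in ("ch_names", "fs", "tmin", "shape"):
        if key not in meta:
            raise ValueError(f"fixture metadata lacks required field {key!r}")
    data = np.load(path / "data.npy")
    if list(data.shape) != list(meta["shape"]):
        raise ValueError(
            f"fixture {path} is truncated or corrupt: data shape {list(data.shape)} "
            f"does not match metadata {meta['shape']}"
        )
    trials = pd.read_csv(path / "trials.csv")
    template = meta.get("template")
    if template in MONTAGE_TEMPLATES:
        tpl_fs = MONTAGE_TEMPLATES[template]["fs"]
        if tpl_fs != meta["fs"]:
            logger.warning(
                "fixture %s declares template %s (fs %s Hz) but carries fs %s Hz; "
                "file is authoritative", path, template, tpl_fs, meta["fs"],
            )
    return EpochedRecording(
        data=data, ch_names=tuple(meta["ch_names"]), fs=meta["fs"],
        tmin=meta["tmin"], trials=trials,
        participant=meta.get("participant", "p0"),
        template=template, experiment=meta.get("experiment"),
    )


def _from_mne_epochs(epochs, participant: str, template: str | None) -> EpochedRecording:
    data = epochs.get_data(copy=True)
    trials = epochs.metadata
    if trials is None:
        trials = pd.DataFrame({"trial": np.arange(len(epochs)),
                               "event_id": epochs.events[:, 2]})
    trials = trials.reset_index(drop=True)
    if "trial" not in trials.columns:
        trials.insert(0, "trial", np.arange(len(trials)))
    return EpochedRecording(
        data=data, ch_names=tuple(epochs.ch_names), fs=float(epochs.info["sfreq"]),
        tmin=float(epochs.times[0]), trials=trials, participant=participant,
        template=template,
    )


def read_epochs(path: str | Path, format: str = "fixture",
                participant: str = "p0", template: str | None = None) -> EpochedRecording:
    """Load epoched EEG from a supported container.

    ``format`` is "fixture" (the package's directory container), "fif"
    (mne epochs) or "set" (EEGLAB epochs; both require mne).
    """
    path = Path(path)
    if format == "fixture":
        return _read_fixture(path)
    if format in ("fif", "set"):
        import mne

        if format == "fif":
            epochs = mne.read_epochs(path, preload=True, verbose="error")
        else:
            epochs = mne.io.read_epochs_eeglab(path, verbose="error")
        return _from_mne_epochs(epochs, participant, template)
    raise ValueError(f"unknown epoch format {format!r}; use fixture, fif or set")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

class SimulationParams(BaseModel):
    """Synthetic-study parameters exposed through the config file."""

    n_participants: int = Field(10, ge=1)
    n_trials_per_condition: int = Field(20, ge=1)
    levels: tuple[int, ...] = (2, 4, 6)
    noise_exponent: float = Field(1.0, ge=0.0)
    noise_scale: float = Field(1.0, ge=0.0)
    base_forward_amplitude: float = Field(1.0, ge=0.0)
    base_backward_amplitude: float = Field(0.5, ge=0.0)
    effect_forward_per_level: float = Field(0.0, ge=0.0)
    wave_frequency: float = Field(10.0, gt=0.0)
    phase_step: float = 2 * np.pi / 7


class PipelineConfig(BaseModel):
    """Validated end-to-end run configuration (YAML/JSON)."""

    dataset_template: Literal["DS1", "DS2"] = "DS1"
    axes_file: Optional[Path] = None
    window_length: float = Field(0.5, gt=0)
    window_step: float = Field(0.1, gt=0)
    bands: dict[str, tuple[float, float]] = Field(default_factory=lambda: dict(BANDS))
    analysis_band: str = "alpha"
    retention: Optional[tuple[float, float]] = None
    trial_statistic: Literal["mean", "median"] = "mean"
    stats_method: Literal["bic_approx", "monte_carlo"] = "bic_approx"
    items_of_interest: Literal["targets", "distractors"] = "targets"
    seed: int = 0
    out_dir: Path = Path("twaves-out")
    input_path: Optional[Path] = None
    input_format: Literal["fixture", "fif", "set"] = "fixture"
    simulation: Optional[SimulationParams] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        if self.analysis_band not in self.bands:
            raise ValueError(
                f"unknown band name {self.analysis_band!r}; "
                f"defined bands: {sorted(self.bands)}"
            )
        for name, (lo, hi) in self.bands.items():
            if not 0 < lo <= hi:
                raise ValueError(f"band {name!r} has invalid range [{lo}, {hi}]")
        if self.retention is not None and not self.retention[0] < self.retention[1]:
            raise ValueError("retention interval must have t0 < t1")
        return self

    @property
    def window(self) -> WindowSpec:
        return WindowSpec(self.window_length, self.window_step)

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    """Read and validate a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    raw = yaml.safe_load(text)
    return PipelineConfig.model_validate(raw)
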