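"""Pipeline configuration, frequency-band table, and shared exceptions.

All stages of the pipeline read their parameters from a single
:class:`PipelineConfig`, which can be loaded from a flat YAML file and
overridden field-by-field (the CLI maps flags onto these fields).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger("epitensor")


class EpitensorError(Exception):
    """Base class for errors raised by this package."""


class ConfigurationError(EpitensorError, ValueError):
    """Invalid configuration or an operation called in an unusable mode."""


class ChannelError(EpitensorError, KeyError):
    """A requested channel is missing from a recording."""


class RateMismatchError(EpitensorError, ValueError):
    """Recording sampling rate does not match the configured rate."""


class BoundsError(EpitensorError, IndexError):
    """A requested time range extends beyond the recording."""


class SizeError(EpitensorError, ValueError):
    """Input too short for the requested windowing/stacking."""


class NumericalError(EpitensorError, ArithmeticError):
    """Non-finite values appeared during an iterative computation."""


class RankSelectionError(EpitensorError, RuntimeError):
    """Rank search exhausted ``R_max`` without reaching the error threshold."""

    def __init__(self, message: str, error_trace: list[float]):
        super().__init__(message)
        self.error_trace = error_trace


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f_lo, f_hi)`` (the topmost band is closed above).

    ``raw`` is the unfiltered signal and carries no bounds.
    """

    name: str
    f_lo: float | None
    f_hi: float | None
    closed_upper: bool = False

    @property
    def is_raw(self) -> bool:
        return self.f_lo is None


#: The five canonical EEG bands plus the unfiltered signal.  Shared edges are
#: assigned to the lower band (half-open intervals); gamma, the topmost band,
#: is closed at 60 Hz.
BANDS: dict[str, BandDefinition] = {
    "raw": BandDefinition("raw", None, None),
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha_band": BandDefinition("alpha_band", 8.0, 15.0),
    "beta": BandDefinition("beta", 15.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 60.0, closed_upper=True),
}

#: Default grid of ridge (regularization) values searched by leave-one-out.
DEFAULT_E_GRID: tuple[float, ...] = tuple(2.0**k for k in range(-10, 11, 2))

#: Default 23-channel montage name list used for synthetic recordings.
DEFAULT_CHANNELS: tuple[str, ...] = tuple(f"CH{i:02d}" for i in range(1, 24))


@dataclass
class PipelineConfig:
    """Parameters for the whole pipeline.

    Attributes
    ----------
    fs : sampling rate in Hz.
    window_s, step_s : sliding-window length and step in seconds.
    alpha : confidence level of the significance threshold.
    L : number of disjoint window sections entering the threshold formula;
        the default 337 is the number of disjoint 8-s sections in 45 min.
    num : networks stacked per tensor (3..6).
    tensor_stride : slices between consecutive tensors; ``None`` means
        ``num`` (disjoint tensors).
    err_thresh : CP relative-error threshold driving rank selection.
    R_max : upper bound of the rank search.
    M : hidden neurons of the ELM.
    E_grid : candidate regularization values for leave-one-out selection.
    alarm_len : consecutive pre-ictal labels required to raise an alert.
    band : which frequency band feeds the network construction.
    binarize_rule : ``"abs"`` thresholds the correlation magnitude
        (default); ``"signed"`` thresholds the signed coefficient.
    feature_family : ``"tensor"``, ``"degree"`` or ``"clustering"``.
    reference_rule : how the reference tensor (whose factors are frozen)
        is picked from the training set: ``"first_preictal"`` (default)
        takes the first tensor of the first pre-ictal training segment in
        catalog order — the pre-ictal class has the richer networks, and a
        near-empty reference yields a degenerate (too small) basis —
        ``"first"`` takes the first training tensor regardless of class.
    reference_index : explicit (segment, tensor) pair overriding the rule.
    seed : master seed; every random stage derives from it.
    """

    fs: float = 256.0
    window_s: float = 8.0
    step_s: float = 4.0
    alpha: float = 0.95
    L: int = 337
    num: int = 3
    tensor_stride: int | None = None
    err_thresh: float = 0.05
    R_max: int = 100
    M: int = 100
    E_grid: tuple[float, ...] = DEFAULT_E_GRID
    alarm_len: int = 30
    band: str = "gamma"
    binarize_rule: str = "abs"
    feature_family: str = "tensor"
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    reference_rule: str = "first_preictal"
    reference_index: tuple[int, int] | None = None
    cp_tol: float = 1e-6
    cp_max_iter: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.window_s > self.step_s > 0:
            raise ConfigurationError("require window_s > step_s > 0")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.L < 2:
            raise ConfigurationError("L must be >= 2")
        if not 0 < self.err_thresh < 1:
            raise ConfigurationError("err_thresh must lie in (0, 1)")
        if self.alarm_len < 1:
            raise ConfigurationError("alarm_len must be >= 1")
        if self.num < 1:
            raise ConfigurationError("num must be >= 1")
        if self.band not in BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}")
        if self.binarize_rule not in ("abs", "signed"):
            raise ConfigurationError("binarize_rule must be 'abs' or 'signed'")
        if self.reference_rule not in ("first_preictal", "first"):
            raise ConfigurationError(
                "reference_rule must be 'first_preictal' or 'first'"
            )
        if self.feature_family not in ("tensor", "degree", "clustering"):
            raise ConfigurationError(
                "feature_family must be 'tensor', 'degree' or 'clustering'"
            )

    @property
    def stride(self) -> int:
        return self.num if self.tensor_stride is None else self.tensor_stride

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key/value YAML file; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("E_grid", "channel_names"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if raw.get("reference_index") is not None:
            raw["reference_index"] = tuple(raw["reference_index"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["E_grid"] = list(self.E_grid)
        d["channel_names"] = list(self.channel_names)
        if self.reference_index is not None:
            d["reference_index"] = list(self.reference_index)
        return d
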