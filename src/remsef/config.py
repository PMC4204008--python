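"""Run configuration: validated defaults, YAML override files."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .detector import Thresholds
from .features import BandConfig
from .preprocessing import EPOCH_SECONDS, SUBEPOCH_SECONDS

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All tunables of a detection run, validated at construction.

    Defaults are the shipped operating conditions: 8-16 Hz analysis
    band, the fixed calibrated thresholds, 30-s epochs of 2-s subepochs,
    a 9-point SEFd smoother, UNSCORED epochs excluded from evaluation
    and MOVEMENT epochs rescored as Wake.
    """

    band: BandConfig = field(default_factory=BandConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    epoch_seconds: float = float(EPOCH_SECONDS)
    subepoch_seconds: float = float(SUBEPOCH_SECONDS)
    smoothing_window: int = 9
    stage_map: dict = field(default_factory=dict)
    exclude_unscored: bool = True
    movement_as_wake: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        # the spectral pipeline is built on the 30 s / 2 s / 256 Hz grid;
        # other epoch geometries are rejected rather than silently ignored
        if self.epoch_seconds != EPOCH_SECONDS:
            raise ValueError(
                f"epoch_seconds={self.epoch_seconds} unsupported; the "
                f"pipeline operates on {EPOCH_SECONDS}-s epochs")
        if self.subepoch_seconds != SUBEPOCH_SECONDS:
            raise ValueError(
                f"subepoch_seconds={self.subepoch_seconds} unsupported; "
                f"the pipeline uses {SUBEPOCH_SECONDS}-s subepochs")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be a positive odd count")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band"] = {"f1": self.band.f1, "f2": self.band.f2}
        d["thresholds"] = self.thresholds.to_dict()
        return d


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Precedence: keyword overrides > YAML file > shipped defaults.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    band = data.pop("band", None)
    thresholds = data.pop("thresholds", None)
    kwargs = dict(data)
    if band is not None:
        if isinstance(band, str):
            f1, f2 = band.split(":")
            band = {"f1": float(f1), "f2": float(f2)}
        kwargs["band"] = BandConfig(**band)
    if thresholds is not None:
        if not isinstance(thresholds, Thresholds):
            thresholds = Thresholds.from_dict(thresholds)
        kwargs["thresholds"] = thresholds
    return RunConfig(**kwargs)
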