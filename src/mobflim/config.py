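"""Domain types shared across the pipeline.

All times are in nanoseconds, all pixel coordinates are 0-based
``(row, col)`` with centroids in continuous pixel units at pixel centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and geometry of a TCSPC acquisition.

    The decay histogram must span exactly one laser period so that the
    periodic (wrapped) phasor normalization is valid:
    ``n_time_bins * bin_width == laser_period``.
    """

    laser_period: float = 12.5       # ns; 80 MHz repetition rate
    n_time_bins: int = 256
    harmonic: int = 1
    irf_sigma: float = 0.0           # ns; Gaussian IRF width, 0 = ideal
    background_rate: float = 0.0     # expected photons per pixel over the frame
    frame_shape: tuple[int, int] = (128, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.laser_period <= 0:
            raise ConfigurationError("laser_period must be positive")
        if self.n_time_bins < 2:
            raise ConfigurationError("n_time_bins must be >= 2")
        if self.harmonic < 1:
            raise ConfigurationError("harmonic must be >= 1")
        if self.irf_sigma < 0:
            raise ConfigurationError("irf_sigma must be >= 0")
        if self.background_rate < 0:
            raise ConfigurationError("background_rate must be >= 0")
        if any(n <= 0 for n in self.frame_shape):
            raise ConfigurationError("frame_shape entries must be positive")

    @property
    def bin_width(self) -> float:
        return self.laser_period / self.n_time_bins

    @property
    def omega(self) -> float:
        """Angular frequency of the configured harmonic (rad/ns)."""
        return 2.0 * math.pi * self.harmonic / self.laser_period

    @property
    def bin_centers(self):
        import numpy as np

        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frame_shape"] = list(self.frame_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        d = dict(d)
        d["frame_shape"] = tuple(d.get("frame_shape", (128, 128)))
        return cls(**d)


@dataclass
class CellTruth:
    """Ground-truth parameters of one simulated cell.

    ``alpha_bound_true`` is the fractional photon contribution of
    enzyme-bound NAD(P)H; ``tau_bound_true``/``tau_free_true`` its bound and
    free lifetimes. ``orr_true`` is the optical redox ratio
    FAD/(FAD + NAD(P)H). ``edge_enrichment`` multiplies intensity in the
    peripheral band, ``polarity_offset`` is the intensity-centroid
    displacement as a fraction of the radius.
    """

    cell_id: int
    population: str
    center: tuple[float, float]      # (row, col)
    radius: float                    # px
    alpha_bound_true: float
    tau_bound_true: float
    tau_free_true: float
    total_photons: float
    orr_true: float
    edge_enrichment: float = 1.0
    polarity_offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tau_bound_true > self.tau_free_true > 0):
            raise ConfigurationError(
                f"cell {self.cell_id}: need tau_bound > tau_free > 0, got "
                f"{self.tau_bound_true} / {self.tau_free_true}"
            )
        if not (0.0 <= self.alpha_bound_true <= 1.0):
            raise ConfigurationError(f"cell {self.cell_id}: alpha_bound outside [0, 1]")
        if self.radius < 2:
            raise ConfigurationError(f"cell {self.cell_id}: radius must be >= 2 px")
        if not (0.0 <= self.orr_true <= 1.0):
            raise ConfigurationError(f"cell {self.cell_id}: orr outside [0, 1]")
        if self.edge_enrichment < 0:
            raise ConfigurationError(f"cell {self.cell_id}: edge_enrichment < 0")
        if not (0.0 <= self.polarity_offset < 1.0):
            raise ConfigurationError(f"cell {self.cell_id}: polarity_offset outside [0, 1)")
        if self.total_photons <= 0:
            raise ConfigurationError(f"cell {self.cell_id}: total_photons must be positive")


# (low, high) clip range per drawn CellTruth field; None = unbounded side
_FIELD_RANGES = {
    "radius": (2.0, None),
    "alpha_bound_true": (0.0, 1.0),
    "tau_bound_true": (1e-3, None),
    "tau_free_true": (1e-3, None),
    "total_photons": (1.0, None),
    "orr_true": (0.0, 1.0),
    "edge_enrichment": (0.0, None),
    "polarity_offset": (0.0, 1.0 - 1e-9),
}

DRAWN_FIELDS = tuple(_FIELD_RANGES)


@dataclass
class PopulationSpec:
    """Mean/dispersion of every drawn cell parameter for one population."""

    name: str
    n_cells: int
    mean: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        missing = set(DRAWN_FIELDS) - set(self.mean)
        if missing:
            raise ConfigurationError(f"population {self.name!r}: missing means for {sorted(missing)}")
        for k, v in self.sd.items():
            if v < 0:
                raise ConfigurationError(f"population {self.name!r}: sd[{k}] < 0")
        for k, (lo, hi) in _FIELD_RANGES.items():
            m = self.mean[k]
            if (lo is not None and m < lo and self.sd.get(k, 0.0) == 0.0) or (
                hi is not None and m > hi and self.sd.get(k, 0.0) == 0.0
            ):
                raise ConfigurationError(
                    f"population {self.name!r}: mean[{k}]={m} outside invariant range"
                )

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationSpec":
        return cls(name=d["name"], n_cells=int(d["n_cells"]),
                   mean=dict(d["mean"]), sd=dict(d.get("sd", {})))

    def to_dict(self) -> dict:
        return {"name": self.name, "n_cells": self.n_cells,
                "mean": dict(self.mean), "sd": dict(self.sd)}


@dataclass(frozen=True)
class PerturbationModel:
    """Linear response of tau_bound to a treatment.

    Applied change per cell: ``delta = a + b * tau_bound_initial + noise``,
    the post value clipped to stay above tau_free. Models pharmacological
    LDH inhibition, whose tau_bound decrease scales with the initial value.
    """

    intercept: float = 0.0   # a, ns
    slope: float = 0.0       # b, dimensionless
    noise_sd: float = 0.0    # ns

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
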