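"""Core data containers for patch-clamp sweeps and recorded cells.

Sign convention: membrane current is stored signed in pA with inward
(excitatory, at -70 mV holding) current negative.  All *amplitudes* reported
by analysis functions are positive magnitudes.  Times are in milliseconds,
positions in micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .exceptions import InvalidParameterError

__all__ = ["SweepRecord", "GridGeometry", "CellRecording"]


@dataclass
class SweepRecord:
    """One membrane-current trace with its stimulation metadata.

    Parameters
    ----------
    samples : ndarray
        Signed current in pA at uniform sampling interval ``dt``.
    dt : float
        Sampling interval in ms.
    stim_onset : float
        Stimulus onset time in ms from the start of the sweep.
    stim_kind : str
        One of ``{"LED", "laser", "uncage", "none"}``.
    grid_index : tuple or None
        ``(row, col)`` photostimulation grid position, if any.
    power : float or None
        Stimulus power in mW (required when ``stim_kind != "none"``).
    holding : float
        Holding potential in mV.
    """

    samples: np.ndarray
    dt: float
    stim_onset: float
    stim_kind: str = "none"
    grid_index: Optional[tuple] = None
    power: Optional[float] = None
    holding: float = -70.0
    sweep_id: Optional[str] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be a 1-D array")
        if self.dt <= 0:
            raise InvalidParameterError(f"dt must be positive, got {self.dt}")
        if not (0 <= self.stim_onset <= self.duration):
            raise InvalidParameterError(
                f"stim_onset {self.stim_onset} ms outside trace span "
                f"[0, {self.duration}] ms"
            )
        if self.stim_kind != "none" and (self.power is None or self.power <= 0):
            raise InvalidParameterError(
                "power must be positive when a stimulus is present"
            )
        if self.grid_index is not None:
            self.grid_index = (int(self.grid_index[0]), int(self.grid_index[1]))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms from sweep start."""
        return np.arange(self.samples.size) * self.dt

    def with_samples(self, samples: np.ndarray) -> "SweepRecord":
        """Copy of this record with the trace replaced (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class GridGeometry:
    """Photostimulation grid: ``rows x cols`` spots at fixed spacing.

    Row 0 is the pia-most row; the soma sits at pixel
    ``(rows // 2, cols // 2)`` so that the grid is centred on the recorded
    neuron, as in grid-mapping experiments.
    """

    rows: int
    cols: int
    x_spacing: float
    y_spacing: float

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise InvalidParameterError("grid must have at least one spot")
        if self.x_spacing <= 0 or self.y_spacing <= 0:
            raise InvalidParameterError("grid spacing must be positive")

    @property
    def soma_pixel(self) -> tuple:
        return (self.rows // 2, self.cols // 2)

    def relative_coords(self, row: int, col: int) -> tuple:
        """Soma-relative (x, y) of a pixel centre, y positive toward pia."""
        r0, c0 = self.soma_pixel
        return ((col - c0) * self.x_spacing, (r0 - row) * self.y_spacing)

    def all_indices(self):
        for r in range(self.rows):
            for c in range(self.cols):
                yield (r, c)


@dataclass
class CellRecording:
    """All sweeps and geometry for one recorded neuron.

    ``pair_id`` ties the two members of a double-patched neighbouring
    WT/KO pair together; ``soma_pos`` is the soma location in slice-frame
    micrometers (x lateral, y vertical with pia-ward positive).
    """

    cell_id: str
    genotype: str  # "WT" | "KO"
    pair_id: str
    mode: str  # "sCRACM" | "AP_map" | "LSPS" | "LED_bulk" | "Sr2+"
    dt: float
    stim_onset: float
    soma_pos: tuple
    sweeps: list = field(default_factory=list)
    grid: Optional[GridGeometry] = None
    led_power: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.genotype not in ("WT", "KO"):
            raise InvalidParameterError(f"unknown genotype {self.genotype!r}")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweeps_by_spot(self) -> dict:
        """Group sweeps by grid index (None key for ungridded sweeps)."""
        out: dict = {}
        for s in self.sweeps:
            out.setdefault(s.grid_index, []).append(s)
        return out
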