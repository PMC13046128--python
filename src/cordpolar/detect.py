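"""Particle extraction, size filtering and overlap-based colocalisation.

Cells are connected components (8-connectivity) of the cleaned binary mask,
kept when their calibrated area falls inside a marker-specific window derived
from literature somal diameters.  ChAT+ cells are further split by size into
presumed interneurons and motor neurons.  Double-positive subsets are defined
by the fraction of a cell's pixels that fall on the thresholded mask of a
second marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

MARKERS = ("ChAT", "GAD67", "Parvalbumin", "Calbindin")

#: Overlap fraction at or above which a cell counts as double positive.
DEFAULT_OVERLAP_CUTOFF = 0.20

#: Area (um^2) splitting ChAT+ interneurons (< 491) from motor neurons
#: (>= 491); corresponds to a 25 um diameter.
CHAT_SPLIT_AREA_UM2 = 491.0
#: Upper area bound of the ChAT+ motor-neuron class (40 um diameter).
CHAT_MOTOR_MAX_AREA_UM2 = 1257.0


def diameter_to_area(d_um: float) -> float:
    """Somal cross-section area (um^2) of a circular cell of diameter ``d_um``."""
    if d_um < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * (d_um / 2.0) ** 2


@dataclass(frozen=True)
class SizeWindow:
    """Inclusive area window for one marker, derived from a diameter range."""

    marker: str
    d_min_um: float
    d_max_um: float
    a_min_um2: float
    a_max_um2: float

    def __post_init__(self) -> None:
        if not self.a_min_um2 < self.a_max_um2:
            raise ValueError("a_min must be below a_max")

    @classmethod
    def from_diameters(cls, marker: str, d_min_um: float, d_max_um: float,
                       ndigits: int = 1) -> "SizeWindow":
        return cls(
            marker,
            d_min_um,
            d_max_um,
            round(diameter_to_area(d_min_um), ndigits),
            round(diameter_to_area(d_max_um), ndigits),
        )

    def contains(self, area_um2: float) -> bool:
        return self.a_min_um2 <= area_um2 <= self.a_max_um2


#: Literature-based somal size windows per marker.  Areas are the rounded
#: printed bounds: ChAT 10-40 um (78.5-1256.6 um^2), Parvalbumin 10-20 um
#: (78.5-314 um^2), GAD-67 8-20 um (50-314 um^2), Calbindin 10-25 um
#: (78.5-490.9 um^2).
SIZE_WINDOWS: dict[str, SizeWindow] = {
    "ChAT": SizeWindow("ChAT", 10.0, 40.0, 78.5, 1256.6),
    "Parvalbumin": SizeWindow("Parvalbumin", 10.0, 20.0, 78.5, 314.0),
    "GAD67": SizeWindow("GAD67", 8.0, 20.0, 50.0, 314.0),
    "Calbindin": SizeWindow("Calbindin", 10.0, 25.0, 78.5, 490.9),
}


@dataclass
class CellRecord:
    """One detected particle and its derived per-cell measurements."""

    id: int
    marker: str
    pixels: np.ndarray           # (n, 2) array of (row, col) member pixels
    centroid: tuple[float, float]  # (x, y) in px
    area_um2: float
    angle_deg: float | None = None
    mirrored_angle_deg: float | None = None
    distance_um: float | None = None
    norm_distance: float | None = None
    coexpression: dict[str, float] = field(default_factory=dict)
    size_class: str | None = None


def find_particles(
    binary: np.ndarray,
    pixel_size: float,
    window: SizeWindow,
    marker: str | None = None,
) -> list[CellRecord]:
    """Extract size-filtered cells from a cleaned binary mask.

    Connected components use 8-connectivity; area is pixel count times
    ``pixel_size**2``; the window is inclusive at both ends.  Centroids are
    the arithmetic mean of member pixel coordinates, reported as (x, y).
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    binary = np.asarray(binary).astype(bool)
    labelled = label(binary, connectivity=2)
    cells: list[CellRecord] = []
    px_area = pixel_size * pixel_size
    for region in regionprops(labelled):
        area_um2 = region.num_pixels * px_area
        if not window.contains(area_um2):
            continue
        cy, cx = region.centroid
        cells.append(
            CellRecord(
                id=len(cells),
                marker=marker if marker is not None else window.marker,
                pixels=region.coords,
                centroid=(float(cx), float(cy)),
                area_um2=float(area_um2),
            )
        )
    return cells


def classify_chat_size(cells: list[CellRecord]) -> list[str]:
    """Split ChAT+ cells into ``interneuron`` / ``motor_neuron`` by area.

    Interneurons are 10-25 um diameter (area in [78.5, 491) um^2), motor
    neurons 25-40 um (area in [491, 1257] um^2); the shared 491 um^2 boundary
    is assigned to the motor-neuron class.  Labels are also written to each
    record's ``size_class``.
    """
    labels: list[str] = []
    lo = SIZE_WINDOWS["ChAT"].a_min_um2
    for cell in cells:
        if cell.area_um2 < lo or cell.area_um2 > CHAT_MOTOR_MAX_AREA_UM2:
            raise ValueError(
                f"area {cell.area_um2:.1f} um^2 outside the ChAT window; "
                "size filtering should have removed this cell"
            )
        cls = "interneuron" if cell.area_um2 < CHAT_SPLIT_AREA_UM2 else "motor_neuron"
        cell.size_class = cls
        labels.append(cls)
    return labels


def overlap_fraction(cell: CellRecord, other_binary: np.ndarray) -> float:
    """Fraction of the cell's pixels lying on the other marker's binary mask."""
    other_binary = np.asarray(other_binary).astype(bool)
    if cell.pixels.shape[0] == 0:
        raise ValueError("cell has an empty pixel set")
    rows = cell.pixels[:, 0]
    cols = cell.pixels[:, 1]
    return float(other_binary[rows, cols].sum()) / cell.pixels.shape[0]


def double_positives(
    cells_a: list[CellRecord],
    binary_b: np.ndarray,
    marker_b: str,
    cutoff: float = DEFAULT_OVERLAP_CUTOFF,
) -> list[CellRecord]:
    """Cells of marker A whose overlap with marker B's mask is >= ``cutoff``.

    The overlap fraction is always stored in each cell's ``coexpression``
    map, including for cells below the cutoff.  The test is anchored on the
    first-listed marker's particles: overlap of A-in-B and B-in-A generally
    differ.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    retained = []
    for cell in cells_a:
        frac = overlap_fraction(cell, binary_b)
        cell.coexpression[marker_b] = frac
        if frac >= cutoff:
            retained.append(cell)
    return retained
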