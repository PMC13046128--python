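"""Canal-referenced polar coordinates, laterality mirroring and distance
normalisation.

Angles follow the mathematical convention of the original measurements:
0 deg points right, 90 deg dorsal, 180 deg left, 270 deg ventral.  Because
anatomical left and right are unidentifiable in free-floating sections,
left-side angles (strictly between 90 and 270 deg) are mirrored onto the
right via theta' = 180 - theta, which preserves the dorsoventral component.

Radial distances are normalised to gray-matter size; three variants are
provided because the normalisation can be read in more than one way:

``radial_fraction`` (default)
    distance to the canal divided by the distance from the canal to the
    gray-matter boundary along the same ray; 0 at the canal, 1 at the edge.
``edge_map``
    depth of the cell in the Euclidean distance transform of the gray-matter
    mask (distance from the tissue edge), divided by the maximum depth.
``canal_over_depthmax``
    distance to the canal divided by the maximum edge-map depth.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi

from .imgproc import SectionGeometry

NORMALISATION_VARIANTS = ("radial_fraction", "edge_map", "canal_over_depthmax")


def roi_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic-mean centroid (x, y) of a binary region's member pixels."""
    mask = np.asarray(mask).astype(bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("empty mask has no centroid")
    return float(cols.mean()), float(rows.mean())


def polar_coords(
    cell_centroid: tuple[float, float],
    canal_centroid: tuple[float, float],
    pixel_size: float,
    dorsal_up: bool = True,
) -> tuple[float, float]:
    """Distance (um) and angle (deg) of a cell relative to the canal centre.

    The angle is the inverse tangent of the dorsal-positive vertical offset
    over the rightward horizontal offset, mapped to [0, 360).  Image rows
    increase downward, so with ``dorsal_up`` the vertical offset sign is
    flipped: a cell directly above the canal yields 90 deg.
    """
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    dx = cell_centroid[0] - canal_centroid[0]
    dy_screen = cell_centroid[1] - canal_centroid[1]
    if dx == 0 and dy_screen == 0:
        raise ValueError("cell and canal centroids coincide; angle undefined")
    dy_dorsal = -dy_screen if dorsal_up else dy_screen
    distance_um = math.hypot(dx, dy_screen) * pixel_size
    angle = math.degrees(math.atan2(dy_dorsal, dx)) % 360.0
    return distance_um, angle


def mirror_left_to_right(theta_deg):
    """Laterality correction theta' = 180 - theta for left-side angles.

    Angles strictly between 90 and 270 deg are reflected about the vertical
    axis; right-side angles (including exactly 90 and 270) are unchanged.
    Accepts scalars or arrays.  sin(theta') == sin(theta), so the
    dorsoventral coordinate is preserved.
    """
    theta = np.asarray(theta_deg, dtype=float) % 360.0
    left = (theta > 90.0) & (theta < 270.0)
    out = np.where(left, (180.0 - theta) % 360.0, theta)
    if np.isscalar(theta_deg) or np.ndim(theta_deg) == 0:
        return float(out)
    return out


def edge_depth_map(gray_mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (px) of each in-mask pixel from the tissue edge."""
    return ndi.distance_transform_edt(np.asarray(gray_mask).astype(bool))


class RadialBoundary:
    """Lookup of the gray-matter boundary radius along rays from the canal.

    The boundary radius r(theta) is the largest in-mask radius along the ray
    at angle theta (screen geometry, dorsal-up convention), sampled on a
    dense angular grid and interpolated.  Using the farthest in-mask sample
    makes the lookup robust to small non-convexities of the mask.
    """

    def __init__(self, gray_mask: np.ndarray, canal_centroid: tuple[float, float],
                 dorsal_up: bool = True, n_angles: int = 3600, step_px: float = 0.25):
        gray_mask = np.asarray(gray_mask).astype(bool)
        h, w = gray_mask.shape
        cx, cy = canal_centroid
        max_r = math.hypot(h, w)
        radii = np.arange(step_px, max_r, step_px)
        theta = np.deg2rad(np.arange(n_angles) * (360.0 / n_angles))
        sign = -1.0 if dorsal_up else 1.0
        xs = cx + np.outer(np.cos(theta), radii)
        ys = cy + sign * np.outer(np.sin(theta), radii)
        rows = np.clip(np.rint(ys).astype(int), 0, h - 1)
        cols = np.clip(np.rint(xs).astype(int), 0, w - 1)
        inside = gray_mask[rows, cols]
        # farthest in-mask sample per ray
        any_inside = inside.any(axis=1)
        last_idx = inside.shape[1] - 1 - np.argmax(inside[:, ::-1], axis=1)
        self._r = np.where(any_inside, radii[last_idx], np.nan)
        self._n = n_angles

    def __call__(self, angle_deg) -> np.ndarray:
        idx = np.rint(np.asarray(angle_deg) / (360.0 / self._n)).astype(int) % self._n
        return self._r[idx]


def _boundary_for(geometry: SectionGeometry) -> RadialBoundary:
    if geometry._boundary_cache is None:
        geometry._boundary_cache = RadialBoundary(
            geometry.gray_mask, geometry.canal_centroid, geometry.dorsal_up
        )
    return geometry._boundary_cache


def normalise_distance(
    cell_centroid: tuple[float, float],
    geometry: SectionGeometry,
    variant: str = "radial_fraction",
    depth_map: np.ndarray | None = None,
) -> float:
    """Normalised radial position of a cell within the gray matter.

    See the module docstring for the three variants.  ``depth_map`` may be
    passed to reuse a precomputed edge-distance transform.
    """
    if variant not in NORMALISATION_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    x, y = cell_centroid
    gray = geometry.gray_mask
    h, w = gray.shape
    r_int, c_int = int(round(y)), int(round(x))
    if not (0 <= r_int < h and 0 <= c_int < w) or not gray[r_int, c_int]:
        raise ValueError("cell centroid lies outside the gray-matter mask")

    cx, cy = geometry.canal_centroid
    dx = x - cx
    dy = y - cy
    r_cell = math.hypot(dx, dy)

    if variant == "radial_fraction":
        if r_cell == 0:
            return 0.0
        _, angle = polar_coords((x, y), (cx, cy), 1.0, geometry.dorsal_up)
        r_boundary = float(_boundary_for(geometry)(angle))
        if not np.isfinite(r_boundary) or r_boundary <= 0:
            raise ValueError("ray from canal does not intersect the mask boundary")
        return min(r_cell / r_boundary, 1.0)

    if depth_map is None:
        depth_map = edge_depth_map(gray)
    d_max = float(depth_map.max())
    if d_max <= 0:
        raise ValueError("degenerate gray-matter mask")
    if variant == "edge_map":
        # sub-pixel bilinear sample of the depth map at the centroid
        value = float(
            ndi.map_coordinates(depth_map, [[y], [x]], order=1, mode="nearest")[0]
        )
        return value / d_max
    # canal_over_depthmax
    return r_cell / d_max


def annotate_cells(
    cells,
    geometry: SectionGeometry,
    pixel_size: float,
    variant: str = "radial_fraction",
) -> None:
    """Fill polar fields of detected cells in place.

    Sets ``angle_deg`` (raw), ``mirrored_angle_deg``, ``distance_um`` and
    ``norm_distance`` for every cell whose centroid does not coincide with
    the canal centroid.
    """
    depth_map = None
    if variant in ("edge_map", "canal_over_depthmax"):
        depth_map = edge_depth_map(geometry.gray_mask)
    for cell in cells:
        distance, angle = polar_coords(
            cell.centroid, geometry.canal_centroid, pixel_size, geometry.dorsal_up
        )
        cell.distance_um = distance
        cell.angle_deg = angle
        cell.mirrored_angle_deg = mirror_left_to_right(angle)
        cell.norm_distance = normalise_distance(
            cell.centroid, geometry, variant, depth_map=depth_map
        )
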