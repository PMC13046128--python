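"""Synthetic four-marker spinal-cord sections with full ground truth.

The generator emulates the inputs of the imaging study: a bilaterally
symmetric butterfly-shaped gray matter with a small central canal, per-marker
cell populations placed in canal-referenced polar coordinates (von Mises
mixture over angle, uniform or beta law over normalised depth), configurable
co-expression subsets, and a rendered 16-bit z-stack per channel (uniform
intensity disks over a smooth background plus Gaussian pixel noise).

Cells are uniform disks rather than Gaussian blobs so that thresholded areas
have a closed-form expectation, which the recovery tests exploit.  Every
sampled cell is recorded in a ground-truth table (position, diameter, marker
memberships, true angle and canal distance) for end-to-end recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage.measure import find_contours

from .detect import MARKERS
from .geometry import RadialBoundary, roi_centroid
from .imgproc import U16_MAX, ChannelStack, SectionGeometry


class ConfigurationError(ValueError):
    """Invalid section configuration (e.g. canal not containable in mask)."""


class PlacementError(RuntimeError):
    """Retry budget exhausted while placing cells."""


@dataclass(frozen=True)
class VonMisesComponent:
    """One component of an angular mixture law (degrees, concentration)."""

    mu_deg: float
    kappa: float
    weight: float = 1.0

    def __post_init__(self):
        if self.kappa < 0:
            raise ConfigurationError("kappa must be >= 0")
        if self.weight <= 0:
            raise ConfigurationError("component weight must be positive")


@dataclass(frozen=True)
class RadialLaw:
    """Law of the normalised depth u in [lo, hi] (0 = canal, 1 = boundary)."""

    kind: str = "uniform"          # "uniform" or "beta"
    lo: float = 0.15
    hi: float = 0.90
    a: float = 2.0                 # beta shape parameters (beta kind only)
    b: float = 2.0

    def __post_init__(self):
        if self.kind not in ("uniform", "beta"):
            raise ConfigurationError("radial law kind must be uniform or beta")
        if not 0.0 <= self.lo < self.hi <= 1.0:
            raise ConfigurationError("radial law needs 0 <= lo < hi <= 1")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        x = rng.random(n) if self.kind == "uniform" else rng.beta(self.a, self.b, n)
        return self.lo + (self.hi - self.lo) * x


@dataclass(frozen=True)
class PopulationSpec:
    """One ground-truth cell population.

    ``markers`` are the channels the population is labelled in; extra
    markers can be co-expressed by a fraction of the population through
    ``coexpression`` (marker -> fraction), assigning exactly
    ``round(fraction * count)`` cells the extra flag.
    """

    name: str
    markers: tuple[str, ...]
    count: int
    angular: tuple[VonMisesComponent, ...]
    radial: RadialLaw = RadialLaw()
    diameter_um: tuple[float, float] = (10.0, 20.0)
    coexpression: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.count < 0:
            raise ConfigurationError("count must be >= 0")
        d0, d1 = self.diameter_um
        if not (0 < d0 <= d1 <= 60.0):
            raise ConfigurationError("diameters must lie in (0, 60] um")
        for m in list(self.markers) + list(self.coexpression):
            if m not in MARKERS:
                raise ConfigurationError(f"unknown marker {m!r}")
        for f in self.coexpression.values():
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("coexpression fractions must be in [0, 1]")


@dataclass(frozen=True)
class GrayMatterParams:
    """Butterfly shape: a central band plus mirrored dorsal/ventral horn
    lobes, each an ellipse (all lengths in um, offsets from the canal;
    positive vertical offsets point ventral/down)."""

    band_semi_um: tuple[float, float] = (120.0, 95.0)
    ventral_center_um: tuple[float, float] = (125.0, 115.0)
    ventral_semi_um: tuple[float, float] = (150.0, 125.0)
    ventral_rot_deg: float = 30.0
    dorsal_center_um: tuple[float, float] = (95.0, -135.0)
    dorsal_semi_um: tuple[float, float] = (90.0, 150.0)
    dorsal_rot_deg: float = -18.0


def _default_populations() -> tuple[PopulationSpec, ...]:
    """Study-like defaults: ~200 cells per section across the four markers.

    Angular laws are bilateral mirrored pairs so raw sections look
    symmetric; after laterality mirroring each pair collapses onto its
    right-side mode.  ChAT+ motor neurons concentrate in the ventral horns,
    ChAT+ (and ChAT+/GAD-67+) interneurons near the canal, the calcium-
    binding-protein populations more dorsally.
    """
    vm = VonMisesComponent
    return (
        PopulationSpec(
            "chat_motor", ("ChAT",), 30,
            (vm(305.0, 2.0, 0.5), vm(235.0, 2.0, 0.5)),
            RadialLaw("beta", 0.30, 0.85, 3.0, 2.0), (26.0, 38.0)),
        PopulationSpec(
            "chat_interneuron", ("ChAT",), 20,
            (vm(20.0, 2.0, 0.5), vm(160.0, 2.0, 0.5)),
            RadialLaw("beta", 0.15, 0.80, 1.5, 3.0), (12.0, 22.0)),
        PopulationSpec(
            "chat_gad", ("ChAT", "GAD67"), 15,
            (vm(25.0, 2.0, 0.5), vm(155.0, 2.0, 0.5)),
            RadialLaw("beta", 0.12, 0.70, 1.2, 3.0), (11.0, 16.0)),
        PopulationSpec(
            "calbindin", ("Calbindin",), 35,
            (vm(60.0, 1.0, 0.5), vm(120.0, 1.0, 0.5)),
            RadialLaw("uniform", 0.20, 0.90), (11.0, 22.0)),
        PopulationSpec(
            "parvalbumin", ("Parvalbumin",), 40,
            (vm(30.0, 1.2, 0.5), vm(150.0, 1.2, 0.5)),
            RadialLaw("uniform", 0.20, 0.90), (11.0, 18.0),
            coexpression={"GAD67": 0.30, "Calbindin": 0.20}),
        PopulationSpec(
            "gad", ("GAD67",), 60,
            (vm(5.0, 1.0, 0.5), vm(175.0, 1.0, 0.5)),
            RadialLaw("uniform", 0.15, 0.90), (10.0, 18.0)),
    )


@dataclass
class SectionConfig:
    """Everything needed to build one synthetic section deterministically."""

    image_size: tuple[int, int] = (640, 640)     # (H, W) px
    n_slices: int = 3
    z_weights: tuple[float, ...] = (0.25, 0.5, 0.25)
    pixel_size: float = 1.0                      # um/px
    gray: GrayMatterParams = field(default_factory=GrayMatterParams)
    canal_radius_um: float = 12.0
    populations: tuple[PopulationSpec, ...] = field(
        default_factory=_default_populations)
    background: float = 2000.0
    gradient_amplitude: float = 0.0
    noise_sd: float = 0.0
    amplitude: float = 20000.0
    enforce_separation: bool = False
    separation_um: float = 4.0
    poisson_counts: bool = True
    retry_budget: int = 400
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.n_slices != len(self.z_weights):
            raise ConfigurationError("z_weights must have one entry per slice")
        if self.canal_radius_um <= 0:
            raise ConfigurationError("canal radius must be positive")


@dataclass
class TrueCell:
    """Ground truth for one placed cell."""

    id: int
    x_px: float
    y_px: float
    diameter_um: float
    markers: set
    angle_deg: float       # raw angle, before laterality mirroring
    distance_um: float
    population: str


@dataclass
class SyntheticSection:
    stacks: dict
    geometry: SectionGeometry
    truth: pd.DataFrame
    config: SectionConfig


def _ellipse_mask(u_um, v_um, center, semi, rot_deg):
    cu = u_um - center[0]
    cv = v_um - center[1]
    t = math.radians(rot_deg)
    ru = cu * math.cos(t) + cv * math.sin(t)
    rv = -cu * math.sin(t) + cv * math.cos(t)
    return (ru / semi[0]) ** 2 + (rv / semi[1]) ** 2 <= 1.0


def make_section_geometry(config: SectionConfig) -> SectionGeometry:
    """Build the butterfly gray-matter mask and central-canal disk.

    The mask is the union of a central band and two mirrored horn-lobe
    pairs.  Mirrored lobes are evaluated on the negated horizontal
    coordinate, so the mask is bit-exactly symmetric about the vertical
    midline; the canal is a disk centred on the midline.
    """
    h, w = config.image_size
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    xc, yc = (w - 1) / 2.0, (h - 1) / 2.0
    px = config.pixel_size
    u = (xs - xc) * px
    v = (ys - yc) * px

    g = config.gray
    gray = _ellipse_mask(u, v, (0.0, 0.0), g.band_semi_um, 0.0)
    for center, semi, rot in (
        (g.ventral_center_um, g.ventral_semi_um, g.ventral_rot_deg),
        (g.dorsal_center_um, g.dorsal_semi_um, g.dorsal_rot_deg),
    ):
        gray |= _ellipse_mask(u, v, center, semi, rot)
        gray |= _ellipse_mask(-u, v, center, semi, rot)

    canal = u**2 + v**2 <= config.canal_radius_um**2
    if not canal.any() or not (canal <= gray).all():
        raise ConfigurationError("central canal must fit inside the gray matter")
    return SectionGeometry(
        gray_mask=gray,
        canal_mask=canal,
        canal_centroid=roi_centroid(canal),
        dorsal_up=True,
    )


def sample_angles(components, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n angles (deg, [0, 360)) from a von Mises mixture."""
    components = tuple(components)
    weights = np.array([c.weight for c in components], dtype=float)
    weights = weights / weights.sum()
    idx = rng.choice(len(components), size=n, p=weights)
    out = np.empty(n)
    for i, c in enumerate(components):
        sel = idx == i
        k = int(sel.sum())
        if k:
            out[sel] = np.degrees(rng.vonmises(math.radians(c.mu_deg), c.kappa, k))
    return out % 360.0


def sample_population(
    spec: PopulationSpec,
    geometry: SectionGeometry,
    pixel_size: float,
    rng: np.random.Generator,
    placed: list | None = None,
    enforce_separation: bool = False,
    separation_um: float = 4.0,
    retry_budget: int = 100,
    start_id: int = 0,
    boundary: RadialBoundary | None = None,
    depth_map: np.ndarray | None = None,
) -> list[TrueCell]:
    """Place one population inside the gray matter by rejection sampling.

    Marker flags are decided first: exactly ``round(fraction * count)``
    cells carry each co-expressed marker.  A candidate position is an
    (angle, depth) draw converted to a point along the ray from the canal
    centroid; it is accepted when the whole cell disk fits inside the gray
    matter (edge-depth margin) and lies outside the canal.  When separation
    is enforced, cells sharing a channel keep ``separation_um`` of
    edge-to-edge clearance so their binary components never merge, while
    cells of disjoint channels merely must not overlap, keeping spurious
    cross-channel colocalisation at zero.  ``placed`` entries are
    (x, y, r_px, channels) tuples shared across populations.  Each cell
    gets ``retry_budget`` attempts before a PlacementError is raised.

    ``boundary`` and ``depth_map`` may be passed to reuse per-section
    precomputations across populations.
    """
    if spec.count == 0:
        return []
    if boundary is None:
        boundary = RadialBoundary(geometry.gray_mask, geometry.canal_centroid,
                                  geometry.dorsal_up)
    depth = depth_map if depth_map is not None \
        else ndi.distance_transform_edt(geometry.gray_mask)
    h, w = geometry.gray_mask.shape
    cx, cy = geometry.canal_centroid
    canal_r_px = math.sqrt(geometry.canal_mask.sum() / math.pi)
    sep_px = separation_um / pixel_size

    # exact co-expression bookkeeping, decided before placement so the
    # separation rule can use each cell's true channel set
    flags = [set(spec.markers) for _ in range(spec.count)]
    for marker, fraction in spec.coexpression.items():
        k = round(fraction * spec.count)
        for j in rng.permutation(spec.count)[:k]:
            flags[j].add(marker)

    if placed is None:
        placed = []
    p_xy = np.array([(p[0], p[1]) for p in placed], dtype=float).reshape(-1, 2)
    p_r = np.array([p[2] for p in placed], dtype=float)
    p_ch = [p[3] for p in placed]

    cells: list[TrueCell] = []
    for i in range(spec.count):
        channels = frozenset(flags[i])
        # required edge-to-edge gap to each prior cell, by channel overlap
        p_gap = np.array([sep_px if channels & ch else 1.0 for ch in p_ch])
        ok = False
        for _ in range(retry_budget):
            theta = float(sample_angles(spec.angular, 1, rng)[0])
            u_depth = float(spec.radial.sample(1, rng)[0])
            d_um = float(rng.uniform(*spec.diameter_um))
            r_cell_px = (d_um / 2.0) / pixel_size
            rho = u_depth * float(boundary(theta))
            if not np.isfinite(rho):
                continue
            x = cx + rho * math.cos(math.radians(theta))
            y = cy - rho * math.sin(math.radians(theta))
            r_int, c_int = int(round(y)), int(round(x))
            if not (0 <= r_int < h and 0 <= c_int < w):
                continue
            if depth[r_int, c_int] < r_cell_px + 2.0:
                continue
            if rho < canal_r_px + r_cell_px + 1.0:
                continue
            if enforce_separation and p_xy.shape[0]:
                dists = np.hypot(p_xy[:, 0] - x, p_xy[:, 1] - y)
                if (dists - p_r - r_cell_px < p_gap).any():
                    continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"could not place cell {i} of population {spec.name!r} "
                f"within {retry_budget} attempts"
            )
        cells.append(TrueCell(
            id=start_id + i, x_px=x, y_px=y, diameter_um=d_um,
            markers=flags[i], angle_deg=theta,
            distance_um=rho * pixel_size, population=spec.name,
        ))
        p_xy = np.vstack([p_xy, [x, y]])
        p_r = np.append(p_r, r_cell_px)
        p_ch.append(channels)

    placed[:] = [(float(xy[0]), float(xy[1]), float(r), ch)
                 for xy, r, ch in zip(p_xy, p_r, p_ch)]
    return cells


def _truth_frame(cells: list[TrueCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "id": c.id, "x_px": c.x_px, "y_px": c.y_px,
            "diameter_um": c.diameter_um, "angle_deg": c.angle_deg,
            "distance_um": c.distance_um, "population": c.population,
        }
        for m in MARKERS:
            row[m] = m in c.markers
        rows.append(row)
    cols = ["id", "x_px", "y_px", "diameter_um", "angle_deg", "distance_um",
            "population", *MARKERS]
    return pd.DataFrame(rows, columns=cols)


def render_section(
    cells: list[TrueCell],
    geometry: SectionGeometry,
    config: SectionConfig,
    rng: np.random.Generator,
) -> tuple[dict, pd.DataFrame]:
    """Render placed cells into one 16-bit z-stack per channel.

    Each cell is a uniform disk of its specified diameter, added to every
    channel whose marker flag it carries, with its amplitude split across
    z-planes by ``z_weights``.  The background is a constant plus a smooth
    linear gradient; independent Gaussian noise is added per voxel; values
    are clipped to the unsigned 16-bit range.
    """
    h, w = config.image_size
    px = config.pixel_size
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    ramp = config.gradient_amplitude * (
        0.6 * xs / max(w - 1, 1) + 0.4 * ys / max(h - 1, 1))
    base = config.background + ramp

    stacks = {}
    for marker in MARKERS:
        planes = np.repeat(base[None, :, :], config.n_slices, axis=0).copy()
        for cell in cells:
            if marker not in cell.markers:
                continue
            r_px = (cell.diameter_um / 2.0) / px
            r0 = max(int(math.floor(cell.y_px - r_px)) - 1, 0)
            r1 = min(int(math.ceil(cell.y_px + r_px)) + 2, h)
            c0 = max(int(math.floor(cell.x_px - r_px)) - 1, 0)
            c1 = min(int(math.ceil(cell.x_px + r_px)) + 2, w)
            yy, xx = np.mgrid[r0:r1, c0:c1].astype(float)
            disk = (yy - cell.y_px) ** 2 + (xx - cell.x_px) ** 2 <= r_px**2
            for k, wz in enumerate(config.z_weights):
                planes[k, r0:r1, c0:c1] += config.amplitude * wz * disk
        if config.noise_sd > 0:
            planes = planes + rng.normal(0.0, config.noise_sd, planes.shape)
        voxels = np.clip(np.rint(planes), 0, U16_MAX).astype(np.uint16)
        stacks[marker] = ChannelStack(voxels, px, marker)
    return stacks, _truth_frame(cells)


def _section_count(mean: int, rng: np.random.Generator) -> int:
    """Per-section population size: Poisson around the configured mean,
    clipped to +/- 20% so crowded sections stay placeable."""
    lo = int(np.floor(0.8 * mean))
    hi = int(np.ceil(1.2 * mean))
    return int(np.clip(rng.poisson(mean), lo, hi))


def make_section(config: SectionConfig,
                 rng: np.random.Generator | None = None) -> SyntheticSection:
    """Geometry + placement + rendering for one section, deterministically.

    The same config (including its seed) always yields bit-identical images
    and truth tables; an external generator may be passed to embed the
    section in a larger seeded study.  With ``poisson_counts`` (default) the
    realised size of each population is Poisson around its configured count,
    emulating section-to-section variability; the ground-truth table always
    records the realised cells.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    geometry = make_section_geometry(config)
    boundary = RadialBoundary(geometry.gray_mask, geometry.canal_centroid,
                              geometry.dorsal_up)
    depth_map = ndi.distance_transform_edt(geometry.gray_mask)
    placed: list = []
    cells: list[TrueCell] = []
    for spec in config.populations:
        if config.poisson_counts:
            spec = replace(spec, count=_section_count(spec.count, rng))
        cells.extend(sample_population(
            spec, geometry, config.pixel_size, rng,
            placed=placed,
            enforce_separation=config.enforce_separation,
            separation_um=config.separation_um,
            retry_budget=config.retry_budget,
            start_id=len(cells),
            boundary=boundary,
            depth_map=depth_map,
        ))
    stacks, truth = render_section(cells, geometry, config, rng)
    return SyntheticSection(stacks, geometry, truth, config)


def _mask_polygon(mask: np.ndarray) -> np.ndarray:
    contours = find_contours(mask.astype(float), 0.5)
    longest = max(contours, key=len)
    # (row, col) -> (x, y)
    return np.column_stack([longest[:, 1], longest[:, 0]])


def _flatten_config(config: SectionConfig) -> dict:
    flat = {
        "image_height": config.image_size[0],
        "image_width": config.image_size[1],
        "n_slices": config.n_slices,
        "pixel_size_um": config.pixel_size,
        "canal_radius_um": config.canal_radius_um,
        "background": config.background,
        "gradient_amplitude": config.gradient_amplitude,
        "noise_sd": config.noise_sd,
        "amplitude": config.amplitude,
        "enforce_separation": config.enforce_separation,
        "separation_um": config.separation_um,
        "seed": config.seed,
        "n_populations": len(config.populations),
    }
    for spec in config.populations:
        flat[f"population_{spec.name}_count"] = spec.count
    return flat


def write_fixture(section: SyntheticSection, directory) -> None:
    """Write a section to disk as plain interchange files.

    One multi-page 16-bit TIFF per channel, gray/canal masks as single-page
    TIFFs plus boundary polygons as vertex CSVs, the ground truth as CSV,
    and the configuration as a flat key=value text file.  TIFF round-trips
    are bit-exact.  The directory must already exist.
    """
    from pathlib import Path

    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"directory {directory} does not exist")
    for marker, stack in section.stacks.items():
        tifffile.imwrite(directory / f"{marker}.tif", stack.voxels,
                         photometric="minisblack")
    tifffile.imwrite(directory / "gray_mask.tif",
                     section.geometry.gray_mask.astype(np.uint8))
    tifffile.imwrite(directory / "canal_mask.tif",
                     section.geometry.canal_mask.astype(np.uint8))
    for name, mask in (("gray", section.geometry.gray_mask),
                       ("canal", section.geometry.canal_mask)):
        poly = _mask_polygon(mask)
        pd.DataFrame(poly, columns=["x", "y"]).to_csv(
            directory / f"{name}_roi.csv", index=False)
    section.truth.to_csv(directory / "truth.csv", index=False)
    with open(directory / "config.txt", "w") as fh:
        for key, value in _flatten_config(section.config).items():
            fh.write(f"{key}={value}\n")


def read_fixture(directory):
    """Read back a written fixture: (stacks, geometry, truth)."""
    from pathlib import Path

    directory = Path(directory)
    with open(directory / "config.txt") as fh:
        flat = dict(line.strip().split("=", 1) for line in fh if line.strip())
    px = float(flat["pixel_size_um"])
    stacks = {
        m: ChannelStack(tifffile.imread(directory / f"{m}.tif"), px, m)
        for m in MARKERS
    }
    gray = tifffile.imread(directory / "gray_mask.tif").astype(bool)
    canal = tifffile.imread(directory / "canal_mask.tif").astype(bool)
    geometry = SectionGeometry(gray, canal, roi_centroid(canal))
    truth = pd.read_csv(directory / "truth.csv")
    return stacks, geometry, truth
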