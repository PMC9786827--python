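"""Disc ellipse geometry and the 24-sector partition.

Conventions (shared by the generator and the colourimetry stage):

* Coordinates are (row, col), 0-based, origin at the top-left.
* Canonical orientation is the right-eye orientation with the temporal side
  toward increasing column.  Left-eye rasters are mirrored horizontally
  before sector geometry is applied (see ``segmentation.mirror_normalize``).
* Angles are measured from the horizontal temporal axis (+col),
  counter-clockwise on the retina, so superior (up, decreasing row) is +90
  degrees and inferior is 270 degrees.
* The 24 areas of the nerve are 3 equal-area concentric elliptical annuli
  crossed with 8 wedges of 45 degrees.  Sector index = annulus * 8 + wedge,
  annulus 0 outermost, wedge 0 centred on the temporal axis.  Sector 0 is
  therefore the temporal-horizontal wedge of the outer annulus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_WEDGES = 8
N_ANNULI = 3
N_SECTORS = N_WEDGES * N_ANNULI

#: wedge indices centred on the vertical poles
SUPERIOR_WEDGE = 2
INFERIOR_WEDGE = 6

#: relative severity effect per wedge (temporal, sup-temporal, superior, ...)
WEDGE_SEVERITY_PROFILE = np.array([0.2, 0.6, 1.0, 0.6, 0.2, 0.6, 1.0, 0.6])

# equal-area annulus boundaries in normalised elliptical radius
ANNULUS_EDGES = np.sqrt([1.0, 2.0 / 3.0, 1.0 / 3.0])  # outer edge of each ring


@dataclass
class Ellipse:
    """Axis-aligned-by-default ellipse: centre (row, col), semi-axes in px.

    ``a`` is the horizontal (column) semi-axis, ``b`` the vertical (row)
    semi-axis, ``theta`` a counter-clockwise rotation in radians (zero for
    generated discs, small for fitted ones).
    """

    center: tuple[float, float]
    a: float
    b: float
    theta: float = 0.0

    @property
    def area_px(self) -> float:
        return float(np.pi * self.a * self.b)

    @property
    def r_major(self) -> float:
        return float(max(self.a, self.b))

    def scaled(self, factor: float) -> "Ellipse":
        return Ellipse(self.center, self.a * factor, self.b * factor, self.theta)


def from_area(area_px: float, axis_ratio: float, center: tuple[float, float],
              theta: float = 0.0) -> Ellipse:
    """Ellipse of given pixel area with vertical/horizontal ratio ``axis_ratio``."""
    a = float(np.sqrt(area_px / (np.pi * axis_ratio)))
    return Ellipse(center, a, a * axis_ratio, theta)


def normalized_coords(shape: tuple[int, int], ellipse: Ellipse):
    """Per-pixel normalised radius and retinal angle for an ellipse.

    Returns ``(rho, theta_deg)``: rho = 1 on the ellipse boundary; theta in
    [0, 360) measured from the temporal (+col) axis, counter-clockwise
    (superior at 90).
    """
    rows, cols = np.indices(shape)
    dr = rows - ellipse.center[0]
    dc = cols - ellipse.center[1]
    if ellipse.theta != 0.0:
        ct, st = np.cos(-ellipse.theta), np.sin(-ellipse.theta)
        dc, dr = ct * dc - st * dr, st * dc + ct * dr
    rho = np.sqrt((dc / ellipse.a) ** 2 + (dr / ellipse.b) ** 2)
    theta = np.degrees(np.arctan2(-dr, dc)) % 360.0
    return rho, theta


def ellipse_mask(shape: tuple[int, int], ellipse: Ellipse) -> np.ndarray:
    rho, _ = normalized_coords(shape, ellipse)
    return rho <= 1.0


def wedge_index(theta_deg: np.ndarray) -> np.ndarray:
    """45-degree wedge index, wedge 0 centred on the temporal axis."""
    return (np.floor(((theta_deg + 22.5) % 360.0) / 45.0)).astype(int)


def annulus_index(rho: np.ndarray) -> np.ndarray:
    """0 = outer ring, 1 = middle, 2 = inner; rings have equal area."""
    idx = np.full(rho.shape, -1, dtype=int)
    idx[rho <= ANNULUS_EDGES[0]] = 0
    idx[rho <= ANNULUS_EDGES[1]] = 1
    idx[rho <= ANNULUS_EDGES[2]] = 2
    return idx


def sector_map(shape: tuple[int, int], ellipse: Ellipse) -> np.ndarray:
    """24-sector label image; -1 outside the disc ellipse."""
    rho, theta = normalized_coords(shape, ellipse)
    ann = annulus_index(rho)
    wed = wedge_index(theta)
    out = np.where(ann >= 0, ann * N_WEDGES + wed, -1)
    return out


def sector_severity_profile() -> np.ndarray:
    """Per-sector relative severity effect (length 24), tiled over annuli."""
    return np.tile(WEDGE_SEVERITY_PROFILE, N_ANNULI)


def supinf_sector_mask() -> np.ndarray:
    """Boolean length-24 mask of the superior and inferior wedges."""
    wedges = np.tile(np.arange(N_WEDGES), N_ANNULI)
    return (wedges == SUPERIOR_WEDGE) | (wedges == INFERIOR_WEDGE)


def cup_geometry(cup_fraction: float, cup_elongation: float
                 ) -> tuple[float, float, float] | None:
    """Cup ellipse relative to the disc semi-axes.

    Returns ``(dx_over_a, ac_over_a, bc_over_b)``: temporal offset of the cup
    centre and the cup semi-axes, all as fractions of the corresponding disc
    semi-axis.  The cup has area ``cup_fraction`` times the disc's and a
    vertical/horizontal ratio ``(1 + cup_elongation)`` times the disc's, and
    is offset toward the temporal side while remaining inside the disc.
    """
    if cup_fraction <= 0:
        return None
    ac = float(np.sqrt(cup_fraction / (1.0 + cup_elongation)))
    bc = float(np.sqrt(cup_fraction * (1.0 + cup_elongation)))
    dx = min(0.12, max(0.0, 1.0 - ac - 0.03))
    return dx, ac, bc


def cup_coverage_fractions(axis_ratio: float, cup_fraction: float,
                           cup_elongation: float, n_grid: int = 121) -> np.ndarray:
    """Fraction of each of the 24 sectors covered by the cup ellipse.

    Pure geometry (no raster), evaluated on a uniform grid over the disc in
    pixel-space proportions so it matches what a renderer would produce.
    """
    geom = cup_geometry(cup_fraction, cup_elongation)
    out = np.zeros(N_SECTORS)
    u = np.linspace(-1, 1, n_grid)
    uu, vv = np.meshgrid(u, u)  # uu = dc/a, vv = dr/b
    rho = np.sqrt(uu ** 2 + vv ** 2)
    inside = rho <= 1.0
    theta = np.degrees(np.arctan2(-vv * axis_ratio, uu)) % 360.0
    sectors = annulus_index(rho) * N_WEDGES + wedge_index(theta)
    counts = np.bincount(sectors[inside], minlength=N_SECTORS)
    if geom is None:
        return out
    dx, ac, bc = geom
    in_cup = inside & (((uu - dx) / ac) ** 2 + (vv / bc) ** 2 <= 1.0)
    cup_counts = np.bincount(sectors[in_cup], minlength=N_SECTORS)
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, cup_counts / np.maximum(counts, 1), 0.0)
    return out


def vertical_cd_from_geometry(cup_fraction: float, cup_elongation: float) -> float:
    """Ground-truth vertical cup/disc ratio of the generator's geometry.

    The cup ellipse has area ``cup_fraction`` times the disc and a
    vertical/horizontal axis ratio ``(1 + cup_elongation)`` times the disc's,
    so the ratio of vertical semi-axes is sqrt(cup_fraction*(1+elongation)).
    """
    if cup_fraction <= 0:
        return 0.0
    return float(min(1.0, np.sqrt(cup_fraction * (1.0 + cup_elongation))))
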