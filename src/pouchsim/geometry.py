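"""Folded-2D-grid crypt-villus topology on a cylindrical pouch.

The epithelial surface of an ileal pouch is modeled as a cylinder tiled
with crypt-villus units.  Each unit carries two square prisms -- a crypt
(invaginated, pointing into the wall) and a villus (projecting into the
lumen) -- and each prism is represented by its ``n_faces`` lateral faces
unwrapped into 2D grids of ``rows x face_width`` lattice sites.  Folding
rules stitch the faces back together:

* within a face, sites have von Neumann row/col neighbors;
* a face's col edges continue onto the adjacent face of the same prism;
* one *cap row* per prism closes the villus tip / crypt valley by joining
  opposite faces (mirrored columns);
* the villus base row crosses the inter-unit flat to the crypt mouth row
  of the offset neighboring unit (faces are paired with the four lattice
  directions; the circumferential direction wraps, the axial one does
  not -- at the axial cut ends the flat folds back onto the same unit).

Every site is addressed by a :class:`GridCoord` and, for array kernels, by
a dense integer index maintained by :class:`GeometryIndex`.  Unit heights
may change between timesteps via :func:`resize_unit`; the index is rebuilt
and per-site payloads are remapped site-for-site on surviving rows.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

logger = logging.getLogger("pouchsim")

__all__ = [
    "Component",
    "GridCoord",
    "CryptVillusUnit",
    "PouchGeometry",
    "GeometryIndex",
    "build_pouch",
    "lattice_pouch",
    "neighbor_sites",
    "to_3d",
    "positions_3d",
    "resize_unit",
    "apply_resizes",
    "axial_position_mm",
]

# Packing limits for the stable 64-bit site key (unit, comp, face, row, col).
_ROW_BITS = 10
_COL_BITS = 10
_MAX_ROWS = 1 << _ROW_BITS
_MAX_COLS = 1 << _COL_BITS

# Lattice direction associated with each of the four prism faces:
# (delta_axial, delta_circumferential).  Face f of a villus looks across
# the inter-unit flat toward the crypt of the unit in direction DIRS[f].
DIRS = ((1, 0), (0, 1), (-1, 0), (0, -1))


class Component(IntEnum):
    CRYPT = 0
    VILLUS = 1


@dataclass(frozen=True)
class GridCoord:
    """Address of one lattice site: (unit, prism, face, row, col).

    Row 0 is the crypt base for CRYPT and the villus base for VILLUS,
    increasing toward the crypt mouth / villus tip.  Rows beyond the
    regular height are cap rows (tip / valley closure).
    """

    unit_index: int
    component: Component
    face: int
    row: int
    col: int


@dataclass
class CryptVillusUnit:
    """Dimensions of one crypt-villus unit (two prisms of unwrapped faces)."""

    villus_height: int = 48
    crypt_depth: int = 12
    face_width: int = 6
    n_faces: int = 4
    cap_rows: int = 1

    def __post_init__(self) -> None:
        if self.villus_height < 1 or self.crypt_depth < 1 or self.face_width < 1:
            raise ValueError(
                "crypt-villus unit needs villus_height, crypt_depth and "
                f"face_width >= 1, got {self}"
            )
        if self.cap_rows < 1:
            raise ValueError("cap_rows must be >= 1 (the fold must close)")

    def height(self, component: Component) -> int:
        return self.crypt_depth if component == Component.CRYPT else self.villus_height

    def rows(self, component: Component) -> int:
        """Stored rows of one face: regular height plus cap rows."""
        return self.height(component) + self.cap_rows

    def n_sites(self) -> int:
        return self.n_faces * self.face_width * (
            self.rows(Component.CRYPT) + self.rows(Component.VILLUS)
        )


@dataclass
class PouchGeometry:
    """A cylinder tiled with an n_axial x n_circ lattice of units.

    Unit indices are row-major, axial-then-circumferential; the
    circumferential direction wraps, the axial one does not.
    """

    diameter_cm: float
    length_cm: float
    unit_spacing_mm: float
    n_axial: int
    n_circ: int
    units: List[CryptVillusUnit] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.n_axial * self.n_circ

    def unit_index(self, axial: int, circ: int) -> int:
        return axial * self.n_circ + circ % self.n_circ

    def unit_axial(self, unit_index: int) -> int:
        return unit_index // self.n_circ

    def unit_circ(self, unit_index: int) -> int:
        return unit_index % self.n_circ

    def neighbor_unit(self, unit_index: int, direction: int) -> Optional[int]:
        """Unit in lattice direction DIRS[direction], or None past an axial end."""
        da, dc = DIRS[direction]
        ax = self.unit_axial(unit_index) + da
        if ax < 0 or ax >= self.n_axial:
            return None
        return self.unit_index(ax, self.unit_circ(unit_index) + dc)

    def total_sites(self) -> int:
        return sum(u.n_sites() for u in self.units)


def build_pouch(
    diameter_cm: float,
    length_cm: float,
    unit_spacing_mm: float,
    template: Optional[CryptVillusUnit] = None,
) -> PouchGeometry:
    """Tile a cylindrical pouch with copies of a crypt-villus unit template.

    ``n_circ = floor(pi * diameter_cm * 10 / unit_spacing_mm)`` and
    ``n_axial = floor(length_cm * 10 / unit_spacing_mm)``; both must come
    out >= 1 (a spacing wider than the circumference is rejected).
    """
    if diameter_cm <= 0 or length_cm <= 0 or unit_spacing_mm <= 0:
        raise ValueError(
            "pouch dimensions must be positive, got "
            f"diameter={diameter_cm} cm, length={length_cm} cm, "
            f"spacing={unit_spacing_mm} mm"
        )
    template = template if template is not None else CryptVillusUnit()
    if template.n_faces != 4:
        raise ValueError(
            "the folded topology is realized for 4-faced prisms; "
            f"got n_faces={template.n_faces}"
        )
    n_circ = int(math.floor(math.pi * diameter_cm * 10.0 / unit_spacing_mm))
    n_axial = int(math.floor(length_cm * 10.0 / unit_spacing_mm))
    if n_circ < 1:
        raise ValueError(
            f"unit spacing {unit_spacing_mm} mm exceeds the pouch "
            f"circumference {math.pi * diameter_cm * 10.0:.3f} mm"
        )
    if n_axial < 1:
        raise ValueError(
            f"unit spacing {unit_spacing_mm} mm exceeds the pouch length "
            f"{length_cm * 10.0:.3f} mm"
        )
    units = [copy.deepcopy(template) for _ in range(n_axial * n_circ)]
    return PouchGeometry(
        diameter_cm=diameter_cm,
        length_cm=length_cm,
        unit_spacing_mm=unit_spacing_mm,
        n_axial=n_axial,
        n_circ=n_circ,
        units=units,
    )


def lattice_pouch(
    n_axial: int,
    n_circ: int,
    template: Optional[CryptVillusUnit] = None,
    unit_spacing_mm: float = 0.5,
) -> PouchGeometry:
    """Build a pouch directly from lattice dimensions (desk-scale runs).

    Physical dimensions are synthesized so that the lattice is exactly
    n_axial x n_circ at the given spacing.
    """
    if n_axial < 1 or n_circ < 1:
        raise ValueError("lattice dimensions must be >= 1")
    template = template if template is not None else CryptVillusUnit()
    if template.n_faces != 4:
        raise ValueError("the folded topology is realized for 4-faced prisms")
    units = [copy.deepcopy(template) for _ in range(n_axial * n_circ)]
    return PouchGeometry(
        diameter_cm=n_circ * unit_spacing_mm / (10.0 * math.pi),
        length_cm=n_axial * unit_spacing_mm / 10.0,
        unit_spacing_mm=unit_spacing_mm,
        n_axial=n_axial,
        n_circ=n_circ,
        units=units,
    )


def axial_position_mm(geom: PouchGeometry, unit_index: int) -> float:
    """Distance of a unit from the proximal (inflow) end, in mm."""
    if not 0 <= unit_index < geom.n_units:
        raise IndexError(f"unit_index {unit_index} out of range 0..{geom.n_units - 1}")
    return geom.unit_axial(unit_index) * geom.unit_spacing_mm


class GeometryIndex:
    """Dense site enumeration plus the folded neighbor table.

    Site order is unit-major, then component (CRYPT before VILLUS), then
    face, row, col.  ``neighbors`` has one row per site with 4 slots
    (down, up, col-, col+ after folding); absent neighbors (axial
    boundary flats) are -1.  ``site_key`` packs (unit, comp, face, row,
    col) into a stable uint64 used by the counter-based RNG, so a site
    keeps its identity across re-partitionings and resizes.
    """

    DOWN, UP, LEFT, RIGHT = 0, 1, 2, 3

    def __init__(self, geom: PouchGeometry):
        self.geom = geom
        self._build()

    # -- construction -------------------------------------------------

    def _build(self) -> None:
        geom = self.geom
        blocks = []  # (unit, comp, face, rows, width, offset)
        offset = 0
        self._block_offset: Dict[Tuple[int, int, int], int] = {}
        for u, unit in enumerate(geom.units):
            if unit.rows(Component.VILLUS) > _MAX_ROWS or unit.face_width > _MAX_COLS:
                raise ValueError("unit dimensions exceed site-key packing limits")
            for comp in (Component.CRYPT, Component.VILLUS):
                rows = unit.rows(comp)
                for f in range(unit.n_faces):
                    blocks.append((u, int(comp), f, rows, unit.face_width, offset))
                    self._block_offset[(u, int(comp), f)] = offset
                    offset += rows * unit.face_width
        self.n_sites = offset

        unit_a = np.empty(offset, dtype=np.int32)
        comp_a = np.empty(offset, dtype=np.int8)
        face_a = np.empty(offset, dtype=np.int8)
        row_a = np.empty(offset, dtype=np.int32)
        col_a = np.empty(offset, dtype=np.int32)
        for u, comp, f, rows, w, off in blocks:
            n = rows * w
            sl = slice(off, off + n)
            unit_a[sl] = u
            comp_a[sl] = comp
            face_a[sl] = f
            row_a[sl] = np.repeat(np.arange(rows, dtype=np.int32), w)
            col_a[sl] = np.tile(np.arange(w, dtype=np.int32), rows)
        self.site_unit = unit_a
        self.site_comp = comp_a
        self.site_face = face_a
        self.site_row = row_a
        self.site_col = col_a

        n_faces = geom.units[0].n_faces if geom.units else 4
        key = (unit_a.astype(np.uint64) * 2 + comp_a.astype(np.uint64)) * np.uint64(
            n_faces
        ) + face_a.astype(np.uint64)
        key = (key << np.uint64(_ROW_BITS)) | row_a.astype(np.uint64)
        key = (key << np.uint64(_COL_BITS)) | col_a.astype(np.uint64)
        self.site_key = key

        self._build_neighbors(blocks)
        self._build_derived()

    def _site(self, u: int, comp: int, f: int, r, c) -> np.ndarray:
        unit = self.geom.units[u]
        w = unit.face_width
        return self._block_offset[(u, comp, f)] + np.asarray(r) * w + np.asarray(c)

    def _build_neighbors(self, blocks) -> None:
        geom = self.geom
        nb = np.full((self.n_sites, 4), -1, dtype=np.int64)
        for u, comp, f, rows, w, off in blocks:
            unit = geom.units[u]
            F = unit.n_faces
            h = unit.height(Component(comp))
            r = np.repeat(np.arange(rows), w)
            c = np.tile(np.arange(w), rows)
            idx = off + r * w + c
            mirror = w - 1 - c

            # --- col neighbors: continue onto adjacent faces of the prism
            left = np.where(
                c > 0,
                self._site(u, comp, f, r, np.maximum(c - 1, 0)),
                self._site(u, comp, (f - 1) % F, r, w - 1),
            )
            right = np.where(
                c < w - 1,
                self._site(u, comp, f, r, np.minimum(c + 1, w - 1)),
                self._site(u, comp, (f + 1) % F, r, 0),
            )
            nb[idx, self.LEFT] = left
            nb[idx, self.RIGHT] = right

            # --- row neighbors within the regular grid
            down = np.full(rows * w, -1, dtype=np.int64)
            up = np.full(rows * w, -1, dtype=np.int64)
            reg = r < h
            m = reg & (r > 0)
            down[m] = self._site(u, comp, f, r[m] - 1, c[m])
            m = reg & (r < h - 1)
            up[m] = self._site(u, comp, f, r[m] + 1, c[m])

            # --- cap rows: chained above the tip (villus) / below the base
            # (crypt); the top cap row joins the opposite face, mirrored.
            cap = ~reg
            k = r - h  # cap row ordinal 0..cap_rows-1
            anchor = h - 1 if comp == int(Component.VILLUS) else 0
            inner = cap & (k == 0)
            outer = cap & (k == unit.cap_rows - 1)
            if comp == int(Component.VILLUS):
                # "down" points toward the tissue base: cap row 0 attaches
                # to regular row h-1, deeper cap rows chain upward.
                down[inner] = self._site(u, comp, f, anchor, c[inner])
                m = cap & (k > 0)
                down[m] = self._site(u, comp, f, r[m] - 1, c[m])
                m = cap & (k < unit.cap_rows - 1)
                up[m] = self._site(u, comp, f, r[m] + 1, c[m])
                up[outer & (k == unit.cap_rows - 1)] = self._site(
                    u, comp, (f + F // 2) % F, h + unit.cap_rows - 1,
                    mirror[outer],
                )
                # regular top row's "up" is the first cap row
                m = reg & (r == h - 1)
                up[m] = self._site(u, comp, f, h, c[m])
            else:
                # crypt valley: cap row 0 attaches below regular row 0;
                # "up" points toward the mouth.
                up[inner] = self._site(u, comp, f, anchor, c[inner])
                m = cap & (k > 0)
                up[m] = self._site(u, comp, f, r[m] - 1, c[m])
                m = cap & (k < unit.cap_rows - 1)
                down[m] = self._site(u, comp, f, r[m] + 1, c[m])
                down[outer] = self._site(
                    u, comp, (f + F // 2) % F, h + unit.cap_rows - 1,
                    mirror[outer],
                )
                # regular base row's "down" is the first cap (valley) row
                m = reg & (r == 0)
                down[m] = self._site(u, comp, f, h, c[m])

            # --- inter-unit flat: villus base <-> neighbor crypt mouth.
            # At the axial cut ends of the cylinder the flat folds back
            # onto the same unit (villus base <-> own crypt mouth), so no
            # column of the lattice is left without a connection to a
            # proliferative compartment.
            v = geom.neighbor_unit(u, f)
            g = (f + F // 2) % F if v is not None else f
            v = u if v is None else v
            if comp == int(Component.VILLUS):
                m = reg & (r == 0)
                d_nbr = geom.units[v].crypt_depth
                down[m] = self._site(
                    v, int(Component.CRYPT), g, d_nbr - 1, mirror[m]
                )
            else:
                m = reg & (r == h - 1)
                up[m] = self._site(
                    v, int(Component.VILLUS), g, 0, mirror[m]
                )
            nb[idx, self.DOWN] = down
            nb[idx, self.UP] = up
        self.neighbors = nb

    def _build_derived(self) -> None:
        """Per-site helper arrays used by the step kernels."""
        geom = self.geom
        comp = self.site_comp
        row = self.site_row
        h = np.empty(self.n_sites, dtype=np.int32)  # regular height of own prism
        unit_crypt_depth = np.array(
            [u.crypt_depth for u in geom.units], dtype=np.int32
        )
        unit_villus_height = np.array(
            [u.villus_height for u in geom.units], dtype=np.int32
        )
        h[:] = np.where(
            comp == int(Component.CRYPT),
            unit_crypt_depth[self.site_unit],
            unit_villus_height[self.site_unit],
        )
        self.site_height = h
        is_cap = row >= h
        self.site_is_cap = is_cap
        k = np.where(is_cap, row - h, 0)
        depth_here = unit_crypt_depth[self.site_unit]
        # Elevation: crypt valley lowest, crypt mouth = depth-1, villus base
        # = depth (across the flat), villus tip cap highest.  Drives the
        # conveyor-belt migration ordering.
        elev = np.where(
            comp == int(Component.CRYPT),
            np.where(is_cap, -(k + 1), row),
            depth_here + np.where(is_cap, h + k, row),
        )
        self.site_elevation = elev.astype(np.int32)
        self.site_axial = (self.site_unit // geom.n_circ).astype(np.int32)

    # -- coordinate conversion ----------------------------------------

    def coord_to_index(self, c: GridCoord) -> int:
        self._check_coord(c)
        unit = self.geom.units[c.unit_index]
        return int(
            self._block_offset[(c.unit_index, int(c.component), c.face)]
            + c.row * unit.face_width
            + c.col
        )

    def index_to_coord(self, i: int) -> GridCoord:
        if not 0 <= i < self.n_sites:
            raise IndexError(f"site index {i} out of range")
        return GridCoord(
            int(self.site_unit[i]),
            Component(int(self.site_comp[i])),
            int(self.site_face[i]),
            int(self.site_row[i]),
            int(self.site_col[i]),
        )

    def _check_coord(self, c: GridCoord) -> None:
        if not 0 <= c.unit_index < self.geom.n_units:
            raise IndexError(f"invalid unit_index {c.unit_index}")
        unit = self.geom.units[c.unit_index]
        if not 0 <= c.face < unit.n_faces:
            raise IndexError(f"invalid face {c.face}")
        if not 0 <= c.row < unit.rows(c.component):
            raise IndexError(
                f"invalid row {c.row} for {c.component.name} of unit "
                f"{c.unit_index} (rows 0..{unit.rows(c.component) - 1})"
            )
        if not 0 <= c.col < unit.face_width:
            raise IndexError(f"invalid col {c.col}")

    # -- masks used by rules ------------------------------------------

    def crypt_base_mask(self, n_rows: int) -> np.ndarray:
        """Crypt valley cap plus the lowest ``n_rows`` regular crypt rows."""
        crypt = self.site_comp == int(Component.CRYPT)
        return crypt & (self.site_is_cap | (self.site_row < n_rows))

    def villus_tip_mask(self, n_rows: int) -> np.ndarray:
        """Villus tip cap plus the top ``n_rows`` regular villus rows."""
        vill = self.site_comp == int(Component.VILLUS)
        top = self.site_row >= self.site_height - n_rows
        return vill & (self.site_is_cap | top)


def neighbor_sites(index, c: GridCoord) -> List[GridCoord]:
    """Von Neumann neighborhood of a site after folding.

    Accepts a :class:`GeometryIndex` (preferred) or a
    :class:`PouchGeometry` (an index is built on the fly).
    """
    if isinstance(index, PouchGeometry):
        index = GeometryIndex(index)
    i = index.coord_to_index(c)
    return [
        index.index_to_coord(int(j)) for j in index.neighbors[i] if j >= 0
    ]


# -- 3D embedding (rendering only; no physics depends on it) -----------

def positions_3d(
    index: GeometryIndex, cell_diameter_um: float = 10.0
) -> np.ndarray:
    """Deterministic (n_sites, 3) embedding in mm.

    Unit centers sit on the cylinder surface; villus sites are displaced
    luminally (outward) by row * cell_diameter, crypt sites inward; the
    villus prism of a unit is offset half a spacing axially and
    tangentially from its crypt (the alternating-prism pattern); faces
    are offset laterally by the prism half-width.
    """
    geom = index.geom
    cd = cell_diameter_um / 1000.0  # mm
    R = geom.diameter_cm * 10.0 / 2.0
    spacing = geom.unit_spacing_mm

    unit = index.site_unit
    comp = index.site_comp.astype(np.int64)
    face = index.site_face.astype(np.int64)
    row = index.site_row
    col = index.site_col
    h = index.site_height
    is_cap = index.site_is_cap
    k = np.where(is_cap, row - h, 0)
    w = np.array([u.face_width for u in geom.units])[unit]

    ax = unit // geom.n_circ
    ci = unit % geom.n_circ
    z_c = ax * spacing + np.where(comp == 1, spacing / 2.0, 0.0)
    arc_c = ci * spacing + np.where(comp == 1, spacing / 2.0, 0.0)

    da = np.array([d[0] for d in DIRS])[face]
    dc = np.array([d[1] for d in DIRS])[face]
    half = w * cd / 2.0
    lat = (col + 0.5 - w / 2.0) * cd
    z = z_c + da * half + (-dc) * lat
    arc = arc_c + dc * half + da * lat

    r_off = np.where(
        comp == 1,
        np.where(is_cap, (h + k) * cd, row * cd),
        np.where(is_cap, -(h + 1 + k) * cd, -(h - row) * cd),
    )
    rho = R + r_off
    theta = 2.0 * math.pi * ci / geom.n_circ + (arc - ci * spacing) / R
    return np.column_stack(
        (rho * np.cos(theta), rho * np.sin(theta), z)
    )


def to_3d(
    index, c: GridCoord, cell_diameter_um: float = 10.0
) -> Tuple[float, float, float]:
    """3D position (mm) of one site; see :func:`positions_3d`."""
    if isinstance(index, PouchGeometry):
        index = GeometryIndex(index)
    i = index.coord_to_index(c)
    # scalar path reuses the vector embedding for consistency
    p = positions_3d(index, cell_diameter_um)[i]
    return float(p[0]), float(p[1]), float(p[2])


# -- dynamic resizing ----------------------------------------------------

def apply_resizes(
    index: GeometryIndex,
    requests: Dict[Tuple[int, Component], int],
    payloads: Dict[str, Tuple[np.ndarray, object]],
    occupied: np.ndarray,
) -> Tuple[GeometryIndex, Dict[str, np.ndarray], Dict[Tuple[int, Component], int]]:
    """Resize several (unit, component) prisms between timesteps.

    Growth appends empty rows at the villus tip / crypt mouth; shrinking
    deletes empty top rows only -- a request that would delete an occupied
    row is clamped to (highest occupied row + 1) and logged.  Cap rows are
    retained and renumbered.  ``payloads`` maps name -> (array aligned to
    the old index along axis -1's site dimension at axis 0 or 1, fill
    value for newly created sites); all payloads are remapped
    site-for-site on surviving sites.

    Returns (new index, remapped payloads, actual new heights).
    """
    geom = index.geom
    actual: Dict[Tuple[int, Component], int] = {}
    new_geom = PouchGeometry(
        diameter_cm=geom.diameter_cm,
        length_cm=geom.length_cm,
        unit_spacing_mm=geom.unit_spacing_mm,
        n_axial=geom.n_axial,
        n_circ=geom.n_circ,
        units=[copy.deepcopy(u) for u in geom.units],
    )
    for (u, comp), new_h in requests.items():
        unit = new_geom.units[u]
        old_h = unit.height(comp)
        if new_h < 1:
            raise ValueError(f"new height must be >= 1, got {new_h}")
        if new_h < old_h:
            # clamp to the highest occupied regular row + 1
            mask = (
                (index.site_unit == u)
                & (index.site_comp == int(comp))
                & (~index.site_is_cap)
                & occupied
            )
            if mask.any():
                top_occ = int(index.site_row[mask].max())
                if new_h < top_occ + 1:
                    logger.warning(
                        "resize of unit %d %s to %d rows clamped to %d "
                        "(row %d occupied)",
                        u, comp.name, new_h, top_occ + 1, top_occ,
                    )
                    new_h = top_occ + 1
        if comp == Component.CRYPT:
            unit.crypt_depth = new_h
        else:
            unit.villus_height = new_h
        actual[(u, comp)] = new_h

    new_index = GeometryIndex(new_geom)

    # Remap by stable identity: regular rows keep their row number, cap
    # rows are renumbered with the new height.
    old_h_arr = index.site_height
    mapped_row = np.where(
        index.site_is_cap,
        _new_height_of(new_index, index) + (index.site_row - old_h_arr),
        index.site_row,
    )
    survives = index.site_is_cap | (mapped_row < _new_height_of(new_index, index))
    new_key = _pack_keys(
        index.site_unit, index.site_comp, index.site_face, mapped_row,
        index.site_col, geom.units[0].n_faces,
    )
    order = np.argsort(new_index.site_key, kind="stable")
    pos = np.searchsorted(new_index.site_key[order], new_key[survives])
    dest = order[pos]

    out: Dict[str, np.ndarray] = {}
    for name, (arr, fill) in payloads.items():
        if arr.ndim == 1:
            new_arr = np.full(new_index.n_sites, fill, dtype=arr.dtype)
            new_arr[dest] = arr[survives]
        else:  # (channels, n_sites)
            new_arr = np.full(
                (arr.shape[0], new_index.n_sites), fill, dtype=arr.dtype
            )
            new_arr[:, dest] = arr[:, survives]
        out[name] = new_arr
    return new_index, out, actual


def _new_height_of(new_index: GeometryIndex, old_index: GeometryIndex) -> np.ndarray:
    """New regular height of each old site's prism, aligned to old sites."""
    geom = new_index.geom
    cd = np.array([u.crypt_depth for u in geom.units], dtype=np.int32)
    vh = np.array([u.villus_height for u in geom.units], dtype=np.int32)
    return np.where(
        old_index.site_comp == int(Component.CRYPT),
        cd[old_index.site_unit],
        vh[old_index.site_unit],
    ).astype(np.int32)


def _pack_keys(unit, comp, face, row, col, n_faces: int) -> np.ndarray:
    key = (
        np.asarray(unit, dtype=np.uint64) * 2 + np.asarray(comp, dtype=np.uint64)
    ) * np.uint64(n_faces) + np.asarray(face, dtype=np.uint64)
    key = (key << np.uint64(_ROW_BITS)) | np.asarray(row, dtype=np.uint64)
    key = (key << np.uint64(_COL_BITS)) | np.asarray(col, dtype=np.uint64)
    return key


def resize_unit(
    index: GeometryIndex,
    unit_index: int,
    component: Component,
    new_height: int,
    payloads: Dict[str, Tuple[np.ndarray, object]],
    occupied: np.ndarray,
) -> Tuple[GeometryIndex, Dict[str, np.ndarray], int]:
    """Resize one prism; see :func:`apply_resizes` for semantics."""
    new_index, out, actual = apply_resizes(
        index, {(unit_index, component): new_height}, payloads, occupied
    )
    return new_index, out, actual[(unit_index, component)]
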