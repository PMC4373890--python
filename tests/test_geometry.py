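"""Folded crypt-villus topology: construction, adjacency, embedding, resizing."""

import math

import numpy as np
import pytest

from pouchsim import (
    Component,
    CryptVillusUnit,
    GeometryIndex,
    GridCoord,
    build_pouch,
    lattice_pouch,
    neighbor_sites,
    positions_3d,
    resize_unit,
    to_3d,
)
from pouchsim.geometry import apply_resizes, axial_position_mm

# ----------------------------------------------------------------------
# brute-force fold oracle: adjacency built straight from the fold rules,
# independently of the package's vectorized construction


def bruteforce_adjacency(n_axial, n_circ, h_v, h_c, w):
    """Enumerate the folded adjacency of a lattice of 4-faced units with
    one cap row per prism, as a dict {coord: set(coord)}."""
    DIRS = ((1, 0), (0, 1), (-1, 0), (0, -1))
    CRYPT, VILLUS = 0, 1

    def unit_at(u, f):
        ax, ci = u // n_circ, u % n_circ
        da, dc = DIRS[f]
        ax += da
        if ax < 0 or ax >= n_axial:
            return None
        return ax * n_circ + (ci + dc) % n_circ

    edges = set()

    def add(a, b):
        edges.add(frozenset((a, b)))

    for u in range(n_axial * n_circ):
        for comp, H in ((CRYPT, h_c), (VILLUS, h_v)):
            for f in range(4):
                for r in range(H + 1):  # rows + 1 cap row
                    for c in range(w):
                        me = (u, comp, f, r, c)
                        # col neighbors, wrapping onto adjacent faces
                        if c + 1 < w:
                            add(me, (u, comp, f, r, c + 1))
                        else:
                            add(me, (u, comp, (f + 1) % 4, r, 0))
                        # regular row neighbors
                        if r + 1 < H:
                            add(me, (u, comp, f, r + 1, c))
                # cap attachment and opposite-face cap partner
                for c in range(w):
                    anchor = H - 1 if comp == VILLUS else 0
                    add((u, comp, f, H, c), (u, comp, f, anchor, c))
                    add((u, comp, f, H, c), (u, comp, (f + 2) % 4, H, w - 1 - c))
                # inter-unit flat: villus base <-> crypt mouth; at axial
                # ends it folds back onto the same unit and face
                if comp == VILLUS:
                    v = unit_at(u, f)
                    g = (f + 2) % 4 if v is not None else f
                    v = u if v is None else v
                    for c in range(w):
                        add((u, VILLUS, f, 0, c), (v, CRYPT, g, h_c - 1, w - 1 - c))
    adj = {}
    for e in edges:
        a, b = tuple(e)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def index_adjacency(index):
    adj = {}
    for i in range(index.n_sites):
        c = index.index_to_coord(i)
        me = (c.unit_index, int(c.component), c.face, c.row, c.col)
        nbrs = set()
        for j in index.neighbors[i]:
            if j >= 0:
                d = index.index_to_coord(int(j))
                nbrs.add((d.unit_index, int(d.component), d.face, d.row, d.col))
        adj[me] = nbrs
    return adj


def test_toy_fold_matches_bruteforce(toy_index):
    """Every site of a 2-row x 2-col toy lattice matches the
    hand-rule-enumerated adjacency table."""
    oracle = bruteforce_adjacency(2, 2, h_v=2, h_c=2, w=2)
    got = index_adjacency(toy_index)
    assert got == oracle


def test_single_unit_fold_matches_bruteforce():
    unit = CryptVillusUnit(villus_height=3, crypt_depth=2, face_width=2)
    index = GeometryIndex(lattice_pouch(1, 1, unit))
    assert index_adjacency(index) == bruteforce_adjacency(1, 1, 3, 2, 2)


# ----------------------------------------------------------------------
# construction


def test_build_pouch_anatomic_dimensions():
    geom = build_pouch(3.5, 6.0, 0.5)
    assert geom.n_circ == math.floor(math.pi * 35 / 0.5) == 219
    assert geom.n_axial == math.floor(60 / 0.5) == 120
    assert geom.n_units == 219 * 120


def test_build_pouch_single_circumferential_column():
    # circumference barely above one spacing -> exactly one unit around
    d = 0.6 / (10 * math.pi)
    geom = build_pouch(d, 0.06, 0.5)
    assert geom.n_circ == 1
    assert geom.n_axial == 1


@pytest.mark.parametrize(
    "dims",
    [(0.0, 6.0, 0.5), (3.5, 0.0, 0.5), (3.5, 6.0, 0.0), (3.5, 6.0, -1.0)],
)
def test_build_pouch_rejects_nonpositive_dimensions(dims):
    with pytest.raises(ValueError):
        build_pouch(*dims)


def test_build_pouch_rejects_spacing_wider_than_circumference():
    with pytest.raises(ValueError, match="circumference"):
        build_pouch(0.01, 6.0, 5.0)


def test_unit_template_validation():
    with pytest.raises(ValueError):
        CryptVillusUnit(villus_height=0)
    with pytest.raises(ValueError):
        CryptVillusUnit(face_width=0)


def test_site_count_formula(small_index):
    geom = small_index.geom
    expect = sum(
        u.n_faces * u.face_width * (u.rows(Component.CRYPT) + u.rows(Component.VILLUS))
        for u in geom.units
    )
    assert small_index.n_sites == expect == geom.total_sites()


# ----------------------------------------------------------------------
# adjacency properties


def test_interior_site_has_four_neighbors():
    unit = CryptVillusUnit(villus_height=10, crypt_depth=4, face_width=6)
    index = GeometryIndex(lattice_pouch(2, 2, unit))
    c = GridCoord(0, Component.VILLUS, 0, 5, 2)
    assert len(neighbor_sites(index, c)) == 4


def test_neighbor_symmetry_and_degree_bound(small_index):
    nb = small_index.neighbors
    deg = (nb >= 0).sum(axis=1)
    assert deg.max() <= 4
    pairs = 0
    for i in range(small_index.n_sites):
        for j in nb[i]:
            if j >= 0:
                assert i in nb[j], f"asymmetric pair {i}<->{j}"
                pairs += 1
    assert pairs > 0


def test_neighbor_sites_rejects_invalid_coordinate(small_index):
    with pytest.raises(IndexError):
        neighbor_sites(small_index, GridCoord(0, Component.CRYPT, 0, 99, 0))
    with pytest.raises(IndexError):
        neighbor_sites(small_index, GridCoord(99, Component.CRYPT, 0, 0, 0))


# ----------------------------------------------------------------------
# 3D embedding


def test_embedding_baseline_alignment(small_index):
    unit = small_index.geom.units[0]
    cd_um = 10.0
    v0 = to_3d(small_index, GridCoord(0, Component.VILLUS, 0, 0, 0), cd_um)
    ctop = to_3d(
        small_index, GridCoord(0, Component.CRYPT, 0, unit.crypt_depth - 1, 0), cd_um
    )
    r_v = math.hypot(v0[0], v0[1])
    r_c = math.hypot(ctop[0], ctop[1])
    assert abs(r_v - r_c) <= cd_um / 1000.0 + 1e-9


def test_embedding_tip_radial_offset(small_index):
    unit = small_index.geom.units[0]
    R = small_index.geom.diameter_cm * 10.0 / 2.0
    tip = to_3d(
        small_index,
        GridCoord(0, Component.VILLUS, 0, unit.villus_height, 0),  # tip cap row
        10.0,
    )
    assert math.hypot(tip[0], tip[1]) == pytest.approx(
        R + unit.villus_height * 0.01, abs=1e-9
    )


def test_embedding_angular_separation(small_index):
    geom = small_index.geom
    a = to_3d(small_index, GridCoord(0, Component.CRYPT, 0, 0, 0))
    b = to_3d(small_index, GridCoord(1, Component.CRYPT, 0, 0, 0))
    ang = abs(
        math.atan2(a[1], a[0]) - math.atan2(b[1], b[0])
    )
    ang = min(ang, 2 * math.pi - ang)
    assert ang == pytest.approx(2 * math.pi / geom.n_circ, rel=1e-6)


def test_embedding_is_injective(small_index):
    pos = positions_3d(small_index)
    uniq = np.unique(np.round(pos, 9), axis=0)
    assert uniq.shape[0] == small_index.n_sites


# ----------------------------------------------------------------------
# dynamic resizing


def _payloads(index):
    lineage = np.full(index.n_sites, -1, dtype=np.int8)
    value = np.zeros(index.n_sites)
    return lineage, value


def test_resize_grow_preserves_payloads(small_index):
    lineage, value = _payloads(small_index)
    lineage[:] = 2
    value[:] = np.arange(small_index.n_sites)
    unit = small_index.geom.units[0]
    new_index, out, actual = resize_unit(
        small_index, 0, Component.VILLUS, unit.villus_height + 2,
        {"lineage": (lineage, -1), "value": (value, 0.0)},
        occupied=lineage >= 0,
    )
    assert actual == unit.villus_height + 2
    added = 2 * unit.face_width * unit.n_faces
    assert new_index.n_sites == small_index.n_sites + added
    assert (out["lineage"] == -1).sum() == added
    # surviving payloads preserved site-for-site
    for i in np.flatnonzero(out["lineage"] >= 0)[:50]:
        c = new_index.index_to_coord(int(i))
        j = small_index.coord_to_index(c)
        assert out["value"][i] == value[j]


def test_resize_shrink_empty_rows(small_index):
    lineage, value = _payloads(small_index)
    # occupy villus rows 0..5 of unit 0 only
    m = (
        (small_index.site_unit == 0)
        & (small_index.site_comp == int(Component.VILLUS))
        & (small_index.site_row < 6)
    )
    lineage[m] = 2
    new_index, out, actual = resize_unit(
        small_index, 0, Component.VILLUS, 8,
        {"lineage": (lineage, -1)}, occupied=lineage >= 0,
    )
    assert actual == 8
    assert (out["lineage"] >= 0).sum() == m.sum()  # occupied sites preserved


def test_resize_shrink_clamped_at_occupied_row(small_index, caplog):
    lineage, _ = _payloads(small_index)
    site = small_index.coord_to_index(GridCoord(0, Component.VILLUS, 1, 7, 0))
    lineage[site] = 2
    with caplog.at_level("WARNING", logger="pouchsim"):
        new_index, out, actual = resize_unit(
            small_index, 0, Component.VILLUS, 4,
            {"lineage": (lineage, -1)}, occupied=lineage >= 0,
        )
    assert actual == 8  # highest occupied row 7 -> clamp to 8
    assert "clamped" in caplog.text
    assert (out["lineage"] >= 0).sum() == 1


def test_resize_rejects_zero_height(small_index):
    lineage, _ = _payloads(small_index)
    with pytest.raises(ValueError):
        resize_unit(
            small_index, 0, Component.VILLUS, 0,
            {"lineage": (lineage, -1)}, occupied=lineage >= 0,
        )


def test_total_sites_conserved_except_resize(small_index):
    before = small_index.geom.total_sites()
    lineage, _ = _payloads(small_index)
    new_index, _, _ = resize_unit(
        small_index, 2, Component.VILLUS, 12,
        {"lineage": (lineage, -1)}, occupied=lineage >= 0,
    )
    per_row = small_index.geom.units[2].face_width * 4
    assert new_index.geom.total_sites() == before + 2 * per_row


# ----------------------------------------------------------------------
# axial positions


def test_axial_positions(small_index):
    geom = small_index.geom
    assert axial_position_mm(geom, 0) == 0.0
    k = geom.n_circ  # first unit of axial row 1
    assert axial_position_mm(geom, k) == pytest.approx(geom.unit_spacing_mm)
    with pytest.raises(IndexError):
        axial_position_mm(geom, geom.n_units)


def test_axial_position_of_anatomic_pouch_terminal_row():
    geom = build_pouch(3.5, 6.0, 0.5)
    last = geom.unit_index(geom.n_axial - 1, 0)
    assert axial_position_mm(geom, last) == pytest.approx(59.5)
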