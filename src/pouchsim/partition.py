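"""Congruent-section domain decomposition with one-cell ghost buffers.

The unit lattice is tiled into near-equal rectangular blocks of
crypt-villus units, one per logical worker (realized as sequential
sub-domain sweeps inside one process -- the contract, not the transport,
is what matters here).  Every grid crossing a block boundary is extended
by exactly one cell length of *ghost* sites replicating the neighboring
block's boundary state; ghosts are refreshed by :func:`exchange_ghosts`
once per phase, so a run on P workers is bit-for-bit identical to a
serial run.

Stochastic rules draw from :func:`site_rng`, a counter-based hash RNG
keyed on (master seed, global site key, timestep, stream).  Deviates
depend only on those four integers -- never on worker layout or
iteration order -- which is what makes the decomposition invisible to
the stochastic dynamics.  Simultaneous moves into one site are resolved
by the owner of the destination with a site_rng tie-break
(:func:`resolve_proposals`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import GeometryIndex, PouchGeometry

__all__ = [
    "Stream",
    "site_rng",
    "site_rng_u64",
    "Partition",
    "ExchangePlan",
    "decompose",
    "valid_worker_counts",
    "Domain",
    "build_domains",
    "exchange_ghosts",
    "resolve_proposals",
]


class Stream(IntEnum):
    """Independent random streams; one per stochastic rule."""

    INIT_CLOCK = 1
    DEATH = 2
    SHED = 3
    DIVISION_CHOICE = 4
    MIGRATION_CHOICE = 5
    CONFLICT = 6
    BIRTH_ID = 7


# -- counter-based RNG --------------------------------------------------

_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def _mix(z: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer (vectorized, wrapping uint64 arithmetic)."""
    z = (z + _GOLDEN).astype(np.uint64)
    z ^= z >> np.uint64(30)
    z = (z * _M1).astype(np.uint64)
    z ^= z >> np.uint64(27)
    z = (z * _M2).astype(np.uint64)
    z ^= z >> np.uint64(31)
    return z


def site_rng_u64(site_key, timestep: int, stream: int, master_seed: int):
    """64-bit hash of (seed, site key, step, stream); array-friendly."""
    key = np.asarray(site_key, dtype=np.uint64)
    with np.errstate(over="ignore"):
        h = _mix(np.uint64(master_seed & 0xFFFFFFFFFFFFFFFF))
        h = _mix(h ^ key)
        h = _mix(h ^ np.uint64(timestep))
        h = _mix(h ^ np.uint64(stream))
    return h


def site_rng(site_key, timestep: int, stream: int, master_seed: int):
    """Uniform deviate(s) in [0, 1) from the counter-based hash.

    A pure function of its four integer arguments: the same site queried
    at the same step from any partitioning yields the same deviate.
    """
    h = site_rng_u64(site_key, timestep, stream, master_seed)
    u = (h >> np.uint64(11)).astype(np.float64) * (2.0 ** -53)
    if np.isscalar(site_key) or np.ndim(site_key) == 0:
        return float(u)
    return u


# -- decomposition ------------------------------------------------------

@dataclass
class Partition:
    """One congruent section: a rectangular block of units plus ghosts."""

    worker_id: int
    axial_range: Tuple[int, int]  # [a0, a1)
    circ_range: Tuple[int, int]   # [c0, c1); wraps are handled by neighbors
    owned_units: np.ndarray = field(repr=False)
    owned_sites: np.ndarray = field(repr=False)
    ghost_sites: np.ndarray = field(repr=False)  # global indices, sorted
    ghost_owner: np.ndarray = field(repr=False)  # worker id of each ghost's owner


@dataclass
class ExchangePlan:
    """Static gather plan: which global sites each worker mirrors as ghosts.

    Every ghost slot has exactly one source (the owning partition), a
    consequence of the owned blocks tiling the lattice exactly.
    """

    n_workers: int
    ghost_sites: List[np.ndarray]
    ghost_owner: List[np.ndarray]


def valid_worker_counts(geom: PouchGeometry) -> List[int]:
    """Worker counts that admit an axial x circumferential block grid."""
    out = []
    for p in range(1, geom.n_axial * geom.n_circ + 1):
        if any(
            p % pa == 0 and p // pa <= geom.n_circ
            for pa in range(1, min(p, geom.n_axial) + 1)
        ):
            out.append(p)
    return out


def _factor(geom: PouchGeometry, n_workers: int) -> Tuple[int, int]:
    best = None
    for pa in range(1, min(n_workers, geom.n_axial) + 1):
        if n_workers % pa:
            continue
        pc = n_workers // pa
        if pc > geom.n_circ:
            continue
        # prefer blocks close to square (in units)
        cost = abs(geom.n_axial / pa - geom.n_circ / pc)
        if best is None or cost < best[0]:
            best = (cost, pa, pc)
    if best is None:
        raise ValueError(
            f"{n_workers} workers admit no axial x circumferential block "
            f"grid on a {geom.n_axial} x {geom.n_circ} unit lattice; valid "
            f"counts: {valid_worker_counts(geom)}"
        )
    return best[1], best[2]


def _ranges(n: int, parts: int) -> List[Tuple[int, int]]:
    cuts = np.linspace(0, n, parts + 1).round().astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(parts)]


def decompose(
    index: GeometryIndex, n_workers: int
) -> Tuple[List[Partition], ExchangePlan]:
    """Tile the unit lattice into near-equal rectangular blocks.

    The circumferential direction wraps (the leftmost and rightmost
    circumferential blocks are neighbors); the axial direction does not.
    Ghost sites of a partition are exactly the sites one folded-grid step
    away from its owned sites that it does not own.
    """
    geom = index.geom
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    pa, pc = _factor(geom, n_workers)
    a_ranges = _ranges(geom.n_axial, pa)
    c_ranges = _ranges(geom.n_circ, pc)

    unit_axial = np.arange(geom.n_units) // geom.n_circ
    unit_circ = np.arange(geom.n_units) % geom.n_circ
    site_owner_unit = index.site_unit

    unit_worker = np.empty(geom.n_units, dtype=np.int32)
    blocks = []
    wid = 0
    for a0, a1 in a_ranges:
        for c0, c1 in c_ranges:
            m = (unit_axial >= a0) & (unit_axial < a1) & (
                unit_circ >= c0
            ) & (unit_circ < c1)
            unit_worker[m] = wid
            blocks.append((wid, (a0, a1), (c0, c1), np.flatnonzero(m)))
            wid += 1

    site_worker = unit_worker[site_owner_unit]
    partitions: List[Partition] = []
    plan_sites: List[np.ndarray] = []
    plan_owner: List[np.ndarray] = []
    for wid, ar, cr, units in blocks:
        owned_sites = np.flatnonzero(site_worker == wid)
        nb = index.neighbors[owned_sites].ravel()
        nb = nb[nb >= 0]
        ghosts = np.unique(nb[site_worker[nb] != wid])
        partitions.append(
            Partition(
                worker_id=wid,
                axial_range=ar,
                circ_range=cr,
                owned_units=units,
                owned_sites=owned_sites,
                ghost_sites=ghosts,
                ghost_owner=site_worker[ghosts],
            )
        )
        plan_sites.append(ghosts)
        plan_owner.append(site_worker[ghosts])
    return partitions, ExchangePlan(n_workers, plan_sites, plan_owner)


# -- worker-local halo views -------------------------------------------

class Domain:
    """A worker's halo view: owned sites plus the one-cell ghost layer.

    Dynamic state is accessed only through local arrays gathered over
    ``halo_sites`` (owned followed by ghosts); the local neighbor table
    ``lnb`` maps each owned site's neighbors into halo-local positions,
    so no rule can read beyond one cell from an owned site -- a neighbor
    outside the halo simply has no local address.  For the trivial
    single-worker decomposition the view is the whole lattice and
    gathers are no-ops on the global arrays.
    """

    def __init__(self, index: GeometryIndex, part: Partition, trivial: bool):
        self.worker_id = part.worker_id
        self.owned_sites = part.owned_sites
        self.ghost_sites = part.ghost_sites
        self.trivial = trivial and part.ghost_sites.size == 0
        if self.trivial:
            self.halo_sites = part.owned_sites
            self.owned_pos = np.arange(part.owned_sites.size)
            self.lnb = index.neighbors
        else:
            self.halo_sites = np.concatenate(
                [part.owned_sites, part.ghost_sites]
            )
            order = np.argsort(self.halo_sites, kind="stable")
            sorted_halo = self.halo_sites[order]
            self.owned_pos = np.arange(part.owned_sites.size)
            gnb = index.neighbors[part.owned_sites]
            valid = gnb >= 0
            pos = np.searchsorted(sorted_halo, np.where(valid, gnb, 0))
            # every neighbor of an owned site must lie inside the halo
            inside = valid & (pos < sorted_halo.size)
            found = np.zeros_like(valid)
            found[inside] = (
                sorted_halo[pos[inside]] == gnb[inside]
            )
            if not np.array_equal(found, valid):
                raise AssertionError(
                    "ghost layer does not close the one-cell neighborhood "
                    f"of worker {part.worker_id}'s owned sites"
                )
            self.lnb = np.where(valid, order[np.minimum(pos, sorted_halo.size - 1)], -1)
        # missing neighbors replaced by the site itself (zero-flux form of
        # the stencil needs no masking then)
        self.lnb_self = np.where(
            self.lnb >= 0, self.lnb, self.owned_pos[:, None]
        )

    def local_to_global(self, local_idx: np.ndarray) -> np.ndarray:
        return self.halo_sites[local_idx]

    def global_to_local(self, global_idx: np.ndarray) -> np.ndarray:
        """Halo-local positions of global sites; raises if outside the halo
        (the debug access guard: state beyond the ghost layer has no
        local address)."""
        order = np.argsort(self.halo_sites, kind="stable")
        sorted_halo = self.halo_sites[order]
        pos = np.searchsorted(sorted_halo, global_idx)
        ok = (pos < sorted_halo.size) & (sorted_halo[np.minimum(pos, sorted_halo.size - 1)] == global_idx)
        if not np.all(ok):
            bad = np.asarray(global_idx)[~np.asarray(ok)]
            raise IndexError(
                f"worker {self.worker_id} attempted to read site(s) {bad[:5]} "
                "beyond its one-cell ghost buffer"
            )
        return order[pos]

    def gather(self, arr: np.ndarray) -> np.ndarray:
        """Local halo copy of a global per-site array (the ghost refresh)."""
        if self.trivial:
            return arr
        if arr.ndim == 1:
            return arr[self.halo_sites]
        return arr[:, self.halo_sites]


def build_domains(
    index: GeometryIndex, partitions: Sequence[Partition]
) -> List[Domain]:
    trivial = len(partitions) == 1
    return [Domain(index, p, trivial) for p in partitions]


def exchange_ghosts(
    domains: Sequence[Domain],
    global_arrays: Dict[str, np.ndarray],
) -> List[Dict[str, np.ndarray]]:
    """Refresh every worker's halo copies from the owning partitions.

    Called once per phase, after local updates have been scattered back
    to the owned (authoritative) storage and before the next phase's
    reads.  After the exchange every ghost value equals the owner's
    value bit-for-bit (it is the same bits, copied).
    """
    return [
        {name: dom.gather(arr) for name, arr in global_arrays.items()}
        for dom in domains
    ]


# -- cross-boundary move resolution ------------------------------------

def resolve_proposals(
    src: np.ndarray,
    dst: np.ndarray,
    site_key: np.ndarray,
    timestep: int,
    master_seed: int,
) -> np.ndarray:
    """Pick one winner per contested destination site.

    The winner is the proposal minimizing (site_rng(source, step,
    CONFLICT), source key) -- a pure function of the proposal set, step
    and seed, so the owner of the destination resolves it identically no
    matter how the lattice is partitioned.  Returns a boolean mask over
    proposals.
    """
    if src.size == 0:
        return np.zeros(0, dtype=bool)
    u = site_rng_u64(site_key[src], timestep, Stream.CONFLICT, master_seed)
    order = np.lexsort((site_key[src], u, dst))
    dst_sorted = dst[order]
    first = np.ones(dst_sorted.size, dtype=bool)
    first[1:] = dst_sorted[1:] != dst_sorted[:-1]
    win = np.zeros(src.size, dtype=bool)
    win[order[first]] = True
    return win
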