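"""Epithelial cell agents and their per-step rules.

Cells occupy lattice sites (at most one per site) and follow the usual
crypt-villus life cycle: stem cells divide in the Wnt-rich crypt base,
progenitors divide and migrate mouthward, differentiate to enterocytes
under BMP (or on entering the villus), ride the mitotic-pressure
conveyor toward the tip, and are shed from the top rows.  Inflammatory
mediators (ROS, TNF-a) kill cells with a monotone dose-dependent
probability; sustained stool-driven TLR exposure converts a unit's
enterocytes to a metaplastic phenotype and lowers its villus target
height (diffuse villus shortening).

All stochastic choices draw from the counter-based ``site_rng``, keyed
on the site, step and a per-rule stream, so rule outcomes are identical
under any domain decomposition.  Neighbor-reading rules (division,
migration) emit *proposals* resolved by the owner of the destination
site (:func:`pouchsim.partition.resolve_proposals`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import Component, GeometryIndex, GridCoord
from .partition import Domain, Stream, site_rng, site_rng_u64
from .signaling import MediatorId

__all__ = [
    "Lineage",
    "EMPTY",
    "CellAgent",
    "RuleParams",
    "death_rate",
    "step_death",
    "step_differentiation",
    "division_proposals",
    "migration_proposals",
    "step_shedding",
    "ulcer_ball",
    "apply_ulcer_arrays",
    "villus_target_height",
]

EMPTY = -1


class Lineage(IntEnum):
    STEM = 0
    PROGENITOR = 1
    ENTEROCYTE = 2
    METAPLASTIC = 3


@dataclass(frozen=True)
class CellAgent:
    """Read-only snapshot of one epithelial cell agent."""

    cell_id: int
    lineage: Lineage
    site: GridCoord
    cycle_clock: int
    health: float
    inflammation_exposure: float


@dataclass
class RuleParams:
    """Rule constants for the cellular dynamics.

    Cycle lengths are in 15-minute steps (stem 96 = 24 h, progenitor
    48 = 12 h); thresholds are in the relative concentration units of the
    mediator fields.
    """

    cycle_len_stem: int = 96
    cycle_len_progenitor: int = 48
    theta_wnt: float = 0.1        # proliferation-drive threshold
    theta_bmp: float = 0.5        # differentiation threshold
    stem_zone_rows: int = 3       # crypt base rows (plus valley cap) hosting stem cells
    shed_rows: int = 1            # top villus rows (plus tip cap) where shedding occurs
    shed_prob: float = 0.007      # per-step shedding probability in the shed zone
    migration_prob: float = 0.2   # per-step probability a cell attempts its move
    death_coeff_ros: float = 0.01   # death_rate = 1 - exp(-(a*ROS + b*TNFA))
    death_coeff_tnfa: float = 0.01
    metaplasia_exposure_threshold: float = 150.0
    metaplasia_height_per_exposure: float = 11.0  # exposure units per row lost
    villus_min_height: int = 12   # metaplastic floor (colon-like flattening)
    atrophic_shed_prob: float = 0.05  # shedding in rows above a unit's target height
    metaplasia_reversible: bool = False

    def cycle_len(self, lineage: np.ndarray) -> np.ndarray:
        return np.where(
            lineage == Lineage.STEM, self.cycle_len_stem, self.cycle_len_progenitor
        )

    def validate(self) -> None:
        if min(self.cycle_len_stem, self.cycle_len_progenitor) < 1:
            raise ValueError("cycle lengths must be >= 1 step")
        if min(self.theta_wnt, self.theta_bmp) < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 <= self.shed_prob <= 1.0:
            raise ValueError("shed_prob must be a probability")
        if not 0.0 < self.migration_prob <= 1.0:
            raise ValueError("migration_prob must be in (0, 1]")
        if min(self.death_coeff_ros, self.death_coeff_tnfa) < 0:
            raise ValueError("death coefficients must be >= 0")
        if self.villus_min_height < 1:
            raise ValueError("villus_min_height must be >= 1")


def death_rate(ros, tnfa, params: RuleParams):
    """Per-step death probability; 0 at (0,0), monotone in both doses."""
    return 1.0 - np.exp(
        -(params.death_coeff_ros * np.asarray(ros)
          + params.death_coeff_tnfa * np.asarray(tnfa))
    )


# -- pointwise rules (operate on a worker's owned sites) ----------------

def step_death(
    lineage: np.ndarray,
    ros: np.ndarray,
    tnfa: np.ndarray,
    site_key: np.ndarray,
    step: int,
    seed: int,
    params: RuleParams,
) -> np.ndarray:
    """Boolean mask of cells dying this step (inflammation-mediated)."""
    occ = lineage != EMPTY
    p = death_rate(ros, tnfa, params)
    u = site_rng(site_key, step, Stream.DEATH, seed)
    return occ & (u < p)


def step_differentiation(
    lineage: np.ndarray,
    bmp: np.ndarray,
    comp: np.ndarray,
    params: RuleParams,
) -> np.ndarray:
    """Progenitor -> enterocyte under BMP or on entering the villus.

    Irreversible (metaplastic conversion excepted).  Returns the updated
    lineage array (a copy).
    """
    out = lineage.copy()
    prog = lineage == Lineage.PROGENITOR
    mature = prog & (
        (bmp >= params.theta_bmp) | (comp == int(Component.VILLUS))
    )
    out[mature] = Lineage.ENTEROCYTE
    return out


def step_shedding(
    lineage: np.ndarray,
    shed_zone: np.ndarray,
    site_key: np.ndarray,
    step: int,
    seed: int,
    params: RuleParams,
    atrophic: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Mask of differentiated cells shed from the top villus rows.

    Sites in the atrophic zone of a metaplastic unit (rows above the
    unit's target height) shed at the faster ``atrophic_shed_prob``.
    """
    occ = (lineage == Lineage.ENTEROCYTE) | (lineage == Lineage.METAPLASTIC)
    zone = shed_zone if atrophic is None else (shed_zone | atrophic)
    cand = np.flatnonzero(occ & zone)
    out = np.zeros(lineage.shape, dtype=bool)
    if cand.size == 0:
        return out
    u = site_rng(site_key[cand], step, Stream.SHED, seed)
    prob = np.full(cand.size, params.shed_prob)
    if atrophic is not None:
        prob[atrophic[cand]] = params.atrophic_shed_prob
    out[cand[np.atleast_1d(u) < prob]] = True
    return out


# -- neighbor-reading rules (proposals over a halo view) ----------------

def _choose_candidate(
    cand: np.ndarray, u: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministically pick one True slot per row of a (n, 4) mask.

    Returns (has_candidate mask, chosen slot index); the pick is the
    floor(u * k)-th candidate among the row's k candidates.
    """
    k = cand.sum(axis=1)
    has = k > 0
    pick = np.minimum((u * k).astype(np.int64), np.maximum(k - 1, 0))
    cum = np.cumsum(cand, axis=1)
    sel = cand & (cum == (pick + 1)[:, None])
    slot = sel.argmax(axis=1)
    return has, slot


def division_proposals(
    dom: Domain,
    lineage_halo: np.ndarray,
    clock_own: np.ndarray,
    prolif_own: np.ndarray,
    index: GeometryIndex,
    params: RuleParams,
    step: int,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Daughter placements proposed by cycling stem/progenitor cells.

    A cell divides iff its cycle clock has run out, the local
    proliferation drive (Wnt plus the STAT3 arm) meets theta_wnt, and an
    empty neighbor site exists; the daughter site is chosen among the
    empties via site_rng.  Returns (parent, daughter) global site
    indices; contested daughters are resolved downstream by the owner.
    """
    own = dom.owned_sites
    lin_own = lineage_halo[dom.owned_pos]
    parent = (lin_own == Lineage.STEM) | (lin_own == Lineage.PROGENITOR)
    ready = parent & (clock_own >= params.cycle_len(lin_own)) & (
        prolif_own >= params.theta_wnt
    )
    rows = np.flatnonzero(ready)
    if rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lnb = dom.lnb[rows]
    cand = (lnb >= 0) & (lineage_halo[np.maximum(lnb, 0)] == EMPTY)
    u = site_rng(index.site_key[own[rows]], step, Stream.DIVISION_CHOICE, seed)
    has, slot = _choose_candidate(cand, np.atleast_1d(u))
    rows = rows[has]
    dst_local = lnb[has, slot[has]]
    return own[rows], dom.local_to_global(dst_local)


def migration_proposals(
    dom: Domain,
    lineage_halo: np.ndarray,
    index: GeometryIndex,
    params: RuleParams,
    step: int,
    seed: int,
    blocked: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Upward moves proposed by non-stem cells (the conveyor belt).

    Each non-stem cell attempts (with probability ``migration_prob``,
    setting the conveyor speed) one move per step into an empty neighbor
    of strictly higher elevation (crypt mouth -> villus base -> tip).
    Returns (source, destination) global site indices.
    """
    own = dom.owned_sites
    lin_own = lineage_halo[dom.owned_pos]
    mover = (lin_own != EMPTY) & (lin_own != Lineage.STEM)
    rows = np.flatnonzero(mover)
    if rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    u = np.atleast_1d(
        site_rng(index.site_key[own[rows]], step, Stream.MIGRATION_CHOICE, seed)
    )
    # one deviate gates the attempt and (rescaled) picks the target
    gate = u < params.migration_prob
    rows = rows[gate]
    if rows.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    u = u[gate] / params.migration_prob
    lnb = dom.lnb[rows]
    safe = np.maximum(lnb, 0)
    gnb = dom.local_to_global(safe)
    higher = index.site_elevation[gnb] > index.site_elevation[own[rows]][:, None]
    cand = (lnb >= 0) & (lineage_halo[safe] == EMPTY) & higher
    if blocked is not None:
        # atrophic rows of metaplastic units receive no migrants
        cand &= ~blocked[gnb]
    has, slot = _choose_candidate(cand, np.atleast_1d(u))
    rows2 = rows[has]
    dst_local = lnb[has, slot[has]]
    return own[rows2], dom.local_to_global(dst_local)


# -- perturbations and metaplasia --------------------------------------

def ulcer_ball(index: GeometryIndex, center: GridCoord, radius_sites: int) -> np.ndarray:
    """Sites within folded-graph distance ``radius_sites`` of the center
    (breadth-first expansion over the neighbor table)."""
    if radius_sites < 0:
        raise ValueError("radius must be >= 0")
    start = index.coord_to_index(center)
    dist = np.full(index.n_sites, -1, dtype=np.int32)
    dist[start] = 0
    frontier = np.array([start], dtype=np.int64)
    for d in range(1, radius_sites + 1):
        nb = index.neighbors[frontier].ravel()
        nb = nb[nb >= 0]
        nb = np.unique(nb[dist[nb] < 0])
        if nb.size == 0:
            break
        dist[nb] = d
        frontier = nb
    return np.flatnonzero(dist >= 0)


def apply_ulcer_arrays(
    index: GeometryIndex,
    lineage: np.ndarray,
    conc: np.ndarray,
    center: GridCoord,
    radius_sites: int,
    bolus_tnfa: float = 5.0,
    bolus_ros: float = 5.0,
) -> np.ndarray:
    """Punch a circular ulcer: remove every agent within the folded-graph
    ball and deposit an inflammatory bolus on the wound bed.

    Mutates ``lineage`` and ``conc`` in place; returns the wound-site
    indices (the caller clears the per-agent payloads and counts the
    removals).
    """
    ball = ulcer_ball(index, center, radius_sites)
    lineage[ball] = EMPTY
    conc[MediatorId.TNFA, ball] += bolus_tnfa
    conc[MediatorId.ROS, ball] += bolus_ros
    return ball


def villus_target_height(
    exposure: float, baseline_height: int, params: RuleParams
) -> int:
    """Villus target height under accumulated inflammatory exposure.

    Monotone non-increasing in exposure with floor villus_min_height:
    above the metaplasia threshold, one row is lost per
    ``metaplasia_height_per_exposure`` units of excess exposure.
    """
    excess = max(0.0, exposure - params.metaplasia_exposure_threshold)
    lost = int(excess / params.metaplasia_height_per_exposure)
    return max(min(params.villus_min_height, baseline_height), baseline_height - lost)
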