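"""Timestep orchestration: one 15-minute step of the coupled model.

Phase order within a step (two-phase read-prev/write-next everywhere,
so update order can never break serial/partitioned equivalence):

1. stool fill/empty cycle and per-unit TLR drive;
2. TLR receptor update and exposure accumulation (pointwise);
3. scenario-driven inflammatory boluses, if any (pointwise);
4. diffusion + decay of secreted mediators (halo phase), then emission;
5. signed-network update of the mediator vector (pointwise);
6. cell rules: clock tick, inflammation-mediated death,
   differentiation, division (halo phase, owner-resolved),
   migration (halo phase, owner-resolved), shedding;
7. metaplastic conversion and villus target-height resizing
   (between-step geometry change);
8. bookkeeping: population time series, conservation check.

Ghost buffers are refreshed (``Domain.gather``) before every halo
phase; proposals that target another worker's sites are resolved by the
owner of the destination.  All randomness flows through ``site_rng``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import cells as C
from . import signaling as S
from . import stool as ST
from .geometry import Component, GeometryIndex, GridCoord, apply_resizes
from .partition import (
    Domain,
    Stream,
    build_domains,
    decompose,
    resolve_proposals,
    site_rng,
    site_rng_u64,
)

logger = logging.getLogger("pouchsim")

_INTRA_IDS = np.array([int(m) for m in S.INTRACELLULAR])
_DIFF_IDS = np.array([int(m) for m in S.DIFFUSIBLE])

SERIES_COLUMNS = [
    "step", "sim_hours", "n_total", "n_crypt", "n_villus", "n_stem",
    "n_progenitor", "n_enterocyte", "n_metaplastic", "births", "deaths",
    "sheds",
]


class Simulation:
    """A running tissue simulation on a fixed seed and worker count."""

    def __init__(
        self,
        index: GeometryIndex,
        rules: C.RuleParams,
        signaling: S.SignalingParams,
        stool_params: ST.StoolParams,
        stool_enabled: bool = False,
        seed: int = 1,
        workers: int = 1,
        debug: bool = False,
    ):
        rules.validate()
        signaling.validate()
        self.index = index
        self.rules = rules
        self.signaling = signaling
        self.stool_params = stool_params
        self.stool_enabled = stool_enabled
        self.seed = int(seed)
        self.workers = int(workers)
        self.debug = debug
        self.step_count = 0
        self.perturbations: List[Tuple[int, Callable[["Simulation"], None]]] = []
        self.inflam_bolus: Tuple[float, float] = (0.0, 0.0)  # (ROS, TNFA)/step

        geom = index.geom
        self.baseline_villus_height = np.array(
            [u.villus_height for u in geom.units], dtype=np.int32
        )
        self.unit_exposure = np.zeros(geom.n_units)
        self.unit_metaplastic = np.zeros(geom.n_units, dtype=bool)
        self.stool_state = ST.StoolState(_fill_steps=stool_params.fill_steps)

        n = index.n_sites
        self.lineage = np.full(n, C.EMPTY, dtype=np.int8)
        self.clock = np.zeros(n, dtype=np.int32)
        self.health = np.zeros(n)
        self.exposure = np.zeros(n)
        self.cell_id = np.zeros(n, dtype=np.uint64)
        self.conc = np.zeros((S.N_MEDIATORS, n))

        self._records: List[list] = []
        self._rebuild_partitions()
        self._rebuild_masks()

    # -- construction helpers -----------------------------------------

    def _rebuild_partitions(self) -> None:
        self.partitions, self.plan = decompose(self.index, self.workers)
        self.domains = build_domains(self.index, self.partitions)
        self.site_worker = np.empty(self.index.n_sites, dtype=np.int32)
        for p in self.partitions:
            self.site_worker[p.owned_sites] = p.worker_id

    def _rebuild_masks(self) -> None:
        self.stem_zone = self.index.crypt_base_mask(self.rules.stem_zone_rows)
        self.shed_zone = self.index.villus_tip_mask(self.rules.shed_rows)
        self.source_masks = {
            int(m): self.signaling.source_mask(self.index, m)
            for m in S.DIFFUSIBLE
        }

    def set_signaling(self, signaling: S.SignalingParams) -> None:
        """Swap signaling parameters (e.g. after a knockout)."""
        signaling.validate()
        self.signaling = signaling
        self._rebuild_masks()

    def init_tissue(self) -> None:
        """Seed a confluent epithelium near its homeostatic architecture.

        Crypts are filled with stem cells in the base zone and
        progenitors above; villi with enterocytes.  Cycle clocks start
        staggered (via site_rng) so divisions do not come in waves.
        """
        idx = self.index
        crypt = idx.site_comp == int(Component.CRYPT)
        self.lineage[crypt] = C.Lineage.PROGENITOR
        self.lineage[crypt & self.stem_zone] = C.Lineage.STEM
        self.lineage[~crypt] = C.Lineage.ENTEROCYTE
        occ = self.lineage != C.EMPTY
        u = site_rng(idx.site_key, 0, Stream.INIT_CLOCK, self.seed)
        self.clock[occ] = (
            u[occ] * self.rules.cycle_len(self.lineage[occ])
        ).astype(np.int32)
        self.health[occ] = 1.0
        self.cell_id[occ] = idx.site_key[occ]

    # -- observables ----------------------------------------------------

    @property
    def occupied(self) -> np.ndarray:
        return self.lineage != C.EMPTY

    @property
    def series(self) -> pd.DataFrame:
        return pd.DataFrame(self._records, columns=SERIES_COLUMNS)

    def population_counts(self) -> Dict[str, int]:
        lin = self.lineage
        crypt = self.index.site_comp == int(Component.CRYPT)
        occ = lin != C.EMPTY
        return {
            "n_total": int(occ.sum()),
            "n_crypt": int((occ & crypt).sum()),
            "n_villus": int((occ & ~crypt).sum()),
            "n_stem": int((lin == C.Lineage.STEM).sum()),
            "n_progenitor": int((lin == C.Lineage.PROGENITOR).sum()),
            "n_enterocyte": int((lin == C.Lineage.ENTEROCYTE).sum()),
            "n_metaplastic": int((lin == C.Lineage.METAPLASTIC).sum()),
        }

    def agents(self) -> List[C.CellAgent]:
        """Snapshot of all cell agents (API/testing convenience)."""
        out = []
        for i in np.flatnonzero(self.occupied):
            out.append(
                C.CellAgent(
                    cell_id=int(self.cell_id[i]),
                    lineage=C.Lineage(int(self.lineage[i])),
                    site=self.index.index_to_coord(int(i)),
                    cycle_clock=int(self.clock[i]),
                    health=float(self.health[i]),
                    inflammation_exposure=float(self.exposure[i]),
                )
            )
        return out

    # -- perturbations --------------------------------------------------

    def at_step(self, step: int, fn: Callable[["Simulation"], None]) -> None:
        """Register a perturbation applied at the start of ``step``."""
        self.perturbations.append((step, fn))

    def apply_ulcer(
        self,
        center: GridCoord,
        radius_sites: int,
        bolus_tnfa: float = 5.0,
        bolus_ros: float = 5.0,
    ) -> np.ndarray:
        """Punch a circular ulcer; removals are counted as deaths."""
        ball = C.apply_ulcer_arrays(
            self.index, self.lineage, self.conc, center, radius_sites,
            bolus_tnfa, bolus_ros,
        )
        n_removed = int((self.health[ball] > 0).sum())
        self._clear_sites(ball)
        self._ulcer_removed = n_removed
        self._wound_sites = ball
        return ball

    def apply_knockouts(self, mediators: Sequence[str]) -> None:
        sig = self.signaling
        for m in mediators:
            sig = S.apply_knockout(sig, m)
        self.set_signaling(sig)

    # -- the timestep ---------------------------------------------------

    def _clear_sites(self, idx: np.ndarray) -> None:
        self.lineage[idx] = C.EMPTY
        self.clock[idx] = 0
        self.health[idx] = 0.0
        self.exposure[idx] = 0.0
        self.cell_id[idx] = 0
        self.conc[np.ix_(_INTRA_IDS, idx)] = 0.0

    def _move_payload(self, src: np.ndarray, dst: np.ndarray) -> None:
        for a in (self.lineage, self.clock, self.health, self.exposure,
                  self.cell_id):
            a[dst] = a[src]
        self.conc[np.ix_(_INTRA_IDS, dst)] = self.conc[np.ix_(_INTRA_IDS, src)]
        self._clear_sites(src)

    def _owner_resolve(self, src: np.ndarray, dst: np.ndarray) -> np.ndarray:
        """Owner-of-destination conflict resolution across workers."""
        win = np.zeros(src.size, dtype=bool)
        for p in self.partitions:
            sel = self.site_worker[dst] == p.worker_id
            if sel.any():
                win[sel] = resolve_proposals(
                    src[sel], dst[sel], self.index.site_key,
                    self.step_count, self.seed,
                )
        return win

    def step(self) -> Dict[str, int]:
        """Advance one 15-minute step; returns the recorded counters."""
        self.step_count += 1
        t = self.step_count
        idx = self.index
        births = deaths = sheds = 0
        self._ulcer_removed = 0

        for at, fn in self.perturbations:
            if at == t:
                fn(self)
        deaths += self._ulcer_removed

        # 1. stool cycle and per-unit TLR drive
        n_axial = idx.geom.n_axial
        if self.stool_enabled:
            ST.step_stool(self.stool_state, self.stool_params, t)
            drive_axial = ST.contact_exposure(
                self.stool_state, n_axial, self.stool_params
            )
        else:
            drive_axial = np.zeros(n_axial)
        drive_unit = drive_axial[np.arange(idx.geom.n_units) // idx.geom.n_circ]
        self.unit_exposure += drive_unit

        # 2. TLR receptor activation + per-agent exposure (pointwise).
        # The drive is added here; receptor decay happens in the network
        # step along with the other intracellular mediators.
        occ = self.occupied
        tlr = self.conc[S.MediatorId.TLR_ACT]
        if drive_axial.any() or tlr.any():
            drive_site = drive_unit[idx.site_unit]
            self.conc[S.MediatorId.TLR_ACT] = np.where(
                occ, tlr + drive_site, 0.0
            )
            self.exposure[occ] += self.conc[S.MediatorId.TLR_ACT][occ]

        # 3. scenario-driven inflammation (recovery scenario)
        ros_rate, tnfa_rate = self.inflam_bolus
        if ros_rate or tnfa_rate:
            self.conc[S.MediatorId.ROS] += ros_rate
            self.conc[S.MediatorId.TNFA] += tnfa_rate

        # 4. diffusion + decay (halo phase), then positional emission.
        # Fields that are identically zero with no emission are skipped
        # (their stencil output is exactly zero either way).
        D, lam, em, _ = self.signaling.arrays()
        active = np.array(
            [
                em[m] > 0.0 or self.conc[m].any()
                for m in _DIFF_IDS
            ]
        )
        ids = _DIFF_IDS[active]
        if ids.size:
            block = self.conc[ids]
            nxt = np.empty_like(block)
            for dom in self.domains:
                vals = dom.gather(block)  # ghost refresh
                out = S.diffuse_decay_step(
                    vals, D[ids], lam[ids], dom.lnb_self, dom.owned_pos
                )
                nxt[:, dom.owned_sites] = out
            for j, m in enumerate(ids):
                if em[m] > 0.0:
                    nxt[j, self.source_masks[int(m)]] += em[m]
            self.conc[ids] = nxt

        # 5. signed-network update (pointwise, synchronous)
        self.conc = S.network_step(self.conc, occ, self.signaling)

        # 6. cell rules
        occ = self.occupied
        self.clock[occ] += 1

        ros = self.conc[S.MediatorId.ROS]
        tnfa = self.conc[S.MediatorId.TNFA]
        if ros.any() or tnfa.any():  # death_rate(0, 0) = 0 exactly
            die = C.step_death(
                self.lineage, ros, tnfa, idx.site_key, t, self.seed,
                self.rules,
            )
            deaths += int(die.sum())
            self._clear_sites(np.flatnonzero(die))

        self.lineage = C.step_differentiation(
            self.lineage, self.conc[S.MediatorId.BMP], idx.site_comp,
            self.rules,
        )

        births += self._division_phase(t)
        atrophic = self._atrophic_mask()
        self._migration_phase(t, blocked=atrophic)

        shed = C.step_shedding(
            self.lineage, self.shed_zone, idx.site_key, t, self.seed,
            self.rules, atrophic=atrophic,
        )
        sheds += int(shed.sum())
        self._clear_sites(np.flatnonzero(shed))

        # 7. metaplasia: phenotype conversion + villus height reduction
        self._metaplasia_phase()

        # 8. record
        counts = self.population_counts()
        row = [t, t * 0.25] + [
            counts[k] for k in SERIES_COLUMNS[2:9]
        ] + [births, deaths, sheds]
        self._records.append(row)
        if self.debug:
            self._check_invariants(births, deaths, sheds)
        return {"births": births, "deaths": deaths, "sheds": sheds, **counts}

    def _division_phase(self, t: int) -> int:
        prolif = S.proliferation_drive(self.conc, self.signaling)
        srcs, dsts = [], []
        for dom in self.domains:
            lh = dom.gather(self.lineage)  # ghost refresh
            s, d = C.division_proposals(
                dom, lh, self.clock[dom.owned_sites],
                prolif[dom.owned_sites], self.index, self.rules, t,
                self.seed,
            )
            srcs.append(s)
            dsts.append(d)
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        if src.size == 0:
            return 0
        win = self._owner_resolve(src, dst)
        ws, wd = src[win], dst[win]
        parent_stem = self.lineage[ws] == C.Lineage.STEM
        self.lineage[wd] = np.where(
            parent_stem & self.stem_zone[wd],
            C.Lineage.STEM, C.Lineage.PROGENITOR,
        ).astype(np.int8)
        self.clock[ws] = 0
        self.clock[wd] = 0
        self.health[wd] = 1.0
        self.exposure[wd] = 0.0
        self.cell_id[wd] = site_rng_u64(
            self.index.site_key[wd], t, Stream.BIRTH_ID, self.seed
        )
        return int(win.sum())

    def _atrophic_mask(self):
        """Villus rows above a metaplastic unit's target height.

        These rows receive no migrants and shed at the atrophic rate,
        so the resize pass can trim them once empty.  Pure function of
        unit-level state, hence identical under any decomposition.
        """
        meta = self.unit_metaplastic
        if not meta.any():
            return None
        idx = self.index
        heights = np.array(
            [u.villus_height for u in idx.geom.units], dtype=np.int64
        )
        targets = heights.copy()
        for u in np.flatnonzero(meta):
            targets[u] = C.villus_target_height(
                self.unit_exposure[u], int(self.baseline_villus_height[u]),
                self.rules,
            )
        excess = meta & (heights > targets)
        if not excess.any():
            return None
        return (
            excess[idx.site_unit]
            & (idx.site_comp == int(Component.VILLUS))
            & (idx.site_row >= targets[idx.site_unit])
        )

    def _migration_phase(self, t: int, blocked=None) -> None:
        srcs, dsts = [], []
        for dom in self.domains:
            lh = dom.gather(self.lineage)  # ghost refresh (post-division)
            s, d = C.migration_proposals(
                dom, lh, self.index, self.rules, t, self.seed,
                blocked=blocked,
            )
            srcs.append(s)
            dsts.append(d)
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        if src.size == 0:
            return
        win = self._owner_resolve(src, dst)
        self._move_payload(src[win], dst[win])

    def _metaplasia_phase(self) -> None:
        thr = self.rules.metaplasia_exposure_threshold
        flagged_now = self.unit_exposure > thr
        if self.rules.metaplasia_reversible:
            self.unit_metaplastic = flagged_now
        else:
            self.unit_metaplastic |= flagged_now
        if not self.unit_metaplastic.any():
            return
        idx = self.index
        in_flagged = self.unit_metaplastic[idx.site_unit]
        conv = in_flagged & (self.lineage == C.Lineage.ENTEROCYTE)
        self.lineage[conv] = C.Lineage.METAPLASTIC

        # villus target height shrinks with exposure; only empty top rows
        # can actually be deleted (resize clamps at the top occupied row)
        occ = self.occupied
        vill_reg = (idx.site_comp == int(Component.VILLUS)) & ~idx.site_is_cap
        top_occ = np.full(idx.geom.n_units, -1, dtype=np.int64)
        m = vill_reg & occ
        np.maximum.at(top_occ, idx.site_unit[m], idx.site_row[m].astype(np.int64))
        requests: Dict[Tuple[int, Component], int] = {}
        for u in np.flatnonzero(self.unit_metaplastic):
            target = C.villus_target_height(
                self.unit_exposure[u], int(self.baseline_villus_height[u]),
                self.rules,
            )
            eff = max(target, int(top_occ[u]) + 1, 1)
            if eff < idx.geom.units[u].villus_height:
                requests[(int(u), Component.VILLUS)] = eff
        if requests:
            self._apply_resizes(requests)

    def _apply_resizes(self, requests: Dict[Tuple[int, Component], int]) -> None:
        payloads = {
            "lineage": (self.lineage, C.EMPTY),
            "clock": (self.clock, 0),
            "health": (self.health, 0.0),
            "exposure": (self.exposure, 0.0),
            "cell_id": (self.cell_id, 0),
            "conc": (self.conc, 0.0),
        }
        new_index, out, _ = apply_resizes(
            self.index, requests, payloads, self.occupied
        )
        self.index = new_index
        self.lineage = out["lineage"]
        self.clock = out["clock"]
        self.health = out["health"]
        self.exposure = out["exposure"]
        self.cell_id = out["cell_id"]
        self.conc = out["conc"]
        self._rebuild_partitions()
        self._rebuild_masks()

    def _check_invariants(self, births: int, deaths: int, sheds: int) -> None:
        if len(self._records) >= 2:
            prev = self._records[-2][2]
            cur = self._records[-1][2]
            assert cur - prev == births - deaths - sheds, (
                "population bookkeeping broken: "
                f"{prev} -> {cur} vs +{births} -{deaths} -{sheds}"
            )
        # negative concentrations forbidden by every operation
        assert (self.conc >= 0.0).all(), "negative mediator concentration"

    def run(self, n_steps: int) -> pd.DataFrame:
        for _ in range(n_steps):
            self.step()
        return self.series

    # -- equivalence ---------------------------------------------------

    def state_signature(self) -> Dict[str, np.ndarray]:
        """Full per-site dynamic state (for lockstep equivalence diffs)."""
        return {
            "lineage": self.lineage.copy(),
            "clock": self.clock.copy(),
            "exposure": self.exposure.copy(),
            "cell_id": self.cell_id.copy(),
            "conc": self.conc.copy(),
            "unit_exposure": self.unit_exposure.copy(),
            "unit_metaplastic": self.unit_metaplastic.copy(),
        }
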