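"""Mediator fields and the signed stimulation/inhibition network.

Each signaling mediator is a per-site non-negative concentration in
relative (dimensionless) units.  Secreted mediators (Wnt, BMP, Hh,
TNF-a, IFN-g, the interleukins, ROS) diffuse over the folded grids with
an explicit 5-point stencil and decay multiplicatively; intracellular
mediators (PTEN, PI3K, Akt, RIP kinase, NF-kB, JAK, STAT3, and TLR
receptor activation) live on the cell occupying a site, do not diffuse,
and travel with the cell when it migrates.

The network couples mediators with signed weighted edges (stimulation
+1 / inhibition -1).  The synchronous per-site update for an
intracellular target is

    next = clamp0( c + sum_stim w*src - sum_inhib w*src + basal - lam*c )

applied from the previous step's vector.  For diffusible targets the
network contributes production only; their decay is applied once, in the
field step.  The morphogen pattern comes from positional sources: Wnt
and Hh are secreted at the crypt base, BMP at the villus tip, so that
at steady state Wnt/Hh fall and BMP rises along the crypt-to-tip axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import Component, GeometryIndex

__all__ = [
    "MediatorId",
    "DIFFUSIBLE",
    "INTRACELLULAR",
    "FieldParams",
    "NetworkEdge",
    "SignedNetwork",
    "SignalingParams",
    "diffuse_decay_step",
    "apply_sources",
    "network_step",
    "apply_knockout",
    "gradient_profile",
    "proliferation_drive",
]


class MediatorId(IntEnum):
    WNT = 0
    BMP = 1
    HH = 2
    PTEN = 3
    PI3K = 4
    AKT = 5
    TNFA = 6
    IFNG = 7
    RIPK = 8
    NFKB = 9
    JAK = 10
    STAT3 = 11
    ROS = 12
    IL6 = 13
    IL10 = 14
    IL13 = 15
    IL15 = 16
    TLR_ACT = 17


N_MEDIATORS = len(MediatorId)

# Secreted mediators diffuse between sites; intracellular ones are carried
# by the resident cell (D = 0) and are cleared when a site empties.
DIFFUSIBLE = (
    MediatorId.WNT, MediatorId.BMP, MediatorId.HH, MediatorId.TNFA,
    MediatorId.IFNG, MediatorId.ROS, MediatorId.IL6, MediatorId.IL10,
    MediatorId.IL13, MediatorId.IL15,
)
INTRACELLULAR = tuple(m for m in MediatorId if m not in DIFFUSIBLE)


@dataclass
class FieldParams:
    """Per-mediator rates: diffusivity (sites^2/step), decay (fraction per
    step), basal production and positional emission (per step)."""

    D: float = 0.0
    lam: float = 0.1
    emission: float = 0.0   # rate at this mediator's source sites
    basal: float = 0.0      # constitutive intracellular production

    def validate(self, name: str) -> None:
        if self.D < 0 or not 0.0 <= self.lam <= 1.0 or self.emission < 0 or self.basal < 0:
            raise ValueError(f"invalid rates for {name}: {self}")
        if 4.0 * self.D > 1.0:
            raise ValueError(
                f"diffusivity {self.D} of {name} violates the explicit "
                "stencil stability bound 4*D <= 1"
            )


@dataclass(frozen=True)
class NetworkEdge:
    source: MediatorId
    target: MediatorId
    sign: int       # +1 stimulation, -1 inhibition
    weight: float


# Minimum hard-wired edge set of the inflammatory/morphogen network; the
# interleukin-13/15 connectors are exposed in configuration with zero
# default weight because their wiring is not pinned down.
DEFAULT_EDGES: Tuple[Tuple[str, str, int, float], ...] = (
    ("TLR_ACT", "NFKB", +1, 0.3),
    ("TNFA", "NFKB", +1, 0.1),
    ("NFKB", "TNFA", +1, 0.1),
    ("NFKB", "IL6", +1, 0.1),
    ("NFKB", "ROS", +1, 0.1),
    ("IFNG", "RIPK", +1, 0.3),
    ("RIPK", "ROS", +1, 0.1),
    ("IL6", "JAK", +1, 0.3),
    ("JAK", "STAT3", +1, 0.3),
    ("IL10", "NFKB", -1, 0.3),
    ("PTEN", "PI3K", -1, 0.3),
    ("PI3K", "AKT", +1, 0.3),
    ("IL13", "NFKB", -1, 0.0),
    ("IL15", "NFKB", +1, 0.0),
)


@dataclass
class SignedNetwork:
    edges: List[NetworkEdge] = field(default_factory=list)

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, str, int, float]]) -> "SignedNetwork":
        edges = []
        for s, t, sign, w in tuples:
            try:
                src, dst = MediatorId[s], MediatorId[t]
            except KeyError as e:
                raise ValueError(f"unknown mediator in network config: {e}") from None
            if src == dst:
                raise ValueError(f"self-edge on {s} not allowed")
            if sign not in (+1, -1) or w < 0:
                raise ValueError(f"bad edge ({s},{t},{sign},{w})")
            edges.append(NetworkEdge(src, dst, sign, float(w)))
        return cls(edges)

    def to_tuples(self) -> List[Tuple[str, str, int, float]]:
        return [
            (e.source.name, e.target.name, e.sign, e.weight) for e in self.edges
        ]


def _default_fields() -> Dict[MediatorId, FieldParams]:
    f: Dict[MediatorId, FieldParams] = {
        m: FieldParams(D=0.0, lam=0.2, emission=0.0, basal=0.0)
        for m in MediatorId
    }
    # morphogens: steep source-anchored gradients
    f[MediatorId.WNT] = FieldParams(D=0.2, lam=0.1, emission=1.0)
    f[MediatorId.HH] = FieldParams(D=0.2, lam=0.1, emission=1.0)
    f[MediatorId.BMP] = FieldParams(D=0.2, lam=0.1, emission=1.0)
    # inflammatory secreted mediators
    for m in (MediatorId.TNFA, MediatorId.IFNG, MediatorId.ROS,
              MediatorId.IL6, MediatorId.IL10, MediatorId.IL13,
              MediatorId.IL15):
        f[m] = FieldParams(D=0.1, lam=0.3)
    # constitutive intracellular tone so the PTEN -| PI3K -> AKT arm is live
    f[MediatorId.PTEN] = FieldParams(lam=0.2, basal=0.1)
    f[MediatorId.PI3K] = FieldParams(lam=0.2, basal=0.1)
    f[MediatorId.TLR_ACT] = FieldParams(lam=0.3)
    return f


@dataclass
class SignalingParams:
    """Full signaling configuration: rates, network, sources, knockouts."""

    fields: Dict[MediatorId, FieldParams] = field(default_factory=_default_fields)
    network: SignedNetwork = field(
        default_factory=lambda: SignedNetwork.from_tuples(DEFAULT_EDGES)
    )
    w_stat3: float = 0.5          # STAT3 -> proliferation-drive weight
    crypt_source_rows: int = 3    # Wnt/Hh secreted in this many basal rows (+valley cap)
    villus_source_rows: int = 4   # BMP secreted in this many tip rows (+tip cap)
    knockouts: Tuple[str, ...] = ()

    def validate(self) -> None:
        for m, fp in self.fields.items():
            fp.validate(MediatorId(m).name)
            if m in INTRACELLULAR and fp.D != 0.0:
                raise ValueError(f"intracellular mediator {MediatorId(m).name} must not diffuse")

    def source_mask(self, index: GeometryIndex, mediator: MediatorId) -> np.ndarray:
        """Positional emission predicate of a mediator (pure in GridCoord)."""
        if mediator in (MediatorId.WNT, MediatorId.HH):
            return index.crypt_base_mask(self.crypt_source_rows)
        if mediator == MediatorId.BMP:
            return index.villus_tip_mask(self.villus_source_rows)
        return np.zeros(index.n_sites, dtype=bool)

    def arrays(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(D, lam, emission, basal) vectors over MediatorId order."""
        D = np.array([self.fields[m].D for m in MediatorId])
        lam = np.array([self.fields[m].lam for m in MediatorId])
        em = np.array([self.fields[m].emission for m in MediatorId])
        basal = np.array([self.fields[m].basal for m in MediatorId])
        return D, lam, em, basal


def apply_knockout(params: SignalingParams, mediator: MediatorId) -> SignalingParams:
    """Zero all production of a mediator (gene knockout).

    Emission, basal production and incoming stimulatory edges are set to
    zero; the existing concentration simply decays.  Returns a modified
    copy; the input is untouched.
    """
    mediator = MediatorId[mediator] if isinstance(mediator, str) else MediatorId(mediator)
    fields = {m: replace(fp) for m, fp in params.fields.items()}
    fields[mediator] = replace(fields[mediator], emission=0.0, basal=0.0)
    edges = [
        replace(e, weight=0.0)
        if (e.target == mediator and e.sign > 0) else e
        for e in params.network.edges
    ]
    return replace(
        params,
        fields=fields,
        network=SignedNetwork(edges),
        knockouts=tuple(params.knockouts) + (mediator.name,),
    )


# -- field dynamics -----------------------------------------------------

def diffuse_decay_step(
    values: np.ndarray,
    D: np.ndarray,
    lam: np.ndarray,
    lnb: np.ndarray,
    owned_pos: np.ndarray,
) -> np.ndarray:
    """One explicit stencil + decay step for a block of fields.

    ``values`` is (n_fields, n_halo) previous-step state over a worker's
    halo; ``lnb`` the (n_owned, 4) halo-local neighbor table in which a
    missing neighbor is replaced by the site itself (``Domain.lnb_self``;
    a -1 entry is also accepted and treated the same way).  Returns
    (n_fields, n_owned) next values.  Missing neighbors contribute no
    flux, so with lam = 0 and no sources the stencil conserves total
    mass on the closed folded surface; decay then removes exactly lam
    times the pre-decay mass.
    """
    own = values[:, owned_pos]
    if (lnb < 0).any():
        lnb = np.where(lnb >= 0, lnb, owned_pos[:, None])
    acc = values[:, lnb[:, 0]]
    for s in range(1, 4):
        acc = acc + values[:, lnb[:, s]]
    acc -= 4.0 * own
    out = own + D[:, None] * acc
    out *= (1.0 - lam)[:, None]
    np.maximum(out, 0.0, out=out)
    return out


def apply_sources(
    values: np.ndarray,
    emission: np.ndarray,
    source_masks: np.ndarray,
) -> None:
    """Add positional emission in place: values[f, mask] += emission[f]."""
    for f in range(values.shape[0]):
        if emission[f] > 0.0:
            values[f, source_masks[f]] += emission[f]


def network_step(
    conc: np.ndarray,
    occupied: np.ndarray,
    params: SignalingParams,
) -> np.ndarray:
    """Synchronous signed-network update of the mediator vector per site.

    ``conc`` is (N_MEDIATORS, n_sites) previous-step state.  Intracellular
    targets get the full production - decay update (restricted to occupied
    sites and cleared elsewhere); diffusible targets receive production
    only, their decay being handled by the field step.  All outputs are
    clamped at zero.
    """
    _, lam, _, basal = params.arrays()
    occ_idx = np.flatnonzero(occupied)
    # per-target production on the occupied subset; edges whose source is
    # identically zero contribute nothing and are skipped outright
    delta: dict = {}
    for e in params.network.edges:
        if e.weight == 0.0 or not conc[e.source].any():
            continue
        d = delta.setdefault(int(e.target), np.zeros(occ_idx.size))
        d += e.sign * e.weight * conc[e.source][occ_idx]
    out = conc.copy()
    for m in MediatorId:
        if m in INTRACELLULAR:
            cur = conc[m]
            if basal[m] == 0.0 and int(m) not in delta and not cur.any():
                continue  # stays exactly zero
            nxt = np.zeros_like(cur)
            v = cur[occ_idx] * (1.0 - lam[m]) + basal[m]
            if int(m) in delta:
                v = v + delta[int(m)]
            nxt[occ_idx] = np.maximum(v, 0.0)
            out[m] = nxt  # intracellular state exists only on cells
        elif int(m) in delta:
            row = out[m]
            row[occ_idx] = np.maximum(row[occ_idx] + delta[int(m)], 0.0)
    return out


def proliferation_drive(conc: np.ndarray, params: SignalingParams) -> np.ndarray:
    """Per-site proliferative stimulus: local Wnt plus the STAT3 arm."""
    return conc[MediatorId.WNT] + params.w_stat3 * conc[MediatorId.STAT3]


# -- observables --------------------------------------------------------

def gradient_profile(
    values: np.ndarray,
    index: GeometryIndex,
    unit_index: Optional[int] = None,
) -> pd.DataFrame:
    """Mean concentration per elevation row along the crypt-base -> villus-tip
    axis (crypt valley first, villus tip cap last).

    ``values`` is a single field (n_sites,).  Returns a DataFrame with
    columns ``row`` (0-based along the axis) and ``mean_concentration``.
    """
    mask = np.ones(index.n_sites, dtype=bool)
    if unit_index is not None:
        mask = index.site_unit == unit_index
    elev = index.site_elevation[mask]
    vals = np.asarray(values)[mask]
    levels = np.unique(elev)
    means = [float(vals[elev == lv].mean()) for lv in levels]
    return pd.DataFrame(
        {"row": np.arange(levels.size), "mean_concentration": means}
    )


def gradient_profiles_csv(
    conc: np.ndarray,
    index: GeometryIndex,
    mediators: Sequence[MediatorId],
    path,
) -> pd.DataFrame:
    """Write per-row profiles of several mediators as tidy CSV."""
    frames = []
    for m in mediators:
        df = gradient_profile(conc[m], index)
        df.insert(1, "mediator", MediatorId(m).name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, index=False)
    return out
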