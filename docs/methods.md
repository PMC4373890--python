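# Methods

This note documents the model implemented in `pouchsim`: its
assumptions, the parameters that matter, the numerical choices, and what
the desk-scale tests do and do not demonstrate.

## Tissue representation

The ileal pouch is a cylinder of diameter × length (anatomic default
3.5 cm × 6 cm) tiled with crypt-villus units at a center-to-center
spacing (default 0.5 mm), giving `n_circ = ⌊π·d/spacing⌋` columns
(wrapping) and `n_axial = ⌊L/spacing⌋` rows (not wrapping). Each unit
carries a crypt prism and a villus prism; each prism is represented by
its four lateral faces unwrapped into `rows × face_width` grids. The
fold joins face col-edges around the prism, closes tip and valley with
one cap row joining opposite faces (mirrored columns), and joins the
villus base row to the crypt mouth row of the unit one lattice step away
in the face's direction (mirrored columns). At the axial cut ends of
the cylinder the flat folds back onto the same unit's crypt. With that
closure every lattice site has exactly four neighbors, the folded
surface is closed (diffusion conserves mass to round-off), and every
villus column is connected to a proliferative compartment — without it,
boundary columns would drain irreversibly.

The prism face count, the one-cap-row closure, and the face↔direction
pairing are this package's concrete realization of the folded topology;
they are configurable where biologically meaningful (template heights,
face width) and fixed where only consistency matters. The default
template is crypt 12 rows deep, villus 48 rows tall, faces 6 wide: at
full occupancy villus and crypt hold sites in ratio
(49·24)/(13·24) ≈ 3.8, placing the homeostatic population ratio near
the ~4:1 histological benchmark.

A dense site index (unit-major, crypt before villus, then face, row,
col) backs all array kernels. Each site has a stable 64-bit key packing
(unit, component, face, row, col); keys survive re-partitioning and
resizing, which is what makes the counter-based RNG layout-independent.

**3D embedding** (rendering only): unit centers on the cylinder
surface, villus sites displaced luminally by `row × cell diameter`
(default 10 µm), crypt sites inward, faces offset laterally by the
prism half-width, the villus prism offset half a spacing from its crypt.
No physics reads these coordinates.

**Dynamic resizing** happens only between steps: growth appends empty
rows at the villus tip / crypt mouth; shrinking removes empty top rows
only and is clamped at the highest occupied row (with a logged
warning). Payloads are remapped site-for-site by identity; cap rows are
renumbered, never deleted.

## Timestep (15 minutes)

Phases, all two-phase (read previous state, write next), in fixed
order: stool cycle → TLR/exposure update → scenario boluses →
diffusion + decay + emission → signed-network update → cell rules
(clock, death, differentiation, division, migration, shedding) →
metaplastic conversion and height targets → bookkeeping. The update
discipline, not the worker layout, determines the result; that is the
basis of the serial/partitioned equivalence.

## Signaling

Concentrations are relative (dimensionless) and non-negative by
clamped updates. Secreted mediators diffuse with an explicit stencil
`c′ = c + D·Σ(c_nbr − c)`, checked against the stability bound
`4D ≤ 1` at configuration time, then decay multiplicatively by
`(1 − λ)`; sources add after decay. Intracellular mediators have
`D = 0`, are cleared when a site empties, and move with a migrating
cell. The split (which mediators diffuse) follows biological
convention; it is not derivable from the network diagram alone.

Defaults: morphogens (Wnt, Hh at crypt base rows 0–2 + valley cap; BMP
at the top 4 villus rows + tip cap) use `D = 0.2, λ = 0.1`, emission
1.0/step, giving a decay length `√(D/λ) ≈ 1.4` rows — steep,
source-anchored gradients whose per-row profiles are strictly monotone
along the crypt→tip axis (Spearman |ρ| ≥ 0.9 in the tests). Secreted
inflammatory mediators use `D = 0.1, λ = 0.3`. Network weights default
to 0.1–0.3 with intracellular decay 0.2; PTEN and PI3K carry a
constitutive basal production (0.1/step) so the PTEN ⊣ PI3K → Akt arm
has a live operating point (a PTEN knockout then strictly raises the
Akt fixed point). The interleukin-13/15 connectors ship with zero
weight: their wiring is left to configuration. A knockout zeroes a
mediator's emission, basal production, and incoming stimulatory edges;
existing concentration decays naturally.

None of these rate constants is an empirical measurement; they are
package defaults chosen (once) so the homeostasis, gradient-shape and
knockout properties hold, and every one of them is exposed in the
shipped `defaults.yaml`.

## Cell rules

* **Division** — stem (cycle 96 steps = 24 h) and progenitor (48 steps
  = 12 h) cells divide when the clock has run out, the proliferative
  drive `Wnt + 0.5·STAT3` meets `θ_wnt = 0.1`, and an empty neighbor
  exists (contact inhibition). The Wnt threshold admits roughly the
  lower two-thirds of the crypt — a transit-amplifying zone — which is
  what lets returning vacancies be absorbed near the crypt mouth
  rather than queuing down to the stem compartment. Stem daughters
  placed in the base zone (3 rows + valley cap) stay stem; all others
  are progenitors.
* **Differentiation** — progenitor → enterocyte at `BMP ≥ 0.5` or on
  entering the villus; irreversible except for metaplastic conversion.
* **Migration** — non-stem cells attempt one move per step, with
  probability `migration_prob = 0.2`, into an empty neighbor of
  strictly higher elevation (crypt valley < crypt mouth < villus base
  < tip). The attempt probability sets the conveyor speed: ~0.2
  rows/step ≈ 50 µm/h, a villus transit of ~2.5 days. The same single
  deviate gates the attempt and picks among candidate targets.
* **Shedding** — enterocytes/metaplastic cells in the top villus row +
  tip cap are removed with `shed_prob = 0.007`/step. This is the flux
  valve: demand (≈0.3 cells/unit/step) sits below both the division
  supply and the conveyor capacity, so homeostasis is shed-limited and
  the villus stays ~90–95 % occupied. The implied epithelial renewal
  is slower than the physiological 3–5 days — the price of keeping
  desk-scale dynamics stable and legible; see Limitations.
* **Death** — `p = 1 − exp(−(0.01·ROS + 0.01·TNFα))` per step: zero at
  zero dose and monotone in both, by construction.
* **Ulcer** — removes all agents within a breadth-first ball on the
  folded graph and deposits a TNFα/ROS bolus (defaults 5.0) on the
  wound bed. With no bolus a wound re-occupies ≥ 95 % by conveyor and
  division; with the bolus it first spreads slightly.
* **Metaplasia** — each unit integrates the stool TLR drive; past an
  exposure threshold (150) its enterocytes convert to the metaplastic
  phenotype (irreversible by default; a config switch makes it track
  exposure) and its villus target height falls by one row per 11 units
  of excess exposure, floored at 12 rows. Rows above the target stop
  receiving migrants and shed at `atrophic_shed_prob = 0.05`, so the
  resize pass can trim them once empty — villus atrophy, implemented
  at unit granularity because the phenomenon is diffuse villus
  shortening, not per-cell detail.

Initialization fills crypts (stem in the base zone, progenitors above)
and villi (enterocytes) with staggered cycle clocks; the first ~500
steps are an equilibration window excluded from steady-state metrics.

## Stool model

No fluid dynamics: one parcel enters per step, the pouch fills in
`fill_steps = 16` steps (exactly 4 h at 15 min/step) and empties.
Parcel IP is evaluated as `ip0 + ΔIP·(residence steps)` — algebraically
the linear recurrence, computed multiplicatively so the linearity is
exact rather than accumulated in floating point. Filling is
terminal-first (the stasis surrogate): parcel *k* of a cycle covers the
*k*-th axial band from the distal end, so the cumulative TLR drive over
a cycle is `k_tlr·ΔIP·(F−b)(F−b−1)/2` for band *b* — monotone
non-increasing toward the inflow, the generative mechanism of the
terminal-dominant metaplasia gradient. A config switch flips to
proximal-first (the gradient reverses — the tests use this as a
mechanism check) or to a pouch-wide scalar IP instead of per-parcel
accounting. `calibrate_delta_ip` bisects ΔIP against the
terminal-quartile metaplastic fraction of a reduced-scale run; the
shipped pouchitis default ΔIP = 0.05 drives the terminal quartile to
full metaplasia at desk scale within a 2000-step run.

## Parallel decomposition

Workers own rectangular blocks of units (near-equal, circumferentially
wrapping); the factorization of P must fit the lattice, otherwise the
error lists admissible counts. Ghost buffers are exactly the one-cell
neighborhood of the owned sites; `exchange_ghosts` refreshes them by
copying owner values (bit-for-bit equality is therefore structural).
Rules read dynamic state only through halo-local arrays — a site beyond
the ghost layer has no local address, which doubles as the access
guard. Neighbor-reading rules emit (source, destination) proposals;
the owner of the destination picks one winner by minimizing
(hash, source-key), a pure function of the proposal set. Logical
workers are sequential sweeps in one process: the specified contract is
the communication pattern and the equivalence, not a particular
transport. Equivalence (P ∈ {1,2,4} byte-identical outputs, including
runs with inflammation and metaplastic resizing) is asserted in the
test suite and available at runtime via `--check-equivalence`.

The RNG is a splitmix64-style counter hash of (master seed, site key,
step, stream), one stream per stochastic rule. It passes a KS
uniformity check at n = 10⁵ and is pure in its arguments, so deviates
never depend on worker layout or iteration order.

## Problem sizes

Desk-scale defaults: 8×8 units ≈ 95,000 sites, 2000 steps (≈ 21
simulated days), minutes on one CPU. The anatomic 3.5 cm × 6 cm
cylinder (219 × 120 units, ≈ 39 M sites) is constructed for size
accounting and config echo but not stepped by default; pouchitis runs
simulate a coarse unit lattice spanning the full axial length, each
unit standing for a patch of tissue. Tests use smaller lattices (2×2
to 4×4 units with reduced templates) except where a criterion names
the desk scale.

## Limitations

* Epithelial renewal at the shipped rates is slower than physiological
  turnover; the architecture (ratio, gradients, wound closure) is the
  validated object, not absolute fluxes.
* No immune cell agents, no microbial population dynamics, no
  receptor-level kinetics, no mechanics: inflammation enters only as
  mediator fields and the stool TLR drive.
* The fold's unstated geometric details (face count, cap closure,
  face↔direction pairing, axial-end closure) are one consistent
  realization; quantities that depend on them (site counts, exact
  adjacency) are internally consistent but not unique.
* Synthetic study conditions: every simulation input is generated by
  the package itself; passing tests demonstrate internal consistency
  and the qualitative behaviors described above, not agreement with
  any particular experimental dataset.
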