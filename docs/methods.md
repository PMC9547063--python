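# Methods

## Model

Flow in every vessel is laminar Stokes flow (Reynolds numbers are checked
and stay below 1 throughout), so each vessel obeys Poiseuille's law with
an effective resistance

    R_ij = 128 L_ij µ µ_rel(D_ij, H_d,ij) / (π D_ij⁴),

where µ is the dynamic plasma viscosity (default 1.2·10⁻³ Pa·s, a
documented default) and µ_rel the relative effective viscosity of blood.
Mass conservation at every interior node yields a sparse symmetric
positive-definite system for nodal pressures with Dirichlet pressures at
boundary nodes. Units: µm for geometry, mmHg for pressure, µm³/ms for
flow; the single conversion constant lives in `capnet.constants`.

Three empirical laws of the Pries–Secomb family represent the particulate
nature of blood (coefficient set pinned as `law_version =
"pries1990_invitro"` in provenance output):

* **Relative effective viscosity** — the 1992 in vitro fit: equal to 1 at
  zero hematocrit, increasing in hematocrit, with the Fahraeus–Lindqvist
  minimum near 7–10 µm. The fit is evaluated with the discharge
  hematocrit, clipped at 0.99 (it has a pole at H_d = 1 for diameters
  with a negative shape exponent).
* **Fahraeus relation** — tube hematocrit H_t = H_d (H_d + (1−H_d) F(D)).
  Because this is quadratic in H_d, the inverse (discharge from tube) is
  evaluated in closed form. The raw F(D) exceeds 1 below ~2.6 µm, which
  would make cells slower than plasma — an extrapolation artifact outside
  the fit's calibration range — so F is floored at 1 there (cells fill
  the lumen and move with the plasma).
* **Phase separation** (Zweifach–Fung) — the logit law with
  B = 1 + 6.98 (1−H_d)/D_f > 1 (the higher-flow daughter receives a
  disproportionate share of cells), the diameter-asymmetry term A, and
  the X₀ cutoff below which a branch receives no cells at all. It applies
  at divergent bifurcations whose parent is wider than 10 µm; narrower
  parents carry cells in single file, and each cell follows the path of
  the largest pressure force, implemented as the largest Δp/L toward a
  candidate daughter (ties broken toward the lower vessel index).

## Discrete RBC tracking

Cells are particles with a vessel and an arc position. Each step of
`time_step` (default 1.0 ms) they move by v_rbc·dt, where v_rbc is the
bulk velocity times H_d/H_t (cells travel faster than bulk blood; the
dilute-limit ratio 1/F(D) is used in empty vessels). A cell reaching a
node is clamped there and routed at the start of the next step:
boundary nodes discharge it from the domain, convergent nodes pass it to
the single outflow, divergent nodes use the routing rules above. Tube
hematocrit is cell count × cell volume (default 55 µm³, a mouse RBC) over
vessel volume; every `coupling_interval` steps (default 10) the
hematocrit, viscosity and pressure field are recomputed — the two-way
coupling that makes the flow field fluctuate in time.

At the default time step a cell moves at most ~a quarter of the shortest
vessel per step on the default networks; `simulate` raises with a
suggested bound if the initial field implies a cell could jump a whole
vessel in one step.

**Injection.** Cells enter at every inflow boundary vessel at the inflow
hematocrit (0.3 for all experiments, kept constant together with the
pressure boundary conditions). Arrival spacing is regular, via a
deterministic per-vessel accumulator (rate = |q|·H_in / V_rbc): the
feeding vessel's hematocrit is steady, and Poisson arrivals would
overstate the inflow variance — with Poisson injection the run-to-run
fluctuation of 15.4 s time-averages exceeded the 10%-change rule in ~15%
of mid-flow vessels, burying the dilation signal at desk scale.

**Hematocrit cap.** Cells are neither routed nor injected into a vessel
whose tube hematocrit has reached `max_tube_hematocrit` (default 0.5);
blocked cells wait at their node and are re-tried after the next field
update. The cap represents the packing limit of single-file cells in
narrow capillaries; it also keeps the viscosity law inside its calibrated
hematocrit range (≲0.6). Without it, near-stagnant vessels slowly fill
toward jamming, and the resulting conductance flicker makes time-averaged
fields irreproducible within the 15.4 s window (a stationarity
diagnostic — the number of vessels whose 15.4 s averages differ by >10%
between two independent baseline runs — drops from ~250 to ~45 of ~3,000
vessels when the cap is lowered from 0.9 to 0.5). A `jam_steps` counter in
the diagnostics reports how often the cap was hit.

**Time averaging and pairing.** The comparison quantity between scenarios
is the per-vessel flow averaged over a 15.4 s window, after a 5 s warm-up
(several network transit times at desk scale; both config-exposed). The
counted cell flux per vessel (departures per second) is also reported and
agrees with time-averaged flow × discharge hematocrit / cell volume to a
few percent on toys (the residual is O(dt / vessel transit time), from
cells clamped at nodes being counted in their parent vessel). Routing
draws at divergent bifurcations come from one random stream per
bifurcation, seeded by (simulation seed, node id); the experiment reuses
one simulation seed for the baseline and all dilation scenarios of a
network, so realizations are paired and scenario-vs-baseline differences
measure the dilation rather than independent fluctuation histories.

## Synthetic cortical networks

The generator emulates the summary statistics of acquired mouse cortical
networks at desk scale (default ~3,000 vessels in a (550 µm)³ domain, a
size at which one full simulation runs in ~25 s on one CPU):

* a capillary mesh built from a jittered 3-D lattice: a random spanning
  tree plus chords preferring low-degree endpoints, interior dead-end
  stubs reconnected or pruned, and pass-through joints merged so that
  every edge is a true inter-bifurcation segment whose tortuous path
  length includes the removed points (mean segment length ~65 µm, floored
  at 15 µm);
* capillary diameters from a truncated normal with mean 3.04 µm, SD
  0.59 µm, truncated to [2.17, 4.81] µm; the underlying location is
  shifted so the truncated distribution's mean equals 3.04 exactly;
* three penetrating-arteriole and three ascending-venule trees: a pial
  vessel at the surface (its far node is the pressure inlet/outlet), a
  trunk descending to 70% of the domain depth with geometric taper
  (15→9 µm arterioles, 20→11 µm venules), coupled to the mesh through
  1–3 segment transition paths; transition diameters are drawn from the
  upper half of the capillary distribution (the arteriole–capillary
  transition zone is wider than the mid-bed, and sub-3 µm couplings would
  throttle the entire tree);
* trunk segmentation chosen so non-capillary vessels make up roughly 4%
  of the network (capillary fraction ~0.96);
* boundary nodes on the lateral and bottom faces of the lattice and at
  the pial roots.

Default boundary pressures are 60 mmHg at pial-artery inlets and 10 mmHg
at pial-vein outlets (config-exposed defaults); capillary boundary nodes
are interpolated between the two levels by relative BFS distance to the
arteriole and venule trees, mimicking the pressure a cut capillary would
see at its position along the arteriole-to-venule path. All downstream
comparisons are relative (dilated vs baseline), so only the overall
perfusion scale depends on these values.

**What the generator does and does not emulate.** It reproduces the
composition (≥94% capillaries), capillary diameter statistics, depth
coordinates, tree topology and a connected 3-D mesh. It does not attempt
anatomical embedding realism (no curvature optimization, no layer-specific
densities), and its capillary diameters follow the in vivo optically
measured distribution (~3 µm), which is narrower than the lumen diameters
typical of vectorized network reconstructions (~4–5 µm). Absolute flows
and RBC fluxes therefore sit several-fold below in vivo line-scan values
(median capillary velocity ~0.1 mm/s here vs ~1 mm/s in vivo), while
relative responses — redistribution, steal, heterogeneity — are the
quantities of interest and are insensitive to this scale. Passing tests
demonstrate the relative phenomenology, not absolute perfusion levels.

## Dilation experiment

Base capillaries must be capillaries at 20–120 µm cortical depth, beyond
four branch orders from the penetrating-arteriole main branch (0th
order), beyond one branch from the ascending-venule main branch, at least
two branches from the domain boundary, and closer than 0.9× the mean x–y
distance of all vessels to the network centre (the last two keep the
dilated region away from the boundary conditions). Depth and distances
use vessel midpoints; "branches apart" counts bifurcations crossed along
the vessel path (an adjacent vessel is 1 branch apart; a vessel touching
a boundary node is 0 branches from the boundary).

The affected set grows from the base capillary's upstream bifurcation
(the higher-pressure endpoint at baseline; near-zero flows break the tie
toward the lower arteriole branch order) in adjacency rings until 6
capillaries have been added, then from the downstream node until the set
(including the base) holds 13. Vessels that are 0th-order mains, <2
branches from a descending-arteriole main branch, or <2 branches from the
boundary are never added. Within a ring, vessels are added in ascending
index order — a deterministic tie-break — stopping at the quota, so sets
are reproducible and sized 13–15. Every member is dilated by the scenario
increment (0.6, 1.1 or 1.6 µm — the adult-average, aged-average and
aged-extreme responses); dilation is a pure geometric perturbation.

## Analysis definitions

* **Relative flow change** = (|q_post| − |q_pre|)/|q_pre| on time-averaged
  flows; differences below 0.1 µm³/ms are set to 0 (fluctuation floor),
  and only |change| > 10% counts as increased/decreased.
* **Neighbour classes**: dilated, Gen1 (sharing a node with a dilated
  vessel), Gen2 (sharing a node with a Gen1 vessel); precedence
  dilated > Gen1 > Gen2.
* **Distance profiles**: vessel midpoint distance to the centre of the
  dilated region (mean coordinate of the dilated capillaries'
  bifurcations), binned at 50 µm, increases and decreases separated,
  medians and quartiles per bin.
* **Steal records**: every bifurcation whose baseline flow pattern is
  divergent with exactly one dilated and one undilated outflow; the
  undilated branch's relative flow and flux changes are reported.
* **Heterogeneity reference**: around every qualifying base capillary an
  affected-style set is built and the sample SD (ddof = 1) of baseline
  |flow| recorded; the median of these SDs is the expected baseline
  heterogeneity, with the 0.75 quantile as a second guide level. The
  dilated set's SD is compared against this distribution per scenario.
* **Stall census**: the threshold is the 5th percentile (linear
  interpolation) of baseline |flow| over vessels with midpoint depth
  ≤ 200 µm; capillaries below it are counted per neighbour class and
  within 200 µm of the dilation centre, per scenario.

## Numerical choices

* Direct sparse LU on the reduced pressure system with up to five rounds
  of iterative refinement (conductances span ~6 orders of magnitude);
  interior-node balance is asserted after every solve at 1e-10 relative
  to the node-local throughflow (floored at the network-mean |flow| so
  dead-end nodes do not divide round-off by round-off). A preconditioned
  conjugate-gradient path exists for systems beyond 200k free nodes.
* CSV I/O writes floats at 17 significant digits and reads them with
  round-trip parsing, so save/load is bit-exact.
* Trifurcations and higher-degree outflows are reduced to sequential
  binary phase-separation splits ordered by flow (the generator rarely
  emits them); the reduction conserves cells exactly.
* Sample SDs use ddof = 1 throughout the heterogeneity analysis.

## Problem sizes

The shipped experiment uses two ~3,000-vessel networks with two base
capillaries each (four cases), simulating a 15.4 s window after 5 s
warm-up for the baseline and each of the three increments — 14
simulations in roughly seven minutes on one CPU. Larger networks (the
acquired-network scale of 12k–19k vessels) are reachable through
`GeneratorConfig(target_vessel_count=...)`.

## Limitations

* Absolute perfusion sits below in vivo values (see the generator note
  above); conclusions are about relative changes.
* No blood-cell adhesion, vasomotion, compliance or oxygen transport; the
  stall census counts low-flow vessels against a baseline percentile and
  is not expected to capture adhesion-mediated stalling.
* The empirical laws are in vitro fits; no endothelial surface layer
  correction is applied.
* Boundary pressures are heuristic; selection criteria deliberately keep
  analyses away from the domain boundary for this reason.
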