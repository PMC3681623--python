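# Methods

This note records the models, conventions and numerical choices behind
`floodsite`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before trusting a number.

## Data model and geometry

A `Topology` is a flat atom table (name, mass, residue, subunit) with named
selections (`protein`, `water_oxygen`, `ligand`) built from residue-name
rules at load time; atom ids are dense and 0-based internally, converted
from 1-based PDB serials only at the I/O boundary. A `Frame` carries time
(ns), three orthorhombic box edges (Å) and positions (Å). Triclinic boxes
are rejected explicitly: membrane systems of the kind this package targets
use orthorhombic cells, and restricting to them keeps the minimum-image
convention exact and cheap.

`minimum_image` maps each displacement component into (−L/2, +L/2]; it is
idempotent and norm-nonincreasing, and is validated in the tests against a
brute-force minimum over all 27 periodic images. Group centers of mass
unwrap member atoms to the periodic image nearest the group's **first
atom** before mass-weighting. The anchor choice is arbitrary but
deterministic; any anchor inside the molecule gives the same answer for
molecules smaller than half a box edge, which the trajectory contract
guarantees. How the original studies maintained molecule wholeness across
boundaries is generally unstated; this convention is ours and is tested by
comparison against a recentered-frame oracle.

PDB reading is a strict fixed-column ATOM/HETATM parser: a malformed record
reports its line number, and an atom whose element cannot be mapped to the
built-in mass table is an error rather than a silent zero mass. Standard
trajectory formats (DCD/XTC/GRO) are read through MDAnalysis; MDAnalysis
also serves as an independent cross-check on PDB coordinates in the test
suite. Ligand pseudo-particles from the generator carry unit mass.

### Plain frame archive

Synthetic trajectories round-trip through a plain-text archive so that
fixtures stay human-readable and language-neutral:

```
FLOODFRAMES 1
natoms <N>
nframes <M>
frame <time_ns> <Lx> <Ly> <Lz>      # once per frame
<x> <y> <z>                          # N lines, "%.4f" (1e-4 Å)
```

All values are ASCII, whitespace-separated, in ns and Å. Positions are
preserved to ≤ 1e-3 Å on a write/read cycle.

## Synthetic flooding generator

Ligands are single pseudo-particles (optionally rigid 3-atom rods for
orientation work) evolved by overdamped Langevin dynamics,

    x ← x − D ∇U dt / kT + sqrt(2 D dt) ξ,   kT ≡ 1,

in a potential `U = U_slab(z) + Σ_i U_site,i` with a tanh-edged membrane
slab well (depth ε_mem, edge width 2 Å) and isotropic Gaussian site wells
(depth ε, width σ). Momenta are never needed by any downstream statistic,
so Brownian rather than full Langevin dynamics is used; the integrator is
Euler–Maruyama, and a config is rejected when the per-step drift
`D·dt·max|∇U|` exceeds half the narrowest potential feature, the scale at
which the explicit scheme misbehaves.

Noise is drawn from one counter-based (Philox) stream per molecule,
spawned from the config seed, so output is bit-identical for identical
(config, seed) regardless of batching. Saved frames are wrapped into
[0, L) with the slab midplane at z = L/2, the convention every analysis
expects.

Defaults emulate the study conditions the package targets: 145 ligand
copies starting in the aqueous phase, a slab depth of 6.6 kT chosen so the
Boltzmann aqueous fraction is ≈ 0.3 % — about 0.4 of 145 copies in water
at equilibrium, i.e. near-complete membrane partitioning. Free diffusion
defaults to 100 Å²/ns, the order of magnitude of a small molecule in
water. The generator's `GroundTruth` records planted centers, depths,
widths, D, and the expected aqueous fraction obtained by 1-D numerical
Boltzmann integration of the slab potential (exact when no site wells are
planted, which is how the partitioning oracles use it).

What the generator does **not** emulate: ligand–ligand interactions,
lipid/protein atoms and their excluded volume, anisotropic diffusion,
electrostatics, or any real isoflurane/bilayer physics. Passing recovery
tests therefore demonstrates that the *estimators* are correct on data
whose truth is known — not that the physics of a real system is captured.

Cavity desolvation series are generated at the level of counts:
`n_water(t) = round(baseline − ratio·n_ligand(t) + ε)`, clipped at zero —
particle-level water adds nothing to a regression of counts on counts.
FEP window samples come from two exactly solvable models: per-window
Gaussian ΔU (window free energy μ − σ²/2RT) and a harmonic spring whose
stiffness is interpolated geometrically (window free energy
(RT/2)·ln(k_{i+1}/k_i)).

## Partitioning

Density profiles are histograms of molecule-COM z positions, recentred so
the bilayer midplane (lipid-selection COM when given, box midpoint
otherwise) sits at z = 0, and normalized per frame so the profile
integrates to the mean molecule count. Phase counts classify COMs by a
membrane z-interval; since the two phases tile the box, aqueous + membrane
counts always sum to the molecule count.

Concentrations use the count convention `c = (n_solute/n_water) × 55.5 M`
with the pure-water molarity as a configurable constant. On the reference
flooding composition (145 ligands / 25310 waters) this yields 0.318 M — a
number usually quoted rounded to 300 mM; the aqueous-volume convention
would give a slightly different value, which is why the convention is
stated here and exposed in the API.

Equilibration detection offers two rules: a fixed discard of the first
20 % of frames (the common convention, and the pipeline default), and a
data-driven rule that returns the first frame index from which consecutive
windowed means of the aqueous count stay within a tolerance — returning
`None`, never a silent guess, when the series does not settle.

## Site discovery

Ligand COMs from all molecules and all post-equilibration frames (with an
optional stride) are pooled into one point cloud. Jarvis–Patrick
clustering joins two points iff each is in the other's K-nearest-neighbor
list **and** they share at least k_t of their K nearest neighbors
(K = 8, k_t = 3 by default); clusters are connected components of the join
graph. Points are never their own neighbors; distances are minimum-image
when the cloud is periodic; neighbor-list ties at rank K are broken by
point index (a stable sort), making the whole clustering deterministic.
The implementation is held equal, on clouds up to a few hundred points, to
a brute-force re-implementation written directly from the definition.

Cluster ranking uses **average density**: each member position becomes a
normalized isotropic Gaussian (σ = 1 Å) summed on a 0.5 Å cubic grid over
the cluster's bounding box padded by 4σ (each Gaussian accumulated on a
local ±5σ window, discarding < 1e-5 of its mass); the integrated mass
(≈ member count, within 1 % quadrature error) is divided by the volume of
the voxels exceeding 1e-3 of the peak density. "Average density" admits
several readings (per-voxel mean, mass over support volume, …); mass over
thresholded support volume is the one implemented, and both the threshold
and the kernel width are parameters. Ties in density are broken by larger
member count, then lower cluster id.

Ranked site reports exclude singletons always, and optionally any cluster
holding less than a configurable fraction of the cloud
(`min_member_fraction`). The floor exists because shared-nearest-neighbor
clustering fragments the rim of a large, dense, continuously occupied blob
into small satellite clusters; those rim fragments sit in high-density
territory and would otherwise outrank genuinely distinct but weaker sites.
A putative binding site should hold a sustained share of the observations,
so a floor of a few percent (the demo uses 3 %) encodes the same
"continuous occupancy" rationale as the density ranking itself.

## Contacts, occupancy, symmetry, RMSD

A residue contacts the ligand in a frame when any ligand atom is within
the cutoff (default 5 Å) of any residue atom, minimum image; frequencies
are percentages of window frames. The search uses MDAnalysis's cell-list
`capped_distance`, and is tested for exact agreement with an all-pairs
O(N²) oracle. The non/possibly/likely classification thresholds
(10 %, 50 %, boundary rounding upward) are conventions of this package —
the classification scheme this mirrors is ordinarily published as colors
without numbers — and are mandatory, documented config.

Site occupancy counts molecules whose **COM** is inside a region (the
any-atom alternative is not offered; COM keeps occupancy consistent with
COM-based site discovery). Residence episodes are maximal [enter, leave)
spans, with a debounce parameter merging re-entries within d frames.
Subunit symmetry compares per-copy mean occupancies by their max/min
ratio (default factor 5), a scale-invariant criterion, with a floor to
suppress flags on essentially empty sites. RMSD uses least-squares (Kabsch)
superposition per frame per selection, so rigid-body motion contributes
exactly zero.

## Cavity and pathways

Regions are named unions of slabs, spheres and capped cylinders, either in
absolute box coordinates or anchored to a protein selection's per-frame
COM; each primitive tests membership via the minimum-image displacement
from its own reference point, so regions behave correctly across periodic
boundaries. Cavity/fenestration declarations must be disjoint (checked on
a probe grid at load), because transit events would otherwise be
ambiguous.

The desolvation analysis regresses cavity water count on cavity ligand
count by ordinary least squares and reports −slope as the displacement
ratio (waters per bound ligand), with r², residual SD and n as
diagnostics. The estimator is exact on noiseless synthetic series and
unbiased on noisy ones.

Transit detection reduces each molecule's per-frame region label sequence
to *confirmed visits* — runs of at least `dwell` frames (default 2;
boundary flicker otherwise dominates event counts) — and matches visit
sequences against a route table. Defaults: lipid → fenestration_i → cavity
is a fenestration entry (the reverse an exit, labeled with the copy
used); aqueous_intracellular → cavity is the intracellular-gate route and
aqueous_extracellular → cavity the selectivity-filter route, so a
closed-gate scenario is testable as zero events on the hydrophilic routes.
Transitions matching no route are labeled `unresolved`, never dropped.

## Ligand dynamics

MSD is averaged over molecules and all time origins at the requested
lags; input traces must be unwrapped, and a jump exceeding half a box edge
is rejected with advice to unwrap (an `unwrap_traces` utility inverts
wrapped trajectories by minimum-image accumulation). D = slope/6 from a
least-squares line over a lag window defaulting to [10 %, 50 %] of the
longest lag — short lags are noise-dominated, long lags origin-starved;
the fit window is a stated convention, not a universal standard. A
negative fitted slope reports D = 0 with a flag, never a negative
coefficient. Per-site dynamics use residence episodes as independent
segments, so displacement origins never cross an episode boundary.

Rotational relaxation computes C_ℓ(τ) = ⟨P_ℓ(u(t)·u(t+τ))⟩ for ℓ = 1 or 2
(default 2, the order relevant to most spectroscopic observables) and fits
a single exponential on the decay range C_ℓ ∈ [0.1, 0.8] by log-linear
least squares. A frozen axis returns a not-relaxed sentinel rather than a
number. The estimators are validated against the closed form
τ_ℓ = 1/(ℓ(ℓ+1)D_r) on simulated isotropic rotational diffusion.

## Free energy

The λ schedule runs 0 → 1 with fine steps (0.025) within a configurable
zone (default 0.1) of both ends and coarse steps (0.05) in the middle;
steps must divide their zones exactly. The per-window estimator is forward
exponential averaging (Zwanzig), ΔG_i = −RT ln⟨exp(−ΔU/RT)⟩, stabilized
with log-sum-exp; windows must tile [0, 1] contiguously. BAR and other
two-sided estimators are out of scope by design. The gas→protein transfer
leg and the vacuum→protein wording found in the literature are treated as
the same quantity.

Constants: R = 1.98720×10⁻³ kcal/(mol·K); V_1M = 1660.5 Å³ (the volume per
molecule at 1 M — the name V_1M is standard, the number is ours to state);
default T = 300 K. ΔG_rstr = RT ln(V_rstr/V_1M);
ΔG_bind = ΔG_gas→prot − (ΔG_solv + ΔG_rstr); Kd = C°·exp(ΔG_bind/RT). The
water→dodecane transfer free energy of the reference anesthetic
(3.0 kcal/mol) is stored as a documented literature constant for the
lipid-partitioning argument; it is not computed here.

## Pipeline and reproducibility

One schema-validated config (unknown keys rejected) drives all stages in
study order; a stage whose inputs are absent is recorded as `skipped` in
the summary, and any stage failure aborts with a stage-named error. The
report bundle embeds the config and seed; identical config + seed yields a
byte-identical `summary.json`. All generator randomness descends from the
single config seed through spawned per-molecule streams.

Problem sizes in the demo and tests are chosen to run in seconds on one
CPU: the bundled three-site demo uses 24 ligands × 1100 frames (17 600
integrator steps), discards the first 700 frames as equilibration, and
samples every 8th retained frame. The demo plants wells of 12/10/8 kT —
within the stability range flooding studies report for their strongest
sites once the ~2 kT spacing needed for unambiguous occupancy ordering at
this sample size is added — and those depths also keep residence times
long against the sampled window, reproducing the continuous-occupancy
regime in which density ranking is meaningful.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- The generator's wells are isotropic Gaussians; real binding pockets are
  neither isotropic nor harmonic, and no ligand–ligand or ligand–lipid
  interactions exist in the synthetic model.
- Jarvis–Patrick fragmentation of dense blobs is mitigated by the member
  floor, not eliminated; very large clouds (≫10⁴ points) also make the
  O(n²) neighbor search slow — use the stride.
- Contact analysis offers distance-based proxies only; no hydrogen-bond
  geometry (donor–acceptor angles) is detected, and nothing here should
  be read as a hydrogen-bond assignment.
- The equilibration detector assumes a monotone-ish approach to a plateau;
  oscillating series can defeat it (it then returns `None`).
- FEP supports the forward exponential estimator only; poorly overlapping
  windows will show the usual bias of that estimator, visible in the
  per-window sample diagnostics.
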