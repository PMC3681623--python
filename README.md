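# floodsite

Analysis pipeline for **ligand-flooding molecular dynamics**: simulations in
which many copies of a small hydrophobic ligand (e.g. a volatile anesthetic
such as isoflurane) are placed in the aqueous phase around a membrane-bound
protein and allowed to partition and bind without bias. The package turns
such trajectories into the quantities a flooding study reports:

- **Membrane partitioning** — ligand center-of-mass (COM) density profiles
  along the bilayer normal, per-frame aqueous/membrane counts, equilibration
  detection, and count → molar-concentration accounting.
- **Binding-site discovery** — Jarvis–Patrick shared-nearest-neighbor
  clustering of pooled ligand COM observations (neighbor list K = 8, shared
  threshold k_t = 3), with clusters ranked by **average Gaussian density**
  (each observation an isotropic Gaussian of width σ = 1 Å integrated on a
  0.5 Å grid): high average density marks continuously occupied, i.e.
  tightly binding, regions.
- **Contact characterization** — per-residue contact frequencies (any
  ligand atom within 5 Å of any residue atom, minimum image) with a
  three-way non/possibly/likely interaction classification, site occupancy
  series with residence episodes, subunit-symmetry comparison, and
  backbone RMSD diagnostics.
- **Cavity desolvation & access pathways** — water and ligand counts inside
  a declared cavity region, the least-squares regression of water count on
  ligand count (the negative slope is the number of waters each bound
  ligand displaces), and transit-event detection through declared routes
  (lipid → fenestration → cavity and the hydrophilic alternatives).
- **Ligand dynamics** — translational diffusion coefficients from the mean
  squared displacement (D = slope/6) and rotational relaxation times from
  Legendre orientation autocorrelations (τ_ℓ = 1/(ℓ(ℓ+1)D_r) for isotropic
  rotational diffusion), per site or in bulk.
- **Free-energy bookkeeping** — the FEP (Zwanzig) exponential estimator
  over a λ schedule (fine 0.025 steps at the ends, 0.05 in the middle),
  the standard-state restraint correction ΔG_rstr = RT ln(V_rstr/V_1M),
  the combination ΔG_bind = ΔG_gas→prot − (ΔG_solv + ΔG_rstr), and
  Kd = C°·exp(ΔG_bind/RT).

Because raw flooding trajectories are rarely deposited, the package ships a
first-class **synthetic-data generator**: ligand pseudo-particles evolved by
overdamped Langevin (Brownian) dynamics in a periodic box with a membrane
slab well and planted Gaussian binding wells, plus cavity-occupancy series
and FEP window samples with analytic ground truth. Every analysis stage is
tested by recovering what the generator planted.

## Worked example

The bundled demo generates a flooding run with three planted binding wells
of depths 12, 10 and 8 kT in a 30 Å periodic box, then runs the full
pipeline:

```python
from floodsite.pipeline import quickstart_config, run_pipeline
summary = run_pipeline(quickstart_config(seed=1), "demo_out")
for site in summary["stages"]["sites"]["top_sites"]:
    print(site["rank"], site["centroid"], round(site["avg_density"], 3))
```

or from the shell (`floodsite synth / partition / sites / contacts / cavity
/ dynamics / fep / run`):

```sh
$ floodsite sites --config demo.yaml --seed 1 --out demo_sites
rank 1: centroid (7.6, 7.6, 7.4) Å, ρ̄=1.490/Å³, 52.0% of points
rank 2: centroid (22.5, 22.4, 7.5) Å, ρ̄=0.522/Å³, 19.7% of points
rank 3: centroid (7.5, 22.4, 22.7) Å, ρ̄=0.149/Å³, 6.6% of points
```

The three planted wells sit at (7.5, 7.5, 7.5), (22.5, 22.5, 7.5) and
(7.5, 22.5, 22.5) Å: the report recovers each center to well under 2 Å, and
the density ranking reproduces the planted depth order (12 > 10 > 8 kT) —
deeper wells hold more ligand observations in a tighter volume, exactly the
"continuous occupancy" signal the ranking is designed to reward.

Concentration accounting on a typical flooding composition (145 ligand
copies, 25310 waters) gives an initial aqueous concentration of
`145/25310 × 55.5 M ≈ 0.318 M`, and a late-window mean of 0.4 aqueous
copies gives `≈ 0.88 mM`:

```python
>>> from floodsite.partitioning import concentration_from_counts
>>> concentration_from_counts(145, 25310)
0.31796...
>>> concentration_from_counts(0.4, 25310)
0.00087712...
```

## Layout

```
src/floodsite/
  core_model.py         topology/trajectory model, PDB + frame-archive I/O,
                        periodic geometry, center-of-mass utilities
  synthetic_data.py     Brownian flooding generator, cavity series, FEP samples
  partitioning.py       density profiles, phase counts, concentrations
  site_discovery.py     Jarvis-Patrick clustering + Gaussian-density ranking
  contacts_occupancy.py contact tables, occupancy, symmetry, RMSD
  cavity_pathway.py     regions, desolvation regression, transit events
  ligand_dynamics.py    MSD/diffusion, rotational relaxation
  free_energy.py        λ schedules, FEP estimator, ΔG ledger, Kd
  pipeline.py, cli.py   orchestration and the `floodsite` command
docs/methods.md         model assumptions, conventions, limitations
```
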