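# polecrowd

Why do aggregates of misfolded protein end up at the poles (and mid-cell) of
rod-shaped bacteria such as *Escherichia coli*?  One hypothesis needs no
active transport at all: aggregates diffuse passively (Brownian motion),
merge irreversibly when they meet, and are excluded from the nucleoids —
the chromosome-packed regions of the cytoplasm where macromolecular
crowding hinders the diffusion of large particles.  What remains accessible
to a growing aggregate is the nucleoid-free space: the two poles and the
gap between the nucleoids.

`polecrowd` implements both sides of the argument as a Python library:

- **the model** — a 3D lattice-free individual-based simulator of protein
  diffusion, obstacle-hindered motion in nucleoids and Smoluchowski-type
  irreversible aggregation (`polecrowd.simulate`);
- **the measurements** — a single-particle-tracking (SPT) analysis stack:
  elongation-corrected mean displacements and mean-squared displacements
  (MSD), diffusion constants, anomalous exponents, fluorescence-intensity
  size classes and Stokes–Einstein fits (`polecrowd.spt`); the ρ(s)
  crescent-density statistic that separates membrane-bound from
  cytoplasmic-bulk focus populations in 2D projections
  (`polecrowd.pole_density`); an evolutionary-strategy (CMA-ES) fit of
  confined-diffusion parameters (`polecrowd.confined`, `polecrowd.cmaes`);
  and subpixel fluorescent-spot localization (`polecrowd.spots`);
- **ground-truth data** — generators for confined-Brownian trajectory
  ensembles with cell-elongation drift and localization noise, pole
  position clouds and Gaussian-PSF spot images (`polecrowd.synthetic`),
  so every stage is testable against known truth.

## The model in brief

Each protein is a sphere of radius *r* performing a fixed-step random walk,
step length *d* = √(6 *D* Δt), with *D* = *D*₀*r*₀/*r* (Stokes–Einstein;
monomers: *r*₀ = 3 nm, *D*₀ = 4.4 µm²/s, so *d* ≈ 5 nm at Δt = 1 µs).  The
cell is a 4 × 1 × 1 µm box with reflective walls; two nucleoid boxes
(1220 × 532 × 532 nm, starting 540 nm from each pole) are filled with
50,000 immobile 10-nm obstacles, and any move that would overlap an
obstacle is rejected.  Overlapping proteins merge with probability
*p*_ag per encounter; the product is a sphere of radius
*r*_C = (*r*_A³ + *r*_B³)^⅓ at the volume-weighted centre of mass, so
monomer number and total protein volume are conserved exactly.  An
aggregate is "detected" when its monomer count first crosses a detection
threshold, mirroring the fluorescence detection limit.

On the analysis side, a sphere confined to a reflective box of size *L*
explores the interval [*r*, *L* − *r*] per axis, so its MSD saturates at
(*L* − 2*r*)²/6 while the short-time slope is 2*D* — which is what the
CMA-ES fit exploits to estimate {*L*_X, *L*_YZ, *r*₁..₅, *D*₁..₅} from
class-wise MSD curves.

## A worked example

```sh
python examples/pole_density_demo.py
```

prints

```
bulk      : edge/centre density =  0.19  trend slope = -6.58e-02 (p = 0.000)  ->  bulk
membrane  : edge/centre density =  6.17  trend slope = +1.45e-01 (p = 0.027)  ->  membrane
control2d : edge/centre density =  1.01  trend slope = -4.10e-04 (p = 0.917)  ->  indeterminate
```

Each line is 10,000 synthetic focus positions in a semi-ellipsoidal cell
pole, projected to 2D as a microscope would see them.  For foci spread in
the 3D bulk the projected density ρ(s) *decays* smoothly toward the pole
outline (edge/centre 0.19); for membrane-bound foci the projection piles
up abruptly at the outline (6.17); a genuinely 2D-uniform control stays
flat.  The classifier reads the sign and significance of the density trend
near s = 1 and recovers all three cases.

The other examples cover the simulator (`simulate_aggregation.py` — where
aggregates first become detectable and how many coexist), the SPT stack
(`analyze_trajectories.py` — per-class diffusion constants and the
Stokes–Einstein constant C₀), the evolutionary fit
(`fit_confinement.py`), and spot localization (`locate_spots.py`).  A thin
CLI wraps the same functions: `polecrowd simulate|msd|rho|fit-confined|
locate-spots|synth|run`.

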