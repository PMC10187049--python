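# Methods

## Model overview

`biofilmsim` is an individual-based (agent-based) model of a two-species
biofilm in the iDynoMiCS tradition. Bacterial cells are hard spheres
characterised by species, position, a biomass pool, and an EPS capsule
pool; dissolved chemicals are concentration fields on a regular voxel
grid. The domain is a box with a solid substratum at z = 0 (zero-flux for
solutes, impenetrable for cells), periodic lateral faces, and well-mixed
bulk medium above a stagnant boundary layer whose position tracks the
biofilm front.

Units are chosen so no conversion factors appear anywhere: lengths in µm,
times in h, cell masses in fg, concentrations in g/L. Because
1 g/L = 1 fg/µm³ exactly, cell volume is mass/density and voxel injection
is mass rate divided by voxel volume.

### Growth

Each cell grows according to dual-substrate Monod kinetics,
`mu = mu_max · Sg/(K_Sg+Sg) · So/(K_So+So)`, evaluated at the
concentrations of the cell's containing voxel. In the inhibition variants
the *S. oralis* rate is additionally multiplied by the noncompetitive
factor `K_I/(K_I+I)`; the producer species is unaffected. Within one
global step the rate is frozen and the biomass pool is updated with the
exact exponential `X·e^(mu·dt)` (operator splitting); the frozen-rate
error is second order in dt. New mass is split between biomass and
capsule by the species' fixed ratio (0.8:0.2 for *S. oralis*, 0.9:0.1 for
*L. paracasei*); in the surfactant-containing variants EPS production is
switched off and all new mass is biomass.

Nutrient consumption is growth-coupled through the Table-of-constants
yields (g solute per g new biomass, negative = consumed). Inhibitor and
surfactant production is a separate first-order reaction in producer
biomass, `rate = yield·k·X`, deliberately decoupled from the growth rate:
no substrate coupling is specified for the production reaction, so a
non-growing producer keeps secreting. The production "yield" is
interpreted as g product per g producer biomass per unit of the
first-order reaction — an assumption, since no unit is attached to it in
the source protocol.

There is no cell death or biomass decay: the rule exists as a no-op stub
because no death parameters are defined anywhere, and agent counts are
therefore non-decreasing.

### Species parameters

| parameter | *S. oralis* So34 | *L. paracasei* LB334 | units |
|---|---|---|---|
| mu_max | 0.32 | 0.153 | 1/h |
| K_Sg (glucose) | 1.756 | 1.2 | g/L |
| K_So (oxygen) | 0.192e-3 | 0.2e-3 | g/L |
| K_I | 0.0025 | — | g/L |
| yield glucose | −3 | −0.17 | g/g |
| yield oxygen | −2 | −1 | g/g |
| biomass : capsule | 0.8 : 0.2 | 0.9 : 0.1 | — |
| production k | — | 0.7 | 1/h |
| inhibitor yield | — | 0.3 | g/g |
| surfactant yield | — | 0.4 | g/g |
| surfactant tolerance | 0.005 | 0.008 | g/L |

Bulk glucose is 2 g/L (the sugar content of full-strength biofilm
medium); bulk oxygen 0.0064 g/L. Dilution sweeps scale only the carbon
source; oxygen is never diluted.

Several constants the source protocol leaves unstated are set to
conventional individual-based-model values and are configurable: biomass
density 150 g/L and capsule density 75 g/L; division radius 1.0 µm with a
uniform 0.45–0.55 mass split; voxel size 8 µm (17³ voxels on the default
domain — larger than any cell diameter, small enough to resolve the
gradients); boundary-layer thickness 40 µm; diffusivities 2.1e4 µm²/h
(glucose, and by default the two secreted products) and 7.2e4 µm²/h
(oxygen).

### The global step

Every step of `dt = 0.05 h` executes, in fixed order: (1) pseudo-steady
solve of the bulk-maintained nutrient fields at the current biomass
distribution; (2) one implicit transient step of the accumulating
inhibitor/surfactant fields; (3) growth of every biofilm cell at its
local effective rate; (4) division of cells at the threshold radius, the
daughters separated by half the sum of their radii in a random direction;
(5) shoving relaxation; (6) surfactant detachment (surfactant variants);
(7) random movement of planktonic cells; (8) time advance. All random
draws come from one counter-based Philox stream per replicate, consumed
in fixed program order, so a (config, seed) pair reproduces a trajectory
bitwise. Replicate i of a batch uses seed base + i.

Simulations start from 176 cells (88 + 88 in dual runs, the species
sequence randomly interleaved) at uniformly random positions on the
substratum, each with a birth biomass uniform in 50–100% of the division
mass, relaxed once by shoving. The seeded-cell count is taken as the
authoritative inoculum: it corresponds to ≈0.0095 cells/µm² on the
18,496 µm² substratum, consistent with the experimental seeding density
of 0.01 cells/µm².

### Solute solvers

Nutrients are assumed pseudo-steady (diffusion across the ≤100 µm domain
equilibrates in ~0.1 h, fast against growth at mu ≤ 0.32/h). The solver
restricts the linear system to the voxel layers below the bulk clamp —
every voxel whose centre lies more than one boundary-layer thickness
above the biofilm front is held at the bulk concentration — with
zero-flux at the substratum and periodic lateral coupling. Monod sinks
are handled by Picard iteration with the secant linearisation
`r(S) ≈ (r(S_prev)/S_prev)·S`, which keeps the operator an M-matrix, so
iterates stay within [0, bulk] and saturating sinks shut off smoothly as
S → 0. Each linearised system is solved by Jacobi-preconditioned
conjugate gradients warm-started from the previous iterate (falling back
to a direct sparse solve if CG stalls); iteration stops when the largest
voxel change per sweep falls below 1e-6 of the bulk concentration, and
non-convergence raises an error carrying the final residual. The
glucose–oxygen cross-coupling (each field's sink depends on the other's
Monod factor) is resolved by an outer fixed-point loop over the fields.

The secreted inhibitor and surfactant accumulate instead: they take an
implicit-Euler diffusion step with source injection under zero-flux top
and bottom boundaries, which conserves mass exactly up to linear-solver
round-off (the factorisation is cached per grid/diffusivity/step). The
zero-flux top (no washout into the bulk) is an assumption: it is the only
boundary condition under which the products' concentrations rise
monotonically past the biologically relevant thresholds within 16 h,
which is the regime the inhibition and surfactant mechanisms require.
Transient accuracy in time is first order; the implicit scheme is
unconditionally stable so no sub-stepping is needed by default.

### Shoving, detachment, movement

Overlap relaxation is damped-Jacobi: every overlapping pair contributes a
displacement of half its overlap to each member along the centre line,
all displacements are accumulated (via a k-d tree neighbour search) and
applied simultaneously, and sweeps repeat until the largest overlap is
below 0.05 µm or a sweep cap (then a warning). The simultaneous update
makes the result independent of pair ordering, hence deterministic.
Division and shoving conserve mass exactly.

Detachment is strictly threshold-based and periphery-only: a biofilm cell
is peripheral when its voxel has at least one biomass-free voxel among
its 26 neighbours (the substratum never counts as free; the domain top
does). A peripheral cell whose local surfactant concentration *strictly
exceeds* its species tolerance becomes planktonic and is relocated to a
uniformly random point in the boundary-layer band just below the bulk.
Detachment is one-way. Planktonic cells take 5-µm isotropic random steps
per global step, reflected at the band edges, and are metabolically inert
— they neither grow, consume, nor produce. This keeps the model free of
invented planktonic kinetics but biases planktonic biomass low; a
`planktonic_growth` flag turns growth back on. A generic height-dependent
shear-erosion rule exists but is disabled in all five variants: all
detachment is attributed to the surfactant.

### Observables

Biovolume is the sum of agent sphere volumes (capsule included by
default; a flag excludes it), without overlap deduplication — overlaps
are bounded by the shove tolerance, and voxelised alternatives differ by
a few percent. Planktonic cells are excluded from biovolume and thickness
but included in counts. Thickness is the mean over occupied (x, y) voxel
columns of the per-column maximum of z + radius. The replicate
coefficient of variation is 100·SD/mean (sample SD) of an observable at
final time. The dilution regression is ordinary least squares of
biovolume on dilution fraction with R² the squared Pearson correlation.

### Calibration

The growth constants were obtained by matching the simulated
single-species dilution response to the observed one. The packaged
objective is *normalised-slope matching*: the OLS slope of final
biovolume versus dilution fraction, divided by the full-strength
biovolume — insensitive to the absolute-unit mismatch between imaged and
simulated biovolume. One parameter at a time (`mu_max` or `K_Sg`) is
fitted by bisection inside a biologically relevant bracket
(mu_max ∈ [0.05, 1.0] /h, K_Sg ∈ [0.01, 5] g/L), with every objective
evaluation reusing the same replicate seeds (common random numbers) so
the objective is a deterministic function of the parameter.

One empirical caveat: the normalised slope is *hump-shaped* in K_Sg, not
globally monotone — at small K_Sg the response flattens because growth
saturates, and at large K_Sg the response collapses toward the seeded
biomass floor at every dilution. Bisection therefore requires a bracket
on a single monotone branch; the implementation checks monotonicity
across the first three evaluated points and aborts with a diagnostic
when the bracket straddles the peak. The parameter-recovery test places
its bracket on the decreasing branch containing the true value.

### Synthetic experiments

The dilution-series generator draws
`biovolume = slope·dilution + intercept + N(0, sd)` floored at zero, over
the standard seven dilution fractions (1, 0.75, 0.5, 0.25, 0.1, 0.05,
0.01) with 10 replicates each. The four default series carry the
regression constants observed in vitro; each default noise SD is solved
from the observed R² through `sd = |slope|·sd_x·sqrt((1−R²)/R²)` so a
refit recovers the reported goodness of fit on average. (The
single-species *L. paracasei* R² is unusable as printed — sign typo — so
that series borrows the dual-series noise level of the same species.)
The zero floor truncates the noise at the lowest dilutions, which biases
a refitted slope a few percent low and the refitted R² slightly high;
both effects are inherent to a floored-Gaussian emulation of a
non-negative measurement. The generator emulates the linear structure
and noise level of the imaging readout only — no segmentation artifacts,
spatial correlation between wells, or instrument drift. Passing tests
against it demonstrate the calibration and postprocessing machinery, not
fidelity to any particular laboratory dataset.

The well-count generator draws per-well counts lognormally around
configured species × state means with a mean-preserving parameterisation
(dispersion 0 reproduces the means exactly), plus a
percentage-of-well-total transform.

## Desk-scale test sizes

The test suite runs the full 136³ µm domain and 16-h duration for the
headline checks, with replicate counts of 3–5 (the full study batches of
5 and 50 replicates are unnecessary to establish the qualitative
orderings, since the replicate CV is ~2%). Mechanism comparisons between
variants always use matched seeds. The calibration-recovery test uses a
64³ µm domain, 24 seeded cells, 8-h runs, and three dilutions; the
solver oracles use single-column and small grids. The acceptance script
runs the replicate-CV computation at the full study size (5 replicates,
full domain, 16 h) and the synthetic-slope computation over 50 seeds.

## Known limitations

- Cells are spheres; rod or filament morphologies are out of scope.
- EPS is a per-cell capsule, not separately excreted particles.
- Planktonic cells are metabolically inert by default (see above).
- No advective flow, pressure, or pH dynamics.
- The no-washout boundary for secreted products makes their
  concentrations rise without bound, so the surfactant variants
  eventually detach every peripheral cell; with the default tolerances
  the 16-h dual biofilm is dispersed essentially completely, a stronger
  effect than a finite-washout system would show.
- Diffusivity defaults are two orders of magnitude below textbook aqueous
  values; they are configurable, and at 16 h the qualitative orderings
  are set by the Monod factors rather than by transport, but absolute
  gradient steepness should not be over-interpreted.
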