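# Methods note

## 1. Equilibrium prozone model (`pkaproz.prozone`)

Each PKA-R protomer is treated as an independent scaffold with one
PKA-C binding site and two cAMP binding sites. With free-ligand
concentrations `C` (PKA-C) and `A` (cAMP), the six microstates
`(c, a)`, `c ∈ {0,1}`, `a ∈ {0,1,2}`, carry statistical weights

```
w(c, a) = (C / K_C)^c · binom(2, a) (A / K_A)^a · alpha^(−c·a)
```

where `alpha > 1` encodes the negative coupling between PKA-C and cAMP
occupancy (cAMP-loaded PKA-R holds PKA-C weakly and vice versa). The
partition function `Z = Σ w` gives mean occupancies `⟨c⟩`, `⟨a⟩`, and
the free concentrations are fixed by the two conservation equations

```
C_free + R_tot ⟨c⟩(C_free, A_free) = C_tot
A_free + R_tot ⟨a⟩(C_free, A_free) = A_tot
```

solved by nested bracketing root finding: the outer bracket on `A_free`
in `[0, A_tot]`, and for each trial `A_free` an inner bracket on
`C_free` in `[0, C_tot]`. Both residuals are monotone in their own
variable on those intervals, so a bracketing method is guaranteed to
converge; we use `scipy.optimize.brentq` (`xtol = 1e−16`,
`rtol = 1e−15`) and verify the final residuals. A `camp_buffered`
mode clamps `A_free = A_tot` for experiments where cAMP is saturated
pharmacologically (forskolin/IBMX).

**Readout.** "Activity" is free PKA-C, the species available to
phosphorylate substrates. `activity_vs_R(R_x)` evaluates the
equilibrium as translocated PKA-R (`R_x`) is added to a basal membrane
compartment: `R_tot = R_basal + R_x`, `C_tot = C_basal + rho·R_x`
(each recruited PKA-R dimer drags along a fraction `rho` of bound
PKA-C), `A_tot` fixed. The curve rises while co-recruited PKA-C and
cAMP-assisted release dominate, peaks, and then falls below its
baseline as excess scaffold titrates PKA-C into cAMP-free complexes.

### Default parameters

| parameter | value | rationale |
|---|---|---|
| `K_C` | 0.01 µM | sub-nM–nM-range holoenzyme affinity, strong PKA-C capture |
| `K_A` | 0.1 µM | cAMP affinity of PKA-R, ~10× weaker than PKA-C site |
| `alpha` | 100 | strong antagonism: cAMP-saturated PKA-R binds PKA-C 100× weaker per site |
| `n_A` | 2 | two cAMP sites per protomer |
| `R_basal`, `C_basal` | 0.1 µM each | low pre-existing membrane holoenzyme |
| `A_tot` | 1.2 µM | basal cAMP comparable to the recruited-scaffold scale, so sequestration of cAMP is felt |
| `rho` | 0.5 | half of recruited PKA-R arrives with PKA-C bound |

`rho` and `A_tot` are the package's own calibration: with full
co-recruitment (`rho = 1`) the added PKA-C always outpaces
sequestration (asymptotically `C_free ≈ sqrt(K_C · C_tot)` grows
without bound) and no biphasic curve exists for *any* binding
constants; a sub-stoichiometric `rho` plus a finite cAMP pool is the
minimal setting that produces the experimentally observed biphasic
response. With these defaults the optimum sits at `R_x ≈ 0.40 µM`
(activity 0.159 µM over a 0.092 µM baseline) and activity crosses
below baseline at `R_x ≈ 1.17 µM`.

## 2. Translocation kinetics (`pkaproz.translocation`)

Rapamycin-induced FKBP/FRB dimerization is modeled as first-order
approach to a dose-dependent plateau:

```
R_x(d, t) = R_max · E(d) · (1 − exp(−k(d) t)),
E(d) = d^h / (d^h + EC50^h),    k(d) = k_max · E(d)
```

Defaults: `R_max = 2 µM`, `EC50 = 10 nM`, `h = 1`, `k_max = 1.5 /min`,
cytoplasmic pool `R_cyto_total = 2.5 µM`. These place the three
experimental dose regimes correctly: 2 nM plateaus at `R_x = 0.33 µM`
(below the activity optimum → slow, sustained response), 20 nM at
1.33 µM (past the below-baseline crossing → transient response that
decays), and 100 nM reaches 98% of plateau by 3 min (fast cytoplasmic
depletion). Activity time courses compose `R_x(t)` with the
equilibrium curve pointwise (quasi-steady-state: binding equilibrates
much faster than translocation).

The FRET-ratio proxy maps activity through a saturating calibration
`S(x) = x / (x + K_act)` with `K_act = 0.2 µM` and dynamic range
`DR = 0.209`: `r(t) = DR · (S(act(t)) − S(act_0))`, so a full-scale
response is a 20.9% ratio increase.

## 3. Gradient device (`pkaproz.gradient`)

A cross-channel of length `L = 250 µm` connects a source and a sink
reservoir (304 such channels per device). With constant boundary
concentrations the 1D diffusion steady state is affine,
`c(y) = c_sink + (c_source − c_sink) · y / L`, giving 0.08 nM/µm for
0–20 nM and 0.04 nM/µm for 10–20 nM. The transient is the standard
Fourier sine series on top of the affine profile with decay rates
`D (nπ/L)²` (`D = 300 µm²/min`); terms are added until their amplitude
bound falls below `1e−9` of the boundary scale. `predicted_cell_profile`
samples the local dose along a 50 µm cell at 20 positions (position 0 =
source-facing front) and runs the translocation + prozone composition
at each; `polarity_score` is front-half minus rear-half mean activity.

## 4. Image analysis (`pkaproz.imaging`)

- Pixel size 0.389 µm (so 20 px = 7.78 µm); dark offset subtracted
  before any ratio or intensity measurement.
- Segmentation: global threshold, 8-connected labeling
  (`skimage.measure.label`), minimum area 50 px, masks ordered by
  centroid for stable ids.
- FRET ratio: `(FRET − dark) / (CFP − dark)` per pixel, defined only
  inside masks where the denominator is positive.
- Cytoplasmic tracking: 3×3 binary erosion iterated 20 times removes a
  ≤ 20 px membrane rim exactly; series normalized to the first frame;
  cells thinner than the erosion depth are excluded with a reason, not
  silently dropped.
- Nuclear tracking: largest connected component per frame, centroid
  row; displacement `(row(0) − row(t)) · pixel_size`, so positive
  displacement is toward the source end (row 0). Missing frames are
  flagged, never interpolated.
- Binned profiles: 20 equal bins over the mask's bounding extent,
  integer bin index, bin 0 at the high-dose end by default.
- Statistics: mean ± SEM (`ddof = 1`), pooled two-tailed Student's
  t-test (`scipy.stats.ttest_ind`, `equal_var=True`) with an explicit
  zero-variance branch (identical constant groups → `t = 0, p = 1`,
  where scipy would return NaN).

## 5. Synthetic generator (`pkaproz.synthetic`)

Camera model per pixel: `DARK_OFFSET (100) + Poisson(signal) +
Normal(0, 3·noise)`, clipped at 0; `noise = 0` disables both terms so
analysis-exactness tests are possible. One `numpy` Generator seeded per
scenario makes arrays and saved TIFF files byte-identical for identical
inputs. Dish scenarios render elliptical cells (3 px rim, lognormal
expression, σ = 0.5) in four channels; the imposed ratio is either the
dose model above or, for saturating stimulation, a linear ramp reaching
exactly `BASE_RATIO · (1 + DR)` at 6 min. Chip scenarios render
stadium-shaped cells in 20 px channels (644 rows ≈ 250 µm), a static
dye channel encoding the linear gradient, a nuclear marker, and a FRET
pair whose per-row ratio follows the local dose; the nuclear marker and
the FRET donor are emitted as separate channels because they represent
separate experiments on the same device.

Migration is a 1D biased random walk (`v0 = 0.3 µm/min` drift,
`σ = 1 µm/frame`, 80% initially source-ward) with reflecting boundaries
25 µm from each end and condition-dependent polarity: in a gradient
each cell flips sink-ward at its own `τ ~ U[15, 60] min`; under a
saturating uniform dose polarity is re-randomized every 30 min;
controls never flip.

**Limitations.** Cells do not divide, deform, overlap, or drift in
dish scenarios; photobleaching, shading, and camera hot pixels are not
modeled; migration is 1D and kinematic (reversal times are imposed, not
emergent from the signaling model); the chip FRET field varies only
along the gradient axis. The generator is a validation instrument for
the analysis pipeline, not a biophysical cell simulator.

## 6. Numerical choices and problem sizes

- Equilibrium solves: nested `brentq`, residual-checked; ~0.5 ms per
  point; the ODE-relaxation oracle in the test suite (mass-action
  kinetics integrated to steady state with LSODA, `rtol = 1e−11`)
  agrees to relative error < 1e−6 on 100 random instances (observed
  ~1e−14).
- Fourier transients: term-wise amplitude cutoff `1e−9`, capped term
  count with an error raised if the cap binds.
- Rendering: a 12-cell, 9-frame dish movie renders and analyzes in
  ~2 s; a 6-cell, 16-frame chip movie in ~4 s; the full test suite
  (143 tests, including property-based suites under `hypothesis` with
  fixed derandomized seeds) runs in ~40 s on one CPU.
- All randomness flows through explicit integer seeds; no global RNG
  state is used anywhere.
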