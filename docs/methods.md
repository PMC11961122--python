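# Methods

`psmclock` simulates the zebrafish pre-somitic mesoderm (PSM) as ~2,300 motile
point-cells carrying coupled phase oscillators, and reads out the synchrony
and frequency of the segmentation clock at the anterior wavefront. This note
documents the model, its parameters, the numerical choices, and what the
package's synthetic tissues do and do not capture.

## Model

### Tissue and frame of reference

The PSM is a hollow horseshoe: two cylinders of radius `rT` (the left and
right lateral PSM) joined posteriorly by a half-torus (the tailbud) with
major radius `R` centred at `(Xc, Yc, Zc)`. The posterior tip is the frame's
origin of motion, so tissue elongation appears as anterior-directed advection
of cells; cells exit the PSM at the wavefront `x = xa`, where their clock
phase freezes and pre-patterns a somite. The AP length is
`L = rT + R + Xc - xa`.

### Cell movement

Overdamped dynamics per cell:

    dx_i/dt = v_d(x_i) + v0(x_i) n_i + sum_j F_ij + F_b(x_i)

* **Advection** `v_d`: piecewise-linear in normalized position
  `X = (x - xa)/L`, from `va` at the anterior through `vp (1 - xq)` at the
  breakpoint `xq` to zero at the posterior tip. The printed form of the
  anterior branch is typographically ambiguous; it is resolved by the three
  constraints the profile must satisfy (value `va` at `X = 0`, continuity at
  `xq`, linearity), giving `v_d(X) = va + X (vp(1 - xq) - va)/xq` on
  `[0, xq]`.
* **Intrinsic motility**: speed `v0(X) = vs / (1 + ((1-X)/Xv)^h)` rising
  toward the posterior, along a persistent direction `n_i` that random-walks
  on the unit sphere with rotational diffusivity `D` (Euler–Maruyama step in
  the local tangent frame, renormalized to the sphere each step; at the poles
  `n ~ +-ez` the frame degenerates and any orthonormal tangent pair preserves
  isotropy — we use `(ex, ey)`).
* **Volume exclusion**: linear soft repulsion `mu (d/dc - 1)` for separations
  `d <= dc` (the cell diameter), zero beyond; no adhesion. Coincident centres
  (only reachable through pathological initial conditions; daughters spawn at
  `d_new > 0`) repel at full strength `mu` along a random direction.
* **Boundary force**: directed toward the local tube axis, with components
  maximal (scale `mu_b`) at the tube surface `r = rT` and decaying as
  `exp(-delta/r_b)` away from it — in both directions, so confinement
  weakens for cells that have escaped far beyond the surface. This is the
  force as printed; in practice the relaxed tissue keeps >99% of cells
  within `rT + 1 um`.

### Clock

Each cell carries a phase `theta_i`:

    dtheta_i/dt = omega(x_i) + (kappa/N_i) sum_{|xj-xi|<=dc} sin(theta_j* - theta_i)
                  + sqrt(2 D_theta) xi_i(t)

* `omega(X) = omega0 (sigma + (1-sigma)(1 - e^{-kX})/(1 - e^{-k}))`: a frozen
  frequency gradient from `sigma omega0` at the wavefront to `omega0`
  posteriorly, producing anterior-travelling phase waves.
* `theta_j*` is the neighbour's current phase, or its phase `tau` minutes ago
  in delayed-coupling mode (delta-notch signal transduction time). Histories
  are ring buffers at step resolution; lookups use the nearest stored sample
  (`tau/dt` is integer for the defaults, so no interpolation error), and
  times before a cell existed return its initial phase (0 for ingressed
  cells, `3pi/2` for founders).
* The neighbour count `N_i` excludes the cell itself. The printed set
  definition would include it; self-inclusion adds `sin(0) = 0` to the sum
  but would dilute the `1/N_i` normalization, so exclusion is the faithful
  reading.
* Arrest: the whole increment (noise included) is zero anterior of the
  wavefront (`x < xa`) and during M-phase of the cell cycle. Arrested cells
  remain visible as coupling sources to their neighbours by default
  (transcriptional silence reads as the clock's "off" phase); an
  `EXCLUDE_MITOTIC` mode removes M-phase cells from neighbours' sums and
  counts instead.

### Cell turnover

Density-triggered ingression: each step, subdomain densities (cells with
`x >= xa` over the analytic subdomain volumes) are compared with the target
`rho0`; if any is deficient, exactly one cell is added to the most deficient
subdomain (ties broken left cylinder, right cylinder, tailbud). Scenarios:

| scenario | tailbud | cylinders |
|---|---|---|
| RANDOM | interior, random phase | interior, random phase |
| DP | dorsal surface quarter, phase 0 | interior, random phase |
| DP_LV | dorsal surface quarter, phase 0 | ventral surface quarter, phase 0 |

Surface/interior draws are uniform in the tube parameters (x or p, r, q) as
the scenarios are defined, not uniform in area/volume. A supplement-style
variant initializes ingressed cells with random phase everywhere.

Division: cell-cycle phase `tau_cc` advances at unit rate through a cycle of
length `TG + TM` (`TM = 15` min of M-phase; `TG = 172.5` min follows from
the observed ~8% M-phase fraction: `TG + TM = 15/0.08 = 187.5`). On
completion a daughter spawns `d_new = dc/10` away in a random direction,
inheriting phase and direction; both restart at `tau_cc = 0`. Division can be
confined to the posterior of `x = xa + xdiv` by pinning `tau_cc = 0` anterior
of that point (`xdiv = 0` lets the whole PSM divide). Founders and ingressed
cells start at a uniform-random cycle phase so the M-phase fraction starts at
its steady state rather than needing a ~190-min burn-in.

Book-keeping: cells more than `3 dc` anterior of the wavefront are culled
(they can no longer neighbour any measured cell); until then frozen cells
continue to advect, repel, and serve as coupling sources.

### Compaction–extension

From the 16-somite stage (t ~ 257 min, found once by bisection of the somite
curve `s(t) = 6 + t/24.7 - a e^{b(t-300)}`, a = 0.5001, b = 0.0049) the
schedules shrink `L` (by moving `xa` posteriorly at `ma` per somite; the
posterior tip stays fixed in the frame) and `rT`, raise the density target,
and shrink the cell diameter, all linear in `s - 16`. The cell-addition
window tracks the wavefront at `xd = 100 um`. Cells left outside the
shrinking radius are herded inward by the boundary force, never teleported.
`dc(t)` is continuous in `s(t)` by default (a per-integer-somite stepwise
variant is available as a flag). Runs terminate when the tissue becomes
shorter than the addition offset (`L < xd`) or when the anterior measurement
window empties; late in compaction the cylinder addition window
`[xa + xd, Xc]` can empty first, in which case additions collapse to the
cylinder–tailbud junction. Advection, motility, and frequency profiles are
held constant throughout (their terminal-stage changes are unquantified).

### Metrics

Synchrony is the Kuramoto order parameter `r` of the anterior measurement
window: the left-side strip `xa <= x <= xa + dc`, `y < Yc`, excluding
M-phase cells when division is on (their arrest would trivially depress the
read-out). Frequency is the mean of the deterministic part of the
instantaneous `dtheta/dt` over the same cells; the excess frequency
subtracts the strip average of `omega` (96-point Gauss quadrature).
Kymographs bin the left side into `dc`-wide AP bins anchored at the current
`xa`; empty bins are missing values, never zeros.

## Numerics

* Forward Euler for positions and phases, `dt = 0.01` min by default;
  synchronous (Jacobi) update — every increment in a step is computed from
  the state at the start of the step, so results are independent of cell
  ordering.
* Noise enters with Euler–Maruyama `sqrt(dt)` scaling; the direction vector
  is renormalized after every step (the continuous equation preserves the
  sphere only in the limit).
* Initialization: `floor(rho0 pi rT^2 Xc)` cells per cylinder and
  `floor(rho0 pi^2 rT^2 R)` in the tailbud (2,321 total at defaults), placed
  uniformly in tube parameters (hence centre-dense), phases all `3pi/2`,
  then 10 min of motion-only relaxation (motility + repulsion + boundary; no
  advection, clock, or turnover). Relaxation precedes `t = 0` and does not
  consume simulation time. It also loses a few dozen cells through the open
  anterior end, leaving subdomains 2–3% below `rho0` until density
  maintenance replenishes them in the first minutes of the run.
* One numpy PCG64 generator per run, seeded from the config; a (config,
  seed) pair reproduces trajectories bit-for-bit. Sweep replicate i uses
  `base_seed + grid_point_index * replicates + i`.
* The fixed-radius neighbour search is a uniform cell list (bin pitch `dc`)
  fused with the pairwise repulsion/coupling accumulation in a jitted
  kernel; it is exact (closed ball, `<= dc`) and the test suite checks it
  pair-for-pair against an all-pairs oracle. Coupling sines use the
  angle-difference identity on per-cell sin/cos tables.

## What the synthetic tissues show — and what they do not

The simulator *is* the data generator: every experiment runs on tissues it
creates. The defaults reproduce the study conditions (zebrafish parameter
table, 1000-min horizon, `dt = 0.01`). The test suite runs two reduced
harnesses chosen to keep the default run fast: `two_cell` (an isolated
oscillator pair whose phase gap obeys the closed form
`phi(t) = 2 arctan(tan(phi0/2) e^{-2 kappa t})`) and `mini_psm` (half-scale
geometry `Xc = 150, R = 30, rT = 12.5`, ~290 cells, `dt = 0.02`). Ordering
and trend checks (ingression scenarios, tissue length, M-phase duration,
coupling delay) use `mini_psm` or the full geometry at `dt = 0.02` with 3–5
replicates; these reproduce the directions of the full-scale effects, but
their medians are noisier than the 100-replicate originals, so trend
assertions carry a small tolerance (0.02 in `r`) against replicate noise.
The tissue-length comparison additionally weakens the coupling to
`kappa = 0.04` /min: at the default coupling the half-scale tissue
synchronizes almost perfectly at every length (a ceiling that hides the
effect), whereas near the synchronization threshold the benefit of a longer
transit time is unambiguous.
Passing at reduced scale demonstrates the mechanisms, not quantitative
agreement at the anterior per-pixel level of the full parameter maps.

No real data enters anywhere: the model abstracts the clock to one phase per
cell (no amplitudes, no Hes/Her network), has no cell adhesion, no spatial
density gradient, no mechanical interaction with surrounding tissues, and
holds most profiles constant in time. Conclusions about terminal-stage
somitogenesis are correspondingly weak.

## Design choices made where the source was open

* `xdiv = 0`, not infinity, encodes "unrestricted division": the halting
  rule pins the cycle wherever `x < xa + xdiv`, so an infinite offset would
  halt everywhere.
* Density counts exclude cells anterior of `xa`; the subdomains are defined
  on `[xa, ·]`.
* At most one ingressed cell per time step; the addition rate is therefore
  bounded by `1/dt` and in practice sits near the advective outflux
  (~5 cells/min at defaults).
* In combined delay + division runs (never combined in the original study) a
  daughter inherits its mother's phase history buffer.
* Early termination (length exhausted / anterior gap) is only checked for
  shrinking tissues; fixed-geometry runs always reach `t_max`.
* The delayed-coupling self-consistency `Omega = omega - kappa sin(Omega tau)`
  is used as an independent check of the two-cell harness, solved numerically
  with Brent's method.

## Known limitations

* Forward Euler is first-order; halving `dt` moves the end-time anterior
  synchrony of the mini harness by well under the 0.05 the engine contract
  allows, but stiff parameter choices (very large `mu` or `mu_b` with large
  `dt`) can destabilize the explicit scheme.
* The uniform-in-parameters surface sampling slightly favours the inner edge
  of the torus dorsal quarter (no area correction), exactly as the scenarios
  are specified.
* `s(t)` is non-monotone past ~870 min; schedules are evaluated as printed
  without clamping, and runs normally terminate long before that point.
* The M-phase coupling default treats arrested cells as phase-0-equivalent
  sources; the EXCLUDE_MITOTIC variant changes individual trajectories but
  not the reported orderings.
* With division enabled, the steady-state mitotic index settles near 5.5%,
  below the 8% instantaneous fraction from which `TG` is derived: that
  derivation assumes a uniform cycle-age distribution, whereas the model
  restarts both cells of a division at age zero, skewing the stationary age
  density young. The 8% figure holds at initialization (ages drawn uniform)
  and decays toward the renewal-theory value ~0.056 within about one cycle.
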