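# Methods

This note documents the model implemented in `cortigen`, the estimators
built on top of it, the default study conditions with their rationale,
and the limits of what the synthetic experiments show.

## 1. The neural field

The field is a discrete-time network of `n` point neurons at random
positions in a bounded square sheet (side `domain`, default 10 length
units; `dt = 1` step). Each directed synapse carries presynaptic flux

    φ_ij(t) = sign_j · ε_ij · g_ij · ρ_ij · Q_j(t − d_ij),

with the axonal delay `d_ij = round(|x_i − x_j| / v)` (conduction speed
`v = 2` length units per step, delays up to ~7 steps at the default
geometry). `sign_j` is +1/−1 by the presynaptic cell's
excitatory/inhibitory identity (80% excitatory by default). The three
gain factors compose multiplicatively so that a zero on any timescale
silences the synapse.

Aggregate afferent flux plus external drive is convolved with a
normalized truncated-exponential dendritic kernel and passed through a
logistic pulse-generation function with `f(θ) = q_max/2` and
`f'(θ) = slope` (`θ = 0`, `slope = 0.25`, `q_max = 1`). A `linear`
activation form (the tangent at threshold) exists so small-signal
behaviour can be verified against closed-form delayed convolution.

**Separate excitatory and inhibitory dendritic kernels.** Excitatory
input integrates with `τ_e = 2` steps, inhibitory with `τ_i = 6`. This
is load-bearing: with a single shared kernel, exact per-dendrite E/I
balance cancels the spatially even mode at *all* frequencies, and the
widespread zero-lag first eigenmode cannot exist as a recurrent
phenomenon. Slower inhibition — generic in this model family and in
cortical physiology — opens a resonant band in which the even mode
survives. The low-level `step()` operation keeps the single-kernel
textbook form; the orchestrated `simulate()` uses the two-kernel
composition.

**Connection topology.** Connections are Bernoulli with probability
proportional to `connection_density = 0.3` times a distance-decay
profile: excitatory axons long-range (scale 5), inhibitory axons local
(scale 1.5). Same-type connections are made bidirectional (symmetric
exchange); every dendrite is guaranteed at least one afferent of each
sign. Initial dynamic gains are lognormal (`median 0.5`, `σ = 0.5`); the
immature field starts *unbalanced* and is pulled to its homeostatic set
point by the anti-Hebbian step itself (an optional `init_balanced` flag
pre-balances at build time).

## 2. Plasticity

Three coupled timescales, all seeded and deterministic:

* **Transient efficacy ε** (fast): grows with the centered pre×post
  rate coincidence at rate `η_ε = 0.01` and decays back to baseline 1
  with `T_ε = 10` steps. The modulation depth is deliberately shallow:
  strong ε modulation is symmetric in the two directions of an exchange
  and masks the disorder of an immature field in the exchange
  statistics.
* **Dynamic gain g** (intermediate, `T_g = 2000`): rectified
  rate-product potentiation `Δg ∝ ε · max(post_c · pre_c, 0)` on
  flux-bearing synapses, gated by a BCM-style sliding threshold
  (`θ_i ← ⟨Q_i²⟩ / q₀`, `T_bcm = 200`, `q₀ = 0.5`). Potentiation-only,
  so sustained coincident flux can never decrease `g`. Per-dendrite
  competitive normalization bounds each sign-block's row sum at
  `g_cap_factor = 4` times its initial value, preserving within-block
  ratios.
* **Structural gain ρ** (slow, `T_ρ = 10⁴`): relaxes toward `g` on
  active synapses only, so a silent window leaves structure untouched.

Hebbian plasticity acts at **excitatory synapses only**; inhibitory
gains change only through the homeostatic step. This is the
biologically canonical split, and it matters dynamically: letting the
coincidence rule rebuild inhibitory weights lets learned cross-cohort
inhibition amplify a two-block "see-saw" mode until it dominates the
first eigenmode and destroys the even/odd mode ordering.

* **Anti-Hebbian normalization** (every `norm_period = 100` steps):
  each neuron's excitatory and inhibitory afferent `g`-blocks are
  multiplicatively rescaled so the window-averaged total excitatory flux
  and the magnitude of the total inhibitory flux both equal
  `target_flux = 3`. The rescale is a scalar per block, so within-block
  (Hebbian) ratios are preserved to machine precision, and the
  recomputed window imbalance `|Σφ_e + Σφ_i| / target` is at the 1e−16
  level after every event. A `population` mode balances the field-wide
  averages instead; per-neuron is the default.

## 3. Synchrony and free-energy estimators

**Eigenmodes.** SVD of the centered pulse-rate trajectory (burn-in
excluded; burn-in = maximum delay + kernel support). Per component:

* *zero-lag synchrony index*: the fraction of neuron pairs whose
  sign-adjusted cross-correlation (signs from the loading product, so
  anti-loaded channels count as synchronous members of the mode) attains
  its maximum at lag 0, weighted by `|u_i u_j|`; lags scanned over ±15
  steps.
* *spatial damping*: loading localization `1 − PR/n` with participation
  ratio `PR = 1/Σu⁴` — 0 for a widespread uniform mode, →1 for a mode
  concentrated on few cells. A loading-vs-distance regression was tried
  first and discarded: converged fields carry sign-mixed interdigitated
  loadings for which the regression slope is ~0 for *both* leading
  modes, making the comparison noise; localization separates the
  widespread first mode from damped higher modes robustly and matches
  the phenomenon being described ("widespread" vs "spatially damped,
  low magnitude").

**Flux free energy.** For every mutually connected pair, the two
directed flux series are mean-subtracted and (by default) normalized to
unit variance; `A` and `C` sum the lagged auto- and cross-correlation
functions over `τ ∈ [0, lag_range]` (default twice the maximum axonal
delay). Two deliberate choices:

* *Per-pair normalization* (correlation coefficients) is the default,
  not raw covariance sums. Empirically, raw sums **increase** through a
  synchronizing run, because homeostasis pins mean flux, not flux
  variance, and variance grows with coherence; the scale-free statement
  is the one the convergence claim actually makes. `normalized=False`
  recovers raw sums.
* *Exchange orientation.* Pairs inside one synchronous assembly
  equilibrate with equal co-directed flux; pairs spanning two
  mirror-paired assemblies equilibrate with equal **oppositely
  directed** flux. Each pair's cross terms therefore enter `C` with an
  orientation `σ = sign(Σ_τ c)`; the fraction of `σ < 0` pairs is
  reported as the *mirror fraction*. The equilibrium residual is
  `Σ_pairs |Σ_τ a − σ Σ_τ c|`, i.e. each pair's distance to the nearest
  admissible equilibrium.

Under strict per-dendrite balance a globally uniform in-phase state
cannot carry recurrent signal (excitatory and inhibitory flux would
cancel identically), so the converged field always contains
counter-directed exchanges between anti-phase cohorts — the mirror-pair
structure is forced by E/I balance, and the orientation-aware statistic
measures convergence onto that equilibrium set rather than punishing
it.

**Prediction error.** Paired runs share geometry, gains and seed and
differ only in drive (the baseline has none). `ΔΦ⁺` is the drive
difference; `ΔΦ⁻` is the oppositely directed recurrent response
(baseline-minus-driven total afferent flux per neuron); the residual is
`‖ΔΦ⁺ − ΔΦ⁻‖` per step. The neutralization this model actually
performs is homeostatic: a balanced field cancels the *sustained*
component of an input (its residual under a constant probe falls below
the no-response level `‖ΔΦ⁺‖`), while an immature unbalanced field
amplifies it. Broadband white noise is not predictable by any setting
of the gains, and the residual says so.

**Trajectory classification.** Windowed `F` with first/second finite
differences; "near zero" means below 5% of the initial `|F|`
(scale-free). Terminal `d²F/dt² > 0` while `F` and `dF/dt` are near
zero classifies the run as approaching an *unstable* fixed point (the
symmetry-broken case); otherwise stable / descending / not-converged.

**Capacity.** `D = n log₂(1 + C/A)` bits; `2^(n/2)` mirror-pair states
and `2^(n_neo − n_limb)` states per limbic state, as exact integers for
exponents up to 62 and in log₂ above that.

## 4. Morphogenesis

Soma positions of `n_patch` long-axon and `n_local` short-axon cells
relax in a bounded sheet under three forces:

* short-range soma repulsion `k_rep (r_core/(d + 0.05 r_core))²`
  (`k_rep = 0.25`, `r_core = 0.3`);
* *synchrony attraction* `w_syn (d/ℓ²) exp(−(d/ℓ)²)` along each pair,
  `ℓ` the pair's mean axon scale: it pulls a pair into axonal reach and
  **saturates inside it** (zero force at `d ≪ ℓ`), so cluster spread
  scales with the local axon length. A plain exponential decay was
  tried first and discarded — it collapses every cluster to the hard
  core regardless of axon scale and the columnar/diffuse continuum
  disappears;
* *wiring cost* `w_wire · d/domain` along each cell's 4 nearest-
  neighbour links (absolute cable length, refreshed every 25
  iterations).

Annealed explicit integration, displacement capped at 5% of the domain;
convergence when the maximum displacement falls below `10⁻³ · domain`
(a non-converged relaxation returns the best layout with
`converged=False`). Defaults: axon scales 4.0 (patch) and 0.5 (local),
both weights 1.

*Axon-ratio sweeps* hold the geometric-mean axon scale fixed
(`s₀ = 1.5`): scale_patch `= s₀√ratio`, scale_local `= s₀/√ratio`. At
ratio 1 the two populations are undifferentiated with intermediate
axons — coupling is loose and the layout more diffuse; increasing
differentiation sharpens the columns. This keeps the total axonal
budget constant so the sweep varies exactly one thing.

*Columnarity* is a Clark–Evans-style statistic: the mean
nearest-neighbour distance of local cells against its Monte-Carlo
expectation under complete spatial randomness in the same domain (99
seeded draws); `index = clip(1 − d_obs/d_CSR, 0, 1)`. Rotation- and
translation-invariant; over-dispersed (regular) layouts clip to 0.

*Tiling* classifies cluster-centre lattices (density-based clustering
of local cells) by the 4-fold vs 6-fold circular concentration of
near-neighbour bond angles (`R_k = |⟨e^{ikθ}⟩|`, threshold 0.4);
unclustered layouts are `diffuse`.

*Mirror symmetry* reflects one side of a candidate axis, registers it
to the other by nearest-neighbour matching, and scores each match by
spatial registration `1 − 2 min(d/s, 1)` (s = median nearest-neighbour
spacing) times, when cells carry handedness, the chirality-reversal
factor `−χ_L χ_R`. An exact reflection with flipped handedness scores
exactly 1. `axis="fit"` scans centroid lines in 5° steps; the
permutation null redraws the reflected side uniformly (99 draws).
Square column lattices support a perfect alternating (checkerboard)
chirality assignment; the triangular adjacency of a hexagonal tiling is
not 2-colourable, so some neighbour pairs are frustrated and the best
attainable score is strictly lower — the broken symmetry of hexagonal
patch arrays, as a graph-colouring fact.

*Apoptotic selection* removes the lowest-scoring fraction by mean
zero-lag correlation with the population, renumbering positions,
delays and all gain matrices consistently.

## 5. The angle-doubling projection

A local map (column) is `(p₀, k, χ)`. The forward projection is

    p − p₀ = χ_op( (i/k) · (P − p₀)² / |P − p₀| ),

modulus scaled by `1/k`, argument doubled, rotated by exactly 90° by
the imaginary unit. **Chirality is implemented as complex conjugation**
(`χ = −1` conjugates), not as a global sign: a global ± is a 180°
in-plane rotation, which is orientation-preserving and cannot produce a
mirror column, whereas the anti-conformal branch yields true mirror
maps and singularity windings `±½` that match the chirality. Flipping
the chirality of every map mirrors the OP raster as an image (positions
reflected, values untouched); for orientation (period-180°) fields,
reflection *with* value negation provably preserves winding, so
"mirror with opposite winding" is only realizable in this
positions-only sense.

The inverse halves the angle on a chosen branch (the two branches
differ by 180° in global angle); round trips are exact to better than
1e−12 relative. The orientation preference of a local position is its
global preimage direction mod 180°, so a full circuit around `p₀`
sweeps OP through exactly one 180° period with winding `χ/2`.

OP rasters use a pixel-centred grid (a map centre falls inside a
plaquette, never on a node) and nearest-centre map assignment; a soft
warning flags resolutions coarser than half the map spacing. Feature
classification: singularities are plaquettes whose wrapped-difference
loop winds ±180° with every step below 60° (suppressing inter-map
discontinuities); saddles are interior local minima of the wrapped
gradient magnitude (lowest 5%) whose locally unwrapped quadratic fit
has an indefinite Hessian — away from singularities the OP phase is
harmonic, so any genuine critical point is a saddle and the test is
confirmatory; linear zones are connected components of the lowest
gradient decile (default 10th percentile).

Image dispersal places each global sample at its projected position
with conduction delay `|P − p|/v`; the twelve-point representation
frame packs (scale, two rotation angles) + (x, y, z) + the two
3-component translation rates, in that documented order, and inverts
exactly.

## 6. Study conditions and problem sizes

The emergence protocol (`cortigen.studies.emergence_study`) runs the
default 64-neuron balanced field for 2×10⁴ steps under spatially and
temporally white Gaussian drive (σ = 0.4 flux units), plasticity on,
five seeds; quartile eigenmode analyses and ten 2000-step free-energy
windows are computed on the same record. The default parameter set
(target flux 3, drive 0.4, unbalanced lognormal start, `T_g = 2000`,
`η_ε = 0.01`) places the field in a coupling-dominated, near-linear
regime in which the synchronizing mechanism operates and learning spans
the run — chosen once, by the dynamical reasoning above, as this
package's reference conditions. Morphogenesis studies use 200 cells
(100 + 100) with relaxations capped at 1500 iterations and the
axon-ratio sweep {1, 2, 4, 8}; mirror comparisons use 4×4 column
arrays with 3-point chiral motifs.

Under these conditions the model reproduces: monotone growth of the
first eigenmode's zero-lag index between the first and last run
quartile; higher spatial damping of the second mode in every seed; a
significantly negative free-energy trend across windows; machine-exact
E/I balance after every homeostatic event; the columnar/diffuse
continuum and its monotone dependence on axon-scale differentiation;
and strictly higher mirror symmetry of square vs hexagonal patch
tilings. One quantitative convergence property falls short of its
idealized level: the windowed equilibrium residual ends near 40% of its
first-window value, not below 20%. Two structural reasons: the
balanced random field *already* synchronizes substantially within the
first window by purely linear dynamics (synchrony without plasticity is
itself part of the theory), so the initial residual is modest; and the
per-neuron white drive continuously injects decorrelation, leaving
roughly a tenth of exchange power unpredicted at any finite run length.

## 7. What the synthetic experiments do and do not show

The generators emulate the *mechanisms* — delayed balanced recurrence,
white-noise developmental drive, two-population axon geometry, chiral
column motifs — not any particular cortex. Pulse rates are smooth
deterministic functions of membrane state (no spiking statistics);
anatomy is 2-D and single-layer; drive is statistically stationary;
apoptosis and layout relaxation are run as separate stages rather than
interleaved with field simulation. Passing tests therefore show that
the claimed phenomena follow from the stated assumptions at these
scales, not that the parameter values are biologically calibrated —
conduction speeds, time constants and flux targets are in model units.
Known limitations: the equilibrium-residual floor above; tiling
classification needs ≥4 detectable columns; mirror-axis search is a
5°-step grid through the centroid, so heavily off-centre axes require
an explicit axis; and the saddle detector reports grid-cell clusters of
candidate points rather than deduplicated critical points.
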