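# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `rdcfit`, in the order a user meets them.

## Forward model and physical constants

A residual dipolar coupling is modelled as
`D = (Dmax/r³)·vᵀSv` with `v` the unit internuclear vector, `r` in Å and
`S` the symmetric traceless Saupe order tensor.  `Dmax`, the maximum
observable coupling at 1 Å separation, is evaluated as
`−μ0·γi·γj·h/(8π³·r0³)` with CODATA-2018 `μ0`, the SI-exact Planck
constant, and gyromagnetic ratios γ(¹H) = 2.6752218744×10⁸,
γ(¹³C) = 6.72828×10⁷, γ(¹⁵N) = −2.7126×10⁷ rad s⁻¹ T⁻¹.  The resulting
unit-distance constants (N-H +24 360 Hz, C-N +6 127 Hz, C-H −60 421 Hz,
H-H −240 240 Hz, Ca-C −15 196 Hz) agree with published normalization
tables; the sign carries `−γiγj`, so ¹⁵N-containing pairs have the opposite
sign from pure ¹³C/¹H pairs.  Per-row `dmax` values in a data file override
the built-in table — the file is authoritative, because measured bond
lengths and vibrational corrections are the user's call.

Time dependence (the angular average that produces a *residual* coupling)
is never represented explicitly: the engine fits the averaged observable,
and all averaging lives in the synthetic-data dynamics models.  Relaxation
effects, cross-correlated couplings, scalar contributions and
field-strength dependence are out of scope.

## The linear system and the SVD solve

Using `Szz = −Sxx − Syy`, each selected, observed equation contributes the
design row `[x²−z², y²−z², 2xy, 2xz, 2yz]` and right-hand side `D·r³/Dmax`.
The system is solved by SVD; singular values below `1e-12 × s_max` are
treated as null, and a rank < 5 (or n < 5) system yields the minimum-norm
least-squares solution plus a machine-readable warning rather than an
error, because sparse fragments are a legitimate use case.  Rows are not
weighted by experimental error; whether the historical engines weight is
undocumented, so this is a stated compatibility caveat.  Residuals are
reported in Hz (back-transformed through each row's `dmax/r³`) so they
compare directly with per-row error bars.

## Tensor decomposition conventions

* Principal values are eigenvalues sorted by magnitude ascending into
  `(Sxx', Syy', Szz')`; magnitude ties break by signed value descending,
  for determinism.
* The rotation returned maps the molecular frame to the principal frame
  (columns are principal axes in molecular coordinates);
  `R·diag(principal)·Rᵀ` reconstructs the tensor.
* Euler angles are **active ZYZ**, degrees, canonicalized to
  α, γ ∈ (−180°, 180°], β ∈ [0°, 180°].  A symmetric tensor carries a
  4-fold frame degeneracy (180° flips about each principal axis);
  `euler_angles` returns the whole class, and comparisons should always be
  made within it.  Note (α, β, γ) ≡ (α+180°, −β, γ+180°), so a reference
  triple quoted with negative β appears here on the β ≥ 0 branch.  When
  β ∈ {0°, 180°} only α±γ is defined; γ is fixed to 0 and the
  decomposition is flagged degenerate.
* `Da(pair) = ½·Dmax(pair, 1 Å)·Szz'` and `R = (2/3)(Sxx'−Syy')/Szz'`,
  which the ordering confines to [0, 2/3].  Conventions for Q and R differ
  across the literature; these are stated here once and used everywhere.

## Monte Carlo solution ensembles

Each trial perturbs every selected observation by an independent uniform
draw in [−error, +error] (uniform matches the hard within-error acceptance
test; Gaussian sampling is available via the noise argument of the
generators), refits, and accepts the trial tensor iff it reproduces every
*unperturbed* observation within its error bar.  Acceptance against the
unperturbed data makes "tensors within error" well-defined and exactly
recountable from the stored tensors.  Draws are unit noise scaled by the
error bars, so rescaling all bars under the same seed rescales the same
draws — acceptance is monotone in bar width.  The within-error test allows
a 1e-9 Hz absolute slack so that exactly-fitting data with zero-width bars
are not rejected by floating-point rounding.  With all bars zero every
trial equals the least-squares solution; whether it is *accepted* then
depends only on whether the data are exactly fittable.

## Error analysis, rejection and localized validation

A violation is a residual strictly greater than the equation's error (plus
the 1e-9 Hz slack).  `iterative_rejection` repeats fit → flag → remove the
single worst violator → refit, stopping when no violations remain, fewer
than five equations would survive, or the iteration cap is reached; one-at-
a-time removal is used because a single bad datum inflates its neighbours'
residuals, making batch removal unstable.

`localized_validation` combines media: after per-medium rejection and
refit, an equation is flagged as structurally suspect only if its residual
exceeds its error in **every** medium.  Single-medium flags conflate three
things — genuine local distortion, noise outliers (uniform noise at the
bar width makes borderline rows unavoidable), and leakage of the residual
tensor-estimate error into large couplings.  The last two are independent
across media while genuine distortion is not, so the intersection isolates
it; this mirrors standard practice of trusting region assignments only when
several media and vector types agree.

## Sanson–Flamsteed products and orientation bands

`sf_project` maps a direction to `lat = arcsin z`, `lon = atan2(y, x)`,
`(px, py) = (lon·cos lat, lat)` — the sinusoidal equal-area projection, so
uniform directions have uniform planar density.  Ensemble plots emit all
three principal axes with labels and both antipodes (the physics cannot
distinguish them; hemisphere folding is off by default).  In 3D mode the
point height is the axis' |order parameter|, so a top view reproduces the
2D plot while a side view separates tensors that share a frame but differ
in alignment magnitude.

Orientation bands are evaluated on an equiangular lat × lon grid
(`resolution` × `2·resolution` cells) at cell centers; the accepted
fraction is the cos(lat)-weighted mask mean, a midpoint quadrature of the
band's solid-angle fraction that agrees with a 10⁶-sample Monte Carlo
estimate to ~3×10⁻⁴ at resolution 256.  The grid coordinate arrays are
constructed with exact mirror symmetry so the mask's antipodal symmetry is
exact in floating point, not merely approximate.  Rendering is deliberately
out of scope; bands and projections are exported as masks and TSV tables.

## Synthetic data: what it emulates and what it does not

`MEDIUM_TENSORS` holds the two reference alignments used throughout
validation: M1 = diag(−3, −5, 8)×10⁻⁴ in the identity frame and
M2 = (2, 5, −7)×10⁻⁴ rotated by ZYZ (−40°, −50°, 60°) — magnitudes typical
of experimental protein alignments.  Vector sets are Fibonacci-spiral
(quasi-uniform, seed-free) or seeded random directions at a 1.02 Å bond
length.  Noise is uniform (±w) or Gaussian; two-state and multi-conformer
averaging take population-weighted means of per-state back-calculations,
exactly linear by construction.

The localized-validation generator emulates a ~300-residue protein with
two mobile loop regions: 233 rigid residues plus two regions of 33
residues each (placed mid-chain), {N-H, Ca-Ha} couplings per residue in
both reference media, mobile-region couplings averaged over 100 conformers,
each conformer a rigid rotation of the whole region about a random axis by
60°, and ±1 Hz uniform noise on every observation with the error column set
to 1 Hz.  These sizes mirror a dimeric-enzyme validation protocol
(two mobile regions of ≈36 and ≈31 residues in a ≈300-residue chain, 100
MD frames, ±1 Hz noise); the 60° rigid rotation stands in for a backbone
dihedral perturbation of that size.  What the generator does **not**
reproduce: real protein geometry (bond-vector correlations along secondary
structure), continuous MD-style conformational distributions, per-pair bond
lengths (1.02 Å is used for all pairs, which inflates Ca-Ha couplings by
~20% relative to a 1.09 Å bond), or experimental artefacts such as peak
overlap.  Passing tests therefore demonstrate the *analysis* behaves
correctly under the assumed motion/noise model, not that any particular
protein fits.

Averaging ~100 random-axis 60° rotations scales a rank-2 tensor by roughly
the l = 2 rotational character χ₂(60°)/5 = 1/5, so mobile-region couplings
shrink to ≈20% of their static values — a strong, detectable signature,
with rows whose static coupling is small remaining genuinely
indistinguishable from rigid rows within ±1 Hz.

## Problem sizes and tolerances used in validation

Exact-recovery checks use 12–20 quasi-uniform vectors (any ≥5 in general
position suffice; recovery is to 1e-10 per element).  Monte Carlo checks
use 200 trials.  The localized-validation dataset has 598 equations per
medium (466 rigid, 132 mobile); the cross-media flag set overlaps the true
mobile annotation with Jaccard ≈ 0.84–0.90 across seeds, and the
post-rejection tensors match the generators to ≤ ~2% per element
(normalized by the largest principal value, since off-diagonal elements
can be exactly zero).  Band calibration uses resolution 256 against a 10⁶
Monte Carlo oracle (agreement < 0.01); the equal-area test bins 10⁵
directions into 120 equal-area cells and applies a χ² test at α = 10⁻³.

## Session state and reports

Session state and reports serialize to canonical JSON (sorted keys, UTF-8,
shortest round-trip floats), with a schema version; unknown future keys are
preserved on load and a newer schema raises explicitly.  Reports can also
be rendered as minimal structured HTML.  The historical binary/GUI session
formats of legacy RDC tools are not read.

## Known limitations

* One tensor per medium; no joint multi-medium or dynamics-aware fits
  (methyl/phenyl rotation variants are out of scope).
* No error-weighted rows in the fit (documented above).
* Q-factor uses rms(observed) in the denominator, not a Da-based
  normalization; values are not directly comparable to Da-normalized Qs.
* PDB extraction reads the first model only, resolves altlocs by highest
  occupancy (first on tie), and uses standard backbone atom names; mmCIF
  and NMR-STAR restraint import are not supported.
* Structure refinement itself (energy minimization against RDC restraints)
  is outside the package's scope; the validation outputs are designed to
  feed such tools.
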