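# Methods

## Scope and model

`paintprox` analyzes sequential multiplexed DNA-PAINT localization data:
one table of super-resolved 2D coordinates per imaging round, one target
protein per round, acquired on the same specimen with an adapter/eraser
switching scheme.  The pipeline has three analysis stages — rigid
registration of rounds, directed nearest-neighbor (NN) proximity
statistics, and per-channel localization-precision estimation — plus a
synthetic-data generator that emulates the acquisition at the
localization level with known ground truth.

Everything is 2D (the acquisition emulated is TIRF); distances are
Euclidean in nm.

## Synthetic data generator

The generator starts at the localization level: there is no camera, PSF,
photon or kinetic model.  What it emulates, per round:

1. **Geometry.** The Golgi is modeled as `n_stacks` "ministacks" placed
   in the field of view.  With `curvature > 0` each ministack is a closed
   ring of radius `1/curvature` — the en-face projection of a closed
   cisternal rim — and the layer at cis→trans offset `o` is the
   concentric ring of radius `1/curvature + o` (cis innermost).  With
   `curvature = 0` ministacks are straight segments perpendicular to
   `stack_axis` and layers are exactly parallel lines `o` apart; this
   flat mode gives analytically exact support separations and is what
   the geometry-fidelity and layer-separation tests use.  Three support
   kinds exist: `layer` (cisternal rim), `interface_puncta` (disks of
   radius `puncta_radius` at an interface offset — membrane contact
   sites), and `uniform_background` (spread across the whole stack span).
2. **Sites.** Labeled sites form a homogeneous Poisson process on the
   support; areal density is converted to a linear rim density via the
   nominal rim width `ribbon_width`, so the expected count is
   `site_density × rim length × ribbon_width` for layers and
   `site_density × π r²` per punctum.
3. **Blinks.** Each site yields `K` localizations per round, `K` drawn
   from a Poisson, geometric, or fixed law with mean
   `mean_blinks_per_site`.  Blinks are grouped into binding events
   spanning consecutive camera frames (geometric event length, mean
   `mean_event_frames` = 3 frames of the `frames_per_round` = 30 000);
   this temporal clustering is what adjacent-frame precision estimation
   relies on, and mimics imager dwell times of a few frames.
4. **Errors.** Every blink gets independent Gaussian localization error
   (`sigma_loc` = 5 nm per coordinate).  Each *site* additionally gets
   one fixed-magnitude, random-direction label offset (`linkage_radius`
   = 7 nm), drawn once per site: the antibody/nanobody/docking-strand
   stalk is rigid over the experiment, so linkage error displaces all of
   a site's blinks coherently.
5. **Degradations.** Uniform false localizations at `false_rate` = 1/µm²
   per round; carryover of a Bernoulli `1 − erasure_efficiency` fraction
   (default efficiency 0.995) of the *previous* round's sites — erasure
   of the previous adapter is effectively but not perfectly complete, and
   only first-order carryover is modeled; and a per-round rigid stage
   shift (`round_shifts`).

All randomness derives from a single integer seed through spawned seed
sequences; identical inputs give bit-identical outputs.

### Default study-emulating model

Eight ring ministacks (rim radius 450 nm, rim width 200 nm) in a
12 × 12 µm field; reference-channel density 200 sites/µm².  Cis→trans
offsets in nm: GRASP65 −5, GM130 0, Giantin 65, GALNT2 73, Rab6 81,
Golgin97 100, TGN46 110.  VPS13B is an `interface_puncta` channel: 20
puncta of radius 40 nm per ministack (160 total, ~20 sites each at
4000 sites/µm²), anchored 28 nm from GM130 on the cis side of the
cis/medial gap — at the membrane contact sites it is thought to bridge —
rather than at the geometric midpoint of the gap, reproducing the
observed pattern that the cis markers are its nearest neighbors.  A
diffuse FAM177A1 channel (uniform across the stack span) is part of the
default model; the default eight-round order images VPS13B plus the
seven reference markers, and FAM177A1 can be appended for the nine-target
variant.  The default acquisition applies zero stage shifts; registration
tests inject shifts explicitly.

What the generator does *not* emulate — and what passing tests therefore
do not certify on real data: frame-level photophysics and camera noise,
spot-fitting artifacts (merged emitters, multi-emitter events),
intra-round drift (assumed corrected upstream by the reconstruction
software), anisotropic or locally varying labeling efficiency, 3D
structure projected into 2D, and antibody cross-reactivity.  Linkage
error inflates all measured inter-channel distances by a few nm; no
correction is applied, matching common practice.

## Registration

Rounds are registered rigidly (translation only: rounds share one
mechanical mount, and intra-round drift is out of scope).  Localizations
are rendered on 10-nm half-open-bin histograms over a common extent and
cross-correlated by FFT (mean-subtracted, circular).

Plain correlation peak-picking fails for multiplexed rounds: two
channels occupy *different* supports, so for concentric-ring structure
the raw correlation maximum sits on a shell of lags at the inter-layer
offset (up to ~100 nm here), not at the stage shift.  For isotropically
oriented stacks, however, the correlation surface is radially symmetric
*about* the true shift.  The estimator therefore locates the surface's
center of symmetry: the correlation window (lags within `max_shift` =
500 nm, lightly smoothed, clipped at zero) is convolved with itself, and
by Cauchy–Schwarz the self-convolution peaks at exactly twice the center
of symmetry for any radially symmetric profile.  A per-axis parabolic
fit refines the peak to sub-bin precision, and the lag window is
re-centered on the estimate over three passes so that window clipping is
symmetric about the solution (this makes integer-bin translations exact
to <0.01 nm).

`align_rounds` defaults to a redundant scheme in the spirit of redundant
cross-correlation drift correction: shifts are measured for every pair
of rounds and combined by least squares on `d_ij = c_j − c_i` (reference
fixed at zero) with three Huber-style reweighting iterations to damp
outlier pairs.  Sparse channels (few puncta) gain the most: their shift
is pinned by several partially independent measurements.  A single-pass
`reference` mode is available.  On the default synthetic experiment with
injected shifts up to 100 nm, worst-case per-axis residuals are ≈4 nm
over 20 seeds (under half a rendering bin).

The image-correlation approach presumes no globally coherent
cross-channel displacement — true when stack orientations are isotropic,
as for the ring geometry here and for real fields containing many
arbitrarily oriented stacks.  A specimen with a single coherently
oriented stack would bias any structure-based registration by part of
the inter-layer offset; fiducial markers are not modeled.

## Proximity statistics

`nn_distances` uses a k-d tree and matches exhaustive O(n²) search
exactly (tested).  Numerical conventions:

* cutoff strict (`d < 500 nm`); boundary equality excluded;
* empty target channels yield an empty sample, not an error;
* NN ties broken by lowest target row index (distances equal, so nothing
  downstream changes);
* median = standard midpoint-of-central-order-statistics definition;
* matrix entries with fewer than `min_pair_count` = 50 retained
  distances are reported missing (guards against medians of tiny
  samples); self-pairs are 0;
* the matrix is directed by default; `symmetrize` pools i→j with j→i.

The closed-form check used in validation: against a homogeneous Poisson
channel of intensity λ, `P(NN > r) = exp(−λπr²)`, so the median NN
distance is `√(ln 2/(πλ))` — 47.0 nm at λ = 10⁻⁴ nm⁻².

## Localization precision

`estimate_precision` implements a NeNA-family estimator adapted to
PAINT-style temporal structure: for each localization, the distance to
its nearest neighbor in the *following* camera frame is collected —
dominated by repeated localizations of the same binding event — and the
histogram over `[0, fit_range]` (default 100 nm) is fit with a mixture
of the same-site term, a Rayleigh of scale `√2·σ` (two independent
σ-errors per coordinate), and a linear term for unrelated neighbors
(uniform 2D density at short range).  The fit is seeded by the Rayleigh
moment estimator `σ₀ = √(E[d²]/4)`, which is also the fallback if the
fit does not converge; a channel whose median pair distance is below
0.5 nm is reported at the moment estimate directly (degenerate,
effectively noiseless).  Fewer than 100 localizations, or fewer than 50
adjacent-frame pairs in range, raise an insufficient-data error.
Recovery is within ±10% for σ between 5 and 20 nm in the tests; the
method label is recorded in every output row.

## Pipeline and problem sizes

The YAML-driven pipeline (simulate/ingest → optional alignment →
proximity → exports) writes the median matrix, long-format pair
distances, precision table, registration report, heatmap, and a manifest
on every run (success or failure).  CSV and HDF5 channel tables are
interchangeable and round-trip losslessly; camera-pixel inputs are
converted with `pixel_size` (default 108 nm).

Test and acceptance computations run at desk scale by design: default
experiments are ~40 000 localizations over eight rounds in a 12-µm
field, registration recovery uses 20 seeds, ranking recovery 100 seeds,
and the closed-form Poisson check 10⁵ source points.  These sizes make
the statistical assertions sharp (binomial/Poisson tolerances are stated
with the tests) while keeping the full suite to a few minutes.

## Known limitations

* Registration is translation-only; rotation, scaling, and non-rigid
  warping are out of scope.
* The precision estimator assumes temporally clustered re-localizations;
  data whose blinks are isolated single frames leave it without
  same-site pairs (it then errors rather than misreporting).
* Median NN distance is a proximity summary, not a colocalization or
  clustering analysis; no Ripley/K-function or segmentation is provided.
* Distances between channels include twice the linkage error in
  quadrature; absolute distances should be interpreted with that offset
  in mind.
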