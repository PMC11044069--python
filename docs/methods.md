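# Methods

## Superimposition

Generalized Procrustes analysis centres every configuration, scales it to
unit centroid size and rotates it to the running consensus; the consensus
is the mean of the aligned shapes, renormalised to unit centroid size and
rotationally pinned to its predecessor (the rotational gauge is otherwise
a neutral direction of the iteration and convergence would stall on it).
Iteration stops when the root-mean-square consensus change drops below
1e-8, with a cap of 100 rounds; for realistic interspecific shape
variance this converges in a handful of rounds, while artificial data
with independent random shapes can need several hundred (the cap is a
keyword argument). Reflections are excluded by default — anchors are
chiral — and can be enabled per pairwise fit.

Centroid size is the square root of the summed squared distances of the
points from their centroid. Some workflows describe centroid size without
the square root; the rooted form is the default here because it is
homogeneous of degree one (CS(s·X) = s·CS(X)), which the size variable of
an allometric regression should satisfy, and a `sqrt=False` switch
provides the un-rooted convention for comparability. Log CS then differs
between the two conventions only by a factor of 2, which rescales
allometric slopes but not explained variance or p-values.

Downstream shape variables are the Procrustes coordinates themselves.
At the shape variances relevant here the difference from an explicit
orthogonal tangent-space projection is far below the statistical
resolution of n = 10 species, so the projection is not applied by
default.

## Sliding semilandmarks

Semilandmarks carry no information along the outline, only across it.
Each slider moves along the normalized chord of its (before, after)
neighbours; the displacement minimises either (a) the bending energy of
the thin-plate spline from the current consensus — all sliders of a
specimen solved jointly, since the bending-energy matrix couples them —
or (b) the squared Procrustes distance to the consensus, which decouples
into per-point orthogonal projections. Sliding is unconstrained along the
tangent line (no clamping to the chord segment, matching standard
practice), degenerate tangents (before = after) are skipped with a
warning, and each sliding pass is followed by a full GPA re-fit; up to 5
outer passes run, stopping early when the consensus stabilises.

A consequence worth knowing: bending-energy sliding re-parameterizes the
outline per specimen (it trades tangential position for smoothness), so
even on synthetic data whose spacing carries no noise it introduces
specimen-specific tangential variation and can mildly dilute
phylogenetic-signal statistics computed on slid coordinates. This is a
property of the criterion, not of the implementation; the
Procrustes-distance criterion is gentler and is available as a
configuration key.

## Shape PCA and allometry

PCA is an eigendecomposition of the covariance matrix (denominator
n − 1) of the flattened Procrustes coordinates; at most n − 1 components
are kept. Allometry is a multivariate regression of the shape variables
on log CS: both sides are mean-centred and the slope is fit through the
origin, so the intercept is absorbed by the mean shape; the explained
share is 100 × SS(predicted)/SS(total). Its permutation test shuffles the
log CS values across specimens, 10,000 times by default, with
p = (1 + #{permuted ≥ observed}) / (1 + N) so p is never exactly zero.

Species values are not independent samples, so the same regression is
also run on phylogenetic independent contrasts: Felsenstein's pruning
with branch-length extension v₁v₂/(v₁+v₂), polytomies resolved
arbitrarily with zero-length internal edges (warned). Contrasts have zero
expectation, so the PIC regression is genuinely through the origin with
no centring; its permutation null additionally flips contrast signs,
which are arbitrary. Size correction takes the ordinary-regression
residuals, re-centred on the grand mean so PCA and mapping apply to them
unchanged.

## Phylogenetic signal

Two statistics are computed, as they answer subtly different questions.

**Mapped tree length.** Squared-change parsimony places internal nodes to
minimise Σ edges ‖Δ‖²/(edge length) (weighted, the default — these
estimates coincide with Brownian-motion maximum-likelihood ancestral
states) or the unweighted sum. The optimum is a linear solve on the
weighted graph Laplacian, so for a fixed tree the mapped tree length —
reported, in either mode, as the plain unweighted Σ‖Δ‖² at the optimum,
in squared units of the input space — is a quadratic form in the tip
data; permutation tests precompute that form and are cheap. The test
permutes whole data rows across tips (jointly over dimensions) and is
**lower-tailed**: phylogenetic structure makes the mapped tree shorter
than a random assignment. A null expectation is sometimes stated in the
direction "no signal ⇒ small tree length"; the distributional logic runs
the other way (signal concentrates similar tips on neighbouring nodes and
shortens the mapping), and this implementation follows the standard
lower-tail convention. The pipeline maps the first 2 PC scores for shape
and the 1-D log CS for size, both configurable.

**Multivariate K.** With C the Brownian tip covariance (shared root-to-tip
path lengths) and a = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y the phylogenetic mean,

K = [tr(YᶜᵀYᶜ)/tr(YᶜᵀC⁻¹Yᶜ)] / [(tr C − n/(1ᵀC⁻¹1))/(n − 1)],  Yᶜ = Y − 1a.

K = 1 exactly when tip covariance equals σ²C (and algebraically exactly
on any equal-branch star tree); K < 1 means less, K > 1 more phylogenetic
structuring than Brownian motion. With p = 1 this is Blomberg's K. The
randomization test permutes rows across tips and is upper-tailed; the
full permuted distribution is kept for histogram export. K is computed on
the full shape-variable set by default (it is dimension-agnostic); PC
scores can be supplied instead.

Both tests use the +1 convention p = (1 + #{at least as extreme})/(1 + N);
ties count as extreme, so degenerate all-identical data yield p = 1 for
the tree-length test (every permutation ties at zero). Missing branch
lengths are replaced by unit lengths only on request and with a warning.
All randomness in a pipeline run flows from one seed through
deterministically derived per-test streams, making report JSONs
byte-stable.

## Thin-plate splines

The interpolating 2-D spline uses the kernel U(r) = r² log r with affine
side conditions; bending energy is WᵀKW summed over output dimensions
(zero iff the warp is affine). Jacobians are evaluated analytically from
the spline coefficients (∂U/∂x = (x − xᵢ)(2 log r + 1)), not by finite
differences, so the identity warp yields factors of exactly 1 and uniform
scaling by s exactly s². Deformation grids default to the reference
bounding box padded 10 %, a diverging colour map centred at 1 and clipped
to [0.5, 2]. Grids run consensus → species by default (switchable), and
phylomorphospace figures are always accompanied by node/edge CSVs from
which the plot can be regenerated.

## Synthetic data

The generator emulates the study conditions: 10 species, one
configuration each, 83 points (5 fixed landmarks, 5 semilandmark arcs of
29/20/12/11/6 points placed at equal chords on circular arcs of a
hook-like template), an ultrametric pure-birth tree, and raw coordinates
written after a random rotation/translation/scaling per specimen so that
superimposition has real work to do. Sizes are drawn log-uniformly from
150–600 digitization units, a plausible span for anchor drawings.

Shape deviations live in an explicit deviation basis: free (x, y) motion
of the fixed landmarks plus smooth outline-normal motion of the
semilandmarks (four cosine profiles per arc), orthogonalized against the
template's similarity transforms. Two modelling points are deliberate:
deviations are smooth along the outline because interspecific shape
differences are, and semilandmark deviations are normal to the outline
because along-curve position is, by definition, arbitrary — signal placed
there would be removed by sliding by construction. The Brownian component
(default rate 1e-4 per basis dimension per unit branch length, giving
shape distances of a few percent of centroid size, comparable to
congeneric anchor differences) and an i.i.d. component are rescaled so
their realized variance shares split (1 − noise_fraction) :
noise_fraction. When an allometric fraction is requested, the
non-allometric deviations are first made exactly orthogonal to centred
log CS and a fixed smooth deformation direction is added with the
closed-form scale that makes the regression's explained share equal the
target exactly — so parameter-recovery tests have a sharp truth to
recover.

What the generator does *not* emulate: intraspecific variation and
measurement error (one specimen per species, as in the study design),
digitization jitter in semilandmark spacing, correlated evolution between
anchor classes, or morphologically faithful anchor outlines. Passing
tests therefore demonstrate correctness of the estimators under their
stated models, not robustness to those real-data complications.

## Numerical choices and edge cases

- GPA tolerance 1e-8 (RMS consensus change), 100 rounds; 5 outer sliding
  passes.
- Squared-change parsimony with a zero-length edge under weighted
  reconstruction substitutes 1e-12 with a warning; a singular Brownian
  covariance (duplicate zero-length tips) raises with a suggestion to add
  an epsilon.
- Permutation counts default to 10,000 (tree length, allometry) and 999
  (K); the pipeline refuses fewer than 99.
- TPS `SCALE=` is recorded but applied only on request, because dialects
  disagree on whether coordinates are pre-scaled; y coordinates are used
  as stored, with a `flip_y` option for image-derived data.
- All file indices can be declared 0- or 1-based; internally everything
  is 0-based.

## Limitations

Two-dimensional data only; no resistant-fit superimposition; no
bilateral-symmetry decomposition; PIC is the only phylogenetic correction
for allometry (no full PGLS); no Pagel's λ or Ornstein–Uhlenbeck
alternatives to the Brownian null. The replication harness depends on an
externally supplied chronogram: statistics that involve branch lengths
(mapped tree lengths, K) are only as reproducible as that tree.
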