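# Methods

`benfc` re-implements, as a tested pipeline over synthetic data, a
paired-design resting-state fMRI analysis: voxel-wise brain entropy (BEN)
before and after a treatment course, seed-based functional connectivity
(FC) from the entropy-change region, cluster-level Monte-Carlo corrected
group inference, correlations with clinical change scores, and spatial
association of the resulting t-maps with gene-expression and
neurotransmitter-receptor atlases.

## Fuzzy entropy

For a series $u_1,\dots,u_N$, embedding dimension $m$ (default 2) and
threshold $r$ (default $0.2\,\mathrm{SD}$):

1. form the $N-m$ templates of length $m$ and of length $m+1$ starting at
   the same indices, each with its own mean removed (local baseline
   removal);
2. for every ordered pair $i \ne j$, compute the Chebyshev distance
   $d_{ij}$ and the graded similarity $D_{ij} = \exp(-(d_{ij}/r)^n)$ with
   fuzzy power $n = 2$;
3. with $\phi_m$ and $\phi_{m+1}$ the pairwise means at the two lengths,
   $\mathrm{FuzzyEn} = -\ln(\phi_{m+1}/\phi_m)$.

Self-matches are excluded (they bias $\phi$ toward 1). With SD-scaled $r$
the estimate is invariant under affine rescaling of the signal; a constant
series returns exactly 0 (all similarities are 1). Zero-variance voxels in
`ben_map` are marked NaN and excluded from statistics — the scalar
convention (0) and the map convention (undefined) serve different callers
and are both tested. The optimized kernel (numba-compiled distance fill +
vectorized membership sums) is verified against a literal double-loop
oracle to 1e-10 on mixed AR/sine/noise series.

FuzzyEn behaves in ways that matter for experimental design and that the
synthetic world has to respect:

* it responds to *waveform regularity*, not variance — white noise > AR(1)
  > slow sine, the property the ordering test pins down;
* a sampled sine is only "regular" to a 2-point embedding when there are
  many samples per period: at TR 2.4 s a 0.05 Hz sine (~8 samples/period)
  is already noticeably less regular than a 0.02-0.03 Hz one. The ordering
  test therefore uses a 0.02 Hz sine and the generator plants 0.03 Hz;
* adding a tone to an already *tonal* background raises rather than lowers
  m=2 entropy (a 4-tone mixture is high-dimensional to a 2-point
  embedding). Slow nuisance components in the generator are band-limited
  noise, not sinusoids, for exactly this reason.

## Preprocessing

Fixed order, recorded in the manifest: discard the first 10 volumes →
Gaussian smoothing (8 mm FWHM, per-axis sigma in mm) → zero-phase
Butterworth band-pass (order 2 per pass, 0.01-0.1 Hz) → nuisance
regression (intercept always; Friston-24 motion expansion by default, plus
global/WM/CSF mean signals when masks are supplied) → motion scrubbing.
Framewise displacement follows the Power formulation with a 50 mm head
radius; volumes with FD > 0.2 mm (a per-volume reading of the threshold;
per-subject mean FD goes to the manifest) are replaced by per-voxel cubic
splines through the unflagged time points and re-enter later estimation.
Sessions with > 50% flagged volumes are rejected. Rank-deficient confound
columns are dropped and reported rather than fatal.

**Confound dimensionality at demo scale.** A band-passed series of $T$
volumes holds roughly $2(f_{hi}-f_{lo})\,T\,\mathrm{TR}$ effective degrees
of freedom — about 40 for the 130-volume demo series. Regressing 24 motion
expansion columns there removes ~25/90 of the energy of *any* in-band
signal and, worse, replaces part of a deterministic waveform with
broadband distortion, which fuzzy entropy punishes severely (verified
during development: Friston-24 at T=90 annihilates a planted oscillation
that survives the basic-6 model intact). The demo/recovery configuration
(`demo_preproc_config`) therefore uses the basic 6-parameter motion model;
Friston-24 remains the default for full-length runs.

## Group inference

Paired and two-sample t-maps use the closed forms (df $n-1$ and
$n_a+n_b-2$), two-tailed throughout; voxels undefined in any subject or
with zero difference variance stay undefined. Cluster correction is
AlphaSim-style: per-axis smoothness of the standardized group residuals by
the first-difference (Forman) estimator with
$\sigma_k = \sqrt{-1/(4\ln\rho)}$ voxels (floored at one voxel width),
then `n_sim` Gaussian fields smoothed to that FWHM on the analysis mask,
re-standardized, thresholded two-tailed at the cluster-forming p (0.001),
sign-split, 26-connected; the minimum significant extent is the
$(1-\alpha)$ order statistic of the null maximum cluster size plus one.
Family-wise error of the whole chain is checked empirically on null
cohorts (≤ 0.08 at nominal 0.05 over 100 runs).

Scalar tests: BH-FDR via statsmodels; Lilliefors normality via
statsmodels' table-interpolated p (null calibration tested); Mann-Whitney
U exact by enumeration for $n_a+n_b \le 12$ without ties, tie-corrected
normal approximation otherwise; clinical change / percent-change
correlations are Pearson r with BH-FDR over the family of
(measure, clinical) pairs, dropping zero-baseline subjects from percent
change with a warning.

## Connectivity and molecular association

The seed signal is the unweighted mean over the seed mask (in the full
pipeline: the union of significant negative entropy clusters); per-voxel
Pearson r is Fisher-z transformed with |r| clipped at 1-1e-7 (finite
self-seed voxels), raw-r mode available. Parcel profiles are unweighted
means of defined voxels (NaN for empty parcels); per-gene spatial Pearson
correlations carry BH-FDR q values, and the selected set is |r| ≥ 0.15
with q < 0.05 (boundary inclusive). Hub genes have degree strictly above
mean + 1 population SD on the confidence-filtered (≥ 0.9) undirected
graph. Receptor association is Spearman rho between the paired t-map and
each receptor map, parcel-level when an atlas is given, voxel-level
otherwise.

**Permutation null.** "Randomly dividing the mixed pre/post maps into two
groups" is implemented as within-subject label exchange: each draw
independently flips which of a subject's two maps counts as post, which
negates that subject's difference and keeps the pairing the subsequent
paired t-test needs (a pairing-breaking shuffle would make that test
ill-defined). Because $\sum d_i^2$ is sign-invariant, all B permuted
t-maps are closed forms of a sign matrix times the difference matrix,
which is what makes B = 5000 cheap. $p_{raw} = (1 + \#\{|\rho_{null}| \ge
|\rho_{obs}|\})/(B+1)$; Bonferroni multiplies by the number of maps
actually tested. No spatial-autocorrelation-preserving (spin) null is
implemented; the permutation exchanges labels, not space, so a smooth map
pair can still show inflated |rho| relative to a spin null — a known
limitation.

## Synthetic world

`SynthConfig` defaults state the emulated study: 46 subjects, paired
pre/post sessions, 217 volumes at TR 2.4 s, 3 mm voxels; the grid
(20x24x20, ellipsoidal mask) is ~10x smaller than an MNI bounding box for
desk-scale runtime, and the demo recovery configuration uses 20 subjects
and 140 volumes. Per subject: spatially independent AR(1) voxel noise
(phi 0.3), three spatially smooth slow components with band-limited-noise
time courses shared across the subject's two sessions (amplitude 5% of
noise SD), and a spatially uniform global fluctuation (10% of noise SD) —
present so that global-signal regression has its intended target and does
not latch onto focal effects. Motion tables are white positional jitter
(0.02 mm) with 0.5 mm one-volume spikes at rate 0.05; slow drift is
deliberately absent (see confound note above). HAMD drops by 15 ± 3 and
MMSE by 1 ± 1 after treatment, clipped to their scales.

Planted effects, post sessions only:

* **entropy decrease** — inside a compact box ROI the signal becomes
  $\sqrt{1-g}\,x + \sqrt{g}\,\sigma\,\mathrm{osc}(t)$ with a common 0.03 Hz
  oscillation and $g$ = `regularity_gain` = 0.3, i.e. the weight is the
  fraction of variance carried by the oscillation and total variance is
  unchanged. The oscillation is coherent across the ROI while voxel noise
  is independent, so 8 mm smoothing *concentrates* the planted regularity
  the way coherent physiology survives smoothing in real data;
* **coupling increase** — one shared band-limited latent signal added to
  the disjoint seed and target ROIs with amplitude
  $\sqrt{\Delta r/(1-\Delta r)}\,\sigma$, raising their correlation by
  ~`delta_r` = 0.3;
* **molecular plantings** — expression columns are
  $\rho z_{ref} + \sqrt{1-\rho^2}\,\varepsilon$ against the standardized
  reference profile (expected Pearson r = rho); receptor maps use the same
  mixture on normal scores with the Gaussian-copula correction
  $\rho_P = 2\sin(\pi\rho_S/6)$ so the *Spearman* correlation hits the
  target, with an exact monotone transform at |rho| = 1.

Effect sizes (0.3/0.3) are stated choices — the emulated study reports
none. What a green recovery test establishes: the implemented chain
detects a coherent planted effect of this size on this grid with correct
localization and calibrated false positives. What it does not establish:
performance on real BOLD (no hemodynamics, physiological noise spectra,
scanner drift or spatial inhomogeneity), nor anything about the original
study's specific regions or genes.

## Numerical conventions

0-based voxel indexing, RAS+ affines, NaN as the undefined marker
everywhere; grid equality (dims + affine) is enforced before any
cross-object computation. All stochastic operations take explicit seeds
and are bit-reproducible; the pipeline spawns per-stage seeds from one
global seed. Fisher z is clipped, not special-cased; Spearman uses
average ranks; ties in region rankings break toward the lower parcel id;
cluster connectivity defaults to 26 (6/18/26 exposed).

## Known limitations

* The Monte-Carlo cluster null simulates *Gaussian* fields at the
  estimated smoothness; heavy-tailed t-fields at very small n are handled
  only through the t-quantile forming threshold.
* Scrub-interpolated volumes re-enter entropy/FC estimation (interpolation
  would otherwise be pointless); censoring variants are not implemented.
* The expression pipeline consumes a ready parcels-by-genes table; donor
  aggregation, probe selection and normalization of microarray data are
  out of scope.
* Receptor association has no spin-test null (hook provided).
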