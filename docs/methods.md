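# Methods

## The metrics

Given region-averaged signals $x_i(t)$, $t = 1 \dots T$, for $N$ regions:

**LOFC** (low-order functional connectivity) is the Pearson correlation of
two regions' full-length signals,

$$\mathrm{LOFC}_{ij} = \frac{\sum_t (x_i(t) - \bar x_i)(x_j(t) - \bar x_j)}
{\sqrt{\sum_t (x_i(t) - \bar x_i)^2}\sqrt{\sum_t (x_j(t) - \bar x_j)^2}},$$

an $N \times N$ symmetric matrix with unit diagonal.

**tHOFC** (topographical-profile high-order FC) correlates two regions'
*connectivity profiles* rather than their signals. All LOFC values are
Fisher z-transformed, and for a pair $(i, j)$ the profiles
$\{z_{ik}\}_{k \ne i,j}$ and $\{z_{jk}\}_{k \ne i,j}$ — length $N-2$, both
self-connections of the pair excluded from both profiles so the vectors
stay aligned — are Pearson-correlated. The result is symmetric in $(i, j)$.

**aHOFC** (associated HOFC) correlates region $i$'s tHOFC profile with
region $j$'s LOFC profile over the same $k \ne i, j$, after Fisher
z-transforming *both* profiles (the tHOFC values are re-transformed even
though they are themselves correlations of z-scores; this follows the
definition of the metric, and is stated here explicitly because the
alternative — using raw tHOFC — is defensible but different). aHOFC is a
cross-level association, so $\mathrm{aHOFC}_{ij} \ne \mathrm{aHOFC}_{ji}$
in general; the matrix is *not* symmetrized, and the diagonal
(self-association) is set to zero so the matrix is comparable to LOFC and
tHOFC summaries.

**dLOFC / dHOFC.** With window length $\omega$ and step 1 there are
$W = T - \omega + 1$ windows; $\mathrm{dLOFC}_{il}(\tau)$ is the Pearson
correlation of $x_i$ and $x_l$ restricted to $[\tau, \tau + \omega - 1]$.
The dHOFC between region pairs $(i,l)$ and $(j,k)$ is the Pearson
correlation of the two dLOFC series over $\tau$. Treating each region pair
as a *hypernode*, the $P \times P$ dHOFC matrix over $P = n(n-1)/2$
hypernodes is a hyper-network with $P(P-1)/2$ unique hyperlinks. Hypernode
pairs sharing one region are legitimate hyperlinks (their shared region is
itself an interesting common driver); only the self-hyperlink is excluded
from summaries.

When exactly two networks are declared, hyperlinks are typed by the
network membership of the four regions: *within-network* (both hypernodes
intra-network, same network), *between-network* (both intra-network,
different networks), *modulatory case 1* (both hypernodes span the two
networks) and *modulatory case 2* (exactly one does). For two-system
analyses the hypernodes are ordered intra-net1, intra-net2, then
inter-network, so matrices display the canonical block layout.

**ICC.** Per-connection test-retest reliability uses the one-way
random-effects intra-class correlation across $S$ subjects and $k$
sessions:

$$\mathrm{ICC} = \frac{MS_b - MS_w}{MS_b + (k-1)\,MS_w},$$

with $MS_b$/$MS_w$ the between-/within-subject mean squares. Negative
estimates are clamped to zero. Categories: poor $[0, 0.2)$, fair
$[0.2, 0.4)$, moderate $[0.4, 0.6)$, good $[0.6, 0.8)$, excellent
$[0.8, 1]$; bins are left-closed (0.2 is "fair", 0.8 is "excellent",
consistent with "excellent > 0.8" phrasing for the top bin).

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| window length $\omega$ | 30 | timepoints (60 s at TR = 2 s) | main-analysis value; sweep {20, 30, 40, 50} available |
| window step | 1 | timepoints | maximally overlapping windows |
| strong-dHOFC threshold | 0.36 | correlation | dynamic correlations below this are plausibly sampling noise (Leonardi & Van De Ville's bound); applied to the **group-mean** matrix with a **strict** inequality (both choices configurable) |
| Fisher-z clamp | $1 - 10^{-7}$ | correlation | keeps $\operatorname{arctanh}$ finite at perfect correlations without moving moderate values |
| ICC scale | raw correlations | — | the estimator is fed correlation values directly; callers can z-transform first if preferred |

Thresholding uses the group-mean rather than per-subject matrices because
the threshold is a noise floor for the *population* connectivity strength;
strict (">") rather than inclusive comparison is arbitrary at a set of
measure zero and is exposed as an argument.

## The synthetic-data generator

The generator emulates a test-retest resting-state study: defaults are 25
subjects × 7 sessions × 295 timepoints at TR = 2 s (a 10-minute scan with
5 initial volumes dropped). Its model:

1. a unit-diagonal **group correlation matrix** with `within_network_r`
   (default 0.5) inside network blocks and `between_network_r` (default
   0.1) across blocks — the modular structure typical of resting-state
   connectivity;
2. **subject effects**: each subject perturbs the Fisher-z of every
   off-diagonal entry by $N(0, \text{subject\_sd}^2)$, default sd 0.15;
3. **session effects**: each session adds $N(0, \text{session\_sd}^2)$,
   default sd 0.10;
4. back-transform to correlations, repair to positive-definite if needed
   (eigenvalue flooring at $10^{-6}$, renormalised to unit diagonal,
   logged with the Frobenius norm of the change), and draw $T$ i.i.d.
   multivariate-Gaussian samples;
5. optional **modulators**: latent signals that add
   $\pm\text{amplitude}$ (on the z scale) to the covariance of listed
   region pairs through time. The default signal is a two-state Markov
   switching process with geometric dwell (mean 20 timepoints), matching
   the state-switching picture of dynamic connectivity; a sinusoid is
   available for analytic checks. Sampling is segment-wise over runs of
   constant state. Each subject's modulator amplitude is jittered by
   $N(0, 0.1^2)$ — a stable individual trait, without which dHOFC would
   have no between-subject variance and hence no reliability to measure.

Perturbing on the z scale keeps correlations in $(-1, 1)$ without
truncation artifacts. The default subject/session scales imply a
theoretical LOFC ICC of ≈ 0.63 (see below), i.e. fair-to-good reliability,
which is the regime reported for resting-state connectivity.

**Seeding.** A single seed expands through `numpy.random.SeedSequence`
spawning: the root spawns one stream per subject; each subject stream
spawns one stream for subject-level draws plus one per session. Any subset
of the design is therefore reproducible on its own, and all outputs are
pure functions of (config, seed).

**Expected reliability.** On the z scale the measured connectivity is
subject effect + session effect + estimation noise, and the Fisher-z of a
Pearson correlation at $T$ samples has variance ≈ $1/(T-3)$, so

$$\mathrm{ICC}_\text{expected} =
\frac{\sigma_b^2}{\sigma_b^2 + \sigma_w^2 + 1/(T-3)}.$$

This is an approximation: it ignores the small bias of the correlation
estimator and any PD-repair shrinkage. With many regions and sizeable
perturbations the repair becomes frequent and adds distortion that biases
estimated ICC slightly below this expectation; the estimator-recovery
checks therefore use independent 2-region draws (a 2×2 correlation matrix
is always positive-definite), while the full-matrix round-trip is held to
a looser 0.1 mean-absolute-deviation band.

**What the generator does not model:** hemodynamic response convolution
and temporal autocorrelation, physiological noise, head motion, spatial
smoothness. Passing tests therefore demonstrate correctness of the
estimators and the qualitative mechanics (noise floors, window-length
trade-offs, variance decomposition) — not performance on real scans,
where autocorrelated signals reduce effective sample size and motion adds
structured artifacts.

## Numerical choices

- Profile correlations (tHOFC/aHOFC) are computed per pair with explicit
  exclusion masks and two-pass centering; this is $O(N^3)$ but agrees
  with a literal sum-of-products evaluation to ~1e-15 and takes ≈ 1.5 s
  at $N = 264$. A faster corrected-running-sums variant was rejected
  because cancellation near degenerate profiles cost several digits.
- Windowed correlations use cumulative sums over all pairs at once,
  $O(TN^2)$; window variances are floored at zero against rounding.
- $N \ge 5$ is required for tHOFC/aHOFC: at $N = 4$ every length-2
  profile correlation degenerates to $\pm 1$ and the z-transformed
  profiles become constant.
- Zero-variance regions/windows produce NaN (with a logged warning),
  never silent drops; NaN propagates to every derived pair.
- ICC with numerically-zero total variance (relative to the data scale)
  is NaN ("undefined"), not 1: grand-mean rounding can otherwise leave
  $MS_b \sim 10^{-30} > MS_w = 0$ on a constant table.
- Subject rows containing NaN are dropped per connection; fewer than 2
  complete rows gives NaN.
- Ties in top-$n$ link selection break by stable index order; an all-tied
  Mann-Whitney comparison reports $p = 1$ directly rather than the
  0/0 normal approximation.

## Problem sizes used in the shipped checks

Estimator-recovery runs use 500 independent connections at 25 subjects ×
7 sessions × 295 timepoints; the dHOFC modulator-recovery experiment uses
8 regions, 6 subjects × 3 sessions; the window-length sweep uses 24
regions (three 4-pair modulators), 16 subjects × 6 sessions, repeated 3
times. These sizes give Monte-Carlo error comfortably below the margins
being asserted while each run stays in the tens of seconds.

## Known limitations

- Whole-brain (264-region) dHOFC is combinatorially excluded (34,716
  hypernodes → ~6·10⁸ hyperlinks); analyses restrict to subsystem ROI
  sets, as intended.
- The asymmetric aHOFC matrix is reported as-is; directed-network
  analysis of it is out of scope.
- No multiple-testing correction is applied to ICC maps — they are
  descriptive estimates, not hypothesis tests.
- ICC here is the one-way model only; two-way ICC(2,1)/ICC(3,1) variants
  and bootstrap confidence intervals are not provided.
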