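# Methods

## Model

The encoder is a restricted Boltzmann machine: binary visible units `v`
(the stimulus) and binary hidden units `h` (the codeword), coupled only
across layers.  The joint energy is

    E(h, v) = -β (Bvᵀv + Bhᵀh + hᵀWv),     P(h, v) ∝ exp(-E),

with `W` of shape `(n_hidden, n_visible)` and the additive constant
fixed to zero.  The inverse temperature β multiplies the whole energy;
`scale_temperature` folds β into the parameters (W, Bh, Bv scaled, β
reset to 1) so downstream code never double-scales.  Internally all
energies and entropies are computed in nats; conversion to bits (÷ ln 2)
happens only at reporting boundaries (tables, profiles).

The bipartite structure makes both conditionals factorial:
`P(hᵢ=1|v) = σ(β(Wv + Bh)ᵢ)` and symmetrically for the visible layer.
Three consequences are used throughout:

* the stimulus-conditioned entropy has the closed form
  `H_{h|v} = Σᵢ g(aᵢ) - aᵢσ(aᵢ)`, `a = β(Wv + Bh)`, `g(x) = log(1+eˣ)`,
  equal to a sum of per-unit binary entropies;
* the hidden-marginal ("codeword") energy and visible free energy are
  single softplus sums, each exact up to one additive constant shared by
  all patterns of that layer;
* sampling from `Q(h|v)` needs no chain: iid Bernoulli draws from the
  unit activations, so the expected codeword energy `⟨E_h⟩_{h|v}` is a
  plain Monte-Carlo average with a standard error that is tracked.

The free-energy identity `E_v = ⟨E(h,v)⟩_{h|v} - H_{h|v}` holds exactly
for every model and every stimulus; the suite enforces it to 1e-8 nats
on enumerable models, as the central regression test.

## Training

One-step contrastive divergence (CD1).  The positive phase uses
data-clamped hidden probabilities; the negative phase takes one full
sampled Gibbs step from the data (sample h, sample v', recompute hidden
probabilities).  The learning rate steps through
0.2, 0.1, 0.05, 0.01, 5e-3, 1e-3 with a fixed number of epochs per
stage (default 8) and minibatch size (default 4).  Where a convention
had to be fixed: weights initialize iid N(0, 0.01²), biases at zero; no
momentum or weight decay; hidden layer updates before visible within a
Gibbs step.  Training is exactly reproducible from its seed.

Enumerated negative log-likelihood on tiny models is checked to be
non-increasing across schedule stages, and a model retrained on data
from a known ground-truth model recovers the visible distribution to
< 0.1 nats KL.

## Synthetic stimuli

*Ising lattices.*  L×L torus, ferromagnetic coupling J = 1, k_B = 1,
periodic boundaries.  Two samplers target the same Boltzmann
distribution: Swendsen-Wang (one step = full bond percolation with
p = 1 - exp(-2/T) + cluster flip) and Metropolis (one sweep = L² random
single-site proposals).  Both are numba kernels seeded explicitly.
Validation: total-variation distance < 0.02 to the enumerated 3×3
distribution; 10×10 mean |magnetization| at T = 2.0 within 0.05 of the
Onsager value (1 - sinh⁻⁴(2/T))^{1/8} = 0.911; SW and Metropolis agree
on 4×4 moments within 3 standard errors at T ∈ {1.5, T_c, 4.0}.

*Textures.*  A stand-in for median-binarized grayscale natural images:
white Gaussian noise smoothed by an isotropic Gaussian kernel whose
standard deviation is the stated correlation length (0 = iid bits),
thresholded at each image's own median, so half the pixels are set (up
to a single-pixel tie correction at odd counts).  These fields are
homogeneous and have a single tunable correlation scale; they do not
reproduce the occlusions, edges or scale-free statistics of real
natural images, so results on them probe dependence on input
correlations, not natural-scene statistics.

*Patches.*  Circular masks are integer-offset disks; radii 2, 2.5 and
3.5 give the standard 13-, 21- and 37-pixel stimuli.  Offsets are
ordered row-major (a fixed public convention); centers are uniform,
wrapping on lattices (consistent with their periodic boundaries) and
restricted to the interior on images.  The empirical patch-pattern
distribution from sampled 3×3 lattices matches the enumerated marginal
to TV < 0.02.

## Stimulus-energy axis and normalization

Per-stimulus tables report both stimulus-energy estimates: the
empirical energy `-log2(frequency)` and the model's visible free energy
(anchored at its minimum over observed stimuli).  The energy-entropy
profile bins stimuli by the **free-energy axis by default**.  Reason:
the empirical estimate is truncated at log2(n) for a sample of n
patterns, so every stimulus rarer than 1/n is recorded at the
truncation value; at the sample sizes used here this visibly distorts
the rare-stimulus bins, while the free energy is defined for
arbitrarily rare stimuli and coincides with the empirical energy for
well-fit models (by the free-energy identity).  The empirical axis
remains available (`ev_source="empirical"`).

Codeword energies are re-anchored so the most probable codeword sits at
zero: the anchor is the energy of the most frequent pattern in a
reference Gibbs sample (or the exact minimum when the hidden layer is
enumerable).  Slopes are anchor-invariant.  `I_enc`, the
frequency-weighted mean of `⟨E_h⟩_{h|v} - H_{h|v}`, is reported on this
anchored scale; it equals the mean KL divergence between conditional
and marginal codeword distributions only up to the anchoring constant,
and can therefore be negative as reported.  The KL identity including
the explicit constant is tested exactly on enumerable models.

## Profiles, slopes, Zipf

Distinct observed stimuli are grouped into equal-width stimulus-energy
bins (right edge inclusive in the last bin; default 14 bins for
exploratory work, 10 in the headline analysis).  Bin means weight
stimuli by empirical frequency (an unweighted option exists).  Three
ordinary-least-squares slopes are fit on nonempty bin means: evoked
entropy vs stimulus energy (negative = variability suppression),
codeword energy vs stimulus energy, and codeword energy vs evoked
entropy — the criticality diagnostic, 1 being the Zipf point.  With
fewer than two nonempty bins the slopes are reported missing.

Rank-frequency tables sort codeword patterns by descending frequency;
the log2-log2 slope is fit over ranks with count ≥ 5 (excluding the
sampling tail) and requires ≥ 10 distinct patterns.

`slope_vs_model_size` flags two onsets over a family of hidden sizes:
the smallest size whose entropy slope is negative, and the smallest
whose energy-vs-entropy slope is within a tolerance band (default
±0.15) of 1.

## Fisher information

The energy is linear in the parameters, so the FIM equals the
covariance of the sufficient statistics t(h,v) = [vec(hvᵀ), v, h] under
the joint model distribution (parameter ordering: weights row-major,
then visible biases, then hidden biases — a fixed public convention).
All six moment blocks reduce to first/second moments of unit
activities; since the statistics are binary, the diagonal is p(1-p).
The estimator accumulates moments in float64 chunks; an exact
enumerated version backs it on small models (element-wise agreement
0.01 at 5e5 samples) and a finite-difference check confirms
KL(φ ‖ φ+εw) = ½ε²wᵀFw within 5%.

Sensitivity uses the square-root convention throughout:
`S(w) = sqrt(wᵀFw)`, so a unit eigenvector scores √λ and the k-th
coordinate direction scores √F_kk.  Unit importance aggregates the FIM
diagonal per hidden unit as the RMS of its diagonal sensitivities over
its bias and incident weights; ties break by unit index.  Note the
aggregate is largest for units in the fluctuation-dominated regime:
very strongly coupled (frozen) units have small activity variance and
hence low FIM sensitivity.

The temperature sweep evaluates, at each β on a strictly increasing
grid (≥ 3 points), the FIM of the β-scaled model with respect to its
own scaled parameters, from fresh Gibbs samples at that β — a
susceptibility curve over a model family, not a reparameterization.
Eigenvalues below 1e-5 are truncated in reported spectra.  An interior
peak of the largest eigenvalue at β = 1 indicates a trained model
sitting at its own critical temperature.

## Problem sizes

The package's analyses run at deliberately moderate scale, chosen as
the smallest sizes at which each phenomenon is stable across seeds:
20,000 lattice samples (Swendsen-Wang, 1000 sweeps burn-in, thinning
100) and 20,000 13-pixel patches; CD1 at 2 epochs per stage with
minibatch 32 for the headline 60-hidden model (the full 8-epoch,
minibatch-4 schedule remains the default for converged fits); 10,000
conditional samples per stimulus for codeword energies; 15,000-100,000
Gibbs samples per β for FIM estimation; hidden-size families
{5, 10, 20, 35, 60} at lattice temperatures 2.5 and 3.5 trained at 6
epochs per stage, minibatch 8.  The measured headline slope is stable
to ±0.01 across seeds at these sizes.

## Numerical policy

Softplus is evaluated as logaddexp(0, x) (exact and overflow-safe to
|x| ≈ 700); conditional entropies are finite and exact at saturated
activations.  Degenerate cases are defined explicitly: constant hidden
units contribute zero Pearson correlation; a constant energy range
yields a single bin; under-determined slope fits return NaN rather than
raising.  Gibbs chains start from iid fair bits with default burn-in
1000 block steps.  All stochastic operations take an explicit integer
seed and are bitwise reproducible given it; pipeline stages derive
their seeds from a master seed via SeedSequence.

## Known limitations

* Empirical fit-quality KL between two finite samples carries a
  positive support-mismatch bias (pseudocount smoothing over the union
  support); comparisons are meaningful across model sizes at fixed
  sample counts, not as absolute divergences.
* The texture generator emulates tunable spatial correlation only; no
  claim is made about natural-image statistics.
* Exact enumeration caps at 24 total units (oracle only); FIM
  estimation beyond that is Monte-Carlo with the stated sample sizes.
* CD1 is a biased maximum-likelihood surrogate; "convergence" here
  means the measured distributional agreement on enumerable models, not
  exact likelihood maximization.
* Training depth moves where the criticality onset sits in model size;
  the onset flags are tolerance-parameterized and should be compared
  only within a fixed training protocol.
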