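# Methods

## Model and procedure

The pipeline treats a DNA sequence as a discrete signal and summarizes its
local frequency content in a fixed-dimensional vector.

**Encoding.** The purine/pyrimidine (PP) map sends A, G → −1 and T, C → +1.
N positions are deleted before framing, so all window coordinates refer to
the N-reduced signal (0-based, half-open). Lowercase is accepted; any other
character raises. Alternative single-track encoders (`real`, `integer`,
`eiip`) sit behind the same interface but PP is the default and the only
encoder the shipped presets use.

**Framing and spectra.** Windows start at 0, winshift, 2·winshift, … while
the full window fits; a signal shorter than the window yields one
whole-signal frame rather than being discarded, preserving small-input
usability. Each frame is zero-padded to the FFT order — the smallest power
of two at or above the window length (351 → 512, 63 → 64) — and reduced to
the magnitudes of bins 0 … order/2 − 1. The DC bin is kept (PP signals of
biased base composition carry information there); the bin at π is dropped.
Magnitudes are invariant to negating the signal, so swapping the purine and
pyrimidine codes changes nothing downstream.

**UBM-GMM.** A diagonal-covariance Gaussian mixture with K components is
fitted by EM on the pooled window spectra of the training fold. Numerical
choices: k-means++ seeding, 3 restarts keeping the best final
log-likelihood; convergence when the relative log-likelihood gain drops
below `tol` (default 1e−6) or after `max_iter` (100) iterations; variances
floored at 1e−4 × the per-dimension global variance; a component whose
total responsibility collapses is reseeded from a random data point and
logged. The per-iteration log-likelihood trace is stored on the model and
is non-decreasing up to floating-point noise (the EM guarantee; variance
flooring is applied symmetrically so it does not break monotonicity in
practice). Fitting is deterministic given the seed.

**MAP adaptation.** Only the means are adapted: with responsibilities
P(k|x_t), n_k = Σ_t P(k|x_t), E_k the responsibility-weighted frame mean and
α_k = n_k/(n_k + r), the adapted mean is α_k E_k + (1 − α_k) μ_k. Every
adapted coordinate therefore lies between the prior mean and the data mean.
A component with n_k = 0 keeps its prior mean (α = 0 by the convention
0/(0 + r)). The relevance factor defaults to r = 16, the conventional value
in the adapted-mixture literature this construction comes from; it is
exposed in the run configuration. Weights and variances are never adapted —
the supervector is the concatenation of the K adapted means, giving K·D
dimensions (1280 for the default 5 × 256).

**Evaluation protocol.** Stratified 4-fold cross-validation; the UBM, the
baseline's median target length and the feature scaler are all fitted on
the three training folds only, so the representation never sees test
sequences. Features are standardized per fold (training mean/σ) before the
classifier; an off-switch exists. The six classifiers map onto scikit-learn
as: 1-nearest-neighbour (Euclidean); random-subspace ensembles of 30
learners on feature subsets of half size (for the subspace k-NN and
subspace discriminant); linear discriminant with lsqr solver and automatic
(Ledoit–Wolf) shrinkage; SVMs with linear and inhomogeneous degree-2
polynomial kernels, C = 1, one-vs-one. The original study names MATLAB
learners without printing their settings, so this mapping is a documented,
configurable stand-in. Metrics are macro-averaged one-vs-rest rates;
precision of a never-predicted class is defined as 0 and flagged. Chance
accuracy is 100·Σ p_i², the expected accuracy of a guesser matching the
class proportions.

**Baseline.** Whole-sequence features for comparison: signals are truncated
to, or anti-symmetrically padded (append −x[L−1], −x[L−2], …, repeating the
reflection of the growing signal as needed) to, the median training length
(lower median on ties, computed on training folds only to avoid
test-length leakage); one magnitude spectrum is taken at the next
power-of-two order; each sequence is represented by its Pearson-correlation
distances d = (1 − r)/2 to all training sequences. The anti-symmetric
reflection convention is a documented choice; the distance form maps
correlation onto [0, 1].

**Region analysis.** Windows are assigned to annotated intervals by maximum
base overlap (ties to the leftmost region, logged; zero overlap →
unassigned). Per sequence and region, the K-dim window posteriors under the
training-fold UBM are averaged into one simplex feature. Averaged
posteriors are used instead of per-region supervectors because single
regions contain too few windows for a stable adaptation. Sequences lacking
a region are excluded from that region's classification run and counted in
the output table. Region tables are read as 0-based half-open TSV; a flag
converts 1-based inclusive exports.

## Synthetic data generator

Classes differ by a short motif embedded as tandem repeats over an i.i.d.
uniform {A,C,G,T} background; a motif of length p gives a period-p ±1
signal inside repeat runs and hence a known spectral peak near bin
order/p. Motif-repeat construction was chosen over Markov backgrounds
precisely because the expected peaks are closed-form. The reference
two-class recipe uses motifs `ATT` (period 3) vs `AAATTTT` (period 7),
60 sequences per class, lengths uniform on 800–2500 nt to exercise
variable-length handling, motif density 0.3 (repeat runs of 5–15 copies
scattered uniformly along the sequence), seed 7. The region-localized
recipe declares six fixed intervals mimicking the 16S V2–V7 layout and
fills only V3 with the class motif, 40 sequences per class, lengths
800–1000.

What the generator does **not** emulate: real nucleotide composition,
phylogenetic correlation between sequences, indel/length structure tied to
taxonomy, or sequencing noise. Passing tests therefore demonstrate that the
pipeline recovers planted periodic structure and ranks the informative
region correctly — not field performance on real taxonomic data.

Two empirical properties of these fixtures are worth recording. First, the
whole-sequence baseline is essentially perfect on the global-motif fixture:
at 30% motif coverage the whole-sequence spectrum carries large
class-specific peaks, and truncation to the median length removes too
little of them to hurt, so the supervector pipeline (≈96%) does not beat
the baseline (100%) here even though both are far above chance — on this
kind of fixture the baseline's known failure modes (information loss for
long sequences, feature dimension growing with the training set) are not
stressed enough to show an accuracy gap. Second, on the region-localized
fixture the whole-sequence supervector (≈74%) scores *below* the best
single region, because the 100 nt of signal is diluted across ~100 windows
of background during adaptation, while the per-region average posterior
isolates it.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| winlen / winshift | 351 / 99 nt (preset `16s`: 63 / 9) | window length and hop on the N-reduced signal |
| fft_order | 512 (preset `16s`: 64) | power-of-two DFT length; spectra have order/2 dims |
| K | 5 | mixture components in the UBM |
| relevance_r | 16 | MAP interpolation: α_k = n_k/(n_k+16) |
| folds | 4 | stratified cross-validation folds |
| tol / max_iter / n_init | 1e−6 / 100 / 3 | EM stopping and restarts |
| variance floor | 1e−4 × global per-dim variance | lower bound on mixture variances |

## Problem sizes used in the shipped checks

The automated checks run the full pipeline at the short-window preset
(63/9/64, K = 5) on the 120-sequence two-class fixture (~15–16 k training
windows per fold, 32-dim spectra, 160-dim supervectors) and the 80-sequence
region fixture; mixture-recovery checks use 2000 simulated 4-dim Gaussian
frames. These sizes make every property cheap to recompute while keeping
all estimation problems well-conditioned.

## Known limitations

- Diagonal covariances only; no weight or variance adaptation, no
  i-vector/PLDA back-ends.
- No quality trimming, reverse-complement canonicalization or alignment;
  region coordinates are consumed as input, not detected.
- EM restarts select by log-likelihood, which on multimodal window-spectrum
  data occasionally prefers a solution whose supervectors generalize
  slightly worse (visible as fold-to-fold accuracy variance).
- Classifier settings approximate the original study's unpublished ones.
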