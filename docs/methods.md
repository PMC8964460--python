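# Methods

## Input model

A protein is represented by its PSSM: an L × 20 matrix of log-odds scores
in the fixed PSI-BLAST column order `A R N D C Q E G H I L K M F P S T W Y
V`, one row per sequence position. The parser reads the first (log-odds)
block of the PSI-BLAST `-out_ascii_pssm` dialect and ignores the
weighted-percentage block and trailing statistics; scores are used raw
(integer log-odds), since the only normalisation the features require — the
per-row standardisation below — is scale-invariant per row. Users
generating their own profiles should follow the usual protocol for membrane
proteins: 3 PSI-BLAST iterations, E-value 0.001, against a large
non-redundant database. Positions are 1-based in files, 0-based in memory.

## Feature descriptors

All five descriptors have length independent of L, so proteins of any
length ≥ 16 map to the same 1730-dimensional space. Defaults, and the
reasoning where the construction admitted choices:

* **Pse-PSSM** (`pse_lag` λ = 1, 20·(1+λ) = 40 dims). Rows are
  standardised with the *population* (divide-by-20) standard deviation;
  rows with zero spread map to zeros rather than NaN. The lag terms follow
  the established pseudo-PSSM convention: per column j and lag ξ,
  `(1/(L−ξ)) Σ (f(i,j) − f(i+ξ,j))²`.
* **AvBlock** (400 dims). Block boundaries at `floor(i·L/20 + 0.5)` so
  block sizes differ by at most one row; blocks that are empty when L < 20
  contribute zeros. Computed on the raw scores — averaging is the point of
  the descriptor, and standardising first would discard row magnitude.
* **DWT** (`wavelet_name` db4, `dwt_levels` 4, 640 dims). The literature on
  wavelet PSSM descriptors does not fix a wavelet; Daubechies-4 is the
  common default and Haar is used in tests because its filters make oracles
  hand-checkable. Statistics (mean, sd, max, min) are taken over *both* the
  detail and the approximation band at every level — the four-stage filter
  bank exposes both paths, and the superset reading is configurable down.
  Signals shorter than 2⁴ are reflect-padded to 16; the cascade itself uses
  symmetric (half-sample) boundary extension, which a test verifies
  coefficient-by-coefficient against the direct
  `y[n] = Σ_k x[k]·g[2n−k]` convolve-and-downsample form.
* **DCT** (`dct_keep_rows` × `dct_keep_cols` = 20 × 20 = 400 dims).
  Orthonormal 2-D DCT-II; energy concentrates in the top-left block, and
  20 × 20 keeps the per-descriptor budget comparable to AvBlock. Profiles
  shorter than 20 rows are zero-padded in coefficient space.
* **HOG** (5 × 5 grid × 10 bins = 250 dims). Gradients by central
  differences (one-sided at edges); orientation folded into [0, π) because
  a profile "image" has no meaningful gradient-sign symmetry; per-cell
  histograms are magnitude-weighted and L2-normalised (ε = 1e−12). The
  25-cell grid with 10 channels is the partition consistent with a
  250-feature budget.

Concatenation order is fixed (`pse_pssm | avblock | dwt | dct | hog`) and
recorded as named segments in the output vector.

## Lifelong classifier

The model is a shared trunk of ReLU layers (default widths 128, 64 on the
1730-dim input) plus an ordered list of binary sigmoid heads, one per
learned class. Input features are standardised by a scaler fitted on the
first task's data and then frozen with the rest of the task-1 parameters,
so later tasks cannot silently shift earlier heads' inputs.

Each task minimises a class-weighted binary cross-entropy plus λ·Ω(W) and
runs three phases:

1. **Selective retraining.** A new head is created and only parameters
   whose freeze timestamp is unset are trained (Ω = element-wise ℓ1,
   λ = 1e−4). From task 2 on this means the head alone.
2. **Expansion.** A stratified 20 % holdout of the task's data is scored
   after phase 1; if its loss exceeds τ = 0.15, k = 16 fresh units are
   appended to every hidden layer. New units receive input from the full
   previous layer, but old units get permanently-zero weights from new
   inputs, so the function computed for earlier heads is unchanged by
   growth. Only the new units and the head are trained, with a per-unit
   group-ℓ2 penalty on incoming weights; units whose incoming norm falls
   below 1e−6 are pruned.
3. **Freeze.** Every parameter touched this task is timestamped with the
   task index and never trained again. Forgetting is therefore exactly
   zero: old parameters are bit-identical, and old heads' scores on fixed
   inputs reproduce bit-for-bit.

Prediction is argmax over head probabilities, 1-based in head order, ties
to the lowest class index. Negatives for each one-vs-rest task are taken
from the other classes present in the *current* input table only — earlier
tasks' datasets are assumed unavailable, which is the constraint that
motivates the architecture.

Optimisation is minibatch SGD (batch 32, learning rate 0.05) with classical
momentum 0.9, 60 epochs, all in float64 numpy. Momentum is used because
plain fixed-rate SGD needs several-fold more epochs to fit even cleanly
separable tasks at these widths; it preserves the determinism that an
adaptive optimiser would complicate. Fixed seeds make training
bit-reproducible on one platform; per-task seeds are derived from the
config seed and the task index. Inverse-frequency class weighting is on by
default because real membrane-protein classes are imbalanced by two orders
of magnitude.

Unit splitting/duplication — a feature of some dynamically expandable
network variants — is not implemented.

## Synthetic data

The generator emulates the two properties of real profiles that the
pipeline is sensitive to: integer log-odds matrices whose **column means**
carry the class signal, and a heavy-tailed length distribution (log-normal,
log-mean 5.5, log-sd 0.8 — median ≈ 245 residues — clipped to ≥ 16 so the
wavelet cascade is defined). Class c's template is a shared random base
vector plus `separation` added to coordinate c, placing every pair of
templates exactly `separation·√2` apart; rows are template plus N(0,
noise_sd²), rounded to integers. Default conditions are 8 classes, 100
proteins per class, separation 8, unit noise. A `template_seed` separate
from the sampling seed lets a train and a test stream share one class
population while drawing independent proteins.

What the generator does **not** model: positional motifs, transmembrane
segment structure, PSI-BLAST's substitution statistics, or realistic
amino-acid composition. Passing tests therefore demonstrate that the
pipeline recovers class structure expressed in profile column statistics —
not that it reaches any particular accuracy on real curated datasets, which
additionally require PSI-BLAST profiles and redundancy filtering.

## Evaluation conventions

Per-class "accuracy" in the benchmark-table sense is the recall on that
class's own members (x correct of y members); overall accuracy is pooled
`Σx/Σy`. SN/SP/ACC/MCC are computed from one-vs-rest tallies; any zero
factor in a denominator defines that metric as 0 (warning logged) instead
of NaN. Rendered percentages use one decimal, round half up. Published
benchmark tables for this problem are not perfectly self-consistent under
any single rounding rule (e.g. 69/78 printed as 88.4), so exact-match
checks are restricted to entries where standard rounding agrees, plus the
overall accuracies, which do agree.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline on the
default synthetic conditions (8 × 100 proteins for training, an equal
independent draw for testing, 3 seeds for the headline check), a
separation-0 control of the same size, and a smaller 15-per-class sweep for
the separation-monotonicity trend. The jointly trained reference model is a
scikit-learn MLP of the same final widths, used only as an independent
baseline, never as the implementation.

## Known limitations

* Real-data accuracy claims are out of scope (no PSI-BLAST, no NR, no
  redundancy filtering); the package consumes precomputed ASCII profiles.
* Expansion adds the same k units to every hidden layer; per-layer
  adaptive growth is not implemented.
* Determinism is per-platform: exact bit-reproducibility across BLAS
  builds is not guaranteed, though freezing is exact on any platform.
* The one-vs-rest heads are trained independently, so their probabilities
  are not jointly calibrated; argmax composition is the standard remedy
  and worked well in all shipped checks.
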