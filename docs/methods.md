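# Methods

## Pipeline model

The package predicts whether two proteins interact from their
sequences alone, on the premise that interacting proteins carry
correlated evolutionary signals in their substitution profiles. The
chain is: per-protein profile → fixed-size condensation → spectral
"local energy" descriptor → SVD reduction → pair concatenation →
feedforward classifier → cross-validated evaluation. Each stage is a
pure function of its inputs and a seed, so any run is exactly
reproducible.

### Profiles

A profile is a U×20 real matrix over the canonical PSI-BLAST column
order `A R N D C Q E G H I L K M F P S T W Y V`. Two sources:

* **PSSM** — the log-odds block of a PSI-BLAST ASCII PSSM
  (`-out_ascii_pssm`), produced externally with 3 iterations and an
  inclusion E-value threshold of 0.001 (both configurable; the cutoff
  can instead be applied to the search E-value). Raw integer log-odds
  are used by default; a per-entry logistic squashing 1/(1+e⁻ˣ) is
  selectable for users who prefer a probability-like scale.
* **SMR** — row t is the BLOSUM62 score row of residue t. This is the
  search-free comparator; it is also the automatic fallback (with a
  warning) when PSI-BLAST finds no homologs for a query.

Ambiguity codes B/Z/X/U map to all-zero SMR rows — a neutral
contribution that never aborts a batch run.

### Condensation

Profiles vary in length, so they are condensed to 20×20 before the 2-D
transform. The default is the length-normalised Gram matrix
M = (QᵀQ)/U: it is symmetric positive semi-definite, invariant to
reordering of sequence positions, and its scale does not grow with
sequence length. An alternative `padtrunc` mode keeps the first 20
rows (zero-padding short sequences), for users who want a
position-preserving condensation; it is not the default because it
discards everything beyond residue 20.

### Local-energy descriptor

The 2-D discrete Hilbert transform is the frequency-domain
single-orthant construction: multiply the 2-D DFT coefficient (u, v)
by h(u)h(v), where h(0)=1, h(k)=2 for 0<k<N/2, h(N/2)=1 for even N,
h(k)=0 beyond, then invert. This separable mask is exactly equivalent
to applying the 1-D analytic-signal transform along every column and
then every row, which is the verification oracle used in the tests.
Note that the even-length Nyquist bin is *kept* (weight 1), matching
the 1-D convention; some library implementations of a 2-D analytic
signal instead zero the Nyquist row/column and therefore differ at
exactly that bin.

The descriptor is the element-wise modulus of the analytic matrix
("local energy"), flattened row-major to 400 dimensions. The squared
modulus is available via `features.energy = squared`. Comparator
descriptors: 2-D DCT-II coefficients (orthonormal), 2-D DFT modulus,
single-level Haar DWT (four 10×10 subbands, 400-d), and per-column
auto-covariance at lags 1..g (default g = 5, 100-d) computed on the
pre-condensation profile.

### SVD reduction and pair assembly

The projector is fitted on the n×400 training descriptor matrix:
column-centre, SVD, keep the top-k right singular vectors (k = 300
default, silently capped at min(n, 400) with a warning when the
training set is small). Column signs are canonicalised
(largest-magnitude entry positive) so fits are identical across
linear-algebra backends. Centring is applied before SVD because the
uncentred decomposition conflates the mean direction with variance
directions. By default the projector is fitted **per training fold**
and applied to the held-out fold — fitting on all data would leak test
information into the representation; a `paper_mode` flag fits once
globally for users who want the laxer protocol, and the choice is
logged. A pair descriptor is the 2k-d concatenation [a; b] in the
pair's listed order; `pair.symmetrize` optionally augments training
data with the swapped copy.

### Classifier

The default (`merged`) network feeds the 600-d pair descriptor through
two ReLU hidden layers of 48 units into a sigmoid unit; the `siamese`
variant passes each 300-d half through its own twin subnetwork
(independent weights — parameter counts are exactly twice one subnet
plus the fusion stack), concatenates the twin outputs and finishes
with fused ReLU layers and the sigmoid output. Training minimises mean
binary cross-entropy with Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) and
inverted dropout on hidden activations (training only). Defaults:
learning rate 0.001, 100 epochs, batch size 64, dropout 0.5,
Glorot-uniform initialisation. Inputs are centred and divided by one
global standard deviation computed on the training set (stored in the
model state, applied at prediction). A single scalar scale is used
deliberately: per-column standardisation would re-amplify the
low-variance tail components that the SVD step just attenuated,
drowning the signal in noise directions.

All randomness — initialisation, epoch shuffling, dropout masks — is
driven by one generator seeded from the config, so training is bitwise
reproducible. The forward/backward passes are hand-written in numpy
and validated against central finite differences; the check is run at
a generic parameter point because zero-initialised biases place dead
samples exactly on the ReLU kink, where the loss is non-differentiable
and central differences measure half-slopes. Decision threshold for
hard labels is 0.5, with score = threshold counting as positive.

KNN (k = 5) and random forest (500 trees) are thin adapters over
scikit-learn exposing the same probability-score contract; they are
comparators, not contributions.

### Evaluation

Accuracy, precision, sensitivity, specificity and MCC from the
confusion table; any 0/0 denominator yields 0 with a warning (and an
MCC of 0 when its denominator vanishes). The ROC curve sweeps every
distinct score threshold; the AUC is the trapezoidal integral, which
equals the rank statistic P(s⁺ > s⁻) + ½P(tie). Cross-validation uses
stratified folds by default (per-fold class ratios within one sample
of the global ratio); a plain random split is available. Reports give
per-fold rows plus mean ± sample SD (n−1 denominator).

Negative sampling draws uniformly without replacement from the ordered
all-pairs candidate space including self-pairs (p proteins → p²
candidates, e.g. 7,437 proteins → 55,308,969 candidates, 55,280,859
after removing 28,110 known interactions). The ordered-with-self
convention is the one whose arithmetic matches those counts; an
`unordered` option (i<j, no self-pairs) exists for the biologically
stricter reading. For large spaces with sparse draws the sampler
switches to rejection sampling; both paths are seeded.

## Synthetic data

The generator emulates exactly the structure the pipeline exploits,
with no biological claim attached. Each protein receives a unit latent
direction in profile space: latents sit near one of three orthonormal
cluster centres in a 4-dimensional subspace embedded into the 20
amino-acid axes, with 0.25 within-cluster noise before normalisation.
Ground-truth interactions are the ordered pairs whose latent dot
product exceeds 0.5 — i.e. interacting proteins share profile
structure — and negatives are sampled from the complement, so labels
are a deterministic function of the latents. A profile is Gaussian
noise (σ = 2) plus a rank-1 planted component
`signal_strength · 3.0 · u wᵀ` (u uniform in [0.5, 1.5] per position,
w the latent direction), rounded to integers and clipped to [−10, 12]
to resemble log-odds magnitudes. At `signal_strength = 0` profiles
carry no latent information, so the labels are independent of the
features and the pipeline's AUC sits at chance; raising the strength
makes the classes separable, and AUC increases monotonically.

Default study conditions: 60 proteins of 50–150 residues, 150
positive + 150 negative pairs, signal strength 2, seed 7. Everything
(sequences, latents, profiles, pair sampling) derives from the config
seed through independent named streams, so fixtures — including
PSI-BLAST-format ASCII PSSM files, which round-trip exactly through
the parser — regenerate identically.

What the generator does **not** emulate: homology-driven profile
similarity, residue-composition bias, domain architecture,
hub-degree distributions, or the noisy labels of real interaction
databases. Passing tests therefore demonstrate that the pipeline
recovers profile-correlation structure when it exists and reports
chance when it does not — they do not certify accuracy on real
interactomes, which depends on how well real PSSMs carry interaction
signal.

A note on the comparators at these conditions: the planted label is a
*relational* (same-cluster) property of a pair, so each feature's
marginal distribution is nearly identical across classes. Distance-
and representation-based classifiers (KNN, the DNN) recover it;
axis-aligned random forests hover near chance — an instructive
illustration that the harness measures the classifier/feature
combination, not the features alone.

## Numerical and design choices

* Profile → 20×20 condensation method, log-odds vs logistic scaling,
  modulus vs squared energy, merged vs Siamese architecture, per-fold
  vs global SVD fit, ordered vs unordered candidate space, stratified
  vs plain folds — each has one documented default (listed above) and
  a config switch; no constant is hard-coded in the pipeline.
* DWT comparator uses Haar at one level because it is exactly rational
  and preserves the 400-d budget (4 × 10 × 10).
* Metric edge cases are defined (0/0 → 0 with a warning) rather than
  raised, so degenerate folds do not abort a sweep.
* SVD determinism: sign canonicalisation plus centring makes repeated
  fits bit-identical.
* Problem sizes in the test suite and acceptance script (60 proteins,
  300 pairs, 20×20 transforms, 50×400 SVD checks) were chosen as the
  smallest sizes at which every property of interest is measurable
  with comfortable margins; all scale linearly if enlarged.

## Known limitations

* The 2-D analytic signal is the separable single-orthant transform;
  direction-selective alternatives (e.g. Riesz-based constructions)
  are out of scope.
* PSI-BLAST itself, database formatting, and profile pseudocount
  computation are external; only the ASCII PSSM contract is owned.
* The DNN is CPU-only numpy; it is sized for hundreds-to-thousands of
  pairs, not millions.
* Real-data performance is untested here by construction (no bundled
  interaction databases); the synthetic study bounds only internal
  correctness.
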