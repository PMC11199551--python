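# Methods

## Model

`perturbsig` infers the transcriptional response of a cell line to a
compound from two inputs: the cell's basal expression profile X1 (DMSO
vehicle, 978 L1000 landmark genes) and a fixed-length compound feature
vector C_mol (ECFP4 fingerprint, 2048 bits, or an externally supplied
embedding such as a 2034-dimensional pretrained graph-transformer vector).
The output is a predicted perturbed profile X2' and the differential
expression signature dX' = X2' − X1.

The architecture couples two variational autoencoders with a compound
encoder and a latent fusion map:

- `encoder_x1` / `decoder_x1`: VAE over basal profiles; encoder hidden
  widths [1200, 100] feeding separate linear heads for the mean and
  log-variance of a d = 100 diagonal Gaussian latent Z1; decoder hidden
  widths [100, 800] back to 978 genes.
- `encoder_x2` / `decoder_x2`: an identically shaped VAE over perturbed
  profiles (latent Z2).
- `mol_encoder`: a one-hidden-layer perceptron mapping C_mol to Z_mol of
  width d.
- `fusion`: a single affine map from the concatenation (Z1-mean ⊕ Z_mol)
  to the Gaussian parameters (mu', logvar') of the predicted perturbed
  latent Z2FZ1.

Hidden layers use ReLU; decoder outputs and all Gaussian heads are linear.
Training minimises the unweighted six-term objective

    L = SSE(X1, X1^) + SSE(X2, X2^) + SSE(dX, dX')
      + KL(q(Z1|X1) || N(0,I)) + KL(q(Z2|X2) || N(0,I))
      + KL(q(Z2|X1,C_mol) || q(Z2|X2))

with reparameterised sampling of Z1, Z2 and Z2FZ1, and the diagonal-Gaussian
KL closed forms (per dimension, sigma^2 = exp(logvar)):

    KL(q || N(0,I)) = −1/2 (1 + logvar − sigma^2 − mu^2)
    KL(q || p)      = −1/2 (1 + log(sq^2/sp^2) − (sq^2 + (mq−mp)^2)/sp^2)

A per-term weight vector exists in the configuration and defaults to all
ones. At inference the latent means are used (no sampling), so prediction
is deterministic; a `sample=True` flag enables stochastic generation.

### Reconstruction-term scale

Reconstruction errors are **per-sample sums over genes** (batch-averaged),
not per-gene means. This is the Gaussian evidence-lower-bound convention:
the KL penalties are sums over latent dimensions, and dividing the
reconstruction term by the gene count down-weights it roughly 1000-fold
against them. Empirically the gene-averaged variant collapses the
posteriors to the prior (the model then predicts the dataset mean and
recovers planted effects at PCC ≈ 0.2 on a noiseless fixture, versus
≈ 0.94 with the summed form). The `LossReport` fields carry the summed
convention; only the relative scale of the six terms, not their ordering or
identities, is affected.

### Standardisation

Expression vectors are standardised per gene inside the model (mean/sd
fitted from the training pairs' X1 and X2, sd floored at 1e-3, inverted at
the output boundary). Loss terms are computed on the standardised scale.
This is a numerical choice of the model, not a data-processing step: the
I/O pipeline consumes level-3-style expression values as-is.

### Optimisation

Adam (lr 1e-3, betas 0.9/0.999), batch size 64, shuffled mini-batches,
all randomness from one seeded generator so trajectories are bit-identical
across runs on one machine. lr 1e-3 is the standard Adam default for small
MLPs; at 1e-4 the model barely moves within the 50-epoch budgets used
here. With a validation pair list, training stops after 10 epochs without
improvement and restores the best parameters. Gaussian-head and fusion
weights are initialised near zero so all posteriors start at the prior and
the KL terms grow only as the latents become informative; other layers use
He initialisation.

### Knockdown pretraining

`pretrain_init` trains only the two VAEs (reconstruction + standard-normal
KL; compound encoder and fusion untouched) on shRNA-style pairs — X1 an
empty-vector control, X2 the knockdown profile, plate-paired exactly like
compound data — and returns the weights as an initialisation for compound
training.

## Data preparation

- **Condition filter**: compound profiles at 24 h / 10 uM (both
  configurable, `None` disables a constraint); control profiles always
  retained.
- **Plate pairing**: each compound profile is paired with the MODZ
  aggregate of the DMSO controls on its own plate (one control: verbatim).
  Plates with compound samples but no control are dropped with a warning.
- **MODZ**: one replicate is returned verbatim; two are averaged equally;
  for k >= 3, replicate i is weighted proportionally to the sum over j /= i
  of Spearman(rep_i, rep_j), each pairwise correlation floored at 0.01
  (keeps weights positive), weights normalised to one. This follows the
  Connectivity Map convention; it is permutation-invariant and idempotent.
- **Collapse**: replicate pairs for one (compound, cell line) are
  MODZ-collapsed independently on X1 and X2 to a single pair.
- **Splits**: chemical-blind partitions compound ids, cell-blind cell
  lines. Ids are shuffled under the split seed; test and validation get
  floor(fraction * N) ids each, the remainder goes to training.

## Evaluation metrics

RMSE, Pearson correlation, Positive/Negative Precision@K (overlap of true
and predicted top-K up-/down-regulated genes; K = 100 for 978-gene
signatures; top-K ties break by ascending gene index so results are
reproducible), SSE, MSE, MAE, and r² implemented as the squared Pearson
correlation (the conventional goodness-of-fit reading; no other formula is
standard for a single predicted vector). Dataset-level values are
per-sample means.

## Connectivity scoring

Signatures are ranked by delta descending (rank 1 = most up-regulated,
ties by gene index). For a gene set of size t in a list of n genes, with
V(j) the rank of the j-th set gene in ascending rank order,

    a = max_j [ j/t − V(j)/n ],  b = max_j [ V(j)/n − (j−1)/t ],
    ES = a if a > b else −b      (a = b returns a; both are >= 0)

The two-tailed connectivity score is ES_up − ES_down when the two
enrichment scores have opposite signs (sign(0) counts as its own sign) and
0 otherwise. The literal difference spans [−2, 2]; the score is
conventionally stated on [−1, 1], so both the raw value and the halved
normalised value are exposed and all ranking uses the normalised one.
Repurposing mode `drug` ranks by descending normalised score (mimics the
query), `disease` by ascending (reverses it); several query signatures are
combined by the per-compound mean normalised score; ties break
lexicographically by id. Query gene sets built from a signature take its
top/bottom 50 genes by default. Landmark signatures are projected to the
10,174-gene space by concatenating the unchanged 978-gene block with the
affine inference W·dx + b over the 9196 inferred genes. Screening
evaluation labels the floor(0.2 N) compounds with the lowest response AUC
as hits and reports the AUROC of recovering them from the ranking order.

## Downstream screening harness

Activity labels: active iff potency < 10 uM (strict), inactives sampled
1:5 per active without replacement, seeded. Response labels: sensitive iff
AUC < 5.5. Representations: one cell's dX' (978 wide), early fusion
(concatenation over cells in the given order; seven cells gives 6846), or
structure baselines (fingerprint, fingerprint ⊕ basal profile). The
learner is dependency-injected; the default is a scikit-learn random
forest with an optional grid search over n_estimators, max_depth,
criterion and oob_score. Classification reports AUPR, AUROC, balanced
accuracy, F1, log-loss and MCC over repeated seeds (mean ± sd); regression
reports the Pearson correlation of predicted vs true AUC and exports the
ranking by predicted AUC. Late fusion averages per-cell probabilities
(bounded by their min/max). Similarity-binned evaluation recomputes
metrics within half-open (lo, hi] bins of each test compound's maximum
ECFP4 Tanimoto to the training compounds; empty or single-class bins are
omitted.

## Synthetic data

The generator emulates the structure that matters for this pipeline:

- per-cell basal means ~ 7 + N(0, 1) per gene (log-expression scale);
- one plate per (cell, replicate) carrying 3 DMSO wells and one well per
  compound; basal draws add N(0, noise_sd_basal);
- compound effects linear in binary features through a rank-r map,
  effect(m) = effect_scale * s * B A f(m), with s one global constant
  scaling the planted effects to unit RMS per gene; perturbed wells add
  the effect plus N(0, noise_sd_pert);
- labels derived from the stored effects: activity from the cosine against
  a target direction; response AUCs decreasing linearly from a resistant
  ceiling of 7.5 with the projection of the effect on a death signature,
  clipped to [0, 8]. Planted disease directions for repurposing tests are
  drawn inside the span of the effect basis, so the disease state is one
  that compound effects can actually mimic or reverse — the premise of
  signature-reversal screening.

Defaults: 978 genes, 3 cell lines, 300 compounds, 3 replicates, 256
binary features (density 0.1), rank 10, noise_sd_basal 0.2, noise_sd_pert
0.25, effect_scale 1. These give a desk-scale study (900 collapsed pairs)
that trains in about two minutes on one CPU while leaving the
signal-to-noise ratio (effect RMS 1 vs perturbation noise 0.25) in a
regime where recovery is informative rather than trivial.

What the generator does **not** emulate: bead-level L1000 deconvolution
artifacts, realistic gene-gene covariance beyond the low-rank effect
structure, dose-response and time dependence (conditions are fixed at the
canonical 24 h / 10 uM), batch effects beyond plate-matched pairing, and
nonlinearity of effects in compound features (a squashing option exists
but is off by default). Passing recovery tests therefore show that the
implementation learns the mapping it is supposed to learn under the stated
noise model — not that the same accuracy would be reached on experimental
profiles.

## Numerical choices and degenerate inputs

- Tanimoto of two all-zero vectors is 0; constant replicate vectors in
  MODZ get pairwise correlation 1 before flooring.
- Pearson on zero-variance input raises by default (NaN behind a flag);
  batch metric means ignore NaNs.
- Top-k and ranking ties always break by ascending gene index or
  lexicographic id, so every reported number is reproducible.
- TSV round-trips preserve values to 6 decimals and metadata exactly;
  empty metadata fields mean "absent" and become NaN.
- Model checkpoints are an npz parameter archive plus a JSON config
  sidecar and round-trip bit-exactly.

## Problem sizes used in the shipped analyses

The test suite exercises the model on 30–60 gene fixtures and the full
pipeline on the default 978-gene configuration with 50 training epochs;
`scripts/acceptance.py` runs the complete study (generate, prepare,
chemical-blind 80/20 split, 50-epoch training, a permuted-compound-feature
baseline trained identically, held-out signature metrics,
signature-reversal repurposing over 300 compounds, and a random-forest
activity screen on predicted signatures) in a few minutes on one CPU.

## Known limitations

- No GPU path and no GCTX binary parsing; the interchange formats are TSV
  and CSV.
- The KPGT-style embedding is consumed as a vector table; no pretrained
  network ships with the package.
- Multi-dose and multi-time conditioning are out of scope (the canonical
  condition is fixed); batch-effect handling is limited to plate-matched
  pairing.
- Early stopping monitors total validation loss only.
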