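# Methods

## Problem and model

Short linear motifs (SLiMs) are contiguous stretches of roughly 3–15 amino
acids, often inside intrinsically disordered regions, that mediate
transient protein–protein interactions. `slimfuse` scores every residue of
a protein with the probability of belonging to such a motif. Three
per-residue evidence channels are combined:

1. **Semantic (Seqfea).** A protein language-model backend maps a length-L
   sequence to an L×1024 embedding; PCA fitted on the pooled residues of
   the *training* sequences reduces this to L×128. Fitting the projection
   on training data only keeps validation/test information out of the
   transform.
2. **Physicochemical (Phy).** AAindex property indices assign one value
   per amino-acid type. Selected accessions are mapped per residue,
   min-max scaled to [0,1] per accession (so heterogeneous property scales
   cannot dominate), and smoothed **twice** with a centred sliding-window
   mean. With 54 selected accessions and window lengths 7 and 11 the block
   is L×108.
3. **Evolutionary (PSSM).** The 20 log-odds columns of a PSI-BLAST ASCII
   profile, reordered to a canonical residue order and standardized by
   per-column mean/sd fitted on training profiles (zero-variance columns
   map to 0).

Two *enhanced attention* modules — single-head attention with output
projection, residual connection and layer normalization, so input and
output shapes coincide — are applied separately to the Phy (D=108) and
PSSM (D=20) blocks. Their outputs are concatenated with Seqfea into an
L×256 matrix (channel order: semantic | evolutionary | physicochemical),
refined by four-head scaled-dot-product attention (head dimension 64,
residual + layer norm), and classified per residue by an MLP 256→64→2 with
GELU activation, dropout 0.3 on the hidden layer and a softmax output.

### The two attention variants

The written definition of the attention output admits two readings: the
standard matrix product of the L×L softmax weights with the value matrix,
and a literal element-wise product. An L×L weight matrix cannot be
multiplied element-wise with an L×D value matrix, so both defensible
interpretations are implemented behind `variant`:

* `matmul` (default): scores QKᵀ/√D, row softmax over key positions,
  output = weights·V — the canonical scaled dot-product form;
* `elementwise`: scores (Q⊙K)/√D (L×D), softmax along the sequence axis
  per channel, output = weights⊙V.

Both variants are verified against naive loop references and carry exact
hand-written gradients.

## Dataset handling

* **Whole-cluster 6:2:2 split.** Sequences arrive grouped into homology
  clusters (CD-HIT `.clstr`, 40% identity in the intended use). Clusters
  are shuffled by seed, ordered largest-first, and greedily assigned to
  the split whose target sequence count is furthest from satisfied. All
  members of a cluster share a split, so homologs can never straddle the
  train/test boundary.
* **Residue balancing.** Motif residues are vastly outnumbered. For
  training, negatives are uniformly down-sampled (seeded) to match the
  positive count. The selection only masks the cross-entropy — attention
  always runs over complete sequences — and validation/test retain the
  natural imbalance so reported metrics reflect deployment conditions.

## Feature selection by simulated annealing

The AAindex pool is searched per (window length, subset size) combination:
window lengths {5, 7, 9, 11, 21, 41}, subset sizes {10, 20}. The objective
of a candidate subset is the mean validation AUC of a linear-kernel SVM
over a seeded stratified 3-fold split of (a capped sample of) the
window-averaged residues. The annealing schedule is geometric: T0 = 100,
termination T1 = 0.1, rate α = 0.95, which gives exactly 135 temperature
plateaus; each plateau performs a configurable number of single-swap moves
(default 10), accepting improvements always and deteriorations with
probability exp(Δ/T). Scores are memoized, so revisited subsets cost
nothing. The final feature set is the frequency consensus across all runs:
the 54 accessions appearing most often in best subsets (lexicographic
tie-break).

Two practical notes. First, score differences live on the AUC scale
(≪ 1), so for most of the default schedule (T ≥ 0.1) worsening moves are
accepted almost freely and the search behaves like randomized exploration
with best-ever tracking; the recovery experiments in the test suite
therefore use a colder, shorter schedule (T0 = 0.1 → T1 = 0.005, α = 0.8,
8 moves/plateau) where the walk is effectively greedy. Second, the SA
residue sample is capped (default 2000, seeded) to keep each SVM
evaluation desk-scale.

## Training

Batches are whole sequences (default 8 per step). The loss is the
two-class cross-entropy — mathematically the binary cross-entropy on the
positive-class softmax probability — averaged over the balanced loss
residues of the batch. Adam (lr 0.001, β = 0.9/0.999) updates all
parameters: both enhanced-attention blocks, the fusion attention and the
MLP. Weights are initialized from a seeded scaled-uniform (fan-in)
distribution; layer-norm gains start at 1, biases at 0. Dropout masks,
batch order and negative sampling all derive from the run seed, so a fixed
seed reproduces a training run bit-for-bit on one thread. Each epoch logs
the mean training loss and validation AUC; the epoch with the best
validation AUC is checkpointed and returned (the last epoch when no
validation set is supplied). Default epoch budget: 100.

## Evaluation conventions

ROC/AUC and PR/AP use the standard descending-score sweep with ties
grouped, trapezoidal AUC and step-wise (non-interpolated) AP. **FPR@TPR**
and **precision@TPR** report the operating point at the *largest*
threshold whose TPR reaches the target — achievable TPRs are multiples of
1/#positives and no interpolation between ROC points is performed, so
every reported number corresponds to a real cutoff. Default TPR targets:
0.2, 0.3, 0.4. Evaluation always runs on the unbalanced validation/test
distribution.

## Synthetic benchmark

The generator emulates the statistical structure the pipeline assumes, in
the exact on-disk dialects the readers parse:

* **Sequences.** Background residues follow an average protein
  composition; motif segments (default two per sequence, lengths 3–15,
  non-overlapping) are drawn from a composition biased toward
  motif-preferred letters (P, L, D, E, S, T). `motif_signal_strength`
  interpolates the motif composition between background (0 = null) and the
  pure preferred-letter law (1). Homology clusters are simulated by
  copying each sequence with seeded point mutations (default 2 copies, 5%
  rate), exercising the whole-cluster split logic.
* **PSSMs.** Integer log-odds noise plus a self-residue bonus; motif
  positions get an extra self-residue conservation bonus scaled by the
  signal strength (zero at the null).
* **AAindex table.** Informative accessions carry a 0.5 baseline on all
  preferred letters plus a bonus on a round-robin share of them — each is
  individually discriminative, several together are strictly better, so
  subset search has a real gradient. Non-informative accessions are random
  letter values orthogonalized against the motif-composition contrast, so
  under any signal strength their expected value is identical for motif
  and background residues: the null is exact by construction.
* **Embeddings.** Each letter has a fixed pseudo-random base vector; a
  residue's embedding mixes its base vector with the mean of its ±2
  neighbours and adds a fixed shift on motif-preferred letters scaled by
  the signal strength. The shift is a function of the sequence alone —
  labels can never leak into features — and reaches motif residues in
  expectation through their biased composition.

What the generator does **not** model: realistic motif grammars
(regular-expression-like patterns), disorder context, position-specific
conservation structure beyond a self-residue bonus, or realistic
phylogenetic correlation between homologs. Passing the end-to-end tests
therefore demonstrates that the pipeline recovers a planted
composition-plus-conservation signal through all three channels and stays
at chance when that signal is removed; it does not certify performance on
curated motif databases.

## Problem sizes and numerical choices

* End-to-end experiments (tests and `scripts/acceptance.py`) use 50 base
  sequences × 2 homolog copies (≈100 sequences, 60/20/20 after the 6:2:2
  cluster split), 60 AAindex entries of which 8 informative, an 800-residue
  SA sample with a shortened schedule (T0=1 → 0.05, α=0.7, 3 moves), and
  25 training epochs — sizes chosen so a full run completes in about a
  minute on a laptop core while leaving wide margins to the acceptance
  bands (high-signal test AUC ≈ 0.98 vs the 0.9 bar; null ≈ 0.52–0.59 vs
  the 0.5 ± 0.1 band).
* Layer-norm ε = 1e-5; GELU is the exact erf form; softmax is
  max-subtracted; the cross-entropy uses log-sum-exp.
* Consensus size adapts downward when the accession pool is small, and the
  lowest-ranked consensus accessions are dropped if needed to keep the
  fused width divisible by the head count (with the intended 544-entry
  pool and 54 consensus accessions this never triggers: 128+20+108 = 256).
* AAindex `NA` values and ambiguity codes X/B/Z/U are imputed with the
  accession's mean over defined values. Window means truncate (shrink) at
  sequence boundaries rather than padding.
* Sequences shorter than a window are handled by the same truncation rule;
  there is no minimum-length filter at ingestion.

## Open design points resolved here

* The double window averaging uses the same window length for both passes.
* The per-window SA runs with subset sizes 10 and 20 are interpreted at
  residue level (pooled residues × accession matrix); no per-sequence
  pooling is performed.
* Phy and PSSM get separate enhanced-attention parameter sets (their
  dimensions differ); the fusion attention includes residual + layer norm
  for stability.
* The label file format is a 1-based inclusive interval TSV
  (`seq_id  start  end`), matching the interval shape of curated motif
  annotations; coordinates are 0-based half-open internally.

## Limitations

* The `protbert` embedding adapter is an interface stub: real pretrained
  weights (and a deep-learning runtime) must be supplied by the user; all
  bundled functionality runs on the synthetic backend.
* Training is CPU-only numpy; it is comfortable at hundreds of sequences
  and ~100 epochs but not tuned for proteome-scale corpora.
* The SA objective uses a linear SVM without class weighting; callers
  balancing extremely skewed residue samples should rely on the built-in
  sample capping, which stratifies implicitly through seeded uniform
  sampling.
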