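# Methods

## The problem

Residue pairs that are close in a folded protein leave a statistical
footprint in the protein's family alignment: when one position mutates, its
spatial neighbours tend to co-mutate to preserve the contact.
`metacontact` infers residue–residue contacts from a multiple sequence
alignment (MSA) by combining several covariation statistics with classical
alignment-profile features in a two-stage neural-network meta-predictor,
scores predictions CASP-style, and converts them into distance restraints
for structure scoring.

The package is validated end-to-end on synthetic protein families drawn
from Potts models built on known contact topologies, so every claim the
test suite makes is checked against a known ground truth.

## Alignment handling and depth

Sequences are canonicalized to a 21-state alphabet (20 amino acids + gap).
Ambiguity codes (B, Z, X, U, O, J) are mapped to the gap state: they carry
no single-residue covariation information and folding them into the gap
keeps the state space at 21, as in standard DCA practice. A3M insertions
(lowercase) are removed so all rows match the query length.

Alignment depth is measured as an effective sequence count N_eff: single-
linkage clustering at 62% pairwise identity (the BLOSUM62 clustering
threshold), N_eff = number of clusters. Identity is matches divided by
columns where at least one of the two rows is non-gap. Each sequence gets
weight 1/(its cluster size), so weights sum exactly to N_eff; all
frequency statistics are weighted. Single linkage is chosen to match the
BLOSUM clustering procedure; the threshold is configurable but a single
redundancy notion (62%) is used throughout.

The alignment-generation pipeline itself (HHblits at E-value 1e-3, 50%
coverage, 3 iterations; jackHMMer supplement at E-value 10, 3 iterations
when the first pass yields fewer than 2000 sequences; deeper alignment
wins, ties to the first pass) is recorded as a machine-checkable
configuration plus two pure decision functions; the external tools are
never executed by this package.

## Covariation engines

All engines consume weighted column frequencies with a uniform pseudocount
λ expressed in effective observation counts (λ/q per single state, λ/q²
per pair, which keeps marginalization exact).

* **MI / MIp** — mutual information in nats from the raw weighted joint
  tables; MIp is MI after average-product correction.
* **mfDCA** — mean-field inverse Potts: the connected-correlation matrix
  C over q−1 = 20 states per column (gap dropped to remove the simplex
  degeneracy) is inverted; couplings e_ij = −(C⁻¹)_ij; the score is the
  Frobenius norm of the zero-sum-gauged 20×20 block. The pseudocount
  defaults to the weighted sequence count (relative weight 0.5), the
  standard mean-field choice and required for invertibility.
* **PSICOV-style** — sparse inverse covariance: the same covariance,
  shrunk toward its diagonal (coefficient 0.1), is fed to an L1-penalized
  maximum-likelihood precision estimate (graphical lasso, coordinate
  descent, rho = 0.005, tol 1e-4, 30 outer sweeps). If the solver rejects
  the matrix as ill-conditioned — routine for shallow, redundant
  alignments — the shrinkage coefficient is doubled until it succeeds
  (error past 0.91). Score: L1 norm of the 20×20 precision block.
  Non-convergence is flagged, not fatal; the per-sweep objective trace is
  kept for inspection.
* **PLM** — pseudolikelihood maximization of a full 21-state Potts model
  with per-site fields and symmetric pair couplings, weighted by the
  redundancy weights and L2-regularized (fields 0.01, couplings 0.1).
  Optimized by L-BFGS with an analytic gradient from zero initialization:
  deterministic without any seed. Default cap 50 iterations — coupling
  *ranking* stabilizes long before full convergence, and the cap is
  flagged in the result metadata. Score: Frobenius norm of the
  zero-sum-gauged coupling block.

Every engine's raw score receives the average product correction
S′(i,j) = S(i,j) − S̄(i,·)S̄(·,j)/S̄ computed over unmasked entries, which
subtracts per-residue background coupling propensity (phylogeny and
composition bias). Pairs closer than `min_separation` = 4 are masked
(interpreting "four or more residues apart" as |i−j| ≥ 4; configurable).
Ties in ranked outputs break lexicographically on (i, j).

The numeric defaults above (pseudocounts, rho, shrinkage, regularization)
are package choices — documented, configurable, and chosen to be standard
for each method family rather than tuned to any benchmark.

## Feature assembly and the two-stage network

Per eligible pair (i, j), stage-1 features are: each included method's
score at (i, j) — by default raw MI, APC-corrected MIp, and the
APC-corrected mfDCA, PSICOV and PLM scores — together with two derived
variants per method: the score's quantile rank among the family's
eligible pairs (scale-free; raw coupling magnitudes vary by orders of
magnitude with alignment depth) and that rank multiplied by a "shallow
gate" 1/(1 + N_eff/50). The gated ranks make depth-conditional method
selection linearly learnable: which engine to trust depends strongly on
depth (on shallow alignments the model-based engines are noise and
mutual information carries what little signal exists), and asking a
single hidden layer to discover that interaction from pooled training
data proved unreliable. Then, for every column in a ±2 window around i and around j,
the 21 weighted frequencies plus gap fraction and Shannon entropy;
a one-hot sequence-separation bin ({4–8, 9–13, 14–18, 19–23, 24–38, ≥39});
and the global depth terms ln(1+N_eff) and ln(1+N). Optional 3-state
secondary-structure probabilities and solvent accessibility are accepted
as a per-residue input table and appended per windowed column — they are
never predicted here. Out-of-range window columns carry a pad sentinel
(−1). Depth modulation between classical and covariation information is
left to the network: on shallow alignments covariation scores are noise
and the profile/depth terms carry the signal; the depth features let the
network learn that gating rather than hard-coding a switch.

Both stages are one-hidden-layer perceptrons (50 logistic hidden units,
logistic output). Inputs are standardized with the per-feature mean and
standard deviation recorded at training time and stored inside the model
(score features span ±50 while probabilities span 1; without
standardization the large-scale features dominate the optimizer). Stage 1
maps pair features to an initial contact map; stage 2 re-estimates each
pair from the 11×11 window of stage-1 probabilities centred on it (121
values, padded off-map) plus the pair's within-map probability quantile,
the depth features (including the shallow gate) and the separation bins —
contacts come in stripes and blocks, so the neighbourhood suppresses
isolated false positives and fills gaps inside true blocks, while the
center-rank feature lets stage 2 simply preserve the stage-1 ranking when
the neighbourhood carries no extra information (shallow alignments).
Training delegates to scikit-learn's MLPClassifier under a single
train_seed that drives initialization and shuffling; fitted weights are
extracted into a plain JSON-serializable container with a numpy forward
pass, so models reload bit-exactly. Non-contacts are deterministically
subsampled to a 5:1 negative:positive ratio (the MLP fit has no
per-sample weighting, so imbalance is handled in the sampling; on the
dense synthetic contact maps the ratio rarely binds). Stage 2 trains on
the stage-1 maps of the same families it will refine, i.e. on realistic
stage-1 output rather than ground truth.

## The synthetic-family generator

A compact self-avoiding chain (bond length 3.8 Å, excluded volume 4.0 Å)
is grown inside a confinement sphere allotting ~160 Å³ per residue;
contacts are pairs at ≤ 8 Å with |i−j| ≥ 4. The confinement matters:
unconfined random walks of modest length almost never form long-range
(|i−j| > 23) contacts, and long-range precision is the headline metric.
A Potts model places random zero-sum-gauge 20×20 coupling blocks (scaled
by β, default 1.2) on exactly the contact pairs, with fields from a fixed
background amino-acid composition. β was calibrated once so that the
covariation engines reach contact-ranking AUC > 0.8 at L=30 with 2000
sequences — i.e. so the generator produces learnable signal — and not
revisited.

Sequences are drawn by parallel single-site Gibbs sampling: one chain per
output sequence from independent random starts, 50 burn-in sweeps, one
harvest after a further `thinning` sweeps. Sampler fidelity is verified
against exact enumeration on hand-built two-site models. Sampled
sequences are gapless (the gap field is −30); alignment-level gap
handling is tested separately on constructed alignments.

Controlled depth: with `target_neff` set, the first `target_neff` samples
act as cluster seeds and the remaining rows are near-duplicates of them
(per-site substitution rate 0.05), reproducing the shallow redundant
families that N_eff is designed to measure; the achieved N_eff is checked
within ±10% of target.

What the generator does *not* emulate: phylogenetic correlation between
family members (weights correct for redundancy, not for tree structure),
insertions/deletions, heterogeneous conservation, and real contact-map
geometry beyond what a compact chain induces. Passing tests therefore
show that the statistics and the pipeline machinery are correct and that
the meta-combiner's advantage is real under the generative model the
covariation methods assume — not that any particular precision carries
over to natural proteins.

## Evaluation and restraints

Predictions are ranked lists (ties lexicographic). Top-L/k precision
selects the ⌊L·k⌋ (minimum 1) highest-probability pairs inside a
separation class and reports the percentage that are true contacts;
long-range means |i−j| > 23 (so separation 24 and up), short-range is
4 ≤ |i−j| ≤ 23 — separation exactly 23 goes to short-range so the two
classes partition the eligible pairs. ⌊L/5⌋ (floor, not rounding) is the
documented top-L/5 convention. CASP RR files are written as
`i j 0 8 p` with p to three decimals between PFRMAT/MODEL/END records.

For structure scoring, every pair with predicted probability ≥ 0.5
becomes a restraint of weight equal to its probability. The pair energy
is a square well: −weight out to 8 Å (Cβ–Cβ; Cα for glycine), decaying
smoothly to zero beyond — Gaussian in the excess distance with width
2 Å by default, with a single-exponential alternative behind the same
configuration, since the exact fall-off is a folding-engine choice.
Short- and long-range restraint energies are accumulated separately
(E_SR-RR, E_LR-RR): short-range contacts are abundant and easy, and a
single pooled term lets them swamp the long-range signal.

Aggregate statistics over a per-domain results table report the mean
precision rounded to the nearest integer percent and the median N_eff
truncated to an integer (an even-count median can be fractional; the
truncation convention is documented rather than inferred).

## Benchmark problem sizes

The canned experiments use: contact-ranking AUC at L=30 with 2000
sequences over 10 seeded families; meta-versus-single comparison and the
N_eff-stratified curve at L=36 with 400–600 sequences per family (long
enough that long-range pairs are plentiful, small enough that the full
covariation stack runs in seconds per family), training on 16 families
whose (N, N_eff) grid spans shallow (N_eff = 10) to full depth — the
training grid must cover the depth range the predictor is applied to,
since the depth features do not extrapolate — and testing on 20 held-out
families. The depth curve uses a paired design: the same base families
are padded to each stratum N_eff ∈ {10, 50, 200, 500}, because a
topology's long-range contact count caps attainable top-L/5 precision
and unpaired strata would compare different ceilings.

On these benchmarks the meta-predictor's mean top-L/5 long-range
precision matches the best individual engine on the shallow end of the
test mixture and exceeds every engine from N_eff ≈ 50 upward. The
synthetic families bound what is achievable at the shallow end: in this
generator the "classical" profile features carry no contact information
by construction (fields are independent of the topology), so the shallow
regime where a real meta-predictor profits from classical features has
no analogue here and the best attainable shallow behaviour is to track
the best covariation statistic.

The training grid size (22 families) was settled by watching held-out
meta precision during development: smaller grids (8 families) left the
stage networks visibly data-starved.
`scripts/acceptance.py` reruns the same experiments at slightly reduced
family counts.

## Known limitations

* The feature set implements the named feature groups with a configurable
  layout; it does not reproduce any particular historical 672/731-entry
  feature list.
* PLM at its default iteration cap underfits coupling magnitudes (ranking
  is what the pipeline consumes); raise `max_iter` for calibrated
  couplings.
* The graphical-lasso stage inherits its solver's conditioning limits;
  the adaptive shrinkage escalation trades statistical efficiency for
  robustness on shallow alignments.
* `table_stats` conventions (integer rounding/truncation) are for
  compact reporting, not statistical inference.
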