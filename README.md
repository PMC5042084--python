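# metacontact

Covariation-based protein residue–residue contact prediction: a tested,
self-contained re-implementation of a MetaPSICOV/CONSIP2-style pipeline.

Residue pairs in contact in a folded protein co-evolve, and the footprint
of that co-evolution can be read out of a deep multiple sequence alignment
(MSA). Different statistical decoupling approaches — mean-field direct
coupling analysis (mfDCA), sparse inverse covariance estimation
(PSICOV-style graphical lasso), and pseudolikelihood maximization of a
Potts model (GREMLIN/CCMpred-style PLM) — recover partially
*non-overlapping* sets of true contacts, and all of them fail on shallow
alignments where classical profile-based prediction still carries signal.
`metacontact` therefore combines all of them: each engine produces an
average-product-corrected (APC) L×L coupling score matrix, and a two-stage
neural network merges these with alignment-profile, sequence-separation
and alignment-depth features into contact probabilities. Stage 1 predicts
each pair from its feature vector; stage 2 re-estimates each pair from the
11×11 window of the stage-1 contact map around it, removing isolated
outliers and filling gaps in contact blocks.

Alignment depth is measured as N_eff — the number of clusters at 62%
sequence identity — and enters the network as a feature, so the balance
between covariation and classical information is learned per alignment.
Evaluation is CASP-style: top-⌊L/5⌋ precision over long-range pairs
(sequence separation > 23). Predicted maps can be converted into
FRAGFOLD-style contact restraints (square well of depth = contact
probability out to 8 Å Cβ–Cβ, smooth decay beyond, PPV ≥ 0.5 filter,
separate short- and long-range energy sums) to score 3D models.

No external sequence database is needed anywhere: a simulator module
generates protein families from Potts models built on compact
self-avoiding-chain topologies with known contacts, and the whole
pipeline — training included — runs on these synthetic families.
See `docs/methods.md` for the model details and the generator's limits.

## Worked example

Simulate a family of 2000 sequences over a 30-residue topology, measure
its depth, and score residue pairs with mean-field DCA:

```
$ metacontact simulate --seed 7 --out-msa fam.fasta --out-truth fam.contacts
$ metacontact neff fam.fasta
N       2000
N_eff   1835
$ metacontact couple fam.fasta --method mfdca --out scores.tsv
$ head -5 scores.tsv
8       16      10.6502
12      20      9.09647
13      19      8.64516
11      15      7.94528
13      17      7.55408
```

The alignment holds 2000 sequences collapsing to 1835 effective sequences
at 62% identity — a deep, diverse family. `scores.tsv` lists residue
pairs (1-based) by descending APC-corrected coupling score; for this
family all six of the top-⌊L/5⌋ = 6 pairs are true contacts of the
generating topology (75 true contacts in total at the 8 Å threshold).

The full chain — train a meta-predictor on simulated families, predict,
evaluate, and score a structure:

```
$ metacontact train --seed 0 --n-families 8 --out model.meta
$ metacontact predict fam.fasta --model model.meta --out pred.rr
$ metacontact eval pred.rr --truth fam.contacts -L 30 --cls lr
$ metacontact score-structure model.pdb --rr pred.rr --out energy.json
```

`pred.rr` is a CASP RR file (`i j 0 8 p` records); every prediction run
writes a JSON manifest beside its output recording inputs, seeds and
per-stage status, and reruns are byte-identical.

The packaged summary of the CONSIP2 server's CASP11 contact-prediction
results (40 domains) aggregates with:

```
$ metacontact table-stats
n_domains           40
mean_precision_pct  27
median_neff         44
```

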