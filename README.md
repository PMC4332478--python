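# modnet — ensemble module network inference

`modnet` reconstructs *module networks* from multi-omics data: modules of
co-expressed genes, a clustering of the samples within each module, and a
prioritized list of candidate regulators — any continuous or discrete
profile measured on the same samples, such as somatic copy-number calls —
that explain each module's condition structure.  It is aimed at systems
biologists integrating a gene × sample expression matrix with matched
regulator-candidate profiles, e.g. to prioritize copy-number driver genes
in tumor cohorts.

The pipeline separates module learning from regulator assignment and is
run as a chain of tasks, the output of one feeding the next:

1. **Two-way Gibbs clustering** — the score of a clustering is the sum of
   normal–normal-gamma log marginal likelihoods over the (module ×
   condition-cluster) blocks: for a block of N values with mean x̄,

       log m = −(N/2)log 2π + ½ log(λ₀/(λ₀+N)) + lnΓ(α₀+N/2) − lnΓ(α₀)
               + α₀ ln β₀ − (α₀+N/2) ln β_N,
       β_N = β₀ + ½Σ(xᵢ−x̄)² + λ₀N(x̄−μ₀)²/(2(λ₀+N)).

   A Gibbs sweep reassigns each gene (then each sample, per module) among
   existing groups plus one fresh empty group with probability
   ∝ exp(Δscore/T), so the number of modules adapts to the data.
2. **Consensus (tight) modules** — an ensemble of seeded runs defines a
   gene–gene co-occurrence graph (edge weight = fraction of runs where the
   pair shares a module); densely connected node sets are extracted by
   Perron-eigenvector ranking with a mean-internal-weight threshold.
   Genes that never co-cluster reliably remain unassigned.
3. **Condition trees** — per consensus module, samples are re-clustered
   and agglomerated into a binary tree by best Bayesian merge score
   (XML-serialized).
4. **Regulator assignment** — each internal split is explained by each
   candidate regulator through a soft logistic split likelihood; node
   posteriors (softmax over candidates) aggregate across a tree ensemble
   into s(r,m) = Σ_trees Σ_nodes p(r|node)·2^(−level), calibrated against
   an empirical null of permuted regulators, with top-fraction selection
   and hub ranking (Nm, Σ score).
5. **Evaluation** — hypergeometric gene-set enrichment per module (BH
   corrected) and relative enrichment of the inferred regulator network at
   short distances in a reference interaction network.

A seeded synthetic generator with planted modules, condition splits and
regulators makes the whole pipeline testable offline.  See
`docs/methods.md` for the model, defaults and limitations.

## Worked example

Everything is available both as a library (`import modnet`) and through
the `modnet` CLI.  A complete run on a synthetic benchmark (5 planted
modules × 20 genes, 60 samples, 1 planted + 49 decoy regulators):

```sh
modnet synth --out data --seed 7
for s in 0 1 2 3 4; do
  modnet cluster --data data/matrix.tsv --out run$s.tsv --seed $s
done
modnet consensus --runs run0.tsv --runs run1.tsv --runs run2.tsv \
                 --runs run3.tsv --runs run4.tsv --out modules.tsv
modnet condition-trees --data data/matrix.tsv --modules modules.tsv \
                       --out trees0.xml --seed 0
modnet condition-trees --data data/matrix.tsv --modules modules.tsv \
                       --out trees1.xml --seed 1
modnet regulators --trees trees0.xml --trees trees1.xml \
                  --reg-data data/regulators.tsv --data data/matrix.tsv \
                  --out scores.tsv --seed 0 --fraction 0.02
```

which logs

```
wrote 100 genes x 60 samples and 54 regulators to data
run 0: 5 modules, score -5196.576
run 1: 5 modules, score -4402.479
run 2: 5 modules, score -4396.211
run 3: 5 modules, score -4389.862
run 4: 5 modules, score -4392.233
5 consensus modules (100 genes assigned, 0 unassigned)
wrote 5 condition trees to trees0.xml
wrote 5 condition trees to trees1.xml
top regulator reg_m04 (module 4): score 4.105, null quantile 1.000
```

Each `cluster` line reports one ensemble member's module count and total
Bayesian score (higher = better; run 0 ended in a poorer local mode, which
is exactly what the consensus step absorbs).  The consensus recovers the
five planted modules with every gene assigned.  `scores.tsv` ranks
(module, regulator) pairs by consensus score — here the five planted
regulators take the top five slots, led by `reg_m04` with s = 4.105,
meaning an average posterior near 1 at the root of both trees plus support
at deeper splits (a regulator at the root of one tree with posterior 1
scores exactly 1); its null quantile 1.000 says no random-regulator draw
came close:

```
4   reg_m04  4.105121130061108
1   reg_m01  4.0269825942282775
0   reg_m00  3.4507257340823063
2   reg_m02  3.4284366723332185
3   reg_m03  3.343619445697039
```

`scores.hubs.tsv` aggregates the selected pairs per regulator (number of
modules, summed score) to expose hub regulators.  Every task also writes a
`*.manifest.json` recording its full parameterization, defaults included.

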