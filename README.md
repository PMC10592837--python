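# bcrtrees

Phylogenetic trees for B cell clones from **paired heavy and light chain**
BCR sequences — including the messy reality of mixed single-cell and bulk
data where many cells are missing their light chain.

Single-cell V(D)J sequencing pairs each B cell's heavy (IGH) and light
(IGK/IGL) chain. Because B cells divide clonally, both chains share one
genealogy, so a clone's chains can be concatenated into a single alignment
and analyzed under one tree. But light chains mutate at roughly **half** the
rate of heavy chains, and light chains are often missing (dropout, or bulk
heavy-only reads mixed in). How a tree-building method handles those
N-filled light chains decides whether its branch lengths — the estimated
mutations per site — can be trusted:

* **maximum parsimony** assumes no mutations in missing sites and
  *underestimates* branch lengths;
* **single-partition maximum likelihood** (one GTR model over the whole
  concatenation) implicitly assumes missing light chains mutated as fast as
  heavy chains and *overestimates*;
* a **scaled multi-partition model** — separate heavy/light partitions
  sharing one topology and branch-length set, with light-chain branch
  lengths multiplied by an ML-estimated scalar `c_light` (heavy pinned at 1)
  — learns the rate ratio from cells with both chains and stays accurate.

`bcrtrees` implements all three natively (Fitch/ratchet parsimony,
Felsenstein pruning under GTR, NNI search, per-partition parameters and
scalar), the clone-preparation pipeline that makes paired alignments
well-defined (light-chain subgroup resolution, consensus germlines,
N-filling, duplicate collapsing, matched heavy-only datasets), the
evaluation metrics (RF cluster distance with short-branch collapsing, codon
bootstrap, divergence, percent tree-length error), and a paired-SHM
simulator with 5-mer hot/cold-spot targeting that generates ground truth
for all of it. See `docs/methods.md` for the full model description.

## Worked example

Simulate a clone of 8 cells (light chains at half the heavy mutation rate),
drop the light chains of half the cells, and fit the scaled model:

```python
import bcrtrees as bt

sim = bt.simulate_clone(n_tips=8, rate_ratio=0.5, seed=42)
masked = bt.mask_light_chains(sim, fraction=0.5, seed=7)
aln = masked.to_clone_alignment()          # AIRR records -> CloneAlignment

result = bt.CloneTreeModel(aln).fit(method="ml-scaled", seed=1)
print(result.summary())

truth = masked.true_tree_for(aln)
rf = bt.rf_cluster_distance(result.tree, truth, threshold=0.001)
print("RF cluster distance to truth:", rf.distance)
print("percent tree-length error:",
      round(bt.percent_length_error(bt.tree_length(truth), result.tree_length), 4))
```

Output:

```
Clone tree fit
==============================
clone                    clone1_1
method                   ml-scaled
n tips                   8
alignment length         690
tree length (subs/site)  0.120326
log-likelihood           -1446.0337
light-chain scalar       0.4491
seed                     1
ascent iterations        8
RF cluster distance to truth: 1
percent tree-length error: 0.0976
```

Reading it: the fitted light-chain scalar (0.45) recovers the simulated
half-rate within the noise of one small clone; the tree length in
alignment-wide substitutions/site lands within ~10% of the true (realized
events per site) length — single-clone noise, which averages out over a
clone set — and the topology differs from the truth by a single clade. A single-partition fit of the same alignment
(`method="ml-single"`) overestimates the tree length, and
`method="parsimony"` underestimates it — the missing-data effects the
package exists to quantify.

The same workflow runs from the shell on AIRR TSV files:

```bash
bcrtrees resolve input.tsv resolved.tsv        # light-chain subgroups
bcrtrees format resolved.tsv --out-dir alns/   # concatenated H+L FASTA
bcrtrees build resolved.tsv --method ml-scaled --out-dir trees/
bcrtrees rf trees/clone1_1.nwk truth.nwk --collapse-threshold 0.001
bcrtrees simulate --reps 10 --seed 7 --out-dir sims/
bcrtrees benchmark --config config.yaml --out-dir bench/
```

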