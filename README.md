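# scmatch

Technology-invariant latent-space integration and cell-to-cell matching for
multi-modal single-cell data.

## The problem

Single-cell profiling consumes the cells it measures. When one aliquot of a
sample goes to scRNA-seq and another to CyTOF, every pairwise correspondence
between the two datasets is lost, and the two technologies need not share a
single feature (transcripts vs. protein channels). Yet both aliquots come
from the same cell suspension, so the *distribution* of cell states is the
same on both sides. `scmatch` exploits exactly that assumption to recover
cell-to-cell pairings between technologies with fully disjoint feature sets.

## The method

**1. Shared latent space by adversarial autoencoders.** Each technology `k`
gets an encoder/decoder pair (ψ_k, φ_k): the encoder maps features to a
Gaussian posterior over an 8-dimensional latent space, the decoder
reconstructs features from a latent point (Gaussian likelihood). A VAE is
first trained on one *source* technology by minimizing

    L_vae = −log p_φ(x | ẑ) + β · D_KL(q_ψ(z|x) ‖ N(0, I)),      β = 0.01,

and its codes ẑ_s are frozen. Every *target* technology is then trained
against a single discriminator γ — a binary classifier with spectral-
normalized weights that receives a latent code concatenated with a one-hot
cell-type label (plus a *censored* class for cells whose label is withheld)
and tries to tell source codes from target codes. The target objective is

    L = L_nll(x_t) + β_adv · L_adv(ẑ_s, ẑ_t),

reconstruction plus the loss the encoder incurs when the discriminator
recognizes its codes as non-source; γ is updated after each autoencoder
step. At convergence the technologies are indistinguishable in latent space
and analogous cells lie close together.

**2. Model selection by a kNN divergence.** Adversarial losses of different
runs are not comparable, so latent-space mixing is scored with a
nonparametric symmetric KL divergence estimated from k-nearest-neighbor
distances between the two code clouds (`divergence_score`); configurations
with low divergence *and* low reconstruction error win (`select_model`).

**3. Matching by minimum-cost maximum-flow.** Candidate pairs are the union
of the two directed kNN queries between code sets, weighted by Euclidean
distance. The bipartite graph is extended with (i) sink-arc capacities that
spread the bigger dataset's n cells uniformly over the smaller dataset's m
cells (one-to-many matching, at most ⌈n/m⌉ per cell) and (ii) a densely
connected *null node* whose cost is the p-th percentile of candidate costs,
absorbing cells with no adequate analog. Pushing n units of flow at minimum
cost yields the matching; the flow program is solved exactly (integral
optimum, verified after every solve).

**4. Ground-truth simulator.** A negative-binomial branching-process
generator produces any number of "technologies" from one lineage tree:
per-feature log-means follow Gaussian random walks along pseudotime
(continuous across branch points), counts are NB draws, and independent
program seeds make feature spaces entirely uncorrelated while the underlying
branch/pseudotime structure — recorded per cell — is shared. This is the
test bed for the whole pipeline.

## Worked example

```python
import scmatch

tree = scmatch.make_default_tree()          # 5 branches, lengths 20/15/25/10/30
datasets = scmatch.generate_technologies(
    tree, n_tech=2, n_cells=2000, n_features=64, seeds=[11, 22]
)
cfg = scmatch.IntegrationConfig(vae_epochs=64, scim_epochs=64, seed=5)
results = scmatch.SCIM(datasets, source_index=0, config=cfg).fit()
print(results.summary())

matches = results.match(0, 1, k=16, p=95)
ev = scmatch.evaluate_matches(
    matches,
    labels_s=datasets[0].branch, labels_t=datasets[1].branch,
    pt_s=datasets[0].pseudotime, pt_t=datasets[1].pseudotime,
    n_source=2000, n_target=2000,
)
print(f"branch-label accuracy: {ev.label_accuracy:.3f}")
```

Output:

```
Adversarial latent-space integration
====================================================
technologies:      tech0, tech1 (source: tech0)
latent dim:        8
epochs:            vae=64 scim=64
beta (vae/adv):    0.01 / 50.0
label fraction:    1.0
----------------------------------------------------
technology       recon NLL    div init   div final
tech1               69.047       8.463       7.133
branch-label accuracy: 0.817
```

The summary rows show, per target technology, the reconstruction error of
its autoencoder and the kNN divergence between its codes and the source
codes before and after the adversarial phase — the drop (8.46 → 7.13) is
the integration signal. 81.7% of the matched cell pairs carry the same
ground-truth branch label even though the two datasets share no features;
most mismatches sit at branch points of the tree, where the label is
genuinely ambiguous. At the full study scale (8000 cells, 256 features) the
accuracy rises to ≈0.89–0.96 with pseudotime correlations ≈0.9–0.98.

The same pipeline is scriptable from the shell:

```bash
scmatch simulate --n-tech 2 --n-cells 2000 --n-features 64 --seed 0 --out sim/
scmatch train --source sim/tech0 --target sim/tech1 --seed 0 --out fit/
scmatch match --codes-source fit/codes_tech0.tsv --codes-target fit/codes_tech1.tsv \
              -k 50 --null-percentile 95 --out matches.tsv
scmatch evaluate --matches matches.tsv --truth-source sim/tech0/cells.tsv \
                 --truth-target sim/tech1/cells.tsv --out report.json
```

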