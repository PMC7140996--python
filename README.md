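# taxonet

Does the taxonomic resolution of a plant–pollinator network change what its
structural indices say about it?  Many interaction datasets — citizen-science
records in particular — identify pollinators only to genus or family, yet
almost all network indices are defined and interpreted on species-level
matrices.  `taxonet` implements the full comparison study for this question:
it computes nine widely used bipartite-network indices on the same network
resolved to species, genus, and family, standardizes the nestedness indices
against null models, and tests whether absolute index values and index
*ranks* are conserved as resolution coarsens.

It is aimed at community ecologists who work with plants × pollinators
incidence matrices (binary presence/absence or count-weighted visitation)
plus a taxonomy table mapping each taxon to its genus and family.

## What it computes

For a plants × pollinators matrix `A` (r × c, F links, total weight E):

* **Nestedness** — NODF (pairwise overlap with strictly decreasing fill,
  mean over row and column pairs, in [0, 100]); WNODF (the count-matrix
  variant using strictly decreasing marginal totals); discrepancy **BR**
  (minimal number of misplaced 1s relative to a perfectly nested matrix
  with the same size, links, and row sums); spectral radius **SR**
  (largest eigenvalue of the bipartite adjacency = largest singular value
  of `A`, for binary and weighted matrices alike).
* **Connectance** `C = F/(r·c)`.
* **Modularity** `Q = Σ_ij (A_ij/E − k_i d_j/E²)·δ(g_i, h_j)` (Barber's
  bipartite form), maximized with the DIRTLPAwb+ strategy: label
  propagation, module agglomeration, repetition until convergence, best-of
  over randomized restarts.
* **Robustness** — area under the attack tolerance curve: pollinators are
  removed in random order, plants go extinct when all partners are gone,
  and the surviving-plant fraction is integrated over the
  remaining-pollinator fraction (identity matrix ⇒ exactly 0.5).
* **Normalized degree** quartiles (each taxon's degree over its number of
  potential partners, pooled across guilds).
* **Motif frequencies** — exact induced-subgraph census of the 17
  connected bipartite motifs with up to 5 nodes, normalized within each
  size class.

Nestedness indices are additionally standardized as Z-scores against 500
null matrices: the binary DD model (`p_ij = (d_j/r + k_i/c)/2`) for NODF,
BR and SR_Bin; the RTCA and Patefield `r2dtable` models for WNODF and
SR_Qua.  NODF can also be normalized as `NODF_c = (NODF/maxNODF)/(C·ln S)`
with `S` the geometric mean of the guild richnesses.

The cross-resolution comparison runs a one-way ANOVA per index over the
three levels, Bonferroni-corrected paired post hoc t-tests, and Spearman
rank correlations between levels.  A synthetic-network generator with a
tunable nestedness-strength knob and a built-in species→genus→family
hierarchy supplies reproducible study corpora (41 networks, 10 binary, by
default).

## Worked example

```python
from taxonet import (GeneratorConfig, aggregate, binarize, connectance,
                     generate_network, nodf, null_ensemble, spectral_radius)

cfg = GeneratorConfig(plants_range=(10, 20), pollinators_range=(15, 30), seed=7)
net, tax = generate_network(cfg, 0, weighted=False)
print(f"{net.name}: {net.n_plants} plants x {net.n_pollinators} pollinators")
for level, m in [("species", net),
                 ("genus", aggregate(net, tax, "genus")),
                 ("family", aggregate(net, tax, "family"))]:
    b = binarize(m)
    print(f"{level:>8}: shape={b.matrix.shape} connectance={connectance(b):.3f} "
          f"NODF={nodf(b):.1f} SR={spectral_radius(b):.2f}")
ens = null_ensemble(binarize(net), "NODF", "DD", n_null=500, seed=1)
print(f"species NODF Z-score (DD, 500 nulls): {ens.z_score:.2f}")
```

prints

```
synthetic_000: 15 plants x 28 pollinators
 species: shape=(15, 28) connectance=0.219 NODF=40.7 SR=6.90
   genus: shape=(8, 15) connectance=0.367 NODF=54.1 SR=5.24
  family: shape=(8, 6) connectance=0.562 NODF=69.6 SR=4.54
species NODF Z-score (DD, 500 nulls): 2.98
```

Aggregation merges congeneric (then confamilial) taxa — counts are summed,
presences OR-ed — so the matrix shrinks and densifies: raw connectance and
NODF rise mechanically with coarser resolution, which is exactly why
null-model standardization is needed before comparing nestedness across
resolutions.  The Z-score of 2.98 says this network is strongly nested
relative to degree-matched random expectation.

A command-line layer mirrors the library (`taxonet aggregate | indices |
motifs | zscore | compare | simulate`); `taxonet compare --config run.yaml
--out report/` writes the full long-form index, Z-score, ANOVA, post hoc
and Spearman tables for a study.

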