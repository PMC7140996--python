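# Methods

## Data model and taxonomic aggregation

A network is a labelled plants × pollinators matrix with non-negative
entries; binary matrices hold presence/absence, weighted ones visitation
counts or frequencies.  Rows are always plants.  A taxonomy table maps each
taxon label to its genus and family per guild, with the constraint that a
genus belongs to exactly one family within a guild; matching is exact and
case-sensitive (synonym resolution is the user's job).

Genus- and family-level matrices are *deduced* from the species-level one
by merging rows (and columns) that share the same higher-rank name:
entrywise **sum** for weighted matrices — visitation counts are additive
across congeneric species — and entrywise **OR** for binary ones.  Both
rules are associative, so species→genus→family equals species→family
directly.  Output labels keep first-appearance order.  "Several families"
in the multi-family filter is operationalized as ≥ 2 distinct families in
each guild (configurable).  All-zero rows/columns are dropped only at
filter/aggregation time; index code raises on degenerate input instead of
silently repairing it.

Binary matrices are never re-interpreted as weighted after aggregation:
the OR rule discards multiplicity, so treating its output as counts would
be meaningless.  The weighted indices therefore only ever see matrices
that were weighted from the start.

## Index conventions

* **NODF**: for each ordered line pair with strictly greater fill in the
  first and nonzero fill in the second, the pair term is
  100·overlap/poorer-fill; equal fills contribute 0.  The mean is taken
  over all r(r−1)/2 + c(c−1)/2 pairs.  Lines with zero fill (possible in
  null draws) contribute zero-valued pairs, keeping the denominator
  size-consistent.
* **WNODF**: same pair structure on marginal totals; a pair term is the
  percentage of the poorer line's nonzero cells that are strictly smaller
  than the matching cell of the richer line.
* **Discrepancy (BR)**: candidate perfectly nested matrices pack each
  row's links into a prefix of one shared column order, preserving **row**
  sums (the definition permits fixing either rows or columns; rows are
  fixed here and documented).  BR is the minimal count of observed 1s
  falling outside the packed positions: exact minimization over all
  column orders up to 7 columns, otherwise greedy ordering by decreasing
  column totals refined by hill-climbing swaps of equal-total columns
  (the only place the greedy order is ambiguous).
* **Spectral radius**: largest singular value of the rectangular matrix,
  numerically identical to the largest eigenvalue of the symmetric
  (r+c)×(r+c) bipartite adjacency but cheaper and free of symmetrization
  error.  Works unchanged on binary (SR_Bin) and weighted (SR_Qua) input.
* **Robustness**: pollinators are removed one at a time in uniformly
  random order; a plant goes extinct when its last partner disappears
  (static preferences, no rewiring).  The tolerance curve takes the
  surviving-plant fraction at x_j=(c−j)/c for j=0..c and is integrated by
  the trapezoidal rule, giving 0.5 exactly for the identity matrix and
  1−0.5/c for a full matrix.  The reported value averages 100 random
  removal orders by default (seeded).  Random order is the default and
  only implemented strategy; degree-ordered attacks are out of scope.
* **Normalized degree**: degree over potential partners, pooled across
  both guilds (per-guild pooling would be a trivial variant but is not
  what is implemented), summarized by quartiles with the linear
  interpolation ("type 7") estimator.
* **Modularity**: Barber's weighted bipartite form
  Q = Σ_m [L_m/E − R_m·C_m/E²] over modules m, with L_m the within-module
  weight and R_m, C_m the module's row- and column-total masses.  Plain
  unipartite modularity is undefined on two-mode incidence input, so the
  bipartite form is what "modularity" means throughout this package.  The
  DIRTLPAwb+ search alternates label-propagation sweeps (seeded random
  node order; a move is accepted only if it strictly increases Q, with
  absolute tolerance 1e-12) and greedy agglomeration (merge the module
  pair with the largest positive gain), repeats both until no
  improvement, and keeps the best of 10 restarts (first restart:
  all-singleton rows; later restarts: random row labels).  Ties in Q are
  broken by fewest modules, then first found.  Q ≥ 0 always because the
  single-module partition scores exactly 0 and is used as fallback.
* **Motifs**: the catalogue of all connected two-mode graphs on 2–5 nodes
  with distinguishable sides is generated exhaustively and deduplicated by
  the lexicographically minimal incidence bit-string over within-side
  permutations; this yields 17 motifs (1/2/4/10 of sizes 2/3/4/5) in a
  deterministic canonical order (by node count, then plant count, then
  bit-string).  Occurrences use induced-subgraph semantics — a node subset
  counts for exactly the motif its induced edges form — enumerated exactly
  (no sampling) by ESU-style connected-subset search.  Frequencies are
  normalized within each node-count class.

## Null models and standardization

* **DD** (binary): independent Bernoulli cells with
  p_ij = (d_j/r + k_i/c)/2.  Σp_ij equals the observed fill analytically.
  Draws may contain empty rows/columns; they are retained so every draw
  has the observed dimensions, and NODF/BR/SR evaluate them without
  complaint (zero-fill lines contribute zero pair terms).
* **RTCA** (weighted): the mean of a row-conserving matrix (each row total
  redistributed over its row by a uniform composition, i.e. iid uniforms
  normalized to the row total — the simplest law consistent with
  "a random portion") and the analogous column-conserving matrix.
  Entries are non-negative and the grand total is exact.
* **r2dtable** (weighted, integer counts): uniform contingency tables with
  exactly the observed margins, delegated to
  `scipy.stats.random_table(method="patefield")`; one-row or one-column
  matrices are returned unchanged since the margins force the table.

Z = (observed − null mean)/null SD with the **sample** (n−1) standard
deviation; a zero null SD raises a "degenerate null" error rather than
returning ±∞ (tiny saturated family-level matrices do hit this, and the
pipeline then drops that network from that index's analysis with a logged
reason).  The default ensemble size is 500.  Pairings: NODF, BR, SR_Bin
under DD; WNODF and SR_Qua under both RTCA and r2dtable.

`maxNODF(r, c, F)` is exact (enumeration of all cell placements) for
r·c ≤ 16, otherwise a greedy nested staircase (cells added in order of
increasing (i+1)(j+1)) refined by hill-climbing single-cell moves between
rows, constrained to staircase shapes.  `NODF_c` uses the **natural** log
of S (the geometric mean of guild richnesses); the normalization's source
uses ln, and the choice matters only as a constant factor.

## Comparison design

The study design compares one value per network per level, but the ANOVA
is a plain fixed-effects one-way ANOVA with level as a 3-group factor
(df 2, 3n−3) — the paired structure is deliberately ignored at this stage,
matching the published analyses this package reproduces; pairing enters
through the post hoc paired t-tests (Bonferroni, m = 3, adjusted
p = min(1, 3p)).  Spearman's rho uses average ranks for ties and the
asymptotic t-approximation p-value.  Networks missing a value at any level
for an index are dropped from that index's ANOVA with a logged count.

## Synthetic generator

The generator emulates the statistical silhouette of literature
plant–pollinator matrices, not any particular dataset: per-network sizes
are log-uniform over 7–135 plants and 12–144 pollinators (log-uniform
because published networks skew small); 10 of 41 networks are binary;
connectance is log-uniform in 0.07–0.30; taxa are organized top-down into
3–10 families per guild with geometric-law genus and species richness
(right-skewed, ≥1), all species-resolved.

Presence follows the abundance-rank mixture
p_ij = (1−s)·ρ + s·σ(κ(a_i + b_j − θ)), with abundance ranks a, b
generalist-first, θ chosen so the nested component has expected fill ρ,
and κ = 6/(1 − 0.999s).  Strength s = 0 gives iid Bernoulli(ρ) cells
(whose NODF Z-scores under DD centre near zero); s = 1 gives a hard
threshold, i.e. a packed nested staircase whose NODF approaches the
attainable maximum for its size and fill.  The default s = 0.6 produces
the nested-leaning structure typical of real mutualistic webs.  Empty
rows/columns are given their single most plausible partner (the highest
probability cell) rather than resampled, keeping generation
deterministic per seed.  Weighted networks draw counts conditional on
presence from 1 + NegBin(mean 4, dispersion 0.6).

What the generator does **not** emulate: sampling effort and detection
bias, phylogenetic signal in interactions, forbidden links from trait
mismatch, or the empirical covariance between network size and
connectance.  Tests passing on synthetic corpora therefore validate the
machinery and the design recovery (degrees of freedom, rank-correlation
decay), not the field-data effect sizes of any particular study.

## Problem sizes and runtime choices

The exact motif census is combinatorial in network size, and max-NODF
hill-climbing is expensive on large supports, so `run_pipeline` computes
motif frequencies and NODF_c only when its config opts in
(`include_motifs`, `include_nodf_c`); both operations are fully
implemented and tested at small scale.  The packaged test suite runs the
full 41-network pipeline with 25-draw null ensembles, 50 robustness
sequences and 5 modularity restarts — ensemble-size reductions that leave
the study design (41 networks, 10 binary, three levels) untouched.
Brute-force oracle comparisons run on matrices up to 5×5 (exhaustive
discrepancy and max-NODF) and up to 8 taxa (exhaustive modularity
partitions).

## Known limitations

* BR beyond 7 columns and maxNODF beyond 16 cells are heuristics: BR is
  then an upper bound on the exact discrepancy, and maxNODF restricted to
  staircase shapes can in principle miss non-staircase optima.
* The modularity search is a stochastic heuristic; restarts make the
  reported Q reproducible but global optimality is only verified
  exhaustively at small sizes.
* Robustness assumes static preferences (no rewiring) and uniformly
  random pollinator loss.
* The generator's taxonomy assigns genera to families at random, so
  synthetic family-level matrices are unstructured mixtures of genera —
  adequate for testing aggregation mechanics, not for studying
  phylogenetic structure.
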