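# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `omphylo`. Everything stated here is computed by the code;
the test suite and `scripts/acceptance.py` exercise each claim.

## Substitution model and simulation

Sequence evolution is a reversible continuous-time Markov chain on the 20
amino acids. A model is specified by a symmetric exchangeability matrix
`S` and stationary frequencies `π`; the generator is `Q = S diag(π)` with
the diagonal set so rows sum to zero, rescaled so the expected rate
`−Σ π_i Q_ii` is 1 (branch lengths are then expected substitutions per
site). Two models ship as data files in the PAML `.dat` layout (lower
triangle of `S`, then `π`):

- `lg.dat` — the empirical LG matrix, the workhorse model for deep
  amino-acid phylogenies;
- `poisson.dat` — equal rates and frequencies. Under Poisson the
  transition probability has the closed form
  `P_ii(t) = 1/20 + 19/20·e^(−20t/19)`, which the tests use as an exact
  oracle.

The `.dat` files list residues in PAML order; they are permuted into the
package's alphabetical state order at load time.

Among-site rate variation is the standard discrete gamma: four
equal-probability categories of a Gamma(α, α) distribution, each
represented by its conditional mean (computed from incomplete-gamma
differences), renormalised to exact unit mean. α defaults to 0.7, a
typical value for conserved single-copy protein markers.

Simulation draws root states from `π`, assigns each site one rate
category for the whole tree, and propagates states down each branch with
`P(r_c t) = exp(Q r_c t)` computed by symmetric eigendecomposition. All
generators are pure functions of a `numpy` seed.

## The schematic Firmicutes fixture

The package's reference topology is an 8-tip clade-level skeleton:

```
(Outgroup,((Halanaerobiales,Natranaerobiales),
 (Bacilli,(Clostridia_A,(Clostridia_B,(Peptococcaceae,Negativicutes))))));
```

with envelope states: Outgroup, Halanaerobiales and Negativicutes diderm,
all other tips monoderm. Two distinct non-Peptococcaceae clostridial
clades are required for the loss-count series (5 → 4 → 3) to be
expressible; a single collapsed Clostridia would conflate the slide
positions. Branch lengths (tips 0.15–0.4, internals 0.1) are plausible
deep-phylogeny values chosen once for simulation; they are inputs, not
estimates. The fixture deliberately does *not* model: unequal lineage
sampling, site-heterogeneous (CAT-like) evolution, alignment error, or
indels (gaps arise only from taxon dropping). Tests passing on this
fixture therefore show algorithmic correctness and internal calibration,
not robustness to the systematic biases of real deep phylogenies.

## Supermatrix rules

- Marker filter: absence fraction strictly greater than `max_absent_frac`
  (default 0.5) removes a marker; exactly at the boundary is retained.
  Paralog-flagged and explicitly excluded markers are removed with
  reasons recorded.
- Trimming: a column is dropped when its gap+missing fraction exceeds
  `max_gap_frac` (default 0.2) or its Shannon entropy over residues
  (gaps excluded) exceeds `max_entropy` (default 3.0 bits; the maximum
  possible is log₂20 ≈ 4.32). This is a deliberately simple gap/entropy
  trimmer, not a similarity-matrix trimmer; thresholds are configuration
  values. Trimming runs per marker on the taxa actually present, before
  any `X`-filling.
- Concatenation: taxa missing strictly more than `max_missing_markers`
  markers (default 11, i.e. about a quarter of a 47-marker set) are
  excluded; a taxon at exactly the maximum is kept. Markers are laid out
  in lexicographic id order — the canonical order recorded in the
  partition file — and missing blocks are filled with `X`, which the
  likelihood treats as fully ambiguous.

## Likelihood machinery

Felsenstein pruning with the Γ₄ mixture, vectorised over unique site
patterns. Partial likelihoods are rescaled per pattern at every internal
node with log-scalers carried separately, so the implementation does not
underflow on trees far larger than the bundled examples. Per-category
log-likelihoods are combined by log-sum-exp.

Branch-length optimisation is coordinate-wise bounded scalar search
(Brent, bounds 10⁻⁸–20 substitutions/site, `xatol` 10⁻⁵). One round
performs a post-order pass, then a pre-order sweep in which each edge is
optimised against its outer partial; the edge's outgoing message is
refreshed immediately, making the sweep an exact monotone coordinate
descent. Each edge evaluation is factorised through the eigenbasis
(`Σ_k (O·R)_k e^{w_k r_c t} (L·D)_k`), so a trial length costs one
elementwise pass rather than a matrix product. α is optimised in
alternation on a bounded interval (0.02–100). Convergence is declared
when a full round improves the total log-likelihood by less than `tol`
(default 10⁻³ nats); a warning (not an error) is raised at the round cap.

Candidate topologies arriving without meaningful branch lengths are
initialised to 0.1 before optimisation. For multi-topology site-lnL
matrices α is re-optimised per topology by default; `share_alpha=True`
estimates it once on the first (reference) topology and reuses it — the
CLI's AU stage does this, trading a negligible likelihood difference for
roughly half the runtime.

NNI search scores each neighbour cheaply by re-optimising only the
exchanged edge, accepts the best improving move, then fully re-optimises;
before declaring a local optimum the best non-improving candidate is
fully optimised once as a guard against the cheap score undervaluing a
move. Ties resolve toward the lexicographically smallest bipartition set,
so the search is deterministic.

Bootstrap supports resample columns with replacement and rerun the NNI
search from the input topology per replicate; support is the percentage
of replicate trees containing each input-tree bipartition.

## AU test

Per-site log-likelihoods are resampled (RELL — no re-optimisation) at
scales r ∈ {0.5, …, 1.4} (the conventional grid of the standard AU
implementation), `n_boot` replicates per scale (default 10,000; tests and
the demo config use less). Exact ties for best are split equally. For
each topology the bootstrap proportions are fitted to
`BP(r) = 1 − Φ(d√r + c/√r)` by weighted least squares on the probit
scale, with binomial-information weights `n φ(z)²/(BP(1−BP))`; scales
with BP of exactly 0 or 1 carry no probit information and are dropped
from the fit. `p_AU = 1 − Φ(d − c)`. Degenerate topologies (best in every
replicate at every scale, or never best) short-circuit to p = 1 or 0; if
fewer than two informative scales remain, the BP at r = 1 is reported
with a diagnostic flag.

Calibration at the fixture's signal level (1,000 sites, LG+Γ₄) is checked
by the acceptance suite: across 100 simulated replicates the generating
topology is rejected at the 5 % level in at most 10, and a 2-SPR-wrong
topology has a strictly smaller mean p-value.

## Internode certainty

Gene trees may be partial and, after collapsing branches with bootstrap
support strictly below the threshold (default 70 %), multifurcating. For
a reference split B, each gene tree is restricted to its taxa shared with
both sides of B; it supports B if its restricted split set contains B,
conflicts if it contains a split incompatible with B (a tree with several
conflicting splits contributes each once). With `f₁` the support count
and `f₂` the count of the single most frequent conflicting split,
`IC = 1 − H₂(f₁/(f₁+f₂))` in bits, signed negative when the rival split
is the more frequent; internodes with no informative gene tree are
reported missing, not zero. Limitation: a conflicting split is identified
by its (restricted taxon set, side) pair, so conflict counts aggregate
only across gene trees sharing the same taxon subset; with heavily and
heterogeneously incomplete gene trees the dominant-rival frequency is
conservative (fragmented across subsets).

## Clade sliding

Alternative placements are generated by pruning the clade and reattaching
it on the successive edges of the path from its original attachment point
toward — and finally onto — the other diderm clade's edge, labelling the
positions 1…n outward. Reattachments that re-create an already-seen
topology (which happens when a path crosses a degree-2 root: both rooted
halves of one unrooted edge lie on the path) are skipped rather than
emitted, so the positions are guaranteed pairwise distinct; an error
reports the number of available positions when the path is too short.
The 8-tip fixture offers five positions per diderm clade; a deeper tree
(e.g. a 16-tip caterpillar) offers the full six-per-clade, twelve
alternatives in total.

## Dollo and Fitch parsimony

The envelope character is binary with the outer membrane assumed present
at the root (the outgroup and the deepest lineages are diderm). Under
Dollo (losses only) the minimal labelling is forced: an internal node is
present iff its subtree contains a present tip, so the reconstruction is
unique — each maximal all-absent subtree contributes exactly one loss on
its stem edge, and no tie-breaking is needed. The labelling is asserted
regain-free on every run. `fitch_changes` gives the unconstrained
two-state Fitch minimum (gains allowed) for comparison; it can never
exceed the Dollo count, because the Dollo labelling is itself a legal
unconstrained labelling.

## Synteny detection

Gene content is abstracted to ordered label lists. Labels present in more
than `max_outgroup_frac` of the outgroup are screened out first — a
cluster conserved in the ingroup but absent from the outgroup cannot
contain shared housekeeping background. For each ingroup genome pair the
remaining shared labels are chained into hit windows (consecutive member
hits separated by at most `max_gap` intervening genes, all sub-chains
enumerated, not only maximal runs — a cluster must not be lost because a
longer, less widely conserved chain engulfs it in one pair); window
intersections of at least `min_genes` labels are pooled as candidates.
A genome *covers* a candidate when all its labels occur in one window;
candidates covering at least `min_ingroup_frac` of the ingroup and at
most `max_outgroup_frac` of the outgroup are kept and reduced to maximal
label sets, ordered by size then label string. Order within a block and
strand are not scored, so detection is invariant under genome reversal.
`min_genes` and `max_gap` have no canonical values; they default to 3 and
1 and are configuration-exposed. Sub-window enumeration is quadratic in
run length; the outgroup screen keeps runs short in realistic inputs.

## Problem sizes and determinism

The bundled demo emulates the study conditions at clade level: 47 markers
of 118 aligned columns (≈ 5,500 concatenated sites) on 8 taxa, α = 0.7,
10 % missing taxa per marker, 2 paralogous markers, 47 single-SPR gene
trees. Heavier stochastic checks use 1,000-site alignments with 100
(AU calibration) or 20 (topology recovery) replicates and 2,000 RELL
replicates per scale — sizes at which each check completes in minutes on
one core while keeping binomial error well below the decision margins.
Every stochastic function takes an explicit seed; the CLI threads one
seed from the configuration through all stages and records it in the run
manifest.

## Known limitations

- ML only: no Bayesian/CAT site-heterogeneous inference; conclusions
  about model-misspecification robustness cannot be drawn from this
  artifact.
- NNI-only search can in principle be trapped by local optima that SPR
  search would escape; at the bundled problem sizes the recovery tests
  show this is not limiting.
- The AU fit uses the plain WLS probit fit; no iterative reweighting.
- IC conflict aggregation across unequally sampled gene trees is
  conservative (see above).
- No indel model; gaps in real alignments carry signal that the
  simulator does not emulate.
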