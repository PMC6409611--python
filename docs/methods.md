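# Methods

`cladediv` tests whether two subclades of a virus species have evolved
divergently within a protein-coding gene, and characterises that divergence
three ways: at the protein level (consensus-signature proteotyping), at the
codon level (a clade-partitioned codon substitution model with a
likelihood-ratio test), and at the level of synonymous codon usage (RSCU
with correspondence analysis). A seeded generator produces codon alignments
with known, planted structure so every stage can be validated end to end
without external sequence data.

## The codon substitution model

The substitution process is the Goldman–Yang codon model on the 61 sense
codons of the standard genetic code. Instantaneous rates between codons
differing at exactly one position are

    q_ij = pi_j            synonymous transversion
    q_ij = kappa * pi_j    synonymous transition
    q_ij = omega * pi_j          nonsynonymous transversion
    q_ij = omega * kappa * pi_j  nonsynonymous transition

with all multi-position changes forbidden and the diagonal set so rows sum
to zero. `kappa` is the transition/transversion rate ratio, `omega` the
nonsynonymous/synonymous rate ratio (dN/dS), `pi` the equilibrium codon
frequencies. Stops are excluded from the state space, so simulated data can
never contain a stop codon.

**Clade model C.** Sites fall into three classes with proportions
(p0, p1, p2):

* class 0 — purifying, `omega0 in (0, 1)`, all branches;
* class 1 — neutral, `omega = 1`, fixed, all branches;
* class 2 — divergent: `omega2[k]` on branches carrying clade-partition
  label k (label 0 = background).

The null configuration merges the two focal subclades into one partition
(K = 2); the alternate splits them (K = 3), adding exactly one free
parameter. The test statistic is `LR = 2 (lnL_alt - lnL_null)`, referred to
χ² with df = the parameter-count difference (1 here).

**Parameter counting.** With branch lengths estimated, a fit on an unrooted
binary tree with n taxa and K partitions has

    Np = (2n - 3) + 1 (kappa) + 2 (p0, p1) + 1 (omega0) + K (omega2)
       = (2n - 3) + 4 + K

so 123 and 124 for n = 60 with K = 2 and 3. Codon frequencies are empirical
(F3x4 by default: products of position-specific nucleotide frequencies
renormalised over sense codons; F61 and uniform are selectable) and are not
counted as free parameters. With `fix_branch_lengths=True` the branch terms
drop out; such fits are only comparable with each other.

**Rate normalisation.** All class generators share one global scale: the
site-class mixture rate of the *background* partition,
`R = p0 r(omega0) + p1 r(1) + p2 r(omega2[0])`, where `r(w)` is the
unnormalised flow `-sum_i pi_i q_ii(w)`. Branch lengths therefore read as
expected substitutions per codon on background branches. A per-partition
mixture scale was rejected: it rescales branch time differently per
partition, which converts a divergent-class difference into a whole-gene
rate difference — in particular, data outside a divergent window would no
longer be exchangeable across partitions, corrupting the
window-excision contrast.

**Nesting of the null labeling.** The merged-clade (null) labeling is
derived from the split-clade labeling by merging branch labels
(`phylo.merge_partitions`), never by re-deriving labels from leaf
monophyly. The leaf-monophyly route would place the merged clade's stem
branch inside the focal partition while the split labeling leaves that stem
in the background; the two models would then not be nested and the χ²(df=1)
reference would be invalid. `fit_nested_pair` constructs the null this way
internally.

**Likelihood computation.** Felsenstein pruning, vectorised over unique
site patterns with per-node rescaling. Gap (`---`) and ambiguous codons are
missing data (all-ones partial vectors). Because the GY94 generator is
reversible, P(t) comes from one symmetric eigendecomposition per distinct
omega per evaluation rather than a matrix exponential per branch; the
public `transition_probs` keeps the generic `expm` route. The pruning
likelihood is checked in the test suite against exhaustive enumeration of
internal-node states on small instances, and the spectral propagator
against `expm`.

**Optimisation.** Box and simplex constraints are removed by
reparameterisation (log for kappa, omega2 and branch lengths, a logistic
simplex for the class proportions, logit for omega0); L-BFGS-B with
numerical gradients runs from multiple starts (default 3: omegas at 1,
omegas spread, random) and the best ln-likelihood is kept — the surface is
multimodal. Convergence is the optimiser's relative-change criterion
(`ftol`, default 1e-9). `fit_nested_pair` additionally warm-starts the
alternate fit from the null solution (making `lnL_alt >= lnL_null` hold by
construction) and refits the null from the alternate's collapsed solution,
keeping the better value — one-sided optimisation error would otherwise
inflate the LR.

## Proteotyping

For each alignment column the consensus is the most frequent non-gap
residue (ties broken alphabetically; all-gap columns have consensus `-`
with frequency 0). The signature matrix rewrites each sequence as `.`
(matches consensus), `-` (gap), or the literal residue, with a fixed
residue→color table for display exports — the tabular form of the
white/black/colored alignment figures used in proteotype displays.

Proteotypes are called by single-linkage clustering of pairwise signature
divergence (fraction of columns, non-gap in both sequences, that differ):
two taxa share a proteotype when a chain of pairs each under the threshold
(default 0.10, the 10%-divergence rule) connects them. Clustering is
preferred over distance-to-consensus because a blended consensus lying
~10% from each of two groups would otherwise merge groups that are plainly
distinct pairwise; both quantities are reported. Ids are ranked by cluster
size then first occurrence, so the grouping (not the numbering) is
invariant to row and column order.

`intergroup_identity` reports mean/min/max percent identity over all
cross-group pairs (pairwise-complete columns, 0.1% precision).
`assortment` arranges per-region proteotype ids in genomic order (rows
sortable by an anchor region) and `breakpoints` lists the region boundaries
where a taxon pair flips between sharing and not sharing an id — the
recombination-boundary readout.

## Codon usage bias and ordination

RSCU(c) = family-size × count(c) / family total, over the 59 codons in
multi-codon families (ATG, TGG and stops excluded). Codons of an absent
amino acid are 0 (columns are never dropped; the 59-column contract is
fixed). Correspondence analysis runs on the RSCU matrix (matching the
stated workflow; CA on raw counts is an option): SVD of the standardised
residuals of the table, row/column principal coordinates, per-dimension
inertia fractions; total inertia equals the table's χ² statistic over its
grand total. Group separation in the 2-D embedding is quantified by the
silhouette score — a package-added statistic standing in for the visual
separation judgement.

## The synthetic generator

`SimulationConfig` defaults define the reference study conditions: 14 taxa
(4 background + two focal subclades of 5), a 253-codon gene, a 62-codon
divergent window starting at codon 138, site-class proportions
(0.5, 0.2, 0.3), omega0 = 0.1, omega2 = (1.0, 0.15, 3.5) for
(background, group 1, group 2), tree depth 0.6 expected
substitutions/codon, kappa = 2, uniform codon frequencies at the root.
These sizes mirror a 253-codon viral gene whose 62-codon regulatory
sub-domain diverges between two subclades while the rest of the gene does
not: outside the window the divergent class uses the background omega on
every branch, so excising the window removes the planted signal exactly.
The omega contrast and depth were chosen so the planted window's
inter-group protein identity falls in the mid-50s to 60s percent — strong
but recognisably homologous divergence — and the full-gene LRT is
decisively significant, while staying small enough for a laptop-scale test
suite. Trees are Yule; `simulate_partitioned_tree` joins three Yule crowns
(each scaled to half the total depth) so both focal groups are clades on a
common stem.

Evolution is simulated by exact sampling from P(t) per site per branch (no
event-by-event simulation; alignments are small). All randomness flows from
the config seed; outputs are byte-identical across re-runs.

Codon usage bias is planted post hoc (`plant_codon_bias`): within each
group, each codon is replaced by the group's preferred synonymous codon
with probability `strength`. This changes exactly what RSCU measures and
nothing the dN/dS machinery sees (the protein sequence is untouched), so
the selection and codon-usage experiment axes stay orthogonal.

**What the generator does not emulate:** indels and alignment error (all
simulated alignments are gap-free and correctly aligned), recombination
mosaics across genes (the assortment scan is exercised on constructed
label tables), rate variation beyond the three-class mixture,
non-equilibrium base composition, and mutational codon bias (usage bias is
planted by resampling, not by a mutation model). Passing tests therefore
demonstrate correctness of the algorithms under the model's own
assumptions, not robustness to real-data artefacts.

## Statistical validation in the test suite

* Pruning ln-likelihood equals exhaustive-state enumeration on all random
  instances with ≤4 taxa and ≤3 sites.
* The split-clade fit never falls below the merged-clade fit (nesting).
* Type-I error of the clade LRT: 200 null simulations (shared
  omega2 = 1.5, 4 taxa, 50 codons, branch lengths fixed at truth) must
  reject at 5% ± 3%. The null's shared omega2 is set away from 1 because
  omega2 = 1 coincides with the fixed neutral class, leaving the class
  proportions unidentified and the LRT nonstandard. The scaled-down
  problem sizes here and below are the package's validation conditions,
  chosen to keep the full suite at desk scale.
* Power and specificity: on 20 draws of the reference conditions the LRT
  rejects at alpha = 0.05 in ≥80% on the full gene and in ≤20% after the
  window is excised (the full-vs-excised contrast).
* Proteotype recovery: planted two-group alignments (between-group
  divergence 2.5× the threshold, within-group noise 0.4×) are recovered
  exactly (ARI = 1) in ≥95% of 100 replicates.
* Codon-usage separation: opposite group preferences at strength 0.8 give
  silhouette > 0.5 in the window's RSCU-CA embedding; a shared preference
  (one codon-optimised environment for both groups) gives < 0.25. The
  shared-preference arm, not a no-bias arm, is the correct negative
  control: under neutral synonymous drift the groups share ancestry and
  show genuine (phylogenetic) codon-usage clustering even with no planted
  bias.
* Neighbor joining reconstructs every random additive distance matrix
  (n ≤ 8) exactly, and matches an independent NJ implementation.

## Numerical and design choices

* Coordinates are 0-based, half-open everywhere; codon index =
  column / 3. Region boundaries on codon alignments must be codon
  multiples.
* Consensus ties: alphabetical. NJ ties: lowest index pair in canonical
  taxon order. Negative NJ branch estimates are clamped to zero with the
  deficit moved to the sibling, preserving the pair's path length.
* Bootstrap supports count replicate bipartitions only on branches of
  positive length (a zero-length branch is an unresolved polytomy, not
  evidence); the default collapse threshold is 70% and is configurable.
  Replicate resampling and tie-breaking run in name-sorted taxon order, so
  supports are invariant to input row order at a fixed seed.
* Distance corrections saturate to infinity with a warning (Poisson at
  p ≥ 1, Jukes–Cantor at p ≥ 3/4); NJ refuses non-finite matrices.
* The spectral propagator clips exponents at 0 (generator eigenvalues are
  non-positive; anything above is round-off).
* Proteotype ids for ties in cluster size follow first occurrence in
  alignment order; only the partition, not the numbering, is
  order-invariant.
* RSCU-CA is computed on RSCU values (not counts) by default, matching the
  stated workflow; counts are available via `correspondence_analysis` on
  any non-negative table.

## Known limitations

* The clade-model LRT's χ²(1) reference is asymptotic; at very small
  problem sizes (few informative branches per partition, short genes) the
  finite-sample LR distribution can deviate from χ²(1) in either
  direction. The calibration test pins the behaviour at one scaled-down
  design; it does not certify every design.
* Branch lengths fixed at input values make fits comparable only with
  other fixed-length fits (Np bookkeeping changes accordingly).
* `label_clades` requires at least one background leaf when non-background
  partitions exist (the tree is re-hung on a background leaf to resolve
  monophyly unambiguously on the unrooted topology).
* The proteotype caller treats all non-gap mismatches equally; no residue
  similarity weighting.
* CA axes are defined up to sign; only inter-point geometry is stable.
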