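# Methods

## Model

`tcstalk` implements a genomic-context method for two-component system
(TCS) specificity. Its underlying assumptions are:

* phosphotransfer specificity is carried by the kinase's DHp domain and
  the regulator's REC domain, so domain-level sequence similarity groups
  proteins with shared partner preferences;
* kinase–regulator pairs encoded in one operon are overwhelmingly
  cognate, so operon co-occurrence is usable as interaction ground truth;
* the kinase→regulator relationship is (approximately) one-to-one at the
  family level, so a row-stochastic cluster-to-cluster table is a
  meaningful predictor.

The pipeline is: domain extraction → all-vs-all local alignment →
graph clustering → operon pairing → interaction table → queries.

## Stages, parameters and defaults

**Domain extraction.** A hit qualifies iff its per-domain *independent*
E-value is strictly below the inclusion threshold (default `0.01`); a
hit at exactly the threshold is excluded. The envelope coordinates (not
alignment coordinates) delimit the excised subsequence: the envelope is
the region the model places the domain in with high posterior mass, and
is the robust choice for multi-domain proteins. Proteins with several
qualifying hits yield several instances (`protein/model/rank`); proteins
carrying both a DHp and a REC instance are flagged hybrids. No length
filter is applied to instances.

**Pairwise similarity.** Exact Smith–Waterman with affine gaps replaces
heuristic database search. At the scale this package targets (hundreds
to low tens of thousands of ~60–120-residue domains) exact DP is
affordable, and it is the sensitivity limit of a search run with every
heuristic filter disabled; it also removes seed/word-size free
parameters. Defaults are the classic gapped protein-search parameters:
BLOSUM62, gap open 11, gap extend 1 (a length-`k` gap costs `11 + k`),
λ = 0.267, K = 0.041. The unknown residue `X` scores 0 against
everything. Raw scores convert to E-values by the Karlin–Altschul form
`E = K·m·n·exp(−λS)` with `m` the query length and `n` the total residue
count of the instance set, so each direction of a pair has its own
E-value while the raw score is symmetric (computed once per pair).
Directed edges are kept at `E ≤ 10` (configurable).

**Graph clustering.** Edge weight is the mean of `−log₁₀E` over the two
directions (a missing direction contributes nothing; an E-value of zero,
or below `10^−200`, contributes the cap 200; negative logs floor at 0).
Self-loops are set to each node's maximum incident weight, floored at 1,
which guarantees every column is normalisable and lets isolated nodes
form singleton attractors. The Markov Cluster algorithm then alternates
expansion (`M ← M²`), inflation (entrywise power, default **5**, then
column renormalisation) and pruning of entries below `10⁻⁵` (fixed
threshold rather than adaptive pruning — simpler, and exactness
dominates speed at this scale), until the flow matrix changes by less
than `10⁻⁸` or 200 iterations elapse (non-convergence returns the
current partition with a logged flag). Clusters are the connected
components of the limit matrix's nonzero structure; node ids are sorted
before matrix layout, so the partition is invariant to input order, and
cluster ids are densely renumbered by first appearance along the sorted
node list. Inflation 5 is a fine-grained setting appropriate for
separating specificity-bearing subfamilies; higher inflation gives finer
partitions.

**Operon assignment.** Two ordinally adjacent genes join one operon iff
they lie on the same replicon and strand and the intergenic distance
(`next.start − prev.end − 1`) is at most 200 bp. This deterministic
strand-and-gap model is a standard operational operon definition; it is
oracle-testable by exhaustive enumeration, and the downstream pairing
rule is the binding constraint in any case. Operon ids are globally
dense in genome order.

**Cognate pairing.** A kinase and regulator in one operon with at most
**two** genes strictly between their ordinals form a probable cognate
pair; a kinase flanked by two qualifying regulators yields two pairs.
Intervening genes are counted regardless of their identity. A hybrid
protein pairs with itself at intervening count 0 (flagged) and remains
eligible for cross-protein pairs. Kinases/regulators in no pair are the
orphans.

**Interaction table.** Each cognate pair increments the count at
(kinase's DHp cluster, regulator's REC cluster) once per
(DHp instance, REC instance) combination of the two proteins — the
plainest treatment of multi-domain proteins, switchable to
once-per-protein-pair. Probabilities are row-normalised per DHp cluster
(likelihood over REC clusters); rows with zero counts are explicit
"no prediction" rows, never renormalised.

**Queries.** Partner prediction ranks a cluster row by probability, ties
broken by larger raw count then lower cluster id (fixed so outputs are
reproducible). Cross-talk prediction routes a query (instance id,
protein id, or novel sequence via best local-alignment hit — smallest
E-value, ties by higher score then lexicographic id; no hit at the
cutoff yields an explicit *unassignable* report) to a DHp cluster, then
reports (a) host kinases sharing that cluster, excluding the query
protein itself, and (b) host regulators in the top partner cluster(s)
(default top 1, optional probability floor 0). Substrate-side candidates
are by construction exactly the host members of the clusters partner
prediction returns.

## Synthetic data generator

The generator emulates the statistical structure the method exploits:
per species, each kinase family contributes operons laid out as kinase,
0–2 random decoy genes, partner-family regulator (one strand per operon;
intra-operon gaps 5–150 bp, below the 200 bp threshold; inter-operon
gaps 400–900 bp, above it); planted orphan kinases/regulators sit in
single-gene operons. Families follow a star phylogeny — one random
consensus per family, members are per-residue point mutants (default
5%) — rather than a tree: it is sufficient to control within/between
family identity (≈90% vs ≈5% at the defaults, far beyond the 30-point
margin the tests require) and keeps identity oracles trivial. Domain
hit tables are synthesized directly (each TCS protein is exactly its
domain, one full-length hit at E = 10⁻⁴⁰), decoupling tests from any
external search tool. Default condition: 5 species, 8 + 8 families under
a seeded random bijective pairing, 10 members per family per species,
3 orphan kinases + 3 orphan regulators placed round-robin over species.

The cross-talk scenario (`crosstalk_family`/`crosstalk_host`) omits one
family's regular operons from a designated host species and plants a
single orphan kinase of that family plus a single orphan regulator of
its partner family there; `plant_foreign_tcs` then adds a fresh mutant
of the family consensus under a dedicated foreign species tag. Ground
truth records exactly which host proteins a correct cross-talk report
must name. Ordinary orphans placed in the scenario host step over the
scenario family so the host carries exactly one kinase of it.

What the generator does **not** emulate: realistic amino-acid
composition and BLOSUM-typical substitution patterns, indels, rate
variation across sites, phylogenetic correlation between species,
horizontal transfer, hybrid kinases, shared promiscuous regulator hubs,
and family-size/divergence heterogeneity. Passing the end-to-end tests
therefore shows the machinery is correct and self-consistent under
clean family structure, not that clustering at inflation 5 resolves real
kinase subfamilies; on real proteomes cluster granularity and table
sharpness depend on divergence structure the simulation deliberately
idealises.

## Numerical and design notes

* All randomness flows from one seeded NumPy generator; a fixed seed
  reproduces emitted files byte for byte, and the analysis pipeline
  itself is deterministic (sorted ids everywhere, fixed tie-breaks).
* Column stochasticity is restored by explicit renormalisation after
  inflation and after pruning; pruning cannot empty a column because a
  stochastic column of dimension n has an entry ≥ 1/n ≫ 10⁻⁵ at any
  practical n.
* TSV floats are written at full precision and re-read with round-trip
  parsing, so writer/reader pairs are lossless.
* Problem sizes used by the shipped benchmark and acceptance script
  (≈400 instances per domain class; the cross-talk scenario at 3 species
  × 4 families × 4 members over 5 sub-seeds) were chosen to exercise
  every stage at comfortably interactive runtimes; all thresholds are
  independent of these sizes.
* The per-domain table parser takes the independent E-value column, not
  the conditional one: the conditional E-value is anti-conservative for
  deciding how many domains a protein truly carries.

## Known limitations

* The dense in-memory MCL is O(n³) per iteration; fine to a few thousand
  instances per class, not for genome-collection scale (hundreds of
  thousands). A sparse implementation would be needed there.
* The operon model is deterministic; probabilistic operon scoring or
  transcription-unit evidence is out of scope.
* The method assumes family-level one-to-one kinase→regulator pairing;
  many-to-many signalling (hub regulators, branched phosphorelays) will
  smear table rows and weaken predictions.
* Residue-level coevolution scoring and Bayesian orphan matching are
  different methods entirely and are not implemented here.
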