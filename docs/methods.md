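# Methods

## The resolution criterion

A species is scored *resolved* on a tree when its sampled individuals are
separated from all other tips by a single edge — i.e. they form an
exclusive clade — and that edge's bootstrap support strictly exceeds the
threshold (default 50). Working with edge bipartitions of the *unrooted*
topology makes the decision independent of rooting, which tree viewers
and ML programs choose arbitrarily. Support absent (an edge never
assessed, or `n_replicates = 0`) is distinct from support 0 and never
counts as passing.

Two boundary policies are explicit because they change denominators
materially:

* **Singletons** (species sampled once) are trivially exclusive. The
  default policy counts them as resolved; `singleton_policy="excluded"`
  removes them from numerator and denominator. Both are reported because
  field surveys routinely contain rare species with one collection.
* **Species with no sequence data** for a combination cannot appear in
  its tree; they are recorded as not assessable and excluded from that
  combination's denominator rather than counted as failures.

Rates are aggregated overall, by major clade, by life form, by genus and
by S/G class — the number of *sampled* congeneric species, capped at 5
for reporting. Percentages are rounded to two decimals with ties away
from zero, matching printed-table convention.

## Alignment

*rbcL* and *matK* align globally. The spacers (*trnH-psbA*, ITS) are too
length-variable across families for a single alignment, so they are
partitioned by family, order, or curated merged groups (an override file
maps a merged group to the families/orders it absorbs). Groups are
aligned independently and placed block-diagonally in the merged matrix
with `'?'` elsewhere: columns from different groups are never claimed to
be homologous, and group-local signal still contributes to within-group
relationships in a concatenated analysis.

The aligner is a generic progressive profile aligner — k-mer distances
(k = 6, one minus the shared k-mer fraction of the smaller multiset)
feed a neighbor-joining guide tree, and profiles are merged by
affine-gap (Gotoh) profile–profile Needleman–Wunsch in post-order.
Default scoring: match +2, mismatch −1 (ambiguity codes score as
mismatch unless identical), gap open −5, gap extend −1. Invariant:
removing gaps from any output row returns the input sequence unchanged.
This is not a re-implementation of any published aligner; externally
produced alignments can be imported instead.

## Tree inference

The built-in engine is distance-based: K80 distances
(`d = ½ln 1/(1−2P−Q) + ¼ln 1/(1−2Q)` from transition and transversion
proportions; JC69 and p-distance also available) under pairwise deletion,
then Saitou–Nei neighbor joining with a fixed tie-break (lowest row,
column index) for determinism; negative branch lengths are clamped to
zero with the deficit logged. Saturated or undefined distances are
flagged, never clamped, and block tree building with an explicit error;
the pipeline first prunes rows whose only recovered locus leaves them
with zero aligned overlap against other groups.

Bootstrap resampling draws columns with replacement *within each
partition independently*, preserving per-locus site counts; support for
each internal edge of the tree built from the original columns is the
percentage of replicate NJ trees containing the same bipartition. A
replicate that produces an undefined distance is redrawn and counted.

This engine deliberately substitutes for a full ML search (GTR+GAMMA in
RAxML is what plot surveys typically use): the resolution layer is
engine-agnostic and accepts imported Newick trees with supports, so a
fidelity run on real data can use external ML trees while the built-in
engine keeps the pipeline self-contained and fast. No rate heterogeneity
or model selection is attempted.

## Statistical layer

Resolved counts per (barcode combination, S/G class) cell are modelled
as Poisson with log link and `log(total)` offset, so unequal class sizes
do not masquerade as rate differences; a binomial response is available
as a sensitivity flag. Analysis of deviance is sequential
(null → +barcode → +class → +interaction); with 8 combinations and 5
classes the degrees of freedom are 7, 4 and 28. Pairwise class contrasts
use the fitted coefficient covariance (z = coefficient difference over
its standard error), labelled "j-i" with the larger class first, with
Bonferroni adjustment multiplied by the C(5,2) = 10 comparisons and
capped at exactly 1. The single-step multivariate-t adjustment used by
some GLM multiple-comparison packages is *not* re-implemented; adjusted
p-values can therefore differ from such output in the mid-range (values
at 1 and below 0.001 agree).

The cross-study regression is ordinary least squares of reported
resolution rate on species-to-genus ratio over the packaged comparison
table of floristic barcoding studies, restricted to studies whose
barcode set includes the three plastid core regions (15 of 19 rows).
Which exact study set underlies the published version of this
relationship is not enumerable from the published tables; the restriction
used here is recorded in the code and gives R² ≈ 0.725 with a strongly
negative slope (p ≈ 6×10⁻⁵), against a printed value of 0.731. The table
rows are transcribed reference data; the regression itself is computed
at run time.

## The synthetic community generator

The generator emulates the statistical structure of a plot-scale barcode
survey; it is the test substrate for every downstream stage.

* **Taxonomy.** A genus-size distribution over S/G classes 1–5 (default
  `{1: 100, 2: 18, 3: 7, 4: 6, 5: 4}` → 201 species, 135 genera, mean
  S/G 1.49) with genera assigned round-robin to 64 families; 3 families
  are gymnosperm (monotypic woody genera, as conifers enter such plots).
  A fraction 19/201 of species are singletons; other species carry a
  truncated-geometric number of individuals on [2, 6] (ratio 0.4, mean
  ≈ 2.6, expected total ≈ 491 specimens). The published class
  denominators cannot all be reconciled exactly with the stated species
  and genus totals; the default distribution satisfies the totals and
  stays close to the implied class sizes.
* **Genealogies.** One genealogy shared by the three plastid loci
  (chloroplast linkage) and an independent one for ITS. Both are
  ultrametric in time with fixed, jittered depth tiers — family 0.30,
  genus 0.10, species 0.03, within-species 0.003 expected
  substitutions/site at the base rate — rather than a parameterised
  coalescent: tiers are sufficient to generate monophyly/non-monophyly
  contrasts, which is all the criterion consumes.
* **Life form.** Woody lineages have every branch below the genus node
  scaled by `rate_multiplier_woody` (default 0.5), a single-knob stand-in
  for the slower substitution rates of woody plants. The value is a free
  parameter, not an empirical estimate.
* **Plastid capture.** With probability `p_capture` per multi-species
  genus (per genome; `p_nuclear_share` for ITS), a pair of congeneric
  species with ≥ 2 individuals each has its tips interleaved along an
  ultrametric caterpillar whose coalescences spread from the
  within-species depth toward the species depth — introgressed lineages
  diverged at intermediate times. No single edge then separates either
  species, so inference has genuine signal *against* exclusivity (a flat
  haplotype merge would leave tie-broken noise topologies that bootstrap
  can spuriously support). Truth flags record, per species and genome
  class, whether the criterion can possibly succeed. Capture defaults
  are arbitrary configuration, not literature estimates.
* **Sequences.** K80 along the genealogy (default κ = 2) with per-locus
  relative rates (rbcL 1.0, matK 1.5, trnH-psbA 2.0, ITS 2.5) and
  lengths (552, 750, 450, 600 bp). Recovery probabilities default to the
  sequencing-success rates typical of plot surveys: rbcL 0.9874,
  matK/trnH-psbA 0.9202, ITS 0.8950. No indels are simulated: alignment
  is still exercised (sequences are emitted unaligned) but the aligner's
  gap placement is not stressed by the generator.

All randomness flows from one seed per entry point; the pipeline derives
per-combination bootstrap seeds from the master seed by hashing.

**What passing on synthetic data does and does not show.** Simulated
loci lack indels, rate heterogeneity among sites, base-composition bias,
alignment error and contamination, and the genealogy has no incomplete
lineage sorting beyond the explicit capture events. Recovery of the
designed truth therefore validates the machinery (alignment bookkeeping,
tree inference, the criterion, the aggregation and the GLM), not the
field performance of any barcode.

## Problem sizes and numerical choices

Default test-scale runs use a 50-species community (four full-length
loci, 100 bootstrap replicates, ≈ 1 minute on one CPU); the capture
scenario uses 12 species. The published percentages from real surveys
depend on hundreds of field specimens and thousand-replicate ML searches
and are out of scope for the built-in engine; the import path exists for
such fidelity runs. Other fixed choices: GLM convergence via
statsmodels IRLS (tol 1e-10, max 100 iterations) with a required
converged flag; bootstrap replicates with undefined distances are
redrawn up to 10× the replicate count before erroring; NJ Q-matrix ties
break to the lowest index pair; distance saturation uses the exact
log-argument boundary (≤ 0).

## Known limitations

* NJ + bootstrap is a desk-scale engine; on low-signal data it is more
  conservative than ML and support values are not comparable across
  engines.
* With literally identical sequences within a clade, NJ's deterministic
  tie-breaking yields an arbitrary but stable local topology; the
  generator avoids this regime deliberately (see plastid capture above),
  but real data containing many identical haplotypes should be
  interpreted with care.
* The Bonferroni contrasts are intentionally simpler than single-step
  multivariate adjustments; borderline significance calls may differ.
* The cross-study regression inherits the transcription and the
  study-set reading documented above.
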