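# barcodetree

Tree-based DNA barcode species discrimination for multi-locus plant
community surveys.

## The problem

Inventories of forest dynamics plots increasingly rely on DNA barcodes —
the plastid regions *rbcL*, *matK* and *trnH-psbA* plus nuclear ribosomal
ITS — to identify both the woody and the herbaceous flora. The standard
question is: **which barcode, or combination of barcodes, discriminates the
most co-occurring species?** Under the tree-based criterion, a species
counts as *resolved* when all of its sampled individuals form an exclusive
clade (a monophyletic group) on a tree inferred from the barcode
alignment, with bootstrap support strictly over a threshold (50% by
default). Resolution rates are compared across the eight combinations
R, M, RM, RP, RI, RMP, RMI, RMPI (R = *rbcL*, M = *matK*, P =
*trnH-psbA*, I = ITS), stratified by life form (herbaceous vs woody),
major clade, and the number of sampled congeneric species per genus
(S/G class 1–5), because close congeners — not overall diversity — are
what defeats barcodes.

`barcodetree` implements that full analysis as a reusable pipeline:

* **seqio** — FASTA / metadata-TSV / Newick I/O; supermatrix
  concatenation with RAxML-style partition files, `'?'`-filling specimens
  that miss a member locus;
* **msa** — group-wise progressive alignment (global for the coding loci;
  partitioned by family/order/curated groups for the length-variable
  spacers, merged block-diagonally so cross-group columns are never
  treated as homologous);
* **phylo** — p/JC69/K80 distances with pairwise deletion, deterministic
  neighbor joining, partition-respecting nonparametric bootstrap, and an
  import path for externally computed ML trees (Newick with supports);
* **resolution** — the monophyly-with-support criterion evaluated as an
  edge bipartition of the unrooted tree, with the stratified rate tables
  and threshold sweeps;
* **stats** — Poisson GLM (log link, `log(total)` offset) over
  resolved-count cells with analysis of deviance and Bonferroni-adjusted
  pairwise class contrasts, plus the cross-study linear regression of
  resolution rate on species-to-genus ratio;
* **simulate** — a synthetic multilocus community generator (nested
  taxonomy, shared plastid vs independent nuclear genealogies, K80
  sequence evolution, per-locus recovery failure, woody rate slowdown,
  plastid-capture events with per-species truth flags) so every stage is
  testable without any sequence download.

## Worked example

Simulate a small clean community and run the whole analysis:

```bash
cat > config.yaml <<EOF
seed: 7
simulate: {n_singleton_genera: 6, n_pairs: 2, length_scale: 0.3, recovery: 1.0}
tree: {bootstrap: 25}
EOF
barcodetree run --config config.yaml --out results/
```

prints

```
overall resolution by combination:
      R: 90.0%
      M: 100.0%
     RM: 100.0%
     RP: 100.0%
     RI: 100.0%
    RMP: 100.0%
    RMI: 100.0%
   RMPI: 100.0%
```

— every multi-locus combination resolves every species, which is the
generator's designed ground truth for a clean community, while the
single slowest locus at this reduced length (`length_scale: 0.3`,
~165 bp of *rbcL*) leaves one of ten species under the 50% support
threshold: exactly the single-barcode-versus-combination gap the
analysis exists to measure. (At full locus lengths all eight
combinations reach 100%; that case is what the acceptance script runs.)
`results/` then holds per-locus
alignments, per-combination supermatrices with partition files,
bootstrapped Newick trees, per-species and stratified resolution tables,
GLM deviance/contrast tables, report grids (combination × S/G class,
combination × life form), and a manifest with content hashes so a re-run
with the same seed is byte-identical.

The interesting cases are the designed failures. With
`simulate: {p_capture: 1.0}` congeneric species pairs share plastid
haplotypes (plastid capture after hybridization): every plastid-only
combination (R, M, RM, RP, RMP) leaves those pairs unresolved, while any
ITS-containing combination (RI, RMI, RMPI) resolves them — the mechanism
by which hybridizing woody genera such as *Salix* or *Cotoneaster* defeat
plastid barcodes.

The cross-study regression uses the packaged comparison table of
floristic barcoding studies:

```bash
barcodetree regress
# n=15 slope=-25.45 R2=0.725 p=5.7e-05
```

i.e. across plot- and regional-scale studies using the three plastid core
barcodes, each additional unit of species-to-genus ratio costs about 25
percentage points of species resolution.

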