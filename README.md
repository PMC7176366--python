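# abyssminer

Anchor-enzyme directed mining of abyssomicin-like biosynthetic gene
clusters (BGCs), for natural-product genomicists who want a
reproducible, scriptable version of a workflow that is usually done by
hand: screen proteomes for Diels–Alderase homologs, reconstruct the
gene neighborhood around each hit, classify the candidate cluster, and
ask where such clusters live (habitats) and how they move (horizontal
transfer).

The abyssomicins are spirotetronate polyketides whose biosynthesis
requires a [4+2]-cycloaddition enzyme (a Diels–Alderase: AbyU, or its
homologs AbsU/AbmU).  Because almost nothing outside these pathways
resembles that enzyme, it works as a *pathway-specific anchor*: one
significant homolog is strong evidence of an abyssomicin-related
cluster nearby.  `abyssminer` implements the full chain:

1. **Screen** — exact Smith–Waterman local alignment (BLOSUM62, affine
   gaps 11/1) of every protein against the anchor queries; raw scores
   become bit scores via the gapped Karlin–Altschul calibration
   `bit = (λS − ln K)/ln 2` (λ = 0.267, K = 0.041) and hits must pass
   `E = m·n·2^(−bit) < 10⁻⁶` over the searched set.
2. **Delimit** — genes flanking the anchor are labeled against a
   reference catalog of aby/abs/abm cluster genes (identity ≥ 0.30,
   reference coverage ≥ 0.50); the candidate grows outward until 4
   consecutive genes fail to label, then is trimmed to labeled ends.
3. **Classify** — a completeness verdict (abyssomicin / potential
   abyssomicin / potential BGC / not a BGC / not enough data, each
   total or partial depending on contig edges and truncated genes) and
   a synteny type (1a, 1b, 2a, 2b, 3, 4, or the no-synteny fallback 5)
   from declarative gene-order motifs, plus transposase/integrase
   proximity flags at ±10 kb.
4. **Compare** — habitat tallies of anchor-positive samples and
   two-sided Mann–Whitney U tests (exact for small tie-free samples)
   of taxon abundance and sequencing depth between positive and
   negative metagenome cohorts.
5. **Trace** — progressive alignment of the hit proteins, p-distance
   neighbor-joining gene trees, Robinson–Foulds distance to a species
   tree, and a genus-level sister-clade screen that flags
   horizontal-transfer candidates.

A first-class synthetic-data module generates every input the pipeline
reads — planted clusters of all seven synteny types, metagenome cohorts
with configurable effects, species trees with simulated gene transfers
— together with ground truth, so each stage is tested by parameter
recovery.  See `docs/methods.md` for models, parameters and
limitations.

> The shipped reference catalog and anchor FASTA contain **synthetic
> placeholder sequences** (the published reference proteins are in
> non-redistributable supplementary material).  For real mining,
> supply your own catalog FASTA keyed by the same labels.

## Worked example

Simulate a small cohort (two genomes with planted clusters, two
without), then mine it:

```sh
abyssminer simulate --preset small --seed 11 --n-genomes 4 --out demo
abyssminer mine --proteome-dir demo/proteomes --features-dir demo/features \
    --catalog-entries demo/catalog_entries.tsv \
    --catalog-fasta demo/catalog_proteins.faa --out demo_out
```

prints

```json
{
  "n_genomes": 4,
  "n_positive_genomes": 2,
  "n_abyssomicin_or_potential": 2,
  "category_histogram": {
    "abyssomicin_total": 2,
    "anchor_negative": 2
  },
  "percent_positive_with_bgc": 100.0,
  "n_anchor_hits": 2
}
```

Two genomes carried a Diels–Alderase hit (`n_positive_genomes`), both
of their neighborhoods classified as complete abyssomicin BGCs
(`abyssomicin_total`), and 100% of anchor-positive genomes therefore
display an abyssomicin-or-potential BGC.  Per-genome detail lands in
`demo_out/report.tsv`:

```
genome_id  n_anchor_hits  category           cluster_types  mobile_flags
genome0    1              abyssomicin_total  1a             none
genome1    0              anchor_negative
```

— genome0's cluster matched the type-1a synteny motifs (tetronate
operon abyA1–A5 next to abyU upstream of the PKS genes, conserved
abyC→abyW block downstream) with no mobile element within 10 kb.  The
anchor hits table (`demo_out/anchor_hits.tsv`) records the alignment
evidence per hit:

```
genome_id  protein_id              anchor  bit_score  evalue     identity  coverage
genome0    genome0_planted_3_abyU  AbyU    274.25     1.76e-77   1.0       1.0
```

`abyssminer stats --metadata demo/metadata.tsv --out demo_out/stats.json`
adds the habitat tallies and the cohort U tests, and
`abyssminer phylo` builds the gene tree and transfer flags from a hit
FASTA, a species tree (newick) and a leaf→genus table.  All
subcommands are thin wrappers over the library
(`abyssminer.pipeline`, `abyssminer.stats_habitat`,
`abyssminer.phylo`), which is the better entry point from Python.

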