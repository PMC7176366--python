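# Methods

`abyssminer` re-casts an anchor-enzyme directed mining workflow — find
Diels–Alderase homologs, reconstruct the gene neighborhood around each
hit, decide whether it is an abyssomicin-type biosynthetic gene cluster
(BGC), and ask how such clusters are distributed across habitats and
lineages — as a deterministic, testable pipeline.  This note documents
the models and procedures, the parameters that matter, and what the
synthetic-data experiments do and do not establish.

## Anchor screening

The Diels–Alderase (AbyU and its homologs AbsU/AbmU) catalyzes the
[4+2] cycloaddition that builds the spirotetronate core and has
essentially no close homologs outside these pathways, which makes it a
pathway-diagnostic anchor: a significant hit is strong evidence that an
abyssomicin-related cluster is (or was) nearby.

Screening uses an exact Smith–Waterman local alignment with affine gaps
(BLOSUM62; gap open 11, extend 1, so a gap of length *k* costs
11 + *k*).  Raw scores are converted to bit scores with the standard
gapped-BLOSUM62 Karlin–Altschul constants, `lambda = 0.267`,
`K = 0.041`:

    bit = (lambda * S - ln K) / ln 2,      E = m * n * 2^(-bit)

where *m* is the anchor length and *n* the summed length of the
searched protein set.  No length correction is applied to the search
space; the point is a *monotone, interpretable* score, not byte-level
parity with any particular BLAST release (the server defaults behind
the original screen are not reconstructible).  The screening threshold
is `E < 1e-6`, two-sidedly safe at these search-space sizes: a random
300-residue protein pair peaks around 40–60 raw (about 20 bits), while
the threshold at *m·n* ≈ 10^7 demands roughly 43 bits.

Each protein reports at most one hit — its best-scoring anchor, ties
broken AbyU > AbsU > AbmU — but a genome may contribute several hit
proteins; paralogs are carried forward as separate candidates and
re-merged only if their delimited spans overlap (keeping the
lower-E-value anchor).

The dynamic-programming kernels (local, global, and profile–profile)
are numba-compiled; traceback ties resolve diagonal > up > left, making
reported spans, identity and coverage deterministic.

## Reference catalog and gene labeling

The catalog carries one labeled reference protein per known cluster
gene: 27 `aby` labels (the published gene inventory plus abyK/abyM/abyN,
which appear in the cluster maps and synteny descriptions), the
`abs`- and `abm`-specific genes, and mobile-element references
(transposase, integrase).  Role classes: PKS (abyB1–B3), tetronate
(abyA1–A5), diels_alderase (abyU/absU/abmU), regulator, transport,
tailoring, other.

The shipped reference sequences are **synthetic placeholders**
(`data/catalog_proteins.synthetic.faa`), generated at a fixed seed with
pairwise global identity below 25%; the published reference proteins
live in supplementary material that is not redistributed here.  Users
mining real data must supply their own FASTA keyed by the same labels —
every algorithm is sequence-agnostic.

A gene is labeled with the best-scoring catalog entry that aligns at
**identity ≥ 0.30** within the aligned region and covers **≥ 0.50 of the
reference** (both configurable in the catalog file; the conventional
floor for confident homolog calling).  Genes failing both are
`unknown`; genes without a linked protein are `unknown` but never
dropped.

## Cluster delimitation

The original workflow delimited clusters with an interactive
cluster-prediction service plus manual curation; that is not
reproducible as computation, so delimitation here is an explicit,
tunable rule.  Starting from the anchor gene, up to `flank_probe = 30`
genes on each side are labeled; the candidate extends outward while
fewer than `max_gap_genes = 4` consecutive genes are unknown, then is
trimmed so its first and last genes carry catalog labels.  Edge flags
are set when the span comes within 1 kb of a contig end.  Orientation is
normalized to catalog reading order: when the PKS block (or, absent
one, the anchor) lies on the minus strand, the gene list is reversed,
so "upstream of the PKS genes" always means *before the PKS block in
the block's transcriptional direction*.

The candidate's PKS block is the longest contiguous run of PKS labels;
equal-length runs are ranked by the PKS density of their ±3-gene
neighborhood (the real PKS operon clusters its genes even when one is
mislabeled) and then by position.

## Completeness classification

Each candidate receives exactly one category; the decision procedure is
first-match-wins:

1. **not_enough_data** — fewer than 5 genes, or contig shorter than
   15 kb (a contig too short to say anything).
2. **not_a_bgc** — no PKS, no tetronate gene, and fewer than 5 catalog
   labels.
3. **abyssomicin_{total|partial}** — biosynthetic core present (≥ 1 PKS
   gene, ≥ 3 of abyA1–A5, the anchor) and ≥ 80% of the anchor's source
   cluster's gene labels recovered.
4. **potential_abyssomicin_{total|partial}** — core present, label
   recall below 80%.
5. **potential_bgc_{total|partial}** — ≥ 5 clustered catalog labels
   without the core.

`_partial` fires whenever any contig-edge flag or per-gene truncation /
internal-stop flag is set; truncation detection is annotation-driven
(the data model stores no nucleotide sequence, so frameshifts must be
declared by the annotation).  The 80% recall bound that separates
"abyssomicin" from "potential abyssomicin" quantifies a judgement the
original analysis delegated to curation; it is exposed in
`CompletenessRules`.  Quartromicin/tetronomycin/chlorothricin clusters
collapse into an `other_tetronate` fallback that only fires when a user
supplies a secondary catalog — the shipped catalog cannot distinguish
them.

## Synteny typing

The seven cluster types are prose descriptions of conserved gene-order
motifs.  Each type is encoded as a motif list over the
orientation-normalized label sequence; a type is *eligible* when all
its mandatory motifs hold, and among eligible types the one satisfying
the largest fraction of its motifs (mandatory + optional) wins, ties to
the lower type number.  Type 5 — no synteny with any other type — is
the fallback, taken exactly when no type's mandatory motifs are all
satisfied.

The prose was quantified once, as config keys (`SyntenyRules`):

* "next to / nearby" → within 5 genes;
* "followed by" → within 2 genes;
* "punctual rearrangements" → at most 2 labels out of the reference
  order, measured as shared labels minus the longest increasing
  subsequence of their reference ranks;
* a conserved block claim needs ≥ 6 shared labels (absence tolerates
  ≤ 2);
* "entire operon" on a given side → ≥ 3 of abyA1–A5 there; the type-3
  adjacent run needs ≥ 4 operon genes with at most one intervening
  gene between consecutive members.

Two robustness choices deserve explanation.  Single mislabeled or
dropped genes are common in real annotations, so motifs whose truth
hinges on one gene are kept out of the mandatory sets where the
remaining motifs still separate the types: abyN (the type-2 signature)
discriminates through the score rather than as a veto, and the anchor
gene always keeps its Diels-Alderase label (its identity comes from the
screening hit, not from catalog labeling — this is also what the
candidate's invariant requires).  With these choices, noise-free
arrangements of all seven types classify perfectly, and at 5% per-gene
label noise (random relabel or drop) typing stays above 95% correct;
the residual errors are cases where the noise removes precisely the
discriminating evidence (e.g. the type-4 abyB1 flank), where falling
back to the best-supported remaining type is arguably the right answer.

Mobile-element proximity mirrors the genomic-island analysis at its
±10 kb window: a transposase/integrase label inside the candidate span
→ `inside_bgc`; within 10 kb of the span → `near_bgc` (reported as
`near_anchor` when the candidate is a lone anchor); otherwise `none`.
Sequence-composition island inference (GC skew and the like) is out of
scope.

## Habitat statistics

Samples carry a two-level habitat path; level 1 is the closed set
{aquatic, terrestrial, engineered, host_associated} and level 2 the
figure-level categories (soil, plants, arthropoda, mammals, annelida,
lichen, bioreactor, …), shipped as extendable YAML.  Tallies report
count and fraction per category; fractions sum to one and rounding
happens only at presentation.

Cohort comparison reproduces the study design: a seeded sample of 50
anchor-positive metagenomes against 50 aquatic and 50 terrestrial
anchor-negative metagenomes, comparing relative abundance of Bacteria
and Actinobacteria and assembled depth with the Mann–Whitney U test.
U is computed from midranks; the exact null distribution is used
whenever max(n1, n2) ≤ 20 with no ties, otherwise a normal
approximation with tie-corrected variance and continuity correction.
The alternative is two-sided throughout, and no multiple-testing
correction is applied across the six comparisons — both choices are
recorded in the report metadata because the original analysis states
neither.  The exact p-values delegate to scipy's implementation and are
verified in the suite against a complete enumeration of group
assignments to 1e-12.

## Phylogenetics and transfer flagging

Anchor-hit proteins are aligned progressively: pairwise global
alignments give an identity distance matrix, average-linkage clustering
fixes the merge order, and groups merge by profile–profile alignment
under the same scoring scheme (alignments only ever insert gaps, never
edit residues).  Distances are p-distances over gap-free column pairs —
transparent and sufficient for topology-level incongruence; a Poisson
correction (−ln(1−p)) sits behind a flag.  Trees are built with
Saitou–Nei neighbor joining: Q-matrix selection with
lexicographically-smallest-pair tie-break, standard branch lengths,
negative branches clamped to zero with the deficit moved to the sister.
On additive matrices the output reproduces the input distances to
1e-9 and recovers the generating topology for every 5-taxon tree.

Incongruence with a user-supplied species tree (the concatenated-marker
pipeline that produced the original species tree is out of scope) is
quantified two ways: the Robinson–Foulds bipartition distance, and a
per-leaf genus-level screen that flags a leaf as a horizontal-transfer
candidate when its gene-tree neighborhood contains no member of its own
genus while its species-tree neighborhood is monogeneric for that
genus.  "Neighborhood" is the smallest subtree adjacent to the leaf's
attachment node on the unrooted view, which makes the rule independent
of where the rooted representation happens to put the root.  This is a
deliberate formalization of a qualitative argument — not a
duplication-transfer-loss reconciliation — and is recorded as such in
the output.

## The synthetic universe

The generators produce every input the pipeline reads, plus ground
truth sufficient to score each downstream decision.  All output is a
pure function of a `GeneratorConfig` (seed included); distinct
operations draw from decoupled seeded streams so, e.g., catalog
references and background genes can never coincide.

* **Catalog/proteins** — i.i.d. uniform residues over the 20 amino
  acids (simplest null), lengths 150–450 aa by default, pairwise
  identity < 25% enforced by resampling.  Mutation is substitution-only
  by default, which keeps identity ≈ 1 − rate analytically; an indel
  mode (for stress tests) exists.
* **Planted clusters** — one canonical template per synteny type,
  constructed to satisfy exactly that type's mandatory motifs; type 5
  is rejection-sampled to violate all of them.  Genomes place a
  configurable number of random background genes (default 60) and the
  planted arrangement on one contig with 50–500 bp intergenic gaps;
  minus-strand plantings are laid down in reverse coordinate order so
  strand-direction reading recovers the template.  An optional
  truncation splits one planted gene at its midpoint across a contig
  break, truncating its protein and flagging both halves.
* **Cohorts** — positives draw habitats from the reported positive mix
  (soil 0.31, plants 0.68, arthropoda 0.01); negatives from the survey
  pool mix (aquatic 0.27, soil 0.31, plants 0.22, engineered 0.10,
  mammals 0.10).  Abundances are Beta-distributed (baseline means:
  Bacteria 0.70, Actinobacteria 0.08, concentration 20) with additive
  positive-cohort effects (defaults +0.10 Bacteria, +0.20
  Actinobacteria); depth is log-normal (log10 mean 9.4, sd 0.30) with a
  +0.4 log10 positive shift.  The effect sizes are not reported
  quantities — they are chosen so the positive/negative contrast is
  clearly detectable at the study's cohort sizes, mirroring its
  qualitative finding.
* **Transfer scenarios** — 12 taxa in four monogeneric clades
  (within-genus branches 0.02–0.06, backbone 0.06–0.12 substitutions
  per site), a 300-residue gene evolved along the species tree by
  per-branch substitution; the recipient's gene instead evolves from
  the donor genus' stem ancestor (branch 0.03), so the gene tree moves
  the recipient while the species tree does not.

What passing these experiments shows — and what it does not: the
synthetic universe has no sequencing error, no assembly chimera, no
codon-level evolution, no compositional bias, and its "unrelated"
proteins are far more random than real unrelated proteins.  Recovery
rates on it validate the *logic* of screening, delimitation,
classification and flagging under controlled corruption; they are not
estimates of performance on real genomes, where annotation quality and
reference completeness dominate.

## Problem sizes and determinism

The default test suite and the acceptance script scale the simulations
to keep runs quick and deterministic: reference proteins of 60–130 aa
and backgrounds of 8–16 genes for the alignment-heavy recovery suites
(the properties under test do not depend on sequence length), 20 seeds
per cluster type, 100-seed transfer experiments, 2000-replicate null
calibration, and 10 000-sample habitat tallies.  Generator *defaults*
remain at the study conditions (150–450 aa references, 60-gene
backgrounds, 50-sample cohorts).  Every random draw in the package goes
through a seeded generator; reports embed their config hash and seed,
and rerunning with the same inputs reproduces them byte-for-byte
(modulo no timestamps: reports carry none).

## Known limitations

* Threshold parity with the original hit list is explicitly not
  claimed; the screen is calibrated for monotone consistency, not for
  reproducing a 2019 database snapshot.
* Cluster boundaries come from the gap-bounded extension rule; where
  they would differ from curated boundaries is unknowable without the
  curation itself.
* Frameshift/pseudogene detection is annotation-driven only.
* The HGT screen is genus-level sister-clade discordance; it cannot
  distinguish transfer from deep paralogy or incomplete lineage
  sorting, and gives no support values.
* The completeness engine's `other_tetronate` class requires a
  user-supplied secondary catalog to ever fire.
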