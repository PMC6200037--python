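# Methods

## The analysis in one paragraph

A panel of bacterial strains is scored for a binary growth phenotype
(growth with methionine as sole sulfur source, defined as mean OD600 ≥
1.0 over triplicates). Their annotated genomes are clustered into
ortholog families from protein sequences; each family's
presence/absence pattern is tested against the phenotype with a
two-sided Fisher exact test and Benjamini–Hochberg correction. The
candidate three-gene cysteine-synthesis cluster is then located in every
genome by a windowed synteny search, classified as chromosomal or
plasmid-borne, and put in phylogenetic context: a core-genome
neighbor-joining tree with bootstrap supports, a gene-cluster tree, a
gene-content dendrogram, and a conservation/transposase profile of the
cluster's genomic neighborhood. Incongruence between the cluster tree
and the core tree, plasmid localization, and transposase flanks are the
evidence pattern for horizontal transfer.

## Synthetic panels: what they emulate, and what they do not

The generator (`genetrait.simulate`) produces panels with the structure
the analysis assumes, so every stage can be scored against planted
truth:

- **Strain phylogeny.** An ultrametric pure-birth (Yule) tree whose
  root split defines two subpopulations; the group-2 fraction defaults
  to 17/62, giving 7 of 24 strains. Crown height is normalized to 1 and
  scaled by `core_substitution_rate` (default 0.02 expected
  substitutions/site root-to-tip), a realistic within-species depth.
- **Core genome.** 200 families present in every strain, evolved along
  the tree under Jukes–Cantor substitution. Start and stop codons are
  held fixed and internal stops arising from substitution are repaired
  (first base T→C), so homologs stay gap-free, equal-length and
  translation-safe — which is why no alignment step is needed anywhere.
- **Accessory genome.** 600 families assigned to one of two gene pools;
  a family is present in a strain of its own pool with probability 0.90
  and in the other pool with 0.15. The high in-pool prevalence makes the
  pools cleanly separable in shared-gene counts while keeping incidental
  association between accessory families and the phenotype negligible
  (the dangerous pattern — presence in all 8 non-growers but almost no
  growers — has per-family probability ~3e-5; see Limitations).
- **The causal cluster.** Three genes (933, 1140, 669 nt — plausible
  sizes for the three enzymes) descend from one ancestor into two
  versions by mutating disjoint random codon sets, so the realized
  inter-version protein identity is exactly the configured 0.70 up to
  alignment effects. Version A sits on a plasmid carried by every
  group-2 strain; version B is chromosomal in 9 group-1 strains; both
  are flanked by transposase-annotated genes, and every strain carries
  a few transposase copies elsewhere (so the transposase families are
  panel-wide and carry no phenotype signal). Within a version, copies
  differ only synonymously (recent acquisition; protein identity 1.0,
  nucleotide variation for the cluster tree).
- **Phenotype.** Growth = cluster carriage. Growers draw OD600
  triplicates from Normal(1.6, 0.15), non-growers from Normal(0.3,
  0.10), truncated at 0 — the threshold rule then reproduces carriage
  exactly (asserted at generation time). One non-carrier receives a
  homolog of the *cysE*-like gene only (15% of residues mutated from
  the ancestor, ~0.72 identity to either version), reproducing the
  observed exception pattern where the serine acetyltransferase alone
  does not confer growth.
- **Decoys.** Two non-carriers receive homologs of all three genes at
  ~0.45 protein identity to version B — above the homology-search floor
  (0.4), below the permissive ortholog threshold (0.5) — placed either
  scattered (every pairwise span forced > 20 kb by filler genes) or
  contiguous in a non-matching order (ctl–cysK–cysE, which is neither
  the query order nor its reversal). They exercise both rejection
  criteria of the locator without contaminating the association test.
- **Intergenic spacing** is uniform 50–400 bp; gene lengths are uniform
  300–1500 nt in codon multiples; strands are random per family. These
  are modeling choices, not inferences about real genomes.

Everything derives from a single seeded `numpy` generator; identical
configurations reproduce identical bytes on disk.

Not emulated: indels and real alignment uncertainty, assembly
fragmentation, genomic islands, rearrangements beyond the decoys,
paralog expansion beyond transposases, and any phenotype noise at the
OD threshold. Passing tests therefore demonstrate correctness of the
computational chain under clean annotations — not robustness to
assembly or annotation error in real data, where the search would also
have to tolerate missed or truncated CDSs.

## Ortholog clustering

Families are single-linkage connected components of the graph joining
gene pairs with global-alignment protein identity ≥ T
(Needleman–Wunsch, match +1, mismatch 0, linear gap −1; identity =
matches / alignment length, computed on the sorted pair for exact
symmetry). Two stringencies bracket the granularity of the common
tools: permissive T = 0.50 merges the two cluster versions (one family
per gene), strict T = 0.95 splits them. Both thresholds are parameters.

Single linkage was chosen over Markov clustering deliberately: it is
deterministic, has a brute-force oracle (all-pairs components), and
reproduces the merge/split contrast that matters here; an inflation
parameter would add nothing testable.

Scaling: candidate pairs must share at least 6 amino-acid 5-mers
(pairs at the permissive threshold and usual gene lengths conserve ~10+
in expectation; unrelated proteins essentially never reach 6). For
equal-length candidates the ungapped identity is checked first — it is
a provable lower bound on the alignment identity under this scoring, so
a pair that clears the threshold ungapped is an edge without running
the aligner. Pairs already connected are skipped; neither shortcut can
change the components. The exact all-pairs path
(`use_prefilter=False`) is what the tests compare against. Family ids
are the lexicographically smallest member gene id, so they are stable
across runs.

At the default substitution depth, strict-mode clustering splits a
fraction of core families between the two subpopulations (pairwise
protein divergence can exceed 5%), so the strict "core" is smaller
than the generated core count; the permissive matrix contains all 200
core families as full columns. The pipeline mirrors the two-tool
design of the study: association runs on permissive families, pan/core
accounting, gene content and the core tree on strict families.

## Association testing

The two-sided Fisher p-value uses the point-probability (minimum
likelihood) convention — the sum of hypergeometric probabilities of all
tables at fixed margins whose point probability is ≤ the observed
one — computed in exact rational arithmetic (`fractions.Fraction` over
integer binomials), so ties are exact and no continuity correction or
pseudo-count enters. This matches `scipy.stats.fisher_exact`'s
two-sided convention, which the tests use as an independent oracle,
alongside exhaustive enumeration for all 5,550 tables with margins
≤ 12.

BH adjustment is the standard step-up with an optional `m_override`, so
a handful of presence patterns can be adjusted as if they sat at the
top ranks of a larger test family (the worked example uses m = 5406).
Significance is strict: `q < alpha`. Adjusted values are cross-checked
against `statsmodels` when m equals the number of tests. Note the BH
step-up is not idempotent (reapplying it to adjusted values inflates
them); only the one-pass values are meaningful.

## Cluster location

Search is against annotated proteomes, not six-frame translation —
simpler, and complete for annotated (here: synthetic) genomes; this is
a documented assumption for real inputs. The 20 kb window is measured
as the full genomic span (leftmost hit start to rightmost hit end,
inclusive), the strictest natural reading; order is checked on the
start-sorted query labels and accepts the exact reversal, since a
cluster on the opposite strand is the same cluster. Strand uniformity
is reported but not required. Among accepted selections of one hit per
query, the minimal-span one is reported per replicon (ties: leftmost
start, then replicon id). `min_identity = 0.4` keeps both versions
(~0.70 identity) comfortably above the floor; the identity shortcuts of
the clustering layer apply here too, plus an exact length-ratio bound
(identity ≤ min(len)/max(len)).

## Phylogenetics

Core alignment: families present in 100% of strains with exactly one
member each, concatenated in family-id order (unequal member lengths
are an error — synthetic homologs are gap-free; real input must be
pre-aligned). Distances are Jukes–Cantor with pairwise deletion of
non-ACGT sites; an observed difference ≥ 0.75 (saturation) is an error
for the point estimate and skips-and-counts a bootstrap replicate.

Neighbor joining is the canonical Q-criterion algorithm with the
Studier–Keppler update. Ties in Q are broken by the sorted label pair,
so the tree is a pure function of the distance matrix. Negative branch
estimates are clamped to zero with the deficit moved to the sibling
branch. Consistency (exact topology recovery on additive matrices) is
tested on 50 random trees, and the topology is cross-checked against
scikit-bio's independent implementation. Distance NJ stands in for
maximum-likelihood tree search as a deliberate scope decision: the
testable contract here is topology and support behavior, not branch
length inference under a richer model.

Bootstrap: columns are collapsed to site patterns with multiplicities,
so a replicate is a multinomial draw over patterns and distances come
from precomputed per-pattern difference counts — identical results to
naive column resampling, an order of magnitude faster. Supports are the
percentage of replicate trees containing each internal bipartition of
the point tree (encoded rooting-invariantly by the side not containing
the smallest leaf label). Default 1000 replicates; analyses and tests
use 100 where only the qualitative pattern matters.

## Gene content and genomic context

Shared counts are computed over accessory (non-100%-core) families;
the Euclidean distance between shared-count rows includes the diagonal
self-count — a strain's own accessory repertoire size is part of its
profile; both choices are parameters. Average linkage with
lexicographic pre-sorting makes merges deterministic; the k-group cut
uses the height that yields exactly k clusters.

Context profiles count strains, not copies: the conservation of a gene
is the fraction of other strains whose family has ≥ 1 member. The
window is ± 10 kb around the focal span, closed-interval overlap,
clipped to replicon bounds. Transposase flagging is keyword-based on
product annotations (transposase / insertion sequence / IS element,
configurable) — sufficient for annotated inputs, no HMM profiles.

## Pipeline and reproducibility

`run_pipeline` executes simulate (or load) → cluster (both modes) →
association → locate → trees → gene content → context, writing every
table plus `manifest.json` with parameters and SHA-256 digests of all
outputs and no timestamps; two runs with the same seed are
byte-identical, which the acceptance suite asserts. A failing stage
writes a `failed/<stage>` marker and aborts with the stage named.
Replicons are treated as linear; features spanning a circular origin
are rejected at the IO layer (the generator never emits them) — a
known limitation for real circular plasmids.

## Known limitations

- **Population-structure confounding is real and untreated.** All
  plasmid carriers form one subpopulation, so accessory families that
  track subpopulations are genuinely correlated with the phenotype. At
  the default pool prevalences this produces, in roughly 1–2% of
  panels, a single borderline accessory family at the BH significance
  boundary (the depletion pattern: present in all non-growers, nearly
  absent in growers). A phylogenetically aware association test would
  remove this; it is out of scope here and the exact-recovery rate is
  reported honestly by the acceptance script.
- Fisher's test at n = 24 is discrete; with small panels (e.g., 10
  strains) no family can reach BH-corrected significance at m in the
  hundreds — panel size, not implementation, is the limit.
- Keyword transposase detection and proteome-based homolog search
  assume sound annotations.
- The problem sizes used by tests and the acceptance script (24-strain
  panels, 200 core + 600 accessory families, 100 bootstrap replicates,
  10–20 panels per recovery estimate) are the package's chosen desk
  scale; all are configuration parameters.
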