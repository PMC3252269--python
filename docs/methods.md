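# Methods

## The detection model

The pipeline treats a horizontally transferred gene (HTG) as a recipient
protein satisfying three independent conditions: (i) strong similarity to
prokaryote proteins under stringent thresholds; (ii) a taxonomic homolog
distribution incompatible with vertical descent through eukaryotes; and
(iii) a gene-tree topology in which the recipient clade nests inside the
prokaryote part of the tree. Contamination is handled as a fourth, separate
axis — a sequence can pass all three phylogenetic conditions and still be an
assembly artifact, so the final verdict additionally requires at least one
line of physical evidence tying the gene to the host genome.

### Similarity tiers

`local_align` is exact Smith–Waterman with affine gaps, scored with a
substitution matrix (default BLOSUM62, gap open 11 / extend 1); there is no
heuristic seeding, which is affordable at the scale this package targets
(panels of 10²–10⁴ proteins). Identity is identical residue pairs over all
alignment columns, gap columns included (the convention of standard search
tools); this is configurable to the gap-free denominator. "Overlap" is the
aligned span as a fraction of the query length; a subject-anchored variant
is provided because either reading is defensible — query-anchored is the
default since the screen asks how much of the *candidate* is explained by
the hit.

E-values use the ungapped Karlin–Altschul form E = K·m·n·e^(−λS) with
published BLOSUM62 parameters (λ = 0.3176, K = 0.134; BLOSUM50 values are
included for completeness). With gapped alignments these E-values are
calibration-approximate; the tier decisions depend only on thresholds
applied uniformly to all candidates, not on absolute calibration. Tier
thresholds: first tier E ≤ 10⁻⁴⁰, overlap ≥ 25 %, identity ≥ 25 %; third
tier E ≤ 10⁻³ with the same floors, where a sub-threshold identity is
rescued when query and subject share an annotated protein domain.

Tabular hit files (12-column `outfmt 6`) do not carry an overlap value;
`read_hit_table` reconstructs it from the query span when query lengths are
supplied, and otherwise sets it to 100 so the overlap criterion cannot veto
externally produced hits on missing information.

### The distribution-spectrum filter

Eukaryote homologs are partitioned into six species sets (protists, fungi,
plants, insects, non-insect arthropods, other metazoans). A candidate is
dropped when **more than two** distinct species — strictly greater, i.e. at
least three — in a single non-insect set each have a homolog strictly
beating the candidate's top bacterial hit on *both* bit score and identity.
Ties never count against the candidate, species are counted once regardless
of hit multiplicity, and a candidate that would drop but has no insect
homolog at all is recovered: a gene absent from all other insects cannot be
a conserved vertical gene, whatever its spectrum looks like. "Score" is
read as bit score; a flag switches to raw score.

### Trees

Distances: p-distance with pairwise deletion of gap columns, optionally
Kimura's empirical correction d = −ln(1 − p − 0.2 p²). The correction
diverges as p → 0.8577; entries with p ≥ 0.85 receive a documented
saturation cap of 10 substitutions/site. A pair with zero comparable
columns is an error naming the pair.

Tree construction is BIONJ: neighbor joining with the standard Q-criterion,
but the reduced distance to a new node is the convex combination
d(u,k) = λ·(d(i,k) − bᵢ) + (1−λ)·(d(j,k) − bⱼ) whose weight λ minimises the
variance of the reduced matrix, with the variance matrix initialised to the
distances and reduced alongside (v(u,k) = λ·v(i,k) + (1−λ)·v(j,k) −
λ(1−λ)·v(i,j)). Negative branch estimates are clamped to zero. When two
pairs tie on the Q-criterion the lexicographically smallest id pair is
joined, which makes every tree reproducible. The suite verifies exact
topology recovery on 1,000 random additive 4–5-taxon matrices and agreement
with an independent neighbor-joining implementation.

Bootstrap resamples alignment columns with replacement; support for each
internal bipartition of the point-estimate tree is the percentage of
replicate trees containing it. Rooting is at the midpoint of the longest
leaf-to-leaf path, ties broken toward the lexicographically smallest leaf
pair; an all-zero-length tree roots at its designated base with a warning.
Externally built trees (e.g. Bayesian or maximum-likelihood Newick with
support labels) enter through the same classification path; full
likelihood-based inference is deliberately out of scope.

### Topology classification

After merging all recipient-lineage homologs into the focal set, the
classifier walks from the focal clade toward the root, recording the leaf
composition of each successive sister subtree. Purely prokaryotic sisters
accumulate; the first sister containing eukaryotes stops the walk. If at
least one prokaryote sister was seen first, the call is **hgt** (the
decisive nesting clade's bootstrap support must reach `min_support`,
default 50, whenever supports are present); if the first informative sister
is purely eukaryotic the call is **vertical**; a mixed
prokaryote/eukaryote first sister is **unresolved** and goes to refinement.
Refinement keeps the candidate, all recipient-lineage rows, and the k
most-similar homologs per taxonomic group (default 3), rebuilds with
bootstrap (default 1,000 replicates; the pipeline uses 200 by default) and
re-classifies; fewer than four retained taxa returns unresolved with a
reason code.

The A–F sub-labels are a heuristic summary of the sister pattern — A: a
single prokaryote leaf; B: a prokaryote clade; F: nesting more than one
prokaryote level deep; C/D/E: insect / other-metazoan / other-eukaryote
first sister — with only the binary transferred/vertical/unresolved call
being normative.

### Donor and transfer depth

A single sister species is reported as the donor at species rank; a
multi-species sister clade resolves to the genus of its member ranked best
among the candidate's bacterial hits. Transfer depth is the most recent
common ancestor, on the fixed hierarchy Bombycoidea ⊂ Macrolepidoptera ⊂
Obtectmera ⊂ Apoditrysia, of the recipient superfamilies carrying a
homolog — a lower bound on the transfer age, monotone in the presence set.

### Contamination triage

A candidate is a suspected contaminant iff *all* evidence is absent: no
EST, never cloned, not anchored on a chromosome/scaffold, and no homolog in
a relative's genome. A top-hit identity above the alert level (default
60 %) is reported as a supporting flag, never decisive alone — genuinely
recent transfers also show high identity.

### Transfer-event types and statistics

Two candidates belong to one transfer event when they are tandem copies
(same scaffold, interval gap ≤ 50 kb) or reciprocal best matches at ≥ 40 %
identity; events are the transitive closure. When sequences are not
available (the packaged candidate table stores annotations only),
`annotation_similarity` substitutes functional-annotation equality for
pairwise identity.

Summary statistics use the population standard deviation (divisor N) and
per-type aggregation skips missing values; both conventions are validated
by reproducing the published per-type summaries (identity mean 50.36 / SD
10.84; GC mean 43.83) exactly. The published per-type GC SD (4.82) is not
recoverable from the two-decimal GC values in the candidate table under
either divisor convention (population form gives ≈ 4.56); it was likely
computed from higher-precision GC fractions, so the mean is asserted and
the SD is reported without an acceptance bound. The enrichment test draws k
values *without replacement* per replicate (matching "extracted randomly
from the 1,176 values"); its null SD therefore carries the finite-population
correction √((N−k)/(N−1)), which the suite checks in closed form. The
intron-free test pairs the simulation with the exact hypergeometric point
probability ∏_{i<k} (m−i)/(N−i), evaluated in log space.

EST-evidence counting excludes cloned candidates: the published table has
13 candidates with nonzero EST counts, of which three are also cloned, and
the reconciled count of 10 matches the published statement; both counts are
derivable from the fixture.

## The synthetic-data generator

The generator emulates the assumed structure of the study system, not any
particular genome release: a recipient clade of five superfamily lineages
(two Bombycoidea species including the focal *Bombyx mori*, two
Papilionoidea, two Noctuoidea, one Pyraloidea, one Tortricoidea) nested
among other insects, arthropods, metazoans, fungi, plants and protists; and
a prokaryote panel of eleven eubacterial lineages (including the common
entomopathogenic genera and an endosymbiont) plus one archaeon. Branch
lengths are expected substitutions/site on fixed clade templates;
per-family lognormal rate multipliers (median ≈ 0.5 for vertical families)
spread families from conserved to fast-evolving, which is what populates
every funnel stage: fast vertical families die in the first similarity
tier, conserved ones survive it and are removed by the spectrum filter or
the tree stage.

Sequences evolve under a Poisson model: each site is redrawn from the
uniform stationary distribution with probability 1 − e^(−t) along a branch
of length t. This is deliberately the simplest exchangeable model — the
pipeline under test is distance-based, and the relevant property (p-distance
monotone in path length) holds by construction and is verified by
simulation.

A planted transfer regrafts the recipient subtree (restricted to the
superfamilies at or below the chosen hierarchy node) onto a donor lineage's
terminal edge with a stem of 0.30 substitutions/site, placing
donor–recipient identity near 50–65 % — the ancient-transfer regime rather
than near-identity. With probability 0.3 the recipient copy is tandem
duplicated (adjacent coordinates, one event type). GC is metadata, not
simulated sequence composition: the transferred gene's GC moves from the
donor's value toward the recipient background proportionally to the
amelioration parameter (default 0.7). Contaminants are near-verbatim
bacterial sequences (0.02 substitutions/site from their source) labelled as
recipient genes with the full no-evidence profile.

Default scenario: 200 families, 15 % carrying one transfer each, 5 %
contaminants, length 300, seed mandatory; generation takes under a second
and the full pipeline on it under a minute on one CPU. What passing on this
generator does **not** show: robustness to alignment error (families are
generated aligned, with no indels), to model misspecification beyond the
Poisson model, to incomplete taxon sampling of the bacterial panel, or to
real contamination that carries partial evidence; those failure modes need
real data.

## Known limitations

- E-values are ungapped-parameter approximations; do not compare them
  across scoring systems.
- The spectrum filter's "more than two species" veto is sensitive to how
  many genomes per set are sampled; with fewer than three genomes in every
  non-insect set it can never drop a candidate.
- Midpoint rooting can misplace the root under strong rate heterogeneity;
  an outgroup-rooted external tree is the safer input in that regime.
- The A–F sub-labels are heuristic conveniences, not calibrated classes.
- The intron-free test treats intron counts as exchangeable across genes;
  real intron distributions correlate with gene family and length.
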