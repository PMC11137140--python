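# Methods

This note documents the models implemented in `erodeome`, the parameters
that matter, the synthetic-data generator's scope, and the design choices
made where the design was genuinely open.

## Gene-status classification

### Model

Each endosymbiont lineage is represented as a consensus genome in reference
coordinates: a string per replicon of exactly the reference length over
{A, C, G, T, N, -}, where '-' marks positions deleted in the lineage. The
model assumes the endosymbiont gene inventory is a subset of the reference
inventory (degeneration only, no gene gain), so every reference gene can be
interrogated at its reference coordinates.

For a gene spanning `[start, end)` the classifier extracts the consensus
over `[start − 25, end + 25)` in reading orientation, collapses gaps, and
enumerates candidate ORFs from every configured start codon whose
(gap-collapsed) position lies within ±25 nt of the reference start. Each
candidate runs to the base before its first in-frame stop, or to the region
end when no stop occurs; candidates shorter than two codons are discarded.
Candidates are scored by Levenshtein edit distance (unit costs) against the
reference CDS, and the minimum-LED candidate wins; ties break to the longer
candidate, then the start offset nearest the reference start, then the
leftmost. The winning LED divided by the reference CDS length is the
size-normalised LED (snLED).

Why nucleotide-level edit distance: frameshifts — a dominant class of
inactivating lesion — truncate the candidate at the first out-of-frame stop,
so the LED grows with the length of coding sequence lost downstream of the
lesion. A protein-level comparison would see only the truncated product.
The stop codon is excluded from both strings so that the distance reflects
coding content only; the snLED denominator is the same stop-less reference
length, which makes a fully deleted gene score exactly 1.0 and keeps snLEDs
comparable across lineages for the same gene (the denominator is constant
per gene).

Genes with no valid start codon in the window are not dropped: they are
scored by the LED of the gap-collapsed gene body against the reference CDS,
entering the mixture as high-snLED points.

### Mixture fit and calling

Per lineage, the snLEDs of all genes with coverage ≥ 0.25 are fitted with a
two-component univariate normal mixture by expectation-maximisation:
starting means (0, 1), starting standard deviations (1, 1), equal starting
weights, convergence when the log-likelihood changes by < 1e-8 (at most 1000
iterations). Components are relabelled so the intact component has the
smaller mean. The classification cutoff is μ_intact + 3σ_intact. Calls:

* coverage (non-gap, non-N fraction of reference CDS positions) < 0.25
  → **missing**, regardless of snLED;
* snLED ≤ cutoff (inclusive boundary) → **intact**;
* otherwise → **pseudogene**.

The fit is per lineage, not pooled, because the neutral divergence level —
the location of the intact component — differs between lineages; a pooled
variant is available behind a config flag.

Degenerate inputs (constant snLEDs, e.g. self-annotation of the reference)
and component collapse (σ → 0 on near-perfect data) cannot support a
mixture fit; both fall back to a fixed cutoff (snLED ≤ 0.02 → intact),
logged prominently.

### Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `flank` | 25 | nt | start-codon search window around the reference start |
| `start_codons` | ATG, GTG, TTG | — | canonical + common alternative bacterial starts |
| `missing_threshold` | 0.25 | fraction | coverage below which a gene is missing |
| `em_tol` | 1e-8 | log-lik | E-M convergence tolerance |
| `em_max_iter` | 1000 | — | E-M iteration cap |
| `fallback_cutoff` | 0.02 | snLED | fixed cutoff when the mixture degenerates |

## Retention matrix and genome features

The binary retention matrix collapses pseudogene and missing to 0 (the
retention string asks "is the gene functional here?", so partial sequence
presence does not count). Categories: *universal_intact* (all 1),
*universal_lost* (all 0), *fractional* otherwise. Lineage exclusions (e.g.
samples that cannot be treated as independent transitions to symbiosis) are
declarative config — they are a biological judgement, not computable from
sequence — and are applied before categorisation.

Genome features per lineage: pooled GC fraction over the consensus of
intact copies of a designated conserved-ortholog set (defaulting to the
lineage's intact set when none is supplied); fraction of the reference
recovered as the non-gap, non-N fraction of the whole consensus (an
analogue, computed from consensus coverage, of read-based genome recovery —
not a replica of it); intact/pseudogene/missing counts; and intact counts
per functional category tag. Trends against patristic distance are ordinary
least squares plus Spearman rank correlation; constant features report
slope 0 and R² 0.

Pathway completeness: a biosynthetic step is satisfied if any of its
alternative genes is intact or host-complemented; a pathway is intact only
if every step is satisfied. Host complementation is consumed as an input
table, never inferred.

## Contingency engine

Entropy is the base-2 Bernoulli entropy of the string's 1-frequency; the
filter threshold defaults to `min_minority_entropy(n, 3)` — the entropy of a
string with exactly three minority lineages, 0.43 bits at n = 34 —
generalising the three-lineage support rule to any panel size. Hamming
distances are exhaustive over all filtered gene pairs. The relationship
strength

    0.5·E_pair + (0.5 / (n/2)) · |H − n/2|

uses E_pair = min(E_a, E_b): the formula has one entropy term for a
two-string comparison, and taking the minimum prevents a near-constant
partner from inflating the score. The constants of the 34-lineage study
(17 = n/2, 34 = n) generalise accordingly; with odd n the "drop H = n/2"
rendering rule never triggers. Relation labels: *direct* when
H ≤ `direct_max`, *reciprocal* when H ≥ n − `reciprocal_slack`; both default
to 0 (strict identity / strict complement) with config knobs, since
near-perfect reciprocal pairs (one or two discordant lineages) are common
and worth capturing with slack 1–2.

Clustering is a simplified Proximus-style recursive radius bisection, not a
port of the published algorithm: each group takes a majority-vote
representative (seeded deterministically from its first member; ties vote
1), members are canonicalised to whichever orientation — as-is or
complemented — is nearer the representative, and any group whose farthest
oriented member exceeds `max_radius` is split around that member and
recursed. Complement canonicalisation is what folds reciprocally retained
genes into the same cluster as their co-retained partners, with orientation
recorded per member.

## Synthetic-data generator

### What it emulates

* a free-living ancestor: non-overlapping CDSs with valid start/stop codons
  and no in-frame internal stops, random strands, GC-controlled coding
  sequence (realised coding GC within about ±0.02 of the target for ≥ 200
  genes), random intergenic spacers;
* independent lineages diverging from that ancestor along a branch-length
  gradient (a comb-like phylogeny with long terminal branches; no shared
  internal structure);
* two-phase degeneration: exponential-hazard gene inactivation (premature
  stop or 1–2 bp frameshifting deletion, 50/50 by default), then erosion of
  the pseudogene by geometric-length deletion blocks, targeting a deleted
  fraction of `1 − exp(−erosion_rate · residual_branch)`;
* AT-biased background substitution: per-site substitution probability
  `1 − exp(−branch)`, with probability `at_bias` the replacement is drawn
  from {A, T}, else uniformly from the three alternatives;
* constraint sets: *essential* genes are never inactivated; *operon*
  members become near-obsolete once any member falls (hazard ×
  `operon_hazard_multiplier`); *redundant pair/set* members evolve under
  relaxed selection while a backup copy exists (hazard ×
  `redundant_hazard_multiplier`) but the last survivor is always retained —
  one member or the other may be lost, never both.

Truth-intact genes are protected: substitutions that would create an
in-frame stop or touch their start/stop codons are skipped, and intact
genes never receive indels, so the truth table's "intact" always denotes a
translatable gene. A gene whose deleted fraction reaches 0.75 is truth
"missing", the complement of the annotator's 0.25 coverage rule.

### Parameters and defaults (the study conditions)

| parameter | default | units / meaning |
|---|---|---|
| `n_genes`, `n_lineages` | 500, 34 | study scale |
| `gene_length_range` | (100, 200) | codons |
| `ancestor_gc` | 0.55 | coding GC of the free-living ancestor |
| branch gradient | geomspace(0.01, 0.5) | substitutions/site; comb-like divergence gradient |
| `at_bias` | 0.8 | strong AT drift, as observed in endosymbionts |
| `inactivation_hazard` | 3.0 | per unit branch; long-branch lineages lose most dispensable genes, matching the heavy inventory reduction of old endosymbionts |
| `erosion_rate` | 4.0 | per unit residual branch; old pseudogenes erode toward "missing" |
| `frameshift_fraction` | 0.5 | lesion mix; both classes are edit-distance-detectable |
| `operon_hazard_multiplier` | 10 | obsolescence after the first member falls |
| `redundant_hazard_multiplier` | 50 | a backed-up copy is effectively neutral, so pairs resolve on even the shortest branches — the near-complete depletion of redundancy that reciprocal-retention analysis targets |
| `deletion_block_mean` | 200 | nt; geometric erosion block length |
| `lesion_window` | 0.9 | lesions fall in the 5' 90% of a gene: tail-proximal truncations rarely abolish function |
| `missing_threshold` | 0.75 | deleted fraction ⇒ truth "missing" |

The default study plants 30 essential genes (which double as the
conserved-ortholog GC set), two four-gene operons and five redundant pairs
(`simulate.default_study_params`). The study analysis classifies relations
with `direct_max = 2`, `reciprocal_slack = 2` and clusters at
`max_radius = 2` — the near-perfect band; the strict defaults (0) remain
the library defaults.

### What it does not emulate

Phylogenetically correlated lineages (tree-structured evolution), codon
models and selection on synonymous sites, insertions relative to the
reference (the consensus model is deletion-only, so LED sees insertions
only indirectly), sequencing error and N-runs, horizontal transfer, and
plasmid dynamics. Passing tests on this generator therefore demonstrate
that the pipeline recovers the planted degeneration signal under the
two-phase model with independent lineages; they do not certify performance
on real consensus data with alignment artefacts or correlated phylogenetic
structure.

## Numerical choices

* Edit distances via edlib (banded Myers bit-vector algorithm); empty
  strings short-circuit to the other string's length. A brute-force
  recursive oracle in the test suite pins the semantics.
* E-M responsibilities are computed in log space (logsumexp); component
  variance hitting 1e-16 raises a collapse error → fixed-cutoff fallback.
* The intact/pseudogene boundary is inclusive (snLED equal to the cutoff is
  intact).
* Entropy-filter comparisons use a 1e-12 absolute slack so strings at
  exactly the threshold entropy pass regardless of floating-point path.
* Majority-vote ties in cluster representatives resolve to 1 (retained);
  orientation ties (a string equidistant from both orientations) keep
  as-is; degenerate splits peel the farthest member into its own group, so
  recursion always terminates.
* Determinism: the master seed drives the ancestor; per-lineage generators
  are seeded `[seed, 1, lineage_index]`, so lineages are independent and
  insensitive to evaluation order; all outputs are byte-stable across runs.

## Problem sizes

The packaged study runs 34 lineages × 500 genes (replicon ≈ 280 kb), which
the full pipeline completes in well under a minute; unit tests use smaller
planted scenarios (e.g. 30 lineages × 60 genes) where exhaustive scanning
of the truth table is practical.

## Known limitations

* "Missing" is defined by consensus coverage, which conflates true deletion
  with failure to align; with real data the two are not distinguishable at
  this layer.
* The snLED of a heavily eroded pseudogene saturates near 1, so the mixture's
  pseudogene component is a pragmatic summary, not a mechanistic model of
  erosion depth.
* The relationship-strength score has no significance model; it ranks
  candidate pairs for inspection rather than testing them.
* The clustering is a simplified Proximus analogue; parity with the
  published algorithm's output is not claimed.
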