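# Methods

This note documents the models, rules and numerical choices behind
phylomatrix, in the order the pipeline applies them.

## Ortholog selection from homology hits

Hit tables use the 12-column BLAST tabular dialect; internally a hit is
(gene, candidate sequence, taxon, e-value, lengths). Two rules apply:

**Length-dependent e-value ceiling.** A hit is kept only if its e-value is at
or below a ceiling set by the reference protein's length: 1e-20 for proteins
shorter than 150 residues, 1e-80 otherwise. Short proteins cannot attain
extreme e-values however good the match, so the lenient ceiling avoids
discarding them wholesale; long proteins that fail even 1e-80 are likely
false positives. Which sequence is "the protein" is ambiguous in practice;
the default tests the subject (candidate) length, switchable to the query
(`SelectionConfig.length_field`), since the ceiling chiefly guards against
spurious short-subject matches. The boundary length 150 uses the stricter
ceiling (conservative inclusion). The filter is idempotent.

**Order-of-magnitude window.** Per (gene, taxon), the minimum-e-value hit is
kept together with every hit whose e-value is within `window_orders`
(default 3) orders of magnitude: `evalue <= best * 10**3`, boundary
inclusive. These near-ties are carried forward as alternative orthologs
until tree evidence decides. Ties are broken by (e-value, sequence id) so
output is independent of input row order. An exact-zero best e-value keeps
only other exact zeros — the order of magnitude of 0 is undefined. A flag
(`per_taxon=False`) applies the window across the whole gene instead; the
per-taxon reading is the default because the window's purpose is to offer
alternatives *for a slot*, not to cull whole taxa.

**Resolution.** One sequence per taxon per gene: the best-ranked candidate
not flagged long-branch in the gene tree; taxa whose candidates are all
flagged are dropped from the gene. Without a gene tree the best candidate
wins.

## Long-branch flagging

A tip is flagged when its statistic exceeds `multiplier` × a robust center
of that statistic over all tips. Defaults: terminal branch length, 4× the
median. The median resists the very outliers being sought; the mean and a
root-to-tip statistic are provided as alternatives. Trees with fewer than
`min_tips` (default 4) tips are skipped with a warning — an outlier rule
over three values is meaningless. Flagging is single-pass by default;
iterative re-flagging after pruning is deliberately not the default, since a
one-shot clean matches how gene matrices are typically curated. Pruning
suppresses resulting degree-2 nodes with branch lengths summed, so patristic
distances among surviving tips are unchanged.

The published cleaning scripts this step mirrors do not document their exact
numeric criteria; the policy object makes the rule explicit and auditable
rather than claiming to reproduce any particular script.

## Supermatrix accounting

Concatenation takes aligned, single-copy gene families, orders taxa
lexicographically (byte-stable outputs), fills absences with `?`, and
records partitions in 1-based inclusive coordinates. Completeness is
100 × non-missing / (taxa × columns) with `?`, `-` and `X` counted missing
by default; because conventions differ on `X`, both modes are exposed
(`count_x_as_missing`). The occupancy filter keeps genes present in at least
half the taxon universe, boundary inclusive. `simple_column_filter` drops
columns whose missing fraction exceeds a threshold and re-spans partitions;
it is a plain occupancy trim and intentionally does not emulate block-based
trimmers (Gblocks parameters, when used upstream, are provenance only).

## Dayhoff-6 recoding

The six classes {A,G,P,S,T} {D,E,N,Q} {H,K,R} {F,W,Y} {I,L,M,V} {C} are the
community-standard Dayhoff groups; the exact table used by any given
published analysis is rarely printed, so the scheme is data-driven and
alternative six-state schemes can be supplied. Output symbols are digits
0–5 to avoid collisions with residue letters, and class symbols map to
themselves, making recoding idempotent. `?` and `-` pass through; `X`, `*`
and ambiguity codes become `?`. Because recoding can only merge states,
pairwise p-distance never increases — emitted as a checkable per-pair
report, and enforced as a property test.

## Saturation diagnostics

Uncorrected p-distances use pairwise deletion (sites where both taxa carry a
non-missing residue); pairs with no comparable site are undefined and are
excluded listwise from the fit, with the count reported. Patristic distances
are tip-to-tip path sums, root-independent. The saturation statistic is the
R² of the ordinary least-squares fit of observed on patristic distance —
equal to the squared Pearson correlation, hence identical for either
regression orientation and invariant under uniform rescaling of either
axis. Lower R² = more saturation.

`bipartition_maxdiff` compares two post-burn-in tree samples: for every
non-trivial unrooted split seen in either sample, the frequency difference
is taken; the maximum is the statistic. Burn-in removal is the caller's
responsibility.

## Synthetic data: what it emulates, and what it does not

The generator emulates the raw material of a transcriptome-based
phylogenomic study, with every random draw taken from one seeded generator
(identical config + seed ⇒ byte-identical files).

* **Species tree**: random bifurcating topology (iterative pair joining)
  with i.i.d. gamma branch lengths, shape 12, mean 0.08 substitutions/site.
  The high shape (CV ≈ 0.29) models a roughly clock-like species history;
  rate variation is injected explicitly through the per-gene rate classes
  and the long-branch multiplier, so that injected outliers are conspicuous
  against the background branch-length spread — an 8× terminal branch on
  even the shortest background branch clears the default 4×-median flagging
  threshold (8 × (μ − 1.4σ) > 4 × 1.2μ, the 1.2 covering median inflation
  from dropout-merged edges and paralog tips).
* **Sequences**: 20-state Poisson process (uniform exchangeabilities and
  frequencies), simulated exactly via the closed-form per-edge identity
  probability `exp(-20 t / 19)`. No indels — families are born aligned;
  alignment inference is outside the package's scope.
* **Rate classes** {0.5, 1, 2, 4} per gene create the saturation gradient;
  gene lengths are uniform on 120–600 residues.
* **Missing data**: each taxon drops out of each gene independently with
  probability 0.25, giving ≈75% supermatrix completeness.
* **Paralogs** (10% per taxon per gene): duplicated at a random internal
  node and evolved independently at 2× rate for a comparable depth, so they
  are genuine sequences with systematically greater divergence.
* **Hit tables**: `log10 E = −identity² × L / 2` with N(0,1) Gaussian noise
  on the log scale (lognormal on E), identity measured against the ancestral
  query sequence. Only the ordering and order-of-magnitude structure matter
  downstream; the map is monotone and gives paralogs stochastically worse
  e-values than the ortholog (≥95% of cases at default noise).
* **Gene trees**: the true per-gene trees (species tree × rate, long-branch
  terminals inflated, paralog tips attached at their source node, absent
  taxa pruned with edge lengths summed) are part of the dataset, mirroring
  a workflow where gene trees arrive from an external inference step. A
  quick NJ estimator (`nj_gene_tree`, Poisson-corrected distances, skbio
  neighbor joining, correction capped at 5 substitutions/site for p ≥ 0.94)
  is provided for pipeline runs on data without trees; flagging recall on
  estimated trees runs ~0.03–0.05 below recall on true trees.

What passing tests on this generator do **not** show: robustness to
alignment error, indels, compositional heterogeneity across lineages,
among-site rate variation, or model misspecification — none of which the
generator produces. The recovery rates measured here are upper bounds tied
to these idealized conditions.

## Problem sizes and defaults

The default study conditions are 20 taxa × 200 genes (seed-controlled),
which the test suite and the acceptance script run end to end in seconds.
Key defaults: e-value ceilings 1e-20 / 1e-80 with the 150-residue cutoff;
3-order window; 4×-median terminal-branch flagging with min 4 tips; ≥50%
occupancy; missing symbols {?, -, X}; Dayhoff-6 output alphabet 0–5.

## Known limitations

* The flagging rule is a heuristic outlier test, not an explicit model of
  rate shifts; its recall depends on the background branch-length spread.
* `simple_column_filter` is not a substitute for block-aware trimming.
* The saturation fit assumes a linear relation near the origin; it reports
  a single global R² and does not model the plateau explicitly.
* Bipartition comparison requires identical tip sets across all trees in
  both samples; no pruning to a common subset is attempted.
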