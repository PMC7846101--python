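# Methods

This note documents the models, defaults and numerical choices behind
`httrace`, and what the simulation-based tests do and do not
demonstrate about real data.

## Similarity search

The engine is classic seed-and-extend: exact k-mer seeds against an
indexed subject panel (both strands, by reverse-complementing the
query), ungapped X-drop extension along each seed diagonal, and —
around every high-scoring ungapped segment — full affine-gap local
(Smith–Waterman) alignment inside a padded subject window. Within a
window, the best local alignment is extracted, its subject span is
masked, and the window is re-aligned until the score threshold fails,
so several nearby copies are each reported. Overlapping hits are
deduplicated keeping the best-scoring representative.

Scoring conventions:

* a gap of length L costs `gap_open + L·gap_extend`;
* N and IUPAC ambiguity codes never match anything, including
  themselves (conservative identity estimates);
* percent identity counts gap columns in the denominator, the usual
  convention of tabular pairwise-hit output, so printed identities are
  comparable with published tables;
* E-values are Karlin–Altschul `E = K·m·n·e^(−λs)` with λ solved by
  bisection from `Σ pᵢpⱼ e^(λsᵢⱼ) = 1` under uniform base frequencies.
  K defaults to 0.1 and is not calibrated for gapped alignment; within
  one parameter set E is monotone in score and linear in search space,
  which is all the thresholds require.

Presets: `default` (word 28, +1/−2, gap open 0 / extend 2 — the
tool's own megablast-like values, not a claim of equivalence with any
external program), `relaxed` (word 10, +3/−4, gap open 30 / extend 6,
X-drop 80/150, E ≤ 2·10⁻⁵, low-complexity seed masking — the deep
cross-phylum regime), and `sensitive` (word 7, wide windows, for
desk-scale pairs). On ≤ 300-bp pairs that share a homologous core the
engine's top hit equals the exhaustive Smith–Waterman optimum exactly
(verified against an independent full-DP implementation on 100 random
pairs). An external engine emitting 12-column tabular hits can be
substituted at the CLI level.

Low-complexity masking (`dust`) suppresses seeds in windows whose
3-mer Shannon entropy falls below 1.5 bits; extension may still cross
masked regions.

## Synthetic genome panels

The generator defines the study conditions every recovery test runs
under.

* **Substitution model**: Jukes–Cantor. Each site is substituted with
  probability `p = ¾(1 − e^(−4d/3))`, uniformly among the other three
  bases; composing two steps of d/2 equals one step of d, so host
  divergence accumulates correctly along branches.
* **Host background**: i.i.d. uniform DNA at 41% GC, evolving at
  1.25·10⁻⁹ substitutions/site/year (= 1.25·10⁻⁸ per generation at a
  10-year generation time, the elapid defaults) along a dated tree.
  Indels are off by default, which keeps truth coordinates stable; an
  indel rate exists as a stress option.
* **TE copies**: vertical families are inserted in the root genome;
  horizontal families are injected on a named branch at a stated time,
  so tip copies carry divergence d = rate × age plus any spec-level
  initial divergence. Copies are 5′-truncated (LINE biology; no 3′
  truncation) with probability `truncation_p`, keeping a 3′ fraction
  f ~ Uniform(0.05, 1); strand is Bernoulli(½). One copy per family
  per recipient genome is untruncated by default: presence calling
  requires a ≥ 1 kb hit, and the surveyed families are each anchored
  by at least one full-length copy in real assemblies, so panels
  without this guarantee would differ from the truth matrix for
  reasons the method is not designed to detect (the flag exists to
  turn it off).
* Ground truth (per-copy coordinates, presence matrix, event list) is
  logged exactly; the truth matrix equals the no-loss propagation of
  the event list by construction, and a test asserts it.

What the simulator does **not** emulate: realistic repeat landscapes
(satellites, LTR elements, nesting by default), gene conversion,
sequencing error or assembly artifacts beyond the engineered
contig-split fixture. Passing recovery tests therefore demonstrates
algorithmic correctness under the stated model, not robustness to
every idiosyncrasy of real assemblies.

## Consensus curation (SEAT)

Each round: search the current consensus (preset `default`), keep the
25 best hits ≥ 1,000 bp by score, extend coordinates ± 1,000 bp
(3,000 bp in cross-species mode) clipped at contig ends,
reverse-complement minus-strand hits, align, trim, and call a majority
consensus. Iteration stops when successive consensi reach 99%
identity — measured with terminal overhangs charged to the
denominator, so a consensus strictly contained in a longer one cannot
spuriously "converge" — or after 10 rounds. Zero qualifying hits is
an error; exactly one qualifying copy is returned verbatim and
flagged `single_copy`.

The multiple alignment is center-star: the center is the row with the
highest summed k-mer-profile similarity to the others (a fast,
order-invariant stand-in for summed pairwise alignment scores), rows
are aligned to it with affine **local** alignment and merged by gap
projection. Local (not end-free global) row alignment is the decision
that matters: the ±1 kb coordinate extension deliberately drags
non-homologous flanking sequence into every row, and a global aligner
will happily stack equal-length random flanks into fully occupied
mismatch columns — worse, the junk head of a 5′-truncated copy lands
on top of genuine 5′ consensus columns and poisons them. With local
alignment the non-homologous head and tail of each row stay unaligned
and occupy sparse single-row columns instead.

Trimming then removes, from each end, everything before the first run
of 10 consecutive columns that have non-gap occupancy ≥ 0.5
(inclusive) **and** majority-base agreement ≥ 0.55, plus internal
columns under 0.2 occupancy. The agreement term is required because
occupancy alone cannot reject a column where many rows stack random
flank sequence without gaps; homologous columns at ≤ 20% copy
divergence agree at ≳ 0.8 while random stacks sit near 0.3. The
majority consensus emits columns at ≥ 0.5 occupancy, ties broken
A<C<G<T. This deterministic filter replaces the by-eye alignment
editing of the original protocol; every threshold is exposed in
`SEATParams`.

Subfamily splitting clusters aligned rows (identity over shared
non-gap columns; rows sharing fewer than 20% of their columns score 0
— they are non-homologous, not coincidentally similar) with average
linkage, cut at 94% identity. Every cut cluster is a subfamily,
including singletons: a single full-length copy legitimately
represents a subfamily downstream. Suffixes H1, H2, … follow
descending cluster size. A "full-length" copy is a hit covering
≥ 95% of the current consensus.

## Screening and presence calls

Panel screens use the `relaxed` preset; close-relative candidate
checks use `default` (the two regimes of the original survey).
Overlapping hits are merged into loci first; the call is
`present_similar` iff some locus ≥ 1,000 bp reaches 75% identity
(best single hit, not a weighted average), `present_divergent` iff
more than one ≥ 1 kb locus exists with all below 75%, else `absent` —
a single sub-75% locus is treated as a probable false positive.
Reciprocal verification re-searches each candidate region against the
whole family library and keeps it only if the probing family is its
best match. Transcript support requires ≥ 95% identity over ≥ 500 bp
(`fragment_only` below the length floor; the 500-bp boundary is this
package's choice and is exposed).

## Dating

Copy divergence is the raw proportion of mismatched sites over
aligned non-gap columns of each copy's best alignment to the
consensus ("substitutions per site" read directly from alignments);
Jukes–Cantor correction is optional and always ≥ the raw value. The
clock divides by the per-generation rate directly — no ploidy factor
of 2 — because each copy is compared with the reconstruction of its
own ancestral state, not with a sister lineage; this is the largest
interpretive choice in the module and is deliberately prominent. Both
the SD over copies and the SE of the mean are reported (the SD is
used for the consistency interval).

Gain parsimony with losses disallowed has a closed-form solution: the
minimal event set is exactly one gain per maximal clade whose tips
are all present. An exhaustive minimal-subset-cover search over all
2⁷ presence patterns on the seven-elapid tree confirms the rule. For
event inference, `present_divergent` counts as absent by default
(transfer events concern the high-identity families); a flag flips
this. A family present in every tip yields a single gain on the root
branch whose stem age is reported as the root age, the oldest
observable bound.

## Truncation profiling

Fragment depth is accumulated per consensus position after locus
merging (no double-counting of tandem fragments). The truncation
statistic is mean depth over the last quartile of consensus positions
divided by the first quartile; a family is called LINE-typical when
the ratio is ≥ 2.0 (inclusive). The threshold is this package's
quantification of a qualitative published pattern: under the
generator's Uniform(0.05, 1) retained-fraction model the expected
ratio at high truncation probability is ≈ 4–7, while full-length
families sit at 1.

## Gene context and flank validation

Category priority: coding exon > 5′ UTR > 3′ UTR > in transcript >
upstream > intergenic — the most functionally specific category wins
when an insertion overlaps several features. "Upstream" is
strand-aware, measured from the insertion's nearest edge to the 5′
UTR start (transcript start when no UTR is annotated, logged), cutoff
5,000 bp inclusive. Flank validation searches each insertion's 2-kb
flanks in comparison assemblies: `split` when the best hits land on
different contigs in *every* comparison, `contiguous` when at least
one comparison places both flanks on one contig within twice the
expected span, `unresolved` otherwise; split records are excluded
from the report and counted in the log.

## Tree discordance

Sequences lacking ≥ 80% of either the endonuclease or reverse
transcriptase domain are removed before tree building. Block trimming
keeps columns at ≥ 50% occupancy in runs of ≥ 5 (a simplified
relaxed-mode block filter). Trees are neighbor-joining on p- (or JC-)
distances over shared non-gap columns, rows sorted by name first so
input order cannot matter, negative branch lengths clamped to zero;
maximum-likelihood inference is outside the built-in scope and can be
attached externally. Discordance is the Robinson–Foulds distance over
unrooted bipartitions, normalized by 2(n−3), between the TE tree's
induced host topology (duplicate-host tips collapsed to the tip with
minimal summed patristic distance to its host group) and the species
tree restricted to shared hosts; each focal tip also reports the host
of its closest non-self neighbor by patristic distance.

## Problem sizes

The test-suite and acceptance-script simulations use genome panels of
25–350 kb per species, families of 1.2–3 kb, and 3–50 copies per
genome — sizes at which every stage's behaviour (presence calling,
curation convergence, clock recovery within a few percent at 10 Ma)
is already asymptotic in the quantities being tested, while a full
run stays in the minutes range on one CPU. Twenty seeded replicates
back the stochastic claims (matrix recovery, truncation detection).

## Known limitations

* The curation trim assumes substitution-dominated divergence; heavy
  indel histories would erode the column-agreement signal.
* E-values are order-of-magnitude guides, not calibrated gapped
  statistics.
* Gain parsimony with no losses is deliberately conservative: real TE
  loss or assembly absence inflates event counts.
* The window-based gapped extension can, in principle, miss an
  optimal alignment that shares no exact word with the query at the
  chosen word size; the `sensitive` preset (word 7) bounds this risk
  for short sequences.
* The divergence clock inherits all uncertainty of the host
  substitution rate and generation time; its SD reflects copy
  scatter, not rate uncertainty.
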