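# Methods

## The model

`ampvar` treats targeted amplicon sequencing as a *routing* problem
rather than a mapping problem.  Every sequenced molecule has the fixed
layout

```
[sample index] [forward primer] [target exon] [reverse primer] [adapter…]
```

with targets designed under 200 bp so that paired 150 bp reads overlap
mid-target.  Because the forward primer is a known constant prefix of
every read from its amplicon, amplicon identity can be decided from a
handful of primer positions, and alignment only ever happens between a
read and one short known reference.  The pipeline stages and their
contracts:

**Public cleaning.**  The capture ("public") sequence appears in a read
only when target capture failed.  Drop rule: discard the pair iff R1
contains the public sequence or R2 contains its reverse complement
(the mates read opposite strands).  Dropping is pairwise even when only
one mate shows the hit — the molecule, not the read, failed.  The pass
is idempotent and survivors provably contain no hit (re-scan invariant,
enforced by a property test).

**Index cleaning.**  The sample index can bleed into the start of R2.
The first `|index| + 2` characters are searched for the index allowing
up to 3 substitutions (no gaps — the substitution-only mismatch
semantics of Bioconductor's `matchPattern`); the leftmost hit is
removed through its end, preserving the most read.  The
fixed budget of 3 does not scale with index length; for the 5–8 bp
indexes in scope that is the whole index at worst, and trimming is
always confirmed by later alignment anyway.  Separately, when the
target is shorter than 150 bp, R1 has read through into adapter and is
truncated to the target length.  In the pipeline, the index trim runs
globally before collapsing when the panel shares one index (the normal
single-sample case); R1 truncation runs globally only when all targets
share one length, since per-amplicon truncation would need the
assignment that happens later.  Residual adapter on unusual panels is
tolerated: the alignment acceptance gate rejects what it pollutes.

**Collapse.**  Pairs are spliced into `R2 + revcomp(R1)` and counted.
Sorting is by frequency descending with lexicographic tie-break, making
the output ordering deterministic (a plain sort on frequency alone would
be platform-dependent).  The occurrence threshold φ defaults to 1 —
every distinct molecule is kept; raising φ trades sensitivity for speed
on deep data.  Frequency mass is conserved: retained + discarded
frequencies always sum to the input pair count.  Each collapsed row also
records its R2 length so the key can later be split back into mates; on
uniform-length input after trimming, this is a single shared value.

**Discriminating positions.**  For forward primers r₁..rₙ the pairwise
difference sets FS(rᵢ, rⱼ) list the positions (over the common prefix)
where two primers disagree.  A position set is *discriminating* when the
per-primer projections are pairwise distinct; at least ⌈log₄ n⌉
positions are needed since a position carries four states.  The
canonical selection is exhaustive: try all position subsets in
increasing cardinality, return the lexicographically smallest valid
tuple (deterministic, provably minimal; panels are tens of primers and
the search trivially fast).  A greedy fast path — rank positions by how
many difference sets they appear in, add until injective — is provided
but not canonical.  Primers identical over the compared range raise an
error at catalog time; the panel loader already rejects exact duplicate
primers at load.

**Assignment.**  A collapsed key's signature is read directly off the
selected positions (the key starts at the forward primer once the index
is trimmed) and matched exactly against the per-amplicon signatures;
injectivity makes the match unique.  Non-matching keys are carried as
`unassigned`, never dropped silently.  A variant landing exactly on a
signature position would mis-route its key; the optional rescue mode
(off by default) aligns the key's leading region against every forward
primer and assigns to the unique best `k ≤ 2` hit, staying within the
pipeline's own alignment machinery.

**Banded local alignment.**  Scoring is match +1, mismatch 0, gap −1,
all cells floored at 0, restricted to the band `|i − j| ≤ ε`.  The
band default is ε = `|m − n| + 1`.  Two implementation choices matter:

* *Canonical paths.*  Under this scoring a contiguous k-bp indel ties
  (and with free mismatches sometimes loses to) the same indel
  fragmented across accidental shifted-frame matches.  The matrix is
  therefore computed as a three-state (match / gap-in-S / gap-in-T)
  integer DP whose scores are scaled by `2(m+n)+4` with a −1 surcharge
  per gap opening: the surcharge can never overturn a plain-score
  difference (paths hold fewer gap runs than the scale), so DP maxima
  are *identical* to the plain recurrence — verified against an
  unbanded Smith–Waterman oracle on thousands of random pairs — while
  the traceback deterministically selects, among score-tied optima, the
  path with fewest gap openings.  Max-cell ties break to the smallest
  row then column.
* *The k statistic.*  `k = min(m, n) − matched_count` counts characters
  of the shorter sequence left unmatched; `k = 0` iff the shorter
  sequence is wholly contained in the longer.  The DP score and the
  match count are both reported: the score ranks candidate alignments,
  `k` gates acceptance.

**Acceptance gate.**  The classical rule "accept when k ≤ 2" is exact
for substitution-only reads but charges every inserted base and every
boundary-clipped base to k, so a clean 5 bp insertion (k = 5) or an
indel near a segment edge would discard the whole read.  For the
shorter sequence k decomposes exactly as

```
k = substitutions on path + gap-explained characters + clipped characters
```

and the gate bounds each term by what it represents: substitutions
≤ `k_max` (2), per-side gap bases ≤ `max_indel` (10), clip
≤ `2·max_indel` (an indel close to a boundary drags a zero-net flank of
up to its own length off the path with it), and at most one gap run per
segment — a segment carries at most one real indel in this assay, and
multiple runs are the signature of an ambiguous fragmented placement.

**Free-mismatch artifact and the penalised fallback.**  When a long
insertion's bases accidentally echo nearby target sequence, a garbled
shifted-frame path can *strictly* outscore the true gapped path (the
garble pays nothing for its mismatches).  The primary aligner keeps the
conventional mismatch-0 scoring; any segment whose path is rejected or
contains gaps is re-aligned once with mismatch −1, and that canonical
path is used if it passes the gate.  This is a numerical-robustness
fallback, not a change of model: gapless, substitution-only reads never
reach it.

**Windows and band headroom.**  A fixed-length read covers a prefix
(R2 side) or suffix (R1 side) of its target, so each segment is aligned
against the matching target window (with `max_indel` slack for
deletions, which make a read span more target than its own length), and
the automatic band is widened to `|m − n| + 1 + max_indel`: an indel
inside a read shifts the true diagonal by up to its own length, which
the bare length-difference rule cannot absorb.  ε remains a config
override for callers who want the bare rule.

**Calling.**  Pileup columns hold five collapse-weighted counters
(A, C, G, T, N — N preserved through cleaning and counted in the
denominator).  SNP rule on the reference-base fraction: `= 100%` is
definitively non-variant, `< 90%` is a variant with the highest-count
non-reference ACGT base as alternate (alphabetical on ties; a column
where only N competes is skipped), and the band [90%, 100%) is
conservatively uncalled.  Both mates of a pair count independently, so
mid-target depth is twice the pair depth (the standard naive-pileup
convention; allele fractions are unaffected).  Indel evidence is the
set of gap runs on accepted paths, left-shifted to canonical form
(leftmost equivalent placement through repeats) before aggregation;
events with support ≥ `min_depth` are emitted as left-anchored VCF
records (deletion REF = anchor + run, ALT = anchor; insertion
mirrored; events touching position 1 anchor on the right instead).

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| φ (`phi`) | 1 | minimum collapse frequency; 1 keeps every molecule |
| ε (`epsilon`) | auto | band half-width; auto = `\|m−n\|+1 + max_indel` |
| `snp_ref_fraction` | 0.90 | SNP threshold on the reference fraction |
| `k_max` | 2 | substitution budget per accepted segment |
| `max_indel` | 10 bp | largest indel the assay is designed for |
| `min_depth` | 10 | support floor for any call; the frequency rule is unstable below it |
| `index_max_mismatch` | 3 | substitution budget for the index search |

`min_depth` = 10 is an artifact parameter: no published depth floor
exists for this rule, but at depth < 10 a single molecule moves the
reference fraction by more than the calling margin.

## The simulator

`simulation_eval` emulates the study conditions: error-free paired
150 bp reads (`error_rate = 0`, settable), depths 50–150, spiked SNPs
and 2–10 bp insertions/deletions at a chosen allele fraction (default
0.5, heterozygous-like; all variants of one amplicon ride one mutated
haplotype, so each read pair is a Bernoulli draw between the two
haplotypes).  Synthetic panels default to 20 amplicons with 20 bp
primers, 130–180 bp targets, an 8 bp shared index and a 30 bp public
sequence — geometry in which molecules exceed the read length, so
error-free reads never run into adapter, while the index still bleeds
into R2 and exercises index cleaning on every read.  The truth
generator places at most two SNPs and one indel per amplicon with
12 bp separation: the k ≤ 2 substitution budget per segment is the
method's design envelope, and denser variation is outside it (and rare
in real exon screens).  Everything is driven by one seed;
(panel, truth, seed) → byte-identical FASTQ.

What the simulator does *not* model: base-quality error profiles,
PCR chimeras/jackpotting, coverage imbalance between amplicons,
structural variants beyond short indels, and contamination.  Passing
tests therefore demonstrate the algorithmic contracts (routing,
alignment, thresholds, indel normalisation), not robustness to
real-world noise.

Evaluation matches SNPs exactly by (amplicon, position, ref, alt) and
indels by (amplicon, kind, left-shifted position, left-shifted allele).
True negatives are positional — target positions carrying neither a
spiked variant nor a call — because variant-calling has no natural
negative *event* universe; FPR and Accuracy are interpretable only
under that convention.  Recall = TP/(TP+FN), TPR ≡ Recall,
FPR = FP/(FP+TN), Accuracy = (TP+TN)/(TP+FP+FN+TN); zero denominators
report as not-available.

## Scale of the shipped experiments

The test suite's end-to-end experiment uses 20 amplicons × depth 50
with 30 SNPs + 20 indels (one thousand read pairs), the package's
chosen desk-scale configuration; it completes in about a second and the
whole suite in a few seconds.  Alignment-oracle and position-selection
oracle suites run 1000 random pairs and 200 random panels respectively.

## Known limitations

* Signature matching is exact; a variant on a discriminating position
  mis-routes its molecule unless rescue mode is enabled.
* Two indels within one read segment are outside the acceptance
  envelope and will be rejected rather than called.
* Indel placement in repetitive or self-similar context is resolved by
  left-shift normalisation; placements that are not shift-equivalent to
  the truth (possible when an insertion echoes flanking sequence in
  both read frames) can surface as a nearby spurious event.
* Germline-database filtering, genotype likelihoods and base-quality
  weighting are out of scope; every call is a raw frequency event.
* CNVs and structural variants other than ≤ 10 bp indels are not
  detected.
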