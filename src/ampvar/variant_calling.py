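"""Pileup accumulation and frequency-threshold SNP/indel calling.

Each assigned collapsed key is split back into its two mate segments,
the primer flanks are removed, and both segments are locally aligned to
the amplicon's target sequence.  An alignment contributes to the pileup
only when it passes the ``k``-statistic acceptance gate; accepted
aligned pairs increment per-position base counters (A, C, G, T, N)
weighted by the key's collapse frequency, and gap runs are recorded as
left-normalised indel evidence.

Calling is a per-position frequency rule.  With counts
``p_1..p_5`` for A, C, G, T, N, the fraction of the reference base is

    P(ref_i) = p_ref / (p_1 + p_2 + p_3 + p_4 + p_5) * 100%.

A position with ``P(ref) = 100%`` is definitively non-variant; a
position with ``P(ref)`` below the 90% threshold is called as a SNP with
the highest-count non-reference base as the alternate allele.  The band
between 90% and 100% is conservatively left uncalled.  Indels are called
from aggregated gap evidence: a gap in the read (target characters
skipped) is a deletion, a gap in the target (extra read characters) is
an insertion; events supported by at least ``min_depth`` collapse-weighted
observations are emitted in left-anchored VCF form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .banded_alignment import (
    AlignmentResult,
    align_local,
    band_width,
    is_local_optimal,
)
from .io_formats import Amplicon, VariantRecord, revcomp
from .pair_collapse import split_collapsed
from .read_assignment import AssignedSequence

__all__ = [
    "BASES",
    "CallingThresholds",
    "PileupColumn",
    "IndelObservation",
    "AmpliconPileup",
    "normalize_deletion",
    "normalize_insertion",
    "pileup",
    "call_snps",
    "call_indels",
    "call_amplicon",
]

BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class CallingThresholds:
    """Tunable constants of the caller.

    ``snp_ref_fraction``: call a SNP when the reference-base fraction
    drops below this value (default 0.90).  ``k_max``: maximum accepted
    ``k`` statistic for an alignment to enter the pileup (default 2).
    ``min_depth``: minimum collapse-weighted depth/support for any call;
    the frequency rule is unstable at tiny depths (default 10).
    ``max_indel``: the largest indel length the assay is expected to
    carry (default 10 bp); it widens the automatic alignment band and
    the target windows so an indel-shifted read still fits the band.
    """

    snp_ref_fraction: float = 0.90
    k_max: int = 2
    min_depth: int = 10
    max_indel: int = 10
    epsilon: int | None = None  # fixed band override; None = auto

    def __post_init__(self) -> None:
        if not 0.0 < self.snp_ref_fraction <= 1.0:
            raise ValueError("snp_ref_fraction must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class PileupColumn:
    """Per-target-position counts of A, C, G, T, N (collapse-weighted)."""

    position: int
    counts: list[int] = field(default_factory=lambda: [0] * 5)

    @property
    def depth(self) -> int:
        return sum(self.counts)

    def count_of(self, base: str) -> int:
        return self.counts[_BASE_INDEX[base]]


@dataclass(frozen=True)
class IndelObservation:
    """Aggregated, left-normalised indel evidence.

    For a deletion ``position`` is the first deleted target base and
    ``allele`` the deleted bases; for an insertion ``position`` is the
    target base after which the ``allele`` bases insert.
    """

    kind: str  # "INS" or "DEL"
    position: int
    allele: str
    support: int


@dataclass
class AmpliconPileup:
    """Pileup of one amplicon: base columns plus indel evidence."""

    amplicon_id: str
    columns: list[PileupColumn]
    indels: list[IndelObservation]
    n_sequences: int = 0
    n_accepted: int = 0
    n_rejected: int = 0


def normalize_deletion(target: str, pos: int, length: int) -> tuple[int, str]:
    """Left-shift a deletion of ``target[pos..pos+length-1]`` (1-based).

    In repetitive context the same deleted haplotype can be written at
    several positions; shifting to the leftmost equivalent placement
    gives every observation of the event one canonical key.
    """
    while pos > 1 and target[pos - 2] == target[pos + length - 2]:
        pos -= 1
    return pos, target[pos - 1 : pos + length - 1]


def normalize_insertion(target: str, pos: int, allele: str) -> tuple[int, str]:
    """Left-shift an insertion of ``allele`` after target position ``pos``."""
    while pos >= 1 and target[pos - 1] == allele[-1]:
        allele = target[pos - 1] + allele[:-1]
        pos -= 1
    return pos, allele


def _strip_suffix_overlap(seq: str, primer: str) -> str:
    """Remove the longest primer *prefix* stuck to the end of ``seq``."""
    for q in range(min(len(primer), len(seq)), 0, -1):
        if seq.endswith(primer[:q]):
            return seq[:-q]
    return seq


def _strip_prefix_overlap(seq: str, primer: str) -> str:
    """Remove the longest primer *suffix* stuck to the start of ``seq``."""
    for q in range(min(len(primer), len(seq)), 0, -1):
        if seq.startswith(primer[len(primer) - q :]):
            return seq[q:]
    return seq


def segment_sequences(
    cs_seq: str, r2_len: int, amplicon: Amplicon
) -> list[tuple[str, str]]:
    """Primer-free target-strand segments of one collapsed key.

    The R2 segment starts at the forward primer (stripped by length) and
    may run into the reverse primer on short targets (stripped by
    overlap); it is anchored at the target ``"start"``.  The R1 segment
    is reverse-complemented into target orientation, ends at the reverse
    primer (stripped by length), may begin inside the forward primer
    (stripped by overlap), and is anchored at the target ``"end"``.
    Returns ``(segment, anchor)`` tuples.
    """
    r2_part, r1_part = split_collapsed(cs_seq, r2_len)
    segments: list[tuple[str, str]] = []
    s_fwd = r2_part[len(amplicon.fwd_primer):]
    s_fwd = _strip_suffix_overlap(s_fwd, amplicon.rev_primer)
    if s_fwd:
        segments.append((s_fwd, "start"))
    s_rev = revcomp(r1_part)
    if len(s_rev) > len(amplicon.rev_primer):
        s_rev = s_rev[: -len(amplicon.rev_primer)]
        s_rev = _strip_prefix_overlap(s_rev, amplicon.fwd_primer)
        if s_rev:
            segments.append((s_rev, "end"))
    return segments


def _target_window(
    target: str, seg_len: int, anchor: str, slack: int
) -> tuple[str, int]:
    """Target window matching a segment's anchor, with its offset.

    A fixed-length read starts at one end of the amplicon, so its
    segment covers a prefix (R2) or suffix (R1) of the target.  Aligning
    against the matching window keeps the alignment on the main
    diagonal, where the narrow band belongs; ``slack`` extra target
    bases absorb deletions, which make a segment span more target than
    its own length.
    """
    span = seg_len + slack
    if span >= len(target):
        return target, 0
    if anchor == "start":
        return target[:span], 0
    return target[-span:], len(target) - span


def _segment_epsilon(
    seg_len: int, target_len: int, thresholds: CallingThresholds
) -> int:
    # The |m - n| + 1 rule sizes the band for the sequences' length
    # difference; an indel inside a fixed-length read shifts the true
    # diagonal by up to its own length on top of that.
    if thresholds.epsilon is not None:
        return thresholds.epsilon
    return band_width(seg_len, target_len) + thresholds.max_indel


def _accept(result: AlignmentResult, thresholds: CallingThresholds) -> bool:
    """Acceptance gate for a segment alignment.

    For the shorter sequence, ``k`` decomposes exactly into substitutions
    on the path, characters explained by indel gaps, and characters
    clipped off the path ends (an indel near a segment boundary makes
    local alignment drop the short overhang rather than pay for the
    gap).  The raw ``k <= k_max`` rule charges all three, so a clean
    insertion or a boundary-clipped read would be discarded wholesale;
    instead each term is bounded by what it represents: substitutions by
    ``k_max``, gap and clip lengths by ``max_indel``.
    """
    if is_local_optimal(result, thresholds.k_max):
        return True
    if not result.aligned_pairs:
        return False
    if result.mismatch_count > thresholds.k_max:
        return False
    if (
        result.s_gap_bases > thresholds.max_indel
        or result.t_gap_bases > thresholds.max_indel
    ):
        return False
    # One segment carries at most one real indel here; several gap runs
    # mean the aligner scattered an ambiguous indel across score-tied
    # fragments (its bases echoing nearby target sequence), and that
    # evidence would surface as spurious calls.  The mate segment sees
    # the same molecule in a different frame and resolves it cleanly.
    if len(result.gaps) > 1:
        return False
    start_i, start_j = result.path[-1]
    if len(result.s) <= len(result.t):
        clip = start_i + (len(result.s) - result.max_i)
    else:
        clip = start_j + (len(result.t) - result.max_j)
    # A boundary indel can drag its short anchoring flank off the path
    # with it (the flank nets zero score against the gap cost), so the
    # legitimate clip reaches twice the indel length.
    return clip <= 2 * thresholds.max_indel


def pileup(
    assigned: Iterable[AssignedSequence],
    amplicon: Amplicon,
    thresholds: CallingThresholds | None = None,
) -> AmpliconPileup:
    """Accumulate the per-position base counts for one amplicon.

    Only sequences assigned to this amplicon contribute, and only
    through alignments passing the acceptance gate.  An amplicon with no
    passing alignment yields an all-zero pileup (reported, not fatal).
    """
    thresholds = thresholds or CallingThresholds()
    target = amplicon.target_seq
    pile = AmpliconPileup(
        amplicon_id=amplicon.amplicon_id,
        columns=[PileupColumn(position=i + 1) for i in range(len(target))],
        indels=[],
    )
    raw_events: dict[tuple[str, int, str], int] = {}
    for a in assigned:
        if a.amplicon_id != amplicon.amplicon_id:
            continue
        pile.n_sequences += 1
        freq = a.collapsed.frequency
        for seg, anchor in segment_sequences(
            a.collapsed.spliced_seq, a.collapsed.r2_len, amplicon
        ):
            window, offset = _target_window(
                target, len(seg), anchor, thresholds.max_indel
            )
            eps = _segment_epsilon(len(seg), len(window), thresholds)
            result = align_local(seg, window, eps)
            primary_ok = _accept(result, thresholds)
            if result.gaps or not primary_ok:
                # Under the free-substitution scoring an indel whose
                # bases accidentally echo nearby target sequence can be
                # scored into a garbled or fragmented path; re-align with
                # substitutions penalised and prefer that canonical gap
                # placement whenever the segment carries gaps at all.
                alt = align_local(seg, window, eps, mismatch=-1)
                if _accept(alt, thresholds):
                    result = alt
                elif not primary_ok:
                    pile.n_rejected += 1
                    continue
            pile.n_accepted += 1
            for si, tj in result.aligned_pairs:
                pile.columns[tj - 1 + offset].counts[
                    _BASE_INDEX[seg[si - 1]]
                ] += freq
            for gap in result.gaps:
                if gap.seq == "S":  # target bases missing from the read
                    pos, allele = normalize_deletion(
                        target, gap.t_pos + offset, gap.length
                    )
                    key = ("DEL", pos, allele)
                else:  # extra read bases relative to the target
                    pos, allele = normalize_insertion(
                        target, gap.t_pos + offset, gap.bases
                    )
                    key = ("INS", pos, allele)
                raw_events[key] = raw_events.get(key, 0) + freq
    pile.indels = [
        IndelObservation(kind=k, position=p, allele=al, support=sup)
        for (k, p, al), sup in sorted(raw_events.items())
    ]
    return pile


def call_snps(
    columns: Sequence[PileupColumn],
    amplicon: Amplicon,
    thresholds: CallingThresholds | None = None,
) -> list[VariantRecord]:
    """Emit a SNP wherever the reference-base fraction falls below threshold.

    The alternate allele is the highest-count non-reference base among
    A, C, G, T (alphabetical on ties); positions below ``min_depth`` are
    skipped, as is the degenerate case where only N competes with the
    reference.
    """
    thresholds = thresholds or CallingThresholds()
    target = amplicon.target_seq
    calls: list[VariantRecord] = []
    for col in columns:
        depth = col.depth
        if depth < thresholds.min_depth:
            continue
        ref = target[col.position - 1]
        ref_fraction = col.count_of(ref) / depth if ref in _BASE_INDEX else 0.0
        if ref_fraction >= thresholds.snp_ref_fraction:
            continue
        candidates = [
            (base, col.count_of(base)) for base in "ACGT" if base != ref
        ]
        alt, alt_count = max(candidates, key=lambda bc: (bc[1], -ord(bc[0])))
        if alt_count == 0:
            continue
        calls.append(
            VariantRecord(
                amplicon_id=amplicon.amplicon_id,
                position=col.position,
                ref_base=ref,
                alt=alt,
                kind="SNP",
                alt_fraction=alt_count / depth,
                depth=depth,
            )
        )
    return calls


def call_indels(
    pile: AmpliconPileup,
    amplicon: Amplicon,
    thresholds: CallingThresholds | None = None,
) -> list[VariantRecord]:
    """Emit INS/DEL records from aggregated gap evidence.

    Events supported by at least ``min_depth`` collapse-weighted
    observations become left-anchored VCF-style records (the anchor base
    is shared between REF and ALT).
    """
    thresholds = thresholds or CallingThresholds()
    target = amplicon.target_seq
    calls: list[VariantRecord] = []
    for obs in pile.indels:
        if obs.support < thresholds.min_depth:
            continue
        if obs.kind == "DEL":
            if obs.position <= 1:
                # Deletion at the very start has no left anchor: anchor on
                # the base following the run instead.
                after = obs.position + len(obs.allele) - 1
                if after >= len(target):
                    continue
                anchor = target[after]
                pos, ref, alt = obs.position, obs.allele + anchor, anchor
            else:
                anchor = target[obs.position - 2]
                pos = obs.position - 1
                ref, alt = anchor + obs.allele, anchor
        else:
            if obs.position < 1:
                anchor = target[0]
                pos, ref, alt = 1, anchor, obs.allele + anchor
            else:
                anchor = target[obs.position - 1]
                pos, ref, alt = obs.position, anchor, anchor + obs.allele
        anchor_col = pile.columns[pos - 1]
        depth = max(anchor_col.depth, obs.support)
        calls.append(
            VariantRecord(
                amplicon_id=amplicon.amplicon_id,
                position=pos,
                ref_base=ref,
                alt=alt,
                kind=obs.kind,
                alt_fraction=min(1.0, obs.support / depth),
                depth=depth,
            )
        )
    return calls


def call_amplicon(
    assigned: Iterable[AssignedSequence],
    amplicon: Amplicon,
    thresholds: CallingThresholds | None = None,
) -> tuple[AmpliconPileup, list[VariantRecord]]:
    """Pileup one amplicon and return its combined SNP + indel calls."""
    thresholds = thresholds or CallingThresholds()
    pile = pileup(assigned, amplicon, thresholds)
    calls = call_snps(pile.columns, amplicon, thresholds)
    calls.extend(call_indels(pile, amplicon, thresholds))
    calls.sort(key=lambda c: (c.position, c.kind, c.alt))
    return pile, calls
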