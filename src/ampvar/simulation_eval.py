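"""Paired-read simulation with variant spike-in, plus evaluation metrics.

The simulator emulates short-insert amplicon sequencing: for every
amplicon a molecule ``forward primer + target + reverse primer`` is
built, the spiked variants of that amplicon are applied to a mutated
haplotype, and each of ``depth`` read pairs samples the mutated
haplotype with probability equal to the allele fraction.  R2 reads the
molecule from the indexed end (the sample index bleeds into its first
bases, exercising index cleaning); R1 reads the complementary strand
from the other end.  Reads are a fixed 150 bp by default, error-free
(``error_rate = 0``), and deterministic given (panel, truth, seed).

Truth-aware evaluation matches calls against the spike-in record —
exactly by position and allele for SNPs, in left-shifted normal form
for indels — and reports recall, true/false positive rate and accuracy.
True negatives are counted positionally: target positions carrying
neither a spiked variant nor a call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    Amplicon,
    AmpliconPanel,
    ReadPair,
    VariantRecord,
    revcomp,
    write_fastq_pair,
)
from .variant_calling import normalize_deletion, normalize_insertion

__all__ = [
    "SpikedSNP",
    "SpikedIndel",
    "SimulationTruth",
    "ConfusionCounts",
    "random_panel",
    "random_truth",
    "apply_variants",
    "simulate_read_pairs",
    "simulate_reads",
    "write_truth",
    "read_truth",
    "truth_events",
    "calls_to_events",
    "match_calls",
    "recall",
    "tpr_fpr_accuracy",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class SpikedSNP:
    amplicon_id: str
    position: int  # 1-based in the target
    ref: str
    alt: str
    allele_fraction: float


@dataclass(frozen=True)
class SpikedIndel:
    amplicon_id: str
    position: int  # DEL: first deleted base; INS: insert after this base
    kind: str  # "INS" or "DEL"
    allele: str  # deleted (DEL) or inserted (INS) bases
    allele_fraction: float


@dataclass
class SimulationTruth:
    """The complete specification of one simulated experiment."""

    snps: list[SpikedSNP] = field(default_factory=list)
    indels: list[SpikedIndel] = field(default_factory=list)
    depth: int = 50
    read_length: int = 150
    error_rate: float = 0.0
    capture_failure_rate: float = 0.0
    seed: int = 0

    def variants_of(self, amplicon_id: str) -> tuple[list[SpikedSNP], list[SpikedIndel]]:
        return (
            [v for v in self.snps if v.amplicon_id == amplicon_id],
            [v for v in self.indels if v.amplicon_id == amplicon_id],
        )


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0


# ---------------------------------------------------------------------------
# Synthetic panels and truth sets
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def random_panel(
    n_amplicons: int = 20,
    *,
    target_len_range: tuple[int, int] = (130, 180),
    primer_len: int = 20,
    index_len: int = 8,
    public_len: int = 30,
    seed: int = 0,
) -> AmpliconPanel:
    """Generate a synthetic amplicon panel with one shared sample index.

    Target lengths default to 130-180 bp so that a 150 bp read always
    spans its primer into the target and paired reads overlap mid-target,
    the geometry the method is designed around.  Forward primers are
    drawn until pairwise distinct; the public sequence is re-drawn if it
    collides with any molecule.
    """
    rng = np.random.default_rng(seed % _SEED_MOD)
    fwd_primers: list[str] = []
    while len(fwd_primers) < n_amplicons:
        p = _random_dna(rng, primer_len)
        if p not in fwd_primers:
            fwd_primers.append(p)
    index_seq = _random_dna(rng, index_len)
    amplicons = []
    lo, hi = target_len_range
    for i, fwd in enumerate(fwd_primers):
        target = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        rev = _random_dna(rng, primer_len)
        amplicons.append(
            Amplicon(
                amplicon_id=f"amp{i + 1:03d}",
                fwd_primer=fwd,
                rev_primer=rev,
                target_seq=target,
                index_seq=index_seq,
            )
        )
    molecules = [a.fwd_primer + a.target_seq + a.rev_primer for a in amplicons]
    for _ in range(100):
        public = _random_dna(rng, public_len)
        rc = revcomp(public)
        if not any(public in m or rc in m for m in molecules):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("could not draw a public sequence free of collisions")
    return AmpliconPanel(amplicons=amplicons, public_seq=public)


def random_truth(
    panel: AmpliconPanel,
    *,
    n_snps: int = 30,
    n_indels: int = 20,
    depth: int = 50,
    allele_fraction: float = 0.5,
    indel_len_range: tuple[int, int] = (2, 10),
    read_length: int = 150,
    error_rate: float = 0.0,
    seed: int = 0,
) -> SimulationTruth:
    """Scatter SNPs and 2-10 bp indels over the panel.

    At most two SNPs and one indel are placed per amplicon, separated by
    a 12 bp buffer and kept away from the target edges — the variant
    density the per-read acceptance gate (k <= 2 substitutions) is
    designed for, and a realistic ceiling for somatic exon screens.
    """
    rng = np.random.default_rng(seed % _SEED_MOD)
    amp_ids = [a.amplicon_id for a in panel.amplicons]
    if n_snps > 2 * len(amp_ids):
        raise ValueError("at most two SNPs per amplicon: panel too small")
    if n_indels > len(amp_ids):
        raise ValueError("at most one indel per amplicon: panel too small")

    taken: dict[str, list[tuple[int, int]]] = {a: [] for a in amp_ids}
    buffer = 12

    def free(amp_id: str, lo_pos: int, hi_pos: int) -> bool:
        return all(
            hi_pos + buffer < s or lo_pos - buffer > e
            for s, e in taken[amp_id]
        )

    indels: list[SpikedIndel] = []
    order = list(rng.permutation(amp_ids))
    for amp_id in order[:n_indels]:
        target = panel[amp_id].target_seq
        length = int(rng.integers(indel_len_range[0], indel_len_range[1] + 1))
        kind = "DEL" if rng.random() < 0.5 else "INS"
        for _ in range(200):
            pos = int(rng.integers(15, len(target) - length - 20))
            if free(amp_id, pos, pos + length):
                break
        else:
            continue
        if kind == "DEL":
            allele = target[pos - 1 : pos + length - 1]
        else:
            allele = _random_dna(rng, length)
        indels.append(
            SpikedIndel(amp_id, pos, kind, allele, allele_fraction)
        )
        taken[amp_id].append((pos, pos + length))

    snps: list[SpikedSNP] = []
    snp_slots = [a for a in amp_ids for _ in range(2)]
    slot_order = list(rng.permutation(len(snp_slots)))
    for amp_id in (snp_slots[i] for i in slot_order):
        if len(snps) == n_snps:
            break
        target = panel[amp_id].target_seq
        for _ in range(200):
            pos = int(rng.integers(10, len(target) - 10))
            if free(amp_id, pos, pos):
                break
        else:
            continue
        ref = target[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        snps.append(SpikedSNP(amp_id, pos, ref, alt, allele_fraction))
        taken[amp_id].append((pos, pos))
    if len(snps) < n_snps or len(indels) < n_indels:
        raise RuntimeError("could not place all requested variants")
    return SimulationTruth(
        snps=snps,
        indels=indels,
        depth=depth,
        read_length=read_length,
        error_rate=error_rate,
        seed=seed % _SEED_MOD,
    )


# ---------------------------------------------------------------------------
# Haplotype construction and read generation
# ---------------------------------------------------------------------------

def apply_variants(
    target: str, snps: Sequence[SpikedSNP], indels: Sequence[SpikedIndel]
) -> str:
    """Build the mutated haplotype carrying all listed variants.

    Positions are reference coordinates; events are applied right to
    left so earlier edits never shift later ones.  A SNP whose stated
    reference base disagrees with the target raises ``ValueError``.
    """
    events: list[tuple[int, str, SpikedSNP | SpikedIndel]] = []
    for s in snps:
        if not 1 <= s.position <= len(target):
            raise ValueError(f"SNP position {s.position} outside target")
        if target[s.position - 1] != s.ref:
            raise ValueError(
                f"SNP ref {s.ref} != target base at position {s.position}"
            )
        events.append((s.position, "SNP", s))
    for d in indels:
        end = d.position + (len(d.allele) if d.kind == "DEL" else 0)
        if not 1 <= d.position <= len(target) or end > len(target) + 1:
            raise ValueError(f"indel at {d.position} outside target")
        events.append((d.position, d.kind, d))
    out = target
    for pos, kind, ev in sorted(events, key=lambda e: -e[0]):
        if kind == "SNP":
            out = out[: pos - 1] + ev.alt + out[pos:]
        elif kind == "DEL":
            out = out[: pos - 1] + out[pos - 1 + len(ev.allele):]
        else:  # INS after position pos
            out = out[:pos] + ev.allele + out[pos:]
    return out


def _inject_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == chars[i]:
            alt = "ACGT"[int(rng.integers(0, 4))]
        chars[i] = alt
    return "".join(chars)


def _read_pair_from_molecule(
    molecule: str,
    amplicon: Amplicon,
    public: str,
    read_length: int,
) -> tuple[str, str]:
    """Fixed-length reads from both ends of an indexed molecule.

    R2 starts at the sample index and runs into the molecule; R1 reads
    the complementary strand from the opposite end.  Short molecules are
    padded with adapter (public) sequence read-through, oriented so that
    surviving pairs are not mistaken for capture failures.
    """
    fill = public * (read_length // max(len(public), 1) + 2)
    fragment_fwd = amplicon.index_seq + molecule + fill
    r2 = fragment_fwd[:read_length]
    fragment_rev = revcomp(molecule) + revcomp(amplicon.index_seq) + revcomp(fill)
    r1 = fragment_rev[:read_length]
    return r1, r2


def simulate_read_pairs(
    panel: AmpliconPanel, truth: SimulationTruth
) -> list[ReadPair]:
    """Generate all read pairs of the experiment, deterministically.

    For each amplicon, ``depth`` pairs are drawn; each pair carries the
    mutated haplotype with probability equal to the amplicon's allele
    fraction.  With ``capture_failure_rate > 0`` a pair is occasionally
    replaced by a capture failure whose R1 contains the public sequence.
    """
    rng = np.random.default_rng(truth.seed % _SEED_MOD)
    pairs: list[ReadPair] = []
    for amp in panel:
        snps, indels = truth.variants_of(amp.amplicon_id)
        fractions = {v.allele_fraction for v in snps} | {
            v.allele_fraction for v in indels
        }
        if len(fractions) > 1:
            raise ValueError(
                f"{amp.amplicon_id}: all variants of one amplicon must share "
                "an allele fraction (they ride one mutated haplotype)"
            )
        fraction = fractions.pop() if fractions else 0.0
        ref_molecule = amp.fwd_primer + amp.target_seq + amp.rev_primer
        mut_molecule = (
            amp.fwd_primer
            + apply_variants(amp.target_seq, snps, indels)
            + amp.rev_primer
        )
        for k in range(truth.depth):
            read_id = f"{amp.amplicon_id}:{k:05d}"
            if (
                truth.capture_failure_rate > 0
                and rng.random() < truth.capture_failure_rate
            ):
                junk = _random_dna(rng, truth.read_length)
                r1 = (
                    junk[: truth.read_length // 3]
                    + panel.public_seq
                    + junk
                )[: truth.read_length]
                r2 = _random_dna(rng, truth.read_length)
                pairs.append(ReadPair(read_id + ":fail", r1, r2))
                continue
            molecule = (
                mut_molecule if rng.random() < fraction else ref_molecule
            )
            r1, r2 = _read_pair_from_molecule(
                molecule, amp, panel.public_seq, truth.read_length
            )
            r1 = _inject_errors(r1, rng, truth.error_rate)
            r2 = _inject_errors(r2, rng, truth.error_rate)
            pairs.append(ReadPair(read_id, r1, r2))
    return pairs


def simulate_reads(
    panel: AmpliconPanel, truth: SimulationTruth, out_prefix
) -> tuple[str, str, str]:
    """Write the simulated experiment to ``<prefix>_R{1,2}.fq`` + truth TSV."""
    pairs = simulate_read_pairs(panel, truth)
    r1_path = f"{out_prefix}_R1.fq"
    r2_path = f"{out_prefix}_R2.fq"
    truth_path = f"{out_prefix}_truth.tsv"
    write_fastq_pair(pairs, r1_path, r2_path)
    write_truth(truth, panel, truth_path)
    return r1_path, r2_path, truth_path


# ---------------------------------------------------------------------------
# Truth serialization
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, panel: AmpliconPanel, path) -> None:
    """Write the spike-in record as TSV.

    Indel rows carry both the raw spike position and the left-shifted
    normal form so downstream evaluation does not need the panel.
    Target lengths are stored as pragma lines for positional TN counting.
    """
    with open(path, "w") as fh:
        fh.write(f"#depth={truth.depth}\n")
        fh.write(f"#read_length={truth.read_length}\n")
        fh.write(f"#error_rate={truth.error_rate}\n")
        fh.write(f"#seed={truth.seed}\n")
        for a in panel:
            fh.write(f"#target_len\t{a.amplicon_id}\t{len(a.target_seq)}\n")
        fh.write(
            "kind\tamplicon_id\tposition\tref\talt\tallele\t"
            "norm_position\tnorm_allele\tallele_fraction\n"
        )
        for s in truth.snps:
            fh.write(
                f"SNP\t{s.amplicon_id}\t{s.position}\t{s.ref}\t{s.alt}\t.\t"
                f"{s.position}\t.\t{s.allele_fraction:.6g}\n"
            )
        for d in truth.indels:
            target = panel[d.amplicon_id].target_seq
            if d.kind == "DEL":
                npos, nallele = normalize_deletion(
                    target, d.position, len(d.allele)
                )
            else:
                npos, nallele = normalize_insertion(target, d.position, d.allele)
            fh.write(
                f"{d.kind}\t{d.amplicon_id}\t{d.position}\t.\t.\t{d.allele}\t"
                f"{npos}\t{nallele}\t{d.allele_fraction:.6g}\n"
            )


def read_truth(path) -> tuple[SimulationTruth, dict[str, int], dict]:
    """Read a truth TSV back.

    Returns ``(truth, target_lens, normalized)`` where ``normalized``
    maps ``"snp"``/``"indel"`` to the canonical event sets used for
    matching.
    """
    truth = SimulationTruth()
    target_lens: dict[str, int] = {}
    snp_events: set[tuple[str, int, str, str]] = set()
    indel_events: set[tuple[str, str, int, str]] = set()
    header_seen = False
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#target_len\t"):
                _, amp, length = line.split("\t")
                target_lens[amp] = int(length)
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "depth":
                    truth.depth = int(value)
                elif key == "read_length":
                    truth.read_length = int(value)
                elif key == "error_rate":
                    truth.error_rate = float(value)
                elif key == "seed":
                    truth.seed = int(value)
                continue
            if not header_seen:
                header_seen = True
                continue
            (kind, amp, pos, ref, alt, allele, npos, nallele, af) = line.split("\t")
            if kind == "SNP":
                truth.snps.append(
                    SpikedSNP(amp, int(pos), ref, alt, float(af))
                )
                snp_events.add((amp, int(pos), ref, alt))
            else:
                truth.indels.append(
                    SpikedIndel(amp, int(pos), kind, allele, float(af))
                )
                indel_events.add((amp, kind, int(npos), nallele))
    normalized = {"snp": snp_events, "indel": indel_events}
    return truth, target_lens, normalized


# ---------------------------------------------------------------------------
# Truth matching and metrics
# ---------------------------------------------------------------------------

def truth_events(truth: SimulationTruth, panel: AmpliconPanel) -> dict:
    """Canonical event sets of a truth record (indels left-normalised)."""
    snp_events = {(s.amplicon_id, s.position, s.ref, s.alt) for s in truth.snps}
    indel_events = set()
    for d in truth.indels:
        target = panel[d.amplicon_id].target_seq
        if d.kind == "DEL":
            npos, nallele = normalize_deletion(target, d.position, len(d.allele))
        else:
            npos, nallele = normalize_insertion(target, d.position, d.allele)
        indel_events.add((d.amplicon_id, d.kind, npos, nallele))
    return {"snp": snp_events, "indel": indel_events}


def calls_to_events(calls: Iterable[VariantRecord]) -> dict:
    """Convert anchored records to the same canonical event keys."""
    snp_events = set()
    indel_events = set()
    for c in calls:
        if c.kind == "SNP":
            snp_events.add((c.amplicon_id, c.position, c.ref_base, c.alt))
        elif c.kind == "DEL":
            if len(c.alt) == 1 and c.ref_base.startswith(c.alt):
                # left-anchored: event starts one base after POS
                indel_events.add(
                    (c.amplicon_id, "DEL", c.position + 1, c.ref_base[1:])
                )
            else:  # right-anchored start-of-target deletion
                indel_events.add(
                    (c.amplicon_id, "DEL", c.position, c.ref_base[:-1])
                )
        else:
            if len(c.ref_base) == 1 and c.alt.startswith(c.ref_base):
                indel_events.add(
                    (c.amplicon_id, "INS", c.position, c.alt[1:])
                )
            else:
                indel_events.add(
                    (c.amplicon_id, "INS", c.position - 1, c.alt[:-1])
                )
    return {"snp": snp_events, "indel": indel_events}


def _event_positions(events: Iterable[tuple]) -> set[tuple[str, int]]:
    out = set()
    for ev in events:
        if len(ev) == 4 and ev[1] in ("INS", "DEL"):
            out.add((ev[0], ev[2]))
        else:
            out.add((ev[0], ev[1]))
    return out


def match_calls(
    calls: Iterable[VariantRecord],
    truth_ev: dict,
    target_lens: dict[str, int],
) -> tuple[ConfusionCounts, ConfusionCounts]:
    """Confusion counts for SNPs and indels separately.

    A SNP matches on (amplicon, position, ref, alt); an indel on
    (amplicon, kind, normalised position, normalised allele).  TN counts
    target positions free of both truth and called events of that class.
    """
    call_ev = calls_to_events(calls)
    total_positions = sum(target_lens.values())
    out = []
    for cls in ("snp", "indel"):
        t, c = truth_ev[cls], call_ev[cls]
        cc = ConfusionCounts(
            tp=len(t & c),
            fp=len(c - t),
            fn=len(t - c),
        )
        occupied = _event_positions(t) | _event_positions(c)
        cc.tn = max(0, total_positions - len(occupied))
        out.append(cc)
    return out[0], out[1]


def recall(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); ``None`` when no positive truth exists."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def tpr_fpr_accuracy(
    c: ConfusionCounts,
) -> tuple[float | None, float | None, float | None]:
    """True positive rate, false positive rate and accuracy.

    Zero denominators yield ``None`` fields rather than raising.
    """
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    fpr = c.fp / (c.fp + c.tn) if (c.fp + c.tn) else None
    total = c.tp + c.fp + c.fn + c.tn
    acc = (c.tp + c.tn) / total if total else None
    return tpr, fpr, acc
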