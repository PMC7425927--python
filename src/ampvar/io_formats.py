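"""Core record types and readers/writers for external formats.

The pipeline touches four formats:

* paired FASTQ (Sanger quality) for the R1/R2 sequencing reads,
* a bespoke tab-separated panel description (one row per amplicon plus a
  ``#public_seq=`` pragma line for the shared capture sequence),
* VCF 4.2 for called variants,
* plain TSV for summary reports (written by the pipeline module).

All sequences are handled as uppercase strings over ``{A, C, G, T, N}``.
Variant positions are 1-based within each amplicon's target sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "DNA_ALPHABET",
    "revcomp",
    "ReadPair",
    "Amplicon",
    "AmpliconPanel",
    "VariantRecord",
    "PanelError",
    "FastqPairingError",
    "FastqParseError",
    "read_fastq_pair",
    "write_fastq_pair",
    "load_panel",
    "write_panel",
    "write_variants",
    "read_variants",
]

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised when an amplicon panel description is invalid."""


class FastqPairingError(ValueError):
    """Raised when R1 and R2 files do not hold the same number of records."""


class FastqParseError(ValueError):
    """Raised on a malformed FASTQ record; message carries the line number."""


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")


@dataclass
class ReadPair:
    """One mate pair: the unit flowing through cleaning and collapsing.

    Quality strings may be ``None`` for simulated error-free data; when
    present they must match the sequence lengths.
    """

    read_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str | None = None
    r2_qual: str | None = None

    def __post_init__(self) -> None:
        self.r1_seq = self.r1_seq.upper()
        self.r2_seq = self.r2_seq.upper()
        _check_dna(self.r1_seq, f"r1_seq of {self.read_id!r}")
        _check_dna(self.r2_seq, f"r2_seq of {self.read_id!r}")
        for seq, qual, name in (
            (self.r1_seq, self.r1_qual, "r1"),
            (self.r2_seq, self.r2_qual, "r2"),
        ):
            if qual is not None and len(qual) != len(seq):
                raise ValueError(
                    f"{name}_qual length {len(qual)} != sequence length "
                    f"{len(seq)} for read {self.read_id!r}"
                )


@dataclass
class Amplicon:
    """One panel entry: primers, target (exon) reference and sample index."""

    amplicon_id: str
    fwd_primer: str
    rev_primer: str
    target_seq: str
    index_seq: str

    def __post_init__(self) -> None:
        for name in ("fwd_primer", "rev_primer", "target_seq", "index_seq"):
            setattr(self, name, getattr(self, name).upper())
            _check_dna(getattr(self, name), f"{name} of {self.amplicon_id!r}")
        if len(self.target_seq) >= 200:
            # Panels are designed so that paired 150 bp reads overlap the
            # target; longer targets are legal but degrade coverage.
            warnings.warn(
                f"target_seq of {self.amplicon_id!r} is "
                f"{len(self.target_seq)} bp (>= 200); paired reads may not "
                "cover it fully",
                stacklevel=2,
            )


@dataclass
class AmpliconPanel:
    """An ordered amplicon collection sharing one public (capture) sequence."""

    amplicons: list[Amplicon]
    public_seq: str

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise PanelError("panel holds no amplicons")
        self.public_seq = self.public_seq.upper()
        _check_dna(self.public_seq, "public_seq")
        ids = [a.amplicon_id for a in self.amplicons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelError(f"duplicate amplicon ids: {dupes}")
        fwds = [a.fwd_primer for a in self.amplicons]
        if len(set(fwds)) != len(fwds):
            # Identical forward primers can never be told apart by any
            # position set, so demultiplexing would be impossible.
            raise PanelError("forward primers are not pairwise distinct")
        self._by_id = {a.amplicon_id: a for a in self.amplicons}

    def __len__(self) -> int:
        return len(self.amplicons)

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    @property
    def shared_index(self) -> str | None:
        """The panel-wide index sequence, or None if amplicons disagree."""
        idx = {a.index_seq for a in self.amplicons}
        return idx.pop() if len(idx) == 1 else None

    @property
    def uniform_target_length(self) -> int | None:
        lens = {len(a.target_seq) for a in self.amplicons}
        return lens.pop() if len(lens) == 1 else None


@dataclass
class VariantRecord:
    """One called variant, stored in VCF-ready left-anchored form.

    For SNPs ``ref_base`` and ``alt`` are single bases at ``position``.
    Indels carry the shared anchor base: a deletion has ``ref_base`` =
    anchor + deleted bases and ``alt`` = anchor; an insertion has
    ``ref_base`` = anchor and ``alt`` = anchor + inserted bases.
    """

    amplicon_id: str
    position: int
    ref_base: str
    alt: str
    kind: str
    alt_fraction: float
    depth: int

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "INS", "DEL"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.ref_base == self.alt:
            raise ValueError("alt allele equals ref allele")
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction outside [0, 1]")
        if self.depth < 0:
            raise ValueError("negative depth")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _qual_string(record) -> str | None:
    phred = record.letter_annotations.get("phred_quality")
    if phred is None:
        return None
    return "".join(chr(q + 33) for q in phred)


def _strip_mate_tag(name: str) -> str:
    name = name.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


def read_fastq_pair(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files in record order.

    Mates are paired positionally (record i of R1 with record i of R2);
    ``/1``/``/2`` suffixes and space-separated tags are tolerated and
    stripped from the pair id.  A record-count mismatch raises
    :class:`FastqPairingError`; a malformed record raises
    :class:`FastqParseError` carrying the approximate line number.
    """
    sentinel = object()
    it1 = SeqIO.parse(str(path_r1), "fastq")
    it2 = SeqIO.parse(str(path_r2), "fastq")
    i = 0
    while True:
        try:
            rec1 = next(it1, sentinel)
            rec2 = next(it2, sentinel)
        except ValueError as exc:
            raise FastqParseError(
                f"malformed FASTQ record near line {4 * i + 1}: {exc}"
            ) from exc
        if rec1 is sentinel and rec2 is sentinel:
            return
        if rec1 is sentinel or rec2 is sentinel:
            short = path_r1 if rec1 is sentinel else path_r2
            raise FastqPairingError(
                f"unequal record counts: {short} ended after {i} records"
            )
        yield ReadPair(
            read_id=_strip_mate_tag(rec1.id),
            r1_seq=str(rec1.seq),
            r2_seq=str(rec2.seq),
            r1_qual=_qual_string(rec1),
            r2_qual=_qual_string(rec2),
        )
        i += 1


def write_fastq_pair(pairs: Iterable[ReadPair], path_r1, path_r2) -> None:
    """Write mate pairs as two canonical 4-line-per-record FASTQ files.

    Absent quality strings are emitted as Q40 (``I``) so files round-trip.
    """
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for pair in pairs:
            q1 = pair.r1_qual or "I" * len(pair.r1_seq)
            q2 = pair.r2_qual or "I" * len(pair.r2_seq)
            f1.write(f"@{pair.read_id}/1\n{pair.r1_seq}\n+\n{q1}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.r2_seq}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# Panel TSV
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["amplicon_id", "fwd_primer", "rev_primer", "index", "target_seq"]


def load_panel(path) -> AmpliconPanel:
    """Load a panel TSV.

    Format: an optional ``#public_seq=<SEQ>`` pragma line, a header line
    with the columns ``amplicon_id  fwd_primer  rev_primer  index
    target_seq``, then one row per amplicon.  Validation failures raise
    :class:`PanelError`.
    """
    public_seq = None
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.startswith("#public_seq="):
                    public_seq = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header != _PANEL_COLUMNS:
                    raise PanelError(
                        f"line {lineno}: expected columns {_PANEL_COLUMNS}, "
                        f"got {header}"
                    )
                continue
            if len(fields) != len(_PANEL_COLUMNS):
                raise PanelError(
                    f"line {lineno}: expected {len(_PANEL_COLUMNS)} fields, "
                    f"got {len(fields)}"
                )
            rows.append([f.strip() for f in fields])
    if header is None or not rows:
        raise PanelError(f"{path}: no amplicon rows found")
    if public_seq is None:
        raise PanelError(f"{path}: missing '#public_seq=' pragma line")
    try:
        amplicons = [
            Amplicon(
                amplicon_id=r[0],
                fwd_primer=r[1],
                rev_primer=r[2],
                index_seq=r[3],
                target_seq=r[4],
            )
            for r in rows
        ]
        return AmpliconPanel(amplicons=amplicons, public_seq=public_seq)
    except ValueError as exc:
        raise PanelError(str(exc)) from exc


def write_panel(panel: AmpliconPanel, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#public_seq={panel.public_seq}\n")
        fh.write("\t".join(_PANEL_COLUMNS) + "\n")
        for a in panel:
            fh.write(
                f"{a.amplicon_id}\t{a.fwd_primer}\t{a.rev_primer}\t"
                f"{a.index_seq}\t{a.target_seq}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ampvar
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pileup depth at the variant position">
##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction of the pileup depth">
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant class: SNP, INS or DEL">
"""


def write_variants(calls: Iterable[VariantRecord], path) -> None:
    """Write calls as a minimal VCF 4.2 file (CHROM = amplicon id).

    Records are sorted by (amplicon id, position) for determinism; an
    empty call set produces a header-only file.
    """
    calls = sorted(calls, key=lambda c: (c.amplicon_id, c.position, c.alt))
    contigs = sorted({c.amplicon_id for c in calls})
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            af = f"{c.alt_fraction:.6g}"
            fh.write(
                f"{c.amplicon_id}\t{c.position}\t.\t{c.ref_base}\t{c.alt}\t"
                f".\t.\tDP={c.depth};AF={af};TYPE={c.kind}\n"
            )


def _infer_kind(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "DEL" if len(ref) > len(alt) else "INS"


def read_variants(path) -> list[VariantRecord]:
    """Parse a VCF written by :func:`write_variants` back into records."""
    from cyvcf2 import VCF

    records = []
    vcf = VCF(str(path))
    for v in vcf:
        alt = v.ALT[0] if v.ALT else v.REF
        kind = v.INFO.get("TYPE") or _infer_kind(v.REF, alt)
        dp = v.INFO.get("DP")
        af = v.INFO.get("AF")
        records.append(
            VariantRecord(
                amplicon_id=v.CHROM,
                position=v.POS,
                ref_base=v.REF,
                alt=alt,
                kind=kind,
                alt_fraction=float(af) if af is not None else 0.0,
                depth=int(dp) if dp is not None else 0,
            )
        )
    vcf.close()
    return records
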