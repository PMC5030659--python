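"""Genome and alignment data model, text-format I/O, coverage and depth.

Coordinates are 0-based, half-open everywhere inside the package; the SAM
boundary (via :mod:`pysam`) converts to and from the 1-based convention.
Only primary alignments are ingested: the split-read pipeline derives split
placements itself from soft clips, so secondary/supplementary records from a
mapper would be redundant evidence.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files (FASTA/SAM/TSV)."""


class UnsupportedFeatureError(ValueError):
    """Raised when an input uses a feature outside this pipeline's scope
    (e.g. hard clips or spliced CIGAR operations)."""


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ReferenceGenome:
    """Named linkage groups (plus any auxiliary sequences such as vectors).

    ``sequences`` preserves input order; all sequences are upper-case DNA
    over the alphabet ``ACGTN``.
    """

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise FormatError("reference genome has no sequences")
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for record {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name!r} contains non-DNA characters: {sorted(bad)}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def names(self) -> list[str]:
        return list(self.sequences)


@dataclass
class Read:
    """A sequencing read; ``qual`` is an optional phred+33 string."""

    id: str
    seq: str
    qual: Optional[str] = None
    #: provenance attached by the simulator (see synthetic_data.ReadOrigin);
    #: absent for reads parsed from files.
    origin: Optional[object] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"read {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(f"read {self.id!r}: quality length mismatch")


#: CIGAR operations this pipeline understands.
SUPPORTED_CIGAR_OPS = frozenset("MSID")


@dataclass
class Alignment:
    """A primary alignment of one read.

    ``seq`` follows the SAM convention: it is the read sequence as stored,
    i.e. reverse complemented when ``strand`` is '-'. ``start`` is the
    0-based reference position of the first aligned (M) base.
    """

    read_id: str
    lg: str
    start: int
    strand: str  # '+' or '-'
    cigar: list[tuple[str, int]]
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for op, ln in self.cigar:
            if op not in SUPPORTED_CIGAR_OPS:
                raise UnsupportedFeatureError(
                    f"read {self.read_id!r}: unsupported CIGAR op {op!r}"
                )
            if ln <= 0:
                raise FormatError(f"read {self.read_id!r}: non-positive CIGAR length")
        read_len = sum(ln for op, ln in self.cigar if op in "MIS")
        if read_len != len(self.seq):
            raise FormatError(
                f"read {self.read_id!r}: CIGAR M/I/S total {read_len} != "
                f"sequence length {len(self.seq)}"
            )
        ops = [op for op, _ in self.cigar]
        if ops.count("S") > 2 or (ops.count("S") and not (
            ops[0] == "S" or ops[-1] == "S"
        )):
            raise FormatError(f"read {self.read_id!r}: internal soft clip")
        if len(ops) > 1 and "S" in ops[1:-1]:
            raise FormatError(f"read {self.read_id!r}: internal soft clip")

    @property
    def leading_clip(self) -> int:
        return self.cigar[0][1] if self.cigar[0][0] == "S" else 0

    @property
    def trailing_clip(self) -> int:
        return self.cigar[-1][1] if len(self.cigar) > 1 and self.cigar[-1][0] == "S" else 0

    @property
    def ref_end(self) -> int:
        """End (exclusive) of the reference span consumed by M/D operations."""
        return self.start + sum(ln for op, ln in self.cigar if op in "MD")

    @property
    def aligned_length(self) -> int:
        """Number of read bases inside M operations."""
        return sum(ln for op, ln in self.cigar if op == "M")


@dataclass
class DepthTrack:
    """Per-base read depth for every linkage group.

    ``depth[lg][i]`` counts reads whose aligned (M) span covers base ``i``;
    soft-clipped bases contribute nothing.
    """

    depth: dict[str, np.ndarray]
    coverage: Optional[float] = None

    @property
    def total(self) -> int:
        return int(sum(int(v.sum()) for v in self.depth.values()))


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str) -> ReferenceGenome:
    """Load a (multi-record) FASTA file as a :class:`ReferenceGenome`.

    Sequences are upper-cased; record order is preserved; duplicate record
    names raise :class:`FormatError`.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate FASTA record name {rec.id!r}")
        sequences[rec.id] = str(rec.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return ReferenceGenome(sequences)


def write_fasta(genome: ReferenceGenome, path: str, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython controls wrapping


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.qual or "I" * len(read.seq)
            fh.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_fastq(path: str) -> list[Read]:
    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        reads.append(Read(rec.id, str(rec.seq).upper(), quals))
    return reads


# ---------------------------------------------------------------------------
# SAM

_PYSAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S"}


def read_sam(path: str, ref: ReferenceGenome) -> list[Alignment]:
    """Parse a text SAM file into :class:`Alignment` records.

    Unmapped (0x4), secondary (0x100) and supplementary (0x800) records are
    skipped. CIGAR operations outside M/I/D/S raise
    :class:`UnsupportedFeatureError`; coordinates are converted to 0-based.
    """
    alignments: list[Alignment] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            lg = rec.reference_name
            if lg not in ref:
                raise FormatError(
                    f"read {rec.query_name!r} mapped to unknown reference {lg!r}"
                )
            cigar = []
            for code, ln in rec.cigartuples or []:
                op = _PYSAM_OPS.get(code)
                if op is None:
                    raise UnsupportedFeatureError(
                        f"read {rec.query_name!r}: unsupported CIGAR op code {code}"
                    )
                cigar.append((op, ln))
            aln = Alignment(
                read_id=rec.query_name,
                lg=lg,
                start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                seq=(rec.query_sequence or "").upper(),
            )
            if aln.ref_end > len(ref[lg]):
                raise FormatError(
                    f"read {rec.query_name!r}: alignment exceeds {lg} bounds"
                )
            alignments.append(aln)
    return alignments


def write_sam(alignments: Sequence[Alignment], ref: ReferenceGenome, path: str) -> None:
    """Write alignments as text SAM (sorted as given)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": name, "LN": len(seq)} for name, seq in ref.sequences.items()
        ],
    }
    names = list(ref.sequences)
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            rec.reference_id = names.index(aln.lg)
            rec.reference_start = aln.start
            rec.mapping_quality = 60
            rec.flag = 16 if aln.strand == "-" else 0
            rec.cigartuples = [
                ({"M": 0, "I": 1, "D": 2, "S": 4}[op], ln) for op, ln in aln.cigar
            ]
            rec.query_sequence = aln.seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(aln.seq))
            out.write(rec)


# ---------------------------------------------------------------------------
# Coverage and depth


def compute_coverage(alignments: Sequence[Alignment], ref: ReferenceGenome) -> float:
    """Genome-wide coverage: mean read length x read count / reference length.

    Read length is the full stored sequence length, clips included (the raw,
    pre-mapping read length).
    """
    if not alignments:
        raise ValueError("cannot compute coverage from zero reads")
    total_bases = sum(len(a.seq) for a in alignments)
    return total_bases / ref.total_length


def compute_depth(
    alignments: Sequence[Alignment],
    ref: ReferenceGenome,
    coverage: Optional[float] = None,
) -> DepthTrack:
    """Per-base depth: number of reads whose M span covers each base."""
    diffs = {name: np.zeros(len(seq) + 1, dtype=np.int64) for name, seq in ref.sequences.items()}
    for aln in alignments:
        pos = aln.start
        d = diffs[aln.lg]
        for op, ln in aln.cigar:
            if op == "M":
                d[pos] += 1
                d[pos + ln] -= 1
                pos += ln
            elif op == "D":
                pos += ln
            # I and S consume no reference
    depth = {name: np.cumsum(d[:-1]) for name, d in diffs.items()}
    return DepthTrack(depth=depth, coverage=coverage)


def log(msg: str, *, verbose: bool = True) -> None:
    """Write a progress message to standard error."""
    if verbose:
        print(f"[balancerscan] {msg}", file=sys.stderr)
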