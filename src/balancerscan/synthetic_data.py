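"""Seeded simulation of rearranged genomes, short single-end reads, and
mapper-emulated alignments.

The simulator emulates the study design the detection pipeline was built
for: a case genome carrying engineered rearrangements (inversions,
reciprocal translocations, deletions, insertions, duplications), sequenced
as ~140 bp single-end reads, mapped back to the *un*-rearranged reference so
that breakpoint-crossing reads appear as soft-clipped records. Mapping is
emulated from ground truth rather than performed by a real aligner: a read
lying inside a colinear segment maps as a single M run; a read crossing a
breakpoint is placed by its longer colinear piece with the remainder
soft-clipped. This guarantees exactly the clip structure the split-read
pipeline consumes while staying deterministic and fast.

Junction micro-indels model end-joining repair scars: most real engineered
junctions carry small indels, so the generator injects them by default
(probability 0.8, at most 10 bp per junction).
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np

from .core_io import (
    Alignment,
    Read,
    ReferenceGenome,
    revcomp,
    write_fasta,
    write_fastq,
    write_sam,
)

# rng stream labels, combined with the master seed so each stage is
# independently reproducible
_STREAM_GENOME = 11
_STREAM_REARRANGE = 13
_STREAM_READS_CASE = 17
_STREAM_READS_CONTROL = 19


# ---------------------------------------------------------------------------
# Plans and configuration


@dataclass(frozen=True)
class Inversion:
    lg: str
    left_cut: int
    right_cut: int


@dataclass(frozen=True)
class ReciprocalTranslocation:
    lg_a: str
    cut_a: int
    lg_b: str
    cut_b: int


@dataclass(frozen=True)
class Deletion:
    lg: str
    start: int
    end: int


@dataclass(frozen=True)
class Insertion:
    lg: str
    pos: int
    inserted_seq: str


@dataclass(frozen=True)
class Duplication:
    lg: str
    start: int
    end: int
    copies: int = 2


Event = Union[Inversion, ReciprocalTranslocation, Deletion, Insertion, Duplication]


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the study conditions.

    Read length is discrete-uniform on ``read_length_mean +- jitter``
    (approximately 140 bp fragments); error rates are per base.
    """

    seed: int = 0
    n_linkage_groups: int = 2
    lengths: tuple = (50_000, 50_000)
    gc_fraction: float = 0.36  # C. elegans-like base composition
    read_length_mean: int = 140
    read_length_jitter: int = 10
    substitution_rate: float = 0.005
    indel_rate: float = 0.0005
    coverage: float = 20.0
    microindel_prob: float = 0.8
    microindel_max: int = 10
    min_seed: int = 20  # shortest colinear piece the emulated mapper will place

    def __post_init__(self) -> None:
        for p in (self.gc_fraction, self.substitution_rate, self.indel_rate,
                  self.microindel_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(l < 1000 for l in self.lengths):
            raise ValueError("linkage groups must be at least 1 kb")
        if len(self.lengths) != self.n_linkage_groups:
            raise ValueError("lengths must match n_linkage_groups")


# ---------------------------------------------------------------------------
# Truth bookkeeping


@dataclass
class Segment:
    """One piece of a derived chromosome.

    ``kind`` is ``'ref'`` for colinear pieces of the source genome,
    ``'insertion'`` for event-inserted novel sequence, and ``'scar'`` for
    junction micro-indel insertions. Non-ref pieces carry their bases in
    ``seq``; ref pieces equal ``ref[src_lg][start:end]`` (orient ``+``) or
    its reverse complement (orient ``-``).
    """

    src_lg: Optional[str]
    start: int = 0
    end: int = 0
    orient: str = "+"
    seq: Optional[str] = None
    kind: str = "ref"

    def materialize(self, ref: ReferenceGenome) -> str:
        if self.src_lg is None:
            return self.seq or ""
        s = ref[self.src_lg][self.start:self.end]
        return s if self.orient == "+" else revcomp(s)

    def length(self) -> int:
        if self.src_lg is None:
            return len(self.seq or "")
        return self.end - self.start


@dataclass
class Breakpoint:
    """A truth junction, in ORIGINAL reference coordinates."""

    lg: str
    pos: int
    partner_lg: str
    partner_pos: int
    orientation: str        # 'same' or 'inverted' strand relation across the junction
    category: str           # expected split-read category at this junction
    microindel: int = 0     # junction scar size (bp), 0 when repair was clean
    derived_lg: str = ""
    derived_pos: int = -1   # junction position on the derived chromosome


@dataclass
class TruthSet:
    """Derived genome plus the segment map and truth breakpoints."""

    ref: ReferenceGenome
    derived: ReferenceGenome
    segments: dict[str, list[Segment]]
    breakpoints: list[Breakpoint]
    plan: list = field(default_factory=list)

    def segment_offsets(self) -> dict[str, np.ndarray]:
        """Derived-coordinate start offset of every segment, per chromosome."""
        out = {}
        for lg, segs in self.segments.items():
            offs = np.zeros(len(segs) + 1, dtype=np.int64)
            for i, seg in enumerate(segs):
                offs[i + 1] = offs[i] + seg.length()
            out[lg] = offs
        return out

    @classmethod
    def identity(cls, ref: ReferenceGenome) -> "TruthSet":
        segs = {
            name: [Segment(name, 0, len(seq), "+")]
            for name, seq in ref.sequences.items()
        }
        return cls(ref=ref, derived=ref, segments=segs, breakpoints=[])


# ---------------------------------------------------------------------------
# Genome simulation


def simulate_genome(config: SimConfig) -> ReferenceGenome:
    """I.i.d. random genome at the configured GC fraction, seeded."""
    rng = np.random.default_rng([config.seed, _STREAM_GENOME])
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    names = [f"chr{'I' * (i + 1)}" if i < 3 else f"chr{i + 1}"
             for i in range(config.n_linkage_groups)]
    sequences = {}
    for name, length in zip(names, config.lengths):
        codes = rng.choice(4, size=length, p=probs)
        sequences[name] = "".join(np.array(list("ACGT"))[codes])
    return ReferenceGenome(sequences)


# ---------------------------------------------------------------------------
# Applying rearrangements


def _validate_plan(ref: ReferenceGenome, plan: Sequence[Event]) -> None:
    intervals: dict[str, list[tuple[int, int]]] = {}

    def claim(lg: str, a: int, b: int) -> None:
        if lg not in ref:
            raise ValueError(f"event references unknown linkage group {lg!r}")
        if not (0 <= a <= b <= len(ref[lg])):
            raise ValueError(f"event interval [{a}, {b}) outside {lg} bounds")
        for x, y in intervals.get(lg, []):
            if a < y and x < b:
                raise ValueError(
                    f"overlapping events on {lg}: [{a},{b}) vs [{x},{y})"
                )
        intervals.setdefault(lg, []).append((a, b))

    for ev in plan:
        if isinstance(ev, Inversion):
            if ev.left_cut >= ev.right_cut:
                raise ValueError("inversion requires left_cut < right_cut")
            claim(ev.lg, ev.left_cut, ev.right_cut)
        elif isinstance(ev, Deletion):
            if ev.start >= ev.end:
                raise ValueError("deletion requires start < end")
            claim(ev.lg, ev.start, ev.end)
        elif isinstance(ev, Duplication):
            if ev.start >= ev.end or ev.copies < 2:
                raise ValueError("duplication requires start < end and copies >= 2")
            claim(ev.lg, ev.start, ev.end)
        elif isinstance(ev, Insertion):
            if not ev.inserted_seq:
                raise ValueError("insertion requires a non-empty sequence")
            claim(ev.lg, ev.pos, ev.pos + 1)
        elif isinstance(ev, ReciprocalTranslocation):
            if ev.lg_a == ev.lg_b:
                raise ValueError("reciprocal translocation needs two linkage groups")
            claim(ev.lg_a, ev.cut_a, ev.cut_a + 1)
            claim(ev.lg_b, ev.cut_b, ev.cut_b + 1)
        else:
            raise TypeError(f"unknown event type {type(ev).__name__}")


def _boundary_coord(seg: Segment, side: str) -> Optional[tuple[str, int]]:
    """Original-frame coordinate of a segment end ('left' = derived 5' end);
    None for novel segments."""
    if seg.src_lg is None:
        return None
    if (side == "left") == (seg.orient == "+"):
        return seg.src_lg, seg.start
    return seg.src_lg, seg.end


def _colinear(a: Segment, b: Segment) -> bool:
    if a.src_lg is None or b.src_lg is None:
        return False
    if a.src_lg != b.src_lg or a.orient != b.orient:
        return False
    return (a.end == b.start) if a.orient == "+" else (a.start == b.end)


@dataclass
class _Junction:
    lg: str               # derived chromosome
    left_seg: Segment     # object immediately left of the junction
    left_coord: Optional[tuple[str, int]]
    right_coord: Optional[tuple[str, int]]
    scar: int = 0
    derived_pos: int = -1
    assigned: bool = False


def apply_rearrangements(
    ref: ReferenceGenome,
    plan: Sequence[Event],
    config: Optional[SimConfig] = None,
) -> TruthSet:
    """Build the derived genome and truth breakpoints for a plan.

    Events must be non-overlapping on the source genome. With
    ``config.microindel_prob > 0``, each engineered junction independently
    receives a small deletion or insertion scar (uniform 1..microindel_max
    bp), mimicking end-joining repair.
    """
    _validate_plan(ref, plan)
    if config is None:
        config = SimConfig(lengths=tuple(len(s) for s in ref.sequences.values()),
                           n_linkage_groups=len(ref.sequences),
                           microindel_prob=0.0)
    rng = np.random.default_rng([config.seed, _STREAM_REARRANGE])

    segments: dict[str, list[Segment]] = {
        name: [Segment(name, 0, len(seq), "+")] for name, seq in ref.sequences.items()
    }

    def split_at(lg: str, pos: int) -> int:
        """Split the colinear segment containing original position pos;
        return the index of the boundary at pos."""
        segs = segments[lg]
        for i, seg in enumerate(segs):
            if (seg.kind == "ref" and seg.src_lg == lg and seg.orient == "+"
                    and seg.start <= pos <= seg.end):
                if pos == seg.start:
                    return i
                if pos == seg.end:
                    return i + 1
                segs[i:i + 1] = [
                    Segment(lg, seg.start, pos, "+"),
                    Segment(lg, pos, seg.end, "+"),
                ]
                return i + 1
        raise ValueError(f"cut {lg}:{pos} does not fall in a colinear region")

    # truth breakpoint specs, generated directly from the events, in order
    bp_specs: list[tuple[str, int, str, int, str, str]] = []

    for ev in plan:
        if isinstance(ev, Inversion):
            i = split_at(ev.lg, ev.left_cut)
            j = split_at(ev.lg, ev.right_cut)
            mid = segments[ev.lg][i:j]
            segments[ev.lg][i:j] = [
                Segment(s.src_lg, s.start, s.end,
                        "-" if s.orient == "+" else "+", s.seq, s.kind)
                for s in reversed(mid)
            ]
            bp_specs.append((ev.lg, ev.left_cut, ev.lg, ev.right_cut,
                             "inverted", "inversion"))
            bp_specs.append((ev.lg, ev.right_cut, ev.lg, ev.left_cut,
                             "inverted", "inversion"))
        elif isinstance(ev, Deletion):
            i = split_at(ev.lg, ev.start)
            j = split_at(ev.lg, ev.end)
            del segments[ev.lg][i:j]
            bp_specs.append((ev.lg, ev.start, ev.lg, ev.end, "same", "deletion"))
        elif isinstance(ev, Insertion):
            i = split_at(ev.lg, ev.pos)
            ins_seq = ev.inserted_seq.upper()
            # a copied insertion (mobile-element style) is recorded as a
            # reference segment: a real mapper places its reads at the
            # source locus, doubling depth there
            copy_seg = None
            for src_lg, src_seq in ref.sequences.items():
                hit = src_seq.find(ins_seq)
                if hit >= 0:
                    copy_seg = Segment(src_lg, hit, hit + len(ins_seq), "+")
                    break
                hit = src_seq.find(revcomp(ins_seq))
                if hit >= 0:
                    copy_seg = Segment(src_lg, hit, hit + len(ins_seq), "-")
                    break
            if copy_seg is not None:
                segments[ev.lg][i:i] = [copy_seg]
                u, v = copy_seg.start, copy_seg.end
                if copy_seg.orient == "+":
                    bp_specs.append((ev.lg, ev.pos, copy_seg.src_lg, u,
                                     "same", "insertion"))
                    bp_specs.append((ev.lg, ev.pos, copy_seg.src_lg, v,
                                     "same", "insertion"))
                else:
                    bp_specs.append((ev.lg, ev.pos, copy_seg.src_lg, v,
                                     "inverted", "insertion"))
                    bp_specs.append((ev.lg, ev.pos, copy_seg.src_lg, u,
                                     "inverted", "insertion"))
            else:
                segments[ev.lg][i:i] = [
                    Segment(None, seq=ins_seq, kind="insertion")
                ]
                bp_specs.append((ev.lg, ev.pos, ev.lg, ev.pos, "same",
                                 "insertion"))
                bp_specs.append((ev.lg, ev.pos, ev.lg, ev.pos, "same",
                                 "insertion"))
        elif isinstance(ev, Duplication):
            i = split_at(ev.lg, ev.start)
            j = split_at(ev.lg, ev.end)
            copy = segments[ev.lg][i:j]
            for _ in range(ev.copies - 1):
                segments[ev.lg][j:j] = [
                    Segment(s.src_lg, s.start, s.end, s.orient, s.seq, s.kind)
                    for s in copy
                ]
                j += len(copy)
                bp_specs.append((ev.lg, ev.end, ev.lg, ev.start, "same", "insertion"))

    for ev in plan:
        if isinstance(ev, ReciprocalTranslocation):
            ia = split_at(ev.lg_a, ev.cut_a)
            ib = split_at(ev.lg_b, ev.cut_b)
            tail_a = segments[ev.lg_a][ia:]
            tail_b = segments[ev.lg_b][ib:]
            segments[ev.lg_a][ia:] = tail_b
            segments[ev.lg_b][ib:] = tail_a
            bp_specs.append((ev.lg_a, ev.cut_a, ev.lg_b, ev.cut_b,
                             "same", "translocation"))
            bp_specs.append((ev.lg_b, ev.cut_b, ev.lg_a, ev.cut_a,
                             "same", "translocation"))

    # --- scan engineered junctions (object-identity based, pre-scar coords)
    junctions: list[_Junction] = []
    for lg, segs in segments.items():
        for b in range(len(segs) - 1):
            left, right = segs[b], segs[b + 1]
            if _colinear(left, right):
                continue
            junctions.append(_Junction(
                lg=lg, left_seg=left,
                left_coord=_boundary_coord(left, "right"),
                right_coord=_boundary_coord(right, "left"),
            ))

    # --- micro-indel scars, one draw per junction
    for jn in junctions:
        if config.microindel_prob <= 0 or rng.random() >= config.microindel_prob:
            continue
        size = int(rng.integers(1, config.microindel_max + 1))
        segs = segments[jn.lg]
        b = next(i for i, s in enumerate(segs) if s is jn.left_seg)
        if rng.random() < 0.5:
            left_trim = int(rng.integers(0, size + 1))
            _trim_segment(segs[b], left_trim, side="right")
            if b + 1 < len(segs):
                _trim_segment(segs[b + 1], size - left_trim, side="left")
            jn.scar = size
        else:
            novel = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=size)])
            segs[b + 1:b + 1] = [Segment(None, seq=novel, kind="scar")]
            jn.scar = size

    # --- derived junction coordinates (zero-length segments contribute 0)
    for lg, segs in segments.items():
        off = 0
        by_id = {}
        for seg in segs:
            by_id[id(seg)] = off
            off += seg.length()
        for jn in junctions:
            if jn.lg == lg and id(jn.left_seg) in by_id:
                jn.derived_pos = by_id[id(jn.left_seg)] + jn.left_seg.length()

    for lg in segments:
        segments[lg] = [s for s in segments[lg] if s.length() > 0]

    derived = ReferenceGenome({
        lg: "".join(seg.materialize(ref) for seg in segs)
        for lg, segs in segments.items()
    })

    # --- match truth breakpoints to junctions
    breakpoints: list[Breakpoint] = []
    ordered = sorted(junctions, key=lambda j: (j.lg, j.derived_pos))

    def coord_dist(c: Optional[tuple[str, int]],
                   t: tuple[str, int]) -> float:
        if c is None:
            return 0.25  # novel side: weak wildcard match
        if c[0] != t[0]:
            return float("inf")
        return abs(c[1] - t[1])

    slack = 2 * config.microindel_max + 2
    for lg, pos, plg, ppos, orientation, category in bp_specs:
        best = None
        best_score = float("inf")
        for jn in ordered:
            if jn.assigned:
                continue
            s_fwd = coord_dist(jn.left_coord, (lg, pos)) + \
                coord_dist(jn.right_coord, (plg, ppos))
            s_rev = 0.5 + coord_dist(jn.left_coord, (plg, ppos)) + \
                coord_dist(jn.right_coord, (lg, pos))
            score = min(s_fwd, s_rev)
            if score < best_score:
                best, best_score = jn, score
        if best is None or best_score > slack:
            raise RuntimeError(
                f"internal error: no junction for breakpoint {lg}:{pos}")
        best.assigned = True
        breakpoints.append(Breakpoint(
            lg=lg, pos=pos, partner_lg=plg, partner_pos=ppos,
            orientation=orientation, category=category,
            microindel=best.scar, derived_lg=best.lg,
            derived_pos=best.derived_pos,
        ))

    return TruthSet(ref=ref, derived=derived, segments=segments,
                    breakpoints=breakpoints, plan=list(plan))


def _trim_segment(seg: Segment, n: int, side: str) -> None:
    n = min(n, seg.length())
    if n <= 0:
        return
    if seg.src_lg is None:
        seg.seq = seg.seq[n:] if side == "left" else seg.seq[:-n]
        return
    # 'left'/'right' refer to the derived orientation of the segment
    if (side == "left") == (seg.orient == "+"):
        seg.start += n
    else:
        seg.end -= n


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ReadOrigin:
    """Where a simulated read came from on the derived genome.

    ``positions`` is None for indel-free reads (implied contiguous range
    ``start..end``); otherwise one derived coordinate per fragment base, with
    -1 marking inserted (error) bases. Coordinates refer to the fragment in
    derived-forward orientation, before any reverse complementing.
    """

    lg: str
    start: int
    end: int
    strand: str
    positions: Optional[np.ndarray] = None


def simulate_reads(genome: ReferenceGenome, config: SimConfig,
                   stream: int = _STREAM_READS_CASE,
                   id_prefix: str = "r") -> list[Read]:
    """Uniformly placed single-end reads with substitution/indel errors.

    The read count targets ``config.coverage`` over the given genome;
    lengths are discrete-uniform on mean +- jitter; strands are equiprobable.
    Deterministic for a fixed (seed, stream).
    """
    rng = np.random.default_rng([config.seed, stream])
    names = genome.names()
    lengths = np.array([len(genome[n]) for n in names], dtype=np.int64)
    total = int(lengths.sum())
    n_reads = int(round(config.coverage * total / config.read_length_mean))
    if n_reads == 0:
        return []

    lg_idx = rng.choice(len(names), size=n_reads, p=lengths / total)
    read_lens = rng.integers(config.read_length_mean - config.read_length_jitter,
                             config.read_length_mean + config.read_length_jitter + 1,
                             size=n_reads)
    read_lens = np.minimum(read_lens, lengths[lg_idx])
    starts = (rng.random(n_reads) * (lengths[lg_idx] - read_lens + 1)).astype(np.int64)
    strands = rng.random(n_reads) < 0.5
    n_subs = rng.binomial(read_lens, config.substitution_rate)
    n_indels = rng.binomial(read_lens, config.indel_rate)

    bases = "ACGT"
    reads: list[Read] = []
    for i in range(n_reads):
        lg = names[int(lg_idx[i])]
        s = int(starts[i])
        L = int(read_lens[i])
        frag = list(genome[lg][s:s + L])
        positions: Optional[np.ndarray] = None
        if n_indels[i] > 0:
            pos_arr = list(range(s, s + L))
            for _ in range(int(n_indels[i])):
                at = int(rng.integers(0, len(frag)))
                if rng.random() < 0.5 and len(frag) > 1:
                    del frag[at]
                    del pos_arr[at]
                else:
                    frag.insert(at, bases[int(rng.integers(0, 4))])
                    pos_arr.insert(at, -1)
            positions = np.array(pos_arr, dtype=np.int64)
        if n_subs[i] > 0:
            for at in rng.integers(0, len(frag), size=int(n_subs[i])):
                old = frag[int(at)]
                choices = [b for b in bases if b != old]
                frag[int(at)] = choices[int(rng.integers(0, 3))]
        frag_s = "".join(frag)
        strand = "-" if strands[i] else "+"
        seq = frag_s if strand == "+" else revcomp(frag_s)
        reads.append(Read(
            id=f"{id_prefix}{i:07d}",
            seq=seq,
            qual="I" * len(seq),
            origin=ReadOrigin(lg=lg, start=s, end=s + L, strand=strand,
                              positions=positions),
        ))
    return reads


# ---------------------------------------------------------------------------
# Mapper emulation


def emulate_mapping(reads: Sequence[Read], ref: ReferenceGenome,
                    truth: TruthSet, min_seed: int = 20) -> list[Alignment]:
    """Place simulated reads on the original reference, from ground truth.

    A read inside one colinear segment maps fully; a breakpoint-crossing
    read is placed by its longest colinear piece, the rest soft-clipped.
    Reads whose longest piece is shorter than ``min_seed`` are dropped as
    unmappable. Returns SAM-convention alignments.
    """
    offsets = truth.segment_offsets()
    seg_lists = truth.segments
    alignments: list[Alignment] = []
    for read in reads:
        org: ReadOrigin = read.origin  # type: ignore[assignment]
        if org is None:
            raise ValueError(f"read {read.id!r} has no simulation origin")
        aln = _place_fragment(read, org, seg_lists[org.lg], offsets[org.lg],
                              ref, min_seed)
        if aln is not None:
            alignments.append(aln)
    return alignments


def _place_fragment(read: Read, org: ReadOrigin, segs: list[Segment],
                    offs: np.ndarray, ref: ReferenceGenome,
                    min_seed: int) -> Optional[Alignment]:
    L = len(read.seq)
    if org.positions is None:
        # fast path: no indel errors
        first = bisect_right(offs, org.start) - 1
        last = bisect_right(offs, org.end - 1) - 1
        if first == last and segs[first].src_lg is not None:
            seg = segs[first]
            d0 = int(offs[first])
            if seg.orient == "+":
                pos = seg.start + (org.start - d0)
                stored = read.seq if org.strand == "+" else revcomp(read.seq)
                strand = org.strand
            else:
                pos = seg.start + (seg.end - seg.start) - (org.end - d0)
                stored = revcomp(read.seq) if org.strand == "+" else read.seq
                strand = "-" if org.strand == "+" else "+"
            return Alignment(read.id, seg.src_lg, pos, strand, [("M", L)], stored)
        positions = np.arange(org.start, org.end, dtype=np.int64)
    else:
        positions = org.positions

    # general path: group fragment bases into runs by segment index
    seg_idx = np.where(positions >= 0,
                       np.searchsorted(offs, positions, side="right") - 1, -1)
    runs: list[tuple[int, int, int]] = []  # (seg index, frag start, frag end)
    i = 0
    n = len(seg_idx)
    while i < n:
        j = i
        while j < n and seg_idx[j] == seg_idx[i]:
            j += 1
        runs.append((int(seg_idx[i]), i, j))
        i = j
    best = None
    for si, a, b in runs:
        if si < 0 or segs[si].src_lg is None:
            continue
        if best is None or (b - a) > (best[2] - best[1]):
            best = (si, a, b)
    if best is None or (best[2] - best[1]) < min_seed:
        return None
    si, a, b = best
    seg = segs[si]
    d0 = int(offs[si])
    # fragment (derived-forward) orientation bookkeeping
    frag = read.seq if org.strand == "+" else revcomp(read.seq)
    pa, pb = int(positions[a]), int(positions[b - 1])
    if seg.orient == "+":
        ref_start = seg.start + (pa - d0)
        lead, trail = a, L - b
        stored = frag
        strand = org.strand
    else:
        ref_start = seg.end - (pb - d0) - 1
        lead, trail = L - b, a
        stored = revcomp(frag)
        strand = "-" if org.strand == "+" else "+"
    m_len = b - a
    ref_start = max(0, min(ref_start, len(ref[seg.src_lg]) - m_len))
    cigar: list[tuple[str, int]] = []
    if lead:
        cigar.append(("S", lead))
    cigar.append(("M", m_len))
    if trail:
        cigar.append(("S", trail))
    return Alignment(read.id, seg.src_lg, ref_start, strand, cigar, stored)


def make_control(ref: ReferenceGenome, config: SimConfig) -> list[Alignment]:
    """Reads simulated from the un-rearranged reference itself, mapped back.

    Uses an independent rng stream of the same master seed, so case and
    control are reproducible together but not correlated.
    """
    truth = TruthSet.identity(ref)
    reads = simulate_reads(ref, config, stream=_STREAM_READS_CONTROL, id_prefix="c")
    return emulate_mapping(reads, ref, truth, min_seed=config.min_seed)


# ---------------------------------------------------------------------------
# Output of a full simulated dataset


def write_truth_table(truth: TruthSet, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lg\tpos\tpartner_lg\tpartner_pos\torientation\tcategory\t"
                 "microindel\tderived_lg\tderived_pos\n")
        for bp in truth.breakpoints:
            fh.write(f"{bp.lg}\t{bp.pos}\t{bp.partner_lg}\t{bp.partner_pos}\t"
                     f"{bp.orientation}\t{bp.category}\t{bp.microindel}\t"
                     f"{bp.derived_lg}\t{bp.derived_pos}\n")


def _event_to_dict(ev: Event) -> dict:
    d = asdict(ev)
    d["type"] = type(ev).__name__
    return d


def simulate_dataset(config: SimConfig, plan: Sequence[Event], out_dir: str) -> dict:
    """Full run: genome, derived genome, case/control reads and SAM, truth.

    Returns a manifest dict (also written as JSON) describing every output.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    ref = simulate_genome(config)
    truth = apply_rearrangements(ref, plan, config)
    case_reads = simulate_reads(truth.derived, config)
    case_alns = emulate_mapping(case_reads, ref, truth, min_seed=config.min_seed)
    control_alns = make_control(ref, config)

    paths = {
        "reference": os.path.join(out_dir, "reference.fa"),
        "derived": os.path.join(out_dir, "derived.fa"),
        "case_reads": os.path.join(out_dir, "case.fastq"),
        "case_sam": os.path.join(out_dir, "case.sam"),
        "control_sam": os.path.join(out_dir, "control.sam"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    write_fasta(ref, paths["reference"])
    write_fasta(truth.derived, paths["derived"])
    write_fastq(case_reads, paths["case_reads"])
    write_sam(case_alns, ref, paths["case_sam"])
    write_sam(control_alns, ref, paths["control_sam"])
    write_truth_table(truth, paths["truth"])
    manifest = {
        "config": asdict(config),
        "plan": [_event_to_dict(ev) for ev in plan],
        "paths": paths,
        "n_case_reads": len(case_reads),
        "n_case_alignments": len(case_alns),
        "n_control_alignments": len(control_alns),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
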