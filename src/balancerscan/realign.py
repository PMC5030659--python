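"""Breakpoint discovery from soft-clipped reads.

The pipeline harvests soft-clipped tails longer than 20 bp from primary
alignments, turns every contiguous 16-mer of each clip (and of its reverse
complement) into an exact-match query, locates all perfect occurrences
genome-wide with an Aho-Corasick automaton, extends each seed into a local
Smith-Waterman alignment of the whole clip against the neighbouring
reference window (match +2, mismatch -1, gap -2, linear), and resolves
equal-scoring candidate loci by proximity to the clip's anchor. Each
accepted realignment together with its anchor yields a split read: a read
whose 5' and 3' regions map to different sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .core_io import Alignment, ReferenceGenome, revcomp

KMER = 16
DEFAULT_MIN_CLIP = 20
DEFAULT_MATCH = 2
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2
#: a realignment must be worth at least one perfect 16-mer
DEFAULT_MIN_SCORE = 2 * KMER
DEFAULT_WINDOW_MARGIN = 20


@dataclass(frozen=True)
class Placement:
    """A located region: reference interval plus strand."""

    lg: str
    start: int
    end: int
    strand: str

    def flipped(self) -> "Placement":
        return Placement(self.lg, self.start, self.end,
                         "-" if self.strand == "+" else "+")


@dataclass
class ClippedSegment:
    """One soft-clipped tail of a read, with its mapped anchor.

    ``side`` says whether the clip is the read's 5' or 3' region *in read
    orientation*; ``clip_seq`` is in stored (reference-forward) orientation,
    as in the SAM record.
    """

    read_id: str
    side: str  # '5p' or '3p'
    clip_seq: str
    anchor: Placement


@dataclass
class LocalAlignment:
    """Result of a local (Smith-Waterman) alignment of ``a`` against ``b``.

    ``edits`` is a CIGAR-like string over the aligned region using
    M (match), X (mismatch), I (gap in b / insertion in a), D (gap in a).
    """

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    edits: str = ""


@dataclass
class ClipRealignment:
    """A clip placed somewhere else on the reference."""

    segment: ClippedSegment
    placement: Placement          # reference interval covered by the clip
    score: int
    clip_start: int               # aligned sub-interval of the clip
    clip_end: int                 # (stored orientation)
    edits: str = ""


@dataclass
class SplitRead:
    """A read whose 5' and 3' regions map to different sites.

    Placements are stored in canonical orientation (see
    :func:`canonicalize`); ``gap`` is the signed distance between the two
    junction coordinates when both regions lie on one linkage group.
    """

    read_id: str
    seg5: Placement
    seg3: Placement
    gap: Optional[int] = None
    category: Optional[str] = None

    @property
    def junction5(self) -> int:
        """Reference coordinate of the read-internal end of the 5' region."""
        return self.seg5.end if self.seg5.strand == "+" else self.seg5.start

    @property
    def junction3(self) -> int:
        """Reference coordinate of the read-internal end of the 3' region."""
        return self.seg3.start if self.seg3.strand == "+" else self.seg3.end


# ---------------------------------------------------------------------------
# Clip harvesting


def extract_clipped(alignments: Iterable[Alignment],
                    min_clip: int = DEFAULT_MIN_CLIP) -> list[ClippedSegment]:
    """Collect soft-clip tails strictly longer than ``min_clip`` bases.

    The clip's side (read 5' vs 3') accounts for the stored orientation: for
    a minus-strand alignment the leading clip holds the read's 3' end.
    """
    segments: list[ClippedSegment] = []
    for aln in alignments:
        m_start = aln.start
        m_end = aln.ref_end
        anchor = Placement(aln.lg, m_start, m_end, aln.strand)
        lead = aln.leading_clip
        trail = aln.trailing_clip
        if lead > min_clip:
            segments.append(ClippedSegment(
                read_id=aln.read_id,
                side="5p" if aln.strand == "+" else "3p",
                clip_seq=aln.seq[:lead],
                anchor=anchor,
            ))
        if trail > min_clip:
            segments.append(ClippedSegment(
                read_id=aln.read_id,
                side="3p" if aln.strand == "+" else "5p",
                clip_seq=aln.seq[len(aln.seq) - trail:],
                anchor=anchor,
            ))
    return segments


# ---------------------------------------------------------------------------
# 16-mer queries


def build_query_set(segment: ClippedSegment, k: int = KMER) -> set[str]:
    """All contiguous k-mers of the clip plus their reverse complements.

    Queries containing N are excluded (N never matches exactly).
    """
    seq = segment.clip_seq
    queries: set[str] = set()
    for i in range(len(seq) - k + 1):
        q = seq[i:i + k]
        if "N" in q:
            continue
        queries.add(q)
        queries.add(revcomp(q))
    return queries


def _query_offsets(clip: str, k: int = KMER) -> Iterator[tuple[str, int, bool]]:
    """Yield (query, clip offset, is_revcomp) for every k-mer of the clip."""
    for i in range(len(clip) - k + 1):
        q = clip[i:i + k]
        if "N" in q:
            continue
        yield q, i, False
        yield revcomp(q), i, True


# ---------------------------------------------------------------------------
# Aho-Corasick multi-pattern exact search


class AhoCorasick:
    """Classic Aho-Corasick automaton over a set of equal-priority patterns.

    Built once per query set, then run in a single linear scan per
    reference sequence. ``find_all`` yields (pattern index, end position).
    """

    def __init__(self, patterns: Sequence[str]):
        self.patterns = list(patterns)
        # node 0 is the root; each node is a dict: char -> next node
        self.goto: list[dict[str, int]] = [{}]
        self.fail: list[int] = [0]
        self.out: list[list[int]] = [[]]
        for idx, pat in enumerate(self.patterns):
            if not pat:
                raise ValueError("empty pattern")
            node = 0
            for ch in pat:
                nxt = self.goto[node].get(ch)
                if nxt is None:
                    self.goto.append({})
                    self.fail.append(0)
                    self.out.append([])
                    nxt = len(self.goto) - 1
                    self.goto[node][ch] = nxt
                node = nxt
            self.out[node].append(idx)
        self._build_failure_links()

    def _build_failure_links(self) -> None:
        from collections import deque

        queue = deque()
        for child in self.goto[0].values():
            self.fail[child] = 0
            queue.append(child)
        while queue:
            node = queue.popleft()
            for ch, child in self.goto[node].items():
                queue.append(child)
                f = self.fail[node]
                while f and ch not in self.goto[f]:
                    f = self.fail[f]
                self.fail[child] = self.goto[f].get(ch, 0)
                if self.fail[child] == child:
                    self.fail[child] = 0
                self.out[child] = self.out[child] + self.out[self.fail[child]]

    def find_all(self, text: str) -> Iterator[tuple[int, int]]:
        """Yield (pattern index, end position) for every occurrence."""
        node = 0
        goto = self.goto
        fail = self.fail
        out = self.out
        for pos, ch in enumerate(text):
            while node and ch not in goto[node]:
                node = fail[node]
            node = goto[node].get(ch, 0)
            if out[node]:
                for idx in out[node]:
                    yield idx, pos + 1


def find_perfect_matches(
    ref: ReferenceGenome, queries: Iterable[str],
) -> list[tuple[str, str, int, str]]:
    """Every exact occurrence of every query, over all linkage groups.

    Each query is searched both as given and as its reverse complement in a
    single linear scan per linkage group; a hit of the query itself carries
    strand '+', a hit of its complement carries strand '-'. Returns
    (query, lg, position, strand) tuples.
    """
    qlist = sorted(set(queries))
    if not qlist:
        return []
    patterns: list[str] = []
    labels: list[tuple[str, str]] = []  # (reported query, strand)
    seen: dict[str, int] = {}
    for q in qlist:
        for pat, strand in ((q, "+"), (revcomp(q), "-")):
            if pat not in seen:
                seen[pat] = len(patterns)
                patterns.append(pat)
                labels.append((q, strand))
    ac = AhoCorasick(patterns)
    hits = []
    for lg, seq in ref.sequences.items():
        for idx, end in ac.find_all(seq):
            q, strand = labels[idx]
            hits.append((q, lg, end - len(patterns[idx]), strand))
    return hits


# ---------------------------------------------------------------------------
# Smith-Waterman local alignment (linear gap penalty)


def smith_waterman(a: str, b: str, match: int = DEFAULT_MATCH,
                   mismatch: int = DEFAULT_MISMATCH,
                   gap: int = DEFAULT_GAP) -> LocalAlignment:
    """Optimal local alignment of ``a`` vs ``b`` under linear gap scoring.

    N is treated as matching nothing (always a mismatch). The empty
    alignment scores 0. Ties are broken deterministically: the best cell
    with the smallest (i, j), and a diagonal > up > left traceback
    preference.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        raise ValueError("smith_waterman requires non-empty sequences")
    prev = [0] * (m + 1)
    # traceback matrix: 0 stop, 1 diag, 2 up, 3 left
    tb = [[0] * (m + 1) for _ in range(n + 1)]
    best_score = 0
    best_i = best_j = 0
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        tbi = tb[i]
        for j in range(1, m + 1):
            bj = b[j - 1]
            s = match if (ai == bj and ai != "N") else mismatch
            diag = prev[j - 1] + s
            up = prev[j] + gap
            left = cur[j - 1] + gap
            v = diag
            t = 1
            if up > v:
                v, t = up, 2
            if left > v:
                v, t = left, 3
            if v <= 0:
                v, t = 0, 0
            cur[j] = v
            tbi[j] = t
            if v > best_score:
                best_score = v
                best_i, best_j = i, j
        prev = cur
    if best_score == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "")
    # traceback
    i, j = best_i, best_j
    ops: list[str] = []
    while i > 0 and j > 0 and tb[i][j] != 0:
        t = tb[i][j]
        if t == 1:
            ops.append("M" if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else "X")
            i -= 1
            j -= 1
        elif t == 2:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    return LocalAlignment(best_score, i, best_i, j, best_j, "".join(ops))


def global_align(a: str, b: str, match: int = DEFAULT_MATCH,
                 mismatch: int = DEFAULT_MISMATCH,
                 gap: int = DEFAULT_GAP) -> LocalAlignment:
    """End-to-end (Needleman-Wunsch) alignment with the same scorer.

    Used for junction-repair comparison, where the whole observed window is
    compared against the whole expected window.
    """
    n, m = len(a), len(b)
    prev = [j * gap for j in range(m + 1)]
    tb = [[3] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cur = [i * gap] + [0] * m
        tb[i][0] = 2
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            diag = prev[j - 1] + s
            up = prev[j] + gap
            left = cur[j - 1] + gap
            v, t = diag, 1
            if up > v:
                v, t = up, 2
            if left > v:
                v, t = left, 3
            cur[j] = v
            tb[i][j] = t
        prev = cur
    i, j = n, m
    ops: list[str] = []
    while i > 0 or j > 0:
        t = tb[i][j]
        if t == 1:
            ops.append("M" if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else "X")
            i -= 1
            j -= 1
        elif t == 2:
            ops.append("I")
            i -= 1
        else:
            ops.append("D")
            j -= 1
    ops.reverse()
    return LocalAlignment(prev[m], 0, n, 0, m, "".join(ops))


# ---------------------------------------------------------------------------
# Realigning a clip


def _seed_candidates(clip: str, hits: Iterable[tuple[int, bool, str, int]],
                     ) -> set[tuple[str, int, str]]:
    """Project seed hits to candidate clip placements.

    ``hits`` carries (clip offset, is_revcomp, lg, hit position) per seed
    occurrence; the projection collapses all seeds of one true locus into a
    single candidate (lg, projected clip start, strand).
    """
    candidates: set[tuple[str, int, str]] = set()
    L = len(clip)
    for offset, is_rc, lg, pos in hits:
        if not is_rc:
            candidates.add((lg, pos - offset, "+"))
        else:
            # the reverse complement of clip[offset:offset+k] occurs at pos,
            # so revcomp(clip) starts at pos - (L - KMER - offset)
            candidates.add((lg, pos - (L - KMER - offset), "-"))
    return candidates


def realign_clip(
    segment: ClippedSegment,
    ref: ReferenceGenome,
    hits: Iterable[tuple[int, bool, str, int]],
    *,
    margin: int = DEFAULT_WINDOW_MARGIN,
    min_score: int = DEFAULT_MIN_SCORE,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> Optional[ClipRealignment]:
    """Best local alignment of the whole clip near its seed hits.

    For each candidate locus the clip (or its reverse complement) is aligned
    against a reference window of the clip length plus a margin on both
    sides. The highest score wins; score ties are resolved by minimal
    distance between the candidate region and the clip's anchor (a
    different linkage group counts as infinitely far), then by linkage-group
    name, then by coordinate. Returns None when the best score is below
    ``min_score``.
    """
    clip = segment.clip_seq
    L = len(clip)
    best: Optional[ClipRealignment] = None
    best_key: Optional[tuple] = None
    for lg, proj_start, strand in sorted(_seed_candidates(clip, hits)):
        seq = ref[lg]
        w_start = max(0, proj_start - margin)
        w_end = min(len(seq), proj_start + L + margin)
        if w_end - w_start < KMER:
            continue
        window = seq[w_start:w_end]
        query = clip if strand == "+" else revcomp(clip)
        # fast path: an exact occurrence achieves the global maximum 2L
        found = window.find(query)
        if found >= 0 and "N" not in query:
            la = LocalAlignment(match * L, 0, L, found, found + L, "M" * L)
        else:
            la = smith_waterman(query, window, match, mismatch, gap)
        if la.score <= 0:
            continue
        placement = Placement(lg, w_start + la.b_start, w_start + la.b_end, strand)
        if strand == "+":
            clip_start, clip_end = la.a_start, la.a_end
        else:
            clip_start, clip_end = L - la.a_end, L - la.a_start
        cand = ClipRealignment(segment, placement, la.score,
                               clip_start, clip_end, la.edits)
        key = (-la.score, _anchor_distance(placement, segment.anchor),
               placement.lg, placement.start)
        if best_key is None or key < best_key:
            best, best_key = cand, key
    if best is None or best.score < min_score:
        return None
    return best


def _anchor_distance(p: Placement, anchor: Placement) -> float:
    if p.lg != anchor.lg:
        return float("inf")
    if p.end <= anchor.start:
        return anchor.start - p.end
    if anchor.end <= p.start:
        return p.start - anchor.end
    return 0.0


# ---------------------------------------------------------------------------
# Split-read construction


def canonicalize(seg5: Placement, seg3: Placement) -> tuple[Placement, Placement]:
    """Canonical orientation for a (5' region, 3' region) placement pair.

    A read and its reverse complement describe the same junction; flipping
    the read maps (seg5, seg3) to (flip(seg3), flip(seg5)). The canonical
    representative is chosen so that both orientations of a junction (and
    both flanks' reads) cluster together:

    - both regions on minus strand: flip (making both plus);
    - opposite strands on one linkage group: flip if the 5' junction
      coordinate exceeds the 3' one;
    - different linkage groups with opposite strands: flip if the 5' group
      sorts after the 3' group.
    """
    def flip(a: Placement, b: Placement) -> tuple[Placement, Placement]:
        return b.flipped(), a.flipped()

    if seg5.strand == "-" and seg3.strand == "-":
        return flip(seg5, seg3)
    if seg5.strand != seg3.strand:
        if seg5.lg == seg3.lg:
            j5 = seg5.end if seg5.strand == "+" else seg5.start
            j3 = seg3.start if seg3.strand == "+" else seg3.end
            if j5 > j3:
                return flip(seg5, seg3)
        elif seg5.lg > seg3.lg:
            return flip(seg5, seg3)
    return seg5, seg3


def build_split_reads(
    realignments: Iterable[ClipRealignment],
) -> list[SplitRead]:
    """Pair each accepted clip realignment with its anchor into a SplitRead.

    The anchor and the realigned clip are ordered by their position within
    the read (5' vs 3' in read orientation); placements are converted to the
    read frame, canonicalized, and clips realigned back onto the anchor
    continuation (not "different sites") are dropped.
    """
    out: list[SplitRead] = []
    for ra in realignments:
        seg = ra.segment
        anchor_strand = seg.anchor.strand
        # read-frame strand of the realigned clip: the realignment was done
        # in stored orientation; minus-strand records flip it
        clip_strand = ra.placement.strand
        if anchor_strand == "-":
            clip_strand = "-" if clip_strand == "+" else "+"
        anchor_rf = Placement(seg.anchor.lg, seg.anchor.start, seg.anchor.end,
                              anchor_strand)
        clip_rf = Placement(ra.placement.lg, ra.placement.start,
                            ra.placement.end, clip_strand)
        if seg.side == "5p":
            seg5, seg3 = clip_rf, anchor_rf
        else:
            seg5, seg3 = anchor_rf, clip_rf
        seg5, seg3 = canonicalize(seg5, seg3)
        sr = SplitRead(read_id=seg.read_id, seg5=seg5, seg3=seg3)
        if seg5.lg == seg3.lg:
            sr.gap = sr.junction3 - sr.junction5
            if (seg5.strand == seg3.strand and sr.gap == 0):
                continue  # clip realigned onto the anchor continuation
            if seg5 == seg3:
                continue
        out.append(sr)
    return out


# ---------------------------------------------------------------------------
# Pipeline driver: all clips against one automaton


def realign_all_clips(
    segments: Sequence[ClippedSegment],
    ref: ReferenceGenome,
    *,
    margin: int = DEFAULT_WINDOW_MARGIN,
    min_score: int = DEFAULT_MIN_SCORE,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> list[ClipRealignment]:
    """Seed and realign every clipped segment with one shared automaton.

    Builds a single Aho-Corasick automaton over the union of all segments'
    16-mer queries, scans each linkage group once, then realigns each clip
    around its own hits.
    """
    if not segments:
        return []
    # query -> [(segment index, clip offset, is_rc)]
    query_map: dict[str, list[tuple[int, int, bool]]] = {}
    for si, seg in enumerate(segments):
        for q, off, is_rc in _query_offsets(seg.clip_seq):
            query_map.setdefault(q, []).append((si, off, is_rc))
    if not query_map:
        return []
    patterns = sorted(query_map)
    ac = AhoCorasick(patterns)
    hits_per_segment: dict[int, list[tuple[int, bool, str, int]]] = {}
    for lg, seq in ref.sequences.items():
        for idx, end in ac.find_all(seq):
            q = patterns[idx]
            pos = end - KMER
            for si, off, is_rc in query_map[q]:
                hits_per_segment.setdefault(si, []).append((off, is_rc, lg, pos))
    out: list[ClipRealignment] = []
    for si, seg in enumerate(segments):
        hits = hits_per_segment.get(si)
        if not hits:
            continue
        ra = realign_clip(seg, ref, hits, margin=margin, min_score=min_score,
                          match=match, mismatch=mismatch, gap=gap)
        if ra is not None:
            out.append(ra)
    return out


def write_split_read_table(srs: Sequence[SplitRead], path: str) -> None:
    """Debug TSV of split reads (one row each, canonical placements)."""
    with open(path, "w") as fh:
        fh.write("read_id\tlg5\tstart5\tend5\tstrand5\t"
                 "lg3\tstart3\tend3\tstrand3\tgap\tcategory\n")
        for sr in srs:
            gap = "" if sr.gap is None else sr.gap
            fh.write(f"{sr.read_id}\t{sr.seg5.lg}\t{sr.seg5.start}\t{sr.seg5.end}\t"
                     f"{sr.seg5.strand}\t{sr.seg3.lg}\t{sr.seg3.start}\t"
                     f"{sr.seg3.end}\t{sr.seg3.strand}\t{gap}\t"
                     f"{sr.category or ''}\n")
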