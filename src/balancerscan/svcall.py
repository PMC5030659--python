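"""Split-read classification, candidate calling, and depth-based filtering.

Split reads fall into five categories from the relative placement of their
5' and 3' regions: deletion-type (3' region downstream), insertion-type
(3' region upstream), inversion-type (opposite strands, one linkage group),
translocation-type (different linkage groups), and translocational
inversion-type (different groups, opposite strands). Candidates are then
assembled from category-wise clusters: >2 deletion-type SRs sharing a gap
call a deletion; pairs of clusters bracketing a region call complicated
variants (insertions, local inversions / inverted insertions, translocated
insertions); reciprocal cluster pairs at chromosome scale call
inversion/translocation breakpoint pairs. Control subtraction removes SRs
seen in the un-rearranged sample; complicated candidates need >= 10
supporting reads; normalized-depth ratios (case/control) remove deletion
candidates without copy loss (DR > 0.75) and promote insertion candidates
with DR > 1.75 / > 2.5 to duplications / multiplications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .core_io import DepthTrack, ReferenceGenome
from .realign import Placement, SplitRead, canonicalize

SV_CLASSES = (
    "deletion",
    "insertion",
    "inversion",
    "translocation",
    "translocational_inversion",
)

#: candidate kinds assembled from a pair of SR clusters
COMPLEX_KINDS = frozenset({
    "insertion",
    "local_inversion_or_inverted_insertion",
    "translocated_insertion",
    "inverted_translocational_insertion",
})

DEFAULT_TOL = 10
DEFAULT_MIN_DEL_SR = 3       # "greater than 2" deletion-type SRs
DEFAULT_MIN_COMPLEX_READS = 10
DEFAULT_LOCAL_SPAN_MAX = 1000
DEFAULT_DR_DEL = 0.75
DEFAULT_DR_DUP = 1.75
DEFAULT_DR_MULT = 2.5
DEFAULT_MAPPED_DEPTH_MIN = 1  # depth "greater than one" marks mapped regions


# ---------------------------------------------------------------------------
# Classification


def classify_split_read(sr: SplitRead) -> str:
    """Assign one of the five split-read categories.

    Works on the canonical placement pair; raises ValueError for a pair of
    identical placements (not a split read).
    """
    seg5, seg3 = canonicalize(sr.seg5, sr.seg3)
    if seg5 == seg3:
        raise ValueError(f"read {sr.read_id!r}: identical placements")
    if seg5.lg != seg3.lg:
        if seg5.strand != seg3.strand:
            return "translocational_inversion"
        return "translocation"
    if seg5.strand != seg3.strand:
        return "inversion"
    j5 = seg5.end if seg5.strand == "+" else seg5.start
    j3 = seg3.start if seg3.strand == "+" else seg3.end
    if seg5.strand == "-":
        j5, j3 = j3, j5  # read direction runs against reference coordinates
    if j3 > j5:
        return "deletion"
    if j3 < j5:
        return "insertion"
    raise ValueError(f"read {sr.read_id!r}: contiguous placements, not split")


def classify_all(srs: Iterable[SplitRead]) -> list[SplitRead]:
    """Classify in place, dropping degenerate (non-split) records."""
    out = []
    for sr in srs:
        try:
            sr.category = classify_split_read(sr)
        except ValueError:
            continue
        out.append(sr)
    return out


# ---------------------------------------------------------------------------
# Control subtraction


def subtract_control(case_srs: Sequence[SplitRead],
                     control_srs: Sequence[SplitRead],
                     tol: int = DEFAULT_TOL) -> list[SplitRead]:
    """Remove case SRs that also occur in the control sample.

    A case SR is removed iff some control SR has the same category, the
    same linkage groups and strands, and both junction coordinates within
    ``tol`` bases.
    """
    index: dict[tuple, list[tuple[int, int]]] = {}
    for sr in control_srs:
        key = (sr.category, sr.seg5.lg, sr.seg5.strand,
               sr.seg3.lg, sr.seg3.strand)
        index.setdefault(key, []).append((sr.junction5, sr.junction3))
    kept = []
    for sr in case_srs:
        key = (sr.category, sr.seg5.lg, sr.seg5.strand,
               sr.seg3.lg, sr.seg3.strand)
        j5, j3 = sr.junction5, sr.junction3
        if any(abs(j5 - a) <= tol and abs(j3 - b) <= tol
               for a, b in index.get(key, [])):
            continue
        kept.append(sr)
    return kept


# ---------------------------------------------------------------------------
# Clustering


@dataclass
class SRCluster:
    """Split reads of one category sharing both junction coordinates."""

    category: str
    lg5: str
    strand5: str
    lg3: str
    strand3: str
    srs: list[SplitRead] = field(default_factory=list)

    @property
    def j5(self) -> int:
        return int(np.median([sr.junction5 for sr in self.srs]))

    @property
    def j3(self) -> int:
        return int(np.median([sr.junction3 for sr in self.srs]))

    @property
    def read_ids(self) -> set[str]:
        return {sr.read_id for sr in self.srs}

    def __len__(self) -> int:
        return len(self.srs)


def cluster_split_reads(srs: Iterable[SplitRead],
                        tol: int = DEFAULT_TOL) -> list[SRCluster]:
    """Greedy 1-d clustering of classified SRs by junction coordinates."""
    groups: dict[tuple, list[SplitRead]] = {}
    for sr in srs:
        if sr.category is None:
            raise ValueError("cluster_split_reads needs classified SRs")
        key = (sr.category, sr.seg5.lg, sr.seg5.strand,
               sr.seg3.lg, sr.seg3.strand)
        groups.setdefault(key, []).append(sr)
    clusters: list[SRCluster] = []
    for key, members in sorted(groups.items()):
        members.sort(key=lambda sr: (sr.junction5, sr.junction3))
        open_clusters: list[SRCluster] = []
        for sr in members:
            placed = False
            for cl in open_clusters:
                ref_sr = cl.srs[0]
                if (abs(sr.junction5 - ref_sr.junction5) <= tol
                        and abs(sr.junction3 - ref_sr.junction3) <= tol):
                    cl.srs.append(sr)
                    placed = True
                    break
            if not placed:
                open_clusters.append(SRCluster(*key, srs=[sr]))
        clusters.extend(open_clusters)
    return clusters


# ---------------------------------------------------------------------------
# Candidates


@dataclass
class VariantCandidate:
    """A called rearrangement (or a filtered-out one, with its status).

    ``lg/start/end`` give the candidate region: the deleted span for
    deletions, the source span of the copied sequence for insertion-class
    candidates, or the two junctions of a breakpoint pair. For candidates
    involving a second locus, ``lg2/pos2`` carry the partner (insertion
    point, or the partner junction of a translocation pair).
    """

    kind: str
    lg: str
    start: int
    end: int
    lg2: Optional[str] = None
    pos2: Optional[int] = None
    support: set = field(default_factory=set)
    dr: Optional[float] = None
    status: str = "kept"
    notes: str = ""

    @property
    def count(self) -> int:
        return len(self.support)

    @property
    def span(self) -> int:
        return self.end - self.start


def call_deletions(srs: Sequence[SplitRead],
                   min_sr: int = DEFAULT_MIN_DEL_SR,
                   tol: int = DEFAULT_TOL) -> list[VariantCandidate]:
    """Deletion candidates from deletion-type SR clusters with a common gap.

    A cluster's SRs share the gap between their 5' and 3' regions (within
    ``tol``); clusters with at least ``min_sr`` reads (default 3, i.e.
    strictly more than 2) call the common gap as a deletion.
    """
    out = []
    for cl in cluster_split_reads(srs, tol):
        if cl.category != "deletion" or len(cl) < min_sr:
            continue
        out.append(VariantCandidate(
            kind="deletion", lg=cl.lg5, start=cl.j5, end=cl.j3,
            support=cl.read_ids,
        ))
    return out


def _close(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def call_paired_variants(srs: Sequence[SplitRead],
                         tol: int = DEFAULT_TOL,
                         local_span_max: int = DEFAULT_LOCAL_SPAN_MAX,
                         min_region: Optional[int] = None,
                         ) -> list[VariantCandidate]:
    """Complicated candidates from pairs of SR clusters bracketing a region.

    A deletion-type plus an insertion-type cluster sharing one junction
    coordinate (the insertion point) delimit the copied source region with
    their other coordinates: an insertion candidate. Two inversion-type
    clusters either reciprocal (a local inversion) or sharing one
    coordinate (an inverted insertion) call a combined local-inversion /
    inverted-insertion candidate. The same geometry on two linkage groups,
    from translocation- or translocational-inversion-type clusters, calls
    translocated / inverted translocational insertions. Regions wider than
    ``local_span_max`` are left to :func:`call_large_breakpoint_pairs`;
    regions narrower than ``min_region`` (default ``3 * tol``) are
    degenerate -- a reciprocal event whose junction estimates are smeared
    by end-joining scars, not a copied region -- and skipped, which bounds
    the method's resolution for copied insertions at ``min_region`` bases.
    Junction-coordinate mismatches at a shared insertion point additionally
    call the uncovered gap as a deletion candidate.
    """
    if min_region is None:
        min_region = 3 * tol
    clusters = cluster_split_reads(srs, tol)
    by_cat: dict[str, list[SRCluster]] = {}
    for cl in clusters:
        by_cat.setdefault(cl.category, []).append(cl)
    out: list[VariantCandidate] = []

    def emit_with_gap(kind: str, lg: str, region: tuple[int, int],
                      lg2: str, t_coords: tuple[int, int],
                      support: set) -> None:
        start, end = min(region), max(region)
        if not (min_region < end - start <= local_span_max):
            return
        t1, t2 = sorted(t_coords)
        out.append(VariantCandidate(
            kind=kind, lg=lg, start=start, end=end, lg2=lg2,
            pos2=(t1 + t2) // 2, support=set(support),
        ))
        if t2 - t1 >= 1:
            # junctions leave an uncovered gap near the border: the target
            # site lost bases as well
            out.append(VariantCandidate(
                kind="deletion", lg=lg2, start=t1, end=t2,
                support=set(support), notes="border_gap",
            ))

    # deletion + insertion type clusters -> insertion candidates
    for d in by_cat.get("deletion", []):
        for i in by_cat.get("insertion", []):
            if d.lg5 != i.lg5:
                continue
            support = d.read_ids | i.read_ids
            if _close(d.j5, i.j3, tol):
                emit_with_gap("insertion", d.lg5, (d.j3, i.j5),
                              d.lg5, (d.j5, i.j3), support)
            elif _close(d.j3, i.j5, tol):
                emit_with_gap("insertion", d.lg5, (d.j5, i.j3),
                              d.lg5, (d.j3, i.j5), support)

    # two inversion-type clusters -> local inversion or inverted insertion
    inv = by_cat.get("inversion", [])
    for a_idx in range(len(inv)):
        for b_idx in range(a_idx + 1, len(inv)):
            a, b = inv[a_idx], inv[b_idx]
            if a.lg5 != b.lg5 or (a.strand5, a.strand3) == (b.strand5, b.strand3):
                continue
            support = a.read_ids | b.read_ids
            if _close(a.j5, b.j5, tol) and _close(a.j3, b.j3, tol):
                # reciprocal: a genuinely inverted region
                start, end = sorted(((a.j5 + b.j5) // 2, (a.j3 + b.j3) // 2))
                if min_region < end - start <= local_span_max:
                    out.append(VariantCandidate(
                        kind="local_inversion_or_inverted_insertion",
                        lg=a.lg5, start=start, end=end, support=support,
                    ))
                continue
            # shared single coordinate: an inverted copy inserted elsewhere
            for x, y, rx, ry in ((a.j5, b.j3, a.j3, b.j5),
                                 (a.j3, b.j5, a.j5, b.j3)):
                if _close(x, y, tol):
                    emit_with_gap("local_inversion_or_inverted_insertion",
                                  a.lg5, (rx, ry), a.lg5, (x, y), support)
                    break

    # translocation-type cluster pairs -> translocated insertions
    cls = by_cat.get("translocation", [])
    for a_idx in range(len(cls)):
        for b_idx in range(len(cls)):
            if a_idx == b_idx:
                continue
            a, b = cls[a_idx], cls[b_idx]
            # a: target -> source junction; b: source -> target junction
            if a.lg5 != b.lg3 or a.lg3 != b.lg5:
                continue
            if not _close(a.j5, b.j3, tol):
                continue
            support = a.read_ids | b.read_ids
            emit_with_gap("translocated_insertion", a.lg3, (a.j3, b.j5),
                          a.lg5, (a.j5, b.j3), support)

    # translocational-inversion-type pairs -> inverted translocational
    # insertions; canonicalization gives both clusters the same linkage-group
    # pair with opposite strand patterns, sharing the insertion-point
    # coordinate on one side
    cls = by_cat.get("translocational_inversion", [])
    for a_idx in range(len(cls)):
        for b_idx in range(a_idx + 1, len(cls)):
            a, b = cls[a_idx], cls[b_idx]
            if (a.lg5 != b.lg5 or a.lg3 != b.lg3
                    or (a.strand5, a.strand3) == (b.strand5, b.strand3)):
                continue
            support = a.read_ids | b.read_ids
            if _close(a.j5, b.j5, tol):
                emit_with_gap("inverted_translocational_insertion",
                              a.lg3, (a.j3, b.j3), a.lg5, (a.j5, b.j5),
                              support)
            elif _close(a.j3, b.j3, tol):
                emit_with_gap("inverted_translocational_insertion",
                              a.lg5, (a.j5, b.j5), a.lg3, (a.j3, b.j3),
                              support)

    # dedupe identical emissions (pair loops can see a pair twice)
    unique: dict[tuple, VariantCandidate] = {}
    for c in out:
        key = (c.kind, c.lg, c.start, c.end, c.lg2, c.pos2, c.notes)
        if key not in unique:
            unique[key] = c
        else:
            unique[key].support |= c.support
    return list(unique.values())


def call_large_breakpoint_pairs(srs: Sequence[SplitRead],
                                tol: int = DEFAULT_TOL,
                                min_span: int = DEFAULT_LOCAL_SPAN_MAX,
                                pair_tol: Optional[int] = None,
                                ) -> list[VariantCandidate]:
    """Chromosome-scale inversions and reciprocal translocations.

    A large inversion produces two reciprocal inversion-type clusters (one
    per junction, same coordinate pair, opposite strand patterns); a
    reciprocal translocation produces two translocation-type clusters with
    swapped linkage groups and matching cut coordinates. Matched pairs are
    reported as breakpoint-pair candidates and kept; unpaired clusters
    wider than ``min_span`` are reported with status ``'unpaired'`` so
    one-sided evidence is not silently lost, but they are not confirmed
    calls. These candidates are copy-neutral: depth filters do not apply.

    ``pair_tol`` (default ``3 * tol``) is the coordinate tolerance for
    matching the two reciprocal clusters. It is deliberately wider than the
    clustering tolerance: each cluster estimates one cut from the clip side
    of its reads, and end-joining scars at the junction systematically
    shift that estimate by up to the scar size, in opposite directions for
    the two clusters.
    """
    if pair_tol is None:
        pair_tol = 3 * tol
    clusters = cluster_split_reads(srs, tol)
    out: list[VariantCandidate] = []

    inv = [c for c in clusters if c.category == "inversion"]
    used: set[int] = set()
    for a_idx in range(len(inv)):
        if a_idx in used:
            continue
        a = inv[a_idx]
        for b_idx in range(a_idx + 1, len(inv)):
            if b_idx in used:
                continue
            b = inv[b_idx]
            if (a.lg5 != b.lg5
                    or (a.strand5, a.strand3) == (b.strand5, b.strand3)):
                continue
            if _close(a.j5, b.j5, pair_tol) and _close(a.j3, b.j3, pair_tol):
                start = (a.j5 + b.j5) // 2
                end = (a.j3 + b.j3) // 2
                if end - start <= min_span:
                    continue
                out.append(VariantCandidate(
                    kind="inversion_breakpoint_pair", lg=a.lg5,
                    start=min(start, end), end=max(start, end),
                    support=a.read_ids | b.read_ids,
                ))
                used.update((a_idx, b_idx))
                break
    for idx, c in enumerate(inv):
        if idx not in used and abs(c.j3 - c.j5) > min_span:
            out.append(VariantCandidate(
                kind="inversion_breakpoint_pair", lg=c.lg5,
                start=min(c.j5, c.j3), end=max(c.j5, c.j3),
                support=c.read_ids, status="unpaired", notes="unpaired",
            ))

    tra = [c for c in clusters if c.category == "translocation"]
    used = set()
    for a_idx in range(len(tra)):
        if a_idx in used:
            continue
        a = tra[a_idx]
        for b_idx in range(a_idx + 1, len(tra)):
            if b_idx in used:
                continue
            b = tra[b_idx]
            if a.lg5 != b.lg3 or a.lg3 != b.lg5:
                continue
            if _close(a.j5, b.j3, pair_tol) and _close(a.j3, b.j5, pair_tol):
                out.append(VariantCandidate(
                    kind="translocation_breakpoint_pair",
                    lg=a.lg5, start=(a.j5 + b.j3) // 2, end=(a.j5 + b.j3) // 2,
                    lg2=a.lg3, pos2=(a.j3 + b.j5) // 2,
                    support=a.read_ids | b.read_ids,
                ))
                used.update((a_idx, b_idx))
                break
    for idx, c in enumerate(tra):
        if idx not in used:
            out.append(VariantCandidate(
                kind="translocation_breakpoint_pair",
                lg=c.lg5, start=c.j5, end=c.j5, lg2=c.lg3, pos2=c.j3,
                support=c.read_ids, status="unpaired", notes="unpaired",
            ))
    return out


def filter_complicated(candidates: Iterable[VariantCandidate],
                       min_reads: int = DEFAULT_MIN_COMPLEX_READS,
                       ) -> list[VariantCandidate]:
    """Remove complicated candidates with fewer than ``min_reads`` reads.

    Only the paired-cluster kinds are affected; simple deletion candidates
    and breakpoint pairs pass through untouched.
    """
    out = []
    for c in candidates:
        if (c.kind in COMPLEX_KINDS and c.status == "kept"
                and c.count < min_reads):
            c.status = "removed_support"
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Depth-based filtering


@dataclass
class NormalizedDepth:
    """Per-base depth / coverage, defined on the mapped-region mask."""

    nd: dict[str, np.ndarray]       # float array, NaN outside mapped regions
    mask: dict[str, np.ndarray]     # bool: depth strictly greater than 1


def normalized_depth(track: DepthTrack,
                     coverage: Optional[float] = None,
                     mapped_depth_min: int = DEFAULT_MAPPED_DEPTH_MIN,
                     ) -> NormalizedDepth:
    """ND = depth / coverage, restricted to mapped regions (depth > 1)."""
    cov = coverage if coverage is not None else track.coverage
    if cov is None or cov <= 0:
        raise ValueError("normalized depth requires a positive coverage")
    nd: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for lg, d in track.depth.items():
        m = d > mapped_depth_min
        v = np.full(d.shape, np.nan)
        v[m] = d[m] / cov
        nd[lg] = v
        mask[lg] = m
    return NormalizedDepth(nd=nd, mask=mask)


@dataclass
class DepthRatio:
    """Per-base case/control ND ratio, where both samples are mapped."""

    dr: dict[str, np.ndarray]  # NaN where either sample is unmapped

    def region(self, lg: str, start: int, end: int) -> float:
        """Mean DR over a region; NaN if no jointly mapped base."""
        start = max(0, start)
        window = self.dr[lg][start:max(start + 1, end)]
        if np.all(np.isnan(window)):
            return float("nan")
        return float(np.nanmean(window))


def depth_ratio(nd_case: NormalizedDepth,
                nd_control: NormalizedDepth) -> DepthRatio:
    dr: dict[str, np.ndarray] = {}
    for lg, case in nd_case.nd.items():
        control = nd_control.nd[lg]
        with np.errstate(invalid="ignore", divide="ignore"):
            v = case / control
        v[~(nd_case.mask[lg] & nd_control.mask[lg])] = np.nan
        dr[lg] = v
    return DepthRatio(dr=dr)


def apply_depth_filters(candidates: Iterable[VariantCandidate],
                        dr: DepthRatio,
                        dr_del: float = DEFAULT_DR_DEL,
                        dr_dup: float = DEFAULT_DR_DUP,
                        dr_mult: float = DEFAULT_DR_MULT,
                        ) -> list[VariantCandidate]:
    """Evaluate candidate regions against the case/control depth ratio.

    Deletion candidates whose region DR exceeds ``dr_del`` show no copy
    loss and are removed. Insertion-class candidates are promoted to
    multiplication (region DR > ``dr_mult``) or duplication (> ``dr_dup``):
    extra copies of the source sequence pile up on the single reference
    copy. Breakpoint pairs are copy-neutral and skipped. Candidates whose
    region has no jointly mapped base keep their call, flagged.
    """
    insertion_kinds = {"insertion", "translocated_insertion",
                       "inverted_translocational_insertion"}
    out = []
    for c in candidates:
        if c.status != "kept":
            out.append(c)
            continue
        if c.kind == "deletion":
            val = dr.region(c.lg, c.start, c.end)
            c.dr = None if np.isnan(val) else val
            if np.isnan(val):
                c.notes = (c.notes + ";" if c.notes else "") + "DR unavailable"
            elif val > dr_del:
                c.status = "removed_depth"
        elif c.kind in insertion_kinds:
            val = dr.region(c.lg, c.start, c.end)
            c.dr = None if np.isnan(val) else val
            if np.isnan(val):
                c.notes = (c.notes + ";" if c.notes else "") + "DR unavailable"
            elif val > dr_mult:
                c.kind = "multiplication"
            elif val > dr_dup:
                c.kind = "duplication"
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Reporting


TSV_COLUMNS = ["kind", "lg", "start", "end", "lg2", "pos2", "count",
               "dr", "status", "notes", "support"]


def write_variant_tsv(candidates: Sequence[VariantCandidate], path: str) -> None:
    """One row per candidate, removed ones included (with status)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for c in candidates:
            fh.write("\t".join(str(x) for x in [
                c.kind, c.lg, c.start, c.end,
                c.lg2 or ".", "." if c.pos2 is None else c.pos2,
                c.count, "." if c.dr is None else f"{c.dr:.4f}",
                c.status, c.notes or ".",
                ",".join(sorted(c.support)) or ".",
            ]) + "\n")


def read_variant_tsv(path: str) -> list[VariantCandidate]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TSV_COLUMNS:
            raise ValueError(f"unexpected variant TSV header in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(VariantCandidate(
                kind=f[0], lg=f[1], start=int(f[2]), end=int(f[3]),
                lg2=None if f[4] == "." else f[4],
                pos2=None if f[5] == "." else int(f[5]),
                dr=None if f[7] == "." else float(f[7]),
                status=f[8], notes="" if f[9] == "." else f[9],
                support=set() if f[10] == "." else set(f[10].split(",")),
            ))
    return out


_VCF_SVTYPE = {
    "deletion": "DEL",
    "insertion": "INS",
    "duplication": "DUP",
    "multiplication": "DUP",
    "local_inversion_or_inverted_insertion": "INV",
    "inversion_breakpoint_pair": "INV",
    "translocated_insertion": "INS",
    "inverted_translocational_insertion": "INS",
}


def write_variant_vcf(candidates: Sequence[VariantCandidate],
                      ref: ReferenceGenome, path: str) -> None:
    """Kept candidates as VCF 4.2; translocation pairs as BND mates."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=balancerscan",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End of variant">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description='
        '"Supporting split reads">',
        '##INFO=<ID=DR,Number=1,Type=Float,Description="Region depth ratio">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=INS,Description="Insertion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=INV,Description="Inversion">',
    ]
    for name, seq in ref.sequences.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    n = 0
    for c in candidates:
        if c.status != "kept":
            continue
        n += 1
        if c.kind == "translocation_breakpoint_pair":
            ref_a = ref[c.lg][max(0, c.start - 1):c.start] or "N"
            ref_b = ref[c.lg2][max(0, (c.pos2 or 1) - 1):(c.pos2 or 1)] or "N"
            id_a, id_b = f"bnd_{n}_a", f"bnd_{n}_b"
            lines.append(
                f"{c.lg}\t{c.start}\t{id_a}\t{ref_a}\t"
                f"{ref_a}[{c.lg2}:{c.pos2 or 1}[\t.\tPASS\t"
                f"SVTYPE=BND;MATEID={id_b};SUPPORT={c.count}")
            lines.append(
                f"{c.lg2}\t{c.pos2 or 1}\t{id_b}\t{ref_b}\t"
                f"{ref_b}[{c.lg}:{c.start}[\t.\tPASS\t"
                f"SVTYPE=BND;MATEID={id_a};SUPPORT={c.count}")
            continue
        svtype = _VCF_SVTYPE.get(c.kind, "BND")
        pos = max(1, c.start)  # VCF is 1-based
        ref_base = ref[c.lg][pos - 1:pos] or "N"
        info = f"SVTYPE={svtype};END={c.end};SUPPORT={c.count}"
        if c.dr is not None:
            info += f";DR={c.dr:.4f}"
        lines.append(
            f"{c.lg}\t{pos}\tsv_{n}\t{ref_base}\t<{svtype}>\t.\tPASS\t{info}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
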