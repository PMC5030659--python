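"""Guide-site scanning, cleavage prediction, and targeting-vector design.

Guides follow the G(N)19-25 NGG pattern (a SpCas9 protospacer starting with
G, for U6/eft-3-driven sgRNA expression, followed by the NGG PAM); the
predicted double-strand break is the blunt cut 3 bp on the PAM-proximal
side of the protospacer, i.e. within 3 bp of the PAM. Targeting vectors for
a planned rearrangement are chimeric fusions of two 1 kb homology arms that
read straight across each novel junction of the rearranged chromosome, so
homologous recombination with both vectors produces exactly the planned
event. Vector construction is therefore dual to the rearrangement itself:
reading the rearranged genome across a junction must reproduce the vector
sequence letter for letter, which is how these constructions are tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core_io import ReferenceGenome, revcomp
from .synthetic_data import TruthSet, apply_rearrangements

DEFAULT_ARM = 1000
MIN_SPACER = 19
MAX_SPACER = 25
CLEAVAGE_OFFSET = 3  # blunt cut, 3 bp PAM-proximal


@dataclass(frozen=True)
class GuideSite:
    """One G(N)19-25 NGG match, in reference coordinates.

    ``protospacer`` is the G + spacer sequence read 5'->3' on the site's
    strand; ``pam_start`` is the reference coordinate of the NGG (for minus
    strand sites, of its reverse complement CCN) triplet.
    """

    lg: str
    strand: str
    protospacer: str
    pam_start: int

    def __post_init__(self) -> None:
        if not self.protospacer.startswith("G"):
            raise ValueError("protospacer must start with G")
        if not (MIN_SPACER + 1 <= len(self.protospacer) <= MAX_SPACER + 1):
            raise ValueError("protospacer length outside G+19..G+25")

    @property
    def start(self) -> int:
        """Reference start of the protospacer."""
        if self.strand == "+":
            return self.pam_start - len(self.protospacer)
        return self.pam_start + 3

    @property
    def end(self) -> int:
        return self.start + len(self.protospacer)


def scan_guides(ref: ReferenceGenome, lg: str,
                start: int = 0, end: Optional[int] = None) -> list[GuideSite]:
    """All overlapping G(N)19-25 NGG sites on both strands of an interval."""
    seq = ref[lg]
    if end is None:
        end = len(seq)
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"interval [{start}, {end}) outside {lg} bounds")
    sites: list[GuideSite] = []
    window = seq[start:end]
    L = len(window)
    for i in range(L):
        if window[i] != "G":
            continue
        for spacer in range(MIN_SPACER, MAX_SPACER + 1):
            pam = i + 1 + spacer
            if pam + 3 > L:
                break
            if window[pam + 1] == "G" and window[pam + 2] == "G":
                sites.append(GuideSite(
                    lg=lg, strand="+",
                    protospacer=window[i:pam],
                    pam_start=start + pam,
                ))
    rc = revcomp(window)
    for i in range(L):
        if rc[i] != "G":
            continue
        for spacer in range(MIN_SPACER, MAX_SPACER + 1):
            pam = i + 1 + spacer
            if pam + 3 > L:
                break
            if rc[pam + 1] == "G" and rc[pam + 2] == "G":
                sites.append(GuideSite(
                    lg=lg, strand="-",
                    protospacer=rc[i:pam],
                    pam_start=start + (L - pam - 3),
                ))
    sites.sort(key=lambda s: (s.start, s.strand, len(s.protospacer)))
    return sites


def predict_cleavage(site: GuideSite, offset: int = CLEAVAGE_OFFSET) -> int:
    """Predicted blunt-cut coordinate (inter-base) for a guide site.

    The cut falls ``offset`` bases on the PAM-proximal side of the PAM
    (default 3, the canonical SpCas9 blunt cut), expressed
    strand-independently in reference coordinates.
    """
    if site.strand == "+":
        return site.pam_start - offset
    return site.pam_start + 3 + offset


# ---------------------------------------------------------------------------
# Targeting vectors


@dataclass
class TargetingVectorPair:
    """The two chimeric donor molecules for one planned rearrangement.

    Each vector is the fusion of two homology arms reading across one of
    the two novel junctions; ``junction`` is the fusion point offset within
    each vector (equal to the arm length). ``arms`` records the four source
    intervals as (lg, start, end, orient) in left-vector then right-vector
    order.
    """

    left_seq: str
    right_seq: str
    junction: int
    arms: list[tuple[str, int, int, str]] = field(default_factory=list)


def build_inversion_vectors(ref: ReferenceGenome,
                            cut_a: tuple[str, int],
                            cut_b: tuple[str, int],
                            arm: int = DEFAULT_ARM) -> TargetingVectorPair:
    """Donor pair for inverting [cut_a, cut_b) on one linkage group.

    The left vector fuses the upstream arm of cut A to the reverse-directed
    upstream arm of cut B; the right vector fuses the reverse-directed
    downstream arm of cut A to the downstream arm of cut B. Together they
    template both junctions of the inversion.
    """
    (lg_a, a), (lg_b, b) = cut_a, cut_b
    if lg_a != lg_b:
        raise ValueError("inversion cuts must lie on one linkage group")
    if not a < b:
        raise ValueError("inversion requires cut_a < cut_b")
    seq = ref[lg_a]
    if a - arm < 0 or b + arm > len(seq):
        raise ValueError("homology arms extend beyond the linkage group")
    left = seq[a - arm:a] + revcomp(seq[b - arm:b])
    right = revcomp(seq[a:a + arm]) + seq[b:b + arm]
    return TargetingVectorPair(
        left_seq=left, right_seq=right, junction=arm,
        arms=[(lg_a, a - arm, a, "+"), (lg_a, b - arm, b, "-"),
              (lg_a, a, a + arm, "-"), (lg_a, b, b + arm, "+")],
    )


def build_translocation_vectors(ref: ReferenceGenome,
                                cut_a: tuple[str, int],
                                cut_b: tuple[str, int],
                                arm: int = DEFAULT_ARM) -> TargetingVectorPair:
    """Donor pair for a reciprocal translocation between two linkage groups.

    The derivative chromosomes exchange distal arms, so the left vector
    reads across the (A-proximal, B-distal) junction and the right vector
    across the (B-proximal, A-distal) junction.
    """
    (lg_a, a), (lg_b, b) = cut_a, cut_b
    if lg_a == lg_b:
        raise ValueError("reciprocal translocation needs two linkage groups")
    seq_a, seq_b = ref[lg_a], ref[lg_b]
    if a - arm < 0 or a + arm > len(seq_a) or b - arm < 0 or b + arm > len(seq_b):
        raise ValueError("homology arms extend beyond a linkage group")
    left = seq_a[a - arm:a] + seq_b[b:b + arm]
    right = seq_b[b - arm:b] + seq_a[a:a + arm]
    return TargetingVectorPair(
        left_seq=left, right_seq=right, junction=arm,
        arms=[(lg_a, a - arm, a, "+"), (lg_b, b, b + arm, "+"),
              (lg_b, b - arm, b, "+"), (lg_a, a, a + arm, "+")],
    )


# ---------------------------------------------------------------------------
# Expected junction models


@dataclass
class JunctionWindow:
    """Expected sequence around one junction of a planned rearrangement."""

    name: str
    derived_lg: str
    derived_pos: int
    seq: str                 # derived genome, junction +- window
    window: int
    #: primer-check windows strictly outside the homology arms, as derived
    #: (start, end) intervals left and right of the junction
    left_primer_window: tuple[int, int] = (0, 0)
    right_primer_window: tuple[int, int] = (0, 0)


@dataclass
class JunctionModel:
    junctions: list[JunctionWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.junctions)


def expected_junctions(plan: Sequence, ref: ReferenceGenome,
                       window: int = 100, arm: int = DEFAULT_ARM,
                       primer_window: int = 200,
                       truth: Optional[TruthSet] = None) -> JunctionModel:
    """Expected (perfect-repair) junction sequences for a plan.

    Builds the rearranged genome without junction scars and reads
    ``window`` bases on both sides of each truth junction; primer-check
    windows are placed just beyond the homology arms, where screening
    primers can bind without amplifying the donor itself.
    """
    if truth is None:
        from .synthetic_data import SimConfig

        config = SimConfig(
            lengths=tuple(len(s) for s in ref.sequences.values()),
            n_linkage_groups=len(ref.sequences),
            microindel_prob=0.0,
        )
        truth = apply_rearrangements(ref, plan, config)
    model = JunctionModel()
    for i, bp in enumerate(truth.breakpoints):
        dseq = truth.derived[bp.derived_lg]
        p = bp.derived_pos
        lo, hi = max(0, p - window), min(len(dseq), p + window)
        model.junctions.append(JunctionWindow(
            name=f"junction_{i + 1}_{bp.lg}_{bp.pos}",
            derived_lg=bp.derived_lg,
            derived_pos=p,
            seq=dseq[lo:hi],
            window=window,
            left_primer_window=(max(0, p - arm - primer_window),
                                max(0, p - arm)),
            right_primer_window=(min(len(dseq), p + arm),
                                 min(len(dseq), p + arm + primer_window)),
        ))
    return model


# ---------------------------------------------------------------------------
# Output


def write_guide_bed(sites: Sequence[GuideSite], path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.lg}\t{s.start}\t{s.end}\t{s.protospacer}\t0\t"
                     f"{s.strand}\n")


def write_vectors_fasta(pair: TargetingVectorPair, path: str,
                        prefix: str = "vector") -> None:
    with open(path, "w") as fh:
        fh.write(f">{prefix}_left junction={pair.junction}\n{pair.left_seq}\n")
        fh.write(f">{prefix}_right junction={pair.junction}\n{pair.right_seq}\n")
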