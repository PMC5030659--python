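"""Screening-efficiency arithmetic, Fisher's exact test, and junction-repair
classification.

A balancer-induction screen is a funnel: injected P0 worms -> fluorescent
F1 candidates -> F1 lines with phenotype-positive F2 progeny -> PCR-positive
F1 lines -> heritable PCR-positive F2 lines. The screen's efficiency ratio
is the isolated-balancer count over fluorescent F1 worms, in percent.
Junctions of recovered rearrangements are classified by comparing the
observed breakpoint sequence with the perfect homologous-recombination
expectation (the targeting-vector chimera): an exact copy means HR, any
junction indel means end-joining repair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .realign import global_align, smith_waterman


@dataclass(frozen=True)
class ScreenCounts:
    """One row of a screening experiment (the funnel invariant is checked)."""

    label: str
    p0_injected: int
    f1_fluorescent: int
    f2_phenotype_positive: int
    f1_pcr_positive: int
    f2_pcr_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.f2_pcr_positive <= self.f1_pcr_positive
                <= self.f2_phenotype_positive <= self.f1_fluorescent):
            raise ValueError(
                f"{self.label!r}: screening funnel counts are not monotone")


@dataclass(frozen=True)
class EfficiencyRatio:
    """Isolated balancers per fluorescent F1 worm, as a percentage.

    Published tables round such percentages inconsistently (sometimes
    half-up, sometimes truncated), so both two-decimal renderings are kept
    alongside the raw value.
    """

    raw: float
    rounded: float
    truncated: float


def efficiency_ratio(counts: ScreenCounts) -> EfficiencyRatio:
    """100 x (heritable PCR-positive F2 lines) / (fluorescent F1 worms)."""
    if counts.f1_fluorescent <= 0:
        raise ValueError("efficiency ratio needs a positive F1 count")
    raw = 100.0 * counts.f2_pcr_positive / counts.f1_fluorescent
    return EfficiencyRatio(
        raw=raw,
        rounded=round(raw + 1e-12, 2),
        truncated=math.floor(raw * 100) / 100,
    )


_TABLE_COLUMNS = ["label", "p0_injected", "f1_fluorescent",
                  "f2_phenotype_positive", "f1_pcr_positive",
                  "f2_pcr_positive"]


def read_screen_table(path) -> list[ScreenCounts]:
    """Load a screening-count TSV (columns as in :data:`_TABLE_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"screen table missing columns: {sorted(missing)}")
    return [
        ScreenCounts(label=str(row.label),
                     p0_injected=int(row.p0_injected),
                     f1_fluorescent=int(row.f1_fluorescent),
                     f2_phenotype_positive=int(row.f2_phenotype_positive),
                     f1_pcr_positive=int(row.f1_pcr_positive),
                     f2_pcr_positive=int(row.f2_pcr_positive))
        for row in df.itertuples()
    ]


def load_example_screen_table() -> list[ScreenCounts]:
    """The bundled example table: six balancer-induction screens on
    chromosome IV (with/without targeting vectors, wild-type vs lig-4)."""
    with resources.as_file(
        resources.files("balancerscan.data") / "screen_counts.tsv"
    ) as p:
        return read_screen_table(p)


# ---------------------------------------------------------------------------
# Fisher's exact test


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Computed by exact hypergeometric enumeration in integer arithmetic:
    the p-value sums the probabilities of all tables with the same margins
    whose probability does not exceed the observed table's.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty 2x2 table")
    r1 = a + b
    c1 = a + c
    # P(k) = C(r1, k) C(n - r1, c1 - k) / C(n, c1); compare numerators
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    obs = math.comb(r1, a) * math.comb(n - r1, c1 - a)
    num = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(n - r1, c1 - k)
        if w <= obs:
            num += w
    return num / math.comb(n, c1)


# ---------------------------------------------------------------------------
# Junction repair classification


@dataclass
class RepairCall:
    """Verdict for one breakpoint junction.

    ``verdict`` is 'HR' when the observed junction equals the expected
    homologous-recombination junction exactly over the comparison window,
    else 'end_joining' with the edit operations recorded as
    (op, position, length) tuples, op in {'X' substitution, 'I' insertion,
    'D' deletion} with positions on the expected sequence.
    """

    breakpoint_id: str
    verdict: str
    edits: list = field(default_factory=list)
    strain: Optional[str] = None


def classify_breakpoint_repair(observed: str, expected: str,
                               breakpoint_id: str = "",
                               strain: Optional[str] = None) -> RepairCall:
    """Compare an observed junction sequence with the HR expectation.

    Equality over the comparison window means clean homologous repair;
    any difference is end joining, with the indel/substitution operations
    extracted from a global alignment under the realignment scorer.
    Raises ValueError when the observed sequence does not overlap the
    junction at all (no meaningful local similarity).
    """
    observed = observed.upper()
    expected = expected.upper()
    if not observed or not expected:
        raise ValueError("empty junction sequence")
    if observed == expected:
        return RepairCall(breakpoint_id=breakpoint_id, verdict="HR",
                          strain=strain)
    local = smith_waterman(observed, expected)
    if local.score < 2 * 16:  # less than one exact 16-mer of similarity
        raise ValueError(
            f"observed sequence does not overlap the expected junction "
            f"({breakpoint_id or 'unnamed'})")
    ga = global_align(observed, expected)
    edits = []
    pos = 0  # position on expected
    for op in ga.edits:
        if op == "M":
            pos += 1
        elif op == "X":
            edits.append(("X", pos, 1))
            pos += 1
        elif op == "D":  # base in expected missing from observed
            edits.append(("D", pos, 1))
            pos += 1
        else:  # 'I': extra base in observed
            edits.append(("I", pos, 1))
    # merge adjacent same-op single-base edits into runs
    merged: list[tuple[str, int, int]] = []
    for op, pos, ln in edits:
        if merged and merged[-1][0] == op and merged[-1][1] + merged[-1][2] == pos:
            merged[-1] = (op, merged[-1][1], merged[-1][2] + ln)
        elif merged and op == "I" and merged[-1][0] == "I" and merged[-1][1] == pos:
            merged[-1] = (op, pos, merged[-1][2] + ln)
        else:
            merged.append((op, pos, ln))
    return RepairCall(breakpoint_id=breakpoint_id, verdict="end_joining",
                      edits=merged, strain=strain)


@dataclass
class RepairSummary:
    hr: int
    end_joining: int
    #: strain -> 'both_HR' | 'mixed' | 'both_EJ' (strains with other than
    #: two classified junctions are labelled by their verdict multiset)
    per_strain: dict = field(default_factory=dict)


def summarize_repair(calls: Sequence[RepairCall]) -> RepairSummary:
    """Totals by verdict plus a per-strain rollup."""
    if not calls:
        raise ValueError("no repair calls to summarize")
    hr = sum(1 for c in calls if c.verdict == "HR")
    ej = sum(1 for c in calls if c.verdict == "end_joining")
    per_strain: dict[str, str] = {}
    strains: dict[str, list[str]] = {}
    for c in calls:
        if c.strain is not None:
            strains.setdefault(c.strain, []).append(c.verdict)
    for strain, verdicts in strains.items():
        if all(v == "HR" for v in verdicts):
            per_strain[strain] = "both_HR" if len(verdicts) == 2 else "all_HR"
        elif all(v == "end_joining" for v in verdicts):
            per_strain[strain] = "both_EJ" if len(verdicts) == 2 else "all_EJ"
        else:
            per_strain[strain] = "mixed"
    return RepairSummary(hr=hr, end_joining=ej, per_strain=per_strain)


def write_repair_calls(calls: Sequence[RepairCall], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("breakpoint_id\tstrain\tverdict\tedits\n")
        for c in calls:
            ed = ";".join(f"{op}@{pos}x{ln}" for op, pos, ln in c.edits) or "."
            fh.write(f"{c.breakpoint_id}\t{c.strain or '.'}\t{c.verdict}\t{ed}\n")
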