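# Methods

## The problem

CRISPR/Cas9 can engineer balancer chromosomes — large inversions,
reciprocal translocations, and crossover-suppressors — at chosen sites in
*C. elegans*. Verifying an engineered balancer from whole-genome sequencing
means finding its two novel junctions in short single-end reads (~140 bp,
Ion-Proton-style libraries), distinguishing them from pre-existing
variation, and confirming there are no unintended copy-number changes.
`balancerscan` implements that verification pipeline, the guide/donor
design arithmetic that precedes it, and the screening and junction-repair
statistics that surround it.

## Split-read detection model

A read crossing a junction maps partially: the mapper aligns one side and
soft-clips the rest. The pipeline:

1. **Coverage and depth.** Coverage = (mean raw read length × read count) /
   reference length, clips included. Depth counts reads whose aligned (M)
   span covers each base; soft-clipped bases contribute nothing.
2. **Clip harvesting.** Soft-clip tails strictly longer than 20 bp are
   kept (shorter tails carry too little seeding information: a 16-mer plus
   a few bases of slack).
3. **Seeding.** Every contiguous 16-mer of a clip and of its reverse
   complement becomes an exact-match query. All queries from all clips are
   compiled into one Aho-Corasick automaton and every linkage group is
   scanned once; N-containing 16-mers are excluded (N matches nothing).
4. **Extension.** Each seed hit is projected to a candidate clip placement
   and the *whole clip* is aligned by Smith–Waterman (match +2, mismatch
   −1, gap −2, linear gap) against a reference window of the clip length
   plus a 20 bp margin on each side. The margin guarantees that the
   optimal alignment of a true-locus clip fits in the window. A placement
   must score at least 32 (one perfect 16-mer) to be accepted. Equal
   scores are resolved by distance to the clip's anchor (different linkage
   group = infinitely far), then linkage-group name, then coordinate —
   proximity first, determinism after.
5. **Split reads.** Anchor and realigned clip are ordered by read
   5′/3′ position and canonicalized so that a read and its reverse
   complement (and reads from either flank of a junction) produce the same
   placement pair. Five categories follow from the geometry: deletion-type
   (3′ region downstream on the same group, same sense), insertion-type
   (upstream), inversion-type (opposite sense, same group),
   translocation-type (different groups), translocational-inversion-type
   (different groups, opposite sense).
6. **Control subtraction.** A case SR is discarded if the control sample
   contains an SR of the same category with both junction coordinates
   within 10 bp — removing shared artifacts and pre-existing variants.
7. **Candidates.**
   - More than 2 deletion-type SRs sharing a common gap (within 10 bp)
     call that gap as a deletion.
   - Cluster pairs bracketing a region call *complicated* candidates:
     del+ins → insertion (the bracketing coordinates delimit the copied
     source; the shared coordinate is the insertion point); inv+inv →
     local inversion or inverted insertion; the same geometries across two
     linkage groups → translocated / inverted-translocational insertions.
     If the two junction estimates at the insertion point disagree, the
     uncovered gap is additionally called as a deletion.
   - Reciprocal cluster pairs at chromosome scale become
     inversion/translocation breakpoint-pair candidates — the engineered
     balancers themselves. These are copy-neutral; depth filters skip
     them. Unpaired large clusters are reported with status `unpaired` but
     are not confirmed calls.
   - Complicated candidates with fewer than 10 supporting reads are
     removed.
8. **Depth filters.** Normalized depth ND = depth / coverage over mapped
   regions (depth strictly greater than 1); depth ratio DR = case ND /
   control ND where both are mapped; a candidate region's DR is the
   arithmetic mean over its bases. Deletions with DR > 0.75 are removed
   (no copy loss); insertion-class candidates with DR > 1.75 or > 2.5 are
   relabeled duplication or multiplication (the copies pile onto the
   single reference copy). Regions with no jointly mapped base keep their
   call, flagged `DR unavailable`.

### Thresholds and tolerances

| knob | default | meaning |
|---|---|---|
| `min_clip` | 20 bp | clips must be strictly longer to be realigned |
| `kmer` | 16 | exact-seed length |
| `match/mismatch/gap` | +2/−1/−2 | Smith–Waterman scores (linear gap) |
| `min_score` | 32 | acceptance score, one perfect 16-mer's worth |
| `window_margin` | 20 bp | reference window slack around a seed |
| `tol` | 10 bp | clustering, control matching, gap identity |
| `pair_tol` | 3×`tol` | reciprocal-pair matching (see below) |
| `min_del_sr` | 3 | "more than 2" deletion-type SRs |
| `min_complex_reads` | 10 | complicated-candidate support |
| `local_span_max` | 1 kb | local-variant vs breakpoint-pair routing |
| `mapped_depth_min` | 1 | depth strictly above this is "mapped" |
| `dr_del/dr_dup/dr_mult` | 0.75/1.75/2.5 | depth-ratio thresholds |

Two threshold readings are deliberately literal and configurable: "more
than 2 supporting reads" is implemented as ≥ 3, and "depth greater than
one" as depth > 1. Both may plausibly have been intended as ≥ 2 / ≥ 1; the
strict reading is the default and the knobs (`min_del_sr`,
`mapped_depth_min`) allow the other.

**Why `pair_tol` is wider than `tol`.** End-joining repair leaves scars of
up to ~10 bp at engineered junctions. Every read crossing one junction
carries the *same* scar bases, so the local aligner extends or trims each
cluster's clip-side junction estimate by the same amount — a systematic,
not random, offset, and opposite in direction for the two reciprocal
clusters of one event. Matching reciprocal clusters therefore tolerates
3×`tol` (30 bp), while clustering and control subtraction keep 10 bp.
The same reasoning sets the minimum trusted source-region span for
complicated candidates at 3×`tol`: a reciprocal event with scars would
otherwise masquerade as a ~15 bp copied insertion. This bounds the
method's resolution for copied insertions at ~30 bp.

**Routing at `local_span_max`.** The same reciprocal-cluster geometry
describes a 300 bp inverted insertion and a 6.7 Mb balancer inversion.
Regions up to 1 kb are treated as local variants (subject to the
complicated-candidate support and depth filters); anything larger is
reported as a breakpoint pair, which is how balancer-scale events are
validated (junction PCR, not copy number). The 1 kb default separates the
two regimes cleanly in practice and is configurable.

## Synthetic data

The generator defines the conditions every downstream claim is tested
under:

- i.i.d. genomes at GC 0.36 (*C. elegans*-like), two 50 kb linkage groups
  by default;
- reads of 140 ± 10 bp (discrete uniform), uniform start positions,
  either strand with probability ½, coverage 20×;
- per-base substitution rate 0.5 % and indel rate 0.05 % — the sequencing
  platform's error profile is not published, so these are configuration,
  not claims;
- junction micro-indels: probability 0.8 per junction, 1–10 bp, half
  deletions (resected flanks) and half novel insertions — mimicking the
  observed predominance of end-joining scars at engineered junctions;
- mapping is *emulated from ground truth*: a read inside one colinear
  segment maps fully; a breakpoint-crossing read is placed by its longest
  colinear piece (minimum 20 bp, mirroring the clip threshold) with the
  remainder soft-clipped. An insertion whose sequence occurs in the
  reference is treated as a copy: its reads map to the source locus, as a
  real mapper would place them.

One master seed is split hierarchically (genome / rearrangement / case
reads / control reads), so any stage is independently reproducible and a
whole run is byte-deterministic.

**What the emulation does not model** — and hence what passing tests do
not show about real data: mapper-specific placement heuristics and mapping
quality, flow-space (homopolymer) error chemistry, library GC bias,
repetitive-genome ambiguity beyond what random sequence provides, and
paired-end evidence (the study design is single-end). Reads containing an
insertion sequencing error keep a single-M CIGAR, so their coordinates may
drift by the indel size; real aligners would emit small I/D operations
instead.

## Design arithmetic

Guide sites are all overlapping matches of G(N)₁₉–₂₅ NGG on both strands.
The predicted cut is the canonical SpCas9 blunt cut 3 bp on the
PAM-proximal side — one realization of "within 3 bp of the PAM", with the
offset configurable. Targeting vectors are chimeric fusions of two 1 kb
homology arms (2 kb total per vector): for an inversion of [a, b),
left = ref[a−arm, a) + revcomp(ref[b−arm, b)) and
right = revcomp(ref[a, a+arm)) + ref[b, b+arm); for a reciprocal
translocation, left = A[a−arm, a) + B[b, b+arm) and
right = B[b−arm, b) + A[a, a+arm). The layout for translocations is
inferred by analogy with the inversion construction and pinned by the
duality property: each vector must equal the rearranged genome read across
its junction, exactly. Note the inversion identity requires the inverted
span to cover at least one arm; shorter spans still give well-formed
donors, but the HR product then differs from the naive chimera.

## Screening statistics and repair classification

The efficiency ratio is 100 × (heritable PCR-positive F2 lines) /
(fluorescent F1 worms). Published tables round such percentages
inconsistently (1/136 → 0.73 is truncated, 1/168 → 0.60 is rounded), so
the operation returns the raw value plus both two-decimal renderings.
Fisher's exact test is computed by exact integer hypergeometric
enumeration (two-sided: all tables with probability ≤ the observed
table's). Junction repair is classified by comparing the observed junction
sequence against the perfect-HR expectation over a ±50 bp window
(configurable): exact equality is HR; anything else is end joining, with
the edits extracted from a global alignment under the same +2/−1/−2
scorer. A sequence with less than one exact 16-mer of local similarity to
the expectation is rejected as not covering the junction.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; SAM conversion at the
  boundary; VCF output is 1-based.
- Smith–Waterman ties: best cell at smallest (i, j); traceback prefers
  diagonal, then up, then left. An exact substring occurrence short-cuts
  the DP (it provably attains the maximum 2·len under match = +2).
- Cluster coordinates are member medians; greedy 1-d clustering anchored
  on the first member, members sorted by junction coordinates.
- A clip realigned exactly onto its anchor's continuation is not a split
  read and is dropped; identical placements raise an error.
- Empty candidate lists produce valid header-only TSV/VCF.
- Multi-mapping primary records are ingested as given; secondary and
  supplementary records are skipped.

## Problem sizes

The test suite and the acceptance script run on desk-scale instances
chosen to exercise every code path: 100 kb two-chromosome genomes at 20×
coverage (~14,000 reads per sample) for recovery experiments — 20 seeded
replicates in the test suite, 5 in the acceptance script — plus a 100 kb
single-chromosome genome for the copy-number demonstrations. Breakpoint
recovery at these sizes is exact up to the injected scar, and nothing in
the pipeline's logic depends on genome length beyond linear running time.

## Known limitations

- Single-end evidence only; no read-pair or assembly corroboration.
- Copied insertions below ~30 bp and local variants whose geometry
  collapses within `pair_tol` are not callable (see above).
- A chance exact 16-mer can seed a spurious realignment of an error clip
  (about once per few hundred clips at 0.5 % substitution error); such
  singletons surface only as `unpaired` records, never as kept calls.
- The depth-ratio summary is an unweighted mean; long candidate regions
  with partial copy change can average out.
- Breakpoint coordinates are junction estimates from clip ends, not
  base-pair-resolved by consensus assembly of the junction.
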