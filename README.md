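# balancerscan

Split-read structural-variant detection and CRISPR design for engineered
balancer chromosomes.

Balancer chromosomes — large inversions, reciprocal translocations and
crossover-suppressors — keep lethal mutations stable in heterozygotes by
suppressing recombination. They can now be engineered at chosen sites with
CRISPR/Cas9. `balancerscan` is the computational side of that workflow,
for geneticists engineering and verifying such rearrangements:

- **design**: scan for G(N)₁₉–₂₅NGG guide sites, predict cleavage
  coordinates (blunt cut within 3 bp of the PAM), and build the chimeric
  targeting vectors — two 1 kb homology arms fused across each planned
  junction — for inversions and reciprocal translocations;
- **detect**: verify the engineered chromosome from short single-end
  whole-genome sequencing (~140 bp reads) by split-read analysis;
- **screen-stats / repair-classify**: screening-efficiency ratios,
  Fisher's exact test, and HR-vs-end-joining classification of observed
  junction sequences;
- **simulate**: a seeded generator of rearranged genomes, reads and
  mapper-emulated alignments, so the whole chain runs and is tested
  without any external data.

## The detection method

A read crossing a rearrangement junction aligns partially; the mapper
soft-clips the rest. For every clip longer than 20 bp, all contiguous
16-mers of the clip and its reverse complement are matched exactly
genome-wide with an Aho-Corasick automaton; each seed is extended by
Smith–Waterman (match +2, mismatch −1, gap −2) of the whole clip against
the neighbouring reference window, ties resolved by proximity to the
clip's anchor. Each accepted realignment yields a split read (SR), whose
5′/3′ placement geometry classifies it as deletion-, insertion-,
inversion-, translocation- or translocational-inversion-type. SRs seen in
a control sample are subtracted; >2 deletion-type SRs sharing a gap call a
deletion; cluster pairs bracketing a region call insertions, local
inversions and translocated insertions (≥10 supporting reads); reciprocal
cluster pairs at chromosome scale call the balancer's breakpoint pairs.
Finally, the per-base normalized depth ND = depth/coverage and the
case/control depth ratio DR remove deletions without copy loss
(DR > 0.75) and promote insertions with DR > 1.75 / > 2.5 to duplications
/ multiplications.

See `docs/methods.md` for the model, every threshold, and the simulator's
scope.

## Worked example

The bundled demo simulates a 50 kb chromosome carrying a 5 kb inversion
(cuts at 20,000 and 25,000), sequences it at 20× with 0.5 % errors and
end-joining scars at the junctions, maps the reads back to the
un-rearranged reference, and runs detection against a clean control:

```bash
balancerscan demo --out-dir demo_run --seed 7
# demo recall: 1.0, kept candidates: 1
cat demo_run/summary.yaml
```

```yaml
seed: 7
kept_candidates: 1
inversion_pairs: 1
recall: 1.0
breakpoint_error_bp: 3
truth_microindel_bp: 6
stage_counts:
  case_alignments: 7143
  control_alignments: 7143
  case_clips: 207
  case_realigned: 207
  case_split_reads: 70
  control_clips: 151
  control_realigned: 151
  control_split_reads: 42
  case_srs_after_control: 69
  candidates: 1
  kept_candidates: 1
```

Reading it: 7,143 simulated case reads produced 207 soft-clips worth
realigning; 70 became split reads; control subtraction left 69; their two
reciprocal inversion-type clusters paired into exactly one kept
`inversion_breakpoint_pair` whose junctions sit 3 bp from the true cuts —
within the 6 bp repair scar the simulator injected. The variant reports
(`demo_run/demo.variants.tsv`, `.vcf`) and the split-read table are
written alongside.

Screening arithmetic works on plain TSV count tables:

```bash
balancerscan screen-stats \
    --table src/balancerscan/data/screen_counts.tsv --out ratios.tsv
```

which reports, per screen, the isolated-balancer/fluorescent-F1 ratio in
percent (e.g. 3/900 → 0.33, 1/312 → 0.32) in raw, rounded and truncated
renderings.

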