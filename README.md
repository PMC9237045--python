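# retrojoin

Analysis pipeline for **de novo LINE-1 (L1) retrotransposon insertions at
genome-editing sites**, together with a seeded synthetic-data generator that
emulates the assays' read structure so the whole pipeline can be exercised,
tested and benchmarked without any external sequencing data.

CRISPR/Cas9 double-strand breaks (and, less frequently, prime- and
base-editing lesions) can capture the 3' end of an L1 mRNA: end-resection
exposes a 3' overhang that base-pairs with the poly(A) tail of the L1
transcript and primes reverse transcription, inserting a 5'-truncated L1 copy
— or a plasmid, pegRNA-scaffold or genomic fragment — into the break. This
package implements the computational side of characterizing such events for
people who study genome-editing outcomes or L1 biology:

* **Amplicon dialect** — paired-end deep sequencing across a target locus:
  barcode demultiplexing (8-bp keys), primer+10-bp specificity filtering,
  insert trimming, attribution of each insert to its source reference
  (codon-optimized L1 reporter, endogenous L1Hs, lentiviral/editor plasmid,
  pegRNA scaffold, genomic DNA) with shared-sequence exclusion rules,
  redundancy collapse (<4 bp), 100-bp fragment maps, and junction analysis.
* **PolyA-seq dialect** — one-sided nested capture of new L1 3' ends
  (poly(A) + downstream genomic flank) for genome-wide junction mapping:
  primer+7A+8A filtering and masking, seeded local alignment, artifact
  filters (score < 30, ambiguity < 4, >= 10-nt gaps, PCR repeats < 3 bp,
  HaeIII GG|CC ligation artifacts), junction calling at the 5' aligned base,
  and poly(A)-tract measurement (>= 11 nt, ordering constraint).
* **Consensus-motif analytics** — the L1 endonuclease nicks at
  5'-TT/AAAA-3'; for each insertion point the −3..+8 genomic flank is
  extracted on the motif strand, a position-weight matrix is built per
  window of 30 insertions, per-position information content
  IC_j = 2 + Σ_b p_bj log2 p_bj (bits) is summed into a motif score, and a
  natural cubic spline interpolates the window scores along a chromosome —
  the signature by which endonuclease-dependent (distal, motif-rich) and
  endonuclease-independent (DSB-proximal, motif-less) insertions separate.
* **Editing efficiency** — quality-aware mutation calling under the
  Neighborhood Quality Standard (Phred >= 30 at the mutation, >= 20 at the
  five bases on either side), after read QC (mean Q >= 20, length >= 50)
  and alignment QC (> 80 aligned bp).

All junction logic is built on one affine local-alignment contract
(match +1, mismatch −2, gap open 2, extend 1): the microhomology of a joint
is the overlap between the break-flank alignment and the insert alignment in
read coordinates, and unmatched sequence between them is an "other sources"
linker.

## Worked example

```python
from retrojoin import build_reference_set, SimulationConfig
from retrojoin.simulate import (simulate_insertion_events, simulate_amplicon_reads,
    default_amplicon_design, default_sample_sheet,
    DEFAULT_FWD_BARCODE, DEFAULT_REV_BARCODE)
from retrojoin.pipeline import run_amplicon_pipeline

refset = build_reference_set(seed=1)          # mini-genome + reporter + plasmids
cfg = SimulationConfig(seed=3, n_reads=500, error_rate=0.0)
events = simulate_insertion_events(refset, cfg)
pairs, truth = simulate_amplicon_reads(
    events, default_amplicon_design(refset),
    DEFAULT_FWD_BARCODE, DEFAULT_REV_BARCODE, cfg)
result = run_amplicon_pipeline(refset, pairs, default_sample_sheet(refset, "amplicon"))
sr = result.samples["S1"]
print(sr.audit)
print({k: round(v, 3) for k, v in sr.summary.items()})
```

prints

```
{'assigned': 500, 'primer_filtered': 0, 'no_insert': 0, 'pcr_duplicates': 117,
 'short_inserts': 0, 'classified_inserts': 383}
{'GENOMIC': 0.298, 'L1HS': 0.008, 'L1_REPORTER': 0.35, 'PLASMID_LENTI': 0.345,
 'unclassified_count': 0}
```

Reading this: of 500 simulated pairs all demultiplexed and passed the primer
filter; 117 inserts were exact duplicates and collapsed as presumed PCR
repeats — mostly reporter insertions, whose 3'-anchored junctions recur
identically, which is why the reporter share (0.35) sits below the simulated
event mixture (0.50). The small L1HS fraction is the shared-sequence
attribution rule at work: inserts falling entirely inside the
reporter/L1Hs-homologous element are credited to endogenous L1Hs. The
left-end microhomology histogram of `sr.junctions` shows a decreasing 0–6 bp
profile, the classic signature of microhomology-mediated joining of L1 cDNA
to resected DSB ends.

A shell interface covers the same ground
(`retrojoin {simulate,demux,filter,classify,junctions,polyaseq,motif,efficiency,run}`):

```sh
retrojoin run --seed 1 --n-reads 120 --dialect polyaseq --out run_pa
# -> junction BED, poly(A) table, window scores, audit log, manifest
# "done; intron assay products: 1192 bp (unspliced) / 292 bp (spliced)"
```

The in-silico intron assay mirrors the bench readout of a completed
retrotransposition cycle: the reporter's antisense-GFP intron (900 bp) is
lost at the DNA level, shortening the diagnostic PCR product from 1192 bp to
292 bp.

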