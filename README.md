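# bcrflow

Analysis of B cell receptor (BCR) heavy-chain repertoires from AIRR
Rearrangement files: copy-number error correction, automatic clonal
clustering, repertoire diversity and gene-usage statistics, somatic
hypermutation (SHM) profiling, lineage tracing of expressed monoclonal
antibodies, cross-compartment clonal sharing, and ELISA-based reactivity
calls. A ground-truth synthetic data generator makes every stage
testable end to end.

## Scientific problem

High-throughput BCR sequencing of sorted B cell populations yields
tables of V(D)J rearrangements annotated with V/J gene calls, the
junction (CDR3) sequence and per-sequence copy numbers. Turning those
reads into biology requires several inference steps, each with sharp
edge cases:

- **Error correction.** PCR and sequencing errors create spurious
  low-copy sequences one substitution away from real ones. Sequences
  with fewer than 5 copies are merged into a Hamming-distance-≤1
  high-copy neighbor when one exists and discarded otherwise, so that
  total copies are conserved (`copies_in = copies_out + copies_discarded`).
- **Clonal clustering.** Sequences descending from one V(D)J
  recombination event share a V gene, a J gene and junction length, and
  have similar junctions. Within each V/J/length partition, sequences
  are single-linkage clustered on length-normalized junction Hamming
  distance. The distance cutoff is detected per repertoire from the
  bimodal distance-to-nearest distribution: the threshold is the
  midpoint of the first non-declining histogram bin after the first
  peak of the smoothed histogram.
- **Repertoire statistics.** Clonal expansion and diversity are
  summarized by Shannon entropy, Gini–Simpson index, D50 (percentage of
  ranked clones needed to reach half the repertoire), top-clone
  cumulative frequencies, V/J gene usage (including distal J fraction)
  and isotype (class-switch) distributions.
- **SHM profiling.** Mutations are counted against per-clone consensus
  germlines over the IMGT-gapped V region (positions 1–312), split by
  framework/CDR region and replacement/silent status, and checked for
  AID hotspot (WRCY/RGYW) context; a 5-mer mutability model can be
  estimated from pooled mutations.
- **Lineage tracing.** Given the heavy chain of a characterized
  monoclonal antibody, all clonally related sequences in a repertoire
  are recovered, with per-compartment descendant counts and copy-number
  contributions.
- **Sharing and connectivity.** Clonal lineages spanning sorted
  compartments are counted on downsampled, pooled repertoires; per-clone
  lineage graphs are simplified relatedness trees (minimum spanning tree
  over Hamming distances, rooted at the germline).
- **Reactivity.** Polyreactivity ELISAs are called against a
  control-derived threshold (mean of positive controls − 2 s.d. at
  1 µg/ml; positive for ≥2 of dsDNA/insulin/LPS ⇒ polyreactive), HEp-2
  reactivity by control-normalized OD > 1, and plasma autoantibodies by
  z-score > 2 against healthy controls.

## Worked example

```python
from bcrflow import (
    SimConfig, generate_repertoires, correct_repertoire,
    nearest_neighbor_distances, detect_threshold, define_clones,
    attach_germlines, diversity_indices, hotspot_fraction, count_mutations,
)
from bcrflow.airr_io import Repertoire

# 1. simulate an antigen-experienced repertoire with known ground truth
reps, truth = generate_repertoires(SimConfig(seed=42, n_lineages=120))
rep = Repertoire(records=[r for rr in reps.values() for r in rr.records])
print(f"input: {len(rep)} sequences "
      f"({truth['is_error_satellite'].sum()} planted error satellites)")

# 2. copy-number error correction
corrected, report = correct_repertoire(rep)
print(f"corrected: {len(corrected)} sequences "
      f"(merged {report.n_merged}, discarded {report.n_discarded_low} low-copy)")
print(f"copy conservation: {report.copies_in} = "
      f"{report.copies_out} + {report.copies_discarded}")

# 3. clonal clustering at an automatically detected junction distance threshold
profile = detect_threshold(nearest_neighbor_distances(corrected))
clones = define_clones(corrected, profile.threshold)
attach_germlines(corrected, clones)
print(f"threshold: {profile.threshold:.3f} ({profile.method}); "
      f"{len(clones)} clones")

# 4. repertoire statistics and somatic hypermutation
div = diversity_indices(clones)
print(f"Shannon H = {div.shannon_H:.3f}, Gini-Simpson = {div.gini_simpson:.3f}, "
      f"D50 = {div.d50:.1f}%")
freqs = [count_mutations(r).frequency for r in corrected.records]
frac, _ = hotspot_fraction(corrected)
print(f"mean SHM frequency = {sum(freqs)/len(freqs):.4f}, "
      f"AID hotspot fraction = {frac:.3f}")
```

Output:

```text
input: 420 sequences (36 planted error satellites)
corrected: 384 sequences (merged 36, discarded 0 low-copy)
copy conservation: 4456 = 4456 + 0
threshold: 0.085 (first_nondeclining); 120 clones
Shannon H = 3.760, Gini-Simpson = 0.937, D50 = 7.5%
mean SHM frequency = 0.0214, AID hotspot fraction = 0.249
```

All 36 planted error satellites are merged away, and the 120 planted
lineages are recovered as exactly 120 clones at the automatically
detected threshold.

## Command-line interface

The `bcrflow` console script wraps each stage:

```bash
bcrflow simulate --seed 42 --n-lineages 120 --out sim/
bcrflow correct sim/sim_CD38int_t0.tsv --out corrected.tsv
bcrflow cluster corrected.tsv --out clustered.tsv
bcrflow stats clustered.tsv --threshold 0.085 --out-prefix results/stats
bcrflow shm clustered.tsv --out-prefix results/shm
bcrflow run --config pipeline.yaml --out results/
```

`bcrflow run` executes the full pipeline (correction → threshold →
clustering → germlines → statistics/SHM → per-donor sharing → optional
query tracing) from a YAML config listing input files keyed by donor,
compartment and timepoint. Identical configs produce identical outputs.

## Testing

```bash
python -m pytest -q tests/
```

The suite covers every module with oracle-backed unit tests (brute-force
reference implementations, Biopython translation, networkx minimum
spanning trees, closed-form arithmetic) plus an end-to-end acceptance
suite in `tests/test_acceptance.py` that checks error-correction
equivalence and recovery, threshold detection, clustering recovery
(adjusted Rand index against planted lineages), diversity closed forms,
SHM and hotspot recovery, lineage-tracer exactness, sharing nulls and
reactivity calls on seeded synthetic data.

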