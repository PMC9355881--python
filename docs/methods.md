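# Methods note

## Scope and model

`bcrflow` analyzes immunoglobulin heavy-chain rearrangements in AIRR
Rearrangement format. All sequence comparisons are Hamming distances
over substitutions on IMGT-gapped alignments; insertions, deletions and
allele-level germline variation are outside the model. The V region is
fixed at IMGT gapped positions 1–312 (FR1 1–78, CDR1 79–114, FR2
115–165, CDR2 166–195, FR3 196–312); the junction occupies gapped
positions 313 … 312 + `junction_length`, followed by FR4.

A *clone* is operationally defined as the transitive closure (single
linkage) of sequences that share at least one V gene and one J gene
(allele suffixes stripped; ambiguous comma-separated calls contribute
their whole gene set, merged transitively), have equal junction length,
and whose length-normalized junction Hamming distance is at most the
threshold τ.

## Stage-by-stage parameters

### Error correction (`error_correction`)

| parameter | default | meaning |
|---|---|---|
| `copy_threshold` | 5 | sequences with fewer copies are low-copy |
| `max_merge_distance` | 1 | max N-tolerant Hamming distance for merging |
| `drop_nonproductive` | True | remove non-functional rearrangements |

Identical alignments are collapsed first (representative: highest-copy
input, ties by smallest `sequence_id`). Each low-copy sequence is then
merged into its best high-copy neighbor — ties broken by smaller
distance, then higher copies, then lexicographically smaller alignment —
or discarded when no neighbor exists. `N` positions never count as
mismatches; unequal lengths never merge. The invariant
`copies_in = copies_out + copies_discarded` holds on every run and is
asserted in the report.

### Threshold detection (`clonal_clustering.detect_threshold`)

Distance-to-nearest distributions are computed within V/J/length
partitions (singleton partitions contribute nothing; fewer than 20
distances raise, callers fall back to `fallback_threshold`). The
histogram uses `bin_width` 0.01 over [0, 1] and a centered moving
average of window 5 (window shrinks at the edges). The first peak is
the first nonzero smoothed bin at index ≥ 1 that is ≥ both neighbors;
τ is the midpoint of the first later bin whose smoothed count is ≥ its
predecessor (the start of the between-clone mode), searching only up to
the last nonzero bin. Two deliberate numerical choices:

- **Peak at bin 0.** When bin 0 dominates bin 1, the peak is taken at
  bin 0. Highly clonal repertoires place most nearest-neighbor
  distances at exactly 0 after collapsing; requiring the peak at index
  ≥ 1 would skip the true within-clone mode and return a τ inside the
  between-clone mode.
- **Zero-tail exclusion.** The non-declining search stops at the last
  nonzero bin, so an all-zero tail (0 ≥ 0) cannot masquerade as the
  valley; a monotonically declining histogram therefore hits the
  documented fallback (default τ = 0.1) instead of fabricating a cutoff.

### Clustering and germlines

Clusters are connected components at distance ≤ τ (tolerance 1e−12).
Clone ids are deterministic: `{v_group}_{j_group}_{length}_{rank}` with
clones ranked by copies then smallest member id. Per-clone consensus
germlines are positionwise majority votes over member germlines (ties
broken by lexicographically smallest base); the junction block is masked
to `N` because the junction is clone-defining, not a mutation track.

### Repertoire statistics

Shannon entropy uses natural log over clone copy frequencies;
Gini–Simpson is 1 − Σp²; D50 is the percentage of abundance-ranked
clones whose cumulative frequency first reaches 50%. Ambiguous gene
calls split their weight 1/k across candidates. Isotypes pool IGHM/IGHD
as unswitched and IgG/IgA/IgE classes as switched; unknown constant
calls are reported separately. Downsampling to n unique sequences is
uniform without replacement under a fixed seed. Treemap tables project
onto the top 2,500 clones, preserving the frequency sum.

### SHM analysis

Mutations are positions in 1–312 where both sequence and germline bases
are in {A, C, G, T} and differ; `N` and gap positions are excluded from
the informative denominator. Replacement/silent status evaluates each
mutation independently against the germline codon (one substitution
applied at a time). AID hotspot context is evaluated on the ungapped
germline: a mutated `C` inside WRCY (window pos−2 … pos+1) or a mutated
`G` inside RGYW (pos−1 … pos+2), with W = A/T, R = A/G, Y = C/T;
incomplete windows are excluded from the denominator. The 5-mer
mutability model divides observed center-position mutation counts by
germline 5-mer background counts and normalizes to sum 1; both contexts
and backgrounds are restricted to the V region so junction and FR4
bases never enter motif statistics. Fewer than `min_mutations` (50)
usable mutations raise — pool repertoires before modelling.

### Lineage tracing (`chain_tracer`)

Queries require junction, V and J calls. Records sharing V gene, J gene
and junction length are prefiltered into a mini-repertoire; this is an
exact optimization because clustering partitions on V/J/length anyway,
and the test suite verifies equality with full-repertoire clustering.
The query is appended with unit copies and excluded from member lists
and contribution denominators. Contribution is matched copies divided
by total compartment copies.

### Connectivity and sharing

"Average clonal connections" is ambiguous between mean clone size, mean
(size − 1) and mean spanning-tree degree 2(s−1)/s; all three are
reported, none privileged. Sharing downsamples each compartment to
`n` (default 10,000) unique sequences, pools them, detects one τ on the
pooled set (fallback on too-few distances) and labels each clone by its
members' compartments. Lineage graphs are minimum spanning trees
(Kruskal, lexicographic tie-breaking) over pairwise Hamming distances
plus a germline root — simplified relatedness graphs, not
maximum-parsimony phylogenies.

### Reactivity

Polyreactivity threshold per antigen: mean of ≥ 2 positive controls
minus 2 sample standard deviations at 1 µg/ml; OD ≥ threshold is
positive; ≥ 2 of dsDNA/insulin/LPS ⇒ polyreactive. HEp-2: OD at
5 µg/ml divided by the same control quantity; strictly > 1 is positive;
non-positive normalizers raise. Autoantibody z-scores use healthy-
control mean and (n−1) standard deviation, ≥ 3 controls required,
z > 2 positive; zero control spread flags the row instead of dividing
by zero.

## Synthetic data generator: scope

`synthetic_data` grows clonal lineages as a branching process from a
bundled deterministic toy germline reference (12 V genes of gapped
length 312, 6 J genes; fixed internal seed — part of the reference, not
a knob). Each lineage member derives from a random earlier member with
Poisson(`mu` × 312) V-region substitutions at positions weighted by
`hotspot_bias` at WRCY/RGYW germline contexts, bounded junction
divergence, irreversible IgM→switched isotype changes, Zipf copy
numbers on a floor of `copy_min` (5), and Poisson error satellites at
Hamming distance exactly 1 with 1–4 copies. All emitted alignments are
unique by construction; when a drawn child would duplicate an existing
sequence, it is redrawn with one extra forced mutation.

What passing tests show: the analysis recovers the planted structure of
this generator — merges exactly the planted satellites, reconstructs
planted lineages (adjusted Rand index), recovers planted mutation rates
and hotspot enrichment, finds planted relatives and compartment
sharing, and reproduces hand-worked arithmetic. What they do not show:
performance on real repertoires with indels, allele variation,
primer/chimera artifacts, non-uniform sequencing depth, or germline
databases beyond the toy reference; nor any clinical claim.

A note on small mutation rates: the uniqueness guarantee inflates the
realized mutation load when Poisson(`mu` × 312) is frequently zero.
Rate-recovery tests therefore allow junction divergence (so uniqueness
is mostly absorbed by the junction) and use single-edge lineages, a
regime where the realized rate matches `mu` closely.

## Numerical and implementation choices

- Pure-Python Hamming loops for correction (N-tolerant semantics);
  numpy byte matrices for all-pairs junction distances within
  partitions.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; pipeline reruns with identical configs are byte-identical, and
  every JSON output embeds the full configuration as provenance.
- Diversity quantities are computed in double precision directly from
  copy frequencies; D50 uses a 1e−12 guard against floating-point
  boundary effects on cumulative sums.
- AIRR I/O is implemented over pandas honoring AIRR field names;
  missing `duplicate_count` defaults to 1, missing `c_call` to
  "unknown", and malformed rows raise with row numbers.

## Limitations

- Substitution-only model: indels shift the IMGT frame and are not
  handled; sequences must arrive pre-aligned (IMGT-gapped).
- Junction-length partitioning means length-variant members of a true
  clone are never joined.
- The threshold detector assumes a bimodal distance-to-nearest
  distribution; unimodal inputs take the fallback τ, which is a
  convention, not an inference.
- Consensus germlines use simple majority voting without weighting by
  copy number.
- The 5-mer mutability model is descriptive (normalized observed over
  background), not a full targeting model with per-position background
  correction.
- Reactivity calls inherit the small-sample behavior of two-control
  thresholds; with exactly 2 controls the standard deviation is highly
  variable.
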