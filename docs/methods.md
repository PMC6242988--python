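# Methods

## Scope and coordinate conventions

The package implements five analysis stages (SL census, protein-model
derivation, BTS classification, architecture detection, 5' extension)
plus the synthetic-data generator that defines the conditions under which
they are tested. Internally every coordinate is 0-based half-open;
emitted files use each format's native convention (GFF3 1-based
inclusive, FASTA wrapped at 60 columns, FASTQ Phred+33).

## Spliced-leader census

The euglenid SL is a 26-nt 5' addition whose assembled remnant is
frequently truncated from its 5' side; the 7-nt 3' suffix `TTTTTCG` is
the minimal detectable core. A contig is SL-positive when the core lies
*entirely* inside the first `window` (default 35) nt, or its reverse
complement lies entirely inside the last `window` nt for contigs
assembled in reverse complement. We deliberately read "within 35 bp" as
containment of the whole core rather than of its start; the window is a
parameter, so the alternative reading is one flag away. The default
("strict") mode pairs orientation with end; `--loose` additionally
accepts the two mirrored combinations, the most literal reading of
"either end". A contig matching at both ends is counted once, as
forward, and flagged ambiguous. When a core is found, the match is
extended leftward (or rightward, mirrored) to the longest contiguous SL
3'-suffix, which is reported as `matched_length`.

False positives are intrinsic to a 7-mer rule: on random uniform
sequence the expected rate is roughly `2 ends x 29 eligible starts x
4^-7 x 2 strands ≈ 0.35%`, which the acceptance script measures
directly.

## Protein models

All maximal stop-to-stop ORFs in the six frames are enumerated with the
standard genetic code; codons containing N translate to X and never act
as stops. A segment containing an in-frame ATG is trimmed to the first
one; otherwise it is reported 5'-open, which is essential for
5'-truncated contigs. The selection rule — there being no single
canonical criterion — is the longest ORF, with ties broken by (1) strand
consistency with the SL orientation when one was detected, (2) forward
strand, (3) smallest CDS start. CDS coordinates are always reported on
the forward strand and include the stop codon when present.

On noiseless, untruncated simulations this chain recovers the planted
CDS exactly for >99% of transcripts; the residual failures are chance
ORFs in other frames that happen to be longer than the planted one,
which is unavoidable under any longest-ORF rule.

## BTS classification

External signal-peptide/TMD/localisation predictors are replaced by
explicit, parameterised heuristics so the pipeline is self-contained and
reproducible; all thresholds live in one `BTSParams` object:

| parameter | default | meaning |
|---|---|---|
| window | 19 | Kyte–Doolittle sliding window (residues) |
| tmd_threshold | 1.6 | min windowed score inside a TMD |
| min_tmd_len | 15 | min TMD run length |
| merge_gap | 3 | sub-threshold gap merged between runs |
| signal_start_max | 15 | TMD1 (signal core) must start by here |
| tmd2_start_max | 100 | anchor search limit |
| spacing_mean ± spacing_tol | 60 ± 8 | anchor spacing rule |
| transit_min_charge / transit_min_st | +1 / 0.15 | transit composition |
| decision_prefix | 120 | only this prefix is ever examined |

The decision procedure: TMD1 within the first 15 residues (else none);
then a transit segment up to the next TMD (or 60 residues) that must be
net-positive, Ser/Thr-rich and hydrophilic on average (else none); then
Class I if a second TMD follows with spacing inside 60 ± 8, Class I
flagged `atypical_spacing` if outside (class none in `--strict` mode),
Class II if absent. Restricting the decision to the first 120 residues
makes the call invariant to C-terminal extensions. The spacing rule's
anchor point is configurable (`spacing_anchor`: protein N-terminus →
TMD2 start, the default, or TMD1 end → TMD2 start) because the original
empirical rule does not pin it down; the hydropathy-profile boundary of
a called TMD can sit a residue or two away from the physical segment
boundary, which the ±8 tolerance absorbs.

## Architecture detection

Tandem (polyprotein) detection is alignment-seeded periodicity: exact
amino-acid 6-mer self-matches vote for their offset; the modal offset
with ≥8 votes (and ≥ the minimal unit length of 50) is the candidate
period; the seeded region is partitioned into period-length windows and
adjacent windows must align globally (match +1, mismatch 0, linear gap
−1) at mean identity ≥0.8, identity being matches over alignment
columns. The repeat unit deliberately *includes* its trailing linker
(period = monomer + linker): linker delimitation in the literature is
done by homology inspection, not algorithmically. K-mers occurring more
than 50 times are skipped as low-complexity guards. The minimum
adjacent identity of 0.8 is a stand-in default: real polyprotein
monomer divergence is not quantified in the source material.

Fusion detection aligns each labelled reference locally to the query
(BLOSUM62, gap open 11 / extend 1, via Bio.Align.PairwiseAligner),
keeps hits with reference coverage ≥0.6 and identity ≥0.5, chains them
greedily in query order without overlap, and calls a fusion when two or
more distinct labels survive.

## 5' extension

Reads are indexed by 15-mers in both orientations. Per iteration, reads
whose implied placement sticks out left of the contig and overlaps its
prefix by ≥25 nt with ≤4% mismatches (ungapped — Illumina errors are
substitution-dominated) contribute overhang columns; a column becomes
consensus when coverage ≥2 and the plurality base reaches 70%,
extending leftward until the first failing column. Ties or thin
coverage halt the extension rather than guess. Stops: SL core inside
the first 35 nt (`sl_found`), no recruiting read (`no_overlap`), empty
consensus (`ambiguous_consensus`), or 50 iterations. Paired-end linking
information is intentionally not used; the algorithm is single-end
overlap only. The module contains no randomness, so results are exactly
reproducible.

## Synthetic data generator

Defaults are the study conditions: 48.5% SL-positive transcripts
(realised as an exact quota so census tests are non-flaky; a Bernoulli
mode exists for interval tests), SL retained-suffix length uniform on
[7, 26] (no empirical truncation distribution is available; this is a
parameter), 30% reverse-complement contigs, 20% of eligible contigs
5'-truncated by 10–200 nt, GC 0.5 i.i.d. background, ORFs of 100–600
residues, presequence class mix 20% / 7.5% / 72.5% (I/II/none), 60 ± 8
anchor spacing, 5% polyproteins of 2–4 units with a run-level conserved
decapeptide linker, 3% two-protein fusions drawn from a 12-protein
reference pool, and 80-bp paired reads at 20× with 0.5% substitution
errors.

Two generator choices deserve emphasis:

* **5' truncation is applied only to SL-negative transcripts by
  default.** SL presence marks a complete 5' end, so clipping SL+
  contigs would contradict the quantity the census measures (and would
  make the planted SL quota unobservable). A `truncate_sl_positive`
  flag restores clipping for recovery tests of core survival.
* **Reads are generated by fragmenting whole transcript copies**
  (fragment lengths ~ N(300, 30), floored at the read length) rather
  than by sampling independent fragment starts. Molecule termini are
  fragment termini, so 5'-terminal bases receive full coverage — the
  physically correct picture of random fragmentation, and the property
  that makes terminal-base consensus (and hence exact prefix recovery)
  possible at 20×. Per-transcript coverage is
  `copies x 2 x read_len / insert ≈ 20x`, within ±20% for transcripts
  longer than twice the insert.

5' UTRs are generated ATG-free so "trim to first ATG" identifies the
planted start unambiguously; codons are drawn uniformly among synonyms.
Determinism: one master stream (seeded by `seed`) makes run-level draws
(SL quota assignment, linker, reference pool); every transcript and its
reads use substreams keyed by the transcript index, so records are
order-independent.

What the generator does **not** emulate: expression-level variation,
indels, quality-score profiles, codon-usage bias, composition
heterogeneity, chimeric contigs, or sequence homology between unrelated
proteins. Passing recovery tests therefore demonstrates algorithmic
correctness under the stated noise model, not performance on real
assemblies, where domain repeats, low-complexity regions and paralogy
will add false positives the simulation cannot produce.

## Problem sizes

The shipped tests and the acceptance script run entirely on simulated
data: censuses at n = 1,000 transcripts, classifier recovery at 1,000
proteins, tandem recovery at 200 polyproteins plus 1,000 random
negatives, ORF-oracle comparison on 1,000 random sequences, extension
on single transcripts at 20–30×, and determinism at n = 50 with
extension capped at a handful of contigs. These sizes give stable
percentages while keeping a full run in the tens of seconds.

## Known limitations

* The SL scanner is a fixed-motif rule; it cannot separate a genuine
  trans-spliced leader from a chance terminal `TTTTTCG` (~0.35% of
  random contigs) and does not look for internal SL remnants.
* The BTS heuristics approximate, not reproduce, dedicated predictors;
  thresholds were chosen to express the published structural criteria,
  and on real proteins the hydropathy-only TMD caller will differ from
  HMM-based topology predictors, particularly at TMD boundaries.
* Tandem detection requires ≥8 exact 6-mer seed matches and so will
  miss highly diverged monomers; fusion detection is limited to the
  supplied reference library.
* Extension is single-end and ungapped; it stops rather than branch at
  genuine repeat boundaries, and cannot jump coverage gaps.
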