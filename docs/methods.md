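# Methods

This note documents the models and procedures implemented in `ubdesign`,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Library curation (`seq_data`)

Scaffold libraries are FASTA files whose description lines carry
`kd_nM=`, `target=` and `class=` tokens. Dimeric constructs are split
into two monomers at the leftmost occurrence, strictly after position 0,
of one of the N-terminal start motifs (MQI, MRI, MAS, MTI); occurrences
at position 0 mark the first monomer's own start, and any further
occurrences are ignored so a dimer yields exactly two monomers. The
concatenation of the outputs always equals the input.

Binder classes partition the positive $K_D$ axis: SB < 10 nM ≤ MB <
100 nM ≤ WB. The printed class table this convention derives from states
an impossible MB interval ("100 nM < K_D ≤ 10 nM"); the half-open
reading above is the only one consistent with the SB and WB definitions.
NB is reserved for "no binding detected" annotations and never produced
from a numeric $K_D$.

Deduplication at 99% identity is greedy and single-pass: a record is
dropped iff its identity to an already-kept record reaches the
threshold; first occurrence wins, order is preserved, and the operation
is idempotent. Because identity is alignment-based and quadratically
many alignments would be slow, pairs that provably cannot reach the
threshold are skipped using the bound
identity ≤ 1 − d/(len(a)+len(b)) for Levenshtein distance d (any
alignment with C columns, S substitutions and I gap columns has
C − S − I matches, S + I ≥ d, and C ≤ len(a)+len(b)).

## Sequence identity (`seq_filters`)

Identity is defined on the optimal global alignment under BLOSUM62 with
gap open −10 and gap extend −0.5: identical columns divided by **all**
columns, gap columns included in the denominator. This convention is
symmetric, equals 1 exactly for identical sequences, and penalises
length differences; the alternative (non-gap columns only) is not
exposed. Contiguous gaps longer than 50 columns raise an error rather
than silently producing a meaningless identity; the cap is checked on
the optimal alignment. Inside `filter_generated` such pairs are treated
as certain rejections, since they are far outside the identity window
either way.

The design windows — identity to the 76-residue ubiquitin wild type in
[0.75, 0.90] and length in [72, 84], both inclusive — are configurable;
the confidence filter discards a model if **any** residue has pLDDT
below 50 (the strictest reading of "regions below 50"; windowed variants
are out of scope).

## Generator (`vae`, `_nn`)

Architecture as in the README. Open details were resolved as follows:

* the 128-unit fully connected layer produces the representation from
  which two parallel linear heads emit the latent mean and log-variance;
  the latent dimension defaults to 128 and is configurable;
* the two decoder input layers are linear maps from $z$ to the initial
  hidden and cell states of the decoder LSTM;
* training uses teacher forcing; generation feeds back the sampled
  token. Temperatures at or below 10⁻⁶ switch to argmax decoding, and
  decoding stops at the first padding token;
* the KL weight is 1 (plain ELBO), with no annealing;
* the train/validation split is random, seeded, 90/10 by default;
  validation ELBO is evaluated at the latent mean (ε = 0), which makes
  early stopping deterministic; the best-validation weights are
  restored at the end;
* max_epochs defaults to 200 with patience-5 early stopping — the epoch
  count at which a given run stops is an outcome, not a parameter;
* forget-gate biases are initialised to 1.

The implementation is NumPy with hand-written backpropagation through
time; a finite-difference gradient test guards every parameter block.
Checkpoints are single zip archives (parameters + config + encoding spec
+ history) that reload bit-identically.

## Structure geometry (`struct_geom`)

Rigid superposition is the SVD-based Kabsch solution with the reflection
guard (determinant correction), returning a proper rotation, translation
and the minimal RMSD. Alignment-guided Cα-RMSD pairs residues at aligned
non-gap columns of the global sequence alignment (an `identical_only`
flag restricts to identical-residue columns), then superposes the paired
Cα atoms. Ligand-RMSD superposes the two receptor copies, applies that
transform to the second pose's ligand, and takes the **plain** RMSD
between ligand copies — no re-superposition, so it measures motion in
the receptor frame. Trajectory summaries apply the same operation per
frame; an atom-selection flag (Cα default, backbone N/CA/C/O available)
covers both conventions with one code path.

Coordinates are Å, residue indexing is 1-based author numbering,
alternate locations keep the first occurrence, HETATM records are
ignored, and multi-chain structures are concatenated in chain order for
superposition. Pose decks are directories of PDB files plus a TSV
manifest (pose_id, file, score).

## Pose triage (`pose_triage`)

Boundary conventions, chosen once and tested at the boundary: a
patch-patch Cα distance of exactly 10 Å is **kept**; a ligand-RMSD of
exactly 2 Å is **rejected** as not "greater than 2"; funnel candidates
exactly at the across-candidate mean energy survive. Greedy clustering
compares each new pose against **all** already-kept poses (leader
clustering), not just the last one — otherwise near-duplicates of early
poses re-enter. Score ties are broken by pose id. The docking-stage and
refinement-stage selections are the same mean-top-k operation with
k = 50 and k = 10.

## Energetics (`energetics`)

Per-frame $\Delta G_t = E_\text{complex} - E_\text{receptor} -
E_\text{ligand}$, with each component already containing its solvation
term; conformational entropy is excluded by construction. The reported
value is the frame mean with its standard error. Frame selection (e.g.
restricting to the last part of a trajectory) is the caller's
responsibility.

Hotspots use a strict inequality ($\Delta G_\text{res} < -2$ kcal/mol);
mutable positions use the inclusive complement (≥ −2) so the two sets
partition any interface. Banding candidates into NB/WB / MB / SB is
quantile-based (terciles by default) because no energy thresholds for
the computational banding are published; the observed 6/9/11 split of a
26-candidate cohort is reproducible only by configuring those fractions
explicitly, and the package makes no claim to predict it.

## Maturation (`maturation`)

Pool clustering is greedy centroid clustering in input order at 97.5%
identity (inclusive at the boundary), with the first member of each
cluster as its representative — a deterministic, dependency-free
stand-in for an external clusterer whose representative choice is
unspecified. Variants with indels are rejected by `diff_mutations`
rather than aligned: maturation operates on fixed-length scaffolds.
Consensus mutants combine the improving singles (ΔΔG < 0) ranked by
whole-variant ΔΔG — per-mutation energy attribution is not published,
so whole-single ranking is used — taking all position-compatible
combinations of order 2..3 from the top 6 improvers; the cap keeps the
combinatorics at campaign scale (without it, a few dozen improving
singles would generate thousands of consensus mutants). Manually curated
extra singles can be supplied alongside the derived ones.

## Fixtures (`fixtures`)

The fixtures plant known answers; they do not imitate binding physics.

* **Library**: 759 records with the study's per-target class marginals
  (HER2 72/59/16, FINC ED-B 36/32/18, others 127/208/191), 329 of them
  monomeric. Variants are the ubiquitin wild type with 5–20 random
  substitutions and occasional short loop insertions up to length 84;
  $K_D$ is log-uniform inside the class band (SB [0.1, 10), MB
  [10, 100), WB [100, 10000) nM), always consistent with the classifier.
  Monomers are resampled until no start motif occurs internally, so the
  planted dimer junctions are exactly where splitting cuts.
* **Pose decks**: two Cα helices; poses are random rigid perturbations
  of a reference ligand, scored −20/(1+L-RMSD-to-reference) plus
  optional noise, with each pose's whole frame additionally moved
  rigidly to exercise receptor superposition. Ground truth comes from a
  brute-force greedy oracle whose superposition goes through SciPy's
  rotation alignment — an independent route from the package's Kabsch.
* **Decompositions**: explicit pairwise energy matrices whose planted
  hotspot rows sum into [−8, −3] kcal/mol and all other rows into
  [−1.5, 0.5], so recovery is exact and the table equals the row sums.
* **Confidence tracks**: passing models stay in [70, 98]; failing
  models get a 5-residue region dipping below 50.
* **Energy frames**: per-frame ΔG drawn Normal(mean, σ) on top of large
  anticorrelated component energies.

What passing these tests shows: the *rules* of the funnel (thresholds,
boundaries, orderings, aggregations) are implemented exactly, and the
generator trains, memorises and samples deterministically. What they do
not show: that the funnel's energies or the generator's samples are
physically meaningful for real complexes — the fixtures carry no
physics, and real sequence libraries are not random mutants.

## Desk-scale problem sizes

Default configurations are sized so the whole funnel runs in minutes on
one CPU, as the package's standard desk-scale setting: the pipeline's
fixture library is 120 records (marginals scaled from the study's
759-record table), the VAE is 64 LSTM units / 16-dim latent trained up
to 120 epochs (patience 20) with generation at temperature 0.8, pose
decks are 40 poses per candidate, and energetics uses 200 frames per
candidate. Library-scale defaults (256 units, 128-dim latent, 164-long
encoding, patience 5) remain the `VAEConfig` defaults. The test suite
uses smaller variants of the same configurations. The desk-scale
generator is deliberately small: after ~120 epochs roughly a third to a
half of its samples fall inside the 75–90% identity window, enough to feed
the downstream stages; it does not reach the sample quality of the
library-scale model.

## Known limitations

* The VAE is CPU-bound NumPy; library-scale default training (256
  units, 200 epochs max) takes tens of minutes, not seconds.
* `max_gap` is verified on the optimal alignment rather than enforced
  inside the DP; a pair whose *optimal* alignment exceeds the cap
  errors out even if a suboptimal alignment within the cap exists.
* Funnel stage counts of the original study (112 → 101 → 39 → 26) are
  not reproduced quantitatively — they depend on a real generator,
  real structures and real docking scores; the published arithmetic
  around those counts is internally inconsistent and is not used as an
  oracle.
* Banding thresholds for NB/WB/MB/SB are configuration, not prediction.
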