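# ubdesign

Computational funnel for designing protein binders on the human ubiquitin
scaffold. The package covers the in-silico side of an affinity campaign
against a receptor target (e.g. HER3): curating a library of scaffold
variants with measured dissociation constants, generating de novo variant
sequences with a recurrent variational autoencoder, filtering the designs
by sequence identity, length and predicted-structure confidence, triaging
rigid-docking poses by interface contact and energy/diversity clustering,
post-processing end-state binding energies (MM-GB(PB)SA style), and
book-keeping an affinity-maturation round of single and consensus mutants.

It is a library first (the `ubdesign` package plus the narrative scripts
in `examples/`), with a thin `ubdesign` CLI for running stages on files.
Heavy external engines (structure prediction, docking, Monte-Carlo
refinement, molecular dynamics) are deliberately out of scope: their
outputs — coordinates, pose scores, energy frames, confidence tracks —
are the package's inputs, and seeded synthetic fixtures emulate all of
them so every stage is testable offline.

## The method

**Binder classes.** A variant with dissociation constant $K_D$ (nM) is a
strong binder (SB) if $K_D < 10$, medium (MB) if $10 \le K_D < 100$ and
weak (WB) if $K_D \ge 100$; NB marks "no binding detected" annotations.

**Generator.** Sequences are one-hot encoded over 164 positions × 21
symbols (20 amino acids + padding). The encoder is an LSTM (256 units)
whose final hidden state feeds a 128-unit fully connected layer and two
linear heads producing the mean and log-variance of a Gaussian latent
$z$. Two linear maps take $z$ to the initial hidden/cell states of the
decoder LSTM (256 units), which runs autoregressively with a 21-way
softmax per position. Training maximises the ELBO
$\mathcal{L} = \mathbb{E}_q[\log p(x\mid z)] - \mathrm{KL}(q(z\mid x)\,\|\,\mathcal{N}(0,I))$
with Adam (lr $10^{-3}$) and patience-5 early stopping; generation
decodes $z \sim \mathcal{N}(0,1)$ with temperature-controlled sampling.
The model is implemented in NumPy with hand-written backpropagation and
trains on CPU in minutes at library scale.

**Filters.** Pairwise identity is computed on the optimal global
alignment (BLOSUM62, gap open −10, extend −0.5, contiguous gaps capped at
50): identical columns / all columns, gaps included. Designs are kept if
identity to the ubiquitin wild type lies in [0.75, 0.90], length in
[72, 84], and no residue of the predicted model has pLDDT < 50.

**Pose triage.** A pose survives the interface filter if any Cα of the
receptor patch is within 10 Å of any Cα of the ligand patch. Surviving
poses are clustered greedily: visit poses by ascending binding energy and
keep one iff its ligand-RMSD (Cα-RMSD of the mobile partner after
superposing the receptors) to every kept pose exceeds 2 Å, until 50 poses
are kept. Candidates whose mean top-$k$ energy is above the
across-candidate average are discarded (k = 50 at the docking stage, 10
at refinement); the strongest candidate always survives.

**Energetics.** $\Delta G = \langle E_\text{complex} - E_\text{receptor}
- E_\text{ligand}\rangle$ over snapshots (entropy excluded);
$\Delta\Delta G = \Delta G_\text{variant} - \Delta G_\text{parent}$, with
negative values predicting improvement. A residue with summed pairwise
interaction energy $\Delta G_\text{res} < -2$ kcal/mol is a hotspot;
interface residues at or above −2 are the mutable positions for
maturation. Variant pools are clustered at 97.5% identity (greedy
centroid), centroids are diffed into single mutations, and the top
improving singles at distinct positions are combined into double/triple
consensus mutants.

## Worked example

```bash
python examples/04_pose_triage.py
```

prints

```
interface filter: 89/100 poses keep the two patches within 10 A
greedy clustering: 50 mutually diverse poses (pairwise L-RMSD > 2.0 A), best first
best pose: pose_000  score -20.00
mean top-50 binding energy: -3.28
funnel over three candidates: kept ['cand_A', 'cand_C'] ...
```

A 100-pose synthetic deck is built around a known reference pose; 89
poses keep the two predicted interface patches in contact, the greedy
rule selects 50 mutually diverse low-energy poses (the reference, scored
−20, ranks first), and the candidate whose mean energy is worse than the
across-candidate average is dropped. `examples/07_full_pipeline.py` runs
the whole funnel (curate → train → generate → filter → triage →
energetics → maturate) at desk scale and prints the per-stage survivor
counts; the same run is available as `ubdesign run --seed 17 --out
pipeline_out`.

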