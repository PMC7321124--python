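# Methods

## Problem and model

Self-docking benchmarks quantify how well a docking protocol (a search
algorithm paired with a scoring function) reproduces a ligand's
crystallographic pose. For each protein–ligand complex and each protocol in
a 14-entry registry, three statistics summarize a run of 20 generated
poses:

- **RMSDmin** (Å): the best pose's RMSD to the crystal pose,
- **RMSDave** (Å): the mean pose RMSD,
- **nRMSD**: the number of poses with RMSD *strictly below* the crystal
  structure's X-ray resolution.

`dockpick` learns to predict these three quantities for every protocol from
the structure of the binding pocket and the chemistry of the ligand, and
recommends a protocol per complex: the argmin of predicted RMSDmin/RMSDave,
the argmax of predicted nRMSD, ties broken toward the lowest registry
index.

### Featurization

The binding pocket is the set of protein heavy atoms within 15 Å of the
ligand's heavy-atom center of mass (mass-weighted; hydrogens excluded so
the center is insensitive to protonation). Atoms carry eight boolean
pharmacophore channels — hydrophobic, aromatic, H-bond acceptor, H-bond
donor, positive ionizable, negative ionizable, metallic, total excluded
volume — assigned from a bundled residue/atom-name rule table
(`data/channel_rules.json`, user-overridable). The excluded-volume channel
is true for every heavy atom.

The pocket is rendered onto a 24 Å cubic grid at 1 Å resolution (24³
voxels, 8 channels) centered on the ligand center. An atom at distance
`r` from a voxel center contributes the pair-correlation occupancy

    n(r) = 1 − exp(−(r_vdw / r)^12),

with van der Waals radii from a bundled Bondi-style element table. Per
voxel and channel the maximum over contributing atoms is taken, which
keeps every value in [0, 1] and makes the grid monotone under atom
addition. Distances are measured from voxel centers (voxel (i,j,k) center
at origin + (i+½, j+½, k+½)·resolution); atoms outside the box still
contribute to voxels within reach. The value at r = 0 is defined as the
limit, 1.

Ligands contribute a 1024-bit circular fingerprint of bond radius 2 and
183 two-dimensional physico-chemical descriptors (a fixed, deterministic
list). Descriptors are z-scored with statistics of the training fold only
(constant features map to zero); unbounded descriptor scales otherwise
destabilize the first linear layer. The ligand input is the concatenation,
length 1207.

### Architecture and losses

Two legs meet in a joint latent space:

- protein leg: five 3D convolutions with ReLU (default channels
  8→16→24→32→48, kernel 3, padding 1, strides 2,2,1,2,1), flattened and
  projected to a 512-dim latent;
- ligand leg: three linear layers with ReLU (1207→768→640→512).

The concatenated 1024-vector is batch normalized and read out by three
per-protocol linear heads with ReLU (each emits 14 values): RMSDmin and
RMSDave trained with mean squared error, nRMSD with the Poisson negative
log-likelihood

    ℓ(y, ŷ) = ŷ − y·log ŷ + log y!,

the natural loss for a count; log y! is evaluated via the log-gamma
function and the rate inside the logarithm is floored at ε = 1e-8 so a
ReLU-zero rate stays finite. The objective is the unweighted sum of the
three terms, each averaged over the non-missing (complex, protocol)
entries; missing labels contribute nothing. nRMSD is modeled as an
unbounded Poisson rate; predictions are clamped to [0, n_poses] only when
reported at selection time.

The network is implemented on a compact plain-numpy engine (`_nn.py`):
im2col convolutions, explicit backward passes, Adam. Two numerical choices
matter:

- the input gradient of a convolution is accumulated per kernel offset
  (k³ small matrix products into strided views) rather than via an
  explicit transposed convolution, and the first convolution skips its
  input gradient entirely;
- output-head biases are initialized to 1. The heads predict strictly
  positive quantities, and a zero-rate start would give the Poisson term
  a gradient of order −y/ε, poisoning the optimizer's second-moment
  estimates for the shared trunk.

Layer gradients are verified against central finite differences in the
test suite.

### Training schedule

Adam with β1 = 0.99, β2 = 0.999 (β1 = 0.99 follows the reference
configuration; 0.9 is the more common convention and is available through
configuration), initial learning rate 1e-3 with exponential decay
γ = 0.95 per epoch, batch size 32, 200 epochs by default. No early
stopping, weight decay or gradient clipping by default. Data augmentation
re-voxelizes each training pocket after a fresh rotation, drawn uniformly
over SO(3) via normalized quaternions, about the ligand center — one
rotation per sample per epoch; validation and inference always use
unrotated grids and batch-norm running statistics, so inference is
deterministic. One master seed fans out to independent streams for
initialization, shuffling and rotations.

### Cross-validation splits

Four 5-fold split constructors, all reproducible from (strategy, k, seed):

- **random** — uniform shuffle, fold sizes within one of each other;
- **ligand scaffold** — k-means (euclidean, seeded, k = fold count) on
  fingerprint bit vectors; cluster index = fold. Unequal fold sizes are
  inherent to scaffold splits;
- **protein classes** — whole protein families packed greedily (largest
  family first, into the currently lightest fold); no family ever spans
  folds;
- **protein classes balanced** — within each family, members are
  shuffled and dealt round-robin from a seeded starting fold, so each
  fold's validation set holds ≈ 1/k (exactly 1/k when divisible) of every
  family.

### Evaluation and significance

Metrics are RMSE and Pearson's R, reported as mean ± 1 standard deviation
over folds. The protocol-centric table carries one row per protocol plus
an Average row (aggregated across the per-protocol means). The
ligand-centric evaluation pools all (complex, protocol) pairs of a fold's
validation set into one vector pair; a per-complex-averaged alternative is
available behind a flag since both conventions appear in practice (pooled
is the default). Whether model-selected protocols beat each fixed protocol
is tested with a one-sided two-sample Mann–Whitney test ('less' for the
RMSD targets, 'greater' for nRMSD) at α = 0.01: exact by full enumeration
of the C(n+m, n) role assignments for combined samples of at most 12
(ties handled by half counts), normal approximation with tie and
continuity corrections above. No multiple-testing correction is applied by
default; Bonferroni is available as an option.

## Synthetic benchmark

The generator produces data with the statistical shape the pipeline
assumes, with no external downloads:

- **pockets**: atoms uniform in a 15 Å sphere; elements C/N/O/S/Zn with
  probabilities 0.60/0.15/0.15/0.05/0.05; one pharmacophore flag per atom
  from an element-conditional categorical; 60 atoms per pocket by default
  (enough structure for the convolutional leg while keeping desk-scale
  voxelization fast);
- **ligands**: Bernoulli(0.05) fingerprint bits and normal descriptors
  with log-normal per-dimension scales (so descriptor standardization is
  actually exercised);
- **labels**: a planted low-dimensional feature vector z concatenates
  standardized pocket channel fractions, sparse fingerprint factors (each
  reading a small random support of bits, mimicking substructure keys)
  and dense descriptor factors. Then per protocol p,
  `RMSDave = softplus(w_pᵀz + b_p + u_family) + noise` (clipped positive),
  `RMSDmin = c · RMSDave` with c ~ U(0.3, 1) per complex, and
  `nRMSD ~ Binomial(20, σ(−1.5·(RMSDave − resolution)))` with per-complex
  resolutions U(1.5, 2.5) Å. Protocol weights share a common prior with
  protocol-specific perturbations and intercepts, creating "easy" and
  "hard" protocols and the anticorrelation between RMSD and pose counts
  seen in real benchmarks.

`SyntheticConfig.signal_dominant()` (500 complexes, noise 0.15 Å,
stronger planted weights, 16-bit fingerprint factors, pocket weight 0.6)
defines the learnability benchmark: the default network trained 50 epochs
on 400 complexes of this benchmark reaches pooled held-out Pearson R
≥ 0.5 on RMSDave for every tested seed. The learnability benchmark runs
without rotation augmentation: augmentation targets rotational robustness
of real pockets, which is orthogonal to what the planted-signal check
establishes, and a fixed-grid run is exactly reproducible.

What the generator does *not* emulate: physically realistic pocket
geometry (no bonds, no secondary structure, no excluded-volume packing),
real chemical fingerprint correlation structure, docking-engine failure
modes, or label distributions of any specific benchmark. Passing tests on
synthetic data therefore demonstrate that the machinery — featurization,
optimization, splits, metrics, selection — works and can recover planted
signal at realistic sample sizes; they say nothing about accuracy on real
protein–ligand data, which requires real structures and docking runs.

## Problem sizes and runtime choices

Everything runs on one CPU. The default convolutional widths are sized so
that a 500-complex, 50-epoch training completes in minutes; all widths,
strides and latent sizes are configurable for larger studies. Voxelization
is exact in float64 (it matches a brute-force per-voxel/per-atom oracle to
1e-12) and offers a float32 fast path used by rotation augmentation, where
grids feed a float32 network anyway. The acceptance script trains a single
fold of the 5-fold random split of the 500-complex benchmark for 50
epochs and evaluates the held-out fold.

## Known limitations

- The numpy engine is single-threaded apart from BLAS; large-scale
  training (thousands of complexes, 200 epochs, augmentation on) is
  feasible but slow compared to a GPU tensor library.
- The channel rule table is an approximation of AutoDock-flavoured
  pharmacophore typing; it covers the 20 standard residues and common
  metals, and atoms it does not cover receive only the excluded-volume
  flag.
- k-means on raw fingerprint bits uses the euclidean metric; Tanimoto- or
  scaffold-key-based groupings are reasonable alternatives the scaffold
  split does not implement.
- The per-protocol heads assume a fixed registry; transferring a trained
  model to a different protocol set requires retraining the heads.
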