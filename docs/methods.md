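# Methods

## The delta-learning model

The package regresses high-level (TDDFT-type) first-singlet energies
E_high from low-level (ZINDO-type) electronic-structure data. The core
identity is a residual connection on the low-level energy:

    E_pred = ML(x) + E_low

so the network head only has to learn the low→high deviation
ΔE = E_high − E_low. Two consequences are load-bearing and tested: a
zero-weight head reproduces E_low exactly, and the minimum achievable
error is set by whatever part of ΔE the descriptors cannot resolve.

The closed-form reference is the ordinary least-squares calibration
E_high ≈ m·E_low + c (fitted with `scipy.stats.linregress`), which can
absorb the systematic bias but not molecule-specific deviations.

## Descriptors

**Atomic potentials.** φᵢ = Σ_{j≠i} Zⱼ/rᵢⱼ in e/Å over *all* atoms,
hydrogens included — the sum has no element filter. Coincident atoms
(r < 1e-6 Å) are a hard error naming the pair; a single atom yields the
empty sum.

**Orbital populations.** In an orthogonalised (INDO-type) basis the
Mulliken population of atom i reduces to pᵢ = Σ_{μ∈i} c_μ²/Σ c_μ². The
particle/hole densities apply this analysis to the dominant natural
transition orbital pair of the S0→S1 excitation; both sum to one. No
overlap matrix is accepted — this is a deliberate contract of the
orthogonalised-basis assumption.

**MO-RDF.** f(r_k) = Σ_{i>j} wᵢwⱼ·g(r_k − d_ij) with the unit-mass
Gaussian g of width σ = 0.05 Å, sampled on the inclusive grid 0.5–15 Å at
0.02 Å (726 points). Each unordered pair counts once and there are no
self terms, so step·Σ_k f(r_k) = Σ_{i>j} wᵢwⱼ whenever all pair distances
sit ≥ 5σ inside the grid — the mass-conservation identity used as a test.
Pipeline code normalises the HOMO weights to Σwᵢ = 1 before computing the
MO-RDF so that its magnitude is size-comparable across molecules and the
mass identity is exact; the low-level data may or may not arrive
normalised, and this choice removes that scale freedom. Negative weights
are accepted but flagged, since populations should be non-negative.

**Morgan fingerprints.** 2048 bits, radius 2. Circular-fingerprint radii
count bonds, not Ångström: a radius-2 fingerprint captures environments up
to 4 bonds across, which is how the conventional "2 Å radius" phrasing is
interpreted here.

**Graph features.** The default-atom (DA) scheme is 41 channels per atom:
element one-hot (15 symbols + other), degree one-hot (0–5 + other), formal
charge, radical electrons, hybridisation one-hot (SP…SP3D2 + other),
aromaticity, ring membership, total-H one-hot (0–4 + other), a
chirality-possible flag and a chiral-tag one-hot. DA+EA appends
(μᵢ, φᵢ, nᵢᵉˡᵉᶜ, nᵢʰᵒˡᵉ) in that order, z-scored per channel with
statistics frozen from the training portion of each fold — raw potentials
are tens of e/Å and would otherwise dwarf the one-hot channels. Requesting
EA features without electronic data is an error, never a silent zero-fill.
Bond features are 10 channels (type one-hot, conjugation, ring, stereo)
and identical for both directions of a bond.

## Architecture

The encoder is an attention-weighted message-passing network: a linear
node embedding, `atom_steps` rounds of neighbour attention (edge-wise
alignment scores → per-target softmax → gated-recurrent state update),
then `mol_steps` rounds of attention from a virtual molecule node over the
atom states, and a linear readout to a fixed-length neural fingerprint.
All aggregation is by segment sum/softmax, so embeddings are invariant to
atom numbering and to graph serialisation order (tested to 1e-5, the
float-reduction reordering level).

Enabled inputs — neural fingerprint, standardised E_ZINDO, MO-RDF, Morgan
bits — are concatenated into a final dense block (default 512/256/32
units, batch normalisation, 20% dropout, softplus activation) with a
scalar head. The raw E_ZINDO bypasses the network through the residual
connection; a z-scored copy also enters the concatenation, since the dense
stack benefits from a standardised input while the residual needs raw eV.
Stand-alone `MPNN(DA[, EA])` variants map the fingerprint straight to the
target with a linear head and no residual.

Encoder width/depth are not dictated by the method; the package defaults
are hidden 200, fingerprint 256, 2 atom and 2 molecule steps, all
configurable. The loss is mean squared error on E_pred (equivalently on
ΔE given the residual identity). The activation default is a smooth
rectifier (softplus); elu, leaky-relu and tanh are selectable.

All neural components run on a package-local reverse-mode autodiff engine
over numpy arrays (`zindelta.autodiff`), sized to exactly the op set the
layers need; its gradients are verified against central finite differences
in the test suite.

## Training protocol

K-fold cross-validation with k = 10 by default: each fold trains one model
with its own weight-initialisation seed (base_seed + fold) and its own
standardisation statistics computed from that fold's training portion only,
which keeps the validation fold out of every gradient step and every
normalisation constant. Optimiser: Adam at 1e-4, batch 32, up to 500
epochs with a triangular cyclical learning rate (period 20 epochs, bounds
[lr/10, lr]) and early stopping on validation MAE with patience 50. The
exact cyclical shape and stopping criterion are implementation choices —
the protocol only fixes that both mechanisms are on; MAE was chosen as the
stopping metric because it is the headline error measure. Prediction
averages the k fold models; each prediction record retains the per-fold
values and asserts that the ensemble value is exactly their mean.

## Synthetic data

The generator emulates the *statistical* structure of a low/high-level
dataset, not its physics. Molecules are assembled from aromatic rings over
C/N/O/S/F (benzene, pyridine, pyrimidine, furan, thiophene, pyrrole,
thiazole, naphthalene), optional biaryl links and 0–3 terminal
substituents; 3-D coordinates come from a seeded distance-geometry embed
(planar fallback), so generation is byte-reproducible. Low-level energies
are Uniform[1.5, 5.5] eV; targets follow

    E_high = 1.08·E_low + 0.52 + δ(molecule) + N(0, noise_sd)

with the default δ = 0.4 eV on molecules containing aromatic nitrogen and
noise_sd = 0.05 eV, which keeps the residual distribution predominantly in
[0, 1.5] eV. Deviation rules are registered by name (`none`,
`heteroaromatic`, `conjugation_length`, `ring_fusion`). Per-atom
electronic fields are random but structured: populations concentrate on
conjugated atoms, the particle density piles onto aromatic nitrogens when
present (the deviation trigger, so EA features are genuinely informative),
and potentials are computed exactly from the geometry. What passing tests
on this data show is that the pipeline can detect and regress a
structure-linked deviation on top of a linear calibration; they say
nothing about real ZINDO/TDDFT error surfaces, basis-set effects or
conformational sensitivity.

## The desk-scale benchmark

`zindelta.benchmark.run_delta_benchmark` fixes the study conditions:
2000 molecules (1500 train / 500 test), δ = 0.4·heteroaromatic, noise
0.05 eV, a 3-fold `Dense(MPNN(DA, EA), E_ZINDO)` ensemble trained up to
100 epochs. The desk-scale network configuration is hidden/fingerprint 64,
dense head 128/64/32, Adam at 1e-3 — a 100-epoch run needs a
proportionally larger step than the 500-epoch full-scale default. Three
numbers matter: the linear baseline's test MAE (≈0.2 eV, the absorbed
average of the bimodal deviation), the ensemble's test MAE, and the
Bayes-optimal floor noise_sd·√(2/π) ≈ 0.0399 eV attained by the oracle
m·E + c + δ. The acceptance contract is that the ensemble lands at least
40% below the linear MAE and within 50% of the floor.

## Curation

The conjugated core is reconstructed as: all aromatic atoms plus atoms of
conjugated bonds, iteratively pruned of sp3 terminal atoms, largest
connected component, canonicalised as the SMILES of the induced subgraph
(free valences hydrogen-capped via a reparse). This is one specific
reconstruction of the "network of π-conjugated bonding" idea and is
isolated behind `extract_conjugated_core`. Clusters whose core has fewer
than 6 heavy atoms are discarded (strict `<`, so a bare benzene core
survives). The nitroso filter matches a two-connected N double-bonded to a
terminal O with no second oxygen neighbour, so nitro, nitrate, nitrite
esters and N-oxides pass. The ring filter counts SSSR rings, keeps counts
{1, 2}, rejects molecules with any all-carbon non-aromatic ring (covering
fused alicyclic polycycles via the per-ring test), and removes ring-free
molecules. The parity split sorts ids numerically when possible and
alternates odd positions to train, even to test.

## Numerical and degenerate-input choices

- Energies are eV, coordinates Cartesian Å throughout; no unit conversion.
- The V2000 SDF coordinate block is fixed at four decimals, so the writer
  adds a `precise_coords` property with full double precision and the
  reader prefers it; schema floats round-trip to 1e-12.
- Missing oscillator strengths are allowed (stored as null) and flagged,
  never defaulted to zero; energy-only workflows proceed.
- Zero-variance channels get unit standard deviation before z-scoring.
- Pearson r on constant vectors is reported as undefined, not NaN-silent.
- Binned error reports mark empty bins as empty (not zero) and count
  out-of-range points in an overflow bucket.
- The emitter threshold f > 0.4 is strict: a molecule at exactly 0.4 is
  negative. The boundary convention is documented rather than assumed
  either way, and pinned by a test.
- Batch normalisation falls back to running statistics for batch size 1.

## Known limitations

- The electronic emulation is distributional; descriptor values are not
  physically consistent with any Hamiltonian.
- NTO analysis uses the dominant pair by default; singular-value-weighted
  averaging over several pairs is available on the population analysis but
  is not exercised by the training pipeline.
- Full-scale metrics on real ZINDO/TDDFT datasets require the released
  data and long training runs; nothing here reproduces them.
- The autodiff engine is single-threaded numpy; it is sized for
  desk-scale experiments, not for 10⁵-molecule production training.
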