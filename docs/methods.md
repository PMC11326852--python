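# Methods

This note records the scientific and numerical choices behind phaseformer:
what is modelled, under which conventions, which parameters matter, what
the synthetic data does and does not emulate, and where the design was
genuinely open.

## Crystallographic model

All structures live in orthorhombic P1 cells (angles fixed at 90°, no
symmetry beyond lattice translations). Structure factors are computed by
direct summation over atoms,

F(h,k,l) = Σ_j f_j(s) · occ_j · exp(−B_j s²/4) · exp(2πi(h x_j/a + k y_j/b + l z_j/c)),

with s = 1/d the scattering-vector magnitude and (x_j/a, …) fractional
coordinates. Two scattering models are available:

- **point** (default): f_j = the element's electron count, independent of
  angle. Point scatterers make analytic oracles exact (e.g. the density
  integral equals the electron count; two-atom amplitude patterns have
  closed forms), which is why they are the testing default.
- **gaussian**: 4-term Cromer–Mann form factors for H, C, N, O, S with the
  standard International-Tables coefficients; cross-checked against gemmi
  in the test suite. B-factors and hydrogen inclusion are explicit flags
  (`b_factor` per atom, `include_hydrogens` in the builder) rather than
  assumptions.

Reflection sets store a Friedel-unique half sphere plus F(0,0,0)
(unique half: l > 0, or l = 0 ∧ k > 0, or k = l = 0 ∧ h ≥ 0); the full
sphere is expanded on demand via F(−h,−k,−l) = conj F(h,k,l).

### Grids and Fourier conventions

Voxel (i, j, k) of an N₁×N₂×N₃ grid samples fractional position
(i/N₁, j/N₂, k/N₃), origin at index 0. `build_grid` uses a nominal voxel
spacing of d_min/oversampling per axis and rounds each dimension up to the
next even integer covering the cell (41×30×24 Å at d_min 1.5 Å and
oversampling 3.0 → 0.5 Å spacing and an 82×60×48 grid). Synthesis places
F(h,k,l) at frequency-grid index (h mod N₁, …) and applies `numpy.fft.fftn`
divided by the cell volume; the result is asserted real to 10⁻⁶ relative
and the imaginary part discarded. The Patterson map is computed either
from squared amplitudes with zero phases, or as the autocorrelation route
p = (1/V)·FFT(|V·IFFT(e)|²); for band-limited maps the two agree to
rounding (a route-equivalence property asserted package-wide). With
oversampling > 2 the resolution sphere is strictly inside the grid's
Nyquist index, so no Friedel pair ever aliases onto one frequency bin;
at oversampling exactly 2 a cell edge that is an integer multiple of
d_min would touch Nyquist, which is why the toy cell is 15.5 Å rather
than 16 Å (below).

### Map normalization

Maps are normalized by dividing by max |value|: the zero level — which is
physically meaningful for density — and the sign pattern are preserved,
all values land in [−1, 1], and the operation is idempotent. An all-zero
map passes through unchanged. (The plausible alternative, min–max
rescaling, destroys the zero level and breaks the sign symmetry the tanh
output head relies on.)

### Phase error

Predicted and true maps are forward-transformed to the d_min they were
built at; per reflection the wrapped absolute phase difference
Δφ ∈ [0°, 180°] is taken, F(0,0,0) excluded. The headline value is the
*unweighted* mean; an amplitude-weighted mean (truth amplitudes) is
reported alongside, since refinement-suite conventions differ and neither
choice is canonical here. Shells are equal-count bins ordered from low to
high resolution; per shell the report carries the mean error and the
fraction below 60°, the conventional threshold for a usefully phased
reflection. Because the dataset builder centers every structure at its
cell's center of mass, maps share a common origin and no origin search is
performed (deliberately not implemented).

## Dataset construction

Each fragment is turned into a training triple (p, e, {u_j}):

1. **Cell assignment.** Variable mode starts from the per-axis coordinate
   ranges and grows all three axes by 0.25 Å per iteration (max 100) until
   the minimum intermolecular contact — over all atom pairs between the
   central copy and its 26 periodic neighbours, intramolecular pairs
   excluded — reaches 2.75 Å; failure discards the fragment with reason
   `expansion_exhausted`. Fixed mode places the fragment in a given cell
   (default 41×30×24 Å, the 15-mer setting) and discards on clash
   (`clash`). Isotropic growth was chosen over per-axis growth to keep
   fragment-to-cell proportions; the step is half the coarsest voxel used.
2. **Reindexing**: axes permuted so a ≥ b ≥ c (stable sort on ties).
3. **Centering**: mass-weighted centroid (standard atomic masses; "center
   of mass" taken literally) moved to (a/2, b/2, c/2). This removes the
   translation ambiguity a Patterson map cannot resolve and is what makes
   direct Pearson/phase comparison meaningful.
4. **Maps**: structure factors to d_min, density and Patterson synthesized
   on the `build_grid` grid, everything normalized.
5. **Partial structures**: one standalone map per residue, computed from
   an idealized template of the residue type (the Chemical Component
   Dictionary conformations bundled with biotite, terminal atoms
   stripped), centered in the cell. Centered placement makes u_j
   *example-independent* — a pure statement of "what this residue type
   looks like" — and avoids leaking the answer's geometry; placement at
   the residue's true centroid is available behind
   `partial_placement="true"` for experiments.
6. **Binning**: examples grouped by exact grid dims; bins smaller than
   `min_batch` dropped (uniform tensor shapes within a batch).

Determinism: identical fragment + config give bit-identical examples.

## Synthetic fragments

Chains are grown residue-by-residue with idealized backbone internal
coordinates (C–N 1.33 Å, N–CA 1.46 Å, CA–C 1.52 Å; angles 116.2°, 121.7°,
110.4°; ω = 180°) and random φ/ψ — uniform by default, or helix-biased
(φ ~ N(−63°, 8°), ψ ~ N(−42°, 8°)) for compact clash-free long chains.
Side-chain and carbonyl atoms come from the residue template superimposed
on the placed N/CA/C triad. Whole chains are rejection-sampled until no
non-bonded pair (different residues, peptide link excluded) is closer than
1.8 Å. Seeds map to outputs as pure functions.

What this emulates: fragment-like molecules with realistic connectivity,
atom counts, element composition and excluded volume, in cells obeying
the same contact rules as the real recipe. What it does not: Ramachandran
statistics, rotamer diversity, sequence realism, experimental noise, or
solvent. Tests passing on these data therefore demonstrate the pipeline's
*mathematical* correctness and the model's *capacity*, not performance on
PDB-derived crystals.

## Model

Input maps pass through a two-convolution stem (3³ kernels, stride 1,
dims-preserving, leaky ReLU between) that expands 1 (or 2, under
recycling) channel to c = 8; the result is partitioned into d₁×d₂×d₃
patches, flattened, projected to token width d_t, and given a learned
positional embedding. Partial-structure maps go through a *separate* stem
and projection, and every u_j receives the *same* positional table — this
shared table is what makes the forward pass invariant to the order of the
partial structures. Their tokens are layer-normalized once and reused,
unchanged, at every layer.

Each of the L layers computes, per head (pre-norm residual placement):

- Q from Patterson tokens only; K and V from the concatenation of
  projected Patterson tokens and projected partial tokens
  (separate W_k′, W_v′ for the partial stream);
- A = softmax(QKᵀ/√d_h) over the S+S·J keys — the attention is one-way:
  partial tokens are keys/values, never queries, and are not updated;
- the usual output projection, then a ReLU feed-forward block.

The 1/√d_h scaling is included although elided in the reference
formulation, as are the norms and skips it acknowledges only "in
practice"; pre-norm placement was chosen for small-scale stability.

Decoding maps tokens back to a patch via a two-layer MLP
(d_t → c·d₁d₂d₃, leaky ReLU, → c·d₁d₂d₃), inverse-rearranges to a
c-channel volume, applies a two-convolution decoder to 1 channel, and
takes tanh — outputs live strictly in (−1, 1), matching the normalized
targets. The hidden layer in the decode MLP matters: a single linear map
confines all decoded patches to a d_t-dimensional subspace, which
measurably caps memorization capacity.

With J = 0 the network reduces exactly to a standard encoder-only 3D
vision transformer (asserted against an independent plain-attention
implementation).

Defaults (16³ grid, 4³ patches, c = 8, d_t = 64, 4 heads × 16, L = 2,
feed-forward 128, truncated-normal init, zero biases, seeded) are a
desk-scale configuration chosen for single-CPU tractability; they are not
claims about any reference setting, and every field is overridable.

### Numerical implementation

The network runs on a package-internal tape-based reverse-mode autodiff
engine over numpy arrays (primitives: arithmetic, matmul, reshape /
transpose / concat, ReLU / leaky ReLU / tanh / exp, reductions, softmax,
and an im2col-based 3D convolution). Every primitive's gradient, and the
full model's, is verified against central finite differences. Training
runs in float32 (≈0.5 s/step at toy scale on one CPU); the
crystallographic core and gradient checks use float64. Leaky ReLU (slope
0.1) in the stems and decoder exists because plain ReLU demonstrably
"dies" on these sparse, peaked maps — predictions collapse to a constant;
the transformer feed-forward keeps plain ReLU as part of the attention
block's stated form.

## Loss and training

loss = 0.9999 · MSE(g(θ,p), e) + 10⁻⁴ · (−PC(g(θ,p), e)),

with PC the Pearson correlation over voxels and ε = 10⁻⁸ inside each root
of its denominator (the denominator is the *product* of the two root
terms; the printed source formula garbles this with a "+", but only the
product form satisfies PC(e, e) = 1). At a perfect prediction the loss is
exactly −10⁻⁴. Optimization is Adam (β = 0.9/0.999), learning rate 10⁻³,
full-batch on the toy set; batches are always drawn within one grid-size
bin, round-robin across bins, shuffled by the run seed. Training is
bit-reproducible given a seed; a non-finite loss aborts with the last
stable parameters attached. At learning rate 10⁻³ the full-batch loss
descends monotonically on the toy set; larger rates trade monotonicity
for little speed and some instability.

**Recycling** retrains a *freshly initialized* model whose input is the
channel pair (Patterson, previous model's prediction for that example);
at evaluation the base model supplies the second channel for test inputs.
Channel order is fixed and round-trips through checkpoints.

**Evaluation** reports per-example PC and mean phase error, per-shell
mean errors, and per-shell fractions of examples below 60°.

## Toy study conditions

The canonical desk-scale setting (`phaseformer.presets`): 8 dipeptides
over a GLY/ALA/SER alphabet, uniform dihedrals, fixed 15.5 ų cells,
d_min 2.0 Å, oversampling 2.0 → exactly 16³ grids, J = 2 partials; the
default model; 500 full-batch Adam steps at 10⁻³. The 15.5 Å edge (not
16) keeps the resolution sphere strictly inside the grid's Nyquist index,
where Friedel mates would otherwise alias onto a single bin and phases
become irrecoverable from sampled maps. Under these conditions the model
overfits its 8 training examples to mean PC ≈ 0.97, demonstrating
capacity; problem sizes throughout (grids ≤ 32³, ≤ 100-fragment audits)
were picked so the whole suite runs on one CPU in minutes.

## Known limitations

- Orthorhombic P1 only; no other space groups, cell angles, anomalous
  scattering, bulk solvent, or experimental-intensity handling.
- No origin/phase-shift search: evaluation assumes builder-centered maps.
- Exact attention only (no low-rank approximations); single device.
- The generator's geometry realism is deliberately minimal (see above).
- Map interpretation/refinement (model building from predicted maps) is
  out of scope; predictions export as CCP4 maps for external tools.
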