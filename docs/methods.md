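# Methods

## The model

`ngnn` predicts a scalar physicochemical property of a solute dissolved in a
solvent (log-solubility, an absorption or emission wavelength, a quantum
yield, ...) from the solute's SMILES and a solvent identifier. The core idea
is to let information *grow* across scales instead of flattening everything
into one feature vector:

1. **Atoms.** Each heavy atom carries two incompatible raw blocks: six
   element-level physical constants in natural (numeric) coding — covalent
   radius (Å), Pauling electronegativity, atomic number, atomic mass (amu),
   first ionization energy (eV), electron affinity (eV) — and a 23-bit one-hot
   block describing the atom in its molecule: valence (0–6), hydrogen count
   (0–4), formal charge in the fixed order (−1, −2, 1, 2, 0), hybridization
   (s, sp, sp2, sp3), plus single in-ring and aromatic bits. Task-defined
   marking rules may append extra bits (the built-in `hydrophobic_halogen`
   rule flags F/Cl/Br/I). Because the two blocks live on different scales,
   each gets its own linear map before concatenation:
   `h_i = concat(σ(W1·h_inherent), σ(W2·h_env))`.

2. **Molecule.** Bond-driven message passing on the intact graph:
   `h_i ← Θ·h_i + (1/N_i)·Σ_{j∈N(i)} h_j ⊙ MLP(σ(W4·e_ij))`, where `e_ij` is
   the 7-bit bond block (bond-type one-hot, conjugated, aromatic, ring), `⊙`
   is the elementwise product (the edge MLP maps into the node width), and
   `N_i` is the degree of the *receiving* atom; isolated atoms receive no
   message. `k_intra` rounds, an independent `Θ` per round.

3. **Solution.** The solute graph is "dissolved" in two complementary ways:
   - *atom dissolution:* every atom is widened with the same solvent tail
     `σ(W3·h_solvent)`, where `h_solvent` is a 66-dimensional whole-molecule
     descriptor vector of the solvent (see below), then passed `k_inter`
     more rounds with the bond-derived gate;
   - *edge solvation:* each directed edge becomes
     `e_c = concat(σ(W4·e_ij), σ(W5·p))` with `p` the five empirical polarity
     scales Et(30), SP, SdP, SA, SB; the un-widened node states are passed
     `k_inter` rounds with a gate computed from `e_c` directly.

4. **Bulk.** Each branch is aggregated by a permutation-invariant readout
   (a set-to-set attention LSTM with `m` processing steps by default; plain
   sum pooling as an alternative), the two graph vectors are concatenated,
   and a small MLP head emits the property.

### Bias conventions

`W1..W5` and all `Θ` are bias-free linear maps — they are written as bare
matrix products and we keep them that way. The edge gates and the prediction
head are genuine MLPs (one hidden layer for the gates) and carry biases.
`W4` is shared between the intramolecular gate and the solvated edge
features; the three stages' gate MLPs and `Θ` banks are independent. The
update is implemented as right-multiplication (`h @ Θ`), which is the same
map up to the stored transpose.

## The solvent representation

The 66 descriptors are fixed in a versioned registry
(`data/solvent_descriptors_v1.tsv`) spanning four families: 13 E-state
(electrotopological state extrema and the E-state/surface-area hybrid bins),
34 van-der-Waals-surface-area contributions (SlogP_VSA, SMR_VSA, PEOE_VSA,
LabuteASA, TPSA), 7 topological (BalabanJ, BertzCT, HallKierAlpha, AvgIpc,
the three Kappa shape indices) and 12 connectivity (Chi0/Chi1 and the n/v
series). AvgIpc is used rather than raw Ipc because the latter grows
combinatorially with molecule size. They are whole-molecule descriptors:
one vector per solvent, computed once, cached, and broadcast to every solute
atom at dissolution — there is no physically meaningful pairing of solvent
atoms to solute atoms at this level of description.

Polarity parameters for the twelve stock solvents (toluene, THF, MeOH, MeCN,
hexane, water, EtOH, ethyl acetate, DMSO, DMF, CHCl3, CH2Cl2) are bundled
with citations: Et(30) in kcal/mol from Reichardt's compilation and the
Catalán SP/SdP/SA/SB scales (dimensionless). A solvent given as SMILES but
absent from the table gets computed descriptors; its polarity is an error
unless zero-filling is explicitly allowed, because silently invented polarity
values would corrupt the edge-solvation branch.

## Defaults and their rationale

| parameter | default | why |
|---|---|---|
| embedding widths | 64 each | comfortable capacity at desk scale; node state 128, widened 192 |
| `k_intra` / `k_inter` | 3 / 2 | 3 hops cover most small-molecule diameters; 2 further rounds mix solvent context |
| activation | LeakyReLU(0.01) | avoids dead units in narrow networks |
| readout | set2set, 3 steps | order-free attention aggregation; `sum` available |
| head | 128–64–1 | |
| loss / optimizer | MSE / Adam, lr 1e-3 | standard for regression at this scale |
| epochs / early stop | 300, patience 30 on validation MAE | |
| batch size | 64 | disjoint-union batching; evaluation is batch-size independent |
| initialization | Glorot-uniform weights, zero biases | fully determined by the run seed |

Targets are z-scored on the training split and restored at prediction time,
so metrics are always in original units. Early stopping monitors a 10%
validation carve-out of the training split — the test set is never touched
during fitting. The carve-out is skipped below 50 training samples, where
10% of the data cannot estimate validation error and would only add noise
(this also makes small-sample overfitting runs deterministic in length).
Splitting, initialization and batch shuffling draw from independent child
streams of the run seed.

No dropout or batch normalization by default: the core is kept minimal, and
regularisation choices are left to the caller.

## Numerical choices

Everything runs in float64 on a small tape-based reverse-mode engine written
for this package (`_autodiff.py`); the test suite validates every stage's
gradient against central finite differences to 1e-4 and every passing stage
against a dense O(n²) reference that loops over ordered atom pairs with an
explicit adjacency mask, to 1e-6 relative. Set2set attention softmax is
computed with a per-graph max shift; sigmoid uses the two-sided stable form.
Degenerate inputs: single-atom solutes have no edges — both passing branches
reduce to repeated `Θ` application and the edge-solvation tensor is empty;
zero-variance targets make R² undefined (reported as NaN), as does MRE when
any target is exactly zero. Multi-fragment SMILES are rejected because
message passing across disconnected components is undefined here.

Checkpoints are JSON: configuration, every tensor as nested lists, and the
target-scaling constants. Python's shortest-repr float serialization makes
the round trip bit-exact.

## The synthetic task family

The `fixtures` module emulates the *shape* of a solute/solvent property
dataset: small organic solutes from five structural families (alkanes,
alcohols, halides, aromatics, heteroaromatics) paired with registry solvents,
and targets that are exact closed-form functions of features the network can
see, plus optional Gaussian noise. The default solvent pool (water, hexane,
DMSO, toluene) spans the polarity scales. Solvents cycle fastest in the
pairing, so solute identity and solvent identity are independent by
construction and a solvent-blind model cannot recover solvent information
from the solute.

Rule constants are α = 10 per SdP unit, β = 5 per aromatic atom, γ = 3 per
halogen atom — frozen once, chosen so the solvent and solute terms have
comparable variance over the default pools. Under `solvent_linear` the best
possible solvent-blind predictor is `E[y | solute]`, giving the closed-form
ceiling `R²_max = 1 − (Var(α·SdP) + σ²) / (Var(y) + σ²)`; the learnability
test requires the full model to beat 0.9 while the ablation with `W3` and
`W5` frozen at zero stays below this ceiling.

What the toy tasks do *not* emulate: real photophysics or solvation
thermodynamics, conformational effects, measurement heteroscedasticity, and
dataset shift. Passing them demonstrates that the architecture can extract
and combine solute-graph and solvent-vector information as designed — not
that it attains any particular accuracy on experimental data.

## Problem sizes used in the standard checks

The bundled end-to-end checks run at desk scale, chosen as the smallest sizes
at which the qualitative claims are visible: overfit capacity on 32 noiseless
samples; learnability and the ablation gap on 2,000 samples at 5% noise with
the default configuration; the marking comparison on a halogen-dominated task
with 1,000 samples (600 in the acceptance script) using a reduced 32-wide
configuration over 3 seeded runs, since the directional marked-vs-unmarked
comparison does not need the full-width network.

## Known limitations

- Formal charges outside {−1, −2, 0, 1, 2}, valences above 6, more than four
  implicit hydrogens, and hybridizations beyond sp3 are rejected rather than
  clamped; the supported chemistry is neutral organics over 16 tabulated
  elements.
- Concentration effects are not represented: the polarity block describes
  the pure solvent only.
- The CPU implementation is intended for datasets up to the low tens of
  thousands of samples; there is no GPU path.
- `AvgIpc`, `BertzCT` and friends depend on the descriptor implementation
  version; the registry file pins the set, and `registry_version` is stored
  in checkpoints so a mismatch is detectable.
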