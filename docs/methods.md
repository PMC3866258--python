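# Methods

## Problem and model

Given a protein of length Np and an RNA of length Nr, every cell (i, j) of
the Np × Nr grid carries a binary variable r_ij indicating whether residue i
and base j are in contact (any-atom distance at or below a threshold,
typically 3 Å — hydrogen-bond range — or 5 Å). The grid is modeled as a
conditional random field: cells are vertices, the neighborhood of (i, j) is
N_ij = {(i±1, j), (i, j±1)}, and each cell's potential is

    U_ij(r, y) = w_f · f_ij(r_ij, y) + w_g · Σ_{(k,l) ∈ N_ij} g_ijkl(r_ij, r_kl, y),

with the two-state Gibbs conditional Pr(r_ij = v | r_N, y) ∝ exp(−U_ij[v]).
Unlike the image-segmentation random fields this construction descends from,
the pairwise term does not merely smooth: its weights are free, so the model
can learn attraction or repulsion between neighboring contacts (contact maps
are sparse and ridge-like, not blob-like).

Observations y are (a) the mutual information m_ij between alignment columns
i and j, counted over organism-paired homolog rows with the gap treated as
an ordinary symbol, optionally APC-corrected (MIp), and (b) the identities
(a_i, b_j) of the target residue and base. Feature families:

1. coevolution only: f = [r; r̄] ⊗ [1; m_ij] (dim 4), g = [r_ij; r̄_ij] ⊗
   [r_kl; r̄_kl] ⊗ [1; m_kl] (dim 8);
2. coevolution + labels: a one-hot δ(a, b) over (grouped residue, base)
   pairs is inserted before the [1; m] block (dims 2·G·4·2 and 4·G·4·2);
3. labels only: the [1; m] block is dropped (dims 2·G·4 and 4·G·4).

The edge features deliberately use the *neighbor's* observations
(m_kl, a_k, b_l); this asymmetry is part of the formulation and is preserved,
not symmetrized. δ excludes the gap symbol because target sequences are
degapped, so its length is exactly G·4 (80 for the full 20-letter alphabet).
Amino acids may be grouped with the Murphy reduced alphabets (2, 4, 8, 10,
15 groups); the same grouping is applied to MI counting and to labels.

## Alignments and MI

Both alignments must contain the target sequence; columns where the target
row carries a gap are deleted, making column indices target positions. Rows
are paired across the two alignments by organism (mnemonic token of
Pfam/Rfam-style identifiers, or `#=GS ... OS` annotations); organisms
present on one side only are dropped, duplicate rows pair first-occurrence,
and the two reference rows are always paired. Frequencies are raw counts
over paired rows divided by the number of pairs — no sequence weighting or
pseudocounts. MI uses the natural logarithm; downstream ranking and the CRF
are invariant to this scale choice. The rectangular APC form
m − (row sum)(column sum)/(grand total) equals the per-position-averaged
form identically (the averaging factors cancel), and makes the corrected
matrix sum to zero; a zero MI matrix is corrected to zero by convention.

## Training

Parameters θ = (w_f, w_g) maximize the log pseudo-likelihood — the sum over
cells of the log conditional of the observed label given its observed
neighbors — optionally penalized by C·(‖w_f‖₁ + ‖w_g‖₁). Each per-cell term
is concave in θ (the potential is linear in θ), so the objective has a
global optimum and initialization at θ = 0 is immaterial. Gradients are
analytic: per cell and state v, (Pr(v | neighbors) − 1[v = observed]) times
the feature vector at v, with ∂U/∂w_f = f_ij and ∂U/∂w_g = Σ_N g_ijkl.

The L1 term is handled by the exact split reformulation w = p − q with
p, q ≥ 0, solved with bound-constrained L-BFGS-B (scipy). This was chosen
over an orthant-wise (OWL-QN) implementation because it attains the same
global optimum of the concave problem, produces exact zeros at the bound
(so the lasso genuinely performs feature selection), and reuses a
maintained optimizer; when C exceeds the sup-norm of the gradient at zero
the subgradient condition holds immediately and the zero vector is returned
exactly. Convergence: projected-gradient tolerance 1e-5 (configurable) or
500 iterations. MI values enter raw — no feature standardization.

## Inference

The total energy Σ_ij U_ij decomposes exactly into unary terms (w_f · f_ij)
and one term per grid edge, since each edge {s, t} appears in the two local
potentials U_s and U_t: edge cost(v_s, v_t) = w_g·g_st(v_s, v_t, obs_t) +
w_g·g_ts(v_t, v_s, obs_s). MAP inference minimizes this energy with
sequential tree-reweighted message passing (TRW-S): raster-order sweeps with
edge weight γ = 1/max(#forward, #backward neighbors) (1/2 on interior
cells), message normalization, and a lower bound computed as the sum of
exact chain minima of the message-reparameterized energy over the
row/column monotonic-chain decomposition — valid by construction and
non-decreasing across sweeps. Labelings are decoded after every sweep by
cell-wise greedy decoding in both raster directions and by exact chain DP
over rows and columns (messages standing in for the undecoded side); the
best labeling by true energy is kept. When the bound meets the best energy
the result is certified optimal. If iteration ends uncertified, the cells
where the decode proposals disagree or where reweighted min-marginals are
near-tied — exactly where the underlying LP relaxation can go fractional —
are searched exhaustively (capped at 12 cells) conditioned on the rest.
TRW-S is exact for binary submodular energies; on frustrated grids the
certificate can fail, in which case the best decoded labeling is returned
with its bound. Ties in all argmins resolve to state 0, making inference
deterministic. A brute-force enumerator (≤ 20 cells, lexicographic
tie-break) serves as the test oracle.

Test-time contact probabilities are the local conditionals
Pr(r_ij = 1 | ·) evaluated against a conditioning grid. Which neighbor
configuration to condition on at test time is genuinely open; the default is
the TRW-S MAP grid, with all-zeros/all-ones exposed as alternatives (with
w_g = 0 the choice is irrelevant). This default is a package choice, exposed
as a flag, not asserted to be the only reasonable one.

## Structures

Contacts are extracted from PDB coordinates with the minimum pairwise
atom distance per (residue, base) pair. All recorded atoms are used;
crystallographic entries usually lack hydrogens, so this is in practice a
heavy-atom criterion — documented, not filtered. Only the first alternate
location is kept; modified residues are accepted when they map to a
standard one-letter code; a mismatch between the chain sequence and the
target sequence is a hard error rather than a silent renumbering.

## Evaluation

Leave-one-pair-out cross-validation: each complex is held out in turn, the
CRF is trained on the rest, every cell of the held-out grid is scored, and
the AUC is the rank-based Mann–Whitney statistic (ties get half credit —
ties occur whenever MI values repeat). The reported figure is the unweighted
mean of fold AUCs; folds whose held-out grid contains a single class are
skipped with a warning. A permutation null (labels shuffled within folds)
provides the reference band around 0.5.

## Synthetic data

The generator emulates the coevolution premise without phylogeny: contacts
are planted i.i.d. Bernoulli(density); residues are uniform over the 20
amino acids; at a contacted RNA column each homolog row copies the group
image (group index mod 4) of one uniformly chosen contacting residue column
with probability `coupling`, else draws uniformly. Choosing the partner per
row (rather than a fixed partner per column) ensures every planted contact
carries signal even when several residues contact the same base, which at
the default density is common. The coupled joint has closed-form MI used to
calibrate tests. Defaults — 40×60 grids, 300 paired rows, density 0.05,
coupling 0.9, Murphy-4 grouping — are the benchmark conditions used by the
test suite and the acceptance script; 13 instances mirror a realistic
curated dataset size. Optional `gap_rate` plants gaps in non-reference rows
to exercise the gap symbol.

What the generator does *not* emulate: phylogenetic correlation between
rows (real alignments are not i.i.d., inflating apparent MI), indels in the
target, alignment errors, non-uniform residue composition, and geometric
structure in the contact map (real interfaces are contiguous patches, not
i.i.d. cells). Passing the synthetic benchmark therefore demonstrates that
the estimation and inference machinery recovers planted dependence, not
that real interface AUCs of any particular magnitude are attainable.

## Numerical choices and limitations

- Conditionals are computed in log space (logaddexp / logistic); grid and
  MI serialization round-trips through TSV at 10 significant digits.
- Gradient correctness is held to max relative error < 1e-5 against central
  finite differences (h = 1e-6), with the scale-protected denominator
  max(1, |analytic|, |numeric|).
- Energy decomposition and per-cell conditional agreement are held to 1e-10;
  APC sum-to-zero to 1e-9.
- The pseudo-likelihood conditions each cell only on its own potential
  U_ij, matching the model's definition of the conditional; the variant
  that also differentiates neighboring potentials containing r_ij is a
  different estimator and is intentionally not implemented.
- Pseudo-likelihood is a surrogate, not the full likelihood; no partition
  function over the grid is ever computed, and no claim of full-likelihood
  consistency is made at small sample sizes.
- Problem sizes in the test suite (grids up to 4×5 for gradient checks,
  3×3/4×4 for exhaustive MAP comparison, 40×60 for the CV benchmark) were
  chosen so every oracle is exact and the whole suite runs in minutes on a
  single core.
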