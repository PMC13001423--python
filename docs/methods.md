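# Methods

## Geometric annotation

A complex is parsed with gemmi; one ligand is selected (waters, a
configurable ion/buffer/glycan blocklist, and polymer residues are never
candidates; `auto` selection requires a unique candidate). Alternate
conformations keep the highest-occupancy atom, ties broken by altloc
identifier. Multi-chain proteins are concatenated in chain order into one
residue sequence (1-based positions); the position ↔ structure-residue map
is retained. Ligand "units" are heavy atoms (hydrogens are dropped from the
ligand), indexed 1..m in file order; this is a configurable choice — an
atom-token view of a SMILES string is aligned to the same indices when a
line notation is supplied.

The binding pocket is every residue with any atom within a cutoff
(default 10 Å) of any ligand heavy atom. Detection restricted to the pocket
is lossless whenever the pocket radius is at least the largest distance
cutoff, which the defaults guarantee; a property test asserts this.

Detection rules per type (all configurable in `RuleConfig`, serialized to
JSON with every run; the values below are this package's defaults chosen
from common interaction-profiler practice, not authoritative constants):

| type | geometry | window (Å) | angular filter |
|---|---|---|---|
| hydrogen bond | ligand N/O vs protein N/O atom | 2.5 – 3.5 | D–H···A ≥ 120° when explicit hydrogens exist on either partner; distance-only fallback otherwise |
| salt bridge | ligand N (cationic) / O (anionic) vs opposite charged side-chain group centroid (ARG/LYS/HIS vs ASP/GLU) | 3.0 – 5.5 | none |
| hydrophobic | carbon vs carbon | 3.3 – 4.0 | none |
| van der Waals | any heavy-atom pair | Σ vdW radii ± 0.5 | none |
| π-π stacking | ring centroid vs aromatic residue ring centroid | 3.5 – 5.5 | interplanar angle ≤ 30° (parallel) or 60–90° (T-shaped) |
| cation-π | charged group vs ring centroid (both directions) | 3.5 – 6.0 | none |

HIS counts as cationic by default (`his_is_cationic=False` turns it off).
Ligand rings are perceived from heavy-atom distances (bond if < 1.8 Å for
C/N/O pairs, < 2.1 Å with S/P/halogens) and the graph cycle basis, sizes 5–6.
Ring- and centroid-based contacts need a single ligand index: the group
member nearest the protein partner is used, ties to the lower index.
Multiple geometric realizations of one (i, j, type) keep the minimum
distance.

**vdW as fallback.** The hydrogen-bond window is nested inside the O/N vdW
window and the hydrophobic window overlaps the C–C vdW window, so any polar
or hydrophobic contact would otherwise also appear as a vdW contact at the
same residue–atom cell. By default a cell explained by a more specific type
is therefore excluded from the vdW map (`vdw_fallback_only`); raw,
unfiltered vdW detection remains available per detector and via config.
This keeps the six maps disjoint in their physical interpretation and makes
planted-contact round trips exact.

Distances inside a window map to strengths through the piecewise-linear
decay: 1 at or below `d_min`, the floor 10⁻⁶ exactly at `d_cut`, linear in
between, 0 beyond. Zero always means "no contact"; every recorded strength
lies in [10⁻⁶, 1]. The overall map is the element-wise maximum of the six
type maps (a sum-then-clip aggregation is available behind config; max
preserves both the range invariant and a strongest-force reading). Residue
labels are the column-wise any-nonzero projection of the overall map.

Affinity stratification (kcal/mol): ≤ −7 positive, ≥ −5 negative, the
moderate band excluded to reduce label ambiguity.

## Model

Hidden size h (default 64) is split across H = 8 heads (h_t = h/8) by
slicing six h×h projection matrices per modality — the standard multi-head
convention. Heads 1–6 are assigned to the six interaction types, heads 7–8
to overall binding. Per head, bidirectional cross-attention and
self-attention are combined as `P*(t) = ½(P_sa(t) + Â_pd(t) V_d(t))` (and
symmetrically for the ligand); head outputs are concatenated and projected
to d (default 64, the fused-token width — unconstrained, kept equal to h).
The classifier mean-pools both token sequences, concatenates
`F = [D̄*, P̄*]` and applies a 2-hidden-layer ReLU MLP (64, 32) with a
sigmoid output.

Losses use natural logarithms. The classification loss is binary
cross-entropy with 10⁻¹² clamps. The attention-alignment loss normalizes
the ground-truth map and the predicted attention globally over all (i, j)
cells to discrete distributions and evaluates the KL divergence weighted
per cell by log(1 + A_raw); zero-truth cells contribute exactly zero.
Because row-softmax attention is directional while the truth map is not,
the loss is computed on Â_dp and on the transpose of Â_pd and averaged —
a symmetric choice that avoids favoring either sequence. Both overall heads
are supervised by the overall map by default (`supervise_overall=False`
restricts supervision to the typed heads). A head whose truth map is
all-zero is skipped (with a warning outside the training loop, where sparse
corpora make this routine); a pair with no annotation at all contributes
only the classification loss. The joint objective is the convex combination
with λ = 0.3 by default.

Residue scores for site localization are the per-column maximum of the mean
of the two overall heads' ligand→protein attention; typed score maps are
the typed heads' Â_dp. All rankings break ties toward the lower index, so
results are deterministic.

Training uses Adam (lr 3·10⁻³), per-sample updates, 30 epochs by default,
all randomness from one integer seed (initialization and shuffling); two
runs with the same seed are bit-identical. Encoders are frozen by
construction: embeddings enter the graph as constants and hold no trainable
parameters. The built-in `hash` encoder maps (token, position) through a
seeded CRC into unit-variance Gaussian rows — a deterministic stand-in
exposing the same interface a pretrained language-model encoder would plug
into via `register_encoder`.

The whole model runs on a small reverse-mode autodiff engine over numpy
arrays written for this package (matmul, elementwise ops, softmax
primitives, reductions, concat/slice); gradients are validated against
central finite differences at 10⁻⁵ relative tolerance in the test suite.

## Evaluation

BRHR@K asks whether any Top-K residue is a true binding residue; IHR@K
whether any Top-K residue–atom cell is a true contact of the given type;
both are 0/1 per pair and averaged, with empty-truth pairs excluded. The
expected IHR@K of a uniform ranker has the closed form
1 − C(mn − n_true, K)/C(mn, K) (n_true/(mn) at K = 1), which the seeded
Monte-Carlo simulation reproduces within sampling error. Binary metrics
(accuracy and F1 at 0.5, AUROC, AUPRC) come from scikit-learn and require
both classes.

Ligand similarity is Tanimoto over radius-2, 2048-bit Morgan (ECFP)
fingerprints (RDKit). Protein similarity is global Needleman–Wunsch
identity (biopython PairwiseAligner; match 1, mismatch 0, gap −1; identity
= matches / alignment length × 100). Similarity-controlled splits use
single-linkage clusters at the threshold (connected components of the
similarity > threshold graph) assigned whole to train or test, so no
cross-split pair can exceed the threshold; a full pairwise audit records
the realized peak and mean and is re-checked after every build. A threshold
that fuses everything into one cluster is reported as infeasible with the
blocking cluster. In-distribution evaluation uses stratified random K-fold.

## Synthetic data

`make_complex` places residues as pseudo-backbones (N, CA, C plus whatever
side chain the planted type needs: ASP carboxylate, PHE ring) on a 12 Å
lattice — beyond every cutoff — and puts each planted ligand atom (or
six-membered ring) on the side-chain axis at exactly the requested
distance. Safe planting windows per type are slightly narrower than the
detection windows so that no secondary atom pairing crosses a cutoff; the
generator validates specs against them, verifies the closed loop through
the annotator, and refuses geometry that would produce extra or missing
contacts. Fixture ligands are labeled pseudo-atoms, not chemically valid
molecules — sufficient for testing detection geometry, not for chemistry.

`make_dataset` builds embedding-level corpora (default 100 pairs, half
positive, 48 residues × 8 ligand atoms, 1–3 contacts per positive pair,
h = 64): each planted contact adds one shared unit latent direction to the
two involved token embeddings plus isotropic Gaussian noise (σ = 0.1), on
top of unit-norm random base rows. Latent directions are drawn from an
8-dimensional corpus-level subspace: a bilinear attention head of dimension
h_t = h/H = 8 can only resolve rank-8 structure, so this is the minimal
statistical regularity under which contact recovery is learnable at all —
the generator emulates the assumption that physically meaningful features
occupy a low-dimensional subspace of a pretrained encoder's representation.
What passing tests therefore show is that the supervision mechanism works
when the encoders carry contact-relevant signal; they do not show that any
particular pretrained encoder does, nor do the toy fixtures capture
conformational variability, correlated noise, or annotation errors of real
structures.

The parameter-recovery experiment trains on 80 pairs and holds out 20,
comparing λ = 0.3 against λ = 0 under identical seeds. Supervised training
reaches held-out BRHR@1 near 1.0 versus a uniform-random baseline around
0.04 and a label-only run around 0.2–0.3 — the designed demonstration that
attention supervision, not classification pressure, is what localizes
binding residues. Problem sizes here (and the 50-complex fidelity suite,
10⁵-trial simulations, 200-item split pools) were chosen so the entire
suite completes in about a minute of desk-scale CPU while keeping every
statistical check well-powered.

## Known limitations

- Detection thresholds are defaults of this package, configurable but not
  validated against curated interaction databases.
- No halogen bonds, water bridges, or metal coordination; no hydrogen
  placement or protonation-state inference; no symmetry-mate expansion.
- The SELFIES view of ligands is accepted as input text but not validated
  or round-tripped; atom tokens come from RDKit's reading of SMILES.
- The trainer is per-sample (no batching) and CPU-bound by design; it is
  built for corpora of hundreds of pairs, not full-scale databases.
- Reference full-scale benchmark numbers in `ncibind.benchmarks` are fixed
  published inputs for gap arithmetic; nothing here retrains at that scale.
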