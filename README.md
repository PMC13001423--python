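# ncibind

Rule-based annotation of non-covalent protein–ligand interactions and
interaction-supervised cross-attention binding prediction — from sequence,
with the physics made explicit.

## The problem

Sequence-based protein–ligand binding predictors have become accurate
classifiers, but they are black boxes: they say *whether* a pair binds, not
*which residues* anchor the ligand or *which non-covalent forces* —
hydrogen bonds, salt bridges, van der Waals contacts, hydrophobic contacts,
π-π stacking, cation-π interactions — mediate recognition. `ncibind`
implements the full loop that closes this gap:

1. **Annotation.** Given a complex structure (PDB/mmCIF), detect the six
   interaction classes with geometric rules (type-specific distance windows,
   optional angular filters) and convert each contact distance *d* to a
   strength by a piecewise-linear decay

   ```
   A_raw(d) = 1                     d ≤ d_min
            = lerp(1 → 1e-6)        d_min < d ≤ d_cut
            = 0                     d > d_cut
   ```

   yielding one m×n strength map per interaction type (m ligand heavy
   atoms × n protein residues), an overall map (element-wise maximum), and
   residue-level binding-site labels (column-wise projection). Binding
   labels come from affinity stratification: ≤ −7 kcal/mol positive,
   ≥ −5 kcal/mol negative, moderate affinities excluded.

2. **Model.** Frozen token encoders give embeddings P ∈ R^{n×h},
   D ∈ R^{m×h}. An 8-head interaction module (six typed heads + two
   overall heads) computes bidirectional cross-attention
   `Â_pd = softmax(Q_p K_d^T / √h_t)` and self-attention per head, fuses
   them (`P* = ½(P_sa + Â_pd V_d)`), mean-pools and classifies with an MLP.
   Training minimizes

   ```
   L = (1 − λ)·BCE(p, y) + λ·L_att,        λ = 0.3
   L_att = mean over supervised heads of Σ_ij log(1 + A_raw,ij) · Ã_ij · log(Ã_ij / Â~_ij)
   ```

   a weighted KL divergence that aligns each head's attention (renormalized
   over residue–atom pairs) with the ground-truth map of its interaction
   type. Pairs without annotations fall back to BCE alone.

3. **Evaluation.** Binding Residue Hit Rate (BRHR@K: does a Top-K residue
   hit a true binding residue?), Interaction Hit Rate (IHR@K: does a Top-K
   residue–atom cell hit a true contact of that type?), standard binary
   metrics, and similarity-controlled splits (ligands: Tanimoto over ECFP;
   proteins: Needleman–Wunsch global identity) with a full pairwise
   leakage audit.

4. **Synthetic fixtures.** Toy complexes with contacts planted at exact
   distances, and embedding-level corpora in which interacting tokens share
   latent directions — so every stage, including attention supervision, is
   testable end to end without any downloads.

## Worked example

Plant three contacts in a toy complex, annotate the emitted structure, and
score the annotation against the planted truth:

```bash
cat > spec.json <<'EOF'
{"n": 6, "m": 9, "contacts": [
  {"itype": "hbond",       "i": 1, "j": 2, "distance": 3.0},
  {"itype": "salt_bridge", "i": 2, "j": 4, "distance": 4.5},
  {"itype": "pipi",        "i": 3, "j": 6, "distance": 4.4}
]}
EOF
ncibind synth --spec spec.json --seed 3 --out fixture
ncibind annotate --structure fixture/complex.pdb --ligand LIG --out annotated.tsv
ncibind evaluate --pred fixture/maps.tsv --truth annotated.tsv --out report.json
```

which prints

```
synthetic artifacts written to fixture
annotated complex: m=9 n=6 contacts=3
{"brhr": {"1": 1, "3": 1, "5": 1}, "ihr1": {"hbond": 1, "salt_bridge": 1, "pipi": 1}}
```

and `annotated.tsv` holds the long-format maps:

```
type	ligand_index	residue_position	strength
hbond	1	2	0.5000005
salt_bridge	2	4	0.4000006
pipi	3	6	0.550226314
...
```

The hydrogen bond planted at 3.0 Å sits exactly halfway through its
[2.5, 3.5] Å window, so its strength is (1 + 10⁻⁶)/2 ≈ 0.5; the π-π
strength differs from the in-memory value 0.5500004 only through the
3-decimal coordinate rounding of the PDB format. All three Top-K hit rates
are 1 because truth was fed back as the prediction. `ncibind train` /
`ncibind predict` drive the attention model the same way (see
`ncibind --help`).

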