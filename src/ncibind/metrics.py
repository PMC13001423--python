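"""Evaluation machinery: binary metrics, hit rates, similarity and splits.

Binding-residue hit rate (BRHR@K) asks whether any of the Top-K ranked
protein residues is a true binding residue; interaction hit rate (IHR@K)
asks whether any of the Top-K ranked residue-atom cells of a per-type score
map is a true contact of that type. Both break score ties toward the lower
index, are computed per pair, and are averaged over a dataset.

Similarity-controlled splits cluster items by single linkage at the chosen
similarity threshold (ligands: Tanimoto over ECFP; proteins: global
Needleman-Wunsch identity) and assign whole clusters to train or test, so
no train-test pair can exceed the threshold on the controlled axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    roc_auc_score,
)

__all__ = [
    "top_k_indices", "brhr_at_k", "dataset_brhr", "ihr_at_k", "dataset_ihr",
    "expected_random_ihr", "simulate_random_ihr", "binary_metrics",
    "ligand_similarity", "protein_similarity",
    "pairwise_ligand_similarity", "pairwise_protein_similarity",
    "SplitSpec", "build_split", "audit_split", "stratified_kfold",
]


# ---------------------------------------------------------------------------
# rankings and hit rates

def top_k_indices(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K largest scores, ties broken toward the lower index."""
    if k < 1:
        raise ValueError("K must be >= 1")
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    return order[:k]


def brhr_at_k(residue_scores: np.ndarray, true_residues: Iterable[int], k: int) -> int:
    """1 iff a Top-K ranked residue (1-based positions) is a true binding residue."""
    truth = set(int(t) for t in true_residues)
    if not truth:
        raise ValueError("empty true-residue set")
    top = top_k_indices(residue_scores, k) + 1
    return int(bool(truth.intersection(top.tolist())))


def dataset_brhr(pairs: Sequence[tuple[np.ndarray, Iterable[int]]], k: int) -> float:
    """Mean BRHR@K over (scores, true residues) pairs; empty-truth pairs are
    excluded with a warning."""
    hits, used = 0, 0
    for scores, truth in pairs:
        truth = set(truth)
        if not truth:
            warnings.warn("pair with empty true-residue set excluded from BRHR")
            continue
        hits += brhr_at_k(scores, truth, k)
        used += 1
    if used == 0:
        raise ValueError("no pairs with a non-empty true-residue set")
    return hits / used


def ihr_at_k(score_map: np.ndarray, true_cells: Iterable[tuple[int, int]], k: int) -> int:
    """1 iff a Top-K ranked residue-atom cell is a true contact.

    ``score_map`` is (m, n); ``true_cells`` holds 1-based (ligand, residue)
    index pairs. Cells are ranked by score with ties toward the lower flat
    (row-major) index.
    """
    truth = {(int(i), int(j)) for i, j in true_cells}
    if not truth:
        raise ValueError("no true contacts of this type")
    m, n = score_map.shape
    flat_top = top_k_indices(score_map.ravel(), k)
    top_cells = {(int(f // n) + 1, int(f % n) + 1) for f in flat_top}
    return int(bool(truth & top_cells))


def dataset_ihr(entries: Sequence[tuple[np.ndarray, Iterable[tuple[int, int]]]], k: int) -> float:
    """Mean IHR@K over (score map, true contacts) entries; entries without
    true contacts are excluded."""
    hits, used = 0, 0
    for score_map, truth in entries:
        truth = set(truth)
        if not truth:
            continue
        hits += ihr_at_k(score_map, truth, k)
        used += 1
    if used == 0:
        raise ValueError("no entries with true contacts")
    return hits / used


def expected_random_ihr(m: int, n: int, n_true: int, k: int = 1) -> float:
    """Closed-form expected IHR@K of a uniformly random ranker:
    1 - C(mn - n_true, k) / C(mn, k); for K=1 this is n_true / (m n)."""
    cells = m * n
    if not 0 <= n_true <= cells or k < 1:
        raise ValueError("invalid parameters")
    if k >= cells - n_true + 1:
        return 1.0
    return 1.0 - comb(cells - n_true, k) / comb(cells, k)


def simulate_random_ihr(
    m: int,
    n: int,
    true_cells: Iterable[tuple[int, int]],
    trials: int,
    k: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Monte-Carlo IHR@K of a uniform random ranker over m x n cells."""
    rng = rng or np.random.default_rng()
    truth_flat = np.array(sorted((i - 1) * n + (j - 1) for i, j in set(true_cells)))
    cells = m * n
    if k == 1:
        draws = rng.integers(0, cells, size=trials)
        return float(np.isin(draws, truth_flat).mean())
    hits = 0
    for _ in range(trials):
        picks = rng.choice(cells, size=k, replace=False)
        hits += bool(np.isin(picks, truth_flat).any())
    return hits / trials


# ---------------------------------------------------------------------------
# binary classification metrics

def binary_metrics(p: Sequence[float], y: Sequence[int]) -> dict[str, float]:
    """Accuracy and F1 at threshold 0.5 plus AUROC and AUPRC."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUROC/AUPRC undefined for single-class labels")
    pred = (p >= 0.5).astype(int)
    return {
        "acc": float(accuracy_score(y, pred)),
        "auroc": float(roc_auc_score(y, p)),
        "auprc": float(average_precision_score(y, p)),
        "f1": float(f1_score(y, pred)),
    }


# ---------------------------------------------------------------------------
# similarity

def _morgan_fp(smiles: str, radius: int, n_bits: int):
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return gen.GetFingerprint(mol)


def tanimoto(bits_a: Iterable[int], bits_b: Iterable[int]) -> float:
    """Jaccard similarity |A & B| / |A | B| of two explicit bit sets."""
    a, b = set(bits_a), set(bits_b)
    if not a and not b:
        raise ValueError("both bit sets are empty")
    return len(a & b) / len(a | b)


def ligand_similarity(a: str, b: str, radius: int = 2, n_bits: int = 2048) -> float:
    """Tanimoto similarity of extended-connectivity fingerprints (ECFP)."""
    from rdkit import DataStructs

    return float(DataStructs.TanimotoSimilarity(
        _morgan_fp(a, radius, n_bits), _morgan_fp(b, radius, n_bits)))


def protein_similarity(
    a: str, b: str,
    match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0,
) -> float:
    """Global (Needleman-Wunsch) percent identity between two sequences.

    Identity = matched positions / alignment length x 100, on the optimal
    global alignment under (match, mismatch, gap) scoring.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for c1, c2 in zip(s1, s2) if c1 == c2 and c1 != "-")
    return 100.0 * matches / len(s1)


def pairwise_ligand_similarity(smiles: Sequence[str], **kw) -> np.ndarray:
    return _pairwise(smiles, lambda a, b: ligand_similarity(a, b, **kw))


def pairwise_protein_similarity(seqs: Sequence[str], **kw) -> np.ndarray:
    return _pairwise(seqs, lambda a, b: protein_similarity(a, b, **kw))


def _pairwise(items: Sequence, fn: Callable) -> np.ndarray:
    n = len(items)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            S[i, j] = S[j, i] = fn(items[i], items[j]) if i != j else _self_sim(fn, items[i])
    return S


def _self_sim(fn: Callable, item) -> float:
    return fn(item, item)


# ---------------------------------------------------------------------------
# similarity-controlled splits

@dataclass
class SplitSpec:
    """A similarity-controlled train/test split over pairs.

    ``axis`` names the controlled side (protein or ligand); the realized
    train-test similarity statistics are filled in by :func:`audit_split`.
    """

    axis: str
    threshold: float
    statistic: str  # "peak" or "mean"
    train_pairs: list[int]
    test_pairs: list[int]
    item_of_pair: list[int]  # controlled-axis item index per pair
    realized: dict = field(default_factory=dict)


def build_split(
    n_pairs: int,
    item_of_pair: Sequence[int],
    similarity: np.ndarray,
    axis: str,
    threshold: float,
    test_fraction: float = 0.2,
    statistic: str = "peak",
    seed: int = 0,
) -> SplitSpec:
    """Cluster-then-assign split controlled on one axis.

    Items whose pairwise similarity exceeds ``threshold`` are merged by
    single linkage (connected components of the thresholded graph); whole
    clusters are assigned to test (shuffled, until the test fraction is
    reached) and the rest to train, so no train-test item pair exceeds the
    threshold. Raises if a single cluster blocks any nonempty split.
    """
    similarity = np.asarray(similarity, dtype=float)
    n_items = similarity.shape[0]
    item_of_pair = list(item_of_pair)
    if max(item_of_pair) >= n_items:
        raise ValueError("pair references an unknown item")
    adj = csr_matrix(np.triu(similarity > threshold, k=1))
    n_comp, comp = connected_components(adj, directed=False)
    if n_comp < 2:
        members = np.flatnonzero(comp == 0).tolist()
        raise ValueError(
            f"threshold {threshold} infeasible: one cluster links all items "
            f"(blocking cluster: {members})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_comp)
    comp_sizes = np.bincount(comp, minlength=n_comp)
    target = test_fraction * n_items
    test_comps: set[int] = set()
    picked = 0
    for c in order:
        if picked >= target:
            break
        if picked + comp_sizes[c] <= n_items - 1:  # keep train nonempty
            test_comps.add(int(c))
            picked += comp_sizes[c]
    if not test_comps:
        test_comps.add(int(order[0]))
    test_items = {i for i in range(n_items) if comp[i] in test_comps}
    train_pairs = [k for k, it in enumerate(item_of_pair) if it not in test_items]
    test_pairs = [k for k, it in enumerate(item_of_pair) if it in test_items]
    if not train_pairs or not test_pairs:
        raise ValueError("split produced an empty side; adjust test_fraction or threshold")
    spec = SplitSpec(axis, threshold, statistic, train_pairs, test_pairs, item_of_pair)
    audit_split(spec, similarity)
    return spec


def audit_split(spec: SplitSpec, similarity: np.ndarray) -> dict:
    """Full pairwise audit of realized train-test similarity on the
    controlled axis; records peak and mean and checks the threshold."""
    train_items = sorted({spec.item_of_pair[k] for k in spec.train_pairs})
    test_items = sorted({spec.item_of_pair[k] for k in spec.test_pairs})
    cross = np.asarray(similarity)[np.ix_(train_items, test_items)]
    realized = {
        "peak": float(cross.max()),
        "mean": float(cross.mean()),
        "n_train_items": len(train_items),
        "n_test_items": len(test_items),
        "within_threshold": bool(cross.max() <= spec.threshold),
    }
    spec.realized = realized
    return realized


def stratified_kfold(labels: Sequence[int], n_folds: int = 5, seed: int = 0):
    """Stratified random K-fold assignments for in-distribution evaluation."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    X = np.zeros((len(labels), 1))
    return [(train.tolist(), test.tolist()) for train, test in skf.split(X, labels)]
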