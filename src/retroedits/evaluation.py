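"""Retrosynthesis evaluation metrics.

Top-k exact match compares canonical reactant SMILES (stereo retained,
maps stripped, fragments individually canonicalized and joined sorted, so
atom and fragment order never matter).  MaxFrag accuracy restricts the
comparison to the largest fragment by heavy-atom count, tolerating
reagent ambiguity in noisy data.  Diversity is the mean pairwise Tanimoto
similarity over concatenated per-fragment ECFP4 fingerprints of the
top-ranked predictions.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .mol_graph import ChemistryError, canonical_reactant_smiles

_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _canonical(smiles: str, keep_stereo: bool = True) -> Optional[str]:
    try:
        return canonical_reactant_smiles(smiles, keep_stereo=keep_stereo)
    except ChemistryError:
        return None


def topk_exact_match(
    predictions: Sequence[Sequence[str]],
    ground_truth: Sequence[str],
    ks: Sequence[int] = (1, 3, 5, 10),
) -> dict[int, float]:
    """Exact-match accuracy at each k.

    ``predictions[p]`` is the ranked reactant-SMILES list for product p. A
    product scores a hit at k if any of its first k predictions equals the
    ground truth after canonicalization.
    """
    if len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground truth differ in length")
    hits = {k: 0 for k in ks}
    for preds, truth in zip(predictions, ground_truth):
        want = _canonical(truth)
        got = [_canonical(p) for p in preds]
        for k in ks:
            if want is not None and want in [g for g in got[:k] if g is not None]:
                hits[k] += 1
    n = max(len(ground_truth), 1)
    return {k: hits[k] / n for k in ks}


def largest_fragment(smiles: str) -> str:
    """Largest fragment by heavy atoms; ties by canonical SMILES order."""
    frags = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise ChemistryError(f"unparseable fragment {part!r}")
        for a in mol.GetAtoms():
            a.SetAtomMapNum(0)
        frags.append((mol.GetNumHeavyAtoms(), Chem.MolToSmiles(mol)))
    frags.sort(key=lambda t: (-t[0], t[1]))
    return frags[0][1]


def maxfrag_accuracy(
    predictions: Sequence[Sequence[str]],
    ground_truth: Sequence[str],
    ks: Sequence[int] = (1, 3, 5, 10),
) -> dict[int, float]:
    """Exact match of only the largest reactant fragment, per k."""
    if len(predictions) != len(ground_truth):
        raise ValueError("predictions and ground truth differ in length")
    hits = {k: 0 for k in ks}
    for preds, truth in zip(predictions, ground_truth):
        try:
            want = largest_fragment(truth)
        except ChemistryError:
            continue
        got = []
        for p in preds:
            try:
                got.append(largest_fragment(p))
            except ChemistryError:
                got.append(None)
        for k in ks:
            if want in [g for g in got[:k] if g is not None]:
                hits[k] += 1
    n = max(len(ground_truth), 1)
    return {k: hits[k] / n for k in ks}


# --------------------------------------------------------------------------
# Diversity
# --------------------------------------------------------------------------


def _concat_fingerprint(smiles: str) -> np.ndarray:
    """Per-fragment ECFP4 bit arrays concatenated in sorted-fragment order."""
    frags = []
    for part in smiles.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise ChemistryError(f"unparseable fragment {part!r}")
        for a in mol.GetAtoms():
            a.SetAtomMapNum(0)
        frags.append((Chem.MolToSmiles(mol), mol))
    frags.sort(key=lambda t: t[0])
    bits = [
        np.frombuffer(
            bytes(_MORGAN.GetFingerprint(m).ToBitString(), "ascii"), dtype=np.uint8
        )
        - ord("0")
        for _, m in frags
    ]
    return np.concatenate(bits).astype(bool)


def _tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) != len(b):
        width = max(len(a), len(b))
        a = np.pad(a, (0, width - len(a)))
        b = np.pad(b, (0, width - len(b)))
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def mean_prediction_similarity(predictions: Sequence[str]) -> float:
    """Mean pairwise Tanimoto similarity among one product's predictions."""
    if len(predictions) < 2:
        raise ValueError("need at least two predictions")
    fps = [_concat_fingerprint(p) for p in predictions]
    sims = [
        _tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    ]
    return float(np.mean(sims))


def prediction_diversity(
    predictions_per_product: Sequence[Sequence[str]],
    n_clusters: int = 10,
    seed: int = 0,
) -> dict:
    """Per-product mean similarity plus a k-means cluster summary.

    Products with fewer than two predictions are skipped with a warning.
    Lower similarity means more diverse predictions.  Clustering is over
    the per-product scalar similarity (k-means, ``n_clusters`` groups),
    reporting each cluster's mean similarity and share of products.
    """
    sims = []
    for preds in predictions_per_product:
        if len(preds) < 2:
            warnings.warn("skipping product with fewer than two predictions")
            continue
        sims.append(mean_prediction_similarity(preds))
    result = {"per_product_similarity": sims, "mean_similarity": float(np.mean(sims)) if sims else float("nan")}
    if len(sims) >= n_clusters:
        from sklearn.cluster import KMeans

        arr = np.asarray(sims).reshape(-1, 1)
        km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10).fit(arr)
        clusters = []
        for label in range(n_clusters):
            members = arr[km.labels_ == label, 0]
            clusters.append(
                {
                    "mean_similarity": float(members.mean()),
                    "fraction": float(len(members) / len(sims)),
                }
            )
        clusters.sort(key=lambda c: c["mean_similarity"])
        result["clusters"] = clusters
    return result
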