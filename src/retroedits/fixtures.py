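"""Seedable synthetic atom-mapped reactions with known edit sequences.

Each template encodes a retro-transformation as a concrete edit sequence
applied to an assembled product scaffold; the resulting fragments become
the reactants, so every record is exactly replayable by construction.
Templates span all edit variants and sequence lengths 1-7:

======================  ========================================  ======
template                edits                                     length
======================  ========================================  ======
phthalimide_deprotect   ChangeAtom + two-dummy AttachLG              2
boc_deprotect           ChangeAtom + AttachLG                        2
coupling                DeleteBond + AttachLG + AttachLG             3
ester_reduction         ChangeBond + AttachLG                        2
multicenter             2 DeleteBond + 3 ChangeBond + 2 AttachLG     7
mitsunobu               DeleteBond + chiral ChangeAtom + AttachLG    3
epimerization           chiral ChangeAtom                            1
hydrogenation           ChangeBond                                   1
======================  ========================================  ======

The generator cross-validates itself against the extractor: a record is
only emitted if :func:`extract_edit_sequence` reproduces the template's
intended edit-kind sequence, and the stored ground-truth labels are the
extractor's (deterministic) output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .edits import (
    AttachLG,
    ChangeAtom,
    ChangeBond,
    DeleteBond,
    Edit,
    EditApplicationError,
    Terminate,
    apply_sequence,
)
from .extraction import extract_edit_sequence
from .mol_graph import (
    ChemistryError,
    MolecularGraph,
    ReactionRecord,
    canonicalize_and_remap,
    normalized_chiral_code,
)

# the leaving groups fixtures draw from; spans single-bond, double-bond
# and multi-attachment (two-dummy) cases
LEAVING_GROUPS = [
    "*Br",
    "*Cl",
    "*I",
    "*O",
    "*=O",
    "*N",
    "*OC",
    "*OCC",
    "*N(C)C",
    "*C(=O)O",
    "*C(=O)OC(C)(C)C",
    "*C(=O)c1ccccc1C(*)=O",
]

_ALKYL = ["C", "CC", "CCC", "C(C)C", "CCCC"]
_ARYL = ["c1ccccc1", "c1ccc(C)cc1", "c1ccc(OC)cc1"]
_CORES = _ALKYL + _ARYL

_COUPLING_LG_A = ["*N(C)C", "*OC", "*N", "*OCC"]
_COUPLING_LG_B = ["*Br", "*Cl", "*I"]


def _flip(code: int) -> int:
    return 3 - code if code in (1, 2) else 1


def _t_phthalimide(rng) -> tuple[str, Callable]:
    # primary amines always deprotect from phthalimide; the retro-route is
    # decided by structure near the edit site (visible to a shallow
    # message-passing encoder), so a product never has conflicting labels
    r = rng.choice(_CORES)
    smi = f"[NH2:901]C{r}"
    def edits(tags):
        a = tags[901]
        return [
            ChangeAtom(a, 0, 0),
            AttachLG(a, "*C(=O)c1ccccc1C(*)=O"),
            Terminate(),
        ]
    return smi, edits


def _t_boc(rng) -> tuple[str, Callable]:
    # N-methyl secondary amine scaffold: disjoint from the primary-amine
    # deprotection family
    r = rng.choice(_CORES)
    smi = f"C[NH:901]C{r}"
    def edits(tags):
        a = tags[901]
        return [
            ChangeAtom(a, 0, 0),
            AttachLG(a, "*C(=O)OC(C)(C)C"),
            Terminate(),
        ]
    return smi, edits


_HALIDE_BY_CHAIN = {"C": "*Br", "CC": "*Cl", "CCC": "*I", "CCCC": "*I", "C(C)C": "*Br"}


def _t_coupling(rng) -> tuple[str, Callable]:
    # aryl on one end keeps the family disjoint from plain alkanes; the
    # amine side is fixed and the halide is keyed on the alkyl chain's
    # shape within three bonds of the edit site, so the label is a
    # function of structure the encoder can actually see
    r1, r2 = rng.choice(_ARYL), rng.choice(_ALKYL)
    lga = "*N(C)C"
    lgb = _HALIDE_BY_CHAIN[r2]
    smi = f"[CH2:901]({r1})[CH2:902]{r2}"
    def edits(tags):
        i, j = tags[901], tags[902]
        return [
            DeleteBond(i, j),
            AttachLG(i, lga),
            AttachLG(j, lgb),
            Terminate(),
        ]
    return smi, edits


def _t_ester_reduction(rng) -> tuple[str, Callable]:
    r = rng.choice(_CORES)
    ester = "*OCC" if r.startswith("c") else "*OC"  # aryl vs alkyl: local
    smi = f"{r}[CH2:901][OH:902]"
    if r.startswith("c"):
        smi = f"[CH2:901]({r})[OH:902]"
    def edits(tags):
        return [
            ChangeBond(tags[901], tags[902], 2, 0),
            AttachLG(tags[901], ester),
            Terminate(),
        ]
    return smi, edits


def _t_multicenter(rng) -> tuple[str, Callable]:
    # 1,2,5-substituted pyrrole ring opening to a 2-halo carbonyl compound
    # plus a ketimine: two ring bonds deleted, three changed, two groups
    # attached -- mirrors a multi-center retro ring formation
    r = rng.choice(_ALKYL)
    smi = f"[cH:905]1[cH:904][c:903](C)[n:902](C)[c:901]1{r}"
    def edits(tags):
        return [
            DeleteBond(tags[901], tags[902]),
            DeleteBond(tags[904], tags[905]),
            ChangeBond(tags[901], tags[905], 1, 0),
            ChangeBond(tags[903], tags[904], 1, 0),
            ChangeBond(tags[902], tags[903], 2, 0),
            AttachLG(tags[905], "*=O"),
            AttachLG(tags[901], "*Br"),
            Terminate(),
        ]
    return smi, edits


def _t_mitsunobu(rng) -> tuple[str, Callable]:
    r1 = rng.choice(["C", "CC"])
    r2 = rng.choice(["CCC", "C(C)C"])
    ether = rng.choice(["C", "CC"])
    chirality = rng.choice(["@", "@@"])
    smi = f"{r1}[C{chirality}H:901]({r2})[O:902]{ether}"
    def edits(tags, graph=None):
        return None  # replaced below; site-dependent payload
    return smi, ("mitsunobu", 901, 902)


def _t_epimerization(rng) -> tuple[str, Callable]:
    r = rng.choice(["CC", "CCC", "C(C)C", "c1ccccc1"])
    chirality = rng.choice(["@", "@@"])
    smi = f"C[C{chirality}H:901]({r})O"
    return smi, ("epimerize", 901)


def _t_hydrogenation(rng) -> tuple[str, Callable]:
    # terminal ethyl on an alkyl chain: an alkane product determines the
    # retro double-bond site up to molecular symmetry
    r = rng.choice(_ALKYL)
    smi = f"{r}[CH2:901][CH3:902]"
    def edits(tags):
        return [ChangeBond(tags[901], tags[902], 2, 0), Terminate()]
    return smi, edits


TEMPLATES: dict[str, Callable] = {
    "phthalimide_deprotect": _t_phthalimide,
    "boc_deprotect": _t_boc,
    "coupling": _t_coupling,
    "ester_reduction": _t_ester_reduction,
    "multicenter": _t_multicenter,
    "mitsunobu": _t_mitsunobu,
    "epimerization": _t_epimerization,
    "hydrogenation": _t_hydrogenation,
}

# default mix: lengths 2-3 dominate, long multi-center and stereo
# transformations are the (realistic) minority
DEFAULT_TEMPLATE_WEIGHTS = {
    "phthalimide_deprotect": 0.13,
    "boc_deprotect": 0.10,
    "coupling": 0.30,
    "ester_reduction": 0.15,
    "multicenter": 0.05,
    "mitsunobu": 0.06,
    "epimerization": 0.06,
    "hydrogenation": 0.15,
}

_TEMPLATE_CLASS = {name: k + 1 for k, name in enumerate(TEMPLATES)}

# intended edit-kind sequences, for generator/extractor cross-validation
TEMPLATE_KINDS = {
    "phthalimide_deprotect": ["ChangeAtom", "AttachLG", "Terminate"],
    "boc_deprotect": ["ChangeAtom", "AttachLG", "Terminate"],
    "coupling": ["DeleteBond", "AttachLG", "AttachLG", "Terminate"],
    "ester_reduction": ["ChangeBond", "AttachLG", "Terminate"],
    "multicenter": [
        "DeleteBond", "DeleteBond", "ChangeBond", "ChangeBond", "ChangeBond",
        "AttachLG", "AttachLG", "Terminate",
    ],
    "mitsunobu": ["DeleteBond", "ChangeAtom", "AttachLG", "Terminate"],
    "epimerization": ["ChangeAtom", "Terminate"],
    "hydrogenation": ["ChangeBond", "Terminate"],
}


def _materialize(smi: str) -> tuple[MolecularGraph, dict[int, int]]:
    """Parse a tagged product SMILES; renumber maps 1..n, return tag->map."""
    mol = Chem.MolFromSmiles(smi)
    if mol is None:
        raise ChemistryError(f"template produced invalid SMILES {smi!r}")
    tags: dict[int, int] = {}
    next_map = 1
    for atom in mol.GetAtoms():
        tag = atom.GetAtomMapNum()
        atom.SetAtomMapNum(next_map)
        if tag >= 900:
            tags[tag] = next_map
        next_map += 1
    return MolecularGraph.from_mol(mol), tags


def _build_edits(spec, graph: MolecularGraph, tags: dict[int, int]) -> list[Edit]:
    if callable(spec):
        return spec(tags)
    if spec[0] == "epimerize":
        a = tags[spec[1]]
        atom = graph.mol.GetAtomWithIdx(graph.atom_index_by_map(a))
        code = normalized_chiral_code(atom)
        return [ChangeAtom(a, atom.GetTotalNumHs(), _flip(code)), Terminate()]
    if spec[0] == "mitsunobu":
        c, o = tags[spec[1]], tags[spec[2]]
        atom = graph.mol.GetAtomWithIdx(graph.atom_index_by_map(c))
        code = normalized_chiral_code(atom)
        return [
            DeleteBond(c, o),
            ChangeAtom(c, atom.GetTotalNumHs(), _flip(code)),
            AttachLG(c, "*O"),
            Terminate(),
        ]
    raise ValueError(f"unknown template spec {spec!r}")


def generate_reactions(
    n: int,
    seed: int = 0,
    template_weights: Optional[dict[str, float]] = None,
) -> list[ReactionRecord]:
    """Generate ``n`` atom-mapped reaction records with known edits.

    Records are canonicalized/remapped and carry the extractor's edit
    sequence as ground truth; generation is deterministic in ``seed``.
    Invalid constructions are rejected and resampled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    weights = dict(DEFAULT_TEMPLATE_WEIGHTS)
    if template_weights is not None:
        weights = {k: float(v) for k, v in template_weights.items() if v > 0}
    names = sorted(weights)
    probs = np.asarray([weights[k] for k in names], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    records: list[ReactionRecord] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 50 * n + 100:  # pragma: no cover - safety valve
            raise RuntimeError("fixture generation kept failing; template bug?")
        name = str(rng.choice(names, p=probs))
        try:
            smi, spec = TEMPLATES[name](rng)
            graph, tags = _materialize(smi)
            edit_seq = _build_edits(spec, graph, tags)
            result = apply_sequence(graph, edit_seq)
        except (ChemistryError, EditApplicationError, KeyError):
            continue

        frags = Chem.GetMolFrags(result.final.mol, asMols=True, sanitizeFrags=False)
        reactant_graphs = [MolecularGraph.from_mol(f, sanitized=False) for f in frags]
        try:
            reactant_smis = [g.to_smiles(strip_maps=False) for g in reactant_graphs]
            product_smi = graph.to_smiles(strip_maps=False)
        except ChemistryError:
            continue
        record = ReactionRecord(
            raw_smiles=f"{'.'.join(reactant_smis)}>>{product_smi}",
            product=graph,
            reactants=reactant_graphs,
            reaction_class=_TEMPLATE_CLASS[name],
            record_id=f"fx-{len(records)}",
        )
        try:
            canon = canonicalize_and_remap(record)
            extracted = extract_edit_sequence(canon, assume_canonical=True)
        except Exception:
            continue
        if [e.kind for e in extracted] != TEMPLATE_KINDS[name]:
            # generator/extractor disagreement: reject, never mislabel
            continue
        canon.edits = extracted
        canon.record_id = record.record_id
        records.append(canon)
    return records


# --------------------------------------------------------------------------
# Tanimoto-based splitting
# --------------------------------------------------------------------------


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _product_fingerprint(record: ReactionRecord):
    mol = record.product.sanitized_copy()
    for a in mol.GetAtoms():
        a.SetAtomMapNum(0)
    return _MORGAN.GetFingerprint(mol)


def tanimoto_split(
    records: Sequence[ReactionRecord],
    threshold: float,
    train_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[list[ReactionRecord], list[ReactionRecord], list[ReactionRecord]]:
    """Scaffold-aware split on product ECFP4 Tanimoto similarity.

    After an initial random split at ``train_fraction`` (the remainder
    halved into validation and test), every validation/test record whose
    product's maximum Tanimoto similarity to any training product exceeds
    ``threshold`` is moved into training.  ``threshold = 1.0`` leaves the
    random split unchanged.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_train = int(round(train_fraction * len(records)))
    n_val = (len(records) - n_train) // 2
    train = [records[i] for i in idx[:n_train]]
    val = [records[i] for i in idx[n_train:n_train + n_val]]
    test = [records[i] for i in idx[n_train + n_val:]]

    train_fps = [_product_fingerprint(r) for r in train]
    def _partition(held):
        keep, moved = [], []
        for rec in held:
            fp = _product_fingerprint(rec)
            sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps) if train_fps else []
            if sims and max(sims) > threshold:
                moved.append(rec)
            else:
                keep.append(rec)
        return keep, moved

    val, moved_v = _partition(val)
    test, moved_t = _partition(test)
    train.extend(moved_v)
    train.extend(moved_t)
    if not test:
        import warnings

        warnings.warn("tanimoto_split: test set is empty at this threshold")
    return train, val, test
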