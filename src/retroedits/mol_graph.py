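"""Molecular graph data model, reaction I/O and featurization.

Molecules are held in an *edit-ready* state: kekulized (aromatic flags
cleared), with hydrogen counts pinned as explicit counts (``NoImplicit``)
so that graph edits control valence bookkeeping explicitly.  Canonical
aromatic SMILES are produced on demand by re-sanitizing a copy.

Atoms are addressed externally by atom-map number (map numbers survive
canonicalization; indices do not) and internally by 0-based index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import SanitizeFlags


class ChemistryError(ValueError):
    """A molecule failed valence/sanitization rules."""


class MappingError(ValueError):
    """Atom-map numbers violate the reaction-record contract."""


class ReactionParseError(ValueError):
    """A reaction SMILES could not be parsed."""


# --------------------------------------------------------------------------
# bond type / stereo integer codes used in edit payloads
# --------------------------------------------------------------------------

BOND_TYPE_CODES = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}
CODE_BOND_TYPES = {v: k for k, v in BOND_TYPE_CODES.items()}

# bond stereo: 0 = none/any, 1 = cis (Z), 2 = trans (E), in the map-sorted
# reference frame (lowest-map neighbor on each end).
_STEREO_TO_CODE = {
    Chem.BondStereo.STEREONONE: 0,
    Chem.BondStereo.STEREOANY: 0,
    Chem.BondStereo.STEREOZ: 1,
    Chem.BondStereo.STEREOCIS: 1,
    Chem.BondStereo.STEREOE: 2,
    Chem.BondStereo.STEREOTRANS: 2,
}


def _parity_of(seq: Sequence[int]) -> int:
    """Inversion parity of a sequence of distinct integers."""
    inv = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                inv += 1
    return inv % 2


def normalized_chiral_code(atom: Chem.Atom) -> int:
    """Tetrahedral parity of ``atom`` in the atom-map-sorted neighbor frame.

    Returns 0 (unspecified), 1 or 2.  RDKit stores the tag relative to the
    atom's bond-list order with any counted hydrogen at the end of the list;
    we re-express it with heavy neighbors sorted by map number (hydrogen
    stays last) so product and reactant atoms can be compared even though
    their bond lists are ordered differently.
    """
    tag = atom.GetChiralTag()
    if tag == Chem.ChiralType.CHI_UNSPECIFIED:
        return 0
    if tag not in (
        Chem.ChiralType.CHI_TETRAHEDRAL_CW,
        Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    ):
        return 0
    maps = [b.GetOtherAtom(atom).GetAtomMapNum() for b in atom.GetBonds()]
    flip = _parity_of(maps)
    code = 1 if tag == Chem.ChiralType.CHI_TETRAHEDRAL_CW else 2
    if flip:
        code = 3 - code
    return code


def set_normalized_chiral_code(atom: Chem.Atom, code: int) -> None:
    """Set the tetrahedral tag so the map-frame parity equals ``code``."""
    if code == 0:
        atom.SetChiralTag(Chem.ChiralType.CHI_UNSPECIFIED)
        return
    maps = [b.GetOtherAtom(atom).GetAtomMapNum() for b in atom.GetBonds()]
    flip = _parity_of(maps)
    eff = 3 - code if flip else code
    atom.SetChiralTag(
        Chem.ChiralType.CHI_TETRAHEDRAL_CW
        if eff == 1
        else Chem.ChiralType.CHI_TETRAHEDRAL_CCW
    )


def _stereo_ref_neighbor(bond: Chem.Bond, end_atom: Chem.Atom) -> Optional[Chem.Atom]:
    other = bond.GetOtherAtom(end_atom)
    nbrs = [a for a in end_atom.GetNeighbors() if a.GetIdx() != other.GetIdx()]
    if not nbrs:
        return None
    return min(nbrs, key=lambda a: (a.GetAtomMapNum(), a.GetIdx()))


def normalized_bond_stereo_code(bond: Chem.Bond) -> int:
    """Cis/trans code of a double bond in the lowest-map-neighbor frame."""
    code = _STEREO_TO_CODE.get(bond.GetStereo(), 0)
    if code == 0:
        return 0
    sa = list(bond.GetStereoAtoms())
    if len(sa) != 2:
        return 0
    ra = _stereo_ref_neighbor(bond, bond.GetBeginAtom())
    rb = _stereo_ref_neighbor(bond, bond.GetEndAtom())
    if ra is None or rb is None:
        return 0
    # stereo atoms are one neighbor of each end; count frame mismatches
    flips = 0
    for idx in sa:
        if idx not in (ra.GetIdx(), rb.GetIdx()):
            flips += 1
    if flips % 2:
        code = 3 - code
    return code


def set_normalized_bond_stereo_code(bond: Chem.Bond, code: int) -> None:
    if code == 0:
        bond.SetStereo(Chem.BondStereo.STEREONONE)
        return
    ra = _stereo_ref_neighbor(bond, bond.GetBeginAtom())
    rb = _stereo_ref_neighbor(bond, bond.GetEndAtom())
    if ra is None or rb is None:
        raise ChemistryError("cannot set cis/trans stereo on a terminal bond")
    bond.SetStereoAtoms(ra.GetIdx(), rb.GetIdx())
    bond.SetStereo(
        Chem.BondStereo.STEREOZ if code == 1 else Chem.BondStereo.STEREOE
    )


# --------------------------------------------------------------------------
# MolecularGraph
# --------------------------------------------------------------------------


def _to_edit_ready(mol: Chem.Mol) -> Chem.Mol:
    """Kekulize and pin hydrogen counts explicitly on a sanitized mol."""
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        atom.SetNumExplicitHs(atom.GetTotalNumHs())
        atom.SetNoImplicit(True)
    mol.UpdatePropertyCache(strict=False)
    return mol


class MolecularGraph:
    """A molecule (or a dot-disconnected set of fragments) under editing.

    Wraps an RDKit molecule kept kekulized with pinned hydrogen counts.
    Instances are treated as immutable by the edit engine: every edit
    produces a new graph.
    """

    __slots__ = ("mol",)

    def __init__(self, mol: Chem.Mol):
        self.mol = mol

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_smiles(cls, smiles: str) -> "MolecularGraph":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ChemistryError(f"unparseable SMILES: {smiles!r}")
        return cls(_to_edit_ready(mol))

    @classmethod
    def from_mol(cls, mol: Chem.Mol, sanitized: bool = True) -> "MolecularGraph":
        if sanitized:
            return cls(_to_edit_ready(mol))
        m = Chem.Mol(mol)
        m.UpdatePropertyCache(strict=False)
        return cls(m)

    def copy(self) -> "MolecularGraph":
        return MolecularGraph(Chem.RWMol(self.mol).GetMol())

    # -- atom addressing ---------------------------------------------------
    def atom_index_by_map(self, map_num: int) -> int:
        for atom in self.mol.GetAtoms():
            if atom.GetAtomMapNum() == map_num:
                return atom.GetIdx()
        raise KeyError(f"no atom with map number {map_num}")

    def map_numbers(self) -> set[int]:
        return {
            a.GetAtomMapNum() for a in self.mol.GetAtoms() if a.GetAtomMapNum()
        }

    def max_map(self) -> int:
        return max((a.GetAtomMapNum() for a in self.mol.GetAtoms()), default=0)

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def num_bonds(self) -> int:
        return self.mol.GetNumBonds()

    def num_fragments(self) -> int:
        return len(Chem.GetMolFrags(self.mol))

    # -- serialization -----------------------------------------------------
    def sanitized_copy(self) -> Chem.Mol:
        """A fully sanitized, re-aromatized copy; raises ChemistryError."""
        mol = Chem.Mol(self.mol)
        try:
            Chem.SanitizeMol(mol)
        except Exception as exc:  # rdkit raises several exception types
            raise ChemistryError(f"molecule fails sanitization: {exc}") from exc
        return mol

    def is_sanitizable(self) -> bool:
        try:
            self.sanitized_copy()
            return True
        except ChemistryError:
            return False

    def to_smiles(self, keep_stereo: bool = True, strip_maps: bool = False) -> str:
        """Deterministic canonical SMILES (fragments sorted, '.'-joined)."""
        mol = self.sanitized_copy()
        if strip_maps:
            for atom in mol.GetAtoms():
                atom.SetAtomMapNum(0)
        if not keep_stereo:
            Chem.RemoveStereochemistry(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        return ".".join(sorted(Chem.MolToSmiles(f) for f in frags))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        try:
            return f"MolecularGraph({self.to_smiles()!r})"
        except ChemistryError:
            return f"MolecularGraph(<unsanitized {self.num_atoms} atoms>)"


def ensure_atom_maps(graph: MolecularGraph) -> MolecularGraph:
    """Return a copy with every atom mapped (fresh numbers in canonical
    ranking order for unmapped atoms); unchanged if already fully mapped."""
    if all(a.GetAtomMapNum() for a in graph.mol.GetAtoms()):
        return graph
    mol = Chem.RWMol(graph.mol).GetMol()
    ranks = list(Chem.CanonicalRankAtoms(mol, includeChirality=False))
    taken = {a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum()}
    next_maps = (m for m in range(1, 2 * mol.GetNumAtoms() + 2) if m not in taken)
    order = sorted(range(mol.GetNumAtoms()), key=lambda i: ranks[i])
    for idx in order:
        atom = mol.GetAtomWithIdx(idx)
        if atom.GetAtomMapNum() == 0:
            atom.SetAtomMapNum(next(next_maps))
    return MolecularGraph.from_mol(mol, sanitized=False)


def to_canonical_smiles(
    graph: MolecularGraph, keep_stereo: bool = True, strip_maps: bool = True
) -> str:
    """Canonical SMILES of a graph; see :meth:`MolecularGraph.to_smiles`."""
    return graph.to_smiles(keep_stereo=keep_stereo, strip_maps=strip_maps)


def canonical_reactant_smiles(smiles: str, keep_stereo: bool = True) -> str:
    """Normalize a (possibly mapped, multi-fragment) SMILES for comparison."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    if not keep_stereo:
        Chem.RemoveStereochemistry(mol)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return ".".join(sorted(Chem.MolToSmiles(f) for f in frags))


# --------------------------------------------------------------------------
# ReactionRecord
# --------------------------------------------------------------------------


@dataclass
class ReactionRecord:
    """An atom-mapped retrosynthesis example: product and its reactants."""

    raw_smiles: str
    product: MolecularGraph
    reactants: list[MolecularGraph]
    reaction_class: Optional[int] = None
    edits: Optional[list] = None  # ground-truth Edit sequence, once extracted
    record_id: Optional[str] = None

    def reactant_union(self) -> MolecularGraph:
        """All reactant fragments combined into one (dot-disconnected) mol."""
        mol = self.reactants[0].mol
        for other in self.reactants[1:]:
            mol = Chem.CombineMols(mol, other.mol)
        m = Chem.Mol(mol)
        m.UpdatePropertyCache(strict=False)
        return MolecularGraph(m)

    def reactants_smiles(self, keep_stereo: bool = True) -> str:
        return ".".join(
            sorted(
                r.to_smiles(keep_stereo=keep_stereo, strip_maps=True)
                for r in self.reactants
            )
        )


def parse_reaction(reaction_smiles: str) -> ReactionRecord:
    """Parse an atom-mapped ``reactants>>product`` SMILES into a record.

    Accepts both the two-part ``reactants>>product`` form and the USPTO
    three-part ``reactants>reagents>product`` form (reagents are dropped).
    Every product atom must carry a map number.
    """
    parts = reaction_smiles.strip().split(">")
    if len(parts) == 3:
        reactant_part, _reagents, product_part = parts
    else:
        raise ReactionParseError(
            f"expected 'reactants>>product', got {reaction_smiles!r}"
        )
    if not reactant_part or not product_part:
        raise ReactionParseError(
            f"empty reactant or product side in {reaction_smiles!r}"
        )

    product_mol = Chem.MolFromSmiles(product_part)
    if product_mol is None:
        raise ReactionParseError(f"unparseable product SMILES: {product_part!r}")
    reactant_mols = []
    for frag in reactant_part.split("."):
        m = Chem.MolFromSmiles(frag)
        if m is None:
            raise ReactionParseError(f"unparseable reactant SMILES: {frag!r}")
        reactant_mols.append(m)

    unmapped = [
        a.GetIdx() for a in product_mol.GetAtoms() if a.GetAtomMapNum() == 0
    ]
    if unmapped:
        raise MappingError(
            f"product atoms without map numbers (indices {unmapped}) in "
            f"{reaction_smiles!r}"
        )
    prod_maps = [a.GetAtomMapNum() for a in product_mol.GetAtoms()]
    if len(prod_maps) != len(set(prod_maps)):
        raise MappingError(f"duplicate product map numbers in {reaction_smiles!r}")

    reactant_maps: list[int] = []
    for m in reactant_mols:
        reactant_maps.extend(
            a.GetAtomMapNum() for a in m.GetAtoms() if a.GetAtomMapNum()
        )
    if len(reactant_maps) != len(set(reactant_maps)):
        raise MappingError(f"duplicate reactant map numbers in {reaction_smiles!r}")
    missing = set(prod_maps) - set(reactant_maps)
    if missing:
        raise MappingError(
            f"product map numbers {sorted(missing)} absent from reactants in "
            f"{reaction_smiles!r}"
        )

    return ReactionRecord(
        raw_smiles=reaction_smiles.strip(),
        product=MolecularGraph.from_mol(product_mol),
        reactants=[MolecularGraph.from_mol(m) for m in reactant_mols],
    )


def canonicalize_and_remap(record: ReactionRecord) -> ReactionRecord:
    """Canonicalize the product and renumber atom maps 1..n canonically.

    Product atoms are renumbered 1..n following the canonical SMILES output
    order; mapped reactant atoms follow the product's new numbers; reactant
    atoms with no product counterpart (future leaving groups) receive fresh
    numbers n+1, n+2, ... in sorted-fragment canonical order.  Applying the
    operation twice equals applying it once.
    """
    prod = record.product.sanitized_copy()
    old_maps = [a.GetAtomMapNum() for a in prod.GetAtoms()]
    bare = Chem.Mol(prod)
    for atom in bare.GetAtoms():
        atom.SetAtomMapNum(0)
    Chem.MolToSmiles(bare)  # computes canonical output order
    order = list(
        map(int, bare.GetProp("_smilesAtomOutputOrder")[1:-1].split(","))
    ) if bare.HasProp("_smilesAtomOutputOrder") else list(range(bare.GetNumAtoms()))

    old_to_new: dict[int, int] = {}
    for rank, atom_idx in enumerate(order):
        old_to_new[old_maps[atom_idx]] = rank + 1
    n = prod.GetNumAtoms()

    for atom in prod.GetAtoms():
        atom.SetAtomMapNum(old_to_new[atom.GetAtomMapNum()])

    # renumber reactants; collect fragments sorted for determinism
    new_reactants: list[Chem.Mol] = []
    for g in record.reactants:
        m = g.sanitized_copy()
        for atom in m.GetAtoms():
            old = atom.GetAtomMapNum()
            atom.SetAtomMapNum(old_to_new.get(old, 0))
        new_reactants.append(m)

    def _frag_key(m: Chem.Mol) -> tuple:
        bare = Chem.Mol(m)
        for a in bare.GetAtoms():
            a.SetAtomMapNum(0)
        return (Chem.MolToSmiles(bare), Chem.MolToSmiles(m))

    new_reactants.sort(key=_frag_key)

    next_map = n + 1
    for m in new_reactants:
        Chem.MolToSmiles(m)
        frag_order = (
            list(map(int, m.GetProp("_smilesAtomOutputOrder")[1:-1].split(",")))
            if m.HasProp("_smilesAtomOutputOrder")
            else list(range(m.GetNumAtoms()))
        )
        for idx in frag_order:
            atom = m.GetAtomWithIdx(idx)
            if atom.GetAtomMapNum() == 0:
                atom.SetAtomMapNum(next_map)
                next_map += 1

    all_maps = [a.GetAtomMapNum() for m in new_reactants for a in m.GetAtoms()]
    if len(all_maps) != len(set(all_maps)):  # pragma: no cover - invariant
        raise MappingError("internal error: map collision after remapping")

    prod_smiles = Chem.MolToSmiles(prod)
    reactant_smiles = ".".join(Chem.MolToSmiles(m) for m in new_reactants)
    return ReactionRecord(
        raw_smiles=f"{reactant_smiles}>>{prod_smiles}",
        product=MolecularGraph.from_mol(prod),
        reactants=[MolecularGraph.from_mol(m) for m in new_reactants],
        reaction_class=record.reaction_class,
        record_id=record.record_id,
    )


# --------------------------------------------------------------------------
# Featurization
# --------------------------------------------------------------------------

# fixed element vocabulary (~65 symbols) + "other" slot
ATOM_ELEMENTS = [
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "W", "Ru", "Nb", "Re", "Te", "Rh", "Ta",
    "Tc", "Ba", "Bi", "Hf", "Mo", "U", "Sm", "Os", "Ir", "Ce", "Gd", "Ga",
    "Cs", "Sc", "Pr",
]
_ELEMENT_INDEX = {}
for _i, _sym in enumerate(ATOM_ELEMENTS):
    _ELEMENT_INDEX.setdefault(_sym, _i)

_DEGREES = list(range(6))
_CHARGES = [-2, -1, 0, 1, 2]
_CHIRAL_CODES = [0, 1, 2]
_H_COUNTS = list(range(5))

ATOM_FDIM = (
    len(ATOM_ELEMENTS) + 1   # element one-hot + other
    + len(_DEGREES) + 1      # degree
    + len(_CHARGES) + 1      # formal charge
    + len(_CHIRAL_CODES)     # chiral parity code
    + len(_H_COUNTS)         # total H count (clipped at 4)
    + 1                      # aromatic flag
)
BOND_FDIM = 4 + 1 + 1 + 3


def _one_hot(value, choices, other_slot=True):
    vec = [0.0] * (len(choices) + (1 if other_slot else 0))
    try:
        vec[choices.index(value)] = 1.0
    except ValueError:
        if other_slot:
            vec[-1] = 1.0
        else:  # pragma: no cover - guarded by callers
            raise
    return vec


def atom_features(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    feats = [0.0] * (len(ATOM_ELEMENTS) + 1)
    feats[_ELEMENT_INDEX.get(sym, len(ATOM_ELEMENTS))] = 1.0
    feats += _one_hot(atom.GetDegree(), _DEGREES)
    feats += _one_hot(atom.GetFormalCharge(), _CHARGES)
    feats += _one_hot(normalized_chiral_code(atom), _CHIRAL_CODES, other_slot=False)
    feats += _one_hot(min(atom.GetTotalNumHs(), 4), _H_COUNTS, other_slot=False)
    feats += [1.0 if atom.GetIsAromatic() else 0.0]
    return np.asarray(feats, dtype=np.float64)


def bond_features(bond: Chem.Bond) -> np.ndarray:
    bt = bond.GetBondType()
    type_oh = [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
    ]
    stereo_oh = [0.0, 0.0, 0.0]
    stereo_oh[normalized_bond_stereo_code(bond)] = 1.0
    feats = type_oh + [
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ] + stereo_oh
    return np.asarray(feats, dtype=np.float64)


@dataclass
class FeaturizedGraph:
    """Numeric arrays plus directed-edge indexing for the encoder.

    Every chemical bond yields two directed edges; ``rev`` maps each
    directed edge to its reverse.  ``bond_pairs`` lists, per undirected
    bond, the (atom_i, atom_j) indices ordered by ascending map number.
    """

    atom_x: np.ndarray          # (n_atoms, ATOM_FDIM)
    edge_x: np.ndarray          # (n_dir_edges, BOND_FDIM)
    edge_src: np.ndarray        # (n_dir_edges,) source atom index
    edge_dst: np.ndarray        # (n_dir_edges,) destination atom index
    rev: np.ndarray             # (n_dir_edges,) index of reverse edge
    bond_pairs: np.ndarray      # (n_bonds, 2) atom indices, map-ascending
    atom_maps: np.ndarray       # (n_atoms,) atom-map numbers
    bond_maps: np.ndarray       # (n_bonds, 2) map numbers, ascending


def featurize(graph: MolecularGraph) -> FeaturizedGraph:
    """Featurize a graph deterministically; unknown elements map to "other".

    Features are computed on the re-aromatized (sanitized) form so that,
    e.g., all benzene bonds look alike; valence-incomplete synthons that do
    not sanitize are featurized in their kekulized editing form.
    """
    try:
        mol = graph.sanitized_copy()
    except ChemistryError:
        mol = graph.mol
    n = mol.GetNumAtoms()
    atom_x = np.zeros((n, ATOM_FDIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        atom_x[atom.GetIdx()] = atom_features(atom)

    srcs, dsts, feats = [], [], []
    bond_pairs, bond_maps = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = bond_features(bond)
        srcs.extend([i, j])
        dsts.extend([j, i])
        feats.extend([f, f])
        mi = mol.GetAtomWithIdx(i).GetAtomMapNum()
        mj = mol.GetAtomWithIdx(j).GetAtomMapNum()
        if (mi, i) <= (mj, j):
            bond_pairs.append((i, j))
            bond_maps.append((mi, mj))
        else:
            bond_pairs.append((j, i))
            bond_maps.append((mj, mi))

    m = len(srcs)
    rev = np.arange(m, dtype=np.int64)
    rev[0::2] += 1
    rev[1::2] -= 1
    return FeaturizedGraph(
        atom_x=atom_x,
        edge_x=np.asarray(feats, dtype=np.float64).reshape(m, BOND_FDIM),
        edge_src=np.asarray(srcs, dtype=np.int64),
        edge_dst=np.asarray(dsts, dtype=np.int64),
        rev=rev,
        bond_pairs=np.asarray(bond_pairs, dtype=np.int64).reshape(-1, 2),
        atom_maps=np.asarray(
            [a.GetAtomMapNum() for a in mol.GetAtoms()], dtype=np.int64
        ),
        bond_maps=np.asarray(bond_maps, dtype=np.int64).reshape(-1, 2),
    )


# --------------------------------------------------------------------------
# Reaction CSV I/O
# --------------------------------------------------------------------------

_RXN_COLUMNS = ("reactants>reagents>production", "rxn_smiles")


def load_reaction_csv(path) -> list[ReactionRecord]:
    """Load reactions from a USPTO-layout CSV (dialect auto-detected)."""
    import pandas as pd

    df = pd.read_csv(path)
    col = next((c for c in _RXN_COLUMNS if c in df.columns), None)
    if col is None:
        raise ValueError(
            f"no reaction column found in {path}; expected one of {_RXN_COLUMNS}"
        )
    records = []
    for _, row in df.iterrows():
        rec = parse_reaction(str(row[col]))
        if "id" in df.columns:
            rec.record_id = str(row["id"])
        if "class" in df.columns:
            cls = row["class"]
            try:
                rec.reaction_class = int(cls)
            except (TypeError, ValueError):
                rec.reaction_class = None
        records.append(rec)
    return records


def save_reaction_csv(records: Iterable[ReactionRecord], path) -> None:
    import pandas as pd

    rows = []
    for i, rec in enumerate(records):
        rows.append(
            {
                "id": rec.record_id if rec.record_id is not None else str(i),
                "class": rec.reaction_class if rec.reaction_class else "UNK",
                "reactants>reagents>production": rec.raw_smiles,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
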