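"""Graph-edit algebra: the five edit variants and the engine applying them.

An edit sequence transforms a product graph into intermediates (synthons)
and finally a reactant set.  The engine performs explicit hydrogen
bookkeeping so that intermediates stay chemically meaningful:

* ``DeleteBond`` frees valence on both ends; each freed unit becomes a
  hydrogen.
* ``ChangeBond`` adjusts hydrogens by the bond-order difference (clamped
  at zero).
* ``ChangeAtom`` sets the hydrogen count and tetrahedral parity of an atom
  to target values.
* ``AttachLG`` merges a dummy-rooted leaving group, bonding every dummy
  position to the target atom, then trims the target's hydrogens down to
  its allowed valence.
* ``Terminate`` marks the sequence end and leaves the graph unchanged.

Edits never mutate their input graph, and pre-existing atoms keep their
map numbers through every edit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from rdkit import Chem

from .mol_graph import (
    CODE_BOND_TYPES,
    BOND_TYPE_CODES,
    ChemistryError,
    MolecularGraph,
    set_normalized_bond_stereo_code,
    set_normalized_chiral_code,
)


class SiteError(KeyError):
    """An edit addressed an atom or bond that does not exist."""


class EditApplicationError(RuntimeError):
    """A step of an edit sequence failed; carries the failing step index."""

    def __init__(self, step: int, edit: "Edit", cause: Exception):
        super().__init__(f"edit step {step} ({edit}) failed: {cause}")
        self.step = step
        self.edit = edit
        self.cause = cause


# --------------------------------------------------------------------------
# Edit variants
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Edit:
    """Base class; concrete edits define ``kind``, site and payload."""

    @property
    def kind(self) -> str:
        return type(self).__name__

    def payload_key(self) -> tuple:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "Edit":
        kind = d["type"]
        site = d.get("site")
        payload = d.get("payload")
        if kind == "DeleteBond":
            return DeleteBond(site[0], site[1])
        if kind == "ChangeBond":
            return ChangeBond(site[0], site[1], payload[0], payload[1])
        if kind == "ChangeAtom":
            return ChangeAtom(site, payload[0], payload[1])
        if kind == "AttachLG":
            return AttachLG(site, payload)
        if kind == "Terminate":
            return Terminate()
        raise ValueError(f"unknown edit type {kind!r}")


@dataclass(frozen=True)
class DeleteBond(Edit):
    """Delete the bond between map numbers (i, j); freed valence becomes H."""

    i: int
    j: int

    def __post_init__(self):
        if self.i > self.j:
            lo, hi = self.j, self.i
            object.__setattr__(self, "i", lo)
            object.__setattr__(self, "j", hi)

    @property
    def site(self) -> tuple[int, int]:
        return (self.i, self.j)

    def payload_key(self) -> tuple:
        return ("DeleteBond",)

    def to_dict(self) -> dict:
        return {"type": "DeleteBond", "site": [self.i, self.j], "payload": None}


@dataclass(frozen=True)
class ChangeBond(Edit):
    """Set bond (i, j) to (bond type code, bond stereo code).

    Type codes: 1 single, 2 double, 3 triple.  Stereo codes: 0 none/any,
    1 cis, 2 trans (in the lowest-map-neighbor frame).
    """

    i: int
    j: int
    bond_type: int
    bond_stereo: int = 0

    @property
    def site(self) -> tuple[int, int]:
        return (self.i, self.j)

    def payload_key(self) -> tuple:
        return ("ChangeBond", self.bond_type, self.bond_stereo)

    def to_dict(self) -> dict:
        return {
            "type": "ChangeBond",
            "site": [self.i, self.j],
            "payload": [self.bond_type, self.bond_stereo],
        }


@dataclass(frozen=True)
class ChangeAtom(Edit):
    """Set atom i's hydrogen count and tetrahedral parity code.

    Chiral codes: 0 unspecified, 1/2 the two parities in the map-sorted
    neighbor frame.
    """

    i: int
    num_hs: int
    chiral: int = 0

    @property
    def site(self) -> int:
        return self.i

    def payload_key(self) -> tuple:
        return ("ChangeAtom", self.num_hs, self.chiral)

    def to_dict(self) -> dict:
        return {
            "type": "ChangeAtom",
            "site": self.i,
            "payload": [self.num_hs, self.chiral],
        }


@dataclass(frozen=True)
class AttachLG(Edit):
    """Attach the dummy-rooted leaving group ``smiles`` to atom i."""

    i: int
    smiles: str

    @property
    def site(self) -> int:
        return self.i

    def payload_key(self) -> tuple:
        return ("AttachLG", self.smiles)

    def to_dict(self) -> dict:
        return {"type": "AttachLG", "site": self.i, "payload": self.smiles}


@dataclass(frozen=True)
class Terminate(Edit):
    """Declare the current graph to be the reactants."""

    @property
    def site(self) -> None:
        return None

    def payload_key(self) -> tuple:
        return ("Terminate",)

    def to_dict(self) -> dict:
        return {"type": "Terminate", "site": None, "payload": None}


def edits_to_jsonl(edits: Iterable[Edit]) -> str:
    return "\n".join(json.dumps(e.to_dict()) for e in edits)


def edits_from_jsonl(text: str) -> list[Edit]:
    return [Edit.from_dict(json.loads(line)) for line in text.splitlines() if line.strip()]


# --------------------------------------------------------------------------
# Engine
# --------------------------------------------------------------------------


def allowed_valence(atom: Chem.Atom) -> int:
    """Default valence adjusted for formal charge (organic-subset heuristic)."""
    pt = Chem.GetPeriodicTable()
    dv = pt.GetDefaultValence(atom.GetAtomicNum())
    chg = atom.GetFormalCharge()
    z = atom.GetAtomicNum()
    if z == 5:
        return dv + abs(chg)
    if z == 6:
        return dv - abs(chg)
    return max(dv + chg, 0)


def _bond_order_sum(atom: Chem.Atom) -> int:
    return int(sum(b.GetBondTypeAsDouble() for b in atom.GetBonds()))


def _check_no_valence_overflow(mol: Chem.Mol) -> None:
    probe = Chem.Mol(mol)
    try:
        probe.UpdatePropertyCache(strict=True)
    except Exception as exc:
        raise ChemistryError(f"valence overflow: {exc}") from exc


def _atom_by_map(mol: Chem.Mol, map_num: int) -> Chem.Atom:
    for atom in mol.GetAtoms():
        if atom.GetAtomMapNum() == map_num:
            return atom
    raise SiteError(f"no atom with map number {map_num}")


def _trim_hs_to_valence(atom: Chem.Atom) -> None:
    overflow = _bond_order_sum(atom) + atom.GetNumExplicitHs() - allowed_valence(atom)
    if overflow > 0:
        atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - overflow))


def apply_edit(graph: MolecularGraph, edit: Edit) -> MolecularGraph:
    """Apply one edit, returning a new graph (the input is untouched).

    Raises :class:`SiteError` if the edit's site is missing and
    :class:`ChemistryError` if the result overflows valence rules.
    """
    if isinstance(edit, Terminate):
        return graph.copy()
    rw = Chem.RWMol(graph.mol)

    if isinstance(edit, DeleteBond):
        a1 = _atom_by_map(rw, edit.i)
        a2 = _atom_by_map(rw, edit.j)
        bond = rw.GetBondBetweenAtoms(a1.GetIdx(), a2.GetIdx())
        if bond is None:
            raise SiteError(f"no bond between map numbers {edit.i} and {edit.j}")
        order = int(bond.GetBondTypeAsDouble())
        rw.RemoveBond(a1.GetIdx(), a2.GetIdx())
        for a in (a1, a2):
            a.SetNumExplicitHs(a.GetNumExplicitHs() + order)

    elif isinstance(edit, ChangeBond):
        a1 = _atom_by_map(rw, edit.i)
        a2 = _atom_by_map(rw, edit.j)
        bond = rw.GetBondBetweenAtoms(a1.GetIdx(), a2.GetIdx())
        if bond is None:
            raise SiteError(f"no bond between map numbers {edit.i} and {edit.j}")
        if edit.bond_type not in CODE_BOND_TYPES:
            raise ValueError(f"invalid bond type code {edit.bond_type}")
        old = int(bond.GetBondTypeAsDouble())
        new = edit.bond_type
        bond.SetBondType(CODE_BOND_TYPES[new])
        bond.SetIsAromatic(False)
        for a in (a1, a2):
            a.SetNumExplicitHs(max(0, a.GetNumExplicitHs() + old - new))
            a.SetIsAromatic(False)
        if new == 2 or edit.bond_stereo == 0:
            set_normalized_bond_stereo_code(bond, edit.bond_stereo)

    elif isinstance(edit, ChangeAtom):
        atom = _atom_by_map(rw, edit.i)
        atom.SetNumExplicitHs(edit.num_hs)
        set_normalized_chiral_code(atom, edit.chiral)

    elif isinstance(edit, AttachLG):
        return attach_leaving_group(graph, edit.i, edit.smiles)

    else:
        raise TypeError(f"unknown edit {edit!r}")

    rw.UpdatePropertyCache(strict=False)
    out = rw.GetMol()
    _check_no_valence_overflow(out)
    return MolecularGraph.from_mol(out, sanitized=False)


def attach_leaving_group(
    graph: MolecularGraph, atom_map: int, lg_smiles: str
) -> MolecularGraph:
    """Attach a dummy-rooted leaving group to the atom with map ``atom_map``.

    Each dummy atom's bond is redirected to the target atom (multi-dummy
    groups form several bonds to the same target), dummies are removed, new
    atoms get fresh map numbers, and the target's hydrogens are trimmed to
    its allowed valence.
    """
    lg = Chem.MolFromSmiles(lg_smiles)
    if lg is None:
        raise ChemistryError(f"unparseable leaving group SMILES: {lg_smiles!r}")
    dummies = [a.GetIdx() for a in lg.GetAtoms() if a.GetAtomicNum() == 0]
    if not dummies:
        raise ChemistryError(
            f"leaving group {lg_smiles!r} contains no dummy atom"
        )
    lg_ready = MolecularGraph.from_mol(lg).mol

    base = graph.mol
    rw = Chem.RWMol(Chem.CombineMols(base, lg_ready))
    offset = base.GetNumAtoms()
    target = _atom_by_map(rw, atom_map)

    next_map = graph.max_map() + 1
    for k in range(lg_ready.GetNumAtoms()):
        atom = rw.GetAtomWithIdx(offset + k)
        if atom.GetAtomicNum() != 0:
            atom.SetAtomMapNum(next_map)
            next_map += 1

    dummy_idxs = []
    for k in range(lg_ready.GetNumAtoms()):
        atom = rw.GetAtomWithIdx(offset + k)
        if atom.GetAtomicNum() != 0:
            continue
        dummy_idxs.append(atom.GetIdx())
        for bond in list(atom.GetBonds()):
            nbr = bond.GetOtherAtom(atom)
            order = bond.GetBondType()
            if rw.GetBondBetweenAtoms(target.GetIdx(), nbr.GetIdx()) is not None:
                raise ChemistryError(
                    f"leaving group {lg_smiles!r} would duplicate a bond"
                )
            # the replacement bond is appended at the end of nbr's bond
            # list while the dummy bond sat at position p: moving one slot
            # per intervening bond flips tetrahedral parity each time
            if nbr.GetChiralTag() in (
                Chem.ChiralType.CHI_TETRAHEDRAL_CW,
                Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
            ):
                nbr_bonds = [b.GetIdx() for b in nbr.GetBonds()]
                p = nbr_bonds.index(bond.GetIdx())
                shift = len(nbr_bonds) - 1 - p
                if shift % 2:
                    nbr.InvertChirality()
            rw.AddBond(target.GetIdx(), nbr.GetIdx(), order)
    for idx in sorted(dummy_idxs, reverse=True):
        rw.RemoveAtom(idx)

    target = _atom_by_map(rw, atom_map)  # indices shifted by removal
    _trim_hs_to_valence(target)
    rw.UpdatePropertyCache(strict=False)
    out = rw.GetMol()
    _check_no_valence_overflow(out)
    return MolecularGraph.from_mol(out, sanitized=False)


@dataclass
class ApplyResult:
    """Outcome of replaying an edit sequence on a product graph."""

    intermediates: list[MolecularGraph]
    final: MolecularGraph
    terminated: bool

    @property
    def reactants(self) -> MolecularGraph:
        return self.final


def apply_sequence(product: MolecularGraph, edits: Sequence[Edit]) -> ApplyResult:
    """Replay ``edits`` on ``product``; returns intermediates and reactants.

    The sequence must be nonempty with at most one Terminate, at the end.
    A sequence lacking Terminate still yields a final graph, flagged
    incomplete.  Step failures propagate as :class:`EditApplicationError`
    carrying the step index.
    """
    if not edits:
        raise ValueError("empty edit sequence")
    terms = [k for k, e in enumerate(edits) if isinstance(e, Terminate)]
    if len(terms) > 1 or (terms and terms[0] != len(edits) - 1):
        raise ValueError("Terminate must appear exactly once, at the end")

    graph = product
    intermediates: list[MolecularGraph] = []
    for step, edit in enumerate(edits):
        try:
            graph = apply_edit(graph, edit)
        except (SiteError, ChemistryError, ValueError) as exc:
            raise EditApplicationError(step, edit, exc) from exc
        if not isinstance(edit, Terminate):
            intermediates.append(graph)
    terminated = bool(terms)
    if terminated:
        try:
            graph.sanitized_copy()
        except ChemistryError as exc:
            raise EditApplicationError(len(edits) - 1, edits[-1], exc) from exc
    return ApplyResult(
        intermediates=intermediates, final=graph, terminated=terminated
    )


# --------------------------------------------------------------------------
# Vocabulary
# --------------------------------------------------------------------------

TERMINATE_KEY = ("Terminate",)


@dataclass
class EditVocabulary:
    """Indexed payload sets for bond edits, atom edits and Terminate.

    Bond payloads occupy indices ``0..n_bond-1``, atom payloads follow, and
    the terminate symbol is always the last index.  Payload order is
    deterministic: descending count, then payload string.
    """

    bond_payloads: list[tuple]
    atom_payloads: list[tuple]
    counts: dict = field(default_factory=dict)

    def __post_init__(self):
        self._bond_index = {p: k for k, p in enumerate(self.bond_payloads)}
        self._atom_index = {p: k for k, p in enumerate(self.atom_payloads)}

    # -- sizes -------------------------------------------------------------
    @property
    def n_bond(self) -> int:
        return len(self.bond_payloads)

    @property
    def n_atom(self) -> int:
        return len(self.atom_payloads)

    def __len__(self) -> int:
        return self.n_bond + self.n_atom + 1

    @property
    def terminate_index(self) -> int:
        return self.n_bond + self.n_atom

    # -- lookups -----------------------------------------------------------
    def bond_payload_index(self, payload: tuple) -> Optional[int]:
        return self._bond_index.get(tuple(payload))

    def atom_payload_index(self, payload: tuple) -> Optional[int]:
        return self._atom_index.get(tuple(payload))

    def contains_edit(self, edit: Edit) -> bool:
        key = edit.payload_key()
        if key == TERMINATE_KEY:
            return True
        if key[0] in ("DeleteBond", "ChangeBond"):
            return key in self._bond_index
        return key in self._atom_index

    def bond_edit(self, payload: tuple, site: tuple[int, int]) -> Edit:
        if payload[0] == "DeleteBond":
            return DeleteBond(site[0], site[1])
        return ChangeBond(site[0], site[1], payload[1], payload[2])

    def atom_edit(self, payload: tuple, site: int) -> Edit:
        if payload[0] == "ChangeAtom":
            return ChangeAtom(site, payload[1], payload[2])
        return AttachLG(site, payload[1])

    # -- persistence ---------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "bond_payloads": [list(p) for p in self.bond_payloads],
                "atom_payloads": [list(p) for p in self.atom_payloads],
                "counts": {json.dumps(list(k)): v for k, v in self.counts.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EditVocabulary":
        d = json.loads(text)
        return cls(
            bond_payloads=[tuple(p) for p in d["bond_payloads"]],
            atom_payloads=[tuple(p) for p in d["atom_payloads"]],
            counts={
                tuple(json.loads(k)): v for k, v in d.get("counts", {}).items()
            },
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "EditVocabulary":
        with open(path) as fh:
            return cls.from_json(fh.read())

    def content_hash(self) -> str:
        payload = json.dumps(
            [list(p) for p in self.bond_payloads]
            + [list(p) for p in self.atom_payloads]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
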