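"""Ground-truth edit extraction by product/reactant diffing.

Because product and reactant atoms share map numbers, the edit sequence of
a retro-reaction can be read off the structural difference: bonds present
in the product but not the reactants are deleted, bonds with changed
order/stereo are changed, hydrogen-count and parity differences become
atom edits, and maximal connected reactant subgraphs of unmapped atoms
become leaving groups attached to their mapped anchor atom.

Edits are emitted with priority DeleteBond > ChangeBond > ChangeAtom >
AttachLG and, within a class, in ascending atom-map order, so extraction
is byte-for-byte deterministic.  A hydrogen-count difference on an atom
that also has a bond edit is not emitted as a ChangeAtom: the engine's
valence bookkeeping accounts for it (parity differences are always
emitted).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from rdkit import Chem

from .edits import (
    AttachLG,
    ChangeAtom,
    ChangeBond,
    DeleteBond,
    Edit,
    EditApplicationError,
    EditVocabulary,
    Terminate,
    apply_sequence,
)
from .mol_graph import (
    BOND_TYPE_CODES,
    MolecularGraph,
    ReactionRecord,
    canonicalize_and_remap,
    normalized_bond_stereo_code,
    normalized_chiral_code,
)


class UnextractableReactionError(ValueError):
    """The reaction cannot be expressed in the edit scheme."""


class ExtractionConsistencyError(RuntimeError):
    """The extracted sequence did not replay back to the reactants."""


def _bond_payload(bond: Chem.Bond) -> tuple[int, int]:
    order = int(bond.GetBondTypeAsDouble())
    return order, normalized_bond_stereo_code(bond)


def _leaving_group_smiles(
    mol: Chem.Mol, component: list[int], anchor_idx: int
) -> str:
    """Dummy-rooted canonical SMILES of one leaving-group component."""
    rw = Chem.RWMol()
    old_to_new = {}
    for idx in component:
        atom = Chem.Atom(mol.GetAtomWithIdx(idx))
        atom.SetAtomMapNum(0)
        old_to_new[idx] = rw.AddAtom(atom)
    seen_bonds: set[int] = set()
    for idx in component:
        for bond in mol.GetAtomWithIdx(idx).GetBonds():
            if bond.GetIdx() in seen_bonds:
                continue
            seen_bonds.add(bond.GetIdx())
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if a in old_to_new and b in old_to_new:
                rw.AddBond(old_to_new[a], old_to_new[b], bond.GetBondType())
            else:
                inner = a if a in old_to_new else b
                outer = b if a in old_to_new else a
                if outer != anchor_idx:  # pragma: no cover - guarded upstream
                    raise UnextractableReactionError(
                        "leaving group touches more than one mapped atom"
                    )
                dummy = rw.AddAtom(Chem.Atom(0))
                rw.AddBond(old_to_new[inner], dummy, bond.GetBondType())
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:
        frag.UpdatePropertyCache(strict=False)
    return Chem.MolToSmiles(frag)


def extract_edit_sequence(
    record: ReactionRecord, assume_canonical: bool = False
) -> list[Edit]:
    """Derive the ground-truth edit sequence of a mapped reaction record.

    The record is canonicalized/remapped first unless ``assume_canonical``.
    Raises :class:`UnextractableReactionError` for reactions requiring bond
    formation between two mapped atoms (or leaving groups bridging two
    anchors) and :class:`ExtractionConsistencyError` if the replayed
    sequence does not reproduce the reactants.
    """
    if not assume_canonical:
        record = canonicalize_and_remap(record)
    product = record.product
    reactants = record.reactant_union()
    pmol, rmol = product.mol, reactants.mol
    n = pmol.GetNumAtoms()

    rmap_to_atom = {
        a.GetAtomMapNum(): a for a in rmol.GetAtoms() if a.GetAtomMapNum()
    }
    pmap_to_atom = {a.GetAtomMapNum(): a for a in pmol.GetAtoms()}

    # ---- bond diffs -------------------------------------------------------
    deletes: list[DeleteBond] = []
    changes: list[ChangeBond] = []
    bond_edit_maps: set[int] = set()
    for bond in pmol.GetBonds():
        mi = bond.GetBeginAtom().GetAtomMapNum()
        mj = bond.GetEndAtom().GetAtomMapNum()
        lo, hi = min(mi, mj), max(mi, mj)
        ra = rmap_to_atom[lo]
        rb = rmap_to_atom[hi]
        rbond = rmol.GetBondBetweenAtoms(ra.GetIdx(), rb.GetIdx())
        if rbond is None:
            deletes.append(DeleteBond(lo, hi))
            bond_edit_maps.update((lo, hi))
        else:
            p_payload = _bond_payload(bond)
            r_payload = _bond_payload(rbond)
            if p_payload != r_payload:
                changes.append(ChangeBond(lo, hi, r_payload[0], r_payload[1]))
                bond_edit_maps.update((lo, hi))

    # new bonds between two mapped atoms are not expressible as edits
    for bond in rmol.GetBonds():
        mi = bond.GetBeginAtom().GetAtomMapNum()
        mj = bond.GetEndAtom().GetAtomMapNum()
        if 0 < mi <= n and 0 < mj <= n:
            pa = pmap_to_atom[mi]
            pb = pmap_to_atom[mj]
            if pmol.GetBondBetweenAtoms(pa.GetIdx(), pb.GetIdx()) is None:
                raise UnextractableReactionError(
                    f"bond formation between mapped atoms {mi} and {mj} "
                    "is unsupported"
                )

    # ---- leaving groups ---------------------------------------------------
    lg_atom_idxs = [
        a.GetIdx()
        for a in rmol.GetAtoms()
        if not (0 < a.GetAtomMapNum() <= n)
    ]
    attaches: list[AttachLG] = []
    seen: set[int] = set()
    for start in lg_atom_idxs:
        if start in seen:
            continue
        # flood fill the unmapped component
        component, stack = [], [start]
        comp_set = set()
        while stack:
            idx = stack.pop()
            if idx in comp_set:
                continue
            comp_set.add(idx)
            component.append(idx)
            for nbr in rmol.GetAtomWithIdx(idx).GetNeighbors():
                if nbr.GetIdx() in comp_set:
                    continue
                if not (0 < nbr.GetAtomMapNum() <= n):
                    stack.append(nbr.GetIdx())
        seen.update(comp_set)
        component.sort()

        anchors = set()
        for idx in component:
            for nbr in rmol.GetAtomWithIdx(idx).GetNeighbors():
                if 0 < nbr.GetAtomMapNum() <= n:
                    anchors.add(nbr.GetIdx())
        if len(anchors) == 0:
            raise UnextractableReactionError(
                "reactants contain a fragment with no mapped atom "
                "(spectator not generatable by edits)"
            )
        if len(anchors) > 1:
            raise UnextractableReactionError(
                "leaving group attaches to more than one mapped atom "
                "(bond formation unsupported)"
            )
        anchor_idx = anchors.pop()
        anchor_map = rmol.GetAtomWithIdx(anchor_idx).GetAtomMapNum()
        attaches.append(
            AttachLG(anchor_map, _leaving_group_smiles(rmol, component, anchor_idx))
        )

    # ---- atom diffs -------------------------------------------------------
    atom_edits: list[ChangeAtom] = []
    for m in range(1, n + 1):
        pa = pmap_to_atom[m]
        ra = rmap_to_atom[m]
        p_h, r_h = pa.GetTotalNumHs(), ra.GetTotalNumHs()
        p_c, r_c = normalized_chiral_code(pa), normalized_chiral_code(ra)
        if p_c != r_c or (p_h != r_h and m not in bond_edit_maps):
            atom_edits.append(ChangeAtom(m, r_h, r_c))

    deletes.sort(key=lambda e: e.site)
    # order-decreasing changes free valence and must precede increases so
    # the clamped hydrogen bookkeeping never strands an atom at zero
    changes.sort(key=lambda e: (e.bond_type, e.site))
    atom_edits.sort(key=lambda e: e.site)
    attaches.sort(key=lambda e: (e.site, e.smiles))
    sequence: list[Edit] = [*deletes, *changes, *atom_edits, *attaches, Terminate()]

    # ---- replay check -----------------------------------------------------
    try:
        result = apply_sequence(product, sequence)
    except EditApplicationError as exc:
        raise ExtractionConsistencyError(
            f"extracted sequence failed to replay: {exc}"
        ) from exc
    got = result.final.to_smiles(keep_stereo=True, strip_maps=True)
    want = record.reactants_smiles(keep_stereo=True)
    if got != want:
        raise ExtractionConsistencyError(
            f"replayed reactants {got!r} differ from ground truth {want!r}"
        )
    return sequence


# --------------------------------------------------------------------------
# Dataset-level operations
# --------------------------------------------------------------------------


@dataclass
class PreprocessReport:
    """Summary of dataset preprocessing (counts, lengths, failures)."""

    n_total: int = 0
    n_extracted: int = 0
    n_failed: int = 0
    failure_reasons: dict = field(default_factory=dict)
    edit_type_counts: dict = field(default_factory=dict)
    length_histogram: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_extracted": self.n_extracted,
            "n_failed": self.n_failed,
            "failure_reasons": self.failure_reasons,
            "edit_type_counts": self.edit_type_counts,
            "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
        }


def preprocess_records(
    records: Iterable[ReactionRecord],
) -> tuple[list[ReactionRecord], PreprocessReport]:
    """Canonicalize records and attach extracted edit sequences.

    Records whose reactions are unextractable are dropped (counted in the
    report), mirroring dataset preparation practice.
    """
    report = PreprocessReport()
    kept: list[ReactionRecord] = []
    for rec in records:
        report.n_total += 1
        try:
            canon = canonicalize_and_remap(rec)
            canon.edits = extract_edit_sequence(canon, assume_canonical=True)
        except (UnextractableReactionError, ExtractionConsistencyError) as exc:
            report.n_failed += 1
            reason = type(exc).__name__
            report.failure_reasons[reason] = report.failure_reasons.get(reason, 0) + 1
            continue
        report.n_extracted += 1
        n_edits = len(canon.edits) - 1  # Terminate not counted as a step
        report.length_histogram[n_edits] = report.length_histogram.get(n_edits, 0) + 1
        for e in canon.edits:
            report.edit_type_counts[e.kind] = report.edit_type_counts.get(e.kind, 0) + 1
        kept.append(canon)
    return kept, report


def build_vocabulary(
    records: Iterable[ReactionRecord], min_lg_count: int = 1
) -> EditVocabulary:
    """Build the edit vocabulary from records carrying edit sequences.

    Leaving-group payloads must occur at least ``min_lg_count`` times to be
    collected (1 for small curated sets, 50 for large noisy ones); all
    other payload kinds are always kept.  Payloads are ordered by
    descending count then payload string, independent of input order.
    """
    if min_lg_count < 1:
        raise ValueError("min_lg_count must be >= 1")
    counts: Counter = Counter()
    for rec in records:
        if rec.edits is None:
            raise ValueError("records must be preprocessed (missing edits)")
        for e in rec.edits:
            if not isinstance(e, Terminate):
                counts[e.payload_key()] += 1

    def _sort_key(item):
        key, cnt = item
        return (-cnt, str(key))

    bond_payloads = [
        k
        for k, _ in sorted(counts.items(), key=_sort_key)
        if k[0] in ("DeleteBond", "ChangeBond")
    ]
    atom_payloads = [
        k
        for k, c in sorted(counts.items(), key=_sort_key)
        if (k[0] == "ChangeAtom") or (k[0] == "AttachLG" and c >= min_lg_count)
    ]
    return EditVocabulary(
        bond_payloads=bond_payloads,
        atom_payloads=atom_payloads,
        counts=dict(counts),
    )


def edit_coverage(
    records: Iterable[ReactionRecord], vocab: EditVocabulary
) -> float:
    """Fraction of records whose every edit is representable in ``vocab``."""
    total = covered = 0
    for rec in records:
        if rec.edits is None:
            continue
        total += 1
        if all(vocab.contains_edit(e) for e in rec.edits):
            covered += 1
    return covered / total if total else 0.0


def validate_applicability(
    records: Iterable[ReactionRecord],
) -> tuple[float, list[tuple[Optional[str], str]]]:
    """Fraction of records whose replayed sequence reproduces the reactants.

    Returns ``(fraction, failures)`` where failures are (record id, reason)
    pairs; failures are counted, never raised.
    """
    total = ok = 0
    failures: list[tuple[Optional[str], str]] = []
    for rec in records:
        total += 1
        try:
            if rec.edits is None:
                rec = canonicalize_and_remap(rec)
                seq = extract_edit_sequence(rec, assume_canonical=True)
            else:
                seq = rec.edits
            result = apply_sequence(rec.product, seq)
            got = result.final.to_smiles(keep_stereo=True, strip_maps=True)
            if got == rec.reactants_smiles(keep_stereo=True):
                ok += 1
            else:
                failures.append((rec.record_id, "replayed reactants differ"))
        except Exception as exc:
            failures.append((rec.record_id, f"{type(exc).__name__}: {exc}"))
    return (ok / total if total else 0.0), failures
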