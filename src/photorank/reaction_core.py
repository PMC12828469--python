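"""Reaction-core extraction from atom-mapped reaction SMILES.

The core of a reaction is the set of atoms that change their bonding
pattern between reactant and product sides, together with flanking atoms
up to a bond-distance radius (3 by default).  Serialized as a canonical
core reaction SMILES, it acts as a reaction-type key: two reactions that
perform the same transformation on different substrates share the same
core string, provided the transformation's whole chemical context lies
within the expansion radius.

An atom counts as *changed* when any of the following differ between its
reactant and product occurrence: the multiset of (neighbor, bond order)
pairs, the formal charge, or the total hydrogen count.  Atoms present on
only one side (leaving groups, incorporated reagents) always count as
changed.  Stereochemistry flags are ignored.  Unmapped spectator atoms are
treated as unchanged and never enter the core.

Atom mapping itself is out of scope: the module requires pre-mapped input
(the synthetic generator emits perfect maps) and accepts any external
mapper through :class:`AtomMapper`.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Callable, Protocol

from rdkit import Chem

from .chem_io import ValidationError

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 3


class AtomMapper(Protocol):
    """Pluggable interface for external atom mappers."""

    def __call__(self, reaction_smiles: str) -> str:
        """Return an atom-mapped reaction SMILES for the input reaction."""
        ...


@dataclass
class MappedReaction:
    """A reaction with per-atom map numbers linking product atoms to their
    reactant origins."""

    reactant_mol: Chem.Mol
    product_mol: Chem.Mol
    reactant_index: dict[int, int]  # map number -> atom index
    product_index: dict[int, int]

    @classmethod
    def from_smiles(cls, mapped_smiles: str) -> "MappedReaction":
        parts = mapped_smiles.split(">")
        if len(parts) not in (2, 3):
            raise ValidationError(f"not a reaction SMILES: {mapped_smiles!r}")
        sides = []
        for label, text in (("reactant", parts[0]), ("product", parts[-1])):
            mol = Chem.MolFromSmiles(text)
            if mol is None:
                raise ValidationError(f"unparsable {label} side: {text!r}")
            index: dict[int, int] = {}
            for atom in mol.GetAtoms():
                num = atom.GetAtomMapNum()
                if num > 0:
                    if num in index:
                        raise ValidationError(
                            f"duplicate atom-map number {num} on {label} side"
                        )
                    index[num] = atom.GetIdx()
            sides.append((mol, index))
        (rmol, ridx), (pmol, pidx) = sides
        missing = set(pidx) - set(ridx)
        if missing:
            logger.warning(
                "product-only atom maps %s (mapper artifact); treated as changed",
                sorted(missing),
            )
        return cls(rmol, pmol, ridx, pidx)

    @property
    def map_numbers(self) -> set[int]:
        return set(self.reactant_index) | set(self.product_index)


@dataclass
class ReactionCore:
    """Changed atoms plus their radius-r neighborhood, serialized."""

    changed_atoms: frozenset[int]
    core_atoms: frozenset[int]
    core_smiles: str
    core_key: str
    is_empty: bool = False


def _atom_signature(mol: Chem.Mol, idx: int) -> tuple:
    """Local bonding environment of one atom, used for change detection.

    Mapped neighbors are identified by map number; unmapped neighbors by
    element symbol (they carry no cross-side identity).
    """
    atom = mol.GetAtomWithIdx(idx)
    neighbors = []
    for bond in atom.GetBonds():
        other = bond.GetOtherAtom(atom)
        num = other.GetAtomMapNum()
        key = num if num > 0 else ("u", other.GetSymbol())
        neighbors.append((str(key), bond.GetBondTypeAsDouble()))
    return (
        atom.GetFormalCharge(),
        atom.GetTotalNumHs(),
        tuple(sorted(neighbors)),
    )


def find_changed_atoms(rxn: MappedReaction) -> set[int]:
    """Map numbers of atoms whose bonding pattern, charge or hydrogen
    count differs between the two sides; one-sided atoms included."""
    changed: set[int] = set()
    for num in rxn.map_numbers:
        in_r = num in rxn.reactant_index
        in_p = num in rxn.product_index
        if not (in_r and in_p):
            changed.add(num)
            continue
        sig_r = _atom_signature(rxn.reactant_mol, rxn.reactant_index[num])
        sig_p = _atom_signature(rxn.product_mol, rxn.product_index[num])
        if sig_r != sig_p:
            changed.add(num)
    return changed


def _bfs_mapped_within(
    mol: Chem.Mol, start_idx: int, radius: int
) -> set[int]:
    """Map numbers of mapped atoms within `radius` bonds of start_idx.

    The walk crosses unmapped atoms (they count toward the distance) but
    only mapped atoms are collected.
    """
    found: set[int] = set()
    dist = {start_idx: 0}
    queue = deque([start_idx])
    while queue:
        idx = queue.popleft()
        d = dist[idx]
        atom = mol.GetAtomWithIdx(idx)
        num = atom.GetAtomMapNum()
        if num > 0:
            found.add(num)
        if d == radius:
            continue
        for nb in atom.GetNeighbors():
            j = nb.GetIdx()
            if j not in dist:
                dist[j] = d + 1
                queue.append(j)
    return found


def expand_core(
    rxn: MappedReaction, changed: set[int], radius: int = DEFAULT_RADIUS
) -> set[int]:
    """Breadth-first expansion of the changed set by `radius` bonds.

    Expansion runs on the reactant side; atoms that exist only on the
    product side are expanded there instead.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    unknown = changed - rxn.map_numbers
    if unknown:
        raise ValidationError(f"changed atoms not in reaction: {sorted(unknown)}")
    core = set(changed)
    for num in changed:
        if num in rxn.reactant_index:
            core |= _bfs_mapped_within(rxn.reactant_mol, rxn.reactant_index[num], radius)
        else:
            core |= _bfs_mapped_within(rxn.product_mol, rxn.product_index[num], radius)
    return core


def _side_fragment_smiles(
    mol: Chem.Mol,
    index: dict[int, int],
    core: set[int],
    attachment_points: bool,
) -> str:
    atoms = sorted(index[num] for num in core if num in index)
    if not atoms:
        return ""
    work = Chem.RWMol(mol)
    atom_set = set(atoms)
    if attachment_points:
        # mark severed bonds with dummy atoms instead of open valences
        extra = []
        for bond in mol.GetBonds():
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if (i in atom_set) != (j in atom_set):
                inside = i if i in atom_set else j
                dummy = work.AddAtom(Chem.Atom(0))
                work.AddBond(inside, dummy, Chem.BondType.SINGLE)
                extra.append(dummy)
        atom_set |= set(extra)
    for atom in work.GetAtoms():
        atom.SetAtomMapNum(0)
    bonds = [
        b.GetIdx()
        for b in work.GetBonds()
        if b.GetBeginAtomIdx() in atom_set and b.GetEndAtomIdx() in atom_set
    ]
    return Chem.MolFragmentToSmiles(
        work.GetMol(),
        atomsToUse=sorted(atom_set),
        bondsToUse=bonds or None,
        canonical=True,
    )


def extract_core(
    rxn: MappedReaction,
    radius: int = DEFAULT_RADIUS,
    attachment_points: bool = False,
) -> ReactionCore:
    """Extract and serialize the reaction core.

    Severed bonds at the core boundary are left as implicit open valences
    by default, keeping cores plain SMILES; with ``attachment_points`` the
    boundary is marked with dummy atoms (``*``) instead.

    An identity reaction has an empty changed set; the returned core is
    flagged ``is_empty`` with an empty core SMILES, and the caller decides
    whether to drop the record.
    """
    changed = find_changed_atoms(rxn)
    if not changed:
        return ReactionCore(frozenset(), frozenset(), "", "", is_empty=True)
    core = expand_core(rxn, changed, radius)
    r_smiles = _side_fragment_smiles(
        rxn.reactant_mol, rxn.reactant_index, core, attachment_points
    )
    p_smiles = _side_fragment_smiles(
        rxn.product_mol, rxn.product_index, core, attachment_points
    )
    core_smiles = f"{r_smiles}>>{p_smiles}"
    return ReactionCore(
        changed_atoms=frozenset(changed),
        core_atoms=frozenset(core),
        core_smiles=core_smiles,
        core_key=core_smiles,
    )


def core_from_mapped_smiles(
    mapped_smiles: str, radius: int = DEFAULT_RADIUS
) -> ReactionCore:
    """Convenience composition: parse + extract."""
    return extract_core(MappedReaction.from_smiles(mapped_smiles), radius=radius)
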