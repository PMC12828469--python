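"""Binary reaction representations: folded Morgan fingerprints and the
differential reaction fingerprint (DRFP).

The MLP recommender consumes two 64-bit inputs per reaction:

* a Morgan fingerprint of the concatenated substrate molecules — circular
  environment hashes folded modulo the vector size, OR-combined across
  substrates;
* a DRFP of the core reaction SMILES — the symmetric difference between
  the reactant-side and product-side *shingle sets* (canonical SMILES of
  every circular atom environment of radius 0..r), hashed and folded into
  a binary vector.

All hashing is done with a fixed, platform-stable 32-bit hash (blake2b
truncated to 4 bytes), never a process-randomized hash, so fingerprints
are reproducible across runs and machines.
"""

from __future__ import annotations

import hashlib
import logging
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin

from .chem_io import ReactionRecord, ValidationError, _mol_or_raise
from .reaction_core import DEFAULT_RADIUS, core_from_mapped_smiles

logger = logging.getLogger(__name__)

MORGAN_BITS = 64
DRFP_BITS = 64
MORGAN_RADIUS = 2  # conventional circular-fingerprint default; size is what matters
DRFP_RADIUS = 3


def stable_hash32(text: str) -> int:
    """Platform-stable 32-bit hash of a string (blake2b, 4-byte digest)."""
    return int.from_bytes(
        hashlib.blake2b(text.encode("utf-8"), digest_size=4).digest(), "little"
    )


def morgan_hashes(molecules: Sequence[str], radius: int = MORGAN_RADIUS) -> set[int]:
    """Unfolded Morgan environment hashes of a set of molecules."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    hashes: set[int] = set()
    for smiles in molecules:
        mol = _mol_or_raise(smiles)
        fp = gen.GetSparseCountFingerprint(mol)
        hashes.update(fp.GetNonzeroElements())
    return hashes


def fold_hashes(hashes: Iterable[int], n_bits: int) -> np.ndarray:
    """Fold integer hashes modulo n_bits into a binary vector."""
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    vec = np.zeros(n_bits, dtype=np.uint8)
    for h in hashes:
        vec[h % n_bits] = 1
    return vec


def morgan_fp(
    substrates: Sequence[str], n_bits: int = MORGAN_BITS, radius: int = MORGAN_RADIUS
) -> np.ndarray:
    """Folded binary Morgan fingerprint of the combined substrate molecules."""
    return fold_hashes(morgan_hashes(substrates, radius), n_bits)


def _parse_side(smiles: str) -> Chem.Mol:
    """Parse one reaction side, tolerating core fragments whose aromatic
    perception fails outside their original ring context."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        mol = Chem.MolFromSmiles(smiles, sanitize=False)
        if mol is None:
            raise ValidationError(f"unparsable reaction side: {smiles!r}")
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    return mol


def shingle_set(molecules: Sequence[str] | str, radius: int = DRFP_RADIUS) -> set[str]:
    """Canonical substructure shingles of one reaction side.

    For every atom and every k in 0..radius, the canonical SMILES of the
    k-bond circular environment is collected; duplicates collapse under
    set semantics.
    """
    if isinstance(molecules, str):
        molecules = [m for m in molecules.split(".") if m]
    shingles: set[str] = set()
    for smiles in molecules:
        mol = _parse_side(smiles)
        for atom in mol.GetAtoms():
            idx = atom.GetIdx()
            shingles.add(Chem.MolFragmentToSmiles(mol, atomsToUse=[idx], canonical=True))
            for k in range(1, radius + 1):
                env = Chem.FindAtomEnvironmentOfRadiusN(mol, k, idx)
                if not env:
                    continue
                atoms = {idx}
                for b in env:
                    bond = mol.GetBondWithIdx(b)
                    atoms.add(bond.GetBeginAtomIdx())
                    atoms.add(bond.GetEndAtomIdx())
                shingles.add(
                    Chem.MolFragmentToSmiles(
                        mol,
                        atomsToUse=sorted(atoms),
                        bondsToUse=list(env),
                        canonical=True,
                    )
                )
    return shingles


def drfp(
    reaction_smiles: str, n_bits: int = DRFP_BITS, radius: int = DRFP_RADIUS
) -> np.ndarray:
    """Differential reaction fingerprint of a reaction SMILES.

    Symmetric difference of the two sides' shingle sets, hashed with
    :func:`stable_hash32` and folded modulo ``n_bits``.  An identity
    reaction therefore maps to the zero vector, and the fingerprint is
    symmetric in the reaction direction.
    """
    parts = reaction_smiles.split(">")
    if len(parts) not in (2, 3):
        raise ValidationError(f"not a reaction SMILES: {reaction_smiles!r}")
    lhs, rhs = parts[0], parts[-1]
    if not lhs and not rhs:
        return np.zeros(n_bits, dtype=np.uint8)
    diff = shingle_set(lhs, radius) ^ shingle_set(rhs, radius)
    return fold_hashes((stable_hash32(s) for s in diff), n_bits)


class MorganFeaturizer(BaseEstimator, TransformerMixin):
    """Morgan fingerprint of the substrates of each reaction record.

    Parameters
    ----------
    n_bits : fingerprint length (64 matches the recommender's input size).
    radius : circular environment radius.
    include_product : also fold the product's environments in (off by
        default — the recommender featurizes substrates only).
    """

    def __init__(
        self,
        n_bits: int = MORGAN_BITS,
        radius: int = MORGAN_RADIUS,
        include_product: bool = False,
    ):
        self.n_bits = n_bits
        self.radius = radius
        self.include_product = include_product

    def fit(self, X: Sequence[ReactionRecord], y=None):
        self.n_features_out_ = self.n_bits
        return self

    def transform(self, X: Sequence[ReactionRecord]) -> np.ndarray:
        out = np.zeros((len(X), self.n_bits), dtype=np.uint8)
        for i, rec in enumerate(X):
            mols = list(rec.reactants)
            if self.include_product:
                mols.append(rec.product)
            out[i] = morgan_fp(mols, self.n_bits, self.radius)
        return out


class DRFPFeaturizer(BaseEstimator, TransformerMixin):
    """DRFP of each record's core reaction (or full reaction as fallback).

    With ``use_core`` (default), the differential fingerprint is computed
    on the radius-3 reaction core extracted from the record's atom-mapped
    SMILES; records without maps fall back to the full reaction SMILES
    with a warning, which is also the behavior behind the ablation flag
    ``use_core=False``.
    """

    def __init__(
        self,
        n_bits: int = DRFP_BITS,
        radius: int = DRFP_RADIUS,
        use_core: bool = True,
        core_radius: int = DEFAULT_RADIUS,
    ):
        self.n_bits = n_bits
        self.radius = radius
        self.use_core = use_core
        self.core_radius = core_radius

    def fit(self, X: Sequence[ReactionRecord], y=None):
        self.n_features_out_ = self.n_bits
        return self

    def _reaction_for(self, rec: ReactionRecord) -> str:
        if self.use_core and rec.mapped_smiles:
            core = core_from_mapped_smiles(rec.mapped_smiles, radius=self.core_radius)
            if not core.is_empty:
                return core.core_smiles
            logger.warning("record %s: empty reaction core; using full reaction", rec.id)
        elif self.use_core:
            logger.warning("record %s: no atom maps; using full reaction", rec.id)
        return rec.reaction_smiles

    def transform(self, X: Sequence[ReactionRecord]) -> np.ndarray:
        out = np.zeros((len(X), self.n_bits), dtype=np.uint8)
        for i, rec in enumerate(X):
            out[i] = drfp(self._reaction_for(rec), self.n_bits, self.radius)
        return out


class ReactionFeaturizer(BaseEstimator, TransformerMixin):
    """Concatenated (Morgan | DRFP) feature block the MLP consumes."""

    def __init__(
        self,
        morgan_bits: int = MORGAN_BITS,
        morgan_radius: int = MORGAN_RADIUS,
        drfp_bits: int = DRFP_BITS,
        drfp_radius: int = DRFP_RADIUS,
        use_core: bool = True,
    ):
        self.morgan_bits = morgan_bits
        self.morgan_radius = morgan_radius
        self.drfp_bits = drfp_bits
        self.drfp_radius = drfp_radius
        self.use_core = use_core

    def fit(self, X: Sequence[ReactionRecord], y=None):
        self.n_features_out_ = self.morgan_bits + self.drfp_bits
        return self

    def transform(self, X: Sequence[ReactionRecord]) -> np.ndarray:
        morgan = MorganFeaturizer(self.morgan_bits, self.morgan_radius).fit(X).transform(X)
        diff = (
            DRFPFeaturizer(self.drfp_bits, self.drfp_radius, use_core=self.use_core)
            .fit(X)
            .transform(X)
        )
        return np.hstack([morgan, diff])
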