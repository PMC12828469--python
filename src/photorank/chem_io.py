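"""Reaction records, the photocatalyst registry, and dataset persistence.

The label space of the recommender is a fixed, ordered registry of 31
archetypal photocatalysts (Ir and Ru polypyridyl complexes, the copper
phenanthroline Cu1, and organic dyes such as Eosin Y, 4CzIPN or
thioxanthone).  Catalysts are one-hot encoded: each registry entry owns a
stable 0-based integer index, and every model in the package emits a
probability vector ordered by those indices.

Reactions are handled as reaction SMILES, either two-part
(``reactants>>product``) or three-part (``reactants>agents>product``);
agents are parsed but discarded, because the recommender deliberately
carries no information about co-catalysts, bases or solvents.  Registry
SMILES store the photoactive ion only — counterions of charged
photocatalysts are not part of the label definition.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")


class ValidationError(ValueError):
    """A SMILES string or record field failed chemical validation."""


class SchemaError(ValueError):
    """A dataset or registry file is missing mandatory columns."""


class LookupMissError(KeyError):
    """A catalyst name or index is not part of the registry."""


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES, raising :class:`ValidationError`
    if the string does not parse to a valid molecular graph."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def _mol_or_raise(smiles: str, what: str = "SMILES") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"unparsable {what}: {smiles!r}")
    return mol


@dataclass(frozen=True)
class ReactionRecord:
    """One labeled reaction.

    ``reactants`` and ``product`` hold canonical SMILES.  ``mapped_smiles``
    optionally holds the atom-mapped reaction SMILES the core extractor
    consumes; ``catalyst_label`` is a registry name when the record is
    labeled.
    """

    id: str
    reactants: tuple[str, ...]
    product: str
    mapped_smiles: str | None = None
    catalyst_label: str | None = None
    split_tag: str | None = None

    @property
    def reaction_smiles(self) -> str:
        return ".".join(self.reactants) + ">>" + self.product


@dataclass
class LoadReport:
    """Counts produced while loading a dataset file."""

    n_read: int = 0
    n_kept: int = 0
    n_dropped_invalid: int = 0
    n_dropped_label: int = 0
    n_dropped_duplicate: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_invalid + self.n_dropped_label + self.n_dropped_duplicate


class CatalystRegistry:
    """Ordered set of photocatalyst classes defining the label space.

    Indices are dense 0..size-1; names are unique.  ``encode``/``decode``
    form a bijection that is stable across runs for a given registry file.
    """

    def __init__(self, entries: Sequence[tuple[int, str, str]]):
        entries = sorted(entries)
        indices = [e[0] for e in entries]
        if indices != list(range(len(entries))):
            raise ValidationError("registry indices must be dense 0..size-1")
        names = [e[1] for e in entries]
        if len(set(names)) != len(names):
            raise ValidationError("registry names must be unique")
        self.entries: list[tuple[int, str, str]] = list(entries)
        self._by_name = {name: idx for idx, name, _ in entries}

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[tuple[int, str, str]]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [name for _, name, _ in self.entries]

    def encode(self, name: str) -> int:
        try:
            return self._by_name[name]
        except KeyError:
            raise LookupMissError(f"unknown catalyst name: {name!r}") from None

    def decode(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise LookupMissError(f"catalyst index out of range: {index}")
        return self.entries[index][1]

    def smiles(self, index: int) -> str:
        if not 0 <= index < self.size:
            raise LookupMissError(f"catalyst index out of range: {index}")
        return self.entries[index][2]

    @classmethod
    def from_csv(cls, path: str | Path) -> "CatalystRegistry":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"index", "name", "smiles"} <= set(
                reader.fieldnames
            ):
                raise SchemaError(
                    "registry file needs columns index,name,smiles; "
                    f"got {reader.fieldnames}"
                )
            entries = [(int(r["index"]), r["name"], r["smiles"]) for r in reader]
        return cls(entries)

    @classmethod
    def default(cls) -> "CatalystRegistry":
        """The shipped 31-catalyst registry (editable package data)."""
        ref = resources.files("photorank.data").joinpath("photocatalysts.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def encode_label(name: str, registry: CatalystRegistry) -> int:
    return registry.encode(name)


def decode_label(index: int, registry: CatalystRegistry) -> str:
    return registry.decode(index)


def parse_reaction(
    text: str,
    record_id: str = "r0",
    keep_largest_product: bool = False,
) -> ReactionRecord:
    """Parse a 2- or 3-part reaction SMILES into a :class:`ReactionRecord`.

    Agents in the middle field of a three-part reaction SMILES are dropped
    with a warning — the recommender does not model additives.  Records
    with more than one product molecule are rejected unless
    ``keep_largest_product`` is set, in which case the product with the
    most heavy atoms is kept.
    """
    parts = text.strip().split(">")
    if len(parts) == 3:
        lhs, agents, rhs = parts
        if agents.strip():
            logger.warning("ignoring agents %r in three-part reaction SMILES", agents)
    elif len(parts) == 2:
        lhs, rhs = parts
    else:
        raise ValidationError(
            f"expected one reaction arrow ('>>' or '>agents>') in {text!r}"
        )
    if not lhs.strip() or not rhs.strip():
        raise ValidationError(f"empty reactant or product side in {text!r}")

    reactants = []
    for frag in lhs.split("."):
        reactants.append(canonicalize(frag))

    products = rhs.split(".")
    if len(products) > 1:
        if not keep_largest_product:
            raise ValidationError(
                f"{len(products)} product molecules in {text!r}; the recommender "
                "expects a single product (set keep_largest_product to override)"
            )
        mols = [_mol_or_raise(p, "product") for p in products]
        largest = max(mols, key=lambda m: m.GetNumHeavyAtoms())
        product = Chem.MolToSmiles(largest)
    else:
        product = canonicalize(products[0])

    return ReactionRecord(id=record_id, reactants=tuple(reactants), product=product)


def _strip_maps_smiles(mapped_smiles: str) -> str:
    """Canonical unmapped reaction SMILES from a mapped one."""
    sides = mapped_smiles.split(">")
    lhs, rhs = sides[0], sides[-1]
    out = []
    for side in (lhs, rhs):
        mol = _mol_or_raise(side, "mapped reaction side")
        for atom in mol.GetAtoms():
            atom.SetAtomMapNum(0)
        out.append(Chem.MolToSmiles(mol))
    return out[0] + ">>" + out[1]


def validate_mapped_smiles(mapped_smiles: str) -> None:
    """Check the atom-map invariant: map numbers unique per side, and every
    product map number present on exactly one reactant atom."""
    parts = mapped_smiles.split(">")
    if len(parts) not in (2, 3):
        raise ValidationError(f"not a reaction SMILES: {mapped_smiles!r}")
    lhs, rhs = parts[0], parts[-1]
    maps: dict[str, list[int]] = {}
    for side_name, side in (("reactant", lhs), ("product", rhs)):
        mol = _mol_or_raise(side, f"{side_name} side")
        nums = [a.GetAtomMapNum() for a in mol.GetAtoms() if a.GetAtomMapNum() > 0]
        if len(nums) != len(set(nums)):
            raise ValidationError(
                f"duplicate atom-map numbers on {side_name} side of {mapped_smiles!r}"
            )
        maps[side_name] = nums
    missing = set(maps["product"]) - set(maps["reactant"])
    if missing:
        raise ValidationError(
            f"product atom maps {sorted(missing)} have no reactant counterpart"
        )


def validate_record(record: ReactionRecord, registry: CatalystRegistry | None) -> None:
    """Raise on any invariant violation of the record."""
    for s in record.reactants:
        canonicalize(s)
    canonicalize(record.product)
    if record.mapped_smiles is not None:
        validate_mapped_smiles(record.mapped_smiles)
    if record.catalyst_label is not None and registry is not None:
        if record.catalyst_label not in registry:
            raise LookupMissError(
                f"catalyst {record.catalyst_label!r} not in registry"
            )


_COLUMNS = ("id", "reaction_smiles", "mapped_smiles", "catalyst")


def _record_to_row(record: ReactionRecord) -> dict[str, str]:
    return {
        "id": record.id,
        "reaction_smiles": record.reaction_smiles,
        "mapped_smiles": record.mapped_smiles or "",
        "catalyst": record.catalyst_label or "",
    }


def _row_to_record(row: dict[str, str], registry: CatalystRegistry | None) -> ReactionRecord:
    if "reaction_smiles" not in row or "id" not in row:
        raise SchemaError(f"row missing mandatory fields: {sorted(row)}")
    rec = parse_reaction(row["reaction_smiles"], record_id=str(row["id"]))
    mapped = row.get("mapped_smiles") or None
    label = row.get("catalyst") or None
    rec = replace(rec, mapped_smiles=mapped, catalyst_label=label)
    validate_record(rec, registry)
    return rec


def load_dataset(
    path: str | Path,
    registry: CatalystRegistry | None = None,
    deduplicate: bool = True,
) -> tuple[list[ReactionRecord], LoadReport]:
    """Load a CSV or JSONL dataset; invalid rows are dropped and counted.

    Mirrors the curation step of the training corpus: rows whose SMILES do
    not parse, whose atom maps are inconsistent, or whose label is outside
    the registry are filtered out, and duplicates on (canonical reaction
    SMILES, label) are collapsed.
    """
    path = Path(path)
    report = LoadReport()
    rows: list[dict[str, str]]
    if path.suffix.lower() == ".jsonl":
        with open(path) as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                warnings.warn(f"empty dataset file: {path}")
                return [], report
            if not {"id", "reaction_smiles"} <= set(reader.fieldnames):
                raise SchemaError(
                    f"dataset needs columns id,reaction_smiles; got {reader.fieldnames}"
                )
            rows = list(reader)
    if not rows:
        warnings.warn(f"empty dataset file: {path}")
        return [], report

    records: list[ReactionRecord] = []
    seen: set[tuple[str, str | None]] = set()
    for row in rows:
        report.n_read += 1
        try:
            rec = _row_to_record(row, registry)
        except LookupMissError as exc:
            report.n_dropped_label += 1
            report.messages.append(f"{row.get('id')}: {exc}")
            continue
        except (ValidationError, SchemaError) as exc:
            report.n_dropped_invalid += 1
            report.messages.append(f"{row.get('id')}: {exc}")
            continue
        key = (rec.reaction_smiles, rec.catalyst_label)
        if deduplicate and key in seen:
            report.n_dropped_duplicate += 1
            continue
        seen.add(key)
        records.append(rec)
        report.n_kept += 1
    return records, report


def write_dataset(records: Iterable[ReactionRecord], path: str | Path) -> None:
    """Write records as CSV or JSONL (chosen by file extension)."""
    path = Path(path)
    rows = [_record_to_row(r) for r in records]
    if path.suffix.lower() == ".jsonl":
        with open(path, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(_COLUMNS))
            writer.writeheader()
            writer.writerows(rows)
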