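"""Compound table I/O and the three-class kingdom label scheme.

Marine natural-product origin annotations are mapped to kingdom level:
0 = Animalia, 1 = Bacteria, 2 = Fungi.  Structures travel as SMILES;
every record is canonicalized on load so that "same molecule, different
SMILES" collapses to one canonical form.

Standardization policy: the largest covalent fragment is kept (public
natural-product exports frequently carry counter-ions) and stereochemistry
is preserved as written.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

LABELS = (0, 1, 2)
LABEL_NAMES = {0: "Animalia", 1: "Bacteria", 2: "Fungi"}
MICROBIAL_LABELS = (1, 2)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


def canonicalize_smiles(smiles: str, strip_salts: bool = True) -> str:
    """Return the canonical SMILES for ``smiles``.

    Idempotent: canonical input maps to itself.  With ``strip_salts``
    (default) only the largest covalent fragment is retained; stereo
    annotations are preserved as written.

    Raises
    ------
    SmilesParseError
        If the string is empty or does not parse.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError(smiles)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    if strip_salts:
        frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        if len(frags) > 1:
            mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One compound: id, canonical SMILES, kingdom label, provenance."""

    id: str
    smiles: str
    label: int
    taxon: str | None = None
    source: str | None = None

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(
                f"label must be one of {LABELS} "
                f"(0=Animalia, 1=Bacteria, 2=Fungi); got {self.label!r}"
            )


class LabeledDataset:
    """Ordered collection of :class:`CompoundRecord` with unique ids."""

    def __init__(self, records: Iterable[CompoundRecord]):
        self.records: list[CompoundRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise ValueError(f"duplicate compound id: {r.id!r}")
            seen.add(r.id)
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __getitem__(self, cid: str) -> CompoundRecord:
        return self._by_id[cid]

    def __contains__(self, cid: str) -> bool:
        return cid in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    def labels(self) -> dict[str, int]:
        return {r.id: r.label for r in self.records}

    @property
    def counts(self) -> dict[int, int]:
        return class_counts(self)

    def subset(self, ids: Iterable[str]) -> "LabeledDataset":
        """Records whose id is in ``ids``, preserving dataset order."""
        wanted = set(ids)
        unknown = wanted - set(self._by_id)
        if unknown:
            raise KeyError(f"unknown compound ids: {sorted(unknown)[:5]}")
        return LabeledDataset(r for r in self.records if r.id in wanted)

    def without(self, ids: Iterable[str]) -> "LabeledDataset":
        """Dataset with the given ids removed."""
        drop = set(ids)
        unknown = drop - set(self._by_id)
        if unknown:
            raise KeyError(f"unknown compound ids: {sorted(unknown)[:5]}")
        return LabeledDataset(r for r in self.records if r.id not in drop)

    def select_label(self, label: int) -> "LabeledDataset":
        return LabeledDataset(r for r in self.records if r.label == label)

    def with_labels(self, new_labels: Mapping[str, int]) -> "LabeledDataset":
        """Copy of the dataset with some records relabeled."""
        out = []
        for r in self.records:
            if r.id in new_labels:
                out.append(
                    CompoundRecord(r.id, r.smiles, new_labels[r.id], r.taxon, r.source)
                )
            else:
                out.append(r)
        return LabeledDataset(out)


def class_counts(ds: LabeledDataset) -> dict[int, int]:
    """Per-kingdom record counts; every label key is present, zeros included."""
    counts = {lab: 0 for lab in LABELS}
    for r in ds:
        counts[r.label] += 1
    return counts


def _parse_label(raw: str | int, context: str) -> int:
    try:
        label = int(raw)
    except (TypeError, ValueError):
        raise ValueError(f"{context}: label {raw!r} is not an integer") from None
    if label not in LABELS:
        raise ValueError(
            f"{context}: label {label} outside the kingdom scheme {set(LABELS)}"
        )
    return label


def _build_records(
    rows: Iterable[tuple[str, str, str | int, str | None, str | None]],
    strict: bool,
) -> list[CompoundRecord]:
    records, n_dropped = [], 0
    for cid, smi, raw_label, taxon, source in rows:
        label = _parse_label(raw_label, f"compound {cid!r}")
        try:
            can = canonicalize_smiles(smi)
        except SmilesParseError:
            if strict:
                raise
            n_dropped += 1
            continue
        records.append(CompoundRecord(str(cid), can, label, taxon or None, source or None))
    if n_dropped:
        logger.warning("dropped %d rows with invalid structures", n_dropped)
    return records


def load_dataset(
    path: str | Path,
    format: str | None = None,
    strict: bool = False,
    label_sidecar: str | Path | None = None,
) -> LabeledDataset:
    """Load a compound table from CSV, SMILES (.smi) or SDF.

    CSV needs columns ``id, smiles, label`` (``taxon``/``source`` optional).
    ``.smi`` holds ``SMILES<TAB>id`` lines with labels supplied via a sidecar
    CSV (columns ``id, label``).  SDF reads ``id`` and ``label`` properties.

    Invalid structures are dropped with a logged count unless ``strict``.
    Duplicate ids and labels outside {0,1,2} always raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        rows = _read_csv_rows(path)
    elif fmt == "smi":
        rows = _read_smi_rows(path, label_sidecar)
    elif fmt == "sdf":
        rows = _read_sdf_rows(path)
    else:
        raise ValueError(f"unsupported format {fmt!r}; expected csv, smi or sdf")
    return LabeledDataset(_build_records(rows, strict=strict))


def _read_csv_rows(path: Path):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "smiles", "label"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for row in reader:
            yield (
                row["id"],
                row["smiles"],
                row["label"],
                row.get("taxon"),
                row.get("source"),
            )


def _read_smi_rows(path: Path, label_sidecar: str | Path | None):
    if label_sidecar is None:
        raise ValueError(".smi input requires a label sidecar CSV (id,label)")
    labels: dict[str, str] = {}
    with open(label_sidecar, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            labels[row["id"]] = row["label"]
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: expected 'SMILES<TAB>id' line, got {line!r}")
            smi, cid = parts[0], parts[1]
            if cid not in labels:
                raise ValueError(f"{path}: id {cid!r} missing from label sidecar")
            yield cid, smi, labels[cid], None, None


def _read_sdf_rows(path: Path):
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            # surfaced as an unparseable-SMILES row so lenient/strict applies
            yield f"_sdf_record_{i}", "", "0", None, None
            continue
        props = mol.GetPropsAsDict()
        if "id" not in props or "label" not in props:
            raise ValueError(f"{path}: SDF record {i} lacks 'id'/'label' properties")
        yield (
            str(props["id"]),
            Chem.MolToSmiles(mol),
            props["label"],
            props.get("taxon"),
            props.get("source"),
        )


def save_dataset(ds: LabeledDataset, path: str | Path, format: str | None = None) -> Path:
    """Write a dataset to CSV or SDF (round-trips ids, labels, canonical SMILES)."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "label", "taxon", "source"])
            for r in ds:
                writer.writerow([r.id, r.smiles, r.label, r.taxon or "", r.source or ""])
    elif fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        for r in ds:
            mol = Chem.MolFromSmiles(r.smiles)
            mol.SetProp("id", r.id)
            mol.SetProp("label", str(r.label))
            if r.taxon:
                mol.SetProp("taxon", r.taxon)
            if r.source:
                mol.SetProp("source", r.source)
            writer.write(mol)
        writer.close()
    else:
        raise ValueError(f"unsupported output format {fmt!r}")
    return path
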