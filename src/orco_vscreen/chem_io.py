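"""Molecule input, standardization and featurization.

This module defines the shared feature space used by every classifier in the
package: sparse hashed circular-fingerprint ids (Morgan environments of bond
radius 0..r, unfolded) unioned with one indicator id per (physicochemical
descriptor, quantile bin) pair.  Keeping fingerprints unfolded avoids folding
collisions, which matters because the naive-Bayes weights are per-feature
frequency estimates.

Structures are handled as SMILES throughout; standardization keeps the
largest organic fragment, neutralizes charges and canonicalizes atom order,
and is idempotent.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Feature ids at or above this value encode (descriptor, bin) indicators;
#: Morgan hash ids are 32-bit and always fall below it.
DESCRIPTOR_ID_BASE = 1 << 35

DESCRIPTOR_NAMES = ("alogp", "mw", "hbd", "hba", "rotb", "fpsa")

ACTIVE = "active"
INACTIVE = "inactive"


class MoleculeError(ValueError):
    """Raised for unparseable, inorganic or otherwise invalid structures."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One small molecule with a stable identifier.

    ``structure`` is a SMILES string; after :func:`standardize` it is the
    canonical form and ``standardized`` is True.  ``label`` (if present) is
    ``"active"`` or ``"inactive"``; ``ic50_um`` is only meaningful for
    actives.
    """

    id: str
    structure: str
    name: str = ""
    source: str = ""
    label: str | None = None
    ic50_um: float | None = None
    standardized: bool = False


@dataclass(frozen=True)
class Rejection:
    """A record that could not be parsed or standardized, with the reason."""

    id: str
    reason: str


@dataclass
class MoleculeSet:
    """Ordered collection of molecule records with unique ids."""

    records: list[MoleculeRecord]
    rejections: list[Rejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise MoleculeError(f"duplicate molecule ids: {dupes}")
        labels = [r.label for r in self.records]
        if any(l is not None for l in labels):
            bad = [r.id for r in self.records if r.label not in (ACTIVE, INACTIVE)]
            if bad:
                raise MoleculeError(f"records with missing/invalid labels: {bad}")
        bad_potency = [r.id for r in self.records if r.ic50_um is not None and r.label == INACTIVE]
        if bad_potency:
            raise MoleculeError(f"potency given for inactive records: {bad_potency}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str] | None:
        if all(r.label is None for r in self.records):
            return None
        return [r.label for r in self.records]  # type: ignore[return-value]

    def subset(self, ids: Iterable[str]) -> "MoleculeSet":
        keep = set(ids)
        return MoleculeSet([r for r in self.records if r.id in keep])

    @property
    def actives(self) -> "MoleculeSet":
        return MoleculeSet([r for r in self.records if r.label == ACTIVE])

    @property
    def inactives(self) -> "MoleculeSet":
        return MoleculeSet([r for r in self.records if r.label == INACTIVE])


# ---------------------------------------------------------------------------
# reading


def read_molecules(path: str | Path, format: str) -> MoleculeSet:
    """Read molecules from ``path`` in one of {sdf, smiles-lines, csv}.

    Every parseable record is returned with a stable id, in file order;
    unparseable records are collected on ``MoleculeSet.rejections`` rather
    than silently dropped.  A missing file, zero valid records or duplicate
    ids are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format in ("smi", "smiles", "smiles-lines"):
        records, rejections = _read_smiles_lines(path)
    elif format == "sdf":
        records, rejections = _read_sdf(path)
    elif format == "csv":
        records, rejections = _read_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected sdf, smiles-lines or csv")
    if not records:
        raise MoleculeError(f"no valid records in {path} (format={format})")
    return MoleculeSet(records, rejections)


def _read_smiles_lines(path: Path) -> tuple[list[MoleculeRecord], list[Rejection]]:
    records, rejections = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"L{lineno}"
            if Chem.MolFromSmiles(smiles) is None:
                rejections.append(Rejection(mol_id, f"line {lineno}: unparseable SMILES {smiles!r}"))
                continue
            records.append(MoleculeRecord(id=mol_id, structure=smiles, source=str(path)))
    return records, rejections


def _read_sdf(path: Path) -> tuple[list[MoleculeRecord], list[Rejection]]:
    records, rejections = [], []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejections.append(Rejection(f"SDF{i + 1}", f"entry {i + 1}: unparseable SDF record"))
            continue
        mol_id = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
        mol_id = mol_id or f"SDF{i + 1}"
        records.append(
            MoleculeRecord(id=mol_id, structure=Chem.MolToSmiles(mol), name=mol_id, source=str(path))
        )
    return records, rejections


def _read_csv(path: Path) -> tuple[list[MoleculeRecord], list[Rejection]]:
    records, rejections = [], []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(reader.fieldnames):
            raise MoleculeError(f"{path}: CSV must have columns id,smiles")
        for row in reader:
            mol_id = row["id"].strip()
            smiles = row["smiles"].strip()
            if Chem.MolFromSmiles(smiles) is None:
                rejections.append(Rejection(mol_id, f"unparseable SMILES {smiles!r}"))
                continue
            label = (row.get("label") or "").strip() or None
            ic50 = row.get("ic50_um")
            ic50_um = float(ic50) if ic50 not in (None, "") else None
            records.append(
                MoleculeRecord(
                    id=mol_id,
                    structure=smiles,
                    name=(row.get("name") or "").strip(),
                    source=str(path),
                    label=label,
                    ic50_um=ic50_um,
                )
            )
    return records, rejections


# ---------------------------------------------------------------------------
# standardization

_FRAGMENT_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize(record: MoleculeRecord) -> MoleculeRecord:
    """Standardize a record: largest organic fragment, neutralized, canonical.

    Idempotent: re-standardizing a standardized record returns an equal
    record.  Unparseable or carbon-free structures raise
    :class:`MoleculeError`.
    """
    mol = Chem.MolFromSmiles(record.structure)
    if mol is None:
        raise MoleculeError(f"{record.id}: unparseable structure {record.structure!r}")
    mol = _FRAGMENT_CHOOSER.choose(mol)
    if not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
        raise MoleculeError(f"{record.id}: no organic fragment in {record.structure!r}")
    mol = _UNCHARGER.uncharge(mol)
    smiles = Chem.MolToSmiles(mol)
    return replace(record, structure=smiles, standardized=True)


def standardize_set(mset: MoleculeSet) -> MoleculeSet:
    """Standardize every record, collecting per-record rejections."""
    records, rejections = [], list(mset.rejections)
    for rec in mset.records:
        try:
            records.append(standardize(rec))
        except MoleculeError as exc:
            rejections.append(Rejection(rec.id, str(exc)))
    if not records:
        raise MoleculeError("no records survived standardization")
    return MoleculeSet(records, rejections)


# ---------------------------------------------------------------------------
# fingerprints and descriptors

_MORGAN_GENERATORS: dict[int, object] = {}


def _morgan_generator(radius: int):
    if radius not in _MORGAN_GENERATORS:
        _MORGAN_GENERATORS[radius] = rdFingerprintGenerator.GetMorganGenerator(radius=radius)
    return _MORGAN_GENERATORS[radius]


def _mol(record: MoleculeRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.structure)
    if mol is None:  # pragma: no cover - standardized structures always parse
        raise MoleculeError(f"{record.id}: unparseable structure")
    return mol


def circular_fingerprint(record: MoleculeRecord, radius: int = 2) -> frozenset[int]:
    """Sparse hashed circular-environment ids for radius 0..``radius``.

    radius=2 corresponds to ECFP4-style features, radius=3 to ECFP6-style.
    The record must be standardized first so that equivalent inputs map to
    identical feature sets.
    """
    if radius not in (1, 2, 3):
        raise ValueError("radius must be 1, 2 or 3")
    if not record.standardized:
        raise MoleculeError(f"{record.id}: standardize the record before fingerprinting")
    fp = _morgan_generator(radius).GetSparseCountFingerprint(_mol(record))
    return frozenset(fp.GetNonzeroElements())


@dataclass(frozen=True)
class DescriptorVector:
    """The six physicochemical descriptors fed to the classifiers."""

    alogp: float
    mw: float
    hbd: int
    hba: int
    rotb: int
    fpsa: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.alogp, self.mw, float(self.hbd), float(self.hba), float(self.rotb), self.fpsa)


def physchem_descriptors(record: MoleculeRecord) -> DescriptorVector:
    """AlogP, molecular weight, HBD/HBA counts, rotatable bonds, fractional PSA.

    Fractional polar surface area is the topological PSA divided by the
    Labute approximate surface area, clipped to [0, 1].
    """
    if not record.standardized:
        raise MoleculeError(f"{record.id}: standardize the record before computing descriptors")
    mol = _mol(record)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    asa = rdMolDescriptors.CalcLabuteASA(mol)
    fpsa = float(np.clip(tpsa / asa, 0.0, 1.0)) if asa > 0 else 0.0
    return DescriptorVector(
        alogp=Crippen.MolLogP(mol),
        mw=Descriptors.MolWt(mol),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rotb=Descriptors.NumRotatableBonds(mol),
        fpsa=fpsa,
    )


# ---------------------------------------------------------------------------
# descriptor binning


@dataclass
class BinningScheme:
    """Per-descriptor quantile cut points learned from a training set.

    Cut points are strictly increasing; values map to a bin by right-open
    search, so the outer bins are open-ended and every real value maps to
    exactly one bin.  The scheme is frozen after fitting and reused unchanged
    at prediction time.
    """

    n_bins: int
    cut_points: dict[str, list[float]]

    @classmethod
    def fit(cls, descriptors: Sequence[DescriptorVector], n_bins: int = 10) -> "BinningScheme":
        if not descriptors:
            raise ValueError("cannot fit a binning scheme on zero molecules")
        mat = np.array([d.as_tuple() for d in descriptors], dtype=float)
        cuts: dict[str, list[float]] = {}
        qs = np.arange(1, n_bins) / n_bins
        for j, name in enumerate(DESCRIPTOR_NAMES):
            pts = np.unique(np.quantile(mat[:, j], qs))
            cuts[name] = [float(p) for p in pts]
        return cls(n_bins=n_bins, cut_points=cuts)

    def bin_index(self, name: str, value: float) -> int:
        return int(np.searchsorted(self.cut_points[name], value, side="left"))

    def feature_ids(self, desc: DescriptorVector) -> frozenset[int]:
        ids = []
        for j, name in enumerate(DESCRIPTOR_NAMES):
            b = self.bin_index(name, desc.as_tuple()[j])
            ids.append(DESCRIPTOR_ID_BASE + j * self.n_bins + b)
        return frozenset(ids)

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "cut_points": self.cut_points}

    @classmethod
    def from_dict(cls, d: dict) -> "BinningScheme":
        return cls(n_bins=int(d["n_bins"]), cut_points={k: list(map(float, v)) for k, v in d["cut_points"].items()})


def featurize(record: MoleculeRecord, radius: int, scheme: BinningScheme | None) -> frozenset[int]:
    """Union of circular-fingerprint ids and descriptor-bin indicator ids.

    The two id families live in disjoint ranges (Morgan hashes are 32-bit;
    descriptor ids start at :data:`DESCRIPTOR_ID_BASE`), so the union size is
    always fingerprint count + number of descriptors.
    """
    fps = circular_fingerprint(record, radius)
    if scheme is None:
        return fps
    return fps | scheme.feature_ids(physchem_descriptors(record))


@dataclass
class Featurizer:
    """Frozen featurization config: fingerprint radius plus a trained scheme."""

    radius: int = 2
    n_bins: int = 10
    use_descriptors: bool = True
    scheme: BinningScheme | None = None

    def fit(self, records: Iterable[MoleculeRecord]) -> "Featurizer":
        if self.use_descriptors:
            self.scheme = BinningScheme.fit([physchem_descriptors(r) for r in records], self.n_bins)
        return self

    def transform(self, record: MoleculeRecord) -> frozenset[int]:
        if self.use_descriptors and self.scheme is None:
            raise ValueError("Featurizer must be fit before transform")
        return featurize(record, self.radius, self.scheme if self.use_descriptors else None)

    def fit_transform(self, records: Sequence[MoleculeRecord]) -> list[frozenset[int]]:
        self.fit(records)
        return [self.transform(r) for r in records]

    def to_dict(self) -> dict:
        return {
            "radius": self.radius,
            "n_bins": self.n_bins,
            "use_descriptors": self.use_descriptors,
            "scheme": self.scheme.to_dict() if self.scheme else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Featurizer":
        return cls(
            radius=int(d["radius"]),
            n_bins=int(d["n_bins"]),
            use_descriptors=bool(d["use_descriptors"]),
            scheme=BinningScheme.from_dict(d["scheme"]) if d.get("scheme") else None,
        )


# ---------------------------------------------------------------------------
# writers


def write_standardized_table(mset: MoleculeSet, path: str | Path) -> None:
    """CSV of id, name, canonical structure plus any rejection reasons."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "name", "structure", "rejection_reason"])
        for rec in mset.records:
            writer.writerow([rec.id, rec.name, rec.structure, ""])
        for rej in mset.rejections:
            writer.writerow([rej.id, "", "", rej.reason])


def write_featurization_manifest(featurizer: Featurizer, path: str | Path) -> None:
    manifest = featurizer.to_dict()
    manifest["descriptor_id_base"] = DESCRIPTOR_ID_BASE
    manifest["descriptor_names"] = list(DESCRIPTOR_NAMES)
    Path(path).write_text(json.dumps(manifest, indent=2))
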