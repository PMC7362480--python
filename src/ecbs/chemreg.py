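"""Molecule ingestion, fingerprinting, canonical keys and Tanimoto similarity.

Molecules enter the toolkit either as parsed chemical structures (SMILES, SDF
or CSV, handled by RDKit) or as precomputed fingerprint bit vectors (the
synthetic universe uses the latter).  Every molecule carries a *canonical key*
— the standard InChIKey when the structure is available — used to remove
redundancy between training and test molecules, and one or more fixed-length
bit fingerprints used for similarity calculations.

Two fingerprint schemes are exposed:

``maccs``
    The 167-bit MACCS structural key set as implemented by RDKit.
``fp4-like``
    A fixed, documented list of SMARTS functional-group patterns in the
    spirit of the OpenBabel FP4 scheme.  Bit identity with the original tool
    is not promised; the pattern list below is the definition.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

FINGERPRINT_SCHEMES = ("maccs", "fp4-like")

# Functional-group SMARTS defining the "fp4-like" scheme.  One bit per
# pattern, set when the molecule contains at least one match.
FP4_LIKE_SMARTS: tuple[tuple[str, str], ...] = (
    ("alcohol", "[OX2H][CX4]"),
    ("phenol", "[OX2H]c"),
    ("carboxylic_acid", "[CX3](=O)[OX2H1]"),
    ("carboxylate", "[CX3](=O)[O-]"),
    ("ester", "[CX3](=O)[OX2H0][#6]"),
    ("amide", "[NX3][CX3](=[OX1])"),
    ("primary_amine", "[NX3;H2;!$(NC=O)]"),
    ("secondary_amine", "[NX3;H1;!$(NC=O)]([#6])[#6]"),
    ("tertiary_amine", "[NX3;H0;!$(NC=O);!$(N=O)]([#6])([#6])[#6]"),
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("ketone", "[#6][CX3](=O)[#6]"),
    ("ether", "[OD2]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("disulfide", "[SX2][SX2]"),
    ("sulfoxide", "[SX3](=[OX1])([#6])[#6]"),
    ("sulfone", "[SX4](=[OX1])(=[OX1])([#6])[#6]"),
    ("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("nitro", "[NX3](=O)=O"),
    ("azo", "[NX2]=[NX2]"),
    ("imine", "[CX3]=[NX2]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2]"),
    ("halide_f", "[F]"),
    ("halide_cl", "[Cl]"),
    ("halide_br", "[Br]"),
    ("halide_i", "[I]"),
    ("aromatic_ring", "a1aaaaa1"),
    ("aromatic_5ring", "a1aaaa1"),
    ("aromatic_n", "n"),
    ("aromatic_o", "o"),
    ("aromatic_s", "s"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("phosphate", "[PX4](=[OX1])([OX2])([OX2])[OX2]"),
    ("heterocycle_n", "[#7;R]"),
    ("heterocycle_o", "[#8;R]"),
    ("fused_rings", "[R2]"),
    ("quaternary_c", "[CX4]([#6])([#6])([#6])[#6]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("anhydride", "[CX3](=[OX1])[OX2][CX3](=[OX1])"),
    ("enol_ether", "[OX2][CX3]=[CX3]"),
    ("hydrazine", "[NX3][NX3]"),
    ("hydroxylamine", "[NX3][OX2H]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
)

_FP4_MOLS = tuple(Chem.MolFromSmarts(s) for _, s in FP4_LIKE_SMARTS)


class ParseError(ValueError):
    """A structure could not be parsed or a file yielded no molecules."""


@dataclass
class Molecule:
    """One chemical entity: id, optional structure, fingerprints and key.

    ``structure`` is a SMILES string, or None for fingerprint-native
    (synthetic) molecules whose bits were supplied directly.
    """

    mol_id: str
    structure: str | None = None
    fingerprints: dict[str, np.ndarray] = field(default_factory=dict)
    canonical_key: str = ""

    def fingerprint(self, scheme: str) -> np.ndarray:
        """Return (computing and caching if needed) the bits for ``scheme``."""
        if scheme not in self.fingerprints:
            self.fingerprints[scheme] = compute_fingerprint(self, scheme)
        return self.fingerprints[scheme]


@dataclass
class MoleculeSet:
    molecules: list[Molecule]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [m.mol_id for m in self.molecules]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate mol_ids within a MoleculeSet")

    def __len__(self) -> int:
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def ids(self) -> list[str]:
        return [m.mol_id for m in self.molecules]

    def by_id(self) -> dict[str, Molecule]:
        return {m.mol_id: m for m in self.molecules}

    def fingerprint_map(self, scheme: str) -> dict[str, np.ndarray]:
        return {m.mol_id: m.fingerprint(scheme) for m in self.molecules}

    def drop_duplicate_structures(self) -> "MoleculeSet":
        """Keep the first molecule per canonical key (set semantics)."""
        seen: set[str] = set()
        kept = []
        for m in self.molecules:
            if m.canonical_key in seen:
                continue
            seen.add(m.canonical_key)
            kept.append(m)
        return MoleculeSet(kept, provenance=self.provenance)


def _mol_from_smiles(smiles: str) -> Chem.Mol | None:
    return Chem.MolFromSmiles(smiles)


def canonical_key(m: Molecule) -> str:
    """Structure-identity key, invariant under atom-order permutation.

    Uses the standard InChIKey when RDKit can generate one; otherwise falls
    back to a SHA-256 digest of the canonical SMILES (prefixed ``SHA256:`` so
    outputs record which generator produced the key).  Hash collisions are
    negligible at any realistic library size.
    """
    if m.structure is None:
        if m.canonical_key:
            return m.canonical_key
        raise ParseError(f"molecule {m.mol_id!r} has neither structure nor key")
    rd = _mol_from_smiles(m.structure)
    if rd is None:
        raise ParseError(f"unparseable structure for {m.mol_id!r}: {m.structure!r}")
    try:
        key = Chem.MolToInchiKey(rd)
    except Exception:  # pragma: no cover - InChI unavailable in some builds
        key = ""
    if key:
        return key
    canon = Chem.MolToSmiles(rd)
    return "SHA256:" + hashlib.sha256(canon.encode()).hexdigest()


def fingerprint_key_for_bits(bits: np.ndarray) -> str:
    """Canonical key for a fingerprint-native molecule (no structure)."""
    packed = np.packbits(np.asarray(bits, dtype=np.uint8))
    return "FPSHA256:" + hashlib.sha256(packed.tobytes()).hexdigest()


def compute_fingerprint(m: Molecule, scheme: str) -> np.ndarray:
    """Bit-vector fingerprint of ``m`` under ``scheme`` (uint8 0/1 array)."""
    if scheme not in FINGERPRINT_SCHEMES:
        raise ValueError(f"unknown fingerprint scheme {scheme!r}; "
                         f"expected one of {FINGERPRINT_SCHEMES}")
    if m.structure is None:
        raise ParseError(f"molecule {m.mol_id!r} has no structure to fingerprint")
    rd = _mol_from_smiles(m.structure)
    if rd is None:
        raise ParseError(f"unparseable structure for {m.mol_id!r}")
    if scheme == "maccs":
        keys = MACCSkeys.GenMACCSKeys(rd)
        return np.array([int(b) for b in keys.ToBitString()], dtype=np.uint8)
    bits = np.zeros(len(_FP4_MOLS), dtype=np.uint8)
    for i, patt in enumerate(_FP4_MOLS):
        if patt is not None and rd.HasSubstructMatch(patt):
            bits[i] = 1
    return bits


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| over bit vectors.

    Raises on length mismatch, and on a pair of all-zero vectors rather than
    defining 0/0 as zero — an empty fingerprint almost always indicates an
    ingest bug upstream.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise ValueError("both fingerprints are all-zero; Tanimoto undefined")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def parse_molecules(path: str | Path, fmt: str = "smiles") -> MoleculeSet:
    """Read molecules from ``path`` in ``fmt`` ∈ {smiles, sdf, csv}.

    Parse failures are counted and logged, not fatal; a file yielding zero
    parseable molecules raises :class:`ParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    records: list[tuple[str, str]] = []  # (mol_id, smiles) or sdf mols
    mols: list[Molecule] = []
    failures = 0

    if fmt == "smiles":
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i + 1}"
            records.append((mol_id, smi))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"mol_id", "smiles"} <= set(reader.fieldnames):
                raise ValueError("CSV must have columns mol_id,smiles")
            for row in reader:
                records.append((row["mol_id"], row["smiles"]))
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path))
        for i, rd in enumerate(supplier):
            if rd is None:
                failures += 1
                continue
            mol_id = rd.GetProp("_Name") if rd.HasProp("_Name") and rd.GetProp("_Name") else f"mol{i + 1}"
            records.append((mol_id, Chem.MolToSmiles(rd)))
    else:
        raise ValueError(f"unsupported format {fmt!r}")

    for mol_id, smi in records:
        rd = _mol_from_smiles(smi)
        if rd is None:
            failures += 1
            logger.warning("failed to parse %r (%s)", mol_id, smi)
            continue
        m = Molecule(mol_id=mol_id, structure=smi)
        m.canonical_key = canonical_key(m)
        mols.append(m)

    if failures:
        logger.warning("%d structure(s) failed to parse in %s", failures, path)
    if not mols:
        raise ParseError(f"no parseable molecules in {path}")
    return MoleculeSet(mols, provenance=str(path))


def deduplicate(train: MoleculeSet, test: MoleculeSet) -> MoleculeSet:
    """Remove from ``test`` every molecule whose canonical key occurs in ``train``.

    This is the redundancy check applied between model-training molecules and
    evaluation molecules so that benchmark scores are not inflated by exact
    structure overlap.
    """
    train_keys = {m.canonical_key for m in train.molecules}
    kept = [m for m in test.molecules if m.canonical_key not in train_keys]
    if not kept:
        logger.warning("deduplicate: every test molecule also occurs in train")
    return MoleculeSet(kept, provenance=test.provenance)


def write_fingerprint_matrix(ms: MoleculeSet, scheme: str, path: str | Path) -> None:
    """Audit writer: mol_id plus one 0/1 column per fingerprint bit."""
    rows = []
    for m in ms:
        bits = m.fingerprint(scheme)
        rows.append([m.mol_id] + [int(b) for b in bits])
    n_bits = len(rows[0]) - 1 if rows else 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id"] + [f"bit{i}" for i in range(n_bits)])
        writer.writerows(rows)


def molecule_from_bits(mol_id: str, bits: Iterable[int],
                       scheme: str = "synthetic") -> Molecule:
    """Build a fingerprint-native molecule (used by the synthetic universe)."""
    arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits,
                     dtype=np.uint8)
    m = Molecule(mol_id=mol_id, structure=None, fingerprints={scheme: arr})
    m.canonical_key = fingerprint_key_for_bits(arr)
    return m
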