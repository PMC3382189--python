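"""The 30-ligand dopamine-D2 training set and ligand preparation.

The shipped library holds 13 full agonists, 5 partial agonists and 12
structurally similar inactives, encoded as isomeric SMILES with activity
labels. Ligands are prepared for screening by protonating the most basic
aliphatic or alicyclic nitrogen (+1), the physiological-pH form that
engages the Asp-TM3 salt bridge; phenols stay neutral.

Tertiary-amine ligands carry ``amine_config_policy = "enumerate"``: on
protonation the ring nitrogen becomes pyramidal and effectively chiral,
and both configurations are used in the modeling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable

from rdkit import Chem

ACTIVITY_CLASSES = ("full", "partial", "inactive")
CONFIG_POLICIES = ("fixed", "enumerate")


class LigandError(ValueError):
    pass


@dataclass(frozen=True)
class LigandRecord:
    """One training-set ligand: short name, isomeric SMILES, activity label."""

    id: str
    smiles: str
    activity_class: str
    amine_config_policy: str = "fixed"

    def __post_init__(self) -> None:
        if self.activity_class not in ACTIVITY_CLASSES:
            raise LigandError(f"unknown activity class {self.activity_class!r}")
        if self.amine_config_policy not in CONFIG_POLICIES:
            raise LigandError(f"unknown config policy {self.amine_config_policy!r}")


def build_library() -> list[LigandRecord]:
    """Load the shipped 30-ligand training set (13 full / 5 partial / 12 inactive)."""
    path = resources.files("d2pharm.data").joinpath("ligands.tsv")
    with path.open("r") as fh:
        return read_library(fh)


def read_library(handle: Iterable[str]) -> list[LigandRecord]:
    reader = csv.DictReader(handle, delimiter="\t")
    records = []
    for row in reader:
        rec = LigandRecord(
            id=row["id"],
            smiles=row["smiles"],
            activity_class=row["activity_class"],
            amine_config_policy=row["amine_config_policy"],
        )
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            raise LigandError(f"ligand {rec.id}: SMILES does not parse")
        if len(Chem.GetMolFrags(mol)) != 1:
            raise LigandError(f"ligand {rec.id}: SMILES is not a single molecule")
        records.append(rec)
    return records


def read_smiles_file(handle: Iterable[str], activity_class: str = "inactive") -> list[LigandRecord]:
    """Read a ``.smi``-style file (SMILES followed by an optional name).

    External ligand sets carry no activity labels; ``activity_class`` is
    assigned uniformly (default "inactive", the conservative choice when
    screening unknowns against an agonist model).
    """
    records = []
    for i, line in enumerate(handle):
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        smiles = parts[0]
        name = parts[1] if len(parts) > 1 else f"mol{i + 1}"
        if Chem.MolFromSmiles(smiles) is None:
            raise LigandError(f"line {i + 1}: SMILES does not parse")
        records.append(LigandRecord(id=name, smiles=smiles, activity_class=activity_class))
    return records


def write_library(records: Iterable[LigandRecord], handle) -> None:
    handle.write("id\tsmiles\tactivity_class\tamine_config_policy\n")
    for rec in records:
        handle.write(
            f"{rec.id}\t{rec.smiles}\t{rec.activity_class}\t{rec.amine_config_policy}\n"
        )


def _is_amide_nitrogen(atom: Chem.Atom) -> bool:
    for nbr in atom.GetNeighbors():
        if nbr.GetSymbol() == "C":
            for bond in nbr.GetBonds():
                other = bond.GetOtherAtom(nbr)
                if other.GetSymbol() in ("O", "S") and bond.GetBondTypeAsDouble() == 2.0:
                    return True
    return False


def basic_nitrogen(mol: Chem.Mol) -> int:
    """Index of the most basic nitrogen: aliphatic, non-amide, non-anilinic.

    Raises :class:`LigandError` when the molecule has no credible basic
    nitrogen (every training-set ligand has exactly one).
    """
    candidates = []
    for atom in mol.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetIsAromatic():
            continue
        if atom.GetFormalCharge() != 0:
            continue
        if _is_amide_nitrogen(atom):
            continue
        if any(nbr.GetIsAromatic() for nbr in atom.GetNeighbors()):
            continue  # anilines / 2-aminoazoles are far less basic
        candidates.append(atom.GetIdx())
    if not candidates:
        raise LigandError("no basic nitrogen found")
    # Prefer the nitrogen with more heavy neighbours (ring amines before
    # primary amines) and break remaining ties by index for determinism.
    candidates.sort(key=lambda i: (-mol.GetAtomWithIdx(i).GetDegree(), i))
    return candidates[0]


def prepare_mol(record: LigandRecord) -> Chem.Mol:
    """RDKit molecule for a ligand: canonical atom order, basic N protonated.

    Canonicalising the atom order before any embedding makes conformer
    generation invariant to how the input SMILES happened to be written.
    """
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise LigandError(f"ligand {record.id}: SMILES does not parse")
    # round-trip through canonical SMILES: atom *and* bond order become
    # functions of the molecular graph alone, not of the input writing
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    already = [a for a in mol.GetAtoms() if a.GetSymbol() == "N" and a.GetFormalCharge() == 1]
    if not already:
        atom = mol.GetAtomWithIdx(basic_nitrogen(mol))
        atom.SetFormalCharge(1)
        atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
        atom.SetNoImplicit(True)
    Chem.SanitizeMol(mol)
    mol.SetProp("_Name", record.id)
    return mol


def enumerate_amine_configs(record: LigandRecord) -> list[LigandRecord]:
    """Both pyramidal configurations of a protonated tertiary amine.

    The protonated amine nitrogen of a ring-constrained tertiary amine is
    effectively a stereocentre; both configurations are screened. Returns
    two records sharing the parent id. Raises :class:`LigandError` when the
    ligand has no tertiary amine.
    """
    mol = prepare_mol(record)
    idx = next(
        a.GetIdx() for a in mol.GetAtoms() if a.GetFormalCharge() == 1 and a.GetSymbol() == "N"
    )
    atom = mol.GetAtomWithIdx(idx)
    if atom.GetDegree() != 3:
        raise LigandError(f"ligand {record.id}: not applicable (no tertiary amine)")
    out = []
    for tag in (Chem.ChiralType.CHI_TETRAHEDRAL_CW, Chem.ChiralType.CHI_TETRAHEDRAL_CCW):
        variant = Chem.Mol(mol)
        variant.GetAtomWithIdx(idx).SetChiralTag(tag)
        smi = Chem.MolToSmiles(variant)
        out.append(replace(record, smiles=smi))
    return out
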