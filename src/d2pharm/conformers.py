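"""Conformer ensemble generation inside a strain-energy window.

Ensembles are produced by distance-geometry embedding (ETKDGv3) followed by
MMFF94S optimisation and strain ranking. Conformers more than ``window``
kcal/mol above the ensemble minimum are discarded, matching the 4 kcal/mol
energy cutoff the screening protocol assumes. Generation is deterministic
for a fixed seed and, because ligand preparation canonicalises atom order,
invariant to how the input was written.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .ligands import LigandRecord, enumerate_amine_configs, prepare_mol

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 4.0  # kcal/mol
DEFAULT_MAX_CONFS = 300
DEFAULT_SEED = 2012

_PRUNE_RMS = 0.3  # Å, heavy-atom RMS threshold for duplicate conformers


class ConformerGenerationError(RuntimeError):
    pass


@dataclass
class Conformer:
    """One 3D embedding of a ligand with its relative strain energy."""

    ligand_id: str
    mol: Chem.Mol  # molecule with explicit hydrogens
    conf_id: int
    delta_e: float  # kcal/mol above the ensemble minimum
    seed_tag: str

    @property
    def coords_all(self) -> np.ndarray:
        return np.array(self.mol.GetConformer(self.conf_id).GetPositions(), dtype=float)

    @property
    def heavy_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    @property
    def coords_heavy(self) -> np.ndarray:
        return self.coords_all[self.heavy_indices]

    @property
    def coords(self) -> np.ndarray:
        """Heavy atoms plus polar hydrogens (hydrogens on N or O)."""
        keep = [
            a.GetIdx()
            for a in self.mol.GetAtoms()
            if a.GetAtomicNum() > 1
            or any(n.GetSymbol() in ("N", "O") for n in a.GetNeighbors())
        ]
        return self.coords_all[keep]


@dataclass
class ConformerEnsemble:
    """Conformers of one ligand, sorted by strain energy ascending."""

    ligand_id: str
    conformers: list[Conformer]
    window: float
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ConformerGenerationError(
                f"conformer generation failed for {self.ligand_id}: empty ensemble"
            )

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)


def _embed_and_rank(
    mol: Chem.Mol, window: float, max_confs: int, seed: int
) -> tuple[Chem.Mol, list[tuple[int, float]]]:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    params.numThreads = 1
    params.pruneRmsThresh = _PRUNE_RMS
    params.useRandomCoords = False
    ids = AllChem.EmbedMultipleConfs(molh, numConfs=max_confs, params=params)
    if len(ids) == 0:
        raise ConformerGenerationError("conformer generation failed: embedding produced none")
    results = AllChem.MMFFOptimizeMoleculeConfs(
        molh, mmffVariant="MMFF94s", maxIters=500, numThreads=1
    )
    energies = []
    for cid, (converged, energy) in zip(ids, results):
        if converged == -1:  # force-field setup failure
            raise ConformerGenerationError("conformer generation failed: no MMFF parameters")
        energies.append((int(cid), float(energy)))
    emin = min(e for _, e in energies)
    kept = [(cid, e - emin) for cid, e in energies if e - emin <= window]
    kept.sort(key=lambda t: (t[1], t[0]))
    # Post-optimisation duplicate pruning: optimisation funnels distinct
    # embeddings into the same minimum; keep the lowest-energy exemplar.
    unique: list[tuple[int, float]] = []
    mol_noh = Chem.RemoveHs(Chem.Mol(molh))
    for cid, de in kept:
        dup = False
        # duplicates land in the same minimum, so their optimised energies
        # agree closely; only those pairs need the expensive RMS check
        for uid, ude in unique:
            if abs(de - ude) > 0.1:
                continue
            rms = AllChem.GetBestRMS(mol_noh, mol_noh, prbId=cid, refId=uid)
            if rms < _PRUNE_RMS:
                dup = True
                break
        if not dup:
            unique.append((cid, de))
    return molh, unique


def generate_conformers(
    ligand: LigandRecord,
    window: float = DEFAULT_WINDOW,
    max_confs: int = DEFAULT_MAX_CONFS,
    seed: int = DEFAULT_SEED,
) -> ConformerEnsemble:
    """Seeded conformer ensemble for one ligand within the energy window.

    For ligands flagged ``amine_config_policy = "enumerate"`` both pyramidal
    configurations of the protonated tertiary amine are embedded and the two
    sub-ensembles merged, with strain energies re-referenced to the overall
    minimum.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if max_confs < 1:
        raise ValueError("max_confs must be >= 1")

    if ligand.amine_config_policy == "enumerate":
        variants = enumerate_amine_configs(ligand)
        per_variant = max(1, max_confs // len(variants))
    else:
        variants = [ligand]
        per_variant = max_confs

    raw: list[tuple[Chem.Mol, int, float, str]] = []
    for vi, variant in enumerate(variants):
        mol = prepare_mol(variant)
        vseed = (seed + 7919 * vi) & 0x7FFFFFFF
        try:
            molh, ranked = _embed_and_rank(mol, window, per_variant, vseed)
        except ConformerGenerationError as err:
            raise ConformerGenerationError(
                f"conformer generation failed for {ligand.id}: {err}"
            ) from err
        tag = f"etkdg3-mmff94s:seed={vseed}"
        for cid, de in ranked:
            raw.append((molh, cid, de, tag))

    # merge variants: re-reference strain to the global minimum
    demin = min(de for _, _, de, _ in raw)
    raw = [(m, cid, de - demin, tag) for m, cid, de, tag in raw if de - demin <= window]
    raw.sort(key=lambda t: (t[2], t[3], t[1]))
    confs = [
        Conformer(ligand_id=ligand.id, mol=m, conf_id=cid, delta_e=de, seed_tag=tag)
        for m, cid, de, tag in raw
    ]
    log.debug("%s: %d conformers within %.1f kcal/mol", ligand.id, len(confs), window)
    return ConformerEnsemble(
        ligand_id=ligand.id,
        conformers=confs,
        window=window,
        generator_params={"method": "etkdg3-mmff94s", "max_confs": max_confs, "seed": seed},
    )


def generate_library_ensembles(
    records: list[LigandRecord],
    window: float = DEFAULT_WINDOW,
    max_confs: int = DEFAULT_MAX_CONFS,
    seed: int = DEFAULT_SEED,
) -> dict[str, ConformerEnsemble]:
    """Ensembles for a whole library, each ligand seeded independently."""
    out = {}
    for i, rec in enumerate(records):
        out[rec.id] = generate_conformers(
            rec, window=window, max_confs=max_confs, seed=(seed + 104729 * i) & 0x7FFFFFFF
        )
    return out


def write_sdf(ensemble: ConformerEnsemble, path: str) -> None:
    """Multi-record SDF with ``delta_e`` and ``seed_tag`` SD tags."""
    writer = Chem.SDWriter(str(path))
    try:
        for conf in ensemble:
            mol = Chem.Mol(conf.mol)
            mol.SetProp("_Name", conf.ligand_id)
            mol.SetProp("delta_e", f"{conf.delta_e:.6f}")
            mol.SetProp("seed_tag", conf.seed_tag)
            writer.write(mol, confId=conf.conf_id)
    finally:
        writer.close()


def read_sdf(path: str, window: float = DEFAULT_WINDOW) -> ConformerEnsemble:
    """Read an ensemble written by :func:`write_sdf`."""
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    confs = []
    name = None
    for mol in supplier:
        if mol is None:
            continue
        name = mol.GetProp("_Name")
        confs.append(
            Conformer(
                ligand_id=name,
                mol=mol,
                conf_id=0,
                delta_e=float(mol.GetProp("delta_e")),
                seed_tag=mol.GetProp("seed_tag") if mol.HasProp("seed_tag") else "",
            )
        )
    confs.sort(key=lambda c: c.delta_e)
    return ConformerEnsemble(ligand_id=name or "", conformers=confs, window=window)
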