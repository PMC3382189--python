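"""Independent reference implementations used only to check the package.

Everything here is deliberately naive: exhaustive enumeration and textbook
formulas, kept separate from the code paths they validate.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def kabsch_scipy(source: np.ndarray, target: np.ndarray):
    """Rigid superposition via scipy's align_vectors."""
    sc = source.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, source - sc)
    R = rot.as_matrix()
    t = tc - R @ sc
    return R, t


def rmsd_after_kabsch(source: np.ndarray, target: np.ndarray) -> float:
    R, t = kabsch_scipy(source, target)
    moved = source @ R.T + t
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def brute_force_match(points, features, excluded_volumes=(), exclo=None, heavy=None):
    """Exhaustive matcher for small instances.

    ``points``: list of (kind, xyz, direction-or-None)
    ``features``: list of (name, kinds, center, radius, essential, direction,
    direction_tol). Returns (best_rmsd, matched_names) or None. Enumerates
    every subset of optional features, every injective assignment and both
    aromatic normal signs; no pruning.
    """
    essentials = [f for f in features if f[4]]
    optionals = [f for f in features if not f[4]]
    best = None
    for r in range(len(optionals) + 1):
        for subset in itertools.combinations(optionals, r):
            feats = essentials + list(subset)
            pools = []
            for f in feats:
                pools.append([i for i, p in enumerate(points) if p[0] in f[1]])
            for combo in itertools.product(*pools):
                if len(set(combo)) != len(combo):
                    continue
                chosen = [points[i] for i in combo]
                sign_opts = []
                for f, p in zip(feats, chosen):
                    if f[5] is not None and p[2] is not None:
                        sign_opts.append((1.0, -1.0) if "aromatic" in f[1] else (1.0,))
                    else:
                        sign_opts.append((0.0,))
                for signs in itertools.product(*sign_opts):
                    src, dst = [], []
                    for f, p, s in zip(feats, chosen, signs):
                        src.append(p[1])
                        dst.append(f[2])
                        if s != 0.0:
                            src.append(np.asarray(p[1]) + s * np.asarray(p[2]))
                            dst.append(np.asarray(f[2]) + np.asarray(f[5]))
                    src = np.asarray(src, dtype=float)
                    dst = np.asarray(dst, dtype=float)
                    if len(src) < 3:
                        continue
                    R, t = kabsch_scipy(src, dst)
                    moved = np.asarray([p[1] for p in chosen]) @ R.T + t
                    ok = True
                    for f, m in zip(feats, moved):
                        if np.linalg.norm(m - f[2]) > f[3] + 1e-9:
                            ok = False
                            break
                    if not ok:
                        continue
                    for f, p, s in zip(feats, chosen, signs):
                        if s == 0.0:
                            continue
                        moved_dir = R @ (s * np.asarray(p[2]))
                        cosang = np.clip(
                            np.dot(moved_dir, f[5])
                            / (np.linalg.norm(moved_dir) * np.linalg.norm(f[5])),
                            -1,
                            1,
                        )
                        if np.degrees(np.arccos(cosang)) > f[6] + 1e-9:
                            ok = False
                            break
                    if not ok:
                        continue
                    if heavy is not None and len(excluded_volumes):
                        hm = np.asarray(heavy) @ R.T + t
                        clash = False
                        for c, rad in excluded_volumes:
                            if np.any(np.linalg.norm(hm - c, axis=1) < rad - 1e-9):
                                clash = True
                                break
                        if clash:
                            continue
                    moved_all = src @ R.T + t
                    fit = float(np.sqrt(np.mean(np.sum((moved_all - dst) ** 2, axis=1))))
                    if best is None or fit < best[0] - 1e-12:
                        best = (fit, tuple(f[0] for f in feats))
    return best


def torsion_grid_conformer_count(mol, window: float, step_deg: float = 30.0) -> int:
    """Exhaustive torsion-grid count of distinct minima within the window.

    Drives every non-terminal, non-ring single bond between heavy atoms
    through a grid, optimises each grid point with MMFF94S, and counts
    distinct resulting minima (deduplicated by heavy-atom RMSD) within the
    strain window. Intended for tiny, acyclic-chain molecules only.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from rdkit.Chem.rdMolTransforms import SetDihedralDeg

    molh = Chem.AddHs(Chem.Mol(mol))
    AllChem.EmbedMolecule(molh, randomSeed=17)
    AllChem.MMFFOptimizeMolecule(molh, mmffVariant="MMFF94s", maxIters=500)

    rot = Chem.MolFromSmarts("[!$([#1])&!$(*#*)&!D1]-&!@[!$([#1])&!$(*#*)&!D1]")
    torsions = []
    for a, b in molh.GetSubstructMatches(rot):
        an = [n.GetIdx() for n in molh.GetAtomWithIdx(a).GetNeighbors()
              if n.GetIdx() != b and n.GetAtomicNum() > 1]
        bn = [n.GetIdx() for n in molh.GetAtomWithIdx(b).GetNeighbors()
              if n.GetIdx() != a and n.GetAtomicNum() > 1]
        if an and bn:
            torsions.append((an[0], a, b, bn[0]))
    grid = np.arange(0.0, 360.0, step_deg)

    seen = []
    energies = []
    base = Chem.Mol(molh)
    heavy_ref = Chem.RemoveHs(Chem.Mol(molh))
    for angles in itertools.product(grid, repeat=len(torsions)):
        work = Chem.Mol(base)
        conf = work.GetConformer()
        for (i, j, k, l), ang in zip(torsions, angles):
            SetDihedralDeg(conf, i, j, k, l, float(ang))
        ff = AllChem.MMFFGetMoleculeForceField(
            work, AllChem.MMFFGetMoleculeProperties(work, mmffVariant="MMFF94s")
        )
        ff.Minimize(maxIts=500)
        energies.append(ff.CalcEnergy())
        seen.append(work)
    emin = min(energies)
    kept = [(m, e) for m, e in zip(seen, energies) if e - emin <= window]

    unique = []
    for m, e in sorted(kept, key=lambda t: t[1]):
        m_noh = Chem.RemoveHs(Chem.Mol(m))
        dup = False
        for u, ue in unique:
            if abs(e - ue) <= 0.1:
                rms = AllChem.GetBestRMS(m_noh, u)
                if rms < 0.3:
                    dup = True
                    break
        if not dup:
            unique.append((m_noh, e))
    del heavy_ref
    return len(unique)
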