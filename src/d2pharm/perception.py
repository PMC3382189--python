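"""Ligand annotation points: the ligand-side half of a pharmacophore match.

A conformer is reduced to typed geometric points:

* ``cation`` — the protonated nitrogen nucleus (salt bridge to Asp-TM3);
* ``aromatic`` — ring centroid with unit normal (face-to-edge interactions
  with the TM6 aromatic cluster; both normal signs are admissible when
  matching);
* ``donor_proj`` / ``acceptor_proj`` — projected hydrogen-bond partner
  positions, placed where the receptor-side heavy atom would sit;
* ``acceptor_atom`` — the acceptor heavy atom itself;
* ``oxygen_atom`` — every oxygen nucleus, consumed by the excluded-oxygen
  (exclO) rule.

Projected points for aryl hydroxyls lie in the aromatic-ring plane at two
positions separated by 120 deg, the in-plane syn/anti lone-pair geometry of
a phenolic OH; other donors project along their O-H / N-H bond directions.
The ideal heavy-atom hydrogen-bond separation of ~2.8 A sets the default
projection distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .geometry import plane_normal, unit

PROJECTION_DISTANCE = 2.8  # Å, ideal heavy-atom H-bond separation

KINDS = ("cation", "aromatic", "donor_proj", "acceptor_proj", "acceptor_atom", "oxygen_atom")


class PerceptionError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotationPoint:
    kind: str
    position: np.ndarray
    direction: np.ndarray | None = None
    source_atoms: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            if abs(np.linalg.norm(d) - 1.0) > 1e-8:
                raise PerceptionError("direction must be a unit vector")
            object.__setattr__(self, "direction", d)

    def transformed(self, transform) -> "AnnotationPoint":
        pos = transform.apply(self.position[None, :])[0]
        direc = None
        if self.direction is not None:
            direc = transform.rotation @ self.direction
        return AnnotationPoint(self.kind, pos, direc, self.source_atoms)


def project_aryl_donor(
    o_pos: np.ndarray,
    c_pos: np.ndarray,
    ring_normal: np.ndarray,
    distance: float = PROJECTION_DISTANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Two in-plane projected H-bond points for an aryl O(H).

    The points sit at ``distance`` from the oxygen, in the aromatic-ring
    plane, at +-60 deg about the extended C->O direction, so the two
    O->point vectors subtend exactly 120 deg.
    """
    o_pos = np.asarray(o_pos, dtype=float)
    along = np.asarray(o_pos) - np.asarray(c_pos)
    n = unit(ring_normal)
    along = along - np.dot(along, n) * n  # force exactly into the ring plane
    along = unit(along)
    perp = np.cross(n, along)
    out = []
    for sign in (+1.0, -1.0):
        ang = np.deg2rad(60.0)
        direction = np.cos(ang) * along + sign * np.sin(ang) * perp
        out.append(o_pos + distance * direction)
    return out[0], out[1]


def _aromatic_rings(mol: Chem.Mol) -> list[tuple[int, ...]]:
    info = mol.GetRingInfo()
    rings = []
    for ring in info.AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            rings.append(tuple(ring))
    return rings


def _ring_plane(coords: np.ndarray, ring: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    pts = coords[list(ring)]
    centroid = pts.mean(axis=0)
    normal = plane_normal(pts)
    return centroid, normal


def _ring_of_atom(rings: list[tuple[int, ...]], idx: int) -> tuple[int, ...] | None:
    for ring in rings:
        if idx in ring:
            return ring
    return None


def _lone_pair_projections(
    mol: Chem.Mol, coords: np.ndarray, idx: int, rings, distance: float
) -> list[np.ndarray]:
    """Projected acceptor-partner points for a non-hydroxy acceptor atom."""
    atom = mol.GetAtomWithIdx(idx)
    pos = coords[idx]
    heavy_nbrs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
    if atom.GetIsAromatic():
        # pyridine-type nitrogen: project in-plane along the external bisector
        ring = _ring_of_atom(rings, idx)
        if ring is None or len(heavy_nbrs) < 2:
            return []
        bisector = unit(
            unit(pos - coords[heavy_nbrs[0]]) + unit(pos - coords[heavy_nbrs[1]])
        )
        return [pos + distance * bisector]
    if len(heavy_nbrs) == 1:
        # carbonyl-type oxygen: two in-plane lone pairs at +-60 deg off the C=O axis
        c = coords[heavy_nbrs[0]]
        cn = mol.GetAtomWithIdx(heavy_nbrs[0])
        others = [n.GetIdx() for n in cn.GetNeighbors() if n.GetIdx() != idx and n.GetAtomicNum() > 1]
        axis = unit(pos - c)
        if others:
            ref = unit(coords[others[0]] - c)
            perp = ref - np.dot(ref, axis) * axis
            perp = unit(perp) if np.linalg.norm(perp) > 1e-8 else _any_perp(axis)
        else:
            perp = _any_perp(axis)
        ang = np.deg2rad(60.0)
        return [
            pos + distance * (np.cos(ang) * axis + s * np.sin(ang) * perp)
            for s in (+1.0, -1.0)
        ]
    if len(heavy_nbrs) == 2:
        # ether-type oxygen: single projection along the external bisector
        bisector = unit(
            unit(pos - coords[heavy_nbrs[0]]) + unit(pos - coords[heavy_nbrs[1]])
        )
        return [pos + distance * bisector]
    return []


def _any_perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def perceive(conformer, distance: float = PROJECTION_DISTANCE) -> list[AnnotationPoint]:
    """All annotation points of one conformer.

    Synthetic probe conformers that already carry explicit points are passed
    through unchanged, which lets model fixtures exercise the matcher
    without inventing chemistry for them.
    """
    explicit = getattr(conformer, "annotation_points", None)
    if explicit is not None:
        return list(explicit)

    mol = conformer.mol
    if mol.GetNumConformers() == 0:
        raise PerceptionError("unembedded conformer")
    coords = conformer.coords_all
    rings = _aromatic_rings(mol)
    points: list[AnnotationPoint] = []

    for atom in mol.GetAtoms():
        if atom.GetSymbol() == "N" and atom.GetFormalCharge() == 1 and not atom.GetIsAromatic():
            points.append(AnnotationPoint("cation", coords[atom.GetIdx()], None, (atom.GetIdx(),)))

    for ring in rings:
        centroid, normal = _ring_plane(coords, ring)
        points.append(AnnotationPoint("aromatic", centroid, normal, ring))

    for atom in mol.GetAtoms():
        idx = atom.GetIdx()
        sym = atom.GetSymbol()
        if sym == "O":
            points.append(AnnotationPoint("oxygen_atom", coords[idx], None, (idx,)))

        if sym not in ("N", "O"):
            continue
        hs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        is_cation = atom.GetFormalCharge() == 1 and not atom.GetIsAromatic()
        aryl_nbr = next(
            (n.GetIdx() for n in atom.GetNeighbors() if n.GetIsAromatic()), None
        )

        if hs and not is_cation:
            # donor projections (the charged amine is covered by the cation point)
            if sym == "O" and aryl_nbr is not None:
                ring = _ring_of_atom(rings, aryl_nbr)
                _, normal = _ring_plane(coords, ring)
                p1, p2 = project_aryl_donor(coords[idx], coords[aryl_nbr], normal, distance)
                for p in (p1, p2):
                    points.append(
                        AnnotationPoint("donor_proj", p, unit(p - coords[idx]), (idx,))
                    )
            else:
                for h in hs:
                    direction = unit(coords[h] - coords[idx])
                    points.append(
                        AnnotationPoint(
                            "donor_proj", coords[idx] + distance * direction, direction, (idx,)
                        )
                    )

        is_acceptor = (
            (sym == "O" and atom.GetFormalCharge() == 0)
            or (sym == "N" and atom.GetIsAromatic() and not hs and atom.GetFormalCharge() == 0)
        )
        if is_acceptor:
            points.append(AnnotationPoint("acceptor_atom", coords[idx], None, (idx,)))
            if not (sym == "O" and hs):  # hydroxyls already project via donor_proj
                for p in _lone_pair_projections(mol, coords, idx, rings, distance):
                    points.append(
                        AnnotationPoint("acceptor_proj", p, unit(p - coords[idx]), (idx,))
                    )
    return points


def points_as_dict(points: list[AnnotationPoint]) -> list[dict]:
    """JSON-ready dump of annotation points (debugging, probe fixtures)."""
    out = []
    for p in points:
        out.append(
            {
                "kind": p.kind,
                "position": [float(x) for x in p.position],
                "direction": None if p.direction is None else [float(x) for x in p.direction],
                "source_atoms": list(p.source_atoms),
            }
        )
    return out
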