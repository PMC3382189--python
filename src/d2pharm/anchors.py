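"""Receptor-side geometry: anchor atoms, hydrogen sites, H-bond criteria.

The receptor enters the pipeline only as an abstract set of named anchor
atoms (Ser193 OG, His393 NE2/ND1, Asn186 OD1/ND2, Asp114 OD), pocket
hydrogen sites and aromatic ring centroids, all in the pharmacophore model
frame. Excluded volumes are constructed from the hydrogen sites (Bondi van
der Waals radii initially — 1.2 A aliphatic, 1.0 A aromatic — widened to
the tuned 2.0/1.8 A) and from ring centroids (2.5 A).

Hydrogen-bond geometry between a matched ligand pose and an anchor is
judged on the heavy-atom separation d and the donor-H-acceptor angle:
acceptable when d is between 2.4 and 3.8 A and the angle within 180+-40
deg; values just outside (up to 0.3 A / 12 deg beyond a bound) are flagged
borderline rather than failed, since the receptor is flexible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import angle_deg, unit
from .model import EV_RADII_FINAL, EV_RADII_INITIAL, ExcludedVolume
from .perception import PROJECTION_DISTANCE

HBOND_D_MIN = 2.4
HBOND_D_MAX = 3.8
HBOND_ANGLE_MIN = 140.0
HBOND_ANGLE_MAX = 220.0
BORDERLINE_D = 0.3  # Å beyond a distance bound
BORDERLINE_ANGLE = 12.0  # degrees beyond an angle bound

ANCHOR_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Anchor:
    name: str  # e.g. "Ser193:OG"
    element: str
    role: str  # "donor", "acceptor" or "both"
    position: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass
class AnchorSet:
    anchors: list[Anchor]
    hydrogen_sites: list[tuple[np.ndarray, str]] = field(default_factory=list)
    ring_centroids: list[np.ndarray] = field(default_factory=list)
    frame_tag: str = ""

    def __post_init__(self) -> None:
        self.hydrogen_sites = [
            (np.asarray(pos, dtype=float), tag) for pos, tag in self.hydrogen_sites
        ]
        self.ring_centroids = [np.asarray(p, dtype=float) for p in self.ring_centroids]
        for pos, tag in self.hydrogen_sites:
            if tag not in ("aliphatic_H", "aromatic_H", "polar_H"):
                raise ValueError(f"unknown hydrogen-site tag {tag!r}")
            if not np.all(np.isfinite(pos)):
                raise ValueError("non-finite hydrogen-site position")

    def anchor(self, name: str) -> Anchor:
        for a in self.anchors:
            if a.name == name:
                return a
        raise KeyError(name)


@dataclass(frozen=True)
class HBondRecord:
    anchor: str
    d: float  # heavy-atom separation, Å
    angle: float  # donor-heavy — H — acceptor-heavy, degrees
    verdict: str  # ok | borderline | fail
    group: str = ""  # ligand group label, e.g. "p"/"m" for catechol hydroxyls


def classify_hbond(d: float, angle: float) -> str:
    """Verdict for a (distance, angle) pair against the acceptance windows."""

    def band(value, lo, hi, slop_lo, slop_hi):
        if lo <= value <= hi:
            return "ok"
        if lo - slop_lo <= value < lo or hi < value <= hi + slop_hi:
            return "borderline"
        return "fail"

    vd = band(d, HBOND_D_MIN, HBOND_D_MAX, BORDERLINE_D, BORDERLINE_D)
    va = band(angle, HBOND_ANGLE_MIN, HBOND_ANGLE_MAX, BORDERLINE_ANGLE, BORDERLINE_ANGLE)
    if vd == "fail" or va == "fail":
        return "fail"
    if vd == "borderline" or va == "borderline":
        return "borderline"
    return "ok"


def hbond_geometry(donor_heavy, hydrogen, acceptor_heavy) -> HBondRecord:
    """Distance/angle record for an explicit donor-H...acceptor triple."""
    donor_heavy = np.asarray(donor_heavy, dtype=float)
    hydrogen = np.asarray(hydrogen, dtype=float)
    acceptor_heavy = np.asarray(acceptor_heavy, dtype=float)
    if (
        np.allclose(donor_heavy, hydrogen)
        or np.allclose(acceptor_heavy, hydrogen)
        or np.allclose(donor_heavy, acceptor_heavy)
    ):
        raise ValueError("degenerate geometry: coincident points")
    d = float(np.linalg.norm(donor_heavy - acceptor_heavy))
    ang = angle_deg(donor_heavy, hydrogen, acceptor_heavy)
    return HBondRecord(anchor="", d=d, angle=ang, verdict=classify_hbond(d, ang))


def build_excluded_volumes(
    anchor_set: AnchorSet, radii_config: dict[str, float] | None = None
) -> list[ExcludedVolume]:
    """One excluded volume per hydrogen site and ring centroid.

    ``radii_config`` maps origin tags to radii; the default is the tuned
    final configuration (2.0 aliphatic / 1.8 aromatic / 2.5 ring centroid).
    ``initial_bondi_radii()`` supplies the Bondi starting values.
    """
    radii = dict(EV_RADII_FINAL)
    if radii_config:
        for tag in radii_config:
            if tag not in radii and tag != "ring_centroid":
                raise ValueError(f"unknown excluded-volume tag {tag!r}")
        radii.update(radii_config)
    evs = [
        ExcludedVolume(center=pos, radius=radii[tag], origin_tag=tag)
        for pos, tag in anchor_set.hydrogen_sites
    ]
    evs.extend(
        ExcludedVolume(center=pos, radius=radii["ring_centroid"], origin_tag="ring_centroid")
        for pos in anchor_set.ring_centroids
    )
    return evs


def initial_bondi_radii() -> dict[str, float]:
    """Bondi van der Waals starting radii for pocket hydrogens."""
    return dict(EV_RADII_INITIAL)


def _ligand_polar_groups(conformer):
    """(heavy_idx, element, h_indices, label) for each donor/acceptor group."""
    mol = conformer.mol
    coords = conformer.coords_all
    groups = []
    catechol_labels = _catechol_labels(mol)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym not in ("N", "O"):
            continue
        if sym == "N" and atom.GetFormalCharge() == 1:
            continue  # the charged amine is the salt-bridge partner, not an H-bond row
        hs = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1]
        is_acceptor = sym == "O" or (atom.GetIsAromatic() and not hs)
        if not hs and not is_acceptor:
            continue
        label = catechol_labels.get(atom.GetIdx(), "")
        groups.append((atom.GetIdx(), sym, hs, label, coords))
    return groups


def _catechol_labels(mol) -> dict[int, str]:
    """Label catechol hydroxy oxygens meta/para relative to the amine chain.

    In the dopamine substructure the ring carbon that carries the path to
    the basic nitrogen defines position 1; the hydroxy two ring bonds away
    is *meta* ("m"), three away *para* ("p").
    """
    from rdkit import Chem

    labels: dict[int, str] = {}
    cation = next(
        (a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N" and a.GetFormalCharge() == 1),
        None,
    )
    if cation is None:
        return labels
    ri = mol.GetRingInfo()
    for ring in ri.AtomRings():
        if not all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        ohs = []
        for i in ring:
            for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
                has_h = nbr.GetTotalNumHs() > 0 or any(
                    h.GetAtomicNum() == 1 for h in nbr.GetNeighbors()
                )
                if nbr.GetSymbol() == "O" and has_h:
                    ohs.append((i, nbr.GetIdx()))
        if len(ohs) != 2:
            continue  # the m/p convention is used for catechols
        # ring atom closest (through bonds) to the basic nitrogen = position 1
        dists = {
            i: len(Chem.GetShortestPath(mol, i, cation)) for i in ring
        }
        attach = min(ring, key=lambda i: dists[i])
        ring_list = list(ring)
        n = len(ring_list)
        pos_attach = ring_list.index(attach)
        for carbon, oxy in ohs:
            sep = abs(ring_list.index(carbon) - pos_attach)
            sep = min(sep, n - sep)
            labels[oxy] = {2: "m", 3: "p"}.get(sep, "")
    return labels


def evaluate_hit(hit, conformer, anchor_set: AnchorSet) -> list[HBondRecord]:
    """Best H-bond geometry of a hit against each named anchor.

    For each ligand donor/acceptor group (in the transformed model frame)
    and each anchor, the geometrically best pairing is reported. When the
    ligand donates, its own hydrogen defines the angle; when the anchor
    donates, the anchor hydrogen is idealised onto the donor-acceptor axis
    (receptor hydrogen positions are unknown), making the angle 180 deg.
    Catechol hydroxyls report separate meta ("m") and para ("p") rows.
    """
    records: list[HBondRecord] = []
    for heavy_idx, sym, hs, label, coords in _ligand_polar_groups(conformer):
        heavy = hit.transform.apply(coords[heavy_idx][None, :])[0]
        h_positions = [hit.transform.apply(coords[h][None, :])[0] for h in hs]
        for anchor in anchor_set.anchors:
            d = float(np.linalg.norm(heavy - anchor.position))
            best: HBondRecord | None = None
            if hs and anchor.role in ("acceptor", "both"):
                for hp in h_positions:
                    rec = hbond_geometry(heavy, hp, anchor.position)
                    rec = HBondRecord(anchor.name, rec.d, rec.angle, rec.verdict, label)
                    if best is None or _hb_quality(rec) > _hb_quality(best):
                        best = rec
            if best is None and anchor.role in ("donor", "both"):
                # anchor donates: idealised hydrogen on the donor-acceptor axis
                hpos = anchor.position + unit(heavy - anchor.position) * 1.0
                rec = hbond_geometry(anchor.position, hpos, heavy)
                best = HBondRecord(anchor.name, rec.d, rec.angle, rec.verdict, label)
            if best is not None:
                records.append(best)
    return records


_VERDICT_RANK = {"ok": 2, "borderline": 1, "fail": 0}


def _hb_quality(rec: HBondRecord) -> tuple:
    return (
        _VERDICT_RANK[rec.verdict],
        -abs(rec.d - PROJECTION_DISTANCE),
        -abs(rec.angle - 180.0),
    )


def best_record_per_anchor(records: list[HBondRecord]) -> dict[str, HBondRecord]:
    best: dict[str, HBondRecord] = {}
    for rec in records:
        key = rec.anchor
        if key not in best or _hb_quality(rec) > _hb_quality(best[key]):
            best[key] = rec
    return best


# ---------------------------------------------------------------------------
# serialisation

def anchor_set_to_dict(aset: AnchorSet) -> dict:
    return {
        "schema_version": ANCHOR_SCHEMA_VERSION,
        "units": "angstrom",
        "frame_tag": aset.frame_tag,
        "anchors": [
            {
                "name": a.name,
                "element": a.element,
                "role": a.role,
                "position": [float(x) for x in a.position],
            }
            for a in aset.anchors
        ],
        "hydrogen_sites": [
            {"position": [float(x) for x in pos], "tag": tag}
            for pos, tag in aset.hydrogen_sites
        ],
        "ring_centroids": [[float(x) for x in p] for p in aset.ring_centroids],
    }


def anchor_set_from_dict(doc: dict) -> AnchorSet:
    if doc.get("schema_version") != ANCHOR_SCHEMA_VERSION:
        raise ValueError(f"unsupported anchor schema version {doc.get('schema_version')!r}")
    return AnchorSet(
        anchors=[
            Anchor(a["name"], a["element"], a["role"], a["position"]) for a in doc["anchors"]
        ],
        hydrogen_sites=[(s["position"], s["tag"]) for s in doc.get("hydrogen_sites", [])],
        ring_centroids=[p for p in doc.get("ring_centroids", [])],
        frame_tag=doc.get("frame_tag", ""),
    )


def save_anchor_set(aset: AnchorSet, path) -> None:
    with open(path, "w") as fh:
        json.dump(anchor_set_to_dict(aset), fh, indent=1)
        fh.write("\n")


def load_anchor_set(path) -> AnchorSet:
    with open(path) as fh:
        return anchor_set_from_dict(json.load(fh))


def load_default_anchor_set() -> AnchorSet:
    from importlib import resources

    path = resources.files("d2pharm.data").joinpath("anchors.json")
    with path.open() as fh:
        return anchor_set_from_dict(json.load(fh))


def anchor_set_from_pdb(path, atom_names: dict[str, str], frame_tag: str = "pdb") -> AnchorSet:
    """Extract named atoms from a PDB file into an :class:`AnchorSet`.

    ``atom_names`` maps anchor names (e.g. ``"Ser193:OG"``) to
    ``"<resname><resnum>:<atomname>"`` selectors. Roles default to "both".
    """
    import gemmi

    structure = gemmi.read_structure(str(path))
    anchors = []
    wanted = {sel: name for name, sel in atom_names.items()}
    for mdl in structure:
        for chain in mdl:
            for res in chain:
                for atom in res:
                    sel = f"{res.name}{res.seqid.num}:{atom.name}"
                    if sel in wanted:
                        anchors.append(
                            Anchor(
                                name=wanted[sel],
                                element=atom.element.name,
                                role="both",
                                position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                            )
                        )
        break
    return AnchorSet(anchors=anchors, frame_tag=frame_tag)
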