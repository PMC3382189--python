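import numpy as np
import pytest

from d2pharm.anchors import (
    Anchor,
    AnchorSet,
    build_excluded_volumes,
    classify_hbond,
    hbond_geometry,
    initial_bondi_radii,
    anchor_set_from_dict,
    anchor_set_to_dict,
)
from d2pharm.geometry import RigidTransform


# ---------------------------------------------------------------------------
# H-bond geometry windows


@pytest.mark.parametrize(
    "d,angle,verdict",
    [
        (2.4, 180.0, "ok"),  # boundary distances are acceptable
        (3.8, 180.0, "ok"),
        (2.9, 140.0, "ok"),  # boundary angles too
        (2.9, 220.0, "ok"),
        (2.9, 157.0, "ok"),  # the catechol meta-OH...His geometry
        (4.1, 151.0, "borderline"),  # just beyond the distance window
        (3.0, 128.0, "borderline"),  # just beyond the angle window
        (4.5, 160.0, "fail"),
        (2.9, 120.0, "fail"),
        (2.0, 180.0, "fail"),
    ],
)
def test_hbond_windows(d, angle, verdict):
    assert classify_hbond(d, angle) == verdict


def test_hbond_geometry_collinear():
    rec = hbond_geometry([0, 0, 0], [1.0, 0, 0], [2.8, 0, 0])
    assert abs(rec.d - 2.8) < 1e-12
    assert abs(rec.angle - 180.0) < 1e-9
    assert rec.verdict == "ok"


def test_hbond_geometry_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        hbond_geometry([0, 0, 0], [0, 0, 0], [2.8, 0, 0])


def test_hbond_geometry_matches_vector_oracle(rng):
    for _ in range(50):
        d_pt, h, a_pt = rng.normal(scale=3, size=(3, 3))
        rec = hbond_geometry(d_pt, h, a_pt)
        assert abs(rec.d - np.linalg.norm(d_pt - a_pt)) < 1e-9
        v1, v2 = d_pt - h, a_pt - h
        expected = np.degrees(
            np.arccos(np.clip(np.dot(v1, v2) / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1))
        )
        assert abs(rec.angle - expected) < 1e-9


def test_hbond_distance_symmetric_angle_not(rng):
    d_pt, h, a_pt = rng.normal(scale=3, size=(3, 3))
    fwd = hbond_geometry(d_pt, h, a_pt)
    rev = hbond_geometry(a_pt, h, d_pt)
    assert abs(fwd.d - rev.d) < 1e-12
    assert abs(fwd.angle - rev.angle) < 1e-9  # the vertex stays at h


def test_hbond_rigid_motion_invariance(rng):
    d_pt, h, a_pt = rng.normal(scale=3, size=(3, 3))
    t = RigidTransform.from_euler(rng.uniform(-180, 180, 3), rng.uniform(-5, 5, 3))
    rec1 = hbond_geometry(d_pt, h, a_pt)
    moved = t.apply(np.vstack([d_pt, h, a_pt]))
    rec2 = hbond_geometry(*moved)
    assert abs(rec1.d - rec2.d) < 1e-9
    assert abs(rec1.angle - rec2.angle) < 1e-9


# ---------------------------------------------------------------------------
# excluded-volume construction


def _anchor_set():
    return AnchorSet(
        anchors=[Anchor("Ser193:OG", "O", "both", (8.0, 0.0, 0.0))],
        hydrogen_sites=[
            ((0.0, 3.0, 0.0), "aliphatic_H"),
            ((1.0, -3.0, 0.0), "aromatic_H"),
            ((5.0, 3.0, 0.0), "polar_H"),
        ],
        ring_centroids=[(4.0, 0.0, 5.0)],
    )


def test_bondi_initial_radii():
    radii = initial_bondi_radii()
    assert radii["aliphatic_H"] == 1.2
    assert radii["aromatic_H"] == 1.0
    assert radii["polar_H"] == 1.0  # set to the benzene-hydrogen value


def test_final_radii_and_count():
    aset = _anchor_set()
    evs = build_excluded_volumes(aset)
    assert len(evs) == len(aset.hydrogen_sites) + len(aset.ring_centroids)
    by_tag = {ev.origin_tag: ev.radius for ev in evs}
    assert by_tag["aliphatic_H"] == 2.0
    assert by_tag["aromatic_H"] == 1.8
    assert by_tag["polar_H"] == 1.8
    assert by_tag["ring_centroid"] == 2.5


def test_bondi_initialised_construction():
    evs = build_excluded_volumes(_anchor_set(), radii_config=initial_bondi_radii())
    by_tag = {ev.origin_tag: ev.radius for ev in evs}
    assert by_tag["aliphatic_H"] == 1.2
    assert by_tag["aromatic_H"] == 1.0


def test_unknown_tag_rejected():
    with pytest.raises(ValueError):
        build_excluded_volumes(_anchor_set(), radii_config={"halogen_H": 1.0})
    with pytest.raises(ValueError):
        AnchorSet(anchors=[], hydrogen_sites=[((0, 0, 0), "weird")])


def test_anchor_set_json_round_trip():
    aset = _anchor_set()
    back = anchor_set_from_dict(anchor_set_to_dict(aset))
    assert len(back.anchors) == len(aset.anchors)
    assert len(back.hydrogen_sites) == len(aset.hydrogen_sites)
    np.testing.assert_allclose(back.ring_centroids[0], aset.ring_centroids[0])


# ---------------------------------------------------------------------------
# hit evaluation


def test_evaluate_hit_by_construction(toy_model):
    """A ligand hydroxyl placed 2.8 A from Ser OG with a collinear hydrogen
    yields an 'ok' record."""
    from rdkit import Chem
    from rdkit.Chem import AllChem
    from d2pharm.anchors import evaluate_hit
    from d2pharm.conformers import Conformer
    from d2pharm.results import Hit

    mol = Chem.AddHs(Chem.MolFromSmiles("CO"))
    AllChem.EmbedMolecule(mol, randomSeed=3)
    conf = mol.GetConformer()
    # place O at origin, H along +x, anchor at 2.8 along +x
    o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
    h_idx = next(
        n.GetIdx() for n in mol.GetAtomWithIdx(o_idx).GetNeighbors() if n.GetAtomicNum() == 1
    )
    c_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "C")
    conf.SetAtomPosition(o_idx, (0.0, 0.0, 0.0))
    conf.SetAtomPosition(h_idx, (0.96, 0.0, 0.0))
    conf.SetAtomPosition(c_idx, (-0.8, 1.1, 0.0))
    ligand = Conformer("probe-ol", mol, 0, 0.0, "t")
    aset = AnchorSet(anchors=[Anchor("Ser193:OG", "O", "both", (2.8, 0.0, 0.0))])
    hit = Hit("probe-ol", 0, RigidTransform.identity(), 0.0, (), 0.0)
    records = evaluate_hit(hit, ligand, aset)
    assert len(records) == 1
    assert records[0].verdict == "ok"
    assert abs(records[0].d - 2.8) < 1e-9
    assert abs(records[0].angle - 180.0) < 1e-6


def test_dpat_hit_has_no_hbond_records(records_by_id, shipped_model, shipped_anchors):
    import d2pharm
    from d2pharm.anchors import evaluate_hit
    from d2pharm.matching import match

    ens = d2pharm.generate_conformers(records_by_id["(S)-DPAT"], max_confs=150, seed=2012)
    hit = None
    for i, c in enumerate(ens):
        hit = match(c, shipped_model, conformer_index=i)
        if hit:
            break
    assert hit is not None, "(S)-DPAT must fit the shipped model"
    assert evaluate_hit(hit, ens.conformers[hit.conformer_index], shipped_anchors) == []
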