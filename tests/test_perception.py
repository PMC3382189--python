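import numpy as np


from d2pharm.geometry import RigidTransform, vector_angle_deg
from d2pharm.perception import (
    PROJECTION_DISTANCE,
    perceive,
    project_aryl_donor,
)

from .conftest import embed_smiles


def kinds(points):
    out = {}
    for p in points:
        out[p.kind] = out.get(p.kind, 0) + 1
    return out


def test_dopamine_points(dopamine_conformer):
    k = kinds(perceive(dopamine_conformer))
    assert k["cation"] == 1
    assert k["aromatic"] == 1
    assert k["donor_proj"] == 4  # two aryl hydroxyls, two in-plane points each
    assert k["oxygen_atom"] == 2


def test_benzene_single_aromatic_point():
    conf = embed_smiles("c1ccccc1")
    pts = perceive(conf)
    assert kinds(pts) == {"aromatic": 1}
    normal = pts[0].direction
    assert abs(np.linalg.norm(normal) - 1.0) < 1e-8


def test_dpat_cation_aromatic_only(records_by_id):
    import d2pharm

    ens = d2pharm.generate_conformers(records_by_id["(S)-DPAT"], max_confs=5, seed=3)
    k = kinds(perceive(ens.conformers[0]))
    assert k["cation"] == 1
    assert k["aromatic"] == 1
    assert "donor_proj" not in k
    assert "acceptor_proj" not in k


def test_phenol_projections_120_degrees():
    conf = embed_smiles("Oc1ccccc1")
    pts = perceive(conf)
    projs = [p for p in pts if p.kind == "donor_proj"]
    assert len(projs) == 2
    o_pos = conf.coords_all[projs[0].source_atoms[0]]
    v1 = projs[0].position - o_pos
    v2 = projs[1].position - o_pos
    assert abs(vector_angle_deg(v1, v2) - 120.0) < 1e-6
    for v in (v1, v2):
        assert abs(np.linalg.norm(v) - PROJECTION_DISTANCE) < 1e-8


def test_phenol_projections_in_ring_plane():
    conf = embed_smiles("Oc1ccccc1")
    pts = perceive(conf)
    ring = next(p for p in pts if p.kind == "aromatic")
    projs = [p for p in pts if p.kind == "donor_proj"]
    for p in projs:
        out_of_plane = np.dot(p.position - ring.position, ring.direction)
        assert abs(out_of_plane) < 5e-2  # within the slight ring puckering


def test_project_aryl_donor_direct_construction():
    o = np.array([1.0, 0.0, 0.0])
    c = np.array([0.0, 0.0, 0.0])
    n = np.array([0.0, 0.0, 1.0])
    p1, p2 = project_aryl_donor(o, c, n, distance=2.8)
    for p in (p1, p2):
        assert abs(np.linalg.norm(p - o) - 2.8) < 1e-9
        assert abs(p[2]) < 1e-9  # in plane
    assert abs(vector_angle_deg(p1 - o, p2 - o) - 120.0) < 1e-9


def test_rigid_motion_invariance(dopamine_conformer, rng):
    pts = perceive(dopamine_conformer)
    transform = RigidTransform.from_euler(rng.uniform(-180, 180, 3), rng.uniform(-5, 5, 3))
    # transform the conformer coordinates in place on a copy
    from rdkit import Chem
    from d2pharm.conformers import Conformer

    mol = Chem.Mol(dopamine_conformer.mol)
    conf = mol.GetConformer(dopamine_conformer.conf_id)
    moved = transform.apply(dopamine_conformer.coords_all)
    for i, xyz in enumerate(moved):
        conf.SetAtomPosition(i, xyz.tolist())
    moved_conf = Conformer(
        ligand_id="dopamine", mol=mol, conf_id=dopamine_conformer.conf_id,
        delta_e=0.0, seed_tag="t",
    )
    pts2 = perceive(moved_conf)
    assert len(pts) == len(pts2)
    for a, b in zip(pts, pts2):
        assert a.kind == b.kind
        np.testing.assert_allclose(transform.apply(a.position[None])[0], b.position, atol=1e-6)
        if a.direction is not None:
            np.testing.assert_allclose(
                np.abs(np.dot(transform.rotation @ a.direction, b.direction)), 1.0, atol=1e-6
            )


def test_point_counts_conformation_independent(records_by_id):
    import d2pharm

    ens = d2pharm.generate_conformers(records_by_id["dopamine"], max_confs=10, seed=5)
    counts = {tuple(sorted(kinds(perceive(c)).items())) for c in ens}
    assert len(counts) == 1


def test_quinpirole_pyrazole_points(records_by_id):
    import d2pharm

    ens = d2pharm.generate_conformers(records_by_id["quinpirole"], max_confs=5, seed=3)
    k = kinds(perceive(ens.conformers[0]))
    assert k["cation"] == 1
    assert k["aromatic"] == 1  # the pyrazole
    assert k.get("donor_proj", 0) == 1  # pyrazole N-H
    assert k.get("acceptor_atom", 0) == 1  # pyridine-type pyrazole N
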