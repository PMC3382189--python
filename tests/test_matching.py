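import numpy as np
import pytest

from d2pharm.fixtures import make_decoy_conformers, make_probe_conformer
from d2pharm.geometry import RigidTransform, UnderdeterminedError
from d2pharm.matching import enumerate_candidates, fit_rmsd, match
from d2pharm.model import ExcludedVolume, ExclusionSphere, Feature, PharmacophoreModel
from d2pharm.perception import AnnotationPoint

from .oracles import brute_force_match, rmsd_after_kabsch


# ---------------------------------------------------------------------------
# fit RMSD


def test_fit_rmsd_coincident_pairs_zero(rng):
    pts = rng.normal(size=(5, 3))
    assert fit_rmsd([(p, p) for p in pts]) < 1e-12


@pytest.mark.parametrize("n,d", [(3, 0.5), (4, 1.0), (6, 0.25)])
def test_fit_rmsd_single_displacement_closed_form(n, d):
    """One pair displaced by d among n coincident pairs gives d/sqrt(n)
    (with the identity transform)."""
    pts = np.array([[i * 10.0, 0.0, 0.0] for i in range(n)])
    targets = pts.copy()
    targets[0, 1] += d
    pairs = list(zip(pts, targets))
    got = fit_rmsd(pairs, transform=RigidTransform.identity())
    assert abs(got - d / np.sqrt(n)) < 1e-12


def test_fit_rmsd_matches_kabsch_oracle(rng):
    for _ in range(25):
        src = rng.normal(size=(5, 3)) * 3
        dst = rng.normal(size=(5, 3)) * 3
        assert abs(fit_rmsd(list(zip(src, dst))) - rmsd_after_kabsch(src, dst)) < 1e-8


def test_fit_rmsd_underdetermined():
    with pytest.raises(UnderdeterminedError):
        fit_rmsd([(np.zeros(3), np.zeros(3)), (np.ones(3), np.ones(3))])


# ---------------------------------------------------------------------------
# probes and decoys


def test_probe_exact_match_zero_rmsd(toy_model):
    probe = make_probe_conformer(toy_model, jitter=0.0)
    hit = match(probe, toy_model)
    assert hit is not None
    assert hit.fit_rmsd < 1e-9


def test_probe_jittered_match_bounded_rmsd(toy_model):
    probe = make_probe_conformer(toy_model, jitter=0.3, seed=5)
    hit = match(probe, toy_model)
    assert hit is not None
    assert hit.fit_rmsd <= 0.3 + 1e-9


def test_probe_displaced_beyond_radius_no_hit(toy_model):
    probe = make_probe_conformer(toy_model)
    f0 = toy_model.essential_features[0]
    pts = [
        AnnotationPoint(
            p.kind,
            p.position + np.array([f0.radius + 1.0, 0, 0])
            if np.allclose(p.position, f0.center)
            else p.position,
            p.direction,
        )
        for p in probe.annotation_points
    ]
    probe.annotation_points = pts
    assert match(probe, toy_model) is None


def test_decoys_each_violate_one_constraint(toy_model):
    # volumes on the cation-aromatic axis, where no admissible pose (the
    # aromatic normal is unsigned, so poses mirror) can dodge them
    model = PharmacophoreModel(
        features=toy_model.features,
        excluded_volumes=(ExcludedVolume((2.0, 0.0, 0.0), 1.8),),
        exclO=ExclusionSphere((6.5, 0.0, 0.0), 1.5),
    )
    assert match(make_probe_conformer(model), model) is not None
    for name, decoy in make_decoy_conformers(model).items():
        assert match(decoy, model) is None, name


def test_atom_at_excluded_volume_center_clashes(toy_model):
    ev_center = np.array([2.0, 0.0, 0.0])
    model = PharmacophoreModel(
        features=toy_model.features,
        excluded_volumes=(ExcludedVolume(ev_center, 1.8),),
    )
    probe = make_probe_conformer(model)
    probe.extra_heavy = ev_center[None, :].copy()
    assert match(probe, model) is None


# ---------------------------------------------------------------------------
# oracle equivalence, invariance, monotonicity


def _random_instance(rng, n_features=None, chiral_probe=True):
    """Random small matching instance with kind-compatible points."""
    n_features = n_features or rng.integers(2, 5)
    kinds = ["cation", "aromatic", "hbond", "hbond"]
    feats = []
    for i in range(n_features):
        kind = kinds[i % len(kinds)]
        center = rng.uniform(-4, 4, 3)
        direction = None
        if kind == "aromatic":
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        feats.append(
            Feature(
                f"f{i}",
                kind,
                center,
                float(rng.uniform(0.6, 1.4)),
                essential=bool(rng.uniform() < 0.7) or i == 0,
                direction=direction,
                direction_tol=45.0,
            )
        )
    points = []
    n_points = int(rng.integers(n_features, 8))
    for i in range(n_points):
        f = feats[i % len(feats)]
        kind = {"cation": "cation", "aromatic": "aromatic", "hbond": "donor_proj"}[f.kind]
        pos = f.center + rng.normal(scale=0.7, size=3)
        direction = None
        if kind in ("aromatic", "donor_proj"):
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        points.append(AnnotationPoint(kind, pos, direction))
    # scramble with a random rigid motion so the matcher has work to do
    t = RigidTransform.from_euler(rng.uniform(-180, 180, 3), rng.uniform(-3, 3, 3))
    points = [p.transformed(t) for p in points]
    return feats, points


class _PointConformer:
    def __init__(self, points, heavy=None):
        self.annotation_points = points
        self.ligand_id = "pts"
        self.delta_e = 0.0
        self._heavy = (
            heavy if heavy is not None else np.asarray([p.position for p in points])
        )

    @property
    def coords_heavy(self):
        return self._heavy


def _to_oracle(feats, points):
    fo = []
    for f in feats:
        fo.append(
            (
                f.name,
                f.compatible_kinds(),
                np.asarray(f.center),
                f.radius,
                f.essential,
                None if f.direction is None else np.asarray(f.direction),
                f.direction_tol,
            )
        )
    po = [(p.kind, np.asarray(p.position), p.direction) for p in points]
    return fo, po


def test_match_equals_brute_force_oracle(rng):
    """Verdict and fit RMSD agree with exhaustive enumeration on 200 random
    small instances."""
    n_checked = 0
    for _ in range(200):
        feats, points = _random_instance(rng)
        model = PharmacophoreModel(features=tuple(feats))
        conformer = _PointConformer(points)
        hit = match(conformer, model)
        fo, po = _to_oracle(feats, points)
        expected = brute_force_match(po, fo)
        if expected is None:
            assert hit is None
        else:
            assert hit is not None
            assert abs(hit.fit_rmsd - expected[0]) < 1e-6
            n_checked += 1
    assert n_checked > 20  # the ensemble of instances must exercise real hits


def test_match_rigid_motion_invariance(rng):
    for _ in range(30):
        feats, points = _random_instance(rng)
        model = PharmacophoreModel(features=tuple(feats))
        hit1 = match(_PointConformer(points), model)
        t = RigidTransform.from_euler(rng.uniform(-180, 180, 3), rng.uniform(-8, 8, 3))
        hit2 = match(_PointConformer([p.transformed(t) for p in points]), model)
        assert (hit1 is None) == (hit2 is None)
        if hit1 is not None:
            assert abs(hit1.fit_rmsd - hit2.fit_rmsd) < 1e-6


def test_constraint_monotonicity(rng):
    """Growing radii, removing volumes, or demoting essential features can
    never turn a hit into a miss."""
    from dataclasses import replace

    n_hits = 0
    for _ in range(60):
        feats, points = _random_instance(rng)
        ev = ExcludedVolume(rng.uniform(-4, 4, 3), float(rng.uniform(1.0, 2.0)))
        model = PharmacophoreModel(features=tuple(feats), excluded_volumes=(ev,))
        conformer = _PointConformer(points)
        hit = match(conformer, model)
        if hit is None:
            continue
        n_hits += 1
        bigger = PharmacophoreModel(
            features=tuple(replace(f, radius=f.radius + 0.5) for f in feats),
            excluded_volumes=(ev,),
        )
        assert match(conformer, bigger) is not None
        no_ev = PharmacophoreModel(features=tuple(feats))
        assert match(conformer, no_ev) is not None
        if any(f.essential for f in feats[1:]):
            demoted = PharmacophoreModel(
                features=(feats[0],)
                + tuple(replace(f, essential=False) for f in feats[1:]),
            )
            assert match(conformer, demoted) is not None
    assert n_hits > 5


def test_match_determinism(rng):
    feats, points = _random_instance(rng)
    model = PharmacophoreModel(features=tuple(feats))
    h1 = match(_PointConformer(points), model)
    h2 = match(_PointConformer(points), model)
    assert (h1 is None) == (h2 is None)
    if h1 is not None:
        assert h1.fit_rmsd == h2.fit_rmsd
        assert h1.matched_feature_names == h2.matched_feature_names


def test_pruning_preserves_candidates(rng):
    """The distance-compatibility pruning must not change the candidate set."""
    from d2pharm import matching

    for _ in range(20):
        feats, points = _random_instance(rng)
        model = PharmacophoreModel(features=tuple(feats))
        conformer = _PointConformer(points)
        with_pruning = enumerate_candidates(conformer, model)
        orig = matching._distance_compatible
        try:
            matching._distance_compatible = lambda *a, **k: True
            without = enumerate_candidates(conformer, model)
        finally:
            matching._distance_compatible = orig
        assert len(with_pruning) == len(without)
        for a, b in zip(with_pruning, without):
            assert abs(a.rmsd - b.rmsd) < 1e-9
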