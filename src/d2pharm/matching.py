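"""The pharmacophore matching engine.

Matching a conformer against a model enumerates kind-compatible, injective
assignments of ligand annotation points to features (essential features
must all be assigned; optional features may be skipped), computes the
least-squares rigid superposition of the assigned points onto the feature
centers, and accepts the assignment when

* every assigned point lies within its feature's radius,
* directional features (aromatic normals) agree within their angular
  tolerance — both normal signs are admissible,
* no ligand heavy atom falls strictly inside an excluded volume, and
* no ligand oxygen falls strictly inside the exclO sphere.

Directional features contribute a pseudo-point (center + unit direction)
to the superposition so that a two-feature cation/aromatic match is still
rigidly determined. The reported fit RMSD runs over all superposed pairs.
The best hit is the valid assignment of minimal fit RMSD, ties broken by
more optional features matched, then by assignment order, which makes the
matcher fully deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, UnderdeterminedError, rmsd as _rmsd, superpose, vector_angle_deg
from .model import Feature, PharmacophoreModel
from .perception import AnnotationPoint, perceive
from .results import Hit, LigandRow, ScreenReport

_PRUNE_EPS = 1e-9


def fit_rmsd(matched_pairs, transform: RigidTransform | None = None) -> float:
    """Root-mean-square distance between feature centers and their points.

    ``matched_pairs`` is a sequence of ``(point_xyz, center_xyz)`` pairs.
    When no transform is given one is derived by superposition, which
    requires at least three pairs.
    """
    pts = np.asarray([p for p, _ in matched_pairs], dtype=float)
    centers = np.asarray([c for _, c in matched_pairs], dtype=float)
    if transform is None:
        if len(pts) < 3:
            raise UnderdeterminedError("underdetermined superposition: need >= 3 pairs")
        transform = superpose(pts, centers)
    return _rmsd(transform.apply(pts), centers)


@dataclass
class Candidate:
    """One geometrically superposed assignment, before radius/volume tests.

    Pair distances and the fit RMSD depend only on the internal geometry of
    the feature cluster, so they stay valid when the whole cluster is
    rigidly re-placed during calibration; only the excluded-volume test
    must be re-run against the re-placed volumes.
    """

    feature_names: tuple[str, ...]
    pair_dists: np.ndarray  # per assigned feature, after superposition
    direction_angles: np.ndarray  # per directional assigned feature, degrees
    rmsd: float
    n_optional: int
    transform: RigidTransform
    heavy_xyz: np.ndarray  # ligand heavy atoms in the model frame
    oxygen_xyz: np.ndarray  # ligand oxygens in the model frame
    pairs: tuple  # ((feature_name, AnnotationPoint), ...)
    order_key: tuple


def _assignment_arrays(features, points, sign_choices):
    src, dst = [], []
    for f, p, sign in zip(features, points, sign_choices):
        src.append(p.position)
        dst.append(f.center)
        if f.direction is not None and p.direction is not None:
            src.append(p.position + sign * p.direction)
            dst.append(f.center + f.direction)
    return np.asarray(src), np.asarray(dst)


def enumerate_candidates(
    conformer,
    model: PharmacophoreModel,
    points: list[AnnotationPoint] | None = None,
    radius_slack: float = 0.0,
) -> list[Candidate]:
    """All superposable assignments whose pair distances pass the (slackened)
    radius test. ``radius_slack`` widens every feature radius, which lets a
    calibration cache keep candidates that only a larger radius would admit.
    """
    if points is None:
        points = perceive(conformer)
    by_kind: dict[str, list[tuple[int, AnnotationPoint]]] = {}
    for i, p in enumerate(points):
        by_kind.setdefault(p.kind, []).append((i, p))

    essentials = list(model.essential_features)
    optionals = list(model.optional_features)
    heavy = conformer.coords_heavy
    oxy = np.asarray(
        [p.position for p in points if p.kind == "oxygen_atom"], dtype=float
    ).reshape(-1, 3)

    candidates: list[Candidate] = []
    for r in range(len(optionals), -1, -1):
        for opt_subset in itertools.combinations(optionals, r):
            feats: list[Feature] = essentials + list(opt_subset)
            pools = []
            ok = True
            for f in feats:
                pool = [
                    (i, p)
                    for kind in f.compatible_kinds()
                    for (i, p) in by_kind.get(kind, [])
                ]
                if not pool:
                    ok = False
                    break
                pools.append(pool)
            if not ok:
                continue
            for combo in itertools.product(*pools):
                idxs = [i for i, _ in combo]
                if len(set(idxs)) != len(idxs):
                    continue
                pts = [p for _, p in combo]
                if not _distance_compatible(feats, pts, radius_slack):
                    continue
                sign_opts = [
                    (+1.0, -1.0)
                    if (f.direction is not None and p.direction is not None and f.kind == "aromatic")
                    else ((+1.0,) if (f.direction is not None and p.direction is not None) else (0.0,))
                    for f, p in zip(feats, pts)
                ]
                for signs in itertools.product(*sign_opts):
                    src, dst = _assignment_arrays(feats, pts, signs)
                    if len(src) < 3:
                        continue
                    try:
                        transform = superpose(src, dst)
                    except UnderdeterminedError:
                        continue
                    moved = transform.apply(np.asarray([p.position for p in pts]))
                    dists = np.linalg.norm(moved - np.asarray([f.center for f in feats]), axis=1)
                    if np.any(dists > np.asarray([f.radius for f in feats]) + radius_slack):
                        continue
                    angles = []
                    dir_ok = True
                    for f, p, sign in zip(feats, pts, signs):
                        if f.direction is None or p.direction is None:
                            continue
                        moved_dir = transform.rotation @ (
                            (sign if sign != 0.0 else 1.0) * p.direction
                        )
                        ang = vector_angle_deg(moved_dir, f.direction)
                        angles.append(ang)
                        if ang > f.direction_tol:
                            dir_ok = False
                            break
                    if not dir_ok:
                        continue
                    fit = fit_rmsd(
                        [(p.position, f.center) for f, p in zip(feats, pts)]
                        + _pseudo_pairs(feats, pts, signs),
                        transform,
                    )
                    candidates.append(
                        Candidate(
                            feature_names=tuple(f.name for f in feats),
                            pair_dists=dists,
                            direction_angles=np.asarray(angles),
                            rmsd=fit,
                            n_optional=len(opt_subset),
                            transform=transform,
                            heavy_xyz=transform.apply(heavy),
                            oxygen_xyz=transform.apply(oxy) if len(oxy) else oxy,
                            pairs=tuple((f.name, p) for f, p in zip(feats, pts)),
                            order_key=tuple(idxs) + signs,
                        )
                    )
    candidates.sort(key=lambda c: (c.rmsd, -c.n_optional, c.order_key))
    return candidates


def _pseudo_pairs(feats, pts, signs):
    out = []
    for f, p, sign in zip(feats, pts, signs):
        if f.direction is not None and p.direction is not None:
            s = sign if sign != 0.0 else 1.0
            out.append((p.position + s * p.direction, f.center + f.direction))
    return out


def _distance_compatible(feats, pts, slack: float) -> bool:
    """Necessary condition: inter-point vs inter-feature distances must agree
    within the sum of the two radii (plus slack) for the points to both land
    inside their spheres."""
    n = len(feats)
    for i in range(n):
        for j in range(i + 1, n):
            dp = np.linalg.norm(pts[i].position - pts[j].position)
            df = np.linalg.norm(feats[i].center - feats[j].center)
            if abs(dp - df) > feats[i].radius + feats[j].radius + 2 * slack + _PRUNE_EPS:
                return False
    return True


def _violates_volumes(cand: Candidate, model: PharmacophoreModel) -> bool:
    if model.excluded_volumes and len(cand.heavy_xyz):
        centers = np.asarray([ev.center for ev in model.excluded_volumes])
        radii = np.asarray([ev.radius for ev in model.excluded_volumes])
        d = np.linalg.norm(cand.heavy_xyz[:, None, :] - centers[None, :, :], axis=2)
        if np.any(d < radii[None, :] - _PRUNE_EPS):
            return True
    if model.exclO is not None and len(cand.oxygen_xyz):
        d = np.linalg.norm(cand.oxygen_xyz - model.exclO.center, axis=1)
        if np.any(d < model.exclO.radius - _PRUNE_EPS):
            return True
    return False


def match(
    conformer,
    model: PharmacophoreModel,
    points: list[AnnotationPoint] | None = None,
    conformer_index: int = 0,
) -> Hit | None:
    """Best valid hit of one conformer in the model, or ``None``."""
    for cand in enumerate_candidates(conformer, model, points=points):
        if _violates_volumes(cand, model):
            continue
        return Hit(
            ligand_id=getattr(conformer, "ligand_id", ""),
            conformer_index=conformer_index,
            transform=cand.transform,
            fit_rmsd=cand.rmsd,
            matched_pairs=cand.pairs,
            delta_e=getattr(conformer, "delta_e", 0.0),
            n_optional=cand.n_optional,
        )
    return None


def screen(
    ensembles,
    model: PharmacophoreModel,
    records=None,
) -> ScreenReport:
    """Screen conformer ensembles against a model.

    ``ensembles`` maps ligand id -> :class:`ConformerEnsemble` (a plain list
    of ensembles is also accepted). Per ligand the report carries the number
    of conformers (#c), the number of hitting conformers (#h) and the best
    hit — the hit of lowest strain energy, ties broken by lower fit RMSD.
    """
    if not isinstance(ensembles, dict):
        ensembles = {e.ligand_id: e for e in ensembles}
    if not ensembles:
        raise ValueError("no ensembles to screen")
    classes = {}
    if records is not None:
        classes = {r.id: r.activity_class for r in records}
    rows = []
    for lig_id, ens in ensembles.items():
        n_hits = 0
        best: Hit | None = None
        for ci, conf in enumerate(ens):
            hit = match(conf, model, conformer_index=ci)
            if hit is None:
                continue
            n_hits += 1
            if best is None or (hit.delta_e, hit.fit_rmsd) < (best.delta_e, best.fit_rmsd):
                best = hit
        rows.append(
            LigandRow(
                ligand_id=lig_id,
                activity_class=classes.get(lig_id),
                n_conformers=len(ens),
                n_hits=n_hits,
                best_hit=best,
            )
        )
    return ScreenReport(rows=rows)
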