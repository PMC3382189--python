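"""Automated calibration of the model placement against the training set.

The reference procedure tuned the alignment of the feature cluster
relative to the excluded-volume set by hand, judged by the hit rate of the
30-ligand training set. Here the same objective — actives in, inactives
out — is optimised by a seeded derivative-free search over

* the rigid placement of the feature cluster (±2 A translation, ±20 deg
  rotation per axis),
* the per-feature match radii (0.5–1.5 A),
* bounded adjustments (±0.4 A) of the excluded-volume radii per origin
  tag and of the exclO radius.

Because a rigid re-placement of the whole feature cluster leaves the
internal superposition of every candidate pose unchanged, candidate poses
are enumerated once per conformer and each objective evaluation only
re-tests pair distances against the trial radii and re-runs the
excluded-volume clash test against the re-placed volumes. The search is
random restarts plus coordinate descent with monotone acceptance: the
incumbent objective never decreases along the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import RigidTransform
from .matching import enumerate_candidates
from .model import ExclusionSphere, ExcludedVolume, PharmacophoreModel
from .results import ScreenReport

log = logging.getLogger(__name__)


@dataclass
class ObjectiveWeights:
    w_full: float = 1.0
    w_partial: float = 0.5
    w_inactive: float = 1.0


@dataclass
class CalibrationConfig:
    translation_bound: float = 2.0  # Å per axis
    rotation_bound: float = 20.0  # degrees per axis
    radius_bounds: tuple[float, float] = (0.5, 1.5)  # Å, per-feature match radii
    ev_radius_delta: float = 0.4  # Å, around the default EV radii
    weights: ObjectiveWeights = field(default_factory=ObjectiveWeights)
    seed: int = 2012
    budget: int = 2000  # objective evaluations
    n_restarts: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.radius_bounds
        if not (0 < lo <= hi):
            raise ValueError("radius bounds must satisfy 0 < lo <= hi")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class CalibrationResult:
    model: PharmacophoreModel
    objective: float
    objective_trace: list[float]
    confusion: dict[str, tuple[int, int]]  # class -> (hit, total)
    params: dict
    warning: bool = False  # no improvement found within budget


def objective(report: ScreenReport, weights: ObjectiveWeights | None = None) -> float:
    """Training-set discrimination score: actives in, inactives out."""
    w = weights or ObjectiveWeights()
    counts = report.class_counts()
    full, _ = counts.get("full", (0, 0))
    partial, _ = counts.get("partial", (0, 0))
    inactive, _ = counts.get("inactive", (0, 0))
    return w.w_full * full + w.w_partial * partial - w.w_inactive * inactive


# ---------------------------------------------------------------------------
# cached fast evaluation


class _LigandCache:
    """Per-ligand stacked candidate poses, radii-agnostic."""

    def __init__(self, ligand_id, activity_class, model, ensemble, radius_slack):
        self.ligand_id = ligand_id
        self.activity_class = activity_class
        feat_index = {f.name: i for i, f in enumerate(model.features)}
        dists, atoms, oxys, rmsds, conf_idx = [], [], [], [], []
        for ci, conf in enumerate(ensemble):
            for cand in enumerate_candidates(conf, model, radius_slack=radius_slack):
                row = np.zeros(len(model.features))
                for name, d in zip(cand.feature_names, cand.pair_dists):
                    row[feat_index[name]] = d
                dists.append(row)
                atoms.append(cand.heavy_xyz)
                oxys.append(cand.oxygen_xyz)
                rmsds.append(cand.rmsd)
                conf_idx.append(ci)
        self.n_pose = len(dists)
        self.n_conformers = len(ensemble)
        if self.n_pose == 0:
            return
        order = np.argsort(rmsds, kind="stable")
        self.pair_dists = np.asarray(dists)[order]
        max_a = max(len(a) for a in atoms)
        max_o = max((len(o) for o in oxys), default=0)
        FAR = 1e6
        self.atoms = np.full((self.n_pose, max_a, 3), FAR)
        self.oxy = np.full((self.n_pose, max(max_o, 1), 3), FAR)
        for i, oi in enumerate(order):
            self.atoms[i, : len(atoms[oi])] = atoms[oi]
            if len(oxys[oi]):
                self.oxy[i, : len(oxys[oi])] = oxys[oi]
        self.conf_idx = np.asarray(conf_idx)[order]

    def hits(self, radii, ev_centers, ev_radii, exclo_center, exclo_radius):
        """(ligand hit?, hitting conformer indices) under trial parameters."""
        if self.n_pose == 0:
            return False, np.zeros(0, dtype=int)
        valid = (self.pair_dists <= radii[None, :] + 1e-9).all(axis=1)
        if not np.any(valid):
            return False, np.zeros(0, dtype=int)
        atoms = self.atoms[valid]
        d2 = ((atoms[:, :, None, :] - ev_centers[None, None, :, :]) ** 2).sum(-1)
        clash = (d2 < (ev_radii**2)[None, None, :] - 1e-9).any(axis=(1, 2))
        if exclo_center is not None:
            oxy = self.oxy[valid]
            d2o = ((oxy - exclo_center[None, None, :]) ** 2).sum(-1)
            clash |= (d2o < exclo_radius**2 - 1e-9).any(axis=1)
        ok = ~clash
        return bool(ok.any()), np.unique(self.conf_idx[valid][ok])


class CalibrationEvaluator:
    """Evaluates trial parameter vectors against cached candidate poses."""

    def __init__(self, model0, ensembles, records, config, anchor_set=None):
        self.model0 = model0
        self.config = config
        self.anchor_set = anchor_set
        classes = {r.id: r.activity_class for r in records}
        slack = max(0.0, config.radius_bounds[1] - min(f.radius for f in model0.features))
        self.caches = [
            _LigandCache(lid, classes.get(lid), model0, ens, slack)
            for lid, ens in ensembles.items()
        ]
        self.ev_centers = np.asarray([ev.center for ev in model0.excluded_volumes]).reshape(
            -1, 3
        )
        self.ev_tags = [ev.origin_tag for ev in model0.excluded_volumes]
        self.ev_radii0 = np.asarray([ev.radius for ev in model0.excluded_volumes])
        self.exclo0 = model0.exclO

    def params0(self) -> dict:
        return {
            "translation": np.zeros(3),
            "rotation": np.zeros(3),
            "feature_radii": np.asarray([f.radius for f in self.model0.features]),
            "d_hydrogen": 0.0,
            "d_ring": 0.0,
            "d_exclO": 0.0,
        }

    def _volumes(self, params):
        transform = RigidTransform.from_euler(params["rotation"], params["translation"])
        inv = transform.inverse()
        centers = inv.apply(self.ev_centers) if len(self.ev_centers) else self.ev_centers
        radii = self.ev_radii0 + np.asarray(
            [
                params["d_ring"] if tag == "ring_centroid" else params["d_hydrogen"]
                for tag in self.ev_tags
            ]
        )
        exclo_center = None
        exclo_radius = 0.0
        if self.exclo0 is not None:
            exclo_center = inv.apply(self.exclo0.center[None, :])[0]
            exclo_radius = self.exclo0.radius + params["d_exclO"]
        return centers, radii, exclo_center, exclo_radius

    def class_counts(self, params) -> dict[str, tuple[int, int]]:
        centers, radii, exclo_c, exclo_r = self._volumes(params)
        counts: dict[str, list[int]] = {}
        for cache in self.caches:
            hit, _ = cache.hits(params["feature_radii"], centers, radii, exclo_c, exclo_r)
            h, t = counts.get(cache.activity_class or "unknown", [0, 0])
            counts[cache.activity_class or "unknown"] = [h + (1 if hit else 0), t + 1]
        return {k: (v[0], v[1]) for k, v in counts.items()}

    def score(self, params) -> float:
        counts = self.class_counts(params)
        w = self.config.weights
        return (
            w.w_full * counts.get("full", (0, 0))[0]
            + w.w_partial * counts.get("partial", (0, 0))[0]
            - w.w_inactive * counts.get("inactive", (0, 0))[0]
        )

    def realise(self, params) -> PharmacophoreModel:
        """Bake a parameter vector into a standalone model."""
        transform = RigidTransform.from_euler(params["rotation"], params["translation"])
        feats = []
        for f, r in zip(self.model0.features, params["feature_radii"]):
            center = transform.apply(f.center[None, :])[0]
            direction = None if f.direction is None else transform.rotation @ f.direction
            feats.append(replace(f, center=center, radius=float(r), direction=direction))
        evs = tuple(
            ExcludedVolume(center=c, radius=float(r), origin_tag=tag)
            for c, r, tag in zip(
                self.ev_centers,
                self.ev_radii0
                + np.asarray(
                    [
                        params["d_ring"] if tag == "ring_centroid" else params["d_hydrogen"]
                        for tag in self.ev_tags
                    ]
                ),
                self.ev_tags,
            )
        )
        exclo = None
        if self.exclo0 is not None:
            exclo = ExclusionSphere(
                self.exclo0.center, float(self.exclo0.radius + params["d_exclO"])
            )
        return PharmacophoreModel(
            features=tuple(feats),
            excluded_volumes=evs,
            exclO=exclo,
            frame_tag=self.model0.frame_tag + "+calibrated",
        )


def _perturbation_norms(params, params0, bounds):
    radius_pert = float(
        np.abs(params["feature_radii"] - params0["feature_radii"]).sum()
        + abs(params["d_hydrogen"])
        + abs(params["d_ring"])
        + abs(params["d_exclO"])
    )
    transform_norm = float(
        np.linalg.norm(params["translation"]) + np.linalg.norm(params["rotation"]) / 10.0
    )
    return radius_pert, transform_norm


def calibrate(
    model0: PharmacophoreModel,
    ensembles,
    records,
    config: CalibrationConfig | None = None,
    anchor_set=None,
) -> CalibrationResult:
    """Seeded search over the model placement maximising discrimination.

    ``ensembles`` maps ligand id to a pre-generated (seeded) ensemble so the
    objective landscape is deterministic. Returns the best model found; its
    objective is never below that of ``model0``. When the budget is
    exhausted without any improvement the input model is returned with a
    warning flag.
    """
    config = config or CalibrationConfig()
    if not isinstance(ensembles, dict):
        ensembles = {e.ligand_id: e for e in ensembles}
    known = {r.id for r in records}
    missing = [lid for lid in ensembles if lid not in known]
    if missing:
        raise ValueError(f"ensembles for unknown ligands: {missing}")
    rng = np.random.default_rng(config.seed)
    ev = CalibrationEvaluator(model0, ensembles, records, config, anchor_set)

    p0 = ev.params0()
    lo_r, hi_r = config.radius_bounds
    nf = len(p0["feature_radii"])

    def clamp(params):
        out = dict(params)
        out["translation"] = np.clip(
            params["translation"], -config.translation_bound, config.translation_bound
        )
        out["rotation"] = np.clip(
            params["rotation"], -config.rotation_bound, config.rotation_bound
        )
        out["feature_radii"] = np.clip(params["feature_radii"], lo_r, hi_r)
        for k in ("d_hydrogen", "d_ring", "d_exclO"):
            out[k] = float(np.clip(params[k], -config.ev_radius_delta, config.ev_radius_delta))
        return out

    evaluations = 0
    trace: list[float] = []
    best_params = None
    best_key = None

    def key_of(params, score):
        rp, tn = _perturbation_norms(params, p0, config)
        return (score, -rp, -tn)

    def evaluate(params):
        nonlocal evaluations, best_params, best_key
        if evaluations >= config.budget:
            return None
        evaluations += 1
        s = ev.score(params)
        k = key_of(params, s)
        if best_key is None or k > best_key:
            best_key, best_params = k, {kk: np.copy(v) if isinstance(v, np.ndarray) else v for kk, v in params.items()}
        trace.append(best_key[0])
        return s

    base_score = evaluate(p0)

    steps = [
        ("translation", 0, 0.5), ("translation", 1, 0.5), ("translation", 2, 0.5),
        ("rotation", 0, 5.0), ("rotation", 1, 5.0), ("rotation", 2, 5.0),
    ]
    steps += [("feature_radii", i, 0.15) for i in range(nf)]
    steps += [("d_hydrogen", None, 0.15), ("d_ring", None, 0.15), ("d_exclO", None, 0.15)]

    def descend(start, start_score):
        current, cur_score = start, start_score
        for scale in (1.0, 0.5, 0.25):
            improved = True
            while improved and evaluations < config.budget:
                improved = False
                for name, idx, step in steps:
                    for sign in (+1.0, -1.0):
                        trial = {
                            k: np.copy(v) if isinstance(v, np.ndarray) else v
                            for k, v in current.items()
                        }
                        if idx is None:
                            trial[name] = trial[name] + sign * step * scale
                        else:
                            trial[name][idx] += sign * step * scale
                        trial = clamp(trial)
                        s = evaluate(trial)
                        if s is None:
                            return current, cur_score
                        if s > cur_score:
                            current, cur_score = trial, s
                            improved = True
                            break
        return current, cur_score

    incumbent, inc_score = descend(p0, base_score)

    for _ in range(config.n_restarts):
        if evaluations >= config.budget:
            break
        start = clamp(
            {
                "translation": rng.uniform(-1, 1, 3) * config.translation_bound,
                "rotation": rng.uniform(-1, 1, 3) * config.rotation_bound,
                "feature_radii": rng.uniform(lo_r, hi_r, nf),
                "d_hydrogen": float(rng.uniform(-1, 1) * config.ev_radius_delta),
                "d_ring": float(rng.uniform(-1, 1) * config.ev_radius_delta),
                "d_exclO": float(rng.uniform(-1, 1) * config.ev_radius_delta),
            }
        )
        s = evaluate(start)
        if s is None:
            break
        descend(start, s)

    warning = best_key is not None and base_score is not None and best_key[0] <= base_score
    if warning:
        # no strict improvement: return the input model (its own parameters)
        best_params = p0
    confusion = ev.class_counts(best_params)
    model = ev.realise(best_params)
    log.info(
        "calibration: objective %.2f after %d evaluations (warning=%s)",
        best_key[0] if best_key else float("nan"),
        evaluations,
        warning,
    )
    return CalibrationResult(
        model=model,
        objective=float(best_key[0]) if best_key else float("nan"),
        objective_trace=trace,
        confusion=confusion,
        params={
            k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in best_params.items()
        },
        warning=warning,
    )
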