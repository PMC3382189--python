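"""Pharmacophore model: features, excluded volumes and the exclO sphere.

The refined D2 full-agonist model holds three features — the Asp-TM3 salt
bridge (essential), the aromatic system with direction (essential) and the
Ser-TM5 projected hydrogen-bond feature (optional) — plus a set of excluded
volumes encoding the steric envelope of the agonist binding pocket and an
excluded-oxygen sphere that rejects ligands placing an ether/hydroxy oxygen
into a hydrophobic region of the pocket.

Models serialise to a versioned JSON document (angstrom units,
right-handed frame).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

SCHEMA_VERSION = 1

# feature kind -> annotation-point kinds it may consume
KIND_COMPAT = {
    "cation": ("cation",),
    "aromatic": ("aromatic",),
    "hbond": ("donor_proj", "acceptor_proj"),
    "donor_proj": ("donor_proj",),
    "acceptor_proj": ("acceptor_proj",),
    "acceptor_atom": ("acceptor_atom",),
}

EV_TAGS = ("aliphatic_H", "aromatic_H", "polar_H", "ring_centroid")

# polar hydrogens are not assigned a Bondi radius; they take the aromatic value
EV_RADII_INITIAL = {"aliphatic_H": 1.2, "aromatic_H": 1.0, "polar_H": 1.0}
EV_RADII_FINAL = {"aliphatic_H": 2.0, "aromatic_H": 1.8, "polar_H": 1.8, "ring_centroid": 2.5}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class Feature:
    name: str
    kind: str
    center: np.ndarray
    radius: float
    essential: bool = True
    direction: np.ndarray | None = None
    direction_tol: float = 30.0  # degrees

    def __post_init__(self) -> None:
        if self.kind not in KIND_COMPAT:
            raise ModelError(f"unknown feature kind {self.kind!r}")
        if self.radius <= 0:
            raise ModelError("feature radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            object.__setattr__(self, "direction", d / np.linalg.norm(d))

    def compatible_kinds(self) -> tuple[str, ...]:
        return KIND_COMPAT[self.kind]


@dataclass(frozen=True)
class ExcludedVolume:
    center: np.ndarray
    radius: float
    origin_tag: str = "aliphatic_H"

    def __post_init__(self) -> None:
        if self.origin_tag not in EV_TAGS:
            raise ModelError(f"unknown excluded-volume tag {self.origin_tag!r}")
        if self.radius <= 0:
            raise ModelError("excluded-volume radius must be positive")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class ExclusionSphere:
    """exclO: a sphere no ligand oxygen may enter."""

    center: np.ndarray
    radius: float = 1.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass(frozen=True)
class PharmacophoreModel:
    features: tuple[Feature, ...]
    excluded_volumes: tuple[ExcludedVolume, ...] = ()
    exclO: ExclusionSphere | None = None
    frame_tag: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))
        object.__setattr__(self, "excluded_volumes", tuple(self.excluded_volumes))
        if not any(f.essential for f in self.features):
            raise ModelError("a model needs at least one essential feature")

    @property
    def essential_features(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if f.essential)

    @property
    def optional_features(self) -> tuple[Feature, ...]:
        return tuple(f for f in self.features if not f.essential)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def with_features(self, features) -> "PharmacophoreModel":
        return replace(self, features=tuple(features))


def ablate(model: PharmacophoreModel, mode: str) -> PharmacophoreModel:
    """Ablated copies used in the discrimination experiments.

    ``drop_excluded_volumes`` removes every excluded volume (the exclO
    sphere is a distinct hit criterion and is retained); ``tm5_essential``
    promotes the optional Ser-TM5 hydrogen-bond feature to essential.
    """
    if mode == "drop_excluded_volumes":
        return replace(model, excluded_volumes=())
    if mode == "tm5_essential":
        feats = [
            replace(f, essential=True) if f.kind == "hbond" else f for f in model.features
        ]
        return model.with_features(feats)
    raise ModelError(f"unknown ablation mode {mode!r}")


def _vec(x) -> list[float]:
    return [float(v) for v in x]


def model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "units": "angstrom",
        "frame": "right-handed",
        "frame_tag": model.frame_tag,
        "features": [
            {
                "name": f.name,
                "kind": f.kind,
                "center": _vec(f.center),
                "radius": float(f.radius),
                "essential": bool(f.essential),
                "direction": None if f.direction is None else _vec(f.direction),
                "direction_tol": float(f.direction_tol),
            }
            for f in model.features
        ],
        "excluded_volumes": [
            {"center": _vec(ev.center), "radius": float(ev.radius), "origin_tag": ev.origin_tag}
            for ev in model.excluded_volumes
        ],
        "exclO": None
        if model.exclO is None
        else {"center": _vec(model.exclO.center), "radius": float(model.exclO.radius)},
    }


def model_from_dict(doc: dict) -> PharmacophoreModel:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ModelError(f"unsupported schema version {doc.get('schema_version')!r}")
    features = tuple(
        Feature(
            name=f["name"],
            kind=f["kind"],
            center=f["center"],
            radius=f["radius"],
            essential=f["essential"],
            direction=f.get("direction"),
            direction_tol=f.get("direction_tol", 30.0),
        )
        for f in doc["features"]
    )
    evs = tuple(
        ExcludedVolume(center=e["center"], radius=e["radius"], origin_tag=e["origin_tag"])
        for e in doc.get("excluded_volumes", [])
    )
    exclo = doc.get("exclO")
    sphere = None if exclo is None else ExclusionSphere(exclo["center"], exclo["radius"])
    return PharmacophoreModel(
        features=features, excluded_volumes=evs, exclO=sphere, frame_tag=doc.get("frame_tag", "")
    )


def save_model(model: PharmacophoreModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")


def load_model(path) -> PharmacophoreModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
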