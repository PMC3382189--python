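"""Result containers shared by the matcher, screen loop and reporting."""

from __future__ import annotations

from dataclasses import dataclass, field

from .geometry import RigidTransform


@dataclass
class Hit:
    """A conformer matched into the model frame."""

    ligand_id: str
    conformer_index: int
    transform: RigidTransform
    fit_rmsd: float
    matched_pairs: tuple  # ((feature_name, AnnotationPoint), ...)
    delta_e: float
    n_optional: int = 0

    @property
    def matched_feature_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.matched_pairs)


@dataclass
class LigandRow:
    ligand_id: str
    activity_class: str | None
    n_conformers: int
    n_hits: int
    best_hit: Hit | None = None
    hbond_records: list = field(default_factory=list)

    @property
    def hit(self) -> bool:
        return self.n_hits > 0


@dataclass
class ScreenReport:
    rows: list[LigandRow]

    def row(self, ligand_id: str) -> LigandRow:
        for r in self.rows:
            if r.ligand_id == ligand_id:
                return r
        raise KeyError(ligand_id)

    @property
    def hit_ids(self) -> set[str]:
        return {r.ligand_id for r in self.rows if r.hit}

    def class_counts(self) -> dict[str, tuple[int, int]]:
        """activity class -> (ligands hit, ligands screened)."""
        out: dict[str, list[int]] = {}
        for r in self.rows:
            cls = r.activity_class or "unknown"
            hit, tot = out.get(cls, [0, 0])
            out[cls] = [hit + (1 if r.hit else 0), tot + 1]
        return {k: (v[0], v[1]) for k, v in out.items()}
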