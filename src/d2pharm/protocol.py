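"""The end-to-end screening protocol used for reproducing the headline
discrimination result: seeded ensembles, calibration of the shipped model
on the training set, then the final screen and the ablation experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .anchors import AnchorSet, load_default_anchor_set
from .calibrate import CalibrationConfig, CalibrationResult, calibrate
from .conformers import DEFAULT_WINDOW, generate_library_ensembles
from .ligands import build_library
from .model import PharmacophoreModel, ablate
from .reporting import screen_and_annotate
from .results import ScreenReport

log = logging.getLogger(__name__)

# Problem size of the standard run: up to 150 conformers per ligand inside
# the 4 kcal/mol window samples the accessible conformational space of this
# library densely (most ligands exhaust their minima well below the cap)
# while keeping a full calibration + screen comfortably interactive.
PROTOCOL_MAX_CONFS = 150
PROTOCOL_BUDGET = 2000


def shipped_model() -> PharmacophoreModel:
    from importlib import resources
    from .model import model_from_dict
    import json

    path = resources.files("d2pharm.data").joinpath("refined_model.json")
    with path.open() as fh:
        return model_from_dict(json.load(fh))


@dataclass
class DiscriminationRun:
    report: ScreenReport
    calibration: CalibrationResult
    counts: dict[str, tuple[int, int]]
    ablation_no_ev: ScreenReport
    ablation_tm5: ScreenReport


def run_discrimination(
    seed: int,
    max_confs: int = PROTOCOL_MAX_CONFS,
    budget: int = PROTOCOL_BUDGET,
    window: float = DEFAULT_WINDOW,
    with_ablation: bool = True,
) -> DiscriminationRun:
    """Full protocol: ensembles -> calibration -> screen (+ ablations)."""
    records = build_library()
    model0 = shipped_model()
    anchor_set: AnchorSet = load_default_anchor_set()
    log.info("generating ensembles (max %d conformers, %.1f kcal/mol)", max_confs, window)
    ensembles = generate_library_ensembles(
        records, window=window, max_confs=max_confs, seed=seed
    )
    log.info("calibrating (budget %d evaluations)", budget)
    config = CalibrationConfig(seed=seed, budget=budget)
    calib = calibrate(model0, ensembles, records, config, anchor_set)
    report = screen_and_annotate(ensembles, calib.model, records, anchor_set)
    counts = report.class_counts()
    log.info("discrimination: %s", counts)

    ab_no_ev = ab_tm5 = None
    if with_ablation:
        no_ev = ablate(calib.model, "drop_excluded_volumes")
        tm5 = ablate(no_ev, "tm5_essential")
        ab_no_ev = screen_and_annotate(ensembles, no_ev, records, anchor_set)
        ab_tm5 = screen_and_annotate(ensembles, tm5, records, anchor_set)
    return DiscriminationRun(
        report=report,
        calibration=calib,
        counts=counts,
        ablation_no_ev=ab_no_ev,
        ablation_tm5=ab_tm5,
    )
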