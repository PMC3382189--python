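"""Screen reports in the style of the training-table, and ablation runs."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .anchors import AnchorSet, HBondRecord, best_record_per_anchor, evaluate_hit
from .matching import screen
from .model import PharmacophoreModel, ablate
from .results import LigandRow, ScreenReport

log = logging.getLogger(__name__)

FORMATS = ("tsv", "csv", "markdown", "json")


def annotate_hbonds(report: ScreenReport, ensembles, anchor_set: AnchorSet) -> ScreenReport:
    """Attach H-bond records (vs. each named anchor) to every best hit."""
    if not isinstance(ensembles, dict):
        ensembles = {e.ligand_id: e for e in ensembles}
    for row in report.rows:
        if row.best_hit is None:
            row.hbond_records = []
            continue
        conf = ensembles[row.ligand_id].conformers[row.best_hit.conformer_index]
        row.hbond_records = evaluate_hit(row.best_hit, conf, anchor_set)
    return report


def screen_and_annotate(ensembles, model, records, anchor_set=None) -> ScreenReport:
    report = screen(ensembles, model, records=records)
    if anchor_set is not None:
        annotate_hbonds(report, ensembles, anchor_set)
    return report


def _hb_cell(records: list[HBondRecord], anchor_prefix: str) -> str:
    cells = []
    for rec in records:
        if not rec.anchor.startswith(anchor_prefix):
            continue
        flag = "*" if rec.verdict == "borderline" else ("!" if rec.verdict == "fail" else "")
        label = f"{rec.group} " if rec.group else ""
        cells.append(f"{label}{rec.d:.1f}({rec.angle:.0f}){flag}")
    return " ".join(cells)


def report_to_dataframe(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for r in report.rows:
        best = r.best_hit
        hb = {a: rec for a, rec in best_record_per_anchor(r.hbond_records).items()}
        rows.append(
            {
                "ligand": r.ligand_id,
                "class": r.activity_class,
                "delta_e": None if best is None else round(best.delta_e, 2),
                "fit_rmsd": None if best is None else round(best.fit_rmsd, 3),
                "n_conformers": r.n_conformers,
                "n_hits": r.n_hits,
                "S193_d_angle": _hb_cell(r.hbond_records, "Ser193:OG"),
                "H393_d_angle": _hb_cell(r.hbond_records, "His393"),
            }
        )
        del hb
    columns = [
        "ligand", "class", "delta_e", "fit_rmsd", "n_conformers", "n_hits",
        "S193_d_angle", "H393_d_angle",
    ]
    return pd.DataFrame(rows, columns=columns)


def report_to_dict(report: ScreenReport) -> dict:
    out = {"rows": [], "summary": {}}
    for r in report.rows:
        best = r.best_hit
        out["rows"].append(
            {
                "ligand": r.ligand_id,
                "class": r.activity_class,
                "n_conformers": r.n_conformers,
                "n_hits": r.n_hits,
                "best_delta_e": None if best is None else best.delta_e,
                "best_fit_rmsd": None if best is None else best.fit_rmsd,
                "hbonds": [
                    {
                        "anchor": h.anchor,
                        "d": h.d,
                        "angle": h.angle,
                        "verdict": h.verdict,
                        "group": h.group,
                    }
                    for h in r.hbond_records
                ],
            }
        )
    out["summary"] = {
        cls: {"hit": hit, "total": tot} for cls, (hit, tot) in report.class_counts().items()
    }
    return out


def report_from_dict(doc: dict) -> ScreenReport:
    rows = []
    for r in doc["rows"]:
        row = LigandRow(
            ligand_id=r["ligand"],
            activity_class=r["class"],
            n_conformers=r["n_conformers"],
            n_hits=r["n_hits"],
        )
        if r["best_delta_e"] is not None:
            from .results import Hit
            from .geometry import RigidTransform

            row.best_hit = Hit(
                ligand_id=r["ligand"],
                conformer_index=-1,
                transform=RigidTransform.identity(),
                fit_rmsd=r["best_fit_rmsd"],
                matched_pairs=(),
                delta_e=r["best_delta_e"],
            )
        row.hbond_records = [
            HBondRecord(h["anchor"], h["d"], h["angle"], h["verdict"], h["group"])
            for h in r["hbonds"]
        ]
        rows.append(row)
    return ScreenReport(rows=rows)


def render_report(report: ScreenReport, fmt: str, path) -> None:
    """Write a report as tsv/csv/markdown (table-style) or json (lossless)."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    df = report_to_dataframe(report)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "markdown":
        with open(path, "w") as fh:
            fh.write(df.to_markdown(index=False))
            fh.write("\n")


def run_ablation_suite(
    model: PharmacophoreModel, ensembles, records, anchor_set=None
) -> dict[str, ScreenReport]:
    """Screens for (refined), (no EVs, TM5 optional), (no EVs, TM5 essential).

    Verifies the monotonicity relations between the hit sets: removing the
    excluded volumes can only add hits, and promoting the optional Ser-TM5
    feature to essential can only remove them.
    """
    no_ev = ablate(model, "drop_excluded_volumes")
    no_ev_tm5 = ablate(no_ev, "tm5_essential")
    reports = {
        "refined": screen_and_annotate(ensembles, model, records, anchor_set),
        "no_excluded_volumes": screen_and_annotate(ensembles, no_ev, records, anchor_set),
        "no_excluded_volumes_tm5_essential": screen_and_annotate(
            ensembles, no_ev_tm5, records, anchor_set
        ),
    }
    refined = reports["refined"].hit_ids
    relaxed = reports["no_excluded_volumes"].hit_ids
    strict = reports["no_excluded_volumes_tm5_essential"].hit_ids
    if not refined <= relaxed:
        raise AssertionError("hit-set monotonicity violated: refined ⊄ no-EV")
    if not strict <= relaxed:
        raise AssertionError("hit-set monotonicity violated: TM5-essential ⊄ TM5-optional")
    return reports
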