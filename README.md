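# d2pharm

3D pharmacophore screening for dopamine D2 **full agonists**: a tested,
reusable implementation of the refined D2-agonist pharmacophore protocol —
ligand annotation-point perception, rigid feature matching with excluded
volumes and an excluded-oxygen sphere, receptor-anchor hydrogen-bond
geometry, and automated calibration of the model placement against the
hit rate of a 30-ligand training set.

It is written for medicinal/computational chemists who want a transparent,
scriptable pharmacophore engine whose every geometric rule is unit-tested,
rather than a black-box modeling suite.

## The model

A ligand conformer hits the model when an assignment of its annotation
points to the features superposes (least-squares, Kabsch) such that every
matched point falls inside its feature sphere and no ligand atom violates
the steric model:

* **Asp-TM3** (essential) — the protonated amine nitrogen N⁺, the salt
  bridge to the conserved TM3 aspartate;
* **Aro** (essential) — aromatic ring centroid with unsigned normal **n̂**
  (tolerance 35°), the face-to-edge π contact with the TM6 cluster;
* **Ser-TM5** (optional) — a projected hydrogen-bond point 2.8 Å from the
  ligand donor/acceptor, where the TM5 serine hydroxyl would sit. Aryl-OH
  groups project two in-plane points separated by exactly 120°;
* **excluded volumes** — spheres of radius 2.0 Å (aliphatic H sites),
  1.8 Å (aromatic/polar H sites) and 2.5 Å (receptor ring centroids) that
  no ligand heavy atom may enter; Bondi radii (1.2/1.0 Å) are the
  documented starting values before tuning;
* **exclO** — a sphere no ligand *oxygen* may enter.

The fit RMSD is `sqrt(mean_i |R x_i + t − c_i|²)` over matched pairs, and
hydrogen bonds against named anchors (Ser193 OG, His393 NE2, …) are
accepted for heavy-atom distances d ∈ [2.4, 3.8] Å and donor–H–acceptor
angles 180±40°, with values just outside flagged as borderline.

Because the essential feature pair (a point and a point-with-axis) is
achiral, all discrimination between enantiomeric ligands comes from the
excluded-volume set — the model's surrogate for the chiral binding
pocket. See `docs/methods.md` for the construction and its assumptions.

## Worked example

Screen three ligands from the shipped 30-ligand training library against
the shipped refined model:

```python
import d2pharm
from d2pharm.protocol import shipped_model

records = [r for r in d2pharm.build_library()
           if r.id in {"(R)-sumanirole", "(S)-sumanirole", "dopamine"}]
model = shipped_model()
ens = {r.id: d2pharm.generate_conformers(r, max_confs=50, seed=2012)
       for r in records}
report = d2pharm.screen(ens, model, records=records)
for row in report.rows:
    print(f"{row.ligand_id:16s} {row.activity_class:8s} "
          f"#c={row.n_conformers:3d} #h={row.n_hits}")
```

```
(R)-sumanirole   full     #c=  2 #h=2
dopamine         full     #c=  4 #h=4
(S)-sumanirole   inactive #c=  2 #h=0
```

`#c` is the number of conformers within the 4 kcal/mol strain window and
`#h` how many of them fit the model. The (R)-enantiomer of sumanirole (a
full agonist) fits while its inactive mirror image is rejected by the
excluded volumes — the feature set alone cannot tell them apart — and
dopamine, the flexible reference agonist, fits with several conformers.

The same screen is available from the command line:

```bash
d2pharm screen --seed 2012 --format markdown --out report.md
d2pharm ablate --seed 2012 --out-dir ablation/
d2pharm calibrate --seed 2012 --out calibrated.json --trace-out trace.csv
```

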