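#!/usr/bin/env python
"""Render the synthetic first-layer network conditions used downstream.

Generates one network per study condition — perfect hexagonal, square,
sparse, amorphous (jittered), hexagonal with an 0.18 oil-inclusion target,
and a 72-site design with 9 excess droplets — and writes the 16-bit images
plus ground truth under scratch/networks/ (large binary artefacts) and a
per-condition summary table to results/networks.csv.
"""

from pathlib import Path

import pandas as pd

import droppack as dp

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "networks"
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

CONDITIONS = {
    "hexagonal": dict(spec=dp.LatticeSpec(lattice_type="hexagonal", nx=10, ny=10,
                                          spacing=45.0, droplet_radius=25.0, seed=SEED)),
    "square": dict(spec=dp.LatticeSpec(lattice_type="square", nx=10, ny=10,
                                       spacing=42.0, droplet_radius=25.0, seed=SEED)),
    "sparse": dict(spec=dp.LatticeSpec(lattice_type="sparse", nx=6, ny=6,
                                       spacing=45.0, droplet_radius=25.0, seed=SEED)),
    "amorphous": dict(spec=dp.LatticeSpec(lattice_type="amorphous", nx=10, ny=10,
                                          spacing=45.0, droplet_radius=25.0,
                                          jitter_sigma=9.0, seed=SEED)),
    "inclusions": dict(spec=dp.LatticeSpec(lattice_type="hexagonal", nx=12, ny=12,
                                           spacing=45.0, droplet_radius=25.0, seed=SEED),
                       inclusion_fraction=0.18),
    "excess": dict(spec=dp.LatticeSpec(lattice_type="hexagonal", nx=8, ny=9,
                                       spacing=45.0, droplet_radius=25.0, seed=SEED),
                   n_excess=9),
}

rows = []
for name, cond in CONDITIONS.items():
    net = dp.synthesize_network(
        cond["spec"],
        inclusion_fraction=cond.get("inclusion_fraction", 0.0),
        n_excess=cond.get("n_excess", 0),
    )
    dp.write_network(net, SCRATCH / name)
    inc = float(net.inclusion_mask.sum())
    total = inc + float((net.ground_truth_labels > 0).sum())
    rows.append(
        {
            "condition": name,
            "n_design": net.n_design,
            "n_active": len(net.centroids),
            "n_excess": net.n_excess,
            "oil_fraction_ground_truth": inc / total if total else 0.0,
            "image_h": net.shape[0],
            "image_w": net.shape[1],
        }
    )
    print(f"{name:12s} design={net.n_design:4d} active={len(net.centroids):4d} "
          f"excess={net.n_excess} oil_gt={inc/total if total else 0:.3f}")

pd.DataFrame(rows).to_csv(OUT / "networks.csv", index=False)
print(f"\nimages under {SCRATCH}; summary in {OUT/'networks.csv'}")
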