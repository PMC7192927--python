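#!/usr/bin/env python
"""Segment each simulated network and classify its local packing.

Reads the images written by 03_simulate_networks.py, runs ridge-based
segmentation, the droplet/inclusion morphology rules, Delaunay triangulation
and the packing classifier, and tabulates per-condition area fractions and
defect statistics into results/packing_fractions.csv. The perfect lattices
should classify almost entirely as their own class; the jittered lattice
should scatter across amorphous/no-packing; the inclusion and excess
networks should reproduce their injected defect levels.
"""

import warnings
from pathlib import Path

import pandas as pd

import droppack as dp

warnings.filterwarnings("ignore", category=FutureWarning)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "networks"
OUT = ROOT / "results"
OUT.mkdir(exist_ok=True)

if not SCRATCH.exists():
    raise SystemExit("run 03_simulate_networks.py first")

rows = []
for cond_dir in sorted(SCRATCH.iterdir()):
    if not (cond_dir / "membrane.tif").exists():
        continue
    import json

    meta = json.loads((cond_dir / "network.json").read_text())
    image = dp.load_image(cond_dir / "membrane.tif")
    seg = dp.segment_network(image)
    dp.classify_regions(seg)
    result = dp.analyze_network(seg, N_t=meta["n_design"])
    row = {
        "condition": cond_dir.name,
        "n_regions": seg.n_regions,
        "n_droplets": result.stats.N,
        "droplet_excess_pct": result.stats.droplet_excess_pct,
        "size_cv_pct": result.stats.size_cv_pct,
        "oil_fraction": result.stats.oil_fraction,
        **{f"frac_{k}": v for k, v in result.fractions.items()},
    }
    rows.append(row)
    print(
        f"{cond_dir.name:12s} droplets={result.stats.N:4d} "
        f"hex={result.fractions['hexagonal']:.3f} sq={result.fractions['square']:.3f} "
        f"amorph={result.fractions['amorphous']:.3f} none={result.fractions['no_packing']:.3f} "
        f"oil={result.stats.oil_fraction:.3f} excess={result.stats.droplet_excess_pct:+.1f}%"
    )

pd.DataFrame(rows).to_csv(OUT / "packing_fractions.csv", index=False)
print(f"\nwrote {OUT/'packing_fractions.csv'}")
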