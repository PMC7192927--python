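#!/usr/bin/env python
"""Closed-form droplet-pair geometry: the critical angle and pair deformation.

Computes the analytic constants that anchor the packing analysis — the
regular-tetrahedron dihedral angle, the critical contact angle theta_c at
which four tetrahedrally packed droplets exclude the interstitial oil, and
the volume of a 100 um printed droplet — then sweeps the contact angle to
tabulate how an equal droplet pair deforms (truncated-sphere radius,
centre-to-centre shrinkage, bilayer radius) and how the work of adhesion
grows. Writes results/pair_geometry.json and results/pair_deformation.csv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

import droppack as dp

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

constants = {
    "tetrahedron_dihedral_angle_deg": dp.tetrahedron_dihedral_angle(),
    "critical_contact_angle_deg": dp.critical_contact_angle(),
    "droplet_100um_volume_pL": dp.sphere_volume_pL(100.0),
}
print("Analytic constants:")
for k, v in constants.items():
    print(f"  {k} = {v:.4f}")

rows = []
for theta in np.arange(0.0, 90.0, 5.0):
    g = dp.equilibrium_pair_geometry(1.0, float(theta))
    e = dp.adhesion_energy(1.0, float(theta))
    rows.append(
        {
            "theta_deg": theta,
            "R_over_R0": g.R_theta,
            "L_over_R0": g.L_theta,
            "r_bilayer_over_R0": g.r_bilayer,
            "gamma_b_over_gamma_m": e.gamma_b,
            "delta_F_over_gamma_m": e.delta_F,
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "pair_deformation.csv", index=False)
(OUT / "pair_geometry.json").write_text(json.dumps(constants, indent=2))

shrink_at_tc = table.set_index("theta_deg")["L_over_R0"]
print(
    f"\nAt theta_c ~ 35 deg the centre distance has shrunk to "
    f"{float(np.interp(dp.critical_contact_angle(), table.theta_deg, table.L_over_R0)):.4f} "
    f"x R0 (from 2.0 at theta = 0): the deformation that repositions printed droplets."
)
print(f"wrote {OUT/'pair_geometry.json'} and {OUT/'pair_deformation.csv'}")
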