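"""Regenerate the frozen white-Monte-Carlo reference fixture.

Runs the seeded white MC engine once at high photon count and freezes
complex reflectance values on a probe grid spanning the default
look-up-table optical-property ranges, at the study geometry (20 mm
separation, n = 1.4). The pytest suite compares the diffusion forward
model against these frozen values; it never re-runs the big simulation.

Usage:  python scripts/build_mc_fixture.py [--photons N] [--seed S]
"""

import argparse
import json
import time
from pathlib import Path

import numpy as np

from hydronirs.montecarlo import WhiteMonteCarlo

OUT = Path(__file__).resolve().parents[1] / "tests" / "data" / "white_mc_reference.json"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--photons", type=int, default=20_000_000)
    ap.add_argument("--seed", type=int, default=20260926)
    args = ap.parse_args()

    engine = WhiteMonteCarlo(n_photons=args.photons, seed=args.seed)
    t0 = time.time()
    engine.run()
    elapsed = time.time() - t0

    rho = 20.0
    mua_probe = np.geomspace(0.001, 0.06, 5)
    musp_probe = np.geomspace(0.3, 2.5, 5)
    mm, ss = np.meshgrid(mua_probe, musp_probe, indexing="ij")
    records = []
    for f in (0.0, 126.0):
        r = engine.reflectance(mm, ss, rho, f)
        for i in range(mm.shape[0]):
            for j in range(mm.shape[1]):
                records.append(
                    {
                        "mua": float(mm[i, j]),
                        "musp": float(ss[i, j]),
                        "frequency_mhz": f,
                        "amplitude": float(np.abs(r[i, j])),
                        "phase": float(-np.angle(r[i, j])),
                    }
                )
    # the single anchor point used by the forward-model example checks
    r = engine.reflectance(0.01, 1.0, rho, 126.0)[0]
    records.append(
        {
            "mua": 0.01,
            "musp": 1.0,
            "frequency_mhz": 126.0,
            "amplitude": float(np.abs(r)),
            "phase": float(-np.angle(r)),
            "anchor": True,
        }
    )

    OUT.parent.mkdir(parents=True, exist_ok=True)
    with open(OUT, "w") as fh:
        json.dump(
            {
                "description": (
                    "White Monte Carlo reference reflectance, semi-infinite "
                    "medium, rho=20mm, n=1.4, isotropic scattering"
                ),
                "n_photons": args.photons,
                "seed": args.seed,
                "elapsed_s": round(elapsed, 1),
                "engine": {
                    "r_min": engine.r_min,
                    "r_max": engine.r_max,
                    "l_max": engine.l_max,
                    "r_kill": engine.r_kill,
                },
                "records": records,
            },
            fh,
            indent=1,
        )
    print(f"wrote {OUT} ({len(records)} records) in {elapsed:.0f}s")


if __name__ == "__main__":
    main()
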