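"""Regenerate the packaged synthetic chromophore basis spectra.

The basis is a smooth PCHIP interpolation of literature-informed anchor
values (hemoglobin molar extinction compilations; pure water and lipid
absorption; a power-law melanin shape). It is a synthetic approximation
constructed for this package -- shapes and magnitudes are realistic, but
the tables are not a verbatim copy of any published compilation. The
simulator and the unmixer share this basis, so pipeline self-consistency
does not depend on its absolute accuracy.

Usage: python scripts/make_basis.py
"""

import json
from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT_DIR = Path(__file__).resolve().parents[1] / "src" / "hydronirs" / "data"

GRID = np.arange(700.0, 1000.0 + 1e-9, 2.0)

# molar extinction anchors, cm^-1 / (mol/L)
WL_HB = np.array(
    [700, 710, 720, 730, 740, 750, 760, 770, 780, 790, 800, 810, 820, 830,
     840, 850, 860, 880, 900, 920, 940, 960, 980, 1000], dtype=float
)
EPS_HBO2 = np.array(
    [290, 320, 350, 390, 440, 518, 586, 650, 710, 770, 816, 864, 916, 974,
     1022, 1058, 1086, 1154, 1198, 1232, 1214, 1204, 1131, 1050], dtype=float
)
EPS_HB = np.array(
    [1795, 1598, 1354, 1102, 1169, 1405, 1549, 1245, 1075, 935, 762, 740,
     710, 693, 682, 692, 700, 742, 762, 744, 694, 637, 564, 504], dtype=float
)

# pure-component absorption anchors, mm^-1 (fraction-scaled)
WL_WATER = np.array(
    [700, 720, 730, 740, 750, 760, 770, 780, 790, 800, 820, 840, 860, 880,
     900, 920, 940, 950, 960, 970, 975, 980, 990, 1000], dtype=float
)
MUA_WATER = np.array(
    [0.00060, 0.00125, 0.00190, 0.00260, 0.00280, 0.00270, 0.00245, 0.00230,
     0.00225, 0.00220, 0.00280, 0.00430, 0.00520, 0.00580, 0.00680, 0.01100,
     0.02670, 0.03300, 0.03900, 0.04500, 0.04650, 0.04620, 0.04270, 0.03640],
    dtype=float,
)
WL_LIPID = np.array(
    [700, 720, 740, 760, 780, 800, 820, 840, 860, 880, 900, 915, 925, 930,
     935, 940, 950, 960, 980, 1000], dtype=float
)
MUA_LIPID = np.array(
    [0.00090, 0.00095, 0.00110, 0.00140, 0.00105, 0.00090, 0.00095, 0.00105,
     0.00120, 0.00200, 0.00420, 0.00700, 0.01000, 0.01100, 0.01050, 0.00900,
     0.00600, 0.00430, 0.00400, 0.00480], dtype=float
)

# molar extinction (log10 convention) -> mm^-1 per uM
EXTINCTION_TO_MM1_PER_UM = np.log(10.0) * 1e-7


def main() -> None:
    eps_hbo2 = PchipInterpolator(WL_HB, EPS_HBO2)(GRID) * EXTINCTION_TO_MM1_PER_UM
    eps_hb = PchipInterpolator(WL_HB, EPS_HB)(GRID) * EXTINCTION_TO_MM1_PER_UM
    water = PchipInterpolator(WL_WATER, MUA_WATER)(GRID)
    lipid = PchipInterpolator(WL_LIPID, MUA_LIPID)(GRID)
    melanin = 0.5 * (GRID / 800.0) ** (-3.48)

    OUT_DIR.mkdir(parents=True, exist_ok=True)
    csv_path = OUT_DIR / "chromophore_basis_synthetic.csv"
    header = (
        "wavelength_nm,eps_hbo2_mm1_per_uM,eps_hb_mm1_per_uM,"
        "mua_water_mm1,mua_lipid_mm1,mua_melanin_mm1"
    )
    data = np.column_stack([GRID, eps_hbo2, eps_hb, water, lipid, melanin])
    np.savetxt(csv_path, data, delimiter=",", header=header, comments="",
               fmt="%.10g")

    with open(OUT_DIR / "chromophore_basis_synthetic.json", "w") as fh:
        json.dump(
            {
                "name": "chromophore_basis_synthetic",
                "provenance": (
                    "Synthetic basis: PCHIP interpolation of literature-"
                    "informed anchor values for HbO2/Hb molar extinction, "
                    "pure water and lipid absorption; melanin modelled as a "
                    "lambda^-3.48 power law (0.5 mm^-1 at 800 nm per unit "
                    "fraction). Constructed for this package; not a verbatim "
                    "copy of any published compilation."
                ),
                "units": {
                    "eps_hbo2_mm1_per_uM": "mm^-1 per uM (ln-based Beer law)",
                    "eps_hb_mm1_per_uM": "mm^-1 per uM",
                    "mua_water_mm1": "mm^-1 at volume fraction 1",
                    "mua_lipid_mm1": "mm^-1 at volume fraction 1",
                    "mua_melanin_mm1": "mm^-1 at fraction 1",
                },
                "grid_nm": [700.0, 1000.0, 2.0],
            },
            fh,
            indent=1,
        )
    print(f"wrote {csv_path}")


if __name__ == "__main__":
    main()
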