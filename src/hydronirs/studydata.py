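"""Synthetic stand-in for the reference cohort's per-subject delta values.

The hemodialysis study cohort that defines this package's default
conditions published only group-level summary statistics (means and
standard deviations of the start-to-end changes per group), not the
underlying per-subject values. ``reference_subject_deltas`` reconstructs a
synthetic per-subject table whose group sample means and sample standard
deviations match those summaries exactly (moment matching of a fixed,
seeded standard-normal pattern). It is a stand-in: any statistic beyond
the matched first two moments (for example an exact t-test p-value) is not
guaranteed to reproduce the original cohort's.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REFERENCE_GROUP_SUMMARY", "reference_subject_deltas"]

# (mean, sd) per metric per group; adverse n=18, nonadverse n=9
REFERENCE_GROUP_SUMMARY = {
    "delta_hbo2": {"adverse": (14.52, 15.82), "nonadverse": (15.96, 12.21)},
    "delta_hb": {"adverse": (2.25, 6.49), "nonadverse": (1.57, 3.88)},
    "delta_sto2": {"adverse": (10.62, 12.41), "nonadverse": (10.32, 15.78)},
    "delta_water_ratio": {"adverse": (0.012, 0.035), "nonadverse": (-0.037, 0.085)},
}

GROUP_SIZES = {"adverse": 18, "nonadverse": 9}


def _moment_matched(n: int, mean: float, sd: float, rng) -> np.ndarray:
    z = rng.standard_normal(n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


def reference_subject_deltas(seed: int = 12345) -> pd.DataFrame:
    """Synthetic per-subject start-to-end deltas matching the group summaries.

    Returns a DataFrame with one row per subject (18 adverse, 9 nonadverse)
    and columns for each delta metric plus ``adverse_event``. Group sample
    means and standard deviations equal ``REFERENCE_GROUP_SUMMARY`` to
    machine precision by construction.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for group, n in GROUP_SIZES.items():
        block = {}
        for metric, per_group in REFERENCE_GROUP_SUMMARY.items():
            mean, sd = per_group[group]
            block[metric] = _moment_matched(n, mean, sd, rng)
        for i in range(n):
            rows[f"{group[:3]}_{i:02d}"] = {
                m: block[m][i] for m in REFERENCE_GROUP_SUMMARY
            } | {"adverse_event": group == "adverse"}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("subject")
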