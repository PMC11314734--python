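"""Reference cohort summary statistics.

Published group-level summaries (means and standard deviations) from a
pilot cohort of 31 adults measured with a portable great-toe extension
dynamometer: 17 older (>65 y) and 14 younger (18-24 y) participants,
9 male and 22 female. These summaries serve two purposes:

* default calibration for the synthetic cohort generator
  (:mod:`toecurve.synthetic`), and
* input to the printed-summary consistency checks (the
  :func:`toecurve.stats.group_differences` operation applied to the
  reference means reproduces the cohort's reported group contrasts).

Only summary statistics are bundled; no participant-level data.
"""

from __future__ import annotations

import pandas as pd

#: Marginal sample sizes of the reference cohort.
N_TOTAL = 31
N_OLDER = 17
N_YOUNGER = 14
N_MALE = 9
N_FEMALE = 22

#: Curve-parameter and grip-strength summaries: variable -> stratum ->
#: group -> (mean, sd). Strata are age strata ("total", "older",
#: "younger"); groups are sex groups ("all", "male", "female").
#: Units: peak_N and avg_after80_N in newtons, rise_time_s in seconds,
#: rfd_N_per_s in N/s, pct_above_avg in percent, grip_strength_N in newtons.
GROUP_SUMMARY: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "peak_N": {
        "total": {"all": (42.89, 15.47), "male": (54.82, 13.06), "female": (38.01, 13.82)},
        "older": {"all": (39.32, 17.25), "male": (58.02, 18.09), "female": (33.57, 12.57)},
        "younger": {"all": (47.22, 12.22), "male": (52.26, 8.79), "female": (44.42, 13.39)},
    },
    "avg_after80_N": {
        "total": {"all": (34.78, 13.15), "male": (42.45, 10.61), "female": (31.64, 12.98)},
        "older": {"all": (31.58, 13.64), "male": (44.42, 13.62), "female": (27.63, 11.39)},
        "younger": {"all": (38.67, 11.84), "male": (40.88, 8.88), "female": (37.44, 13.55)},
    },
    "rise_time_s": {
        "total": {"all": (2.29, 1.94), "male": (1.02, 0.41), "female": (2.82, 2.09)},
        "older": {"all": (2.94, 2.22), "male": (1.11, 0.62), "female": (3.50, 2.23)},
        "younger": {"all": (1.52, 1.21), "male": (0.96, 0.17), "female": (1.83, 1.44)},
    },
    "rfd_N_per_s": {
        "total": {"all": (28.64, 21.80), "male": (46.87, 14.76), "female": (21.18, 19.89)},
        "older": {"all": (21.79, 20.09), "male": (49.17, 19.59), "female": (13.37, 12.21)},
        "younger": {"all": (36.95, 20.82), "male": (45.02, 11.74), "female": (32.47, 23.91)},
    },
    "pct_above_avg": {
        "total": {"all": (42.59, 13.53), "male": (50.22, 11.59), "female": (39.48, 13.24)},
        "older": {"all": (36.15, 11.37), "male": (42.45, 10.61), "female": (34.21, 11.27)},
        "younger": {"all": (50.42, 11.96), "male": (56.44, 8.69), "female": (47.08, 12.63)},
    },
    "grip_strength_N": {
        "total": {"all": (259.14, 100.20), "male": (374.85, 66.11), "female": (211.81, 67.77)},
        "older": {"all": (239.99, 93.56), "male": (355.37, 89.58), "female": (204.50, 67.76)},
        "younger": {"all": (282.39, 103.26), "male": (390.44, 45.17), "female": (222.36, 70.39)},
    },
}

#: Demographic summaries by sex: variable -> sex -> (mean, sd).
DEMOGRAPHICS_BY_SEX: dict[str, dict[str, tuple[float, float]]] = {
    "weight_kg": {"male": (77.06, 14.38), "female": (60.47, 10.13)},
    "height_m": {"male": (1.78, 0.09), "female": (1.62, 0.09)},
}


def group_summary_frame() -> pd.DataFrame:
    """Reference summaries as a tidy DataFrame.

    Columns: ``variable``, ``stratum``, ``group``, ``mean``, ``sd``.
    """
    rows = []
    for variable, strata in GROUP_SUMMARY.items():
        for stratum, groups in strata.items():
            for group, (mean, sd) in groups.items():
                rows.append(
                    {"variable": variable, "stratum": stratum, "group": group,
                     "mean": mean, "sd": sd}
                )
    return pd.DataFrame(rows)


def reference_group_means() -> dict[str, dict[str, float]]:
    """Group means in the shape :func:`toecurve.stats.group_differences` takes.

    Returns ``{variable: {"male": m, "female": f, "younger": y, "older": o}}``
    using the total-sample sex means and the all-sexes age-stratum means.
    """
    out: dict[str, dict[str, float]] = {}
    for variable, strata in GROUP_SUMMARY.items():
        out[variable] = {
            "male": strata["total"]["male"][0],
            "female": strata["total"]["female"][0],
            "older": strata["older"]["all"][0],
            "younger": strata["younger"]["all"][0],
        }
    return out
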