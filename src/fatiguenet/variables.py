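"""Canonical variable names, units and column aliases for the fatigue-network dataset.

The measurement table is long-format: one row per participant x intensity.
Nine variables are measured per exhaustive test (mechanical outputs and
physiological responses); four characterise the participant and are
constant across the participant's four tests.
"""

from __future__ import annotations

#: Mechanical / per-test variables, measured once per participant x intensity.
INTENSITY_VARIABLES: tuple[str, ...] = (
    "force",          # N
    "velocity",       # m/s
    "power_mean",     # W
    "power_peak",     # W
    "work",           # kJ
    "time_limit",     # s, time to exhaustion
    "heart_rate",     # bpm
    "lactate_peak",   # mmol/L
    "lactate_time",   # s, time until peak blood lactate
)

#: Subject-level variables, measured once per participant and repeated
#: verbatim on each of the participant's rows.
SUBJECT_VARIABLES: tuple[str, ...] = (
    "lean_mass",           # %
    "aerobic_capacity",    # W  (critical power)
    "anaerobic_capacity",  # kJ (anaerobic work capacity)
    "ipaq",                # a.u. (MET-min/week)
)

#: Node order used everywhere a network is built: subject-level first.
#: Keeping the subject block first lets the generator hold those variables
#: fixed across intensities while preserving the target correlations.
ALL_VARIABLES: tuple[str, ...] = SUBJECT_VARIABLES + INTENSITY_VARIABLES

#: Identifier columns of the long-format table.
ID_COLUMNS: tuple[str, ...] = ("participant_id", "intensity")

UNITS: dict[str, str] = {
    "force": "N",
    "velocity": "m/s",
    "power_mean": "W",
    "power_peak": "W",
    "work": "kJ",
    "time_limit": "s",
    "heart_rate": "bpm",
    "lactate_peak": "mmol/L",
    "lactate_time": "s",
    "lean_mass": "%",
    "aerobic_capacity": "W",
    "anaerobic_capacity": "kJ",
    "ipaq": "a.u.",
}

#: Accepted case-insensitive header aliases for cohort CSV files.
COLUMN_ALIASES: dict[str, str] = {
    "participant": "participant_id",
    "subject": "participant_id",
    "subject_id": "participant_id",
    "model": "intensity",
    "test": "intensity",
    "power": "power_mean",
    "mean power": "power_mean",
    "mean_power": "power_mean",
    "peak power": "power_peak",
    "peak_power": "power_peak",
    "tlim": "time_limit",
    "time limit": "time_limit",
    "time_to_exhaustion": "time_limit",
    "hr": "heart_rate",
    "heart rate": "heart_rate",
    "peak lactate": "lactate_peak",
    "peak_lactate": "lactate_peak",
    "lactate": "lactate_peak",
    "lactate time": "lactate_time",
    "lean mass": "lean_mass",
    "aerobic capacity": "aerobic_capacity",
    "anaerobic capacity": "anaerobic_capacity",
    "ipaq_score": "ipaq",
    "ipaq score": "ipaq",
}


def canonical_column(name: str) -> str:
    """Map a CSV header to its canonical column name.

    Raises ``KeyError`` listing the accepted names when the header is unknown.
    """
    key = name.strip().lower()
    if key in ID_COLUMNS or key in ALL_VARIABLES:
        return key
    if key in COLUMN_ALIASES:
        return COLUMN_ALIASES[key]
    accepted = sorted(set(ID_COLUMNS) | set(ALL_VARIABLES) | set(COLUMN_ALIASES))
    raise KeyError(
        f"unknown column {name!r}; accepted (case-insensitive): {', '.join(accepted)}"
    )
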