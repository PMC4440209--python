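"""Synthetic cohort generator for the fatigue-network analysis.

Emulates a tethered-running study design: a small cohort of participants
each runs to exhaustion at four effort intensities, yielding mechanical
outputs (force, velocity, power, work, time limit) and physiological
responses (heart rate, lactate kinetics) per test, plus subject-level
characteristics (lean mass, aerobic/anaerobic capacity, IPAQ score)
measured once.

The generator draws a multivariate-normal backbone with a user-supplied
target correlation matrix per intensity, rescales it to configured
means/SDs, and keeps all physical quantities positive by resampling
offending rows. Optionally it enforces mechanical identities
(P = F*v, W = P*t, hyperbolic power-duration relation) on top of the
statistical draw.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variables import (
    ALL_VARIABLES,
    ID_COLUMNS,
    INTENSITY_VARIABLES,
    SUBJECT_VARIABLES,
)

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "planted_hub_config",
    "planted_hub_matrix",
    "default_correlation_matrix",
    "nearest_psd_correlation",
    "DEFAULT_INTENSITY_STATS",
    "DEFAULT_SUBJECT_STATS",
]

_PSD_TOL = 1e-10
_MAX_RESAMPLE = 1000

# Per-intensity (mean, SD) defaults for each measured variable, calibrated to
# the group summary statistics of the study the generator emulates: nine
# recreationally active adults, four tethered-running intensities set by
# elastic resistance, time to exhaustion falling from ~10 min to ~3 min as
# intensity rises.
DEFAULT_INTENSITY_STATS: dict[int, dict[str, tuple[float, float]]] = {
    1: {
        "power_mean": (247.84, 47.46),
        "power_peak": (380.34, 48.91),
        "force": (120.05, 11.32),
        "velocity": (2.11, 0.33),
        "time_limit": (626.08, 149.27),
        "work": (162.45, 56.04),
        "lactate_peak": (12.20, 3.38),
        "lactate_time": (819.41, 287.44),
        "heart_rate": (180.11, 10.54),
    },
    2: {
        "power_mean": (294.46, 40.18),
        "power_peak": (445.23, 48.79),
        "force": (136.65, 17.53),
        "velocity": (2.19, 0.38),
        "time_limit": (462.67, 133.29),
        "work": (135.48, 45.02),
        "lactate_peak": (12.52, 4.49),
        "lactate_time": (709.33, 260.12),
        "heart_rate": (179.00, 9.82),
    },
    3: {
        "power_mean": (412.71, 93.75),
        "power_peak": (585.19, 123.14),
        "force": (161.86, 25.30),
        "velocity": (2.54, 0.40),
        "time_limit": (236.64, 97.24),
        "work": (92.00, 25.03),
        "lactate_peak": (15.12, 5.00),
        "lactate_time": (583.30, 219.01),
        "heart_rate": (180.00, 9.53),
    },
    4: {
        "power_mean": (512.42, 105.25),
        "power_peak": (784.63, 96.00),
        "force": (187.90, 27.55),
        "velocity": (2.77, 0.56),
        "time_limit": (173.75, 62.68),
        "work": (77.73, 16.15),
        "lactate_peak": (15.34, 5.49),
        "lactate_time": (433.75, 251.68),
        "heart_rate": (179.55, 8.42),
    },
}

# Subject-level (mean, SD) defaults: critical power (aerobic capacity, W),
# anaerobic work capacity (kJ), lean mass (%), IPAQ physical-activity score.
DEFAULT_SUBJECT_STATS: dict[str, tuple[float, float]] = {
    "aerobic_capacity": (139.26, 43.65),
    "anaerobic_capacity": (47.14, 26.06),
    "lean_mass": (91.49, 3.24),
    "ipaq": (2106.66, 1162.06),
}


def nearest_psd_correlation(matrix: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, bool]:
    """Project a symmetric matrix onto the PSD correlation matrices.

    Negative eigenvalues are clipped to ``floor``, the matrix is rebuilt and
    the diagonal renormalised to one. Returns ``(repaired, was_repaired)``;
    a matrix already PSD (eigenvalues >= -1e-10) is returned unchanged.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    eigval, eigvec = np.linalg.eigh(matrix)
    if eigval.min() >= -_PSD_TOL:
        return matrix, False
    clipped = np.clip(eigval, floor, None)
    repaired = (eigvec * clipped) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    repaired = (repaired + repaired.T) / 2.0
    return repaired, True


def _validate_correlation(matrix: np.ndarray, k: int, label: str) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (k, k):
        raise ValueError(f"{label}: expected a {k}x{k} matrix, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError(f"{label}: matrix is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        raise ValueError(f"{label}: diagonal must be all ones")
    lo = np.linalg.eigvalsh(m).min()
    if lo < -_PSD_TOL:
        raise ValueError(
            f"{label}: matrix is not positive semi-definite "
            f"(smallest eigenvalue {lo:.3e})"
        )
    return m


def default_correlation_matrix() -> np.ndarray:
    """A plausible target correlation structure over the 13 variables.

    Synthetic placeholder, not an estimate from any measured dataset: the
    mechanical outputs are strongly inter-correlated, endurance-related
    quantities (time limit, capacities) moderately so, and everything else
    weakly. Ordered as :data:`fatiguenet.variables.ALL_VARIABLES`.
    """
    k = len(ALL_VARIABLES)
    idx = {v: i for i, v in enumerate(ALL_VARIABLES)}
    m = np.full((k, k), 0.15)

    def _set(a: str, b: str, r: float) -> None:
        m[idx[a], idx[b]] = r
        m[idx[b], idx[a]] = r

    mechanical = ("force", "velocity", "power_mean", "power_peak", "work")
    for i, a in enumerate(mechanical):
        for b in mechanical[i + 1:]:
            _set(a, b, 0.60)
    _set("time_limit", "aerobic_capacity", 0.45)
    _set("time_limit", "anaerobic_capacity", 0.45)
    _set("time_limit", "work", 0.55)
    _set("lactate_peak", "lactate_time", 0.40)
    _set("lactate_peak", "anaerobic_capacity", 0.35)
    _set("heart_rate", "lactate_peak", 0.30)
    _set("aerobic_capacity", "anaerobic_capacity", 0.25)
    _set("lean_mass", "aerobic_capacity", 0.25)
    _set("ipaq", "aerobic_capacity", 0.25)
    np.fill_diagonal(m, 1.0)
    repaired, _ = nearest_psd_correlation(m)
    return repaired


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Parameters
    ----------
    n_participants
        Cohort size; the emulated design uses 9.
    intensities
        Ordered effort-intensity labels.
    intensity_stats
        ``{intensity: {variable: (mean, sd)}}`` for the per-test variables.
    subject_stats
        ``{variable: (mean, sd)}`` for the subject-level variables.
    correlation_targets
        ``{intensity: matrix}`` over all 13 variables in canonical order
        (subject-level block first). The subject-level block must be
        identical across intensities, because those variables are drawn
        once per participant.
    physics_consistency
        When true, overwrite mean power with force x velocity, time limit
        with the hyperbolic power-duration prediction AWC/(P - CP) from the
        participant's own capacities, and work with P x tlim, each plus
        relative Gaussian noise of scale ``consistency_noise``.
    consistency_noise
        Relative SD of the residuals added to the mechanical identities.
    seed
        Seed for all randomness; a fixed seed makes output bit-identical.
    psd_repair_applied
        Metadata flag recording that a hand-built correlation target was
        projected to the nearest PSD correlation matrix.
    """

    n_participants: int = 9
    intensities: tuple[int, ...] = (1, 2, 3, 4)
    intensity_stats: Mapping[int, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_INTENSITY_STATS
    )
    subject_stats: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_SUBJECT_STATS
    )
    correlation_targets: Mapping[int, np.ndarray] | None = None
    physics_consistency: bool = False
    consistency_noise: float = 0.0
    seed: int | None = 0
    psd_repair_applied: bool = False

    def resolved_targets(self) -> dict[int, np.ndarray]:
        """Validated per-intensity correlation matrices (defaults filled in)."""
        k = len(ALL_VARIABLES)
        if self.correlation_targets is None:
            base = default_correlation_matrix()
            return {i: base for i in self.intensities}
        out: dict[int, np.ndarray] = {}
        for intensity in self.intensities:
            if intensity not in self.correlation_targets:
                raise ValueError(f"no correlation target for intensity {intensity}")
            out[intensity] = _validate_correlation(
                self.correlation_targets[intensity], k, f"intensity {intensity}"
            )
        n_sub = len(SUBJECT_VARIABLES)
        first = out[self.intensities[0]][:n_sub, :n_sub]
        for intensity in self.intensities[1:]:
            if not np.allclose(out[intensity][:n_sub, :n_sub], first, atol=1e-12):
                raise ValueError(
                    "subject-level correlation block must be identical across "
                    "intensities (those variables are drawn once per participant)"
                )
        return out

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ValueError("n_participants must be >= 3")
        if len(self.intensities) == 0:
            raise ValueError("at least one intensity is required")
        if len(set(self.intensities)) != len(self.intensities):
            raise ValueError("intensity labels must be unique")
        if self.consistency_noise < 0:
            raise ValueError("consistency_noise must be >= 0")
        for intensity in self.intensities:
            if intensity not in self.intensity_stats:
                raise ValueError(f"no intensity_stats for intensity {intensity}")
            stats = self.intensity_stats[intensity]
            for var in INTENSITY_VARIABLES:
                if var not in stats:
                    raise ValueError(f"intensity {intensity}: missing stats for {var!r}")
                _, sd = stats[var]
                if sd < 0:
                    raise ValueError(f"intensity {intensity}: negative SD for {var!r}")
        for var in SUBJECT_VARIABLES:
            if var not in self.subject_stats:
                raise ValueError(f"missing subject stats for {var!r}")
            if self.subject_stats[var][1] < 0:
                raise ValueError(f"negative SD for subject variable {var!r}")
        self.resolved_targets()

    def to_json(self) -> str:
        """Serialise the config (matrices as nested lists) for provenance."""
        d = dataclasses.asdict(self)
        d["intensity_stats"] = {
            str(i): {v: list(ms) for v, ms in s.items()}
            for i, s in self.intensity_stats.items()
        }
        d["subject_stats"] = {v: list(ms) for v, ms in self.subject_stats.items()}
        if self.correlation_targets is not None:
            d["correlation_targets"] = {
                str(i): np.asarray(m).tolist()
                for i, m in self.correlation_targets.items()
            }
        d["intensities"] = list(self.intensities)
        return json.dumps(d, sort_keys=True)


def _cholesky_factor(matrix: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, with a tiny jitter escape for singular PSD targets."""
    try:
        return np.linalg.cholesky(matrix)
    except np.linalg.LinAlgError:
        k = matrix.shape[0]
        jittered = matrix + 1e-10 * np.eye(k)
        d = np.sqrt(np.diag(jittered))
        jittered = jittered / np.outer(d, d)
        return np.linalg.cholesky(jittered)


def _scale(z: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    return means + sds * z


def _resample_rows(
    rng: np.random.Generator,
    draw: "callable",
    accept: "callable",
    n: int,
    what: str,
) -> np.ndarray:
    """Draw n rows, redrawing rejected ones up to a bounded number of rounds."""
    values = draw(n)
    for _ in range(_MAX_RESAMPLE):
        bad = ~accept(values)
        if not bad.any():
            return values
        values[bad] = draw(int(bad.sum()))[: int(bad.sum())]
    raise RuntimeError(
        f"could not draw strictly positive {what} after {_MAX_RESAMPLE} resampling rounds"
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a complete participant x intensity measurement table.

    Returns a long-format DataFrame with columns ``participant_id``,
    ``intensity`` and the 13 canonical variables. Per intensity, variables
    are a linear (Cholesky) transform of independent standard normals whose
    population correlation matches the target, affinely rescaled to the
    configured means/SDs. Subject-level variables are drawn once per
    participant and repeated on every row. Rows with any non-positive
    quantity are redrawn (truncation by resampling), so extreme-CV
    variables acquire the corresponding truncated-normal bias.
    """
    config.validate()
    targets = config.resolved_targets()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    n_sub = len(SUBJECT_VARIABLES)
    sub_means = np.array([config.subject_stats[v][0] for v in SUBJECT_VARIABLES])
    sub_sds = np.array([config.subject_stats[v][1] for v in SUBJECT_VARIABLES])

    # Subject latents are shared across intensities; the subject block of the
    # Cholesky factor only touches them, so subject variables stay constant.
    first = targets[config.intensities[0]]
    l_sub = _cholesky_factor(first)[:n_sub, :n_sub]

    def draw_subject(m: int) -> np.ndarray:
        return rng.standard_normal((m, n_sub))

    z_sub = _resample_rows(
        rng,
        draw_subject,
        lambda z: (_scale(z @ l_sub.T, sub_means, sub_sds) > 0).all(axis=1),
        n,
        "subject-level variables",
    )
    subject_values = _scale(z_sub @ l_sub.T, sub_means, sub_sds)

    frames = []
    for intensity in config.intensities:
        chol = _cholesky_factor(targets[intensity])
        stats = config.intensity_stats[intensity]
        means = np.array([stats[v][0] for v in INTENSITY_VARIABLES])
        sds = np.array([stats[v][1] for v in INTENSITY_VARIABLES])
        # x = [z_sub, z_int] @ L.T ; subject part is fixed, so intensity
        # variables are drawn conditionally on the subject latents.
        l_cross = chol[n_sub:, :n_sub]
        l_int = chol[n_sub:, n_sub:]
        cross = z_sub @ l_cross.T  # fixed per participant within this intensity

        n_int = len(INTENSITY_VARIABLES)
        z_int = rng.standard_normal((n, n_int)) @ l_int.T
        base = _scale(z_int + cross, means, sds)
        for _ in range(_MAX_RESAMPLE):
            bad = ~(base > 0).all(axis=1)
            if not bad.any():
                break
            m = int(bad.sum())
            z_new = rng.standard_normal((m, n_int)) @ l_int.T
            base[bad] = _scale(z_new + cross[bad], means, sds)
        else:
            raise RuntimeError(
                f"could not draw strictly positive intensity-{intensity} "
                f"variables after {_MAX_RESAMPLE} resampling rounds"
            )

        frame = pd.DataFrame(base, columns=list(INTENSITY_VARIABLES))
        for j, var in enumerate(SUBJECT_VARIABLES):
            frame[var] = subject_values[:, j]
        frame.insert(0, "intensity", intensity)
        frame.insert(0, "participant_id", [f"P{p + 1:02d}" for p in range(n)])
        frames.append(frame)

    cohort = pd.concat(frames, ignore_index=True)[list(ID_COLUMNS) + list(ALL_VARIABLES)]
    if config.physics_consistency:
        cohort = _apply_physics(cohort, config, rng)
    return cohort


def _apply_physics(
    cohort: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Overwrite mechanically linked columns with their physical identities.

    P = F x v [W]; tlim = AWC/(P - CP) [s] with CP the participant's aerobic
    capacity (W) and AWC the anaerobic capacity (J); W = P x tlim / 1000 [kJ].
    Each identity gets relative Gaussian noise of scale ``consistency_noise``.
    Rows whose mean power does not exceed CP are redrawn from the power
    distribution of their intensity; persistent failure is an error naming
    the participant.
    """
    noise = config.consistency_noise
    out = cohort.copy()
    cp = out["aerobic_capacity"].to_numpy()
    awc_j = out["anaerobic_capacity"].to_numpy() * 1000.0

    power = out["force"].to_numpy() * out["velocity"].to_numpy()
    if noise > 0:
        power = power * (1.0 + noise * rng.standard_normal(len(out)))

    bad = power <= cp
    for _ in range(_MAX_RESAMPLE):
        if not bad.any():
            break
        for i in np.flatnonzero(bad):
            intensity = out["intensity"].iloc[i]
            f_mu, f_sd = config.intensity_stats[intensity]["force"]
            v_mu, v_sd = config.intensity_stats[intensity]["velocity"]
            f = -1.0
            v = -1.0
            while f <= 0 or v <= 0:
                f = f_mu + f_sd * rng.standard_normal()
                v = v_mu + v_sd * rng.standard_normal()
            p = f * v
            if noise > 0:
                p = p * (1.0 + noise * rng.standard_normal())
            out.iloc[i, out.columns.get_loc("force")] = f
            out.iloc[i, out.columns.get_loc("velocity")] = v
            power[i] = p
        bad = power <= cp
    if bad.any():
        who = out.loc[bad, "participant_id"].unique().tolist()
        raise RuntimeError(
            "mean power could not be drawn above critical power for "
            f"participant(s) {who} within {_MAX_RESAMPLE} resampling rounds"
        )

    tlim = awc_j / (power - cp)
    work = power * tlim / 1000.0
    if noise > 0:
        tlim = np.abs(tlim * (1.0 + noise * rng.standard_normal(len(out))))
        work = np.abs(work * (1.0 + noise * rng.standard_normal(len(out))))
    out["power_mean"] = power
    out["time_limit"] = tlim
    out["work"] = work
    return out


def planted_hub_matrix(
    hub_variable: str, hub_strength: float, background: float
) -> tuple[np.ndarray, bool]:
    """Correlation matrix linking one hub variable to all others.

    The hub's row/column is ``hub_strength`` off-diagonal and every other
    pair is ``background``. Returns ``(matrix, repaired)``; a non-PSD
    construction is projected to the nearest PSD correlation matrix.
    """
    if hub_variable not in ALL_VARIABLES:
        raise KeyError(f"unknown variable {hub_variable!r}")
    if not (0.0 <= background < hub_strength <= 0.95):
        raise ValueError("need 0 <= background < hub_strength <= 0.95")
    k = len(ALL_VARIABLES)
    h = ALL_VARIABLES.index(hub_variable)
    m = np.full((k, k), background)
    m[h, :] = hub_strength
    m[:, h] = hub_strength
    np.fill_diagonal(m, 1.0)
    return nearest_psd_correlation(m)


def planted_hub_config(
    hub_variable: str | Mapping[int, str],
    hub_strength: float,
    background: float,
    *,
    n_participants: int = 200,
    intensities: Sequence[int] = (1, 2, 3, 4),
    seed: int | None = 0,
) -> GeneratorConfig:
    """A generator config with a known hub planted in the correlation target.

    ``hub_variable`` may be a single name (same hub at every intensity) or a
    mapping from intensity to hub name, to emulate the hub migrating across
    effort levels. Subject-level variables cannot be per-intensity hubs.
    """
    if isinstance(hub_variable, str):
        hubs = {i: hub_variable for i in intensities}
    else:
        hubs = dict(hub_variable)
    repaired_any = False
    targets: dict[int, np.ndarray] = {}
    for intensity in intensities:
        if intensity not in hubs:
            raise ValueError(f"no hub specified for intensity {intensity}")
        hub = hubs[intensity]
        if len(set(hubs.values())) > 1 and hub in SUBJECT_VARIABLES:
            raise ValueError(
                "a subject-level variable cannot host an intensity-specific hub"
            )
        matrix, repaired = planted_hub_matrix(hub, hub_strength, background)
        repaired_any = repaired_any or repaired
        targets[intensity] = matrix
    return GeneratorConfig(
        n_participants=n_participants,
        intensities=tuple(intensities),
        correlation_targets=targets,
        seed=seed,
        psd_repair_applied=repaired_any,
    )
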