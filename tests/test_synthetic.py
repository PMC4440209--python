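"""Generator: determinism, calibration, correlation fidelity, physics mode."""

import numpy as np
import pytest
from scipy import stats as sps

from fatiguenet.synthetic import (
    DEFAULT_INTENSITY_STATS,
    DEFAULT_SUBJECT_STATS,
    GeneratorConfig,
    default_correlation_matrix,
    generate_cohort,
    nearest_psd_correlation,
    planted_hub_config,
    planted_hub_matrix,
)
from fatiguenet.variables import ALL_VARIABLES, INTENSITY_VARIABLES, SUBJECT_VARIABLES

K = len(ALL_VARIABLES)


def zero_sd_config(**kw) -> GeneratorConfig:
    stats = {
        i: {v: (m, 0.0) for v, (m, _) in s.items()}
        for i, s in DEFAULT_INTENSITY_STATS.items()
    }
    subject = {v: (m, 0.0) for v, (m, _) in DEFAULT_SUBJECT_STATS.items()}
    return GeneratorConfig(
        intensity_stats=stats,
        subject_stats=subject,
        correlation_targets={i: np.eye(K) for i in (1, 2, 3, 4)},
        **kw,
    )


def test_deterministic_output_is_bit_identical():
    cfg = GeneratorConfig(seed=123)
    a = generate_cohort(cfg).to_csv(index=False)
    b = generate_cohort(cfg).to_csv(index=False)
    assert a == b


def test_different_seeds_differ():
    a = generate_cohort(GeneratorConfig(seed=1))
    b = generate_cohort(GeneratorConfig(seed=2))
    assert not a.equals(b)


def test_zero_variance_config_reproduces_means_exactly():
    cohort = generate_cohort(zero_sd_config(seed=0))
    for intensity, stats in DEFAULT_INTENSITY_STATS.items():
        block = cohort[cohort["intensity"] == intensity]
        for var, (mean, _) in stats.items():
            assert (block[var] == mean).all()
    for var, (mean, _) in DEFAULT_SUBJECT_STATS.items():
        assert (cohort[var] == mean).all()


def test_complete_grid_and_constant_subject_variables():
    cohort = generate_cohort(GeneratorConfig(seed=5))
    assert len(cohort) == 9 * 4
    counts = cohort.groupby(["participant_id", "intensity"]).size()
    assert (counts == 1).all() and len(counts) == 36
    for _, block in cohort.groupby("participant_id"):
        for var in SUBJECT_VARIABLES:
            assert block[var].nunique() == 1
    assert (cohort[list(ALL_VARIABLES)] > 0).all().all()


def test_target_correlation_recovered_at_large_n():
    target = np.eye(K)
    i, j = ALL_VARIABLES.index("force"), ALL_VARIABLES.index("power_mean")
    target[i, j] = target[j, i] = 0.9
    cfg = GeneratorConfig(
        n_participants=500,
        intensities=(1,),
        correlation_targets={1: target},
        seed=7,
    )
    cohort = generate_cohort(cfg)
    r = np.corrcoef(cohort["force"], cohort["power_mean"])[0, 1]
    assert abs(r - 0.9) <= 0.05


def test_correlation_fidelity_across_whole_matrix():
    """Sample correlations track the (possibly repaired) target within 0.1."""
    cfg = planted_hub_config("velocity", 0.8, 0.1, n_participants=1000,
                             intensities=(1,), seed=9)
    cohort = generate_cohort(cfg)
    sample = np.corrcoef(cohort[list(ALL_VARIABLES)].to_numpy().T)
    target = cfg.correlation_targets[1]
    assert np.abs(sample - target).max() <= 0.1


def _rejection_oracle_moments(intensity: int, n: int, seed: int):
    """Brute-force reference for the positivity-constrained draw.

    Re-derives the expected per-variable moments from scratch: correlated
    normals via a Cholesky transform, subject rows rejected until the
    subject block is positive, intensity rows redrawn (conditional on the
    subject latents) until the intensity block is positive.
    """
    target = default_correlation_matrix()
    chol = np.linalg.cholesky(target)
    n_sub = len(SUBJECT_VARIABLES)
    sub_mu = np.array([DEFAULT_SUBJECT_STATS[v][0] for v in SUBJECT_VARIABLES])
    sub_sd = np.array([DEFAULT_SUBJECT_STATS[v][1] for v in SUBJECT_VARIABLES])
    st = DEFAULT_INTENSITY_STATS[intensity]
    int_mu = np.array([st[v][0] for v in INTENSITY_VARIABLES])
    int_sd = np.array([st[v][1] for v in INTENSITY_VARIABLES])

    rng = np.random.default_rng(seed)
    z_sub = rng.standard_normal((n, n_sub))
    while True:
        sub = sub_mu + sub_sd * (z_sub @ chol[:n_sub, :n_sub].T)
        bad = ~(sub > 0).all(axis=1)
        if not bad.any():
            break
        z_sub[bad] = rng.standard_normal((int(bad.sum()), n_sub))
    cross = z_sub @ chol[n_sub:, :n_sub].T
    z_int = rng.standard_normal((n, len(INTENSITY_VARIABLES)))
    while True:
        vals = int_mu + int_sd * (cross + z_int @ chol[n_sub:, n_sub:].T)
        bad = ~(vals > 0).all(axis=1)
        if not bad.any():
            break
        z_int[bad] = rng.standard_normal((int(bad.sum()), len(INTENSITY_VARIABLES)))
    frame = {v: vals[:, j] for j, v in enumerate(INTENSITY_VARIABLES)}
    frame.update({v: sub[:, j] for j, v in enumerate(SUBJECT_VARIABLES)})
    return {v: (x.mean(), x.std(ddof=1)) for v, x in frame.items()}


@pytest.mark.parametrize("intensity", [1, 2, 3, 4])
def test_calibration_of_means_and_sds(intensity):
    """Large-cohort sample moments match the configured values wherever the
    positivity constraint is inactive; variables with non-negligible mass
    below zero instead match a brute-force rejection-sampling reference.
    n is large enough that the 2% band is not dominated by sampling error
    of the skewed (truncated) marginals."""
    cfg = GeneratorConfig(n_participants=40_000, intensities=(intensity,), seed=31)
    cohort = generate_cohort(cfg)
    oracle = _rejection_oracle_moments(intensity, n=200_000, seed=77)
    stats = {**DEFAULT_INTENSITY_STATS[intensity], **DEFAULT_SUBJECT_STATS}
    for var, (mean, sd) in stats.items():
        if sps.norm.cdf(-mean / sd) < 1e-3:  # truncation negligible
            exp_mean, exp_sd = mean, sd
        else:
            exp_mean, exp_sd = oracle[var]
        assert abs(cohort[var].mean() - exp_mean) <= 0.02 * exp_mean, var
        assert abs(cohort[var].std(ddof=1) - exp_sd) <= 0.02 * exp_sd, var


def test_time_limit_mean_matches_study_calibration():
    """Intensity-1 time to exhaustion averages ~626 s under the defaults."""
    cfg = GeneratorConfig(n_participants=10_000, intensities=(1,), seed=13)
    cohort = generate_cohort(cfg)
    assert abs(cohort["time_limit"].mean() - 626.08) <= 0.02 * 626.08


def test_physics_consistency_identities_hold_exactly():
    cfg = GeneratorConfig(physics_consistency=True, consistency_noise=0.0, seed=17)
    c = generate_cohort(cfg)
    assert np.allclose(c["power_mean"], c["force"] * c["velocity"], rtol=1e-12)
    assert np.allclose(c["work"], c["power_mean"] * c["time_limit"] / 1000.0, rtol=1e-12)
    awc_j = c["anaerobic_capacity"] * 1000.0
    pred = awc_j / (c["power_mean"] - c["aerobic_capacity"])
    assert np.allclose(c["time_limit"], pred, rtol=1e-12)
    assert (c["power_mean"] > c["aerobic_capacity"]).all()


def test_physics_consistency_with_noise_stays_positive():
    cfg = GeneratorConfig(physics_consistency=True, consistency_noise=0.05, seed=19)
    c = generate_cohort(cfg)
    assert (c[list(INTENSITY_VARIABLES)] > 0).all().all()
    # identities now hold only approximately
    rel = np.abs(c["power_mean"] / (c["force"] * c["velocity"]) - 1.0)
    assert 0 < rel.max() < 0.5


def test_planted_hub_matrix_shape_and_structure():
    m, repaired = planted_hub_matrix("velocity", 0.8, 0.1)
    assert m.shape == (K, K)
    assert np.allclose(np.diag(m), 1.0)
    assert np.allclose(m, m.T)
    assert np.linalg.eigvalsh(m).min() >= -1e-10
    iv = ALL_VARIABLES.index("velocity")
    hub_row = np.delete(m[iv], iv)
    rest = np.delete(np.delete(m, iv, 0), iv, 1)
    background = rest[np.triu_indices(K - 1, 1)]
    # hub links must dominate background even after any PSD repair
    assert hub_row.min() > background.max() + 0.2


def test_planted_hub_preconditions():
    with pytest.raises(ValueError):
        planted_hub_matrix("velocity", 0.5, 0.5)
    with pytest.raises(KeyError):
        planted_hub_matrix("not_a_variable", 0.8, 0.1)
    with pytest.raises(ValueError):
        planted_hub_config({1: "lean_mass", 2: "force"}, 0.8, 0.1,
                           intensities=(1, 2))


def test_non_psd_target_rejected_with_eigenvalue():
    bad = np.eye(K)
    a, b, c = 0, 1, 2
    for i, j in [(a, b), (a, c), (b, c)]:
        bad[i, j] = bad[j, i] = 0.9
    bad[b, c] = bad[c, b] = -0.9  # impossible triangle
    cfg = GeneratorConfig(correlation_targets={i: bad for i in (1, 2, 3, 4)})
    with pytest.raises(ValueError, match="eigenvalue"):
        generate_cohort(cfg)


def test_nearest_psd_projection_is_psd_unit_diagonal():
    rng = np.random.default_rng(3)
    m = rng.uniform(-1, 1, (8, 8))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    fixed, repaired = nearest_psd_correlation(m)
    assert repaired
    assert np.linalg.eigvalsh(fixed).min() >= -1e-10
    assert np.allclose(np.diag(fixed), 1.0)


def test_default_matrix_is_valid_correlation_target():
    m = default_correlation_matrix()
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert np.linalg.eigvalsh(m).min() >= -1e-10


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(n_participants=2).validate()
    bad_stats = {
        i: {**s, "force": (120.0, -1.0)} for i, s in DEFAULT_INTENSITY_STATS.items()
    }
    with pytest.raises(ValueError, match="negative SD"):
        GeneratorConfig(intensity_stats=bad_stats).validate()
    # subject-level correlation block must not vary across intensities
    t1 = np.eye(K)
    t2 = np.eye(K)
    t2[0, 1] = t2[1, 0] = 0.5  # lean_mass x aerobic_capacity
    cfg = GeneratorConfig(
        intensities=(1, 2),
        correlation_targets={1: t1, 2: t2},
    )
    with pytest.raises(ValueError, match="subject-level"):
        cfg.validate()
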