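"""Generator checks: determinism, planted effects, covariance structure."""

import numpy as np
import pytest

from connlife import netfc
from connlife.confounds import framewise_displacement, screen_subject
from connlife.dualreg import SpatialMap, TemplateSet
from connlife.exceptions import GenerationError, ParameterError
from connlife.graphnet import build_connectivity
from connlife.inference import partial_correlation
from connlife.parcellation import make_parcellation
from connlife.similarity import build_reference, eta_squared, similarity_table
from connlife.synthcohort import (
    CohortConfig,
    generate_cohort,
    generate_motion_trace,
    generate_node_timeseries,
    generate_spatial_maps,
    make_templates,
)


def test_same_seed_gives_identical_cohort_timeseries_motion_and_maps(
    small_parcellation,
):
    cfg = CohortConfig(n_subjects=6, seed=42, grid_shape=(10, 10, 5))
    tmpl = make_templates(small_parcellation.rsn_networks, (10, 10, 5), seed=42)
    runs = []
    for _ in range(2):
        subjects, truth = generate_cohort(cfg)
        ts = generate_node_timeseries(subjects[3], small_parcellation, truth, 40)
        tr = generate_motion_trace(subjects[3], truth, 40)
        maps = generate_spatial_maps(subjects[3], truth, tmpl)
        runs.append((subjects, ts.values, tr.params, maps["auditory"].grid))
    assert [s.ace_r_total for s in runs[0][0]] == [s.ace_r_total for s in runs[1][0]]
    assert np.array_equal(runs[0][1], runs[1][1])
    assert np.array_equal(runs[0][2], runs[1][2])
    assert np.array_equal(runs[0][3], runs[1][3])


def test_null_generative_model_gives_constant_ace_r():
    cfg = CohortConfig(
        n_subjects=20,
        seed=5,
        mediation_a=0.0,
        mediation_b=0.0,
        mediation_cprime=0.0,
        noise_sd=0.0,
        sex_coef=0.0,
    )
    subjects, _ = generate_cohort(cfg)
    scores = {s.ace_r_total for s in subjects}
    assert scores == {cfg.ace_base}


def test_cohort_parameter_validation_and_age_bounds():
    with pytest.raises(ParameterError):
        generate_cohort(CohortConfig(n_subjects=1, seed=0))
    subjects, _ = generate_cohort(CohortConfig(n_subjects=200, seed=0))
    ages = np.array([s.age for s in subjects])
    assert ages.min() >= 21 and ages.max() <= 86
    assert all(0 <= s.ace_r_total <= 100 for s in subjects)
    assert all(s.cognitive_pass == (s.ace_r_total >= 89) for s in subjects)


def test_planted_negative_age_effect_on_ace_recovered_across_seeds():
    """The age->ACE-R total effect (controlling sex) has the planted
    negative sign in at least 95% of 100 seeded cohorts at n=200."""
    hits = 0
    for seed in range(100):
        subjects, _ = generate_cohort(CohortConfig(n_subjects=200, seed=seed))
        age = np.array([s.age for s in subjects])
        ace = np.array([s.ace_r_total for s in subjects])
        sex = np.array([s.sex for s in subjects], dtype=float)
        if partial_correlation(age, ace, covariates=sex).r < 0:
            hits += 1
    assert hits >= 95


def test_uncoupled_nodes_show_near_zero_correlations(small_parcellation):
    cfg = CohortConfig(
        n_subjects=2, seed=3, within_base=0.0, between_base=0.0,
        other_coupling=0.0, within_slope=0.0, between_slope=0.0,
    )
    subjects, truth = generate_cohort(cfg)
    T = 500
    ts = generate_node_timeseries(subjects[0], small_parcellation, truth, T)
    r = np.corrcoef(ts.values, rowvar=False)
    off = np.abs(r[~np.eye(r.shape[0], dtype=bool)])
    assert off.mean() < 3.0 / np.sqrt(T)


def test_planted_within_coupling_recovered_at_large_t():
    parc = make_parcellation({"language": 9}, n_other=4)
    cfg = CohortConfig(
        n_subjects=2, seed=9, within_base=0.5, within_slope=0.0,
        between_slope=0.0, other_coupling=0.0,
    )
    subjects, truth = generate_cohort(cfg)
    ts = generate_node_timeseries(subjects[0], parc, truth, 10_000)
    r = np.corrcoef(ts.values, rowvar=False)
    idx = parc.network_nodes("language")
    block = r[np.ix_(idx, idx)]
    mean_r = block[np.triu_indices(9, 1)].mean()
    assert abs(mean_r - 0.5) < 0.02


def test_negative_within_slope_lowers_wnfc_across_age_tertiles(small_parcellation):
    cfg = CohortConfig(
        n_subjects=300, seed=21, within_slope=-0.12, between_slope=0.0
    )
    subjects, truth = generate_cohort(cfg)
    vals, ages = [], []
    for s in subjects:
        ts = generate_node_timeseries(s, small_parcellation, truth, 100)
        conn = build_connectivity(ts)
        vals.append(netfc.wnfc(conn, small_parcellation, "language"))
        ages.append(s.age)
    vals, ages = np.array(vals), np.array(ages)
    t1, t2 = np.quantile(ages, [1 / 3, 2 / 3])
    young = vals[ages <= t1].mean()
    old = vals[ages > t2].mean()
    assert old < young


def test_unrepairable_coupling_names_offending_block(small_parcellation):
    cfg = CohortConfig(n_subjects=2, seed=0, within_base=1.5)
    subjects, truth = generate_cohort(cfg)
    with pytest.raises(GenerationError, match="language|auditory|visuospatial"):
        generate_node_timeseries(subjects[0], small_parcellation, truth, 50)


def test_zero_motion_scale_gives_identically_zero_fd():
    cfg = CohortConfig(
        n_subjects=3, seed=2, motion_scale_low=0.0, motion_jitter_sd=0.0
    )
    subjects, truth = generate_cohort(cfg)
    tr = generate_motion_trace(subjects[0], truth, 50)
    assert np.all(tr.params == 0)
    assert np.all(framewise_displacement(tr) == 0)


def test_configured_high_motion_fraction_matches_screened_exclusions():
    cfg = CohortConfig(n_subjects=100, seed=17, high_motion_fraction=0.5)
    subjects, truth = generate_cohort(cfg)
    excluded = 0
    for s in subjects:
        fd = framewise_displacement(generate_motion_trace(s, truth))
        if not screen_subject(fd).include:
            excluded += 1
    assert abs(excluded / 100 - 0.5) <= 0.10


def test_noise_free_maps_with_zero_decay_equal_templates_and_give_eta_one():
    cfg = CohortConfig(
        n_subjects=4, seed=8, eta_decay=0.0, lambda_base=0.0,
        map_latent_sd=0.0, map_noise_sd=0.0, grid_shape=(10, 10, 5),
    )
    subjects, truth = generate_cohort(cfg)
    tmpl = make_templates(("auditory", "language"), (10, 10, 5), seed=8)
    maps = {
        s.subject_id: generate_spatial_maps(s, truth, tmpl) for s in subjects
    }
    for m in maps.values():
        assert np.array_equal(m["auditory"].grid, tmpl["auditory"].grid)
    ages = {s.subject_id: s.age for s in subjects}
    ref = build_reference(maps, ages, cutoff_age=90)
    table = similarity_table(maps, ref)
    assert np.allclose(table["eta_sq"], 1.0)


def test_planted_eta_decay_gives_negative_age_similarity_correlation():
    """Sign of the planted map-dissimilarity slope is recovered (eta^2 vs
    age, controlling sex) in at least 95% of seeded 150-subject cohorts."""
    labels = ("auditory", "language", "visuospatial", "primary_visual")
    hits, n_seeds = 0, 40
    for seed in range(n_seeds):
        cfg = CohortConfig(n_subjects=150, seed=seed, grid_shape=(12, 12, 6))
        subjects, truth = generate_cohort(cfg)
        tmpl = make_templates(labels, (12, 12, 6), seed=seed)
        maps = {s.subject_id: generate_spatial_maps(s, truth, tmpl) for s in subjects}
        ages = {s.subject_id: s.age for s in subjects}
        ref = build_reference(maps, ages, cutoff_age=30)
        eta = np.array(
            [eta_squared(maps[s.subject_id]["language"], ref["language"])
             for s in subjects]
        )
        age = np.array([s.age for s in subjects])
        sex = np.array([s.sex for s in subjects], dtype=float)
        if partial_correlation(eta, age, covariates=sex).r < 0:
            hits += 1
    assert hits >= int(0.95 * n_seeds)


def test_noise_only_maps_show_no_age_gradient_in_similarity():
    kw = dict(
        n_subjects=80, eta_decay=0.0, lambda_base=0.0,
        map_latent_sd=0.0, map_noise_sd=1.0, grid_shape=(10, 10, 5),
    )
    subjects, truth = generate_cohort(CohortConfig(seed=13, **kw))
    zero = SpatialMap(np.zeros((10, 10, 5)), "auditory")
    tmpl = TemplateSet((zero,), ("auditory",))
    maps = {s.subject_id: generate_spatial_maps(s, truth, tmpl) for s in subjects}
    # reference from an independent donor cohort, so no subject's own noise
    # leaks into the reference map
    donors, donor_truth = generate_cohort(CohortConfig(seed=14, **kw))
    donor_maps = {
        f"ref-{d.subject_id}": generate_spatial_maps(d, donor_truth, tmpl)
        for d in donors
    }
    donor_ages = {f"ref-{d.subject_id}": d.age for d in donors}
    ref = build_reference(donor_maps, donor_ages, cutoff_age=45)
    table = similarity_table(maps, ref).set_index("subject_id")
    age = np.array([s.age for s in subjects])
    eta = table.loc[[s.subject_id for s in subjects], "eta_sq"].to_numpy()
    # permutation test on the age-eta correlation: observed |r| should not
    # be extreme relative to label shuffles
    rng = np.random.default_rng(0)
    obs = abs(np.corrcoef(age, eta)[0, 1])
    perm = np.array(
        [abs(np.corrcoef(rng.permutation(age), eta)[0, 1]) for _ in range(500)]
    )
    assert (perm >= obs).mean() > 0.01


def test_ar1_option_keeps_block_structure_with_serial_correlation(
    small_parcellation,
):
    cfg = CohortConfig(n_subjects=2, seed=6, ar_phi=0.5)
    subjects, truth = generate_cohort(cfg)
    ts = generate_node_timeseries(subjects[0], small_parcellation, truth, 4000)
    x = ts.values[:, 0]
    lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
    assert 0.35 < lag1 < 0.65
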