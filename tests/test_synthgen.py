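"""Generator calibration, sampling, and statistical faithfulness."""

import numpy as np
import pytest

from pscarbor.genotypes import GENOTYPE_ORDER, load_genotype_config
from pscarbor.io import arbor_to_swc_text
from pscarbor.morphometry import summarize_cohort
from pscarbor.synthgen import (
    calibrate_config,
    expected_metrics,
    sample_arbor,
    sample_cohort,
)
from pscarbor.templates import make_template
from pscarbor.types import (
    CalibrationError,
    GenotypeConfig,
    InfeasibleTargetsError,
    polyline_length,
)


def _toy_template(presence=1.0):
    rows = [
        ("a", "-", 0.0, 0.55, 0.835, 80.0, 2.0, 1.0),
        ("b", "a", 0.3, 1.0, 0.0, 40.0, 1.0, presence),
        ("c", "a", 0.7, -0.5, 0.866, 30.0, 1.0, presence),
    ]
    return make_template(rows)


def _toy_config(**kw):
    base = dict(
        name="toy", n_animals=10,
        target_branch_mean=3.0, target_branch_sem=0.01,
        target_total_len_mean=150.0, target_total_len_sem=5.0,
        target_varicosity_mean=5.0, target_varicosity_sem=1.0,
    )
    base.update(kw)
    return GenotypeConfig(**base)


@pytest.mark.parametrize("name", GENOTYPE_ORDER)
def test_calibration_reproduces_published_cohort_means_within_1pct(
        name, template, calibrated):
    cfg = load_genotype_config(name)
    cal = calibrated(name)
    exp = expected_metrics(cal, template)
    assert exp["branch_count"] == pytest.approx(cfg.target_branch_mean, rel=0.01)
    assert exp["total_length"] == pytest.approx(cfg.target_total_len_mean, rel=0.01)
    assert exp["varicosity_count"] == pytest.approx(cfg.target_varicosity_mean, rel=0.01)


def test_calibration_of_all_present_targets_is_the_identity():
    t = _toy_template(presence=1.0)
    cfg = _toy_config(target_branch_mean=3.0, target_total_len_mean=150.0)
    cal = calibrate_config(cfg, t)
    assert cal.length_scale == pytest.approx(1.0, abs=0.01)
    assert cal.variable_branch_rate == pytest.approx(0.0, abs=0.02)


def test_targets_below_the_skeletal_floor_are_infeasible():
    t = _toy_template(presence=1.0)
    cfg = _toy_config(target_branch_mean=2.0)  # template always yields 3
    with pytest.raises(InfeasibleTargetsError):
        calibrate_config(cfg, t)


def test_sampling_refuses_uncalibrated_configs(template):
    cfg = load_genotype_config("wildtype")
    with pytest.raises(CalibrationError):
        sample_arbor(cfg, template, np.random.default_rng(0))


def test_all_present_config_yields_exactly_the_skeleton(rng):
    t = _toy_template(presence=1.0)
    cal = calibrate_config(_toy_config(), t)
    for _ in range(5):
        arbor = sample_arbor(cal, t, rng)
        skeletal = [b for b in arbor.branches if b.label.startswith("skeletal:")]
        assert len(skeletal) == 3
        assert not any(b.routing_error for b in arbor.branches)


def test_negligible_varicosity_density_yields_no_varicosities(rng):
    t = _toy_template(presence=1.0)
    cal = calibrate_config(
        _toy_config(target_varicosity_mean=1e-4, target_varicosity_sem=0.0), t
    )
    arbor = sample_arbor(cal, t, rng)
    assert arbor.varicosity_count == 0


def test_branch_length_matches_polyline_arc_length(template, calibrated, rng):
    arbor = sample_arbor(calibrated("wildtype"), template, rng)
    for b in arbor.branches:
        assert b.length == pytest.approx(polyline_length(b.polyline), rel=1e-9)
        assert b.length > 0
    arbor.validate_structure(tol=1e-3)


def test_identical_seeds_give_byte_identical_swc(template, calibrated):
    cal = calibrated("wildtype")
    a1 = sample_arbor(cal, template, np.random.default_rng(77))
    a2 = sample_arbor(cal, template, np.random.default_rng(77))
    a3 = sample_arbor(cal, template, np.random.default_rng(78))
    assert arbor_to_swc_text(a1) == arbor_to_swc_text(a2)
    assert arbor_to_swc_text(a1) != arbor_to_swc_text(a3)


def test_cohort_has_requested_size_and_is_seed_deterministic(template, calibrated):
    cal = calibrated("wildtype")
    c1 = sample_cohort(cal, template, np.random.default_rng(5))
    assert len(c1) == cal.n_animals
    c2 = sample_cohort(cal, template, np.random.default_rng(5))
    assert all(arbor_to_swc_text(x) == arbor_to_swc_text(y) for x, y in zip(c1, c2))
    single = sample_cohort(cal, template, np.random.default_rng(5), n=1)
    assert len(single) == 1


def test_expected_varicosities_monotone_in_density(template, calibrated):
    cal = calibrated("wildtype")
    base = expected_metrics(cal, template)["varicosity_count"]
    denser = cal.copy(varicosity_density=cal.varicosity_density * 1.5)
    assert expected_metrics(denser, template)["varicosity_count"] >= base


def test_expected_branch_count_monotone_in_variable_rate(template, calibrated):
    cal = calibrated("wildtype")
    base = expected_metrics(cal, template)["branch_count"]
    more = cal.copy(variable_branch_rate=cal.variable_branch_rate + 2.0)
    assert expected_metrics(more, template)["branch_count"] >= base


def test_monte_carlo_means_recover_published_wildtype_targets(template, calibrated):
    """1000-draw style faithfulness at reduced n: sample means of the three
    metrics fall within 3 standard errors of the published values."""
    cal = calibrated("wildtype")
    rng = np.random.default_rng(2024)
    cohort = sample_cohort(cal, template, rng, n=300)
    ms = summarize_cohort(cohort)
    for vals, target in [
        ([m.branch_count for m in ms], cal.target_branch_mean),
        ([m.total_length for m in ms], cal.target_total_len_mean),
        ([m.varicosity_count for m in ms], cal.target_varicosity_mean),
    ]:
        vals = np.asarray(vals, float)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - target) < 3 * se + 1e-9


def test_guidance_errors_move_the_entry_to_the_metathoracic_band(template, calibrated):
    cal = calibrated("plexa_rnai_lof")  # 56% guidance-error rate
    rng = np.random.default_rng(8)
    cohort = sample_cohort(cal, template, rng, n=200)
    freq = np.mean([a.guidance_error for a in cohort])
    se = np.sqrt(0.56 * 0.44 / 200)
    assert abs(freq - 0.56) < 3 * se
    for a in cohort:
        if a.guidance_error:
            assert a.entry_region == "metathoracic"
            assert a.entry_point[1] > 120
        else:
            assert a.entry_region == "mesothoracic"


def test_routed_branches_keep_their_ground_truth_label(template, calibrated, rng):
    cal = calibrated("plexa_rnai")
    routed = 0
    for _ in range(20):
        a = sample_arbor(cal, template, rng)
        for b in a.branches:
            if b.routing_error:
                routed += 1
                assert b.label.startswith("skeletal:")
    assert routed > 0
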