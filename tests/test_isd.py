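"""Partitioning and Diamond-Katz permeability against closed-form oracles."""

import math

import numpy as np
import pytest

from prodperm import (
    MembraneProfile, PhysicalSettings, ProfileShapeParams, delta_log,
    partition_from_profile, permeability_from_profile, run_snapshots,
    synth_profile,
)
from prodperm.isd import R_KCAL_PER_MOL_K

from conftest import make_flat_profile

RT_293 = R_KCAL_PER_MOL_K * 293.0
DECADE_293 = RT_293 * math.log(10.0)  # 1.3407 kcal/mol per factor 10


def profile_with_min(dG_min, span=80.0, layers=81):
    """Flat water profile with a single well/peak of the given dG at z=0."""
    p = make_flat_profile(span=span, layers=layers)
    dG = np.zeros(layers)
    dG[layers // 2] = dG_min
    return MembraneProfile(z=p.z, dG=dG, D=p.D)


# ----------------------------------------------------------- partitioning

def test_flat_profile_has_zero_logK(flat_profile, settings):
    logK, dG_min = partition_from_profile(flat_profile, settings)
    assert logK == 0.0
    assert dG_min == 0.0


def test_one_decade_minimum_gives_logK_one(settings):
    logK, _ = partition_from_profile(profile_with_min(-DECADE_293), settings)
    assert logK == pytest.approx(1.000, abs=1e-9)


def test_positive_minimum_gives_negative_logK(settings):
    # a +0.913 kcal/mol global minimum: no favorable membrane region
    logK, dG_min = partition_from_profile(profile_with_min(+0.913, layers=81), settings)
    assert dG_min == pytest.approx(0.0)  # flat edges are the global minimum
    # force the whole profile up so the minimum is +0.913
    p = make_flat_profile(dG=0.913)
    logK, dG_min = partition_from_profile(p, settings)
    assert dG_min == pytest.approx(0.913)
    assert logK == pytest.approx(-0.681, abs=1e-3)


def test_deepening_the_minimum_never_decreases_K(settings):
    depths = [-0.5, -1.0, -2.0, -4.0]
    logKs = [partition_from_profile(profile_with_min(d), settings)[0]
             for d in depths]
    assert all(b > a for a, b in zip(logKs, logKs[1:]))


# ----------------------------------------------------------- permeability

def test_flat_membrane_closed_form(flat_profile, settings):
    # P = D / 2L = 1e-5 cm2/s / 80 A = 12.5 cm/s
    logPerm = permeability_from_profile(flat_profile, settings)
    assert logPerm == pytest.approx(math.log10(12.5), abs=1e-9)
    assert logPerm == pytest.approx(1.0969, abs=1e-4)


def test_uniform_decade_offset_shifts_logPerm_by_exactly_minus_one(settings):
    base = synth_profile(ProfileShapeParams(barrier_height=8.0, min_depth=2.0))
    shifted = MembraneProfile(z=base.z, dG=base.dG + DECADE_293, D=base.D)
    lp0 = permeability_from_profile(base, settings)
    lp1 = permeability_from_profile(shifted, settings)
    assert lp0 - lp1 == pytest.approx(1.000, abs=1e-9)


def test_uniform_5kcal_barrier_costs_3_73_decades(settings):
    base = make_flat_profile()
    raised = MembraneProfile(z=base.z, dG=base.dG + 5.0, D=base.D)
    drop = (permeability_from_profile(base, settings)
            - permeability_from_profile(raised, settings))
    assert drop == pytest.approx(5.0 / DECADE_293, rel=1e-9)
    assert drop == pytest.approx(3.73, abs=0.01)


def test_quadrature_refinement_50_vs_5000_layers(settings):
    shape = dict(barrier_height=15.0, min_depth=3.0, noise_sd=0.0)
    coarse = synth_profile(ProfileShapeParams(layers=50, **shape))
    fine = synth_profile(ProfileShapeParams(layers=5000, **shape))
    lp_coarse = permeability_from_profile(coarse, settings)
    lp_fine = permeability_from_profile(fine, settings)
    assert abs(lp_coarse - lp_fine) < 1e-2


def test_halving_layer_width_changes_logPerm_below_tolerance(settings):
    shape = dict(barrier_height=15.0, min_depth=3.0, noise_sd=0.0)
    lp50 = permeability_from_profile(synth_profile(ProfileShapeParams(layers=50, **shape)), settings)
    lp100 = permeability_from_profile(synth_profile(ProfileShapeParams(layers=100, **shape)), settings)
    assert abs(lp50 - lp100) < 1e-2


def test_raising_dG_pointwise_never_increases_P(settings):
    rng = np.random.default_rng(13)
    base = synth_profile(ProfileShapeParams(barrier_height=6.0, min_depth=2.0))
    lp_base = permeability_from_profile(base, settings)
    for _ in range(10):
        bump = np.where(rng.random(base.z.size) < 0.3,
                        rng.uniform(0, 3, base.z.size), 0.0)
        raised = MembraneProfile(z=base.z, dG=base.dG + bump, D=base.D)
        assert permeability_from_profile(raised, settings) <= lp_base + 1e-12


def test_square_barrier_slope_matches_analytic_limit(settings):
    """d(log10 P)/d(barrier) = -1/(RT ln10) within 1% for dominant barriers."""

    def logP_with_square_barrier(height):
        p = make_flat_profile(layers=801)
        dG = np.where(np.abs(p.z) < 15.0, height, 0.0)
        return permeability_from_profile(
            MembraneProfile(z=p.z, dG=dG, D=p.D), settings)

    slope = (logP_with_square_barrier(12.0) - logP_with_square_barrier(10.0)) / 2.0
    assert slope == pytest.approx(-1.0 / DECADE_293, rel=0.01)


# ------------------------------------------------------------- aggregation

def test_identical_snapshots_have_zero_sd(settings):
    profiles = [make_flat_profile(snapshot_id=i) for i in range(1, 6)]
    result = run_snapshots(profiles, settings)
    assert result.logK_sd == 0.0
    assert result.logPerm_sd == 0.0
    assert not result.single_snapshot


def test_snapshot_mean_and_sample_sd(settings):
    targets = [-13.15, -13.17, -13.19, -13.21, -13.23]
    base = permeability_from_profile(make_flat_profile(), settings)
    profiles = []
    for i, t in enumerate(targets, start=1):
        offset = (base - t) * DECADE_293  # uniform dG offset hits the target
        p = make_flat_profile(snapshot_id=i)
        profiles.append(MembraneProfile(z=p.z, dG=p.dG + offset, D=p.D,
                                        snapshot_id=i))
    result = run_snapshots(profiles, settings)
    assert result.logPerm_mean == pytest.approx(-13.19, abs=1e-9)
    assert result.logPerm_sd == pytest.approx(0.0316, abs=1e-4)
    assert [s.snapshot_id for s in result.per_snapshot] == [1, 2, 3, 4, 5]


def test_single_profile_is_flagged(settings, flat_profile):
    result = run_snapshots([flat_profile], settings)
    assert result.single_snapshot
    assert result.logPerm_sd == 0.0


def test_mismatched_grids_rejected(settings):
    with pytest.raises(ValueError, match="identical depth grid"):
        run_snapshots([make_flat_profile(layers=81), make_flat_profile(layers=51)],
                      settings)


def test_empty_snapshot_list_rejected(settings):
    with pytest.raises(ValueError, match="at least one"):
        run_snapshots([], settings)


# ------------------------------------------------------------ delta_log

def test_delta_log_from_published_pairs(table2):
    pali = delta_log(table2.result("paliperidone"), table2.result("Pali-fru"))
    assert pali.dlogPerm == pytest.approx(2.35, abs=1e-9)
    fu = delta_log(table2.result("fluorouracil"), table2.result("FU-fru"))
    assert fu.dlogK == pytest.approx(1.82, abs=1e-9)
    assert fu.sd_dlogK == pytest.approx(math.hypot(0.11, 0.06), abs=1e-12)


def test_delta_log_of_identical_results_is_zero(table2):
    r = table2.result("cytarabine")
    d = delta_log(r, r)
    assert d.dlogK == 0.0 and d.dlogPerm == 0.0
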