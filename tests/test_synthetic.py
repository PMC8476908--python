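"""Synthetic fluence simulation: geometry, determinism, cohort structure."""

import numpy as np
import pytest

from epidfluence.core import ErrorVector
from epidfluence.synthetic_data import (
    ArcSegment,
    FluenceSimulator,
    SimulationConfig,
    default_plan,
    generate_cohort,
    generate_phantom,
    simulate_fluence,
)

# desk-scale configuration: coarse pitch keeps the phantom inside a small
# field of view, a coarse angular step keeps the arcs cheap
SMALL = SimulationConfig(
    n_patients=2, image_size=128, pitch_mm=1.5,
    angular_step_deg=15.0, master_seed=7,
)
SMALL_NOISELESS = SimulationConfig(
    n_patients=1, image_size=128, pitch_mm=1.5,
    angular_step_deg=15.0, master_seed=7, noise_sigma_frac=0.0,
)
# full-pitch configuration for sub-millimetre geometry checks
FULLPITCH = SimulationConfig(
    n_patients=1, image_size=512, angular_step_deg=15.0,
    master_seed=7, noise_sigma_frac=0.0,
)


def test_phantom_deterministic_and_seed_dependent():
    p1 = generate_phantom(123, SMALL)
    p2 = generate_phantom(123, SMALL)
    p3 = generate_phantom(124, SMALL)
    assert p1 == p2
    centers1 = {c.center for c in p1.components}
    centers3 = {c.center for c in p3.components}
    assert centers1 != centers3  # heterogeneity positions move with the seed


def test_phantom_attenuation_grid_nonnegative_and_covers_body():
    ph = generate_phantom(5, SMALL)
    grid = ph.attenuation_grid(voxel_mm=4.0)
    assert grid.min() >= 0.0
    r_xy, r_z = ph.bounding_radii_mm()
    # grid spans the full phantom extent on every axis
    assert grid.shape[0] * 4.0 >= 2 * r_xy
    assert grid.shape[2] * 4.0 >= 2 * r_z
    assert grid.max() > 0


def test_arc_angles_avoid_under_couch_range():
    arc = ArcSegment(240.0, 120.0, clockwise=True, step_deg=5.0)
    angles = arc.angles()
    assert angles[0] == 240.0 and angles[-1] == 120.0
    assert len(angles) == 49
    # the 120-240 range under the couch is never visited (endpoints aside)
    interior = angles[(angles > 121) & (angles < 239)]
    assert len(interior) == 0


def test_zero_shift_identity():
    ph = generate_phantom(1, SMALL_NOISELESS)
    sim = FluenceSimulator(ph, default_plan(1, step_deg=15.0), SMALL_NOISELESS)
    a = sim.simulate(ErrorVector(0, 0, 0), noise_seed=3)
    b = sim.simulate(ErrorVector(0, 0, 0), noise_seed=3)
    assert np.array_equal(a.pixels, b.pixels)


def test_si_shift_displaces_image_coherently():
    """Open-field SI shift: integer-lag cross-correlation peaks at
    round(4 mm / 0.336 mm) = 12 rows."""
    ph = generate_phantom(2, FULLPITCH)
    plan = default_plan(2, step_deg=15.0, open_aperture=True)
    sim = FluenceSimulator(ph, plan, FULLPITCH)
    base = sim.simulate(ErrorVector(0, 0, 0), 0).pixels
    shifted = sim.simulate(ErrorVector(0, 4, 0), 0).pixels

    def ncc(lag):
        if lag >= 0:
            x, y = base[: base.shape[0] - lag], shifted[lag:]
        else:
            x, y = base[-lag:], shifted[: shifted.shape[0] + lag]
        x = x - x.mean()
        y = y - y.mean()
        return float((x * y).sum() / np.sqrt((x * x).sum() * (y * y).sum()))

    scores = {lag: ncc(lag) for lag in range(-16, 17)}
    assert max(scores, key=scores.get) == 12


def test_si_dd_exceeds_lr_dd_and_monotonicity():
    """SI shifts displace the integrated image coherently; in-plane LR
    shifts partially cancel over the arc, so their DD is smaller.  DD is
    also non-decreasing in shift size along each axis."""
    ph = generate_phantom(3, FULLPITCH)
    sim = FluenceSimulator(ph, default_plan(3, step_deg=15.0), FULLPITCH)
    base = sim.simulate(ErrorVector(0, 0, 0), 0).pixels

    def mean_dd(err):
        moved = sim.simulate(err, 0).pixels
        return float(np.abs(base - moved).mean())

    si = [mean_dd(ErrorVector(0, s, 0)) for s in (0, 2, 4)]
    lr = [mean_dd(ErrorVector(s, 0, 0)) for s in (0, 2, 4)]
    assert si[2] > lr[2]
    assert si[0] <= si[1] <= si[2]
    assert lr[0] <= lr[1] <= lr[2]


def test_out_of_fov_error_rejected():
    ph = generate_phantom(1, SMALL_NOISELESS)
    sim = FluenceSimulator(ph, default_plan(1, step_deg=15.0), SMALL_NOISELESS)
    with pytest.raises(ValueError, match="field of view"):
        sim.simulate(ErrorVector(0, 500, 0), 0)


def test_simulate_fluence_wrapper_maps_are_valid():
    ph = generate_phantom(4, SMALL_NOISELESS)
    fm = simulate_fluence(
        ph, default_plan(4, step_deg=15.0), ErrorVector(2, 0, 0),
        SMALL_NOISELESS, noise_seed=9,
    )
    assert fm.pixels.shape == (128, 128)
    assert fm.pixels.min() >= 0
    assert fm.error == ErrorVector(2, 0, 0)


def test_cohort_structure_and_determinism():
    records = generate_cohort(SMALL)
    assert len(records) == 2 * 28
    per_patient = {}
    for r in records:
        per_patient.setdefault(r.patient_id, []).append(r)
    for recs in per_patient.values():
        assert len(recs) == 28
        baselines = [r for r in recs if r.role == "baseline"]
        errors = [r for r in recs if r.role == "error"]
        assert len(baselines) == 1 and len(errors) == 27
        assert sorted(r.serial for r in recs) == list(range(1, 29))
        # serial 2 is a fresh acquisition of the unshifted position
        s2 = next(r for r in errors if r.serial == 2)
        assert s2.map.error.as_tuple() == (0, 0, 0)
        assert s2.labels is not None and s2.labels.type1 == 1
        assert baselines[0].noise_seed != s2.noise_seed
        # every error record carries consistent labels
        for r in errors:
            assert r.labels.type3 in range(1, 9)

    again = generate_cohort(SMALL)
    for r1, r2 in zip(records, again):
        assert np.array_equal(r1.map.pixels, r2.map.pixels)


def test_zero_noise_resim_of_origin_equals_baseline():
    cfg = SimulationConfig(
        n_patients=1, image_size=128, pitch_mm=1.5,
        angular_step_deg=15.0, master_seed=3, noise_sigma_frac=0.0,
    )
    records = generate_cohort(cfg)
    base = next(r for r in records if r.role == "baseline")
    s2 = next(r for r in records if r.serial == 2)
    assert np.array_equal(base.map.pixels, s2.map.pixels)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_patients=0)
    with pytest.raises(ValueError):
        SimulationConfig(magnification=0)
    with pytest.raises(ValueError):
        SimulationConfig(noise_sigma_frac=-0.1)
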