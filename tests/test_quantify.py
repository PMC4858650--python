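"""Index quantification: round trips, LUV, HH15/LHL15 and their oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hepaspect.acquisition import (
    dynamic_schedule,
    expected_organ_counts,
    render_acquisition,
    static_schedule,
)
from hepaspect.kinetics import TC99M_HALF_LIFE_MIN, blood_tac, liver_tac
from hepaspect.phantom import GeometryConfig, LabelVolume, make_phantom
from hepaspect.quantify import (
    TimeActivityCurve,
    compute_hh15,
    compute_lhl15,
    compute_luv,
    extract_tac,
    liver_volume,
    roi_activity,
)


# ---------------------------------------------------------------------------
# roi_activity / round trip
# ---------------------------------------------------------------------------


def test_noiseless_round_trip_recovers_analytic_activity(control_animal):
    """render -> roi_activity on noiseless input reproduces the analytic
    frame-averaged decayed activity to 1e-9 relative error."""
    frames = static_schedule()
    acq = render_acquisition(None, control_animal, frames, poisson=False)
    measured = roi_activity(acq, None, "liver", 0, decay_correct=False)
    expected_counts = expected_organ_counts(control_animal, frames, 50.0, 0.1)[0, 1]
    analytic = expected_counts / (50.0 * 30.0)
    assert measured == pytest.approx(analytic, rel=1e-9)


def test_decay_correction_recovers_instantaneous_fraction(control_animal):
    """Decay-corrected recovery at the 40-min static frame approximates
    injected x liver fraction at the frame midpoint (frame-averaging over
    30 s is a < 1e-3 relative effect)."""
    acq = render_acquisition(None, control_animal, static_schedule(), poisson=False)
    measured = roi_activity(acq, None, "liver", 0, decay_correct=True)
    frac = liver_tac(control_animal.kinetics, 40.0)
    assert measured == pytest.approx(control_animal.injected_MBq * frac, rel=1e-3)


def test_all_zero_counts_give_zero_activity(control_animal):
    acq = render_acquisition(None, control_animal, static_schedule(), poisson=False)
    acq.counts = np.zeros_like(acq.counts)
    assert roi_activity(acq, None, "liver", 0) == 0.0


def test_poisson_recovery_unbiased(control_animal):
    """1000 Poisson replicates: mean recovered activity within 3 SE."""
    frames = static_schedule()
    mu_counts = expected_organ_counts(control_animal, frames, 50.0, 0.1)[0, 1]
    vals = np.array([
        roi_activity(render_acquisition(None, control_animal, frames, seed=s),
                     None, "liver", 0)
        for s in range(1000)
    ])
    expected = mu_counts / (50.0 * 30.0)
    se = math.sqrt(mu_counts / 1000) / (50.0 * 30.0)
    assert abs(vals.mean() - expected) <= 3 * se


def test_unknown_label_rejected(control_animal):
    acq = render_acquisition(None, control_animal, static_schedule(), poisson=False)
    with pytest.raises(KeyError):
        roi_activity(acq, None, "spleen", 0)


def test_roi_additivity_over_disjoint_labels(control_animal):
    """Voxel-mode activities are additive over disjoint organ labels."""
    ph = make_phantom(GeometryConfig(shape=(24, 24, 40), voxel_size_mm=(1.0, 1.0, 1.0)))
    acq = render_acquisition(ph, control_animal, static_schedule(),
                             mode="voxel", poisson=False)
    parts = sum(roi_activity(acq, ph, organ, 0)
                for organ in ("body", "liver", "heart_blood", "intestine", "bladder"))
    whole = sum(
        acq.counts[0][ph.labels == v].sum() for v in (1, 2, 3, 4, 5)
    ) / (50.0 * 30.0)
    assert parts == pytest.approx(whole, rel=1e-12)


# ---------------------------------------------------------------------------
# liver volume and LUV
# ---------------------------------------------------------------------------


def test_liver_volume_from_voxel_count():
    labels = np.zeros((40, 40, 40), dtype=int)
    labels[:20, :20, :20] = 2  # 8000 voxels
    labels[0, 0, 39] = 3  # non-empty heart
    ph = LabelVolume(labels=labels, voxel_size_mm=(0.5, 0.5, 0.5))
    assert liver_volume(ph) == pytest.approx(1.0)  # 8000 x 0.125 mm^3


def test_compute_luv_identity_and_zero():
    assert compute_luv(18.0, 18.0, 1.0) == pytest.approx(100.0)
    assert compute_luv(0.0, 18.0, 1.0) == 0.0


@pytest.mark.parametrize("bad", [dict(injected_MBq=0.0), dict(liver_volume_mL=-1.0)])
def test_compute_luv_rejects_nonpositive(bad):
    kw = dict(liver_activity_MBq=1.0, injected_MBq=18.0, liver_volume_mL=1.0)
    kw.update(bad)
    with pytest.raises(ValueError):
        compute_luv(**kw)


@given(c=st.floats(1e-6, 1e6))
def test_luv_scale_invariance(c):
    """Rescaling injected dose and liver activity together leaves LUV fixed."""
    base = compute_luv(4.6, 18.0, 1.2)
    assert compute_luv(4.6 * c, 18.0 * c, 1.2) == pytest.approx(base, rel=1e-12)


# ---------------------------------------------------------------------------
# TACs and the dynamic indices
# ---------------------------------------------------------------------------


def tac(values, times=None, durations=30.0):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = 0.25 + 0.5 * np.arange(values.size)
    return TimeActivityCurve(
        roi_label="heart_blood", times_min=np.asarray(times), values=values,
        frame_durations_s=np.full(values.size, durations),
    )


def test_extract_tac_matches_frames(control_animal):
    acq = render_acquisition(None, control_animal, dynamic_schedule(), poisson=False)
    curve = extract_tac(acq, None, "liver")
    assert curve.times_min.size == 30
    np.testing.assert_allclose(curve.times_min, 0.25 + 0.5 * np.arange(30))


def test_hh15_constant_curve_is_one():
    assert compute_hh15(tac(np.ones(30))) == pytest.approx(1.0)


def test_hh15_pure_exponential_closed_form():
    """exp(-ln2 * t / 6) sampled on 30 s frames: the 15- and 3-min lookups
    land on midpoints exactly 12 min apart, so HH15 = 2^-2 = 0.25."""
    times = 0.25 + 0.5 * np.arange(30)
    curve = tac(np.exp(-math.log(2.0) * times / 6.0))
    assert compute_hh15(curve) == pytest.approx(0.25, rel=1e-12)


def test_nominal_time_tie_takes_earlier_frame():
    """3.0 min is equidistant from the 2.75 and 3.25 midpoints; the
    earlier frame wins."""
    values = np.arange(30.0) + 1.0
    curve = tac(values)
    assert curve.at(3.0) == values[5]  # midpoint 2.75
    assert curve.at(15.0) == values[29]  # midpoint 14.75 (last frame)


def test_curve_must_span_nominal_times():
    short = tac(np.ones(10))  # covers 0-5 min only
    with pytest.raises(ValueError, match="span"):
        compute_hh15(short)


def test_hh15_zero_early_activity_rejected():
    vals = np.ones(30)
    vals[5] = 0.0  # the 3-min lookup frame
    with pytest.raises(ValueError, match="zero"):
        compute_hh15(tac(vals))


def test_lhl15_trivial_values():
    l = tac(np.full(30, 2.0))
    h = tac(np.full(30, 2.0))
    assert compute_lhl15(l, h) == pytest.approx(0.5)
    assert compute_lhl15(l, tac(np.zeros(30))) == pytest.approx(1.0)


def test_lhl15_zero_total_rejected():
    z = tac(np.zeros(30))
    with pytest.raises(ValueError):
        compute_lhl15(z, z)


def test_dynamic_indices_match_analytic_compartments(control_animal):
    """HH15 and LHL15 from the rendered noiseless acquisition agree with
    direct evaluation of the kinetic model to within 1% (frame binning)."""
    p = control_animal.kinetics
    acq = render_acquisition(None, control_animal, dynamic_schedule(), poisson=False)
    heart = extract_tac(acq, None, "heart_blood")
    liver = extract_tac(acq, None, "liver")

    # The nominal 3- and 15-min lookups land on the 2.75- and 14.75-min
    # frame midpoints; the oracle evaluates the model there, so the only
    # residual discrepancies are the 30 s frame averaging and — for the
    # default raw-count HH15 — the physical decay over the 12-min spacing.
    t3, t15 = 2.75, 14.75
    decay = 2.0 ** (-(t15 - t3) / TC99M_HALF_LIFE_MIN)
    hh15_ref = blood_tac(p, t15) / blood_tac(p, t3)
    l15, h15 = liver_tac(p, t15), 0.1 * blood_tac(p, t15)
    lhl15_ref = l15 / (l15 + h15)
    assert compute_hh15(heart) == pytest.approx(hh15_ref * decay, rel=0.01)
    assert compute_lhl15(liver, heart) == pytest.approx(lhl15_ref, rel=0.01)

    # decay-corrected extraction removes the decay factor entirely
    heart_dc = extract_tac(acq, None, "heart_blood", decay_correct=True)
    assert compute_hh15(heart_dc) == pytest.approx(hh15_ref, rel=0.01)


def test_lhl15_increases_with_receptor_density(control_animal):
    import dataclasses
    lows = []
    for r in (0.5, 1.0):
        a = dataclasses.replace(control_animal, asgpr_rel=r,
                                kinetics=control_animal.kinetics.with_receptor_density(r))
        acq = render_acquisition(None, a, dynamic_schedule(), poisson=False)
        lows.append(compute_lhl15(extract_tac(acq, None, "liver"),
                                  extract_tac(acq, None, "heart_blood")))
    assert lows[1] > lows[0]


def test_hh15_below_one_for_decreasing_heart_curve(control_animal):
    acq = render_acquisition(None, control_animal, dynamic_schedule(), poisson=False)
    heart = extract_tac(acq, None, "heart_blood")
    assert np.all(np.diff(heart.values) < 0)
    assert compute_hh15(heart) < 1.0
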