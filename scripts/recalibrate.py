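"""Recompute the per-group k_up calibration constants.

The liver fraction is linear in ``k_up * R``, so each group's uptake
constant is a linear solve: the decay-corrected, frame-averaged liver
fraction recovered from the static frame at unit ``k_up * R`` is evaluated
in closed form, and ``k_up = target_LUV * V / (100 * R_mean * g)``.

Run from the repository root after changing the kinetic defaults or the
static schedule in ``src/hepaspect/config/reference.yaml``; paste the
printed constants back into that file.
"""

import sys

from hepaspect.kinetics import (
    DECAY_RATE_PER_MIN,
    TC99M_HALF_LIFE_MIN,
    KineticParams,
    frame_integral,
    liver_mixture,
)
from hepaspect.pipeline import reference_config

TARGET_LUV = {"control": 25.5, "ccl4_4wk": 19.0, "ccl4_8wk": 14.3,
              "ccl4_12wk": 14.3, "ccl4_tanIIA": 21.0}
NOMINAL_LIVER_VOLUME_ML = 1.0


def unit_uptake_recovered_fraction(kinetic_defaults, static_cfg) -> float:
    """Recovered liver fraction at k_up * R = 1 for the static frame."""
    p = KineticParams(k_up=1.0, R=1.0, **kinetic_defaults)
    t_mid = float(static_cfg["center_min"])
    half = float(static_cfg["duration_s"]) / 120.0
    t0, t1 = t_mid - half, t_mid + half
    integral = frame_integral(liver_mixture(p), t0, t1, extra_rate=DECAY_RATE_PER_MIN)
    return integral / (t1 - t0) * 2.0 ** (t_mid / TC99M_HALF_LIFE_MIN)


def main() -> int:
    raw = reference_config()
    g = unit_uptake_recovered_fraction(
        raw["cohort"]["kinetic_defaults"], raw["acquisition"]["static"]
    )
    print(f"# unit-uptake recovered liver fraction at static frame: {g!r}")
    for name, grp in raw["cohort"]["groups"].items():
        r_mean = grp["asgpr_rel"]["mean"]
        k_up = TARGET_LUV[name] * NOMINAL_LIVER_VOLUME_ML / (100.0 * r_mean * g)
        print(f"{name}: k_up: {k_up!r}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
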