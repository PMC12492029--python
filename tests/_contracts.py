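"""Shared qualitative-fidelity checks for the fermentation oracle.

Each check varies one nutrient around the mid-range medium with everything
else fixed and compares the 4-day growth rate and the final fresh mass, the
behaviour the design loop is supposed to discover: nitrate and phosphate set
the growth rate (nitrate with an inhibitory high end), while sucrose and
ammonium cap the final yield without moving the early rate.
"""

import numpy as np

from fermbed.simulator import SimulatorParams, observe, simulate_batch

MID = np.array([100.0, 20.0, 5.0, 40.0, 15.0])
_IDX = {"sucrose": 0, "ammonium": 1, "phosphate": 2, "nitrate": 3, "start_fm": 4}


def _run(params: SimulatorParams, **overrides):
    x = MID.copy()
    for name, value in overrides.items():
        x[_IDX[name]] = value
    traj = simulate_batch(x, params, noise=False)
    rate96 = observe(traj, 96.0)[1]
    final = observe(traj, params.horizon)[0]
    return rate96, final


def check_nitrate_raises_rate(params: SimulatorParams) -> None:
    r10, _ = _run(params, nitrate=10.0)
    r60, _ = _run(params, nitrate=60.0)
    r150, _ = _run(params, nitrate=150.0)
    assert r60 > r10, "raising nitrate 10->60 mM must raise the 96-h growth rate"
    assert r150 <= r60, "raising nitrate 60->150 mM must not raise the 96-h rate"


def check_phosphate_raises_rate(params: SimulatorParams) -> None:
    r2, _ = _run(params, phosphate=2.0)
    r10, _ = _run(params, phosphate=10.0)
    assert r10 > r2, "raising phosphate 2->10 mM must raise the 96-h growth rate"


def check_sucrose_caps_yield_only(params: SimulatorParams) -> None:
    r_full, f_full = _run(params)
    r_half, f_half = _run(params, sucrose=50.0)
    assert abs(r_half - r_full) / r_full < 0.05, "halving sucrose must leave the 96-h rate within 5%"
    assert f_half < f_full, "halving sucrose must lower the final fresh mass"


def check_ammonium_caps_yield_only(params: SimulatorParams) -> None:
    r_hi, f_hi = _run(params, ammonium=40.0)
    r_lo, f_lo = _run(params, ammonium=10.0)
    assert abs(r_lo - r_hi) / r_hi < 0.05, "ammonium 40->10 mM must leave the 96-h rate within 5%"
    assert f_lo < f_hi, "ammonium 40->10 mM must lower the final fresh mass"


def check_required_substrates(params: SimulatorParams) -> None:
    for name in ("sucrose", "ammonium"):
        traj = simulate_batch(
            np.where(np.arange(5) == _IDX[name], 0.0, MID), params, noise=False
        )
        assert traj.fm[-1] == MID[4], f"zero {name} must give zero growth"


def check_monotone_capped_converged(params: SimulatorParams) -> None:
    traj = simulate_batch(MID, params, noise=False)
    assert np.all(np.diff(traj.fm) >= 0), "noise-free fresh mass must be nondecreasing"
    cap = MID[4] + min(
        params.Y_S * MID[0], params.Y_NH4 * MID[1] + params.Y_NO3 * MID[3]
    )
    assert traj.fm[-1] <= cap * (1 + 1e-6), "final fresh mass must respect the substrate cap"
    import dataclasses

    fine = dataclasses.replace(params, step=params.step / 2)
    f2 = simulate_batch(MID, fine, noise=False).fm[-1]
    assert abs(f2 - traj.fm[-1]) / traj.fm[-1] < 1e-3, "halving the step must move FM(168) < 0.1%"


ALL_CHECKS = (
    check_nitrate_raises_rate,
    check_phosphate_raises_rate,
    check_sucrose_caps_yield_only,
    check_ammonium_caps_yield_only,
    check_required_substrates,
    check_monotone_capped_converged,
)
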