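"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's integration code paths:
the catenary solution is the textbook closed form, and the ODE oracle uses
scipy's adaptive integrator on the raw right-hand side with RF applied as
explicit discontinuities.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from hp13c import AcquisitionScheme, InputFunction, KineticParams


@pytest.fixture
def study_params() -> KineticParams:
    """The reference kinetic constants of the simulated brain system."""
    return KineticParams(kPL=0.012, kLB=0.001, T1P=35.0, T1L=30.0, T1B=10.0)


@pytest.fixture
def long_scheme() -> AcquisitionScheme:
    """TR 1 s, 240 excitations (the reference simulation clock)."""
    return AcquisitionScheme(TR=1.0, n_steps=240, flip_P=1.0, flip_L=1.0, flip_B=1.0)


@pytest.fixture
def bolus() -> InputFunction:
    return InputFunction(kind="bolus_at_zero", amplitude=1.0)


def catenary_closed_form(params: KineticParams, times: np.ndarray, P0: float = 1.0):
    """Bateman solution of the three-pool catenary at zero flip.

    Valid for kPB_direct = 0 and pairwise-distinct pool decay rates.
    """
    aP = 1.0 / params.T1P + params.kPL
    aL = 1.0 / params.T1L + params.kLB
    aB = 1.0 / params.T1B
    t = np.asarray(times, dtype=float)
    P = P0 * np.exp(-aP * t)
    L = P0 * params.kPL * (np.exp(-aP * t) - np.exp(-aL * t)) / (aL - aP)
    B = P0 * params.kPL * params.kLB * (
        np.exp(-aP * t) / ((aL - aP) * (aB - aP))
        + np.exp(-aL * t) / ((aP - aL) * (aB - aL))
        + np.exp(-aB * t) / ((aP - aB) * (aL - aB))
    )
    return np.column_stack([P, L, B])


def ode_oracle(
    params: KineticParams,
    scheme: AcquisitionScheme,
    input_fn: InputFunction,
    rtol: float = 1e-11,
) -> np.ndarray:
    """Adaptive-step integration with RF events as discontinuities.

    Returns the magnetization immediately before each excitation, shape
    (n_steps, 3).  Independent of the package's propagator: plain RHS
    evaluation handed to scipy's RK45 with tight tolerances, integrating
    each TR separately and applying the cos-flip losses between segments.
    """
    A = params.system_matrix()

    def rhs(t, y):
        return A @ y + np.array([float(input_fn.value(t)), 0.0, 0.0])

    cosf = np.cos(np.radians(scheme.flips))
    y = np.zeros(3)
    if input_fn.kind == "bolus_at_zero":
        y[0] = input_fn.amplitude
    out = np.empty((scheme.n_steps, 3))
    for k in range(scheme.n_steps):
        t0, t1 = k * scheme.TR, (k + 1) * scheme.TR
        sol = solve_ivp(rhs, (t0, t1), y, rtol=rtol, atol=1e-14,
                        max_step=scheme.TR / 4)
        y = sol.y[:, -1]
        out[k] = y
        y = y * cosf
    return out


def random_system(rng: np.random.Generator):
    """A random but well-posed parameter set, scheme and input."""
    params = KineticParams(
        kPL=float(rng.uniform(0, 0.05)),
        kLB=float(rng.uniform(0, 0.01)),
        kPB_direct=float(rng.choice([0.0, rng.uniform(0, 0.005)])),
        T1P=float(rng.uniform(20, 60)),
        T1L=float(rng.uniform(15, 45)),
        T1B=float(rng.uniform(5, 20)),
    )
    scheme = AcquisitionScheme(
        TR=float(rng.uniform(0.5, 3.0)),
        n_steps=int(rng.integers(25, 50)),
        flip_P=float(rng.uniform(0, 90)),
        flip_L=float(rng.choice([0.0, 90.0, rng.uniform(0, 90)])),
        flip_B=float(rng.uniform(0, 90)),
    )
    if rng.random() < 0.5:
        input_fn = InputFunction(kind="bolus_at_zero", amplitude=float(rng.uniform(0.5, 2)))
    else:
        input_fn = InputFunction(
            kind="gamma_variate",
            amplitude=float(rng.uniform(0.5, 2)),
            alpha=float(rng.uniform(1.5, 4)),
            beta=float(rng.uniform(0.5, 3)),
            t0=float(rng.uniform(0, 5)),
        )
    return params, scheme, input_fn
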