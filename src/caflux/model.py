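"""Two-pool cytosol–ER calcium dynamics with Hill-type CICR.

The model tracks two concentrations (both in µM): cytosolic calcium ``ca_i``
and ER calcium ``ca_er``.  Calcium enters the cytosol from outside at a
constant rate γ and leaves at rate β·ca_i; the ER exchanges calcium with the
cytosol through a passive leak (k), SERCA uptake (k1) and a Hill-activated
CICR flux (α, half-occupation δ, coefficient n):

    d[Ca]_i/dt  = k·[Ca]_ER − k1·[Ca]_i + α·H([Ca]_i)·[Ca]_ER + γ − β·[Ca]_i
    d[Ca]_ER/dt = −(k·[Ca]_ER − k1·[Ca]_i + α·H([Ca]_i)·[Ca]_ER)

with H(c) = c^n / (δ^n + c^n).  The ER equation is exactly the negative of
the cytosol–ER exchange fluxes, so the total d([Ca]_i+[Ca]_ER)/dt = γ − β·[Ca]_i
— which forces the time-average of [Ca]_i over any limit cycle (or at any
steady state) to equal γ/β.

Substrate electroconductivity enters through (β, γ): a higher-conductivity
extracellular environment shortens the membrane charging time, which is
modeled as faster inward flow (larger γ) and slower efflux (smaller β).
Units are µM and seconds throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterator, Literal, Sequence

import numpy as np

from .errors import InsufficientDataError, IntegrationError, ValidationError

__all__ = [
    "ModelParams",
    "CaState",
    "Trajectory",
    "ConductivityCondition",
    "StabilityReport",
    "CONTROL_PARAMS",
    "CONDITION_LABELS",
    "hill_activation",
    "rhs",
    "fixed_point",
    "jacobian",
    "stability",
    "simulate",
    "cycle_average",
    "classify_trajectory",
    "condition_params",
    "sweep",
    "sample_oscillatory_params",
]


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the two-pool model.

    Parameters
    ----------
    beta : float
        Calcium efflux rate from cytosol to the extracellular space, 1/s.
    alpha : float
        Maximum CICR flux rate through the IP3R channel, 1/s.
    gamma : float
        Constant inward calcium flow across the plasma membrane, µM/s.
    n : int
        Hill coefficient of CICR activation (dimensionless, ≥ 1).
    delta : float
        Cytosolic concentration giving half occupation of the channel, µM.
    k : float
        Passive ER→cytosol leak rate, 1/s.
    k1 : float
        Maximum SERCA uptake rate (cytosol→ER), 1/s.
    """

    beta: float = 2.0
    alpha: float = 1.3
    gamma: float = 2.0
    n: int = 4
    delta: float = 1.3
    k: float = 0.01
    k1: float = 2.0

    def __post_init__(self) -> None:
        for name in ("beta", "alpha", "gamma", "delta", "k", "k1"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"parameter {name} must be a finite positive number, got {v!r}")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValidationError(f"Hill coefficient n must be an integer >= 1, got {self.n!r}")

    def to_dict(self) -> dict:
        return {
            "beta_per_s": self.beta,
            "alpha_per_s": self.alpha,
            "gamma_uM_per_s": self.gamma,
            "n": int(self.n),
            "delta_uM": self.delta,
            "k_per_s": self.k,
            "k1_per_s": self.k1,
        }


#: Control-condition parameter set (middle value of the printed β/γ triplets).
CONTROL_PARAMS = ModelParams()

CONDITION_LABELS = ("low", "control", "high")

# Conductivity → (gamma, beta) pairing.  Higher conductivity shortens the
# membrane charging time, modeled as larger inward flow γ and smaller efflux
# β; this antagonistic pairing of the value triplet is the only one under
# which mean cytosolic calcium (= γ/β on any attractor) rises with
# conductivity.  The pairing is recorded in output metadata.
_CONDITION_GAMMA_BETA = {
    "low": (1.9, 2.1),
    "control": (2.0, 2.0),
    "high": (2.1, 1.9),
}


@dataclass(frozen=True)
class CaState:
    """Instantaneous (cytosolic, ER) calcium concentrations in µM."""

    ca_i: float
    ca_er: float

    def __post_init__(self) -> None:
        for name in ("ca_i", "ca_er"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.ca_i, self.ca_er], dtype=float)


@dataclass(frozen=True)
class ConductivityCondition:
    """A labeled substrate-conductivity condition with its parameter set."""

    label: str
    params: ModelParams


@dataclass(frozen=True)
class StabilityReport:
    """Linear stability of the unique fixed point."""

    fixed_point: CaState
    jacobian: tuple[tuple[float, float], tuple[float, float]]
    jacobian_trace: float
    jacobian_determinant: float
    eigenvalues: tuple[complex, complex]
    classification: Literal["stable", "unstable", "center/marginal"]

    def to_dict(self) -> dict:
        return {
            "fixed_point_uM": {"ca_i": self.fixed_point.ca_i, "ca_er": self.fixed_point.ca_er},
            "jacobian_per_s": [list(row) for row in self.jacobian],
            "jacobian_trace_per_s": self.jacobian_trace,
            "jacobian_determinant_per_s2": self.jacobian_determinant,
            "eigenvalues_per_s": [[ev.real, ev.imag] for ev in self.eigenvalues],
            "classification": self.classification,
        }


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled simulation output.

    ``ca_i`` and ``ca_er`` are arrays aligned with ``times``; ``states``
    exposes the same data as a sequence of :class:`CaState` for convenience.
    """

    times: np.ndarray
    ca_i: np.ndarray
    ca_er: np.ndarray
    params: ModelParams
    dt: float
    method: str

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> CaState:
        return CaState(float(self.ca_i[i]), float(self.ca_er[i]))

    @property
    def states(self) -> Iterator[CaState]:
        for i in range(len(self.times)):
            yield self.state(i)


def hill_activation(ca_i: float, delta: float, n: int) -> float:
    """Hill activation fraction ca_i^n / (delta^n + ca_i^n), in [0, 1).

    Monotone nondecreasing in ``ca_i``; equals 0.5 at ``ca_i == delta``.
    """
    if not (math.isfinite(ca_i) and ca_i >= 0):
        raise ValidationError(f"ca_i must be finite and >= 0, got {ca_i!r}")
    if not (math.isfinite(delta) and delta > 0):
        raise ValidationError(f"delta must be finite and > 0, got {delta!r}")
    if not n >= 1:
        raise ValidationError(f"Hill coefficient must be >= 1, got {n!r}")
    if ca_i == 0.0:
        return 0.0
    # work with the ratio for overflow safety at large ca_i; an overflowing
    # ratio means ca_i is negligible against delta
    try:
        r = (delta / ca_i) ** n
    except OverflowError:
        return 0.0
    return 1.0 / (1.0 + r)


def rhs(state: CaState, params: ModelParams) -> tuple[float, float]:
    """Time derivatives (d ca_i/dt, d ca_er/dt) in µM/s.

    The ER derivative is by construction the negative of the cytosol–ER
    exchange fluxes, so the two derivatives always sum to γ − β·ca_i.
    """
    p = params
    h = hill_activation(state.ca_i, p.delta, p.n)
    exchange = p.k * state.ca_er - p.k1 * state.ca_i + p.alpha * h * state.ca_er
    return exchange + p.gamma - p.beta * state.ca_i, -exchange


def fixed_point(params: ModelParams) -> CaState:
    """Closed-form unique fixed point.

    Setting the ER equation to zero forces the exchange flux to vanish, which
    reduces the cytosol equation to γ = β·ca_i; hence ca_i* = γ/β and
    ca_er* = k1·ca_i* / (k + α·H(ca_i*)).
    """
    ca_i = params.gamma / params.beta
    h = hill_activation(ca_i, params.delta, params.n)
    ca_er = params.k1 * ca_i / (params.k + params.alpha * h)
    return CaState(ca_i, ca_er)


def jacobian(state: CaState, params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` at ``state`` (units 1/s)."""
    p = params
    c = state.ca_i
    h = hill_activation(c, p.delta, p.n)
    if c == 0.0:
        dh = 0.0 if p.n > 1 else 1.0 / p.delta
    else:
        dh = p.n * (p.delta**p.n) * c ** (p.n - 1) / (p.delta**p.n + c**p.n) ** 2
    d_exch_dc = -p.k1 + p.alpha * dh * state.ca_er
    d_exch_de = p.k + p.alpha * h
    return np.array(
        [[d_exch_dc - p.beta, d_exch_de], [-d_exch_dc, -d_exch_de]], dtype=float
    )


_STABILITY_TOL = 1e-9


def stability(params: ModelParams) -> StabilityReport:
    """Linear stability classification of the fixed point.

    The sign of the largest eigenvalue real part (tolerance 1e−9 1/s) decides
    between ``stable``, ``unstable`` and ``center/marginal``.  An unstable
    fixed point of this bounded two-variable system implies a limit cycle,
    i.e. sustained calcium oscillation.
    """
    fp = fixed_point(params)
    jac = jacobian(fp, params)
    eig = np.linalg.eigvals(jac)
    max_re = float(np.max(eig.real))
    if max_re > _STABILITY_TOL:
        cls: Literal["stable", "unstable", "center/marginal"] = "unstable"
    elif max_re < -_STABILITY_TOL:
        cls = "stable"
    else:
        cls = "center/marginal"
    return StabilityReport(
        fixed_point=fp,
        jacobian=((float(jac[0, 0]), float(jac[0, 1])), (float(jac[1, 0]), float(jac[1, 1]))),
        jacobian_trace=float(np.trace(jac)),
        jacobian_determinant=float(np.linalg.det(jac)),
        eigenvalues=(complex(eig[0]), complex(eig[1])),
        classification=cls,
    )


def _simulate_rk4(params: ModelParams, init: CaState, n_steps: int, dt: float):
    """Fixed-step classical RK4 on the two-variable system (scalar math)."""
    p = params
    beta, alpha, gamma, n, delta, k, k1 = p.beta, p.alpha, p.gamma, p.n, p.delta, p.k, p.k1
    dn = delta**n

    def f(c: float, e: float) -> tuple[float, float]:
        cn = c**n
        exch = k * e - k1 * c + alpha * (cn / (dn + cn)) * e
        return exch + gamma - beta * c, -exch

    ca_i = np.empty(n_steps + 1)
    ca_er = np.empty(n_steps + 1)
    c, e = init.ca_i, init.ca_er
    ca_i[0], ca_er[0] = c, e
    half = dt / 2.0
    sixth = dt / 6.0
    for i in range(1, n_steps + 1):
        k1c, k1e = f(c, e)
        k2c, k2e = f(c + half * k1c, e + half * k1e)
        k3c, k3e = f(c + half * k2c, e + half * k2e)
        k4c, k4e = f(c + dt * k3c, e + dt * k3e)
        c = c + sixth * (k1c + 2.0 * k2c + 2.0 * k3c + k4c)
        e = e + sixth * (k1e + 2.0 * k2e + 2.0 * k3e + k4e)
        if not (math.isfinite(c) and math.isfinite(e)):
            raise IntegrationError(
                f"state became non-finite at t={i * dt:.6g} s (dt={dt} too large?)"
            )
        if c < -1e-9 or e < -1e-9:
            raise IntegrationError(
                f"state became negative at t={i * dt:.6g} s: ca_i={c:.3g}, ca_er={e:.3g}"
            )
        ca_i[i], ca_er[i] = c, e
    return ca_i, ca_er


def simulate(
    params: ModelParams,
    init: CaState = CaState(0.1, 5.0),
    duration: float = 300.0,
    dt: float = 1e-3,
    method: Literal["rk4_fixed", "adaptive"] = "rk4_fixed",
) -> Trajectory:
    """Integrate the model on a uniform time grid.

    ``rk4_fixed`` (default) is a classical fixed-step 4th-order Runge–Kutta —
    fully deterministic and accurate at the model's time scales.
    ``adaptive`` delegates to scipy's RK45 with tight tolerances and samples
    the dense output on the same grid.
    """
    if duration < 0:
        raise ValidationError(f"duration must be >= 0, got {duration}")
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    if n_steps == 0:
        return Trajectory(times, np.array([init.ca_i]), np.array([init.ca_er]), params, dt, method)
    if method == "rk4_fixed":
        ca_i, ca_er = _simulate_rk4(params, init, n_steps, dt)
    elif method == "adaptive":
        from scipy.integrate import solve_ivp

        def f(_t, y):
            d = rhs(CaState(max(y[0], 0.0), max(y[1], 0.0)), params)
            return [d[0], d[1]]

        sol = solve_ivp(
            f, (0.0, n_steps * dt), [init.ca_i, init.ca_er],
            t_eval=times, rtol=1e-9, atol=1e-12, method="RK45",
        )
        if not sol.success:
            raise IntegrationError(f"adaptive integration failed: {sol.message}")
        ca_i, ca_er = sol.y[0], sol.y[1]
    else:
        raise ValidationError(f"unknown integration method {method!r}")
    return Trajectory(times, ca_i, ca_er, params, dt, method)


#: Post-transient peak-to-trough range below which a trajectory is "steady".
STEADY_RANGE_TOL = 1e-4


def _post_transient(traj: Trajectory, transient_fraction: float):
    if not 0 <= transient_fraction < 1:
        raise ValidationError("transient_fraction must be in [0, 1)")
    start = int(len(traj.times) * transient_fraction)
    return traj.ca_i[start:]


def classify_trajectory(traj: Trajectory, transient_fraction: float = 0.5) -> str:
    """'oscillatory' or 'steady' from the post-transient peak-to-trough range."""
    x = _post_transient(traj, transient_fraction)
    return "steady" if float(x.max() - x.min()) < STEADY_RANGE_TOL else "oscillatory"


def cycle_average(traj: Trajectory, transient_fraction: float = 0.5) -> float:
    """Mean cytosolic calcium over an integer number of oscillation periods.

    Discards the leading ``transient_fraction`` of the trajectory.  If the
    remainder has settled (peak-to-trough < 1e−4 µM) the terminal plateau
    mean is returned; otherwise periods are delimited by upward crossings of
    the window mean and the average is taken between the first and last
    crossing.  For any attractor of this model the result equals γ/β, because
    the total-calcium balance d(ca_i+ca_er)/dt = γ − β·ca_i integrates to
    zero over a period.
    """
    x = _post_transient(traj, transient_fraction)
    if len(x) < 2:
        raise InsufficientDataError("post-transient window too short")
    if float(x.max() - x.min()) < STEADY_RANGE_TOL:
        return float(np.mean(x[int(0.9 * len(x)):]))
    level = float(np.mean(x))
    below = x[:-1] < level
    above = x[1:] >= level
    crossings = np.nonzero(below & above)[0]
    if len(crossings) < 3:
        raise InsufficientDataError(
            f"only {max(len(crossings) - 1, 0)} full periods in the post-transient window; "
            "need >= 2 (extend duration or reduce transient_fraction)"
        )
    return float(np.mean(x[crossings[0]: crossings[-1]]))


def condition_params(label: str) -> ConductivityCondition:
    """Parameter set for a conductivity condition ('low' | 'control' | 'high')."""
    try:
        gamma, beta = _CONDITION_GAMMA_BETA[label]
    except KeyError:
        raise ValidationError(
            f"unknown condition label {label!r}; expected one of {CONDITION_LABELS}"
        ) from None
    return ConductivityCondition(label, replace(CONTROL_PARAMS, gamma=gamma, beta=beta))


@dataclass(frozen=True)
class SimSettings:
    """Integration settings shared by sweeps and condition simulations."""

    init: CaState = CaState(0.1, 5.0)
    duration: float = 300.0
    dt: float = 1e-3
    method: str = "rk4_fixed"
    transient_fraction: float = 0.5


def sweep(
    beta_grid: Sequence[float],
    gamma_grid: Sequence[float],
    sim_settings: SimSettings = SimSettings(),
    base_params: ModelParams = CONTROL_PARAMS,
):
    """Simulate every (β, γ) grid point and tabulate classification and mean ca_i.

    Returns a pandas DataFrame with columns beta_per_s, gamma_uM_per_s,
    classification, mean_ca_i_uM.  Integration failures are re-raised with
    the offending grid point named.
    """
    import pandas as pd

    if len(beta_grid) == 0 or len(gamma_grid) == 0:
        raise ValidationError("beta_grid and gamma_grid must be nonempty")
    rows = []
    s = sim_settings
    for beta in beta_grid:
        for gamma in gamma_grid:
            params = replace(base_params, beta=float(beta), gamma=float(gamma))
            try:
                traj = simulate(params, s.init, s.duration, s.dt, s.method)
                rows.append(
                    {
                        "beta_per_s": float(beta),
                        "gamma_uM_per_s": float(gamma),
                        "classification": classify_trajectory(traj, s.transient_fraction),
                        "mean_ca_i_uM": cycle_average(traj, s.transient_fraction),
                    }
                )
            except (IntegrationError, InsufficientDataError) as exc:
                raise type(exc)(f"at grid point beta={beta}, gamma={gamma}: {exc}") from exc
    return pd.DataFrame(rows)


def sample_oscillatory_params(
    rng: np.random.Generator, n: int, max_tries: int = 1000
) -> list[ModelParams]:
    """Draw parameter sets in the oscillatory (unstable fixed point) regime.

    Samples multiplicative perturbations around the control set and keeps
    draws whose fixed point is linearly unstable.  Used for property tests of
    the cycle-average law.
    """
    out: list[ModelParams] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not find enough oscillatory parameter sets")
        f = rng.uniform(0.8, 1.25, size=5)
        p = ModelParams(
            beta=2.0 * f[0], alpha=1.3 * f[1], gamma=2.0 * f[2],
            n=4, delta=1.3 * f[3], k=0.01, k1=2.0 * f[4],
        )
        if stability(p).classification == "unstable":
            out.append(p)
    return out
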