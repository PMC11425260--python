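"""Ground-truthed synthetic calcium recordings.

Emulates 3-minute multi-cell Fluo-4 recordings for three substrate
conductivity conditions, in two modes:

* ``parametric`` — each cell is a deterministic pulse train (saturating
  exponential rise, exponential decay) whose baseline, amplitude, period and
  time constants are condition means scaled by per-cell lognormal jitter,
  plus Gaussian noise and optional linear bleaching.  The full per-cell
  ground truth is retained so featurizer recovery can be tested exactly.
* ``ode`` — each cell is an integration of the two-pool CICR model at that
  condition's (β, γ), with per-cell jitter on the rates, mapped to
  fluorescence by an affine gain and observed through the same noise model.

Condition effects follow the reported imaging phenotype: higher conductivity
raises amplitude and basal threshold and lengthens rise/decay, with no
frequency change.  Effect *magnitudes* are not reported anywhere, so the
defaults here (high vs low: amplitude ×1.5, threshold ×1.3, rise ×1.4,
decay ×1.4, frequency ×1.0; control at the geometric midpoint) are invented,
documented, and configurable.

What the generator does not emulate: focus drift, motion, ROI segmentation
error, indicator saturation — only additive Gaussian noise and linear
bleaching.  Tests passing on these traces validate the estimators'
correctness, not their robustness to every imaging artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from .errors import ValidationError
from .features import Trace
from .model import CONDITION_LABELS, condition_params, simulate, CaState, ModelParams

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "CellCohort",
    "DEFAULT_CONDITION_EFFECTS",
    "make_pulse_trace",
    "add_noise",
    "generate_cohort",
    "render_clean",
]

_FEATURE_KEYS = ("amplitude", "threshold", "rise_time", "decay_time", "frequency")

#: Invented default effect multipliers (relative to the 'low' condition).
DEFAULT_CONDITION_EFFECTS: dict[str, dict[str, float]] = {
    "low": {"amplitude": 1.0, "threshold": 1.0, "rise_time": 1.0, "decay_time": 1.0, "frequency": 1.0},
    "control": {
        "amplitude": math.sqrt(1.5),
        "threshold": math.sqrt(1.3),
        "rise_time": math.sqrt(1.4),
        "decay_time": math.sqrt(1.4),
        "frequency": 1.0,
    },
    "high": {"amplitude": 1.5, "threshold": 1.3, "rise_time": 1.4, "decay_time": 1.4, "frequency": 1.0},
}

#: Factor by which the saturating rise must approach its ceiling before the
#: kernel switches to decay; exp(-7) keeps the peak within 0.1% of
#: baseline + amplitude.
RISE_SPAN_TAUS = 7.0

#: 10–90% rise (and 90–10% decay) duration per unit time constant for the
#: exponential kernels: ln(0.9/0.1) ≈ 2.1972.
TEN_NINETY_FACTOR = math.log(9.0)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for cohort generation.

    Defaults encode the emulated experiment: 3-minute recordings sampled at
    20 Hz, 30 cells per condition, resting fluorescence 1.0 with transients
    of amplitude 2.0 every ~30 s (rise τ 1 s, decay τ 3 s), per-cell
    lognormal parameter jitter of CV 0.15, and Gaussian observation noise of
    SD 0.2 (amplitude SNR 10 in the low condition).
    """

    n_cells_per_condition: int = 30
    conditions: tuple[str, ...] = CONDITION_LABELS
    duration: float = 180.0
    dt: float = 0.05
    baseline: float = 1.0
    amplitude: float = 2.0
    period: float = 30.0
    rise_tau: float = 1.0
    decay_tau: float = 3.0
    condition_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {c: dict(m) for c, m in DEFAULT_CONDITION_EFFECTS.items()}
    )
    cell_variability: float = 0.15
    noise_sd: float = 0.2
    bleach_rate: float = 0.0
    gain: float = 1.0  # ode mode: fluorescence units per µM
    offset: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_cells_per_condition < 1:
            raise ValidationError("n_cells_per_condition must be >= 1")
        if self.duration <= 0 or self.dt <= 0:
            raise ValidationError("duration and dt must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.cell_variability < 0:
            raise ValidationError("cell_variability must be >= 0")
        if not 0 <= self.bleach_rate * self.duration < 1:
            raise ValidationError("bleach_rate * duration must lie in [0, 1)")
        for cond in self.conditions:
            effects = self.condition_effects.get(cond)
            if effects is None:
                raise ValidationError(f"condition_effects missing condition {cond!r}")
            for key in _FEATURE_KEYS:
                if effects.get(key, 1.0) <= 0:
                    raise ValidationError(f"multiplier {key} for {cond!r} must be > 0")

    def to_dict(self) -> dict:
        return {
            "n_cells_per_condition": self.n_cells_per_condition,
            "conditions": list(self.conditions),
            "duration_s": self.duration,
            "dt_s": self.dt,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "period_s": self.period,
            "rise_tau_s": self.rise_tau,
            "decay_tau_s": self.decay_tau,
            "condition_effects": {c: dict(m) for c, m in self.condition_effects.items()},
            "cell_variability": self.cell_variability,
            "noise_sd": self.noise_sd,
            "bleach_rate_per_s": self.bleach_rate,
            "gain": self.gain,
            "offset": self.offset,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Generative parameters of one cell; fully determines its clean trace."""

    cell_id: str
    condition: str
    mode: str
    baseline: float
    amplitude: float
    period: float
    rise_tau: float
    decay_tau: float
    event_times: tuple[float, ...]
    seed: int
    ode_params: Optional[ModelParams] = None

    @property
    def n_events(self) -> int:
        return len(self.event_times)

    @property
    def rise_time_10_90(self) -> float:
        return TEN_NINETY_FACTOR * self.rise_tau

    @property
    def decay_time_90_10(self) -> float:
        return TEN_NINETY_FACTOR * self.decay_tau

    def to_dict(self) -> dict:
        d = {
            "cell_id": self.cell_id,
            "condition": self.condition,
            "mode": self.mode,
            "baseline": self.baseline,
            "amplitude": self.amplitude,
            "period_s": self.period,
            "rise_tau_s": self.rise_tau,
            "decay_tau_s": self.decay_tau,
            "event_times_s": list(self.event_times),
            "seed": self.seed,
        }
        if self.ode_params is not None:
            d["ode_params"] = self.ode_params.to_dict()
        return d


@dataclass(frozen=True)
class CellCohort:
    """Labeled multi-condition trace collection with its generative truth."""

    traces: list[Trace]
    ground_truth: list[GroundTruth]
    config: GeneratorConfig

    def __post_init__(self) -> None:
        if len(self.traces) != len(self.ground_truth):
            raise ValidationError("traces and ground_truth must have equal length")

    def __len__(self) -> int:
        return len(self.traces)

    def by_condition(self, condition: str) -> list[Trace]:
        return [tr for tr in self.traces if tr.condition == condition]


def _pulse_values(
    times: np.ndarray,
    baseline: float,
    amplitude: float,
    event_times: np.ndarray,
    rise_tau: float,
    decay_tau: float,
) -> np.ndarray:
    """Render a clean pulse train (vectorized over samples)."""
    v = np.full_like(times, baseline, dtype=float)
    rise_span = RISE_SPAN_TAUS * rise_tau
    for t0 in event_times:
        peak_t = t0 + rise_span
        rise_mask = (times >= t0) & (times < peak_t)
        v[rise_mask] = baseline + amplitude * (1.0 - np.exp(-(times[rise_mask] - t0) / rise_tau))
        decay_mask = times >= peak_t
        # decay replaces the tail until the next event overwrites it
        peak_amp = amplitude * (1.0 - math.exp(-RISE_SPAN_TAUS))
        v[decay_mask] = baseline + peak_amp * np.exp(-(times[decay_mask] - peak_t) / decay_tau)
    return v


def _event_times(duration: float, period: float, rise_tau: float, t_first: Optional[float]) -> np.ndarray:
    """Onset times whose peaks fall inside the record; default start period/2."""
    if t_first is None:
        t_first = period / 2.0
    rise_span = RISE_SPAN_TAUS * rise_tau
    onsets = np.arange(t_first, duration, period)
    return onsets[onsets + rise_span < duration]


def make_pulse_trace(
    baseline: float,
    amplitude: float,
    period: float,
    rise_tau: float,
    decay_tau: float,
    duration: float,
    dt: float,
    t_first: Optional[float] = None,
    cell_id: str = "cell",
    condition: Optional[str] = None,
) -> tuple[Trace, np.ndarray]:
    """Deterministic pulse-train trace; returns (trace, event onset times).

    Each event rises toward baseline+amplitude with time constant
    ``rise_tau`` (for 7 time constants, so peaks are within 0.1% of the
    ceiling) then decays exponentially with ``decay_tau``.  With the default
    start offset of period/2, the event count is floor(duration/period).
    """
    for name, val in (("baseline", baseline), ("amplitude", amplitude), ("period", period),
                      ("rise_tau", rise_tau), ("decay_tau", decay_tau),
                      ("duration", duration), ("dt", dt)):
        if val <= 0:
            raise ValidationError(f"{name} must be > 0, got {val}")
    if period <= rise_tau + decay_tau:
        raise ValidationError(
            f"period ({period} s) must exceed rise_tau + decay_tau "
            f"({rise_tau + decay_tau} s); kernels would overlap"
        )
    n = int(round(duration / dt))
    times = np.arange(n + 1) * dt
    events = _event_times(duration, period, rise_tau, t_first)
    values = _pulse_values(times, baseline, amplitude, events, rise_tau, decay_tau)
    return Trace(times, values, cell_id=cell_id, condition=condition), events


def add_noise(
    trace: Trace, noise_sd: float, bleach_rate: float = 0.0, seed: int = 0
) -> Trace:
    """Observation model: value·(1 − bleach_rate·t) + Gaussian(0, noise_sd).

    Deterministic for a fixed seed; ``noise_sd=0, bleach_rate=0`` is the
    identity.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    t_end = trace.times[-1]
    if not 0 <= bleach_rate * t_end < 1:
        raise ValidationError("bleach_rate * duration must lie in [0, 1)")
    values = trace.values * (1.0 - bleach_rate * trace.times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return replace(trace, values=values)


def render_clean(gt: GroundTruth, config: GeneratorConfig) -> Trace:
    """Re-render the noiseless trace from its ground truth (parametric mode)."""
    if gt.mode != "parametric":
        raise ValidationError("render_clean supports parametric ground truth only")
    n = int(round(config.duration / config.dt))
    times = np.arange(n + 1) * config.dt
    values = _pulse_values(
        times, gt.baseline, gt.amplitude, np.asarray(gt.event_times), gt.rise_tau, gt.decay_tau
    )
    return Trace(times, values, cell_id=gt.cell_id, condition=gt.condition)


def _lognormal_jitter(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 lognormal multipliers with coefficient of variation ``cv``."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_cohort(
    config: GeneratorConfig, mode: Literal["parametric", "ode"] = "parametric"
) -> CellCohort:
    """Generate a labeled multi-condition cohort with full ground truth.

    Per-cell parameters are condition means × independent mean-1 lognormal
    jitter (CV = ``cell_variability``); each cell's pulse train starts at a
    random phase within one period.  Reproducible from ``config.seed``
    (mandatory).  In ``ode`` mode the parametric effect multipliers are
    ignored: each condition uses its conductivity parameter set, jittered
    per cell, integrated and mapped to fluorescence by ``gain``/``offset``.
    """
    if config.seed is None:
        raise ValidationError("GeneratorConfig.seed is mandatory for cohort generation")
    rng = np.random.default_rng(config.seed)
    traces: list[Trace] = []
    truths: list[GroundTruth] = []
    for cond in config.conditions:
        effects = {k: config.condition_effects[cond].get(k, 1.0) for k in _FEATURE_KEYS}
        for j in range(config.n_cells_per_condition):
            cell_id = f"{cond}_{j:03d}"
            cell_seed = int(rng.integers(0, 2**31 - 1))
            if mode == "parametric":
                jit = _lognormal_jitter(rng, config.cell_variability, 5)
                baseline = config.baseline * effects["threshold"] * jit[0]
                amplitude = config.amplitude * effects["amplitude"] * jit[1]
                period = config.period / effects["frequency"] * jit[2]
                rise_tau = config.rise_tau * effects["rise_time"] * jit[3]
                decay_tau = config.decay_tau * effects["decay_time"] * jit[4]
                t_first = float(rng.uniform(0.25, 0.75) * period)
                clean, events = make_pulse_trace(
                    baseline, amplitude, period, rise_tau, decay_tau,
                    config.duration, config.dt, t_first=t_first,
                    cell_id=cell_id, condition=cond,
                )
                truths.append(
                    GroundTruth(
                        cell_id=cell_id, condition=cond, mode="parametric",
                        baseline=baseline, amplitude=amplitude, period=period,
                        rise_tau=rise_tau, decay_tau=decay_tau,
                        event_times=tuple(float(x) for x in events), seed=cell_seed,
                    )
                )
            elif mode == "ode":
                jit = _lognormal_jitter(rng, config.cell_variability, 2)
                base = condition_params(cond).params
                params = replace(base, gamma=base.gamma * jit[0], beta=base.beta * jit[1])
                traj = simulate(params, CaState(0.1, 5.0), config.duration, dt=1e-3)
                stride = max(int(round(config.dt / 1e-3)), 1)
                times = traj.times[::stride]
                values = config.gain * traj.ca_i[::stride] + config.offset
                clean = Trace(times, values, cell_id=cell_id, condition=cond)
                truths.append(
                    GroundTruth(
                        cell_id=cell_id, condition=cond, mode="ode",
                        baseline=float(values.min()), amplitude=float(values.max() - values.min()),
                        period=float("nan"), rise_tau=float("nan"), decay_tau=float("nan"),
                        event_times=(), seed=cell_seed, ode_params=params,
                    )
                )
            else:
                raise ValidationError(f"unknown cohort mode {mode!r}")
            traces.append(
                add_noise(clean, config.noise_sd, config.bleach_rate, seed=cell_seed)
            )
    return CellCohort(traces=traces, ground_truth=truths, config=config)
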