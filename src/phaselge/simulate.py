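"""Longitudinal-magnetization simulation of the pulsed Look-Locker FLASH
experiment and phase-resolved multi-TI stack generation.

The simulator is purely longitudinal (ideal spoiling, no T2*/off-resonance):
between pulses ``Mz -> M0 + (Mz - M0) exp(-dt/T1)``, each FLASH pulse emits
``Mz sin(a)`` and leaves ``Mz cos(a)``, and the adiabatic inversion maps
``Mz -> -eff * Mz``.  Excitation pulses are contiguous at TR throughout
(dummy pulses fill the inter-window gaps), with the pulse grid anchored at
the inversion: the inversion fires in the slot of a regular FLASH pulse,
immediately after it, so every readout falls an integer number of TRs after
the inversion.  Planned sample times are realized at the nearest grid slot
and the stack's TI table records the realized times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import PhantomSpec, PhantomConfigError, TissueCompartment
from .timing import AcquisitionPlan, CardiacTiming, InvalidParameterError, SequenceParams

__all__ = [
    "pulsed_steady_state",
    "apparent_t1",
    "simulate_pulse_train",
    "PulseTrain",
    "MultiTIStack",
    "generate_stack",
    "noise_cov_simulation",
]


def pulsed_steady_state(
    t1_ms: float, flip_deg: float, tr_ms: float, m0: float = 1.0
) -> float:
    """Longitudinal magnetization just before a pulse in the pulsed steady
    state of a spoiled FLASH train: ``m0 (1 - E1) / (1 - E1 cos a)``."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise InvalidParameterError("t1_ms and tr_ms must be > 0")
    if not (0 <= flip_deg < 90):
        raise InvalidParameterError("flip_deg must be in [0, 90)")
    e1 = math.exp(-tr_ms / t1_ms)
    a = math.radians(flip_deg)
    return m0 * (1.0 - e1) / (1.0 - e1 * math.cos(a))


def apparent_t1(t1_ms: float, flip_deg: float, tr_ms: float) -> float:
    """Apparent relaxation time of the pulsed recovery,
    ``1/T1* = 1/T1 - ln(cos a)/TR``; equals T1 at zero flip angle."""
    if t1_ms <= 0 or tr_ms <= 0:
        raise InvalidParameterError("t1_ms and tr_ms must be > 0")
    if not (0 <= flip_deg < 90):
        raise InvalidParameterError("flip_deg must be in [0, 90)")
    a = math.radians(flip_deg)
    return 1.0 / (1.0 / t1_ms - math.log(math.cos(a)) / tr_ms)


@dataclass
class PulseTrain:
    """Readout samples of one inversion-recovery epoch on the TR grid.

    ``ti_ms[k] = (k+1) * TR`` holds the inversion time of each readout after
    the inversion, ``signal`` the signed readout signal (``Mz sin a``).
    """

    ti_ms: np.ndarray
    signal: np.ndarray
    tr_ms: float
    steady_state_signal: float
    settle_pulses: int

    def sample_plan(self, plan: AcquisitionPlan) -> tuple[np.ndarray, np.ndarray]:
        """Signed signals and realized TIs for every planned sample.

        Each planned TI is realized at the nearest pulse slot (at least one
        TR after the inversion).  Returns ``(signals, realized_ti)`` shaped
        ``(n_phases, n_ti)``.
        """
        n = np.rint(plan.ti_ms / self.tr_ms).astype(int)
        n = np.clip(n, 1, None)
        if n.max() > self.ti_ms.size:
            raise ValueError("pulse train shorter than the planned recovery")
        realized = n * self.tr_ms
        if np.any(np.diff(realized, axis=1) <= 0):
            raise ValueError(
                "planned TIs collapse onto the same pulse slot; "
                "offsets closer than one TR are not supported"
            )
        return self.signal[n - 1], realized


def simulate_pulse_train(
    compartment: TissueCompartment,
    params: SequenceParams,
    timing: CardiacTiming,
    plan: AcquisitionPlan,
) -> PulseTrain:
    """Event-by-event simulation of one Look-Locker epoch for a compartment.

    The magnetization is first driven to the pulsed steady state by a
    contiguous FLASH train (iterated to numerical convergence), then a pulse
    plus inversion fires, and readouts are recorded every TR until the
    longest planned inversion time is covered.
    """
    tr = params.tr_ms
    a = math.radians(params.flip_deg)
    sin_a, cos_a = math.sin(a), math.cos(a)
    m0 = compartment.proton_density
    e1 = math.exp(-tr / compartment.t1_ms)

    def relax(mz: float) -> float:
        return m0 + (mz - m0) * e1

    # Drive to pulsed steady state from thermal equilibrium.
    mz = m0
    settle = 0
    max_settle = max(1000, int(20 * compartment.t1_ms / tr))
    while settle < max_settle:
        prev = mz
        mz = relax(mz * cos_a)
        settle += 1
        if abs(mz - prev) < 1e-15 * m0:
            break
    ss_signal = mz * sin_a

    # Inversion slot: regular pulse, immediately followed by the inversion.
    mz = mz * cos_a
    mz = -params.inv_efficiency * mz

    max_ti = float(plan.ti_ms.max())
    n_readouts = int(math.ceil(max_ti / tr)) + 2
    ti = np.arange(1, n_readouts + 1) * tr
    signal = np.empty(n_readouts)
    for k in range(n_readouts):
        mz = relax(mz)
        signal[k] = mz * sin_a
        mz = mz * cos_a

    return PulseTrain(
        ti_ms=ti,
        signal=signal,
        tr_ms=tr,
        steady_state_signal=ss_signal,
        settle_pulses=settle,
    )


@dataclass
class MultiTIStack:
    """Phase-resolved, TI-indexed magnitude image stack.

    ``data`` is indexed ``[phase, ti_index, row, col]``; ``ti_ms`` holds the
    matching per-phase inversion times (strictly increasing).
    """

    data: np.ndarray
    ti_ms: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        self.ti_ms = np.asarray(self.ti_ms, float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D [phase, ti, row, col]")
        if self.ti_ms.shape != self.data.shape[:2]:
            raise ValueError("ti_ms shape must match data [phase, ti]")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if np.any(np.diff(self.ti_ms, axis=1) <= 0):
            raise ValueError("TIs must be strictly increasing per phase")

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]

    @property
    def n_ti(self) -> int:
        return self.data.shape[1]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]


def resolve_noise_sd(spec: PhantomSpec, params: SequenceParams) -> float:
    """Noise standard deviation in signal units.

    With ``baseline_snr`` the SD is the pulsed-steady-state readout signal of
    the reference compartment divided by the SNR, so that by construction
    (steady-state signal)/(noise SD) equals the requested SNR.
    """
    if spec.baseline_snr is None:
        return float(spec.noise_sd)
    ref = spec.compartment(spec.snr_reference)
    ss = pulsed_steady_state(
        ref.t1_ms, params.flip_deg, params.tr_ms, ref.proton_density
    )
    return ss * math.sin(math.radians(params.flip_deg)) / spec.baseline_snr


def compartment_signals(
    spec: PhantomSpec,
    params: SequenceParams,
    timing: CardiacTiming,
    plan: AcquisitionPlan,
) -> tuple[np.ndarray, np.ndarray]:
    """Signed per-compartment plan samples.

    Returns ``(signals, realized_ti)`` with ``signals`` shaped
    ``(n_compartments, n_phases, n_ti)``.
    """
    sigs = []
    realized = None
    for comp in spec.compartments:
        train = simulate_pulse_train(comp, params, timing, plan)
        s, ti = train.sample_plan(plan)
        sigs.append(s)
        realized = ti
    return np.stack(sigs), realized


def generate_stack(
    spec: PhantomSpec,
    params: SequenceParams,
    timing: CardiacTiming,
    plan: AcquisitionPlan,
    n_repetitions: int = 1,
    seed: int | None = None,
) -> list[MultiTIStack]:
    """Assemble phase-resolved multi-TI magnitude stacks from a phantom.

    Voxels take the signal of their compartment; zero-mean Gaussian noise is
    added to the signed signal and the magnitude is taken (Rician-type).
    Repetitions differ only in their noise draws.  A seed is mandatory
    whenever noise is present.
    """
    sd = resolve_noise_sd(spec, params)
    if sd > 0 and seed is None:
        raise PhantomConfigError("seed is mandatory when noise is present")
    rng = np.random.default_rng(seed)

    sigs, realized_ti = compartment_signals(spec, params, timing, plan)
    n_p, n_t = realized_ti.shape
    h, w = spec.shape

    clean = np.zeros((n_p, n_t, h, w))
    for p in range(n_p):
        lm = spec.label_map_for_phase(p, n_p)
        for c in range(len(spec.compartments)):
            m = lm == c + 1
            if m.any():
                clean[p, :, m] = sigs[c, p]

    meta = {
        "tr_ms": params.tr_ms,
        "flip_deg": params.flip_deg,
        "rr_ms": list(timing.rr_ms),
        "phase_duration_ms": timing.phase_duration_ms,
        "noise_sd": sd,
        "n_repetitions": n_repetitions,
        "seed": seed,
    }
    stacks = []
    for _ in range(n_repetitions):
        noisy = clean if sd == 0 else clean + rng.normal(0.0, sd, clean.shape)
        stacks.append(MultiTIStack(np.abs(noisy), realized_ti.copy(), dict(meta)))
    return stacks


def noise_cov_simulation(
    t1_ms: float,
    params: SequenceParams,
    timing: CardiacTiming,
    plan: AcquisitionPlan,
    snr: float = 20.0,
    n_repetitions: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Per-phase coefficient of variation (%) of the fitted T1* under noise.

    Single-compartment noisy simulation: Gaussian noise at the requested
    baseline SNR is added to the signed plan samples, the magnitude is
    taken, polarity is restored and the two-parameter model fitted; the CoV
    of T1* over the repetitions is returned per cardiac phase.
    """
    from .fitting import fit_magnitude

    comp = TissueCompartment("sim", t1_ms)
    train = simulate_pulse_train(comp, params, timing, plan)
    signed, realized_ti = train.sample_plan(plan)
    sd = train.steady_state_signal / snr
    rng = np.random.default_rng(seed)

    n_p = realized_ti.shape[0]
    t1s = np.empty((n_repetitions, n_p))
    for r in range(n_repetitions):
        noisy = np.abs(signed + rng.normal(0.0, sd, signed.shape))
        for p in range(n_p):
            fit = fit_magnitude(realized_ti[p], noisy[p])
            t1s[r, p] = fit.t1_star_ms
    return 100.0 * t1s.std(axis=0, ddof=1) / t1s.mean(axis=0)
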