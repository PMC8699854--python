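"""Two-spin (1H-15N) density-matrix propagation under MAS and RF recoupling.

The spin system is an isolated I=1/2 (1H), S=1/2 (15N) pair.  The rotating
frame Hamiltonian during a recoupling sequence is

    H(t)/2pi = d(t) * 2 Iz Sz + nu1(t) * (Ix cos phi + Iy sin phi)
               + off_I * Iz + off_S * Sz,

with the MAS-modulated secular dipolar frequency (axially symmetric tensor,
crystallite polar angles beta, gamma relative to the rotor axis)

    d(t) = d * [ sqrt(2) sin(beta) cos(beta) cos(w_r t + gamma)
                 + (1/2) sin^2(beta) cos(2 w_r t + 2 gamma) ],

where d is the dipolar coupling constant in Hz (the full splitting-defining
constant: 11,477.3 Hz at a 1.02 A N-H distance).  RF is applied on the 1H
channel only, so [H, Sz] = 0 and the 4x4 propagator factorizes into exact
2x2 blocks for Sz = +/- 1/2 -- each integration step is a closed-form SU(2)
rotation, no matrix exponentials needed.

Starting from transverse 15N magnetization, the 15N observable is sampled
stroboscopically once per symmetry cycle (n rotor periods), mirroring the
constant-time dipolar dimension of the experiment.  The scaling factor kappa
is the positive-frequency maximum of the trajectory's magnitude spectrum
divided by the input coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .elements import PulseSchedule, get_element
from .symmetry import CandidateRecord, SymmetrySpec, allowed_terms, classify_correlation, \
    is_gamma_encoded, kp as element_kp, match_field, phase_schedule


class ScheduleError(ValueError):
    """Schedule incommensurate with the rotor period or otherwise unusable."""


@dataclass(frozen=True)
class SpinSystem:
    """Isolated 1H-15N pair.  d_coupling in Hz; offsets in Hz (carrier frame)."""

    d_coupling: float = 10e3
    offset_i: float = 0.0
    offset_s: float = 0.0

    def __post_init__(self):
        if self.d_coupling < 0:
            raise ValueError("d_coupling must be >= 0")


@dataclass(frozen=True)
class Orientation:
    """Crystallite Euler angles (deg) taking the dipolar PAS to the rotor frame."""

    alpha: float = 0.0
    beta: float = 90.0
    gamma: float = 0.0
    weight: float = 1.0


#: the simulation default: the orientation maximizing the |m|=2 dipolar
#: component that the candidate sequences recouple.
SINGLE_CRYSTAL = Orientation(alpha=0.0, beta=90.0, gamma=0.0, weight=1.0)


def powder_orientations(n_orient: int = 376, n_gamma: int = 16) -> list[Orientation]:
    """ZCW-style quasi-uniform powder set with an explicit gamma grid.

    (alpha, beta) follow a golden-ratio spiral over the hemisphere (uniform in
    cos(beta)); each is replicated over ``n_gamma`` evenly spaced gamma
    angles.  Equal weights summing to 1.
    """
    if n_orient < 1 or n_gamma < 1:
        raise ValueError("n_orient and n_gamma must be >= 1")
    golden = (1 + 5**0.5) / 2
    out = []
    w = 1.0 / (n_orient * n_gamma)
    for j in range(n_orient):
        alpha = math.degrees(2 * math.pi * ((j / golden) % 1.0))
        beta = math.degrees(math.acos((j + 0.5) / n_orient))
        for g in range(n_gamma):
            out.append(Orientation(alpha, beta, 360.0 * g / n_gamma, w))
    return out


@dataclass(frozen=True)
class Trajectory:
    """Rotor-synchronized dipolar evolution; first point normalized to 1."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-15):
            raise ValueError("trajectory times must be uniform")

    @property
    def dwell(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class Spectrum:
    freqs: np.ndarray
    amplitudes: np.ndarray


@dataclass(frozen=True)
class EfficiencyCurve:
    """kappa versus applied field (and the back-calculated flip angle)."""

    fields: np.ndarray
    theta: np.ndarray
    kappas: np.ndarray


def _substeps(schedule: PulseSchedule, omega_r: float, points_per_rotor: int):
    """Split the schedule into integration steps of <= tau_r/points_per_rotor.

    Returns (t_mid, dt, amp, phase_rad) arrays over one cycle.
    """
    tau_r = 1.0 / omega_r
    n_per = schedule.total_duration * omega_r
    if abs(n_per - round(n_per)) > 1e-6:
        raise ScheduleError(
            f"schedule duration {schedule.total_duration} is not an integer "
            f"number of rotor periods at omega_r={omega_r}"
        )
    target = tau_r / points_per_rotor
    t0 = 0.0
    t_mid, dts, amps, phis = [], [], [], []
    for seg in schedule.segments:
        k = max(1, math.ceil(seg.duration / target - 1e-12))
        dt = seg.duration / k
        mids = t0 + dt * (np.arange(k) + 0.5)
        t_mid.append(mids)
        dts.append(np.full(k, dt))
        amps.append(np.full(k, seg.rf_amplitude))
        phis.append(np.full(k, math.radians(seg.rf_phase)))
        t0 += seg.duration
    gap = schedule.total_duration - t0
    if gap > 1e-15 * schedule.total_duration:  # free evolution tail
        k = max(1, math.ceil(gap / target))
        dt = gap / k
        mids = t0 + dt * (np.arange(k) + 0.5)
        t_mid.append(mids)
        dts.append(np.full(k, dt))
        amps.append(np.zeros(k))
        phis.append(np.zeros(k))
    return (np.concatenate(t_mid), np.concatenate(dts),
            np.concatenate(amps), np.concatenate(phis))


def _dipolar_timecourse(d, beta_deg, gamma_deg, omega_r, t):
    """d(t) in Hz at times t for crystallites (beta, gamma); broadcastable.

    ``d``, ``beta_deg``, ``gamma_deg`` may be arrays of a common batch shape
    B; result has shape B + t.shape.
    """
    d = np.asarray(d, dtype=float)[..., None]
    beta = np.deg2rad(np.asarray(beta_deg, dtype=float))[..., None]
    gamma = np.deg2rad(np.asarray(gamma_deg, dtype=float))[..., None]
    wt = 2 * np.pi * omega_r * t
    return d * (
        math.sqrt(2) * np.sin(beta) * np.cos(beta) * np.cos(wt + gamma)
        + 0.5 * np.sin(beta) ** 2 * np.cos(2 * wt + 2 * gamma)
    )


def _tree_product(a, b, c, d):
    """Time-ordered product of 2x2 matrices [[a, b], [c, d]] along the last
    axis (last element applied last), by pairwise tree reduction.

    Working on four component arrays instead of a (..., K, 2, 2) stack keeps
    every operation contiguous, which is what makes large powder x coupling
    batches affordable.
    """
    while a.shape[-1] > 1:
        tail = None
        if a.shape[-1] % 2:
            tail = (a[..., -1:], b[..., -1:], c[..., -1:], d[..., -1:])
            a, b, c, d = a[..., :-1], b[..., :-1], c[..., :-1], d[..., :-1]
        a1, b1, c1, d1 = a[..., 0::2], b[..., 0::2], c[..., 0::2], d[..., 0::2]
        a2, b2, c2, d2 = a[..., 1::2], b[..., 1::2], c[..., 1::2], d[..., 1::2]
        a, b, c, d = (a2 * a1 + b2 * c1, a2 * b1 + b2 * d1,
                      c2 * a1 + d2 * c1, c2 * b1 + d2 * d1)
        if tail is not None:
            a = np.concatenate([a, tail[0]], -1)
            b = np.concatenate([b, tail[1]], -1)
            c = np.concatenate([c, tail[2]], -1)
            d = np.concatenate([d, tail[3]], -1)
    return a[..., 0], b[..., 0], c[..., 0], d[..., 0]


def _cycle_propagators(schedule, system, omega_r, points_per_rotor,
                       d_batch, beta_batch, gamma_batch):
    """Exact SU(2) cycle propagators U+ and U- for a batch of crystallites.

    Returns arrays of shape B + (2, 2).  U+- propagate the 1H spin within
    the Sz = +/- 1/2 blocks (possible because RF acts on 1H only, so
    [H, Sz] = 0); the scalar 15N offset phase is folded into U+-.  Each
    integration step is a closed-form SU(2) rotation about the
    piecewise-constant effective field, evaluated at the step midpoint.
    """
    t_mid, dt, amp, phi = _substeps(schedule, omega_r, points_per_rotor)
    dtc = _dipolar_timecourse(d_batch, beta_batch, gamma_batch, omega_r, t_mid)
    batch_shape = dtc.shape[:-1]
    hx = amp * np.cos(phi)
    hy = amp * np.sin(phi)
    out = []
    for s in (+0.5, -0.5):
        hz = 2 * s * dtc + system.offset_i  # B x K
        hnorm = np.sqrt(hx**2 + hy**2 + hz**2)
        half = np.pi * dt * hnorm  # rotation half-angle per step
        with np.errstate(invalid="ignore", divide="ignore"):
            inv = np.where(hnorm > 0, 1.0 / hnorm, 0.0)
        cos_h = np.cos(half)
        sn = np.sin(half)
        scal = np.exp(-1j * 2 * np.pi * system.offset_s * s * dt)
        snz = sn * hz * inv
        snxy = sn * inv * (hx - 1j * hy)
        # step propagators scal * (cos*1 - i*sin*(n.sigma)) as components
        pa, pb, pc, pd = _tree_product(
            scal * (cos_h - 1j * snz),
            scal * (-1j * snxy),
            scal * (-1j * np.conj(snxy)),
            scal * (cos_h + 1j * snz),
        )
        U = np.empty(batch_shape + (2, 2), dtype=complex)
        U[..., 0, 0], U[..., 0, 1] = pa, pb
        U[..., 1, 0], U[..., 1, 1] = pc, pd
        out.append(U)
    return out[0], out[1]


def _trajectory_from_blocks(Up, Um, n_points):
    """<Sx>(k cycles)/<Sx>(0) from the block propagators; batched."""
    A = np.broadcast_to(np.eye(2, dtype=complex), Up.shape).copy()
    sig = np.empty(Up.shape[:-2] + (n_points,))
    Umh = np.conj(np.swapaxes(Um, -1, -2))
    for k in range(n_points):
        sig[..., k] = 0.5 * np.real(np.trace(A, axis1=-2, axis2=-1))
        A = Up @ A @ Umh
    return sig


def propagate(
    schedule: PulseSchedule,
    system: SpinSystem,
    orient: Orientation = SINGLE_CRYSTAL,
    omega_r: float = 60e3,
    n_points: int = 128,
    points_per_rotor: int = 720,
) -> Trajectory:
    """Stroboscopic 15N transverse trajectory under repeated application of
    ``schedule`` (one symmetry cycle), for a single crystallite.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    Up, Um = _cycle_propagators(
        schedule, system, omega_r, points_per_rotor,
        np.array(system.d_coupling), np.array(orient.beta), np.array(orient.gamma),
    )
    sig = _trajectory_from_blocks(Up[None], Um[None], n_points)[0]
    times = np.arange(n_points) * schedule.total_duration
    return Trajectory(times=times, intensities=sig / sig[0] if sig[0] != 0 else sig)


def powder_trajectory(
    schedule, system, orientations, omega_r=60e3, n_points=15, points_per_rotor=360
) -> Trajectory:
    """Weight-averaged trajectory over a crystallite set, first point 1."""
    d = np.full(len(orientations), system.d_coupling)
    beta = np.array([o.beta for o in orientations])
    gamma = np.array([o.gamma for o in orientations])
    w = np.array([o.weight for o in orientations])
    Up, Um = _cycle_propagators(schedule, system, omega_r, points_per_rotor, d, beta, gamma)
    sig = _trajectory_from_blocks(Up, Um, n_points)
    avg = (w / w.sum()) @ sig
    times = np.arange(n_points) * schedule.total_duration
    return Trajectory(times=times, intensities=avg / avg[0])


def spectrum(traj: Trajectory, zero_fill: int = 128) -> Spectrum:
    """Magnitude spectrum of the real trajectory after zero-filling.

    The imaginary part is filled with zeros and the record extended to
    ``zero_fill`` points, as in the experimental processing.
    """
    n = len(traj.intensities)
    if zero_fill < n:
        raise ValueError(f"zero_fill={zero_fill} < trajectory length {n}")
    data = np.zeros(zero_fill, dtype=complex)
    data[:n] = traj.intensities
    amps = np.abs(np.fft.fftshift(np.fft.fft(data)))
    freqs = np.fft.fftshift(np.fft.fftfreq(zero_fill, d=traj.dwell))
    return Spectrum(freqs=freqs, amplitudes=amps)


def _peak_frequency(traj: Trajectory, zero_fill_factor: int = 32) -> float:
    """Positive-frequency magnitude maximum with parabolic sub-bin refinement.

    The trajectory mean is removed first: the un-recoupled fraction of the
    polarization shows up as a zero-frequency component that would otherwise
    dominate the magnitude spectrum.
    """
    y = traj.intensities - traj.intensities.mean()
    if np.max(np.abs(y)) < 1e-9:  # nothing recoupled
        return 0.0
    nfft = zero_fill_factor * len(y)
    spec = np.abs(np.fft.rfft(y, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=traj.dwell)
    i = int(np.argmax(spec))
    if 0 < i < len(spec) - 1:  # parabolic interpolation on the magnitude
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if denom != 0 else 0.0
        return float(freqs[i] + shift * (freqs[1] - freqs[0]))
    return float(freqs[i])


def scaling_factor(
    spec: SymmetrySpec,
    element="pi",
    theta: float = 0.0,
    omega_r: float = 60e3,
    system: SpinSystem = SpinSystem(),
    orient: Orientation = SINGLE_CRYSTAL,
    n_cycles: int = 256,
    points_per_rotor: int = 720,
) -> float:
    """Recoupling scaling factor kappa = recoupled splitting / dipolar coupling.

    Single-crystal two-spin simulation at the element's matched field.  The
    stroboscopic 15N trajectory oscillates at half the recoupled doublet
    splitting, so kappa is twice the positive-frequency maximum of its
    (mean-subtracted) magnitude spectrum divided by the input coupling --
    the splitting-over-static-limit convention.
    """
    sched = phase_schedule(spec, element, theta, omega_r)
    traj = propagate(sched, system, orient, omega_r, n_cycles, points_per_rotor)
    if system.d_coupling == 0:
        return 0.0
    kappa = 2.0 * _peak_frequency(traj) / system.d_coupling
    return float(min(max(kappa, 0.0), 1.0))


def _theta_for_field(element, spec: SymmetrySpec, field: float, omega_r: float) -> float:
    """Back-calculate the flip angle giving the requested matched field.

    Uses the affine form of k_p in theta; elements without a theta dependence
    only admit their single field.
    """
    element = get_element(element)
    kp0 = float(element_kp(element, 0))
    base = match_field(spec, 1, omega_r)
    slope = sum(float(s.flip_coef) for s in element.segments) / 180.0
    if slope == 0:
        if abs(field - kp0 * base) > 1e-6 * base:
            raise ValueError(
                f"element {element.name!r} has fixed kp={kp0}; cannot reach {field} Hz"
            )
        return 0.0
    theta = (field / base - kp0) / slope
    element.check_theta(theta)
    return theta


def efficiency_curve(
    spec: SymmetrySpec,
    element="1a",
    omega_r: float = 60e3,
    field_grid=None,
    system: SpinSystem = SpinSystem(),
    n_cycles: int = 256,
    points_per_rotor: int = 360,
) -> EfficiencyCurve:
    """kappa over a grid of applied fields (theta back-calculated per field)."""
    element = get_element(element)
    if field_grid is None:
        lo = match_field(spec, float(element_kp(element, 0)), omega_r)
        field_grid = np.linspace(lo, 250e3, 101)
    field_grid = np.asarray(field_grid, dtype=float)
    thetas = np.array([_theta_for_field(element, spec, f, omega_r) for f in field_grid])
    kappas = np.array([
        scaling_factor(spec, element, th, omega_r, system,
                       n_cycles=n_cycles, points_per_rotor=points_per_rotor)
        for th in thetas
    ])
    return EfficiencyCurve(fields=field_grid, theta=thetas, kappas=kappas)


def optimize(
    spec: SymmetrySpec, element="1a", omega_r: float = 60e3, field_grid=None, **kw
) -> CandidateRecord:
    """Best kappa over the field grid; ties broken toward lower field."""
    curve = efficiency_curve(spec, element, omega_r, field_grid, **kw)
    best = np.max(curve.kappas)
    i = int(np.nonzero(curve.kappas >= best - 1e-12)[0][0])
    het = allowed_terms(spec, "het_dipolar")
    return CandidateRecord(
        spec=spec,
        element_name=get_element(element).name,
        theta=float(curve.theta[i]),
        match_field_Hz=float(curve.fields[i]),
        kappa=float(curve.kappas[i]),
        correlation=classify_correlation(het) if het else "mixed",
        gamma_encoded=is_gamma_encoded(het),
    )


def robustness_scan(
    spec: SymmetrySpec,
    element="1a",
    theta: float = 0.0,
    omega_r: float = 60e3,
    factors=(0.9, 1.0, 1.1),
    offsets=(),
    system: SpinSystem = SpinSystem(),
    n_cycles: int = 256,
    points_per_rotor: int = 720,
):
    """Peak-frequency shifts under RF mis-set and 1H carrier offset.

    RF mis-set multiplies every segment amplitude by ``factor`` with the
    timings held fixed, emulating B1 inhomogeneity.  Returns a list of dict
    rows: {kind, value, peak_Hz, shift_Hz}.
    """
    sched = phase_schedule(spec, element, theta, omega_r)

    def peak(schedule, sys):
        traj = propagate(schedule, sys, SINGLE_CRYSTAL, omega_r, n_cycles, points_per_rotor)
        return _peak_frequency(traj)

    ref = peak(sched, system)
    rows = []
    for f in factors:
        if f <= 0:
            raise ValueError("mis-set factors must be > 0")
        scaled = PulseSchedule(
            segments=tuple(
                replace(s, rf_amplitude=s.rf_amplitude * f) for s in sched.segments
            ),
            total_duration=sched.total_duration,
            label=sched.label + f" x{f}",
        )
        p = peak(scaled, system)
        rows.append({"kind": "field_factor", "value": f, "peak_Hz": p,
                     "shift_Hz": p - ref})
    for off in offsets:
        p = peak(sched, replace(system, offset_i=off))
        rows.append({"kind": "offset_Hz", "value": off, "peak_Hz": p,
                     "shift_Hz": p - ref})
    return rows
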