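"""RNnv / CNnv symmetry sequences and first-order selection rules.

A symmetry sequence packs N spin-space rotations (R: net pi rotations, C: net
2*pi cycles) into n rotor periods, with element phases alternating +/- pi*nu/N
(R sequences).  To first order in average-Hamiltonian theory a rotational
component (l, m, lambda, mu) of an interaction survives the sequence iff

    R:  m*n - mu*nu = (N/2) * Z,  Z an integer with the parity of lambda,
    C:  m*n - mu*nu = N * Z,      Z any integer.

Space components with l=2, m=0 are additionally removed by magic-angle
spinning itself.  Scanning these rules over quantum-number ranges, requiring
the heteronuclear dipolar coupling to survive, homonuclear couplings to
vanish and the result to be gamma-encoded, yields candidate recoupling
sequences whose RF match condition nu_1 = k_p * (N/2n) * omega_r can be
filtered against what a probe can deliver.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Iterable, Optional

from .elements import (
    PulseSchedule,
    PulseSegment,
    get_element,
    kp,
    segment_timings,
)


class QuantumNumberError(ValueError):
    """Invalid symmetry quantum numbers."""


#: interaction -> (space rank l, spin rank lambda).  Spin rank is that of the
#: irradiated (1H) spin: heteronuclear dipolar and 1H CSA are rank 1 on 1H,
#: the homonuclear 1H-1H coupling is rank 2, the isotropic shift rank 1 with
#: l = 0.
INTERACTIONS: dict[str, tuple[int, int]] = {
    "het_dipolar": (2, 1),
    "homo_dipolar": (2, 2),
    "csa_I": (2, 1),
    "iso_shift_I": (0, 1),
}


@dataclass(frozen=True, order=True)
class SymmetrySpec:
    """Quantum numbers of an RNnv (kind='R') or CNnv (kind='C') sequence."""

    N: int
    n: int
    nu: int
    kind: str = "R"

    def __post_init__(self):
        if self.kind not in ("R", "C"):
            raise QuantumNumberError(f"kind must be 'R' or 'C', got {self.kind!r}")
        if self.N < 2:
            raise QuantumNumberError(f"N must be >= 2, got N={self.N}")
        if self.kind == "R" and self.N % 2:
            raise QuantumNumberError(f"R sequences need even N, got N={self.N}")
        if self.n < 1:
            raise QuantumNumberError(f"n must be >= 1, got n={self.n}")
        if not (0 <= self.nu <= self.N / 2):
            raise QuantumNumberError(
                f"nu must satisfy 0 <= nu <= N/2, got nu={self.nu} for N={self.N}"
            )

    @property
    def base_phase_deg(self) -> float:
        """Magnitude of the element phase alternation, pi*nu/N in degrees."""
        return 180.0 * self.nu / self.N

    @property
    def name(self) -> str:
        return f"{self.kind}{self.N}_{self.n}^{self.nu}"


@dataclass(frozen=True, order=True)
class HamTerm:
    """One rotational component of an interaction: space (l, m), spin (lam, mu)."""

    l: int
    m: int
    lam: int
    mu: int

    def __post_init__(self):
        if abs(self.m) > self.l or abs(self.mu) > self.lam:
            raise QuantumNumberError(f"component out of range in {self!r}")


def _survives(spec: SymmetrySpec, m: int, mu: int, lam: int) -> bool:
    v = m * spec.n - mu * spec.nu
    if spec.kind == "C":
        return v % spec.N == 0
    if (2 * v) % spec.N != 0:
        return False
    z = 2 * v // spec.N
    return (z - lam) % 2 == 0


def allowed_terms(spec: SymmetrySpec, interaction: str) -> frozenset[HamTerm]:
    """Terms of ``interaction`` surviving the first-order selection rule.

    l=2, m=0 components are excluded regardless of the rule: magic-angle
    spinning nulls them on its own.
    """
    if interaction not in INTERACTIONS:
        raise QuantumNumberError(
            f"unknown interaction {interaction!r}; one of {sorted(INTERACTIONS)}"
        )
    l, lam = INTERACTIONS[interaction]
    terms = set()
    for m in range(-l, l + 1):
        if l == 2 and m == 0:
            continue
        for mu in range(-lam, lam + 1):
            if _survives(spec, m, mu, lam):
                terms.add(HamTerm(l=l, m=m, lam=lam, mu=mu))
    return frozenset(terms)


def is_gamma_encoded(terms: Iterable[HamTerm]) -> bool:
    """True iff the recoupled amplitude is independent of the crystallite gamma.

    Holds when the term set is non-empty and no spin component mu is recoupled
    through space components of both signs (a single m per mu means the gamma
    phase exp(i*m*gamma) only rotates the effective axis, never the size).
    """
    terms = list(terms)
    if not terms:
        return False
    signs: dict[int, set[bool]] = {}
    for t in terms:
        signs.setdefault(t.mu, set()).add(t.m > 0)
    return all(len(s) == 1 for s in signs.values())


def classify_correlation(terms: Iterable[HamTerm]) -> str:
    """'correlated' if sign(m) == sign(mu) for every term, 'anticorrelated'
    if opposite for every term, else 'mixed'.

    Correlated sets trade a second-order RF mis-set sensitivity for a
    second-order offset sensitivity; anticorrelated sets the reverse.
    """
    terms = list(terms)
    if not terms:
        raise QuantumNumberError("cannot classify an empty term set")
    sgn = lambda x: (x > 0) - (x < 0)
    pairs = {(sgn(t.m), sgn(t.mu)) for t in terms}
    if all(a == b and a != 0 for a, b in pairs):
        return "correlated"
    if all(a == -b and a != 0 for a, b in pairs):
        return "anticorrelated"
    return "mixed"


def match_field(spec: SymmetrySpec, kp_value=1, omega_r: float = 60e3) -> float:
    """RF nutation frequency (Hz) required by the symmetry: kp * (N/2n) * omega_r."""
    if omega_r <= 0:
        raise ValueError(f"omega_r must be > 0, got {omega_r}")
    if kp_value <= 0:
        raise ValueError(f"kp must be > 0, got {kp_value}")
    return float(kp_value) * spec.N * omega_r / (2 * spec.n)


@dataclass
class CandidateRecord:
    """One enumerated/optimized symmetry-element pairing."""

    spec: SymmetrySpec
    element_name: str = "pi"
    theta: float = 0.0
    match_field_Hz: float = 0.0
    kappa: Optional[float] = None
    correlation: str = "mixed"
    gamma_encoded: bool = False

    def __post_init__(self):
        if self.kappa is not None and not (0 <= self.kappa <= 1):
            raise ValueError(f"kappa must lie in [0, 1], got {self.kappa}")


def enumerate_candidates(
    N_range: tuple[int, int],
    n_range: tuple[int, int],
    omega_r: float,
    field_window: tuple[float, float] = (0.0, float("inf")),
    require_gamma_encoding: bool = True,
    disallow_homonuclear: bool = True,
    dedup_repeats: bool = True,
    kind: str = "R",
    element="pi",
) -> list[CandidateRecord]:
    """Scan R symmetries over N in N_range, n in n_range, 1 <= nu <= N/2.

    A candidate survives when its heteronuclear dipolar term set is non-empty,
    its homonuclear set empty (if ``disallow_homonuclear``), gamma-encoding
    holds (if required) and the base (kp=1) match field lies inside
    ``field_window``.  With ``dedup_repeats`` only primitive quantum-number
    triples, gcd(N, n, nu) = 1, are emitted: R(kN)_(kn)^(k nu) is the same RF
    waveform as k back-to-back repeats of RN_n^nu.  Sorted by (N, n, nu).
    """
    element = get_element(element)
    lo, hi = field_window
    out: list[CandidateRecord] = []
    N_lo, N_hi = N_range
    n_lo, n_hi = n_range
    step = 2 if kind == "R" else 1
    start = N_lo + (N_lo % 2) if kind == "R" else N_lo
    for N in range(max(start, 2), N_hi + 1, step):
        for n in range(max(n_lo, 1), n_hi + 1):
            for nu in range(1, N // 2 + 1):
                if dedup_repeats and gcd(gcd(N, n), nu) != 1:
                    continue
                spec = SymmetrySpec(N=N, n=n, nu=nu, kind=kind)
                het = allowed_terms(spec, "het_dipolar")
                if not het:
                    continue
                if disallow_homonuclear and allowed_terms(spec, "homo_dipolar"):
                    continue
                encoded = is_gamma_encoded(het)
                if require_gamma_encoding and not encoded:
                    continue
                base_field = match_field(spec, 1, omega_r)
                if not (lo < base_field < hi):
                    continue
                out.append(
                    CandidateRecord(
                        spec=spec,
                        element_name=element.name,
                        theta=0.0,
                        match_field_Hz=base_field,
                        correlation=classify_correlation(het),
                        gamma_encoded=encoded,
                    )
                )
    out.sort(key=lambda r: (r.spec.N, r.spec.n, r.spec.nu))
    return out


def phase_schedule(
    spec: SymmetrySpec, element="pi", theta: float = 0.0, omega_r: float = 60e3
) -> PulseSchedule:
    """Explicit RF segment list realizing one full symmetry cycle.

    N elements span exactly n rotor periods; element j carries the base phase
    +pi*nu/N for even j and -pi*nu/N for odd j, added to each internal
    segment phase.  The RF amplitude is the matched field for the element's
    k_p at this theta.
    """
    element = get_element(element)
    kp_val = kp(element, theta)
    field = match_field(spec, kp_val, omega_r)
    timing = segment_timings(element, theta, spec, omega_r)
    from .elements import _exactify

    th = _exactify(theta)
    flips = [seg.flip(th) for seg in element.segments]
    segments = []
    for j in range(spec.N):
        base = spec.base_phase_deg if j % 2 == 0 else -spec.base_phase_deg
        for seg, flip in zip(element.segments, flips):
            if flip <= 0:
                continue
            duration = float(flip) / 360.0 / field
            segments.append(
                PulseSegment(
                    rf_amplitude=field,
                    rf_phase=base + float(seg.phase_deg),
                    duration=duration,
                )
            )
    total = spec.n / omega_r
    return PulseSchedule(
        segments=tuple(segments),
        total_duration=total,
        label=f"{spec.name}({element.name}, theta={theta})",
    )
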