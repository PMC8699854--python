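"""Variable-flip-angle composite inversion elements (R-elements).

An R-element is any net pi rotation about a transverse axis, possibly built
from several back-to-back RF segments.  Each segment has a flip angle that is
an affine function of a free parameter theta (degrees) and a fixed phase.
Keeping the flip angles as exact affine coefficients (a + b*theta) lets the
sweep-angle factor k_p and the segment timing fractions be computed with
rational arithmetic.

The catalog ships the plain pi pulse, the two classic composite inversions
[90(0) 90(90) 90(0)] and [90(0) 270(180)], and the three variable-flip-angle
elements "1a" (theta(0) [180+theta](180)), "2a" (theta(0) [180+2theta](180)
theta(0)) and "4a" (90(0) theta(90) 90(0)).  User-defined segment templates
extend the catalog through the same RElementSpec interface.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation


class ElementDomainError(ValueError):
    """theta outside the element's valid domain, or a non-positive segment."""


@dataclass(frozen=True)
class Segment:
    """One RF segment: flip = const + coef*theta degrees at a fixed phase."""

    flip_const: Fraction
    flip_coef: Fraction
    phase_deg: Fraction

    def flip(self, theta):
        """Flip angle in degrees at the given theta."""
        return self.flip_const + self.flip_coef * theta


def _frac(x) -> Fraction:
    if isinstance(x, Rational):
        return Fraction(x)
    if isinstance(x, (int, np.integer)):
        return Fraction(int(x))
    return Fraction(x).limit_denominator(10**9)


@dataclass(frozen=True)
class RElementSpec:
    """Parametric composite inversion pulse.

    ``segments`` are played in order; every theta in ``theta_domain`` must
    yield a net pi rotation (checked numerically by :func:`net_rotation`).
    """

    name: str
    segments: tuple[Segment, ...]
    theta_domain: tuple[float, float] = (0.0, 720.0)

    def __post_init__(self):
        if not self.segments:
            raise ElementDomainError(f"element {self.name!r} has no segments")

    @property
    def uses_theta(self) -> bool:
        return any(s.flip_coef != 0 for s in self.segments)

    def check_theta(self, theta) -> None:
        lo, hi = self.theta_domain
        if not (lo <= theta <= hi):
            raise ElementDomainError(
                f"theta={theta} outside domain [{lo}, {hi}] of element {self.name!r}"
            )
        for seg in self.segments:
            if seg.flip(_exactify(theta)) < 0:
                raise ElementDomainError(
                    f"theta={theta} gives a negative flip in element {self.name!r}"
                )


def _exactify(theta):
    """Represent theta exactly when it is (close to) rational."""
    return _frac(theta)


def make_element(name: str, segs: Sequence[tuple], theta_domain=(0.0, 720.0)) -> RElementSpec:
    """Build an element from (flip_const, flip_coef, phase) triples."""
    segments = tuple(
        Segment(_frac(a), _frac(b), _frac(p)) for a, b, p in segs
    )
    return RElementSpec(name=name, segments=segments, theta_domain=tuple(theta_domain))


#: Shipped element catalog.  Flip angles in degrees, phases relative to the
#: element's base phase (set later by the symmetry's +/- pi*nu/N alternation).
CATALOG: dict[str, RElementSpec] = {
    "pi": make_element("pi", [(180, 0, 0)]),
    "90-90-90": make_element("90-90-90", [(90, 0, 0), (90, 0, 90), (90, 0, 0)]),
    "90-270": make_element("90-270", [(90, 0, 0), (270, 0, 180)]),
    "1a": make_element("1a", [(0, 1, 0), (180, 1, 180)]),
    "2a": make_element("2a", [(0, 1, 0), (180, 2, 180), (0, 1, 0)]),
    "4a": make_element("4a", [(90, 0, 0), (0, 1, 90), (90, 0, 0)]),
}


def get_element(name_or_spec) -> RElementSpec:
    if isinstance(name_or_spec, RElementSpec):
        return name_or_spec
    try:
        return CATALOG[name_or_spec]
    except KeyError:
        raise ElementDomainError(
            f"unknown element {name_or_spec!r}; catalog: {sorted(CATALOG)}"
        ) from None


def kp(element, theta=0):
    """Pulse contribution to the match condition: total swept arc / 180 deg.

    Exact (a Fraction) when theta is rational.
    """
    element = get_element(element)
    element.check_theta(theta)
    th = _exactify(theta)
    total = sum(seg.flip(th) for seg in element.segments)
    return total / 180


@dataclass(frozen=True)
class SegmentTiming:
    """Relative segment durations within one element window.

    ``fractions`` sum to exactly 1; ``element_duration`` is the element
    window n*tau_r/N in seconds so that duration * match_field * fraction_i
    equals flip_i/360 for every segment.
    """

    fractions: tuple
    element_duration: float


def segment_timings(element, theta, spec, omega_r) -> SegmentTiming:
    """Timing fractions of each segment and the element window duration.

    Zero-length segments (e.g. the theta portions of "1a" at theta=0) are
    collapsed; the remaining fractions still sum to 1.
    """
    from .symmetry import SymmetrySpec  # cycle-free: symmetry imports nothing here

    element = get_element(element)
    element.check_theta(theta)
    if not isinstance(spec, SymmetrySpec):
        raise TypeError("spec must be a SymmetrySpec")
    th = _exactify(theta)
    flips = [seg.flip(th) for seg in element.segments]
    total = sum(flips)
    if total <= 0:
        raise ElementDomainError("element sweeps no arc at this theta")
    fractions = tuple(f / total for f in flips if f > 0)
    duration = spec.n / (spec.N * omega_r)
    return SegmentTiming(fractions=fractions, element_duration=duration)


def net_rotation(element, theta):
    """Compose the segment rotations; return (axis, angle_deg).

    Every catalog element composes to a 180 deg rotation about some
    transverse axis for all theta in its domain.
    """
    element = get_element(element)
    element.check_theta(theta)
    total = Rotation.identity()
    for seg in element.segments:
        flip = float(seg.flip(_exactify(theta)))
        if flip == 0.0:
            continue
        phase = np.deg2rad(float(seg.phase_deg))
        axis = np.array([np.cos(phase), np.sin(phase), 0.0])
        total = Rotation.from_rotvec(np.deg2rad(flip) * axis) * total
    rotvec = total.as_rotvec()
    angle = np.linalg.norm(rotvec)
    axis = rotvec / angle if angle > 0 else np.array([1.0, 0.0, 0.0])
    return axis, np.rad2deg(angle)


@dataclass(frozen=True)
class PulseSegment:
    """A literal RF segment: amplitude (Hz), phase (deg), duration (s)."""

    rf_amplitude: float
    rf_phase: float
    duration: float


@dataclass(frozen=True)
class PulseSchedule:
    """Explicit single-channel (1H) RF segment list over one symmetry cycle."""

    segments: tuple[PulseSegment, ...]
    total_duration: float
    label: str = ""

    def __post_init__(self):
        if any(s.duration <= 0 for s in self.segments):
            raise ElementDomainError("schedule contains a non-positive duration")
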