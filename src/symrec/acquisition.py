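"""Constant-time acquisition arithmetic for the dipolar dimension.

The recoupling dimension of the 3D experiment increments in units of whole
symmetry cycles: increment = k * n * tau_r, where k is the number of repeated
symmetry blocks per increment.  The recoupling runs only during the first
half of a constant-time echo, so the total echo is

    tau_echo = 2 * increment * (n_points - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .symmetry import SymmetrySpec


@dataclass(frozen=True)
class AcquisitionPlan:
    increment: float        # s
    n_points: int
    k: int
    echo_time: float        # s
    spectral_width: float   # Hz


def plan_acquisition(
    spec: SymmetrySpec, omega_r: float = 60e3, k: int = 1, n_points: int = 15
) -> AcquisitionPlan:
    """Increment, echo time and spectral width for a symmetry at omega_r."""
    if omega_r <= 0 or k < 1 or n_points < 1:
        raise ValueError("omega_r, k and n_points must be positive")
    increment = k * spec.n / omega_r
    return AcquisitionPlan(
        increment=increment,
        n_points=n_points,
        k=k,
        echo_time=2 * increment * (n_points - 1),
        spectral_width=1.0 / increment,
    )
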