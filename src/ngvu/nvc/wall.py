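"""Kelvin-Voigt viscoelastic vessel wall.

Radius dynamics dR/dt = (R0_pas/eta) (R dp/h - E(F_r) (R - R0(F_r))/R0(F_r))
with h = 0.1 R exactly, so the pressure term is the constant 10 dp.  E and
R0 interpolate linearly between passive (F_r = 0) and active (F_r = 1)
states.  Units: R in um, pressures/moduli in Pa, eta in Pa s.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class WallState:
    radius: float = 20.0      # um
    dp: float = 4000.0        # transmural pressure [Pa]
    eta: float = 1.0e5        # wall viscosity [Pa s]
    e_act: float = 233.0e3
    e_pas: float = 30.0e3
    r0_act: float = 12.0
    r0_pas: float = 20.0

    @property
    def thickness(self) -> float:
        return 0.1 * self.radius


def modulus(f_r: float, wall: WallState) -> float:
    return wall.e_pas + f_r * (wall.e_act - wall.e_pas)


def reference_radius(f_r: float, wall: WallState) -> float:
    return wall.r0_pas + f_r * (wall.r0_act - wall.r0_pas)


def wall_radius_rhs(wall: WallState, f_r: float) -> float:
    """dR/dt [um/s]; with h = 0.1 R the pressure term is 10 dp."""
    if wall.eta <= 0:
        raise ValueError("wall viscosity must be positive")
    e = modulus(f_r, wall)
    r0 = reference_radius(f_r, wall)
    return wall.r0_pas / wall.eta * (
        10.0 * wall.dp - e * (wall.radius - r0) / r0)


def steady_radius(wall: WallState, f_r: float) -> float:
    """Closed form R* = R0(F_r) (1 + 10 dp / E(F_r))."""
    return reference_radius(f_r, wall) * (
        1.0 + 10.0 * wall.dp / modulus(f_r, wall))


def wall_step(wall: WallState, f_r: float, dt: float) -> WallState:
    out = WallState(**vars(wall))
    out.radius = wall.radius + dt * wall_radius_rhs(wall, f_r)
    if out.radius <= 0:
        raise FloatingPointError("wall radius collapsed")
    return out
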