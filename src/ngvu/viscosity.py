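"""Blood viscosity laws shared by the macro- and micro-circulation solvers.

Two laws are provided behind a common interface ``mu(diameter)``:

``constant``
    Diameter-independent Newtonian viscosity (default 3.5e-3 Pa s).
``pries_invitro``
    The empirical in-vitro fit of apparent blood viscosity versus tube
    diameter at discharge hematocrit H_D, relative to plasma viscosity.

Each law records a ``name`` attribute so runs can log which one was used.
"""

from __future__ import annotations

import numpy as np

MU_CONSTANT_PAS = 3.5e-3   # Pa s
MU_PLASMA_PAS = 1.2e-3     # Pa s


class ViscosityLaw:
    """Callable mapping vessel diameter [cm] -> dynamic viscosity [Pa s]."""

    name = "base"

    def __call__(self, diameter_cm):  # pragma: no cover - interface
        raise NotImplementedError


class ConstantViscosity(ViscosityLaw):
    name = "constant"

    def __init__(self, mu_pas: float = MU_CONSTANT_PAS):
        if mu_pas <= 0:
            raise ValueError("viscosity must be positive")
        self.mu_pas = float(mu_pas)

    def __call__(self, diameter_cm):
        return np.broadcast_to(self.mu_pas, np.shape(diameter_cm)).copy() \
            if np.ndim(diameter_cm) else self.mu_pas


class PriesInVitroViscosity(ViscosityLaw):
    """Diameter-dependent in-vitro apparent viscosity.

    mu_rel_45(D) = 220 exp(-1.3 D) + 3.2 - 2.44 exp(-0.06 D^0.645), D in um,
    with the usual hematocrit correction
    mu_rel = 1 + (mu_rel_45 - 1) * ((1-H)^C - 1) / ((1-0.45)^C - 1),
    C(D) = (0.8 + e^{-0.075 D}) (-1 + 1/(1+1e-11 D^12)) + 1/(1+1e-11 D^12).
    """

    name = "pries_invitro"

    def __init__(self, hematocrit: float = 0.45,
                 mu_plasma_pas: float = MU_PLASMA_PAS):
        if not 0.0 <= hematocrit < 1.0:
            raise ValueError("hematocrit must be in [0, 1)")
        self.hematocrit = float(hematocrit)
        self.mu_plasma_pas = float(mu_plasma_pas)

    def __call__(self, diameter_cm):
        d_um = np.asarray(diameter_cm, dtype=float) * 1.0e4
        d_um = np.maximum(d_um, 1e-3)
        mu45 = 220.0 * np.exp(-1.3 * d_um) + 3.2 \
            - 2.44 * np.exp(-0.06 * d_um ** 0.645)
        h = self.hematocrit
        if abs(h - 0.45) < 1e-12:
            mu_rel = mu45
        else:
            frac = 1.0 / (1.0 + 1e-11 * d_um ** 12)
            c = (0.8 + np.exp(-0.075 * d_um)) * (frac - 1.0) + frac
            mu_rel = 1.0 + (mu45 - 1.0) * ((1.0 - h) ** c - 1.0) \
                / ((1.0 - 0.45) ** c - 1.0)
        out = mu_rel * self.mu_plasma_pas
        return float(out) if np.ndim(diameter_cm) == 0 else out


def get_viscosity_law(name: str = "constant", **kwargs) -> ViscosityLaw:
    laws = {"constant": ConstantViscosity, "pries_invitro": PriesInVitroViscosity}
    try:
        return laws[name](**kwargs)
    except KeyError:
        raise ValueError(f"unknown viscosity law {name!r}; options: {sorted(laws)}")
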