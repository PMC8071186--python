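"""Kelvin-Voigt fractional-derivative (KVFD) shear rheology.

The KVFD constitutive law for shear is

    sigma = 2 (mu + eta d^alpha/dt^alpha) epsilon,

a spring of stiffness ``mu`` (Pa) in parallel with a "spring-pot" of
consistency ``eta`` (Pa s^alpha) and fractional order ``alpha``.  In the
frequency domain the model has the complex shear modulus

    G*(w) = mu + eta (i w)^alpha,

whose real and imaginary parts are the storage and loss moduli.  The
principal branch (i w)^alpha = w^alpha (cos(alpha pi/2) + i sin(alpha pi/2))
is used throughout, so

    G'(w)  = mu + eta w^alpha cos(alpha pi / 2)
    G''(w) =      eta w^alpha sin(alpha pi / 2).

For a monochromatic plane shear wave the phase velocity follows from the
complex wavenumber k = w sqrt(rho / G*), equivalently

    rho c^2 = 2 (G'^2 + G''^2) / (G' + sqrt(G'^2 + G''^2)),

and the attenuation coefficient is -Im(k) (Np/m).

Presets for normal and cancerous prostatic tissue are registered under
``MATERIALS``; the cancerous values are the normal ones with ``mu`` and
``eta`` scaled by a stiffness-contrast ratio of 1.2 at unchanged ``alpha``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "KVFDMaterial",
    "MATERIALS",
    "get_material",
    "storage_modulus",
    "loss_modulus",
    "complex_modulus",
    "phase_velocity",
    "attenuation_coefficient",
    "scaled_material",
    "dispersion_table",
    "truncate_1dp",
]


@dataclass(frozen=True)
class KVFDMaterial:
    """One tissue type: density plus the shear KVFD triplet (mu, eta, alpha).

    Parameters
    ----------
    density : float
        Mass density rho, kg/m^3.
    shear_elastic : float
        Shear elastic modulus mu, Pa.
    shear_viscous : float
        Shear viscous consistency eta, Pa s^alpha.
    fractional_order : float
        Order alpha of the fractional time derivative, dimensionless.
        Accepted range is [0, 2]; values above 1 are unusual for dynamic
        elastography and trigger a warning.
    name : str
        Human-readable label.
    """

    density: float
    shear_elastic: float
    shear_viscous: float
    fractional_order: float
    name: str = "unnamed"

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be > 0, got {self.density}")
        if self.shear_elastic <= 0:
            raise ValueError(f"shear_elastic must be > 0, got {self.shear_elastic}")
        if self.shear_viscous < 0:
            raise ValueError(f"shear_viscous must be >= 0, got {self.shear_viscous}")
        if not 0.0 <= self.fractional_order <= 2.0:
            raise ValueError(
                f"fractional_order must lie in [0, 2], got {self.fractional_order}"
            )
        if self.fractional_order > 1.0:
            warnings.warn(
                f"fractional_order={self.fractional_order} > 1 is outside the "
                "usual dynamic-elastography range",
                stacklevel=2,
            )

    @property
    def elastic_velocity(self) -> float:
        """Lossless shear speed sqrt(mu/rho), m/s (the eta=0 limit)."""
        return float(np.sqrt(self.shear_elastic / self.density))


#: Prostatic-tissue presets (rho = 1000 kg/m^3 for all soft tissue).
MATERIALS: dict[str, KVFDMaterial] = {
    "prostate_normal": KVFDMaterial(
        density=1000.0,
        shear_elastic=3000.0,
        shear_viscous=35.0,
        fractional_order=0.35,
        name="prostate_normal",
    ),
    "prostate_cancer": KVFDMaterial(
        density=1000.0,
        shear_elastic=3600.0,
        shear_viscous=42.0,
        fractional_order=0.35,
        name="prostate_cancer",
    ),
}


def get_material(name: str) -> KVFDMaterial:
    """Look up a registered material preset by name."""
    try:
        return MATERIALS[name]
    except KeyError:
        raise KeyError(
            f"unknown material preset {name!r}; available: {sorted(MATERIALS)}"
        ) from None


def _check_omega(omega, allow_zero: bool = True):
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("angular frequency must be non-negative")
    if not allow_zero and np.any(w == 0):
        raise ValueError("angular frequency must be positive")
    return w


def storage_modulus(material: KVFDMaterial, omega) -> np.ndarray | float:
    """Storage modulus G'(w) = mu + eta w^alpha cos(alpha pi/2), Pa."""
    w = _check_omega(omega)
    a = material.fractional_order
    with np.errstate(invalid="ignore"):
        wa = np.where(w > 0, w**a, 0.0 if a > 0 else 1.0)
    out = material.shear_elastic + material.shear_viscous * wa * np.cos(a * np.pi / 2)
    return out if isinstance(omega, np.ndarray) else float(out)


def loss_modulus(material: KVFDMaterial, omega) -> np.ndarray | float:
    """Loss modulus G''(w) = eta w^alpha sin(alpha pi/2), Pa."""
    w = _check_omega(omega)
    a = material.fractional_order
    with np.errstate(invalid="ignore"):
        wa = np.where(w > 0, w**a, 0.0 if a > 0 else 1.0)
    out = material.shear_viscous * wa * np.sin(a * np.pi / 2)
    return out if isinstance(omega, np.ndarray) else float(out)


def complex_modulus(material: KVFDMaterial, omega) -> np.ndarray | complex:
    """Complex shear modulus G*(w) = mu + eta (i w)^alpha, Pa.

    Uses the principal branch, so ``G*.real == storage_modulus`` and
    ``G*.imag == loss_modulus`` identically.
    """
    w = _check_omega(omega)
    out = storage_modulus(material, w) + 1j * loss_modulus(material, w)
    return out if isinstance(omega, np.ndarray) else complex(out)


def phase_velocity(material: KVFDMaterial, omega) -> np.ndarray | float:
    """Phase velocity c(w) of a plane shear wave, m/s.

    rho c^2 = 2 (G'^2 + G''^2) / (G' + sqrt(G'^2 + G''^2)).

    At w = 0 the lossless limit sqrt(mu/rho) is returned (for alpha > 0 the
    viscous branch vanishes there).
    """
    w = _check_omega(omega)
    gp = storage_modulus(material, w)
    gpp = loss_modulus(material, w)
    mag = np.hypot(gp, gpp)
    c2 = 2.0 * mag**2 / (material.density * (gp + mag))
    out = np.sqrt(c2)
    return out if isinstance(omega, np.ndarray) else float(out)


def attenuation_coefficient(material: KVFDMaterial, omega) -> np.ndarray | float:
    """Attenuation -Im(k), Np/m, with k = w sqrt(rho/G*), Re(k) > 0."""
    w = _check_omega(omega, allow_zero=False)
    gstar = complex_modulus(material, w)
    k = w * np.sqrt(material.density / gstar)
    k = np.where(np.real(k) >= 0, k, -k)
    out = -np.imag(k)
    return out if isinstance(omega, np.ndarray) else float(out)


def scaled_material(material: KVFDMaterial, ratio: float, name: str | None = None) -> KVFDMaterial:
    """Return a copy with mu and eta multiplied by ``ratio``.

    Models a stiffness contrast (e.g. tumour vs background): alpha and rho
    are kept unchanged.
    """
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    return replace(
        material,
        shear_elastic=material.shear_elastic * ratio,
        shear_viscous=material.shear_viscous * ratio,
        name=name if name is not None else f"{material.name}_x{ratio:g}",
    )


def dispersion_table(material: KVFDMaterial, frequencies_hz) -> "pandas.DataFrame":
    """Evaluate the dispersion and attenuation curves on a frequency grid.

    Returns a DataFrame with columns ``frequency_hz``, ``velocity_mps``,
    ``Gstar_abs_pa`` and ``attenuation_np_per_m`` (suitable for CSV export).
    """
    import pandas as pd

    f = np.asarray(frequencies_hz, dtype=float)
    w = 2 * np.pi * f
    return pd.DataFrame(
        {
            "frequency_hz": f,
            "velocity_mps": phase_velocity(material, w),
            "Gstar_abs_pa": np.abs(complex_modulus(material, w)),
            "attenuation_np_per_m": attenuation_coefficient(material, w),
        }
    )


def truncate_1dp(x: float) -> float:
    """Truncate (not round) towards zero to one decimal place.

    Reported ranges such as "3.2 to 3.6 kPa" follow this convention.
    """
    return float(np.trunc(10.0 * x) / 10.0)
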