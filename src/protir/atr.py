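"""Polarized ATR linear dichroism: effective fields, dichroic ratios, and
resolution of absorbance spectra into in-plane (xy) and normal (z) parts.

The evanescent-field amplitudes at the internal-reflection-element surface
follow the two-phase (thick-film) Harrick approximation.  With
n31 = n3/n1, s = sin^2(alpha), c2 = cos^2(alpha) and
D = (1 - n31^2) ((1 + n31^2) s - n31^2):

    Ey^2 = 4 c2 / (1 - n31^2)
    Ex^2 = 4 c2 (s - n31^2) / D
    Ez^2 = 4 c2 s / D

For a uniaxial film (a_x = a_y = a_xy, membrane normal along z) the
polarized absorbances are A_perp = Ey^2 a_xy and
A_par = Ex^2 a_xy + Ez^2 a_z, so the components resolve as
A_xy = A_perp / Ey^2 and A_z = (A_par - (Ex^2/Ey^2) A_perp) / Ez^2; an
isotropic absorber then gives A_xy = A_z by construction.  The isotropic
dichroic ratio R = (Ex^2 + Ez^2)/Ey^2 depends only on alpha and the index
ratio and is inverted for the incidence angle by bracketed root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

# mid-IR refractive indices used for the water calibration of the incidence angle
N_SILICON = 3.42
N_WATER = 1.32
N_FILM = 1.6  # rehydrated membrane protein film

ALPHA_DEFAULT = 39.0  # degrees


class TotalReflectionError(ValueError):
    """Incidence angle at or below the critical angle."""


@dataclass(frozen=True)
class ATRGeometry:
    """Incidence angle (degrees) and refractive indices n1 (IRE), n3 (sample)."""

    alpha: float = ALPHA_DEFAULT
    n1: float = N_SILICON
    n3: float = N_FILM

    def __post_init__(self):
        if not (0.0 < self.alpha < 90.0):
            raise ValueError("alpha must lie in (0, 90) degrees")
        if not (self.n1 > self.n3 > 0):
            raise ValueError("need n1 > n3 > 0 for internal reflection")
        if self.alpha <= self.critical_angle:
            raise TotalReflectionError(
                f"alpha = {self.alpha:.2f} deg is not above the critical angle "
                f"{self.critical_angle:.2f} deg"
            )

    @property
    def n31(self) -> float:
        return self.n3 / self.n1

    @property
    def critical_angle(self) -> float:
        return float(np.degrees(np.arcsin(self.n31)))


@dataclass
class DichroicSpectra:
    """Polarized absorbances with their resolved xy/z components."""

    nu: np.ndarray
    A_par: np.ndarray
    A_perp: np.ndarray
    A_xy: np.ndarray
    A_z: np.ndarray
    R: np.ndarray  # A_par / A_perp, nan where A_perp == 0


def field_amplitudes(geometry: ATRGeometry) -> tuple[float, float, float]:
    """Squared effective-field amplitudes (Ex^2, Ey^2, Ez^2)."""
    a = np.radians(geometry.alpha)
    n2 = geometry.n31**2
    s = np.sin(a) ** 2
    c2 = np.cos(a) ** 2
    D = (1.0 - n2) * ((1.0 + n2) * s - n2)
    Ey2 = 4.0 * c2 / (1.0 - n2)
    Ex2 = 4.0 * c2 * (s - n2) / D
    Ez2 = 4.0 * c2 * s / D
    return Ex2, Ey2, Ez2


def iso_dichroic_ratio(geometry: ATRGeometry) -> float:
    """Dichroic ratio (Ex^2 + Ez^2)/Ey^2 of an isotropic thick sample."""
    n2 = geometry.n31**2
    s = np.sin(np.radians(geometry.alpha)) ** 2
    return float((2.0 * s - n2) / ((1.0 + n2) * s - n2))


def angle_from_ratio(R: float, n1: float = N_SILICON, n3: float = N_WATER) -> float:
    """Invert the isotropic dichroic-ratio formula for the incidence angle.

    Unique root on (critical angle, 90 deg); R must lie strictly between
    the 90-degree limit 2 - n31^2 and the (diverging toward 1/n31^2)
    grazing-critical limit.
    """
    n31 = n3 / n1
    theta_c = np.degrees(np.arcsin(n31))
    lo, hi = theta_c + 1e-9, 90.0 - 1e-12

    def f(alpha):
        return iso_dichroic_ratio(ATRGeometry(alpha, n1, n3)) - R

    r_lo, r_hi = f(lo), f(hi)
    if not (r_lo > 0 > r_hi or r_lo < 0 < r_hi):
        raise ValueError(
            f"R = {R} outside the attainable range "
            f"({2 - n31**2:.4f}, {1/n31**2:.4f}) for n31 = {n31:.4f}"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def resolve_components(
    A_par: np.ndarray, A_perp: np.ndarray, geometry: ATRGeometry,
    nu: np.ndarray | None = None,
) -> DichroicSpectra:
    """Resolve polarized absorbances into in-plane and normal components.

    Uniaxial-film model: A_perp = Ey^2 a_xy, A_par = Ex^2 a_xy + Ez^2 a_z.
    Normalized so an isotropic absorber yields A_xy = A_z.
    """
    A_par = np.atleast_1d(np.asarray(A_par, dtype=float))
    A_perp = np.atleast_1d(np.asarray(A_perp, dtype=float))
    if A_par.shape != A_perp.shape:
        raise ValueError("A_par and A_perp grids differ")
    if nu is None:
        nu = np.arange(A_par.size, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if nu.shape != A_par.shape:
        raise ValueError("nu grid does not match the absorbance arrays")
    Ex2, Ey2, Ez2 = field_amplitudes(geometry)
    A_xy = A_perp / Ey2
    A_z = (A_par - (Ex2 / Ey2) * A_perp) / Ez2
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        R = np.where(A_perp != 0, A_par / A_perp, np.nan)
    return DichroicSpectra(nu, A_par, A_perp, A_xy, A_z, R)


def forward_model(
    a_xy: np.ndarray, a_z: np.ndarray, geometry: ATRGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize (A_par, A_perp) from intrinsic uniaxial absorptions."""
    a_xy = np.asarray(a_xy, dtype=float)
    a_z = np.asarray(a_z, dtype=float)
    Ex2, Ey2, Ez2 = field_amplitudes(geometry)
    return Ex2 * a_xy + Ez2 * a_z, Ey2 * a_xy


def sensitivity_scan(
    A_par: np.ndarray,
    A_perp: np.ndarray,
    geometry: ATRGeometry,
    alphas: tuple = (37.0, 39.0, 41.0),
    n3s: tuple = (1.5, 1.6, 1.7),
    nu: np.ndarray | None = None,
) -> list[dict]:
    """Resolve the spectra for every (alpha, n3) pair of the scan grid.

    Each record reports the resolved components and their maximum absolute
    deviation from the reference-geometry resolution.
    """
    ref = resolve_components(A_par, A_perp, geometry, nu=nu)
    records = []
    for alpha in alphas:
        for n3 in n3s:
            geo = ATRGeometry(alpha, geometry.n1, n3)
            res = resolve_components(A_par, A_perp, geo, nu=nu)
            records.append(
                dict(
                    alpha=alpha,
                    n3=n3,
                    A_xy=res.A_xy,
                    A_z=res.A_z,
                    max_dev_xy=float(np.max(np.abs(res.A_xy - ref.A_xy))),
                    max_dev_z=float(np.max(np.abs(res.A_z - ref.A_z))),
                )
            )
    return records
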