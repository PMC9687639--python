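"""Constitutive models of the aneurysm wall and thrombus, and synthetic stress.

The anisotropic wall model is an exponential strain-energy function of the
in-plane Green strains (circumferential E_tt, longitudinal E_ll, shear E_tl):

    W = b0 * ( exp(1/2 b1 E_tt^2) + exp(1/2 b2 E_ll^2) + exp(b3 E_tt E_ll)
             + exp(1/2 b4 E_tl^2) + exp(b5 E_tt E_tl) + exp(b6 E_ll E_tl) - 6 )

with b0 carrying the stress units and b1..b6 acting as dimensionless
exponent multipliers (the only dimensionally consistent reading). The
intraluminal thrombus (ILT) is a two-parameter isotropic polynomial model
W = c1 (I1 - 3) + c2 (I2 - 3).

No finite-element solve happens here: for testing and cohort simulation,
``synthetic_stress_field`` produces a Laplace-law (thin-walled tube) von
Mises surrogate, sigma = P r / t, driven by the local distance from the
craniocaudal axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import MaterialRangeError, MeshValidationError
from .mesh_core import NodalField, SurfaceMesh

__all__ = [
    "WallMaterialParams",
    "ILTParams",
    "StrainState",
    "wall_strain_energy",
    "ilt_strain_energy",
    "synthetic_stress_field",
    "MMHG_TO_N_PER_CM2",
]

# 1 mmHg = 133.322 Pa; 1 N/cm^2 = 10 kPa.
MMHG_TO_N_PER_CM2 = 133.322 / 1e4

_EXP_ARG_MAX = 700.0  # beyond this, exp overflows float64


@dataclass(frozen=True)
class WallMaterialParams:
    """Exponential wall-model constants; b0 in kPa, b1..b6 dimensionless.

    Defaults are the population-mean biaxial constants for aneurysmal wall;
    the shear (b4) and shear-normal (b5, b6) couplings default to zero —
    they are not required to fit experimental stress-strain data.
    """

    b0: float = 0.14
    b1: float = 477.0
    b2: float = 416.4
    b3: float = 408.3
    b4: float = 0.0
    b5: float = 0.0
    b6: float = 0.0

    def __post_init__(self):
        if self.b0 <= 0:
            raise MeshValidationError("b0 must be positive")


@dataclass(frozen=True)
class ILTParams:
    """Two-parameter isotropic ILT model constants (N/cm^2)."""

    c1: float = 2.6
    c2: float = 2.6

    def __post_init__(self):
        if self.c1 <= 0 or self.c2 <= 0:
            raise MeshValidationError("c1 and c2 must be positive")


@dataclass(frozen=True)
class StrainState:
    """In-plane Green strains (dimensionless): circumferential, longitudinal, shear."""

    E_theta_theta: float
    E_LL: float
    E_thetaL: float = 0.0

    def __post_init__(self):
        for name in ("E_theta_theta", "E_LL", "E_thetaL"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise MeshValidationError(f"{name} must be finite")
            if abs(v) >= 1.0:
                raise MeshValidationError(f"|{name}| must be < 1 (sanity bound)")


def wall_strain_energy(strain: StrainState, params: WallMaterialParams = WallMaterialParams()) -> float:
    """Strain-energy density of the anisotropic wall model (units of b0).

    Exactly the printed six-exponential form; W = 0 at zero strain. Raises
    ``MaterialRangeError`` naming the term whose exponent would overflow.
    """
    et, el, es = strain.E_theta_theta, strain.E_LL, strain.E_thetaL
    p = params
    args = {
        "circumferential (b1)": 0.5 * p.b1 * et * et,
        "longitudinal (b2)": 0.5 * p.b2 * el * el,
        "normal coupling (b3)": p.b3 * et * el,
        "shear (b4)": 0.5 * p.b4 * es * es,
        "shear-circumferential (b5)": p.b5 * et * es,
        "shear-longitudinal (b6)": p.b6 * el * es,
    }
    total = 0.0
    for term, arg in args.items():
        if arg > _EXP_ARG_MAX:
            raise MaterialRangeError(f"exponential overflow in {term} term (arg={arg:.3g})")
        total += np.exp(arg)
    return float(p.b0 * (total - 6.0))


def ilt_strain_energy(invariants_shift, params: ILTParams = ILTParams()) -> float:
    """ILT strain energy W = c1 (I1 - 3) + c2 (I2 - 3), in N/cm^2.

    ``invariants_shift`` is the pair (I1 - 3, I2 - 3); both must be >= 0.
    """
    i1s, i2s = float(invariants_shift[0]), float(invariants_shift[1])
    if i1s < 0 or i2s < 0:
        raise MeshValidationError("shifted invariants (I1-3, I2-3) must be non-negative")
    return float(params.c1 * i1s + params.c2 * i2s)


def synthetic_stress_field(mesh: SurfaceMesh, pressure: float = 120.0,
                           thickness: float = 1.9, noise_sd: float = 0.0,
                           seed: int = 0, z_window: float = 2.0) -> NodalField:
    """Laplace-law surrogate stress field for a roughly tubular surface.

    Per node, the local radius is the distance from the Z axis averaged
    over a z-window (``z_window`` mm wide bins, interpolated), and

        sigma = P * r / t   (converted to N/cm^2, 1 mmHg = 133.322 Pa)

    plus Gaussian noise with the given seed, clipped at zero so the result
    is a valid stress field. Deterministic per seed.

    Parameters use the reference loading of image-based AAA stress
    analysis: systolic pressure 120 mmHg, uniform wall thickness 1.9 mm.
    """
    if pressure <= 0 or thickness <= 0:
        raise MeshValidationError("pressure and thickness must be positive")
    if noise_sd < 0 or z_window <= 0:
        raise MeshValidationError("noise_sd must be >= 0 and z_window > 0")
    xy = mesh.nodes[:, :2]
    z = mesh.nodes[:, 2]
    r_node = np.linalg.norm(xy, axis=1)
    z_min, z_max = float(z.min()), float(z.max())
    n_bins = max(1, int(np.ceil((z_max - z_min) / z_window)))
    edges = np.linspace(z_min, z_max, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=r_node, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    occupied = counts > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    r_local = np.interp(z, centers[occupied], sums[occupied] / counts[occupied])

    p_ncm2 = pressure * MMHG_TO_N_PER_CM2
    stress = p_ncm2 * r_local / thickness
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stress = stress + rng.normal(0.0, noise_sd, size=len(stress))
    stress = np.maximum(stress, 0.0)
    return NodalField(stress, name="von_mises_stress")
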