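"""Parameterized synthetic AAA geometry and two-group cohort simulation.

Real AAA surface datasets are rarely shareable, so every algorithm in this
package is exercisable on synthetic fusiform sacs with *known* ground-truth
bounds: an open-ended tube along Z whose radius profile is a non-dilated
neck plus a compactly supported C2 bump,

    r(z) = r_neck + (r_max - r_neck) * bump(2 z / L_sac),

where ``bump`` is a raised cosine windowed by a quintic smoothstep over the
outermost ``edge_smoothing`` fraction of the sac half-length (so radius,
slope and curvature all vanish continuously at the ground-truth bounds
z = +/- L_sac / 2). An asymmetric sac offsets the cross-section centre
laterally by ``asymmetry * (r_max - r_neck) * bump``.

Cohorts emulate a stable/unstable comparison: per-case geometry is drawn by
jittering the base spec multiplicatively (neck radius varies the most,
mirroring the wide clinical range of non-aneurysmal aortic diameters), a
Laplace-law stress field is attached, and unstable cases receive a constant
stress offset inside the ground-truth sac only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import MeshValidationError
from .materials import synthetic_stress_field
from .mesh_core import NodalField, SurfaceMesh

__all__ = [
    "FusiformSpec",
    "CohortSpec",
    "CohortCase",
    "make_fusiform",
    "make_cylinder",
    "make_cohort",
]

# Relative-sd multipliers applied to CohortSpec.geometry_jitter per parameter.
# Neck (non-dilated aorta) diameter varies far more across patients, relative
# to its mean, than the repair-threshold sac diameter does.
_JITTER_WEIGHTS = {
    "neck_radius": 2.0,
    "max_radius": 0.8,
    "sac_length": 1.0,
    "neck_length": 1.0,
}


@dataclass(frozen=True)
class FusiformSpec:
    """Geometry of one synthetic fusiform sac (mm). Defaults: ~5 cm max
    diameter on a 2 cm neck, 60 mm sac with 25 mm necks per side."""

    neck_radius: float = 10.0
    max_radius: float = 25.0
    sac_length: float = 60.0
    neck_length: float = 25.0
    asymmetry: float = 0.0
    axial_resolution: int = 100
    circumferential_resolution: int = 64
    seed: int = 0
    edge_smoothing: float = 0.2  # fraction of the sac half-length

    def __post_init__(self):
        if not (self.max_radius > self.neck_radius > 0):
            raise MeshValidationError("require max_radius > neck_radius > 0")
        if self.sac_length <= 0 or self.neck_length <= 0:
            raise MeshValidationError("sac_length and neck_length must be positive")
        if not (0.0 <= self.asymmetry <= 1.0):
            raise MeshValidationError("asymmetry must lie in [0, 1]")
        if self.axial_resolution < 8 or self.circumferential_resolution < 8:
            raise MeshValidationError("resolutions must be >= 8")
        if not (0.0 < self.edge_smoothing < 1.0):
            raise MeshValidationError("edge_smoothing must lie in (0, 1)")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort: sizes, sac stress offset for the unstable group,
    multiplicative geometry jitter (fractional sd), nodal noise, seed."""

    n_stable: int = 20
    n_unstable: int = 20
    unstable_stress_offset: float = 3.0
    geometry_jitter: float = 0.15
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_stable < 1 or self.n_unstable < 1:
            raise MeshValidationError("group sizes must be >= 1")
        if self.unstable_stress_offset < 0:
            raise MeshValidationError("unstable_stress_offset must be >= 0")
        if self.geometry_jitter < 0 or self.noise_sd < 0:
            raise MeshValidationError("jitter and noise must be >= 0")


@dataclass
class CohortCase:
    case_id: str
    mesh: SurfaceMesh
    stress: NodalField
    label: str  # "stable" | "unstable"
    ground_truth: tuple[float, float]
    spec: FusiformSpec


def _smootherstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


def _bump(u: np.ndarray, edge_smoothing: float) -> np.ndarray:
    """C2 compact bump on [-1, 1]: raised cosine x quintic-smoothstep window."""
    u = np.asarray(u, dtype=np.float64)
    inside = np.abs(u) < 1.0
    out = np.zeros_like(u)
    ui = u[inside]
    window = _smootherstep((1.0 - np.abs(ui)) / edge_smoothing)
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * ui)) * window
    return out


def _revolve(z: np.ndarray, radius: np.ndarray, center_x: np.ndarray,
             circ: int, provenance: str) -> SurfaceMesh:
    """Triangulated open-ended tube from an axial profile (rings x circ grid)."""
    phi = np.linspace(0.0, 2.0 * np.pi, circ, endpoint=False)
    x = center_x[:, None] + radius[:, None] * np.cos(phi)[None, :]
    y = radius[:, None] * np.sin(phi)[None, :]
    zz = np.repeat(z[:, None], circ, axis=1)
    nodes = np.column_stack([x.ravel(), y.ravel(), zz.ravel()])

    n_ax = len(z)
    tris = []
    for i in range(n_ax - 1):
        base = i * circ
        nxt = (i + 1) * circ
        j = np.arange(circ)
        jp = (j + 1) % circ
        tris.append(np.column_stack([base + j, base + jp, nxt + j]))
        tris.append(np.column_stack([base + jp, nxt + jp, nxt + j]))
    triangles = np.vstack(tris)
    return SurfaceMesh(nodes, triangles, provenance=provenance)


def make_fusiform(spec: FusiformSpec = FusiformSpec()) -> tuple[SurfaceMesh, tuple[float, float]]:
    """Generate a fusiform sac surface plus its ground-truth sac bounds.

    Returns ``(mesh, (z_inf, z_sup))`` with bounds at +/- sac_length / 2,
    strictly inside the generated z-extent (necks exist on both sides).
    Fully deterministic for a given spec.
    """
    half_sac = spec.sac_length / 2.0
    z_half = half_sac + spec.neck_length
    z = np.linspace(-z_half, z_half, spec.axial_resolution)
    u = z / half_sac
    bump = _bump(u, spec.edge_smoothing)
    delta = spec.max_radius - spec.neck_radius
    radius = spec.neck_radius + delta * bump
    center_x = spec.asymmetry * delta * bump
    mesh = _revolve(z, radius, center_x, spec.circumferential_resolution,
                    provenance=f"synthetic fusiform seed={spec.seed}")
    return mesh, (-half_sac, half_sac)


def make_cylinder(radius: float = 10.0, length: float = 100.0,
                  axial_resolution: int = 50,
                  circumferential_resolution: int = 32) -> SurfaceMesh:
    """Open-ended constant-radius tube along Z, centred at the origin."""
    if radius <= 0 or length <= 0:
        raise MeshValidationError("radius and length must be positive")
    if axial_resolution < 8 or circumferential_resolution < 8:
        raise MeshValidationError("resolutions must be >= 8")
    z = np.linspace(-length / 2.0, length / 2.0, axial_resolution)
    r = np.full_like(z, float(radius))
    return _revolve(z, r, np.zeros_like(z), circumferential_resolution,
                    provenance="synthetic cylinder")


def _jitter_spec(base: FusiformSpec, rng: np.random.Generator,
                 jitter: float) -> FusiformSpec:
    factors = {}
    for name, weight in _JITTER_WEIGHTS.items():
        sd = weight * jitter
        # Clip at 2 sd so jittered specs stay geometrically valid.
        f = 1.0 + float(np.clip(rng.normal(0.0, sd), -2.0 * sd, 2.0 * sd)) if sd > 0 else 1.0
        factors[name] = f
    return replace(
        base,
        neck_radius=base.neck_radius * factors["neck_radius"],
        max_radius=base.max_radius * factors["max_radius"],
        sac_length=base.sac_length * factors["sac_length"],
        neck_length=base.neck_length * factors["neck_length"],
    )


def make_cohort(spec: CohortSpec = CohortSpec(),
                base: FusiformSpec | None = None,
                pressure: float = 120.0, thickness: float = 1.9) -> list[CohortCase]:
    """Simulate a stable/unstable cohort with known ground truth.

    Stable cases come first, then unstable. Each case jitters the base
    geometry, attaches a Laplace-law stress field (120 mmHg, 1.9 mm wall),
    and — for unstable cases — adds ``unstable_stress_offset`` to every
    node inside the ground-truth sac. Reproducible from (spec, seed).
    """
    if base is None:
        # Desk-scale resolution: cohort simulations trade mesh density for
        # the many cases a power/null study requires.
        base = FusiformSpec(asymmetry=0.2, axial_resolution=48,
                            circumferential_resolution=24)
    rng = np.random.default_rng(spec.seed)
    cases: list[CohortCase] = []
    labels = ["stable"] * spec.n_stable + ["unstable"] * spec.n_unstable
    for k, label in enumerate(labels):
        case_spec = _jitter_spec(base, rng, spec.geometry_jitter)
        stress_seed = int(rng.integers(0, 2**31 - 1))
        case_spec = replace(case_spec, seed=stress_seed)
        mesh, truth = make_fusiform(case_spec)
        stress = synthetic_stress_field(mesh, pressure=pressure, thickness=thickness,
                                        noise_sd=spec.noise_sd, seed=stress_seed)
        if label == "unstable" and spec.unstable_stress_offset > 0:
            z = mesh.nodes[:, 2]
            in_sac = (z >= truth[0]) & (z <= truth[1])
            vals = stress.values.copy()
            vals[in_sac] += spec.unstable_stress_offset
            stress = NodalField(vals, name=stress.name)
        cases.append(CohortCase(
            case_id=f"case_{k:03d}", mesh=mesh, stress=stress, label=label,
            ground_truth=truth, spec=case_spec,
        ))
    return cases
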