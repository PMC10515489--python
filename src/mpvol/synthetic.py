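"""Synthetic 3D particles with known volume, and their 2D projections.

Ground-truth engine for validating the 2D-to-3D volume models without
laboratory data.  A particle is a star-shaped solid: an ellipsoid with
semi-axes ``a >= b >= c`` whose radius is modulated by a smooth,
zero-mean random roughness field

    R(u) = r_ellipsoid(u) * (1 + amplitude * f(u))

where ``f`` is a band-limited spherical-harmonic field with unit
pointwise variance and an angular correlation scale that sets the
harmonic band (small scale -> high degrees -> micro-valleys and cracks).
Roughness 0 reproduces the exact ellipsoid.

Two independent volume oracles are provided (voxel counting on the
radial inside test, and the divergence-theorem sum over a triangulated
mesh of the same surface); they must agree within 1 %.

Projection follows the lowest-energy resting assumption of the
ellipsoid-based models: the particle is rotated so that its smallest
principal-axis extent is vertical, then orthographically projected and
rasterized at a given pixels-per-mm scale (default 40 px/mm, inside the
high-resolution imaging regime of 42-44 px/mm).  Repeated "throws"
re-project with a fresh random in-plane rotation and an optional flip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.interpolate import RegularGridInterpolator
from scipy.special import sph_legendre_p_all

from .shape_metrics import ParticleMask

__all__ = [
    "SyntheticParticle3D",
    "MixtureSpec",
    "SimulatedMixture",
    "VolumeOracle",
    "generate_particle",
    "true_volume",
    "project_lowest_energy",
    "simulate_mixture",
    "DEFAULT_SCALE_PX_MM",
]

DEFAULT_SCALE_PX_MM = 40.0
_THETA_N, _PHI_N = 181, 361  # angular grid for the radius table
_L_MIN = 2                   # lowest harmonic degree of the roughness band
_FIELD_CLIP = 3.0            # clip the unit-variance field at 3 sigma


def _roughness_field(l_max: int, rng: np.random.Generator,
                     theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Band-limited zero-mean random field on the (theta, phi) grid.

    Real spherical harmonics of degrees ``_L_MIN..l_max`` with iid
    standard-normal coefficients, evaluated separably (associated
    Legendre in theta, trigonometric in phi) and normalized to unit
    pointwise variance via the addition theorem.
    """
    degrees = np.arange(_L_MIN, l_max + 1)
    # normalized associated Legendre N_lm P_lm(cos theta): shape (l+1, 2m+1, n_theta)
    plm = sph_legendre_p_all(l_max, l_max, theta)[0]
    field = np.zeros((len(theta), len(phi)))
    cos_m = {m: np.cos(m * phi) for m in range(l_max + 1)}
    sin_m = {m: np.sin(m * phi) for m in range(1, l_max + 1)}
    for l in degrees:
        for m in range(0, l + 1):
            basis_theta = plm[l, m, :]  # (n_theta,)
            if m == 0:
                a = rng.standard_normal()
                field += a * basis_theta[:, None] * np.ones_like(phi)[None, :]
            else:
                a, b = rng.standard_normal(2)
                f_theta = math.sqrt(2.0) * basis_theta[:, None]
                field += f_theta * (a * cos_m[m][None, :] + b * sin_m[m][None, :])
    variance = float(np.sum(2 * degrees + 1) / (4 * math.pi))
    field /= math.sqrt(variance)
    return np.clip(field, -_FIELD_CLIP, _FIELD_CLIP)


@dataclass
class SyntheticParticle3D:
    """A rough ellipsoid defined by a radial surface table.

    The surface is ``R(theta, phi)`` on a regular angular grid; a
    triangulated mesh of the same surface is kept for the
    divergence-theorem volume and for inertia-based orientation.
    """

    a: float
    b: float
    c: float
    roughness: float
    angular_scale: float
    seed: int
    radius: np.ndarray = field(repr=False)
    theta: np.ndarray = field(repr=False)
    phi: np.ndarray = field(repr=False)
    mesh: trimesh.Trimesh = field(repr=False)
    particle_id: str = ""

    def __post_init__(self) -> None:
        self._interp = RegularGridInterpolator(
            (self.theta, self.phi), self.radius, method="linear",
            bounds_error=False, fill_value=None)

    @property
    def max_radius(self) -> float:
        return float(self.radius.max())

    def radius_at(self, points: np.ndarray) -> np.ndarray:
        """Surface radius along the directions of Cartesian ``points`` (N, 3)."""
        r = np.linalg.norm(points, axis=-1)
        cosang = np.divide(points[..., 2], r, out=np.zeros_like(r), where=r > 0)
        th = np.arccos(np.clip(cosang, -1, 1))
        ph = np.mod(np.arctan2(points[..., 1], points[..., 0]), 2 * math.pi)
        return self._interp(np.stack([th, ph], axis=-1))

    def contains(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points, axis=-1)
        return r <= self.radius_at(points)

    @property
    def volume_mm3(self) -> float:
        """True volume (mm^3): divergence-theorem sum over the surface mesh."""
        return float(self.mesh.volume)


@dataclass
class VolumeOracle:
    """Volume of one particle by two independent routes (mm^3)."""

    voxel_mm3: float
    mesh_mm3: float

    @property
    def relative_gap(self) -> float:
        return abs(self.voxel_mm3 - self.mesh_mm3) / self.mesh_mm3


def generate_particle(
    a: float, b: float, c: float,
    roughness: float = 0.0,
    angular_scale: float = 0.3,
    seed: int = 0,
    subdivisions: int = 5,
    particle_id: str = "",
) -> SyntheticParticle3D:
    """Build a rough ellipsoid with semi-axes ``a >= b >= c`` (mm).

    ``roughness`` is the perturbation amplitude as a fraction of the
    local radius (must be < 1; at 1 the surface risks self-intersection);
    ``angular_scale`` (radians) sets the correlation scale of the
    roughness — the harmonic band extends to ``l_max ~ pi/angular_scale``.
    Deterministic for a fixed seed.
    """
    if not (a >= b >= c > 0):
        raise ValueError(f"require a >= b >= c > 0, got {(a, b, c)}")
    if not 0.0 <= roughness < 1.0:
        raise ValueError(f"roughness must be in [0, 1), got {roughness}")
    theta = np.linspace(0.0, math.pi, _THETA_N)
    phi = np.linspace(0.0, 2 * math.pi, _PHI_N)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    ux = np.sin(tt) * np.cos(pp)
    uy = np.sin(tt) * np.sin(pp)
    uz = np.cos(tt)
    r_ell = 1.0 / np.sqrt((ux / a) ** 2 + (uy / b) ** 2 + (uz / c) ** 2)
    if roughness > 0:
        l_max = max(_L_MIN + 1, int(round(math.pi / angular_scale)))
        rng = np.random.default_rng(seed)
        f = _roughness_field(l_max, rng, theta, phi)
        f[:, -1] = f[:, 0]          # periodic seam
        f[0, :] = f[0, 0]           # single-valued poles
        f[-1, :] = f[-1, 0]
        # keep the radius strictly positive even at high amplitudes
        f = np.clip(f, -0.95 / roughness, 0.95 / roughness)
        radius = r_ell * (1.0 + roughness * f)
    else:
        radius = r_ell
    radius = np.maximum(radius, 1e-6)
    part = SyntheticParticle3D(
        a=a, b=b, c=c, roughness=roughness, angular_scale=angular_scale,
        seed=seed, radius=radius, theta=theta, phi=phi,
        mesh=_surface_mesh(radius, theta, phi, subdivisions),
        particle_id=particle_id,
    )
    return part


def _surface_mesh(radius: np.ndarray, theta: np.ndarray, phi: np.ndarray,
                  subdivisions: int) -> trimesh.Trimesh:
    """Triangulated surface with vertices on the interpolated radius table."""
    base = trimesh.creation.icosphere(subdivisions=subdivisions)
    interp = RegularGridInterpolator((theta, phi), radius, method="linear",
                                     bounds_error=False, fill_value=None)
    v = base.vertices
    th = np.arccos(np.clip(v[:, 2], -1, 1))
    ph = np.mod(np.arctan2(v[:, 1], v[:, 0]), 2 * math.pi)
    r = interp(np.stack([th, ph], axis=-1))
    return trimesh.Trimesh(vertices=v * r[:, None], faces=base.faces, process=False)


def true_volume(particle: SyntheticParticle3D,
                voxel_pitch: float | None = None) -> VolumeOracle:
    """Particle volume by voxel counting and by the mesh divergence sum.

    The two estimates are independent discretizations of the same
    surface and must agree within 1 % at the default resolution
    (voxel pitch = c/20, capped at ~4e6 voxels).
    """
    mesh_v = particle.volume_mm3
    if not particle.mesh.is_watertight:
        raise ValueError("particle surface is not closed")
    pitch = voxel_pitch or particle.c / 20.0
    rmax = particle.max_radius + pitch
    n = int(math.ceil(2 * rmax / pitch))
    while n ** 3 > 4e6:
        pitch *= 1.26
        n = int(math.ceil(2 * rmax / pitch))
    axis = (np.arange(n) - (n - 1) / 2.0) * pitch
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    count = 0
    for z in axis:  # slice-wise to bound memory
        pts = np.stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)], axis=-1)
        count += int(particle.contains(pts).sum())
    return VolumeOracle(voxel_mm3=count * pitch ** 3, mesh_mm3=mesh_v)


def _alignment_rotation(particle: SyntheticParticle3D,
                        pre_rotation: np.ndarray | None) -> np.ndarray:
    """Rotation matrix (rows = lab axes in particle frame) putting the
    smallest principal-axis extent along lab z and the largest along x."""
    mesh = particle.mesh
    if pre_rotation is not None:
        mesh = trimesh.Trimesh(vertices=mesh.vertices @ pre_rotation.T,
                               faces=mesh.faces, process=False)
    vecs = np.asarray(mesh.principal_inertia_vectors)
    proj = mesh.vertices @ vecs.T
    extents = proj.max(axis=0) - proj.min(axis=0)
    order = np.argsort(extents)[::-1]  # largest extent first -> lab x
    rot = vecs[order]
    if np.linalg.det(rot) < 0:
        rot[1] *= -1.0
    if pre_rotation is not None:
        rot = rot @ pre_rotation
    return rot


def project_lowest_energy(
    particle: SyntheticParticle3D,
    scale: float = DEFAULT_SCALE_PX_MM,
    in_plane_deg: float = 0.0,
    flip: bool = False,
    pre_rotation: np.ndarray | None = None,
) -> ParticleMask:
    """Orthographic projection of the particle resting at lowest energy.

    The particle is rotated so its smallest principal-axis extent is
    vertical (the resting pose the ellipsoid models assume), optionally
    flipped upside down and spun in-plane (a new "throw"), and the
    silhouette is rasterized at ``scale`` px/mm.  A coarse mask (< 5 px
    across the minor extent) is flagged, not rejected.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rot = _alignment_rotation(particle, pre_rotation)
    if flip:
        rot = np.diag([1.0, -1.0, -1.0]) @ rot
    psi = math.radians(in_plane_deg)
    rz = np.array([[math.cos(psi), -math.sin(psi), 0.0],
                   [math.sin(psi), math.cos(psi), 0.0],
                   [0.0, 0.0, 1.0]])
    rot = rz @ rot
    # lab-frame extents from the rotated mesh
    verts = particle.mesh.vertices @ rot.T
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    pad = 2.0 / scale
    nx = int(math.ceil((hi[0] - lo[0] + 2 * pad) * scale)) + 1
    ny = int(math.ceil((hi[1] - lo[1] + 2 * pad) * scale)) + 1
    xs = lo[0] - pad + (np.arange(nx) + 0.5) / scale
    ys = lo[1] - pad + (np.arange(ny) + 0.5) / scale
    nz = 33
    zs = np.linspace(lo[2], hi[2], nz)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    mask = np.zeros(xx.shape, dtype=bool)
    inv = rot.T  # lab -> particle
    for z in zs:
        todo = ~mask
        if not todo.any():
            break
        pts_lab = np.stack([xx[todo], yy[todo], np.full(int(todo.sum()), z)], axis=-1)
        pts = pts_lab @ inv.T
        mask[todo] |= particle.contains(pts)
    # masks are (row, col); use rows = y (image convention), cols = x
    mask = mask.T
    coarse = min(particle.b, particle.c) * 2 * scale < 5
    return ParticleMask(np.pad(mask, 1), scale=scale,
                        image_id=particle.particle_id or "synthetic", coarse=coarse)


@dataclass
class MixtureSpec:
    """What a simulated particle mixture looks like.

    Defaults emulate a sieved 2-5 mm secondary-microplastic group:
    major axes uniform over the sieve range, aspect ratios uniform in
    1-3 (the full observed range across groups runs to 13), and the
    Simon-consistent height rule ``c = b**2 / a`` unless overridden.
    """

    n: int = 250
    major_range: tuple[float, float] = (2.0, 5.0)     # full major axis, mm
    aspect_range: tuple[float, float] = (1.0, 3.0)    # a / b
    roughness: float = 0.0
    angular_scale: float = 0.3
    height_rule: str = "simon"        # "simon": c = b^2/a ; "uniform": c ~ U(0.5, 1)*b
    scale: float = DEFAULT_SCALE_PX_MM
    seed: int = 0
    subdivisions: int = 4

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("particle count must be >= 1")
        if self.major_range[0] <= 0 or self.aspect_range[0] < 1:
            raise ValueError("size and aspect distributions must yield positive dimensions")
        if self.height_rule not in ("simon", "uniform"):
            raise ValueError(f"unknown height rule {self.height_rule!r}")


@dataclass
class SimulatedMixture:
    """Generated particles, their canonical-pose masks and the truth table."""

    spec: MixtureSpec
    particles: list[SyntheticParticle3D]
    masks: list[ParticleMask]
    truth: pd.DataFrame

    @property
    def true_collective_mm3(self) -> float:
        return float(self.truth["true_volume_mm3"].sum())

    def throw(self, seed: int) -> list[ParticleMask]:
        """Re-project every particle with a fresh in-plane pose."""
        rng = np.random.default_rng(seed)
        masks = []
        for p in self.particles:
            masks.append(project_lowest_energy(
                p, scale=self.spec.scale,
                in_plane_deg=float(rng.uniform(0, 360)),
                flip=bool(rng.integers(2)),
            ))
        return masks


def simulate_mixture(spec: MixtureSpec) -> SimulatedMixture:
    """Generate a mixture with known per-particle and collective volume.

    Deterministic under ``spec.seed``.  The returned truth table pairs
    every mask (canonical pose, one per particle) with its true volume;
    use :meth:`SimulatedMixture.throw` for repeat depositions.
    """
    rng = np.random.default_rng(spec.seed)
    particles, masks, rows = [], [], []
    for i in range(spec.n):
        major = rng.uniform(*spec.major_range)
        a = major / 2.0
        b = a / rng.uniform(*spec.aspect_range)
        if spec.height_rule == "simon":
            c = b * b / a
        else:
            c = b * float(rng.uniform(0.5, 1.0))
        pid = f"p{i:03d}"
        pseed = int(rng.integers(0, 2 ** 31 - 1))
        p = generate_particle(a, b, c, roughness=spec.roughness,
                              angular_scale=spec.angular_scale, seed=pseed,
                              subdivisions=spec.subdivisions, particle_id=pid)
        particles.append(p)
        masks.append(project_lowest_energy(p, scale=spec.scale))
        rows.append({"id": pid, "a_mm": a, "b_mm": b, "c_mm": c,
                     "roughness": spec.roughness, "seed": pseed,
                     "true_volume_mm3": p.volume_mm3})
    return SimulatedMixture(spec=spec, particles=particles, masks=masks,
                            truth=pd.DataFrame(rows))
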