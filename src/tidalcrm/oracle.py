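"""Independent validators for the contact engine.

Two cross-checks that share no code path with the engine's analytic distance
queries:

* a closed-form phase-coverage probability for a point-sized animal meeting a
  rotating blade sector (``closed_form_point_cp``), and
* a dense fixed-step brute-force detector that samples device surfaces with
  points (``brute_force_detect``), plus a point-sampled clearance estimator
  (``sampled_clearance``) for static pose checks.

These are test-support tools, not a production fast path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .engine import Scenario, SimulationInstance, _prepare
from .geometry import (KIND_SEGMENT, KIND_SPHERE, KIND_TRI, Component,
                       DeviceAssembly, RotorSpec, SealBody)


@dataclass(frozen=True)
class PointEncounterSpec:
    """Inputs of the closed-form encounter probability for a point animal.

    ``phi_rad`` is the blade's angular width at radial position ``r_m``;
    ``axial_extent_m`` is the animal's axial length plus the blade thickness
    (the axial overlap window is that extent divided by the approach speed).
    """

    r_m: float
    approach_speed_ms: float
    omega_rads: float
    n_blades: int
    phi_rad: float
    axial_extent_m: float

    def __post_init__(self):
        if self.r_m <= 0:
            raise ValueError("r_m must be > 0")
        if min(self.omega_rads, self.phi_rad, self.axial_extent_m) < 0:
            raise ValueError("omega, phi and axial extent must be >= 0")
        if self.n_blades < 1:
            raise ValueError("n_blades must be >= 1")


def closed_form_point_cp(spec: PointEncounterSpec) -> float:
    """Fraction of uniform initial phases for which a blade sector sweeps the
    point during its axial overlap window:

        CP = min(1, n * (phi + omega * a / v) / (2 pi))

    Each of the ``n`` blades covers the point's angular position for ``phi``
    radians of phase plus the ``omega * a / v`` radians it sweeps while the
    animal's axial extent overlaps the rotor plane.
    """
    if spec.approach_speed_ms <= 0:
        raise ValueError("approach speed must be > 0 (infinite exposure)")
    covered = spec.n_blades * (
        spec.phi_rad
        + spec.omega_rads * spec.axial_extent_m / spec.approach_speed_ms)
    return min(1.0, covered / (2.0 * math.pi))


def make_sector_device(n_blades: int = 3, root_radius_m: float = 1.0,
                       tip_radius_m: float = 9.0, phi_rad: float = 0.25,
                       thickness_m: float = 0.02, rpm: float = 8.0,
                       sense: int = 1, n_arc: int = 4) -> DeviceAssembly:
    """Constant-angular-width annular-sector blades (oracle test geometry).

    Unlike the tapered production blade, the angular width phi of a sector is
    exact at every radius, which is what the closed form needs.  The sector is
    triangulated into ``n_arc`` angular panels (the straight radial side edges
    are exact; arc chords only perturb the inner/outer boundary by the sagitta,
    < 1 mm at the defaults).
    """
    rotor = RotorSpec(n_blades=n_blades, radius_m=tip_radius_m, rpm=rpm,
                      sense=sense)
    comps = []
    for j in range(n_blades):
        ref = 2.0 * math.pi * j / n_blades
        angs = ref + np.linspace(-phi_rad / 2.0, phi_rad / 2.0, n_arc + 1)
        tris = []
        for k in range(n_arc):
            a0, a1 = angs[k], angs[k + 1]
            p00 = np.array([0.0, root_radius_m * math.cos(a0),
                            root_radius_m * math.sin(a0)])
            p01 = np.array([0.0, root_radius_m * math.cos(a1),
                            root_radius_m * math.sin(a1)])
            p10 = np.array([0.0, tip_radius_m * math.cos(a0),
                            tip_radius_m * math.sin(a0)])
            p11 = np.array([0.0, tip_radius_m * math.cos(a1),
                            tip_radius_m * math.sin(a1)])
            tris.append([p00, p01, p11])
            tris.append([p00, p11, p10])
        comps.append(Component(
            component_id=f"sector_{j}", kind=KIND_TRI, motion="rotating",
            data=np.array(tris), inflation=thickness_m / 2.0, ref_angle=ref))
    return DeviceAssembly(components=comps, rotor=rotor)


# ---------------------------------------------------------------------------
# point sampling of device surfaces
# ---------------------------------------------------------------------------

def _sample_triangles(tris: np.ndarray, n: int, rng) -> np.ndarray:
    areas = 0.5 * np.linalg.norm(
        np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0]), axis=1)
    total = areas.sum()
    if total <= 0:
        return tris[:, 0]
    counts = np.maximum(1, np.round(n * areas / total).astype(int))
    pts = []
    for tri, m in zip(tris, counts):
        r1 = np.sqrt(rng.random(m))
        r2 = rng.random(m)
        a, b, c = tri
        pts.append((1 - r1)[:, None] * a
                   + (r1 * (1 - r2))[:, None] * b
                   + (r1 * r2)[:, None] * c)
    return np.concatenate(pts)


def _sample_rounded_plate(tris: np.ndarray, inflation: float, n: int,
                          rng) -> np.ndarray:
    """Points on the surface of a rounded plate (triangles + inflation).

    The surface decomposes into flat faces (core points offset along the two
    normals), quarter-cylinder edges (points along each edge swept in angle)
    and sphere patches at the vertices.  Sampling each part explicitly keeps
    the estimator's bias quadratic in the sample spacing even for edge-on
    closest-point configurations.  Points generated on interior (shared)
    edges fall inside the solid and are harmless (never the pairwise argmin).
    """
    faces = _sample_triangles(tris, n, rng)
    normals = np.cross(tris[:, 1] - tris[:, 0], tris[:, 2] - tris[:, 0])
    areas = 0.5 * np.linalg.norm(normals, axis=1)
    # assign each face sample its triangle normal by re-deriving counts the
    # same way _sample_triangles allocated them
    counts = np.maximum(1, np.round(n * areas / areas.sum()).astype(int))
    unit_n = normals / (2 * areas[:, None] + 1e-300)
    face_n = np.repeat(unit_n, counts, axis=0)[:len(faces)]
    sign = np.where(rng.random(len(faces)) < 0.5, 1.0, -1.0)[:, None]
    pts = [faces + sign * inflation * face_n]
    # rounded edges: full circles around each edge (half land interior)
    edges = tris[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2, 3)
    edge_vec = edges[:, 1] - edges[:, 0]
    lengths = np.linalg.norm(edge_vec, axis=1)
    m_total = max(n // 2, 100)
    for (a, _b), ev, L in zip(edges, edge_vec, lengths):
        m = max(4, int(m_total * L / lengths.sum()))
        t = rng.random(m)[:, None]
        psi = rng.uniform(0, 2 * math.pi, m)
        e_u = ev / (L + 1e-300)
        ref = np.array([0.0, 0.0, 1.0]) if abs(e_u[2]) < 0.9 \
            else np.array([1.0, 0.0, 0.0])
        b1 = np.cross(e_u, ref)
        b1 /= np.linalg.norm(b1)
        b2 = np.cross(e_u, b1)
        ring = (np.cos(psi)[:, None] * b1[None, :]
                + np.sin(psi)[:, None] * b2[None, :])
        pts.append(a[None, :] + t * ev[None, :] + inflation * ring)
    # vertex sphere patches
    verts = tris.reshape(-1, 3)
    m_v = 30
    v = rng.normal(size=(len(verts) * m_v, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts.append(np.repeat(verts, m_v, axis=0) + inflation * v)
    return np.concatenate(pts)


def sample_device_core_points(device: DeviceAssembly, n_per_component: int,
                              rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample each component's *core* geometry, carrying its exact inflation
    as a per-point radius.

    Sampling the core (triangle areas and boundary edges, segment axes, sphere
    centres) with the inflation as a point radius makes the only error the
    tangential sampling spacing; the normal offset is exact.
    Returns (points (m, 3), radii (m,), rotating (m,) uint8).
    """
    pts, radii, rot = [], [], []
    for comp in device.components:
        is_rot = 1 if comp.motion == "rotating" else 0
        if comp.kind == KIND_TRI:
            p = _sample_triangles(comp.data, n_per_component, rng)
            # boundary edges sampled explicitly: edge-on contacts otherwise
            # suffer first-order (rather than quadratic) sampling error
            edges = comp.data[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2, 3)
            m_e = max(2, n_per_component // (4 * len(edges)))
            t = rng.random((len(edges), m_e))[..., None]
            ep = edges[:, None, 0] * (1 - t) + edges[:, None, 1] * t
            p = np.concatenate([p, ep.reshape(-1, 3)])
        elif comp.kind == KIND_SPHERE:
            p = comp.data  # centre point with the sphere radius is exact
        else:
            t = np.linspace(0.0, 1.0, max(2, n_per_component))[:, None]
            p = comp.data[0] * (1 - t) + comp.data_b[0] * t
        pts.append(p)
        radii.append(np.full(len(p), comp.inflation))
        rot.append(np.full(len(p), is_rot, np.uint8))
    return (np.concatenate(pts), np.concatenate(radii), np.concatenate(rot))


def _sample_capsule_surface(p0, p1, radius, n, rng):
    """Uniform points on a capsule surface (cylinder + two hemispheres)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    u = axis / length if length > 1e-12 else np.array([1.0, 0.0, 0.0])
    # orthonormal frame
    a = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    area_cyl = 2 * math.pi * radius * length
    area_caps = 4 * math.pi * radius ** 2
    n_cyl = int(round(n * area_cyl / (area_cyl + area_caps)))
    n_caps = n - n_cyl
    t = rng.random(n_cyl)
    ang = rng.uniform(0, 2 * math.pi, n_cyl)
    cyl = (p0[None, :] + t[:, None] * axis[None, :]
           + radius * (np.cos(ang)[:, None] * e1[None, :]
                       + np.sin(ang)[:, None] * e2[None, :]))
    # uniform sphere points, split by hemisphere onto the two caps
    v = rng.normal(size=(n_caps, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    along = v @ u
    base = np.where(along[:, None] >= 0, p1[None, :], p0[None, :])
    caps = base + radius * v
    return np.concatenate([cyl, caps])


def sampled_clearance(seal: SealBody, device: DeviceAssembly,
                      rotor_angle: float = 0.0, n_per_surface: int = 20000,
                      seed: int = 0) -> float:
    """Brute-force minimum-distance estimate from dense surface sampling.

    Samples >= ``n_per_surface`` points on the seal capsule surface and on
    every device component surface (core samples pushed out by the inflation
    radius), then takes the minimum pairwise distance via a KD-tree.  Always
    an overestimate of the true minimum; the bias is the sampling spacing
    folded through the local surface curvature.
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    p0, p1 = seal.core_endpoints()
    seal_pts = _sample_capsule_surface(p0, p1, seal.radius, n_per_surface, rng)
    dev_pts = []
    ca, sa = math.cos(rotor_angle), math.sin(rotor_angle)
    hub = device.hub
    for comp in device.components:
        if comp.kind == KIND_TRI:
            if comp.inflation > 0:
                core = _sample_rounded_plate(comp.data, comp.inflation,
                                             n_per_surface, rng)
            else:
                core = _sample_triangles(comp.data, n_per_surface, rng)
        elif comp.kind == KIND_SPHERE:
            v = rng.normal(size=(n_per_surface, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            core = comp.data[0][None, :] + comp.inflation * v
        else:
            core = _sample_capsule_surface(comp.data[0], comp.data_b[0],
                                           comp.inflation, n_per_surface, rng)
        if comp.motion == "rotating":
            y = core[:, 1] - hub[1]
            z = core[:, 2] - hub[2]
            core = np.column_stack([core[:, 0],
                                    hub[1] + ca * y - sa * z,
                                    hub[2] + sa * y + ca * z])
        dev_pts.append(core)
    dev_pts = np.concatenate(dev_pts)
    tree = cKDTree(dev_pts)
    d, _ = tree.query(seal_pts, k=1)
    return float(d.min())


# ---------------------------------------------------------------------------
# brute-force transit detector
# ---------------------------------------------------------------------------

def brute_force_detect(instance: SimulationInstance, scenario: Scenario,
                       dt: float = 1e-3, n_per_component: int = 10000,
                       seed: int = 0,
                       _points=None) -> tuple[bool, float | None]:
    """Fixed-step transit detector by dense device-point sampling.

    Steps the full configuration at fixed ``dt``; a transit is collided at the
    first step where any sampled device point (core sample + exact inflation
    radius) touches the exact seal capsule.  Returns (collided, t_contact).

    ``_points`` allows reusing one sampled point set across many instances.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    prep = _prepare(scenario)
    if _points is None:
        rng = np.random.default_rng(seed)
        _points = sample_device_core_points(prep.device, n_per_component, rng)
    pts, radii, rot = _points
    n_steps = int(math.ceil(prep.t_end / dt)) + 1
    x_lo, x_hi = prep.x_lo, prep.x_hi
    hit, istep = _kernels.brute_force_scan(
        instance.start_y, instance.start_z, prep.x0, prep.v,
        prep.seal_half, prep.seal_r, instance.phase_rad, prep.omega,
        dt, n_steps, np.ascontiguousarray(pts), np.ascontiguousarray(radii),
        np.ascontiguousarray(rot), prep.compiled.hub[1], prep.compiled.hub[2],
        x_lo, x_hi)
    return (True, istep * dt) if hit else (False, None)
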