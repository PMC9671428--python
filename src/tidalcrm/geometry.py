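"""Animal and device geometry.

The animal is a capsule (a cylinder with hemispherical caps) matching the two
published dimensions of an adult harbour seal: nose-to-tail length and maximum
body diameter.  The turbine is a parametric stand-in for a three-bladed
horizontal-axis tidal turbine: flat tapered blade plates, a spherical hub, and
a static foundation (vertical monopile plus a downstream nacelle cylinder).
An arbitrary STL/OBJ triangle mesh can replace the parametric device.

Coordinate convention (right-handed): +X is the flow/approach direction and the
rotor axis; +Z is up; the rotor plane passes through the hub centre; rotor
angles are in radians, measured counterclockwise viewed from upstream, with
``sense`` flipping the handedness.

Every component reduces to an *inflated primitive* — a core point, segment or
triangle plus an inflation radius — so minimum-distance queries are exact
closed forms and the clearance sign is exact through contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

_X = np.array([1.0, 0.0, 0.0])

KIND_TRI = 0
KIND_SPHERE = 1
KIND_SEGMENT = 2


def _as_vec3(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SealSpec:
    """Animal dimensions: adult harbour seal defaults (1.41 m x 0.34 m)."""

    length_m: float = 1.41
    width_m: float = 0.34

    def __post_init__(self):
        if not (self.length_m > self.width_m > 0):
            raise ValueError(
                f"require length_m > width_m > 0, got length={self.length_m}, "
                f"width={self.width_m}")

    @property
    def radius_m(self) -> float:
        return self.width_m / 2.0

    @property
    def core_half_length_m(self) -> float:
        """Half-length of the capsule's core segment."""
        return (self.length_m - self.width_m) / 2.0


@dataclass(frozen=True)
class RotorSpec:
    """Rotor layout: blade count, tip radius, rotation rate and handedness."""

    n_blades: int = 3
    radius_m: float = 9.0
    rpm: float = 8.0
    hub_center: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (1.0, 0.0, 0.0)
    sense: int = 1

    def __post_init__(self):
        if self.n_blades < 1:
            raise ValueError(f"n_blades must be >= 1, got {self.n_blades}")
        if self.radius_m <= 0:
            raise ValueError(f"radius_m must be > 0, got {self.radius_m}")
        if self.rpm < 0:
            raise ValueError(f"rpm must be >= 0, got {self.rpm}")
        ax = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
            raise ValueError("rotor axis must be a unit vector")
        if not np.allclose(ax, _X, atol=1e-12):
            raise ValueError(
                "this implementation fixes the rotor axis to +X (the flow "
                "direction); rotate your scenario into that frame")
        if self.sense not in (1, -1):
            raise ValueError(f"sense must be +1 or -1, got {self.sense}")

    @property
    def hub(self) -> np.ndarray:
        return np.asarray(self.hub_center, dtype=float)


@dataclass(frozen=True)
class BladeSpec:
    """Flat tapered plate stand-in for a turbine blade.

    The chord varies linearly along the span; the plate is realised as core
    triangles in the rotor plane inflated by ``thickness_m / 2``, i.e. a plate
    of the stated thickness with rounded edges.  The planform is clipped so the
    plate *surface* never exceeds the rotor tip radius.
    """

    root_radius_m: float = 1.0
    tip_radius_m: float = 9.0
    root_chord_m: float = 1.6
    tip_chord_m: float = 0.8
    thickness_m: float = 0.12

    def __post_init__(self):
        if not (0 <= self.root_radius_m < self.tip_radius_m):
            raise ValueError("require 0 <= root_radius_m < tip_radius_m")
        if min(self.root_chord_m, self.tip_chord_m, self.thickness_m) <= 0:
            raise ValueError("chords and thickness must be > 0")


@dataclass(frozen=True)
class FoundationSpec:
    """Static support structure: vertical monopile + downstream nacelle."""

    pile_radius_m: float = 1.5
    pile_top_m: float = 0.0
    pile_bottom_m: float = -11.5
    nacelle_radius_m: float = 1.5
    nacelle_length_m: float = 5.0

    def __post_init__(self):
        if self.pile_top_m <= self.pile_bottom_m:
            raise ValueError("require pile_top_m > pile_bottom_m")
        if min(self.pile_radius_m, self.nacelle_radius_m,
               self.nacelle_length_m) <= 0:
            raise ValueError("foundation radii/length must be > 0")


# ---------------------------------------------------------------------------
# bodies
# ---------------------------------------------------------------------------

@dataclass
class SealBody:
    """A posed seal capsule: centre position and unit travel/body axis."""

    spec: SealSpec
    center: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        self.center = _as_vec3(self.center, "center")
        ax = _as_vec3(self.axis, "axis")
        n = np.linalg.norm(ax)
        if n < 1e-12:
            raise ValueError("seal axis must be nonzero")
        self.axis = ax / n

    @property
    def nose(self) -> np.ndarray:
        return self.center + (self.spec.length_m / 2.0) * self.axis

    @property
    def tail(self) -> np.ndarray:
        return self.center - (self.spec.length_m / 2.0) * self.axis

    @property
    def radius(self) -> float:
        return self.spec.radius_m

    def core_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        h = self.spec.core_half_length_m
        return self.center - h * self.axis, self.center + h * self.axis


def make_seal(spec: SealSpec, center, axis) -> SealBody:
    """Pose a capsule seal with its nose on the +axis end."""
    return SealBody(spec=spec, center=np.asarray(center, float),
                    axis=np.asarray(axis, float))


@dataclass
class Component:
    """One device component: a set of same-kind inflated primitives."""

    component_id: str
    kind: int                      # KIND_TRI / KIND_SPHERE / KIND_SEGMENT
    motion: str                    # "rotating" | "static"
    # triangles: (n, 3, 3); spheres: centers (n, 3); segments: a (n,3), b (n,3)
    data: np.ndarray
    data_b: np.ndarray | None = None
    inflation: float = 0.0
    ref_angle: float = 0.0         # angular culling reference (rotating tris)

    def __post_init__(self):
        if self.motion not in ("rotating", "static"):
            raise ValueError(f"motion tag must be rotating/static, got "
                             f"{self.motion!r}")


@dataclass
class Clearance:
    """Signed separation between seal and device (negative = penetration)."""

    distance_m: float
    point_on_seal: np.ndarray
    point_on_device: np.ndarray
    component_id: str


@dataclass
class DeviceAssembly:
    components: list
    rotor: RotorSpec | None = None
    _compiled: "CompiledDevice | None" = field(default=None, repr=False)

    def __post_init__(self):
        if self.rotor is None:
            for c in self.components:
                if c.motion == "rotating":
                    raise ValueError(
                        "rotating components require a RotorSpec")

    @property
    def hub(self) -> np.ndarray:
        if self.rotor is not None:
            return self.rotor.hub
        return np.zeros(3)

    def compiled(self) -> "CompiledDevice":
        if self._compiled is None:
            self._compiled = compile_device(self)
        return self._compiled

    def component(self, component_id: str) -> Component:
        for c in self.components:
            if c.component_id == component_id:
                return c
        raise KeyError(f"unknown component_id {component_id!r}")


# ---------------------------------------------------------------------------
# parametric construction
# ---------------------------------------------------------------------------

def _blade_triangles(blade: BladeSpec, rotor: RotorSpec, angle: float,
                     n_panels: int = 8) -> np.ndarray:
    """Core triangles of one blade plate posed at rotor angle ``angle``.

    The plate lies in the rotor plane, spanwise radial, chord tangential.  The
    outer edge sits at span sqrt(R_eff^2 - (tip_chord/2)^2) with
    R_eff = tip_radius - thickness/2, so that after inflation by thickness/2
    the plate surface reaches, and never exceeds, the rotor tip radius.
    """
    hub = rotor.hub
    r_eff = blade.tip_radius_m - blade.thickness_m / 2.0
    half_tip = blade.tip_chord_m / 2.0
    if r_eff <= half_tip:
        raise ValueError("tip chord too large for rotor radius")
    s_out = math.sqrt(r_eff * r_eff - half_tip * half_tip)
    s_in = blade.root_radius_m
    if s_out <= s_in:
        raise ValueError("blade span collapses; check radii/chord")
    e_span = np.array([0.0, math.cos(angle), math.sin(angle)])
    e_chord = np.array([0.0, -math.sin(angle), math.cos(angle)])
    s_vals = np.linspace(s_in, s_out, n_panels + 1)
    chord = np.interp(s_vals, [s_in, s_out],
                      [blade.root_chord_m, blade.tip_chord_m])
    tris = []
    for p in range(n_panels):
        s0, s1 = s_vals[p], s_vals[p + 1]
        c0, c1 = chord[p] / 2.0, chord[p + 1] / 2.0
        v00 = hub + s0 * e_span - c0 * e_chord
        v01 = hub + s0 * e_span + c0 * e_chord
        v10 = hub + s1 * e_span - c1 * e_chord
        v11 = hub + s1 * e_span + c1 * e_chord
        tris.append([v00, v01, v11])
        tris.append([v00, v11, v10])
    return np.array(tris)


def make_device(rotor: RotorSpec, blade: BladeSpec,
                foundation: FoundationSpec | None = None,
                hub_radius_m: float = 1.0) -> DeviceAssembly:
    """Assemble the parametric turbine.

    ``n_blades`` identical plates equally spaced about the rotor axis, a
    spherical hub (rotating — its surface speed is omega*r of the contact
    point), and optionally the static foundation.
    """
    if not math.isclose(blade.tip_radius_m, rotor.radius_m,
                        rel_tol=0, abs_tol=1e-9):
        raise ValueError(
            f"blade tip radius ({blade.tip_radius_m}) must equal rotor "
            f"radius ({rotor.radius_m})")
    hub = rotor.hub
    comps: list[Component] = []
    for j in range(rotor.n_blades):
        ang = 2.0 * math.pi * j / rotor.n_blades
        comps.append(Component(
            component_id=f"blade_{j}", kind=KIND_TRI, motion="rotating",
            data=_blade_triangles(blade, rotor, ang),
            inflation=blade.thickness_m / 2.0, ref_angle=ang))
    if hub_radius_m > 0:
        comps.append(Component(
            component_id="hub", kind=KIND_SPHERE, motion="rotating",
            data=hub.reshape(1, 3), inflation=hub_radius_m))
    if foundation is not None:
        pa = np.array([hub[0], hub[1], foundation.pile_bottom_m])
        pb = np.array([hub[0], hub[1], foundation.pile_top_m])
        comps.append(Component(
            component_id="pile", kind=KIND_SEGMENT, motion="static",
            data=pa.reshape(1, 3), data_b=pb.reshape(1, 3),
            inflation=foundation.pile_radius_m))
        na = hub.copy()
        nb = hub + np.array([foundation.nacelle_length_m, 0.0, 0.0])
        comps.append(Component(
            component_id="nacelle", kind=KIND_SEGMENT, motion="static",
            data=na.reshape(1, 3), data_b=nb.reshape(1, 3),
            inflation=foundation.nacelle_radius_m))
    return DeviceAssembly(components=comps, rotor=rotor)


def load_device_mesh(path, motion_tags="static",
                     rotor: RotorSpec | None = None) -> DeviceAssembly:
    """Load an STL/OBJ triangle mesh as device geometry.

    ``motion_tags`` is either a single tag applied to every mesh component or a
    mapping ``{geometry_name: "rotating"|"static"}``.  Distance queries operate
    on the raw triangles (zero inflation).
    """
    import trimesh

    loaded = trimesh.load(str(path))
    if isinstance(loaded, trimesh.Scene):
        geoms = dict(loaded.geometry)
    else:
        geoms = {"mesh": loaded}
    comps = []
    for name, mesh in geoms.items():
        if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
            raise ValueError(f"mesh component {name!r} has no triangles")
        tag = motion_tags if isinstance(motion_tags, str) \
            else motion_tags.get(name, "static")
        tris = mesh.triangles.astype(float)
        comps.append(Component(component_id=name, kind=KIND_TRI, motion=tag,
                               data=np.array(tris), inflation=0.0))
    if not comps:
        raise ValueError(f"no mesh geometry found in {path}")
    return DeviceAssembly(components=comps, rotor=rotor)


# ---------------------------------------------------------------------------
# compiled (array) form used by the kernels
# ---------------------------------------------------------------------------

@dataclass
class CompiledDevice:
    """Flat array view of a DeviceAssembly for the numba kernels."""

    tri_v: np.ndarray
    tri_inf: np.ndarray
    tri_rot: np.ndarray
    tri_comp: np.ndarray
    tri_ref: np.ndarray
    tri_half: np.ndarray        # angular half-extent about ref (pi = no cull)
    tri_rmin: np.ndarray        # radial band of the core triangle
    tri_rmax: np.ndarray
    sph_c: np.ndarray
    sph_r: np.ndarray
    sph_rot: np.ndarray
    sph_comp: np.ndarray
    seg_a: np.ndarray
    seg_b: np.ndarray
    seg_r: np.ndarray
    seg_rot: np.ndarray
    seg_comp: np.ndarray
    comp_ids: list
    comp_motion: list
    hub: np.ndarray

    def component_id(self, kind: int, idx: int) -> str:
        if kind == KIND_TRI:
            return self.comp_ids[self.tri_comp[idx]]
        if kind == KIND_SPHERE:
            return self.comp_ids[self.sph_comp[idx]]
        return self.comp_ids[self.seg_comp[idx]]

    def is_rotating(self, kind: int, idx: int) -> bool:
        if kind == KIND_TRI:
            return bool(self.tri_rot[idx])
        if kind == KIND_SPHERE:
            return bool(self.sph_rot[idx])
        return bool(self.seg_rot[idx])

    def x_extent(self) -> tuple[float, float]:
        """Axial extent of the device surface (core extents + inflation)."""
        lo, hi = np.inf, -np.inf
        if len(self.tri_v):
            lo = min(lo, float(self.tri_v[..., 0].min() - self.tri_inf.max()))
            hi = max(hi, float(self.tri_v[..., 0].max() + self.tri_inf.max()))
        if len(self.sph_c):
            lo = min(lo, float((self.sph_c[:, 0] - self.sph_r).min()))
            hi = max(hi, float((self.sph_c[:, 0] + self.sph_r).max()))
        if len(self.seg_a):
            xs = np.concatenate([self.seg_a[:, 0] - self.seg_r,
                                 self.seg_b[:, 0] - self.seg_r])
            lo = min(lo, float(xs.min()))
            xs = np.concatenate([self.seg_a[:, 0] + self.seg_r,
                                 self.seg_b[:, 0] + self.seg_r])
            hi = max(hi, float(xs.max()))
        if not np.isfinite(lo):
            raise ValueError("empty device assembly")
        return lo, hi


def _axis_distance(points: np.ndarray, hub: np.ndarray) -> np.ndarray:
    """Lateral (y, z) distance of points from the rotor axis."""
    return np.hypot(points[..., 1] - hub[1], points[..., 2] - hub[2])


def _tri_rmin(tri: np.ndarray, hub: np.ndarray) -> float:
    """Min distance from the rotor axis to the triangle (min over edges)."""
    best = np.inf
    for i in range(3):
        a = tri[i]
        b = tri[(i + 1) % 3]
        # minimise |lateral(a + t (b-a))| over t in [0, 1]
        ay, az = a[1] - hub[1], a[2] - hub[2]
        dy, dz = b[1] - a[1], b[2] - a[2]
        denom = dy * dy + dz * dz
        if denom > 0:
            t = -(ay * dy + az * dz) / denom
            t = min(max(t, 0.0), 1.0)
        else:
            t = 0.0
        best = min(best, math.hypot(ay + t * dy, az + t * dz))
    return best


def compile_device(assembly: DeviceAssembly) -> CompiledDevice:
    hub = assembly.hub
    tri_v, tri_inf, tri_rot, tri_comp, tri_ref, tri_half = [], [], [], [], [], []
    tri_rmin, tri_rmax = [], []
    sph_c, sph_r, sph_rot, sph_comp = [], [], [], []
    seg_a, seg_b, seg_r, seg_rot, seg_comp = [], [], [], [], []
    comp_ids, comp_motion = [], []
    for c in assembly.components:
        ci = len(comp_ids)
        comp_ids.append(c.component_id)
        comp_motion.append(c.motion)
        rot = 1 if c.motion == "rotating" else 0
        if c.kind == KIND_TRI:
            for tri in c.data:
                tri_v.append(tri)
                tri_inf.append(c.inflation)
                tri_rot.append(rot)
                tri_comp.append(ci)
                tri_ref.append(c.ref_angle)
                if rot:
                    ang = np.arctan2(tri[:, 2] - hub[2], tri[:, 1] - hub[1])
                    rel = np.mod(ang - c.ref_angle + np.pi, 2 * np.pi) - np.pi
                    tri_half.append(float(np.abs(rel).max()))
                else:
                    tri_half.append(math.pi)
                tri_rmin.append(_tri_rmin(tri, hub))
                tri_rmax.append(float(_axis_distance(tri, hub).max()))
        elif c.kind == KIND_SPHERE:
            for p in c.data:
                sph_c.append(p)
                sph_r.append(c.inflation)
                sph_rot.append(rot)
                sph_comp.append(ci)
        else:
            for a, b in zip(c.data, c.data_b):
                seg_a.append(a)
                seg_b.append(b)
                seg_r.append(c.inflation)
                seg_rot.append(rot)
                seg_comp.append(ci)
    f8 = np.float64
    return CompiledDevice(
        tri_v=np.array(tri_v, f8).reshape(-1, 3, 3),
        tri_inf=np.array(tri_inf, f8),
        tri_rot=np.array(tri_rot, np.uint8),
        tri_comp=np.array(tri_comp, np.int32),
        tri_ref=np.array(tri_ref, f8),
        tri_half=np.array(tri_half, f8),
        tri_rmin=np.array(tri_rmin, f8),
        tri_rmax=np.array(tri_rmax, f8),
        sph_c=np.array(sph_c, f8).reshape(-1, 3),
        sph_r=np.array(sph_r, f8),
        sph_rot=np.array(sph_rot, np.uint8),
        sph_comp=np.array(sph_comp, np.int32),
        seg_a=np.array(seg_a, f8).reshape(-1, 3),
        seg_b=np.array(seg_b, f8).reshape(-1, 3),
        seg_r=np.array(seg_r, f8),
        seg_rot=np.array(seg_rot, np.uint8),
        seg_comp=np.array(seg_comp, np.int32),
        comp_ids=comp_ids,
        comp_motion=comp_motion,
        hub=np.asarray(hub, f8),
    )


# ---------------------------------------------------------------------------
# clearance query
# ---------------------------------------------------------------------------

def clearance(seal: SealBody, device: DeviceAssembly,
              rotor_angle: float = 0.0) -> Clearance:
    """Minimum signed distance between the seal and any device component.

    Negative values are penetration depth (core distance minus inflation).
    For non-negative values the realizing surface points satisfy
    |point_on_seal - point_on_device| == distance.
    """
    cd = device.compiled()
    p0, p1 = seal.core_endpoints()
    args = (p0[0], p0[1], p0[2], p1[0], p1[1], p1[2], seal.radius,
            float(rotor_angle))
    prims = (cd.tri_v, cd.tri_inf, cd.tri_rot, cd.sph_c, cd.sph_r, cd.sph_rot,
             cd.seg_a, cd.seg_b, cd.seg_r, cd.seg_rot, cd.hub[1], cd.hub[2])
    dist, kind, idx = _kernels.clearance_scan(*args, *prims)
    if kind < 0:
        raise ValueError("empty device assembly")
    d2, sx, sy, sz, dx, dy, dz = _kernels.clearance_points(
        *args, kind, idx, *prims)
    return Clearance(distance_m=float(dist),
                     point_on_seal=np.array([sx, sy, sz]),
                     point_on_device=np.array([dx, dy, dz]),
                     component_id=cd.component_id(kind, idx))
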