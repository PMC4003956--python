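"""Test-pattern geometry for tremor assessment.

The test battery contains 19 patterns probing the three clinical tremor
regimes: static patterns (1-2, postural/rest tremor), kinematic 2D patterns
drawn on a screen (3-11, intentional tremor in simple and combined
movements), 3D line-following patterns (12-14) and dynamic patterns (15-19)
which reuse earlier geometries under a virtual force field.

Coordinate convention (device frame, metres): Y points up, the X-Y plane is
the subject's coronal plane, Y-Z the sagittal plane and X-Z the transverse
plane.  Screen patterns are embedded at constant Z; the screen half-extent
is set by ``workspace_scale`` (the screen-to-workspace mapping of the
original apparatus is not part of the recordings, so 2D extents are
configurable defaults).  The 3D line patterns have fixed physical lengths:
0.40 m (coronal), 0.20 m (sagittal) and 0.48 m (all-planes polyline).
"""

from __future__ import annotations

import enum
import io
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import integrate, optimize, special

from .forces import ForceSpec

__all__ = [
    "PathKind",
    "PatternCategory",
    "RecordedChannels",
    "ReferencePath",
    "Pattern",
    "make_pattern",
    "pattern_catalogue",
    "path_length",
    "deviation_from_path",
    "deviation_series",
    "detrended_axes",
    "geometry_polyline_csv",
]

#: Default half-width of the on-screen workspace mapped into the device frame.
DEFAULT_WORKSPACE_SCALE = 0.30

#: Printed lengths of the 3D line patterns, metres.
PATTERN12_LENGTH = 0.40
PATTERN13_LENGTH = 0.20
PATTERN14_LENGTH = 0.48

#: Dynamic pattern -> base pattern whose geometry it reuses.
DYNAMIC_BASE = {15: 2, 16: 3, 17: 3, 18: 8, 19: 13}


class PathKind(str, enum.Enum):
    POINT = "point"
    SEGMENT = "segment"
    ELLIPSE = "ellipse"
    ARCHIMEDEAN_SPIRAL = "archimedean_spiral"
    SINUSOID = "sinusoid"
    VARIABLE_AMPLITUDE_GRAPH = "variable_amplitude_graph"
    SEGMENT_3D = "segment_3d"


class PatternCategory(str, enum.Enum):
    STATIC = "static"
    KINEMATIC = "kinematic"
    THREE_D = "three_d"
    DYNAMIC = "dynamic"


class RecordedChannels(str, enum.Enum):
    XYZ_POSITIONS = "xyz_positions"
    XY_DEVIATION_FROM_POINT = "xy_deviation_from_point"
    SCALAR_DEVIATION_FROM_PATH = "scalar_deviation_from_path"
    XY_POSITIONS = "xy_positions"
    SPATIAL_DEVIATION_3D = "spatial_deviation_3d"


@dataclass(frozen=True)
class ReferencePath:
    """A parametrized reference curve (or point) in the device frame.

    The canonical curve is defined by ``kind`` and ``params`` in a local
    frame; an optional rigid transform (``rotation``, ``translation``) maps
    it into the device frame.  The curve is exposed through ``point_at(u)``
    with ``u`` in [0, 1] running from the prescribed start to the end of the
    traversal.

    Parameters per kind (all lengths in metres, angles in radians):

    - ``point``: ``target`` (3,)
    - ``segment`` / ``segment_3d``: ``vertices`` (m, 3) polyline, m >= 2
    - ``ellipse``: ``center`` (3,), ``a``, ``b`` semi-axes in the local XY
      plane
    - ``archimedean_spiral``: ``center`` (3,), ``pitch_coeff`` k of r = k *
      theta, ``theta_max``; traversed from the outside (theta_max) inwards
    - ``sinusoid``: ``x0``, ``x1``, ``amplitude``, ``cycles``, drawn as
      y = A sin(2 pi c (x - x0) / (x1 - x0)) in the local XY plane
    - ``variable_amplitude_graph``: as sinusoid plus ``amplitude_end``; the
      envelope decays linearly from ``amplitude`` at x0 to ``amplitude_end``
      at x1 between two converging straight borders
    """

    kind: PathKind
    params: dict
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    # -- parametrization ---------------------------------------------------
    def _local_point(self, u: np.ndarray) -> np.ndarray:
        u = np.atleast_1d(np.asarray(u, dtype=float))
        p = self.params
        if self.kind is PathKind.POINT:
            return np.broadcast_to(np.asarray(p["target"], float), (u.size, 3)).copy()
        if self.kind in (PathKind.SEGMENT, PathKind.SEGMENT_3D):
            verts = np.asarray(p["vertices"], float)
            seg = np.diff(verts, axis=0)
            seg_len = np.linalg.norm(seg, axis=1)
            total = seg_len.sum()
            if total == 0.0:
                return np.broadcast_to(verts[0], (u.size, 3)).copy()
            cum = np.concatenate([[0.0], np.cumsum(seg_len)]) / total
            idx = np.clip(np.searchsorted(cum, u, side="right") - 1, 0, len(seg) - 1)
            denom = np.where(seg_len[idx] > 0, cum[idx + 1] - cum[idx], 1.0)
            frac = np.clip((u - cum[idx]) / denom, 0.0, 1.0)
            return verts[idx] + frac[:, None] * seg[idx]
        if self.kind is PathKind.ELLIPSE:
            th = 2.0 * np.pi * u
            c = np.asarray(p["center"], float)
            out = np.zeros((u.size, 3))
            out[:, 0] = p["a"] * np.cos(th)
            out[:, 1] = p["b"] * np.sin(th)
            return out + c
        if self.kind is PathKind.ARCHIMEDEAN_SPIRAL:
            th = p["theta_max"] * (1.0 - u)  # outside -> in
            r = p["pitch_coeff"] * th
            c = np.asarray(p["center"], float)
            out = np.zeros((u.size, 3))
            out[:, 0] = r * np.cos(th)
            out[:, 1] = r * np.sin(th)
            return out + c
        if self.kind in (PathKind.SINUSOID, PathKind.VARIABLE_AMPLITUDE_GRAPH):
            x0, x1 = p["x0"], p["x1"]
            x = x0 + (x1 - x0) * u
            phase = 2.0 * np.pi * p["cycles"] * u
            if self.kind is PathKind.SINUSOID:
                amp = p["amplitude"]
            else:
                amp = p["amplitude"] + (p["amplitude_end"] - p["amplitude"]) * u
            out = np.zeros((u.size, 3))
            out[:, 0] = x
            out[:, 1] = amp * np.sin(phase)
            return out
        raise ValueError(f"unknown path kind {self.kind!r}")

    def _local_speed(self, u: np.ndarray) -> np.ndarray:
        """|dp/du| of the canonical parametrization (for quadrature)."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        p = self.params
        if self.kind is PathKind.ELLIPSE:
            th = 2.0 * np.pi * u
            return 2.0 * np.pi * np.hypot(p["a"] * np.sin(th), p["b"] * np.cos(th))
        if self.kind is PathKind.ARCHIMEDEAN_SPIRAL:
            th = p["theta_max"] * (1.0 - u)
            return p["theta_max"] * p["pitch_coeff"] * np.sqrt(1.0 + th**2)
        if self.kind in (PathKind.SINUSOID, PathKind.VARIABLE_AMPLITUDE_GRAPH):
            dx = p["x1"] - p["x0"]
            w = 2.0 * np.pi * p["cycles"]
            phase = w * u
            if self.kind is PathKind.SINUSOID:
                amp, damp = p["amplitude"], 0.0
            else:
                amp = p["amplitude"] + (p["amplitude_end"] - p["amplitude"]) * u
                damp = p["amplitude_end"] - p["amplitude"]
            dy = damp * np.sin(phase) + amp * w * np.cos(phase)
            return np.hypot(dx, dy)
        raise ValueError(f"no analytic speed for kind {self.kind!r}")

    def point_at(self, u) -> np.ndarray:
        """Device-frame point(s) at parameter ``u`` in [0, 1]."""
        scalar = np.isscalar(u) or (isinstance(u, np.ndarray) and u.ndim == 0)
        pts = self._local_point(u) @ self.rotation.T + self.translation
        return pts[0] if scalar else pts

    @property
    def start_point(self) -> np.ndarray:
        return self.point_at(0.0)

    @property
    def end_point(self) -> np.ndarray:
        return self.point_at(1.0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ReferencePath":
        """Compose a further rigid transform onto this path."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        return replace(self, rotation=R @ self.rotation,
                       translation=R @ self.translation + t)

    # -- geometry ----------------------------------------------------------
    def length(self, rel_tol: float = 1e-9) -> float:
        """Arc length in metres (analytic where possible, quadrature otherwise)."""
        p = self.params
        if self.kind is PathKind.POINT:
            return 0.0
        if self.kind in (PathKind.SEGMENT, PathKind.SEGMENT_3D):
            verts = np.asarray(p["vertices"], float)
            return float(np.linalg.norm(np.diff(verts, axis=0), axis=1).sum())
        if self.kind is PathKind.ELLIPSE:
            a, b = max(p["a"], p["b"]), min(p["a"], p["b"])
            if a == 0.0:
                return 0.0
            return float(4.0 * a * special.ellipe(1.0 - (b / a) ** 2))
        val, _ = integrate.quad(lambda u: float(self._local_speed(u)[0]),
                                0.0, 1.0, epsrel=rel_tol, limit=200)
        return float(val)

    def distance_to(self, position: np.ndarray, n_coarse: int = 2048) -> float:
        """Euclidean distance from ``position`` to the nearest point of the path.

        Closed form for points and (poly)segments; otherwise a dense
        parameter scan refined by bounded scalar minimization, accurate to
        well below 1e-6 m for the catalogue geometries.
        """
        x = np.asarray(position, float)
        if not np.all(np.isfinite(x)):
            raise ValueError("position must be finite")
        if self.kind is PathKind.POINT:
            return float(np.linalg.norm(x - self.point_at(0.0)))
        if self.kind in (PathKind.SEGMENT, PathKind.SEGMENT_3D):
            verts = np.asarray(self.params["vertices"], float) @ self.rotation.T + self.translation
            return float(_point_polyline_distance(x, verts))
        # Periodic curves (ellipse) wrap; sample with endpoint duplication.
        u = np.linspace(0.0, 1.0, n_coarse)
        d2 = np.sum((self.point_at(u) - x) ** 2, axis=1)
        i = int(np.argmin(d2))
        lo = u[max(i - 1, 0)]
        hi = u[min(i + 1, n_coarse - 1)]

        def f(uu: float) -> float:
            return float(np.sum((self.point_at(uu) - x) ** 2))

        res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-14})
        best = min(res.fun, d2[i])
        if self.kind is PathKind.ELLIPSE:
            # guard the wrap-around seam at u = 0/1
            best = min(best, f(0.0))
        return float(math.sqrt(best))


def _point_polyline_distance(x: np.ndarray, verts: np.ndarray) -> float:
    if len(verts) == 1:
        return float(np.linalg.norm(x - verts[0]))
    a = verts[:-1]
    ab = np.diff(verts, axis=0)
    denom = np.einsum("ij,ij->i", ab, ab)
    tt = np.zeros(len(ab))
    nz = denom > 0
    tt[nz] = np.clip(np.einsum("ij,ij->i", (x - a)[nz], ab[nz]) / denom[nz], 0.0, 1.0)
    proj = a + tt[:, None] * ab
    return float(np.sqrt(np.min(np.sum((proj - x) ** 2, axis=1))))


@dataclass(frozen=True)
class Pattern:
    """One of the 19 test definitions: geometry, category and force field."""

    id: int
    category: PatternCategory
    geometry: ReferencePath
    recorded_channels: RecordedChannels
    force: Optional[ForceSpec] = None
    description: str = ""

    @property
    def base_id(self) -> int:
        """The pattern whose geometry this one uses (itself if non-dynamic)."""
        return DYNAMIC_BASE.get(self.id, self.id)


def _screen(v2, z: float = 0.0) -> np.ndarray:
    return np.array([v2[0], v2[1], z], float)


def make_pattern(pattern_id: int,
                 workspace_scale: float = DEFAULT_WORKSPACE_SCALE) -> Pattern:
    """Build the canonical definition of pattern ``pattern_id`` (1-19).

    ``workspace_scale`` sets the on-screen extent (metres) of the 2D
    patterns; the 3D patterns keep their fixed physical lengths regardless.
    """
    if not (isinstance(pattern_id, (int, np.integer)) and 1 <= pattern_id <= 19):
        raise ValueError(f"unknown pattern id {pattern_id!r}; valid ids are 1-19")
    pid = int(pattern_id)
    h = workspace_scale / 2.0

    if pid in DYNAMIC_BASE:
        base = make_pattern(DYNAMIC_BASE[pid], workspace_scale)
        force = {
            15: ForceSpec.constant((0.0, -5.0, 0.0)),
            16: ForceSpec.spring(K=0.0005, direction=(0.0, 1.0, 0.0)),
            17: ForceSpec.mass_spring_damper(M=0.05, B=0.0015, K=0.0),
            18: ForceSpec.mass_spring_damper(M=0.05, B=0.0015, K=0.0),
            19: ForceSpec.mass_spring_damper(M=0.05, B=0.0015, K=0.0),
        }[pid]
        desc = {
            15: "hold the target point under a constant 5 N downward load",
            16: "horizontal line with a progressively stiffening spring in Y",
            17: "horizontal line with virtual inertia and viscous friction",
            18: "spiral with virtual inertia and viscous friction",
            19: "sagittal 3D line with virtual inertia and viscous friction",
        }[pid]
        return Pattern(pid, PatternCategory.DYNAMIC, base.geometry,
                       base.recorded_channels, force, desc)

    if pid == 1:
        geo = ReferencePath(PathKind.POINT, {"target": np.zeros(3)})
        return Pattern(pid, PatternCategory.STATIC, geo,
                       RecordedChannels.XYZ_POSITIONS,
                       description="rest: relaxed hand, elbow supported; XYZ recorded")
    if pid == 2:
        geo = ReferencePath(PathKind.POINT, {"target": np.zeros(3)})
        return Pattern(pid, PatternCategory.STATIC, geo,
                       RecordedChannels.XY_DEVIATION_FROM_POINT,
                       description="postural: keep the cursor on a fixed screen target")
    if pid == 3:
        verts = np.array([_screen((-h, 0.0)), _screen((h, 0.0))])
    elif pid == 4:  # sloping line, traversed bottom-up
        verts = np.array([_screen((-h, -h)), _screen((h, h))])
    elif pid == 5:  # sloping line, traversed top-down
        verts = np.array([_screen((-h, h)), _screen((h, -h))])
    elif pid == 6:  # vertical line, down-up
        verts = np.array([_screen((0.0, -h)), _screen((0.0, h))])
    else:
        verts = None

    if verts is not None:
        geo = ReferencePath(PathKind.SEGMENT, {"vertices": verts})
        return Pattern(pid, PatternCategory.KINEMATIC, geo,
                       RecordedChannels.SCALAR_DEVIATION_FROM_PATH,
                       description="straight-line tracking on screen")
    if pid == 7:
        geo = ReferencePath(PathKind.ELLIPSE,
                            {"center": np.zeros(3), "a": h, "b": 0.75 * h})
        return Pattern(pid, PatternCategory.KINEMATIC, geo,
                       RecordedChannels.SCALAR_DEVIATION_FROM_PATH,
                       description="elliptical tracking; deviation from the central circumference")
    if pid in (8, 9):
        turns = 3 if pid == 8 else 5  # pattern 9: narrower inter-turn spacing
        theta_max = 2.0 * np.pi * turns
        geo = ReferencePath(PathKind.ARCHIMEDEAN_SPIRAL,
                            {"center": np.zeros(3),
                             "pitch_coeff": h / theta_max,
                             "theta_max": theta_max})
        return Pattern(pid, PatternCategory.KINEMATIC, geo,
                       RecordedChannels.XY_POSITIONS,
                       description="Archimedean spiral followed from the outside in")
    if pid == 10:
        geo = ReferencePath(PathKind.SINUSOID,
                            {"x0": -h, "x1": h, "amplitude": h / 3.0, "cycles": 2.0})
        return Pattern(pid, PatternCategory.KINEMATIC, geo,
                       RecordedChannels.XY_POSITIONS,
                       description="sinusoidal curve followed start to end")
    if pid == 11:
        geo = ReferencePath(PathKind.VARIABLE_AMPLITUDE_GRAPH,
                            {"x0": -h, "x1": h, "amplitude": h / 3.0,
                             "amplitude_end": h / 30.0, "cycles": 4.0})
        return Pattern(pid, PatternCategory.KINEMATIC, geo,
                       RecordedChannels.XY_POSITIONS,
                       description="variable-amplitude graph traced from outside to inside")
    if pid == 12:  # coronal plane: constant Z
        half = PATTERN12_LENGTH / 2.0
        verts = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    elif pid == 13:  # sagittal plane: constant X (arm flexion/extension)
        half = PATTERN13_LENGTH / 2.0
        verts = np.array([[0.0, 0.0, -half], [0.0, 0.0, half]])
    else:  # 14: three segments spanning all three axes
        s = PATTERN14_LENGTH / 3.0
        verts = np.array([[0.0, 0.0, 0.0], [s, 0.0, 0.0],
                          [s, s, 0.0], [s, s, s]])
    geo = ReferencePath(PathKind.SEGMENT_3D, {"vertices": verts})
    return Pattern(pid, PatternCategory.THREE_D, geo,
                   RecordedChannels.SPATIAL_DEVIATION_3D,
                   description="3D line following")


def pattern_catalogue(workspace_scale: float = DEFAULT_WORKSPACE_SCALE) -> list:
    """All 19 patterns."""
    return [make_pattern(i, workspace_scale) for i in range(1, 20)]


def path_length(path: ReferencePath) -> float:
    """Arc length of a reference path, metres (0 for a point target)."""
    return path.length()


def deviation_from_path(position, path: ReferencePath) -> float:
    """Distance (m) from a 3D point to the nearest point of the reference geometry."""
    return path.distance_to(position)


def detrended_axes(xyz: np.ndarray) -> np.ndarray:
    """Linearly detrend each position axis (used for the rest pattern)."""
    from scipy.signal import detrend

    return detrend(np.asarray(xyz, float), axis=0, type="linear")


def deviation_series(recording, pattern: Pattern) -> np.ndarray:
    """Per-sample scalar analysis channel of a recording under a pattern.

    Path patterns yield the distance to the nearest point of the reference
    geometry; the static target patterns (2 and 15) yield the planar X-Y
    distance from the target; the rest pattern (1) yields the
    highest-variance detrended axis (per-axis detrended positions are
    available via :func:`detrended_axes`).
    """
    if recording.pattern_id is not None and recording.pattern_id != pattern.id:
        raise ValueError(
            f"recording was made for pattern {recording.pattern_id}, "
            f"not pattern {pattern.id}")
    xyz = np.asarray(recording.xyz, float)
    ch = pattern.recorded_channels
    if ch is RecordedChannels.XYZ_POSITIONS:
        det = detrended_axes(xyz)
        return det[:, int(np.argmax(det.var(axis=0)))]
    if ch is RecordedChannels.XY_DEVIATION_FROM_POINT:
        target = pattern.geometry.point_at(0.0)
        return np.hypot(xyz[:, 0] - target[0], xyz[:, 1] - target[1])
    return np.array([pattern.geometry.distance_to(p) for p in xyz])


def geometry_polyline_csv(pattern: Pattern, n: int = 200) -> str:
    """Dump a pattern's geometry as an x,y,z CSV polyline (for inspection)."""
    pts = pattern.geometry.point_at(np.linspace(0.0, 1.0, n))
    buf = io.StringIO()
    buf.write("x,y,z\n")
    for p in pts:
        buf.write(f"{p[0]:.6g},{p[1]:.6g},{p[2]:.6g}\n")
    return buf.getvalue()
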