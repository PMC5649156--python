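"""Spherical-conductor MEG forward model and geometry.

The head is modeled as a single homogeneous sphere: MEG in a spherically
symmetric conductor is insensitive to the conductivity profile, so a single
sphere captures everything the magnetic forward problem needs.  Sensors are
axial gradiometers — two coaxial coils separated radially by a baseline —
placed quasi-uniformly on an upper spherical cap (helmet).  Sources live on
a spherical shell strictly inside the conductor, each with two tangential
orientations (radial dipoles are magnetically silent in a sphere).

Coordinate frame: conductor center at the origin, +x anterior, +y left,
+z superior.  All lengths in meters, dipole moments in A·m, fields in T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MU0_OVER_4PI = 1e-7  # T·m/(A·m)

REGION_NAMES = ("frontal", "central", "parietal", "temporal", "occipital")

#: Anatomical landmark directions (MNI mm, RAS) used to register named proxy
#: points for the left/right precuneus onto the source shell.
PRECUNEUS_MNI_MM = {"precuneus_left": (-8.0, -68.0, 49.0),
                    "precuneus_right": (7.0, -68.0, 39.0)}


class GeometryError(ValueError):
    """Invalid sensor/source geometry (radii, containment, baselines)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SensorArray:
    """Axial-gradiometer array on a spherical helmet.

    positions : (n_chan, 3) inner-coil positions, all at the helmet radius
    orientations : (n_chan, 3) unit radial coil axes
    baseline : radial separation of the two coils (m)
    labels : channel names
    regions : one of REGION_NAMES per channel
    """

    positions: np.ndarray
    orientations: np.ndarray
    baseline: float
    labels: list[str]
    regions: np.ndarray

    @property
    def n_chan(self) -> int:
        return self.positions.shape[0]

    @property
    def helmet_radius(self) -> float:
        return float(np.linalg.norm(self.positions[0]))

    def region_channels(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.regions == region)


@dataclass
class SourceGrid:
    """Quasi-uniform points on a spherical shell inside the conductor.

    names maps anatomical-style labels (e.g. ``precuneus_left``) to grid
    indices of designated points.
    """

    coords: np.ndarray
    spacing: float
    names: dict[str, int] = field(default_factory=dict)

    @property
    def n_src(self) -> int:
        return self.coords.shape[0]


@dataclass
class LeadField:
    """Gradiometer gain matrix: (n_chan, n_src*2), T per unit A·m.

    Columns 2*j and 2*j+1 hold the two tangential orientations of grid
    point j (local tangent basis in ``tangentials``).
    """

    gain: np.ndarray
    grid: SourceGrid
    conductor_radius: float
    conductor_center: np.ndarray
    tangentials: np.ndarray  # (n_src, 2, 3)


# ---------------------------------------------------------------------------
# sensor array construction
# ---------------------------------------------------------------------------

def _fibonacci_cap(n: int, z_min: float) -> np.ndarray:
    """n quasi-uniform unit vectors on the cap z >= z_min (golden-angle spiral)."""
    i = np.arange(n)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def build_sensor_array(n_chan: int = 151, helmet_radius: float = 0.11,
                       baseline: float = 0.05, seed: int = 0,
                       z_min: float = 0.02) -> SensorArray:
    """Quasi-uniform axial-gradiometer helmet on the upper spherical cap.

    Deterministic for a given seed (a small seeded azimuthal rotation is the
    only random element, so distinct seeds give slightly different but
    equally valid helmets).
    """
    if n_chan < 4:
        raise GeometryError("need at least 4 channels")
    if helmet_radius <= 0 or baseline <= 0:
        raise GeometryError("helmet_radius and baseline must be positive")
    units = _fibonacci_cap(n_chan, z_min)
    rot = np.random.default_rng(seed).uniform(0.0, 2 * np.pi)
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    units = units @ R.T
    positions = helmet_radius * units
    labels = [f"MEG{i:03d}" for i in range(n_chan)]
    regions = partition_regions_from_positions(positions)
    return SensorArray(positions=positions, orientations=units,
                       baseline=float(baseline), labels=labels, regions=regions)


def partition_regions_from_positions(positions: np.ndarray) -> np.ndarray:
    """Assign frontal/central/parietal/temporal/occipital by angular sectors.

    Azimuth is measured from the anterior (+x) axis; elevation from the
    horizontal plane.  Low lateral sensors are temporal; low anterior are
    frontal; low posterior occipital; the superior crown splits into
    central (anterior half) and parietal (posterior half).
    """
    x, y, z = positions.T
    r = np.linalg.norm(positions, axis=1)
    az = np.degrees(np.abs(np.arctan2(y, x)))  # 0 anterior .. 180 posterior
    el = np.degrees(np.arcsin(np.clip(z / r, -1.0, 1.0)))
    regions = np.empty(len(positions), dtype=object)
    for i in range(len(positions)):
        if el[i] < 35.0 and 60.0 < az[i] < 120.0:
            regions[i] = "temporal"
        elif el[i] < 65.0 and az[i] <= 60.0:
            regions[i] = "frontal"
        elif el[i] < 65.0 and az[i] >= 120.0:
            regions[i] = "occipital"
        elif az[i] < 90.0:
            regions[i] = "central"
        else:
            regions[i] = "parietal"
    return regions.astype(str)


def partition_regions(array: SensorArray) -> np.ndarray:
    """Region label per channel (deterministic angular sectors)."""
    return partition_regions_from_positions(array.positions)


# ---------------------------------------------------------------------------
# source grid
# ---------------------------------------------------------------------------

def mni_direction_to_frame(mni_mm: tuple[float, float, float]) -> np.ndarray:
    """Map an MNI (RAS, mm) direction into the helmet frame (ALS) as a unit vector.

    Only the direction is meaningful here: named points are registered by
    pure scaling onto the source shell (no anatomy is available).
    """
    x, y, z = mni_mm
    v = np.array([y, -x, z])  # anterior, left, superior
    return v / np.linalg.norm(v)


def build_source_grid(spacing: float = 0.01, shell_radius: float = 0.07,
                      conductor_radius: float = 0.09, z_min_frac: float = -0.5,
                      named_points: dict[str, tuple[float, float, float]] | None = None,
                      ) -> SourceGrid:
    """Quasi-uniform shell grid plus named proxy points (MNI directions, scaled).

    Point count is set so the nominal inter-point distance matches
    ``spacing``.  The shell is cut below ``z_min_frac`` × radius (brain-like
    extent: MEG has no sensitivity, and no cortex, far below the helmet).
    Named points are appended exactly so VOI lookups hit them.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    if shell_radius >= conductor_radius:
        raise GeometryError("source shell must be strictly inside the conductor")
    area = 2.0 * np.pi * shell_radius**2 * (1.0 - z_min_frac)
    n = max(int(round(area / spacing**2)), 12)
    i = np.arange(n)
    z = z_min_frac + (1.0 - z_min_frac) * (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    coords = shell_radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if named_points is None:
        named_points = PRECUNEUS_MNI_MM
    names: dict[str, int] = {}
    extra = []
    for name, mni in named_points.items():
        extra.append(shell_radius * mni_direction_to_frame(mni))
        names[name] = n + len(extra) - 1
    if extra:
        coords = np.vstack([coords, extra])
    return SourceGrid(coords=coords, spacing=float(spacing), names=names)


def voi_indices(grid: SourceGrid, center: np.ndarray, radius: float = 0.005) -> np.ndarray:
    """Indices of grid points within ``radius`` of ``center`` (may be empty)."""
    if radius <= 0:
        raise GeometryError("VOI radius must be positive")
    center = np.asarray(center, dtype=float)
    d = np.linalg.norm(grid.coords - center, axis=1)
    return np.flatnonzero(d <= radius)


# ---------------------------------------------------------------------------
# Sarvas forward model
# ---------------------------------------------------------------------------

def sarvas_field(dipole_pos: np.ndarray, dipole_moment: np.ndarray,
                 sensor_pos: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Radial magnetic field (T) of a current dipole in a spherical conductor.

    Closed-form solution for a spherically symmetric conductor; the radial
    component at each sensor is returned, which is what an axial coil
    measures.  ``sensor_pos`` may be (3,) or (n, 3).  A dipole whose moment
    is parallel to its position vector (radial) gives exactly zero field.
    """
    if center is None:
        center = np.zeros(3)
    r0 = np.asarray(dipole_pos, dtype=float) - center
    q = np.asarray(dipole_moment, dtype=float)
    sensors = np.atleast_2d(np.asarray(sensor_pos, dtype=float)) - center

    r = sensors                                    # (n, 3)
    rn = np.linalg.norm(r, axis=1)                 # |r|
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if np.any(a == 0) or np.any(rn == 0):
        raise GeometryError("sensor coincides with dipole or conductor center")
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)
    F = a * (rn * a + rn**2 - r0_dot_r)
    if np.any(F == 0):
        raise GeometryError("degenerate geometry (sensor inside conductor?)")
    gradF = ((a**2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
             - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0)
    Q = np.cross(q, r0)                            # (3,)
    B = (F[:, None] * Q - (r @ Q)[:, None] * gradF) * (MU0_OVER_4PI / F**2)[:, None]
    b_radial = np.einsum("ij,ij->i", B, r) / rn
    if np.ndim(sensor_pos) == 1:
        return b_radial[0]
    return b_radial


def gradiometer_output(array: SensorArray, dipole_pos: np.ndarray,
                       dipole_moment: np.ndarray,
                       center: np.ndarray | None = None) -> np.ndarray:
    """Axial-gradiometer responses: radial field at the inner coil minus the
    outer coil (inner + baseline along the coil axis)."""
    inner = sarvas_field(dipole_pos, dipole_moment, array.positions, center)
    outer_pos = array.positions + array.baseline * array.orientations
    outer = sarvas_field(dipole_pos, dipole_moment, outer_pos, center)
    return inner - outer


def _tangent_basis(coords: np.ndarray) -> np.ndarray:
    """Local tangent basis (n, 2, 3) at shell points; radial is excluded.

    A point at the conductor center has no radial direction; it gets the
    (x, y) basis (its field is identically zero anyway).
    """
    norms0 = np.linalg.norm(coords, axis=1, keepdims=True)
    at_center = norms0[:, 0] < 1e-12
    safe = np.where(norms0 > 1e-12, norms0, 1.0)
    n = coords / safe
    n[at_center] = np.array([0.0, 0.0, 1.0])
    zaxis = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(np.broadcast_to(zaxis, n.shape), n)
    norms = np.linalg.norm(e1, axis=1)
    poles = norms < 1e-12
    if np.any(poles):  # pole points: use x-axis to seed the basis
        e1[poles] = np.cross(np.array([1.0, 0.0, 0.0]), n[poles])
        norms = np.linalg.norm(e1, axis=1)
    e1 /= norms[:, None]
    e2 = np.cross(n, e1)
    return np.stack([e1, e2], axis=1)


def compute_leadfield(array: SensorArray, grid: SourceGrid,
                      conductor_radius: float = 0.09,
                      conductor_center: np.ndarray | None = None) -> LeadField:
    """Gradiometer lead field for two tangential orientations per grid point."""
    if conductor_center is None:
        conductor_center = np.zeros(3)
    radii = np.linalg.norm(grid.coords - conductor_center, axis=1)
    if np.any(radii >= conductor_radius):
        raise GeometryError("source grid point outside the conductor sphere")
    tang = _tangent_basis(grid.coords - conductor_center)
    gain = np.empty((array.n_chan, grid.n_src * 2))
    for j in range(grid.n_src):
        for k in range(2):
            gain[:, 2 * j + k] = gradiometer_output(
                array, grid.coords[j], tang[j, k], conductor_center)
    return LeadField(gain=gain, grid=grid, conductor_radius=float(conductor_radius),
                     conductor_center=np.asarray(conductor_center, dtype=float),
                     tangentials=tang)
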