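"""Vector geometry shared by the whole pipeline.

Best-fit ring planes, interplanar tilt angles, minimum heavy-atom
distances, rigid (Kabsch) superposition, dihedral angles, and idealized
hydrogen construction for crystal structures that lack protons.

Conventions: distances in angstroms, angles in degrees.  The tilt angle
between two ring planes is folded into [0, 90] degrees so that it never
depends on the (arbitrary) sign of either plane normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometryError",
    "RingPlane",
    "RigidTransform",
    "fit_ring_plane",
    "tilt_angle",
    "min_heavy_distance",
    "superpose",
    "dihedral",
    "place_atom",
    "build_hydrogens",
    "rotation_about_axis",
    "random_rotation",
    "CH_BOND",
    "OH_BOND",
    "NH_BOND",
    "TETRAHEDRAL_ANGLE",
]

CH_BOND = 1.09
OH_BOND = 0.96
NH_BOND = 1.01
TETRAHEDRAL_ANGLE = 109.4712206344907  # arccos(-1/3)


class GeometryError(ValueError):
    """Raised for degenerate geometric input (collinear points, empty sets...)."""


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane through a ring system.

    ``unit_normal`` has unit length; its sign is arbitrary and every
    downstream angle computation folds it away.
    """

    centroid: np.ndarray
    unit_normal: np.ndarray
    rms_out_of_plane: float
    source_atoms: tuple = field(default_factory=tuple)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError(f"expected an (n, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("non-finite coordinates")
    return pts


def fit_ring_plane(points, source_atoms: tuple = ()) -> RingPlane:
    """Fit the least-squares plane through ``points`` (>= 3, non-collinear).

    The plane minimizes the sum of squared perpendicular deviations; its
    normal is the singular vector of the centered coordinates with the
    smallest singular value.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise GeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: only one non-negligible singular value
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise GeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return RingPlane(centroid=centroid, unit_normal=normal, rms_out_of_plane=rms,
                     source_atoms=tuple(source_atoms))


def tilt_angle(plane_a: RingPlane, plane_b: RingPlane) -> float:
    """Interplanar tilt omega in degrees, folded into [0, 90].

    omega = arccos(|n_a . n_b|): symmetric in its arguments and invariant
    to flipping either normal.
    """
    c = abs(float(np.dot(plane_a.unit_normal, plane_b.unit_normal)))
    return float(np.degrees(np.arccos(min(c, 1.0))))


def min_heavy_distance(atoms_a, atoms_b) -> float:
    """Minimum pairwise Euclidean distance between two heavy-atom sets."""
    a = _as_points(atoms_a)
    b = _as_points(atoms_b)
    if len(a) == 0 or len(b) == 0:
        raise GeometryError("empty atom set")
    from scipy.spatial.distance import cdist

    return float(cdist(a, b).min())


def superpose(mobile, reference) -> RigidTransform:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm with the reflection branch excluded; returns the
    transform and the RMSD it attains.
    """
    mob = _as_points(mobile)
    ref = _as_points(reference)
    if len(mob) != len(ref):
        raise GeometryError("point lists must have equal length")
    if len(mob) < 3:
        raise GeometryError("superposition needs at least 3 points")
    mc = mob.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = rc - rot @ mc
    moved = mob @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return RigidTransform(rotation=rot, translation=trans, rmsd=rmsd)


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, IUPAC convention, in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if np.linalg.norm(b1) < 1e-10 or np.linalg.norm(b2) < 1e-10 or np.linalg.norm(b3) < 1e-10:
        raise GeometryError("coincident consecutive points in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("collinear points in dihedral")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = -float(np.dot(m1, n2))
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if np.isclose(ang, -180.0) else ang


def place_atom(p1, p2, p3, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a fourth atom from internal coordinates (NeRF construction).

    The new atom X is at distance ``bond`` from ``p3``, with angle(p2,p3,X)
    = ``angle`` degrees and dihedral(p1,p2,p3,X) = ``torsion`` degrees.
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = p3 - p2
    bc /= np.linalg.norm(bc)
    ab = p2 - p1
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("collinear reference atoms in place_atom")
    n /= nn
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return p3 + d[0] * bc + d[1] * m + d[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_hydrogens(heavy_center, bonded_heavies, n_h: int,
                    reference_dihedral: float | None = None,
                    pre_reference=None,
                    bond_length: float | None = None) -> list[np.ndarray]:
    """Idealized hydrogen positions on an sp3 center (or hydroxyl oxygen).

    Parameters
    ----------
    heavy_center : (3,) position of the atom carrying the hydrogens.
    bonded_heavies : (k, 3) positions of the known heavy neighbours.
    n_h : number of hydrogens to build; ``k + n_h`` must be 4 for carbon,
        2 for a hydroxyl oxygen (k = 1).
    reference_dihedral : for the hydroxyl / single-neighbour case, the
        dihedral angle (degrees) of the first hydrogen measured as
        dihedral(pre_reference, neighbour, center, H).
    pre_reference : atom defining the dihedral origin (e.g. C4' for the
        C4'-C5'-O5'-H torsion); required with ``reference_dihedral``.
    bond_length : override the default X-H bond length (1.09 A for C,
        0.96 A for a hydroxyl O).

    Geometry is idealized: tetrahedral angles of 109.47 degrees; this is a
    deterministic geometric stand-in for quantum-mechanical proton
    optimization and is documented as such.
    """
    c = np.asarray(heavy_center, dtype=float)
    nb = np.asarray(bonded_heavies, dtype=float).reshape(-1, 3)
    k = len(nb)
    if n_h < 1:
        raise GeometryError("n_h must be >= 1")

    if k == 3 and n_h == 1:
        length = CH_BOND if bond_length is None else bond_length
        units = [(p - c) / np.linalg.norm(p - c) for p in nb]
        d = -np.sum(units, axis=0)
        norm = np.linalg.norm(d)
        if norm < 1e-8:
            raise GeometryError("degenerate substituent geometry")
        return [c + length * d / norm]

    if k == 2 and n_h == 2:
        length = CH_BOND if bond_length is None else bond_length
        u1 = (nb[0] - c) / np.linalg.norm(nb[0] - c)
        u2 = (nb[1] - c) / np.linalg.norm(nb[1] - c)
        bis = -(u1 + u2)
        nbis = np.linalg.norm(bis)
        perp = np.cross(u1, u2)
        nperp = np.linalg.norm(perp)
        if nbis < 1e-8 or nperp < 1e-8:
            raise GeometryError("degenerate substituent geometry")
        bis /= nbis
        perp /= nperp
        half = np.radians(TETRAHEDRAL_ANGLE / 2.0)
        h1 = np.cos(half) * bis + np.sin(half) * perp
        h2 = np.cos(half) * bis - np.sin(half) * perp
        return [c + length * h1, c + length * h2]

    if k == 1:
        # hydroxyl (n_h=1) or methyl (n_h=3): needs a torsion reference
        if reference_dihedral is None or pre_reference is None:
            raise GeometryError(
                "single-neighbour hydrogen placement needs reference_dihedral "
                "and pre_reference")
        if bond_length is None:
            bond_length = OH_BOND if n_h == 1 else CH_BOND
        out = []
        for i in range(n_h):
            tor = reference_dihedral + 120.0 * i
            out.append(place_atom(pre_reference, nb[0], c,
                                  bond_length, TETRAHEDRAL_ANGLE, tor))
        return out

    raise GeometryError(
        f"unsupported hybridization: {k} heavy neighbours with {n_h} hydrogens")
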