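"""Primitive geometric algorithms the ensemble descriptors build on.

Plane and helix-axis fitting, torsion angles, Kabsch superposition and
ensemble RMSD, centers of mass, and Shrake-Rupley solvent-accessible
surface area.  All lengths are Å, all angles degrees.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    ElementError,
    InsufficientDataError,
    RadiusAssignmentError,
    ValidationError,
)
from .structure_io import (
    AtomRecord,
    Model,
    SelectionSpec,
    StructureEnsemble,
    select_atoms,
)

__all__ = [
    "Plane",
    "Axis",
    "SuperpositionResult",
    "EnsembleRMSD",
    "fit_plane",
    "fit_helix_axis",
    "dihedral",
    "superpose",
    "ensemble_rmsd",
    "center_of_mass",
    "sasa",
    "vdw_radius",
    "atomic_mass",
]


def _load_table(name: str, key: str, value: str) -> dict[str, float]:
    ref = importlib.resources.files("hemebundle.data") / name
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df[key], df[value].astype(float)))


_RADII = _load_table("radii.tsv", "element", "radius_A")
_MASSES = _load_table("masses.tsv", "element", "mass_u")


def vdw_radius(element: str) -> float:
    """Bondi-type van der Waals radius (Å) for an element symbol."""
    try:
        return _RADII[element.capitalize()]
    except KeyError:
        raise RadiusAssignmentError(f"no vdW radius for element '{element}'") from None


def atomic_mass(element: str) -> float:
    """Standard atomic weight (u) for an element symbol."""
    try:
        return _MASSES[element.capitalize()]
    except KeyError:
        raise ElementError(f"no atomic mass for element '{element}'") from None


# ---------------------------------------------------------------------------
# Planes and axes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """Total-least-squares plane through a point cloud."""

    centroid: np.ndarray
    unit_normal: np.ndarray
    rms_residual: float


@dataclass(frozen=True)
class Axis:
    """Straight axis with an N-terminus -> C-terminus orientation."""

    point: np.ndarray
    unit_direction: np.ndarray
    rise_per_residue: float


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body superposition (proper rotation only)."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def fit_plane(
    points: np.ndarray | Sequence, reference_up: np.ndarray | None = None
) -> Plane:
    """Fit a total-least-squares plane to ``points`` (>= 3, non-collinear).

    The normal is the smallest principal component of the centered
    points.  Its sign is arbitrary unless ``reference_up`` is given, in
    which case the normal is flipped so ``dot(normal, reference_up) >= 0``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise DegenerateGeometryError("plane fit needs >= 3 points in 3-D")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    # SVD: right singular vectors are the principal directions
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    # collinear: second singular value ~ 0 relative to the first
    if svals[0] < 1e-12 or svals[1] / svals[0] < 1e-9:
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = vt[2]
    if reference_up is not None and float(np.dot(normal, reference_up)) < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(centroid=centroid, unit_normal=normal / np.linalg.norm(normal),
                 rms_residual=rms)


def _bisector(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    # unit bisector at b of the a-b-c angle; points toward the helix axis
    u = a - b
    v = c - b
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    w = u + v
    n = np.linalg.norm(w)
    if n < 1e-12:
        raise DegenerateGeometryError("straight angle; bisector undefined")
    return w / n


def _fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centroid, vt[0] / np.linalg.norm(vt[0])


def fit_helix_axis(ca_positions: np.ndarray | Sequence) -> Axis:
    """Fit a helix axis through ordered Cα positions (>= 5 residues).

    Local helix centers are estimated from sliding windows of four
    consecutive Cα atoms: the angle bisectors at the two inner atoms
    both point toward the axis, so the center is taken as the midpoint
    of closest approach of the two bisector lines (Kahn-style
    construction).  A total-least-squares line through the centers gives
    the axis; PCA on the raw Cα would be biased by the helical winding.
    The direction is oriented from the first to the last residue and
    ``rise_per_residue`` is the mean step of the Cα projections.
    """
    ca = np.asarray(ca_positions, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValidationError("ca_positions must be (n, 3)")
    n = ca.shape[0]
    if n < 5:
        raise InsufficientDataError(f"helix axis fit needs >= 5 Cα, got {n}")

    centers = []
    for i in range(n - 3):
        p0, p1, p2, p3 = ca[i : i + 4]
        try:
            b1 = _bisector(p0, p1, p2)
            b2 = _bisector(p1, p2, p3)
        except DegenerateGeometryError:
            continue  # locally straight stretch; skip the window
        # closest approach of lines p1 + t b1 and p2 + s b2
        d = p2 - p1
        a11 = 1.0
        a12 = -float(b1 @ b2)
        a22 = 1.0
        r1 = float(b1 @ d)
        r2 = -float(b2 @ d)
        det = a11 * a22 - a12 * a12
        if abs(det) < 1e-10:
            continue
        t = (r1 * a22 - r2 * a12) / det
        s = (a11 * r2 - a12 * r1) / det
        centers.append(0.5 * ((p1 + t * b1) + (p2 + s * b2)))

    if len(centers) >= 2:
        point, direction = _fit_line(np.asarray(centers))
    else:
        # collinear/degenerate input: fall back to a direct line fit
        point, direction = _fit_line(ca)

    if float(direction @ (ca[-1] - ca[0])) < 0:
        direction = -direction
    proj = ca @ direction
    rise = float(np.mean(np.diff(proj)))
    return Axis(point=point, unit_direction=direction, rise_per_residue=rise)


# ---------------------------------------------------------------------------
# Torsions
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle (degrees, IUPAC sign: cis = 0, trans = 180) in (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b, pair in ((b1, "p1/p2"), (b2, "p2/p3"), (b3, "p3/p4")):
        if np.linalg.norm(b) < 1e-9:
            raise DegenerateGeometryError(f"coincident points {pair}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(n1 @ n2)
    y = float(m1 @ n2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


# ---------------------------------------------------------------------------
# Superposition and ensemble RMSD
# ---------------------------------------------------------------------------

def superpose(reference: np.ndarray, mobile: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Kabsch algorithm (via quaternion alignment); the rotation is always
    proper, so mirror images are not silently matched.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValidationError("reference and mobile must be equal-shape (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise DegenerateGeometryError("superposition needs >= 3 atom pairs")
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    if np.allclose(ref - ref_c, 0) or np.allclose(mob - mob_c, 0):
        raise DegenerateGeometryError("all points coincident")
    rot, rssd = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    rmsd = float(rssd / np.sqrt(n))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


@dataclass(frozen=True)
class EnsembleRMSD:
    """Per-model RMSD to the converged mean structure."""

    mean: float
    sd: float
    per_model: np.ndarray
    n_iterations: int


def ensemble_rmsd(
    ensemble: StructureEnsemble,
    spec: SelectionSpec | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> EnsembleRMSD:
    """RMSD of an NMR bundle to its iteratively superposed mean structure.

    All models are superposed onto model 1, a mean structure is formed,
    models are re-superposed onto the mean, and the cycle repeats until
    the mean shifts by less than ``tol`` Å (RMS).  Reported are the mean
    and standard deviation of the per-model RMSDs to the converged mean.
    """
    if ensemble.n_models < 2:
        raise InsufficientDataError("ensemble RMSD needs >= 2 models")
    if spec is None:
        spec = SelectionSpec()
    sel = select_atoms(ensemble, spec)
    coords = np.stack([[a.position for a in atoms] for atoms in sel])

    mean = coords[0].copy()
    fitted = coords.copy()
    n_it = 0
    for n_it in range(1, max_iter + 1):
        for i in range(coords.shape[0]):
            sp = superpose(mean, coords[i])
            fitted[i] = sp.apply(coords[i])
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_mean - mean) ** 2)))
        mean = new_mean
        if shift < tol:
            break

    rmsds = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=1))
    return EnsembleRMSD(
        mean=float(rmsds.mean()),
        sd=float(rmsds.std(ddof=1)),
        per_model=rmsds,
        n_iterations=n_it,
    )


# ---------------------------------------------------------------------------
# Centers of mass
# ---------------------------------------------------------------------------

def center_of_mass(
    atoms: Sequence[AtomRecord], weighting: str = "mass"
) -> np.ndarray:
    """Weighted mean position of ``atoms`` (weighting ``mass`` or ``geometric``)."""
    if not atoms:
        raise ValidationError("center_of_mass of an empty atom list")
    pos = np.array([a.position for a in atoms], dtype=float)
    if weighting == "geometric":
        return pos.mean(axis=0)
    if weighting == "mass":
        w = np.array([atomic_mass(a.element) for a in atoms])
        return (pos * w[:, None]).sum(axis=0) / w.sum()
    raise ValidationError(f"unknown weighting '{weighting}'")


# ---------------------------------------------------------------------------
# Shrake-Rupley SASA
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    # golden-spiral quasi-uniform points on the unit sphere
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def sasa(
    model: Model,
    spec: SelectionSpec | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: dict[str, float] | None = None,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley solvent-accessible surface area.

    Test points are placed quasi-uniformly on each reported atom's
    solvent sphere (radius ``r_atom + probe``); the unoccluded fraction
    times the sphere area is that atom's SASA.  Occlusion is judged
    against *all* atoms of the model, whatever the selection — the
    selection only chooses which atoms are reported.

    Returns ``(per_atom_areas, total_area)`` in Å².
    """
    if n_sphere_points < 100:
        raise ValidationError("n_sphere_points must be >= 100")
    all_atoms = model.atoms
    if spec is None:
        spec = SelectionSpec()
    reported_idx = [i for i, a in enumerate(all_atoms) if spec.matches(a)]
    if not reported_idx:
        from .errors import EmptySelectionError

        raise EmptySelectionError("SASA selection matched no atoms")

    def radius_of(a: AtomRecord) -> float:
        if radii is not None and a.element.capitalize() in radii:
            return radii[a.element.capitalize()]
        return vdw_radius(a.element)

    pos = np.array([a.position for a in all_atoms])
    rad = np.array([radius_of(a) for a in all_atoms]) + probe_radius
    unit = _sphere_points(n_sphere_points)

    areas = np.zeros(len(reported_idx))
    for k, i in enumerate(reported_idx):
        pts = pos[i] + rad[i] * unit
        # neighbors whose solvent sphere can reach atom i's sphere
        d2 = np.sum((pos - pos[i]) ** 2, axis=1)
        nbr = np.where((d2 < (rad + rad[i]) ** 2) & (d2 > 1e-12))[0]
        if nbr.size:
            diff = pts[:, None, :] - pos[nbr][None, :, :]
            occluded = np.any(
                np.sum(diff**2, axis=2) < (rad[nbr] ** 2)[None, :], axis=1
            )
            frac = 1.0 - occluded.mean()
        else:
            frac = 1.0
        areas[k] = frac * 4.0 * np.pi * rad[i] ** 2
    return areas, float(areas.sum())
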