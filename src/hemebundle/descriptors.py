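"""Per-model and ensemble descriptors of helix-porphyrin-helix bundles.

Implements the quantities used to characterize NMR bundles of peptide-
porphyrin sandwich miniproteins: the interhelical angle between the
proximal (TD, His-bearing tetradecapeptide) and distal (D, decapeptide)
helices with single-linkage family clustering; the signed orientation
angle θ of the axial-His imidazole relative to the porphyrin N21-N23
reference axis; the metal-to-chain center-of-mass distance; porphyrin
solvent exposure; side-chain rotamer labels; backbone φ/ψ statistics and
simplified Ramachandran region assignment; hydrogen bonds with ensemble
occupancy; and conformational (secondary) chemical shifts.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import circmean, circstd

from .errors import (
    EmptySelectionError,
    IllDefinedOrientationError,
    InsufficientDataError,
    TopologyError,
    ValidationError,
)
from .geometry import (
    Axis,
    Plane,
    center_of_mass,
    dihedral,
    fit_helix_axis,
    fit_plane,
    sasa,
)
from .structure_io import (
    AtomRecord,
    Model,
    PorphyrinTopology,
    SelectionSpec,
    StructureEnsemble,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HisOrientation",
    "RotamerAssignment",
    "HBond",
    "BackboneDihedrals",
    "ConformationalShift",
    "interhelical_angle",
    "cluster_families",
    "his_theta",
    "co_to_chain_com",
    "classify_rotamer",
    "backbone_dihedrals",
    "circular_mean_sd",
    "ramachandran_region",
    "detect_hbonds",
    "conformational_shifts",
    "descriptor_table",
]

IMIDAZOLE_RING_ATOMS = ("CG", "ND1", "CD2", "CE1", "NE2")
BACKBONE_NAMES = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# Interhelical angle and family clustering
# ---------------------------------------------------------------------------

def interhelical_angle(axis_a: Axis, axis_b: Axis) -> float:
    """Angle (degrees, [0, 180]) between two N→C oriented helix axes.

    Deliberately *not* folded to [0, 90]: with both axes oriented from
    the N- to the C-terminus, nearly antiparallel helices report angles
    close to 180° and the two bundle families of a crossed sandwich
    (e.g. 64° vs 96°) stay distinguishable.
    """
    c = float(np.clip(axis_a.unit_direction @ axis_b.unit_direction, -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


@dataclass(frozen=True)
class FamilyClustering:
    labels: np.ndarray           # family label per input value (1-based)
    means: dict[int, float]
    sds: dict[int, float]
    sizes: dict[int, int]
    split_gap: float             # largest sorted gap, whether or not split


def cluster_families(
    values: np.ndarray | list[float], gap_threshold: float = 20.0
) -> FamilyClustering:
    """1-D single-linkage split of per-model angles into bundle families.

    The sorted values are split at the largest inter-point gap iff that
    gap exceeds ``gap_threshold`` (default 20°); otherwise a single
    family is reported.  The larger family gets label 1; on a size tie
    the family with the lower mean gets label 1.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 2:
        raise InsufficientDataError("family clustering needs >= 2 values")
    order = np.argsort(vals)
    svals = vals[order]
    gaps = np.diff(svals)
    big = int(np.argmax(gaps)) if gaps.size else 0
    split_gap = float(gaps[big]) if gaps.size else 0.0

    labels = np.ones(vals.size, dtype=int)
    if split_gap > gap_threshold:
        lower_idx = order[: big + 1]
        upper_idx = order[big + 1 :]
        groups = [lower_idx, upper_idx]
        sizes = [len(lower_idx), len(upper_idx)]
        means = [float(vals[g].mean()) for g in groups]
        if sizes[0] > sizes[1] or (sizes[0] == sizes[1] and means[0] <= means[1]):
            first, second = 0, 1
        else:
            first, second = 1, 0
        labels[groups[first]] = 1
        labels[groups[second]] = 2

    out_means, out_sds, out_sizes = {}, {}, {}
    for lab in sorted(set(labels.tolist())):
        sel = vals[labels == lab]
        out_means[lab] = float(sel.mean())
        out_sds[lab] = float(sel.std(ddof=1)) if sel.size > 1 else 0.0
        out_sizes[lab] = int(sel.size)
    return FamilyClustering(
        labels=labels, means=out_means, sds=out_sds, sizes=out_sizes,
        split_gap=split_gap,
    )


# ---------------------------------------------------------------------------
# Histidine orientation θ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HisOrientation:
    """Signed axial-His orientation relative to the porphyrin.

    θ is the acute angle from the N21→N23 reference axis to the
    projection of the imidazole plane normal onto the porphyrin plane,
    signed by the right-hand rule about the porphyrin normal oriented
    toward the His-bearing (proximal) side, and folded into (−90, 90].
    """

    theta: float
    porphyrin_plane: Plane
    imidazole_plane: Plane
    reference_axis: np.ndarray


def _porphyrin_ring_atoms(model: Model, topology: PorphyrinTopology) -> list[AtomRecord]:
    names = set(topology.ring_atom_names)
    atoms = [
        a for a in model.atoms
        if a.residue_name == topology.residue_name and a.atom_name in names
    ]
    if len(atoms) < len(names):
        missing = names - {a.atom_name for a in atoms}
        raise TopologyError(
            f"porphyrin ring incomplete: missing {sorted(missing)[:6]}"
        )
    return atoms


def _named_position(atoms: list[AtomRecord], name: str) -> np.ndarray:
    for a in atoms:
        if a.atom_name == name:
            return a.position
    raise TopologyError(f"atom {name} not found")


def _fold_half_circle(theta: float) -> float:
    while theta <= -90.0:
        theta += 180.0
    while theta > 90.0:
        theta -= 180.0
    return theta


def his_theta(
    model: Model,
    topology: PorphyrinTopology,
    his_residue: tuple[str, int],
    parallel_tol_deg: float = 10.0,
) -> HisOrientation:
    """Signed θ angle of the axial His imidazole (degrees in (−90, 90])."""
    ring = _porphyrin_ring_atoms(model, topology)
    n21 = _named_position(ring, "N21")
    n23 = _named_position(ring, "N23")

    chain, resnum = his_residue
    imid = [
        a for a in model.atoms
        if a.chain_id == chain and a.residue_number == resnum
        and a.atom_name in IMIDAZOLE_RING_ATOMS
    ]
    if len(imid) < 3:
        raise TopologyError(
            f"His {chain}{resnum}: found {len(imid)} imidazole ring atoms, need >= 3"
        )

    porph_plane = fit_plane(np.array([a.position for a in ring]))
    imid_pts = np.array([a.position for a in imid])
    imid_plane = fit_plane(imid_pts)

    # porphyrin normal oriented toward the His-bearing side
    n_p = porph_plane.unit_normal.copy()
    if float(n_p @ (imid_pts.mean(axis=0) - porph_plane.centroid)) < 0:
        n_p = -n_p

    n_h = imid_plane.unit_normal
    tilt = np.degrees(np.arccos(np.clip(abs(float(n_h @ n_p)), 0.0, 1.0)))
    if tilt < parallel_tol_deg:
        raise IllDefinedOrientationError(
            f"imidazole plane within {parallel_tol_deg}° of parallel to the "
            f"porphyrin (normal-normal tilt {tilt:.1f}°); θ ill-defined"
        )

    ref = n23 - n21
    ref = ref - (ref @ n_p) * n_p     # keep the reference in the porphyrin plane
    ref /= np.linalg.norm(ref)
    proj = n_h - (n_h @ n_p) * n_p
    proj /= np.linalg.norm(proj)

    theta = float(np.degrees(np.arctan2(float(np.cross(ref, proj) @ n_p),
                                        float(ref @ proj))))
    theta = _fold_half_circle(theta)
    return HisOrientation(
        theta=theta,
        porphyrin_plane=porph_plane,
        imidazole_plane=imid_plane,
        reference_axis=ref,
    )


# ---------------------------------------------------------------------------
# Metal-to-chain distance
# ---------------------------------------------------------------------------

def co_to_chain_com(
    model: Model,
    topology: PorphyrinTopology,
    chain_id: str,
    residue_range: tuple[int, int] | None = None,
    backbone_names: tuple[str, ...] = BACKBONE_NAMES,
) -> float:
    """Distance (Å) from the metal ion to the mass-weighted center of
    mass of the selected chain backbone."""
    metal = [a for a in model.atoms if a.atom_name == topology.metal_atom_name]
    if not metal:
        raise TopologyError(f"metal atom {topology.metal_atom_name} not found")
    sel = [
        a for a in model.atoms
        if a.chain_id == chain_id and a.atom_name in backbone_names
        and (residue_range is None
             or residue_range[0] <= a.residue_number <= residue_range[1])
    ]
    if not sel:
        raise EmptySelectionError(
            f"no backbone atoms for chain {chain_id} range {residue_range}"
        )
    com = center_of_mass(sel, weighting="mass")
    return float(np.linalg.norm(metal[0].position - com))


# ---------------------------------------------------------------------------
# Rotamers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotamerAssignment:
    """χ1/χ2 rotamer in penultimate-library letters (p=+60°, t=180°, m=−60°)."""

    chi1: float
    chi2: float
    label: str
    residue_id: tuple[str, int] | None = None


_CANONICAL_CHI = {"p": 60.0, "t": 180.0, "m": -60.0}


def _nearest_letter(chi: float) -> str:
    def circ_dist(a, b):
        d = abs(a - b) % 360.0
        return min(d, 360.0 - d)

    return min(_CANONICAL_CHI, key=lambda L: circ_dist(chi, _CANONICAL_CHI[L]))


def classify_rotamer(
    chi1: float, chi2: float, residue_id: tuple[str, int] | None = None
) -> RotamerAssignment:
    """Map (χ1, χ2) to the nearest canonical rotamer letters on the circle."""
    if not (np.isfinite(chi1) and np.isfinite(chi2)):
        raise ValidationError("χ angles must be finite")
    label = _nearest_letter(chi1) + _nearest_letter(chi2)
    return RotamerAssignment(chi1=float(chi1), chi2=float(chi2), label=label,
                             residue_id=residue_id)


# ---------------------------------------------------------------------------
# Backbone dihedrals and Ramachandran regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackboneDihedrals:
    residue_number: int
    residue_name: str
    phi: float | None      # None at chain start / across breaks
    psi: float | None      # None at chain end / across breaks


def _chain_residues(model: Model, chain_id: str) -> list[dict]:
    by_res: dict[int, dict] = {}
    names: dict[int, str] = {}
    for a in model.atoms:
        if a.chain_id != chain_id or a.is_hetero:
            continue
        by_res.setdefault(a.residue_number, {})[a.atom_name] = a.position
        names[a.residue_number] = a.residue_name
    return [
        {"resnum": rn, "resname": names[rn], "atoms": by_res[rn]}
        for rn in sorted(by_res)
    ]


def backbone_dihedrals(
    model: Model, chain_id: str, bond_cutoff: float = 2.0
) -> list[BackboneDihedrals]:
    """φ/ψ torsions along one chain; undefined angles are ``None``.

    A C(i−1)–N(i) distance above ``bond_cutoff`` Å is treated as a chain
    break: φ of residue i and ψ of residue i−1 are absent.
    """
    residues = _chain_residues(model, chain_id)
    if not residues:
        raise EmptySelectionError(f"chain {chain_id}: no peptide residues")

    def bonded(r_prev, r_next) -> bool:
        if "C" not in r_prev["atoms"] or "N" not in r_next["atoms"]:
            return False
        d = np.linalg.norm(r_prev["atoms"]["C"] - r_next["atoms"]["N"])
        return d < bond_cutoff and r_next["resnum"] == r_prev["resnum"] + 1

    out = []
    for i, res in enumerate(residues):
        at = res["atoms"]
        phi = psi = None
        has_core = all(n in at for n in ("N", "CA", "C"))
        if has_core and i > 0 and bonded(residues[i - 1], res):
            phi = dihedral(residues[i - 1]["atoms"]["C"], at["N"], at["CA"], at["C"])
        if has_core and i + 1 < len(residues) and bonded(res, residues[i + 1]):
            psi = dihedral(at["N"], at["CA"], at["C"], residues[i + 1]["atoms"]["N"])
        out.append(BackboneDihedrals(res["resnum"], res["resname"], phi, psi))
    return out


def circular_mean_sd(angles_deg) -> tuple[float, float]:
    """Circular mean and circular SD (degrees) of a list of angles."""
    a = np.asarray([x for x in angles_deg if x is not None], dtype=float)
    if a.size == 0:
        raise InsufficientDataError("no defined angles to aggregate")
    m = float(np.degrees(circmean(np.radians(a))))
    if m > 180.0:
        m -= 360.0
    s = float(np.degrees(circstd(np.radians(a))))
    return m, s


def _load_rama_grid() -> np.ndarray:
    ref = importlib.resources.files("hemebundle.data") / "rama_regions.txt"
    rows = []
    for line in ref.read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        rows.append(list(line.strip()))
    grid = np.array(rows)
    if grid.shape != (36, 36):
        raise ValidationError("packaged Ramachandran grid must be 36x36")
    return grid


_RAMA_GRID = _load_rama_grid()
_RAMA_LABELS = {
    "F": "favored",
    "A": "additionally_allowed",
    "G": "generously_allowed",
    "D": "disallowed",
}


def ramachandran_region(phi: float, psi: float) -> str:
    """Simplified PROCHECK-style region label from a packaged 10°×10° grid."""
    if phi is None or psi is None:
        raise ValidationError("phi/psi must be defined for region lookup")
    i = int(((phi + 180.0) % 360.0) // 10.0) % 36
    j = int(((psi + 180.0) % 360.0) // 10.0) % 36
    return _RAMA_LABELS[_RAMA_GRID[i, j]]


# ---------------------------------------------------------------------------
# Hydrogen bonds with ensemble occupancy
# ---------------------------------------------------------------------------

@dataclass
class HBond:
    donor: tuple[str, int, str]
    hydrogen: tuple[str, int, str] | None
    acceptor: tuple[str, int, str]
    distance_da: float                 # mean over models where present, Å
    angle_dha: float                   # mean over models where present, deg
    present_in_models: set[int] = field(default_factory=set)
    occupancy: float = 0.0


def _attached_hydrogens(model: Model) -> dict[int, list[int]]:
    """heavy-atom index -> indices of H atoms within covalent range."""
    pos = model.coords()
    h_idx = [i for i, a in enumerate(model.atoms) if a.element == "H"]
    heavy = [i for i, a in enumerate(model.atoms) if a.element in ("N", "O")]
    attach: dict[int, list[int]] = {i: [] for i in heavy}
    if not h_idx or not heavy:
        return attach
    hp = pos[h_idx]
    for i in heavy:
        d = np.linalg.norm(hp - pos[i], axis=1)
        for k in np.where(d < 1.25)[0]:
            attach[i].append(h_idx[k])
    return attach


def _build_amide_h(model: Model, idx_n: int) -> np.ndarray | None:
    """Ideal amide H on a backbone N: 1.01 Å opposite the CA/C(i−1) bisector."""
    a = model.atoms[idx_n]
    ca = cprev = None
    for b in model.atoms:
        if b.chain_id == a.chain_id:
            if b.residue_number == a.residue_number and b.atom_name == "CA":
                ca = b.position
            if b.residue_number == a.residue_number - 1 and b.atom_name == "C":
                cprev = b.position
    if ca is None or cprev is None:
        return None
    u = ca - a.position
    v = cprev - a.position
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    w = -(u + v)
    n = np.linalg.norm(w)
    if n < 1e-6:
        return None
    return a.position + 1.01 * w / n


def detect_hbonds(
    ensemble: StructureEnsemble,
    d_max: float = 3.5,
    angle_min: float = 120.0,
    donor_elements: tuple[str, ...] = ("N", "O"),
    acceptor_elements: tuple[str, ...] = ("O", "N"),
) -> list[HBond]:
    """Geometric hydrogen bonds, merged across models, with occupancy.

    A donor-acceptor pair counts in a model when the heavy-atom D···A
    distance is at most ``d_max`` Å and some D−H···A angle is at least
    ``angle_min``°.  Hydrogens missing on backbone amide donors are
    built at ideal positions (1.01 Å); other donors without hydrogens
    are skipped with a log warning.  Occupancy is the fraction of
    models in which the contact is present; identical donor/acceptor
    pairs are merged across models.
    """
    found: dict[tuple, dict] = {}
    n_models = ensemble.n_models
    warned: set[tuple] = set()

    for model in ensemble.models:
        pos = model.coords()
        attach = _attached_hydrogens(model)
        donors = []
        for i, a in enumerate(model.atoms):
            if a.element not in donor_elements:
                continue
            hs = [(pos[h], model.atoms[h].identity) for h in attach.get(i, [])]
            if not hs and a.element == "N" and a.atom_name == "N":
                hpos = _build_amide_h(model, i)
                if hpos is not None:
                    hs = [(hpos, None)]
            if not hs:
                if a.element == "N" and a.identity not in warned:
                    logger.warning("donor %s has no buildable hydrogen; skipped",
                                   a.identity)
                    warned.add(a.identity)
                continue
            donors.append((i, hs))
        acceptors = [
            i for i, a in enumerate(model.atoms)
            if a.element in acceptor_elements and not attach.get(i)
        ]
        for i, hs in donors:
            d_atom = model.atoms[i]
            for j in acceptors:
                a_atom = model.atoms[j]
                if i == j:
                    continue
                if (d_atom.chain_id, d_atom.residue_number) == (
                    a_atom.chain_id, a_atom.residue_number
                ):
                    continue
                dda = float(np.linalg.norm(pos[i] - pos[j]))
                if dda > d_max or dda < 2.0:
                    continue
                best = None
                for hpos, hid in hs:
                    v1 = pos[i] - hpos
                    v2 = pos[j] - hpos
                    cosang = float(
                        v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    )
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if ang >= angle_min and (best is None or ang > best[0]):
                        best = (ang, hid)
                if best is None:
                    continue
                key = (d_atom.identity, a_atom.identity)
                rec = found.setdefault(
                    key, {"models": set(), "d": [], "ang": [], "h": best[1]}
                )
                rec["models"].add(model.index)
                rec["d"].append(dda)
                rec["ang"].append(best[0])

    out = []
    for (don, acc), rec in sorted(found.items()):
        out.append(
            HBond(
                donor=don,
                hydrogen=rec["h"],
                acceptor=acc,
                distance_da=float(np.mean(rec["d"])),
                angle_dha=float(np.mean(rec["ang"])),
                present_in_models=rec["models"],
                occupancy=len(rec["models"]) / n_models,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Conformational shifts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConformationalShift:
    residue_number: int
    residue_name: str
    nucleus: str
    delta_obs: float
    delta_rc: float

    @property
    def shift(self) -> float:
        return self.delta_obs - self.delta_rc


def _load_rc_table() -> dict[str, float]:
    ref = importlib.resources.files("hemebundle.data") / "random_coil_ha.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    return dict(zip(df["residue"], df["delta_rc_ppm"].astype(float)))


def conformational_shifts(
    observed: pd.DataFrame,
    rc_table: dict[str, float] | None = None,
    nucleus: str = "HA",
) -> tuple[list[ConformationalShift], dict[str, int]]:
    """Δδ = δ_obs − δ_rc per residue, plus upfield/downfield counts.

    ``observed`` needs columns ``residue_number``, ``residue_name`` and
    ``delta_obs`` (ppm).  Negative shifts are upfield — the helical
    signature for Hα.
    """
    if rc_table is None:
        rc_table = _load_rc_table()
    shifts = []
    for row in observed.itertuples(index=False):
        rname = str(row.residue_name).upper()
        if rname not in rc_table:
            raise ValidationError(
                f"no random-coil entry for residue type '{rname}'"
            )
        shifts.append(
            ConformationalShift(
                residue_number=int(row.residue_number),
                residue_name=rname,
                nucleus=nucleus,
                delta_obs=float(row.delta_obs),
                delta_rc=rc_table[rname],
            )
        )
    summary = {
        "upfield": sum(1 for s in shifts if s.shift < 0),
        "downfield": sum(1 for s in shifts if s.shift > 0),
        "unshifted": sum(1 for s in shifts if s.shift == 0),
    }
    return shifts, summary


# ---------------------------------------------------------------------------
# The descriptor table
# ---------------------------------------------------------------------------

def _chain_ca(model: Model, chain_id: str, residue_range: tuple[int, int]):
    lo, hi = residue_range
    ca = [
        a.position for a in model.atoms
        if a.chain_id == chain_id and a.atom_name == "CA"
        and lo <= a.residue_number <= hi
    ]
    if len(ca) < 5:
        raise InsufficientDataError(
            f"chain {chain_id} range {residue_range}: {len(ca)} Cα (need >= 5)"
        )
    return np.asarray(ca)


def descriptor_table(
    ensemble: StructureEnsemble,
    td_chain: str = "T",
    d_chain: str = "D",
    td_range: tuple[int, int] = (2, 13),
    d_range: tuple[int, int] = (2, 9),
    his_residue: tuple[str, int] | None = None,
    compute_sasa: bool = True,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    gap_threshold: float = 20.0,
) -> pd.DataFrame:
    """Per-model descriptor table with ensemble/family aggregates.

    One row per model with columns ``interhelical_angle``, ``theta_his``,
    ``co_to_com_distance``, ``porphyrin_sasa`` and ``family_label``;
    family aggregates (mean ± sd per descriptor) are attached as
    ``df.attrs["aggregates"]``.  Default helix-axis residue ranges are
    TD 2-13 and D 2-9 (the helical stretches of the two chains).
    """
    if his_residue is None:
        his_residue = (td_chain, 6)
    topo = ensemble.topology
    rows = []
    for model in ensemble.models:
        axis_td = fit_helix_axis(_chain_ca(model, td_chain, td_range))
        axis_d = fit_helix_axis(_chain_ca(model, d_chain, d_range))
        row = {
            "model": model.index,
            "interhelical_angle": interhelical_angle(axis_td, axis_d),
            "theta_his": his_theta(model, topo, his_residue).theta,
            "co_to_com_distance": co_to_chain_com(model, topo, d_chain, d_range),
        }
        if compute_sasa:
            porph_names = frozenset(topo.ring_atom_names) | {topo.metal_atom_name}
            _, total = sasa(
                model,
                SelectionSpec.make(atom_names=porph_names, hetero=True),
                probe_radius=probe_radius,
                n_sphere_points=n_sphere_points,
            )
            row["porphyrin_sasa"] = total
        rows.append(row)

    df = pd.DataFrame(rows)
    if len(df) >= 2:
        fam = cluster_families(df["interhelical_angle"].to_numpy(), gap_threshold)
    else:
        fam = FamilyClustering(
            labels=np.ones(len(df), dtype=int),
            means={1: float(df["interhelical_angle"].iloc[0])},
            sds={1: 0.0}, sizes={1: len(df)}, split_gap=0.0,
        )
    df["family_label"] = fam.labels

    aggregates: dict[int, dict[str, tuple[float, float]]] = {}
    for lab in sorted(fam.sizes):
        sub = df[df["family_label"] == lab]
        agg = {}
        for col in df.columns:
            if col in ("model", "family_label"):
                continue
            v = sub[col].to_numpy(dtype=float)
            agg[col] = (
                float(v.mean()),
                float(v.std(ddof=1)) if v.size > 1 else 0.0,
            )
        agg["n_models"] = fam.sizes[lab]
        aggregates[lab] = agg
    df.attrs["aggregates"] = aggregates
    df.attrs["family_split_gap"] = fam.split_gap
    return df
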