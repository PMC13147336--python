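"""Synthetic structures, ensembles, NOE peak lists and spectra.

Everything downstream (descriptors, restraint calibration, isomer rules,
spectral fitting) is testable against known ground truth without any
deposited data: this module builds ideal α-helices with standard
backbone geometry, an idealized planar deuteroporphyrin template, and
assembles helix-porphyrin-helix sandwiches with controllable
interhelical angle, axial-His orientation θ, metal-to-chain distance and
per-model coordinate jitter.  NOE peak lists follow the r⁻⁶ intensity
law; spectra wrap the Mössbauer simulator with blueprint bookkeeping.

The default peptide sequences emulate the two chains of the miniprotein
family studied here (a 14-mer proximal His-bearing chain and a 10-mer
distal chain with Aib and Dab nonstandard residues); positions not
dictated by the design are filled with Gln, i.e. the sequences are
synthetic stand-ins, not a literature transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AssemblyError, ValidationError
from .geometry import fit_helix_axis
from .noe import ContactPattern, NOEPeak
from .spin import MossbauerDoublet, MossbauerSpectrum, simulate_mossbauer
from .structure_io import (
    AtomRecord,
    Model,
    PorphyrinTopology,
    StructureEnsemble,
    default_topology,
)

__all__ = [
    "SandwichBlueprint",
    "SandwichTruth",
    "TD_SEQUENCE",
    "D_SEQUENCE",
    "build_ideal_helix",
    "porphyrin_template",
    "assemble_sandwich",
    "generate_noe_peaks",
    "generate_mossbauer",
]

#: proximal tetradecapeptide: His6 carries the axial ligand; Lys9 anchors.
TD_SEQUENCE = ("ASP", "LEU", "GLN", "GLN", "LEU", "HIS", "SER",
               "GLN", "LYS", "ARG", "LYS", "ILE", "THR", "LEU")
#: distal decapeptide: Aib3/Aib7 promote the helix, Dab9 anchors.
D_SEQUENCE = ("ASP", "GLU", "AIB", "GLN", "LEU", "SER", "AIB",
              "GLN", "DAB", "ARG")

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL", "U": "AIB", "X": "DAB",
}

_KNOWN_RESIDUES = set(_ONE_TO_THREE.values())

# standard backbone geometry
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_B_C_O, _A_CA_C_O = 1.231, 120.8


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd|=bond, angle(b,c,d) and
    torsion(a,b,c,d) in the IUPAC sign convention."""
    theta = np.radians(angle_deg)
    chi = np.radians(-torsion_deg)  # frame below is left-handed in the torsion
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_u)
    n_u = n / np.linalg.norm(n)
    m_u = np.cross(n_u, bc_u)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_u + d_local[1] * m_u + d_local[2] * n_u


def _element_of(atom_name: str) -> str:
    return "H" if atom_name.startswith("H") else atom_name[0]


def _normalize_sequence(sequence) -> list[str]:
    if isinstance(sequence, str):
        seq = [_ONE_TO_THREE.get(ch.upper()) for ch in sequence]
        if None in seq:
            bad = sequence[seq.index(None)]
            raise ValidationError(f"unknown one-letter residue code '{bad}'")
        return seq
    seq = [str(s).upper() for s in sequence]
    for s in seq:
        if s not in _KNOWN_RESIDUES:
            raise ValidationError(f"unknown residue code '{s}'")
    return seq


def build_ideal_helix(
    sequence,
    phi: float = -57.0,
    psi: float = -47.0,
    chain_id: str = "A",
    start_resnum: int = 1,
    side_chain_chis: dict[int, tuple[float, float]] | None = None,
) -> Model:
    """Ideal helix with standard bond geometry and exact (φ, ψ).

    Backbone N/CA/C/O plus amide H, Hα and a Cβ stub per residue; Leu,
    His, Ser and Dab get rotamer-template side chains whose χ angles
    (``side_chain_chis``, keyed by residue number) are reproduced
    exactly by the torsion routine; Aib gets two β-methyls, Gly no Cβ.
    Recomputing backbone dihedrals on the result returns (φ, ψ) to
    numerical precision.
    """
    seq = _normalize_sequence(sequence)
    if not seq:
        raise ValidationError("empty sequence")
    if not (-180.0 < phi <= 180.0 and -180.0 < psi <= 180.0):
        raise ValidationError("phi/psi must lie in (-180, 180]")
    chis = side_chain_chis or {}

    n_res = len(seq)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi)
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi)

    atoms: list[AtomRecord] = []

    def add(resnum: int, resname: str, name: str, pos: np.ndarray):
        atoms.append(
            AtomRecord(
                chain_id=chain_id,
                residue_number=resnum,
                residue_name=resname,
                atom_name=name,
                element=_element_of(name),
                position=np.asarray(pos, dtype=float),
            )
        )

    for i, resname in enumerate(seq):
        rn = start_resnum + i
        add(rn, resname, "N", N[i])
        add(rn, resname, "CA", CA[i])
        add(rn, resname, "C", C[i])
        # carbonyl O: anti to the next amide N (torsion ψ+180)
        add(rn, resname, "O",
            _nerf(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0))
        if i > 0:
            u = CA[i] - N[i]
            v = C[i - 1] - N[i]
            u /= np.linalg.norm(u)
            v /= np.linalg.norm(v)
            w = -(u + v)
            add(rn, resname, "H", N[i] + 1.01 * w / np.linalg.norm(w))

        # side chain
        cb = None
        if resname != "GLY":
            cb = _nerf(C[i], N[i], CA[i], 1.53, 110.5, 122.0)
            add(rn, resname, "CB", cb)
        if resname == "AIB":
            cb2 = _nerf(C[i], N[i], CA[i], 1.53, 110.5, -118.0)
            add(rn, resname, "CB2", cb2)
            add(rn, resname, "HB2", cb2 + 1.0 * _unit(cb2 - CA[i]))
        ha_ref = cb if cb is not None else None
        dirs = [_unit(N[i] - CA[i]), _unit(C[i] - CA[i])]
        if ha_ref is not None:
            dirs.append(_unit(ha_ref - CA[i]))
        ha_dir = -np.sum(dirs, axis=0)
        if resname != "AIB":  # Aib has no Hα (two β-methyls instead)
            add(rn, resname, "HA", CA[i] + 1.09 * ha_dir / np.linalg.norm(ha_dir))

        chi1, chi2 = chis.get(rn, _default_chis(resname))
        if resname == "LEU" and cb is not None:
            cg = _nerf(N[i], CA[i], cb, 1.53, 114.0, chi1)
            cd1 = _nerf(CA[i], cb, cg, 1.53, 110.5, chi2)
            cd2 = _nerf(CA[i], cb, cg, 1.53, 110.5, chi2 + 120.0)
            add(rn, resname, "CG", cg)
            add(rn, resname, "CD1", cd1)
            add(rn, resname, "CD2", cd2)
            add(rn, resname, "HD1", cd1 + 1.0 * _unit(cd1 - cg))
            add(rn, resname, "HD2", cd2 + 1.0 * _unit(cd2 - cg))
        elif resname == "HIS" and cb is not None:
            cg = _nerf(N[i], CA[i], cb, 1.50, 113.8, chi1)
            nd1 = _nerf(CA[i], cb, cg, 1.378, 122.5, chi2)
            ce1 = _nerf(cb, cg, nd1, 1.32, 109.0, 180.0)
            ne2 = _nerf(cg, nd1, ce1, 1.32, 111.3, 0.0)
            cd2 = _nerf(ce1, nd1, cg, 1.36, 105.2, 0.0)
            for nm, p in (("CG", cg), ("ND1", nd1), ("CE1", ce1),
                          ("NE2", ne2), ("CD2", cd2)):
                add(rn, resname, nm, p)
            add(rn, resname, "HD1", nd1 + 1.01 * _unit(nd1 - 0.5 * (cg + ce1)))
        elif resname == "SER" and cb is not None:
            og = _nerf(N[i], CA[i], cb, 1.42, 110.8, chi1)
            add(rn, resname, "OG", og)
            add(rn, resname, "HG", og + 0.96 * _unit(og - cb))
        elif resname == "DAB" and cb is not None:
            cg = _nerf(N[i], CA[i], cb, 1.53, 112.0, chi1)
            nd = _nerf(CA[i], cb, cg, 1.47, 111.0, chi2)
            add(rn, resname, "CG", cg)
            add(rn, resname, "ND", nd)
            # the side-chain amide protons (the NHδ anchor of the distal chain)
            add(rn, resname, "HD1", nd + 1.01 * _unit(nd - cg))
            hd2 = _nerf(cb, cg, nd, 1.01, 109.5, 60.0)
            add(rn, resname, "HD2", hd2)
        elif cb is not None:
            add(rn, resname, "HB", cb + 1.0 * _unit(cb - CA[i]))

    return Model(index=1, atoms=atoms)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _default_chis(resname: str) -> tuple[float, float]:
    return {"LEU": (-60.0, 180.0), "HIS": (-76.0, 86.0)}.get(resname, (-60.0, 180.0))


# ---------------------------------------------------------------------------
# Porphyrin template
# ---------------------------------------------------------------------------

# radial layout of the idealized macrocycle (Å)
_R_N, _R_CA, _R_CB, _R_MESO = 2.05, 3.00, 4.28, 3.42
_R_SUB, _R_SUB2 = 5.55, 6.95


def porphyrin_template(
    topology: PorphyrinTopology | None = None,
    chain_id: str = "X",
) -> list[AtomRecord]:
    """Idealized planar deuteroporphyrin + metal at the ring center.

    The macrocycle lies exactly in z = 0 with N21 on +x and N23 on −x,
    so the N21→N23 reference axis is −x and the N22–N24 axis is exactly
    orthogonal.  Ring positions 1-20 run counterclockwise; methyls sit
    at 3, 8, 13 and 17, ring protons at the deutero positions 7 and 12,
    and propionyl methylene stubs at the anchoring positions 2 and 18.
    """
    topo = topology or default_topology()
    atoms: list[AtomRecord] = []

    def add(name: str, radius: float, angle_deg: float, resname: str,
            resnum: int, element: str | None = None):
        a = np.radians(angle_deg)
        atoms.append(
            AtomRecord(
                chain_id=chain_id,
                residue_number=resnum,
                residue_name=resname,
                atom_name=name,
                element=element or _element_of(name),
                position=np.array([radius * np.cos(a), radius * np.sin(a), 0.0]),
                is_hetero=True,
            )
        )

    rname = topo.residue_name
    for k in range(4):  # pyrroles on +x, +y, -x, -y
        base = 90.0 * k
        add(f"N2{k + 1}", _R_N, base, rname, 1, element="N")
        p = 5 * k
        add(f"C{p + 1}", _R_CA, base - 27.0, rname, 1)
        add(f"C{p + 2}", _R_CB, base - 11.0, rname, 1)
        add(f"C{p + 3}", _R_CB, base + 11.0, rname, 1)
        add(f"C{p + 4}", _R_CA, base + 27.0, rname, 1)
        add(f"C{p + 5}", _R_MESO, base + 45.0, rname, 1)

    angle_of_pos = {}
    for k in range(4):
        base = 90.0 * k
        for p, a in ((5 * k + 1, base - 27.0), (5 * k + 2, base - 11.0),
                     (5 * k + 3, base + 11.0), (5 * k + 4, base + 27.0),
                     (5 * k + 5, base + 45.0)):
            angle_of_pos[p] = a

    # substituents: propionyls at 2 and 18, methyls at 3/8/13/17, H at 7/12
    for pos, names in topo.substituent_positions.items():
        a = angle_of_pos[pos]
        if pos in topo.propionyl_attachment:
            add(names[0], _R_SUB, a, rname, 1)
            if len(names) > 1:
                add(names[1], _R_SUB2, a, rname, 1)
        else:
            add(names[0], _R_SUB if names[0][0] != "H" else 5.25, a, rname, 1)

    atoms.append(
        AtomRecord(
            chain_id=chain_id, residue_number=2,
            residue_name=topo.metal_residue_name,
            atom_name=topo.metal_atom_name, element="Co",
            position=np.zeros(3), is_hetero=True,
        )
    )
    return atoms


# ---------------------------------------------------------------------------
# Sandwich assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SandwichBlueprint:
    """Ground-truth parameters of one synthetic sandwich ensemble."""

    td_sequence: tuple[str, ...] = TD_SEQUENCE
    d_sequence: tuple[str, ...] = D_SEQUENCE
    target_interhelical_angle: float = 21.0
    target_theta_his: float = -33.4
    td_anchor_position: int = 18
    metal_offset: float = 7.0
    jitter_sd: float = 0.0
    n_models: int = 20
    seed: int = 0
    phi: float = -57.0
    psi: float = -47.0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValidationError("n_models must be >= 1")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.td_anchor_position not in (2, 18):
            raise ValidationError("td_anchor_position must be 2 or 18")


@dataclass(frozen=True)
class SandwichTruth:
    """Exact pre-jitter descriptor values implied by a blueprint."""

    interhelical_angle: float
    theta_his: float
    co_to_com_distance: float
    td_anchor_position: int
    dab9_contacts: ContactPattern
    leu5_contacts: ContactPattern
    diastereomer: str = "Delta"


_HIS_NE2_Z = -2.1          # coordination distance below the metal
_IMID_RING_R = 1.17        # circumradius of the imidazole pentagon
_CLASH_CUTOFF = 2.4        # Å, non-bonded heavy-atom clash threshold

# Leu5↔ring contact labels for the two macrocycle sides (Δ rule table)
_SIDE_A_LABELS = ("3CH3", "5H", "7CH3", "8H", "10H")
_SIDE_B_LABELS = ("12CH3", "13H", "15H", "17CH3")


def _orient_helix(model: Model, chain_id: str, axis_range: tuple[int, int],
                  anchor_resnum: int) -> np.ndarray:
    """Coordinates rotated so the fitted helix axis is exactly +x and the
    anchor residue's Cα azimuth points to +z; axis passes through 0."""
    ca = np.asarray([
        a.position for a in model.atoms
        if a.atom_name == "CA" and axis_range[0] <= a.residue_number <= axis_range[1]
    ])
    axis = fit_helix_axis(ca)
    coords = model.coords() - axis.point
    anchor = next(
        a.position for a in model.atoms
        if a.atom_name == "CA" and a.residue_number == anchor_resnum
    ) - axis.point
    perp = anchor - (anchor @ axis.unit_direction) * axis.unit_direction
    rot, _ = Rotation.align_vectors(
        [[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]],
        [axis.unit_direction, perp / np.linalg.norm(perp)],
    )
    return coords @ rot.as_matrix().T


def _imidazole_ring(theta_deg: float) -> dict[str, np.ndarray]:
    """Imidazole ring below the metal in a plane containing the porphyrin
    normal, rotated so the recovered θ equals ``theta_deg`` exactly.

    With the porphyrin in z = 0 (N21 on +x, N23 on −x) the reference
    axis is −x and the proximal-side normal is −z; the ring's in-plane
    horizontal direction u is chosen so the plane normal's projection
    makes the signed angle θ with the reference axis.
    """
    a = np.radians(-(90.0 + theta_deg))
    u = np.array([np.cos(a), np.sin(a), 0.0])
    z = np.array([0.0, 0.0, 1.0])
    ne2 = np.array([0.0, 0.0, _HIS_NE2_Z])
    center = ne2 + _IMID_RING_R * np.array([0.0, 0.0, -1.0])
    ring = {}
    for name, vertex_deg in (("NE2", 90.0), ("CE1", 162.0), ("ND1", 234.0),
                             ("CG", 306.0), ("CD2", 18.0)):
        va = np.radians(vertex_deg)
        ring[name] = center + _IMID_RING_R * (np.cos(va) * u + np.sin(va) * z)
    ring["CB"] = ring["CG"] + 1.50 * _unit(ring["CG"] - center)
    return ring


def _check_clashes(groups: dict[str, list[AtomRecord]],
                   exempt: set[tuple[str, str]]) -> None:
    names = list(groups)
    for gi in range(len(names)):
        for gj in range(gi + 1, len(names)):
            a_list = [a for a in groups[names[gi]] if a.element != "H"]
            b_list = [b for b in groups[names[gj]] if b.element != "H"]
            pa = np.array([a.position for a in a_list])
            pb = np.array([b.position for b in b_list])
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            for i, j in zip(*np.where(d < _CLASH_CUTOFF)):
                pair = (a_list[i].atom_name, b_list[j].atom_name)
                if pair in exempt or pair[::-1] in exempt:
                    continue
                raise AssemblyError(
                    f"steric clash {names[gi]}:{a_list[i].identity} - "
                    f"{names[gj]}:{b_list[j].identity} at {d[i, j]:.2f} Å"
                )


def assemble_sandwich(
    blueprint: SandwichBlueprint,
    topology: PorphyrinTopology | None = None,
) -> tuple[StructureEnsemble, SandwichTruth]:
    """Build a jittered sandwich ensemble plus its exact ground truth.

    The porphyrin template sits at the origin in z = 0; the proximal TD
    helix runs along +x below the plane with its His6 imidazole bonded
    to the metal (Nε2 at 2.1 Å) and oriented to the target θ; the
    distal D helix runs above the plane, rotated about the porphyrin
    normal to the target interhelical angle, with its backbone center
    of mass placed at ``metal_offset`` from the metal.  Per-model
    isotropic N(0, jitter_sd²) coordinate noise is seeded.  Chain ids:
    TD = "T", D = "D", porphyrin/metal = "X".
    """
    bp = blueprint
    topo = topology or default_topology()
    porph = porphyrin_template(topo)

    # --- proximal helix with controlled His orientation -------------------
    td_raw = build_ideal_helix(bp.td_sequence, bp.phi, bp.psi, chain_id="T")
    his_resnum = next(
        (i + 1 for i, r in enumerate(_normalize_sequence(bp.td_sequence))
         if r == "HIS"), None)
    if his_resnum is None:
        raise ValidationError("TD sequence must contain a His residue")
    td_coords = _orient_helix(td_raw, "T", (2, len(bp.td_sequence) - 1), his_resnum)
    his_ca_idx = next(
        i for i, a in enumerate(td_raw.atoms)
        if a.residue_number == his_resnum and a.atom_name == "CA"
    )
    ring = _imidazole_ring(bp.target_theta_his)
    target_ca = ring["CB"] + 1.53 * np.array([0.0, 0.0, -1.0])
    td_coords = td_coords + (target_ca - td_coords[his_ca_idx])

    ring_names = set(ring)
    td_atoms = []
    for a, pos in zip(td_raw.atoms, td_coords):
        if a.residue_number == his_resnum and (
            a.atom_name in ring_names or a.atom_name in ("HB", "HD1")
        ):
            continue  # replaced by the metal-anchored ring
        td_atoms.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                                   a.atom_name, a.element, pos))
    for name, pos in ring.items():
        td_atoms.append(AtomRecord("T", his_resnum, "HIS", name,
                                   _element_of(name), pos))

    # --- distal helix at the target interhelical angle --------------------
    d_raw = build_ideal_helix(bp.d_sequence, bp.phi, bp.psi, chain_id="D")
    d_range = (2, len(bp.d_sequence) - 1)
    d_coords = _orient_helix(d_raw, "D", d_range, 5)
    rz = Rotation.from_euler("z", bp.target_interhelical_angle, degrees=True)
    d_coords = d_coords @ rz.as_matrix().T
    # place the backbone CoM of the axis range at metal_offset above the metal
    from .geometry import atomic_mass

    bb_idx = [
        i for i, a in enumerate(d_raw.atoms)
        if a.atom_name in ("N", "CA", "C", "O")
        and d_range[0] <= a.residue_number <= d_range[1]
    ]
    w = np.array([atomic_mass(d_raw.atoms[i].element) for i in bb_idx])
    com = (d_coords[bb_idx] * w[:, None]).sum(axis=0) / w.sum()
    d_coords = d_coords + (np.array([0.0, 0.0, bp.metal_offset]) - com)
    d_atoms = [
        AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                   a.atom_name, a.element, pos)
        for a, pos in zip(d_raw.atoms, d_coords)
    ]

    exempt = {("NE2", topo.metal_atom_name), ("CE1", topo.metal_atom_name),
              ("CD2", topo.metal_atom_name)}
    _check_clashes({"T": td_atoms, "D": d_atoms, "X": porph}, exempt)

    base_atoms = td_atoms + d_atoms + porph
    rng = np.random.default_rng(bp.seed)
    models = []
    for m in range(1, bp.n_models + 1):
        if bp.jitter_sd > 0:
            noise = rng.normal(0.0, bp.jitter_sd, size=(len(base_atoms), 3))
        else:
            noise = np.zeros((len(base_atoms), 3))
        models.append(
            Model(
                index=m,
                atoms=[
                    AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                               a.atom_name, a.element, a.position + dn,
                               is_hetero=a.is_hetero)
                    for a, dn in zip(base_atoms, noise)
                ],
            )
        )

    ensemble = StructureEnsemble(
        models=models, topology=topo,
        metadata={"blueprint": bp, "generator": "assemble_sandwich"},
    )
    # the distal-chain anchor proton contacts its *own* propionyl, i.e. the
    # one the TD chain does not occupy
    dab_propionyl = 2 if bp.td_anchor_position == 18 else 18
    leu5_labels = _SIDE_A_LABELS if bp.td_anchor_position == 18 else _SIDE_B_LABELS
    truth = SandwichTruth(
        interhelical_angle=bp.target_interhelical_angle,
        theta_his=bp.target_theta_his,
        co_to_com_distance=bp.metal_offset,
        td_anchor_position=bp.td_anchor_position,
        dab9_contacts=ContactPattern.make(
            "Dab9 NHδ", {f"propionyl-{dab_propionyl}"}),
        leu5_contacts=ContactPattern.make("Leu5 side chain", leu5_labels),
        diastereomer="Delta",
    )
    return ensemble, truth


# ---------------------------------------------------------------------------
# NOE peaks and spectra
# ---------------------------------------------------------------------------

def generate_noe_peaks(
    model: Model,
    cutoff: float = 5.0,
    c: float = 1.0,
    noise_cv: float = 0.0,
    seed: int | None = None,
    intensity_floor: float = 1e-12,
) -> list[NOEPeak]:
    """One peak per proton pair within ``cutoff`` Å, intensity c/d⁶.

    Multiplicative Gaussian noise with coefficient of variation
    ``noise_cv`` emulates integration error; intensities are floored at
    a small positive value so downstream calibration never sees zero.
    """
    if not (2.0 <= cutoff <= 7.0):
        raise ValidationError("cutoff must lie in [2, 7] Å")
    rng = np.random.default_rng(seed)
    protons = [a for a in model.atoms if a.element == "H"]
    peaks = []
    for i in range(len(protons)):
        for j in range(i + 1, len(protons)):
            d = float(np.linalg.norm(protons[i].position - protons[j].position))
            if d > cutoff or d < 1e-6:
                continue
            inten = c / d**6
            if noise_cv > 0:
                inten *= 1.0 + rng.normal(0.0, noise_cv)
            peaks.append(
                NOEPeak(
                    atom_a=protons[i].identity,
                    atom_b=protons[j].identity,
                    intensity=max(inten, intensity_floor),
                )
            )
    return peaks


def generate_mossbauer(
    doublets: list[MossbauerDoublet],
    grid: np.ndarray,
    total_depth: float = 0.1,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> tuple[MossbauerSpectrum, dict]:
    """Simulate a spectrum and keep the generating truth for recovery
    assertions; a 1.0/0.0 area split degenerates to a single doublet."""
    live = [d for d in doublets if d.area_fraction > 0.0]
    spectrum = simulate_mossbauer(
        live, grid, total_depth=total_depth, noise_sd=noise_sd, seed=seed
    )
    truth = {
        "doublets": list(doublets),
        "total_depth": total_depth,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return spectrum, truth
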