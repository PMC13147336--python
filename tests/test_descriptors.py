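"""Ensemble descriptors: angles, θ, distances, rotamers, H-bonds, shifts."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from hemebundle.descriptors import (
    backbone_dihedrals,
    circular_mean_sd,
    classify_rotamer,
    cluster_families,
    co_to_chain_com,
    conformational_shifts,
    descriptor_table,
    detect_hbonds,
    his_theta,
    interhelical_angle,
    ramachandran_region,
)
from hemebundle.errors import IllDefinedOrientationError, ValidationError
from hemebundle.geometry import Axis
from hemebundle.structure_io import (
    AtomRecord,
    Model,
    StructureEnsemble,
    default_topology,
)
from hemebundle.synthetic import (
    SandwichBlueprint,
    assemble_sandwich,
    build_ideal_helix,
)


def _axis(direction):
    d = np.asarray(direction, float)
    return Axis(point=np.zeros(3), unit_direction=d / np.linalg.norm(d),
                rise_per_residue=1.5)


# ---------------------------------------------------------------------------
# interhelical angle + families
# ---------------------------------------------------------------------------

class TestInterhelicalAngle:
    def test_parallel_is_zero(self):
        assert interhelical_angle(_axis([1, 0, 0]), _axis([1, 0, 0])) == 0.0

    def test_antiparallel_is_180(self):
        a = interhelical_angle(_axis([1, 0, 0]), _axis([-1, 0, 0]))
        assert a == pytest.approx(180.0, abs=1e-9)

    def test_obtuse_not_folded(self):
        # oriented axes at 96° must report 96, not 84
        d = Rotation.from_euler("z", 96, degrees=True).apply([1, 0, 0])
        assert interhelical_angle(_axis([1, 0, 0]), _axis(d)) == pytest.approx(96.0)

    def test_symmetric(self, rng):
        a, b = _axis(rng.normal(size=3)), _axis(rng.normal(size=3))
        assert interhelical_angle(a, b) == pytest.approx(
            interhelical_angle(b, a), abs=1e-12)


class TestClusterFamilies:
    def test_tight_values_one_family(self):
        fam = cluster_families([20.0, 21.5, 22.0, 24.0, 19.0])
        assert set(fam.labels) == {1}
        assert fam.sizes == {1: 5}

    def test_bimodal_12_8_split(self):
        # mirrors the two-family bundle: 12 models near 60°, 8 near 95°.
        # jitter (sd ~5°) is clipped to ±7° so the inter-family gap the
        # rule keys on is guaranteed to exceed the 20° threshold
        rng = np.random.default_rng(7)
        vals = np.concatenate([
            60.0 + np.clip(rng.normal(0.0, 5.0, size=12), -7, 7),
            95.0 + np.clip(rng.normal(0.0, 5.0, size=8), -7, 7),
        ])
        fam = cluster_families(vals)
        assert fam.sizes == {1: 12, 2: 8}
        assert fam.means[1] == pytest.approx(60.0, abs=5.0)
        assert fam.means[2] == pytest.approx(95.0, abs=5.0)

    def test_larger_family_gets_label_1_even_if_higher_mean(self):
        vals = [10.0, 11.0, 90.0, 91.0, 92.0]
        fam = cluster_families(vals)
        assert fam.sizes[1] == 3 and fam.means[1] > fam.means[2]


# ---------------------------------------------------------------------------
# His θ
# ---------------------------------------------------------------------------

class TestHisTheta:
    def test_blueprint_theta_recovered_exactly(self, clean_sandwich):
        ens, truth = clean_sandwich
        ori = his_theta(ens.models[0], ens.topology, ("T", 6))
        assert ori.theta == pytest.approx(truth.theta_his, abs=1e-6)

    def test_zero_theta(self):
        bp = SandwichBlueprint(target_theta_his=0.0, jitter_sd=0.0, n_models=1)
        ens, _ = assemble_sandwich(bp)
        ori = his_theta(ens.models[0], ens.topology, ("T", 6))
        assert ori.theta == pytest.approx(0.0, abs=1e-6)

    def test_rigid_transform_invariance(self, clean_sandwich, rng):
        ens, truth = clean_sandwich
        m = ens.models[0]
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 10
        moved = Model(index=1, atoms=[
            AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                       a.atom_name, a.element, a.position @ R.T + t,
                       is_hetero=a.is_hetero)
            for a in m.atoms
        ])
        ori = his_theta(moved, ens.topology, ("T", 6))
        assert ori.theta == pytest.approx(truth.theta_his, abs=1e-6)

    def test_mirror_flips_sign(self, clean_sandwich):
        ens, truth = clean_sandwich
        m = ens.models[0]
        mirrored = Model(index=1, atoms=[
            AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                       a.atom_name, a.element,
                       a.position * np.array([-1.0, 1.0, 1.0]),
                       is_hetero=a.is_hetero)
            for a in m.atoms
        ])
        ori = his_theta(mirrored, ens.topology, ("T", 6))
        assert ori.theta == pytest.approx(-truth.theta_his, abs=1e-6)

    def test_parallel_imidazole_rejected(self, clean_sandwich):
        # flatten the imidazole into the porphyrin plane: θ undefined
        ens, _ = clean_sandwich
        m = ens.models[0]
        ring = ["NE2", "CE1", "ND1", "CG", "CD2"]
        # horizontal pentagon at z = -3: imidazole parallel to the porphyrin
        flat = {
            nm: np.array([np.cos(a), np.sin(a), -3.0])
            for nm, a in zip(ring, np.linspace(0, 2 * np.pi, 5, endpoint=False))
        }
        atoms = []
        for a in m.atoms:
            pos = a.position.copy()
            if a.residue_number == 6 and a.chain_id == "T" and a.atom_name in flat:
                pos = flat[a.atom_name]
            atoms.append(AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                                    a.atom_name, a.element, pos,
                                    is_hetero=a.is_hetero))
        with pytest.raises(IllDefinedOrientationError):
            his_theta(Model(index=1, atoms=atoms), ens.topology, ("T", 6))


# ---------------------------------------------------------------------------
# Co–CoM distance
# ---------------------------------------------------------------------------

class TestCoToChainCom:
    def test_blueprint_offset_exact(self, clean_sandwich):
        ens, truth = clean_sandwich
        d = co_to_chain_com(ens.models[0], ens.topology, "D", (2, 9))
        assert d == pytest.approx(truth.co_to_com_distance, abs=1e-9)

    def test_metal_at_com_gives_zero(self, clean_sandwich):
        ens, _ = clean_sandwich
        m = ens.models[0]
        from hemebundle.geometry import center_of_mass

        bb = [a for a in m.atoms if a.chain_id == "D"
              and a.atom_name in ("N", "CA", "C", "O")]
        com = center_of_mass(bb, "mass")
        atoms = [
            AtomRecord(a.chain_id, a.residue_number, a.residue_name,
                       a.atom_name, a.element,
                       com if a.atom_name == "CO" else a.position,
                       is_hetero=a.is_hetero)
            for a in m.atoms
        ]
        d = co_to_chain_com(Model(index=1, atoms=atoms), ens.topology, "D")
        assert d == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# rotamers, φ/ψ, Ramachandran
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "chi1,chi2,label",
    [
        (-175.0, 64.0, "tp"),   # Leu5 of the first diastereomer
        (-80.0, 172.0, "mt"),   # Leu2 of the second
        (-161.0, 170.0, "tt"),  # Leu5 of the second
        (60.0, 60.0, "pp"),
        (175.0, -170.0, "tt"),  # wrap-around near ±180
    ],
)
def test_classify_rotamer(chi1, chi2, label):
    assert classify_rotamer(chi1, chi2).label == label


class TestBackboneDihedrals:
    def test_ideal_helix_round_trip(self):
        m = build_ideal_helix(["ALA"] * 8, -57.0, -47.0)
        bd = backbone_dihedrals(m, "A")
        inner = bd[1:-1]
        assert all(b.phi == pytest.approx(-57.0, abs=1e-6) for b in inner)
        assert all(b.psi == pytest.approx(-47.0, abs=1e-6) for b in inner)

    def test_termini_absent(self):
        m = build_ideal_helix(["ALA"] * 6, -57.0, -47.0)
        bd = backbone_dihedrals(m, "A")
        assert bd[0].phi is None and bd[-1].psi is None
        assert bd[0].psi is not None and bd[-1].phi is not None

    def test_circular_mean(self):
        m, s = circular_mean_sd([179.0, -179.0])
        assert m == pytest.approx(180.0, abs=1e-6) or m == pytest.approx(-180.0, abs=1e-6)
        assert s < 2.0


class TestRamachandran:
    def test_helical_mean_favored(self):
        assert ramachandran_region(-68.0, -36.0) == "favored"

    def test_origin_disallowed(self):
        assert ramachandran_region(0.0, 0.0) == "disallowed"

    def test_every_cell_labelled(self):
        labels = {"favored", "additionally_allowed", "generously_allowed",
                  "disallowed"}
        seen = set()
        for phi in range(-175, 185, 10):
            for psi in range(-175, 185, 10):
                seen.add(ramachandran_region(float(phi), float(psi)))
        assert seen <= labels and "favored" in seen and "disallowed" in seen


# ---------------------------------------------------------------------------
# H-bonds
# ---------------------------------------------------------------------------

def _nh_o_model(index: int, d_no: float) -> Model:
    """Linear N-H···O=C at a chosen N···O distance."""
    atoms = [
        AtomRecord("A", 1, "ALA", "N", "N", np.array([0.0, 0.0, 0.0])),
        AtomRecord("A", 1, "ALA", "H", "H", np.array([1.01, 0.0, 0.0])),
        AtomRecord("A", 1, "ALA", "CA", "C", np.array([-0.8, 1.2, 0.0])),
        AtomRecord("A", 2, "GLY", "O", "O", np.array([d_no, 0.0, 0.0])),
        AtomRecord("A", 2, "GLY", "C", "C", np.array([d_no + 1.23, 0.0, 0.0])),
    ]
    return Model(index=index, atoms=atoms)


class TestDetectHBonds:
    def test_ideal_linear_contact(self):
        ens = StructureEnsemble(models=[_nh_o_model(1, 2.9)])
        bonds = detect_hbonds(ens)
        assert len(bonds) == 1
        b = bonds[0]
        assert b.donor == ("A", 1, "N") and b.acceptor == ("A", 2, "O")
        assert b.occupancy == 1.0
        assert b.distance_da == pytest.approx(2.9, abs=1e-9)

    def test_long_contact_rejected(self):
        ens = StructureEnsemble(models=[_nh_o_model(1, 4.5)])
        assert detect_hbonds(ens) == []

    def test_occupancy_15_of_20(self):
        # contact satisfied in 15 models, broken in 5 -> occupancy 0.75,
        # the occurrence pattern reported for the distal-serine contact
        models = [_nh_o_model(i, 2.9 if i <= 15 else 4.6) for i in range(1, 21)]
        ens = StructureEnsemble(models=models)
        bonds = detect_hbonds(ens)
        assert len(bonds) == 1
        assert bonds[0].occupancy == pytest.approx(0.75)
        assert bonds[0].present_in_models == set(range(1, 16))

    def test_helix_has_i_to_i4_pattern(self, clean_sandwich):
        ens, _ = clean_sandwich
        bonds = detect_hbonds(ens)
        seps = {
            b.donor[1] - b.acceptor[1]
            for b in bonds
            if b.donor[0] == b.acceptor[0] == "T"
            and b.donor[2] == "N" and b.acceptor[2] == "O"
        }
        assert 4 in seps


# ---------------------------------------------------------------------------
# conformational shifts
# ---------------------------------------------------------------------------

class TestConformationalShifts:
    def test_basic_arithmetic(self):
        obs = pd.DataFrame(
            {"residue_number": [2], "residue_name": ["LEU"], "delta_obs": [3.90]}
        )
        shifts, summary = conformational_shifts(
            obs, rc_table={"LEU": 4.30})
        assert shifts[0].shift == pytest.approx(-0.40)
        assert summary["upfield"] == 1

    def test_equal_gives_zero(self):
        obs = pd.DataFrame(
            {"residue_number": [1], "residue_name": ["ALA"], "delta_obs": [4.32]}
        )
        shifts, summary = conformational_shifts(obs, rc_table={"ALA": 4.32})
        assert shifts[0].shift == 0.0 and summary["unshifted"] == 1

    def test_helical_offsets_all_upfield(self):
        rc = {"ALA": 4.32, "LEU": 4.34, "SER": 4.47}
        rows = [
            {"residue_number": i + 1, "residue_name": r,
             "delta_obs": rc[r] - 0.30}
            for i, r in enumerate(["ALA", "LEU", "SER", "LEU", "ALA"])
        ]
        shifts, summary = conformational_shifts(pd.DataFrame(rows), rc_table=rc)
        assert summary["upfield"] == len(rows) and summary["downfield"] == 0

    def test_missing_rc_entry_names_residue(self):
        obs = pd.DataFrame(
            {"residue_number": [1], "residue_name": ["XXX"], "delta_obs": [4.0]}
        )
        with pytest.raises(ValidationError, match="XXX"):
            conformational_shifts(obs, rc_table={"ALA": 4.32})


# ---------------------------------------------------------------------------
# descriptor table
# ---------------------------------------------------------------------------

class TestDescriptorTable:
    def test_clean_recovery_and_shape(self, clean_sandwich):
        ens, truth = clean_sandwich
        df = descriptor_table(ens, compute_sasa=False)
        assert len(df) == ens.n_models
        assert df["interhelical_angle"].iloc[0] == pytest.approx(
            truth.interhelical_angle, abs=0.5)
        assert df["theta_his"].iloc[0] == pytest.approx(truth.theta_his, abs=0.5)
        assert df["co_to_com_distance"].iloc[0] == pytest.approx(
            truth.co_to_com_distance, abs=0.05)
        agg = df.attrs["aggregates"]
        assert agg[1]["n_models"] == ens.n_models

    def test_aggregates_recomputable_from_rows(self, jittered_sandwich):
        ens, _ = jittered_sandwich
        df = descriptor_table(ens, compute_sasa=False)
        agg = df.attrs["aggregates"]
        for lab, stats in agg.items():
            sub = df[df["family_label"] == lab]
            for col, val in stats.items():
                if col == "n_models":
                    assert val == len(sub)
                    continue
                assert val[0] == pytest.approx(sub[col].mean(), abs=1e-9)
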