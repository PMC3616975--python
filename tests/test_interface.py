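"""SASA, buried surface area, contacts, stacking, and the energy proxy."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from tetherdock.fixtures import PlantedFeature, make_helix_domain, make_two_domain_complex
from tetherdock.interface import (
    COULOMB_CONSTANT,
    DEFAULT_NONBONDED,
    NonbondedParams,
    buried_surface_area,
    hydrophobic_contacts,
    interaction_energy,
    ionic_contacts,
    salt_bridges,
    sasa,
    stacking_pairs,
    total_nonbonded_energy,
)
from tetherdock.structure import Atom, DomainDefinition, Structure


def atom(serial, name, element, pos, res=1, chain="A", resname="ALA"):
    return Atom(serial, name, element, (chain, res, ""), resname, np.asarray(pos, float))


DOM_A = DomainDefinition("A", "A", 1, 100)
DOM_B = DomainDefinition("B", "B", 101, 200)


@pytest.fixture(scope="module")
def ionic_complex():
    a = make_helix_domain("ALKEFYRDIL", chain="A")
    b = make_helix_domain("ALKEFYRDIL", chain="B", start_residue=101)
    feat = PlantedFeature("ionic_pair", ("A", 3, ""), ("B", 104, ""), 5.9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, ledger = make_two_domain_complex(a, b, planted_features=[feat])
    return cx, ledger


def test_single_sphere_sasa_analytic():
    s = Structure([atom(1, "C", "C", [0, 0, 0])])
    area = sasa(s, probe_radius=1.4, n_sphere_points=960).sum()
    assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)


def test_distant_atoms_additive():
    s = Structure([atom(1, "C", "C", [0, 0, 0]), atom(2, "O", "O", [100, 0, 0], res=2)])
    a1 = sasa(Structure([s.atoms[0]])).sum()
    a2 = sasa(Structure([s.atoms[1]])).sum()
    assert sasa(s).sum() == pytest.approx(a1 + a2, rel=1e-9)


def dense_two_sphere_oracle(r1, r2, d, probe, n=40000):
    """High-density quadrature SASA of two overlapping equal spheres."""
    rng = np.random.default_rng(0)
    total = 0.0
    centers = [np.zeros(3), np.array([d, 0.0, 0.0])]
    radii = [r1 + probe, r2 + probe]
    for i in (0, 1):
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = centers[i] + radii[i] * pts
        other = 1 - i
        ok = np.sum((pts - centers[other]) ** 2, axis=1) > radii[other] ** 2
        total += 4 * np.pi * radii[i] ** 2 * ok.mean()
    return total


def test_overlapping_spheres_match_dense_oracle():
    d = 2.0
    s = Structure([atom(1, "C", "C", [0, 0, 0]), atom(2, "C", "C", [d, 0, 0], res=2)])
    ours = sasa(s, n_sphere_points=960).sum()
    oracle = dense_two_sphere_oracle(1.70, 1.70, d, 1.4)
    assert ours == pytest.approx(oracle, rel=0.02)


def test_unknown_element_warns_and_uses_default():
    s = Structure([atom(1, "X1", "Xx", [0, 0, 0])])
    with pytest.warns(UserWarning, match="unknown"):
        area = sasa(s).sum()
    assert area == pytest.approx(4 * np.pi * (1.70 + 1.4) ** 2, rel=0.01)


def test_bsa_zero_for_separated_domains():
    a = make_helix_domain("ALKEF", chain="A")
    b = make_helix_domain("ALKEF", chain="B", start_residue=101)
    far = b.with_coords(b.coords + np.array([100.0, 0, 0]))
    cx = Structure(list(a.atoms) + list(far.atoms))
    assert buried_surface_area(cx, DOM_A, DOM_B, n_sphere_points=240) == pytest.approx(
        0.0, abs=1.0
    )


def test_bsa_deterministic_and_definitional(ionic_complex):
    cx, _ = ionic_complex
    b1 = buried_surface_area(cx, DOM_A, DOM_B, n_sphere_points=240)
    b2 = buried_surface_area(cx, DOM_A, DOM_B, n_sphere_points=240)
    assert b1 == b2
    # independent recomputation from three sasa calls
    a_atoms = [x for x in cx.atoms if DOM_A.contains(x.residue_key)]
    b_atoms = [x for x in cx.atoms if DOM_B.contains(x.residue_key)]
    sa = sasa(Structure(a_atoms), n_sphere_points=240).sum()
    sb = sasa(Structure(b_atoms), n_sphere_points=240).sum()
    sab = sasa(Structure(a_atoms + b_atoms), n_sphere_points=240).sum()
    assert b1 == pytest.approx(sa + sb - sab, abs=1e-9)


def test_bsa_invariant_under_rigid_motion(ionic_complex):
    cx, _ = ionic_complex
    R = Rotation.from_euler("xyz", [0.3, -0.8, 1.1]).as_matrix()
    moved = cx.with_coords(cx.coords @ R.T + np.array([7.0, -3.0, 11.0]))
    b1 = buried_surface_area(cx, DOM_A, DOM_B, n_sphere_points=240)
    b2 = buried_surface_area(moved, DOM_A, DOM_B, n_sphere_points=240)
    assert b2 == pytest.approx(b1, abs=1.0)


def test_overlapping_domain_definitions_raise(ionic_complex):
    cx, _ = ionic_complex
    with pytest.raises(ValueError, match="overlap"):
        buried_surface_area(cx, DomainDefinition("A", "A", 1, 10),
                            DomainDefinition("B", "A", 5, 10))


def _two_leu_complex(scale):
    """Two LEU side chains whose closest heavy atoms sit at `scale` Å."""
    a = make_helix_domain("ALLLA", chain="A")
    b = make_helix_domain("ALLLA", chain="B", start_residue=101)
    feat = PlantedFeature("hydrophobic_pair", ("A", 3, ""), ("B", 103, ""), scale)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(a, b, planted_features=[feat])
    return cx


def test_hydrophobic_boundary_case():
    cx_in = _two_leu_complex(4.9)
    pairs_in = hydrophobic_contacts(cx_in, DOM_A, DOM_B)
    assert (("A", 3, ""), ("B", 103, "")) in pairs_in
    cx_out = _two_leu_complex(5.1)
    assert (("A", 3, ""), ("B", 103, "")) not in hydrophobic_contacts(
        cx_out, DOM_A, DOM_B
    )


def test_hydrophobic_class_filter_excludes_serine():
    # SER apposed to LEU at close range: not a hydrophobic pair
    a = make_helix_domain("ALLLA", chain="A")
    b = make_helix_domain("ASSSA", chain="B", start_residue=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(a, b, gap=3.0)
    pairs = hydrophobic_contacts(cx, DOM_A, DOM_B)
    assert all(kb[1] not in (102, 103, 104) for _, kb in pairs)


def test_contacts_match_brute_force(ionic_complex):
    """Contact lists equal an O(n^2) all-pairs recount on the fixture."""
    cx, _ = ionic_complex
    from tetherdock.structure import DEFAULT_CLASS_TABLE as T

    a_atoms = [x for x in cx.atoms if DOM_A.contains(x.residue_key)]
    b_atoms = [x for x in cx.atoms if DOM_B.contains(x.residue_key)]

    def brute_hydrophobic():
        found = set()
        for x in a_atoms:
            if x.residue_name not in T.hydrophobic or x.name in {"N", "CA", "C", "O"}:
                continue
            for y in b_atoms:
                if y.residue_name not in T.hydrophobic or y.name in {"N", "CA", "C", "O"}:
                    continue
                if np.linalg.norm(x.position - y.position) <= 5.0:
                    found.add((x.residue_key, y.residue_key))
        return found

    def brute_ionic():
        found = set()
        for x in a_atoms:
            sx = T.charge_sign(x.residue_name)
            if sx == 0 or x.name not in T.charged_group_atoms.get(x.residue_name, ()):
                continue
            for y in b_atoms:
                sy = T.charge_sign(y.residue_name)
                if sy == 0 or sx * sy >= 0:
                    continue
                if y.name not in T.charged_group_atoms.get(y.residue_name, ()):
                    continue
                if np.linalg.norm(x.position - y.position) <= 6.0:
                    found.add((x.residue_key, y.residue_key))
        return found

    assert set(hydrophobic_contacts(cx, DOM_A, DOM_B)) == brute_hydrophobic()
    assert {(ka, kb) for ka, kb, _, _ in ionic_contacts(cx, DOM_A, DOM_B)} == brute_ionic()


def test_planted_ionic_pair_found_and_ablated(ionic_complex):
    cx, ledger = ionic_complex
    assert ledger[0]["achieved_distance"] == pytest.approx(5.9, abs=0.05)
    pairs = ionic_contacts(cx, DOM_A, DOM_B)
    assert (("A", 3, ""), ("B", 104, ""), 1, -1) in pairs
    # removing the acidic partner abolishes the contact
    pruned = Structure([x for x in cx.atoms if x.residue_key != ("B", 104, "")])
    assert not any(
        kb == ("B", 104, "") for _, kb, _, _ in ionic_contacts(pruned, DOM_A, DOM_B)
    )


def test_same_sign_pair_not_ionic():
    # LYS apposed to ARG: both positive, never an ionic contact
    a = make_helix_domain("AKKKA", chain="A")
    b = make_helix_domain("ARRRA", chain="B", start_residue=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(a, b, gap=3.0)
    assert ionic_contacts(cx, DOM_A, DOM_B) == []


def test_salt_bridge_distances_satisfy_cutoff(ionic_complex):
    cx, _ = ionic_complex
    for _, _, d in salt_bridges(cx, DOM_A, DOM_B):
        assert d <= 6.0


def test_stacking_pair_at_5_8():
    a = make_helix_domain("ALKEFYRDIL", chain="A")
    b = make_helix_domain("ALKEFYRDIL", chain="B", start_residue=101)
    feat = PlantedFeature("stacking_pair", ("A", 6, ""), ("B", 106, ""), 5.8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(a, b, planted_features=[feat])
    pairs = stacking_pairs(cx, DOM_A, DOM_B)
    match = [(ka, kb, d) for ka, kb, d in pairs if ka == ("A", 6, "") and kb == ("B", 106, "")]
    assert len(match) == 1
    assert match[0][2] == pytest.approx(5.8, abs=0.05)


def test_stacking_out_of_range():
    a = make_helix_domain("ALKEFYRDIL", chain="A")
    b = make_helix_domain("ALKEFYRDIL", chain="B", start_residue=101)
    feat = PlantedFeature("stacking_pair", ("A", 6, ""), ("B", 106, ""), 7.5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(a, b, planted_features=[feat])
    assert not any(
        ka == ("A", 6, "") and kb == ("B", 106, "")
        for ka, kb, _ in stacking_pairs(cx, DOM_A, DOM_B)
    )


def test_ring_centroid_is_mean_of_ring_atoms():
    from tetherdock.structure import DEFAULT_CLASS_TABLE as T

    s = make_helix_domain("AFA")
    key = ("A", 2, "")
    ring_names = set(T.ring_atoms["PHE"])
    pts = np.asarray(
        [a.position for a in s.atoms if a.residue_key == key and a.name in ring_names]
    )
    # brute-force: centroid equals arithmetic mean; check through stacking distance
    b = make_helix_domain("AFA", chain="B", start_residue=101)
    feat = PlantedFeature("stacking_pair", key, ("B", 102, ""), 5.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cx, _ = make_two_domain_complex(s, b, planted_features=[feat])
    pair = stacking_pairs(cx, DOM_A, DOM_B)[0]
    cen_a = pts.mean(axis=0)
    cen_b = np.asarray(
        [
            a.position
            for a in cx.atoms
            if a.residue_key == ("B", 102, "") and a.name in ring_names
        ]
    ).mean(axis=0)
    assert pair[2] == pytest.approx(np.linalg.norm(cen_a - cen_b), abs=1e-9)


def test_coulomb_pair_closed_form():
    """Two unit opposite charges at 10 Å, eps_r 1, no LJ -> -33.20636 kcal/mol."""
    params = NonbondedParams(
        lj_sigma={}, lj_epsilon={"N": 0.0, "O": 0.0}, relative_dielectric=1.0
    )
    atoms = [
        atom(1, "NZ", "N", [0, 0, 0], res=1, chain="A", resname="LYS"),
        atom(2, "OE1", "O", [10, 0, 0], res=101, chain="B", resname="GLU"),
        atom(3, "OE2", "O", [10, 0, 100], res=101, chain="B", resname="GLU"),
    ]
    cx = Structure(atoms)
    rep = interaction_energy(cx, DOM_A, DOM_B, params)
    # GLU charge is split over OE1/OE2 (0.5 each): k*1*(-0.5)/10 + k*1*(-0.5)/sqrt(10100)
    expected = COULOMB_CONSTANT * (
        (1.0 * -0.5) / 10.0 + (1.0 * -0.5) / np.sqrt(10.0**2 + 100.0**2)
    )
    assert rep.e_ele == pytest.approx(expected, abs=1e-9)
    assert rep.e_vdw == 0.0
    assert rep.e_bind == pytest.approx(rep.e_ele + rep.e_vdw, abs=1e-12)


def test_energy_vanishes_at_infinite_separation():
    a = make_helix_domain("AKDEA", chain="A")
    b = make_helix_domain("AKDEA", chain="B", start_residue=101)
    far = b.with_coords(b.coords + np.array([1e9, 0, 0]))
    cx = Structure(list(a.atoms) + list(far.atoms))
    rep = interaction_energy(cx, DOM_A, DOM_B)
    assert rep.e_ele == pytest.approx(0.0, abs=1e-6)
    assert rep.e_vdw == pytest.approx(0.0, abs=1e-12)


def test_ebind_subtraction_equals_cross_domain_sum(ionic_complex):
    """E_complex - E_A - E_B from the brute-force total-energy routine equals
    the cross-domain pair sum to 1e-9 (pairwise additivity)."""
    cx, _ = ionic_complex
    a_atoms = [x for x in cx.atoms if DOM_A.contains(x.residue_key)]
    b_atoms = [x for x in cx.atoms if DOM_B.contains(x.residue_key)]
    e_complex = total_nonbonded_energy(cx)
    e_a = total_nonbonded_energy(Structure(a_atoms))
    e_b = total_nonbonded_energy(Structure(b_atoms))
    rep = interaction_energy(cx, DOM_A, DOM_B)
    assert e_complex - e_a - e_b == pytest.approx(rep.e_bind, abs=1e-9)


def test_e_ele_antisymmetric_under_one_domain_charge_flip():
    """Negating every charge on one domain negates E_ele exactly."""
    from tetherdock.structure import ResidueClassTable

    def table(b_sign_positive):
        return ResidueClassTable(
            hydrophobic=set(),
            positive={"LYS"} | ({"XXX"} if b_sign_positive else set()),
            negative=set() if b_sign_positive else {"XXX"},
            aromatic=set(),
            charged_group_atoms={"LYS": ("NZ",), "XXX": ("NZ",)},
            ring_atoms={},
        )

    atoms = [
        atom(1, "NZ", "N", [0, 0, 0], res=1, chain="A", resname="LYS"),
        atom(2, "NZ", "N", [8.0, 1.0, -2.0], res=101, chain="B", resname="XXX"),
        atom(3, "NZ", "N", [12.0, -4.0, 3.0], res=102, chain="B", resname="XXX"),
    ]
    cx = Structure(atoms)
    e_pos = interaction_energy(
        cx, DOM_A, DOM_B, NonbondedParams(class_table=table(True), lj_sigma={}, lj_epsilon={})
    ).e_ele
    e_neg = interaction_energy(
        cx, DOM_A, DOM_B, NonbondedParams(class_table=table(False), lj_sigma={}, lj_epsilon={})
    ).e_ele
    assert e_neg == pytest.approx(-e_pos, abs=1e-12)
    assert e_pos > 0


def test_lj_closed_form_points():
    """LJ is 0 at r = sigma and -eps at the 2^(1/6) sigma minimum."""
    sigma, eps = 3.50, 0.066
    params = NonbondedParams(relative_dielectric=1.0)

    def lj_at(r):
        atoms = [
            atom(1, "CB", "C", [0, 0, 0], res=1, chain="A"),
            atom(2, "CB", "C", [r, 0, 0], res=101, chain="B"),
        ]
        return interaction_energy(Structure(atoms), DOM_A, DOM_B, params).e_vdw

    assert lj_at(sigma) == pytest.approx(0.0, abs=1e-12)
    assert lj_at(2 ** (1 / 6) * sigma) == pytest.approx(-eps, abs=1e-12)


def test_clash_raises():
    atoms = [
        atom(1, "CB", "C", [0, 0, 0], res=1, chain="A"),
        atom(2, "CB", "C", [0.3, 0, 0], res=101, chain="B"),
    ]
    with pytest.raises(ValueError, match="clash"):
        interaction_energy(Structure(atoms), DOM_A, DOM_B)
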