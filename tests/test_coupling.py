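"""Mutual-information engine: analytic oracles, calibration, site grouping."""

import numpy as np
import pytest

from tetherdock.coupling import (
    TorsionSeries,
    cluster_sites,
    coupling_null,
    export_network,
    extract_torsions,
    pair_mutual_information,
    residue_coupling_matrix,
)
from tetherdock.fixtures import make_helix_domain, make_jitter_ensemble, make_rotamer_ensemble
from tetherdock.structure import Ensemble

JOINT = np.array([[0.4, 0.1], [0.1, 0.4]])


def analytic_mi(joint: np.ndarray) -> float:
    """Closed-form MI of a discrete joint table, nats (independent oracle)."""
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    total = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            if joint[i, j] > 0:
                total += joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
    return total


def two_state_series(joint, n, seed, noise=5.0):
    rng = np.random.default_rng(seed)
    flat = rng.choice(4, size=n, p=np.asarray(joint).ravel())
    wells = np.array([-60.0, 180.0])
    a = TorsionSeries(("A", 1, ""), "chi1", wells[flat // 2] + rng.normal(0, noise, n))
    b = TorsionSeries(("A", 2, ""), "chi1", wells[flat % 2] + rng.normal(0, noise, n))
    return a, b


def test_self_mi_of_two_equal_bins_is_ln2():
    vals = np.array([-60.0, 180.0] * 500)
    s = TorsionSeries(("A", 1, ""), "chi1", vals)
    assert pair_mutual_information(s, s) == pytest.approx(np.log(2), abs=1e-12)


def test_self_mi_of_k_equal_bins_is_ln_k():
    # 4 equally occupied 15-degree bins
    vals = np.tile(np.array([-170.0, -100.0, 10.0, 120.0]), 250)
    s = TorsionSeries(("A", 1, ""), "chi1", vals)
    assert pair_mutual_information(s, s) == pytest.approx(np.log(4), abs=1e-12)


def test_mi_invariant_under_bin_relabeling():
    a, b = two_state_series(JOINT, 5000, 0)
    mi1 = pair_mutual_information(a, b)
    # rotate both series into different wells (relabels occupied bins)
    a2 = TorsionSeries(a.residue_key, "chi1", ((a.values + 90.0 + 180) % 360) - 180)
    b2 = TorsionSeries(b.residue_key, "chi1", ((b.values + 90.0 + 180) % 360) - 180)
    assert pair_mutual_information(a2, b2) == pytest.approx(mi1, abs=0.02)


def test_length_mismatch_raises():
    a = TorsionSeries(("A", 1, ""), "chi1", np.zeros(10))
    b = TorsionSeries(("A", 2, ""), "chi1", np.zeros(11))
    with pytest.raises(ValueError, match="length"):
        pair_mutual_information(a, b)


def test_two_state_joint_recovered_within_3_se():
    """Plugin MI at n=50,000 matches the closed-form value of the 2x2 table."""
    n = 50000
    a, b = two_state_series(JOINT, n, 123)
    mi = pair_mutual_information(a, b)
    expected = analytic_mi(JOINT)
    # delta-method SE of plugin MI for a 2x2 table
    terms = []
    for i in range(2):
        for j in range(2):
            terms.append(np.log(JOINT[i, j] / (JOINT[i].sum() * JOINT[:, j].sum())))
    var = float(np.sum(JOINT.ravel() * np.square(terms)) - expected**2)
    se = np.sqrt(var / n)
    assert abs(mi - expected) <= 3 * se


def test_independent_series_corrected_to_zero():
    rng = np.random.default_rng(7)
    a = TorsionSeries(("A", 1, ""), "chi1", rng.uniform(-180, 180, 10000))
    b = TorsionSeries(("A", 2, ""), "chi1", rng.uniform(-180, 180, 10000))
    raw = pair_mutual_information(a, b)
    assert raw > 0  # small positive sampling bias
    null = coupling_null(a, b, n_permutations=100, seed=1)
    assert raw <= null.p95 + 0.005  # consistent with the null
    assert null.mean == pytest.approx(raw, rel=0.5)


def test_coupled_pair_beats_null():
    a, b = two_state_series(JOINT, 2000, 5)
    null = coupling_null(a, b, n_permutations=100, seed=2)
    assert pair_mutual_information(a, b) > null.p95


def test_null_is_deterministic_under_seed():
    a, b = two_state_series(JOINT, 1000, 9)
    n1 = coupling_null(a, b, n_permutations=60, seed=42)
    n2 = coupling_null(a, b, n_permutations=60, seed=42)
    assert (n1.mean, n1.p95) == (n2.mean, n2.p95)


def test_independence_calibration_false_positive_rate():
    """Over 500 independent pairs, at most ~5% (+/-2) are called significant."""
    rng = np.random.default_rng(2024)
    n, n_pairs = 1000, 500
    fp = 0
    for k in range(n_pairs):
        a = TorsionSeries(("A", 1, ""), "chi1", rng.uniform(-180, 180, n))
        b = TorsionSeries(("A", 2, ""), "chi1", rng.uniform(-180, 180, n))
        null = coupling_null(a, b, n_permutations=60, seed=k)
        if pair_mutual_information(a, b) > null.p95:
            fp += 1
    assert fp / n_pairs <= 0.07


def test_planted_pair_is_matrix_argmax():
    ens, ledger = make_rotamer_ensemble(8, [(1, 5, JOINT)], 1200, seed=11)
    series = extract_torsions(ens)
    m = residue_coupling_matrix(
        series, n_permutations=60, seed=3, torsion_labels={"chi1"}
    )
    i, j = np.unravel_index(np.argmax(m.values), m.values.shape)
    found = {m.residue_order[i][1], m.residue_order[j][1]}
    assert found == {2, 6}  # residues are 1-based


def test_all_independent_matrix_mostly_zero():
    ens, _ = make_rotamer_ensemble(8, [], 800, seed=21)
    series = extract_torsions(ens)
    m = residue_coupling_matrix(
        series, n_permutations=60, seed=4, torsion_labels={"chi1"}
    )
    n = len(m.residue_order)
    off = m.values[np.triu_indices(n, 1)]
    assert np.mean(off == 0.0) >= 0.85


def test_matrix_symmetric_and_diagonal_zero():
    ens, _ = make_rotamer_ensemble(6, [(0, 3, JOINT)], 600, seed=31)
    series = extract_torsions(ens)
    m = residue_coupling_matrix(series, n_permutations=60, seed=5,
                                torsion_labels={"chi1"})
    np.testing.assert_array_equal(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)


def test_cluster_sites_two_planted_blocks():
    """Two 3-residue coupled blocks are recovered as exactly two groups."""
    order = [("A", i, "") for i in range(1, 9)]
    vals = np.zeros((8, 8))
    for block in [(0, 1, 2), (4, 5, 6)]:
        for i in block:
            for j in block:
                if i != j:
                    vals[i, j] = 0.5
    mask = vals > 0
    from tetherdock.coupling import CouplingMatrix

    m = CouplingMatrix(order, vals, mask, 100, 0)
    groups = cluster_sites(m, min_coupling=0.1)
    assert len(groups) == 2
    memberships = sorted(sorted(k[1] for k in g.residue_keys) for g in groups)
    assert memberships == [[1, 2, 3], [5, 6, 7]]


def test_cluster_sites_empty_matrix_and_single_pair():
    from tetherdock.coupling import CouplingMatrix

    order = [("A", i, "") for i in range(1, 5)]
    zero = CouplingMatrix(order, np.zeros((4, 4)), np.zeros((4, 4), bool), 100, 0)
    assert cluster_sites(zero) == []
    vals = np.zeros((4, 4))
    vals[0, 2] = vals[2, 0] = 0.4
    m = CouplingMatrix(order, vals, vals > 0, 100, 0)
    groups = cluster_sites(m, 0.1)
    assert len(groups) == 1
    assert {k[1] for k in groups[0].residue_keys} == {1, 3}


def test_export_network_edges(tmp_path):
    from tetherdock.coupling import CouplingMatrix

    order = [("A", i, "") for i in range(1, 5)]
    vals = np.zeros((4, 4))
    for i, j in [(0, 1), (0, 2), (2, 3)]:
        vals[i, j] = vals[j, i] = 0.3
    m = CouplingMatrix(order, vals, vals > 0, 100, 0)
    path = tmp_path / "net.tsv"
    n = export_network(m, path)
    lines = path.read_text().splitlines()
    assert n == 3 and len(lines) == 4
    weights = [float(l.split("\t")[2]) for l in lines[1:]]
    assert weights == [pytest.approx(0.3)] * 3

    empty = CouplingMatrix(order, np.zeros((4, 4)), np.zeros((4, 4), bool), 100, 0)
    n0 = export_network(empty, tmp_path / "empty.tsv")
    assert n0 == 0
    assert (tmp_path / "empty.tsv").read_text() == "source\ttarget\tweight\n"


def test_extract_torsions_helix_recovers_construction_angles():
    s = make_helix_domain("AAAAAAAAAA", phi=-57.0, psi=-47.0)
    ens = Ensemble([s])
    series = {
        (t.residue_key[1], t.torsion_label): t.values[0] for t in extract_torsions(ens)
    }
    for res in range(2, 10):
        assert series[(res, "phi")] == pytest.approx(-57.0, abs=0.5)
    for res in range(1, 9):
        assert series[(res, "psi")] == pytest.approx(-47.0, abs=0.5)


def test_terminal_residues_lack_phi_psi():
    s = make_helix_domain("AA")
    labels = {(t.residue_key[1], t.torsion_label) for t in extract_torsions(Ensemble([s]))}
    assert (1, "phi") not in labels
    assert (2, "psi") not in labels
    assert (1, "psi") in labels and (2, "phi") in labels


def test_constant_ensemble_gives_constant_series():
    s = make_helix_domain("ALKE")
    ens = make_jitter_ensemble(s, 0.0, 5, seed=0)
    for t in extract_torsions(ens):
        assert np.ptp(t.values) == pytest.approx(0.0, abs=1e-9)
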