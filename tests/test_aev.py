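"""Descriptor correctness: closed forms, brute-force oracle, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from deltapot.aev import AEVParams, aev_jacobian, compute_aev, cutoff_fn
from deltapot.chem import Molecule, MoleculeError

from conftest import random_cluster


def brute_force_aev(molecule, params):
    """Independent reference: explicit loops over pairs and triples."""
    n = molecule.n_atoms
    coords = molecule.coordinates
    el = [params.element_index(e) for e in molecule.elements]
    nrs = len(params.radial_shifts)
    feats = np.zeros((n, params.feature_length))

    def fc(r, rc):
        return 0.5 * np.cos(np.pi * r / rc) + 0.5 if r < rc else 0.0

    for i in range(n):
        for j in range(n):
            if j == i:
                continue
            r = np.linalg.norm(coords[i] - coords[j])
            for s, rs in enumerate(params.radial_shifts):
                feats[i, el[j] * nrs + s] += (
                    np.exp(-params.eta_radial * (r - rs) ** 2)
                    * fc(r, params.radial_cutoff))
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k):
                    continue
                r1 = np.linalg.norm(coords[j] - coords[i])
                r2 = np.linalg.norm(coords[k] - coords[i])
                cosT = np.dot(coords[j] - coords[i], coords[k] - coords[i]) / (r1 * r2)
                theta = np.arccos(np.clip(cosT, -1 + 1e-12, 1 - 1e-12))
                p = params.pair_index(el[j], el[k])
                block = len(params.angular_shifts) * params.n_theta
                for s, rs in enumerate(params.angular_shifts):
                    for t, ts in enumerate(params.theta_sections):
                        val = (2.0 ** (1 - params.zeta)
                               * (1 + np.cos(theta - ts)) ** params.zeta
                               * np.exp(-params.eta_angular * ((r1 + r2) / 2 - rs) ** 2)
                               * fc(r1, params.angular_cutoff)
                               * fc(r2, params.angular_cutoff))
                        col = (params.radial_length + p * block
                               + s * params.n_theta + t)
                        feats[i, col] += val
    return feats


def test_cutoff_closed_forms():
    assert cutoff_fn(0.0, 5.2) == 1.0
    assert cutoff_fn(5.2, 5.2) == 0.0
    assert cutoff_fn(7.0, 5.2) == 0.0
    rc = 3.0
    assert cutoff_fn(rc / 2, rc) == pytest.approx(0.5, abs=1e-14)
    with pytest.raises(ValueError):
        cutoff_fn(-0.1, 5.2)


@settings(deadline=None, derandomize=True)
@given(r=st.floats(0.0, 20.0), rc=st.floats(0.5, 10.0))
def test_cutoff_range_and_boundary_properties(r, rc):
    f = cutoff_fn(r, rc)
    assert 0.0 <= f <= 1.0
    if r >= rc:
        assert f == 0.0


def test_cutoff_monotone_and_c1_at_cutoff():
    rc = 4.0
    r = np.linspace(0, rc, 200)
    f = cutoff_fn(r, rc)
    assert np.all(np.diff(f) <= 1e-15)
    h = 1e-6
    deriv_at_rc = (cutoff_fn(rc, rc) - cutoff_fn(rc - h, rc)) / h
    assert abs(deriv_at_rc) < 1e-5


def test_isolated_atom_zero_features(small_aev):
    desc = compute_aev(Molecule(("C",), np.zeros((1, 3))), small_aev)
    assert np.all(desc.features == 0)
    assert np.all(aev_jacobian(Molecule(("C",), np.zeros((1, 3))), small_aev) == 0)


def test_feature_length_formula(small_aev):
    p = small_aev
    assert p.feature_length == 4 * 8 + 10 * 4 * 4
    desc = compute_aev(Molecule(("H", "O"), [[0, 0, 0], [1, 0, 0]]), p)
    assert desc.features.shape == (2, p.feature_length)


def test_matches_brute_force_oracle(small_aev, rng):
    for _ in range(5):
        mol = random_cluster(rng, n_atoms=int(rng.integers(3, 7)))
        fast = compute_aev(mol, small_aev).features
        slow = brute_force_aev(mol, small_aev)
        np.testing.assert_allclose(fast, slow, atol=1e-12)


def test_triangle_matches_brute_force(small_aev):
    mol = Molecule(("H", "O", "H"),
                   [[0, 0, 0], [1.0, 0, 0], [0.4, 1.1, 0]])
    np.testing.assert_allclose(
        compute_aev(mol, small_aev).features,
        brute_force_aev(mol, small_aev), atol=1e-12)


def test_rotation_translation_invariance(small_aev, rng):
    for k in range(10):
        mol = random_cluster(rng)
        ref = compute_aev(mol, small_aev).features
        rot = Rotation.random(random_state=k).as_matrix()
        moved = mol.with_coordinates(mol.coordinates @ rot.T + rng.normal(size=3))
        np.testing.assert_allclose(
            compute_aev(moved, small_aev).features, ref, atol=1e-10)


def test_permutation_covariance(small_aev, rng):
    mol = random_cluster(rng, n_atoms=6)
    perm = rng.permutation(6)
    permuted = Molecule(tuple(mol.elements[i] for i in perm), mol.coordinates[perm])
    np.testing.assert_allclose(
        compute_aev(permuted, small_aev).features,
        compute_aev(mol, small_aev).features[perm], atol=1e-10)


def test_locality_beyond_cutoff(small_aev):
    near = Molecule(("C", "H"), [[0, 0, 0], [1.0, 0, 0]])
    with_far = Molecule(("C", "H", "O"),
                        [[0, 0, 0], [1.0, 0, 0], [50.0, 0, 0]])
    farther = Molecule(("C", "H", "O"),
                       [[0, 0, 0], [1.0, 0, 0], [80.0, 0, 0]])
    a = compute_aev(with_far, small_aev).features
    b = compute_aev(farther, small_aev).features
    assert np.array_equal(a[:2], b[:2])  # bitwise: outside-cutoff atom is invisible
    np.testing.assert_array_equal(a[:2], compute_aev(near, small_aev).features)


def test_jacobian_matches_finite_differences(small_aev, rng):
    mol = random_cluster(rng, n_atoms=5)
    jac = aev_jacobian(mol, small_aev)
    h = 1e-4
    for a in range(5):
        for k in range(3):
            cp = mol.coordinates.copy(); cp[a, k] += h
            cm = mol.coordinates.copy(); cm[a, k] -= h
            fd = (compute_aev(mol.with_coordinates(cp), small_aev).features
                  - compute_aev(mol.with_coordinates(cm), small_aev).features) / (2 * h)
            scale = max(np.max(np.abs(fd)), 1e-10)
            assert np.max(np.abs(fd - jac[:, :, a, k])) / scale < 1e-6


def test_diatomic_jacobian_antisymmetric(small_aev):
    mol = Molecule(("H", "H"), [[0, 0, 0], [1.1, 0, 0]])
    jac = aev_jacobian(mol, small_aev)
    # radial feature of atom 0 w.r.t. its own x equals minus w.r.t. partner x
    np.testing.assert_allclose(jac[0, :, 0, 0], -jac[0, :, 1, 0], atol=1e-12)


def test_degenerate_geometry_rejected(small_aev):
    mol = Molecule(("H", "H"), [[0, 0, 0], [0.05, 0, 0]])
    with pytest.raises(MoleculeError, match="degenerate"):
        compute_aev(mol, small_aev)


def test_smoothness_across_cutoff(small_aev):
    # feature derivative w.r.t. bond length goes to zero approaching Rc
    rc = small_aev.radial_cutoff
    eps = 1e-5
    f_in = compute_aev(Molecule(("H", "H"), [[0, 0, 0], [rc - eps, 0, 0]]),
                       small_aev).features
    f_at = compute_aev(Molecule(("H", "H"), [[0, 0, 0], [rc, 0, 0]]),
                       small_aev).features
    assert np.max(np.abs(f_in - f_at)) / eps < 1e-3
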