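"""Generalized Procrustes analysis and the size regression."""
import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from morphocompare import LandmarkDataset, procrustes_fit, regress_out_size
from morphocompare.shape import ConvergenceError, DegenerateSpecimenError

from conftest import make_labels


def _random_config(rng, k=5):
    return rng.standard_normal((k, 2))


def _similarity(coords, rng, scale_range=(0.5, 3.0)):
    """Apply a random rotation, scaling and translation."""
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    R = np.array([[c, -s], [s, c]])
    scale = rng.uniform(*scale_range)
    t = rng.uniform(-10, 10, 2)
    return scale * coords @ R.T + t


def naive_gpa(coords, n_iter=200):
    """Brute-force GPA oracle: centre, unit-scale, then repeatedly rotate each
    configuration to the running consensus with scipy's orthogonal Procrustes
    solver (reflection suppressed by determinant correction), re-averaging the
    consensus.  Independent of the package's closed-form planar rotation."""
    X = coords.astype(float).copy()
    X -= X.mean(axis=1, keepdims=True)
    X /= np.sqrt((X ** 2).sum(axis=(1, 2)))[:, None, None]
    mean = X[0].copy()
    for _ in range(n_iter):
        for i in range(X.shape[0]):
            R, _ = orthogonal_procrustes(X[i], mean)
            if np.linalg.det(R) < 0:
                U, s, Vt = np.linalg.svd(X[i].T @ mean)
                D = np.diag([1, np.sign(np.linalg.det(U @ Vt))])
                R = U @ D @ Vt
            X[i] = X[i] @ R
        mean = X.mean(axis=0)
        mean -= mean.mean(axis=0)
        mean /= np.sqrt((mean ** 2).sum())
    return X, mean


def test_copies_of_one_shape_align_exactly(rng):
    """Arbitrarily rotated/scaled/translated copies of one configuration all
    map onto the same aligned shape."""
    base = _random_config(rng)
    coords = np.stack([_similarity(base, rng) for _ in range(6)])
    fit = procrustes_fit(LandmarkDataset(make_labels(6), coords))
    diffs = fit.aligned - fit.aligned[0]
    assert np.abs(diffs).max() < 1e-9


def test_centroid_size_scale_equivariance(rng):
    base = _random_config(rng)
    coords = np.stack([base, base * 2, _similarity(base, rng)])
    fit = procrustes_fit(LandmarkDataset(make_labels(3), coords))
    assert fit.centroid_size[1] == pytest.approx(2 * fit.centroid_size[0])
    np.testing.assert_allclose(fit.aligned[0], fit.aligned[1], atol=1e-9)


def test_gpa_matches_brute_force_oracle(rng):
    """Alignment of 10 random 5-landmark configurations agrees with the
    brute-force oracle to 1e-6 (up to the arbitrary common orientation)."""
    coords = np.stack([_random_config(rng) for _ in range(10)])
    fit = procrustes_fit(LandmarkDataset(make_labels(10), coords))
    X_ref, mean_ref = naive_gpa(coords)
    # remove the orientation ambiguity: rotate the oracle onto our consensus
    R, _ = orthogonal_procrustes(mean_ref, fit.mean_shape)
    if np.linalg.det(R) < 0:  # oracle is reflection-free; force proper
        R[:, 1] = -R[:, 1]
    np.testing.assert_allclose(X_ref @ R, fit.rotated, atol=1e-6)


def test_unit_centroid_size_and_centred_before_projection(rng):
    coords = np.stack([_random_config(rng, 7) for _ in range(8)])
    fit = procrustes_fit(LandmarkDataset(make_labels(8), coords))
    cs = np.sqrt((fit.rotated ** 2).sum(axis=(1, 2)))
    np.testing.assert_allclose(cs, 1.0, atol=1e-9)
    np.testing.assert_allclose(fit.rotated.mean(axis=1), 0.0, atol=1e-9)
    # mean of aligned shapes equals the consensus
    np.testing.assert_allclose(fit.aligned.mean(axis=0),
                               fit.mean_shape.reshape(-1), atol=1e-8)


def test_tangent_residuals_orthogonal_to_mean(rng):
    coords = np.stack([_random_config(rng, 6) for _ in range(12)])
    fit = procrustes_fit(LandmarkDataset(make_labels(12), coords))
    m = fit.mean_shape.reshape(-1)
    dots = (fit.aligned - m) @ m
    assert np.abs(dots).max() < 1e-9


def test_gpa_objective_nonincreasing(rng):
    coords = np.stack([_random_config(rng, 8) for _ in range(15)])
    fit = procrustes_fit(LandmarkDataset(make_labels(15), coords))
    hist = np.array(fit.objective_history)
    assert (np.diff(hist) <= 1e-12).all()


def test_degenerate_specimen_named(rng):
    coords = np.stack([_random_config(rng), np.zeros((5, 2))])
    with pytest.raises(DegenerateSpecimenError, match="i01"):
        procrustes_fit(LandmarkDataset(make_labels(2), coords))


def test_nonconvergence_reports_final_change(rng):
    coords = np.stack([_random_config(rng, 9) for _ in range(30)])
    with pytest.raises(ConvergenceError, match="did not converge"):
        procrustes_fit(LandmarkDataset(make_labels(30), coords), max_iter=1,
                       tol=1e-15)


def test_residuals_invariant_to_common_similarity_transform(rng):
    """Transforming every specimen by one common similarity leaves the
    residual shape variables unchanged."""
    coords = np.stack([_random_config(rng, 6) + 0.05 * _random_config(rng, 6)
                       for _ in range(20)])
    data = LandmarkDataset(make_labels(20), coords)
    theta = 1.1
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    moved = LandmarkDataset(make_labels(20), 1.7 * coords @ R.T + [3.0, -2.0])
    res_a = regress_out_size(procrustes_fit(data))
    res_b = regress_out_size(procrustes_fit(moved))
    np.testing.assert_allclose(res_a.values, res_b.values, atol=1e-8)


def test_size_regression_null_and_recovery(rng):
    """Null allometry gives ~zero slope; a planted logCS slope is recovered."""
    k, n = 6, 100
    base = _random_config(rng, k)
    base -= base.mean(axis=0)
    base /= np.sqrt((base ** 2).sum())
    # plant the allometric direction in shape space proper: orthogonal to the
    # scaling (base), translation and rotation-orbit directions that the
    # superimposition removes
    nuisance = [base.reshape(-1),
                np.tile([1.0, 0.0], k), np.tile([0.0, 1.0], k),
                (base @ np.array([[0.0, -1.0], [1.0, 0.0]]).T).reshape(-1)]
    direction = rng.standard_normal(2 * k)
    for v in nuisance:
        v = v / np.linalg.norm(v)
        direction -= (direction @ v) * v
    direction /= np.linalg.norm(direction)
    sizes = np.exp(rng.uniform(2.0, 4.0, n))
    c = 0.01
    coords = np.empty((n, k, 2))
    for i in range(n):
        shape = base + (c * np.log(sizes[i])
                        * direction.reshape(k, 2)) \
            + 0.002 * rng.standard_normal((k, 2))
        coords[i] = sizes[i] * shape
    fit = procrustes_fit(LandmarkDataset(make_labels(n), coords))
    res = regress_out_size(fit)
    slope = res.slopes[("sp1",)]
    # the fit reports shapes in its own (canonical) orientation: rotate the
    # planted direction into that frame before projecting
    R, _ = orthogonal_procrustes(base, fit.mean_shape)
    dir_fit = (direction.reshape(k, 2) @ R).reshape(-1)
    recovered = float(slope @ dir_fit)
    assert 0.5 * c < recovered < 2.0 * c
    # and the slope vector points along the planted direction
    cos = recovered / np.linalg.norm(slope)
    assert cos > 0.9
    # residual-logCS covariance vanishes coordinate-wise
    z = fit.logCS - fit.logCS.mean()
    cov = z @ res.values / n
    assert np.abs(cov).max() < 1e-10
    # null data: no spurious allometry of comparable size
    coords0 = np.stack([sizes[i] * (base + 0.002 * rng.standard_normal((k, 2)))
                        for i in range(n)])
    res0 = regress_out_size(procrustes_fit(
        LandmarkDataset(make_labels(n), coords0)))
    assert np.abs(res0.slopes[("sp1",)]).max() < 0.2 * c


def test_constant_logcs_warns_and_zeroes_slope(rng):
    base = _random_config(rng, 5)
    coords = np.stack([base + 0.01 * rng.standard_normal((5, 2))
                       for _ in range(10)])
    coords -= coords.mean(axis=1, keepdims=True)
    coords /= np.sqrt((coords ** 2).sum(axis=(1, 2)))[:, None, None]
    fit = procrustes_fit(LandmarkDataset(make_labels(10), coords))
    with pytest.warns(UserWarning, match="constant"):
        res = regress_out_size(fit)
    assert np.abs(res.slopes[("sp1",)]).max() == 0.0
    with pytest.raises(np.linalg.LinAlgError):
        regress_out_size(fit, strict=True)
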