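"""Clustering engine: membership updates, blending, iteration, labels."""

import numpy as np
import pytest

from mmtdfcm import (
    FcmConfig,
    defuzzify,
    fcm_objective,
    fuzzy_membership,
    init_centers,
    mean_neighbor_membership,
    medium_membership,
    run_fcm,
    run_mmtdfcm,
    segment,
    update_centers,
    misclassification_rate,
)
from conftest import membership_oracle, mmtd_iteration_oracle, random_stochastic


# ------------------------------------------------------------ memberships

def test_fuzzy_membership_examples():
    u = fuzzy_membership([50.0], [0.0, 100.0], 2.0)
    np.testing.assert_allclose(u[:, 0], [0.5, 0.5])
    u = fuzzy_membership([25.0], [0.0, 100.0], 2.0)
    np.testing.assert_allclose(u[:, 0], [0.9, 0.1])


@pytest.mark.parametrize("m", [1.5, 2.0, 3.0])
def test_zero_distance_gives_crisp_column(m):
    u = fuzzy_membership([100.0], [100.0, 37.0], m)
    np.testing.assert_array_equal(u[:, 0], [1.0, 0.0])
    # coincident centers: crisp membership goes to the lowest index
    u = fuzzy_membership([100.0], [100.0, 100.0], m)
    np.testing.assert_array_equal(u[:, 0], [1.0, 0.0])


def test_fuzzy_membership_matches_loop_oracle(rng):
    pixels = rng.integers(0, 256, size=30).astype(float)
    centers = [12.0, 130.5, 251.0]
    for m in (1.8, 2.0, 2.5):
        got = fuzzy_membership(pixels, centers, m)
        np.testing.assert_allclose(got, membership_oracle(pixels, centers, m),
                                   atol=1e-12)
        np.testing.assert_allclose(got.sum(axis=0), 1.0, atol=1e-9)


def test_fuzzy_membership_rejects_bad_inputs():
    with pytest.raises(ValueError):
        fuzzy_membership([1.0], [np.nan, 2.0], 2.0)
    with pytest.raises(ValueError):
        fuzzy_membership([1.0], [0.0, 2.0], 1.0)


# ------------------------------------------------ neighbourhood averaging

def test_mean_neighbor_membership_constant_field():
    u = np.tile([[0.3], [0.7]], (1, 12))
    got = mean_neighbor_membership(u, (3, 4))
    np.testing.assert_allclose(got, u, atol=1e-12)


def test_mean_neighbor_membership_crisp_surrounded():
    u = np.zeros((2, 9))
    u[1, :] = 1.0
    u[:, 4] = [1.0, 0.0]  # center pixel of the 3x3 grid disagrees
    got = mean_neighbor_membership(u, (3, 3))
    np.testing.assert_allclose(got[:, 4], [0.0, 1.0], atol=1e-12)


@pytest.mark.parametrize("border_mode", ["replicate", "valid"])
@pytest.mark.parametrize("include_center", [False, True])
def test_mean_neighbor_matches_bruteforce(border_mode, include_center, rng):
    M, N, c = 4, 4, 3
    u = random_stochastic(rng, c, M * N)
    got = mean_neighbor_membership(u, (M, N), border_mode, include_center)
    expected = np.zeros_like(u)
    for i in range(M):
        for j in range(N):
            cols = []
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == 0 and dj == 0 and not include_center:
                        continue
                    ii, jj = i + di, j + dj
                    if border_mode == "replicate":
                        ii, jj = min(max(ii, 0), M - 1), min(max(jj, 0), N - 1)
                    elif not (0 <= ii < M and 0 <= jj < N):
                        continue
                    cols.append(u[:, ii * N + jj])
            expected[:, i * N + j] = np.mean(cols, axis=0)
    np.testing.assert_allclose(got, expected, atol=1e-12)
    np.testing.assert_allclose(got.sum(axis=0), 1.0, atol=1e-9)


# -------------------------------------------------------------- blending

def test_blend_is_identity_at_hbar_one(rng):
    u = random_stochastic(rng, 3, 10)
    ub = random_stochastic(rng, 3, 10)
    got = medium_membership(u, ub, np.ones(10), neighborhood_size=8.0)
    np.testing.assert_allclose(got, ub, atol=1e-12)


def test_blend_is_identity_when_fields_agree(rng):
    u = random_stochastic(rng, 4, 7)
    h = rng.uniform(0.1, 1.0, size=7)
    got = medium_membership(u, u, h, neighborhood_size=8.0)
    np.testing.assert_allclose(got, u, atol=1e-12)


def test_plain_convex_blend_example():
    """With unit neighbourhood weight the blend is h*ubar + (1-h)*u."""
    u = np.array([[0.9], [0.1]])
    ub = np.array([[0.5], [0.5]])
    got = medium_membership(u, ub, [0.8], neighborhood_size=1.0)
    np.testing.assert_allclose(got[:, 0], [0.58, 0.42], atol=1e-12)


def test_blend_stays_between_inputs_and_stochastic(rng):
    u = random_stochastic(rng, 3, 40)
    ub = random_stochastic(rng, 3, 40)
    h = rng.uniform(0.01, 1.0, size=40)
    for size in (1.0, 8.0):
        got = medium_membership(u, ub, h, neighborhood_size=size)
        np.testing.assert_allclose(got.sum(axis=0), 1.0, atol=1e-9)
        assert np.all(got >= np.minimum(u, ub) - 1e-12)
        assert np.all(got <= np.maximum(u, ub) + 1e-12)


def test_blend_rejects_bad_similarity(rng):
    u = random_stochastic(rng, 2, 3)
    with pytest.raises(ValueError):
        medium_membership(u, u, [0.5, 0.0, 0.5])
    with pytest.raises(ValueError):
        medium_membership(u, u, [0.5, 1.5, 0.5])


# ---------------------------------------------------------------- centers

def test_update_centers_examples():
    crisp = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    np.testing.assert_allclose(
        update_centers(crisp, [10.0, 20.0, 90.0], 2.0), [15.0, 90.0]
    )
    uniform = np.full((3, 4), 1 / 3)
    np.testing.assert_allclose(
        update_centers(uniform, [0.0, 10.0, 20.0, 30.0], 2.0), [15.0, 15.0, 15.0]
    )
    u = np.array([[0.9, 0.1], [0.1, 0.9]])
    got = update_centers(u, [0.0, 100.0], 2.0)
    assert got[0] == pytest.approx(0.01 * 100 / 0.82)


def test_update_centers_degenerate_row():
    u = np.array([[1.0, 1.0], [0.0, 0.0]])
    with pytest.raises(Exception):
        update_centers(u, [5.0, 7.0], 2.0)
    got = update_centers(u, [5.0, 7.0], 2.0, prev_centers=[0.0, 42.0])
    np.testing.assert_allclose(got, [6.0, 42.0])


# ------------------------------------------------------------- defuzzify

def test_defuzzify_argmax_and_ties():
    u = np.array([[0.2, 0.5, 1.0], [0.7, 0.5, 0.0], [0.1, 0.0, 0.0]])
    np.testing.assert_array_equal(defuzzify(u, (1, 3)), [[1, 0, 0]])


# ---------------------------------------------------------------- inits

def test_quantile_init_hits_separated_masses(phantom128):
    image, _ = phantom128
    centers = init_centers(image, FcmConfig(c=3))
    np.testing.assert_allclose(centers, [0.0, 160.0, 255.0])


def test_quantile_init_constant_image():
    centers = init_centers(np.full((4, 4), 7), FcmConfig(c=2))
    np.testing.assert_allclose(centers, [7.0, 7.0])


def test_random_init_is_seeded(phantom128):
    image, _ = phantom128
    cfg = FcmConfig(c=3, init_method="random", seed=11)
    a = init_centers(image, cfg)
    b = init_centers(image, cfg)
    np.testing.assert_array_equal(a, b)
    assert np.unique(a).size == 3


def test_init_rejects_too_many_clusters():
    with pytest.raises(ValueError):
        init_centers(np.array([[1, 2]]), FcmConfig(c=3))


# ------------------------------------------------------------- full runs

def test_clean_phantom_exact_recovery(phantom128, config3):
    image, truth = phantom128
    for runner in (run_fcm, run_mmtdfcm):
        res = runner(image, config3)
        assert res.converged
        assert misclassification_rate(res.labels, truth, 3) == 0.0
        assert np.max(np.abs(np.sort(res.centers) - [0, 160, 255])) < 1.0


def test_constant_image_degenerates_gracefully():
    res = run_mmtdfcm(np.full((6, 6), 90), FcmConfig(c=2))
    assert res.converged and res.n_iter <= 2
    assert np.unique(res.labels).size == 1


def test_fcm_fixed_point_from_crisp_init():
    image = np.array([[0, 0, 160, 160, 255, 255]] * 4)
    res = run_fcm(image, FcmConfig(c=3, max_iter=1), initial_centers=[0, 160, 255])
    np.testing.assert_allclose(res.centers, [0, 160, 255])


def test_fcm_objective_descends(rng):
    for _ in range(5):
        img = rng.integers(0, 256, size=(16, 16))
        res = run_fcm(img, FcmConfig(c=3, max_iter=40))
        obj = np.array(res.objective_history)
        assert np.all(np.diff(obj) <= 1e-8)


def test_impulse_pixel_reassigned_by_spatial_variant():
    """An isolated impulse joins its region under MMTDFCM, not FCM."""
    image = np.full((11, 11), 160, dtype=int)
    image[5, 5] = 255
    image[:, :3] = 0
    image[:, 8:] = 255  # three gray populations so c=3 is well posed
    cfg = FcmConfig(c=3)
    centers0 = init_centers(image, cfg)
    fcm = run_fcm(image, cfg, initial_centers=centers0)
    mmtd = run_mmtdfcm(image, cfg, initial_centers=centers0)
    region_label_fcm = fcm.labels[5, 4]
    assert fcm.labels[5, 5] != region_label_fcm          # gray-nearest
    assert mmtd.labels[5, 5] == mmtd.labels[5, 4]        # outvoted by region


def test_noisy_phantom_paired_improvement(phantom128, config3):
    from mmtdfcm import add_salt_pepper, init_centers

    image, truth = phantom128
    noisy = add_salt_pepper(image, 0.05, seed=3)
    centers0 = init_centers(noisy, config3)
    fcm = run_fcm(noisy, config3, initial_centers=centers0)
    mmtd = run_mmtdfcm(noisy, config3, initial_centers=centers0)
    assert (misclassification_rate(mmtd.labels, truth, 3)
            < misclassification_rate(fcm.labels, truth, 3))


def test_permutation_equivariance(phantom128, config3):
    image, _ = phantom128
    img = image[::4, ::4]  # 32x32 for speed
    perm = [2, 0, 1]
    a = run_mmtdfcm(img, config3, initial_centers=[0.0, 160.0, 255.0])
    b = run_mmtdfcm(img, config3,
                    initial_centers=np.asarray([0.0, 160.0, 255.0])[perm])
    np.testing.assert_allclose(b.centers, a.centers[perm], atol=1e-10)
    np.testing.assert_allclose(b.memberships, a.memberships[perm], atol=1e-10)
    # label maps agree up to the relabeling induced by perm
    np.testing.assert_array_equal(a.labels, np.asarray(perm)[b.labels])


def test_runs_are_bit_reproducible(phantom128):
    image, _ = phantom128
    cfg = FcmConfig(c=3, init_method="random", seed=7)
    a = segment(image, cfg)
    b = segment(image, cfg)
    np.testing.assert_array_equal(a.labels, b.labels)
    np.testing.assert_array_equal(a.memberships, b.memberships)
    np.testing.assert_array_equal(a.centers, b.centers)


def test_single_iteration_matches_transliterated_oracle(rng):
    image = rng.integers(0, 256, size=(5, 5))
    centers0 = [60.0, 200.0]
    cfg = FcmConfig(c=2, m=2.0, max_iter=1)
    res = run_mmtdfcm(image, cfg, initial_centers=centers0)
    u_expected, v_expected = mmtd_iteration_oracle(image, centers0, 2.0)
    np.testing.assert_allclose(res.memberships, u_expected, atol=1e-12)
    np.testing.assert_allclose(res.centers, v_expected, atol=1e-12)


def test_config_validation():
    with pytest.raises(ValueError):
        FcmConfig(c=1)
    with pytest.raises(ValueError):
        FcmConfig(m=1.0)
    with pytest.raises(ValueError):
        FcmConfig(eps=0.0)
    with pytest.raises(ValueError):
        FcmConfig(variant="kmeans")
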