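import numpy as np
import pytest

from ploidyhic.compare import (
    DifferenceMatrix,
    call_differential_bins,
    difference_matrix,
    obs_exp_interchrom,
    rank_sum_test,
    region_pair_frequencies,
    trans_cis_ratio,
)
from ploidyhic.contacts import BALANCED, ContactMatrix, kr_balance
from ploidyhic.genome import GenomeLayout


def _layout(n_bins, name="chr1"):
    return GenomeLayout([(name, n_bins * 50_000)], bin_size=50_000)


def _balanced(layout, M):
    return ContactMatrix(layout, np.asarray(M, dtype=float), state=BALANCED)


# -- difference matrix -----------------------------------------------------


def test_identical_inputs_give_zero_Z():
    rng = np.random.default_rng(0)
    A = rng.uniform(0.5, 2.0, (6, 6))
    A = A + A.T
    layout = _layout(6)
    D = difference_matrix(_balanced(layout, A), _balanced(layout, A))
    assert np.abs(D.Z).max() < 1e-12


def test_global_scale_is_removed():
    rng = np.random.default_rng(1)
    A = rng.uniform(0.5, 2.0, (6, 6))
    A = A + A.T
    layout = _layout(6)
    D = difference_matrix(_balanced(layout, A), _balanced(layout, 2 * A))
    assert np.abs(D.Z).max() < 1e-9


def test_four_by_four_fixture_matches_step_by_step_oracle():
    A = np.array(
        [[1.0, 0.0, 2.0, 0.5],
         [0.0, 3.0, 1.0, 0.0],
         [2.0, 1.0, 4.0, 1.5],
         [0.5, 0.0, 1.5, 2.0]]
    )
    B = np.array(
        [[2.0, 1.0, 1.0, 0.5],
         [1.0, 2.0, 2.0, 1.0],
         [1.0, 2.0, 3.0, 0.5],
         [0.5, 1.0, 0.5, 1.0]]
    )
    layout = _layout(4)
    D = difference_matrix(_balanced(layout, A), _balanced(layout, B), patch_quantile=0.01)
    # independent step-by-step computation: patch, ratio, log2, median-centre
    Ap, Bp = A.copy(), B.copy()
    Ap[Ap == 0] = np.quantile(A[A > 0], 0.01)
    Bp[Bp == 0] = np.quantile(B[B > 0], 0.01)
    L = np.log2(Ap / Bp)
    expect = L - np.median(L)
    assert np.abs(D.Z - expect).max() < 1e-12
    assert abs(np.median(D.Z)) < 1e-12


def test_Z_invariant_to_scaling_either_input():
    rng = np.random.default_rng(2)
    A = rng.uniform(0.5, 2.0, (5, 5))
    A = A + A.T
    B = rng.uniform(0.5, 2.0, (5, 5))
    B = B + B.T
    layout = _layout(5)
    D0 = difference_matrix(_balanced(layout, A), _balanced(layout, B))
    D1 = difference_matrix(_balanced(layout, 3.7 * A), _balanced(layout, B))
    D2 = difference_matrix(_balanced(layout, A), _balanced(layout, 0.2 * B))
    assert np.abs(D0.Z - D1.Z).max() < 1e-9
    assert np.abs(D0.Z - D2.Z).max() < 1e-9


# -- differential bins -----------------------------------------------------


def test_zero_Z_flags_nothing():
    layout = _layout(10)
    D = DifferenceMatrix(layout, np.zeros((10, 10)), np.ones(10, bool), 0.01)
    flags = call_differential_bins(D, top_fraction=0.25)
    assert not flags.any()


def test_single_perturbed_row_is_the_only_flag():
    n, k = 20, 7
    Z = np.zeros((n, n))
    Z[k, :] = 2.0
    Z[:, k] = 2.0
    D = DifferenceMatrix(_layout(n), Z, np.ones(n, bool), 0.01)
    flags = call_differential_bins(
        D, stat="median_abs", top_fraction=0.10, distance_normalize=False
    )
    assert flags[k] and flags.sum() == 1  # median score of other rows is 0


def test_differential_recovery_on_simulated_ground_truth(default_dataset, balanced_pair):
    D = difference_matrix(balanced_pair["diploid"], balanced_pair["tetraploid"])
    flags = call_differential_bins(D)
    intended = default_dataset.intended_differential
    recovered = flags[intended].mean()
    false_rate = flags[~intended].mean()
    assert recovered >= 0.90
    assert false_rate <= 0.10


# -- trans/cis and region classes -----------------------------------------


def test_trans_cis_ratio_matches_brute_force():
    layout = GenomeLayout([("chr1", 150_000), ("chr2", 150_000)], bin_size=50_000)
    M = np.full((6, 6), 2.0)
    cm = _balanced(layout, M)
    per_chrom, genome = trans_cis_ratio(cm)
    # brute force over labelled upper-triangle cells (incl. diagonal)
    cis = trans = 0.0
    for i in range(6):
        for j in range(i, 6):
            if (i < 3) == (j < 3):
                cis += M[i, j]
            else:
                trans += M[i, j]
    assert genome == pytest.approx(trans / cis)
    assert per_chrom["chr1"] == pytest.approx(trans / (sum(M[i, j] for i in range(3) for j in range(i, 3))))


def test_trans_cis_zero_trans_and_linearity():
    layout = GenomeLayout([("chr1", 100_000), ("chr2", 100_000)], bin_size=50_000)
    M = np.zeros((4, 4))
    M[:2, :2] = 1.0
    M[2:, 2:] = 1.0
    _, r0 = trans_cis_ratio(_balanced(layout, M))
    assert r0 == 0.0
    M2 = M.copy()
    M2[:2, 2:] = 0.5
    M2[2:, :2] = 0.5
    _, r1 = trans_cis_ratio(_balanced(layout, M2))
    M3 = M.copy()
    M3[:2, 2:] = 1.0
    M3[2:, :2] = 1.0
    _, r2 = trans_cis_ratio(_balanced(layout, M3))
    assert r2 == pytest.approx(2 * r1)


def test_region_classes_enumerate_expected_pairs(toy_layout):
    n = toy_layout.n_bins
    rng = np.random.default_rng(5)
    M = rng.uniform(0.1, 1.0, (n, n))
    M = M + M.T
    cm = _balanced(toy_layout, M)
    # chr1: 10 bins, pericentromere bins 4-5 -> left arm 4 bins, right arm 4 bins
    intra_arm = region_pair_frequencies(cm, "intra_arm")
    # per arm with a bins: a*(a+1)/2 pairs incl. diagonal
    # chr1 arms: 4+4 ; chr2 (8 bins, peri 3-4): 3 left, 3 right
    expect = 4 * 5 // 2 + 4 * 5 // 2 + 3 * 4 // 2 + 3 * 4 // 2
    assert intra_arm.size == expect
    peri = region_pair_frequencies(cm, "intra_pericentromere")
    assert peri.size == 2 * 3 // 2 + 2 * 3 // 2  # 2 peri bins per chromosome


def test_single_pericentromeric_bin_yields_diagonal_only():
    layout = GenomeLayout(
        [("chr1", 150_000)], bin_size=50_000, pericentromeres={"chr1": (50_000, 100_000)}
    )
    M = np.arange(9.0).reshape(3, 3)
    M = M + M.T
    vals = region_pair_frequencies(_balanced(layout, M), "intra_pericentromere")
    assert vals.tolist() == [M[1, 1]]


def test_inter_chrom_on_single_chromosome_raises():
    cm = _balanced(_layout(4), np.ones((4, 4)))
    with pytest.raises(ValueError, match="empty"):
        region_pair_frequencies(cm, "inter_chrom")


# -- rank-sum test ---------------------------------------------------------


def test_rank_sum_symmetric_samples_give_p_one():
    res = rank_sum_test([1, 2, 3], [1, 2, 3])
    assert res.p_two_sided == pytest.approx(1.0)


def test_rank_sum_exact_small_sample():
    res = rank_sum_test([1, 2], [3, 4])
    assert res.statistic == 0
    assert res.p_two_sided == pytest.approx(1 / 3)


def test_rank_sum_identical_constant_warns_p_one():
    with pytest.warns(UserWarning, match="identical"):
        res = rank_sum_test([5, 5, 5], [5, 5])
    assert res.p_two_sided == 1.0


def test_rank_sum_agrees_with_permutation_oracle():
    rng = np.random.default_rng(11)
    x = rng.normal(0.0, 1.0, 40)
    y = rng.normal(0.5, 1.0, 35)
    res = rank_sum_test(x, y)

    def u_stat(a, b):
        return (a[:, None] > b[None, :]).sum() + 0.5 * (a[:, None] == b[None, :]).sum()

    obs = u_stat(x, y)
    pooled = np.concatenate([x, y])
    n_shuffles = 10_000
    count = 0
    mid = x.size * y.size / 2
    for _ in range(n_shuffles):
        rng.shuffle(pooled)
        u = u_stat(pooled[: x.size], pooled[x.size :])
        if abs(u - mid) >= abs(obs - mid) - 1e-12:
            count += 1
    p_perm = count / n_shuffles
    mc_err = 3 * np.sqrt(p_perm * (1 - p_perm) / n_shuffles) + 0.005
    assert abs(res.p_two_sided - p_perm) <= mc_err


# -- observed/expected inter-chromosome -----------------------------------


def _three_chrom_layout(bins_per_chrom=2):
    return GenomeLayout(
        [(f"chr{i+1}", bins_per_chrom * 50_000) for i in range(3)], bin_size=50_000
    )


def test_obs_exp_uniform_trans_is_zero():
    layout = _three_chrom_layout()
    M = np.ones((6, 6))
    oe = obs_exp_interchrom(_balanced(layout, M))
    off = oe[~np.isnan(oe)]
    assert np.abs(off).max() < 1e-12


def test_obs_exp_matches_hand_computed_expectation():
    layout = _three_chrom_layout(1)
    M = np.array([[1.0, 2.0, 4.0], [2.0, 1.0, 6.0], [4.0, 6.0, 1.0]])
    oe = obs_exp_interchrom(_balanced(layout, M))
    # trans sums: T12=2, T13=4, T23=6; marginals 6, 8, 10; shares 6/24, 8/24, 10/24
    shares = np.array([6, 8, 10]) / 24
    denom = shares[0] * shares[1] + shares[0] * shares[2] + shares[1] * shares[2]
    total = 2 + 4 + 6  # each chromosome pair counted once
    expect12 = total * shares[0] * shares[1] / denom  # = 144/47
    assert oe[0, 1] == pytest.approx(np.log2(2 / expect12))
    assert np.isnan(oe[0, 0])


def test_obs_exp_boosted_pair_sign():
    layout = _three_chrom_layout()
    M = np.ones((6, 6))
    M[:2, 2:4] = 3.0
    M[2:4, :2] = 3.0
    oe = obs_exp_interchrom(_balanced(layout, M))
    assert oe[0, 1] > 0
    assert oe[0, 2] < 0 and oe[1, 2] < 0
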