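"""Assessment metrics: SSIM, PSNR, CNR, ROI placement, weighted kappa."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octenhance import (
    CNR_PAIRS, ROIPair, auto_rois, cnr, kappa_panel, make_phantom, psnr, ssim,
    weighted_kappa,
)


# ------------------------------------------------------------------- SSIM

def test_ssim_identity_and_symmetry(phantom):
    rng = np.random.default_rng(0)
    x = phantom.clean
    y = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
    assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)
    assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)
    assert -1.0 <= ssim(x, y) <= 1.0
    assert ssim(x, y) < 1.0


def test_ssim_of_inverted_binary_image_is_negative():
    rng = np.random.default_rng(1)
    x = (rng.random((64, 64)) > 0.5).astype(float)
    from scipy.ndimage import gaussian_filter
    x = gaussian_filter(x, 1.0)
    assert ssim(x, 1.0 - x) < 0.0


def test_ssim_of_independent_noise_is_near_zero():
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(seed)
        vals.append(ssim(rng.random((96, 96)), rng.random((96, 96))))
    assert abs(np.mean(vals)) < 0.05


def test_ssim_shape_mismatch_rejected(phantom):
    with pytest.raises(ValueError):
        ssim(phantom.clean, phantom.clean[:64])


# ------------------------------------------------------------------- PSNR

def test_psnr_closed_forms(phantom):
    x = np.clip(phantom.clean, 0.0, 0.9)
    assert psnr(x, x) == float("inf")
    assert psnr(x + 0.1, x) == pytest.approx(20.0, abs=1e-9)
    assert psnr(x + 0.01, x) == pytest.approx(40.0, abs=1e-9)


def test_psnr_decreases_with_mse_and_is_permutation_invariant(phantom):
    rng = np.random.default_rng(2)
    x = phantom.clean
    a = np.clip(x + rng.normal(0, 0.02, x.shape), 0, 1)
    b = np.clip(x + rng.normal(0, 0.08, x.shape), 0, 1)
    assert psnr(a, x) > psnr(b, x)
    perm = rng.permutation(x.size)
    assert psnr(a.ravel()[perm].reshape(x.shape),
                x.ravel()[perm].reshape(x.shape)) == pytest.approx(
        psnr(a, x), abs=1e-9)


# -------------------------------------------------------------------- CNR

def _checker(mean, amp, shape=(4, 4)):
    out = np.full(shape, mean)
    out[::2, ::2] += amp
    out[1::2, 1::2] += amp
    out[::2, 1::2] -= amp
    out[1::2, ::2] -= amp
    return out


def test_cnr_matches_hand_evaluation():
    # High ROI: mean 0.8, var 0.0001; low ROI: mean 0.2, var 0.0001
    # -> CNR = 0.6 / sqrt(0.0002) = 42.4264...
    img = np.zeros((8, 8))
    img[0:4, 0:4] = _checker(0.8, 0.01)
    img[4:8, 4:8] = _checker(0.2, 0.01)
    pair = ROIPair("IPL/INL", high_rois=((0, 0),), low_rois=((4, 4),))
    result = cnr(img, pair)
    assert result.h == pytest.approx(0.8)
    assert result.var_h == pytest.approx(1e-4)
    assert result.cnr == pytest.approx(0.6 / np.sqrt(2e-4), rel=1e-9)


@settings(deadline=None, max_examples=25)
@given(st.floats(0.1, 5.0), st.floats(-0.5, 0.5))
def test_cnr_invariant_under_positive_affine_maps(a, b):
    rng = np.random.default_rng(4)
    img = rng.random((8, 8))
    pair = ROIPair("OPL/ONL", high_rois=((0, 0),), low_rois=((4, 4),))
    base = cnr(img, pair).cnr
    mapped = cnr(a * img + b, pair).cnr
    assert mapped == pytest.approx(base, rel=1e-6)


def test_cnr_degenerate_and_out_of_bounds_rois_rejected():
    img = np.full((8, 8), 0.5)
    pair = ROIPair("IPL/INL", high_rois=((0, 0),), low_rois=((4, 4),))
    with pytest.raises(ValueError, match="degenerate"):
        cnr(img, pair)
    bad = ROIPair("IPL/INL", high_rois=((6, 6),), low_rois=((0, 0),))
    with pytest.raises(ValueError, match="outside"):
        cnr(img, bad)


# ------------------------------------------------------------ ROI placement

def test_auto_rois_places_label_pure_windows(phantom):
    for name in CNR_PAIRS:
        pair = auto_rois(phantom.layer_map, name, n_pairs=50, seed=0)
        assert len(pair.high_rois) == 50 and len(pair.low_rois) == 50
        high, low = CNR_PAIRS[name]
        labels = phantom.layer_map.labels
        for layer, rois in ((high, pair.high_rois), (low, pair.low_rois)):
            from octenhance.phantom import LAYER_INDEX
            for r, c in rois:
                window = labels[r : r + 4, c : c + 4]
                assert (window == LAYER_INDEX[layer]).all()


def test_auto_rois_minimal_and_error_cases(phantom):
    single = auto_rois(phantom.layer_map, "IPL/INL", n_pairs=1, seed=0)
    assert len(single.high_rois) == 1
    with pytest.raises(ValueError):
        auto_rois(phantom.layer_map, "not/a-pair", seed=0)
    # A 64x64 phantom's thinnest layers cannot host 50 pure 4x4 windows.
    small = make_phantom(64, 64, seed=0)
    with pytest.raises(ValueError):
        auto_rois(small.layer_map, "ELM/ONL", n_pairs=50, seed=0)


def test_averaging_improves_cnr_on_phantom(phantom, aligned_stack):
    from octenhance import average_frames

    single = aligned_stack.frames[0]
    avg = average_frames(aligned_stack, list(range(len(aligned_stack))))
    for name in CNR_PAIRS:
        pair = auto_rois(phantom.layer_map, name, seed=1)
        assert cnr(avg, pair).cnr > cnr(single, pair).cnr


# --------------------------------------------------------- weighted kappa

def _kappa_oracle(table: np.ndarray, weighting: str) -> float:
    """Brute-force weighted kappa from a contingency table."""
    n = table.sum()
    k = table.shape[0]
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]).astype(float)
    if weighting == "quadratic":
        w = w**2
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    observed = (w * table).sum() / n
    expected = (w * np.outer(row, col)).sum() / n**2
    if expected == 0:
        return float("nan")
    return 1.0 - observed / expected


def test_kappa_perfect_agreement():
    assert weighted_kappa([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == pytest.approx(1.0)


def test_kappa_matches_oracle_on_crossed_example():
    a, b = [1, 1, 2, 2], [2, 2, 1, 1]
    table = np.zeros((2, 2))
    for x, y in zip(a, b):
        table[x - 1, y - 1] += 1
    assert weighted_kappa(a, b, "linear") == pytest.approx(
        _kappa_oracle(table, "linear"))


@pytest.mark.parametrize("weighting", ["linear", "quadratic"])
def test_kappa_matches_oracle_on_all_small_contingency_tables(weighting):
    """Exhaustive check over every 3-category contingency table with n <= 6."""
    cells = 9
    for n in range(1, 7):
        for cuts in itertools.combinations(range(n + cells - 1), cells - 1):
            # stars-and-bars decomposition of n into 9 cells
            counts = []
            prev = -1
            for c in cuts:
                counts.append(c - prev - 1)
                prev = c
            counts.append(n + cells - 1 - prev - 1)
            table = np.array(counts, dtype=float).reshape(3, 3)
            expected = _kappa_oracle(table, weighting)
            scores_a, scores_b = [], []
            for i in range(3):
                for j in range(3):
                    scores_a += [i + 1] * int(table[i, j])
                    scores_b += [j + 1] * int(table[i, j])
            if np.isnan(expected):
                with pytest.raises(ValueError):
                    weighted_kappa(scores_a, scores_b, weighting)
            else:
                assert weighted_kappa(scores_a, scores_b, weighting) == \
                    pytest.approx(expected, abs=1e-12)


def test_kappa_near_zero_for_shuffled_scores():
    rng = np.random.default_rng(0)
    vals = []
    for _ in range(20):
        a = rng.integers(1, 6, size=400)
        b = rng.permutation(a)
        vals.append(weighted_kappa(a, b))
    assert abs(np.mean(vals)) < 0.05


def test_kappa_input_validation():
    with pytest.raises(ValueError):
        weighted_kappa([1, 2], [1])
    with pytest.raises(ValueError):
        weighted_kappa([], [])
    with pytest.raises(ValueError):
        weighted_kappa([2, 2, 2], [2, 2, 2])  # zero expected disagreement
    with pytest.raises(ValueError):
        weighted_kappa([1, 2], [1, 2], weighting="cubic")


def test_kappa_panel_averages_pairwise_values():
    scores = np.array([
        [5, 5, 4],
        [4, 4, 4],
        [2, 3, 2],
        [1, 1, 2],
        [3, 3, 3],
    ])
    panel = kappa_panel(scores)
    assert len(panel["pairwise"]) == 3
    assert panel["mean"] == pytest.approx(
        np.mean(list(panel["pairwise"].values())))
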