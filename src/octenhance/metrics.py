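"""Image-quality assessment: SSIM, PSNR, paired-ROI CNR, weighted kappa.

SSIM and PSNR are computed against a gold standard over the whole image.
CNR is local: paired 4x4-px regions of interest in a high-reflection and a
low-reflection retinal layer,

    CNR = (h - l) / sqrt(var_h + var_l),

with h, l the ROI mean intensities and var_h, var_l their variances.  The
six canonical pairs are IPL/INL, OPL/ONL, ELM/ONL, IS-OS/Inner-RPE,
Outer-RPE/Inner-RPE and choroid/background.  Rater agreement on ordinal
quality scores is summarised by weighted Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import peak_signal_noise_ratio, structural_similarity
from sklearn.metrics import cohen_kappa_score

from .phantom import LayerMap

#: The six high/low layer pairs used for CNR assessment.
CNR_PAIRS: dict[str, tuple[str, str]] = {
    "IPL/INL": ("IPL", "INL"),
    "OPL/ONL": ("OPL", "ONL"),
    "ELM/ONL": ("ELM", "ONL"),
    "IS-OS/Inner-RPE": ("IS-OS", "Inner-RPE"),
    "Outer-RPE/Inner-RPE": ("Outer-RPE", "Inner-RPE"),
    "choroid/background": ("choroid", "background"),
}

DEFAULT_ROI_WINDOW = 4
DEFAULT_N_PAIRS = 50


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def ssim(x: np.ndarray, y: np.ndarray, window: int = 11,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity on data range 1.

    Gaussian-weighted 11-px windows with the canonical stabilisers
    c1 = (k1 * L)^2, c2 = (k2 * L)^2 at L = 1.
    """
    _check_pair(x, y)
    return float(
        structural_similarity(
            x, y, win_size=window, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=k1, K2=k2, data_range=1.0,
        )
    )


def psnr(x: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB on data range 1; inf at zero MSE."""
    _check_pair(x, ref)
    if np.array_equal(x, ref):
        return float("inf")
    return float(peak_signal_noise_ratio(ref, x, data_range=1.0))


@dataclass(frozen=True)
class ROIPair:
    """Paired 4x4-px ROI windows in a high- and a low-reflection layer.

    Windows are (row, col) top-left corners of ``window``-sized squares.
    """

    pair_name: str
    high_rois: tuple[tuple[int, int], ...]
    low_rois: tuple[tuple[int, int], ...]
    window: int = DEFAULT_ROI_WINDOW

    def __post_init__(self) -> None:
        if self.pair_name not in CNR_PAIRS:
            raise ValueError(f"unknown CNR pair {self.pair_name!r}")
        if not self.high_rois or not self.low_rois:
            raise ValueError("ROI lists must be non-empty")


@dataclass(frozen=True)
class CNRResult:
    pair_name: str
    h: float
    l: float
    var_h: float
    var_l: float
    cnr: float


@dataclass
class MetricsReport:
    """Assessment of one enhanced image against a gold standard."""

    ssim: float
    psnr: float
    cnr_by_pair: dict[str, CNRResult] = field(default_factory=dict)
    kappa: float | None = None

    def to_dict(self) -> dict:
        out = {"ssim": self.ssim, "psnr": self.psnr}
        for name, res in self.cnr_by_pair.items():
            out[f"cnr[{name}]"] = res.cnr
        if self.kappa is not None:
            out["kappa"] = self.kappa
        return out


def _gather(image: np.ndarray, rois, window: int) -> np.ndarray:
    h, w = image.shape
    pixels = []
    for r, c in rois:
        if r < 0 or c < 0 or r + window > h or c + window > w:
            raise ValueError(f"ROI at ({r}, {c}) lies outside the image")
        pixels.append(image[r : r + window, c : c + window].ravel())
    return np.concatenate(pixels)


def cnr(image: np.ndarray, pair: ROIPair) -> CNRResult:
    """Contrast-to-noise ratio of one layer pair on one image."""
    hi = _gather(image, pair.high_rois, pair.window)
    lo = _gather(image, pair.low_rois, pair.window)
    h, l = float(hi.mean()), float(lo.mean())
    var_h, var_l = float(hi.var()), float(lo.var())
    if var_h + var_l <= 0.0:
        raise ValueError(
            f"degenerate ROIs for pair {pair.pair_name!r}: both variances are zero"
        )
    return CNRResult(
        pair_name=pair.pair_name, h=h, l=l, var_h=var_h, var_l=var_l,
        cnr=(h - l) / float(np.sqrt(var_h + var_l)),
    )


def _feasible_windows(mask: np.ndarray, window: int) -> np.ndarray:
    """Boolean map of top-left corners whose full window is label-pure."""
    view = np.lib.stride_tricks.sliding_window_view(mask, (window, window))
    return view.all(axis=(2, 3))


def _place_layer_windows(
    layer_map: LayerMap, layer: str, n: int, window: int,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], ...]:
    feas = _feasible_windows(layer_map.mask(layer), window)
    cols_ok = np.flatnonzero(feas.any(axis=0))
    if cols_ok.size < n:
        raise ValueError(
            f"layer {layer!r} too thin or narrow for {n} {window}x{window}-px "
            "windows; use a larger phantom"
        )
    # Equal horizontal intervals across the feasible span, snapped to the
    # nearest feasible column (keeping columns distinct where possible).
    targets = np.linspace(cols_ok[0], cols_ok[-1], n)
    chosen_cols: list[int] = []
    used: set[int] = set()
    for t in targets:
        order = cols_ok[np.argsort(np.abs(cols_ok - t), kind="stable")]
        col = next((int(c) for c in order if int(c) not in used), int(order[0]))
        used.add(col)
        chosen_cols.append(col)
    out = []
    for col in chosen_cols:
        rows_ok = np.flatnonzero(feas[:, col])
        out.append((int(rng.choice(rows_ok)), col))
    return tuple(out)


def auto_rois(
    layer_map: LayerMap,
    pair_name: str,
    n_pairs: int = DEFAULT_N_PAIRS,
    window: int = DEFAULT_ROI_WINDOW,
    seed: int = 0,
) -> ROIPair:
    """Automatic stand-in for manual ROI marking on phantom label maps.

    Places ``n_pairs`` label-pure windows per layer at approximately equal
    horizontal intervals; the row within the layer is drawn uniformly among
    feasible rows.  Deterministic given ``seed``.
    """
    if pair_name not in CNR_PAIRS:
        raise ValueError(f"unknown CNR pair {pair_name!r}")
    high, low = CNR_PAIRS[pair_name]
    for layer in (high, low):
        if not layer_map.mask(layer).any():
            raise ValueError(f"layer {layer!r} absent from the label map")
    rng = np.random.default_rng(seed)
    return ROIPair(
        pair_name=pair_name,
        high_rois=_place_layer_windows(layer_map, high, n_pairs, window, rng),
        low_rois=_place_layer_windows(layer_map, low, n_pairs, window, rng),
        window=window,
    )


def all_cnr(
    image: np.ndarray,
    layer_map: LayerMap,
    n_pairs: int = DEFAULT_N_PAIRS,
    window: int = DEFAULT_ROI_WINDOW,
    seed: int = 0,
) -> dict[str, CNRResult]:
    """CNR for all six layer pairs with automatically placed ROIs."""
    return {
        name: cnr(image, auto_rois(layer_map, name, n_pairs, window, seed))
        for name in CNR_PAIRS
    }


def weighted_kappa(
    scores_a, scores_b, weighting: str = "quadratic"
) -> float:
    """Weighted Cohen's kappa between two raters' ordinal scores.

    1 - (observed weighted disagreement) / (chance-expected weighted
    disagreement), with linear or quadratic distance weights.
    """
    a = np.asarray(scores_a)
    b = np.asarray(scores_b)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("score vectors must be 1-D")
    if len(a) != len(b):
        raise ValueError("score vectors must have equal length")
    if len(a) == 0:
        raise ValueError("score vectors must be non-empty")
    if weighting not in ("linear", "quadratic"):
        raise ValueError("weighting must be 'linear' or 'quadratic'")
    # Pass the full integer range as labels: weights must measure ordinal
    # distance even when intermediate categories are never used.
    lo = int(min(a.min(), b.min()))
    hi = int(max(a.max(), b.max()))
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # degenerate single-category panels surface as nan and are turned
        # into the error below; sklearn's warnings about them are redundant
        warnings.simplefilter("ignore")
        k = cohen_kappa_score(a, b, weights=weighting,
                              labels=np.arange(lo, hi + 1))
    if np.isnan(k):
        raise ValueError(
            "kappa undefined: zero chance-expected disagreement "
            "(all scores in one category for both raters)"
        )
    return float(k)


def kappa_panel(scores: np.ndarray, weighting: str = "quadratic") -> dict:
    """Agreement summary for a rater panel (items x raters matrix).

    Pairwise weighted kappas over all rater pairs, averaged.
    """
    scores = np.asarray(scores)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise ValueError("need an items x raters matrix with >= 2 raters")
    n_raters = scores.shape[1]
    pairwise = {}
    for i in range(n_raters):
        for j in range(i + 1, n_raters):
            pairwise[(i, j)] = weighted_kappa(scores[:, i], scores[:, j], weighting)
    return {
        "weighting": weighting,
        "pairwise": pairwise,
        "mean": float(np.mean(list(pairwise.values()))),
    }


def evaluate(
    image: np.ndarray,
    gold: np.ndarray,
    layer_map: LayerMap | None = None,
    rater_scores: np.ndarray | None = None,
    n_pairs: int = DEFAULT_N_PAIRS,
    seed: int = 0,
) -> MetricsReport:
    """Full assessment of one enhanced image: SSIM, PSNR, optional CNR and
    rater-panel kappa."""
    report = MetricsReport(ssim=ssim(image, gold), psnr=psnr(image, gold))
    if layer_map is not None:
        report.cnr_by_pair = all_cnr(image, layer_map, n_pairs=n_pairs, seed=seed)
    if rater_scores is not None:
        report.kappa = kappa_panel(rater_scores)["mean"]
    return report
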