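"""Traditional multi-frame enhancement: register, exclude, average.

The pipeline mirrors clinical frame-averaging practice: the frame with the
strongest signal-to-noise ratio becomes the reference; every other frame is
rigidly aligned to it by maximising mutual information between pixel
intensities; frames whose normalised cross-correlation against the reference
falls below 70% of the reference's (unit) zero-lag autocorrelation are
discarded as fixation losses; the surviving frames are averaged pixel-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu

from .phantom import FrameStack
from .transform import RigidTransform, warp_image

DEFAULT_EXCLUSION_THRESHOLD = 0.70


@dataclass(frozen=True)
class RegistrationConfig:
    """Settings for mutual-information rigid registration.

    bins: joint-histogram bin count for the MI estimate.
    max_shift: half-width (px) of the exhaustive integer translation search.
    max_rotation: bound (deg) for the rotation refinement.
    smooth_sigma: Gaussian pre-smoothing (px) applied before MI evaluation;
        damps speckle-induced local optima without moving the global one.
    refine: run derivative-free simplex refinement over (dx, dy, theta)
        after the coarse translation search.
    """

    bins: int = 32
    max_shift: int = 12
    max_rotation: float = 4.0
    smooth_sigma: float = 1.5
    refine: bool = True
    refine_maxiter: int = 200


@dataclass
class RegistrationResult:
    transforms: list[RigidTransform]
    mi_values: list[float]
    correlations: list[float] = field(default_factory=list)
    excluded: set[int] = field(default_factory=set)
    reference_index: int = 0


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 32) -> float:
    """MI (nats) of the joint intensity histogram of two equal-shape images."""
    if x.shape != y.shape:
        raise ValueError("images must share shape")
    joint, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def normalized_mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 32) -> float:
    """Studholme normalised MI, (H(X) + H(Y)) / H(X, Y).

    Used as the registration objective: unlike raw MI it is insensitive to
    the size of the overlap region, which otherwise biases coarse
    translation search toward large shifts.
    """
    if x.shape != y.shape:
        raise ValueError("images must share shape")
    joint, _, _ = np.histogram2d(
        x.ravel(), y.ravel(), bins=bins, range=[[0.0, 1.0], [0.0, 1.0]]
    )
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    hx = -(px[px > 0] * np.log(px[px > 0])).sum()
    hy = -(py[py > 0] * np.log(py[py > 0])).sum()
    hxy = -(p[p > 0] * np.log(p[p > 0])).sum()
    if hxy == 0:
        raise ValueError("mutual information undefined for a constant image")
    return float((hx + hy) / hxy)


def _half(x: np.ndarray) -> np.ndarray:
    """2x2 block-mean downsampling."""
    h2, w2 = x.shape[0] // 2, x.shape[1] // 2
    return x[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def _shift_overlap(a: np.ndarray, b: np.ndarray, dx: int, dy: int):
    """Overlapping sub-arrays of a shifted by (dx, dy) against b."""
    h, w = a.shape
    ax0, bx0 = max(0, -dx), max(0, dx)
    ay0, by0 = max(0, -dy), max(0, dy)
    ww, hh = w - abs(dx), h - abs(dy)
    if ww <= 0 or hh <= 0:
        return None, None
    return (
        a[ay0 : ay0 + hh, ax0 : ax0 + ww],
        b[by0 : by0 + hh, bx0 : bx0 + ww],
    )


def select_reference(stack: FrameStack) -> int:
    """Index of the frame with the strongest signal-to-noise ratio.

    SNR is estimated as mean(tissue pixels) / std(background pixels) with the
    tissue/background split by Otsu thresholding of the frame.  An all-
    constant frame has zero background spread and is treated as infinite SNR.
    Ties break to the lowest index.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    snrs = np.empty(len(stack))
    for i, frame in enumerate(stack.frames):
        if np.ptp(frame) == 0:
            snrs[i] = math.inf
            continue
        t = threshold_otsu(frame)
        tissue = frame > t
        background = ~tissue
        bg_sd = frame[background].std() if background.any() else 0.0
        if bg_sd == 0:
            snrs[i] = math.inf
        else:
            snrs[i] = frame[tissue].mean() / bg_sd
    return int(np.argmax(snrs))


def register_rigid(
    moving: np.ndarray,
    reference: np.ndarray,
    config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, float]:
    """Rigid transform aligning ``moving`` to ``reference`` by MI maximisation.

    Exhaustive integer translation search within ``max_shift`` px, then
    Nelder-Mead refinement of (dx, dy, theta) on the smoothed images.
    Returns the transform and the final MI of the aligned pair (computed on
    the unsmoothed images).  Deterministic given the config.
    """
    config = config or RegistrationConfig()
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share shape")
    if np.ptp(moving) == 0 or np.ptp(reference) == 0:
        raise ValueError("mutual information undefined for a constant image")

    if config.smooth_sigma > 0:
        mov = gaussian_filter(moving, config.smooth_sigma)
        ref = gaussian_filter(reference, config.smooth_sigma)
    else:
        mov, ref = moving, reference

    # Coarse: exhaustive translation grid at half resolution, repeated for a
    # small fan of candidate rotations (a pure-translation scan is blind to
    # the vertical edge displacement a few degrees of tilt causes).
    mov2, ref2 = _half(mov), _half(ref)
    cval2 = float(np.median(mov2))
    s2 = max(1, config.max_shift // 2) + 1
    if config.max_rotation > 0:
        thetas = np.linspace(-config.max_rotation, config.max_rotation, 5)
    else:
        thetas = np.array([0.0])
    best = (-math.inf, 0, 0, 0.0)
    for th in thetas:
        movr = warp_image(mov2, RigidTransform(0.0, 0.0, float(th)), cval=cval2)
        for dy in range(-s2, s2 + 1):
            for dx in range(-s2, s2 + 1):
                a, b = _shift_overlap(movr, ref2, dx, dy)
                if a is None:
                    continue
                nmi = normalized_mutual_information(a, b, config.bins)
                if nmi > best[0]:
                    best = (nmi, dx, dy, float(th))
    _, dxh, dyh, theta0 = best
    dx0, dy0 = 2 * dxh, 2 * dyh

    if config.refine:
        cval = float(np.median(mov))
        bound = 1e3  # soft penalty keeps the simplex finite out of bounds

        def objective(params: np.ndarray) -> float:
            t = RigidTransform(params[0], params[1], params[2])
            excess = max(0.0, abs(t.theta) - config.max_rotation) + max(
                0.0, max(abs(t.dx), abs(t.dy)) - (config.max_shift + 2)
            )
            if excess > 0:
                return bound * (1.0 + excess)
            warped = warp_image(mov, t, cval=cval)
            return -normalized_mutual_information(warped, ref, config.bins)

        x0 = np.array([dx0, dy0, theta0])
        simplex = np.vstack(
            [x0, x0 + [1.25, 0, 0], x0 + [0, 1.25, 0], x0 + [0, 0, 0.75]]
        )
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={
                "initial_simplex": simplex, "xatol": 0.02, "fatol": 1e-7,
                "maxiter": config.refine_maxiter,
            },
        )
        dx, dy, theta = res.x
    else:
        dx, dy, theta = float(dx0), float(dy0), float(theta0)

    transform = RigidTransform(float(dx), float(dy), float(theta))
    aligned = warp_image(moving, transform, cval=float(np.median(moving)))
    return transform, mutual_information(aligned, reference, config.bins)


def ncc_peak(frame: np.ndarray, reference: np.ndarray, max_shift: int = 5) -> float:
    """Peak normalised cross-correlation within a small shift window.

    Both images are standardised to zero mean and unit variance, so the
    reference's zero-lag autocorrelation equals 1 and the exclusion threshold
    is scale-free.  A constant frame correlates with nothing and scores 0.
    """
    if frame.shape != reference.shape:
        raise ValueError("frames must share shape")
    if np.ptp(frame) == 0 or np.ptp(reference) == 0:
        return 0.0
    a = (frame - frame.mean()) / frame.std()
    b = (reference - reference.mean()) / reference.std()
    corr = fftconvolve(a, b[::-1, ::-1], mode="same") / a.size
    h, w = corr.shape
    cy, cx = h // 2 - (1 - h % 2), w // 2 - (1 - w % 2)
    window = corr[
        max(0, cy - max_shift) : cy + max_shift + 1,
        max(0, cx - max_shift) : cx + max_shift + 1,
    ]
    return float(window.max())


def exclude_poor_fixation(
    aligned: FrameStack,
    reference_index: int,
    threshold_fraction: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> set[int]:
    """Indices of frames failing the 70%-correlation fixation rule.

    A frame is excluded when its NCC peak against the reference is below
    ``threshold_fraction`` times the reference's zero-lag autocorrelation
    (which is 1 after normalisation).  The reference is never excluded.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ValueError("threshold_fraction must be in (0, 1]")
    if not 0 <= reference_index < len(aligned):
        raise ValueError("reference index out of range")
    reference = aligned.frames[reference_index]
    excluded = set()
    for i, frame in enumerate(aligned.frames):
        if i == reference_index:
            continue
        if ncc_peak(frame, reference) < threshold_fraction:
            excluded.add(i)
    return excluded


def average_frames(aligned: FrameStack, subset: list[int]) -> np.ndarray:
    """Pixel-wise arithmetic mean of the selected aligned frames."""
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    bad = set(subset) & aligned.excluded
    if bad:
        raise ValueError(f"subset contains excluded frames: {sorted(bad)}")
    out = aligned.frames[list(subset)].mean(axis=0)
    return np.clip(out, 0.0, 1.0)


def register_stack(
    stack: FrameStack,
    config: RegistrationConfig | None = None,
    threshold_fraction: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[FrameStack, RegistrationResult]:
    """Full alignment pass: reference selection, per-frame MI registration,
    fixation exclusion.  Returns the aligned stack and the bookkeeping.

    Stacks already flagged aligned skip the MI step (identity transforms)
    but still run reference selection and the exclusion rule.
    """
    config = config or RegistrationConfig()
    ref_idx = select_reference(stack)
    reference = stack.frames[ref_idx]
    h, w = reference.shape

    transforms: list[RigidTransform] = []
    mi_values: list[float] = []
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        if i == ref_idx or stack.aligned:
            t = RigidTransform.identity()
            out[i] = frame
            mi = mutual_information(frame, reference, config.bins)
        else:
            t, mi = register_rigid(frame, reference, config)
            out[i] = np.clip(warp_image(frame, t, cval=float(np.median(frame))), 0.0, 1.0)
        transforms.append(t)
        mi_values.append(mi)

    aligned = FrameStack(frames=out, aligned=True, reference_index=ref_idx)
    excluded = exclude_poor_fixation(aligned, ref_idx, threshold_fraction)
    aligned.excluded = excluded
    correlations = [ncc_peak(out[i], reference) for i in range(len(out))]
    result = RegistrationResult(
        transforms=transforms, mi_values=mi_values, correlations=correlations,
        excluded=excluded, reference_index=ref_idx,
    )
    return aligned, result


def enhance_by_averaging(
    stack: FrameStack,
    k: int,
    config: RegistrationConfig | None = None,
    threshold_fraction: float = DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[np.ndarray, RegistrationResult]:
    """Avg-k enhancement: register, exclude, average the first k survivors.

    Frames are taken in acquisition order after exclusion.  Raises if fewer
    than k frames survive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    aligned, result = register_stack(stack, config, threshold_fraction)
    survivors = aligned.surviving_indices()
    if len(survivors) < k:
        raise ValueError(
            f"only {len(survivors)} frames survive exclusion; {k} requested"
        )
    enhanced = average_frames(aligned, survivors[:k])
    return enhanced, result
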