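"""Synthetic layered-retina phantom and multi-frame B-scan acquisition.

The phantom stands in for repeated clinical B-scans of one macular location:
a fixed underlying reflectivity scene (ten tissue classes stacked with smooth,
foveally curved boundaries), imaged many times with independent multiplicative
speckle, additive sensor noise, small rigid inter-frame eye motion, and an
occasional fixation-loss frame that is fully decorrelated from the scene.

The statistical structure is exactly what multi-frame enhancement assumes:
the scene is identical across frames while the noise is independent, so that
registration + averaging (and a learned multi-frame denoiser) can recover it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .transform import RigidTransform, warp_image

# Tissue classes, top to bottom anatomically.  Background fills the vitreous
# above the retina and the space below the choroid.
LAYER_NAMES = (
    "background",
    "IPL",
    "INL",
    "OPL",
    "ONL",
    "ELM",
    "IS-OS",
    "Inner-RPE",
    "Outer-RPE",
    "choroid",
)
LAYER_INDEX = {name: i for i, name in enumerate(LAYER_NAMES)}

HIGH_REFLECTION = frozenset({"IPL", "OPL", "ELM", "IS-OS", "Outer-RPE", "choroid"})
LOW_REFLECTION = frozenset({"INL", "ONL", "Inner-RPE", "background"})

# Mean reflectivity per class, chosen so every high-reflection layer is
# brighter than the low-reflection layer it is paired with for CNR.
DEFAULT_REFLECTIVITY = {
    "background": 0.05,
    "IPL": 0.55,
    "INL": 0.25,
    "OPL": 0.55,
    "ONL": 0.18,
    "ELM": 0.60,
    "IS-OS": 0.70,
    "Inner-RPE": 0.30,
    "Outer-RPE": 0.75,
    "choroid": 0.45,
}

# Layer thicknesses as fractions of image height (tissue band only); the top
# background margin takes ~12% and the remainder below the choroid is
# background again.  At the default 128-px height every layer is thick enough
# to hold 4x4-px ROI windows.
DEFAULT_THICKNESS_FRACTIONS = {
    "IPL": 0.10,
    "INL": 0.08,
    "OPL": 0.07,
    "ONL": 0.13,
    "ELM": 0.05,
    "IS-OS": 0.06,
    "Inner-RPE": 0.05,
    "Outer-RPE": 0.06,
    "choroid": 0.16,
}
_TOP_MARGIN_FRACTION = 0.12

DEFAULT_SPECKLE_SHAPE = 12.0
DEFAULT_SENSOR_SIGMA = 0.02
MIN_SIZE = 64


@dataclass(frozen=True)
class Lesion:
    """Elliptical reflectivity perturbation inside the tissue band.

    kind="fluid" lowers reflectivity (hypo-reflective fluid pocket);
    kind="focus" raises it (hyper-reflective focus).
    """

    kind: str  # "fluid" | "focus"
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]  # (semi-height, semi-width) in px
    offset: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("fluid", "focus"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.offset <= 0:
            raise ValueError("lesion offset must be positive")


@dataclass
class LayerMap:
    """Per-pixel tissue labels (indices into LAYER_NAMES)."""

    labels: np.ndarray

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def mask(self, layer: str) -> np.ndarray:
        return self.labels == LAYER_INDEX[layer]


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic acquisition."""

    clean: np.ndarray
    layer_map: LayerMap
    speckle_shape: float = DEFAULT_SPECKLE_SHAPE
    sensor_sigma: float = DEFAULT_SENSOR_SIGMA
    lesions: list[Lesion] = field(default_factory=list)
    motions: list[RigidTransform] = field(default_factory=list)
    fixation_loss_frames: set[int] = field(default_factory=set)

    @property
    def shape(self) -> tuple[int, int]:
        return self.clean.shape


@dataclass
class FrameStack:
    """N repeated frames of one location plus alignment bookkeeping."""

    frames: np.ndarray  # (N, H, W) in [0, 1]
    aligned: bool = False
    reference_index: int = 0
    excluded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.frames.ndim != 3 or len(self.frames) < 1:
            raise ValueError("frames must be a non-empty (N, H, W) array")
        if self.reference_index in self.excluded:
            raise ValueError("reference frame cannot be excluded")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def surviving_indices(self) -> list[int]:
        return [i for i in range(len(self)) if i not in self.excluded]


def _boundary_curve(x: np.ndarray, depth: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth boundary: shared foveal dip plus a tiny low-order wobble."""
    u = (x - x.mean()) / (x.max() - x.min() + 1e-12)  # [-0.5, 0.5]
    wobble = rng.uniform(-1.0, 1.0) * u + rng.uniform(-1.0, 1.0) * (u**2 - 1 / 12)
    return depth + wobble


def make_phantom(
    height: int = 128,
    width: int = 256,
    lesions: list[Lesion] | None = None,
    seed: int = 0,
    reflectivity: dict[str, float] | None = None,
    speckle_shape: float = DEFAULT_SPECKLE_SHAPE,
    sensor_sigma: float = DEFAULT_SENSOR_SIGMA,
    foveal_dip: float | None = None,
    boundary_smoothness: float = 2.0,
    n_vessels: int = 6,
) -> PhantomTruth:
    """Generate a clean layered-retina scene with per-pixel labels.

    The tissue band is a stack of nine layers between background above and
    below; all boundaries share a smooth foveal curvature (a shallow central
    dip) plus a small per-boundary low-order wobble, so boundaries are smooth
    curves and layer thicknesses stay near their defaults.  Deterministic
    given ``seed``.
    """
    if height < MIN_SIZE or width < MIN_SIZE:
        raise ValueError(
            f"phantom must be at least {MIN_SIZE}x{MIN_SIZE} px, got {height}x{width}"
        )
    refl = dict(DEFAULT_REFLECTIVITY)
    if reflectivity:
        refl.update(reflectivity)
    rng = np.random.default_rng(seed)

    x = np.arange(width, dtype=float)
    u = (x - x.mean()) / width
    if foveal_dip is None:
        foveal_dip = 0.06 * height
    # Shared curvature: shallow parabolic dip centred in x.
    curvature = foveal_dip * (1.0 - 4.0 * u**2)

    top = _TOP_MARGIN_FRACTION * height + curvature
    boundaries = [top]
    for name in LAYER_NAMES[1:]:  # IPL..choroid, in anatomical order
        thickness = DEFAULT_THICKNESS_FRACTIONS[name] * height
        nxt = boundaries[-1] + _boundary_curve(x, thickness, rng)
        boundaries.append(nxt)
    # boundaries[i] is the top edge of tissue layer i (1-based over LAYER_NAMES[1:]);
    # boundaries[-1] is the bottom of the choroid.

    rows = np.arange(height, dtype=float)[:, None]
    labels = np.zeros((height, width), dtype=np.int8)  # background
    for i, name in enumerate(LAYER_NAMES[1:], start=1):
        lo = boundaries[i - 1][None, :]
        hi = boundaries[i][None, :]
        labels[np.logical_and(rows >= lo, rows < hi)] = i

    clean = np.empty((height, width), dtype=float)
    for i, name in enumerate(LAYER_NAMES):
        clean[labels == i] = refl[name]

    tissue = labels > 0
    for lesion in lesions or []:
        r0, c0 = lesion.center
        ar, ac = lesion.axes
        if not (0 <= r0 < height and 0 <= c0 < width):
            raise ValueError("lesion centre outside image bounds")
        if r0 - ar < 0 or r0 + ar >= height or c0 - ac < 0 or c0 + ac >= width:
            raise ValueError("lesion extends outside image bounds")
        rr, cc = np.ogrid[:height, :width]
        inside = ((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        inside &= tissue  # lesions perturb reflectivity only inside tissue
        delta = -lesion.offset if lesion.kind == "fluid" else lesion.offset
        clean[inside] = np.clip(clean[inside] + delta, 0.0, 1.0)

    # Retinal vessel shadows: vertical attenuation bands cast downward from
    # inner-retinal vessels.  They give the scene horizontal structure (as in
    # real macular B-scans), without which horizontal registration would be
    # ill-posed on a pure layer-stripe image.
    if n_vessels > 0:
        centres = rng.uniform(0.05 * width, 0.95 * width, size=n_vessels)
        widths = rng.uniform(2.0, 4.0, size=n_vessels)
        depths = rng.uniform(0.25, 0.5, size=n_vessels)
        attenuation = np.ones(width)
        for c0, wv, dv in zip(centres, widths, depths):
            attenuation *= 1.0 - dv * np.exp(-((x - c0) ** 2) / (2.0 * wv**2))
        shadow_top = boundaries[0][None, :]  # from the inner retina downward
        shadowed = rows >= shadow_top
        clean = np.where(shadowed, clean * attenuation[None, :], clean)

    # Mild blur so layer interfaces are band-limited like real B-scans.
    clean = gaussian_filter(clean, boundary_smoothness / 2.0)
    clean = np.clip(clean, 0.0, 1.0)

    return PhantomTruth(
        clean=clean,
        layer_map=LayerMap(labels=labels),
        speckle_shape=float(speckle_shape),
        sensor_sigma=float(sensor_sigma),
        lesions=list(lesions or []),
    )


def _fixation_loss_frame(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Pure-noise frame with B-scan-like intensity statistics but no scene."""
    frame = rng.normal(0.3, 0.2, size=shape)
    return np.clip(frame, 0.0, 1.0)


def acquire_frames(
    truth: PhantomTruth,
    n_frames: int = 50,
    motion_scale: tuple[float, float] = (0.0, 0.0),
    p_fixation_loss: float = 0.0,
    seed: int = 0,
) -> FrameStack:
    """Simulate an N-frame acquisition of the phantom scene.

    Each frame is the clean scene under a per-frame rigid motion (drawn
    uniformly within ``motion_scale`` = (max |shift| px, max |rotation| deg);
    the reference frame, index 0, keeps the identity), multiplied by i.i.d.
    unit-mean Gamma speckle with concentration ``truth.speckle_shape``
    (``inf`` disables speckle), plus additive Gaussian sensor noise of
    standard deviation ``truth.sensor_sigma``, clipped to [0, 1].  With
    probability ``p_fixation_loss`` a non-reference frame is replaced by a
    decorrelated pure-noise frame.  True motions and loss indices are
    recorded on ``truth``.  Deterministic given ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if motion_scale[0] < 0 or motion_scale[1] < 0:
        raise ValueError("motion_scale components must be non-negative")
    if not 0.0 <= p_fixation_loss < 1.0:
        raise ValueError("p_fixation_loss must be in [0, 1)")

    rng = np.random.default_rng(seed)
    h, w = truth.shape
    background = float(truth.clean[truth.layer_map.mask("background")].mean())

    frames = np.empty((n_frames, h, w), dtype=float)
    motions: list[RigidTransform] = []
    losses: set[int] = set()
    max_shift, max_rot = motion_scale
    for i in range(n_frames):
        if i == 0 or (max_shift == 0 and max_rot == 0):
            motion = RigidTransform.identity()
        else:
            motion = RigidTransform(
                dx=float(rng.uniform(-max_shift, max_shift)),
                dy=float(rng.uniform(-max_shift, max_shift)),
                theta=float(rng.uniform(-max_rot, max_rot)),
            )
        motions.append(motion)

        if i != 0 and p_fixation_loss > 0 and rng.random() < p_fixation_loss:
            frames[i] = _fixation_loss_frame((h, w), rng)
            losses.add(i)
            continue

        frame = warp_image(truth.clean, motion, cval=background)
        if np.isfinite(truth.speckle_shape):
            a = truth.speckle_shape
            frame = frame * rng.gamma(a, 1.0 / a, size=(h, w))
        if truth.sensor_sigma > 0:
            frame = frame + rng.normal(0.0, truth.sensor_sigma, size=(h, w))
        if np.isfinite(truth.speckle_shape) or truth.sensor_sigma > 0:
            frame = np.clip(frame, 0.0, 1.0)
        frames[i] = frame

    truth.motions = motions
    truth.fixation_loss_frames = losses
    aligned = max_shift == 0 and max_rot == 0
    return FrameStack(frames=frames, aligned=aligned, reference_index=0)
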