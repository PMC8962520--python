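"""Reading and writing stacks, images and parameter sidecars.

Stacks travel as NPZ containers (frames, clean image, label map, true
motions) with a JSON sidecar recording all generation parameters; single
images are written as 16-bit grayscale PNG or TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .phantom import FrameStack, LayerMap, PhantomTruth
from .transform import RigidTransform


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0,1] image as 16-bit grayscale PNG or TIFF (by suffix)."""
    path = Path(path)
    data = np.round(np.clip(image, 0.0, 1.0) * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def load_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data, dtype=float)
    if data.max() > 1.0:
        data = data / (65535.0 if data.max() > 255 else 255.0)
    return data


def save_stack(
    path: str | Path,
    stack: FrameStack,
    truth: PhantomTruth | None = None,
    params: dict | None = None,
) -> None:
    """Write a stack (and optional ground truth) as NPZ + JSON sidecar."""
    path = Path(path)
    arrays = {
        "frames": stack.frames,
        "reference_index": np.array(stack.reference_index),
        "aligned": np.array(stack.aligned),
        "excluded": np.array(sorted(stack.excluded), dtype=int),
    }
    if truth is not None:
        arrays["clean"] = truth.clean
        arrays["labels"] = truth.layer_map.labels
        if truth.motions:
            arrays["motions"] = np.array([m.as_tuple() for m in truth.motions])
        arrays["fixation_loss"] = np.array(
            sorted(truth.fixation_loss_frames), dtype=int
        )
        arrays["noise"] = np.array([truth.speckle_shape, truth.sensor_sigma])
    np.savez_compressed(path, **arrays)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(params, indent=2, default=str))


def load_stack(path: str | Path) -> tuple[FrameStack, PhantomTruth | None]:
    data = np.load(Path(path))
    stack = FrameStack(
        frames=data["frames"],
        aligned=bool(data["aligned"]),
        reference_index=int(data["reference_index"]),
        excluded=set(int(i) for i in data["excluded"]),
    )
    truth = None
    if "clean" in data:
        truth = PhantomTruth(
            clean=data["clean"],
            layer_map=LayerMap(labels=data["labels"]),
            speckle_shape=float(data["noise"][0]),
            sensor_sigma=float(data["noise"][1]),
        )
        if "motions" in data:
            truth.motions = [RigidTransform(*row) for row in data["motions"]]
        truth.fixation_loss_frames = set(int(i) for i in data["fixation_loss"])
    return stack, truth
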