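"""Desk-scale replication experiments: frame-count sweep and head-to-head.

The sweep reproduces the qualitative relationship between frame count and
image quality for frame averaging (Avg-k) and the learned enhancer (DL-k):
SSIM/PSNR against the ground truth rise with k, steepest at small k, and the
learned method dominates averaging at equal k.  The head-to-head runs a
paired comparison at one k over replicate phantoms, with paired t-tests.

On phantoms the comparison target is the true clean scene (which a clinical
study cannot observe and must approximate by Avg-50); a switch allows an
Avg-50-style pseudo gold standard instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import metrics, net
from .phantom import FrameStack, PhantomTruth, acquire_frames, make_phantom
from .registration import RegistrationConfig, average_frames, register_stack


@dataclass(frozen=True)
class SweepConfig:
    """Study conditions for the sweep / head-to-head experiments."""

    height: int = 128
    width: int = 256
    n_frames: int = 25
    motion_scale: tuple[float, float] = (0.0, 0.0)
    p_fixation_loss: float = 0.0
    speckle_shape: float | None = None  # None -> phantom default
    sensor_sigma: float | None = None
    n_train: int = 100
    train_epochs: int = 12
    base_channels: int = 8
    batch_size: int = 4
    augmentation_draws: int = 1
    gold_standard: str = "clean"  # "clean" | "avg-all"
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)


@dataclass
class SweepResult:
    method: str  # "averaging" | "deep-learning"
    k: int
    mean_ssim: float
    sd_ssim: float
    mean_psnr: float
    sd_psnr: float
    n_replicates: int


def _make_stacks(n: int, cfg: SweepConfig, seed0: int,
                 n_frames: int | None = None):
    noise = {}
    if cfg.speckle_shape is not None:
        noise["speckle_shape"] = cfg.speckle_shape
    if cfg.sensor_sigma is not None:
        noise["sensor_sigma"] = cfg.sensor_sigma
    out = []
    for i in range(n):
        truth = make_phantom(cfg.height, cfg.width, seed=seed0 + i, **noise)
        stack = acquire_frames(
            truth, n_frames or cfg.n_frames, cfg.motion_scale,
            cfg.p_fixation_loss, seed=seed0 + 10_000 + i,
        )
        out.append((stack, truth))
    return out


def _gold(stack: FrameStack, truth: PhantomTruth, cfg: SweepConfig) -> np.ndarray:
    if cfg.gold_standard == "clean":
        return truth.clean
    return stack.frames[stack.surviving_indices()].mean(axis=0)


def _aligned(stack: FrameStack, cfg: SweepConfig) -> FrameStack:
    # register_stack short-circuits the MI step for stacks flagged aligned
    # but still applies reference selection and the fixation-exclusion rule.
    aligned, _ = register_stack(stack, cfg.registration)
    return aligned


def train_model_for_k(k: int, cfg: SweepConfig, seed: int) -> net.TrainedModel:
    """Train one enhancement model for frame count k on a disjoint split."""
    train_set = []
    for stack, truth in _make_stacks(cfg.n_train, cfg, seed0=seed + 50_000):
        aligned = _aligned(stack, cfg)
        train_set.append((aligned, _gold(aligned, truth, cfg)))
    model = net.build_network(
        net.NetConfig(n_input_frames=k, base_channels=cfg.base_channels, seed=seed)
    )
    tc = net.TrainConfig(
        max_epochs=cfg.train_epochs, batch_size=cfg.batch_size,
        augmentation_draws=cfg.augmentation_draws, seed=seed + 1,
    )
    return net.train(model, train_set, tc)


def run_sweep(
    k_values: list[int],
    n_phantoms: int,
    methods: tuple[str, ...] = ("averaging", "deep-learning"),
    config: SweepConfig | None = None,
    seed: int = 0,
    models: dict[int, net.TrainedModel] | None = None,
) -> list[SweepResult]:
    """SSIM/PSNR versus frame count over replicate phantoms.

    Generates ``n_phantoms`` test stacks; for each method and each k the
    enhanced image is scored against the gold standard.  Deep-learning
    models are trained once per k on a disjoint training split (or passed in
    via ``models``).  Deterministic given ``seed``.
    """
    config = config or SweepConfig()
    if any(k < 1 or k > 20 for k in k_values):
        raise ValueError("k values must lie in [1, 20]")
    if n_phantoms < 2:
        raise ValueError("need at least 2 phantoms")
    if max(k_values) > config.n_frames:
        raise ValueError("k exceeds the number of acquired frames")
    for m in methods:
        if m not in ("averaging", "deep-learning"):
            raise ValueError(f"unknown method {m!r}")

    test = _make_stacks(n_phantoms, config, seed0=seed)
    aligned_test = [(_aligned(s, config), t) for s, t in test]

    if "deep-learning" in methods:
        models = dict(models or {})
        for k in k_values:
            if k not in models:
                models[k] = train_model_for_k(k, config, seed)

    results: list[SweepResult] = []
    for method in methods:
        for k in k_values:
            ssims, psnrs = [], []
            for aligned, truth in aligned_test:
                gold = _gold(aligned, truth, config)
                if method == "averaging":
                    out = average_frames(aligned, aligned.surviving_indices()[:k])
                else:
                    out = net.enhance(models[k], aligned)
                ssims.append(metrics.ssim(out, gold))
                psnrs.append(metrics.psnr(out, gold))
            results.append(SweepResult(
                method=method, k=k,
                mean_ssim=float(np.mean(ssims)), sd_ssim=float(np.std(ssims)),
                mean_psnr=float(np.mean(psnrs)), sd_psnr=float(np.std(psnrs)),
                n_replicates=n_phantoms,
            ))
    return results


def head_to_head(
    k: int,
    n_phantoms: int,
    config: SweepConfig | None = None,
    seed: int = 0,
    model: net.TrainedModel | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Paired DL-k vs Avg-k comparison over replicate phantoms.

    Per phantom: SSIM, PSNR and the six-pair CNRs for both methods, paired
    differences, and paired t-test p-values (marked not-applicable when the
    pairing is degenerate or n < 2).  Optionally writes CSV + JSON.
    """
    config = config or SweepConfig()
    if model is None:
        model = train_model_for_k(k, config, seed)

    rows = []
    for i, (stack, truth) in enumerate(_make_stacks(n_phantoms, config, seed0=seed)):
        aligned = _aligned(stack, config)
        gold = _gold(aligned, truth, config)
        avg = average_frames(aligned, aligned.surviving_indices()[:k])
        dl = net.enhance(model, aligned)
        single = aligned.frames[aligned.surviving_indices()[0]]
        row = {
            "phantom": i,
            "ssim_avg": metrics.ssim(avg, gold),
            "ssim_dl": metrics.ssim(dl, gold),
            "psnr_avg": metrics.psnr(avg, gold),
            "psnr_dl": metrics.psnr(dl, gold),
        }
        for name in metrics.CNR_PAIRS:
            pair = metrics.auto_rois(truth.layer_map, name, seed=seed)
            row[f"cnr_single[{name}]"] = metrics.cnr(single, pair).cnr
            row[f"cnr_avg[{name}]"] = metrics.cnr(avg, pair).cnr
            row[f"cnr_dl[{name}]"] = metrics.cnr(dl, pair).cnr
        rows.append(row)
    table = pd.DataFrame(rows)

    def paired(metric: str) -> dict:
        d = table[f"{metric}_dl"] - table[f"{metric}_avg"]
        entry = {
            "mean_diff": float(d.mean()),
            "sd_diff": float(d.std(ddof=1)) if len(d) > 1 else float("nan"),
            "positive_fraction": float((d > 0).mean()),
        }
        if len(d) < 2 or np.allclose(d, d.iloc[0]):
            entry["p_value"] = None
            entry["t_test"] = "not-applicable"
        else:
            t, p = stats.ttest_rel(table[f"{metric}_dl"], table[f"{metric}_avg"])
            entry["p_value"] = float(p)
            entry["t_test"] = "paired"
        return entry

    report = {
        "k": k,
        "n_phantoms": n_phantoms,
        "ssim": paired("ssim"),
        "psnr": paired("psnr"),
        "mean": {c: float(table[c].mean()) for c in table.columns if c != "phantom"},
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / f"head_to_head_k{k}.csv", index=False)
        (out_dir / f"head_to_head_k{k}.json").write_text(
            json.dumps(report, indent=2)
        )
    report["table"] = table
    return report


def sweep_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])
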