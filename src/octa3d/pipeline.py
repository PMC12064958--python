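"""End-to-end experiment pipelines.

Glue that mirrors how the method is actually run: phantom volumes with
repeated acquisitions stand in for OCTA scans, registration + averaging
builds the labels, superposition with avascular noise slices builds the
inputs, the adversarial model is trained, and held-out volumes are
enhanced depth-by-depth and scored with the vascular metrics.

Scaled-down study conditions used throughout desk-scale experiments:
64×64 en face images, generator with 6 levels / 16 base channels (cap
64), discriminator with 3 middle blocks, 50 vascular training pairs plus
5 noise-only and 5 black pairs, 30 epochs, batch 1, Adam lr 1e-3,
lambda = 1e3.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import __version__
from .enhance import enhance_volume
from .exceptions import ValidationError
from .gan import (
    DiscriminatorSpec,
    GeneratorSpec,
    LossRecord,
    TrainConfig,
    UNetGenerator,
    save_loss_csv,
    train,
)
from .metrics import cross_sectional_cnr, evaluate_image
from .phantom import (
    DriftParams,
    PhantomConfig,
    avascular_cscan,
    generate_clean_volume,
    simulate_repeat_acquisitions,
)
from .projection import average_registered, depth_encoded_mip, mip, register_enface
from .synthesis import SynthesisWeights, build_training_set, synthesize_input
from .volume_io import write_image, write_volume

__all__ = [
    "PhantomSample",
    "scaled_generator_spec",
    "scaled_discriminator_spec",
    "scaled_train_config",
    "make_phantom_dataset",
    "run_training_experiment",
    "run_weight_grid",
    "run_end_to_end_demo",
]


def scaled_generator_spec(size: int = 64) -> GeneratorSpec:
    """Generator sized for desk-scale experiments: enough stride-2 levels
    to reach a 1×1 bottleneck at the given (power-of-two) image size."""
    n_levels = max(2, int(np.log2(size)))
    return GeneratorSpec(n_levels=n_levels, base_channels=16, max_channels=64)


def scaled_discriminator_spec(size: int = 64) -> DiscriminatorSpec:
    """Discriminator sized so the stated stack reduces ``size`` → 1×1
    (entry conv + n blocks at 4×4/s2/p1, then the 4×4/s2/p0 head)."""
    n_blocks = max(1, int(np.log2(size)) - 3)
    return DiscriminatorSpec(base_channels=16, n_blocks=n_blocks, max_channels=64)


def scaled_train_config(seed: int = 0, epochs: int = 30) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed)


@dataclass(frozen=True)
class PhantomSample:
    """One phantom 'acquisition set': single-shot en face image, averaged
    label, noise-free ground-truth en face image, and the clean volume's
    vessel-free depth band for B-scan CNR."""

    enface: np.ndarray
    label: np.ndarray
    clean_enface: np.ndarray
    volume: np.ndarray | None = None
    background_band: tuple[int, int] = (0, 4)


def _sample_config(base: PhantomConfig, size: int, depth: int, seed: int) -> PhantomConfig:
    return replace(base, shape=(depth, size, size), seed=seed)


def make_phantom_dataset(
    n_volumes: int,
    size: int = 64,
    depth: int = 32,
    n_repeats: int = 10,
    seed: int = 0,
    base_config: PhantomConfig | None = None,
    n_noise_images: int = 8,
    keep_volumes: bool = False,
) -> tuple[list[PhantomSample], list[np.ndarray]]:
    """Generate phantom acquisition sets and an avascular noise pool.

    Repeats here are drift-free and averaged directly; the drifting
    repeats + SIFT registration path is exercised by
    :func:`run_end_to_end_demo` and its own tests. Deterministic in
    ``seed``.
    """
    if n_volumes < 1:
        raise ValidationError("n_volumes must be >= 1")
    base = base_config or PhantomConfig()
    root = np.random.SeedSequence(seed)
    samples: list[PhantomSample] = []
    for v in range(n_volumes):
        sub = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(v,)))
        cfg = _sample_config(base, size, depth, seed=int(sub.integers(2**31)))
        clean, _ = generate_clean_volume(cfg)
        drift = DriftParams(max_shift=0.0, max_rotation=0.0, seed=int(sub.integers(2**31)))
        repeats = simulate_repeat_acquisitions(clean, n_repeats, drift, cfg)
        enfaces = [mip(r.volume) for r in repeats]
        samples.append(PhantomSample(
            enface=enfaces[0],
            label=np.clip(np.mean(enfaces, axis=0), 0.0, 1.0),
            clean_enface=mip(clean),
            volume=repeats[0].volume if keep_volumes else None,
            background_band=(0, max(2, int(0.1 * depth))),
        ))
    noise_rng = np.random.default_rng(root.spawn(1)[0])
    noise_cfg = _sample_config(base, size, depth, seed=0)
    noise_pool = [avascular_cscan(noise_cfg, seed=int(noise_rng.integers(2**31)))
                  for _ in range(n_noise_images)]
    return samples, noise_pool


@dataclass(frozen=True)
class ExperimentResult:
    """Outcome of one scaled training experiment."""

    records: list[LossRecord]
    input_metrics: list[dict]
    enhanced_metrics: list[dict]
    l1_input: float
    l1_enhanced: float
    generator: UNetGenerator

    @property
    def content_first5(self) -> float:
        return float(np.mean([r.content_loss for r in self.records[:5]]))

    @property
    def content_last5(self) -> float:
        return float(np.mean([r.content_loss for r in self.records[-5:]]))

    def mean(self, which: str, key: str) -> float:
        rows = self.input_metrics if which == "input" else self.enhanced_metrics
        return float(np.mean([r[key] for r in rows]))


def run_training_experiment(
    seed: int = 0,
    n_train: int = 50,
    n_test: int = 10,
    size: int = 64,
    depth: int = 32,
    epochs: int = 30,
    weights: SynthesisWeights | None = None,
    n_noise_only: int = 5,
    n_black: int = 5,
    base_config: PhantomConfig | None = None,
) -> ExperimentResult:
    """Train the scaled model on phantom pairs and score held-out images.

    Builds ``n_train`` vascular pairs (plus noise-only and black pairs),
    trains for ``epochs``, then for each held-out sample compares the
    synthetic degraded input against its enhanced version: CNR and VC via
    the metric chain, and L1 distance to the noise-free ground truth.
    """
    w = weights or SynthesisWeights()
    samples, noise_pool = make_phantom_dataset(
        n_train + n_test, size=size, depth=depth, seed=seed, base_config=base_config)
    train_samples, test_samples = samples[:n_train], samples[n_train:]
    dataset = build_training_set(
        [(s.enface, s.label) for s in train_samples], noise_pool, w,
        n_noise_only=n_noise_only, n_black=n_black, seed=seed,
    )
    config = scaled_train_config(seed=seed, epochs=epochs)
    generator, records = train(
        dataset, config,
        gen_spec=scaled_generator_spec(size),
        disc_spec=scaled_discriminator_spec(size),
        dtype=np.float32,
    )
    test_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(987,)))
    input_metrics, enhanced_metrics = [], []
    l1_in, l1_enh = [], []
    for s in test_samples:
        noise = noise_pool[int(test_rng.integers(len(noise_pool)))]
        x = synthesize_input(s.enface, noise, w)
        y = np.clip(np.asarray(generator.forward(x, train=False), dtype=np.float64), 0.0, 1.0)
        input_metrics.append(evaluate_image(x).as_dict())
        enhanced_metrics.append(evaluate_image(y).as_dict())
        l1_in.append(float(np.mean(np.abs(x - s.clean_enface))))
        l1_enh.append(float(np.mean(np.abs(y - s.clean_enface))))
    return ExperimentResult(
        records=records,
        input_metrics=input_metrics,
        enhanced_metrics=enhanced_metrics,
        l1_input=float(np.mean(l1_in)),
        l1_enhanced=float(np.mean(l1_enh)),
        generator=generator,
    )


def run_weight_grid(
    grid: list[tuple[float, float]] | None = None,
    seed: int = 0,
    out_csv: str | Path | None = None,
    **experiment_kwargs,
) -> list[dict]:
    """Train one scaled model per (alpha, beta) setting and tabulate the
    held-out metrics; default grid includes the published (0.25, 0.75)."""
    grid = grid or [(0.75, 0.25), (0.5, 0.5), (0.25, 0.75), (0.1, 0.9)]
    if not grid:
        raise ValidationError("grid must be nonempty")
    rows: list[dict] = []
    for alpha, beta in grid:
        res = run_training_experiment(
            seed=seed, weights=SynthesisWeights(alpha, beta), **experiment_kwargs)
        rows.append({
            "alpha": alpha,
            "beta": beta,
            "cnr": res.mean("enhanced", "cnr"),
            "vd": res.mean("enhanced", "vd"),
            "vdi": res.mean("enhanced", "vdi"),
            "vc": res.mean("enhanced", "vc"),
            "l1_to_truth": res.l1_enhanced,
            "final_content_loss": res.records[-1].content_loss,
        })
    if out_csv is not None:
        out_csv = Path(out_csv)
        out_csv.parent.mkdir(parents=True, exist_ok=True)
        keys = list(rows[0].keys())
        lines = [",".join(keys)]
        lines += [",".join(repr(row[k]) for k in keys) for row in rows]
        out_csv.write_text("\n".join(lines) + "\n")
    return rows


def _manifest_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_end_to_end_demo(
    seed: int = 0,
    out_dir: str | Path = "demo_out",
    n_train: int = 12,
    n_test: int = 2,
    size: int = 64,
    depth: int = 32,
    n_repeats: int = 10,
    epochs: int = 10,
    drift: DriftParams | None = None,
    base_config: PhantomConfig | None = None,
    register: bool = True,
) -> dict:
    """The whole workflow under one seed, writing artifacts + manifest.

    phantom volumes → drifting repeats → SIFT registration + averaging
    labels (for the first training volume; remaining labels use drift-free
    averaging to keep the demo fast) → input synthesis → scaled training →
    depth-by-depth enhancement of a held-out volume → MIP, depth-encoded
    MIP and a metrics report. Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    base = base_config or PhantomConfig()
    w = SynthesisWeights()
    stage = "phantom"
    try:
        samples, noise_pool = make_phantom_dataset(
            n_train + n_test, size=size, depth=depth, n_repeats=n_repeats,
            seed=seed, base_config=base, keep_volumes=True)
        registration_info = {"used": False}
        if register:
            # the registration showcase runs at >= 128 px: SIFT needs
            # feature-rich images, independent of the training scale
            stage = "registration"
            cfg = _sample_config(base, max(size, 128), depth, seed=seed)
            clean, _ = generate_clean_volume(cfg)
            drift = drift or DriftParams(max_shift=3.0, max_rotation=1.5, seed=seed + 1)
            repeats = simulate_repeat_acquisitions(clean, n_repeats, drift, cfg)
            enfaces = [mip(r.volume) for r in repeats]
            reg = register_enface(enfaces, reference_index=0)
            registered_label = average_registered(reg)
            registration_info = {
                "used": True,
                "crop_box": list(reg.crop_box),
                "n_repeats": n_repeats,
            }
            write_image(registered_label, out / "registered_label.png")
        stage = "synthesis"
        dataset = build_training_set(
            [(s.enface, s.label) for s in samples[:n_train]], noise_pool, w,
            n_noise_only=3, n_black=3, seed=seed)
        stage = "training"
        run_dir = out / "train"
        run_dir.mkdir(exist_ok=True)
        config = TrainConfig(epochs=epochs, seed=seed)
        generator, records = train(
            dataset, config,
            gen_spec=scaled_generator_spec(size),
            disc_spec=scaled_discriminator_spec(size),
            dtype=np.float32,
            checkpoint_dir=run_dir,
        )
        save_loss_csv(records, run_dir / "losses.csv")
        stage = "enhancement"
        held_out = samples[n_train]
        test_volume = held_out.volume
        enhanced = enhance_volume(test_volume, generator)
        write_volume(test_volume, out / "input_volume.tiff")
        write_volume(enhanced, out / "enhanced_volume.tiff")
        stage = "projection"
        write_image(mip(test_volume), out / "input_mip.png")
        write_image(mip(enhanced), out / "enhanced_mip.png")
        write_image(np.clip(depth_encoded_mip(enhanced), 0, 1), out / "enhanced_depth_mip.png")
        stage = "evaluation"
        band = held_out.background_band
        cnr_in = cross_sectional_cnr(test_volume, band)
        cnr_enh = cross_sectional_cnr(enhanced, band)
        metrics = {
            "input_mip": evaluate_image(mip(test_volume)).as_dict(),
            "enhanced_mip": evaluate_image(mip(enhanced)).as_dict(),
            "mean_bscan_cnr_input": float(np.mean(cnr_in)),
            "mean_bscan_cnr_enhanced": float(np.mean(cnr_enh)),
        }
    except Exception as exc:
        raise RuntimeError(f"demo failed at stage '{stage}': {exc}") from exc
    settings = {
        "seed": seed, "n_train": n_train, "n_test": n_test, "size": size,
        "depth": depth, "n_repeats": n_repeats, "epochs": epochs,
        "weights": dataclasses.asdict(w),
        "phantom": dataclasses.asdict(base),
    }
    manifest = {
        "package_version": __version__,
        "settings": settings,
        "config_hash": _manifest_hash(settings),
        "registration": registration_info,
        "metrics": metrics,
        "final_losses": dataclasses.asdict(records[-1]),
        "runtime_s": round(time.perf_counter() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
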