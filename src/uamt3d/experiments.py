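"""Canned desk-scale experiments on synthetic phantoms.

These are the study conditions used by the test suite and the acceptance
script: a small semi-supervised benchmark (few labeled cases, many unlabeled
degraded cases, 3 seeds) comparing consistency training against the
supervised-only ablation, and a fully supervised sanity run.  Problem sizes
are chosen for a single CPU with the pure-numpy backend: 20 cases of
32x32x12 voxels, a 3-level U-Net with 4 base channels, 15 epochs at lr 0.01.
The learning rate is raised above the clinical-scale default because the
scaled runs have ~200 optimisation steps rather than tens of thousands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .backbone import NetworkSpec
from .io_inference import normalize_intensity
from .objectives import LossConfig
from .phantoms import PhantomSpec, generate_case
from .seg_metrics import dsc
from .trainer import Dataset, TrainerConfig, train

__all__ = ["BenchmarkSettings", "ssl_benchmark", "supervised_sanity"]

#: seeds of the three benchmark replicates
BENCHMARK_SEEDS = (11, 12, 13)


@dataclass(frozen=True)
class BenchmarkSettings:
    volume_shape: tuple = (32, 32, 12)
    n_cases: int = 20
    labeled_fraction: float = 0.10
    test_fraction: float = 0.20
    epochs: int = 15
    lr: float = 0.01
    lambda_max: float = 0.1
    rampup_length: int = 100
    network: NetworkSpec = field(default_factory=lambda: NetworkSpec(
        levels=3, base_channels=4, sam_kernel=3))


def _build_dataset(settings: BenchmarkSettings, seed: int,
                   labeled_fraction: float | None = None,
                   test_fraction: float | None = None) -> Dataset:
    spec = PhantomSpec(
        volume_shape=settings.volume_shape, n_cases=settings.n_cases,
        labeled_fraction=labeled_fraction if labeled_fraction is not None
        else settings.labeled_fraction,
        test_fraction=test_fraction if test_fraction is not None
        else settings.test_fraction,
        seed=seed)
    cases = [generate_case(spec, i) for i in range(spec.n_cases)]
    return Dataset.from_cases(cases, spec)


def _mean_dsc(network, records) -> float:
    scores = []
    for rec in records:
        probs = network.predict_proba(normalize_intensity(rec["degraded"])[None])
        scores.append(dsc(probs.argmax(axis=0) > 0, rec["mask"] > 0))
    return float(np.mean(scores))


def _run_arm(settings: BenchmarkSettings, dataset: Dataset, seed: int,
             lambda_max: float):
    cfg = TrainerConfig(epochs=settings.epochs, lr=settings.lr, seed=seed)
    loss_cfg = LossConfig(lambda_max=lambda_max,
                          rampup_length=settings.rampup_length)
    return train(dataset, settings.network, cfg, loss_cfg)


def ssl_benchmark(seeds=BENCHMARK_SEEDS,
                  settings: BenchmarkSettings | None = None) -> dict:
    """Consistency training (lambda>0) vs supervised-only (lambda=0), each on
    the same 10%-labeled phantom sets, replicated over ``seeds``.

    Returns per-seed test DSC (teacher and student networks) for both arms
    and the across-seed medians.
    """
    settings = settings or BenchmarkSettings()
    out = {"seeds": list(seeds), "supervised_only": [], "consistency": []}
    for seed in seeds:
        dataset = _build_dataset(settings, seed)
        for arm, lam in (("supervised_only", 0.0),
                         ("consistency", settings.lambda_max)):
            student, teacher, _ = _run_arm(settings, dataset, seed, lam)
            out[arm].append({"seed": seed,
                             "teacher_dsc": _mean_dsc(teacher, dataset.test),
                             "student_dsc": _mean_dsc(student, dataset.test)})
    for arm in ("supervised_only", "consistency"):
        out[f"{arm}_median_teacher_dsc"] = float(
            np.median([r["teacher_dsc"] for r in out[arm]]))
        out[f"{arm}_median_student_dsc"] = float(
            np.median([r["student_dsc"] for r in out[arm]]))
    return out


def supervised_sanity(seed: int = 11, n_cases: int = 8, epochs: int = 60,
                      settings: BenchmarkSettings | None = None) -> dict:
    """Fully supervised mode (100% labels, lambda=0); returns train-set DSC."""
    settings = settings or BenchmarkSettings(epochs=epochs)
    spec = PhantomSpec(volume_shape=settings.volume_shape, n_cases=n_cases,
                       labeled_fraction=1.0, test_fraction=0.0, seed=seed)
    cases = [generate_case(spec, i) for i in range(n_cases)]
    dataset = Dataset.from_cases(cases, spec)
    cfg = TrainerConfig(epochs=epochs, lr=settings.lr, seed=seed)
    student, teacher, _ = train(dataset, settings.network, cfg,
                                LossConfig(lambda_max=0.0))
    return {"train_dsc_student": _mean_dsc(student, dataset.labeled),
            "train_dsc_teacher": _mean_dsc(teacher, dataset.labeled),
            "n_cases": n_cases, "epochs": epochs}
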