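"""Mean-teacher training loop.

Per step: one labeled and one unlabeled case are drawn (batch of 2); both
student inputs receive independent Gaussian noise; the student is updated by
SGD on Dice+CE plus the uncertainty-gated consistency loss against the
teacher's Monte-Carlo mean prediction; the teacher then receives an
exponential-moving-average update z' <- eps z' + (1-eps) z (never gradients).

Labeled batches draw the clean (CT-like) or degraded (CBCT-like) rendering of
the case at the configured 5:3 ratio; unlabeled batches always use the
degraded rendering, which is the modality the model must segment at test
time.  An epoch is one pass over the unlabeled pool (or the labeled pool in
purely supervised mode).
"""

from __future__ import annotations

import csv
import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .backbone import NetworkSpec, UNet3D, build_network
from .errors import ConfigurationError, TrainingDivergedError
from .io_inference import center_crop, load_volume, normalize_intensity
from .objectives import (LossConfig, consistency_loss, joint_loss,
                         lambda_schedule, supervised_loss, threshold_schedule)
from .phantoms import CLEAN_TO_DEGRADED_RATIO
from .uncertainty import NoiseSpec, mc_forward, uncertainty_map
from . import autograd as ag

__all__ = ["TrainerConfig", "TrainerState", "SGD", "ema_update", "make_batch",
           "Dataset", "train", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class TrainerConfig:
    epochs: int = 15
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    poly_decay: bool = False
    ema_decay: float = 0.99
    n_mc_passes: int = 8
    noise_sigma: float = 0.1
    noise_clip: float = 0.2
    sub_volume: tuple | None = None   # None: full volume
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1 or self.lr <= 0:
            raise ConfigurationError("epochs and lr must be positive")
        if not 0.0 <= self.ema_decay <= 1.0:
            raise ConfigurationError("ema_decay must lie in [0,1]")
        if self.n_mc_passes < 1:
            raise ConfigurationError("n_mc_passes must be >= 1")


@dataclass
class TrainerState:
    step: int = 0
    epoch: int = 0
    ema_decay: float = 0.99


class SGD:
    """Plain SGD with momentum and decoupled-from-nothing L2 weight decay."""

    def __init__(self, params: dict, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self.momentum * self.velocity[k] - lr * g
            self.velocity[k] = v
            p.data = p.data + v

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def ema_update(teacher_params: dict, student_params: dict, decay: float) -> None:
    """teacher <- decay * teacher + (1 - decay) * student, parameterwise."""
    if set(teacher_params) != set(student_params):
        raise ConfigurationError("teacher/student parameter sets are incongruent")
    for k, t in teacher_params.items():
        s = student_params[k]
        if t.data.shape != s.data.shape:
            raise ConfigurationError(f"parameter {k} shapes differ")
        t.data = decay * t.data + (1.0 - decay) * s.data


# -- data ------------------------------------------------------------------

@dataclass
class Dataset:
    labeled: list = field(default_factory=list)    # {clean, degraded, mask, case_id}
    unlabeled: list = field(default_factory=list)  # {degraded, case_id}
    test: list = field(default_factory=list)
    spacing: tuple = (1.0, 1.0, 1.0)

    @classmethod
    def from_cases(cls, cases, spec) -> "Dataset":
        """Build an in-memory dataset from generated PhantomCases using the
        same labeled/split assignment as ``generate_dataset``."""
        from .phantoms import split_assignment

        ds = cls(spacing=tuple(spec.spacing))
        for case, (labeled, split) in zip(cases, split_assignment(spec)):
            rec = {"case_id": case.case_id, "clean": case.clean_volume,
                   "degraded": case.degraded_volume, "mask": case.mask}
            if split == "test":
                ds.test.append(rec)
            elif labeled:
                ds.labeled.append(rec)
            else:
                ds.unlabeled.append(rec)
        return ds

    @classmethod
    def from_manifest(cls, manifest: dict, data_dir) -> "Dataset":
        data_dir = Path(data_dir)
        ds = cls(spacing=tuple(manifest["spec"]["spacing"]))
        for entry in manifest["cases"]:
            rec = {"case_id": entry["case_id"]}
            for kind, fname in entry["paths"].items():
                rec[kind], _, _ = load_volume(data_dir / fname)
            if entry["split"] == "test":
                ds.test.append(rec)
            elif entry["labeled"]:
                ds.labeled.append(rec)
            else:
                ds.unlabeled.append(rec)
        return ds


def make_batch(dataset: Dataset, rng: np.random.Generator,
               sub_volume=None, clean_ratio=CLEAN_TO_DEGRADED_RATIO):
    """One (labeled, unlabeled) pair for a training step.

    Returns ``(x_l, y_l, x_u)`` with volumes normalised and center-cropped;
    ``x_u`` is None when the unlabeled pool is empty (supervised mode).  The
    labeled rendering is clean with probability 5/8 (the configured
    clean:degraded ratio in expectation).
    """
    if not dataset.labeled:
        raise ConfigurationError("labeled pool is empty")
    rec = dataset.labeled[rng.integers(len(dataset.labeled))]
    p_clean = clean_ratio[0] / (clean_ratio[0] + clean_ratio[1])
    kind = "clean" if rng.random() < p_clean else "degraded"

    def prep(vol):
        vol = normalize_intensity(vol, "zscore")
        if sub_volume is not None:
            vol, _ = center_crop(vol, sub_volume, fill=float(vol.min()))
        return vol

    x_l = prep(rec[kind])
    y_l = rec["mask"]
    if sub_volume is not None:
        y_l, _ = center_crop(y_l, sub_volume, fill=0)
    y_l = (np.asarray(y_l) > 0).astype(np.int64)
    x_u = None
    if dataset.unlabeled:
        urec = dataset.unlabeled[rng.integers(len(dataset.unlabeled))]
        x_u = prep(urec["degraded"])
    return x_l, y_l, x_u


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(path, student: UNet3D, teacher: UNet3D,
                    state: TrainerState) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for prefix, net in (("student", student), ("teacher", teacher)):
        for k, v in net.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    meta = json.dumps({"network_spec": student.spec.to_dict(),
                       "state": asdict(state)})
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("arrays.npz", buf.getvalue())
        zf.writestr("meta.json", meta)


def load_checkpoint(path):
    """Returns (student, teacher, NetworkSpec, TrainerState)."""
    path = Path(path)
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        with zf.open("arrays.npz") as fh:
            arrays = dict(np.load(io.BytesIO(fh.read())))
    spec = NetworkSpec.from_dict(meta["network_spec"])
    state = TrainerState(**meta["state"])
    student = build_network(spec)
    teacher = build_network(spec)
    student.load_state_dict({k.split("/", 1)[1]: v for k, v in arrays.items()
                             if k.startswith("student/")})
    teacher.load_state_dict({k.split("/", 1)[1]: v for k, v in arrays.items()
                             if k.startswith("teacher/")})
    return student, teacher, spec, state


# -- training loop ------------------------------------------------------------

def _rng_streams(seed: int) -> dict:
    names = ("batch", "noise_student", "noise_teacher", "dropout_student",
             "dropout_teacher")
    return {name: np.random.default_rng([int(seed) % (2 ** 31), i])
            for i, name in enumerate(names)}


def train(dataset: Dataset, net_spec: NetworkSpec, cfg: TrainerConfig,
          loss_cfg: LossConfig, out_dir=None, *, use_dropout: bool = True,
          use_noise: bool = True, log_rows: list | None = None):
    """Run the full loop; returns (student, teacher, state).

    ``use_dropout=False`` together with ``use_noise=False`` and
    ``lambda_max=0`` reduces the loop to deterministic supervised training.
    Writes ``checkpoint.zip`` and ``log.csv`` into ``out_dir`` when given.
    """
    cfg.validate()
    loss_cfg.validate()
    rngs = _rng_streams(cfg.seed)
    student = build_network(net_spec, seed=cfg.seed)
    teacher = build_network(net_spec, seed=cfg.seed)
    teacher.load_state_dict(student.state_dict())  # copy initialisation
    opt = SGD(student.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    noise = NoiseSpec(cfg.noise_sigma if use_noise else 0.0, cfg.noise_clip)

    use_ssl = loss_cfg.lambda_max > 0 and len(dataset.unlabeled) > 0
    # an epoch is one pass over the unlabeled pool whenever one exists, so
    # consistency and supervised-only arms see the same optimisation budget
    steps_per_epoch = max(len(dataset.unlabeled) or len(dataset.labeled), 1)
    total_steps = cfg.epochs * steps_per_epoch
    state = TrainerState(step=0, epoch=0, ema_decay=cfg.ema_decay)
    rows = log_rows if log_rows is not None else []
    teacher_params = teacher.parameters()
    student_params = student.parameters()

    for epoch in range(cfg.epochs):
        state.epoch = epoch
        for _ in range(steps_per_epoch):
            x_l, y_l, x_u = make_batch(dataset, rngs["batch"],
                                       sub_volume=cfg.sub_volume)
            x_l = noise.apply(x_l[None].astype(np.float32), rngs["noise_student"])
            logits_l = student.forward(x_l, training=use_dropout,
                                       rng=rngs["dropout_student"])
            sup = supervised_loss(logits_l, y_l, smooth=loss_cfg.smooth)

            con = None
            lam = lambda_schedule(state.step, loss_cfg)
            if use_ssl and x_u is not None and lam > 0:
                x_us = noise.apply(x_u[None].astype(np.float32),
                                   rngs["noise_student"])
                logits_u = student.forward(x_us, training=use_dropout,
                                           rng=rngs["dropout_student"])
                f_student = ag.softmax(logits_u, axis=0)
                stack = mc_forward(teacher, x_u, n_passes=cfg.n_mc_passes,
                                   noise=noise, rng=rngs["noise_teacher"],
                                   stochastic=use_dropout)
                umap = uncertainty_map(stack)
                thr = threshold_schedule(state.step, loss_cfg.rampup_length,
                                         net_spec.num_classes)
                con = consistency_loss(f_student, umap.mean_prob,
                                       umap.entropy, thr)
            total = sup if con is None else joint_loss(sup, con, state.step, loss_cfg)
            if not np.isfinite(total.item()):
                raise TrainingDivergedError(state.step)

            opt.zero_grad()
            total.backward()
            lr = cfg.lr * (1.0 - state.step / total_steps) ** 0.9 if cfg.poly_decay else cfg.lr
            opt.step(lr=lr)
            ema_update(teacher_params, student_params, cfg.ema_decay)
            rows.append({"step": state.step, "epoch": epoch, "lr": lr,
                         "lambda": lam, "sup": float(sup.item()),
                         "con": 0.0 if con is None else float(con.item()),
                         "total": float(total.item())})
            state.step += 1

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "checkpoint.zip", student, teacher, state)
        with open(out_dir / "log.csv", "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            w.writeheader()
            w.writerows(rows)
    return student, teacher, state
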