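"""Losses and the three-phase training schedule.

Phase 1 trains view classification (cross-entropy) and segmentation
(cross-entropy + Dice); phase 2 trains the GLS/LVEF/GWE regressions (mean
squared error); phase 3 trains Gensini regression and CAD classification
while the encoder and all phase-1/2 heads are frozen exactly (parameters
excluded from the optimizer and their normalisation layers held in
evaluation mode, so neither weights nor running statistics move).

Each phase re-warms a cosine-annealed learning rate (linear warmup over the
first 5% of the phase) and steps the optimizer after every
``grad_accum`` accumulated micro-batches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2_contingency

from .network import GENSINI_SCALE, IECadNetwork, PERCENT_SCALE
from .nn import Adam, Tensor, WarmupCosine
from .preprocess import VIEWS
from .synthetic import SubjectRecord

__all__ = ["TrainConfig", "PhaseState", "TrainingSample", "task_losses",
           "dice_loss", "cross_entropy", "make_training_samples", "run_phase",
           "train_model", "split_cohort", "PHASE_TASKS"]

PHASE_TASKS = {1: ("view", "seg"), 2: ("gls", "lvef", "gwe"),
               3: ("gensini", "cad")}


@dataclass
class TrainConfig:
    phase_epochs: tuple[int, int, int] = (30, 30, 90)
    #: learning rate; a 3-tuple gives each phase its own peak rate
    lr: float | tuple[float, float, float] = 2e-4
    weight_decay: float = 1e-5
    batch_size: int = 16
    grad_accum: int = 3
    seed: int = 0
    loss_weights: dict[str, float] = field(default_factory=dict)  # default 1.0
    warmup_frac: float = 0.05
    #: optionally keep earlier phases' losses in later phases
    joint_losses: bool = False

    def __post_init__(self):
        if any(e < 1 for e in self.phase_epochs):
            raise ValueError("each phase needs at least one epoch")
        if min(np.atleast_1d(self.lr)) <= 0 or self.grad_accum < 1 \
                or self.batch_size < 1:
            raise ValueError("invalid optimisation settings")

    def weight(self, task: str) -> float:
        return self.loss_weights.get(task, 1.0)

    def phase_lr(self, phase: int) -> float:
        if isinstance(self.lr, (tuple, list)):
            return float(self.lr[phase - 1])
        return float(self.lr)


@dataclass
class PhaseState:
    phase: int
    epoch_losses: list[float]
    trainable: list[str]
    lr_history: list[float]

    @property
    def improved(self) -> bool:
        return self.epoch_losses[-1] < self.epoch_losses[0]


@dataclass
class TrainingSample:
    """One clip with every task target (clinical units)."""

    x: np.ndarray            # (20, S, S)
    view_index: int
    seg: np.ndarray          # (20, S, S) int labels
    gls_curve: np.ndarray    # (20,), %
    lvef_curve: np.ndarray   # (20,), %
    gwe: float               # %
    gensini: float           # points
    significant: int         # 0/1
    subject_id: str


def make_training_samples(records: list[SubjectRecord]) -> list[TrainingSample]:
    samples = []
    for rec in records:
        for vi, view in enumerate(VIEWS):
            samples.append(TrainingSample(
                x=rec.clips[view].data, view_index=vi,
                seg=rec.masks[view].data, gls_curve=rec.strain,
                lvef_curve=rec.ef, gwe=rec.gwe, gensini=rec.gensini,
                significant=int(rec.significant), subject_id=rec.subject_id))
    return samples


# ---------------------------------------------------------------------------
# losses


def cross_entropy(logits: Tensor, labels: np.ndarray, n_classes: int,
                  class_axis: int = 1) -> Tensor:
    """Mean cross-entropy from logits; labels are integer class maps."""
    onehot = np.moveaxis(
        np.eye(n_classes, dtype=np.float32)[np.asarray(labels)], -1, class_axis)
    logp = logits.log_softmax(axis=class_axis)
    n = labels.size
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def dice_loss(logits: Tensor, labels: np.ndarray, n_classes: int = 3,
              eps: float = 1e-6) -> Tensor:
    """1 - mean over classes of 2 sum(pq) / (sum(p^2) + sum(q^2) + eps)."""
    p = logits.softmax(axis=1)
    onehot = np.moveaxis(
        np.eye(n_classes, dtype=np.float32)[np.asarray(labels)], -1, 1)
    q = Tensor(onehot)
    axes = tuple(i for i in range(len(p.shape)) if i != 1)
    inter = (p * q).sum(axis=axes)
    denom = (p * p).sum(axis=axes) + (q * q).sum(axis=axes) + eps
    dice = (2.0 * inter / denom).mean()
    return 1.0 - dice


def _mse(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=np.float32))
    return (diff * diff).mean()


def task_losses(out: dict[str, Tensor], batch: list[TrainingSample]
                ) -> dict[str, Tensor]:
    """Named per-task losses for one forward pass over a micro-batch.

    Regression targets are compared on the network's internal scales
    (fractions for the percent-valued metrics, Gensini per 100 points).
    """
    losses: dict[str, Tensor] = {}
    if "view_logits" in out:
        losses["view"] = cross_entropy(
            out["view_logits"], np.array([s.view_index for s in batch]),
            len(VIEWS))
    if "seg_logits" in out:
        segs = np.stack([s.seg for s in batch])
        losses["seg"] = cross_entropy(out["seg_logits"], segs, 3) + \
            dice_loss(out["seg_logits"], segs)
    if "gls" in out:
        losses["gls"] = _mse(out["gls"], np.stack(
            [s.gls_curve for s in batch]) / PERCENT_SCALE)
    if "lvef" in out:
        losses["lvef"] = _mse(out["lvef"], np.stack(
            [s.lvef_curve for s in batch]) / PERCENT_SCALE)
    if "gwe" in out:
        losses["gwe"] = _mse(out["gwe"], np.array(
            [s.gwe for s in batch]) / PERCENT_SCALE)
    if "gensini" in out:
        losses["gensini"] = _mse(out["gensini"], np.array(
            [s.gensini for s in batch]) / GENSINI_SCALE)
    if "cad_logits" in out:
        losses["cad"] = cross_entropy(
            out["cad_logits"], np.array([s.significant for s in batch]), 2)
    return losses


# ---------------------------------------------------------------------------
# phase bookkeeping


def _phase_module_names(phase: int) -> tuple[str, ...]:
    if phase == 1:
        return ("encoder", "conv_block", "view_fc", "seg_conv", "seg_out")
    if phase == 2:
        return ("encoder", "conv_block", "lowrank_gls", "lowrank_lvef",
                "lowrank_gwe", "gls_lstm", "gls_fc", "lvef_lstm", "lvef_fc",
                "gwe_fc")
    if phase == 3:
        return ("lowrank_gensini", "gensini_conv", "gensini_att",
                "gensini_fc1", "gensini_fc2", "cad_conv", "cad_att",
                "cad_fc1", "cad_fc2")
    raise ValueError(f"phase must be 1, 2 or 3, got {phase}")


def phase_parameters(model: IECadNetwork, phase: int):
    """(names, parameters) trained in this phase."""
    wanted = _phase_module_names(phase)
    named = [(n, p) for n, p in model.named_parameters()
             if n.split(".")[0] in wanted]
    return [n for n, _ in named], [p for _, p in named]


def _set_phase_mode(model: IECadNetwork, phase: int) -> None:
    """Train mode for this phase's modules; frozen modules stay in eval so
    their normalisation statistics cannot drift."""
    model.train()
    wanted = set(_phase_module_names(phase))
    for name in vars(model):
        sub = getattr(model, name)
        if hasattr(sub, "eval") and name not in wanted:
            sub.eval()


def _forward_tasks(model: IECadNetwork, xs: np.ndarray, tasks,
                   frozen_trunk: bool = False) -> dict:
    """Forward computing only the active heads.

    With ``frozen_trunk`` the encoder, conv block and phase-1/2 low-rank
    blocks run gradient-free (their outputs are constants in the graph),
    which is both the exact-freezing contract and a large speedup.
    """
    from .network import FeatureBundle
    from .nn import no_grad

    if frozen_trunk:
        with no_grad():
            x = Tensor(xs)
            low_pre, low, deep = model.encoder(x)
            frozen = FeatureBundle(
                low_level_pre=low_pre, low_level=low, deep=deep,
                backbone=model.conv_block(deep),
                sparse_gls=model.lowrank_gls(deep),
                sparse_lvef=model.lowrank_lvef(deep),
                sparse_gwe=model.lowrank_gwe(deep),
                sparse_gensini=None)
        frozen.sparse_gensini = model.lowrank_gensini(frozen.deep)
        fb = frozen
    else:
        fb = model.encode(Tensor(xs))
    return model.decode_all(fb, tasks=tuple(tasks))


# ---------------------------------------------------------------------------
# the training loop


def run_phase(model: IECadNetwork, samples: list[TrainingSample],
              config: TrainConfig, phase: int) -> PhaseState:
    """Run one training phase; returns its loss history."""
    if not samples:
        raise ValueError("no training samples")
    tasks = PHASE_TASKS[phase]
    if config.joint_losses:
        tasks = sum((PHASE_TASKS[p] for p in range(1, phase + 1)), ())
    names, params = phase_parameters(model, phase)
    lr = config.phase_lr(phase)
    opt = Adam(params, lr=lr, weight_decay=config.weight_decay)
    epochs = config.phase_epochs[phase - 1]
    n = len(samples)
    batches_per_epoch = int(np.ceil(n / config.batch_size))
    updates = max(1, int(np.ceil(batches_per_epoch * epochs
                                 / config.grad_accum)))
    sched = WarmupCosine(lr, updates, warmup_frac=config.warmup_frac)
    state = PhaseState(phase=phase, epoch_losses=[], trainable=names,
                       lr_history=[])
    _set_phase_mode(model, phase)
    update = 0
    micro = 0
    for epoch in range(epochs):
        rng = np.random.default_rng((config.seed, phase, epoch))
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(batches_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            batch = [samples[i] for i in idx]
            xs = np.stack([s.x for s in batch])[:, None]
            out = _forward_tasks(model, xs, tasks,
                                 frozen_trunk=(phase == 3
                                               and not config.joint_losses))
            losses = task_losses(out, batch)
            total = None
            for t in tasks:
                term = losses[t] * config.weight(t)
                total = term if total is None else total + term
            val = float(total.data)
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss in phase {phase}, epoch {epoch}: "
                    f"{ {t: float(losses[t].data) for t in tasks} }")
            epoch_loss += val
            (total * (1.0 / config.grad_accum)).backward()
            micro += 1
            if micro % config.grad_accum == 0 or b == batches_per_epoch - 1:
                state.lr_history.append(sched.apply(opt, update))
                opt.step()
                opt.zero_grad()
                update += 1
        state.epoch_losses.append(epoch_loss / batches_per_epoch)
    return state


def train_model(model: IECadNetwork, records: list[SubjectRecord],
                config: TrainConfig | None = None) -> list[PhaseState]:
    """Full three-phase schedule on a cohort; returns per-phase histories."""
    config = config or TrainConfig()
    samples = make_training_samples(records)
    return [run_phase(model, samples, config, phase) for phase in (1, 2, 3)]


# ---------------------------------------------------------------------------
# cohort splitting


def split_cohort(records: list, ratio: float = 0.8, seed: int = 0,
                 max_attempts: int = 20
                 ) -> tuple[list, list]:
    """Subject-level stratified split on (significant, severe).

    Within each stratum the test side receives floor(stratum * (1 - ratio))
    subjects and the remainder trains; the resulting label proportions are
    screened with a chi-squared test (p > 0.1 on both labels), redrawing the
    within-stratum shuffles a bounded number of times.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    strata: dict[tuple[bool, bool], list[int]] = {}
    for i, rec in enumerate(records):
        strata.setdefault((bool(rec.significant), bool(rec.severe)),
                          []).append(i)
    if min(len(v) for v in strata.values()) < 2:
        raise ValueError("cohort too small to stratify on (significant, severe)")
    for attempt in range(max_attempts):
        rng = np.random.default_rng((seed, attempt))
        train_idx: list[int] = []
        test_idx: list[int] = []
        for members in strata.values():
            perm = rng.permutation(members)
            # epsilon guards float round-off (e.g. 30 * (1 - 0.8) = 5.999...)
            n_test = int(np.floor(len(members) * (1.0 - ratio) + 1e-9))
            test_idx.extend(perm[:n_test])
            train_idx.extend(perm[n_test:])
        train = [records[i] for i in sorted(train_idx)]
        test = [records[i] for i in sorted(test_idx)]
        if _labels_matched(train, test):
            return train, test
    return train, test  # bounded attempts exhausted; last draw stands


def _labels_matched(train: list, test: list, p_threshold: float = 0.1) -> bool:
    for attr in ("significant", "severe"):
        a = sum(bool(getattr(r, attr)) for r in train)
        b = sum(bool(getattr(r, attr)) for r in test)
        table = np.array([[a, len(train) - a], [b, len(test) - b]])
        if table.min() == 0 and (table[:, 0].sum() == 0
                                 or table[:, 1].sum() == 0):
            continue  # label constant in both subsets: trivially matched
        p = chi2_contingency(table, correction=True).pvalue
        if p <= p_threshold:
            return False
    return True
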