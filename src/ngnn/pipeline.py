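"""Training and evaluation protocol.

Random 80/20 train/test splitting (optionally stratified by solvent), MSE
training with Adam on z-scored targets, early stopping on a validation
carve-out of the training split, MAE/RMSE/MRE/R2 reporting, and the
multi-seed averaging protocol.

Random streams for splitting, parameter initialization and batch shuffling are
independent children of the run seed, so each source of run-to-run variance
can be isolated.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._autodiff import Tensor, sum_all
from .featurize import DissolvedSample
from .model import (
    GraphBatch,
    ModelError,
    NGNNConfig,
    NGNNParameters,
    forward_tensor,
    load_checkpoint,
    save_checkpoint,
)

__all__ = [
    "SplitSpec",
    "MetricsReport",
    "TrainConfig",
    "RunRecord",
    "split_dataset",
    "compute_metrics",
    "train",
    "predict_samples",
    "evaluate",
    "multi_run",
    "save_model",
    "load_model",
]


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratify_by_solvent: bool = False

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    samples: Sequence[DissolvedSample], spec: SplitSpec
) -> tuple[list[DissolvedSample], list[DissolvedSample]]:
    """Random partition with |train| = round(train_fraction * n).

    Stratified mode applies the same rounding within each solvent's samples,
    so every solvent keeps an approximate 80/20 balance.
    """
    samples = list(samples)
    n = len(samples)
    if n < 5:
        raise ValueError(f"need at least 5 samples to split, got {n}")
    rng = np.random.default_rng(spec.seed)
    if not spec.stratify_by_solvent:
        order = rng.permutation(n)
        n_train = _round_half_up(spec.train_fraction * n)
        train_idx, test_idx = order[:n_train], order[n_train:]
    else:
        strata: dict[str, list[int]] = {}
        for i, s in enumerate(samples):
            strata.setdefault(s.solvent_name, []).append(i)
        train_idx, test_idx = [], []
        for name in sorted(strata):
            idx = np.array(strata[name])
            if len(idx) < 2:
                raise ValueError(f"solvent stratum {name!r} has fewer than 2 samples")
            idx = idx[rng.permutation(len(idx))]
            k = _round_half_up(spec.train_fraction * len(idx))
            k = min(max(k, 1), len(idx) - 1)  # both sides non-empty per stratum
            train_idx.extend(idx[:k])
            test_idx.extend(idx[k:])
        train_idx, test_idx = np.array(train_idx), np.array(test_idx)
    return [samples[i] for i in train_idx], [samples[i] for i in test_idx]


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class MetricsReport:
    mae: float
    rmse: float
    mre: float  # NaN when undefined (some |target| = 0)
    r2: float  # NaN when undefined (zero-variance targets)
    n: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_metrics(predictions: Sequence[float], targets: Sequence[float]) -> MetricsReport:
    """MAE, RMSE, MRE and R2 of a prediction/target pair.

    MRE is reported as NaN if any target is exactly zero; R2 is NaN for
    zero-variance targets (the coefficient of determination is undefined
    there).
    """
    y_hat = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    if y_hat.shape != y.shape or y.ndim != 1 or len(y) == 0:
        raise ValueError("predictions and targets must be equal-length nonempty 1-D arrays")
    err = y_hat - y
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    with np.errstate(over="ignore", divide="ignore"):
        mre = float(np.mean(np.abs(err) / np.abs(y))) if np.all(y != 0) else math.nan
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else math.nan
    return MetricsReport(mae=mae, rmse=rmse, mre=mre, r2=r2, n=len(y))


# --------------------------------------------------------------------------
# optimizer
# --------------------------------------------------------------------------
class Adam:
    def __init__(self, tensors: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in tensors.items()}

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for name, tensor in self.tensors.items():
            if tensor.grad is None:
                continue
            g = tensor.grad
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g**2
            m_hat = self.m[name] / (1 - b1**self.t)
            v_hat = self.v[name] / (1 - b2**self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    epochs: int = 300
    batch_size: int = 64
    patience: int = 30  # early-stopping patience on validation MAE
    val_fraction: float = 0.1  # carve-out of the training split; 0 disables
    standardize_targets: bool = True
    freeze_zero: tuple[str, ...] = ()  # parameters pinned at 0 (e.g. solvent-blind ablation)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunRecord:
    train_mae_trace: list[float]
    val_mae_trace: list[float]
    final_train: MetricsReport
    config: dict
    train_config: dict
    seed: int
    n_epochs_run: int
    best_epoch: int
    notes: str = ""


def _mean_abs(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(np.abs(pred - y)))


def train(
    train_set: Sequence[DissolvedSample],
    config: NGNNConfig | None = None,
    seed: int = 0,
    train_config: TrainConfig | None = None,
    log=None,
) -> tuple[NGNNParameters, RunRecord]:
    """Fit the network by mini-batch Adam on mean-squared error.

    Targets are z-scored on the training split (restored at prediction time);
    a validation carve-out of the training data drives early stopping so the
    test set is never touched during fitting. Fully reproducible from `seed`.
    """
    config = config or NGNNConfig()
    tc = train_config or TrainConfig()
    samples = list(train_set)
    if not samples:
        raise ValueError("empty training set")

    ss = np.random.SeedSequence(seed)
    carve_rng, init_rng, shuffle_rng = (np.random.default_rng(c) for c in ss.spawn(3))

    # validation carve-out; skipped for tiny sets where 10% of the data cannot
    # estimate validation error and early stopping would just add noise
    n = len(samples)
    n_val = _round_half_up(tc.val_fraction * n) if tc.val_fraction > 0 and n >= 50 else 0
    order = carve_rng.permutation(n)
    val = [samples[i] for i in order[:n_val]]
    fit = [samples[i] for i in order[n_val:]]

    y_fit = np.array([s.target for s in fit])
    if tc.standardize_targets:
        mu, sd = float(y_fit.mean()), float(y_fit.std())
        sd = sd if sd > 0 else 1.0
    else:
        mu, sd = 0.0, 1.0

    k_flags = fit[0].solute.n_custom_flags
    params = NGNNParameters.initialize(
        config, n_custom_flags=k_flags, seed=int(init_rng.integers(2**31 - 1))
    )
    params.target_mean, params.target_std = mu, sd
    for name in tc.freeze_zero:
        params.tensors[name].data[:] = 0.0
    optimizer = Adam(params.tensors, lr=tc.lr)

    val_batch = GraphBatch.from_samples(val) if val else None
    y_val = np.array([s.target for s in val]) if val else None

    train_trace: list[float] = []
    val_trace: list[float] = []
    best_val = math.inf
    best_epoch = -1
    best_state = None
    epochs_run = 0

    for epoch in range(tc.epochs):
        idx = shuffle_rng.permutation(len(fit))
        abs_err_sum, count = 0.0, 0
        for lo in range(0, len(fit), tc.batch_size):
            chunk = [fit[i] for i in idx[lo : lo + tc.batch_size]]
            batch = GraphBatch.from_samples(chunk)
            y_std = (batch.targets - mu) / sd
            params.zero_grad()
            pred = forward_tensor(batch, params)
            diff = pred - Tensor(y_std[:, None])
            loss = sum_all(diff * diff) * (1.0 / len(chunk))
            if not np.isfinite(loss.data):
                raise ModelError(f"training diverged (non-finite loss) at epoch {epoch}")
            loss.backward()
            for name in tc.freeze_zero:
                params.tensors[name].grad = None
            optimizer.step()
            abs_err_sum += float(np.sum(np.abs(pred.data[:, 0] - y_std))) * sd
            count += len(chunk)
        epochs_run = epoch + 1
        train_mae = abs_err_sum / count
        train_trace.append(train_mae)
        if val_batch is not None:
            pred_val = forward_tensor(val_batch, params).data[:, 0] * sd + mu
            val_mae = _mean_abs(pred_val, y_val)
            val_trace.append(val_mae)
            if log:
                log(f"epoch {epoch:4d} train_mae {train_mae:.6g} val_mae {val_mae:.6g} lr {tc.lr:g}")
            if val_mae < best_val - 1e-12:
                best_val, best_epoch = val_mae, epoch
                best_state = {k: v.data.copy() for k, v in params.tensors.items()}
            elif epoch - best_epoch >= tc.patience:
                break
        elif log:
            log(f"epoch {epoch:4d} train_mae {train_mae:.6g} lr {tc.lr:g}")

    if best_state is not None:
        for k, v in best_state.items():
            params.tensors[k].data = v

    pred_train = predict_samples(params, samples)
    record = RunRecord(
        train_mae_trace=train_trace,
        val_mae_trace=val_trace,
        final_train=compute_metrics(pred_train, [s.target for s in samples]),
        config=config.to_dict(),
        train_config=tc.to_dict(),
        seed=seed,
        n_epochs_run=epochs_run,
        best_epoch=best_epoch if best_state is not None else epochs_run - 1,
    )
    return params, record


def predict_samples(
    params: NGNNParameters, samples: Sequence[DissolvedSample], batch_size: int = 256
) -> np.ndarray:
    """Property predictions in original target units."""
    samples = list(samples)
    mu = getattr(params, "target_mean", 0.0)
    sd = getattr(params, "target_std", 1.0)
    out = []
    for lo in range(0, len(samples), batch_size):
        batch = GraphBatch.from_samples(samples[lo : lo + batch_size])
        out.append(forward_tensor(batch, params).data[:, 0] * sd + mu)
    return np.concatenate(out)


def evaluate(
    params: NGNNParameters, test_set: Sequence[DissolvedSample]
) -> tuple[MetricsReport, "pd.DataFrame"]:
    """Metrics plus the per-sample prediction table they were computed from."""
    import pandas as pd

    samples = list(test_set)
    if not samples:
        raise ValueError("empty evaluation set")
    predictions = predict_samples(params, samples)
    targets = [s.target for s in samples]
    frame = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "target": targets,
            "prediction": predictions,
        }
    )
    return compute_metrics(predictions, targets), frame


# --------------------------------------------------------------------------
# multi-run protocol
# --------------------------------------------------------------------------
def multi_run(
    samples: Sequence[DissolvedSample],
    config: NGNNConfig | None = None,
    n_runs: int = 3,
    base_seed: int = 0,
    train_config: TrainConfig | None = None,
    split_spec: SplitSpec | None = None,
    log=None,
) -> dict:
    """Independent runs with seeds base_seed..base_seed+n_runs-1, fresh split each.

    Returns per-run train/test reports and their arithmetic mean row.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    base_split = split_spec or SplitSpec()
    runs = []
    for i in range(n_runs):
        seed = base_seed + i
        try:
            tr, te = split_dataset(samples, dataclasses.replace(base_split, seed=seed))
            params, record = train(tr, config, seed=seed, train_config=train_config, log=log)
            test_report, _ = evaluate(params, te)
        except Exception as err:
            raise RuntimeError(f"run with seed {seed} failed: {err}") from err
        runs.append(
            {"seed": seed, "train": record.final_train, "test": test_report, "record": record}
        )

    def mean_report(reports: list[MetricsReport]) -> dict:
        keys = ("mae", "rmse", "mre", "r2")
        return {k: float(np.mean([getattr(r, k) for r in reports])) for k in keys}

    return {
        "runs": runs,
        "mean_train": mean_report([r["train"] for r in runs]),
        "mean_test": mean_report([r["test"] for r in runs]),
    }


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------
def save_model(params: NGNNParameters, path):
    save_checkpoint(
        params,
        path,
        extra={
            "target_mean": getattr(params, "target_mean", 0.0),
            "target_std": getattr(params, "target_std", 1.0),
        },
    )


def load_model(path) -> NGNNParameters:
    params, extra = load_checkpoint(path)
    params.target_mean = extra.get("target_mean", 0.0)
    params.target_std = extra.get("target_std", 1.0)
    return params
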