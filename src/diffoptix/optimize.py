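"""Gradient-based discovery engine: AdamW over named parameter families,
random restarts, convergence detection, finite-difference gradient checks,
and the data-driven (input→target) trainer.

The loss callable receives a dict of named autodiff Tensors (one leaf per
parameter array) and returns a real scalar Tensor; gradients are obtained by
reverse-mode differentiation through the optical simulator.  Runs are
bit-reproducible for a fixed configuration and seed, and every optimization
can stream a resumable HDF5 checkpoint.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["OptimizerConfig", "RunResult", "AdamW", "optimize", "grad_check",
           "train_data_driven", "save_checkpoint", "load_checkpoint", "resume"]


@dataclasses.dataclass
class OptimizerConfig:
    """Settings of the stochastic-gradient discovery loop.

    Separate learning rates for scalar families and phase rasters reflect
    their very different conditioning (a raster pixel influences one detector
    pixel; a distance influences all of them).
    """

    algorithm: str = "adamw"
    learning_rate: float = 1e-2
    raster_learning_rate: float = 1e-1
    weight_decay: float = 0.0
    steps: int = 1000
    restarts: int = 5
    convergence_window: int = 50
    convergence_rtol: float = 1e-5
    seed: int = 0
    checkpoint_path: str | None = None

    def __post_init__(self):
        if self.steps < 0 or self.learning_rate <= 0:
            raise ValueError("need non-negative budget and positive rate")
        if self.algorithm not in ("adam", "adamw"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclasses.dataclass
class RunResult:
    """Best restart of an optimization: parameters, trace, metadata."""

    best_params: dict
    best_loss: float
    loss_trace: np.ndarray
    argmin_detector: np.ndarray
    all_final_losses: list
    seed: int
    converged_at: int | None = None


class AdamW:
    """Decoupled-weight-decay Adam over a dict of named numpy arrays."""

    def __init__(self, params: dict, lr: float = 1e-2, raster_lr: float | None = None,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = {k: np.asarray(v, dtype=np.float64).copy() for k, v in params.items()}
        self.lr, self.raster_lr = lr, (raster_lr if raster_lr is not None else lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self.t = 0

    def _rate(self, name: str, arr: np.ndarray) -> float:
        return self.raster_lr if arr.ndim >= 2 else self.lr

    def step(self, grads: dict):
        self.t += 1
        for k, g in grads.items():
            if g is None:
                continue
            p = self.params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            lr = self._rate(k, p)
            p -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.wd * p)

    def state(self) -> dict:
        return {"m": self.m, "v": self.v, "t": self.t}


def _leaves(params: dict) -> dict:
    return {k: Tensor(np.asarray(v, dtype=np.float64).copy(), requires_grad=True)
            for k, v in params.items()}


def _eval_with_grads(loss_fn, params: dict):
    leaves = _leaves(params)
    out = loss_fn(leaves)
    aux = None
    if isinstance(out, tuple):
        out, aux = out
    if not np.isfinite(out.value):
        return float(out.value), None, aux
    ad.backward(out)
    grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.value))
             for k, t in leaves.items()}
    return float(out.value), grads, aux


def _run_single(loss_fn, init: dict, cfg: OptimizerConfig, restart_seed: int):
    opt = AdamW(init, lr=cfg.learning_rate, raster_lr=cfg.raster_learning_rate,
                weight_decay=(cfg.weight_decay if cfg.algorithm == "adamw" else 0.0))
    trace, argmins = [], []
    best = np.inf
    converged_at = None
    for step in range(cfg.steps):
        loss, grads, aux = _eval_with_grads(loss_fn, opt.params)
        if grads is None:
            return None  # non-finite: abort this restart
        trace.append(loss)
        argmins.append(-1 if aux is None else int(aux))
        best = min(best, loss)
        w = cfg.convergence_window
        if len(trace) > w:
            prev = min(trace[:-w])
            cur = min(trace)
            if (prev - cur) / max(abs(prev), 1e-300) < cfg.convergence_rtol:
                converged_at = step
                break
        opt.step(grads)
        # checkpoint after the update: params carry len(trace) steps exactly,
        # so resume() re-extends the stored trace without duplication
        if cfg.checkpoint_path is not None:
            save_checkpoint(cfg.checkpoint_path, opt, trace, restart_seed)
    final_loss, _, aux = _eval_with_grads(loss_fn, opt.params)
    trace.append(final_loss)
    argmins.append(-1 if aux is None else int(aux))
    return opt.params, np.asarray(trace), np.asarray(argmins), converged_at


def optimize(loss_fn, init: dict, cfg: OptimizerConfig,
             init_sampler=None) -> RunResult:
    """Minimize ``loss_fn`` with AdamW and random restarts.

    ``init`` is the dict of initial arrays used for the first restart;
    further restarts draw fresh initializations from ``init_sampler(seed)``
    (defaults to re-using ``init``).  The best restart by final loss wins.
    Deterministic given ``cfg.seed``.
    """
    results = []
    rng = np.random.default_rng(cfg.seed)
    restart_seeds = [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=max(cfg.restarts, 1))]
    for ridx, rseed in enumerate(restart_seeds):
        start = init if (ridx == 0 or init_sampler is None) else init_sampler(rseed)
        if isinstance(start, dict):
            start_arrays = start
        else:  # ParameterVector
            start_arrays = start.arrays
        out = _run_single(loss_fn, start_arrays, cfg, rseed)
        if out is not None:
            results.append(out)
    if not results:
        raise RuntimeError("all restarts diverged to non-finite loss")
    finals = [float(r[1][-1]) for r in results]
    best = int(np.argmin(finals))
    params, trace, argmins, conv = results[best]
    return RunResult(best_params=params, best_loss=float(trace[-1]),
                     loss_trace=trace, argmin_detector=argmins,
                     all_final_losses=finals, seed=cfg.seed, converged_at=conv)


def grad_check(loss_fn, params: dict, n_probes: int = 3, eps: float = 1e-5,
               seed: int = 0) -> float:
    """Max relative error between analytic and central finite-difference
    gradients over ``n_probes`` random coordinates of every parameter family."""
    if n_probes < 1:
        raise ValueError("need at least one probe")
    _, grads, _ = _eval_with_grads(loss_fn, params)
    rng = np.random.default_rng(seed)

    def eval_at(p):
        out = loss_fn({k: Tensor(v) for k, v in p.items()})
        if isinstance(out, tuple):
            out = out[0]
        return float(out.value)

    worst = 0.0
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=np.float64)
        flat_idx = rng.choice(arr.size, size=min(n_probes, arr.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, arr.shape) if arr.shape else ()
            pp = {k: np.array(v, dtype=np.float64) for k, v in params.items()}
            pp[name] = pp[name].copy()
            base = pp[name][idx] if arr.shape else float(pp[name])
            h = eps * max(1.0, abs(base))
            if arr.shape:
                pp[name][idx] = base + h
                fp = eval_at(pp)
                pp[name][idx] = base - h
                fm = eval_at(pp)
            else:
                pp[name] = np.array(base + h)
                fp = eval_at(pp)
                pp[name] = np.array(base - h)
                fm = eval_at(pp)
            fd = (fp - fm) / (2 * h)
            an = grads[name][idx] if arr.shape else float(grads[name])
            denom = max(abs(fd), abs(an))
            err = 0.0 if denom == 0 else abs(fd - an) / denom
            worst = max(worst, err)
    return worst


def train_data_driven(simulate, dataset: list, batch: int,
                      cfg: OptimizerConfig, init: dict,
                      loss_kind: str = "mse", validation=None):
    """Supervised training of an optical setup on (input, target) pairs.

    ``simulate(params, input_raster)`` must return the detected intensity as
    a Tensor; the per-step objective is the batch-average MSE between the
    detected and target rasters, with parameters shared across the batch.
    Pairs are sampled with reshuffling each epoch.  Returns a
    :class:`RunResult` whose trace is the per-step batch loss (and, if
    ``validation=(input, target)`` is given, carries ``val_trace``).
    """
    from .objectives import mse_loss

    n = len(dataset)
    if n < 1:
        raise ValueError("dataset must be non-empty")
    order_rng = np.random.default_rng(cfg.seed + 1)
    order: list = []

    def next_batch():
        nonlocal order
        out = []
        for _ in range(batch):
            if not order:
                order = list(order_rng.permutation(n))
            out.append(dataset[order.pop()])
        return out

    opt = AdamW(init, lr=cfg.learning_rate, raster_lr=cfg.raster_learning_rate,
                weight_decay=(cfg.weight_decay if cfg.algorithm == "adamw" else 0.0))
    trace, val_trace = [], []

    def batch_loss(leaves, pairs):
        total = None
        for inp, tgt in pairs:
            det = simulate(leaves, inp)
            l = mse_loss(det, tgt)
            total = l if total is None else total + l
        return total * (1.0 / len(pairs))

    def val_loss(params):
        if validation is None:
            return None
        leaves = {k: Tensor(v) for k, v in params.items()}
        det = simulate(leaves, validation[0])
        return float(ad.tmean((det - validation[1]) * (det - validation[1])).value)

    v0 = val_loss(opt.params)
    if v0 is not None:
        val_trace.append(v0)
    for step in range(cfg.steps):
        pairs = next_batch()
        leaves = _leaves(opt.params)
        loss = batch_loss(leaves, pairs)
        ad.backward(loss)
        grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.value))
                 for k, t in leaves.items()}
        trace.append(float(loss.value))
        opt.step(grads)
    vf = val_loss(opt.params)
    if vf is not None:
        val_trace.append(vf)
    res = RunResult(best_params=opt.params, best_loss=(trace[-1] if trace else np.inf),
                    loss_trace=np.asarray(trace), argmin_detector=np.zeros(len(trace), int),
                    all_final_losses=[trace[-1] if trace else np.inf], seed=cfg.seed)
    res.val_trace = np.asarray(val_trace)
    return res


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, opt: AdamW, trace: list, restart_seed: int) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        for group, arrays in (("params", opt.params), ("m", opt.m), ("v", opt.v)):
            gr = f.create_group(group)
            for k, v in arrays.items():
                gr.create_dataset(k, data=v)
        f.create_dataset("trace", data=np.asarray(trace))
        f.attrs["t"] = opt.t
        f.attrs["restart_seed"] = restart_seed


def load_checkpoint(path):
    import h5py
    with h5py.File(path, "r") as f:
        params = {k: f["params"][k][...] for k in f["params"]}
        m = {k: f["m"][k][...] for k in f["m"]}
        v = {k: f["v"][k][...] for k in f["v"]}
        trace = list(f["trace"][...])
        t = int(f.attrs["t"])
        rseed = int(f.attrs["restart_seed"])
    return params, m, v, t, trace, rseed


def resume(path, loss_fn, cfg: OptimizerConfig):
    """Continue an interrupted optimization from its checkpoint; the combined
    trace extends the stored one exactly."""
    params, m, v, t, trace, rseed = load_checkpoint(path)
    opt = AdamW(params, lr=cfg.learning_rate, raster_lr=cfg.raster_learning_rate,
                weight_decay=(cfg.weight_decay if cfg.algorithm == "adamw" else 0.0))
    opt.m, opt.v, opt.t = m, v, t
    remaining = cfg.steps - len(trace)
    for _ in range(max(remaining, 0)):
        loss, grads, aux = _eval_with_grads(loss_fn, opt.params)
        if grads is None:
            break
        trace.append(loss)
        opt.step(grads)
    final, _, _ = _eval_with_grads(loss_fn, opt.params)
    trace.append(final)
    return RunResult(best_params=opt.params, best_loss=float(trace[-1]),
                     loss_trace=np.asarray(trace),
                     argmin_detector=np.full(len(trace), -1),
                     all_final_losses=[float(trace[-1])], seed=cfg.seed)
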