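"""Trainers for the subject-dependent and cross-subject (LOSO) protocols,
classification metrics, and paired statistical comparison.

Subject-dependent runs train the base network (temporal + spatio-temporal
branches only) with cross-entropy.  LOSO runs train the full model: each
optimisation step forwards a labelled source batch and an unlabelled batch of
the held-out subject's trials, and adds ``lambda * MMD^2`` between the two
batches' penultimate features to the loss.  Target labels are never read by
the training path — the target loader exposes trials only.

Checkpoint policy: the weights with the lowest validation *classification*
loss are kept (comparable across lambda settings) and evaluated on the test
split.  A max-norm constraint renormalises convolution kernels after every
optimiser step.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from . import nn
from .domain_adapt import KernelSpec, cross_entropy_loss, mmd_loss
from .eeg_io import EEGTrialSet, SplitSpec, split_loso, zscore_fit_apply
from .network import FusedFeatures, ModelConfig, RMETNet
from .riemannian import build_riemannian_inputs

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "train_subject_dependent",
    "train_loso",
    "load_checkpoint",
    "confusion_matrix",
    "classification_metrics",
    "wilcoxon_paired",
    "summarize",
]


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 64
    epochs: int = 500
    learning_rate: float = 1e-4
    weight_decay: float = 0.075
    lam: float = 1.0
    seed: int = 0
    maxnorm: float = 2.0
    mode: str = "subject_dependent"  # or "cross_subject"
    shrinkage: float = 1e-3
    alignment_policy: str = "per_domain"

    def __post_init__(self):
        for name in ("batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("learning_rate", "maxnorm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lam < 0 or self.weight_decay < 0:
            raise ValueError("lam and weight_decay must be non-negative")
        if self.mode not in ("subject_dependent", "cross_subject"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclasses.dataclass
class TrainResult:
    state: dict
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    log: pd.DataFrame
    best_epoch: int
    test_subject: int | None
    accuracy: float
    kappa: float
    confusion: np.ndarray
    predictions: np.ndarray
    model_mode: str = "base"

    def save(self, path) -> None:
        import json

        np.savez(
            path,
            **{f"param/{k}": v for k, v in self.state.items()},
            model_cfg=self.model_cfg.to_json(),
            train_cfg=json.dumps(dataclasses.asdict(self.train_cfg)),
            model_mode=self.model_mode,
        )


def load_checkpoint(path):
    """Rebuild a model (and its configs) from a saved checkpoint file."""
    import json

    with np.load(path, allow_pickle=False) as f:
        model_cfg = ModelConfig.from_json(str(f["model_cfg"]))
        train_cfg = TrainConfig(**json.loads(str(f["train_cfg"])))
        mode = str(f["model_mode"])
        state = {k[len("param/"):]: f[k] for k in f.files if k.startswith("param/")}
    model = RMETNet(model_cfg, seed=train_cfg.seed)
    model.load_state_dict(state)
    return model, model_cfg, train_cfg, mode


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield idx[start : start + batch_size]


def _eval_probs(model: RMETNet, eeg, riem, mode, batch_size=128) -> np.ndarray:
    model.eval()
    out = []
    for start in range(0, len(eeg), batch_size):
        sl = slice(start, start + batch_size)
        ff = model(eeg[sl], None if riem is None else riem[sl], mode=mode)
        out.append(ff.probs.data)
    return np.vstack(out)


def _train_model(
    trial_set: EEGTrialSet,
    split: SplitSpec,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    mode: str,
) -> TrainResult:
    if len(split.val) == 0:
        raise ValueError("validation split is empty; checkpoint policy undefined")
    train = trial_set.subset(split.train)
    val = trial_set.subset(split.val)
    test = trial_set.subset(split.test)
    train_n, (val_n, test_n), _ = zscore_fit_apply(train, [val, test])

    riem_tr = riem_val = riem_te = None
    if mode == "full":
        # unlabelled target trials participate only through their signals
        source = EEGTrialSet(
            trials=np.concatenate([train_n.trials, val_n.trials]),
            labels=np.concatenate([train_n.labels, val_n.labels]),
            subjects=np.concatenate([train_n.subjects, val_n.subjects]),
            fs=trial_set.fs,
        )
        src_aligned, tgt_aligned = build_riemannian_inputs(
            source, test_n, shrinkage=cfg.shrinkage, policy=cfg.alignment_policy,
            apply_log=model_cfg.apply_log_alignment,
        )
        riem_tr = src_aligned.matrices[: len(split.train)]
        riem_val = src_aligned.matrices[len(split.train):]
        riem_te = tgt_aligned.matrices

    model = RMETNet(model_cfg, seed=cfg.seed)
    params = model.trainable_parameters(mode)
    opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    nn.apply_maxnorm(model, cfg.maxnorm)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 20)))
    use_mmd = split.mode == "cross_subject" and cfg.lam > 0
    log_rows = []
    best = (np.inf, -1, None)
    for epoch in range(cfg.epochs):
        model.train()
        tgt_cycle = itertools.cycle(_batches(test_n.n_trials, cfg.batch_size, rng)) \
            if use_mmd else None
        ep_cls = ep_mmd = 0.0
        n_steps = 0
        for bidx in _batches(train_n.n_trials, cfg.batch_size, rng):
            model.zero_grad()
            ff: FusedFeatures = model(
                train_n.trials[bidx],
                None if riem_tr is None else riem_tr[bidx],
                mode=mode,
            )
            loss = cross_entropy_loss(ff.probs, train_n.labels[bidx])
            ep_cls += float(loss.data)
            if use_mmd:
                tb = next(tgt_cycle)
                ff_t = model(
                    test_n.trials[tb],
                    None if riem_te is None else riem_te[tb],
                    mode=mode,
                )
                mmd = mmd_loss(ff.fused, ff_t.fused, KernelSpec())
                ep_mmd += float(mmd.data)
                loss = loss + cfg.lam * mmd
            loss.backward()
            opt.step()
            nn.apply_maxnorm(model, cfg.maxnorm)
            n_steps += 1
        val_probs = _eval_probs(model, val_n.trials, riem_val, mode)
        from .domain_adapt import cross_entropy as _ce

        val_loss = _ce(val_probs, val_n.labels)
        log_rows.append(
            {
                "epoch": epoch,
                "cls": ep_cls / n_steps,
                "mmd": ep_mmd / n_steps,
                "lam": cfg.lam,
                "total": ep_cls / n_steps + cfg.lam * ep_mmd / n_steps,
                "val_loss": val_loss,
            }
        )
        if val_loss < best[0]:
            best = (val_loss, epoch, model.state_dict())

    model.load_state_dict(best[2])
    test_probs = _eval_probs(model, test_n.trials, riem_te, mode)
    preds = test_probs.argmax(axis=1)
    cm = confusion_matrix(test_n.labels, preds, model_cfg.K)
    acc, kappa = classification_metrics(cm)
    return TrainResult(
        state=best[2],
        model_cfg=model_cfg,
        train_cfg=cfg,
        log=pd.DataFrame(log_rows),
        best_epoch=best[1],
        test_subject=split.test_subject,
        accuracy=acc,
        kappa=kappa,
        confusion=cm,
        predictions=preds,
        model_mode=mode,
    )


def train_subject_dependent(
    trial_set: EEGTrialSet, split: SplitSpec, model_cfg: ModelConfig, cfg: TrainConfig
) -> TrainResult:
    """Train the base network (no Riemannian branch, no MMD) on one subject."""
    if split.mode != "subject_dependent":
        raise ValueError("split mode must be subject_dependent")
    return _train_model(trial_set, split, model_cfg, cfg, mode="base")


def train_loso(
    trial_set: EEGTrialSet,
    test_subject: int,
    model_cfg: ModelConfig,
    cfg: TrainConfig,
    use_riemannian: bool = True,
) -> TrainResult:
    """Leave-one-subject-out transfer training.

    The held-out subject's trials enter only as unlabelled target batches for
    the MMD term and for transductive covariance alignment; their labels are
    read exclusively by the final evaluation.  ``use_riemannian=False`` drops
    the covariance branch (ablation); setting ``cfg.lam = 0`` disables MMD.
    """
    split = split_loso(trial_set, test_subject, seed=cfg.seed)
    return _train_model(
        trial_set, split, model_cfg, cfg, mode="full" if use_riemannian else "base"
    )


# ---------------------------------------------------------------------------
# metrics


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def classification_metrics(cm: np.ndarray) -> tuple[float, float]:
    """Accuracy and Cohen's kappa from a (true x predicted) count matrix.

    kappa = (P_o - P_e) / (1 - P_e); defined as 0 in the degenerate case
    P_e = 1 (all mass in one cell).
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    if abs(1.0 - p_e) < 1e-12:
        return float(p_o), 0.0
    return float(p_o), float((p_o - p_e) / (1.0 - p_e))


def wilcoxon_paired(a, b) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided).

    Zero differences are dropped; the statistic is ``W+ - W-`` (sign-symmetric
    in the arguments).  The null distribution is enumerated exactly over all
    sign assignments for n <= 25 and normally approximated (with tie
    correction) above.  If every difference is zero the result is the
    conventional ``(0.0, 1.0)``.
    """
    from scipy.stats import norm, rankdata

    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = w_plus - w_minus
    untied = np.allclose(ranks, np.round(ranks))
    if n <= 25 and untied:
        # exact null: distribution of W+ over all sign assignments, by
        # polynomial convolution over the integer ranks
        r_int = np.round(ranks).astype(int)
        dist = np.zeros(r_int.sum() + 1)
        dist[0] = 1.0
        for r in r_int:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: dist.size - r]
            dist = dist + shifted
        dist /= dist.sum()
        lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
        p = float(dist[: int(lo) + 1].sum() + dist[int(hi):].sum())
    elif n <= 14:
        # ties: brute-force enumeration of the 2^n sign assignments
        signs = np.array(list(itertools.product((-1.0, 1.0), repeat=n)))
        null = signs @ ranks
        p = float(np.mean(np.abs(null) >= abs(stat) - 1e-12))
    else:
        z = stat / np.sqrt(float((ranks**2).sum()))  # Var(W+ - W-) = sum r_i^2
        p = float(2.0 * norm.sf(abs(z)))
    return stat, min(p, 1.0)


@dataclasses.dataclass
class EvalReport:
    """Per-subject scores with aggregate statistics and pairwise tests."""

    per_subject: pd.DataFrame  # columns: subject, acc, kappa
    comparisons: dict[str, float] = dataclasses.field(default_factory=dict)
    single_subject: bool = False

    @property
    def mean_acc(self) -> float:
        return float(self.per_subject["acc"].mean())

    @property
    def sd_acc(self) -> float:
        if len(self.per_subject) < 2:
            return 0.0
        return float(self.per_subject["acc"].std(ddof=1))

    @property
    def mean_kappa(self) -> float:
        return float(self.per_subject["kappa"].mean())

    def to_csv(self, path) -> None:
        self.per_subject.to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "EvalReport":
        df = pd.read_csv(path)
        return EvalReport(per_subject=df, single_subject=len(df) == 1)


def summarize(results, comparisons: dict[str, tuple] | None = None) -> EvalReport:
    """Aggregate per-subject results and run paired Wilcoxon comparisons.

    ``results`` is a list of (subject, accuracy, kappa) triples or
    :class:`TrainResult` objects; ``comparisons`` maps a label to a pair of
    equal-length score vectors.
    """
    rows = []
    for r in results:
        if isinstance(r, TrainResult):
            rows.append({"subject": r.test_subject, "acc": r.accuracy, "kappa": r.kappa})
        else:
            s, acc, kap = r
            rows.append({"subject": s, "acc": acc, "kappa": kap})
    if not rows:
        raise ValueError("no results to summarize")
    pvals = {}
    for label, (x, y) in (comparisons or {}).items():
        pvals[label] = wilcoxon_paired(x, y)[1]
    return EvalReport(
        per_subject=pd.DataFrame(rows),
        comparisons=pvals,
        single_subject=len(rows) == 1,
    )
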