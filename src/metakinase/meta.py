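"""MAML-style meta-training of the two-tower model over head-kinase episodes.

The meta-learner seeks an initialization theta' such that, for a new kinase
with only a 5+5 support set, a few full-batch gradient steps on the support
loss yield a good task-specific model:

    inner loop:  theta''_k = theta - alpha * grad L_{S_k}(theta)   (x inner_steps)
    outer loop:  theta  <-  theta - beta * grad_theta  sum_k L_{Q_k}(theta''_k)

With ``order='second'`` the outer gradient differentiates through the inner
updates: backpropagating g through one inner step multiplies it by
(I - alpha * H_{S_k}(theta_t)), so the chain needs one support-loss
Hessian-vector product per inner step and task (computed exactly via the
complex-step trick in :mod:`.ilmc`).  ``order='first'`` stops gradients at
the adapted parameters (FOMAML).  With ``inner_steps=0`` the two orders
coincide and the procedure degenerates to joint training on query losses.

Tail kinases are served by :func:`few_shot_adapt`, which runs the same
inner loop from the meta-trained initialization, and by :func:`predict_new`
/ :func:`rank_kinases` for inductive scoring of unseen compounds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_features import FeatureMatrix
from .dataset import Episode, LongTailSplit, sample_episode
from .ilmc import (
    TowerArch,
    TowerParams,
    _Adam,
    hessian_vector_product,
    init_params,
    loss_and_grad,
    pair_features,
    predict_proba,
)
from .seeding import substream


@dataclass
class MetaConfig:
    """Bi-level optimization controls.

    alpha (inner_lr) and beta (outer_lr) default to 0.01 with 4 inner
    gradient steps; the outer update is a literal single gradient step on
    the summed query losses (``outer_optimizer='sgd'``), with Adam optional.
    """

    inner_lr: float = 0.01
    outer_lr: float = 0.01
    inner_steps: int = 4
    outer_iterations: int = 200
    order: str = "second"
    task_batch: int | str = "all"
    seed: int = 0
    lambda_reg: float = 1e-4
    outer_optimizer: str = "sgd"
    n_support_per_class: int = 5
    n_query_per_class: int = 10
    hidden: tuple[int, ...] = (128,)
    embedding_dim: int = 64

    def __post_init__(self):
        if self.inner_lr < 0 or self.outer_lr < 0:
            raise ValueError("learning rates must be >= 0")
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be >= 0")
        if self.order not in ("second", "first"):
            raise ValueError("order must be 'second' or 'first'")
        if self.outer_optimizer not in ("sgd", "adam"):
            raise ValueError("outer_optimizer must be 'sgd' or 'adam'")
        if self.task_batch != "all" and int(self.task_batch) < 1:
            raise ValueError("task_batch must be 'all' or a positive integer")


# ---------------------------------------------------------------------------
# inner loop


def _inner_trajectory(theta, arch, Xc, Xp, y, inner_lr, inner_steps, lambda_reg):
    """Run the inner loop, returning every iterate (theta_0 .. theta_K)."""
    iterates = [theta]
    t = theta
    for _ in range(inner_steps):
        _, g = loss_and_grad(t, arch, Xc, Xp, y, lambda_reg)
        t = t - inner_lr * g
        iterates.append(t)
    return iterates


def inner_adapt(
    params: TowerParams,
    support_Xc,
    support_Xp,
    support_y,
    inner_lr: float,
    inner_steps: int,
    lambda_reg: float = 0.0,
) -> TowerParams:
    """``inner_steps`` full-batch gradient steps on the support loss.

    Value semantics: the input parameters are never modified.  With
    ``inner_lr=0`` or ``inner_steps=0`` the output equals the input.
    """
    y = np.asarray(support_y, dtype=float)
    if len(y) == 0:
        raise ValueError("empty support set")
    iterates = _inner_trajectory(
        params.theta, params.arch,
        np.asarray(support_Xc, float), np.asarray(support_Xp, float), y,
        inner_lr, inner_steps, lambda_reg,
    )
    return TowerParams(params.arch, iterates[-1].copy())


# ---------------------------------------------------------------------------
# outer loop


def _meta_gradient_one_task(theta, arch, task, config):
    """Query loss and the meta-gradient contribution of one task.

    ``task`` is ((Xc_s, Xp_s, y_s), (Xc_q, Xp_q, y_q)).
    """
    (Xc_s, Xp_s, y_s), (Xc_q, Xp_q, y_q) = task
    if len(y_s) == 0:
        raise ValueError("empty support set in meta step")
    if len(y_q) == 0:
        raise ValueError("empty query set in meta step")
    iterates = _inner_trajectory(
        theta, arch, Xc_s, Xp_s, y_s, config.inner_lr, config.inner_steps,
        config.lambda_reg,
    )
    q_loss, g = loss_and_grad(
        iterates[-1], arch, Xc_q, Xp_q, y_q, config.lambda_reg
    )
    if config.order == "second":
        # reverse through theta_{t+1} = theta_t - alpha * grad L_S(theta_t):
        # g <- (I - alpha * H_S(theta_t)) g, applied from the last step back.
        for t in range(config.inner_steps - 1, -1, -1):
            hv = hessian_vector_product(
                iterates[t], g, arch, Xc_s, Xp_s, y_s, config.lambda_reg
            )
            g = g - config.inner_lr * hv
    return float(q_loss), g


def meta_step_arrays(theta, arch, tasks, config, opt=None):
    """One outer update over a batch of (support, query) array tasks.

    Returns (new_theta, mean query loss at adapted parameters).
    """
    total = np.zeros_like(theta)
    losses = []
    for task in tasks:
        q_loss, g = _meta_gradient_one_task(theta, arch, task, config)
        losses.append(q_loss)
        total += g
    if opt is not None:
        theta = opt.step(theta, total)
    else:
        theta = theta - config.outer_lr * total
    return theta, float(np.mean(losses))


def _episode_arrays(episode: Episode, compound_feats, kinase_feats):
    sup = episode.support.assign(kinase_id=episode.kinase_id)
    qry = episode.query.assign(kinase_id=episode.kinase_id)
    return (
        pair_features(sup, compound_feats, kinase_feats),
        pair_features(qry, compound_feats, kinase_feats),
    )


def meta_step(
    params: TowerParams,
    episodes: Sequence[Episode],
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
    config: MetaConfig,
) -> TowerParams:
    """One outer gradient step over one episode per selected head task."""
    tasks = [_episode_arrays(e, compound_feats, kinase_feats) for e in episodes]
    theta, _ = meta_step_arrays(params.theta.copy(), params.arch, tasks, config)
    return TowerParams(params.arch, theta)


def meta_train(
    split: LongTailSplit,
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
    config: MetaConfig,
    init: TowerParams | None = None,
) -> tuple[TowerParams, list[float]]:
    """Episodic meta-training over the head tasks.

    Each outer iteration resamples a fresh support/query episode per head
    kinase from its training pool, optionally subsamples ``task_batch``
    tasks, and applies one outer update.  Returns the meta-trained
    parameters and the per-iteration mean query loss.
    """
    head_ids = split.head_kinases
    if not head_ids:
        raise ValueError("split has no head tasks")
    need = config.n_support_per_class + config.n_query_per_class
    for kid in head_ids:
        pool = split.head_support[kid]
        for label in (1, 0):
            have = int((pool["label"] == label).sum())
            if have < need:
                raise ValueError(
                    f"head task {kid!r} cannot supply "
                    f"{config.n_support_per_class}+{config.n_query_per_class} "
                    f"episodes: only {have} pairs of class {label}"
                )

    if init is None:
        arch = TowerArch(
            compound_feats.d, kinase_feats.d,
            hidden=tuple(config.hidden), embedding_dim=config.embedding_dim,
        )
        params = init_params(arch, seed=config.seed)
    else:
        params = init.copy()
    theta = params.theta.copy()
    opt = (
        _Adam(theta.size, config.outer_lr)
        if config.outer_optimizer == "adam"
        else None
    )
    task_rng = substream(config.seed, "meta", "task-batch")
    history: list[float] = []
    for it in range(config.outer_iterations):
        if config.task_batch == "all" or int(config.task_batch) >= len(head_ids):
            chosen = head_ids
        else:
            idx = task_rng.choice(len(head_ids), size=int(config.task_batch), replace=False)
            chosen = [head_ids[i] for i in np.sort(idx)]
        tasks = []
        for kid in chosen:
            rng = substream(config.seed, "meta", "episode", str(it), kid)
            ep = sample_episode(
                split.head_support[kid], kid,
                config.n_support_per_class, config.n_query_per_class, rng,
            )
            tasks.append(_episode_arrays(ep, compound_feats, kinase_feats))
        theta, mean_q = meta_step_arrays(theta, params.arch, tasks, config, opt)
        history.append(mean_q)
    return TowerParams(params.arch, theta), history


# ---------------------------------------------------------------------------
# few-shot adaptation and inductive prediction


@dataclass
class AdaptedModel:
    """Task-specific parameters theta''_k for one kinase, with provenance."""

    kinase_id: str
    params: TowerParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.provenance:
            raise ValueError("AdaptedModel requires non-empty provenance")


def support_fingerprint(support: pd.DataFrame) -> str:
    rows = sorted(map(tuple, support[["compound_id", "label"]].to_numpy().tolist()))
    return hashlib.sha1(repr(rows).encode()).hexdigest()[:16]


def few_shot_adapt(
    meta_params: TowerParams,
    kinase_id: str,
    support: pd.DataFrame,
    compound_feats: FeatureMatrix,
    kinase_feats: FeatureMatrix,
    config: MetaConfig,
    meta_checkpoint_id: str = "in-memory",
) -> AdaptedModel:
    """Adapt the meta-initialization to one tail kinase's support set."""
    sup = support.assign(kinase_id=str(kinase_id))
    Xc, Xp, y = pair_features(sup, compound_feats, kinase_feats)
    adapted = inner_adapt(
        meta_params, Xc, Xp, y, config.inner_lr, config.inner_steps,
        config.lambda_reg,
    )
    return AdaptedModel(
        kinase_id=str(kinase_id),
        params=adapted,
        provenance={
            "meta_checkpoint": meta_checkpoint_id,
            "support_fingerprint": support_fingerprint(support),
            "inner_lr": config.inner_lr,
            "inner_steps": config.inner_steps,
        },
    )


def predict_new(x_new, adapted: AdaptedModel, kinase_features):
    """Active probability of a new compound against the adapted kinase model.

    ``kinase_features`` is either the kinase FeatureMatrix (the adapted
    model's kinase_id selects the row) or an explicit descriptor vector.
    """
    if isinstance(kinase_features, FeatureMatrix):
        x_p = kinase_features.row(adapted.kinase_id)
    else:
        x_p = np.asarray(kinase_features, dtype=float)
    return predict_proba(x_new, x_p, adapted.params)


def rank_kinases(
    x_c,
    models: Mapping[str, AdaptedModel | TowerParams],
    kinase_feats: FeatureMatrix,
    top: int | None = None,
) -> list[tuple[str, float]]:
    """Prioritize kinases for one compound by predicted active probability.

    Descending score; equal scores break lexicographically by kinase_id.
    ``models`` maps kinase_id to its adapted model (or shared global params).
    """
    if not models:
        raise ValueError("no models to rank")
    scored = []
    for kid in sorted(models):
        model = models[kid]
        params = model.params if isinstance(model, AdaptedModel) else model
        scored.append((kid, float(predict_proba(x_c, kinase_feats.row(kid), params))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top] if top is not None else scored
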