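"""Interpretable conditional VAE with a term-masked linear decoder.

The architecture couples a flexible nonlinear encoder with a linear
decoder whose weight matrix ``W`` (genes x terms) is constrained by the
term membership mask: latent dimension ``t`` can only reconstruct genes
annotated to term ``t``.  That makes each latent coordinate directly
readable as the activity of one perturbation term.  Two regularizers
shape the decoder:

* a **group lasso** on each annotated column, ``sum_t sqrt(d_t) *
  ||W[:, t]||_2`` — able to switch whole terms off ("pruning");
* an **L1 "soft mask"** on a second weight matrix ``W_soft`` living only
  *off* the annotation mask — letting a term recruit a few unannotated
  genes ("enrichment") without re-weighting annotated ones twice.

Counts are modelled with a negative-binomial likelihood with gene-wise
learned inverse-dispersion; conditions (batch / tissue source) enter
one-hot into the encoder input and as per-condition decoder offsets.  An
optional attention-like sigmoid gate, computed from the last encoder
hidden layer, multiplies the latent sample elementwise so the model can
focus on the terms relevant to each cell.

The network is small enough that forward and backward passes are written
directly in numpy (with an Adam optimizer); every source of randomness is
driven by the config seed, so training is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, expit, gammaln

from .dataset import ExpressionDataset
from .genesets import TermSet

__all__ = [
    "ModelConfig",
    "ModelState",
    "kl_divergence",
    "nb_log_likelihood",
    "group_lasso_penalty",
    "l1_penalty",
    "encode",
    "attention_gate",
    "decode",
    "loss",
    "train",
    "inactive_terms",
    "build_mask",
    "save_model",
    "load_model",
]

_LOGVAR_CLIP = 8.0
_ETA_CLIP = (-30.0, 15.0)
_CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters.

    Defaults follow the reference setting: 512-unit hidden layers, 4
    encoder layers, KL weight 0.005 and group-lasso weight 0.95; the
    latent dimension is always the number of terms and is not set here.
    """

    n_hidden: int = 512
    n_encoder_layers: int = 4
    alpha_kl: float = 0.005
    alpha_group: float = 0.95
    alpha_l1: float = 0.5
    use_soft_mask: bool = True
    use_attention: bool = True
    likelihood: str = "nb"
    max_epochs: int = 200
    patience: int = 15
    learning_rate: float = 1e-3
    batch_size: int = 128
    seed: int = 0
    inactive_norm_threshold: float = 1e-3
    kl_warmup_fraction: float = 0.1
    soft_mask_warmup_fraction: float = 0.3
    val_fraction: float = 0.1
    target_sum: float = 1e4

    def __post_init__(self) -> None:
        if min(self.alpha_kl, self.alpha_group, self.alpha_l1) < 0:
            raise ValueError("regularization weights must be >= 0")
        if self.likelihood != "nb":
            raise ValueError("only the negative-binomial likelihood is supported")
        if self.n_encoder_layers < 1:
            raise ValueError("need at least one encoder layer")


@dataclass
class ModelState:
    """Trained parameters plus the metadata needed to apply them."""

    config: ModelConfig
    gene_ids: list[str]
    term_ids: list[str]
    condition_labels: list[str]
    mask: np.ndarray = field(repr=False)  # genes x terms, {0,1}
    params: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    history: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def latent_dim(self) -> int:
        return len(self.term_ids)

    def condition_index(self, labels: Sequence[str]) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.condition_labels)}
        idx = np.empty(len(labels), dtype=np.int64)
        for i, lab in enumerate(labels):
            if lab not in lut:
                raise KeyError(
                    f"unknown condition {lab!r}; known: {self.condition_labels}. "
                    "Use mapping.map_query to introduce new conditions."
                )
            idx[i] = lut[lab]
        return idx

    def decoder_weights(self) -> np.ndarray:
        """Effective linear decoder ``W + W_soft`` (genes x terms)."""
        return self.params["W_dec"] + self.params["W_soft"]

    def check_mask_invariant(self, atol: float = 0.0) -> None:
        off = np.abs(self.params["W_dec"] * (1 - self.mask)).max(initial=0.0)
        on = np.abs(self.params["W_soft"] * self.mask).max(initial=0.0)
        if off > atol or on > atol:
            raise AssertionError(
                f"mask invariant violated: off-mask |W|={off}, on-mask |W_soft|={on}"
            )


# ---------------------------------------------------------------------------
# closed-form loss pieces
# ---------------------------------------------------------------------------


def kl_divergence(mu: np.ndarray, logvar: np.ndarray) -> float:
    """KL( N(mu, diag exp(logvar)) || N(0, I) ), summed over latent
    dimensions and averaged over the batch (a 1-D input is one cell)."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    logvar = np.atleast_2d(np.asarray(logvar, dtype=float))
    per_cell = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    return float(per_cell.mean())


def _nb_ll_matrix(x: np.ndarray, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Elementwise NB log-pmf, mean/inverse-dispersion parameterization."""
    log_theta_mu = np.log(theta + mean)
    return (
        gammaln(x + theta)
        - gammaln(theta)
        - gammaln(x + 1.0)
        + theta * (np.log(theta) - log_theta_mu)
        + x * (np.log(mean) - log_theta_mu)
    )


def nb_log_likelihood(x: np.ndarray, mean: np.ndarray, theta: np.ndarray) -> float:
    """Sum over genes of the NB log-pmf for one cell's count vector."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x != np.round(x)):
        raise ValueError("counts must be non-negative integers")
    mean = np.broadcast_to(np.asarray(mean, dtype=float), x.shape)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), x.shape)
    if np.any(mean <= 0) or np.any(theta <= 0):
        raise ValueError("mean and theta must be positive")
    return float(_nb_ll_matrix(x, mean, theta).sum())


def group_lasso_penalty(W: np.ndarray, support_dims: np.ndarray | None = None) -> float:
    """``sum_t sqrt(d_t) * ||W[:, t]||_2`` with ``d_t`` the column support
    size (non-zero count if not given explicitly)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2:
        raise ValueError("W must be genes x terms")
    if support_dims is None:
        support_dims = (W != 0).sum(axis=0)
    dims = np.asarray(support_dims, dtype=float)
    norms = np.linalg.norm(W, axis=0)
    return float(np.sum(np.sqrt(dims) * norms))


def l1_penalty(W_soft: np.ndarray) -> float:
    return float(np.abs(np.asarray(W_soft, dtype=float)).sum())


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------


def _normalize_log1p(counts: np.ndarray, target_sum: float) -> np.ndarray:
    lib = counts.sum(axis=1, keepdims=True)
    return np.log1p(counts / np.maximum(lib, 1.0) * target_sum)


def _one_hot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((len(idx), n))
    out[np.arange(len(idx)), idx] = 1.0
    return out


def _encoder_forward(
    params: dict[str, np.ndarray], xin: np.ndarray, n_layers: int
) -> list[np.ndarray]:
    """Return hidden activations [h_0, ..., h_{L-1}] (ReLU MLP)."""
    hs = []
    h = xin
    for l in range(n_layers):
        h = np.maximum(h @ params[f"enc_W_{l}"] + params[f"enc_b_{l}"], 0.0)
        hs.append(h)
    return hs


def _heads_forward(
    params: dict[str, np.ndarray], h: np.ndarray, use_attention: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    mu = h @ params["W_mu"] + params["b_mu"]
    logvar_raw = h @ params["W_lv"] + params["b_lv"]
    logvar = np.clip(logvar_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    if use_attention:
        gate_pre = h @ params["W_gate"] + params["b_gate"]
        gate = expit(gate_pre)
    else:
        gate_pre = np.zeros_like(mu)
        gate = np.ones_like(mu)
    return mu, logvar, gate, gate_pre


def _full_encode(
    state: ModelState, counts: np.ndarray, cond_idx: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, np.ndarray]:
    xin = np.concatenate(
        [
            _normalize_log1p(counts, state.config.target_sum),
            _one_hot(cond_idx, len(state.condition_labels)),
        ],
        axis=1,
    )
    hs = _encoder_forward(state.params, xin, state.config.n_encoder_layers)
    mu, logvar, gate, _ = _heads_forward(state.params, hs[-1], state.config.use_attention)
    return hs, mu, logvar, gate


def encode(
    state: ModelState, counts: np.ndarray, conditions: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and log-variance per term for each cell.

    ``counts`` is raw (cells x genes); library-size normalization to
    ``target_sum`` and log1p happen internally.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if counts.shape[1] != state.n_genes:
        raise ValueError(
            f"expected {state.n_genes} genes, got {counts.shape[1]}"
        )
    cond_idx = state.condition_index(list(conditions))
    _, mu, logvar, _ = _full_encode(state, counts, cond_idx)
    return mu, logvar


def attention_gate(state: ModelState, h: np.ndarray) -> np.ndarray:
    """Sigmoid gate in (0,1) per term from the last encoder hidden layer;
    identically 1 when attention is disabled."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if not state.config.use_attention:
        return np.ones((h.shape[0], state.latent_dim))
    return expit(h @ state.params["W_gate"] + state.params["b_gate"])


def decode(
    state: ModelState,
    z: np.ndarray,
    condition: str | Sequence[str],
    library: float | np.ndarray,
) -> np.ndarray:
    """NB mean per gene: ``library * exp((W + W_soft) z + offsets)``."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    labels = [condition] * z.shape[0] if isinstance(condition, str) else list(condition)
    cond_idx = state.condition_index(labels)
    eta = (
        z @ state.decoder_weights().T
        + state.params["b_gene"]
        + state.params["B_cond"][cond_idx]
    )
    eta = np.clip(eta, *_ETA_CLIP)
    lib = np.broadcast_to(np.asarray(library, dtype=float), (z.shape[0],))
    mean = lib[:, None] * np.exp(eta)
    return mean[0] if mean.shape[0] == 1 and np.isscalar(library) else mean


# ---------------------------------------------------------------------------
# loss (forward only; the trainer has its own fused forward/backward)
# ---------------------------------------------------------------------------


def loss(
    counts: np.ndarray,
    conditions: Sequence[str],
    state: ModelState,
    kl_weight: float | None = None,
    sample: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, float]]:
    """Total objective and its components on a batch.

    total = -NB log-lik + alpha_kl * KL + alpha_group * group-lasso
            + alpha_l1 * L1(soft mask)

    With ``sample=False`` the latent is the (gated) posterior mean, making
    the value deterministic; this is what validation uses.
    """
    cfg = state.config
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    cond_idx = state.condition_index(list(conditions))
    _, mu, logvar, gate = _full_encode(state, counts, cond_idx)
    if sample:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        z = mu + rng.standard_normal(mu.shape) * np.exp(0.5 * logvar)
    else:
        z = mu
    zg = gate * z
    eta = np.clip(
        zg @ state.decoder_weights().T
        + state.params["b_gene"]
        + state.params["B_cond"][cond_idx],
        *_ETA_CLIP,
    )
    lib = counts.sum(axis=1, keepdims=True)
    mean = np.maximum(lib, 1.0) * np.exp(eta)
    theta = np.exp(state.params["log_theta"])
    recon = -float(_nb_ll_matrix(counts, mean, theta).sum(axis=1).mean())
    kl = kl_divergence(mu, logvar)
    dims = state.mask.sum(axis=0)
    grp = group_lasso_penalty(state.params["W_dec"], dims)
    l1 = l1_penalty(state.params["W_soft"])
    kl_w = cfg.alpha_kl if kl_weight is None else kl_weight
    components = {
        "reconstruction": recon,
        "kl": kl,
        "kl_weighted": kl_w * kl,
        "group_lasso": grp,
        "group_lasso_weighted": cfg.alpha_group * grp,
        "l1": l1,
        "l1_weighted": cfg.alpha_l1 * l1,
    }
    total = recon + kl_w * kl + cfg.alpha_group * grp + cfg.alpha_l1 * l1
    if not np.isfinite(total):
        raise FloatingPointError(f"non-finite loss: {components}")
    components["total"] = total
    return total, components


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def build_mask(termset: TermSet, gene_ids: Sequence[str]) -> np.ndarray:
    """Membership mask on the dataset's gene order; every term must keep at
    least one gene, otherwise training cannot proceed."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    mask = np.zeros((len(gene_ids), len(termset)), dtype=np.int8)
    empty = []
    for j, t in enumerate(termset):
        rows = [pos[g] for g in t.genes if g in pos]
        if not rows:
            empty.append(t.term_id)
        mask[rows, j] = 1
    if empty:
        raise ValueError(
            f"terms with empty mask columns after gene alignment: {empty}; "
            "re-run genesets.align_terms against this dataset's genes first"
        )
    return mask


def _init_params(
    rng: np.random.Generator,
    n_genes: int,
    n_cond: int,
    n_hidden: int,
    n_layers: int,
    latent: int,
    mask: np.ndarray,
    gene_log_freq: np.ndarray,
) -> dict[str, np.ndarray]:
    params: dict[str, np.ndarray] = {}
    fan_in = n_genes + n_cond
    for l in range(n_layers):
        params[f"enc_W_{l}"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, n_hidden)
        )
        params[f"enc_b_{l}"] = np.zeros(n_hidden)
        fan_in = n_hidden
    for name in ("W_mu", "W_lv"):
        params[name] = rng.normal(0.0, 0.01, size=(n_hidden, latent))
    params["b_mu"] = np.zeros(latent)
    params["b_lv"] = np.zeros(latent)
    params["W_gate"] = np.zeros((n_hidden, latent))
    params["b_gate"] = np.zeros(latent)
    params["W_dec"] = rng.normal(0.0, 0.2, size=mask.shape) * mask
    params["W_soft"] = np.zeros(mask.shape)
    params["b_gene"] = gene_log_freq.copy()
    params["B_cond"] = np.zeros((n_cond, n_genes))
    params["log_theta"] = np.zeros(n_genes)
    return params


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _batch_grads(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    mask: np.ndarray,
    x: np.ndarray,
    xin: np.ndarray,
    cond_onehot: np.ndarray,
    lib: np.ndarray,
    eps_noise: np.ndarray,
    kl_weight: float,
    dims: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Fused forward + manual backward for one minibatch.

    Penalty gradients use the subgradient at zero (0 for both the group
    norm and the L1 term), and clipped activations pass no gradient.
    """
    n = x.shape[0]
    L = cfg.n_encoder_layers

    hs = _encoder_forward(params, xin, L)
    h = hs[-1]
    mu = h @ params["W_mu"] + params["b_mu"]
    logvar_raw = h @ params["W_lv"] + params["b_lv"]
    lv_ok = (np.abs(logvar_raw) < _LOGVAR_CLIP).astype(float)
    logvar = np.clip(logvar_raw, -_LOGVAR_CLIP, _LOGVAR_CLIP)
    sigma = np.exp(0.5 * logvar)
    z = mu + eps_noise * sigma
    if cfg.use_attention:
        gate_pre = h @ params["W_gate"] + params["b_gate"]
        gate = expit(gate_pre)
    else:
        gate = np.ones_like(z)
    zg = gate * z

    M = params["W_dec"] + params["W_soft"]
    eta_raw = zg @ M.T + params["b_gene"] + cond_onehot @ params["B_cond"]
    eta_ok = ((eta_raw > _ETA_CLIP[0]) & (eta_raw < _ETA_CLIP[1])).astype(float)
    eta = np.clip(eta_raw, *_ETA_CLIP)
    mean = lib[:, None] * np.exp(eta)
    theta = np.exp(params["log_theta"])

    recon = -float(_nb_ll_matrix(x, mean, theta).sum(axis=1).mean())
    kl = kl_divergence(mu, logvar)
    grp = group_lasso_penalty(params["W_dec"], dims)
    l1v = l1_penalty(params["W_soft"])
    total = recon + kl_weight * kl + cfg.alpha_group * grp + cfg.alpha_l1 * l1v
    if not np.isfinite(total):
        raise FloatingPointError(
            f"non-finite loss (recon={recon}, kl={kl}, group={grp}, l1={l1v})"
        )

    grads: dict[str, np.ndarray] = {}

    # reconstruction -> eta
    ratio = (x + theta) / (theta + mean)
    d_eta = -(x - mean * ratio) / n * eta_ok  # d total / d eta_raw

    # gene-wise dispersion
    d_ll_d_theta = (
        digamma(x + theta)
        - digamma(theta)
        + np.log(theta)
        - np.log(theta + mean)
        + 1.0
        - ratio
    )
    grads["log_theta"] = -(d_ll_d_theta.sum(axis=0) / n) * theta

    # decoder; the group-lasso / L1 terms are handled proximally after the
    # optimizer step, not through (sub)gradients here
    grads["b_gene"] = d_eta.sum(axis=0)
    grads["B_cond"] = cond_onehot.T @ d_eta
    dM = d_eta.T @ zg
    grads["W_dec"] = dM * mask
    if cfg.use_soft_mask:
        grads["W_soft"] = dM * (1 - mask)
    else:
        grads["W_soft"] = np.zeros_like(params["W_soft"])

    # back to latent
    d_zg = d_eta @ M
    if cfg.use_attention:
        d_gate = d_zg * z
        d_z = d_zg * gate
        d_pre = d_gate * gate * (1.0 - gate)
        grads["W_gate"] = h.T @ d_pre
        grads["b_gate"] = d_pre.sum(axis=0)
        dh = d_pre @ params["W_gate"].T
    else:
        d_z = d_zg
        grads["W_gate"] = np.zeros_like(params["W_gate"])
        grads["b_gate"] = np.zeros_like(params["b_gate"])
        dh = np.zeros_like(h)

    d_mu = d_z + kl_weight * mu / n
    d_lv = (
        d_z * eps_noise * 0.5 * sigma + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / n
    ) * lv_ok

    grads["W_mu"] = h.T @ d_mu
    grads["b_mu"] = d_mu.sum(axis=0)
    grads["W_lv"] = h.T @ d_lv
    grads["b_lv"] = d_lv.sum(axis=0)
    dh = dh + d_mu @ params["W_mu"].T + d_lv @ params["W_lv"].T

    # encoder MLP
    for l in range(L - 1, -1, -1):
        dh = dh * (hs[l] > 0)
        inp = xin if l == 0 else hs[l - 1]
        grads[f"enc_W_{l}"] = inp.T @ dh
        grads[f"enc_b_{l}"] = dh.sum(axis=0)
        if l > 0:
            dh = dh @ params[f"enc_W_{l}"].T

    return total, grads


def _enforce_masks(params: dict[str, np.ndarray], mask: np.ndarray, use_soft: bool) -> None:
    params["W_dec"] *= mask
    if use_soft:
        params["W_soft"] *= 1 - mask
    else:
        params["W_soft"][:] = 0.0


def _proximal_step(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    dims: np.ndarray,
    soft_active: bool,
) -> None:
    """Proximal operators of the two decoder penalties.

    Group lasso: each annotated column is norm-shrunk by
    ``lr * alpha_group * sqrt(d_t)`` and zeroed when the norm falls below
    that amount — whole-term pruning with exact zeros.  Soft mask:
    elementwise soft-thresholding by ``lr * alpha_l1``.
    """
    lr = cfg.learning_rate
    if cfg.alpha_group > 0:
        W = params["W_dec"]
        norms = np.linalg.norm(W, axis=0)
        shrink = lr * cfg.alpha_group * np.sqrt(dims)
        scale = np.maximum(1.0 - shrink / np.maximum(norms, 1e-12), 0.0)
        W *= scale
    if soft_active and cfg.alpha_l1 > 0:
        Ws = params["W_soft"]
        params["W_soft"] = np.sign(Ws) * np.maximum(np.abs(Ws) - lr * cfg.alpha_l1, 0.0)


def train(
    dataset: ExpressionDataset,
    termset: TermSet,
    config: ModelConfig | None = None,
    epoch_callback: Callable[[int, ModelState], None] | None = None,
    trainable: Sequence[str] | None = None,
    grad_masks: dict[str, np.ndarray] | None = None,
    initial_state: ModelState | None = None,
) -> ModelState:
    """Fit the model; deterministic given ``config.seed``.

    The latent dimension equals the number of terms.  A seeded
    ``val_fraction`` split drives early stopping (deterministic validation
    loss at the full KL weight); the KL weight is linearly annealed from 0
    over the first ``kl_warmup_fraction`` of ``max_epochs``.  The mask
    invariants (``W`` zero off-mask, ``W_soft`` zero on-mask) are enforced
    after every optimizer step.

    ``trainable``/``initial_state`` support query mapping: only the named
    parameters receive updates, everything else stays frozen.
    """
    cfg = config or ModelConfig()
    if dataset.n_cells < 2:
        raise ValueError("need at least 2 cells to train")

    x_all = dataset.dense().astype(float)
    if initial_state is None:
        mask = build_mask(termset, dataset.genes).astype(float)
        condition_labels = sorted(pd.unique(dataset.conditions.astype(str)))
        rng = np.random.default_rng(cfg.seed)
        # z = 0 then reconstructs each gene at its overall frequency
        gene_log_freq = np.log(
            np.maximum(x_all.sum(axis=0) / max(x_all.sum(), 1.0), 1e-8)
        )
        params = _init_params(
            rng,
            dataset.n_genes,
            len(condition_labels),
            cfg.n_hidden,
            cfg.n_encoder_layers,
            len(termset),
            mask,
            gene_log_freq,
        )
        state = ModelState(
            config=cfg,
            gene_ids=list(dataset.genes),
            term_ids=termset.term_ids,
            condition_labels=condition_labels,
            mask=mask,
            params=params,
        )
    else:
        state = initial_state
        cfg = state.config if config is None else cfg
        mask = state.mask
        params = state.params
        rng = np.random.default_rng(cfg.seed)

    if state.latent_dim != len(termset):
        raise ValueError(
            f"latent_dim {state.latent_dim} != number of terms {len(termset)}"
        )

    cond_idx_all = state.condition_index(list(dataset.conditions.astype(str)))
    xin_all = np.concatenate(
        [
            _normalize_log1p(x_all, cfg.target_sum),
            _one_hot(cond_idx_all, len(state.condition_labels)),
        ],
        axis=1,
    )
    lib = np.maximum(x_all.sum(axis=1), 1.0)
    cond_onehot_all = _one_hot(cond_idx_all, len(state.condition_labels))
    dims = mask.sum(axis=0)

    n = dataset.n_cells
    perm = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n)) if n >= 10 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(tr_idx) == 0:
        tr_idx, val_idx = perm, perm[:0]

    opt = _Adam(params, cfg.learning_rate)
    trainable_set = set(trainable) if trainable is not None else None
    warmup = max(1, int(np.ceil(cfg.kl_warmup_fraction * cfg.max_epochs)))
    soft_warmup = int(np.ceil(cfg.soft_mask_warmup_fraction * cfg.max_epochs))
    decoder_trainable = trainable_set is None or "W_dec" in trainable_set
    soft_trainable = trainable_set is None or "W_soft" in trainable_set

    best_val = np.inf
    best_params: dict[str, np.ndarray] | None = None
    best_epoch = 0
    bad_epochs = 0
    rows = []

    def _val_loss() -> float:
        if len(val_idx) == 0:
            return np.nan
        tot, _ = _eval_total(
            params, cfg, mask, x_all[val_idx], xin_all[val_idx],
            cond_onehot_all[val_idx], lib[val_idx], cfg.alpha_kl, dims,
        )
        return tot

    for epoch in range(1, cfg.max_epochs + 1):
        kl_w = cfg.alpha_kl * min(1.0, epoch / warmup)
        # annotated columns establish themselves before off-mask
        # recruitment opens, otherwise the cheap soft path can absorb a
        # term's genes and let the group lasso kill the annotated column
        soft_active = cfg.use_soft_mask and soft_trainable and epoch > soft_warmup
        order = tr_idx[rng.permutation(len(tr_idx))]
        epoch_tot = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            bidx = order[start : start + cfg.batch_size]
            eps_noise = rng.standard_normal((len(bidx), state.latent_dim))
            tot, grads = _batch_grads(
                params, cfg, mask, x_all[bidx], xin_all[bidx],
                cond_onehot_all[bidx], lib[bidx], eps_noise, kl_w, dims,
            )
            if not soft_active:
                grads.pop("W_soft", None)
            if trainable_set is not None:
                grads = {k: g for k, g in grads.items() if k in trainable_set}
            if grad_masks:
                for k, m in grad_masks.items():
                    if k in grads:
                        grads[k] = grads[k] * m
            opt.step(params, grads)
            _enforce_masks(params, mask, cfg.use_soft_mask)
            if decoder_trainable:
                _proximal_step(params, cfg, dims, soft_active)
                _enforce_masks(params, mask, cfg.use_soft_mask)
            epoch_tot += tot
            n_batches += 1
        val = _val_loss()
        rows.append(
            {
                "epoch": epoch,
                "train_total": epoch_tot / max(n_batches, 1),
                "val_total": val,
                "kl_weight": kl_w,
            }
        )
        if epoch_callback is not None:
            state.history = pd.DataFrame(rows)
            epoch_callback(epoch, state)
        if len(val_idx) > 0:
            if val < best_val - 1e-6:
                best_val = val
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if epoch > warmup and bad_epochs > cfg.patience:
                    break

    if best_params is not None:
        for k in params:
            params[k] = best_params[k]
    state.history = pd.DataFrame(rows)
    state.history.attrs["best_epoch"] = best_epoch
    state.check_mask_invariant()
    return state


def _eval_total(
    params: dict[str, np.ndarray],
    cfg: ModelConfig,
    mask: np.ndarray,
    x: np.ndarray,
    xin: np.ndarray,
    cond_onehot: np.ndarray,
    lib: np.ndarray,
    kl_weight: float,
    dims: np.ndarray,
) -> tuple[float, dict[str, float]]:
    """Deterministic (z = gated posterior mean) objective for validation."""
    hs = _encoder_forward(params, xin, cfg.n_encoder_layers)
    mu, logvar, gate, _ = _heads_forward(params, hs[-1], cfg.use_attention)
    zg = gate * mu
    M = params["W_dec"] + params["W_soft"]
    eta = np.clip(zg @ M.T + params["b_gene"] + cond_onehot @ params["B_cond"], *_ETA_CLIP)
    mean = lib[:, None] * np.exp(eta)
    theta = np.exp(params["log_theta"])
    recon = -float(_nb_ll_matrix(x, mean, theta).sum(axis=1).mean())
    kl = kl_divergence(mu, logvar)
    grp = group_lasso_penalty(params["W_dec"], dims)
    l1v = l1_penalty(params["W_soft"])
    total = recon + kl_weight * kl + cfg.alpha_group * grp + cfg.alpha_l1 * l1v
    return total, {"reconstruction": recon, "kl": kl, "group_lasso": grp, "l1": l1v}


def inactive_terms(state: ModelState, threshold: float | None = None) -> list[str]:
    """Terms pruned by the group lasso: combined decoder column norm
    ``||W[:,t]|| + ||W_soft[:,t]||`` below the threshold."""
    thr = state.config.inactive_norm_threshold if threshold is None else threshold
    norms = np.linalg.norm(state.params["W_dec"], axis=0) + np.linalg.norm(
        state.params["W_soft"], axis=0
    )
    return [t for t, v in zip(state.term_ids, norms) if v < thr]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(state: ModelState, directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "params").mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": _CHECKPOINT_VERSION,
        "config": dataclasses.asdict(state.config),
        "gene_ids": state.gene_ids,
        "term_ids": state.term_ids,
        "condition_labels": state.condition_labels,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
    np.save(directory / "mask.npy", state.mask)
    for name, arr in state.params.items():
        np.save(directory / "params" / f"{name}.npy", arr)
    if len(state.history):
        state.history.to_csv(directory / "history.csv", index=False)


def load_model(directory: str | Path) -> ModelState:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text(encoding="utf-8"))
    if meta["format_version"] != _CHECKPOINT_VERSION:
        warnings.warn(
            f"checkpoint version {meta['format_version']} != {_CHECKPOINT_VERSION}",
            stacklevel=2,
        )
    params = {
        p.stem: np.load(p) for p in sorted((directory / "params").glob("*.npy"))
    }
    history = pd.DataFrame()
    if (directory / "history.csv").exists():
        history = pd.read_csv(directory / "history.csv")
    return ModelState(
        config=ModelConfig(**meta["config"]),
        gene_ids=list(meta["gene_ids"]),
        term_ids=list(meta["term_ids"]),
        condition_labels=list(meta["condition_labels"]),
        mask=np.load(directory / "mask.npy"),
        params=params,
        history=history,
    )
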