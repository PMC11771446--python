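"""Reference-to-query projection, label transfer, and cross-dataset overlap.

A trained model acts as the *reference*.  Query datasets are projected
into the same term latent space with the reference core (encoder body,
decoder weights, dispersions) frozen; only embeddings for condition
labels the reference never saw are added and briefly fine-tuned
(architecture-surgery style).  Reference influence scores are therefore
immutable under mapping, which the frozen-core hash check asserts.
"""

from __future__ import annotations

import copy
import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .dataset import ExpressionDataset
from .genesets import Term, TermSet
from .model import ModelConfig, ModelState, train
from .scoring import (
    ENRICHMENT_THRESHOLD,
    EnrichmentResult,
    InfluenceScoreMatrix,
    enrichment,
    influence_scores,
)

__all__ = [
    "QueryProjection",
    "frozen_core_hash",
    "map_query",
    "label_transfer",
    "term_overlap",
    "cross_validate",
]

_MIN_SUPPORT_COVERAGE = 0.9

# parameters a query is allowed to extend; everything else is the frozen core
_CONDITION_PARAMS = ("enc_W_0", "B_cond")


@dataclass
class QueryProjection:
    scores: InfluenceScoreMatrix
    state: ModelState  # possibly extended with new condition embeddings
    new_conditions: list[str]
    fine_tune_epochs: int
    coverage: float
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


def frozen_core_hash(state: ModelState, n_ref_conditions: int | None = None) -> str:
    """SHA-256 over every parameter tensor except condition embeddings
    added after the first ``n_ref_conditions`` (default: all current)
    conditions — i.e. the part mapping promises never to touch."""
    n_ref = (
        len(state.condition_labels) if n_ref_conditions is None else n_ref_conditions
    )
    h = hashlib.sha256()
    for name in sorted(state.params):
        arr = state.params[name]
        if name in _CONDITION_PARAMS:
            # only the rows tied to reference conditions are core
            if name == "enc_W_0":
                arr = arr[: state.n_genes + n_ref]
            else:
                arr = arr[:n_ref]
        h.update(name.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _align_query_genes(
    state: ModelState, query: ExpressionDataset
) -> tuple[np.ndarray, float]:
    """Reindex query counts onto the model's gene order.

    Missing genes are zero-filled; coverage is measured over the genes in
    the decoder's term support, which is what the latent space can see.
    """
    qpos = {g: i for i, g in enumerate(query.genes)}
    cols = np.array([qpos.get(g, -1) for g in state.gene_ids])
    support = np.asarray(state.mask).sum(axis=1) > 0
    present = cols >= 0
    coverage = float(present[support].mean()) if support.any() else float(present.mean())
    if coverage < _MIN_SUPPORT_COVERAGE:
        raise ValueError(
            f"query covers only {coverage:.1%} of term-support genes "
            f"(floor {_MIN_SUPPORT_COVERAGE:.0%}); gene ids may need harmonization"
        )
    dense = query.dense().astype(float)
    out = np.zeros((query.n_cells, state.n_genes))
    out[:, present] = dense[:, cols[present]]
    if coverage < 1.0:
        warnings.warn(
            f"{(~present[support]).sum()} term-support genes missing from the "
            f"query were zero-filled (coverage {coverage:.1%})",
            stacklevel=3,
        )
    return out, coverage


def map_query(
    state: ModelState,
    query: ExpressionDataset,
    fine_tune_epochs: int = 20,
    seed: int = 0,
    retrain_core: bool = False,
) -> QueryProjection:
    """Project query cells into the reference term space.

    Conditions already known to the reference need no fine-tuning; unseen
    condition labels receive fresh embedding vectors (encoder one-hot rows
    and decoder offsets) trained for ``fine_tune_epochs`` with every other
    parameter frozen.  ``retrain_core=True`` instead fine-tunes *all*
    parameters on the query — the frozen-core guarantee (and hence
    comparability of reference scores) is deliberately given up.
    """
    counts, coverage = _align_query_genes(state, query)
    q_conditions = list(query.conditions.astype(str))
    new_conditions = sorted(set(q_conditions) - set(state.condition_labels))

    if not new_conditions and not retrain_core:
        scores = influence_scores(
            state,
            ExpressionDataset(
                counts=counts.astype(np.int64),
                genes=list(state.gene_ids),
                obs=query.obs.copy(),
            ),
        )
        return QueryProjection(
            scores=scores,
            state=state,
            new_conditions=[],
            fine_tune_epochs=0,
            coverage=coverage,
        )

    core_before = frozen_core_hash(state)
    ext = copy.deepcopy(state)
    rng = np.random.default_rng(seed)
    n_new = len(new_conditions)
    # grow the condition one-hot block of the encoder input and the decoder offsets
    w0 = ext.params["enc_W_0"]
    new_rows = rng.normal(0.0, 0.01, size=(n_new, w0.shape[1]))
    ext.params["enc_W_0"] = np.vstack([w0, new_rows])
    ext.params["B_cond"] = np.vstack(
        [ext.params["B_cond"], np.zeros((n_new, ext.n_genes))]
    )
    ext.condition_labels = list(state.condition_labels) + new_conditions

    aligned_query = ExpressionDataset(
        counts=counts.astype(np.int64),
        genes=list(state.gene_ids),
        obs=query.obs.copy(),
    )
    history = pd.DataFrame()
    if fine_tune_epochs > 0:
        ft_cfg = copy.deepcopy(ext.config)
        ft_cfg.max_epochs = fine_tune_epochs
        ft_cfg.patience = fine_tune_epochs
        ft_cfg.kl_warmup_fraction = 0.0
        ft_cfg.seed = seed
        ft_cfg.val_fraction = 0.0
        ext.config = ft_cfg
        termset = TermSet(
            tuple(
                Term(t, "", tuple(g for g, m in zip(ext.gene_ids, ext.mask[:, j]) if m))
                for j, t in enumerate(ext.term_ids)
            )
        )
        if retrain_core:
            ext = train(aligned_query, termset, config=ft_cfg, initial_state=ext)
        else:
            # updates flow only into the freshly added condition rows
            n_ref = len(state.condition_labels)
            w0_mask = np.zeros_like(ext.params["enc_W_0"])
            w0_mask[state.n_genes + n_ref :] = 1.0
            bcond_mask = np.zeros_like(ext.params["B_cond"])
            bcond_mask[n_ref:] = 1.0
            ext = train(
                aligned_query,
                termset,
                config=ft_cfg,
                trainable=list(_CONDITION_PARAMS),
                grad_masks={"enc_W_0": w0_mask, "B_cond": bcond_mask},
                initial_state=ext,
            )
        history = ext.history

    if not retrain_core and (
        frozen_core_hash(ext, n_ref_conditions=len(state.condition_labels))
        != core_before
    ):
        raise AssertionError("frozen core changed during query mapping")

    scores = influence_scores(ext, aligned_query)
    return QueryProjection(
        scores=scores,
        state=ext,
        new_conditions=new_conditions,
        fine_tune_epochs=fine_tune_epochs,
        coverage=coverage,
        history=history,
    )


def label_transfer(
    ref_scores: InfluenceScoreMatrix,
    ref_labels: Sequence[str] | pd.Series,
    query_scores: InfluenceScoreMatrix,
    k: int = 15,
    true_labels: Sequence[str] | pd.Series | None = None,
) -> tuple[list[str], float | None]:
    """kNN majority vote in influence-score space (Euclidean).

    Ties between equally frequent labels go to the one with the smallest
    summed neighbor distance.  Returns predicted labels and, when truth is
    supplied, the accuracy.
    """
    if list(ref_scores.terms) != list(query_scores.terms):
        raise ValueError("reference and query must share the same term order")
    labels = np.asarray(pd.Series(ref_labels).astype(str))
    if len(labels) != len(ref_scores.cells):
        raise ValueError("one reference label per reference cell required")
    if k > len(labels):
        raise ValueError(f"k={k} exceeds the {len(labels)} reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(ref_scores.scores)
    dist, idx = nn.kneighbors(query_scores.scores)
    predicted: list[str] = []
    for drow, irow in zip(dist, idx):
        votes: dict[str, tuple[int, float]] = {}
        for d, i in zip(drow, irow):
            cnt, tot = votes.get(labels[i], (0, 0.0))
            votes[labels[i]] = (cnt + 1, tot + d)
        predicted.append(
            min(votes, key=lambda lab: (-votes[lab][0], votes[lab][1], lab))
        )
    accuracy = None
    if true_labels is not None:
        truth = np.asarray(pd.Series(true_labels).astype(str))
        accuracy = float(np.mean(truth == np.asarray(predicted)))
    return predicted, accuracy


def term_overlap(
    enr_a: EnrichmentResult,
    enr_b: EnrichmentResult,
    groups_a: Sequence[str] | None = None,
    groups_b: Sequence[str] | None = None,
    min_groups: int = 2,
) -> dict:
    """Cross-dataset agreement of significant terms.

    A term enters a dataset's set only when significant in at least
    ``min_groups`` of that dataset's selected groups — recurrent hits,
    not one-off cluster calls.  Reports the two sets, their intersection,
    Jaccard, and containment relative to each side.
    """

    def _recurrent(enr: EnrichmentResult, groups) -> set[str]:
        table = enr.table
        if groups is not None:
            groups = list(groups)
            if not groups:
                raise ValueError("empty group selection")
            table = table[table["group"].isin(groups)]
        sig = table[table["significant"]]
        counts = sig.groupby("term")["group"].nunique()
        return set(counts[counts >= min_groups].index)

    set_a = _recurrent(enr_a, groups_a)
    set_b = _recurrent(enr_b, groups_b)
    inter = set_a & set_b
    union = set_a | set_b
    return {
        "set_a": sorted(set_a),
        "set_b": sorted(set_b),
        "overlap": sorted(inter),
        "jaccard": len(inter) / len(union) if union else 0.0,
        "containment_a": len(inter) / len(set_a) if set_a else 0.0,
        "containment_b": len(inter) / len(set_b) if set_b else 0.0,
    }


def cross_validate(
    dataset: ExpressionDataset,
    termset: TermSet,
    config: ModelConfig,
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = ENRICHMENT_THRESHOLD,
) -> dict:
    """k-fold reproducibility of the per-type significant-term calls.

    Cells are partitioned into seeded folds (sizes differing by at most
    one); each fold is scored by a model trained on the remaining folds,
    enrichment is computed per cell type, and agreement is the mean
    pairwise Jaccard of the per-type significant-term sets across folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = dataset.n_cells
    rng = np.random.default_rng(seed)
    fold_of = np.zeros(n, dtype=int)
    perm = rng.permutation(n)
    for f in range(n_folds):
        fold_of[perm[f::n_folds]] = f

    per_fold_sets: list[dict[str, set[str]]] = []
    for f in range(n_folds):
        test_idx = np.flatnonzero(fold_of == f)
        train_idx = np.flatnonzero(fold_of != f)
        cfg = copy.deepcopy(config)
        cfg.seed = int(np.random.default_rng(seed + 104729 * (f + 1)).integers(2**31 - 1))
        state = train(dataset.subset(train_idx), termset, cfg)
        held = dataset.subset(test_idx)
        scores = influence_scores(state, held)
        enr = enrichment(
            scores, held.cell_types, threshold=threshold, seed=seed + f
        )
        per_fold_sets.append(
            {g: set(enr.significant_terms(g)) for g in pd.unique(held.cell_types)}
        )

    all_types = sorted(set().union(*[set(d) for d in per_fold_sets]))
    per_type: dict[str, float] = {}
    for ct in all_types:
        folds_with = [d[ct] for d in per_fold_sets if ct in d]
        if len(folds_with) < len(per_fold_sets):
            warnings.warn(
                f"cell type {ct!r} missing from some folds; excluded from agreement",
                stacklevel=2,
            )
        if len(folds_with) < 2:
            continue
        jaccards = []
        for i in range(len(folds_with)):
            for j in range(i + 1, len(folds_with)):
                a, b = folds_with[i], folds_with[j]
                union = a | b
                jaccards.append(len(a & b) / len(union) if union else 1.0)
        per_type[ct] = float(np.mean(jaccards))
    return {
        "per_type_jaccard": per_type,
        "mean_jaccard": float(np.mean(list(per_type.values()))) if per_type else np.nan,
        "fold_sizes": [int((fold_of == f).sum()) for f in range(n_folds)],
        "per_fold_significant": [
            {k: sorted(v) for k, v in d.items()} for d in per_fold_sets
        ],
    }
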