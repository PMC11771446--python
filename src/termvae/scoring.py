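"""Influence scores, Bayes-factor enrichment, and gene attribution.

The *influence term score* of term ``t`` in cell ``i`` is the signed,
attention-gated posterior mean ``g_it * mu_it`` — a deterministic readout
of how strongly that perturbation's program is inferred to act in the
cell, and in which direction.

Group-level testing uses a Bayes factor built from the exceedance
probability ``p = P(z_a > z_b)`` over cross pairs of scores from the two
groups:

    log BF = ln((p + eps) / (1 - p + eps))

A (group, term) pair is called significant when ``|log BF| > 2.3``
("strong evidence"); ``|log BF|`` is reported as the enrichment score.
No further multiple-testing correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .model import ModelState, _full_encode

__all__ = [
    "InfluenceScoreMatrix",
    "EnrichmentResult",
    "influence_scores",
    "bayes_factor",
    "enrichment",
    "permutation_fdr",
    "top_terms",
    "gene_contributions",
    "ENRICHMENT_THRESHOLD",
    "EXHAUSTIVE_PAIR_LIMIT",
]

ENRICHMENT_THRESHOLD = 2.3
EXHAUSTIVE_PAIR_LIMIT = 1_000_000


@dataclass
class InfluenceScoreMatrix:
    """Cells x terms signed latent scores."""

    cells: list[str]
    terms: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cells), len(self.terms)):
            raise ValueError("score matrix shape mismatch")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cells, columns=self.terms)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="cell_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InfluenceScoreMatrix":
        df = pd.read_csv(path, sep="\t", index_col="cell_id")
        return cls(list(df.index.astype(str)), list(df.columns), df.to_numpy())


@dataclass
class EnrichmentResult:
    """One row per (group, term); ``significant`` iff |log_bf| > threshold."""

    table: pd.DataFrame  # columns: group, term, log_bf, sign, enrichment_score, significant
    threshold: float = ENRICHMENT_THRESHOLD

    def significant_terms(self, group: str) -> list[str]:
        sub = self.table[(self.table["group"] == group) & self.table["significant"]]
        return list(sub["term"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = ENRICHMENT_THRESHOLD):
        df = pd.read_csv(path, sep="\t")
        return cls(df, threshold)


def influence_scores(
    state: ModelState,
    dataset: ExpressionDataset,
    sample: bool = False,
    seed: int = 0,
) -> InfluenceScoreMatrix:
    """Signed per-cell term scores: gated posterior means by default.

    ``sample=True`` gates a seeded posterior draw instead — a sensitivity
    toggle; the deterministic means are what downstream testing uses.
    """
    if list(dataset.genes) != list(state.gene_ids):
        for a, b in zip(dataset.genes, state.gene_ids):
            if a != b:
                raise ValueError(f"gene mismatch with model: {a!r} != {b!r}")
        raise ValueError(
            f"gene count mismatch: dataset {dataset.n_genes} vs model {state.n_genes}"
        )
    counts = dataset.dense().astype(float)
    cond_idx = state.condition_index(list(dataset.conditions.astype(str)))
    _, mu, logvar, gate = _full_encode(state, counts, cond_idx)
    z = mu
    if sample:
        rng = np.random.default_rng(seed)
        z = mu + rng.standard_normal(mu.shape) * np.exp(0.5 * logvar)
    return InfluenceScoreMatrix(dataset.cell_ids, list(state.term_ids), gate * z)


def _exceedance(a: np.ndarray, b: np.ndarray) -> float:
    """P(value from a > value from b) over all cross pairs (strict)."""
    b_sorted = np.sort(b)
    wins = np.searchsorted(b_sorted, a, side="left").sum()
    return float(wins) / (len(a) * len(b))


def bayes_factor(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    mode: Literal["exhaustive", "sampled"] = "exhaustive",
    n_pairs: int = 100_000,
    eps: float = 1e-8,
    seed: int = 0,
) -> float:
    """Log Bayes factor of group-a scores exceeding group-b scores.

    Exhaustive mode enumerates all |a| x |b| cross pairs; sampled mode
    draws ``n_pairs`` uniform pairs with a seeded generator.  ``eps``
    bounds the log-odds at ``ln((1 + eps)/eps)`` when p saturates.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both score groups must be non-empty")
    if not 0.0 <= eps < 0.5:
        raise ValueError("eps must be in [0, 0.5)")
    if mode == "exhaustive":
        p = _exceedance(a, b)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        ia = rng.integers(0, len(a), size=n_pairs)
        ib = rng.integers(0, len(b), size=n_pairs)
        p = float(np.mean(a[ia] > b[ib]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if eps == 0.0 and p in (0.0, 1.0):
        raise ZeroDivisionError("p saturated with eps=0; use a positive eps")
    return float(np.log((p + eps) / (1.0 - p + eps)))


def enrichment(
    scores: InfluenceScoreMatrix,
    groups: Sequence[str] | pd.Series,
    threshold: float = ENRICHMENT_THRESHOLD,
    mode: Literal["auto", "exhaustive", "sampled"] = "auto",
    n_pairs: int = 100_000,
    eps: float = 1e-8,
    seed: int = 0,
) -> EnrichmentResult:
    """One-vs-rest Bayes-factor test for every (group, term) pair.

    ``mode="auto"`` enumerates all cross pairs when their number is at
    most 10^6 and falls back to seeded pair sampling above that.  Groups
    with fewer than 2 cells are skipped with a warning.
    """
    labels = np.asarray(pd.Series(groups).astype(str))
    if len(labels) != len(scores.cells):
        raise ValueError("one label per cell required")
    uniq = sorted(pd.unique(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for group in uniq:
        in_g = labels == group
        n_a, n_b = int(in_g.sum()), int((~in_g).sum())
        if n_a < 2:
            warnings.warn(f"group {group!r} has <2 cells; skipped", stacklevel=2)
            continue
        use_mode = mode
        if mode == "auto":
            use_mode = "exhaustive" if n_a * n_b <= EXHAUSTIVE_PAIR_LIMIT else "sampled"
        for j, term in enumerate(scores.terms):
            sa = scores.scores[in_g, j]
            sb = scores.scores[~in_g, j]
            log_bf = bayes_factor(
                sa, sb, mode=use_mode, n_pairs=n_pairs, eps=eps,
                seed=seed + 7919 * j,
            )
            sign = "+" if sa.mean() >= sb.mean() else "-"
            rows.append(
                {
                    "group": group,
                    "term": term,
                    "log_bf": log_bf,
                    "sign": sign,
                    "enrichment_score": abs(log_bf),
                    "significant": abs(log_bf) > threshold,
                }
            )
    return EnrichmentResult(pd.DataFrame(rows), threshold)


def permutation_fdr(
    scores: InfluenceScoreMatrix,
    groups: Sequence[str] | pd.Series,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    **enrichment_kwargs,
) -> pd.DataFrame:
    """Benjamini-Hochberg control on permutation p-values (optional path).

    For each (group, term), the p-value is the fraction of label
    permutations whose |log BF| meets or exceeds the observed one (with
    the +1 pseudocount); BH is applied across all pairs.  This is an
    alternative to the plain 2.3 rule, off the default path.
    """
    from statsmodels.stats.multitest import multipletests

    labels = pd.Series(groups).astype(str).reset_index(drop=True)
    observed = enrichment(scores, labels, seed=seed, **enrichment_kwargs).table
    observed = observed.set_index(["group", "term"])
    exceed = pd.Series(0, index=observed.index, dtype=float)
    rng = np.random.default_rng(seed)
    for _ in range(n_permutations):
        shuffled = labels.iloc[rng.permutation(len(labels))].reset_index(drop=True)
        null = enrichment(
            scores, shuffled, seed=int(rng.integers(2**31 - 1)), **enrichment_kwargs
        ).table.set_index(["group", "term"])
        null = null["enrichment_score"].reindex(exceed.index)
        exceed += (null >= observed["enrichment_score"]).astype(float)
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    rejected, qvals, _, _ = multipletests(pvals.to_numpy(), alpha=alpha, method="fdr_bh")
    out = observed.reset_index()
    out["p_value"] = pvals.to_numpy()
    out["q_value"] = qvals
    out["significant_fdr"] = rejected
    return out


def top_terms(
    enr: EnrichmentResult, k: int = 10
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Per-group top-k significant terms by enrichment score, plus the
    recurrence count of each term across the groups' top-k lists."""
    per_group: dict[str, list[str]] = {}
    for group in pd.unique(enr.table["group"]):
        sub = enr.table[(enr.table["group"] == group) & enr.table["significant"]]
        ordered = sub.sort_values(
            ["enrichment_score", "term"], ascending=[False, True]
        )
        per_group[str(group)] = list(ordered["term"].head(k)) if k > 0 else []
    recurrence: dict[str, int] = {}
    for terms in per_group.values():
        for t in terms:
            recurrence[t] = recurrence.get(t, 0) + 1
    return per_group, recurrence


def gene_contributions(
    state: ModelState, term: str, top_n: int | None = None
) -> pd.DataFrame:
    """Genes of a term's support ranked by absolute decoder weight.

    The support is the annotated mask column plus any genes the soft mask
    recruited (non-zero ``W_soft``); genes outside it never appear.  Ties
    in |weight| are broken lexically by gene id.
    """
    if term not in state.term_ids:
        raise KeyError(f"unknown term {term!r}")
    j = state.term_ids.index(term)
    w = state.params["W_dec"][:, j] + state.params["W_soft"][:, j]
    support = (state.mask[:, j] > 0) | (state.params["W_soft"][:, j] != 0)
    df = pd.DataFrame(
        {
            "gene": [g for g, s in zip(state.gene_ids, support) if s],
            "weight": w[support],
        }
    )
    df["abs_weight"] = df["weight"].abs()
    df["annotated"] = [
        bool(state.mask[i, j]) for i, s in enumerate(support) if s
    ]
    df = df.sort_values(
        ["abs_weight", "gene"], ascending=[False, True], ignore_index=True
    )
    if top_n is not None:
        df = df.head(top_n).reset_index(drop=True)
    return df
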