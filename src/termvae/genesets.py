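"""Perturbation term (gene set) handling.

A *term* is a named gene set derived from one perturbation signature
(compound x cell line x time x direction).  Terms define the latent
dimensions of the model: the genes x terms binary membership mask built
here constrains the linear decoder, so term order is contractual and is
preserved everywhere downstream.

Gene identifiers are matched exactly (case-sensitive, no alias mapping).
If your expression data and term collection use different id schemes,
harmonize them upstream before calling :func:`align_terms`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Direction",
    "Term",
    "TermSet",
    "MembershipMask",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "extract_signature_terms",
    "align_terms",
]


class Direction(enum.Enum):
    """Sign of the differential-expression signature a term came from."""

    UP = "UP"
    DOWN = "DOWN"
    NA = "NA"


class GmtParseError(ValueError):
    """Raised for malformed GMT content; message carries the line number."""


@dataclass(frozen=True)
class Term:
    term_id: str
    description: str
    genes: tuple[str, ...]
    direction: Direction = Direction.NA

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if len(self.genes) == 0:
            raise ValueError(f"term {self.term_id!r} has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"term {self.term_id!r} has duplicate genes")


@dataclass(frozen=True)
class TermSet:
    """An ordered collection of terms; order defines latent-dimension order."""

    terms: tuple[Term, ...]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate term_id {dup!r}")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    @property
    def term_ids(self) -> list[str]:
        return [t.term_id for t in self.terms]

    def __getitem__(self, term_id: str) -> Term:
        for t in self.terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    def gene_universe(self) -> list[str]:
        """Union of member genes, in first-seen order."""
        seen: dict[str, None] = {}
        for t in self.terms:
            for g in t.genes:
                seen.setdefault(g, None)
        return list(seen)


@dataclass(frozen=True)
class MembershipMask:
    """Binary genes x terms membership matrix fed to the masked decoder.

    Row order follows the gene universe the mask was aligned against; the
    expression matrix handed to the model must use the same gene order.
    """

    genes: tuple[str, ...]
    terms: tuple[str, ...]
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.shape != (len(self.genes), len(self.terms)):
            raise ValueError(
                f"mask shape {m.shape} does not match "
                f"({len(self.genes)}, {len(self.terms)})"
            )
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")

    @property
    def column_sums(self) -> np.ndarray:
        return np.asarray(self.mask).sum(axis=0)


def _parse_direction(term_id: str) -> Direction:
    if term_id.endswith("_UP"):
        return Direction.UP
    if term_id.endswith("_DOWN"):
        return Direction.DOWN
    return Direction.NA


def read_gmt(path: str | Path) -> TermSet:
    """Read a GMT file (one term per line: id, description, genes...).

    Duplicate genes within a line are collapsed keeping first occurrence;
    a trailing ``_UP``/``_DOWN`` suffix on the term id sets the direction.
    Blank lines are ignored.
    """
    path = Path(path)
    terms: list[Term] = []
    seen_ids: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields "
                    f"(id, description, genes...), got {len(fields)}"
                )
            term_id, description = fields[0], fields[1]
            if term_id in seen_ids:
                raise GmtParseError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
            seen_ids.add(term_id)
            genes: dict[str, None] = {}
            for g in fields[2:]:
                if g:  # tolerate trailing empty fields
                    genes.setdefault(g, None)
            if not genes:
                raise GmtParseError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms.append(
                Term(term_id, description, tuple(genes), _parse_direction(term_id))
            )
    return TermSet(tuple(terms))


def write_gmt(termset: TermSet, path: str | Path) -> None:
    """Write a TermSet as GMT; round-trips exactly through :func:`read_gmt`."""
    path = Path(path)
    lines = []
    for t in termset:
        if "\t" in t.description or "\n" in t.description:
            raise ValueError(
                f"term {t.term_id!r}: description contains a reserved "
                "delimiter (tab/newline)"
            )
        lines.append("\t".join([t.term_id, t.description, *t.genes]))
    path.write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def extract_signature_terms(
    scores: pd.DataFrame,
    threshold: float = 2.0,
    max_genes: int = 500,
    min_genes: int = 5,
) -> TermSet:
    """Derive UP/DOWN terms from a genes x signatures differential-score matrix.

    For each signature column ``s``, the UP term collects genes with
    ``score >= +threshold`` and the DOWN term genes with
    ``score <= -threshold`` — the genes significantly differentially
    expressed under that perturbation.  Each term is capped to
    ``max_genes`` by descending ``|score|`` (ties broken lexically by gene
    id for deterministic builds) and dropped if fewer than ``min_genes``
    genes survive.  Emitted ids are ``<signature>_UP`` / ``<signature>_DOWN``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_genes < 1 or max_genes < min_genes:
        raise ValueError("require max_genes >= min_genes >= 1")
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("signature scores contain non-finite entries")
    if scores.index.has_duplicates:
        raise ValueError("duplicate gene ids in score matrix index")

    terms: list[Term] = []
    genes_idx = scores.index.to_numpy()
    for sig in scores.columns:
        col = scores[sig].to_numpy(dtype=float)
        for suffix, sel in (("UP", col >= threshold), ("DOWN", col <= -threshold)):
            idx = np.flatnonzero(sel)
            if idx.size < min_genes:
                continue
            order = sorted(idx, key=lambda i: (-abs(col[i]), str(genes_idx[i])))
            chosen = order[:max_genes]
            terms.append(
                Term(
                    term_id=f"{sig}_{suffix}",
                    description=f"genes with |score| >= {threshold} ({suffix}) in {sig}",
                    genes=tuple(str(genes_idx[i]) for i in chosen),
                    direction=Direction[suffix],
                )
            )
    if not terms:
        import warnings

        warnings.warn(
            "no signature passed the threshold; returning an empty TermSet",
            stacklevel=2,
        )
        return TermSet(())
    return TermSet(tuple(terms))


def align_terms(
    termset: TermSet,
    gene_universe: Sequence[str] | Iterable[str],
    min_genes: int = 5,
) -> tuple[TermSet, MembershipMask]:
    """Intersect terms with a gene universe and build the membership mask.

    Terms retaining fewer than ``min_genes`` genes are removed.  Mask rows
    follow ``gene_universe`` order exactly; columns follow the surviving
    term order.
    """
    universe = list(gene_universe)
    if not universe:
        raise ValueError("gene_universe is empty")
    if len(set(universe)) != len(universe):
        raise ValueError("gene_universe contains duplicate ids")
    pos = {g: i for i, g in enumerate(universe)}

    kept: list[Term] = []
    for t in termset:
        surviving = tuple(g for g in t.genes if g in pos)
        if len(surviving) >= min_genes:
            kept.append(Term(t.term_id, t.description, surviving, t.direction))
    if not kept:
        raise ValueError(
            "no terms survive alignment; lower min_genes or harmonize gene ids "
            "between the term collection and the expression data"
        )
    aligned = TermSet(tuple(kept))
    mask = np.zeros((len(universe), len(kept)), dtype=np.int8)
    for j, t in enumerate(kept):
        for g in t.genes:
            mask[pos[g], j] = 1
    return aligned, MembershipMask(tuple(universe), tuple(aligned.term_ids), mask)
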