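"""Permutation tests for enrichment of validated miRNA targets.

Given a database of experimentally validated miRNA->target pairs, a set of
regulated miRNAs and a differentially expressed gene list, the observed
overlap o = |union of the regulated miRNAs' targets ∩ DE genes| is
compared against a permutation null built under one of two strategies:

- MIRNA_NULL: draw as many miRNAs as were regulated, pool their targets;
- GENE_NULL: draw as many genes as the regulated miRNAs target in total.

The p-value is the plain exceedance fraction p = #{e_i > o} / N with
strict inequality and no +1 correction — kept literally, at the cost of a
slight anti-conservativeness (p can be exactly 0).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MIRNA_NULL = "MIRNA_NULL"
GENE_NULL = "GENE_NULL"


class TargetDB:
    """miRNA -> target-gene pair table with set and matrix views."""

    def __init__(self, pairs: pd.DataFrame | Iterable[tuple[str, str]]):
        if not isinstance(pairs, pd.DataFrame):
            pairs = pd.DataFrame(list(pairs), columns=["mirna", "gene"])
        pairs = pairs[["mirna", "gene"]].drop_duplicates().reset_index(drop=True)
        self.pairs = pairs
        self.mirnas: list[str] = sorted(pairs["mirna"].unique())
        self.genes: list[str] = sorted(pairs["gene"].unique())
        self._by_mirna = {
            m: set(g) for m, g in pairs.groupby("mirna")["gene"]
        }
        self._matrix: np.ndarray | None = None

    def targets_of(self, mirnas: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for m in mirnas:
            out |= self._by_mirna.get(m, set())
        return out

    @property
    def matrix(self) -> np.ndarray:
        """Boolean (n_mirnas x n_genes) incidence matrix, built lazily."""
        if self._matrix is None:
            gidx = {g: j for j, g in enumerate(self.genes)}
            mat = np.zeros((len(self.mirnas), len(self.genes)), dtype=bool)
            for i, m in enumerate(self.mirnas):
                for g in self._by_mirna[m]:
                    mat[i, gidx[g]] = True
            self._matrix = mat
        return self._matrix

    def gene_mask(self, genes: Iterable[str]) -> np.ndarray:
        gset = set(genes)
        return np.array([g in gset for g in self.genes])


@dataclasses.dataclass
class EnrichmentResult:
    o: int
    e: np.ndarray
    N: int
    p: float
    strategy: str
    gene_list_label: str = ""

    def summary(self) -> dict:
        return {
            "strategy": self.strategy,
            "list": self.gene_list_label,
            "o": int(self.o),
            "N": int(self.N),
            "p": float(self.p),
            "e_summary": {
                "mean": float(self.e.mean()),
                "sd": float(self.e.std(ddof=1)) if self.N > 1 else 0.0,
                "min": int(self.e.min()),
                "max": int(self.e.max()),
            },
        }


def vote_filter(
    prediction_tables: Sequence[pd.DataFrame],
    min_votes: int = 3,
) -> pd.DataFrame:
    """Consensus target pairs predicted by at least ``min_votes`` methods.

    Each table holds (mirna, gene) pairs from one prediction method;
    within-table duplicates count once.
    """
    if min_votes > len(prediction_tables):
        raise ValueError("min_votes exceeds the number of prediction tables")
    votes: dict[tuple[str, str], int] = {}
    for table in prediction_tables:
        seen = set(zip(table["mirna"], table["gene"]))
        for pair in seen:
            votes[pair] = votes.get(pair, 0) + 1
    kept = sorted(p for p, v in votes.items() if v >= min_votes)
    return pd.DataFrame(kept, columns=["mirna", "gene"])


def observed_overlap(
    regulated_mirnas: Iterable[str],
    db: TargetDB,
    de_genes: Iterable[str],
) -> int:
    """o = |union of targets of the regulated miRNAs ∩ DE gene list|.

    miRNAs absent from the database contribute no targets (a warning-level
    event left to the caller's logging; the union is simply smaller).
    """
    return len(db.targets_of(regulated_mirnas) & set(de_genes))


def permute_mirnas(
    db: TargetDB,
    size: int,
    de_genes: Iterable[str],
    n_perm: int = 400,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null overlaps from drawing ``size`` miRNAs without replacement per
    permutation and pooling their targets (union, deduplicated)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M = len(db.mirnas)
    if size > M:
        raise ValueError("size exceeds the miRNA universe")
    de_mask = db.gene_mask(de_genes)
    idx = np.argsort(rng.random((n_perm, M)), axis=1)[:, :size]
    pooled = db.matrix[idx]  # (n_perm, size, n_genes)
    union = pooled.any(axis=1)
    return union[:, de_mask].sum(axis=1).astype(int)


def permute_genes(
    db: TargetDB,
    size: int,
    de_genes: Iterable[str],
    n_perm: int = 400,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Null overlaps from drawing ``size`` genes without replacement from
    the database's gene universe per permutation."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Gn = len(db.genes)
    if size > Gn:
        raise ValueError("size exceeds the gene universe")
    de_mask = db.gene_mask(de_genes)
    idx = np.argsort(rng.random((n_perm, Gn)), axis=1)[:, :size]
    return de_mask[idx].sum(axis=1).astype(int)


def perm_pvalue(o: int, e: np.ndarray, N: int | None = None) -> float:
    """p = #{e_i > o} / N, strict inequality, no +1 correction."""
    e = np.asarray(e)
    if N is None:
        N = len(e)
    if len(e) != N or N < 1:
        raise ValueError("e must have length N >= 1")
    return float(np.count_nonzero(e > o)) / N


def enrichment_test(
    db: TargetDB,
    regulated_mirnas: Iterable[str],
    de_genes: Iterable[str],
    strategy: str = MIRNA_NULL,
    n_perm: int = 400,
    seed: int | np.random.Generator = 0,
    gene_list_label: str = "",
) -> EnrichmentResult:
    """Observed overlap plus permutation null and p-value for one list."""
    regulated = sorted(set(regulated_mirnas))
    o = observed_overlap(regulated, db, de_genes)
    if strategy == MIRNA_NULL:
        e = permute_mirnas(db, len(regulated), de_genes, n_perm, seed)
    elif strategy == GENE_NULL:
        size = len(db.targets_of(regulated))
        e = permute_genes(db, size, de_genes, n_perm, seed)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return EnrichmentResult(
        o=o, e=e, N=n_perm, p=perm_pvalue(o, e, n_perm),
        strategy=strategy, gene_list_label=gene_list_label,
    )
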