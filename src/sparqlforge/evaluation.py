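"""Execution-based scoring of generated queries against ground truth.

A SPARQL SELECT result is treated as a table whose rows are *sets* of cell
values (column identity is ignored and duplicate values within a row
collapse).  Two result tables G (ground truth, N_g rows) and Q (generated,
N_q rows) are compared by:

1. computing the Jaccard coefficient between every pair of rows, giving an
   N_g x N_q similarity matrix S;
2. solving a maximum-weight bipartite matching on S, since the true row
   correspondence is unknown; and
3. normalizing the matched weight by max(N_g, N_q), so that unmatched rows
   on either side are penalized:

       score = (1 / max(N_g, N_q)) * sum_{(i,j) in M} S_ij

Edge conventions the formula leaves open: two empty tables score 1.0 (a
correctly empty answer), one empty table scores 0.0 (follows from the
formula).  Values are compared exactly after normalization; semantically
equivalent but lexically different values (e.g. "Mouse" vs "Mus musculus")
score 0 — a known property of the metric, addressable upstream by entity
normalization, deliberately not "fixed" here.

Variable-selection and parameter-extraction quality use a plain set Jaccard
over variable names and exact (variable, value) pairs respectively.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "ResultTable",
    "SimilarityMatrix",
    "Matching",
    "row_jaccard",
    "similarity_matrix",
    "optimal_matching",
    "table_similarity",
    "set_jaccard",
    "score_distribution",
    "BIN_LABELS",
    "read_table_tsv",
    "write_table_tsv",
]

BIN_LABELS = ("x=0", "0<x<0.5", "x=0.5", "0.5<x<1.0", "x=1.0")

_ASSIGN_TOL = 1e-12


@dataclass(frozen=True)
class ResultTable:
    """Ordered rows of cell-value sets, as produced by executing a query."""

    rows: tuple[frozenset[str], ...]
    origin: str | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "rows", tuple(frozenset(str(c) for c in row) for row in self.rows)
        )

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_rows(cls, rows: Iterable[Iterable[str]], origin: str | None = None
                  ) -> "ResultTable":
        return cls(rows=tuple(frozenset(r) for r in rows), origin=origin)


@dataclass(frozen=True)
class SimilarityMatrix:
    """N_g x N_q grid of row-level Jaccard coefficients."""

    values: tuple[tuple[float, ...], ...]

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.values), len(self.values[0]) if self.values else 0)

    def as_array(self) -> np.ndarray:
        ng, nq = self.shape
        return np.array(self.values, dtype=float).reshape(ng, nq)


@dataclass(frozen=True)
class Matching:
    """A one-to-one pairing of G-row indices with Q-row indices."""

    pairs: frozenset[tuple[int, int]]

    def __post_init__(self):
        rows = [i for i, _ in self.pairs]
        cols = [j for _, j in self.pairs]
        assert len(set(rows)) == len(rows) and len(set(cols)) == len(cols), \
            "matching is not one-to-one"


def row_jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|a ∩ b| / |a ∪ b|; 1.0 when both rows are empty.  Symmetric."""
    sa, sb = frozenset(a), frozenset(b)
    union = sa | sb
    if not union:
        return 1.0
    return len(sa & sb) / len(union)


def similarity_matrix(G: ResultTable, Q: ResultTable) -> SimilarityMatrix:
    """Row-pairwise Jaccard for all (i, j); shape N_g x N_q (possibly empty)."""
    return SimilarityMatrix(values=tuple(
        tuple(row_jaccard(g, q) for q in Q.rows) for g in G.rows
    ))


def _max_weight(S: np.ndarray) -> float:
    if S.size == 0:
        return 0.0
    ri, ci = linear_sum_assignment(S, maximize=True)
    return float(S[ri, ci].sum())


def optimal_matching(S: SimilarityMatrix) -> tuple[Matching, float]:
    """Maximum-weight one-to-one matching on S with a deterministic tie-break.

    The total weight comes from the assignment solver and is unique among
    maximizers; the reported pair set omits zero-weight pairs and is the
    lexicographically smallest positive-weight set attaining that weight,
    found by greedy refinement with solver feasibility checks.
    """
    A = S.as_array()
    total = _max_weight(A)
    if total <= _ASSIGN_TOL:
        return Matching(frozenset()), 0.0
    ng, nq = A.shape
    chosen: list[tuple[int, int]] = []
    chosen_weight = 0.0
    free_rows = list(range(ng))
    free_cols = list(range(nq))
    for i in range(ng):
        if i not in free_rows:
            continue
        for j in list(free_cols):
            w = A[i, j]
            if w <= 0.0:
                continue
            rest_rows = [r for r in free_rows if r != i]
            rest_cols = [c for c in free_cols if c != j]
            rest = A[np.ix_(rest_rows, rest_cols)] if rest_rows and rest_cols \
                else np.zeros((0, 0))
            if chosen_weight + w + _max_weight(rest) >= total - _ASSIGN_TOL:
                chosen.append((i, j))
                chosen_weight += w
                free_rows.remove(i)
                free_cols.remove(j)
                break
    return Matching(frozenset(chosen)), total


def table_similarity(G: ResultTable, Q: ResultTable) -> float:
    """Normalized matched weight: sum over M of S_ij divided by max(N_g, N_q).

    Both tables empty -> 1.0; exactly one empty -> 0.0.
    """
    if len(G) == 0 and len(Q) == 0:
        return 1.0
    if len(G) == 0 or len(Q) == 0:
        return 0.0
    _, weight = optimal_matching(similarity_matrix(G, Q))
    return weight / max(len(G), len(Q))


def set_jaccard(predicted: Iterable, truth: Iterable) -> float:
    """Exact set Jaccard over hashable items; both empty -> 1.0.

    Used for variable names and for (variable, value) parameter pairs, which
    are compared as exact pairs — a value differing in any character counts
    as a different item.
    """
    sp, st = set(predicted), set(truth)
    union = sp | st
    if not union:
        return 1.0
    return len(sp & st) / len(union)


def score_distribution(scores: Sequence[float]) -> dict[str, int]:
    """Counts over the five bins x=0, 0<x<0.5, x=0.5, 0.5<x<1.0, x=1.0.

    Boundary scores are classified exactly; anything outside [0, 1] raises.
    """
    counts = dict.fromkeys(BIN_LABELS, 0)
    for x in scores:
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"score {x} outside [0, 1]")
        if x == 0.0:
            counts["x=0"] += 1
        elif x < 0.5:
            counts["0<x<0.5"] += 1
        elif x == 0.5:
            counts["x=0.5"] += 1
        elif x < 1.0:
            counts["0.5<x<1.0"] += 1
        else:
            counts["x=1.0"] += 1
    return counts


# ---------------------------------------------------------------------------
# delimited-text I/O (one row per line, cells tab-separated)
# ---------------------------------------------------------------------------


def read_table_tsv(text: str, origin: str | None = None) -> ResultTable:
    """Parse a tab-separated table; blank trailing lines are ignored."""
    rows = []
    for line in text.splitlines():
        if line == "":
            continue
        rows.append(frozenset(line.split("\t")))
    return ResultTable(rows=tuple(rows), origin=origin)


def write_table_tsv(table: ResultTable) -> str:
    """Serialize with cells sorted within each row for stable output."""
    return "".join("\t".join(sorted(row)) + "\n" for row in table.rows)
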