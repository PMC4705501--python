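"""Quantitative evaluation of predicted modules against references.

Implements the matching-matrix statistics used throughout the protein
complex prediction literature — sensitivity Sn, positive predictive value
PPV and their geometric-mean accuracy Acc — plus the overlap-score
"matched" count and the hypergeometric enrichment p-value used to assess
biological significance of modules against a function annotation table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .graph_io import AnnotationTable, ModuleSet

__all__ = [
    "MatchMatrix",
    "EnrichmentQuery",
    "matching_matrix",
    "sensitivity",
    "ppv",
    "accuracy",
    "overlap_score",
    "matched_count",
    "enrichment_pvalue",
    "annotate_modules",
]


@dataclass(frozen=True)
class MatchMatrix:
    """Reference x predicted overlap-count matrix T.

    ``t[i, j]`` is the number of proteins shared by reference module i and
    predicted module j; ``row_sizes[i]`` is the size of reference module i.
    """

    t: np.ndarray
    row_sizes: np.ndarray

    def __post_init__(self):
        if self.t.ndim != 2:
            raise ValueError("T must be two-dimensional")
        if (self.t < 0).any():
            raise ValueError("T entries must be non-negative")
        if len(self.row_sizes) != self.t.shape[0]:
            raise ValueError("row_sizes length must match T's row count")
        if (self.t.max(axis=1, initial=0) > self.row_sizes).any():
            raise ValueError("an overlap exceeds its reference module size")

    @property
    def n(self) -> int:
        """Number of reference modules (rows)."""
        return self.t.shape[0]

    @property
    def m(self) -> int:
        """Number of predicted modules (columns)."""
        return self.t.shape[1]


def matching_matrix(reference: ModuleSet, predicted: ModuleSet) -> MatchMatrix:
    """Exact set-intersection counts, rows = reference, columns = predicted."""
    if len(reference) == 0 or len(predicted) == 0:
        raise ValueError("matching_matrix requires non-empty module sets")
    ref_sets = reference.sets()
    pred_sets = predicted.sets()
    t = np.array([[len(r & p) for p in pred_sets] for r in ref_sets],
                 dtype=int)
    sizes = np.array([len(r) for r in ref_sets], dtype=int)
    return MatchMatrix(t, sizes)


def sensitivity(T: MatchMatrix) -> float:
    """Sn = sum_i max_j t(i,j) / sum_i n(i)."""
    denom = int(T.row_sizes.sum())
    if denom == 0:
        raise ValueError("sensitivity undefined: empty reference modules")
    return float(T.t.max(axis=1).sum() / denom)


def ppv(T: MatchMatrix) -> float:
    """PPV = sum_j max_i t(i,j) / sum_ij t(i,j); 0 when T is all-zero."""
    denom = int(T.t.sum())
    if denom == 0:
        return 0.0
    return float(T.t.max(axis=0).sum() / denom)


def accuracy(sn: float, ppv_value: float) -> float:
    """Geometric-mean accuracy  Acc = sqrt(Sn * PPV).

    The published benchmark tables are consistent with the geometric mean
    of sensitivity and positive predictive value (the standard accuracy of
    complex-prediction evaluation), which is what is computed here.
    """
    for name, x in (("Sn", sn), ("PPV", ppv_value)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {x}")
    return math.sqrt(sn * ppv_value)


def overlap_score(a: frozenset | set, b: frozenset | set) -> float:
    """Neighborhood-affinity overlap  omega(A, B) = |A∩B|^2 / (|A||B|)."""
    if not a or not b:
        raise ValueError("overlap_score requires non-empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def matched_count(reference: ModuleSet, predicted: ModuleSet,
                  threshold: float = 0.2) -> int:
    """Predicted modules matching at least one reference at omega >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ref_sets = reference.sets()
    return sum(
        1 for p in predicted.sets()
        if any(overlap_score(p, r) >= threshold for r in ref_sets))


@dataclass(frozen=True)
class EnrichmentQuery:
    """Inputs of one hypergeometric enrichment test.

    ``k`` proteins of a module of size ``C`` carry a function shared by
    ``F`` of the ``N`` proteins in the genome background.
    """

    k: int
    module_size: int
    term_size: int
    genome_size: int

    def __post_init__(self):
        k, C, F, N = (self.k, self.module_size, self.term_size,
                      self.genome_size)
        if not (0 <= k <= min(C, F)):
            raise ValueError(f"need 0 <= k <= min(C, F); got k={k}, C={C}, F={F}")
        if C < 1 or C > N:
            raise ValueError(f"need 1 <= C <= N; got C={C}, N={N}")
        if F < 1 or F > N:
            raise ValueError(f"need 1 <= F <= N; got F={F}, N={N}")


def enrichment_pvalue(k: int, module_size: int, term_size: int,
                      genome_size: int) -> float:
    """Probability of observing >= k annotated proteins by chance.

        p = 1 - sum_{i=0}^{k-1} C(F,i) C(N-F,C-i) / C(N,C)

    evaluated as the algebraically identical upper-tail sum sum_{i>=k} in
    exact arbitrary-precision integer arithmetic, then rounded once to
    double precision.  The literal complement suffers catastrophic
    cancellation at genome scale (p-values down to 1e-63 are routinely
    reported); the exact tail does not.
    """
    q = EnrichmentQuery(k, module_size, term_size, genome_size)
    C, F, N = q.module_size, q.term_size, q.genome_size
    if k == 0:
        return 1.0
    numerator = sum(math.comb(F, i) * math.comb(N - F, C - i)
                    for i in range(k, min(C, F) + 1)
                    if C - i <= N - F)
    if numerator == 0:
        return 0.0
    return float(Fraction(numerator, math.comb(N, C)))


def annotate_modules(modules: ModuleSet, annotations: AnnotationTable,
                     alpha: float = 0.01) -> pd.DataFrame:
    """Best-enrichment annotation of every module.

    For each module, every term sharing at least one protein is tested and
    the minimum-p term is reported (ties break to the smaller term name),
    together with the overlap ``k``, the cluster frequency ``k / C`` and a
    significance flag at ``p < alpha``.  A module with no annotated protein
    is reported with no term and p = 1.
    """
    rows = []
    for label, members in modules:
        C = len(members)
        best: tuple[float, str, int] | None = None
        for term in sorted(annotations.entries):
            prots = annotations.entries[term]
            k = len(members & prots)
            if k == 0:
                continue
            p = enrichment_pvalue(k, C, len(prots), annotations.genome_size)
            if best is None or p < best[0]:
                best = (p, term, k)
        if best is None:
            rows.append((label, C, None, 1.0, 0, 0.0, False))
        else:
            p, term, k = best
            rows.append((label, C, term, p, k, k / C, p < alpha))
    return pd.DataFrame(
        rows, columns=["module", "size", "term", "p_value", "overlap",
                       "cluster_frequency", "significant"])
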