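"""Best-match-average similarity coefficients between PS term profiles.

Two profiles are compared through the pairwise matrix of MICA information
contents: entry (i, j) is the IC of the most informative common ancestor of
term i of profile A and term j of profile B. The similarity coefficient is
the best-match average (BMA) of that matrix,

    w = (sum_i max_j M_ij + sum_j max_i M_ij) / (n_rows + n_cols),

the average of all maximum similarities on each row and column. Profiles
that share only the ontology root have w = 0 exactly; w is measured in nats
and bounded above by the corpus's maximum IC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np
import pandas as pd

from .ontology import ICTable, OntologyDAG, ancestors
from .profiles import TermProfile

#: BMA readings: "pooled" averages row and column maxima together (default);
#: "two-mean" averages the row-wise mean and the column-wise mean. The two
#: coincide for square matrices only.
BMA_SCHEMES = ("pooled", "two-mean")


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise MICA-IC matrix between two term profiles (nats)."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    values: np.ndarray  # shape (len(rows), len(cols))


@dataclass(frozen=True)
class SimilarityCoefficient:
    ps_a: str
    ps_b: str
    namespace: str
    w: float


class MicaIcCache:
    """Memoises IC(MICA(t1, t2)) across the many profile pairs of a run."""

    def __init__(self, dag: OntologyDAG, ic: ICTable):
        self.dag = dag
        self.ic = ic
        self._cache: dict[tuple[str, str], float] = {}

    def __call__(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        val = self._cache.get(key)
        if val is None:
            common = ancestors(self.dag, t1) & ancestors(self.dag, t2)
            val = max(self.ic.ic.get(a, 0.0) for a in common)
            self._cache[key] = val
        return val


def pairwise_ic_matrix(
    pa: TermProfile,
    pb: TermProfile,
    dag: OntologyDAG,
    ic: ICTable,
    cache: MicaIcCache | None = None,
) -> SimilarityMatrix:
    """Assemble the |pa| x |pb| matrix of MICA information contents."""
    if pa.namespace != pb.namespace:
        raise ValueError(f"namespace mismatch: {pa.namespace} vs {pb.namespace}")
    if cache is None:
        cache = MicaIcCache(dag, ic)
    values = np.array(
        [[cache(a, b) for b in pb.terms] for a in pa.terms], dtype=float
    )
    return SimilarityMatrix(rows=pa.terms, cols=pb.terms, values=values)


def best_match_average(m: SimilarityMatrix, scheme: str = "pooled") -> float:
    """Best-match average of a pairwise IC matrix."""
    if m.values.size == 0:
        raise ValueError("empty similarity matrix")
    row_max = m.values.max(axis=1)
    col_max = m.values.max(axis=0)
    if scheme == "pooled":
        return float((row_max.sum() + col_max.sum()) / (len(row_max) + len(col_max)))
    if scheme == "two-mean":
        return float((row_max.mean() + col_max.mean()) / 2.0)
    raise ValueError(f"unknown BMA scheme {scheme!r}")


def coefficient(
    pa: TermProfile,
    pb: TermProfile,
    dag: OntologyDAG,
    ic: ICTable,
    cache: MicaIcCache | None = None,
    scheme: str = "pooled",
) -> SimilarityCoefficient:
    w = best_match_average(pairwise_ic_matrix(pa, pb, dag, ic, cache), scheme)
    return SimilarityCoefficient(pa.ps_id, pb.ps_id, pa.namespace, w)


def all_pair_coefficients(
    profiles: Iterable[TermProfile],
    dag: OntologyDAG,
    ic: ICTable,
    scheme: str = "pooled",
) -> list[SimilarityCoefficient]:
    """One coefficient per unordered PS pair, in sorted-id order."""
    ordered = sorted(profiles, key=lambda p: p.ps_id)
    ids = [p.ps_id for p in ordered]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ps_id among profiles")
    if len(ordered) < 2:
        raise ValueError("need at least two profiles")
    cache = MicaIcCache(dag, ic)
    return [
        coefficient(pa, pb, dag, ic, cache, scheme)
        for pa, pb in itertools.combinations(ordered, 2)
    ]


def self_coefficients(
    profiles: Iterable[TermProfile],
    dag: OntologyDAG,
    ic: ICTable,
    scheme: str = "pooled",
) -> dict[str, float]:
    """BMA of each profile against itself (the clustering-matrix diagonal)."""
    cache = MicaIcCache(dag, ic)
    return {
        p.ps_id: best_match_average(pairwise_ic_matrix(p, p, dag, ic, cache), scheme)
        for p in profiles
    }


def coefficients_to_tsv(
    coefficients: Iterable[SimilarityCoefficient], stream: TextIO
) -> None:
    df = pd.DataFrame(
        [(c.ps_a, c.ps_b, c.namespace, c.w) for c in coefficients],
        columns=["ps_a", "ps_b", "namespace", "w"],
    )
    df.to_csv(stream, sep="\t", index=False, float_format="%.10g")


def coefficients_from_tsv(stream: TextIO) -> list[SimilarityCoefficient]:
    df = pd.read_csv(stream, sep="\t", dtype={"ps_a": str, "ps_b": str})
    return [
        SimilarityCoefficient(r.ps_a, r.ps_b, r.namespace, float(r.w))
        for r in df.itertuples(index=False)
    ]


def coefficient_map(
    coefficients: Iterable[SimilarityCoefficient],
) -> dict[tuple[str, str], float]:
    """Unordered-pair -> w lookup (keys are sorted id tuples, no self pairs)."""
    out: dict[tuple[str, str], float] = {}
    for c in coefficients:
        if c.ps_a == c.ps_b:
            continue
        key = (c.ps_a, c.ps_b) if c.ps_a <= c.ps_b else (c.ps_b, c.ps_a)
        out[key] = c.w
    return out
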