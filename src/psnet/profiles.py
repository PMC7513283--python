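"""Representative term profiles for phenotypic series.

A PS is annotated indirectly, through its member diseases. Before comparing
two PS, each one is reduced to a *representative profile*: for M original
terms contributed by the members, M representative terms annotating the PS
as a whole. Each original term is matched against every other member's term
set — the identical term when the other member carries it, otherwise the
closest common ancestor in the hierarchy — and the representative is the
middle element of that shared-term list sorted by ascending specificity
(IC). A single-member PS keeps its terms unchanged.

Clinical profiles use the members' HPO annotations; biological profiles use,
per GO sub-ontology, the union of GO terms of each member disease's gene
products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TextIO

import pandas as pd

from .corpus import AnnotationCorpus, PhenotypicSeries
from .ontology import ICTable, OntologyDAG, closest_common_ancestor

logger = logging.getLogger(__name__)

CLINICAL = "clinical"
BIOLOGICAL = "biological"


@dataclass(frozen=True)
class TermProfile:
    """The representative annotation terms of one PS in one namespace."""

    ps_id: str
    namespace: str
    terms: tuple[str, ...]
    source: str  # "clinical" | "biological"

    def __len__(self) -> int:
        return len(self.terms)


def _member_term_sets(
    ps: PhenotypicSeries,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    source: str,
) -> list[tuple[str, list[str]]]:
    """Per member disease, its usable (primary-id, non-obsolete) term set."""
    members: list[tuple[str, list[str]]] = []
    for omim_id in sorted(ps.member_diseases):
        disease = corpus.diseases[omim_id]
        if source == CLINICAL:
            raw = disease.hpo_terms
        else:
            raw = set()
            for symbol in disease.gene_products:
                raw |= corpus.gene_products[symbol].go_terms.get(dag.namespace, set())
        terms: set[str] = set()
        for t in raw:
            primary = dag.resolve(t)
            if primary is not None and not dag.terms[primary].obsolete:
                terms.add(primary)
        if terms:
            members.append((omim_id, sorted(terms)))
    return members


def representative_profile(
    ps: PhenotypicSeries,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    ic: ICTable,
    source: str = CLINICAL,
) -> TermProfile | None:
    """Reduce a PS's member annotations to its representative terms.

    Returns ``None`` when no member carries usable annotations in the
    namespace; the PS is then excluded from that similarity network.
    """
    members = _member_term_sets(ps, corpus, dag, source)
    if not members:
        logger.debug("%s: no %s annotations in %s", ps.ps_id, source, dag.namespace)
        return None
    if len(members) == 1:
        return TermProfile(ps.ps_id, dag.namespace, tuple(members[0][1]), source)

    reps: list[str] = []
    for member_id, terms in members:
        others = [o for o in members if o[0] != member_id]
        for t in terms:
            shared: list[str] = []
            for _, other_terms in others:
                if t in other_terms:
                    # identical term: always the most informative shared
                    # ancestor, by IC monotonicity
                    shared.append(t)
                    continue
                # best match: the counterpart whose closest common ancestor
                # with t is most informative; ties prefer the higher-IC
                # counterpart, then the smallest ids
                best: tuple[float, float, str, str] | None = None
                for t2 in other_terms:
                    a = closest_common_ancestor(dag, t, t2, ic)
                    key = (-ic[a], -ic[t2], a, t2)
                    if best is None or key < best:
                        best = key
                shared.append(best[2])  # type: ignore[index]
            shared.sort(key=lambda s: (ic[s], s))  # ascending specificity
            reps.append(shared[len(shared) // 2])
    return TermProfile(ps.ps_id, dag.namespace, tuple(reps), source)


def profiles_to_tsv(profiles: list[TermProfile], stream: TextIO) -> None:
    rows = [
        {"ps_id": p.ps_id, "namespace": p.namespace, "term_id": t, "source": p.source}
        for p in profiles
        for t in p.terms
    ]
    pd.DataFrame(rows, columns=["ps_id", "namespace", "term_id", "source"]).to_csv(
        stream, sep="\t", index=False
    )


def profiles_from_tsv(stream: TextIO) -> list[TermProfile]:
    df = pd.read_csv(stream, sep="\t", dtype=str)
    out: list[TermProfile] = []
    for (ps_id, namespace, source), grp in df.groupby(
        ["ps_id", "namespace", "source"], sort=True
    ):
        out.append(TermProfile(ps_id, namespace, tuple(grp["term_id"]), source))
    return out
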