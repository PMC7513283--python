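import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psnet.ontology import (
    OntologyError,
    ancestors,
    closest_common_ancestor,
    compute_ic,
    descendants,
    mica,
    parse_obo,
    write_obo,
)
from psnet.synthetic import EX_HPO, random_dag

MINIMAL_OBO = """\
format-version: 1.2

[Term]
id: HP:0000001
name: All
"""

FIXTURE_OBO = """\
format-version: 1.2

[Term]
id: HP:0000000
name: root

[Term]
id: HP:0000001
name: term 1
is_a: HP:0000000

[Term]
id: HP:0000004
name: term 4
is_a: HP:0000000

[Term]
id: HP:0000002
name: term 2
is_a: HP:0000004

[Term]
id: HP:0000003
name: term 3
is_a: HP:0000004
alt_id: HP:0009999

[Term]
id: HP:0000005
name: gone
is_obsolete: true
replaced_by: HP:0000002
"""


# ---------------------------------------------------------------------------
# parsing

def test_parse_single_term_file_yields_root_only_dag():
    dag = parse_obo(MINIMAL_OBO, "HPO")
    assert len(dag) == 1
    assert dag.root_id == "HP:0000001"
    assert ancestors(dag, "HP:0000001") == {"HP:0000001"}


def test_parse_five_term_tree_and_metadata():
    dag = parse_obo(FIXTURE_OBO, "HPO")
    assert dag.root_id == "HP:0000000"
    assert ancestors(dag, "HP:0000002") == {"HP:0000002", "HP:0000004", "HP:0000000"}
    # alt_id resolves to its primary accession
    assert dag.resolve("HP:0009999") == "HP:0000003"
    # obsolete terms stay flagged, carry no parents, refuse ancestor queries
    assert dag.terms["HP:0000005"].obsolete
    assert not dag.terms["HP:0000005"].parent_ids
    with pytest.raises(KeyError):
        ancestors(dag, "HP:0000005")


def test_parse_rejects_cycles_and_missing_root():
    cyclic = (
        "[Term]\nid: HP:0000001\nis_a: HP:0000002\n\n"
        "[Term]\nid: HP:0000002\nis_a: HP:0000001\n"
    )
    with pytest.raises(OntologyError, match="cycle|root"):
        parse_obo(cyclic, "HPO")
    two_roots = "[Term]\nid: HP:0000001\n\n[Term]\nid: HP:0000002\n"
    with pytest.raises(OntologyError, match="root"):
        parse_obo(two_roots, "HPO")


def test_go_namespace_filtering():
    text = (
        "[Term]\nid: GO:0000001\nnamespace: biological_process\n\n"
        "[Term]\nid: GO:0000002\nnamespace: biological_process\nis_a: GO:0000001\n\n"
        "[Term]\nid: GO:0000003\nnamespace: cellular_component\n"
    )
    bp = parse_obo(text, "GO-BP")
    assert set(bp.terms) == {"GO:0000001", "GO:0000002"}
    cc = parse_obo(text, "GO-CC")
    assert set(cc.terms) == {"GO:0000003"}


@pytest.mark.parametrize("seed", range(5))
def test_obo_write_then_parse_round_trip(seed, rng):
    dag = random_dag(np.random.default_rng(seed), 50, "HPO", "HP", max_depth=5)
    buf = io.StringIO()
    write_obo(dag, buf)
    again = parse_obo(buf.getvalue(), "HPO")
    assert set(again.terms) == set(dag.terms)
    assert again.root_id == dag.root_id
    for t in dag.terms:
        assert again.terms[t].parent_ids == dag.terms[t].parent_ids


def test_parser_agrees_with_obonet_on_fixture():
    obonet = pytest.importorskip("obonet")
    dag = parse_obo(FIXTURE_OBO, "HPO")
    g = obonet.read_obo(io.StringIO(FIXTURE_OBO))
    # obonet drops obsolete terms; compare the active sets and is_a edges
    active = {t for t in dag.terms if not dag.terms[t].obsolete}
    assert active == set(g.nodes)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            assert parent in dag.terms[child].parent_ids


# ---------------------------------------------------------------------------
# ancestors

def _brute_force_ancestors(dag, t):
    out = {t}
    while True:
        grown = set(out)
        for x in out:
            grown |= dag.terms[x].parent_ids
        if grown == out:
            return out
        out = grown


@pytest.mark.parametrize("seed", range(8))
def test_ancestors_equals_repeated_parent_expansion(seed):
    dag = random_dag(np.random.default_rng(seed), 30, "HPO", "HP", max_depth=6)
    for t in dag.active_ids:
        assert ancestors(dag, t) == _brute_force_ancestors(dag, t)
        assert dag.root_id in ancestors(dag, t)  # root always shared


def test_descendants_inverts_ancestors(worked_example):
    hpo, _, _ = worked_example
    assert descendants(hpo, EX_HPO[4]) == {EX_HPO[2], EX_HPO[3], EX_HPO[4]}


# ---------------------------------------------------------------------------
# information content

def test_ic_root_zero_and_fallback_when_all_annotations_at_root(worked_example):
    hpo, _, _ = worked_example
    ic = compute_ic(hpo, {"e1": {EX_HPO[0]}, "e2": {EX_HPO[0]}})
    assert ic[EX_HPO[0]] == 0.0
    # nothing else was annotated: the fallback (max observed IC) is 0
    assert all(v == 0.0 for v in ic.ic.values())


def test_ic_hand_count_on_fixture_corpus(worked_example):
    hpo, _, _ = worked_example
    # 4 entities, 2 annotated within the subtree of term 4
    corpus = {
        "e1": {EX_HPO[2]},
        "e2": {EX_HPO[3]},
        "e3": {EX_HPO[1]},
        "e4": {EX_HPO[1]},
    }
    ic = compute_ic(hpo, corpus)
    assert ic[EX_HPO[4]] == pytest.approx(-math.log(2 / 4), abs=1e-4)
    assert ic[EX_HPO[2]] == pytest.approx(-math.log(1 / 4))
    assert ic.corpus_size == 4


def test_ic_rejects_empty_corpus(worked_example):
    hpo, _, _ = worked_example
    with pytest.raises(ValueError):
        compute_ic(hpo, {})


def test_ic_remaps_obsolete_annotation_via_replaced_by():
    dag = parse_obo(FIXTURE_OBO, "HPO")
    ic = compute_ic(dag, {"e1": {"HP:0000005"}, "e2": {"HP:0000004"}})
    # HP:0000005 -> replaced_by HP:0000002, a child of HP:0000004
    assert ic["HP:0000002"] == pytest.approx(-math.log(1 / 2))
    assert ic["HP:0000004"] == 0.0  # both entities fall under term 4 & root


@pytest.mark.parametrize("seed", range(5))
def test_ic_monotone_along_edges(seed):
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, 40, "HPO", "HP", max_depth=6)
    ids = dag.active_ids
    corpus = {
        f"e{i}": {ids[int(rng.integers(len(ids)))] for _ in range(3)}
        for i in range(12)
    }
    ic = compute_ic(dag, corpus)
    assert ic[dag.root_id] == 0.0
    for t in ids:
        for p in dag.terms[t].parent_ids:
            assert ic[p] <= ic[t] + 1e-12


# ---------------------------------------------------------------------------
# shared-ancestor queries

def test_mica_identity_and_fixture_values(worked_example, example_ic):
    hpo, _, _ = worked_example
    assert mica(hpo, example_ic, EX_HPO[2], EX_HPO[2]) == EX_HPO[2]
    assert mica(hpo, example_ic, EX_HPO[2], EX_HPO[3]) == EX_HPO[4]
    assert closest_common_ancestor(hpo, EX_HPO[2], EX_HPO[3]) == EX_HPO[4]
    # containment: the parent is the closest common ancestor of parent, child
    assert closest_common_ancestor(hpo, EX_HPO[4], EX_HPO[2]) == EX_HPO[4]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_terms=st.integers(5, 40))
def test_structural_invariants_on_arbitrary_dags(seed, n_terms):
    """Reflexive closure, root membership, IC monotonicity, MICA symmetry."""
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, n_terms, "HPO", "HP", max_depth=6)
    ids = dag.active_ids
    corpus = {
        f"e{i}": {ids[int(rng.integers(len(ids)))]} for i in range(5)
    }
    ic = compute_ic(dag, corpus)
    assert ic[dag.root_id] == 0.0
    for t in ids:
        anc = ancestors(dag, t)
        assert t in anc and dag.root_id in anc
        assert all(ic[a] <= ic[t] + 1e-12 for a in anc)
    t1, t2 = ids[int(rng.integers(len(ids)))], ids[int(rng.integers(len(ids)))]
    m = mica(dag, ic, t1, t2)
    assert m == mica(dag, ic, t2, t1)
    assert all(
        ic[m] >= ic[a] for a in ancestors(dag, t1) & ancestors(dag, t2)
    )


def _random_dag_with_ic(seed, n_terms=35):
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, n_terms, "HPO", "HP", max_depth=6)
    ids = dag.active_ids
    corpus = {
        f"e{i}": {ids[int(rng.integers(len(ids)))] for _ in range(2)}
        for i in range(10)
    }
    return rng, dag, compute_ic(dag, corpus)


@pytest.mark.parametrize("seed", range(10))
def test_mica_equals_brute_force_argmax(seed):
    rng, dag, ic = _random_dag_with_ic(seed)
    ids = dag.active_ids
    for _ in range(25):
        t1, t2 = (ids[int(i)] for i in rng.integers(len(ids), size=2))
        common = ancestors(dag, t1) & ancestors(dag, t2)
        got = mica(dag, ic, t1, t2)
        assert got in common
        assert ic[got] == max(ic[a] for a in common)
        assert got == mica(dag, ic, t2, t1)  # symmetry


@pytest.mark.parametrize("seed", range(10))
def test_closest_common_ancestor_equals_brute_force_minimum(seed):
    nx = pytest.importorskip("networkx")
    rng, dag, ic = _random_dag_with_ic(seed)
    g = nx.DiGraph()
    for t in dag.active_ids:
        g.add_node(t)
        for p in dag.terms[t].parent_ids:
            g.add_edge(t, p)
    ids = dag.active_ids
    for _ in range(25):
        t1, t2 = (ids[int(i)] for i in rng.integers(len(ids), size=2))
        d1 = nx.single_source_shortest_path_length(g, t1)
        d2 = nx.single_source_shortest_path_length(g, t2)
        common = ancestors(dag, t1) & ancestors(dag, t2)
        best = min(d1[a] + d2[a] for a in common)
        got = closest_common_ancestor(dag, t1, t2, ic)
        assert d1[got] + d2[got] == best
        assert got == closest_common_ancestor(dag, t2, t1, ic)  # symmetry
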