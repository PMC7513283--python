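"""Synthetic ontologies and PS cohorts with planted ground truth.

Real OMIM/HPO/GO snapshots are large, versioned and partly access-restricted,
so every pipeline stage is exercised on generated data whose true structure
is known. The generator emulates the statistical shape the analysis assumes:

* rooted ontology DAGs whose term specificity grows with depth (deep terms
  are rare in annotations, hence high-IC);
* phenotypic series containing several diseases each, diseases linked to
  causal gene products;
* planted groups of mutually similar PS: members of a group draw their
  annotations from a shared, leaf-biased term pool, so planted similarity is
  carried by informative terms. Clinical and biological similarity are
  planted independently per group, which lets every quadrant of the
  clinical-vs-biological comparison be populated on purpose;
* per-annotation noise: each annotation is resampled uniformly at random
  with a configurable probability.

All randomness flows from one integer seed through ``numpy``'s Generator
with integer-indexed sampling, so cohorts are byte-reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .corpus import (
    GO_NAMESPACES,
    AnnotationCorpus,
    Disease,
    GeneProduct,
    PhenotypicSeries,
)
from .ontology import OntologyDAG, OntologyTerm, descendants
from .networks import SimilarityNetwork

GroupMode = Literal["both", "clin", "bio", "neither"]

#: Top-level Disease Ontology layout used for synthetic corpora: the root's
#: child categories plus the anatomical-system disorders beneath
#: "disease of anatomical entity".
DO_ROOT = "DOID:4"
DO_TOP_CLASSES = (
    "syndrome",
    "genetic disease",
    "physical disorder",
    "disease by infectious agent",
    "disease of metabolism",
    "disease of mental health",
    "disease of cellular proliferation",
    "disease of anatomical entity",
)
DO_ANATOMICAL_CLASSES = (
    "cardiovascular system disease",
    "endocrine system disease",
    "gastrointestinal system disease",
    "hematopoietic system disease",
    "immune system disease",
    "integumentary system disease",
    "musculoskeletal system disease",
    "nervous system disease",
    "reproductive system disease",
    "respiratory system disease",
    "thoracic disease",
    "urinary system disease",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a simulated cohort."""

    seed: int = 0
    n_ps: int = 24
    diseases_per_ps: tuple[int, int] = (2, 4)
    genes_per_disease: tuple[int, int] = (1, 2)
    terms_per_ontology: int = 300
    dag_depth: int = 10
    branching: float = 0.25  # probability a term gains a second parent
    n_planted_groups: int = 8
    group_modes: tuple[GroupMode, ...] | None = None
    within_group_term_overlap: float = 0.95
    between_group_term_overlap: float = 0.1
    annotation_noise: float = 0.05
    annotations_per_disease: tuple[int, int] = (4, 6)
    go_annotations_per_gene: tuple[int, int] = (3, 6)
    pool_size: int = 5

    def validate(self) -> None:
        for frac in (
            self.within_group_term_overlap,
            self.between_group_term_overlap,
            self.annotation_noise,
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("overlap/noise fractions must lie in [0, 1]")
        if self.within_group_term_overlap <= self.between_group_term_overlap:
            raise ValueError(
                "within-group overlap must exceed between-group overlap "
                "(otherwise no group structure can be planted)"
            )
        if self.n_planted_groups < 1 or self.n_ps < self.n_planted_groups:
            raise ValueError("need 1 <= n_planted_groups <= n_ps")
        if self.group_modes is not None and len(self.group_modes) != self.n_planted_groups:
            raise ValueError("group_modes length must equal n_planted_groups")


@dataclass
class GroundTruth:
    """What the generator planted, for exact-recovery tests."""

    group_of: dict[str, int]
    modes: dict[int, GroupMode]
    do_class_of_group: dict[int, str]
    dominant_subontology: dict[int, str]

    def expected_quadrant(self, ps_a: str, ps_b: str) -> str:
        """Quadrant a pair should land in at a cutoff between the planted levels."""
        ga, gb = self.group_of[ps_a], self.group_of[ps_b]
        if ga != gb:
            return "I"
        return {"both": "II", "bio": "III", "clin": "IV", "neither": "I"}[self.modes[ga]]

    def group_labels(self, ps_ids: Sequence[str]) -> list[int]:
        return [self.group_of[p] for p in ps_ids]


@dataclass
class SyntheticCohort:
    config: SyntheticConfig
    corpus: AnnotationCorpus
    hpo: OntologyDAG
    go: dict[str, OntologyDAG]  # namespace -> DAG
    do: OntologyDAG
    truth: GroundTruth


# ---------------------------------------------------------------------------
# ontology generation

def random_dag(
    rng: np.random.Generator,
    n_terms: int,
    namespace: str,
    prefix: str,
    max_depth: int = 6,
    branching: float = 0.25,
) -> OntologyDAG:
    """A random rooted DAG; term i's parents come from terms 0..i-1.

    Construction by index order guarantees acyclicity; each non-root term has
    one parent drawn from terms above the depth cap and, with probability
    ``branching``, a second one. The first ``n_top`` terms attach directly to
    the root, mimicking the broad top level of real ontologies.
    """
    ids = [f"{prefix}:{i:07d}" for i in range(n_terms)]
    terms = {ids[0]: OntologyTerm(id=ids[0], name=f"{namespace} root", namespace=namespace)}
    depth = {ids[0]: 0}
    n_top = min(12, max(2, n_terms // 12))
    for i in range(1, n_terms):
        if i <= n_top:
            parent = ids[0]
        else:
            eligible = [j for j in range(i) if depth[ids[j]] < max_depth]
            parent = ids[int(rng.integers(len(eligible)))] if eligible else ids[0]
        parents = {parent}
        if i >= 2 and rng.random() < branching:
            parents.add(ids[int(rng.integers(i))])
        terms[ids[i]] = OntologyTerm(
            id=ids[i], name=f"{namespace} term {i}", parent_ids=parents, namespace=namespace
        )
        depth[ids[i]] = min(depth[p] for p in parents) + 1
    return OntologyDAG(terms=terms, namespace=namespace, root_id=ids[0])


def make_do_dag() -> OntologyDAG:
    """Fixed two-level Disease Ontology skeleton for synthetic corpora."""
    terms = {DO_ROOT: OntologyTerm(id=DO_ROOT, name="disease", namespace="DO")}
    for i, name in enumerate(DO_TOP_CLASSES):
        tid = f"DOID:{10 + i}"
        terms[tid] = OntologyTerm(id=tid, name=name, parent_ids={DO_ROOT}, namespace="DO")
    anatomical = f"DOID:{10 + DO_TOP_CLASSES.index('disease of anatomical entity')}"
    for i, name in enumerate(DO_ANATOMICAL_CLASSES):
        tid = f"DOID:{100 + i}"
        terms[tid] = OntologyTerm(id=tid, name=name, parent_ids={anatomical}, namespace="DO")
    return OntologyDAG(terms=terms, namespace="DO", root_id=DO_ROOT)


def _depth_weights(dag: OntologyDAG, rng: np.random.Generator) -> tuple[list[str], np.ndarray]:
    """Sampling weights favouring deep (specific, future high-IC) terms."""
    ids = [t for t in dag.active_ids if t != dag.root_id]
    depths = np.array([dag.depth(t) for t in ids], dtype=float)
    w = np.exp(depths)  # leaf-biased
    return ids, w / w.sum()


def _sample_terms(
    rng: np.random.Generator, ids: list[str], weights: np.ndarray, n: int
) -> list[str]:
    take = rng.choice(len(ids), size=min(n, len(ids)), replace=False, p=weights)
    return [ids[int(i)] for i in sorted(take)]


def _pick_anchors(
    rng: np.random.Generator, dag: OntologyDAG, n: int, min_subtree: int
) -> list[str]:
    """Non-root anchor terms with large enough, mutually disjoint subtrees.

    Disjointness keeps the planted groups separated: nested or overlapping
    subtrees would leak similarity between groups through shared ancestry.
    """
    candidates = [
        t
        for t in dag.active_ids
        if t != dag.root_id and len(descendants(dag, t)) >= min_subtree
    ]
    # smallest subtrees first: packs the most disjoint anchors into the DAG;
    # random tie-break keeps cohorts varied across seeds
    tiebreak = rng.permutation(len(candidates))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (len(descendants(dag, candidates[i])), tiebreak[i]),
    )
    chosen: list[str] = []
    taken: set[str] = set()
    for i in order:
        t = candidates[int(i)]
        subtree = descendants(dag, t)
        if taken & subtree:  # overlapping, nested or enclosing subtree
            continue
        chosen.append(t)
        taken |= subtree
        if len(chosen) == n:
            return chosen
    raise ValueError(
        f"{dag.namespace}: could not find {n} disjoint subtrees of "
        f">= {min_subtree} terms (grow terms_per_ontology or shrink pool_size)"
    )


def _subtree_pool(
    rng: np.random.Generator, dag: OntologyDAG, anchor: str, n: int
) -> list[str]:
    """Leaf-biased sample of ``n`` terms from the anchor's subtree."""
    if n <= 0:
        return []
    ids = sorted(descendants(dag, anchor))
    depths = np.array([dag.depth(t) for t in ids], dtype=float)
    w = np.exp(depths - depths.max())
    return _sample_terms(rng, ids, w / w.sum(), n)


# ---------------------------------------------------------------------------
# cohort simulation

def simulate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a reproducible cohort with planted similarity groups."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    hpo = random_dag(
        rng, config.terms_per_ontology, "HPO", "HP", config.dag_depth, config.branching
    )
    go = {
        ns: random_dag(
            rng,
            config.terms_per_ontology,
            ns,
            "GO",
            config.dag_depth,
            config.branching,
        )
        for ns in GO_NAMESPACES
    }
    do = make_do_dag()

    n_groups = config.n_planted_groups
    modes: dict[int, GroupMode] = {
        g: (config.group_modes[g] if config.group_modes else "both")
        for g in range(n_groups)
    }
    anatomical_ids = [f"DOID:{100 + i}" for i in range(len(DO_ANATOMICAL_CLASSES))]
    do_class_of_group = {g: anatomical_ids[g % len(anatomical_ids)] for g in range(n_groups)}
    dominant = {g: GO_NAMESPACES[g % len(GO_NAMESPACES)] for g in range(n_groups)}

    # Term pools are subtree-localised: each group gets an anchor term and
    # draws its pool from the anchor's descendants, leaf-biased. Similar
    # diseases annotate nearby terms in real ontologies, and localisation is
    # what lets shared ancestry (not only identical terms) carry the planted
    # similarity. A shared extra pool provides the between-group overlap.
    pools: dict[tuple[int, str], list[str]] = {}
    background: dict[str, tuple[list[str], np.ndarray]] = {}
    all_ids = {ns: dag.active_ids for ns, dag in {"HPO": hpo, **go}.items()}
    n_shared = int(round(config.between_group_term_overlap * config.pool_size))
    for ns, dag in {"HPO": hpo, **go}.items():
        anchors = _pick_anchors(rng, dag, n_groups + 1, config.pool_size)
        shared = (
            _subtree_pool(rng, dag, anchors[-1], n_shared) if n_shared else []
        )
        planted_terms: set[str] = set()
        for a in anchors:
            planted_terms |= descendants(dag, a)
        for g in range(n_groups):
            fresh = _subtree_pool(
                rng, dag, anchors[g], config.pool_size - len(shared)
            )
            pools[(g, ns)] = sorted(set(shared) | set(fresh))
        # background annotations avoid the planted subtrees: disease-relevant
        # regions of real ontologies are dominated by the diseases that
        # define them, and the separation keeps planted terms informative
        bg_ids = [
            t for t in dag.active_ids
            if t != dag.root_id and t not in planted_terms
        ]
        depths = np.array([dag.depth(t) for t in bg_ids], dtype=float)
        w = np.exp(depths - depths.max())
        background[ns] = (bg_ids, w / w.sum())

    def draw_annotations(ns: str, group: int, planted: bool, n: int) -> set[str]:
        bg_ids, bg_w = background[ns]
        pool = pools[(group, ns)]
        out: set[str] = set()
        for _ in range(n):
            if planted and rng.random() < config.within_group_term_overlap:
                t = pool[int(rng.integers(len(pool)))]
            else:
                t = bg_ids[int(rng.choice(len(bg_ids), p=bg_w))]
            if rng.random() < config.annotation_noise:
                t = all_ids[ns][int(rng.integers(len(all_ids[ns])))]
            out.add(t)
        return out

    corpus = AnnotationCorpus()
    truth = GroundTruth(
        group_of={}, modes=modes, do_class_of_group=do_class_of_group,
        dominant_subontology=dominant,
    )
    next_omim = 100000
    next_gene = 0
    for i in range(config.n_ps):
        group = i % n_groups
        mode = modes[group]
        ps_id = f"PS{600000 + i}"
        ps = PhenotypicSeries(ps_id=ps_id, label=f"series {i} (group {group})")
        truth.group_of[ps_id] = group
        n_diseases = int(rng.integers(config.diseases_per_ps[0], config.diseases_per_ps[1] + 1))
        for _ in range(n_diseases):
            omim_id = str(next_omim)
            next_omim += 1
            disease = Disease(omim_id=omim_id, label=f"disease {omim_id}")
            n_annot = int(
                rng.integers(config.annotations_per_disease[0], config.annotations_per_disease[1] + 1)
            )
            disease.hpo_terms = draw_annotations("HPO", group, mode in ("both", "clin"), n_annot)
            disease.do_terms = {do_class_of_group[group]}
            n_genes = int(rng.integers(config.genes_per_disease[0], config.genes_per_disease[1] + 1))
            for _ in range(n_genes):
                symbol = f"GP{next_gene:04d}"
                next_gene += 1
                gp = GeneProduct(symbol=symbol)
                for ns in GO_NAMESPACES:
                    n_go = int(
                        rng.integers(config.go_annotations_per_gene[0], config.go_annotations_per_gene[1] + 1)
                    )
                    planted = mode in ("both", "bio") and ns == dominant[group]
                    gp.go_terms[ns] = draw_annotations(ns, group, planted, n_go)
                corpus.gene_products[symbol] = gp
                disease.gene_products.add(symbol)
            corpus.diseases[omim_id] = disease
            ps.member_diseases.add(omim_id)
        corpus.series[ps_id] = ps
    corpus.validate()
    return SyntheticCohort(config=config, corpus=corpus, hpo=hpo, go=go, do=do, truth=truth)


# ---------------------------------------------------------------------------
# flat-file export (same dialects the corpus parsers read)

def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, str]:
    """Write a cohort as the flat-file set a real-data run would start from.

    Emits hp.obo, go.obo (all three sub-ontologies), doid.obo,
    phenotype_annotation.tab, goa_human.gaf, genemap2.txt, morbidmap.txt,
    ps_membership.tsv and do_annotations.tsv. Returns name -> path.
    """
    import os

    from . import corpus as corpus_io
    from .ontology import write_obo

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}

    def _open(name: str):
        paths[name] = os.path.join(directory, name)
        return open(paths[name], "w")

    with _open("hp.obo") as fh:
        write_obo(cohort.hpo, fh)
    with _open("doid.obo") as fh:
        write_obo(cohort.do, fh)
    with _open("go.obo") as fh:
        fh.write("format-version: 1.2\n")
        for ns in GO_NAMESPACES:
            buf = io.StringIO()
            write_obo(cohort.go[ns], buf)
            fh.write(buf.getvalue().split("\n", 1)[1])

    with _open("phenotype_annotation.tab") as fh:
        corpus_io.write_phenotype_annotations(
            {d.omim_id: d.hpo_terms for d in cohort.corpus.diseases.values() if d.hpo_terms},
            fh,
        )
    with _open("goa_human.gaf") as fh:
        corpus_io.write_gaf(
            {gp.symbol: gp.go_terms for gp in cohort.corpus.gene_products.values()}, fh
        )
    symbol_to_mim = {
        s: str(600000 + i) for i, s in enumerate(sorted(cohort.corpus.gene_products))
    }
    with _open("genemap2.txt") as fh:
        corpus_io.write_genemap2({m: s for s, m in symbol_to_mim.items()}, fh)
    with _open("morbidmap.txt") as fh:
        corpus_io.write_morbidmap(cohort.corpus, symbol_to_mim, fh)
    with _open("ps_membership.tsv") as fh:
        corpus_io.write_ps_membership(cohort.corpus, fh)
    with _open("do_annotations.tsv") as fh:
        corpus_io.write_do_annotations(
            {d.omim_id: d.do_terms for d in cohort.corpus.diseases.values() if d.do_terms},
            fh,
        )
    return paths


# ---------------------------------------------------------------------------
# the worked three-PS example

EX_HPO = {i: f"HP:{i:07d}" for i in range(5)}
EX_GO = {i: f"GO:{i:07d}" for i in range(5)}


def _five_term_dag(ids: dict[int, str], namespace: str) -> OntologyDAG:
    # 0 is the root; 1 and 4 are its children; 2 and 3 are children of 4
    parents = {0: set(), 1: {ids[0]}, 4: {ids[0]}, 2: {ids[4]}, 3: {ids[4]}}
    terms = {
        ids[i]: OntologyTerm(
            id=ids[i], name=f"term {i}", parent_ids=set(parents[i]), namespace=namespace
        )
        for i in range(5)
    }
    return OntologyDAG(terms=terms, namespace=namespace, root_id=ids[0])


def make_three_series_example() -> tuple[OntologyDAG, OntologyDAG, AnnotationCorpus]:
    """The minimal three-PS worked example (series A, B and C).

    Both ontologies are five-term trees in which 4 is the common ancestor of
    2 and 3, and 0 is the root. A is annotated {1, 2}, B {1}, C {3}, so A–B
    share the identical term 1, A–C share 4 as a common ancestor of 2 and 3,
    and B–C share only the root.
    """
    hpo = _five_term_dag(EX_HPO, "HPO")
    go_bp = _five_term_dag(EX_GO, "GO-BP")
    annot = {"A": [1, 2], "B": [1], "C": [3]}
    corpus = AnnotationCorpus()
    for i, (label, idxs) in enumerate(sorted(annot.items()), start=1):
        omim_id = f"10000{i}"
        symbol = f"GP{label}"
        gp = GeneProduct(symbol=symbol)
        gp.go_terms["GO-BP"] = {EX_GO[j] for j in idxs}
        corpus.gene_products[symbol] = gp
        corpus.diseases[omim_id] = Disease(
            omim_id=omim_id,
            label=f"disease {label}",
            hpo_terms={EX_HPO[j] for j in idxs},
            gene_products={symbol},
        )
        corpus.series[f"PS00000{i}"] = PhenotypicSeries(
            ps_id=f"PS00000{i}", label=label, member_diseases={omim_id}
        )
    corpus.validate()
    return hpo, go_bp, corpus


# ---------------------------------------------------------------------------
# planted-winner network triples (for the general-BSN merge)

def make_network_triple(
    seed: int, n_nodes: int = 12
) -> tuple[dict[str, SimilarityNetwork], dict[tuple[str, str], str]]:
    """Three complete sub-ontology networks with a planted winner per pair.

    Returns the networks keyed by name and the ground-truth map of which
    sub-ontology was given the strictly largest weight for each pair.
    """
    rng = np.random.default_rng(seed)
    names = ("BSN-BP", "BSN-CC", "BSN-MF")
    nodes = [f"PS{700000 + i}" for i in range(n_nodes)]
    edges: dict[str, dict[tuple[str, str], float]] = {n: {} for n in names}
    winners: dict[tuple[str, str], str] = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            pair = (nodes[i], nodes[j])
            base = rng.uniform(0.0, 1.5, size=3)
            winner = int(rng.integers(3))
            base[winner] = base.max() + rng.uniform(0.5, 1.0)  # strict winner
            for k, name in enumerate(names):
                edges[name][pair] = float(base[k])
            winners[pair] = names[winner]
    nets = {
        name: SimilarityNetwork(name=name, nodes=frozenset(nodes), edges=edges[name])
        for name in names
    }
    return nets, winners
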