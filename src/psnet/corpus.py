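"""The annotation corpus: phenotypic series, diseases, gene products.

OMIM groups clinically similar inherited diseases, caused by mutations in
different genes, into *phenotypic series* (PS). This module models the
three-level PS -> disease -> gene-product structure and loads it from the
standard flat-file dialects:

* ``phenotype_annotation.tab`` — disease -> HPO term associations;
* GAF 2.x — gene product -> GO term associations, split per sub-ontology;
* OMIM ``genemap2.txt`` / ``morbidmap.txt`` — disease -> causal gene links;
* a two-column PS-membership TSV (OMIM distributes the PS lists on request,
  so the loader accepts a plain ``ps_id<TAB>omim_id[<TAB>label]`` export);
* ``doid.obo`` OMIM cross-references for Disease Ontology classes.

Matching writers emit the same dialects, so synthetic corpora round-trip
through the parsers.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, TextIO

from .ontology import OntologyDAG, _iter_stanzas, ancestors

logger = logging.getLogger(__name__)

GO_NAMESPACES = ("GO-BP", "GO-CC", "GO-MF")
_ASPECT_TO_NS = {"P": "GO-BP", "C": "GO-CC", "F": "GO-MF"}
_NS_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NS.items()}


@dataclass
class Disease:
    """One OMIM phenotype entry with its clinical and class annotations."""

    omim_id: str
    label: str = ""
    hpo_terms: set[str] = field(default_factory=set)
    do_terms: set[str] = field(default_factory=set)
    gene_products: set[str] = field(default_factory=set)


@dataclass
class GeneProduct:
    """A disease gene product with GO annotations per sub-ontology."""

    symbol: str
    go_terms: dict[str, set[str]] = field(
        default_factory=lambda: {ns: set() for ns in GO_NAMESPACES}
    )


@dataclass
class PhenotypicSeries:
    """An OMIM phenotypic series: a named set of clinically similar diseases."""

    ps_id: str
    label: str = ""
    member_diseases: set[str] = field(default_factory=set)
    do_class: str | None = None


@dataclass
class AnnotationCorpus:
    diseases: dict[str, Disease] = field(default_factory=dict)
    gene_products: dict[str, GeneProduct] = field(default_factory=dict)
    series: dict[str, PhenotypicSeries] = field(default_factory=dict)

    def validate(self) -> None:
        """Check referential integrity (PS -> disease -> gene product)."""
        for ps in self.series.values():
            if not ps.member_diseases:
                raise ValueError(f"{ps.ps_id}: phenotypic series without members")
            missing = ps.member_diseases - self.diseases.keys()
            if missing:
                raise ValueError(f"{ps.ps_id}: unknown member diseases {sorted(missing)}")
        for d in self.diseases.values():
            missing = d.gene_products - self.gene_products.keys()
            if missing:
                raise ValueError(f"{d.omim_id}: unknown gene products {sorted(missing)}")

    def ps_gene_products(self, ps_id: str) -> set[str]:
        """All gene products linked to any member disease of a PS."""
        out: set[str] = set()
        for d in self.series[ps_id].member_diseases:
            out |= self.diseases[d].gene_products
        return out


# ---------------------------------------------------------------------------
# phenotype_annotation.tab

class PhenotypeAnnotationResult(NamedTuple):
    annotations: dict[str, set[str]]
    n_skipped: int
    n_non_omim: int


_HPO_RE = re.compile(r"^HP:\d{7}$")


def parse_phenotype_annotations(stream: TextIO | str) -> PhenotypeAnnotationResult:
    """Aggregate OMIM-sourced rows of a phenotype_annotation.tab file.

    Classic layout: column 0 database, column 1 object id, column 4 HPO term.
    Malformed rows are skipped with a counter; rows from other databases
    (DECIPHER, ORPHA) are counted separately. Raises ``ValueError`` when no
    usable row remains.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    annotations: dict[str, set[str]] = {}
    n_skipped = n_non_omim = 0
    for raw in stream:
        if not raw.strip() or raw.startswith(("#", "!")):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 5 or not cols[1].strip() or not _HPO_RE.match(cols[4].strip()):
            n_skipped += 1
            continue
        if cols[0].strip().upper() != "OMIM":
            n_non_omim += 1
            continue
        annotations.setdefault(cols[1].strip(), set()).add(cols[4].strip())
    if not annotations:
        raise ValueError("phenotype annotations: no usable OMIM row found")
    if n_skipped or n_non_omim:
        logger.info(
            "phenotype annotations: %d malformed rows skipped, %d non-OMIM rows ignored",
            n_skipped,
            n_non_omim,
        )
    return PhenotypeAnnotationResult(annotations, n_skipped, n_non_omim)


def write_phenotype_annotations(
    annotations: Mapping[str, Iterable[str]], stream: TextIO
) -> None:
    for omim_id in sorted(annotations):
        for term in sorted(annotations[omim_id]):
            cols = ["OMIM", omim_id, f"disease {omim_id}", "", term] + [""] * 9
            stream.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GAF

class GafResult(NamedTuple):
    annotations: dict[str, dict[str, set[str]]]
    n_not_qualified: int


def parse_gaf(
    stream: TextIO | str, exclude_evidence: Iterable[str] = ()
) -> GafResult:
    """Read a GAF 2.x file into symbol -> sub-ontology -> GO term sets.

    Rows with a NOT qualifier are dropped (negation is not an annotation).
    All evidence codes are kept unless listed in ``exclude_evidence`` (e.g.
    ``{"IEA"}``). Raises ``ValueError`` for a header-only file.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    exclude = set(exclude_evidence)
    out: dict[str, dict[str, set[str]]] = {}
    n_not = 0
    for raw in stream:
        if not raw.strip() or raw.startswith("!"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 9:
            continue
        symbol, qualifier, go_id, evidence, aspect = (
            cols[2].strip(),
            cols[3],
            cols[4].strip(),
            cols[6].strip(),
            cols[8].strip(),
        )
        if "NOT" in qualifier.split("|"):
            n_not += 1
            continue
        ns = _ASPECT_TO_NS.get(aspect)
        if ns is None or not symbol or not go_id or evidence in exclude:
            continue
        out.setdefault(symbol, {n: set() for n in GO_NAMESPACES})[ns].add(go_id)
    if not out:
        raise ValueError("GAF: no usable annotation row found")
    return GafResult(out, n_not)


def write_gaf(annotations: Mapping[str, Mapping[str, Iterable[str]]], stream: TextIO) -> None:
    stream.write("!gaf-version: 2.1\n")
    for symbol in sorted(annotations):
        for ns in GO_NAMESPACES:
            for go_id in sorted(annotations[symbol].get(ns, ())):
                cols = [
                    "UniProtKB", symbol, symbol, "", go_id, "PMID:0", "IEA", "",
                    _NS_TO_ASPECT[ns], symbol, "", "protein", "taxon:9606",
                    "20200101", "GOA", "", "",
                ]
                stream.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# OMIM gene map / morbid map / PS membership

_PHENO_MIM_RE = re.compile(r"(\d{6})")


def parse_omim_maps(
    genemap: TextIO | str,
    morbidmap: TextIO | str,
    ps_membership: TextIO | str,
) -> AnnotationCorpus:
    """Build the corpus skeleton from OMIM-dialect files.

    ``genemap2.txt`` supplies gene MIM -> approved symbol; ``morbidmap.txt``
    supplies phenotype MIM -> causal gene; the PS membership TSV lists
    ``ps_id<TAB>omim_id``. Diseases without a mapped gene are retained and
    flagged; series whose members all fail to resolve are dropped.
    """
    genemap, morbidmap, ps_membership = (
        io.StringIO(s) if isinstance(s, str) else s
        for s in (genemap, morbidmap, ps_membership)
    )

    mim_to_symbol: dict[str, str] = {}
    for raw in genemap:
        if not raw.strip() or raw.startswith(("#", "!")):
            continue
        cols = raw.rstrip("\n").split("\t")
        # genemap2 layout: ... MIM Number (5), Gene Symbols (6), Name (7),
        # Approved Gene Symbol (8) ...
        if len(cols) > 8 and cols[5].strip().isdigit():
            symbol = cols[8].strip() or cols[6].split(",")[0].strip()
            if symbol:
                mim_to_symbol[cols[5].strip()] = symbol

    corpus = AnnotationCorpus()
    for raw in morbidmap:
        if not raw.strip() or raw.startswith(("#", "!")):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 3:
            continue
        phenotype, gene_symbols, gene_mim = cols[0], cols[1], cols[2].strip()
        m = _PHENO_MIM_RE.search(phenotype)
        if not m:
            continue
        omim_id = m.group(1)
        label = phenotype[: m.start()].rstrip(" ,")
        disease = corpus.diseases.setdefault(omim_id, Disease(omim_id=omim_id))
        if label and not disease.label:
            disease.label = label
        symbol = mim_to_symbol.get(gene_mim) or gene_symbols.split(",")[0].strip()
        if symbol:
            disease.gene_products.add(symbol)
            corpus.gene_products.setdefault(symbol, GeneProduct(symbol=symbol))

    n_unmapped = sum(1 for d in corpus.diseases.values() if not d.gene_products)
    if n_unmapped:
        logger.info("morbidmap: %d diseases without a mapped gene (retained)", n_unmapped)

    n_dropped_ps = 0
    for raw in ps_membership:
        if not raw.strip() or raw.startswith(("#", "!")):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) < 2:
            continue
        ps_id, omim_id = cols[0].strip(), cols[1].strip()
        label = cols[2].strip() if len(cols) > 2 else ""
        ps = corpus.series.setdefault(ps_id, PhenotypicSeries(ps_id=ps_id, label=label))
        if label and not ps.label:
            ps.label = label
        # membership may reference diseases absent from morbidmap; keep them,
        # flagged by their empty gene set.
        corpus.diseases.setdefault(omim_id, Disease(omim_id=omim_id))
        ps.member_diseases.add(omim_id)
    for ps_id in [p for p, ps in corpus.series.items() if not ps.member_diseases]:
        del corpus.series[ps_id]
        n_dropped_ps += 1
    if n_dropped_ps:
        logger.info("PS membership: dropped %d series with no resolvable disease", n_dropped_ps)
    if not corpus.series:
        raise ValueError("PS membership: no phenotypic series could be built")
    corpus.validate()
    return corpus


def write_genemap2(gene_mims: Mapping[str, str], stream: TextIO) -> None:
    """``gene_mims``: gene MIM number -> approved symbol."""
    stream.write(
        "# Chromosome\tGenomic Position Start\tGenomic Position End\tCyto Location\t"
        "Computed Cyto Location\tMIM Number\tGene Symbols\tGene Name\t"
        "Approved Gene Symbol\n"
    )
    for mim in sorted(gene_mims):
        symbol = gene_mims[mim]
        stream.write(f"chr1\t0\t0\t1p\t1p\t{mim}\t{symbol}\tgene {symbol}\t{symbol}\n")


def write_morbidmap(
    corpus: AnnotationCorpus, symbol_to_mim: Mapping[str, str], stream: TextIO
) -> None:
    stream.write("# Phenotype\tGene Symbols\tMIM Number\tCyto Location\n")
    for omim_id in sorted(corpus.diseases):
        d = corpus.diseases[omim_id]
        label = d.label or f"disease {omim_id}"
        for symbol in sorted(d.gene_products):
            stream.write(
                f"{label}, {omim_id} (3)\t{symbol}\t{symbol_to_mim[symbol]}\t1p\n"
            )


def write_ps_membership(corpus: AnnotationCorpus, stream: TextIO) -> None:
    stream.write("# ps_id\tomim_id\tlabel\n")
    for ps_id in sorted(corpus.series):
        ps = corpus.series[ps_id]
        for omim_id in sorted(ps.member_diseases):
            stream.write(f"{ps_id}\t{omim_id}\t{ps.label}\n")


# ---------------------------------------------------------------------------
# attachment of annotations and DO classes

def attach_hpo(corpus: AnnotationCorpus, annotations: Mapping[str, Iterable[str]]) -> None:
    for omim_id, terms in annotations.items():
        if omim_id in corpus.diseases:
            corpus.diseases[omim_id].hpo_terms |= set(terms)


def attach_go(
    corpus: AnnotationCorpus, annotations: Mapping[str, Mapping[str, Iterable[str]]]
) -> None:
    for symbol, per_ns in annotations.items():
        if symbol in corpus.gene_products:
            gp = corpus.gene_products[symbol]
            for ns, terms in per_ns.items():
                gp.go_terms.setdefault(ns, set()).update(terms)


def attach_do(corpus: AnnotationCorpus, annotations: Mapping[str, Iterable[str]]) -> None:
    for omim_id, terms in annotations.items():
        if omim_id in corpus.diseases:
            corpus.diseases[omim_id].do_terms |= set(terms)


def parse_do_omim_xrefs(stream: TextIO | str) -> dict[str, set[str]]:
    """Extract OMIM cross-references from a doid.obo file (omim id -> DO ids)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, set[str]] = {}
    for kind, tags in _iter_stanzas(stream):
        if kind != "Term":
            continue
        do_id = next((v for t, v in tags if t == "id"), None)
        if do_id is None:
            continue
        for tag, value in tags:
            if tag == "xref" and value.upper().startswith("OMIM:"):
                omim_id = value.split(":", 1)[1].strip().split()[0]
                out.setdefault(omim_id, set()).add(do_id)
    return out


def write_do_annotations(annotations: Mapping[str, Iterable[str]], stream: TextIO) -> None:
    stream.write("# omim_id\tdo_id\n")
    for omim_id in sorted(annotations):
        for do_id in sorted(annotations[omim_id]):
            stream.write(f"{omim_id}\t{do_id}\n")


def parse_do_annotations(stream: TextIO | str) -> dict[str, set[str]]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, set[str]] = {}
    for raw in stream:
        if not raw.strip() or raw.startswith(("#", "!")):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) >= 2:
            out.setdefault(cols[0].strip(), set()).add(cols[1].strip())
    return out


def assign_do_class(
    ps: PhenotypicSeries,
    corpus: AnnotationCorpus,
    do_dag: OntologyDAG,
    categories: Iterable[str] | None = None,
) -> str | None:
    """Top-level Disease Ontology class annotating the plurality of members.

    Categories default to the children of the DO root plus the children of
    ``disease of anatomical entity`` (the anatomical-system disorders). Each
    member disease maps to its deepest matching category; the category held
    by the most diseases wins, ties breaking to the smallest DO id. Returns
    ``None`` when no member carries a DO annotation.
    """
    if categories is None:
        cats = set(do_dag.children(do_dag.root_id))
        anatomical = next(
            (
                c
                for c in cats
                if do_dag.terms[c].name.lower() == "disease of anatomical entity"
            ),
            None,
        )
        if anatomical is not None:
            cats |= do_dag.children(anatomical)
    else:
        cats = set(categories)

    votes: dict[str, int] = {}
    for omim_id in ps.member_diseases:
        disease = corpus.diseases[omim_id]
        matched: set[str] = set()
        for t in disease.do_terms:
            primary = do_dag.resolve(t)
            if primary is None or do_dag.terms[primary].obsolete:
                continue
            matched |= ancestors(do_dag, primary) & cats
        if not matched:
            continue
        # prefer the most specific category (e.g. an anatomical system over
        # the generic anatomical-entity parent)
        best = min(matched, key=lambda c: (-do_dag.depth(c), c))
        votes[best] = votes.get(best, 0) + 1
    if not votes:
        return None
    return min(votes, key=lambda c: (-votes[c], c))
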