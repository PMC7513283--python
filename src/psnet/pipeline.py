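"""End-to-end orchestration: corpus -> profiles -> networks -> analyses.

A run proceeds through the fixed stage order

    profiles -> coefficients -> networks (CSN, BSN-BP/CC/MF, general BSN)
    -> topology stats at the analysis threshold -> fragmentation curves
    -> islands and clusters at the node-retention threshold
    -> clinical-vs-biological quadrant summary

writing every inter-stage result as plain TSV, so any stage can be
inspected or replayed from its cached inputs. A JSON manifest records the
package version, seed, thresholds and the row counts of every artifact.

Defaults follow the analysis conventions of the study design: topology is
read at a weight threshold of 1.0, islands are isolated at the threshold
that first retains at most 20% of the nodes, and the quadrant cutoff is a
coefficient of 2.0 in both networks.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import corpus as corpus_io
from .cluster import (
    average_linkage_cluster,
    full_similarity_matrix,
    quadrant_counts,
    quadrant_table,
)
from .corpus import GO_NAMESPACES, AnnotationCorpus
from .networks import (
    SimilarityNetwork,
    apply_threshold,
    assemble,
    contribution_fractions,
    fragmentation_curve,
    islands,
    merge_max,
    threshold_for_node_fraction,
    topology_stats,
    stats_table,
    write_edge_tsv,
    write_graphml,
)
from .ontology import ICTable, OntologyDAG, compute_ic, parse_obo
from .profiles import (
    BIOLOGICAL,
    CLINICAL,
    TermProfile,
    profiles_to_tsv,
    representative_profile,
)
from .similarity import (
    SimilarityCoefficient,
    all_pair_coefficients,
    coefficient_map,
    coefficients_to_tsv,
    self_coefficients,
)
from .synthetic import SyntheticCohort, SyntheticConfig, simulate_cohort

logger = logging.getLogger(__name__)

NETWORK_OF_NAMESPACE = {
    "HPO": "CSN",
    "GO-BP": "BSN-BP",
    "GO-CC": "BSN-CC",
    "GO-MF": "BSN-MF",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a run needs: inputs, thresholds, output directory, seed."""

    outdir: str
    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    analysis_threshold: float = 1.0
    retention_target: float = 0.20
    quadrant_threshold: float = 2.0
    n_clusters: int = 8
    n_fragmentation_points: int = 25
    seed: int = 0

    def validate(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_dir or synthetic config")
        if self.analysis_threshold < 0 or self.quadrant_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if not 0.0 < self.retention_target <= 1.0:
            raise ValueError("retention target must be in (0, 1]")


@dataclass
class Workspace:
    """An in-memory corpus plus the ontologies it is annotated against."""

    corpus: AnnotationCorpus
    hpo: OntologyDAG
    go: dict[str, OntologyDAG]
    do: OntologyDAG


def load_workspace(input_dir: str) -> Workspace:
    """Load a flat-file workspace (the dialects ``write_cohort`` emits)."""

    def path(name: str) -> str:
        return os.path.join(input_dir, name)

    with open(path("hp.obo")) as fh:
        hpo = parse_obo(fh, "HPO")
    go: dict[str, OntologyDAG] = {}
    for ns in GO_NAMESPACES:
        with open(path("go.obo")) as fh:
            go[ns] = parse_obo(fh, ns)
    with open(path("doid.obo")) as fh:
        do = parse_obo(fh, "DO")

    with open(path("genemap2.txt")) as gm, open(path("morbidmap.txt")) as mm, open(
        path("ps_membership.tsv")
    ) as psm:
        corpus = corpus_io.parse_omim_maps(gm, mm, psm)
    with open(path("phenotype_annotation.tab")) as fh:
        corpus_io.attach_hpo(corpus, corpus_io.parse_phenotype_annotations(fh).annotations)
    with open(path("goa_human.gaf")) as fh:
        corpus_io.attach_go(corpus, corpus_io.parse_gaf(fh).annotations)
    do_path = path("do_annotations.tsv")
    if os.path.exists(do_path):
        with open(do_path) as fh:
            corpus_io.attach_do(corpus, corpus_io.parse_do_annotations(fh))
    else:
        with open(path("doid.obo")) as fh:
            corpus_io.attach_do(corpus, corpus_io.parse_do_omim_xrefs(fh))
    corpus.validate()
    return Workspace(corpus=corpus, hpo=hpo, go=go, do=do)


def workspace_from_cohort(cohort: SyntheticCohort) -> Workspace:
    return Workspace(corpus=cohort.corpus, hpo=cohort.hpo, go=cohort.go, do=cohort.do)


@dataclass
class RunArtifacts:
    """All in-memory results of a run, plus where they were written."""

    outdir: str
    profiles: dict[str, list[TermProfile]]
    networks: dict[str, SimilarityNetwork]
    stats: pd.DataFrame
    fragmentation: pd.DataFrame
    retention: dict[str, tuple[float, float]]
    islands: dict[str, list[set[str]]]
    clusters: dict[str, dict[str, int]]
    quadrants: "pd.DataFrame"
    quadrant_summary: dict[str, int]
    contribution: dict[str, float]
    manifest: dict


def _write(df: pd.DataFrame, path: str) -> int:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return len(df)


def run(config: RunConfig, cohort: SyntheticCohort | None = None) -> RunArtifacts:
    """Execute the full pipeline and write all artifacts under ``outdir``."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    net_dir = os.path.join(config.outdir, "networks")
    os.makedirs(net_dir, exist_ok=True)
    manifest: dict = {
        "psnet_version": __version__,
        "seed": config.seed,
        "analysis_threshold": config.analysis_threshold,
        "retention_target": config.retention_target,
        "quadrant_threshold": config.quadrant_threshold,
        "n_clusters": config.n_clusters,
        "artifacts": {},
    }

    # ---- inputs -----------------------------------------------------------
    stage = "load"
    try:
        if cohort is not None:
            ws = workspace_from_cohort(cohort)
        elif config.synthetic is not None:
            cohort = simulate_cohort(config.synthetic)
            ws = workspace_from_cohort(cohort)
        else:
            ws = load_workspace(config.input_dir)  # type: ignore[arg-type]
        manifest["n_series"] = len(ws.corpus.series)
        manifest["n_diseases"] = len(ws.corpus.diseases)
        manifest["n_gene_products"] = len(ws.corpus.gene_products)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise StageError(stage, str(exc)) from exc

    # ---- information content ---------------------------------------------
    stage = "ic"
    try:
        dags: dict[str, OntologyDAG] = {"HPO": ws.hpo, **ws.go}
        ic: dict[str, ICTable] = {}
        ic["HPO"] = compute_ic(
            ws.hpo, {d.omim_id: d.hpo_terms for d in ws.corpus.diseases.values()}
        )
        for ns in GO_NAMESPACES:
            ic[ns] = compute_ic(
                ws.go[ns],
                {gp.symbol: gp.go_terms.get(ns, set())
                 for gp in ws.corpus.gene_products.values()},
            )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- representative profiles -----------------------------------------
    stage = "profiles"
    try:
        profiles: dict[str, list[TermProfile]] = {}
        for ns, dag in dags.items():
            source = CLINICAL if ns == "HPO" else BIOLOGICAL
            got = []
            for ps_id in sorted(ws.corpus.series):
                prof = representative_profile(
                    ws.corpus.series[ps_id], ws.corpus, dag, ic[ns], source
                )
                if prof is not None:
                    got.append(prof)
            if len(got) < 2:
                raise ValueError(f"{ns}: fewer than two PS have usable annotations")
            profiles[ns] = got
            logger.info("profiles[%s]: %d series", ns, len(got))
        with open(os.path.join(config.outdir, "profiles.tsv"), "w") as fh:
            profiles_to_tsv([p for ps in profiles.values() for p in ps], fh)
        manifest["artifacts"]["profiles.tsv"] = sum(
            len(p) for ps in profiles.values() for p in ps
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- similarity coefficients -----------------------------------------
    stage = "similarity"
    try:
        coefficients = {
            ns: all_pair_coefficients(profiles[ns], dags[ns], ic[ns])
            for ns in profiles
        }
        diagonal = {
            ns: self_coefficients(profiles[ns], dags[ns], ic[ns]) for ns in profiles
        }
        with open(os.path.join(config.outdir, "coefficients.tsv"), "w") as fh:
            coefficients_to_tsv(
                [c for cs in coefficients.values() for c in cs], fh
            )
        manifest["artifacts"]["coefficients.tsv"] = sum(
            len(c) for c in coefficients.values()
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- networks ---------------------------------------------------------
    stage = "networks"
    try:
        networks: dict[str, SimilarityNetwork] = {}
        for ns, name in NETWORK_OF_NAMESPACE.items():
            networks[name] = assemble(coefficients[ns], name)
        networks["BSN"] = merge_max(
            networks["BSN-BP"], networks["BSN-CC"], networks["BSN-MF"]
        )
        contribution = contribution_fractions(networks["BSN"])
        for name, net in networks.items():
            with open(os.path.join(net_dir, f"{name}.tsv"), "w") as fh:
                write_edge_tsv(net, fh)
            write_graphml(net, os.path.join(net_dir, f"{name}.graphml"))
            manifest["artifacts"][f"networks/{name}.tsv"] = net.n_edges
            logger.info("network %s: %d nodes, %d edges", name, net.n_nodes, net.n_edges)
        manifest["bsn_contribution"] = contribution
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- topology stats ---------------------------------------------------
    stage = "stats"
    try:
        per_net: dict[str, dict[float, object]] = {}
        for name, net in networks.items():
            per_net[name] = {0.0: topology_stats(net)}
            cut = apply_threshold(net, config.analysis_threshold)
            if cut.n_nodes >= 2:
                per_net[name][config.analysis_threshold] = topology_stats(cut)
            else:
                logger.warning(
                    "%s: fewer than two nodes survive threshold %.3g; "
                    "topology stats skipped at that threshold",
                    name,
                    config.analysis_threshold,
                )
        stats_df = stats_table(per_net)  # type: ignore[arg-type]
        manifest["artifacts"]["stats.tsv"] = _write(
            stats_df, os.path.join(config.outdir, "stats.tsv")
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- fragmentation curves --------------------------------------------
    stage = "fragmentation"
    try:
        frag_rows = []
        for name, net in networks.items():
            w_max = max(net.edges.values())
            grid = list(np.linspace(0.0, w_max, config.n_fragmentation_points))
            curve = fragmentation_curve(net, grid)
            frag_rows.extend(
                {
                    "network": name,
                    "threshold": t,
                    "node_fraction": nf,
                    "edge_fraction": ef,
                }
                for t, nf, ef in zip(
                    curve.thresholds, curve.node_fraction, curve.edge_fraction
                )
            )
        frag_df = pd.DataFrame(frag_rows)
        manifest["artifacts"]["fragmentation.tsv"] = _write(
            frag_df, os.path.join(config.outdir, "fragmentation.tsv")
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- islands and clusters at the retention threshold ------------------
    stage = "islands"
    try:
        retention: dict[str, tuple[float, float]] = {}
        island_map: dict[str, list[set[str]]] = {}
        cluster_map: dict[str, dict[str, int]] = {}
        island_rows = []
        cluster_rows = []
        namespace_of_network = {v: k for k, v in NETWORK_OF_NAMESPACE.items()}
        for name, net in networks.items():
            t, frac = threshold_for_node_fraction(net, config.retention_target)
            retention[name] = (t, frac)
            cut = apply_threshold(net, t)
            comps = islands(cut)
            island_map[name] = comps
            for i, comp in enumerate(comps, start=1):
                for ps_id in sorted(comp):
                    island_rows.append(
                        {"network": name, "threshold": t, "island": i, "ps_id": ps_id}
                    )
            # cluster the retained PS on their full similarity-profile rows
            retained = sorted(cut.nodes)
            if len(retained) < 2:
                continue
            ns = namespace_of_network.get(name)
            if ns is not None:
                pair_map = coefficient_map(coefficients[ns])
                diag = diagonal[ns]
            else:  # general BSN: edges are the per-pair maxima
                pair_map = dict(networks["BSN"].edges)
                diag = {
                    p: max(diagonal[n].get(p, 0.0) for n in GO_NAMESPACES)
                    for p in retained
                }
            sub = [
                SimilarityCoefficient(a, b, name, pair_map[(a, b)])
                for i, a in enumerate(retained)
                for b in retained[i + 1:]
            ]
            matrix = full_similarity_matrix(
                sub, retained, {p: diag[p] for p in retained}
            )
            k = min(config.n_clusters, len(retained))
            assignment = average_linkage_cluster(matrix, k)
            cluster_map[name] = assignment.as_dict()
            cluster_rows.extend(
                {"network": name, "ps_id": p, "cluster": c}
                for p, c in sorted(assignment.as_dict().items())
            )
        manifest["retention"] = {
            name: {"threshold": t, "node_fraction": f}
            for name, (t, f) in retention.items()
        }
        manifest["artifacts"]["islands.tsv"] = _write(
            pd.DataFrame(island_rows), os.path.join(config.outdir, "islands.tsv")
        )
        manifest["artifacts"]["clusters.tsv"] = _write(
            pd.DataFrame(cluster_rows), os.path.join(config.outdir, "clusters.tsv")
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- quadrant analysis -------------------------------------------------
    stage = "quadrants"
    try:
        clinical = coefficient_map(coefficients["HPO"])
        biological = dict(networks["BSN"].edges)
        summary = quadrant_counts(clinical, biological, config.quadrant_threshold)
        qdf = quadrant_table(summary)
        manifest["artifacts"]["quadrant_pairs.tsv"] = _write(
            qdf, os.path.join(config.outdir, "quadrant_pairs.tsv")
        )
        manifest["quadrants"] = summary.counts
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return RunArtifacts(
        outdir=config.outdir,
        profiles=profiles,
        networks=networks,
        stats=stats_df,
        fragmentation=frag_df,
        retention=retention,
        islands=island_map,
        clusters=cluster_map,
        quadrants=qdf,
        quadrant_summary=summary.counts,
        contribution=contribution,
        manifest=manifest,
    )


def percent_edges_removed(n_edges_before: int, n_edges_after: int) -> float:
    """Edge loss across a thresholding step, as a percentage."""
    if n_edges_before <= 0:
        raise ValueError("need a positive pre-threshold edge count")
    return 100.0 * (1.0 - n_edges_after / n_edges_before)


def percent_nodes_lost(n_nodes_before: int, n_nodes_after: int) -> float:
    """Node loss across a thresholding step, as a percentage."""
    if n_nodes_before <= 0:
        raise ValueError("need a positive pre-threshold node count")
    return 100.0 * (1.0 - n_nodes_after / n_nodes_before)


def retention_percent(n_retained: int, n_total: int) -> float:
    """Retained nodes as a percentage of the unthresholded network."""
    if n_total <= 0:
        raise ValueError("need a positive total node count")
    return 100.0 * n_retained / n_total
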