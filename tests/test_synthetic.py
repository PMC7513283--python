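import io

import numpy as np
import pytest

from psnet.corpus import parse_gaf, parse_phenotype_annotations, write_gaf, write_phenotype_annotations
from psnet.ontology import compute_ic, parse_obo, write_obo
from psnet.profiles import CLINICAL, representative_profile
from psnet.similarity import all_pair_coefficients, coefficient_map, self_coefficients
from psnet.cluster import average_linkage_cluster, full_similarity_matrix
from psnet.synthetic import (
    SyntheticConfig,
    make_three_series_example,
    simulate_cohort,
    write_cohort,
)


def _clinical_coefficients(cohort):
    corpus = cohort.corpus
    ic = compute_ic(
        cohort.hpo, {d.omim_id: d.hpo_terms for d in corpus.diseases.values()}
    )
    profiles = [
        representative_profile(corpus.series[p], corpus, cohort.hpo, ic, CLINICAL)
        for p in sorted(corpus.series)
    ]
    return profiles, all_pair_coefficients(profiles, cohort.hpo, ic), ic


# ---------------------------------------------------------------------------
# configuration and determinism

def test_infeasible_overlap_contrast_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SyntheticConfig(
            within_group_term_overlap=0.2, between_group_term_overlap=0.5
        ).validate()


def test_same_seed_gives_byte_identical_workspace(tmp_path):
    for sub in ("a", "b"):
        write_cohort(simulate_cohort(SyntheticConfig(seed=13)), tmp_path / sub)
    for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes(), name


def test_different_seeds_differ(tmp_path):
    c1 = simulate_cohort(SyntheticConfig(seed=1))
    c2 = simulate_cohort(SyntheticConfig(seed=2))
    assert {d.omim_id: d.hpo_terms for d in c1.corpus.diseases.values()} != {
        d.omim_id: d.hpo_terms for d in c2.corpus.diseases.values()
    }


# ---------------------------------------------------------------------------
# planted structure

@pytest.mark.parametrize("seed", range(20))
def test_within_group_similarity_exceeds_between_group(seed):
    """Zero noise: mean within-group BMA strictly exceeds between-group."""
    cohort = simulate_cohort(
        SyntheticConfig(seed=seed, n_ps=12, n_planted_groups=4, annotation_noise=0.0)
    )
    _, coeffs, _ = _clinical_coefficients(cohort)
    group = cohort.truth.group_of
    within = [c.w for c in coeffs if group[c.ps_a] == group[c.ps_b]]
    between = [c.w for c in coeffs if group[c.ps_a] != group[c.ps_b]]
    assert np.mean(within) > np.mean(between)


@pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
def test_planted_groups_recovered_by_clustering_at_zero_noise(seed):
    sklearn = pytest.importorskip("sklearn.metrics")
    cohort = simulate_cohort(SyntheticConfig(seed=seed, annotation_noise=0.0))
    profiles, coeffs, ic = _clinical_coefficients(cohort)
    diag = self_coefficients(profiles, cohort.hpo, ic)
    ids = [p.ps_id for p in profiles]
    matrix = full_similarity_matrix(coeffs, ids, diag)
    assignment = average_linkage_cluster(
        matrix, cohort.config.n_planted_groups
    )
    ari = sklearn.adjusted_rand_score(
        cohort.truth.group_labels(ids), assignment.labels
    )
    assert ari == 1.0


def test_recovery_degrades_with_noise_on_average():
    sklearn = pytest.importorskip("sklearn.metrics")

    def mean_ari(noise):
        out = []
        for seed in (1, 2, 3):
            cohort = simulate_cohort(
                SyntheticConfig(seed=seed, annotation_noise=noise)
            )
            profiles, coeffs, ic = _clinical_coefficients(cohort)
            diag = self_coefficients(profiles, cohort.hpo, ic)
            ids = [p.ps_id for p in profiles]
            assignment = average_linkage_cluster(
                full_similarity_matrix(coeffs, ids, diag),
                cohort.config.n_planted_groups,
            )
            out.append(
                sklearn.adjusted_rand_score(
                    cohort.truth.group_labels(ids), assignment.labels
                )
            )
        return float(np.mean(out))

    assert mean_ari(0.0) >= mean_ari(0.6)


def test_quadrant_modes_plant_all_four_regimes():
    """Groups planted clin-only / bio-only / both / neither land in IV/III/II/I."""
    from psnet.networks import assemble, merge_max
    from psnet.cluster import quadrant_counts
    from psnet.profiles import BIOLOGICAL

    modes = ("both", "bio", "clin", "neither") * 2
    cohort = simulate_cohort(
        SyntheticConfig(seed=2, group_modes=modes, annotation_noise=0.0)
    )
    corpus = cohort.corpus
    _, clin_coeffs, _ = _clinical_coefficients(cohort)
    clinical = coefficient_map(clin_coeffs)
    nets = {}
    for ns, dag in cohort.go.items():
        ic = compute_ic(
            dag,
            {gp.symbol: gp.go_terms.get(ns, set())
             for gp in corpus.gene_products.values()},
        )
        profs = [
            representative_profile(corpus.series[p], corpus, dag, ic, BIOLOGICAL)
            for p in sorted(corpus.series)
        ]
        nets[ns] = assemble(all_pair_coefficients(profs, dag, ic), "BSN-" + ns[3:])
    biological = dict(
        merge_max(nets["GO-BP"], nets["GO-CC"], nets["GO-MF"]).edges
    )

    truth = cohort.truth
    expected = {pair: truth.expected_quadrant(*pair) for pair in clinical}
    # the cutoff lies between the planted levels: above every pair planted
    # low on an axis, below every pair planted high on it
    clin_high = [clinical[p] for p, q in expected.items() if q in ("II", "IV")]
    clin_low = [clinical[p] for p, q in expected.items() if q in ("I", "III")]
    bio_high = [biological[p] for p, q in expected.items() if q in ("II", "III")]
    bio_low = [biological[p] for p, q in expected.items() if q in ("I", "IV")]
    assert min(clin_high) > max(clin_low)
    assert min(bio_high) > max(bio_low)
    threshold = (
        max(max(clin_low), max(bio_low)) + min(min(clin_high), min(bio_high))
    ) / 2
    summary = quadrant_counts(clinical, biological, threshold)
    for q, pairs in summary.pairs.items():
        for pair in pairs:
            assert expected[pair] == q


def test_dominant_subontology_carries_within_group_biology():
    from psnet.profiles import BIOLOGICAL

    cohort = simulate_cohort(SyntheticConfig(seed=3, annotation_noise=0.0))
    corpus = cohort.corpus
    truth = cohort.truth
    per_ns = {}
    for ns, dag in cohort.go.items():
        ic = compute_ic(
            dag,
            {gp.symbol: gp.go_terms.get(ns, set())
             for gp in corpus.gene_products.values()},
        )
        profs = [
            representative_profile(corpus.series[p], corpus, dag, ic, BIOLOGICAL)
            for p in sorted(corpus.series)
        ]
        per_ns[ns] = coefficient_map(all_pair_coefficients(profs, dag, ic))
    for pair in next(iter(per_ns.values())):
        ga, gb = truth.group_of[pair[0]], truth.group_of[pair[1]]
        if ga == gb:
            dominant = truth.dominant_subontology[ga]
            assert per_ns[dominant][pair] == max(m[pair] for m in per_ns.values())


# ---------------------------------------------------------------------------
# the worked example round-trips through every writer

def test_figure_fixture_round_trips_through_writers():
    hpo, go_bp, corpus = make_three_series_example()

    buf = io.StringIO()
    write_obo(hpo, buf)
    assert parse_obo(buf.getvalue(), "HPO").terms.keys() == hpo.terms.keys()

    buf = io.StringIO()
    write_phenotype_annotations(
        {d.omim_id: d.hpo_terms for d in corpus.diseases.values()}, buf
    )
    again = parse_phenotype_annotations(buf.getvalue()).annotations
    assert again == {d.omim_id: d.hpo_terms for d in corpus.diseases.values()}

    buf = io.StringIO()
    write_gaf({gp.symbol: gp.go_terms for gp in corpus.gene_products.values()}, buf)
    gaf = parse_gaf(buf.getvalue()).annotations
    for symbol, gp in corpus.gene_products.items():
        assert gaf[symbol]["GO-BP"] == gp.go_terms["GO-BP"]
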