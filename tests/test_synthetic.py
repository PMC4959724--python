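"""Ground-truthed generators: planted SSRs, allotetraploid variants, admixture."""

from collections import Counter

import numpy as np
import pytest

from milletmarkers import (find_ssrs, plant_ssrs, random_ssr_specs,
                           simulate_allotetraploid_variants,
                           simulate_genotype_matrix)
from milletmarkers.synthetic import (DEFAULT_SPECTRUM_WEIGHTS, HOMEOLOG_RATE,
                                     SSRTruth)
from milletmarkers.variants import substitution_class

# ------------------------------------------------------------ plant_ssrs


def test_empty_plant_is_trivial():
    records, truths = plant_ssrs(1, 1000, [], seed=7)
    assert len(records) == 1 and len(records[0][1]) == 1000
    assert truths == []
    assert find_ssrs(*records[0]) == []  # clean background


def test_planted_ssr_round_trip():
    spec = SSRTruth("contig_1", 100, "AT", 6)
    records, truths = plant_ssrs(1, 1000, [spec], seed=7)
    loci = find_ssrs(*records[0])
    assert [(l.start, l.end, l.motif) for l in loci] == [(100, 112, "AT")]
    assert truths == [spec]


def test_plant_recall_and_precision_are_exact(rng):
    specs = random_ssr_specs(30, 5, 8000, seed=5)
    records, truths = plant_ssrs(5, 8000, specs, seed=5)
    mined = {(l.contig_id, l.start, l.end, l.motif)
             for name, seq in records for l in find_ssrs(name, seq)}
    planted = {(t.contig_id, t.start, t.end, t.motif) for t in truths}
    assert mined == planted  # 100% recall and 100% precision


def test_plant_rejects_overlap_and_reducible_motifs():
    with pytest.raises(ValueError):
        plant_ssrs(1, 1000, [SSRTruth("contig_1", 0, "AT", 6),
                             SSRTruth("contig_1", 5, "GC", 6)], seed=1)
    with pytest.raises(ValueError):
        SSRTruth("contig_1", 0, "ATAT", 5)
    with pytest.raises(ValueError):
        SSRTruth("contig_1", 0, "AT", 4)
    with pytest.raises(ValueError):
        plant_ssrs(1, 50, [SSRTruth("contig_1", 40, "ACG", 5)], seed=1)


def test_plant_is_seed_deterministic():
    a, _ = plant_ssrs(3, 2000, random_ssr_specs(5, 3, 2000, seed=2), seed=2)
    b, _ = plant_ssrs(3, 2000, random_ssr_specs(5, 3, 2000, seed=2), seed=2)
    assert a == b


def test_default_class_mix_is_apportioned_exactly():
    """Unit-size mix follows the observed 80 / 18.3 / 1.2 split."""
    specs = random_ssr_specs(1000, 10, 10_000, seed=3)
    counts = Counter(len(s.motif) for s in specs)
    weights = np.array([0.80, 0.183, 0.012])
    expected = weights / weights.sum() * 1000
    assert counts[2] in (int(expected[0]), int(expected[0]) + 1)
    assert abs(counts[3] - expected[1]) <= 1
    assert abs(counts[4] - expected[2]) <= 1
    assert sum(counts.values()) == 1000


# ------------------------------------------------------------- variants


def test_zero_rates_rejected():
    with pytest.raises(ValueError):
        simulate_allotetraploid_variants(1000, homeolog_rate=0.0)
    with pytest.raises(ValueError):
        simulate_allotetraploid_variants(1000, allelic_rate=1.5)


def test_homeolog_count_matches_binomial_expectation():
    """1/657 bp over 100 kb: ~152 homeologous sites, within 3 sigma."""
    L = 100_000
    expected = L * HOMEOLOG_RATE
    sigma = np.sqrt(L * HOMEOLOG_RATE * (1 - HOMEOLOG_RATE))
    counts = []
    for seed in range(10):
        _, _, truths = simulate_allotetraploid_variants(L, seed=seed)
        counts.append(sum(t.kind == "homeologous" for t in truths))
    assert abs(np.mean(counts) - expected) < 3 * sigma / np.sqrt(len(counts))


def test_homeologs_present_in_at_least_one_self_set():
    self_sets, combined, truths = simulate_allotetraploid_variants(
        50_000, seed=2)
    self_union = {s.key for sites in self_sets.values() for s in sites}
    hom = {(t.contig_id, t.position) for t in truths if t.kind == "homeologous"}
    assert self_union == hom
    # self-set sites are heterozygous calls of that genotype
    for g, sites in self_sets.items():
        assert all(s.calls[g] == (0, 1) for s in sites)
    # allelic truths never appear in self sets, only in the combined set
    allelic = {(t.contig_id, t.position) for t in truths if t.kind == "allelic"}
    assert allelic.isdisjoint(self_union)
    assert allelic <= {s.key for s in combined}


def test_truth_positions_are_collision_free():
    _, _, truths = simulate_allotetraploid_variants(20_000, seed=3)
    positions = [(t.contig_id, t.position) for t in truths]
    assert len(positions) == len(set(positions))


def test_truth_sites_pass_filters_and_decoys_fail():
    _, combined, truths = simulate_allotetraploid_variants(
        50_000, seed=6, degraded_fraction=0.3)
    truth_pos = {t.position for t in truths}
    for s in combined:
        if s.position in truth_pos:
            assert s.quality >= 30 and s.depth >= 3
        else:
            assert s.quality < 30 or s.depth < 3


def test_substitution_spectrum_matches_generator_weights():
    """CT/AG near 62% and CG near 7.5% of simulated homeologous sites."""
    classes: Counter = Counter()
    n = 0
    for seed in range(8):
        _, _, truths = simulate_allotetraploid_variants(200_000, seed=seed)
        for t in truths:
            if t.kind == "homeologous":
                classes[substitution_class(t.ref, t.alt)] += 1
                n += 1
    for cls, weight in DEFAULT_SPECTRUM_WEIGHTS.items():
        sigma = np.sqrt(weight * (1 - weight) / n)
        assert abs(classes[cls] / n - weight) < 4 * sigma


def test_variants_seed_deterministic():
    a = simulate_allotetraploid_variants(20_000, seed=9)
    b = simulate_allotetraploid_variants(20_000, seed=9)
    assert a[2] == b[2]
    assert [(s.key, s.quality, s.depth) for s in a[1]] == \
           [(s.key, s.quality, s.depth) for s in b[1]]


# ------------------------------------------------------- genotype matrix


def test_k1_truth_is_degenerate():
    matrix, truth = simulate_genotype_matrix(1, 10, 20, seed=1)
    assert truth.K == 1
    assert np.allclose(truth.Q_true, 1.0)


def test_maximal_divergence_separates_populations():
    matrix, truth = simulate_genotype_matrix(2, 8, 30, divergence=1.0,
                                             alpha=1e-6, seed=2)
    assert np.allclose(np.sort(truth.P_true, axis=0),
                       np.array([[0.0] * 30, [1.0] * 30]))
    # every sample homozygous for its population's allele
    for i, sid in enumerate(matrix.sample_ids):
        k = 0 if i < 8 else 1
        allele = "A" if truth.P_true[k, 0] == 0.0 else "B"
        for c in matrix.calls[i]:
            assert c == (allele, allele)


def test_q_rows_sum_to_one_and_missing_rate(rng):
    matrix, truth = simulate_genotype_matrix(3, 10, 200, missing_rate=0.1,
                                             seed=5)
    assert np.allclose(truth.Q_true.sum(axis=1), 1.0)
    missing = sum(c is None for row in matrix.calls for c in row)
    total = matrix.n_samples * matrix.n_loci
    assert abs(missing / total - 0.1) < 3 * np.sqrt(0.1 * 0.9 / total)


def test_matrix_generator_rejects_bad_arguments():
    with pytest.raises(ValueError):
        simulate_genotype_matrix(0, 5, 5)
    with pytest.raises(ValueError):
        simulate_genotype_matrix(2, 5, 5, alpha=0.0)
    with pytest.raises(ValueError):
        simulate_genotype_matrix(2, 5, 5, selfing=1.5)


def test_matrix_seed_deterministic():
    a, _ = simulate_genotype_matrix(2, 6, 25, missing_rate=0.05, seed=13)
    b, _ = simulate_genotype_matrix(2, 6, 25, missing_rate=0.05, seed=13)
    assert a.calls == b.calls and a.sample_ids == b.sample_ids
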