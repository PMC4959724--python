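"""IBS distance, UPGMA, admixture Gibbs sampling, LnP(D) and delta-K."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

from milletmarkers import (GenotypeMatrix, align_runs, best_k, delta_k,
                           gibbs_admixture, ibs_distance, lnpd,
                           simulate_genotype_matrix, upgma)
from milletmarkers.popstruct import StructureRun, ladderize_with_outgroup

# ------------------------------------------------------------------- IBS


def _pair_matrix(call_a, call_b):
    return GenotypeMatrix(["x", "y"], ["L1"], [[call_a], [call_b]])


def test_ibs_identical_and_disjoint():
    assert ibs_distance(_pair_matrix(("A", "A"), ("A", "A")))["x", "y"] == 0.0
    assert ibs_distance(_pair_matrix(("A", "A"), ("B", "B")))["x", "y"] == 1.0


def test_ibs_half_shared():
    assert ibs_distance(_pair_matrix(("A", "A"), ("A", "G")))["x", "y"] == 0.5


def test_ibs_requires_shared_locus():
    m = GenotypeMatrix(["x", "y"], ["L1", "L2"],
                       [[("A", "A"), None], [None, ("A", "A")]])
    with pytest.raises(ValueError, match="share no called locus"):
        ibs_distance(m)


# ----------------------------------------------------------------- UPGMA


def test_upgma_two_taxa_cherry():
    tree = upgma(DistanceMatrix([[0, 3], [3, 0]], ids=["X", "Y"]))
    tips = {t.name: t.length for t in tree.tips()}
    assert tips == {"X": 1.5, "Y": 1.5}


def test_upgma_three_taxa_hand_example():
    dm = DistanceMatrix([[0, 2, 8], [2, 0, 8], [8, 8, 0]], ids=["A", "B", "C"])
    tree = upgma(dm)
    dists = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
    assert dists == {"A": 4.0, "B": 4.0, "C": 4.0}
    ab = tree.lowest_common_ancestor(["A", "B"])
    assert {t.name for t in ab.tips()} == {"A", "B"}
    assert ab.children[0].length == 1.0  # merged at height 1


def test_upgma_matches_scipy_average_linkage(rng):
    """Tip-to-tip (cophenetic) distances equal scipy's average linkage."""
    for n in (4, 5, 6, 7, 8):
        for _ in range(10):
            pts = rng.random((n, 3))
            d = squareform(np.round(
                np.linalg.norm(pts[:, None] - pts[None], axis=-1), 6))
            ids = [f"t{i}" for i in range(n)]
            tree = upgma(DistanceMatrix(squareform(d), ids=ids))
            got = tree.tip_tip_distances(ids)
            expected = squareform(cophenet(linkage(d, method="average")))
            assert np.allclose(np.asarray(got.data), expected, atol=1e-9)


def test_upgma_is_ultrametric(rng):
    d = squareform(np.round(rng.random(28), 5))
    tree = upgma(DistanceMatrix(d, ids=[f"t{i}" for i in range(8)]))
    heights = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
    assert max(heights) - min(heights) < 1e-9


def test_upgma_rejects_nan():
    class Stub:
        ids = ("X", "Y")
        data = np.array([[0.0, np.nan], [np.nan, 0.0]])

    with pytest.raises(ValueError):
        upgma(Stub())


def test_ladderize_moves_outgroup_first_without_rerooting():
    dm = DistanceMatrix([[0, 1, 9, 9], [1, 0, 9, 9], [9, 9, 0, 2], [9, 9, 2, 0]],
                        ids=["A", "B", "OUT", "D"])
    tree = upgma(dm)
    before = sorted(tree.tip_tip_distances(["A", "B", "OUT", "D"]).condensed_form())
    tree = ladderize_with_outgroup(tree, "OUT")
    after = sorted(tree.tip_tip_distances(["A", "B", "OUT", "D"]).condensed_form())
    assert np.allclose(before, after)  # distances untouched
    first_clade_tips = {t.name for t in tree.children[0].tips()} \
        if tree.children[0].children else {tree.children[0].name}
    assert "OUT" in first_clade_tips
    with pytest.raises(ValueError):
        ladderize_with_outgroup(tree, "missing")


# ------------------------------------------------------------- admixture


def test_gibbs_k1_gives_unit_q():
    matrix, _ = simulate_genotype_matrix(1, 8, 20, seed=3)
    run = gibbs_admixture(matrix, K=1, burnin=10, reps=30, seed=0)
    assert np.allclose(run.Q, 1.0)


def test_gibbs_rejects_bad_arguments():
    matrix, _ = simulate_genotype_matrix(1, 4, 10, seed=3)
    with pytest.raises(ValueError):
        gibbs_admixture(matrix, K=5, burnin=1, reps=1)
    with pytest.raises(ValueError):
        gibbs_admixture(matrix, K=2, alpha=0.0)


def test_gibbs_seed_deterministic():
    matrix, _ = simulate_genotype_matrix(2, 5, 15, seed=3)
    a = gibbs_admixture(matrix, 2, burnin=20, reps=50, seed=7)
    b = gibbs_admixture(matrix, 2, burnin=20, reps=50, seed=7)
    assert np.array_equal(a.Q, b.Q)
    assert np.array_equal(a.loglik_trace, b.loglik_trace)


def test_gibbs_q_rows_sum_to_one_and_p_normalised():
    matrix, _ = simulate_genotype_matrix(2, 6, 20, missing_rate=0.1, seed=4)
    run = gibbs_admixture(matrix, 3, burnin=20, reps=50, seed=1)
    assert np.allclose(run.Q.sum(axis=1), 1.0)
    assert np.allclose(run.P.sum(axis=2), 1.0)


def test_gibbs_recovers_two_population_structure():
    """Strongly differentiated K=2 fixture: aligned Q within 0.1 MAE."""
    matrix, truth = simulate_genotype_matrix(
        2, 25, 100, divergence=1.0, alpha=0.1, seed=17)
    run = gibbs_admixture(matrix, 2, burnin=1000, reps=5000, alpha=0.1, seed=1)
    mae = min(np.abs(run.Q - truth.Q_true).mean(),
              np.abs(run.Q[:, ::-1] - truth.Q_true).mean())
    assert mae < 0.1
    # chain is stationary: last quarter no worse than first quarter
    trace = run.loglik_trace
    q = len(trace) // 4
    assert trace[-q:].mean() >= trace[:q].mean() - 2 * trace.std()


# ------------------------------------------------------------------ lnpd


def test_lnpd_examples():
    assert lnpd(np.array([-100.0, -100.0, -100.0])) == -100.0
    assert lnpd(np.array([-100.0, -102.0])) == -102.0
    low_var = lnpd(np.array([-101.0, -101.0, -101.0]))
    high_var = lnpd(np.array([-98.0, -101.0, -104.0]))
    assert high_var < low_var  # equal mean, more variance, lower evidence
    with pytest.raises(ValueError):
        lnpd(np.array([]))


def test_lnpd_invariant_under_label_permutation():
    matrix, _ = simulate_genotype_matrix(2, 5, 15, seed=3)
    run = gibbs_admixture(matrix, 2, burnin=20, reps=50, seed=7)
    permuted = StructureRun(run.K, run.Q[:, ::-1], run.P[::-1], run.alpha,
                            run.loglik_trace, run.seed, run.burnin, run.reps)
    assert lnpd(permuted) == lnpd(run)


# --------------------------------------------------------------- delta-K


def test_delta_k_linear_lnpd_gives_zero():
    table = {k: [-1000.0 + 10 * k + eps for eps in (-0.5, 0.5)]
             for k in range(1, 6)}
    result = delta_k(table)
    interior = result["delta_k"].dropna()
    assert (interior == 0).all()


def test_delta_k_slope_break_detected(rng):
    """argmax delta-K equals the planted slope-break K on 100 random tables."""
    for _ in range(100):
        kb = int(rng.integers(2, 6))
        s1, s2 = 100.0, 5.0
        table = {}
        for k in range(1, 7):
            mean = -5000 + s1 * min(k, kb) + s2 * max(0, k - kb)
            table[k] = list(mean + rng.normal(0, 1.0, size=4))
        assert best_k(delta_k(table)) == kb


def test_delta_k_preconditions():
    with pytest.raises(ValueError):
        delta_k({1: [0.0], 2: [0.0]})
    # zero sd flagged undefined, not an error
    table = {k: [float(k), float(k)] for k in range(1, 4)}
    result = delta_k(table)
    assert result["delta_k"].isna().all()


# ----------------------------------------------------------- run combine


def _run(Q):
    return StructureRun(Q.shape[1], Q, None, 1.0, np.zeros(2), 0, 0, 2)


def test_align_identity_and_swap(rng):
    Q = rng.dirichlet((1, 1), size=12)
    assert np.allclose(align_runs([_run(Q), _run(Q.copy())]), Q)
    assert np.allclose(align_runs([_run(Q), _run(Q[:, ::-1])]), Q)


def test_align_exhaustive_and_assignment_modes_agree(rng):
    for K in (2, 3, 4):
        runs = [_run(rng.dirichlet(np.ones(K), size=15)) for _ in range(4)]
        a = align_runs(runs, exhaustive=True)
        b = align_runs(runs, exhaustive=False)
        assert np.allclose(a, b)


def test_align_rejects_mixed_k(rng):
    with pytest.raises(ValueError):
        align_runs([_run(rng.dirichlet((1, 1), size=5)),
                    _run(rng.dirichlet((1, 1, 1), size=5))])


def test_align_output_rows_sum_to_one(rng):
    runs = [_run(rng.dirichlet((0.5, 0.5, 0.5), size=10)) for _ in range(3)]
    assert np.allclose(align_runs(runs).sum(axis=1), 1.0)
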