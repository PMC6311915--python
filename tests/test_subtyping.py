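import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from csprv import (
    ClusterAssignment,
    SurvivalRecord,
    logrank_test,
    select_alpha,
    spectral_cluster,
)
from csprv.similarity import SimilarityMatrix
from csprv.subtyping import normalized_laplacian


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def set_partitions(n, m):
    """All partitions of range(n) into exactly m non-empty blocks
    (restricted-growth-string enumeration)."""
    def rec(i, labels, used):
        if i == n:
            if used == m:
                yield tuple(labels)
            return
        for lab in range(min(used + 1, m)):
            labels.append(lab)
            yield from rec(i + 1, labels, max(used, lab + 1))
            labels.pop()
    yield from rec(0, [], 0)


def trace_objective(W, labels):
    """Trace(Q' L Q) for the scaled partition matrix of a discrete labeling."""
    L = normalized_laplacian(W)
    total = 0.0
    for lab in set(labels):
        idx = np.array([i for i, l in enumerate(labels) if l == lab])
        total += L[np.ix_(idx, idx)].sum() / len(idx)
    return total


def best_partition_bruteforce(W, m):
    labelings = list(set_partitions(W.shape[0], m))
    objs = [trace_objective(W, labs) for labs in labelings]
    return labelings[int(np.argmin(objs))]


def planted_block_similarity(sizes, within=0.9, between=0.1, noise=0.02, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    v = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    jitter = rng.uniform(-noise, noise, (n, n))
    v += (jitter + jitter.T) / 2
    np.fill_diagonal(v, 1.0)
    W = SimilarityMatrix(v, [f"s{i}" for i in range(n)], "combined")
    return W, labels + 1


def two_group_logrank_oracle(times, events, groups):
    """Textbook two-group log-rank arithmetic: observed minus expected events
    in group 1 at each distinct event time, hypergeometric variance."""
    order = np.argsort(times)
    times, events, groups = (np.asarray(x)[order] for x in (times, events, groups))
    O_minus_E = 0.0
    V = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n_t = at_risk.sum()
        n1_t = (at_risk & (groups == 1)).sum()
        d_t = ((times == t) & (events == 1)).sum()
        d1_t = ((times == t) & (events == 1) & (groups == 1)).sum()
        O_minus_E += d1_t - d_t * n1_t / n_t
        if n_t > 1:
            V += d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    chi2 = O_minus_E ** 2 / V
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# spectral clustering
# ---------------------------------------------------------------------------

class TestSpectralCluster:
    def test_two_planted_blocks_recovered_exactly(self):
        W, truth = planted_block_similarity([5, 5], seed=1)
        assign = spectral_cluster(W, 2, seed=0)
        assert adjusted_rand_score(truth, assign.labels) == 1.0
        # and it coincides with exhaustive minimization of the trace objective
        brute = best_partition_bruteforce(W.values, 2)
        assert adjusted_rand_score(brute, assign.labels) == 1.0

    @pytest.mark.parametrize("sizes,m,seed", [
        ([5, 5], 2, 2), ([4, 6], 2, 3), ([3, 3, 4], 3, 4), ([2, 4, 3], 3, 5),
    ])
    def test_agrees_with_exhaustive_trace_minimization(self, sizes, m, seed):
        W, _ = planted_block_similarity(sizes, seed=seed)
        assign = spectral_cluster(W, m, seed=0)
        brute = best_partition_bruteforce(W.values, m)
        assert adjusted_rand_score(brute, assign.labels) == 1.0

    def test_m_equals_n_gives_singletons(self):
        W, _ = planted_block_similarity([2, 2], seed=6)
        assign = spectral_cluster(W, 4, seed=0)
        assert len(set(assign.labels.tolist())) == 4

    def test_permutation_equivariance_of_the_partition(self):
        W, _ = planted_block_similarity([5, 5], seed=7)
        assign = spectral_cluster(W, 2, seed=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(10)
        Wp = SimilarityMatrix(W.values[np.ix_(perm, perm)],
                              [W.sample_ids[i] for i in perm], "combined")
        assign_p = spectral_cluster(Wp, 2, seed=0)
        back = np.empty(10, dtype=int)
        back[perm] = assign_p.labels
        assert adjusted_rand_score(assign.labels, back) == 1.0

    def test_m_larger_than_n_rejected(self):
        W, _ = planted_block_similarity([2, 2], seed=8)
        with pytest.raises(ValueError):
            spectral_cluster(W, 5, seed=0)

    def test_cluster_assignment_invariants(self):
        with pytest.raises(ValueError, match="non-empty"):
            ClusterAssignment(["a", "b"], np.array([1, 1]), m=2)
        with pytest.raises(ValueError, match="outside"):
            ClusterAssignment(["a", "b"], np.array([1, 3]), m=2)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def make_assignment(labels):
    return ClusterAssignment([f"s{i}" for i in range(len(labels))],
                             np.asarray(labels), m=max(labels))


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        """Two groups with the same survival data: statistic 0, p = 1."""
        times = [5.0, 10.0, 15.0] * 2
        surv = [SurvivalRecord(f"s{i}", t, 1) for i, t in enumerate(times)]
        assign = make_assignment([1, 1, 1, 2, 2, 2])
        stat, p = logrank_test(assign, surv)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        surv = [SurvivalRecord(f"s{i}", float(t), int(e))
                for i, (t, e) in enumerate(zip(rng.exponential(100, 30),
                                               rng.integers(0, 2, 30)))]
        labels = rng.integers(1, 4, 30)
        labels[:3] = [1, 2, 3]
        a = make_assignment(labels.tolist())
        swapped = {1: 2, 2: 1, 3: 3}
        b = make_assignment([swapped[l] for l in labels])
        assert logrank_test(a, surv) == pytest.approx(logrank_test(b, surv))

    def test_two_group_toy_matches_textbook_arithmetic(self):
        """Early-event group (1,2,3) vs late group (4,5,6), all events."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        groups = [1, 1, 1, 2, 2, 2]
        surv = [SurvivalRecord(f"s{i}", t, 1) for i, t in enumerate(times)]
        stat, p = logrank_test(make_assignment(groups), surv)
        o_stat, o_p = two_group_logrank_oracle(times, [1] * 6, groups)
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_samples_without_clinical_rows_dropped(self, caplog):
        surv = [SurvivalRecord(f"s{i}", float(i + 1), 1) for i in range(4)]
        assign = make_assignment([1, 1, 2, 2, 1, 2])  # s4, s5 lack records
        stat, p = logrank_test(assign, surv)
        assert np.isfinite(stat)

    def test_single_group_after_join_rejected(self):
        surv = [SurvivalRecord("s0", 1.0, 1), SurvivalRecord("s1", 2.0, 1)]
        assign = make_assignment([1, 1, 2])  # group 2's sample has no record
        with pytest.raises(ValueError, match="2 non-empty groups"):
            logrank_test(assign, surv)


# ---------------------------------------------------------------------------
# alpha selection
# ---------------------------------------------------------------------------

def _views(seed=0, n=12):
    rng = np.random.default_rng(seed)
    def mk(view, labels):
        base = np.where(labels[:, None] == labels[None, :], 0.8, 0.2)
        jitter = rng.uniform(-0.05, 0.05, (n, n))
        v = base + (jitter + jitter.T) / 2
        np.fill_diagonal(v, 1.0)
        return SimilarityMatrix(v, [f"s{i}" for i in range(n)], view)
    informative = np.repeat([1, 2], n // 2)
    noise = rng.permutation(informative)
    return mk("gene", informative), mk("mirna", noise), informative


class TestSelectAlpha:
    def _surv(self, labels, seed=0):
        rng = np.random.default_rng(seed)
        scale = {1: 400.0, 2: 60.0}
        return [SurvivalRecord(f"s{i}", float(rng.exponential(scale[l])), 1)
                for i, l in enumerate(labels)]

    def test_single_element_grid_returned(self):
        Wg, Wm, truth = _views()
        report = select_alpha(Wg, Wm, self._surv(truth), 2, [0.3], seed=0)
        assert report.best_alpha == 0.3
        assert len(report.p_values) == 1

    def test_gene_signal_pushes_alpha_up(self):
        """Survival tracks the gene-view blocks, so fusion favors the gene view."""
        Wg, Wm, truth = _views(seed=1, n=20)
        report = select_alpha(Wg, Wm, self._surv(truth, seed=1), 2,
                              [0.0, 0.25, 0.5, 0.75, 1.0], seed=0)
        assert report.best_alpha >= 0.5

    def test_tie_breaks_toward_balanced_fusion(self):
        # identical views make every alpha tie exactly
        Wg, Wm, truth = _views(seed=2)
        Wm2 = SimilarityMatrix(Wg.values.copy(), list(Wg.sample_ids), "mirna")
        report = select_alpha(Wg, Wm2, self._surv(truth, seed=2), 2,
                              [0.0, 0.2, 0.5, 0.8, 1.0], seed=0)
        assert report.best_alpha == 0.5

    def test_empty_grid_rejected(self):
        Wg, Wm, truth = _views(seed=3)
        with pytest.raises(ValueError):
            select_alpha(Wg, Wm, self._surv(truth), 2, [], seed=0)
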