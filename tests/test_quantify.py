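import numpy as np
import pytest

from amplicycle.cycles import derive_cycles, find_simple_cycles, partition_cycles
from amplicycle.quantify import (
    build_design_matrix,
    filter_candidates,
    fit_lasso,
    select_cycles,
)


@pytest.fixture
def fig1c_cluster(fig1c_graph):
    g, fid = fig1c_graph
    cycles = find_simple_cycles(g)
    (cluster,) = partition_cycles(cycles, g.fragments)
    derive_cycles(cluster, g.fragments)
    return g, fid, cluster


class TestDesignMatrix:
    def test_duplicated_fragment_counts_twice(self, fig1c_cluster):
        g, fid, cluster = fig1c_cluster
        dm = build_design_matrix(cluster, list(g.fragments.values()))
        row_b = next(i for i, f in enumerate(dm.fragments) if f.fid == fid["B"])
        abdbc = next(
            i for i, c in enumerate(dm.cycles)
            if [f for f, _ in c.path].count(fid["B"]) == 2
        )
        assert dm.X[row_b, abdbc] == 2

    def test_entries_equal_independent_recount(self, fig1c_cluster):
        g, _, cluster = fig1c_cluster
        dm = build_design_matrix(cluster, list(g.fragments.values()))
        for i, c in enumerate(dm.cycles):
            for j, f in enumerate(dm.fragments):
                assert dm.X[j, i] == sum(1 for fid, _ in c.path if fid == f.fid)
        assert np.all(dm.X.sum(axis=0) >= 1)  # every column non-empty

    def test_single_cycle_over_one_fragment(self):
        from amplicycle.cycles import CycleCluster
        from amplicycle.fragments import Fragment
        from amplicycle.graph import AmpliconGraph

        g = AmpliconGraph()
        g.add_fragment(Fragment(0, "chr1", 1000, 2000, 40.0))
        g.add_junction((0, "t"), (0, "h"), "sv", 40.0, "DUP", 0)
        (cycle,) = find_simple_cycles(g)
        dm = build_design_matrix(CycleCluster(0, [cycle]), list(g.fragments.values()))
        assert dm.X.tolist() == [[1.0]]


def two_cycle_dm():
    """Design of the noiseless ABC(30x)/BD(20x) fixture, background 5x:
    rows A,B,C,D with Y = 35,55,35,25; columns ABC=(1,1,1,0), BD=(0,1,0,1)."""
    from amplicycle.cycles import Cycle, CycleCluster, JunctionRef
    from amplicycle.fragments import Fragment
    from amplicycle.quantify import DesignMatrix

    frags = [
        Fragment(0, "chr1", 0, 100, 35.0),
        Fragment(1, "chr1", 100, 200, 55.0),
        Fragment(2, "chr1", 200, 300, 35.0),
        Fragment(3, "chr1", 300, 400, 25.0),
    ]
    X = np.array([[1, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
    Y = np.array([35.0, 55.0, 35.0, 25.0])
    j = JunctionRef(0, "sv", "DUP", (0, "t"), (0, "h"), 30.0)
    cycles = [
        Cycle(((0, "+"), (1, "+"), (2, "+")), (j, j, j), canon_key="ABC"),
        Cycle(((1, "+"), (3, "+")), (j, j), canon_key="BD"),
    ]
    return DesignMatrix(frags, cycles, X, Y)


class TestFitLasso:
    def test_noiseless_recovery_and_unpenalized_limit(self):
        dm = two_cycle_dm()
        fit = fit_lasso(dm, alpha=0.1, background_cov=5.0)
        assert fit.beta == pytest.approx([30.0, 20.0], rel=0.02)
        assert fit.beta0 == pytest.approx(5.0, abs=0.5)
        exact = fit_lasso(dm, alpha=0.0, background_cov=5.0)
        assert exact.beta == pytest.approx([30.0, 20.0], abs=1e-6)
        assert exact.beta0 == pytest.approx(5.0, abs=1e-6)

    def test_zero_target_gives_zero_fit(self):
        dm = two_cycle_dm()
        dm.Y = np.zeros_like(dm.Y)
        fit = fit_lasso(dm, alpha=0.1)
        assert np.all(fit.beta == 0) and fit.beta0 == 0.0

    def test_objective_identity(self):
        """Reported objective equals the penalized cost recomputed
        independently from (X, Y, beta, beta0)."""
        dm = two_cycle_dm()
        for alpha in (0.1, 1.0):
            fit = fit_lasso(dm, alpha=alpha, background_cov=5.0)
            resid = dm.Y - fit.beta0 - dm.X @ fit.beta
            expected = np.mean(resid**2) + alpha * np.sum(np.abs(fit.beta))
            assert fit.objective == pytest.approx(expected, abs=1e-8)

    def test_single_cycle_uniform_coverage_splits_with_intercept(self):
        from amplicycle.quantify import DesignMatrix

        dm = two_cycle_dm()
        dm2 = DesignMatrix(dm.fragments[:2], dm.cycles[:1],
                           np.array([[1.0], [1.0]]), np.array([40.0, 40.0]))
        fit = fit_lasso(dm2, alpha=0.1)
        assert fit.beta[0] + fit.beta0 == pytest.approx(40.0, abs=1e-4)

    def test_nonnegativity_is_enforced(self):
        dm = two_cycle_dm()
        dm.Y = np.array([1.0, 50.0, 1.0, 50.0])  # would want beta_ABC < 0
        fit = fit_lasso(dm, alpha=0.1, background_cov=5.0)
        assert np.all(fit.beta >= 0)

    def test_scale_equivariance(self):
        dm = two_cycle_dm()
        base = fit_lasso(dm, alpha=0.1, background_cov=5.0)
        k = 7.0
        dm_scaled = two_cycle_dm()
        dm_scaled.Y = dm_scaled.Y * k
        scaled = fit_lasso(dm_scaled, alpha=0.1 * k, background_cov=5.0 * k)
        assert scaled.beta == pytest.approx(base.beta * k, rel=1e-4)
        assert scaled.beta0 == pytest.approx(base.beta0 * k, rel=1e-4)

    def test_sparsity_monotone_in_alpha(self):
        dm = two_cycle_dm()
        n_selected = []
        for alpha in (0.01, 0.1, 1.0, 5.0, 20.0, 100.0):
            fit = fit_lasso(dm, alpha=alpha, background_cov=5.0)
            n_selected.append(sum(q.selected for q in select_cycles(fit, dm)))
        assert n_selected == sorted(n_selected, reverse=True)

    def test_parameter_recovery_under_noise(self):
        """Synthetic clusters, Gaussian coverage noise sigma <= 2x: fitted
        proportions within max(10%, 2x) of truth in >= 95% of 200 trials."""
        rng = np.random.default_rng(42)
        ok = 0
        trials = 200
        for _ in range(trials):
            n_cyc = int(rng.integers(1, 6))
            n_private = int(rng.integers(3, 6))  # fragments per ring, as in
            n_shared = int(rng.integers(0, 3))   # multi-fragment amplicons
            n_frag = n_cyc * n_private + n_shared
            # each cycle gets private fragments (identifiability) plus
            # random shared ones
            X = np.zeros((n_frag, n_cyc))
            for i in range(n_cyc):
                X[i * n_private : (i + 1) * n_private, i] = 1
            for j in range(n_cyc * n_private, n_frag):
                members = rng.choice(n_cyc, size=int(rng.integers(1, n_cyc + 1)),
                                     replace=False)
                X[j, members] = 1
            beta_true = rng.uniform(10, 100, size=n_cyc)
            sigma = rng.uniform(0, 2)
            y = X @ beta_true + 5.0 + rng.normal(0, sigma, size=n_frag)
            from amplicycle.cycles import Cycle, JunctionRef
            from amplicycle.fragments import Fragment
            from amplicycle.quantify import DesignMatrix

            j = JunctionRef(0, "sv", None, (0, "t"), (0, "h"), 1.0)
            frags = [Fragment(i, "chr1", i * 100, (i + 1) * 100, float(y[i]))
                     for i in range(n_frag)]
            cycles = [Cycle(((0, "+"),), (j,), canon_key=str(i)) for i in range(n_cyc)]
            dm = DesignMatrix(frags, cycles, X, y)
            fit = fit_lasso(dm, alpha=0.1, background_cov=5.0)
            tolerance = np.maximum(0.1 * beta_true, 2.0)
            if np.all(np.abs(fit.beta - beta_true) <= tolerance):
                ok += 1
        assert ok / trials >= 0.95


class TestSelection:
    def test_threshold_is_quarter_of_max_min_coverage(self, fig1c_cluster):
        g, fid, cluster = fig1c_cluster
        dm = build_design_matrix(cluster, list(g.fragments.values()))
        fit = fit_lasso(dm, alpha=0.1, background_cov=5.0)
        quantified = select_cycles(fit, dm)
        # per-cycle min coverages peak at 35 (ring ABC) -> t = 8.75
        cov = {f.fid: f.mean_cov for f in dm.fragments}
        t = max(min(cov[f] for f in c.fragment_ids) for c in dm.cycles) / 4
        assert t == pytest.approx(35 / 4)
        for q in quantified:
            assert q.selected == (q.proportion > t)

    def test_all_zero_betas_select_nothing(self):
        dm = two_cycle_dm()
        dm.Y = np.zeros_like(dm.Y)
        fit = fit_lasso(dm, alpha=0.1)
        assert all(not q.selected for q in select_cycles(fit, dm))

    def test_beta_equal_to_threshold_is_excluded(self):
        from amplicycle.quantify import LassoFit

        dm = two_cycle_dm()
        # per-cycle mins are 35 (ABC) and 25 (BD) -> t = 8.75
        fit = LassoFit(np.array([8.75, 8.7500001]), 5.0, 0.1, 0.0)
        flags = {q.cycle.canon_key: q.selected for q in select_cycles(fit, dm)}
        assert flags == {"ABC": False, "BD": True}


class TestCandidateFilter:
    def make(self, proportion, total_len):
        from amplicycle.quantify import QuantifiedCycle

        dm = two_cycle_dm()
        cycle = dm.cycles[0]
        cycle.total_len = total_len
        return QuantifiedCycle(cycle, proportion, True, 0)

    def test_proportion_at_or_below_wgs_mean_is_dropped(self):
        assert filter_candidates([self.make(7.0, 150_000)], wgs_mean=8.0) == []
        assert filter_candidates([self.make(8.0, 150_000)], wgs_mean=8.0) == []
        assert len(filter_candidates([self.make(8.1, 150_000)], wgs_mean=8.0)) == 1

    def test_ecdna_labeling_above_100kb(self):
        (big,) = filter_candidates([self.make(171.0, 150_000)], wgs_mean=8.0)
        assert big.label == "ecDNA"
        (small,) = filter_candidates([self.make(171.0, 90_000)], wgs_mean=8.0)
        assert small.label == "circular"
        (edge,) = filter_candidates([self.make(171.0, 100_000)], wgs_mean=8.0)
        assert edge.label == "circular"  # strictly greater than 0.1 Mb
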