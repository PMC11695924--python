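import math
import warnings

import numpy as np
import pytest

from confret import (
    AnnotationTable,
    CostVector,
    LossCurveSet,
    MatchSpec,
    ScoreKind,
    ScoreMatrix,
    build_loss_curves,
    crc_threshold,
    default_grid,
    hierarchical_risk_certificate,
    ltt_threshold,
)


# ---------------------------------------------------------------------------
# Brute-force oracles: scan every grid value and apply the defining
# criterion directly.  Kept independent of the implementation's search.


def oracle_crc_index(losses, alpha, bound):
    n = losses.shape[0]
    target = alpha - (bound - alpha) / n
    risk = losses.mean(axis=0)
    qualifying = [k for k in range(losses.shape[1]) if risk[k] <= target + 1e-12]
    nonincreasing = np.all(np.diff(losses, axis=1) <= 1e-12)
    if not qualifying:
        return 0, False
    if nonincreasing:
        return min(qualifying), True
    return max(qualifying), True  # mirrored orientation


def oracle_ltt_index(losses, alpha, delta, bound):
    n = losses.shape[0]
    risk = losses.mean(axis=0)
    margin = bound * math.sqrt(math.log(1 / delta) / (2 * n))
    idx = None
    for k in range(losses.shape[1]):  # restrictive -> permissive
        if risk[k] + margin <= alpha + 1e-12:
            idx = k
        else:
            break
    if idx is None:
        return 0, False
    return idx, True


def make_curves(losses, bound=1.0, grid=None, kind=ScoreKind.DISTANCE):
    losses = np.asarray(losses, dtype=float)
    grid = np.arange(losses.shape[1], dtype=float) if grid is None else np.asarray(grid)
    return LossCurveSet(
        grid=grid,
        losses=losses,
        bound=bound,
        query_ids=[f"q{i}" for i in range(losses.shape[0])],
        loss_name="fnr",
        score_kind=kind,
    )


class TestBuildLossCurves:
    def test_single_query_fnr_rows(self):
        matrix = ScoreMatrix(
            ["q"], ["a", "b"], np.array([[0.9, 0.2]]), ScoreKind.SIMILARITY
        )
        ann = AnnotationTable(entries={"q": {"PF1"}, "a": {"PF1"}, "b": {"PF2"}})
        curves = build_loss_curves(
            matrix, ann, MatchSpec("pfam_exact"), grid=[0.1, 0.5, 0.95], loss="fnr"
        )
        by_lambda = dict(zip(curves.user_grid(), curves.losses[0]))
        # lambda=0.1 and 0.5 retrieve the true match at 0.9; lambda=0.95 misses it
        assert by_lambda[0.1] == 0.0
        assert by_lambda[0.5] == 0.0
        assert by_lambda[0.95] == 1.0

    def test_all_zero_when_everything_matches(self):
        matrix = ScoreMatrix(
            ["q"], ["a", "b"], np.array([[0.9, 0.2]]), ScoreKind.SIMILARITY
        )
        ann = AnnotationTable(entries={"q": {"PF1"}, "a": {"PF1"}, "b": {"PF1"}})
        curves = build_loss_curves(matrix, ann, MatchSpec("pfam_exact"), loss="fdr")
        assert np.all(curves.losses == 0.0)

    def test_fdr_dip_then_rise_flags_non_monotone(self):
        # descending scores: non-match, match, match -> FDR 1, 1/2, 1/3 then
        # adding a trailing non-match would rise; dip alone breaks monotone
        matrix = ScoreMatrix(
            ["q"],
            ["a", "b", "c", "d"],
            np.array([[0.9, 0.7, 0.5, 0.3]]),
            ScoreKind.SIMILARITY,
        )
        ann = AnnotationTable(
            entries={"q": {"PF1"}, "a": {"PF2"}, "b": {"PF1"}, "c": {"PF1"}, "d": {"PF2"}}
        )
        curves = build_loss_curves(
            matrix, ann, MatchSpec("pfam_exact"), grid=[0.8, 0.6, 0.4, 0.2], loss="fdr"
        )
        assert not curves.monotone

    def test_fnr_rows_monotone_and_match_naive_recount(self, flat_instance):
        matrix, ann, mask = flat_instance
        spec = MatchSpec("pfam_exact")
        curves = build_loss_curves(matrix, ann, spec, grid=50, loss="fnr")
        assert curves.rows_nonincreasing.all()
        # naive recount at a few grid points
        lam_grid = curves.user_grid()
        for k in (0, 20, 40):
            lam = lam_grid[k]
            for i in (0, 7, 23):
                retrieved = matrix.scores[i] >= lam
                total = mask[i].sum()
                expected = 0.0 if total == 0 else (mask[i] & ~retrieved).sum() / total
                assert curves.losses[i, k] == pytest.approx(expected)

    def test_fdr_matches_naive_recount(self, flat_instance):
        matrix, ann, mask = flat_instance
        curves = build_loss_curves(matrix, ann, MatchSpec("pfam_exact"), grid=50, loss="fdr")
        lam_grid = curves.user_grid()
        for k in (5, 25, 45):
            lam = lam_grid[k]
            for i in (1, 11):
                retrieved = matrix.scores[i] >= lam
                n_ret = retrieved.sum()
                expected = 0.0 if n_ret == 0 else (retrieved & ~mask[i]).sum() / n_ret
                assert curves.losses[i, k] == pytest.approx(expected)

    def test_hierarchical_rows_nondecreasing(self):
        from confret import HierarchySpec, gen_hierarchy_instance

        matrix, ann, _ = gen_hierarchy_instance(
            HierarchySpec(seed=5, n_query=30, branching=(3, 2, 2, 2))
        )
        spec = MatchSpec(mode="hierarchical")
        curves = build_loss_curves(matrix, ann, spec, grid=60, loss="hierarchical")
        assert curves.rows_nondecreasing.all()
        assert curves.bound == 4.0

    def test_most_restrictive_grid_point_gives_empty_sets(self, flat_instance):
        matrix, ann, _ = flat_instance
        curves = build_loss_curves(matrix, ann, MatchSpec("pfam_exact"), loss="fdr")
        assert np.all(curves.losses[:, 0] == 0.0)  # empty sets: FDR 0

    def test_empty_grid_rejected(self, flat_instance):
        matrix, ann, _ = flat_instance
        with pytest.raises(ValueError):
            build_loss_curves(matrix, ann, MatchSpec("pfam_exact"), grid=[], loss="fdr")


class TestCrcThreshold:
    def test_n9_alpha_point1_forces_zero_risk(self):
        # alpha - (1 - alpha)/n = 0.1 - 0.9/9 = 0 exactly: only strictly
        # zero-risk grid values can qualify
        losses = np.array([[1.0, 0.0, 0.0]] * 9)
        losses[0] = [1.0, 0.001, 0.0]
        curves = make_curves(losses)
        res = crc_threshold(curves, 0.1)
        assert res.empirical_risk == 0.0
        assert res.canonical_threshold == 2.0  # only the strictly-zero column

    def test_all_zero_curves_select_most_permissive(self):
        curves = make_curves(np.zeros((5, 4)))
        res = crc_threshold(curves, 0.5)
        assert res.canonical_threshold == curves.grid[0]  # least permissive qualifying

    def test_all_zero_mirrored_selects_most_permissive(self):
        # a strictly nondecreasing row forces the mirrored orientation
        losses = np.zeros((5, 4))
        losses[0] = [0.0, 0.1, 0.2, 0.3]
        curves = make_curves(losses)
        res = crc_threshold(curves, 0.99)  # lax alpha: everything qualifies
        assert res.mirrored
        assert res.canonical_threshold == curves.grid[-1]

    def test_matches_oracle_on_handwritten_curves(self):
        losses = np.array(
            [
                [1.0, 0.5, 0.2, 0.0, 0.0],
                [1.0, 1.0, 0.4, 0.1, 0.0],
                [0.8, 0.6, 0.6, 0.2, 0.1],
            ]
        )
        curves = make_curves(losses)
        for alpha in (0.3, 0.5, 0.9):
            idx, ok = oracle_crc_index(losses, alpha, 1.0)
            res = crc_threshold(curves, alpha)
            assert res.criterion_met == ok
            assert res.canonical_threshold == curves.grid[idx]

    def test_non_monotone_curves_are_rejected(self):
        losses = np.array([[0.0, 0.5, 0.2]])
        curves = make_curves(losses)
        with pytest.raises(ValueError, match="ltt"):
            crc_threshold(curves, 0.3)

    def test_unattainable_alpha_falls_back_restrictive(self):
        losses = np.tile([1.0, 0.2, 0.0], (2, 1))  # n=2, alpha below B/(n+1)
        curves = make_curves(losses)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = crc_threshold(curves, 0.2)
        assert not res.criterion_met
        assert res.canonical_threshold == curves.grid[0]
        assert any("restrictive" in str(w.message) for w in caught)

    def test_crc_certificate_inequality_holds(self):
        rng = np.random.default_rng(8)
        losses = np.sort(rng.random((12, 20)), axis=1)[:, ::-1].copy()
        curves = make_curves(losses)
        res = crc_threshold(curves, 0.5)
        n = curves.n
        assert res.empirical_risk <= 0.5 - (1.0 - 0.5) / n + 1e-12

    def test_lambda_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        losses = np.sort(rng.random((15, 25)), axis=1)[:, ::-1].copy()
        curves = make_curves(losses)
        alphas = np.linspace(0.15, 0.9, 12)
        ts = [crc_threshold(curves, a).canonical_threshold for a in alphas]
        # loss shrinks as sets grow: larger alpha tolerates less permissive
        assert all(b <= a + 1e-12 for a, b in zip(ts, ts[1:]))

    def test_mirrored_lambda_monotone_in_alpha(self):
        rng = np.random.default_rng(10)
        losses = np.sort(rng.random((15, 25)) * 4, axis=1)
        curves = make_curves(losses, bound=4.0)
        alphas = np.linspace(0.5, 3.5, 10)
        ts = [crc_threshold(curves, a).canonical_threshold for a in alphas]
        assert all(b >= a - 1e-12 for a, b in zip(ts, ts[1:]))

    def test_similarity_orientation_roundtrip(self):
        losses = np.array([[1.0, 0.0, 0.0]])
        grid = np.array([-0.9, -0.5, -0.1])  # canonical = negated similarity
        curves = make_curves(losses, grid=grid, kind=ScoreKind.SIMILARITY)
        res = crc_threshold(curves, 0.6)
        assert res.canonical_threshold == -0.5
        assert res.lambda_hat == 0.5  # back in similarity orientation


class TestLttThreshold:
    def test_hoeffding_bound_validates(self):
        losses = np.full((100, 1), 0.05)
        curves = make_curves(losses, grid=np.array([0.0]))
        res = ltt_threshold(curves, alpha=0.2, delta=0.1)
        assert res.criterion_met
        expected = 0.05 + math.sqrt(math.log(10) / 200)
        assert res.adjusted_risk == pytest.approx(expected)
        assert res.adjusted_risk <= 0.2

    def test_hoeffding_bound_rejects(self):
        losses = np.full((100, 1), 0.05)
        curves = make_curves(losses, grid=np.array([0.0]))
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = ltt_threshold(curves, alpha=0.1, delta=0.1)
        assert not res.criterion_met
        assert any("fails" in str(w.message) for w in caught)

    def test_zero_risk_large_n_reaches_most_permissive(self):
        losses = np.zeros((5000, 6))
        curves = make_curves(losses)
        res = ltt_threshold(curves, alpha=0.1, delta=0.1)
        assert res.canonical_threshold == curves.grid[-1]

    def test_fixed_sequence_stops_at_first_failure(self):
        # risk pattern pass, pass, FAIL, pass: lambda-hat is grid[1]
        n = 400
        risks = [0.0, 0.02, 0.9, 0.0]
        losses = np.tile(risks, (n, 1))
        curves = make_curves(losses)
        res = ltt_threshold(curves, alpha=0.2, delta=0.1)
        assert res.canonical_threshold == curves.grid[1]

    def test_invalid_delta_rejected(self):
        curves = make_curves(np.zeros((5, 3)))
        for bad in (0.0, 1.0, -0.2, 2.0):
            with pytest.raises(ValueError):
                ltt_threshold(curves, 0.1, bad)

    def test_unknown_bound_rejected(self):
        curves = make_curves(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            ltt_threshold(curves, 0.1, 0.1, bound="bernstein")

    def test_lambda_monotone_in_alpha(self):
        rng = np.random.default_rng(11)
        losses = np.sort(rng.random((50, 30)), axis=1)  # rising risk profile
        curves = make_curves(losses)
        ts = [
            ltt_threshold(curves, a, 0.1).canonical_threshold
            for a in np.linspace(0.2, 0.95, 10)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ts, ts[1:]))


class TestOracleEquivalenceRandomInstances:
    """crc/ltt agree with exhaustive brute-force scans (n<=20, |grid|<=50)."""

    def test_crc_random(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            g = int(rng.integers(2, 51))
            mirrored = rng.random() < 0.5
            losses = np.sort(rng.random((n, g)), axis=1)
            if not mirrored:
                losses = losses[:, ::-1].copy()
            curves = make_curves(losses)
            alpha = float(rng.uniform(0.05, 0.95))
            idx, ok = oracle_crc_index(losses, alpha, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = crc_threshold(curves, alpha)
            assert res.criterion_met == ok
            assert res.canonical_threshold == curves.grid[idx]

    def test_ltt_random(self):
        rng = np.random.default_rng(43)
        for _ in range(100):
            n = int(rng.integers(2, 21))
            g = int(rng.integers(2, 51))
            losses = rng.random((n, g))
            losses[:, 0] = 0.0  # restrictive end is safe for most draws
            curves = make_curves(losses)
            alpha = float(rng.uniform(0.1, 0.9))
            delta = float(rng.uniform(0.05, 0.5))
            idx, ok = oracle_ltt_index(losses, alpha, delta, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ltt_threshold(curves, alpha, delta)
            assert res.criterion_met == ok
            assert res.canonical_threshold == curves.grid[idx]


class TestHierarchicalRiskCertificate:
    def test_implied_bounds(self):
        report = hierarchical_risk_certificate([0.0], CostVector.unit(), alpha=0.1)
        assert report["bound"].tolist() == pytest.approx(
            [math.inf, 0.1, 0.05, 0.1 / 3, 0.025]
        )

    def test_all_zero_losses_satisfy_every_level(self):
        report = hierarchical_risk_certificate(
            np.zeros(200), CostVector.unit(), alpha=0.1
        )
        assert not report["violated"].any()

    def test_flagrant_violation_is_flagged(self):
        losses = np.full(1000, 4.0)  # every loss at the top level
        report = hierarchical_risk_certificate(losses, CostVector.unit(), alpha=0.1)
        assert bool(report.loc[report["cost"] == 4.0, "violated"].iloc[0])

    def test_empirical_frequencies_sum_to_one_on_cost_support(self):
        rng = np.random.default_rng(12)
        losses = rng.choice([0.0, 1.0, 2.0, 3.0, 4.0], size=500)
        report = hierarchical_risk_certificate(losses, CostVector.unit(), alpha=1.0)
        assert report["empirical_frequency"].sum() == pytest.approx(1.0)


class TestDefaultGrid:
    def test_includes_empty_set_sentinel(self, flat_instance):
        matrix, _, _ = flat_instance
        grid = default_grid(matrix)
        canon = matrix.canonical_scores()
        assert grid[0] < canon.min()
        assert grid[-1] == canon.max()
        assert np.all(np.diff(grid) > 0)

    def test_grid_size_policy(self, flat_instance):
        matrix, _, _ = flat_instance
        assert default_grid(matrix, 50).size <= 52
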