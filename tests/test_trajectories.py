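"""Weighted log-linear trajectory fits, classification, dominant clones,
competition, and the gene-group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chipdyn import (Trajectory, TrajectoryFit, TrajectoryObservation,
                     assemble_trajectories, classify_trajectory,
                     classify_two_timepoint, compare_gene_groups,
                     competition_report, doubling_period, exclude_high_start,
                     fit_trajectory, gene_growth_odds, select_dominant)
from tests.conftest import make_trajectory


def wls_normal_equations(ages, y, weights):
    """Independent closed-form WLS oracle: solve (XᵀWX)b = XᵀWy."""
    X = np.column_stack([np.ones_like(ages), ages])
    W = np.diag(weights)
    b = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return b[0], b[1]


class TestFit:
    def test_exact_log_linear_points(self):
        t = make_trajectory([60, 65, 70], [0.01, 0.02, 0.04], [1000] * 3)
        fit = fit_trajectory(t)
        assert fit.beta == pytest.approx(math.log10(2) / 5, abs=1e-12)
        assert fit.p_value == 0.0  # perfect fit
        assert 10 ** (fit.C + fit.beta * 60) == pytest.approx(0.01, rel=1e-9)

    def test_flat_series_beta_zero(self):
        t = make_trajectory([60, 65, 70, 75], [0.02] * 4, [500, 900, 2000, 3000])
        fit = fit_trajectory(t)
        assert fit.beta == pytest.approx(0.0, abs=1e-14)

    def test_collinear_points_ignore_weights(self):
        vafs = [0.01, 0.02, 0.04, 0.08]
        ages = [60, 65, 70, 75]
        equal = fit_trajectory(make_trajectory(ages, vafs, [1000] * 4))
        unequal = fit_trajectory(make_trajectory(ages, vafs, [100, 5000, 300, 800]))
        assert unequal.beta == pytest.approx(equal.beta, abs=1e-12)
        assert unequal.C == pytest.approx(equal.C, abs=1e-10)

    def test_matches_normal_equations_on_random_inputs(self, rng):
        for _ in range(100):
            n = rng.integers(3, 7)
            ages = np.sort(rng.uniform(50, 80, n))
            while len(np.unique(ages)) < n:
                ages = np.sort(rng.uniform(50, 80, n))
            vafs = 10 ** rng.uniform(-3.5, -0.4, n)
            depths = rng.integers(200, 5000, n)
            t = make_trajectory(ages, vafs, depths)
            fit = fit_trajectory(t)
            C, beta = wls_normal_equations(
                ages, np.log10(np.maximum(vafs, 1e-4)), np.sqrt(depths))
            assert fit.C == pytest.approx(C, abs=1e-10)
            assert fit.beta == pytest.approx(beta, abs=1e-10)

    def test_zero_vafs_floored(self):
        t = make_trajectory([60, 70], [0.0, 0.01], [1000, 1000])
        fit = fit_trajectory(t, vaf_floor=1e-4)
        assert fit.beta == pytest.approx((math.log10(0.01) - (-4)) / 10)
        assert math.isnan(fit.p_value)  # n=2: no residual df

    def test_equal_ages_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_trajectory([60, 60], [0.01, 0.02], [1000, 1000])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_floor_below_min_vaf_is_inert(self, seed):
        """For all-nonzero series any floor at or below the smallest VAF
        leaves the fit unchanged, so raising it never flips beta's sign."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        ages = np.sort(rng.uniform(50, 80, n))
        if len(np.unique(ages)) < n:
            return
        vafs = 10 ** rng.uniform(-3, -0.4, n)
        t = make_trajectory(ages, vafs, rng.integers(200, 5000, n))
        ref = fit_trajectory(t, vaf_floor=vafs.min())
        for floor in (1e-6, 1e-4, vafs.min() / 2, vafs.min()):
            fit = fit_trajectory(t, vaf_floor=floor)
            assert fit.beta == pytest.approx(ref.beta, abs=1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "beta,p,label",
        [
            (0.05, 0.3, "growing"),
            (-0.02, 0.2, "shrinking"),
            (0.0, 0.2, "shrinking"),  # beta <= 0 is shrinking when P < 0.5
            (0.05, 0.7, "static"),
            (0.05, 0.5, "static"),  # P >= threshold inclusive
        ],
    )
    def test_label_rule(self, beta, p, label):
        fit = TrajectoryFit(C=0, beta=beta, p_value=p, n_obs=4)
        assert classify_trajectory(fit) == label

    def test_undefined_p_gets_no_label(self):
        fit = TrajectoryFit(C=0, beta=0.1, p_value=float("nan"), n_obs=2)
        assert classify_trajectory(fit) is None

    def test_partition_every_defined_p_has_exactly_one_label(self, rng):
        for _ in range(200):
            fit = TrajectoryFit(C=0, beta=rng.normal(0, 0.05),
                                p_value=rng.uniform(0, 1), n_obs=4)
            assert classify_trajectory(fit) in {"growing", "shrinking", "static"}

    def test_two_timepoint_rule(self):
        assert classify_two_timepoint(0.3) == "growing"
        assert classify_two_timepoint(0.0) == "non-growing"
        assert classify_two_timepoint(-0.3) == "non-growing"


class TestDoubling:
    @pytest.mark.parametrize(
        "beta,years",
        [
            (math.log10(2), 1.0),
            (math.log10(2) / 5, 5.0),
            (0.0405, math.log10(2) / 0.0405),  # ~7.433 years
        ],
    )
    def test_doubling_period(self, beta, years):
        assert doubling_period(beta) == pytest.approx(years, rel=1e-12)

    def test_non_positive_beta_undefined(self):
        for beta in (0.0, -0.05):
            with pytest.raises(ValueError):
                doubling_period(beta)

    def test_fit_of_exact_doubling_recovers_period(self, rng):
        for k in (2.0, 5.0, 7.43):
            beta = math.log10(2) / k
            ages = np.array([60.0, 64.0, 68.0, 72.0])
            vafs = 0.01 * 10 ** (beta * (ages - 60))
            t = make_trajectory(ages, vafs, [2803] * 4)
            fit = fit_trajectory(t)
            assert doubling_period(fit.beta) == pytest.approx(k, abs=1e-9)


class TestAssembly:
    def _drivers(self, rows):
        return pd.DataFrame(
            rows,
            columns=["subject_id", "timepoint", "variant_id", "gene", "depth",
                     "alt_count"],
        )

    def _manifest(self, subject_tp_ages):
        return pd.DataFrame(
            [{"subject_id": s, "timepoint": t, "age": a}
             for s, t, a in subject_tp_ages]
        )

    def test_two_timepoint_subject_excluded(self):
        drivers = self._drivers(
            [("S1", "BL", "v1", "TET2", 2000, 100),
             ("S1", "AV1", "v1", "TET2", 2000, 150)])
        manifest = self._manifest([("S1", "BL", 60), ("S1", "AV1", 61)])
        assert assemble_trajectories(drivers, manifest) == []

    def test_no_vaf_above_one_percent_excluded(self):
        drivers = self._drivers(
            [("S1", tp, "v1", "TET2", 2000, 10) for tp in ("BL", "AV1", "AV3")])
        manifest = self._manifest(
            [("S1", "BL", 60), ("S1", "AV1", 61), ("S1", "AV3", 63)])
        assert assemble_trajectories(drivers, manifest) == []  # max VAF 0.005

    def test_low_depth_observation_dropped(self):
        drivers = self._drivers(
            [("S1", "BL", "v1", "TET2", 150, 30),  # depth < 200: dropped
             ("S1", "AV1", "v1", "TET2", 2000, 100),
             ("S1", "AV3", "v1", "TET2", 2000, 150)])
        manifest = self._manifest(
            [("S1", "BL", 60), ("S1", "AV1", 61), ("S1", "AV3", 63)])
        trajs = assemble_trajectories(drivers, manifest)
        assert len(trajs) == 1 and len(trajs[0].observations) == 2

    def test_low_alt_with_good_depth_becomes_zero_vaf(self):
        drivers = self._drivers(
            [("S1", "BL", "v1", "TET2", 2000, 1),  # alt < 2 at depth >= 200
             ("S1", "AV1", "v1", "TET2", 2000, 100),
             ("S1", "AV3", "v1", "TET2", 2000, 150)])
        manifest = self._manifest(
            [("S1", "BL", 60), ("S1", "AV1", 61), ("S1", "AV3", 63)])
        trajs = assemble_trajectories(drivers, manifest)
        assert trajs[0].observations[0].vaf == 0.0
        assert trajs[0].observations[0].depth == 2000

    def test_missing_age_drops_observation_with_log(self, caplog):
        drivers = self._drivers(
            [("S1", "BL", "v1", "TET2", 2000, 100),
             ("S1", "AV1", "v1", "TET2", 2000, 120),
             ("S1", "AV9", "v1", "TET2", 2000, 150)])
        manifest = self._manifest(
            [("S1", "BL", 60), ("S1", "AV1", 61), ("S1", "AV3", 63)])
        with caplog.at_level("WARNING"):
            trajs = assemble_trajectories(drivers, manifest)
        assert "missing from manifest" in caplog.text
        assert len(trajs[0].observations) == 2


class TestHighStartExclusion:
    @pytest.mark.parametrize(
        "start_vaf,kept",
        [(0.12, False), (0.10, True), (0.0, True)],
        ids=["above", "exactly-10pct", "floored-zero"],
    )
    def test_rule_is_strict(self, start_vaf, kept):
        depths = [1000] * 3
        vafs = [start_vaf, 0.05, 0.06]
        t = make_trajectory([60, 65, 70], vafs, depths)
        assert (t in exclude_high_start([t])) == kept


class TestDominant:
    def test_picks_peak_vaf(self):
        a = make_trajectory([60, 65, 70], [0.02, 0.05, 0.08], [1000] * 3,
                            variant="1:1:A:G")
        b = make_trajectory([60, 65, 70], [0.01, 0.02, 0.03], [1000] * 3,
                            variant="1:2:A:G")
        dom = select_dominant([a, b])
        assert dom.trajectory.variant_id == "1:1:A:G"

    def test_delta_one_decade(self):
        t = make_trajectory([60, 65, 70], [0.005, 0.02, 0.05], [1000] * 3)
        dom = select_dominant([t])
        assert dom.delta_log10_vaf == pytest.approx(1.0, abs=1e-12)

    def test_tie_breaks_on_final_vaf(self):
        a = make_trajectory([60, 65], [0.08, 0.02], [1000] * 2, variant="1:1:A:G")
        b = make_trajectory([60, 65], [0.02, 0.08], [1000] * 2, variant="1:2:A:G")
        dom = select_dominant([a, b])
        assert dom.trajectory.variant_id == "1:2:A:G"

    def test_requires_two_nonzero_vafs(self):
        t = make_trajectory([60, 65, 70], [0.0, 0.0, 0.05], [1000] * 3)
        assert select_dominant([t]) is None


class TestCompetition:
    def _fit(self, label):
        f = TrajectoryFit(C=0, beta=0.05 if label == "growing" else -0.05,
                          p_value=0.1 if label != "static" else 0.9, n_obs=4)
        f.label = label
        return f

    def test_non_growing_chip_clone_with_growing_cooccurrence_flagged(self):
        grow = make_trajectory([60, 65, 70], [0.01, 0.05, 0.2], [1000] * 3,
                               variant="1:1:A:G")
        shrink = make_trajectory([60, 65, 70], [0.03, 0.02, 0.01], [1000] * 3,
                                 variant="1:2:A:G")
        rep = competition_report([grow, shrink],
                                 [self._fit("growing"), self._fit("shrinking")])
        flagged = rep.set_index("variant_id")["competition_candidate"]
        assert flagged["1:2:A:G"] and not flagged["1:1:A:G"]

    def test_single_clone_subject_empty(self):
        t = make_trajectory([60, 65, 70], [0.01, 0.05, 0.2], [1000] * 3)
        rep = competition_report([t], [self._fit("growing")])
        assert rep.empty

    def test_two_static_clones_listed_not_flagged(self):
        a = make_trajectory([60, 65, 70], [0.03, 0.03, 0.03], [1000] * 3,
                            variant="1:1:A:G")
        b = make_trajectory([60, 65, 70], [0.04, 0.04, 0.04], [1000] * 3,
                            variant="1:2:A:G")
        rep = competition_report([a, b], [self._fit("static"), self._fit("static")])
        assert len(rep) == 2 and not rep["competition_candidate"].any()


def mwu_enumeration(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration of group labelings."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    dev_obs = abs(u_obs - n * m / 2)
    count = total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = pooled[list(combo)]
        ys = np.delete(pooled, list(combo))
        total += 1
        if abs(u_stat(xs, ys) - n * m / 2) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total


class TestGeneGroups:
    def _df(self, major, other):
        return pd.DataFrame(
            {"gene": ["DNMT3A"] * len(major) + ["JAK2"] * len(other),
             "beta": list(major) + list(other)})

    def test_exact_example(self):
        u, p = compare_gene_groups(self._df([1, 2, 3], [4, 5, 6]))
        assert u == 0.0 and p == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        _, p = compare_gene_groups(self._df([1, 2, 3], [1, 2, 3]))
        assert p == pytest.approx(1.0)

    def test_matches_full_enumeration_small_n(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, size=int(rng.integers(2, 5)))
            y = rng.normal(0.5, 1, size=int(rng.integers(2, 5)))
            df = self._df(x, y)
            u, p = compare_gene_groups(df)
            u_ref, p_ref = mwu_enumeration(x, y)
            assert u == pytest.approx(u_ref)
            assert p == pytest.approx(p_ref, abs=1e-12)

    def test_power_on_shifted_groups(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.normal(0.0, 1.0, 20)
            y = rng.normal(2.0, 1.0, 20)  # 2 s.d. shift
            _, p = compare_gene_groups(self._df(x, y))
            hits += p < 0.05
        assert hits / 50 > 0.8

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_gene_groups(self._df([1, 2], []))

    def test_doubling_period_option(self):
        df = pd.DataFrame({"gene": ["DNMT3A", "DNMT3A", "JAK2", "JAK2"],
                           "beta": [0.01, 0.02, 0.05, 0.06],
                           "doubling_period": [30.1, 15.05, 6.02, 5.02]})
        _, p_beta = compare_gene_groups(df, value="beta")
        _, p_doub = compare_gene_groups(df, value="doubling_period")
        assert p_beta == pytest.approx(p_doub)  # rank-reversal symmetry


class TestGeneOdds:
    def _labeled(self, a, b, c, d, gene="DNMT3A"):
        rows = (
            [{"gene": gene, "label": "growing"}] * a
            + [{"gene": gene, "label": "static"}] * b
            + [{"gene": "TET2", "label": "growing"}] * c
            + [{"gene": "TET2", "label": "static"}] * d
        )
        return pd.DataFrame(rows)

    def test_cross_product_ratio(self):
        or_, p, corrected = gene_growth_odds(self._labeled(10, 20, 20, 10), "DNMT3A")
        assert or_ == pytest.approx(0.25)
        assert not corrected

    def test_independence(self):
        or_, p, _ = gene_growth_odds(self._labeled(5, 5, 5, 5), "DNMT3A")
        assert or_ == 1.0 and p == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        or_, _, corrected = gene_growth_odds(self._labeled(0, 10, 10, 10), "DNMT3A")
        assert corrected and np.isfinite(or_) and or_ > 0
        assert or_ == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_single_gene_rejected(self):
        df = pd.DataFrame([{"gene": "DNMT3A", "label": "growing"}] * 4)
        with pytest.raises(ValueError):
            gene_growth_odds(df, "DNMT3A")

    def test_logistic_route_close_to_fisher_or(self):
        df = self._labeled(10, 20, 20, 10)
        or_f, _, _ = gene_growth_odds(df, "DNMT3A", method="fisher")
        or_l, p_l, _ = gene_growth_odds(df, "DNMT3A", method="logistic")
        assert or_l == pytest.approx(or_f, rel=1e-6)  # saturated 2x2 logistic
        assert 0 < p_l < 1
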