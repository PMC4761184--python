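"""Rank correlations, multiple-testing arithmetic, bands, EC50 pipeline."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from unbio.molgraph import parse_structure
from unbio.synthetic import SimulationParams, simulate_study
from unbio.toxcorr import (
    CorrelationError,
    ToxicityRecord,
    band_analysis,
    bonferroni_threshold,
    correlate_endpoint,
    ec50_from_curve,
    family_wise_prob,
    fisher_ci,
    hit_rate_curve,
    spearman,
    yeast_filter,
)


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)

    def test_average_rank_ties(self):
        # rank-based Pearson computed by hand: ranks x (1, 2.5, 2.5, 4),
        # ranks y (1.5, 1.5, 3, 4) -> r = 5/6
        rho, _ = spearman([1, 2, 2, 3], [1, 1, 2, 3])
        assert rho == pytest.approx(5 / 6, abs=1e-9)

    def test_agrees_with_rank_pearson(self):
        rng = random.Random(4)
        x = [rng.randint(0, 5) for _ in range(40)]
        y = [rng.gauss(xi, 2.0) for xi in x]
        rho, _ = spearman(x, y)
        ref = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert rho == pytest.approx(ref, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = random.Random(8)
        x = [rng.uniform(0.1, 5) for _ in range(30)]
        y = [rng.uniform(0.1, 5) for _ in range(30)]
        base = spearman(x, y)[0]
        assert spearman([math.log(v) for v in x], y)[0] == pytest.approx(base)
        assert spearman(x, [v**3 for v in y])[0] == pytest.approx(base)

    def test_constant_vector_flagged(self):
        with pytest.raises(CorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestMultipleTesting:
    def test_family_threshold(self):
        assert bonferroni_threshold(35, 2, 0.05) == pytest.approx(0.000714, abs=5e-7)
        assert bonferroni_threshold(1, 1, 0.05) == 0.05
        assert bonferroni_threshold(10, 2, 0.01) == pytest.approx(0.0005)

    def test_family_wise_probability(self):
        assert family_wise_prob(70, 0.05 / 70) == pytest.approx(0.05, abs=0.005)
        assert family_wise_prob(1, 0.3) == pytest.approx(0.3)
        assert family_wise_prob(2, 0.5) == pytest.approx(0.75)

    def test_family_wise_bound(self):
        # 1-(1-a/n)^n <= a for the Bonferroni-corrected level
        for e, m in [(35, 2), (10, 1), (3, 4)]:
            alpha_star = bonferroni_threshold(e, m, 0.05)
            assert family_wise_prob(e * m, alpha_star) <= 0.05 + 1e-12


class TestFisherCI:
    def test_known_interval(self):
        lo, hi = fisher_ci(0.5, 30)
        assert (lo, hi) == (pytest.approx(0.170, abs=5e-4), pytest.approx(0.729, abs=5e-4))

    def test_needs_four_points(self):
        with pytest.raises(CorrelationError):
            fisher_ci(0.5, 3)


def _records(values, ids=None, endpoint="test"):
    ids = ids or [f"C{i}" for i in range(len(values))]
    return [
        ToxicityRecord(compound_id=i, smiles="C", endpoint=endpoint, log10_value=v)
        for i, v in zip(ids, values)
    ]


def _ub_frame(ids, ub, n=3):
    return pd.DataFrame({"id": ids, f"ub{n}": ub})


class TestEndpointCorrelation:
    def test_planted_signal_recovered(self):
        met, comps, table, recs = simulate_study(SimulationParams(seed=1))
        res = correlate_endpoint(recs, table, 3)
        assert res.rho < 0 and res.p_value < 0.01

    def test_shuffled_records_give_identical_result(self):
        met, comps, table, recs = simulate_study(SimulationParams(seed=2))
        rng = random.Random(0)
        shuffled = recs[:]
        rng.shuffle(shuffled)
        assert correlate_endpoint(shuffled, table, 3) == correlate_endpoint(recs, table, 3)

    def test_constant_ub_column_flagged(self):
        ids = [f"C{i}" for i in range(10)]
        with pytest.raises(CorrelationError):
            correlate_endpoint(
                _records(list(np.linspace(-5, -1, 10)), ids),
                _ub_frame(ids, [3] * 10),
                3,
            )

    def test_small_join_refused_with_diagnostics(self):
        ids = ["a", "b", "c"]
        with pytest.raises(CorrelationError, match="joined"):
            correlate_endpoint(
                _records([-1, -2, -3], ids), _ub_frame(["x", "y", "z"], [1, 2, 3]), 3
            )

    def test_tier_assignment(self):
        rng = random.Random(1)
        ids = [f"C{i}" for i in range(200)]
        ub = [rng.randint(0, 8) for _ in ids]
        vals = [-0.4 * u + rng.gauss(0, 0.8) for u in ub]
        res = correlate_endpoint(_records(vals, ids), _ub_frame(ids, ub), 3)
        assert res.tier == "***" and res.p_value < bonferroni_threshold(35, 2)


class TestBandAnalysis:
    def test_fisher_ci_on_bands(self):
        rng = random.Random(12)
        ids = [f"C{i}" for i in range(120)]
        ub = [rng.randint(0, 6) for _ in ids]
        vals = [rng.uniform(-5.5, -0.5) for _ in ids]
        bands = band_analysis(_records(vals, ids), _ub_frame(ids, ub), 3, edges=[-4, -3])
        assert sum(b.n for b in bands) == 120  # bands partition the records
        for b in bands:
            if b.n >= 4 and not math.isnan(b.rho):
                assert b.ci_lo <= b.rho <= b.ci_hi

    def test_under_populated_bands_have_no_ci(self):
        ids = [f"C{i}" for i in range(6)]
        vals = [-2.5, -2.2, -2.4, -2.1, -2.9, -2.3]  # all in [-3, -2)
        bands = band_analysis(
            _records(vals, ids), _ub_frame(ids, [1, 2, 3, 4, 5, 6]), 3, edges=[-4, -3, -2]
        )
        populated = [b for b in bands if b.n > 0]
        assert len(populated) == 1 and populated[0].n == 6
        for b in bands:
            if b.n < 4:
                assert math.isnan(b.rho) and math.isnan(b.ci_lo)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            band_analysis([], _ub_frame([], []), 3, edges=[-3, -4])

    def test_planted_effect_lives_in_the_weak_band(self):
        met, comps, table, recs = simulate_study(SimulationParams(seed=3))
        bands = band_analysis(recs, table, 3, edges=[-4, -3])
        weak, strong = bands[-1], bands[0]
        assert weak.rho < 0
        assert math.isnan(strong.rho) or weak.rho < strong.rho


class TestHitRate:
    def test_all_active(self):
        curve = hit_rate_curve([("a", 1e-6, True), ("b", 3e-6, True)], 0.25)
        assert (curve["hit_rate"] == 1.0).all()

    def test_inactive_counts_in_denominator_only(self):
        curve = hit_rate_curve([("a", 1e-6, True), ("b", 1e-6, False)], 0.25)
        assert curve["n_tested"].tolist() == [2] and curve["hit_rate"].tolist() == [0.5]

    def test_binned_fractions(self):
        tests = [
            ("a", 1e-6, True), ("b", 1e-6, False), ("c", 1e-6, False),
            ("d", 1e-5, True), ("e", 1e-5, True),
        ]
        curve = hit_rate_curve(tests, 0.25)
        assert curve["hit_rate"].tolist() == pytest.approx([1 / 3, 1.0])

    def test_rejects_non_positive_concentration(self):
        with pytest.raises(ValueError):
            hit_rate_curve([("a", 0.0, True)], 0.25)


class TestEC50:
    def test_log_linear_midpoint(self):
        ec = ec50_from_curve([10e-6, 100e-6], [30, 70])
        assert ec == pytest.approx(31.6228e-6, rel=1e-4)

    def test_exact_crossing_returns_tested_concentration(self):
        assert ec50_from_curve([10e-6, 100e-6], [50, 80]) == 10e-6

    def test_no_crossing_is_undefined(self):
        assert ec50_from_curve([1e-6, 1e-5, 1e-4], [10, 25, 40]) is None

    def test_first_crossing_wins_on_noisy_curve(self):
        ec = ec50_from_curve([1e-6, 1e-5, 1e-4, 1e-3], [20, 60, 40, 80])
        assert 1e-6 < ec < 1e-5


def _matrix(rows):
    return pd.DataFrame(rows, columns=["id", "strain", "concentration_M", "pct_inhibition"])


class TestYeastFilter:
    STRUCTS = {
        "ok": "CCOCC",
        "weak": "CCCCO",
        "organo": "CC[Hg]CC",
        "salt": "[Na+].CC([O-])=O",
        "mix": "CCO.CCN",
    }

    def _curve(self, cid, inhibitions, strain="s1"):
        concs = [1e-6, 1e-5, 1e-4]
        return [(cid, strain, c, y) for c, y in zip(concs, inhibitions)]

    def test_low_top_inhibition_excluded(self):
        m = _matrix(self._curve("weak", [5, 15, 40]) + self._curve("ok", [10, 45, 90]))
        table, log = yeast_filter(m, self.STRUCTS)
        assert table["id"].tolist() == ["ok"]
        rule = log.set_index("id").loc["weak", "rule"]
        assert rule == "max<50%"

    def test_high_bottom_inhibition_excluded(self):
        m = _matrix(self._curve("weak", [60, 80, 95]))
        _, log = yeast_filter(m, self.STRUCTS)
        assert log["rule"].tolist() == ["min>50%"]

    def test_organometallic_excluded(self):
        m = _matrix(self._curve("organo", [10, 55, 90]))
        _, log = yeast_filter(m, self.STRUCTS)
        assert log["rule"].tolist() == ["organometallic"]

    def test_alkali_salt_retained_and_scored_on_organic_part(self):
        m = _matrix(self._curve("salt", [10, 55, 90]))
        table, log = yeast_filter(m, self.STRUCTS)
        assert len(log) == 0
        assert table["smiles"].tolist() == [parse_structure("CC(=O)O").canonical]

    def test_organic_mixture_excluded(self):
        m = _matrix(self._curve("mix", [10, 55, 90]))
        _, log = yeast_filter(m, self.STRUCTS)
        assert log["rule"].tolist() == ["mixture/salt"]

    def test_strain_spread_exclusion(self):
        rows = []
        # strains with EC50s spread over two orders of magnitude
        rows += self._curve("ok", [10, 55, 90], strain="s1")
        rows += [("ok", "s2", 1e-6, 10), ("ok", "s2", 1e-5, 20), ("ok", "s2", 1e-4, 55)]
        _, log = yeast_filter(_matrix(rows), self.STRUCTS)
        assert log["rule"].tolist() == ["strain spread"]

    def test_consistent_strains_averaged(self):
        rows = self._curve("ok", [10, 55, 90], "s1") + self._curve("ok", [12, 58, 88], "s2")
        table, log = yeast_filter(_matrix(rows), self.STRUCTS)
        assert len(table) == 1 and len(log) == 0
        assert table.loc[0, "n_strains"] == 2
        assert 1e-6 < table.loc[0, "ec50_M"] < 1e-4
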