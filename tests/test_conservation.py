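"""Divergence, the dt~dp regression, Cook's distance, score aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nimtscan as ns
from nimtscan.conservation import (DivergencePoint, aggregate_scores,
                                   build_points, divergence, fit_and_flag,
                                   numt_flanks)
from nimtscan.core import GenomicInterval, MtlHit, NumtRecord, revcomp
from nimtscan.synteny import classify_hits, expected_copies

from conftest import perfect_hits


# --- independent oracle: textbook edit-distance dynamic program -----------

def edit_distance_oracle(a: str, b: str) -> int:
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                          D[i - 1][j] + 1, D[i][j - 1] + 1)
    return D[n][m]


dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestDivergence:
    def test_identical_sequences_diverge_zero(self):
        assert divergence("ACGTACGT", "ACGTACGT") == 0.0

    def test_single_substitution(self):
        assert divergence("ACGT", "ACGA") == 0.25

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 31)))
            b = "".join("ACGT"[k] for k in rng.integers(0, 4, rng.integers(1, 31)))
            assert divergence(a, b) == edit_distance_oracle(a, b) / max(len(a), len(b))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_symmetric_and_revcomp_invariant(self, a, b):
        assert divergence(a, b) == divergence(b, a)
        assert divergence(a, b) == divergence(revcomp(a), revcomp(b))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            divergence("", "ACGT")


class TestBuildPoints:
    def _run(self, truth):
        numts = [i.numt for i in truth.insertions]
        exp = expected_copies(numts, truth.template.genes)
        validated, _ = classify_hits(perfect_hits(truth), exp, numts)
        return build_points(validated, numts, truth.extant_mito, truth.nuclear)

    def test_zero_rate_simulation_gives_origin_points(self, zero_rate_truth):
        points = self._run(zero_rate_truth)
        assert points and all(p.dt == 0.0 and p.dp == 0.0 for p in points)

    def test_flank_filter_boundary_50_excluded_51_included(self):
        # numt of length (flank + 70-nt gene); gene fully inside
        from nimtscan.numtsim import TrnaGene
        gene = TrnaGene("Tyr", 100, 170, "." * 70)
        seq = "A" * 1000

        def point_count(flank_len):
            half = flank_len // 2
            extra = flank_len - half
            numt = NumtRecord(
                GenomicInterval("chr1", 0, flank_len + 70, "+"),
                GenomicInterval("chrM", 100 - half, 170 + extra, "+"), "n0")
            exp = expected_copies([numt], [gene])
            hit = MtlHit(exp[0].projected, "Tyr", 50.0, "builtin")
            validated, _ = classify_hits([hit], exp, [numt])
            mito = ns.SequenceRecord("chrM", seq)
            nuc = ns.SequenceRecord("chr1", seq[:flank_len + 70])
            return len(build_points(validated, [numt], mito, nuc))

        assert point_count(50) == 0
        assert point_count(51) == 1

    def test_functional_mtl_falls_below_diagonal_in_expectation(self):
        """st = 0.2*sp: mean dt sits well under mean dp across replicates."""
        dts, dps = [], []
        for seed in range(25):
            p = ns.EvolutionParams(seed=seed, sn=0.0, sp=0.1, st=0.1,
                                   functional_factor=0.2, functional_fraction=1.0,
                                   fixed_insertion_time=1.5, t_max=1.5,
                                   n_insertions=2, nuclear_length=8000,
                                   insertion_length_range=(300, 400),
                                   min_trnas_per_insertion=1, intronic_fraction=0)
            truth = ns.simulate(p)
            for pt in self._run(truth):
                dts.append(pt.dt)
                dps.append(pt.dp)
        assert np.mean(dts) < np.mean(dps) * 0.5


def loo_cooks_oracle(dp, dt):
    """Leave-one-out Cook's distance: D_i = sum_j (yhat_j - yhat_j(i))^2 / (p*s^2)."""
    import statsmodels.api as sm
    X = sm.add_constant(dp)
    res = sm.OLS(dt, X).fit()
    yhat = res.fittedvalues
    s2 = res.mse_resid
    out = np.empty(len(dt))
    for i in range(len(dt)):
        keep = np.arange(len(dt)) != i
        res_i = sm.OLS(dt[keep], X[keep]).fit()
        yhat_i = X @ res_i.params
        out[i] = np.sum((yhat - yhat_i) ** 2) / (2 * s2)
    return out


class TestFitAndFlag:
    def _points(self, dp, dt):
        return [DivergencePoint(f"p{i}", float(t), float(p), 70, 200)
                for i, (t, p) in enumerate(zip(dt, dp))]

    def test_point_on_fitted_line_not_flagged(self):
        dp = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        dt = 0.5 * dp + 0.01
        dt[1] += 0.05  # bend the rest; p3 stays near the line
        fit = fit_and_flag(self._points(dp, dt))
        on_line = np.argmin(np.abs(fit.residuals))
        assert not fit.flags[on_line]
        assert np.all(fit.cooks_d >= 0)

    def test_cooks_distance_matches_loo_oracle(self):
        rng = np.random.default_rng(1)
        for n in (4, 7, 12):
            dp = rng.random(n)
            dt = 0.8 * dp + rng.normal(0, 0.05, n)
            fit = fit_and_flag(self._points(dp, dt))
            oracle = loo_cooks_oracle(dp, dt)
            assert np.max(np.abs(fit.cooks_d - oracle)) < 1e-10

    def test_default_threshold_is_three_times_mean(self):
        rng = np.random.default_rng(2)
        dp = rng.random(20)
        dt = dp + rng.normal(0, 0.02, 20)
        fit = fit_and_flag(self._points(dp, dt))
        assert fit.k == 3.0
        assert fit.threshold == pytest.approx(3.0 * fit.cooks_d.mean())

    def test_flagging_is_one_sided_conserved_direction(self):
        dp = np.linspace(0.05, 0.4, 12)
        dt = dp.copy()
        dt[3] += 0.3   # extreme but ABOVE the line: not conserved
        dt[8] -= 0.25  # extreme below the line: conserved outlier
        fit = fit_and_flag(self._points(dp, dt))
        assert fit.flags[8] and not fit.flags[3]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            fit_and_flag(self._points(np.array([0.1, 0.2]), np.array([0.1, 0.2])))
        with pytest.raises(ValueError, match="degenerate"):
            fit_and_flag(self._points(np.array([0.1] * 5), np.arange(5) / 10))


class TestAggregateScores:
    FEATS = [("f1", GenomicInterval("chr1", 100, 150, "+")),
             ("f2", GenomicInterval("chr1", 300, 340, "+"))]
    FLANKS = {"f1": [GenomicInterval("chr1", 0, 100, "+")],
              "f2": [GenomicInterval("chr1", 340, 400, "+")]}

    def test_constant_track_gives_zero_delta(self):
        scores = {"chr1": {i: 1.0 for i in range(400)}}
        aggs, signs = aggregate_scores(self.FEATS, self.FLANKS, scores)
        assert all(a.delta == 0.0 for a in aggs)
        assert signs["zero"] == 2

    def test_feature_boost_recovered_exactly(self):
        scores = {"chr1": {i: 0.2 for i in range(400)}}
        for fid, iv in self.FEATS:
            for i in range(iv.start, iv.end):
                scores["chr1"][i] = 0.7
        aggs, signs = aggregate_scores(self.FEATS, self.FLANKS, scores)
        assert all(a.delta == pytest.approx(0.5) for a in aggs)
        assert signs["positive"] == 2

    def test_empty_score_map_reports_missing(self):
        with pytest.warns(UserWarning, match="empty score map"):
            aggs, signs = aggregate_scores(self.FEATS, self.FLANKS, {})
        assert all(a.mean is None and a.n_bases == 0 for a in aggs)
        assert signs["missing"] == 2

    def test_unscored_bases_excluded_not_zero_filled(self):
        scores = {"chr1": {i: 1.0 for i in range(100, 125)}}  # half of f1
        aggs, _ = aggregate_scores(self.FEATS[:1], self.FLANKS, scores)
        assert aggs[0].mean == 1.0 and aggs[0].n_bases == 25

    def test_numt_flank_subtraction(self):
        numt = NumtRecord(GenomicInterval("chr1", 0, 500, "+"),
                          GenomicInterval("chrM", 0, 500, "+"), "n0")
        flanks = numt_flanks(numt, [GenomicInterval("chr1", 100, 150, "+")])
        assert [(f.start, f.end) for f in flanks] == [(0, 100), (150, 500)]
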