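"""HPD intervals, congruence decisions, consensus filter, regression."""

import numpy as np
import pytest

from biogeodiva.areas import AreaAlphabet
from biogeodiva.calibrations import load_calibrations
from biogeodiva.congruence import (
    GeoEventWindow,
    HypothesisRow,
    VicarianceCall,
    congruence_test,
    consensus_vicariance,
    hpd_interval,
    precision_regression,
    run_hypothesis_table,
)
from biogeodiva.fixtures import load_fixture
from biogeodiva.reconstruction import AncestralReconstruction
from biogeodiva.trees import parse_newick


def brute_force_hpd(samples, mass=0.95):
    """Independent oracle: try every window over the sorted samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    k = int(np.ceil(mass * n)) - 1
    best = None
    for i in range(n - k):
        w = x[i + k] - x[i]
        if best is None or w < best[1] - 1e-15:
            best = ((x[i], x[i + k]), w)
    return best[0]


class TestHPD:
    def test_constant_samples_zero_width(self):
        iv = hpd_interval([4.2] * 50)
        assert (iv.lower, iv.upper) == (4.2, 4.2)

    def test_standard_normal_length(self):
        rng = np.random.default_rng(2)
        iv = hpd_interval(rng.standard_normal(10_000))
        assert iv.width == pytest.approx(3.92, rel=0.05)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            samples = rng.gamma(2.0, 3.0, size=20)
            iv = hpd_interval(samples)
            assert (iv.lower, iv.upper) == pytest.approx(brute_force_hpd(samples))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            hpd_interval([])

    def test_coverage_calibration(self):
        """A fresh draw lands inside the 95% HPD of its peers ~95% of the time."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            draws = rng.standard_normal(2000)
            probe = rng.standard_normal()
            iv = hpd_interval(draws)
            hits += iv.lower <= probe <= iv.upper
        assert hits / n_rep == pytest.approx(0.95, abs=0.02)


class TestCongruence:
    def test_gaarlandia_style_rejection(self):
        # a 35–33 Ma window misses all three node-age intervals
        window = GeoEventWindow("older-window", 35, 33)
        decision = congruence_test(
            {"B1": (8.14, 19.72), "B2": (9.29, 22.29), "B3": (9.22, 23.16)}, window
        )
        assert decision.decision == "rejected"
        assert not any(decision.flags.values())

    def test_overlap_in_all_runs_keeps_null(self):
        window = GeoEventWindow("mid-window", 25, 10)
        decision = congruence_test(
            {"B1": (11.92, 31.64), "B2": (16.71, 28.34), "B3": (14.18, 26.05)}, window
        )
        assert decision.decision == "not_rejected"
        assert all(decision.flags.values())

    def test_single_disjoint_analysis_rejects(self):
        # middle interval misses the 10–7 Ma window → rejected
        window = GeoEventWindow("young-window", 10.0, 7.0)
        decision = congruence_test(
            {"B1": (9.51, 20.88), "B2": (14.76, 28.37), "B3": (8.83, 18.27)}, window
        )
        assert decision.decision == "rejected"
        assert decision.flags == {"B1": True, "B2": False, "B3": True}

    def test_window_equal_to_intervals(self):
        window = GeoEventWindow("exact", 12.0, 5.0)
        decision = congruence_test({l: (5.0, 12.0) for l in "abc"}, window)
        assert decision.decision == "not_rejected"

    def test_shared_endpoint_counts_as_overlap(self):
        window = GeoEventWindow("touching", 25.0, 20.0)
        decision = congruence_test({"B1": (10.0, 20.0)}, window)
        assert decision.decision == "not_rejected"

    def test_any_run_overlap_rule(self):
        window = GeoEventWindow("w", 10.0, 7.0)
        intervals = {"B1": (9.51, 20.88), "B2": (14.76, 28.37), "B3": (19.0, 25.0)}
        assert congruence_test(intervals, window, "any-run-overlap").decision == "not_rejected"
        assert congruence_test(intervals, window, "all-runs-overlap").decision == "rejected"

    def test_malformed_window_rejected(self):
        with pytest.raises(ValueError, match="older"):
            GeoEventWindow("backwards", 5.0, 10.0)

    def test_overlap_predicate_symmetric(self):
        rng = np.random.default_rng(23)
        for _ in range(1000):
            a = np.sort(rng.uniform(0, 50, 2))
            b = np.sort(rng.uniform(0, 50, 2))
            w_ab = GeoEventWindow("w", b[1], b[0])
            w_ba = GeoEventWindow("w", a[1], a[0])
            assert w_ab.overlaps(a[0], a[1]) == w_ba.overlaps(b[0], b[1])

    def test_widening_never_flips_to_rejected(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            lo, hi = np.sort(rng.uniform(0, 40, 2))
            y, o = np.sort(rng.uniform(0, 40, 2))
            window = GeoEventWindow("w", o, y)
            base = congruence_test({"B1": (lo, hi)}, window).decision
            if base == "not_rejected":
                wider = (lo - rng.uniform(0, 5), hi + rng.uniform(0, 5))
                assert congruence_test({"B1": wider}, window).decision == "not_rejected"


class TestHypothesisTable:
    def test_packaged_table_reproduces_recorded_decisions(self):
        rows = load_fixture("table3")
        report = run_hypothesis_table(rows)
        assert len(rows) == 14
        assert report.mismatches == []
        assert report.n_rejected == 2
        assert report.n_cladogenetic_events == 11
        assert report.n_geological_hypotheses == 13

    def test_empty_table(self):
        report = run_hypothesis_table([])
        assert (
            report.n_cladogenetic_events,
            report.n_geological_hypotheses,
            report.n_rejected,
        ) == (0, 0, 0)

    def test_single_disjoint_row_counts_one_rejection(self):
        row = HypothesisRow(
            cladogenetic_event="split",
            window=GeoEventWindow("w", 40.0, 35.0),
            intervals={"B1": (5.0, 10.0), "B2": (36.0, 42.0), "B3": (34.0, 41.0)},
        )
        assert run_hypothesis_table([row]).n_rejected == 1

    def test_duplicate_pair_rejected(self):
        row = HypothesisRow(
            "split", GeoEventWindow("w", 40.0, 35.0), {"B1": (36.0, 42.0)}
        )
        with pytest.raises(ValueError, match="duplicate"):
            run_hypothesis_table([row, row])


def _recon(topology, vicariant_clades):
    r = AncestralReconstruction(
        method="stub", topology=topology, alphabet=AreaAlphabet("AB"), node_weights={}
    )
    for c in vicariant_clades:
        r.events[tuple(sorted(c))] = ("vicariance",)
    return r


class TestConsensus:
    topologies = {
        "ML": parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"),
        "B1": parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"),
        "B2": parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"),
        "B3": parse_newick("(((A:1,B:1):1,C:2):1,D:3);"),
    }

    def _grid(self, hits, clade=("A", "B")):
        grid = []
        for i in range(16):
            label = ["ML", "B1", "B2", "B3"][i % 4]
            grid.append(_recon(label, [clade] if i < hits else []))
        return grid

    def test_support_over_half_and_all_topologies(self):
        calls = consensus_vicariance(self._grid(9), self.topologies)
        assert [c.clade for c in calls] == [("A", "B")]
        assert calls[0].support == pytest.approx(9 / 16)  # 0.5625
        assert calls[0].topology_presence == 4

    def test_boundary_half_inclusive(self):
        calls = consensus_vicariance(self._grid(8), self.topologies)
        assert [c.clade for c in calls] == [("A", "B")]

    def test_below_half_excluded(self):
        assert consensus_vicariance(self._grid(7), self.topologies) == []

    def test_clade_missing_from_one_topology_excluded(self):
        # {C, D} is a clade of only three of the four topologies
        calls = consensus_vicariance(
            self._grid(16, clade=("C", "D")), self.topologies
        )
        assert calls == []

    def test_unknown_topology_tag(self):
        with pytest.raises(ValueError, match="unknown topology"):
            consensus_vicariance([_recon("??", [("A", "B")])], self.topologies)


class TestPrecisionRegression:
    def _summaries(self, widths):
        clades = [(f"x{i}",) for i in range(len(widths))]
        means = np.linspace(5, 40, len(widths))
        return {c: (m, w) for c, m, w in zip(clades, means, widths)}

    def test_constant_width_gives_zero_slope(self):
        fits = precision_regression({"B1": self._summaries([3.0] * 10)})
        assert fits["B1"].slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        means = np.linspace(5, 40, 8)
        summ = {(f"x{i}",): (m, 0.5 * m) for i, m in enumerate(means)}
        fit = precision_regression({"B1": summ})["B1"]
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(123)
        m = rng.uniform(2, 50, 50)
        w = 0.2 * m + rng.normal(0, 0.5, 50)
        summ = {(f"x{i}",): (m[i], w[i]) for i in range(50)}
        fit = precision_regression({"B1": summ})["B1"]
        # closed-form normal equations, computed independently
        mx, wx = m.mean(), w.mean()
        slope = ((m - mx) * (w - wx)).sum() / ((m - mx) ** 2).sum()
        intercept = wx - slope * mx
        assert fit.slope == pytest.approx(slope, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    def test_statsmodels_cross_check(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        m = rng.uniform(2, 50, 30)
        w = 0.3 * m + rng.normal(0, 1.0, 30)
        summ = {(f"x{i}",): (m[i], w[i]) for i in range(30)}
        fit = precision_regression({"B1": summ})["B1"]
        ols = sm.OLS(w, sm.add_constant(m)).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-9)
        assert fit.slope == pytest.approx(ols.params[1], abs=1e-9)
        assert fit.residual_se == pytest.approx(np.sqrt(ols.mse_resid), abs=1e-9)

    def test_unshared_nodes_dropped_with_warning(self):
        s1 = self._summaries([1, 2, 3, 4])
        s2 = dict(list(self._summaries([1, 2, 3, 4]).items())[:3])
        with pytest.warns(UserWarning, match="dropped"):
            fits = precision_regression({"B1": s1, "B2": s2})
        assert fits["B1"].n == 3

    def test_too_few_shared_nodes(self):
        with pytest.raises(ValueError, match="3 nodes"):
            precision_regression({"B1": self._summaries([1.0, 2.0])})


class TestCalibrations:
    def test_packaged_configuration_counts(self):
        priors, counts = load_fixture("table1")
        assert counts == {"B1": 1, "B2": 6, "B3": 7}
        assert len({p.name for p in priors}) == 7

    def test_emesinae_b2_prior_is_exponential_min_25(self):
        priors, _ = load_fixture("table1")
        b2_emesinae = [
            p for p in priors
            if p.name == "Danzigia christelae" and "B2" in p.configurations
        ]
        assert len(b2_emesinae) == 1
        assert b2_emesinae[0].kind == "exponential"
        assert b2_emesinae[0].hard_minimum == 25.0
        assert b2_emesinae[0].mean == 10.5  # decimal comma normalised

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("name\tclade_taxa\tkind\tmean\tsd_or_offset\tconfigurations\n")
        with pytest.raises(ValueError, match="no priors"):
            load_calibrations(path)

    def test_unknown_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "name\tclade_taxa\tkind\tmean\tsd_or_offset\tconfigurations\n"
            "X\ta;b\tcauchy\t10\t1\tB1\n"
        )
        with pytest.raises(ValueError, match="cauchy"):
            load_calibrations(path)
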