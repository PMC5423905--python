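import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import splicescape as sp
from splicescape.sqtl import Marker, quasibinomial_fit


def _junction(chrom="chr1", start=100, end=200, strand="+"):
    return sp.SpliceJunction(sp.GenomeInterval(chrom, start, end, strand))


def _panel_one_chrom(n_lines=20, geno=None):
    markers = [Marker("m0", sp.GenomeInterval("chr1", 0, 10_000))]
    if geno is None:
        geno = ["B"] * (n_lines // 2) + ["M"] * (n_lines - n_lines // 2)
    df = pd.DataFrame({"m0": geno}, index=[f"L{i}" for i in range(n_lines)])
    return sp.RilPanel(list(df.index), markers, df)


class TestFrequencyAndEligibility:
    @pytest.mark.parametrize("y,r,expected", [(20, 80, 0.2), (0, 50, 0.0), (50, 0, 1.0)])
    def test_splicing_frequency(self, y, r, expected):
        assert sp.splicing_frequency(y, r) == pytest.approx(expected)

    def test_zero_total_is_nan(self):
        assert math.isnan(sp.splicing_frequency(0, 0))

    def test_minimum_spanning_reads(self):
        low = sp.JunctionCountSet(_junction(), np.array([19]), np.array([100]))
        ok = sp.JunctionCountSet(_junction(), np.array([20]), np.array([100]))
        assert sp.eligible_junctions([low, ok]) == [ok]

    def test_mean_per_line_boundary(self):
        # 105 lines, 525 total -> mean exactly 5.0 -> kept
        y = np.full(105, 5)
        c = sp.JunctionCountSet(_junction(), y, np.full(105, 50))
        assert sp.eligible_junctions([c]) == [c]
        y2 = np.full(105, 5)
        y2[0] = 4
        c2 = sp.JunctionCountSet(_junction(), y2, np.full(105, 50))
        assert sp.eligible_junctions([c2]) == []

    def test_matches_brute_force(self, rng):
        counts = [
            sp.JunctionCountSet(
                _junction(start=i * 1000, end=i * 1000 + 100),
                rng.integers(0, 12, size=8),
                rng.integers(0, 60, size=8),
            )
            for i in range(100)
        ]
        kept = {id(c) for c in sp.eligible_junctions(counts)}
        for c in counts:
            total = sum(int(v) for v in c.junction_reads)
            ok = total >= 20 and total / 8 >= 5.0
            assert (id(c) in kept) == ok


class TestQuasiBinomialFit:
    def test_identical_group_proportions(self):
        y = np.array([20, 30, 20, 30], dtype=float)
        n = np.array([100, 100, 100, 100], dtype=float)
        X = np.column_stack([np.ones(4), [0, 0, 1, 1]])
        fit = quasibinomial_fit(y, n, X)
        assert fit.params[1] == pytest.approx(0.0, abs=1e-8)
        assert fit.pvalues[1] == pytest.approx(1.0, abs=1e-6)

    def test_pure_binomial_dispersion_near_one(self, rng):
        phis = []
        for _ in range(30):
            n = np.full(100, 60)
            g = rng.integers(0, 2, 100).astype(float)
            p = 1 / (1 + np.exp(-(-1.0 + 0.0 * g)))
            y = rng.binomial(n, p)
            X = np.column_stack([np.ones(100), g])
            phis.append(quasibinomial_fit(y, n, X).dispersion)
        assert 0.7 <= float(np.median(phis)) <= 1.3

    def test_planted_log_odds_recovered(self, rng):
        errs = []
        for rep in range(50):
            sim = sp.simulate_ril_panel(
                n_lines=100, n_junctions=1, planted=[(0, "cis", 0.8)],
                rho=0.05, depth=50, seed=500 + rep,
            )
            tests = sp.cis_scan(sim.panel, sim.counts)
            errs.append(abs(tests[0].beta_genotype - 0.8))
        assert float(np.median(errs)) <= 0.2

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(ValueError):
            quasibinomial_fit(np.array([1, 2, 3, 4]), np.full(4, 10), X)

    def test_y_greater_than_n_rejected(self):
        X = np.ones((3, 1))
        with pytest.raises(ValueError):
            quasibinomial_fit(np.array([5, 1, 1]), np.array([4, 10, 10]), X)

    def test_separation_falls_back_flagged(self):
        # genotype perfectly separates 0% from 100% splicing
        y = np.array([0, 0, 0, 30, 30, 30], dtype=float)
        n = np.full(6, 30, dtype=float)
        X = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])
        fit = quasibinomial_fit(y, n, X)
        assert fit.separated
        assert np.isfinite(fit.params).all() and np.isfinite(fit.pvalues).all()


class TestCalibration:
    def test_type_i_error_controlled_and_naive_wald_inflated(self, rng):
        """The Pearson-dispersion t-test holds its nominal level under
        beta-binomial overdispersion where the plain binomial Wald test
        does not — the reason the overdispersion control exists."""
        import statsmodels.api as sm

        quasi_rej, naive_rej = [], []
        for rep in range(60):
            sim = sp.simulate_ril_panel(
                n_lines=100, n_junctions=5, planted=(), rho=0.1, depth=50,
                seed=2000 + rep,
            )
            for c in sim.counts:
                m = sim.panel.marker_containing(c.junction.intron.chrom,
                                                c.junction.intron.start)
                g = sim.panel.genotype_vector(m.marker_id).to_numpy()
                y = c.junction_reads.astype(float)
                n = y + c.gene_other_reads.astype(float)
                X = np.column_stack([np.ones(len(y)), g])
                fit = quasibinomial_fit(y, n, X)
                quasi_rej.append(fit.pvalues[1] < 0.05)
                res = sm.GLM(np.column_stack([y, n - y]), X,
                             family=sm.families.Binomial()).fit()
                naive_rej.append(res.pvalues[1] < 0.05)
        assert 0.03 <= float(np.mean(quasi_rej)) <= 0.07
        assert float(np.mean(naive_rej)) > 0.10

    def test_label_swap_negates_beta_exactly(self, rng):
        sim = sp.simulate_ril_panel(n_lines=80, n_junctions=1,
                                    planted=[(0, "cis", 0.6)], seed=77)
        c = sim.counts[0]
        m = sim.panel.marker_containing(c.junction.intron.chrom,
                                        c.junction.intron.start)
        g = sim.panel.genotype_vector(m.marker_id).to_numpy()
        y = c.junction_reads.astype(float)
        n = y + c.gene_other_reads.astype(float)
        X = np.column_stack([np.ones(len(y)), g])
        Xs = np.column_stack([np.ones(len(y)), 1.0 - g])
        f1 = quasibinomial_fit(y, n, X)
        f2 = quasibinomial_fit(y, n, Xs)
        assert f1.params[1] == pytest.approx(-f2.params[1], rel=1e-6)
        assert f1.pvalues[1] == pytest.approx(f2.pvalues[1], rel=1e-6)


class TestCisScan:
    def test_bh_adjustment_matches_hand_computation(self):
        """The BH q-values used by the cis scan agree with the step-up
        procedure computed by hand: q_(i) = min over j>=i of p_(j)*n/j."""
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.01, 0.02, 0.9])
        _, q, _, _ = multipletests(p, method="fdr_bh")
        n = len(p)
        order = np.argsort(p)
        hand = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            idx = order[rank]
            running = min(running, p[idx] * n / (rank + 1))
            hand[idx] = running
        assert np.allclose(q, hand)
        assert np.allclose(q, [0.004, 0.02, 0.02666667, 0.9])

    def test_q_values_monotone_in_p(self, rng):
        sim = sp.simulate_ril_panel(n_lines=60, n_junctions=12, seed=31)
        tests = sp.cis_scan(sim.panel, sim.counts)
        tests = sorted(tests, key=lambda t: t.p_genotype)
        qs = [t.q for t in tests]
        assert qs == sorted(qs)

    def test_fold_filter_and_direction(self, rng):
        sim = sp.simulate_ril_panel(
            n_lines=120, n_junctions=6,
            planted=[(0, "cis", math.log(3.0)), (1, "cis", -math.log(3.0))],
            rho=0.02, depth=80, seed=90,
        )
        tests = sp.cis_scan(sim.panel, sim.counts)
        sig = sp.significant_cis(tests, fold=2.0)
        keys = {t.junction_key for t in sig}
        assert sim.counts[0].junction.key in keys
        assert sim.counts[1].junction.key in keys
        by_key = {t.junction_key: t for t in sig}
        assert by_key[sim.counts[0].junction.key].direction == "up-in-M"
        assert by_key[sim.counts[1].junction.key].direction == "up-in-B"
        for t in sig:
            assert t.odds_fold_change >= 2.0


class TestTransScan:
    def test_planted_trans_effect_found_without_interaction(self):
        sim = sp.simulate_ril_panel(
            n_lines=120, n_junctions=2, planted=[(0, "trans", 1.0)],
            rho=0.02, depth=60, seed=11,
        )
        eff = sim.effects[0]
        tests = sp.trans_scan(sim.panel, sim.counts[0])
        hit = [t for t in tests if t.marker_id == eff.marker_id][0]
        assert hit.p_genotype < 1e-4
        assert hit.p_interaction > 0.001  # no planted interaction

    def test_planted_m_only_interaction_found(self):
        sim = sp.simulate_ril_panel(
            n_lines=150, n_junctions=2, planted=[(0, "interaction", 1.5)],
            rho=0.02, depth=60, seed=12,
        )
        eff = sim.effects[0]
        tests = sp.trans_scan(sim.panel, sim.counts[0])
        hit = [t for t in tests if t.marker_id == eff.marker_id][0]
        assert hit.p_interaction is not None and hit.p_interaction < 1e-3

    def test_null_p_values_uniform(self):
        pvals = []
        for rep in range(10):
            sim = sp.simulate_ril_panel(
                n_lines=100, n_junctions=2, planted=(), rho=0.05, depth=50,
                seed=3000 + rep,
            )
            for c in sim.counts:
                pvals.extend(t.p_genotype for t in sp.trans_scan(sim.panel, c))
        _, p_ks = stats.kstest(pvals, "uniform")
        assert p_ks > 0.01


class TestTransCutoff:
    def _panel(self, markers):
        ids = [m.marker_id for m in markers]
        df = pd.DataFrame({mid: ["B", "M"] for mid in ids}, index=["L0", "L1"])
        return sp.RilPanel(["L0", "L1"], markers, df)

    def test_fully_occupied_regions(self):
        # 2 chroms x 100 occupied regions, 10 junctions per chrom:
        # 20 junctions x 100 other-chrom regions -> 0.05/2000
        markers = []
        L = 100_000
        for chrom in ("chr1", "chr2"):
            for k in range(100):
                markers.append(
                    Marker(f"{chrom}_m{k}",
                           sp.GenomeInterval(chrom, k * 1000, (k + 1) * 1000))
                )
        panel = self._panel(markers)
        chroms = ["chr1"] * 10 + ["chr2"] * 10
        cutoff = sp.trans_cutoff(panel, chroms, {"chr1": L, "chr2": L})
        assert cutoff == pytest.approx(0.05 / 2000)

    def test_partially_occupied_regions(self):
        # 37 markers in 37 distinct regions of chr2; one chr1 junction
        L = 100_000
        markers = [
            Marker(f"m{k}", sp.GenomeInterval("chr2", k * 1000 + 10, k * 1000 + 20))
            for k in range(37)
        ]
        panel = self._panel(markers)
        cutoff = sp.trans_cutoff(panel, ["chr1"], {"chr1": L, "chr2": L})
        assert cutoff == pytest.approx(0.05 / 37)

    def test_no_trans_markers_is_an_error(self):
        markers = [Marker("m0", sp.GenomeInterval("chr1", 0, 100))]
        panel = self._panel(markers)
        with pytest.raises(ValueError):
            sp.trans_cutoff(panel, ["chr1"], {"chr1": 100_000})


class TestSpliceSiteWindows:
    def test_plus_strand_coordinates(self):
        donor, acceptor = sp.splice_site_windows(_junction(start=100, end=200))
        assert (donor.start, donor.end) == (97, 106)
        assert (acceptor.start, acceptor.end) == (198, 201)

    def test_minus_strand_mirrors(self):
        donor, acceptor = sp.splice_site_windows(
            _junction(start=100, end=200, strand="-")
        )
        assert (donor.start, donor.end) == (194, 203)
        assert (acceptor.start, acceptor.end) == (99, 102)

    def test_windows_total_twelve_bp(self, rng):
        for _ in range(50):
            s = int(rng.integers(100, 10_000))
            e = s + int(rng.integers(60, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            donor, acceptor = sp.splice_site_windows(_junction(start=s, end=e,
                                                               strand=strand))
            assert donor.length + acceptor.length == 12


class TestSnpEnrichment:
    def test_yates_worked_value(self):
        chi2, p = sp.yates_chi2([[10, 90], [30, 70]])
        assert chi2 == pytest.approx(11.28, abs=0.01)
        assert p == pytest.approx(7.8e-4, rel=0.05)

    def test_yates_matches_closed_form(self):
        a, b, c, d = 10, 90, 30, 70
        N = a + b + c + d
        expected = (
            N * (abs(a * d - b * c) - N / 2) ** 2
            / ((a + b) * (c + d) * (a + c) * (b + d))
        )
        chi2, _ = sp.yates_chi2([[a, b], [c, d]])
        assert chi2 == pytest.approx(expected)

    def test_identical_proportions_near_zero(self):
        chi2, p = sp.yates_chi2([[20, 80], [20, 80]])
        assert chi2 == pytest.approx(0.0, abs=0.2)
        assert p > 0.5

    def test_planted_enrichment_detected(self):
        planted = [(i, "cis", 1.0) for i in range(15)]
        sim = sp.simulate_ril_panel(
            n_lines=50, n_junctions=60, planted=planted, seed=8,
            snp_window_prob_flagged=0.6, snp_window_prob_background=0.02,
        )
        sig = [sim.counts[i].junction for i in range(15)]
        alljs = [c.junction for c in sim.counts]
        table, chi2, p = sp.snp_enrichment(sig, alljs, sim.snp_positions)
        assert table.sum() == 60
        assert p < 0.05


class TestProximity:
    def test_window_examples(self):
        genes = [sp.GenomeInterval("chr1", 1_500_000, 1_600_000)]
        # sQTL at 1.0 Mb: gene 0.5 Mb away
        assert sp.proximity_overlap([("chr1", 1_000_000)], genes, 1_000_000) == 1.0
        # gene 1.5 Mb away: miss at 1 Mb, hit at 10 Mb
        far = [sp.GenomeInterval("chr1", 2_500_000, 2_600_000)]
        assert sp.proximity_overlap([("chr1", 1_000_000)], far, 1_000_000) == 0.0
        assert sp.proximity_overlap([("chr1", 1_000_000)], far, 10_000_000) == 1.0

    def test_matches_brute_force(self, rng):
        genes = [
            sp.GenomeInterval("chr1", int(s), int(s) + 1000)
            for s in rng.integers(0, 10**7, size=30)
        ]
        pos = [("chr1", int(p)) for p in rng.integers(0, 10**7, size=50)]
        w = 200_000
        frac = sp.proximity_overlap(pos, genes, w)
        hits = 0
        for chrom, p in pos:
            if any(g.start <= p + w and p - w <= g.end for g in genes):
                hits += 1
        assert frac == pytest.approx(hits / len(pos))
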