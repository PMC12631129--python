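"""Coverage/noise filters, binomial-GLM LRT, BH and enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from juncsplice import differential as diff
from juncsplice.simulate import simulate_differential_counts


def table(rows):
    return pd.DataFrame(rows, columns=["event_id", "sample", "group", "I", "E"])


class TestCoverageFilter:
    def test_low_inclusion_total_dropped(self):
        t = table(
            [
                ("e1", "s1", "A", 4, 20),
                ("e1", "s2", "B", 5, 20),
            ]
        )
        assert diff.coverage_filter(t) == []  # total I = 9 < 10

    def test_zero_threshold_identity(self):
        t = table([("e1", "s1", "A", 1, 0), ("e1", "s2", "B", 0, 1)])
        assert diff.coverage_filter(t, min_total=0) == ["e1"]

    def test_equals_brute_force(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(40):
            for s, g in [("s1", "A"), ("s2", "A"), ("s3", "B"), ("s4", "B")]:
                rows.append((f"e{i}", s, g, int(rng.integers(0, 8)), int(rng.integers(0, 8))))
        t = table(rows)
        brute = []
        for ev, sub in t.groupby("event_id"):
            ok = sub["I"].sum() >= 10 and sub["E"].sum() >= 10
            for g in ("A", "B"):
                gsub = sub[sub["group"] == g]
                ok = ok and (gsub["I"].sum() + gsub["E"].sum()) >= 10
            if ok:
                brute.append(ev)
        assert diff.coverage_filter(t) == sorted(brute)


class TestNoiseFilter:
    def test_interior_intervals_pass(self):
        assert diff.noise_filter(0.2, 0.6, 0.3, 0.7)

    def test_both_groups_pinned_low_fail(self):
        assert not diff.noise_filter(0.0, 0.04, 0.0, 0.03)

    def test_opposite_pins_pass(self):
        # group A pinned at 0, group B pinned at 1: a maximal PSI
        # difference, not splicing noise — all four conditions hold
        assert diff.noise_filter(0.0, 0.04, 0.97, 1.0)

    def test_uninformative_interval_fails(self):
        # group A's CI spans nearly [0, 1]: condition 3 is violated
        assert not diff.noise_filter(0.02, 0.98, 0.3, 0.7)

    def test_truth_table_exhaustive(self):
        """All 16 boundary configurations agree with independent
        evaluation of the four published conditions."""
        lo_vals = {True: 0.10, False: 0.01}   # L > 0.05 ?
        hi_vals = {True: 0.90, False: 0.99}   # H < 0.95 ?
        for la, ha, lb, hb in itertools.product([True, False], repeat=4):
            L_a, H_a = lo_vals[la], hi_vals[ha]
            L_b, H_b = lo_vals[lb], hi_vals[hb]
            expected = (
                (la or lb) and (ha or hb) and (la or ha) and (lb or hb)
            )
            assert diff.noise_filter(L_a, H_a, L_b, H_b) == expected, (
                la, ha, lb, hb,
            )


def binom_loglik(I, n, p):
    out = 0.0
    for i, ni in zip(I, n):
        if 0 < p < 1:
            out += i * math.log(p) + (ni - i) * math.log(1 - p)
        elif (p == 0 and i > 0) or (p == 1 and i < ni):
            return -math.inf
    return out


class TestGlmLrt:
    def test_identical_groups_null(self):
        t = table(
            [
                ("e", "s1", "A", 10, 10),
                ("e", "s2", "A", 10, 10),
                ("e", "s3", "B", 10, 10),
                ("e", "s4", "B", 10, 10),
            ]
        )
        p, delta, _ = diff.glm_lrt(t)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert delta == 0.0

    def test_deviance_matches_closed_form_mle(self):
        """For a two-group intercept/group design the binomial MLEs are
        the pooled proportions; the GLM deviance difference must match
        the closed-form log-likelihood ratio to 1e-6."""
        t = table(
            [
                ("e", "s1", "A", 12, 8),
                ("e", "s2", "A", 15, 5),
                ("e", "s3", "B", 6, 14),
                ("e", "s4", "B", 9, 11),
            ]
        )
        p, delta, _ = diff.glm_lrt(t)
        I = t["I"].to_numpy()
        n = (t["I"] + t["E"]).to_numpy()
        grp = t["group"].to_numpy()
        ll0 = binom_loglik(I, n, I.sum() / n.sum())
        ll1 = 0.0
        for g in ("A", "B"):
            m = grp == g
            ll1 += binom_loglik(I[m], n[m], I[m].sum() / n[m].sum())
        from scipy.stats import chi2

        expected_p = chi2.sf(2 * (ll1 - ll0), 1)
        assert p == pytest.approx(expected_p, abs=1e-6)
        assert delta == pytest.approx(27 / 40 - 15 / 40)

    def test_label_swap_flips_delta_sign_only(self):
        t = table(
            [
                ("e", "s1", "g1", 12, 8),
                ("e", "s2", "g1", 15, 5),
                ("e", "s3", "g2", 6, 14),
                ("e", "s4", "g2", 9, 11),
            ]
        )
        p1, d1, _ = diff.glm_lrt(t)
        swapped = t.assign(group=t["group"].map({"g1": "g2", "g2": "g1"}))
        p2, d2, _ = diff.glm_lrt(swapped)
        assert p1 == pytest.approx(p2, abs=1e-9)
        assert d1 == pytest.approx(-d2)

    def test_separation_flagged_and_finite(self):
        t = table(
            [
                ("e", "s1", "A", 20, 0),
                ("e", "s2", "A", 15, 0),
                ("e", "s3", "B", 2, 18),
                ("e", "s4", "B", 3, 17),
            ]
        )
        p, delta, sep = diff.glm_lrt(t)
        assert sep and 0 <= p < 0.05 and delta == 1 - 5 / 40

    def test_type_one_error_calibrated_under_null(self):
        """Fraction of p < 0.05 under equal PSI stays within binomial
        sampling error of the nominal level."""
        counts = simulate_differential_counts(n_events=200, delta_psi=0.0, seed=3)
        ps = np.array(
            [diff.glm_lrt(sub)[0] for _, sub in counts.groupby("event_id")]
        )
        rate = (ps < 0.05).mean()
        # 3 sigma band for 200 Bernoulli(0.05) trials
        band = 3 * math.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= band

    def test_power_at_moderate_effect(self):
        """dPSI = 0.3, 20 samples, coverage 50: > 80% of events are
        called specific after BH at FDR < 0.01."""
        counts = simulate_differential_counts(
            n_events=200, n_samples_per_group=10, coverage=50, delta_psi=0.3, seed=4
        )
        results = diff.differential_splicing(counts)
        assert sum(r.specific for r in results) / 200 > 0.8


class TestBhAndCalls:
    def test_single_p_unchanged(self):
        assert diff.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_computed_step_up(self):
        got = diff.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert diff.bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @pytest.mark.parametrize(
        "fdr,dpsi,expected",
        [(0.005, 0.25, True), (0.005, 0.15, False), (0.02, 0.5, False)],
    )
    def test_specific_requires_both_cutoffs(self, fdr, dpsi, expected):
        r = diff.DiffSplicingResult("e", 0.5, 0.5 - dpsi, dpsi, p_value=fdr)
        r.fdr = fdr
        r.specific = bool(r.fdr < 0.01 and abs(r.delta_psi) > 0.2)
        assert r.specific is expected


class TestEnrichment:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(500)]
        expression = pd.Series(rng.lognormal(3, 1, size=500), index=genes)
        gene_sets = {
            "setA": set(genes[:50]),
            "setB": set(genes[50:100]),
        }
        return genes, expression, gene_sets

    def test_planted_enrichment_detected(self):
        genes, expression, gene_sets = self._setup()
        test = set(genes[:40])  # drawn from setA
        bg = set(genes)
        out = diff.enrichment_test(test, bg, gene_sets, expression, seed=1)
        row = out.set_index("gene_set").loc["setA"]
        assert row["p_value"] < 0.05 and row["odds_ratio"] > 1

    def test_random_test_genes_not_enriched(self):
        genes, expression, gene_sets = self._setup()
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            test = set(rng.choice(genes, size=40, replace=False))
            out = diff.enrichment_test(test, set(genes), gene_sets, expression, seed=seed)
            hits += int(out["enriched"].any())
        assert hits <= 2

    def test_set_proportional_test_genes_odds_near_one(self):
        """A test set mirroring the background's set composition shows
        no enrichment."""
        genes, expression, gene_sets = self._setup()
        test = set(genes[::5])  # uniform stride across both sets
        out = diff.enrichment_test(test, set(genes), gene_sets, expression, seed=2)
        assert (out["p_value"] >= 0.05).all()
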