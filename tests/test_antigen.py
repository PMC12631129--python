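"""Atypical-isoform calling, peptide translation, MHC ranks and ATB."""

import numpy as np
import pytest

from juncsplice import antigen as ag
from juncsplice import quantify as qt


def counts_for_proportion(p, n=1000):
    """(I, E) with inclusion proportion p at depth n."""
    I = int(round(p * n))
    return (I, n - I)


class TestCallAtypicalVsNormal:
    def test_high_cancer_low_normals_is_atypical(self):
        """Cancer p=0.4 with normals at p<=0.02 satisfies both the 10x
        mean rule and the 4x per-tissue CI-bound rule."""
        cancer = {"e1": counts_for_proportion(0.4)}
        normals = {
            "t1": {"e1": counts_for_proportion(0.02)},
            "t2": {"e1": counts_for_proportion(0.01)},
        }
        out = ag.call_atypical_vs_normal(cancer, normals)
        sides = {(c.event_id, c.atypical_side) for c in out}
        assert ("e1", "inclusion") in sides
        assert ("e1", "exclusion") not in sides

    def test_single_hot_normal_tissue_blocks_call(self):
        """One normal tissue at p=0.1 violates the 4x CI-bound rule
        (CI low ~0.37 < 0.4)."""
        cancer = {"e1": counts_for_proportion(0.4)}
        normals = {
            "t1": {"e1": counts_for_proportion(0.1)},
            "t2": {"e1": counts_for_proportion(0.0)},
        }
        out = ag.call_atypical_vs_normal(cancer, normals)
        assert not any(c.atypical_side == "inclusion" for c in out)

    def test_degenerate_folds_accept_everything_detectable(self):
        cancer = {"e1": counts_for_proportion(0.4), "e2": counts_for_proportion(0.6)}
        normals = {"t1": {k: (0, 0) for k in cancer}}
        out = ag.call_atypical_vs_normal(cancer, normals, fold_mean=1, fold_max=1)
        assert {c.event_id for c in out} == {"e1", "e2"}

    def test_detectability_gate(self):
        # I < 5 fails the per-cell-type gate
        cancer = {"e1": (4, 100)}
        out = ag.call_atypical_vs_normal(cancer, {"t1": {"e1": (0, 100)}})
        assert out == []

    def test_relaxing_folds_never_shrinks_the_set(self):
        rng = np.random.default_rng(3)
        cancer = {
            f"e{i}": counts_for_proportion(rng.uniform(0.1, 0.9), 500)
            for i in range(30)
        }
        normals = {
            "t1": {
                k: counts_for_proportion(rng.uniform(0, 0.15), 500) for k in cancer
            }
        }
        strict = ag.call_atypical_vs_normal(cancer, normals, fold_mean=10, fold_max=4)
        loose = ag.call_atypical_vs_normal(cancer, normals, fold_mean=5, fold_max=2)
        key = lambda out: {(c.event_id, c.atypical_side) for c in out}
        assert key(strict) <= key(loose)


class TestCallTumorSpecificVsStroma:
    def _cand(self):
        return ag.AntigenCandidate("e1", "inclusion", 0.5)

    def test_clean_stroma_retained(self):
        cancer = {"e1": counts_for_proportion(0.5)}
        stroma = {
            "p1": {"e1": counts_for_proportion(0.05)},
            "p2": {"e1": counts_for_proportion(0.1)},
        }
        out = ag.call_tumor_specific_vs_stroma([self._cand()], cancer, stroma)
        assert len(out) == 1

    def test_hot_stromal_patient_drops_candidate(self):
        cancer = {"e1": counts_for_proportion(0.5)}
        stroma = {
            "p1": {"e1": counts_for_proportion(0.3)},  # CI low ~0.47 < 2 x 0.3
            "p2": {"e1": counts_for_proportion(0.0)},
        }
        out = ag.call_tumor_specific_vs_stroma([self._cand()], cancer, stroma)
        assert out == []

    def test_detection_in_tissue_reference_drops_candidate(self):
        cancer = {"e1": counts_for_proportion(0.5)}
        stroma = {"p1": {"e1": (0, 100)}}
        ref = {"sample1": {"e1": (1, 99)}}  # one supporting read: detected
        out = ag.call_tumor_specific_vs_stroma(
            [self._cand()], cancer, stroma, tissue_reference=ref
        )
        assert out == []


class TestTranslateAtypical:
    def test_fixture_peptides_match_generator_truth(
        self, fixture_exact, detected_events, models, genome
    ):
        """Peptide sets equal the generator's independent brute-force
        enumeration over both protein strings."""
        refs = fixture_exact.references
        man = fixture_exact.manifest
        by_exc = {
            tuple(ev["exclusion_junction"]): name
            for name, ev in man["events"].items()
        }
        checked = 0
        for ev in detected_events:
            name = by_exc[ev.exclusion_junction]
            truth = man["antigen_truth"].get(name)
            if not truth or "peptides" not in truth:
                continue
            peps = ag.translate_atypical(
                ev, truth["atypical_side"], models, genome, refs["proteome"]
            )
            assert peps == set(truth["peptides"]), name
            checked += 1
        assert checked >= 3

    def test_peptides_absent_from_reference_proteome(
        self, fixture_exact, detected_events, models, genome
    ):
        refs = fixture_exact.references
        man = fixture_exact.manifest
        by_exc = {
            tuple(ev["exclusion_junction"]): name
            for name, ev in man["events"].items()
        }
        for ev in detected_events:
            truth = man["antigen_truth"].get(by_exc[ev.exclusion_junction])
            if not truth or "peptides" not in truth:
                continue
            peps = ag.translate_atypical(
                ev, truth["atypical_side"], models, genome, refs["proteome"]
            )
            for pep in peps:
                assert 8 <= len(pep) <= 11
                assert not any(pep in s for s in refs["proteome"].values())

    def test_ineligible_type_rejected(self, detected_events, models, genome):
        mxe = next(e for e in detected_events if e.as_type == "MXE")
        with pytest.raises(TypeError, match="not antigen-eligible"):
            ag.translate_atypical(mxe, "inclusion", models, genome, {})


class TestMhcRanks:
    def _cand(self, peptides):
        c = ag.AntigenCandidate("e1", "inclusion", 0.5)
        c.peptides = set(peptides)
        return c

    def test_best_rank_over_alleles(self):
        table = {("PEPTIDEK", "A1"): 0.3, ("PEPTIDEK", "B1"): 1.2}
        (c,) = ag.attach_mhc_ranks([self._cand(["PEPTIDEK"])], table, ["A1", "B1"])
        assert c.best_percent_rank == 0.3 and c.strong_binder

    def test_all_weak_is_not_strong(self):
        table = {("PEPTIDEK", "A1"): 0.5}
        (c,) = ag.attach_mhc_ranks([self._cand(["PEPTIDEK"])], table, ["A1"])
        assert not c.strong_binder

    def test_empty_allele_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ag.attach_mhc_ranks([self._cand(["PEPTIDEK"])], {}, [])

    def test_missing_peptide_treated_as_nonbinder(self):
        with pytest.warns(UserWarning, match="missing"):
            (c,) = ag.attach_mhc_ranks([self._cand(["PEPTIDEK"])], {}, ["A1"])
        assert c.best_percent_rank is None and not c.strong_binder


class TestComputeAtb:
    def _strong(self, eid, prop):
        c = ag.AntigenCandidate(eid, "inclusion", prop)
        c.strong_binder = True
        return c

    def test_single_candidate_product(self):
        atb = ag.compute_atb(
            "s1", [self._strong("e1", 0.2)], {"g1": 50.0}, {"e1": "g1"}
        )
        assert atb.atb == pytest.approx(10.0)

    def test_no_strong_binders_zero(self):
        c = ag.AntigenCandidate("e1", "inclusion", 0.2)
        atb = ag.compute_atb("s1", [c], {"g1": 50.0}, {"e1": "g1"})
        assert atb.atb == 0.0

    def test_sum_and_linearity_in_cpm(self):
        cands = [self._strong(f"e{i}", 0.1 * (i + 1)) for i in range(5)]
        genes = {f"e{i}": f"g{i}" for i in range(5)}
        cpm1 = {f"g{i}": 10.0 * (i + 1) for i in range(5)}
        atb1 = ag.compute_atb("s", cands, cpm1, genes)
        expected = sum(0.1 * (i + 1) * 10.0 * (i + 1) for i in range(5))
        assert atb1.atb == pytest.approx(expected)
        cpm3 = {g: 3 * v for g, v in cpm1.items()}
        atb3 = ag.compute_atb("s", cands, cpm3, genes)
        assert atb3.atb == pytest.approx(3 * atb1.atb)
        assert atb1.atb == pytest.approx(sum(atb1.contributions.values()))
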