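"""Event grouping, classification, IR/MXE detection, coding effect, NMD."""

import itertools

import numpy as np
import pytest
from pyfaidx import Fasta

from juncsplice import annotation as ann
from juncsplice import detection as det
from juncsplice.junctions import SpliceJunction
from juncsplice.simulate import _safe_background
from tests.conftest import write_fasta


def jn(chrom, s, e, count=10, cell="c1"):
    return SpliceJunction(chrom, s, e, {cell: count})


def as_table(junctions):
    return {j.key: j for j in junctions}


class TestDetectJunctionEvents:
    def test_textbook_cassette_exon(self):
        table = as_table(
            [jn("c1", 100, 500), jn("c1", 100, 300), jn("c1", 400, 500)]
        )
        events = det.detect_junction_events(table)
        ce = [e for e in events if len(e.inclusion_junctions) == 2]
        assert len(ce) == 1
        assert ce[0].exclusion_junction == (100, 500)
        assert set(ce[0].inclusion_junctions) == {(100, 300), (400, 500)}

    def test_single_side_candidate(self):
        table = as_table([jn("c1", 100, 500), jn("c1", 100, 300)])
        events = det.detect_junction_events(table)
        assert len(events) == 1
        assert events[0].inclusion_junctions == ((100, 300),)
        assert events[0].shared_side == "start"

    def test_top_two_junctions_by_read_count(self):
        """Of four junctions sharing a splice position only the two with
        the highest read counts are kept as inclusion candidates."""
        table = as_table(
            [
                jn("c1", 100, 900, count=100),
                jn("c1", 100, 300, count=50),
                jn("c1", 100, 400, count=40),
                jn("c1", 100, 500, count=30),
                jn("c1", 100, 600, count=20),
            ]
        )
        events = det.detect_junction_events(table)
        singles = [
            e
            for e in events
            if e.exclusion_junction == (100, 900)
            and len(e.inclusion_junctions) == 1
        ]
        kept = {e.inclusion_junctions[0] for e in singles}
        assert kept == {(100, 300), (100, 400)}

    def test_detection_invariant_to_input_order(self, junction_table):
        from juncsplice.junctions import filter_min_support

        filtered = filter_min_support(junction_table, 10)
        base = {e.event_id for e in det.detect_junction_events(filtered)}
        shuffled = dict(
            sorted(filtered.items(), key=lambda kv: hash(kv[0]))
        )
        assert {e.event_id for e in det.detect_junction_events(shuffled)} == base

    def test_equals_brute_force_all_pairs_scan(self, junction_table):
        """Independent enumeration over all junction pairs reproduces the
        detected candidate set."""
        from juncsplice.junctions import filter_min_support

        filtered = filter_min_support(junction_table, 10)
        jns = list(filtered.values())
        brute = set()
        for exc in jns:
            left = [
                j
                for j in jns
                if j.chrom == exc.chrom
                and j.intron_start == exc.intron_start
                and j.intron_end < exc.intron_end
            ]
            right = [
                j
                for j in jns
                if j.chrom == exc.chrom
                and j.intron_end == exc.intron_end
                and j.intron_start > exc.intron_start
            ]
            key = lambda j: (
                -j.total_support,
                j.intron_end - j.intron_start,
                j.intron_start,
            )
            left = sorted(left, key=key)[:2]
            right = sorted(right, key=key)[:2]
            paired = set()
            for l, r in itertools.product(left, right):
                if l.intron_end + 2 <= r.intron_start:
                    brute.add(
                        (exc.key, tuple(sorted([l.key, r.key])))
                    )
                    paired |= {l.key, r.key}
            for j in left + right:
                if j.key not in paired:
                    brute.add((exc.key, (j.key,)))
        got = set()
        for e in det.detect_junction_events(filtered):
            exc = (e.chrom, *e.exclusion_junction)
            inc = tuple(sorted((e.chrom, s, x) for s, x in e.inclusion_junctions))
            got.add((exc, inc))
        assert got == brute


class TestClassification:
    def test_fixture_types_recovered_exactly(
        self, detected_events, manifest_by_exclusion
    ):
        """Recall and precision 1 for type labels on the planted fixture."""
        assert len(detected_events) == len(manifest_by_exclusion)
        for ev in detected_events:
            name, m = manifest_by_exclusion[ev.exclusion_junction]
            assert ev.as_type == m["as_type"], name
            assert ev.novelty == m["novelty"], name
            if m["gene_id"] is not None:
                assert ev.gene_id == m["gene_id"], name

    def test_afe_proximal_junction_is_inclusion(self, detected_events):
        for ev in detected_events:
            if ev.as_type in ("AFE", "ALE"):
                assert ev.proximal_is_inclusion
                (inc,) = ev.inclusion_junctions
                inc_len = inc[1] - inc[0]
                exc_len = ev.exclusion_junction[1] - ev.exclusion_junction[0]
                assert inc_len < exc_len

    def test_unlinked_candidate_classified_un(self, index):
        cand = det.ASEvent(
            chrom="chrS",
            exclusion_junction=(95_000, 95_999),
            inclusion_junctions=((95_000, 95_499),),
            shared_side="start",
        )
        out = det.classify_event(cand, index)
        assert out.as_type == "UN" and out.novelty == "novel"


class TestBlacklist:
    def _event(self, novelty):
        return det.ASEvent(
            chrom="c1",
            exclusion_junction=(1000, 2000),
            inclusion_junctions=((1000, 1500),),
            as_type="UN",
            novelty=novelty,
        )

    def test_novel_event_in_ig_region_removed(self):
        models = [
            ann.TranscriptModel(
                "t",
                "ig1",
                "IGHV1-2",
                "+",
                [ann.GenomicInterval("c1", 500, 2500, "+")],
            )
        ]
        bl = det.build_blacklist(models)
        assert det.apply_region_blacklist([self._event("novel")], bl) == []

    def test_known_event_in_blacklist_region_retained(self):
        bl = [ann.GenomicInterval("c1", 500, 2500)]
        kept = det.apply_region_blacklist([self._event("known")], bl)
        assert len(kept) == 1

    def test_empty_blacklist_is_identity(self):
        evs = [self._event("novel")]
        assert det.apply_region_blacklist(evs, []) == evs


class TestAnnotatedIRMXE:
    def test_fixture_ir_recovered_exactly(self, models, fixture_exact):
        ir = det.detect_annotated_ir(models)
        planted = [
            ev
            for ev in fixture_exact.manifest["events"].values()
            if ev["as_type"] == "IR"
        ]
        assert {e.exclusion_junction for e in ir} == {
            tuple(p["exclusion_junction"]) for p in planted
        }
        for e in ir:
            assert e.novelty == "known"

    def test_gene_without_retention_isoform_yields_no_ir(self):
        exons = [
            ann.GenomicInterval("c1", 1, 100, "+"),
            ann.GenomicInterval("c1", 201, 300, "+"),
        ]
        m = ann.TranscriptModel("t", "g", "g", "+", exons)
        assert det.detect_annotated_ir([m]) == []

    def test_fixture_mxe_recovered(self, models, fixture_exact):
        mxe = det.detect_annotated_mxe(models)
        planted = [
            ev
            for ev in fixture_exact.manifest["events"].values()
            if ev["as_type"] == "MXE"
        ]
        assert len(mxe) == len(planted) == 1
        (e,), (p,) = mxe, planted
        assert e.exclusion_junction == tuple(p["exclusion_junction"])
        # inclusion exon is the 5'-most alternative exon
        assert (e.mxe_exons[0].start, e.mxe_exons[0].end) == tuple(p["mxe_exons"][0])

    def test_co_occurring_middle_exons_are_not_mxe(self):
        ivs = {
            "U": (1, 100),
            "X": (201, 300),
            "Y": (401, 500),
            "D": (601, 700),
        }

        def tx(tid, names):
            return ann.TranscriptModel(
                tid,
                "g",
                "g",
                "+",
                [ann.GenomicInterval("c1", *ivs[n], "+") for n in names],
            )

        both = [tx("t1", ["U", "X", "Y", "D"]), tx("t2", ["U", "X", "D"])]
        assert det.detect_annotated_mxe(both) == []


class TestCodingEffect:
    def test_fixture_effects_match_manifest(
        self, detected_events, manifest_by_exclusion, models, genome
    ):
        for ev in detected_events:
            name, m = manifest_by_exclusion[ev.exclusion_junction]
            got = (
                det.classify_coding_effect(ev, models, genome)
                if ev.gene_id
                else "unknown"
            )
            assert got == m["coding_effect"], name


def _nmd_case(tmp_path, name, stop_distance=None, stop_in_last_exon=False, with_cds=True):
    """Hand-constructed frameshifting cassette gene.

    Exons A(1-300), B(501-591, 91 nt cassette), C(791-1090), D(1291-1590).
    The exclusion isoform [A, C, D] has its last exon-exon junction at
    transcript position 600. A stop codon is planted so that exactly
    ``stop_distance`` nt separate its last base from that junction (or
    inside exon D when ``stop_in_last_exon``).
    """
    rng = np.random.default_rng(42)
    seq = _safe_background(1700, rng)
    # no stop codon may straddle a spliced junction: exon edges -> C
    for a, b in [(1, 300), (501, 591), (791, 1090), (1291, 1590)]:
        seq[a - 1 : a + 1] = ["C", "C"]
        seq[b - 2 : b] = ["C", "C"]
    if stop_in_last_exon:
        q_end = 651  # transcript position of stop codon's last base
        gpos = 1291 + (q_end - 2 - 601)  # genomic of codon start, 1-based
    else:
        q_end = 600 - stop_distance
        gpos = 791 + (q_end - 2 - 301)
    s0 = next(s for s in (49, 50, 51) if (q_end - 2 - s) % 3 == 0)
    if with_cds:
        seq[s0 - 1 : s0 + 2] = list("ATG")
        seq[gpos - 1 : gpos + 2] = list("TAA")
        c_end = next(c for c in (889, 890, 891) if (c - s0 - 398) % 3 == 0)
        seq[c_end - 3 : c_end] = list("TAA")
        cds = [
            ann.GenomicInterval("cN", s0, 300, "+"),
            ann.GenomicInterval("cN", 501, 591, "+"),
            ann.GenomicInterval("cN", 791, c_end, "+"),
        ]
    else:
        cds = None
    fa = write_fasta(tmp_path / f"{name}.fa", {"cN": "".join(seq)})
    exons = [
        ann.GenomicInterval("cN", 1, 300, "+"),
        ann.GenomicInterval("cN", 501, 591, "+"),
        ann.GenomicInterval("cN", 791, 1090, "+"),
        ann.GenomicInterval("cN", 1291, 1590, "+"),
    ]
    model = ann.TranscriptModel("tx", "g", "g", "+", exons, cds=cds)
    event = det.ASEvent(
        chrom="cN",
        exclusion_junction=(301, 790),
        inclusion_junctions=((301, 500), (592, 790)),
        as_type="CE",
        gene_id="g",
        strand="+",
    )
    return event, [model], Fasta(str(fa))


class TestNMDFiftyNtRule:
    """Decisions on hand-constructed transcripts with known stop
    placements relative to the last exon-exon junction."""

    @pytest.mark.parametrize(
        "name,kwargs,expected",
        [
            ("far_upstream", dict(stop_distance=277), True),
            ("fifty_one_nt", dict(stop_distance=51), True),
            ("exactly_fifty_nt", dict(stop_distance=50), False),
            ("thirty_nt", dict(stop_distance=30), False),
            ("stop_in_last_exon", dict(stop_in_last_exon=True), False),
            ("no_cds_transcript", dict(stop_distance=100, with_cds=False), None),
        ],
    )
    def test_rule_decisions(self, tmp_path, name, kwargs, expected):
        event, models, genome = _nmd_case(tmp_path, name, **kwargs)
        assert det.predict_nmd(event, models, genome) is expected

    def test_fixture_nmd_matches_manifest(
        self, detected_events, manifest_by_exclusion, models, genome
    ):
        for ev in detected_events:
            name, m = manifest_by_exclusion[ev.exclusion_junction]
            got = det.predict_nmd(ev, models, genome) if ev.gene_id else None
            assert got is m["nmd"] or got == m["nmd"], name
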