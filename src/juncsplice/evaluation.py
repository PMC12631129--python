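"""Run the full method on a synthetic fixture and measure recovery.

Convenience layer used by the acceptance checks: executes detection,
classification, quantification and the antigen chain on a generated
fixture and compares the results with the fixture's planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam
from pyfaidx import Fasta

from juncsplice import annotation as ann
from juncsplice import antigen as ag
from juncsplice import detection as det
from juncsplice import junctions as jx
from juncsplice import quantify as qt
from juncsplice.pipeline import detect_events
from juncsplice.simulate import Fixture


@dataclass
class FixtureAnalysis:
    fixture: Fixture
    models: list
    index: object
    genome: Fasta
    junctions: dict
    spans: dict
    events: list
    name_by_exclusion: dict  # planted-event name keyed by exclusion junction

    def event_name(self, ev) -> str | None:
        return self.name_by_exclusion.get(ev.exclusion_junction)


def analyze_fixture(fx: Fixture, min_reads: int = 10) -> FixtureAnalysis:
    """Extract junctions and detect/classify events on a fixture."""
    models = ann.load_annotation(fx.gtf)
    index = ann.build_boundary_index(models)
    with pysam.AlignmentFile(str(fx.bam)) as bam:
        junctions = jx.extract_junctions(bam)
    ir = det.detect_annotated_ir(models)
    sites = {s for ev in ir for s in ev.ir_boundary_sites}
    with pysam.AlignmentFile(str(fx.bam)) as bam:
        spans = jx.count_boundary_spans(bam, sites)
    filtered = jx.filter_min_support(junctions, min_reads)
    events = detect_events(models, index, filtered, spans)
    name_by_exclusion = {
        tuple(ev["exclusion_junction"]): name
        for name, ev in fx.manifest["events"].items()
    }
    return FixtureAnalysis(
        fixture=fx,
        models=models,
        index=index,
        genome=Fasta(str(fx.genome_fa)),
        junctions=junctions,
        spans=spans,
        events=events,
        name_by_exclusion=name_by_exclusion,
    )


def recovery_metrics(fa: FixtureAnalysis) -> dict:
    """Type recall/precision and exactness of per-cell counts against
    the planted manifest."""
    man = fa.fixture.manifest
    n_planted = len(man["events"])
    tp = fp = 0
    count_rows = count_matches = 0
    for ev in fa.events:
        name = fa.event_name(ev)
        if name is None:
            fp += 1
            continue
        if ev.as_type == man["events"][name]["as_type"]:
            tp += 1
        got = qt.count_event(ev, fa.junctions, fa.spans)
        for cell, (I, E) in man["counts"][name].items():
            if I + E == 0:
                continue
            count_rows += 1
            count_matches += got.get(cell, (0, 0)) == (I, E)
    return {
        "n_planted": n_planted,
        "n_detected": len(fa.events),
        "type_recall": tp / n_planted,
        "type_precision": tp / len(fa.events) if fa.events else 0.0,
        "n_false_positive": fp,
        "count_rows_checked": count_rows,
        "count_exact_fraction": count_matches / count_rows if count_rows else 0.0,
    }


def grouped_counts(fa: FixtureAnalysis):
    """(cancer pooled, stroma per sample) (I, E) maps keyed by event_id."""
    cells = {c["barcode"]: c for c in fa.fixture.manifest["cells"]}
    table = qt.build_count_table(fa.events, fa.junctions, fa.spans)
    cancer: dict[str, tuple[int, int]] = {}
    stroma: dict[str, dict[str, tuple[int, int]]] = {}
    for r in table.df.itertuples(index=False):
        c = cells[r.unit]
        if c["cell_type"] == "cancer":
            I, E = cancer.get(r.event_id, (0, 0))
            cancer[r.event_id] = (I + r.I, E + r.E)
        else:
            d = stroma.setdefault(c["sample"], {})
            I, E = d.get(r.event_id, (0, 0))
            d[r.event_id] = (I + r.I, E + r.E)
    return cancer, stroma


def run_antigen_chain(fa: FixtureAnalysis):
    """Antigen pipeline on the fixture; returns (candidates keyed by
    planted-event name, ATBResult)."""
    refs = fa.fixture.references
    cancer, stroma = grouped_counts(fa)
    ev_by_id = {e.event_id: e for e in fa.events}
    name_of = {
        eid: fa.event_name(ev) for eid, ev in ev_by_id.items()
    }

    def remap(tables):
        return {
            key: {
                eid: tables[key].get(name_of[eid], (0, 0)) for eid in ev_by_id
            }
            for key in tables
        }

    gene_cpm = ag.cpm(fa.fixture.manifest["gene_counts"]["cancer"])
    cands, atb = ag.antigen_pipeline(
        ev_by_id,
        cancer,
        remap(refs["normals"]),
        stroma,
        fa.models,
        fa.genome,
        refs["proteome"],
        refs["rank_table"],
        refs["alleles"],
        gene_cpm,
        tissue_reference=remap(refs["tissue_reference"]),
    )
    return {name_of[c.event_id]: c for c in cands}, atb


def analytic_atb(fx: Fixture) -> float:
    """Manifest-side ATB: sum of planted cancer proportion x CPM over
    designated strong-binder candidates (computed from planted numbers
    only, independent of the detection path)."""
    man = fx.manifest
    gene_cpm = ag.cpm(man["gene_counts"]["cancer"])
    total = 0.0
    for name, truth in man["antigen_truth"].items():
        if "strong_peptide" not in truth:
            continue
        ev = man["events"][name]
        psi = ev["psi"]["cancer"]
        prop = psi if ev["atypical_side"] == "inclusion" else 1 - psi
        total += prop * gene_cpm[ev["gene_id"]]
    return total
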