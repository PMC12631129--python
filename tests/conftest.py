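"""Shared fixtures: the synthetic dataset is generated once per session."""

from __future__ import annotations

import pysam
import pytest
from pyfaidx import Fasta

from juncsplice import annotation as ann
from juncsplice import detection as det
from juncsplice import junctions as jx
from juncsplice.pipeline import detect_events
from juncsplice.simulate import generate_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture_exact(tmp_path_factory):
    """Exact-mode fixture: 200 cells (100 cancer, 100 stromal),
    10 molecules per cell per event, deterministic counts."""
    out = tmp_path_factory.mktemp("fixture_exact")
    return generate_fixture(out, seed=FIXTURE_SEED, mode="exact")


@pytest.fixture(scope="session")
def models(fixture_exact):
    return ann.load_annotation(fixture_exact.gtf)


@pytest.fixture(scope="session")
def index(models):
    return ann.build_boundary_index(models)


@pytest.fixture(scope="session")
def genome(fixture_exact):
    return Fasta(str(fixture_exact.genome_fa))


@pytest.fixture(scope="session")
def junction_table(fixture_exact):
    with pysam.AlignmentFile(str(fixture_exact.bam)) as bam:
        return jx.extract_junctions(bam)


@pytest.fixture(scope="session")
def span_table(fixture_exact, models):
    ir = det.detect_annotated_ir(models)
    sites = {s for ev in ir for s in ev.ir_boundary_sites}
    with pysam.AlignmentFile(str(fixture_exact.bam)) as bam:
        return jx.count_boundary_spans(bam, sites)


@pytest.fixture(scope="session")
def detected_events(models, index, junction_table, span_table):
    filtered = jx.filter_min_support(junction_table, 10)
    return detect_events(models, index, filtered, span_table)


@pytest.fixture(scope="session")
def manifest_by_exclusion(fixture_exact):
    """Planted events keyed by their exclusion-junction coordinates."""
    return {
        tuple(ev["exclusion_junction"]): (name, ev)
        for name, ev in fixture_exact.manifest["events"].items()
    }


def write_fasta(path, sequences: dict[str, str]):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
    return path
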