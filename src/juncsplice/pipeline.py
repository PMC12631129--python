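"""Stage orchestration: annotate -> junctions -> detect -> quantify.

``run_pipeline`` executes the detection/quantification stages on a
BAM + GTF + FASTA triple with one flat configuration, writing each
stage's table with a content hash so that reruns with the same config
are verifiable byte-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam
from pyfaidx import Fasta

from juncsplice import annotation as ann
from juncsplice import detection as det
from juncsplice import junctions as jx
from juncsplice import quantify as qt


@dataclass
class RunConfig:
    """Flat run configuration; defaults are the method's published
    operating points (read floors 10/5, FDR 0.01, |dPSI| 0.2,
    normal/stroma folds 10, 4, 5, 2, strong-binder %rank 0.5)."""

    bam: str = ""
    gtf: str = ""
    fasta: str = ""
    assembled_gtf: str | None = None
    out_dir: str = "run"
    mode: str = "single_cell"
    cb_tag: str = "CB"
    umi_tag: str = "UB"
    min_junction_reads: int = 10
    min_event_reads: int = 5
    fdr_cut: float = 0.01
    dpsi_cut: float = 0.2
    fold_mean_normal: float = 10.0
    fold_max_normal: float = 4.0
    fold_mean_stroma: float = 5.0
    fold_ci_stroma: float = 2.0
    strong_rank_cut: float = 0.5
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def validate(self) -> None:
        for name in ("bam", "gtf", "fasta"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: missing input {p!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, log: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    log[path.name] = _sha256(path)


def detect_events(models, index, junctions, spans=None):
    """Junction-defined events classified and deduplicated against
    annotation-defined MXE, plus annotated IR and MXE events."""
    candidates = det.detect_junction_events(junctions)
    classified = [det.classify_event(c, index) for c in candidates]
    blacklist = det.build_blacklist(models)
    classified = det.apply_region_blacklist(classified, blacklist)
    mxe = det.detect_annotated_mxe(models)
    classified = det.dedupe_against_mxe(classified, mxe, models)
    ir = det.detect_annotated_ir(models)
    return classified + ir + mxe


def events_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "as_type": ev.as_type,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "exclusion_start": ev.exclusion_junction[0],
                "exclusion_end": ev.exclusion_junction[1],
                "inclusion_junctions": ";".join(
                    f"{s}-{e}" for s, e in ev.inclusion_junctions
                ),
                "novelty": ev.novelty,
                "coding_effect": ev.coding_effect,
                "nmd_predicted": ev.nmd_predicted,
            }
        )
    return pd.DataFrame(rows).sort_values("event_id").reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run annotate/junctions/detect/quantify; returns a provenance log
    of stage output hashes and kept/dropped counts."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"hashes": {}, "stages": {}}

    models = ann.load_annotation(config.gtf, ann.PRIMARY)
    if config.assembled_gtf:
        models += ann.load_annotation(config.assembled_gtf, ann.ASSEMBLED)
    index = ann.build_boundary_index(models)
    log["stages"]["annotate"] = {"n_transcripts": len(models)}

    with pysam.AlignmentFile(config.bam) as bam:
        junctions = jx.extract_junctions(
            bam, config.cb_tag, config.umi_tag, config.mode
        )
    filtered = jx.filter_min_support(junctions, config.min_junction_reads)
    log["stages"]["junctions"] = {
        "n_junctions": len(junctions),
        "n_pass_filter": len(filtered),
    }
    _write(
        pd.DataFrame(jx.junctions_to_rows(filtered)),
        out / "junctions.tsv",
        log["hashes"],
    )

    ir_events = det.detect_annotated_ir(models)
    sites = {s for ev in ir_events for s in ev.ir_boundary_sites}
    with pysam.AlignmentFile(config.bam) as bam:
        spans = jx.count_boundary_spans(
            bam, sites, config.cb_tag, config.umi_tag, config.mode
        )

    events = detect_events(models, index, filtered, spans)
    genome = Fasta(config.fasta)
    for ev in events:
        if ev.gene_id is not None:
            ev.coding_effect = det.classify_coding_effect(ev, models, genome)
            ev.nmd_predicted = det.predict_nmd(ev, models, genome)
    log["stages"]["detect"] = {
        "n_events": len(events),
        "by_type": dict(
            pd.Series([e.as_type for e in events]).value_counts().items()
        ),
    }
    _write(events_frame(events), out / "events.tsv", log["hashes"])

    table = qt.build_count_table(events, filtered, spans)
    _write(table.df, out / "counts.tsv", log["hashes"])
    psi = qt.psi_table(table)
    _write(psi, out / "psi.tsv", log["hashes"])
    log["stages"]["quantify"] = {"n_rows": len(table)}

    (out / "provenance.json").write_text(json.dumps(log, indent=1, default=str))
    return log
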