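"""Transcript-model parsing and exon-boundary indexing.

Loads GTF annotation (Ensembl dialect) into :class:`TranscriptModel`
objects and builds the :class:`BoundaryIndex` that the detection layer
uses to align observed junctions to annotated exon boundaries.

Coordinate convention: every coordinate in this package is 1-based and
inclusive (the GTF convention). Alignment files use 0-based half-open
coordinates; those are converted once, at the read boundary in
:mod:`juncsplice.junctions`, and nowhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

PRIMARY = "primary_annotation"
ASSEMBLED = "assembled_annotation"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


class FrameIncompleteError(ValueError):
    """Raised when a CDS cannot be translated (bad length or start)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class TranscriptModel:
    """One transcript: exons in transcription (5'->3') order, optional CDS.

    ``frame_incomplete`` marks transcripts whose concatenated CDS length
    is not a positive multiple of 3; they are kept for junction
    classification but excluded from translation-dependent operations.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] | None = None
    source: str = PRIMARY
    frame_incomplete: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        # normalise to transcription order
        rev = self.strand == "-"
        self.exons = sorted(self.exons, key=lambda e: e.start, reverse=rev)
        for a, b in zip(self.exons, self.exons[1:]):
            left, right = (b, a) if rev else (a, b)
            if right.start <= left.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
        if self.cds is not None:
            self.cds = sorted(self.cds, key=lambda c: c.start, reverse=rev)
            for c in self.cds:
                if not any(e.contains(c) for e in self.exons):
                    raise AnnotationError(
                        f"transcript {self.transcript_id}: CDS {c} outside exons"
                    )
            if self.cds_length % 3 != 0 or self.cds_length == 0:
                self.frame_incomplete = True

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds) if self.cds else 0

    @property
    def introns(self) -> list[GenomicInterval]:
        """Introns in transcription order, as 1-based inclusive intervals."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            left, right = (b, a) if self.strand == "-" else (a, b)
            out.append(
                GenomicInterval(a.chrom, left.end + 1, right.start - 1, self.strand)
            )
        return out

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def last_exon(self) -> GenomicInterval:
        return self.exons[-1]


@dataclass
class BoundaryIndex:
    """Splice-site and intron indices over a set of transcript models.

    Sites are keyed ``(chrom, strand, pos)``. A donor is the last exonic
    base before an intron in transcript orientation; an acceptor is the
    first exonic base after an intron. First/last-exon indices are keyed
    by the splice-adjacent boundary base of the terminal exon.
    """

    donor_sites: set[tuple[str, str, int]] = field(default_factory=set)
    acceptor_sites: set[tuple[str, str, int]] = field(default_factory=set)
    first_exon_index: dict[tuple[str, str, int], set[str]] = field(
        default_factory=dict
    )
    last_exon_index: dict[tuple[str, str, int], set[str]] = field(default_factory=dict)
    intron_index: dict[tuple[str, int, int], set[str]] = field(default_factory=dict)
    site_genes: dict[tuple[str, int], set[str]] = field(default_factory=dict)
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def genes_for_intron(self, chrom: str, start: int, end: int) -> set[str]:
        txs = self.intron_index.get((chrom, start, end), set())
        return {self.transcripts[t].gene_id for t in txs}

    def gene_strand(self, gene_id: str) -> str:
        for tx in self.transcripts.values():
            if tx.gene_id == gene_id:
                return tx.strand
        raise KeyError(gene_id)

    def transcripts_of_gene(self, gene_id: str) -> list[TranscriptModel]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]


def load_annotation(gtf_path, source_label: str = PRIMARY) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    Uses an in-memory gffutils database; exon and CDS features are
    grouped by ``transcript_id``. Transcripts with zero exons are
    excluded with a warning. GTF coordinates are preserved unchanged.
    """
    if source_label not in (PRIMARY, ASSEMBLED):
        raise ValueError(f"unknown source label {source_label!r}")
    try:
        db = gffutils.create_db(
            str(gtf_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps line info in the message
        raise AnnotationError(f"malformed GTF {gtf_path}: {exc}") from exc

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{gtf_path}: {feat.featuretype} feature at "
                f"{feat.seqid}:{feat.start} missing {exc}"
            ) from exc
        gname = feat.attributes.get("gene_name", [gid])[0]
        meta.setdefault(tid, (gid, gname, feat.strand))
        iv = GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    models = []
    for tid, (gid, gname, strand) in meta.items():
        if tid not in exons:
            warnings.warn(f"transcript {tid} has zero exons; excluded")
            continue
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                gene_name=gname,
                strand=strand,
                exons=exons[tid],
                cds=cds.get(tid),
                source=source_label,
            )
        )
    return models


def build_boundary_index(models: Iterable[TranscriptModel]) -> BoundaryIndex:
    """Index donor/acceptor sites, terminal-exon boundaries and introns."""
    models = list(models)
    if not models:
        raise ValueError("no transcript models given")
    idx = BoundaryIndex()
    for tx in models:
        idx.transcripts[tx.transcript_id] = tx
        chrom, strand = tx.exons[0].chrom, tx.strand
        for intron in tx.introns:
            key = (chrom, intron.start, intron.end)
            idx.intron_index.setdefault(key, set()).add(tx.transcript_id)
            if strand == "+":
                donor_pos, acceptor_pos = intron.start - 1, intron.end + 1
            else:
                donor_pos, acceptor_pos = intron.end + 1, intron.start - 1
            idx.donor_sites.add((chrom, strand, donor_pos))
            idx.acceptor_sites.add((chrom, strand, acceptor_pos))
            for pos in (intron.start - 1, intron.end + 1):
                idx.site_genes.setdefault((chrom, pos), set()).add(tx.gene_id)
        if len(tx.exons) > 1:
            first, last = tx.first_exon, tx.last_exon
            fpos = first.end if strand == "+" else first.start
            lpos = last.start if strand == "+" else last.end
            idx.first_exon_index.setdefault((chrom, strand, fpos), set()).add(
                tx.transcript_id
            )
            idx.last_exon_index.setdefault((chrom, strand, lpos), set()).add(
                tx.transcript_id
            )
    return idx


def fetch_sequence(genome: Fasta, chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of the genome, forward strand."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} absent from genome")
    return str(genome[chrom][start - 1 : end]).upper()


def extract_coding_sequence(model: TranscriptModel, genome: Fasta) -> str:
    """Spliced CDS in transcript orientation.

    Raises :class:`FrameIncompleteError` if the model is flagged
    frame-incomplete or the assembled CDS does not start with ATG.
    """
    if model.cds is None:
        raise ValueError(f"transcript {model.transcript_id} has no CDS")
    if model.frame_incomplete:
        raise FrameIncompleteError(
            f"transcript {model.transcript_id}: CDS length {model.cds_length} "
            "is not a positive multiple of 3"
        )
    parts = []
    for c in model.cds:  # already in transcription order
        s = fetch_sequence(genome, c.chrom, c.start, c.end)
        parts.append(reverse_complement(s) if model.strand == "-" else s)
    seq = "".join(parts)
    if not seq.startswith("ATG"):
        raise FrameIncompleteError(
            f"transcript {model.transcript_id}: CDS does not start with ATG"
        )
    return seq


def spliced_sequence(
    exons: Iterable[GenomicInterval], strand: str, genome: Fasta
) -> str:
    """Spliced transcript sequence for an exon chain in transcription order."""
    parts = []
    for e in exons:
        s = fetch_sequence(genome, e.chrom, e.start, e.end)
        parts.append(reverse_complement(s) if strand == "-" else s)
    return "".join(parts)


def serialize_gtf(models: Iterable[TranscriptModel], path) -> None:
    """Write models back to GTF (exon + CDS features, genomic order)."""
    with open(path, "w") as fh:
        for tx in models:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_name}";'
            )
            feats = [("exon", e) for e in tx.exons]
            if tx.cds:
                feats += [("CDS", c) for c in tx.cds]
            for ftype, iv in sorted(feats, key=lambda t: (t[1].start, t[0])):
                fh.write(
                    f"{iv.chrom}\tjuncsplice\t{ftype}\t{iv.start}\t{iv.end}\t.\t"
                    f"{tx.strand}\t.\t{attrs}\n"
                )
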