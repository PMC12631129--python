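"""ASE detection and classification from filtered junctions.

An alternative splicing event (ASE) binds an *exclusion* junction to
inclusion evidence: two nested junctions for a cassette exon (CE), one
junction sharing a single splice position for A5SS/A3SS/AFE/ALE/UN, a
pair of exon-intron boundary sites for intron retention (IR), or the
diagnostic junction pair of a mutually-exclusive-exon (MXE) choice.

Junction-defined events (CE and single-side types) are discovered
purely from the junction table; IR and MXE are only taken from
annotation because junction reads alone cannot delimit them reliably.

Classification rules (types named in transcript orientation):
- two-side sharing -> CE;
- one-side sharing where both alternative positions are annotated
  donors -> A5SS, acceptors -> A3SS, first-exon boundaries -> AFE,
  last-exon boundaries -> ALE;
- no transcript linkage (or two conflicting genes) -> UN.

The inclusion isoform of a single-side event is the junction with the
shorter intron (more retained exonic sequence); for AFE/ALE this makes
the proximal alternative exon the inclusion side, the distal one the
exclusion side.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from juncsplice.annotation import (
    BoundaryIndex,
    GenomicInterval,
    TranscriptModel,
    spliced_sequence,
)
from juncsplice.junctions import SpliceJunction

AS_TYPES = ("CE", "AFE", "ALE", "A5SS", "A3SS", "MXE", "IR", "UN")

STOP_CODONS = {"TAA", "TAG", "TGA"}
NMD_RULE_NT = 50

BLACKLIST_PATTERNS = {
    "IG": r"^IG[HKL]",
    "TCR": r"^TR[ABGD]",
    "HLA": r"^HLA-",
}


@dataclass
class ASEvent:
    """A classified alternative splicing event."""

    chrom: str
    exclusion_junction: tuple[int, int]
    inclusion_junctions: tuple[tuple[int, int], ...]
    as_type: str | None = None
    gene_id: str | None = None
    gene_name: str | None = None
    strand: str | None = None
    novelty: str | None = None  # known | novel
    coding_effect: str | None = None
    nmd_predicted: bool | None = None
    proximal_is_inclusion: bool | None = None
    shared_side: str | None = None  # start | end (single-side events)
    ir_boundary_sites: tuple[tuple[str, int], tuple[str, int]] | None = None
    mxe_exons: tuple[GenomicInterval, GenomicInterval] | None = None
    ambiguous: bool = False

    @property
    def event_id(self) -> str:
        """Deterministic key from coordinates and type."""
        exc = f"{self.exclusion_junction[0]}-{self.exclusion_junction[1]}"
        inc = ";".join(f"{s}-{e}" for s, e in sorted(self.inclusion_junctions))
        return f"{self.chrom}:{exc}|{inc}|{self.as_type or 'candidate'}"

    def differing_regions(self) -> list[GenomicInterval]:
        """Genomic region(s) exonic in one isoform and intronic in the other."""
        xs, xe = self.exclusion_junction
        if self.as_type == "CE":
            (l, r) = sorted(self.inclusion_junctions)
            return [GenomicInterval(self.chrom, l[1] + 1, r[0] - 1)]
        if self.as_type == "IR":
            return [GenomicInterval(self.chrom, xs, xe)]
        if self.as_type == "MXE":
            return [self.mxe_exons[0], self.mxe_exons[1]]
        # single-side events
        (inc,) = self.inclusion_junctions
        if self.shared_side == "start":
            return [GenomicInterval(self.chrom, inc[1] + 1, xe)]
        return [GenomicInterval(self.chrom, xs, inc[0] - 1)]


def _top_two(cands: list[SpliceJunction]) -> list[SpliceJunction]:
    """Top two junctions by support; ties: shorter intron, then leftmost."""
    return sorted(
        cands,
        key=lambda j: (
            -j.total_support,
            j.intron_end - j.intron_start,
            j.intron_start,
        ),
    )[:2]


def detect_junction_events(
    junctions: Mapping[tuple[str, int, int], SpliceJunction],
) -> list[ASEvent]:
    """Group filtered junctions into candidate (untyped) events.

    For every junction treated as the exclusion junction, inclusion
    candidates are junctions sharing intron_start or intron_end and
    nested strictly inside its intron. When more than two share one
    splice position only the top two by read count are kept. A
    compatible left+right pair forms a CE candidate (the exon between
    them being the cassette); junctions participating in no CE pair
    yield single-side candidates.
    """
    by_start: dict[tuple[str, int], list[SpliceJunction]] = {}
    by_end: dict[tuple[str, int], list[SpliceJunction]] = {}
    for jn in junctions.values():
        by_start.setdefault((jn.chrom, jn.intron_start), []).append(jn)
        by_end.setdefault((jn.chrom, jn.intron_end), []).append(jn)

    events: dict[str, ASEvent] = {}
    for exc in junctions.values():
        left = _top_two(
            [
                j
                for j in by_start.get((exc.chrom, exc.intron_start), ())
                if j.intron_end < exc.intron_end
            ]
        )
        right = _top_two(
            [
                j
                for j in by_end.get((exc.chrom, exc.intron_end), ())
                if j.intron_start > exc.intron_start
            ]
        )
        in_pair: set[tuple[str, int, int]] = set()
        for l in left:
            for r in right:
                if l.intron_end + 2 <= r.intron_start:  # >=1 exonic base between
                    ev = ASEvent(
                        chrom=exc.chrom,
                        exclusion_junction=(exc.intron_start, exc.intron_end),
                        inclusion_junctions=(
                            (l.intron_start, l.intron_end),
                            (r.intron_start, r.intron_end),
                        ),
                        shared_side=None,
                    )
                    events.setdefault(ev.event_id, ev)
                    in_pair.add(l.key)
                    in_pair.add(r.key)
        for side, cands in (("start", left), ("end", right)):
            for j in cands:
                if j.key in in_pair:
                    continue
                ev = ASEvent(
                    chrom=exc.chrom,
                    exclusion_junction=(exc.intron_start, exc.intron_end),
                    inclusion_junctions=((j.intron_start, j.intron_end),),
                    shared_side=side,
                )
                events.setdefault(ev.event_id, ev)
    return list(events.values())


def _linked_genes(ev: ASEvent, index: BoundaryIndex) -> set[str]:
    genes: set[str] = set()
    for s, e in (ev.exclusion_junction, *ev.inclusion_junctions):
        genes |= index.genes_for_intron(ev.chrom, s, e)
        for pos in (s - 1, e + 1):
            genes |= index.site_genes.get((ev.chrom, pos), set())
    return genes


def classify_event(candidate: ASEvent, index: BoundaryIndex) -> ASEvent:
    """Assign AS type, gene, strand and novelty to a candidate event.

    Candidates linking two different genes, or no gene at all, are
    classified UN (the former with an ambiguity flag).
    """
    ev = candidate
    genes = _linked_genes(ev, index)
    if len(genes) != 1:
        ev.as_type = "UN"
        ev.novelty = "novel"
        ev.ambiguous = len(genes) > 1
        return ev
    gene = genes.pop()
    ev.gene_id = gene
    ev.strand = index.gene_strand(gene)
    ev.gene_name = next(
        t.gene_name for t in index.transcripts.values() if t.gene_id == gene
    )

    all_jns = (ev.exclusion_junction, *ev.inclusion_junctions)
    ev.novelty = (
        "known"
        if all((ev.chrom, s, e) in index.intron_index for s, e in all_jns)
        else "novel"
    )

    if len(ev.inclusion_junctions) == 2:
        ev.as_type = "CE"
        return ev

    (inc,) = ev.inclusion_junctions
    xs, xe = ev.exclusion_junction
    if ev.shared_side == "start":
        alt_positions = (inc[1] + 1, xe + 1)  # exonic base right of each intron
    else:
        alt_positions = (inc[0] - 1, xs - 1)
    keys = [(ev.chrom, ev.strand, p) for p in alt_positions]

    if all(k in index.first_exon_index for k in keys):
        ev.as_type = "AFE"
    elif all(k in index.last_exon_index for k in keys):
        ev.as_type = "ALE"
    elif all(k in index.donor_sites for k in keys):
        ev.as_type = "A5SS"
    elif all(k in index.acceptor_sites for k in keys):
        ev.as_type = "A3SS"
    else:
        ev.as_type = "UN"
        return ev
    if ev.as_type in ("AFE", "ALE"):
        # inclusion is the nested (shorter-intron) junction = proximal exon
        ev.proximal_is_inclusion = True
    return ev


def build_blacklist(
    models: Iterable[TranscriptModel],
    patterns: Mapping[str, str] = BLACKLIST_PATTERNS,
) -> list[GenomicInterval]:
    """Resolve IG/TCR/HLA gene-name patterns to genomic intervals."""
    compiled = [re.compile(p) for p in patterns.values()]
    spans: dict[str, GenomicInterval] = {}
    for tx in models:
        if not any(p.match(tx.gene_name) for p in compiled):
            continue
        lo = min(e.start for e in tx.exons)
        hi = max(e.end for e in tx.exons)
        chrom = tx.exons[0].chrom
        prev = spans.get(tx.gene_id)
        if prev is not None:
            lo, hi = min(lo, prev.start), max(hi, prev.end)
        spans[tx.gene_id] = GenomicInterval(chrom, lo, hi)
    return list(spans.values())


def apply_region_blacklist(
    events: Iterable[ASEvent], blacklist: Sequence[GenomicInterval]
) -> list[ASEvent]:
    """Drop *novel* events overlapping IG/TCR/HLA regions; keep known ones."""
    out = []
    for ev in events:
        if ev.novelty == "novel":
            xs, xe = ev.exclusion_junction
            span = GenomicInterval(
                ev.chrom,
                min(xs, *(s for s, _ in ev.inclusion_junctions)),
                max(xe, *(e for _, e in ev.inclusion_junctions)),
            )
            if any(span.overlaps(b) for b in blacklist):
                continue
        out.append(ev)
    return out


def detect_annotated_ir(
    models: Iterable[TranscriptModel], junctions=None, spans=None
) -> list[ASEvent]:
    """IR events: an intron of one transcript fully exonic in another
    transcript of the same gene. Inclusion evidence is the pair of
    exon-intron boundary sites; exclusion is the intron's junction."""
    models = list(models)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in models:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    events: dict[str, ASEvent] = {}
    for gene, txs in by_gene.items():
        for tx in txs:
            for intron in tx.introns:
                retained = any(
                    other is not tx
                    and any(e.contains(intron) for e in other.exons)
                    for other in txs
                )
                if not retained:
                    continue
                ev = ASEvent(
                    chrom=intron.chrom,
                    exclusion_junction=(intron.start, intron.end),
                    inclusion_junctions=(),
                    as_type="IR",
                    gene_id=gene,
                    gene_name=tx.gene_name,
                    strand=tx.strand,
                    novelty="known",
                    ir_boundary_sites=(
                        (intron.chrom, intron.start - 1),
                        (intron.chrom, intron.end),
                    ),
                )
                events.setdefault(ev.event_id, ev)
    return list(events.values())


def detect_annotated_mxe(models: Iterable[TranscriptModel]) -> list[ASEvent]:
    """MXE events: two internal exons of one gene, never co-occurring in
    any transcript, sharing both flanking exons. The 5'-most alternative
    exon (gene orientation) is the inclusion exon; counting junctions
    run from the upstream shared exon into each alternative exon."""
    models = list(models)
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx in models:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    events: dict[str, ASEvent] = {}
    for gene, txs in by_gene.items():
        triples = []  # (U, X, D, tx) in transcription order
        for tx in txs:
            for i in range(1, len(tx.exons) - 1):
                triples.append((tx.exons[i - 1], tx.exons[i], tx.exons[i + 1], tx))
        for u1, x, d1, t1 in triples:
            for u2, y, d2, t2 in triples:
                if t1 is t2 or (u1, d1) != (u2, d2) or x == y or x.overlaps(y):
                    continue
                co_occur = any(x in tx.exons and y in tx.exons for tx in txs)
                if co_occur:
                    continue
                strand = t1.strand
                # 5'-most alternative exon in gene orientation
                if (x.start < y.start) == (strand == "+"):
                    incl, excl = x, y
                else:
                    incl, excl = y, x
                upstream = u1  # shared exon upstream in transcription order
                if strand == "+":
                    inc_jn = (upstream.end + 1, incl.start - 1)
                    exc_jn = (upstream.end + 1, excl.start - 1)
                else:
                    inc_jn = (incl.end + 1, upstream.start - 1)
                    exc_jn = (excl.end + 1, upstream.start - 1)
                ev = ASEvent(
                    chrom=x.chrom,
                    exclusion_junction=exc_jn,
                    inclusion_junctions=(inc_jn,),
                    as_type="MXE",
                    gene_id=gene,
                    gene_name=t1.gene_name,
                    strand=strand,
                    novelty="known",
                    mxe_exons=(incl, excl),
                )
                events.setdefault(ev.event_id, ev)
    return list(events.values())


def mxe_junction_sets(mxe_events: Iterable[ASEvent], models) -> list[set]:
    """Diagnostic junction coordinate sets of annotated MXE events
    (upstream and downstream pairs), used to deduplicate junction-defined
    candidates that re-describe an MXE choice."""
    models = list(models)
    by_tx = {t.transcript_id: t for t in models}
    sets = []
    for ev in mxe_events:
        if ev.as_type != "MXE":
            continue
        jns = {ev.exclusion_junction, *ev.inclusion_junctions}
        # downstream pair: from each alternative exon into the shared
        # downstream exon, recovered from transcripts containing the exon
        for alt in ev.mxe_exons:
            for tx in models:
                if tx.gene_id != ev.gene_id or alt not in tx.exons:
                    continue
                i = tx.exons.index(alt)
                if i + 1 < len(tx.exons):
                    nxt = tx.exons[i + 1]
                    if tx.strand == "+":
                        jns.add((alt.end + 1, nxt.start - 1))
                    else:
                        jns.add((nxt.end + 1, alt.start - 1))
        sets.append((ev.chrom, jns))
    return sets


def dedupe_against_mxe(
    events: Iterable[ASEvent], mxe_events: Iterable[ASEvent], models
) -> list[ASEvent]:
    """Drop junction-defined events whose junctions are all diagnostic
    junctions of one annotated MXE event (the MXE event supersedes)."""
    sets = mxe_junction_sets(mxe_events, models)
    out = []
    for ev in events:
        mine = {ev.exclusion_junction, *ev.inclusion_junctions}
        if any(ev.chrom == chrom and mine <= jns for chrom, jns in sets):
            continue
        out.append(ev)
    return out


# ---------------------------------------------------------------------------
# coding effect and NMD


def _representative_transcript(
    gene_id: str, models: Iterable[TranscriptModel]
) -> TranscriptModel | None:
    """Linking transcript with the longest (frame-complete) CDS."""
    cands = [
        t
        for t in models
        if t.gene_id == gene_id and t.cds and not t.frame_incomplete
    ]
    if not cands:
        return None
    return max(cands, key=lambda t: (t.cds_length, t.transcript_id))


def _cds_start_position(tx: TranscriptModel) -> int:
    """Genomic coordinate of the first base of the start codon."""
    first = tx.cds[0]
    return first.start if tx.strand == "+" else first.end


def classify_coding_effect(
    event: ASEvent, models: Iterable[TranscriptModel], genome=None
) -> str:
    """Coding-effect label of an event against the representative CDS.

    noncoding: differing region entirely outside the genomic span of
    every CDS of the gene (a retained intron *between* CDS exons is
    inside the span, hence coding); coding-disruptive: alters the start
    codon or changes the coding sequence by a non-multiple of 3;
    in-frame: change a multiple of 3 without touching the start codon.
    """
    models = list(models)
    if event.gene_id is None:
        return "unknown"
    rep = _representative_transcript(event.gene_id, models)
    if rep is None:
        return "unknown"
    spans = []
    for t in models:
        if t.gene_id == event.gene_id and t.cds:
            spans.append(
                GenomicInterval(
                    t.cds[0].chrom,
                    min(c.start for c in t.cds),
                    max(c.end for c in t.cds),
                )
            )
    regions = event.differing_regions()
    if not any(r.overlaps(s) for r in regions for s in spans):
        return "noncoding"
    start_pos = _cds_start_position(rep)
    if any(r.start <= start_pos <= r.end for r in regions):
        return "coding-disruptive"
    # inserted/removed exonic length within the coding region
    lengths = [len(r) for r in regions]
    delta = lengths[0] - lengths[1] if event.as_type == "MXE" else lengths[0]
    return "in-frame" if delta % 3 == 0 else "coding-disruptive"


def _remove_region(
    exons: list[GenomicInterval], region: GenomicInterval
) -> list[GenomicInterval]:
    out = []
    for e in exons:
        if not e.overlaps(region):
            out.append(e)
            continue
        if e.start < region.start:
            out.append(GenomicInterval(e.chrom, e.start, region.start - 1, e.strand))
        if region.end < e.end:
            out.append(GenomicInterval(e.chrom, region.end + 1, e.end, e.strand))
    return out


def _insert_region(
    exons: list[GenomicInterval], region: GenomicInterval
) -> list[GenomicInterval]:
    merged = sorted(exons + [region], key=lambda e: e.start)
    out = [merged[0]]
    for e in merged[1:]:
        prev = out[-1]
        if e.start <= prev.end + 1:  # book-ended or overlapping -> one exon
            out[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, e.end), prev.strand
            )
        else:
            out.append(e)
    return out


def isoform_exon_chains(
    event: ASEvent, rep: TranscriptModel
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Exon chains (genomic order) of the inclusion and exclusion
    isoforms, derived by applying the event to the representative
    transcript. The inclusion isoform contains the differing region(s)
    of CE/A5SS/A3SS/IR events; for MXE it contains the inclusion exon."""
    exons = sorted(rep.exons, key=lambda e: e.start)
    if event.as_type == "MXE":
        x, y = event.mxe_exons  # inclusion exon, exclusion exon
        base = _remove_region(_remove_region(exons, x), y)
        return _insert_region(base, x), _insert_region(base, y)
    (region,) = event.differing_regions()
    covered = sum(
        max(0, min(region.end, e.end) - max(region.start, e.start) + 1)
        for e in exons
    )
    if covered == len(region):  # rep is the inclusion isoform
        return exons, _remove_region(exons, region)
    return _insert_region(exons, region), exons


def _genomic_to_transcript(
    chain: list[GenomicInterval], strand: str, gpos: int
) -> int | None:
    """0-based transcript coordinate of a genomic base, or None."""
    ordered = chain if strand == "+" else list(reversed(chain))
    offset = 0
    for e in ordered:
        if e.start <= gpos <= e.end:
            return offset + (gpos - e.start if strand == "+" else e.end - gpos)
        offset += len(e)
    return None


def _first_stop(seq: str, start: int) -> int | None:
    """0-based offset of the first in-frame stop codon at/after start."""
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def predict_nmd(
    event: ASEvent, models: Iterable[TranscriptModel], genome
) -> bool | None:
    """Nonsense-mediated decay prediction by the 50-nt rule.

    The event is applied to the representative transcript (longest CDS)
    to obtain the altered isoform; its CDS is translated from the
    annotated start codon. The altered isoform is predicted to undergo
    NMD iff the stop codon ends more than 50 nt upstream of the final
    exon-exon junction of the altered transcript (hence never when the
    stop lies in the last exon). Returns None when no frame-complete
    CDS transcript links the event or the start codon is lost.
    """
    models = list(models)
    if event.gene_id is None:
        return None
    rep = _representative_transcript(event.gene_id, models)
    if rep is None:
        return None
    incl_chain, excl_chain = isoform_exon_chains(event, rep)
    rep_sorted = sorted(rep.exons, key=lambda e: e.start)
    altered = excl_chain if incl_chain == rep_sorted else incl_chain
    strand = rep.strand
    start_pos = _cds_start_position(rep)
    tpos = _genomic_to_transcript(altered, strand, start_pos)
    if tpos is None:
        return None
    ordered = altered if strand == "+" else list(reversed(altered))
    seq = spliced_sequence(ordered, strand, genome)
    stop = _first_stop(seq, tpos)
    if stop is None:
        return False
    if len(altered) < 2:
        return False
    last_junction = len(seq) - len(ordered[-1])  # transcript coord of junction
    stop_end = stop + 3  # one past the stop codon's last base
    if stop_end > last_junction:  # stop in (or straddling into) last exon
        return False
    return last_junction - stop_end > NMD_RULE_NT
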