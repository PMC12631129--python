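"""Junction-read and boundary-span extraction from barcoded alignments.

A *junction read* is an alignment whose CIGAR contains a reference skip
(N); the skipped interval is the intron. In single-cell mode all reads
sharing (cell barcode, UMI) are merged into one molecule before
counting: a molecule supports a junction if any of its reads spans it,
and supports it at most once. In bulk mode every primary read counts.

Reference skips shorter than ``min_intron`` bases (default 20) are
treated as deletions, not junctions. Secondary and supplementary
alignments are ignored.

BAM coordinates (0-based half-open) are converted to the package-wide
1-based inclusive convention here and only here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pysam

MIN_INTRON = 20
DEFAULT_CB_TAG = "CB"
DEFAULT_UMI_TAG = "UB"

BULK_BARCODE = "bulk"


@dataclass
class SpliceJunction:
    """An observed intron with per-cell deduplicated molecule support."""

    chrom: str
    intron_start: int  # 1-based first intronic base
    intron_end: int  # 1-based last intronic base
    per_cell_support: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.intron_start, self.intron_end)

    @property
    def total_support(self) -> int:
        return sum(self.per_cell_support.values())


@dataclass
class BoundarySpanCounts:
    """Non-gapped read support contiguously covering site and site+1."""

    site: tuple[str, int]
    per_cell_support: dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.per_cell_support.values())


def _iter_primary(alignments: pysam.AlignmentFile):
    for read in alignments.fetch():
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        yield read


def _read_introns(read: pysam.AlignedSegment, min_intron: int):
    """Introns of one read as 1-based inclusive (start, end) tuples."""
    pos = read.reference_start  # 0-based
    for op, length in read.cigartuples or ():
        if op == 3:  # N: reference skip
            if length >= min_intron:
                yield (pos + 1, pos + length)  # 1-based inclusive
            pos += length
        elif op in (0, 2, 7, 8):  # M, D, =, X consume reference
            pos += length


def _molecule_key(read, cb_tag: str, umi_tag: str):
    try:
        return (read.get_tag(cb_tag), read.get_tag(umi_tag))
    except KeyError:
        return None


def _require_indexed(alignments: pysam.AlignmentFile) -> None:
    if not alignments.has_index():
        raise ValueError("alignment file must be coordinate-sorted and indexed")


def extract_junctions(
    alignments: pysam.AlignmentFile,
    cb_tag: str = DEFAULT_CB_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
    mode: str = "single_cell",
    min_intron: int = MIN_INTRON,
) -> dict[tuple[str, int, int], SpliceJunction]:
    """Extract UMI-deduplicated junction support per cell.

    Returns a dict keyed by ``(chrom, intron_start, intron_end)``. In
    bulk mode the UMI-unification step is skipped and all support is
    recorded under the pseudo-barcode ``"bulk"``.
    """
    if mode not in ("single_cell", "bulk"):
        raise ValueError(f"unknown mode {mode!r}")
    _require_indexed(alignments)

    junctions: dict[tuple[str, int, int], SpliceJunction] = {}
    # molecule -> set of junction keys already credited
    seen: dict[tuple, set] = {}
    n_untagged = 0
    for read in _iter_primary(alignments):
        chrom = read.reference_name
        introns = list(_read_introns(read, min_intron))
        if not introns:
            continue
        if mode == "single_cell":
            mol = _molecule_key(read, cb_tag, umi_tag)
            if mol is None:
                n_untagged += 1
                continue
            cell = mol[0]
            credited = seen.setdefault(mol, set())
        else:
            cell = BULK_BARCODE
            credited = None
        for s, e in introns:
            key = (chrom, s, e)
            if credited is not None:
                if key in credited:
                    continue
                credited.add(key)
            jn = junctions.setdefault(key, SpliceJunction(chrom, s, e))
            jn.per_cell_support[cell] = jn.per_cell_support.get(cell, 0) + 1
    if n_untagged:
        warnings.warn(
            f"skipped {n_untagged} reads missing {cb_tag}/{umi_tag} tags"
        )
    return junctions


def count_boundary_spans(
    alignments: pysam.AlignmentFile,
    sites: set[tuple[str, int]],
    cb_tag: str = DEFAULT_CB_TAG,
    umi_tag: str = DEFAULT_UMI_TAG,
    mode: str = "single_cell",
) -> dict[tuple[str, int], BoundarySpanCounts]:
    """Count molecules whose reads contiguously cover site and site+1.

    A read whose reference skip starts exactly at the boundary is a
    junction read, not a spanning read, and is not counted: the covering
    bases must come from a single aligned (M/=/X) block.
    """
    if mode not in ("single_cell", "bulk"):
        raise ValueError(f"unknown mode {mode!r}")
    _require_indexed(alignments)

    spans: dict[tuple[str, int], BoundarySpanCounts] = {
        s: BoundarySpanCounts(s) for s in sites
    }
    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in sites:
        by_chrom.setdefault(chrom, []).append(pos)

    seen: dict[tuple, set] = {}
    n_untagged = 0
    for read in _iter_primary(alignments):
        chrom = read.reference_name
        positions = by_chrom.get(chrom)
        if not positions:
            continue
        # aligned blocks as 1-based inclusive intervals
        blocks = []
        pos = read.reference_start
        for op, length in read.cigartuples or ():
            if op in (0, 7, 8):
                blocks.append((pos + 1, pos + length))
                pos += length
            elif op in (2, 3):
                pos += length
        covered = [
            p for p in positions if any(bs <= p and p + 1 <= be for bs, be in blocks)
        ]
        if not covered:
            continue
        if mode == "single_cell":
            mol = _molecule_key(read, cb_tag, umi_tag)
            if mol is None:
                n_untagged += 1
                continue
            cell = mol[0]
            credited = seen.setdefault(mol, set())
        else:
            cell = BULK_BARCODE
            credited = None
        for p in covered:
            key = (chrom, p)
            if credited is not None:
                if key in credited:
                    continue
                credited.add(key)
            bc = spans[key]
            bc.per_cell_support[cell] = bc.per_cell_support.get(cell, 0) + 1
    if n_untagged:
        warnings.warn(
            f"skipped {n_untagged} reads missing {cb_tag}/{umi_tag} tags"
        )
    return spans


def filter_min_support(
    junctions: dict[tuple[str, int, int], SpliceJunction], min_reads: int
) -> dict[tuple[str, int, int], SpliceJunction]:
    """Keep junctions whose total deduplicated support is >= min_reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return {k: j for k, j in junctions.items() if j.total_support >= min_reads}


def junctions_to_rows(junctions) -> list[dict]:
    """Flatten junction support to TSV-ready rows."""
    rows = []
    for jn in junctions.values():
        for cell, n in sorted(jn.per_cell_support.items()):
            rows.append(
                {
                    "chrom": jn.chrom,
                    "intron_start": jn.intron_start,
                    "intron_end": jn.intron_end,
                    "cell_barcode": cell,
                    "count": n,
                }
            )
    rows.sort(
        key=lambda r: (r["chrom"], r["intron_start"], r["intron_end"], r["cell_barcode"])
    )
    return rows
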