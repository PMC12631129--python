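"""Self-contained synthetic fixtures with machine-readable ground truth.

Generates a toy genome (one ~100 kb chromosome), a GTF with gene pairs
realizing each AS type (CE, A5SS, A3SS, AFE, ALE, MXE, IR) plus one
annotation-free (UN) junction pair, barcode/UMI-tagged reads planted at
known per-cell molecule counts, normal-tissue count references, a
normal proteome and an MHC %rank table — together with a manifest
recording every planted truth (event coordinates, type, per-cell
counts, coding effect, NMD status, designated antigen candidates and
their expected peptides).

Sequence design: the background sequence never contains a T followed
by A or G, so no stop codon exists in any forward reading frame except
the ones planted explicitly. This lets coding consequences be laid out
by hand: an in-frame cassette (90 nt), a frameshifting cassette whose
skip exposes a premature stop far upstream of the last junction
(NMD), one whose shifted stop falls in the last exon (no NMD), a
purely 3'UTR cassette, and a frameshifting intron retention.

Two modes: "exact" plants deterministic molecule counts (for oracle
tests); "sampled" draws molecule counts binomially at the planted PSI
(for statistical tests). Each junction-bearing molecule emits duplicate
reads sharing (CB, UB) so UMI deduplication is exercised everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

CHROM = "chrS"
GENOME_LENGTH = 100_000
GENE_SPACING = 4500
CELL_TYPES = ("cancer", "stromal")
DEFAULT_ALLELES = ("HLA-A*01:01", "HLA-B*07:02")
STRONG_RANK = 0.3
WEAK_RANK = 2.0


# ---------------------------------------------------------------------------
# gene layouts


def _gene_defs() -> list[dict]:
    """Static layouts; coordinates relative to each gene's origin (0-based
    offsets, converted to absolute 1-based later)."""

    def iv(a, b):
        return (a, b)

    defs = []
    # G1: cassette exon, in-frame (90 nt), atypical inclusion in cancer
    defs.append(
        dict(
            gene_id="G1",
            gene_name="CEIF",
            strand="+",
            exons=dict(A=iv(0, 299), B=iv(500, 589), C=iv(790, 1089)),
            transcripts=dict(
                T1i=dict(exons=["A", "B", "C"], cds=[(50, 299), (500, 589), (790, 893)]),
                T1e=dict(exons=["A", "C"], cds=[(50, 299), (790, 893)]),
            ),
            plants=[(50, "ATG"), (53, "C"), (891, "TAA")],
            event=dict(
                name="CE_inframe",
                as_type="CE",
                exclusion=(300, 789),
                inclusions=[(300, 499), (590, 789)],
                isoform_tx=dict(inclusion="T1i", exclusion="T1e"),
                psi=dict(cancer=0.6, stromal=0.0),
                coding_effect="in-frame",
                nmd=False,
                atypical_side="inclusion",
            ),
        )
    )
    # G2: cassette exon, frameshift with PTC far upstream of last junction
    defs.append(
        dict(
            gene_id="G2",
            gene_name="CEFN",
            strand="+",
            exons=dict(
                A=iv(0, 299),
                B=iv(500, 590),
                C=iv(791, 940),
                D=iv(1141, 1290),
                E=iv(1491, 1790),
            ),
            transcripts=dict(
                T2i=dict(
                    exons=["A", "B", "C", "D", "E"],
                    cds=[(50, 299), (500, 590), (791, 940), (1141, 1290), (1491, 1590)],
                ),
                T2e=dict(exons=["A", "C", "D", "E"], cds=None),
            ),
            plants=[(50, "ATG"), (53, "C"), (1588, "TAA"), (811, "TAA")],
            event=dict(
                name="CE_frameshift_nmd",
                as_type="CE",
                exclusion=(300, 790),
                inclusions=[(300, 499), (591, 790)],
                isoform_tx=dict(inclusion="T2i", exclusion="T2e"),
                psi=dict(cancer=0.5, stromal=1.0),
                coding_effect="coding-disruptive",
                nmd=True,
                atypical_side="exclusion",
            ),
        )
    )
    # G3: cassette exon, frameshift whose shifted stop lands in the last exon
    defs.append(
        dict(
            gene_id="G3",
            gene_name="CEFX",
            strand="+",
            exons=dict(A=iv(0, 299), B=iv(500, 590), C=iv(791, 1090)),
            transcripts=dict(
                T3i=dict(
                    exons=["A", "B", "C"], cds=[(50, 299), (500, 590), (791, 890)]
                ),
                T3e=dict(exons=["A", "C"], cds=None),
            ),
            plants=[(50, "ATG"), (53, "C"), (888, "TAA"), (991, "TAA")],
            event=dict(
                name="CE_frameshift_nonmd",
                as_type="CE",
                exclusion=(300, 790),
                inclusions=[(300, 499), (591, 790)],
                isoform_tx=dict(inclusion="T3i", exclusion="T3e"),
                psi=dict(cancer=0.4, stromal=1.0),
                coding_effect="coding-disruptive",
                nmd=False,
                atypical_side="exclusion",
            ),
        )
    )
    # G4: cassette exon entirely in the 3'UTR (noncoding effect)
    defs.append(
        dict(
            gene_id="G4",
            gene_name="CENC",
            strand="+",
            exons=dict(A=iv(0, 299), B=iv(500, 619), C=iv(820, 1019), D=iv(1220, 1519)),
            transcripts=dict(
                T4i=dict(exons=["A", "B", "C", "D"], cds=[(50, 250)]),
                T4e=dict(exons=["A", "B", "D"], cds=[(50, 250)]),
            ),
            plants=[(50, "ATG"), (53, "C"), (248, "TAA")],
            event=dict(
                name="CE_noncoding",
                as_type="CE",
                exclusion=(620, 1219),
                inclusions=[(620, 819), (1020, 1219)],
                isoform_tx=dict(inclusion="T4i", exclusion="T4e"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="noncoding",
                nmd=True,
                atypical_side=None,
            ),
        )
    )
    # G5: alternative 5' splice site on internal exon B
    defs.append(
        dict(
            gene_id="G5",
            gene_name="A5G",
            strand="+",
            exons=dict(A=iv(0, 299), BL=iv(500, 849), BS=iv(500, 799), C=iv(1100, 1399)),
            transcripts=dict(
                T5a=dict(exons=["A", "BL", "C"], cds=[(50, 181)]),
                T5b=dict(exons=["A", "BS", "C"], cds=[(50, 181)]),
            ),
            plants=[(50, "ATG"), (53, "C"), (179, "TAA")],
            event=dict(
                name="A5SS",
                as_type="A5SS",
                exclusion=(800, 1099),
                inclusions=[(850, 1099)],
                isoform_tx=dict(inclusion="T5a", exclusion="T5b"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="noncoding",
                nmd=True,
                atypical_side=None,
            ),
        )
    )
    # G6: alternative 3' splice site on internal exon B
    defs.append(
        dict(
            gene_id="G6",
            gene_name="A3G",
            strand="+",
            exons=dict(A=iv(0, 299), BL=iv(500, 799), BS=iv(560, 799), C=iv(1100, 1399)),
            transcripts=dict(
                T6a=dict(exons=["A", "BL", "C"], cds=[(50, 181)]),
                T6b=dict(exons=["A", "BS", "C"], cds=[(50, 181)]),
            ),
            plants=[(50, "ATG"), (53, "C"), (179, "TAA")],
            event=dict(
                name="A3SS",
                as_type="A3SS",
                exclusion=(300, 559),
                inclusions=[(300, 499)],
                isoform_tx=dict(inclusion="T6a", exclusion="T6b"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="noncoding",
                nmd=True,
                atypical_side=None,
            ),
        )
    )
    # G7: alternative first exons sharing the acceptor of exon 2
    defs.append(
        dict(
            gene_id="G7",
            gene_name="AFEG",
            strand="+",
            exons=dict(F1=iv(0, 199), F2=iv(400, 599), E2=iv(1000, 1299)),
            transcripts=dict(
                T7a=dict(exons=["F1", "E2"], cds=None),
                T7b=dict(exons=["F2", "E2"], cds=None),
            ),
            plants=[],
            event=dict(
                name="AFE",
                as_type="AFE",
                exclusion=(200, 999),
                inclusions=[(600, 999)],
                isoform_tx=dict(inclusion="T7b", exclusion="T7a"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="unknown",
                nmd=None,
                atypical_side=None,
            ),
        )
    )
    # G8: alternative last exons sharing the donor of exon 1
    defs.append(
        dict(
            gene_id="G8",
            gene_name="ALEG",
            strand="+",
            exons=dict(A=iv(0, 299), L1=iv(500, 699), L2=iv(900, 1199)),
            transcripts=dict(
                T8a=dict(exons=["A", "L1"], cds=None),
                T8b=dict(exons=["A", "L2"], cds=None),
            ),
            plants=[],
            event=dict(
                name="ALE",
                as_type="ALE",
                exclusion=(300, 899),
                inclusions=[(300, 499)],
                isoform_tx=dict(inclusion="T8a", exclusion="T8b"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="unknown",
                nmd=None,
                atypical_side=None,
            ),
        )
    )
    # G9: mutually exclusive exons X/Y between shared flanks U and D
    defs.append(
        dict(
            gene_id="G9",
            gene_name="MXEG",
            strand="+",
            exons=dict(U=iv(0, 299), X=iv(500, 619), Y=iv(800, 949), D=iv(1100, 1399)),
            transcripts=dict(
                T9a=dict(exons=["U", "X", "D"], cds=None),
                T9b=dict(exons=["U", "Y", "D"], cds=None),
            ),
            plants=[],
            event=dict(
                name="MXE",
                as_type="MXE",
                exclusion=(300, 799),
                inclusions=[(300, 499)],
                downstream_junctions=dict(inclusion=(620, 1099), exclusion=(950, 1099)),
                mxe_exons=[(500, 619), (800, 949)],
                isoform_tx=dict(inclusion="T9a", exclusion="T9b"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="unknown",
                nmd=None,
                atypical_side=None,
            ),
        )
    )
    # G10: intron retention; retention frameshifts into exon B
    defs.append(
        dict(
            gene_id="G10",
            gene_name="IRG",
            strand="+",
            exons=dict(A=iv(0, 299), B=iv(500, 799), R=iv(0, 799)),
            transcripts=dict(
                T10a=dict(exons=["A", "B"], cds=[(50, 299), (500, 603)]),
                T10b=dict(exons=["R"], cds=None),
            ),
            plants=[(50, "ATG"), (53, "C"), (601, "TAA")],
            event=dict(
                name="IR",
                as_type="IR",
                exclusion=(300, 499),
                inclusions=[],
                boundary_sites=[299, 499],
                isoform_tx=dict(inclusion="T10b", exclusion="T10a"),
                psi=dict(cancer=0.5, stromal=0.0),
                coding_effect="coding-disruptive",
                nmd=False,
                atypical_side="inclusion",
            ),
        )
    )
    # G11: minus-strand cassette exon (no CDS)
    defs.append(
        dict(
            gene_id="G11",
            gene_name="NEGC",
            strand="-",
            exons=dict(E3=iv(0, 199), E2=iv(400, 489), E1=iv(700, 899)),
            transcripts=dict(
                T11i=dict(exons=["E1", "E2", "E3"], cds=None),
                T11e=dict(exons=["E1", "E3"], cds=None),
            ),
            plants=[],
            event=dict(
                name="CE_minus",
                as_type="CE",
                exclusion=(200, 699),
                inclusions=[(200, 399), (490, 699)],
                isoform_tx=dict(inclusion="T11i", exclusion="T11e"),
                psi=dict(cancer=0.5, stromal=0.5),
                coding_effect="unknown",
                nmd=None,
                atypical_side=None,
            ),
        )
    )
    # order so the first eight genes cover all seven AS types
    order = ["G1", "G5", "G6", "G7", "G8", "G9", "G10", "G2", "G3", "G4", "G11"]
    by_id = {d["gene_id"]: d for d in defs}
    return [by_id[g] for g in order]


_UN_EVENT = dict(
    name="UN",
    as_type="UN",
    exclusion=(0, 999),
    inclusions=[(0, 499)],
    isoform_tx=None,
    psi=dict(cancer=0.5, stromal=0.5),
    coding_effect="unknown",
    nmd=None,
    atypical_side=None,
)


def _safe_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random sequence containing no TA or TG dinucleotide (stop-free in
    every forward frame)."""
    letters = np.array(list("ACGT"))
    after_t = np.array(list("CT"))
    seq = np.empty(length, dtype="<U1")
    draws = rng.integers(0, 4, size=length)
    draws_t = rng.integers(0, 2, size=length)
    prev_t = False
    for i in range(length):
        seq[i] = after_t[draws_t[i]] if prev_t else letters[draws[i]]
        prev_t = seq[i] == "T"
    return seq


def generate_genome_and_annotation(seed: int, n_genes: int = 11):
    """Toy genome string, transcript records and manifest skeleton.

    Returns (genome_str, manifest). ``n_genes`` below the built-in
    layout count truncates the layouts (at least 8 needed for one gene
    per AS type); larger values are capped at the layout count.
    """
    if n_genes < 8:
        raise ValueError("need at least 8 genes (one per AS type)")
    rng = np.random.default_rng(seed)
    seq = _safe_background(GENOME_LENGTH, rng)
    defs = _gene_defs()[: max(8, min(n_genes, 11))]

    genes = {}
    events = {}
    for slot, gd in enumerate(defs):
        origin = slot * GENE_SPACING  # 0-based
        # splicing juxtaposes exon edges, which can create stop codons
        # the genomically-local background guarantee cannot see; force
        # the two bases at every exon edge to C (stops contain no C) so
        # no junction-straddling codon is ever a stop, in any frame
        for a, b in gd["exons"].values():
            seq[origin + a : origin + a + 2] = ["C", "C"]
            seq[origin + b - 1 : origin + b + 1] = ["C", "C"]
        for pos, nt in gd["plants"]:
            seq[origin + pos : origin + pos + len(nt)] = list(nt)
        exon_abs = {
            name: (origin + a + 1, origin + b + 1) for name, (a, b) in gd["exons"].items()
        }
        txs = {}
        for tid, tx in gd["transcripts"].items():
            txs[tid] = dict(
                exons=[list(exon_abs[e]) for e in tx["exons"]],
                cds=(
                    [[origin + a + 1, origin + b + 1] for a, b in tx["cds"]]
                    if tx["cds"]
                    else None
                ),
            )
        genes[gd["gene_id"]] = dict(
            gene_name=gd["gene_name"], strand=gd["strand"], transcripts=txs
        )
        ev = dict(gd["event"])
        ev["gene_id"] = gd["gene_id"]
        ev["chrom"] = CHROM
        ev["novelty"] = "known"
        ev["exclusion_junction"] = [origin + ev.pop("exclusion")[0] + 1,
                                    origin + gd["event"]["exclusion"][1] + 1]
        ev["inclusion_junctions"] = [
            [origin + a + 1, origin + b + 1] for a, b in ev.pop("inclusions")
        ]
        if "boundary_sites" in ev:
            ev["ir_boundary_sites"] = [
                [CHROM, origin + p + 1] for p in ev.pop("boundary_sites")
            ]
        if "mxe_exons" in ev:
            ev["mxe_exons"] = [[origin + a + 1, origin + b + 1] for a, b in ev["mxe_exons"]]
        if "downstream_junctions" in ev:
            ev["downstream_junctions"] = {
                k: [origin + a + 1, origin + b + 1]
                for k, (a, b) in ev["downstream_junctions"].items()
            }
        events[ev["name"]] = ev

    # annotation-free junction pair in the intergenic tail
    un_origin = len(defs) * GENE_SPACING
    un = dict(_UN_EVENT)
    un["gene_id"] = None
    un["chrom"] = CHROM
    un["novelty"] = "novel"
    un["exclusion_junction"] = [un_origin + 1, un_origin + 1000]
    un["inclusion_junctions"] = [[un_origin + 1, un_origin + 500]]
    un.pop("exclusion")
    un.pop("inclusions")
    events[un["name"]] = un

    manifest = dict(
        seed=seed,
        chrom=CHROM,
        genome_length=GENOME_LENGTH,
        genes=genes,
        events=events,
    )
    return "".join(seq), manifest


def write_genome(genome: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_gtf(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for gid, g in manifest["genes"].items():
            for tid, tx in g["transcripts"].items():
                attrs = (
                    f'gene_id "{gid}"; transcript_id "{tid}"; '
                    f'gene_name "{g["gene_name"]}";'
                )
                feats = [("exon", s, e) for s, e in tx["exons"]]
                if tx["cds"]:
                    feats += [("CDS", s, e) for s, e in tx["cds"]]
                for ftype, s, e in sorted(feats, key=lambda t: (t[1], t[0])):
                    fh.write(
                        f"{manifest['chrom']}\tsynthetic\t{ftype}\t{s}\t{e}\t.\t"
                        f"{g['strand']}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# reads


def _junction_read(s: int, e: int, flank: int = 30):
    """Read spanning intron (s, e): 0-based start, cigartuples."""
    return s - flank - 1, [(0, flank), (3, e - s + 1), (0, flank)]


def _span_read(p: int, half: int = 20):
    """Non-gapped read covering 1-based positions p-half+1 .. p+half."""
    return p - half, [(0, 2 * half)]


def _event_templates(ev: dict) -> dict[str, list]:
    """Read templates per isoform: list of (start0, cigartuples)."""
    if ev["as_type"] == "IR":
        s1, s2 = (p for _, p in ev["ir_boundary_sites"])
        incl = [_span_read(s1), _span_read(s2)]
        excl = [_junction_read(*ev["exclusion_junction"])]
    elif ev["as_type"] == "MXE":
        incl = [
            _junction_read(*ev["inclusion_junctions"][0]),
            _junction_read(*ev["downstream_junctions"]["inclusion"]),
        ]
        excl = [
            _junction_read(*ev["exclusion_junction"]),
            _junction_read(*ev["downstream_junctions"]["exclusion"]),
        ]
    elif ev["as_type"] == "CE":
        incl = [_junction_read(*jn) for jn in ev["inclusion_junctions"]]
        excl = [_junction_read(*ev["exclusion_junction"])]
    else:
        incl = [_junction_read(*ev["inclusion_junctions"][0])]
        excl = [_junction_read(*ev["exclusion_junction"])]
    return {"inclusion": incl, "exclusion": excl}


def make_cells(cells_per_type: dict[str, int], n_samples: int) -> list[dict]:
    cells = []
    for ct, n in cells_per_type.items():
        for i in range(n):
            cells.append(
                dict(
                    barcode=f"{ct[:2].upper()}{i:05d}",
                    sample=f"S{i % n_samples + 1}",
                    cell_type=ct,
                )
            )
    return cells


def sample_read_starts(
    tx_len: int, n: int, bias_5prime: float, rng: np.random.Generator
) -> np.ndarray:
    """Read start positions along a transcript; uniform at bias 0,
    decaying from the 5' end for bias in (0, 1)."""
    if not 0 <= bias_5prime < 1:
        raise ValueError("bias_5prime must be in [0, 1)")
    if bias_5prime == 0:
        return rng.integers(0, tx_len, size=n)
    scale = tx_len * (1 - bias_5prime)
    out = np.empty(n, dtype=int)
    for i in range(n):
        while True:
            x = rng.exponential(scale)
            if x < tx_len:
                out[i] = int(x)
                break
    return out


def simulate_reads(
    manifest: dict,
    genome: str,
    bam_path: Path,
    cells_per_type: dict[str, int] | None = None,
    molecules_per_cell: int = 10,
    n_samples: int = 4,
    mode: str = "exact",
    seed: int = 0,
) -> list[dict]:
    """Write a sorted, indexed BAM of planted molecules; fills
    ``manifest['counts']`` with per-cell (I, E) truth and
    ``manifest['cells']`` / ``manifest['gene_counts']``.

    Exact mode: per cell and event, I = round(PSI * molecules_per_cell),
    E = molecules_per_cell - I, each molecule emitting 2 duplicate
    reads. Sampled mode: I ~ Binomial(molecules_per_cell, PSI), 1-3
    duplicates.
    """
    if mode not in ("exact", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    if cells_per_type is None:
        cells_per_type = {ct: 100 for ct in CELL_TYPES}
    cells = make_cells(cells_per_type, n_samples)
    manifest["cells"] = cells
    manifest["mode"] = mode
    manifest["molecules_per_cell"] = molecules_per_cell

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": manifest["chrom"], "LN": manifest["genome_length"]}],
        }
    )
    counts: dict[str, dict[str, list[int]]] = {}
    gene_counts: dict[str, dict[str, int]] = {ct: {} for ct in cells_per_type}
    reads = []
    umi_counter = 0
    for name, ev in manifest["events"].items():
        templates = _event_templates(ev)
        counts[name] = {}
        for cell in cells:
            psi = ev["psi"][cell["cell_type"]]
            n = molecules_per_cell
            if mode == "exact":
                I = int(round(psi * n))
            else:
                I = int(rng.binomial(n, psi))
            E = n - I
            counts[name][cell["barcode"]] = [I, E]
            if ev["gene_id"] is not None:
                gc = gene_counts[cell["cell_type"]]
                gc[ev["gene_id"]] = gc.get(ev["gene_id"], 0) + n
            for side, k in (("inclusion", I), ("exclusion", E)):
                for _ in range(k):
                    umi_counter += 1
                    umi = f"U{umi_counter:08d}"
                    n_dup = 2 if mode == "exact" else int(rng.integers(1, 4))
                    for start0, cigar in templates[side]:
                        for _dup in range(n_dup):
                            reads.append((start0, cigar, cell["barcode"], umi))
    manifest["counts"] = counts
    manifest["gene_counts"] = gene_counts

    reads.sort(key=lambda r: r[0])
    tmp = str(bam_path) + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, (start0, cigar, cb, umi) in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i:09d}"
            a.reference_id = 0
            a.reference_start = start0
            a.mapping_quality = 255
            a.cigartuples = cigar
            pieces = []
            pos = start0
            for op, length in cigar:
                if op == 0:
                    pieces.append(genome[pos : pos + length])
                    pos += length
                elif op == 3:
                    pos += length
            a.query_sequence = "".join(pieces)
            a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
            a.set_tag("CB", cb)
            a.set_tag("UB", umi)
            a.flag = 0
            out.write(a)
    pysam.sort("-o", str(bam_path), tmp)
    Path(tmp).unlink()
    pysam.index(str(bam_path))
    return cells


# ---------------------------------------------------------------------------
# references: normals, proteome, MHC ranks


def _translate_from(genome: str, exons: list[list[int]], strand: str, start_gpos: int) -> str:
    """Protein of an exon chain from a genomic start-codon position."""
    from juncsplice.annotation import reverse_complement

    chain = sorted(exons, key=lambda e: e[0], reverse=strand == "-")
    parts = []
    for s, e in chain:
        sub = genome[s - 1 : e]
        parts.append(reverse_complement(sub) if strand == "-" else sub)
    seq = "".join(parts)
    offset = 0
    for s, e in chain:
        if s <= start_gpos <= e:
            offset += (start_gpos - s) if strand == "+" else (e - start_gpos)
            break
        offset += e - s + 1
    coding = seq[offset:]
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate(to_stop=True))


def _kmers(protein: str, kmin: int = 8, kmax: int = 11) -> set[str]:
    return {
        protein[i : i + k]
        for k in range(kmin, kmax + 1)
        for i in range(len(protein) - k + 1)
    }


def generate_references(
    manifest: dict,
    genome: str,
    n_tissues: int = 3,
    contamination: float = 0.0,
    seed: int = 0,
    normal_depth: int = 100,
) -> dict:
    """Normal-tissue counts, tissue-of-origin reference, proteome and
    MHC %rank table, with expected antigen truths in the manifest.

    Normal tissues express only the designated normal isoform of each
    event except for a ``contamination`` fraction of atypical-side
    molecules. The proteome holds every normal-isoform protein. The
    rank table marks one designated peptide per strong-binder candidate
    below the strong cutoff; all other peptides rank weakly.
    """
    genes = manifest["genes"]
    events = manifest["events"]

    def side_counts(ev, atyp_prop):
        # (I, E) with atypical-side proportion atyp_prop
        n = normal_depth
        if ev["atypical_side"] == "inclusion":
            I = int(round(atyp_prop * n))
            return (I, n - I)
        if ev["atypical_side"] == "exclusion":
            E = int(round(atyp_prop * n))
            return (n - E, E)
        psi = 0.5
        I = int(round(psi * n))
        return (I, n - I)

    normals = {
        f"tissue{t + 1}": {
            name: side_counts(ev, contamination) for name, ev in events.items()
        }
        for t in range(n_tissues)
    }
    tissue_reference = {
        "breast_ref": {name: side_counts(ev, 0.0) for name, ev in events.items()}
    }

    proteome = {}
    for gid, g in genes.items():
        cds_txs = {
            tid: tx for tid, tx in g["transcripts"].items() if tx["cds"]
        }
        if not cds_txs:
            continue
        ev = next(
            (e for e in events.values() if e["gene_id"] == gid), None
        )
        if ev is not None and ev["atypical_side"] is not None:
            normal_side = "exclusion" if ev["atypical_side"] == "inclusion" else "inclusion"
            normal_tid = ev["isoform_tx"][normal_side]
        else:
            normal_tid = max(
                cds_txs, key=lambda t: sum(e - s + 1 for s, e in cds_txs[t]["cds"])
            )
        rep_tid = max(
            cds_txs, key=lambda t: sum(e - s + 1 for s, e in cds_txs[t]["cds"])
        )
        start_gpos = (
            cds_txs[rep_tid]["cds"][0][0]
            if g["strand"] == "+"
            else cds_txs[rep_tid]["cds"][0][1]
        )
        tx = g["transcripts"][normal_tid]
        proteome[f"PROT_{gid}"] = _translate_from(
            genome, tx["exons"], g["strand"], start_gpos
        )

    # expected unique peptides for designated antigen candidates
    antigen_truth = {}
    for name, ev in events.items():
        if ev["atypical_side"] is None or ev["as_type"] not in ("CE", "A5SS", "A3SS", "IR"):
            continue
        if ev["nmd"]:
            antigen_truth[name] = dict(excluded_by="nmd")
            continue
        g = genes[ev["gene_id"]]
        cds_txs = {tid: tx for tid, tx in g["transcripts"].items() if tx["cds"]}
        rep_tid = max(
            cds_txs, key=lambda t: sum(e - s + 1 for s, e in cds_txs[t]["cds"])
        )
        start_gpos = (
            cds_txs[rep_tid]["cds"][0][0]
            if g["strand"] == "+"
            else cds_txs[rep_tid]["cds"][0][1]
        )
        atyp_tid = ev["isoform_tx"][ev["atypical_side"]]
        norm_side = "exclusion" if ev["atypical_side"] == "inclusion" else "inclusion"
        norm_tid = ev["isoform_tx"][norm_side]
        atyp = _translate_from(
            genome, g["transcripts"][atyp_tid]["exons"], g["strand"], start_gpos
        )
        norm = _translate_from(
            genome, g["transcripts"][norm_tid]["exons"], g["strand"], start_gpos
        )
        peptides = sorted(
            pep
            for pep in _kmers(atyp)
            if pep not in _kmers(norm)
            and not any(pep in p for p in proteome.values())
        )
        if not peptides:
            raise AssertionError(
                f"designated antigen candidate {name} yielded no unique "
                "peptides; fixture sequence design violated"
            )
        antigen_truth[name] = dict(
            atypical_side=ev["atypical_side"], peptides=peptides
        )

    # rank table: strong peptide for the CE_inframe and IR candidates
    strong_events = [
        n for n in ("CE_inframe", "IR") if n in antigen_truth and "peptides" in antigen_truth[n]
    ]
    rank_table = {}
    for name, truth in antigen_truth.items():
        for pep in truth.get("peptides", []):
            for allele in DEFAULT_ALLELES:
                rank_table[(pep, allele)] = WEAK_RANK
    for name in strong_events:
        peps = antigen_truth[name]["peptides"]
        if peps:
            rank_table[(peps[0], DEFAULT_ALLELES[0])] = STRONG_RANK
            antigen_truth[name]["strong_peptide"] = peps[0]

    manifest["antigen_truth"] = antigen_truth
    manifest["n_tissues"] = n_tissues
    manifest["contamination"] = contamination
    return dict(
        normals=normals,
        tissue_reference=tissue_reference,
        proteome=proteome,
        rank_table=rank_table,
        alleles=list(DEFAULT_ALLELES),
    )


# ---------------------------------------------------------------------------
# whole fixture


@dataclass
class Fixture:
    out_dir: Path
    genome: str
    manifest: dict
    references: dict
    genome_fa: Path
    gtf: Path
    bam: Path
    cells_tsv: Path
    manifest_json: Path


def generate_fixture(
    out_dir,
    seed: int = 0,
    mode: str = "exact",
    cells_per_type: dict[str, int] | None = None,
    molecules_per_cell: int = 10,
    n_samples: int = 4,
    n_tissues: int = 3,
    contamination: float = 0.0,
) -> Fixture:
    """Full fixture: genome FASTA, GTF, tagged BAM, cell table,
    references and manifest JSON, all under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, manifest = generate_genome_and_annotation(seed)
    genome_fa = out_dir / "genome.fa"
    write_genome(genome, genome_fa)
    gtf = out_dir / "annotation.gtf"
    write_gtf(manifest, gtf)
    bam = out_dir / "reads.bam"
    cells = simulate_reads(
        manifest,
        genome,
        bam,
        cells_per_type=cells_per_type,
        molecules_per_cell=molecules_per_cell,
        n_samples=n_samples,
        mode=mode,
        seed=seed,
    )
    cells_tsv = out_dir / "cells.tsv"
    pd.DataFrame(cells).to_csv(cells_tsv, sep="\t", index=False)
    references = generate_references(
        manifest, genome, n_tissues=n_tissues, contamination=contamination, seed=seed
    )
    with open(out_dir / "proteome.fa", "w") as fh:
        for name, seq in references["proteome"].items():
            fh.write(f">{name}\n{seq}\n")
    manifest_json = out_dir / "manifest.json"
    with open(manifest_json, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return Fixture(
        out_dir=out_dir,
        genome=genome,
        manifest=manifest,
        references=references,
        genome_fa=genome_fa,
        gtf=gtf,
        bam=bam,
        cells_tsv=cells_tsv,
        manifest_json=manifest_json,
    )


# ---------------------------------------------------------------------------
# count-level simulators for the statistical layers


def simulate_embedding_counts(
    n_events: int = 50,
    n_samples: int = 8,
    cell_types: tuple[str, ...] = ("typeA", "typeB"),
    frac_diff: float = 0.2,
    coverage: int = 200,
    psi_shift: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Unit-level (sample x cell type) counts with a planted cell-type
    PSI difference in ``frac_diff`` of events. Returns (counts,
    differential event ids)."""
    rng = np.random.default_rng(seed)
    rows = []
    diff_events = []
    for i in range(n_events):
        eid = f"ev{i:04d}"
        base = rng.uniform(0.2, 0.8)
        psis = {ct: base for ct in cell_types}
        if i < int(round(frac_diff * n_events)):
            diff_events.append(eid)
            sign = 1 if base < 0.5 else -1
            psis[cell_types[-1]] = float(np.clip(base + sign * psi_shift, 0.05, 0.95))
        for s in range(n_samples):
            for ct in cell_types:
                n = coverage
                I = int(rng.binomial(n, psis[ct]))
                rows.append(
                    dict(
                        event_id=eid,
                        sample=f"S{s + 1}",
                        cell_type=ct,
                        I=I,
                        E=n - I,
                    )
                )
    return pd.DataFrame(rows), diff_events


def simulate_differential_counts(
    n_events: int = 200,
    n_samples_per_group: int = 10,
    coverage: int = 50,
    delta_psi: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample two-group count table with a planted group effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_events):
        eid = f"ev{i:04d}"
        base = rng.uniform(0.25, 0.75)
        psis = {
            "grpA": float(np.clip(base + delta_psi / 2, 0.02, 0.98)),
            "grpB": float(np.clip(base - delta_psi / 2, 0.02, 0.98)),
        }
        for g, psi in psis.items():
            for s in range(n_samples_per_group):
                n = max(1, int(rng.poisson(coverage)))
                I = int(rng.binomial(n, psi))
                rows.append(
                    dict(
                        event_id=eid,
                        sample=f"{g}_s{s + 1}",
                        group=g,
                        I=I,
                        E=n - I,
                    )
                )
    return pd.DataFrame(rows)
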