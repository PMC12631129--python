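"""Splice-derived tumor antigens and the antigen burden (ATB).

The chain: (1) call *atypical* isoforms whose proportion (PSI or
1-PSI) in cancer cells exceeds normal-tissue references by fold/CI
rules; (2) tighten against stromal cells and a tissue-of-origin
reference; (3) drop NMD-predicted isoforms, translate the surviving
atypical isoforms and enumerate the 8-11-mer peptides unique to them
(absent from the normal isoform and from the reference proteome);
(4) attach externally predicted MHC %rank values (strong binder:
%rank < 0.5 over the patient's <= 6 alleles); (5) per sample, the ATB
is the sum over strong-binding candidates of isoform proportion x
gene CPM in cancer cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import warnings

from Bio.Seq import Seq

from juncsplice.annotation import TranscriptModel, spliced_sequence
from juncsplice.detection import (
    ASEvent,
    _genomic_to_transcript,
    _cds_start_position,
    _representative_transcript,
    isoform_exon_chains,
    predict_nmd,
)
from juncsplice.quantify import clopper_pearson

FOLD_MEAN_NORMAL = 10.0
FOLD_MAX_NORMAL = 4.0
FOLD_MEAN_STROMA = 5.0
FOLD_CI_STROMA = 2.0
STRONG_RANK_CUT = 0.5
KMIN, KMAX = 8, 11
DETECT_MIN_READS = 5
DETECT_CI_LO = 0.05
DETECT_CI_HI = 0.95

ANTIGEN_TYPES = {"CE", "A5SS", "A3SS", "IR"}


@dataclass
class AntigenCandidate:
    event_id: str
    atypical_side: str  # inclusion | exclusion
    atypical_proportion: float
    nmd: bool | None = None
    peptides: set[str] = field(default_factory=set)
    best_percent_rank: float | None = None
    strong_binder: bool = False
    abundance: float = 0.0


@dataclass
class ATBResult:
    sample_id: str
    atb: float
    contributions: dict[str, float]


def _proportion(I: int, E: int, side: str) -> float:
    return I / (I + E) if side == "inclusion" else E / (I + E)


def _proportion_ci_low(I: int, E: int, side: str) -> float:
    lo, hi = clopper_pearson(I, I + E)
    return lo if side == "inclusion" else 1.0 - hi


def passes_detectability(I: int, E: int, min_reads: int = DETECT_MIN_READS) -> bool:
    """Per-cell-type gate: both counts >= 5 and neither isoform is
    splicing noise (95% CI of PSI within (0.05, 0.95))."""
    if I < min_reads or E < min_reads:
        return False
    lo, hi = clopper_pearson(I, I + E)
    return lo > DETECT_CI_LO and hi < DETECT_CI_HI


def call_atypical_vs_normal(
    cancer_counts: Mapping[str, tuple[int, int]],
    normals: Mapping[str, Mapping[str, tuple[int, int]]],
    fold_mean: float = FOLD_MEAN_NORMAL,
    fold_max: float = FOLD_MAX_NORMAL,
    require_detectable: bool = True,
) -> list[AntigenCandidate]:
    """Atypical isoform calls against normal-tissue bulk references.

    ``cancer_counts`` maps event_id -> (I, E) in cancer cells;
    ``normals`` maps tissue -> {event_id -> (I, E)}. An isoform side is
    atypical iff its cancer proportion is >= fold_mean times the mean
    proportion over normal tissues AND its CI lower bound is
    >= fold_max times the proportion in every individual normal tissue.
    Events absent from a normal tissue's table count as proportion 0
    there (the junctions were assayable but unobserved).
    """
    out = []
    for event_id, (I, E) in sorted(cancer_counts.items()):
        if I + E < 1:
            continue
        if require_detectable and not passes_detectability(I, E):
            continue
        for side in ("inclusion", "exclusion"):
            p = _proportion(I, E, side)
            ci_lo = _proportion_ci_low(I, E, side)
            normal_ps = []
            for tissue in normals:
                nI, nE = normals[tissue].get(event_id, (0, 0))
                normal_ps.append(
                    _proportion(nI, nE, side) if nI + nE > 0 else 0.0
                )
            mean_norm = sum(normal_ps) / len(normal_ps) if normal_ps else 0.0
            if p < fold_mean * mean_norm:
                continue
            if mean_norm == 0.0 and p == 0.0:
                continue
            if any(ci_lo < fold_max * np_ for np_ in normal_ps):
                continue
            if p == 0.0:
                continue
            out.append(
                AntigenCandidate(
                    event_id=event_id, atypical_side=side, atypical_proportion=p
                )
            )
    return out


def call_tumor_specific_vs_stroma(
    candidates: Iterable[AntigenCandidate],
    cancer_counts: Mapping[str, tuple[int, int]],
    stroma_counts: Mapping[str, Mapping[str, tuple[int, int]]],
    tissue_reference: Mapping[str, Mapping[str, tuple[int, int]]] | None = None,
    fold_mean: float = FOLD_MEAN_STROMA,
    fold_ci: float = FOLD_CI_STROMA,
) -> list[AntigenCandidate]:
    """Tighten atypical calls against per-patient stromal aggregates.

    Retained iff cancer proportion >= fold_mean x mean stromal
    proportion AND the cancer CI lower bound >= fold_ci x the stromal
    proportion in every individual patient, AND the atypical isoform is
    undetectable (zero supporting reads) in every sample of the
    tissue-of-origin bulk reference, when one is supplied.
    """
    out = []
    for cand in candidates:
        I, E = cancer_counts[cand.event_id]
        side = cand.atypical_side
        p = _proportion(I, E, side)
        ci_lo = _proportion_ci_low(I, E, side)
        stroma_ps = []
        for patient in stroma_counts:
            sI, sE = stroma_counts[patient].get(cand.event_id, (0, 0))
            stroma_ps.append(_proportion(sI, sE, side) if sI + sE > 0 else 0.0)
        mean_stroma = sum(stroma_ps) / len(stroma_ps) if stroma_ps else 0.0
        if p < fold_mean * mean_stroma:
            continue
        if any(ci_lo < fold_ci * sp for sp in stroma_ps):
            continue
        if tissue_reference is not None:
            detected = False
            for sample in tissue_reference:
                rI, rE = tissue_reference[sample].get(cand.event_id, (0, 0))
                supporting = rI if side == "inclusion" else rE
                if supporting > 0:
                    detected = True
                    break
            if detected:
                continue
        out.append(cand)
    return out


def _translate_chain(
    chain, strand: str, start_gpos: int, genome
) -> str | None:
    """Protein from a genomic exon chain, annotated start codon to stop."""
    ordered = chain if strand == "+" else list(reversed(chain))
    tpos = _genomic_to_transcript(chain, strand, start_gpos)
    if tpos is None:
        return None
    seq = spliced_sequence(ordered, strand, genome)[tpos:]
    seq = seq[: len(seq) - len(seq) % 3]
    return str(Seq(seq).translate(to_stop=True))


def translate_atypical(
    event: ASEvent,
    atypical_side: str,
    models: Iterable[TranscriptModel],
    genome,
    proteome: Mapping[str, str],
    kmin: int = KMIN,
    kmax: int = KMAX,
) -> set[str]:
    """Unique 8-11-mer peptides of the atypical isoform.

    Both isoforms of the event are translated from the representative
    transcript's start codon; k-mers present in the atypical protein
    but absent from the normal protein and absent as substrings of
    every reference-proteome sequence are returned. Only coding-region
    CE/A5SS/A3SS/IR events are eligible; NMD-predicted isoforms are
    excluded upstream.
    """
    if event.as_type not in ANTIGEN_TYPES:
        raise TypeError(f"event type {event.as_type} not antigen-eligible")
    models = list(models)
    rep = _representative_transcript(event.gene_id, models)
    if rep is None:
        return set()
    incl_chain, excl_chain = isoform_exon_chains(event, rep)
    atyp_chain = incl_chain if atypical_side == "inclusion" else excl_chain
    norm_chain = excl_chain if atypical_side == "inclusion" else incl_chain
    start = _cds_start_position(rep)
    atyp = _translate_chain(atyp_chain, rep.strand, start, genome)
    norm = _translate_chain(norm_chain, rep.strand, start, genome)
    if atyp is None or norm is None:
        return set()
    normal_kmers = {
        norm[i : i + k]
        for k in range(kmin, kmax + 1)
        for i in range(len(norm) - k + 1)
    }
    ref_seqs = list(proteome.values())
    out = set()
    for k in range(kmin, kmax + 1):
        for i in range(len(atyp) - k + 1):
            pep = atyp[i : i + k]
            if pep in normal_kmers:
                continue
            if any(pep in s for s in ref_seqs):
                continue
            out.add(pep)
    return out


def attach_mhc_ranks(
    candidates: Iterable[AntigenCandidate],
    rank_table: Mapping[tuple[str, str], float],
    patient_alleles: Sequence[str],
    strong_cut: float = STRONG_RANK_CUT,
) -> list[AntigenCandidate]:
    """Attach the best (lowest) %rank over peptides x patient alleles.

    Peptides absent from the table are treated as non-binders, with a
    warning. Strong binder iff best %rank < strong_cut.
    """
    if not patient_alleles:
        raise ValueError("patient allele list is empty")
    out = []
    for cand in candidates:
        best = None
        missing = 0
        for pep in sorted(cand.peptides):
            for allele in patient_alleles:
                r = rank_table.get((pep, allele))
                if r is None:
                    missing += 1
                    continue
                if best is None or r < best:
                    best = r
        if missing:
            warnings.warn(
                f"{cand.event_id}: {missing} peptide/allele pairs missing "
                "from rank table; treated as non-binders"
            )
        cand.best_percent_rank = best
        cand.strong_binder = best is not None and best < strong_cut
        out.append(cand)
    return out


def compute_atb(
    sample_id: str,
    candidates: Iterable[AntigenCandidate],
    gene_cpm: Mapping[str, float],
    candidate_genes: Mapping[str, str],
) -> ATBResult:
    """ATB = sum over strong-binding candidates of proportion x CPM.

    ``candidate_genes`` maps event_id -> gene_id; genes missing from
    ``gene_cpm`` contribute 0 with a warning.
    """
    contributions: dict[str, float] = {}
    for cand in candidates:
        if not cand.strong_binder:
            continue
        gene = candidate_genes.get(cand.event_id)
        cpm = gene_cpm.get(gene)
        if cpm is None:
            warnings.warn(f"no expression for {cand.event_id} ({gene}); 0 used")
            cpm = 0.0
        key = f"{cand.event_id}|{cand.atypical_side}"
        contributions[key] = cand.atypical_proportion * cpm
    return ATBResult(
        sample_id=sample_id,
        atb=sum(contributions.values()),
        contributions=contributions,
    )


def cpm(gene_counts: Mapping[str, float]) -> dict[str, float]:
    """Counts-per-million over a gene-count vector."""
    total = sum(gene_counts.values())
    if total <= 0:
        return {g: 0.0 for g in gene_counts}
    return {g: 1e6 * c / total for g, c in gene_counts.items()}


def antigen_pipeline(
    events: Mapping[str, ASEvent],
    cancer_counts: Mapping[str, tuple[int, int]],
    normals: Mapping[str, Mapping[str, tuple[int, int]]],
    stroma_counts: Mapping[str, Mapping[str, tuple[int, int]]],
    models: Iterable[TranscriptModel],
    genome,
    proteome: Mapping[str, str],
    rank_table: Mapping[tuple[str, str], float],
    patient_alleles: Sequence[str],
    gene_cpm: Mapping[str, float],
    sample_id: str = "sample",
    tissue_reference=None,
    require_detectable: bool = True,
) -> tuple[list[AntigenCandidate], ATBResult]:
    """End-to-end antigen chain for one sample."""
    models = list(models)
    cands = call_atypical_vs_normal(
        cancer_counts, normals, require_detectable=require_detectable
    )
    cands = call_tumor_specific_vs_stroma(
        cands, cancer_counts, stroma_counts, tissue_reference
    )
    kept = []
    for cand in cands:
        ev = events.get(cand.event_id)
        if ev is None or ev.as_type not in ANTIGEN_TYPES:
            continue
        nmd = predict_nmd(ev, models, genome)
        cand.nmd = nmd
        if nmd:
            continue
        cand.peptides = translate_atypical(
            ev, cand.atypical_side, models, genome, proteome
        )
        if cand.peptides:
            kept.append(cand)
    kept = attach_mhc_ranks(kept, rank_table, patient_alleles)
    genes = {eid: ev.gene_id for eid, ev in events.items()}
    atb = compute_atb(sample_id, kept, gene_cpm, genes)
    return kept, atb
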