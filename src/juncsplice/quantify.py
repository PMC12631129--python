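"""Inclusion/exclusion counting and PSI with exact binomial intervals.

PSI = I / (I + E), where I and E are deduplicated inclusion and
exclusion molecule counts. Counting rules per AS type:

- CE: the single inclusion junction with the larger pooled total is
  used for every cell (a per-cell choice would make PSI incomparable
  across cells);
- A5SS/A3SS/UN: the single inclusion junction;
- AFE/ALE: the proximal junction is inclusion, the distal exclusion;
- IR: per cell, the maximum of the two exon-intron boundary-span
  counts is the inclusion count;
- MXE: the diagnostic junction from the upstream shared exon into the
  inclusion exon.

The 95% interval is the exact (Clopper-Pearson) binomial interval —
the interval R's ``binom.test`` reports — computed from beta quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import beta as beta_dist

from juncsplice.detection import ASEvent


@dataclass(frozen=True)
class PSIEstimate:
    psi: float
    ci_low: float
    ci_high: float
    I: int
    E: int


class ASECountTable:
    """Inclusion/exclusion molecule counts keyed by (event_id, unit).

    A unit is a cell barcode or, after :func:`aggregate`, a group id.
    Backed by a pandas DataFrame with columns event_id, unit, I, E.
    """

    COLUMNS = ["event_id", "unit", "I", "E"]

    def __init__(self, df: pd.DataFrame | None = None):
        if df is None:
            df = pd.DataFrame(columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        df = df[self.COLUMNS].copy()
        if (df[["I", "E"]] < 0).any().any():
            raise ValueError("negative counts")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "ASECountTable":
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    def totals(self) -> pd.DataFrame:
        """Pooled (I, E) per event over all units."""
        return self.df.groupby("event_id")[["I", "E"]].sum()

    def __len__(self) -> int:
        return len(self.df)


def _cell_counts(per_cell: Mapping[str, int] | None) -> dict[str, int]:
    return dict(per_cell) if per_cell else {}


def count_event(
    event: ASEvent,
    junctions: Mapping[tuple[str, int, int], "SpliceJunction"],
    spans: Mapping[tuple[str, int], "BoundarySpanCounts"] | None = None,
) -> dict[str, tuple[int, int]]:
    """Per-cell (I, E) molecule counts for one event.

    Cells with I + E = 0 are omitted. Returns {} for an event with no
    reads at all.
    """

    def support(key) -> dict[str, int]:
        jn = junctions.get(key)
        return _cell_counts(jn.per_cell_support if jn else None)

    exc = support((event.chrom, *event.exclusion_junction))

    if event.as_type == "IR":
        if spans is None:
            raise ValueError("IR counting requires boundary-span counts")
        s1, s2 = event.ir_boundary_sites
        c1 = _cell_counts(spans[s1].per_cell_support if s1 in spans else None)
        c2 = _cell_counts(spans[s2].per_cell_support if s2 in spans else None)
        inc = {c: max(c1.get(c, 0), c2.get(c, 0)) for c in set(c1) | set(c2)}
    elif event.as_type == "CE":
        cands = [support((event.chrom, *jn)) for jn in event.inclusion_junctions]
        # one junction chosen by pooled total, the same for every cell
        inc = max(cands, key=lambda d: sum(d.values()))
    else:
        (jn,) = event.inclusion_junctions
        inc = support((event.chrom, *jn))

    cells = set(inc) | set(exc)
    return {
        c: (inc.get(c, 0), exc.get(c, 0))
        for c in cells
        if inc.get(c, 0) + exc.get(c, 0) >= 1
    }


def build_count_table(events, junctions, spans=None) -> ASECountTable:
    """Per-cell count table over a collection of events."""
    rows = []
    for ev in events:
        for cell, (i, e) in sorted(count_event(ev, junctions, spans).items()):
            rows.append({"event_id": ev.event_id, "unit": cell, "I": i, "E": e})
    return ASECountTable.from_rows(rows)


def aggregate(
    table: ASECountTable, grouping: Mapping[str, str]
) -> ASECountTable:
    """Sum cell-level counts into group-level rows.

    Cells absent from ``grouping`` are dropped (with their counts).
    """
    df = table.df.copy()
    df["group"] = df["unit"].map(grouping)
    df = df.dropna(subset=["group"])
    out = (
        df.groupby(["event_id", "group"], as_index=False)[["I", "E"]]
        .sum()
        .rename(columns={"group": "unit"})
    )
    return ASECountTable(out)


def clopper_pearson(I: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval for I successes in n."""
    alpha = 1.0 - conf_level
    lo = 0.0 if I == 0 else float(beta_dist.ppf(alpha / 2, I, n - I + 1))
    hi = 1.0 if I == n else float(beta_dist.ppf(1 - alpha / 2, I + 1, n - I))
    return lo, hi


def compute_psi(I: int, E: int, conf_level: float = 0.95) -> PSIEstimate:
    """PSI = I/(I+E) with its exact binomial confidence interval."""
    n = I + E
    if n < 1:
        raise ValueError("PSI undefined for I + E = 0")
    lo, hi = clopper_pearson(I, n, conf_level)
    return PSIEstimate(psi=I / n, ci_low=lo, ci_high=hi, I=I, E=E)


def psi_table(table: ASECountTable, conf_level: float = 0.95) -> pd.DataFrame:
    """PSI and CI per (event, unit) row of a count table."""
    recs = []
    for r in table.df.itertuples(index=False):
        if r.I + r.E < 1:
            continue
        est = compute_psi(int(r.I), int(r.E), conf_level)
        recs.append(
            {
                "event_id": r.event_id,
                "unit": r.unit,
                "I": r.I,
                "E": r.E,
                "psi": est.psi,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    return pd.DataFrame(
        recs,
        columns=["event_id", "unit", "I", "E", "psi", "ci_low", "ci_high"],
    )
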