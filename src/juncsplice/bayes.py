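"""Beta-binomial Bayesian PSI for embedding, and its permutation null.

Per event i, the latent PSI across (sample, cell type) aggregation
units is modelled as Beta(a_i, b_i), so observed inclusion counts I
out of n = I + E are beta-binomial. The prior (a_i, b_i) is fitted by
direct maximum likelihood; the posterior for a unit with counts (I, E)
is Beta(a_i + I, b_i + E) and its *median* is the inferred PSI. Units
with no coverage receive the prior median (imputation).

The permutation null destroys splicing information while keeping
coverage: for each unit, p ~ Beta(a_i, b_i), then I' ~ Binomial(n, p),
E' = n - I', so every I + E total is preserved exactly. Priors are not
refit on permuted data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import beta as beta_dist
from scipy.stats import betabinom

PRIOR_BOUND = (1e-3, 1e6)

# study-condition defaults for the embedding filters
MIN_SAMPLE_READS = 1_000_000
MIN_CELLTYPE_READS = 5000
MIN_DETECTION_FRACTION = 0.8


@dataclass(frozen=True)
class BetaPrior:
    event_id: str
    a: float
    b: float
    clamped: bool = False

    @property
    def median(self) -> float:
        return float(beta_dist.ppf(0.5, self.a, self.b))


def filter_for_embedding(
    counts: pd.DataFrame,
    min_sample_reads: int = MIN_SAMPLE_READS,
    min_celltype_reads: int = MIN_CELLTYPE_READS,
    min_detection_fraction: float = MIN_DETECTION_FRACTION,
) -> tuple[list[str], pd.DataFrame]:
    """Coverage filters for the embedding matrix.

    ``counts`` has columns event_id, sample, cell_type, I, E. Units are
    (sample, cell_type) pairs. Drops samples with < min_sample_reads
    total junction reads, units with < min_celltype_reads, and events
    detected (I + E >= 1) in fewer than min_detection_fraction of the
    retained samples. Returns (event_ids, filtered counts).
    """
    df = counts.copy()
    df["n"] = df["I"] + df["E"]
    sample_tot = df.groupby("sample")["n"].sum()
    keep_samples = sample_tot[sample_tot >= min_sample_reads].index
    df = df[df["sample"].isin(keep_samples)]
    unit_tot = df.groupby(["sample", "cell_type"])["n"].sum()
    keep_units = unit_tot[unit_tot >= min_celltype_reads].index
    df = df.set_index(["sample", "cell_type"]).loc[
        lambda d: d.index.isin(keep_units)
    ].reset_index()
    if df.empty:
        raise ValueError("no units pass the embedding coverage filters")
    n_samples = df["sample"].nunique()
    det = (
        df[df["n"] >= 1]
        .groupby("event_id")["sample"]
        .nunique()
        .div(n_samples)
    )
    events = sorted(det[det >= min_detection_fraction].index)
    return events, df[df["event_id"].isin(events)].drop(columns="n")


def _betabinom_negll(log_ab: np.ndarray, I: np.ndarray, n: np.ndarray) -> float:
    a, b = np.exp(log_ab)
    return -float(np.sum(betabinom.logpmf(I, n, a, b)))


def fit_beta_prior(
    event_id: str, I: Sequence[int], E: Sequence[int]
) -> BetaPrior:
    """Maximum-likelihood Beta(a, b) prior from (I, E) pairs across units.

    Started from method-of-moments estimates; parameters are bounded to
    [1e-3, 1e6] and flagged ``clamped`` when the optimum hits a bound
    (degenerate data with all PSI at 0 or 1).
    """
    I = np.asarray(I, dtype=float)
    E = np.asarray(E, dtype=float)
    n = I + E
    mask = n >= 1
    I, n = I[mask], n[mask]
    if len(I) < 3:
        raise ValueError("prior fitting needs >= 3 units with coverage")
    p = I / n
    m, v = float(np.mean(p)), float(np.var(p))
    m = min(max(m, 1e-3), 1 - 1e-3)
    if v < 1e-6:
        s0 = 100.0
    else:
        s0 = max(m * (1 - m) / v - 1.0, 0.01)
    x0 = np.log(np.clip([m * s0, (1 - m) * s0], *PRIOR_BOUND))
    lb, ub = np.log(PRIOR_BOUND[0]), np.log(PRIOR_BOUND[1])
    res = minimize(
        _betabinom_negll,
        x0,
        args=(I, n),
        method="L-BFGS-B",
        bounds=[(lb, ub), (lb, ub)],
    )
    a, b = np.exp(res.x)
    eps = 1e-6
    clamped = bool(
        np.any(res.x <= lb + eps) or np.any(res.x >= ub - eps)
    )
    return BetaPrior(event_id=event_id, a=float(a), b=float(b), clamped=clamped)


def posterior_psi(prior: BetaPrior, I: int, E: int) -> float:
    """Median of the posterior Beta(a + I, b + E); prior median if no data."""
    return float(beta_dist.ppf(0.5, prior.a + I, prior.b + E))


def permute_counts(
    counts: pd.DataFrame, priors: dict[str, BetaPrior], rng: np.random.Generator
) -> pd.DataFrame:
    """Splicing-information-destroying resample at fixed coverage.

    For each row, p ~ Beta(a, b) then I' ~ Binomial(I + E, p); rows
    with I + E = 0 are unchanged.
    """
    out = counts.copy()
    n = (out["I"] + out["E"]).to_numpy()
    new_I = np.zeros(len(out), dtype=int)
    for idx, (event_id, ni) in enumerate(zip(out["event_id"], n)):
        if ni == 0:
            continue
        pr = priors[event_id]
        p = rng.beta(pr.a, pr.b)
        new_I[idx] = rng.binomial(int(ni), p)
    out["I"] = new_I
    out["E"] = n - new_I
    return out


def build_matrix(
    counts: pd.DataFrame,
    events: Sequence[str],
    priors: dict[str, BetaPrior],
    provenance: str = "observed",
) -> pd.DataFrame:
    """Dense (sample, cell_type) x event matrix of inferred PSI values.

    Missing (zero-coverage) cells are imputed with the prior median.
    The result feeds standard PCA/tSNE; rows are labelled by the
    MultiIndex (sample, cell_type) and ``provenance`` is stored in
    ``df.attrs``.
    """
    units = sorted(set(zip(counts["sample"], counts["cell_type"])))
    lookup = {
        (r.sample, r.cell_type, r.event_id): (int(r.I), int(r.E))
        for r in counts.itertuples(index=False)
    }
    data = np.empty((len(units), len(events)))
    for i, (s, c) in enumerate(units):
        for j, ev in enumerate(events):
            I, E = lookup.get((s, c, ev), (0, 0))
            data[i, j] = posterior_psi(priors[ev], I, E)
    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(units, names=["sample", "cell_type"]),
        columns=list(events),
    )
    df.attrs["provenance"] = provenance
    return df


def fit_all_priors(counts: pd.DataFrame, events: Sequence[str]) -> dict[str, BetaPrior]:
    """Fit one beta prior per event from unit-level counts."""
    priors = {}
    for ev in events:
        sub = counts[counts["event_id"] == ev]
        priors[ev] = fit_beta_prior(ev, sub["I"].to_numpy(), sub["E"].to_numpy())
    return priors
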