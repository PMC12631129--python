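"""Differential splicing: coverage/noise filters, binomial-GLM LRT,
BH correction, and expression-matched enrichment testing.

The test compares nested binomial regressions with logit link on
(I, E) rows — H1: (I, E) ~ sample + group vs H0: (I, E) ~ sample (or
intercept-only when no sample covariate applies) — by likelihood-ratio
test with df equal to the number of extra parameters. Events with
BH-adjusted p (FDR) < 0.01 and |dPSI| > 0.2 are called "specific";
dPSI is computed from pooled counts per group, never as a mean of
per-row PSIs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, fisher_exact
from statsmodels.stats.multitest import multipletests

from juncsplice.quantify import clopper_pearson

FDR_CUT = 0.01
DPSI_CUT = 0.2
MIN_TOTAL = 10
NOISE_LO = 0.05
NOISE_HI = 0.95


@dataclass
class DiffSplicingResult:
    event_id: str
    psi_group_a: float
    psi_group_b: float
    delta_psi: float
    p_value: float
    fdr: float = np.nan
    specific: bool = False
    separation_flag: bool = False


def coverage_filter(
    counts: pd.DataFrame, min_total: int = MIN_TOTAL
) -> list[str]:
    """Events with pooled I >= min_total, pooled E >= min_total and a
    junction-read total >= min_total in each of the two groups.

    ``counts`` columns: event_id, group, I, E (one row per sample or
    unit).
    """
    out = []
    for ev, sub in counts.groupby("event_id"):
        if sub["I"].sum() < min_total or sub["E"].sum() < min_total:
            continue
        grp_tot = sub.groupby("group").apply(
            lambda g: g["I"].sum() + g["E"].sum(), include_groups=False
        )
        if len(grp_tot) < 2 or (grp_tot < min_total).any():
            continue
        out.append(ev)
    return sorted(out)


def noise_filter(
    L_a: float, H_a: float, L_b: float, H_b: float,
    lo: float = NOISE_LO, hi: float = NOISE_HI,
) -> bool:
    """Four-condition splicing-noise filter on the pooled-PSI 95% CI
    bounds of the two groups; all four must hold:

    1. L_a > lo or L_b > lo
    2. H_a < hi or H_b < hi
    3. L_a > lo or H_a < hi
    4. L_b > lo or H_b < hi
    """
    return (
        (L_a > lo or L_b > lo)
        and (H_a < hi or H_b < hi)
        and (L_a > lo or H_a < hi)
        and (L_b > lo or H_b < hi)
    )


def noise_filter_from_counts(
    counts: pd.DataFrame, lo: float = NOISE_LO, hi: float = NOISE_HI
) -> bool:
    """Noise filter evaluated on pooled counts of the two groups."""
    groups = sorted(counts["group"].unique())
    if len(groups) != 2:
        raise ValueError("noise filter needs exactly two groups")
    bounds = []
    for g in groups:
        sub = counts[counts["group"] == g]
        I, E = int(sub["I"].sum()), int(sub["E"].sum())
        bounds.append(clopper_pearson(I, I + E))
    (L_a, H_a), (L_b, H_b) = bounds
    return noise_filter(L_a, H_a, L_b, H_b, lo, hi)


def _fit_binomial(endog: np.ndarray, X: np.ndarray) -> float:
    """Log-likelihood of a binomial GLM (logit link) fit."""
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    return float(model.fit(maxiter=200).llf)


def _design(df: pd.DataFrame, with_group: bool, with_sample: bool) -> np.ndarray:
    cols = [np.ones(len(df))]
    if with_sample:
        d = pd.get_dummies(df["sample"], drop_first=True, dtype=float)
        cols.extend(d[c].to_numpy() for c in d.columns)
    if with_group:
        d = pd.get_dummies(df["group"], drop_first=True, dtype=float)
        cols.extend(d[c].to_numpy() for c in d.columns)
    return np.column_stack(cols)


def glm_lrt(
    counts: pd.DataFrame, use_sample_covariate: bool | None = None
) -> tuple[float, float, bool]:
    """Likelihood-ratio test for the group effect on splicing.

    ``counts`` columns: I, E, group and optionally sample. Rows with
    I + E = 0 are dropped. Returns (p_value, delta_psi, separation_flag);
    delta_psi is pooled PSI(first group) - pooled PSI(second group) in
    sorted group order. Complete separation (a group entirely at PSI 0
    or 1) is handled by adding 0.5 to every I and E, flagged.
    """
    df = counts.copy()
    df = df[(df["I"] + df["E"]) >= 1].reset_index(drop=True)
    groups = sorted(df["group"].unique())
    if len(groups) != 2 or len(df) < 2:
        raise ValueError("glm_lrt needs two group levels over >= 2 rows")
    if use_sample_covariate is None:
        # the sample covariate only identifies when at least one sample is
        # observed in both groups (cell-type-within-sample comparisons);
        # for group-of-samples designs H0 is intercept-only
        use_sample_covariate = (
            "sample" in df.columns
            and df["sample"].nunique() > 1
            and (df.groupby("sample")["group"].nunique() > 1).any()
        )

    pooled = df.groupby("group")[["I", "E"]].sum()
    psi = pooled["I"] / (pooled["I"] + pooled["E"])
    delta = float(psi[groups[0]] - psi[groups[1]])

    sep = bool(
        ((pooled["I"] == 0) | (pooled["E"] == 0)).any()
    )
    work = df.copy()
    if sep:
        work["I"] = work["I"] + 0.5
        work["E"] = work["E"] + 0.5

    endog = work[["I", "E"]].to_numpy(dtype=float)
    X1 = _design(work, with_group=True, with_sample=use_sample_covariate)
    X0 = _design(work, with_group=False, with_sample=use_sample_covariate)
    rank1 = np.linalg.matrix_rank(X1)
    if rank1 < X1.shape[1]:
        raise ValueError("singular design matrix: aliased group/sample columns")
    ll1 = _fit_binomial(endog, X1)
    ll0 = _fit_binomial(endog, X0)
    dof = X1.shape[1] - X0.shape[1]
    stat = max(0.0, 2.0 * (ll1 - ll0))
    p = float(chi2.sf(stat, dof))
    return p, delta, sep


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_specific(
    results: list[DiffSplicingResult],
    fdr_cut: float = FDR_CUT,
    dpsi_cut: float = DPSI_CUT,
) -> list[DiffSplicingResult]:
    """BH-adjust and flag events with FDR < fdr_cut and |dPSI| > dpsi_cut."""
    fdrs = bh_adjust([r.p_value for r in results])
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
        r.specific = bool(f < fdr_cut and abs(r.delta_psi) > dpsi_cut)
    return results


def differential_splicing(
    counts: pd.DataFrame,
    min_total: int = MIN_TOTAL,
    fdr_cut: float = FDR_CUT,
    dpsi_cut: float = DPSI_CUT,
    apply_noise_filter: bool = True,
) -> list[DiffSplicingResult]:
    """Full two-group differential pipeline over a per-sample table.

    ``counts`` columns: event_id, group, I, E and optionally sample.
    Applies the coverage and noise filters, the binomial-GLM LRT per
    event, BH correction across tested events, and the specific call.
    """
    keep = coverage_filter(counts, min_total)
    results = []
    groups = sorted(counts["group"].unique())
    for ev in keep:
        sub = counts[counts["event_id"] == ev]
        if apply_noise_filter and not noise_filter_from_counts(sub):
            continue
        p, delta, sep = glm_lrt(sub)
        pooled = sub.groupby("group")[["I", "E"]].sum()
        psi = pooled["I"] / (pooled["I"] + pooled["E"])
        results.append(
            DiffSplicingResult(
                event_id=ev,
                psi_group_a=float(psi[groups[0]]),
                psi_group_b=float(psi[groups[1]]),
                delta_psi=delta,
                p_value=p,
                separation_flag=sep,
            )
        )
    return call_specific(results, fdr_cut, dpsi_cut)


def _match_background(
    test_expr: pd.Series,
    bg_expr: pd.Series,
    rng: np.random.Generator,
    n_bins: int = 10,
) -> list:
    """Down-sample background genes per expression decile so the bin
    distribution matches the test genes' (proportionally)."""
    all_expr = pd.concat([test_expr, bg_expr])
    edges = np.unique(np.quantile(all_expr, np.linspace(0, 1, n_bins + 1)))
    t_bins = np.clip(np.searchsorted(edges, test_expr, side="right") - 1, 0, len(edges) - 2)
    b_bins = np.clip(np.searchsorted(edges, bg_expr, side="right") - 1, 0, len(edges) - 2)
    t_frac = pd.Series(t_bins).value_counts(normalize=True)
    b_counts = pd.Series(b_bins).value_counts()
    # scale so that no bin is over-demanded
    ratios = [
        b_counts.get(b, 0) / t_frac[b] for b in t_frac.index if t_frac[b] > 0
    ]
    total = int(min(ratios)) if ratios else 0
    chosen = []
    bg_genes = np.asarray(bg_expr.index)
    for b, frac in t_frac.items():
        pool = bg_genes[b_bins == b]
        k = min(len(pool), int(round(frac * total)))
        if k > 0:
            chosen.extend(rng.choice(pool, size=k, replace=False))
    return chosen


def enrichment_test(
    test_genes: set,
    background_genes: set,
    gene_sets: dict[str, set],
    expression: pd.Series,
    seed: int = 0,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Expression-matched one-tailed Fisher enrichment over gene sets.

    Background genes are down-sampled per expression decile to match
    the test genes' expression distribution, then each gene set is
    tested with a one-tailed (greater) Fisher exact test on the 2x2
    table of set membership x test/background, BH-corrected.
    """
    rng = np.random.default_rng(seed)
    test = sorted(test_genes & set(expression.index))
    bg = sorted((background_genes - test_genes) & set(expression.index))
    matched = _match_background(expression[test], expression[bg], rng)
    recs = []
    for name, members in gene_sets.items():
        a = sum(1 for g in test if g in members)
        b = len(test) - a
        c = sum(1 for g in matched if g in members)
        d = len(matched) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        recs.append({"gene_set": name, "odds_ratio": odds, "p_value": p})
    df = pd.DataFrame(recs)
    if len(df):
        df["fdr"] = bh_adjust(df["p_value"])
        df["enriched"] = df["fdr"] < fdr_cut
    return df


def results_to_frame(results: list[DiffSplicingResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
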