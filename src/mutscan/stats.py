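"""Significance testing, FDR control, QC correlations and evidence calibration.

Per-variant significance is assessed by a two-tailed Student's t-test of the
log-transformed replicate enrichments against the pooled log enrichments of
all synonymous-variant replicates; an F-test on the two variances selects
between the equal-variance and Welch forms.  P values are corrected with
the two-stage step-up FDR procedure (Benjamini, Krieger & Yekutieli 2006)
at Q = 1%.

Assay-level evidence strength follows the OddsPath framework: among
variants with prior clinical labels (pathogenic/benign), the posterior odds
of pathogenicity given an abnormal (or normal) assay readout are compared
against the label prior, and mapped to ACMG PS3/BS3 evidence tiers.

QC utilities cover replicate correlation, codon-consistency correlation
(different nucleotide changes encoding the same amino acid change),
hydropathy association of gain/loss-of-function classes, and piecewise
concordance with external prediction scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

#: Kyte–Doolittle hydropathy index per amino acid (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


def log_t_test(
    variant_reps: np.ndarray,
    synonymous_pool_reps: np.ndarray,
    variance_alpha: float = 0.05,
) -> dict:
    """t-test of a variant's log enrichments against the synonymous pool.

    Both groups are natural-log transformed (the t statistic is invariant
    to the log base).  A two-sided F-test on the variances decides between
    the equal-variance and Welch t-tests.  All values must be positive;
    returns dict with t, p and variance_test_p.
    """
    v = np.asarray(variant_reps, dtype=float)
    s = np.asarray(synonymous_pool_reps, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 variant replicates")
    if len(s) < 10:
        raise ValueError("synonymous pool must have >= 10 values")
    if (v <= 0).any() or (s <= 0).any():
        raise ValueError("enrichment values must be > 0 before log transform")
    lv, ls = np.log(v), np.log(s)
    f = np.var(lv, ddof=1) / np.var(ls, ddof=1)
    df1, df2 = len(lv) - 1, len(ls) - 1
    if np.isnan(f) or f == 0 or np.isinf(f):
        var_p = np.nan
    else:
        cdf = sps.f.cdf(f, df1, df2)
        var_p = 2 * min(cdf, 1 - cdf)
    equal_var = not (var_p < variance_alpha)
    t, p = sps.ttest_ind(lv, ls, equal_var=equal_var)
    return {"t": float(t), "p": float(p), "variance_test_p": float(var_p),
            "equal_var": equal_var}


def test_table(
    enrichment: pd.DataFrame,
    is_synonymous: pd.Series,
    assayed: pd.Series | None = None,
    Q: float = 0.01,
) -> pd.DataFrame:
    """Per-variant t-tests vs the pooled synonymous replicates, with FDR.

    ``enrichment`` holds one column per replicate.  Returns t, p, q,
    discovery and variance_test_p per testable variant.
    """
    mask = is_synonymous.reindex(enrichment.index, fill_value=False)
    if assayed is not None:
        mask &= assayed.reindex(enrichment.index, fill_value=False)
    pool = enrichment[mask].to_numpy().ravel()
    pool = pool[np.isfinite(pool) & (pool > 0)]
    rows = {}
    for key, reps in enrichment.iterrows():
        vals = reps.to_numpy(dtype=float)
        if assayed is not None and not assayed.get(key, True):
            continue
        if (vals <= 0).any() or not np.isfinite(vals).all():
            continue
        res = log_t_test(vals, pool)
        rows[key] = res
    out = pd.DataFrame.from_dict(rows, orient="index")
    if len(out):
        q, disc = bky_fdr(out["p"].to_numpy(), Q)
        out["q"] = q
        out["discovery"] = disc
    return out


def bky_fdr(p_values: np.ndarray, Q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage step-up FDR control (Benjamini–Krieger–Yekutieli 2006).

    Returns (q_values, discovery_flags) at level ``Q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=Q, method="fdr_tsbky")
    return q, reject


def replicate_correlation(score_matrix: pd.DataFrame) -> pd.DataFrame:
    """All pairwise replicate correlations (Pearson and Spearman).

    Constant columns yield undefined coefficients, reported as NaN.
    """
    cols = list(score_matrix.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 replicates")
    rows = []
    for a, b in combinations(cols, 2):
        x = score_matrix[a].to_numpy(dtype=float)
        y = score_matrix[b].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
            pearson = spearman = np.nan
        else:
            pearson = sps.pearsonr(x, y).statistic
            spearman = sps.spearmanr(x, y).statistic
        rows.append({"rep_a": a, "rep_b": b, "pearson": pearson,
                     "spearman": spearman, "n": len(x)})
    return pd.DataFrame(rows)


def codon_consistency(
    medians: pd.Series,
    design: pd.DataFrame,
) -> dict:
    """Correlation between nucleotide variants encoding the same aa change.

    For every amino acid change encoded by >= 2 nucleotide variants, the
    variant at the lowest CDS position is paired with each subsequent one
    (deterministic enumeration), and the paired median enrichments are
    correlated.  Returns Pearson/Spearman coefficients and the pair count.
    """
    df = design.loc[design.index.intersection(medians.index)].copy()
    df["median"] = medians.reindex(df.index)
    df = df[df["median"].notna()]
    first_vals, other_vals = [], []
    for _, grp in df.groupby("aa_change", sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values(["cds_pos", "alt_nt"])
        anchor = grp["median"].iloc[0]
        for v in grp["median"].iloc[1:]:
            first_vals.append(anchor)
            other_vals.append(v)
    if len(first_vals) < 3:
        return {"pearson": np.nan, "spearman": np.nan, "n_pairs": len(first_vals)}
    x, y = np.array(first_vals), np.array(other_vals)
    return {
        "pearson": float(sps.pearsonr(x, y).statistic),
        "spearman": float(sps.spearmanr(x, y).statistic),
        "n_pairs": len(x),
    }


@dataclass(frozen=True)
class OddsPathThresholds:
    """ACMG functional-evidence tier cut points for OddsPath."""

    pathogenic: tuple[tuple[float, str], ...] = (
        (350.0, "very strong"),
        (18.7, "strong"),
        (4.3, "moderate"),
        (2.1, "supporting"),
    )
    benign: tuple[tuple[float, str], ...] = (
        (0.053, "strong"),
        (0.23, "moderate"),
        (0.48, "supporting"),
    )

    def pathogenic_tier(self, odds: float) -> str:
        for bound, tier in self.pathogenic:
            if odds >= bound:
                return tier
        return "indeterminate"

    def benign_tier(self, odds: float) -> str:
        for bound, tier in self.benign:
            if odds <= bound:
                return tier
        return "indeterminate"


def odds_path(
    assay_calls: pd.Series,
    control_labels: pd.Series,
    thresholds: OddsPathThresholds | None = None,
) -> dict:
    """OddsPath calibration of an assay against labelled clinical controls.

    ``control_labels`` maps variants to {pathogenic, benign};
    ``assay_calls`` maps variants to {functionally_abnormal,
    functionally_normal}.  With P1 the pathogenic fraction among all
    labelled controls and P2 the pathogenic fraction among controls with a
    given assay readout, OddsPath = [P2 x (1 - P1)] / [(1 - P2) x P1].  A
    0.5-count continuity correction is applied (and flagged) when P2 is
    degenerate (0 or 1).
    """
    thresholds = thresholds or OddsPathThresholds()
    idx = control_labels.index.intersection(assay_calls.index)
    labels = control_labels.loc[idx]
    calls = assay_calls.loc[idx]
    n_path = int((labels == "pathogenic").sum())
    n_ben = int((labels == "benign").sum())
    if n_path == 0 or n_ben == 0:
        raise ValueError("need both pathogenic and benign labelled controls")
    p1 = n_path / (n_path + n_ben)

    def posterior(mask: pd.Series) -> tuple[float, bool]:
        k = int((labels[mask] == "pathogenic").sum())
        m = int(mask.sum())
        if m == 0:
            return np.nan, True
        p2 = k / m
        if p2 in (0.0, 1.0):
            return (k + 0.5) / (m + 1.0), True
        return p2, False

    p2_path, corr_path = posterior(calls == "functionally_abnormal")
    p2_ben, corr_ben = posterior(calls == "functionally_normal")

    def odds(p2: float) -> float:
        return (p2 * (1 - p1)) / ((1 - p2) * p1)

    op = odds(p2_path)
    ob = odds(p2_ben)
    return {
        "P1": p1,
        "P2_path": p2_path,
        "P2_benign": p2_ben,
        "odds_path_pathogenic": op,
        "odds_path_benign": ob,
        "tier_pathogenic": thresholds.pathogenic_tier(op),
        "tier_benign": thresholds.benign_tier(ob),
        "continuity_corrected": corr_path or corr_ben,
        "n_pathogenic": n_path,
        "n_benign": n_ben,
    }


def hydropathy_association(
    classification: pd.DataFrame,
    design: pd.DataFrame,
    scale: dict[str, float] | None = None,
) -> dict:
    """Association of GoF/LoF classes with hydrophobicity change.

    For missense variants, delta-hydropathy = scale(alt_aa) - scale(ref_aa).
    GoF (hit) and LoF classes are each compared to neutral variants with a
    two-sided Wilcoxon rank-sum test (exact for small samples); a 2x2
    hydrophobicity-increasing/decreasing x class table is tested with
    Fisher's exact test.
    """
    scale = scale or KYTE_DOOLITTLE
    df = design.loc[design.index.intersection(classification.index)]
    df = df[df["consequence"] == "missense"]
    calls = classification.reindex(df.index)
    dh = df["alt_aa"].map(scale) - df["ref_aa"].map(scale)
    hit = (calls["hit"] == True)  # noqa: E712 -- NA-tolerant
    lof = (calls["lof"] == True)  # noqa: E712
    neutral = ~hit & ~lof & calls["assayed"]

    def ranksum(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) == 0 or len(b) == 0:
            return np.nan
        method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
        return float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )

    gof_dh = dh[hit].to_numpy()
    lof_dh = dh[lof].to_numpy()
    neu_dh = dh[neutral].to_numpy()
    table = np.array(
        [
            [(gof_dh > 0).sum(), (gof_dh < 0).sum()],
            [(neu_dh > 0).sum(), (neu_dh < 0).sum()],
        ]
    )
    fisher_p = (
        float(sps.fisher_exact(table).pvalue) if table.sum() else np.nan
    )
    return {
        "gof_median_dh": float(np.median(gof_dh)) if len(gof_dh) else np.nan,
        "lof_median_dh": float(np.median(lof_dh)) if len(lof_dh) else np.nan,
        "neutral_median_dh": float(np.median(neu_dh)) if len(neu_dh) else np.nan,
        "gof_vs_neutral_p": ranksum(gof_dh, neu_dh),
        "lof_vs_neutral_p": ranksum(lof_dh, neu_dh),
        "fisher_2x2_p": fisher_p,
        "contingency": table,
    }


def exact_rank_sum_p(group_a, group_b, alternative: str = "greater") -> float:
    """One-sided exact Wilcoxon rank-sum p value (full enumeration for small n)."""
    return float(
        sps.mannwhitneyu(group_a, group_b, alternative=alternative,
                         method="exact").pvalue
    )


def prediction_score_correlation(
    medians: pd.Series,
    external_scores: pd.Series,
    min_stratum: int = 10,
) -> dict:
    """Spearman correlation with an external prediction score, piecewise.

    Computed separately for variants with median enrichment > 1 and < 1
    (plus overall); a stratum with fewer than ``min_stratum`` variants is
    reported as NaN.
    """
    idx = medians.index.intersection(external_scores.index)
    m = medians.loc[idx].astype(float)
    s = external_scores.loc[idx].astype(float)
    ok = m.notna() & s.notna()
    m, s = m[ok], s[ok]

    def rho(mask: pd.Series) -> float:
        if mask.sum() < min_stratum:
            return np.nan
        return float(sps.spearmanr(m[mask], s[mask]).statistic)

    return {
        "rho_enriched": rho(m > 1),
        "rho_depleted": rho(m < 1),
        "rho_overall": rho(pd.Series(True, index=m.index)),
        "n_enriched": int((m > 1).sum()),
        "n_depleted": int((m < 1).sum()),
        "n_overall": int(len(m)),
    }
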