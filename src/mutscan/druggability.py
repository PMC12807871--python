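"""Integration of activation and resistance screens into a druggability catalog.

Each variant carries three boolean phenotypes — activating, pemigatinib
resistant, futibatinib resistant — whose seven non-empty combinations
(2^3 - 1) define the phenotype groups; variants negative in all three are
"none".  A variant is druggable when it is activating and remains sensitive
to at least one inhibitor.  Downstream utilities score concordance of the
catalog against clinical resistance cases (lead mutation = the observed
mutation with the strongest resistance enrichment for the administered
drug), stratify activation by somatic recurrence counts, and compare amino
acid effects across paralogs through a user-supplied alignment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = (
    "act_sensitive_both",
    "act_pemR_only",
    "act_futR_only",
    "act_dual_resistant",
    "pemR_only",
    "futR_only",
    "dual_resistant",
    "none",
)

#: Inhibitor -> screened-drug mapping; erdafitinib (reversible, untested)
#: is evaluated against the pemigatinib screen.
DEFAULT_DRUG_MAP = {
    "pemigatinib": "pem",
    "futibatinib": "fut",
    "erdafitinib": "pem",
}


def phenotype_group(act: bool, pem: bool, fut: bool) -> str:
    """Map the three phenotype flags to one of the 7 groups (or none)."""
    if act:
        if pem and fut:
            return "act_dual_resistant"
        if pem:
            return "act_pemR_only"
        if fut:
            return "act_futR_only"
        return "act_sensitive_both"
    if pem and fut:
        return "dual_resistant"
    if pem:
        return "pemR_only"
    if fut:
        return "futR_only"
    return "none"


def is_druggable(act: bool, pem: bool, fut: bool) -> bool:
    """Activating and sensitive to at least one inhibitor."""
    return act and not (pem and fut)


def integrate(
    activation_calls: pd.DataFrame,
    pem_calls: pd.DataFrame,
    fut_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Combine the three per-screen call tables into DruggabilityRecords.

    Variants missing from any table are kept but flagged ``partial`` and
    assigned no group.  Returns a table with per-screen tiers, group and
    druggable flag.
    """
    universe = activation_calls.index.union(pem_calls.index).union(fut_calls.index)
    out = pd.DataFrame(index=universe)

    def flags(calls: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        hit = calls["hit"].reindex(universe)
        tier = calls["tier"].reindex(universe, fill_value="missing")
        return hit, tier

    act_hit, out["activation_tier"] = flags(activation_calls)
    pem_hit, out["pem_tier"] = flags(pem_calls)
    fut_hit, out["fut_tier"] = flags(fut_calls)
    out["partial"] = act_hit.isna() | pem_hit.isna() | fut_hit.isna()

    groups, druggable = [], []
    for a, p, f, partial in zip(
        act_hit.map(lambda v: bool(v) if pd.notna(v) else False),
        pem_hit.map(lambda v: bool(v) if pd.notna(v) else False),
        fut_hit.map(lambda v: bool(v) if pd.notna(v) else False),
        out["partial"],
    ):
        if partial:
            groups.append("partial")
            druggable.append(False)
        else:
            groups.append(phenotype_group(bool(a), bool(p), bool(f)))
            druggable.append(is_druggable(bool(a), bool(p), bool(f)))
    out["group"] = groups
    out["druggable"] = druggable
    return out


def group_summary(records: pd.DataFrame) -> pd.Series:
    """Variant counts per phenotype group, in canonical order."""
    counts = records["group"].value_counts()
    return pd.Series({g: int(counts.get(g, 0)) for g in GROUPS})


def druggable_count(records: pd.DataFrame) -> int:
    return int(records["druggable"].sum())


def export_catalog(
    records: pd.DataFrame,
    design: pd.DataFrame,
    out_path: str | Path,
    medians: dict[str, pd.Series] | None = None,
    stats: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write the integrated catalog TSV (one row per nucleotide variant).

    Rows are ordered deterministically by (gene, CDS position, alt base) so
    re-export is byte-identical.  Optional ``medians`` adds per-screen
    median-enrichment columns; optional ``stats`` adds q values.
    """
    cat = design[["gene", "cds_pos", "alt_nt", "hgvs_c", "hgvs_p"]].copy()
    cat = cat.join(records, how="left")
    if medians:
        for screen, med in medians.items():
            cat[f"median_{screen}"] = med.reindex(cat.index)
    if stats is not None and "q" in stats:
        cat["q_value"] = stats["q"].reindex(cat.index)
    cat = cat.sort_values(["gene", "cds_pos", "alt_nt"], kind="mergesort")
    cat.to_csv(out_path, sep="\t", index_label="key")
    return cat


def clinical_concordance(
    cases: pd.DataFrame,
    catalog: pd.DataFrame,
    medians: dict[str, pd.Series],
    drug_map: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Lead-mutation concordance of the catalog with clinical cases.

    ``cases`` has columns case_id, drug and hgvs (variant key into the
    catalog); one row per observed mutation.  For each case the
    administered inhibitor is mapped to a screened drug, the observed
    mutation with the maximum median enrichment in that resistance screen
    becomes the lead mutation, and the case is concordant when the lead is
    a resistance hit at any tier.  Observed mutations absent from the
    catalog are excluded with a warning column.  Returns the per-case table
    and a summary with the concordant fraction and integer percentage.
    """
    drug_map = drug_map or DEFAULT_DRUG_MAP
    rows = []
    for case_id, grp in cases.groupby("case_id", sort=True):
        drugs = grp["drug"].unique()
        if len(drugs) != 1:
            raise ValueError(f"case {case_id} has multiple drugs; split into cases")
        screen = drug_map[drugs[0]]
        med = medians[screen]
        tier_col = f"{screen}_tier"
        known = grp[grp["hgvs"].isin(catalog.index)]
        n_missing = len(grp) - len(known)
        if known.empty:
            rows.append(
                {"case_id": case_id, "drug": drugs[0], "screen": screen,
                 "lead": None, "lead_enrichment": np.nan, "concordant": False,
                 "n_mutations": len(grp), "n_missing": n_missing}
            )
            continue
        enr = med.reindex(known["hgvs"]).to_numpy(dtype=float)
        lead = known["hgvs"].iloc[int(np.nanargmax(enr))]
        lead_tier = catalog.loc[lead, tier_col]
        concordant = lead_tier not in ("none", "missing", "no_call")
        rows.append(
            {"case_id": case_id, "drug": drugs[0], "screen": screen,
             "lead": lead, "lead_enrichment": float(np.nanmax(enr)),
             "concordant": bool(concordant), "n_mutations": len(grp),
             "n_missing": n_missing}
        )
    table = pd.DataFrame(rows)
    n = len(table)
    k = int(table["concordant"].sum()) if n else 0
    summary = {
        "n_cases": n,
        "n_concordant": k,
        "fraction": k / n if n else np.nan,
        "percent": int(round(100.0 * k / n)) if n else np.nan,
    }
    return table, summary


def recurrence_stratification(
    catalog: pd.DataFrame,
    recurrence_counts: pd.Series,
    bins: tuple = (0, 1, (2, 4), 5),
) -> pd.DataFrame:
    """Fraction of activating variants per somatic recurrence bin.

    ``recurrence_counts`` is keyed like the catalog (missing variants count
    as 0).  Default bins: 0, 1, 2-4, >=5.  The activating flag is any
    activation tier other than none/missing/no_call.
    """
    rec = recurrence_counts.reindex(catalog.index).fillna(0).astype(int)
    activating = ~catalog["activation_tier"].isin(["none", "missing", "no_call"])

    def in_bin(values: pd.Series, b) -> pd.Series:
        if isinstance(b, tuple):
            return (values >= b[0]) & (values <= b[1])
        if b == bins[-1]:
            return values >= b
        return values == b

    rows = []
    for b in bins:
        mask = in_bin(rec, b)
        n = int(mask.sum())
        k = int((activating & mask).sum())
        label = f"{b[0]}-{b[1]}" if isinstance(b, tuple) else (
            f">={b}" if b == bins[-1] and not isinstance(b, tuple) else str(b)
        )
        rows.append(
            {"bin": label, "n_variants": n, "n_activating": k,
             "fraction_activating": k / n if n else np.nan}
        )
    return pd.DataFrame(rows)


def cross_paralog_overlap(
    catalogs: dict[str, pd.DataFrame],
    alignment: dict[str, str],
    medians: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Compare amino-acid-level effects across paralogs via an alignment.

    ``alignment`` maps gene -> aligned (gapped) protein sequence, all of
    equal length.  ``catalogs`` maps gene -> per-variant call table that
    includes design columns ``codon``, ``ref_aa``, ``alt_aa`` and an
    activation ``hit`` flag (plus ``aa_median`` if available).  Output: one
    row per (alignment column, alt amino acid) observed in any gene, with
    each gene's aa-level median enrichment and a conserved_in_k count of
    genes where the change is an activation hit.  Genes gapped at a column
    have missing entries.
    """
    genes = sorted(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must share one length")
    # per gene: alignment column (0-based) -> protein position (1-based)
    col_to_pos: dict[str, dict[int, int]] = {}
    for g in genes:
        pos = 0
        mapping = {}
        for i, ch in enumerate(alignment[g]):
            if ch != "-":
                pos += 1
                mapping[i] = pos
        col_to_pos[g] = mapping

    # per gene: (protein position, alt aa) -> (aa-median, any-hit)
    per_gene: dict[str, dict] = {}
    for g, cat in catalogs.items():
        agg: dict = {}
        for _, row in cat.iterrows():
            key = (int(row["codon"]), row["alt_aa"])
            agg.setdefault(key, {"medians": [], "hit": False})
            med = row.get("aa_median", row.get("median_enrichment", np.nan))
            agg[key]["medians"].append(med)
            if bool(row.get("hit") is True):
                agg[key]["hit"] = True
        per_gene[g] = {
            k: {"median": float(np.nanmedian(v["medians"])), "hit": v["hit"]}
            for k, v in agg.items()
        }

    ncols = lengths.pop()
    rows = []
    for col in range(ncols):
        alts = set()
        for g in genes:
            pos = col_to_pos[g].get(col)
            if pos is None:
                continue
            alts.update(a for (p, a) in per_gene.get(g, {}) if p == pos)
        for alt in sorted(alts):
            row = {"alignment_column": col + 1, "alt_aa": alt}
            k = 0
            for g in genes:
                pos = col_to_pos[g].get(col)
                entry = per_gene.get(g, {}).get((pos, alt)) if pos else None
                row[f"{g}_pos"] = pos
                row[f"{g}_median"] = entry["median"] if entry else np.nan
                row[f"{g}_hit"] = entry["hit"] if entry else False
                if entry and entry["hit"]:
                    k += 1
            row["conserved_in_k"] = k
            rows.append(row)
    return pd.DataFrame(rows)


def alignment_identity_percent(alignment: dict[str, str]) -> float:
    """Percentage of alignment columns identical (and ungapped) in all genes."""
    seqs = list(alignment.values())
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must share one length")
    n = len(seqs[0])
    ident = sum(
        1 for i in range(n)
        if "-" not in {s[i] for s in seqs} and len({s[i] for s in seqs}) == 1
    )
    return 100.0 * ident / n if n else np.nan
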