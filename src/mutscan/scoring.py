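"""Synonymous-normalised enrichment scores from variant counts.

For each selection replicate, counts are converted to within-sample
frequencies, divided by the median plasmid-baseline frequency (across
baseline replicates), and then divided by the median of that ratio over
synonymous variants, which serve as the neutral control population.  The
resulting enrichment score is 1 for a variant behaving like a synonymous
change, >1 for enrichment under selection, and <1 for depletion.

A pseudocount (default 0.5) guards against zero counts; with pseudocount 0
the score is an exact ratio of frequencies and is invariant to sequencing
depth.  Variants absent from the plasmid library (raw count 0 in a strict
majority of baseline replicates) are flagged unassayed and excluded from
hit calling and from the synonymous control pool.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def to_frequencies(counts: pd.Series, pseudocount: float = 0.5) -> pd.Series:
    """Normalise a count column to frequencies summing to 1.

    f_i = (c_i + pseudocount) / sum_j (c_j + pseudocount).  Raises on an
    all-zero column with zero pseudocount (depth undefined).
    """
    if (counts < 0).any():
        raise ValueError("negative counts")
    shifted = counts.astype(float) + pseudocount
    total = shifted.sum()
    if total == 0:
        raise ValueError("all-zero count column with zero pseudocount")
    return shifted / total


def assayed_mask(plasmid_counts: pd.DataFrame) -> pd.Series:
    """True for variants present in the plasmid library.

    A variant with raw count 0 in a strict majority of baseline replicates
    is considered absent and cannot be scored.
    """
    zeros = (plasmid_counts == 0).sum(axis=1)
    return zeros <= plasmid_counts.shape[1] / 2


def baseline_ratio(
    selection_freqs: pd.Series,
    plasmid_freq_replicates: pd.DataFrame,
) -> pd.Series:
    """Selection frequency over the median plasmid-baseline frequency."""
    missing = selection_freqs.index.difference(plasmid_freq_replicates.index)
    if len(missing):
        raise ValueError(f"variants missing from plasmid baseline: {list(missing)[:5]}")
    baseline = plasmid_freq_replicates.median(axis=1)
    return selection_freqs / baseline.reindex(selection_freqs.index)


def synonymous_normalize(
    ratios: pd.Series,
    is_synonymous: pd.Series,
    assayed: pd.Series | None = None,
    min_synonymous: int = 10,
) -> pd.Series:
    """Divide ratios by the median ratio over assayed synonymous variants."""
    mask = is_synonymous.reindex(ratios.index, fill_value=False)
    if assayed is not None:
        mask &= assayed.reindex(ratios.index, fill_value=False)
    n_syn = int(mask.sum())
    if n_syn < min_synonymous:
        raise ValueError(
            f"only {n_syn} assayed synonymous controls; need >= {min_synonymous}"
        )
    return ratios / ratios[mask].median()


def summarize(
    enrichment: pd.DataFrame,
    threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-variant median enrichment and count of replicates at threshold.

    The median over an even number of replicates is the mean of the two
    central values.  Columns: ``median_enrichment``,
    ``n_replicates_ge_threshold``.
    """
    if enrichment.shape[1] < 2:
        raise ValueError("need at least 2 replicates to summarise")
    return pd.DataFrame(
        {
            "median_enrichment": enrichment.median(axis=1),
            "n_replicates_ge_threshold": (enrichment >= threshold).sum(axis=1),
        }
    )


def score_screen(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    plasmid_columns: list[str],
    selection_columns: list[str],
    pseudocount: float = 0.5,
    threshold: float = 1.5,
    min_synonymous: int = 10,
    include_wildtype: bool = False,
) -> pd.DataFrame:
    """Full scoring of one screen: counts -> per-replicate enrichment table.

    ``counts`` is a variants x samples matrix (wild-type rows, named
    ``<tile>:WT``, are excluded from the frequency denominator unless
    ``include_wildtype``).  Returns a table indexed like ``design`` with one
    ``E_<sample>`` column per selection replicate plus ``median_enrichment``,
    ``n_replicates_ge_threshold`` and ``assayed``.
    """
    variant_rows = counts.index.intersection(design.index)
    if not include_wildtype:
        counts = counts.loc[variant_rows]
    missing = design.index.difference(counts.index)
    if len(missing):
        raise ValueError(f"designed variants missing from counts: {list(missing)[:5]}")

    plasmid_raw = counts[plasmid_columns]
    assayed = assayed_mask(plasmid_raw.loc[variant_rows])
    plasmid_freqs = pd.DataFrame(
        {c: to_frequencies(counts[c], pseudocount) for c in plasmid_columns}
    )
    is_syn = design["consequence"] == "synonymous"

    table = pd.DataFrame(index=variant_rows)
    enr_cols = []
    for c in selection_columns:
        sel = to_frequencies(counts[c], pseudocount)
        ratio = baseline_ratio(sel, plasmid_freqs).loc[variant_rows]
        enr = synonymous_normalize(ratio, is_syn, assayed, min_synonymous)
        name = f"E_{c}"
        table[name] = enr
        enr_cols.append(name)
    summary = summarize(table[enr_cols], threshold)
    table["median_enrichment"] = summary["median_enrichment"]
    table["n_replicates_ge_threshold"] = summary["n_replicates_ge_threshold"]
    table["assayed"] = assayed
    return table.reindex(design.index)


def enrichment_columns(table: pd.DataFrame) -> list[str]:
    """The per-replicate enrichment columns of a scored table."""
    return [c for c in table.columns if c.startswith("E_")]


def write_scores(
    table: pd.DataFrame,
    design: pd.DataFrame,
    out_path: str | Path,
    mavedb_path: str | Path | None = None,
) -> None:
    """Write the score table as TSV, optionally with a MAVEdb-style export.

    The MAVEdb-style file has two columns (hgvs_pro, score) with the median
    enrichment per protein-level variant string.
    """
    out = table.copy()
    out.insert(0, "hgvs_p", design["hgvs_p"].reindex(out.index))
    out.insert(0, "hgvs_c", design["hgvs_c"].reindex(out.index))
    out.to_csv(out_path, sep="\t", index_label="key")
    if mavedb_path is not None:
        mave = pd.DataFrame(
            {
                "hgvs_pro": design["hgvs_p"].reindex(table.index),
                "score": table["median_enrichment"],
            }
        )
        mave.to_csv(mavedb_path, sep="\t", index=False)
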