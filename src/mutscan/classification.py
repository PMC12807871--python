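"""Hit calling, effect tiers and loss-of-function classification.

A variant is a hit in a screen when its median enrichment is >= 1.5 and it
reaches that threshold in enough individual replicates (3 of 4 for the
activation screen, 2 of 3 for the resistance screens — the conjunctive
rule guards against single-replicate outliers given the high dispersion of
strongly selected variants).  Hits are tiered by median enrichment:
[1.5, 2.5] potential, (2.5, 5] weak, (5, 10] moderate, (10, inf) strong.
Loss of function is the mirrored depletion call: median <= 0.4 with enough
replicates at or below that threshold, tiered as (0.2, 0.4] inactivating
and <= 0.2 strongly inactivating.  All thresholds are configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mutscan.scoring import enrichment_columns

TIERS = ("none", "potential", "weak", "moderate", "strong")
LOF_TIERS = ("none", "inactivating", "strongly_inactivating")

SCREENS = ("activation", "pem_resistance", "fut_resistance")


@dataclass(frozen=True)
class ScreenConfig:
    """Replicate structure and thresholds for one screen."""

    screen: str
    n_replicates: int
    min_replicates_for_hit: int
    hit_threshold: float = 1.5
    tier_bounds: tuple[float, ...] = (1.5, 2.5, 5.0, 10.0)
    lof_threshold: float = 0.4
    lof_min_replicates: int | None = None
    lof_strong_bound: float = 0.2

    def __post_init__(self):
        if self.min_replicates_for_hit > self.n_replicates:
            raise ValueError("min_replicates_for_hit exceeds n_replicates")
        if list(self.tier_bounds) != sorted(set(self.tier_bounds)):
            raise ValueError("tier bounds must be strictly increasing")

    @property
    def lof_min_reps(self) -> int:
        # LoF replicate rule mirrors the hit rule unless overridden
        return (
            self.lof_min_replicates
            if self.lof_min_replicates is not None
            else self.min_replicates_for_hit
        )

    @classmethod
    def default(cls, screen: str) -> "ScreenConfig":
        """Activation: 3 of 4 replicates; resistance: 2 of 3."""
        if screen == "activation":
            return cls(screen, n_replicates=4, min_replicates_for_hit=3)
        if screen in ("pem_resistance", "fut_resistance"):
            return cls(screen, n_replicates=3, min_replicates_for_hit=2)
        raise ValueError(f"unknown screen {screen!r}")


def call_hit(
    median: float, n_ge_threshold: int, config: ScreenConfig
) -> bool:
    """Median >= threshold AND enough replicates individually at threshold."""
    return (
        median >= config.hit_threshold
        and n_ge_threshold >= config.min_replicates_for_hit
    )


def assign_tier(median: float, config: ScreenConfig | None = None) -> str:
    """Effect tier of a hit from its median enrichment (right-closed bins)."""
    bounds = config.tier_bounds if config else (1.5, 2.5, 5.0, 10.0)
    if median < bounds[0]:
        raise ValueError(f"median {median} below hit threshold {bounds[0]}")
    if median <= bounds[1]:
        return "potential"
    if median <= bounds[2]:
        return "weak"
    if median <= bounds[3]:
        return "moderate"
    return "strong"


def call_lof(
    median: float,
    n_le_threshold: int,
    config: ScreenConfig,
) -> tuple[bool, str]:
    """Depletion call mirroring the hit rule at the low threshold."""
    lof = median <= config.lof_threshold and n_le_threshold >= config.lof_min_reps
    if not lof:
        return False, "none"
    tier = (
        "strongly_inactivating"
        if median <= config.lof_strong_bound
        else "inactivating"
    )
    return True, tier


def classify_screen(
    enrichment_table: pd.DataFrame,
    config: ScreenConfig,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant hit/tier/LoF calls for one screen.

    ``enrichment_table`` is the output of :func:`mutscan.scoring.score_screen`.
    Unassayed variants get no call (hit and lof are NA, not False).  When a
    design frame is supplied, an ``aa_median`` convenience column gives the
    median enrichment over nucleotide variants encoding the same amino acid
    change.
    """
    enr_cols = enrichment_columns(enrichment_table)
    if len(enr_cols) != config.n_replicates:
        raise ValueError(
            f"table has {len(enr_cols)} replicates; config expects {config.n_replicates}"
        )
    median = enrichment_table["median_enrichment"]
    n_ge = enrichment_table["n_replicates_ge_threshold"]
    n_le = (enrichment_table[enr_cols] <= config.lof_threshold).sum(axis=1)
    assayed = enrichment_table.get(
        "assayed", pd.Series(True, index=enrichment_table.index)
    ).astype(bool)

    hit = (median >= config.hit_threshold) & (n_ge >= config.min_replicates_for_hit)
    lof_flag = (median <= config.lof_threshold) & (n_le >= config.lof_min_reps)

    tier = pd.Series("none", index=enrichment_table.index, dtype=object)
    for idx in enrichment_table.index[hit & assayed]:
        tier.loc[idx] = assign_tier(float(median.loc[idx]), config)
    lof_tier = pd.Series("none", index=enrichment_table.index, dtype=object)
    lof_tier[lof_flag & assayed & (median <= config.lof_strong_bound)] = (
        "strongly_inactivating"
    )
    lof_tier[lof_flag & assayed & (median > config.lof_strong_bound)] = "inactivating"

    out = pd.DataFrame(
        {
            "median_enrichment": median,
            "n_replicates_ge_threshold": n_ge,
            "hit": hit.astype(object).where(assayed, other=pd.NA),
            "tier": tier.where(assayed, other="no_call"),
            "lof": lof_flag.astype(object).where(assayed, other=pd.NA),
            "lof_tier": lof_tier.where(assayed, other="no_call"),
            "assayed": assayed,
        }
    )
    if design is not None:
        aa = design["aa_change"].reindex(out.index)
        out["aa_median"] = median.groupby(aa).transform("median")
    return out


def screen_summary(calls: pd.DataFrame) -> dict:
    """Counts per tier plus totals, for logging and reports."""
    assayed = calls["assayed"]
    hits = calls["hit"] == True  # noqa: E712 -- NA-tolerant truth test
    summary = {
        "n_variants": int(len(calls)),
        "n_assayed": int(assayed.sum()),
        "n_hits": int(hits.sum()),
        "n_lof": int((calls["lof"] == True).sum()),  # noqa: E712
    }
    for tier in TIERS[1:]:
        summary[f"n_{tier}"] = int((calls["tier"] == tier).sum())
    return summary


def hit_fraction_percent(n_hits: int, n_tested: int, ndigits: int = 1) -> float:
    """Hit fraction as a percentage rounded for reporting (474/8407 -> 5.6)."""
    if n_tested <= 0:
        raise ValueError("n_tested must be positive")
    return round(100.0 * n_hits / n_tested, ndigits)
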