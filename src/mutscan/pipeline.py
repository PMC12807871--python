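"""End-to-end orchestration: simulate -> FASTQ -> count -> score -> classify.

Convenience layer tying the modules together for parameter-recovery runs on
synthetic screens.  The FASTQ round trip exercises the full read-handling
path (head-crop, merge, tile assignment, single-mutation calling) before
scoring, so recovered counts — not the simulated ones — feed the enrichment
scores.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from mutscan import read_calling as rc
from mutscan import scoring
from mutscan import simulate as sim
from mutscan.classification import ScreenConfig, classify_screen

#: short screen name -> classification screen name
SCREEN_OF = {
    "activation": "activation",
    "pem": "pem_resistance",
    "fut": "fut_resistance",
}


def score_and_classify(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    layout: dict[str, list[str]],
    screen: str,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score one screen from a count matrix and call hits with its defaults."""
    table = scoring.score_screen(
        counts, design, layout["plasmid"], layout[screen], pseudocount=pseudocount
    )
    config = ScreenConfig.default(SCREEN_OF[screen])
    calls = classify_screen(table, config, design)
    return table, calls


def run_synthetic_fastq_pipeline(
    design: pd.DataFrame,
    tile_ref: rc.TileReference,
    config: sim.SimConfig,
    workdir: str | Path,
    screens: tuple[str, ...] = ("activation", "pem"),
) -> dict:
    """Full parameter-recovery run through the FASTQ round trip.

    Simulates counts under ``config``, writes paired FASTQ for the plasmid
    baseline and the requested selection screens, re-counts the reads with
    the variant-calling pipeline, scores and classifies each screen from
    the *recovered* counts, and reports recovery against the programmed
    truth.  Returns truth, simulated and recovered counts, per-screen score
    and call tables, the recovery report and per-sample accounting.
    """
    workdir = Path(workdir)
    layout = sim.sample_layout(config)
    truth = sim.make_true_effects(design, config)
    simulated = sim.simulate_counts(design, truth, config)
    columns = layout["plasmid"] + [c for s in screens for c in layout[s]]
    sheet = sim.simulate_fastq(simulated[columns], design, tile_ref, config, workdir)
    recovered, accounting = rc.count_sample_sheet(sheet, design, [tile_ref])

    tables, calls = {}, {}
    for screen in screens:
        tables[screen], calls[screen] = score_and_classify(
            recovered, design, layout, screen
        )
    report = sim.recovery_report(calls, truth)
    return {
        "truth": truth,
        "simulated_counts": simulated,
        "recovered_counts": recovered,
        "scores": tables,
        "calls": calls,
        "recovery": report,
        "accounting": accounting,
    }
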