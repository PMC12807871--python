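"""Ground-truthed synthetic screens for parameter-recovery testing.

The generator emulates the statistical structure the scoring model
assumes: a near-equimolar plasmid library (symmetric Dirichlet abundances,
concentration 50, matching the high library homogeneity verified by
sequencing QC), single-endpoint multiplicative selection (each variant's
expected selection frequency is its baseline frequency times a per-screen
effect multiplier, renormalised), multinomial sequencing sampling at a
configurable depth (default 300 reads per variant, the sequencing floor of
the assay), and i.i.d. substitution sequencing errors on simulated 210-nt
read pairs whose forward read carries a 10-nt degenerate prefix (so the
head-crop stage is exercised).

True effects are drawn per class among missense variants only; synonymous
variants are neutral by construction, which is exactly the assumption the
synonymous-normalisation step relies on.  An analytic (sampling-disabled)
mode emits expected frequencies instead of sampled counts; with zero
pseudocount the pipeline then recovers each programmed effect exactly,
providing a closed-form oracle.

What this generator does not model: PCR jackpots and chimeras, positional
quality profiles, index hopping, or growth dynamics beyond a single
endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mutscan.read_calling import TileReference

CLASSES = ("neutral", "gof", "lof", "pemR", "futR", "dual")
SCREEN_NAMES = ("activation", "pem", "fut")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated screen set.

    ``depth`` is reads per variant; class fractions apply to missense
    variants; effect folds are the log-normal medians of the drawn
    multipliers (sigma on the log scale).
    """

    seed: int
    depth: int = 300
    dirichlet_concentration: float = 50.0
    class_fractions: dict = field(
        default_factory=lambda: {
            "gof": 0.05, "lof": 0.05, "pemR": 0.03, "futR": 0.02, "dual": 0.02,
        }
    )
    gof_fold: float = 6.0
    resistance_fold: float = 6.0
    lof_fold: float = 0.2
    effect_sigma: float = 0.4
    error_rate: float = 0.0
    read_length: int = 210
    headcrop_prefix: int = 10
    n_baseline: int = 3
    n_activation: int = 4
    n_resistance: int = 3

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if sum(self.class_fractions.values()) > 1:
            raise ValueError("class fractions must sum to <= 1")


def sample_layout(config: SimConfig) -> dict[str, list[str]]:
    """Column names per role for a simulated count matrix."""
    return {
        "plasmid": [f"plasmid_{i+1}" for i in range(config.n_baseline)],
        "activation": [f"act_{i+1}" for i in range(config.n_activation)],
        "pem": [f"pem_{i+1}" for i in range(config.n_resistance)],
        "fut": [f"fut_{i+1}" for i in range(config.n_resistance)],
    }


def make_true_effects(design: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw per-variant classes and per-screen effect multipliers.

    Only missense variants receive non-neutral classes; draws are
    reproducible from (seed, config).  Returns a frame indexed like
    ``design`` with columns class, effect_activation, effect_pem,
    effect_fut.
    """
    rng = np.random.default_rng([config.seed, 1])
    truth = pd.DataFrame(index=design.index)
    truth["class"] = "neutral"
    for s in SCREEN_NAMES:
        truth[f"effect_{s}"] = 1.0

    missense = design.index[design["consequence"] == "missense"].to_numpy()
    fractions = config.class_fractions
    n_needed = {c: int(round(f * len(missense))) for c, f in fractions.items()}
    if sum(n_needed.values()) > len(missense):
        raise ValueError("class fractions exceed the missense pool")
    shuffled = rng.permutation(missense)
    cursor = 0
    for cls in ("gof", "lof", "pemR", "futR", "dual"):
        n = n_needed.get(cls, 0)
        members = shuffled[cursor : cursor + n]
        cursor += n
        truth.loc[members, "class"] = cls
        if cls == "gof":
            truth.loc[members, "effect_activation"] = _lognormal(
                rng, config.gof_fold, config.effect_sigma, n
            )
        elif cls == "lof":
            truth.loc[members, "effect_activation"] = _lognormal(
                rng, config.lof_fold, config.effect_sigma, n
            )
        elif cls == "pemR":
            truth.loc[members, "effect_pem"] = _lognormal(
                rng, config.resistance_fold, config.effect_sigma, n
            )
        elif cls == "futR":
            truth.loc[members, "effect_fut"] = _lognormal(
                rng, config.resistance_fold, config.effect_sigma, n
            )
        else:  # dual resistance
            truth.loc[members, "effect_pem"] = _lognormal(
                rng, config.resistance_fold, config.effect_sigma, n
            )
            truth.loc[members, "effect_fut"] = _lognormal(
                rng, config.resistance_fold, config.effect_sigma, n
            )
    return truth


def _lognormal(rng, median: float, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size=n))


def simulate_counts(
    design: pd.DataFrame,
    truth: pd.DataFrame,
    config: SimConfig,
    analytic: bool = False,
) -> pd.DataFrame:
    """Dirichlet-multinomial count matrix for all samples of all screens.

    Plasmid abundances are drawn once (shared by all samples); baseline
    replicates sample the abundances, selection replicates sample
    abundance x effect renormalised.  In ``analytic`` mode no sampling
    occurs and expected frequencies (scaled to total depth, as floats) are
    returned — the infinite-depth limit.
    """
    if not truth.index.equals(design.index):
        truth = truth.reindex(design.index)
        if truth.isna().any().any():
            raise ValueError("truth does not cover the design")
    rng = np.random.default_rng([config.seed, 2])
    n = len(design)
    total = config.depth * n
    alpha = np.full(n, config.dirichlet_concentration)
    abundance = rng.dirichlet(alpha)

    layout = sample_layout(config)
    effect_of_role = {
        "plasmid": np.ones(n),
        "activation": truth["effect_activation"].to_numpy(float),
        "pem": truth["effect_pem"].to_numpy(float),
        "fut": truth["effect_fut"].to_numpy(float),
    }
    cols = {}
    for role, names in layout.items():
        p = abundance * effect_of_role[role]
        p = p / p.sum()
        for name in names:
            if analytic:
                cols[name] = p * total
            else:
                cols[name] = rng.multinomial(total, p)
    dtype = float if analytic else np.int64
    return pd.DataFrame(cols, index=design.index).astype(dtype)


def _design_read_arrays(design: pd.DataFrame, reference: TileReference):
    """Per-variant (reference offset, alt base index) arrays for one tile."""
    lo, _ = reference.variable_span
    offsets = design["cds_pos"].to_numpy(int) - reference.cds_nt_start + lo
    alts = _BASE_INDEX[
        np.frombuffer("".join(design["alt_nt"]).encode("ascii"), dtype=np.uint8)
    ]
    return offsets, alts


def simulate_fastq(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    reference: TileReference,
    config: SimConfig,
    out_dir: str | Path,
) -> pd.DataFrame:
    """Emit paired FASTQ files for every sample column of ``counts``.

    Each counted read becomes one pair: the forward read is a
    ``headcrop_prefix``-nt random prefix followed by the start of the
    amplicon; the reverse read covers the amplicon end (reverse
    complemented), so the merged pair reconstructs the full reference
    span.  Substitution errors are injected i.i.d. at ``error_rate`` per
    base; error positions get a low quality character.  Returns a sample
    sheet frame (sample_id, role, replicate, fastq1, fastq2, tile).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = reference.sequence
    L = len(ref)
    rl = config.read_length
    prefix = config.headcrop_prefix
    if rl - prefix > L or rl > L:
        raise ValueError("read geometry inconsistent with reference length")
    ref_idx = _BASE_INDEX[np.frombuffer(ref.encode("ascii"), dtype=np.uint8)]
    if (ref_idx < 0).any():
        raise ValueError("reference contains non-ACGT bases")
    offsets, alts = _design_read_arrays(design, reference)

    role_of = {}
    for role, names in sample_layout(config).items():
        for i, name in enumerate(names):
            role_of[name] = (role, i + 1)

    rows = []
    for si, sample in enumerate(counts.columns):
        rng = np.random.default_rng([config.seed, 3, si])
        col = counts[sample].to_numpy(np.int64)
        n_reads = int(col.sum())
        varpos = np.repeat(offsets, col)
        varbase = np.repeat(alts, col)
        amplicon = np.broadcast_to(ref_idx, (n_reads, L)).copy()
        amplicon[np.arange(n_reads), varpos] = varbase

        fwd = np.concatenate(
            [rng.integers(0, 4, size=(n_reads, prefix)), amplicon[:, : rl - prefix]],
            axis=1,
        )
        rev = (3 - amplicon[:, L - rl :])[:, ::-1]  # revcomp in index space

        f_path = out_dir / f"{sample}_R1.fastq"
        r_path = out_dir / f"{sample}_R2.fastq"
        _write_fastq(f_path, fwd, sample, rng, config.error_rate)
        _write_fastq(r_path, rev, sample, rng, config.error_rate)
        role, rep = role_of.get(sample, ("unknown", 0))
        rows.append(
            {"sample_id": sample, "role": "plasmid_baseline" if role == "plasmid"
             else role, "replicate": rep, "fastq1": str(f_path),
             "fastq2": str(r_path), "tile": reference.tile_id}
        )
    return pd.DataFrame(rows)


def _write_fastq(path: Path, idx_mat: np.ndarray, sample: str,
                 rng: np.random.Generator, error_rate: float) -> None:
    n, L = idx_mat.shape
    qual = np.full((n, L), ord("I"), dtype=np.uint8)
    if error_rate > 0 and n:
        mask = rng.random((n, L)) < error_rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        idx_mat = idx_mat.copy()
        idx_mat[mask] = (idx_mat[mask] + shift) % 4
        qual[mask] = ord("#")
    if n == 0:
        path.write_text("")
        return
    # fixed-width records assembled in one uint8 matrix for throughput
    headers = "".join(f"@{sample}:{i:09d}" for i in range(n))
    w = len(sample) + 11
    hmat = np.frombuffer(headers.encode("ascii"), dtype=np.uint8).reshape(n, w)
    nl, plus = ord("\n"), ord("+")
    rec = np.empty((n, w + 1 + L + 1 + 2 + L + 1), dtype=np.uint8)
    rec[:, :w] = hmat
    rec[:, w] = nl
    rec[:, w + 1 : w + 1 + L] = _BASES[idx_mat]
    rec[:, w + 1 + L] = nl
    rec[:, w + 2 + L] = plus
    rec[:, w + 3 + L] = nl
    rec[:, w + 4 + L : w + 4 + 2 * L] = qual
    rec[:, -1] = nl
    with open(path, "wb") as fh:
        fh.write(rec.tobytes())


def recovery_report(
    calls: dict[str, pd.DataFrame],
    truth: pd.DataFrame,
    effect_bins: tuple[float, ...] = (1.5, 5.0, 10.0),
) -> pd.DataFrame:
    """Sensitivity/specificity of pipeline calls against the programmed truth.

    ``calls`` maps screen name (activation/pem/fut) to a classification
    table with a ``hit`` column.  Per screen and per programmed-effect bin:
    sensitivity = called hits / true non-neutral variants; for neutral
    variants (effect 1) the false-positive rate is reported instead.
    """
    rows = []
    for screen, table in calls.items():
        effect = truth[f"effect_{screen}"].reindex(table.index).astype(float)
        hit = (table["hit"] == True)  # noqa: E712 -- NA-tolerant
        neutral = effect == 1.0
        n_neu = int(neutral.sum())
        fp = int((hit & neutral).sum())
        rows.append(
            {"screen": screen, "bin": "neutral", "n": n_neu, "n_called": fp,
             "rate": fp / n_neu if n_neu else np.nan, "metric": "false_positive_rate"}
        )
        edges = (*effect_bins, np.inf)
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (effect >= lo) & (effect < hi)
            n = int(mask.sum())
            k = int((hit & mask).sum())
            rows.append(
                {"screen": screen, "bin": f"[{lo},{hi})", "n": n, "n_called": k,
                 "rate": k / n if n else np.nan, "metric": "sensitivity"}
            )
        strong = effect >= 5.0
        n = int(strong.sum())
        k = int((hit & strong).sum())
        rows.append(
            {"screen": screen, "bin": ">=5", "n": n, "n_called": k,
             "rate": k / n if n else np.nan, "metric": "sensitivity"}
        )
    return pd.DataFrame(rows)


def random_cds(
    n_codons: int,
    rng: np.random.Generator,
    start_codon: bool = True,
) -> str:
    """A random in-frame CDS without internal stop codons."""
    stops = {"TAA", "TAG", "TGA"}
    codons = []
    if start_codon:
        codons.append("ATG")
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            codons.append(c)
    return "".join(codons[:n_codons])
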