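"""Single-mutation variant calling from pooled amplicon reads.

Paired 210-nt amplicon reads are processed in four stages mirroring a
FLASH-style pipeline: (1) the forward read is head-cropped (default 10 nt,
removing the degenerate PCR-primer bases); (2) the pair is merged by an
exhaustive minimum-mismatch-density overlap search; (3) the merged read is
assigned to a tile by anchored comparison against each tile's 260-nt
wild-type reference (240-nt variable region + 10-nt context each side);
(4) the read is accepted only if it carries exactly zero (wild-type) or one
(single SNV) substitution relative to the reference — reads with two or
more substitutions, indels or an ambiguous base at the variant position are
rejected and accounted for.

Because the amplicons are fixed-locus, gapped genome alignment is
unnecessary: direct anchored comparison against the short references is
exact for single-substitution reads.  A vectorised numpy batch path
(:func:`merge_pairs_batch`) handles high read volumes; it is equivalent to
the scalar :func:`merge_pair` and property-tested as such.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from mutscan.library_design import Tile

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

REJECT_REASONS = (
    "multi_mismatch",
    "indel",
    "no_tile",
    "short_overlap",
    "high_mismatch_density",
    "ambiguous_base",
)


@dataclass(frozen=True)
class TileReference:
    """A tile's 260-nt wild-type reference used for calling.

    ``context_nt`` bases of wild-type sequence flank the variable region on
    each side; ``cds_nt_start`` is the 1-based CDS coordinate of the first
    variable-region base.
    """

    tile_id: str
    gene_id: str
    sequence: str
    cds_nt_start: int
    context_nt: int = 10

    @property
    def variable_span(self) -> tuple[int, int]:
        """0-based half-open span of the variable region in ``sequence``."""
        return self.context_nt, len(self.sequence) - self.context_nt

    @classmethod
    def from_tile(cls, tile: Tile, context_nt: int = 10) -> "TileReference":
        if len(tile.left_flank) < context_nt or len(tile.right_flank) < context_nt:
            raise ValueError("tile flanks shorter than requested context")
        seq = (
            tile.left_flank[-context_nt:]
            + tile.variable_region
            + tile.right_flank[:context_nt]
        )
        return cls(tile.tile_id, tile.gene_id, seq, tile.cds_nt_start, context_nt)


@dataclass
class MutationCall:
    """Outcome of calling one merged read against a tile reference."""

    tile_id: str | None
    status: str  # wildtype | single_snv | rejected
    cds_nt_position: int | None = None
    alt_nt: str | None = None
    reject_reason: str | None = None


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def headcrop(seq: str, qual: str, n: int = 10) -> tuple[str, str] | None:
    """Drop the first ``n`` bases/qualities; ``None`` if the read is too short."""
    if len(seq) <= n:
        return None
    return seq[n:], qual[n:]


def merge_pair(
    fwd_seq: str,
    fwd_qual: str,
    rev_seq: str,
    rev_qual: str,
    min_overlap: int = 10,
    max_overlap: int = 200,
    max_mismatch_density: float = 0.25,
) -> tuple[str, str] | tuple[None, str]:
    """Merge a read pair by exhaustive overlap search (scalar reference).

    The reverse read is reverse-complemented, then every overlap length in
    ``[min_overlap, min(max_overlap, len(f), len(r))]`` between the forward
    suffix and reverse prefix is scored by mismatch density
    (mismatches / overlap length).  The minimum-density candidate wins,
    ties going to the longer overlap.  Disagreeing overlap bases resolve to
    the higher-quality base (forward wins quality ties).  Returns
    ``(merged_seq, merged_qual)`` or ``(None, reject_reason)``.
    """
    rc = reverse_complement(rev_seq)
    rq = rev_qual[::-1]
    hi = min(max_overlap, len(fwd_seq), len(rc))
    if hi < min_overlap:
        return None, "short_overlap"
    best_o, best_mm = None, 0
    for o in range(min_overlap, hi + 1):
        tail = fwd_seq[len(fwd_seq) - o :]
        head = rc[:o]
        mm = sum(a != b for a, b in zip(tail, head))
        # exact rational comparison: density(o) <= density(best); tie -> longer o
        if best_o is None or mm * best_o <= best_mm * o:
            best_o, best_mm = o, mm
    if best_mm > max_mismatch_density * best_o:
        return None, "high_mismatch_density"
    o = best_o
    f_tail_start = len(fwd_seq) - o
    seq = list(fwd_seq + rc[o:])
    qual = list(fwd_qual + rq[o:])
    for k in range(o):
        i = f_tail_start + k
        if fwd_seq[i] != rc[k]:
            if rq[k] > fwd_qual[i]:
                seq[i] = rc[k]
                qual[i] = rq[k]
        else:
            qual[i] = max(fwd_qual[i], rq[k])
    return "".join(seq), "".join(qual)


def _to_matrix(strings: Sequence[str]) -> np.ndarray:
    """Equal-length ASCII strings as a uint8 matrix (N, L)."""
    if not strings:
        return np.empty((0, 0), dtype=np.uint8)
    joined = "".join(strings).encode("ascii")
    return np.frombuffer(joined, dtype=np.uint8).reshape(len(strings), -1)


_RC_TABLE = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC_TABLE[_a] = _b


def merge_pairs_batch(
    fwd_seqs: Sequence[str],
    fwd_quals: Sequence[str],
    rev_seqs: Sequence[str],
    rev_quals: Sequence[str],
    min_overlap: int = 10,
    max_overlap: int = 200,
    max_mismatch_density: float = 0.25,
) -> list[tuple[str, str] | tuple[None, str]]:
    """Vectorised :func:`merge_pair` for pairs sharing read lengths.

    All forward reads must share one length and all reverse reads another.
    Returns one result per pair, in order, identical to the scalar path.
    """
    n = len(fwd_seqs)
    if n == 0:
        return []
    fmat = _to_matrix(fwd_seqs)
    fq = _to_matrix(fwd_quals)
    rmat = _RC_TABLE[_to_matrix(rev_seqs)][:, ::-1]
    rq = _to_matrix(rev_quals)[:, ::-1]
    lf, lr = fmat.shape[1], rmat.shape[1]
    hi = min(max_overlap, lf, lr)
    if hi < min_overlap:
        return [(None, "short_overlap")] * n

    best_o = np.full(n, min_overlap, dtype=np.int64)
    best_mm = np.count_nonzero(
        fmat[:, lf - min_overlap :] != rmat[:, :min_overlap], axis=1
    ).astype(np.int64)
    for o in range(min_overlap + 1, hi + 1):
        mm = np.count_nonzero(fmat[:, lf - o :] != rmat[:, :o], axis=1)
        take = mm * best_o <= best_mm * o
        best_o[take] = o
        best_mm[take] = mm[take]

    ok = best_mm <= max_mismatch_density * best_o
    results: list[tuple[str, str] | tuple[None, str]] = [
        (None, "high_mismatch_density")
    ] * n
    # merged layout depends on the chosen overlap; group rows sharing it
    for o in np.unique(best_o[ok]):
        rows = np.nonzero(ok & (best_o == o))[0]
        o = int(o)
        seq = np.concatenate([fmat[rows], rmat[rows, o:]], axis=1)
        qual = np.concatenate([fq[rows], rq[rows, o:]], axis=1)
        f_tail = fmat[rows, lf - o :]
        r_head = rmat[rows, :o]
        fq_tail = fq[rows, lf - o :]
        rq_head = rq[rows, :o]
        disagree = f_tail != r_head
        take_rev = disagree & (rq_head > fq_tail)
        ov_seq = np.where(take_rev, r_head, f_tail)
        ov_qual = np.where(disagree, np.where(take_rev, rq_head, fq_tail),
                           np.maximum(fq_tail, rq_head))
        seq[:, lf - o : lf] = ov_seq
        qual[:, lf - o : lf] = ov_qual
        seq_bytes = seq.tobytes()
        qual_bytes = qual.tobytes()
        width = seq.shape[1]
        for j, row in enumerate(rows):
            results[int(row)] = (
                seq_bytes[j * width : (j + 1) * width].decode("ascii"),
                qual_bytes[j * width : (j + 1) * width].decode("ascii"),
            )
    return results


def _anchor_score(window: str, ref: str, ref_start: int, shift_range: int = 5) -> int:
    """Best (minimum) mismatch count of ``window`` against ``ref`` anchored
    near ``ref_start``, over shifts of +/- ``shift_range``."""
    best = len(window)
    for s in range(-shift_range, shift_range + 1):
        start = ref_start + s
        if start < 0 or start + len(window) > len(ref):
            continue
        mm = sum(a != b for a, b in zip(window, ref[start : start + len(window)]))
        best = min(best, mm)
    return best


def assign_tile(
    merged: str,
    references: Sequence[TileReference],
    anchor_nt: int = 15,
    shift_range: int = 5,
) -> str | None:
    """Assign a merged read to a tile by its first/last ``anchor_nt`` bases.

    Each reference is scored as the sum of the best head-anchor and
    tail-anchor mismatch counts over a +/- ``shift_range`` shift search; a
    unique minimum that matches reasonably well (each anchor at most 1/3
    mismatched) wins.  Ties or poor matches return ``None``.
    """
    if len({r.sequence for r in references}) != len(references):
        raise ValueError("tile references must be mutually distinct")
    if len(merged) < anchor_nt:
        return None
    head = merged[:anchor_nt]
    tail = merged[-anchor_nt:]
    scores = []
    for ref in references:
        s = _anchor_score(head, ref.sequence, 0, shift_range) + _anchor_score(
            tail, ref.sequence, len(ref.sequence) - anchor_nt, shift_range
        )
        scores.append(s)
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    best = order[0]
    if scores[best] > 2 * anchor_nt // 3:
        return None
    if len(scores) > 1 and scores[order[1]] == scores[best]:
        return None
    return references[best].tile_id


def call_variant(merged: str, reference: TileReference) -> MutationCall:
    """Compare a merged read to its tile reference and call the mutation.

    Equal-length reads are compared positionally; shorter reads are slid to
    their unique best placement (covering a contiguous reference window,
    i.e. truncation at the ends is tolerated); longer reads, or shorter
    reads with no clean placement, are rejected as indels.
    """
    ref = reference.sequence
    tid = reference.tile_id
    if len(merged) == len(ref):
        offset = 0
        window = merged
    elif len(merged) < len(ref):
        best_off, best_mm, second = 0, len(merged) + 1, len(merged) + 1
        for off in range(len(ref) - len(merged) + 1):
            mm = sum(a != b for a, b in zip(merged, ref[off : off + len(merged)]))
            if mm < best_mm:
                best_off, best_mm, second = off, mm, best_mm
            elif mm < second:
                second = mm
        if best_mm > max(2, len(merged) // 10) or second == best_mm:
            return MutationCall(tid, "rejected", reject_reason="indel")
        offset = best_off
        window = merged
    else:
        return MutationCall(tid, "rejected", reject_reason="indel")

    mismatches = [
        i for i, (a, b) in enumerate(zip(window, ref[offset : offset + len(window)]))
        if a != b
    ]
    if not mismatches:
        return MutationCall(tid, "wildtype")
    if len(mismatches) > 1:
        return MutationCall(tid, "rejected", reject_reason="multi_mismatch")
    i = mismatches[0]
    base = window[i]
    if base not in "ACGT":
        return MutationCall(tid, "rejected", reject_reason="ambiguous_base")
    ref_pos = offset + i
    lo, hi = reference.variable_span
    if not (lo <= ref_pos < hi):
        # a lone substitution in flank context is not a designed variant
        return MutationCall(tid, "wildtype")
    cds_pos = reference.cds_nt_start + (ref_pos - lo)
    return MutationCall(tid, "single_snv", cds_nt_position=cds_pos, alt_nt=base)


def call_variants_batch(
    merged_seqs: Sequence[str],
    reference: TileReference,
) -> list[MutationCall]:
    """Vectorised :func:`call_variant` against one reference.

    Reads whose length equals the reference length go through a numpy
    positional comparison; all others fall back to the scalar path.
    """
    ref = reference.sequence
    equal_idx = [i for i, s in enumerate(merged_seqs) if len(s) == len(ref)]
    results: list[MutationCall | None] = [None] * len(merged_seqs)
    for i, s in enumerate(merged_seqs):
        if len(s) != len(ref):
            results[i] = call_variant(s, reference)
    if equal_idx:
        mat = _to_matrix([merged_seqs[i] for i in equal_idx])
        refv = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        diff = mat != refv
        nm = diff.sum(axis=1)
        lo, hi = reference.variable_span
        first = diff.argmax(axis=1)
        for j, i in enumerate(equal_idx):
            n = nm[j]
            if n == 0:
                results[i] = MutationCall(reference.tile_id, "wildtype")
            elif n > 1:
                results[i] = MutationCall(
                    reference.tile_id, "rejected", reject_reason="multi_mismatch"
                )
            else:
                pos = int(first[j])
                base = chr(mat[j, pos])
                if base not in "ACGT":
                    results[i] = MutationCall(
                        reference.tile_id, "rejected", reject_reason="ambiguous_base"
                    )
                elif lo <= pos < hi:
                    results[i] = MutationCall(
                        reference.tile_id,
                        "single_snv",
                        cds_nt_position=reference.cds_nt_start + pos - lo,
                        alt_nt=base,
                    )
                else:
                    results[i] = MutationCall(reference.tile_id, "wildtype")
    return results  # type: ignore[return-value]


@dataclass
class SampleAccounting:
    """Per-sample read bookkeeping across all pipeline stages."""

    sample_id: str
    total_pairs: int = 0
    headcrop_dropped: int = 0
    merge_rejected: int = 0
    unassigned: int = 0
    wildtype: int = 0
    single_snv: int = 0
    rejected: int = 0
    reject_reasons: dict = field(default_factory=dict)

    def add_reject(self, reason: str) -> None:
        """Record a call-stage reject (read was assigned to a tile)."""
        self.rejected += 1
        self._count_reason(reason)

    def _count_reason(self, reason: str) -> None:
        self.reject_reasons[reason] = self.reject_reasons.get(reason, 0) + 1

    @property
    def assigned(self) -> int:
        """Reads that reached variant calling; conservation:
        assigned = wildtype + single_snv + rejected."""
        return self.wildtype + self.single_snv + self.rejected


def count_read_pairs(
    pairs: Iterable[tuple[str, str, str, str]],
    references: Sequence[TileReference],
    sample_id: str = "sample",
    tile_id: str | None = None,
    headcrop_n: int = 10,
    min_overlap: int = 10,
    max_overlap: int = 200,
    max_mismatch_density: float = 0.25,
    batch_size: int = 200_000,
) -> tuple[dict, SampleAccounting]:
    """Process (fwd_seq, fwd_qual, rev_seq, rev_qual) pairs to variant counts.

    Returns ``(counts, accounting)`` where ``counts`` maps
    ``(tile_id, cds_nt_position, alt_nt)`` — or ``(tile_id, None, None)``
    for wild-type — to read counts.  If ``tile_id`` is given, tile
    assignment is skipped (single-pool sample).
    """
    by_id = {r.tile_id: r for r in references}
    if tile_id is not None and tile_id not in by_id:
        raise ValueError(f"unknown tile {tile_id}")
    acc = SampleAccounting(sample_id)
    counts: dict = {}

    def flush(group: dict[tuple[int, int], list]) -> None:
        for (_lf, _lr), quad in group.items():
            fs, fqs, rs, rqs = quad
            merged = merge_pairs_batch(
                fs, fqs, rs, rqs, min_overlap, max_overlap, max_mismatch_density
            )
            per_tile: dict[str, list[str]] = {}
            for m, reason in merged:
                if m is None:
                    acc.merge_rejected += 1
                    acc._count_reason(reason)
                    continue
                tid = tile_id if tile_id is not None else assign_tile(m, references)
                if tid is None:
                    acc.unassigned += 1
                    acc._count_reason("no_tile")
                    continue
                per_tile.setdefault(tid, []).append(m)
            for tid, seqs in per_tile.items():
                for call in call_variants_batch(seqs, by_id[tid]):
                    _record_call(call, counts, acc)
        group.clear()

    group: dict[tuple[int, int], list] = {}
    pending = 0
    for fwd_seq, fwd_qual, rev_seq, rev_qual in pairs:
        acc.total_pairs += 1
        cropped = headcrop(fwd_seq, fwd_qual, headcrop_n)
        if cropped is None:
            acc.headcrop_dropped += 1
            continue
        fs, fq = cropped
        key = (len(fs), len(rev_seq))
        quad = group.setdefault(key, [[], [], [], []])
        quad[0].append(fs)
        quad[1].append(fq)
        quad[2].append(rev_seq)
        quad[3].append(rev_qual)
        pending += 1
        if pending >= batch_size:
            flush(group)
            pending = 0
    flush(group)
    return counts, acc


def _record_call(call: MutationCall, counts: dict, acc: SampleAccounting) -> None:
    if call.status == "wildtype":
        acc.wildtype += 1
        key = (call.tile_id, None, None)
        counts[key] = counts.get(key, 0) + 1
    elif call.status == "single_snv":
        acc.single_snv += 1
        key = (call.tile_id, call.cds_nt_position, call.alt_nt)
        counts[key] = counts.get(key, 0) + 1
    else:
        acc.add_reject(call.reject_reason or "unknown")


def iter_fastq_pairs(fastq1: str | Path, fastq2: str | Path):
    """Yield (fwd_seq, fwd_qual, rev_seq, rev_qual) from paired FASTQ files."""
    import gzip

    def opener(p):
        p = str(p)
        return gzip.open(p, "rt") if p.endswith(".gz") else open(p)

    with opener(fastq1) as f1, opener(fastq2) as f2:
        for (_, s1, q1), (_, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2), strict=True
        ):
            yield s1, q1, s2, q2


def tabulate(
    counts: dict,
    manifest: pd.DataFrame,
    sample_id: str,
    accounting: SampleAccounting | None = None,
    role: str | None = None,
    min_reads_per_variant: int = 300,
) -> pd.Series:
    """Turn per-position counts into a CountMatrix column over designed variants.

    The returned Series is indexed by variant key (``gene:c.posRef>Alt``)
    plus one ``<tile_id>:WT`` row per tile seen.  For plasmid-baseline
    samples a coverage screen warns when mean assigned reads per designed
    variant fall below ``min_reads_per_variant``.
    """
    pos_to_key = dict(
        zip(
            zip(manifest["gene"], manifest["cds_pos"].astype(int), manifest["alt_nt"]),
            manifest.index,
        )
    )
    tile_of_gene_pool = {
        f"{g}_pool{p}": g for g, p in zip(manifest["gene"], manifest["pool"])
    }
    tallies: dict[str, int] = {}
    wt_rows: dict[str, int] = {}
    unmatched = 0
    for (tid, pos, alt), n in counts.items():
        if pos is None:
            wt_rows[f"{tid}:WT"] = wt_rows.get(f"{tid}:WT", 0) + n
            continue
        gene = tile_of_gene_pool.get(tid, tid.split("_pool")[0])
        key = pos_to_key.get((gene, pos, alt))
        if key is None:
            unmatched += n
        else:
            tallies[key] = tallies.get(key, 0) + n
    col = pd.Series(tallies, dtype=np.int64, name=sample_id).reindex(
        manifest.index, fill_value=0
    )
    if unmatched:
        logger.warning("%s: %d single-SNV reads matched no designed variant",
                       sample_id, unmatched)
    if wt_rows:
        col = pd.concat([col, pd.Series(wt_rows, dtype=np.int64, name=sample_id)])
    if role == "plasmid_baseline" and accounting is not None and len(manifest):
        per_variant = accounting.assigned / len(manifest)
        if per_variant < min_reads_per_variant:
            logger.warning(
                "%s: plasmid coverage %.1f reads/variant below the %d-read screen",
                sample_id, per_variant, min_reads_per_variant,
            )
    return col


def count_sample_sheet(
    sample_sheet: pd.DataFrame,
    manifest: pd.DataFrame,
    references: Sequence[TileReference],
    **params,
) -> tuple[pd.DataFrame, dict[str, SampleAccounting]]:
    """Run the counting pipeline for every row of a sample sheet.

    The sheet needs columns sample_id, role, replicate, fastq1, fastq2 and
    optionally tile.  Returns the counts matrix (variants x samples) and
    per-sample accounting.
    """
    if sample_sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    columns = []
    accounting = {}
    for _, row in sample_sheet.iterrows():
        pairs = iter_fastq_pairs(row["fastq1"], row["fastq2"])
        tile = row.get("tile") if "tile" in row and pd.notna(row.get("tile")) else None
        counts, acc = count_read_pairs(
            pairs, references, sample_id=row["sample_id"], tile_id=tile, **params
        )
        col = tabulate(counts, manifest, row["sample_id"], acc, role=row.get("role"))
        if acc.total_pairs == 0:
            logger.warning("%s: empty FASTQ input", row["sample_id"])
        columns.append(col)
        accounting[row["sample_id"]] = acc
    matrix = pd.concat(columns, axis=1).fillna(0).astype(np.int64)
    return matrix, accounting
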