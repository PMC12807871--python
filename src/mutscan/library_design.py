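"""Saturation SNV library design for a tiled coding region.

A kinase (or any) domain inside a CDS is split into contiguous tiles of a
fixed codon length (default 80 codons = 240 nt).  For every nucleotide of
every tile, all three alternative bases are enumerated, yielding 3 x 240 =
720 single-nucleotide variants per tile.  Each variant is emitted as a
synthesis-ready oligo: 30 nt of wild-type context on each side of the
mutated 240-nt variable region, i.e. 300 nt total.  Variants are annotated
with codon change, consequence (synonymous / missense / nonsense) and HGVS
coding/protein strings.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqIO import parse as fasta_parse
from Bio.SeqUtils import seq3

NUCLEOTIDES = "ACGT"

#: Columns of the design manifest, in order.
MANIFEST_COLUMNS = [
    "gene",
    "pool",
    "cds_pos",
    "ref_nt",
    "alt_nt",
    "codon",
    "ref_aa",
    "alt_aa",
    "consequence",
    "hgvs_c",
    "hgvs_p",
    "oligo",
]


@dataclass(frozen=True)
class GeneModel:
    """A validated coding sequence with a designated mutagenesis domain.

    Parameters
    ----------
    gene_id :
        Identifier used in variant keys and output files.
    cds :
        Unambiguous A/C/G/T coding sequence; length divisible by 3.
    domain_start_codon, domain_end_codon :
        1-based inclusive codon indices of the mutagenised domain within
        the CDS-encoded protein.
    numbering_offset :
        Added to CDS codon indices so reported protein positions match the
        canonical isoform numbering (0 when the CDS is the canonical
        full-length transcript).
    """

    gene_id: str
    cds: str
    domain_start_codon: int
    domain_end_codon: int
    numbering_offset: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    @property
    def domain_n_codons(self) -> int:
        return self.domain_end_codon - self.domain_start_codon + 1

    @property
    def domain_nt_span(self) -> tuple[int, int]:
        """1-based inclusive CDS nucleotide span of the domain."""
        return (self.domain_start_codon - 1) * 3 + 1, self.domain_end_codon * 3


@dataclass(frozen=True)
class Tile:
    """One oligo pool: a contiguous codon window plus wild-type flanks."""

    gene_id: str
    pool_index: int
    codon_span: tuple[int, int]
    variable_region: str
    left_flank: str
    right_flank: str

    @property
    def cds_nt_start(self) -> int:
        """1-based CDS coordinate of the first variable-region base."""
        return (self.codon_span[0] - 1) * 3 + 1

    @property
    def tile_id(self) -> str:
        return f"{self.gene_id}_pool{self.pool_index}"


@dataclass(frozen=True)
class VariantDesign:
    """A single designed nucleotide substitution with its oligo."""

    gene_id: str
    pool_index: int
    cds_nt_position: int
    ref_nt: str
    alt_nt: str
    codon_number: int
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    consequence: str
    hgvs_c: str
    hgvs_p: str
    oligo_sequence: str

    @property
    def key(self) -> str:
        """Stable per-variant identifier (gene + coding HGVS)."""
        return f"{self.gene_id}:{self.hgvs_c}"

    @property
    def aa_change(self) -> str:
        """Amino-acid-level key, shared by codon-equivalent variants."""
        return f"{self.gene_id}:p.{self.ref_aa}{self.codon_number}{self.alt_aa}"


def _validate_sequence(seq: str) -> None:
    for i, base in enumerate(seq):
        if base not in NUCLEOTIDES:
            raise ValueError(
                f"non-ACGT character {base!r} at CDS offset {i + 1}"
            )


def load_gene_model(
    fasta_path: str | Path,
    domain_span: tuple[int, int],
    numbering_offset: int = 0,
    gene_id: str | None = None,
) -> GeneModel:
    """Read a CDS FASTA record and validate the mutagenesis domain span.

    ``domain_span`` is a 1-based inclusive (start_codon, end_codon) pair.
    """
    records = list(fasta_parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA record found in {fasta_path}")
    record = records[0]
    return make_gene_model(
        gene_id or record.id,
        str(record.seq).upper(),
        domain_span,
        numbering_offset,
    )


def make_gene_model(
    gene_id: str,
    cds: str,
    domain_span: tuple[int, int],
    numbering_offset: int = 0,
) -> GeneModel:
    """Construct and validate a :class:`GeneModel` from an in-memory CDS."""
    cds = cds.upper()
    _validate_sequence(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not divisible by 3")
    start, end = domain_span
    if end < start:
        raise ValueError(f"domain end codon {end} precedes start codon {start}")
    if start < 1 or end > len(cds) // 3:
        raise ValueError(
            f"domain span {start}-{end} outside CDS of {len(cds) // 3} codons"
        )
    return GeneModel(gene_id, cds, start, end, numbering_offset)


def tile_domain(
    gene_model: GeneModel,
    tile_len_codons: int = 80,
    flank_nt: int = 30,
) -> list[Tile]:
    """Split the domain into contiguous tiles of ``tile_len_codons`` codons.

    Tiles abut without gap or overlap and jointly reproduce the domain
    sequence.  The domain must divide exactly into whole tiles, and the CDS
    must provide ``flank_nt`` of wild-type context beyond both domain ends.
    """
    n = gene_model.domain_n_codons
    if n % tile_len_codons != 0:
        raise ValueError(
            f"domain of {n} codons does not divide into {tile_len_codons}-codon tiles"
        )
    nt_start, nt_end = gene_model.domain_nt_span
    if nt_start - 1 < flank_nt:
        raise ValueError(
            f"only {nt_start - 1} nt of upstream context; {flank_nt} required"
        )
    if len(gene_model.cds) - nt_end < flank_nt:
        raise ValueError(
            f"only {len(gene_model.cds) - nt_end} nt of downstream context; "
            f"{flank_nt} required"
        )
    tiles = []
    for i in range(n // tile_len_codons):
        start_codon = gene_model.domain_start_codon + i * tile_len_codons
        end_codon = start_codon + tile_len_codons - 1
        lo = (start_codon - 1) * 3  # 0-based
        hi = end_codon * 3
        tiles.append(
            Tile(
                gene_id=gene_model.gene_id,
                pool_index=i + 1,
                codon_span=(start_codon, end_codon),
                variable_region=gene_model.cds[lo:hi],
                left_flank=gene_model.cds[lo - flank_nt : lo],
                right_flank=gene_model.cds[hi : hi + flank_nt],
            )
        )
    return tiles


def enumerate_snvs(tile: Tile) -> list[VariantDesign]:
    """All 3L single-nucleotide substitutions of an L-nt tile, as oligos.

    Consequence and HGVS fields are left blank; use :func:`annotate_variant`
    or :func:`design_library`.  Ordering is by CDS position then alt base.
    """
    designs = []
    region = tile.variable_region
    for offset, ref in enumerate(region):
        cds_pos = tile.cds_nt_start + offset
        for alt in NUCLEOTIDES:
            if alt == ref:
                continue
            mutated = region[:offset] + alt + region[offset + 1 :]
            designs.append(
                VariantDesign(
                    gene_id=tile.gene_id,
                    pool_index=tile.pool_index,
                    cds_nt_position=cds_pos,
                    ref_nt=ref,
                    alt_nt=alt,
                    codon_number=0,
                    ref_codon="",
                    alt_codon="",
                    ref_aa="",
                    alt_aa="",
                    consequence="",
                    hgvs_c=f"c.{cds_pos}{ref}>{alt}",
                    hgvs_p="",
                    oligo_sequence=tile.left_flank + mutated + tile.right_flank,
                )
            )
    return designs


def _translate_codon(codon: str) -> str:
    if codon in standard_dna_table.stop_codons:
        return "*"
    return str(Seq(codon).translate())


def _aa_long(aa: str) -> str:
    return "Ter" if aa == "*" else seq3(aa)


def annotate_variant(design: VariantDesign, gene_model: GeneModel) -> VariantDesign:
    """Fill codon change, consequence and HGVS protein fields of a design."""
    pos0 = design.cds_nt_position - 1
    codon_index = pos0 // 3  # 0-based codon within CDS
    within = pos0 % 3
    ref_codon = gene_model.cds[codon_index * 3 : codon_index * 3 + 3]
    if ref_codon[within] != design.ref_nt:
        raise ValueError(
            f"design ref {design.ref_nt} at c.{design.cds_nt_position} "
            f"disagrees with CDS base {ref_codon[within]}"
        )
    alt_codon = ref_codon[:within] + design.alt_nt + ref_codon[within + 1 :]
    ref_aa = _translate_codon(ref_codon)
    alt_aa = _translate_codon(alt_codon)
    if alt_aa == ref_aa:
        consequence = "synonymous"
    elif alt_aa == "*":
        consequence = "nonsense"
    else:
        consequence = "missense"
    codon_number = codon_index + 1 + gene_model.numbering_offset
    if consequence == "synonymous":
        hgvs_p = f"p.{_aa_long(ref_aa)}{codon_number}="
    else:
        hgvs_p = f"p.{_aa_long(ref_aa)}{codon_number}{_aa_long(alt_aa)}"
    return replace(
        design,
        codon_number=codon_number,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        consequence=consequence,
        hgvs_p=hgvs_p,
    )


def design_library(
    gene_model: GeneModel,
    tile_len_codons: int = 80,
    flank_nt: int = 30,
) -> tuple[list[Tile], list[VariantDesign]]:
    """Tile the domain and enumerate + annotate every SNV design."""
    tiles = tile_domain(gene_model, tile_len_codons, flank_nt)
    designs = [
        annotate_variant(d, gene_model)
        for tile in tiles
        for d in enumerate_snvs(tile)
    ]
    return tiles, designs


def write_design(
    designs: Sequence[VariantDesign],
    out_prefix: str | Path,
) -> tuple[Path, Path]:
    """Write oligo FASTA and TSV manifest; returns the two paths.

    Records are sorted by (gene, CDS position, alt base) so repeated runs
    produce byte-identical files.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ordered = sorted(
        designs, key=lambda d: (d.gene_id, d.cds_nt_position, d.alt_nt)
    )
    fasta_path = out_prefix.with_suffix(".oligos.fasta")
    manifest_path = out_prefix.with_suffix(".manifest.tsv")
    with open(fasta_path, "w") as fh:
        for d in ordered:
            fh.write(f">{d.gene_id}_pool{d.pool_index}_{d.hgvs_c}\n")
            fh.write(d.oligo_sequence + "\n")
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for d in ordered:
            writer.writerow(
                [
                    d.gene_id,
                    d.pool_index,
                    d.cds_nt_position,
                    d.ref_nt,
                    d.alt_nt,
                    d.codon_number,
                    d.ref_aa,
                    d.alt_aa,
                    d.consequence,
                    d.hgvs_c,
                    d.hgvs_p,
                    d.oligo_sequence,
                ]
            )
    return fasta_path, manifest_path


def coverage_fold(n_units: int, n_variants: int) -> float:
    """Library coverage: units (colonies, reads) per designed variant."""
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    return n_units / n_variants


def designs_to_frame(designs: Iterable[VariantDesign]):
    """Designs as a pandas DataFrame indexed by variant key."""
    import pandas as pd

    rows = [
        {
            "key": d.key,
            "gene": d.gene_id,
            "pool": d.pool_index,
            "cds_pos": d.cds_nt_position,
            "ref_nt": d.ref_nt,
            "alt_nt": d.alt_nt,
            "codon": d.codon_number,
            "ref_aa": d.ref_aa,
            "alt_aa": d.alt_aa,
            "consequence": d.consequence,
            "hgvs_c": d.hgvs_c,
            "hgvs_p": d.hgvs_p,
            "aa_change": d.aa_change,
        }
        for d in designs
    ]
    return pd.DataFrame(rows).set_index("key")


def read_manifest(path: str | Path):
    """Load a design manifest TSV back into a DataFrame keyed like designs."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    df["key"] = df["gene"] + ":" + df["hgvs_c"]
    df["aa_change"] = (
        df["gene"]
        + ":p."
        + df["ref_aa"]
        + df["codon"].astype(str)
        + df["alt_aa"]
    )
    return df.set_index("key")
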