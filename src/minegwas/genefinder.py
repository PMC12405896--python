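"""Map selected chromosomal bins to the genes they contain (local GFF3).

An offline gene lookup: the user supplies the genome annotation as GFF3 (for
sorghum, the Phytozome release), and every gene whose interval overlaps a
selected bin by at least one base pair is reported.  Chromosome naming is
normalized (case-insensitive "chr" prefixes and leading zeros stripped)
because VCF and GFF3 dialects routinely disagree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from minegwas.genomatrix import ChromosomalBin


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.gene_id}: start > end")


def normalize_chrom(name: str) -> str:
    """Strip chr/Chr prefix and leading zeros: 'Chr01' -> '1', '01' -> '1'."""
    s = re.sub(r"^chr", "", str(name).strip(), flags=re.IGNORECASE)
    s = s.lstrip("0") or "0"
    return s


_ATTR_ID = re.compile(r"(?:^|;)\s*ID=([^;]+)")
_ATTR_NAME = re.compile(r"(?:^|;)\s*Name=([^;]+)")
_ATTR_NOTE = re.compile(r"(?:^|;)\s*(?:Note|description)=([^;]+)")

_GFF_COLS = ["seqid", "source", "type", "start", "end",
             "score", "strand", "phase", "attributes"]


def read_gff3_genes(path) -> list[GeneRecord]:
    """Gene features from a GFF3 file (9-column table, '#' comments)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None, names=_GFF_COLS,
        dtype={"seqid": str, "attributes": str},
    )
    genes = df[df["type"] == "gene"]
    records = []
    for row in genes.itertuples(index=False):
        attrs = row.attributes if isinstance(row.attributes, str) else ""
        m = _ATTR_NAME.search(attrs) or _ATTR_ID.search(attrs)
        gid = m.group(1) if m else f"{row.seqid}:{row.start}-{row.end}"
        note = _ATTR_NOTE.search(attrs)
        records.append(
            GeneRecord(
                gene_id=gid,
                chrom=str(row.seqid),
                start_bp=int(row.start),
                end_bp=int(row.end),
                annotation=note.group(1) if note else "",
            )
        )
    return records


def genes_in_regions(bins: list[ChromosomalBin], gff) -> list[tuple[ChromosomalBin, GeneRecord]]:
    """Pairs (bin, gene) for every gene overlapping a bin by >= 1 bp
    (closed intervals), sorted by bin order then gene start.

    ``gff`` may be a GFF3 path or an already-parsed list of GeneRecords.
    """
    genes = read_gff3_genes(gff) if not isinstance(gff, list) else gff
    by_chrom: dict[str, IntervalTree] = {}
    for g in genes:
        # interval tree is half-open; +1 makes the closed end inclusive
        by_chrom.setdefault(normalize_chrom(g.chrom), IntervalTree()).addi(
            g.start_bp, g.end_bp + 1, g
        )
    bin_chroms = {normalize_chrom(b.chrom) for b in bins}
    if bins and genes and not (bin_chroms & set(by_chrom)):
        raise ValueError(
            "no shared chromosome names after normalization: "
            f"bins use {sorted(bin_chroms)}, annotation uses {sorted(by_chrom)}"
        )
    out: list[tuple[ChromosomalBin, GeneRecord]] = []
    for b in bins:
        tree = by_chrom.get(normalize_chrom(b.chrom))
        if tree is None:
            continue
        hits = sorted((iv.data for iv in tree.overlap(b.start_bp, b.end_bp + 1)),
                      key=lambda g: (g.start_bp, g.end_bp, g.gene_id))
        out.extend((b, g) for g in hits)
    return out


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_label": [b.label for b, _ in pairs],
            "gene_id": [g.gene_id for _, g in pairs],
            "chrom": [g.chrom for _, g in pairs],
            "start": [g.start_bp for _, g in pairs],
            "end": [g.end_bp for _, g in pairs],
            "annotation": [g.annotation for _, g in pairs],
        }
    )
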