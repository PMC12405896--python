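"""Genotype matrix construction: VCF input, SNP binning, and the design matrix.

Adjacent SNPs on a chromosome are collapsed into chromosomal bins of at least
50 kb (the "sum method") so that distinct design-matrix columns escape
linkage-driven LD, which in a highly selfing species such as *Sorghum bicolor*
decays over roughly 3.5–35.5 kb.  Each bin is scored per accession by its mean
reference-allele dosage, a number in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class VariantTable:
    """Per-accession biallelic genotypes with genomic coordinates.

    ``ref_count[i, s]`` is the number of reference alleles (0, 1 or 2) carried
    by accession ``i`` at SNP ``s``; missing genotypes are flagged in
    ``missing_mask`` and never imputed here.
    """

    accession_ids: list[str]
    chrom: np.ndarray          # (n_snps,) str
    pos: np.ndarray            # (n_snps,) int, 1-based
    ref_count: np.ndarray      # (n_acc, n_snps) int8
    missing_mask: np.ndarray   # (n_acc, n_snps) bool

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_count = np.asarray(self.ref_count)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.ref_count.shape != (len(self.accession_ids), len(self.pos)):
            raise ValueError("ref_count shape does not match accessions x SNPs")
        if self.n_accessions < 1 or self.n_snps < 1:
            raise ValueError("need at least one accession and one SNP")
        valid = self.ref_count[~self.missing_mask]
        if valid.size and (valid.min() < 0 or valid.max() > 2):
            raise ValueError("ref_count outside {0,1,2} at non-missing entries")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)


@dataclass(frozen=True)
class ChromosomalBin:
    """A contiguous run of SNPs spanning >= min_span_bp on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    snp_indices: tuple[int, ...]

    @property
    def span(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.start_bp}-{self.end_bp}"


@dataclass
class DesignMatrix:
    """Rows = accessions or plants, columns = chromosomal bins (X of the model)."""

    row_ids: list[str]
    bins: list[ChromosomalBin]
    values: np.ndarray
    level: str = "accession"   # {"accession", "plant"}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.bins)):
            raise ValueError("values shape does not match row_ids x bins")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValueError("design matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def bin_labels(self) -> list[str]:
        return [b.label for b in self.bins]

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.bin_labels)
        df.index.name = "row_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, level: str = "accession") -> "DesignMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bins = []
        for j, lab in enumerate(df.columns):
            chrom, rng = lab.rsplit(":", 1)
            start, end = (int(v) for v in rng.split("-"))
            bins.append(ChromosomalBin(chrom, start, end, (j,)))
        return cls([str(r) for r in df.index], bins, df.to_numpy(float), level)

    def bin_manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [b.chrom for b in self.bins],
                "start": [b.start_bp for b in self.bins],
                "end": [b.end_bp for b in self.bins],
                "n_snps": [len(b.snp_indices) for b in self.bins],
            }
        )


# ---------------------------------------------------------------------------
# operations


def read_vcf(path, accession_subset: list[str] | None = None) -> VariantTable:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`VariantTable`.

    Multiallelic records, indels and non-SNP records are dropped (counted in
    the log).  ``ref_count`` is the number of REF alleles in the diploid
    genotype; missing genotypes are flagged, not imputed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if accession_subset is not None:
        missing = [a for a in accession_subset if a not in vcf.samples]
        if missing:
            raise KeyError(f"accessions not in VCF header: {missing}")
        vcf.set_samples(accession_subset)
    samples = list(vcf.samples)

    chroms: list[str] = []
    positions: list[int] = []
    counts: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_dropped += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        miss = gt == 2
        rc = np.where(gt == 0, 2, np.where(gt == 1, 1, 0)).astype(np.int8)
        rc[miss] = 0
        chroms.append(var.CHROM)
        positions.append(var.POS)
        counts.append(rc)
        missing_cols.append(miss)
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not counts:
        raise ValueError(f"no biallelic SNP records found in {path}")
    return VariantTable(
        accession_ids=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref_count=np.column_stack(counts),
        missing_mask=np.column_stack(missing_cols),
    )


def bin_variants(vt: VariantTable, min_span_bp: int = 50_000) -> list[ChromosomalBin]:
    """Greedy left-to-right binning: extend each bin with adjacent SNPs until
    its span (last pos - first pos + 1) reaches ``min_span_bp``.

    The final bin of a chromosome may be shorter; it is kept as-is and flagged
    in the log so the trailing-bin choice is auditable.
    """
    bins: list[ChromosomalBin] = []
    for chrom in vt.chromosomes:
        idx = np.flatnonzero(vt.chrom == chrom)
        if idx.size == 0:
            logger.info("bin_variants: chromosome %s has no SNPs, skipped", chrom)
            continue
        pos = vt.pos[idx]
        i = 0
        while i < idx.size:
            j = i
            while pos[j] - pos[i] + 1 < min_span_bp and j + 1 < idx.size:
                j += 1
            b = ChromosomalBin(
                chrom=chrom,
                start_bp=int(pos[i]),
                end_bp=int(pos[j]),
                snp_indices=tuple(int(k) for k in idx[i : j + 1]),
            )
            if b.span < min_span_bp:
                logger.info(
                    "bin_variants: trailing bin %s shorter than %d bp kept",
                    b.label, min_span_bp,
                )
            bins.append(b)
            i = j + 1
    return bins


def build_design_matrix(vt: VariantTable, bins: list[ChromosomalBin]) -> DesignMatrix:
    """Normalized reference-allele counts per accession and bin.

    Entry (i, j) = sum of ref_count over non-missing SNPs of bin j for
    accession i, divided by 2 x (number of non-missing SNPs), i.e. the mean
    reference-allele dosage in [0, 1].  Cells where every SNP of the bin is
    missing take the bin's column mean.
    """
    covered = [k for b in bins for k in b.snp_indices]
    if sorted(covered) != list(range(vt.n_snps)):
        raise ValueError("bins do not partition the variant table's SNPs")
    n_acc = vt.n_accessions
    X = np.empty((n_acc, len(bins)))
    rc = vt.ref_count.astype(float)
    ok = ~vt.missing_mask
    for j, b in enumerate(bins):
        if not b.snp_indices:
            raise ValueError(f"bin {j} has zero SNPs")
        cols = list(b.snp_indices)
        num = np.where(ok[:, cols], rc[:, cols], 0.0).sum(axis=1)
        denom = 2.0 * ok[:, cols].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            col = num / denom
        empty = denom == 0
        if empty.any():
            fill = col[~empty].mean() if (~empty).any() else 0.5
            col[empty] = fill
            logger.info(
                "build_design_matrix: bin %s fully missing for %d accession(s); "
                "column mean imputed", b.label, int(empty.sum()),
            )
        X[:, j] = col
    return DesignMatrix(list(vt.accession_ids), list(bins), X, level="accession")


def join_chromosomes(per_chrom: list[DesignMatrix]) -> DesignMatrix:
    """Concatenate per-chromosome design matrices column-wise, genome order."""
    if not per_chrom:
        raise ValueError("no design matrices to join")
    first = per_chrom[0]
    for dm in per_chrom[1:]:
        if dm.row_ids != first.row_ids:
            bad = sorted(set(dm.row_ids) ^ set(first.row_ids))
            raise ValueError(f"row ids differ between chromosome matrices: {bad[:10]}")
    bins = [b for dm in per_chrom for b in dm.bins]
    values = np.hstack([dm.values for dm in per_chrom])
    return DesignMatrix(list(first.row_ids), bins, values, level=first.level)


def expand_to_plants(dm: DesignMatrix, plant_map: dict[str, str]) -> DesignMatrix:
    """Replicate accession rows to one row per plant (rows of X must match Y)."""
    row_index = {r: i for i, r in enumerate(dm.row_ids)}
    plants = list(plant_map)
    rows = []
    for p in plants:
        acc = plant_map[p]
        if acc not in row_index:
            raise KeyError(f"plant {p!r} maps to unknown accession {acc!r}")
        rows.append(row_index[acc])
    values = dm.values[rows] if rows else np.empty((0, dm.n_bins))
    return DesignMatrix(plants, list(dm.bins), values, level="plant")
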