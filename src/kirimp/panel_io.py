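"""Phased haplotype panels and KIR type tables: containers, file formats, alignment.

The central containers are :class:`HaplotypePanel` (phased binary SNP alleles,
haplotype x SNP) and :class:`KirTypeTable` (per-haplotype or per-individual KIR
types: 17 copy-number loci plus the whole-haplotype ``KIRhaplotype`` and
``AvsB`` classifications).  Supported on-disk formats are SHAPEIT-style
``.haps``/``.sample`` pairs, VCF with phased genotypes, and delimited type
tables.  :func:`align_alleles` recodes a query panel onto a reference panel's
allele coding using nucleotide identity, strand complement, and allele
frequencies for strand-ambiguous pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing allele in the matrix

#: the 17 copy-number loci typed by qPCR, in genomic (centromeric->telomeric) order
COPY_NUMBER_LOCI = (
    "KIR2DS2",
    "KIR2DL2",
    "KIR2DL3",
    "KIR2DP1",
    "KIR2DL1",
    "KIR3DP1",
    "KIR2DL4",
    "KIR3DL1ex4",
    "KIR3DL1ex9",
    "KIR3DS1",
    "KIR2DL5",
    "KIR2DS3",
    "KIR2DS5",
    "KIR2DS1",
    "KIR2DS4TOTAL",
    "KIR2DS4WT",
    "KIR2DS4DEL",
)
HAPLOTYPE_LOCUS = "KIRhaplotype"
AVSB_LOCUS = "AvsB"
#: all 19 target loci: copy numbers plus the two whole-haplotype classifications
ALL_LOCI = COPY_NUMBER_LOCI + (HAPLOTYPE_LOCUS, AVSB_LOCUS)

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PURINES = frozenset("AG")


class PanelFormatError(ValueError):
    """A file does not conform to the expected panel format."""


class PanelValidationError(ValueError):
    """Panel or type-table content violates a domain invariant."""


@dataclass(frozen=True)
class SnpDefinition:
    """One biallelic SNP: identifier, GRCh37 position (1-based) and alleles."""

    snp_id: str
    position: int
    allele1: str
    allele2: str
    rsid: str | None = None
    gene_annotation: str | None = None
    poor_clustering: bool = False

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise PanelValidationError(f"{self.snp_id}: position must be positive")
        if self.allele1 not in _NUCLEOTIDES or self.allele2 not in _NUCLEOTIDES:
            raise PanelValidationError(
                f"{self.snp_id}: alleles must be nucleotides, got "
                f"{self.allele1}/{self.allele2}"
            )
        if self.allele1 == self.allele2:
            raise PanelValidationError(f"{self.snp_id}: alleles must differ")

    @property
    def is_strand_ambiguous(self) -> bool:
        """True for A/T and C/G pairs, where strand cannot be told from alleles."""
        return self.allele2 == _COMPLEMENT[self.allele1]


@dataclass
class HaplotypePanel:
    """Phased binary alleles for a set of haplotypes over an ordered SNP set.

    ``alleles[i, j]`` is 0 if haplotype ``i`` carries ``snps[j].allele1``,
    1 for ``allele2`` and ``MISSING`` (-1) when unknown.  SNPs are kept sorted
    by genomic position with no duplicate positions.
    """

    snps: list[SnpDefinition]
    haplotype_ids: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (len(self.haplotype_ids), len(self.snps)):
            raise PanelValidationError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.haplotype_ids)} haplotypes x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise PanelValidationError("allele entries must be 0, 1 or missing")
        pos = self.positions
        if not np.all(np.diff(pos) > 0):
            order = np.argsort(pos, kind="stable")
            self.snps = [self.snps[i] for i in order]
            self.alleles = self.alleles[:, order]
            pos = self.positions
            if np.any(np.diff(pos) == 0):
                dup = int(pos[np.where(np.diff(pos) == 0)[0][0]])
                raise PanelValidationError(f"duplicate SNP position {dup}")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.snps], dtype=np.int64)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def has_missing(self) -> bool:
        return bool((self.alleles == MISSING).any())

    def allele1_frequency(self) -> np.ndarray:
        """Per-SNP frequency of allele1 among non-missing alleles (NaN if none)."""
        a = self.alleles
        obs = a != MISSING
        with np.errstate(invalid="ignore"):
            return np.where(
                obs.sum(axis=0) > 0,
                ((a == 0) & obs).sum(axis=0) / np.maximum(obs.sum(axis=0), 1),
                np.nan,
            )

    def subset_snps(self, index: Sequence[int]) -> "HaplotypePanel":
        index = list(index)
        return HaplotypePanel(
            snps=[self.snps[i] for i in index],
            haplotype_ids=list(self.haplotype_ids),
            alleles=self.alleles[:, index].copy(),
        )

    def subset_haplotypes(self, index: Sequence[int]) -> "HaplotypePanel":
        index = list(index)
        return HaplotypePanel(
            snps=list(self.snps),
            haplotype_ids=[self.haplotype_ids[i] for i in index],
            alleles=self.alleles[index, :].copy(),
        )

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in self.snps],
                "rsid": [s.rsid for s in self.snps],
                "position": self.positions,
                "allele1": [s.allele1 for s in self.snps],
                "allele2": [s.allele2 for s in self.snps],
                "poor_clustering": [s.poor_clustering for s in self.snps],
            }
        )


@dataclass
class KirTypeTable:
    """Categorical KIR types, one row per haplotype or per individual.

    Copy-number loci hold small non-negative integers; ``KIRhaplotype`` and
    ``AvsB`` hold string labels and are only defined at the haplotype level.
    Missing labels are pandas NA.
    """

    unit: str  # "haplotype" | "individual"
    values: pd.DataFrame  # index: unit ids, columns: locus names

    def __post_init__(self) -> None:
        if self.unit not in ("haplotype", "individual"):
            raise PanelValidationError(f"unknown unit {self.unit!r}")
        if self.unit == "individual":
            forbidden = {HAPLOTYPE_LOCUS, AVSB_LOCUS} & set(self.values.columns)
            if forbidden:
                raise PanelValidationError(
                    f"per-individual tables cannot carry haplotype-level loci "
                    f"{sorted(forbidden)}: these are only defined per haplotype"
                )
        for locus in self.values.columns:
            col = self.values[locus]
            if locus in COPY_NUMBER_LOCI or locus not in (HAPLOTYPE_LOCUS, AVSB_LOCUS):
                nums = pd.to_numeric(col, errors="coerce")
                if ((nums.notna()) & (nums < 0)).any():
                    raise PanelValidationError(f"{locus}: negative copy number")
        if AVSB_LOCUS in self.values.columns:
            col = self.values[AVSB_LOCUS].dropna()
            bad = set(col.unique()) - {"A", "B"}
            if bad:
                raise PanelValidationError(f"AvsB values outside {{A,B}}: {sorted(bad)}")

    @property
    def loci(self) -> list[str]:
        return list(self.values.columns)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class ReferencePanel:
    """A haplotype panel joined to per-haplotype KIR types for training."""

    haplotypes: HaplotypePanel
    kir_types: KirTypeTable

    def __post_init__(self) -> None:
        if self.kir_types.unit != "haplotype":
            raise PanelValidationError("reference panel requires haplotype-level types")
        hap_ids = list(self.haplotypes.haplotype_ids)
        if list(self.kir_types.values.index) != hap_ids:
            try:
                self.kir_types = KirTypeTable(
                    unit="haplotype", values=self.kir_types.values.loc[hap_ids]
                )
            except KeyError as exc:
                raise PanelValidationError(
                    "KIR type table does not cover all panel haplotypes"
                ) from exc

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.n_haplotypes

    def locus_labels(self, locus: str) -> pd.Series:
        if locus not in self.kir_types.values.columns:
            raise PanelValidationError(f"locus {locus!r} absent from panel")
        return self.kir_types.values[locus]


class AlignmentAction(str, Enum):
    KEPT_AS_IS = "kept_as_is"
    SWAPPED_CODING = "swapped_coding"
    STRAND_FLIPPED = "strand_flipped"
    DROPPED_AMBIGUOUS = "dropped_ambiguous"
    DROPPED_ABSENT = "dropped_absent"


@dataclass
class AlleleAlignmentReport:
    """Per-SNP record of what :func:`align_alleles` did to the query panel."""

    records: pd.DataFrame  # snp_id, position, action, freq_diff

    def action_counts(self) -> dict[str, int]:
        return self.records["action"].value_counts().to_dict()

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SHAPEIT haps/sample dialect


def read_haps(haps_path, sample_path) -> HaplotypePanel:
    """Read a SHAPEIT-style ``.haps``/``.sample`` pair into a panel.

    The haps file is space-delimited with five leading columns
    (chromosome, SNP id, position, alleleA, alleleB) followed by 2N phased
    alleles in {0,1} ("?" for missing).  Each sample contributes two
    haplotypes named ``<sample>_1`` and ``<sample>_2``.
    """
    samples = _read_sample_ids(sample_path)
    n_expected = 2 * len(samples)
    snps: list[SnpDefinition] = []
    columns: list[np.ndarray] = []
    seen_ids: set[str] = set()
    token_map = {"0": 0, "1": 1, "?": MISSING}
    with open(haps_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 5 + n_expected:
                raise PanelFormatError(
                    f"{haps_path}: line {lineno}: expected {5 + n_expected} fields, "
                    f"got {len(fields)}"
                )
            _chrom, snp_id, pos, a1, a2 = fields[:5]
            if snp_id in seen_ids:
                raise PanelFormatError(f"{haps_path}: duplicate SNP ID {snp_id!r}")
            seen_ids.add(snp_id)
            try:
                col = np.array([token_map[t] for t in fields[5:]], dtype=np.int8)
            except KeyError as exc:
                raise PanelFormatError(
                    f"{haps_path}: line {lineno}: allele token {exc.args[0]!r} "
                    "is not 0, 1 or ?"
                ) from None
            snps.append(
                SnpDefinition(snp_id=snp_id, position=int(pos), allele1=a1, allele2=a2)
            )
            columns.append(col)
    if not snps:
        raise PanelFormatError(f"{haps_path}: no SNP records")
    hap_ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
    return HaplotypePanel(
        snps=snps, haplotype_ids=hap_ids, alleles=np.column_stack(columns)
    )


def _read_sample_ids(sample_path) -> list[str]:
    with open(sample_path) as fh:
        lines = [ln.split() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise PanelFormatError(f"{sample_path}: too short for a .sample file")
    # two header lines (column names and types), then one row per sample
    return [row[1] if len(row) > 1 else row[0] for row in lines[2:]]


def write_haps(panel: HaplotypePanel, haps_path, sample_path, chrom: str = "19") -> None:
    """Write a panel as a SHAPEIT-style ``.haps``/``.sample`` pair."""
    if panel.n_haplotypes % 2 != 0:
        raise PanelValidationError("haps format requires an even haplotype count")
    samples = []
    for i in range(0, panel.n_haplotypes, 2):
        hid = panel.haplotype_ids[i]
        samples.append(hid[:-2] if hid.endswith("_1") else f"sample{i // 2}")
    token = {0: "0", 1: "1", MISSING: "?"}
    with open(haps_path, "w") as fh:
        for j, snp in enumerate(panel.snps):
            col = " ".join(token[int(v)] for v in panel.alleles[:, j])
            fh.write(
                f"{chrom} {snp.snp_id} {snp.position} {snp.allele1} {snp.allele2} {col}\n"
            )
    with open(sample_path, "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in samples:
            fh.write(f"{s} {s} 0\n")


# ---------------------------------------------------------------------------
# VCF


def read_vcf_phased(vcf_path) -> HaplotypePanel:
    """Read phased biallelic SNP records from a VCF into a panel.

    REF maps to allele 0, ALT to 1.  Multi-allelic, non-SNP and unphased
    records are skipped (count logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    snps: list[SnpDefinition] = []
    columns: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped += 1
            continue
        if rec.REF not in _NUCLEOTIDES or rec.ALT[0] not in _NUCLEOTIDES:
            skipped += 1
            continue
        gts = rec.genotype.array()
        phased = gts[:, 2] == 1
        if not phased.all():
            skipped += 1
            continue
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = gts[:, 0]
        col[1::2] = gts[:, 1]
        col[col < 0] = MISSING
        snps.append(
            SnpDefinition(
                snp_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                position=rec.POS,
                allele1=rec.REF,
                allele2=rec.ALT[0],
            )
        )
        columns.append(col)
    if not snps:
        raise PanelFormatError(f"{vcf_path}: no phased biallelic SNP records")
    if skipped:
        logger.info("read_vcf_phased: skipped %d unusable records", skipped)
    hap_ids = [f"{s}_{k}" for s in samples for k in (1, 2)]
    panel = HaplotypePanel(
        snps=snps, haplotype_ids=hap_ids, alleles=np.column_stack(columns)
    )
    panel.skipped_records = skipped  # type: ignore[attr-defined]
    return panel


def write_vcf_phased(panel: HaplotypePanel, vcf_path, chrom: str = "19") -> None:
    """Write a panel as an uncompressed VCF with phased GT fields."""
    if panel.n_haplotypes % 2 != 0:
        raise PanelValidationError("VCF output requires an even haplotype count")
    samples = [panel.haplotype_ids[i].rsplit("_", 1)[0]
               for i in range(0, panel.n_haplotypes, 2)]
    token = {0: "0", 1: "1", MISSING: "."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, snp in enumerate(panel.snps):
            col = panel.alleles[:, j]
            gts = "\t".join(
                f"{token[int(col[i])]}|{token[int(col[i + 1])]}"
                for i in range(0, panel.n_haplotypes, 2)
            )
            fh.write(
                f"{chrom}\t{snp.position}\t{snp.snp_id}\t{snp.allele1}\t"
                f"{snp.allele2}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# KIR type tables


def read_kir_types(path, unit: str, allow_extra: bool = False, sep: str = "\t") -> KirTypeTable:
    """Read a delimited KIR type table (one row per haplotype or individual).

    The first column holds unit identifiers; remaining columns are locus
    names.  Unknown locus names are rejected unless ``allow_extra`` is set.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    unknown = [c for c in df.columns if c not in ALL_LOCI]
    if unknown and not allow_extra:
        raise PanelValidationError(
            f"unknown locus names {unknown}; pass allow_extra to keep them"
        )
    out = {}
    for locus in df.columns:
        col = df[locus].replace("", pd.NA)
        if locus in (HAPLOTYPE_LOCUS, AVSB_LOCUS):
            out[locus] = col
        else:
            nums = pd.to_numeric(col, errors="raise")
            out[locus] = nums.astype("Int64")
    return KirTypeTable(unit=unit, values=pd.DataFrame(out, index=df.index))


def write_kir_types(table: KirTypeTable, path, sep: str = "\t") -> None:
    table.values.to_csv(path, sep=sep, index_label="id")


# ---------------------------------------------------------------------------
# Alignment and filters


def align_alleles(
    reference: HaplotypePanel,
    query: HaplotypePanel,
    freq_tol: float = 0.1,
) -> tuple[HaplotypePanel, AlleleAlignmentReport]:
    """Recode a query panel's allele coding onto the reference panel's.

    SNPs are matched by GRCh37 position.  For each shared position the query
    coding is reconciled with the reference by exact nucleotide match, then by
    strand complement (purine <-> pyrimidine).  Strand-ambiguous pairs (A/T,
    C/G), where complementing is indistinguishable from swapping, are resolved
    by matching allele-1 frequencies within ``freq_tol``, else dropped.  Query
    SNPs absent from the reference are dropped.
    """
    ref_by_pos = {s.position: (j, s) for j, s in enumerate(reference.snps)}
    ref_freq = reference.allele1_frequency()
    qry_freq = query.allele1_frequency()
    keep: list[int] = []
    invert: list[bool] = []
    new_defs: list[SnpDefinition] = []
    rows = []
    for j, snp in enumerate(query.snps):
        action, freq_diff, flip = _classify_snp(
            snp, j, ref_by_pos, ref_freq, qry_freq, freq_tol
        )
        rows.append(
            {"snp_id": snp.snp_id, "position": snp.position,
             "action": action.value, "freq_diff": freq_diff}
        )
        if action in (AlignmentAction.DROPPED_ABSENT, AlignmentAction.DROPPED_AMBIGUOUS):
            continue
        ref_snp = ref_by_pos[snp.position][1]
        keep.append(j)
        invert.append(flip)
        new_defs.append(
            replace(snp, allele1=ref_snp.allele1, allele2=ref_snp.allele2)
        )
    if not any(snp.position in ref_by_pos for snp in query.snps):
        raise PanelValidationError("no positions shared between panels")
    alleles = query.alleles[:, keep].copy()
    flip_cols = np.array(invert, dtype=bool)
    if flip_cols.any():
        block = alleles[:, flip_cols]
        obs = block != MISSING
        block[obs] = 1 - block[obs]
        alleles[:, flip_cols] = block
    aligned = HaplotypePanel(
        snps=new_defs, haplotype_ids=list(query.haplotype_ids), alleles=alleles
    )
    report = AlleleAlignmentReport(records=pd.DataFrame(rows))
    return aligned, report


def _classify_snp(snp, j, ref_by_pos, ref_freq, qry_freq, freq_tol):
    """Decide the alignment action for one query SNP; returns (action, freq_diff, flip)."""
    hit = ref_by_pos.get(snp.position)
    if hit is None:
        return AlignmentAction.DROPPED_ABSENT, np.nan, False
    rj, ref_snp = hit
    r1, r2 = ref_snp.allele1, ref_snp.allele2
    q1, q2 = snp.allele1, snp.allele2
    rf, qf = ref_freq[rj], qry_freq[j]

    if snp.is_strand_ambiguous or ref_snp.is_strand_ambiguous:
        same_pair = {q1, q2} == {r1, r2} or \
            {_COMPLEMENT[q1], _COMPLEMENT[q2]} == {r1, r2}
        if not same_pair:
            return AlignmentAction.DROPPED_AMBIGUOUS, np.nan, False
        if np.isnan(rf) or np.isnan(qf):
            return AlignmentAction.DROPPED_AMBIGUOUS, np.nan, False
        if abs(qf - rf) <= freq_tol:
            return AlignmentAction.KEPT_AS_IS, abs(qf - rf), False
        if abs((1.0 - qf) - rf) <= freq_tol:
            return AlignmentAction.SWAPPED_CODING, abs((1.0 - qf) - rf), True
        return AlignmentAction.DROPPED_AMBIGUOUS, np.nan, False

    diff = abs(qf - rf) if not (np.isnan(qf) or np.isnan(rf)) else np.nan
    if (q1, q2) == (r1, r2):
        return AlignmentAction.KEPT_AS_IS, diff, False
    if (q2, q1) == (r1, r2):
        d = abs((1.0 - qf) - rf) if not (np.isnan(qf) or np.isnan(rf)) else np.nan
        return AlignmentAction.SWAPPED_CODING, d, True
    c1, c2 = _COMPLEMENT[q1], _COMPLEMENT[q2]
    if (c1, c2) == (r1, r2):
        return AlignmentAction.STRAND_FLIPPED, diff, False
    if (c2, c1) == (r1, r2):
        d = abs((1.0 - qf) - rf) if not (np.isnan(qf) or np.isnan(rf)) else np.nan
        return AlignmentAction.STRAND_FLIPPED, d, True
    return AlignmentAction.DROPPED_AMBIGUOUS, np.nan, False


def filter_by_region(panel: HaplotypePanel, start_bp: float, end_bp: float) -> HaplotypePanel:
    """Keep SNPs with start_bp <= position <= end_bp (closed interval, GRCh37)."""
    if start_bp >= end_bp:
        raise PanelValidationError("start_bp must be < end_bp")
    pos = panel.positions
    idx = np.where((pos >= start_bp) & (pos <= end_bp))[0]
    if idx.size == 0:
        logger.info("filter_by_region: empty result for [%s, %s]", start_bp, end_bp)
    return panel.subset_snps(idx)


def drop_monomorphic(panel: HaplotypePanel) -> HaplotypePanel:
    """Remove SNPs whose non-missing alleles are all 0 or all 1."""
    a = panel.alleles
    obs = a != MISSING
    n0 = ((a == 0) & obs).sum(axis=0)
    n1 = ((a == 1) & obs).sum(axis=0)
    poly = (n0 > 0) & (n1 > 0)
    if not poly.any():
        raise PanelValidationError("all SNPs are monomorphic")
    return panel.subset_snps(np.where(poly)[0])
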