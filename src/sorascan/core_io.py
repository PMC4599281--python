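"""Readers, writers and coordinate normalization for every format the pipeline touches.

All internal coordinates are 1-based inclusive, matching the convention in which
the study's variant positions are printed; the BED12 reader owns the 0-based
half-open arithmetic. Chromosome names are normalized to the ``chrN`` dialect by
default (a single style switch flips this).

Diploid genotypes are stored as the count of non-reference alleles
(0, 1, 2) with :data:`MISSING` (= -1) for any call containing an undetermined
allele; downstream perfect-segregation logic requires definite calls.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "MISSING",
    "VariantSite",
    "GenotypeMatrix",
    "SampleSheetRow",
    "GeneModel",
    "CandidateGeneSet",
    "SurvivalRecord",
    "normalize_chrom",
    "chrom_sort_key",
    "Reference",
    "read_vcf",
    "write_vcf",
    "read_sample_sheet",
    "read_fasta",
    "read_gene_models",
    "read_gene_list",
    "read_survival_table",
    "summarize_cohort",
]

#: Sentinel genotype for calls with at least one undetermined allele.
MISSING: int = -1

_VALID_ALLELE = re.compile(r"^[ACGT]+$")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted under the pipeline's rules."""


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize a chromosome name to the requested dialect.

    ``style="chr"`` yields ``chr1``/``chrX``; ``style="plain"`` yields ``1``/``X``.
    """
    stripped = name[3:] if name.lower().startswith("chr") else name
    return f"chr{stripped}" if style == "chr" else stripped


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing chr1..chr22 numerically before chrX/chrY/others."""
    body = normalize_chrom(chrom, "plain")
    if body.isdigit():
        return (int(body), "")
    return (1000, body)


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic variant locus on the plus strand of the reference."""

    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alt: str
    id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not _VALID_ALLELE.match(allele):
                raise ValueError(f"allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Unphased diploid genotypes: variants x samples, non-reference allele counts."""

    sites: list[VariantSite]
    samples: list[str]
    g: np.ndarray  # shape (len(sites), len(samples)), int8, values {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=np.int8)
        if self.g.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.g.shape} does not match "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample IDs are not unique")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            raise ValueError("variant sites are not unique by (chrom,pos,ref,alt)")

    def row(self, i: int) -> np.ndarray:
        return self.g[i]

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in samples]
        return GenotypeMatrix(list(self.sites), list(samples), self.g[:, idx])


@dataclass
class SampleSheetRow:
    """One cohort member: phenotype either as TTP months or an explicit label."""

    sample: str
    ttp_months: float | None = None
    label: str | None = None
    extra: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ttp_months is None and self.label is None:
            raise ValueError(f"sample {self.sample}: needs ttp_months or label")
        if self.ttp_months is not None and self.ttp_months <= 0:
            raise ValueError(f"sample {self.sample}: ttp_months must be > 0")
        if self.label is not None:
            self.label = self.label.strip().lower()
            if self.label not in ("good", "poor"):
                raise ValueError(f"sample {self.sample}: label must be good|poor")


@dataclass
class GeneModel:
    """A gene body with CDS structure and plus-strand reference sequence.

    ``span`` and every interval are 1-based inclusive. ``sequence`` covers the
    span in plus-strand orientation regardless of ``strand``; orientation is
    applied only when the coding sequence is assembled. ``exons`` (from BED12
    blocks or GFF3 exon features) are optional and only needed to distinguish
    UTR from intron.
    """

    gene: str
    chrom: str
    strand: str
    span: tuple[int, int]
    cds: list[tuple[int, int]]
    sequence: str
    exons: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene}: strand must be + or -")
        start, end = self.span
        if end < start:
            raise ValueError(f"{self.gene}: empty span")
        if len(self.sequence) != end - start + 1:
            raise ValueError(
                f"{self.gene}: sequence length {len(self.sequence)} does not cover "
                f"span of length {end - start + 1}"
            )
        self.cds = sorted(self.cds)
        prev_end = 0
        total = 0
        for a, b in self.cds:
            if a < start or b > end:
                raise ValueError(f"{self.gene}: CDS interval ({a},{b}) outside span")
            if a <= prev_end:
                raise ValueError(f"{self.gene}: CDS intervals overlap")
            prev_end = b
            total += b - a + 1
        if total % 3 != 0:
            raise ValueError(f"{self.gene}: CDS length {total} not divisible by 3")

    def base_at(self, pos: int) -> str:
        return self.sequence[pos - self.span[0]]

    def contains(self, pos: int) -> bool:
        return self.span[0] <= pos <= self.span[1]

    def in_cds(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in self.cds)

    def in_exon(self, pos: int) -> bool | None:
        """True/False when exon structure is known, None otherwise."""
        if self.exons is None:
            return None
        return any(a <= pos <= b for a, b in self.exons)

    def coding_sequence(self) -> str:
        """CDS concatenated in genomic order, reverse-complemented for minus strand."""
        s0 = self.span[0]
        cat = "".join(self.sequence[a - s0 : b - s0 + 1] for a, b in self.cds)
        if self.strand == "-":
            cat = str(Seq(cat).reverse_complement())
        return cat

    def cds_offset(self, pos: int) -> int:
        """0-based offset of ``pos`` within the strand-oriented coding sequence."""
        if not self.in_cds(pos):
            raise ValueError(f"{self.gene}: position {pos} not in CDS")
        off = 0
        for a, b in self.cds:
            if pos > b:
                off += b - a + 1
            elif pos >= a:
                off += pos - a
                break
        if self.strand == "-":
            total = sum(b - a + 1 for a, b in self.cds)
            off = total - 1 - off
        return off

    def validate_orf(self) -> None:
        """Check the translated CDS starts with Met and has no internal stop."""
        aa = str(Seq(self.coding_sequence()).translate())
        if not aa.startswith("M"):
            raise ValueError(f"{self.gene}: CDS does not begin with a start codon")
        if "*" in aa[:-1]:
            raise ValueError(f"{self.gene}: internal stop codon in CDS")


@dataclass
class CandidateGeneSet:
    """Drug-target and ADME candidate gene symbols (sets may overlap)."""

    targets: set[str]
    adme: set[str]

    @property
    def all(self) -> set[str]:
        return self.targets | self.adme


@dataclass
class SurvivalRecord:
    """One subject of a time-to-event validation cohort."""

    sample: str
    time: float  # months
    event: int  # 1 = progression/death observed, 0 = censored
    group: str  # genotype stratum label
    stage: float = 0.0  # ordinal covariate

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"sample {self.sample}: time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"sample {self.sample}: event must be 0 or 1")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    split_multiallelic: bool = False,
    chrom_style: str = "chr",
) -> GenotypeMatrix:
    """Read a diploid VCF 4.x into a :class:`GenotypeMatrix`.

    Genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2; any call with an
    undetermined allele (``./.``, ``./1`` ...) maps to :data:`MISSING`.
    Phasing separators are ignored. Multi-allelic records are rejected unless
    ``split_multiallelic`` is set, in which case each alternate allele becomes
    its own biallelic site (allele counts computed per alternate).
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfParseError(f"{path}: not a readable VCF ({exc})") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise VcfParseError(f"{path}: VCF has no sample columns")
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for rec in vf:
        if rec.alts is None or len(rec.alts) == 0:
            raise VcfParseError(f"{path}: record at {rec.chrom}:{rec.pos} has no ALT")
        if len(rec.alts) > 1 and not split_multiallelic:
            raise VcfParseError(
                f"{path}: multi-allelic record at {rec.chrom}:{rec.pos} "
                "(set split_multiallelic=True to split)"
            )
        chrom = normalize_chrom(rec.chrom, chrom_style)
        for ai, alt in enumerate(rec.alts, start=1):
            row = np.empty(len(samples), dtype=np.int8)
            for j, name in enumerate(samples):
                sample = rec.samples[name]
                gt = sample.get("GT")
                if gt is None:
                    raise VcfParseError(
                        f"{path}: GT absent for sample {name} at {rec.chrom}:{rec.pos}"
                    )
                if len(gt) != 2 or any(a is None for a in gt):
                    row[j] = MISSING
                else:
                    row[j] = sum(1 for a in gt if a == ai)
            sites.append(
                VariantSite(chrom, rec.pos, rec.ref, alt, rec.id)
            )
            rows.append(row)
    g = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(sites, samples, g)


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal but valid VCF 4.2 with GT-only genotype columns."""
    chroms: list[str] = []
    for s in matrix.sites:
        if s.chrom not in chroms:
            chroms.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        order = sorted(
            range(len(matrix.sites)),
            key=lambda i: (chrom_sort_key(matrix.sites[i].chrom), matrix.sites[i].pos),
        )
        for i in order:
            s = matrix.sites[i]
            gts = "\t".join(_GT_STRINGS[int(v)] for v in matrix.g[i])
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.id or '.'}\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Sample sheet and survival table (TSV)
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleSheetRow]:
    """Read a TSV sample sheet with columns ``sample`` and ``ttp_months``/``label``.

    Any additional numeric or string columns are kept in ``extra`` (so cohort
    covariates such as age can travel with the phenotype).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if "sample" not in df.columns:
        raise ValueError(f"{path}: missing 'sample' column")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"{path}: duplicate sample ID {dup!r}")
    known = {"sample", "ttp_months", "label"}
    rows = []
    for _, r in df.iterrows():
        ttp = r.get("ttp_months")
        ttp = None if ttp is None or pd.isna(ttp) else float(ttp)
        label = r.get("label")
        label = None if label is None or pd.isna(label) else str(label)
        extra = {k: r[k] for k in df.columns if k not in known and not pd.isna(r[k])}
        try:
            rows.append(SampleSheetRow(str(r["sample"]), ttp, label, extra))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return rows


def read_survival_table(path: str | Path) -> list[SurvivalRecord]:
    """Read a TSV survival table: sample, time_months, event, genotype, stage."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "genotype": str})
    required = {"sample", "time_months", "event", "genotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for _, r in df.iterrows():
        records.append(
            SurvivalRecord(
                sample=str(r["sample"]),
                time=float(r["time_months"]),
                event=int(r["event"]),
                group=str(r["genotype"]),
                stage=float(r.get("stage", 0.0)),
            )
        )
    return records


# ---------------------------------------------------------------------------
# FASTA and gene models
# ---------------------------------------------------------------------------

_REGION_ID = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


class Reference:
    """Plus-strand reference sequence assembled from FASTA records.

    Record IDs may be plain chromosome names (covering the chromosome from
    base 1) or samtools-faidx region names like ``chr3:121640001-121650000``,
    in which case the record covers that 1-based inclusive window — this lets
    compact reference extracts back gene models at genome-scale coordinates.
    Several windows of the same chromosome may coexist.
    """

    def __init__(self, windows: dict[str, list[tuple[int, str]]]):
        self._windows = windows

    @property
    def chroms(self) -> set[str]:
        return set(self._windows)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of the 1-based inclusive interval ``chrom:start-end``."""
        if chrom not in self._windows:
            raise ValueError(f"FASTA lacks chromosome {chrom!r}")
        for w_start, seq in self._windows[chrom]:
            if w_start <= start and end <= w_start + len(seq) - 1:
                return seq[start - w_start : end - w_start + 1]
        raise ValueError(
            f"interval {chrom}:{start}-{end} not covered by any sequence window"
        )


def read_fasta(path: str | Path, chrom_style: str = "chr") -> Reference:
    """Read FASTA (plain or region-named records) into a :class:`Reference`."""
    windows: dict[str, list[tuple[int, str]]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _REGION_ID.match(rec.id)
        if m:
            chrom = normalize_chrom(m.group("chrom"), chrom_style)
            start = int(m.group("start"))
            seq = str(rec.seq).upper()
            if int(m.group("end")) - start + 1 != len(seq):
                raise ValueError(f"{path}: region id {rec.id} does not match sequence length")
        else:
            chrom, start, seq = normalize_chrom(rec.id, chrom_style), 1, str(rec.seq).upper()
        windows.setdefault(chrom, []).append((start, seq))
    if not windows:
        raise ValueError(f"{path}: no FASTA records")
    return Reference(windows)


def _slice_reference(ref: Reference, chrom: str, start: int, end: int, what: str) -> str:
    try:
        return ref.fetch(chrom, start, end)
    except ValueError as exc:
        raise ValueError(f"{what}: {exc}") from exc


def _gene_models_from_bed12(path: str | Path, ref, chrom_style: str) -> list[GeneModel]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    models = []
    for _, r in df.iterrows():
        chrom = normalize_chrom(str(r.chrom), chrom_style)
        span = (int(r.start) + 1, int(r.end))  # 0-based half-open -> 1-based inclusive
        sizes = [int(x) for x in str(r.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(r.blockStarts).rstrip(",").split(",")]
        exons = [
            (int(r.start) + s + 1, int(r.start) + s + sz) for s, sz in zip(starts, sizes)
        ]
        thick = (int(r.thickStart) + 1, int(r.thickEnd))
        cds = []
        for a, b in exons:
            lo, hi = max(a, thick[0]), min(b, thick[1])
            if lo <= hi:
                cds.append((lo, hi))
        seq = _slice_reference(ref, chrom, span[0], span[1], str(r["name"]))
        try:
            models.append(
                GeneModel(str(r["name"]), chrom, str(r.strand), span, cds, seq, exons)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return models


_GFF_ATTR = re.compile(r"(\w+)=([^;]+)")


def _gene_models_from_gff3(path: str | Path, ref, chrom_style: str) -> list[GeneModel]:
    cols = ["chrom", "source", "type", "start", "end", "score", "strand", "phase", "attr"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df["attrs"] = df["attr"].map(lambda a: dict(_GFF_ATTR.findall(str(a))))
    genes = df[df["type"] == "gene"]
    models = []
    for _, g in genes.iterrows():
        gid = g["attrs"].get("ID") or g["attrs"].get("Name")
        name = g["attrs"].get("Name") or gid
        children = df[df["attrs"].map(lambda a: a.get("Parent") == gid)]
        cds = [
            (int(c.start), int(c.end)) for _, c in children[children["type"] == "CDS"].iterrows()
        ]
        exon_rows = children[children["type"] == "exon"]
        exons = (
            [(int(e.start), int(e.end)) for _, e in exon_rows.iterrows()]
            if len(exon_rows)
            else None
        )
        chrom = normalize_chrom(str(g.chrom), chrom_style)
        span = (int(g.start), int(g.end))
        seq = _slice_reference(ref, chrom, span[0], span[1], str(name))
        try:
            models.append(
                GeneModel(str(name), chrom, str(g.strand), span, cds, seq,
                          sorted(exons) if exons else None)
            )
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return models


def read_gene_models(
    path: str | Path, fasta: str | Path, chrom_style: str = "chr"
) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3 (detected by extension) plus FASTA."""
    ref = read_fasta(fasta, chrom_style)
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return _gene_models_from_gff3(path, ref, chrom_style)
    return _gene_models_from_bed12(path, ref, chrom_style)


def read_gene_list(path: str | Path) -> set[str]:
    """Read a candidate gene list: one symbol per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(rows: Iterable[SampleSheetRow], numeric_field: str) -> dict:
    """n, median and IQR of a numeric sample-sheet field.

    ``numeric_field`` may be ``ttp_months`` or any key of ``extra``. Median is
    the standard mid-point definition; IQR bounds are the 25th/75th percentiles
    with linear interpolation.
    """
    values = []
    for r in rows:
        v = getattr(r, numeric_field, None) if numeric_field == "ttp_months" else r.extra.get(numeric_field)
        if v is not None:
            try:
                values.append(float(v))
            except (TypeError, ValueError):
                pass
    if not values:
        raise ValueError(f"no numeric values for field {numeric_field!r}")
    arr = np.asarray(values, dtype=float)
    q25, q75 = np.percentile(arr, [25, 75])
    return {
        "n": len(values),
        "median": float(np.median(arr)),
        "iqr": (float(q25), float(q75)),
    }
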