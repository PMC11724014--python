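"""Readers, writers and shared domain types for the pipeline's external formats.

All genomic coordinates are held 1-based inclusive (the VCF convention);
SEG-dialect and BED inputs declare their own convention and are converted on
read.  Variant tables travel either as a minimal VCF subset (read-only, via
cyvcf2) or as plain TSV; allele-specific copy-number segments, chromosome-arm
definitions, signature matrices and promoter-methylation calls are delimited
text.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "VariantRecord",
    "Segment",
    "SegmentProfile",
    "ChromosomeArms",
    "MethylationCall",
    "SignatureSet",
    "MutationalCatalog",
    "TumorSample",
    "SBS96_CHANNELS",
    "read_variants",
    "write_variants_tsv",
    "read_segments",
    "write_segments",
    "read_arms",
    "read_signature_set",
    "read_methylation",
    "to_one_based",
    "to_zero_based",
]


class ParseError(ValueError):
    """A file could not be parsed into the expected schema."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


CONSEQUENCES = frozenset(
    {"stop_gain", "frameshift", "splice_essential", "missense", "other"}
)
LOF_CONSEQUENCES = frozenset({"stop_gain", "frameshift", "splice_essential"})
ORIGINS = frozenset({"germline", "somatic"})

METHYLATION_STATUSES = frozenset(
    {"unmethylated", "heterozygous_methylated", "homozygous_methylated", "unknown"}
)
METHYLATION_ALLELES = frozenset({"wildtype", "variant", "unknown"})


# --------------------------------------------------------------------------
# coordinate conventions


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start + 1, end


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start - 1, end


# --------------------------------------------------------------------------
# domain types


@dataclass
class VariantRecord:
    """One observed small variant with its read support and annotations.

    ``vaf`` is derived from the read counts and is ``None`` when the site has
    zero depth (such records carry the ``"no_depth"`` filter flag).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    origin: str = "somatic"
    alt_reads: int = 0
    ref_reads: int = 0
    gnomad_af: float | None = None
    annotations: dict = field(default_factory=dict)
    filter_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValidationError(
                f"unknown consequence {self.consequence!r}; "
                f"legal values: {sorted(CONSEQUENCES)}"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(f"unknown origin {self.origin!r}")
        if self.alt_reads < 0 or self.ref_reads < 0:
            raise ValidationError("read counts must be non-negative")
        if self.gnomad_af is not None and not (0.0 <= self.gnomad_af <= 1.0):
            raise ValidationError(f"gnomad_af {self.gnomad_af} outside [0, 1]")
        if self.depth == 0:
            self.filter_flags.add("no_depth")

    @property
    def depth(self) -> int:
        return self.alt_reads + self.ref_reads

    @property
    def vaf(self) -> float | None:
        if self.depth == 0:
            return None
        return self.alt_reads / self.depth

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class Segment:
    """An allele-specific copy-number segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    baf: float | None = None
    log2: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start > end"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValidationError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValidationError(
                f"minor_cn {self.minor_cn} exceeds major copy number "
                f"({self.total_cn - self.minor_cn}) on "
                f"{self.chrom}:{self.start}-{self.end}"
            )
        if self.baf is not None and not (0.0 <= self.baf <= 0.5):
            raise ValidationError(f"baf {self.baf} outside [0, 0.5]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def is_loh(self) -> bool:
        return self.minor_cn == 0 and self.total_cn >= 1

    @property
    def is_imbalanced(self) -> bool:
        return self.minor_cn != self.total_cn - self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class SegmentProfile:
    """Ordered, non-overlapping segments for one sample."""

    sample_id: str
    segments: list[Segment]
    genome_build: str = "unknown"

    def __post_init__(self) -> None:
        self.segments = sorted(self.segments, key=lambda s: (s.chrom, s.start))
        prev: Segment | None = None
        for seg in self.segments:
            if prev is not None and prev.chrom == seg.chrom and seg.start <= prev.end:
                raise ValidationError(
                    f"overlapping segments on {seg.chrom}: "
                    f"{prev.start}-{prev.end} and {seg.start}-{seg.end}"
                )
            prev = seg

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for seg in self.segments:
            seen.setdefault(seg.chrom, None)
        return list(seen)

    def by_chrom(self, chrom: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom]

    def segment_at(self, chrom: str, pos: int) -> Segment | None:
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None


@dataclass(frozen=True)
class ArmDefinition:
    chrom_start: int
    centromere_start: int
    centromere_end: int
    chrom_end: int

    def __post_init__(self) -> None:
        if not (
            self.chrom_start
            < self.centromere_start
            < self.centromere_end
            < self.chrom_end
        ):
            raise ValidationError(
                "arm bounds must satisfy chrom_start < centromere_start "
                "< centromere_end < chrom_end"
            )


class ChromosomeArms:
    """Per-chromosome arm boundaries (1-based bp)."""

    def __init__(self, arms: Mapping[str, ArmDefinition]):
        self._arms = dict(arms)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._arms

    def __getitem__(self, chrom: str) -> ArmDefinition:
        try:
            return self._arms[chrom]
        except KeyError:
            raise KeyError(f"no arm definition for chromosome {chrom!r}") from None

    def chromosomes(self) -> list[str]:
        return list(self._arms)

    def arm_of(self, chrom: str, pos: int) -> str:
        """Return 'p' or 'q' for a position ('cen' inside the centromere)."""
        arm = self[chrom]
        if pos < arm.centromere_start:
            return "p"
        if pos > arm.centromere_end:
            return "q"
        return "cen"


@dataclass
class MethylationCall:
    """Promoter-methylation status for one gene in one sample.

    The methylated allele is only attributable when a single allele is
    methylated, so it must be ``unknown`` for any other status.
    """

    sample_id: str
    gene: str
    status: str = "unknown"
    methylated_allele: str = "unknown"

    def __post_init__(self) -> None:
        if self.status not in METHYLATION_STATUSES:
            raise ValidationError(f"unknown methylation status {self.status!r}")
        if self.methylated_allele not in METHYLATION_ALLELES:
            raise ValidationError(
                f"unknown methylated_allele {self.methylated_allele!r}"
            )
        single_allele = self.status == "heterozygous_methylated"
        if not single_allele and self.methylated_allele != "unknown":
            raise ValidationError(
                "methylated_allele can only be attributed for "
                "heterozygous_methylated status"
            )


def _sbs96_channels() -> list[str]:
    subs = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
    bases = "ACGT"
    return [
        f"{five}[{sub}]{three}" for sub in subs for five in bases for three in bases
    ]


#: The 96 trinucleotide substitution channels in COSMIC order
#: (substitution-major, then 5' and 3' context lexicographic).
SBS96_CHANNELS: tuple[str, ...] = tuple(_sbs96_channels())


class SignatureSet:
    """A named set of SBS96 reference signatures.

    Columns are renormalised to sum to one; rows follow COSMIC channel order.
    """

    def __init__(self, names: Sequence[str], matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (96, len(names)):
            raise ValidationError(
                f"signature matrix must be 96 x {len(names)}, got {matrix.shape}"
            )
        if (matrix < 0).any():
            raise ValidationError("signature matrix has negative entries")
        sums = matrix.sum(axis=0)
        if (sums <= 0).any():
            bad = [names[i] for i in np.flatnonzero(sums <= 0)]
            raise ValidationError(f"signatures with zero mass: {bad}")
        self.names = list(names)
        self.matrix = matrix / sums
        self.channel_order = list(SBS96_CHANNELS)

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def subset(self, names: Sequence[str]) -> "SignatureSet":
        idx = [self.names.index(n) for n in names]
        return SignatureSet(list(names), self.matrix[:, idx])


@dataclass
class MutationalCatalog:
    """SBS96 channel counts for one (pooled) catalogue."""

    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValidationError("catalogue must have exactly 96 channels")
        if (self.counts < 0).any():
            raise ValidationError("catalogue counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TumorSample:
    """All observations for one tumour: purity, segments, variants, methylation."""

    sample_id: str
    profile: SegmentProfile
    germline_variant: VariantRecord | None = None
    somatic_variants: list[VariantRecord] = field(default_factory=list)
    methylation: list[MethylationCall] = field(default_factory=list)
    purity: float | None = None


# --------------------------------------------------------------------------
# variant IO

_VARIANT_TSV_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "origin",
    "alt_reads",
    "ref_reads",
    "gnomad_af",
    "annotations",
    "filter_flags",
]
_ANNOTATION_KEYS = ("cadd_phred", "revel", "clinvar_class", "genotype")


def _check_chrom_style(chroms: Iterable[str], source: str) -> None:
    styles = {c.startswith("chr") for c in chroms}
    if len(styles) > 1:
        raise ValidationError(
            f"{source}: mixed chromosome naming (with and without 'chr' prefix)"
        )


def _apply_chrom_style(chrom: str, style: str | None) -> str:
    if style == "strip" and chrom.startswith("chr"):
        return chrom[3:]
    if style == "add" and not chrom.startswith("chr"):
        return "chr" + chrom
    return chrom


def read_variants(
    path: str | Path,
    dialect: str = "tsv",
    default_origin: str = "somatic",
    chrom_style: str | None = None,
) -> list[VariantRecord]:
    """Read a variant table (``tsv`` dialect) or a minimal VCF subset (``vcf``).

    VCF records need single-sample FORMAT ``AD`` (or INFO ``ALT_READS`` /
    ``REF_READS``) for depth; multi-allelic rows are split into biallelic
    records.  An unparseable gnomAD AF becomes missing, never zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        records = _read_variants_tsv(path, default_origin)
    elif dialect == "vcf":
        records = _read_variants_vcf(path, default_origin)
    else:
        raise ValueError(f"unknown variant dialect {dialect!r}")
    _check_chrom_style((r.chrom for r in records), str(path))
    if chrom_style:
        records = [replace(r, chrom=_apply_chrom_style(r.chrom, chrom_style)) for r in records]
    return records


def _parse_optional_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def _read_variants_tsv(path: Path, default_origin: str) -> list[VariantRecord]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # malformed delimiter structure
        raise ParseError(f"{path}: {exc}") from exc
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        row = row._asdict()
        try:
            annotations = {}
            for key in _ANNOTATION_KEYS:
                val = row.get(key)
                if val is not None and not (isinstance(val, float) and math.isnan(val)):
                    parsed = _parse_optional_float(val)
                    annotations[key] = parsed if parsed is not None else val
            flags_raw = row.get("filter_flags")
            flags = (
                set(str(flags_raw).split(";"))
                if flags_raw and not (isinstance(flags_raw, float) and math.isnan(flags_raw))
                else set()
            )
            flags.discard("")
            rec = VariantRecord(
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                gene=str(row.get("gene") or "") if not _isnan(row.get("gene")) else "",
                consequence=_str_or(row.get("consequence"), "other"),
                origin=_str_or(row.get("origin"), default_origin),
                alt_reads=_int_or(row.get("alt_reads"), 0),
                ref_reads=_int_or(row.get("ref_reads"), 0),
                gnomad_af=_parse_optional_float(row.get("gnomad_af")),
                annotations=annotations,
                filter_flags=flags,
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i}: {exc}") from exc
        records.append(rec)
    return records


def _isnan(value) -> bool:
    return isinstance(value, float) and math.isnan(value)


def _str_or(value, default: str) -> str:
    if value is None or _isnan(value):
        return default
    return str(value)


def _int_or(value, default: int) -> int:
    if value is None or _isnan(value):
        return default
    return int(float(value))


def _read_variants_vcf(path: Path, default_origin: str) -> list[VariantRecord]:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF header ({exc})") from exc
    records: list[VariantRecord] = []
    n_samples = len(vcf.samples)
    for variant in vcf:
        alts = variant.ALT or []
        ad = None
        if n_samples >= 1:
            try:
                ad = variant.format("AD")
            except KeyError:
                ad = None
        for alt_index, alt in enumerate(alts):
            if ad is not None:
                ref_reads = int(ad[0][0])
                alt_reads = int(ad[0][alt_index + 1])
            else:
                alt_reads = variant.INFO.get("ALT_READS")
                ref_reads = variant.INFO.get("REF_READS")
                if alt_reads is None or ref_reads is None:
                    raise ParseError(
                        f"{path}: {variant.CHROM}:{variant.POS}: no depth "
                        "information; required fields: FORMAT/AD or "
                        "INFO/ALT_READS + INFO/REF_READS"
                    )
                alt_reads, ref_reads = int(alt_reads), int(ref_reads)
            gnomad_af = _parse_optional_float(variant.INFO.get("GNOMAD_AF"))
            annotations = {}
            for info_key, ann_key in (
                ("CADD", "cadd_phred"),
                ("REVEL", "revel"),
                ("CLNSIG", "clinvar_class"),
                ("GT_CLASS", "genotype"),
            ):
                val = variant.INFO.get(info_key)
                if val is not None:
                    parsed = _parse_optional_float(val)
                    annotations[ann_key] = parsed if parsed is not None else str(val)
            records.append(
                VariantRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    gene=str(variant.INFO.get("GENE") or ""),
                    consequence=str(variant.INFO.get("CONSEQ") or "other"),
                    origin=str(variant.INFO.get("ORIGIN") or default_origin),
                    alt_reads=max(alt_reads, 0),
                    ref_reads=max(ref_reads, 0),
                    gnomad_af=gnomad_af,
                    annotations=annotations,
                )
            )
    return records


def write_variants_tsv(records: Iterable[VariantRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "gene": r.gene,
            "consequence": r.consequence,
            "origin": r.origin,
            "alt_reads": r.alt_reads,
            "ref_reads": r.ref_reads,
            "gnomad_af": "" if r.gnomad_af is None else repr(r.gnomad_af),
            "filter_flags": ";".join(sorted(r.filter_flags)),
        }
        for key in _ANNOTATION_KEYS:
            if key in r.annotations:
                row[key] = r.annotations[key]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_variants_vcf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write the minimal VCF subset this pipeline reads back."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="germline or somatic">',
        '##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="gnomAD allele frequency">',
        '##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred">',
        '##INFO=<ID=REVEL,Number=1,Type=Float,Description="REVEL score">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE",
    ]
    for r in records:
        info = [f"GENE={r.gene or '.'}", f"CONSEQ={r.consequence}", f"ORIGIN={r.origin}"]
        if r.gnomad_af is not None:
            info.append(f"GNOMAD_AF={r.gnomad_af:g}")
        if "cadd_phred" in r.annotations:
            info.append(f"CADD={r.annotations['cadd_phred']:g}")
        if "revel" in r.annotations:
            info.append(f"REVEL={r.annotations['revel']:g}")
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
            f"{';'.join(info)}\tAD\t{r.ref_reads},{r.alt_reads}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# segment / arm IO

_SEG_COLUMNS = ["chrom", "start", "end", "total_cn", "minor_cn"]


def read_segments(
    path: str | Path,
    sample_id: str | None = None,
    dialect: str = "one_based",
    genome_build: str = "unknown",
    chrom_style: str | None = None,
) -> SegmentProfile:
    """Read a SEG-like TSV into a validated :class:`SegmentProfile`.

    ``dialect`` is ``"one_based"`` (inclusive, the internal convention) or
    ``"zero_half_open"`` (BED-style; converted on read).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(_SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    if dialect not in {"one_based", "zero_half_open"}:
        raise ValueError(f"unknown segment dialect {dialect!r}")
    _check_chrom_style(df["chrom"].astype(str), str(path))
    segments = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        start, end = int(row.start), int(row.end)
        if dialect == "zero_half_open":
            start, end = to_one_based(start, end)
        try:
            segments.append(
                Segment(
                    chrom=_apply_chrom_style(str(row.chrom), chrom_style),
                    start=start,
                    end=end,
                    total_cn=int(row.total_cn),
                    minor_cn=int(row.minor_cn),
                    baf=_parse_optional_float(getattr(row, "baf", None)),
                    log2=_parse_optional_float(getattr(row, "log2", None)),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    if sample_id is None:
        sample_id = (
            str(df["sample_id"].iloc[0]) if "sample_id" in df.columns and len(df) else path.stem
        )
    return SegmentProfile(sample_id=sample_id, segments=segments, genome_build=genome_build)


def write_segments(
    profile: SegmentProfile, path: str | Path, dialect: str = "one_based"
) -> None:
    rows = []
    for seg in profile:
        start, end = seg.start, seg.end
        if dialect == "zero_half_open":
            start, end = to_zero_based(start, end)
        rows.append(
            {
                "sample_id": profile.sample_id,
                "chrom": seg.chrom,
                "start": start,
                "end": end,
                "total_cn": seg.total_cn,
                "minor_cn": seg.minor_cn,
                "baf": "" if seg.baf is None else repr(seg.baf),
                "log2": "" if seg.log2 is None else repr(seg.log2),
            }
        )
    pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start", "end", "total_cn", "minor_cn", "baf", "log2"],
    ).to_csv(path, sep="\t", index=False)


def read_arms(path: str | Path) -> ChromosomeArms:
    """Read a chromosome-arm table: chrom, chrom_start, cen_start, cen_end, chrom_end."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "chrom_start", "cen_start", "cen_end", "chrom_end"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    arms = {}
    for row in df.itertuples(index=False):
        arms[str(row.chrom)] = ArmDefinition(
            chrom_start=int(row.chrom_start),
            centromere_start=int(row.cen_start),
            centromere_end=int(row.cen_end),
            chrom_end=int(row.chrom_end),
        )
    return ChromosomeArms(arms)


def read_signature_set(path: str | Path, transpose: bool = False) -> SignatureSet:
    """Read a COSMIC-layout signature matrix TSV (channels x signatures)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.shape[0] != 96:
        raise ParseError(f"{path}: expected 96 channels, found {df.shape[0]} rows")
    unknown = set(df.index) - set(SBS96_CHANNELS)
    if unknown:
        raise ParseError(f"{path}: unrecognised channel labels, e.g. {sorted(unknown)[:3]}")
    df = df.loc[list(SBS96_CHANNELS)]
    return SignatureSet(list(df.columns), df.to_numpy(dtype=float))


def write_signature_set(signatures: SignatureSet, path: str | Path) -> None:
    pd.DataFrame(
        signatures.matrix, index=list(SBS96_CHANNELS), columns=signatures.names
    ).to_csv(path, sep="\t", index_label="channel")


def read_methylation(path: str | Path) -> list[MethylationCall]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "gene", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(
                MethylationCall(
                    sample_id=str(row.sample_id),
                    gene=str(row.gene),
                    status=str(row.status),
                    methylated_allele=str(getattr(row, "methylated_allele", "unknown")),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {i}: {exc}") from exc
    return calls
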