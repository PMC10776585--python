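"""Reading and writing sex-stratified variant count data.

Two input dialects are supported:

* a tab-separated count table with header columns
  ``variant_id, chrom, pos, ref, alt, v_f, a_f, v_m, a_m`` and optional
  ``hom_f, hemi_m, qc_fail`` (``#``-prefixed lines are comments);
* VCF 4.x whose INFO fields carry sex-stratified counts in the gnomAD
  dialect (``AC_female``/``AN_female``/``AC_male``/``AN_male`` and optionally
  ``nhomalt_female``), read through cyvcf2 with multiallelic sites
  decomposed to one record per alternate allele.

Every record is validated against the count invariants and assigned exactly
one region label (PAR1/PAR2/non-PAR X/autosome).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from .ratio import CountValidationError, SexStratifiedCounts
from .regions import GenomicRegionMap, Region, classify_region, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "VcfFieldMap",
    "TableReadResult",
    "read_count_table",
    "write_count_table",
    "read_vcf_counts",
    "write_vcf_counts",
    "filter_by_allele_count",
]

TABLE_COLUMNS = ("variant_id", "chrom", "pos", "ref", "alt", "v_f", "a_f", "v_m", "a_m")
OPTIONAL_COLUMNS = ("hom_f", "hemi_m", "qc_fail")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant with sex-stratified counts and a region label."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    counts: SexStratifiedCounts
    region: Region
    qc_fail: Optional[bool] = None


@dataclass(frozen=True)
class VcfFieldMap:
    """Names of the INFO keys carrying sex-stratified counts (gnomAD dialect)."""

    ac_female: str = "AC_female"
    an_female: str = "AN_female"
    ac_male: str = "AC_male"
    an_male: str = "AN_male"
    nhomalt_female: Optional[str] = "nhomalt_female"


@dataclass
class TableReadResult:
    """Parsed records plus row-level diagnostics for rejected rows."""

    records: List[VariantRecord] = field(default_factory=list)
    errors: List[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return int(value)


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    text = str(value).strip().lower()
    if text in ("1", "true", "yes", "y"):
        return True
    if text in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean qc_fail flag")


def read_count_table(
    path: Union[str, Path],
    region_map: Optional[GenomicRegionMap] = None,
    sep: str = "\t",
    strict: bool = False,
) -> TableReadResult:
    """Read a delimited sex-stratified count table.

    Rows violating the count invariants (negative counts, ``v > a``, …) are
    rejected with a diagnostic naming the 1-based data row; in ``strict``
    mode the first bad row raises instead.  A missing required column raises
    a schema error.
    """
    region_map = region_map or GenomicRegionMap.grch38()
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"chrom": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table {path} is missing required columns: {', '.join(missing)}")

    result = TableReadResult()
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            counts = SexStratifiedCounts(
                v_f=int(getattr(row, "v_f")),
                a_f=int(getattr(row, "a_f")),
                v_m=int(getattr(row, "v_m")),
                a_m=int(getattr(row, "a_m")),
                hom_f=_opt_int(getattr(row, "hom_f", None)),
                hemi_m=_opt_int(getattr(row, "hemi_m", None)),
            )
            chrom = normalize_chrom(getattr(row, "chrom"))
            pos = int(getattr(row, "pos"))
            record = VariantRecord(
                variant_id=str(getattr(row, "variant_id")),
                chrom=chrom,
                pos=pos,
                ref=str(getattr(row, "ref")),
                alt=str(getattr(row, "alt")),
                counts=counts,
                region=classify_region(chrom, pos, region_map),
                qc_fail=_opt_bool(getattr(row, "qc_fail", None)),
            )
        except (CountValidationError, ValueError) as exc:
            message = f"row {idx} ({getattr(row, 'variant_id', '?')}): {exc}"
            if strict:
                raise ValueError(message) from exc
            result.errors.append(message)
            logger.warning("rejected %s", message)
            continue
        result.records.append(record)
    logger.info(
        "read %d records (%d rejected) from %s", len(result.records), len(result.errors), path
    )
    return result


def write_count_table(
    records: Sequence[VariantRecord],
    path: Union[str, Path],
    sep: str = "\t",
) -> None:
    """Write records in the count-table dialect (round-trips exactly)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "variant_id": rec.variant_id,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alt,
                "v_f": rec.counts.v_f,
                "a_f": rec.counts.a_f,
                "v_m": rec.counts.v_m,
                "a_m": rec.counts.a_m,
                "hom_f": rec.counts.hom_f,
                "hemi_m": rec.counts.hemi_m,
                "qc_fail": rec.qc_fail,
            }
        )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS) + list(OPTIONAL_COLUMNS))
    df.to_csv(path, sep=sep, index=False, na_rep="")


def read_vcf_counts(
    path: Union[str, Path],
    field_map: Optional[VcfFieldMap] = None,
    region_map: Optional[GenomicRegionMap] = None,
) -> TableReadResult:
    """Read sex-stratified counts from a gnomAD-dialect VCF.

    Multiallelic sites are decomposed to one record per alternate allele;
    per-allele AC/nhomalt lists are split while the site-level AN totals are
    shared across alleles.  Sites missing a mapped INFO key are skipped and
    counted in the diagnostics.  On the non-pseudoautosomal X, ``hemi_m`` is
    taken to equal the male alt allele count (hemizygous carriage).
    """
    from cyvcf2 import VCF  # imported lazily: only VCF input needs it

    field_map = field_map or VcfFieldMap()
    region_map = region_map or GenomicRegionMap.grch38()
    result = TableReadResult()

    vcf = VCF(str(path))
    try:
        for site in vcf:
            ac_f = site.INFO.get(field_map.ac_female)
            an_f = site.INFO.get(field_map.an_female)
            ac_m = site.INFO.get(field_map.ac_male)
            an_m = site.INFO.get(field_map.an_male)
            if ac_f is None or an_f is None or ac_m is None or an_m is None:
                result.errors.append(
                    f"{site.CHROM}:{site.POS}: missing one of the mapped INFO keys; site skipped"
                )
                continue
            nhom_f = (
                site.INFO.get(field_map.nhomalt_female) if field_map.nhomalt_female else None
            )
            alts = list(site.ALT)
            ac_f_list = _per_allele(ac_f, len(alts))
            ac_m_list = _per_allele(ac_m, len(alts))
            nhom_list = _per_allele(nhom_f, len(alts)) if nhom_f is not None else [None] * len(alts)
            try:
                chrom = normalize_chrom(site.CHROM)
            except ValueError as exc:
                result.errors.append(f"{site.CHROM}:{site.POS}: {exc}")
                continue
            region = classify_region(chrom, site.POS, region_map)
            for alt, vf, vm, hom in zip(alts, ac_f_list, ac_m_list, nhom_list):
                vid = site.ID if site.ID not in (None, ".") else f"{chrom}-{site.POS}-{site.REF}-{alt}"
                if len(alts) > 1:
                    vid = f"{vid}-{alt}" if site.ID not in (None, ".") else vid
                try:
                    counts = SexStratifiedCounts(
                        v_f=int(vf),
                        a_f=int(an_f),
                        v_m=int(vm),
                        a_m=int(an_m),
                        hom_f=int(hom) if hom is not None else None,
                        hemi_m=int(vm) if region is Region.NONPAR_X else None,
                    )
                except CountValidationError as exc:
                    result.errors.append(f"{chrom}:{site.POS} alt {alt}: {exc}")
                    continue
                result.records.append(
                    VariantRecord(
                        variant_id=vid,
                        chrom=chrom,
                        pos=int(site.POS),
                        ref=site.REF,
                        alt=alt,
                        counts=counts,
                        region=region,
                    )
                )
    finally:
        vcf.close()
    logger.info("read %d records from VCF %s (%d skipped)", len(result.records), path, len(result.errors))
    return result


def _per_allele(value, n_alt: int) -> list:
    """INFO values arrive as a scalar for one ALT or a tuple for several."""
    if isinstance(value, (tuple, list)):
        return list(value)
    return [value] * 1 if n_alt == 1 else [value] * n_alt


def write_vcf_counts(
    records: Sequence[VariantRecord],
    path: Union[str, Path],
    field_map: Optional[VcfFieldMap] = None,
) -> None:
    """Write records as an uncompressed gnomAD-dialect VCF (one ALT per line)."""
    field_map = field_map or VcfFieldMap()
    lines = [
        "##fileformat=VCFv4.2",
        f'##INFO=<ID={field_map.ac_female},Number=A,Type=Integer,Description="Alt allele count in females">',
        f'##INFO=<ID={field_map.an_female},Number=1,Type=Integer,Description="Total allele number in females">',
        f'##INFO=<ID={field_map.ac_male},Number=A,Type=Integer,Description="Alt allele count in males">',
        f'##INFO=<ID={field_map.an_male},Number=1,Type=Integer,Description="Total allele number in males">',
    ]
    if field_map.nhomalt_female:
        lines.append(
            f'##INFO=<ID={field_map.nhomalt_female},Number=A,Type=Integer,'
            'Description="Count of homozygous alt females">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        info = (
            f"{field_map.ac_female}={rec.counts.v_f};{field_map.an_female}={rec.counts.a_f};"
            f"{field_map.ac_male}={rec.counts.v_m};{field_map.an_male}={rec.counts.a_m}"
        )
        if field_map.nhomalt_female and rec.counts.hom_f is not None:
            info += f";{field_map.nhomalt_female}={rec.counts.hom_f}"
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.variant_id}\t{rec.ref}\t{rec.alt}\t.\t.\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def filter_by_allele_count(
    records: Sequence[VariantRecord],
    min_ac: int = 5,
    per_sex: bool = False,
) -> List[VariantRecord]:
    """Keep variants observed at least ``min_ac`` times ("at least" is inclusive).

    By default the sex-combined minor allele count ``v_f + v_m`` is compared
    (the gnomAD AC convention); with ``per_sex=True`` each sex must reach
    ``min_ac`` on its own.  Input order is preserved; kept/dropped counts go
    to the run log.
    """
    if min_ac < 0:
        raise ValueError("min_ac must be non-negative")
    if per_sex:
        kept = [r for r in records if r.counts.v_f >= min_ac and r.counts.v_m >= min_ac]
    else:
        kept = [r for r in records if r.counts.combined_minor_count >= min_ac]
    logger.info(
        "allele-count filter (min_ac=%d): kept %d of %d records",
        min_ac,
        len(kept),
        len(records),
    )
    return kept
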