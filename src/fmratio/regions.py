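"""Genomic region classification: pseudoautosomal vs non-PAR X vs autosome.

Males are diploid in the two pseudoautosomal regions (PAR1, PAR2) of the X
chromosome and hemizygous everywhere else on X.  Because PAR loci have no
sex asymmetry in copy number, PAR variants are the built-in null against
which the high-ratio threshold is calibrated.

Coordinates are 1-based; intervals are half-open ``[start, end)``.  Default
PAR intervals follow the standard Ensembl definitions for GRCh37 and GRCh38.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Tuple, Union

import yaml

__all__ = [
    "Region",
    "GenomicRegionMap",
    "classify_region",
    "normalize_chrom",
    "ACCEPTED_CHROMS",
]

ACCEPTED_CHROMS = tuple(str(i) for i in range(1, 23)) + ("X",)


class Region(str, Enum):
    PAR1 = "PAR1"
    PAR2 = "PAR2"
    NONPAR_X = "NONPAR_X"
    AUTOSOME = "AUTOSOME"


def normalize_chrom(chrom: str) -> str:
    """Normalise chromosome labels: ``"chrX"`` → ``"X"``, ``"chr21"`` → ``"21"``.

    Raises ``ValueError`` for labels outside 1–22 and X (the analysis is
    defined on autosomes and the X chromosome only).
    """
    name = str(chrom).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper() if name.lower() == "x" else name
    if name not in ACCEPTED_CHROMS:
        raise ValueError(
            f"unknown chromosome label {chrom!r}; accepted labels: "
            f"{', '.join(ACCEPTED_CHROMS)} (optionally 'chr'-prefixed)"
        )
    return name


@dataclass(frozen=True)
class GenomicRegionMap:
    """PAR interval definitions for one genome build.

    ``par1`` and ``par2`` are half-open 1-based ``(start, end)`` intervals on X.
    """

    build: str
    par1: Tuple[int, int]
    par2: Tuple[int, int]

    def __post_init__(self) -> None:
        for name, (start, end) in (("par1", self.par1), ("par2", self.par2)):
            if not (1 <= start < end):
                raise ValueError(f"{name} interval must satisfy 1 <= start < end, got {start}..{end}")
        if not (self.par1[1] <= self.par2[0] or self.par2[1] <= self.par1[0]):
            raise ValueError("PAR intervals must not overlap")

    @classmethod
    def grch37(cls) -> "GenomicRegionMap":
        return cls(build="GRCh37", par1=(60_001, 2_699_521), par2=(154_931_044, 155_260_561))

    @classmethod
    def grch38(cls) -> "GenomicRegionMap":
        return cls(build="GRCh38", par1=(10_001, 2_781_480), par2=(155_701_383, 156_030_896))

    @classmethod
    def from_build(cls, build: str) -> "GenomicRegionMap":
        key = build.strip().lower()
        if key in ("grch37", "hg19", "37"):
            return cls.grch37()
        if key in ("grch38", "hg38", "38"):
            return cls.grch38()
        raise ValueError(f"unknown build {build!r}; use grch37, grch38, or a custom PAR file")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GenomicRegionMap":
        """Load a custom region map: ``build``, ``par1``/``par2`` with start/end."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            build=str(data.get("build", "custom")),
            par1=(int(data["par1"]["start"]), int(data["par1"]["end"])),
            par2=(int(data["par2"]["start"]), int(data["par2"]["end"])),
        )

    def to_dict(self) -> dict:
        return {
            "build": self.build,
            "par1": {"start": self.par1[0], "end": self.par1[1]},
            "par2": {"start": self.par2[0], "end": self.par2[1]},
        }


def classify_region(chrom: str, pos: int, region_map: GenomicRegionMap) -> Region:
    """Assign exactly one region label to a 1-based genomic position."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    name = normalize_chrom(chrom)
    if name != "X":
        return Region.AUTOSOME
    if region_map.par1[0] <= pos < region_map.par1[1]:
        return Region.PAR1
    if region_map.par2[0] <= pos < region_map.par2[1]:
        return Region.PAR2
    return Region.NONPAR_X
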