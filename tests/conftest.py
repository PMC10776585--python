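import textwrap

import pytest
from hypothesis import HealthCheck, settings

from fmratio import GenomicRegionMap, SexStratifiedCounts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rs201580891_counts() -> SexStratifiedCounts:
    """Published counts for the FMR1 variant observed only in het females."""
    return SexStratifiedCounts(v_f=18736, a_f=104056, v_m=0, a_m=38527, hom_f=0, hemi_m=0)


@pytest.fixture
def grch38_map() -> GenomicRegionMap:
    return GenomicRegionMap.grch38()


@pytest.fixture
def count_table(tmp_path):
    """Write a small well-formed count table; returns its path."""

    def _write(rows, header="variant_id\tchrom\tpos\tref\talt\tv_f\ta_f\tv_m\ta_m\thom_f\themi_m\tqc_fail"):
        path = tmp_path / "counts.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return path

    return _write


@pytest.fixture
def single_site_vcf(tmp_path):
    """Write a minimal gnomAD-dialect VCF; returns a writer function."""

    def _write(body_lines, name="test.vcf"):
        header = textwrap.dedent(
            """\
            ##fileformat=VCFv4.2
            ##contig=<ID=X,length=156040895>
            ##contig=<ID=21,length=46709983>
            ##INFO=<ID=AC_female,Number=A,Type=Integer,Description="x">
            ##INFO=<ID=AN_female,Number=1,Type=Integer,Description="x">
            ##INFO=<ID=AC_male,Number=A,Type=Integer,Description="x">
            ##INFO=<ID=AN_male,Number=1,Type=Integer,Description="x">
            ##INFO=<ID=nhomalt_female,Number=A,Type=Integer,Description="x">
            #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
            """
        )
        path = tmp_path / name
        path.write_text(header + "\n".join(body_lines) + ("\n" if body_lines else ""))
        return path

    return _write
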