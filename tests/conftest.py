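"""Shared fixtures: tiny hand-built VCF/metadata files and call factories."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from chipdyn import ClonePair, FilterPolicy, VariantCall, load_panel

settings.register_profile("repro", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_panel():
    return load_panel()


def make_call(
    individual_id="IND01",
    timepoint=1,
    contig="chr2",
    pos=25234301,  # inside the default DNMT3A territory
    ref="C",
    alt="T",
    depth=2000,
    alt_reads=100,
    gene="DNMT3A",
    **kwargs,
) -> VariantCall:
    return VariantCall(
        individual_id=individual_id, timepoint=timepoint, contig=contig,
        pos=pos, ref=ref, alt=alt, depth=depth, alt_reads=alt_reads,
        vaf=alt_reads / depth, gene=gene, **kwargs,
    )


def make_pair(
    individual_id="IND01",
    gene="DNMT3A",
    key=("chr2", 25234301, "C", "T"),
    vaf1=0.04,
    vaf2=0.06,
    dt_years=5.0,
    **kwargs,
) -> ClonePair:
    defaults = dict(pass_t1=True, pass_t2=True)
    defaults.update(kwargs)
    return ClonePair(
        individual_id=individual_id, gene=gene, mutation_key=key,
        vaf1=vaf1, vaf2=vaf2, dt_years=dt_years, **defaults,
    )


def write_vcf(path: Path, records, samples) -> Path:
    """Minimal two-sample VCF writer for hand-built scenarios.

    ``records``: list of (contig, pos, ref, alts, {sample: (depth, (ad...))}).
    """
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
        """)
    contigs = sorted({r[0] for r in records})
    lines = [header]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
    for contig, pos, ref, alts, per_sample in records:
        n_alleles = 1 + len(alts)
        cells = []
        for s in samples:
            if s in per_sample:
                depth, ad = per_sample[s]
                cells.append(f"0/1:{depth}:" + ",".join(str(a) for a in ad))
            else:
                cells.append("./.:.:" + ",".join("." * n_alleles))
        lines.append(
            f"{contig}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\t"
            f"GT:DP:AD\t" + "\t".join(cells) + "\n"
        )
    path.write_text("".join(lines))
    return path


def two_sample_metadata(individual="IND01", dt_years=5.0, **extra) -> pd.DataFrame:
    rows = []
    for tp, age in ((1, 60.0), (2, 60.0 + dt_years)):
        row = {
            "individual_id": individual, "sample_id": f"{individual}_T{tp}",
            "timepoint": tp, "age": age, "blood_cancer_flag": 0,
        }
        row.update(extra)
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def policy():
    return FilterPolicy()
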