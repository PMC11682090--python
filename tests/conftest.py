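"""Shared fixtures: hand-built VCF text, in-memory tables, small cohorts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from moiscan.vcf_model import (
    CohortManifest,
    EffectAnnotation,
    GenotypeClass,
    QualLabel,
    Role,
    VariantRecord,
    VariantTable,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


VCF_HEADER = """##fileformat=VCFv4.2
##FILTER=<ID=FAIL,Description="failed">
##FILTER=<ID=LowQual,Description="low">
##INFO=<ID=ANN,Number=.,Type=String,Description="ann">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
"""


def write_vcf_text(
    path: Path,
    samples: list[str],
    rows: list[tuple],
    contigs: dict[str, int] | None = None,
) -> Path:
    """Write a small VCF from (chrom, pos, ref, alt, filter, info, gts) rows."""
    contigs = contigs or {"1": 100_000_000, "2": 100_000_000}
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, pos, ref, alt, filt, info, gts in rows:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\tGT\t" + "\t".join(gts) + "\n"
            )
    return path


def make_manifest(
    n_cases: int = 2, n_tier1: int = 2, n_tier2: int = 2, pops: list[str] | None = None
) -> CohortManifest:
    entries = []
    for i in range(1, n_cases + 1):
        entries.append((f"case_{i}", Role.CASE, "Holstein"))
    for i in range(1, n_tier1 + 1):
        entries.append((f"ctrl1_{i:04d}", Role.TIER1_CONTROL, "Tier1Mixed"))
    pops = pops or ["PopA"]
    for i in range(1, n_tier2 + 1):
        entries.append((f"t2_{i:04d}", Role.TIER2_CONTROL, pops[(i - 1) % len(pops)]))
    return CohortManifest(entries)


GC = GenotypeClass


def make_table(
    manifest: CohortManifest,
    rows: list[tuple],
) -> VariantTable:
    """Build a VariantTable directly from rows of
    (chrom, pos, ref, alt, qual_label, effect_terms_or_None, genotype classes)."""
    records = []
    for chrom, pos, ref, alt, qual, terms, classes in rows:
        effects = ()
        if terms is not None:
            effects = (
                EffectAnnotation(
                    allele=alt,
                    gene_symbol=f"G{pos}",
                    effect_terms=tuple(terms),
                    impact="MODERATE",
                ),
            )
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                qual_label=qual,
                effects=effects,
                genotypes=np.array([int(c) for c in classes], dtype=np.int8),
            )
        )
    return VariantTable(manifest.samples, records)


@pytest.fixture
def two_case_manifest() -> CohortManifest:
    return make_manifest(n_cases=2, n_tier1=3, n_tier2=3, pops=["PopA", "PopB"])
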