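"""Per-population genotype counts and variant-allele frequencies.

Tabulates, for one target variant, the hom-alt / het / hom-ref / missing
genotype counts within each population of the cohort manifest and the
variant-allele frequency

    AF = (2 * n_hom_alt + n_het) / (2 * (n_hom_alt + n_het + n_hom_ref))

Missing genotypes are counted separately and excluded from the frequency
denominator (array/WGS mixtures have differential missingness; nothing is
imputed).  Percent display uses two significant figures; the exact
fraction is always emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .vcf_model import CohortManifest, GenotypeClass, VariantTable


@dataclass(frozen=True)
class GenotypeCounts:
    population: str
    n_var_var: int
    n_ref_var: int
    n_ref_ref: int
    n_missing: int

    def __post_init__(self) -> None:
        for name in ("n_var_var", "n_ref_var", "n_ref_ref", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_genotyped(self) -> int:
        return self.n_var_var + self.n_ref_var + self.n_ref_ref


@dataclass(frozen=True)
class PopFreqRow:
    counts: GenotypeCounts
    allele_frequency: float | None  # None when no sample was genotyped
    percent: str

    @property
    def defined(self) -> bool:
        return self.allele_frequency is not None


def genotype_counts(
    table: VariantTable,
    key: tuple[str, int, str, str],
    population: str,
    manifest: CohortManifest,
) -> GenotypeCounts:
    """Genotype-class counts for one variant among one population's samples.

    An unknown variant key is a hard error; an empty population yields
    all-zero counts.
    """
    record = table.find(key)  # KeyError on unknown key
    counts = {c: 0 for c in GenotypeClass}
    for s in manifest.samples_in_population(population):
        counts[GenotypeClass(record.genotypes[table.sample_index(s)])] += 1
    return GenotypeCounts(
        population=population,
        n_var_var=counts[GenotypeClass.HOM_ALT],
        n_ref_var=counts[GenotypeClass.HET],
        n_ref_ref=counts[GenotypeClass.HOM_REF],
        n_missing=counts[GenotypeClass.MISSING],
    )


def format_percent(fraction: float) -> str:
    """Format a fraction as a percentage with two significant figures.

    0.0060622 -> "0.61%", 0.0033076 -> "0.33%", 0.0273973 -> "2.7%",
    0.0 -> "0%".
    """
    pct = fraction * 100.0
    if pct == 0:
        return "0%"
    decimals = 1 - math.floor(math.log10(abs(pct)))
    rounded = round(pct, decimals)
    return f"{rounded:.{max(decimals, 0)}f}%"


def allele_frequency(counts: GenotypeCounts) -> tuple[float | None, str]:
    """Variant-allele frequency and its two-significant-figure percent string.

    Returns ``(None, "NA")`` (flagged undefined) when no sample in the
    population was genotyped.
    """
    denom = 2 * counts.n_genotyped
    if denom == 0:
        return None, "NA"
    frac = (2 * counts.n_var_var + counts.n_ref_var) / denom
    return frac, format_percent(frac)


def population_frequency_row(counts: GenotypeCounts) -> PopFreqRow:
    frac, pct = allele_frequency(counts)
    return PopFreqRow(counts=counts, allele_frequency=frac, percent=pct)


def population_frequency_table(
    table: VariantTable,
    key: tuple[str, int, str, str],
    manifest: CohortManifest,
    populations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per population: genotype counts plus allele frequency."""
    pops = populations if populations is not None else manifest.populations
    rows = []
    for pop in pops:
        row = population_frequency_row(genotype_counts(table, key, pop, manifest))
        c = row.counts
        rows.append(
            {
                "population": pop,
                "var_var": c.n_var_var,
                "ref_var": c.n_ref_var,
                "ref_ref": c.n_ref_ref,
                "missing": c.n_missing,
                "allele_freq_fraction": row.allele_frequency,
                "allele_freq_percent": row.percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "population",
            "var_var",
            "ref_var",
            "ref_ref",
            "missing",
            "allele_freq_fraction",
            "allele_freq_percent",
        ],
    )


def carrier_scan(
    table: VariantTable,
    key: tuple[str, int, str, str],
    manifest: CohortManifest,
) -> list[tuple[str, str, GenotypeClass]]:
    """All non-hom-ref, non-missing samples for one variant.

    Rows are (sample, population, genotype class), sorted by population
    then sample.  An unknown key is a hard error.
    """
    record = table.find(key)
    rows = []
    for s in manifest.samples:
        g = GenotypeClass(record.genotypes[table.sample_index(s)])
        if g in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
            rows.append((s, manifest.population(s), g))
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows


def write_popfreq_tsv(
    frame: pd.DataFrame, path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False)
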