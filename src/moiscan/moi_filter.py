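"""Mode-of-inheritance-stratified private-variant filtering.

The core inference of the package: candidate causal variants for a rare
monogenic disorder are those restricted to affected genomes relative to
tiered control cohorts, under one of three inheritance scenarios:

* recessive shared  — one variant homozygous-alternate in *every* case;
* recessive per-case — homozygous-alternate in one case considered alone;
* dominant per-case — carried (het or hom-alt) by one case and absent from
  all controls.

Each scenario runs a four-stage funnel: all zygosity-compatible variants,
private against the tier-1 control cohort, protein-changing by annotation,
and surviving the larger tier-2 (global) cohort.  A funnel report records
the per-case counts at every stage.

Privacy thresholds are configurable.  By default the recessive filters
allow heterozygous control carriers (a recessive causal allele segregates
in carrier state in the wider population and strict allele-absence would
discard it) while the dominant filter requires strict absence of the
alternate allele from all controls.  Missing control genotypes never count
as carriers; a missing case genotype excludes the variant for that case.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .vcf_model import (
    CohortManifest,
    GenotypeClass,
    QualLabel,
    Role,
    VariantRecord,
    VariantTable,
    write_vcf,
)

#: Effect terms counted as protein-changing by default.  Covers missense,
#: stop/start changes, frameshifts, in-frame indels and splice-site
#: disruption; configurable because annotation pipelines differ.
DEFAULT_PROTEIN_CHANGING_TERMS = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "frameshift_variant",
        "conservative_inframe_deletion",
        "disruptive_inframe_deletion",
        "conservative_inframe_insertion",
        "disruptive_inframe_insertion",
        "splice_acceptor_variant",
        "splice_donor_variant",
        "protein_altering_variant",
    }
)

#: case_id used by the recessive-shared filter (all cases jointly).
ALL_CASES = "ALL"


class Moi(str, enum.Enum):
    RECESSIVE_SHARED = "RECESSIVE_SHARED"
    RECESSIVE_INDIVIDUAL = "RECESSIVE_INDIVIDUAL"
    DOMINANT_INDIVIDUAL = "DOMINANT_INDIVIDUAL"


class Stage(enum.IntEnum):
    ALL = 0
    PRIVATE_TIER1 = 1
    PROTEIN_CHANGING = 2
    POST_TIER2 = 3


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the privacy filters.

    ``None`` means unbounded.  Tier-1 thresholds gate the first privacy
    stage, tier-2 thresholds the final stage.  ``require_pass`` restricts
    the analysis to PASS-labelled records; ``include_unlabeled`` lets
    records with no FILTER entry through as well.
    """

    protein_changing_terms: frozenset[str] = DEFAULT_PROTEIN_CHANGING_TERMS
    recessive_max_control_het_tier1: int | None = None
    recessive_max_control_homalt_tier1: int = 0
    dominant_max_control_alt_alleles_tier1: int = 0
    recessive_max_control_het_tier2: int | None = None
    recessive_max_control_homalt_tier2: int = 0
    dominant_max_control_alt_alleles_tier2: int = 0
    require_pass: bool = True
    include_unlabeled: bool = False

    def __post_init__(self) -> None:
        for name in (
            "recessive_max_control_het_tier1",
            "recessive_max_control_homalt_tier1",
            "dominant_max_control_alt_alleles_tier1",
            "recessive_max_control_het_tier2",
            "recessive_max_control_homalt_tier2",
            "dominant_max_control_alt_alleles_tier2",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0 or None, got {v}")

    def as_dict(self) -> dict:
        d = {
            "protein_changing_terms": sorted(self.protein_changing_terms),
            "recessive_max_control_het_tier1": self.recessive_max_control_het_tier1,
            "recessive_max_control_homalt_tier1": self.recessive_max_control_homalt_tier1,
            "dominant_max_control_alt_alleles_tier1": self.dominant_max_control_alt_alleles_tier1,
            "recessive_max_control_het_tier2": self.recessive_max_control_het_tier2,
            "recessive_max_control_homalt_tier2": self.recessive_max_control_homalt_tier2,
            "dominant_max_control_alt_alleles_tier2": self.dominant_max_control_alt_alleles_tier2,
            "require_pass": self.require_pass,
            "include_unlabeled": self.include_unlabeled,
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: Mapping) -> "FilterConfig":
        kwargs = dict(data)
        if "protein_changing_terms" in kwargs:
            kwargs["protein_changing_terms"] = frozenset(kwargs["protein_changing_terms"])
        return cls(**kwargs)


@dataclass
class CandidateSet:
    """Variants surviving one funnel stage for one (case, MOI) pair."""

    case_id: str
    moi: Moi
    stage: Stage
    variants: list[VariantRecord]
    samples: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> list[tuple[str, int, str, str]]:
        return [v.key for v in self.variants]

    def gene_symbols(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.variants:
            for g in v.gene_symbols():
                seen.setdefault(g, None)
        return tuple(sorted(seen))


def _quality_mask(table: VariantTable, cfg: FilterConfig) -> np.ndarray:
    if not cfg.require_pass:
        return np.ones(len(table), dtype=bool)
    allowed = {QualLabel.PASS}
    if cfg.include_unlabeled:
        allowed.add(QualLabel.UNLABELED)
    return np.array([r.qual_label in allowed for r in table.records], dtype=bool)


def _le(counts: np.ndarray, limit: int | None) -> np.ndarray:
    if limit is None:
        return np.ones(len(counts), dtype=bool)
    return counts <= limit


def _tier_counts(m: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (het, hom-alt, alt-allele) counts over control columns."""
    sub = m[:, cols] if len(cols) else np.zeros((m.shape[0], 0), dtype=np.int8)
    het = (sub == GenotypeClass.HET).sum(axis=1)
    hom = (sub == GenotypeClass.HOM_ALT).sum(axis=1)
    return het, hom, het + 2 * hom


def _check_case(case_id: str, manifest: CohortManifest) -> None:
    if case_id not in manifest.samples:
        raise KeyError(f"unknown sample id {case_id!r}")
    if manifest.role(case_id) is not Role.CASE:
        raise ValueError(f"sample {case_id!r} does not have role CASE")


def _select(table: VariantTable, keep: np.ndarray) -> list[VariantRecord]:
    return [table.records[i] for i in np.flatnonzero(keep)]


def _recessive_private_mask(
    table: VariantTable,
    manifest: CohortManifest,
    cfg: FilterConfig,
    case_mask: np.ndarray,
) -> np.ndarray:
    m = table.genotype_matrix()
    t1 = table.sample_indices(manifest.tier1_controls)
    het, hom, _ = _tier_counts(m, t1)
    return (
        case_mask
        & _quality_mask(table, cfg)
        & _le(hom, cfg.recessive_max_control_homalt_tier1)
        & _le(het, cfg.recessive_max_control_het_tier1)
    )


def filter_recessive_shared(
    table: VariantTable, manifest: CohortManifest, cfg: FilterConfig
) -> CandidateSet:
    """Variants homozygous-alternate in every case and private to tier-1.

    A MISSING genotype in any case excludes the variant.  Returns the
    PRIVATE_TIER1 stage for (ALL, RECESSIVE_SHARED).
    """
    m = table.genotype_matrix()
    case_cols = table.sample_indices(manifest.cases)
    all_hom = (m[:, case_cols] == GenotypeClass.HOM_ALT).all(axis=1)
    keep = _recessive_private_mask(table, manifest, cfg, all_hom)
    return CandidateSet(
        ALL_CASES, Moi.RECESSIVE_SHARED, Stage.PRIVATE_TIER1, _select(table, keep), table.samples
    )


def filter_recessive_individual(
    table: VariantTable, case_id: str, manifest: CohortManifest, cfg: FilterConfig
) -> CandidateSet:
    """Variants homozygous-alternate in one case, private to tier-1.

    Other cases are ignored — each case is considered individually.
    """
    _check_case(case_id, manifest)
    m = table.genotype_matrix()
    col = table.sample_index(case_id)
    hom_case = m[:, col] == GenotypeClass.HOM_ALT
    keep = _recessive_private_mask(table, manifest, cfg, hom_case)
    return CandidateSet(
        case_id, Moi.RECESSIVE_INDIVIDUAL, Stage.PRIVATE_TIER1, _select(table, keep), table.samples
    )


def filter_dominant_individual(
    table: VariantTable, case_id: str, manifest: CohortManifest, cfg: FilterConfig
) -> CandidateSet:
    """Variants carried by one case with the alt allele (near-)absent in tier-1.

    The default threshold of 0 alt alleles implements strict absence of the
    variant allele from all tier-1 controls.
    """
    _check_case(case_id, manifest)
    m = table.genotype_matrix()
    col = table.sample_index(case_id)
    carrier = (m[:, col] == GenotypeClass.HET) | (m[:, col] == GenotypeClass.HOM_ALT)
    t1 = table.sample_indices(manifest.tier1_controls)
    _, _, alt_ct = _tier_counts(m, t1)
    keep = (
        carrier
        & _quality_mask(table, cfg)
        & _le(alt_ct, cfg.dominant_max_control_alt_alleles_tier1)
    )
    return CandidateSet(
        case_id, Moi.DOMINANT_INDIVIDUAL, Stage.PRIVATE_TIER1, _select(table, keep), table.samples
    )


def stage_all(
    table: VariantTable,
    manifest: CohortManifest,
    cfg: FilterConfig,
    moi: Moi,
    case_id: str | None = None,
) -> CandidateSet:
    """The funnel's ALL stage: zygosity-compatible variants for a (case, MOI).

    Mirrors the per-case "all variants" column of a filtering funnel: the
    quality-passing variants whose case genotype already satisfies the MOI
    (hom-alt for recessive, any alt carrier for dominant), before any
    control-cohort comparison.
    """
    m = table.genotype_matrix()
    qmask = _quality_mask(table, cfg)
    if moi is Moi.RECESSIVE_SHARED:
        case_cols = table.sample_indices(manifest.cases)
        zmask = (m[:, case_cols] == GenotypeClass.HOM_ALT).all(axis=1)
        cid = ALL_CASES
    else:
        assert case_id is not None, "case_id required for per-case MOIs"
        _check_case(case_id, manifest)
        col = table.sample_index(case_id)
        if moi is Moi.RECESSIVE_INDIVIDUAL:
            zmask = m[:, col] == GenotypeClass.HOM_ALT
        else:
            zmask = (m[:, col] == GenotypeClass.HET) | (m[:, col] == GenotypeClass.HOM_ALT)
        cid = case_id
    return CandidateSet(cid, moi, Stage.ALL, _select(table, zmask & qmask), table.samples)


def apply_protein_changing_filter(cset: CandidateSet, cfg: FilterConfig) -> CandidateSet:
    """Retain variants with >=1 annotation term in the protein-changing set."""
    if cset.stage is not Stage.PRIVATE_TIER1:
        raise ValueError(
            f"protein-changing filter expects stage PRIVATE_TIER1, got {cset.stage.name}"
        )
    terms = cfg.protein_changing_terms
    kept = [
        v
        for v in cset.variants
        if any(terms.intersection(e.effect_terms) for e in v.effects)
    ]
    return CandidateSet(cset.case_id, cset.moi, Stage.PROTEIN_CHANGING, kept, cset.samples)


def apply_tier2_filter(
    cset: CandidateSet,
    manifest: CohortManifest,
    cfg: FilterConfig,
    review_path: str | Path | None = None,
) -> CandidateSet:
    """Re-apply the MOI-appropriate carrier thresholds against tier-2 controls.

    With an empty tier-2 cohort the output equals the input.  If
    ``review_path`` is given, a manual-review TSV (chrom, pos, ref, alt,
    case, genotype, gene) is written for the surviving variants — the
    machine-readable stand-in for a by-eye alignment inspection.
    """
    if cset.stage is not Stage.PROTEIN_CHANGING:
        raise ValueError(
            f"tier-2 filter expects stage PROTEIN_CHANGING, got {cset.stage.name}"
        )
    sample_index = {s: i for i, s in enumerate(cset.samples)}
    t2 = np.array([sample_index[s] for s in manifest.tier2_controls], dtype=np.intp)
    kept: list[VariantRecord] = []
    for v in cset.variants:
        sub = v.genotypes[t2] if len(t2) else np.zeros(0, dtype=np.int8)
        het = int((sub == GenotypeClass.HET).sum())
        hom = int((sub == GenotypeClass.HOM_ALT).sum())
        if cset.moi is Moi.DOMINANT_INDIVIDUAL:
            ok = _le(np.array([het + 2 * hom]), cfg.dominant_max_control_alt_alleles_tier2)[0]
        else:
            ok = (
                _le(np.array([hom]), cfg.recessive_max_control_homalt_tier2)[0]
                and _le(np.array([het]), cfg.recessive_max_control_het_tier2)[0]
            )
        if ok:
            kept.append(v)
    out = CandidateSet(cset.case_id, cset.moi, Stage.POST_TIER2, kept, cset.samples)
    if review_path is not None:
        manual_review_frame(out, manifest).to_csv(review_path, sep="\t", index=False)
    return out


def manual_review_frame(cset: CandidateSet, manifest: CohortManifest) -> pd.DataFrame:
    """Per-(variant, case) genotype table for manual review of final candidates."""
    cases = manifest.cases if cset.case_id == ALL_CASES else (cset.case_id,)
    sample_index = {s: i for i, s in enumerate(cset.samples)}
    rows = []
    for v in cset.variants:
        for c in cases:
            g = GenotypeClass(v.genotypes[sample_index[c]])
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "case": c,
                    "genotype": g.name,
                    "gene": ",".join(v.gene_symbols()) or ".",
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "case", "genotype", "gene"]
    )


def run_moi_pipeline(
    table: VariantTable,
    manifest: CohortManifest,
    cfg: FilterConfig,
    moi: Moi,
    case_id: str | None = None,
    review_path: str | Path | None = None,
) -> dict[Stage, CandidateSet]:
    """Run the four-stage funnel for one (case, MOI) pair."""
    stages: dict[Stage, CandidateSet] = {}
    stages[Stage.ALL] = stage_all(table, manifest, cfg, moi, case_id)
    if moi is Moi.RECESSIVE_SHARED:
        private = filter_recessive_shared(table, manifest, cfg)
    elif moi is Moi.RECESSIVE_INDIVIDUAL:
        private = filter_recessive_individual(table, case_id, manifest, cfg)
    else:
        private = filter_dominant_individual(table, case_id, manifest, cfg)
    stages[Stage.PRIVATE_TIER1] = private
    stages[Stage.PROTEIN_CHANGING] = apply_protein_changing_filter(private, cfg)
    stages[Stage.POST_TIER2] = apply_tier2_filter(
        stages[Stage.PROTEIN_CHANGING], manifest, cfg, review_path=review_path
    )
    return stages


@dataclass(frozen=True)
class FunnelRow:
    case_id: str
    moi: Moi
    n_all: int
    n_private_tier1: int
    n_protein_changing: int
    n_post_tier2: int
    candidate_genes: tuple[str, ...]


@dataclass
class FunnelReport:
    """Machine twin of a per-case filtering-funnel table."""

    rows: list[FunnelRow]

    #: TSV column order mirrors the published funnel tables:
    #: all -> private(tier-1) -> protein-changing -> post-tier-2 -> genes.
    COLUMNS = (
        "case_id",
        "moi",
        "all_variants",
        "private_variants_tier1",
        "private_protein_changing_tier1",
        "remaining_post_tier2",
        "candidate_genes",
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "case_id": r.case_id,
                    "moi": r.moi.value,
                    "all_variants": r.n_all,
                    "private_variants_tier1": r.n_private_tier1,
                    "private_protein_changing_tier1": r.n_protein_changing,
                    "remaining_post_tier2": r.n_post_tier2,
                    "candidate_genes": ",".join(r.candidate_genes) or "None",
                }
                for r in self.rows
            ],
            columns=list(self.COLUMNS),
        )

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def build_funnel_report(
    stages_by_case: Mapping[tuple[str, Moi], Mapping[Stage, CandidateSet]],
) -> FunnelReport:
    """Assemble the stage counts of several funnels into one report.

    Requires all four stages per (case, MOI); raises if one is missing or
    if counts increase along the funnel (which would indicate a filter bug).
    """
    rows = []
    for (case_id, moi), stages in stages_by_case.items():
        missing = [s.name for s in Stage if s not in stages]
        if missing:
            raise ValueError(
                f"funnel for ({case_id}, {moi.value}) missing stage(s): {', '.join(missing)}"
            )
        counts = [len(stages[s]) for s in Stage]
        if any(a < b for a, b in zip(counts, counts[1:])):
            raise ValueError(
                f"funnel counts increase along stages for ({case_id}, {moi.value}): {counts}"
            )
        rows.append(
            FunnelRow(
                case_id=case_id,
                moi=moi,
                n_all=counts[0],
                n_private_tier1=counts[1],
                n_protein_changing=counts[2],
                n_post_tier2=counts[3],
                candidate_genes=stages[Stage.POST_TIER2].gene_symbols(),
            )
        )
    return FunnelReport(rows)


def write_candidate_vcf(
    cset: CandidateSet, table: VariantTable, path: str | Path
) -> None:
    """Write one candidate set as a VCF subset of the source table."""
    write_vcf(table.subset(cset.variants), path)
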