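"""Seeded generator of annotated multi-sample VCF cohorts with known truth.

Emulates the study design of a rare-disease case/control resequencing
cohort: a handful of affected genomes, a primary (tier-1) control cohort,
a larger global (tier-2) cohort partitioned into labelled populations,
background polymorphism, planted causal variants consistent with a chosen
mode of inheritance, heterozygous carriers of case alleles in designated
control populations, and per-sample runs-of-homozygosity blocks.  Every
run also writes a machine-readable truth table so each pipeline stage can
be checked exactly, with no external data.

Model choices (deliberately minimal, not population-genetically realistic):

* background genotypes are drawn under Hardy–Weinberg equilibrium with a
  per-variant allele frequency uniform on a configurable interval — the
  minimal neutral choice; there is no linkage, no coalescent structure,
  no sequencing-error model;
* evenly spaced "marker" variants provide the homozygosity track; inside a
  sample's planted ROH block every genotype of that sample is homozygous
  (an ROH is homozygous at every site by definition), outside, markers are
  heterozygous at a configurable rate so runs terminate quickly;
* zero false candidates are guaranteed *by construction*: any non-planted
  variant with no homozygous-alternate tier-1 control gets one forced, so
  no background variant can ever be private to a case under either the
  recessive (hom-alt threshold 0) or dominant (alt-allele threshold 0)
  definition.

Outputs are deterministic given the seed (byte-identical VCF); different
seeds change the background but never the planted truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence  # noqa: F401  (Sequence used in TruthTable API)

import numpy as np

from .moi_filter import DEFAULT_PROTEIN_CHANGING_TERMS, FilterConfig, Moi, Stage
from .vcf_model import GT_STRINGS, CohortManifest, GenotypeClass, Role

logger = logging.getLogger(__name__)

_BASES = ("A", "C", "G", "T")

HOM_REF = int(GenotypeClass.HOM_REF)
HET = int(GenotypeClass.HET)
HOM_ALT = int(GenotypeClass.HOM_ALT)
MISSING = int(GenotypeClass.MISSING)


@dataclass(frozen=True)
class PlantedVariant:
    """One planted variant with its MOI-consistent genotype layout.

    Target cases receive HOM_ALT (recessive MOIs) or HET (dominant);
    ``control_het_carriers`` maps population labels (tier-2 populations or
    the tier-1 population label) to a count of heterozygous carriers,
    assigned deterministically to the first samples of that population.
    A dominant planting with control carriers is a tier-2 "decoy": it
    survives tier-1 privacy but is removed by the global cohort, and the
    truth table records that expected fate.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    moi: Moi
    target_cases: tuple[str, ...]
    control_het_carriers: Mapping[str, int] = field(default_factory=dict)
    gene_symbol: str = "GENE"
    effect_terms: tuple[str, ...] = ("missense_variant",)
    impact: str = "MODERATE"
    hgvs_c: str = ""
    hgvs_p: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ROHBlock:
    """A planted homozygous block (0-based half-open) for a set of samples."""

    samples: tuple[str, ...]
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ROHBlock requires end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one simulated cohort."""

    n_cases: int = 7
    n_tier1_controls: int = 25
    tier2_populations: Mapping[str, int] = field(
        default_factory=lambda: {"PopA": 10, "PopB": 10}
    )
    case_population: str = "Holstein"
    tier1_population: str = "Tier1Mixed"
    n_background_variants: int = 300
    background_af_range: tuple[float, float] = (0.01, 0.5)
    plantings: tuple[PlantedVariant, ...] = ()
    roh_blocks: tuple[ROHBlock, ...] = ()
    chromosome_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"1": 50_000_000, "2": 50_000_000}
    )
    markers_per_mb: float = 20.0
    het_rate_outside_roh: float = 0.5
    missing_rate: float = 0.0
    seed: int = 0

    @property
    def case_ids(self) -> tuple[str, ...]:
        return tuple(f"case_{i}" for i in range(1, self.n_cases + 1))

    @property
    def tier1_ids(self) -> tuple[str, ...]:
        return tuple(f"ctrl1_{i:04d}" for i in range(1, self.n_tier1_controls + 1))

    def tier2_ids(self, population: str) -> tuple[str, ...]:
        n = self.tier2_populations[population]
        return tuple(f"{population}_{i:04d}" for i in range(1, n + 1))

    @property
    def sample_ids(self) -> tuple[str, ...]:
        out = list(self.case_ids) + list(self.tier1_ids)
        for pop in self.tier2_populations:
            out.extend(self.tier2_ids(pop))
        return tuple(out)

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ValueError("need at least one case")
        lengths = dict(self.chromosome_lengths)
        cases = set(self.case_ids)
        pops = set(self.tier2_populations) | {self.tier1_population}
        pop_sizes = dict(self.tier2_populations)
        pop_sizes[self.tier1_population] = self.n_tier1_controls
        for p in self.plantings:
            if p.chrom not in lengths or not 1 <= p.pos <= lengths[p.chrom]:
                raise ValueError(f"planting {p.key} outside chromosome table")
            unknown = set(p.target_cases) - cases
            if unknown:
                raise ValueError(f"planting {p.key} targets unknown case(s) {unknown}")
            for pop, count in p.control_het_carriers.items():
                if pop not in pops:
                    raise ValueError(f"planting {p.key}: unknown population {pop!r}")
                if count > pop_sizes[pop]:
                    raise ValueError(
                        f"planting {p.key}: {count} carriers exceed population "
                        f"{pop!r} of size {pop_sizes[pop]}"
                    )
        ids = set(self.sample_ids)
        for b in self.roh_blocks:
            if b.chrom not in lengths or b.end > lengths[b.chrom]:
                raise ValueError(f"ROH block {b} outside chromosome table")
            unknown = set(b.samples) - ids
            if unknown:
                raise ValueError(f"ROH block targets unknown sample(s) {unknown}")

    def manifest(self) -> CohortManifest:
        entries: list[tuple[str, Role, str]] = []
        for s in self.case_ids:
            entries.append((s, Role.CASE, self.case_population))
        for s in self.tier1_ids:
            entries.append((s, Role.TIER1_CONTROL, self.tier1_population))
        for pop in self.tier2_populations:
            for s in self.tier2_ids(pop):
                entries.append((s, Role.TIER2_CONTROL, pop))
        return CohortManifest(entries)


@dataclass
class TruthTable:
    """Machine-readable record of everything the generator planted."""

    plantings: list[dict]
    roh_blocks: list[dict]
    expected_froh: dict[str, float]
    chromosome_lengths: dict[str, int]
    seed: int

    def expected_final_keys(
        self, moi: Moi, case_id: str | None = None
    ) -> list[tuple[str, int, str, str]]:
        """Keys of plantings expected to survive the full funnel."""
        return self.expected_keys_at(moi, Stage.POST_TIER2, case_id)

    def expected_filter_survivors(
        self,
        moi: Moi,
        all_cases: Sequence[str],
        case_id: str | None = None,
        cfg: FilterConfig | None = None,
        tier1_population: str = "Tier1Mixed",
        stage: Stage = Stage.POST_TIER2,
    ) -> list[tuple[str, int, str, str]]:
        """Planting keys whose *genotype layout* satisfies a filter.

        Unlike :meth:`expected_keys_at`, which groups plantings by their
        nominal MOI, this evaluates the actual genotype layout against a
        filter's definition: a shared recessive planting (hom-alt in every
        case) also satisfies the per-case recessive filter for each target
        case, and any planting whose case carries the alt allele enters
        the dominant funnel — subject to the carrier thresholds at each
        tier.  This is what an exact recovery check must compare against.
        """
        cfg = cfg or FilterConfig()
        moi = Moi(moi)
        out = []
        for p in self.plantings:
            p_moi = Moi(p["moi"])
            targets = set(p["target_cases"])
            hom = p_moi is not Moi.DOMINANT_INDIVIDUAL  # targets are HOM_ALT else HET
            carriers = {k: int(v) for k, v in p["control_het_carriers"].items()}
            t1_het = carriers.get(tier1_population, 0)
            t2_het = sum(v for k, v in carriers.items() if k != tier1_population)
            protein = bool(set(p["effect_terms"]) & cfg.protein_changing_terms)
            if moi is Moi.RECESSIVE_SHARED:
                zyg_ok = hom and targets >= set(all_cases)
            elif moi is Moi.RECESSIVE_INDIVIDUAL:
                zyg_ok = hom and case_id in targets
            else:
                zyg_ok = case_id in targets  # HET and HOM_ALT both carry the allele
            if not zyg_ok:
                continue
            if moi is Moi.DOMINANT_INDIVIDUAL:
                t1_ok = 2 * 0 + t1_het <= cfg.dominant_max_control_alt_alleles_tier1
                t2_ok = t2_het <= cfg.dominant_max_control_alt_alleles_tier2
            else:
                t1_ok = cfg.recessive_max_control_het_tier1 is None or (
                    t1_het <= cfg.recessive_max_control_het_tier1
                )
                t2_ok = cfg.recessive_max_control_het_tier2 is None or (
                    t2_het <= cfg.recessive_max_control_het_tier2
                )
            reached = Stage.ALL
            if t1_ok:
                reached = Stage.PRIVATE_TIER1
                if protein:
                    reached = Stage.PROTEIN_CHANGING
                    if t2_ok:
                        reached = Stage.POST_TIER2
            if reached >= stage:
                out.append((p["chrom"], p["pos"], p["ref"], p["alt"]))
        return out

    def expected_keys_at(
        self, moi: Moi, stage: Stage, case_id: str | None = None
    ) -> list[tuple[str, int, str, str]]:
        """Keys of plantings expected to reach at least ``stage``."""
        out = []
        for p in self.plantings:
            if Moi(p["moi"]) is not Moi(moi):
                continue
            if case_id is not None and case_id not in p["target_cases"]:
                continue
            if Stage[p["expected_stage"]] >= stage:
                out.append((p["chrom"], p["pos"], p["ref"], p["alt"]))
        return out

    def to_json(self, path: str | Path) -> None:
        data = {
            "plantings": self.plantings,
            "roh_blocks": self.roh_blocks,
            "expected_froh": self.expected_froh,
            "chromosome_lengths": self.chromosome_lengths,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            plantings=data["plantings"],
            roh_blocks=data["roh_blocks"],
            expected_froh=data["expected_froh"],
            chromosome_lengths=data["chromosome_lengths"],
            seed=data["seed"],
        )


@dataclass(frozen=True)
class SimulatedCohort:
    vcf_path: Path
    manifest_path: Path
    truth_path: Path
    genome_path: Path
    manifest: CohortManifest
    truth: TruthTable


def _expected_stage(p: PlantedVariant, cfg: FilterConfig, tier1_population: str) -> Stage:
    """Furthest funnel stage a planting reaches under the given thresholds."""
    t1_het = int(p.control_het_carriers.get(tier1_population, 0))
    t2_het = sum(
        int(c) for pop, c in p.control_het_carriers.items() if pop != tier1_population
    )
    protein_changing = bool(set(p.effect_terms) & cfg.protein_changing_terms)
    if p.moi is Moi.DOMINANT_INDIVIDUAL:
        t1_ok = t1_het <= cfg.dominant_max_control_alt_alleles_tier1
        t2_ok = t2_het <= cfg.dominant_max_control_alt_alleles_tier2
    else:
        t1_ok = cfg.recessive_max_control_het_tier1 is None or (
            t1_het <= cfg.recessive_max_control_het_tier1
        )
        t2_ok = cfg.recessive_max_control_het_tier2 is None or (
            t2_het <= cfg.recessive_max_control_het_tier2
        )
    if not t1_ok:
        return Stage.ALL
    if not protein_changing:
        return Stage.PRIVATE_TIER1
    if not t2_ok:
        return Stage.PROTEIN_CHANGING
    return Stage.POST_TIER2


def _build_truth(config: SimConfig, filter_cfg: FilterConfig) -> TruthTable:
    plantings = []
    for p in config.plantings:
        plantings.append(
            {
                "chrom": p.chrom,
                "pos": p.pos,
                "ref": p.ref,
                "alt": p.alt,
                "moi": p.moi.value,
                "target_cases": list(p.target_cases),
                "control_het_carriers": dict(p.control_het_carriers),
                "gene_symbol": p.gene_symbol,
                "effect_terms": list(p.effect_terms),
                "expected_stage": _expected_stage(p, filter_cfg, config.tier1_population).name,
            }
        )
    blocks = [
        {"samples": list(b.samples), "chrom": b.chrom, "start": b.start, "end": b.end}
        for b in config.roh_blocks
    ]
    genome = sum(config.chromosome_lengths.values())
    froh: dict[str, float] = {s: 0.0 for s in config.case_ids}
    for b in config.roh_blocks:
        for s in b.samples:
            froh[s] = froh.get(s, 0.0) + b.length / genome
    return TruthTable(
        plantings=plantings,
        roh_blocks=blocks,
        expected_froh=froh,
        chromosome_lengths=dict(config.chromosome_lengths),
        seed=config.seed,
    )


def _ann(allele: str, terms: Sequence[str], impact: str, gene: str,
         hgvs_c: str = "", hgvs_p: str = "") -> str:
    return "|".join(
        [allele, "&".join(terms), impact, gene, gene, "transcript",
         f"{gene}.t1", "protein_coding", "1/1", hgvs_c, hgvs_p]
    )


def _blocks_for_sample(config: SimConfig, sample: str, chrom: str) -> list[tuple[int, int]]:
    return [
        (b.start, b.end)
        for b in config.roh_blocks
        if b.chrom == chrom and sample in b.samples
    ]


def _homozygose_blocks(
    config: SimConfig,
    chrom: str,
    pos: np.ndarray,
    geno: np.ndarray,
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    resample: bool,
) -> None:
    """Force each scoped sample homozygous at variants inside its blocks.

    ``resample`` redraws masked markers as HOM_REF/HOM_ALT (used for the
    marker track); otherwise heterozygous calls are set to HOM_REF and
    existing homozygous calls kept (used for background variants).
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    for b in config.roh_blocks:
        if b.chrom != chrom:
            continue
        mask = (pos - 1 >= b.start) & (pos - 1 < b.end)
        k = int(mask.sum())
        if k == 0:
            continue
        for s in b.samples:
            col = idx[s]
            if resample:
                draw = rng.random(k)
                geno[mask, col] = np.where(draw < 0.7, HOM_REF, HOM_ALT).astype(np.int8)
            else:
                sub = geno[mask, col]
                sub[sub == HET] = HOM_REF
                sub[sub == MISSING] = HOM_REF
                geno[mask, col] = sub


def _enforce_tier1_homalt(
    geno: np.ndarray, tier1_cols: np.ndarray, rng: np.random.Generator
) -> None:
    """Give every variant at least one hom-alt tier-1 control.

    Defeats case privacy deterministically for non-planted variants: the
    tier-1 hom-alt count is >= 1 (recessive threshold 0 fails) and the
    tier-1 alt-allele count >= 2 (dominant threshold 0 fails).
    """
    if len(tier1_cols) == 0:
        return
    hom_any = (geno[:, tier1_cols] == HOM_ALT).any(axis=1)
    rows = np.flatnonzero(~hom_any)
    if len(rows):
        picks = rng.integers(0, len(tier1_cols), size=len(rows))
        geno[rows, tier1_cols[picks]] = HOM_ALT


def simulate_cohort(config: SimConfig, out_dir: str | Path,
                    filter_cfg: FilterConfig | None = None) -> SimulatedCohort:
    """Generate the cohort VCF, manifest TSV, truth JSON and genome table.

    Deterministic given ``config.seed`` (byte-identical outputs).  The
    truth table's expected funnel stages are computed under ``filter_cfg``
    (defaults to the package's default thresholds).
    """
    config.validate()
    filter_cfg = filter_cfg or FilterConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    samples = config.sample_ids
    n_s = len(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    tier1_cols = np.array([sample_index[s] for s in config.tier1_ids], dtype=np.intp)

    planted_pos = {(p.chrom, p.pos) for p in config.plantings}
    rows: list[tuple[str, int, str, str, str, np.ndarray]] = []

    # --- marker track (evenly spaced; drives ROH detection) ---
    p_het = config.het_rate_outside_roh
    p_hr = 0.70 * (1.0 - p_het)
    for chrom, length in config.chromosome_lengths.items():
        if config.markers_per_mb <= 0:
            continue
        spacing = int(round(1_000_000 / config.markers_per_mb))
        pos = np.arange(max(spacing // 2, 1), length + 1, spacing, dtype=np.int64)
        keep = np.array([(chrom, int(p)) not in planted_pos for p in pos])
        pos = pos[keep]
        n_m = len(pos)
        refs = rng.integers(0, 4, size=n_m)
        alt_off = rng.integers(1, 4, size=n_m)
        u = rng.random((n_m, n_s))
        geno = np.where(
            u < p_hr, HOM_REF, np.where(u < p_hr + p_het, HET, HOM_ALT)
        ).astype(np.int8)
        _homozygose_blocks(config, chrom, pos, geno, samples, rng, resample=True)
        _enforce_tier1_homalt(geno, tier1_cols, rng)
        if config.missing_rate > 0:
            miss = rng.random((n_m, n_s)) < config.missing_rate
            geno[miss] = MISSING
        for i in range(n_m):
            ref = _BASES[refs[i]]
            alt = _BASES[(refs[i] + alt_off[i]) % 4]
            ann = _ann(alt, ("intron_variant",), "MODIFIER", f"MRK{chrom}G{i // 50}")
            rows.append((chrom, int(pos[i]), ref, alt, ann, geno[i]))

    # --- background polymorphism (HWE, uniform allele-frequency prior) ---
    chrom_names = list(config.chromosome_lengths)
    chrom_len = np.array([config.chromosome_lengths[c] for c in chrom_names], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    used = {(c, p) for (c, p, *_rest) in [(r[0], r[1]) for r in rows]}
    used |= planted_pos
    bg_terms = (
        ("intron_variant", "MODIFIER"),
        ("synonymous_variant", "LOW"),
        ("missense_variant", "MODERATE"),
    )
    lo, hi = config.background_af_range
    n_b = config.n_background_variants
    if n_b > 0:
        freqs = rng.uniform(lo, hi, size=n_b)
        term_idx = rng.choice(len(bg_terms), size=n_b, p=(0.6, 0.2, 0.2))
        refs = rng.integers(0, 4, size=n_b)
        alt_off = rng.integers(1, 4, size=n_b)
        u = rng.random((n_b, n_s))
        for i in range(n_b):
            while True:
                ci = int(rng.choice(len(chrom_names), p=chrom_p))
                chrom = chrom_names[ci]
                pos = int(rng.integers(1, config.chromosome_lengths[chrom] + 1))
                if (chrom, pos) not in used:
                    used.add((chrom, pos))
                    break
                logger.debug("background position collision at %s:%d; redrawn", chrom, pos)
            f = freqs[i]
            p_ha, p_he = f * f, 2 * f * (1 - f)
            geno = np.where(
                u[i] < p_ha, HOM_ALT, np.where(u[i] < p_ha + p_he, HET, HOM_REF)
            ).astype(np.int8)
            garr = geno.reshape(1, -1)
            _homozygose_blocks(
                config, chrom, np.array([pos]), garr, samples, rng, resample=False
            )
            _enforce_tier1_homalt(garr, tier1_cols, rng)
            geno = garr[0]
            term, impact = bg_terms[term_idx[i]]
            ref = _BASES[refs[i]]
            alt = _BASES[(refs[i] + alt_off[i]) % 4]
            ann = _ann(alt, (term,), impact, f"BG{i:05d}")
            rows.append((chrom, pos, ref, alt, ann, geno))

    # --- planted variants (stamped exactly; never randomized) ---
    for p in config.plantings:
        geno = np.full(n_s, HOM_REF, dtype=np.int8)
        target = HET if p.moi is Moi.DOMINANT_INDIVIDUAL else HOM_ALT
        for c in p.target_cases:
            geno[sample_index[c]] = target
        for pop, count in p.control_het_carriers.items():
            carriers = (
                config.tier1_ids[: int(count)]
                if pop == config.tier1_population
                else config.tier2_ids(pop)[: int(count)]
            )
            for s in carriers:
                geno[sample_index[s]] = HET
        ann = _ann(p.alt, p.effect_terms, p.impact, p.gene_symbol, p.hgvs_c, p.hgvs_p)
        rows.append((p.chrom, p.pos, p.ref, p.alt, ann, geno))

    chrom_rank = {c: i for i, c in enumerate(chrom_names)}
    rows.sort(key=lambda r: (chrom_rank[r[0]], r[1], r[2], r[3]))

    vcf_path = out_dir / "cohort.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
            "Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chrom_names:
            fh.write(f"##contig=<ID={c},length={config.chromosome_lengths[c]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        for chrom, pos, ref, alt, ann, geno in rows:
            gts = "\t".join(GT_STRINGS[g] for g in geno)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tANN={ann}\tGT\t{gts}\n")

    manifest = config.manifest()
    manifest_path = out_dir / "cohort.tsv"
    manifest.to_tsv(manifest_path)

    truth = _build_truth(config, filter_cfg)
    truth_path = out_dir / "truth.json"
    truth.to_json(truth_path)

    genome_path = out_dir / "autosomes.tsv"
    with open(genome_path, "w") as fh:
        fh.write("chrom\tlength\n")
        for c in chrom_names:
            fh.write(f"{c}\t{config.chromosome_lengths[c]}\n")

    return SimulatedCohort(
        vcf_path=vcf_path,
        manifest_path=manifest_path,
        truth_path=truth_path,
        genome_path=genome_path,
        manifest=manifest,
        truth=truth,
    )


def paper_like_preset(seed: int = 1) -> SimConfig:
    """A cohort preset structurally mirroring the published study design.

    Seven cases against a tier-1 cohort of 1031 control genomes and a
    tiered global cohort; one recessive case-private planting with
    heterozygous carriers in three tier-2 populations (carrier counts
    71/6/4); seven dominant case-private plantings across cases 1–6 with
    case 3 digenic (two genes); one dominant tier-2 decoy for case 7; five
    shared homozygous blocks totalling 2.2 Mb plus per-case private blocks
    sized so that case F_ROH values are {0.10 … 0.20} with mean 0.15 and
    sample SD ≈ 0.039.  Tier-2 population sizes are scaled down from the
    study's (the funnel structure, not tier-2 allele frequencies, is the
    point of the preset); the pseudo-genome is two 50-Mb autosomes.
    """
    cases = tuple(f"case_{i}" for i in range(1, 8))
    mk = PlantedVariant
    plantings = (
        mk("1", 42_424_685, "T", "C", Moi.RECESSIVE_INDIVIDUAL, ("case_7",),
           {"SwissHolstein": 71, "SwissFleckvieh": 6, "RedDanish": 4},
           gene_symbol="TOR3A", hgvs_c="c.58G>T", hgvs_p="p.Phe111Leu"),
        mk("1", 8_234_401, "G", "A", Moi.DOMINANT_INDIVIDUAL, ("case_1",),
           gene_symbol="MPEG1", hgvs_c="c.163C>T", hgvs_p="p.Arg55Trp"),
        mk("1", 12_655_510, "G", "A", Moi.DOMINANT_INDIVIDUAL, ("case_2",),
           gene_symbol="LHX8", hgvs_c="c.290C>T", hgvs_p="p.Thr97Ile"),
        mk("1", 18_082_172, "CGCCCGAGCCCGA", "C", Moi.DOMINANT_INDIVIDUAL, ("case_3",),
           gene_symbol="WHAMM", effect_terms=("disruptive_inframe_deletion",),
           hgvs_c="c.199_210delCCCGAGCCCGAG", hgvs_p="p.Pro67Glu70del"),
        mk("1", 21_640_669, "G", "A", Moi.DOMINANT_INDIVIDUAL, ("case_3",),
           gene_symbol="NGRN", hgvs_c="c.328G>A", hgvs_p="p.Gly110Ser"),
        mk("1", 28_094_040, "T", "C", Moi.DOMINANT_INDIVIDUAL, ("case_4",),
           gene_symbol="TTN", hgvs_c="c.6374T>C", hgvs_p="p.Ile2125Thr"),
        mk("1", 31_902_947, "G", "A", Moi.DOMINANT_INDIVIDUAL, ("case_5",),
           gene_symbol="ATP1A1", hgvs_c="c.680C>T", hgvs_p="p.Pro227Leu"),
        mk("1", 38_935_731, "G", "A", Moi.DOMINANT_INDIVIDUAL, ("case_6",),
           gene_symbol="PCDH1", hgvs_c="c.3556C>T", hgvs_p="p.Arg1186Cys"),
        # tier-2 decoy: private and protein-changing at tier 1, but a
        # single global-cohort carrier removes it at the final stage.
        mk("1", 46_123_457, "C", "T", Moi.DOMINANT_INDIVIDUAL, ("case_7",),
           {"RedDanish": 1}, gene_symbol="DNAH1"),
    )
    shared = (
        ("1", 5_000_000, 5_300_000),
        ("1", 15_000_000, 15_350_000),
        ("1", 25_000_000, 25_400_000),
        ("1", 35_000_000, 35_500_000),
        ("1", 44_000_000, 44_650_000),
    )  # 0.30 + 0.35 + 0.40 + 0.50 + 0.65 = 2.2 Mb
    private_mb = (7.8, 8.8, 10.8, 12.8, 14.8, 16.8, 17.8)  # + 2.2 shared -> F_ROH 0.10..0.20
    blocks = [ROHBlock(cases, c, s, e) for c, s, e in shared]
    for i, mb in enumerate(private_mb, start=1):
        start = 1_000_000 + i * 3_000_000
        blocks.append(ROHBlock((f"case_{i}",), "2", start, start + int(mb * 1_000_000)))
    return SimConfig(
        n_cases=7,
        n_tier1_controls=1031,
        tier2_populations={
            "SwissHolstein": 300,
            "SwissFleckvieh": 100,
            "RedDanish": 73,
            "OtherBreeds": 200,
        },
        n_background_variants=2000,
        plantings=plantings,
        roh_blocks=tuple(blocks),
        chromosome_lengths={"1": 50_000_000, "2": 50_000_000},
        markers_per_mb=100.0,
        het_rate_outside_roh=0.5,
        seed=seed,
    )
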