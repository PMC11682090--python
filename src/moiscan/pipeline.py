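"""End-to-end orchestration: filter (3 MOIs) -> ROH -> popfreq -> classify.

One entry point, :func:`run_full_analysis`, reads a VCF + manifest (+
optional genome table and evidence file), runs every funnel, the
homozygosity mapping and the frequency/classification reports, and writes
a plain TSV/BED/JSON report bundle.  Every TSV carries the configuration
hash in a leading comment line so outputs are traceable to their inputs;
rerunning with identical inputs rewrites identical content.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .classify import classify_bundles, read_evidence_yaml
from .moi_filter import (
    ALL_CASES,
    CandidateSet,
    FilterConfig,
    FunnelReport,
    Moi,
    Stage,
    build_funnel_report,
    manual_review_frame,
    run_moi_pipeline,
    write_candidate_vcf,
)
from .popfreq import population_frequency_table, write_popfreq_tsv
from .roh import (
    ROHParams,
    detect_roh_for_samples,
    genomic_inbreeding,
    load_chromosome_table,
    regions_to_bed,
    segments_to_bed,
    shared_homozygous_regions,
)
from .vcf_model import CohortManifest, read_annotated_vcf

logger = logging.getLogger(__name__)

_MOI_SLUG = {
    Moi.RECESSIVE_SHARED: "recessive_shared",
    Moi.RECESSIVE_INDIVIDUAL: "recessive_individual",
    Moi.DOMINANT_INDIVIDUAL: "dominant",
}


@dataclass
class RunConfig:
    """Paths plus sub-configurations for one full analysis run."""

    vcf: Path
    manifest: Path
    out_dir: Path
    genome_table: Path | None = None
    evidence: Path | None = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    roh_params: ROHParams = field(default_factory=ROHParams)
    min_shared_length: int = 10_000
    roh_stride: int = 1
    defaults_applied: tuple[str, ...] = ()

    def content_dict(self) -> dict:
        return {
            "vcf": str(self.vcf),
            "manifest": str(self.manifest),
            "genome_table": str(self.genome_table) if self.genome_table else None,
            "evidence": str(self.evidence) if self.evidence else None,
            "filter_config": self.filter_config.as_dict(),
            "roh_params": {
                "min_snp": self.roh_params.min_snp,
                "min_length": self.roh_params.min_length,
                "max_gap": self.roh_params.max_gap,
                "max_opposite": self.roh_params.max_opposite,
                "max_missing": self.roh_params.max_missing,
            },
            "min_shared_length": self.min_shared_length,
            "roh_stride": self.roh_stride,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.content_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, out_dir: Path | None = None) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}

        def _p(key: str) -> Path | None:
            v = data.get(key)
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base / p

        defaults: list[str] = []
        if "filter_config" in data:
            fcfg = FilterConfig.from_dict(data["filter_config"])
        else:
            fcfg = FilterConfig()
            defaults.append("filter_config")
        if "roh_params" in data:
            rparams = ROHParams(**data["roh_params"])
        else:
            rparams = ROHParams()
            defaults.append("roh_params")
        for key in ("min_shared_length", "roh_stride"):
            if key not in data:
                defaults.append(key)
        vcf = _p("vcf")
        manifest = _p("manifest")
        if vcf is None or manifest is None:
            raise ValueError(f"run config {path} must set 'vcf' and 'manifest'")
        resolved_out = out_dir or _p("out_dir") or (base / "moiscan_out")
        return cls(
            vcf=vcf,
            manifest=manifest,
            out_dir=Path(resolved_out),
            genome_table=_p("genome_table"),
            evidence=_p("evidence"),
            filter_config=fcfg,
            roh_params=rparams,
            min_shared_length=int(data.get("min_shared_length", 10_000)),
            roh_stride=int(data.get("roh_stride", 1)),
            defaults_applied=tuple(defaults),
        )


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run the whole analysis and write the report bundle under ``out_dir``.

    Returns a summary dict: funnel reports per MOI, shared regions, the
    inbreeding result and the list of files written.
    """
    for p, name in ((cfg.vcf, "vcf"), (cfg.manifest, "manifest")):
        if not Path(p).exists():
            raise FileNotFoundError(f"{name} file not found: {p}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    comment = f"moiscan {__version__} config_hash={chash}"
    written: list[Path] = []

    manifest = CohortManifest.from_tsv(cfg.manifest)
    table = read_annotated_vcf(cfg.vcf, manifest)
    logger.info("read %d normalized variants over %d samples", len(table), len(manifest))

    # --- MOI funnels ---
    funnels: dict[Moi, FunnelReport] = {}
    final_sets: list[CandidateSet] = []
    stage_maps: dict[Moi, dict] = {}
    for moi in Moi:
        stages_by_case = {}
        case_ids = (ALL_CASES,) if moi is Moi.RECESSIVE_SHARED else manifest.cases
        review_rows = []
        for case_id in case_ids:
            cid = None if moi is Moi.RECESSIVE_SHARED else case_id
            stages = run_moi_pipeline(table, manifest, cfg.filter_config, moi, cid)
            stages_by_case[(case_id, moi)] = stages
            final = stages[Stage.POST_TIER2]
            final_sets.append(final)
            review_rows.append(manual_review_frame(final, manifest))
            if len(final):
                vcf_path = out / f"candidates_{_MOI_SLUG[moi]}_{case_id}.vcf"
                write_candidate_vcf(final, table, vcf_path)
                written.append(vcf_path)
        report = build_funnel_report(stages_by_case)
        funnels[moi] = report
        stage_maps[moi] = stages_by_case
        path = out / f"funnel_{_MOI_SLUG[moi]}.tsv"
        report.to_tsv(path, header_comment=comment)
        written.append(path)
        if review_rows:
            import pandas as pd

            review = pd.concat(review_rows, ignore_index=True)
            rpath = out / f"manual_review_{_MOI_SLUG[moi]}.tsv"
            with open(rpath, "w") as fh:
                fh.write(f"# {comment}\n")
                review.to_csv(fh, sep="\t", index=False)
            written.append(rpath)

    # --- runs of homozygosity on the case genomes ---
    roh_by_case = detect_roh_for_samples(
        table, manifest.cases, cfg.roh_params, stride=cfg.roh_stride
    )
    seg_path = out / "roh_segments.bed"
    segments_to_bed(
        [s for segs in roh_by_case.values() for s in segs], seg_path
    )
    written.append(seg_path)
    regions, total_shared = shared_homozygous_regions(
        roh_by_case, cases=list(manifest.cases), min_shared_length=cfg.min_shared_length
    )
    reg_path = out / "shared_regions.bed"
    regions_to_bed(regions, reg_path)
    written.append(reg_path)

    if cfg.genome_table is not None:
        chrom_lengths = load_chromosome_table(cfg.genome_table)
    else:
        chrom_lengths = None
    inbreeding = None
    if chrom_lengths:
        inbreeding = genomic_inbreeding(roh_by_case, chrom_lengths, group=manifest.cases)
        froh_path = out / "froh.tsv"
        with open(froh_path, "w") as fh:
            fh.write(f"# {comment}\n")
            fh.write("sample\tfroh\n")
            for s in inbreeding.group:
                fh.write(f"{s}\t{inbreeding.froh[s]:.6f}\n")
            fh.write(f"#mean\t{inbreeding.mean:.6f}\n")
            fh.write(f"#sd\t{inbreeding.sd:.6f}\n")
        written.append(froh_path)

    # --- population frequencies of the final candidates ---
    final_keys: dict[tuple, None] = {}
    for cset in final_sets:
        for k in cset.keys():
            final_keys.setdefault(k, None)
    if final_keys:
        import pandas as pd

        frames = []
        for key in final_keys:
            frame = population_frequency_table(table, key, manifest)
            frame.insert(0, "variant", f"{key[0]}:{key[1]}:{key[2]}:{key[3]}")
            frames.append(frame)
        pf_path = out / "popfreq.tsv"
        write_popfreq_tsv(pd.concat(frames, ignore_index=True), pf_path, comment)
        written.append(pf_path)

    # --- classification (only when evidence is supplied) ---
    if cfg.evidence is not None:
        bundles = read_evidence_yaml(cfg.evidence)
        cls_path = out / "classification.tsv"
        with open(cls_path, "w") as fh:
            fh.write(f"# {comment}\n")
            classify_bundles(bundles).to_csv(fh, sep="\t", index=False)
        written.append(cls_path)

    log = {
        "version": __version__,
        "config_hash": chash,
        "config": cfg.content_dict(),
        "defaults_applied": list(cfg.defaults_applied),
        "n_variants": len(table),
        "n_samples": len(manifest),
        "n_cases": len(manifest.cases),
        "n_tier1_controls": len(manifest.tier1_controls),
        "n_tier2_controls": len(manifest.tier2_controls),
        "shared_region_count": len(regions),
        "shared_region_total_bp": total_shared,
        "froh_mean": inbreeding.mean if inbreeding else None,
        "froh_sd": inbreeding.sd if inbreeding else None,
        "outputs": [str(p) for p in written],
    }
    run_log = out / "run.json"
    with open(run_log, "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    written.append(run_log)

    return {
        "funnels": funnels,
        "stages": stage_maps,
        "roh_by_case": roh_by_case,
        "shared_regions": regions,
        "total_shared_bp": total_shared,
        "inbreeding": inbreeding,
        "outputs": written,
        "config_hash": chash,
        "table": table,
        "manifest": manifest,
    }
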