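"""Evidence combination and candidate-variant classification.

Combines per-variant evidence — zygosity under the assumed mode of
inheritance, an in-silico deleteriousness consensus, residue conservation
across species, and a user-supplied flag marking the gene as a
neuromuscular-disease (NMD) candidate — into a three-way call:

* LIKELY_PATHOGENIC — homozygous under a recessive model, predicted
  deleterious, in an NMD candidate gene;
* UNCERTAIN_SIGNIFICANCE — a deleterious-predicted carrier-state candidate
  (dominant model or heterozygous) lacking segregation evidence;
* NOT_A_CANDIDATE — no deleteriousness support or the gene is not an NMD
  candidate.

This is a deliberately small, frozen rule cascade ("ACMG-lite"): the full
28-criterion clinical framework is under-determined by the evidence this
pipeline sees, so only the rules it can actually evaluate are encoded.
Residue conservation is descriptive evidence: it annotates the rationale
but never changes the class.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .moi_filter import Moi
from .vcf_model import GenotypeClass

GAP_CHARS = frozenset("-.")

#: Conservation fraction at or above which the rationale notes a conserved
#: residue (annotation only, never class-changing).
CONSERVATION_SUPPORT_THRESHOLD = 0.9


class Prediction(str, enum.Enum):
    DELETERIOUS = "DELETERIOUS"
    NEUTRAL = "NEUTRAL"
    UNAVAILABLE = "UNAVAILABLE"


class Consensus(str, enum.Enum):
    DELETERIOUS = "DELETERIOUS"
    NOT_DELETERIOUS = "NOT_DELETERIOUS"
    UNAVAILABLE = "UNAVAILABLE"


class ClassValue(enum.IntEnum):
    """Ordered so that more pathogenic compares greater."""

    NOT_A_CANDIDATE = 0
    UNCERTAIN_SIGNIFICANCE = 1
    LIKELY_PATHOGENIC = 2


#: Rule ids appearing in rationales.
RULES = {
    "R1": "no deleteriousness consensus or gene is not an NMD candidate",
    "R2": "homozygous under recessive MOI, predicted deleterious, NMD candidate gene",
    "R3": "carrier-state deleterious candidate without segregation data",
    "C1": "affected residue conserved across aligned species",
}


@dataclass(frozen=True)
class CandidateClass:
    value: ClassValue
    rationale: tuple[str, ...]


@dataclass(frozen=True)
class EvidenceBundle:
    """Per-variant evidence feeding the classification cascade.

    ``segregation`` is "NONE" when no parental/pedigree information exists
    (the common situation for retrospective livestock case series).
    ``conservation`` and ``allele_freq_global`` are None when unavailable.
    """

    moi: Moi
    zygosity_in_case: GenotypeClass
    deleterious_predictions: tuple[tuple[str, Prediction], ...] = ()
    conservation: float | None = None
    gene_is_nmd_candidate: bool = False
    gene_note: str = ""
    allele_freq_global: float | None = None
    segregation: str = "NONE"
    variant: str = ""
    gene_symbol: str = ""


def consensus_deleteriousness(
    predictions: Iterable[tuple[str, Prediction]],
) -> Consensus:
    """Fold tool predictions: deleterious if at least one tool says so.

    NOT_DELETERIOUS requires at least one tool to have reported and none
    deleterious; no informative report at all yields UNAVAILABLE.
    """
    any_reported = False
    for _tool, pred in predictions:
        pred = Prediction(pred)
        if pred is Prediction.DELETERIOUS:
            return Consensus.DELETERIOUS
        if pred is Prediction.NEUTRAL:
            any_reported = True
    return Consensus.NOT_DELETERIOUS if any_reported else Consensus.UNAVAILABLE


def conservation_fraction(
    alignment: Sequence,
    column: int,
    reference_id: str | None = None,
) -> float | None:
    """Fraction of non-gap aligned sequences matching the reference residue.

    ``alignment`` is any sequence of aligned, equal-length records — plain
    strings, Bio.SeqRecord objects, or a Bio.Align.MultipleSeqAlignment.
    The reference is the first sequence unless ``reference_id`` names
    another record.  Returns 1.0 for complete conservation; None (flagged
    unavailable) when the column is all-gap or the reference itself is
    gapped there.
    """
    seqs: list[tuple[str, str]] = []
    for i, rec in enumerate(alignment):
        if hasattr(rec, "seq"):
            seqs.append((getattr(rec, "id", str(i)), str(rec.seq)))
        else:
            seqs.append((str(i), str(rec)))
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0][1])
    if any(len(s) != length for _, s in seqs):
        raise ValueError("alignment sequences differ in length")
    if not 0 <= column < length:
        raise IndexError(f"column {column} out of range for alignment of length {length}")
    if reference_id is None:
        ref_residue = seqs[0][1][column]
    else:
        matches = [s for rid, s in seqs if rid == reference_id]
        if not matches:
            raise KeyError(f"reference sequence {reference_id!r} not in alignment")
        ref_residue = matches[0][column]
    if ref_residue in GAP_CHARS:
        return None
    residues = [s[column] for _, s in seqs if s[column] not in GAP_CHARS]
    if not residues:
        return None
    ref_upper = ref_residue.upper()
    return sum(1 for r in residues if r.upper() == ref_upper) / len(residues)


def classify_candidate(
    bundle: EvidenceBundle,
    conservation_support_threshold: float = CONSERVATION_SUPPORT_THRESHOLD,
) -> CandidateClass:
    """Apply the rule cascade to one evidence bundle.

    Hard error on inconsistent bundles (a candidate variant must be carried
    by the case, so hom-ref or missing zygosity is invalid).  Every valid
    bundle maps to exactly one class, deterministically.
    """
    zyg = GenotypeClass(bundle.zygosity_in_case)
    if zyg not in (GenotypeClass.HET, GenotypeClass.HOM_ALT):
        raise ValueError(
            f"inconsistent evidence bundle: case zygosity {zyg.name} "
            "(candidate variants must be carried by the case)"
        )
    cons = consensus_deleteriousness(bundle.deleterious_predictions)
    if cons is not Consensus.DELETERIOUS or not bundle.gene_is_nmd_candidate:
        return CandidateClass(ClassValue.NOT_A_CANDIDATE, ("R1",))
    fired: list[str] = []
    moi = Moi(bundle.moi)
    recessive = moi in (Moi.RECESSIVE_SHARED, Moi.RECESSIVE_INDIVIDUAL)
    if recessive and zyg is GenotypeClass.HOM_ALT:
        value = ClassValue.LIKELY_PATHOGENIC
        fired.append("R2")
    else:
        value = ClassValue.UNCERTAIN_SIGNIFICANCE
        fired.append("R3")
    if (
        bundle.conservation is not None
        and bundle.conservation >= conservation_support_threshold
    ):
        fired.append("C1")
    return CandidateClass(value, tuple(fired))


def classify_bundles(bundles: Iterable[EvidenceBundle]) -> pd.DataFrame:
    """Classify several bundles into a tidy table (machine-readable report)."""
    rows = []
    for b in bundles:
        result = classify_candidate(b)
        cons = consensus_deleteriousness(b.deleterious_predictions)
        rows.append(
            {
                "variant": b.variant,
                "gene": b.gene_symbol,
                "moi": Moi(b.moi).value,
                "zygosity": GenotypeClass(b.zygosity_in_case).name,
                "consensus": cons.value,
                "conservation": b.conservation,
                "nmd_candidate_gene": b.gene_is_nmd_candidate,
                "segregation": b.segregation,
                "class": result.value.name,
                "rules_fired": ",".join(result.rationale),
                "gene_note": b.gene_note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant",
            "gene",
            "moi",
            "zygosity",
            "consensus",
            "conservation",
            "nmd_candidate_gene",
            "segregation",
            "class",
            "rules_fired",
            "gene_note",
        ],
    )


def read_evidence_yaml(path: str | Path) -> list[EvidenceBundle]:
    """Read per-variant evidence bundles from a YAML file.

    The file is a list of mappings with keys mirroring
    :class:`EvidenceBundle`; ``deleterious_predictions`` is a mapping of
    tool name to prediction string.  An optional ``alignment`` sub-mapping
    (``fasta``: path to an aligned FASTA, ``column``: 0-based column,
    ``reference_id``: optional) computes ``conservation`` from file.
    """
    from Bio import SeqIO

    with open(path) as fh:
        data = yaml.safe_load(fh) or []
    bundles = []
    base = Path(path).parent
    for item in data:
        preds = tuple(
            (tool, Prediction(str(p).upper()))
            for tool, p in (item.get("deleterious_predictions") or {}).items()
        )
        conservation = item.get("conservation")
        aln_spec = item.get("alignment")
        if conservation is None and aln_spec:
            fasta = Path(aln_spec["fasta"])
            if not fasta.is_absolute():
                fasta = base / fasta
            records = list(SeqIO.parse(str(fasta), "fasta"))
            conservation = conservation_fraction(
                records, int(aln_spec["column"]), aln_spec.get("reference_id")
            )
        bundles.append(
            EvidenceBundle(
                moi=Moi(item["moi"]),
                zygosity_in_case=GenotypeClass[item["zygosity_in_case"]],
                deleterious_predictions=preds,
                conservation=conservation,
                gene_is_nmd_candidate=bool(item.get("gene_is_nmd_candidate", False)),
                gene_note=item.get("gene_note", ""),
                allele_freq_global=item.get("allele_freq_global"),
                segregation=item.get("segregation", "NONE"),
                variant=item.get("variant", ""),
                gene_symbol=item.get("gene_symbol", ""),
            )
        )
    return bundles
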