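"""Normalized in-memory model of an annotated multi-sample VCF.

This module turns a multi-sample VCF into an ordered table of biallelic
:class:`VariantRecord` objects.  Multiallelic sites are split into one record
per alternate allele, per-sample genotypes are reduced to a four-state
zygosity class (hom-ref / het / hom-alt / missing), the FILTER column is
mapped onto a three-state quality label, and functional annotations are
parsed out of the standard ``ANN`` INFO sub-field (pipe-delimited entries,
comma-separated per allele/transcript).

Coordinates are 1-based inclusive throughout this module (VCF convention);
interval-based code in :mod:`moiscan.roh` works 0-based half-open and the
conversion lives in a single function, :func:`pos_to_zero_based`.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

_BASES_RE = re.compile(r"^[ACGT]+$")

#: Minimum number of pipe-delimited sub-fields for a usable ANN entry
#: (allele .. HGVS.p); shorter entries are skipped with a warning.
ANN_MIN_FIELDS = 11


def normalize_chrom(name: str) -> str:
    """Strip a case-insensitive ``chr`` prefix ("Chr16" and "16" are the same)."""
    return name[3:] if name[:3].lower() == "chr" else name


def pos_to_zero_based(pos: int) -> int:
    """Convert a 1-based inclusive position to its 0-based coordinate."""
    return pos - 1


class GenotypeClass(enum.IntEnum):
    """Diploid zygosity of one sample at one biallelic record."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = 3


#: VCF GT strings emitted by the writer, indexed by GenotypeClass value.
GT_STRINGS = ("0/0", "0/1", "1/1", "./.")


class QualLabel(str, enum.Enum):
    """Per-record quality label derived from the VCF FILTER column."""

    PASS = "PASS"
    FAIL = "FAIL"
    UNLABELED = "UNLABELED"


class Role(str, enum.Enum):
    CASE = "CASE"
    TIER1_CONTROL = "TIER1_CONTROL"
    TIER2_CONTROL = "TIER2_CONTROL"


@dataclass(frozen=True)
class EffectAnnotation:
    """One parsed ANN entry (one transcript-level functional annotation).

    HGVS strings are carried verbatim, never validated: upstream annotation
    pipelines occasionally emit internally inconsistent genomic/cDNA pairs
    and the filter logic only ever consumes ``effect_terms``.
    """

    allele: str
    gene_symbol: str
    effect_terms: tuple[str, ...]
    impact: str
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if not self.effect_terms:
            raise ValueError("EffectAnnotation requires at least one effect term")


def parse_ann_field(ann_value: str) -> list[EffectAnnotation]:
    """Parse a raw ``ANN=`` INFO string into :class:`EffectAnnotation` objects.

    Entries are comma-separated; sub-fields pipe-delimited; ampersand-joined
    effect terms are split into the term list.  Empty input yields an empty
    list.  Entries with fewer than ``ANN_MIN_FIELDS`` sub-fields are skipped
    with a warning.
    """
    if not ann_value:
        return []
    out: list[EffectAnnotation] = []
    for entry in ann_value.split(","):
        fields = entry.split("|")
        if len(fields) < ANN_MIN_FIELDS:
            logger.warning(
                "skipping ANN entry with %d < %d fields: %r",
                len(fields), ANN_MIN_FIELDS, entry,
            )
            continue
        terms = tuple(t for t in fields[1].split("&") if t)
        if not terms:
            logger.warning("skipping ANN entry with empty effect field: %r", entry)
            continue
        out.append(
            EffectAnnotation(
                allele=fields[0],
                gene_symbol=fields[3],
                effect_terms=terms,
                impact=fields[2],
                hgvs_c=fields[9],
                hgvs_p=fields[10],
            )
        )
    return out


def format_ann_entry(e: EffectAnnotation, alt: str) -> str:
    """Serialize one annotation back into a standard 11-field ANN entry."""
    allele = e.allele or alt
    gene = e.gene_symbol
    return "|".join(
        [
            allele,
            "&".join(e.effect_terms),
            e.impact,
            gene,
            gene,
            "transcript",
            f"{gene}.t1",
            "protein_coding",
            "1/1",
            e.hgvs_c,
            e.hgvs_p,
        ]
    )


@dataclass(eq=False)
class VariantRecord:
    """One normalized biallelic variant.

    ``genotypes`` is an int8 array of :class:`GenotypeClass` values aligned
    to the sample order of the owning :class:`VariantTable` (i.e. the
    manifest order).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual_label: QualLabel
    effects: tuple[EffectAnnotation, ...]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        if not _BASES_RE.match(self.ref) or not _BASES_RE.match(self.alt):
            raise ValueError(
                f"ref/alt must be nonempty ACGT strings, got {self.ref!r}>{self.alt!r}"
            )
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def gene_symbols(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for e in self.effects:
            if e.gene_symbol:
                seen.setdefault(e.gene_symbol, None)
        return tuple(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantRecord):
            return NotImplemented
        return (
            self.key == other.key
            and self.qual_label == other.qual_label
            and self.effects == other.effects
            and np.array_equal(self.genotypes, other.genotypes)
        )


@dataclass(frozen=True)
class RawSite:
    """A raw (possibly multiallelic) VCF site before splitting.

    ``allele_pairs`` is an (n_samples, 2) int array of allele indices with
    negative values for missing alleles.  Phased and unphased genotypes are
    not distinguished (filters use zygosity only), and half-missing
    genotypes become MISSING after splitting.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual_label: QualLabel
    effects: tuple[EffectAnnotation, ...]
    allele_pairs: np.ndarray


def classify_genotypes(allele_pairs: np.ndarray, alt_index: int) -> np.ndarray:
    """Map raw diploid allele pairs to GenotypeClass for one alt allele.

    For the record carrying alt allele ``j``: HOM_ALT iff both alleles are
    ``j``; HET iff exactly one allele is ``j`` and the other is 0; HOM_REF
    iff both are 0; MISSING otherwise — including half-missing genotypes and
    genotypes carrying a different alt allele.
    """
    a = allele_pairs[:, 0]
    b = allele_pairs[:, 1]
    j = alt_index
    ok = (a >= 0) & (b >= 0) & ((a == 0) | (a == j)) & ((b == 0) | (b == j))
    n_alt = (a == j).astype(np.int8) + (b == j).astype(np.int8)
    cls = np.where(
        ~ok,
        int(GenotypeClass.MISSING),
        np.where(
            n_alt == 2,
            int(GenotypeClass.HOM_ALT),
            np.where(n_alt == 1, int(GenotypeClass.HET), int(GenotypeClass.HOM_REF)),
        ),
    )
    return cls.astype(np.int8)


def split_multiallelic(site: RawSite) -> list[VariantRecord]:
    """Split a raw site into one biallelic :class:`VariantRecord` per alt.

    Symbolic or non-ACGT alt alleles are dropped with a warning.  ANN
    entries are attached to the record whose alt matches their allele
    sub-field; entries whose allele matches none of the site's alts are
    kept on every record.
    """
    site_alts = set(site.alts)
    records: list[VariantRecord] = []
    for j, alt in enumerate(site.alts, start=1):
        if not _BASES_RE.match(alt):
            logger.warning(
                "dropping symbolic/non-ACGT alt %r at %s:%d", alt, site.chrom, site.pos
            )
            continue
        effects = tuple(
            e for e in site.effects if e.allele == alt or e.allele not in site_alts
        )
        records.append(
            VariantRecord(
                chrom=site.chrom,
                pos=site.pos,
                ref=site.ref,
                alt=alt,
                qual_label=site.qual_label,
                effects=effects,
                genotypes=classify_genotypes(site.allele_pairs, j),
            )
        )
    return records


class CohortManifest:
    """Sample -> role (case / tier-1 control / tier-2 control) and population.

    The frame all filters are evaluated against: tier sizes are entirely
    manifest-driven, never hard-coded.
    """

    def __init__(self, entries: Sequence[tuple[str, Role, str]]):
        ids = [e[0] for e in entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids in manifest: {dupes}")
        self._entries = [(s, Role(r), p) for s, r, p in entries]
        if not any(r is Role.CASE for _, r, _ in self._entries):
            raise ValueError("manifest must contain at least one CASE sample")
        self._role = {s: r for s, r, _ in self._entries}
        self._population = {s: p for s, _, p in self._entries}

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(s for s, _, _ in self._entries)

    @property
    def cases(self) -> tuple[str, ...]:
        return tuple(s for s, r, _ in self._entries if r is Role.CASE)

    @property
    def tier1_controls(self) -> tuple[str, ...]:
        return tuple(s for s, r, _ in self._entries if r is Role.TIER1_CONTROL)

    @property
    def tier2_controls(self) -> tuple[str, ...]:
        return tuple(s for s, r, _ in self._entries if r is Role.TIER2_CONTROL)

    def role(self, sample: str) -> Role:
        return self._role[sample]

    def population(self, sample: str) -> str:
        return self._population[sample]

    @property
    def populations(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, _, p in self._entries:
            seen.setdefault(p, None)
        return tuple(seen)

    def samples_in_population(self, population: str) -> tuple[str, ...]:
        return tuple(s for s, _, p in self._entries if p == population)

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortManifest):
            return NotImplemented
        return self._entries == other._entries

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortManifest":
        """Read a 3-column TSV (sample, role, population); header optional.

        Role spellings are normalized case-insensitively and ``-`` is
        treated as ``_`` (``tier1-control`` == ``TIER1_CONTROL``).
        """
        entries: list[tuple[str, Role, str]] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 tab-separated columns, got {len(parts)}"
                    )
                sample, role_s, pop = parts[0], parts[1], parts[2]
                if lineno == 1 and sample.lower() in {"sample", "sample_id", "id"}:
                    continue
                role_norm = role_s.strip().upper().replace("-", "_")
                try:
                    role = Role(role_norm)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: unknown role {role_s!r}"
                    ) from exc
                entries.append((sample, role, pop))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\trole\tpopulation\n")
            for s, r, p in self._entries:
                fh.write(f"{s}\t{r.value}\t{p}\n")


class VariantTable:
    """Ordered collection of biallelic VariantRecords sharing a sample axis.

    Iteration order is strictly sorted by (chromosome rank, pos, ref, alt),
    where chromosome rank follows the provided chromosome order (header
    contigs by default).
    """

    def __init__(
        self,
        samples: Sequence[str],
        records: Iterable[VariantRecord],
        chrom_order: Sequence[str] | None = None,
    ):
        self.samples = tuple(samples)
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        records = list(records)
        for r in records:
            if len(r.genotypes) != len(self.samples):
                raise ValueError(
                    f"record {r.key} has {len(r.genotypes)} genotypes for "
                    f"{len(self.samples)} samples"
                )
        order: dict[str, int] = {}
        for c in chrom_order or ():
            order.setdefault(normalize_chrom(c), len(order))
        for r in records:
            order.setdefault(r.chrom, len(order))
        self.chrom_order = tuple(order)
        records.sort(key=lambda r: (order[r.chrom], r.pos, r.ref, r.alt))
        self.records = records
        self._by_key = {r.key: r for r in self.records}
        self._matrix: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return self.samples == other.samples and self.records == other.records

    def sample_index(self, sample: str) -> int:
        return self._sample_index[sample]

    def sample_indices(self, samples: Iterable[str]) -> np.ndarray:
        return np.array([self._sample_index[s] for s in samples], dtype=np.intp)

    def find(self, key: tuple[str, int, str, str]) -> VariantRecord:
        norm = (normalize_chrom(key[0]), key[1], key[2], key[3])
        try:
            return self._by_key[norm]
        except KeyError:
            raise KeyError(f"variant {norm[0]}:{norm[1]}:{norm[2]}:{norm[3]} not in table") from None

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return (normalize_chrom(key[0]), key[1], key[2], key[3]) in self._by_key

    def genotype_matrix(self) -> np.ndarray:
        """(n_variants, n_samples) int8 matrix of GenotypeClass values."""
        if self._matrix is None:
            if self.records:
                self._matrix = np.vstack([r.genotypes for r in self.records])
            else:
                self._matrix = np.zeros((0, len(self.samples)), dtype=np.int8)
        return self._matrix

    def subset(self, records: Iterable[VariantRecord]) -> "VariantTable":
        return VariantTable(self.samples, records, chrom_order=self.chrom_order)


def _qual_label_from_filters(filters: list[str]) -> QualLabel:
    if filters == ["PASS"]:
        return QualLabel.PASS
    if not filters:
        return QualLabel.UNLABELED
    return QualLabel.FAIL


def read_annotated_vcf(
    vcf_path: str | Path,
    manifest: CohortManifest,
    chrom_order: Sequence[str] | None = None,
) -> VariantTable:
    """Read a multi-sample VCF into a normalized, sorted VariantTable.

    All manifest samples must be present in the VCF header (hard error
    naming the missing ones otherwise); extra VCF samples are ignored.
    Multiallelic sites are split, genotypes are mapped to
    :class:`GenotypeClass` and FILTER to :class:`QualLabel`
    (PASS -> PASS, ``.`` -> UNLABELED, anything else -> FAIL).
    """
    vcf = VCF(str(vcf_path))
    header_samples = set(vcf.samples)
    missing = [s for s in manifest.samples if s not in header_samples]
    if missing:
        vcf.close()
        raise ValueError(
            f"manifest sample(s) absent from VCF header: {', '.join(missing)}"
        )
    header_contigs = list(vcf.seqnames)
    if set(vcf.samples) != set(manifest.samples):
        vcf.close()
        vcf = VCF(str(vcf_path), samples=list(manifest.samples))
    # htslib keeps header order under subsetting; permute to manifest order.
    perm = np.array([vcf.samples.index(s) for s in manifest.samples], dtype=np.intp)

    n = len(manifest.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        chrom = normalize_chrom(var.CHROM)
        qual = _qual_label_from_filters(var.FILTERS)
        try:
            ann = var.INFO.get("ANN")
        except KeyError:
            ann = None
        effects = tuple(parse_ann_field(ann or ""))
        garr = var.genotype.array() if var.genotype is not None else None
        if garr is None or garr.shape[1] < 2:
            # No parseable GT for this site: zygosity undeterminable.
            logger.warning(
                "unparseable GT at %s:%d; genotypes set to MISSING", chrom, var.POS
            )
            pairs = np.full((n, 2), -1, dtype=np.int16)
        else:
            pairs = garr[perm, :2].astype(np.int16)
        if not _BASES_RE.match(var.REF or ""):
            logger.warning("dropping record with non-ACGT REF at %s:%d", chrom, var.POS)
            continue
        site = RawSite(
            chrom=chrom,
            pos=var.POS,
            ref=var.REF,
            alts=tuple(var.ALT),
            qual_label=qual,
            effects=effects,
            allele_pairs=pairs,
        )
        records.extend(split_multiallelic(site))
    vcf.close()
    order = chrom_order if chrom_order is not None else header_contigs
    return VariantTable(manifest.samples, records, chrom_order=order)


def write_vcf(
    table: VariantTable,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write the normalized table back out as a plain-text VCF 4.2 file.

    The writer is the round-trip partner of :func:`read_annotated_vcf`:
    re-reading its output yields an identical table field-for-field.
    """
    filter_map = {
        QualLabel.PASS: "PASS",
        QualLabel.UNLABELED: ".",
        QualLabel.FAIL: "FAIL",
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=FAIL,Description="Failed upstream quality control">\n')
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
            "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
            "Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p'\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in table.chrom_order:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for r in table:
            if r.effects:
                info = "ANN=" + ",".join(format_ann_entry(e, r.alt) for e in r.effects)
            else:
                info = "."
            gts = "\t".join(GT_STRINGS[g] for g in r.genotypes)
            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\t"
                f"{filter_map[r.qual_label]}\t{info}\tGT\t{gts}\n"
            )
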