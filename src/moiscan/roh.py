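"""Runs of homozygosity, shared homozygous regions and genomic inbreeding.

A run of homozygosity (ROH) is a contiguous stretch of consecutive
homozygous markers.  This module implements the consecutive-runs method:
no sliding window — runs are grown marker by marker, tolerating a bounded
number of heterozygous and missing calls and a bounded physical gap
between adjacent markers, then filtered on marker count and physical
length.

Scan semantics (frozen so an exact oracle exists): runs are emitted left to
right; each run starts at the earliest unconsumed homozygous marker,
extends to the furthest marker satisfying the tolerance constraints, and is
trimmed back to its last homozygous marker.  Equivalently: among all valid
intervals with homozygous endpoints, greedily keep the one with the
smallest start (largest end on ties) and discard overlapping intervals.
Emitted segments are therefore pairwise disjoint and maximal.

Intervals are 0-based half-open here; marker positions arrive 1-based
(VCF convention) and are converted through
:func:`moiscan.vcf_model.pos_to_zero_based` only.

The genomic inbreeding coefficient F_ROH of a sample is the summed length
of its autosomal ROH divided by the total autosome length — a [0, 1]
fraction of the genome lying in homozygous runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .vcf_model import GenotypeClass, VariantTable, normalize_chrom, pos_to_zero_based

Marker = tuple[str, int, GenotypeClass]


@dataclass(frozen=True)
class ROHParams:
    """Consecutive-runs detection parameters.

    min_snp
        minimum number of markers spanned by a run;
    min_length
        minimum physical run length in bp;
    max_gap
        maximum physical distance in bp between adjacent markers inside a run;
    max_opposite
        heterozygous calls tolerated inside a run;
    max_missing
        missing calls tolerated inside a run.
    """

    min_snp: int = 20
    min_length: int = 50_000
    max_gap: int = 1_000_000
    max_opposite: int = 1
    max_missing: int = 1

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be > 0")
        for name in ("min_snp", "max_gap", "max_opposite", "max_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run of one sample; 0-based half-open interval."""

    sample_id: str
    chrom: str
    start: int
    end: int
    n_snp: int
    n_het_inside: int
    n_missing_inside: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("ROHSegment requires end > start")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SharedRegion:
    """Interval homozygous in every supporting case; 0-based half-open."""

    chrom: str
    start: int
    end: int
    supporting_cases: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InbreedingResult:
    froh: dict[str, float]
    group: tuple[str, ...]
    mean: float
    sd: float


def _is_hom(c: int) -> bool:
    return c == GenotypeClass.HOM_REF or c == GenotypeClass.HOM_ALT


def detect_roh_consecutive(
    track: Sequence[Marker],
    params: ROHParams,
    sample_id: str = "sample",
) -> list[ROHSegment]:
    """Detect homozygous runs on one sample's ordered marker track.

    ``track`` is a sequence of (chrom, 1-based pos, GenotypeClass) sorted by
    chromosome block then position, with unique positions per chromosome;
    unsorted input is a hard error.  Run boundaries are the first and last
    homozygous marker of the run.
    """
    # group into chromosome blocks, verifying order
    segments: list[ROHSegment] = []
    seen_chroms: set[str] = set()
    i = 0
    n = len(track)
    while i < n:
        chrom = track[i][0]
        if chrom in seen_chroms:
            raise ValueError(f"marker track not grouped by chromosome: {chrom!r} reappears")
        seen_chroms.add(chrom)
        j = i
        while j < n and track[j][0] == chrom:
            j += 1
        pos = np.array([track[k][1] for k in range(i, j)], dtype=np.int64)
        cls = np.array([int(track[k][2]) for k in range(i, j)], dtype=np.int8)
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions not strictly increasing on {chrom!r}")
        segments.extend(_detect_on_chrom(chrom, pos, cls, params, sample_id))
        i = j
    return segments


def _detect_on_chrom(
    chrom: str,
    pos: np.ndarray,
    cls: np.ndarray,
    params: ROHParams,
    sample_id: str,
) -> list[ROHSegment]:
    n = len(pos)
    hom = (cls == GenotypeClass.HOM_REF) | (cls == GenotypeClass.HOM_ALT)
    out: list[ROHSegment] = []
    s = 0
    while True:
        while s < n and not hom[s]:
            s += 1
        if s >= n:
            break
        het = miss = 0
        j = s + 1
        while j < n:
            if pos[j] - pos[j - 1] > params.max_gap:
                break
            c = cls[j]
            if c == GenotypeClass.HET:
                if het + 1 > params.max_opposite:
                    break
                het += 1
            elif c == GenotypeClass.MISSING:
                if miss + 1 > params.max_missing:
                    break
                miss += 1
            j += 1
        # furthest constraint-satisfying index is j-1; trim to last hom marker
        e = j - 1
        while not hom[e]:
            e -= 1
        inside = cls[s : e + 1]
        n_snp = e - s + 1
        length = int(pos[e] - pos[s] + 1)
        if n_snp >= params.min_snp and length >= params.min_length:
            out.append(
                ROHSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=pos_to_zero_based(int(pos[s])),
                    end=int(pos[e]),  # half-open: (last pos - 1) + 1
                    n_snp=n_snp,
                    n_het_inside=int((inside == GenotypeClass.HET).sum()),
                    n_missing_inside=int((inside == GenotypeClass.MISSING).sum()),
                )
            )
        s = j  # markers in (e, j-1] are non-homozygous; next run starts at/after j
    return out


def sample_track(table: VariantTable, sample_id: str, stride: int = 1) -> list[Marker]:
    """Extract one sample's (chrom, pos, class) marker track from a table.

    Markers at duplicated positions (e.g. split multiallelics) are collapsed
    to the first record at that position.  ``stride`` keeps every stride-th
    marker to bound runtime on dense whole-genome tables.
    """
    col = table.sample_index(sample_id)
    track: list[Marker] = []
    last: tuple[str, int] | None = None
    for r in table:
        if (r.chrom, r.pos) == last:
            continue
        last = (r.chrom, r.pos)
        track.append((r.chrom, r.pos, GenotypeClass(r.genotypes[col])))
    if stride > 1:
        track = track[::stride]
    return track


def detect_roh_for_samples(
    table: VariantTable,
    samples: Iterable[str],
    params: ROHParams,
    stride: int = 1,
) -> dict[str, list[ROHSegment]]:
    return {
        s: detect_roh_consecutive(sample_track(table, s, stride=stride), params, sample_id=s)
        for s in samples
    }


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [ivs[0]]
    for s, e in ivs[1:]:
        ls, le = out[-1]
        if s <= le:
            out[-1] = (ls, max(le, e))
        else:
            out.append((s, e))
    return out


def _intersect_two(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    out = []
    i = jj = 0
    while i < len(a) and jj < len(b):
        s = max(a[i][0], b[jj][0])
        e = min(a[i][1], b[jj][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[jj][1]:
            i += 1
        else:
            jj += 1
    return out


def shared_homozygous_regions(
    roh_by_case: Mapping[str, Sequence[ROHSegment]],
    cases: Sequence[str] | None = None,
    min_shared_length: int = 10_000,
) -> tuple[list[SharedRegion], int]:
    """Intersect the ROH unions of all cases into shared homozygous regions.

    Returns the regions of length >= ``min_shared_length`` (sorted by
    chromosome then start) and the total shared length in bp.  The result
    is invariant under case order.  Zero cases is a hard error.
    """
    if cases is None:
        cases = sorted(roh_by_case)
    if len(cases) == 0:
        raise ValueError("shared_homozygous_regions requires at least one case")
    per_case: list[dict[str, list[tuple[int, int]]]] = []
    for c in cases:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for seg in roh_by_case.get(c, ()):
            by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end))
        per_case.append({k: _merge_intervals(v) for k, v in by_chrom.items()})
    chroms = set(per_case[0])
    for d in per_case[1:]:
        chroms &= set(d)
    regions: list[SharedRegion] = []
    for chrom in sorted(chroms):
        inter = per_case[0][chrom]
        for d in per_case[1:]:
            inter = _intersect_two(inter, d[chrom])
            if not inter:
                break
        for s, e in inter:
            if e - s >= min_shared_length:
                regions.append(SharedRegion(chrom, s, e, tuple(cases)))
    regions.sort(key=lambda r: (r.chrom, r.start))
    total = sum(r.length for r in regions)
    return regions, total


def genomic_inbreeding(
    roh_by_sample: Mapping[str, Sequence[ROHSegment]],
    chromosome_lengths: Mapping[str, int],
    group: Sequence[str] | None = None,
) -> InbreedingResult:
    """Compute F_ROH per sample plus mean and sample SD over a group.

    F_ROH(sample) = sum of autosomal ROH lengths / sum of autosome lengths,
    with the autosome set defined by ``chromosome_lengths``.  A segment on a
    chromosome absent from the table is a hard error.  The SD uses the
    n-1 (sample) denominator and is NaN for groups smaller than 2.
    """
    lengths = {normalize_chrom(k): int(v) for k, v in chromosome_lengths.items()}
    genome = sum(lengths.values())
    if genome <= 0:
        raise ValueError("chromosome length table is empty")
    froh: dict[str, float] = {}
    for sample, segs in roh_by_sample.items():
        total = 0
        for seg in segs:
            if seg.chrom not in lengths:
                raise KeyError(
                    f"ROH segment of {sample!r} on chromosome {seg.chrom!r} "
                    "absent from the chromosome table"
                )
            total += seg.length
        froh[sample] = total / genome
    if group is None:
        group = tuple(sorted(froh))
    vals = np.array([froh[s] for s in group], dtype=float)
    mean = float(vals.mean()) if len(vals) else float("nan")
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")
    return InbreedingResult(froh=froh, group=tuple(group), mean=mean, sd=sd)


def segments_to_bed(segments: Iterable[ROHSegment], path: str | Path) -> None:
    """Write per-sample ROH as BED4 (chrom, start, end, sample)."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.sample_id}\n")


def regions_to_bed(regions: Iterable[SharedRegion], path: str | Path) -> None:
    """Write shared regions as BED4 (chrom, start, end, n_supporting_cases)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{len(r.supporting_cases)}\n")


def load_chromosome_table(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV (chromosome, length in bp); '#' lines skipped."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].lower() in {"chrom", "chromosome"}:
                continue
            out[normalize_chrom(parts[0])] = int(parts[1])
    if not out:
        raise ValueError(f"no chromosomes read from {path}")
    return out


def ars_ucd12_autosomes() -> dict[str, int]:
    """Bundled autosome lengths for the cattle ARS-UCD1.2 reference assembly."""
    ref = resources.files("moiscan.data") / "ars_ucd1_2_autosomes.tsv"
    with resources.as_file(ref) as p:
        return load_chromosome_table(p)
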