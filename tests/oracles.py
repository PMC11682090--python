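"""Independent brute-force oracles for the filtering and ROH algorithms.

Everything here is written as flat scans over plain Python structures,
deliberately sharing no code with the package implementation: the MOI
filters as per-variant loops over a genotype truth matrix, ROH detection
as enumeration of all valid homozygous-endpoint intervals followed by
greedy selection, and shared-region intersection as a per-basepair sweep
over boolean coverage arrays.
"""

from __future__ import annotations

import numpy as np

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, 3


# ---------------------------------------------------------------- MOI filters
def oracle_recessive_shared(
    matrix, quality_ok, case_cols, control_cols, max_het, max_homalt
):
    """Indices of variants hom-alt in every case and private to the controls."""
    keep = []
    for i, row in enumerate(matrix):
        if not quality_ok[i]:
            continue
        if any(row[c] != HOM_ALT for c in case_cols):
            continue
        het = sum(1 for c in control_cols if row[c] == HET)
        hom = sum(1 for c in control_cols if row[c] == HOM_ALT)
        if hom > max_homalt:
            continue
        if max_het is not None and het > max_het:
            continue
        keep.append(i)
    return keep


def oracle_recessive_individual(
    matrix, quality_ok, case_col, control_cols, max_het, max_homalt
):
    keep = []
    for i, row in enumerate(matrix):
        if not quality_ok[i]:
            continue
        if row[case_col] != HOM_ALT:
            continue
        het = sum(1 for c in control_cols if row[c] == HET)
        hom = sum(1 for c in control_cols if row[c] == HOM_ALT)
        if hom > max_homalt:
            continue
        if max_het is not None and het > max_het:
            continue
        keep.append(i)
    return keep


def oracle_dominant_individual(matrix, quality_ok, case_col, control_cols, max_alt):
    keep = []
    for i, row in enumerate(matrix):
        if not quality_ok[i]:
            continue
        if row[case_col] not in (HET, HOM_ALT):
            continue
        alt = sum(
            (1 if row[c] == HET else 2 if row[c] == HOM_ALT else 0)
            for c in control_cols
        )
        if alt > max_alt:
            continue
        keep.append(i)
    return keep


def oracle_protein_changing(effect_terms_per_variant, indices, term_set):
    return [
        i
        for i in indices
        if any(set(terms) & term_set for terms in effect_terms_per_variant[i])
    ]


# ------------------------------------------------------------------------ ROH
def oracle_roh(pos, cls, min_snp, min_length, max_gap, max_opposite, max_missing):
    """Greedy-maximal disjoint homozygous runs on one chromosome.

    Enumerates, for every homozygous start, the largest valid
    homozygous-endpoint interval, then selects intervals greedily by start
    and drops overlaps; finally applies the size filters.  Returns (start
    index, end index) marker-index pairs.
    """
    n = len(pos)
    hom = [c in (HOM_REF, HOM_ALT) for c in cls]
    best_end = {}
    for s in range(n):
        if not hom[s]:
            continue
        het = miss = 0
        best = s
        for e in range(s + 1, n):
            if pos[e] - pos[e - 1] > max_gap:
                break
            if cls[e] == HET:
                het += 1
                if het > max_opposite:
                    break
            elif cls[e] == MISSING:
                miss += 1
                if miss > max_missing:
                    break
            if hom[e]:
                best = e
        best_end[s] = best
    selected = []
    cursor = -1
    for s in sorted(best_end):
        if s > cursor:
            selected.append((s, best_end[s]))
            cursor = best_end[s]
    return [
        (s, e)
        for s, e in selected
        if e - s + 1 >= min_snp and pos[e] - pos[s] + 1 >= min_length
    ]


# ------------------------------------------------------------- shared regions
def oracle_shared_regions(intervals_per_case, min_len, genome_len):
    """Per-basepair sweep: AND boolean coverage arrays across cases."""
    covered = np.ones(genome_len, dtype=bool)
    for intervals in intervals_per_case:
        mask = np.zeros(genome_len, dtype=bool)
        for s, e in intervals:
            mask[s:e] = True
        covered &= mask
    out = []
    i = 0
    while i < genome_len:
        if covered[i]:
            j = i
            while j < genome_len and covered[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out
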