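"""Multi-locus sequence typing: allele assignment, sequence types, summaries.

Allele numbering follows the standard MLST convention: two strains share an
allele number at a locus iff their sequences over the full fragment are
exactly identical (no ambiguity-code folding; a single mismatch makes a new
allele).  The combination of allele numbers across loci, in a fixed locus
order, defines the sequence type (ST).  Numbers are assigned contiguously
from 1 by order of first appearance in the input strain order, so permuting
the strains permutes labels but never the partition.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import pandas as pd

from .errors import AlignmentError, CrossReferenceError
from .seqio import LocusAlignment


@dataclasses.dataclass
class AlleleTable:
    """Per-locus allele assignment: strain -> allele number (1..k contiguous)."""

    locus: str
    assignments: dict  # strain -> int
    representatives: dict  # allele number -> representative sequence

    @property
    def n_alleles(self) -> int:
        if self.representatives:
            return len(self.representatives)
        return len(set(self.assignments.values()))


@dataclasses.dataclass
class STAssignment:
    """Strain -> allele vector (fixed locus order) and strain -> ST number."""

    locus_order: tuple
    profiles: dict  # strain -> tuple of allele numbers
    sts: dict  # strain -> int

    @property
    def n_sts(self) -> int:
        return len(set(self.sts.values()))


def assign_alleles(aln: LocusAlignment) -> AlleleTable:
    """Number the distinct sequences of one locus by order of first appearance."""
    seen: dict[str, int] = {}
    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for sid, seq in zip(aln.ids, aln.seqs):
        if seq not in seen:
            seen[seq] = len(seen) + 1
            representatives[seen[seq]] = seq
        assignments[sid] = seen[seq]
    return AlleleTable(aln.name, assignments, representatives)


def assign_sts(
    tables: Mapping[str, AlleleTable], locus_order: Sequence[str]
) -> STAssignment:
    """Combine per-locus alleles into sequence types.

    Every strain must be typed at every locus in ``locus_order``.
    """
    missing_loci = [lc for lc in locus_order if lc not in tables]
    if missing_loci:
        raise CrossReferenceError(f"no allele table for loci {missing_loci}",
                                  missing_loci)
    strains = list(tables[locus_order[0]].assignments)
    for lc in locus_order:
        absent = [s for s in strains if s not in tables[lc].assignments]
        extra = [s for s in tables[lc].assignments if s not in strains]
        if absent or extra:
            raise CrossReferenceError(
                f"locus {lc}: strain set differs from {locus_order[0]} "
                f"(missing {absent}, extra {extra})",
                absent + extra,
            )
    profiles = {
        s: tuple(tables[lc].assignments[s] for lc in locus_order) for s in strains
    }
    seen: dict[tuple, int] = {}
    sts: dict[str, int] = {}
    for s in strains:
        prof = profiles[s]
        if prof not in seen:
            seen[prof] = len(seen) + 1
        sts[s] = seen[prof]
    return STAssignment(tuple(locus_order), profiles, sts)


def allele_summary(tables: Mapping[str, AlleleTable]) -> pd.DataFrame:
    """Distinct-allele count per locus, one row per locus."""
    rows = [
        {"locus": lc, "n_alleles": tables[lc].n_alleles,
         "n_strains": len(tables[lc].assignments)}
        for lc in tables
    ]
    return pd.DataFrame(rows)


def allele_sharing(
    tables: Mapping[str, AlleleTable], region_of: Mapping[str, str]
) -> pd.DataFrame:
    """Which strains share which alleles, and whether sharing crosses regions.

    One row per (locus, allele) shared by >= 2 strains; ``cross_region``
    marks alleles shared between strains of different regions.
    """
    rows = []
    for lc, tab in tables.items():
        by_allele: dict[int, list[str]] = {}
        for strain, allele in tab.assignments.items():
            by_allele.setdefault(allele, []).append(strain)
        for allele, strains in sorted(by_allele.items()):
            if len(strains) < 2:
                continue
            regions = sorted({region_of[s] for s in strains})
            rows.append(
                {"locus": lc, "allele": allele, "strains": ",".join(strains),
                 "n_strains": len(strains), "regions": ",".join(regions),
                 "cross_region": len(regions) > 1}
            )
    return pd.DataFrame(
        rows, columns=["locus", "allele", "strains", "n_strains", "regions",
                       "cross_region"]
    )


def concatenate_loci(
    alignments: Mapping[str, LocusAlignment], locus_order: Sequence[str]
) -> LocusAlignment:
    """Join loci in order into one alignment, recording locus boundaries."""
    missing = [lc for lc in locus_order if lc not in alignments]
    if missing:
        raise CrossReferenceError(f"missing alignments for {missing}", missing)
    first = alignments[locus_order[0]]
    strain_set = set(first.ids)
    for lc in locus_order[1:]:
        if set(alignments[lc].ids) != strain_set:
            raise AlignmentError(
                f"locus {lc}: strain set differs from {locus_order[0]}"
            )
    boundaries: dict[str, tuple] = {}
    pos = 0
    for lc in locus_order:
        L = alignments[lc].length
        boundaries[lc] = (pos, pos + L)
        pos += L
    index = {
        lc: {s: i for i, s in enumerate(alignments[lc].ids)} for lc in locus_order
    }
    seqs = tuple(
        "".join(alignments[lc].seqs[index[lc][s]] for lc in locus_order)
        for s in first.ids
    )
    return LocusAlignment("concatenated", first.ids, seqs, boundaries=boundaries)


def st_table(assignment: STAssignment) -> pd.DataFrame:
    """Strain x locus allele matrix with the ST column (Table-style output)."""
    rows = []
    for strain, prof in assignment.profiles.items():
        row = {"strain": strain, "ST": assignment.sts[strain]}
        row.update(dict(zip(assignment.locus_order, prof)))
        rows.append(row)
    return pd.DataFrame(rows)
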