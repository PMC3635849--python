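"""Readers, writers and validated in-memory containers.

Formats handled: FASTA (one aligned locus per file, record id = strain id),
TSV strain metadata, CSV MALDI peak lists, square PHYLIP distance matrices,
newick trees and TSV result tables.  All readers validate and raise
:mod:`ventpop.errors` exceptions on malformed input; all writers emit a
stable, deterministic ordering.

Distance matrices are carried as :class:`skbio.DistanceMatrix` (symmetric,
hollow, labelled), the standard container for this purpose.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import DistanceMatrix

from .errors import AlignmentError, CrossReferenceError, FormatError

__all__ = [
    "LocusAlignment",
    "StrainRecord",
    "PeakList",
    "DistanceMatrix",
    "distance_matrix",
    "read_locus_fasta",
    "write_locus_fasta",
    "read_metadata",
    "write_metadata",
    "read_peaks",
    "write_peaks",
    "read_distance_phylip",
    "write_distance_phylip",
    "write_newick",
    "write_table",
    "validate_dataset",
]

#: nucleotide alphabet accepted in alignments (IUPAC ambiguity + gap)
VALID_CHARS = frozenset("ACGTRYSWKMBDHVN-")


@dataclasses.dataclass
class LocusAlignment:
    """Aligned nucleotide sequences for one locus across strains.

    Sequences are stored uppercase, must be equal-length and non-empty,
    and strain ids must be unique.  ``boundaries`` is only populated on
    concatenated alignments and maps locus name -> (start, end) in
    0-based half-open nucleotide coordinates.
    """

    name: str
    ids: tuple
    seqs: tuple
    boundaries: dict | None = None

    def __post_init__(self):
        self.ids = tuple(self.ids)
        self.seqs = tuple(s.upper() for s in self.seqs)
        if len(self.ids) == 0:
            raise AlignmentError(f"{self.name}: alignment has no sequences")
        if len(self.ids) != len(self.seqs):
            raise AlignmentError(f"{self.name}: ids and sequences differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError(f"{self.name}: duplicate strain ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.name}: ragged sequence lengths {sorted(lengths)}"
            )
        if self.length == 0:
            raise AlignmentError(f"{self.name}: zero-length alignment")
        bad = set("".join(self.seqs)) - VALID_CHARS
        if bad:
            raise FormatError(f"{self.name}: invalid characters {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def as_array(self) -> np.ndarray:
        """(n, L) uint8 array of ASCII codes."""
        return (
            np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
            .reshape(self.n, self.length)
            .copy()
        )

    def select(self, ids: Sequence[str]) -> "LocusAlignment":
        """Sub-alignment restricted to ``ids`` (in the given order)."""
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise CrossReferenceError(
                f"{self.name}: strains not in alignment: {missing}", missing
            )
        return LocusAlignment(
            self.name,
            tuple(ids),
            tuple(self.seqs[index[s]] for s in ids),
            boundaries=self.boundaries,
        )


@dataclasses.dataclass
class StrainRecord:
    """One strain's metadata: site, region, optional WGS84 coordinates."""

    strain: str
    site: str
    region: str
    lat: float | None = None
    lon: float | None = None
    attrs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if (self.lat is None) != (self.lon is None):
            raise FormatError(f"{self.strain}: lat/lon must both be given or absent")


@dataclasses.dataclass
class PeakList:
    """One MALDI-TOF spot: (m/z, intensity) pairs sorted by ascending m/z.

    ``support`` (set by replicate merging) counts the replicates that
    contributed to each peak.
    """

    strain: str
    replicate: str
    mz: np.ndarray
    intensity: np.ndarray
    support: np.ndarray | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise FormatError(f"{self.strain}/{self.replicate}: m/z–intensity mismatch")
        if self.mz.size:
            if np.any(self.mz <= 0) or np.any(self.intensity <= 0):
                raise FormatError(
                    f"{self.strain}/{self.replicate}: non-positive m/z or intensity"
                )
            if np.any(np.diff(self.mz) < 0):
                raise FormatError(f"{self.strain}/{self.replicate}: m/z not sorted")
            if np.any(np.diff(self.mz) == 0):
                raise FormatError(f"{self.strain}/{self.replicate}: duplicate m/z")

    def __len__(self) -> int:
        return self.mz.size


def distance_matrix(data, labels) -> DistanceMatrix:
    """Build a labelled symmetric distance matrix (validates symmetry/hollowness)."""
    return DistanceMatrix(np.asarray(data, dtype=float), ids=list(labels))


# ---------------------------------------------------------------------------
# FASTA

def read_locus_fasta(path, name: str | None = None) -> LocusAlignment:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]  # Biopython id = header token up to whitespace
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"{path}: duplicate FASTA headers {dups}")
    seqs = [str(r.seq).upper() for r in records]
    return LocusAlignment(name or path.stem, tuple(ids), tuple(seqs))


def write_locus_fasta(aln: LocusAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.ids, aln.seqs):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Metadata TSV

_META_REQUIRED = ("strain", "site", "region")


def read_metadata(path) -> list[StrainRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _META_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing columns {missing}")
    if df["strain"].duplicated().any():
        dups = sorted(df.loc[df["strain"].duplicated(), "strain"])
        raise FormatError(f"{path}: duplicate strain ids {dups}")
    has_coords = "lat" in df.columns and "lon" in df.columns
    extra = [c for c in df.columns if c not in _META_REQUIRED + ("lat", "lon")]
    records = []
    for row in df.itertuples(index=False):
        lat = lon = None
        if has_coords:
            lat_s, lon_s = getattr(row, "lat"), getattr(row, "lon")
            if not (pd.isna(lat_s) and pd.isna(lon_s)):
                if pd.isna(lat_s) or pd.isna(lon_s):
                    raise FormatError(f"{row.strain}: one of lat/lon is missing")
                lat, lon = float(lat_s), float(lon_s)
        attrs = {c: getattr(row, c) for c in extra}
        records.append(
            StrainRecord(row.strain, row.site, row.region, lat, lon, attrs)
        )
    return records


def write_metadata(records: Sequence[StrainRecord], path) -> None:
    extra = sorted({k for r in records for k in r.attrs})
    rows = []
    for r in records:
        row = {"strain": r.strain, "site": r.site, "region": r.region,
               "lat": r.lat, "lon": r.lon}
        row.update({k: r.attrs.get(k) for k in extra})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MALDI peak CSV

def read_peaks(path) -> list[PeakList]:
    df = pd.read_csv(path)
    required = {"strain", "replicate", "mz", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: peaks CSV missing columns {sorted(missing)}")
    out = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        grp = grp.sort_values("mz")
        out.append(
            PeakList(str(strain), str(rep), grp["mz"].to_numpy(),
                     grp["intensity"].to_numpy())
        )
    return out


def write_peaks(peaklists: Iterable[PeakList], path) -> None:
    rows = []
    for pl in peaklists:
        for mz, inten in zip(pl.mz, pl.intensity):
            rows.append({"strain": pl.strain, "replicate": pl.replicate,
                         "mz": mz, "intensity": inten})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PHYLIP square distance matrix / newick / tables

def write_distance_phylip(dm: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")


def read_distance_phylip(path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: bad PHYLIP header") from exc
    if len(lines) != n + 1:
        raise FormatError(f"{path}: expected {n} matrix rows")
    labels, data = [], []
    for ln in lines[1:]:
        parts = ln.split()
        labels.append(parts[0])
        data.append([float(v) for v in parts[1:]])
    arr = np.asarray(data)
    if arr.shape != (n, n):
        raise FormatError(f"{path}: matrix is not {n}x{n}")
    return distance_matrix(arr, labels)


def write_newick(tree, path) -> None:
    tree.write(str(path), format="newick")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dataset-level validation

def drop_incomplete_strains(
    alignments: Mapping[str, LocusAlignment],
) -> tuple[dict, list]:
    """Restrict every locus to the strains typed at *all* loci.

    Returns ``(filtered alignments, dropped strain ids)``; the permissive
    counterpart to the default all-loci requirement.
    """
    common = set.intersection(*(set(a.ids) for a in alignments.values()))
    dropped = sorted(
        {s for a in alignments.values() for s in a.ids} - common
    )
    first = next(iter(alignments.values()))
    order = [s for s in first.ids if s in common]
    return {name: aln.select(order) for name, aln in alignments.items()}, dropped


def validate_dataset(
    alignments: Mapping[str, LocusAlignment],
    records: Sequence[StrainRecord],
    peaklists: Sequence[PeakList] | None = None,
    allow_missing: bool = False,
) -> None:
    """Cross-reference every data file against the metadata table.

    Every strain id appearing in any alignment or peak list must appear in
    the metadata; every metadata strain must be typed at every locus (the
    scheme types all strains at all loci).  Raises
    :class:`CrossReferenceError` listing offenders; with ``allow_missing``
    strains absent from some loci are tolerated (use
    :func:`drop_incomplete_strains` to remove them).
    """
    known = {r.strain for r in records}
    for aln in alignments.values():
        unknown = sorted(set(aln.ids) - known)
        if unknown:
            raise CrossReferenceError(
                f"locus {aln.name}: strains absent from metadata: {unknown}", unknown
            )
        absent = sorted(known - set(aln.ids))
        if absent and not allow_missing:
            raise CrossReferenceError(
                f"locus {aln.name}: metadata strains missing from alignment: {absent}",
                absent,
            )
    if peaklists is not None:
        unknown = sorted({pl.strain for pl in peaklists} - known)
        if unknown:
            raise CrossReferenceError(
                f"peak lists name strains absent from metadata: {unknown}", unknown
            )
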