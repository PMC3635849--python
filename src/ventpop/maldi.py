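"""Whole-cell MALDI-TOF/MS fingerprint pipeline.

Replicate spot peak lists are merged by 1-D single-linkage grouping within
a small m/z tolerance (default 5 Da), low-mass noise is removed (peaks at
or below 2100 Da, operationalizing "around 2000 m/z"), the 15 most intense
peaks per strain become its fingerprint (relative intensities scaled to
max = 1), fingerprints are pooled into presence/absence bins within a
14 Da tolerance, and strains are clustered by Ward's minimum-variance
method on the binary bin matrix.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy

from .errors import NotComputable
from .seqio import PeakList

__all__ = [
    "Fingerprint",
    "BinMatrix",
    "Dendrogram",
    "merge_replicates",
    "filter_noise",
    "top_peaks",
    "bin_peaks",
    "ward_cluster",
    "fingerprint_pipeline",
]


@dataclasses.dataclass
class Fingerprint:
    """A strain's top peaks: consensus m/z and relative intensity (max = 1)."""

    strain: str
    mz: np.ndarray
    rel_intensity: np.ndarray
    short: bool = False  # fewer peaks than requested were available


@dataclasses.dataclass
class BinMatrix:
    """Strains x m/z-bin presence/absence matrix."""

    strains: tuple
    centers: np.ndarray
    matrix: np.ndarray  # uint8, entries in {0, 1}
    chained: np.ndarray  # bool per bin: single-linkage span exceeded 2*tol
    tol: float


@dataclasses.dataclass
class Dendrogram:
    """Ward merge history (scipy linkage matrix) over labelled leaves."""

    linkage: np.ndarray
    labels: tuple

    def cut(self, k: int) -> dict:
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return {label: int(c) for label, c in zip(self.labels, flat)}

    def to_newick(self) -> str:
        root = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.get_left()), rec(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        return "(" + rec(root).rsplit(":", 1)[0] + ");"


def _single_linkage_groups(mz: np.ndarray, tol: float) -> list[np.ndarray]:
    """Indices of groups formed by merging adjacent sorted m/z gaps <= tol."""
    order = np.argsort(mz, kind="stable")
    s = mz[order]
    if s.size == 0:
        return []
    breaks = np.nonzero(np.diff(s) > tol)[0]
    bounds = np.concatenate([[0], breaks + 1, [s.size]])
    return [order[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]


def merge_replicates(replicates: Sequence[PeakList], mz_tol: float = 5.0) -> PeakList:
    """Average replicate spots of one strain into a single peak list.

    Peaks across replicates within ``mz_tol`` Da (single linkage) are one
    consensus peak with unweighted mean m/z and mean intensity; the
    ``support`` array records how many replicates contributed, so peaks
    seen in only one spot stay flagged rather than dropped.
    """
    if not replicates:
        raise NotComputable("no replicates to merge")
    strains = {pl.strain for pl in replicates}
    if len(strains) != 1:
        raise NotComputable(f"replicates from several strains: {sorted(strains)}")
    mz = np.concatenate([pl.mz for pl in replicates])
    inten = np.concatenate([pl.intensity for pl in replicates])
    rep_of = np.concatenate(
        [np.full(len(pl), i) for i, pl in enumerate(replicates)]
    )
    out_mz, out_int, out_sup = [], [], []
    for grp in _single_linkage_groups(mz, mz_tol):
        out_mz.append(mz[grp].mean())
        out_int.append(inten[grp].mean())
        out_sup.append(len(np.unique(rep_of[grp])))
    order = np.argsort(out_mz)
    return PeakList(
        replicates[0].strain,
        "merged",
        np.asarray(out_mz)[order],
        np.asarray(out_int)[order],
        support=np.asarray(out_sup)[order],
    )


def filter_noise(peaks: PeakList, low_mz_cut: float = 2100.0) -> PeakList:
    """Drop low-mass noise: peaks with m/z <= ``low_mz_cut`` Da."""
    keep = peaks.mz > low_mz_cut
    return PeakList(
        peaks.strain,
        peaks.replicate,
        peaks.mz[keep],
        peaks.intensity[keep],
        support=None if peaks.support is None else peaks.support[keep],
    )


def top_peaks(peaks: PeakList, n: int = 15) -> Fingerprint:
    """The ``n`` most intense peaks, ties broken toward lower m/z; relative
    intensity is intensity / max intensity.  Short lists are kept, flagged."""
    if len(peaks) == 0:
        return Fingerprint(peaks.strain, np.empty(0), np.empty(0), short=True)
    order = np.lexsort((peaks.mz, -peaks.intensity))[:n]
    sel = np.sort(order)  # back to ascending m/z
    mz = peaks.mz[sel]
    inten = peaks.intensity[sel]
    return Fingerprint(
        peaks.strain, mz, inten / inten.max(), short=len(peaks) < n
    )


def bin_peaks(fingerprints: Sequence[Fingerprint], tol: float = 14.0) -> BinMatrix:
    """Pool all fingerprint peaks into cross-strain presence/absence bins.

    Bins form by 1-D single linkage: adjacent pooled m/z values with gap
    <= ``tol`` share a bin (deterministic and input-order-free).  Bin
    center = mean member m/z; a cell is 1 iff the strain contributed at
    least one peak.  Bins whose total span exceeds 2*tol are flagged as
    chained.
    """
    if len(fingerprints) < 2:
        raise NotComputable("binning needs >= 2 strains")
    strains = tuple(fp.strain for fp in fingerprints)
    mz = np.concatenate([fp.mz for fp in fingerprints])
    strain_of = np.concatenate(
        [np.full(len(fp.mz), i) for i, fp in enumerate(fingerprints)]
    )
    groups = _single_linkage_groups(mz, tol)
    centers = np.asarray([mz[g].mean() for g in groups])
    order = np.argsort(centers)
    matrix = np.zeros((len(strains), len(groups)), dtype=np.uint8)
    chained = np.zeros(len(groups), dtype=bool)
    for out_col, gi in enumerate(order):
        g = groups[gi]
        matrix[strain_of[g], out_col] = 1
        chained[out_col] = (mz[g].max() - mz[g].min()) > 2 * tol
    return BinMatrix(strains, centers[order], matrix, chained, tol)


def ward_cluster(bm: BinMatrix) -> Dendrogram:
    """Ward minimum-variance clustering of strains on binary bin rows."""
    if len(bm.strains) < 2:
        raise NotComputable("clustering needs >= 2 strains")
    Z = hierarchy.linkage(bm.matrix.astype(float), method="ward")
    return Dendrogram(Z, bm.strains)


def fingerprint_pipeline(
    peaklists: Sequence[PeakList],
    mz_tol: float = 5.0,
    low_mz_cut: float = 2100.0,
    top_n: int = 15,
    bin_tol: float = 14.0,
):
    """Full pipeline: merge replicates -> filter -> top peaks -> bin -> Ward.

    Returns ``(fingerprints, bin_matrix, dendrogram)``.  Strains are
    processed in sorted order so the result is input-order-free.
    """
    by_strain: dict[str, list[PeakList]] = {}
    for pl in peaklists:
        by_strain.setdefault(pl.strain, []).append(pl)
    fingerprints = []
    for strain in sorted(by_strain):
        merged = merge_replicates(by_strain[strain], mz_tol=mz_tol)
        fingerprints.append(top_peaks(filter_noise(merged, low_mz_cut), n=top_n))
    bm = bin_peaks(fingerprints, tol=bin_tol)
    return fingerprints, bm, ward_cluster(bm)
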