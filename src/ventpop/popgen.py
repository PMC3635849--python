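"""Per-locus population-genetic statistics for coding-gene alignments.

Implements the panel computed for each typing locus: mean pairwise identity
(nucleotide and amino acid), segregating-site counts, Watterson's theta,
Tajima's D (with the variant that substitutes the total number of mutations
eta for the number of segregating sites S), Ka/Ks by the Li (1993) /
Pamilo-Bianchi-Li site-degeneracy method with Kimura two-parameter
correction and a 90-nt/18-nt sliding window, a codon-bootstrap Z-test of
purifying selection (dS > dN), and the PHI (pairwise homoplasy index)
recombination test of Bruen et al. (2006).

Conventions (pinned by the oracle tests):

* Ambiguity codes and gaps are treated as missing data under pairwise
  deletion everywhere; codons containing missing bases, and stop codons,
  are excluded from Ka/Ks.
* Sites whose degeneracy class differs between the two sequences of a pair
  contribute half a site (and half of any substitution) to each class.
* Multi-hit codons are counted site by site (no pathway enumeration).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .errors import AlignmentError, NotComputable, UndefinedStatistic
from .seqio import LocusAlignment

__all__ = [
    "SiteCounts",
    "PopGenSummary",
    "pairwise_identity",
    "segregating_sites",
    "watterson_theta",
    "tajimas_d",
    "kaks_li",
    "kaks_locus",
    "z_test_selection",
    "phi_test",
    "locus_summary",
]

# ---------------------------------------------------------------------------
# Codon bookkeeping (bacterial code, frame 1)

_BASES = b"ACGT"
_B2I = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _B2I[_b] = _i

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: amino acid (one letter, '*' = stop) for codon index 16*b1 + 4*b2 + b3
CODON_AA = np.empty(64, dtype="U1")
#: degeneracy class (0, 2 or 4) of each codon position; -1 for stop codons
CODON_DEGEN = np.full((64, 3), -1, dtype=np.int8)

def _aa_of(codon: str) -> str:
    return _CODON_TABLE.forward_table.get(codon, "*")


for _idx in range(64):
    _codon = "".join(chr(_BASES[(_idx >> (2 * (2 - p))) & 3]) for p in range(3))
    _aa = _aa_of(_codon)
    CODON_AA[_idx] = _aa
    if _aa == "*":
        continue
    for _pos in range(3):
        _syn = sum(
            _aa_of(_codon[:_pos] + chr(b) + _codon[_pos + 1 :]) == _aa
            for b in _BASES
            if chr(b) != _codon[_pos]
        )
        # 4-fold: all three alternatives synonymous; 0-fold: none;
        # everything else (incl. Ile's 3-fold third position) is 2-fold.
        CODON_DEGEN[_idx, _pos] = 4 if _syn == 3 else (0 if _syn == 0 else 2)

#: map degeneracy value (0, 2, 4) to class index (0, 1, 2)
_DEG2CLS = np.full(5, -1, dtype=np.int8)
_DEG2CLS[[0, 2, 4]] = [0, 1, 2]


def _base_indices(aln: LocusAlignment) -> np.ndarray:
    """(n, L) int8 array: 0..3 for A,C,G,T; -1 for anything else (missing)."""
    return _B2I[aln.as_array()]


def _codon_indices(b: np.ndarray) -> np.ndarray:
    """(n, L/3) codon indices from base indices; -1 where any base missing."""
    n, L = b.shape
    if L % 3:
        raise AlignmentError(f"length {L} not divisible by 3")
    c = b.reshape(n, L // 3, 3)
    idx = 16 * c[:, :, 0] + 4 * c[:, :, 1] + c[:, :, 2]
    idx[(c < 0).any(axis=2)] = -1
    return idx.astype(np.int64)


# ---------------------------------------------------------------------------
# Identity / diversity

@dataclasses.dataclass
class SiteCounts:
    """Polymorphism counts: S segregating sites, eta total mutations."""

    n: int
    L: int
    S: int
    eta: int


@dataclasses.dataclass
class PopGenSummary:
    """One locus's row of the per-locus statistics table."""

    locus: str
    n: int
    length: int
    nt_identity_mean: float
    nt_identity_sd: float
    aa_identity_mean: float
    aa_identity_sd: float
    kaks_mean: float
    kaks_sd: float
    S: int
    eta: int
    theta_eta: float
    theta_S: float
    tajimas_d_eta: float | None
    tajimas_d_S: float | None
    z: float | None
    z_p: float | None


def _pair_diff_matrices(b: np.ndarray):
    """Matrices of per-pair match and compared-site counts under pairwise deletion."""
    valid = b >= 0
    matches = np.zeros((b.shape[0],) * 2)
    for base in range(4):
        x = (b == base).astype(float)
        matches += x @ x.T
    compared = valid.astype(float) @ valid.astype(float).T
    return matches, compared


def pairwise_identity(aln: LocusAlignment, level: str = "nucleotide"):
    """Mean and SD (ddof=1) of percent identity over all strain pairs."""
    if aln.n < 2:
        raise UndefinedStatistic("pairwise identity needs >= 2 sequences")
    if level == "nucleotide":
        b = _base_indices(aln)
    elif level == "amino_acid":
        cod = _codon_indices(_base_indices(aln))
        b = np.where(cod >= 0, cod, -1)
        # recode codons to amino-acid classes so identity compares residues
        aa_codes = np.frombuffer(
            "".join(CODON_AA).encode("ascii"), dtype=np.uint8
        ).astype(np.int64)
        b = np.where(b >= 0, aa_codes[np.clip(b, 0, 63)], -1)
        valid = b >= 0
        iu = np.triu_indices(aln.n, k=1)
        vals = []
        for i, j in zip(*iu):
            both = valid[i] & valid[j]
            if not both.any():
                raise UndefinedStatistic("no comparable sites")
            vals.append(100.0 * np.mean(b[i][both] == b[j][both]))
        vals = np.asarray(vals)
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    else:
        raise ValueError(f"unknown level {level!r}")
    matches, compared = _pair_diff_matrices(b)
    iu = np.triu_indices(aln.n, k=1)
    comp = compared[iu]
    if np.any(comp == 0):
        raise UndefinedStatistic("a pair has no comparable sites")
    vals = 100.0 * matches[iu] / comp
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0


def segregating_sites(aln: LocusAlignment) -> SiteCounts:
    """Count segregating sites S and total mutations eta (states-1 per column)."""
    if aln.n < 2:
        raise UndefinedStatistic("need >= 2 sequences")
    b = _base_indices(aln)
    states = np.zeros(aln.length, dtype=int)
    for base in range(4):
        states += (b == base).any(axis=0)
    S = int(np.sum(states >= 2))
    eta = int(np.sum(np.maximum(states - 1, 0)))
    return SiteCounts(aln.n, aln.length, S, eta)


def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def watterson_theta(counts: SiteCounts, basis: str = "eta") -> float:
    """Watterson's estimator per site: basis_count / (a1 * L)."""
    if counts.L == 0:
        raise UndefinedStatistic("zero-length alignment")
    k = counts.eta if basis == "eta" else counts.S
    return k / (_harmonic(counts.n) * counts.L)


def mean_pairwise_differences(aln: LocusAlignment) -> float:
    """Mean number of differing sites per pair (pairwise deletion, raw counts)."""
    b = _base_indices(aln)
    matches, compared = _pair_diff_matrices(b)
    iu = np.triu_indices(aln.n, k=1)
    return float((compared[iu] - matches[iu]).mean())


def tajimas_d(aln: LocusAlignment, basis: str = "eta") -> float:
    """Tajima's D; ``basis='eta'`` uses the total number of mutations.

    Raises :class:`UndefinedStatistic` when the alignment is monomorphic.
    """
    if aln.n < 2:
        raise UndefinedStatistic("need >= 2 sequences")
    counts = segregating_sites(aln)
    k = counts.eta if basis == "eta" else counts.S
    if k == 0:
        raise UndefinedStatistic("no polymorphism: Tajima's D undefined")
    n = aln.n
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi = mean_pairwise_differences(aln)
    var = e1 * k + e2 * k * (k - 1)
    return float((pi - k / a1) / np.sqrt(var))


# ---------------------------------------------------------------------------
# Li / Pamilo-Bianchi-Li Ka/Ks

def _pair_codon_contribs(b1: np.ndarray, b2: np.ndarray):
    """Per-codon degeneracy-class site and substitution counts for one pair.

    Returns (L, ts, tv), each (n_codons, 3) with class order
    [0-fold, 2-fold, 4-fold].  Codons with missing bases or stops in either
    sequence contribute nothing (pairwise deletion).
    """
    C = b1.shape[0] // 3
    cb1 = b1.reshape(C, 3)
    cb2 = b2.reshape(C, 3)
    c1 = _codon_indices(b1[None, :])[0]
    c2 = _codon_indices(b2[None, :])[0]
    ok = (c1 >= 0) & (c2 >= 0)
    ok &= np.where(ok, CODON_AA[np.clip(c1, 0, 63)] != "*", False)
    ok &= np.where(ok, CODON_AA[np.clip(c2, 0, 63)] != "*", False)
    L = np.zeros((C, 3))
    ts = np.zeros((C, 3))
    tv = np.zeros((C, 3))
    rows = np.nonzero(ok)[0]
    if rows.size == 0:
        return L, ts, tv
    for pos in range(3):
        cls1 = _DEG2CLS[CODON_DEGEN[c1[rows], pos]]
        cls2 = _DEG2CLS[CODON_DEGEN[c2[rows], pos]]
        np.add.at(L, (rows, cls1), 0.5)
        np.add.at(L, (rows, cls2), 0.5)
        x, y = cb1[rows, pos], cb2[rows, pos]
        diff = x != y
        is_ts = diff & ((x & 1) == (y & 1))  # A<->G, C<->T
        is_tv = diff & ~is_ts
        np.add.at(ts, (rows[is_ts], cls1[is_ts]), 0.5)
        np.add.at(ts, (rows[is_ts], cls2[is_ts]), 0.5)
        np.add.at(tv, (rows[is_tv], cls1[is_tv]), 0.5)
        np.add.at(tv, (rows[is_tv], cls2[is_tv]), 0.5)
    return L, ts, tv


def _pbl(L, ts, tv):
    """Pamilo-Bianchi-Li (Ka, Ks) from class totals; class axis is last.

    Uses Kimura two-parameter corrections per class:
    A_i = -ln(1-2P-Q)/2 + ln(1-2Q)/4,  B_i = -ln(1-2Q)/2, then
    Ks = (L2 A2 + L4 A4)/(L2+L4) + B4 and Ka = A0 + (L0 B0 + L2 B2)/(L0+L2).
    Returns NaN where the correction is saturated or a class sum is empty.
    """
    L = np.asarray(L, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(L > 0, ts / np.where(L > 0, L, 1.0), 0.0)
        Q = np.where(L > 0, tv / np.where(L > 0, L, 1.0), 0.0)
        x = 1.0 - 2.0 * P - Q
        y = 1.0 - 2.0 * Q
        A = np.where((x > 0) & (y > 0), -0.5 * np.log(x) + 0.25 * np.log(y), np.nan)
        B = np.where(y > 0, -0.5 * np.log(y), np.nan)
        # empty classes carry zero weight; make their terms exact zeros
        A = np.where(L > 0, A, 0.0)
        B = np.where(L > 0, B, 0.0)
        w24 = L[..., 1] + L[..., 2]
        w02 = L[..., 0] + L[..., 1]
        Ks = np.where(
            w24 > 0,
            (L[..., 1] * A[..., 1] + L[..., 2] * A[..., 2])
            / np.where(w24 > 0, w24, 1.0)
            + B[..., 2],
            np.nan,
        )
        Ka = np.where(
            w02 > 0,
            A[..., 0]
            + (L[..., 0] * B[..., 0] + L[..., 1] * B[..., 1])
            / np.where(w02 > 0, w02, 1.0),
            np.nan,
        )
    return Ka, Ks


def kaks_li(seq1: str, seq2: str):
    """(Ka, Ks) for one pair of gap-free coding sequences (PBL method)."""
    if len(seq1) != len(seq2):
        raise AlignmentError("sequences differ in length")
    if len(seq1) % 3:
        raise AlignmentError("length not divisible by 3")
    aln = LocusAlignment("pair", ("a", "b"), (seq1, seq2))
    b = _base_indices(aln)
    L, ts, tv = _pair_codon_contribs(b[0], b[1])
    Ka, Ks = _pbl(L.sum(axis=0), ts.sum(axis=0), tv.sum(axis=0))
    return float(Ka), float(Ks)


@dataclasses.dataclass
class KaKsSummary:
    mean: float
    sd: float
    n_pairs_used: int
    n_pairs_excluded: int
    n_windows_skipped: int
    window: int
    step: int


def kaks_locus(aln: LocusAlignment, window: int = 90, step: int = 18) -> KaKsSummary:
    """Locus-level Ka/Ks: sliding-window means per pair, then mean (SD) over pairs.

    Windows advance on nucleotide coordinates (trailing partial window
    dropped); a window contributes the ratio Ka/Ks and is skipped when its
    Ks is 0 or the correction saturates.  Pairs with no usable window
    (e.g. identical sequences) are excluded and counted.
    """
    if aln.length % 3 or window % 3 or step % 3:
        raise AlignmentError("length, window and step must be divisible by 3")
    if aln.n < 2:
        raise UndefinedStatistic("need >= 2 sequences")
    b = _base_indices(aln)
    C = aln.length // 3
    wc, sc = window // 3, step // 3
    starts = list(range(0, C - wc + 1, sc))
    per_pair = []
    excluded = 0
    skipped = 0
    for i in range(aln.n):
        for j in range(i + 1, aln.n):
            L, ts, tv = _pair_codon_contribs(b[i], b[j])
            cl = np.concatenate([np.zeros((1, 3)), np.cumsum(L, axis=0)])
            cts = np.concatenate([np.zeros((1, 3)), np.cumsum(ts, axis=0)])
            ctv = np.concatenate([np.zeros((1, 3)), np.cumsum(tv, axis=0)])
            ratios = []
            for s in starts:
                Lw = cl[s + wc] - cl[s]
                tsw = cts[s + wc] - cts[s]
                tvw = ctv[s + wc] - ctv[s]
                Ka, Ks = _pbl(Lw, tsw, tvw)
                if np.isfinite(Ka) and np.isfinite(Ks) and Ks > 0:
                    ratios.append(Ka / Ks)
                else:
                    skipped += 1
            if ratios:
                per_pair.append(float(np.mean(ratios)))
            else:
                excluded += 1
    if per_pair:
        arr = np.asarray(per_pair)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        mean, sd = float("nan"), float("nan")
    return KaKsSummary(mean, sd, len(per_pair), excluded, skipped, window, step)


# ---------------------------------------------------------------------------
# Z-test of purifying selection (codon bootstrap, PBL distances)

@dataclasses.dataclass
class ZTestResult:
    z: float
    p: float
    dn: float
    ds: float
    se: float
    reps: int


def z_test_selection(
    aln: LocusAlignment, reps: int = 1000, seed: int | None = None
) -> ZTestResult:
    """One-tailed test of dS > dN (purifying selection).

    dN and dS are overall averages of pairwise PBL estimates; the standard
    error of (dS - dN) comes from ``reps`` bootstrap resamples of codon
    columns; p is the standard-normal upper tail.
    """
    if aln.n < 2:
        raise UndefinedStatistic("need >= 2 sequences")
    if aln.length % 3:
        raise AlignmentError("length not divisible by 3")
    C = aln.length // 3
    if C < 10:
        raise NotComputable("fewer than 10 codon columns")
    b = _base_indices(aln)
    pairs = [(i, j) for i in range(aln.n) for j in range(i + 1, aln.n)]
    T = np.empty((len(pairs), C, 9))
    for k, (i, j) in enumerate(pairs):
        L, ts, tv = _pair_codon_contribs(b[i], b[j])
        T[k] = np.concatenate([L, ts, tv], axis=1)
    tot = T.sum(axis=1)  # (pairs, 9)
    Ka, Ks = _pbl(tot[:, 0:3], tot[:, 3:6], tot[:, 6:9])
    dn, ds = float(np.nanmean(Ka)), float(np.nanmean(Ks))
    if not (np.isfinite(dn) and np.isfinite(ds)):
        raise UndefinedStatistic("pairwise distances saturated")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(C, np.full(C, 1.0 / C), size=reps).astype(float)
    sums = (
        T.transpose(0, 2, 1).reshape(len(pairs) * 9, C) @ counts.T
    ).reshape(len(pairs), 9, reps)
    bKa, bKs = _pbl(
        np.moveaxis(sums[:, 0:3, :], 1, -1),
        np.moveaxis(sums[:, 3:6, :], 1, -1),
        np.moveaxis(sums[:, 6:9, :], 1, -1),
    )
    with np.errstate(invalid="ignore"):
        diff = np.nanmean(bKs - bKa, axis=0)  # (reps,)
    se = float(np.nanstd(diff, ddof=1)) if reps > 1 else 0.0
    if se == 0.0 or not np.isfinite(se):
        raise UndefinedStatistic("bootstrap SE of dS-dN is zero or undefined")
    z = (ds - dn) / se
    return ZTestResult(float(z), float(stats.norm.sf(z)), dn, ds, se, reps)


# ---------------------------------------------------------------------------
# PHI recombination test

@dataclasses.dataclass
class PhiResult:
    phi: float
    p: float
    n_informative: int
    n_pairs: int
    permutations: int


def _refined_incompatibility(col_i: np.ndarray, col_j: np.ndarray) -> int:
    """Extra mutations forced by analysing sites i and j jointly.

    Builds the bipartite state-intersection graph over rows where both
    sites are unambiguous; the score is E - V + C (number of independent
    cycles), 0 iff the two sites are compatible on some tree.
    """
    ok = (col_i >= 0) & (col_j >= 0)
    a, b = col_i[ok], col_j[ok]
    joint = np.unique(a * 4 + b)
    ua = np.unique(a)
    ub = np.unique(b)
    # union-find over states of both sites
    parent = {("a", int(s)): ("a", int(s)) for s in ua}
    parent.update({("b", int(s)): ("b", int(s)) for s in ub})

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    comps = len(parent)
    for code in joint:
        x, y = find(("a", int(code) // 4)), find(("b", int(code) % 4))
        if x != y:
            parent[x] = y
            comps -= 1
    return int(len(joint) - (len(ua) + len(ub)) + comps)


def phi_test(
    aln: LocusAlignment,
    window: int = 100,
    permutations: int = 1000,
    seed: int | None = None,
) -> PhiResult:
    """PHI test for recombination.

    Phi is the mean refined-incompatibility score over pairs of parsimony-
    informative sites within ``window`` nucleotides of each other; the
    permutation p-value is the fraction of random site orderings giving a
    mean at most as large (clonal evolution makes incompatibility
    independent of distance; recombination concentrates compatibility
    among nearby sites).
    """
    if aln.n < 4:
        raise NotComputable("PHI needs >= 4 sequences")
    b = _base_indices(aln)
    informative = []
    for col in range(aln.length):
        vals = b[:, col]
        vals = vals[vals >= 0]
        if vals.size < 4:
            continue
        counts = np.bincount(vals, minlength=4)
        if np.sum(counts >= 2) >= 2:
            informative.append(col)
    m = len(informative)
    if m < 2:
        raise NotComputable("fewer than 2 parsimony-informative sites")
    positions = np.asarray(informative)
    score = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            s = _refined_incompatibility(b[:, positions[i]], b[:, positions[j]])
            score[i, j] = score[j, i] = s
    ia, ib = np.nonzero(
        (np.abs(positions[:, None] - positions[None, :]) <= window)
        & (np.arange(m)[:, None] < np.arange(m)[None, :])
    )
    if ia.size == 0:
        raise NotComputable("no informative site pairs within the window")
    obs = float(score[ia, ib].mean())
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(m)
        if score[perm[ia], perm[ib]].mean() <= obs + 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return PhiResult(obs, float(p), m, int(ia.size), permutations)


# ---------------------------------------------------------------------------
# Locus summary row

def locus_summary(
    aln: LocusAlignment,
    window: int = 90,
    step: int = 18,
    z_reps: int = 1000,
    seed: int | None = None,
) -> PopGenSummary:
    """The full per-locus statistics row (identity, Ka/Ks, theta, Z, Tajima's D)."""
    nt_mean, nt_sd = pairwise_identity(aln, "nucleotide")
    aa_mean, aa_sd = pairwise_identity(aln, "amino_acid")
    counts = segregating_sites(aln)
    kaks = kaks_locus(aln, window=window, step=step)
    try:
        d_eta = tajimas_d(aln, basis="eta")
        d_s = tajimas_d(aln, basis="S")
    except UndefinedStatistic:
        d_eta = d_s = None
    try:
        zres = z_test_selection(aln, reps=z_reps, seed=seed)
        z, z_p = zres.z, zres.p
    except (UndefinedStatistic, NotComputable):
        z = z_p = None
    return PopGenSummary(
        locus=aln.name,
        n=aln.n,
        length=aln.length,
        nt_identity_mean=nt_mean,
        nt_identity_sd=nt_sd,
        aa_identity_mean=aa_mean,
        aa_identity_sd=aa_sd,
        kaks_mean=kaks.mean,
        kaks_sd=kaks.sd,
        S=counts.S,
        eta=counts.eta,
        theta_eta=watterson_theta(counts, "eta"),
        theta_S=watterson_theta(counts, "S"),
        tajimas_d_eta=d_eta,
        tajimas_d_S=d_s,
        z=z,
        z_p=z_p,
    )
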