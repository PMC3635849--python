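"""Population differentiation and distance-decay analysis.

F_ST uses the Hudson (1992) pi-based estimator
F_ST = (pi_between - pi_within) / pi_between, with pi_between the mean
pairwise per-site difference between populations and pi_within the
unweighted mean of the two within-population means.  Slightly negative
estimates are legal.  Significance comes from a label-permutation test
(the standard device; the upstream description of "randomized bootstrap
resamplings" is treated as loose usage for this).

The Mantel test correlates the upper triangles of two labelled distance
matrices and permutes the row/column order of the second; geographic
distances are great-circle (haversine, R = 6371.0088 km) between the
strains' sites, and environmental distances are absolute differences of a
site variable.  End-member fluid compositions are recovered by ordinary
least squares extrapolation of a species concentration to Mg = 0.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from .errors import UndefinedStatistic
from .popgen import _base_indices, _pair_diff_matrices
from .seqio import LocusAlignment, StrainRecord, distance_matrix

__all__ = [
    "FstResult",
    "MantelResult",
    "RegressionResult",
    "pairwise_fst",
    "fst_matrix",
    "mantel",
    "geographic_distances",
    "env_distances",
    "combined_env_distances",
    "distance_decay",
    "end_member",
]

EARTH_RADIUS_KM = 6371.0088


@dataclasses.dataclass
class FstResult:
    pop_a: str
    pop_b: str
    fst: float
    p: float
    permutations: int


@dataclasses.dataclass
class MantelResult:
    r: float
    p: float
    permutations: int


@dataclasses.dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    intercept_se: float


# ---------------------------------------------------------------------------
# F_ST

def _per_site_diff_matrix(aln: LocusAlignment) -> np.ndarray:
    """Pairwise per-site difference fraction under pairwise deletion."""
    b = _base_indices(aln)
    matches, compared = _pair_diff_matrices(b)
    if np.any(compared[np.triu_indices(aln.n, k=1)] == 0):
        raise UndefinedStatistic("a pair has no comparable sites")
    with np.errstate(invalid="ignore"):
        pd_ = (compared - matches) / np.where(compared > 0, compared, 1.0)
    np.fill_diagonal(pd_, 0.0)
    return pd_


def _hudson_fst(pdm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    pi_b = pdm[np.ix_(idx_a, idx_b)].mean()
    if pi_b == 0:
        raise UndefinedStatistic("pi_between is zero: F_ST undefined")

    def within(idx):
        if len(idx) < 2:
            return np.nan
        sub = pdm[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return sub[iu].mean()

    wa, wb = within(idx_a), within(idx_b)
    pi_w = np.nanmean([wa, wb])
    return float((pi_b - pi_w) / pi_b)


def pairwise_fst(
    aln: LocusAlignment,
    populations: Mapping[str, Sequence[str]],
    pop_a: str,
    pop_b: str,
    permutations: int = 1000,
    seed: int | None = None,
) -> FstResult:
    """Hudson F_ST between two populations with a label-permutation test.

    p is the fraction of permutations (observed configuration included in
    numerator and denominator) with F_ST at least as large as observed.
    """
    members_a, members_b = list(populations[pop_a]), list(populations[pop_b])
    if len(members_a) < 2 or len(members_b) < 2:
        raise UndefinedStatistic("each population needs >= 2 strains")
    index = {s: i for i, s in enumerate(aln.ids)}
    idx_a = np.asarray([index[s] for s in members_a])
    idx_b = np.asarray([index[s] for s in members_b])
    pdm = _per_site_diff_matrix(aln)
    obs = _hudson_fst(pdm, idx_a, idx_b)
    pool = np.concatenate([idx_a, idx_b])
    na = len(idx_a)
    rng = np.random.default_rng(seed)
    hits = 1  # observed counted
    for _ in range(permutations):
        perm = rng.permutation(pool)
        try:
            f = _hudson_fst(pdm, perm[:na], perm[na:])
        except UndefinedStatistic:
            continue
        if f >= obs - 1e-12:
            hits += 1
    p = hits / (permutations + 1)
    return FstResult(pop_a, pop_b, obs, float(p), permutations)


def fst_matrix(
    aln: LocusAlignment,
    populations: Mapping[str, Sequence[str]],
    permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """All pairwise F_ST values (with p) among populations of >= 2 strains."""
    names = [p for p in populations if len(populations[p]) >= 2]
    rows = []
    rng = np.random.default_rng(seed)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = pairwise_fst(
                aln, populations, a, b, permutations=permutations,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.append(
                {"pop_a": a, "pop_b": b, "fst": res.fst, "p": res.p,
                 "permutations": res.permutations}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel

def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    permutations: int = 1000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation over upper-triangle entries; p is
    two-sided, from permutations of the row/column order of ``d2``.
    """
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    n = d1.shape[0]
    if n < 4:
        raise UndefinedStatistic("Mantel test needs >= 4 objects")
    iu = np.triu_indices(n, k=1)
    x = d1.data[iu]
    y = d2.data[iu]
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatistic("zero variance in a distance matrix")
    obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = d2.data[np.ix_(perm, perm)][iu]
        r = np.corrcoef(x, yp)[0, 1]
        if abs(r) >= abs(obs) - 1e-12:
            hits += 1
    p = hits / (permutations + 1)
    return MantelResult(obs, float(p), permutations)


# ---------------------------------------------------------------------------
# Geographic / environmental distances

def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km (WGS84 coordinates, spherical Earth)."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distances(records: Sequence[StrainRecord]) -> DistanceMatrix:
    """Strain-level great-circle distances between the strains' sites (km).

    Co-located strains get distance 0.
    """
    missing = [r.strain for r in records if r.lat is None]
    if missing:
        raise UndefinedStatistic(f"strains without coordinates: {missing}")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(
                records[i].lat, records[i].lon, records[j].lat, records[j].lon
            )
    return distance_matrix(d, [r.strain for r in records])


def env_distances(
    records: Sequence[StrainRecord], env: pd.DataFrame, variable: str
) -> DistanceMatrix:
    """|value_i - value_j| of a site environment variable, at strain level.

    ``env`` is indexed by site (or has a ``site`` column) and must cover
    every strain's site with a non-missing value of ``variable``.
    """
    if "site" in env.columns:
        env = env.set_index("site")
    if variable not in env.columns:
        raise UndefinedStatistic(f"variable {variable!r} not in environment table")
    vals = []
    for r in records:
        if r.site not in env.index or pd.isna(env.loc[r.site, variable]):
            raise UndefinedStatistic(f"no {variable!r} value for site {r.site!r}")
        vals.append(float(env.loc[r.site, variable]))
    v = np.asarray(vals)
    return distance_matrix(np.abs(v[:, None] - v[None, :]),
                           [r.strain for r in records])


def combined_env_distances(
    records: Sequence[StrainRecord], env: pd.DataFrame, variables: Sequence[str]
) -> DistanceMatrix:
    """Sum of |z-score differences| across several site variables.

    One defensible reading of a joint environment-distance matrix; per-
    variable Mantel tests remain the primary output.
    """
    if "site" in env.columns:
        env = env.set_index("site")
    total = None
    for var in variables:
        col = env[var].astype(float)
        mu, sd = col.mean(), col.std(ddof=0)
        if sd == 0:
            raise UndefinedStatistic(f"variable {var!r} has zero variance")
        z = (col - mu) / sd
        vals = np.asarray([float(z.loc[r.site]) for r in records])
        d = np.abs(vals[:, None] - vals[None, :])
        total = d if total is None else total + d
    return distance_matrix(total, [r.strain for r in records])


# ---------------------------------------------------------------------------
# Regressions

def distance_decay(
    genetic: DistanceMatrix, geographic: DistanceMatrix
) -> RegressionResult:
    """OLS of genetic on geographic distance over upper-triangle pairs."""
    if list(genetic.ids) != list(geographic.ids):
        geographic = geographic.filter(genetic.ids)
    n = genetic.shape[0]
    iu = np.triu_indices(n, k=1)
    x = geographic.data[iu]
    y = genetic.data[iu]
    if len(np.unique(np.round(x, 12))) < 3:
        raise UndefinedStatistic("fewer than 3 distinct geographic distances")
    fit = stats.linregress(x, y)
    return RegressionResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2),
        float(fit.stderr), float(fit.intercept_stderr),
    )


def end_member(mixing: pd.DataFrame, species: str = "species", mg: str = "mg"):
    """Extrapolate a species concentration to Mg = 0 (end-member composition).

    OLS fit of species ~ Mg over the mixing samples; returns
    ``(intercept, intercept_se)``.
    """
    x = mixing[mg].to_numpy(dtype=float)
    y = mixing[species].to_numpy(dtype=float)
    if len(x) < 2:
        raise UndefinedStatistic("need >= 2 mixing samples")
    if np.std(x) == 0:
        raise UndefinedStatistic("Mg has zero variance: degenerate design")
    fit = stats.linregress(x, y)
    se = fit.intercept_stderr if len(x) > 2 else 0.0
    return float(fit.intercept), float(se)
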