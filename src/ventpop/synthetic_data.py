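"""Synthetic two-region isolate collections with the structure the
downstream analysis assumes.

Sequences: each region carries one clonal Kingman genealogy (msprime) that
all loci share; loci evolve along it by single-nucleotide substitutions
(transition:transversion 2:1, no indels) under purifying selection
implemented as acceptance-rejection — a proposed nonsynonymous change is
accepted with probability ``omega_sim``, mutations to stop codons are
always rejected.  Region ancestors diverge from a common ancestral codon
sequence so that realized between-region divergence is about ``d_between``
substitutions/site, and realized within-region diversity about
``d_within``; attempted-mutation counts are scaled by the inverse of the
acceptance probability so the ``d`` parameters describe realized
distances.  Homologous recombination is whole-locus replacement: with
probability ``rho`` per strain and locus, the locus is swapped for another
same-region lineage's copy, which discords locus trees without breakpoint
machinery.

Spectra: every strain/replicate carries each universal peak (default m/z
9678), region-wide peaks shared by all strains of a region, and
strain-specific noise peaks, all with Gaussian m/z jitter, in triplicate,
with m/z in 2000-14000 and intensities in 2000-55000 counts.

A linear seawater/end-member mixing series generator supports the Mg = 0
extrapolation of fluid compositions.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .popgen import CODON_AA
from .seqio import LocusAlignment, PeakList, StrainRecord, write_locus_fasta, \
    write_metadata, write_peaks

__all__ = [
    "Site",
    "Region",
    "SpectrumParams",
    "SimulationConfig",
    "SyntheticTruth",
    "default_config",
    "simulate_sequences",
    "simulate_spectra",
    "simulate_mixing_series",
    "write_dataset",
]

_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_NONSTOP = np.asarray([i for i in range(64) if CODON_AA[i] != "*"])


@dataclasses.dataclass
class Site:
    name: str
    lat: float
    lon: float
    n_strains: int


@dataclasses.dataclass
class Region:
    name: str
    sites: list

    @property
    def n_strains(self) -> int:
        return sum(s.n_strains for s in self.sites)


@dataclasses.dataclass
class SpectrumParams:
    universal_mz: tuple = (9678.0,)
    n_region_peaks: int = 5
    n_noise_peaks: int = 3
    mz_jitter_sd: float = 3.0
    intensity_range: tuple = (2000.0, 55000.0)
    n_replicates: int = 3
    mz_range: tuple = (2000.0, 14000.0)


#: six coding loci with the study's fragment lengths, in typing column order
DEFAULT_LOCI = (
    ("atpA", 669),
    ("dnaK", 495),
    ("gyrB", 843),
    ("metG", 555),
    ("napA", 882),
    ("tkt", 810),
)


@dataclasses.dataclass
class SimulationConfig:
    loci: tuple = DEFAULT_LOCI
    regions: list = None
    d_between: float = 0.05
    d_within: float = 0.005
    omega_sim: float = 0.05
    rho: float = 0.1
    spectrum: SpectrumParams = dataclasses.field(default_factory=SpectrumParams)
    seed: int = 0

    def __post_init__(self):
        if self.regions is None:
            self.regions = _default_regions()
        self.loci = tuple((str(n), int(L)) for n, L in self.loci)
        if not self.loci:
            raise ConfigurationError("no loci configured")
        bad = [n for n, L in self.loci if L <= 0 or L % 3]
        if bad:
            raise ConfigurationError(f"locus lengths must be positive multiples of 3: {bad}")
        if not self.regions or sum(r.n_strains for r in self.regions) == 0:
            raise ConfigurationError("no strains configured")
        if not (0.0 <= self.omega_sim <= 1.0):
            raise ConfigurationError("omega_sim must be in [0, 1]")
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigurationError("rho must be in [0, 1]")
        if self.d_between < 0 or self.d_within < 0:
            raise ConfigurationError("divergence parameters must be >= 0")


def _default_regions() -> list:
    # Two regions ~2300 km apart; intra-region sites within ~50 km.
    # Coordinates are placeholders, not measured positions.
    return [
        Region("OT", [
            Site("iheya_north", 27.79, 126.90, 4),
            Site("hatoma_knoll", 27.55, 126.64, 1),
        ]),
        Region("SMT", [
            Site("urashima", 12.92, 143.65, 16),
            Site("snail", 12.95, 143.62, 3),
            Site("archaean", 12.94, 143.70, 10),
            Site("pika", 12.93, 143.66, 2),
        ]),
    ]


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default two-region study design (5 + 31 strains, six loci)."""
    return SimulationConfig(seed=seed, **overrides)


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a simulated collection."""

    region_of: dict
    site_of: dict
    site_coords: dict  # site -> (lat, lon)
    donors: dict  # locus -> {recipient strain -> donor strain}

    def records(self) -> list[StrainRecord]:
        return [
            StrainRecord(s, self.site_of[s], self.region_of[s],
                         self.site_coords[self.site_of[s]][0],
                         self.site_coords[self.site_of[s]][1])
            for s in self.region_of
        ]

    def to_json(self) -> str:
        return json.dumps(
            {"region_of": self.region_of, "site_of": self.site_of,
             "site_coords": {k: list(v) for k, v in self.site_coords.items()},
             "donors": self.donors},
            indent=2, sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Sequence machinery

def _random_root(rng: np.random.Generator, length: int) -> np.ndarray:
    codons = rng.choice(_NONSTOP, size=length // 3)
    bases = np.empty(length, dtype=np.int8)
    bases[0::3] = (codons >> 4) & 3
    bases[1::3] = (codons >> 2) & 3
    bases[2::3] = codons & 3
    return bases


def _codon_of(seq: np.ndarray, codon_i: int) -> int:
    o = 3 * codon_i
    return 16 * int(seq[o]) + 4 * int(seq[o + 1]) + int(seq[o + 2])


def _mutate(seq: np.ndarray, attempts: int, omega: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply ``attempts`` proposed substitutions with purifying rejection."""
    seq = seq.copy()
    L = seq.size
    for _ in range(attempts):
        pos = int(rng.integers(L))
        b = int(seq[pos])
        u = rng.random()
        if u < 0.5:
            new = b ^ 2  # transition: A<->G, C<->T
        else:
            tvs = [x for x in range(4) if (x & 1) != (b & 1)]
            new = tvs[0] if u < 0.75 else tvs[1]
        ci = pos // 3
        old_codon = _codon_of(seq, ci)
        seq[pos] = new
        new_codon = _codon_of(seq, ci)
        old_aa, new_aa = CODON_AA[old_codon], CODON_AA[new_codon]
        if new_aa == "*":
            seq[pos] = b  # never fix premature stops
        elif new_aa != old_aa and rng.random() >= omega:
            seq[pos] = b  # nonsynonymous change rejected
    return seq


def acceptance_probability(seq: np.ndarray, omega: float) -> float:
    """Expected acceptance probability of a proposed mutation on ``seq``.

    Averages over sites and the 2:1 transition:transversion proposal:
    synonymous -> 1, nonsynonymous -> omega, to a stop codon -> 0.
    """
    total = 0.0
    L = seq.size
    for pos in range(L):
        b = int(seq[pos])
        ci = pos // 3
        old_codon = _codon_of(seq, ci)
        old_aa = CODON_AA[old_codon]
        for new, w in [(b ^ 2, 0.5)] + [
            (x, 0.25) for x in range(4) if (x & 1) != (b & 1)
        ]:
            shift = 2 * (2 - pos % 3)
            new_codon = old_codon + ((new - b) << shift)
            new_aa = CODON_AA[new_codon]
            if new_aa == "*":
                continue
            total += w * (1.0 if new_aa == old_aa else omega)
    return total / L


def _region_genealogy(n: int, seed: int):
    """One clonal Kingman genealogy for a region (haploid, Ne = 1, so the
    expected pairwise path length is 2 coalescent time units)."""
    ts = msprime.sim_ancestry(
        samples=n, ploidy=1, population_size=1.0, random_seed=seed
    )
    return ts.first()


def simulate_sequences(config: SimulationConfig):
    """Simulate per-locus alignments; returns ``(alignments, truth)``.

    ``alignments`` maps locus name -> :class:`LocusAlignment` (gap-free,
    equal length); strain order is region order, then site order, then
    index.  Deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng([config.seed, 0])
    region_of, site_of, site_coords = {}, {}, {}
    region_strains: dict[str, list] = {}
    for region in config.regions:
        names = []
        k = 0
        for site in region.sites:
            site_coords[site.name] = (site.lat, site.lon)
            for _ in range(site.n_strains):
                k += 1
                name = f"{region.name}-{k}"
                names.append(name)
                region_of[name] = region.name
                site_of[name] = site.name
        region_strains[region.name] = names

    genealogies = {}
    for region in config.regions:
        n = region.n_strains
        if n > 1:
            genealogies[region.name] = _region_genealogy(
                n, int(rng.integers(1, 2**31 - 1))
            )

    alignments = {}
    donors_all: dict[str, dict] = {}
    all_strains = [s for r in config.regions for s in region_strains[r.name]]
    for locus, L in config.loci:
        root = _random_root(rng, L)
        p_acc = acceptance_probability(root, config.omega_sim)
        rate = 1.0 / max(p_acc, 1e-9)
        seqs: dict[str, np.ndarray] = {}
        for region in config.regions:
            anc = _mutate(
                root,
                int(rng.poisson(config.d_between * L * rate / 2.0)),
                config.omega_sim, rng,
            )
            names = region_strains[region.name]
            if len(names) == 1:
                seqs[names[0]] = _mutate(
                    anc,
                    int(rng.poisson(config.d_within * L * rate / 2.0)),
                    config.omega_sim, rng,
                )
                continue
            tree = genealogies[region.name]
            mu = config.d_within * rate / 2.0  # per site per coalescent unit
            node_seq = {}
            for u in tree.nodes(order="preorder"):
                parent = tree.parent(u)
                if parent == -1:
                    node_seq[u] = anc
                    continue
                attempts = int(rng.poisson(mu * tree.branch_length(u) * L))
                node_seq[u] = _mutate(node_seq[parent], attempts,
                                      config.omega_sim, rng)
            for i, name in enumerate(names):
                seqs[name] = node_seq[i]
        # whole-locus replacement within region
        donors: dict[str, str] = {}
        pre = {s: seqs[s] for s in seqs}
        for region in config.regions:
            names = region_strains[region.name]
            if len(names) < 2:
                continue
            for name in names:
                if rng.random() < config.rho:
                    others = [s for s in names if s != name]
                    donor = others[int(rng.integers(len(others)))]
                    seqs[name] = pre[donor]
                    donors[name] = donor
        donors_all[locus] = donors
        alignments[locus] = LocusAlignment(
            locus,
            tuple(all_strains),
            tuple(bytes(_IDX2BASE[seqs[s]]).decode("ascii") for s in all_strains),
        )
    truth = SyntheticTruth(region_of, site_of, site_coords, donors_all)
    return alignments, truth


# ---------------------------------------------------------------------------
# Spectra

def _draw_center(rng, taken: list, lo: float, hi: float, min_gap: float) -> float:
    for _ in range(10000):
        x = float(rng.uniform(lo, hi))
        if all(abs(x - t) >= min_gap for t in taken):
            return x
    raise ConfigurationError("could not place a peak center: m/z range too crowded")


def simulate_spectra(config: SimulationConfig, truth: SyntheticTruth):
    """Triplicate peak lists per strain: universal + region + noise peaks."""
    sp = config.spectrum
    rng = np.random.default_rng([config.seed, 1])
    lo_mz, hi_mz = sp.mz_range
    lo_i, hi_i = sp.intensity_range
    span = hi_i - lo_i
    margin = 10 * sp.mz_jitter_sd + 1.0
    draw_lo, draw_hi = lo_mz + 200.0, hi_mz - 200.0

    taken = list(sp.universal_mz)
    region_centers: dict[str, list] = {}
    for region in config.regions:
        centers = []
        for _ in range(sp.n_region_peaks):
            c = _draw_center(rng, taken, draw_lo, draw_hi, 50.0)
            centers.append(c)
            taken.append(c)
        region_centers[region.name] = centers
    noise_centers: dict[str, list] = {}
    for strain in truth.region_of:
        own = list(sp.universal_mz) + region_centers[truth.region_of[strain]]
        centers = []
        for _ in range(sp.n_noise_peaks):
            c = _draw_center(rng, own + centers, draw_lo, draw_hi, margin)
            centers.append(c)
        noise_centers[strain] = centers

    out = []
    for strain in truth.region_of:
        region = truth.region_of[strain]
        for rep in range(1, sp.n_replicates + 1):
            mzs, intens = [], []
            for c in sp.universal_mz:
                mzs.append(c + rng.normal(0, sp.mz_jitter_sd))
                intens.append(rng.uniform(lo_i + 0.6 * span, hi_i))
            for c in region_centers[region]:
                mzs.append(c + rng.normal(0, sp.mz_jitter_sd))
                intens.append(rng.uniform(lo_i + 0.2 * span, lo_i + 0.8 * span))
            for c in noise_centers[strain]:
                mzs.append(c + rng.normal(0, sp.mz_jitter_sd))
                intens.append(rng.uniform(lo_i, lo_i + 0.2 * span))
            mzs = np.clip(np.asarray(mzs), lo_mz + 1.0, hi_mz - 1.0)
            order = np.argsort(mzs)
            out.append(
                PeakList(strain, str(rep), mzs[order],
                         np.asarray(intens)[order])
            )
    return out


# ---------------------------------------------------------------------------
# Mixing series

def simulate_mixing_series(
    end_member_value: float,
    seawater_value: float,
    mg_seawater: float = 54.0,
    fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Linear seawater-admixture series: rows of (Mg, species) + noise.

    ``fractions`` are seawater fractions in [0, 1]; the end-member has
    Mg = 0, so extrapolating the species concentration to Mg = 0 recovers
    ``end_member_value`` (exactly, when ``noise_sd`` is 0).
    """
    fractions = list(fractions)
    if not fractions:
        raise ConfigurationError("empty fractions list")
    if any(f < 0 or f > 1 for f in fractions):
        raise ConfigurationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fractions:
        mg = f * mg_seawater
        species = f * seawater_value + (1.0 - f) * end_member_value
        if noise_sd > 0:
            species += rng.normal(0, noise_sd)
        rows.append({"mg": mg, "species": species})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Writers

def write_dataset(outdir, config: SimulationConfig, alignments, truth,
                  peaklists=None) -> None:
    """Write FASTA per locus, metadata TSV, peaks CSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for locus, _ in config.loci:
        write_locus_fasta(alignments[locus], outdir / f"{locus}.fasta")
    write_metadata(truth.records(), outdir / "metadata.tsv")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
    if peaklists is not None:
        write_peaks(peaklists, outdir / "peaks.csv")
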