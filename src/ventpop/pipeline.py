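"""End-to-end orchestration: simulate/load -> type -> popgen -> phylo ->
biogeo -> maldi -> genotype-phenotype concordance.

Each stage draws from its own RNG stream derived from the master seed and
the stage name, so any stage rerun in isolation reproduces its output.
Stage errors propagate annotated with the stage name.  The run report
records the seed, the software version, every headline number, and the
methodological deviations this toolkit makes from the upstream study's
software (NJ instead of ML trees; Hudson's pi-based F_ST; label
permutation as the F_ST significance device).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigurationError, NotComputable, UndefinedStatistic, VentpopError
from . import biogeo, maldi, mlsa_typing, phylo, popgen, seqio, synthetic_data

DEVIATION_NOTES = (
    "trees built by neighbor joining with bootstrap, not maximum likelihood",
    "F_ST is the Hudson (1992) pi-based estimator",
    "F_ST significance by label permutation (described upstream as "
    "'randomized bootstrap resamplings')",
)


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: synthetic_data.SimulationConfig | None = None
    input_dir: str | None = None
    locus_order: tuple | None = None
    basis: str = "eta"
    kaks_window: int = 90
    kaks_step: int = 18
    permutations: int = 1000
    bootstrap_reps: int = 100
    z_reps: int = 1000
    phi_window: int = 100
    replicate_tol: float = 5.0
    low_mz_cut: float = 2100.0
    top_n: int = 15
    bin_tol: float = 14.0
    with_maldi: bool = True

    def __post_init__(self):
        if self.simulate is None and self.input_dir is None:
            raise ConfigurationError("either 'simulate' or 'input_dir' must be set")
        if self.input_dir is not None and not Path(self.input_dir).is_dir():
            raise ConfigurationError(f"input_dir does not exist: {self.input_dir}")


@dataclasses.dataclass
class RunReport:
    seed: int
    version: str
    config: dict
    deviations: tuple
    results: dict
    tables: dict

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "version": self.version, "config": self.config,
             "deviations": list(self.deviations), "results": self.results},
            indent=2, sort_keys=True, default=str,
        )


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage RNG seed derived from the master seed."""
    rng = np.random.default_rng([int(master), zlib.crc32(stage.encode())])
    return int(rng.integers(0, 2**31 - 1))


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except VentpopError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
        return inner
    return wrap


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate is not None:
        sim = dataclasses.replace(
            cfg.simulate, seed=stage_seed(cfg.seed, "simulate")
        )
        alignments, truth = synthetic_data.simulate_sequences(sim)
        records = truth.records()
        peaks = synthetic_data.simulate_spectra(sim, truth) if cfg.with_maldi else None
        locus_order = tuple(n for n, _ in sim.loci)
        return alignments, records, peaks, locus_order
    indir = Path(cfg.input_dir)
    records = seqio.read_metadata(indir / "metadata.tsv")
    fastas = sorted(indir.glob("*.fasta"))
    if not fastas:
        raise ConfigurationError(f"no *.fasta loci found in {indir}")
    alignments = {f.stem: seqio.read_locus_fasta(f) for f in fastas}
    peaks = None
    if cfg.with_maldi:
        peaks_path = indir / "peaks.csv"
        if not peaks_path.exists():
            raise ConfigurationError(
                "with_maldi is set but input_dir has no peaks.csv"
            )
        peaks = seqio.read_peaks(peaks_path)
    locus_order = cfg.locus_order or tuple(sorted(alignments))
    return alignments, records, peaks, locus_order


def run_all(cfg: PipelineConfig) -> RunReport:
    """Execute every stage; returns the report (also written to ``outdir``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tables: dict = {}

    alignments, records, peaks, locus_order = _stage("load")(_load_inputs)(cfg)
    seqio.validate_dataset(alignments, records, peaks)
    region_of = {r.strain: r.region for r in records}
    regions = sorted(set(region_of.values()))

    # --- typing -----------------------------------------------------------
    def typing():
        allele_tables = {
            lc: mlsa_typing.assign_alleles(alignments[lc]) for lc in locus_order
        }
        sts = mlsa_typing.assign_sts(allele_tables, locus_order)
        tables["st_table"] = mlsa_typing.st_table(sts)
        tables["allele_summary"] = mlsa_typing.allele_summary(allele_tables)
        tables["allele_sharing"] = mlsa_typing.allele_sharing(
            allele_tables, region_of
        )
        results["n_strains"] = len(sts.sts)
        results["n_sts"] = sts.n_sts
        concat = mlsa_typing.concatenate_loci(alignments, locus_order)
        results["concatenated_length_bp"] = concat.length
        return concat

    concat = _stage("typing")(typing)()

    # --- per-locus population genetics ------------------------------------
    def popgen_stage():
        seed = stage_seed(cfg.seed, "popgen")
        rows = []
        for lc in locus_order:
            s = popgen.locus_summary(
                alignments[lc], window=cfg.kaks_window, step=cfg.kaks_step,
                z_reps=cfg.z_reps, seed=stage_seed(seed, lc),
            )
            rows.append(dataclasses.asdict(s))
        tables["popgen"] = pd.DataFrame(rows)
        counts = popgen.segregating_sites(concat)
        results["variable_positions"] = counts.S
        results["total_mutations_eta"] = counts.eta
        try:
            phi = popgen.phi_test(
                concat, window=cfg.phi_window, permutations=cfg.permutations,
                seed=stage_seed(seed, "phi"),
            )
            results["phi"] = phi.phi
            results["phi_p"] = phi.p
            results["phi_informative_sites"] = phi.n_informative
        except NotComputable as exc:
            results["phi_p"] = None
            results["phi_note"] = str(exc)

    _stage("popgen")(popgen_stage)()

    # --- phylogeny ---------------------------------------------------------
    def phylo_stage():
        tree, support = phylo.bootstrap_support(
            concat, model="jc69", reps=cfg.bootstrap_reps,
            seed=stage_seed(cfg.seed, "phylo"),
        )
        seqio.write_newick(tree, outdir / "concat_nj.nwk")
        if len(regions) == 2:
            leaves = frozenset(concat.ids)
            side = frozenset(s for s in concat.ids if region_of[s] == regions[0])
            results["regions_monophyletic"] = phylo.monophyly_check(tree, side)
            key = phylo._canonical(side, leaves)
            results["between_region_support_pct"] = support.get(key, 0.0)
        return tree

    tree = _stage("phylo")(phylo_stage)()

    # --- biogeography ------------------------------------------------------
    def biogeo_stage():
        seed = stage_seed(cfg.seed, "biogeo")
        pops: dict[str, list] = {}
        for r in records:
            pops.setdefault(r.region, []).append(r.strain)
        if len(regions) == 2 and all(len(v) >= 2 for v in pops.values()):
            fst = biogeo.pairwise_fst(
                concat, pops, regions[0], regions[1],
                permutations=cfg.permutations, seed=stage_seed(seed, "fst"),
            )
            results["fst_between_regions"] = fst.fst
            results["fst_p"] = fst.p
        site_pops: dict[str, list] = {}
        for r in records:
            site_pops.setdefault(r.site, []).append(r.strain)
        tables["fst_sites"] = biogeo.fst_matrix(
            concat, site_pops, permutations=cfg.permutations,
            seed=stage_seed(seed, "fst_sites"),
        )
        if all(r.lat is not None for r in records):
            dgen = phylo.genetic_distance(concat, model="p")
            dgeo = biogeo.geographic_distances(records)
            m = biogeo.mantel(dgen, dgeo, permutations=cfg.permutations,
                              seed=stage_seed(seed, "mantel"))
            results["mantel_r_genetic_geographic"] = m.r
            results["mantel_p_genetic_geographic"] = m.p
            try:
                reg = biogeo.distance_decay(dgen, dgeo)
                results["distance_decay_r2"] = reg.r_squared
                results["distance_decay_slope"] = reg.slope
            except UndefinedStatistic as exc:
                results["distance_decay_note"] = str(exc)
            seqio.write_distance_phylip(dgen, outdir / "genetic_p.dist")
            seqio.write_distance_phylip(dgeo, outdir / "geographic_km.dist")

    _stage("biogeo")(biogeo_stage)()

    # --- MALDI + concordance ----------------------------------------------
    if peaks is not None:
        def maldi_stage():
            fps, bm, dend = maldi.fingerprint_pipeline(
                peaks, mz_tol=cfg.replicate_tol, low_mz_cut=cfg.low_mz_cut,
                top_n=cfg.top_n, bin_tol=cfg.bin_tol,
            )
            tables["bin_matrix"] = pd.DataFrame(
                bm.matrix, index=list(bm.strains),
                columns=[f"{c:.1f}" for c in bm.centers],
            ).reset_index(names="strain")
            (outdir / "maldi_dendrogram.nwk").write_text(dend.to_newick() + "\n")
            results["n_peak_bins"] = len(bm.centers)
            cut = dend.cut(2)
            truth_part = {s: region_of[s] for s in bm.strains}
            from sklearn.metrics import adjusted_rand_score
            labels = sorted(cut)
            results["maldi_region_ari"] = float(adjusted_rand_score(
                [truth_part[s] for s in labels], [cut[s] for s in labels]
            ))
            results["genotype_phenotype_ari"] = phylo.concordance(tree, dend, k=2)

        _stage("maldi")(maldi_stage)()

    report = RunReport(
        seed=cfg.seed,
        version=__version__,
        config={k: str(v) for k, v in dataclasses.asdict(cfg).items()},
        deviations=DEVIATION_NOTES,
        results=results,
        tables=tables,
    )
    for name, df in tables.items():
        seqio.write_table(df, outdir / f"{name}.tsv")
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
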