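"""End-to-end pipeline: simulate → annotate → compare → screen.

Each stage reads and writes plain-text intermediates (FASTA, newick,
TSV/CSV) under one output directory and can be re-run on its own; the
final stage writes a machine-readable JSON summary with the headline
statistics of the incongruence analysis.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import markers, metabolomics, pangenome, signal, simulate, trees

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of the synthetic incongruence study.

    Simulation defaults encode the study regime: a slow marker (~20× below
    the core rate), fast accessory gain/loss, Brownian and white-noise
    metabolites, and a 5-replicate two-ion-mode LC-MS design.  Threshold
    defaults are the analysis constants: OTU cutoff 97% identity,
    core/rare prevalence 0.9/0.1, clustering cutoffs 0.75/0.75, FDR alpha
    0.05, signal alpha 0.01 with 1,000 randomizations, 100 bootstrap reps.
    """

    seed: int = 0
    # simulation
    n_taxa: int = 16
    birth_rate: float = 1.0
    tree_depth: float = 0.1
    marker_length: int = 1500
    marker_rate: float = 0.05
    marker_copies: int = 1
    core_length: int = 10000
    core_rate: float = 1.0
    core_size: int = 200
    accessory_pool: int = 100
    gain_rate: float = 1500.0
    loss_rate: float = 5.0
    n_bm_metabolites: int = 20
    n_noise_metabolites: int = 20
    bm_sigma2: float = 1.0
    n_replicates: int = 5
    missing_rate: float = 0.1
    control_level: float = 100.0
    feature_families: dict = field(default_factory=lambda: {
        "resistance": 20, "gcf": 40, "cazy": 60, "hallmark": 12,
    })
    # thresholds / analysis constants
    identity_thresholds: list = field(default_factory=lambda: [
        90.0, 92.0, 94.0, 95.0, 96.0, 97.0, 98.0, 98.5, 99.0, 99.5, 100.0,
    ])
    otu_cutoff: float = 97.0
    near_identical_cutoff: float = 99.0
    core_fraction: float = 0.9
    rare_fraction: float = 0.1
    cluster_identity: float = 0.75
    cluster_coverage: float = 0.75
    fdr_alpha: float = 0.05
    signal_alpha: float = 0.01
    n_randomizations: int = 1000
    bootstrap_reps: int = 100
    min_replicates: int = 3
    glog_lambda: float = 1.0
    max_missing_fraction: float = 0.5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_msa(msa, path):
    from .align import write_fasta
    write_fasta(msa, path)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the synthetic study and write all primary inputs."""
    outdir.mkdir(parents=True, exist_ok=True)
    pg = simulate.simulate_pangenome(
        n_taxa=cfg.n_taxa, seed=cfg.seed, depth=cfg.tree_depth,
        birth_rate=cfg.birth_rate, marker_length=cfg.marker_length,
        marker_rate=cfg.marker_rate, marker_copies=cfg.marker_copies,
        core_length=cfg.core_length, core_rate=cfg.core_rate,
        core_size=cfg.core_size, accessory_pool=cfg.accessory_pool,
        gain_rate=cfg.gain_rate, loss_rate=cfg.loss_rate,
    )
    trees.write_newick(pg.tree, outdir / "species_tree.nwk")
    _write_msa(pg.marker_msa, outdir / "marker_alignment.fasta")
    _write_msa(pg.core_msa, outdir / "core_alignment.fasta")
    pangenome.write_presence_absence(pg.pa, outdir / "presence_absence.tsv")
    pg.genome_length.to_csv(outdir / "genome_lengths.tsv", sep="\t",
                            index_label="strain")
    ss = np.random.SeedSequence([cfg.seed, 101]).spawn(len(cfg.feature_families) + 2)
    anns = []
    for k, (cat, n_fam) in enumerate(sorted(cfg.feature_families.items())):
        dist = 0.8 if cat == "hallmark" else "tied"  # hallmarks are broadly shared
        anns.append(simulate.assign_feature_families(
            pg.pa, cat, n_families=n_fam, prevalence_distribution=dist, seed=ss[k]))
    feat.write_feature_tsv(anns, outdir / "features.tsv")
    traits = simulate.simulate_traits(
        pg.tree, n_bm=cfg.n_bm_metabolites, n_noise=cfg.n_noise_metabolites,
        sigma2=cfg.bm_sigma2, seed=ss[-2])
    lcms = simulate.simulate_lcms(
        traits, n_replicates=cfg.n_replicates, missing_rate=cfg.missing_rate,
        control_level=cfg.control_level, seed=ss[-1])
    lcms.to_csv(outdir / "lcms.csv", index=False)
    pd.Series(traits.generator, name="generator").to_csv(
        outdir / "trait_generators.tsv", sep="\t", index_label="metabolite")
    return {"pangenome": pg, "traits": traits, "lcms": lcms, "annotations": anns}


def stage_markers(cfg: PipelineConfig, outdir: Path, pg=None) -> pd.DataFrame:
    """Pairwise marker identity with the length filter and best-copy rule."""
    if pg is None:
        copies = markers.read_marker_fasta(outdir / "marker_alignment.fasta")
    else:
        copies = pg.marker_copies
    kept = markers.filter_by_reference_length(
        copies, reference_length=cfg.marker_length, tolerance=0.2)
    ident = markers.pairwise_marker_identity(kept, aligner="auto")
    markers.write_identity_matrix(ident, outdir / "marker_identity.tsv")
    return ident


def stage_pangenome(cfg: PipelineConfig, outdir: Path, pg=None) -> dict:
    """Frequency spectrum and all-pairs ANI/content table."""
    if pg is None:
        raise ValueError("stage_pangenome needs the simulated pangenome in memory")
    p = pangenome.Pangenome(pa=pg.pa, sequences=pg.family_sequences,
                            genome_length=pg.genome_length)
    spectrum, n_core, n_rare = pangenome.family_frequency_spectrum(
        pg.pa, cfg.core_fraction, cfg.rare_fraction)
    spectrum.rename("n_families").to_csv(outdir / "family_spectrum.tsv", sep="\t")
    table = pangenome.ani_table(p)
    table.to_csv(outdir / "ani_table.tsv", sep="\t", index=False)
    return {"spectrum": spectrum, "n_core": n_core, "n_rare": n_rare,
            "ani_table": table, "pangenome_obj": p}


def stage_trees(cfg: PipelineConfig, outdir: Path, pg) -> dict:
    """Marker, core, and composition trees with bootstrap supports; RF table."""
    built = {}
    seeds = np.random.SeedSequence([cfg.seed, 202]).spawn(3)
    built["marker"] = trees.bootstrap_support(
        pg.marker_msa, method="nj", n_reps=cfg.bootstrap_reps, seed=seeds[0])
    built["core"] = trees.bootstrap_support(
        pg.core_msa, method="nj", n_reps=cfg.bootstrap_reps, seed=seeds[1])
    built["composition"] = trees.bootstrap_support(
        pg.pa, method="upgma", n_reps=cfg.bootstrap_reps, seed=seeds[2])
    for tag, t in built.items():
        trees.write_newick(t, outdir / f"tree_{tag}.nwk")
    div = trees.scaled_patristic(built["core"])
    div.to_csv(outdir / "core_divergence.tsv", sep="\t", index_label="strain")
    rows = []
    tags = list(built) + ["generating"]
    all_trees = dict(built, generating=pg.tree)
    import itertools
    for a, b in itertools.combinations(tags, 2):
        rows.append((a, b, trees.rf_distance(all_trees[a], all_trees[b])))
    rf = pd.DataFrame(rows, columns=["tree_a", "tree_b", "rf"])
    rf.to_csv(outdir / "rf_distances.tsv", sep="\t", index=False)
    return {"trees": built, "rf": rf, "divergence": div}


def stage_features(cfg: PipelineConfig, outdir: Path, identity: pd.DataFrame,
                   annotations) -> dict:
    """Overlap curves and spectra per feature category (and per flag series)."""
    curves = {}
    spectra = {}
    for ann in annotations:
        series = [("all", ann)]
        if ann.flags:
            series += [(fl, ann.subset_by_flag(fl)) for fl in sorted(set(ann.flags.values()))]
        for label, sub in series:
            curve = feat.overlap_curve(identity, sub, cfg.identity_thresholds)
            curve.to_csv(outdir / f"overlap_{ann.category}_{label}.tsv",
                         sep="\t", index=False)
            curves[(ann.category, label)] = curve
        hist, prev = feat.feature_spectra(ann)
        hist.rename("n_features").to_csv(
            outdir / f"spectrum_{ann.category}.tsv", sep="\t")
        prev.to_csv(outdir / f"prevalence_{ann.category}.tsv", sep="\t",
                    index_label="feature")
        spectra[ann.category] = (hist, prev)
    return {"curves": curves, "spectra": spectra}


def stage_metabolomics(cfg: PipelineConfig, outdir: Path, lcms: pd.DataFrame) -> dict:
    """Replicate filter → impute → glog/autoscale → ANOVA+FDR."""
    raw = metabolomics.build_trait_matrix(
        lcms, min_replicates=cfg.min_replicates, total_replicates=cfg.n_replicates)
    metabolomics.write_trait_matrix(raw, outdir / "traits_raw.tsv")
    imputed = metabolomics.impute_and_filter_missing(raw, cfg.max_missing_fraction)
    metabolomics.write_trait_matrix(imputed, outdir / "traits_imputed.tsv")
    scaled = metabolomics.glog_autoscale(imputed, cfg.glog_lambda)
    metabolomics.write_trait_matrix(scaled, outdir / "traits_autoscaled.tsv")
    rep_matrix, groups = metabolomics.build_replicate_matrix(
        lcms, min_replicates=cfg.min_replicates, total_replicates=cfg.n_replicates)
    rep_imputed = metabolomics.impute_and_filter_missing(rep_matrix,
                                                         cfg.max_missing_fraction)
    rep_scaled = metabolomics.glog_autoscale(rep_imputed, cfg.glog_lambda)
    anova = metabolomics.anova_fdr(rep_scaled, groups, alpha=cfg.fdr_alpha)
    anova.to_csv(outdir / "anova_fdr.tsv", sep="\t", index=False)
    order = metabolomics.ward_cluster_order(scaled)
    pd.Series(order["row_order"], name="strain").to_csv(
        outdir / "heatmap_row_order.tsv", sep="\t", index_label="position")
    return {"raw": raw, "autoscaled": scaled, "anova": anova, "order": order}


def stage_signal(cfg: PipelineConfig, outdir: Path, scaled, built_trees) -> dict:
    """Blomberg's K screen of every metabolite against every tree."""
    screen = signal.signal_screen(
        scaled.values, built_trees, n_randomizations=cfg.n_randomizations,
        seed=cfg.seed, alpha=cfg.signal_alpha)
    screen.to_csv(outdir / "k_screen.tsv", sep="\t", index=False)
    incong = signal.incongruent_metabolites(screen, alpha=cfg.signal_alpha)
    incong.to_csv(outdir / "k_incongruent.tsv", sep="\t", index_label="metabolite")
    return {"screen": screen, "incongruent": incong}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run all stages and write summary.json; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("stage simulate: seed=%d n_taxa=%d", cfg.seed, cfg.n_taxa)
    sim = stage_simulate(cfg, outdir)
    pg = sim["pangenome"]
    logger.info("stage markers")
    ident = stage_markers(cfg, outdir, pg)
    logger.info("stage pangenome")
    pan = stage_pangenome(cfg, outdir, pg)
    logger.info("stage trees")
    tr = stage_trees(cfg, outdir, pg)
    logger.info("stage features")
    stage_features(cfg, outdir, ident, sim["annotations"])
    logger.info("stage metabolomics")
    met = stage_metabolomics(cfg, outdir, sim["lcms"])
    logger.info("stage signal")
    sig = stage_signal(cfg, outdir, met["autoscaled"], tr["trees"])

    ani = pan["ani_table"]
    pair_ident = np.array(
        [ident.loc[a, b] for a, b in zip(ani["strain_a"], ani["strain_b"])])
    def _ani_range(cut):
        vals = ani["ani"][pair_ident >= cut]
        return (float(vals.max() - vals.min()), int(len(vals))) if len(vals) else (None, 0)
    range99, n99 = _ani_range(cfg.near_identical_cutoff)
    range97, n97 = _ani_range(cfg.otu_cutoff)
    rf = {(r.tree_a, r.tree_b): int(r.rf) for r in tr["rf"].itertuples()}
    screen = sig["screen"]
    sig_col = screen.columns[-1]
    summary = {
        "config": cfg.to_dict(),
        "n_strains": int(pg.pa.shape[0]),
        "n_gene_families": int(pg.pa.shape[1]),
        "n_core_families": pan["n_core"],
        "n_rare_families": pan["n_rare"],
        "fraction_rare": round(pan["n_rare"] / pg.pa.shape[1], 4),
        "mean_ani": round(float(ani["ani"].mean()), 4),
        "min_ani": round(float(ani["ani"].min()), 4),
        "conditional_ani_range_near_identical_marker": {
            "cutoff": cfg.near_identical_cutoff, "n_pairs": n99,
            "range_pct": None if range99 is None else round(range99, 4)},
        "conditional_ani_range_otu": {
            "cutoff": cfg.otu_cutoff, "n_pairs": n97,
            "range_pct": None if range97 is None else round(range97, 4)},
        "rf_marker_vs_composition": rf[("marker", "composition")],
        "rf_core_vs_generating": rf[("core", "generating")],
        "rf_marker_vs_core": rf[("marker", "core")],
        "n_metabolites_tested": int(met["anova"].shape[0]),
        "n_differential_metabolites": int(met["anova"]["significant"].sum()),
        "n_signal_significant_calls": int(screen[sig_col].sum()),
        "n_incongruent_metabolites": int(sig["incongruent"].shape[0]),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
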