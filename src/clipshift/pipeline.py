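"""End-to-end orchestration: synthetic bundle (or files on disk) through
peak calling, expression quantification, shift tests, ΔTE enrichment,
coverage tests, and time-course cluster enrichment, with a JSON manifest
recording the effective config, per-stage seeds, outputs, and checksums.

The in-memory entry point is :func:`analyze_bundle`; :func:`run_pipeline`
wraps it with file I/O, stage skipping, and the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import coverage as cov
from . import expression as ex
from . import peaks as pk
from . import shift as sh
from . import simulate as sim
from . import translation as tr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "analyze_bundle", "run_pipeline",
           "stage_seed"]

# stage offsets for deriving per-stage seeds from the global seed
_STAGE_OFFSETS = {"peaks": 11, "enrichment": 13, "clusters": 17, "kmers": 19}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed; independent of which other stages run."""
    ss = np.random.SeedSequence([int(global_seed), _STAGE_OFFSETS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Every tunable of the analysis, serializable to YAML."""

    seed: int = 0
    outdir: str = "clipshift_out"

    # peak calling / robust sites
    peak_fdr: float = 0.01
    n_perm_peaks: int = 100
    min_ph: int = 5
    min_replicates: int = 3
    min_antisera: int = 2
    merge_mode: str = "per_replicate"
    top_fraction: float = 0.20
    stratify_scope: str = "per_region"

    # expression
    min_rpkm: float = 3.0
    min_cpm: float = 1.0
    min_cpm_replicates: int = 2
    pseudocount: float = 0.5
    normalization: str = "median_of_ratios"

    # shift / annotation
    annotation_mode: str = "non_exclusive"
    tiers: str = "all,top"
    cits_stringent: bool = False
    cits_alpha: float = 0.05

    # enrichment
    weight_p: float = 1.0
    n_perm_enrichment: int = 1000

    # coverage
    coverage_window: int = 20
    metagene_min_reads: int = 10
    metagene_anchor: str = "both"

    # clusters
    k_clusters: int = 20
    kmeans_n_init: int = 10

    # stage toggles
    stages: tuple = ("peaks", "expression", "shift", "translation",
                     "coverage", "clusters")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass
class AnalysisResult:
    robust_sites: list = field(default_factory=list)
    assignments: dict = field(default_factory=dict)
    filter_table: pd.DataFrame | None = None
    log2fc_rna: pd.Series | None = None
    log2fc_rp: pd.Series | None = None
    dte: pd.Series | None = None
    shift_results: list = field(default_factory=list)
    enrichment_results: list = field(default_factory=list)
    coverage_tests: pd.DataFrame | None = None
    coverage_correlation: pd.Series | None = None
    metagene: dict = field(default_factory=dict)
    cluster_assignments: pd.Series | None = None
    cluster_enrichments: list = field(default_factory=list)
    cits: list = field(default_factory=list)

    def shift_by_class(self) -> dict:
        return {r.class_label: r for r in self.shift_results}

    def enrichment_by_set(self) -> dict:
        return {r.gene_set: r for r in self.enrichment_results}


def _call_all_peaks(bundle: sim.Bundle, cfg: PipelineConfig) -> list:
    """Per-replicate peak calling over every gene with tags."""
    seed0 = stage_seed(cfg.seed, "peaks")
    all_peaks = []
    for ri, (rep, tags) in enumerate(sorted(bundle.clip_tags.items())):
        by_gene = pk.assign_tags_to_genes(tags, bundle.gene_models)
        for gi, gid in enumerate(sorted(by_gene)):
            all_peaks.extend(
                pk.call_peaks(
                    by_gene[gid],
                    bundle.gene_models[gid],
                    alpha=cfg.peak_fdr,
                    n_perm=cfg.n_perm_peaks,
                    seed=(seed0 + 1_000_003 * ri + gi) % (2**31),
                )
            )
    return all_peaks


def analyze_bundle(bundle: sim.Bundle, cfg: PipelineConfig | None = None) -> AnalysisResult:
    """Run the full analysis on an in-memory bundle."""
    cfg = cfg or PipelineConfig()
    res = AnalysisResult()

    # --- peaks -> robust sites -> region annotation -> PH tiers
    if "peaks" in cfg.stages:
        peaks = _call_all_peaks(bundle, cfg)
        sites = pk.define_robust_sites(
            peaks,
            min_ph=cfg.min_ph,
            min_replicates=cfg.min_replicates,
            min_antisera=cfg.min_antisera,
            merge_mode=cfg.merge_mode,
        )
        sites = pk.annotate_sites(sites, bundle.gene_models, cfg.annotation_mode)
        if len(sites) >= 5:
            sites = pk.stratify_by_ph(sites, cfg.top_fraction, cfg.stratify_scope)
        res.robust_sites = sites
        if cfg.cits_stringent:
            pooled = [t for tags in bundle.clip_tags.values() for t in tags]
            peak_like = sites
            res.cits = pk.call_cits(pooled, peak_like, alpha=cfg.cits_alpha)

    # --- expression
    # Size factors come from genes without a robust binding site (when the
    # peaks stage ran): one-directional regulation of the bound targets
    # would otherwise bias a global median-of-ratios toward them.
    if "expression" in cfg.stages:
        res.filter_table = ex.filter_genes(
            bundle.rna, bundle.riboprof,
            min_rpkm=cfg.min_rpkm, min_cpm=cfg.min_cpm,
            min_cpm_replicates=cfg.min_cpm_replicates,
        )
        reference = None
        if res.robust_sites:
            bound = {s.gene_id for s in res.robust_sites}
            reference = [g for g in bundle.rna.counts.index if g not in bound]
        res.log2fc_rna = ex.estimate_log2fc(
            bundle.rna, cfg.pseudocount, cfg.normalization, reference
        )
        res.log2fc_rp = ex.estimate_log2fc(
            bundle.riboprof, cfg.pseudocount, cfg.normalization, reference
        )
        logger.info(
            "expression: %d/%d genes pass the joint filter",
            int(res.filter_table["passes"].sum()), len(res.filter_table),
        )

    # --- target classification + CDF shift tests
    if "shift" in cfg.stages and res.log2fc_rna is not None:
        res.assignments = sh.classify_targets(
            res.robust_sites, bundle.gene_models, cfg.annotation_mode,
            cits_sites=res.cits if cfg.cits_stringent else None,
        )
        res.shift_results = sh.run_shift_analysis(
            res.assignments,
            res.log2fc_rna,
            passes=res.filter_table["passes"],
            tiers=cfg.tiers,
        )

    # --- ΔTE + pre-ranked enrichment
    # Each target set is ranked against the no-binding background only
    # (set ∪ background universe), so one class's signal cannot masquerade
    # as another class's depletion.
    if "translation" in cfg.stages and res.log2fc_rna is not None:
        res.dte = tr.compute_dte(res.log2fc_rna, res.log2fc_rp)
        passing = set(res.filter_table.index[res.filter_table["passes"]])
        dte = res.dte.loc[sorted(set(res.dte.index) & passing)]
        background = {g for g in dte.index if g not in res.assignments}
        gene_sets = {}
        for region in ("UTR3", "CDS", "intron"):
            members = {
                g for g, a in res.assignments.items()
                if region in a.classes and g in dte.index
            }
            if members:
                gene_sets[region] = members
            if region == "UTR3":
                top = {g for g in members
                       if res.assignments[g].tiers.get("UTR3") == "top"}
                if top:
                    gene_sets["UTR3_top"] = top
        seed = stage_seed(cfg.seed, "enrichment")
        for name, members in gene_sets.items():
            universe = sorted(members | background)
            if not 0 < len(members) < len(universe):
                continue
            ranked = tr.rank_genes(dte.loc[universe])
            res.enrichment_results.extend(
                tr.preranked_enrichment(
                    ranked, {name: members},
                    weight_p=cfg.weight_p,
                    n_perm=cfg.n_perm_enrichment,
                    seed=seed,
                )
            )

    # --- coverage
    if "coverage" in cfg.stages and bundle.coverage.get("WT"):
        res.coverage_tests = cov.binomial_test_all(
            bundle.coverage["KO"], bundle.coverage["WT"]
        )
        corr = {}
        for g in sorted(set(bundle.coverage["WT"]) & set(bundle.coverage["KO"])):
            wp = cov.window_coverage(bundle.coverage["WT"][g], cfg.coverage_window)
            kp = cov.window_coverage(bundle.coverage["KO"][g], cfg.coverage_window)
            if len(wp.values) > 2 and wp.values.std() > 0 and kp.values.std() > 0:
                corr[g] = float(np.corrcoef(wp.values, kp.values)[0, 1])
        res.coverage_correlation = pd.Series(corr, name="wt_ko_window_corr")
        for geno in ("WT", "KO"):
            res.metagene[geno] = cov.metagene(
                bundle.coverage[geno], bundle.cds_bounds,
                min_reads=cfg.metagene_min_reads, anchor=cfg.metagene_anchor,
            )

    # --- time-course clusters
    if "clusters" in cfg.stages and bundle.timecourse is not None:
        k = min(cfg.k_clusters, len(bundle.timecourse))
        res.cluster_assignments = cl.kmeans_timecourse(
            bundle.timecourse, k=k, n_init=cfg.kmeans_n_init,
            seed=stage_seed(cfg.seed, "clusters"),
        )
        targets = {
            g for g, a in res.assignments.items()
            if a.classes & {"UTR3", "CDS"}
        }
        if targets:
            res.cluster_enrichments = cl.fisher_cluster_enrichment(
                res.cluster_assignments, targets
            )
    return res


# ---------------------------------------------------------------------------
# file-based orchestration


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_outputs(res: AnalysisResult, outdir: str) -> dict[str, str]:
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    if res.robust_sites:
        rows = [
            {
                "site_id": s.site_id, "gene_id": s.gene_id,
                "chrom": s.interval.chrom, "start": s.interval.start,
                "end": s.interval.end, "strand": s.interval.strand,
                "ph": s.ph, "n_tags": s.n_tags,
                "n_replicates": len(s.support_replicates),
                "n_antisera": len(s.support_antisera),
                "tier": s.tier or "",
                "regions": ";".join(sorted(s.regions)),
            }
            for s in res.robust_sites
        ]
        pd.DataFrame(rows).to_csv(p("robust_sites.tsv"), sep="\t", index=False)
    if res.filter_table is not None:
        res.filter_table.to_csv(p("expression_filter.tsv"), sep="\t",
                                index_label="gene_id")
        fc = pd.DataFrame({"log2fc_rna": res.log2fc_rna,
                           "log2fc_rp": res.log2fc_rp})
        if res.dte is not None:
            fc["dte"] = res.dte
        fc.to_csv(p("fold_changes.tsv"), sep="\t", index_label="gene_id")
    if res.shift_results:
        pd.DataFrame(
            [
                {
                    "class": r.class_label, "n_class": r.n_class,
                    "n_background": r.n_background, "D": r.D,
                    "p_value": r.p_value, "q_value": r.q_value,
                    "median_shift": r.median_shift, "low_power": r.low_power,
                }
                for r in res.shift_results
            ]
        ).to_csv(p("shift_results.tsv"), sep="\t", index=False)
        for r in res.shift_results:
            if r.cdf_table is not None:
                r.cdf_table.to_csv(
                    p(f"cdf_{r.class_label}.tsv"), sep="\t", index=False
                )
    if res.enrichment_results:
        pd.DataFrame(
            [
                {
                    "gene_set": r.gene_set, "ES": r.es, "NES": r.nes,
                    "p_perm": r.p_perm, "FDR": r.fdr,
                    "n_permutations": r.n_permutations, "seed": r.seed,
                    "leading_edge": ";".join(r.leading_edge),
                }
                for r in res.enrichment_results
            ]
        ).to_csv(p("te_enrichment.tsv"), sep="\t", index=False)
    if res.coverage_tests is not None:
        res.coverage_tests.to_csv(p("coverage_binomial.tsv"), sep="\t")
        for geno, mg in res.metagene.items():
            mg.to_csv(p(f"metagene_{geno}.tsv"), sep="\t", index=False)
    if res.cluster_assignments is not None:
        res.cluster_assignments.to_frame().to_csv(
            p("cluster_assignments.tsv"), sep="\t", index_label="gene_id"
        )
        if res.cluster_enrichments:
            pd.DataFrame(
                [dataclasses.asdict(e) for e in res.cluster_enrichments]
            ).to_csv(p("cluster_enrichment.tsv"), sep="\t", index=False)
    return paths


def run_pipeline(
    cfg: PipelineConfig,
    sim_config: "sim.SimulationConfig | None" = None,
    force: bool = False,
) -> dict:
    """Run all enabled stages on a synthetic bundle and write a manifest.

    Outputs already present under ``cfg.outdir`` (tracked in a previous
    manifest with matching config) are not recomputed unless ``force``.
    Returns the manifest dict.
    """
    os.makedirs(cfg.outdir, exist_ok=True)
    manifest_path = os.path.join(cfg.outdir, "manifest.json")
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["stages"] = list(cfg_dict["stages"])

    prev = None
    if not force and os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            prev = json.load(fh)
        if prev.get("config") != cfg_dict:
            prev = None
    if prev is not None:
        missing = [n for n, pth in prev["outputs"].items() if not os.path.exists(pth)]
        if not missing:
            logger.info("all outputs present; nothing to recompute")
            return prev
        logger.info("recomputing; missing outputs: %s", missing)

    if sim_config is None:
        sim_config = sim.SimulationConfig(seed=cfg.seed)
    bundle = sim.simulate_dataset(sim_config)
    input_paths = sim.write_fixture(bundle, os.path.join(cfg.outdir, "inputs"))
    res = analyze_bundle(bundle, cfg)
    out_paths = _write_outputs(res, cfg.outdir)

    manifest = {
        "config": cfg_dict,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_OFFSETS},
        "inputs": {n: p for n, p in input_paths.items()},
        "outputs": out_paths,
        "checksums": {n: _sha256(p) for n, p in
                      list(input_paths.items()) + list(out_paths.items())},
        "row_counts": {
            "robust_sites": len(res.robust_sites),
            "genes_passing_filter": (
                int(res.filter_table["passes"].sum())
                if res.filter_table is not None else 0
            ),
            "target_genes": len(res.assignments),
        },
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
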