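"""Synthetic data generator for the whole pipeline.

Emulates the statistical structure of a CLIP + RNAseq + ribosome-profiling
study of an AU-rich-element binding protein knockout:

* gene models with 5'UTR/CDS/3'UTR/intron structure on a toy genome;
* CLIP tags concentrated at planted AU-rich sites (per-replicate Poisson
  intensity with multiplicative jitter, truncation positions at the site
  center) over a uniform genic background;
* negative-binomial RNAseq and ribosome-profiling counts with
  class/tier-specific genotype effects on abundance (δ_abund) and
  translation efficiency (δ_TE), oriented KO/WT in log2 units;
* per-transcript footprint coverage sharing a shape vector between
  genotypes with magnitude scaled by 2^δ_TE;
* a clustered activation time course in which binding targets concentrate
  in rapidly-induced patterns.

Effect sizes are free parameters of the generator (the study they emulate
reports CDF curves and p-values, not effect magnitudes); the defaults
plant a weaker abundance effect than translation effect, a larger
translation effect for CDS than 3'UTR binding, a null intron class, and a
top-PH-tier 3'UTR class with no abundance effect but a retained
translation effect.

Identical seeds give identical outputs; each output artifact draws from
its own seeded stream so enabling one never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .coverage import TranscriptCoverage
from .expression import CountMatrix
from .peaks import ClipTag
from .annotation import GenomicInterval

__all__ = ["SimulationConfig", "Bundle", "simulate_dataset", "write_fixture",
           "read_tags_bed", "read_count_matrix"]

# per-artifact RNG stream offsets (spawned as default_rng([seed, offset]))
_STREAMS = {
    "genes": 1,
    "clip": 2,
    "rna": 3,
    "riboprof": 4,
    "coverage": 5,
    "timecourse": 6,
    "sequence": 7,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_genes: int = 1000

    # target plan: counts per binding class, and top-tier fraction within
    n_utr3_targets: int = 150
    n_cds_targets: int = 80
    n_intron_targets: int = 60
    top_tier_fraction: float = 0.20

    # CLIP design
    n_clip_replicates: int = 5
    antiserum_of_replicate: dict = field(
        default_factory=lambda: {"r1": "A", "r2": "A", "r3": "A",
                                 "r4": "B", "r5": "B"}
    )
    lambda_site: float = 12.0       # expected tags/site/replicate, bulk tier
    lambda_site_top: float = 30.0   # top tier
    lambda_bg_per_kb: float = 0.2   # background tags per kb per replicate
    tag_length: int = 35
    replicate_jitter_sd: float = 0.2  # lognormal sigma on per-replicate rate

    # effect sizes in log2 units, keyed (class, tier)
    delta_abund: dict = field(
        default_factory=lambda: {
            ("UTR3", "bulk"): 0.2, ("UTR3", "top"): 0.0,
            ("CDS", "bulk"): 0.2, ("CDS", "top"): 0.2,
            ("intron", "bulk"): 0.0, ("intron", "top"): 0.0,
        }
    )
    delta_te: dict = field(
        default_factory=lambda: {
            ("UTR3", "bulk"): 0.3, ("UTR3", "top"): 0.3,
            ("CDS", "bulk"): 0.5, ("CDS", "top"): 0.5,
            ("intron", "bulk"): 0.0, ("intron", "top"): 0.0,
        }
    )

    # count model
    n_replicates_per_genotype: int = 4
    depth: float = 1e6
    dispersion: float = 0.05          # NB variance = mu + phi * mu^2
    expression_lognorm_sd: float = 1.0

    # coverage model
    coverage_mean_reads: float = 2000.0
    coverage_read_sd: float = 0.5     # lognormal sigma on per-gene read rate

    # time course
    timepoints: tuple = (0, 1, 2, 4, 8, 16, 24, 48)
    n_archetypes: int = 6
    target_induced_prob: float = 0.6  # P(target gene gets the rapid pattern)
    timecourse_noise_sd: float = 0.3

    # site sequence
    motif: str = "UAUUUAUU"
    window_nt: int = 30

    # gene geometry
    downstream_ext: int = 10_000

    def __post_init__(self) -> None:
        n_targets = self.n_utr3_targets + self.n_cds_targets + self.n_intron_targets
        if n_targets > self.n_genes:
            raise ValueError(
                f"target plan ({n_targets}) exceeds n_genes ({self.n_genes})"
            )
        for name in ("lambda_site", "lambda_site_top", "lambda_bg_per_kb",
                     "depth", "coverage_mean_reads"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 <= self.top_tier_fraction <= 1:
            raise ValueError("top_tier_fraction must be in [0, 1]")


@dataclass
class Bundle:
    config: SimulationConfig
    gene_models: dict[str, GeneModel]
    clip_tags: dict[str, list[ClipTag]]  # replicate_id -> tags
    rna: CountMatrix
    riboprof: CountMatrix
    coverage: dict[str, dict[str, TranscriptCoverage]]  # genotype -> gene
    cds_bounds: dict[str, tuple[int, int]]  # transcript coords
    timecourse: pd.DataFrame
    truth: pd.DataFrame
    site_windows: list[str]


def _rng(cfg: SimulationConfig, artifact: str) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAMS[artifact]])


def _nb(rng, mu, phi, size=None):
    """NB draws with mean mu and variance mu + phi mu^2."""
    mu = np.asarray(mu, float)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p, size=size if size is not None else mu.shape)


def _make_genes(cfg: SimulationConfig, rng) -> tuple[dict[str, GeneModel], pd.DataFrame]:
    """Lay out genes with UTR/CDS/intron structure; plan targets and sites."""
    n = cfg.n_genes
    classes = (
        ["UTR3"] * cfg.n_utr3_targets
        + ["CDS"] * cfg.n_cds_targets
        + ["intron"] * cfg.n_intron_targets
        + ["none"] * (n - cfg.n_utr3_targets - cfg.n_cds_targets - cfg.n_intron_targets)
    )
    rng.shuffle(classes)
    tiers = []
    for cls in classes:
        if cls == "none":
            tiers.append("")
        else:
            tiers.append("top" if rng.random() < cfg.top_tier_fraction else "bulk")

    models: dict[str, GeneModel] = {}
    rows = []
    cursor = {}
    for i in range(n):
        gid = f"g{i:04d}"
        chrom = f"chr{i % 4 + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(100, 300))
        cds = int(rng.integers(900, 1500))
        utr3 = int(rng.integers(400, 800))
        intron_len = int(rng.integers(500, 2000))
        start = cursor.get(chrom, 12_000)
        # two exons with the break inside the CDS; on the minus strand the
        # genomic-left exonic block is the 3'UTR
        exonic = utr5 + cds + utr3
        cds_left = utr5 if strand == "+" else utr3
        break_at = cds_left + cds // 2
        exons = [
            (start, start + break_at),
            (start + break_at + intron_len, start + exonic + intron_len),
        ]
        cds_span = (start + cds_left, start + cds_left + cds + intron_len)
        gm = GeneModel.from_exons(gid, chrom, strand, exons, cds_span,
                                  cfg.downstream_ext)
        models[gid] = gm
        cursor[chrom] = gm.span.end + cfg.downstream_ext + 2000

        cls, tier = classes[i], tiers[i]
        site_start = -1
        if cls != "none":
            region = {"UTR3": gm.utr3, "CDS": gm.cds, "intron": gm.introns}[cls]
            reg = max(region, key=lambda r: r.length)
            center = (reg.start + reg.end) // 2
            site_start = center
        lam = (
            0.0 if cls == "none"
            else cfg.lambda_site_top if tier == "top"
            else cfg.lambda_site
        )
        rows.append(
            {
                "gene_id": gid,
                "target_class": cls,
                "tier": tier,
                "site_center": site_start,
                "lambda_site": lam,
                "delta_abund": cfg.delta_abund.get((cls, tier), 0.0),
                "delta_te": cfg.delta_te.get((cls, tier), 0.0),
            }
        )
    return models, pd.DataFrame(rows).set_index("gene_id")


def _make_clip_tags(cfg, models, truth, rng) -> dict[str, list[ClipTag]]:
    tags: dict[str, list[ClipTag]] = {r: [] for r in cfg.antiserum_of_replicate}
    for rep, serum in cfg.antiserum_of_replicate.items():
        jitter = float(np.exp(rng.normal(0.0, cfg.replicate_jitter_sd)))
        for gid, row in truth.iterrows():
            gm = models[gid]
            span = gm.span
            # planted site tags: truncation (5' end) at the site center
            if row["target_class"] != "none":
                k = rng.poisson(row["lambda_site"] * jitter)
                centers = int(row["site_center"]) + np.round(
                    rng.normal(0, 2.0, size=k)
                ).astype(int)
                for c in centers:
                    c = int(np.clip(c, span.start + cfg.tag_length,
                                    span.end - cfg.tag_length - 1))
                    if gm.strand == "+":
                        iv = GenomicInterval(gm.chrom, c, c + cfg.tag_length, "+")
                    else:
                        iv = GenomicInterval(
                            gm.chrom, c - cfg.tag_length + 1, c + 1, "-"
                        )
                    tags[rep].append(ClipTag(iv, rep, serum))
            # uniform background over the extended span
            n_bg = rng.poisson(cfg.lambda_bg_per_kb * span.length / 1000.0)
            starts = rng.integers(span.start, span.end - cfg.tag_length, size=n_bg)
            for s in starts:
                iv = GenomicInterval(gm.chrom, int(s), int(s) + cfg.tag_length,
                                     gm.strand)
                tags[rep].append(ClipTag(iv, rep, serum))
    return tags


def _make_counts(cfg, truth, assay: str, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(truth)
    w = np.exp(rng.normal(0.0, cfg.expression_lognorm_sd, size=n))
    mu = cfg.depth * w / w.sum()
    delta = truth["delta_abund"].to_numpy()
    if assay == "riboprof":
        delta = delta + truth["delta_te"].to_numpy()
    cols, data = [], []
    for geno, eff in (("WT", 0.0), ("KO", 1.0)):
        for j in range(cfg.n_replicates_per_genotype):
            cols.append(f"{assay}_{geno}_{j + 1}")
            data.append(_nb(rng, mu * 2.0 ** (delta * eff), cfg.dispersion))
    counts = pd.DataFrame(
        np.column_stack(data), index=truth.index, columns=cols
    )
    meta = pd.DataFrame(
        {
            "genotype": [c.split("_")[1] for c in cols],
            "replicate": [c.split("_")[2] for c in cols],
            "assay": assay,
        },
        index=pd.Index(cols, name="sample"),
    )
    return counts, meta


def _make_coverage(cfg, models, truth, rng):
    """Footprint read centers per transcript position, per genotype.

    All transcripts share their shape vector between genotypes; targets'
    KO read rate is scaled by 2^delta_te.
    """
    cov = {"WT": {}, "KO": {}}
    cds_bounds = {}
    for gid, row in truth.iterrows():
        gm = models[gid]
        if not gm.is_coding:
            continue
        utr5_len = sum(u.length for u in gm.utr5)
        cds_len = sum(c.length for c in gm.cds)
        L = gm.exonic_length
        cds_bounds[gid] = (utr5_len, utr5_len + cds_len)
        # shared shape with the dynamic range of real footprint profiles:
        # lognormal of smoothed noise (multiplicative structure), an
        # initiation peak at the CDS start, CDS-weighted regions
        raw = rng.normal(0.0, 1.0, size=L)
        kernel = np.ones(25) / 25
        shape = np.exp(1.5 * np.convolve(raw, kernel, mode="same") * 5.0)
        shape[utr5_len : utr5_len + 20] *= 4.0  # initiation peak
        shape[: utr5_len] *= 0.3
        shape[utr5_len + cds_len :] *= 0.15
        shape /= shape.sum()
        rate = cfg.coverage_mean_reads * float(
            np.exp(rng.normal(0.0, cfg.coverage_read_sd))
        )
        for geno, eff in (("WT", 0.0), ("KO", 1.0)):
            n_reads = rng.poisson(rate * 2.0 ** (row["delta_te"] * eff))
            counts = rng.multinomial(n_reads, shape)
            cov[geno][gid] = TranscriptCoverage(gid, geno, counts, 1)
    for geno in cov:
        lib = int(sum(tc.n_reads for tc in cov[geno].values()))
        for tc in cov[geno].values():
            tc.library_size = max(lib, 1)
    return cov, cds_bounds


def _make_timecourse(cfg, truth, rng) -> pd.DataFrame:
    t = np.array(cfg.timepoints, float)
    tn = t / t.max()
    archetypes = [
        np.exp(-((tn - 0.08) ** 2) / 0.01),       # rapid induction
        np.exp(-((tn - 0.5) ** 2) / 0.05),        # late induction
        tn,                                        # gradual rise
        1.0 - tn,                                  # gradual decline
        np.exp(-tn * 6.0),                         # fast shutdown
        np.zeros_like(tn),                         # flat
    ][: cfg.n_archetypes]
    is_target = truth["target_class"].isin(["UTR3", "CDS"]).to_numpy()
    rows = []
    for i, gid in enumerate(truth.index):
        if is_target[i] and rng.random() < cfg.target_induced_prob:
            a = 0  # rapid-induction pattern
        else:
            a = int(rng.integers(len(archetypes)))
        rows.append(archetypes[a] + rng.normal(0, cfg.timecourse_noise_sd, len(t)))
    return pd.DataFrame(
        rows, index=truth.index, columns=[f"t{int(x)}h" for x in cfg.timepoints]
    )


def _make_site_windows(cfg, truth, rng) -> list[str]:
    """30-nt windows centered on planted sites with the AU-rich motif
    embedded in random background sequence."""
    alphabet = np.array(list("ACGU"))
    windows = []
    m = cfg.motif.upper().replace("T", "U")
    for gid, row in truth.iterrows():
        if row["target_class"] == "none":
            continue
        seq = alphabet[rng.integers(0, 4, size=cfg.window_nt)]
        off = (cfg.window_nt - len(m)) // 2
        seq[off : off + len(m)] = list(m)
        windows.append("".join(seq))
    return windows


def simulate_dataset(cfg: SimulationConfig | None = None) -> Bundle:
    """Generate the full synthetic bundle for one seed."""
    cfg = cfg or SimulationConfig()
    models, truth = _make_genes(cfg, _rng(cfg, "genes"))
    clip_tags = _make_clip_tags(cfg, models, truth, _rng(cfg, "clip"))
    rna_counts, rna_meta = _make_counts(cfg, truth, "rnaseq", _rng(cfg, "rna"))
    rp_counts, rp_meta = _make_counts(cfg, truth, "riboprof", _rng(cfg, "riboprof"))
    lengths = pd.Series(
        {gid: models[gid].exonic_length for gid in truth.index}, name="length"
    )
    rna = CountMatrix(rna_counts, rna_meta, lengths)
    rp = CountMatrix(rp_counts, rp_meta, lengths)
    cov, cds_bounds = _make_coverage(cfg, models, truth, _rng(cfg, "coverage"))
    tc = _make_timecourse(cfg, truth, _rng(cfg, "timecourse"))
    windows = _make_site_windows(cfg, truth, _rng(cfg, "sequence"))
    return Bundle(
        config=cfg,
        gene_models=models,
        clip_tags=clip_tags,
        rna=rna,
        riboprof=rp,
        coverage=cov,
        cds_bounds=cds_bounds,
        timecourse=tc,
        truth=truth,
        site_windows=windows,
    )


# ---------------------------------------------------------------------------
# fixture I/O


def write_tags_bed(tags: list[ClipTag], path) -> None:
    """BED6: name encodes replicate:antiserum; the 5' interval end is the
    truncation position by the tag invariant."""
    with open(path, "w") as fh:
        for t in sorted(tags, key=lambda t: (t.interval.chrom, t.interval.start)):
            fh.write(
                f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.replicate_id}:{t.antiserum_id}\t0\t{t.interval.strand}\n"
            )


def read_tags_bed(path) -> list[ClipTag]:
    tags = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: BED6 requires 6 fields")
            rep, _, serum = f[3].partition(":")
            tags.append(
                ClipTag(
                    GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    rep, serum or rep,
                )
            )
    return tags


def write_genes_bed12(models: dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(models):
            gm = models[gid]
            s, e = gm.tx_start, gm.tx_end
            if gm.is_coding:
                ts, te = gm.cds[0].start, gm.cds[-1].end
            else:
                ts = te = s
            sizes = ",".join(str(x.length) for x in gm.exons)
            starts = ",".join(str(x.start - s) for x in gm.exons)
            fh.write(
                f"{gm.chrom}\t{s}\t{e}\t{gid}\t0\t{gm.strand}\t{ts}\t{te}\t0\t"
                f"{len(gm.exons)}\t{sizes},\t{starts},\n"
            )


def write_count_matrix(cm: CountMatrix, counts_path, meta_path, lengths_path=None):
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample")
    if lengths_path is not None and cm.lengths is not None:
        cm.lengths.to_frame().to_csv(lengths_path, sep="\t", index_label="gene_id")


def read_count_matrix(counts_path, meta_path, lengths_path=None) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene_id").iloc[:, 0]
    return CountMatrix(counts, meta, lengths)


def write_fixture(bundle: Bundle, outdir) -> dict[str, Any]:
    """Write the bundle as plain-text files; returns {name: path}."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_genes_bed12(bundle.gene_models, p("genes.bed12"))
    for rep, tags in bundle.clip_tags.items():
        write_tags_bed(tags, p(f"tags_{rep}.bed"))
    write_count_matrix(bundle.rna, p("rna_counts.tsv"), p("rna_meta.tsv"),
                       p("gene_lengths.tsv"))
    write_count_matrix(bundle.riboprof, p("rp_counts.tsv"), p("rp_meta.tsv"))
    bundle.timecourse.to_csv(p("timecourse.tsv"), sep="\t", index_label="gene_id")
    bundle.truth.to_csv(p("truth.tsv"), sep="\t", index_label="gene_id")
    with open(p("site_windows.txt"), "w") as fh:
        fh.write("\n".join(bundle.site_windows) + "\n")
    return paths
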