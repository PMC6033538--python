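"""Count-matrix quantification: RPKM/cpm, expression filters, and a
normalized log2(KO/WT) fold-change estimator.

The fold-change estimator is deliberately simple and fully deterministic:
median-of-ratios size factors (or plain library-size scaling), then the
pseudocounted ratio of genotype means.  Downstream analyses consume only
these log2 fold changes and their ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "compute_rpkm",
    "compute_cpm",
    "filter_genes",
    "estimate_log2fc",
    "size_factors",
]


@dataclass
class CountMatrix:
    """Genes x samples integer counts with sample metadata.

    ``meta`` is indexed by sample id with columns ``genotype`` ("WT"/"KO"),
    ``replicate`` and ``assay`` ("rnaseq"/"riboprof").  ``lengths`` gives
    per-gene effective length in nt (for RPKM).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("genotype", "assay"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks {col!r} column")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if (self.lengths <= 0).any() or self.lengths.isna().any():
                raise ValueError("gene lengths must be positive for all genes")

    def samples(self, genotype: str | None = None) -> list[str]:
        m = self.meta.loc[list(self.counts.columns)]
        if genotype is not None:
            m = m[m["genotype"] == genotype]
        return list(m.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def compute_rpkm(cm: CountMatrix) -> pd.DataFrame:
    """RPKM = count / ((length/1e3) * (library_size/1e6)) per gene, sample."""
    if cm.lengths is None:
        raise ValueError("RPKM requires per-gene lengths")
    lib = cm.library_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    kb = cm.lengths / 1e3
    return cm.counts.div(lib / 1e6, axis=1).div(kb, axis=0)


def compute_cpm(cm: CountMatrix) -> pd.DataFrame:
    lib = cm.library_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    return cm.counts.div(lib / 1e6, axis=1)


def filter_genes(
    rna: CountMatrix,
    rp: CountMatrix,
    min_rpkm: float = 3.0,
    min_cpm: float = 1.0,
    min_cpm_replicates: int = 2,
) -> pd.DataFrame:
    """Joint expression filter for downstream CDF/ΔTE analyses.

    A gene passes iff its mean RPKM exceeds ``min_rpkm`` in WT or KO RNAseq
    replicates (strict >), and its ribosome-profiling cpm exceeds
    ``min_cpm`` in at least ``min_cpm_replicates`` replicates of one
    genotype.  Genes missing from either assay are excluded with reason
    "missing_assay".  Returns a frame indexed by the union of gene ids with
    boolean columns and a ``reason`` for failures.
    """
    rpkm = compute_rpkm(rna)
    cpm = compute_cpm(rp)
    all_genes = rna.counts.index.union(rp.counts.index)

    rna_pass = pd.Series(False, index=all_genes)
    for g in ("WT", "KO"):
        cols = rna.samples(g)
        if cols:
            rna_pass |= (rpkm[cols].mean(axis=1) > min_rpkm).reindex(
                all_genes, fill_value=False
            )
    rp_pass = pd.Series(False, index=all_genes)
    for g in ("WT", "KO"):
        cols = rp.samples(g)
        if cols:
            rp_pass |= (
                (cpm[cols] > min_cpm).sum(axis=1) >= min_cpm_replicates
            ).reindex(all_genes, fill_value=False)

    in_both = all_genes.isin(rna.counts.index) & all_genes.isin(rp.counts.index)
    out = pd.DataFrame(
        {
            "passes_rna_filter": rna_pass & in_both,
            "passes_rp_filter": rp_pass & in_both,
        },
        index=all_genes,
    )
    out["passes"] = out["passes_rna_filter"] & out["passes_rp_filter"]
    reason = np.where(
        ~in_both,
        "missing_assay",
        np.where(
            out["passes"],
            "",
            np.where(~out["passes_rna_filter"], "rna_filter", "rp_filter"),
        ),
    )
    out["reason"] = reason
    return out


def size_factors(
    counts: pd.DataFrame,
    method: str = "median_of_ratios",
    reference_genes=None,
) -> pd.Series:
    """Per-sample normalization factors.

    ``median_of_ratios``: median over all-positive genes of
    count / geometric-mean (DESeq-style).  ``library_size``: library size
    relative to its mean.

    ``reference_genes`` restricts the median to a set of presumed-unregulated
    control genes.  With a substantial fraction of genes regulated in one
    direction, the unrestricted median is pulled toward the regulated genes
    (their ratios blur into the null distribution); control genes — e.g.
    genes without a binding site — remove that contamination.
    """
    if method == "library_size":
        lib = counts.sum(axis=0)
        return lib / lib.mean()
    if method != "median_of_ratios":
        raise ValueError(f"unknown normalization {method!r}")
    sub = counts
    if reference_genes is not None:
        ref_idx = counts.index.intersection(pd.Index(list(reference_genes)))
        if len(ref_idx) >= 20:  # enough controls for a stable median
            sub = counts.loc[ref_idx]
    logc = np.log(sub.where(sub > 0))
    ref = logc.mean(axis=1)  # NaN for genes with any zero
    ratios = logc.sub(ref, axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    if sf.isna().any():
        raise ValueError("median-of-ratios undefined: no all-positive genes")
    return sf


def estimate_log2fc(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    normalization: str = "median_of_ratios",
    reference_genes=None,
) -> pd.Series:
    """Per-gene normalized log2(KO/WT).

    Counts are scaled by per-sample size factors (optionally computed on a
    control-gene reference set; see :func:`size_factors`), then
    log2fc = log2((mean_KO + pc) / (mean_WT + pc)).  With pseudocount 0 an
    all-zero gene raises; with pc > 0 it yields exactly 0.
    """
    wt, ko = cm.samples("WT"), cm.samples("KO")
    if not wt or not ko:
        raise ValueError("need at least one replicate per genotype")
    sf = size_factors(cm.counts, normalization, reference_genes)
    norm = cm.counts.div(sf, axis=1)
    mean_wt, mean_ko = norm[wt].mean(axis=1), norm[ko].mean(axis=1)
    if pseudocount <= 0 and ((mean_wt == 0) | (mean_ko == 0)).any():
        raise ValueError("zero genotype mean with pseudocount 0")
    fc = np.log2(mean_ko + pseudocount) - np.log2(mean_wt + pseudocount)
    fc.name = "log2fc"
    return fc
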