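"""Ribosome-footprint coverage along transcripts.

Coverage counts read centers (footprint midpoints) per transcript-coordinate
position.  Three views are provided: depth-normalized sliding-window
profiles, a per-transcript binomial test of the KO read fraction against
the library-depth expectation, and a metagene profile averaging
per-transcript read proportions anchored to the coding region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptCoverage",
    "WindowProfile",
    "TranscriptBinomialResult",
    "window_coverage",
    "binomial_genotype_test",
    "binomial_test_all",
    "metagene",
    "coverage_from_intervals",
    "cds_transcript_bounds",
]


@dataclass
class TranscriptCoverage:
    """Read-center counts along one transcript for one genotype."""

    gene_id: str
    genotype: str
    counts: np.ndarray  # per transcript-coordinate position
    library_size: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any():
            raise ValueError("negative coverage counts")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    @property
    def n_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class WindowProfile:
    gene_id: str
    genotype: str
    window: int
    values: np.ndarray  # reads per window per million mapped, step 1


@dataclass
class TranscriptBinomialResult:
    gene_id: str
    x_ko: int
    n: int
    p0: float
    p_value: float
    q_value: float = float("nan")


def window_coverage(tc: TranscriptCoverage, w: int = 20, step: int = 1) -> WindowProfile:
    """Sliding-window, depth-normalized coverage profile.

    Window value = (read centers in [i, i+w)) / library_size * 1e6.
    Transcripts shorter than w yield an empty profile with a warning.
    """
    if w < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    L = len(tc.counts)
    if L < w:
        logger.warning("%s: transcript length %d < window %d", tc.gene_id, L, w)
        return WindowProfile(tc.gene_id, tc.genotype, w, np.empty(0))
    cs = np.concatenate([[0], np.cumsum(tc.counts)])
    sums = cs[w:] - cs[:-w]
    values = sums[::step] / tc.library_size * 1e6
    return WindowProfile(tc.gene_id, tc.genotype, w, values)


def binomial_genotype_test(
    x_ko: int, x_wt: int, depth_ko: int, depth_wt: int
) -> TranscriptBinomialResult:
    """Two-sided exact binomial test of the KO read share on one transcript.

    Under no genotype difference, each of the n = x_ko + x_wt reads is KO
    with probability p0 = depth_ko / (depth_ko + depth_wt); the two-sided
    p-value sums outcome probabilities <= P(x_ko) (minimum-likelihood
    method).
    """
    if depth_ko <= 0 or depth_wt <= 0:
        raise ValueError("library depths must be positive")
    n = x_ko + x_wt
    if n < 1:
        raise ValueError("need at least one read")
    p0 = depth_ko / (depth_ko + depth_wt)
    p = stats.binomtest(x_ko, n, p0, alternative="two-sided").pvalue
    return TranscriptBinomialResult("", x_ko, n, p0, float(p))


def binomial_test_all(
    ko: dict[str, TranscriptCoverage],
    wt: dict[str, TranscriptCoverage],
    depth_ko: int | None = None,
    depth_wt: int | None = None,
) -> pd.DataFrame:
    """Per-transcript binomial tests with BH correction across transcripts."""
    genes = sorted(set(ko) & set(wt))
    if not genes:
        raise ValueError("no transcripts present in both genotypes")
    if depth_ko is None:
        depth_ko = next(iter(ko.values())).library_size
    if depth_wt is None:
        depth_wt = next(iter(wt.values())).library_size
    rows = []
    for g in genes:
        x_ko, x_wt = ko[g].n_reads, wt[g].n_reads
        if x_ko + x_wt < 1:
            continue
        r = binomial_genotype_test(x_ko, x_wt, depth_ko, depth_wt)
        rows.append((g, x_ko, r.n, r.p0, r.p_value))
    df = pd.DataFrame(rows, columns=["gene_id", "x_ko", "n", "p0", "p_value"])
    df["q_value"] = stats.false_discovery_control(df["p_value"], method="bh")
    return df.set_index("gene_id")


def cds_transcript_bounds(gm) -> tuple[int, int]:
    """CDS start/end in transcript (exonic, 5'->3') coordinates."""
    utr5 = sum(i.length for i in gm.utr5)
    cds = sum(i.length for i in gm.cds)
    return utr5, utr5 + cds


def coverage_from_intervals(
    intervals, gm, genotype: str, library_size: int
) -> TranscriptCoverage:
    """Project genomic footprint intervals onto transcript coordinates.

    Each footprint contributes one count at the transcript position of its
    genomic midpoint; footprints whose midpoint falls outside the exons
    (intronic/flanking) are dropped.  Minus-strand genes are reversed so
    position 0 is the transcript 5' end.
    """
    L = gm.exonic_length
    counts = np.zeros(L, dtype=np.int64)
    # exon offsets in genomic order
    offsets = np.cumsum([0] + [e.length for e in gm.exons[:-1]])
    for iv in intervals:
        mid = iv.start + (iv.length - 1) // 2
        for off, exon in zip(offsets, gm.exons):
            if exon.start <= mid < exon.end:
                pos = off + (mid - exon.start)
                if gm.strand == "-":
                    pos = L - 1 - pos
                counts[pos] += 1
                break
    return TranscriptCoverage(gm.gene_id, genotype, counts, library_size)


def _anchored_proportions(
    props: np.ndarray, cds: tuple[int, int], edge: int, n_mid_bins: int
) -> np.ndarray | None:
    """Map a proportion vector onto the common metagene grid:
    ``edge`` nt anchored at the CDS start, a middle segment rescaled to
    ``n_mid_bins`` bins, and ``edge`` nt anchored at the CDS stop."""
    s, e = cds
    if e - s < 2 * edge + 2:
        return None
    head = props[s : s + edge]
    tail = props[e - edge : e]
    mid = props[s + edge : e - edge]
    # rescale the middle by proportional binning, conserving total mass
    edges = np.linspace(0, len(mid), n_mid_bins + 1)
    cs = np.concatenate([[0.0], np.cumsum(mid)])
    binned = np.interp(edges[1:], np.arange(len(mid) + 1), cs) - np.interp(
        edges[:-1], np.arange(len(mid) + 1), cs
    )
    return np.concatenate([head, binned, tail])


def metagene(
    coverages: dict[str, TranscriptCoverage],
    cds_bounds: dict[str, tuple[int, int]],
    min_reads: int = 10,
    anchor: str = "both",
    edge: int = 50,
    n_mid_bins: int = 100,
    window: int | None = None,
) -> pd.DataFrame:
    """Metagene profile: mean per-position read proportion across transcripts.

    Transcripts with fewer than ``min_reads`` read centers inside the CDS
    (the region of interest) are excluded.  Each remaining transcript's CDS
    counts are converted to proportions summing to 1 and mapped onto a
    common grid (``anchor="both"``: ``edge`` nt at the start and stop with
    a length-rescaled middle; ``"start"``/``"stop"``: a single anchored
    ``window``-nt block).  The mean at each grid position is taken over the
    transcripts contributing at that position only.
    """
    if anchor not in ("start", "stop", "both"):
        raise ValueError(f"anchor must be start/stop/both, got {anchor!r}")
    rows = []
    for g, tc in sorted(coverages.items()):
        if g not in cds_bounds:
            continue
        s, e = cds_bounds[g]
        if tc.counts[s:e].sum() < min_reads:
            continue
        props = tc.counts / max(tc.counts.sum(), 1)
        if anchor == "both":
            vec = _anchored_proportions(props, (s, e), edge, n_mid_bins)
        elif anchor == "start":
            vec = props[s : s + (window or 2 * edge)]
        else:
            vec = props[max(0, e - (window or 2 * edge)) : e]
        if vec is None or len(vec) == 0:
            continue
        rows.append(vec)
    if not rows:
        logger.warning("metagene: no transcripts pass the %d-read filter", min_reads)
        return pd.DataFrame(columns=["position", "mean_proportion", "n_transcripts"])
    width = max(len(r) for r in rows)
    # per-position mean over contributing transcripts only (stop-anchored
    # vectors align at their anchored end)
    mat = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        if anchor == "stop":
            mat[i, width - len(r):] = r
        else:
            mat[i, : len(r)] = r
    n_at = np.sum(~np.isnan(mat), axis=0)
    mean = np.where(n_at > 0, np.nansum(mat, axis=0) / np.maximum(n_at, 1), np.nan)
    if anchor == "both":
        labels = (
            [f"start+{i}" for i in range(edge)]
            + [f"mid{i}" for i in range(n_mid_bins)]
            + [f"stop-{edge - i}" for i in range(edge)]
        )[:width]
    elif anchor == "start":
        labels = [f"start+{i}" for i in range(width)]
    else:
        labels = [f"stop-{width - i}" for i in range(width)]
    return pd.DataFrame(
        {"position": labels, "mean_proportion": mean, "n_transcripts": n_at}
    )
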