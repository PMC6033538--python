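"""CLIP tag pileups, permutation-FDR peak calling, robust sites, CITS,
and a k-mer enrichment screen.

Peaks are called per gene against a uniform "genic background" null over
the extended gene span (transcript + downstream extension), the same span
used to accumulate the pileup.  Binding magnitude is summarized by peak
height (PH), the maximum pileup depth inside the peak.  Robust sites are
peaks merged across replicates that jointly clear thresholds on PH,
biological-replicate support, and antiserum support.  Cross-link-induced
truncation sites (CITS) are positions inside peaks where read 5' ends pile
up beyond binomial expectation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, GenomicInterval, assign_region

logger = logging.getLogger(__name__)

__all__ = [
    "ClipTag",
    "Peak",
    "RobustSite",
    "CitsSite",
    "pileup",
    "call_peaks",
    "define_robust_sites",
    "annotate_sites",
    "stratify_by_ph",
    "call_cits",
    "kmer_enrichment",
    "assign_tags_to_genes",
]


@dataclass(frozen=True)
class ClipTag:
    """One aligned CLIP tag with replicate/antiserum provenance.

    ``truncation_pos`` is the genomic coordinate of the read 5' end
    (the reverse-transcription stop): interval start on the + strand,
    ``end - 1`` on the - strand.
    """

    interval: GenomicInterval
    replicate_id: str
    antiserum_id: str
    truncation_pos: int = -1

    def __post_init__(self) -> None:
        if self.truncation_pos < 0:
            pos = (
                self.interval.start
                if self.interval.strand == "+"
                else self.interval.end - 1
            )
            object.__setattr__(self, "truncation_pos", pos)
        if not (self.interval.start <= self.truncation_pos < self.interval.end):
            raise ValueError("truncation_pos outside tag interval")


@dataclass
class Peak:
    interval: GenomicInterval
    gene_id: str
    ph: int
    n_tags: int
    fdr: float
    support_replicates: frozenset = frozenset()
    support_antisera: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.ph < 1 or self.ph > self.n_tags:
            raise ValueError(f"invalid PH={self.ph} for n_tags={self.n_tags}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"FDR out of [0,1]: {self.fdr}")


@dataclass
class RobustSite:
    """Replicate-merged peak passing the active support thresholds."""

    interval: GenomicInterval
    gene_id: str
    ph: int
    n_tags: int
    support_replicates: frozenset
    support_antisera: frozenset
    tier: str | None = None  # "top"/"bulk", set by stratify_by_ph
    regions: set = field(default_factory=set)

    @property
    def site_id(self) -> str:
        return f"{self.gene_id}:{self.interval.start}-{self.interval.end}"


@dataclass
class CitsSite:
    position: int
    truncation_count: int
    peak_id: str
    p_value: float
    q_value: float


# ---------------------------------------------------------------------------
# pileup and candidate peaks


def pileup(tags, gm: GeneModel) -> np.ndarray:
    """Per-base tag depth over the extended gene span.

    Tags falling entirely outside the span are excluded (counted in a
    warning); tags partially outside are clipped.
    """
    span = gm.span
    depth = np.zeros(span.length, dtype=np.int64)
    excluded = 0
    for t in tags:
        s = max(t.interval.start, span.start) - span.start
        e = min(t.interval.end, span.end) - span.start
        if e <= s:
            excluded += 1
            continue
        depth[s] += 1
        if e < span.length:
            depth[e] -= 1
    if excluded:
        logger.warning("%s: %d tags outside extended span excluded",
                       gm.gene_id, excluded)
    return np.cumsum(depth)


def _split_run(depth: np.ndarray, valley_frac: float) -> list[tuple[int, int, int]]:
    """Split one positive-coverage run at valleys below ``valley_frac`` of the
    smaller flanking maximum.  Returns (start, end, ph) offsets.

    A position is a valley candidate when its depth is strictly below
    ``valley_frac * min(max depth to its left, max depth to its right)``
    within the run; each contiguous below-threshold stretch contributes one
    split at the leftmost position of its minimum.  The rule is
    order-independent and single-pass.
    """
    n = len(depth)
    lmax = np.maximum.accumulate(depth)
    rmax = np.maximum.accumulate(depth[::-1])[::-1]
    below = depth < valley_frac * np.minimum(lmax, rmax)
    if not below.any():
        return [(0, n, int(depth.max()))]
    bounds = [0]
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            bounds.append(i + int(np.argmin(depth[i : j + 1])))
            i = j + 1
        else:
            i += 1
    bounds.append(n)
    return [
        (s, e, int(depth[s:e].max())) for s, e in zip(bounds, bounds[1:]) if e > s
    ]


def _candidate_peaks(
    starts: np.ndarray, ends: np.ndarray, valley_frac: float = 0.5
) -> list[tuple[int, int, int]]:
    """Candidate peaks from tag intervals: maximal runs of positive depth,
    valley-split.  Works on run-local dense arrays only, so cost scales with
    covered bases, not span length."""
    if len(starts) == 0:
        return []
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    peaks: list[tuple[int, int, int]] = []
    run_s, run_e, members = int(starts[0]), int(ends[0]), [0]
    for i in range(1, len(starts)):
        if starts[i] < run_e:  # still inside the current run
            run_e = max(run_e, int(ends[i]))
            members.append(i)
        else:
            peaks.extend(_finish_run(starts, ends, members, run_s, run_e, valley_frac))
            run_s, run_e, members = int(starts[i]), int(ends[i]), [i]
    peaks.extend(_finish_run(starts, ends, members, run_s, run_e, valley_frac))
    return peaks


def _finish_run(starts, ends, members, run_s, run_e, valley_frac):
    depth = np.zeros(run_e - run_s, dtype=np.int64)
    for i in members:
        depth[starts[i] - run_s] += 1
        e = ends[i] - run_s
        if e < len(depth):
            depth[e] -= 1
    depth = np.cumsum(depth)
    return [
        (run_s + s, run_s + e, ph)
        for s, e, ph in _split_run(depth, valley_frac)
    ]


# ---------------------------------------------------------------------------
# peak calling with permutation FDR

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _null_ph_counts(starts, ends, valley_frac, max_ph):  # pragma: no cover
    """Count candidate peaks with PH >= h (h = 1..max_ph) over sorted,
    permutation-offset tag intervals.  Same run/valley-split semantics as
    ``_candidate_peaks``; PH counting may skip below-threshold stretches
    because their depths cannot set a segment maximum."""
    counts = np.zeros(max_ph + 2, np.int64)
    n = starts.shape[0]
    i = 0
    while i < n:
        run_s = starts[i]
        run_e = ends[i]
        j = i + 1
        while j < n and starts[j] < run_e:
            if ends[j] > run_e:
                run_e = ends[j]
            j += 1
        L = int(run_e - run_s)
        diff = np.zeros(L + 1, np.int64)
        for k in range(i, j):
            diff[starts[k] - run_s] += 1
            diff[ends[k] - run_s] -= 1
        d = np.cumsum(diff)[:L]
        lmax = np.empty(L, np.int64)
        m = 0
        for t in range(L):
            if d[t] > m:
                m = d[t]
            lmax[t] = m
        rmax = np.empty(L, np.int64)
        m = 0
        for t in range(L - 1, -1, -1):
            if d[t] > m:
                m = d[t]
            rmax[t] = m
        seg_max = 0
        t = 0
        while t < L:
            mn = lmax[t] if lmax[t] < rmax[t] else rmax[t]
            if d[t] < valley_frac * mn:
                hi = seg_max if seg_max < max_ph else max_ph
                for h in range(1, hi + 1):
                    counts[h] += 1
                seg_max = 0
                while t < L:
                    mn = lmax[t] if lmax[t] < rmax[t] else rmax[t]
                    if d[t] < valley_frac * mn:
                        t += 1
                    else:
                        break
            else:
                if d[t] > seg_max:
                    seg_max = int(d[t])
                t += 1
        hi = seg_max if seg_max < max_ph else max_ph
        for h in range(1, hi + 1):
            counts[h] += 1
        i = j
    return counts


def call_peaks(
    tags,
    gm: GeneModel,
    alpha: float = 0.01,
    n_perm: int = 100,
    seed: int = 0,
    valley_frac: float = 0.5,
) -> list[Peak]:
    """Call peaks on one gene with permutation FDR over the genic background.

    Candidate peaks are valley-split runs of positive depth.  The null
    re-places the gene's tags uniformly over the extended span ``n_perm``
    times; FDR(h) = E[null candidates with PH >= h] / observed candidates
    with PH >= h, monotonized to be non-increasing in h.  Candidates with
    FDR <= ``alpha`` are returned with replicate/antiserum support sets.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable FDR estimate")
    tags = list(tags)
    if not tags:
        return []
    span = gm.span
    starts = np.array([max(t.interval.start, span.start) for t in tags])
    ends = np.array([min(t.interval.end, span.end) for t in tags])
    keep = ends > starts
    if not keep.all():
        logger.warning("%s: %d tags outside extended span excluded",
                       gm.gene_id, int((~keep).sum()))
        starts, ends = starts[keep], ends[keep]
        tags = [t for t, k in zip(tags, keep) if k]
    if len(starts) == 0:
        return []

    cands = _candidate_peaks(starts, ends, valley_frac)
    max_ph = max(ph for _, _, ph in cands)
    obs_ph = np.array([ph for _, _, ph in cands])

    lengths = ends - starts
    rng = np.random.default_rng(seed)
    # all permutations in one kernel pass: offset each permutation into its
    # own coordinate block so runs can never bridge permutations
    block = int(span.length + lengths.max() + 2)
    offs = (np.arange(n_perm, dtype=np.int64) * block)[:, None]
    ns = rng.integers(0, span.length - lengths + 1, size=(n_perm, len(lengths)))
    flat_s = (ns + offs).ravel()
    flat_e = flat_s + np.tile(lengths, n_perm)
    order = np.argsort(flat_s, kind="stable")
    null_ge = (
        _null_ph_counts(flat_s[order], flat_e[order], valley_frac, max_ph)
        / n_perm
    )

    fdr_h = np.ones(max_ph + 1)
    for h in range(1, max_ph + 1):
        n_obs = int((obs_ph >= h).sum())
        fdr_h[h] = min(1.0, null_ge[h] / n_obs) if n_obs else 1.0
    fdr_h = np.minimum.accumulate(fdr_h)  # non-increasing in h

    out: list[Peak] = []
    for s, e, ph in cands:
        if fdr_h[ph] > alpha:
            continue
        in_peak = [t for t in tags if t.interval.start < e and t.interval.end > s]
        out.append(
            Peak(
                interval=GenomicInterval(gm.chrom, s, e, gm.strand),
                gene_id=gm.gene_id,
                ph=ph,
                n_tags=len(in_peak),
                fdr=float(fdr_h[ph]),
                support_replicates=frozenset(t.replicate_id for t in in_peak),
                support_antisera=frozenset(t.antiserum_id for t in in_peak),
            )
        )
    return out


# ---------------------------------------------------------------------------
# robust sites


def define_robust_sites(
    peaks,
    min_ph: int = 5,
    min_replicates: int | None = None,
    min_antisera: int = 2,
    merge_mode: str = "per_replicate",
) -> list[RobustSite]:
    """Merge peaks across replicates and apply joint support thresholds.

    Peaks overlapping by >= 1 bp (same gene) merge to their union interval;
    merged PH is the maximum constituent PH and support sets are unioned.
    A site is retained iff PH > ``min_ph`` (strict), replicate support >=
    ``min_replicates`` and antiserum support >= ``min_antisera``.

    ``merge_mode="per_replicate"`` (default ``min_replicates=3``) merges
    independently-called per-replicate peaks; ``"pooled"`` (default
    ``min_replicates=6``, the strict reading of "more than 5") expects peaks
    called on pooled tags whose support sets were recorded from member tags.
    """
    if merge_mode not in ("per_replicate", "pooled"):
        raise ValueError(f"unknown merge_mode {merge_mode!r}")
    if min_replicates is None:
        min_replicates = 3 if merge_mode == "per_replicate" else 6
    for p in peaks:
        if not p.support_replicates or not p.support_antisera:
            raise ValueError(f"peak {p.gene_id}:{p.interval.start} lacks "
                             "replicate/antiserum provenance")

    by_gene: dict[str, list[Peak]] = defaultdict(list)
    for p in peaks:
        by_gene[p.gene_id].append(p)

    sites: list[RobustSite] = []
    for gid in sorted(by_gene):
        group = sorted(by_gene[gid], key=lambda p: (p.interval.start, p.interval.end))
        cur: list[Peak] = []
        cur_end = -1
        for p in group + [None]:
            if p is not None and cur and p.interval.start < cur_end:
                cur.append(p)
                cur_end = max(cur_end, p.interval.end)
                continue
            if cur:
                iv = GenomicInterval(
                    cur[0].interval.chrom,
                    min(q.interval.start for q in cur),
                    max(q.interval.end for q in cur),
                    cur[0].interval.strand,
                )
                site = RobustSite(
                    interval=iv,
                    gene_id=gid,
                    ph=max(q.ph for q in cur),
                    n_tags=max(q.n_tags for q in cur),
                    support_replicates=frozenset().union(
                        *(q.support_replicates for q in cur)
                    ),
                    support_antisera=frozenset().union(
                        *(q.support_antisera for q in cur)
                    ),
                )
                if (
                    site.ph > min_ph
                    and len(site.support_replicates) >= min_replicates
                    and len(site.support_antisera) >= min_antisera
                ):
                    sites.append(site)
            if p is not None:
                cur, cur_end = [p], p.interval.end
    return sites


def annotate_sites(sites, gene_models: dict, mode: str = "non_exclusive"):
    """Attach region labels (UTR3/CDS/UTR5/intron/downstream) to each site."""
    out = []
    for s in sites:
        if s.gene_id not in gene_models:
            raise KeyError(f"site references unknown gene {s.gene_id}")
        regions = assign_region(s.interval, gene_models[s.gene_id], mode)
        out.append(replace(s, regions=regions))
    return out


def stratify_by_ph(
    sites, top_fraction: float = 0.20, scope: str = "per_region"
) -> list[RobustSite]:
    """Label each site "top" or "bulk" by PH rank.

    Sites are ranked by PH descending (ties by n_tags then site id); the
    top ``ceil(top_fraction * N)`` are "top".  ``scope="per_region"`` ranks
    within each exclusive region label; ``"global"`` ranks all sites
    together.
    """
    sites = list(sites)
    if len(sites) < 5:
        raise ValueError("need at least 5 sites to stratify by PH")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")

    def region_key(s: RobustSite) -> str:
        for label in ("UTR3", "CDS", "UTR5", "noncoding", "intron", "downstream"):
            if label in s.regions:
                return label
        return "none"

    groups: dict[str, list[RobustSite]] = defaultdict(list)
    for s in sites:
        groups[region_key(s) if scope == "per_region" else "all"].append(s)

    out: list[RobustSite] = []
    for group in groups.values():
        ranked = sorted(group, key=lambda s: (-s.ph, -s.n_tags, s.site_id))
        n_top = int(np.ceil(top_fraction * len(ranked)))
        for i, s in enumerate(ranked):
            out.append(replace(s, tier="top" if i < n_top else "bulk"))
    return sorted(out, key=lambda s: s.site_id)


# ---------------------------------------------------------------------------
# CITS


def call_cits(tags, peaks, alpha: float = 0.05) -> list[CitsSite]:
    """Cross-link-induced truncation sites from pooled tags.

    Within each peak of width w containing m truncation events, a position
    with c truncations is tested against the upper tail of Binomial(m, 1/w);
    Benjamini-Hochberg is applied across all tested positions and sites with
    q <= ``alpha`` are returned.
    """
    tested: list[tuple[int, int, str, float]] = []
    for p in peaks:
        w = p.interval.length
        trunc = [
            t.truncation_pos
            for t in tags
            if p.interval.start <= t.truncation_pos < p.interval.end
            and t.interval.strand == p.interval.strand
            and t.interval.chrom == p.interval.chrom
        ]
        m = len(trunc)
        if m == 0:
            continue
        pos, counts = np.unique(trunc, return_counts=True)
        peak_id = f"{p.gene_id}:{p.interval.start}-{p.interval.end}"
        for x, c in zip(pos, counts):
            pval = float(stats.binom.sf(int(c) - 1, m, 1.0 / w))
            tested.append((int(x), int(c), peak_id, pval))
    if not tested:
        return []
    qvals = stats.false_discovery_control([t[3] for t in tested], method="bh")
    return [
        CitsSite(position=x, truncation_count=c, peak_id=pid,
                 p_value=pval, q_value=float(q))
        for (x, c, pid, pval), q in zip(tested, qvals)
        if q <= alpha
    ]


# ---------------------------------------------------------------------------
# k-mer enrichment (motif stand-in)


def _dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson shuffle preserving exact dinucleotide counts."""
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(seq, seq[1:]):
        edges[a].append(b)
    last = seq[-1]
    verts = [v for v in edges if v != last]
    # choose last-exit edges forming a tree into `last`
    while True:
        last_edge = {v: edges[v][rng.integers(len(edges[v]))] for v in verts}
        ok = True
        for v in verts:
            seen, cur = {v}, v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    shuffled: dict[str, list[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        shuffled[v] = rest + ([last_edge[v]] if v in last_edge else [])
    out = [seq[0]]
    idx: dict[str, int] = defaultdict(int)
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][idx[cur]]
        idx[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def _count_kmers(seqs, k: int) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for s in seqs:
        for i in range(len(s) - k + 1):
            counts[s[i : i + k]] += 1
    return counts


def kmer_enrichment(
    windows,
    k: int = 8,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank k-mers by enrichment over dinucleotide-shuffled windows.

    For each k-mer observed in the site windows, z = (obs - mean_null) /
    sd_null over ``n_shuffles`` per-window dinucleotide shuffles.  The sd
    is floored at one count so rare k-mers absent from every shuffle get a
    finite, count-resolution z rather than an inflated one.  T is
    normalized to U.  Windows shorter than k are excluded with a warning.
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    rng = np.random.default_rng(seed)
    seqs = [w.upper().replace("T", "U") for w in windows]
    short = sum(len(s) < k for s in seqs)
    if short:
        logger.warning("%d windows shorter than k=%d excluded", short, k)
    seqs = [s for s in seqs if len(s) >= k]
    if not seqs:
        raise ValueError("no windows of length >= k")

    obs = _count_kmers(seqs, k)
    null = np.zeros((n_shuffles, len(obs)))
    index = {km: i for i, km in enumerate(obs)}
    for j in range(n_shuffles):
        sh = _count_kmers([_dinucleotide_shuffle(s, rng) for s in seqs], k)
        for km, c in sh.items():
            if km in index:
                null[j, index[km]] = c
    mean = null.mean(axis=0)
    sd = np.maximum(null.std(axis=0, ddof=1), 1.0)  # count-resolution floor
    df = pd.DataFrame(
        {
            "kmer": list(obs),
            "observed": list(obs.values()),
            "null_mean": mean,
            "null_sd": sd,
        }
    )
    df["z"] = (df["observed"] - df["null_mean"]) / df["null_sd"]
    return df.sort_values(["z", "kmer"], ascending=[False, True], ignore_index=True)


# ---------------------------------------------------------------------------
# tag-to-gene assignment


def assign_tags_to_genes(tags, gene_models: dict) -> dict[str, list[ClipTag]]:
    """Assign tags to every gene whose extended span they overlap (same
    strand).  Tags overlapping multiple genes are assigned to all of them."""
    by_cs: dict[tuple[str, str], list[GeneModel]] = defaultdict(list)
    for gm in gene_models.values():
        by_cs[(gm.chrom, gm.strand)].append(gm)
    index = {}
    for key, gms in by_cs.items():
        gms.sort(key=lambda g: g.span.start)
        index[key] = (np.array([g.span.start for g in gms]),
                      np.array([g.span.end for g in gms]), gms,
                      max(g.span.length for g in gms))
    out: dict[str, list[ClipTag]] = defaultdict(list)
    for t in tags:
        key = (t.interval.chrom, t.interval.strand)
        if key not in index:
            continue
        starts, ends, gms, max_len = index[key]
        j = int(np.searchsorted(starts, t.interval.end)) - 1
        while j >= 0 and starts[j] > t.interval.start - max_len:
            if ends[j] > t.interval.start:
                out[gms[j].gene_id].append(t)
            j -= 1
    return dict(out)
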