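"""Target classification by binding region and CDF-shift (KS) tests.

Genes are classified by where their robust CLIP sites fall (3'UTR, CDS,
intron); the log2(KO/WT) fold-change distribution of each class is compared
against the background of genes with no site anywhere on the transcript
with a two-sided two-sample Kolmogorov-Smirnov test.  Optional tier subsets
("top" = highest-PH quintile) reproduce binding-magnitude stratification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TargetClassAssignment",
    "ShiftTestResult",
    "classify_targets",
    "ks_two_sample",
    "run_shift_analysis",
]

TARGET_REGIONS = ("UTR3", "CDS", "intron")

#: product n_x * n_y above which the asymptotic KS p-value replaces the
#: exact one
KS_EXACT_LIMIT = 10_000


@dataclass
class TargetClassAssignment:
    gene_id: str
    classes: set[str] = field(default_factory=set)
    tiers: dict = field(default_factory=dict)  # region -> best tier in region
    mode: str = "non_exclusive"


@dataclass
class ShiftTestResult:
    class_label: str
    n_class: int
    n_background: int
    D: float
    p_value: float
    q_value: float = float("nan")
    median_shift: float = float("nan")
    low_power: bool = False
    cdf_table: pd.DataFrame | None = None


def classify_targets(
    robust_sites,
    gene_models: dict,
    mode: str = "non_exclusive",
    cits_sites=None,
) -> dict[str, TargetClassAssignment]:
    """Assign each gene to binding-region classes from its robust sites.

    A gene is in class C iff it has at least one robust site overlapping
    region C (sites must already carry region labels from
    ``annotate_sites``).  In exclusive mode each site contributes only its
    highest-precedence label, so a gene whose sites are all 3'UTR+CDS
    resolves to {UTR3}.  ``cits_sites`` optionally restricts to sites
    overlapping a statistically robust truncation site (stringent mode).
    Genes with no site anywhere form the background (absent from the
    returned mapping).
    """
    from .annotation import REGION_PRECEDENCE

    sites = list(robust_sites)
    if cits_sites is not None:
        positions = {(c.peak_id.split(":")[0], c.position) for c in cits_sites}
        sites = [
            s
            for s in sites
            if any(
                g == s.gene_id and s.interval.start <= pos < s.interval.end
                for g, pos in positions
            )
        ]
    out: dict[str, TargetClassAssignment] = {}
    for s in sites:
        if s.gene_id not in gene_models:
            raise KeyError(f"site references unknown gene {s.gene_id}")
        labels = set(s.regions) & set(TARGET_REGIONS)
        if mode == "exclusive":
            labels = {
                next(
                    (r for r in REGION_PRECEDENCE if r in s.regions),
                    "none",
                )
            } & set(TARGET_REGIONS)
        a = out.setdefault(s.gene_id, TargetClassAssignment(s.gene_id, mode=mode))
        a.classes |= labels
        for r in labels:
            if s.tier == "top" or a.tiers.get(r) != "top":
                a.tiers[r] = s.tier
    return {g: a for g, a in out.items() if a.classes}


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample KS test.

    D = sup |ECDF_x - ECDF_y|.  The exact p-value is used when
    n_x * n_y <= 1e4, the asymptotic Kolmogorov distribution otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    method = "exact" if len(x) * len(y) <= KS_EXACT_LIMIT else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _ecdf_table(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(np.sort(values), grid, side="right") / len(values)


def run_shift_analysis(
    assignments: dict,
    log2fc: pd.Series,
    passes: pd.Series | None = None,
    tiers: str = "all,top",
    min_n: int = 10,
) -> list[ShiftTestResult]:
    """KS shift tests of each target class against the no-site background.

    ``assignments`` maps gene -> TargetClassAssignment; genes absent from it
    (but present in ``log2fc`` and passing the expression filter) form the
    background.  For each region a full-class test is run and, when
    requested via ``tiers``, a "top" subset restricted to genes whose best
    site in that region is top-tier.  Benjamini-Hochberg q-values are
    reported across the family alongside raw p-values.  Classes with fewer
    than ``min_n`` genes are flagged low-power, not suppressed.
    """
    genes = log2fc.index
    if passes is not None:
        genes = genes[passes.reindex(genes, fill_value=False)]
    genes = set(genes)
    bg = sorted(genes - set(assignments))
    bg_vals = log2fc.loc[bg].to_numpy()
    if len(bg_vals) == 0:
        raise ValueError("empty background gene set")
    want = {t.strip() for t in tiers.split(",") if t.strip()}

    requested: list[tuple[str, list[str]]] = []
    for region in TARGET_REGIONS:
        members = sorted(
            g for g, a in assignments.items() if region in a.classes and g in genes
        )
        if "all" in want:
            requested.append((region, members))
        if "top" in want and region != "intron":
            top = [g for g in members if assignments[g].tiers.get(region) == "top"]
            requested.append((f"{region}_top", top))

    grid = np.sort(log2fc.loc[sorted(genes)].to_numpy())
    results: list[ShiftTestResult] = []
    for label, members in requested:
        if not members:
            results.append(
                ShiftTestResult(label, 0, len(bg_vals), float("nan"),
                                float("nan"), low_power=True)
            )
            continue
        vals = log2fc.loc[members].to_numpy()
        D, p = ks_two_sample(vals, bg_vals)
        cdf = pd.DataFrame(
            {
                "log2fc": grid,
                "ecdf_class": _ecdf_table(vals, grid),
                "ecdf_background": _ecdf_table(bg_vals, grid),
            }
        )
        results.append(
            ShiftTestResult(
                class_label=label,
                n_class=len(vals),
                n_background=len(bg_vals),
                D=D,
                p_value=p,
                median_shift=float(np.median(vals) - np.median(bg_vals)),
                low_power=len(vals) < min_n,
                cdf_table=cdf,
            )
        )
    tested = [r for r in results if np.isfinite(r.p_value)]
    if tested:
        q = stats.false_discovery_control([r.p_value for r in tested], method="bh")
        for r, qv in zip(tested, q):
            r.q_value = float(qv)
    return results
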