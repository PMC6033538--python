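"""Gene models and stranded interval arithmetic.

All coordinates are 0-based half-open (BED convention) on both strands.
A :class:`GeneModel` carries the exon/CDS/UTR/intron partition of a gene
plus a configurable downstream extension (default 10 kb) past the annotated
3' end, used as the genic background span for CLIP peak calling so that
non-annotated 3'UTR variants are not mistaken for intergenic signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "load_gene_models",
    "assign_region",
    "distance_to_transcript_end",
    "write_regions_bed",
    "REGION_PRECEDENCE",
]

#: Precedence used to resolve a single label in exclusive annotation mode.
REGION_PRECEDENCE = ("UTR3", "CDS", "UTR5", "noncoding", "intron", "downstream")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def midpoint(self) -> int:
        """Midpoint position; even lengths round toward the 5' end."""
        lo = self.start + (self.length - 1) // 2
        hi = self.start + self.length // 2
        return lo if self.strand == "+" else hi


def _merge_sorted(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """Union gene model: exon structure, CDS/UTR partition, downstream span.

    ``exons`` are non-overlapping and stored in genomic coordinate order;
    UTR assignment respects the strand (the 3'UTR of a minus-strand gene
    lies at the lower genomic coordinates).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds: list[GenomicInterval] = field(default_factory=list)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    introns: list[GenomicInterval] = field(default_factory=list)
    downstream_ext: GenomicInterval | None = None

    @property
    def tx_start(self) -> int:
        return self.exons[0].start

    @property
    def tx_end(self) -> int:
        return self.exons[-1].end

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> GenomicInterval:
        """Extended gene span: transcript plus the downstream extension."""
        lo, hi = self.tx_start, self.tx_end
        if self.downstream_ext is not None:
            lo = min(lo, self.downstream_ext.start)
            hi = max(hi, self.downstream_ext.end)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def region_intervals(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {
            "UTR3": self.utr3,
            "CDS": self.cds,
            "UTR5": self.utr5,
            "intron": self.introns,
        }
        if not self.is_coding:
            out["noncoding"] = self.exons
        if self.downstream_ext is not None:
            out["downstream"] = [self.downstream_ext]
        return out

    @classmethod
    def from_exons(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        exons: Sequence[tuple[int, int]],
        cds_span: tuple[int, int] | None = None,
        downstream: int = 10_000,
    ) -> "GeneModel":
        """Build a gene model from exon blocks and a genomic CDS span.

        ``cds_span`` follows the BED12 thickStart/thickEnd convention:
        ``None`` or an empty span marks a noncoding gene.
        """
        ex = sorted((int(s), int(e)) for s, e in exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{gene_id}: overlapping exons [{s1},{e1}) and [{s2},{e2})"
                )
        exon_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in ex]
        introns = [
            GenomicInterval(chrom, e1, s2, strand)
            for (_, e1), (s2, _) in zip(ex, ex[1:])
            if s2 > e1
        ]

        cds: list[GenomicInterval] = []
        left: list[GenomicInterval] = []  # exonic parts 5' of CDS in + orientation
        right: list[GenomicInterval] = []
        if cds_span is not None and cds_span[1] > cds_span[0]:
            cs, ce = cds_span
            for s, e in ex:
                if e > cs and s < ce:
                    cds.append(GenomicInterval(chrom, max(s, cs), min(e, ce), strand))
                if s < cs:
                    left.append(GenomicInterval(chrom, s, min(e, cs), strand))
                if e > ce:
                    right.append(GenomicInterval(chrom, max(s, ce), e, strand))
        utr5, utr3 = (left, right) if strand == "+" else (right, left)

        tx_start, tx_end = ex[0][0], ex[-1][1]
        ext = None
        if downstream > 0:
            if strand == "+":
                ext = GenomicInterval(chrom, tx_end, tx_end + downstream, strand)
            elif tx_start > 0:
                ext = GenomicInterval(chrom, max(0, tx_start - downstream), tx_start, strand)
        return cls(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=exon_ivs,
            cds=cds,
            utr5=utr5,
            utr3=utr3,
            introns=introns,
            downstream_ext=ext,
        )


def _parse_bed12_line(line: str, lineno: int, downstream: int) -> GeneModel:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"line {lineno}: BED12 requires 12 fields, got {len(f)}")
    try:
        chrom, start, end = f[0], int(f[1]), int(f[2])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 record: {exc}") from exc
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"line {lineno}: blockCount disagrees with block lists")
    exons = [(start + o, start + o + sz) for o, sz in zip(starts, sizes)]
    if exons[0][0] != start or exons[-1][1] != end:
        raise ValueError(f"line {lineno}: blocks do not span chromStart..chromEnd")
    cds_span = (thick_start, thick_end) if thick_end > thick_start else None
    return GeneModel.from_exons(name, chrom, strand, exons, cds_span, downstream)


def load_gene_models(
    path,
    format: str = "BED12",
    downstream: int = 10_000,
) -> dict[str, GeneModel]:
    """Load gene models from a BED12 or GTF annotation file.

    Multiple transcripts sharing a gene id are collapsed to a union model:
    union of exons, CDS taken from the longest coding transcript.  GTF
    coordinates (1-based inclusive) are converted to 0-based half-open on
    read.
    """
    fmt = format.upper()
    if fmt == "BED12":
        raw: list[GeneModel] = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                raw.append(_parse_bed12_line(line, lineno, downstream))
        return _collapse_isoforms(raw, downstream)
    if fmt == "GTF":
        return _load_gtf(path, downstream)
    raise ValueError(f"unknown annotation format {format!r}")


def _load_gtf(path, downstream: int) -> dict[str, GeneModel]:
    # pyranges converts GTF 1-based inclusive coords to 0-based half-open
    import pyranges as pr

    df = pr.read_gtf(path).df
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: GTF records lack a gene_id attribute")
    if "transcript_id" not in df.columns:
        df = df.assign(transcript_id=df["gene_id"])
    df = df[df["Feature"].isin(["exon", "CDS"])]
    models: list[GeneModel] = []
    for (gid, tid), sub in df.groupby(["gene_id", "transcript_id"], sort=True):
        exon_rows = sub[sub["Feature"] == "exon"]
        cds_rows = sub[sub["Feature"] == "CDS"]
        exons = _merge_sorted(
            list(zip(exon_rows["Start"], exon_rows["End"]))
            or list(zip(cds_rows["Start"], cds_rows["End"]))
        )
        cds_span = None
        if len(cds_rows):
            cds_span = (int(cds_rows["Start"].min()), int(cds_rows["End"].max()))
        models.append(
            GeneModel.from_exons(
                str(gid), str(sub["Chromosome"].iloc[0]),
                str(sub["Strand"].iloc[0]), exons, cds_span, downstream,
            )
        )
    return _collapse_isoforms(models, downstream)


def _collapse_isoforms(models: Iterable[GeneModel], downstream: int) -> dict[str, GeneModel]:
    by_gene: dict[str, list[GeneModel]] = {}
    for gm in models:
        by_gene.setdefault(gm.gene_id, []).append(gm)
    out: dict[str, GeneModel] = {}
    for gid, group in by_gene.items():
        if len(group) == 1:
            out[gid] = group[0]
            continue
        exons = _merge_sorted([(e.start, e.end) for gm in group for e in gm.exons])
        coding = [gm for gm in group if gm.is_coding]
        cds_span = None
        if coding:
            best = max(coding, key=lambda gm: sum(c.length for c in gm.cds))
            cds_span = (best.cds[0].start, best.cds[-1].end)
        out[gid] = GeneModel.from_exons(
            gid, group[0].chrom, group[0].strand, exons, cds_span, downstream
        )
    return out


def assign_region(
    iv: GenomicInterval, gm: GeneModel, mode: str = "non_exclusive"
) -> set[str]:
    """Label the gene-model regions an interval overlaps.

    ``non_exclusive`` returns every overlapped region; ``exclusive``
    resolves to the single highest-precedence label
    (UTR3 > CDS > UTR5 > intron > downstream).  ``{"none"}`` marks an
    interval overlapping no region of the extended gene span.
    """
    if iv.chrom != gm.chrom or iv.strand != gm.strand:
        raise ValueError(
            f"interval {iv.chrom}{iv.strand} not on gene "
            f"{gm.gene_id} ({gm.chrom}{gm.strand})"
        )
    hit = {
        label
        for label, ivs in gm.region_intervals().items()
        for reg in ivs
        if iv.overlaps(reg)
    }
    if not hit:
        return {"none"}
    if mode == "non_exclusive":
        return hit
    if mode == "exclusive":
        for label in REGION_PRECEDENCE:
            if label in hit:
                return {label}
        return {"none"}
    raise ValueError(f"mode must be exclusive or non_exclusive, got {mode!r}")


def distance_to_transcript_end(iv: GenomicInterval, gm: GeneModel) -> int:
    """Signed offset of the interval midpoint from the annotated 3' end.

    Measured in transcript orientation: negative values lie upstream of the
    3'-terminal base, positive values downstream.  The midpoint of an
    even-length interval rounds toward the 5' end.
    """
    if iv.chrom != gm.chrom or iv.strand != gm.strand:
        raise ValueError("interval and gene on different chrom/strand")
    mid = iv.midpoint()
    if gm.strand == "+":
        return mid - (gm.tx_end - 1)
    return gm.tx_start - mid


def write_regions_bed(models: Iterable[GeneModel], path) -> None:
    """Write the derived region structure as a BED6 track (score unused)."""
    with open(path, "w") as fh:
        for gm in models:
            for label, ivs in gm.region_intervals().items():
                for reg in ivs:
                    fh.write(
                        f"{reg.chrom}\t{reg.start}\t{reg.end}\t"
                        f"{gm.gene_id}:{label}\t0\t{reg.strand}\n"
                    )
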