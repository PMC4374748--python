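"""Gene models, promoter windows and peak-to-promoter assignment.

Each gene is collapsed to a *unique gene model*: the per-base union of the
exons of all its annotated isoforms, merged into a single virtual mRNA. The
transcription start site (TSS) of that model — the 5'-most merged-exon
boundary on the gene's strand — defines the gene's promoter, a fixed window
spanning 500 bp upstream to 50 bp downstream of the TSS by default.
ChIP-seq peaks overlapping such windows by at least one base are assigned
to the corresponding genes; one peak may serve several genes (divergent
promoter pairs) and those assignments are kept separate.

All coordinates are 0-based half-open internally. Browser-style region
strings like ``"chr17:35424724-35424884"`` are treated as 1-based inclusive
and converted on parse.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """Merged-exon model of one gene with a single strand-aware TSS."""

    gene_id: str
    contig: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon in gene {self.gene_id}")
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"exons of gene {self.gene_id} overlap or are unsorted"
                )
            prev_end = end

    @property
    def tss(self) -> int:
        """0-based TSS: min exon start on +, max exon end − 1 on −."""
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1] - 1


@dataclasses.dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    contig: str
    interval: Interval
    strand: str


@dataclasses.dataclass(frozen=True)
class Peak:
    peak_id: str
    contig: str
    interval: Interval
    score: float | None = None

    def __post_init__(self):
        if not self.contig:
            raise ValueError("peak contig must be non-empty")
        if self.interval[1] <= self.interval[0]:
            raise ValueError(f"peak {self.peak_id} has an empty interval")
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be non-negative")


_REGION_RE = re.compile(r"^(?P<contig>[^:]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chr:start-end`` string to 0-based half-open."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValueError(f"cannot parse region string {region!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    if start < 1 or end < start:
        raise ValueError(f"invalid coordinates in region string {region!r}")
    return m.group("contig"), start - 1, end


def merge_intervals(intervals: Iterable[Interval]) -> tuple[Interval, ...]:
    """Union of integer intervals, returned sorted and disjoint."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for start, end in ivs:
        if end <= start:
            continue
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return tuple((s, e) for s, e in merged)


def parse_gene_models(annotation) -> list[GeneModel]:
    """Build unique gene models from a GTF/GFF file.

    ``annotation`` may be a path to a GTF/GFF file or an already-open
    :class:`gffutils.FeatureDB`. For every ``gene_id`` the exons of all its
    isoforms are merged into a single set of disjoint intervals; the TSS
    follows the strand rule. Exon records lacking a strand or gene_id are
    rejected with a logged warning; a gene whose exons fall on more than one
    contig raises an error naming the gene.
    """
    if isinstance(annotation, gffutils.FeatureDB):
        db = annotation
    else:
        db = gffutils.create_db(
            str(annotation),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )

    per_gene: dict[str, dict] = {}
    for feat in db.features_of_type("exon"):
        gene_ids = feat.attributes.get("gene_id")
        if not gene_ids:
            logger.warning("exon at %s:%s-%s lacks gene_id; skipped",
                           feat.seqid, feat.start, feat.end)
            continue
        if feat.strand not in "+-":
            logger.warning("exon of gene %s lacks strand; skipped", gene_ids[0])
            continue
        gid = gene_ids[0]
        rec = per_gene.setdefault(
            gid, {"contig": feat.seqid, "strand": feat.strand, "exons": []}
        )
        if rec["contig"] != feat.seqid:
            raise ValueError(
                f"gene {gid} has exons on multiple contigs "
                f"({rec['contig']} and {feat.seqid})"
            )
        # gffutils keeps GFF 1-based inclusive coordinates
        rec["exons"].append((feat.start - 1, feat.end))

    models = []
    for gid, rec in per_gene.items():
        exons = merge_intervals(rec["exons"])
        if not exons:
            logger.warning("gene %s has zero-length exon union; dropped", gid)
            continue
        models.append(
            GeneModel(gene_id=gid, contig=rec["contig"],
                      strand=rec["strand"], exons=exons)
        )
    return models


def promoter_window_from_tss(
    gene_id: str,
    contig: str,
    tss: int,
    strand: str,
    upstream_bp: int = 500,
    downstream_bp: int = 50,
    contig_length: int | None = None,
) -> PromoterWindow:
    """Promoter window around a 0-based TSS.

    On the + strand the window is ``[tss - upstream, tss + downstream)``.
    On the − strand "upstream" means higher coordinates, so the window is
    mirrored: ``[tss - downstream + 1, tss + upstream + 1)``. Both contain
    the TSS and have length ``upstream + downstream`` (before clipping).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window widths must be non-negative")
    if strand == "+":
        start, end = tss - upstream_bp, tss + downstream_bp
    elif strand == "-":
        start, end = tss - downstream_bp + 1, tss + upstream_bp + 1
    else:
        raise ValueError(f"strand must be + or -, got {strand!r}")
    start = max(0, start)
    if contig_length is not None:
        end = min(end, contig_length)
    return PromoterWindow(gene_id=gene_id, contig=contig,
                          interval=(start, end), strand=strand)


def promoter_windows(
    models: Iterable[GeneModel],
    upstream_bp: int = 500,
    downstream_bp: int = 50,
    contig_lengths: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """Promoter windows for a collection of gene models."""
    out = []
    for m in models:
        clen = contig_lengths.get(m.contig) if contig_lengths else None
        out.append(
            promoter_window_from_tss(
                m.gene_id, m.contig, m.tss, m.strand,
                upstream_bp=upstream_bp, downstream_bp=downstream_bp,
                contig_length=clen,
            )
        )
    return out


def assign_peaks_to_promoters(
    peaks: Sequence[Peak], promoters: Sequence[PromoterWindow]
) -> tuple[pd.DataFrame, list[str]]:
    """Assign peaks to every promoter window they overlap by >= 1 base.

    Returns ``(assignments, unassigned_peak_ids)`` where ``assignments`` has
    columns ``peak_id, gene_id, overlap_bp`` sorted by (peak_id, gene_id).
    A peak overlapping several promoters yields several rows and vice versa.
    """
    trees: dict[str, IntervalTree] = {}
    for w in promoters:
        trees.setdefault(w.contig, IntervalTree()).addi(*w.interval, w)

    rows = []
    unassigned = []
    for p in peaks:
        hits = trees.get(p.contig, IntervalTree()).overlap(*p.interval)
        if not hits:
            unassigned.append(p.peak_id)
            continue
        for h in hits:
            overlap = min(p.interval[1], h.end) - max(p.interval[0], h.begin)
            rows.append((p.peak_id, h.data.gene_id, overlap))
    table = pd.DataFrame(rows, columns=["peak_id", "gene_id", "overlap_bp"])
    table = table.sort_values(["peak_id", "gene_id"]).reset_index(drop=True)
    return table, sorted(unassigned)


# -- BED I/O --------------------------------------------------------------


def read_peaks_bed(path) -> list[Peak]:
    """Read peaks from a BED file (0-based half-open; name/score optional)."""
    peaks = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            name = fields[3] if len(fields) > 3 else f"peak_{i + 1}"
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(
                Peak(peak_id=name, contig=fields[0],
                     interval=(int(fields[1]), int(fields[2])), score=score)
            )
    return peaks


def write_windows_bed(windows: Sequence[PromoterWindow], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(
                f"{w.contig}\t{w.interval[0]}\t{w.interval[1]}\t"
                f"{w.gene_id}\t0\t{w.strand}\n"
            )


def read_windows_bed(path) -> list[PromoterWindow]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                PromoterWindow(gene_id=f[3], contig=f[0],
                               interval=(int(f[1]), int(f[2])), strand=f[5])
            )
    return out
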