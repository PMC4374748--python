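"""Genome-wide spacing-constrained search for complete S–X–Y modules.

A module match is any placement of the three motifs, on either strand,
where every normalized PWM score reaches its model threshold and both
inter-motif gaps (S→X and X→Y, measured end-to-start) fall inside the
authorized ranges, inclusive at both ends. Candidates sharing the same X
placement and strand are collapsed to the best-scoring triple, and
palindromic double counts — the same X interval matched on both strands —
are collapsed keeping the strand with the higher X score.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import PromoterWindow
from .discovery import ModuleModel
from .pwm import encode, revcomp

Interval = tuple[int, int]


@dataclasses.dataclass(frozen=True)
class ModuleMatch:
    """One accepted S–X–Y placement in genome coordinates (0-based)."""

    contig: str
    strand: str
    s_interval: Interval
    x_interval: Interval
    y_interval: Interval
    scores: tuple[float, float, float]
    spacing_sx: int
    spacing_xy: int

    @property
    def span(self) -> Interval:
        lo = min(self.s_interval[0], self.x_interval[0], self.y_interval[0])
        hi = max(self.s_interval[1], self.x_interval[1], self.y_interval[1])
        return lo, hi


def _best_flank(
    scores: np.ndarray,
    starts: np.ndarray,
    threshold: float,
) -> tuple[int, float] | None:
    """Best candidate among flank placements; ties → leftmost start."""
    valid = (
        (starts >= 0)
        & (starts < scores.size)
    )
    if not valid.any():
        return None
    st = starts[valid]
    sc = scores[st]
    ok = ~np.isnan(sc) & (sc >= threshold)
    if not ok.any():
        return None
    st, sc = st[ok], sc[ok]
    order = np.lexsort((st, -sc))
    j = order[0]
    return int(st[j]), float(sc[j])


def _scan_strand(seq: str, model: ModuleModel) -> list[dict]:
    """Scan the forward strand of ``seq``; offsets are on that strand."""
    codes = encode(seq)
    ws, wx, wy = model.pwm_s.width, model.pwm_x.width, model.pwm_y.width
    s_scores = model.pwm_s.score_all(codes)
    x_scores = model.pwm_x.score_all(codes)
    y_scores = model.pwm_y.score_all(codes)
    if x_scores.size == 0:
        return []

    sx_lo, sx_hi = model.spacing_sx
    xy_lo, xy_hi = model.spacing_xy
    sx_gaps = np.arange(sx_lo, sx_hi + 1)
    xy_gaps = np.arange(xy_lo, xy_hi + 1)

    hits = []
    with np.errstate(invalid="ignore"):
        x_pos = np.nonzero(~np.isnan(x_scores)
                           & (x_scores >= model.threshold_x))[0]
    for x in x_pos:
        s_hit = _best_flank(s_scores, x - sx_gaps - ws, model.threshold_s)
        if s_hit is None:
            continue
        y_hit = _best_flank(y_scores, x + wx + xy_gaps, model.threshold_y)
        if y_hit is None:
            continue
        s_start, s_sc = s_hit
        y_start, y_sc = y_hit
        hits.append({
            "s": (s_start, s_start + ws),
            "x": (int(x), int(x) + wx),
            "y": (y_start, y_start + wy),
            "scores": (s_sc, float(x_scores[x]), y_sc),
            "sx": int(x) - (s_start + ws),
            "xy": y_start - (int(x) + wx),
        })
    return hits


def scan_for_modules(
    genome: Mapping[str, str], model: ModuleModel
) -> list[ModuleMatch]:
    """Find all accepted S–X–Y modules on both strands of every contig.

    Matches are returned sorted by contig, then X-interval start. Windows
    containing non-ACGT characters are skipped.
    """
    matches: list[ModuleMatch] = []
    for contig in sorted(genome):
        seq = genome[contig]
        length = len(seq)
        per_x: dict[Interval, ModuleMatch] = {}
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for hit in _scan_strand(s, model):
                if strand == "+":
                    s_iv, x_iv, y_iv = hit["s"], hit["x"], hit["y"]
                else:
                    s_iv = (length - hit["s"][1], length - hit["s"][0])
                    x_iv = (length - hit["x"][1], length - hit["x"][0])
                    y_iv = (length - hit["y"][1], length - hit["y"][0])
                match = ModuleMatch(
                    contig=contig, strand=strand,
                    s_interval=s_iv, x_interval=x_iv, y_interval=y_iv,
                    scores=hit["scores"],
                    spacing_sx=hit["sx"], spacing_xy=hit["xy"],
                )
                prev = per_x.get(x_iv)
                # palindromic double count: keep the higher X score
                if prev is None or match.scores[1] > prev.scores[1]:
                    per_x[x_iv] = match
        matches.extend(
            sorted(per_x.values(), key=lambda m: m.x_interval)
        )
    return matches


def annotate_matches(
    matches: Sequence[ModuleMatch],
    promoters: Sequence[PromoterWindow],
) -> pd.DataFrame:
    """Label matches TSS-proximal (S-to-Y span overlaps a promoter) or distal.

    Returns a table with one row per match: coordinates, scores, spacings,
    ``proximal`` flag and comma-joined ``gene_ids`` of overlapped promoters.
    """
    by_contig: dict[str, list[PromoterWindow]] = {}
    for w in promoters:
        by_contig.setdefault(w.contig, []).append(w)

    rows = []
    for m in matches:
        lo, hi = m.span
        genes = sorted(
            w.gene_id
            for w in by_contig.get(m.contig, [])
            if w.interval[0] < hi and lo < w.interval[1]
        )
        rows.append({
            "contig": m.contig,
            "strand": m.strand,
            "span_start": lo,
            "span_end": hi,
            "s_start": m.s_interval[0], "s_end": m.s_interval[1],
            "x_start": m.x_interval[0], "x_end": m.x_interval[1],
            "y_start": m.y_interval[0], "y_end": m.y_interval[1],
            "score_s": m.scores[0], "score_x": m.scores[1],
            "score_y": m.scores[2],
            "spacing_sx": m.spacing_sx, "spacing_xy": m.spacing_xy,
            "proximal": bool(genes),
            "gene_ids": ",".join(genes),
        })
    return pd.DataFrame(rows)


def matches_to_bed12(matches: Sequence[ModuleMatch], path) -> None:
    """Write matches as BED12 records with S, X, Y as the three blocks."""
    with open(path, "w") as fh:
        for i, m in enumerate(matches):
            lo, hi = m.span
            blocks = sorted([m.s_interval, m.x_interval, m.y_interval])
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - lo) for s, _ in blocks)
            score = int(round(1000 * min(m.scores)))
            fh.write(
                f"{m.contig}\t{lo}\t{hi}\tmodule_{i + 1}\t{score}\t"
                f"{m.strand}\t{lo}\t{hi}\t0\t3\t{sizes}\t{starts}\n"
            )


def matches_to_tsv(matches: Sequence[ModuleMatch], path) -> None:
    annotate_matches(matches, []).drop(
        columns=["proximal", "gene_ids"]
    ).to_csv(path, sep="\t", index=False)
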