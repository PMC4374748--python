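"""Anchored de-novo discovery of the tripartite S–X–Y promoter module.

The procedure mirrors how composite MHC-promoter modules are derived from a
small set of promoter-proximal ChIP-seq peak sequences:

1. an anchor motif (the X box) is discovered de novo on both strands with a
   zero-or-one-occurrence-per-sequence (ZOOPS) EM model;
2. every peak sequence is oriented so its best X occurrence lies on the
   forward strand;
3. the flanking S and Y motifs are discovered within fixed windows (60 bp
   by default, 100 bp for a relaxed search) measured from the center of the
   X box, upstream and downstream respectively;
4. the three PWMs, per-motif score thresholds set to 95% of the minimum
   training-occurrence score, and inter-motif spacing ranges widened by
   ±5 nt around the observed extremes are assembled into a
   :class:`ModuleModel` that drives the genome-wide scan.

Inter-motif "spacing" is the gap in bp between the end of the upstream
motif and the start of the downstream motif. The 60/100-bp search windows
are measured from the X-box center, as is conventional for these modules.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import jensenshannon

from .pwm import PWM, UNIFORM_BACKGROUND, encode, pwm_from_counts, revcomp

logger = logging.getLogger(__name__)

DEFAULT_WIDTHS = {"S": 7, "X": 14, "Y": 10}


@dataclasses.dataclass(frozen=True)
class MotifOccurrence:
    """Best occurrence of a motif on one (possibly re-oriented) sequence."""

    seq_id: str
    motif: str
    offset: int
    strand_flip: bool
    score: float
    width: int


@dataclasses.dataclass
class ModuleModel:
    """Three PWMs plus score thresholds and authorized spacing ranges."""

    pwm_s: PWM
    pwm_x: PWM
    pwm_y: PWM
    threshold_s: float
    threshold_x: float
    threshold_y: float
    spacing_sx: tuple[int, int]
    spacing_xy: tuple[int, int]
    window_bp: int
    provenance: list = dataclasses.field(default_factory=list)

    def pwm(self, motif: str) -> PWM:
        return {"S": self.pwm_s, "X": self.pwm_x, "Y": self.pwm_y}[motif]

    def threshold(self, motif: str) -> float:
        return {
            "S": self.threshold_s, "X": self.threshold_x, "Y": self.threshold_y
        }[motif]

    def to_dict(self) -> dict:
        def _pwm(p: PWM) -> dict:
            return {
                "name": p.name,
                "matrix": p.matrix.tolist(),
                "pseudocount": p.pseudocount,
                "background": p.background.tolist(),
            }

        return {
            "pwms": {"S": _pwm(self.pwm_s), "X": _pwm(self.pwm_x),
                     "Y": _pwm(self.pwm_y)},
            "thresholds": {"S": self.threshold_s, "X": self.threshold_x,
                           "Y": self.threshold_y},
            "spacing_sx": list(self.spacing_sx),
            "spacing_xy": list(self.spacing_xy),
            "window_bp": self.window_bp,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleModel":
        def _pwm(dd: dict) -> PWM:
            return PWM(name=dd["name"], matrix=np.array(dd["matrix"]),
                       pseudocount=dd["pseudocount"],
                       background=np.array(dd["background"]))

        return cls(
            pwm_s=_pwm(d["pwms"]["S"]), pwm_x=_pwm(d["pwms"]["X"]),
            pwm_y=_pwm(d["pwms"]["Y"]),
            threshold_s=d["thresholds"]["S"],
            threshold_x=d["thresholds"]["X"],
            threshold_y=d["thresholds"]["Y"],
            spacing_sx=tuple(d["spacing_sx"]),
            spacing_xy=tuple(d["spacing_xy"]),
            window_bp=d["window_bp"],
            provenance=d.get("provenance", []),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "ModuleModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# -- ZOOPS EM -------------------------------------------------------------


class _Candidates:
    """Enumerated N-free candidate windows of one sequence."""

    __slots__ = ("windows", "offsets", "strands")

    def __init__(self, codes: np.ndarray, width: int, both_strands: bool):
        wins, offs, strands = [], [], []
        if codes.size >= width:
            sw = np.lib.stride_tricks.sliding_window_view(codes, width)
            valid = (sw >= 0).all(axis=1)
            idx = np.nonzero(valid)[0]
            if idx.size:
                wins.append(sw[idx])
                offs.append(idx)
                strands.append(np.zeros(idx.size, dtype=np.int8))
                if both_strands:
                    wins.append(3 - sw[idx][:, ::-1])  # reverse complement
                    offs.append(idx)
                    strands.append(np.ones(idx.size, dtype=np.int8))
        if wins:
            self.windows = np.concatenate(wins)
            self.offsets = np.concatenate(offs)
            self.strands = np.concatenate(strands)
        else:
            self.windows = np.empty((0, width), dtype=codes.dtype)
            self.offsets = np.empty(0, dtype=int)
            self.strands = np.empty(0, dtype=np.int8)

    def __len__(self) -> int:
        return self.windows.shape[0]


def _e_step(
    cands: list[_Candidates],
    log_theta: np.ndarray,
    gamma: float,
    log_bg: np.ndarray,
    want_counts: bool = True,
):
    """One E pass; returns (ll, counts, sum of occurrence posteriors, qs)."""
    width = log_theta.shape[0]
    ks = np.arange(width)
    counts = np.zeros((width, 4)) if want_counts else None
    gamma_acc = 0.0
    ll = 0.0
    qs = np.empty(len(cands))
    for i, c in enumerate(cands):
        m = len(c)
        log_lr = (log_theta[ks[None, :], c.windows]
                  - log_bg[c.windows]).sum(axis=1)
        a = (gamma / m) * np.exp(log_lr)
        denom = (1.0 - gamma) + a.sum()
        z = a / denom
        ll += np.log(denom)
        qs[i] = z.sum()
        gamma_acc += qs[i]
        if want_counts:
            for k in range(width):
                np.add.at(counts[k], c.windows[:, k], z)
    return ll, counts, gamma_acc, qs


def _zoops_em_once(
    cands: list[_Candidates],
    width: int,
    theta0: np.ndarray,
    background: np.ndarray,
    pseudocount: float,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, float]:
    """One EM run; returns (theta, gamma, penalized log-likelihood).

    The pseudocount makes the M-step a MAP update under a Dirichlet prior,
    so the monotone quantity is the penalized log-likelihood (data term up
    to the constant background factor, plus the prior term); it is asserted
    to be non-decreasing at every iteration.
    """
    theta = theta0.copy()
    gamma = 0.5
    log_bg = np.log(background)
    prev_obj = -np.inf
    for _ in range(max_iter):
        log_theta = np.log(theta)
        ll, counts, gamma_acc, _ = _e_step(cands, log_theta, gamma, log_bg)
        obj = ll + pseudocount * log_theta.sum()
        assert obj >= prev_obj - 1e-9 * max(1.0, abs(prev_obj)), (
            "EM penalized log-likelihood decreased"
        )
        converged = obj - prev_obj < tol * max(1.0, abs(obj))
        prev_obj = obj
        theta = counts + pseudocount
        theta /= theta.sum(axis=1, keepdims=True)
        gamma = float(np.clip(gamma_acc / len(cands), 1e-4, 1 - 1e-4))
        if converged:
            break
    return theta, gamma, prev_obj


def _as_mapping(sequences) -> dict[str, str]:
    if isinstance(sequences, Mapping):
        return dict(sequences)
    return {f"seq_{i:04d}": s for i, s in enumerate(sequences)}


def _best_occurrence(
    seq_id: str, pwm: PWM, codes: np.ndarray, both_strands: bool
) -> MotifOccurrence | None:
    """Best-scoring window; ties → smallest offset, then forward strand."""
    fwd = pwm.score_all(codes)
    rev = pwm.reverse_complement().score_all(codes) if both_strands else None
    best = None  # (score, offset, flip)
    for scores, flip in ((fwd, False), (rev, True)):
        if scores is None or scores.size == 0:
            continue
        ok = ~np.isnan(scores)
        if not ok.any():
            continue
        off = int(np.nanargmax(scores))
        cand = (float(scores[off]), off, flip)
        if best is None or (cand[0], -cand[1], not cand[2]) > (
            best[0], -best[1], not best[2]
        ):
            best = cand
    if best is None:
        return None
    return MotifOccurrence(seq_id=seq_id, motif=pwm.name, offset=best[1],
                           strand_flip=best[2], score=best[0],
                           width=pwm.width)


def _run_discovery(
    seqs: dict[str, str],
    name: str,
    width: int,
    n_starts: int,
    seed: int,
    both_strands: bool,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> tuple[PWM, list[MotifOccurrence]]:
    if width < 4:
        raise ValueError(f"motif width must be >= 4, got {width}")
    background = UNIFORM_BACKGROUND if background is None else background
    usable = {}
    for sid, s in seqs.items():
        if len(s) < width:
            logger.warning("sequence %s shorter than motif width; skipped", sid)
            continue
        usable[sid] = s
    if not usable:
        raise ValueError("all sequences are shorter than the motif width")
    if len(usable) < 2:
        raise ValueError("motif discovery needs at least 2 usable sequences")

    codes = {sid: encode(s) for sid, s in usable.items()}
    cand_map: dict[str, _Candidates] = {}
    for sid in usable:
        c = _Candidates(codes[sid], width, both_strands)
        if len(c):
            cand_map[sid] = c
        else:
            logger.warning("sequence %s has no N-free window; skipped", sid)
    cands = list(cand_map.values())
    if len(cands) < 2:
        raise ValueError("fewer than 2 sequences have N-free windows")

    rng = np.random.default_rng(seed)
    all_windows = np.concatenate([c.windows for c in cands])
    log_bg = np.log(np.asarray(background, dtype=float))

    # Candidate seeds: rank a large random sample of data windows by the
    # one-pass likelihood of a matrix centred on each, then refine only
    # the most promising ones by full EM. A uniformly random start almost
    # never lands on a motif instance, so unranked restarts converge to
    # shifted local optima.
    n_seed = max(50, 10 * n_starts)
    seed_idx = rng.integers(len(all_windows), size=n_seed)
    seed_lls = np.empty(n_seed)
    thetas = []
    for j, idx in enumerate(seed_idx):
        theta0 = np.full((width, 4), 0.4 / 3)
        theta0[np.arange(width), all_windows[idx]] = 0.6
        thetas.append(theta0)
        ll, _, _, _ = _e_step(cands, np.log(theta0), 0.5, log_bg,
                              want_counts=False)
        seed_lls[j] = ll
    top = np.argsort(-seed_lls, kind="stable")[:n_starts]

    best = None
    for j in top:
        theta, gamma, obj = _zoops_em_once(
            cands, width, thetas[j], background, pseudocount,
            max_iter=max_iter, tol=tol,
        )
        if best is None or obj > best[2]:
            best = (theta, gamma, obj)

    # column-shift refinement: restart EM from the winning matrix shifted
    # by one column in each direction to escape off-register local optima
    for _ in range(6):
        improved = False
        for s in (-1, 1):
            shifted = np.full((width, 4), 0.25)
            if s > 0:
                shifted[s:] = best[0][:-s]
            else:
                shifted[:s] = best[0][-s:]
            theta, gamma, obj = _zoops_em_once(
                cands, width, shifted, background, pseudocount,
                max_iter=max_iter, tol=tol,
            )
            if obj > best[2] + 1e-9:
                best = (theta, gamma, obj)
                improved = True
        if not improved:
            break

    theta, gamma, _ = best
    pwm = PWM(name=name, matrix=theta, pseudocount=pseudocount,
              background=np.asarray(background, dtype=float))
    # keep an occurrence only when the fitted ZOOPS model believes the
    # sequence contains the motif at all (posterior >= 0.5)
    _, _, _, qs = _e_step(cands, np.log(theta), gamma, log_bg,
                          want_counts=False)

    occurrences = []
    for (sid, _), q in zip(cand_map.items(), qs):
        if q < 0.5:
            logger.info("sequence %s: no confident %s occurrence", sid, name)
            continue
        occ = _best_occurrence(sid, pwm, codes[sid], both_strands)
        if occ is not None:
            occurrences.append(occ)
    return pwm, occurrences


def discover_anchor_motif(
    sequences,
    width: int = DEFAULT_WIDTHS["X"],
    n_starts: int = 20,
    seed: int = 0,
    name: str = "X",
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> tuple[PWM, list[MotifOccurrence]]:
    """De-novo anchor (X box) discovery on both strands with ZOOPS EM.

    Runs ``n_starts`` seeded restarts and keeps the highest-likelihood one;
    results are bit-reproducible given ``(seed, n_starts)``. Returns the PWM
    and each sequence's best occurrence.
    """
    seqs = _as_mapping(sequences)
    return _run_discovery(seqs, name, width, n_starts, seed,
                          both_strands=True, pseudocount=pseudocount,
                          background=background)


def orient_peak_sequences(
    sequences,
    x_occurrences: Sequence[MotifOccurrence],
    threshold: float | None = None,
) -> tuple[dict[str, str], list[MotifOccurrence]]:
    """Reverse-complement sequences whose X occurrence is on the − strand.

    After orientation every returned X occurrence lies on the forward
    strand of its (possibly flipped) sequence. Sequences without an
    occurrence, or scoring below ``threshold`` when one is given, are
    excluded with a logged warning. Orienting twice is a no-op.
    """
    seqs = _as_mapping(sequences)
    by_id = {o.seq_id: o for o in x_occurrences}
    oriented: dict[str, str] = {}
    occs: list[MotifOccurrence] = []
    for sid, seq in seqs.items():
        occ = by_id.get(sid)
        if occ is None or (threshold is not None and occ.score < threshold):
            logger.warning("sequence %s has no X occurrence above threshold; "
                           "excluded from orientation", sid)
            continue
        if occ.strand_flip:
            oriented[sid] = revcomp(seq)
            new_off = len(seq) - occ.offset - occ.width
            occs.append(dataclasses.replace(occ, offset=new_off,
                                            strand_flip=False))
        else:
            oriented[sid] = seq
            occs.append(occ)
    return oriented, occs


def discover_flanking_motif(
    oriented_sequences,
    x_occurrences: Sequence[MotifOccurrence],
    side: str,
    window_bp: int = 60,
    width: int | None = None,
    x_width: int = DEFAULT_WIDTHS["X"],
    n_starts: int = 20,
    seed: int = 0,
    pseudocount: float = 0.01,
) -> tuple[PWM, list[MotifOccurrence], dict[str, int]]:
    """Discover the S (upstream) or Y (downstream) motif near the X box.

    The search is restricted to a ``window_bp``-wide window measured from
    the center of each sequence's X box, on the stated side, forward strand
    only (sequences are already oriented). Windows extending beyond a
    sequence are clipped; sequences whose clipped window cannot hold the
    motif are excluded with a logged warning.

    Returns ``(pwm, occurrences, gaps)`` where ``occurrences`` carry offsets
    on the full oriented sequences and ``gaps[seq_id]`` is the number of bp
    between the end of the upstream motif and the start of the downstream
    one (S→X or X→Y, depending on ``side``).
    """
    if side not in ("upstream", "downstream"):
        raise ValueError("side must be 'upstream' or 'downstream'")
    name = "S" if side == "upstream" else "Y"
    if width is None:
        width = DEFAULT_WIDTHS[name]
    seqs = _as_mapping(oriented_sequences)
    by_id = {o.seq_id: o for o in x_occurrences}

    subseqs: dict[str, str] = {}
    window_start: dict[str, int] = {}
    for sid, seq in seqs.items():
        occ = by_id.get(sid)
        if occ is None:
            continue
        # the window's outer bound is measured from the X-box center; the
        # inner bound is the X-box edge so the flank cannot overlap the X
        center = occ.offset + occ.width // 2
        if side == "upstream":
            lo, hi = max(0, center - window_bp), occ.offset
        else:
            lo, hi = occ.offset + occ.width, min(len(seq),
                                                 center + window_bp)
        if hi - lo < width:
            logger.warning("sequence %s has an empty/too-short %s window; "
                           "excluded", sid, side)
            continue
        subseqs[sid] = seq[lo:hi]
        window_start[sid] = lo

    pwm, sub_occs = _run_discovery(subseqs, name, width, n_starts, seed,
                                   both_strands=False,
                                   pseudocount=pseudocount)
    occurrences = []
    gaps: dict[str, int] = {}
    for occ in sub_occs:
        abs_off = occ.offset + window_start[occ.seq_id]
        occurrences.append(dataclasses.replace(occ, offset=abs_off))
        x = by_id[occ.seq_id]
        if side == "upstream":
            gaps[occ.seq_id] = x.offset - (abs_off + width)
        else:
            gaps[occ.seq_id] = abs_off - (x.offset + x.width)
    return pwm, occurrences, gaps


def build_module_model(
    pwm_s: PWM,
    pwm_x: PWM,
    pwm_y: PWM,
    s_occurrences: Sequence[MotifOccurrence],
    x_occurrences: Sequence[MotifOccurrence],
    y_occurrences: Sequence[MotifOccurrence],
    window_bp: int = 60,
) -> ModuleModel:
    """Assemble the module model from complete (S, X, Y) training triplets.

    Thresholds are 95% of the minimum training score per motif; authorized
    spacing ranges are the observed [min, max] gaps widened by 5 nt on each
    side and floored at 0.
    """
    s_by = {o.seq_id: o for o in s_occurrences}
    x_by = {o.seq_id: o for o in x_occurrences}
    y_by = {o.seq_id: o for o in y_occurrences}
    ids = [i for i in x_by if i in s_by and i in y_by]
    if not ids:
        raise ValueError("no complete (S, X, Y) training triplet")

    sx_gaps, xy_gaps, provenance = [], [], []
    for i in ids:
        s, x, y = s_by[i], x_by[i], y_by[i]
        sx = x.offset - (s.offset + pwm_s.width)
        xy = y.offset - (x.offset + pwm_x.width)
        sx_gaps.append(sx)
        xy_gaps.append(xy)
        provenance.append({
            "seq_id": i,
            "offsets": {"S": s.offset, "X": x.offset, "Y": y.offset},
            "scores": {"S": s.score, "X": x.score, "Y": y.score},
            "spacing": {"SX": sx, "XY": xy},
        })

    return ModuleModel(
        pwm_s=pwm_s, pwm_x=pwm_x, pwm_y=pwm_y,
        threshold_s=0.95 * min(s_by[i].score for i in ids),
        threshold_x=0.95 * min(x_by[i].score for i in ids),
        threshold_y=0.95 * min(y_by[i].score for i in ids),
        spacing_sx=(max(0, min(sx_gaps) - 5), max(sx_gaps) + 5),
        spacing_xy=(max(0, min(xy_gaps) - 5), max(xy_gaps) + 5),
        window_bp=window_bp,
        provenance=provenance,
    )


def align_to_reference(
    pwm_x: PWM,
    x_occurrences: Sequence[MotifOccurrence],
    reference: str,
) -> tuple[PWM, list[MotifOccurrence]]:
    """Orient a discovered anchor motif against a known reference.

    A de-novo motif is only defined up to reverse complement; like the
    published practice of recognizing the discovered anchor as "the X
    box", the discovered PWM is compared with the reference consensus at
    the best ungapped alignment in both orientations, and the PWM and its
    occurrences are flipped when the reverse complement agrees better.
    """

    def best_matches(consensus: str) -> int:
        a, b = consensus, reference
        short, long_ = (a, b) if len(a) <= len(b) else (b, a)
        return max(
            sum(x == y for x, y in zip(short, long_[off:off + len(short)]))
            for off in range(len(long_) - len(short) + 1)
        )

    fwd = best_matches(pwm_x.consensus)
    rev = best_matches(revcomp(pwm_x.consensus))
    if rev > fwd:
        pwm_x = pwm_x.reverse_complement()
        x_occurrences = [
            dataclasses.replace(o, strand_flip=not o.strand_flip)
            for o in x_occurrences
        ]
    return pwm_x, list(x_occurrences)


def discover_module(
    sequences,
    widths: Mapping[str, int] | None = None,
    window_bp: int = 60,
    n_starts: int = 20,
    seed: int = 0,
    reference_x: str | None = None,
) -> ModuleModel:
    """Full anchored discovery: X anchor, orientation, S and Y flanks.

    ``reference_x`` optionally fixes the strand of the discovered anchor
    (a de-novo motif is defined only up to reverse complement) against a
    known X-box consensus before the peaks are oriented.
    """
    widths = dict(DEFAULT_WIDTHS, **(widths or {}))
    seqs = _as_mapping(sequences)
    pwm_x, x_occs = discover_anchor_motif(
        seqs, width=widths["X"], n_starts=n_starts, seed=seed)
    if reference_x is not None:
        pwm_x, x_occs = align_to_reference(pwm_x, x_occs, reference_x)
    oriented, x_occs = orient_peak_sequences(seqs, x_occs)
    pwm_s, s_occs, _ = discover_flanking_motif(
        oriented, x_occs, "upstream", window_bp=window_bp,
        width=widths["S"], x_width=widths["X"], n_starts=n_starts,
        seed=seed + 1)
    pwm_y, y_occs, _ = discover_flanking_motif(
        oriented, x_occs, "downstream", window_bp=window_bp,
        width=widths["Y"], x_width=widths["X"], n_starts=n_starts,
        seed=seed + 2)
    return build_module_model(pwm_s, pwm_x, pwm_y, s_occs, x_occs, y_occs,
                              window_bp=window_bp)


# -- model comparison -----------------------------------------------------


def _best_alignment_jsd(a: PWM, b: PWM) -> tuple[np.ndarray, int]:
    """Per-position JSD at the best full-overlap ungapped alignment."""
    short, long_, sign = (a, b, 1) if a.width <= b.width else (b, a, -1)
    best_prof, best_off = None, 0
    for off in range(long_.width - short.width + 1):
        prof = np.array([
            jensenshannon(short.matrix[k], long_.matrix[off + k], base=2) ** 2
            for k in range(short.width)
        ])
        if best_prof is None or prof.mean() < best_prof.mean():
            best_prof, best_off = prof, off
    return best_prof, sign * best_off


def compare_module_consensus(model_a: ModuleModel, model_b: ModuleModel) -> dict:
    """Per-position Jensen–Shannon divergence between two module models.

    For each motif the best ungapped alignment (full overlap of the shorter
    PWM) is used. Returns, per motif, the per-position divergences, their
    mean, and the alignment offset (positive: motif of ``model_a`` is the
    shorter one shifted into ``model_b``'s).
    """
    out = {}
    for motif in "SXY":
        prof, off = _best_alignment_jsd(model_a.pwm(motif),
                                        model_b.pwm(motif))
        out[motif] = {
            "per_position_jsd": prof,
            "mean_jsd": float(prof.mean()),
            "offset": off,
        }
    return out
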