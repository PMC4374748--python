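"""Shared fixtures: a planted-module study and independent scan oracle."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import sxyscan as sx
from sxyscan.pwm import revcomp
from sxyscan.synthetic import H2T_LIKE_SPACING, STRINGENT_SPACINGS


@dataclasses.dataclass
class PlantedStudy:
    genome: dict
    truth: object
    peak_seqs: dict
    model_stringent: object  # 60-bp flank window
    model_relaxed: object    # 100-bp flank window


@pytest.fixture(scope="session")
def planted_study() -> PlantedStudy:
    """200 kb genome, 22 stringent + 2 H2-T-like planted modules (5% mut),
    peak sequences around each site, and fitted 60/100-bp module models."""
    genome = sx.generate_background_genome(1, (200_000,), seed=11)
    spacings = [STRINGENT_SPACINGS[i % 3] for i in range(22)] \
        + [H2T_LIKE_SPACING] * 2
    strands = ["+" if i % 2 == 0 else "-" for i in range(24)]
    genome, truth = sx.plant_modules(genome, spacings, strands,
                                     mutation_rate=0.05, seed=12)
    peak_seqs = {}
    for i, m in enumerate(truth.modules):
        lo = min(m.s_interval[0], m.y_interval[0]) - 150
        hi = max(m.s_interval[1], m.y_interval[1]) + 150
        peak_seqs[f"pk{i}"] = genome[m.contig][lo:hi]
    # like the published workflow, the discovered anchor is recognized as
    # the known X box, fixing the module's strand
    model60 = sx.discover_module(peak_seqs, window_bp=60, n_starts=10,
                                 seed=5, reference_x=sx.synthetic.X_CONSENSUS)
    model100 = sx.discover_module(peak_seqs, window_bp=100, n_starts=10,
                                  seed=5,
                                  reference_x=sx.synthetic.X_CONSENSUS)
    return PlantedStudy(genome=genome, truth=truth, peak_seqs=peak_seqs,
                        model_stringent=model60, model_relaxed=model100)


def exhaustive_scan_oracle(genome, model):
    """Triple-loop reference scanner, independent of the vectorized path.

    Returns {x_interval: (strand, s_start, x_score, y_start)} per contig,
    collapsed over strands by X placement keeping the higher X score.
    """
    ws, wx, wy = (model.pwm_s.width, model.pwm_x.width, model.pwm_y.width)
    out = {}
    for contig in sorted(genome):
        seq0 = genome[contig]
        L = len(seq0)
        per_x = {}
        for strand in "+-":
            seq = seq0 if strand == "+" else revcomp(seq0)

            def score(pwm, i, w):
                win = seq[i:i + w]
                if len(win) < w or any(b not in "ACGT" for b in win):
                    return None
                return pwm.score(win)

            for x in range(L - wx + 1):
                xs = score(model.pwm_x, x, wx)
                if xs is None or xs < model.threshold_x:
                    continue
                best_s = None
                for g in range(model.spacing_sx[0], model.spacing_sx[1] + 1):
                    st = x - g - ws
                    if st < 0:
                        continue
                    v = score(model.pwm_s, st, ws)
                    if v is None or v < model.threshold_s:
                        continue
                    if best_s is None or v > best_s[1] or (
                        v == best_s[1] and st < best_s[0]
                    ):
                        best_s = (st, v)
                if best_s is None:
                    continue
                best_y = None
                for g in range(model.spacing_xy[0], model.spacing_xy[1] + 1):
                    st = x + wx + g
                    v = score(model.pwm_y, st, wy)
                    if v is None or v < model.threshold_y:
                        continue
                    if best_y is None or v > best_y[1] or (
                        v == best_y[1] and st < best_y[0]
                    ):
                        best_y = (st, v)
                if best_y is None:
                    continue
                x_iv = (x, x + wx) if strand == "+" else (L - x - wx, L - x)
                rec = (strand, best_s[0], xs, best_y[0])
                if x_iv not in per_x or xs > per_x[x_iv][2]:
                    per_x[x_iv] = rec
        out[contig] = per_x
    return out
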