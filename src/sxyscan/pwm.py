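"""Position weight matrices and normalized log-probability scoring.

A :class:`PWM` stores per-position nucleotide probabilities for one motif
(S, X or Y box, or anything else). Scores are log-probability sums that are
min–max normalized onto [0, 1]: 0 is the worst possible window under the
matrix, 1 the per-position consensus. On this scale a rule such as "95% of
the minimum training score" is monotone and well defined, which is not true
of raw log-odds (which change sign). All scanning and thresholding in this
package operates on the normalized scale.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from Bio import motifs as bio_motifs
from Bio.Seq import Seq

ALPHABET = "ACGT"

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

UNIFORM_BACKGROUND = np.full(4, 0.25)


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    return _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


@dataclasses.dataclass
class PWM:
    """Per-position nucleotide probability matrix with scoring metadata.

    Parameters
    ----------
    name
        Motif label, conventionally ``"S"``, ``"X"`` or ``"Y"``.
    matrix
        Array of shape ``(width, 4)``; every row sums to 1 and, because a
        pseudocount is always applied when matrices are estimated, every
        entry is strictly positive.
    pseudocount
        The per-cell pseudocount used during estimation (kept for
        provenance; it is already folded into ``matrix``).
    background
        Background nucleotide probabilities (length 4).
    """

    name: str
    matrix: np.ndarray
    pseudocount: float = 0.01
    background: np.ndarray = dataclasses.field(
        default_factory=lambda: UNIFORM_BACKGROUND.copy()
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if self.width < 4:
            raise ValueError(f"PWM width must be >= 4, got {self.width}")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM rows must each sum to 1")
        if np.any(self.matrix <= 0):
            raise ValueError("PWM entries must be strictly positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self._log = np.log(self.matrix)
        self._min_raw = float(self._log.min(axis=1).sum())
        self._max_raw = float(self._log.max(axis=1).sum())

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            matrix=self.matrix[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background.copy(),
        )

    # -- scoring -----------------------------------------------------------

    def _normalize(self, raw: np.ndarray | float):
        span = self._max_raw - self._min_raw
        if span <= 0:  # fully degenerate matrix: every window is consensus
            return np.ones_like(np.asarray(raw, dtype=float)) + 0.0
        return (raw - self._min_raw) / span

    def score(self, window: str) -> float:
        """Normalized score of a single window (length must equal width)."""
        codes = encode(window)
        if codes.size != self.width:
            raise ValueError(
                f"window length {codes.size} != PWM width {self.width}"
            )
        if np.any(codes < 0):
            raise ValueError("window contains non-ACGT characters")
        raw = float(self._log[np.arange(self.width), codes].sum())
        return float(self._normalize(raw))

    def score_all(self, codes: np.ndarray) -> np.ndarray:
        """Normalized scores at every offset of an encoded sequence.

        Returns an array of length ``len(codes) - width + 1``; offsets whose
        window contains a non-ACGT character are NaN. Returns an empty array
        when the sequence is shorter than the motif.
        """
        w = self.width
        if codes.size < w:
            return np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(codes, w)
        valid = (windows >= 0).all(axis=1)
        raw = np.full(windows.shape[0], np.nan)
        if valid.any():
            vw = windows[valid]
            raw[valid] = self._log[np.arange(w)[None, :], vw].sum(axis=1)
        out = np.full(windows.shape[0], np.nan)
        out[valid] = self._normalize(raw[valid])
        return out


def pwm_from_counts(
    name: str,
    counts: np.ndarray,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> PWM:
    """Build a PWM from (weighted) nucleotide counts plus a pseudocount."""
    counts = np.asarray(counts, dtype=float) + pseudocount
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return PWM(
        name=name,
        matrix=matrix,
        pseudocount=pseudocount,
        background=UNIFORM_BACKGROUND.copy() if background is None else background,
    )


def pwm_from_sites(
    name: str, sites: Sequence[str], pseudocount: float = 0.01
) -> PWM:
    """Estimate a PWM by stacking aligned, equal-length site sequences."""
    if not sites:
        raise ValueError("need at least one site")
    w = len(sites[0])
    counts = np.zeros((w, 4))
    for s in sites:
        codes = encode(s)
        if codes.size != w:
            raise ValueError("sites must all have equal length")
        if np.any(codes < 0):
            raise ValueError(f"site contains non-ACGT characters: {s}")
        counts[np.arange(w), codes] += 1
    return pwm_from_counts(name, counts, pseudocount=pseudocount)


# -- MEME minimal motif format ------------------------------------------


def write_meme(pwms: Iterable[PWM], path) -> None:
    """Write motifs in MEME minimal format (version 4)."""
    pwms = list(pwms)
    bg = pwms[0].background if pwms else UNIFORM_BACKGROUND
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg)
        )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            # a large nsites keeps parsers that reconstruct integer counts
            # from quantizing the probabilities
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 100000 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list[PWM]:
    """Read motifs from MEME minimal format (via Biopython's parser)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    out = []
    for m in parsed:
        mat = np.column_stack([m.pwm[b] for b in ALPHABET])
        # renormalize away round-tripping noise from fixed-precision text
        mat = np.clip(mat, 1e-9, None)
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.array([m.background[b] for b in ALPHABET])
        out.append(PWM(name=m.name, matrix=mat, background=bg))
    return out
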