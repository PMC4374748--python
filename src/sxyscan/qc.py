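"""ChIP-seq reproducibility and quality metrics.

This layer reimplements, from their published definitions, the quality
metrics used to validate low-peak-count ChIP-seq experiments:

* **strand cross-correlation** — Pearson correlation between the
  strand-specific 5' tag-coverage vectors as the reverse strand is shifted;
  the shift maximizing it (outside a guard band around the read length)
  estimates the fragment length;
* **NSC** (normalized strand coefficient) = cc(fragment) / cc(background),
  with the background taken as the median correlation over the largest 10%
  of shifts; NSC >= 1 by construction;
* **RSC** (relative strand correlation) =
  (cc(fragment) − cc(background)) / (cc(read length) − cc(background));
* **FRiP** — fraction of tag 5' positions falling inside any peak;
* **IDR** — irreproducible discovery rate: a two-component Gaussian
  mixture on rank-derived normal scores of paired peak intensities from
  two replicates (correlated "reproducible" component against independent
  standard-normal noise), fitted by EM; the local idr of a peak pair is
  the posterior probability of the noise component, and peaks are counted
  reproducible when their cumulative (global) IDR is below the threshold.

Tags enter as stranded 5' positions per contig (tagAlign/BED convention:
the 5' end is ``start`` on + and ``end − 1`` on −); only uniquely mapping
reads are assumed, which is an input contract, not enforced here.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Peak


@dataclasses.dataclass
class TagDataset:
    """Sorted stranded 5' tag positions per contig."""

    positions: dict[str, dict[str, np.ndarray]]
    read_length: int
    contig_lengths: dict[str, int] | None = None

    def __post_init__(self):
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        clean: dict[str, dict[str, np.ndarray]] = {}
        for contig, strands in self.positions.items():
            clean[contig] = {}
            for strand in "+-":
                pos = np.sort(
                    np.asarray(strands.get(strand, []), dtype=np.int64)
                )
                if self.contig_lengths and contig in self.contig_lengths:
                    L = self.contig_lengths[contig]
                    if pos.size and (pos[0] < 0 or pos[-1] >= L):
                        raise ValueError(
                            f"tag positions outside contig {contig}"
                        )
                clean[contig][strand] = pos
        self.positions = clean

    @property
    def n_tags(self) -> int:
        return sum(p.size for s in self.positions.values()
                   for p in s.values())

    def iter_tags(self):
        for contig in sorted(self.positions):
            for strand in "+-":
                for p in self.positions[contig][strand]:
                    yield contig, strand, int(p)

    @classmethod
    def from_records(cls, records, read_length: int,
                     contig_lengths=None) -> "TagDataset":
        acc: dict[str, dict[str, list[int]]] = {}
        for contig, strand, pos in records:
            acc.setdefault(contig, {"+": [], "-": []})[strand].append(pos)
        return cls(positions=acc, read_length=read_length,
                   contig_lengths=contig_lengths)

    @classmethod
    def from_bed(cls, path, read_length: int | None = None,
                 contig_lengths=None) -> "TagDataset":
        """Read a tagAlign/BED6 file; 5' = start on +, end − 1 on −."""
        recs = []
        rl = read_length
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                start, end, strand = int(f[1]), int(f[2]), f[5]
                recs.append((f[0], strand,
                             start if strand == "+" else end - 1))
                if rl is None:
                    rl = end - start
        return cls.from_records(recs, read_length=rl or 36,
                                contig_lengths=contig_lengths)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for contig, strand, pos in self.iter_tags():
                if strand == "+":
                    s, e = pos, pos + self.read_length
                else:
                    s, e = pos - self.read_length + 1, pos + 1
                fh.write(f"{contig}\t{s}\t{e}\tN\t1000\t{strand}\n")


def split_pseudo_replicates(
    tags: TagDataset, k: int = 5, n_per_rep: int | None = None,
    seed: int = 0,
) -> list[TagDataset]:
    """Split tags into ``k`` disjoint seeded pseudo-replicates.

    Sampling is without replacement; each replicate receives exactly
    ``n_per_rep`` tags (default: an equal share of the total).
    """
    all_tags = list(tags.iter_tags())
    total = len(all_tags)
    if n_per_rep is None:
        n_per_rep = total // k
    if k * n_per_rep > total:
        raise ValueError(
            f"cannot draw {k} x {n_per_rep} tags from {total} "
            f"(short by {k * n_per_rep - total})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(total)
    reps = []
    for i in range(k):
        chunk = order[i * n_per_rep:(i + 1) * n_per_rep]
        reps.append(TagDataset.from_records(
            (all_tags[j] for j in chunk),
            read_length=tags.read_length,
            contig_lengths=tags.contig_lengths,
        ))
    return reps


@dataclasses.dataclass
class CrossCorrelationProfile:
    shifts: np.ndarray
    correlation: np.ndarray
    fragment_length: int
    nsc: float
    rsc: float

    def cc_at(self, shift: int) -> float:
        return float(self.correlation[np.searchsorted(self.shifts, shift)])


def _coverage(tags: TagDataset, contig: str, strand: str,
              length: int) -> np.ndarray:
    cov = np.zeros(length)
    pos = tags.positions[contig][strand]
    np.add.at(cov, pos, 1.0)
    return cov


def strand_cross_correlation(
    tags: TagDataset, max_shift: int = 400, guard_band: int = 10,
) -> CrossCorrelationProfile:
    """Cross-correlation profile with fragment length, NSC and RSC.

    The Pearson correlation between forward and (shifted) reverse 5'
    coverage is pooled over contigs for each shift in ``[0, max_shift]``.
    The fragment length is the argmax over shifts excluding a
    ``guard_band`` around the read length; the background correlation is
    the median over the largest 10% of shifts.
    """
    n_fwd = sum(tags.positions[c]["+"].size for c in tags.positions)
    n_rev = sum(tags.positions[c]["-"].size for c in tags.positions)
    if n_fwd == 0 or n_rev == 0:
        raise ValueError("both strands must have at least one tag")

    lengths = {}
    for contig in tags.positions:
        if tags.contig_lengths and contig in tags.contig_lengths:
            lengths[contig] = tags.contig_lengths[contig]
        else:
            hi = max((int(p[-1]) for p in tags.positions[contig].values()
                      if p.size), default=0)
            lengths[contig] = hi + max_shift + 1

    covs = {
        c: (_coverage(tags, c, "+", L), _coverage(tags, c, "-", L))
        for c, L in lengths.items()
    }

    shifts = np.arange(0, max_shift + 1)
    corr = np.empty(shifts.size)
    for i, d in enumerate(shifts):
        xs, ys = [], []
        for fwd, rev in covs.values():
            if fwd.size <= d:
                continue
            xs.append(fwd[: fwd.size - d])
            ys.append(rev[d:])
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        sx, sy = x.std(), y.std()
        corr[i] = 0.0 if sx == 0 or sy == 0 else float(
            np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
        )

    rl = tags.read_length
    allowed = np.abs(shifts - rl) > guard_band
    frag_idx = int(np.flatnonzero(allowed)[np.argmax(corr[allowed])])
    fragment_length = int(shifts[frag_idx])

    n_bg = max(1, shifts.size // 10)
    cc_bg = float(np.median(corr[-n_bg:]))
    cc_frag = float(corr[frag_idx])
    rl_idx = min(rl, max_shift)
    cc_rl = float(corr[rl_idx])

    # Denominators are floored at the sampling noise of a null Pearson
    # correlation over this many positions, so a background that happens
    # to sit at (or below) zero yields a large but meaningful ratio.
    eps = 1.0 / np.sqrt(sum(lengths.values()))
    nsc = cc_frag / max(cc_bg, eps)
    rsc = max(0.0, (cc_frag - cc_bg) / max(cc_rl - cc_bg, eps))
    return CrossCorrelationProfile(
        shifts=shifts, correlation=corr,
        fragment_length=fragment_length, nsc=nsc, rsc=rsc,
    )


def compute_frip(tags: TagDataset, peaks: Sequence[Peak]) -> float:
    """Fraction of tag 5' positions falling inside any peak interval."""
    if tags.n_tags == 0:
        raise ValueError("dataset has no tags")
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p.interval)

    inside = 0
    for contig, strands in tags.positions.items():
        ivs = by_contig.get(contig)
        if not ivs:
            continue
        # merge so searchsorted parity works on overlapping peaks
        merged = []
        for s, e in sorted(ivs):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        for strand in "+-":
            pos = strands[strand]
            if pos.size == 0:
                continue
            j = np.searchsorted(starts, pos, side="right") - 1
            ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
            inside += int(ok.sum())
    return inside / tags.n_tags


# -- IDR ------------------------------------------------------------------


class IdrConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, trace):
        super().__init__(
            f"IDR EM did not converge after {len(trace)} iterations"
        )
        self.trace = trace


@dataclasses.dataclass
class IdrResult:
    local_idr: np.ndarray
    global_idr: np.ndarray
    reproducible_fraction: float
    correlation: float
    mean: float
    variance: float
    n_reproducible_at_threshold: int
    threshold: float
    loglik_trace: list[float] = dataclasses.field(default_factory=list)


def _mixture_quantile(u: np.ndarray, pi: float, mu: float,
                      s: float) -> np.ndarray:
    """Inverse CDF of the mixture marginal pi*N(mu, s^2) + (1-pi)*N(0,1)."""
    lo = min(-8.0, mu - 8 * s)
    hi = max(8.0, mu + 8 * s)
    grid = np.linspace(lo, hi, 4001)
    cdf = pi * stats.norm.cdf(grid, loc=mu, scale=s) \
        + (1 - pi) * stats.norm.cdf(grid)
    return np.interp(u, cdf, grid)


def _em_pass(z1, z2, pi, mu, s2, rho, n_iter, tol):
    """EM on pseudo-data for the 2-component Gaussian copula mixture."""
    n = z1.size
    ll = -np.inf
    p_rep = np.full(n, pi)
    for _ in range(n_iter):
        null_logpdf = stats.norm.logpdf(z1) + stats.norm.logpdf(z2)
        det = s2 * s2 * (1 - rho**2)
        d1, d2 = z1 - mu, z2 - mu
        quad = (d1**2 - 2 * rho * d1 * d2 + d2**2) / (s2 * (1 - rho**2))
        rep_logpdf = -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad
        log_num = np.log(pi) + rep_logpdf
        log_den = np.logaddexp(log_num, np.log1p(-pi) + null_logpdf)
        p_rep = np.exp(log_num - log_den)
        new_ll = float(log_den.sum())
        done = abs(new_ll - ll) < tol * max(1.0, abs(new_ll))
        ll = new_ll
        w = p_rep.sum()
        pi = float(np.clip(w / n, 1e-4, 1 - 1e-4))
        mu = float(max((p_rep * (z1 + z2)).sum() / (2 * w), 0.05))
        d1, d2 = z1 - mu, z2 - mu
        s2 = float(max((p_rep * (d1**2 + d2**2)).sum() / (2 * w), 1e-4))
        rho = float(np.clip((p_rep * d1 * d2).sum() / (w * s2), 0.0, 0.999))
        if done:
            break
    return pi, mu, s2, rho, ll, p_rep


def estimate_idr(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    threshold: float = 0.01,
    max_iter: int = 1500,
    tol: float = 1e-6,
) -> IdrResult:
    """Irreproducible discovery rate for paired peak scores.

    ``scores_a[i]`` and ``scores_b[i]`` are the intensities of the same
    peak in two (pseudo-)replicates. The semiparametric Gaussian copula
    mixture is fitted: ranks are mapped to pseudo-data through the inverse
    marginal CDF of the current mixture (a correlated bivariate Gaussian
    "reproducible" component against independent standard-normal noise),
    and the mixture parameters are re-estimated by EM; the two steps are
    alternated to convergence. The local idr of a pair is the posterior
    probability of the noise component; reproducible peaks are counted by
    cumulative (global) IDR at the given threshold. Requires >= 20 pairs.
    """
    x = np.asarray(scores_a, dtype=float)
    y = np.asarray(scores_b, dtype=float)
    n = x.size
    if n < 20 or y.size != n:
        raise ValueError("need >= 20 paired peak scores")

    u1 = (stats.rankdata(x, method="average") - 0.5) / n
    u2 = (stats.rankdata(y, method="average") - 0.5) / n

    # conventional starting values for the copula mixture
    pi, mu, s2, rho = 0.7, 2.6, 1.69, 0.8
    trace: list[float] = []
    converged = False
    p_rep = np.full(n, pi)
    rho_collapsed = 0
    for _ in range(max_iter):
        s = np.sqrt(s2)
        z1 = _mixture_quantile(u1, pi, mu, s)
        z2 = _mixture_quantile(u2, pi, mu, s)
        prev = (pi, mu, s2, rho)
        pi, mu, s2, rho, ll, p_rep = _em_pass(z1, z2, pi, mu, s2, rho,
                                              n_iter=1, tol=tol)
        trace.append(ll)
        if max(abs(a - b) for a, b in zip(prev, (pi, mu, s2, rho))) < 1e-3:
            converged = True
            break
        # once the correlation collapses the remaining parameters drift
        # along a non-identifiable ridge; stop as degenerate-converged
        rho_collapsed = rho_collapsed + 1 if rho < 1e-6 else 0
        if rho_collapsed >= 10:
            converged = True
            break
    if not converged:
        raise IdrConvergenceError(trace)

    local_idr = 1.0 - p_rep
    if rho < 0.2:
        # Without a positively correlated component the mixture is not
        # identifiable from the rank copula (any split of independent
        # data fits equally well), so there is no evidence that any pair
        # is reproducible.
        local_idr = np.ones(n)
    order = np.argsort(local_idr)
    csum = np.cumsum(local_idr[order]) / np.arange(1, n + 1)
    global_idr = np.empty(n)
    global_idr[order] = csum
    return IdrResult(
        local_idr=local_idr,
        global_idr=global_idr,
        reproducible_fraction=pi,
        correlation=rho,
        mean=mu,
        variance=s2,
        n_reproducible_at_threshold=int((global_idr <= threshold).sum()),
        threshold=threshold,
        loglik_trace=trace,
    )


def qc_summary(
    tags: TagDataset,
    peaks: Sequence[Peak],
    max_shift: int = 400,
) -> dict:
    """One-stop QC dictionary: fragment length, NSC, RSC and FRiP."""
    prof = strand_cross_correlation(tags, max_shift=max_shift)
    return {
        "n_tags": tags.n_tags,
        "fragment_length": prof.fragment_length,
        "nsc": prof.nsc,
        "rsc": prof.rsc,
        "frip": compute_frip(tags, peaks),
    }
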