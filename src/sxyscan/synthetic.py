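"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the analysis can be exercised without any external data:

* background genomes of i.i.d. nucleotides at a controlled GC fraction;
* planted S–X–Y module instances at controlled spacings, strands and
  per-base mutation rates, with a machine-readable truth table;
* multi-isoform gene annotations (GTF) so exon merging and TSS extraction
  are testable against a known truth;
* strand-shifted ChIP tag pileups around peak summits with controlled
  fragment length and signal-to-noise for the QC metrics;
* the reporter-construct box-swap utility used for specificity tests,
  with default H2-K / H2-E construct sequences assembled from their
  cloning primer pairs (10-bp overlap merge of the forward primer and the
  reverse-complemented reverse primer, restriction-site extensions
  trimmed).

Default planted geometry follows the stringent module consensus observed
at NLRC5-occupied promoters: S–X gaps drawn from {16}, X–Y gaps from
{20, 21, 22}, plus an optional "H2-T-like" class with an X–Y gap of 48 to
exercise the relaxed 100-bp search window.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np

from .annotation import Peak
from .pwm import ALPHABET, revcomp
from .qc import TagDataset

# stringent-consensus defaults for planted modules
S_CONSENSUS = "CAGTTTC"
X_CONSENSUS = "GGTCAGGTCCTTCT"
Y_CONSENSUS = "CATTGGGTGG"
STRINGENT_SPACINGS = [(16, 20), (16, 21), (16, 22)]
H2T_LIKE_SPACING = (16, 48)


@dataclasses.dataclass
class PlantedModule:
    contig: str
    strand: str
    s_interval: tuple[int, int]
    x_interval: tuple[int, int]
    y_interval: tuple[int, int]
    spacing_sx: int
    spacing_xy: int
    n_mutations: int


@dataclasses.dataclass
class SimulationTruth:
    """Everything needed to verify a synthetic dataset after the fact."""

    seed: int
    modules: list[PlantedModule] = dataclasses.field(default_factory=list)
    genes: list[dict] = dataclasses.field(default_factory=list)
    tag_params: dict = dataclasses.field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "seed": self.seed,
                "modules": [dataclasses.asdict(m) for m in self.modules],
                "genes": self.genes,
                "tag_params": self.tag_params,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            d = json.load(fh)
        modules = [
            PlantedModule(**{
                **m,
                "s_interval": tuple(m["s_interval"]),
                "x_interval": tuple(m["x_interval"]),
                "y_interval": tuple(m["y_interval"]),
            })
            for m in d["modules"]
        ]
        return cls(seed=d["seed"], modules=modules, genes=d["genes"],
                   tag_params=d["tag_params"])


def generate_background_genome(
    n_contigs: int = 1,
    lengths: Sequence[int] = (100_000,),
    gc_fraction: float = 0.42,
    seed: int = 0,
) -> dict[str, str]:
    """I.i.d. nucleotide contigs at the stated GC fraction, seeded."""
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be strictly between 0 and 1")
    if len(lengths) != n_contigs:
        raise ValueError("need one length per contig")
    if any(L <= 0 for L in lengths):
        raise ValueError("contig lengths must be positive")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    probs = [at, gc, gc, at]
    return {
        f"contig_{i + 1}": "".join(
            np.array(list(ALPHABET))[rng.choice(4, size=L, p=probs)]
        )
        for i, L in enumerate(lengths)
    }


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    out = list(seq)
    n_mut = 0
    for i, base in enumerate(out):
        if rng.random() < rate:
            choices = [b for b in ALPHABET if b != base]
            out[i] = choices[rng.integers(3)]
            n_mut += 1
    return "".join(out), n_mut


def plant_modules(
    genome: Mapping[str, str],
    spacings: Sequence[tuple[int, int]],
    strands: Sequence[str] | None = None,
    s_consensus: str = S_CONSENSUS,
    x_consensus: str = X_CONSENSUS,
    y_consensus: str = Y_CONSENSUS,
    mutation_rate: float = 0.0,
    seed: int = 0,
    positions: Sequence[tuple[str, int]] | None = None,
    margin: int = 100,
) -> tuple[dict[str, str], SimulationTruth]:
    """Write one module instance per requested (sx, xy) spacing pair.

    Each instance is ``S + sx spacer + X + xy spacer + Y`` written over the
    background (spacer bases keep the background sequence); per-base
    mutations at ``mutation_rate`` are applied to the motif bases only.
    Minus-strand instances are written reverse-complemented, so the motif
    order is mirrored in genome coordinates. Sites are placed at least
    ``margin`` bp apart (or at the caller-specified ``positions``);
    overlapping sites raise an error.
    """
    if any(sx < 0 or xy < 0 for sx, xy in spacings):
        raise ValueError("spacings must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(spacings)
    strands = list(strands) if strands is not None else ["+"] * n
    if len(strands) != n:
        raise ValueError("need one strand per spacing pair")

    seqs = {c: list(s) for c, s in genome.items()}
    contigs = sorted(genome)
    span_of = lambda sx, xy: (len(s_consensus) + sx + len(x_consensus)
                              + xy + len(y_consensus))

    # choose sites
    sites: list[tuple[str, int, int]] = []  # contig, start, end
    if positions is not None:
        if len(positions) != n:
            raise ValueError("need one position per spacing pair")
        for (contig, start), (sx, xy) in zip(positions, spacings):
            sites.append((contig, start, start + span_of(sx, xy)))
    else:
        for sx, xy in spacings:
            span = span_of(sx, xy)
            for _ in range(1000):
                contig = contigs[rng.integers(len(contigs))]
                limit = len(genome[contig]) - span - margin
                if limit <= margin:
                    continue
                start = int(rng.integers(margin, limit))
                end = start + span
                if all(c != contig or end + margin <= s or e + margin <= start
                       for c, s, e in sites):
                    sites.append((contig, start, end))
                    break
            else:
                raise ValueError("could not place all modules without overlap")
    for i, (c1, s1, e1) in enumerate(sites):
        for c2, s2, e2 in sites[i + 1:]:
            if c1 == c2 and s1 < e2 and s2 < e1:
                raise ValueError("planted sites overlap")
        if s1 < 0 or e1 > len(genome[c1]):
            raise ValueError(f"site outside contig {c1}")

    truth = SimulationTruth(seed=seed)
    ws, wx, wy = len(s_consensus), len(x_consensus), len(y_consensus)
    for (contig, start, end), (sx, xy), strand in zip(sites, spacings,
                                                      strands):
        s_seq, m1 = _mutate(s_consensus, mutation_rate, rng)
        x_seq, m2 = _mutate(x_consensus, mutation_rate, rng)
        y_seq, m3 = _mutate(y_consensus, mutation_rate, rng)
        # forward-orientation coordinates within the site
        s_iv = (start, start + ws)
        x_iv = (start + ws + sx, start + ws + sx + wx)
        y_iv = (x_iv[1] + xy, x_iv[1] + xy + wy)
        if strand == "+":
            for iv, seq in ((s_iv, s_seq), (x_iv, x_seq), (y_iv, y_seq)):
                seqs[contig][iv[0]:iv[1]] = seq
        else:
            # mirror the whole module: motif order Y..X..S in genome coords
            mirror = lambda iv: (start + end - iv[1], start + end - iv[0])
            s_iv, x_iv, y_iv = mirror(s_iv), mirror(x_iv), mirror(y_iv)
            for iv, seq in ((s_iv, s_seq), (x_iv, x_seq), (y_iv, y_seq)):
                seqs[contig][iv[0]:iv[1]] = revcomp(seq)
        truth.modules.append(PlantedModule(
            contig=contig, strand=strand,
            s_interval=s_iv, x_interval=x_iv, y_interval=y_iv,
            spacing_sx=sx, spacing_xy=xy, n_mutations=m1 + m2 + m3,
        ))
    return {c: "".join(s) for c, s in seqs.items()}, truth


def generate_gene_annotations(
    genome: Mapping[str, str],
    n_genes: int = 20,
    isoforms_per_gene: int = 3,
    seed: int = 0,
    gene_length: tuple[int, int] = (600, 3000),
) -> tuple[str, SimulationTruth]:
    """Random multi-isoform genes as GTF text plus a truth TSS table.

    Isoforms of one gene carry overlapping exon sets within a shared gene
    span, on a random strand; the truth records the per-base exon union
    and the strand-aware TSS every parser must recover.
    """
    rng = np.random.default_rng(seed)
    contigs = sorted(genome)
    lines = []
    truth = SimulationTruth(seed=seed)
    for g in range(n_genes):
        contig = contigs[rng.integers(len(contigs))]
        L = len(genome[contig])
        glen = int(rng.integers(*gene_length))
        if L <= glen + 2:
            raise ValueError(
                f"contig {contig} ({L} bp) too short for a {glen} bp gene"
            )
        g0 = int(rng.integers(0, L - glen))
        strand = "+-"[rng.integers(2)]
        gene_id = f"gene_{g + 1:03d}"
        union: set[int] = set()
        for t in range(isoforms_per_gene):
            tx_id = f"{gene_id}.t{t + 1}"
            n_exons = int(rng.integers(1, 5))
            cuts = np.sort(rng.choice(glen, size=2 * n_exons, replace=False))
            for k in range(n_exons):
                es, ee = int(cuts[2 * k]), int(cuts[2 * k + 1])
                if ee == es:
                    continue
                start, end = g0 + es, g0 + ee
                union.update(range(start, end))
                lines.append(
                    f"{contig}\tsim\texon\t{start + 1}\t{end}\t.\t{strand}"
                    f"\t.\tgene_id \"{gene_id}\"; "
                    f"transcript_id \"{tx_id}\";"
                )
        if not union:
            continue
        tss = min(union) if strand == "+" else max(union)
        truth.genes.append({
            "gene_id": gene_id, "contig": contig, "strand": strand,
            "tss": tss, "exon_union_bp": len(union),
        })
    return "\n".join(lines) + "\n", truth


def simulate_chip_tags(
    genome: Mapping[str, str],
    peaks: Sequence[Peak],
    fragment_length: int = 150,
    enrichment: float = 10.0,
    n_tags: int = 100_000,
    read_length: int = 36,
    jitter_sd: float = 15.0,
    artifact_rate: float = 0.02,
    block_bp: int = 5000,
    block_shape: float = 0.5,
    seed: int = 0,
) -> TagDataset:
    """Stranded 5' tag positions with peak signal and realistic background.

    Three tag classes, mirroring the components real ChIP libraries show
    in a strand cross-correlation profile:

    * **signal** (probability ``(1 − artifact_rate)(1 − 1/enrichment)``):
      fragment ends around a random peak's summit (+ strand at
      summit − fragment_length/2, − strand at summit + fragment_length/2,
      Gaussian-jittered), producing the fragment-length peak;
    * **background**: positions drawn from a block-wise non-uniform rate
      (Gamma-distributed rate per ``block_bp`` window, shared between
      strands), giving the positive baseline correlation that real
      coverage biases create at every shift;
    * **artifact** (probability ``artifact_rate``): both-strand tags at
      shared hotspot positions offset by the read length — the
      "phantom peak" at the read length that the RSC denominator needs.

    ``enrichment = 1`` yields no signal tags at all.
    """
    if n_tags <= 0:
        raise ValueError("n_tags must be positive")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    if fragment_length <= read_length:
        raise ValueError("fragment_length must exceed read_length")
    p_enr = 1.0 - 1.0 / enrichment
    if p_enr > 0 and not peaks:
        raise ValueError("enrichment > 1 requires at least one peak")

    rng = np.random.default_rng(seed)
    contigs = sorted(genome)
    lens = np.array([len(genome[c]) for c in contigs], dtype=float)
    contig_p = lens / lens.sum()
    lengths = {c: len(genome[c]) for c in contigs}

    # block-wise background rates, shared between strands
    block_rates = {}
    for c in contigs:
        n_blocks = max(1, -(-lengths[c] // block_bp))
        r = rng.gamma(block_shape, 1.0 / block_shape, size=n_blocks)
        block_rates[c] = r / r.sum()

    # both-strand artifact hotspots
    n_hot = max(10, n_tags // 500)
    hot_contigs = [contigs[i] for i in
                   rng.choice(len(contigs), size=n_hot, p=contig_p)]
    hot_pos = [int(rng.integers(read_length, lengths[c] - read_length))
               for c in hot_contigs]

    records = []
    half = fragment_length // 2
    for _ in range(n_tags):
        strand = "+-"[rng.integers(2)]
        u = rng.random()
        if u < artifact_rate:
            h = rng.integers(n_hot)
            contig = hot_contigs[h]
            pos = hot_pos[h] if strand == "+" else \
                hot_pos[h] + read_length - 1
        elif u < artifact_rate + (1 - artifact_rate) * p_enr:
            pk = peaks[rng.integers(len(peaks))]
            summit = (pk.interval[0] + pk.interval[1]) // 2
            shift = -half if strand == "+" else half
            pos = summit + shift + int(round(rng.normal(0, jitter_sd)))
            contig = pk.contig
        else:
            ci = rng.choice(len(contigs), p=contig_p)
            contig = contigs[ci]
            block = rng.choice(block_rates[contig].size,
                               p=block_rates[contig])
            pos = int(block) * block_bp + int(rng.integers(block_bp))
        pos = int(np.clip(pos, 0, lengths[contig] - 1))
        records.append((contig, strand, pos))
    return TagDataset.from_records(records, read_length=read_length,
                                   contig_lengths=lengths)


def planted_peak_study(
    seed: int,
    n_modules: int = 24,
    n_h2t_like: int = 2,
    genome_length: int = 200_000,
    mutation_rate: float = 0.05,
    flank_bp: int = 150,
) -> tuple[dict[str, str], SimulationTruth, dict[str, str]]:
    """A complete synthetic ChIP-seq study for module discovery.

    Plants ``n_modules`` instances (the last ``n_h2t_like`` with the
    48-bp X–Y gap of the H2-T promoters, the rest at the stringent
    16 / 20–22 geometry) on alternating strands in a background genome,
    and cuts a peak-like sequence of ±``flank_bp`` around each planted
    span. Returns ``(genome, truth, peak_seqs)``.
    """
    genome = generate_background_genome(1, (genome_length,), seed=seed)
    n_stringent = n_modules - n_h2t_like
    spacings = [STRINGENT_SPACINGS[i % len(STRINGENT_SPACINGS)]
                for i in range(n_stringent)] \
        + [H2T_LIKE_SPACING] * n_h2t_like
    strands = ["+" if i % 2 == 0 else "-" for i in range(n_modules)]
    genome, truth = plant_modules(genome, spacings, strands,
                                  mutation_rate=mutation_rate,
                                  seed=seed + 1)
    peak_seqs = {}
    for i, m in enumerate(truth.modules):
        lo = max(0, min(m.s_interval[0], m.y_interval[0]) - flank_bp)
        hi = min(len(genome[m.contig]),
                 max(m.s_interval[1], m.y_interval[1]) + flank_bp)
        peak_seqs[f"peak_{i + 1:02d}"] = genome[m.contig][lo:hi]
    return genome, truth, peak_seqs


# -- reporter-construct box swapping --------------------------------------


@dataclasses.dataclass(frozen=True)
class AnnotatedModule:
    """A promoter-module sequence with S/X/Y box interval annotations."""

    sequence: str
    boxes: dict[str, tuple[int, int]]

    def __post_init__(self):
        prev = 0
        for name in sorted(self.boxes, key=lambda b: self.boxes[b][0]):
            s, e = self.boxes[name]
            if s < prev or e > len(self.sequence) or e <= s:
                raise ValueError(f"box {name} interval invalid or overlapping")
            prev = e

    def box_seq(self, name: str) -> str:
        s, e = self.boxes[name]
        return self.sequence[s:e]


def swap_box(
    module_a: AnnotatedModule,
    module_b: AnnotatedModule,
    boxes_to_swap: set[str] | Sequence[str],
) -> AnnotatedModule:
    """Replace the named boxes of ``module_a`` with ``module_b``'s.

    Flanking and inter-box sequence of ``module_a`` is untouched; box
    interval annotations are updated for any length changes. Swapping no
    boxes returns an identical module; swapping the same boxes back
    restores the original box contents.
    """
    boxes_to_swap = set(boxes_to_swap)
    missing = boxes_to_swap - set(module_a.boxes) | (
        boxes_to_swap - set(module_b.boxes)
    )
    if missing:
        raise ValueError(f"box annotation missing: {sorted(missing)}")

    order = sorted(module_a.boxes, key=lambda b: module_a.boxes[b][0])
    pieces = []
    new_boxes = {}
    cursor = 0
    out_pos = 0
    for name in order:
        s, e = module_a.boxes[name]
        pieces.append(module_a.sequence[cursor:s])
        out_pos += s - cursor
        content = (module_b.box_seq(name) if name in boxes_to_swap
                   else module_a.sequence[s:e])
        pieces.append(content)
        new_boxes[name] = (out_pos, out_pos + len(content))
        out_pos += len(content)
        cursor = e
    pieces.append(module_a.sequence[cursor:])
    return AnnotatedModule(sequence="".join(pieces), boxes=new_boxes)


def merge_primer_pair(forward: str, reverse: str,
                      trim: int = 10) -> str:
    """Assemble a cloning insert from a partially complementary primer pair.

    The forward primer is merged with the reverse complement of the
    reverse primer over their longest suffix/prefix overlap, and ``trim``
    bases of restriction-site extension are removed from each end.
    """
    rcr = revcomp(reverse)
    best = 0
    for k in range(1, min(len(forward), len(rcr)) + 1):
        if forward[-k:] == rcr[:k]:
            best = k
    if best < 6:
        raise ValueError("primers share no usable overlap")
    merged = forward + rcr[best:]
    return merged[trim:len(merged) - trim]


# Printed cloning primers for the H2-K and H2-E SXY reporter inserts.
H2K_PRIMERS = (
    "ATGCACGCGTCCACAGTTTCACTTCTGCACCTAACCTGGGTCAGGTCCTTCTGTCCGGACACTGTTG",
    "TGGTAGATCTCGCCACCCAATGGGGGTAAGAGCTGACTGCGCGTCAACAGTGTC",
)
H2E_PRIMERS = (
    "ATGCACGCGTAACTGCAAGTTTCAGAAGGGGACCTGCAAACTGAATCTCTAACTAGCAACTGATGA",
    "TGGTAGATCTTGGGAGCCAATCAGCATCAAAGGAGTCCAGCATCATCAGTTG",
)


def reporter_constructs() -> tuple[AnnotatedModule, AnnotatedModule]:
    """The H2-K and H2-E SXY reporter inserts with box annotations.

    Box regions follow the segment boundaries used to build the hybrid
    constructs: the S and X segments of the forward primers and the
    CCAAT-containing (Y box) prefix of the reverse primers.
    """
    k_seq = merge_primer_pair(*H2K_PRIMERS)
    e_seq = merge_primer_pair(*H2E_PRIMERS)
    h2k = AnnotatedModule(
        sequence=k_seq,
        boxes={"S": (0, 28), "X": (28, 43),
               "Y": (len(k_seq) - 11, len(k_seq))},
    )
    h2e = AnnotatedModule(
        sequence=e_seq,
        boxes={"S": (0, 26), "X": (26, 41),
               "Y": (len(e_seq) - 11, len(e_seq))},
    )
    return h2k, h2e
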