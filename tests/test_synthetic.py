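"""Synthetic generators: genomes, planted modules, annotations, box swaps."""

import numpy as np
import pytest

import sxyscan as sx
from sxyscan.pwm import revcomp
from sxyscan.synthetic import (
    S_CONSENSUS,
    X_CONSENSUS,
    Y_CONSENSUS,
    merge_primer_pair,
    H2K_PRIMERS,
    H2E_PRIMERS,
)


class TestBackgroundGenome:
    def test_gc_fraction_is_respected(self):
        genome = sx.generate_background_genome(1, (10_000,),
                                               gc_fraction=0.5, seed=1)
        seq = genome["contig_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("gc", [0.0, 1.0, -0.1])
    def test_degenerate_gc_raises(self, gc):
        with pytest.raises(ValueError):
            sx.generate_background_genome(1, (100,), gc_fraction=gc)

    def test_same_seed_reproduces_sequence(self):
        a = sx.generate_background_genome(2, (500, 700), seed=42)
        b = sx.generate_background_genome(2, (500, 700), seed=42)
        assert a == b


class TestPlantModules:
    def test_zero_mutation_round_trip(self):
        genome = sx.generate_background_genome(1, (20_000,), seed=2)
        genome, truth = sx.plant_modules(genome, [(16, 21)], ["+"], seed=3)
        (m,) = truth.modules
        seq = genome[m.contig]
        assert seq[slice(*m.s_interval)] == S_CONSENSUS
        assert seq[slice(*m.x_interval)] == X_CONSENSUS
        assert seq[slice(*m.y_interval)] == Y_CONSENSUS
        assert m.spacing_sx == 16 and m.spacing_xy == 21

    def test_minus_strand_instance_mirrors_coordinates(self):
        genome = sx.generate_background_genome(1, (20_000,), seed=4)
        genome, truth = sx.plant_modules(genome, [(16, 20)], ["-"], seed=5)
        (m,) = truth.modules
        seq = genome[m.contig]
        # on the minus strand the genome order is Y..X..S and each motif
        # reads as its reverse complement on the plus strand
        assert m.y_interval[0] < m.x_interval[0] < m.s_interval[0]
        assert revcomp(seq[slice(*m.x_interval)]) == X_CONSENSUS
        assert revcomp(seq[slice(*m.s_interval)]) == S_CONSENSUS
        assert revcomp(seq[slice(*m.y_interval)]) == Y_CONSENSUS
        # scanning the reverse complement finds it on the forward strand
        L = len(seq)
        rc = revcomp(seq)
        x_lo = L - m.x_interval[1]
        assert rc[x_lo:x_lo + len(X_CONSENSUS)] == X_CONSENSUS

    def test_overlapping_explicit_positions_raise(self):
        genome = sx.generate_background_genome(1, (5_000,), seed=6)
        with pytest.raises(ValueError, match="overlap"):
            sx.plant_modules(genome, [(16, 20), (16, 20)], ["+", "+"],
                             positions=[("contig_1", 100),
                                        ("contig_1", 130)])

    def test_truth_table_round_trips_through_json(self, tmp_path):
        genome = sx.generate_background_genome(1, (30_000,), seed=7)
        genome, truth = sx.plant_modules(genome, [(16, 20), (16, 22)],
                                         ["+", "-"], mutation_rate=0.05,
                                         seed=8)
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = sx.SimulationTruth.from_json(path)
        assert back.modules == truth.modules
        assert back.seed == truth.seed


class TestChipTagSimulator:
    def test_no_enrichment_frip_matches_peak_fraction(self):
        genome = sx.generate_background_genome(1, (500_000,), seed=9)
        rng = np.random.default_rng(10)
        peaks = [sx.Peak(f"p{i}", "contig_1", (int(c), int(c) + 400))
                 for i, c in
                 enumerate(rng.integers(0, 499_000, size=25))]
        tags = sx.simulate_chip_tags(genome, peaks, enrichment=1.0,
                                     n_tags=80_000, seed=11)
        expected = 25 * 400 / 500_000
        # block-structured background adds variance beyond binomial noise
        assert sx.compute_frip(tags, peaks) == pytest.approx(expected,
                                                             rel=0.5)

    def test_cross_correlation_argmax_near_fragment_length(self):
        genome = sx.generate_background_genome(1, (200_000,), seed=12)
        peaks = [sx.Peak("p", "contig_1", (50_000, 50_400)),
                 sx.Peak("q", "contig_1", (120_000, 120_400))]
        tags = sx.simulate_chip_tags(genome, peaks, fragment_length=180,
                                     enrichment=20, n_tags=40_000, seed=13)
        prof = sx.strand_cross_correlation(tags, max_shift=350)
        assert abs(prof.fragment_length - 180) <= 10

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_tags": 0},
            {"enrichment": 0.5},
            {"fragment_length": 30, "read_length": 36},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        genome = {"c1": "ACGT" * 1000}
        peaks = [sx.Peak("p", "c1", (100, 200))]
        with pytest.raises(ValueError):
            sx.simulate_chip_tags(genome, peaks, **kwargs)

    def test_enrichment_without_peaks_raises(self):
        genome = {"c1": "ACGT" * 1000}
        with pytest.raises(ValueError):
            sx.simulate_chip_tags(genome, [], enrichment=2.0, n_tags=100)


class TestBoxSwap:
    def test_swapping_nothing_is_identity(self):
        h2k, _ = sx.reporter_constructs()
        out = sx.swap_box(h2k, h2k, set())
        assert out == h2k

    def test_swapping_all_boxes_back_restores_content(self):
        h2k, h2e = sx.reporter_constructs()
        hybrid = sx.swap_box(h2k, h2e, {"S", "X", "Y"})
        for box in "SXY":
            assert hybrid.box_seq(box) == h2e.box_seq(box)
        restored = sx.swap_box(hybrid, h2k, {"S", "X", "Y"})
        for box in "SXY":
            assert restored.box_seq(box) == h2k.box_seq(box)

    def test_flanks_untouched_and_intervals_updated(self):
        h2k, h2e = sx.reporter_constructs()
        hybrid = sx.swap_box(h2k, h2e, {"S"})
        # S boxes differ in length (28 vs 26), later boxes shift by -2
        delta = len(h2e.box_seq("S")) - len(h2k.box_seq("S"))
        assert hybrid.boxes["X"][0] == h2k.boxes["X"][0] + delta
        assert hybrid.box_seq("X") == h2k.box_seq("X")
        assert hybrid.box_seq("Y") == h2k.box_seq("Y")
        # sequence between X and Y is the H2-K backbone
        assert hybrid.sequence[hybrid.boxes["X"][1]:hybrid.boxes["Y"][0]] \
            == h2k.sequence[h2k.boxes["X"][1]:h2k.boxes["Y"][0]]

    def test_missing_annotation_raises(self):
        h2k, h2e = sx.reporter_constructs()
        bare = sx.AnnotatedModule(sequence=h2e.sequence,
                                  boxes={"S": h2e.boxes["S"]})
        with pytest.raises(ValueError, match="missing"):
            sx.swap_box(h2k, bare, {"X"})

    def test_primer_merge_reconstructs_printed_inserts(self):
        k = merge_primer_pair(*H2K_PRIMERS)
        e = merge_primer_pair(*H2E_PRIMERS)
        assert len(k) == 91 and len(e) == 88
        assert k.startswith("CCACAGTTTCACTTCTGCACCTAACCTG")
        assert k.endswith("ATTGGGTGGCG")
        assert e.startswith("AACTGCAAGTTTCAGAAGGGGACCTG")
        assert e.endswith("ATTGGCTCCCA")

    def test_s_box_swap_breaks_module_match_but_xy_swaps_do_not(self):
        """Constructed specificity experiment: module_a conforms to a
        fitted model; module_b has near-consensus X and Y boxes but a
        divergent S box. Swapping S kills the match, swapping X or Y
        does not — the S box carries the specificity."""
        rng = np.random.default_rng(30)
        bg = lambda n: "".join("ACGT"[i] for i in
                               rng.integers(0, 4, size=n))
        flank5, gap1, gap2, flank3 = bg(40), bg(16), bg(21), bg(40)
        seq_a = flank5 + S_CONSENSUS + gap1 + X_CONSENSUS + gap2 \
            + Y_CONSENSUS + flank3
        boxes_a = {
            "S": (40, 47),
            "X": (40 + 7 + 16, 40 + 7 + 16 + 14),
            "Y": (40 + 7 + 16 + 14 + 21, 40 + 7 + 16 + 14 + 21 + 10),
        }
        module_a = sx.AnnotatedModule(sequence=seq_a, boxes=boxes_a)

        # partner: module-conforming X and Y boxes (as interchangeable as
        # the real pair's X boxes are) but a scrambled, divergent S box
        seq_b = flank5 + "GTACGAC" + gap1 + X_CONSENSUS + gap2 \
            + Y_CONSENSUS + flank3
        module_b = sx.AnnotatedModule(sequence=seq_b, boxes=boxes_a)

        seqs = {}
        for i in range(20):
            seqs[f"t{i}"] = bg(120) + S_CONSENSUS + bg(16) \
                + X_CONSENSUS + bg(21) + Y_CONSENSUS + bg(120)
        model = sx.discover_module(seqs, window_bp=60, n_starts=10,
                                   seed=31)

        def n_matches(module):
            return len(sx.scan_for_modules({"m": module.sequence}, model))

        assert n_matches(module_a) == 1
        assert n_matches(sx.swap_box(module_a, module_b, {"S"})) == 0
        assert n_matches(sx.swap_box(module_a, module_b, {"X"})) == 1
        assert n_matches(sx.swap_box(module_a, module_b, {"Y"})) == 1


class TestGeneAnnotationGenerator:
    def test_gene_too_long_for_contig_raises(self):
        genome = {"c1": "ACGT" * 100}
        with pytest.raises(ValueError, match="too short"):
            sx.generate_gene_annotations(genome, n_genes=1, seed=1,
                                         gene_length=(2000, 2001))

    def test_truth_matches_generated_records(self, tmp_path):
        genome = sx.generate_background_genome(1, (80_000,), seed=20)
        gtf, truth = sx.generate_gene_annotations(genome, n_genes=100,
                                                  isoforms_per_gene=3,
                                                  seed=21)
        path = tmp_path / "g.gtf"
        path.write_text(gtf)
        models = {m.gene_id: m for m in sx.parse_gene_models(path)}
        assert len(models) == len(truth.genes)
        for g in truth.genes:
            m = models[g["gene_id"]]
            assert m.tss == g["tss"]
            assert sum(e - s for s, e in m.exons) == g["exon_union_bp"]
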