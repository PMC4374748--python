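"""Anchored ZOOPS-EM discovery of the S-X-Y module."""

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

import sxyscan as sx
from sxyscan.discovery import (
    MotifOccurrence,
    build_module_model,
    compare_module_consensus,
    discover_anchor_motif,
    discover_flanking_motif,
    orient_peak_sequences,
)
from sxyscan.pwm import pwm_from_sites, revcomp

PLANTED_X = "GGTCAGGTCCTTCT"


def _planted_sequences(n=50, length=500, seed=0, mutations=1,
                       motif=PLANTED_X):
    """Background sequences each carrying the motif once, ~1 mismatch."""
    rng = np.random.default_rng(seed)
    seqs, offsets = {}, {}
    for i in range(n):
        s = list("ACGT"[j] for j in rng.integers(0, 4, size=length))
        inst = list(motif)
        for k in rng.choice(len(motif), size=rng.integers(0, mutations + 1),
                            replace=False):
            inst[k] = "ACGT"[rng.integers(4)]
        off = int(rng.integers(0, length - len(motif)))
        s[off:off + len(motif)] = inst
        seqs[f"s{i}"] = "".join(s)
        offsets[f"s{i}"] = off
    return seqs, offsets


class TestAnchorDiscovery:
    def test_recovers_planted_consensus(self):
        seqs, offsets = _planted_sequences(seed=21)
        pwm, occs = discover_anchor_motif(seqs, width=14, n_starts=10,
                                          seed=1)
        assert pwm.consensus == PLANTED_X
        # per-column confidence on the planted alignment
        assert (pwm.matrix.max(axis=1) >= 0.8).all()
        found = {o.seq_id: o.offset for o in occs if not o.strand_flip}
        hit = sum(found.get(sid) == off for sid, off in offsets.items())
        assert hit >= 45

    def test_same_seed_gives_bit_identical_pwm(self):
        seqs, _ = _planted_sequences(n=20, seed=22)
        pwm1, _ = discover_anchor_motif(seqs, width=14, n_starts=5, seed=9)
        pwm2, _ = discover_anchor_motif(seqs, width=14, n_starts=5, seed=9)
        assert np.array_equal(pwm1.matrix, pwm2.matrix)

    def test_identical_sequences_give_degenerate_columns(self):
        seqs = {f"s{i}": "ACGTACGTGGTCAGGTCCTTCTACGT" for i in range(5)}
        pwm, occs = discover_anchor_motif(seqs, width=14, n_starts=3,
                                          seed=0)
        assert (pwm.matrix.max(axis=1) > 0.95).all()

    def test_reverse_complemented_inputs_recover_same_module(self):
        seqs, _ = _planted_sequences(n=30, seed=23)
        rc_seqs = {k: revcomp(v) for k, v in seqs.items()}
        pwm_f, _ = discover_anchor_motif(seqs, width=14, n_starts=10,
                                         seed=2)
        pwm_r, _ = discover_anchor_motif(rc_seqs, width=14, n_starts=10,
                                         seed=2)
        assert pwm_r.consensus in (pwm_f.consensus,
                                   revcomp(pwm_f.consensus))

    def test_too_short_or_narrow_inputs_raise(self):
        with pytest.raises(ValueError):
            discover_anchor_motif({"a": "ACG", "b": "ACGT"}, width=14)
        with pytest.raises(ValueError):
            discover_anchor_motif({"a": "ACGTACGT", "b": "ACGTACGT"},
                                  width=3)


class TestOrientation:
    def test_forward_sequence_unchanged_and_rc_restored(self):
        seqs, offsets = _planted_sequences(n=4, seed=30, mutations=0)
        flipped = dict(seqs)
        flipped["s0"] = revcomp(seqs["s0"])
        # occurrences with known offsets/strands, independent of EM
        occs = []
        for sid, off in offsets.items():
            if sid == "s0":
                occs.append(MotifOccurrence(
                    seq_id=sid, motif="X",
                    offset=len(seqs[sid]) - off - 14,
                    strand_flip=True, score=1.0, width=14))
            else:
                occs.append(MotifOccurrence(
                    seq_id=sid, motif="X", offset=off,
                    strand_flip=False, score=1.0, width=14))
        oriented, o_occs = orient_peak_sequences(flipped, occs)
        # the flipped sequence comes back as the original (involution)
        assert oriented["s0"] == seqs["s0"]
        assert oriented["s1"] == seqs["s1"]
        for o in o_occs:
            assert not o.strand_flip
            assert o.offset == offsets[o.seq_id]
            win = oriented[o.seq_id][o.offset:o.offset + o.width]
            assert win == PLANTED_X

    def test_orienting_twice_is_idempotent(self):
        seqs, _ = _planted_sequences(n=10, seed=31)
        _, occs = discover_anchor_motif(seqs, width=14, n_starts=5, seed=4)
        once, occs1 = orient_peak_sequences(seqs, occs)
        twice, occs2 = orient_peak_sequences(once, occs1)
        assert once == twice
        assert occs1 == occs2


class TestFlankingDiscovery:
    @staticmethod
    def _module_sequences(n, sx_gap, xy_gap, seed, length=400):
        rng = np.random.default_rng(seed)
        s_c, y_c = "CAGTTTC", "CATTGGGTGG"
        seqs, x_offsets = {}, {}
        span = 7 + sx_gap + 14 + xy_gap + 10
        for i in range(n):
            s = list("ACGT"[j] for j in rng.integers(0, 4, size=length))
            off = int(rng.integers(120, length - span - 120))
            mod = s_c + "".join(
                "ACGT"[j] for j in rng.integers(0, 4, size=sx_gap)
            ) + PLANTED_X + "".join(
                "ACGT"[j] for j in rng.integers(0, 4, size=xy_gap)
            ) + y_c
            s[off:off + span] = mod
            seqs[f"m{i}"] = "".join(s)
            x_offsets[f"m{i}"] = off + 7 + sx_gap
        occs = [MotifOccurrence(seq_id=k, motif="X", offset=v,
                                strand_flip=False, score=1.0, width=14)
                for k, v in x_offsets.items()]
        return seqs, occs

    def test_planted_s_found_at_distance_16(self):
        seqs, x_occs = self._module_sequences(20, 16, 21, seed=40)
        pwm, occs, gaps = discover_flanking_motif(
            seqs, x_occs, "upstream", window_bp=60, width=7, n_starts=10,
            seed=6)
        assert pwm.consensus == "CAGTTTC"
        assert all(g == 16 for g in gaps.values())

    def test_distant_y_needs_the_relaxed_window(self):
        seqs, x_occs = self._module_sequences(20, 16, 70, seed=41)
        planted_starts = {o.seq_id: o.offset + 14 + 70 for o in x_occs}
        _, occs60, _ = discover_flanking_motif(
            seqs, x_occs, "downstream", window_bp=60, width=10,
            n_starts=10, seed=7)
        assert all(o.offset != planted_starts[o.seq_id] for o in occs60)
        pwm100, occs100, gaps100 = discover_flanking_motif(
            seqs, x_occs, "downstream", window_bp=100, width=10,
            n_starts=10, seed=7)
        assert pwm100.consensus == "CATTGGGTGG"
        found = [o for o in occs100
                 if o.offset == planted_starts[o.seq_id]]
        assert len(found) >= 18
        assert all(gaps100[o.seq_id] == 70 for o in found)


class TestModuleModel:
    @staticmethod
    def _occ(sid, motif, offset, score, width):
        return MotifOccurrence(seq_id=sid, motif=motif, offset=offset,
                               strand_flip=False, score=score, width=width)

    def _pwms(self):
        return (pwm_from_sites("S", ["CAGTTTC"] * 3),
                pwm_from_sites("X", [PLANTED_X] * 3),
                pwm_from_sites("Y", ["CATTGGGTGG"] * 3))

    def test_single_triplet_thresholds(self):
        ps, px, py = self._pwms()
        model = build_module_model(
            ps, px, py,
            [self._occ("a", "S", 0, 0.80, 7)],
            [self._occ("a", "X", 23, 0.90, 14)],
            [self._occ("a", "Y", 57, 0.85, 10)],
        )
        assert model.threshold_s == pytest.approx(0.76)
        assert model.threshold_x == pytest.approx(0.855)
        assert model.threshold_y == pytest.approx(0.8075)

    def test_spacing_ranges_widened_by_five_and_floored(self):
        ps, px, py = self._pwms()
        s_occ, x_occ, y_occ = [], [], []
        for i, xy in enumerate((20, 21, 22)):
            s_occ.append(self._occ(f"t{i}", "S", 0, 0.9, 7))
            x_occ.append(self._occ(f"t{i}", "X", 7 + 16, 0.9, 14))
            y_occ.append(self._occ(f"t{i}", "Y", 7 + 16 + 14 + xy, 0.9, 10))
        model = build_module_model(ps, px, py, s_occ, x_occ, y_occ)
        assert model.spacing_sx == (11, 21)
        assert model.spacing_xy == (15, 27)
        # floor at zero when the observed minimum is below 5
        model2 = build_module_model(
            ps, px, py,
            [self._occ("a", "S", 0, 0.9, 7)],
            [self._occ("a", "X", 9, 0.9, 14)],   # gap 2
            [self._occ("a", "Y", 43, 0.9, 10)],  # gap 20
        )
        assert model2.spacing_sx == (0, 7)

    def test_no_complete_triplet_raises(self):
        ps, px, py = self._pwms()
        with pytest.raises(ValueError):
            build_module_model(ps, px, py,
                               [self._occ("a", "S", 0, 0.9, 7)],
                               [self._occ("b", "X", 20, 0.9, 14)], [])

    def test_yaml_round_trip(self, tmp_path, planted_study):
        path = tmp_path / "model.yaml"
        model = planted_study.model_stringent
        model.save(path)
        back = sx.ModuleModel.load(path)
        assert np.allclose(back.pwm_x.matrix, model.pwm_x.matrix)
        assert back.spacing_sx == model.spacing_sx
        assert back.threshold_y == pytest.approx(model.threshold_y)
        assert len(back.provenance) == len(model.provenance)


class TestConsensusComparison:
    def test_self_comparison_is_zero(self, planted_study):
        model = planted_study.model_stringent
        out = compare_module_consensus(model, model)
        for motif in "SXY":
            assert out[motif]["mean_jsd"] == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, planted_study):
        a = planted_study.model_stringent
        b = planted_study.model_relaxed
        ab = compare_module_consensus(a, b)
        ba = compare_module_consensus(b, a)
        for motif in "SXY":
            assert ab[motif]["mean_jsd"] == pytest.approx(
                ba[motif]["mean_jsd"])

    def test_uniform_vs_point_mass_matches_closed_form(self):
        uniform = sx.PWM(name="S", matrix=np.full((7, 4), 0.25))
        point = pwm_from_sites("S", ["AAAAAAA"] * 50, pseudocount=1e-9)
        m_u = sx.discovery.ModuleModel(
            pwm_s=uniform, pwm_x=uniform, pwm_y=uniform,
            threshold_s=0, threshold_x=0, threshold_y=0,
            spacing_sx=(0, 1), spacing_xy=(0, 1), window_bp=60)
        m_p = sx.discovery.ModuleModel(
            pwm_s=point, pwm_x=point, pwm_y=point,
            threshold_s=0, threshold_x=0, threshold_y=0,
            spacing_sx=(0, 1), spacing_xy=(0, 1), window_bp=60)
        expected = jensenshannon(
            [0.25] * 4, np.array([1 - 3e-9, 1e-9, 1e-9, 1e-9]), base=2
        ) ** 2
        out = compare_module_consensus(m_u, m_p)
        assert out["S"]["per_position_jsd"] == pytest.approx(
            np.full(7, expected), rel=1e-6)
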