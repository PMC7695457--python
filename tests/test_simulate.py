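"""Synthetic sample generation and recovery scoring."""

import numpy as np
import pandas as pd
import pytest

from dloopmap import (
    CallerParams,
    SimConfig,
    Strand,
    call_footprints,
    evaluate_recovery,
    process_reads,
    simulate_sample,
    write_fastq,
)
from dloopmap.caller import Footprint
from dloopmap.simulate import _reciprocal_overlap


def run_caller(reads, ref, preset="t40w50"):
    profiles, _, _ = process_reads(reads, ref)
    params = CallerParams.from_preset(preset)
    return [f for p in profiles for f in call_footprints(p, params, ref)], profiles


class TestSimulateSample:
    def test_full_conversion_marks_exactly_the_dloop_cytosines(self, ds931):
        cfg = SimConfig(n_reads=40, frac_invaded=1.0, dloop_length=500,
                        p_conv=1.0, p_bg=0.0, sub_error=0.0, strand_mode="top",
                        seed=5)
        reads, truth = simulate_sample(cfg, ds931)
        for row in truth.itertuples():
            conv = (
                np.array([int(x) for x in row.converted_positions.split(",")])
                if row.converted_positions
                else np.array([], dtype=int)
            )
            cpos = ds931.cytosine_index_top
            expected = cpos[(cpos >= row.dloop_start) & (cpos <= row.dloop_end)]
            assert conv.tolist() == expected.tolist()

    def test_no_invasion_no_background_means_no_conversions(self, ds931):
        cfg = SimConfig(n_reads=30, frac_invaded=0.0, p_bg=0.0, seed=9)
        reads, truth = simulate_sample(cfg, ds931)
        assert (truth["converted_positions"] == "").all()
        assert truth["dloop_start"].isna().all()

    def test_same_seed_reproduces_byte_identical_output(self, ds931, tmp_path):
        cfg = SimConfig(n_reads=25, frac_invaded=0.4, dloop_length=300,
                        sub_error=0.01, orientation_random=True, seed=42)
        out = []
        for tag in ("a", "b"):
            reads, truth = simulate_sample(cfg, ds931)
            fq = tmp_path / f"{tag}.fastq"
            write_fastq(reads, fq)
            out.append((fq.read_bytes(), truth.to_csv(sep="\t")))
        assert out[0] == out[1]

    def test_dloops_confined_to_homology(self, ds931):
        cfg = SimConfig(n_reads=200, frac_invaded=1.0,
                        dloop_length={"mean": 400, "sd": 150, "min": 100},
                        strand_mode="top", seed=3)
        _, truth = simulate_sample(cfg, ds931)
        assert (truth["dloop_start"] >= ds931.homology_start).all()
        assert (truth["dloop_end"] < ds931.homology_end).all()

    def test_impossible_length_model_rejected(self, ds931):
        cfg = SimConfig(n_reads=5, frac_invaded=1.0, dloop_length=2000, seed=1)
        with pytest.raises(ValueError, match="impossible"):
            simulate_sample(cfg, ds931)

    def test_bottom_reads_never_carry_dloop_conversions(self, ds931):
        cfg = SimConfig(n_reads=100, frac_invaded=1.0, dloop_length=500,
                        p_conv=1.0, p_bg=0.0, strand_mode="bottom", seed=2)
        _, truth = simulate_sample(cfg, ds931)
        assert (truth["converted_positions"] == "").all()

    def test_three_prime_anchoring(self, ds931):
        cfg = SimConfig(n_reads=50, frac_invaded=1.0, dloop_length=300,
                        dloop_position={"three_prime_weight": 1.0},
                        strand_mode="top", seed=4)
        _, truth = simulate_sample(cfg, ds931)
        assert (truth["dloop_end"] == ds931.homology_end - 1).all()


class TestEvaluateRecovery:
    def test_boundary_error_arithmetic(self):
        truth = pd.DataFrame(
            [
                {"read_id": "r1", "strand": "TOP", "dloop_start": 100,
                 "dloop_end": 600, "converted_positions": ""},
            ]
        )
        called = [Footprint("r1", Strand.TOP, 110, 580, 100, 70)]
        rep = evaluate_recovery(called, truth)
        assert rep.n_detected == 1
        assert rep.median_abs_start_error == 10
        assert rep.median_abs_end_error == 20
        assert rep.median_abs_span_error == 30

    def test_truth_without_call_is_missed(self):
        truth = pd.DataFrame(
            [{"read_id": "r1", "strand": "TOP", "dloop_start": 100,
              "dloop_end": 600, "converted_positions": ""}]
        )
        rep = evaluate_recovery([], truth)
        assert (rep.n_truth, rep.n_detected) == (1, 0)
        assert rep.detection_rate == 0.0

    def test_reciprocal_overlap_rule(self):
        assert _reciprocal_overlap((0, 99), (50, 149)) == pytest.approx(0.5)
        assert _reciprocal_overlap((0, 99), (200, 299)) == 0.0
        # one-sided containment: small call inside big truth fails reciprocity
        assert _reciprocal_overlap((0, 999), (0, 99)) == pytest.approx(0.1)

    def test_perfect_conversion_gives_full_recovery(self, ds931):
        cfg = SimConfig(n_reads=60, frac_invaded=0.5, dloop_length=500,
                        p_conv=1.0, p_bg=0.0, sub_error=0.0, seed=6)
        reads, truth = simulate_sample(cfg, ds931)
        fps, _ = run_caller(reads, ds931)
        rep = evaluate_recovery(fps, truth)
        assert rep.detection_rate == 1.0
        assert rep.bottom_false_call_rate == 0.0
        # trimmed boundaries sit on the outermost converted cytosines:
        # the error is bounded by one inter-cytosine gap at each end
        max_gap = int(np.diff(ds931.cytosine_index_top).max())
        assert rep.median_abs_start_error <= max_gap
        assert rep.median_abs_end_error <= max_gap

    def test_partial_conversion_recovery_stable_across_seeds(self, ds931):
        rates, spans = [], []
        for seed in (11, 22, 33):
            cfg = SimConfig(n_reads=80, frac_invaded=0.5, dloop_length=500,
                            p_conv=0.7, p_bg=0.01, strand_mode="top", seed=seed)
            reads, truth = simulate_sample(cfg, ds931)
            fps, _ = run_caller(reads, ds931)
            rep = evaluate_recovery(fps, truth)
            rates.append(rep.detection_rate)
            spans.append(np.median([f.span_nt for f in fps]))
        assert all(r >= 0.9 for r in rates)
        # the typical call underestimates the 500 nt truth by a bounded
        # trim margin (background near the edges fattens only the upper tail)
        assert all(450 <= s < 500 for s in spans)
        assert max(spans) - min(spans) < 30

    def test_shorter_dloops_shift_cluster_mass_down(self, ds931):
        from dloopmap import assign_length_clusters, default_cluster_edges

        edges = default_cluster_edges(ds931)
        mass_low = {}
        for name, length in (("long", 700), ("short", 300)):
            cfg = SimConfig(n_reads=60, frac_invaded=1.0, dloop_length=length,
                            p_conv=0.9, p_bg=0.0, strand_mode="top", seed=13)
            reads, _ = simulate_sample(cfg, ds931)
            fps, _ = run_caller(reads, ds931)
            _, table = assign_length_clusters([f.span_nt for f in fps], edges)
            low = table.loc[table["cluster"].isin(["0-249", "250-499"]), "pct"].sum()
            mass_low[name] = low
        assert mass_low["short"] > mass_low["long"]
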