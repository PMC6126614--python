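import numpy as np
import pandas as pd
import pytest

import teprof
from teprof.polysome_profiles import (
    ProfileTrace,
    compare_peaks,
    detect_peaks,
    holm_sidak,
    peak_fold_changes,
    quantify_auc,
    read_trace,
    write_trace,
)
from teprof.synthetic_data import simulate_trace

SEVEN_PEAKS = [(1.0 + 1.2 * i, 0.12, 1.0 + 0.2 * i) for i in range(7)]


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        tr = simulate_trace([(5.0, 0.5, 1.0)], noise_sd=0.01, seed=1)
        path = tmp_path / "trace.tsv"
        write_trace(tr, path)
        back = read_trace(path)
        assert np.allclose(back.position, tr.position)
        assert np.allclose(back.absorbance, tr.absorbance)

    def test_header_auto_skip(self, tmp_path):
        x = np.linspace(0, 10, 200)
        y = np.exp(-((x - 5) ** 2))
        with_header = tmp_path / "h.tsv"
        without = tmp_path / "n.tsv"
        body = "".join(f"{a}\t{b}\n" for a, b in zip(x, y))
        with_header.write_text("position\tabsorbance\n" + body)
        without.write_text(body)
        t1, t2 = read_trace(with_header), read_trace(without)
        assert np.allclose(t1.absorbance, t2.absorbance)

    def test_non_monotone_positions_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        rows = [(float(i), 1.0) for i in range(60)]
        rows[10] = (100.0, 1.0)  # breaks monotonicity
        path.write_text("".join(f"{a}\t{b}\n" for a, b in rows))
        with pytest.raises(ValueError, match="increasing"):
            read_trace(path)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="points"):
            ProfileTrace(np.arange(10.0), np.ones(10))


class TestSimulateTrace:
    def test_single_peak_total_area(self):
        tr = simulate_trace([(5.0, 0.3, 1.0)], baseline=0.0, noise_sd=0.0)
        total = np.trapezoid(tr.absorbance, tr.position)
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_two_peak_area_ratio(self):
        tr = simulate_trace([(3.0, 0.2, 2.0), (7.0, 0.2, 1.0)], noise_sd=0.0)
        peaks = detect_peaks(tr, min_prominence=0.5, min_separation=1.0)
        q = quantify_auc(tr, peaks, "zero")
        assert q["auc"].iloc[0] / q["auc"].iloc[1] == pytest.approx(2.0, rel=0.02)

    def test_same_seed_identical(self):
        t1 = simulate_trace([(5.0, 0.3, 1.0)], noise_sd=0.05, seed=9)
        t2 = simulate_trace([(5.0, 0.3, 1.0)], noise_sd=0.05, seed=9)
        assert np.array_equal(t1.absorbance, t2.absorbance)

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            simulate_trace([(5.0, 0.3, 1.0), (5.0, 0.2, 1.0)])

    def test_decreasing_centers_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            simulate_trace([(5.0, 0.3, 1.0), (4.0, 0.2, 1.0)])


class TestDetectPeaks:
    def test_seven_gaussians_found_at_centers(self):
        tr = simulate_trace(SEVEN_PEAKS, baseline=0.1, noise_sd=0.005, seed=1, x_range=(0, 12))
        peaks = detect_peaks(tr, min_prominence=0.3, min_separation=0.5)
        assert len(peaks) == 7
        step = np.median(np.diff(tr.position))
        for pk, (center, _, _) in zip(peaks, SEVEN_PEAKS):
            assert abs(pk.apex_position - center) <= step + 1e-12

    def test_flat_trace_empty_with_warning(self):
        tr = ProfileTrace(np.linspace(0, 10, 200), np.full(200, 0.3))
        with pytest.warns(UserWarning, match="no peaks"):
            peaks = detect_peaks(tr, min_prominence=0.1)
        assert len(peaks) == 0

    def test_close_peaks_merged_keeping_larger(self):
        tr = simulate_trace([(5.0, 0.15, 1.0), (5.5, 0.15, 2.0)], noise_sd=0.0)
        peaks = detect_peaks(tr, min_prominence=0.2, min_separation=1.0)
        assert len(peaks) == 1
        assert abs(peaks.peaks[0].apex_position - 5.5) < 0.2

    def test_default_names_left_to_right(self):
        tr = simulate_trace(SEVEN_PEAKS, noise_sd=0.0, x_range=(0, 12))
        peaks = detect_peaks(tr, min_prominence=0.3, min_separation=0.5)
        assert peaks.names() == ["40S", "60S", "monosome", "P1", "P2", "P3", "P4"]


class TestQuantifyAuc:
    def test_unit_gaussian_zero_baseline(self):
        tr = simulate_trace([(5.0, 0.3, 1.0)], baseline=0.0, noise_sd=0.0)
        peaks = detect_peaks(tr, min_prominence=0.2)
        q = quantify_auc(tr, peaks, "zero")
        assert q["auc"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_unit_gaussian_on_offset_with_chord(self):
        tr = simulate_trace([(5.0, 0.3, 1.0)], baseline=0.5, noise_sd=0.0)
        peaks = detect_peaks(tr, min_prominence=0.2)
        q = quantify_auc(tr, peaks, "linear-under-peak")
        assert q["auc"].iloc[0] == pytest.approx(1.0, abs=0.02)

    def test_triangle_exact_under_trapezoid(self):
        x = np.linspace(0, 2, 201)
        y = 1.0 - np.abs(x - 1.0)  # height 1, base 2 -> area 1
        tr = ProfileTrace(x, y)
        peaks = teprof.PeakSet(
            [teprof.Peak(name="tri", apex=100, left=0, right=200, apex_position=1.0)]
        )
        q = quantify_auc(tr, peaks, "zero")
        assert q["auc"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_negative_area_clipped_and_flagged(self):
        x = np.linspace(0, 10, 100)
        y = -np.exp(-((x - 5) ** 2))
        tr = ProfileTrace(x, y + 1.0)
        peaks = teprof.PeakSet(
            [teprof.Peak(name="dip", apex=50, left=30, right=70, apex_position=5.0)]
        )
        q = quantify_auc(tr, peaks, "linear-under-peak")
        assert q["auc"].iloc[0] == 0.0
        assert bool(q["clipped"].iloc[0])

    def test_auc_additivity_when_splitting(self):
        tr = simulate_trace([(5.0, 0.4, 2.0)], noise_sd=0.0)
        whole = teprof.PeakSet(
            [teprof.Peak(name="w", apex=500, left=200, right=800, apex_position=5.0)]
        )
        left = teprof.PeakSet(
            [teprof.Peak(name="l", apex=450, left=200, right=500, apex_position=4.5)]
        )
        right = teprof.PeakSet(
            [teprof.Peak(name="r", apex=550, left=500, right=800, apex_position=5.5)]
        )
        total = quantify_auc(tr, whole, "zero")["auc"].iloc[0]
        parts = (
            quantify_auc(tr, left, "zero")["auc"].iloc[0]
            + quantify_auc(tr, right, "zero")["auc"].iloc[0]
        )
        assert parts == pytest.approx(total, abs=1e-12)

    def test_bad_baseline_mode(self):
        tr = simulate_trace([(5.0, 0.3, 1.0)], noise_sd=0.0)
        with pytest.raises(ValueError, match="baseline_mode"):
            quantify_auc(tr, teprof.PeakSet([]), "spline")


def _two_group_quants(seed=5, suppression=0.5, n_rep=4):
    rows = []
    rng = np.random.default_rng(seed)
    for group, scale in (("wt", 1.0), ("mut", suppression)):
        for rep in range(1, n_rep + 1):
            spec = [
                (1.0 + i * 1.2, 0.12, scale * (1.0 + 0.2 * i) * rng.normal(1, 0.03))
                for i in range(7)
            ]
            tr = simulate_trace(spec, baseline=0.05, noise_sd=0.002, seed=100 + rep)
            peaks = detect_peaks(tr, min_prominence=0.3, min_separation=0.5)
            q = quantify_auc(tr, peaks, "linear-under-peak")
            for _, r in q.iterrows():
                rows.append(
                    {"group": group, "replicate": rep, "peak": r["peak"], "auc": r["auc"]}
                )
    return pd.DataFrame(rows)


class TestFoldChangesAndCompare:
    def test_reference_vs_itself_is_one(self):
        quants = _two_group_quants()
        fc = peak_fold_changes(quants, reference=("wt", "P1"))
        row = fc[(fc["group"] == "wt") & (fc["peak"] == "P1")]
        assert row["fold_change"].iloc[0] == pytest.approx(1.0)

    def test_linearity_under_doubling(self):
        quants = _two_group_quants()
        doubled = quants.copy()
        doubled.loc[doubled["group"] == "mut", "auc"] *= 2
        fc1 = peak_fold_changes(quants, reference=("wt", "P1"))
        fc2 = peak_fold_changes(doubled, reference=("wt", "P1"))
        m1 = fc1[fc1["group"] == "mut"].set_index("peak")["fold_change"]
        m2 = fc2[fc2["group"] == "mut"].set_index("peak")["fold_change"]
        assert np.allclose(m2, 2 * m1)

    def test_planted_suppression_recovered(self):
        quants = _two_group_quants(suppression=0.5)
        fc = peak_fold_changes(quants, reference=("wt", "P1"))
        wide = fc.pivot(index="peak", columns="group", values="fold_change")
        ratio = wide["mut"] / wide["wt"]
        assert np.allclose(ratio, 0.5, atol=0.05)

    def test_missing_reference_errors(self):
        quants = _two_group_quants()
        with pytest.raises(ValueError, match="reference peak"):
            peak_fold_changes(quants, reference=("wt", "P9"))

    def test_compare_identical_groups(self):
        quants = _two_group_quants()
        wt = quants[quants["group"] == "wt"]
        res = compare_peaks(wt, wt.copy())
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)

    def test_compare_detects_suppression(self):
        quants = _two_group_quants(suppression=0.5)
        res = compare_peaks(
            quants[quants["group"] == "wt"], quants[quants["group"] == "mut"]
        )
        assert (res["padj"] < 0.05).all()

    def test_single_replicate_skipped(self):
        quants = _two_group_quants()
        lone = quants[(quants["group"] == "mut") & (quants["replicate"] == 1)]
        res = compare_peaks(quants[quants["group"] == "wt"], lone)
        assert res["skipped"].all()


class TestHolmSidak:
    def test_hand_computation(self):
        adj = holm_sidak([0.01, 0.04])
        assert adj[0] == pytest.approx(1 - 0.99**2)
        assert adj[1] == pytest.approx(0.04)

    def test_single_p_identity(self):
        assert holm_sidak([0.2])[0] == pytest.approx(0.2)

    def test_monotone_and_geq_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=30)
        adj = holm_sidak(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
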