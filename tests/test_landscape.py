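"""Landscape construction, zone heuristics and composition estimates."""

import numpy as np
import pandas as pd
import pytest

from zingerscan import landscape as lsc
from zingerscan import motifs, simulate
from zingerscan.landscape import (
    EnrichmentZone,
    build_landscape,
    composition,
    corrected_fraction,
    derive_zone,
    find_distance_boundaries,
    find_score_threshold,
    positional_density,
)

from conftest import random_sequence


@pytest.fixture(scope="module")
def thap_pwm():
    return motifs.pfm_to_pwm(simulate.zinger_pfms()["THAP11_like"])


def brute_force_top_hit(pwm, seq, floor):
    """Independent best-hit selection: max score, tie nearest centre/left/+."""
    L = pwm.width
    comp = str.maketrans("ACGTN", "TGCAN")
    center = (len(seq) - 1) // 2
    best = None
    for start in range(len(seq) - L + 1):
        word = seq[start : start + L]
        for si, strand in enumerate("+-"):
            w = word if strand == "+" else word.translate(comp)[::-1]
            s = motifs.relative_score(pwm, w)
            if s < floor:
                continue
            mid = start + L // 2
            key = (-s, abs(mid - center), start, si)
            if best is None or key < best[0]:
                best = (key, mid - center, s, strand)
    return best


class TestLandscape:
    def test_region_length_enforced(self, thap_pwm):
        with pytest.raises(ValueError):
            build_landscape({"p": "ACGT" * 100}, thap_pwm)

    def test_planted_centre_hit_has_zero_distance(self, thap_pwm):
        site = "".join("ACGT"[i] for i in thap_pwm.weights.argmax(axis=0))
        L = thap_pwm.width
        seq = list("C" * lsc.REGION_LENGTH)
        start = 500 - L // 2
        seq[start : start + L] = site
        out = build_landscape({"p": "".join(seq)}, thap_pwm)
        assert bool(out.loc["p", "has_motif"])
        assert out.loc["p", "signed_distance"] == 0
        assert out.loc["p", "rel_score"] == pytest.approx(100.0)

    def test_no_window_above_floor_is_motif_less(self, thap_pwm):
        out = build_landscape({"p": "C" * lsc.REGION_LENGTH}, thap_pwm, floor_score=70)
        assert not bool(out.loc["p", "has_motif"])

    def test_matches_brute_force_best_hit(self, thap_pwm, rng):
        seqs = {f"p{i}": random_sequence(rng, lsc.REGION_LENGTH) for i in range(8)}
        out = build_landscape(seqs, thap_pwm, floor_score=70)
        for pid, seq in seqs.items():
            expected = brute_force_top_hit(thap_pwm, seq, 70)
            if expected is None:
                assert not out.loc[pid, "has_motif"]
            else:
                _, dist, score, strand = expected
                assert out.loc[pid, "signed_distance"] == dist
                assert out.loc[pid, "rel_score"] == pytest.approx(score)
                assert out.loc[pid, "strand"] == strand


class TestDensity:
    def _frame(self, distances):
        return pd.DataFrame(
            {"has_motif": True, "signed_distance": distances,
             "rel_score": 90.0, "strand": "+", "start_offset": 0}
        )

    def test_all_hits_at_zero_fill_one_bin(self):
        density = positional_density(self._frame([0] * 50))
        assert (density > 0).sum() == 1
        assert density.sum() == 50

    def test_bins_conserve_hit_count(self, rng):
        d = rng.integers(-500, 501, size=1000)
        density = positional_density(self._frame(d))
        assert density.sum() == 1000

    def test_uniform_hits_within_poisson_tolerance(self, rng):
        n = 20000
        d = rng.integers(-500, 500, size=n)  # the 200 full 5 bp bins
        density = positional_density(self._frame(d))
        expected = n / 200
        assert (np.abs(density.to_numpy()[:200] - expected) < 5 * np.sqrt(expected)).all()


class TestBoundaries:
    def test_flat_density_defaults_and_flags(self):
        flat = pd.Series(10.0, index=np.arange(201) * 5 - 500 + 2.0)
        left, right, found = find_distance_boundaries(flat)
        assert (left, right) == (-90, 90)
        assert not found

    def test_symmetric_density_gives_symmetric_boundaries(self):
        centers = np.arange(201) * 5 - 500 + 2.0
        counts = np.full(201, 20.0)
        counts[np.abs(centers) < 60] = 60.0
        left, right, found = find_distance_boundaries(pd.Series(counts, index=centers))
        assert found and left == -right

    def test_planted_landscape_recovers_boundaries(self, rng):
        landscape, _ = simulate.calibration_landscape(300_000, 80, 85, rng)
        density = positional_density(landscape)
        left, right, found = find_distance_boundaries(density)
        assert found
        assert abs(left + 80) <= 15 and abs(right - 80) <= 15


class TestScoreThreshold:
    def test_pure_background_has_no_threshold(self, rng):
        n = 20000
        landscape = pd.DataFrame(
            {"has_motif": True,
             "signed_distance": rng.integers(-500, 501, size=n).astype(float),
             "rel_score": rng.uniform(70, 100, size=n),
             "strand": "+", "start_offset": 0}
        )
        assert find_score_threshold(landscape, (-90, 90)) is None

    def test_proximal_planting_bounds_threshold(self, rng):
        landscape, _ = simulate.calibration_landscape(200_000, 90, 88, rng)
        thr = find_score_threshold(landscape, (-90, 90))
        assert thr is not None and thr <= 88

    def test_raising_ratio_never_lowers_threshold(self, rng):
        landscape, _ = simulate.calibration_landscape(100_000, 90, 85, rng)
        prev = 70
        for ratio in (1.1, 1.2, 1.3, 1.5):
            thr = find_score_threshold(landscape, (-90, 90), ratio=ratio)
            if thr is None:
                break
            assert thr >= prev
            prev = thr


class TestComposition:
    def test_corrected_fraction_arithmetic(self):
        assert corrected_fraction(300, 100, 1000) == pytest.approx(0.2)
        assert corrected_fraction(100, 100, 1000) == 0.0
        assert corrected_fraction(50, 100, 1000) == 0.0  # floored at zero
        with pytest.raises(ValueError):
            corrected_fraction(1, 1, 0)

    def _landscape(self, dists, scores):
        return pd.DataFrame(
            {"has_motif": ~np.isnan(np.asarray(dists, float)),
             "signed_distance": dists, "rel_score": scores,
             "strand": "+", "start_offset": 0}
        )

    def test_all_chipped_dataset(self):
        zone = EnrichmentZone(-90, 90, 82.0)
        chip = self._landscape([0.0] * 10, [95.0] * 10)
        zing = self._landscape([np.nan] * 10, [np.nan] * 10)
        est = composition(chip, zone, {"CTCF_like": (zing, zone)})
        assert est.raw_fractions() == (1.0, 0.0, 0.0)

    def test_peak_with_both_motifs_counts_as_chipped(self):
        zone = EnrichmentZone(-90, 90, 82.0)
        chip = self._landscape([5.0], [95.0])
        zing = self._landscape([0.0], [99.0])
        est = composition(chip, zone, {"CTCF_like": (zing, zone)})
        assert est.raw_chipped == 1.0 and est.raw_zinger == 0.0

    def test_raw_fractions_sum_to_one(self, rng):
        zone = EnrichmentZone(-90, 90, 82.0)
        n = 500
        chip = self._landscape(
            rng.integers(-500, 501, size=n).astype(float), rng.uniform(70, 100, size=n)
        )
        zing = self._landscape(
            rng.integers(-500, 501, size=n).astype(float), rng.uniform(70, 100, size=n)
        )
        est = composition(chip, zone, {"CTCF_like": (zing, zone)})
        assert sum(est.raw_fractions()) == pytest.approx(1.0)

    def test_distal_zone_geometry(self):
        zone = EnrichmentZone(-100, 100, 82.0)
        (l0, l1), (r0, r1) = zone.distal_segments()
        assert l1 - l0 + (r1 - r0) == pytest.approx(zone.width)
        assert l1 == -150 and r0 == 150  # 50 bp clear of the zone


class TestPlot:
    def test_plot_landscape_renders(self, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        landscape, _ = simulate.calibration_landscape(2000, 90, 85, rng)
        zone = lsc.EnrichmentZone(-90, 90, 85.0)
        ax = lsc.plot_landscape(landscape, zone)
        ax.figure.savefig(tmp_path / "landscape.png")
        assert (tmp_path / "landscape.png").stat().st_size > 0


class TestDeriveZone:
    def test_null_landscape_falls_back_to_defaults(self, rng):
        n = 5000
        landscape = pd.DataFrame(
            {"has_motif": True,
             "signed_distance": rng.integers(-500, 501, size=n).astype(float),
             "rel_score": rng.uniform(70, 100, size=n),
             "strand": "+", "start_offset": 0}
        )
        zone = derive_zone(landscape)
        assert (zone.left_bp, zone.right_bp) == (-90, 90) or zone.boundaries_found
        if not zone.threshold_found:
            assert zone.score_threshold == 82.0
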