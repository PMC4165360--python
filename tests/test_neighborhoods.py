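"""Neighborhood merging, recurrence, de-overlap and proximity testing."""

import numpy as np
import pandas as pd
import pytest

from zingerscan.neighborhoods import (
    declass_overlaps,
    feature_proximity_screen,
    merge_neighborhoods,
    proximity_test,
    recurrence_summary,
)


def members_frame(positions, tfs=None, cell_lines=None, chrom="chr1"):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "peakmax": positions,
            "tf": tfs if tfs is not None else ["TFA"] * n,
            "cell_line": cell_lines if cell_lines is not None else ["CL0"] * n,
        }
    )


def transitive_closure_oracle(positions, merge_bp=50):
    """O(n^2) union-find over all pairs within merge_bp."""
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= merge_bp:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


class TestMerging:
    def test_single_peak_neighborhood(self):
        nb, labelled = merge_neighborhoods(members_frame([1000]))
        assert len(nb) == 1
        assert nb.loc[0, "width"] == 0
        assert nb.loc[0, "n_unique_tfs"] == 1

    def test_chained_peaks_merge(self):
        nb, _ = merge_neighborhoods(members_frame([0, 40, 80]))
        assert len(nb) == 1  # consecutive gaps of 40 <= 50 chain together
        assert nb.loc[0, "width"] == 80

    def test_gap_above_threshold_splits(self):
        nb, _ = merge_neighborhoods(members_frame([0, 60]))
        assert len(nb) == 2

    def test_matches_transitive_closure_oracle(self, rng):
        positions = rng.integers(0, 20_000, size=1000).tolist()
        nb, labelled = merge_neighborhoods(members_frame(positions))
        got = sorted(
            tuple(sorted(g["peakmax"].tolist()))
            for _, g in labelled.groupby("neighborhood_id")
        )
        assert got == transitive_closure_oracle(positions)

    def test_every_peak_in_exactly_one_neighborhood(self, rng):
        members = members_frame(rng.integers(0, 100_000, size=500).tolist())
        nb, labelled = merge_neighborhoods(members)
        assert len(labelled) == len(members)
        assert labelled["neighborhood_id"].nunique() == len(nb)
        assert int(nb["n_members"].sum()) == len(members)

    def test_merging_centers_is_idempotent(self, rng):
        members = members_frame(rng.integers(0, 10**7, size=400).tolist())
        nb, _ = merge_neighborhoods(members)
        centers = members_frame(nb["center"].tolist())
        gaps_ok = np.diff(np.sort(nb["center"].to_numpy())) > 50
        nb2, _ = merge_neighborhoods(centers)
        if gaps_ok.all():
            assert len(nb2) == len(nb)

    def test_chroms_never_merge(self):
        members = pd.concat(
            [members_frame([100], chrom="chr1"), members_frame([110], chrom="chr2")]
        )
        nb, _ = merge_neighborhoods(members)
        assert len(nb) == 2


class TestRecurrence:
    def test_same_tf_everywhere_gives_no_multi(self):
        nb, _ = merge_neighborhoods(members_frame([0, 10, 20], tfs=["TFA"] * 3))
        summary = recurrence_summary(nb)
        assert summary["n_multi_tf"] == 0

    def test_input_order_invariance(self, rng):
        positions = rng.integers(0, 50_000, size=300).tolist()
        tfs = [f"TF{i % 5}" for i in range(300)]
        members = members_frame(positions, tfs=tfs)
        shuffled = members.sample(frac=1.0, random_state=3)
        a, _ = merge_neighborhoods(members)
        b, _ = merge_neighborhoods(shuffled)
        pd.testing.assert_frame_equal(
            a.sort_values(["chrom", "start"]).reset_index(drop=True),
            b.sort_values(["chrom", "start"]).reset_index(drop=True),
        )

    def test_shared_region_multi_tf_fraction_recovered(self, rng):
        # 30% of regions carry peaks from 5 TFs, the rest from one
        rows = []
        for r in range(600):
            pos = 10_000 * (r + 1)
            n_tfs = 5 if rng.random() < 0.30 else 1
            for t in range(n_tfs):
                rows.append(("chr1", pos + int(rng.integers(-15, 16)), f"TF{t}", "CL0"))
        members = pd.DataFrame(rows, columns=["chrom", "peakmax", "tf", "cell_line"])
        nb, _ = merge_neighborhoods(members)
        summary = recurrence_summary(nb)
        assert summary["frac_multi_tf"] == pytest.approx(0.30, abs=0.05)


class TestDeclassing:
    def _nbhds(self, centers, chrom="chr1"):
        return pd.DataFrame(
            {"chrom": chrom, "start": centers, "end": [c + 1 for c in centers],
             "center": centers, "width": 0, "n_members": 1,
             "n_unique_tfs": 1, "n_unique_cell_lines": 1}
        )

    def test_distant_sets_are_untouched(self):
        chipped = self._nbhds([0, 10_000, 20_000])
        out = declass_overlaps(chipped, self._nbhds([5000]), self._nbhds([15_000]))
        assert len(out) == 3

    def test_identical_centers_are_removed(self):
        chipped = self._nbhds([100, 5000])
        out = declass_overlaps(chipped, self._nbhds([100]), self._nbhds([]))
        assert out["center"].tolist() == [5000]

    def test_matches_all_pairs_scan(self, rng):
        chipped = self._nbhds(sorted(rng.integers(0, 200_000, size=200).tolist()))
        zinger = self._nbhds(sorted(rng.integers(0, 200_000, size=100).tolist()))
        unid = self._nbhds(sorted(rng.integers(0, 200_000, size=100).tolist()))
        out = declass_overlaps(chipped, zinger, unid)
        others = zinger["center"].tolist() + unid["center"].tolist()
        expected = [
            c for c in chipped["center"] if all(abs(c - o) > 300 for o in others)
        ]
        assert out["center"].tolist() == expected
        for c in out["center"]:
            assert all(abs(c - o) > 300 for o in others)


class TestProximity:
    def _nbhds(self, centers):
        return pd.DataFrame({"chrom": "chr1", "center": centers})

    def test_track_on_a_only(self):
        a = self._nbhds(list(range(0, 100_000, 5000)))
        b = self._nbhds(list(range(2_000_000, 2_100_000, 5000)))
        track = pd.DataFrame({"chrom": "chr1", "peakmax": a["center"]})
        fa, fb, p = proximity_test(a, b, track)
        assert fa == 1.0 and fb == 0.0
        assert p < 1e-6

    def test_identical_sets_not_significant(self):
        a = self._nbhds(list(range(0, 100_000, 5000)))
        track = pd.DataFrame({"chrom": "chr1", "peakmax": [0, 10_000]})
        _, _, p = proximity_test(a, a.copy(), track)
        assert p >= 0.5

    def test_empty_track_rejected(self):
        a = self._nbhds([1, 2])
        with pytest.raises(ValueError):
            proximity_test(a, a, pd.DataFrame(columns=["chrom", "peakmax"]))


class TestFeatureScreen:
    def _dataset(self, rng, n_zinger, proximal):
        track_pos = np.arange(100) * 50_000
        if proximal:
            zp = rng.choice(track_pos, size=n_zinger) + rng.integers(-100, 101, size=n_zinger)
        else:
            zp = rng.integers(0, 5_000_000, size=n_zinger) + 2000
        cp = rng.integers(0, 5_000_000, size=400)
        frame = lambda pos: pd.DataFrame({"chrom": "chr1", "peakmax": pos})
        return frame(zp), frame(cp), frame(track_pos)

    def test_small_datasets_excluded(self, rng):
        zp, cp, track = self._dataset(rng, 150, True)
        out = feature_proximity_screen({"ds1": (zp, cp)}, {"TSS": track})
        assert out.loc["TSS", "n_eligible"] == 0
        assert out.loc["TSS", "verdict"] == "no-eligible-datasets"

    def test_unanimous_proximal_verdict(self, rng):
        groups = {}
        track = None
        for i in range(4):
            zp, cp, track = self._dataset(rng, 300, True)
            groups[f"ds{i}"] = (zp, cp)
        out = feature_proximity_screen(groups, {"cohesin": track})
        assert out.loc["cohesin", "verdict"] == "proximal"

    def test_split_directions_give_no_verdict(self, rng):
        groups = {}
        for i in range(4):
            zp, cp, track = self._dataset(rng, 300, proximal=(i < 2))
            # make the distal half significantly *distal*: chipped proximal
            if i >= 2:
                cp = pd.DataFrame(
                    {"chrom": "chr1",
                     "peakmax": np.repeat(np.arange(100) * 50_000, 4)[:400]}
                )
            groups[f"ds{i}"] = (zp, cp)
        out = feature_proximity_screen(
            groups, {"cohesin": pd.DataFrame({"chrom": "chr1",
                                              "peakmax": np.arange(100) * 50_000})}
        )
        assert out.loc["cohesin", "verdict"] == "none"
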