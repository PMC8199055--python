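"""Joint MK-MD histogram, healthy occupancy, signature region, labeling."""
import dataclasses

import numpy as np
import pytest

import kurtosig as kg
from kurtosig.grids import Grid, ParametricMap, SegmentationMask
from kurtosig.signature import (
    Binning,
    Bounds,
    JointHistogram,
    build_reference_occupancy,
    derive_signature_region,
    joint_histogram,
    label_voxels,
    manual_gate_region,
)


def _maps_from(md_vals, mk_vals, shape=(4, 4, 4)):
    grid = Grid.centered(shape, (2, 2, 2))
    md = np.full(shape, np.nan)
    mk = np.full(shape, np.nan)
    mask = np.zeros(shape, dtype=bool)
    flat_md, flat_mk = md.ravel(), mk.ravel()
    flat_mask = mask.ravel()
    flat_md[: len(md_vals)] = md_vals
    flat_mk[: len(mk_vals)] = mk_vals
    flat_mask[: len(md_vals)] = True
    return (
        ParametricMap(md, "MD", grid),
        ParametricMap(mk, "MK", grid),
        SegmentationMask(mask, grid),
    )


class TestJointHistogram:
    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        md_v = rng.uniform(-0.5, 4.5, 60)  # some deliberately out of range
        mk_v = rng.uniform(-0.5, 3.5, 60)
        md, mk, mask = _maps_from(md_v, mk_v)
        h = joint_histogram(md, mk, mask)
        assert int(h.counts.sum()) + h.n_out_of_range == h.n_total == 60

    def test_single_voxel_lands_in_bruteforce_bin(self):
        md, mk, mask = _maps_from([1.00], [0.50])
        h = joint_histogram(md, mk, mask)
        assert h.counts.sum() == 1
        i, j = np.argwhere(h.counts)[0]
        # oracle: linear scan over the edges
        def scan(v, edges):
            for b in range(edges.size - 1):
                if edges[b] <= v < edges[b + 1] or (
                    b == edges.size - 2 and v == edges[-1]
                ):
                    return b
            raise AssertionError("value out of range")

        assert i == scan(1.00, h.binning.md_edges)
        assert j == scan(0.50, h.binning.mk_edges)

    def test_empty_mask_is_vacuous(self):
        md, mk, mask = _maps_from([], [])
        h = joint_histogram(md, mk, mask)
        assert h.n_total == 0 and not h.counts.any()

    def test_invalid_voxels_are_excluded_and_counted(self):
        md, mk, mask = _maps_from([1.0, np.nan, 2.0], [0.5, 0.5, np.nan])
        h = joint_histogram(md, mk, mask)
        assert h.n_total == 1
        assert h.n_invalid == 2

    def test_grid_mismatch_rejected(self):
        md, mk, _ = _maps_from([1.0], [0.5])
        other = SegmentationMask(
            np.ones((3, 3, 3), bool), Grid.centered((3, 3, 3), (1, 1, 1))
        )
        with pytest.raises(ValueError, match="grid"):
            joint_histogram(md, mk, other)


class TestOccupancy:
    def _hist(self, counts, binning=None):
        binning = binning or Binning()
        arr = np.zeros(binning.shape, dtype=np.int64)
        for (i, j), c in counts.items():
            arr[i, j] = c
        return JointHistogram(
            binning=binning,
            counts=arr,
            n_total=int(arr.sum()),
            n_out_of_range=0,
        )

    def test_tau_zero_equals_pooled_support(self):
        h1 = self._hist({(3, 4): 5, (10, 10): 1})
        h2 = self._hist({(3, 4): 2, (20, 30): 4})
        occ = build_reference_occupancy([h1, h2], tau=0.0, dilate=0)
        np.testing.assert_array_equal(occ.occupied, (h1.counts + h2.counts) > 0)

    def test_rare_bin_below_tau_is_unoccupied(self):
        h = self._hist({(5, 5): 1, (8, 8): 999_999})
        occ = build_reference_occupancy([h], tau=1e-5, dilate=0)
        assert not occ.occupied[5, 5]  # frequency 1e-6 < tau
        assert occ.occupied[8, 8]

    def test_dilation_is_a_monotone_superset(self):
        h = self._hist({(10, 20): 3, (40, 70): 8})
        occ0 = build_reference_occupancy([h], tau=0.0, dilate=0)
        occ1 = build_reference_occupancy([h], tau=0.0, dilate=1)
        assert np.all(occ1.occupied[occ0.occupied])  # superset, bin by bin
        assert occ1.occupied.sum() > occ0.occupied.sum()
        # dilate=1 reaches exactly the Chebyshev-1 neighbourhood
        assert occ1.occupied[9:12, 19:22].all()

    def test_mismatched_edges_rejected(self):
        h1 = self._hist({(0, 0): 1})
        other = Binning(md_edges=np.linspace(0, 3, 31))
        h2 = self._hist({(0, 0): 1}, binning=other)
        with pytest.raises(ValueError, match="mismatched"):
            build_reference_occupancy([h1, h2])


class TestSignatureRegion:
    def test_full_occupancy_gives_empty_region(self):
        occ = build_reference_occupancy(
            [TestOccupancy()._hist({(0, 0): 1})], tau=0.0, dilate=0
        )
        occ.occupied[:] = True
        region = derive_signature_region(occ)
        assert not region.region.any()

    def test_empty_occupancy_region_matches_bruteforce_bounds_scan(self):
        occ = build_reference_occupancy(
            [TestOccupancy()._hist({(0, 0): 1})], tau=0.0, dilate=0
        )
        occ.occupied[:] = False
        bounds = Bounds()
        region = derive_signature_region(occ, bounds)
        count = 0
        for c_md in occ.binning.md_centers:  # exhaustive bin-centre test
            for c_mk in occ.binning.mk_centers:
                if bounds.md[0] < c_md <= bounds.md[1] and bounds.mk[0] < c_mk <= bounds.mk[1]:
                    count += 1
        assert int(region.region.sum()) == count

    def test_region_disjoint_from_randomized_occupancy(self):
        rng = np.random.default_rng(4)
        occ = build_reference_occupancy(
            [TestOccupancy()._hist({(0, 0): 1})], tau=0.0, dilate=0
        )
        occ.occupied[:] = rng.random(occ.occupied.shape) < 0.3
        region = derive_signature_region(occ)
        assert not (region.region & occ.occupied).any()

    def test_bounds_excluding_all_bins_rejected(self):
        occ = build_reference_occupancy(
            [TestOccupancy()._hist({(0, 0): 1})], tau=0.0, dilate=0
        )
        with pytest.raises(ValueError, match="bounds"):
            derive_signature_region(occ, Bounds(md=(10.0, 11.0), mk=(0.1, 2.0)))


class TestLabeling:
    def test_noiseless_phantom_labels_exact_tumor(self, small_truth, truth_maps):
        """Construction check: healthy occupancy from healthy phantoms leaves
        exactly the tumor voxels in the signature region (Dice 1)."""
        md, mk = truth_maps
        hists = []
        for seed in (21, 22, 23):
            spec = dataclasses.replace(small_truth.spec.healthy(), seed=seed)
            t = kg.build_phantom(spec)
            hists.append(
                joint_histogram(
                    ParametricMap(t.md_truth, "MD", t.grid),
                    ParametricMap(t.mk_truth, "MK", t.grid),
                    t.brain_mask,
                )
            )
        occ = build_reference_occupancy(hists, tau=0.0, dilate=1)
        region = derive_signature_region(occ)
        label = label_voxels(md, mk, small_truth.brain_mask, region)
        np.testing.assert_array_equal(label.values, small_truth.tumor_mask_dki.values)
        assert kg.dice(label, small_truth.tumor_mask_dki) == 1.0

    def test_empty_region_labels_nothing(self, small_truth, truth_maps):
        md, mk = truth_maps
        region = manual_gate_region(Binning(), (3.4, 3.45), (2.9, 2.95))
        region.region[:] = False
        label = label_voxels(md, mk, small_truth.brain_mask, region)
        assert label.n_voxels == 0

    def test_min_cluster_removes_small_islands_like_floodfill_oracle(self):
        shape = (12, 12, 6)
        grid = Grid.centered(shape, (2, 2, 5))
        md = np.full(shape, 1.0)
        mk = np.full(shape, 0.7)
        mask = SegmentationMask(np.ones(shape, bool), grid)
        # plant a 3-voxel island and a large blob of signature-region values
        island = [(1, 1, 1), (1, 2, 1), (2, 2, 2)]  # 26-connected triple
        for p in island:
            md[p], mk[p] = 2.5, 0.3
        md[6:10, 6:10, 2:5], mk[6:10, 6:10, 2:5] = 2.5, 0.3
        region = manual_gate_region(Binning(), (2.0, 3.0), (0.2, 0.4))
        label = label_voxels(
            ParametricMap(md, "MD", grid),
            ParametricMap(mk, "MK", grid),
            mask,
            region,
            min_cluster=5,
        )

        # oracle: flood fill over the 26-neighbourhood
        raw = np.zeros(shape, bool)
        for p in island:
            raw[p] = True
        raw[6:10, 6:10, 2:5] = True
        seen = np.zeros(shape, bool)
        keep = np.zeros(shape, bool)
        for start in zip(*np.nonzero(raw)):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                v = stack.pop()
                comp.append(v)
                for dx in (-1, 0, 1):
                    for dy in (-1, 0, 1):
                        for dz in (-1, 0, 1):
                            w = (v[0] + dx, v[1] + dy, v[2] + dz)
                            if all(0 <= w[a] < shape[a] for a in range(3)):
                                if raw[w] and not seen[w]:
                                    seen[w] = True
                                    stack.append(w)
            if len(comp) >= 5:
                for v in comp:
                    keep[v] = True
        np.testing.assert_array_equal(label.values, keep)

    def test_reference_subject_has_zero_false_positives_on_itself(self, small_truth):
        """tau=0, dilate=0: labeling an occupancy-building subject's own maps
        yields the empty set — the signature truly 'does not occur' there."""
        spec = small_truth.spec.healthy()
        t = kg.build_phantom(spec)
        md = ParametricMap(t.md_truth, "MD", t.grid)
        mk = ParametricMap(t.mk_truth, "MK", t.grid)
        h = joint_histogram(md, mk, t.brain_mask)
        occ = build_reference_occupancy([h], tau=0.0, dilate=0)
        region = derive_signature_region(occ)
        label = label_voxels(md, mk, t.brain_mask, region, min_cluster=0)
        assert label.n_voxels == 0

    def test_raising_tau_never_shrinks_region_or_labels(self, small_truth, truth_maps):
        md, mk = truth_maps
        h = joint_histogram(md, mk, small_truth.brain_mask)
        labels, regions = [], []
        for tau in (0.0, 1e-4, 1e-2):
            occ = build_reference_occupancy([h], tau=tau, dilate=0)
            region = derive_signature_region(occ)
            lab = label_voxels(md, mk, small_truth.brain_mask, region, min_cluster=0)
            regions.append(region.region)
            labels.append(lab.values)
        for lo, hi in zip(regions, regions[1:]):
            assert np.all(hi[lo])
        for lo, hi in zip(labels, labels[1:]):
            assert np.all(hi[lo])

    def test_heldout_healthy_phantom_specificity(self, small_truth):
        """A healthy phantom with unseen jitter stays below 0.1% labeled."""
        hists = []
        for seed in (31, 32, 33):
            spec = dataclasses.replace(small_truth.spec.healthy(), seed=seed)
            t = kg.build_phantom(spec)
            hists.append(
                joint_histogram(
                    ParametricMap(t.md_truth, "MD", t.grid),
                    ParametricMap(t.mk_truth, "MK", t.grid),
                    t.brain_mask,
                )
            )
        occ = build_reference_occupancy(hists)  # defaults: tau=1e-5, dilate=1
        region = derive_signature_region(occ)
        held = kg.build_phantom(
            dataclasses.replace(small_truth.spec.healthy(), seed=99)
        )
        label = label_voxels(
            ParametricMap(held.md_truth, "MD", held.grid),
            ParametricMap(held.mk_truth, "MK", held.grid),
            held.brain_mask,
            region,
        )
        assert label.n_voxels <= 0.001 * held.brain_mask.n_voxels

    def test_labeled_bins_are_subset_of_region(self, small_truth, truth_maps):
        md, mk = truth_maps
        region = manual_gate_region(Binning(), (1.1, 1.7), (0.1, 0.5))
        label = label_voxels(md, mk, small_truth.brain_mask, region, min_cluster=0)
        from kurtosig.signature import _bin_index

        sel = label.values
        i = _bin_index(md.values[sel], region.binning.md_edges)
        j = _bin_index(mk.values[sel], region.binning.mk_edges)
        assert np.all(region.region[i, j])
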