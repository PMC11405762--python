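import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imiomics_cpet.cpet_indices import pearson_p_value
from imiomics_cpet.statmap import (
    CorrelationMap,
    cluster_filter,
    region_summary,
    significant_fraction,
    stratified_maps,
    voxelwise_pearson,
)
from imiomics_cpet.voxel_maps import VoxelMapStack


def make_stack(volume, labels=None, mask=None):
    n = volume.shape[0]
    shape = volume.shape[1:]
    if labels is None:
        labels = np.full(shape, 4, dtype=np.int16)  # muscle everywhere
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    return VoxelMapStack(
        subjects=[f"S{i}" for i in range(n)],
        volume=volume.astype(np.float32),
        fat=volume.astype(np.float32),
        mask=mask,
        labels=labels,
        spacing=(1.0, 1.0, 1.0),
    )


class TestVoxelwisePearson:
    def test_voxel_equal_to_covariate_has_unit_correlation(self, rng):
        vol = rng.normal(size=(10, 3, 3, 3))
        cov = rng.normal(size=10)
        vol[:, 1, 1, 1] = cov
        cmap = voxelwise_pearson(make_stack(vol), cov, "volume")
        assert cmap.r[1, 1, 1] == pytest.approx(1.0)
        assert cmap.p[1, 1, 1] == 0.0

    def test_matches_per_voxel_pearsonr_oracle(self, rng):
        """5x5x5 stack, n=10: r and p equal scipy.stats.pearsonr applied
        voxel by voxel to 1e-10."""
        vol = rng.normal(size=(10, 5, 5, 5))
        cov = rng.normal(size=10)
        stack = make_stack(vol)
        cmap = voxelwise_pearson(stack, cov, "volume")
        stored = stack.volume.astype(np.float64)
        for idx in np.ndindex(5, 5, 5):
            r_ref, p_ref = stats.pearsonr(stored[(slice(None),) + idx], cov)
            assert cmap.r[idx] == pytest.approx(r_ref, abs=1e-10)
            assert cmap.p[idx] == pytest.approx(p_ref, abs=1e-10)

    def test_p_value_from_t_transform(self):
        """r = 0.5, n = 25 -> t ~ 2.769, two-sided p ~ 0.0107."""
        p = pearson_p_value(0.5, 25)
        t = 0.5 * np.sqrt(23) / np.sqrt(1 - 0.25)
        assert t == pytest.approx(2.769, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(t, 23), rel=1e-12)
        assert p == pytest.approx(0.0109, abs=2e-4)

    def test_zero_variance_voxels_excluded(self, rng):
        vol = rng.normal(size=(8, 3, 3, 3))
        vol[:, 0, 0, 0] = 5.0
        cmap = voxelwise_pearson(make_stack(vol), rng.normal(size=8), "volume")
        assert np.isnan(cmap.r[0, 0, 0])
        assert not cmap.sig_mask[0, 0, 0]

    def test_constant_covariate_rejected(self, rng):
        vol = rng.normal(size=(8, 3, 3, 3))
        with pytest.raises(ValueError, match="constant"):
            voxelwise_pearson(make_stack(vol), np.ones(8), "volume")

    def test_too_few_subjects_rejected(self, rng):
        vol = rng.normal(size=(2, 3, 3, 3))
        with pytest.raises(ValueError, match="3"):
            voxelwise_pearson(make_stack(vol), np.array([1.0, 2.0]), "volume")

    def test_fdr_never_increases_significance(self, rng):
        vol = rng.normal(size=(12, 6, 6, 6))
        cov = rng.normal(size=12)
        raw = voxelwise_pearson(make_stack(vol), cov, "volume")
        fdr = voxelwise_pearson(make_stack(vol), cov, "volume", fdr=True)
        assert fdr.sig_mask.sum() <= raw.sig_mask.sum()
        assert np.all(raw.sig_mask[fdr.sig_mask])


def flood_fill_components(mask, connectivity):
    """Independent BFS connected-component labelling oracle."""
    offs = []
    for d in np.ndindex(3, 3, 3):
        d = np.array(d) - 1
        if not d.any():
            continue
        order = int(np.abs(d).sum())
        if (connectivity, order) in [(6, 1)] or (connectivity == 18 and order <= 2) or connectivity == 26:
            offs.append(d)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        queue = [start]
        labels[start] = nxt
        while queue:
            p = queue.pop()
            for d in offs:
                q = tuple(np.array(p) + d)
                if all(0 <= q[i] < mask.shape[i] for i in range(3)) and mask[q] and not labels[q]:
                    labels[q] = nxt
                    queue.append(q)
    return labels, nxt


def cmap_from_mask(sig, r=None):
    shape = sig.shape
    return CorrelationMap(
        r=np.where(np.ones(shape, bool), 0.5, 0.5) if r is None else r,
        p=np.where(sig, 0.01, 0.5),
        sig_mask=sig,
        clusters=np.zeros(shape, np.int32),
        n=20,
        covariate="x",
        map_family="volume",
        sex="pooled",
        alpha=0.05,
    )


class TestClusterFilter:
    def test_isolated_voxel_removed(self):
        sig = np.zeros((9, 9, 9), bool)
        sig[4, 4, 4] = True
        out = cluster_filter(cmap_from_mask(sig), np.full((9, 9, 9), 4, np.int16), min_voxels=27)
        assert not out.sig_mask.any()

    def test_solid_block_retained_as_one_cluster(self):
        sig = np.zeros((9, 9, 9), bool)
        sig[3:6, 3:6, 3:6] = True
        out = cluster_filter(cmap_from_mask(sig), np.full((9, 9, 9), 4, np.int16), min_voxels=27)
        assert out.sig_mask.sum() == 27
        assert set(np.unique(out.clusters)) == {0, 1}

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_component_labelling_matches_flood_fill_oracle(self, rng, connectivity):
        sig = rng.random((8, 8, 8)) < 0.3
        labels = np.full((8, 8, 8), 4, np.int16)
        out = cluster_filter(cmap_from_mask(sig), labels, min_voxels=1, connectivity=connectivity)
        ours, _ = np.unique(out.clusters, return_counts=True)
        oracle_lab, n_oracle = flood_fill_components(sig, connectivity)
        # same partition: bijection between nonzero label sets
        assert out.sig_mask.sum() == sig.sum()
        assert len(ours[ours > 0]) == n_oracle
        for cid in range(1, n_oracle + 1):
            m = oracle_lab == cid
            assert len(np.unique(out.clusters[m])) == 1

    def test_cluster_never_spans_anatomical_structures(self):
        sig = np.zeros((8, 8, 8), bool)
        sig[2:6, 2:6, 2:6] = True  # 64 voxels spanning a label boundary
        labels = np.full((8, 8, 8), 4, np.int16)
        labels[4:] = 5
        out = cluster_filter(cmap_from_mask(sig), labels, min_voxels=27)
        ids_a = set(np.unique(out.clusters[labels == 4])) - {0}
        ids_b = set(np.unique(out.clusters[labels == 5])) - {0}
        assert ids_a and ids_b and not (ids_a & ids_b)
        # each half is 32 voxels >= 27 so both survive
        assert out.sig_mask.sum() == 64


class TestStratifiedMaps:
    def covariate_table(self, n_m, n_f, rng, effect_f=0.0, stack_vals=None):
        ids = [f"S{i}" for i in range(n_m + n_f)]
        sex = ["male"] * n_m + ["female"] * n_f
        return pd.DataFrame({"id": ids, "sex": sex, "x": rng.normal(size=n_m + n_f)})

    def test_males_only_cohort_yields_male_maps_only(self, rng):
        vol = rng.normal(size=(12, 4, 4, 4))
        stack = make_stack(vol)
        cov = self.covariate_table(12, 0, rng)
        maps = stratified_maps(stack, cov, ["x"], families=("volume",))
        assert ("male", "x", "volume") in maps
        assert all(k[0] != "female" for k in maps)

    def test_female_only_planted_effect_recovered_in_female_maps(self, rng):
        """A correlate present only in females shows positive mean r in
        the female map and near-zero in the male map."""
        n = 40
        shape = (5, 5, 5)
        sex = np.array(["male"] * n + ["female"] * n)
        x = rng.normal(size=2 * n)
        vol = rng.normal(0, 0.3, size=(2 * n,) + shape)
        vol[n:] += 0.5 * x[n:, None, None, None]  # female-only effect
        stack = make_stack(vol)
        cov = pd.DataFrame({"id": stack.subjects, "sex": sex, "x": x})
        maps = stratified_maps(stack, cov, ["x"], families=("volume",), min_cluster_voxels=1)
        r_f = np.nanmean(maps[("female", "x", "volume")].r)
        r_m = np.nanmean(maps[("male", "x", "volume")].r)
        assert r_f > 0.5
        assert abs(r_m) < 0.2
        assert significant_fraction(maps[("female", "x", "volume")], stack.mask) > 0.5

    def test_alignment_is_by_identifier_not_position(self, rng):
        vol = rng.normal(size=(10, 3, 3, 3))
        vol[:, 0, 0, 0] = np.arange(10)
        stack = make_stack(vol)
        cov = pd.DataFrame(
            {
                "id": stack.subjects[::-1],  # shuffled table
                "sex": ["male"] * 10,
                "x": np.arange(10)[::-1],  # value matches subject S_i = i
            }
        )
        maps = stratified_maps(stack, cov, ["x"], families=("volume",), min_cluster_voxels=1)
        assert maps[("male", "x", "volume")].r[0, 0, 0] == pytest.approx(1.0)

    def test_missing_subject_in_table_rejected(self, rng):
        vol = rng.normal(size=(6, 3, 3, 3))
        stack = make_stack(vol)
        cov = pd.DataFrame({"id": ["nope"], "sex": ["male"], "x": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            stratified_maps(stack, cov, ["x"])

    def test_permuted_covariate_keeps_type_one_error_at_alpha(self, rng):
        """Permutation null: with an unrelated covariate the share of
        significant voxels is ~alpha (raw p < 0.05, no correction)."""
        vol = rng.normal(size=(40, 12, 12, 12))
        stack = make_stack(vol)
        cov = rng.normal(size=40)
        shares = []
        for _ in range(10):
            perm = rng.permutation(cov)
            cmap = voxelwise_pearson(stack, perm, "volume")
            shares.append(significant_fraction(cmap, stack.mask))
        assert np.mean(shares) == pytest.approx(0.05, abs=0.01)


class TestRegionSummary:
    def test_uniform_significant_map_summarised_exactly(self):
        shape = (6, 6, 6)
        labels = np.full(shape, 4, np.int16)
        labels[:2] = 1
        sig = np.ones(shape, bool)
        cmap = cmap_from_mask(sig, r=np.full(shape, 0.3))
        cmap = cluster_filter(cmap, labels, min_voxels=1)
        df = region_summary(cmap, labels, np.ones(shape, bool))
        covered = df[df.covered]
        assert set(covered.label) == {"subq_trunk", "muscle"}
        assert np.allclose(covered.mean_r, 0.3)
        assert np.allclose(covered.sig_share, 1.0)

    def test_empty_significance_mask_gives_zero_shares(self, rng):
        shape = (5, 5, 5)
        labels = np.full(shape, 4, np.int16)
        cmap = cmap_from_mask(np.zeros(shape, bool), r=rng.normal(size=shape))
        df = region_summary(cmap, labels, np.ones(shape, bool))
        assert (df.sig_share == 0).all()
        assert (df.largest_cluster == 0).all()

    def test_masked_mean_matches_independent_computation(self, rng):
        shape = (7, 7, 7)
        labels = rng.integers(1, 4, size=shape).astype(np.int16)
        mask = rng.random(shape) < 0.8
        r = rng.normal(size=shape)
        cmap = cmap_from_mask(rng.random(shape) < 0.2, r=r)
        df = region_summary(cmap, labels, mask).set_index("label_id")
        for lid in (1, 2, 3):
            m = mask & (labels == lid)
            if m.sum():
                assert df.loc[lid, "mean_r"] == pytest.approx(r[m].mean(), rel=1e-12)
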