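import itertools

import numpy as np
import pytest

from mhcdepth import (
    FilterProfile,
    GeneFamily,
    GeneRegion,
    Genotype,
    GenotypeMatrix,
    SiteRecord,
    apply_allelic_balance_filter,
    apply_depth_filter,
    apply_hard_filters,
    depth_threshold,
    select_biallelic_exonic,
)

REGION = GeneRegion("G1", "chr1", ((100, 400),), GeneFamily.MHC_I)


def matrix_for(sites, calls=None, depth=None, allele_depths=None):
    n = len(sites)
    calls = calls if calls is not None else np.full((n, 2), Genotype.HOM_REF)
    return GenotypeMatrix(
        sites=sites,
        individuals=["K1", "K2"],
        calls=calls,
        depth=depth,
        allele_depths=allele_depths,
    )


def site(pos=150, ref="A", alt="G", qual=500.0, mq=60.0, mqrs=0.0, rprs=0.0):
    return SiteRecord(
        chrom="chr1", pos=pos, ref=ref, alt=alt, qual=qual, mq=mq,
        mq_rank_sum=mqrs, read_pos_rank_sum=rprs,
    )


class TestSelectBiallelicExonic:
    def test_intronic_and_multiallelic_removed(self):
        sites = (
            [site(pos=110 + i) for i in range(7)]
            + [site(pos=50), site(pos=450), site(pos=500)]  # outside the exon
        )
        m, rep = select_biallelic_exonic(matrix_for(sites), [REGION])
        assert m.n_sites == 7 and rep["removed_non_exonic"] == 3

        sites = [site(pos=120), site(pos=130, alt="G,T")]
        m, rep = select_biallelic_exonic(matrix_for(sites), [REGION])
        assert m.n_sites == 1 and rep["removed_non_biallelic"] == 1

    def test_empty_intersection_warns(self):
        with pytest.warns(UserWarning):
            m, _ = select_biallelic_exonic(matrix_for([site(pos=50)]), [REGION])
        assert m.n_sites == 0


class TestHardFilters:
    def test_qual_strictly_less_than_80_removed(self):
        m, _ = apply_hard_filters(matrix_for([site(qual=79.9)]), FilterProfile.mhc())
        assert m.n_sites == 0
        m, _ = apply_hard_filters(matrix_for([site(qual=80.0)]), FilterProfile.mhc())
        assert m.n_sites == 1

    def test_rank_sums_apply_only_to_mhc_profile(self):
        bad = site(qual=100.0, mq=60.0, mqrs=13.0)
        m, _ = apply_hard_filters(matrix_for([bad]), FilterProfile.mhc())
        assert m.n_sites == 0
        m, _ = apply_hard_filters(matrix_for([bad]), FilterProfile.tlr())
        assert m.n_sites == 1

    def test_mq_boundary_is_strict(self):
        m, _ = apply_hard_filters(matrix_for([site(mq=40.0)]), FilterProfile.mhc())
        assert m.n_sites == 1
        m, _ = apply_hard_filters(matrix_for([site(mq=39.99)]), FilterProfile.mhc())
        assert m.n_sites == 0

    def test_absent_rank_sum_passes(self):
        s = SiteRecord(chrom="chr1", pos=150, ref="A", alt="G", qual=100.0, mq=60.0)
        m, _ = apply_hard_filters(matrix_for([s]), FilterProfile.mhc())
        assert m.n_sites == 1


class TestDepthFilter:
    @pytest.mark.parametrize(
        "target,expected_t", [(15.0, 5.0), (6.0, 2.0), (60.0, 10.0), (30.0, 10.0)]
    )
    def test_threshold_rule(self, target, expected_t):
        assert depth_threshold(target) == pytest.approx(expected_t)

    @pytest.mark.parametrize(
        "target,mean_depth,kept",
        [
            (15.0, 4.9, False),
            (15.0, 5.0, True),
            (6.0, 1.9, False),
            (60.0, 12.0, True),
        ],
    )
    def test_mean_depth_boundaries(self, target, mean_depth, kept):
        depth = np.array([[mean_depth, mean_depth]])
        m, _ = apply_depth_filter(matrix_for([site()], depth=depth), target)
        assert (m.n_sites == 1) is kept


class TestAllelicBalanceFilter:
    def make(self, ad_pairs):
        n = len(ad_pairs)
        calls = np.full((1, n), Genotype.HET)
        ad = np.array([ad_pairs])
        depth = ad.sum(axis=-1)
        return GenotypeMatrix(
            sites=[site()],
            individuals=[f"K{i}" for i in range(n)],
            calls=calls,
            depth=depth,
            allele_depths=ad,
        )

    def test_balanced_retained(self):
        m, _ = apply_allelic_balance_filter(self.make([(10, 10), (8, 12)]))
        assert m.n_sites == 1

    def test_extreme_imbalance_removed(self):
        m, _ = apply_allelic_balance_filter(self.make([(96, 4)]))  # diff 0.92
        assert m.n_sites == 0

    def test_boundary_point_nine_retained(self):
        m, _ = apply_allelic_balance_filter(self.make([(19, 1)]))  # diff 0.9 exactly
        assert m.n_sites == 1

    def test_no_het_passes_vacuously(self):
        mat = self.make([(20, 0)])
        mat.calls[:] = Genotype.HOM_REF
        m, _ = apply_allelic_balance_filter(mat)
        assert m.n_sites == 1


class TestCascadeProperties:
    def stages(self, target_depth=15.0):
        return [
            lambda m: select_biallelic_exonic(m, [REGION])[0],
            lambda m: apply_hard_filters(m, FilterProfile.mhc())[0],
            lambda m: apply_depth_filter(m, target_depth)[0],
            lambda m: apply_allelic_balance_filter(m)[0],
        ]

    def random_matrix(self, seed):
        rng = np.random.default_rng(seed)
        n_s, n_i = 30, 6
        sites = [
            site(
                pos=int(rng.integers(50, 500)) + 1000 * i,  # unique positions
                qual=float(rng.uniform(50, 600)),
                mq=float(rng.uniform(30, 60)),
                mqrs=float(rng.uniform(-15, 15)),
                rprs=float(rng.uniform(-10, 10)),
            )
            for i in range(n_s)
        ]
        # unique positions spanning exonic and non-exonic space
        positions = rng.choice(np.arange(50, 500), size=n_s, replace=False)
        sites = [
            SiteRecord(
                chrom="chr1",
                pos=int(p),
                ref="A",
                alt="G",
                qual=s.qual,
                mq=s.mq,
                mq_rank_sum=s.mq_rank_sum,
                read_pos_rank_sum=s.read_pos_rank_sum,
            )
            for s, p in zip(sites, positions)
        ]
        calls = rng.integers(0, 4, size=(n_s, n_i)).astype(np.int8)
        depth = rng.poisson(8, size=(n_s, n_i))
        nalt = rng.binomial(depth, 0.5)
        ad = np.stack([depth - nalt, nalt], axis=-1)
        return GenotypeMatrix(
            sites=sites,
            individuals=[f"K{i}" for i in range(n_i)],
            calls=calls,
            depth=depth,
            allele_depths=ad,
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_order_stability(self, seed):
        m = self.random_matrix(seed)
        stage_list = self.stages()
        reference = None
        for order in itertools.permutations(range(4)):
            out = m
            for i in order:
                out = stage_list[i](out)
            keys = out.site_keys()
            if reference is None:
                reference = keys
            assert keys == reference

    def test_stages_only_remove_sites(self):
        m = self.random_matrix(3)
        for stage in self.stages():
            out = stage(m)
            kept = {k: i for i, k in enumerate(m.site_keys())}
            for i, k in enumerate(out.site_keys()):
                assert np.array_equal(out.calls[i], m.calls[kept[k]])

    def test_idempotent(self):
        m = self.random_matrix(4)
        for stage in self.stages():
            once = stage(m)
            twice = stage(once)
            assert twice.site_keys() == once.site_keys()
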