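"""Breeding-design generator and phenotype simulator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spiderqg.pedigree import FEMALE, MALE, additive_relationship
from spiderqg.simulate import (
    TRAIT_PRESETS,
    DesignSpec,
    TraitTruth,
    assortative_pairing,
    generate_pedigree,
    simulate_breeding_values,
    simulate_phenotypes,
    simulate_study,
)


def flat_truth(**kw) -> TraitTruth:
    base = dict(
        name="toy", mu_f=10.0, mu_m=20.0,
        V_Af=0.0, V_Am=0.0, COV_Amf=0.0,
        V_CEM_f=0.0, V_CEM_m=0.0, V_PE_f=0.0, V_PE_m=0.0,
        V_R_f=0.0, V_R_m=0.0,
    )
    base.update(kw)
    return TraitTruth(**base)


class TestDesign:
    def test_default_design_matches_study_layout(self):
        ped = generate_pedigree(DesignSpec(), seed=0)
        gen = np.array(ped.generation)
        assert (gen == "offspring").sum() == 29 * 10
        assert (gen == "parental").sum() == 30 + 31
        # each family shares exactly one dam and one sire
        off = np.where(gen == "offspring")[0]
        fams = {}
        for i in off:
            fams.setdefault((ped.dam[i], ped.sire[i]), []).append(i)
        assert len(fams) == 29
        assert all(len(v) == 10 for v in fams.values())

    def test_single_family_fullsibs(self):
        spec = DesignSpec(n_dams=1, n_sires=1, n_families=1,
                          daughters_per_family=1, sons_per_family=1)
        ped = generate_pedigree(spec, seed=1)
        assert len(ped) == 4
        A = additive_relationship(ped).A
        off = [i for i, g in enumerate(ped.generation) if g == "offspring"]
        assert A[off[0], off[1]] == 0.5

    def test_determinism_and_seed_sensitivity(self):
        p1 = generate_pedigree(DesignSpec(), seed=42)
        p2 = generate_pedigree(DesignSpec(), seed=42)
        p3 = generate_pedigree(DesignSpec(), seed=43)
        assert p1.ids == p2.ids
        np.testing.assert_array_equal(p1.dam, p2.dam)
        assert not np.array_equal(p1.dam, p3.dam)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="n_families"):
            DesignSpec(n_dams=5, n_sires=5, n_families=6)
        with pytest.raises(ValueError, match="replicate"):
            DesignSpec(parent_replicates=0)


class TestAssortativePairing:
    def test_rank_matching(self):
        pairs, ud, us = assortative_pairing(
            {"d1": 3.0, "d2": 1.0, "d3": 2.0},
            {"s1": 10.0, "s2": 30.0, "s3": 20.0},
        )
        assert pairs == [("d1", "s2"), ("d3", "s3"), ("d2", "s1")]
        assert ud == [] and us == []

    def test_ties_broken_by_id_order(self):
        pairs, _, _ = assortative_pairing(
            {"db": 1.0, "da": 1.0}, {"sb": 5.0, "sa": 5.0}
        )
        assert pairs == [("da", "sa"), ("db", "sb")]

    def test_unequal_counts_reported(self):
        pairs, ud, us = assortative_pairing(
            {"d1": 2.0, "d2": 1.0}, {"s1": 9.0, "s2": 8.0, "s3": 7.0}
        )
        assert len(pairs) == 2
        assert ud == [] and us == ["s3"]

    def test_noiseless_scores_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        d = {f"d{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        s = {f"s{i}": float(v) for i, v in enumerate(rng.normal(size=30))}
        pairs, _, _ = assortative_pairing(d, s)
        rho = stats.spearmanr(
            [d[a] for a, _ in pairs], [s[b] for _, b in pairs]
        ).statistic
        assert rho == pytest.approx(1.0)


class TestPhenotypes:
    def test_zero_variance_gives_exact_means(self):
        ped = generate_pedigree(DesignSpec(n_families=3), seed=0)
        df = simulate_phenotypes(ped, flat_truth(), DesignSpec(n_families=3), seed=0)
        f = df[df.sex == "female"].value
        m = df[df.sex == "male"].value
        assert (f == 10.0).all() and (m == 20.0).all()

    def test_residual_only_variance_recovered(self):
        """Sample variance of V_R-only records within 3% of V_R."""
        recs = [(f"x{i}", "NA", "NA", "f") for i in range(5000)]
        recs += [(f"y{i}", "NA", "NA", "m") for i in range(5000)]
        from spiderqg.pedigree import Pedigree
        ped = Pedigree.from_records(recs, generation=["parental"] * 10000)
        truth = flat_truth(V_R_f=4.0, V_R_m=4.0)
        df = simulate_phenotypes(ped, truth, DesignSpec(parent_replicates=1), seed=7)
        assert df.value.size == 10000
        v = df.groupby("sex").value.var(ddof=1)
        assert v["female"] == pytest.approx(4.0, rel=0.03)
        assert v["male"] == pytest.approx(4.0, rel=0.03)

    def test_breeding_value_cross_sex_covariance(self):
        """Unrelated founders, V_Af=V_Am=COV=V: (a_f, a_m) covariance = [[V,V],[V,V]]."""
        from spiderqg.pedigree import Pedigree
        recs = [(f"x{i}", "NA", "NA", "f") for i in range(20000)]
        ped = Pedigree.from_records(recs)
        G = np.array([[2.0, 2.0], [2.0, 2.0]])
        a = simulate_breeding_values(ped, G, np.random.default_rng(3))
        emp = np.cov(a.T)
        np.testing.assert_allclose(emp, G, atol=0.08)

    def test_zero_cross_sex_covariance_independent(self):
        from spiderqg.pedigree import Pedigree
        recs = [(f"x{i}", "NA", "NA", "f") for i in range(20000)]
        ped = Pedigree.from_records(recs)
        G = np.diag([1.0, 1.0])
        a = simulate_breeding_values(ped, G, np.random.default_rng(4))
        assert abs(np.corrcoef(a.T)[0, 1]) < 0.03

    def test_censoring_bounds(self):
        ped = generate_pedigree(DesignSpec(n_families=5), seed=2)
        truth = flat_truth(mu_f=200.0, mu_m=200.0, V_R_f=1e4, V_R_m=1e4,
                           censor_limit=300.0)
        df = simulate_phenotypes(ped, truth, DesignSpec(n_families=5), seed=2)
        assert df.value.max() <= 300.0
        assert df.value.min() >= 1.0
        assert (df.value == 300.0).any()  # censoring actually bites

    def test_log_trait_observed_on_raw_scale(self):
        ped = generate_pedigree(DesignSpec(n_families=2), seed=3)
        truth = flat_truth(mu_f=3.0, mu_m=3.0, transform="log", censor_limit=300.0)
        df = simulate_phenotypes(ped, truth, DesignSpec(n_families=2), seed=3)
        assert df.value.unique() == pytest.approx([np.exp(3.0)])

    def test_fullsib_phenotypic_covariance(self):
        """Same-sex full-sib covariance = 0.5 V_A + V_CE/M over many families."""
        spec = DesignSpec(
            n_dams=1000, n_sires=1000, n_families=1000,
            daughters_per_family=2, sons_per_family=0,
            parent_replicates=1,
        )
        ped = generate_pedigree(spec, seed=5)
        truth = flat_truth(V_Af=1.0, V_Am=1.0, COV_Amf=0.0,
                           V_CEM_f=0.5, V_CEM_m=0.5, V_R_f=0.3, V_R_m=0.3)
        df = simulate_phenotypes(ped, truth, spec, seed=5)
        off = df[df.generation == "offspring"]
        fam = off.groupby(off.id.str.extract(r"(F\d+)", expand=False))
        pairs = np.array([g.value.to_numpy()[:2] for _, g in fam if len(g) == 2])
        cov = np.cov(pairs.T)[0, 1]
        expected = 0.5 * 1.0 + 0.5
        assert cov == pytest.approx(expected, abs=0.12)

    def test_parent_repeat_covariance(self):
        """Within-individual covariance across replicates = V_A + V_PE (founders)."""
        spec = DesignSpec(n_dams=4000, n_sires=4000, n_families=1,
                          daughters_per_family=1, sons_per_family=1,
                          parent_replicates=2)
        ped = generate_pedigree(spec, seed=6)
        truth = flat_truth(V_Af=1.0, V_Am=1.0, V_PE_f=0.7, V_PE_m=0.7,
                           V_R_f=0.5, V_R_m=0.5)
        df = simulate_phenotypes(ped, truth, spec, seed=6)
        par = df[(df.generation == "parental") & (df.sex == "female")]
        wide = par.pivot_table(index="id", columns="replicate", values="value")
        cov = np.cov(wide[1], wide[2])[0, 1]
        assert cov == pytest.approx(1.7, abs=0.1)


class TestStudy:
    def test_study_structure_and_determinism(self):
        ped1, df1, _ = simulate_study(seed=9)
        ped2, df2, _ = simulate_study(seed=9)
        assert ped1.ids == ped2.ids
        pd.testing.assert_frame_equal(df1, df2)
        assert set(df1.trait.unique()) == set(TRAIT_PRESETS)
        # parents scored twice, offspring once (non-dyadic traits)
        act = df1[df1.trait == "activity"]
        assert (act.groupby("id").size()[
            act[act.generation == "parental"].id.unique()
        ] == 2).all()

    def test_aggression_contests_are_same_sex_dyads(self):
        _, df, _ = simulate_study(seed=10)
        ag = df[(df.trait == "aggression") & (df.contest_id != "NA")]
        sizes = ag.groupby("contest_id").agg(n=("id", "size"), s=("sex", "nunique"))
        assert (sizes.n == 2).all()
        assert (sizes.s == 1).all()

    def test_assortative_study_correlates_mates(self):
        """Realized dam-sire aggression scores correlate strongly under
        rank-matched pairing."""
        ped, df, _ = simulate_study(seed=11)
        ag = df[(df.trait == "aggression") & (df.generation == "parental")]
        scores = ag.groupby("id").value.mean()
        off = [i for i, g in enumerate(ped.generation) if g == "offspring"]
        mates = {(ped.ids[ped.dam[i]], ped.ids[ped.sire[i]]) for i in off}
        d, s = zip(*[(scores[a], scores[b]) for a, b in mates])
        assert stats.spearmanr(d, s).statistic > 0.9
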