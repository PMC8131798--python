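"""Model assembly and the Gibbs sampler's correctness properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spiderqg.model import (
    ChainConfig,
    ModelError,
    ModelSpec,
    PriorSpec,
    build_model,
    gibbs_fit,
)
from spiderqg.pedigree import Pedigree
from spiderqg.simulate import (
    TRAIT_PRESETS,
    DesignSpec,
    TraitTruth,
    generate_pedigree,
    simulate_phenotypes,
    simulate_study,
)
from spiderqg.diagnostics import effective_sample_size

from test_simulate import flat_truth


def founder_table(values, sexes, trait="toy", contest=None):
    rows = []
    for k, (v, s) in enumerate(zip(values, sexes)):
        cid = contest[k] if contest is not None else "NA"
        rows.append((f"x{k}", "female" if s == "f" else "male", "parental",
                     trait, 1, cid, v))
    return pd.DataFrame(
        rows,
        columns=["id", "sex", "generation", "trait", "replicate",
                 "contest_id", "value"],
    )


def founder_ped(sexes):
    return Pedigree.from_records(
        [(f"x{k}", "NA", "NA", s) for k, s in enumerate(sexes)],
        generation=["parental"] * len(sexes),
    )


class TestBuildModel:
    def test_two_founders_four_latent_breeding_values(self):
        ped = founder_ped(["f", "m"])
        df = founder_table([1.0, 2.0], ["f", "m"])
        state = build_model(df, ped, ModelSpec(trait="toy", include_ce=False,
                                               include_pe=False))
        assert state.n_ind == 2  # eta is (2, 2): 2 individuals x 2 sexes
        assert state.n_records == 2

    def test_contest_levels(self):
        sexes = ["f"] * 10 + ["m"] * 10
        cids = [f"c{k // 2}" for k in range(20)]
        ped = founder_ped(sexes)
        df = founder_table(np.arange(20.0), sexes, contest=cids)
        state = build_model(df, ped, ModelSpec(trait="toy", dyadic=True))
        assert state.n_con == 10
        assert all((state.rec_con == k).sum() == 2 for k in range(10))

    def test_log_transform_applied(self):
        ped = founder_ped(["f"])
        df = founder_table([300.0], ["f"])
        state = build_model(df, ped, ModelSpec(trait="toy", transform="log"))
        assert state.y[0] == pytest.approx(np.log(300.0), abs=1e-4)
        assert state.y[0] == pytest.approx(5.7038, abs=1e-4)

    def test_unknown_id_rejected(self):
        ped = founder_ped(["f"])
        df = founder_table([1.0, 2.0], ["f", "m"])
        with pytest.raises(ModelError, match="absent from pedigree"):
            build_model(df, ped, ModelSpec(trait="toy"))

    def test_bad_contests_rejected(self):
        sexes = ["f", "f", "f"]
        ped = founder_ped(sexes)
        df = founder_table([1.0, 2.0, 3.0], sexes, contest=["c0", "c0", "c0"])
        with pytest.raises(ModelError, match="need 2"):
            build_model(df, ped, ModelSpec(trait="toy", dyadic=True))
        sexes = ["f", "m"]
        df = founder_table([1.0, 2.0], sexes, contest=["c0", "c0"])
        with pytest.raises(ModelError, match="mixes sexes"):
            build_model(df, founder_ped(sexes), ModelSpec(trait="toy", dyadic=True))


class TestGibbsSampler:
    def test_residual_only_matches_conjugate_posterior(self):
        """Retained V_R draws reproduce the closed-form scaled-inv-chi2
        posterior in the known-mean, residual-only Gaussian model."""
        rng = np.random.default_rng(12)
        n = 80
        y = rng.normal(0.0, 1.5, size=n)
        ped = founder_ped(["f"] * n)
        df = founder_table(y, ["f"] * n)
        spec = ModelSpec(trait="toy", fixed="none", include_animal=False,
                         include_ce=False, include_pe=False)
        state = build_model(df, ped, spec)
        nu0, s0 = 0.002, state.phenotypic_variance / 2.0
        draws = gibbs_fit(
            state,
            priors=PriorSpec(var_nu=nu0, var_scale=s0),
            chain=ChainConfig(1100, 100, 1, seed=3),
        )
        sse = float(np.sum(state.y**2))
        direct = (nu0 * s0 + sse) / np.random.default_rng(99).chisquare(
            nu0 + n, size=10_000
        )
        ks = stats.ks_2samp(draws["V_R_f"], direct)
        assert ks.pvalue > 0.01

    def test_determinism_contract(self):
        ped, pheno, _ = simulate_study(DesignSpec(n_families=6), seed=20)
        spec = ModelSpec(trait="boldness")
        state = build_model(pheno, ped, spec)
        d1 = gibbs_fit(state, chain=ChainConfig(1100, 100, 1, seed=5)).draws
        d2 = gibbs_fit(state, chain=ChainConfig(1100, 100, 1, seed=5)).draws
        d3 = gibbs_fit(state, chain=ChainConfig(1100, 100, 1, seed=6)).draws
        pd.testing.assert_frame_equal(d1, d2)
        assert not np.allclose(d1["V_R_f"], d3["V_R_f"])
        # different seeds, overlapping posteriors
        assert abs(d1["V_R_f"].mean() - d3["V_R_f"].mean()) < 3 * d1["V_R_f"].std()

    def test_draw_invariants(self):
        """Every retained draw: variances >= 0 and G PSD."""
        ped, pheno, _ = simulate_study(DesignSpec(n_families=8), seed=21)
        state = build_model(pheno, ped, ModelSpec(trait="activity", transform="log"))
        d = gibbs_fit(state, chain=ChainConfig(2000, 500, 2, seed=7)).draws
        var_cols = [c for c in d.columns if c.startswith("V_")]
        assert (d[var_cols].to_numpy() >= 0).all()
        assert (d["COV_A_mf"] ** 2 <= d["V_A_f"] * d["V_A_m"] + 1e-12).all()

    def test_identity_relationship_equals_independent_individual_effect(self):
        """With A = I, the animal variance posterior matches fitting the same
        individual effect as a permanent-environment term under the
        matched marginal prior (IW 2x2 diagonal marginal = scaled-inv-chi2
        with nu = 1.002)."""
        n = 150
        sexes = ["f"] * n
        ped = founder_ped(sexes)
        truth = flat_truth(V_PE_f=1.0, V_R_f=0.5)
        spec_design = DesignSpec(parent_replicates=3)
        df = simulate_phenotypes(ped, truth, spec_design, seed=13)
        vp_half = None  # resolved per-fit from the same data

        sa = build_model(df, ped, ModelSpec(
            trait="toy", fixed="intercept", include_animal=True,
            identity_relationship=True, include_ce=False, include_pe=False))
        pa = PriorSpec(px_g=False, px_var=False, g_nu=2.002)
        da = gibbs_fit(sa, priors=pa, chain=ChainConfig(6000, 1000, 5, seed=8))

        sb = build_model(df, ped, ModelSpec(
            trait="toy", fixed="intercept", include_animal=False,
            include_ce=False, include_pe=True))
        vp_half = sb.phenotypic_variance / 2.0
        pb = PriorSpec(px_g=False, px_var=False,
                       pe_nu=1.002, pe_scale=vp_half / 1.002)
        db = gibbs_fit(sb, priors=pb, chain=ChainConfig(6000, 1000, 5, seed=9))

        va = da["V_A_f"]
        vb = db["V_PE_f"]
        mcse = np.sqrt(
            va.var() / max(effective_sample_size(va)[0], 1)
            + vb.var() / max(effective_sample_size(vb)[0], 1)
        )
        assert abs(va.mean() - vb.mean()) < 5 * mcse + 0.02

    def test_sex_contrast_of_means_recovered(self):
        """Posterior of mu_m - mu_f covers the simulated fixed sex difference."""
        ped, pheno, _ = simulate_study(seed=22)
        state = build_model(pheno, ped, ModelSpec(trait="activity", transform="log"))
        d = gibbs_fit(state, chain=ChainConfig.test(seed=10)).draws
        diff = d["mu_m"] - d["mu_f"]
        lo, hi = np.quantile(diff, [0.025, 0.975])
        truth_diff = TRAIT_PRESETS["activity"].mu_m - TRAIT_PRESETS["activity"].mu_f
        assert lo <= truth_diff <= hi

    def test_strong_additive_signal_recovered(self):
        """With nearly all variance additive, the V_A posterior concentrates
        near the generating value."""
        spec = DesignSpec(n_families=29)
        truth = {"toy": flat_truth(V_Af=1.0, V_Am=1.0, COV_Amf=0.9,
                                   V_R_f=0.05, V_R_m=0.05)}
        ped, pheno, _ = simulate_study(spec, truth, seed=23)
        state = build_model(pheno, ped, ModelSpec(
            trait="toy", include_ce=False, include_pe=False))
        d = gibbs_fit(state, chain=ChainConfig.test(seed=11)).draws
        for col in ("V_A_f", "V_A_m"):
            lo, hi = np.quantile(d[col], [0.025, 0.975])
            assert lo <= 1.0 <= hi, f"{col}: [{lo:.3f}, {hi:.3f}]"

    def test_zero_variance_truth_flags_degeneracy(self):
        """A constant response is flagged as near-degenerate, not a crash."""
        ped = founder_ped(["f"] * 30 + ["m"] * 30)
        df = founder_table([1.0] * 60, ["f"] * 30 + ["m"] * 30)
        state = build_model(df, ped, ModelSpec(trait="toy", include_ce=False))
        with pytest.warns(RuntimeWarning, match="near-degenerate"):
            draws = gibbs_fit(state, chain=ChainConfig(1100, 100, 1, seed=14))
        assert draws.warnings
        assert np.isfinite(draws.draws.to_numpy()).all()
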