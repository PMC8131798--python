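"""End-to-end study orchestration.

``run_study`` takes a pedigree and phenotype table (simulated or from
files), fits the sex-specific animal model per trait, runs convergence
diagnostics, and emits by-sex variance-component and evolvability tables
with female-minus-male contrasts -- the per-trait analogues of the study's
two summary tables -- together with a cross-sex covariance summary, the
r_mf reporting policy, and a reproducibility manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .derived import (
    SummaryRow,
    cross_sex_correlation,
    evolvability_coefficients,
    heritability,
    sex_contrast,
    summarize,
)
from .diagnostics import DiagnosticReport, diagnose_draws
from .model import (
    ChainConfig,
    ModelSpec,
    PosteriorDraws,
    PriorSpec,
    build_model,
    gibbs_fit,
)
from .pedigree import Pedigree, read_pedigree
from .simulate import (
    TRAIT_PRESETS,
    DesignSpec,
    TraitTruth,
    simulate_study,
    write_study,
)

__all__ = ["RunConfig", "TraitResult", "StudyResult", "run_study", "simulate_command"]

#: posterior-mass rule for refusing the cross-sex genetic correlation: if
#: the lower 95% bound of either sex's V_A is below this fraction of the
#: phenotypic variance, the additive variance is indistinguishable from
#: zero and the point estimate of r_mf is withheld.
RMF_REFUSAL_VP_FRACTION = 1e-3


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full study run."""

    out_dir: str | Path = "results/study"
    traits: tuple[str, ...] = ("aggression", "activity", "exploration", "boldness")
    seed: int = 1
    profile: str = "test"  # "test" | "full"
    interval: str = "hpd"  # "hpd" | "quantile"
    pedigree_path: str | None = None
    phenotypes_path: str | None = None
    design: DesignSpec = field(default_factory=DesignSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    rmf_floor: float = 1e-12

    def chain(self, offset: int = 0) -> ChainConfig:
        make = ChainConfig.test if self.profile == "test" else ChainConfig.full
        return make(seed=self.seed + 7919 * (offset + 1))


@dataclass
class TraitResult:
    """Everything the pipeline derives for one trait."""

    trait: str
    draws: PosteriorDraws
    diagnostics: DiagnosticReport
    components_table: pd.DataFrame
    evolvability_table: pd.DataFrame
    rmf_summary: dict
    warnings: list[str] = field(default_factory=list)


@dataclass
class StudyResult:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    traits: dict[str, TraitResult]
    manifest: dict
    failed: dict[str, str] = field(default_factory=dict)


def _fmt(x: float) -> str:
    """3-decimal table formatting with the '<0.001' convention."""
    if not np.isfinite(x):
        return "NA"
    if 0 < abs(x) < 0.001:
        return "<0.001" if x > 0 else ">-0.001"
    return f"{x:.3f}"


def _row_records(name: str, sex: str, row: SummaryRow) -> dict:
    return {
        "quantity": name,
        "sex": sex,
        "mean": row.mean,
        "lower": row.lower,
        "upper": row.upper,
        "pMCMC": row.pmcmc,
        "display": f"{_fmt(row.mean)} [{_fmt(row.lower)}, {_fmt(row.upper)}]",
    }


def trait_tables(
    trait: str,
    draws: PosteriorDraws,
    dyadic: bool,
    mean_f: float,
    mean_m: float,
    interval: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """By-sex variance-component/h2 and evolvability-coefficient tables."""
    per_sex: dict[str, dict[str, np.ndarray]] = {"f": {}, "m": {}}
    for s in ("f", "m"):
        per_sex[s]["V_A"] = draws[f"V_A_{s}"]
        per_sex[s]["V_CEM"] = draws[f"V_CEM_{s}"]
        per_sex[s]["V_PE"] = draws[f"V_PE_{s}"]
        per_sex[s]["V_R"] = draws[f"V_R_{s}"]
        per_sex[s]["h2"] = heritability(draws, s, dyadic=dyadic)
    cvs = evolvability_coefficients(draws, mean_f, mean_m)
    for s in ("f", "m"):
        for q in ("CV_A", "CV_CEM", "CV_PE", "CV_R", "I_A"):
            per_sex[s][q] = cvs[f"{q}_{s}"]

    def build(quantities: list[str]) -> pd.DataFrame:
        rows = []
        for q in quantities:
            rf = summarize(per_sex["f"][q], name=q, interval=interval)
            rm = summarize(per_sex["m"][q], name=q, interval=interval)
            _, rc = sex_contrast(
                per_sex["f"][q], per_sex["m"][q], name=q, interval=interval
            )
            rows.append(_row_records(q, "female", rf))
            rows.append(_row_records(q, "male", rm))
            rows.append(_row_records(q, "female_minus_male", rc))
            # contrast linearity cross-check at emit time
            assert abs(rc.mean - (rf.mean - rm.mean)) < 1e-10 * max(
                1.0, abs(rf.mean), abs(rm.mean)
            ), "contrast row inconsistent with by-sex rows"
        df = pd.DataFrame(rows)
        df.insert(0, "trait", trait)
        return df

    t1 = build(["V_A", "V_CEM", "V_PE", "V_R", "h2"])
    t2 = build(["CV_A", "CV_CEM", "CV_PE", "CV_R", "I_A"])
    return t1, t2


def rmf_policy(
    draws: PosteriorDraws, interval: str, floor: float, vp: float
) -> dict:
    """Cross-sex correlation summary with the refusal rule.

    Per-draw r_mf is undefined below the absolute variance-product floor;
    additionally the point estimate is withheld when the posterior for
    either sex's V_A is concentrated at zero (lower 95% bound below
    RMF_REFUSAL_VP_FRACTION of the phenotypic variance) -- in that regime
    the correlation cannot be estimated with confidence.
    """
    r, frac = cross_sex_correlation(draws, floor=floor)
    cov_row = summarize(draws["COV_A_mf"], name="COV_A_mf", interval=interval)
    va_f = summarize(draws["V_A_f"], name="V_A_f", interval=interval)
    va_m = summarize(draws["V_A_m"], name="V_A_m", interval=interval)
    near_zero = min(va_f.lower, va_m.lower) < RMF_REFUSAL_VP_FRACTION * vp
    withheld = frac < 0.5 or near_zero
    out = {
        "defined_fraction": frac,
        "withheld": bool(withheld),
        "cov_mean": cov_row.mean,
        "cov_lower": cov_row.lower,
        "cov_upper": cov_row.upper,
        "note": "",
    }
    if withheld:
        out["note"] = (
            "additive genetic variance of one or both sexes is consistent "
            "with zero; r_mf not estimable with confidence"
        )
    else:
        row = summarize(r, name="r_mf", interval=interval)
        out.update(
            {"rmf_mean": row.mean, "rmf_lower": row.lower, "rmf_upper": row.upper}
        )
    return out


def analyse_trait(
    trait: str,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    truth: TraitTruth | None = None,
    priors: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    interval: str = "hpd",
    rmf_floor: float = 1e-12,
) -> TraitResult:
    """Fit, diagnose and summarize one trait.

    ``truth`` (when the trait is a known preset) only supplies the model
    shape -- transform and dyadic flag; generating values are never used in
    the fit.
    """
    preset = truth or TRAIT_PRESETS.get(trait)
    transform = preset.transform if preset else "none"
    dyadic = preset.dyadic if preset else False
    spec = ModelSpec(trait=trait, transform=transform, dyadic=dyadic)
    state = build_model(phenotypes, pedigree, spec)
    draws = gibbs_fit(state, priors=priors, chain=chain)
    report = diagnose_draws(draws.draws.loc[:, draws.draws.columns != "V_C"]
                            if not dyadic else draws.draws)

    sub = phenotypes[phenotypes["trait"] == trait]
    mean_f = float(sub.loc[sub["sex"] == "female", "value"].mean())
    mean_m = float(sub.loc[sub["sex"] == "male", "value"].mean())
    t1, t2 = trait_tables(trait, draws, dyadic, mean_f, mean_m, interval)
    rmf = rmf_policy(draws, interval, rmf_floor, state.phenotypic_variance)
    return TraitResult(
        trait=trait, draws=draws, diagnostics=report,
        components_table=t1, evolvability_table=t2, rmf_summary=rmf,
        warnings=list(draws.warnings),
    )


def run_study(config: RunConfig) -> StudyResult:
    """Run the full pipeline: data in, per-trait fits and tables out.

    Inputs come from ``config.pedigree_path``/``phenotypes_path`` when
    given, otherwise a synthetic study at the design scale is simulated
    from the trait presets.  A failing trait aborts that trait only; the
    result records the failure and the remaining traits continue.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.pedigree_path and config.phenotypes_path:
        ped = read_pedigree(config.pedigree_path)
        pheno = pd.read_csv(config.phenotypes_path, keep_default_na=False)
        pheno["value"] = pheno["value"].astype(float)
        source = {"pedigree": str(config.pedigree_path),
                  "phenotypes": str(config.phenotypes_path)}
    else:
        truths = {t: TRAIT_PRESETS[t] for t in config.traits if t in TRAIT_PRESETS}
        ped, pheno, info = simulate_study(config.design, truths, seed=config.seed)
        write_study(out / "input", ped, pheno, info)
        source = {"simulated": True, "seed": config.seed}

    results: dict[str, TraitResult] = {}
    failed: dict[str, str] = {}
    for k, trait in enumerate(config.traits):
        try:
            res = analyse_trait(
                trait, ped, pheno,
                priors=config.priors,
                chain=config.chain(offset=k),
                interval=config.interval,
                rmf_floor=config.rmf_floor,
            )
        except Exception as exc:  # continue with remaining traits
            failed[trait] = f"{type(exc).__name__}: {exc}"
            continue
        results[trait] = res
        tdir = out / trait
        tdir.mkdir(exist_ok=True)
        res.draws.save(tdir / "draws.csv")
        res.components_table.to_csv(tdir / "variance_components.csv", index=False)
        res.evolvability_table.to_csv(tdir / "evolvability.csv", index=False)
        res.diagnostics.to_frame().to_csv(tdir / "diagnostics.csv", index=False)
        with open(tdir / "cross_sex.yaml", "w") as fh:
            yaml.safe_dump(res.rmf_summary, fh, sort_keys=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "profile": config.profile,
        "interval": config.interval,
        "traits": list(config.traits),
        "source": source,
        "chain_seeds": {t: config.chain(offset=k).seed
                        for k, t in enumerate(config.traits)},
        "failed": failed,
        "elapsed_seconds": round(time.time() - t0, 2),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return StudyResult(
        pedigree=ped, phenotypes=pheno, traits=results,
        manifest=manifest, failed=failed,
    )


def simulate_command(
    out_dir: str | Path,
    design: DesignSpec | None = None,
    truths: dict[str, TraitTruth] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate a study and write pedigree/phenotype/config files."""
    ped, pheno, info = simulate_study(design or DesignSpec(), truths, seed=seed)
    return write_study(out_dir, ped, pheno, info)
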