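"""Synthetic breeding-design and phenotype generator.

Emulates the statistical structure of a two-generation spider breeding
study: a field-collected parental generation (~30 dams, ~31 sires) scored
twice per behavioural test, mated assortatively by aggressiveness into
monogamous pairs; 29 full-sib families with a target of 5 daughters and 5
sons each, scored once.  Phenotypes follow a Gaussian animal model with a
2x2 cross-sex additive genetic covariance G over the pedigree relationship
matrix, plus common-environment/maternal, permanent-environment, dyadic
contest and residual components.  Latency traits are right-censored at
300 s on the observation scale; activity and exploration are analysed on
the natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import FEMALE, MALE, SEX_LABELS, Pedigree, inbreeding_coefficients

__all__ = [
    "DesignSpec",
    "TraitTruth",
    "TRAIT_PRESETS",
    "generate_pedigree",
    "assortative_pairing",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_study",
    "write_study",
]

PHENOTYPE_COLUMNS = ["id", "sex", "generation", "trait", "replicate", "contest_id", "value"]


@dataclass(frozen=True)
class DesignSpec:
    """Breeding-design dimensions; defaults reproduce the study layout."""

    n_dams: int = 30
    n_sires: int = 31
    n_families: int = 29
    daughters_per_family: int = 5
    sons_per_family: int = 5
    parent_replicates: int = 2
    offspring_replicates: int = 1
    assortative: bool = True
    #: binomially resample each family's 5/5 sex split (clutches sex-biased)
    sex_ratio_jitter: bool = False

    def __post_init__(self):
        if self.n_families > min(self.n_dams, self.n_sires):
            raise ValueError("n_families exceeds available parental pairs")
        if min(self.parent_replicates, self.offspring_replicates) < 1:
            raise ValueError("replicate counts must be >= 1")


@dataclass(frozen=True)
class TraitTruth:
    """Generating values for one trait, on the analysis scale.

    For log-transformed traits (``transform == "log"``) the latent model and
    all variance components live on the natural-log scale; observed values
    are exponentiated, then clipped to [1, censor_limit] seconds.  V_C is
    the dyadic contest variance and is only meaningful for traits scored in
    same-sex pairs.
    """

    name: str
    mu_f: float
    mu_m: float
    V_Af: float
    V_Am: float
    COV_Amf: float
    V_CEM_f: float
    V_CEM_m: float
    V_PE_f: float
    V_PE_m: float
    V_R_f: float
    V_R_m: float
    V_C: float | None = None
    censor_limit: float | None = None
    transform: str = "none"  # "none" | "log"

    def __post_init__(self):
        variances = (
            self.V_Af, self.V_Am, self.V_CEM_f, self.V_CEM_m,
            self.V_PE_f, self.V_PE_m, self.V_R_f, self.V_R_m,
        )
        if any(v < 0 for v in variances) or (self.V_C is not None and self.V_C < 0):
            raise ValueError(f"{self.name}: variances must be >= 0")
        if self.COV_Amf**2 > self.V_Af * self.V_Am + 1e-12:
            raise ValueError(f"{self.name}: G not PSD (COV_Amf^2 > V_Af*V_Am)")
        if self.censor_limit is not None and self.censor_limit <= 0:
            raise ValueError("censor_limit must be positive")
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")

    @property
    def dyadic(self) -> bool:
        return self.V_C is not None

    @property
    def G(self) -> np.ndarray:
        """2x2 cross-sex additive covariance, order (female, male)."""
        return np.array([[self.V_Af, self.COV_Amf], [self.COV_Amf, self.V_Am]])

    def mu(self, sex: int) -> float:
        return self.mu_f if sex == FEMALE else self.mu_m

    def to_dict(self) -> dict:
        return asdict(self)


# Generating values per trait: variance components are the fitted posterior
# means of the original study; behavioural means are set to match the
# reported raw-scale sex contrasts and mean-standardized coefficients.  The
# contest variance of aggression is not printed in the source tables; 5.0
# is a deliberate mid-range choice (see docs/methods.md).
TRAIT_PRESETS: dict[str, TraitTruth] = {
    "aggression": TraitTruth(
        name="aggression", mu_f=5.2, mu_m=17.4,
        V_Af=3.330, V_Am=59.367, COV_Amf=3.109,
        V_CEM_f=1.663, V_CEM_m=31.016,
        V_PE_f=13.471, V_PE_m=41.030,
        V_R_f=0.723, V_R_m=110.382,
        V_C=5.0, censor_limit=None, transform="none",
    ),
    "activity": TraitTruth(
        name="activity", mu_f=3.4, mu_m=3.7,
        V_Af=0.006, V_Am=0.071, COV_Amf=-0.001,
        V_CEM_f=0.012, V_CEM_m=0.038,
        V_PE_f=0.027, V_PE_m=0.170,
        V_R_f=0.116, V_R_m=0.035,
        V_C=None, censor_limit=300.0, transform="log",
    ),
    "exploration": TraitTruth(
        name="exploration", mu_f=3.6, mu_m=3.4,
        V_Af=0.015, V_Am=0.051, COV_Amf=-0.002,
        V_CEM_f=0.053, V_CEM_m=0.042,
        V_PE_f=0.144, V_PE_m=0.203,
        V_R_f=0.168, V_R_m=0.146,
        V_C=None, censor_limit=300.0, transform="log",
    ),
    "boldness": TraitTruth(
        name="boldness", mu_f=120.0, mu_m=114.25,
        V_Af=327.139, V_Am=173.983, COV_Amf=23.220,
        V_CEM_f=379.028, V_CEM_m=208.236,
        V_PE_f=1326.757, V_PE_m=1431.35,
        V_R_f=2852.365, V_R_m=1100.852,
        V_C=None, censor_limit=300.0, transform="none",
    ),
}


def _founder_ids(spec: DesignSpec) -> tuple[list[str], list[str]]:
    dams = [f"D{i:03d}" for i in range(1, spec.n_dams + 1)]
    sires = [f"S{i:03d}" for i in range(1, spec.n_sires + 1)]
    return dams, sires


def _founder_pedigree(spec: DesignSpec) -> Pedigree:
    dams, sires = _founder_ids(spec)
    recs = [(d, "NA", "NA", "female") for d in dams] + [
        (s, "NA", "NA", "male") for s in sires
    ]
    gen = ["parental"] * len(recs)
    return Pedigree.from_records(recs, generation=gen)


def assortative_pairing(
    dam_scores: dict[str, float], sire_scores: dict[str, float]
) -> tuple[list[tuple[str, str]], list[str], list[str]]:
    """Rank-match dams to sires by phenotypic score (highest with highest).

    Ties are broken by id order.  With unequal counts only the top
    min(n_dams, n_sires) of each sex are paired; the remainder is returned
    unpaired.

    Returns
    -------
    pairs, unpaired_dams, unpaired_sires
    """
    dams = sorted(dam_scores, key=lambda k: (-dam_scores[k], k))
    sires = sorted(sire_scores, key=lambda k: (-sire_scores[k], k))
    k = min(len(dams), len(sires))
    pairs = list(zip(dams[:k], sires[:k]))
    return pairs, dams[k:], sires[k:]


def _offspring_counts(spec: DesignSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    counts = []
    for _ in range(spec.n_families):
        total = spec.daughters_per_family + spec.sons_per_family
        if spec.sex_ratio_jitter:
            p = spec.daughters_per_family / total
            nd = int(rng.binomial(total, p))
        else:
            nd = spec.daughters_per_family
        counts.append((nd, total - nd))
    return counts


def _build_pedigree(
    spec: DesignSpec, pairs: list[tuple[str, str]], rng: np.random.Generator
) -> Pedigree:
    dams, sires = _founder_ids(spec)
    recs = [(d, "NA", "NA", "female") for d in dams] + [
        (s, "NA", "NA", "male") for s in sires
    ]
    gen = ["parental"] * len(recs)
    fam_idx = rng.choice(len(pairs), size=spec.n_families, replace=False)
    fam_idx.sort()
    counts = _offspring_counts(spec, rng)
    for f, (pi, (nd, ns)) in enumerate(zip(fam_idx, counts), start=1):
        dam, sire = pairs[pi]
        for k in range(1, nd + 1):
            recs.append((f"F{f:02d}D{k}", dam, sire, "female"))
            gen.append("offspring")
        for k in range(1, ns + 1):
            recs.append((f"F{f:02d}S{k}", dam, sire, "male"))
            gen.append("offspring")
    return Pedigree.from_records(recs, generation=gen)


def generate_pedigree(spec: DesignSpec, seed: int) -> Pedigree:
    """Generate the two-generation pedigree alone (id-order pairing).

    When phenotype-based assortative mating is wanted, use
    :func:`simulate_study`, which scores the parents first and pairs by
    realized aggression.  Here pairing is by id order (``assortative`` off)
    or by a seeded random permutation, which is exchangeable with any
    phenotype-blind pairing.
    """
    rng = np.random.default_rng(seed)
    dams, sires = _founder_ids(spec)
    if spec.assortative:
        # no scores available at this point: random exchangeable pairing
        sires = [sires[i] for i in rng.permutation(len(sires))]
    pairs = list(zip(dams, sires))
    return _build_pedigree(spec, pairs, rng)


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw (n, 2) paired breeding values a = (a_female, a_male).

    The stacked vector is multivariate normal with covariance G (x) A.  The
    draw walks the pedigree: founders ~ N(0, G); non-founders get the
    parental mid-value plus Mendelian noise with covariance
    G * (1 - 0.25 k_d (1+F_d) - 0.25 k_s (1+F_s)), k = 1 if the parent is
    known -- the gene-flow decomposition of G (x) A.
    """
    n = len(ped)
    vals, vecs = np.linalg.eigh(G)
    if vals.min() < -1e-9 * max(vals.max(), 1.0):
        raise ValueError("G is not positive semi-definite")
    a = np.zeros((n, 2))
    F = inbreeding_coefficients(ped)
    z = rng.standard_normal((n, 2))
    sqrt_vals = np.sqrt(np.clip(vals, 0.0, None))
    for i in range(n):
        d, s = ped.dam[i], ped.sire[i]
        mid = np.zeros(2)
        scale = 1.0
        if d >= 0:
            mid += 0.5 * a[d]
            scale -= 0.25 * (1.0 + F[d])
        if s >= 0:
            mid += 0.5 * a[s]
            scale -= 0.25 * (1.0 + F[s])
        L = (vecs * (sqrt_vals * np.sqrt(scale))) @ vecs.T
        a[i] = mid + L @ z[i]
    return a


def _observe(latent: np.ndarray, truth: TraitTruth) -> np.ndarray:
    """Map latent analysis-scale values to observed (raw) values."""
    raw = np.exp(latent) if truth.transform == "log" else latent.copy()
    if truth.censor_limit is not None:
        raw = np.clip(raw, 1.0, truth.censor_limit)
    return raw


def _contest_rounds(
    ids: list[str], sexes: np.ndarray, n_rounds: int, tag: str,
    rng: np.random.Generator,
) -> list[tuple[str, int, str]]:
    """Random same-sex dyads per measurement round.

    Returns (individual, replicate, contest_id) rows; with an odd count one
    individual per sex sits the round out (no record).
    """
    out = []
    for r in range(1, n_rounds + 1):
        for sx in (FEMALE, MALE):
            members = [i for i, s in zip(ids, sexes) if s == sx]
            perm = rng.permutation(len(members))
            for k in range(len(members) // 2):
                c1, c2 = members[perm[2 * k]], members[perm[2 * k + 1]]
                cid = f"{tag}_{SEX_LABELS[sx][0]}{r}_{k + 1}"
                out.append((c1, r, cid))
                out.append((c2, r, cid))
    return out


def simulate_phenotypes(
    ped: Pedigree,
    truth: TraitTruth,
    spec: DesignSpec,
    seed: int | np.random.Generator,
    breeding_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate a long-format phenotype table for one trait over a pedigree.

    Each record is y = mu_sex + a_(i,sex) + ce_(family,sex) + pe_i
    [+ c_contest] + e on the analysis scale; only the sex-matching component
    of the breeding-value pair is expressed.  Common-environment/maternal
    effects attach to individuals with a known dam (offspring share clutch
    and mother); founders carry none.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ped)
    a = (
        breeding_values
        if breeding_values is not None
        else simulate_breeding_values(ped, truth.G, rng)
    )
    if a.shape != (n, 2):
        raise ValueError("breeding_values shape mismatch with pedigree")

    sd_ce = np.array([np.sqrt(truth.V_CEM_f), np.sqrt(truth.V_CEM_m)])
    sd_pe = np.array([np.sqrt(truth.V_PE_f), np.sqrt(truth.V_PE_m)])
    sd_r = np.array([np.sqrt(truth.V_R_f), np.sqrt(truth.V_R_m)])

    # common environment/maternal effect: one level per (dam, record sex)
    ce_levels: dict[tuple[int, int], float] = {}

    def ce_effect(i: int) -> float:
        d = ped.dam[i]
        if d < 0:
            return 0.0
        key = (d, int(ped.sex[i]))
        if key not in ce_levels:
            ce_levels[key] = rng.normal(0.0, sd_ce[key[1]])
        return ce_levels[key]

    pe = rng.normal(0.0, 1.0, size=n) * sd_pe[ped.sex]

    is_parent = np.array([g == "parental" for g in ped.generation])
    rows: list[tuple] = []

    def records_for(idx: np.ndarray, n_rep: int, tag: str):
        ids = [ped.ids[i] for i in idx]
        sexes = ped.sex[idx]
        if truth.dyadic:
            sched = _contest_rounds(ids, sexes, n_rep, tag, rng)
            contest_eff = {}
            for ident, rep, cid in sched:
                if cid not in contest_eff:
                    contest_eff[cid] = rng.normal(0.0, np.sqrt(truth.V_C))
                i = ped.index[ident]
                sx = int(ped.sex[i])
                y = (
                    truth.mu(sx) + a[i, sx] + ce_effect(i) + pe[i]
                    + contest_eff[cid] + rng.normal(0.0, sd_r[sx])
                )
                rows.append((ident, SEX_LABELS[sx], ped.generation[i],
                             truth.name, rep, cid, y))
        else:
            for rep in range(1, n_rep + 1):
                for i in idx:
                    sx = int(ped.sex[i])
                    y = (
                        truth.mu(sx) + a[i, sx] + ce_effect(i) + pe[i]
                        + rng.normal(0.0, sd_r[sx])
                    )
                    rows.append((ped.ids[i], SEX_LABELS[sx], ped.generation[i],
                                 truth.name, rep, "NA", y))

    records_for(np.where(is_parent)[0], spec.parent_replicates, "P")
    records_for(np.where(~is_parent)[0], spec.offspring_replicates, "O")

    df = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    df["value"] = _observe(df["value"].to_numpy(float), truth)
    return df


def simulate_study(
    spec: DesignSpec = DesignSpec(),
    truths: dict[str, TraitTruth] | None = None,
    seed: int = 0,
) -> tuple[Pedigree, pd.DataFrame, dict]:
    """Simulate the full study: pedigree plus phenotypes for every trait.

    Mirrors the actual field protocol: the parental generation is scored
    first (twice per test), pairs are then formed assortatively by each
    individual's mean aggression score, families are drawn, and offspring
    are scored once.  Offspring breeding values for aggression are drawn
    conditionally on the realized parental values, so assortative mating
    propagates into the genetic structure the way it did in the study.

    Returns (pedigree, phenotype table, info dict).
    """
    truths = dict(TRAIT_PRESETS) if truths is None else truths
    rng = np.random.default_rng(seed)
    info: dict = {"seed": seed, "design": asdict(spec)}

    pair_trait = "aggression" if "aggression" in truths else next(iter(truths))
    tr = truths[pair_trait]

    founders = _founder_pedigree(spec)
    a_founder = simulate_breeding_values(founders, tr.G, rng)
    parent_pheno = simulate_phenotypes(
        founders, tr, spec, rng, breeding_values=a_founder
    )

    if spec.assortative:
        scores = parent_pheno.groupby("id")["value"].mean()
        dam_scores = {i: scores.get(i, -np.inf) for i in founders.ids
                      if founders.sex_of(i) == FEMALE}
        sire_scores = {i: scores.get(i, -np.inf) for i in founders.ids
                       if founders.sex_of(i) == MALE}
        pairs, un_d, un_s = assortative_pairing(dam_scores, sire_scores)
        info["unpaired"] = {"dams": un_d, "sires": un_s}
    else:
        dams, sires = _founder_ids(spec)
        pairs = list(zip(dams, sires))
    ped = _build_pedigree(spec, pairs, rng)

    # carry the realized parental aggression breeding values into the full
    # pedigree, then draw offspring conditionally (gene flow)
    a_full = np.zeros((len(ped), 2))
    founder_set = set(founders.ids)
    for ident in founders.ids:
        a_full[ped.index[ident]] = a_founder[founders.index[ident]]
    z = rng.standard_normal((len(ped), 2))
    vals, vecs = np.linalg.eigh(tr.G)
    L_half = vecs @ np.diag(np.sqrt(np.clip(vals, 0.0, None) * 0.5)) @ vecs.T
    for i in range(len(ped)):
        if ped.ids[i] in founder_set:
            continue
        d, s = ped.dam[i], ped.sire[i]
        a_full[i] = 0.5 * (a_full[d] + a_full[s]) + L_half @ z[i]

    tables = [parent_pheno]
    # offspring records for the pairing trait, on the full pedigree
    off_idx = np.where(np.array([g != "parental" for g in ped.generation]))[0]
    if len(off_idx):
        tables.append(_offspring_phenotypes(ped, tr, spec, rng, a_full, off_idx))

    for name, truth in truths.items():
        if name == pair_trait:
            continue
        tables.append(simulate_phenotypes(ped, truth, spec, rng))

    pheno = pd.concat(tables, ignore_index=True)
    info["truths"] = {k: v.to_dict() for k, v in truths.items()}
    return ped, pheno, info


def _offspring_phenotypes(
    ped: Pedigree, truth: TraitTruth, spec: DesignSpec,
    rng: np.random.Generator, a: np.ndarray, idx: np.ndarray,
) -> pd.DataFrame:
    """Offspring records for the pairing trait, given fixed breeding values."""
    sd_ce = np.array([np.sqrt(truth.V_CEM_f), np.sqrt(truth.V_CEM_m)])
    sd_pe = np.array([np.sqrt(truth.V_PE_f), np.sqrt(truth.V_PE_m)])
    sd_r = np.array([np.sqrt(truth.V_R_f), np.sqrt(truth.V_R_m)])
    ce_levels: dict[tuple[int, int], float] = {}
    pe = rng.normal(0.0, 1.0, size=len(ped)) * sd_pe[ped.sex]
    rows: list[tuple] = []
    ids = [ped.ids[i] for i in idx]
    sexes = ped.sex[idx]
    if truth.dyadic:
        sched = _contest_rounds(ids, sexes, spec.offspring_replicates, "O", rng)
        contest_eff: dict[str, float] = {}
        for ident, rep, cid in sched:
            if cid not in contest_eff:
                contest_eff[cid] = rng.normal(0.0, np.sqrt(truth.V_C))
            i = ped.index[ident]
            sx = int(ped.sex[i])
            key = (ped.dam[i], sx)
            if key not in ce_levels:
                ce_levels[key] = rng.normal(0.0, sd_ce[sx])
            y = (truth.mu(sx) + a[i, sx] + ce_levels[key] + pe[i]
                 + contest_eff[cid] + rng.normal(0.0, sd_r[sx]))
            rows.append((ident, SEX_LABELS[sx], ped.generation[i],
                         truth.name, rep, cid, y))
    else:
        for rep in range(1, spec.offspring_replicates + 1):
            for i in idx:
                sx = int(ped.sex[i])
                key = (ped.dam[i], sx)
                if key not in ce_levels:
                    ce_levels[key] = rng.normal(0.0, sd_ce[sx])
                y = (truth.mu(sx) + a[i, sx] + ce_levels[key] + pe[i]
                     + rng.normal(0.0, sd_r[sx]))
                rows.append((ped.ids[i], SEX_LABELS[sx], ped.generation[i],
                             truth.name, rep, "NA", y))
    df = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    df["value"] = _observe(df["value"].to_numpy(float), truth)
    return df


def write_study(
    out_dir: str | Path, ped: Pedigree, pheno: pd.DataFrame, info: dict
) -> dict[str, Path]:
    """Write pedigree, phenotypes and the generating configuration."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": out / "pedigree.csv",
        "phenotypes": out / "phenotypes.csv",
        "truth": out / "simulation_config.yaml",
    }
    ped.write(paths["pedigree"])
    pheno.to_csv(paths["phenotypes"], index=False)
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(info, fh, sort_keys=False)
    return paths
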