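"""Bayesian animal model with sex-specific variance structure, by Gibbs sampling.

The model for a record j on individual i of sex s is

    y_ij = mu_s + a_{i,s} + ce_{fam(i),s} + pe_i + c_{contest(ij)} + e_ij

where the breeding-value pairs a_i = (a_{i,f}, a_{i,m}) are jointly
multivariate normal with covariance G (x) A over the pedigree (an
unstructured 2x2 cross-sex G; only the sex-matching component is ever
expressed in a record), and the common-environment/maternal (ce),
permanent-environment (pe) and residual terms carry independent per-sex
variances with cross-sex covariances constrained to zero.  The contest term
(dyadic traits only) is a single pooled variance shared by the two same-sex
contestants of a trial.

Sampling is a systematic-scan Gibbs sweep: Gaussian full conditionals for
all location effects (breeding-value pairs updated individual-by-individual
through the sparse A-inverse), an inverse-Wishart conditional for G driven
by the A-inverse-weighted cross-products of the pairs, and scaled
inverse-chi-square conditionals for every diagonal variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from numba import njit
from scipy import sparse
from scipy.stats import invwishart

from .pedigree import FEMALE, MALE, Pedigree, inverse_relationship

__all__ = [
    "ModelSpec",
    "PriorSpec",
    "ChainConfig",
    "ModelState",
    "PosteriorDraws",
    "ModelError",
    "build_model",
    "gibbs_fit",
]

#: canonical parameter order of the posterior draw matrix
PARAM_NAMES = [
    "V_A_f", "V_A_m", "COV_A_mf",
    "V_CEM_f", "V_CEM_m",
    "V_PE_f", "V_PE_m",
    "V_R_f", "V_R_m",
    "V_C",
    "mu_f", "mu_m",
]


class ModelError(ValueError):
    """Raised for records or structures the model cannot accommodate."""


@dataclass(frozen=True)
class ModelSpec:
    """Which terms the model carries for one trait.

    The animal term is always a 2x2 unstructured cross-sex block; CE/M, PE
    and residual are sex-diagonal (no cross-sex covariance).  ``dyadic``
    adds the pooled contest variance.  ``include_animal`` exists so reduced
    models (e.g. residual-only) can be fitted for calibration; the full
    analysis always keeps it on.
    """

    trait: str
    transform: str = "none"  # "none" | "log"
    dyadic: bool = False
    fixed: str = "sex"  # "sex" | "intercept" | "none"
    include_animal: bool = True
    include_ce: bool = True
    include_pe: bool = True
    #: replace A with the identity (independent individual genetic effects)
    identity_relationship: bool = False

    def __post_init__(self):
        if self.transform not in ("none", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.fixed not in ("sex", "intercept", "none"):
            raise ValueError(f"unknown fixed-effect spec {self.fixed!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative conjugate priors.

    The 2x2 G block takes an inverse-Wishart prior with ``g_nu`` degrees of
    freedom; by default it is parameter-expanded (``px_g``): the breeding
    values are modelled as a = diag(lambda_f, lambda_m) eta with
    eta ~ N(0, G_w (x) A), G_w ~ IW(g_scale, g_nu) on an identity-scale
    working parameterization and lambda_s ~ N(0, ``px_variance``), giving
    the reported G = Lambda G_w Lambda a heavy-tailed prior with mass at
    zero -- appropriate for additive variances that may vanish.  With
    ``px_g=False`` the IW acts directly on G with scale diag(V_P / 2).
    Every diagonal variance takes a scaled inverse-chi-square prior with
    scale ``var_scale`` (default V_P / 2) and tiny belief ``var_nu``;
    fixed effects are N(0, ``fixed_variance``).  ``None`` scales are
    resolved against the observed phenotypic variance at fit time.
    """

    g_scale: np.ndarray | None = None
    g_nu: float = 2.002
    var_scale: float | None = None
    var_nu: float = 0.002
    fixed_variance: float = 1e8
    px_g: bool = True
    #: parameter-expand the CE/M, PE and contest variances as well
    px_var: bool = True
    px_variance: float | None = None  # None -> phenotypic variance
    #: optional overrides for the permanent-environment block
    pe_scale: float | None = None
    pe_nu: float | None = None

    def resolved(self, phenotypic_variance: float) -> "PriorSpec":
        # degenerate-input guard: a constant response still yields proper priors
        phenotypic_variance = max(float(phenotypic_variance), 1e-8)
        g = self.g_scale
        if g is None:
            g = (
                np.eye(2)
                if self.px_g
                else np.eye(2) * phenotypic_variance / 2.0
            )
        g = np.asarray(g, dtype=float)
        if g.shape != (2, 2) or not np.allclose(g, g.T):
            raise ValueError("g_scale must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(g).min() <= 0:
            raise ValueError("g_scale must be positive definite")
        if self.g_nu <= 1.0:
            raise ValueError("g_nu must exceed dim - 1 = 1 for a proper prior")
        v = self.var_scale if self.var_scale is not None else phenotypic_variance / 2.0
        pxv = self.px_variance if self.px_variance is not None else phenotypic_variance
        return PriorSpec(
            g_scale=g, g_nu=self.g_nu, var_scale=float(v),
            var_nu=self.var_nu, fixed_variance=self.fixed_variance,
            px_g=self.px_g, px_var=self.px_var, px_variance=float(pxv),
            pe_scale=self.pe_scale if self.pe_scale is not None else float(v),
            pe_nu=self.pe_nu if self.pe_nu is not None else self.var_nu,
        )


@dataclass(frozen=True)
class ChainConfig:
    """MCMC chain settings."""

    n_iterations: int = 130_000
    burn_in: int = 30_000
    thin: int = 100
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_retained < 100:
            raise ValueError("fewer than 100 retained draws; lengthen the chain")

    @property
    def n_retained(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin

    @classmethod
    def full(cls, seed: int = 0) -> "ChainConfig":
        return cls(130_000, 30_000, 100, seed)

    @classmethod
    def test(cls, seed: int = 0) -> "ChainConfig":
        """Short profile for desk-scale runs (1,000 retained draws)."""
        return cls(13_000, 3_000, 10, seed)


@dataclass
class ModelState:
    """Assembled design structures linking records to random-effect levels."""

    spec: ModelSpec
    y: np.ndarray                  # transformed record values
    rec_ind: np.ndarray            # pedigree index per record
    rec_sex: np.ndarray            # 0/1 per record
    n_ind: int
    ind_sex: np.ndarray            # sex per pedigree individual
    Ainv: sparse.csr_matrix | None
    rec_ce: np.ndarray             # CE level per record, -1 if none
    ce_sex: np.ndarray             # sex per CE level
    rec_pe: np.ndarray             # PE level (= individual) per record
    rec_con: np.ndarray            # contest level per record, -1 if none
    n_con: int
    con_sex: np.ndarray
    phenotypic_variance: float
    ids: tuple[str, ...] = ()

    @property
    def n_records(self) -> int:
        return self.y.size


def build_model(
    phenotypes: pd.DataFrame, ped: Pedigree, spec: ModelSpec
) -> ModelState:
    """Assemble incidence structures for one trait.

    Applies the trait's transform here (natural log for latency-type
    traits), attaches the sparse A-inverse, and validates that every record
    maps into the pedigree and every contest is a same-sex dyad.
    """
    df = phenotypes[phenotypes["trait"] == spec.trait]
    if df.empty:
        raise ModelError(f"no records for trait {spec.trait!r}")

    missing = sorted(set(df["id"].astype(str)) - set(ped.ids))
    if missing:
        raise ModelError(f"record id(s) absent from pedigree: {missing[:5]}")

    rec_ind = np.array([ped.index[i] for i in df["id"].astype(str)], dtype=np.int64)
    rec_sex = ped.sex[rec_ind].astype(np.int64)

    y = df["value"].to_numpy(dtype=float)
    if spec.transform == "log":
        if (y <= 0).any():
            raise ModelError("log transform requires strictly positive values")
        y = np.log(y)

    # common environment/maternal: level per (dam, record sex); founders none
    if spec.include_ce:
        dam = ped.dam[rec_ind]
        keys = [(int(d), int(s)) if d >= 0 else None for d, s in zip(dam, rec_sex)]
        level_of: dict[tuple[int, int], int] = {}
        rec_ce = np.full(len(df), -1, dtype=np.int64)
        ce_sex_list: list[int] = []
        for r, k in enumerate(keys):
            if k is None:
                continue
            if k not in level_of:
                level_of[k] = len(ce_sex_list)
                ce_sex_list.append(k[1])
            rec_ce[r] = level_of[k]
        ce_sex = np.array(ce_sex_list, dtype=np.int64)
    else:
        rec_ce = np.full(len(df), -1, dtype=np.int64)
        ce_sex = np.zeros(0, dtype=np.int64)

    rec_pe = rec_ind if spec.include_pe else np.full(len(df), -1, dtype=np.int64)

    if spec.dyadic:
        contest = df["contest_id"].astype(str).to_numpy()
        if (contest == "NA").any() or (contest == "nan").any():
            raise ModelError("dyadic trait has records without a contest_id")
        con_levels = {c: k for k, c in enumerate(pd.unique(contest))}
        rec_con = np.array([con_levels[c] for c in contest], dtype=np.int64)
        con_sex = np.zeros(len(con_levels), dtype=np.int64)
        for c, k in con_levels.items():
            members = np.where(rec_con == k)[0]
            if members.size != 2:
                raise ModelError(f"contest {c!r} has {members.size} records, need 2")
            if rec_sex[members[0]] != rec_sex[members[1]]:
                raise ModelError(f"contest {c!r} mixes sexes")
            con_sex[k] = rec_sex[members[0]]
        n_con = len(con_levels)
    else:
        rec_con = np.full(len(df), -1, dtype=np.int64)
        con_sex = np.zeros(0, dtype=np.int64)
        n_con = 0

    if spec.include_animal:
        if spec.identity_relationship:
            Ainv = sparse.identity(len(ped), format="csr")
        else:
            Ainv = inverse_relationship(ped)
    else:
        Ainv = None

    return ModelState(
        spec=spec,
        y=y,
        rec_ind=rec_ind,
        rec_sex=rec_sex,
        n_ind=len(ped),
        ind_sex=ped.sex.astype(np.int64),
        Ainv=Ainv,
        rec_ce=rec_ce,
        ce_sex=ce_sex,
        rec_pe=rec_pe,
        rec_con=rec_con,
        n_con=n_con,
        con_sex=con_sex,
        phenotypic_variance=float(np.var(y, ddof=1)) if y.size > 1 else 1.0,
        ids=ped.ids,
    )


@njit(cache=True)
def _bv_sweep(indptr, indices, data, a, ginv00, ginv01, ginv11, dprec, r, z):
    """One systematic sweep over breeding-value pairs.

    For individual i the full conditional of a_i = (a_f, a_m) has precision
    Ainv[i,i] * Ginv + diag(dprec[i]) and linear term
    -Ginv @ (sum_{j != i} Ainv[i,j] a_j) + r[i]; solved by a hand-rolled
    2x2 Cholesky so the sweep stays allocation-free.
    """
    n = a.shape[0]
    for i in range(n):
        s0 = 0.0
        s1 = 0.0
        aii = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            w = data[k]
            if j == i:
                aii = w
            else:
                s0 += w * a[j, 0]
                s1 += w * a[j, 1]
        p00 = aii * ginv00 + dprec[i, 0]
        p01 = aii * ginv01
        p11 = aii * ginv11 + dprec[i, 1]
        b0 = -(ginv00 * s0 + ginv01 * s1) + r[i, 0]
        b1 = -(ginv01 * s0 + ginv11 * s1) + r[i, 1]
        # Cholesky P = L L^T
        l00 = np.sqrt(p00)
        l10 = p01 / l00
        l11 = np.sqrt(p11 - l10 * l10)
        # mean = P^-1 b via forward/back substitution
        u0 = b0 / l00
        u1 = (b1 - l10 * u0) / l11
        m1 = u1 / l11
        m0 = (u0 - l10 * m1) / l00
        # noise with covariance P^-1: solve L^T x = z
        x1 = z[i, 1] / l11
        x0 = (z[i, 0] - l10 * x1) / l00
        a[i, 0] = m0 + x0
        a[i, 1] = m1 + x1
    return a


@dataclass
class PosteriorDraws:
    """Retained MCMC samples over variance components and fixed effects."""

    draws: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.draws)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    @property
    def warnings(self) -> list[str]:
        return self.meta.get("warnings", [])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.draws.to_csv(path, index=False)
        with open(path.with_suffix(".meta.yaml"), "w") as fh:
            yaml.safe_dump(self.meta, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PosteriorDraws":
        path = Path(path)
        draws = pd.read_csv(path)
        meta_path = path.with_suffix(".meta.yaml")
        meta = {}
        if meta_path.exists():
            with open(meta_path) as fh:
                meta = yaml.safe_load(fh)
        return cls(draws=draws, meta=meta)


def _scaled_inv_chi2(rng, nu: float, scale_sum: float) -> float:
    """Draw from nu*s^2 / chi2_nu given the accumulated scale nu*s^2.

    Floored at a tiny positive value so degenerate (constant) data cannot
    produce a division by zero downstream; the near-degeneracy is flagged
    separately.
    """
    return max(scale_sum / rng.chisquare(nu), 1e-300)


def gibbs_fit(
    state: ModelState, priors: PriorSpec | None = None,
    chain: ChainConfig | None = None,
) -> PosteriorDraws:
    """Fit the assembled model by systematic-scan Gibbs sampling.

    Deterministic given ``chain.seed``.  Returns the retained draws after
    burn-in and thinning, with chain metadata (spec, priors, seed,
    accumulated degeneracy warnings) attached.
    """
    priors = (priors or PriorSpec()).resolved(state.phenotypic_variance)
    chain = chain or ChainConfig()
    rng = np.random.default_rng(chain.seed)
    spec = state.spec

    y = state.y
    n_rec = y.size
    rec_ind, rec_sex = state.rec_ind, state.rec_sex
    n_ind = state.n_ind
    sex_mask = [rec_sex == FEMALE, rec_sex == MALE]
    n_by_sex = np.array([int(m.sum()) for m in sex_mask])

    has_animal = spec.include_animal
    has_ce = spec.include_ce and state.ce_sex.size > 0
    has_pe = spec.include_pe
    has_con = spec.dyadic and state.n_con > 0

    if has_animal:
        Ainv = state.Ainv.tocsr()
        indptr, indices, dataA = Ainv.indptr, Ainv.indices, Ainv.data
        # records per individual, own sex only
        n_rec_ind = np.bincount(rec_ind, minlength=n_ind).astype(float)

    # state initialisation: half the phenotypic variance to the residual,
    # the rest spread across the fitted components
    vp = state.phenotypic_variance
    n_comp = 1 + has_animal + has_ce + has_pe + has_con
    share = max(vp, 1e-8) / max(n_comp, 1)
    px = bool(priors.px_g) and has_animal
    px_var = bool(priors.px_var)
    Gw = np.eye(2) * (1.0 if px else max(share, 1e-8))
    lam = np.ones(2)
    # working variances and expansion scalars for the diagonal blocks;
    # reported variance = lambda^2 * W (lambda fixed at 1 without PX)
    W_CEM = np.array([share, share]) if has_ce else np.zeros(2)
    W_PE = np.array([share, share]) if has_pe else np.zeros(2)
    W_C = share if has_con else 0.0
    lam_ce = np.ones(2)
    lam_pe = np.ones(2)
    lam_c = 1.0
    V_R = np.array([max(vp - (n_comp - 1) * share, share), ] * 2)

    mu = np.zeros(2)
    eta = np.zeros((n_ind, 2))  # working breeding values; a = Lambda eta
    ce = np.zeros(max(state.ce_sex.size, 1))
    pe = np.zeros(n_ind)
    con = np.zeros(max(state.n_con, 1))

    # per-record contributions of each term
    def location(exclude: str = "") -> np.ndarray:
        pred = mu[rec_sex].copy() if spec.fixed != "none" else np.zeros(n_rec)
        if spec.fixed == "intercept":
            pred = np.full(n_rec, mu[0])
        if has_animal and exclude != "a":
            pred += lam[rec_sex] * eta[rec_ind, rec_sex]
        if has_ce and exclude != "ce":
            m = state.rec_ce >= 0
            lvl = state.rec_ce[m]
            pred[m] += lam_ce[state.ce_sex[lvl]] * ce[lvl]
        if has_pe and exclude != "pe":
            pred += lam_pe[rec_sex] * pe[rec_ind]
        if has_con and exclude != "con":
            pred += lam_c * con[state.rec_con]
        return pred

    n_save = chain.n_retained
    out = np.empty((n_save, len(PARAM_NAMES)))
    save_k = 0
    warn_msgs: list[str] = []
    degenerate_flagged = False
    if vp < 1e-12 * max(float(np.mean(y**2)), 1e-300):
        degenerate_flagged = True
        msg = (
            "response is (nearly) constant: conditionals are near-degenerate "
            "and the posterior is prior-dominated"
        )
        warn_msgs.append(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    g_nu0 = priors.g_nu
    g_S0 = priors.g_scale
    v_nu0 = priors.var_nu
    v_s0 = priors.var_scale
    mu_prec0 = 1.0 / priors.fixed_variance

    ce_sex_masks = (
        [state.ce_sex == FEMALE, state.ce_sex == MALE] if has_ce else None
    )
    ind_sex_masks = [state.ind_sex == FEMALE, state.ind_sex == MALE]
    rec_has_ce = state.rec_ce >= 0

    for it in range(chain.n_iterations):
        w_rec = 1.0 / V_R[rec_sex]

        # --- fixed effects ---
        if spec.fixed != "none":
            resid = y - location(exclude="")
            resid += mu[rec_sex] if spec.fixed == "sex" else mu[0]
            if spec.fixed == "sex":
                for s in (FEMALE, MALE):
                    m = sex_mask[s]
                    if not m.any():
                        mu[s] = 0.0
                        continue
                    prec = n_by_sex[s] / V_R[s] + mu_prec0
                    mean = (resid[m].sum() / V_R[s]) / prec
                    mu[s] = mean + rng.standard_normal() / np.sqrt(prec)
            else:
                prec = float(np.sum(w_rec)) + mu_prec0
                mean = float(np.sum(resid * w_rec)) / prec
                mu[0] = mu[1] = mean + rng.standard_normal() / np.sqrt(prec)

        # --- breeding-value pairs (working scale) ---
        if has_animal:
            resid = y - location(exclude="a")
            r = np.zeros((n_ind, 2))
            np.add.at(r, (rec_ind, rec_sex), resid * w_rec)
            r[:, 0] *= lam[0]
            r[:, 1] *= lam[1]
            dprec = np.zeros((n_ind, 2))
            dprec[np.arange(n_ind), state.ind_sex] = (
                lam[state.ind_sex] ** 2 * n_rec_ind / V_R[state.ind_sex]
            )
            Ginv = np.linalg.inv(Gw)
            z = rng.standard_normal((n_ind, 2))
            _bv_sweep(
                indptr, indices, dataA, eta,
                Ginv[0, 0], Ginv[0, 1], Ginv[1, 1], dprec, r, z,
            )
            if px:
                # expansion scalars: per-sex regression of the partial
                # residual on the working breeding value
                x = eta[rec_ind, rec_sex]
                for s in (FEMALE, MALE):
                    m = sex_mask[s]
                    if not m.any():
                        continue
                    sxx = float(np.sum(x[m] ** 2)) / V_R[s]
                    sxy = float(np.sum(x[m] * resid[m])) / V_R[s]
                    prec = sxx + 1.0 / priors.px_variance
                    lam = lam.copy()
                    lam[s] = sxy / prec + rng.standard_normal() / np.sqrt(prec)

        def _px_scalar(x_rec, resid, mask):
            """Gaussian draw for an expansion scalar by weighted regression."""
            sxx = float(np.sum((x_rec[mask] ** 2) * w_rec[mask]))
            sxy = float(np.sum(x_rec[mask] * resid[mask] * w_rec[mask]))
            prec = sxx + 1.0 / priors.px_variance
            return sxy / prec + rng.standard_normal() / np.sqrt(prec)

        # --- common environment/maternal levels ---
        if has_ce:
            resid = y - location(exclude="ce")
            lvl_lam = lam_ce[state.ce_sex]
            n_lvl = np.bincount(
                state.rec_ce[rec_has_ce], minlength=state.ce_sex.size
            ).astype(float)
            ssum = np.bincount(
                state.rec_ce[rec_has_ce],
                weights=(resid * w_rec)[rec_has_ce],
                minlength=state.ce_sex.size,
            )
            prec = lvl_lam**2 * n_lvl / V_R[state.ce_sex] + 1.0 / W_CEM[state.ce_sex]
            ce = (lvl_lam * ssum) / prec + rng.standard_normal(
                state.ce_sex.size
            ) / np.sqrt(prec)
            if px_var:
                x = np.zeros(n_rec)
                x[rec_has_ce] = ce[state.rec_ce[rec_has_ce]]
                lam_ce = lam_ce.copy()
                for s in (FEMALE, MALE):
                    m = rec_has_ce & sex_mask[s]
                    if m.any():
                        lam_ce[s] = _px_scalar(x, resid, m)

        # --- permanent environment levels ---
        if has_pe:
            resid = y - location(exclude="pe")
            lvl_lam = lam_pe[state.ind_sex]
            n_lvl = np.bincount(rec_ind, minlength=n_ind).astype(float)
            ssum = np.bincount(rec_ind, weights=resid * w_rec, minlength=n_ind)
            prec = lvl_lam**2 * n_lvl / V_R[state.ind_sex] + 1.0 / W_PE[state.ind_sex]
            pe = (lvl_lam * ssum) / prec + rng.standard_normal(n_ind) / np.sqrt(prec)
            if px_var:
                x = pe[rec_ind]
                lam_pe = lam_pe.copy()
                for s in (FEMALE, MALE):
                    m = sex_mask[s]
                    if m.any():
                        lam_pe[s] = _px_scalar(x, resid, m)

        # --- contest levels ---
        if has_con:
            resid = y - location(exclude="con")
            n_lvl = np.bincount(state.rec_con, minlength=state.n_con).astype(float)
            ssum = np.bincount(
                state.rec_con, weights=resid * w_rec, minlength=state.n_con
            )
            prec = lam_c**2 * n_lvl / V_R[state.con_sex] + 1.0 / W_C
            con = (lam_c * ssum) / prec + rng.standard_normal(
                state.n_con
            ) / np.sqrt(prec)
            if px_var:
                x = con[state.rec_con]
                lam_c = _px_scalar(x, resid, np.ones(n_rec, dtype=bool))

        # --- variance components ---
        if has_animal:
            Sa = (eta.T @ (Ainv @ eta))
            Sa = 0.5 * (Sa + Sa.T)
            Gw = invwishart.rvs(
                df=g_nu0 + n_ind, scale=g_S0 + Sa, random_state=rng
            )
            Gw = np.atleast_2d(Gw)

        # Under PX the working blocks take a unit-scale inverse-chi-square
        # with 1 df, so each reported variance lambda^2 W has a scaled-F
        # marginal (heavy tail, finite density at zero); without PX the
        # data-scale priors act directly.
        w_s0 = 1.0 if px_var else v_s0
        w_nu0 = 1.0 if px_var else v_nu0
        if has_ce:
            for s in (FEMALE, MALE):
                m = ce_sex_masks[s]
                cnt = int(m.sum())
                if cnt == 0:
                    continue
                ss = float(np.sum(ce[m] ** 2))
                W_CEM[s] = _scaled_inv_chi2(rng, w_nu0 + cnt, w_nu0 * w_s0 + ss)

        if has_pe:
            pe_s0 = 1.0 if px_var else priors.pe_scale
            pe_nu0 = 1.0 if px_var else priors.pe_nu
            for s in (FEMALE, MALE):
                m = ind_sex_masks[s]
                cnt = int(m.sum())
                if cnt == 0:
                    continue
                ss = float(np.sum(pe[m] ** 2))
                W_PE[s] = _scaled_inv_chi2(
                    rng, pe_nu0 + cnt, pe_nu0 * pe_s0 + ss
                )

        if has_con:
            ss = float(np.sum(con**2))
            W_C = _scaled_inv_chi2(rng, w_nu0 + state.n_con, w_nu0 * w_s0 + ss)

        resid = y - location(exclude="")
        for s in (FEMALE, MALE):
            m = sex_mask[s]
            if not m.any():
                continue
            ss = float(np.sum(resid[m] ** 2))
            V_R[s] = _scaled_inv_chi2(rng, v_nu0 + n_by_sex[s], v_nu0 * v_s0 + ss)

        if not np.all(np.isfinite(V_R)) or not np.all(np.isfinite(Gw)):
            raise ModelError(
                "conditional precision not positive definite: identifiability "
                f"failure at iteration {it}"
            )
        if not degenerate_flagged and (V_R.min() < 1e-12 * max(vp, 1e-8)):
            degenerate_flagged = True
            msg = (
                "near-degenerate residual variance encountered; posterior may "
                "be dominated by the prior"
            )
            warn_msgs.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            if save_k < n_save:
                G = Gw * np.outer(lam, lam)  # reported scale
                out[save_k] = [
                    G[0, 0], G[1, 1], G[0, 1],
                    lam_ce[0] ** 2 * W_CEM[0], lam_ce[1] ** 2 * W_CEM[1],
                    lam_pe[0] ** 2 * W_PE[0], lam_pe[1] ** 2 * W_PE[1],
                    V_R[0], V_R[1],
                    lam_c**2 * W_C,
                    mu[0], mu[1],
                ]
                save_k += 1

    draws = pd.DataFrame(out[:save_k], columns=PARAM_NAMES)
    meta = {
        "trait": spec.trait,
        "model": asdict(spec),
        "priors": {
            "g_scale": np.asarray(priors.g_scale).tolist(),
            "g_nu": priors.g_nu,
            "var_scale": priors.var_scale,
            "var_nu": priors.var_nu,
            "fixed_variance": priors.fixed_variance,
            "px_g": bool(priors.px_g),
            "px_var": bool(priors.px_var),
            "px_variance": priors.px_variance,
        },
        "chain": asdict(chain),
        "n_records": int(n_rec),
        "n_individuals": int(n_ind),
        "phenotypic_variance": float(vp),
        "warnings": warn_msgs,
    }
    return PosteriorDraws(draws=draws, meta=meta)
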