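"""Multi-trait genomic-polygenic repeatability model.

The model for records on three traits (VOL, NS, MOT) is

    y = Xb + Za a + Zp p + e

with fixed effects b (contemporary group, ejaculate order, age, ambient
temperature, heterozygosity), breeding values a ~ N(0, Va (x) H) over every
pedigree animal, permanent-environment effects p ~ N(0, Vp (x) I) over the
animals with records, and residuals e ~ N(0, Ve per record, block-diagonal).
H is the single-step genomic-polygenic relationship matrix (A when no
genotypes are supplied).  Records may miss individual traits; the residual
covariance of a record is the corresponding submatrix of Ve.

Estimation is REML through Henderson's mixed-model equations:
expectation-maximisation (EM) steps, which increase the restricted
likelihood monotonically, optionally accelerated by average-information (AI)
steps that fall back to EM whenever they fail to improve the likelihood.
The likelihood reported is the restricted log-likelihood up to an additive
constant (the -n/2 log 2*pi term is omitted).

Usage follows the statsmodels convention::

    model = RepeatabilityModel(phen, pedigree=ped, relationships=rel)
    res = model.fit()          # RepeatabilityResults
    print(res.summary())
    sols = model.solve(res.vc) # BLUE/BLUP solutions at fixed components
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .io import DataError, PedigreeTable, PhenotypeTable
from .relationships import RelationshipSet, build_relationships

_VECH = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]


class ModelError(RuntimeError):
    """Numerical failure while fitting or solving the mixed model."""


# ---------------------------------------------------------------------------
# variance components

@dataclass
class VarianceComponents:
    """The 3x3 additive (Va), permanent-environment (Vp) and residual (Ve)
    covariance matrices of the repeatability model."""

    Va: np.ndarray
    Vp: np.ndarray
    Ve: np.ndarray
    traits: list[str] = field(default_factory=lambda: ["VOL", "NS", "MOT"])

    def __post_init__(self):
        for name in ("Va", "Vp", "Ve"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (len(self.traits),) * 2:
                raise DataError(f"{name} must be {len(self.traits)}x{len(self.traits)}")
            setattr(self, name, 0.5 * (m + m.T))

    @property
    def sigma_a2(self) -> np.ndarray:
        return np.diag(self.Va).copy()

    def phenotypic(self) -> np.ndarray:
        return self.Va + self.Vp + self.Ve

    def heritability(self) -> np.ndarray:
        return np.diag(self.Va) / np.diag(self.phenotypic())

    def repeatability(self) -> np.ndarray:
        return (np.diag(self.Va) + np.diag(self.Vp)) / np.diag(self.phenotypic())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in (("Va", self.Va), ("Vp", self.Vp), ("Ve", self.Ve)):
            for i, t in enumerate(self.traits):
                for j, u in enumerate(self.traits):
                    if j <= i:
                        rows.append((name, t, u, m[i, j]))
        return pd.DataFrame(rows, columns=["component", "trait_1", "trait_2", "value"])


def _ensure_pd(m: np.ndarray, floor_frac: float = 1e-6) -> np.ndarray:
    """Project to the PD cone by eigenvalue clipping (keeps solves valid)."""
    m = 0.5 * (m + m.T)
    w, v = np.linalg.eigh(m)
    floor = floor_frac * max(float(w.max()), 1e-12)
    if w.min() < floor:
        w = np.maximum(w, floor)
        m = (v * w) @ v.T
    return m


# ---------------------------------------------------------------------------
# design

@dataclass
class Design:
    """Record-level design: fixed-effect matrix F (shared across traits,
    trait-specific coefficients), per-record animal id, the n x T response
    with NaN for missing traits, and the observation mask."""

    F: np.ndarray
    columns: list[str]
    y: np.ndarray
    mask: np.ndarray
    animals: list[str]
    traits: list[str]


def build_design(phen: PhenotypeTable, drop_constant: bool = True) -> Design:
    """Fixed-effect design: intercept, dummy-coded contemporary group and
    ejaculate order (reference level dropped), and the age / temperature /
    heterozygosity covariates.  Constant covariate columns are dropped; a
    remaining rank deficiency is fatal and names the aliased columns."""
    df = phen.df
    if not len(df):
        raise DataError("phenotype table is empty")
    parts = [pd.Series(1.0, index=df.index, name="intercept")]
    for cat in ("contemporary_group", "ejaculate_order"):
        d = pd.get_dummies(df[cat].astype(str), prefix=cat, drop_first=True, dtype=float)
        if len(d.columns):
            parts.append(d)
    for cov in ("age_months", "ambient_temp_C", "heterozygosity"):
        parts.append(df[cov].astype(float))
    X = pd.concat(parts, axis=1)
    if drop_constant:
        keep = ["intercept"] + [c for c in X.columns[1:] if X[c].nunique() > 1]
        X = X[keep]
    F = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(F)
    if r < F.shape[1]:
        _, R, piv = sla.qr(F, mode="economic", pivoting=True)
        bad = [X.columns[p] for p in piv[r:]]
        raise DataError(f"fixed-effect design is rank deficient; aliased columns: {bad}")
    y = df[phen.traits].to_numpy(dtype=float)
    return Design(F, list(X.columns), y, ~np.isnan(y), list(df["animal"].astype(str)),
                  list(phen.traits))


# ---------------------------------------------------------------------------
# solutions

@dataclass
class SolutionSet:
    """Mixed-model equation solutions at fixed variance components."""

    fixed_effects: pd.DataFrame       # design column x trait
    gebv: pd.DataFrame                # every pedigree animal x trait
    permanent_env: pd.DataFrame       # phenotyped animal x trait
    residuals: np.ndarray             # record x trait, NaN where unobserved
    loglik: float


# ---------------------------------------------------------------------------
# internal MME engine

class _Engine:
    """Pattern-grouped assembly of the multi-trait mixed-model equations and
    the EM / AI-REML quantities derived from them."""

    def __init__(self, design: Design, hinv: np.ndarray, animal_order: list[str]):
        self.design = design
        self.T = len(design.traits)
        self.Hinv = np.asarray(hinv, dtype=float)
        self.q = self.Hinv.shape[0]
        sign, ld = np.linalg.slogdet(self.Hinv)
        if sign <= 0:
            raise ModelError("H inverse is not positive definite")
        self.logdet_H = -ld
        index = {a: i for i, a in enumerate(animal_order)}
        missing = sorted(set(design.animals) - set(index))
        if missing:
            raise DataError(f"phenotyped animals absent from pedigree: {missing[:5]}")
        self.anim = np.array([index[a] for a in design.animals], dtype=int)
        pe_animals = sorted(set(self.anim))
        self.pe_animals = [animal_order[i] for i in pe_animals]
        pe_map = {ai: k for k, ai in enumerate(pe_animals)}
        self.pe = np.array([pe_map[a] for a in self.anim], dtype=int)
        self.pe_anim = np.array(pe_animals, dtype=int)   # pedigree index per pe level
        self.m = len(pe_animals)
        self.f = design.F.shape[1]
        self.n = design.F.shape[0]
        self.n_obs = int(design.mask.sum())
        self.animal_order = list(animal_order)
        # block offsets: [b (T*f)] [a (T*q)] [p (T*m)]
        self.D = self.T * (self.f + self.q + self.m)
        self.b0 = 0
        self.a0 = self.T * self.f
        self.p0 = self.a0 + self.T * self.q
        self._group_patterns()

    def bsl(self, t):
        return slice(self.b0 + t * self.f, self.b0 + (t + 1) * self.f)

    def asl(self, t):
        return slice(self.a0 + t * self.q, self.a0 + (t + 1) * self.q)

    def psl(self, t):
        return slice(self.p0 + t * self.m, self.p0 + (t + 1) * self.m)

    def _group_patterns(self):
        mask = self.design.mask
        self.groups = []
        seen = {}
        keys = mask @ (1 << np.arange(self.T))
        for key in np.unique(keys):
            idx = np.nonzero(keys == key)[0]
            obs = tuple(np.nonzero(mask[idx[0]])[0])
            F = self.design.F[idx]
            anim, pe = self.anim[idx], self.pe[idx]
            y = self.design.y[np.ix_(idx, list(obs))]
            g = {
                "idx": idx, "obs": obs, "F": F, "anim": anim, "pe": pe, "y": y,
                "n": len(idx),
                "FtF": F.T @ F,
                "Fty": F.T @ y,                                  # f x |obs|
                "yty": y.T @ y,                                  # |obs| x |obs|
                "cnt_a": np.bincount(anim, minlength=self.q).astype(float),
                "cnt_p": np.bincount(pe, minlength=self.m).astype(float),
            }
            FtZa = np.zeros((self.q, F.shape[1]))
            np.add.at(FtZa, anim, F)
            g["ZatF"] = FtZa                                     # q x f
            FtZp = np.zeros((self.m, F.shape[1]))
            np.add.at(FtZp, pe, F)
            g["ZptF"] = FtZp                                     # m x f
            Zaty = np.zeros((self.q, len(obs)))
            np.add.at(Zaty, anim, y)
            g["Zaty"] = Zaty
            Zpty = np.zeros((self.m, len(obs)))
            np.add.at(Zpty, pe, y)
            g["Zpty"] = Zpty
            self.groups.append(g)

    # -- assembly -----------------------------------------------------------

    def assemble(self, vc: VarianceComponents):
        T, f, q, m, D = self.T, self.f, self.q, self.m, self.D
        VaI = np.linalg.inv(_ensure_pd(vc.Va))
        VpI = np.linalg.inv(_ensure_pd(vc.Vp))
        C = np.zeros((D, D))
        rhs = np.zeros(D)
        rinvs: list = []
        log_R = 0.0
        ytRy = 0.0
        for g in self.groups:
            obs = g["obs"]
            Voo = vc.Ve[np.ix_(obs, obs)]
            sign, ld = np.linalg.slogdet(Voo)
            if sign <= 0:
                raise ModelError("residual covariance not positive definite")
            Rinv = np.linalg.inv(Voo)
            rinvs.append(Rinv)
            log_R += g["n"] * ld
            ytRy += float(np.sum(Rinv * g["yty"]))
            for a_pos, t in enumerate(obs):
                for b_pos, u in enumerate(obs):
                    w = Rinv[a_pos, b_pos]
                    if w == 0.0:
                        continue
                    C[self.bsl(t), self.bsl(u)] += w * g["FtF"]
                    C[self.bsl(t), self.asl(u)] += w * g["ZatF"].T
                    C[self.asl(t), self.bsl(u)] += w * g["ZatF"]
                    C[self.bsl(t), self.psl(u)] += w * g["ZptF"].T
                    C[self.psl(t), self.bsl(u)] += w * g["ZptF"]
                    ar = np.arange(q)
                    C[self.a0 + t * q + ar, self.a0 + u * q + ar] += w * g["cnt_a"]
                    pr = np.arange(m)
                    C[self.p0 + t * m + pr, self.p0 + u * m + pr] += w * g["cnt_p"]
                    # Za'Zp: each pe level belongs to one animal
                    C[self.a0 + t * q + self.pe_anim, self.p0 + u * m + np.arange(m)] += w * g["cnt_p"]
                    C[self.p0 + t * m + np.arange(m), self.a0 + u * q + self.pe_anim] += w * g["cnt_p"]
                    rhs[self.bsl(t)] += w * g["Fty"][:, b_pos]
                    rhs[self.asl(t)] += w * g["Zaty"][:, b_pos]
                    rhs[self.psl(t)] += w * g["Zpty"][:, b_pos]
        C[self.a0:self.p0, self.a0:self.p0] += np.kron(VaI, self.Hinv)
        C[self.p0:, self.p0:] += np.kron(VpI, np.eye(m))
        return C, rhs, rinvs, log_R, ytRy

    def solve_system(self, vc: VarianceComponents, want_inverse: bool = False):
        C, rhs, rinvs, log_R, ytRy = self.assemble(vc)
        try:
            cf = sla.cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise ModelError("singular mixed-model coefficient matrix; check for "
                             "confounded fixed effects or degenerate components") from exc
        theta = sla.cho_solve(cf, rhs, check_finite=False)
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        sign_a, ld_a = np.linalg.slogdet(_ensure_pd(vc.Va))
        sign_p, ld_p = np.linalg.slogdet(_ensure_pd(vc.Vp))
        ll = -0.5 * (log_R + self.q * ld_a + self.T * self.logdet_H
                     + self.m * ld_p + logdet_C + ytRy - float(theta @ rhs))
        if not np.isfinite(ll):
            raise ModelError("non-finite restricted likelihood")
        out = {"C": C, "rhs": rhs, "theta": theta, "loglik": ll, "factor": cf,
               "rinvs": rinvs}
        if want_inverse:
            Cinv = sla.cho_solve(cf, np.eye(self.D), check_finite=False)
            out["Cinv"] = Cinv
        return out

    # -- derived record-level quantities ------------------------------------

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """Record x trait residuals (NaN where the trait is unobserved)."""
        T, f, q, m = self.T, self.f, self.q, self.m
        b = theta[: self.a0].reshape(T, f)
        a = theta[self.a0:self.p0].reshape(T, q)
        p = theta[self.p0:].reshape(T, m)
        fitted = self.design.F @ b.T + a[:, self.anim].T + p[:, self.pe].T
        res = self.design.y - fitted
        res[~self.design.mask] = np.nan
        return res

    def _block(self, Cinv, sl1, sl2):
        return Cinv[sl1, sl2]

    def em_update(self, vc: VarianceComponents, sol: dict) -> VarianceComponents:
        """Exact EM-REML update of (Va, Vp, Ve); monotone in the restricted
        likelihood, with missing traits handled by conditional imputation."""
        T, q, m = self.T, self.q, self.m
        Cinv, theta = sol["Cinv"], sol["theta"]
        a = theta[self.a0:self.p0].reshape(T, q)
        p = theta[self.p0:].reshape(T, m)
        Q = a @ self.Hinv @ a.T
        M1 = np.empty((T, T))
        M2 = np.empty((T, T))
        for t in range(T):
            for u in range(T):
                M1[t, u] = float(np.sum(self.Hinv * Cinv[self.asl(t), self.asl(u)]))
                M2[t, u] = float(np.trace(Cinv[self.psl(t), self.psl(u)]))
        Va_new = (Q + M1) / q
        Vp_new = (p @ p.T + M2) / m
        res = self.residuals(theta)
        Ve_new = np.zeros((T, T))
        for g, Rinv in zip(self.groups, sol["rinvs"]):
            obs = list(g["obs"])
            e = res[np.ix_(g["idx"], obs)]
            Gram = e.T @ e
            Asum = self._wcw_sum(Cinv, g)
            S = vc.Ve[:, obs] @ Rinv
            schur = vc.Ve - vc.Ve[:, obs] @ Rinv @ vc.Ve[obs, :]
            Ve_new += S @ (Gram + Asum) @ S.T + g["n"] * schur
        Ve_new /= self.n
        return VarianceComponents(_ensure_pd(Va_new), _ensure_pd(Vp_new),
                                  _ensure_pd(Ve_new), vc.traits)

    def _wcw_sum(self, Cinv, g):
        """sum_i W_i Cinv W_i' over the records of one pattern group
        (|obs| x |obs|), where W_i stacks the record's design rows."""
        obs = g["obs"]
        k = len(obs)
        F, anim, pe = g["F"], g["anim"], g["pe"]
        out = np.empty((k, k))
        acols = [self.a0 + t * self.q + anim for t in obs]
        pcols = [self.p0 + t * self.m + pe for t in obs]
        for i, t in enumerate(obs):
            bt = self.bsl(t)
            for j, u in enumerate(obs):
                if j < i:
                    out[i, j] = out[j, i]
                    continue
                bu = self.bsl(u)
                v = np.einsum("ij,jk,ik->", F, Cinv[bt, bu], F)
                v += np.einsum("ij,ji->", F, Cinv[bt, :][:, acols[j]])
                v += np.einsum("ij,ji->", F, Cinv[bt, :][:, pcols[j]])
                v += np.einsum("ij,ji->", F, Cinv[bu, :][:, acols[i]])
                v += np.einsum("ij,ji->", F, Cinv[bu, :][:, pcols[i]])
                v += float(np.sum(Cinv[acols[i], acols[j]]))
                v += float(np.sum(Cinv[acols[i], pcols[j]]))
                v += float(np.sum(Cinv[pcols[i], acols[j]]))
                v += float(np.sum(Cinv[pcols[i], pcols[j]]))
                out[i, j] = v
        return out

    # -- AI-REML ------------------------------------------------------------

    def scores_and_ai(self, vc: VarianceComponents, sol: dict):
        """First derivatives and the average-information matrix over the 18
        parameters (vech of Va, Vp, Ve, in that order)."""
        T, q, m, n = self.T, self.q, self.m, self.n
        Cinv, theta, cf = sol["Cinv"], sol["theta"], sol["factor"]
        a = theta[self.a0:self.p0].reshape(T, q)
        p = theta[self.p0:].reshape(T, m)
        VaI = np.linalg.inv(_ensure_pd(vc.Va))
        VpI = np.linalg.inv(_ensure_pd(vc.Vp))
        Q = a @ self.Hinv @ a.T
        Pq = p @ p.T
        M1 = np.empty((T, T))
        M2 = np.empty((T, T))
        for t in range(T):
            for u in range(T):
                M1[t, u] = float(np.sum(self.Hinv * Cinv[self.asl(t), self.asl(u)]))
                M2[t, u] = float(np.trace(Cinv[self.psl(t), self.psl(u)]))
        res = self.residuals(theta)
        rinvs = sol["rinvs"]
        eps = np.full_like(res, np.nan)      # Rinv-scaled residuals
        asums, grams = [], []
        for g, Rinv in zip(self.groups, rinvs):
            obs = list(g["obs"])
            eps[np.ix_(g["idx"], obs)] = res[np.ix_(g["idx"], obs)] @ Rinv.T
            asums.append(self._wcw_sum(Cinv, g))
            e = eps[np.ix_(g["idx"], obs)]
            grams.append(e.T @ e)

        def basis(t, u):
            E = np.zeros((T, T))
            E[t, u] = E[u, t] = 1.0
            return E

        params = []
        for name, V, VI in (("Va", vc.Va, VaI), ("Vp", vc.Vp, VpI), ("Ve", vc.Ve, None)):
            for t, u in _VECH:
                params.append((name, t, u))

        scores = np.zeros(len(params))
        fvecs = np.full((len(params), n, T), np.nan)
        for k, (name, t, u) in enumerate(params):
            E = basis(t, u)
            if name == "Va":
                B = VaI @ E @ VaI
                trace = q * float(np.trace(VaI @ E)) - float(np.sum(B * M1))
                quad = float(np.sum(B * Q))
                coef = E @ VaI
                fa = coef @ a                      # T x q
                fvecs[k][self.design.mask] = fa[:, self.anim].T[self.design.mask]
            elif name == "Vp":
                B = VpI @ E @ VpI
                trace = m * float(np.trace(VpI @ E)) - float(np.sum(B * M2))
                quad = float(np.sum(B * Pq))
                coef = E @ VpI
                fp = coef @ p
                fvecs[k][self.design.mask] = fp[:, self.pe].T[self.design.mask]
            else:
                trace = quad = 0.0
                for g, Rinv, Asum, Gram in zip(self.groups, rinvs, asums, grams):
                    obs = list(g["obs"])
                    Eoo = E[np.ix_(obs, obs)]
                    trace += g["n"] * float(np.trace(Rinv @ Eoo))
                    trace -= float(np.sum((Rinv @ Eoo @ Rinv) * Asum))
                    quad += float(np.sum(Eoo * Gram))
                    fvecs[k][np.ix_(g["idx"], obs)] = eps[np.ix_(g["idx"], obs)] @ Eoo.T
            scores[k] = -0.5 * (trace - quad)

        # AI_{kl} = 0.5 f_k' P f_l with P f = Rinv f - Rinv W Cinv W' Rinv f
        npar = len(params)
        gvecs = np.full_like(fvecs, np.nan)
        hmat = np.zeros((npar, self.D))
        for g, Rinv in zip(self.groups, rinvs):
            obs = list(g["obs"])
            fg = fvecs[:, g["idx"], :][:, :, obs]
            gg = fg @ Rinv.T
            for kk in range(npar):
                gvecs[np.ix_([kk], g["idx"], obs)] = gg[kk][None]
            for j, u in enumerate(obs):
                w = gg[:, :, j]                     # npar x n_g
                hmat[:, self.bsl(u)] += w @ g["F"]
                np.add.at(hmat.T, self.a0 + u * self.q + g["anim"], w.T)
                np.add.at(hmat.T, self.p0 + u * self.m + g["pe"], w.T)
        svecs = sla.cho_solve(cf, hmat.T, check_finite=False)
        fg_dot = np.zeros((npar, npar))
        ff = np.nan_to_num(fvecs).reshape(npar, -1)
        gg_ = np.nan_to_num(gvecs).reshape(npar, -1)
        fg_dot = ff @ gg_.T
        ai = 0.5 * (fg_dot - hmat @ svecs)
        ai = 0.5 * (ai + ai.T)
        return scores, ai, params


def _vc_to_theta(vc: VarianceComponents) -> np.ndarray:
    return np.concatenate([[m[t, u] for t, u in _VECH] for m in (vc.Va, vc.Vp, vc.Ve)])


def _theta_to_vc(theta: np.ndarray, traits) -> VarianceComponents:
    mats = []
    for b in range(3):
        m = np.zeros((3, 3))
        for k, (t, u) in enumerate(_VECH):
            m[t, u] = m[u, t] = theta[b * 6 + k]
        mats.append(_ensure_pd(m))
    return VarianceComponents(*mats, traits=list(traits))


# ---------------------------------------------------------------------------
# public model / results

class RepeatabilityModel:
    """3-trait repeatability animal model with a single-step H matrix.

    Parameters
    ----------
    phenotypes : PhenotypeTable
        Repeated records with the fixed-effect covariates.
    pedigree : PedigreeTable, optional
        Needed unless ``relationships`` is given.
    relationships : RelationshipSet, optional
        Prebuilt matrices; defaults to the pedigree-only A (classic BLUP).
    genotypes : GenotypeMatrix, optional
        Convenience: builds the single-step H internally from pedigree +
        genotypes when ``relationships`` is not supplied.
    """

    def __init__(self, phenotypes: PhenotypeTable, pedigree: PedigreeTable | None = None,
                 relationships: RelationshipSet | None = None, genotypes=None):
        if relationships is None:
            if pedigree is None:
                raise DataError("need a pedigree or a RelationshipSet")
            relationships = build_relationships(pedigree, genotypes)
        self.phenotypes = phenotypes
        self.relationships = relationships
        self.traits = list(phenotypes.traits)
        self.design = build_design(phenotypes)
        self.engine = _Engine(self.design, relationships.H_inverse,
                              relationships.animal_ids)

    @classmethod
    def from_tables(cls, phenotypes: PhenotypeTable, pedigree: PedigreeTable,
                    genotypes=None, blend_params=None) -> "RepeatabilityModel":
        rel = build_relationships(pedigree, genotypes, blend_params)
        return cls(phenotypes, relationships=rel)

    def start_values(self) -> VarianceComponents:
        """Neutral equal split: Va = Vp = Ve = diag(sample variance) / 3."""
        sv = np.nanvar(self.design.y, axis=0, ddof=1)
        sv = np.where(np.isfinite(sv) & (sv > 0), sv, 1.0)
        third = np.diag(sv / 3.0)
        return VarianceComponents(third.copy(), third.copy(), third.copy(), self.traits)

    def loglik(self, vc: VarianceComponents) -> float:
        return self.engine.solve_system(vc)["loglik"]

    def solve(self, vc: VarianceComponents) -> SolutionSet:
        """BLUE/BLUP solutions of the mixed-model equations at given
        variance components (no REML iteration)."""
        eng = self.engine
        sol = eng.solve_system(vc)
        theta = sol["theta"]
        T, f, q, m = eng.T, eng.f, eng.q, eng.m
        b = theta[: eng.a0].reshape(T, f)
        a = theta[eng.a0:eng.p0].reshape(T, q)
        p = theta[eng.p0:].reshape(T, m)
        fixed = pd.DataFrame(b.T, index=self.design.columns, columns=self.traits)
        gebv = pd.DataFrame(a.T, index=pd.Index(eng.animal_order, name="animal"),
                            columns=self.traits)
        pe = pd.DataFrame(p.T, index=pd.Index(eng.pe_animals, name="animal"),
                          columns=self.traits)
        return SolutionSet(fixed, gebv, pe, eng.residuals(theta), sol["loglik"])

    def fit(self, start: VarianceComponents | None = None, method: str = "ai",
            max_iter: int = 200, tol: float = 1e-8,
            verbose: bool = False) -> "RepeatabilityResults":
        """REML fit.

        ``method='em'`` runs pure EM (monotone, slow); ``method='ai'``
        attempts an average-information step each round and falls back to EM
        whenever the AI step does not increase the restricted likelihood.
        Convergence: maximum absolute relative parameter change < ``tol``.
        """
        if method not in ("em", "ai"):
            raise DataError(f"unknown REML method {method!r}")
        eng = self.engine
        vc = start or self.start_values()
        vc = VarianceComponents(_ensure_pd(vc.Va), _ensure_pd(vc.Vp),
                                _ensure_pd(vc.Ve), self.traits)
        ll_path: list[float] = []
        steps: list[str] = []
        converged = False
        stalled = False
        sol = eng.solve_system(vc, want_inverse=True)
        for it in range(max_iter):
            ll = sol["loglik"]
            ll_path.append(ll)
            theta_old = _vc_to_theta(vc)
            slack = 1e-9 * max(abs(ll), 1.0)
            cand = None
            used = "em"
            # AI acceleration after two stabilising EM warm-up rounds
            if method == "ai" and it >= 2:
                try:
                    scores, ai, params = eng.scores_and_ai(vc, sol)
                    delta = np.linalg.solve(ai + 1e-10 * np.eye(len(scores)), scores)
                    # trust region: never move a parameter by more than 10x
                    # the current component scale in one step
                    scale = max(float(np.abs(theta_old).max()), 1e-8)
                    if np.abs(delta).max() > 10.0 * scale:
                        delta *= 10.0 * scale / np.abs(delta).max()
                    for damp in (1.0, 0.5, 0.25, 0.1, 0.05, 0.02):
                        trial = _theta_to_vc(theta_old + damp * delta, self.traits)
                        try:
                            ll_trial = eng.solve_system(trial)["loglik"]
                        except ModelError:
                            continue
                        if ll_trial >= ll - slack:
                            cand = trial
                            sol_new = eng.solve_system(trial, want_inverse=True)
                            used = "ai"
                            break
                except (np.linalg.LinAlgError, ModelError):
                    cand = None
            if cand is None:
                # exact EM; guard against numerically inexact steps when the
                # coefficient matrix is ill-conditioned near the PSD boundary
                cand = eng.em_update(vc, sol)
                theta_em = _vc_to_theta(cand)
                sol_new = None
                for frac in (1.0, 0.5, 0.25):
                    trial = _theta_to_vc(theta_old + frac * (theta_em - theta_old),
                                         self.traits)
                    tsol = eng.solve_system(trial, want_inverse=True)
                    if tsol["loglik"] >= ll - slack:
                        cand, sol_new = trial, tsol
                        break
                if sol_new is None:
                    stalled = True
                    break
                used = "em"
            steps.append(used)
            theta_new = _vc_to_theta(cand)
            rel = np.max(np.abs(theta_new - theta_old) /
                         np.maximum(np.abs(theta_old), 1e-10))
            vc, sol = cand, sol_new
            if verbose:
                print(f"iter {it + 1:3d} [{used}] logL={sol['loglik']:.6f} "
                      f"max rel change={rel:.3e}")
            if rel < tol:
                converged = True
                break
        ll_path.append(sol["loglik"])
        if stalled:
            warnings.warn("REML stopped early: no likelihood-increasing step "
                          "found (estimate on or near the PSD boundary)",
                          stacklevel=2)
        if not converged:
            warnings.warn("REML did not converge within max_iter", stacklevel=2)
        solutions = self.solve(vc)
        return RepeatabilityResults(self, vc, solutions, np.array(ll_path),
                                    steps, converged, len(steps))


def reml_fit(phenotypes: PhenotypeTable, pedigree: PedigreeTable | None = None,
             relationships: RelationshipSet | None = None, **kwargs):
    """Functional wrapper: build the model and fit in one call."""
    return RepeatabilityModel(phenotypes, pedigree, relationships).fit(**kwargs)


def solve_mme(phenotypes: PhenotypeTable, vc: VarianceComponents,
              pedigree: PedigreeTable | None = None,
              relationships: RelationshipSet | None = None) -> SolutionSet:
    """Henderson's mixed-model equations at fixed variance components."""
    return RepeatabilityModel(phenotypes, pedigree, relationships).solve(vc)


class RepeatabilityResults:
    """REML estimates with their derived quantities.

    Attributes
    ----------
    vc : VarianceComponents
    solutions : SolutionSet
        BLUE/BLUP at the final components (GEBVs for every pedigree animal).
    loglik_path : ndarray
        Restricted log-likelihood at each accepted iterate (non-decreasing).
    """

    def __init__(self, model, vc, solutions, loglik_path, steps, converged, n_iter):
        self.model = model
        self.vc = vc
        self.solutions = solutions
        self.loglik_path = loglik_path
        self.steps = steps
        self.converged = converged
        self.n_iter = n_iter

    @property
    def gebv(self) -> pd.DataFrame:
        return self.solutions.gebv

    @property
    def loglik(self) -> float:
        return float(self.loglik_path[-1])

    def gebv_for(self, animal_ids) -> np.ndarray:
        return self.solutions.gebv.loc[list(animal_ids)].to_numpy()

    def summary(self) -> str:
        vc = self.vc
        lines = ["Genomic-polygenic repeatability model (REML)",
                 "=" * 52,
                 f"records: {self.model.engine.n}   traits: {', '.join(vc.traits)}",
                 f"animals in pedigree: {self.model.engine.q}   "
                 f"with records: {self.model.engine.m}",
                 f"converged: {self.converged}   iterations: {self.n_iter} "
                 f"(ai: {self.steps.count('ai')}, em: {self.steps.count('em')})",
                 f"restricted logL: {self.loglik:.4f}", ""]
        for name, m in (("Va (additive)", vc.Va), ("Vp (permanent env.)", vc.Vp),
                        ("Ve (residual)", vc.Ve)):
            lines.append(name)
            for i, t in enumerate(vc.traits):
                lines.append("  " + t.ljust(6) +
                             " ".join(f"{m[i, j]:10.5f}" for j in range(len(vc.traits))))
        lines.append("")
        h2 = vc.heritability()
        rep = vc.repeatability()
        lines.append("trait   h^2      repeatability")
        for i, t in enumerate(vc.traits):
            lines.append(f"{t.ljust(7)}{h2[i]:.4f}   {rep[i]:.4f}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<RepeatabilityResults converged={self.converged} "
                f"iterations={self.n_iter} logL={self.loglik:.3f}>")
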