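"""Restricted maximum likelihood (REML) for pedigree mixed models.

The animal model is ``y = Xb + Z_a a + Z_c c + e`` with additive genetic
effects ``a ~ N(0, A sigma2_A)`` (``A`` the numerator relationship matrix),
litter / common-environment effects ``c ~ N(0, I sigma2_CE)`` and residuals
``e ~ N(0, I sigma2_R)``.  The engine below is generic: any number of
random terms, each with an optional covariance kernel over its levels, and
one or two traits with unstructured 2x2 component matrices.  Records
missing one trait contribute to the likelihood through the observed entries
only (no complete-case deletion).

Estimation uses average-information (AI) REML: Newton-type updates with the
AI matrix in place of the expected Hessian, safeguarded by step-halving so
the restricted log-likelihood never decreases, and with parameters
projected back into the admissible region (variances above a small floor,
correlations inside (-1, 1)).  Standard errors of variance components come
from the inverse AI matrix at the optimum; standard errors of heritability
and correlations use the first-order delta method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from nutrieff.pedigree import Pedigree, RelationshipMatrix

logger = logging.getLogger(__name__)

VAR_FLOOR_FRACTION = 1e-6  # component floor relative to phenotypic variance
CORR_CLAMP = 0.999


class DesignError(ValueError):
    """Problem constructing model matrices."""


# ---------------------------------------------------------------------------
# model specification and design construction


@dataclass
class ModelFormula:
    """Response(s), fixed terms and random terms of a pedigree mixed model.

    Fixed terms are column names; an interaction is written ``"a:b"`` and
    requires both main effects to be listed.  Random terms are
    ``(column, structure)`` pairs with structure ``"pedigree"`` (covariance
    proportional to A) or ``"identity"``.
    """

    responses: list[str]
    fixed_terms: list[str] = field(default_factory=list)
    random_terms: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.responses) <= 2:
            raise ValueError("one or two responses supported")
        mains = {t for t in self.fixed_terms if ":" not in t}
        for t in self.fixed_terms:
            if ":" in t:
                for part in t.split(":"):
                    if part not in mains:
                        raise ValueError(
                            f"interaction {t!r} requires main effect {part!r}"
                        )
        for _, tag in self.random_terms:
            if tag not in ("pedigree", "identity"):
                raise ValueError(f"unknown covariance structure {tag!r}")


def _encode_term(data: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    """Columns (n, k) and names for one fixed term (main effect or interaction)."""
    parts = term.split(":")
    blocks: list[tuple[np.ndarray, list[str]]] = []
    for p in parts:
        col = data[p]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col.astype(str)))
            # reference-level coding: drop the first level
            mat = np.column_stack(
                [(col.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
            ) if len(levels) > 1 else np.zeros((len(col), 0))
            blocks.append((mat, [f"{p}[{lv}]" for lv in levels[1:]]))
        else:
            blocks.append((col.to_numpy(float)[:, None], [p]))
    mat, names = blocks[0]
    for bmat, bnames in blocks[1:]:
        mat = np.einsum("ni,nj->nij", mat, bmat).reshape(len(data), -1)
        names = [f"{a}:{b}" for a in names for b in bnames]
    return mat, names


def fixed_design(data: pd.DataFrame, terms: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    """Full-rank fixed-effect design with intercept; aliased columns dropped."""
    cols = [np.ones((len(data), 1))]
    names = ["(Intercept)"]
    for t in terms:
        m, nm = _encode_term(data, t)
        cols.append(m)
        names.extend(nm)
    X = np.hstack(cols)
    # sequential Gram-Schmidt rank screen: earlier terms take precedence,
    # later aliased columns are dropped
    n = X.shape[0]
    Q = np.zeros((n, 0))
    keep: list[int] = []
    for j in range(X.shape[1]):
        v = X[:, j]
        r = v - Q @ (Q.T @ v)
        r = r - Q @ (Q.T @ r)  # re-orthogonalise for stability
        if np.linalg.norm(r) > max(np.linalg.norm(v), 1.0) * 1e-8:
            keep.append(j)
            Q = np.column_stack([Q, r / np.linalg.norm(r)])
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropping aliased fixed-effect columns: %s", dropped)
    return X[:, keep], [names[j] for j in keep]


@dataclass
class Designs:
    """Model matrices for one or two traits sharing a record table."""

    y: np.ndarray                    # (n_records, n_traits), NaN = missing
    X: np.ndarray                    # (n_records, p) shared fixed design
    xnames: list[str]
    animal_index: np.ndarray | None  # record -> row of A
    litter_index: np.ndarray | None  # record -> litter level
    litter_levels: list | None
    trait_names: list[str]


def build_design(
    data: pd.DataFrame, formula: ModelFormula, ped: Pedigree | None = None
) -> Designs:
    """Assemble response, fixed design and random-term index maps.

    Every record's ``animal_id`` must be present in the pedigree when a
    pedigree-structured random term is requested.
    """
    for col in formula.responses:
        if col not in data.columns:
            raise DesignError(f"response column {col!r} not in data")
    X, xnames = fixed_design(data, formula.fixed_terms)
    animal_index = None
    litter_index = None
    litter_levels = None
    for col, tag in formula.random_terms:
        if tag == "pedigree":
            if ped is None:
                raise DesignError("pedigree-structured term requires a pedigree")
            missing = [a for a in data[col] if a not in ped]
            if missing:
                raise DesignError(
                    f"animal {missing[0]!r} has records but is absent from the pedigree"
                )
            animal_index = np.array([ped.index(a) for a in data[col]])
        else:
            litter_levels = sorted(pd.unique(data[col].astype(str)))
            lut = {lv: i for i, lv in enumerate(litter_levels)}
            litter_index = np.array([lut[str(v)] for v in data[col]])
    y = data[formula.responses].to_numpy(float)
    return Designs(y, X, xnames, animal_index, litter_index, litter_levels,
                   list(formula.responses))


# ---------------------------------------------------------------------------
# core REML engine


@dataclass
class RandomTerm:
    """One random term: level index per record plus optional level kernel."""

    name: str
    levels: np.ndarray                 # (n_records,) int level codes
    kernel: np.ndarray | None = None   # (n_levels, n_levels); None = identity
    traits: tuple[int, ...] | None = None  # trait indices the term applies to


@dataclass
class REMLFit:
    """Result of a restricted-maximum-likelihood fit."""

    trait_names: list[str]
    components: dict[str, np.ndarray]    # term -> (m x m) component matrix
    component_traits: dict[str, tuple[int, ...]]
    param_names: list[str]
    theta: np.ndarray
    beta: np.ndarray
    beta_names: list[str]
    beta_cov: np.ndarray                 # (X' V^-1 X)^-1
    loglik: float
    converged: bool
    iterations: int
    ai_matrix: np.ndarray
    n_obs: int
    residual_df: int
    at_boundary: list[str]

    @property
    def cov_params(self) -> np.ndarray:
        """Asymptotic covariance of the variance parameters (inverse AI)."""
        try:
            return np.linalg.inv(self.ai_matrix)
        except np.linalg.LinAlgError:
            return np.full_like(self.ai_matrix, np.nan)

    def component(self, name: str, i: int = 0, j: int = 0) -> float:
        return float(self.components[name][i, j])


def _incidence_to_index(Z: np.ndarray) -> np.ndarray:
    Z = np.asarray(Z)
    if Z.ndim == 1:
        return Z.astype(int)
    if not np.all((Z.sum(axis=1) == 1) & (Z.max(axis=1) == 1)):
        raise DesignError("incidence matrix must have exactly one 1 per row")
    return np.argmax(Z, axis=1)


class _Workspace:
    """Precomputed observation-level structures for one REML problem."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray | Sequence[np.ndarray],
        terms: list[RandomTerm],
        trait_names: list[str],
    ):
        y = np.asarray(y, float)
        if y.ndim == 1:
            y = y[:, None]
        n_rec, n_traits = y.shape
        if n_traits > 2:
            raise ValueError("at most two traits supported")
        if isinstance(X, (list, tuple)):
            X_list = [np.asarray(x, float) for x in X]
        else:
            X_list = [np.asarray(X, float)] * n_traits
        obs_rec, obs_trait = [], []
        for t in range(n_traits):
            ok = np.flatnonzero(~np.isnan(y[:, t]))
            obs_rec.append(ok)
            obs_trait.append(np.full(ok.size, t))
        self.rec = np.concatenate(obs_rec)
        self.trait = np.concatenate(obs_trait)
        self.yv = np.concatenate([y[obs_rec[t], t] for t in range(n_traits)])
        self.n_obs = self.yv.size
        self.n_traits = n_traits
        self.trait_names = trait_names
        blocks = []
        for t in range(n_traits):
            Xt = X_list[t][obs_rec[t]]
            blocks.append(Xt)
        self.X = linalg.block_diag(*blocks) if n_traits > 1 else blocks[0]
        self.rank_x = np.linalg.matrix_rank(self.X)
        # residual term appended last, identity by record
        self.terms = list(terms) + [RandomTerm("residual", np.arange(n_rec))]
        self.masks = [self.trait == t for t in range(n_traits)]
        # observation-level kernels
        self.K = []
        for term in self.terms:
            lv = term.levels[self.rec]
            if term.kernel is None:
                Kt = (lv[:, None] == lv[None, :]).astype(float)
            else:
                Kt = np.asarray(term.kernel, float)[np.ix_(lv, lv)]
            self.K.append(Kt)
        # parameter bookkeeping
        self.par_index: list[tuple[int, int, int]] = []  # (term, trait_i, trait_j)
        self.param_names: list[str] = []
        self.term_traits: list[tuple[int, ...]] = []
        for k, term in enumerate(self.terms):
            tr = term.traits if term.traits is not None else tuple(range(n_traits))
            self.term_traits.append(tuple(tr))
            for i, j in combinations_with_replacement(tr, 2):
                self.par_index.append((k, i, j))
                if n_traits == 1:
                    self.param_names.append(f"V_{term.name}")
                else:
                    lab = (f"V_{term.name}({trait_names[i]})" if i == j
                           else f"C_{term.name}({trait_names[i]},{trait_names[j]})")
                    self.param_names.append(lab)
        self.n_par = len(self.par_index)
        # per-trait phenotypic variance for floors and starting values
        self.vp = np.empty(n_traits)
        for t in range(n_traits):
            yt = self.yv[self.masks[t]]
            Xt = self.X[self.masks[t]]
            resid = yt - Xt @ np.linalg.lstsq(Xt, yt, rcond=None)[0]
            dfree = max(yt.size - np.linalg.matrix_rank(Xt), 1)
            self.vp[t] = max(resid @ resid / dfree, np.finfo(float).tiny)

    # -- parameter vector <-> component matrices -------------------------------
    def start_values(self) -> np.ndarray:
        """Generic split of phenotypic variance over the random terms.

        First non-residual term gets 1/3 of V_P, further non-residual terms
        1/10 each, residual the remainder; covariances start at half the
        geometric mean of the corresponding variances, signed by the sample
        covariance of the traits.
        """
        frac = []
        for k in range(len(self.terms) - 1):
            frac.append(1 / 3 if k == 0 else 1 / 10)
        frac.append(max(1.0 - sum(frac), 0.3))
        sign = np.ones((self.n_traits, self.n_traits))
        if self.n_traits == 2:
            r0 = self.rec[self.masks[0]]
            r1 = self.rec[self.masks[1]]
            common, i0, i1 = np.intersect1d(r0, r1, return_indices=True)
            if common.size > 3:
                c = np.cov(self.yv[self.masks[0]][i0], self.yv[self.masks[1]][i1])[0, 1]
                sign[0, 1] = sign[1, 0] = 1.0 if c >= 0 else -1.0
        theta = np.empty(self.n_par)
        for p, (k, i, j) in enumerate(self.par_index):
            if i == j:
                theta[p] = frac[k] * self.vp[i]
            else:
                theta[p] = sign[i, j] * 0.5 * frac[k] * np.sqrt(self.vp[i] * self.vp[j])
        return theta

    def comp_matrices(self, theta: np.ndarray) -> list[np.ndarray]:
        mats = [np.zeros((self.n_traits, self.n_traits)) for _ in self.terms]
        for p, (k, i, j) in enumerate(self.par_index):
            mats[k][i, j] = mats[k][j, i] = theta[p]
        return mats

    def project(self, theta: np.ndarray) -> np.ndarray:
        """Clamp variances to their floors and correlations inside (-1, 1).

        A variance pinned at its floor is degenerate: the corresponding
        covariances are set to zero rather than clamped to a vanishing
        correlation bound, which keeps the information matrix workable.
        """
        th = theta.copy()
        floored: set[tuple[int, int]] = set()
        for p, (k, i, j) in enumerate(self.par_index):
            if i == j:
                floor = VAR_FLOOR_FRACTION * self.vp[i]
                if th[p] <= floor:
                    th[p] = floor
                    floored.add((k, i))
        for p, (k, i, j) in enumerate(self.par_index):
            if i != j:
                if (k, i) in floored or (k, j) in floored:
                    th[p] = 0.0
                    continue
                vi = th[self._diag_pos(k, i)]
                vj = th[self._diag_pos(k, j)]
                lim = CORR_CLAMP * np.sqrt(vi * vj)
                th[p] = np.clip(th[p], -lim, lim)
        return th

    def _diag_pos(self, k: int, i: int) -> int:
        return self.par_index.index((k, i, i))

    def pinned(self, theta: np.ndarray, score: np.ndarray) -> np.ndarray:
        """Coordinates held at a bound by the gradient (excluded from updates)."""
        out = np.zeros(self.n_par, dtype=bool)
        floored: set[tuple[int, int]] = set()
        for p, (k, i, j) in enumerate(self.par_index):
            if i == j and theta[p] <= VAR_FLOOR_FRACTION * self.vp[i] * (1 + 1e-6):
                floored.add((k, i))
                if score[p] < 0:
                    out[p] = True
        for p, (k, i, j) in enumerate(self.par_index):
            if i != j:
                if (k, i) in floored or (k, j) in floored:
                    out[p] = True
                    continue
                vi = theta[self._diag_pos(k, i)]
                vj = theta[self._diag_pos(k, j)]
                lim = CORR_CLAMP * np.sqrt(vi * vj)
                if abs(theta[p]) >= lim * (1 - 1e-9) and score[p] * np.sign(theta[p]) > 0:
                    out[p] = True
        return out

    def boundary_params(self, theta: np.ndarray) -> list[str]:
        out = []
        for p, (k, i, j) in enumerate(self.par_index):
            if i == j:
                if theta[p] <= VAR_FLOOR_FRACTION * self.vp[i] * (1 + 1e-6):
                    out.append(self.param_names[p])
            else:
                vi = theta[self._diag_pos(k, i)]
                vj = theta[self._diag_pos(k, j)]
                if abs(theta[p]) >= CORR_CLAMP * np.sqrt(vi * vj) * (1 - 1e-9):
                    out.append(self.param_names[p])
        return out

    # -- likelihood machinery ---------------------------------------------------
    def build_V(self, theta: np.ndarray) -> np.ndarray:
        mats = self.comp_matrices(theta)
        V = np.zeros((self.n_obs, self.n_obs))
        for k, term in enumerate(self.terms):
            C = mats[k]
            if self.n_traits == 1:
                V += C[0, 0] * self.K[k]
            else:
                Cobs = C[self.trait[:, None], self.trait[None, :]]
                V += Cobs * self.K[k]
        return V

    def chol_loglik(self, theta: np.ndarray):
        """Restricted log-likelihood plus the Cholesky factor of V(theta)."""
        V = self.build_V(theta)
        L, info = linalg.lapack.dpotrf(V, lower=1, overwrite_a=False)
        if info != 0:
            return -np.inf, None
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        ViX = linalg.cho_solve((L, True), self.X)
        Viy = linalg.cho_solve((L, True), self.yv)
        XtVX = self.X.T @ ViX
        try:
            Lx = linalg.cholesky(XtVX, lower=True)
        except linalg.LinAlgError:
            return -np.inf, None
        logdet_x = 2.0 * np.sum(np.log(np.diag(Lx)))
        beta = linalg.cho_solve((Lx, True), self.X.T @ Viy)
        Py = Viy - ViX @ beta
        ll = float(-0.5 * (logdet_v + logdet_x + self.yv @ Py))
        return ll, L

    def loglik(self, theta: np.ndarray) -> float:
        return self.chol_loglik(theta)[0]

    def full_eval(self, theta: np.ndarray, L: np.ndarray | None = None):
        """Log-likelihood plus P, Py, beta, beta covariance at theta."""
        if L is None:
            _, L = self.chol_loglik(theta)
            if L is None:
                raise linalg.LinAlgError("V(theta) not positive definite")
        logdet_v = 2.0 * np.sum(np.log(np.diag(L)))
        # inverse from the existing factor (dpotri fills one triangle)
        Vi, info = linalg.lapack.dpotri(L, lower=1)
        if info != 0:  # pragma: no cover - factor was already validated
            raise linalg.LinAlgError("dpotri failed")
        Vi = np.tril(Vi) + np.tril(Vi, -1).T
        ViX = Vi @ self.X
        XtVX = self.X.T @ ViX
        Lx = linalg.cholesky(XtVX, lower=True)
        logdet_x = 2.0 * np.sum(np.log(np.diag(Lx)))
        XtVX_inv = linalg.cho_solve((Lx, True), np.eye(self.X.shape[1]))
        beta = XtVX_inv @ (ViX.T @ self.yv)
        P = Vi - ViX @ XtVX_inv @ ViX.T
        Py = P @ self.yv
        ll = float(-0.5 * (logdet_v + logdet_x + self.yv @ Py))
        return ll, P, Py, beta, XtVX_inv

    def score_ai(self, P: np.ndarray, Py: np.ndarray):
        """Gradient and average-information matrix at the current point."""
        F = np.empty((self.n_obs, self.n_par))
        score = np.empty(self.n_par)
        for p, (k, i, j) in enumerate(self.par_index):
            Kt = self.K[k]
            if self.n_traits == 1:
                f = Kt @ Py
                tr = float(np.sum(P * Kt))
            else:
                mi, mj = self.masks[i], self.masks[j]
                gj = Kt @ (Py * mj)
                if i == j:
                    f = mi * gj
                    tr = float(np.sum((P * Kt)[np.ix_(mi, mj)]))
                else:
                    gi = Kt @ (Py * mi)
                    f = mi * gj + mj * gi
                    tr = 2.0 * float(np.sum((P * Kt)[np.ix_(mi, mj)]))
            F[:, p] = f
            score[p] = 0.5 * (Py @ f - tr)
        AI = 0.5 * (F.T @ (P @ F))
        AI = 0.5 * (AI + AI.T)
        return score, AI


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray | Sequence[np.ndarray],
    random_terms: list[RandomTerm],
    *,
    trait_names: Sequence[str] | None = None,
    beta_names: Sequence[str] | None = None,
    start: np.ndarray | None = None,
    fix: dict[str, float] | None = None,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
) -> REMLFit:
    """Fit a Gaussian mixed model by AI-REML with monotone safeguards.

    ``y`` is ``(n_records,)`` or ``(n_records, n_traits)`` with NaN marking
    missing observations; ``X`` is a shared fixed design or one per trait.
    ``fix`` pins named parameters at given values (they are excluded from
    the update and treated as known, i.e. infinite information).
    """
    y = np.asarray(y, float)
    n_traits = 1 if y.ndim == 1 else y.shape[1]
    if trait_names is None:
        trait_names = [f"trait{t+1}" for t in range(n_traits)]
    ws = _Workspace(y, X, random_terms, list(trait_names))
    theta = ws.project(np.asarray(start, float) if start is not None else ws.start_values())
    fixed_idx: list[int] = []
    if fix:
        unknown = set(fix) - set(ws.param_names)
        if unknown:
            raise ValueError(f"cannot fix unknown parameters {sorted(unknown)}")
        for name, val in fix.items():
            p = ws.param_names.index(name)
            theta[p] = val
            fixed_idx.append(p)

    def constrain(score: np.ndarray, AI: np.ndarray):
        for p in fixed_idx:
            score[p] = 0.0
            AI[p, :] = AI[:, p] = 0.0
            AI[p, p] = 1e30  # treated as known: no sampling variance
        return score, AI

    def reproject(th: np.ndarray) -> np.ndarray:
        th = ws.project(th)
        for p in fixed_idx:
            th[p] = fix[ws.param_names[p]]
        return th

    theta = reproject(theta) if fixed_idx else theta

    ll, P, Py, beta, beta_cov = ws.full_eval(theta)
    converged = False
    it = 0
    stall = 0
    score = np.zeros(ws.n_par)
    AI = np.eye(ws.n_par)
    for it in range(1, max_iter + 1):
        score, AI = ws.score_ai(P, Py)
        score, AI = constrain(score, AI)
        # Newton step on the AI matrix restricted to coordinates not pinned
        # at a bound, ridged until finite and bounded
        pinned = ws.pinned(theta, score)
        free = np.flatnonzero(~pinned)
        AI_f = AI[np.ix_(free, free)]
        score_f = score[free]
        ridge = 0.0
        scale = np.linalg.norm(theta) + 1e-12
        step_f = score_f
        for _ in range(30):
            try:
                step_f = np.linalg.solve(AI_f + ridge * np.eye(free.size), score_f)
            except np.linalg.LinAlgError:
                step_f = None
            if step_f is not None and np.all(np.isfinite(step_f)) and (
                np.linalg.norm(step_f) <= 1e3 * scale
            ):
                break
            ridge = max(ridge * 10, 1e-10 * np.trace(AI_f) / max(free.size, 1))
        else:  # pragma: no cover - pathological
            step_f = score_f * scale / (np.linalg.norm(score_f) + 1e-300)
        step = np.zeros(ws.n_par)
        step[free] = step_f
        accepted = False
        full_step = False
        diag_step = np.where(pinned, 0.0, score / np.maximum(np.diag(AI), 1e-300))
        for trial_step in (step, diag_step):
            frac = 1.0
            for _ in range(12):
                cand = reproject(theta + frac * trial_step)
                ll_new, L_new = ws.chol_loglik(cand)
                if not np.array_equal(cand, theta) and ll_new >= ll:
                    accepted = True
                    full_step = frac == 1.0 and trial_step is step
                    break
                frac *= 0.5
            if accepted:
                break
        if not accepted:
            logger.debug("no improving step found at iteration %d; stopping", it)
            converged = True
            break
        rel_change = np.max(
            np.abs(cand - theta) / np.maximum(np.abs(theta), 1e-12)
        )
        d_ll = ll_new - ll
        theta = cand
        ll, P, Py, beta, beta_cov = ws.full_eval(theta, L_new)
        stall = stall + 1 if abs(d_ll) < tol_loglik else 0
        if abs(d_ll) < tol_loglik and rel_change < tol_param and full_step:
            converged = True
            break
        if stall >= 3 or (not full_step and abs(d_ll) < 1e-10):
            # repeated (or negligible) sub-tolerance gains off the full AI
            # step: the boundary crawl has flattened out
            converged = True
            break
    score, AI = ws.score_ai(P, Py)
    score, AI = constrain(score, AI)

    mats = ws.comp_matrices(theta)
    components = {t.name: mats[k] for k, t in enumerate(ws.terms)}
    comp_traits = {t.name: ws.term_traits[k] for k, t in enumerate(ws.terms)}
    if beta_names is None:
        beta_names = [f"b{j}" for j in range(ws.X.shape[1])]
    else:
        beta_names = list(beta_names)
        if n_traits == 2 and len(beta_names) * 2 == ws.X.shape[1]:
            beta_names = [
                f"{trait_names[t]}:{b}" for t in range(2) for b in beta_names
            ]
    return REMLFit(
        trait_names=list(trait_names),
        components=components,
        component_traits=comp_traits,
        param_names=ws.param_names,
        theta=theta,
        beta=beta,
        beta_names=beta_names,
        beta_cov=beta_cov,
        loglik=ll,
        converged=converged,
        iterations=it,
        ai_matrix=AI,
        n_obs=ws.n_obs,
        residual_df=ws.n_obs - ws.rank_x,
        at_boundary=ws.boundary_params(theta),
    )


# ---------------------------------------------------------------------------
# spec-level wrappers


def _terms_from_designs(
    Z_a=None, A: RelationshipMatrix | np.ndarray | None = None, Z_c=None,
) -> list[RandomTerm]:
    terms = []
    if Z_a is not None:
        if A is None:
            raise ValueError("Z_a given without a relationship matrix")
        Avals = A.values if isinstance(A, RelationshipMatrix) else np.asarray(A, float)
        terms.append(RandomTerm("animal", _incidence_to_index(Z_a), Avals))
    if Z_c is not None:
        terms.append(RandomTerm("litter", _incidence_to_index(Z_c)))
    return terms


def reml_univariate(y, X, Z_a=None, A=None, Z_c=None, **kwargs) -> REMLFit:
    """Univariate animal model ``y = Xb + Z_a a + Z_c c + e``.

    ``Z_a`` / ``Z_c`` may be 0/1 incidence matrices or integer level codes;
    ``A`` is the numerator relationship matrix over the pedigree positions
    referenced by ``Z_a``.
    """
    return fit_mixed_model(np.asarray(y, float), X,
                           _terms_from_designs(Z_a, A, Z_c), **kwargs)


def reml_bivariate(y1, y2, X, Z_a=None, A=None, Z_c=None,
                   trait_names=("trait1", "trait2"), **kwargs) -> REMLFit:
    """Bivariate animal model with unstructured 2x2 component matrices.

    Records missing one trait (NaN) are retained for the other trait.
    """
    y = np.column_stack([np.asarray(y1, float), np.asarray(y2, float)])
    return fit_mixed_model(y, X, _terms_from_designs(Z_a, A, Z_c),
                           trait_names=list(trait_names), **kwargs)


# ---------------------------------------------------------------------------
# derived genetic parameters and standard errors


@dataclass
class GeneticParameters:
    """Heritabilities, litter-effect ratios and (bivariate) correlations."""

    h2: dict[str, float]
    h2_se: dict[str, float]
    ce2: dict[str, float]
    ce2_se: dict[str, float]
    rg: float | None = None
    rg_se: float | None = None
    rp: float | None = None
    rp_se: float | None = None

    def summary(self) -> pd.DataFrame:
        rows = []
        for t in self.h2:
            rows.append({"trait": t, "h2": self.h2[t], "h2_se": self.h2_se[t],
                         "ce2": self.ce2.get(t, np.nan),
                         "ce2_se": self.ce2_se.get(t, np.nan)})
        return pd.DataFrame(rows)


def _param_transforms(fit: REMLFit, genetic: str, litter: str | None):
    """Scalar functions of theta for each derived parameter."""

    names = fit.param_names

    def pos(label: str) -> int | None:
        return names.index(label) if label in names else None

    n_traits = len(fit.trait_names)
    funcs: dict[str, callable] = {}
    if n_traits == 1:
        idx_a = pos(f"V_{genetic}")
        funcs["h2:" + fit.trait_names[0]] = lambda th: th[idx_a] / th.sum()
        if litter is not None and pos(f"V_{litter}") is not None:
            idx_c = pos(f"V_{litter}")
            funcs["ce2:" + fit.trait_names[0]] = lambda th: th[idx_c] / th.sum()
    else:
        t1, t2 = fit.trait_names
        # per-trait phenotypic variance = sum of V_term(trait) over terms
        var_idx = {t: [p for p, lab in enumerate(names)
                       if lab.startswith("V_") and lab.endswith(f"({t})")]
                   for t in (t1, t2)}
        cov_idx = [p for p, lab in enumerate(names) if lab.startswith("C_")]
        ia1 = pos(f"V_{genetic}({t1})")
        ia2 = pos(f"V_{genetic}({t2})")
        ica = pos(f"C_{genetic}({t1},{t2})")
        for t in (t1, t2):
            ia = pos(f"V_{genetic}({t})")
            funcs[f"h2:{t}"] = (lambda th, ia=ia, vi=var_idx[t]:
                                th[ia] / th[vi].sum())
            if litter is not None and pos(f"V_{litter}({t})") is not None:
                ic = pos(f"V_{litter}({t})")
                funcs[f"ce2:{t}"] = (lambda th, ic=ic, vi=var_idx[t]:
                                     th[ic] / th[vi].sum())
        if ica is not None:
            funcs["rg"] = lambda th: th[ica] / np.sqrt(th[ia1] * th[ia2])
        funcs["rp"] = (lambda th:
                       th[cov_idx].sum()
                       / np.sqrt(th[var_idx[t1]].sum() * th[var_idx[t2]].sum()))
    return funcs


def _delta_se(func, theta: np.ndarray, cov: np.ndarray) -> float:
    """First-order delta-method SE with a central-difference gradient."""
    g = np.empty_like(theta)
    for p in range(theta.size):
        h = max(abs(theta[p]), 1e-8) * 1e-5
        up, dn = theta.copy(), theta.copy()
        up[p] += h
        dn[p] -= h
        g[p] = (func(up) - func(dn)) / (2 * h)
    var = float(g @ cov @ g)
    return float(np.sqrt(var)) if var >= 0 else np.nan


def genetic_parameters(
    fit: REMLFit, genetic: str = "animal", litter: str | None = "litter"
) -> GeneticParameters:
    """Heritability, litter-effect ratio and correlations with delta-method SEs.

    h2 = V_A / V_P with V_P the sum of all variance components of the
    trait; CE2 = V_CE / V_P; r_g rescales the additive covariance by the
    additive variances; r_p rescales the total covariance by the
    phenotypic variances.
    """
    if f"V_{genetic}" not in fit.param_names and not any(
        lab.startswith(f"V_{genetic}(") for lab in fit.param_names
    ):
        raise ValueError(f"fit has no random term named {genetic!r}")
    if litter is not None and litter not in fit.components:
        litter = None
    theta = fit.theta
    cov = fit.cov_params
    funcs = _param_transforms(fit, genetic, litter)
    h2, h2_se, ce2, ce2_se = {}, {}, {}, {}
    rg = rg_se = rp = rp_se = None
    for label, f in funcs.items():
        val = float(f(theta))
        se = _delta_se(f, theta, cov)
        if label.startswith("h2:"):
            h2[label[3:]] = val
            h2_se[label[3:]] = se
        elif label.startswith("ce2:"):
            ce2[label[4:]] = val
            ce2_se[label[4:]] = se
        elif label == "rg":
            rg, rg_se = val, se
        elif label == "rp":
            rp, rp_se = val, se
    return GeneticParameters(h2, h2_se, ce2, ce2_se, rg, rg_se, rp, rp_se)


def standard_errors(fit: REMLFit) -> pd.Series:
    """Component standard errors from the inverse average-information matrix."""
    cov = fit.cov_params
    diag = np.diag(cov)
    if np.any(~np.isfinite(diag)) or np.any(diag < 0):
        logger.warning("information matrix singular or indefinite; SEs undefined")
        return pd.Series(np.nan, index=fit.param_names)
    return pd.Series(np.sqrt(diag), index=fit.param_names)
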