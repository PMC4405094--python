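"""REML estimation for linear mixed ("animal") models.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k K_k), where K_k is
either a genomic relatedness matrix over individuals or an identity over
grouping levels (birth year, year of measurement, permanent environment).
Estimation maximises the restricted likelihood by average-information
(AI) updates with step-halving and a boundary active set; components are
constrained to be non-negative and estimates stuck at the zero boundary
are flagged.  Standard errors come from the inverse AI matrix at the
optimum and ratio standard errors from a first-order delta method.

The restricted log-likelihood used throughout is
    logL = -1/2 [ log|V| + log|X'V^-1 X| + y'Py ],
so nested models fitted to the same data and fixed effects are directly
comparable with a chi-square likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .io import GRM

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "VarianceFit",
    "build_model",
    "fit_variance_components",
    "likelihood_ratio_test",
    "variance_ratios",
]

log = logging.getLogger(__name__)


@dataclass
class RandomTerm:
    """One random effect: an incidence matrix and its covariance structure.

    ``covariance=None`` means identity over the term's levels (a plain
    grouping effect); otherwise it is a PSD matrix over the columns of Z
    (e.g. a GRM over individuals).
    """

    name: str
    Z: np.ndarray  # (n_obs, q) 0/1 incidence
    covariance: np.ndarray | None = None

    def gram(self) -> np.ndarray:
        """Z K Z', the n_obs x n_obs contribution pattern of this term.

        Cached: nested-model fits sharing a term reuse the product.
        """
        cached = getattr(self, "_gram", None)
        if cached is not None:
            return cached
        if self.covariance is None:
            G = self.Z @ self.Z.T
        else:
            G = self.Z @ self.covariance @ self.Z.T
        self._gram = G
        return G

    def check_psd(self) -> None:
        """Reject genuinely indefinite structures.

        GCTA-form GRMs are mildly indefinite when markers are few (their
        diagonal is not the Gram diagonal), so sampling-level negativity
        is tolerated.
        """
        if self.covariance is None:
            return
        w = np.linalg.eigvalsh(self.covariance)
        if w.min() < -0.05 * max(1.0, abs(w.max())):
            raise ValueError(f"covariance structure for term {self.name!r} is not PSD")


@dataclass
class ModelSpec:
    """Data and design for one univariate mixed model."""

    y: np.ndarray
    X: np.ndarray
    terms: list[RandomTerm]
    obs_ids: list[str]  # individual id per observation (repeats allowed)
    fixed_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = len(self.y)
        if self.X.shape[0] != n or len(self.obs_ids) != n:
            raise ValueError("y, X and obs_ids must agree in length")
        for t in self.terms:
            if t.Z.shape[0] != n:
                raise ValueError(f"incidence for term {t.name!r} not conformable with y")
            if not np.allclose(t.Z.sum(axis=1), 1):
                raise ValueError(
                    f"term {t.name!r}: every observation must map to exactly one level"
                )

    def drop_term(self, name: str) -> "ModelSpec":
        kept = [t for t in self.terms if t.name != name]
        if len(kept) == len(self.terms):
            raise ValueError(f"no term named {name!r}")
        return ModelSpec(self.y, self.X, kept, self.obs_ids, self.fixed_names)


@dataclass
class VarianceFit:
    """REML estimates for one model."""

    components: dict[str, float]  # term name -> s2 (includes 'residual')
    se: dict[str, float]  # NaN for boundary-fixed components
    loglik: float
    converged: bool
    n_iter: int
    boundary: dict[str, bool]
    ai_cov: np.ndarray  # covariance of free components, param order below
    param_names: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    resid_blup: np.ndarray  # e-hat = s2_e * P y, one entry per observation
    obs_ids: list[str]

    @property
    def total_variance(self) -> float:
        return float(sum(self.components.values()))


def _design_from_factors(df: pd.DataFrame, factors: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded multilevel factors, aliased columns dropped."""
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in factors:
        d = pd.get_dummies(df[f].astype("category"), prefix=f, drop_first=True)
        for c in d.columns:
            cols.append(d[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    # drop aliased columns (rank-deficient design) via QR diagonal
    _, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        log.info("dropping aliased fixed-effect columns: %s", dropped)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return X, names


def build_model(
    pheno: pd.DataFrame,
    trait: str,
    grms: dict[str, GRM] | None = None,
    groups: list[str] | None = None,
    permanent_env: bool = False,
    fixed: list[str] = ("sex", "age"),
) -> ModelSpec:
    """Assemble a ModelSpec from a phenotype table.

    ``grms`` maps term names to GRMs (levels = GRM sample ids, incidence by
    the ``id`` column); ``groups`` are column names fitted as identity
    random effects; ``permanent_env`` adds an identity-on-individual term
    for repeated measures.  Fixed effects are multilevel factors.
    """
    df = pheno.dropna(subset=[trait]).reset_index(drop=True)
    y = df[trait].to_numpy(dtype=float)
    obs_ids = list(df["id"].astype(str))
    X, fixed_names = _design_from_factors(df, [f for f in fixed if f in df.columns])

    terms: list[RandomTerm] = []
    if grms:
        for name, grm in grms.items():
            pos = {s: i for i, s in enumerate(grm.sample_ids)}
            missing = [i for i in obs_ids if i not in pos]
            if missing:
                raise ValueError(f"GRM {name!r} lacks ids: {missing[:5]}")
            Z = np.zeros((len(df), len(grm.sample_ids)))
            Z[np.arange(len(df)), [pos[i] for i in obs_ids]] = 1.0
            terms.append(RandomTerm(name, Z, grm.values))
    for col in groups or []:
        levels = pd.Categorical(df[col])
        Z = np.zeros((len(df), len(levels.categories)))
        Z[np.arange(len(df)), levels.codes] = 1.0
        terms.append(RandomTerm(col, Z))
    if permanent_env:
        levels = pd.Categorical(obs_ids)
        Z = np.zeros((len(df), len(levels.categories)))
        Z[np.arange(len(df)), levels.codes] = 1.0
        terms.append(RandomTerm("pe", Z))
    return ModelSpec(y, X, terms, obs_ids, fixed_names)


# ---------------------------------------------------------------------------
# AI-REML


def _reml_pass(y, X, grams, theta):
    """One evaluation: logL, scores, AI matrix and solver by-products."""
    n, p = X.shape
    V = theta[-1] * np.eye(n)
    for t, G in zip(theta[:-1], grams):
        V += t * G
    cf = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(cf[0])).sum()
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    C = X.T @ Vi_X
    Ccf = cho_factor(C)
    logdet_c = 2.0 * np.log(np.abs(np.diag(Ccf[0]))).sum()
    beta = cho_solve(Ccf, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    yPy = float(y @ Py)
    loglik = -0.5 * (logdet_v + logdet_c + yPy)

    Vi = cho_solve(cf, np.eye(n))
    Ci = cho_solve(Ccf, np.eye(p))

    k = len(grams) + 1
    Gy = [G @ Py for G in grams] + [Py]
    # score_i = -1/2 (tr(P G_i) - y' P G_i P y)
    quad = np.array([float(Py @ g) for g in Gy])
    traces = np.array(
        [_tr_PG(Vi, Vi_X, Ci, grams[i]) if i < k - 1 else _tr_PG(Vi, Vi_X, Ci, None)
         for i in range(k)]
    )
    scores = -0.5 * (traces - quad)

    # AI_ij = 1/2 (G_i P y)' P (G_j P y)
    T = np.column_stack(Gy)
    Vi_T = cho_solve(cf, T)
    PT = Vi_T - Vi_X @ cho_solve(Ccf, X.T @ Vi_T)
    AI = 0.5 * (T.T @ PT)
    return {
        "loglik": loglik,
        "scores": scores,
        "AI": AI,
        "beta": beta,
        "beta_cov": Ci,
        "Py": Py,
    }


def _tr_PG(Vi, Vi_X, Ci, G):
    if G is None:
        tr_ViG = float(np.trace(Vi))
        XViG = Vi_X
    else:
        tr_ViG = float(np.sum(Vi * G))
        XViG = G @ Vi_X
    return tr_ViG - float(np.sum((Vi_X @ Ci) * XViG))


def fit_variance_components(
    spec: ModelSpec,
    max_iter: int = 200,
    tol_loglik: float = 1e-8,
    tol_grad: float = 1e-4,
    restart_on_failure: bool = True,
    start: np.ndarray | None = None,
) -> VarianceFit:
    """AI-REML with step-halving and a zero-boundary active set.

    Starting values split the phenotypic variance equally across all
    components; a failed fit restarts once from perturbed values.
    Deterministic given the data and options.
    """
    y, X = spec.y, spec.X
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after aliasing")
    grams = [t.gram() for t in spec.terms]
    names = [t.name for t in spec.terms] + ["residual"]
    vp = float(np.var(y)) or 1.0
    k = len(grams) + 1
    floor = 1e-6 * vp

    def run(theta0: np.ndarray):
        theta = theta0.copy()
        fixed = np.zeros(k, dtype=bool)
        # indefinite unit GRMs can make the equal-split V non-PD: shift
        # weight toward the residual until the first pass factorises
        for attempt in range(4):
            try:
                info = _reml_pass(y, X, grams, theta)
                break
            except np.linalg.LinAlgError:
                if attempt == 3:
                    for t in spec.terms:
                        t.check_psd()  # names the offending indefinite term
                    raise
                theta[:-1] *= 0.2
                theta[-1] = max(vp - theta[:-1].sum(), 0.5 * vp)
        last_ll = info["loglik"]
        for it in range(1, max_iter + 1):
            free = ~fixed
            s = info["scores"][free]
            AI = info["AI"][np.ix_(free, free)]
            try:
                delta = np.linalg.solve(AI, s)
            except np.linalg.LinAlgError:
                delta = s / np.maximum(np.diag(AI), 1e-12)
            step = 1.0
            for _ in range(12):
                cand = theta.copy()
                cand[free] = theta[free] + step * delta
                if (cand[free] >= floor).all() or step < 1e-3:
                    cand[free] = np.maximum(cand[free], floor)
                    try:
                        new_info = _reml_pass(y, X, grams, cand)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if new_info["loglik"] >= last_ll - 1e-6 or step < 1e-3:
                        break
                step *= 0.5
            else:
                return theta, info, it, False, fixed
            theta, info = cand, new_info
            # active set: pin components stuck at the floor with a
            # negative gradient (pushing further out of bounds)
            at_floor = theta <= floor * (1 + 1e-9)
            fixed = at_floor & (info["scores"] < 0)
            proj_grad = info["scores"].copy()
            proj_grad[fixed] = 0.0
            rel = abs(info["loglik"] - last_ll) / max(1.0, abs(info["loglik"]))
            if rel < tol_loglik and np.linalg.norm(proj_grad) < tol_grad:
                return theta, info, it, True, fixed
            last_ll = info["loglik"]
        return theta, info, max_iter, False, fixed

    theta0 = start if start is not None else np.full(k, vp / k)
    theta, info, n_iter, ok, fixed = run(np.asarray(theta0, dtype=float))
    if fixed.any():
        # evaluate the constrained optimum with boundary components at
        # exactly 0 so nested-model log-likelihoods are comparable
        theta_b = theta.copy()
        theta_b[fixed] = 0.0
        try:
            info_b = _reml_pass(y, X, grams, theta_b)
            if info_b["loglik"] >= info["loglik"]:
                theta, info = theta_b, info_b
        except np.linalg.LinAlgError:
            pass
    if not ok and restart_on_failure:
        rng = np.random.default_rng(0)
        theta0b = np.asarray(theta0, dtype=float) * rng.uniform(0.4, 1.6, size=k)
        theta_b, info_b, n_b, ok_b, fixed_b = run(theta0b)
        if ok_b or info_b["loglik"] > info["loglik"]:
            theta, info, n_iter, ok, fixed = theta_b, info_b, n_iter + n_b, ok_b, fixed_b

    free = ~fixed
    se = np.full(k, np.nan)
    cov = np.full((k, k), np.nan)
    try:
        inv = np.linalg.inv(info["AI"][np.ix_(free, free)])
        cov[np.ix_(free, free)] = inv
        se[free] = np.sqrt(np.maximum(np.diag(inv), 0.0))
    except np.linalg.LinAlgError:
        log.warning("AI matrix singular at optimum; SEs unavailable")

    comp = {n: (0.0 if f and t <= 2 * floor else float(t)) for n, t, f in zip(names, theta, fixed)}
    return VarianceFit(
        components=comp,
        se={n: float(s) for n, s in zip(names, se)},
        loglik=float(info["loglik"]),
        converged=bool(ok),
        n_iter=n_iter,
        boundary={n: bool(f) for n, f in zip(names, fixed)},
        ai_cov=cov,
        param_names=names,
        beta=info["beta"],
        beta_cov=info["beta_cov"],
        fixed_names=list(spec.fixed_names),
        resid_blup=float(theta[-1]) * info["Py"],
        obs_ids=list(spec.obs_ids),
    )


def likelihood_ratio_test(fit_full: VarianceFit, fit_reduced: VarianceFit):
    """2*(logL_full - logL_reduced) against chi-square with 1 df.

    The reduced model must drop exactly one variance component of the full
    model.  The statistic is floored at zero (REML optima of nested models
    can cross by numerical tolerance).
    """
    full = set(fit_full.param_names)
    red = set(fit_reduced.param_names)
    if not (red < full and len(full - red) == 1):
        raise ValueError(
            "models are not nested with one fewer variance component: "
            f"{sorted(full)} vs {sorted(red)}"
        )
    lrt = max(0.0, 2.0 * (fit_full.loglik - fit_reduced.loglik))
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return lrt, p


def lrt_pvalue(lrt: float, boundary_mixture: bool = False) -> float:
    """Upper-tail P for an LRT statistic.

    Default is the plain chi-square(1) reference; ``boundary_mixture``
    switches to the 1/2 chi2(0) + 1/2 chi2(1) mixture appropriate for a
    variance component tested on its boundary (more liberal).
    """
    if lrt <= 0:
        return 1.0
    p = float(stats.chi2.sf(lrt, df=1))
    return 0.5 * p if boundary_mixture else p


def variance_ratios(
    fit: VarianceFit, numerator_terms: list[str] | str
) -> dict[str, tuple[float, float]]:
    """Proportions of phenotypic variance with delta-method SEs.

    ratio_k = s2_k / sum_j s2_j; SE from the AI covariance via the
    gradient d ratio / d s2_j = (delta_kj * total - s2_k) / total^2.
    """
    if not fit.converged:
        raise ValueError("variance ratios require a converged fit")
    if isinstance(numerator_terms, str):
        numerator_terms = [numerator_terms]
    total = fit.total_variance
    if total <= 0:
        raise ValueError("total variance is zero")
    out = {}
    theta = np.array([fit.components[n] for n in fit.param_names])
    for name in numerator_terms:
        if name not in fit.components:
            raise ValueError(f"no component named {name!r}")
        kidx = fit.param_names.index(name)
        ratio = fit.components[name] / total
        grad = -theta[kidx] / total**2 * np.ones(len(theta))
        grad[kidx] += 1.0 / total
        cov = np.nan_to_num(fit.ai_cov, nan=0.0)
        se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
        out[name] = (float(ratio), se)
    return out
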