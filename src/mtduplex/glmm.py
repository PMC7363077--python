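"""Mixed-effects binomial logistic regression of mutation frequency.

Each observation (cell) is a mutation count k out of w sequenced
nucleotides for one individual x tissue x compartment x mutation-type
stratum; the model is

    k_i ~ Binomial(w_i, p_i),  logit p_i = x_i' beta + u_g(i),
    u_g ~ N(0, sigma^2)

with a random intercept per individual.  Fixed effects are the
categorical predictors age category (mother/pup), tissue, mtDNA
compartment (D-loop / non-D-loop) and mutation type (transversion,
A>G/T>C, C>T/G>A), treatment-coded against the baselines mother,
brain, D-loop, transversion.

Estimation maximises the exact marginal likelihood via adaptive
Gauss-Hermite quadrature (each individual's integral is centred at its
posterior mode with Laplace scaling), so a single set of routines
serves both the mixed model and its sigma = 0 (ordinary weighted
logistic) boundary.  Inference: Wald tests per coefficient from the
numerical Hessian; likelihood-ratio chi-squared tests per variable
(full vs. reduced refits) and for the random effect (mixed vs.
fixed-only; the naive chi-squared reference is conservative at this
boundary).  Variance explained follows the latent-scale pseudo-R^2 for
logit models: marginal R^2 = var(X beta) / (var(X beta) + sigma^2 +
pi^2/3), conditional adds sigma^2 to the numerator, and per-variable
partial R^2 = (R2_full - R2_red) / (1 - R2_red) from marginal values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "GlmmFit",
    "build_cells",
    "fit_glmm",
    "pseudo_r2",
    "likelihood_ratio_tests",
    "analyze_cells",
]

BASELINES = {
    "age": "mother",
    "tissue": "brain",
    "compartment": "D-loop",
    "mutation_class": "transversion",
}
LEVELS = {
    "age": ["mother", "pup"],
    "tissue": ["brain", "muscle", "single_oocyte", "oocyte_pool"],
    "compartment": ["D-loop", "non-D-loop"],
    "mutation_class": ["transversion", "AG_TC", "CT_GA"],
}

#: reference-strand bases capable of producing each mutation class
_CLASS_BASES = {
    "AG_TC": ("A", "T"),
    "CT_GA": ("C", "G"),
    "transversion": ("A", "C", "G", "T"),
}

_LOGIT_RESIDUAL_VAR = np.pi**2 / 3


def mutation_class(mutation_type: str) -> str:
    if mutation_type in ("A>G", "T>C"):
        return "AG_TC"
    if mutation_type in ("C>T", "G>A"):
        return "CT_GA"
    return "transversion"


# ----------------------------------------------------------------------
# cells


def build_cells(
    records: pd.DataFrame,
    nt_table: pd.DataFrame,
    metadata: pd.DataFrame,
    min_nt: float = 200_000.0,
) -> pd.DataFrame:
    """Construct model cells from classified mutations and denominators.

    ``records``: de novo mutation events (needs sample_id, position,
    mutation_type, compartment, n_events).  ``nt_table``: per sample,
    per compartment ("D-loop"/"non-D-loop"), per reference base counts
    of sequenced nucleotides (columns sample_id, compartment, base,
    nt).  Single oocytes are combined per individual; cells below
    ``min_nt`` sequenced nucleotides are dropped (low-depth bias
    guard).  Absent sample x stratum combinations yield no cell.
    """
    meta = metadata.set_index("sample_id")
    nt = nt_table.merge(
        metadata[["sample_id", "individual", "generation", "tissue"]], on="sample_id"
    )
    counts: dict[tuple, int] = {}
    for r in records.itertuples(index=False):
        m = meta.loc[r.sample_id]
        comp = "D-loop" if r.compartment == "D-loop" else "non-D-loop"
        key = (
            m["individual"],
            m["generation"],
            m["tissue"],
            comp,
            mutation_class(r.mutation_type),
        )
        counts[key] = counts.get(key, 0) + int(r.n_events)

    nt_sum = (
        nt.groupby(["individual", "generation", "tissue", "compartment", "base"])["nt"]
        .sum()
        .reset_index()
    )
    rows = []
    for (ind, gen, tissue), grp in nt_sum.groupby(["individual", "generation", "tissue"]):
        for comp in LEVELS["compartment"]:
            sub = grp[grp["compartment"] == comp].set_index("base")["nt"]
            if sub.empty:
                continue
            for mclass in LEVELS["mutation_class"]:
                w = float(sum(sub.get(b, 0.0) for b in _CLASS_BASES[mclass]))
                if w <= 0:
                    continue
                k = counts.get((ind, gen, tissue, comp, mclass), 0)
                rows.append(
                    {
                        "individual": ind,
                        "age": gen,
                        "tissue": tissue,
                        "compartment": comp,
                        "mutation_class": mclass,
                        "k": k,
                        "w": w,
                    }
                )
    cells = pd.DataFrame(rows)
    if cells.empty:
        return cells
    return cells[cells["w"] >= min_nt].reset_index(drop=True)


# ----------------------------------------------------------------------
# design matrix


def design_matrix(
    cells: pd.DataFrame, include_interactions: bool = False
) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded design with intercept (and optional mutation-type
    x {age, tissue, compartment} two-way interactions)."""
    cols: list[np.ndarray] = [np.ones(len(cells))]
    names = ["(Intercept)"]
    dummies: dict[str, list[tuple[str, np.ndarray]]] = {}
    for var, levels in LEVELS.items():
        present = [l for l in levels if (cells[var] == l).any()]
        if cells[var].nunique() != len(present):
            raise ValueError(f"unknown level in variable {var}")
        # fall back to the first present level when the configured
        # baseline is absent from the data (e.g. a dropped compartment)
        baseline = BASELINES[var] if BASELINES[var] in present else present[0]
        dummies[var] = []
        for level in present:
            if level == baseline:
                continue
            vec = (cells[var] == level).to_numpy(dtype=float)
            dummies[var].append((f"{var}[{level}]", vec))
            cols.append(vec)
            names.append(f"{var}[{level}]")
    if include_interactions:
        for var in ("age", "tissue", "compartment"):
            for n1, v1 in dummies["mutation_class"]:
                for n2, v2 in dummies[var]:
                    cols.append(v1 * v2)
                    names.append(f"{n1}:{n2}")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "check for single-level factors or aliased columns"
        )
    return X, names


# ----------------------------------------------------------------------
# likelihood


class _Marginal:
    """Adaptive Gauss-Hermite marginal log-likelihood machinery."""

    def __init__(self, X, k, w, group_idx, n_groups, n_quad=15):
        self.X = X
        self.k = k
        self.w = w
        self.g = group_idx
        self.G = n_groups
        nodes, weights = hermegauss(n_quad)  # weight e^{-x^2/2}
        self.nodes = nodes
        self.logw = np.log(weights)
        # binomial normalising constants (model-independent)
        self.const = float(
            np.sum(special.gammaln(w + 1) - special.gammaln(k + 1) - special.gammaln(w - k + 1))
        )

    def _group_ll(self, eta):
        """Per-group sum of binomial log-likelihood terms (no constants)."""
        ll = self.k * eta - self.w * np.logaddexp(0.0, eta)
        return np.bincount(self.g, weights=ll, minlength=self.G)

    def loglik(self, beta, sigma):
        xb = self.X @ beta
        if sigma <= 1e-8:
            return float(self._group_ll(xb).sum()) + self.const
        # posterior mode per group by Newton
        u = np.zeros(self.G)
        for _ in range(50):
            eta = xb + u[self.g]
            p = special.expit(eta)
            grad = np.bincount(self.g, weights=self.k - self.w * p, minlength=self.G)
            grad -= u / sigma**2
            hess = -np.bincount(self.g, weights=self.w * p * (1 - p), minlength=self.G)
            hess -= 1 / sigma**2
            step = grad / hess
            u -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        tau = 1.0 / np.sqrt(-hess)
        total = 0.0
        G = self.G
        vals = np.empty((self.nodes.size, G))
        for j, (x, lw) in enumerate(zip(self.nodes, self.logw)):
            uu = u + tau * x
            eta = xb + uu[self.g]
            ll = self._group_ll(eta)
            ll += -0.5 * (uu / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
            vals[j] = ll + lw + 0.5 * x**2
        total = float(np.sum(special.logsumexp(vals, axis=0) + np.log(tau)))
        return total + self.const


@dataclass
class GlmmFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    sigma2: float
    loglik: float
    converged: bool
    n_cells: int
    n_groups: int
    marginal_r2: float
    conditional_r2: float
    odds_ratios: np.ndarray
    message: str = ""

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "std_error": self.se,
                "z": self.wald_z,
                "p_value": self.wald_p,
                "odds_ratio": self.odds_ratios,
            }
        )


def fit_glmm(
    cells: pd.DataFrame,
    include_interactions: bool = False,
    random_effect: bool = True,
    n_quad: int = 15,
    tol: float = 1e-6,
) -> GlmmFit:
    """Fit the binomial-logit model by maximum (marginal) likelihood.

    ``random_effect=False`` fixes sigma at 0, i.e. an ordinary weighted
    logistic regression fitted with the same machinery, used as the
    reduced model in the random-effect likelihood-ratio test.
    Non-convergence raises nothing but is flagged on the result.
    """
    if cells["individual"].nunique() < 2 and random_effect:
        raise ValueError("need >= 2 individuals for a random intercept")
    X, names = design_matrix(cells, include_interactions)
    k = cells["k"].to_numpy(dtype=float)
    w = cells["w"].to_numpy(dtype=float)
    groups, group_idx = np.unique(cells["individual"], return_inverse=True)
    m = _Marginal(X, k, w, group_idx, len(groups), n_quad)

    # starting values from a few IRLS steps at sigma = 0
    beta0 = np.zeros(X.shape[1])
    beta0[0] = special.logit(max(k.sum() / w.sum(), 1e-12))
    beta = beta0.copy()
    for _ in range(25):
        eta = X @ beta
        p = special.expit(eta)
        mu = w * p
        W = np.maximum(w * p * (1 - p), 1e-12)
        z = eta + (k - mu) / W
        WX = X * W[:, None]
        try:
            beta_new = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new

    if not random_effect:
        theta0 = beta
        nll = lambda th: -m.loglik(th, 0.0)
        res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-8})
        beta_hat, sigma2 = res.x, 0.0
        ll = -res.fun
        free = res.x
        hess_fun = lambda th: -m.loglik(th, 0.0)
    else:
        theta0 = np.append(beta, np.log(0.3))
        nll = lambda th: -m.loglik(th[:-1], np.exp(th[-1]))
        res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-7})
        if not res.success:  # fall back to a derivative-free polish
            res = optimize.minimize(
                nll, res.x, method="Nelder-Mead",
                options={"xatol": 1e-7, "fatol": tol, "maxiter": 20000, "maxfev": 40000},
            )
        beta_hat = res.x[:-1]
        sigma2 = float(np.exp(res.x[-1]) ** 2)
        ll = -res.fun
        free = res.x
        hess_fun = nll

    # numerical observed-information standard errors for beta
    from statsmodels.tools.numdiff import approx_hess1

    H = approx_hess1(free, hess_fun if random_effect else nll)
    p_fixed = X.shape[1]
    try:
        cov = np.linalg.inv(H)[:p_fixed, :p_fixed]
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p_fixed, np.nan)
    zstat = np.divide(beta_hat, se, out=np.full(p_fixed, np.nan), where=se > 0)
    wald_p = 2 * sps.norm.sf(np.abs(zstat))

    lp = X @ beta_hat
    var_fixed = float(np.var(lp))
    denom = var_fixed + sigma2 + _LOGIT_RESIDUAL_VAR
    marginal = var_fixed / denom
    conditional = (var_fixed + sigma2) / denom

    return GlmmFit(
        names=names,
        beta=beta_hat,
        se=se,
        wald_z=zstat,
        wald_p=wald_p,
        sigma2=sigma2,
        loglik=ll,
        converged=bool(res.success),
        n_cells=len(cells),
        n_groups=len(groups),
        marginal_r2=marginal,
        conditional_r2=conditional,
        odds_ratios=np.exp(beta_hat),
        message=str(res.message),
    )


def pseudo_r2(full_marginal: float, reduced_marginal: float) -> float:
    """Partial pseudo-R^2 of a variable from full/reduced marginal values:
    ((1 - R2_red) - (1 - R2_full)) / (1 - R2_red)."""
    return ((1 - reduced_marginal) - (1 - full_marginal)) / (1 - reduced_marginal)


def _drop_variable(cells: pd.DataFrame, var: str) -> pd.DataFrame:
    """Collapse a variable to its baseline so its dummies vanish."""
    out = cells.copy()
    out[var] = BASELINES[var]
    return out


def likelihood_ratio_tests(
    cells: pd.DataFrame,
    full: GlmmFit,
    include_interactions: bool = False,
    n_quad: int = 15,
) -> pd.DataFrame:
    """Per-variable LRTs (full vs. variable-removed refits) with partial
    pseudo-R^2, plus the random-effect LRT against the fixed-only fit.

    With interactions, removing a variable also removes the
    interactions that involve it.
    """
    rows = []
    for var in LEVELS:
        reduced = fit_glmm(
            _drop_variable(cells, var),
            include_interactions=include_interactions,
            n_quad=n_quad,
        )
        stat = max(0.0, 2 * (full.loglik - reduced.loglik))
        df = sum(n.startswith(f"{var}[") or f"{var}[" in n.split(":")[-1] for n in full.names)
        p = sps.chi2.sf(stat, df) if df > 0 else np.nan
        rows.append(
            {
                "term": var,
                "lrt_chi2": stat,
                "df": df,
                "p_value": p,
                "partial_pseudo_r2": pseudo_r2(full.marginal_r2, reduced.marginal_r2),
            }
        )
    fixed_only = fit_glmm(
        cells, include_interactions=include_interactions, random_effect=False
    )
    stat = max(0.0, 2 * (full.loglik - fixed_only.loglik))
    rows.append(
        {
            "term": "random:individual",
            "lrt_chi2": stat,
            "df": 1,
            "p_value": sps.chi2.sf(stat, 1),
            "partial_pseudo_r2": np.nan,
        }
    )
    return pd.DataFrame(rows)


def analyze_cells(
    cells: pd.DataFrame, include_interactions: bool = False, n_quad: int = 15
) -> tuple[GlmmFit, pd.DataFrame]:
    """Fit the model and produce the coefficient + LRT report tables."""
    full = fit_glmm(cells, include_interactions=include_interactions, n_quad=n_quad)
    tests = likelihood_ratio_tests(
        cells, full, include_interactions=include_interactions, n_quad=n_quad
    )
    return full, tests
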