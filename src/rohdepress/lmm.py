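"""Genomic relationship matrix and the repeated-records animal model.

The model for record l of bull m is

    y = X b + Z_bull u + Z_bull p + e,
    u ~ N(0, G sigma_a^2),  p ~ N(0, I sigma_pe^2),  e ~ N(0, I sigma_e^2),

with fixed effects X covering the overall mean, year-season, AI centre,
collection-interval class, samples-per-day class, a linear regression on
age at collection, and optional per-bull inbreeding covariates (F_SNP,
F_ROH, or the five ROH length-class coefficients fitted jointly).  G is
the VanRaden method-1 genomic relationship matrix.

Variance components are estimated by average-information REML with an
EM fallback whenever the AI update leaves the parameter space or fails
to increase the restricted likelihood; accepted iterations therefore
never decrease it.  All linear algebra is carried out in the bull
dimension (q x q) through the Woodbury identity, so record counts in the
hundreds of thousands remain tractable.

Inference on fixed-effect coefficients uses the GLS solution at the
converged variance components; estimate/SE is referred to Student's t
with (number of bulls - rank of the fixed-effect design) degrees of
freedom, since bulls (not records) are the effective replication for
per-bull covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .io import GenotypeMatrix

CATEGORICAL_EFFECTS = ("year_season", "center", "interval", "n_sample")

_GRM_RIDGE = 1e-6


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message: str, history: list):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class VarianceComponents:
    """Additive-genetic, permanent-environment and residual variances."""

    sigma_a2: float
    sigma_pe2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("variance components must be finite and non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.sigma_a2, self.sigma_pe2, self.sigma_e2], dtype=float)

    @property
    def total(self) -> float:
        return float(self.as_array().sum())


@dataclass
class GRM:
    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        q = len(self.sample_ids)
        if self.matrix.shape != (q, q):
            raise ValueError("GRM shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")


@dataclass
class FitResult:
    """Coefficients, variance components and metadata from one model fit."""

    coefficients: pd.DataFrame
    vc: VarianceComponents
    vc_se: np.ndarray | None
    loglik: float
    converged: bool
    n_records: int
    n_bulls: int
    n_iter: int
    history: list = field(default_factory=list, repr=False)

    def coefficient(self, name: str) -> pd.Series:
        return self.coefficients.set_index("name").loc[name]


def build_grm(g: GenotypeMatrix, ridge: float = _GRM_RIDGE) -> GRM:
    """VanRaden method-1 GRM: G = ZZ' / (2 sum p_j (1 - p_j)).

    Z centres dosages by twice the observed allele frequency.  A small
    ridge stabilizes the diagonal so downstream factorizations succeed.
    Monomorphic markers must have been removed by QC.
    """
    p = g.allele_freq_b()
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic markers present; run marker QC before the GRM")
    m = g.dosage.astype(float)
    z = m - 2.0 * p[np.newaxis, :]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    mat = z @ z.T / denom
    mat[np.diag_indices_from(mat)] += ridge
    return GRM(sample_ids=list(g.samples), matrix=mat)


# ---------------------------------------------------------------------------
# design construction

def build_design(
    ph: pd.DataFrame,
    bull_order: list[str],
    covariates: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray, list[str]]:
    """Assemble (y, X, names, bull_idx, na_terms) for the animal model.

    Categorical fixed effects are reference-encoded (first level by string
    sort dropped); factors with a single observed level are absorbed into
    the intercept.  ``covariates`` holds per-bull numeric columns indexed
    by bull id; zero-variance covariates are excluded from the design and
    reported in ``na_terms`` instead of being silently dropped.
    """
    missing = set(ph["bull_id"]) - set(bull_order)
    if missing:
        raise ValueError(f"records for bulls absent from the GRM: {sorted(missing)[:5]}")
    index = {b: i for i, b in enumerate(bull_order)}
    bull_idx = ph["bull_id"].map(index).to_numpy()
    y = ph["value"].to_numpy(dtype=float)

    cols: list[np.ndarray] = [np.ones(len(ph))]
    names: list[str] = ["intercept"]
    for factor in CATEGORICAL_EFFECTS:
        levels = sorted(ph[factor].astype(str).unique())
        for level in levels[1:]:
            cols.append((ph[factor].astype(str) == level).to_numpy(float))
            names.append(f"{factor}[{level}]")
    cols.append(ph["age_months"].to_numpy(dtype=float))
    names.append("age_months")

    na_terms: list[str] = []
    if covariates is not None:
        cov = covariates.reindex(bull_order)
        if cov.isna().any().any():
            bad = cov.columns[cov.isna().any()].tolist()
            raise ValueError(f"covariates {bad} missing for some bulls in the GRM")
        for name in cov.columns:
            per_bull = cov[name].to_numpy(dtype=float)
            if np.ptp(per_bull) == 0:
                na_terms.append(str(name))
                continue
            cols.append(per_bull[bull_idx])
            names.append(str(name))

    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        dropped = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"fixed-effect design is singular; collinear columns: {dropped}")
    return y, X, names, bull_idx, na_terms


# ---------------------------------------------------------------------------
# REML machinery (bull-dimension Woodbury algebra)

class _Workspace:
    """Sufficient statistics and per-theta REML quantities.

    With V = sigma_e2 I + Z (sigma_a2 G + sigma_pe2 I) Z' and Z the
    record-to-bull incidence matrix, every trace and quadratic form needed
    by AI-REML reduces to q x q algebra via Z'Z = diag(records per bull).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, bull_idx: np.ndarray, G: np.ndarray):
        self.y, self.X, self.bull_idx, self.G = y, X, bull_idx, G
        self.n, self.p = X.shape
        self.q = G.shape[0]
        self.D = np.bincount(bull_idx, minlength=self.q).astype(float)
        self.Zy = np.bincount(bull_idx, weights=y, minlength=self.q)
        self.ZX = np.zeros((self.q, self.p))
        np.add.at(self.ZX, bull_idx, X)
        self.XX = X.T @ X
        self.Xy = X.T @ y
        self.yy = float(y @ y)

    def evaluate(self, theta: np.ndarray, derivatives: bool = True) -> dict:
        sa, sp, se = theta
        q, n, p = self.q, self.n, self.p
        K = sa * self.G + sp * np.eye(q)
        A = np.eye(q) + K * (self.D / se)[np.newaxis, :]
        C = np.linalg.solve(A, K)
        C = 0.5 * (C + C.T)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("V is not positive definite at these components")
        logdet_V = n * np.log(se) + logdet_A

        ZXC = self.ZX.T @ C                      # p x q
        XVX = (self.XX - ZXC @ self.ZX / se) / se
        CZy = C @ self.Zy
        XVy = (self.Xy - ZXC @ self.Zy / se) / se
        yVy = (self.yy - self.Zy @ CZy / se) / se
        sign_x, logdet_XVX = np.linalg.slogdet(XVX)
        if sign_x <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        B = np.linalg.inv(XVX)
        beta = B @ XVy
        yPy = yVy - XVy @ beta
        loglik = -0.5 * (logdet_V + logdet_XVX + yPy)
        out = {"loglik": float(loglik), "B": B, "beta": beta, "XVy": XVy, "C": C}
        if not derivatives:
            return out

        D, G = self.D, self.G
        S = (np.diag(D) - (D[:, None] * C * D[None, :]) / se) / se   # Z'V^-1 Z
        T = (self.ZX.T - ZXC * (D / se)[None, :]) / se               # X'V^-1 Z
        ViX = (self.X - (C @ self.ZX / se)[self.bull_idx]) / se
        Viy = (self.y - (CZy / se)[self.bull_idx]) / se
        f = Viy - ViX @ beta                                          # P y
        Zf = np.bincount(self.bull_idx, weights=f, minlength=q)
        GZf = G @ Zf

        tr_Vinv = n / se - float(np.sum(np.diag(C) * D)) / se**2
        tr_PVa = float(np.sum(G * S)) - float(np.sum(B * (T @ G @ T.T)))
        tr_PVpe = float(np.trace(S)) - float(np.sum(B * (T @ T.T)))
        tr_PVe = tr_Vinv - float(np.sum(B * (ViX.T @ ViX)))
        quad = np.array([float(Zf @ GZf), float(Zf @ Zf), float(f @ f)])
        traces = np.array([tr_PVa, tr_PVpe, tr_PVe])
        grad = 0.5 * (quad - traces)

        # average-information matrix: 0.5 v_i' P v_j with v_i = dV/dtheta_i P y
        Vmat = np.column_stack([GZf[self.bull_idx], Zf[self.bull_idx], f])
        ZV = np.zeros((q, 3))
        np.add.at(ZV, self.bull_idx, Vmat)
        ViV = (Vmat - (C @ ZV / se)[self.bull_idx]) / se
        PV = ViV - ViX @ (B @ (ViX.T @ Vmat))
        AI = 0.5 * (Vmat.T @ PV)
        AI = 0.5 * (AI + AI.T)
        out.update(grad=grad, AI=AI, quad=quad, traces=traces, f=f, Zf=Zf)
        return out


def _reml(
    y: np.ndarray,
    X: np.ndarray,
    bull_idx: np.ndarray,
    G: np.ndarray,
    start: np.ndarray,
    max_iter: int = 200,
    tol_vc: float = 1e-8,
    tol_ll: float = 1e-9,
):
    ws = _Workspace(y, X, bull_idx, G)
    floor = 1e-10 * float(np.var(y))
    theta = np.maximum(np.asarray(start, dtype=float), floor)
    em_weights = np.array([ws.q, ws.q, ws.n], dtype=float)
    history: list[tuple[np.ndarray, float]] = []
    state = ws.evaluate(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        history.append((theta.copy(), state["loglik"]))
        new_theta, new_state = None, None
        try:
            delta = np.linalg.solve(state["AI"], state["grad"])
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(state["AI"], state["grad"], rcond=None)[0]
        # AI step, clamped to the floor and step-halved if it overshoots
        for _ in range(8):
            cand = np.maximum(theta + delta, floor)
            try:
                cand_state = ws.evaluate(cand)
            except np.linalg.LinAlgError:
                delta = 0.5 * delta
                continue
            if cand_state["loglik"] >= state["loglik"] - 1e-10:
                new_theta, new_state = cand, cand_state
                break
            delta = 0.5 * delta
        if new_theta is None:
            # EM step (guaranteed ascent in exact arithmetic), with halving
            em = theta + theta**2 * (state["quad"] - state["traces"]) / em_weights
            em = np.maximum(em, floor)
            step = em - theta
            for _ in range(25):
                cand = theta + step
                try:
                    cand_state = ws.evaluate(cand)
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if cand_state["loglik"] >= state["loglik"] - 1e-10:
                    new_theta, new_state = cand, cand_state
                    break
                step *= 0.5
            if new_theta is None:
                new_theta, new_state = theta, state  # flat: treat as converged
        d_ll = abs(new_state["loglik"] - state["loglik"])
        d_vc = np.max(np.abs(new_theta - theta) / np.maximum(theta, floor))
        theta, state = new_theta, new_state
        if d_vc < tol_vc or d_ll < tol_ll:
            converged = True
            break
    history.append((theta.copy(), state["loglik"]))
    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", history
        )
    vc_se = None
    try:
        ai_inv = np.linalg.inv(state["AI"])
        if np.all(np.diag(ai_inv) > 0):
            vc_se = np.sqrt(np.diag(ai_inv))
    except np.linalg.LinAlgError:
        pass
    return theta, state, history, it, vc_se, ws


def _default_start(y: np.ndarray) -> np.ndarray:
    v = float(np.var(y, ddof=1))
    return np.array([v / 3.0, v / 3.0, v / 3.0])


def fit_animal_model(
    ph: pd.DataFrame,
    grm: GRM,
    trait: str | None = None,
    covariates: pd.DataFrame | None = None,
    start_vc: VarianceComponents | None = None,
    max_iter: int = 200,
    tol_vc: float = 1e-8,
    tol_ll: float = 1e-9,
) -> FitResult:
    """Fit the repeated-records animal model by AI-REML.

    ``covariates`` carries the per-bull inbreeding regressors (one column
    for F_ROH or F_SNP; omit it entirely to estimate heritability without
    the inbreeding effect).  Returns coefficient estimates with SEs and
    two-sided t-test p-values, plus the variance components.
    """
    if trait is not None:
        ph = ph.loc[ph["trait"] == trait]
    if ph.empty:
        raise ValueError("no phenotype records to fit")
    y, X, names, bull_idx, na_terms = build_design(ph, grm.sample_ids, covariates)
    start = start_vc.as_array() if start_vc is not None else _default_start(y)
    theta, state, history, n_iter, vc_se, ws = _reml(
        y, X, bull_idx, grm.matrix, start, max_iter, tol_vc, tol_ll
    )
    beta, B = state["beta"], state["B"]
    se = np.sqrt(np.diag(B))
    df = ws.q - X.shape[1]
    tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(df, 1))
    coef = pd.DataFrame(
        {"name": names, "estimate": beta, "se": se, "t": tstat, "p": pvals}
    )
    for term in na_terms:  # zero-variance covariates: flagged, not dropped silently
        coef.loc[len(coef)] = [term, np.nan, np.nan, np.nan, np.nan]
    return FitResult(
        coefficients=coef,
        vc=VarianceComponents(*np.maximum(theta, 0.0)),
        vc_se=vc_se,
        loglik=state["loglik"],
        converged=True,
        n_records=len(y),
        n_bulls=ws.q,
        n_iter=n_iter,
        history=history,
    )


def fit_model2(
    ph: pd.DataFrame,
    grm: GRM,
    f_classes: pd.DataFrame,
    trait: str | None = None,
    **kwargs,
) -> FitResult:
    """Model with the five ROH length-class coefficients fitted jointly.

    ``f_classes`` has one per-bull column per length class; classes with
    zero variance across bulls are reported as NA coefficients.
    """
    if f_classes.shape[1] != 5:
        raise ValueError("expected five ROH length-class covariate columns")
    return fit_animal_model(ph, grm, trait=trait, covariates=f_classes, **kwargs)


def heritability_repeatability(vc: VarianceComponents) -> tuple[float, float]:
    """h2 = sigma_a2 / total and r = (sigma_a2 + sigma_pe2) / total."""
    if vc.total <= 0:
        raise ValueError("total variance must be positive")
    h2 = vc.sigma_a2 / vc.total
    r = (vc.sigma_a2 + vc.sigma_pe2) / vc.total
    return h2, r


def gls_coefficients(
    y: np.ndarray, X: np.ndarray, bull_idx: np.ndarray, G: np.ndarray,
    vc: VarianceComponents,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS fixed-effect solution and covariance at fixed variance components."""
    ws = _Workspace(y, X, bull_idx, G)
    state = ws.evaluate(vc.as_array(), derivatives=False)
    return state["beta"], state["B"]
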