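"""Recursive path-model (SEM) engine: ML covariance fitting, fit indices, effects.

The engine handles observed-variable path models: a directed acyclic graph over
p observed variables, one free coefficient per edge, one free variance per
exogenous variable and one free residual variance per endogenous variable, no
residual covariances and no mean structure.  Writing A for the p x p matrix of
direct coefficients (A[t, s] = coefficient of s -> t) and Psi for the diagonal
matrix of exogenous/residual variances, the model-implied covariance is

    Sigma(theta) = (I - A)^-1 Psi (I - A)^-T

and parameters are estimated by minimizing the maximum-likelihood discrepancy

    F_ML(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

against the sample covariance S.  For this model class (recursive, diagonal
Psi) the likelihood factorizes over equations, so the per-equation
ordinary-least-squares solution is the exact ML optimum; it is used as the
optimizer start and the quasi-Newton polish normally terminates immediately.
Standard errors come from the inverse information matrix of ((n-1)/2) F_ML
(numerical Hessian), the chi-square statistic is (n-1) F_min, and total
effects are (I - A)^-1 - I on both the raw and the standardized scale.

Variables are rescaled to unit sample variance internally before optimization
and back-transformed afterwards; this keeps the free parameters O(1) even when
raw variables differ in scale by several orders of magnitude.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PathModel",
    "MomentSummary",
    "SemFit",
    "FitIndexSet",
    "build_model",
    "parse_model_config",
    "sample_moments",
    "describe",
    "pearson_matrix",
    "implied_sigma",
    "fit_ml",
    "standard_errors",
    "standardize",
    "fit_indices",
    "decompose_effects",
]


# ---------------------------------------------------------------------------
# Model specification


@dataclass(frozen=True)
class PathModel:
    """Observed-variable recursive path model.

    ``paths`` are (source, target) pairs, each carrying one free coefficient;
    every variable gets one free variance (exogenous variance or residual).
    """

    variables: tuple[str, ...]
    paths: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        seen = set()
        for s, t in self.paths:
            if s not in self.variables or t not in self.variables:
                raise ValueError(f"path {s} -> {t} uses unknown variable")
            if s == t:
                raise ValueError(f"self-loop {s} -> {t}")
            if (s, t) in seen:
                raise ValueError(f"duplicate path {s} -> {t}")
            seen.add((s, t))
        deps = {v: {s for s, t in self.paths if t == v} for v in self.variables}
        try:
            list(graphlib.TopologicalSorter(deps).static_order())
        except graphlib.CycleError as exc:
            raise ValueError("path set contains a cycle; only recursive (acyclic) "
                             "models are supported") from exc

    @property
    def p(self) -> int:
        return len(self.variables)

    @property
    def endogenous(self) -> tuple[str, ...]:
        tgt = {t for _, t in self.paths}
        return tuple(v for v in self.variables if v in tgt)

    @property
    def exogenous(self) -> tuple[str, ...]:
        tgt = {t for _, t in self.paths}
        return tuple(v for v in self.variables if v not in tgt)

    @property
    def n_free(self) -> int:
        # one coefficient per path + one variance per variable
        return len(self.paths) + self.p

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_free

    @property
    def param_names(self) -> tuple[str, ...]:
        names = [f"{s} -> {t}" for s, t in self.paths]
        names += [f"var({v})" for v in self.exogenous]
        names += [f"resid({v})" for v in self.endogenous]
        return tuple(names)

    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(s for s, t in self.paths if t == v)


def build_model(variables: Sequence[str], paths: Iterable) -> PathModel:
    """Validate and build a :class:`PathModel`.

    ``paths`` may be (source, target) pairs or ``"source -> target"`` strings.
    """
    parsed = []
    for p_ in paths:
        if isinstance(p_, str):
            s, _, t = p_.partition("->")
            if not t:
                raise ValueError(f"cannot parse path spec {p_!r}")
            parsed.append((s.strip(), t.strip()))
        else:
            s, t = p_
            parsed.append((str(s), str(t)))
    model = PathModel(tuple(variables), tuple(parsed))
    if model.df < 0:
        raise ValueError(f"model is not identifiable: df = {model.df} < 0")
    return model


def parse_model_config(source) -> PathModel:
    """Build a model from a TOML config (text, path, or pre-parsed mapping).

    The config lists ``variables = [...]`` and ``paths = ["a -> b", ...]``.
    """
    if isinstance(source, Mapping):
        cfg = source
    else:
        import tomllib

        text = source if "\n" in str(source) or "=" in str(source) else open(source).read()
        if hasattr(source, "read"):
            text = source.read()
        cfg = tomllib.loads(text)
    return build_model(cfg["variables"], cfg["paths"])


# ---------------------------------------------------------------------------
# Sample moments and descriptives


@dataclass(frozen=True)
class MomentSummary:
    """Sample size, means and covariance matrix (denominator recorded as ddof)."""

    n: int
    means: pd.Series
    cov: pd.DataFrame
    ddof: int = 1

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.cov.columns)


def _check_frame(records: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    sub = records[list(variables)]
    if sub.isna().any().any():
        bad = sub.isna().stack()
        idx, col = bad[bad].index[0]
        raise ValueError(f"missing value in record {idx!r}, field {col!r}")
    return sub.astype(float)


def sample_moments(records: pd.DataFrame, variables: Sequence[str], ddof: int = 1) -> MomentSummary:
    """Means and covariance of the named columns with the stated denominator."""
    sub = _check_frame(records, variables)
    if len(sub) < 2:
        raise ValueError("need at least 2 records")
    return MomentSummary(n=len(sub), means=sub.mean(), cov=sub.cov(ddof=ddof), ddof=ddof)


def describe(records: pd.DataFrame, variable: str) -> dict[str, float]:
    """Mean, n-1 variance, bias-corrected skewness and excess kurtosis."""
    x = _check_frame(records, [variable])[variable].to_numpy()
    if x.size < 4:
        raise ValueError("need at least 4 observations for kurtosis")
    return {
        "mean": float(x.mean()),
        "variance": float(x.var(ddof=1)),
        "skewness": float(stats.skew(x, bias=False)),
        "kurtosis": float(stats.kurtosis(x, bias=False, fisher=True)),
    }


def pearson_matrix(records: pd.DataFrame, variables: Sequence[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix and two-sided p-values via the t transform."""
    sub = _check_frame(records, variables)
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 records for correlation p-values")
    sds = sub.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant column(s): {list(sds.index[sds == 0])}")
    r = sub.corr()
    rv = r.to_numpy(copy=True)
    np.clip(rv, -0.9999999999, 0.9999999999, out=rv)
    t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, np.nan)
    return r, pd.DataFrame(p, index=r.index, columns=r.columns)


# ---------------------------------------------------------------------------
# ML fitting


def _matrices(model: PathModel, theta: np.ndarray, order: Mapping[str, int]) -> tuple[np.ndarray, np.ndarray]:
    p = model.p
    A = np.zeros((p, p))
    for i, (s, t) in enumerate(model.paths):
        A[order[t], order[s]] = theta[i]
    psi = np.zeros(p)
    k = len(model.paths)
    for v in model.exogenous:
        psi[order[v]] = theta[k]
        k += 1
    for v in model.endogenous:
        psi[order[v]] = theta[k]
        k += 1
    return A, psi


def implied_sigma(model: PathModel, theta: np.ndarray) -> np.ndarray:
    """Model-implied covariance Sigma = (I-A)^-1 Psi (I-A)^-T at ``theta``.

    ``theta`` follows :attr:`PathModel.param_names` order.
    """
    order = {v: i for i, v in enumerate(model.variables)}
    A, psi = _matrices(model, np.asarray(theta, float), order)
    B = np.linalg.inv(np.eye(model.p) - A)
    sig = B @ np.diag(psi) @ B.T
    return (sig + sig.T) / 2.0


def _f_ml(model: PathModel, S: np.ndarray, ld_S: float, theta: np.ndarray) -> float:
    sig = implied_sigma(model, theta)
    sign, ld = np.linalg.slogdet(sig)
    if sign <= 0:
        return np.inf
    return ld + float(np.trace(S @ np.linalg.inv(sig))) - ld_S - model.p


def _f_grad(model: PathModel, S: np.ndarray, theta: np.ndarray) -> np.ndarray:
    order = {v: i for i, v in enumerate(model.variables)}
    A, psi = _matrices(model, theta, order)
    p = model.p
    B = np.linalg.inv(np.eye(p) - A)
    sig = B @ np.diag(psi) @ B.T
    sig_inv = np.linalg.inv(sig)
    Q = sig_inv - sig_inv @ S @ sig_inv  # dF = tr(Q dSigma)
    grad = np.zeros(theta.size)
    for i, (s, t) in enumerate(model.paths):
        ti, si = order[t], order[s]
        d = np.outer(B[:, ti], sig[si, :])  # B E_ts Sigma
        grad[i] = float(np.trace(Q @ (d + d.T)))
    k = len(model.paths)
    for v in list(model.exogenous) + list(model.endogenous):
        vi = order[v]
        d = np.outer(B[:, vi], B[:, vi])
        grad[k] = float(np.trace(Q @ d))
        k += 1
    return grad


def _ols_start(model: PathModel, S: np.ndarray) -> np.ndarray:
    """Per-equation least-squares solution computed from the covariance matrix."""
    order = {v: i for i, v in enumerate(model.variables)}
    coefs = np.zeros(len(model.paths))
    psi: dict[str, float] = {v: S[order[v], order[v]] for v in model.exogenous}
    for v in model.endogenous:
        srcs = [order[s] for s in model.parents(v)]
        Sxx = S[np.ix_(srcs, srcs)]
        sxy = S[srcs, order[v]]
        b = np.linalg.solve(Sxx, sxy)
        for s, bi in zip(model.parents(v), b):
            coefs[model.paths.index((s, v))] = bi
        psi[v] = S[order[v], order[v]] - float(sxy @ b)
    return np.concatenate([coefs, [psi[v] for v in list(model.exogenous) + list(model.endogenous)]])


@dataclass
class SemFit:
    """Fitted path model: estimates and everything derived from them."""

    model: PathModel
    moments: MomentSummary
    estimates: pd.Series  # unstandardized, indexed by param_names
    implied_cov: pd.DataFrame
    discrepancy: float
    converged: bool
    iterations: int
    gradient_norm: float
    chi2_multiplier: int  # n-1 (default) or n
    # scaled-space internals reused by standard_errors
    _theta_scaled: np.ndarray = field(repr=False, default=None)
    _S_scaled: np.ndarray = field(repr=False, default=None)
    _back_scale: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.moments.n

    @property
    def chi2(self) -> float:
        return self.chi2_multiplier * self.discrepancy

    def coefficient_matrix(self, standardized: bool = False) -> pd.DataFrame:
        """Direct-effect matrix A with A[target, source] = coefficient."""
        v = self.model.variables
        order = {name: i for i, name in enumerate(v)}
        A, _ = _matrices(self.model, self.estimates.to_numpy(), order)
        if standardized:
            sd = np.sqrt(np.diag(self.implied_cov.to_numpy()))
            A = A * (sd[np.newaxis, :] / sd[:, np.newaxis])
        return pd.DataFrame(A, index=v, columns=v)


def fit_ml(
    model: PathModel,
    moments: MomentSummary,
    *,
    chi2_multiplier: str = "n-1",
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> SemFit:
    """Fit the model to ``moments.cov`` by minimizing the ML discrepancy.

    Variables are internally rescaled to unit sample variance, the optimizer
    starts at the per-equation OLS solution (exact for this model class) and
    polishes with BFGS; convergence requires gradient norm < ``gtol``.
    """
    names = list(moments.variables)
    missing = set(model.variables) - set(names)
    if missing:
        raise ValueError(f"moments lack model variables: {sorted(missing)}")
    S_raw = moments.cov.loc[list(model.variables), list(model.variables)].to_numpy()
    eigmin = np.linalg.eigvalsh(S_raw).min()
    if eigmin <= 0:
        raise ValueError(f"sample covariance is not positive definite (min eig {eigmin:.3g})")
    if moments.n <= model.n_free:
        raise ValueError(f"n = {moments.n} must exceed the {model.n_free} free parameters")
    mult = {"n-1": moments.n - 1, "n": moments.n}[chi2_multiplier]

    sd = np.sqrt(np.diag(S_raw))
    Sz = S_raw / np.outer(sd, sd)
    ld_Sz = float(np.linalg.slogdet(Sz)[1])

    theta0 = _ols_start(model, Sz)
    res = optimize.minimize(
        lambda th: _f_ml(model, Sz, ld_Sz, th),
        theta0,
        jac=lambda th: _f_grad(model, Sz, th),
        method="BFGS",
        options={"gtol": gtol, "maxiter": max_iter},
    )
    theta_z = res.x
    gnorm = float(np.linalg.norm(_f_grad(model, Sz, theta_z)))
    converged = bool(gnorm < max(gtol, 1e-8) or res.success)
    if not converged:
        import warnings

        warnings.warn(
            f"ML fit did not converge: gradient norm {gnorm:.3g} after {res.nit} iterations",
            stacklevel=2,
        )

    # back-transform: b = b_z * sd_t / sd_s ; variance = psi_z * sd_v^2
    order = {v: i for i, v in enumerate(model.variables)}
    back = np.array(
        [sd[order[t]] / sd[order[s]] for s, t in model.paths]
        + [sd[order[v]] ** 2 for v in list(model.exogenous) + list(model.endogenous)]
    )
    theta = theta_z * back
    sig = implied_sigma(model, theta)
    return SemFit(
        model=model,
        moments=moments,
        estimates=pd.Series(theta, index=list(model.param_names)),
        implied_cov=pd.DataFrame(sig, index=model.variables, columns=model.variables),
        discrepancy=float(max(res.fun, 0.0)),
        converged=converged,
        iterations=int(res.nit),
        gradient_norm=gnorm,
        chi2_multiplier=mult,
        _theta_scaled=theta_z,
        _S_scaled=Sz,
        _back_scale=back,
    )


def _hessian(f, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = x.size
    H = np.zeros((k, k))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = steps[i]
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return H


def standard_errors(fit: SemFit) -> pd.DataFrame:
    """Asymptotic SEs, critical ratios and two-sided normal p-values.

    The parameter covariance is the inverse information matrix of
    (multiplier/2) * F_ML, with the Hessian taken numerically at the optimum in
    the unit-variance parameterization and mapped back through the (diagonal,
    linear) rescaling.
    """
    if not fit.converged:
        raise ValueError("standard errors require a converged fit")
    model, Sz = fit.model, fit._S_scaled
    ld_Sz = float(np.linalg.slogdet(Sz)[1])
    H = _hessian(lambda th: _f_ml(model, Sz, ld_Sz, th), fit._theta_scaled)
    info = (fit.chi2_multiplier / 2.0) * H
    try:
        acov_z = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        eigvals = np.linalg.eigvalsh(info)
        idx = int(np.argmin(np.abs(eigvals)))
        raise ValueError(
            f"singular information matrix; near-unidentified direction involves "
            f"parameter {model.param_names[idx]!r}"
        ) from exc
    acov = acov_z * np.outer(fit._back_scale, fit._back_scale)
    se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    b = fit.estimates.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cr = np.where(se > 0, b / se, np.nan)
    return pd.DataFrame(
        {
            "estimate": b,
            "se": se,
            "critical_ratio": cr,
            "p_value": 2.0 * stats.norm.sf(np.abs(cr)),
        },
        index=list(model.param_names),
    )


def standardize(fit: SemFit) -> pd.Series:
    """Standardized path coefficients beta = b * SD(source)/SD(target).

    SDs are model-implied; for variance parameters the standardized value is
    the share of implied variance (residual/implied), matching the usual
    standardized-solution convention.
    """
    sd = np.sqrt(np.diag(fit.implied_cov.to_numpy()))
    if np.any(sd == 0):
        zero = [v for v, s in zip(fit.model.variables, sd) if s == 0]
        raise ValueError(f"zero implied variance for {zero}")
    order = {v: i for i, v in enumerate(fit.model.variables)}
    out = {}
    for i, (s, t) in enumerate(fit.model.paths):
        out[f"{s} -> {t}"] = fit.estimates.iloc[i] * sd[order[s]] / sd[order[t]]
    k = len(fit.model.paths)
    for v in list(fit.model.exogenous) + list(fit.model.endogenous):
        name = fit.model.param_names[k]
        out[name] = fit.estimates.iloc[k] / sd[order[v]] ** 2
        k += 1
    return pd.Series(out)


# ---------------------------------------------------------------------------
# Fit indices


@dataclass(frozen=True)
class FitIndexSet:
    chi2: float
    df: int
    p_value: float
    rmr: float
    srmr: float
    gfi: float
    agfi: float
    nfi: float
    rfi: float
    ifi: float
    cfi: float
    pnfi: float
    pcfi: float
    rmsea: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "chi2", "df", "p_value", "rmr", "srmr", "gfi", "agfi", "nfi",
            "rfi", "ifi", "cfi", "pnfi", "pcfi", "rmsea")}


def fit_indices(fit: SemFit) -> FitIndexSet:
    """Chi-square test and the descriptive fit-index suite.

    The incremental indices use the independence baseline (zero covariances,
    free variances), whose ML discrepancy has the closed form -ln|R| with R
    the sample correlation matrix.  With df = 0 the RMSEA and RFI are
    undefined and reported as NaN.
    """
    model = fit.model
    p = model.p
    S = fit.moments.cov.loc[list(model.variables), list(model.variables)].to_numpy()
    sig = fit.implied_cov.to_numpy()
    mult = fit.chi2_multiplier
    df = model.df
    chi2 = fit.chi2
    p_value = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan

    iu = np.triu_indices(p)
    rmr = float(np.sqrt(np.mean((S - sig)[iu] ** 2)))
    ds = np.sqrt(np.diag(S))
    dsig = np.sqrt(np.diag(sig))
    res_corr = S / np.outer(ds, ds) - sig / np.outer(dsig, dsig)
    srmr = float(np.sqrt(np.mean(res_corr[iu] ** 2)))

    W = np.linalg.inv(sig) @ S
    gfi = float(1.0 - np.trace((W - np.eye(p)) @ (W - np.eye(p))) / np.trace(W @ W))
    agfi = float(1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)) if df > 0 else np.nan

    R = S / np.outer(ds, ds)
    chi2_b = mult * float(-np.linalg.slogdet(R)[1])
    df_b = p * (p - 1) // 2
    nfi = (chi2_b - chi2) / chi2_b
    rfi = 1.0 - (chi2 / df) / (chi2_b / df_b) if df > 0 else np.nan
    ifi = (chi2_b - chi2) / (chi2_b - df)
    cfi = 1.0 - max(chi2 - df, 0.0) / max(chi2_b - df_b, chi2 - df, 0.0)
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * mult))) if df > 0 else np.nan
    pnfi = (df / df_b) * nfi
    pcfi = (df / df_b) * cfi
    return FitIndexSet(chi2=float(chi2), df=int(df), p_value=p_value, rmr=rmr, srmr=srmr,
                       gfi=gfi, agfi=agfi, nfi=float(nfi), rfi=float(rfi), ifi=float(ifi),
                       cfi=float(cfi), pnfi=float(pnfi), pcfi=float(pcfi), rmsea=rmsea)


# ---------------------------------------------------------------------------
# Effect decomposition


def decompose_effects(fit: SemFit) -> pd.DataFrame:
    """Direct, indirect and total effects on the b and beta scales.

    The total-effect matrix is (I - A)^-1 - I (the sum of coefficient products
    over every directed route); indirect = total - direct, so additivity holds
    exactly on both scales.  One row per (source, target) ordered pair with an
    endogenous target and source != target.
    """
    v = list(fit.model.variables)
    p = len(v)
    rows = []
    mats = {}
    for scale in ("b", "beta"):
        A = fit.coefficient_matrix(standardized=(scale == "beta")).to_numpy()
        total = np.linalg.inv(np.eye(p) - A) - np.eye(p)
        mats[scale] = (A, total)
    for t in fit.model.endogenous:
        ti = v.index(t)
        for s in v:
            if s == t:
                continue
            si = v.index(s)
            row = {"source": s, "target": t}
            for scale in ("b", "beta"):
                A, total = mats[scale]
                direct = A[ti, si]
                indirect = total[ti, si] - direct
                row[f"direct_{scale}"] = direct
                row[f"indirect_{scale}"] = indirect
                # recompose so total == direct + indirect holds bit-exactly
                row[f"total_{scale}"] = direct + indirect
            rows.append(row)
    return pd.DataFrame(rows)
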