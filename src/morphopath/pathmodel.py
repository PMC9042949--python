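"""Layered Bayesian path model linking age, BMI, facial measurements and the
two perceived outcomes.

Model structure (all variables standardised within samples):

* age is exogenous;
* BMI is a univariate normal regression on age;
* the mediator block (CIELab channels or the colour factor, fWHR, SShD,
  DIST, optionally the two shape-trait scores) is one multivariate normal
  regression on age and BMI with a full residual correlation matrix;
* perceived sex-typicality and perceived dominance form a bivariate normal
  regression on age, BMI and every mediator, with a residual correlation —
  the outcome-outcome association is deliberately non-directed.

Priors: Normal(0, 0.2) intercepts, Normal(0, 0.5) slopes, Exponential(1)
residual standard deviations, LKJ(eta=2) on both residual correlation
matrices (density used unnormalised; constants cancel in MCMC).

Sampling is blocked Gibbs with Metropolis steps: the regression coefficient
blocks have exact multivariate-normal full conditionals (conjugate given the
residual covariance), while sds and correlation entries are updated by
componentwise adaptive random-walk Metropolis (log scale for sds; proposals
violating positive definiteness are rejected). Adaptation runs during
warm-up only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky

__all__ = [
    "OUTCOMES",
    "PathModelSpec",
    "ParameterManifest",
    "PosteriorDraws",
    "build_model",
    "standardize",
    "inverse_standardize",
    "log_density",
    "fit",
    "summarize",
]

OUTCOMES = ("perceived_sextypicality", "perceived_dominance")

_CHANNEL_MEDIATORS = ["L", "a", "b", "fwhr", "sshd", "dist"]
_FACTOR_MEDIATORS = ["colour", "fwhr", "sshd", "dist"]
_SHAPE_TRAITS = {"shape_dominance_only": ["shape_dominance"],
                 "shape_sextypicality_only": ["shape_sextypicality"],
                 "extended": ["shape_dominance", "shape_sextypicality"]}
VARIANTS = ("default", "extended", "shape_dominance_only",
            "shape_sextypicality_only")


@dataclass
class PathModelSpec:
    """Model variant, colour handling, priors and sampling defaults."""

    variant: str = "default"
    colour_mode: str = "channels"
    prior_intercept_sd: float = 0.2
    prior_slope_sd: float = 0.5
    lkj_eta: float = 2.0
    sd_rate: float = 1.0
    n_draws: int = 10_000

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected one of {VARIANTS}")
        if self.colour_mode not in ("channels", "factor"):
            raise ValueError(f"unknown colour_mode {self.colour_mode!r}")
        for name in ("prior_intercept_sd", "prior_slope_sd", "lkj_eta",
                     "sd_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def mediators(self) -> list[str]:
        base = (_CHANNEL_MEDIATORS if self.colour_mode == "channels"
                else _FACTOR_MEDIATORS)
        return base + _SHAPE_TRAITS.get(self.variant, [])


@dataclass
class ParameterManifest:
    """Enumeration of every sampled parameter of a model variant.

    The BMI residual sd is sampled like the others but kept in its own
    category (``aux_sd_names``) so the counted categories match the
    published parameter accounting exactly.
    """

    spec: PathModelSpec
    mediators: list[str]
    outcomes: tuple[str, str] = OUTCOMES
    intercept_names: list[str] = field(default_factory=list)
    slope_names: list[str] = field(default_factory=list)
    aux_sd_names: list[str] = field(default_factory=list)
    mediator_sd_names: list[str] = field(default_factory=list)
    mediator_corr_entries: list[str] = field(default_factory=list)
    outcome_sd_names: list[str] = field(default_factory=list)
    outcome_corr_entries: list[str] = field(default_factory=list)

    @property
    def names(self) -> list[str]:
        return (self.intercept_names + self.slope_names + self.aux_sd_names
                + self.mediator_sd_names + self.mediator_corr_entries
                + self.outcome_sd_names + self.outcome_corr_entries)

    @property
    def n_parameters(self) -> int:
        return len(self.names)

    @property
    def n_mediators(self) -> int:
        return len(self.mediators)

    def counts(self) -> dict[str, int]:
        return {
            "intercepts": len(self.intercept_names),
            "slopes": len(self.slope_names),
            "mediator_variances": len(self.mediator_sd_names),
            "mediator_covariances": len(self.mediator_corr_entries),
            "outcome_variances": len(self.outcome_sd_names),
            "outcome_covariances": len(self.outcome_corr_entries),
        }

    def index(self, name: str) -> int:
        return self.names.index(name)

    # --- slices into the flat parameter vector -------------------------
    def _offsets(self):
        n_i = len(self.intercept_names)
        n_s = len(self.slope_names)
        m = self.n_mediators
        n_c = len(self.mediator_corr_entries)
        o = {}
        pos = 0
        for key, size in (
            ("intercepts", n_i), ("slopes", n_s), ("aux_sd", 1),
            ("mediator_sds", m), ("mediator_corrs", n_c),
            ("outcome_sds", 2), ("outcome_corr", 1),
        ):
            o[key] = slice(pos, pos + size)
            pos += size
        return o


def build_model(spec: PathModelSpec) -> ParameterManifest:
    """Enumerate every sampled parameter implied by a model spec.

    Intercepts: every variable except age. Slopes: age->BMI, (age,BMI)->each
    mediator, and (age, BMI, each mediator)->each outcome. Residual
    structure: one sd per mediator plus all pairwise mediator correlations;
    two outcome sds plus one outcome correlation.
    """
    med = spec.mediators
    out = list(OUTCOMES)
    manifest = ParameterManifest(spec=spec, mediators=med)
    manifest.intercept_names = [f"intercept[{v}]" for v in ["bmi"] + med + out]
    slopes = ["slope[age->bmi]"]
    for v in med:
        slopes += [f"slope[age->{v}]", f"slope[bmi->{v}]"]
    for o in out:
        slopes += [f"slope[age->{o}]", f"slope[bmi->{o}]"]
        slopes += [f"slope[{v}->{o}]" for v in med]
    manifest.slope_names = slopes
    manifest.aux_sd_names = ["sd[bmi]"]
    manifest.mediator_sd_names = [f"sd[{v}]" for v in med]
    manifest.mediator_corr_entries = [
        f"corr[{med[i]},{med[j]}]"
        for i in range(len(med)) for j in range(i + 1, len(med))
    ]
    manifest.outcome_sd_names = [f"sd[{o}]" for o in out]
    manifest.outcome_corr_entries = [f"corr[{out[0]},{out[1]}]"]
    duplicates = len(manifest.names) != len(set(manifest.names))
    if duplicates:  # pragma: no cover - structural guard
        raise RuntimeError("duplicate parameter names in manifest")
    return manifest


# ---------------------------------------------------------------------------
# standardisation

def standardize(table: pd.DataFrame, variables: list[str],
                by: list[str] | None = None):
    """Z-score ``variables`` (optionally within ``by`` groups).

    Returns ``(standardised copy, transform table)`` where the transform
    table records mean and sd per variable (and group) for back-mapping.
    Raises on constant variables, naming them.
    """
    out = table.copy()
    records = []
    if by:
        grouped = out.groupby(by, sort=False)
        for key, idx in grouped.groups.items():
            key_t = key if isinstance(key, tuple) else (key,)
            for v in variables:
                vals = out.loc[idx, v].astype(float)
                mu, sd = float(vals.mean()), float(vals.std(ddof=0))
                if sd == 0 or not np.isfinite(sd):
                    raise ValueError(f"variable {v!r} constant within group {key_t}")
                out.loc[idx, v] = (vals - mu) / sd
                records.append(dict(zip(by, key_t)) | {"variable": v,
                                                       "mean": mu, "sd": sd})
    else:
        for v in variables:
            vals = out[v].astype(float)
            mu, sd = float(vals.mean()), float(vals.std(ddof=0))
            if sd == 0 or not np.isfinite(sd):
                raise ValueError(f"variable {v!r} is constant")
            out[v] = (vals - mu) / sd
            records.append({"variable": v, "mean": mu, "sd": sd})
    return out, pd.DataFrame(records)


def inverse_standardize(table: pd.DataFrame, transform: pd.DataFrame,
                        by: list[str] | None = None) -> pd.DataFrame:
    """Undo :func:`standardize` using its recorded transform table."""
    out = table.copy()
    for _, row in transform.iterrows():
        v = row["variable"]
        if by:
            mask = np.ones(len(out), dtype=bool)
            for b in by:
                mask &= out[b] == row[b]
            out.loc[mask, v] = out.loc[mask, v] * row["sd"] + row["mean"]
        else:
            out[v] = out[v] * row["sd"] + row["mean"]
    return out


# ---------------------------------------------------------------------------
# density

def _corr_from_entries(entries: np.ndarray, dim: int) -> np.ndarray:
    r = np.eye(dim)
    idx = 0
    for i in range(dim):
        for j in range(i + 1, dim):
            r[i, j] = r[j, i] = entries[idx]
            idx += 1
    return r


def _entries_from_corr(r: np.ndarray) -> np.ndarray:
    dim = r.shape[0]
    return np.array([r[i, j] for i in range(dim) for j in range(i + 1, dim)])


class _Blocks:
    """Design matrices and cross-products for the three likelihood blocks."""

    def __init__(self, manifest: ParameterManifest, data: pd.DataFrame | None):
        med, out = manifest.mediators, list(manifest.outcomes)
        self.m = len(med)
        if data is None or len(data) == 0:
            self.n = 0
            p_o = 3 + self.m
            self.Xb = np.zeros((0, 2)); self.yb = np.zeros(0)
            self.Xm = np.zeros((0, 3)); self.Ym = np.zeros((0, self.m))
            self.Xo = np.zeros((0, p_o)); self.Yo = np.zeros((0, 2))
        else:
            cols = ["age", "bmi"] + med + out
            missing = [c for c in cols if c not in data.columns]
            if missing:
                raise ValueError(f"data is missing columns: {missing}")
            df = data[cols].astype(float)
            if df.isna().any().any():
                n0 = len(df)
                df = df.dropna()
                warnings.warn(f"dropped {n0 - len(df)} rows with missing values",
                              stacklevel=3)
            self.n = len(df)
            age = df["age"].to_numpy()
            bmi_v = df["bmi"].to_numpy()
            ones = np.ones(self.n)
            self.Xb = np.column_stack([ones, age]); self.yb = bmi_v
            self.Xm = np.column_stack([ones, age, bmi_v])
            self.Ym = df[med].to_numpy()
            self.Xo = np.column_stack([ones, age, bmi_v, self.Ym])
            self.Yo = df[out].to_numpy()
        for tag in ("b", "m", "o"):
            x = getattr(self, f"X{tag}")
            y = getattr(self, "yb" if tag == "b" else f"Y{tag}")
            y2 = y[:, None] if y.ndim == 1 else y
            setattr(self, f"XtX_{tag}", x.T @ x)
            setattr(self, f"XtY_{tag}", x.T @ y2)
            setattr(self, f"YtY_{tag}", y2.T @ y2)


def _mvn_block_ll(n: int, w: np.ndarray, sigma: np.ndarray,
                  xtx: np.ndarray, xty: np.ndarray, yty: np.ndarray) -> float:
    """Multivariate-normal regression log likelihood from cross-products."""
    q = sigma.shape[0]
    s = yty - w.T @ xty - xty.T @ w + w.T @ xtx @ w
    try:
        c, low = cho_factor(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    tr = np.trace(cho_solve((c, low), s))
    return -0.5 * (n * q * np.log(2 * np.pi) + n * logdet + tr)


def log_density(manifest: ParameterManifest, theta: np.ndarray,
                data: pd.DataFrame | None = None,
                blocks: _Blocks | None = None) -> float:
    """Joint log prior + log likelihood at one parameter point.

    Returns ``-inf`` for non-positive sds, correlations outside (-1, 1) or a
    non-positive-definite mediator correlation matrix. With no data the
    prior-only density is returned (LKJ terms unnormalised).
    """
    spec = manifest.spec
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != manifest.n_parameters:
        raise ValueError(
            f"theta has {theta.shape[0]} entries; manifest expects "
            f"{manifest.n_parameters}")
    o = manifest._offsets()
    intercepts = theta[o["intercepts"]]
    slopes = theta[o["slopes"]]
    sd_b = theta[o["aux_sd"]][0]
    sds_m = theta[o["mediator_sds"]]
    corr_m = theta[o["mediator_corrs"]]
    sds_o = theta[o["outcome_sds"]]
    r_o = theta[o["outcome_corr"]][0]

    all_sds = np.concatenate([[sd_b], sds_m, sds_o])
    if np.any(all_sds <= 0):
        return -np.inf
    if np.any(np.abs(corr_m) >= 1) or abs(r_o) >= 1:
        return -np.inf
    m = manifest.n_mediators
    R_m = _corr_from_entries(corr_m, m)
    try:
        c_m = cholesky(R_m, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_m = 2.0 * np.sum(np.log(np.diag(c_m)))

    lp = 0.0
    s_i = spec.prior_intercept_sd
    s_s = spec.prior_slope_sd
    lp += -0.5 * np.sum((intercepts / s_i) ** 2) \
        - intercepts.size * (np.log(s_i) + 0.5 * np.log(2 * np.pi))
    lp += -0.5 * np.sum((slopes / s_s) ** 2) \
        - slopes.size * (np.log(s_s) + 0.5 * np.log(2 * np.pi))
    lp += np.sum(np.log(spec.sd_rate) - spec.sd_rate * all_sds)
    lp += (spec.lkj_eta - 1.0) * logdet_m
    lp += (spec.lkj_eta - 1.0) * np.log1p(-r_o ** 2)

    if blocks is None:
        blocks = _Blocks(manifest, data)
    if blocks.n == 0:
        return float(lp)

    w_b, w_m, w_o = _unpack_weights(manifest, intercepts, slopes)
    # bmi univariate term
    ll = _mvn_block_ll(blocks.n, w_b[:, None], np.array([[sd_b ** 2]]),
                       blocks.XtX_b, blocks.XtY_b, blocks.YtY_b)
    # mediator multivariate term
    sigma_m = np.outer(sds_m, sds_m) * R_m
    ll += _mvn_block_ll(blocks.n, w_m, sigma_m,
                        blocks.XtX_m, blocks.XtY_m, blocks.YtY_m)
    # outcome bivariate term
    R_o = np.array([[1.0, r_o], [r_o, 1.0]])
    sigma_o = np.outer(sds_o, sds_o) * R_o
    ll += _mvn_block_ll(blocks.n, w_o, sigma_o,
                        blocks.XtX_o, blocks.XtY_o, blocks.YtY_o)
    return float(lp + ll)


def _unpack_weights(manifest, intercepts, slopes):
    """Split flat intercepts/slopes into the three regression weight blocks.

    Returns ``w_b`` (2,), ``w_m`` (3, m), ``w_o`` (3+m, 2); row 0 of each is
    the intercept row.
    """
    m = manifest.n_mediators
    w_b = np.array([intercepts[0], slopes[0]])
    w_m = np.zeros((3, m))
    w_m[0] = intercepts[1:1 + m]
    med_slopes = slopes[1:1 + 2 * m].reshape(m, 2)
    w_m[1] = med_slopes[:, 0]   # age
    w_m[2] = med_slopes[:, 1]   # bmi
    w_o = np.zeros((3 + m, 2))
    w_o[0] = intercepts[1 + m:]
    out_slopes = slopes[1 + 2 * m:].reshape(2, 2 + m)
    for k in range(2):
        w_o[1, k] = out_slopes[k, 0]
        w_o[2, k] = out_slopes[k, 1]
        w_o[3:, k] = out_slopes[k, 2:]
    return w_b, w_m, w_o


def _pack_weights(manifest, w_b, w_m, w_o):
    m = manifest.n_mediators
    intercepts = np.concatenate([[w_b[0]], w_m[0], w_o[0]])
    slopes = [w_b[1]]
    for j in range(m):
        slopes += [w_m[1, j], w_m[2, j]]
    for k in range(2):
        slopes += [w_o[1, k], w_o[2, k], *w_o[3:, k]]
    return intercepts, np.array(slopes)


# ---------------------------------------------------------------------------
# sampler

@dataclass
class PosteriorDraws:
    """Post-warm-up joint posterior draws plus convergence diagnostics."""

    draws: np.ndarray          # (chains, draws_per_chain, n_parameters)
    parameter_names: list[str]
    seed: int
    rhat: np.ndarray
    ess: np.ndarray
    converged: bool
    manifest: ParameterManifest | None = None

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.flat.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flat, columns=self.parameter_names)

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.parameter_names,
                             "rhat": self.rhat, "ess": self.ess})


def _draw_weight_block(rng, xtx, xty, sigma_inv, prior_prec_rows):
    """Exact conjugate draw of a (p x q) regression weight block.

    Posterior precision = Sigma^-1 (x) XtX + diag(prior precisions);
    posterior mean solves it against vec(XtY Sigma^-1). Column-stacking vec
    convention throughout.
    """
    p, q = xty.shape[0], sigma_inv.shape[0]
    prec = np.kron(sigma_inv, xtx)
    prior_prec = np.tile(prior_prec_rows, q)
    prec[np.diag_indices_from(prec)] += prior_prec
    b = (xty @ sigma_inv).reshape(-1, order="F")
    c = cholesky(prec, lower=True)
    mean = cho_solve((c, True), b)
    z = rng.standard_normal(p * q)
    w_vec = mean + np.linalg.solve(c.T, z)
    return w_vec.reshape(p, q, order="F")


class _CovBlockSampler:
    """Componentwise adaptive MH for one residual covariance block.

    Maintains the inverse and log-determinant of the current correlation
    matrix so that sd updates are closed-form in the cached quantities and
    correlation updates cost one small Cholesky + inverse per proposal.
    """

    def __init__(self, dim, eta, rate, fixed_sds=None, fixed_corrs=None):
        self.dim = dim
        self.eta = eta
        self.rate = rate
        self.n_corr = dim * (dim - 1) // 2
        self.log_sds = np.zeros(dim)
        self.corr = np.eye(dim)
        self.steps = np.full(dim + self.n_corr, 0.3)
        self.fixed_sds = dict(fixed_sds or {})
        self.fixed_corrs = dict(fixed_corrs or {})
        for k, v in self.fixed_sds.items():
            self.log_sds[k] = np.log(v)
        for (i, j), v in self.fixed_corrs.items():
            self.corr[i, j] = self.corr[j, i] = v
        self._inv = np.linalg.inv(self.corr)
        self._logdet = float(np.linalg.slogdet(self.corr)[1])

    def _sd_target(self, log_sds, b, n):
        """Log target in the sds for fixed R; ``b = R^-1 * S`` elementwise."""
        sds = np.exp(log_sds)
        val = np.sum(-self.rate * sds + log_sds)
        if n > 0:
            u = 1.0 / sds
            val += -n * np.sum(log_sds) - 0.5 * (u @ b @ u)
        return val

    def _corr_target(self, inv, logdet, n, s):
        val = (self.eta - 1.0) * logdet
        if n > 0:
            t = s / np.outer(self.sds, self.sds)
            val += -0.5 * n * logdet - 0.5 * np.sum(inv * t)
        return val

    def sweep(self, rng, n, s, adapt, t_adapt, n_sweeps=2):
        gamma = min(0.25, 2.0 / np.sqrt(t_adapt + 10.0)) if adapt else 0.0
        for _ in range(n_sweeps):
            b = self._inv * s
            current = self._sd_target(self.log_sds, b, n)
            for k in range(self.dim):
                if k in self.fixed_sds:
                    continue
                prop = self.log_sds.copy()
                prop[k] += self.steps[k] * rng.standard_normal()
                cand = self._sd_target(prop, b, n)
                acc = min(1.0, np.exp(min(cand - current, 0.0)))
                if rng.random() < acc:
                    self.log_sds = prop
                    current = cand
                if adapt:
                    self.steps[k] *= np.exp(gamma * (acc - 0.44))
            idx = self.dim
            current = self._corr_target(self._inv, self._logdet, n, s)
            for i in range(self.dim):
                for j in range(i + 1, self.dim):
                    if (i, j) in self.fixed_corrs:
                        idx += 1
                        continue
                    val = self.corr[i, j] \
                        + self.steps[idx] * rng.standard_normal()
                    acc = 0.0
                    if abs(val) < 1.0:
                        prop_r = self.corr.copy()
                        prop_r[i, j] = prop_r[j, i] = val
                        try:
                            chol_p = np.linalg.cholesky(prop_r)
                        except np.linalg.LinAlgError:
                            chol_p = None
                        if chol_p is not None:
                            logdet_p = 2.0 * np.sum(np.log(np.diag(chol_p)))
                            inv_p = np.linalg.inv(prop_r)
                            cand = self._corr_target(inv_p, logdet_p, n, s)
                            acc = min(1.0, np.exp(min(cand - current, 0.0)))
                            if rng.random() < acc:
                                self.corr = prop_r
                                self._inv = inv_p
                                self._logdet = logdet_p
                                current = cand
                    if adapt:
                        self.steps[idx] *= np.exp(gamma * (acc - 0.44))
                    idx += 1

    @property
    def sds(self):
        return np.exp(self.log_sds)

    @property
    def sigma_inv(self):
        u = 1.0 / self.sds
        return self._inv * np.outer(u, u)


def _residual_cross(w, xtx, xty, yty):
    return yty - w.T @ xty - xty.T @ w + w.T @ xtx @ w


def fit(manifest: ParameterManifest, data: pd.DataFrame | None = None,
        seed: int = 0, n_draws: int | None = None, warmup: int | None = None,
        chains: int = 4, mh_sweeps: int = 2,
        fixed: dict[str, float] | None = None) -> PosteriorDraws:
    """Sample the joint posterior (or, with no data, the prior).

    ``n_draws`` is the total retained across ``chains`` (default from the
    model spec, 10 000); warm-up defaults to half the per-chain draws and is
    discarded. Convergence requires split-R-hat <= 1.01 and bulk ESS >= 400
    for every parameter; failing that the draws are still returned with
    ``converged=False`` and a warning. ``fixed`` pins named sd/correlation
    parameters at given values (useful for conditional analyses and exact
    conjugate cross-checks); fixed parameters are excluded from the
    convergence verdict.
    """
    spec = manifest.spec
    if n_draws is None:
        n_draws = spec.n_draws
    draws_per_chain = int(np.ceil(n_draws / chains))
    if warmup is None:
        warmup = draws_per_chain // 2
    blocks = _Blocks(manifest, data)
    m = manifest.n_mediators
    n = blocks.n

    prior_prec_b = np.array([1 / spec.prior_intercept_sd ** 2,
                             1 / spec.prior_slope_sd ** 2])
    prior_prec_m = np.array([1 / spec.prior_intercept_sd ** 2]
                            + [1 / spec.prior_slope_sd ** 2] * 2)
    prior_prec_o = np.array([1 / spec.prior_intercept_sd ** 2]
                            + [1 / spec.prior_slope_sd ** 2] * (2 + m))

    fixed = dict(fixed or {})
    unknown = set(fixed) - set(manifest.aux_sd_names
                               + manifest.mediator_sd_names
                               + manifest.mediator_corr_entries
                               + manifest.outcome_sd_names
                               + manifest.outcome_corr_entries)
    if unknown:
        raise ValueError(f"only sd/corr parameters can be fixed; got {unknown}")
    med, out = manifest.mediators, list(manifest.outcomes)
    fixed_med_sds = {med.index(nm[3:-1]): v for nm, v in fixed.items()
                     if nm in manifest.mediator_sd_names}
    fixed_out_sds = {out.index(nm[3:-1]): v for nm, v in fixed.items()
                     if nm in manifest.outcome_sd_names}
    pair_index = {}
    idx = 0
    for i in range(m):
        for j in range(i + 1, m):
            pair_index[manifest.mediator_corr_entries[idx]] = (i, j)
            idx += 1
    fixed_med_corrs = {pair_index[nm]: v for nm, v in fixed.items()
                       if nm in manifest.mediator_corr_entries}
    fixed_out_corrs = ({(0, 1): fixed[manifest.outcome_corr_entries[0]]}
                       if manifest.outcome_corr_entries[0] in fixed else {})
    sd_b_fixed = fixed.get("sd[bmi]")

    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    all_draws = np.empty((chains, draws_per_chain, manifest.n_parameters))

    for c_idx in range(chains):
        rng = np.random.default_rng(chain_seeds[c_idx])
        med_cov = _CovBlockSampler(m, spec.lkj_eta, spec.sd_rate,
                                   fixed_med_sds, fixed_med_corrs)
        out_cov = _CovBlockSampler(2, spec.lkj_eta, spec.sd_rate,
                                   fixed_out_sds, fixed_out_corrs)
        log_sd_b = 0.0 if sd_b_fixed is None else float(np.log(sd_b_fixed))
        step_b = 0.3
        w_b = np.zeros(2)
        w_m = np.zeros((3, m))
        w_o = np.zeros((3 + m, 2))

        for it in range(warmup + draws_per_chain):
            adapt = it < warmup
            # --- conjugate weight draws -------------------------------
            sd_b = np.exp(log_sd_b)
            w_b = _draw_weight_block(
                rng, blocks.XtX_b, blocks.XtY_b,
                np.array([[1.0 / sd_b ** 2]]), prior_prec_b)[:, 0]
            w_m = _draw_weight_block(
                rng, blocks.XtX_m, blocks.XtY_m,
                med_cov.sigma_inv, prior_prec_m)
            w_o = _draw_weight_block(
                rng, blocks.XtX_o, blocks.XtY_o,
                out_cov.sigma_inv, prior_prec_o)
            # --- covariance MH ----------------------------------------
            s_b = _residual_cross(w_b[:, None], blocks.XtX_b,
                                  blocks.XtY_b, blocks.YtY_b).item()
            gamma = min(0.25, 2.0 / np.sqrt(it + 10.0)) if adapt else 0.0
            for _ in range(mh_sweeps if sd_b_fixed is None else 0):
                prop = log_sd_b + step_b * rng.standard_normal()

                def _sd_b_target(ls):
                    sd = np.exp(ls)
                    val = -spec.sd_rate * sd + ls
                    if n > 0:
                        val += -n * ls - 0.5 * s_b / sd ** 2
                    return val

                cand, cur = _sd_b_target(prop), _sd_b_target(log_sd_b)
                acc = min(1.0, np.exp(min(cand - cur, 0.0)))
                if rng.random() < acc:
                    log_sd_b = prop
                if adapt:
                    step_b *= np.exp(gamma * (acc - 0.44))
            s_m = _residual_cross(w_m, blocks.XtX_m, blocks.XtY_m,
                                  blocks.YtY_m)
            s_o = _residual_cross(w_o, blocks.XtX_o, blocks.XtY_o,
                                  blocks.YtY_o)
            med_cov.sweep(rng, n, s_m, adapt, it, n_sweeps=mh_sweeps)
            out_cov.sweep(rng, n, s_o, adapt, it, n_sweeps=mh_sweeps)

            if it >= warmup:
                intercepts, slopes = _pack_weights(manifest, w_b, w_m, w_o)
                theta = np.concatenate([
                    intercepts, slopes, [np.exp(log_sd_b)],
                    med_cov.sds, _entries_from_corr(med_cov.corr),
                    out_cov.sds, [out_cov.corr[0, 1]],
                ])
                all_draws[c_idx, it - warmup] = theta

    rhat, ess = _diagnostics(all_draws)
    free = np.array([nm not in fixed for nm in manifest.names])
    converged = bool(np.all(rhat[free] <= 1.01) and np.all(ess[free] >= 400))
    if not converged:
        warnings.warn(
            f"fit may not have converged: max R-hat={np.nanmax(rhat):.3f}, "
            f"min ESS={np.nanmin(ess):.0f}", stacklevel=2)
    return PosteriorDraws(
        draws=all_draws, parameter_names=manifest.names, seed=seed,
        rhat=rhat, ess=ess, converged=converged, manifest=manifest,
    )


def _diagnostics(draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split-R-hat and bulk ESS per parameter via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(draws)
        rhat = np.asarray(az.rhat(ds)["x"].values, dtype=float)
        ess = np.asarray(az.ess(ds)["x"].values, dtype=float)
    return rhat, ess


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean and central 95% interval per parameter.

    The outcome residual dependence is the correlation parameter itself
    (variables are standardised), reported under its ``corr[...]`` name.
    """
    flat = draws.flat
    if flat.size == 0:
        raise ValueError("no draws to summarise")
    lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "parameter": draws.parameter_names,
        "mean": flat.mean(axis=0),
        "lower95": lo,
        "upper95": hi,
    }).set_index("parameter")


def format_estimate(mean: float, lo: float, hi: float) -> str:
    """Render one estimate in the reporting style ``0.42 (CI: 0.16, 0.64)``."""
    return f"{mean:.2f} (CI: {lo:.2f}, {hi:.2f})"
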