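"""Choice-model estimation for two-alternative panel data.

Implements the random-utility family used throughout the package:

* conditional logit (homogeneous coefficients),
* panel mixed logit with independent normal mixing, estimated by
  maximum simulated likelihood over Halton draws,
* latent-class logit (finite mixture of conditional logits) fitted by
  EM with seeded restarts,
* individual-level conditional (posterior) coefficients,
* AIC/BIC/CAIC model selection over the class count.

Utility is U = beta'x + eps with i.i.d. type-I extreme-value errors, so
the per-choice-set probability is multinomial logit and a respondent's
sequence probability is the product over their choice sets. The mixed
logit likelihood integrates that product over the mixing distribution;
the latent-class likelihood sums it over classes weighted by shares.
All computation is done in the log domain, so tiny sequence
probabilities underflow gracefully instead of needing an explicit floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp
from scipy.stats import norm, qmc

from .coding import ASC_COLUMN, ResponseDataset

__all__ = [
    "ModelSpec",
    "PanelArrays",
    "ClogitEstimate",
    "MixedLogitEstimate",
    "IndividualCoefficients",
    "LatentClassEstimate",
    "logit_prob",
    "sequence_prob",
    "clogit_fit",
    "halton_normal_draws",
    "msl_loglik",
    "mxl_fit",
    "conditional_coefficients",
    "share_sign",
    "lcm_loglik",
    "lcm_fit",
    "posterior_class_probs",
    "information_criteria",
    "choose_class_count",
    "select_n_classes",
]


# ---------------------------------------------------------------------------
# panel tensorisation

@dataclass
class PanelArrays:
    """Dense (respondent, choice set, alternative) view of a dataset.

    Respondents answer different numbers of sets (blocks of 5 or 6), so
    the time axis is padded to the longest sequence and masked.
    """

    X: np.ndarray        # (N, T_max, 2, P)
    chosen: np.ndarray   # (N, T_max) int, index of chosen alternative
    mask: np.ndarray     # (N, T_max) bool
    respondents: np.ndarray
    columns: list[str]

    @property
    def n_respondents(self) -> int:
        return self.X.shape[0]

    @property
    def n_rows(self) -> int:
        return int(2 * self.mask.sum())

    @property
    def n_choices(self) -> int:
        return int(self.mask.sum())


def panel_arrays(data: ResponseDataset, columns: list[str] | None = None) -> PanelArrays:
    cols = list(columns) if columns is not None else list(data.covariates)
    df = data.df.sort_values(["respondent_id", "set_id", "alternative_index"])
    resp_ids = df["respondent_id"].unique()
    n = len(resp_ids)
    t_counts = df.groupby("respondent_id", sort=False)["set_id"].nunique()
    t_max = int(t_counts.max())
    X = np.zeros((n, t_max, 2, len(cols)))
    chosen = np.zeros((n, t_max), dtype=int)
    mask = np.zeros((n, t_max), dtype=bool)
    xmat = df[cols].to_numpy(dtype=float)
    ch = df["chosen"].to_numpy(dtype=int)
    pos = 0
    resp_index = {r: i for i, r in enumerate(resp_ids)}
    for (resp, _sid), g_len in df.groupby(["respondent_id", "set_id"], sort=False).size().items():
        if g_len != 2:
            raise ValueError(
                f"respondent {resp}: choice set with {g_len} alternatives (expected 2)"
            )
        i = resp_index[resp]
        t = int(mask[i].sum())
        X[i, t] = xmat[pos : pos + 2]
        c = ch[pos : pos + 2]
        if c.sum() != 1:
            raise ValueError(f"respondent {resp}: set without exactly one chosen row")
        chosen[i, t] = int(np.argmax(c))
        mask[i, t] = True
        pos += 2
    return PanelArrays(X=X, chosen=chosen, mask=mask, respondents=resp_ids, columns=cols)


# ---------------------------------------------------------------------------
# choice probabilities

def logit_prob(beta: np.ndarray, X_rows: np.ndarray) -> np.ndarray:
    """Multinomial logit probabilities over the J rows of a choice set.

    Shift-invariant: adding a constant to every alternative's utility
    leaves the probabilities unchanged (the maximum utility is subtracted
    before exponentiation, so large utilities cannot overflow).
    """
    u = np.asarray(X_rows, dtype=float) @ np.asarray(beta, dtype=float)
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def sequence_prob(beta: np.ndarray, respondent_df: pd.DataFrame, covariates: list[str]) -> float:
    """Probability of one respondent's observed choice sequence: the
    product over their choice sets of the chosen alternative's logit
    probability."""
    p = 1.0
    for _, g in respondent_df.groupby("set_id"):
        g = g.sort_values("alternative_index")
        probs = logit_prob(beta, g[covariates].to_numpy(dtype=float))
        p *= float(probs[np.argmax(g["chosen"].to_numpy())])
    return p


def _log_seq(pan: PanelArrays, beta: np.ndarray) -> np.ndarray:
    """Log sequence probability per respondent and mixture point.

    ``beta`` has shape (N, M, P) (M draws or classes); returns (N, M).
    """
    U = np.einsum("ntjp,nmp->nmtj", pan.X, beta)
    Umax = U.max(axis=-1, keepdims=True)
    lse = Umax[..., 0] + np.log(np.exp(U - Umax).sum(axis=-1))
    Uch = np.take_along_axis(
        U, pan.chosen[:, None, :, None], axis=-1
    )[..., 0]
    logp = (Uch - lse) * pan.mask[:, None, :]
    return logp.sum(axis=-1)


def _seq_scores(pan: PanelArrays, beta: np.ndarray) -> np.ndarray:
    """d log S / d beta per respondent and mixture point: (N, M, P)."""
    U = np.einsum("ntjp,nmp->nmtj", pan.X, beta)
    U = U - U.max(axis=-1, keepdims=True)
    e = np.exp(U)
    P = e / e.sum(axis=-1, keepdims=True)
    onehot = np.zeros_like(P)
    np.put_along_axis(onehot, pan.chosen[:, None, :, None], 1.0, axis=-1)
    resid = (onehot - P) * pan.mask[:, None, :, None]
    return np.einsum("nmtj,ntjp->nmp", resid, pan.X)


# ---------------------------------------------------------------------------
# conditional logit

@dataclass
class ClogitEstimate:
    params: pd.Series
    se: pd.Series
    tstat: pd.Series
    loglik: float
    loglik_null: float
    converged: bool
    message: str
    n_rows: int
    n_respondents: int

    @property
    def k(self) -> int:
        return len(self.params)


def _column_scales(pan: PanelArrays) -> np.ndarray:
    """Max-abs scale per column (euro-valued money columns are orders of
    magnitude larger than the effects codes; fitting in scaled space
    keeps the optimiser well conditioned). Exact reparameterisation."""
    s = np.abs(pan.X[pan.mask]).max(axis=(0, 1))
    s[s == 0] = 1.0
    return s


def _clogit_negll_grad(beta, pan):
    b = beta[None, None, :]
    b = np.broadcast_to(b, (pan.X.shape[0], 1, beta.shape[0]))
    ll = _log_seq(pan, b).sum()
    g = _seq_scores(pan, b)[:, 0, :].sum(axis=0)
    return -ll, -g


def _clogit_hessian(beta, pan):
    """Observed information of the conditional logit (analytic)."""
    b = np.broadcast_to(beta[None, None, :], (pan.X.shape[0], 1, len(beta)))
    U = np.einsum("ntjp,nmp->nmtj", pan.X, b)[:, 0]
    U = U - U.max(axis=-1, keepdims=True)
    e = np.exp(U)
    P = e / e.sum(axis=-1, keepdims=True)  # (N, T, J)
    xbar = np.einsum("ntj,ntjp->ntp", P, pan.X)
    dev = pan.X - xbar[:, :, None, :]
    W = P * pan.mask[:, :, None]
    H = np.einsum("ntj,ntjp,ntjq->pq", W, dev, dev)
    return H  # = -d2LL/dbeta2


def clogit_fit(
    data: ResponseDataset | PanelArrays, columns: list[str] | None = None,
) -> ClogitEstimate:
    """Maximum-likelihood conditional logit with a single shared beta.

    Standard errors come from the inverse of the analytic observed
    information at the optimum; a singular information matrix (perfect
    separation / non-identification) is reported as non-convergence
    rather than returning silent garbage.
    """
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, columns)
    s = _column_scales(pan)
    pan_s = PanelArrays(
        X=pan.X / s, chosen=pan.chosen, mask=pan.mask,
        respondents=pan.respondents, columns=pan.columns,
    )
    fun = lambda b: _clogit_negll_grad(b, pan_s)
    beta0 = np.zeros(len(pan.columns))
    res = optimize.minimize(fun, beta0, jac=True, method="trust-ncg",
                            hess=lambda b: _clogit_hessian(b, pan_s),
                            options={"gtol": 1e-7, "maxiter": 500})
    if not res.success:  # fall back on quasi-Newton from the Newton iterate
        res2 = optimize.minimize(fun, res.x, jac=True, method="BFGS",
                                 options={"gtol": 1e-5, "maxiter": 500})
        if res2.fun <= res.fun:
            res = res2
    beta_s = res.x
    H = _clogit_hessian(beta_s, pan_s)
    converged = bool(res.success)
    message = res.message
    try:
        cov = np.linalg.inv(H)
        se_s = np.sqrt(np.clip(np.diag(cov), 0, None))
        if not np.isfinite(se_s).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se_s = np.full(len(beta_s), np.nan)
        converged = False
        message = "information matrix singular (separation or non-identification)"
    params = pd.Series(beta_s / s, index=pan.columns)
    se = pd.Series(se_s / s, index=pan.columns)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = params / se
    ll_null = -float(pan.mask.sum()) * np.log(2.0)
    return ClogitEstimate(
        params=params, se=se, tstat=tstat, loglik=-float(res.fun),
        loglik_null=ll_null, converged=converged, message=str(message),
        n_rows=pan.n_rows, n_respondents=pan.n_respondents,
    )


# ---------------------------------------------------------------------------
# mixed logit (maximum simulated likelihood)

@dataclass(frozen=True)
class ModelSpec:
    """Coefficient menu for the mixed logit.

    Every column of the dataset gets a mean; columns in ``random`` also
    get a normal standard deviation. The alternative-specific constant
    is always fixed. The MN1 preset makes everything random except the
    constant and the money coefficient; MN2 fixes only the constant.
    """

    columns: tuple[str, ...]
    random: tuple[str, ...]
    n_draws: int = 500
    seed: int = 0
    halton_drop: int = 10

    def __post_init__(self) -> None:
        unknown = [c for c in self.random if c not in self.columns]
        if unknown:
            raise ValueError(f"random coefficients not in columns: {unknown}")
        if ASC_COLUMN in self.random:
            raise ValueError("the alternative-specific constant is always fixed")

    @classmethod
    def mn1(cls, columns, money: str = "remuneration", **kw) -> "ModelSpec":
        rnd = tuple(c for c in columns if c not in (ASC_COLUMN, money))
        return cls(columns=tuple(columns), random=rnd, **kw)

    @classmethod
    def mn2(cls, columns, **kw) -> "ModelSpec":
        rnd = tuple(c for c in columns if c != ASC_COLUMN)
        return cls(columns=tuple(columns), random=rnd, **kw)

    @property
    def n_random(self) -> int:
        return len(self.random)

    @property
    def k(self) -> int:
        """Free parameters: one mean per column plus one SD per random
        coefficient (20 for MN1 and 21 for MN2 on the bundled
        11-column coding)."""
        return len(self.columns) + len(self.random)

    def random_indices(self) -> np.ndarray:
        return np.array([self.columns.index(c) for c in self.random], dtype=int)


def halton_normal_draws(
    n_respondents: int, n_draws: int, n_dims: int, seed: int, drop: int = 10
) -> np.ndarray:
    """Scrambled-Halton standard-normal draws, shape (N, R, Q).

    One Halton dimension per random coefficient, the first ``drop``
    points discarded, consecutive blocks of R points per respondent.
    Bit-identical for a given (seed, shape) request.
    """
    if n_dims == 0:
        return np.zeros((n_respondents, n_draws, 0))
    eng = qmc.Halton(d=n_dims, scramble=True, seed=seed)
    if drop:
        eng.fast_forward(drop)
    u = eng.random(n_respondents * n_draws)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = norm.ppf(u)
    return z.reshape(n_respondents, n_draws, n_dims)


def _mxl_beta(means, sds, draws, rand_idx):
    n, r, _ = draws.shape
    beta = np.broadcast_to(means[None, None, :], (n, r, len(means))).copy()
    beta[:, :, rand_idx] += sds[None, None, :] * draws
    return beta


def _msl_parts(means, sds, pan, draws, rand_idx):
    beta = _mxl_beta(means, sds, draws, rand_idx)
    logS = _log_seq(pan, beta)  # (N, R)
    R = draws.shape[1]
    ll_n = logsumexp(logS, axis=1) - np.log(R)
    return beta, logS, ll_n


def msl_loglik(
    means: np.ndarray,
    sds: np.ndarray,
    pan: PanelArrays,
    draws: np.ndarray,
    rand_idx: np.ndarray,
    return_scores: bool = False,
):
    """Simulated log likelihood sum_n ln[(1/R) sum_r S_n(beta_r)].

    With all SDs zero every draw collapses onto the mean, so the value
    equals the conditional-logit log likelihood for any draw count.
    Deterministic given the draw array. Optionally returns the
    per-respondent score vectors (d ll_n / d(means, sds)) used for the
    gradient and the BHHH covariance.
    """
    beta, logS, ll_n = _msl_parts(means, sds, pan, draws, rand_idx)
    ll = float(ll_n.sum())
    if not return_scores:
        return ll
    w = np.exp(logS - logsumexp(logS, axis=1, keepdims=True))  # (N, R)
    g = _seq_scores(pan, beta)  # (N, R, P)
    score_means = np.einsum("nr,nrp->np", w, g)
    score_sds = np.einsum("nr,nrq,nrq->nq", w, g[:, :, rand_idx], draws)
    scores = np.concatenate([score_means, score_sds], axis=1)  # (N, P+Q)
    return ll, scores


@dataclass
class MixedLogitEstimate:
    means: pd.Series
    sds: pd.Series                # random coefficients only, reported as |SD|
    se_means: pd.Series
    se_sds: pd.Series
    tstat_means: pd.Series
    tstat_sds: pd.Series
    loglik: float
    spec: ModelSpec
    converged: bool
    message: str
    n_rows: int
    n_respondents: int
    sd_sign_flipped: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return len(self.means) + len(self.sds)

    def summary(self) -> pd.DataFrame:
        rows = []
        for c in self.means.index:
            rows.append({"coefficient": c, "role": "mean", "estimate": self.means[c],
                         "se": self.se_means[c], "t": self.tstat_means[c]})
            if c in self.sds.index:
                rows.append({"coefficient": c, "role": "sd", "estimate": self.sds[c],
                             "se": self.se_sds[c], "t": self.tstat_sds[c]})
        return pd.DataFrame(rows)


def mxl_fit(data: ResponseDataset | PanelArrays, spec: ModelSpec) -> MixedLogitEstimate:
    """Panel mixed logit by maximum simulated likelihood.

    Halton draws are generated once per fit and shared across all
    likelihood evaluations; the optimiser is quasi-Newton (BFGS) on the
    analytic simulated score. SDs are estimated unconstrained and
    reported as absolute values (the simulated likelihood is symmetric
    in each SD's sign); coefficients whose SD estimate came out negative
    are listed in ``sd_sign_flipped``. Standard errors are BHHH (outer
    product of per-respondent scores) at the optimum.
    """
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, list(spec.columns))
    if list(pan.columns) != list(spec.columns):
        pan = PanelArrays(
            X=pan.X[:, :, :, [pan.columns.index(c) for c in spec.columns]],
            chosen=pan.chosen, mask=pan.mask, respondents=pan.respondents,
            columns=list(spec.columns),
        )
    P, Q = len(spec.columns), spec.n_random
    rand_idx = spec.random_indices()
    s = _column_scales(pan)
    pan_s = PanelArrays(X=pan.X / s, chosen=pan.chosen, mask=pan.mask,
                        respondents=pan.respondents, columns=pan.columns)
    draws = halton_normal_draws(pan.n_respondents, spec.n_draws, Q, spec.seed, spec.halton_drop)

    start = clogit_fit(pan_s)
    theta0 = np.concatenate([start.params.to_numpy(), np.full(Q, 0.1)])

    def negll(theta):
        ll, scores = msl_loglik(theta[:P], theta[P:], pan_s, draws, rand_idx, return_scores=True)
        return -ll, -scores.sum(axis=0)

    res = optimize.minimize(negll, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 1000})
    theta = res.x
    _, scores = msl_loglik(theta[:P], theta[P:], pan_s, draws, rand_idx, return_scores=True)
    converged, message = bool(res.success), str(res.message)
    try:
        cov = np.linalg.inv(scores.T @ scores)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        if not np.isfinite(se).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se = np.full(P + Q, np.nan)
        converged, message = False, "BHHH information singular"

    scale_full = np.concatenate([s, s[rand_idx]])
    est = theta / scale_full
    se = se / scale_full
    means = pd.Series(est[:P], index=list(spec.columns))
    se_means = pd.Series(se[:P], index=list(spec.columns))
    raw_sds = pd.Series(est[P:], index=list(spec.random))
    flipped = tuple(raw_sds.index[raw_sds < 0])
    sds = raw_sds.abs()
    se_sds = pd.Series(se[P:], index=list(spec.random))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_means = means / se_means
        t_sds = sds / se_sds
    return MixedLogitEstimate(
        means=means, sds=sds, se_means=se_means, se_sds=se_sds,
        tstat_means=t_means, tstat_sds=t_sds, loglik=-float(res.fun),
        spec=spec, converged=converged, message=message,
        n_rows=pan.n_rows, n_respondents=pan.n_respondents,
        sd_sign_flipped=flipped,
    )


@dataclass
class IndividualCoefficients:
    """Per-respondent conditional (posterior) coefficient means given the
    observed choice sequence, with a simulation-noise estimate."""

    means: pd.DataFrame       # respondents x coefficients
    sim_error: pd.DataFrame   # approximate Monte-Carlo SE of each mean
    flagged: tuple = ()       # respondents whose sequence prob underflowed


def conditional_coefficients(
    est: MixedLogitEstimate, data: ResponseDataset | PanelArrays
) -> IndividualCoefficients:
    """E[beta_n | observed choices] by importance weighting the fit's own
    Halton draws with the respondent's sequence probability:
    sum_r beta_r S_n(beta_r) / sum_r S_n(beta_r). With all SDs zero this
    is the population mean for every respondent."""
    spec = est.spec
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, list(spec.columns))
    rand_idx = spec.random_indices()
    draws = halton_normal_draws(pan.n_respondents, spec.n_draws, spec.n_random,
                                spec.seed, spec.halton_drop)
    means = est.means.to_numpy()
    sds = est.sds.to_numpy()
    beta = _mxl_beta(means, sds, draws, rand_idx)
    logS = _log_seq(pan, beta)
    flagged = tuple(pan.respondents[np.all(~np.isfinite(logS), axis=1)])
    w = np.exp(logS - logsumexp(logS, axis=1, keepdims=True))
    cond = np.einsum("nr,nrp->np", w, beta)
    dev2 = (beta - cond[:, None, :]) ** 2
    var_w = np.einsum("nr,nrp->np", w, dev2)
    ess = 1.0 / np.maximum((w**2).sum(axis=1), 1e-300)
    err = np.sqrt(var_w / ess[:, None])
    idx = pd.Index(pan.respondents, name="respondent_id")
    return IndividualCoefficients(
        means=pd.DataFrame(cond, index=idx, columns=list(spec.columns)),
        sim_error=pd.DataFrame(err, index=idx, columns=list(spec.columns)),
        flagged=flagged,
    )


def share_sign(
    est: MixedLogitEstimate,
    coefficient: str,
    direction: str = "positive",
    individuals: IndividualCoefficients | None = None,
) -> dict[str, float | None]:
    """Share of the population valuing a coefficient with a given sign.

    Returns both estimands: ``population`` is Phi(+-mean/SD) under the
    fitted normal (a step function 0/1 when the coefficient is fixed),
    and ``empirical`` is the fraction of respondents whose conditional
    mean has the requested sign (None unless ``individuals`` is given).
    """
    if coefficient not in est.means.index:
        raise KeyError(coefficient)
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    mean = float(est.means[coefficient])
    sd = float(est.sds.get(coefficient, 0.0))
    if sd == 0.0:
        pop = float(mean > 0.0) if direction == "positive" else float(mean < 0.0)
    else:
        pop = 1.0 - norm.cdf(-mean / sd) if direction == "positive" else norm.cdf(-mean / sd)
        pop = float(pop)
    emp = None
    if individuals is not None:
        vals = individuals.means[coefficient].to_numpy()
        emp = float((vals > 0).mean() if direction == "positive" else (vals < 0).mean())
    return {"population": pop, "empirical": emp}


# ---------------------------------------------------------------------------
# latent class logit

@dataclass
class LatentClassEstimate:
    class_coefs: pd.DataFrame   # classes x coefficients
    shares: np.ndarray
    posterior: pd.DataFrame     # respondents x classes
    loglik: float
    se: pd.DataFrame
    tstat: pd.DataFrame
    ll_trace: np.ndarray
    restart_log: list[dict]
    converged: bool
    n_rows: int
    n_respondents: int

    @property
    def n_classes(self) -> int:
        return len(self.shares)

    @property
    def k(self) -> int:
        """Free parameters: one coefficient vector per class plus C-1
        share parameters (47 for four classes on the bundled coding)."""
        C, P = self.class_coefs.shape
        return C * P + (C - 1)

    def average_shares(self) -> np.ndarray:
        return self.posterior.to_numpy().mean(axis=0)


def lcm_loglik(
    class_coefs: np.ndarray, shares: np.ndarray, pan: PanelArrays
) -> float:
    """Mixture log likelihood sum_n ln sum_c pi_c S_n(beta_c)."""
    shares = np.asarray(shares, dtype=float)
    if np.any(shares <= 0) or abs(shares.sum() - 1.0) > 1e-8:
        raise ValueError("class shares must be positive and sum to 1")
    C = len(shares)
    beta = np.broadcast_to(
        np.asarray(class_coefs)[None, :, :], (pan.X.shape[0], C, np.asarray(class_coefs).shape[1])
    )
    logS = _log_seq(pan, beta)
    return float(logsumexp(np.log(shares)[None, :] + logS, axis=1).sum())


def _em_run(pan, n_classes, beta_init, shares_init, max_iter, tol):
    N, P = pan.X.shape[0], pan.X.shape[3]
    beta = beta_init.copy()
    shares = shares_init.copy()
    trace = []
    empty_class = False
    converged = False
    for it in range(max_iter):
        bfull = np.broadcast_to(beta[None, :, :], (N, n_classes, P))
        logS = _log_seq(pan, bfull)
        logj = np.log(shares)[None, :] + logS
        ll = float(logsumexp(logj, axis=1).sum())
        trace.append(ll)
        if it > 0 and trace[-1] - trace[-2] < tol:
            converged = True
            break
        h = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
        shares = h.mean(axis=0)
        if shares.min() < 1e-4:
            empty_class = True
        shares = np.clip(shares, 1e-8, None)
        shares /= shares.sum()
        for c in range(n_classes):
            fit = _weighted_clogit(pan, h[:, c], beta[c])
            beta[c] = fit
    return beta, shares, np.array(trace), converged, empty_class


def _weighted_clogit(pan, w, beta0):
    def fun(b):
        bb = np.broadcast_to(b[None, None, :], (pan.X.shape[0], 1, len(b)))
        ll = float(w @ _log_seq(pan, bb)[:, 0])
        g = (w[:, None] * _seq_scores(pan, bb)[:, 0, :]).sum(axis=0)
        return -ll, -g

    res = optimize.minimize(fun, beta0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 200})
    return res.x


def lcm_fit(
    data: ResponseDataset | PanelArrays,
    n_classes: int,
    seed: int = 0,
    n_restarts: int = 50,
    max_iter: int = 2000,
    tol: float = 1e-7,
    columns: list[str] | None = None,
) -> LatentClassEstimate:
    """Latent-class logit by EM with seeded random restarts.

    Each M step fully maximises the weighted conditional-logit objective
    per class, so the likelihood trace is monotone non-decreasing. The
    best restart is kept and classes are canonically ordered by
    descending share. t statistics come from the BHHH covariance of the
    full-mixture per-respondent score (class coefficients plus C-1
    multinomial share parameters).
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, columns)
    s = _column_scales(pan)
    pan_s = PanelArrays(X=pan.X / s, chosen=pan.chosen, mask=pan.mask,
                        respondents=pan.respondents, columns=pan.columns)
    N, P = pan.X.shape[0], pan.X.shape[3]
    base = clogit_fit(pan_s).params.to_numpy()
    rng = np.random.default_rng(seed)
    best = None
    restart_log = []
    for r in range(max(1, n_restarts)):
        if n_classes == 1:
            beta0 = base[None, :].copy()
            shares0 = np.array([1.0])
        else:
            beta0 = base[None, :] + rng.normal(scale=1.0, size=(n_classes, P))
            shares0 = rng.dirichlet(np.full(n_classes, 5.0))
        beta, shares, trace, conv, empty = _em_run(
            pan_s, n_classes, beta0, shares0, max_iter, tol
        )
        restart_log.append({
            "restart": r, "loglik": float(trace[-1]), "n_iter": len(trace),
            "converged": conv, "empty_class": empty,
            "monotone": bool(np.all(np.diff(trace) >= -1e-8)),
        })
        if best is None or trace[-1] > best[2][-1]:
            best = (beta, shares, trace, conv)
        if n_classes == 1:
            break
    beta, shares, trace, conv = best
    order = np.argsort(-shares)
    beta, shares = beta[order], shares[order]
    bfull = np.broadcast_to(beta[None, :, :], (N, n_classes, P))
    logS = _log_seq(pan_s, bfull)
    logj = np.log(shares)[None, :] + logS
    h = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
    # BHHH scores: class coefficients, then C-1 share logits.
    g = _seq_scores(pan_s, bfull)  # (N, C, P)
    score_beta = h[:, :, None] * g
    scores = [score_beta.reshape(N, n_classes * P)]
    if n_classes > 1:
        scores.append(h[:, :-1] - shares[None, :-1])
    S = np.concatenate(scores, axis=1)
    try:
        cov = np.linalg.inv(S.T @ S)
        se_flat = np.sqrt(np.clip(np.diag(cov)[: n_classes * P], 0, None))
        se_ok = np.isfinite(se_flat).all()
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(S.T @ S)
        se_flat = np.sqrt(np.clip(np.diag(cov)[: n_classes * P], 0, None))
        se_ok = False
    se = se_flat.reshape(n_classes, P) / s[None, :]
    coefs = beta / s[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coefs / se
    class_index = pd.RangeIndex(1, n_classes + 1, name="class")
    resp_index = pd.Index(pan.respondents, name="respondent_id")
    return LatentClassEstimate(
        class_coefs=pd.DataFrame(coefs, index=class_index, columns=pan.columns),
        shares=shares,
        posterior=pd.DataFrame(h, index=resp_index, columns=class_index),
        loglik=float(trace[-1]),
        se=pd.DataFrame(se, index=class_index, columns=pan.columns),
        tstat=pd.DataFrame(tstat, index=class_index, columns=pan.columns),
        ll_trace=trace,
        restart_log=restart_log,
        converged=bool(conv) and se_ok,
        n_rows=pan.n_rows,
        n_respondents=pan.n_respondents,
    )


def posterior_class_probs(
    est: LatentClassEstimate, data: ResponseDataset | PanelArrays
) -> tuple[pd.DataFrame, np.ndarray]:
    """Posterior membership matrix (rows sum to one) and average shares
    (column means), recomputed from the estimate on the given data."""
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, list(est.class_coefs.columns))
    C = est.n_classes
    beta = est.class_coefs.to_numpy()
    bfull = np.broadcast_to(beta[None, :, :], (pan.X.shape[0], C, beta.shape[1]))
    logS = _log_seq(pan, bfull)
    logj = np.log(est.shares)[None, :] + logS
    h = np.exp(logj - logsumexp(logj, axis=1, keepdims=True))
    post = pd.DataFrame(h, index=pd.Index(pan.respondents, name="respondent_id"),
                        columns=est.class_coefs.index)
    return post, h.mean(axis=0)


# ---------------------------------------------------------------------------
# information criteria and class-count selection

def information_criteria(loglik: float, k: int, n_obs: int) -> dict[str, float]:
    """AIC = 2k - 2LL; BIC = k ln N - 2LL; CAIC = k (ln N + 1) - 2LL.

    ``n_obs`` follows whichever sample-size convention the caller wants
    (alternative rows or respondents); both are in common use.
    """
    if k < 0 or n_obs < 1:
        raise ValueError("k must be >= 0 and n_obs >= 1")
    return {
        "AIC": 2.0 * k - 2.0 * loglik,
        "BIC": k * np.log(n_obs) - 2.0 * loglik,
        "CAIC": k * (np.log(n_obs) + 1.0) - 2.0 * loglik,
    }


def choose_class_count(counts, values) -> int:
    """Arg-min of an information criterion over class counts; ties go to
    the smaller count."""
    best_c, best_v = None, None
    for c, v in sorted(zip(counts, values)):
        if best_v is None or v < best_v:
            best_c, best_v = c, v
    return int(best_c)


def select_n_classes(
    data: ResponseDataset | PanelArrays,
    class_range,
    seed: int = 0,
    n_restarts: int = 10,
    criterion: str = "BIC",
    n_convention: str = "respondents",
    columns: list[str] | None = None,
    **lcm_kwargs,
):
    """Fit the latent-class model over a range of class counts and pick
    the count minimising the requested criterion (default BIC, with the
    respondent count as BIC/CAIC sample size)."""
    class_range = list(class_range)
    if not class_range:
        raise ValueError("class_range is empty")
    pan = data if isinstance(data, PanelArrays) else panel_arrays(data, columns)
    n_obs = pan.n_respondents if n_convention == "respondents" else pan.n_rows
    rows, fits = [], {}
    for i, c in enumerate(class_range):
        fit = lcm_fit(pan, c, seed=seed + i, n_restarts=n_restarts, **lcm_kwargs)
        ic = information_criteria(fit.loglik, fit.k, n_obs)
        rows.append({"n_classes": c, "loglik": fit.loglik, "k": fit.k,
                     "converged": fit.converged, **ic})
        fits[c] = fit
    table = pd.DataFrame(rows)
    chosen = choose_class_count(table["n_classes"], table[criterion.upper()])
    return table, chosen, fits
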