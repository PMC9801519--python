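"""Exact Bayesian model averaging for linear regression.

The linear model for one candidate subset M of the s covariates is

    y = alpha + X_M beta_M + eps,   eps ~ N(0, sigma^2 I),

with alpha always included. Priors: flat on alpha and log sigma, and a
Zellner g prior beta_M | sigma^2 ~ N(0, g sigma^2 (X_M' X_M)^{-1}) on the
included block. On mean-centered data this conjugate structure gives a
closed-form marginal likelihood for every model:

    log P(y | M) = const(n, y)
                   + (n-1-k)/2 * log(1+g)
                   - (n-1)/2   * log(1 + g (1 - R^2_M)),

where k = |M| and R^2_M is the in-model coefficient of determination
(R^2 of the empty model is 0). Posterior model probabilities follow from
Bayes' theorem under a uniform model prior, and every reported quantity
(inclusion probabilities, model-averaged coefficient means and spreads,
sign-robustness rates, the model-size distribution) is a posterior-
probability-weighted average over the enumerated model space.

All probability arithmetic is done in log space with log-sum-exp.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import gammaln, logsumexp
from scipy.stats import t as student_t

from .data import StudyTable, validate_and_center
from .errors import ModelSpaceError, SingularModelError, DataValidationError
from .priors import PriorSettings

__all__ = [
    "ModelIndex",
    "ModelFit",
    "BMAResult",
    "ENUMERATION_CAP",
    "enumerate_models",
    "fit_model",
    "fit_all_models",
    "posterior_model_probs",
    "average",
    "classify_evidence",
    "model_size_distribution",
    "run_bma",
    "DEFAULT_THRESHOLDS",
    "EVIDENCE_GRADES",
]

#: Largest covariate count for which the full 2^s space is enumerated.
ENUMERATION_CAP = 25

#: Posterior-inclusion-probability cut points separating the evidence bands.
DEFAULT_THRESHOLDS = (0.5, 0.75, 0.95)

#: Band labels, ordered by increasing evidence.
EVIDENCE_GRADES = ("none", "weak", "positive", "strong")


@dataclass(frozen=True, order=True)
class ModelIndex:
    """One point in the 2^s model space: the set of included covariates.

    The intercept is not part of the index; it belongs to every model.
    The empty tuple is the null (intercept-only) model.
    """

    included: tuple[int, ...]

    def __post_init__(self) -> None:
        inc = tuple(int(j) for j in self.included)
        if any(j < 0 for j in inc):
            raise ModelSpaceError(f"negative covariate index in {inc}")
        if len(set(inc)) != len(inc):
            raise ModelSpaceError(f"duplicate covariate index in {inc}")
        object.__setattr__(self, "included", tuple(sorted(inc)))

    @property
    def size(self) -> int:
        return len(self.included)

    def __contains__(self, j: int) -> bool:
        return j in self.included

    def bits(self, s: int) -> tuple[int, ...]:
        """Inclusion indicator vector of length s."""
        mask = set(self.included)
        return tuple(1 if j in mask else 0 for j in range(s))


def enumerate_models(s: int, cap: int = ENUMERATION_CAP) -> list[ModelIndex]:
    """All 2^s covariate subsets, ordered by size then lexicographically.

    The first element is always the null model, the last the full model.
    Beyond ``cap`` covariates the space is too large to enumerate and
    only the MC3 sampler applies.
    """
    if s < 1:
        raise ModelSpaceError(f"need at least one candidate covariate, got s={s}")
    if s > cap:
        raise ModelSpaceError(
            f"s={s} exceeds the enumeration cap ({cap}); use the MC3 sampler"
        )
    models = []
    for k in range(s + 1):
        for combo in itertools.combinations(range(s), k):
            models.append(ModelIndex(combo))
    return models


@dataclass(frozen=True)
class ModelFit:
    """Closed-form conditional inference for one model.

    ``coef_mean``/``coef_var`` are the marginal posterior mean and
    variance of each *included* coefficient (a Student t with n-1
    degrees of freedom); arrays are empty for the null model.
    ``log_marginal`` includes all constants, so it is directly
    comparable with numerical integration of likelihood x prior.
    """

    model: ModelIndex
    log_marginal: float
    coef_mean: np.ndarray
    coef_var: np.ndarray
    r_squared: float
    resid_df: int
    n: int
    g: float

    @property
    def t_df(self) -> int:
        """Degrees of freedom of the marginal coefficient posterior."""
        return self.n - 1


class _Gram:
    """Precomputed cross-products shared by all model fits on one table."""

    def __init__(self, table: StudyTable):
        x = table.covariates
        y = table.outcome
        self.xtx = x.T @ x
        self.xty = x.T @ y
        self.tss = float(y @ y)
        self.n = table.n
        self.s = table.s


def _fit_from_gram(gram: _Gram, model: ModelIndex, g: float) -> ModelFit:
    n = gram.n
    k = model.size
    if gram.tss <= 0.0:
        raise DataValidationError("outcome has zero variance after centering")
    if k > 0 and max(model.included) >= gram.s:
        raise ModelSpaceError(
            f"model {model.included} references a covariate outside 0..{gram.s - 1}"
        )
    if k == 0:
        r2 = 0.0
        beta_hat = np.empty(0)
        v_diag = np.empty(0)
    else:
        idx = list(model.included)
        xtx = gram.xtx[np.ix_(idx, idx)]
        xty = gram.xty[idx]
        if k > 1 and np.linalg.cond(xtx) > 1.0 / np.finfo(float).eps:
            raise SingularModelError(
                f"collinear covariates in model {model.included}"
            )
        try:
            cho = sla.cho_factor(xtx)
            beta_hat = sla.cho_solve(cho, xty)
            v_diag = np.diag(sla.cho_solve(cho, np.eye(k)))
        except sla.LinAlgError as exc:
            raise SingularModelError(
                f"collinear covariates in model {model.included}: {exc}"
            ) from exc
        if not np.all(np.isfinite(beta_hat)):
            raise SingularModelError(
                f"collinear covariates in model {model.included}"
            )
        r2 = float(beta_hat @ xty) / gram.tss
        r2 = min(max(r2, 0.0), 1.0)

    delta = g / (1.0 + g)
    # Posterior sum of squares: y'y - delta * SSR = TSS (1 + g(1-R^2)) / (1+g)
    ss = gram.tss * (1.0 + g * (1.0 - r2)) / (1.0 + g)
    log_marginal = (
        gammaln((n - 1) / 2.0)
        - ((n - 1) / 2.0) * math.log(2.0 * math.pi)
        - 0.5 * math.log(n)
        - (k / 2.0) * math.log1p(g)
        - ((n - 1) / 2.0) * math.log(ss / 2.0)
    )
    coef_mean = delta * beta_hat
    # t with nu = n-1 df: variance = scale^2 * nu/(nu-2), scale^2 = delta V_jj SS/(n-1)
    coef_var = delta * v_diag * ss / (n - 3)
    return ModelFit(
        model=model,
        log_marginal=float(log_marginal),
        coef_mean=coef_mean,
        coef_var=coef_var,
        r_squared=r2,
        resid_df=n - 1 - k,
        n=n,
        g=g,
    )


def fit_model(
    centered: StudyTable, model: ModelIndex, prior: PriorSettings
) -> ModelFit:
    """Closed-form conditional posterior and marginal likelihood of one model.

    Expects a centered table (see :func:`bma_vision.data.validate_and_center`).
    """
    gram = _Gram(centered)
    g = prior.resolve_g(gram.n, gram.s)
    return _fit_from_gram(gram, model, g)


def fit_all_models(
    centered: StudyTable, models: list[ModelIndex], prior: PriorSettings
) -> list[ModelFit]:
    """Fit every model in one pass, sharing the table's cross-products."""
    gram = _Gram(centered)
    g = prior.resolve_g(gram.n, gram.s)
    return [_fit_from_gram(gram, m, g) for m in models]


def posterior_model_probs(
    fits: list[ModelFit], prior: PriorSettings | None = None
) -> np.ndarray:
    """Posterior model probabilities under the uniform model prior.

    Normalisation is done with log-sum-exp, so arbitrary spreads of log
    marginal likelihoods (hundreds of nats) neither overflow nor
    underflow.
    """
    if len(fits) == 0:
        raise ModelSpaceError("cannot normalise an empty list of model fits")
    log_ml = np.array([f.log_marginal for f in fits])
    # uniform model prior: equal log-prior cancels in the normalisation
    log_pmp = log_ml - logsumexp(log_ml)
    pmp = np.exp(log_pmp)
    return pmp / pmp.sum()  # remove residual float round-off


def classify_evidence(
    pip: float, thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Evidence grade for one posterior inclusion probability.

    Bands are left-closed: [0, t1) none, [t1, t2) weak, [t2, t3)
    positive, [t3, 1] strong, with default cut points 0.5 / 0.75 / 0.95.
    """
    if not 0.0 <= pip <= 1.0:
        raise ValueError(f"posterior inclusion probability {pip} outside [0, 1]")
    t1, t2, t3 = thresholds
    if pip < t1:
        return EVIDENCE_GRADES[0]
    if pip < t2:
        return EVIDENCE_GRADES[1]
    if pip < t3:
        return EVIDENCE_GRADES[2]
    return EVIDENCE_GRADES[3]


def model_size_distribution(pmp: np.ndarray, models: list[ModelIndex]) -> np.ndarray:
    """Posterior probability of each model size 0..s_max.

    Entry k is the summed posterior probability of all size-k models.
    """
    if len(pmp) != len(models):
        raise ModelSpaceError(
            f"{len(pmp)} probabilities for {len(models)} models"
        )
    sizes = np.array([m.size for m in models])
    return np.bincount(sizes, weights=np.asarray(pmp))


@dataclass(frozen=True)
class BMAResult:
    """Model-averaged posterior summaries: the per-variable report payload.

    For each covariate j:

    * ``pip`` — posterior inclusion probability, the summed posterior
      probability of every model containing j;
    * ``post_mean`` — unconditional model-averaged coefficient mean
      (conditional mean where included, 0 elsewhere);
    * ``post_sd`` — model-averaged posterior standard deviation by the
      law of total variance (within-model variance plus between-model
      dispersion of the conditional means);
    * ``sign_consistency`` — probability, conditional on inclusion, that
      the coefficient's sign agrees with the sign of ``post_mean``
      (defined as 1 for never-included covariates);
    * ``evidence_grade`` — the band label from :func:`classify_evidence`.
    """

    names: tuple[str, ...]
    models: tuple[ModelIndex, ...]
    pmp: np.ndarray
    pip: np.ndarray
    post_mean: np.ndarray
    post_sd: np.ndarray
    sign_consistency: np.ndarray
    evidence_grade: tuple[str, ...]
    size_distribution: np.ndarray
    g: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if abs(self.pmp.sum() - 1.0) > 1e-10:
            raise ValueError("posterior model probabilities do not sum to 1")
        if abs(self.size_distribution.sum() - 1.0) > 1e-10:
            raise ValueError("model-size distribution does not sum to 1")


def average(
    fits: list[ModelFit],
    pmp: np.ndarray,
    names: tuple[str, ...],
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    within_model_variance_only: bool = False,
) -> BMAResult:
    """Average conditional posteriors over the model space.

    ``within_model_variance_only=True`` reproduces the narrower spread
    obtained by averaging only the within-model variances, omitting the
    between-model dispersion of conditional means; the default keeps
    the full law-of-total-variance form, which is the one that satisfies
    the total-variance identity checked in the tests.
    """
    if len(fits) != len(pmp):
        raise ModelSpaceError(f"{len(fits)} fits for {len(pmp)} probabilities")
    pmp = np.asarray(pmp, dtype=float)
    s = len(names)
    pip = np.zeros(s)
    post_mean = np.zeros(s)
    second_moment = np.zeros(s)
    within_var = np.zeros(s)

    # per-model positions of each covariate for coefficient lookups
    for fit, w in zip(fits, pmp):
        for pos, j in enumerate(fit.model.included):
            pip[j] += w
            m = fit.coef_mean[pos]
            v = fit.coef_var[pos]
            post_mean[j] += w * m
            second_moment[j] += w * (v + m * m)
            within_var[j] += w * v

    pip = np.clip(pip, 0.0, 1.0)  # guard accumulation round-off at the ends

    if within_model_variance_only:
        total_var = within_var
    else:
        total_var = second_moment - post_mean**2
    post_sd = np.sqrt(np.maximum(total_var, 0.0))

    # Sign robustness: inclusion-weighted P(sign(beta_j) = sign(post_mean_j))
    # under each model's conditional Student-t posterior.
    sign_consistency = np.ones(s)
    ref_sign = np.where(post_mean >= 0.0, 1.0, -1.0)
    agree = np.zeros(s)
    for fit, w in zip(fits, pmp):
        if w == 0.0 or fit.model.size == 0:
            continue
        nu = fit.t_df
        for pos, j in enumerate(fit.model.included):
            m = fit.coef_mean[pos]
            scale2 = fit.coef_var[pos] * (nu - 2) / nu
            if scale2 <= 0.0:
                p_pos = 1.0 if m > 0 else (0.5 if m == 0 else 0.0)
            else:
                p_pos = float(student_t.sf(-m / math.sqrt(scale2), df=nu))
            agree[j] += w * (p_pos if ref_sign[j] > 0 else 1.0 - p_pos)
    nonzero = pip > 0
    sign_consistency[nonzero] = agree[nonzero] / pip[nonzero]
    sign_consistency = np.clip(sign_consistency, 0.0, 1.0)

    grades = tuple(classify_evidence(float(p), thresholds) for p in pip)
    size_dist = model_size_distribution(pmp, [f.model for f in fits])
    return BMAResult(
        names=tuple(names),
        models=tuple(f.model for f in fits),
        pmp=pmp,
        pip=pip,
        post_mean=post_mean,
        post_sd=post_sd,
        sign_consistency=sign_consistency,
        evidence_grade=grades,
        size_distribution=size_dist,
        g=fits[0].g,
    )


def run_bma(
    table: StudyTable,
    prior: PriorSettings | None = None,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    within_model_variance_only: bool = False,
) -> BMAResult:
    """Full exact pipeline: center, enumerate, fit, normalise, average."""
    prior = prior or PriorSettings()
    centered, _ = validate_and_center(table)
    models = enumerate_models(table.s)
    fits = fit_all_models(centered, models, prior)
    pmp = posterior_model_probs(fits, prior)
    return average(
        fits,
        pmp,
        table.names,
        thresholds=thresholds,
        within_model_variance_only=within_model_variance_only,
    )
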