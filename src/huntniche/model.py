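"""Bayesian categorical (multinomial) logit regression of prey type.

The response has three unordered categories (anomalure, duiker, squirrel);
anomalure is the reference with linear predictor fixed at 0, so for hunt i
with covariate row x_i the probability of category k is

    P(y_i = k) = softmax(0, x_i'β_duiker, x_i'β_squirrel)_k .

Coefficients get independent weakly-informative Student-t priors
(df 3, location 0, scale 2.5 by default). The posterior is sampled with an
affine-invariant ensemble sampler run as several independent ensembles
("chains"), initialised from an overdispersed Laplace approximation around
the posterior mode; convergence is screened with split-Rhat (< 1.01).
Numeric covariates are standardized to mean 0, sd 1 (sample sd) before
fitting, matching how the coefficients are reported.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp, softmax
from scipy.stats import t as student_t
from sklearn.base import BaseEstimator, ClassifierMixin

logger = logging.getLogger(__name__)

__all__ = [
    "BayesianCategoricalLogit",
    "standardize",
    "categorical_log_likelihood",
    "fit_categorical",
    "predict_category_probs",
    "vif",
]

RHAT_THRESHOLD = 1.01
DEFAULT_TERMS = ("group", "n_available_males", "n_available_females",
                 "mean_association", "usage_difference", "sin_date",
                 "cos_date")


def standardize(table, columns=None):
    """Standardize numeric columns to mean 0, sd 1 (n−1 denominator).

    Binary/indicator columns are the caller's business (the group dummy is
    left as 0/1). Returns ``(standardized_table, constants)`` where
    constants maps column -> (mean, sd). A zero-variance column is an
    error naming the column.
    """
    out = table.copy()
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    constants = {}
    for c in columns:
        x = table[c].astype(float)
        mu, sd = x.mean(), x.std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise ValueError(f"zero-variance column cannot be standardized: {c!r}")
        out[c] = (x - mu) / sd
        constants[c] = (float(mu), float(sd))
    return out, constants


def _design_matrix(X, terms):
    """Covariate DataFrame/array -> (n, 1+p) design with leading intercept."""
    if isinstance(X, pd.DataFrame):
        X = X[list(terms)].to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates in design matrix")
    return np.column_stack([np.ones(len(X)), X])


def categorical_log_likelihood(coefficients, covariates, y_index, terms=None):
    """Log likelihood of observed categories under the categorical logit.

    ``coefficients`` is (p+1, K−1) — intercept row first — and ``y_index``
    holds 0 for the reference category, 1..K−1 otherwise.
    """
    if terms is None and isinstance(covariates, pd.DataFrame):
        terms = [c for c in covariates.columns]
    Xd = (_design_matrix(covariates, terms) if terms is not None
          else np.column_stack([np.ones(len(covariates)),
                                np.asarray(covariates, dtype=float)]))
    B = np.asarray(coefficients, dtype=float)
    eta = Xd @ B                                   # (n, K-1)
    eta_full = np.column_stack([np.zeros(len(eta)), eta])
    lse = logsumexp(eta_full, axis=1)
    return float(eta_full[np.arange(len(eta)), y_index].sum() - lse.sum())


def vif(covariate_table):
    """Variance inflation factors, 1/(1−R²) of each predictor on the rest.

    Perfectly collinear predictors report ``inf``.
    """
    X = covariate_table.to_numpy(dtype=float) \
        if isinstance(covariate_table, pd.DataFrame) else np.asarray(covariate_table, float)
    names = (list(covariate_table.columns)
             if isinstance(covariate_table, pd.DataFrame)
             else [f"x{j}" for j in range(X.shape[1])])
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for j in range(p):
        yj = X[:, j]
        if yj.std() == 0:
            raise ValueError(f"zero-variance predictor: {names[j]!r}")
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1 - ss_res / ss_tot
        out[names[j]] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


class BayesianCategoricalLogit(BaseEstimator, ClassifierMixin):
    """Bayesian multinomial logistic regression via ensemble MCMC.

    Parameters
    ----------
    prior_df, prior_scale : Student-t prior on every intercept and slope
        (location 0). df=3, scale=2.5 is the conventional weakly
        informative choice.
    chains, iterations, warmup : MCMC layout. Each chain is an independent
        walker ensemble; exactly ``iterations − warmup`` thinned draws are
        retained per chain, so the posterior holds
        ``chains × (iterations − warmup)`` draws.
    reference : response category with linear predictor fixed at 0
        (default: first category in sorted order).
    reference_group : level of the binary ``group`` column coded 0; only
        used when covariates arrive as a DataFrame with a non-numeric
        ``group`` column.
    standardize_numeric : standardize numeric covariates before fitting
        (the 0/1 group indicator is never standardized).
    n_walkers : walker-ensemble width per chain.
    random_state : seed for MAP scatter and the samplers.

    Attributes
    ----------
    draws_ : (chains, draws_per_chain, K−1, p+1) posterior draws.
    coef_ : (K−1, p+1) posterior means, intercept first.
    se_, ci_ : posterior sd and equal-tailed 95% intervals.
    rhat_ : split-Rhat per parameter; converged_ : all rhat < 1.01.
    classes_, terms_, standardization_constants_.
    """

    def __init__(self, prior_df=3.0, prior_scale=2.5, chains=4,
                 iterations=2000, warmup=1000, reference=None,
                 reference_group=None, standardize_numeric=True,
                 n_walkers=32, random_state=None):
        self.prior_df = prior_df
        self.prior_scale = prior_scale
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.reference = reference
        self.reference_group = reference_group
        self.standardize_numeric = standardize_numeric
        self.n_walkers = n_walkers
        self.random_state = random_state

    # -- internals -------------------------------------------------------

    def _validate(self):
        if self.warmup >= self.iterations:
            raise ValueError("warmup must be < iterations")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for Rhat")
        if self.prior_df <= 0 or self.prior_scale <= 0:
            raise ValueError("prior df and scale must be positive")

    def _prepare(self, X, y):
        y = pd.Series(y).reset_index(drop=True)
        classes = sorted(y.unique())
        if len(classes) < 2:
            raise ValueError("need at least 2 observed categories")
        ref = self.reference if self.reference is not None else classes[0]
        if ref not in classes:
            raise ValueError(f"reference category {ref!r} not observed")
        self.classes_ = [ref] + [c for c in classes if c != ref]
        y_index = y.map({c: k for k, c in enumerate(self.classes_)}).to_numpy()

        if isinstance(X, pd.DataFrame):
            X = X.reset_index(drop=True).copy()
            if "group" in X.columns and not pd.api.types.is_numeric_dtype(X["group"]):
                levels = sorted(X["group"].unique())
                ref_g = (self.reference_group if self.reference_group is not None
                         else levels[0])
                X["group"] = (X["group"] != ref_g).astype(float)
                self.group_levels_ = {0: ref_g,
                                      1: next(g for g in levels if g != ref_g)
                                      if len(levels) > 1 else None}
            terms = list(X.columns)
            num = [c for c in terms if c != "group"]
            if self.standardize_numeric and num:
                X, consts = standardize(X, columns=num)
            else:
                consts = {}
            self.standardization_constants_ = consts
            Xd = _design_matrix(X, terms)
        else:
            Xa = np.asarray(X, dtype=float)
            terms = [f"x{j}" for j in range(Xa.shape[1])]
            self.standardization_constants_ = {}
            Xd = np.column_stack([np.ones(len(Xa)), Xa])
            if not np.all(np.isfinite(Xd)):
                raise ValueError("non-finite covariates")
        self.terms_ = ["intercept"] + terms
        return Xd, y_index

    def _log_posterior_vec(self, theta, Xd, Yhot):
        """Vectorised log posterior for (W, D) walker positions."""
        W = theta.shape[0]
        K1, P = self._k1, Xd.shape[1]
        B = theta.reshape(W, K1, P)
        eta = np.einsum("np,wkp->wnk", Xd, B)
        # log(1 + sum_k exp eta) done stably
        m = np.maximum(eta.max(axis=2), 0.0)
        lse = m + np.log(np.exp(-m) + np.exp(eta - m[:, :, None]).sum(axis=2))
        ll = (eta * Yhot[None, :, :]).sum(axis=(1, 2)) - lse.sum(axis=1)
        # Student-t log prior up to its normalising constant
        df, s = self.prior_df, self.prior_scale
        lp = -0.5 * (df + 1) * np.log1p(theta * theta / (df * s * s)).sum(axis=1)
        return ll + lp

    def _neg_log_post_and_grad(self, theta, Xd, Yhot):
        K1, P = self._k1, Xd.shape[1]
        B = theta.reshape(K1, P)
        eta = Xd @ B.T                            # (n, K1)
        eta_full = np.column_stack([np.zeros(len(eta)), eta])
        lse = logsumexp(eta_full, axis=1)
        probs = np.exp(eta - lse[:, None])        # (n, K1), non-ref probs
        ll = float((eta * Yhot).sum() - lse.sum())
        grad_ll = (Yhot - probs).T @ Xd           # (K1, P)
        df, s = self.prior_df, self.prior_scale
        lp = student_t.logpdf(theta, df, 0.0, s).sum()
        grad_lp = -(df + 1) * theta / (df * s * s + theta * theta)
        return -(ll + lp), -(grad_ll.ravel() + grad_lp)

    def _sample(self, Xd, y_index, seed):
        import emcee

        K1 = self._k1
        n, P = Xd.shape
        D = K1 * P
        Yhot = np.zeros((n, K1))
        obs = y_index > 0
        Yhot[np.arange(n)[obs], y_index[obs] - 1] = 1.0

        # Laplace approximation: posterior mode + curvature for init scatter
        res = optimize.minimize(self._neg_log_post_and_grad, np.zeros(D),
                                args=(Xd, Yhot), jac=True, method="BFGS",
                                options={"maxiter": 500, "gtol": 1e-6})
        mode = res.x
        hess_inv = np.atleast_2d(res.hess_inv)
        sd_approx = np.sqrt(np.clip(np.diag(hess_inv), 1e-4, 25.0))

        ss = np.random.SeedSequence(seed)
        chain_seeds = ss.spawn(self.chains)
        draws_per_chain = self.iterations - self.warmup
        n_walkers = max(self.n_walkers, 2 * D + 2)
        # each chain is an ensemble run for `iterations` steps: the first
        # `warmup` discarded, the remainder thinned so that exactly
        # (iterations - warmup) walker-draws are retained
        kept_steps = int(np.ceil(draws_per_chain / n_walkers))
        thin = max(1, (self.iterations - self.warmup) // kept_steps)
        # differential-evolution moves mix far faster than the default
        # stretch move on this correlated 16-parameter posterior
        moves = [(emcee.moves.DEMove(), 0.8),
                 (emcee.moves.DESnookerMove(), 0.2)]

        log_prob = lambda th: self._log_posterior_vec(th, Xd, Yhot)
        all_chains = []
        for cs in chain_seeds:
            rng = np.random.default_rng(cs)
            p0 = mode + 2.0 * sd_approx * rng.standard_normal((n_walkers, D))
            sampler = emcee.EnsembleSampler(n_walkers, D, log_prob,
                                            vectorize=True, moves=moves)
            sampler.random_state = np.random.RandomState(
                rng.integers(2 ** 31)).get_state()
            state = sampler.run_mcmc(p0, self.warmup, progress=False)
            sampler.reset()
            # thin_by multiplies the internal step count: kept_steps stored
            # from kept_steps * thin further moves
            sampler.run_mcmc(state, kept_steps, thin_by=thin, progress=False)
            chain = sampler.get_chain()            # (kept_steps, W, D)
            flat = chain.reshape(-1, D)[:draws_per_chain]
            all_chains.append(flat)
            self._acceptance_fractions.append(
                float(sampler.acceptance_fraction.mean()))
        return np.stack(all_chains)                # (chains, draws, D)

    # -- sklearn API -----------------------------------------------------

    def fit(self, X, y):
        self._validate()
        Xd, y_index = self._prepare(X, y)
        if len(Xd) < 20:
            raise ValueError("need at least 20 observations to fit")
        self._k1 = len(self.classes_) - 1
        self._acceptance_fractions = []
        seed = self.random_state if self.random_state is not None else 0
        draws = self._sample(Xd, y_index, seed)

        K1, P = self._k1, Xd.shape[1]
        self.draws_ = draws.reshape(self.chains, -1, K1, P)
        flat = draws.reshape(-1, K1 * P)
        self.coef_ = flat.mean(axis=0).reshape(K1, P)
        self.se_ = flat.std(axis=0, ddof=1).reshape(K1, P)
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        self.ci_ = np.stack([lo.reshape(K1, P), hi.reshape(K1, P)], axis=-1)
        self.rhat_ = self._split_rhat(draws)
        self.converged_ = bool(np.all(self.rhat_ < RHAT_THRESHOLD))
        if not self.converged_:
            warnings.warn(
                f"convergence warning: max Rhat = {self.rhat_.max():.4f} "
                f">= {RHAT_THRESHOLD}", RuntimeWarning)
        prior_bound = self.prior_scale * student_t.ppf(
            0.999, self.prior_df) * 4
        if np.any(np.abs(self.coef_) > prior_bound):
            warnings.warn("possible complete separation: a coefficient "
                          "posterior sits in prior-dominated territory",
                          RuntimeWarning)
        self.acceptance_fraction_ = float(np.mean(self._acceptance_fractions))
        self.n_obs_ = len(Xd)
        return self

    @staticmethod
    def _split_rhat(draws):
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            ds = az.convert_to_dataset(draws)
            r = az.rhat(ds)["x"].to_numpy()
        return np.asarray(r).ravel()

    def summary(self):
        """Tidy per-parameter table: category, term, estimate, se, CI, Rhat."""
        rows = []
        rh = self.rhat_.reshape(self._k1, len(self.terms_))
        for k in range(self._k1):
            for j, term in enumerate(self.terms_):
                rows.append({
                    "category": self.classes_[k + 1],
                    "term": term,
                    "estimate": self.coef_[k, j],
                    "se": self.se_[k, j],
                    "ci_low": self.ci_[k, j, 0],
                    "ci_high": self.ci_[k, j, 1],
                    "rhat": rh[k, j],
                })
        return pd.DataFrame(rows)

    def _linear_predictors(self, Xd):
        """(chains*draws, n, K) linear predictors incl. reference zeros."""
        flat = self.draws_.reshape(-1, self._k1, len(self.terms_))
        eta = np.einsum("np,dkp->dnk", Xd, flat)
        zeros = np.zeros(eta.shape[:2] + (1,))
        return np.concatenate([zeros, eta], axis=2)

    def predict_proba(self, X):
        """Posterior-mean category probabilities per row of X (columns in
        ``classes_`` order). Numeric covariates are transformed with the
        stored standardization constants."""
        Xd = self._transform_new(X)
        eta = self._linear_predictors(Xd)
        return softmax(eta, axis=2).mean(axis=0)

    def predict(self, X):
        probs = self.predict_proba(X)
        return np.asarray(self.classes_)[probs.argmax(axis=1)]

    def _transform_new(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.copy()
            if "group" in X.columns and not pd.api.types.is_numeric_dtype(X["group"]):
                ref_g = getattr(self, "group_levels_", {0: None})[0]
                X["group"] = (X["group"] != ref_g).astype(float)
            for c, (mu, sd) in self.standardization_constants_.items():
                X[c] = (X[c].astype(float) - mu) / sd
            Xd = _design_matrix(X, self.terms_[1:])
        else:
            Xa = np.asarray(X, dtype=float)
            Xd = np.column_stack([np.ones(len(Xa)), Xa])
        return Xd

    def predict_group_probs(self, group_value):
        """Posterior category probabilities for a group at covariate means.

        All standardized numerics sit at 0 and the group indicator at
        ``group_value`` (0 = reference group, 1 = other). Returns a
        DataFrame with posterior mean and equal-tailed 95% CI per category;
        every draw's probabilities sum to 1.
        """
        x = np.zeros((1, len(self.terms_)))
        x[0, 0] = 1.0
        if "group" in self.terms_:
            x[0, self.terms_.index("group")] = float(group_value)
        eta = np.einsum("np,dkp->dnk",
                        x, self.draws_.reshape(-1, self._k1, len(self.terms_)))
        eta = np.concatenate([np.zeros(eta.shape[:2] + (1,)), eta], axis=2)
        probs = softmax(eta, axis=2)[:, 0, :]      # (draws, K)
        lo, hi = np.percentile(probs, [2.5, 97.5], axis=0)
        return pd.DataFrame({
            "category": self.classes_,
            "mean": probs.mean(axis=0),
            "ci_low": lo,
            "ci_high": hi,
        })


def fit_categorical(covariates, prey, prior_df=3.0, prior_scale=2.5,
                    chains=4, iterations=2000, warmup=1000, seed=None,
                    reference="anomalure", reference_group="Ekalakala"):
    """Fit the prey-type model; thin wrapper over BayesianCategoricalLogit.

    ``covariates`` is the hunt-covariate table (Table-2 predictors);
    ``prey`` the observed categories. Rows with missing covariates are
    dropped as complete cases with a logged count.
    """
    cov = covariates.copy()
    if isinstance(prey, str):
        prey = cov.pop(prey)
    prey = pd.Series(prey).reset_index(drop=True)
    cov = cov.reset_index(drop=True)
    keep_cols = [c for c in DEFAULT_TERMS if c in cov.columns]
    cov = cov[keep_cols]
    complete = cov.notna().all(axis=1) & prey.notna()
    dropped = int((~complete).sum())
    if dropped:
        logger.warning("dropping %d hunts with missing covariates", dropped)
    model = BayesianCategoricalLogit(
        prior_df=prior_df, prior_scale=prior_scale, chains=chains,
        iterations=iterations, warmup=warmup, reference=reference,
        reference_group=reference_group, random_state=seed,
    ).fit(cov[complete], prey[complete])
    model.n_dropped_ = dropped
    return model


def predict_category_probs(fit, group_value):
    """Posterior predicted probabilities for one group at covariate means."""
    return fit.predict_group_probs(group_value)
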