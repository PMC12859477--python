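"""Per-guide mixture model for calling guide expression in single cells.

For each guide, the UMI counts per cell are modelled as a two-component
mixture: a zero-inflated negative binomial (ZINB) describing ambient /
background capture, and a plain negative binomial (NB) describing cells that
genuinely express the guide. Identifiability is maintained by constraining
the non-inflated NB to have the larger mean. Writing pi for the mixing
weight of the expressing component and w0 for the zero-inflation weight of
the background, the per-cell likelihood is

    P(x) = (1 - pi) * [w0 * 1{x=0} + (1 - w0) * NB(x; mu_lo, r_lo)]
         + pi * NB(x; mu_hi, r_hi),          mu_hi > mu_lo,

with NB in the mean/size parameterisation

    NB(x; mu, r) = Gamma(x+r) / (Gamma(r) x!) * (r/(r+mu))^r * (mu/(r+mu))^x.

Parameters are estimated by maximum likelihood via EM over the three
expanded latent components (point mass at zero, low NB, high NB). A cell is
called as expressing the guide when the posterior probability that its count
arose from the larger-mean NB component strictly exceeds 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma, gammaln, logsumexp

__all__ = [
    "MixtureParams",
    "GuideCall",
    "GuideMixtureModel",
    "GuideMixtureResults",
    "nb_logpmf",
    "zinb_logpmf",
    "mixture_loglik",
    "weighted_nb_mle",
    "fit_mixture",
    "posterior_high",
    "classify_counts",
]

_LOG_R_LO, _LOG_R_HI = -10.0, 10.0  # bisection bracket for log(size)
_R_CAP = float(np.exp(_LOG_R_HI))


def _validate_counts(x) -> np.ndarray:
    x = np.asarray(x)
    if x.size and not np.issubdtype(x.dtype, np.integer):
        xf = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(xf)) or np.any(xf != np.floor(xf)):
            raise ValueError("counts must be nonnegative integers")
        x = xf.astype(np.int64)
    if x.size and x.min() < 0:
        raise ValueError("counts must be nonnegative integers")
    return x.astype(np.int64)


def nb_logpmf(x, mu: float, r: float):
    """Log pmf of the negative binomial in mean/size form.

    log P(x) = lgamma(x+r) - lgamma(r) - lgamma(x+1)
             + r*(log r - log(r+mu)) + x*(log mu - log(r+mu))
    """
    if not (mu > 0 and r > 0):
        raise ValueError(f"mu and r must be positive (got mu={mu}, r={r})")
    x = _validate_counts(x)
    log_rm = np.log(r + mu)
    return (
        gammaln(x + r)
        - gammaln(r)
        - gammaln(x + 1)
        + r * (np.log(r) - log_rm)
        + x * (np.log(mu) - log_rm)
    )


def zinb_logpmf(x, w0: float, mu: float, r: float):
    """Log pmf of the zero-inflated NB: w0 * 1{x=0} + (1-w0) * NB(x; mu, r)."""
    if not 0.0 <= w0 < 1.0:
        raise ValueError(f"w0 must be in [0, 1) (got {w0})")
    x = _validate_counts(x)
    base = nb_logpmf(x, mu, r)
    if w0 == 0.0:
        return base
    out = np.asarray(np.log1p(-w0) + base, dtype=float)
    scalar = out.ndim == 0
    out = np.atleast_1d(out)
    zero = np.atleast_1d(x) == 0
    # log(w0 + (1-w0)*NB(0)) via logaddexp for stability
    out[zero] = np.logaddexp(np.log(w0), out[zero])
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class MixtureParams:
    """Fitted mixture parameters.

    pi     weight of the expressing (non-inflated, larger-mean) NB component
    w0     zero-inflation weight inside the background component
    mu_lo, r_lo   mean and size of the background NB
    mu_hi, r_hi   mean and size of the expressing NB (mu_hi > mu_lo)
    """

    pi: float
    w0: float
    mu_lo: float
    r_lo: float
    mu_hi: float
    r_hi: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError(f"pi must be in (0,1), got {self.pi}")
        if not 0.0 <= self.w0 < 1.0:
            raise ValueError(f"w0 must be in [0,1), got {self.w0}")
        for name in ("mu_lo", "r_lo", "mu_hi", "r_hi"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not self.mu_hi > self.mu_lo:
            raise ValueError(
                f"identifiability requires mu_hi > mu_lo (got {self.mu_hi} <= {self.mu_lo})"
            )


@dataclass(frozen=True)
class GuideCall:
    """Expression call for one (cell, guide) pair.

    ``expressed`` is True iff the posterior probability of the expressing
    component strictly exceeds 0.5 (ties resolve to not expressed). For
    guides fitted with the degenerate fallback, ``posterior`` is None and the
    call is count-threshold based.
    """

    cell_barcode: str
    guide_id: str
    count: int
    posterior: float | None
    expressed: bool


def mixture_loglik(counts, params: MixtureParams) -> float:
    """Total log-likelihood of counts under the mixture, via log-sum-exp."""
    counts = _validate_counts(counts)
    if counts.size == 0:
        raise ValueError("empty counts")
    lo = np.log1p(-params.pi) + zinb_logpmf(counts, params.w0, params.mu_lo, params.r_lo)
    hi = np.log(params.pi) + nb_logpmf(counts, params.mu_hi, params.r_hi)
    return float(np.logaddexp(lo, hi).sum())


def _nb_score_in_r(log_r: float, x: np.ndarray, w: np.ndarray, mu: float) -> float:
    # derivative of the weighted NB log-likelihood in r at fixed mu = weighted mean;
    # the (mu - x)/(r + mu) term vanishes because sum w*(mu - x) = 0
    r = np.exp(log_r)
    return float(np.sum(w * (digamma(x + r) - digamma(r))) + np.sum(w) * (np.log(r) - np.log(r + mu)))


def weighted_nb_mle(counts, weights) -> tuple[float, float]:
    """Weighted ML estimate of (mu, r) for the NB in mean/size form.

    mu is the weighted mean (exact for any r); r solves the weighted score
    equation by bisection on log r over [-10, 10]. Underdispersed samples
    (weighted variance <= weighted mean) get r capped at e^10, i.e. an
    effectively Poisson fit.
    """
    x = _validate_counts(counts).astype(float)
    w = np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match counts in shape")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    W = w.sum()
    if W <= 0:
        raise ValueError("all-zero effective sample")
    mu = float(np.sum(w * x) / W)
    if mu <= 0:
        raise ValueError("weighted mean is zero; NB mean must be positive")
    var = float(np.sum(w * (x - mu) ** 2) / W)
    if var <= mu:
        return mu, _R_CAP
    s_lo = _nb_score_in_r(_LOG_R_LO, x, w, mu)
    s_hi = _nb_score_in_r(_LOG_R_HI, x, w, mu)
    if s_lo > 0 and s_hi < 0:
        log_r = brentq(_nb_score_in_r, _LOG_R_LO, _LOG_R_HI, args=(x, w, mu), xtol=1e-10)
        return mu, float(np.exp(log_r))
    # score one-signed on the bracket: likelihood maximised at an endpoint
    return (mu, _R_CAP) if s_hi >= 0 else (mu, float(np.exp(_LOG_R_LO)))


def posterior_high(params: MixtureParams, x):
    """Posterior probability that count x arose from the larger-mean NB component.

    p = pi*NB(x; mu_hi, r_hi) / [pi*NB(x; mu_hi, r_hi) + (1-pi)*ZINB(x; w0, mu_lo, r_lo)]
    computed in the log domain.
    """
    lo = np.log1p(-params.pi) + zinb_logpmf(x, params.w0, params.mu_lo, params.r_lo)
    hi = np.log(params.pi) + nb_logpmf(x, params.mu_hi, params.r_hi)
    return np.exp(hi - np.logaddexp(lo, hi))


class GuideMixtureModel:
    """ZINB + NB mixture for one guide's per-cell UMI counts.

    Parameters
    ----------
    counts : array-like of nonnegative int
        One UMI count per cell, zeros included (the zero-inflated background
        component exists to absorb them).

    Examples
    --------
    >>> model = GuideMixtureModel(counts)
    >>> res = model.fit(seed=0)
    >>> calls = res.classify(barcodes, "GATA5_PS1")
    """

    def __init__(self, counts):
        counts = _validate_counts(counts)
        if counts.size < 2:
            raise ValueError("need at least 2 observations to fit the mixture")
        self.counts = counts
        # EM iterates over unique values with multiplicities: cost per
        # iteration is O(#distinct counts), not O(#cells)
        self._values, self._mult = np.unique(counts, return_counts=True)

    @property
    def n_cells(self) -> int:
        return int(self.counts.size)

    @property
    def n_positive(self) -> int:
        return int((self.counts > 0).sum())

    # --- EM internals -----------------------------------------------------

    def _component_logpmf(self, th: MixtureParams) -> np.ndarray:
        """3 x n_values log joint of (component, x): point mass at 0, NB_lo, NB_hi."""
        v = self._values
        with np.errstate(divide="ignore"):
            log_zero = np.where(v == 0, 0.0, -np.inf) + np.log((1 - th.pi) * th.w0)
        log_lo = np.log((1 - th.pi) * (1 - th.w0)) + nb_logpmf(v, th.mu_lo, th.r_lo)
        log_hi = np.log(th.pi) + nb_logpmf(v, th.mu_hi, th.r_hi)
        return np.vstack([log_zero, log_lo, log_hi])

    def loglik(self, th: MixtureParams) -> float:
        lj = self._component_logpmf(th)
        return float(np.sum(self._mult * logsumexp(lj, axis=0)))

    def _m_step(self, resp: np.ndarray, th: MixtureParams) -> MixtureParams:
        eps = 1e-10
        w = resp * self._mult  # effective weights per unique value, per component
        totals = w.sum(axis=1)
        n = self._mult.sum()
        pi = float(np.clip(totals[2] / n, eps, 1 - eps))
        bg = totals[0] + totals[1]
        w0 = float(np.clip(totals[0] / bg, 0.0, 1 - eps)) if bg > eps else 0.0
        mu_lo, r_lo, mu_hi, r_hi = th.mu_lo, th.r_lo, th.mu_hi, th.r_hi
        if totals[1] > eps and np.sum(w[1] * self._values) > 0:
            mu_lo, r_lo = weighted_nb_mle(self._values, w[1])
        if totals[2] > eps and np.sum(w[2] * self._values) > 0:
            mu_hi, r_hi = weighted_nb_mle(self._values, w[2])
        if mu_hi <= mu_lo:
            # swap-and-relabel: the relabelled 3-component density is
            # identical, so the log-likelihood is unchanged and EM stays
            # monotone while the constraint holds
            new_pi = (1 - pi) * (1 - w0)
            zero_mass = (1 - pi) * w0
            new_bg = 1 - new_pi
            new_w0 = zero_mass / new_bg if new_bg > eps else 0.0
            pi, w0 = float(np.clip(new_pi, eps, 1 - eps)), float(np.clip(new_w0, 0.0, 1 - eps))
            mu_lo, r_lo, mu_hi, r_hi = mu_hi, r_hi, mu_lo, r_lo
        if mu_hi <= mu_lo:  # identical means: nudge apart to stay feasible
            mu_hi = mu_lo * (1 + 1e-9) + 1e-12
        return MixtureParams(pi=pi, w0=w0, mu_lo=mu_lo, r_lo=r_lo, mu_hi=mu_hi, r_hi=r_hi)

    def _initial_params(self, which: int) -> MixtureParams:
        """Moment-based start i: split the sorted counts at the (0.80 + 0.05*i) quantile."""
        q = 0.80 + 0.05 * which
        x = np.sort(self.counts).astype(float)
        cut = max(1, min(x.size - 1, int(np.floor(q * x.size))))
        lower, upper = x[:cut], x[cut:]

        def moments(part: np.ndarray, fallback_mu: float) -> tuple[float, float]:
            mu = float(part.mean()) if part.size else fallback_mu
            mu = max(mu, 1e-3)
            var = float(part.var()) if part.size > 1 else mu
            if var > mu:
                r = mu**2 / (var - mu)
            else:
                r = _R_CAP
            return mu, float(np.clip(r, np.exp(_LOG_R_LO), _R_CAP))

        mu_lo, r_lo = moments(lower, 0.1)
        mu_hi, r_hi = moments(upper, mu_lo * 10 + 1)
        if mu_hi <= mu_lo:
            mu_hi = mu_lo * 2 + 1.0
        pi = float(np.clip(upper.size / x.size, 1e-4, 0.5))
        frac_zero = float((self.counts == 0).mean())
        nb_lo_zero = float(np.exp(nb_logpmf(0, mu_lo, r_lo)))
        w0 = max(0.1, frac_zero - nb_lo_zero)
        w0 = float(np.clip(w0, 0.0, 1 - 1e-6))
        return MixtureParams(pi=pi, w0=w0, mu_lo=mu_lo, r_lo=r_lo, mu_hi=mu_hi, r_hi=r_hi)

    def _fit_one(self, start: MixtureParams, max_iter: int, tol: float):
        th = start
        trace = []
        converged = False
        for _ in range(max_iter + 1):
            lj = self._component_logpmf(th)
            lse = logsumexp(lj, axis=0)
            ll = float(np.sum(self._mult * lse))
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite likelihood")
            if trace and abs(ll - trace[-1]) < tol:
                trace.append(ll)
                converged = True
                break
            trace.append(ll)
            if len(trace) > max_iter:
                break
            resp = np.exp(lj - lse[None, :])
            th = self._m_step(resp, th)
        th, extra, polished = self._polish(th, trace[-1])
        if extra is not None:
            trace.append(extra)
        return th, trace, converged or polished

    # unconstrained reparameterisation for the quasi-Newton polish:
    # (logit pi, logit w0, log mu_lo, log r_lo, log(mu_hi - mu_lo), log r_hi)
    @staticmethod
    def _pack(th: MixtureParams) -> np.ndarray:
        def logit(p: float) -> float:
            p = min(max(p, 1e-12), 1 - 1e-12)
            return np.log(p / (1 - p))

        return np.array(
            [
                logit(th.pi),
                logit(max(th.w0, 1e-12)),
                np.log(th.mu_lo),
                np.log(th.r_lo),
                np.log(max(th.mu_hi - th.mu_lo, 1e-12)),
                np.log(th.r_hi),
            ]
        )

    @staticmethod
    def _unpack(v: np.ndarray) -> MixtureParams:
        from scipy.special import expit

        mu_lo = float(np.exp(v[2]))
        return MixtureParams(
            pi=float(np.clip(expit(v[0]), 1e-12, 1 - 1e-12)),
            w0=float(np.clip(expit(v[1]), 0.0, 1 - 1e-12)),
            mu_lo=mu_lo,
            r_lo=float(np.exp(v[3])),
            mu_hi=mu_lo + float(np.exp(v[4])),
            r_hi=float(np.exp(v[5])),
        )

    def _polish(self, th: MixtureParams, ll_em: float):
        """Quasi-Newton refinement of the EM solution on the unconstrained scale.

        EM creeps along the near-flat ridge between zero inflation and a
        small-mean, low-size background NB; a few dozen L-BFGS steps finish
        the climb. Accepted only if the likelihood improves, so the overall
        optimisation trace stays non-decreasing.
        """
        from scipy.optimize import minimize

        def nll(v: np.ndarray) -> float:
            try:
                cand = self._unpack(v)
            except (ValueError, OverflowError):
                return np.inf
            ll = self.loglik(cand)
            return -ll if np.isfinite(ll) else np.inf

        bounds = [(-30, 30), (-30, 30), (-25, 15), (_LOG_R_LO, _LOG_R_HI), (-25, 15), (_LOG_R_LO, _LOG_R_HI)]
        try:
            opt = minimize(nll, self._pack(th), method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            return th, None, False
        if np.isfinite(opt.fun) and -opt.fun > ll_em:
            return self._unpack(opt.x), float(-opt.fun), bool(opt.success)
        return th, None, False

    def _background_only_loglik(self) -> float:
        """ML log-likelihood of a single ZINB (no expressing component)."""
        from scipy.optimize import minimize
        from scipy.special import expit

        x = self.counts.astype(float)
        mu0 = max(float(x.mean()), 1e-3)
        var0 = max(float(x.var()), mu0 * 1.001)
        r0 = float(np.clip(mu0**2 / (var0 - mu0), np.exp(_LOG_R_LO), _R_CAP))
        frac_zero = float((x == 0).mean())
        w0_0 = float(np.clip(frac_zero - np.exp(nb_logpmf(0, mu0, r0)), 0.05, 0.95))

        def nll(v: np.ndarray) -> float:
            w0 = float(np.clip(expit(v[0]), 0.0, 1 - 1e-12))
            mu, r = float(np.exp(v[1])), float(np.exp(v[2]))
            ll = float(np.sum(self._mult * zinb_logpmf(self._values, w0, mu, r)))
            return -ll if np.isfinite(ll) else np.inf

        start = np.array([np.log(w0_0 / (1 - w0_0)), np.log(mu0), np.log(r0)])
        opt = minimize(
            nll, start, method="L-BFGS-B",
            bounds=[(-30, 30), (-25, 15), (_LOG_R_LO, _LOG_R_HI)],
        )
        return float(-opt.fun) if np.isfinite(opt.fun) else -np.inf

    # --- public API -------------------------------------------------------

    def fit(
        self,
        max_iter: int = 500,
        tol: float = 1e-6,
        n_init: int = 3,
        seed: int | None = None,
        min_positive: int = 5,
    ) -> "GuideMixtureResults":
        """Fit by EM from ``n_init`` quantile-split starts; return the best by log-likelihood.

        Guides with fewer than ``min_positive`` nonzero counts are not fit.
        Guides whose counts are statistically indistinguishable from pure
        background — the two-component mixture does not beat a single ZINB
        by the BIC margin for its 3 extra parameters — are likewise declared
        unfittable. Both come back with ``status='degenerate_fallback'`` and
        no parameters, and classification falls back to a count threshold.
        """
        if self.n_positive < min_positive:
            return GuideMixtureResults(
                model=self,
                params=None,
                loglik=float("nan"),
                n_iter=0,
                converged=False,
                status="degenerate_fallback",
                seed=seed,
            )
        best = None
        errors = []
        for i in range(n_init):
            try:
                th, trace, conv = self._fit_one(self._initial_params(i), max_iter, tol)
            except (FloatingPointError, ValueError) as exc:
                errors.append(exc)
                continue
            if best is None or trace[-1] > best[1][-1]:
                best = (th, trace, conv)
        if best is None:
            raise RuntimeError(f"all {n_init} initializations failed: {errors[-1]}")
        th, trace, conv = best
        # one-population guard: without an expressing subpopulation the
        # mixture overfits the background; require BIC support for the
        # 3 extra parameters before trusting the two-component MLE
        ll_background = self._background_only_loglik()
        if trace[-1] - ll_background < 1.5 * np.log(self.n_cells):
            return GuideMixtureResults(
                model=self,
                params=None,
                loglik=float("nan"),
                n_iter=len(trace) - 1,
                converged=conv,
                status="degenerate_fallback",
                seed=seed,
            )
        return GuideMixtureResults(
            model=self,
            params=th,
            loglik=trace[-1],
            n_iter=len(trace) - 1,
            converged=conv,
            status="ok",
            seed=seed,
            loglik_trace=tuple(trace),
        )


@dataclass(frozen=True)
class GuideMixtureResults:
    """Results of a per-guide mixture fit (the MLE, diagnostics, and calling)."""

    model: GuideMixtureModel
    params: MixtureParams | None
    loglik: float
    n_iter: int
    converged: bool
    status: str  # 'ok' | 'degenerate_fallback'
    seed: int | None = None
    loglik_trace: tuple = ()

    @property
    def n_cells(self) -> int:
        return self.model.n_cells

    @property
    def n_positive(self) -> int:
        return self.model.n_positive

    def posterior(self, x):
        """Posterior probability of the expressing component at count(s) x."""
        if self.params is None:
            raise ValueError("degenerate fallback fit has no posterior")
        return posterior_high(self.params, x)

    def classify(
        self, barcodes, guide_id: str, counts=None, fallback_min_count: int = 3
    ) -> list[GuideCall]:
        """Per-cell expression calls: expressed iff posterior > 0.5 (strict).

        Degenerate-fallback guides are called by count >= fallback_min_count
        with no posterior reported.
        """
        x = self.model.counts if counts is None else _validate_counts(counts)
        barcodes = list(barcodes)
        if len(barcodes) != x.size:
            raise ValueError("barcodes and counts differ in length")
        if self.status == "degenerate_fallback":
            return [
                GuideCall(bc, guide_id, int(xi), None, bool(xi >= fallback_min_count))
                for bc, xi in zip(barcodes, x)
            ]
        p = np.atleast_1d(self.posterior(x))
        return [
            GuideCall(bc, guide_id, int(xi), float(pi), bool(pi > 0.5))
            for bc, xi, pi in zip(barcodes, x, p)
        ]

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Guide expression mixture (ZINB background + NB signal)",
            "=" * 54,
            f"{'n cells':<28}{self.n_cells}",
            f"{'n positive (count > 0)':<28}{self.n_positive}",
            f"{'status':<28}{self.status}",
        ]
        if self.params is not None:
            th = self.params
            lines += [
                f"{'log-likelihood':<28}{self.loglik:.4f}",
                f"{'EM iterations':<28}{self.n_iter}",
                f"{'converged':<28}{self.converged}",
                "-" * 54,
                f"{'pi (expressing weight)':<28}{th.pi:.6g}",
                f"{'w0 (zero inflation)':<28}{th.w0:.6g}",
                f"{'mu_lo, r_lo (background)':<28}{th.mu_lo:.6g}, {th.r_lo:.6g}",
                f"{'mu_hi, r_hi (expressing)':<28}{th.mu_hi:.6g}, {th.r_hi:.6g}",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "loglik": None if not np.isfinite(self.loglik) else self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "status": self.status,
            "n_cells": self.n_cells,
            "n_positive": self.n_positive,
        }
        if self.params is not None:
            th = self.params
            d.update(
                pi=th.pi, w0=th.w0, mu_lo=th.mu_lo, r_lo=th.r_lo, mu_hi=th.mu_hi, r_hi=th.r_hi
            )
        return d


def fit_mixture(
    counts,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_init: int = 3,
    seed: int | None = None,
    min_positive: int = 5,
) -> GuideMixtureResults:
    """Functional wrapper: build a :class:`GuideMixtureModel` and fit it."""
    return GuideMixtureModel(counts).fit(
        max_iter=max_iter, tol=tol, n_init=n_init, seed=seed, min_positive=min_positive
    )


def classify_counts(
    fit: GuideMixtureResults, barcodes, guide_id: str, counts=None, fallback_min_count: int = 3
) -> list[GuideCall]:
    """Functional wrapper for :meth:`GuideMixtureResults.classify`."""
    return fit.classify(barcodes, guide_id, counts=counts, fallback_min_count=fallback_min_count)
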