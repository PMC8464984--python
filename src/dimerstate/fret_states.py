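"""Corrected burst FRET efficiencies and Gaussian conformational-state inference.

Each selected doubly labeled burst yields one corrected efficiency

.. math::

    F_{corr} = f_{DA} - Lk\\,f_{DD} - Di\\,f_{AA}, \\qquad
    E = \\frac{F_{corr}}{F_{corr} + \\gamma f_{DD}},

and the sample of per-burst efficiencies is decomposed into K Gaussian
components by maximum-likelihood expectation-maximization.  The component
weights are the conformational-state populations; shot noise sets the
component widths, so widths are free per component with a small floor.

The estimator :class:`FretMixture` follows the scikit-learn protocol
(``fit`` / ``predict`` / ``score``, fitted attributes with a trailing
underscore) and therefore composes with sklearn tooling; :func:`fit_mixture`
and friends are thin functional wrappers matching the pipeline vocabulary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, DensityMixin

from .calibrate import CorrectionSet
from .exceptions import FitError

__all__ = [
    "EfficiencySet",
    "MixtureModel",
    "FretMixture",
    "burst_efficiency",
    "efficiencies",
    "fit_mixture",
    "state_populations",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


@dataclass
class EfficiencySet:
    """Per-burst corrected FRET efficiencies ready for mixture fitting.

    Values are clamped to [-0.1, 1.1]: shot noise legitimately pushes single
    bursts slightly past the physical range, and clipping extreme overshoot
    keeps the Gaussian fit well conditioned.  ``n_clamped`` and
    ``n_discarded`` record how much the clamp and the nonpositive-denominator
    filter actually did.
    """

    E_values: np.ndarray
    corrections: CorrectionSet
    n_clamped: int = 0
    n_discarded: int = 0

    @property
    def n_bursts(self) -> int:
        return int(self.E_values.size)


@dataclass
class MixtureModel:
    """A fitted K-component Gaussian mixture over burst efficiencies."""

    K: int
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    n_data: int
    ll_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def burst_efficiency(burst, corrections: CorrectionSet | None = None) -> float | None:
    """Corrected FRET efficiency of one background-subtracted burst.

    Returns ``None`` (with a warning) when the corrected total signal is not
    positive — such bursts are discarded rather than raising.
    """
    if corrections is None:
        corrections = CorrectionSet()
    f_corr = burst.f_da_sub - corrections.Lk * burst.f_dd_sub - corrections.Di * burst.f_aa_sub
    denom = f_corr + corrections.gamma * burst.f_dd_sub
    if denom <= 0:
        warnings.warn("burst discarded: corrected total signal <= 0", stacklevel=2)
        return None
    return float(f_corr / denom)


def efficiencies(
    bursts,
    corrections: CorrectionSet | None = None,
    clamp: tuple[float, float] = (-0.1, 1.1),
) -> EfficiencySet:
    """Vectorized :func:`burst_efficiency` over a burst list."""
    if corrections is None:
        corrections = CorrectionSet()
    f_dd = np.array([b.f_dd_sub for b in bursts], dtype=float)
    f_da = np.array([b.f_da_sub for b in bursts], dtype=float)
    f_aa = np.array([b.f_aa_sub for b in bursts], dtype=float)
    f_corr = f_da - corrections.Lk * f_dd - corrections.Di * f_aa
    denom = f_corr + corrections.gamma * f_dd
    ok = denom > 0
    e = f_corr[ok] / denom[ok]
    clamped = (e < clamp[0]) | (e > clamp[1])
    e = np.clip(e, *clamp)
    return EfficiencySet(e, corrections, int(clamped.sum()), int((~ok).sum()))


def _norm_pdf_matrix(x: np.ndarray, mu: np.ndarray, sg: np.ndarray) -> np.ndarray:
    z = (x[:, None] - mu[None, :]) / sg[None, :]
    return np.exp(-0.5 * z * z) / (sg[None, :] * _SQRT2PI)


class FretMixture(DensityMixin, BaseEstimator):
    """1-D Gaussian mixture fitted by EM with multiple restarts.

    Parameters
    ----------
    n_components : int or "auto"
        Number of Gaussian states; ``"auto"`` selects K in {1, 2, 3} by BIC.
    n_init : int
        Independent EM restarts; the best log-likelihood wins.
    tol : float
        Relative log-likelihood change declaring convergence.
    sigma_floor : float
        Lower bound on component widths (efficiency units).
    fixed_means, fixed_sigmas : array-like or None
        When given, EM only updates the weights.  This is how titration
        points share components globally: the component locations come from a
        reference (e.g. pooled) fit and only populations move.
    random_state : int or numpy Generator
        Seeds the restart initializations.

    Attributes
    ----------
    means_, sigmas_, weights_ : components sorted by ascending mean.
    loglik_, bic_, converged_, n_iter_, ll_path_ : fit diagnostics.
    """

    def __init__(
        self,
        n_components=2,
        n_init: int = 20,
        tol: float = 1e-8,
        max_iter: int = 500,
        sigma_floor: float = 0.01,
        fixed_means=None,
        fixed_sigmas=None,
        random_state=None,
    ):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.sigma_floor = sigma_floor
        self.fixed_means = fixed_means
        self.fixed_sigmas = fixed_sigmas
        self.random_state = random_state

    # -- EM core -----------------------------------------------------------
    def _em_once(self, x, mu, sg, w):
        fix_mu = self.fixed_means is not None
        fix_sg = self.fixed_sigmas is not None
        n = x.size
        ll_old = -np.inf
        path = []
        converged = False
        for it in range(self.max_iter):
            dens = w[None, :] * _norm_pdf_matrix(x, mu, sg)
            tot = dens.sum(axis=1) + 1e-300
            ll = float(np.log(tot).sum())
            path.append(ll)
            if ll < ll_old - 1e-9 * (abs(ll_old) + 1.0):
                # only possible when the sigma floor binds; keep the previous optimum
                break
            if ll - ll_old <= self.tol * (abs(ll) + 1.0):
                converged = True
                break
            ll_old = ll
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0) + 1e-12
            w = nk / n
            if not fix_mu:
                mu = (resp * x[:, None]).sum(axis=0) / nk
            if not fix_sg:
                var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
                sg = np.maximum(np.sqrt(var), self.sigma_floor)
        return mu, sg, w, float(path[-1]), converged, len(path), np.array(path)

    def _fit_k(self, x, k, rng):
        if self.fixed_means is not None:
            mu0 = np.asarray(self.fixed_means, dtype=float)
            k = mu0.size
        if self.fixed_sigmas is not None and self.fixed_means is None:
            raise FitError("fixed_sigmas requires fixed_means")
        best = None
        spread = max(float(x.std()), self.sigma_floor)
        for i in range(self.n_init):
            if self.fixed_means is not None:
                mu = np.asarray(self.fixed_means, dtype=float).copy()
            else:
                qs = (np.arange(k) + 0.5) / k
                mu = np.quantile(x, qs) + (0.0 if i == 0 else rng.normal(0, spread / 2, k))
            if self.fixed_sigmas is not None:
                sg = np.maximum(np.asarray(self.fixed_sigmas, dtype=float).copy(), self.sigma_floor)
            else:
                sg = np.full(k, max(spread / max(k, 1), self.sigma_floor))
            w = rng.dirichlet(np.full(k, 10.0)) if i else np.full(k, 1.0 / k)
            result = self._em_once(x, mu, sg, w)
            if best is None or result[3] > best[3]:
                best = result
        return best

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size < 2:
            raise FitError("need at least 2 efficiency values")
        rng = (
            self.random_state
            if isinstance(self.random_state, np.random.Generator)
            else np.random.default_rng(self.random_state)
        )
        ks = (1, 2, 3) if self.n_components == "auto" else (int(self.n_components),)
        best_bic = np.inf
        chosen = None
        for k in ks:
            mu, sg, w, ll, conv, n_iter, path = self._fit_k(x, k, rng)
            if self.fixed_means is not None:
                n_free = k - 1
            else:
                n_free = 3 * k - 1 - (k if self.fixed_sigmas is not None else 0)
            bic = -2.0 * ll + n_free * np.log(x.size)
            if bic < best_bic:
                best_bic = bic
                chosen = (k, mu, sg, w, ll, conv, n_iter, path, bic)
        k, mu, sg, w, ll, conv, n_iter, path, bic = chosen
        order = np.argsort(mu)
        self.means_ = mu[order]
        self.sigmas_ = sg[order]
        self.weights_ = w[order]
        self.loglik_ = ll
        self.bic_ = bic
        self.converged_ = conv
        self.n_iter_ = n_iter
        self.ll_path_ = path
        self.n_features_in_ = 1
        self.n_data_ = int(x.size)
        if not conv:
            warnings.warn("EM did not converge within max_iter; best attempt kept", stacklevel=2)
        return self

    def predict(self, X):
        """Most probable component index (sorted by mean) per efficiency value."""
        x = np.asarray(X, dtype=float).ravel()
        dens = self.weights_[None, :] * _norm_pdf_matrix(x, self.means_, self.sigmas_)
        return dens.argmax(axis=1)

    def score_samples(self, X):
        x = np.asarray(X, dtype=float).ravel()
        dens = self.weights_[None, :] * _norm_pdf_matrix(x, self.means_, self.sigmas_)
        return np.log(dens.sum(axis=1) + 1e-300)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    def to_model(self) -> MixtureModel:
        return MixtureModel(
            K=self.means_.size,
            means=self.means_.copy(),
            sigmas=self.sigmas_.copy(),
            weights=self.weights_.copy(),
            loglik=self.loglik_,
            bic=self.bic_,
            converged=self.converged_,
            n_iter=self.n_iter_,
            n_data=self.n_data_,
            ll_path=self.ll_path_.copy(),
        )


def fit_mixture(
    e_set: EfficiencySet | np.ndarray,
    K=2,
    random_state=None,
    **kwargs,
) -> MixtureModel:
    """Maximum-likelihood Gaussian mixture over burst efficiencies.

    ``K="auto"`` selects K in {1, 2, 3} by the Bayesian information
    criterion.  Extra keyword arguments are forwarded to :class:`FretMixture`.
    """
    x = e_set.E_values if isinstance(e_set, EfficiencySet) else np.asarray(e_set, float)
    est = FretMixture(n_components=K, random_state=random_state, **kwargs).fit(x)
    return est.to_model()


def refit_weights(model: MixtureModel, e_values: np.ndarray, random_state=None) -> np.ndarray:
    """Component weights for new data with means/sigmas held at a reference fit."""
    est = FretMixture(
        n_components=model.K,
        fixed_means=model.means,
        fixed_sigmas=model.sigmas,
        n_init=1,
        random_state=random_state,
    ).fit(e_values)
    return est.weights_


def state_populations(
    model: MixtureModel,
    E_values: np.ndarray | None = None,
    n_boot: int = 200,
    invert: bool = False,
    random_state=None,
) -> dict:
    """Label mixture weights as conformational-state populations.

    By convention state 1 is the low-efficiency component and state 2 the
    high-efficiency one (the labeling convention of the primary dye site);
    ``invert=True`` swaps the mapping for label sites where the low-FRET peak
    corresponds to state 2.  If ``E_values`` is given, a nonparametric burst
    bootstrap (weights refit with components fixed) provides standard errors.
    """
    if model.K == 1:
        w = {"state1": 1.0, "state2": 0.0}
        se = {"state1": 0.0, "state2": 0.0}
    else:
        lo, hi = float(model.weights[0]), float(model.weights[-1])
        if model.K > 2:
            hi = float(model.weights[1:].sum())
        w = {"state1": lo, "state2": hi}
        se = {"state1": np.nan, "state2": np.nan}
        if E_values is not None and n_boot > 0:
            rng = np.random.default_rng(random_state)
            n = E_values.size
            lows = np.empty(n_boot)
            for b in range(n_boot):
                sample = E_values[rng.integers(0, n, n)]
                wts = refit_weights(model, sample)
                lows[b] = wts[0]
            se = {"state1": float(lows.std(ddof=1)), "state2": float(lows.std(ddof=1))}
    if invert:
        w = {"state1": w["state2"], "state2": w["state1"]}
        se = {"state1": se["state2"], "state2": se["state1"]}
    return {
        "state1": w["state1"],
        "state2": w["state2"],
        "se": se,
        "convention": "state1=high-E" if invert else "state1=low-E",
    }
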