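"""Titration binding analysis: state populations vs ligand -> dissociation constant.

The enriched conformational state's population across a ligand titration is
fitted to the one-site isotherm

.. math::

    f(L) = f_0 + (f_{max} - f_0) \\frac{L}{K_D + L},

with the free-ligand ~ total-ligand approximation (the labeled receptor sits
at ~100 pM, orders of magnitude below any K_D of interest; an exact
quadratic tight-binding form is available behind the ``model`` flag).
Uncertainties propagate the dominant noise source — per-burst counting
statistics — by a nonparametric bootstrap over bursts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import FitError
from .fret_states import MixtureModel, fit_mixture, refit_weights

__all__ = [
    "TitrationCurve",
    "BindingFit",
    "BindingIsotherm",
    "fit_isotherm",
    "kd_ratio",
    "analyze_titration",
]


@dataclass
class TitrationCurve:
    """Enriched-state fraction vs total ligand concentration (molar)."""

    concentrations: np.ndarray
    enriched_fraction: np.ndarray
    se: np.ndarray | None = None
    ligand_label: str = ""
    enriched_state: str = "state1"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.enriched_fraction = np.asarray(self.enriched_fraction, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be nonnegative")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.enriched_fraction < 0) | (self.enriched_fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class BindingFit:
    """A fitted one-site isotherm with bootstrap uncertainty on K_D."""

    kd: float
    kd_se: float
    kd_ci: tuple[float, float]
    f0: float
    fmax: float
    f0_se: float
    fmax_se: float
    residuals: np.ndarray
    n_boot: int = 0
    flagged: bool = False
    kd_samples: np.ndarray | None = None
    ligand_label: str = ""


def _hyperbola(L, f0, fmax, kd):
    return f0 + (fmax - f0) * L / (kd + L)


def _quadratic(L, f0, fmax, kd, receptor):
    b = receptor + L + kd
    theta = (b - np.sqrt(np.maximum(b * b - 4.0 * receptor * L, 0.0))) / (2.0 * receptor)
    return f0 + (fmax - f0) * theta


class BindingIsotherm(RegressorMixin, BaseEstimator):
    """One-site binding-isotherm regressor in the scikit-learn idiom.

    ``fit(L, f, sample_sigma=...)`` performs weighted least squares; fitted
    attributes are ``kd_``, ``f0_``, ``fmax_`` with standard errors from the
    covariance of the fit.  ``model='quadratic'`` uses the ligand-depletion
    (tight-binding) form and requires ``receptor_conc``.
    """

    def __init__(self, model: str = "hyperbolic", receptor_conc: float | None = None):
        self.model = model
        self.receptor_conc = receptor_conc

    def fit(self, X, y, sample_sigma=None):
        L = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        if L.size < 4:
            raise FitError("need >= 4 titration points")
        if sample_sigma is not None:
            sample_sigma = np.asarray(sample_sigma, dtype=float).ravel()
            if np.any(sample_sigma <= 0):
                sample_sigma = None

        scale = np.median(L[L > 0]) if np.any(L > 0) else 1.0
        p0 = (float(f[0]), float(f[-1]), float(scale))
        if self.model == "hyperbolic":
            func = _hyperbola
        elif self.model == "quadratic":
            if not self.receptor_conc or self.receptor_conc <= 0:
                raise FitError("quadratic model needs a positive receptor_conc")
            r0 = float(self.receptor_conc)

            def func(Lc, f0, fmax, kd):
                return _quadratic(Lc, f0, fmax, kd, r0)
        else:
            raise FitError(f"unknown isotherm model {self.model!r}")

        try:
            popt, pcov = curve_fit(
                func,
                L,
                f,
                p0=p0,
                sigma=sample_sigma,
                absolute_sigma=sample_sigma is not None,
                bounds=([-0.0, -0.0, scale * 1e-9], [1.0, 1.0, scale * 1e9]),
                maxfev=20000,
            )
        except RuntimeError as exc:  # pragma: no cover
            raise FitError(f"isotherm fit failed: {exc}") from exc
        self.f0_, self.fmax_, self.kd_ = (float(v) for v in popt)
        perr = np.sqrt(np.maximum(np.diag(pcov), 0.0))
        self.f0_se_, self.fmax_se_, self.kd_se_ = (float(v) for v in perr)
        self.residuals_ = f - func(L, *popt)
        # no saturation trend: plateau indistinguishable from baseline
        sep = abs(self.fmax_ - self.f0_)
        self.flagged_ = bool(sep < 2.0 * np.hypot(self.f0_se_, self.fmax_se_))
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        L = np.asarray(X, dtype=float).ravel()
        if self.model == "quadratic":
            return _quadratic(L, self.f0_, self.fmax_, self.kd_, float(self.receptor_conc))
        return _hyperbola(L, self.f0_, self.fmax_, self.kd_)


def fit_isotherm(
    curve: TitrationCurve,
    model: str = "hyperbolic",
    receptor_conc: float | None = None,
) -> BindingFit:
    """Weighted least-squares isotherm fit of a titration curve.

    Uncertainties here come from the fit covariance; the burst-level
    bootstrap lives in :func:`analyze_titration`, which owns the raw
    efficiency samples.  A fit whose plateau is statistically
    indistinguishable from its baseline is flagged unreliable.
    """
    est = BindingIsotherm(model=model, receptor_conc=receptor_conc)
    est.fit(curve.concentrations, curve.enriched_fraction, sample_sigma=curve.se)
    if est.flagged_:
        warnings.warn("no saturation trend: K_D unreliable", stacklevel=2)
    kd_ci = (est.kd_ - 1.96 * est.kd_se_, est.kd_ + 1.96 * est.kd_se_)
    return BindingFit(
        kd=est.kd_,
        kd_se=est.kd_se_,
        kd_ci=kd_ci,
        f0=est.f0_,
        fmax=est.fmax_,
        f0_se=est.f0_se_,
        fmax_se=est.fmax_se_,
        residuals=est.residuals_,
        flagged=est.flagged_,
        ligand_label=curve.ligand_label,
    )


def kd_ratio(fit_a: BindingFit, fit_b: BindingFit, random_state=None, n_pairs: int = 2000) -> dict:
    """Fold-difference KD_b / KD_a with a bootstrap (or delta-method) CI.

    When both fits carry bootstrap samples the CI comes from pair resampling;
    otherwise a log-normal approximation from the standard errors is used.
    If either input fit was flagged unreliable, the flag propagates.
    """
    ratio = fit_b.kd / fit_a.kd
    flagged = fit_a.flagged or fit_b.flagged
    if fit_a.kd_samples is not None and fit_b.kd_samples is not None:
        rng = np.random.default_rng(random_state)
        sa = fit_a.kd_samples
        sb = fit_b.kd_samples
        idx_a = rng.integers(0, sa.size, n_pairs)
        idx_b = rng.integers(0, sb.size, n_pairs)
        samples = sb[idx_b] / sa[idx_a]
        ci = (float(np.quantile(samples, 0.025)), float(np.quantile(samples, 0.975)))
    else:
        rel = np.hypot(fit_a.kd_se / fit_a.kd, fit_b.kd_se / fit_b.kd)
        ci = (ratio * np.exp(-1.96 * rel), ratio * np.exp(1.96 * rel))
    return {"ratio": float(ratio), "ci": ci, "flagged": flagged}


def analyze_titration(
    e_sets: list[np.ndarray],
    concentrations,
    enriched_state: str = "state1",
    reference_model: MixtureModel | None = None,
    share_components: bool = True,
    n_boot: int = 200,
    ligand_label: str = "",
    random_state=None,
    model: str = "hyperbolic",
    receptor_conc: float | None = None,
) -> tuple[TitrationCurve, BindingFit, MixtureModel]:
    """Full titration analysis from per-concentration burst efficiencies.

    A two-state mixture is fitted to the pooled efficiencies (or taken from
    ``reference_model``); with ``share_components`` (default) the component
    means and widths are then held fixed across concentrations and only the
    weights are refitted per point — the stabilizing choice when one state's
    population becomes small at the titration endpoints.  The enriched
    state's fraction per point forms the titration curve, and a burst
    bootstrap (``n_boot`` replicates) supplies both the per-point standard
    errors and the K_D sampling distribution.
    """
    concentrations = np.asarray(concentrations, dtype=float)
    if len(e_sets) != concentrations.size:
        raise ValueError("one efficiency set per concentration required")
    rng = np.random.default_rng(random_state)

    if reference_model is None:
        pooled = np.concatenate(e_sets)
        reference_model = fit_mixture(pooled, K=2, random_state=rng)
    if reference_model.K < 2:
        raise FitError("titration analysis needs a two-state reference model")

    idx = 0 if enriched_state == "state1" else -1

    def point_fractions(sets) -> np.ndarray:
        out = np.empty(len(sets))
        for i, e in enumerate(sets):
            if share_components:
                w = refit_weights(reference_model, e)
            else:
                w = fit_mixture(e, K=2, n_init=5, random_state=rng).weights
            out[i] = w[idx]
        return out

    fractions = point_fractions(e_sets)

    boot_fracs = np.empty((n_boot, len(e_sets)))
    kd_samples = []
    for b in range(n_boot):
        resampled = [e[rng.integers(0, e.size, e.size)] for e in e_sets]
        boot_fracs[b] = point_fractions(resampled)
    se = boot_fracs.std(axis=0, ddof=1) if n_boot > 1 else None
    if se is not None:
        se = np.maximum(se, 1e-4)

    curve = TitrationCurve(
        concentrations, np.clip(fractions, 0.0, 1.0), se, ligand_label, enriched_state
    )
    fit = fit_isotherm(curve, model=model, receptor_conc=receptor_conc)

    if n_boot > 1:
        est = BindingIsotherm(model=model, receptor_conc=receptor_conc)
        for b in range(n_boot):
            try:
                est.fit(concentrations, np.clip(boot_fracs[b], 0, 1), sample_sigma=se)
                kd_samples.append(est.kd_)
            except FitError:  # pragma: no cover
                continue
        if kd_samples:
            samples = np.asarray(kd_samples)
            fit.kd_samples = samples
            fit.n_boot = samples.size
            fit.kd_se = float(samples.std(ddof=1))
            fit.kd_ci = (float(np.quantile(samples, 0.025)), float(np.quantile(samples, 0.975)))
    return curve, fit, reference_model
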