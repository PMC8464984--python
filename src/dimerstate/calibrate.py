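"""Correction-factor calibration from DNA-ruler measurements.

Doubly labeled double-stranded DNA standards with different donor-acceptor
base separations (hence different, known-to-be-distinct FRET efficiencies)
are measured under the same optical settings as the protein sample and used
to determine three instrument/dye corrections:

* ``Lk`` — donor leakage into the acceptor detection channel, estimated from
  donor-only standards as the pooled count ratio sum(f_DA)/sum(f_DD);
* ``Di`` — acceptor direct excitation at the donor laser wavelength,
  estimated from acceptor-only standards as sum(f_DA)/sum(f_AA);
* ``gamma`` — the acceptor/donor detection-efficiency and quantum-yield
  ratio, from the linear relation between inverse stoichiometry and the
  crosstalk-corrected proximity ratio across rulers:
  ``1/S = Omega + Sigma * E_PR``, with
  ``gamma = (Omega - 1) / (Omega + Sigma - 1)`` and the excitation-ratio
  factor ``beta = Omega + Sigma - 1``.

Pooled (summed-count) ratios are used throughout: they carry far less
small-count bias than averaging per-burst ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .exceptions import CalibrationError

if TYPE_CHECKING:  # pragma: no cover
    from .bursts import Burst

__all__ = [
    "CorrectionSet",
    "estimate_leakage",
    "estimate_direct",
    "estimate_gamma",
    "calibrate_from_rulers",
]


@dataclass
class CorrectionSet:
    """Leakage, direct excitation and detection correction factor.

    The default ``(Lk, Di, gamma) = (0, 0, 1)`` is the identity correction:
    applying it leaves proximity ratios unchanged.
    """

    Lk: float = 0.0
    Di: float = 0.0
    gamma: float = 1.0
    beta: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.Lk < 0 or self.Di < 0:
            raise CalibrationError("Lk and Di must be >= 0")
        if self.gamma <= 0:
            raise CalibrationError("gamma must be positive")

    @property
    def is_identity(self) -> bool:
        return self.Lk == 0.0 and self.Di == 0.0 and self.gamma == 1.0


def _pooled(bursts: Iterable["Burst"], attr: str) -> float:
    return float(sum(getattr(b, attr) for b in bursts))


def estimate_leakage(donor_only_bursts: Sequence["Burst"], min_bursts: int = 50) -> float:
    """Donor leakage Lk = sum(f_DA) / sum(f_DD) over donor-only bursts."""
    if len(donor_only_bursts) < min_bursts:
        raise CalibrationError(
            f"need >= {min_bursts} donor-only bursts, got {len(donor_only_bursts)}"
        )
    f_dd = _pooled(donor_only_bursts, "f_dd_sub")
    f_da = _pooled(donor_only_bursts, "f_da_sub")
    if f_dd <= 0:
        raise CalibrationError("pooled donor-channel signal is zero")
    return f_da / f_dd


def estimate_direct(acceptor_only_bursts: Sequence["Burst"], min_bursts: int = 50) -> float:
    """Acceptor direct excitation Di = sum(f_DA) / sum(f_AA) over acceptor-only bursts."""
    if len(acceptor_only_bursts) < min_bursts:
        raise CalibrationError(
            f"need >= {min_bursts} acceptor-only bursts, got {len(acceptor_only_bursts)}"
        )
    f_aa = _pooled(acceptor_only_bursts, "f_aa_sub")
    f_da = _pooled(acceptor_only_bursts, "f_da_sub")
    if f_aa <= 0:
        raise CalibrationError("pooled acceptor-channel signal is zero")
    return f_da / f_aa


def ruler_summary(bursts: Sequence["Burst"], Lk: float, Di: float) -> tuple[float, float, float]:
    """Pooled crosstalk-corrected proximity ratio, apparent S and total photons."""
    f_dd = _pooled(bursts, "f_dd_sub")
    f_da = _pooled(bursts, "f_da_sub")
    f_aa = _pooled(bursts, "f_aa_sub")
    f_da_c = f_da - Lk * f_dd - Di * f_aa
    denom_e = f_da_c + f_dd
    denom_s = f_da_c + f_dd + f_aa
    if denom_e <= 0 or denom_s <= 0:
        raise CalibrationError("ruler has no usable pooled signal")
    return f_da_c / denom_e, (f_dd + f_da_c) / denom_s, f_dd + f_da + f_aa


def estimate_gamma(
    ruler_burst_sets: Sequence[Sequence["Burst"]],
    Lk: float = 0.0,
    Di: float = 0.0,
    min_spread: float = 0.1,
) -> tuple[float, float]:
    """Detection factor gamma (and beta) from >= 2 rulers of distinct efficiency.

    Fits the weighted linear relation ``1/S = Omega + Sigma * E_PR`` across
    rulers (weights: total pooled photons) and returns
    ``gamma = (Omega - 1)/(Omega + Sigma - 1)``, ``beta = Omega + Sigma - 1``.
    Raises :class:`CalibrationError` when fewer than two rulers are given or
    the apparent-efficiency spread is below ``min_spread`` (an underdetermined
    or collinear design).
    """
    if len(ruler_burst_sets) < 2:
        raise CalibrationError("gamma fit needs >= 2 ruler burst sets")
    e_pr, inv_s, w = [], [], []
    for bursts in ruler_burst_sets:
        e, s, n = ruler_summary(bursts, Lk, Di)
        if s <= 0:
            raise CalibrationError("nonpositive apparent stoichiometry")
        e_pr.append(e)
        inv_s.append(1.0 / s)
        w.append(n)
    e_pr = np.asarray(e_pr)
    spread = e_pr.max() - e_pr.min()
    if spread < min_spread:
        raise CalibrationError(
            f"ruler apparent-E spread {spread:.3f} < {min_spread}: cannot separate "
            "slope from intercept; use rulers with more distinct dye separations"
        )
    sigma_fit, omega = np.polyfit(e_pr, np.asarray(inv_s), 1, w=np.sqrt(np.asarray(w)))
    beta = omega + sigma_fit - 1.0
    if beta <= 0:
        raise CalibrationError(f"implausible regression (Omega={omega:.3f}, Sigma={sigma_fit:.3f})")
    gamma = (omega - 1.0) / beta
    if gamma <= 0:
        raise CalibrationError(f"fitted gamma {gamma:.3f} is nonpositive")
    return float(gamma), float(beta)


def calibrate_from_rulers(
    ruler_burst_sets: Sequence[Sequence["Burst"]],
    donor_only_bursts: Sequence["Burst"],
    acceptor_only_bursts: Sequence["Burst"],
    min_bursts: int = 50,
) -> CorrectionSet:
    """Full calibration: Lk and Di from single-label controls, then gamma."""
    lk = estimate_leakage(donor_only_bursts, min_bursts)
    di = estimate_direct(acceptor_only_bursts, min_bursts)
    gamma, beta = estimate_gamma(ruler_burst_sets, lk, di)
    return CorrectionSet(
        Lk=lk,
        Di=di,
        gamma=gamma,
        beta=beta,
        provenance={
            "n_rulers": len(ruler_burst_sets),
            "n_donor_only": len(donor_only_bursts),
            "n_acceptor_only": len(acceptor_only_bursts),
        },
    )
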