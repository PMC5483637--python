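"""Davis biophysical model of the BOLD signal.

The Davis model ties the fractional BOLD signal change to fractional
changes in cerebral blood flow (CBF) and the cerebral metabolic rate of
oxygen (CMRO2),

    dBOLD/BOLD0 = M * (1 - (1 + dCBF/CBF0)**(alpha - beta)
                          * (1 + dCMRO2/CMRO2_0)**beta),

where ``alpha`` links CBF to cerebral blood volume, ``beta`` captures the
field-strength-dependent susceptibility of deoxyhemoglobin, and ``M`` is a
participant-specific scaling constant equal to the maximal BOLD increase
obtainable by washing out all resting deoxyhemoglobin.  ``M`` is estimated
from a hypercapnic gas challenge, which raises CBF with (assumed)
unchanged CMRO2, so the same forward equation with dCMRO2 = 0 can be
solved for M.

All functions here are pure and operate on *fractional* changes
(0.02 means +2 % from baseline); multiply by 100 only at reporting
boundaries.  Inputs may be scalars or numpy arrays (broadcasting applies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DavisParams",
    "forward_bold",
    "estimate_m",
    "estimate_m_from_changes",
    "compute_delta_cmro2",
    "compute_n",
    "DavisDomainError",
    "CalibrationError",
    "CouplingUndefinedError",
]


class DavisDomainError(ValueError):
    """A ratio argument left the model's domain (non-positive base)."""


class CalibrationError(ValueError):
    """M cannot be estimated or used (zero CBF change, M <= 0, dBOLD >= M)."""


class CouplingUndefinedError(ZeroDivisionError):
    """The coupling ratio n = dCBF/dCMRO2 is undefined (dCMRO2 == 0)."""


@dataclass(frozen=True)
class DavisParams:
    """Model constants.

    alpha : CBF-CBV coupling exponent (Grubb-type), dimensionless.
    beta  : deoxyhemoglobin susceptibility exponent at the field strength
            used, dimensionless.  Defaults are the 3 T literature values
            used throughout the package.
    """

    alpha: float = 0.38
    beta: float = 1.3

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")


DEFAULT_PARAMS = DavisParams()


def _check_ratio(value, name: str) -> np.ndarray:
    """Validate that 1 + value > 0 wherever a power of the ratio is taken."""
    r = 1.0 + np.asarray(value, dtype=float)
    if np.any(r <= 0):
        raise DavisDomainError(
            f"{name} implies a non-positive baseline ratio (1 + {name} <= 0)"
        )
    return r


def forward_bold(delta_cbf, delta_cmro2, m, params: DavisParams = DEFAULT_PARAMS):
    """Forward Davis model: fractional BOLD change from dCBF, dCMRO2 and M.

    Exact algebraic inverse of :func:`compute_delta_cmro2`.
    """
    r_cbf = _check_ratio(delta_cbf, "delta_cbf")
    r_cmro2 = _check_ratio(delta_cmro2, "delta_cmro2")
    m = np.asarray(m, dtype=float)
    if np.any(m < 0):
        raise CalibrationError("M must be >= 0")
    out = m * (1.0 - r_cbf ** (params.alpha - params.beta) * r_cmro2 ** params.beta)
    return out if out.ndim else float(out)


def estimate_m(bold_0, bold_hc, cbf_0, cbf_hc, params: DavisParams = DEFAULT_PARAMS):
    """Estimate the calibration constant M from a hypercapnic challenge.

    M = (dBOLD_hc/BOLD0) / (1 - (1 + dCBF_hc/CBF0)**(alpha - beta)),
    i.e. the forward model solved for M under the assumption that
    hypercapnia leaves CMRO2 unchanged.  Depends on the inputs only
    through the two fractional changes, so it is invariant to rescaling
    either modality by a positive constant.
    """
    bold_0 = np.asarray(bold_0, dtype=float)
    cbf_0 = np.asarray(cbf_0, dtype=float)
    if np.any(bold_0 <= 0) or np.any(cbf_0 <= 0):
        raise DavisDomainError("baseline signals must be positive")
    d_bold = (np.asarray(bold_hc, dtype=float) - bold_0) / bold_0
    d_cbf = (np.asarray(cbf_hc, dtype=float) - cbf_0) / cbf_0
    return estimate_m_from_changes(d_bold, d_cbf, params)


def estimate_m_from_changes(
    delta_bold_hc, delta_cbf_hc, params: DavisParams = DEFAULT_PARAMS
):
    """M from the hypercapnic fractional changes themselves.

    Same quantity as :func:`estimate_m`, for callers that already hold
    (BOLD_hc - BOLD_0)/BOLD_0 and (CBF_hc - CBF_0)/CBF_0 (e.g. ROI means
    of voxelwise change maps).
    """
    d_cbf = np.asarray(delta_cbf_hc, dtype=float)
    if np.any(d_cbf == 0):
        raise CalibrationError("zero hypercapnic CBF change: M is undefined")
    r_cbf = _check_ratio(d_cbf, "delta_cbf_hc")
    out = np.asarray(delta_bold_hc, dtype=float) / (
        1.0 - r_cbf ** (params.alpha - params.beta)
    )
    return out if out.ndim else float(out)


def compute_delta_cmro2(delta_bold, delta_cbf, m, params: DavisParams = DEFAULT_PARAMS):
    """Invert the Davis model for the fractional CMRO2 change.

    dCMRO2/CMRO2_0 = (1 - dBOLD/M)**(1/beta) * (1 + dCBF)**(1 - alpha/beta) - 1
    """
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise CalibrationError("M must be > 0 to invert the model")
    delta_bold = np.asarray(delta_bold, dtype=float)
    if np.any(delta_bold / m >= 1.0):
        raise CalibrationError(
            "delta_bold >= M: BOLD change exceeds the calibration ceiling"
        )
    r_cbf = _check_ratio(delta_cbf, "delta_cbf")
    out = (1.0 - delta_bold / m) ** (1.0 / params.beta) * r_cbf ** (
        1.0 - params.alpha / params.beta
    ) - 1.0
    return out if out.ndim else float(out)


def compute_n(delta_cbf, delta_cmro2):
    """Neural-vascular coupling ratio n = dCBF / dCMRO2 (both fractional)."""
    delta_cmro2 = np.asarray(delta_cmro2, dtype=float)
    if np.any(delta_cmro2 == 0):
        raise CouplingUndefinedError(
            "coupling ratio undefined for zero delta_cmro2"
        )
    out = np.asarray(delta_cbf, dtype=float) / delta_cmro2
    return out if out.ndim else float(out)
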