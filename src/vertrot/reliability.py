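"""Intra-observer variability and the significance gate.

The same observer re-measures each inter-endplate rotation change after
an interval; with paired reads :math:`(\\alpha_n, \\alpha_m)` the
intra-observer difference is :math:`\\Delta\\alpha = |\\alpha_n -
\\alpha_m|` and the 95% limit of agreement is

.. math:: \\mathrm{LoA}_{95} = 1.96 \\times \\mathrm{SD}(\\Delta\\alpha),

with the sample (n-1) standard deviation.  Only rotation changes whose
magnitude strictly exceeds this limit are deemed significant.  Note the
SD is taken over the *absolute* differences; the classical signed-
difference Bland-Altman variant is available via ``method="signed"``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyInputError, InsufficientDataError, ParameterError
from .rotation import RotationChangeRecord, classify_change

__all__ = [
    "RaterPairSet",
    "ReliabilityResult",
    "intra_observer_differences",
    "limits_of_agreement",
    "limits_of_agreement_from_pairs",
    "gate_records",
]


@dataclass
class RaterPairSet:
    """Repeated change measurements (alpha_n, alpha_m) at matched levels."""

    pairs: np.ndarray  # (n, 2) degrees
    observer: str = "observer1"

    def __post_init__(self):
        p = np.asarray(self.pairs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 2:
            raise ParameterError("pairs must be an (n, 2) array")
        if p.shape[0] < 2:
            raise InsufficientDataError("at least 2 measurement pairs are required")
        if not np.all(np.isfinite(p)):
            raise ParameterError("pair values must be finite")
        self.pairs = p


@dataclass
class ReliabilityResult:
    """Intra-observer differences, their SD and the 1.96 x SD 95% limit."""

    delta_alpha: np.ndarray  # absolute differences, degrees
    sd_intra: float
    loa95: float
    n_pairs: int

    def rounded(self, ndigits: int = 1) -> "ReliabilityResult":
        """Values rounded for reporting (one decimal place by convention)."""
        return replace(
            self, sd_intra=round(self.sd_intra, ndigits), loa95=round(self.loa95, ndigits)
        )


def intra_observer_differences(pairs: RaterPairSet) -> np.ndarray:
    """Elementwise absolute differences |alpha_n - alpha_m|, order-preserving."""
    if pairs.pairs.shape[0] == 0:
        raise EmptyInputError("no measurement pairs")
    return np.abs(pairs.pairs[:, 0] - pairs.pairs[:, 1])


def limits_of_agreement(delta_alpha: Sequence[float]) -> ReliabilityResult:
    """Sample SD of the intra-observer differences and the 1.96 x SD limit."""
    d = np.asarray(delta_alpha, dtype=float)
    if d.size < 2:
        raise InsufficientDataError("at least 2 differences are required")
    sd = float(np.std(d, ddof=1))
    return ReliabilityResult(delta_alpha=d, sd_intra=sd, loa95=1.96 * sd, n_pairs=int(d.size))


def limits_of_agreement_from_pairs(
    pairs: RaterPairSet, method: str = "absolute"
) -> ReliabilityResult:
    """Limits of agreement straight from paired reads.

    ``method="absolute"`` (default) takes the SD of |alpha_n - alpha_m|;
    ``method="signed"`` is the classical Bland-Altman variant using the
    SD of the signed differences.
    """
    if method == "absolute":
        return limits_of_agreement(intra_observer_differences(pairs))
    if method == "signed":
        d = pairs.pairs[:, 0] - pairs.pairs[:, 1]
        sd = float(np.std(d, ddof=1))
        return ReliabilityResult(
            delta_alpha=np.abs(d), sd_intra=sd, loa95=1.96 * sd, n_pairs=int(d.size)
        )
    raise ParameterError("method must be 'absolute' or 'signed'")


def gate_records(
    records: Iterable[RotationChangeRecord], loa95: float
) -> list[RotationChangeRecord]:
    """Re-classify significance of change records against a limit of agreement.

    Idempotent; lowering the limit never decreases the significant count.
    """
    if loa95 <= 0:
        raise ParameterError("loa95 must be positive")
    out = []
    for rec in records:
        significant, loss = classify_change(rec.change, rec.direction_vs_apex, loa95)
        out.append(replace(rec, significant=significant, loss_of_correction=loss))
    return out
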