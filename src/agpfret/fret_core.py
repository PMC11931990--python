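"""Förster-law forward/inverse computation and multi-fluorophore combination.

The measured efficiencies in this system arise from an ensemble of labeling
configurations: each Agp2 dimer carries (at most) one donor distributed over
14 candidate cysteine sites (7 positions x 2 chains), while each Agp1 dimer
carries one acceptor per monomer at the mutated position.  The per-pair
Förster law is combined across that ensemble in two steps:

1. for each Agp1 monomer, an occupancy-weighted mean of the pair efficiencies
   over all donor sites (one donor present at a time, probability = weight);
2. the two monomer aggregates are combined as independent transfer channels,
   ``E_total = 1 - (1 - E1)(1 - E2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import InvalidArgumentError

#: Förster radius of the Atto-495/Atto-565 pair, manufacturer value.
DEFAULT_FORSTER_RADIUS = 50.0

#: Combined efficiencies may exceed 1 by at most this much before raising.
_CLAMP_TOL = 1e-12


@dataclass(frozen=True)
class FretParams:
    """Photophysical parameters of the donor/acceptor pair.

    Parameters
    ----------
    forster_radius_R
        Distance of half-maximal transfer, in Å (50 Å for Atto-495/Atto-565).
    excitation_wavelength
        Donor excitation wavelength in nm (bookkeeping only; the Förster law
        itself does not depend on it).
    """

    forster_radius_R: float = DEFAULT_FORSTER_RADIUS
    excitation_wavelength: float = 470.0

    def __post_init__(self) -> None:
        if not self.forster_radius_R > 0:
            raise InvalidArgumentError(
                f"forster_radius_R must be positive, got {self.forster_radius_R}"
            )


@dataclass(frozen=True)
class PairEfficiency:
    """Single donor-site/acceptor-site transfer efficiency."""

    donor_site_id: str
    acceptor_site_id: str
    distance_r: float
    efficiency: float

    def __post_init__(self) -> None:
        if self.distance_r < 0:
            raise InvalidArgumentError(f"distance_r must be >= 0, got {self.distance_r}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise InvalidArgumentError(
                f"efficiency must be in [0, 1], got {self.efficiency}"
            )


@dataclass(frozen=True)
class CombinedEfficiency:
    """Aggregate efficiencies of the two Agp1 monomers and their combination."""

    e1: float
    e2: float
    e_total: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if np.isnan(self.e_total):
            object.__setattr__(self, "e_total", combine_total(self.e1, self.e2))


def forward_efficiency(r, params: FretParams = FretParams()):
    """Transfer efficiency at donor-acceptor distance ``r``.

    ``E = 1 / (1 + (r/R)^6)``; strictly decreasing in ``r`` and 1 at contact.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise InvalidArgumentError("distance r must be >= 0")
    e = 1.0 / (1.0 + (r / params.forster_radius_R) ** 6)
    return float(e) if e.ndim == 0 else e


def relative_distance(efficiency):
    """Relative distance ``r/R = (1/E - 1)^(1/6)`` from an efficiency.

    Exact inverse of :func:`forward_efficiency` up to floating tolerance.
    Only defined on the open interval 0 < E < 1 (E = 0 means no measurable
    transfer, E = 1 means contact).
    """
    e = np.asarray(efficiency, dtype=float)
    if np.any(e <= 0.0) or np.any(e >= 1.0):
        raise InvalidArgumentError(
            f"efficiency must lie strictly in (0, 1), got {efficiency}"
        )
    rr = (1.0 / e - 1.0) ** (1.0 / 6.0)
    return float(rr) if rr.ndim == 0 else rr


def apparent_distance(efficiency, params: FretParams = FretParams()):
    """Apparent donor-acceptor distance in Å: ``(1/E - 1)^(1/6) * R``.

    For a multi-label measurement this is an effective, not a physical,
    separation: the single distance whose Förster efficiency would equal the
    observed ensemble value.
    """
    return relative_distance(efficiency) * params.forster_radius_R


def aggregate_monomer_efficiency(
    pair_efficiencies: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Occupancy-weighted mean pair efficiency for one Agp1 monomer.

    ``E_monomer = sum_j w_j E_j`` over the donor sites ``j``, with the
    occupancy weights ``w_j >= 0`` summing to 1 (uniform by default).  The
    weighted mean is the expectation over the single-donor ensemble, so the
    result is itself a valid efficiency in [0, 1].
    """
    e = np.asarray(pair_efficiencies, dtype=float)
    if e.ndim != 1 or e.size == 0:
        raise InvalidArgumentError("pair_efficiencies must be a non-empty 1-D sequence")
    if np.any(e < 0) or np.any(e > 1):
        raise InvalidArgumentError("pair efficiencies must lie in [0, 1]")
    if weights is None:
        w = np.full(e.size, 1.0 / e.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != e.shape:
            raise InvalidArgumentError(
                f"weights length {w.size} does not match {e.size} pair efficiencies"
            )
        if np.any(w < 0):
            raise InvalidArgumentError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise InvalidArgumentError(f"weights must sum to 1, got {w.sum()!r}")
    return float(np.dot(w, e))


def combine_total(e1: float, e2: float) -> float:
    """Combine the two monomer aggregates: ``1 - (1 - E1)(1 - E2)``.

    Treats the two acceptor channels as independent; symmetric in its
    arguments and bounded by ``max(e1, e2) <= E_total <= min(1, e1 + e2)``.
    """
    for name, e in (("e1", e1), ("e2", e2)):
        if not -_CLAMP_TOL <= e <= 1.0 + _CLAMP_TOL:
            raise InvalidArgumentError(f"{name} must lie in [0, 1], got {e}")
    total = 1.0 - (1.0 - e1) * (1.0 - e2)
    # absorb floating error only; genuine violations raised above
    return min(1.0, max(0.0, total))


def combine_alternative(
    pair_efficiencies_1: Sequence[float],
    pair_efficiencies_2: Sequence[float],
    weights: Sequence[float] | None = None,
) -> float:
    """Alternative combination order: average per-donor-site totals.

    Combines each donor site's two monomer channels first,
    ``1 - (1 - E_1j)(1 - E_2j)``, then takes the occupancy-weighted mean over
    sites.  This models the per-configuration efficiency of the single-donor
    ensemble exactly; the default pipeline instead averages first and
    combines afterwards (mean-then-combine), reproducing the published order
    of operations.  Off by default; selected via ``combination_mode``.
    """
    e1 = np.asarray(pair_efficiencies_1, dtype=float)
    e2 = np.asarray(pair_efficiencies_2, dtype=float)
    if e1.shape != e2.shape:
        raise InvalidArgumentError("per-monomer pair efficiency lists differ in length")
    totals = 1.0 - (1.0 - e1) * (1.0 - e2)
    return aggregate_monomer_efficiency(totals, weights)
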