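"""Indemnity schedules, actuarial pricing with markup, and wealth accounting.

The livestock contract pays max(0, M - t) per insured TLU, where t is the
trigger (deductible) mortality rate: no payout below 23% mortality by
default, and above it enough to restore wealth to the (1 - t) floor, minus
the premium.  The premium is the actuarially fair price (expected payout)
marked up by a proportional loading m.

All accounting here is done in fractions of the insured value (1 insured
TLU = 1.0); currency is applied as a final display scale.  CRRA certainty
equivalents scale linearly in wealth, so welfare ratios are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ContractTerms",
    "PricedContract",
    "indemnity",
    "indemnity_crop",
    "actuarially_fair_price",
    "premium",
    "price_contract",
    "wealth_next",
]


@dataclass(frozen=True)
class ContractTerms:
    """Contract parameters.

    trigger
        mortality fraction below which nothing is paid (deductible),
        default 0.23.
    markup
        proportional loading on the actuarially fair price, default 0.25.
    insured_units
        insured herd size in TLU, default 1.
    unit_value
        currency value per TLU, default $1000; a pure display scale.
    mode
        "livestock" (mortality-based payout) or "crop" (yield-shortfall
        payout; uses ``crop_price``, ``crop_mean_yield``, ``yield_trigger``).
    """

    trigger: float = 0.23
    markup: float = 0.25
    insured_units: float = 1.0
    unit_value: float = 1000.0
    mode: str = "livestock"
    crop_price: float | None = None
    crop_mean_yield: float | None = None
    yield_trigger: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.trigger < 1.0:
            raise ValueError(f"trigger must be in [0, 1), got {self.trigger}")
        if self.markup < 0:
            raise ValueError(f"markup must be >= 0, got {self.markup}")
        if self.insured_units <= 0:
            raise ValueError(f"insured_units must be > 0, got {self.insured_units}")
        if self.unit_value <= 0:
            raise ValueError(f"unit_value must be > 0, got {self.unit_value}")
        if self.mode not in ("livestock", "crop"):
            raise ValueError(f"unknown contract mode {self.mode!r}")


@dataclass
class PricedContract:
    """Contract terms plus the AFP and premium derived from data.

    ``afp`` and ``premium`` are in fractions of the insured value per
    season (multiply by ``terms.insured_units * terms.unit_value`` for
    currency).
    """

    terms: ContractTerms
    afp: float
    premium: float

    def __post_init__(self) -> None:
        if self.afp < 0:
            raise ValueError("actuarially fair price must be >= 0")
        expected = self.afp * (1.0 + self.terms.markup)
        if not np.isclose(self.premium, expected, rtol=1e-12, atol=1e-15):
            raise ValueError(
                f"premium {self.premium} inconsistent with afp*(1+m)={expected}"
            )

    @property
    def premium_currency(self) -> float:
        return self.premium * self.terms.insured_units * self.terms.unit_value


def indemnity(mortality, terms: ContractTerms) -> np.ndarray | float:
    """Indemnity payout, as a fraction of the insured value.

    I(M) = max(0, M - t) * k1 with k1 normalized to one insured unit; the
    same schedule applies whether M is observed mortality (the perfect
    contract) or a model prediction (an index contract).
    """
    m = np.asarray(mortality, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("mortality must lie in [0, 1]")
    out = np.maximum(0.0, m - terms.trigger)
    return float(out) if out.ndim == 0 else out


def indemnity_crop(predicted_yield, terms: ContractTerms) -> np.ndarray | float:
    """Crop-contract payout in currency: q * max(0, t_y * mu_l - yhat).

    ``terms.crop_mean_yield`` is the long-term mean yield mu_l of the
    location, ``terms.yield_trigger`` the yield trigger t_y, and
    ``terms.crop_price`` the unit crop price q.
    """
    if terms.crop_mean_yield is None or terms.crop_mean_yield <= 0:
        raise ValueError("crop_mean_yield must be set and > 0 for crop contracts")
    q = terms.crop_price if terms.crop_price is not None else 1.0
    t_y = terms.yield_trigger if terms.yield_trigger is not None else terms.trigger
    y = np.asarray(predicted_yield, dtype=float)
    if np.any(y < 0):
        raise ValueError("predicted yield must be >= 0")
    out = q * np.maximum(0.0, t_y * terms.crop_mean_yield - y)
    return float(out) if out.ndim == 0 else out


def actuarially_fair_price(
    payouts: Sequence[float] | np.ndarray,
    weights: Sequence[float] | np.ndarray | None = None,
) -> float:
    """Expected indemnity payout per insured unit.

    With ``weights`` (a probability vector over mortality states) this is
    the probability-weighted mean; without, the simple mean over observed
    seasons (the backcast or empirical pricing mode).
    """
    p = np.asarray(payouts, dtype=float)
    if p.size == 0:
        raise ValueError("no payouts to price over")
    if weights is None:
        return float(p.mean())
    w = np.asarray(weights, dtype=float)
    if w.shape != p.shape:
        raise ValueError("weights must match payouts in length")
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights sum to {w.sum()!r}, not 1")
    return float(p @ w)


def premium(afp: float, markup: float) -> float:
    """Market premium: AFP marked up by the loading m, p = AFP * (1 + m)."""
    if afp < 0:
        raise ValueError("afp must be >= 0")
    if markup < 0:
        raise ValueError("markup must be >= 0")
    return afp * (1.0 + markup)


def price_contract(
    payouts: Sequence[float] | np.ndarray,
    terms: ContractTerms,
    weights=None,
) -> PricedContract:
    """Price a contract from its backcast payouts (fractions of value)."""
    afp = actuarially_fair_price(payouts, weights)
    return PricedContract(terms=terms, afp=afp, premium=premium(afp, terms.markup))


def wealth_next(
    mortality,
    *,
    indemnity_paid=0.0,
    premium_paid: float = 0.0,
    insured: bool = False,
    insured_units: float = 1.0,
) -> np.ndarray | float:
    """Next-season wealth in fractions of one insured unit's value.

    Uninsured: k1 * (1 - M).  Insured: k1 * (1 - M) + I - p, with the
    premium charged every season, payout seasons included.  Natural herd
    growth is ignored.  Wealth can go non-positive (total loss plus
    premium); the welfare layer guards against that domain.
    """
    m = np.asarray(mortality, dtype=float)
    base = insured_units * (1.0 - m)
    if insured:
        base = base + np.asarray(indemnity_paid, dtype=float) - premium_paid
    return float(base) if base.ndim == 0 else base
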