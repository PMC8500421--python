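"""Expected-utility welfare engine for insurance-contract quality.

A household with constant-relative-risk-aversion (CRRA) preferences values
risky wealth k by U(k) = k^(1-rho) / (1-rho) (log utility at rho = 1).
Insurance quality is measured by how much a contract raises expected
utility over holding no insurance:

* IB  = EU(with contract) - EU(no insurance), the insurance benefit on the
  utility scale; IB > 0 is the minimum quality standard.
* IBhat = CE(with) - CE(without), the same benefit expressed in currency
  through certainty equivalents CE = U^{-1}(EU).
* RIB = IBhat(candidate) / IBhat(perfect contract), the relative insurance
  benefit: 1 means as good as a contract that observes losses perfectly,
  0 means worthless, negative means actively harmful.

A first-order Taylor decomposition writes IB as the sum over states of
(wealth transfer) x (shadow value of money) x (probability), which shows
*why* a contract scores as it does: payouts are valuable exactly when they
arrive in states where the marginal utility of wealth, lambda(k) = k^-rho,
is high.  Payout errors are classified season by season (false positives,
and small / intermediate / severe false negatives) following the same
logic.

Wealth enters in fractions of one insured unit's value; currency is a
final display scale, under which RIB is invariant (CRRA homotheticity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .contracts import ContractTerms, indemnity, price_contract

__all__ = [
    "WelfareParams",
    "WelfareReport",
    "utility",
    "shadow_value",
    "expected_utility",
    "certainty_equivalent",
    "insurance_benefit",
    "ib_hat",
    "rib",
    "decompose_ib",
    "classify_payouts",
    "evaluate_contract",
    "rho_sweep",
    "ERROR_CLASSES",
]

#: Payout error classes (exhaustive, mutually exclusive).
ERROR_CLASSES = ("TN", "FP", "FN_small", "FN_intermediate", "FN_severe")


@dataclass(frozen=True)
class WelfareParams:
    """Welfare-engine parameters.

    rho
        coefficient of relative risk aversion (default 2, a moderately
        risk-averse smallholder).
    wealth_floor
        minimum admissible wealth as a fraction of one insured unit's
        value.  ``None`` (default) raises a domain error on non-positive
        wealth; a small positive floor (e.g. 0.01) clips instead.
    lambda_at
        wealth at which the shadow value is evaluated in the Taylor
        decomposition: "uninsured" (default; the state the household is in
        absent the transfer) or "insured".
    fn_small, fn_severe
        shortfall thresholds (fractions of insured value) separating
        small / intermediate / severe false negatives; defaults 0.10, 0.30.
    """

    rho: float = 2.0
    wealth_floor: float | None = None
    lambda_at: str = "uninsured"
    fn_small: float = 0.10
    fn_severe: float = 0.30

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if self.lambda_at not in ("uninsured", "insured"):
            raise ValueError(f"lambda_at must be 'uninsured' or 'insured'")
        if not 0 < self.fn_small < self.fn_severe:
            raise ValueError("need 0 < fn_small < fn_severe")


def _guard_wealth(k: np.ndarray, params: WelfareParams, label: str) -> np.ndarray:
    if params.wealth_floor is not None:
        return np.maximum(k, params.wealth_floor)
    if np.any(k <= 0):
        j = int(np.argmin(k))
        raise ValueError(
            f"non-positive wealth in {label} series (state {j}: {k[j]:.6g}); "
            "CRRA utility is undefined at k <= 0 — set a wealth_floor or "
            "check premium and mortality inputs"
        )
    return k


def utility(k, rho: float):
    """CRRA utility U(k) = k^(1-rho)/(1-rho); ln(k) at rho = 1; k at rho = 0."""
    arr = np.asarray(k, dtype=float)
    if np.any(arr <= 0) and rho >= 1:
        bad = arr[arr <= 0]
        raise ValueError(f"utility undefined at non-positive wealth {bad.tolist()}")
    if rho == 1.0:
        out = np.log(arr)
    else:
        out = arr ** (1.0 - rho) / (1.0 - rho)
    return float(out) if out.ndim == 0 else out


def shadow_value(k, rho: float):
    """Marginal utility of wealth, lambda(k) = k^-rho.

    High in bad states (low wealth), low in good ones; constant 1 under
    risk neutrality (rho = 0).
    """
    arr = np.asarray(k, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("shadow value undefined at non-positive wealth")
    out = arr ** (-rho)
    return float(out) if out.ndim == 0 else out


def _weights(n: int, weights) -> np.ndarray:
    if weights is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(weights, dtype=float)
    if w.size != n:
        raise ValueError("weights length mismatch")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    return w


def expected_utility(wealth, rho: float, weights=None) -> float:
    """Probability-weighted mean utility over wealth states.

    With no weights, the empirical mode: the simple average across
    location-seasons.
    """
    k = np.asarray(wealth, dtype=float)
    w = _weights(k.size, weights)
    return float(utility(k, rho) @ w)


def certainty_equivalent(eu: float, rho: float) -> float:
    """The sure wealth whose utility equals the given expected utility.

    Inverts the CRRA utility: CE = [(1-rho) EU]^(1/(1-rho)) for rho != 1,
    exp(EU) for rho = 1, EU itself for rho = 0.
    """
    if rho == 1.0:
        return float(np.exp(eu))
    base = (1.0 - rho) * eu
    if base <= 0:
        raise ValueError(
            f"EU {eu} outside the CRRA utility range for rho={rho}"
        )
    return float(base ** (1.0 / (1.0 - rho)))


def insurance_benefit(eu_with: float, eu_without: float) -> float:
    """Utility-scale insurance benefit IB = EU_with - EU_without."""
    return eu_with - eu_without


def ib_hat(ce_with: float, ce_without: float) -> float:
    """Currency-scale insurance benefit: difference of certainty equivalents."""
    return ce_with - ce_without


def rib(ibhat_j: float, ibhat_p: float) -> float:
    """Relative insurance benefit: IBhat of the candidate over the perfect
    contract's.  At most 1 (up to rounding); negative when the candidate
    leaves the household worse off than no insurance.
    """
    if ibhat_p <= 0:
        raise ValueError(
            "perfect insurance offers no benefit on this data; RIB undefined"
        )
    return ibhat_j / ibhat_p


def decompose_ib(
    delta,
    wealth_uninsured,
    rho: float,
    weights=None,
    wealth_insured=None,
    lambda_at: str = "uninsured",
) -> pd.DataFrame:
    """First-order Taylor decomposition of the insurance benefit.

    Each state contributes delta_j * lambda_j * pi_j, where delta is the
    insured-minus-uninsured wealth transfer (indemnity minus premium) and
    lambda the shadow value of money in that state.  The sum approximates
    the exact IB, with error of second order in the transfer size.

    Returns a per-state DataFrame with attrs ``total`` (the Taylor sum),
    ``exact_ib`` and ``approx_error``.
    """
    d = np.asarray(delta, dtype=float)
    k_n = np.asarray(wealth_uninsured, dtype=float)
    w = _weights(d.size, weights)
    if lambda_at == "insured":
        if wealth_insured is None:
            wealth_insured = k_n + d
        lam = shadow_value(np.asarray(wealth_insured, dtype=float), rho)
    else:
        lam = shadow_value(k_n, rho)
    contrib = d * lam * w
    out = pd.DataFrame(
        {"delta": d, "lambda": lam, "weight": w, "contribution": contrib}
    )
    exact = expected_utility(k_n + d, rho, w) - expected_utility(k_n, rho, w)
    out.attrs["total"] = float(contrib.sum())
    out.attrs["exact_ib"] = float(exact)
    out.attrs["approx_error"] = float(abs(contrib.sum() - exact))
    return out


def classify_payouts(
    payout_perfect,
    payout_index,
    params: WelfareParams = WelfareParams(),
) -> np.ndarray:
    """Classify each season's payout error.

    The shortfall s = I_P - I_J is measured in fractions of the insured
    value (both payout series are already on that scale).  Classes:

    * TN — no payment due and none paid;
    * FP — the contract overpays (s < 0);
    * FN_severe — underpays by more than ``fn_severe`` (30%);
    * FN_intermediate — underpays between ``fn_small`` and ``fn_severe``;
    * FN_small — underpays by at most ``fn_small`` (exact payment included).

    The partition is exhaustive and exclusive.
    """
    ip = np.asarray(payout_perfect, dtype=float)
    ij = np.asarray(payout_index, dtype=float)
    if ip.shape != ij.shape:
        raise ValueError("payout series must align")
    s = ip - ij
    out = np.empty(ip.shape, dtype=object)
    out[(ip == 0) & (ij == 0)] = "TN"
    out[s < 0] = "FP"
    fn = (s >= 0) & (ip > 0)
    out[fn & (s <= params.fn_small)] = "FN_small"
    out[fn & (s > params.fn_small) & (s <= params.fn_severe)] = "FN_intermediate"
    out[fn & (s > params.fn_severe)] = "FN_severe"
    return out


@dataclass
class WelfareReport:
    """Full welfare accounting for one candidate contract.

    Expected utilities are on the internal scale (wealth in fractions of
    one insured unit's value); certainty equivalents and IBhat are in
    currency.  ``records`` holds the per-season payout table with error
    classes and decomposition terms.
    """

    rho: float
    n: int
    eu_n: float
    eu_j: float
    eu_p: float
    ce_n: float
    ce_j: float
    ce_p: float
    ib_j: float
    ib_p: float
    ibhat_j: float
    ibhat_p: float
    rib: float
    afp_j: float
    afp_p: float
    premium_j: float
    premium_p: float
    expected_wealth: float
    class_counts: dict[str, int] = field(default_factory=dict)
    records: pd.DataFrame | None = None

    def summary_dict(self) -> dict:
        """JSON-serializable summary (drops the per-season table)."""
        out = {
            k: v
            for k, v in self.__dict__.items()
            if k != "records"
        }
        return out


def evaluate_contract(
    mortality,
    predicted,
    terms: ContractTerms = ContractTerms(),
    params: WelfareParams = WelfareParams(),
    weights=None,
    keys: pd.DataFrame | None = None,
    strict_rib: bool = True,
) -> WelfareReport:
    """End-to-end welfare evaluation of an index contract.

    Takes observed mortality and model-predicted mortality per
    location-season (or per outcome state, with ``weights`` as the state
    probabilities), builds the perfect and index payout series, prices both
    contracts from their own backcast payouts, forms the three wealth
    series (uninsured, index-insured, perfect-insured), and computes the
    full chain EU -> CE -> IB -> RIB plus the payout-error classification
    and Taylor decomposition.

    ``keys`` (optional) is a DataFrame of identifying columns copied onto
    the per-season records.  With ``strict_rib=False`` a dataset on which
    perfect insurance offers no benefit yields RIB = NaN instead of an
    error (used by the rho sweep at the risk-neutral end).
    """
    m = np.asarray(mortality, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if m.shape != pred.shape:
        raise ValueError("mortality and predictions must align")
    if m.size == 0:
        raise ValueError("no observations")
    w = _weights(m.size, weights)

    i_p = indemnity(m, terms)
    i_j = indemnity(np.clip(pred, 0.0, 1.0), terms)
    perfect = price_contract(i_p, terms, weights)
    index = price_contract(i_j, terms, weights)

    k1 = terms.insured_units
    k_n = k1 * (1.0 - m)
    k_j = k_n + k1 * (i_j - index.premium)
    k_p = k_n + k1 * (i_p - perfect.premium)

    rho = params.rho
    k_n = _guard_wealth(k_n, params, "uninsured")
    k_j = _guard_wealth(k_j, params, "index-insured")
    k_p = _guard_wealth(k_p, params, "perfect-insured")

    eu_n = expected_utility(k_n, rho, w)
    eu_j = expected_utility(k_j, rho, w)
    eu_p = expected_utility(k_p, rho, w)
    ce_n = certainty_equivalent(eu_n, rho)
    ce_j = certainty_equivalent(eu_j, rho)
    ce_p = certainty_equivalent(eu_p, rho)

    ibhat_j = ib_hat(ce_j, ce_n)
    ibhat_p = ib_hat(ce_p, ce_n)
    if strict_rib or ibhat_p > 0:
        rib_value = rib(ibhat_j, ibhat_p)
    else:
        rib_value = float("nan")
    scale = terms.unit_value  # currency per unit of internal wealth

    classes = classify_payouts(i_p, i_j, params)
    counts = {c: int(np.sum(classes == c)) for c in ERROR_CLASSES}

    lam_wealth = k_j if params.lambda_at == "insured" else k_n
    records = pd.DataFrame(
        {
            "mortality": m,
            "predicted": pred,
            "payout_perfect": i_p,
            "payout_index": i_j,
            "delta": k1 * (i_j - index.premium),
            "lambda": shadow_value(lam_wealth, rho),
            "weight": w,
            "error_class": classes,
        }
    )
    if keys is not None:
        records = pd.concat(
            [keys.reset_index(drop=True), records.reset_index(drop=True)], axis=1
        )

    return WelfareReport(
        rho=rho,
        n=m.size,
        eu_n=eu_n,
        eu_j=eu_j,
        eu_p=eu_p,
        ce_n=ce_n * scale,
        ce_j=ce_j * scale,
        ce_p=ce_p * scale,
        ib_j=insurance_benefit(eu_j, eu_n),
        ib_p=insurance_benefit(eu_p, eu_n),
        ibhat_j=ibhat_j * scale,
        ibhat_p=ibhat_p * scale,
        rib=rib_value,
        afp_j=index.afp * scale * k1,
        afp_p=perfect.afp * scale * k1,
        premium_j=index.premium * scale * k1,
        premium_p=perfect.premium * scale * k1,
        expected_wealth=float(k_n @ w) * scale,
        class_counts=counts,
        records=records,
    )


def rho_sweep(
    mortality,
    predicted,
    terms: ContractTerms = ContractTerms(),
    rho_grid: Sequence[float] = tuple(np.round(np.arange(0.0, 3.01, 0.25), 2)),
    params: WelfareParams = WelfareParams(),
    weights=None,
) -> pd.DataFrame:
    """RIB (and the underlying benefits) over a grid of risk aversion rho.

    rho = 1 is handled by the log-utility branch.  At rho = 0 (risk
    neutrality) an actuarially fair perfect contract has IB exactly 0 and
    a marked-up one has IB < 0, so RIB is undefined; such grid points keep
    their IB values but report NaN RIB.
    """
    rows = []
    for r in rho_grid:
        p = WelfareParams(
            rho=float(r),
            wealth_floor=params.wealth_floor,
            lambda_at=params.lambda_at,
            fn_small=params.fn_small,
            fn_severe=params.fn_severe,
        )
        rep = evaluate_contract(
            mortality, predicted, terms, p, weights, strict_rib=False
        )
        rows.append(
            {
                "rho": float(r),
                "rib": rep.rib,
                "ib_j": rep.ib_j,
                "ib_p": rep.ib_p,
                "ibhat_j": rep.ibhat_j,
                "ibhat_p": rep.ibhat_p,
                "ce_n": rep.ce_n,
            }
        )
    return pd.DataFrame(rows)
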