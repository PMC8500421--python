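"""Model x index sweeps and k-fold cross-validation.

The sweep fits every requested (index, model) combination on one season
table and reports conventional goodness of fit (R-squared, RMSE) next to
the welfare-based quality measures (RIB, pricing, payout-error counts), so
the two views of index quality can be compared on one table.

Cross-validation refits each model on k-1 folds, pools the out-of-fold
predictions, and computes R-squared and RIB once on the pooled series —
one welfare number directly comparable to the in-sample one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contracts import ContractTerms, indemnity, price_contract
from .index_prep import zscore_frame
from .loss_models import (
    LossModelSpec,
    fit_model,
    goodness_of_fit,
    predict_mortality,
)
from .welfare import (
    ERROR_CLASSES,
    WelfareParams,
    certainty_equivalent,
    evaluate_contract,
    expected_utility,
    rib,
)

__all__ = ["IndexSpec", "CVResult", "sweep", "kfold_cv"]


@dataclass(frozen=True)
class IndexSpec:
    """One candidate index: a raw column plus preparation flags."""

    column: str
    log: bool = False
    season_stratified: bool = False

    @property
    def name(self) -> str:
        return f"L{self.column}" if self.log else self.column


def _coerce_index(spec) -> IndexSpec:
    if isinstance(spec, IndexSpec):
        return spec
    if isinstance(spec, str):
        return IndexSpec(spec)
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return IndexSpec(spec[0], bool(spec[1]))
    raise ValueError(f"cannot interpret index spec {spec!r}")


def sweep(
    df: pd.DataFrame,
    indices,
    models,
    terms: ContractTerms = ContractTerms(),
    params: WelfareParams = WelfareParams(),
) -> pd.DataFrame:
    """Fit and welfare-evaluate every (index, model) combination.

    ``indices`` is a list of column names, (column, log) pairs or
    :class:`IndexSpec`; ``models`` a list of model kinds or
    :class:`LossModelSpec`.  One row per combination, with failures of
    individual combinations recorded in an ``error`` column rather than
    aborting the sweep.  Rows are emitted in a canonical (index, model)
    order, so the result is independent of input row order.
    """
    index_specs = [_coerce_index(i) for i in indices]
    model_specs = [
        s if isinstance(s, LossModelSpec) else LossModelSpec(s) for s in models
    ]
    if not index_specs or not model_specs:
        raise ValueError("need at least one index and one model")

    df = df.sort_values(["location", "year", "season"]).reset_index(drop=True)
    m = df["mortality"].to_numpy(dtype=float)
    rows = []
    for ispec in index_specs:
        try:
            z = zscore_frame(
                df,
                ispec.column,
                log=ispec.log,
                season_stratified=ispec.season_stratified,
            ).frame["z"].to_numpy()
        except Exception as exc:  # per-row failure capture
            for mspec in model_specs:
                rows.append(
                    {"index": ispec.name, "model": mspec.kind.value, "error": str(exc)}
                )
            continue
        for mspec in model_specs:
            row = {"index": ispec.name, "model": mspec.kind.value, "error": ""}
            try:
                fit = fit_model(mspec, z, m)
                gof = goodness_of_fit(fit, z, m)
                pred = predict_mortality(fit, z)
                rep = evaluate_contract(m, pred, terms, params)
                row.update(
                    r_squared=gof["r_squared"],
                    rmse=gof["rmse"],
                    rib=rep.rib,
                    afp=rep.afp_j,
                    premium=rep.premium_j,
                    **{f"n_{c}": rep.class_counts[c] for c in ERROR_CLASSES},
                )
            except Exception as exc:
                row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """k-fold cross-validation outcome for one model spec."""

    k: int
    seed: int
    spec: LossModelSpec
    fold_of: np.ndarray
    predictions: np.ndarray
    r_squared_cv: float
    r_squared_in: float
    rib_cv: float
    rib_in: float
    fold_r_squared: list[float] = field(default_factory=list)


def _make_folds(n: int, k: int, rng: np.random.Generator, block_by=None) -> np.ndarray:
    """Fold index per record: random records, or whole blocks (locations)."""
    fold_of = np.empty(n, dtype=int)
    if block_by is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k)):
            fold_of[chunk] = f
    else:
        blocks = np.asarray(block_by)
        uniq = rng.permutation(np.unique(blocks))
        if uniq.size < k:
            raise ValueError(f"only {uniq.size} blocks for {k} folds")
        for f, chunk in enumerate(np.array_split(uniq, k)):
            fold_of[np.isin(blocks, chunk)] = f
    return fold_of


def kfold_cv(
    z,
    mortality,
    spec: LossModelSpec,
    terms: ContractTerms = ContractTerms(),
    params: WelfareParams = WelfareParams(),
    k: int = 5,
    seed: int = 0,
    block_by=None,
    price_on: str = "pooled_oof",
) -> CVResult:
    """k-fold cross-validated goodness of fit and welfare quality.

    Records are partitioned into ``k`` random folds (seeded; or whole
    locations with ``block_by``), the model is refit on each training
    split, and the out-of-fold predictions are pooled into one series
    covering every record exactly once.  R-squared and RIB are computed on
    that pooled series.

    ``price_on`` selects how the index contract premium is set: a single
    pricing pass over the pooled out-of-fold payouts (``"pooled_oof"``,
    default) or per-fold pricing from each training split's backcast
    payouts (``"train_folds"``), under which each record carries its own
    fold's premium.
    """
    z = np.asarray(z, dtype=float)
    m = np.asarray(mortality, dtype=float)
    n = z.size
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n records ({k} folds, {n} records)")
    spec = spec if isinstance(spec, LossModelSpec) else LossModelSpec(spec)
    rng = np.random.default_rng(seed)
    fold_of = _make_folds(n, k, rng, block_by)

    pooled = np.empty(n)
    fold_r2 = []
    train_premium = np.empty(n)
    for f in range(k):
        test = fold_of == f
        train = ~test
        try:
            fit = fit_model(spec, z[train], m[train])
        except Exception as exc:
            raise ValueError(f"degenerate design in fold {f}: {exc}") from exc
        pooled[test] = predict_mortality(fit, z[test])
        if np.ptp(m[test]) > 0:
            fold_r2.append(goodness_of_fit(fit, z[test], m[test])["r_squared"])
        else:  # singleton or constant fold: per-fold R^2 undefined
            fold_r2.append(float("nan"))
        payouts_train = indemnity(predict_mortality(fit, z[train]), terms)
        train_premium[test] = price_contract(payouts_train, terms).premium

    in_fit = fit_model(spec, z, m)
    in_pred = predict_mortality(in_fit, z)
    r2_in = goodness_of_fit(in_fit, z, m)["r_squared"]
    rib_in = evaluate_contract(m, in_pred, terms, params).rib

    sse = float(np.sum((m - pooled) ** 2))
    sst = float(np.sum((m - m.mean()) ** 2))
    r2_cv = 1.0 - sse / sst

    if price_on == "pooled_oof":
        rib_cv = evaluate_contract(m, pooled, terms, params).rib
    elif price_on == "train_folds":
        rib_cv = _rib_with_premium(m, pooled, train_premium, terms, params)
    else:
        raise ValueError(f"unknown price_on mode {price_on!r}")

    return CVResult(
        k=k,
        seed=seed,
        spec=spec,
        fold_of=fold_of,
        predictions=pooled,
        r_squared_cv=r2_cv,
        r_squared_in=r2_in,
        rib_cv=rib_cv,
        rib_in=rib_in,
        fold_r_squared=fold_r2,
    )


def _rib_with_premium(m, pred, premium_j, terms, params) -> float:
    """RIB when the index premium varies by record (per-fold pricing)."""
    i_p = indemnity(m, terms)
    i_j = indemnity(np.clip(pred, 0.0, 1.0), terms)
    perfect = price_contract(i_p, terms)
    k1 = terms.insured_units
    k_n = k1 * (1.0 - m)
    k_j = k_n + k1 * (i_j - np.asarray(premium_j))
    k_p = k_n + k1 * (i_p - perfect.premium)
    rho = params.rho
    ce = lambda kk: certainty_equivalent(expected_utility(kk, rho), rho)
    ce_n, ce_j, ce_p = ce(k_n), ce(k_j), ce(k_p)
    return rib(ce_j - ce_n, ce_p - ce_n)
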