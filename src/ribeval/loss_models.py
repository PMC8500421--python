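"""Mortality loss models: map standardized forage-index z-scores to
predicted livestock mortality.

Five model kinds are supported, all with mortality M as response and the
index z-score as the single regressor:

``lm``
    ordinary least squares over all observations,
        M = b0 + b1 * z + e.
``lm0`` / ``lm5``
    the same line, but estimated only on the subset z < 0 (resp.
    z < -0.5), where forage scarcity actually drives mortality; the fitted
    line is extrapolated over all z when predicting.
``sm``
    continuous segmented (broken-stick) regression with an estimated
    breakpoint psi,
        M = b0 + b1 * z + b02 * (z - psi) * 1[z > psi] + e,
    so the slope is b1 below the break and b1 + b02 above it.
``qr``
    linear conditional-quantile regression at quantile tau (default the
    77th percentile), minimizing the pinball (check) loss.

Predictions are clipped to [0, 1] at prediction time; fitting is always
done on the raw scale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "ModelKind",
    "LossModelSpec",
    "FittedLossModel",
    "fit_linear",
    "fit_truncated",
    "fit_segmented",
    "fit_quantile",
    "fit_model",
    "predict_mortality",
    "goodness_of_fit",
    "pinball_loss",
]

#: Minimum observations on each side of a candidate breakpoint.
MIN_SEG = 3


class ModelKind(str, enum.Enum):
    LM = "lm"
    LM0 = "lm0"
    LM5 = "lm5"
    SM = "sm"
    QR = "qr"


@dataclass(frozen=True)
class LossModelSpec:
    """Which model to fit, and its fixed hyperparameters.

    ``cutoff`` is the z threshold of the truncated fits (0 for lm0, -0.5
    for lm5); ``tau`` the target quantile of the qr fit.
    """

    kind: ModelKind
    cutoff: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is ModelKind.LM0 and self.cutoff is None:
            object.__setattr__(self, "cutoff", 0.0)
        if kind is ModelKind.LM5 and self.cutoff is None:
            object.__setattr__(self, "cutoff", -0.5)
        if kind is ModelKind.QR:
            tau = 0.77 if self.tau is None else float(self.tau)
            if not 0.0 < tau < 1.0:
                raise ValueError(f"tau must be in (0, 1), got {tau}")
            object.__setattr__(self, "tau", tau)


@dataclass
class FittedLossModel:
    """Coefficients and fit diagnostics of a fitted loss model."""

    spec: LossModelSpec
    beta0: float
    beta1: float
    beta02: float | None = None
    psi: float | None = None
    n_fit: int = 0
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    sse: float = float("nan")
    #: achieved pinball objective (qr only)
    objective: float | None = None

    def coefficients(self) -> dict[str, float]:
        out = {"beta0": self.beta0, "beta1": self.beta1}
        if self.spec.kind is ModelKind.SM:
            out.update(beta02=self.beta02, psi=self.psi)
        return out


def _as_xy(z, m) -> tuple[np.ndarray, np.ndarray]:
    z = np.asarray(z, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    if z.shape != m.shape:
        raise ValueError("z and mortality must have equal length")
    if np.isnan(z).any() or np.isnan(m).any():
        raise ValueError("NaN in fitting data")
    return z, m


def fit_linear(z, m) -> FittedLossModel:
    """OLS fit of mortality on the index z-score (model kind ``lm``)."""
    z, m = _as_xy(z, m)
    if z.size < 3:
        raise ValueError(f"need >= 3 observations, got {z.size}")
    if np.ptp(z) == 0:
        raise ValueError("degenerate design: all z equal")
    X = np.column_stack([np.ones_like(z), z])
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ beta
    return FittedLossModel(
        spec=LossModelSpec(ModelKind.LM),
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        n_fit=z.size,
        residuals=resid,
        sse=float(resid @ resid),
    )


def fit_truncated(z, m, cutoff: float) -> FittedLossModel:
    """OLS restricted to observations with z below ``cutoff``.

    Identical to :func:`fit_linear` on the subset z < cutoff; the fitted
    line is later extrapolated over the full z range when predicting.
    """
    z, m = _as_xy(z, m)
    mask = z < cutoff
    if mask.sum() < 3:
        raise ValueError(
            f"only {int(mask.sum())} observations with z < {cutoff}; need >= 3"
        )
    sub = fit_linear(z[mask], m[mask])
    kind = ModelKind.LM5 if cutoff == -0.5 else ModelKind.LM0
    return FittedLossModel(
        spec=LossModelSpec(kind, cutoff=cutoff),
        beta0=sub.beta0,
        beta1=sub.beta1,
        n_fit=sub.n_fit,
        residuals=sub.residuals,
        sse=sub.sse,
    )


def _segmented_sse(z: np.ndarray, m: np.ndarray, psi: float):
    """Exact OLS of the continuous two-slope model at fixed breakpoint."""
    hinge = np.where(z > psi, z - psi, 0.0)
    X = np.column_stack([np.ones_like(z), z, hinge])
    beta, *_ = np.linalg.lstsq(X, m, rcond=None)
    resid = m - X @ beta
    return float(resid @ resid), beta, resid


def fit_segmented(z, m, *, min_seg: int = MIN_SEG, refine_tol: float = 1e-8) -> FittedLossModel:
    """Segmented (broken-stick) regression with estimated breakpoint.

    The breakpoint psi is found by profiling the SSE over every observed z
    value that leaves at least ``min_seg`` observations on each side, then
    refining the best candidate with a golden-section search between its
    grid neighbours.  For fixed psi the remaining parameters are exact OLS
    on the regressors {1, z, (z - psi) * 1[z > psi]}.  Ties in the profile
    break toward the smallest psi.
    """
    z, m = _as_xy(z, m)
    if z.size < 2 * min_seg:
        raise ValueError(f"need >= {2 * min_seg} observations, got {z.size}")
    zs = np.sort(np.unique(z))
    order = np.sort(z)
    lo, hi = order[min_seg - 1], order[-min_seg]
    candidates = zs[(zs >= lo) & (zs <= hi)]
    if candidates.size == 0:
        raise ValueError(
            "no admissible breakpoint candidate leaves "
            f"{min_seg} observations on each side"
        )

    sses = np.array([_segmented_sse(z, m, psi)[0] for psi in candidates])
    best = int(np.argmin(sses))  # argmin takes the first (smallest psi) on ties

    # golden-section refinement between the neighbouring candidates
    a = candidates[max(best - 1, 0)]
    b = candidates[min(best + 1, candidates.size - 1)]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = _segmented_sse(z, m, c)[0], _segmented_sse(z, m, d)[0]
    while b - a > refine_tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = _segmented_sse(z, m, c)[0]
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = _segmented_sse(z, m, d)[0]
    psi_ref = 0.5 * (a + b)
    sse_ref, beta_ref, resid_ref = _segmented_sse(z, m, psi_ref)

    if sse_ref <= sses[best]:
        psi, sse = psi_ref, sse_ref
        beta, resid = beta_ref, resid_ref
    else:
        psi = float(candidates[best])
        sse, beta, resid = _segmented_sse(z, m, psi)
    return FittedLossModel(
        spec=LossModelSpec(ModelKind.SM),
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta02=float(beta[2]),
        psi=float(psi),
        n_fit=z.size,
        residuals=resid,
        sse=float(sse),
    )


def pinball_loss(u: np.ndarray, tau: float) -> float:
    """Check-loss sum: rho_tau(u) = u * (tau - 1[u < 0])."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def fit_quantile(z, m, tau: float = 0.77) -> FittedLossModel:
    """Linear conditional-quantile regression at quantile ``tau``.

    Solves the exact linear program

        min_{b0, b1, u+, u-}  tau * sum(u+) + (1 - tau) * sum(u-)
        s.t.  u+ - u- = M - b0 - b1 * z,   u+, u- >= 0

    with the HiGHS solver, so the achieved pinball objective is the global
    optimum (deterministic, no iteration-budget failures on well-posed
    data).
    """
    z, m = _as_xy(z, m)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if z.size < 10:
        raise ValueError(f"need >= 10 observations for a quantile fit, got {z.size}")
    if np.ptp(z) == 0:
        raise ValueError("degenerate design: all z equal")

    n = z.size
    # variables: [b0+, b0-, b1+, b1-, u+ (n), u- (n)]
    c = np.concatenate([[0.0, 0.0, 0.0, 0.0], np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.zeros((n, 4 + 2 * n))
    A_eq[:, 0] = 1.0
    A_eq[:, 1] = -1.0
    A_eq[:, 2] = z
    A_eq[:, 3] = -z
    A_eq[np.arange(n), 4 + np.arange(n)] = 1.0
    A_eq[np.arange(n), 4 + n + np.arange(n)] = -1.0
    res = linprog(c, A_eq=A_eq, b_eq=m, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"quantile fit failed: {res.message}")
    x = res.x
    beta0 = float(x[0] - x[1])
    beta1 = float(x[2] - x[3])
    resid = m - beta0 - beta1 * z
    return FittedLossModel(
        spec=LossModelSpec(ModelKind.QR, tau=tau),
        beta0=beta0,
        beta1=beta1,
        n_fit=n,
        residuals=resid,
        sse=float(resid @ resid),
        objective=pinball_loss(resid, tau),
    )


def fit_model(spec: LossModelSpec, z, m, *, min_seg: int = MIN_SEG) -> FittedLossModel:
    """Dispatch on the model kind."""
    spec = spec if isinstance(spec, LossModelSpec) else LossModelSpec(spec)
    kind = spec.kind
    if kind is ModelKind.LM:
        return fit_linear(z, m)
    if kind in (ModelKind.LM0, ModelKind.LM5):
        cutoff = spec.cutoff if spec.cutoff is not None else (
            0.0 if kind is ModelKind.LM0 else -0.5
        )
        return fit_truncated(z, m, cutoff)
    if kind is ModelKind.SM:
        return fit_segmented(z, m, min_seg=min_seg)
    if kind is ModelKind.QR:
        return fit_quantile(z, m, spec.tau if spec.tau is not None else 0.77)
    raise ValueError(f"unknown model kind {kind!r}")


def predict_mortality(model: FittedLossModel, z) -> np.ndarray:
    """Predicted mortality at z, clipped to [0, 1].

    Truncated fits (lm0, lm5) extrapolate their line over the full range;
    the segmented model evaluates its two-slope form.  Total function on
    the reals: returns a float for scalar input.
    """
    z_arr = np.asarray(z, dtype=float)
    raw = model.beta0 + model.beta1 * z_arr
    if model.spec.kind is ModelKind.SM:
        raw = raw + model.beta02 * np.where(z_arr > model.psi, z_arr - model.psi, 0.0)
    out = np.clip(raw, 0.0, 1.0)
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def goodness_of_fit(model: FittedLossModel, z, m) -> dict[str, float]:
    """R-squared and RMSE on the supplied evaluation set.

    R^2 = 1 - SSE/SST with SST about the mean of the evaluation mortality;
    RMSE = sqrt(SSE/n).  For truncated fits this is conventionally computed
    on the full dataset with extrapolated (clipped) predictions, so all
    model kinds share one axis; pass the subset instead for subset-only
    scores.
    """
    z, m = _as_xy(z, m)
    pred = predict_mortality(model, z)
    sse = float(np.sum((m - pred) ** 2))
    sst = float(np.sum((m - m.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant mortality in evaluation set: R^2 undefined")
    return {"r_squared": 1.0 - sse / sst, "rmse": float(np.sqrt(sse / m.size))}
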