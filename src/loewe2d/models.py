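"""Biphasic (inverted v-shaped) dose-response models and two-dimensional effective doses.

Inducible whole-cell biosensors respond to an analyte with a peak-shaped
("inverted v") dose-response curve: the signal (e.g. a bioluminescence
induction factor, BIF) rises with dose up to a maximum at the maximum
permissive concentration (MPC) and declines beyond it as toxicity sets in.
Two five-parameter peak functions are provided:

* ``gaussian`` -- a split (bi-)Gaussian in dose,
* ``loggaussian`` -- a split Gaussian in log-dose.

Both share a baseline ``c``, a peak response ``d`` (= E_max) attained at dose
``e`` (= MPC), a left-branch width ``b`` and an asymmetry ratio ``f`` (the
right-branch width is ``b * f``):

    response(x) = c + (d - c) * exp(-0.5 * (delta / w)^2)

with ``delta = x - e`` (gaussian) or ``ln x - ln e`` (loggaussian) and
``w = b`` on the ascending branch (delta <= 0), ``w = b * f`` on the
descending branch.

Because the curve is non-monotonic, a scalar effective dose is ambiguous.
The fractional effect ``p`` in [-100, 100] indexes positions on the curve:
``p = 0`` is the peak, ``p < 0`` the induction (ascending) branch and
``p > 0`` the inhibition (descending) branch. The two-dimensional effective
dose ED_p = (D_(p), E_(p)) couples the dose achieving fractional effect p
with the empirical response attained there,

    E_(p) = c + (1 - |p|/100) * (d - c),

so curves with different maximal effects share one fractional scale while the
empirical effect axis is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ModelKind",
    "DoseResponseDataset",
    "BiphasicModel",
    "FitResult",
    "EDpVector",
    "InvalidInputError",
    "InvalidStateError",
    "FitFailureError",
    "evaluate",
    "effect_at_p",
    "dose_at_p",
    "edp",
    "fit_biphasic",
    "select_model",
    "BOXCOX_LAMBDA_GRID",
]

ModelKind = Literal["gaussian", "loggaussian"]

#: Default Box-Cox exponent grid for the transform-both-sides fit.
BOXCOX_LAMBDA_GRID: tuple[float, ...] = (-1.0, -0.5, 0.0, 0.33, 0.5, 1.0)


class InvalidInputError(ValueError):
    """An argument violates an operation's contract."""


class InvalidStateError(RuntimeError):
    """Inputs are individually valid but jointly unusable (e.g. zero doses)."""


class FitFailureError(RuntimeError):
    """All candidate model fits failed."""

    def __init__(self, failures: dict[str, str]):
        self.failures = dict(failures)
        msg = "; ".join(f"{k}: {v}" for k, v in failures.items())
        super().__init__(f"all candidate fits failed ({msg})")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseResponseDataset:
    """Tidy replicate-level observations for one compound or one mixture ray.

    Parameters
    ----------
    series_id
        Label of the compound or mixture ray.
    dose
        Concentrations (>= 0, consistent units; total dose for mixtures).
    response
        Empirical effect on the tau scale (e.g. BIF), same length as ``dose``.
    replicate
        Integer replicate labels, same length as ``dose``.
    """

    series_id: str
    dose: np.ndarray
    response: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        response = np.asarray(self.response, dtype=float)
        replicate = np.asarray(self.replicate, dtype=int)
        if not (dose.shape == response.shape == replicate.shape) or dose.ndim != 1:
            raise InvalidInputError("dose, response and replicate must be 1-d arrays of equal length")
        if dose.size == 0:
            raise InvalidInputError("empty dataset")
        if not np.all(np.isfinite(dose)) or np.any(dose < 0):
            raise InvalidInputError("all doses must be finite and >= 0")
        if not np.all(np.isfinite(response)):
            raise InvalidInputError("all responses must be finite")
        object.__setattr__(self, "dose", dose)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "replicate", replicate)

    @property
    def n_dose_levels(self) -> int:
        return int(np.unique(self.dose).size)

    @property
    def n_replicates(self) -> int:
        return int(np.unique(self.replicate).size)

    def subset_replicate(self, rep: int) -> "DoseResponseDataset":
        mask = self.replicate == rep
        return DoseResponseDataset(self.series_id, self.dose[mask], self.response[mask], self.replicate[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "series_id": self.series_id,
                "dose": self.dose,
                "response": self.response,
                "replicate": self.replicate,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, series_id: str | None = None) -> "DoseResponseDataset":
        if series_id is None:
            ids = df["series_id"].unique()
            if len(ids) != 1:
                raise InvalidInputError(f"frame holds {len(ids)} series; pass series_id explicitly")
            series_id = str(ids[0])
        else:
            df = df[df["series_id"] == series_id]
            if df.empty:
                raise InvalidInputError(f"series {series_id!r} not present in frame")
        return cls(
            series_id=series_id,
            dose=df["dose"].to_numpy(float),
            response=df["response"].to_numpy(float),
            replicate=df["replicate"].to_numpy(int),
        )


@dataclass(frozen=True)
class BiphasicModel:
    """A fitted five-parameter peak curve.

    ``d`` is the peak response E_max attained at dose ``e`` (the MPC); ``c``
    is the baseline approached in both tails; ``b`` is the left-branch width
    (dose units for ``gaussian``, log-dose units for ``loggaussian``) and
    ``f`` the right/left width ratio (``f = 1`` means a symmetric peak).
    """

    kind: ModelKind
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "loggaussian"):
            raise InvalidInputError(f"unknown model kind {self.kind!r}")
        if not all(np.isfinite([self.b, self.c, self.d, self.e, self.f])):
            raise InvalidInputError("model parameters must be finite")
        if self.b <= 0 or self.f <= 0:
            raise InvalidInputError("widths b and asymmetry f must be > 0")
        if self.c < 0:
            raise InvalidInputError("baseline c must be >= 0")
        if self.d <= self.c:
            raise InvalidInputError("peak d must exceed baseline c")
        if self.kind == "loggaussian" and self.e <= 0:
            raise InvalidInputError("loggaussian peak location e must be > 0")

    @property
    def e_max(self) -> float:
        """Peak response (alias of ``d``)."""
        return self.d

    @property
    def mpc(self) -> float:
        """Maximum permissive concentration (alias of ``e``)."""
        return self.e

    # convenience method forms of the module-level operations
    def __call__(self, dose):
        return evaluate(self, dose)

    def edp(self, p: float) -> "EDpVector":
        return edp(self, p)


@dataclass(frozen=True)
class EDpVector:
    """Two-dimensional effective dose (p, D_(p), E_(p))."""

    p: float
    dose: float
    effect: float


@dataclass(frozen=True)
class FitResult:
    """Outcome of a biphasic least-squares fit."""

    model: BiphasicModel
    rss: float
    n_obs: int
    converged: bool
    param_covariance: np.ndarray | None = None
    boxcox_lambda: float | None = None
    message: str = ""
    rss_untransformed: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.rss < 0:
            raise InvalidInputError("rss must be >= 0")


# ---------------------------------------------------------------------------
# Model evaluation and inversion
# ---------------------------------------------------------------------------


def _delta_and_width(model: BiphasicModel, dose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if model.kind == "gaussian":
        delta = dose - model.e
    else:
        with np.errstate(divide="ignore"):
            delta = np.where(dose > 0, np.log(np.where(dose > 0, dose, 1.0)) - np.log(model.e), -np.inf)
    width = np.where(delta <= 0, model.b, model.b * model.f)
    return delta, width


def evaluate(model: BiphasicModel, dose) -> np.ndarray | float:
    """Response of a biphasic model at one or more doses.

    For the log-Gaussian, a dose of 0 is handled as the left-tail limit and
    returns the baseline ``c``.
    """
    arr = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("dose must be finite")
    if np.any(arr < 0):
        raise InvalidInputError("dose must be >= 0")
    delta, width = _delta_and_width(model, arr)
    with np.errstate(over="ignore"):
        z = np.where(np.isneginf(delta), np.inf, np.abs(delta) / width)
        resp = model.c + (model.d - model.c) * np.exp(-0.5 * np.square(np.where(np.isfinite(z), z, np.inf)))
    if arr.ndim == 0:
        return float(resp)
    return resp


def _check_p(p, *, open_interval: bool) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("fractional effect p must be finite")
    inside = (arr > -100.0) & (arr < 100.0) if open_interval else (arr >= -100.0) & (arr <= 100.0)
    if not np.all(inside):
        bracket = "(-100, 100)" if open_interval else "[-100, 100]"
        raise InvalidInputError(f"fractional effect p must lie in {bracket}")
    return arr


def effect_at_p(model: BiphasicModel, p) -> np.ndarray | float:
    """Empirical effect E_(p) at fractional effect(s) ``p``.

    Interpolates between baseline ``c`` (|p| = 100) and peak ``d`` (p = 0);
    depends on ``p`` only through |p|, so the induction-branch and
    inhibition-branch vectors at +/-p share the same effect component.
    """
    arr = _check_p(p, open_interval=False)
    out = model.c + (1.0 - np.abs(arr) / 100.0) * (model.d - model.c)
    return float(out) if arr.ndim == 0 else out


def dose_at_p(model: BiphasicModel, p) -> np.ndarray | float:
    """Dose D_(p) achieving fractional effect(s) ``p`` (closed-form inversion).

    Negative ``p`` selects the ascending (induction) branch, positive ``p``
    the descending (inhibition) branch; ``p = 0`` returns the MPC. For the
    plain Gaussian a left-branch dose below 0 is clipped to 0 with a warning
    (the model then has no attainable dose for that p).
    """
    arr = _check_p(p, open_interval=True)
    s = np.sqrt(-2.0 * np.log1p(-np.abs(arr) / 100.0))
    width = np.where(arr < 0, model.b, model.b * model.f)
    signed = np.sign(arr) * width * s
    if model.kind == "gaussian":
        dose = model.e + signed
        if np.any(dose < 0):
            warnings.warn(
                "gaussian dose at some p is negative; clipped to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            dose = np.maximum(dose, 0.0)
    else:
        dose = model.e * np.exp(signed)
    return float(dose) if arr.ndim == 0 else dose


def edp(model: BiphasicModel, p: float) -> EDpVector:
    """Two-dimensional effective dose ED_p = (D_(p), E_(p))."""
    return EDpVector(p=float(p), dose=dose_at_p(model, p), effect=effect_at_p(model, p))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    if lam == 0.0:
        return np.log(y)
    return (np.power(y, lam) - 1.0) / lam


def _predict_raw(kind: ModelKind, theta: np.ndarray, dose: np.ndarray) -> np.ndarray:
    # theta = (b, c, amp, e, f) with amp = d - c, all bounded positive
    b, c, amp, e, f = theta
    if kind == "gaussian":
        delta = dose - e
    else:
        with np.errstate(divide="ignore"):
            delta = np.where(dose > 0, np.log(np.where(dose > 0, dose, 1.0)) - np.log(e), -np.inf)
    width = np.where(delta <= 0, b, b * f)
    with np.errstate(over="ignore"):
        z = np.where(np.isneginf(delta), np.inf, np.abs(delta) / width)
        return c + amp * np.exp(-0.5 * np.square(np.where(np.isfinite(z), z, np.inf)))


def _initial_theta(kind: ModelKind, dose: np.ndarray, response: np.ndarray) -> np.ndarray:
    """Moment-style initial values from the per-dose mean response profile."""
    df = pd.DataFrame({"dose": dose, "response": response}).groupby("dose")["response"].mean()
    doses = df.index.to_numpy(float)
    means = df.to_numpy(float)
    i_peak = int(np.argmax(means))
    e0 = doses[i_peak]
    d0 = float(means[i_peak])
    c0 = max(float(means.min()), 0.0)
    amp0 = max(d0 - c0, 1e-6 * max(d0, 1.0))
    if kind == "loggaussian" and e0 <= 0:
        pos = doses[doses > 0]
        e0 = float(pos.min()) if pos.size else 1.0

    def axis(x: np.ndarray) -> np.ndarray:
        if kind == "gaussian":
            return x
        return np.log(np.where(x > 0, x, np.nan))

    ax = axis(doses)
    span = np.nanmax(ax) - np.nanmin(ax)
    half = c0 + 0.5 * amp0
    left = np.where((doses < e0) & (means < half))[0]
    if left.size and np.isfinite(ax[left[-1]]):
        b0 = 0.5 * abs(axis(np.array([e0]))[0] - ax[left[-1]])
    else:
        b0 = span / 4.0
    b0 = max(b0, 1e-3)
    return np.array([b0, c0, amp0, e0 if kind == "gaussian" else max(e0, 1e-9), 1.0])


def _theta_to_model(kind: ModelKind, theta: np.ndarray) -> BiphasicModel:
    b, c, amp, e, f = (float(v) for v in theta)
    return BiphasicModel(kind=kind, b=b, c=max(c, 0.0), d=max(c, 0.0) + amp, e=e, f=f)


def _fit_theta(
    kind: ModelKind,
    dose: np.ndarray,
    response: np.ndarray,
    theta0: np.ndarray,
    lam: float | None,
    max_iter: int,
) -> tuple[np.ndarray, float, bool, np.ndarray | None]:
    tiny = 1e-12
    lower = np.array([tiny, 0.0, tiny, tiny if kind == "loggaussian" else -np.inf, tiny])
    upper = np.full(5, np.inf)
    y = response
    if lam is not None:
        y = _boxcox(np.maximum(response, tiny), lam)

    def residuals(theta: np.ndarray) -> np.ndarray:
        pred = _predict_raw(kind, theta, dose)
        if lam is not None:
            pred = _boxcox(np.maximum(pred, tiny), lam)
        return pred - y

    theta0 = np.clip(theta0, lower + tiny, None)
    try:
        sol = optimize.least_squares(
            residuals,
            theta0,
            bounds=(lower, upper),
            max_nfev=max_iter,
            method="trf",
            x_scale="jac",
        )
    except Exception:  # pragma: no cover - optimizer-internal failure
        return theta0, np.inf, False, None
    rss = float(2.0 * sol.cost)
    cov = None
    if sol.jac is not None and sol.jac.size:
        try:
            jtj = sol.jac.T @ sol.jac
            dof = max(len(y) - 5, 1)
            cov = np.linalg.pinv(jtj) * rss / dof
        except np.linalg.LinAlgError:
            cov = None
    return sol.x, rss, bool(sol.success), cov


def fit_biphasic(
    data: DoseResponseDataset,
    kind: ModelKind = "loggaussian",
    *,
    boxcox: bool = False,
    lambda_grid: Sequence[float] = BOXCOX_LAMBDA_GRID,
    max_iter: int = 2000,
    multistart: bool = True,
) -> FitResult:
    """Least-squares fit of a biphasic model to replicate-level data.

    Parameters are estimated under the bounds ``b > 0``, ``c >= 0``,
    ``d > c`` (via the amplitude ``d - c``), ``e > 0`` (log-Gaussian) and
    ``f > 0``. With ``boxcox=True`` the same Box-Cox power transform is
    applied to observations and model predictions (transform-both-sides)
    and the exponent ``lambda`` is chosen on ``lambda_grid`` by maximum
    profile likelihood; ``rss`` is then reported on the transformed scale
    while ``rss_untransformed`` carries the raw-scale residual sum of
    squares. With ``multistart=True`` the initial width and asymmetry are
    jittered by factors {0.5, 1, 2} and the best solution kept.

    A fit that does not converge, or that collapses to a degenerate
    (near-flat) curve, is returned with ``converged=False`` rather than
    raising.
    """
    if data.n_dose_levels < 5:
        raise InvalidInputError(
            f"need at least 5 distinct dose levels to fit, got {data.n_dose_levels}"
        )
    dose, response = data.dose, data.response
    theta0 = _initial_theta(kind, dose, response)

    # warn when the sampled doses do not straddle the empirical peak
    means = pd.DataFrame({"d": dose, "r": response}).groupby("d")["r"].mean()
    if means.idxmax() in (means.index.min(), means.index.max()):
        warnings.warn(
            f"series {data.series_id!r}: maximal mean response at the edge of the dose "
            "range; doses may not span both branches of the peak",
            RuntimeWarning,
            stacklevel=2,
        )

    starts = [theta0]
    if multistart:
        for kb in (0.5, 2.0):
            for kf in (0.5, 2.0):
                t = theta0.copy()
                t[0] *= kb
                t[4] *= kf
                starts.append(t)

    def best_fit(lam: float | None) -> tuple[np.ndarray, float, bool, np.ndarray | None]:
        results = [_fit_theta(kind, dose, response, t0, lam, max_iter) for t0 in starts]
        finite = [r for r in results if np.isfinite(r[1])]
        if not finite:
            return results[0]
        return min(finite, key=lambda r: r[1])

    lam_chosen: float | None = None
    if boxcox:
        if np.any(response <= 0):
            raise InvalidInputError("Box-Cox transform-both-sides requires strictly positive responses")
        n = len(response)
        log_y_sum = float(np.sum(np.log(response)))
        best = None
        for lam in lambda_grid:
            theta, rss, ok, cov = best_fit(lam)
            if not np.isfinite(rss) or rss <= 0:
                continue
            loglik = -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_y_sum
            if best is None or loglik > best[0]:
                best = (loglik, lam, theta, rss, ok, cov)
        if best is None:
            theta, rss, ok, cov = best_fit(None)
        else:
            _, lam_chosen, theta, rss, ok, cov = best
    else:
        theta, rss, ok, cov = best_fit(None)

    # degenerate amplitude: flat data cannot identify a peak
    amp = theta[2]
    scale = max(float(np.max(np.abs(response))), 1e-12)
    degenerate = amp < 1e-6 * scale
    converged = ok and not degenerate and np.isfinite(rss)
    message = "" if converged else ("degenerate (near-flat) fit" if degenerate else "optimizer did not converge")

    try:
        model = _theta_to_model(kind, theta)
    except InvalidInputError:
        # force a representable model; flag non-convergence
        theta = np.maximum(theta, 1e-9)
        theta[2] = max(theta[2], 1e-9)
        model = _theta_to_model(kind, theta)
        converged = False
        message = message or "parameters at bounds"

    raw_pred = _predict_raw(kind, theta, dose)
    rss_raw = float(np.sum((raw_pred - response) ** 2))
    return FitResult(
        model=model,
        rss=rss if np.isfinite(rss) else rss_raw,
        n_obs=len(response),
        converged=converged,
        param_covariance=cov,
        boxcox_lambda=lam_chosen,
        message=message,
        rss_untransformed=rss_raw,
    )


def select_model(
    data: DoseResponseDataset,
    candidates: Iterable[ModelKind] = ("gaussian", "loggaussian"),
    **fit_kwargs,
) -> FitResult:
    """Fit each candidate kind and keep the converged fit with minimal RSS.

    Candidates are compared on the untransformed residual-sum-of-squares
    scale. Ties are broken toward the log-Gaussian, the usual convention for
    concentration data. If only some candidates converge, the best converged
    one is returned with a warning; if none do, a :class:`FitFailureError`
    lists every failure.
    """
    candidates = list(candidates)
    if not candidates:
        raise InvalidInputError("candidates must be non-empty")
    fit_kwargs.pop("boxcox", None)  # selection is defined on the raw scale
    results: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for kind in candidates:
        try:
            res = fit_biphasic(data, kind, boxcox=False, **fit_kwargs)
        except Exception as exc:  # invalid data raises before any fit
            raise exc if isinstance(exc, InvalidInputError) else FitFailureError({kind: str(exc)})
        if res.converged:
            results[kind] = res
        else:
            failures[kind] = res.message or "did not converge"
    if not results:
        raise FitFailureError(failures)
    if failures:
        warnings.warn(
            f"series {data.series_id!r}: candidate(s) failed: {failures}; "
            f"returning best of {sorted(results)}",
            RuntimeWarning,
            stacklevel=2,
        )

    def sort_key(item: tuple[str, FitResult]):
        kind, res = item
        return (res.rss_untransformed, 0 if kind == "loggaussian" else 1)

    return min(results.items(), key=sort_key)[1]
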