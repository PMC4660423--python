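"""Additive mixture prediction under the two-dimensional Loewe formulation.

Loewe additivity (concentration addition) treats mixture components as
dilutions of one another: at a common fractional effect p the component
doses satisfy sum_i D_i / D_(p),i = 1. Writing each component dose as a
fixed fraction j_i of the total mixture dose (a constant-ratio ray,
j_i = D_i / D_mix) and rearranging gives the predictive form

    D_add(p) = ( sum_i j_i / D_(p),i )^-1,

the j-weighted harmonic mean of the component effective doses. Because
biphasic curves carry a second, empirical-effect coordinate E_(p), the same
structure is projected onto the effect dimension:

    E_add(p) = ( sum_i j_i / E_(p),i )^-1.

Sweeping p yields the additive dose-response curve of the mixture as a
parametric (dose, effect) path. For a sham mixture (every component the same
compound) both harmonic means collapse to the component values, so the
additive prediction coincides with the single-compound curve identically --
the algebraic counterpart of the experimental sham validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .models import (
    BiphasicModel,
    InvalidInputError,
    InvalidStateError,
    dose_at_p,
    effect_at_p,
)

__all__ = [
    "MixtureSpec",
    "PredictedCurve",
    "additive_dose",
    "additive_effect",
    "predict_curve",
    "predict_with_interaction",
    "curve_in_branch_variable",
    "default_p_grid",
]

EffectWeights = Literal["dose_fractions"]


@dataclass(frozen=True)
class MixtureSpec:
    """Mixture composition: component ids with dose fractions summing to 1.

    ``fractions[i]`` is j_i = D_i / D_mix, the share of component i in the
    total mixture dose along a constant-ratio ray.
    """

    component_ids: tuple[str, ...]
    fractions: tuple[float, ...]

    def __init__(self, component_ids: Sequence[str], fractions: Sequence[float]):
        ids = tuple(str(c) for c in component_ids)
        fr = tuple(float(x) for x in fractions)
        if len(ids) < 2:
            raise InvalidInputError("a mixture needs at least 2 components")
        if len(ids) != len(fr):
            raise InvalidInputError("component_ids and fractions must have equal length")
        if any(x <= 0 for x in fr):
            raise InvalidInputError("all fractions must be > 0")
        if abs(sum(fr) - 1.0) > 1e-12:
            raise InvalidInputError(f"fractions must sum to 1 (got {sum(fr)!r})")
        object.__setattr__(self, "component_ids", ids)
        object.__setattr__(self, "fractions", fr)

    @property
    def n_components(self) -> int:
        return len(self.component_ids)


@dataclass(frozen=True)
class PredictedCurve:
    """Parametric mixture curve: rows (p, dose, effect) indexed by fractional effect."""

    p: np.ndarray
    dose: np.ndarray
    effect: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"p": self.p, "dose": self.dose, "effect": self.effect})

    def response_at_dose(self, total_dose) -> np.ndarray | float:
        """Interpolate the curve's response at total mixture dose(s).

        The dose coordinate is strictly increasing in p, so the parametric
        curve is single-valued in dose; interpolation is monotone in p.
        Doses outside the tabulated range are clamped to the end values with
        a warning from the caller's side (see ``simulate.simulate_mixture``).
        """
        x = np.asarray(total_dose, dtype=float)
        out = np.interp(x, self.dose, self.effect)
        return float(out) if x.ndim == 0 else out


def default_p_grid(step: float = 0.5) -> np.ndarray:
    """Fractional-effect grid [-99, 99]; the endpoints +/-100 are excluded
    because the corresponding dose is 0 or unbounded."""
    return np.arange(-99.0, 99.0 + step / 2, step)


def _check_spec(fits: Sequence[BiphasicModel], spec: MixtureSpec) -> None:
    if len(fits) != spec.n_components:
        raise InvalidInputError(
            f"{spec.n_components} fractions but {len(fits)} component models"
        )


def additive_dose(fits: Sequence[BiphasicModel], spec: MixtureSpec, p) -> np.ndarray | float:
    """Additive total mixture dose D_add(p): j-weighted harmonic mean of D_(p),i."""
    _check_spec(fits, spec)
    arr = np.asarray(p, dtype=float)
    d = np.stack([np.atleast_1d(dose_at_p(m, arr)) for m in fits])  # (n_comp, n_p)
    if np.any(d <= 0):
        raise InvalidStateError("component effective dose <= 0 on the requested p grid")
    j = np.asarray(spec.fractions)[:, None]
    out = 1.0 / np.sum(j / d, axis=0)
    return float(out[0]) if arr.ndim == 0 else out


def additive_effect(fits: Sequence[BiphasicModel], spec: MixtureSpec, p) -> np.ndarray | float:
    """Additive mixture effect E_add(p): the dose-dimension harmonic-mean
    structure projected onto the empirical effect scale, weighted by the dose
    fractions j_i."""
    _check_spec(fits, spec)
    arr = np.asarray(p, dtype=float)
    e = np.stack([np.atleast_1d(effect_at_p(m, arr)) for m in fits])
    if np.any(e <= 0):
        raise InvalidStateError("component effect <= 0 on the requested p grid")
    j = np.asarray(spec.fractions)[:, None]
    out = 1.0 / np.sum(j / e, axis=0)
    return float(out[0]) if arr.ndim == 0 else out


def predict_curve(
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    p_grid: np.ndarray | None = None,
) -> PredictedCurve:
    """Additive dose-response curve of the mixture over a fractional-effect grid."""
    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size and (p_grid.min() <= -100 or p_grid.max() >= 100):
        raise InvalidInputError("p_grid must lie strictly inside (-100, 100)")
    if np.any(np.diff(p_grid) <= 0):
        raise InvalidInputError("p_grid must be strictly increasing")
    dose = np.asarray(additive_dose(fits, spec, p_grid))
    effect = np.asarray(additive_effect(fits, spec, p_grid))
    return PredictedCurve(p=p_grid, dose=dose, effect=effect)


def predict_with_interaction(
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    p_grid: np.ndarray | None = None,
    *,
    ci_d: float = 1.0,
    ci_e: float = 1.0,
) -> PredictedCurve:
    """Mixture curve under constant combination indices (CI_D, CI_E).

    The additive dose at each p is multiplied by ``ci_d`` (CI_D < 1: the
    mixture needs less total dose than additively expected -- synergism in D)
    and the additive effect divided by ``ci_e`` (CI_E < 1: the mixture
    attains a higher empirical effect than expected). With both indices at 1
    this is exactly :func:`predict_curve`, and re-estimating the indices from
    the generated curve recovers the inputs.
    """
    if not (ci_d > 0 and ci_e > 0):
        raise InvalidInputError("ci_d and ci_e must be > 0")
    base = predict_curve(fits, spec, p_grid)
    return PredictedCurve(p=base.p, dose=ci_d * base.dose, effect=base.effect / ci_e)


def curve_in_branch_variable(
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    t_grid: np.ndarray,
    *,
    ci_d: float = 1.0,
    ci_e: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(dose, effect) of the CI-scaled additive curve in the branch variable t.

    ``t`` is the signed number of left-branch widths from the peak: the
    effect fraction is q = exp(-t^2 / 2) (so p = sign(t) * 100 * (1 - q)),
    and each component's dose is ``e_i * exp(w_i(t) * t)`` (log-Gaussian) or
    ``e_i + w_i(t) * t`` (Gaussian) with ``w_i = b_i`` for t <= 0 and
    ``b_i * f_i`` for t > 0. Unlike the p parameterization, t reaches
    arbitrarily deep into the tails without loss of precision (p saturates at
    +/-100 in floating point while q underflows gracefully), which matters
    when tabulating the true curve down to strong dilutions. Doses clipped
    below 0 by a Gaussian left branch are dropped.
    """
    _check_spec(fits, spec)
    if not (ci_d > 0 and ci_e > 0):
        raise InvalidInputError("ci_d and ci_e must be > 0")
    t = np.asarray(t_grid, dtype=float)
    q = np.exp(-0.5 * t**2)
    j = np.asarray(spec.fractions)[:, None]
    doses = []
    effects = []
    for m in fits:
        w = np.where(t <= 0, m.b, m.b * m.f)
        if m.kind == "loggaussian":
            doses.append(m.e * np.exp(w * t))
        else:
            doses.append(m.e + w * t)
        effects.append(m.c + q * (m.d - m.c))
    dose_comp = np.stack(doses)
    eff_comp = np.stack(effects)
    valid = np.all(dose_comp > 0, axis=0)
    dose = ci_d / np.sum(j / dose_comp[:, valid], axis=0)
    effect = 1.0 / np.sum(j / eff_comp[:, valid], axis=0) / ci_e
    return dose, effect
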