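"""Synthetic dose-response data with known ground truth, plus design helpers.

The generator mirrors the structure of a whole-cell biosensor mixture
experiment: factor-2 serial dilution series (7-9 levels) of single compounds
and constant-ratio mixture rays, measured as induction factors in 3-4
independent replicates with multiplicative scatter. Noise is by default
mean-corrected lognormal -- biosensor induction factors are positive with
spread roughly proportional to the signal -- with an additive-Gaussian option
for robustness experiments.

Mixture ground truth is defined parametrically in the fractional effect p
(scaling a biphasic curve by constant combination indices has no closed form
in dose): the true curve is tabulated on a dense p grid and responses at the
requested total doses are obtained by monotone interpolation along it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .mixture import MixtureSpec, curve_in_branch_variable
from .models import (
    BiphasicModel,
    DoseResponseDataset,
    InvalidInputError,
    InvalidStateError,
    dose_at_p,
    evaluate,
)

__all__ = [
    "NoiseModel",
    "dilution_series",
    "constant_ratio_design",
    "simulate_single",
    "simulate_mixture",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise specification.

    ``multiplicative_lognormal`` perturbs each true response by a lognormal
    factor with unit mean (sigma^2/2 mean correction) and coefficient of
    variation ``cv_or_sd``; ``additive_gaussian`` adds zero-mean Gaussian
    noise with standard deviation ``cv_or_sd``. Either way the expected
    noisy response equals the true response.
    """

    kind: Literal["multiplicative_lognormal", "additive_gaussian"] = "multiplicative_lognormal"
    cv_or_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative_lognormal", "additive_gaussian"):
            raise InvalidInputError(f"unknown noise kind {self.kind!r}")
        if self.cv_or_sd < 0:
            raise InvalidInputError("cv_or_sd must be >= 0")

    def apply(self, true_response: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        y = np.asarray(true_response, dtype=float)
        if self.cv_or_sd == 0:
            return y.copy()
        if self.kind == "multiplicative_lognormal":
            sigma = np.sqrt(np.log1p(self.cv_or_sd**2))
            return y * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=y.shape)
        return y + rng.normal(0.0, self.cv_or_sd, size=y.shape)


def dilution_series(top_dose: float, factor: float = 2.0, n: int = 8) -> np.ndarray:
    """Descending geometric dilution series top_dose / factor**k, k = 0..n-1."""
    if not top_dose > 0:
        raise InvalidInputError("top_dose must be > 0")
    if not factor > 1:
        raise InvalidInputError("dilution factor must be > 1")
    if not n >= 2:
        raise InvalidInputError("need at least 2 dilution levels")
    return top_dose / np.power(float(factor), np.arange(n))


def constant_ratio_design(
    fits: Sequence[BiphasicModel],
    basis_p: float = -50.0,
    weights: Sequence[float] | None = None,
) -> MixtureSpec:
    """Constant-ratio mixture fractions anchored at each component's D_(basis_p).

    A "1:1" design (equal weights) doses every component at the same multiple
    of its own half-peak induction dose D_(-50), so the fractions are
    j_i = D_(basis_p),i / sum_k D_(basis_p),k. Unequal weights (e.g. 75:25)
    scale those multiples. Component ids default to ``C1..Cn``; build a
    :class:`~loewe2d.mixture.MixtureSpec` directly for custom labelling.
    """
    if len(fits) < 2:
        raise InvalidInputError("need at least 2 component fits")
    w = np.ones(len(fits)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (len(fits),) or np.any(w <= 0):
        raise InvalidInputError("weights must be positive, one per component")
    d = np.array([dose_at_p(m, basis_p) for m in fits])
    if np.any(d <= 0):
        raise InvalidStateError(f"component dose at p={basis_p} is zero")
    raw = w * d
    fractions = raw / raw.sum()
    ids = [f"C{i+1}" for i in range(len(fits))]
    return MixtureSpec(component_ids=ids, fractions=fractions.tolist())


def _replicated(
    series_id: str,
    doses: np.ndarray,
    true_response: np.ndarray,
    noise: NoiseModel,
    n_rep: int,
    rng: np.random.Generator,
) -> DoseResponseDataset:
    all_dose = np.tile(doses, n_rep)
    all_resp = np.concatenate([noise.apply(true_response, rng) for _ in range(n_rep)])
    all_rep = np.repeat(np.arange(1, n_rep + 1), doses.size)
    return DoseResponseDataset(series_id=series_id, dose=all_dose, response=all_resp, replicate=all_rep)


def simulate_single(
    model: BiphasicModel,
    doses: Sequence[float],
    noise: NoiseModel | None = None,
    n_rep: int = 3,
    series_id: str = "sim",
) -> DoseResponseDataset:
    """Replicate observations of one compound from a known biphasic model.

    Deterministic for a fixed ``noise.seed``.
    """
    if n_rep < 1:
        raise InvalidInputError("n_rep must be >= 1")
    noise = noise or NoiseModel(cv_or_sd=0.0)
    doses = np.asarray(doses, dtype=float)
    true = np.asarray(evaluate(model, doses), dtype=float)
    rng = np.random.default_rng(noise.seed)
    return _replicated(series_id, doses, true, noise, n_rep, rng)


def simulate_mixture(
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    doses: Sequence[float],
    *,
    ci_d: float = 1.0,
    ci_e: float = 1.0,
    noise: NoiseModel | None = None,
    n_rep: int = 3,
    series_id: str = "mix",
    t_max: float = 12.0,
    t_step: float = 0.01,
) -> DoseResponseDataset:
    """Replicate observations along a mixture ray with imposed interaction.

    The true curve is the additive prediction scaled by constant combination
    indices (``ci_d = ci_e = 1`` reproduces pure Loewe additivity). It is
    tabulated in the branch variable t (effect fraction exp(-t^2/2)) on
    [-t_max, t_max], which reaches arbitrarily deep serial dilutions -- at
    t = +/-12 the curve sits within ~1e-31 of its baseline -- and the
    response at each requested total dose is obtained by monotone
    interpolation. Doses outside even that range are clamped to the tail
    values with a warning.
    """
    if not (ci_d > 0 and ci_e > 0):
        raise InvalidInputError("ci_d and ci_e must be > 0")
    if n_rep < 1:
        raise InvalidInputError("n_rep must be >= 1")
    noise = noise or NoiseModel(cv_or_sd=0.0)
    doses = np.asarray(doses, dtype=float)
    t_grid = np.arange(-t_max, t_max + t_step / 2, t_step)
    curve_dose, curve_effect = curve_in_branch_variable(fits, spec, t_grid, ci_d=ci_d, ci_e=ci_e)
    if doses.min() < curve_dose[0] or doses.max() > curve_dose[-1]:
        warnings.warn(
            "requested mixture dose outside the tabulated curve range "
            f"[{curve_dose[0]:.4g}, {curve_dose[-1]:.4g}]; clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    true = np.interp(doses, curve_dose, curve_effect)
    rng = np.random.default_rng(noise.seed)
    return _replicated(series_id, doses, true, noise, n_rep, rng)
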