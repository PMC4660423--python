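"""Departures from additivity: two-dimensional combination indices and tests.

At each fractional effect p the mixture's observed behaviour is compared with
its Loewe-additive expectation in both coordinates of the effective dose:

* ``CI_D(p) = D_mix(p) / D_add(p)`` -- the ratio of the fitted mixture's
  effective total dose to the additive prediction. CI_D < 1: the mixture
  reaches fractional effect p at a lower total dose than expected
  (synergism in the dose dimension); CI_D > 1: antagonism.
* ``CI_E(p) = E_add(p) / E_mix(p)`` -- oriented so that CI_E < 1 means the
  mixture attains a *higher* empirical effect than additively expected
  (synergism in the effect dimension). The literal ratio E_mix/E_add is
  available through ``orientation="literal"``.

The weighted index ``CI_w = CI_D * CI_E`` condenses both dimensions into one
overall score: counteracting departures pull CI_w toward 1 (or cancel), while
concordant departures compound (e.g. CI_D = CI_E = 0.5 gives CI_w = 0.25,
strong overall synergism). Pointwise significance against H0: CI = 1 uses a
two-sided one-sample t-test on log-scale replicate CI values; the pragmatic
risk-management classification labels CI_w < 0.5 synergism, CI_w > 2
antagonism, and anything in between (boundaries included) additive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import MixtureSpec, additive_dose, additive_effect
from .models import BiphasicModel, InvalidInputError, dose_at_p, effect_at_p

__all__ = [
    "CIResult",
    "ci_at_p",
    "ci_weighted",
    "ci_profile",
    "ci_with_replicates",
    "test_departure",
    "classify_management",
    "polygonogram_summary",
    "CI_SYNERGISM_THRESHOLD",
    "CI_ANTAGONISM_THRESHOLD",
]

Orientation = Literal["interpretation", "literal"]
Category = Literal["synergism", "additive", "antagonism"]

#: Risk-management thresholds on CI_w: below 0.5 synergism, above 2 antagonism.
CI_SYNERGISM_THRESHOLD = 0.5
CI_ANTAGONISM_THRESHOLD = 2.0


@dataclass(frozen=True)
class CIResult:
    """Combination indices at one fractional effect, with optional inference."""

    p: float
    ci_d: float
    ci_e: float
    ci_w: float
    category: Category
    replicate_ci: tuple[tuple[float, float], ...] | None = None
    t_stat_d: float | None = None
    t_stat_e: float | None = None
    p_value_d: float | None = None
    p_value_e: float | None = None

    @property
    def n_replicates(self) -> int:
        return 0 if self.replicate_ci is None else len(self.replicate_ci)


def ci_weighted(ci_d: float, ci_e: float) -> float:
    """Overall weighted combination index CI_w = CI_D * CI_E."""
    if not (ci_d > 0 and ci_e > 0):
        raise InvalidInputError("combination indices must be > 0")
    return float(ci_d * ci_e)


def classify_management(ci_w: float) -> Category:
    """Risk-management category from CI_w: <0.5 synergism, >2 antagonism,
    otherwise additive (boundaries count as additive)."""
    if not ci_w > 0:
        raise InvalidInputError("ci_w must be > 0")
    if ci_w < CI_SYNERGISM_THRESHOLD:
        return "synergism"
    if ci_w > CI_ANTAGONISM_THRESHOLD:
        return "antagonism"
    return "additive"


def ci_at_p(
    mix_fit: BiphasicModel,
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    p: float,
    *,
    orientation: Orientation = "interpretation",
) -> CIResult:
    """Two-dimensional combination index of a fitted mixture at fractional effect p.

    ``mix_fit`` is the biphasic model fitted to the mixture on its total-dose
    axis; ``fits`` are the single-component models in the order of
    ``spec.component_ids``.
    """
    d_add = additive_dose(fits, spec, p)
    e_add = additive_effect(fits, spec, p)
    d_mix = dose_at_p(mix_fit, p)
    e_mix = effect_at_p(mix_fit, p)
    if d_mix <= 0 or e_mix <= 0:
        raise InvalidInputError(f"mixture effective dose/effect <= 0 at p={p}")
    ci_d = d_mix / d_add
    ci_e = e_add / e_mix if orientation == "interpretation" else e_mix / e_add
    ci_w = ci_weighted(ci_d, ci_e)
    return CIResult(p=float(p), ci_d=ci_d, ci_e=ci_e, ci_w=ci_w, category=classify_management(ci_w))


def ci_profile(
    mix_fit: BiphasicModel,
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    p_grid: np.ndarray,
    *,
    orientation: Orientation = "interpretation",
) -> list[CIResult]:
    """Combination-index profile over a fractional-effect grid (the table
    behind extended p-CI and p-CI_w plots)."""
    return [ci_at_p(mix_fit, fits, spec, p, orientation=orientation) for p in np.asarray(p_grid, float)]


def ci_with_replicates(
    replicate_mix_fits: Sequence[BiphasicModel],
    fits: Sequence[BiphasicModel],
    spec: MixtureSpec,
    p: float,
    *,
    orientation: Orientation = "interpretation",
    pooled_mix_fit: BiphasicModel | None = None,
) -> CIResult:
    """Combination index with replicate-level inference.

    One mixture model per independent replicate experiment yields one
    (CI_D, CI_E) pair per replicate; the point estimate comes from
    ``pooled_mix_fit`` when given (the fit to all replicates together),
    otherwise from the geometric mean of the replicate indices. A two-sided
    t-test of H0: CI = 1 on the log replicate values gives per-dimension
    p-values.
    """
    if len(replicate_mix_fits) < 1:
        raise InvalidInputError("need at least one replicate mixture fit")
    reps = [ci_at_p(m, fits, spec, p, orientation=orientation) for m in replicate_mix_fits]
    pairs = tuple((r.ci_d, r.ci_e) for r in reps)
    if pooled_mix_fit is not None:
        point = ci_at_p(pooled_mix_fit, fits, spec, p, orientation=orientation)
        ci_d, ci_e = point.ci_d, point.ci_e
    else:
        ci_d = float(np.exp(np.mean(np.log([a for a, _ in pairs]))))
        ci_e = float(np.exp(np.mean(np.log([b for _, b in pairs]))))
    t_d = t_e = p_d = p_e = None
    if len(pairs) >= 2:
        t_d, p_d = test_departure([a for a, _ in pairs])
        t_e, p_e = test_departure([b for _, b in pairs])
    ci_w = ci_weighted(ci_d, ci_e)
    return CIResult(
        p=float(p),
        ci_d=ci_d,
        ci_e=ci_e,
        ci_w=ci_w,
        category=classify_management(ci_w),
        replicate_ci=pairs,
        t_stat_d=t_d,
        t_stat_e=t_e,
        p_value_d=p_d,
        p_value_e=p_e,
    )


def test_departure(replicate_ci: Sequence[float], null_value: float = 1.0) -> tuple[float, float]:
    """Two-sided one-sample t-test of H0: CI = null_value on log(CI).

    CI is a positive ratio, so the null is multiplicative and the test is run
    on the natural-log scale with n - 1 degrees of freedom. Degenerate
    zero-variance samples return p = 1 when they sit exactly at the null and
    p = 0 (with a warning) otherwise.
    """
    x = np.asarray(replicate_ci, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need at least 2 replicate CI values")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise InvalidInputError("replicate CI values must be positive and finite")
    if not null_value > 0:
        raise InvalidInputError("null_value must be > 0")
    logs = np.log(x) - np.log(null_value)
    sd = float(np.std(logs, ddof=1))
    if sd == 0.0:
        if np.allclose(logs, 0.0):
            return 0.0, 1.0
        warnings.warn("zero-variance replicate CIs away from the null; p-value set to 0", RuntimeWarning, stacklevel=2)
        return float(np.sign(np.mean(logs)) * np.inf), 0.0
    t, p = stats.ttest_1samp(logs, 0.0)
    return float(t), float(p)


def polygonogram_summary(
    pair_results: Mapping[tuple[str, str], Mapping[float, CIResult]],
    p_levels: Sequence[float] = (-50.0, 0.0, 50.0),
) -> pd.DataFrame:
    """Tidy pairwise-interaction table behind a polygonogram.

    One row per (component pair, fractional-effect level) with CI_w and its
    management category; a pair missing a requested level is listed with the
    category ``absent`` and a missing CI_w rather than being fabricated.
    """
    rows = []
    for (a, b), by_p in pair_results.items():
        for p in p_levels:
            res = by_p.get(float(p))
            if res is None:
                rows.append({"component_a": a, "component_b": b, "p": float(p), "ci_w": np.nan, "category": "absent"})
            else:
                rows.append(
                    {
                        "component_a": a,
                        "component_b": b,
                        "p": float(p),
                        "ci_w": res.ci_w,
                        "category": res.category,
                    }
                )
    return pd.DataFrame(rows, columns=["component_a", "component_b", "p", "ci_w", "category"])
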