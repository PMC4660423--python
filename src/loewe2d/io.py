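"""CSV/YAML readers and writers for datasets, fit tables and mixture specs.

All tabular interchange is plain UTF-8 CSV with a header, decimal point and
comma separator. Column orders are fixed:

* dataset:        ``series_id,dose,response,replicate``
* fit report:     ``series_id,kind,b,c,d,e,f,rss,n_obs,boxcox_lambda,converged``
* ED_p table:     ``series_id,p,dose,effect``
* predicted curve: ``p,dose,effect``
* CI table:       ``p,ci_d,ci_e,ci_w,p_value_d,p_value_e,category,n_replicates``

Mixture specifications are YAML or JSON, either an explicit composition
``components: [{id, fraction}, ...]`` or a constant-ratio rule
``ratio_design: {basis_p: -50, weights: [1, 1]}`` resolved against the
single-compound fits at run time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .interaction import CIResult
from .mixture import MixtureSpec, PredictedCurve
from .models import BiphasicModel, DoseResponseDataset, EDpVector, FitResult, InvalidInputError
from .simulate import constant_ratio_design

__all__ = [
    "DATASET_COLUMNS",
    "read_dataset",
    "write_dataset",
    "fit_report_frame",
    "write_fit_report",
    "read_fit_report",
    "edp_table",
    "write_curve",
    "ci_table",
    "read_mixture_config",
    "resolve_mixture_config",
]

DATASET_COLUMNS = ("series_id", "dose", "response", "replicate")


def read_dataset(path: str | Path) -> dict[str, DoseResponseDataset]:
    """Read a tidy dose-response CSV into one dataset per series.

    Validation errors cite the offending column or 1-based data row numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required column(s) {missing}")
    for col in ("dose", "response"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()] + 1
        if len(bad):
            raise InvalidInputError(f"{path}: non-numeric {col} at row(s) {list(bad[:10])}")
        df[col] = vals
    neg = df.index[df["dose"] < 0] + 1
    if len(neg):
        raise InvalidInputError(f"{path}: negative dose at row(s) {list(neg[:10])}")
    nonfinite = df.index[~np.isfinite(df["response"])] + 1
    if len(nonfinite):
        raise InvalidInputError(f"{path}: non-finite response at row(s) {list(nonfinite[:10])}")
    out: dict[str, DoseResponseDataset] = {}
    for sid, sub in df.groupby("series_id", sort=False):
        out[str(sid)] = DoseResponseDataset.from_frame(sub, series_id=str(sid))
    return out


def write_dataset(datasets: Mapping[str, DoseResponseDataset] | DoseResponseDataset, path: str | Path) -> None:
    if isinstance(datasets, DoseResponseDataset):
        datasets = {datasets.series_id: datasets}
    frame = pd.concat([ds.to_frame() for ds in datasets.values()], ignore_index=True)
    frame.to_csv(path, index=False, columns=list(DATASET_COLUMNS))


def fit_report_frame(fits: Mapping[str, FitResult]) -> pd.DataFrame:
    rows = []
    for sid, res in fits.items():
        m = res.model
        rows.append(
            {
                "series_id": sid,
                "kind": m.kind,
                "b": m.b,
                "c": m.c,
                "d": m.d,
                "e": m.e,
                "f": m.f,
                "rss": res.rss,
                "n_obs": res.n_obs,
                "boxcox_lambda": res.boxcox_lambda if res.boxcox_lambda is not None else "",
                "converged": res.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["series_id", "kind", "b", "c", "d", "e", "f", "rss", "n_obs", "boxcox_lambda", "converged"],
    )


def write_fit_report(fits: Mapping[str, FitResult], path: str | Path) -> None:
    fit_report_frame(fits).to_csv(path, index=False)


def read_fit_report(path: str | Path) -> dict[str, BiphasicModel]:
    """Read a fit-report CSV back into models (one per series)."""
    df = pd.read_csv(path)
    needed = {"series_id", "kind", "b", "c", "d", "e", "f"}
    missing = needed - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing fit-report column(s) {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["series_id"])] = BiphasicModel(
            kind=str(row["kind"]),
            b=float(row["b"]),
            c=float(row["c"]),
            d=float(row["d"]),
            e=float(row["e"]),
            f=float(row["f"]),
        )
    return out


def edp_table(vectors: Mapping[str, Sequence[EDpVector]]) -> pd.DataFrame:
    rows = [
        {"series_id": sid, "p": v.p, "dose": v.dose, "effect": v.effect}
        for sid, vs in vectors.items()
        for v in vs
    ]
    return pd.DataFrame(rows, columns=["series_id", "p", "dose", "effect"])


def write_curve(curve: PredictedCurve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def ci_table(results: Sequence[CIResult]) -> pd.DataFrame:
    rows = [
        {
            "p": r.p,
            "ci_d": r.ci_d,
            "ci_e": r.ci_e,
            "ci_w": r.ci_w,
            "p_value_d": r.p_value_d if r.p_value_d is not None else "",
            "p_value_e": r.p_value_e if r.p_value_e is not None else "",
            "category": r.category,
            "n_replicates": r.n_replicates,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["p", "ci_d", "ci_e", "ci_w", "p_value_d", "p_value_e", "category", "n_replicates"]
    )


def read_mixture_config(path: str | Path) -> dict:
    """Load a mixture configuration (YAML or JSON) without resolving it."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict) or ("components" not in cfg and "ratio_design" not in cfg):
        raise InvalidInputError(f"{path}: expected a mapping with 'components' or 'ratio_design'")
    return cfg


def resolve_mixture_config(cfg: dict, fits: Mapping[str, BiphasicModel]) -> MixtureSpec:
    """Turn a mixture configuration into a concrete :class:`MixtureSpec`.

    Explicit ``components`` entries give ids and fractions directly; a
    ``ratio_design`` entry lists ``components`` (ids), an optional
    ``basis_p`` (default -50) and optional ``weights``, and the fractions
    are derived from the single-compound fits' D_(basis_p) values.
    """
    if "components" in cfg and "ratio_design" not in cfg:
        ids = [str(c["id"]) for c in cfg["components"]]
        fractions = [float(c["fraction"]) for c in cfg["components"]]
        spec = MixtureSpec(ids, fractions)
    else:
        rd = cfg["ratio_design"]
        ids = [str(i) for i in rd["components"]]
        basis_p = float(rd.get("basis_p", -50.0))
        weights = rd.get("weights")
        models = [fits[i] for i in ids]
        spec = constant_ratio_design(models, basis_p=basis_p, weights=weights)
        spec = MixtureSpec(ids, spec.fractions)
    unknown = [i for i in spec.component_ids if i not in fits]
    if unknown:
        raise InvalidInputError(f"mixture references unknown component fit(s): {unknown}")
    return spec
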