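"""End-to-end analysis pipeline: fit -> ED_p -> predict -> CI -> report.

A :class:`RunConfig` fully determines a run; outputs are deterministic given
the config (and seed, for simulated inputs), with fixed CSV column orders.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .interaction import CIResult, ci_profile, ci_with_replicates, polygonogram_summary
from .io import (
    ci_table,
    edp_table,
    read_dataset,
    read_mixture_config,
    resolve_mixture_config,
    write_curve,
    write_fit_report,
)
from .mixture import predict_curve
from .models import (
    DoseResponseDataset,
    FitResult,
    InvalidInputError,
    edp,
    fit_biphasic,
    select_model,
)
from .plotting import plot_curve_overlay, plot_extended_ci, plot_polygonogram

__all__ = ["RunConfig", "MixtureRun", "PipelineError", "run_pipeline"]

log = logging.getLogger("loewe2d")


class PipelineError(RuntimeError):
    """A pipeline stage failed; details are in the run summary."""


@dataclass(frozen=True)
class MixtureRun:
    """One mixture ray to analyse: its data series and its composition."""

    series_id: str
    mixture_config: str | dict  # path to YAML/JSON, or the parsed mapping


@dataclass
class RunConfig:
    """Reproducible pipeline configuration (serializable to YAML/JSON)."""

    input: str
    components: list[str]
    mixtures: list[MixtureRun] = field(default_factory=list)
    model: str = "auto"  # auto | gaussian | loggaussian
    boxcox: bool = False
    multistart: bool = True
    seed: int = 0
    p_grid: tuple[float, float, float] = (-99.0, 99.0, 1.0)
    p_levels: tuple[float, ...] = (-50.0, 0.0, 50.0)
    out_dir: str = "loewe2d_out"
    log_level: str = "INFO"
    make_plots: bool = True

    def grid(self) -> np.ndarray:
        start, stop, step = self.p_grid
        return np.arange(start, stop + step / 2, step)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["mixtures"] = [asdict(m) if isinstance(m, MixtureRun) else m for m in self.mixtures]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        d["mixtures"] = [MixtureRun(**m) if isinstance(m, dict) else m for m in d.get("mixtures", [])]
        if "p_grid" in d:
            d["p_grid"] = tuple(d["p_grid"])
        if "p_levels" in d:
            d["p_levels"] = tuple(d["p_levels"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


def _fit_series(data: DoseResponseDataset, cfg: RunConfig) -> FitResult:
    if cfg.model == "auto":
        return select_model(data, multistart=cfg.multistart)
    return fit_biphasic(data, cfg.model, boxcox=cfg.boxcox, multistart=cfg.multistart)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis and write all report files under ``out_dir``.

    Returns the machine-readable run summary (also written as
    ``summary.json``). Raises :class:`PipelineError` after recording the
    failing stage if any stage fails.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    def finish(stage: str, error: Exception) -> None:
        summary["stages"][stage] = {"status": "error", "message": str(error)}
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise PipelineError(f"stage {stage!r} failed: {error}") from error

    # --- validate series availability up front -----------------------------
    try:
        datasets = read_dataset(config.input)
        wanted = list(config.components) + [m.series_id for m in config.mixtures]
        unknown = [s for s in wanted if s not in datasets]
        if unknown:
            raise InvalidInputError(f"series not present in {config.input}: {unknown}")
        summary["stages"]["read"] = {"status": "ok", "n_series": len(datasets)}
    except PipelineError:
        raise
    except Exception as exc:
        finish("read", exc)

    # --- single-compound fits ----------------------------------------------
    try:
        single_fits: dict[str, FitResult] = {}
        for sid in config.components:
            single_fits[sid] = _fit_series(datasets[sid], config)
            log.info("fitted %s: kind=%s rss=%.4g", sid, single_fits[sid].model.kind, single_fits[sid].rss)
        write_fit_report(single_fits, out / "fit.csv")
        summary["stages"]["fit"] = {
            "status": "ok",
            "kinds": {s: r.model.kind for s, r in single_fits.items()},
            "converged": {s: r.converged for s, r in single_fits.items()},
        }
    except PipelineError:
        raise
    except Exception as exc:
        finish("fit", exc)

    # --- ED_p tables --------------------------------------------------------
    try:
        vectors = {
            sid: [edp(res.model, p) for p in config.p_levels] for sid, res in single_fits.items()
        }
        edp_table(vectors).to_csv(out / "edp.csv", index=False)
        summary["stages"]["edp"] = {"status": "ok", "p_levels": list(config.p_levels)}
    except PipelineError:
        raise
    except Exception as exc:
        finish("edp", exc)

    # --- mixtures: prediction + CI ------------------------------------------
    pair_results: dict[tuple[str, str], dict[float, CIResult]] = {}
    try:
        models = {sid: r.model for sid, r in single_fits.items()}
        grid = config.grid()
        mix_fits: dict[str, FitResult] = {}
        for mix in config.mixtures:
            cfg_raw = (
                mix.mixture_config
                if isinstance(mix.mixture_config, dict)
                else read_mixture_config(mix.mixture_config)
            )
            spec = resolve_mixture_config(cfg_raw, models)
            comp_models = [models[i] for i in spec.component_ids]

            curve = predict_curve(comp_models, spec, grid)
            write_curve(curve, out / f"curve_{mix.series_id}.csv")

            data = datasets[mix.series_id]
            pooled = _fit_series(data, config)
            mix_fits[mix.series_id] = pooled
            rep_fits = []
            for rep in np.unique(data.replicate):
                sub = data.subset_replicate(int(rep))
                if sub.n_dose_levels >= 5:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        res = _fit_series(sub, config)
                    if res.converged:
                        rep_fits.append(res.model)

            profile = ci_profile(pooled.model, comp_models, spec, grid)
            ci_table(profile).to_csv(out / f"ci_{mix.series_id}.csv", index=False)

            level_results: dict[float, CIResult] = {}
            for p in config.p_levels:
                if len(rep_fits) >= 2:
                    level_results[float(p)] = ci_with_replicates(
                        rep_fits, comp_models, spec, p, pooled_mix_fit=pooled.model
                    )
                else:
                    level_results[float(p)] = profile[int(np.argmin(np.abs(grid - p)))]
            ci_table(list(level_results.values())).to_csv(out / f"ci_levels_{mix.series_id}.csv", index=False)
            if spec.n_components == 2:
                pair_results[tuple(spec.component_ids)] = level_results

            if config.make_plots:
                plot_curve_overlay(
                    curve,
                    out / f"curve_{mix.series_id}.png",
                    observed=data,
                    mixture_model=pooled.model,
                    title=mix.series_id,
                )
                plot_extended_ci(profile, out / f"ci_{mix.series_id}.png", title=mix.series_id)
        write_fit_report(mix_fits, out / "fit_mixtures.csv")
        summary["stages"]["mixtures"] = {"status": "ok", "n_mixtures": len(config.mixtures)}
    except PipelineError:
        raise
    except Exception as exc:
        finish("mixtures", exc)

    # --- polygonogram --------------------------------------------------------
    try:
        if pair_results:
            poly = polygonogram_summary(pair_results, config.p_levels)
            poly.to_csv(out / "polygonogram.csv", index=False)
            if config.make_plots:
                plot_polygonogram(poly, out / "polygonogram.png")
        summary["stages"]["polygonogram"] = {"status": "ok", "n_pairs": len(pair_results)}
    except PipelineError:
        raise
    except Exception as exc:
        finish("polygonogram", exc)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
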