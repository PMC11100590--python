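"""End-to-end batch analysis: classify -> guess -> fit with fallbacks.

A :class:`RunConfig` names input CSVs (with their assay kinds), solver
and optimizer options, masks and seeds; :func:`run_pipeline` executes
every dataset, never aborting the batch on a single failure, and returns
a machine-readable report.  Result tables are deterministic functions of
config and inputs (no timestamps in outputs).
"""

from __future__ import annotations

import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as skio
from .binding import fit_association, fit_titration_quadratic
from .fitting import (
    FitOptions,
    classify_slow_association,
    fit_single_turnover,
    initial_guess,
)
from .thermo import fit_dG_thres

__all__ = ["RunConfig", "run_pipeline", "format_tau", "write_report"]


def format_tau(seconds: float) -> str:
    """tau_slice in adaptive units: s below 120 s, min below 120 min,
    otherwise h."""
    if seconds < 120.0:
        return f"{seconds:.3g} s"
    minutes = seconds / 60.0
    if minutes < 120.0:
        return f"{minutes:.3g} min"
    return f"{minutes / 60.0:.3g} h"


@dataclass
class RunConfig:
    """Declarative batch description.

    ``inputs`` is a list of dicts with keys ``path``, ``kind``
    ("slicing" | "titration" | "association" | "thermo") and optional
    kind-specific options (``target_total``, ``risc_total``).
    """

    inputs: list = field(default_factory=list)
    output_dir: str | None = None
    seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-10
    max_iter: int = 200

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for item in cfg.inputs:
            if not Path(item["path"]).exists():
                raise FileNotFoundError(item["path"])
        return cfg


def _slicing_entry(data, opts: FitOptions) -> dict:
    slow = classify_slow_association(data)
    guess = initial_guess(data)
    fit = fit_single_turnover(data, opts)
    flags = [k for k, v in fit.constrained.items() if v]
    notes = []
    if fit.constrained["k_on_at_diffusion_limit"]:
        notes.append("k_on fixed at diffusion limit")
    if fit.constrained["k_phase2_zero"]:
        notes.append("k_phase2 fixed at zero")
    return {
        "slow_association": bool(slow),
        "guess": {
            "k_on": guess.k_on,
            "k_slice": guess.k_slice,
            "k_phase2": guess.k_phase2,
            "f_a": guess.f_a,
        },
        "params": {
            "k_on": fit.params.k_on,
            "k_slice": fit.params.k_slice,
            "k_phase2": fit.params.k_phase2,
            "f_a": fit.params.f_a,
        },
        "tau_slice_s": fit.tau_slice,
        "tau_slice": format_tau(fit.tau_slice),
        "tau_slice_ci95": list(fit.tau_slice_ci95 or ()) or None,
        "ci95": {k: (list(v) if v else None) for k, v in fit.ci95.items()},
        "constrained": flags,
        "notes": notes,
        "cost": fit.cost,
        "converged": fit.converged,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured dataset; per-dataset errors are captured in
    the report instead of aborting the batch."""
    opts = FitOptions(rtol=config.rtol, atol=config.atol,
                      max_iter=config.max_iter)
    results = []
    for item in config.inputs:
        entry = {"path": str(item["path"]), "kind": item["kind"]}
        try:
            if item["kind"] == "slicing":
                data = skio.read_slicing_csv(item["path"])
                entry["guide_id"] = data.guide_id
                entry["target_id"] = data.target_id
                entry.update(_slicing_entry(data, opts))
            elif item["kind"] == "titration":
                data = skio.read_titration_csv(
                    item["path"], target_total=item.get("target_total", 1.0)
                )
                res = fit_titration_quadratic(data)
                entry.update(
                    {
                        "stock_pM": res.stock,
                        "yint": res.yint,
                        "kd_pM": res.kd,
                        "model_used": res.model_used,
                        "p_value_stock": res.p_value_stock,
                    }
                )
            elif item["kind"] == "association":
                data = skio.read_association_csv(
                    item["path"], risc_total=item.get("risc_total")
                )
                res = fit_association(data)
                entry.update(
                    {
                        "A": res.a,
                        "k_on": res.k_on,
                        "k_on_per_min": res.k_on_per_min,
                        "lower_bound": res.lower_bound,
                        "summary": res.summary(),
                    }
                )
            elif item["kind"] == "thermo":
                points = skio.read_thermo_csv(item["path"])
                res = fit_dG_thres(points)
                entry.update(
                    {
                        "dG_thres": res.dG_thres,
                        "ci95": list(res.ci95) if res.ci95 else None,
                        "p_value": res.p_value,
                        "unidentifiable": res.unidentifiable,
                    }
                )
            else:
                raise ValueError(f"unknown input kind {item['kind']!r}")
            entry["status"] = "ok"
        except Exception as exc:
            entry["status"] = "error"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["traceback"] = traceback.format_exc(limit=3)
        results.append(entry)
    return {"seed": config.seed, "n_datasets": len(results),
            "results": results}


def _human_summary(report: dict) -> str:
    lines = [f"slicekin report ({report['n_datasets']} dataset(s))"]
    for r in report["results"]:
        if r["status"] != "ok":
            lines.append(f"- {r['path']}: ERROR {r['error']}")
            continue
        if r["kind"] == "slicing":
            ks = r["params"]["k_slice"]
            notes = f" [{'; '.join(r['notes'])}]" if r["notes"] else ""
            lines.append(
                f"- {r['path']}: k_slice = {ks:.3g} s^-1, tau_slice = "
                f"{r['tau_slice']}{notes}"
            )
        elif r["kind"] == "titration":
            lines.append(
                f"- {r['path']}: stock = {r['stock_pM']:.4g} pM "
                f"({r['model_used']} fit)"
            )
        elif r["kind"] == "association":
            lines.append(f"- {r['path']}: {r['summary']}")
        elif r["kind"] == "thermo":
            lines.append(
                f"- {r['path']}: dG_thres = {r['dG_thres']:.3g} kcal/mol"
            )
    return "\n".join(lines) + "\n"


def write_report(report: dict, output_dir) -> None:
    """Write results.json (sorted keys, deterministic) and summary.txt."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    (out / "summary.txt").write_text(_human_summary(report))
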