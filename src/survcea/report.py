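"""Report assembly: run the staged analyses and write their artifacts.

Each run writes CSV/JSON outputs plus a ``manifest.json`` recording the
SHA-256 of the resolved input document, the seed and the package version,
so identical configurations produce byte-identical output directories.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .params import EconomicInputs, default_inputs
from .sensitivity import BaseCaseResult, base_case, ceac, one_way_tornado, run_psa, threshold_price

log = logging.getLogger("survcea")

__all__ = ["run_base_case", "run_full_report", "manifest_for"]


def _inputs_digest(inputs: EconomicInputs) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    blob = json.dumps(dataclasses.asdict(inputs), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def manifest_for(inputs: EconomicInputs, seed: int | None = None) -> dict:
    return {
        "package": "survcea",
        "version": __version__,
        "inputs_sha256": _inputs_digest(inputs),
        "seed": seed if seed is not None else inputs.psa_seed,
        "engine_mode": inputs.spec.mode,
    }


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def run_base_case(inputs: EconomicInputs | None = None, out_dir=None) -> BaseCaseResult:
    """Run both arms at baseline; optionally write the incremental summary
    (Table-2 analogue), per-arm cost components and the manifest."""
    inputs = inputs if inputs is not None else default_inputs()
    res = base_case(inputs)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary = pd.DataFrame(
            [
                {"arm": "control", "total_cost": res.control.total_cost, "total_qalys": res.control.total_qalys},
                {"arm": "active", "total_cost": res.active.total_cost, "total_qalys": res.active.total_qalys},
            ]
        )
        summary.to_csv(out / "arm_results.csv", index=False)
        inc = res.incremental.as_dict()
        (out / "incremental.json").write_text(json.dumps(inc, indent=2) + "\n")
        pd.DataFrame(
            [
                {"arm": arm.arm, "component": comp, "cost": v}
                for arm in (res.control, res.active)
                for comp, v in arm.components.items()
            ]
        ).to_csv(out / "cost_components.csv", index=False)
        _write_manifest(out, manifest_for(inputs))
    return res


def run_full_report(
    inputs: EconomicInputs | None = None,
    out_dir="survcea_report",
    n_draws: int | None = None,
    seed: int | None = None,
    wtp_grid=None,
    plots: bool = True,
) -> dict:
    """Base case + tornado + PSA + CEAC + threshold price in one bundle.

    Later stages are skipped (with the cause logged) if an earlier stage
    fails; the returned dict maps stage name to result or exception.
    """
    inputs = inputs if inputs is not None else default_inputs()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}

    stages = [
        ("base_case", lambda: run_base_case(inputs, out)),
        ("tornado", lambda: one_way_tornado(inputs)),
        ("psa", lambda: run_psa(inputs, n_draws=n_draws, seed=seed)),
    ]
    failed = False
    for name, fn in stages:
        if failed:
            log.warning("skipping %s: earlier stage failed", name)
            continue
        try:
            results[name] = fn()
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            log.error("stage %s failed: %s", name, exc)
            results[name] = exc
            failed = True

    if not failed:
        tor: pd.DataFrame = results["tornado"]  # type: ignore[assignment]
        psa: pd.DataFrame = results["psa"]  # type: ignore[assignment]
        tor.to_csv(out / "tornado.csv", index=False)
        psa.to_csv(out / "psa_samples.csv", index=False)
        psa[["delta_cost", "delta_qalys"]].to_csv(out / "psa_scatter.csv", index=False)
        grid = wtp_grid if wtp_grid is not None else np.arange(0, 400_001, 10_000)
        curve = ceac(psa, grid)
        curve.to_csv(out / "ceac.csv", index=False)
        results["ceac"] = curve
        try:
            price = threshold_price(inputs)
            results["threshold_price"] = price
            (out / "threshold_price.json").write_text(
                json.dumps({"wtp": inputs.wtp, "price_per_80mg": price}, indent=2) + "\n"
            )
        except Exception as exc:  # noqa: BLE001
            log.error("threshold-price stage failed: %s", exc)
            results["threshold_price"] = exc
            failed = True
        if plots:
            _plots(out, tor, psa, curve, inputs.wtp)
    _write_manifest(out, manifest_for(inputs, seed))
    results["failed"] = failed
    return results


def _plots(out: Path, tornado: pd.DataFrame, psa: pd.DataFrame, curve: pd.DataFrame, wtp: float) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    top = tornado.head(10).iloc[::-1]
    lo = np.minimum(top["icer_at_min"], top["icer_at_max"])
    hi = np.maximum(top["icer_at_min"], top["icer_at_max"])
    ax.barh(top["parameter"], hi - lo, left=lo, color="steelblue")
    ax.set_xlabel("ICER ($/QALY)")
    ax.set_title("One-way sensitivity (top 10)")
    fig.tight_layout()
    fig.savefig(out / "tornado.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(psa["delta_qalys"], psa["delta_cost"], s=6, alpha=0.4)
    q = np.linspace(0, psa["delta_qalys"].max() * 1.05, 50)
    ax.plot(q, wtp * q, "r--", label=f"WTP ${wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost ($)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "psa_scatter.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["prob_cost_effective"])
    ax.set_xlabel("Willingness to pay ($/QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_ylim(-0.02, 1.02)
    fig.tight_layout()
    fig.savefig(out / "ceac.png", dpi=120)
    plt.close(fig)
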