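"""Pipeline orchestration: chain the fitting stages into one report.

Stage order follows the data dependencies of a dimerization study: decay
histograms give average lifetimes, lifetime-concentration tables give K_D,
K_D(T) gives the van't Hoff enthalpy/entropy; quenching series and NMR
titrations are independent side branches. A failing stage is recorded in
the report and does not stop later independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import io as sfio
from .errors import ConfigurationError, SuprafitError
from .isotherm import fit_isotherm
from .nmr_titration import fit_titration
from .photophysics import fit_decay
from .quenching import fit_stern_volmer
from .thermo import fit_vant_hoff

__all__ = ["AnalysisReport", "run_pipeline"]

log = logging.getLogger("suprafit")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


@dataclass
class AnalysisReport:
    """Aggregated, serializable results of a pipeline run."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(_jsonable(
            {"stages": self.stages, "provenance": self.provenance,
             "warnings": self.warnings}), indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "AnalysisReport":
        payload = json.loads(text)
        return cls(stages=payload["stages"],
                   provenance=payload["provenance"],
                   warnings=payload["warnings"])

    def save(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: dict, base_dir=None) -> AnalysisReport:
    """Execute the stages named in ``config`` and aggregate one report.

    Recognized stage keys (all optional, at least one required):

    * ``decays``: list of ``{"decay": file, "irf": file, "n": int}``
    * ``isotherm``: ``{"file": csv}``
    * ``vant_hoff``: ``{"file": csv, "weighted": bool}``
    * ``quench``: ``{"file": csv, "max_q": float}``
    * ``titration``: ``{"file": csv, "mode": "monomer"|"dimer",
      "k_dimer": float}``

    Plus an optional top-level ``seed`` recorded in provenance. File paths
    are resolved against ``base_dir`` when given.
    """
    known = {"decays", "isotherm", "vant_hoff", "quench", "titration", "seed"}
    unknown = set(config) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    stage_keys = [k for k in config if k != "seed"]
    if not stage_keys:
        raise ConfigurationError("config names no stages")

    base = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(name, stage):
        p = base / name
        if not p.exists():
            raise ConfigurationError(f"stage {stage!r}: input {p} not found")
        return p

    report = AnalysisReport()
    report.provenance = {
        "package": "suprafit",
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": config.get("seed"),
        "inputs": {},
    }

    def record_input(path):
        report.provenance["inputs"][str(path)] = _digest(path)

    def run_stage(name, fn):
        try:
            report.stages[name] = fn()
            log.info("stage %s completed", name)
        except (SuprafitError, OSError) as exc:
            log.warning("stage %s failed: %s", name, exc)
            report.stages[name] = {"error": str(exc)}
            report.warnings.append(f"{name}: {exc}")

    if "decays" in config:
        def _decays():
            out = []
            for entry in config["decays"]:
                dpath = resolve(entry["decay"], "decays")
                ipath = resolve(entry["irf"], "decays")
                record_input(dpath)
                record_input(ipath)
                res = fit_decay(sfio.read_decay_csv(dpath),
                                sfio.read_decay_csv(ipath),
                                n_components=int(entry.get("n", 3)))
                out.append({
                    "decay_file": str(dpath),
                    "lifetimes_ns": res.model.lifetimes,
                    "amplitudes": res.model.amplitudes,
                    "average_lifetime_ns": res.average_lifetime,
                    "fractional_contributions": res.fractional_contributions,
                    "reduced_chi_square": res.reduced_chi_square,
                    "overparameterized": res.overparameterized,
                    "units": {"lifetimes": "ns"},
                })
            return out
        run_stage("decays", _decays)

    if "isotherm" in config:
        def _isotherm():
            path = resolve(config["isotherm"]["file"], "isotherm")
            record_input(path)
            res = fit_isotherm(sfio.read_isotherm_csv(path))
            return {
                "K_D": res.k_dimer, "K_D_stderr": res.k_dimer_stderr,
                "tau_monomer_ns": res.tau_monomer,
                "tau_monomer_stderr_ns": res.tau_monomer_stderr,
                "tau_dimer_ns": res.tau_dimer,
                "tau_dimer_stderr_ns": res.tau_dimer_stderr,
                "k_unreliable": res.k_unreliable,
                "units": {"K_D": "L/mol", "tau": "ns"},
            }
        run_stage("isotherm", _isotherm)

    if "vant_hoff" in config:
        def _vanthoff():
            path = resolve(config["vant_hoff"]["file"], "vant_hoff")
            record_input(path)
            res = fit_vant_hoff(sfio.read_vant_hoff_csv(path),
                                weighted=bool(config["vant_hoff"].get("weighted")))
            return {
                "delta_H_kJ_mol": res.delta_h,
                "delta_H_stderr_kJ_mol": res.delta_h_stderr,
                "delta_S_J_K_mol": res.delta_s,
                "delta_S_stderr_J_K_mol": res.delta_s_stderr,
                "r_squared": res.r_squared,
                "units": {"delta_H": "kJ/mol", "delta_S": "J/(K mol)"},
            }
        run_stage("vant_hoff", _vanthoff)

    if "quench" in config:
        def _quench():
            path = resolve(config["quench"]["file"], "quench")
            record_input(path)
            res = fit_stern_volmer(sfio.read_quench_csv(path),
                                   max_q=config["quench"].get("max_q"))
            return {
                "K_SV": res.k_sv, "K_SV_stderr": res.k_sv_stderr,
                "tau_unquenched_ns": res.tau_unquenched,
                "k_q": res.k_q, "k_q_stderr": res.k_q_stderr,
                "r_squared": res.r_squared,
                "intercept_deviates": res.intercept_deviates,
                "units": {"K_SV": "L/mol", "k_q": "L/(mol s)"},
            }
        run_stage("quench", _quench)

    if "titration" in config:
        def _titration():
            cfg = config["titration"]
            path = resolve(cfg["file"], "titration")
            record_input(path)
            res = fit_titration(sfio.read_titration_csv(path),
                                stoichiometry=cfg.get("mode", "monomer"),
                                k_dimer=cfg.get("k_dimer"))
            return {
                "K_a": res.k_assoc, "K_a_stderr": res.k_assoc_stderr,
                "delta_max_ppm": res.delta_max,
                "delta_max_stderr_ppm": res.delta_max_stderr,
                "effective_host_M": res.effective_host,
                "saturation_final": res.saturation_final,
                "weak_saturation": res.weak_saturation,
                "units": {"K_a": "L/mol", "delta_max": "ppm",
                          "effective_host": "mol/L"},
            }
        run_stage("titration", _titration)

    return report
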