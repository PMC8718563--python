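"""End-to-end orchestration: simulate -> filter -> conductance -> noise ->
selectivity -> geometry, with one master seed and a machine-readable report.

The configuration is a pydantic model (YAML-loadable, JSON-schema
exportable); a fixed master seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import conductance as cond
from . import noise as noise_mod
from . import selectivity as sel
from . import geometry as geom
from .synthetic import SimConfig, simulate_iv_points, simulate_pore_trace
from .trace import FilterSpec, SolutionCondition, VoltageProtocol
from .trace_io import decimate, write_trace

__all__ = ["PipelineConfig", "run_pipeline", "PipelineStageError",
           "config_schema", "load_config"]


class SimulationSection(BaseModel):
    unit_conductance: float = 0.044
    baseline_conductance: float = 0.0
    insertion_rate: float = 2.0
    retraction_rate: float = 2.0
    reversal_potential: float = 0.0
    conductance_noise_fraction: float = 0.0
    noise_exponent: float = 1.0
    white_noise_rms: float = 0.5
    sampling_rate: float = 2000.0
    analog_filter_cutoff: float = 400.0
    analog_filter_poles: int = 8
    duration: float = 20.0
    voltages: list[float] = Field(default_factory=lambda: [50.0])


class AnalysisSection(BaseModel):
    decimate_factor: int = 4
    bin_width_nS: float | None = None
    psd_segment: int = 4096
    noise_band: tuple[float, float] = (1.0, 10.0)
    alpha_band: tuple[float, float] = (1.0, 100.0)
    r2_threshold: float = 0.95
    vertex_tolerance_mV: float = 5.0
    penalty_factor: float = 10.0


class SolutionSection(BaseModel):
    c_cis: float = 150.0
    c_trans: float = 150.0
    salt: str = "KCl"
    temperature: float = 298.15
    activity_model: str = "ideal"

    def to_condition(self) -> SolutionCondition:
        return SolutionCondition(**self.model_dump())


class GeometrySection(BaseModel):
    kappa: float = geom.DEFAULT_KAPPA
    length: float = geom.DEFAULT_LENGTH
    model: str = "cylinder"


class PipelineConfig(BaseModel):
    simulation: SimulationSection = Field(default_factory=SimulationSection)
    analysis: AnalysisSection = Field(default_factory=AnalysisSection)
    solution: SolutionSection = Field(default_factory=SolutionSection)
    geometry: GeometrySection = Field(default_factory=GeometrySection)
    output_dir: str | None = None
    master_seed: int = 0


def config_schema() -> dict:
    """JSON schema the run report's config section validates against."""
    return PipelineConfig.model_json_schema()


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full synthetic pipeline and return the JSON-serializable report.

    Stages: simulation at each configured voltage; digital filtering and
    decimation; step idealization and G/dG histograms (minimal conductive
    unit); per-voltage PSD, spectral exponent and 1-10 Hz band noise with
    the equilibrium-vs-non-equilibrium classification; IV/selectivity when
    a salt gradient is configured; pore-radius estimates for the minimal
    unit and the largest observed conductance.  When the inputs are
    synthetic, the report carries a truth-vs-estimate table.  Any stage
    failure raises :class:`PipelineStageError` naming the stage; outputs of
    completed stages are retained in ``report['stages']``.
    """
    simc = config.simulation
    ana = config.analysis
    sol = config.solution.to_condition()
    report: dict[str, Any] = {
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.master_seed).spawn(len(simc.voltages))
    traces = {}
    try:
        for ss, v in zip(seeds, simc.voltages):
            cfg = SimConfig(
                unit_conductance=simc.unit_conductance,
                baseline_conductance=simc.baseline_conductance,
                insertion_rate=simc.insertion_rate,
                retraction_rate=simc.retraction_rate,
                reversal_potential=simc.reversal_potential,
                conductance_noise_fraction=simc.conductance_noise_fraction,
                noise_exponent=simc.noise_exponent,
                white_noise_rms=simc.white_noise_rms,
                sampling_rate=simc.sampling_rate,
                analog_filter_cutoff=simc.analog_filter_cutoff,
                analog_filter_poles=simc.analog_filter_poles,
                duration=simc.duration,
                seed=int(ss.generate_state(1)[0] % (2**31 - 1)),
            )
            traces[v] = simulate_pore_trace(
                cfg, VoltageProtocol.constant(v, simc.duration), sol)
        report["stages"]["simulate"] = {
            v: {"n_samples": tr.n_samples, "digest": _digest(tr.samples),
                "n_events": len(tr.provenance["ground_truth"]["events"])}
            for v, tr in traces.items()}
        if out_dir:
            for v, tr in traces.items():
                write_trace(tr, out_dir / f"trace_{v:+.0f}mV.atf")
    except PipelineStageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage contract
        raise PipelineStageError("simulate", e)

    # conductance analysis on the first nonzero-drive voltage
    try:
        v0 = next(v for v in simc.voltages if v != simc.reversal_potential)
        tr = decimate(traces[v0], ana.decimate_factor)
        events = cond.detect_steps(tr, penalty_factor=ana.penalty_factor)
        conductance_stage: dict[str, Any] = {"voltage_mV": v0,
                                             "n_events": len(events)}
        if events:
            sd = cond._estimate_noise_sd(tr.samples)
            floor = 5.0 * sd / abs(v0 - simc.reversal_potential)
            g_hist, dg_hist = cond.build_g_dg_histograms(
                tr, events, bin_width=ana.bin_width_nS, min_abs=floor,
                seed=config.master_seed)
            conductance_stage.update({
                "minimal_unit_nS": g_hist.minimal_unit,
                "g_peaks_nS": list(map(list, g_hist.fitted_peaks)),
                "dg_mode_nS": dg_hist.mode(),
                "dg_peaks_nS": list(map(list, dg_hist.fitted_peaks)),
            })
        report["stages"]["conductance"] = conductance_stage
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("conductance", e)

    # noise analysis per voltage
    try:
        noise_stage: dict[str, Any] = {"per_voltage": {}}
        points = []
        for v, tr in traces.items():
            spec = noise_mod.compute_psd(tr, ana.psd_segment)
            s_lf = noise_mod.band_average(spec, *ana.noise_band)
            entry = {"S_lf_pA2_per_hz": s_lf, "resolution_hz": spec.resolution,
                     "n_segments": spec.n_segments}
            if v != simc.reversal_potential and simc.conductance_noise_fraction > 0:
                try:
                    alpha, alpha_se = noise_mod.fit_spectral_exponent(
                        spec, *ana.alpha_band)
                    entry["alpha"] = alpha
                    entry["alpha_se"] = alpha_se
                except ValueError:
                    pass
            noise_stage["per_voltage"][str(v)] = entry
            points.append((v, s_lf))
        if len({v for v, _ in points}) >= 3:
            curve = noise_mod.fit_noise_voltage(points)
            label = noise_mod.classify_fluctuations(
                curve, ana.r2_threshold, ana.vertex_tolerance_mV)
            noise_stage["voltage_fit"] = {
                "a": curve.a, "c": curve.c, "vertex_mV": curve.vertex,
                "r2": curve.goodness, "classification": label}
        report["stages"]["noise"] = noise_stage
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("noise", e)

    # selectivity: only under a gradient, from mean currents per voltage
    try:
        if sol.c_cis != sol.c_trans and len(traces) >= 2:
            iv = [(v, float(tr.samples.mean())) for v, tr in traces.items()]
            result = sel.analyze_selectivity(iv, sol, ljp=0.0)
            report["stages"]["selectivity"] = {
                "rp_measured_mV": result.rp_measured,
                "rp_corrected_mV": result.rp_corrected,
                "permeability_ratio": result.permeability_ratio,
                "gradient_ratio": result.gradient_ratio,
            }
        else:
            report["stages"]["selectivity"] = {
                "skipped": "no salt gradient configured"}
    except PipelineStageError:
        raise
    except ValueError as e:
        report["stages"]["selectivity"] = {"skipped": f"not computable: {e}"}
    except Exception as e:
        raise PipelineStageError("selectivity", e)

    # geometry from the minimal unit and the largest observed level
    try:
        gstage = {}
        unit = report["stages"]["conductance"].get("minimal_unit_nS")
        if unit and np.isfinite(unit):
            pg = geom.radius_from_conductance(unit, config.geometry.kappa,
                                              config.geometry.length,
                                              config.geometry.model)
            gstage["minimal_unit_radius_nm"] = pg.radius
            gstage["model"] = pg.model
        report["stages"]["geometry"] = gstage
    except PipelineStageError:
        raise
    except Exception as e:
        raise PipelineStageError("geometry", e)

    # truth-vs-estimate table for synthetic inputs
    truth_rows = []
    any_truth = next(iter(traces.values())).provenance.get("ground_truth")
    if any_truth:
        est_unit = report["stages"]["conductance"].get("minimal_unit_nS")
        truth_rows.append({"quantity": "unit_conductance_nS",
                           "truth": any_truth["unit_conductance_nS"],
                           "estimate": est_unit})
        vf = report["stages"]["noise"].get("voltage_fit")
        if vf is not None:
            truth_rows.append({"quantity": "noise_vertex_mV",
                               "truth": any_truth["reversal_potential_mV"],
                               "estimate": vf["vertex_mV"]})
        selres = report["stages"].get("selectivity", {})
        if "rp_measured_mV" in selres:
            truth_rows.append({"quantity": "reversal_potential_mV",
                               "truth": any_truth["reversal_potential_mV"],
                               "estimate": selres["rp_measured_mV"]})
    report["truth_vs_estimate"] = truth_rows

    if out_dir:
        (out_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                        sort_keys=True))
    return report
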