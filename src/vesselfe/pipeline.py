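"""Two-level macro → micro → statistics pipeline driven by one RunConfig.

Stages (each callable on its own, chained by :func:`run_pipeline`):

  synth    - synthetic network + tissue intensity volume
  mesh     - segmentation, voxel meshing, surface smoothing, beam splitting
  simulate - explicit macroscale CCI run
  map      - vessel-stress map and threshold exceedance areas
  analyze  - per-beam records, correlations, partial correlations, ROC

Every stage is deterministic given the configured seeds; rerunning a
pipeline with the same config reproduces the CSV outputs byte for byte.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .analysis import build_records, correlation_suite, tension_compression_roc
from .config import RunConfig, dump_config
from .mapping import map_vessel_stress, threshold_area
from .materials import OgdenPronyMaterial, VesselMaterial
from .meshing import discretize_network, segment_image, smooth_outer_surface, voxelize
from .solver import SimulationHistory, SolverControls, run_macro
from .synthetic import (
    NetworkCalibration,
    generate_network,
    generate_tissue_image,
    make_cci_scenario,
    network_stats,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "materials_from_config",
           "analyze_records"]


@dataclass
class PipelineResult:
    network: object
    image: object
    mesh: object
    beams: object
    history: SimulationHistory
    stress_map: object
    areas: dict
    records: pd.DataFrame
    stats: dict
    paths: dict


def materials_from_config(cfg: RunConfig):
    t = cfg.materials.tissue
    v = cfg.materials.vessel
    tissue = OgdenPronyMaterial(
        ogden_terms=tuple(tuple(x) for x in t.ogden_terms),
        prony_terms=tuple(tuple(x) for x in t.prony_terms),
        density=t.density,
        poisson_ratio=t.poisson_ratio,
    )
    vessel = VesselMaterial(
        elastic_modulus=v.elastic_modulus,
        poisson_ratio=v.poisson_ratio,
        density=v.density,
    )
    return tissue, vessel


def analyze_records(records: pd.DataFrame, n_bootstrap: int = 500,
                    seed: int = 0, tension_only: bool = True) -> dict:
    """The direction/correlation statistics battery on a records table.

    Magnitude correlations are computed on tensile records (the injury
    metric is tension); the tension-vs-compression ROC uses all records.
    """
    tens = records[records["axial_stress"] > 0] if tension_only else records
    out: dict = {"n_records": len(records), "n_tension": len(tens)}

    cs = correlation_suite(tens, "angle_stress", "axial_stress", control="s1")
    out.update(r_angle_stress=cs.r, p_angle_stress=cs.p,
               partial_r_angle_stress=cs.partial_r)
    lg = correlation_suite(tens, "angle_stress", "axial_stress",
                           transform="log10")
    out.update(log_slope_angle_stress=lg.slope, log_r2_angle_stress=lg.r_squared)
    ce = correlation_suite(tens, "angle_strain", "axial_stress", control="e1")
    out.update(r_angle_strain=ce.r, p_angle_strain=ce.p,
               partial_r_angle_strain=ce.partial_r)

    for name, xcol, ctrl in (
        ("dev_stress", "s1_dev", "angle_stress"),
        ("total_stress", "s1", "angle_stress"),
        ("dev_strain", "e1_dev", "angle_strain"),
        ("total_strain", "e1", "angle_strain"),
    ):
        c = correlation_suite(tens, xcol, "axial_stress", control=ctrl)
        out[f"r_{name}"] = c.r
        out[f"partial_r_{name}"] = c.partial_r

    roc_s = tension_compression_roc(records, "angle_stress",
                                    n_bootstrap=n_bootstrap, seed=seed)
    out.update(auc_angle_stress=roc_s.auc, auc_angle_stress_ci_low=roc_s.ci_low,
               auc_angle_stress_ci_high=roc_s.ci_high)
    roc_e = tension_compression_roc(records, "angle_strain",
                                    n_bootstrap=n_bootstrap, seed=seed + 1)
    out.update(auc_angle_strain=roc_e.auc, auc_angle_strain_ci_low=roc_e.ci_low,
               auc_angle_strain_ci_high=roc_e.ci_high)
    return out


def run_pipeline(cfg: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    out = Path(out_dir if out_dir is not None else cfg.output.directory)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(cfg, out / "resolved_config.yaml")
    t_wall = time.perf_counter()

    # --- synth ---
    domain = np.asarray(cfg.domain_size, dtype=float)
    cal = NetworkCalibration(**cfg.network.calibration)
    net = generate_network(domain, cal, seed=cfg.seed)
    stats_net = network_stats(net)
    logger.info("synth: %d segments, mean diameter %.2f µm, volume fraction %.3f",
                stats_net.segment_count, stats_net.mean_diameter,
                stats_net.volume_fraction or -1.0)
    vio.write_network_csv(net, out / "network_nodes.csv",
                          out / "network_segments.csv")
    vio.write_network_json(net, out / "network.json")
    img = generate_tissue_image(domain, cfg.image.spacing, net=None,
                                seed=cfg.seed + 1, shape=cfg.image.shape,
                                noise_sd=cfg.image.noise_sd)
    if cfg.output.write_image:
        vio.write_image(img, out / "image.tif")

    # --- mesh ---
    mask = segment_image(img, cfg.image.threshold)
    mesh = voxelize(mask, img.spacing, coarsen=cfg.meshing.coarsen,
                    origin=img.origin)
    if cfg.meshing.smooth_iterations > 0:
        mesh = smooth_outer_surface(mesh, cfg.meshing.smooth_iterations,
                                    cfg.meshing.smooth_strength)
    beam_max_len = cfg.meshing.beam_max_len or mesh.element_size or 50.0
    beams = discretize_network(net, max_len=beam_max_len)
    logger.info("mesh: %d hex elements (%.1f µm), %d beams",
                mesh.n_elements, mesh.element_size or -1.0, beams.n_elements)

    # --- simulate ---
    tissue, vessel = materials_from_config(cfg)
    scenario = make_cci_scenario(cfg.scenario.model_dump())
    s = cfg.solver
    controls = SolverControls(
        output_interval=s.output_interval, safety=s.safety,
        hourglass_coeff=s.hourglass_coeff,
        hourglass_stiffness=s.hourglass_stiffness,
        contact_stiffness_scale=s.contact_stiffness_scale,
        contact_damping=s.contact_damping,
        energy_tolerance=s.energy_tolerance, check_energy=s.check_energy,
        lateral_bc=s.lateral_bc,
        total_time=s.total_time,
    )
    history = run_macro(mesh, beams, tissue, vessel, scenario, controls)
    if cfg.output.write_fields:
        vio.write_field_series(history, mesh, beams, out / "fields")

    # --- map ---
    smap = map_vessel_stress(history, mesh, beams,
                             cfg.mapping.neighbourhood_radius,
                             tensile_only=cfg.mapping.tensile_only)
    areas = {
        "all": threshold_area(smap, mesh, cfg.mapping.thresholds,
                              slice_axis=cfg.mapping.slice_axis,
                              slice_coord=cfg.mapping.slice_coord)
    }

    # --- analyze ---
    records = build_records(history, mesh, beams)
    stats = analyze_records(records, n_bootstrap=cfg.analysis.n_bootstrap,
                            seed=cfg.seed,
                            tension_only=cfg.analysis.tension_only_correlations)
    paths = vio.export_tables(records, areas, stats, out)
    logger.info("pipeline done in %.1f s: %s", time.perf_counter() - t_wall,
                {k: v for k, v in stats.items() if k.startswith(("r_", "auc"))})
    return PipelineResult(
        network=net, image=img, mesh=mesh, beams=beams, history=history,
        stress_map=smap, areas=areas, records=records, stats=stats, paths=paths,
    )
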