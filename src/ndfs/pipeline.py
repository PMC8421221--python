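"""End-to-end pipeline: angle tables in, landscapes / predictions / forces out.

Stages
------
``landscape``   density, Boltzmann free energy, torque, force map, bootstrap
                uncertainties for every device ensemble in the input table.
``couple``      coupled hinge-linker-sample prediction seeded by each
                device's measured (or synthetic) angular distribution.
``nucleosome``  unwrapping and constrained-angle predictions plus the
                tensile-force estimate at the constrained most-likely angle.
``elastica``    post-buckling force versus end-to-end distance for the
                configured sample rod.

Every JSON summary is stamped with the configuration hash and the seed so a
rerun with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import numpy as np

from . import io as ndfs_io
from .config import RunConfig
from .coupling import CoupledSystemSpec, coupled_free_energy_and_force
from .elastica import ElasticaSpec, euler_critical_force, postbuckling_force
from .exceptions import InputError
from .landscape import (
    boltzmann_free_energy,
    bootstrap_uncertainty,
    estimate_density,
    force_map,
    peak_angle,
    torque_profile,
)
from .nucleosome import (
    mean_total_unwrapped,
    predict_constrained_angle_distribution,
    predict_unwrap_distribution,
    tensile_force_estimate,
)

log = logging.getLogger("ndfs.pipeline")

ALL_STAGES = ("landscape", "couple", "nucleosome", "elastica")


def _summary_stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash, "seed": config.seed}


def run_pipeline(
    config: RunConfig,
    angle_table=None,
    stages=ALL_STAGES,
    outdir=None,
) -> dict:
    """Execute the requested stages and (optionally) write their outputs.

    ``angle_table`` is a path to a delimited angle table or an
    :class:`ndfs.io.AngleTable`; it is required by every stage except
    ``elastica``. Returns a result bundle keyed by stage.
    """
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise InputError(f"unknown stages: {sorted(unknown)}; valid: {ALL_STAGES}")
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    results: dict = {"config": config.to_dict(), "config_hash": config.config_hash}
    needs_angles = any(s in stages for s in ("landscape", "couple", "nucleosome"))
    table = None
    if needs_angles:
        if angle_table is None:
            raise InputError(
                "stages landscape/couple/nucleosome require an angle table; "
                "none was provided"
            )
        table = (
            angle_table
            if isinstance(angle_table, ndfs_io.AngleTable)
            else ndfs_io.read_angle_table(angle_table)
        )

    thermal = config.thermal()
    geometry = config.geometry()

    if "landscape" in stages:
        t0 = time.perf_counter()
        stage: dict = {}
        for label, ens in table.ensembles.items():
            dist = estimate_density(ens, bin_width=config.angle_bin)
            scape = boltzmann_free_energy(
                dist, cutoff=config.density_cutoff, smoothing=config.spline_smoothing
            )
            profile = force_map(
                torque_profile(scape, thermal),
                config.radial_min,
                config.radial_max,
            )
            boot = bootstrap_uncertainty(
                ens, "mean", replicates=config.bootstrap_replicates, seed=config.seed
            )
            summary = {
                **_summary_stamp(config),
                "device_label": label,
                "n_particles": len(ens),
                "valid_range_deg": list(scape.valid_range),
                "peak_angle_deg": peak_angle(dist),
                "mean_angle_deg": boot.point_estimate,
                "mean_angle_bootstrap_sd_deg": boot.standard_deviation,
                "force_range_pN": [
                    float(np.min(profile.force_map)),
                    float(np.max(profile.force_map)),
                ],
            }
            stage[label] = {
                "distribution": dist,
                "landscape": scape,
                "profile": profile,
                "summary": summary,
            }
            if outdir is not None:
                tag = label.replace(".", "_") or "ensemble"
                ndfs_io.write_distribution_csv(outdir / f"density_{tag}.csv", dist)
                ndfs_io.landscape_to_frame(scape).to_csv(
                    outdir / f"landscape_{tag}.csv", index=False
                )
                ndfs_io.torque_to_frame(profile).to_csv(
                    outdir / f"torque_{tag}.csv", index=False
                )
                ndfs_io.force_map_to_frame(profile).to_csv(
                    outdir / f"force_map_{tag}.csv", index=False
                )
                (outdir / f"summary_{tag}.json").write_text(
                    json.dumps(summary, indent=2) + "\n"
                )
        results["landscape"] = stage
        log.info("landscape stage: %.2f s", time.perf_counter() - t0)

    if "couple" in stages:
        if "landscape" not in results:
            raise InputError(
                "stage 'couple' needs the angular distributions from the "
                "'landscape' stage; add 'landscape' to the requested stages"
            )
        t0 = time.perf_counter()
        stage = {}
        for label, entry in results["landscape"].items():
            spec = CoupledSystemSpec(
                hinge_dist=entry["distribution"],
                linker1=config.linker(),
                linker2=config.linker(),
                sample=config.sample_wlc(),
                geometry=geometry,
                grid_spacing=config.grid_spacing,
            )
            coupled = coupled_free_energy_and_force(spec, thermal)
            i_peak = int(np.argmax(coupled.distribution.density))
            summary = {
                **_summary_stamp(config),
                "device_label": label,
                "predicted_peak_angle_deg": float(
                    coupled.distribution.bin_centers[i_peak]
                ),
                "force_at_peak_pN": float(
                    coupled.force[np.argmin(coupled.G)]
                ),
                "force_range_pN": [float(coupled.force.min()), float(coupled.force.max())],
            }
            stage[label] = {"coupled": coupled, "summary": summary}
            if outdir is not None:
                tag = label.replace(".", "_") or "ensemble"
                ndfs_io.write_distribution_csv(
                    outdir / f"coupled_distribution_{tag}.csv", coupled.distribution
                )
                (outdir / f"coupled_force_{tag}.json").write_text(
                    json.dumps(summary, indent=2) + "\n"
                )
        results["couple"] = stage
        log.info("couple stage: %.2f s", time.perf_counter() - t0)

    if "nucleosome" in stages:
        if "landscape" not in results:
            raise InputError(
                "stage 'nucleosome' needs the angular distributions from the "
                "'landscape' stage; add 'landscape' to the requested stages"
            )
        t0 = time.perf_counter()
        stage = {}
        nuc = config.nucleosome_spec()
        for label, entry in results["landscape"].items():
            dist = entry["distribution"]
            unwrap = predict_unwrap_distribution(dist, nuc, geometry)
            constrained = predict_constrained_angle_distribution(dist, nuc, geometry)
            theta_star = peak_angle(constrained)
            lo, hi = entry["landscape"].valid_range
            force = None
            if lo + 0.2 <= theta_star <= hi - 0.2:
                force = tensile_force_estimate(
                    entry["landscape"], theta_star, geometry, thermal
                )
            summary = {
                **_summary_stamp(config),
                "device_label": label,
                "mean_unwrapped_bp": mean_total_unwrapped(dist, nuc, geometry),
                "constrained_peak_angle_deg": theta_star,
                "tensile_force_pN": force,
            }
            stage[label] = {
                "unwrapping": unwrap,
                "constrained": constrained,
                "summary": summary,
            }
            if outdir is not None:
                tag = label.replace(".", "_") or "ensemble"
                uw = ndfs_io.pd.DataFrame(
                    {
                        "bin_left_bp": unwrap.bin_edges[:-1],
                        "bin_right_bp": unwrap.bin_edges[1:],
                        "density_per_bp": unwrap.density,
                    }
                )
                uw.to_csv(outdir / f"unwrapping_{tag}.csv", index=False)
                ndfs_io.write_distribution_csv(
                    outdir / f"constrained_angles_{tag}.csv", constrained
                )
                (outdir / f"nucleosome_force_{tag}.json").write_text(
                    json.dumps(summary, indent=2) + "\n"
                )
        results["nucleosome"] = stage
        log.info("nucleosome stage: %.2f s", time.perf_counter() - t0)

    if "elastica" in stages:
        t0 = time.perf_counter()
        spec = ElasticaSpec.from_wlc(config.sample_wlc(), thermal)
        ee = np.linspace(0.2 * spec.Lc, 0.995 * spec.Lc, 160)
        force = np.array([postbuckling_force(e, spec) for e in ee])
        summary = {
            **_summary_stamp(config),
            "EI_pN_nm2": spec.EI,
            "Lc_nm": spec.Lc,
            "critical_force_pN": euler_critical_force(spec),
        }
        results["elastica"] = {
            "end_to_end_nm": ee,
            "force_pN": force,
            "summary": summary,
        }
        if outdir is not None:
            ndfs_io.pd.DataFrame(
                {"end_to_end_nm": ee, "force_pN": force}
            ).to_csv(outdir / "elastica_force.csv", index=False)
            (outdir / "elastica_summary.json").write_text(
                json.dumps(summary, indent=2) + "\n"
            )
        log.info("elastica stage: %.2f s", time.perf_counter() - t0)

    return results
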