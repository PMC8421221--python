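"""Readers and writers for angle tables, distributions, and landscapes.

All formats are plain delimited text (CSV/TSV) or JSON. Angle tables carry
one hinge angle per row in an ``angle_deg`` column with an optional
``device_label`` column; rows outside (0, 180) degrees are rejected and
counted rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .landscape import (
    AngleEnsemble,
    AngularDistribution,
    FreeEnergyLandscape,
    TorqueForceProfile,
)

#: Reject the whole file when more than this fraction of rows is unparseable.
MAX_BAD_ROW_FRACTION = 0.5


@dataclass
class AngleTable:
    """Parsed angle table: one ensemble per device label plus rejection stats."""

    ensembles: dict
    n_rejected: int
    rejected_rows: list


def read_angle_table(path, source: str = "measured") -> AngleTable:
    """Read a delimited angle table into per-label ensembles.

    The delimiter is sniffed (CSV and TSV both work). Rows whose angle is
    missing, unparseable, or outside (0, 180) are rejected; their 1-based
    data row numbers are reported. More than half bad rows is an input
    error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"angle table not found: {path}")
    # sniff the delimiter from the header; csv.Sniffer misfires on
    # single-column files
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise InputError(f"angle table is empty: {path}") from None
    if "angle_deg" not in frame.columns:
        raise InputError(
            f"angle table {path} is missing the required 'angle_deg' column "
            f"(found: {list(frame.columns)})"
        )
    if len(frame) == 0:
        raise InputError(f"angle table has no data rows: {path}")
    angles = pd.to_numeric(frame["angle_deg"], errors="coerce")
    ok = angles.notna() & (angles > 0) & (angles < 180)
    rejected = [int(i) + 1 for i in np.flatnonzero(~ok.to_numpy())]
    if len(rejected) > MAX_BAD_ROW_FRACTION * len(frame):
        raise InputError(
            f"{len(rejected)}/{len(frame)} rows of {path} are unusable "
            f"(first bad rows: {rejected[:10]})"
        )
    if not ok.any():
        raise InputError(f"no valid angle rows in {path}")
    labels = (
        frame["device_label"].astype(str)
        if "device_label" in frame.columns
        else pd.Series([""] * len(frame))
    )
    ensembles = {}
    for label, group in angles[ok].groupby(labels[ok]):
        ensembles[label] = AngleEnsemble(
            group.to_numpy(), device_label=label, source=source
        )
    return AngleTable(ensembles=ensembles, n_rejected=len(rejected), rejected_rows=rejected)


def write_angle_table(path, ensembles) -> None:
    """Write one or more ensembles back to a CSV angle table."""
    if isinstance(ensembles, AngleEnsemble):
        ensembles = [ensembles]
    if isinstance(ensembles, dict):
        ensembles = list(ensembles.values())
    rows = []
    for ens in ensembles:
        for a in ens.angles:
            rows.append({"angle_deg": f"{a:.4f}", "device_label": ens.device_label})
    pd.DataFrame(rows).to_csv(path, index=False)


def distribution_to_frame(dist: AngularDistribution) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_left_deg": dist.bin_edges[:-1],
            "bin_right_deg": dist.bin_edges[1:],
            "density_per_deg": dist.density,
        }
    )


def write_distribution_csv(path, dist: AngularDistribution) -> None:
    distribution_to_frame(dist).to_csv(path, index=False)


def read_distribution_csv(path) -> AngularDistribution:
    frame = pd.read_csv(path)
    required = {"bin_left_deg", "bin_right_deg", "density_per_deg"}
    if not required.issubset(frame.columns):
        raise InputError(
            f"distribution file {path} must have columns {sorted(required)}"
        )
    edges = np.concatenate(
        [frame["bin_left_deg"].to_numpy(), frame["bin_right_deg"].to_numpy()[-1:]]
    )
    return AngularDistribution(edges, frame["density_per_deg"].to_numpy())


def landscape_to_frame(landscape: FreeEnergyLandscape) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "theta_deg": landscape.theta_grid,
            "G_kBT": landscape.G,
            "G_spline_kBT": landscape.spline(landscape.theta_grid),
        }
    )


def torque_to_frame(profile: TorqueForceProfile) -> pd.DataFrame:
    return pd.DataFrame({"theta_deg": profile.theta_grid, "torque_pN_nm": profile.torque})


def force_map_to_frame(profile: TorqueForceProfile) -> pd.DataFrame:
    if profile.force_map is None:
        raise InputError("profile has no force map; call force_map() first")
    t, d = np.meshgrid(profile.theta_grid, profile.d_grid, indexing="ij")
    return pd.DataFrame(
        {
            "theta_deg": t.ravel(),
            "radial_nm": d.ravel(),
            "force_pN": profile.force_map.ravel(),
        }
    )
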