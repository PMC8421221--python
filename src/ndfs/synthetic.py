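"""Synthetic data generators emulating the measured inputs of the pipeline.

Electron-micrograph angle measurements of hinge devices arrive as one angle
per particle. The generators here emulate those ensembles with a
skew-normal angle distribution truncated to (0, 180) degrees plus Gaussian
measurement noise, with per-variant presets fit to the reported summary
statistics of the device family:

* ``nDFS.A`` - the flexible baseline: mean 70 deg, bulk ~50-100 deg with
  tails reaching ~25-125 deg.
* ``nDFS.B`` - biased open: mean 83 deg, bulk ~70-110 deg, ~90%+ of mass
  above 60 deg.
* ``nDFS.C-35`` - biased closed: ~93% of mass below 60 deg, primarily
  10-50 deg.

The generators are the measurement proxy only: they emulate the angular
statistics, not micrograph formation, particle picking, or any
two-dimensional projection bias of surface-deposited particles.

The module also provides Monte-Carlo samplers that serve as independent
oracles for the deterministic models: inverse-CDF sampling of the
stiff-polymer end-to-end density, and an importance-weighted sampler of the
coupled hinge-linker-sample distribution. All generators are pure functions
of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .coupling import CoupledSystemSpec, chord_distance
from .exceptions import InputError, ModelError, ParameterError
from .landscape import AngleEnsemble, AngularDistribution
from .polymer import WLCSpec, wlc_frey_pdf

_PRESETS = {
    # label: (skew a, location, scale) of the skew-normal, degrees
    "nDFS.A": (1.0, 59.8, 18.0),
    "nDFS.B": (2.0, 73.0, 14.0),
    "nDFS.C-35": (2.0, 27.0, 18.0),
}

#: Manifest schema version written by :func:`make_fixture_suite`.
FIXTURE_SCHEMA = 1


@dataclass(frozen=True)
class DeviceVariantModel:
    """Skew-normal angle-ensemble model for one device variant.

    ``loc``/``scale``/``skew`` parameterize the skew-normal before
    truncation to (0, 180); ``measurement_noise_sd`` is the SD (degrees) of
    independent additive noise emulating the manual two-line angle
    measurement.
    """

    label: str
    loc: float
    scale: float
    skew: float = 0.0
    measurement_noise_sd: float = 2.0
    default_N: int = 500

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ParameterError(f"scale must be positive, got {self.scale}")
        if self.measurement_noise_sd < 0:
            raise ParameterError("measurement noise SD must be non-negative")

    @classmethod
    def preset(cls, label: str, **overrides) -> "DeviceVariantModel":
        try:
            skew, loc, scale = _PRESETS[label]
        except KeyError:
            raise InputError(
                f"unknown device preset {label!r}; available: {sorted(_PRESETS)}"
            ) from None
        params = dict(label=label, loc=loc, scale=scale, skew=skew)
        params.update(overrides)
        return cls(**params)


def generate_angle_ensemble(
    model: DeviceVariantModel, N: int = None, seed: int = None
) -> AngleEnsemble:
    """Draw ``N`` noisy hinge angles from the variant model (degrees).

    Draws outside (0, 180) after adding measurement noise are redrawn, so
    the output emulates truncation rather than clipping. Reproducible per
    seed.
    """
    N = model.default_N if N is None else N
    if N < 1:
        raise InputError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    out = np.empty(0)
    while out.size < N:
        deficit = N - out.size
        draw = stats.skewnorm.rvs(
            model.skew, loc=model.loc, scale=model.scale, size=2 * deficit + 16,
            random_state=rng,
        )
        draw = draw + rng.normal(0.0, model.measurement_noise_sd, size=draw.size)
        draw = draw[(draw > 0) & (draw < 180)]
        out = np.concatenate([out, draw[:deficit]])
    return AngleEnsemble(out, device_label=model.label, source="synthetic")


def sample_wlc_eed(spec: WLCSpec, N: int, seed: int = None) -> np.ndarray:
    """Inverse-CDF samples of the stiff-polymer end-to-end distance (nm)."""
    if N < 1:
        raise InputError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, spec.Lc, 4001)
    pdf = wlc_frey_pdf(grid, spec)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    # drop duplicate CDF values so interpolation is well defined
    keep = np.concatenate([[True], np.diff(cdf) > 0])
    u = rng.uniform(size=N)
    return np.interp(u, cdf[keep], grid[keep])


def sample_coupled_mc(
    spec: CoupledSystemSpec, N: int, seed: int = None
) -> AngularDistribution:
    """Monte-Carlo oracle for the coupled hinge-linker-sample distribution.

    Samples hinge angles from the prior and linker end-to-end vectors from
    their 3-D Gaussians, weights each draw by the WLC density at the
    closure-implied sample extension, and histograms the weighted angles on
    the prior's bins. Warns when the effective sample size falls below 100.
    """
    if N < 1:
        raise InputError(f"N must be >= 1, got {N}")
    rng = np.random.default_rng(seed)
    prior = spec.hinge_dist.normalized()
    probs = prior.probabilities
    idx = rng.choice(probs.size, size=N, p=probs / probs.sum())
    theta = rng.uniform(prior.bin_edges[idx], prior.bin_edges[idx + 1])
    sd1 = np.sqrt(spec.linker1.variance / 3.0)
    sd2 = np.sqrt(spec.linker2.variance / 3.0)
    v = rng.normal(0.0, sd1, size=(N, 3)) + rng.normal(0.0, sd2, size=(N, 3))
    c = chord_distance(np.clip(theta, 0.0, 180.0), spec.geometry)
    r_d = np.sqrt(v[:, 0] ** 2 + v[:, 1] ** 2 + (c - v[:, 2]) ** 2)
    w = wlc_frey_pdf(r_d, spec.sample)
    total = w.sum()
    if total <= 0:
        raise ModelError("closure infeasible for every Monte-Carlo draw")
    ess = total ** 2 / np.sum(w ** 2)
    if ess < 100:
        import warnings

        warnings.warn(
            f"effective sample size {ess:.0f} < 100; increase N", stacklevel=2
        )
    mass, _ = np.histogram(theta, bins=prior.bin_edges, weights=w)
    density = mass / np.sum(mass * prior.bin_widths)
    return AngularDistribution(prior.bin_edges, density)


def _write_angle_csv(path: Path, ensemble: AngleEnsemble) -> None:
    lines = ["angle_deg,device_label"]
    lines += [f"{a:.4f},{ensemble.device_label}" for a in ensemble.angles]
    path.write_text("\n".join(lines) + "\n")


def make_fixture_suite(outdir, seed: int = 0) -> dict:
    """Write the standard synthetic input bundle to ``outdir``.

    Emits per-variant angle tables (N = 500 each), a 5-angle hand-checkable
    worked example, stiff-polymer end-to-end samples for the 249 bp duplex,
    and a JSON manifest recording every seed and parameter so regeneration
    is byte-identical.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise InputError(f"cannot create fixture directory {outdir}: {err}") from err
    manifest = {
        "schema": FIXTURE_SCHEMA,
        "seed": int(seed),
        "files": {},
    }
    for i, label in enumerate(sorted(_PRESETS)):
        model = DeviceVariantModel.preset(label)
        sub_seed = int(seed) * 1000 + i
        ens = generate_angle_ensemble(model, N=500, seed=sub_seed)
        fname = f"angles_{label.replace('.', '_')}.csv"
        _write_angle_csv(outdir / fname, ens)
        manifest["files"][fname] = {
            "kind": "angle_table",
            "device_label": label,
            "N": 500,
            "seed": sub_seed,
            "model": {
                "loc": model.loc,
                "scale": model.scale,
                "skew": model.skew,
                "measurement_noise_sd": model.measurement_noise_sd,
            },
        }
    worked = AngleEnsemble([80.0, 80.0, 80.0, 80.0, 90.0], device_label="worked-example",
                           source="synthetic")
    _write_angle_csv(outdir / "worked_example.csv", worked)
    manifest["files"]["worked_example.csv"] = {
        "kind": "angle_table",
        "device_label": "worked-example",
        "N": 5,
        "seed": None,
    }
    wlc = WLCSpec(Lc=85.0, lp=50.0)
    wlc_seed = int(seed) * 1000 + 99
    samples = sample_wlc_eed(wlc, N=2000, seed=wlc_seed)
    lines = ["eed_nm"] + [f"{r:.4f}" for r in samples]
    (outdir / "wlc_eed_samples.csv").write_text("\n".join(lines) + "\n")
    manifest["files"]["wlc_eed_samples.csv"] = {
        "kind": "wlc_eed_samples",
        "N": 2000,
        "seed": wlc_seed,
        "Lc_nm": wlc.Lc,
        "lp_nm": wlc.lp,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
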