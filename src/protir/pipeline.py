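"""End-to-end orchestration: simulate -> dipoles -> spectra -> ATR.

A single RunConfig (YAML-serializable) drives all stages; all randomness
derives from one root seed through named substreams, so identical
config + seed reproduces byte-identical outputs.  Every stage writes a JSON
manifest with the config hash, seed and SHA-256 checksums of its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .atr import ATRGeometry, resolve_components, sensitivity_scan
from .cluster_sim import (
    ConfinementSpec,
    HopperSpec,
    SimParams,
    attach_proton_hopper,
    build_cluster,
    run_toy_md,
    synthesize_wannier_trajectory,
)
from .dipole_defect import (
    ChargeModel,
    dipole_series,
    zundel_site_selection,
)
from .spectra import (
    SpectralConfig,
    average_segments,
    difference_spectrum,
    smooth_gaussian,
    spectrum_from_dipole,
)
from .trajectory_io import (
    read_absorbance_csv,
    read_xyz_trajectory,
    write_spectrum_table,
    write_xyz_trajectory,
)

log = logging.getLogger("protir")

GEOMETRY_SPECS = {
    "chain_narrow": ConfinementSpec.narrow_chain,
    "chain_wide": ConfinementSpec.wide_chain,
    "disc": ConfinementSpec.disc,
    "droplet": ConfinementSpec.droplet,
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    geometry: str = "chain_narrow"
    n_waters: int = 15
    protonated: bool = True
    T: float = 300.0
    dt: float = 0.5
    equil_time: float = 15.0
    segment_time: float = 5.0
    n_segments: int = 4
    hop_rate: float = 20.0
    transit_time_range: tuple = (5.0, 20.0)
    charge_mode: str = "nuclear_effective"
    wannier_jitter_sd: float = 0.02
    sigma_nu: float = 50.0
    nu_max: float = 4000.0
    alpha: float = 39.0
    n1: float = 3.42
    n3: float = 1.6
    band: tuple = (1700.0, 2200.0)
    outdir: str = "results"
    seed: int = 1

    def validate(self) -> None:
        bad = []
        if self.geometry not in GEOMETRY_SPECS:
            bad.append(f"geometry={self.geometry!r}")
        if self.n_waters < 2:
            bad.append("n_waters")
        if self.dt <= 0:
            bad.append("dt")
        if self.n_segments < 1:
            bad.append("n_segments")
        if self.charge_mode not in ("nuclear_effective", "wannier_full"):
            bad.append(f"charge_mode={self.charge_mode!r}")
        if bad:
            raise ConfigError("invalid config keys: " + ", ".join(bad))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        for key in ("transit_time_range", "band"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]

    def sim_params(self) -> SimParams:
        return SimParams(
            n_waters=self.n_waters, T=self.T, dt=self.dt,
            protonated=self.protonated, equil_time=self.equil_time,
            segment_time=self.segment_time, n_segments=self.n_segments,
            seed=self.seed,
        )

    def hopper_spec(self) -> HopperSpec:
        policy = "chain" if self.geometry.startswith("chain") else self.geometry
        return HopperSpec(
            hop_rate=self.hop_rate,
            transit_time_range=self.transit_time_range,
            policy=policy,
        )

    def spectral_config(self) -> SpectralConfig:
        return SpectralConfig(sigma_nu=self.sigma_nu, nu_max=self.nu_max)

    def atr_geometry(self) -> ATRGeometry:
        return ATRGeometry(self.alpha, self.n1, self.n3)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, name: str, config: RunConfig, files: list[Path],
                    extra: dict | None = None) -> Path:
    manifest = dict(
        stage=name,
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash,
        config=asdict(config),
        outputs={f.name: _sha256(f) for f in files},
    )
    manifest.update(extra or {})
    path = outdir / f"{name}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=list))
    return path


def cmd_simulate(config: RunConfig) -> dict:
    """Generate NVE-segment trajectories and write them as XYZ + manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = GEOMETRY_SPECS[config.geometry]()
    params = config.sim_params()
    frame0 = build_cluster(spec, params)
    log.info("simulate: %s, %d waters, protonated=%s, %d segments",
             config.geometry, config.n_waters, config.protonated, config.n_segments)
    segments = run_toy_md(frame0, spec, params)
    with_wc = config.charge_mode == "wannier_full"
    files = []
    net_charge = 1 if config.protonated else 0
    for traj in segments:
        if with_wc:
            traj = synthesize_wannier_trajectory(
                traj, jitter_sd=config.wannier_jitter_sd, seed=config.seed
            )
        path = outdir / f"{config.geometry}_{traj.segment_id}.xyz"
        write_xyz_trajectory(traj, path, include_wannier=with_wc)
        files.append(path)
    manifest = _write_manifest(
        outdir, "simulate", config, files,
        extra=dict(net_charge=net_charge,
                   nvt_mean_temperature_K=segments[0].info["nvt_mean_temperature_K"]),
    )
    return dict(trajectories=[str(f) for f in files], manifest=str(manifest))


def _segment_spectra(config: RunConfig, paths, model: ChargeModel, subgroup: bool):
    """Per-segment smoothed spectra of molecular (+ optional defect) dipoles."""
    hopper = config.hopper_spec()
    raw_cfg = SpectralConfig(sigma_nu=0.0, nu_max=config.nu_max)
    specs = []
    for k, p in enumerate(paths):
        traj = read_xyz_trajectory(p, dt=config.dt * 2)
        if subgroup:
            sel = zundel_site_selection(traj, with_wannier=model.mode.value == "wannier_full")
            series = dipole_series(traj, model, subset=sel)
        else:
            series = dipole_series(traj, model)
            if config.protonated and config.hop_rate > 0:
                series = series + attach_proton_hopper(traj, hopper, seed=config.seed + k)
        specs.append(spectrum_from_dipole(series, raw_cfg))
    return smooth_gaussian(average_segments(specs), config.sigma_nu)


def cmd_spectrum(config: RunConfig, trajectories: list, neutral_trajectories: list | None = None) -> dict:
    """Direction-resolved spectra: full/nuclear, Zundel subgroup, difference.

    Writes one CSV per curve family on a shared wavenumber grid with
    segment-error columns; the Zundel subgroup is skipped (with a logged
    reason) for neutral inputs, and the protonated-minus-neutral difference
    is produced when a neutral run is supplied.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wann = config.charge_mode == "wannier_full"
    files = {}
    comment = f"protir {__version__} seed={config.seed} config={config.config_hash}"

    nuclear = _segment_spectra(config, trajectories, ChargeModel.nuclear_effective(), False)
    files["nuclear"] = outdir / f"{config.geometry}_nuclear.csv"
    write_spectrum_table(nuclear, files["nuclear"], header_comment=comment)
    if wann:
        full = _segment_spectra(config, trajectories, ChargeModel.wannier_full(), False)
        files["full"] = outdir / f"{config.geometry}_full.csv"
        write_spectrum_table(full, files["full"], header_comment=comment)
    if config.protonated:
        sub_n = _segment_spectra(config, trajectories, ChargeModel.nuclear_effective(), True)
        files["zundel_nuclear"] = outdir / f"{config.geometry}_zundel_nuclear.csv"
        write_spectrum_table(sub_n, files["zundel_nuclear"], header_comment=comment)
        if wann:
            sub_f = _segment_spectra(config, trajectories, ChargeModel.wannier_full(), True)
            files["zundel_full"] = outdir / f"{config.geometry}_zundel_full.csv"
            write_spectrum_table(sub_f, files["zundel_full"], header_comment=comment)
    else:
        log.info("spectrum: neutral run, Zundel subgroup spectra skipped (no defect)")
    if neutral_trajectories:
        neutral_cfg = RunConfig(**{**asdict(config), "protonated": False})
        neutral = _segment_spectra(neutral_cfg, neutral_trajectories,
                                   ChargeModel.nuclear_effective(), False)
        diff = difference_spectrum(nuclear, neutral)
        files["difference"] = outdir / f"{config.geometry}_difference.csv"
        write_spectrum_table(diff, files["difference"], header_comment=comment)
    manifest = _write_manifest(outdir, "spectrum", config, list(files.values()))
    out = {k: str(v) for k, v in files.items()}
    out["manifest"] = str(manifest)
    return out


def cmd_atr(config: RunConfig, a_par_path, a_perp_path) -> dict:
    """Resolve polarized absorbances into xy/z, scan alpha/n3, report band means."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nu1, a_par = read_absorbance_csv(a_par_path)
    nu2, a_perp = read_absorbance_csv(a_perp_path)
    if nu1.shape != nu2.shape or not np.allclose(nu1, nu2):
        raise ValueError("polarized inputs are on different wavenumber grids")
    geometry = config.atr_geometry()
    res = resolve_components(a_par, a_perp, geometry, nu=nu1)
    import pandas as pd

    csv_path = Path(outdir) / "atr_resolved.csv"
    pd.DataFrame(
        {
            "wavenumber_cm-1": res.nu,
            "A_par": res.A_par,
            "A_perp": res.A_perp,
            "A_xy": res.A_xy,
            "A_z": res.A_z,
            "R": res.R,
        }
    ).to_csv(csv_path, index=False)
    lo, hi = config.band
    mask = (nu1 >= lo) & (nu1 <= hi)
    if not mask.any():
        raise ValueError(f"band {config.band} outside the input grid")
    scan = sensitivity_scan(a_par, a_perp, geometry, nu=nu1)
    report = dict(
        band_cm=list(config.band),
        band_mean_A_xy=float(res.A_xy[mask].mean()),
        band_mean_A_z=float(res.A_z[mask].mean()),
        geometry=dict(alpha=geometry.alpha, n1=geometry.n1, n3=geometry.n3),
        scan=[
            {k: v for k, v in rec.items() if k not in ("A_xy", "A_z")}
            for rec in scan
        ],
    )
    json_path = Path(outdir) / "atr_report.json"
    json_path.write_text(json.dumps(report, indent=2))
    manifest = _write_manifest(outdir, "atr", config, [csv_path, json_path])
    return dict(resolved=str(csv_path), report=str(json_path), manifest=str(manifest),
                **{k: report[k] for k in ("band_mean_A_xy", "band_mean_A_z")})
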