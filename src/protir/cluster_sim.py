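"""Synthetic confined water-cluster trajectories and analytic fixtures.

This module stands in for ab initio MD at desk scale.  It provides

* harmonically confined cluster templates (narrow/wide chain, disc,
  droplet) with the confinement constants of the study setup
  (K_xy = 2000 / 20 kJ mol^-1 nm^-2 for narrow/wide chains, K_z = 2000 and
  K_xy = 30 for the disc, K_r = 40 for the droplet), applied to oxygens;
* a classical flexible-water toy force field (harmonic O-H bonds and
  H-O-H angles tuned by normal-mode analysis to put the bend near
  1645 cm^-1 and the stretches near 3400 cm^-1, SPC-like point charges,
  Lennard-Jones on O) integrated with Langevin NVT equilibration and
  velocity-Verlet NVE segments;
* a stochastic proton-hop dipole emulator: a +1 e defect charge performs
  Poisson-timed hops between oxygen sites with fast linear transits,
  injecting broadband dipole power along the hop directions (axial for
  chains, in-plane for discs, isotropic for droplets);
* synthetic Wannier centers (two bond centers, two lone-pair centers per
  water) for exercising the full nuclei+electrons dipole path;
* analytic oscillator/OU dipole fixtures with closed-form reference
  spectra for validating the spectral estimator.

All randomness flows from explicit integer seeds through
numpy.random.SeedSequence substreams; outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dipole_defect import DipoleSeries, assign_molecules
from .trajectory_io import Frame, Trajectory
from .units import (
    C_CM_PER_FS,
    COULOMB_INTERNAL,
    KB_INTERNAL,
    KJ_MOL_PER_INTERNAL,
    MASS_H,
    MASS_O,
)

# --- toy force-field constants (internal units: amu, Angstrom, fs, e) ------
R_OH = 0.9572  # A
THETA0 = np.deg2rad(104.52)
K_BOND = 0.389  # amu/fs^2; isolated-water stretches ~3380-3425 cm^-1
K_ANGLE = 0.0413  # amu A^2/fs^2/rad^2; bend ~1645 cm^-1
Q_O_FF, Q_H_FF = -0.82, 0.41  # SPC-like water point charges (e)
Q_O_HYD_FF, Q_H_HYD_FF = -0.5, 0.5  # hydronium stand-in, net +1 e
LJ_EPS = 0.6502 / KJ_MOL_PER_INTERNAL  # O-O Lennard-Jones
LJ_SIG = 3.166  # A
VELOCITY_LIMIT = 0.5  # A/fs; integrator blow-up guard

_KJNM2_TO_INTERNAL = 1.0 / (KJ_MOL_PER_INTERNAL * 100.0)  # kJ/mol/nm^2 -> int/A^2


class StabilityError(RuntimeError):
    """Integrator blow-up; try a smaller timestep."""


@dataclass(frozen=True)
class ConfinementSpec:
    """Harmonic confinement acting on oxygen atoms (kJ mol^-1 nm^-2)."""

    geometry: str  # chain | disc | droplet
    K_xy: float = 0.0
    K_z: float = 0.0
    K_r: float = 0.0

    def __post_init__(self):
        if self.geometry not in ("chain", "disc", "droplet"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if min(self.K_xy, self.K_z, self.K_r) < 0:
            raise ValueError("confinement constants must be >= 0")

    @classmethod
    def narrow_chain(cls):
        return cls("chain", K_xy=2000.0)

    @classmethod
    def wide_chain(cls):
        return cls("chain", K_xy=20.0)

    @classmethod
    def disc(cls):
        return cls("disc", K_z=2000.0, K_xy=30.0)

    @classmethod
    def droplet(cls):
        return cls("droplet", K_r=40.0)


@dataclass
class SimParams:
    """Simulation protocol: NVT equilibration then NVE segments."""

    n_waters: int = 15
    T: float = 300.0  # K
    dt: float = 0.5  # fs
    protonated: bool = False
    equil_time: float = 15.0  # ps
    segment_time: float = 5.0  # ps
    n_segments: int = 1
    inter_segment_time: float = 0.5  # ps of NVT between snapshots
    friction: float = 0.02  # fs^-1 Langevin friction
    record_stride: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        if self.n_waters < 2:
            raise ValueError("need at least 2 waters")


@dataclass
class HopperSpec:
    """Stochastic defect-hop emulator parameters."""

    hop_rate: float = 20.0  # ps^-1
    transit_time_range: tuple[float, float] = (5.0, 20.0)  # fs
    policy: str = "chain"  # chain | disc | droplet
    defect_charge: float = 1.0  # e
    neighbor_cutoff: float = 3.5  # A

    def __post_init__(self):
        lo, hi = self.transit_time_range
        if self.hop_rate < 0 or lo <= 0 or hi < lo:
            raise ValueError("invalid hopper parameters")
        if self.policy not in ("chain", "disc", "droplet"):
            raise ValueError(f"unknown hop policy {self.policy!r}")


# ---------------------------------------------------------------------------
# cluster construction


def _water_hydrogens(o_pos, d1, azimuth):
    """H positions for a water given the first O-H direction and an azimuth
    for the second bond on the theta0 cone around d1."""
    d1 = d1 / np.linalg.norm(d1)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d1 @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(d1, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d1, p1)
    d2 = np.cos(THETA0) * d1 + np.sin(THETA0) * (np.cos(azimuth) * p1 + np.sin(azimuth) * p2)
    return o_pos + R_OH * d1, o_pos + R_OH * d2


def _chain_sites(n):
    z = (np.arange(n) - (n - 1) / 2.0) * 2.7
    return np.column_stack([np.zeros(n), np.zeros(n), z])


def _disc_sites(n, a=2.8):
    pts = []
    for i in range(-4, 5):
        for j in range(-4, 5):
            pts.append((a * (i + 0.5 * j), a * (np.sqrt(3) / 2.0) * j, 0.0))
    pts = np.array(pts)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    sites = pts[order[:n]]
    return sites - sites.mean(axis=0)


def _droplet_sites(n, a=2.9):
    pts = []
    for i in range(-3, 4):
        for j in range(-3, 4):
            for k in range(-3, 4):
                pts.append((a * i, a * j, a * k))
    pts = np.array(pts, dtype=float)
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    sites = pts[order[:n]]
    return sites - sites.mean(axis=0)


def build_cluster(spec: ConfinementSpec, params: SimParams) -> Frame:
    """Initial frame: waters on a hydrogen-bond-friendly template.

    Chains place oxygens ~2.7 A apart along z with one O-H bond donated to
    the next oxygen; discs use a triangular lattice in the xy plane;
    droplets a compact cubic packing.  Orientations are randomized (seeded).
    If protonated, one extra H is placed 1.0 A from the most central oxygen
    on its lone-pair side.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 101]))
    n = params.n_waters
    if spec.geometry == "chain":
        o_sites = _chain_sites(n)
    elif spec.geometry == "disc":
        o_sites = _disc_sites(n)
    else:
        o_sites = _droplet_sites(n)
    elements, positions = [], []
    for i, o in enumerate(o_sites):
        if spec.geometry == "chain":
            d1 = (o_sites[i + 1] - o) if i + 1 < n else np.array([0.0, 0.0, 1.0])
        else:
            d1 = rng.normal(size=3)
        h1, h2 = _water_hydrogens(o, d1, rng.uniform(0, 2 * np.pi))
        elements += ["O", "H", "H"]
        positions += [o, h1, h2]
    positions = np.array(positions)
    if params.protonated:
        o_rows = np.arange(n) * 3
        center = int(np.argmin(np.linalg.norm(o_sites - o_sites.mean(axis=0), axis=1)))
        o = positions[o_rows[center]]
        u1 = positions[o_rows[center] + 1] - o
        u2 = positions[o_rows[center] + 2] - o
        lp = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        lp /= np.linalg.norm(lp)
        elements.append("H")
        positions = np.vstack([positions, o + 1.0 * lp])
    return Frame(elements, positions, time=0.0)


# ---------------------------------------------------------------------------
# toy force field


@dataclass
class _Topology:
    masses: np.ndarray
    charges: np.ndarray  # force-field charges, e
    bonds: np.ndarray  # (nb, 2) H, O
    angles: np.ndarray  # (na, 3) H, O, H
    nb_i: np.ndarray  # nonbonded pair lists (i < j, intermolecular)
    nb_j: np.ndarray
    nb_qq: np.ndarray  # COULOMB_INTERNAL * q_i * q_j
    lj_mask: np.ndarray  # O-O pairs among (nb_i, nb_j)
    o_indices: np.ndarray

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())


def build_topology(frame: Frame) -> _Topology:
    """Derive bonds/angles/charges from nearest-O assignment of a frame."""
    asg = assign_molecules(frame)
    n = frame.n_atoms
    elements = np.array(frame.elements)
    masses = np.where(elements == "O", MASS_O, MASS_H)
    charges = np.zeros(n)
    bonds, angles = [], []
    mol_id = np.empty(n, dtype=int)
    for m, o in enumerate(asg.o_indices):
        hs = asg.hydrogens_of(int(o))
        mol_id[o] = m
        mol_id[hs] = m
        hyd = hs.size == 3
        charges[o] = Q_O_HYD_FF if hyd else Q_O_FF
        charges[hs] = Q_H_HYD_FF if hyd else Q_H_FF
        for h in hs:
            bonds.append((int(h), int(o)))
        for a in range(hs.size):
            for b in range(a + 1, hs.size):
                angles.append((int(hs[a]), int(o), int(hs[b])))
    ii, jj = np.triu_indices(n, k=1)
    keep = mol_id[ii] != mol_id[jj]
    ii, jj = ii[keep], jj[keep]
    qq = COULOMB_INTERNAL * charges[ii] * charges[jj]
    lj_mask = (elements[ii] == "O") & (elements[jj] == "O")
    return _Topology(
        masses, charges, np.array(bonds), np.array(angles), ii, jj, qq, lj_mask,
        asg.o_indices,
    )


def _confinement_internal(pos, o_idx, spec: ConfinementSpec):
    """Confinement energy/forces on oxygens in internal units."""
    E = 0.0
    F = np.zeros_like(pos)
    ro = pos[o_idx]
    if spec.geometry == "chain":
        k = spec.K_xy * _KJNM2_TO_INTERNAL
        E += 0.5 * k * np.sum(ro[:, :2] ** 2)
        F[o_idx, :2] -= k * ro[:, :2]
    elif spec.geometry == "disc":
        kz = spec.K_z * _KJNM2_TO_INTERNAL
        kxy = spec.K_xy * _KJNM2_TO_INTERNAL
        E += 0.5 * kz * np.sum(ro[:, 2] ** 2) + 0.5 * kxy * np.sum(ro[:, :2] ** 2)
        F[o_idx, 2] -= kz * ro[:, 2]
        F[o_idx, :2] -= kxy * ro[:, :2]
    else:
        kr = spec.K_r * _KJNM2_TO_INTERNAL
        E += 0.5 * kr * np.sum(ro**2)
        F[o_idx] -= kr * ro
    return E, F


def confinement_energy(frame: Frame, spec: ConfinementSpec):
    """Confinement energy (kJ/mol) and forces (kJ/mol/A) on all atoms.

    The harmonic wall acts on oxygen atoms only: K_xy (x^2+y^2)/2 for
    chains, K_z z^2/2 + K_xy (x^2+y^2)/2 for discs, K_r r^2/2 for droplets,
    with K in kJ mol^-1 nm^-2 and coordinates measured from the confinement
    axis/plane/center at the origin.
    """
    o_idx = np.nonzero(np.array(frame.elements) == "O")[0]
    E, F = _confinement_internal(frame.positions, o_idx, spec)
    return E * KJ_MOL_PER_INTERNAL, F * KJ_MOL_PER_INTERNAL


def _forces(pos, topo: _Topology, spec: ConfinementSpec):
    """Total potential energy and forces, internal units."""
    F = np.zeros_like(pos)
    # bonds
    bi, bj = topo.bonds[:, 0], topo.bonds[:, 1]
    d = pos[bi] - pos[bj]
    r = np.linalg.norm(d, axis=1)
    u = d / r[:, None]
    E = 0.5 * K_BOND * np.sum((r - R_OH) ** 2)
    fb = -K_BOND * (r - R_OH)[:, None] * u
    np.add.at(F, bi, fb)
    np.add.at(F, bj, -fb)
    # angles
    ai, aj, ak = topo.angles[:, 0], topo.angles[:, 1], topo.angles[:, 2]
    uvec = pos[ai] - pos[aj]
    vvec = pos[ak] - pos[aj]
    un = np.linalg.norm(uvec, axis=1)
    vn = np.linalg.norm(vvec, axis=1)
    uh = uvec / un[:, None]
    vh = vvec / vn[:, None]
    cth = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
    th = np.arccos(cth)
    sth = np.sqrt(np.clip(1.0 - cth**2, 1e-12, None))
    E += 0.5 * K_ANGLE * np.sum((th - THETA0) ** 2)
    dEdth = K_ANGLE * (th - THETA0)
    gi = (cth[:, None] * uh - vh) / (un * sth)[:, None]
    gk = (cth[:, None] * vh - uh) / (vn * sth)[:, None]
    fi = -dEdth[:, None] * gi
    fk = -dEdth[:, None] * gk
    np.add.at(F, ai, fi)
    np.add.at(F, ak, fk)
    np.add.at(F, aj, -(fi + fk))
    # nonbonded
    dv = pos[topo.nb_i] - pos[topo.nb_j]
    r2 = np.sum(dv * dv, axis=1)
    rinv = 1.0 / np.sqrt(r2)
    E += np.sum(topo.nb_qq * rinv)
    fscal = topo.nb_qq * rinv**3
    if topo.lj_mask.any():
        s6 = (LJ_SIG**2 * rinv[topo.lj_mask] ** 2) ** 3
        E += np.sum(4.0 * LJ_EPS * (s6**2 - s6))
        fscal_lj = 4.0 * LJ_EPS * (12.0 * s6**2 - 6.0 * s6) * rinv[topo.lj_mask] ** 2
        fscal = fscal.copy()
        fscal[topo.lj_mask] += fscal_lj
    fnb = fscal[:, None] * dv
    np.add.at(F, topo.nb_i, fnb)
    np.add.at(F, topo.nb_j, -fnb)
    # confinement
    Ec, Fc = _confinement_internal(pos, topo.o_indices, spec)
    return E + Ec, F + Fc


def potential_energy(frame: Frame, spec: ConfinementSpec, topo: _Topology | None = None):
    """Toy force-field potential energy (kJ/mol) and forces (kJ/mol/A)."""
    topo = topo or build_topology(frame)
    E, F = _forces(frame.positions, topo, spec)
    return E * KJ_MOL_PER_INTERNAL, F * KJ_MOL_PER_INTERNAL


def _kinetic(vel, masses):
    return 0.5 * np.sum(masses[:, None] * vel**2)


def _temperature(vel, masses):
    ndof = 3 * len(masses)
    return 2.0 * _kinetic(vel, masses) / (ndof * KB_INTERNAL)


def _check_stable(vel):
    if np.max(np.abs(vel)) > VELOCITY_LIMIT:
        raise StabilityError(
            "velocity exceeded the stability threshold; use a smaller dt"
        )


def _langevin_steps(pos, vel, topo, spec, dt, n_steps, T, gamma, rng, sample_every=20):
    """BAOAB Langevin integrator; returns sampled instantaneous temperatures."""
    m = topo.masses[:, None]
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt((1.0 - c1**2) * KB_INTERNAL * T / topo.masses)[:, None]
    _, F = _forces(pos, topo, spec)
    temps = []
    for step in range(n_steps):
        vel += 0.5 * dt * F / m
        pos += 0.5 * dt * vel
        vel = c1 * vel + c2 * rng.standard_normal(vel.shape)
        pos += 0.5 * dt * vel
        _, F = _forces(pos, topo, spec)
        vel += 0.5 * dt * F / m
        if step % sample_every == 0:
            _check_stable(vel)
            temps.append(_temperature(vel, topo.masses))
    return pos, vel, np.array(temps)


def _nve_segment(pos, vel, topo, spec, dt, n_steps, record_stride, elements, t0=0.0):
    """Velocity-Verlet NVE run recording frames every record_stride steps."""
    m = topo.masses[:, None]
    E, F = _forces(pos, topo, spec)
    frames = [Frame(list(elements), pos.copy(), time=t0)]
    etot = [E + _kinetic(vel, topo.masses)]
    ekin = [_kinetic(vel, topo.masses)]
    for step in range(1, n_steps + 1):
        vel += 0.5 * dt * F / m
        pos += dt * vel
        E, F = _forces(pos, topo, spec)
        vel += 0.5 * dt * F / m
        if step % record_stride == 0:
            _check_stable(vel)
            frames.append(Frame(list(elements), pos.copy(), time=t0 + step * dt))
            etot.append(E + _kinetic(vel, topo.masses))
            ekin.append(_kinetic(vel, topo.masses))
    return pos, vel, frames, np.array(etot), np.array(ekin)


def run_toy_md(
    frame: Frame, spec: ConfinementSpec, params: SimParams
) -> list[Trajectory]:
    """NVT-equilibrate then launch NVE segments from successive snapshots.

    Returns one Trajectory per NVE segment (frame spacing
    params.dt * params.record_stride).  Each trajectory's ``info`` carries
    the recorded total/kinetic energies (internal units), the NVT mean
    temperature, and the force-field net charge.
    """
    topo = build_topology(frame)
    ss = np.random.SeedSequence([params.seed, 202])
    rng = np.random.default_rng(ss)
    pos = frame.positions.copy()
    vel = rng.standard_normal(pos.shape) * np.sqrt(
        KB_INTERNAL * params.T / topo.masses
    )[:, None]
    n_equil = int(round(params.equil_time * 1000.0 / params.dt))
    pos, vel, temps = _langevin_steps(
        pos, vel, topo, spec, params.dt, n_equil, params.T, params.friction, rng
    )
    nvt_mean_T = float(np.mean(temps[len(temps) // 2:])) if len(temps) else float("nan")
    n_seg_steps = int(round(params.segment_time * 1000.0 / params.dt))
    n_inter = int(round(params.inter_segment_time * 1000.0 / params.dt))
    segments = []
    geometry_label = spec.geometry
    for k in range(params.n_segments):
        seg_pos, seg_vel = pos.copy(), vel.copy()
        _, _, frames, etot, ekin = _nve_segment(
            seg_pos, seg_vel, topo, spec, params.dt, n_seg_steps,
            params.record_stride, frame.elements,
        )
        traj = Trajectory(
            frames,
            dt=params.dt * params.record_stride,
            segment_id=f"seg{k:02d}",
            geometry=geometry_label,
            protonated=params.protonated,
            info=dict(
                total_energy_internal=etot,
                kinetic_energy_internal=ekin,
                nvt_mean_temperature_K=nvt_mean_T,
                nvt_temperatures_K=temps,
                ff_net_charge=topo.net_charge,
                seed=params.seed,
            ),
        )
        segments.append(traj)
        # continue the NVT mother trajectory to the next snapshot
        if k + 1 < params.n_segments:
            pos, vel, _ = _langevin_steps(
                pos, vel, topo, spec, params.dt, n_inter, params.T,
                params.friction, rng,
            )
    return segments


def nve_energy_drift(trajectory: Trajectory) -> float:
    """|windowed-mean E(end) - E(start)| / mean kinetic energy of a segment.

    Ten-percent windows at either end average out the bounded symplectic
    energy oscillation of velocity Verlet so only genuine drift is measured.
    """
    etot = np.asarray(trajectory.info["total_energy_internal"])
    ekin = np.asarray(trajectory.info["kinetic_energy_internal"])
    w = max(1, etot.size // 10)
    drift = abs(etot[-w:].mean() - etot[:w].mean())
    return float(drift / ekin.mean())


# ---------------------------------------------------------------------------
# proton-hop dipole emulator


def attach_proton_hopper(
    trajectory: Trajectory, hopper: HopperSpec, seed: int
) -> DipoleSeries:
    """Defect-charge dipole time series from Poisson-timed site hops.

    A charge of ``hopper.defect_charge`` (+1 e) rides an oxygen site and
    hops to an adjacent oxygen chosen by the axis policy (along the chain,
    in-plane for discs, isotropic for droplets) after exponentially
    distributed waiting times; the position is linearly interpolated over a
    transit time drawn uniformly from ``transit_time_range``.  Chain ends
    reflect.  The dipole is referenced to the instantaneous oxygen centroid
    and projected onto the policy's axis subspace, so chain defects carry
    strictly zero x,y dipole components and disc defects zero z.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    o_idx = np.nonzero(np.array(trajectory.elements) == "O")[0]
    if o_idx.size < 2:
        raise ValueError("hopper needs at least two oxygen sites")
    opos = trajectory.positions_array()[:, o_idx, :]  # (F, nO, 3)
    times = trajectory.times
    t_end = times[-1]
    chain_order = np.argsort(opos[0, :, 2], kind="stable")
    chain_rank = np.empty(o_idx.size, dtype=int)
    chain_rank[chain_order] = np.arange(o_idx.size)
    centroid0 = opos[0].mean(axis=0)
    site = int(np.argmin(np.linalg.norm(opos[0] - centroid0, axis=1)))

    def choose_target(s, frame_k):
        p = opos[frame_k]
        if hopper.policy == "chain":
            rank = chain_rank[s]
            if rank == 0:
                nxt = 1
            elif rank == o_idx.size - 1:
                nxt = rank - 1
            else:
                nxt = rank + (1 if rng.random() < 0.5 else -1)
            return int(chain_order[nxt])
        d = np.linalg.norm(p - p[s], axis=1)
        d[s] = np.inf
        cand = np.nonzero(d < hopper.neighbor_cutoff)[0]
        if hopper.policy == "disc" and cand.size:
            dv = p[cand] - p[s]
            inplane = cand[np.abs(dv[:, 2]) <= np.linalg.norm(dv[:, :2], axis=1)]
            if inplane.size:
                cand = inplane
        if cand.size == 0:
            return int(np.argmin(d))
        return int(cand[rng.integers(cand.size)])

    # build the continuous-time hop schedule
    events = []  # (t_start, t_end, from_site, to_site)
    rate_per_fs = hopper.hop_rate / 1000.0
    t = 0.0
    while rate_per_fs > 0:
        t += rng.exponential(1.0 / rate_per_fs)
        if t >= t_end:
            break
        frame_k = min(int(np.searchsorted(times, t)), len(times) - 1)
        target = choose_target(site, frame_k)
        tau = rng.uniform(*hopper.transit_time_range)
        events.append((t, t + tau, site, target))
        site = target
        t += tau

    mu = np.empty((len(times), 3))
    ev = 0
    cur = int(np.argmin(np.linalg.norm(opos[0] - centroid0, axis=1)))
    for k, tk in enumerate(times):
        while ev < len(events) and events[ev][1] <= tk:
            cur = events[ev][3]
            ev += 1
        p = opos[k]
        if ev < len(events) and events[ev][0] <= tk < events[ev][1]:
            t0, t1, s_from, s_to = events[ev]
            lam = (tk - t0) / (t1 - t0)
            r = (1.0 - lam) * p[s_from] + lam * p[s_to]
        else:
            r = p[cur]
        mu[k] = hopper.defect_charge * (r - p.mean(axis=0))
    if hopper.policy == "chain":
        mu[:, :2] = 0.0
    elif hopper.policy == "disc":
        mu[:, 2] = 0.0
    return DipoleSeries(times, mu, label="defect")


# ---------------------------------------------------------------------------
# synthetic Wannier centers

WC_BOND_DIST = 0.5  # A from O along each O-H bond
WC_LP_DIST = 0.3  # A from O for lone-pair centers


def synthesize_wannier(frame: Frame, jitter_sd: float = 0.0, seed: int = 0) -> Frame:
    """Attach four synthetic Wannier centers per oxygen.

    Waters get two bond centers 0.5 A from O along each O-H bond and two
    lone-pair centers 0.3 A from O along +/- the normal of the HOH plane;
    hydronium oxygens get three bond centers and a single lone-pair center
    opposite the bond-direction sum.  Optional Gaussian jitter (SD in A) is
    seeded and reproducible.  Every molecule's wannier_full charge sum is 0
    (+1 for hydronium).
    """
    asg = assign_molecules(frame)
    centers = []
    for o in asg.o_indices:
        opos = frame.positions[o]
        hs = asg.hydrogens_of(int(o))
        units = []
        for h in hs:
            u = frame.positions[h] - opos
            u /= np.linalg.norm(u)
            units.append(u)
            centers.append(opos + WC_BOND_DIST * u)
        if len(units) == 2:
            nrm = np.cross(units[0], units[1])
            nrm /= np.linalg.norm(nrm)
            centers.append(opos + WC_LP_DIST * nrm)
            centers.append(opos - WC_LP_DIST * nrm)
        elif len(units) == 3:
            lp = -np.sum(units, axis=0)
            lp /= np.linalg.norm(lp)
            centers.append(opos + WC_LP_DIST * lp)
        else:
            raise ValueError(f"oxygen {o} has {len(units)} hydrogens; expected 2 or 3")
    centers = np.array(centers)
    if jitter_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
        centers = centers + rng.normal(scale=jitter_sd, size=centers.shape)
    return Frame(list(frame.elements), frame.positions.copy(), wannier=centers,
                 time=frame.time)


def synthesize_wannier_trajectory(
    trajectory: Trajectory, jitter_sd: float = 0.0, seed: int = 0
) -> Trajectory:
    """Per-frame synthetic Wannier centers for a whole trajectory."""
    from dataclasses import replace

    frames = [
        synthesize_wannier(fr, jitter_sd=jitter_sd, seed=seed + k)
        for k, fr in enumerate(trajectory.frames)
    ]
    return replace(trajectory, frames=frames)


# ---------------------------------------------------------------------------
# analytic fixtures

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def generate_oscillator_dipole(
    modes: Sequence[tuple],
    ou_noise: tuple | None,
    N: int,
    dt: float,
    seed: int = 0,
):
    """Cosine-mode dipole fixture with optional integrated-OU broadband term.

    ``modes`` is a list of (nu_cm, amplitude, axis, phase); ``ou_noise`` is
    (sd, tau_fs, axis) or None — an Ornstein-Uhlenbeck process v(t) with
    stationary SD ``sd`` and correlation time ``tau`` is integrated into the
    dipole so that mu_dot carries the OU (Lorentzian) spectrum.  Returns
    (DipoleSeries, reference) where ``reference`` holds the closed-form
    mu_dot spectrum content: per-line integrated intensities and the OU
    Lorentzian parameters (see :func:`protir.spectra.ou_lorentzian`).
    """
    if N < 16:
        raise ValueError("need N >= 16 samples")
    t = np.arange(N) * dt
    mu = np.zeros((N, 3))
    lines = []
    for nu_cm, amp, axis, phase in modes:
        e = _AXES[axis] if isinstance(axis, str) else np.asarray(axis, dtype=float)
        f = nu_cm * C_CM_PER_FS
        mu += amp * np.cos(2 * np.pi * f * t + phase)[:, None] * e
        # mu_dot amplitude a*2*pi*f -> one-sided line integral a^2 (2 pi f)^2 / 2
        lines.append(dict(nu=nu_cm, axis=axis, integral=0.5 * (amp * 2 * np.pi * f) ** 2))
    reference = {"lines": lines, "ou": None}
    if ou_noise is not None:
        sd, tau, axis = ou_noise
        rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
        rho = np.exp(-dt / tau)
        v = np.empty(N)
        v[0] = rng.normal(scale=sd)
        eps = rng.standard_normal(N - 1) * sd * np.sqrt(1.0 - rho**2)
        for i in range(1, N):
            v[i] = rho * v[i - 1] + eps[i - 1]
        e = _AXES[axis] if isinstance(axis, str) else np.asarray(axis, dtype=float)
        mu += dt * np.concatenate([[0.0], np.cumsum(v[:-1])])[:, None] * e
        reference["ou"] = dict(sd=sd, tau=tau, axis=axis)
    return DipoleSeries(t, mu, label="fixture"), reference


def single_water_frame() -> Frame:
    """Ideal gas-phase water in the xz plane, bisector along +z."""
    o = np.zeros(3)
    h1 = R_OH * np.array([np.sin(THETA0 / 2), 0.0, np.cos(THETA0 / 2)])
    h2 = R_OH * np.array([-np.sin(THETA0 / 2), 0.0, np.cos(THETA0 / 2)])
    return Frame(["O", "H", "H"], np.vstack([o, h1, h2]))


def water_normal_modes() -> np.ndarray:
    """Vibrational frequencies (cm^-1) of one toy water from the FF Hessian.

    Mass-weighted finite-difference Hessian of the bond+angle potential;
    the six zero modes (translation/rotation) are dropped.  Serves as the
    independent oracle for the band positions of the toy model.
    """
    frame = single_water_frame()
    topo = build_topology(frame)
    spec = ConfinementSpec("droplet", K_r=0.0)
    x0 = frame.positions.ravel().copy()
    ndim = x0.size
    h = 1e-5

    def grad(x):
        _, F = _forces(x.reshape(-1, 3), topo, spec)
        return -F.ravel()

    H = np.empty((ndim, ndim))
    for i in range(ndim):
        xp, xm = x0.copy(), x0.copy()
        xp[i] += h
        xm[i] -= h
        H[:, i] = (grad(xp) - grad(xm)) / (2 * h)
    H = 0.5 * (H + H.T)
    m = np.repeat(topo.masses, 3)
    W = H / np.sqrt(np.outer(m, m))
    ev = np.sort(np.linalg.eigvalsh(W))
    ev = ev[ev > 1e-8]
    return np.sqrt(ev) / (2 * np.pi * C_CM_PER_FS)
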