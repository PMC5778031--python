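"""Molecule assignment, excess-proton/Zundel tracking, and dipole assembly.

Hydrogens (and Wannier centers) are re-assigned to their nearest oxygen on
every frame, which is the standard geometric tracker for a Grotthuss-hopping
defect: the hydronium is the unique oxygen coordinated by three hydrogens.
The shared proton H* of the defect, its two flanking oxygens and the
asymmetry coordinate delta = |d(O1-H*) - d(O2-H*)| classify the solvation
state as Zundel-like (delta below threshold, proton shared) or Eigen-like.

Dipoles are sums q_i * r_i over selected sites in one of two charge models:

* ``nuclear_effective`` -- nuclei only with q_H = +1 e, q_O = -2 e, which
  keeps every water neutral and gives the excess proton charge +1 e;
* ``wannier_full`` -- valence-core charges O +6 e, H +1 e plus -2 e per
  Wannier center (four electron pairs per water), adding the electronic
  polarization to the dipole.

For selections with net charge (the protonated cluster, the Zundel subgroup
O2H5+) the dipole is referenced to the selection's instantaneous geometric
center so it is translation independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .trajectory_io import Frame, Trajectory

DELTA_THRESHOLD_DEFAULT = 0.25  # Angstrom; Zundel/Eigen discriminator
WANNIER_CUTOFF_DEFAULT = 1.0  # Angstrom; centers sit within ~0.5 A of O


class DefectError(ValueError):
    """Zero-or-multiple hydronium assignment where one was required."""


class ChargeMode(str, Enum):
    WANNIER_FULL = "wannier_full"
    NUCLEAR_EFFECTIVE = "nuclear_effective"


@dataclass(frozen=True)
class ChargeModel:
    mode: ChargeMode
    q_O: float
    q_H: float
    q_wc: float = 0.0

    @classmethod
    def nuclear_effective(cls) -> "ChargeModel":
        return cls(ChargeMode.NUCLEAR_EFFECTIVE, q_O=-2.0, q_H=+1.0)

    @classmethod
    def wannier_full(cls) -> "ChargeModel":
        return cls(ChargeMode.WANNIER_FULL, q_O=+6.0, q_H=+1.0, q_wc=-2.0)

    def nuclear_charges(self, elements: list[str]) -> np.ndarray:
        return np.array([self.q_O if e == "O" else self.q_H for e in elements])


@dataclass
class MoleculeAssignment:
    """Per-frame nearest-O bookkeeping."""

    o_indices: np.ndarray  # atom indices of the oxygens
    h_indices: np.ndarray  # atom indices of the hydrogens
    h_parent: np.ndarray  # for each H (in h_indices order): parent O atom index
    coordination: np.ndarray  # per O (in o_indices order): number of assigned H
    wc_parent: np.ndarray | None = None  # per Wannier center: parent O atom index
    warnings: list[str] = field(default_factory=list)

    def hydrogens_of(self, o_index: int) -> np.ndarray:
        return self.h_indices[self.h_parent == o_index]

    def wannier_of(self, o_index: int) -> np.ndarray:
        if self.wc_parent is None:
            return np.array([], dtype=int)
        return np.nonzero(self.wc_parent == o_index)[0]


@dataclass
class ZundelState:
    hydronium_O: int
    shared_H: int
    partner_O: int
    delta: float
    is_zundel: bool


def assign_molecules(
    frame: Frame, wannier_cutoff: float = WANNIER_CUTOFF_DEFAULT
) -> MoleculeAssignment:
    """Map every H (and Wannier center) to its nearest O.

    Ties resolve to the lower atom index (np.argmin convention).  Wannier
    centers farther than ``wannier_cutoff`` from every O are still assigned
    to the nearest O but flagged in ``warnings``.
    """
    elements = np.array(frame.elements)
    o_idx = np.nonzero(elements == "O")[0]
    h_idx = np.nonzero(elements == "H")[0]
    if o_idx.size == 0 or h_idx.size == 0:
        raise ValueError("frame must contain both O and H atoms")
    d_ho = cdist(frame.positions[h_idx], frame.positions[o_idx])
    nearest = np.argmin(d_ho, axis=1)
    h_parent = o_idx[nearest]
    coordination = np.bincount(nearest, minlength=o_idx.size)
    wc_parent = None
    warnings: list[str] = []
    if frame.wannier is not None and len(frame.wannier):
        d_wo = cdist(frame.wannier, frame.positions[o_idx])
        wnearest = np.argmin(d_wo, axis=1)
        wc_parent = o_idx[wnearest]
        far = np.nonzero(d_wo[np.arange(len(wnearest)), wnearest] > wannier_cutoff)[0]
        for w in far:
            warnings.append(
                f"Wannier center {w} is {d_wo[w, wnearest[w]]:.2f} A from its nearest O"
            )
    return MoleculeAssignment(o_idx, h_idx, h_parent, coordination, wc_parent, warnings)


def find_excess_proton(assignment: MoleculeAssignment) -> int | None:
    """Return the hydronium O atom index, or None for a neutral frame."""
    if np.any(assignment.coordination >= 4):
        bad = assignment.o_indices[assignment.coordination >= 4]
        raise DefectError(f"oxygen(s) {bad.tolist()} carry >=4 hydrogens")
    over = assignment.o_indices[assignment.coordination == 3]
    if over.size == 0:
        return None
    if over.size > 1:
        raise DefectError(f"multiple hydronium candidates: {over.tolist()}")
    return int(over[0])


def classify_zundel(
    frame: Frame,
    assignment: MoleculeAssignment,
    delta_threshold: float = DELTA_THRESHOLD_DEFAULT,
) -> ZundelState:
    """Locate the shared proton of the defect and classify its symmetry.

    Among the three hydronium hydrogens, the shared proton H* is the one with
    the smallest asymmetry delta = |d(O_h - H) - d(O2 - H)| where O2 is the
    nearest non-hydronium oxygen to that H.  delta = 0 is the symmetric
    Zundel limit.
    """
    hyd = find_excess_proton(assignment)
    if hyd is None:
        raise DefectError("frame has no excess proton")
    h_of_hyd = assignment.hydrogens_of(hyd)
    other_o = assignment.o_indices[assignment.o_indices != hyd]
    if other_o.size == 0:
        raise DefectError("need at least two oxygens to classify a Zundel state")
    d_h_other = cdist(frame.positions[h_of_hyd], frame.positions[other_o])
    partner_pos = np.argmin(d_h_other, axis=1)
    d1 = np.linalg.norm(frame.positions[h_of_hyd] - frame.positions[hyd], axis=1)
    d2 = d_h_other[np.arange(h_of_hyd.size), partner_pos]
    deltas = np.abs(d1 - d2)
    best = int(np.argmin(deltas))
    return ZundelState(
        hydronium_O=hyd,
        shared_H=int(h_of_hyd[best]),
        partner_O=int(other_o[partner_pos[best]]),
        delta=float(deltas[best]),
        is_zundel=bool(deltas[best] < delta_threshold),
    )


def zundel_occupation(
    trajectory: Trajectory, delta_threshold: float = DELTA_THRESHOLD_DEFAULT
) -> float:
    """Fraction of frames whose defect is Zundel-like."""
    flags = [
        classify_zundel(fr, assign_molecules(fr), delta_threshold).is_zundel
        for fr in trajectory.frames
    ]
    return float(np.mean(flags))


def zundel_records(
    trajectory: Trajectory, delta_threshold: float = DELTA_THRESHOLD_DEFAULT
):
    """Per-frame defect records as a pandas DataFrame (CSV-exportable)."""
    import pandas as pd

    rows = []
    for k, fr in enumerate(trajectory.frames):
        st = classify_zundel(fr, assign_molecules(fr), delta_threshold)
        rows.append(
            dict(
                frame=k,
                time_fs=fr.time,
                hydronium_index=st.hydronium_O,
                shared_H_index=st.shared_H,
                partner_O_index=st.partner_O,
                delta_A=st.delta,
                is_zundel=st.is_zundel,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class DipoleSeries:
    """Dipole 3-vector per frame (e*A) with uniform time grid (fs)."""

    times: np.ndarray
    mu: np.ndarray  # (n_frames, 3)
    label: str = "full"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (self.times.size, 3):
            raise ValueError("mu must be (n_frames, 3)")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("non-finite dipole entries")

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise ValueError("need >=2 frames for a timestep")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
            raise ValueError("nonuniform time grid")
        return float(steps[0])

    def __add__(self, other: "DipoleSeries") -> "DipoleSeries":
        if self.times.shape != other.times.shape or not np.allclose(
            self.times, other.times
        ):
            raise ValueError("time grids differ")
        return DipoleSeries(self.times, self.mu + other.mu, label=self.label)


def zundel_site_selection(trajectory: Trajectory, with_wannier: bool = False):
    """Per-frame (atom indices, Wannier indices) of the O2H5+ complex.

    Selects hydronium O, partner O, the three hydronium H and the partner's
    assigned H (5 H total); with_wannier additionally selects the centers
    assigned to the two oxygens.
    """
    selections = []
    for fr in trajectory.frames:
        asg = assign_molecules(fr)
        st = classify_zundel(fr, asg)
        atoms = np.concatenate(
            [
                [st.hydronium_O, st.partner_O],
                asg.hydrogens_of(st.hydronium_O),
                asg.hydrogens_of(st.partner_O),
            ]
        ).astype(int)
        wcs = (
            np.concatenate([asg.wannier_of(st.hydronium_O), asg.wannier_of(st.partner_O)])
            if with_wannier
            else np.array([], dtype=int)
        )
        selections.append((atoms, wcs.astype(int)))
    return selections


def dipole_series(
    trajectory: Trajectory,
    model: ChargeModel,
    subset=None,
    label: str | None = None,
) -> DipoleSeries:
    """Assemble mu(t) = sum_i q_i r_i(t) over selected sites.

    ``subset`` is an optional per-frame list of (atom index array, Wannier
    index array); omitted means all sites.  Selections with net charge are
    referenced to the instantaneous geometric center of the selected nuclei,
    making the series translation independent for the +1 e defect cluster.
    """
    if trajectory.n_frames == 0:
        raise ValueError("empty trajectory")
    wann = model.mode is ChargeMode.WANNIER_FULL
    if wann and not trajectory.has_wannier():
        raise ValueError("wannier_full charge model requires Wannier centers on every frame")
    if subset is not None and len(subset) != trajectory.n_frames:
        raise ValueError("subset must provide one selection per frame")
    mus = np.empty((trajectory.n_frames, 3))
    for k, fr in enumerate(trajectory.frames):
        if subset is None:
            atom_idx = np.arange(fr.n_atoms)
            wc_idx = np.arange(len(fr.wannier)) if (wann and fr.wannier is not None) else np.array([], dtype=int)
        else:
            atom_idx, wc_idx = subset[k]
            atom_idx = np.asarray(atom_idx, dtype=int)
            wc_idx = np.asarray(wc_idx, dtype=int)
            if atom_idx.size == 0:
                raise ValueError(f"empty site selection at frame {k}")
        q = model.nuclear_charges([fr.elements[i] for i in atom_idx])
        pos = fr.positions[atom_idx]
        qtot = q.sum() + (model.q_wc * wc_idx.size if wann else 0.0)
        origin = pos.mean(axis=0) if abs(qtot) > 1e-9 else np.zeros(3)
        mu = q @ (pos - origin)
        if wann and wc_idx.size:
            mu = mu + model.q_wc * (fr.wannier[wc_idx] - origin).sum(axis=0)
        mus[k] = mu
    if label is None:
        if subset is not None:
            label = "subgroup"
        else:
            label = "full" if wann else "nuclear"
    return DipoleSeries(trajectory.times, mus, label=label)


def total_charge(frame: Frame, model: ChargeModel) -> float:
    """Net charge of a frame in the given model (e)."""
    q = model.nuclear_charges(frame.elements).sum()
    if model.mode is ChargeMode.WANNIER_FULL:
        if frame.wannier is None:
            raise ValueError("wannier_full charge model requires Wannier centers")
        q += model.q_wc * len(frame.wannier)
    return float(q)
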