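"""Trajectory, Wannier-center and spectrum-table I/O.

Reads and writes multi-frame XYZ / extended-XYZ trajectories (non-periodic,
elements O and H; optional Wannier centers as pseudo-atoms with symbol
``X``), parallel Wannier-center files, and the CSV spectrum-table contract
used across the package.  Coordinates in files are Angstrom, times in fs,
wavenumbers in cm^-1.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

WANNIER_SYMBOL = "X"


class XYZParseError(ValueError):
    """Malformed XYZ content; message names the 1-based frame index."""


class AlignmentError(ValueError):
    """Auxiliary file does not line up with the trajectory frames."""


@dataclass
class Frame:
    """One snapshot: nuclei plus (optionally) Wannier centers.

    positions and wannier are (n, 3) float arrays in Angstrom; time in fs.
    """

    elements: list[str]
    positions: np.ndarray
    wannier: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} does not match "
                f"{len(self.elements)} elements"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if self.wannier is not None:
            self.wannier = np.asarray(self.wannier, dtype=float).reshape(-1, 3)
            if not np.all(np.isfinite(self.wannier)):
                raise ValueError("non-finite Wannier coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def select(self, indices: Sequence[int]) -> "Frame":
        idx = np.asarray(indices, dtype=int)
        return Frame(
            [self.elements[i] for i in idx],
            self.positions[idx],
            time=self.time,
        )


@dataclass
class Trajectory:
    """Ordered frames with a uniform timestep (fs)."""

    frames: list[Frame]
    dt: float
    segment_id: str = ""
    geometry: str = ""
    protonated: bool = False
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.frames:
            ref = self.frames[0].elements
            for k, fr in enumerate(self.frames):
                if fr.elements != ref:
                    raise ValueError(f"frame {k} has a different element list")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0

    @property
    def elements(self) -> list[str]:
        return self.frames[0].elements

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    def positions_array(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) stack of nuclear coordinates."""
        return np.stack([fr.positions for fr in self.frames])

    def wannier_array(self) -> np.ndarray:
        if any(fr.wannier is None for fr in self.frames):
            raise ValueError("trajectory has frames without Wannier centers")
        return np.stack([fr.wannier for fr in self.frames])

    def has_wannier(self) -> bool:
        return bool(self.frames) and all(fr.wannier is not None for fr in self.frames)


def _iter_xyz_blocks(lines: list[str]):
    """Yield (frame_index_1based, comment, symbols, coords) per XYZ block."""
    i, k = 0, 0
    n_lines = len(lines)
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        k += 1
        try:
            natoms = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise XYZParseError(f"frame {k}: invalid atom-count header {lines[i]!r}")
        if natoms <= 0:
            raise XYZParseError(f"frame {k}: nonpositive atom count")
        if i + 1 + natoms >= n_lines + 1:
            pass
        comment = lines[i + 1].rstrip("\n") if i + 1 < n_lines else ""
        symbols, coords = [], []
        for j in range(natoms):
            li = i + 2 + j
            if li >= n_lines or not lines[li].strip():
                raise XYZParseError(
                    f"frame {k}: declares {natoms} atoms but block ends after {j}"
                )
            parts = lines[li].split()
            if len(parts) < 4:
                raise XYZParseError(f"frame {k}: short atom line {lines[li]!r}")
            symbols.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError:
                raise XYZParseError(f"frame {k}: non-numeric coordinate in {lines[li]!r}")
        yield k, comment, symbols, np.array(coords)
        i += 2 + natoms


def read_xyz_trajectory(path: str | Path, dt: float) -> Trajectory:
    """Read a multi-frame (extended) XYZ file.

    Pseudo-atoms with symbol ``X`` are split off into the frame's Wannier
    block; element symbols are normalized to title case.  Frame times are
    k*dt in file order.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    lines = Path(path).read_text().splitlines()
    frames: list[Frame] = []
    for k, _comment, symbols, coords in _iter_xyz_blocks(lines):
        symbols = [s.title() for s in symbols]
        is_wc = np.array([s == WANNIER_SYMBOL for s in symbols])
        elements = [s for s, w in zip(symbols, is_wc) if not w]
        wannier = coords[is_wc] if is_wc.any() else None
        frames.append(
            Frame(elements, coords[~is_wc], wannier=wannier, time=(k - 1) * dt)
        )
    if not frames:
        raise XYZParseError("frame 1: file contains no frames")
    counts = {fr.n_atoms for fr in frames}
    if len(counts) != 1:
        raise XYZParseError("frames have unequal atom counts")
    return Trajectory(frames, dt=dt)


def write_xyz_trajectory(
    trajectory: Trajectory,
    path: str | Path,
    include_wannier: bool = False,
    comment: str = "",
) -> None:
    """Write multi-frame XYZ; Wannier centers appended as ``X`` pseudo-atoms."""
    buf = io.StringIO()
    for fr in trajectory.frames:
        wc = fr.wannier if (include_wannier and fr.wannier is not None) else None
        n = fr.n_atoms + (0 if wc is None else len(wc))
        buf.write(f"{n}\n")
        buf.write(f"time_fs={fr.time:.6f} {comment}".rstrip() + "\n")
        for el, (x, y, z) in zip(fr.elements, fr.positions):
            buf.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")
        if wc is not None:
            for x, y, z in wc:
                buf.write(f"{WANNIER_SYMBOL} {x:.10f} {y:.10f} {z:.10f}\n")
    Path(path).write_text(buf.getvalue())


def write_wannier_file(trajectory: Trajectory, path: str | Path) -> None:
    """Write the Wannier centers alone as a parallel XYZ-like file."""
    buf = io.StringIO()
    for fr in trajectory.frames:
        if fr.wannier is None:
            raise ValueError("frame without Wannier centers")
        buf.write(f"{len(fr.wannier)}\n")
        buf.write(f"wannier time_fs={fr.time:.6f}\n")
        for x, y, z in fr.wannier:
            buf.write(f"{WANNIER_SYMBOL} {x:.10f} {y:.10f} {z:.10f}\n")
    Path(path).write_text(buf.getvalue())


def read_wannier_centers(path: str | Path, trajectory: Trajectory) -> Trajectory:
    """Attach a parallel Wannier-center file to a trajectory.

    The file must contain one XYZ-like block per trajectory frame; the
    per-frame center count must be constant.
    """
    lines = Path(path).read_text().splitlines()
    blocks = [coords for _k, _c, _s, coords in _iter_xyz_blocks(lines)]
    if len(blocks) != trajectory.n_frames:
        raise AlignmentError(
            f"{len(blocks)} Wannier blocks for {trajectory.n_frames} frames"
        )
    counts = {len(b) for b in blocks}
    if len(counts) != 1:
        raise AlignmentError(f"Wannier center count varies across frames: {sorted(counts)}")
    frames = [replace(fr, wannier=b) for fr, b in zip(trajectory.frames, blocks)]
    return replace(trajectory, frames=frames)


# ---------------------------------------------------------------------------
# spectrum tables

SPECTRUM_COLUMNS = ["wavenumber_cm-1", "A_xx", "A_yy", "A_zz", "A_xy_mean", "error"]


def write_spectrum_table(spectrum, path: str | Path, header_comment: str = "") -> None:
    """Write a Spectrum as CSV per the table contract.

    Columns: wavenumber_cm-1, A_xx, A_yy, A_zz, A_xy_mean, error (pooled RMS
    of the per-component standard errors, 0 when absent).  When per-component
    errors exist they are additionally written as err_xx/err_yy/err_zz so the
    matching reader round-trips losslessly.
    """
    if spectrum.nu.size == 0:
        raise ValueError("refusing to write an empty spectrum table")
    df = pd.DataFrame(
        {
            "wavenumber_cm-1": spectrum.nu,
            "A_xx": spectrum.A_xx,
            "A_yy": spectrum.A_yy,
            "A_zz": spectrum.A_zz,
            "A_xy_mean": 0.5 * (spectrum.A_xx + spectrum.A_yy),
        }
    )
    if spectrum.err is not None:
        df["error"] = np.sqrt(np.mean(spectrum.err**2, axis=0))
        df["err_xx"], df["err_yy"], df["err_zz"] = spectrum.err
    else:
        df["error"] = 0.0
    df = df[SPECTRUM_COLUMNS + [c for c in df.columns if c not in SPECTRUM_COLUMNS]]
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spectrum_table(path: str | Path):
    """Read a spectrum CSV written by :func:`write_spectrum_table`."""
    from .spectra import Spectrum

    df = pd.read_csv(path, comment="#")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spectrum table missing columns {missing}")
    err = None
    if {"err_xx", "err_yy", "err_zz"} <= set(df.columns):
        err = np.vstack([df["err_xx"], df["err_yy"], df["err_zz"]])
    return Spectrum(
        nu=df["wavenumber_cm-1"].to_numpy(),
        A_xx=df["A_xx"].to_numpy(),
        A_yy=df["A_yy"].to_numpy(),
        A_zz=df["A_zz"].to_numpy(),
        err=err,
    )


def read_absorbance_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavenumber_cm-1, absorbance) CSV."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError("absorbance table needs two columns")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
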