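"""Surface tension of slab configurations from pressure-tensor anisotropy.

For a slab with its normal along z the mechanical (virial) route gives

    gamma = (Lz / n_interfaces) * < Pzz - (Pxx + Pyy) / 2 >

in epsilon/sigma^2; dividing by the run temperature T* expresses it in
kB T / sigma^2.  Uncertainties come from block averaging the per-frame
anisotropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .engine import Trajectory

__all__ = [
    "PressureTensorSeries",
    "SurfaceTension",
    "surface_tension",
    "compare_mixture_tensions",
]


@dataclass(frozen=True)
class PressureTensorSeries:
    """Per-frame diagonal pressure-tensor components in epsilon/sigma^3."""

    pxx: np.ndarray
    pyy: np.ndarray
    pzz: np.ndarray
    box: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("pxx", "pyy", "pzz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size < 1 or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must hold at least one finite frame")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "box", np.asarray(self.box, dtype=float))

    @classmethod
    def from_trajectory(cls, traj: Trajectory, equilibration_fraction: float = 0.5):
        sc = traj.scalars
        start = int(np.floor(equilibration_fraction * len(sc)))
        sc = sc.iloc[start:]
        return cls(
            pxx=sc["Pxx"].to_numpy(),
            pyy=sc["Pyy"].to_numpy(),
            pzz=sc["Pzz"].to_numpy(),
            box=traj.box,
            times=sc["time"].to_numpy(),
        )

    def __len__(self) -> int:
        return len(self.pxx)


@dataclass(frozen=True)
class SurfaceTension:
    """A surface-tension estimate with its block-averaging uncertainty."""

    label: str
    gamma: float
    uncertainty: float
    temperature: float = float("nan")

    @property
    def units(self) -> str:
        return "kB T/sigma^2" if np.isfinite(self.temperature) else "epsilon/sigma^2"


def surface_tension(
    series: PressureTensorSeries,
    n_interfaces: int = 2,
    temperature: float | None = None,
    n_blocks: int = 10,
) -> tuple[float, float]:
    """Surface tension and its uncertainty from the pressure-tensor anisotropy.

    Returns gamma in epsilon/sigma^2, or in kB T/sigma^2 when the run
    temperature T* is supplied.  The uncertainty is the standard error over
    ``n_blocks`` contiguous blocks (at least 5; NaN for a single frame).
    Slab geometry with the normal along z (the elongated axis) is assumed;
    a box whose z edge is not the longest is flagged.
    """
    if n_interfaces < 1:
        raise ValueError("n_interfaces must be >= 1")
    box = series.box
    if box[2] < max(box[0], box[1]):
        raise ValueError("non-slab geometry: expected the slab normal (z) on the long axis")
    aniso = series.pzz - 0.5 * (series.pxx + series.pyy)
    gamma_frames = (box[2] / n_interfaces) * aniso
    gamma = float(gamma_frames.mean())
    if len(gamma_frames) < 2:
        unc = float("nan")
    else:
        nb = max(5, min(n_blocks, len(gamma_frames)))
        means = [blk.mean() for blk in np.array_split(gamma_frames, nb) if len(blk)]
        unc = float(np.std(means, ddof=1) / np.sqrt(len(means)))
    if temperature is not None:
        gamma /= temperature
        unc /= temperature
    return gamma, unc


def compare_mixture_tensions(results: Sequence[SurfaceTension]) -> dict:
    """Rank surface tensions and classify pairwise differences.

    Two values are 'significant'ly different when they differ by more than
    the sum of their uncertainties (two-uncertainty criterion), otherwise
    'indistinguishable'.  Results measured at different T* are flagged.
    """
    if len(results) < 2:
        raise ValueError("need at least two surface-tension results to compare")
    temps = [r.temperature for r in results if np.isfinite(r.temperature)]
    mismatch = len(temps) >= 2 and (max(temps) - min(temps)) > 1e-12
    ranking = sorted(results, key=lambda r: r.gamma)
    pairs = {}
    for i, a in enumerate(ranking):
        for b in ranking[i + 1 :]:
            significant = abs(a.gamma - b.gamma) > (a.uncertainty + b.uncertainty)
            pairs[(a.label, b.label)] = {
                "lower": a.label,
                "difference": b.gamma - a.gamma,
                "verdict": "significant" if significant else "indistinguishable",
            }
    return {
        "ranking": [r.label for r in ranking],
        "gammas": {r.label: (r.gamma, r.uncertainty) for r in results},
        "pairs": pairs,
        "temperature_mismatch": mismatch,
    }
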