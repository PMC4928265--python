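"""Per-residue alpha-helix occupancy of a conformational ensemble.

Backbone phi/psi torsions are computed for every model of a multi-model
structure; a residue counts as helical in a frame when both angles fall in
a configurable alpha basin (default a generous box around the canonical
-57/-47 degrees).  Occupancy is the fraction of frames in which a residue
is helical, with frames where the residue's torsions are undefined (chain
termini, missing atoms) excluded from both numerator and denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .io import Region, RegionKind


@dataclass(frozen=True)
class AlphaBasin:
    """Torsion-angle box (degrees) counted as alpha-helical."""

    phi_min: float = -90.0
    phi_max: float = -30.0
    psi_min: float = -77.0
    psi_max: float = -17.0

    def __post_init__(self) -> None:
        if not (self.phi_min < self.phi_max and self.psi_min < self.psi_max):
            raise ValueError("malformed alpha basin")

    def contains(self, phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Boolean in-basin mask; NaN torsions are False."""
        with np.errstate(invalid="ignore"):
            return (
                (phi >= self.phi_min) & (phi <= self.phi_max)
                & (psi >= self.psi_min) & (psi <= self.psi_max)
            )


@dataclass
class TorsionFrame:
    """Backbone torsions (degrees) of one ensemble frame; NaN = undefined."""

    frame_index: int
    phi: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        if self.phi.shape != self.psi.shape:
            raise ValueError("phi and psi must have equal length")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            finite = arr[np.isfinite(arr)]
            if np.any((finite <= -180.0) | (finite > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    @property
    def n_residues(self) -> int:
        return len(self.phi)


@dataclass
class HelicityProfile:
    """Per-residue alpha-basin occupancy over an ensemble."""

    occupancy: np.ndarray   # NaN where no frame had usable torsions
    n_frames: int
    alpha_basin: AlphaBasin

    def __post_init__(self) -> None:
        occ = self.occupancy[np.isfinite(self.occupancy)]
        if np.any((occ < 0) | (occ > 1)):
            raise ValueError("occupancy must be in [0, 1]")


def dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> float:
    """Four-point dihedral angle in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else ang


def torsions_from_models(
    source: str | Path | struc.AtomArrayStack,
) -> list[TorsionFrame]:
    """Backbone phi/psi for every model of a multi-model PDB (or stack).

    The first residue's phi and the last residue's psi are undefined (NaN);
    residues with missing backbone atoms come back NaN rather than raising.
    """
    if isinstance(source, (str, Path)):
        stack = PDBFile.read(str(source)).get_structure(model=None)
    else:
        stack = source
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames: list[TorsionFrame] = []
    for k in range(stack.stack_depth()):
        model = stack[k]
        phi, psi, _omega = struc.dihedral_backbone(model)
        phi_deg = np.degrees(np.asarray(phi, dtype=float))
        psi_deg = np.degrees(np.asarray(psi, dtype=float))
        # map -180 into the (-180, 180] convention
        phi_deg[phi_deg == -180.0] = 180.0
        psi_deg[psi_deg == -180.0] = 180.0
        frames.append(TorsionFrame(frame_index=k, phi=phi_deg, psi=psi_deg))
    return frames


def helicity_profile(
    frames: list[TorsionFrame], alpha_basin: AlphaBasin | None = None
) -> HelicityProfile:
    """Fraction of frames per residue with torsions inside the alpha basin.

    A residue-frame with undefined torsions is excluded from numerator and
    denominator for that residue; a residue with no usable frame at all is
    reported NaN.
    """
    if not frames:
        raise ValueError("need at least one frame")
    basin = alpha_basin or AlphaBasin()
    n_res = frames[0].n_residues
    in_basin = np.zeros(n_res, dtype=float)
    usable = np.zeros(n_res, dtype=float)
    for frame in frames:
        if frame.n_residues != n_res:
            raise ValueError("frames have differing residue counts")
        ok = np.isfinite(frame.phi) & np.isfinite(frame.psi)
        usable += ok
        in_basin += basin.contains(frame.phi, frame.psi) & ok
    with np.errstate(invalid="ignore", divide="ignore"):
        occupancy = np.where(usable > 0, in_basin / np.maximum(usable, 1), np.nan)
    return HelicityProfile(occupancy=occupancy, n_frames=len(frames), alpha_basin=basin)


def contiguous_helix_runs(
    frame: TorsionFrame,
    alpha_basin: AlphaBasin | None = None,
    min_run: int = 4,
    protein_id: str = "chain",
) -> list[Region]:
    """Maximal runs of in-basin residues of length >= ``min_run`` in a frame."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    basin = alpha_basin or AlphaBasin()
    mask = basin.contains(frame.phi, frame.psi) & np.isfinite(frame.phi) & np.isfinite(frame.psi)
    from .io import mask_to_regions

    runs = mask_to_regions(mask, protein_id, RegionKind.CUSTOM, min_len=min_run)
    return [
        Region(r.protein_id, r.start, r.end, RegionKind.CUSTOM, label="helix")
        for r in runs
    ]
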