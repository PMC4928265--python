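"""Low-complexity region and homorepeat detection.

LCRs are found with a windowed Shannon-entropy scheme: windows whose
entropy falls at or below a trigger threshold seed a region, which is
extended over adjacent windows while their entropy stays at or below a
(looser) extension threshold; overlapping window spans are merged.  This is
a deliberate simplification of SEG's two-pass probability refinement —
adequate for flagging compositionally biased segments, with both thresholds
exposed in configuration.

Homorepeats (polyQ and friends) are maximal single-residue runs of at least
a minimum length.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io import ProteinRecord, Region, RegionKind, regions_to_mask


@dataclass(frozen=True)
class LcrParams:
    window: int = 12
    entropy_trigger: float = 2.2   # bits
    entropy_extend: float = 2.5    # bits
    min_homorepeat: int = 5

    def __post_init__(self) -> None:
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.entropy_trigger > self.entropy_extend:
            raise ValueError("entropy_trigger must be <= entropy_extend")
        if self.min_homorepeat < 2:
            raise ValueError("min_homorepeat must be >= 2")


def window_entropy(sequence_window: str) -> float:
    """Shannon entropy in bits of the residue composition of a window.

    ``X`` residues are excluded from the counts.  An empty window (or one
    consisting only of X) is an error.
    """
    counts = Counter(aa for aa in sequence_window if aa != "X")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty window (no standard residues)")
    return -sum((c / total) * math.log2(c / total) for c in counts.values())


def _window_entropies(sequence: str, window: int) -> np.ndarray:
    """Entropy of each window start (NaN where no standard residue)."""
    n = len(sequence)
    out = np.empty(n - window + 1)
    for i in range(n - window + 1):
        win = sequence[i : i + window]
        try:
            out[i] = window_entropy(win)
        except ValueError:
            out[i] = np.nan
    return out


def detect_lcr(protein: ProteinRecord, params: LcrParams | None = None) -> list[Region]:
    """Trigger/extend windowed-entropy LCR detection.

    Maximal runs of windows with entropy <= ``entropy_extend`` that contain
    at least one window with entropy <= ``entropy_trigger`` are reported;
    the region span is the union of the qualifying windows' residues.
    Overlapping spans are merged so the returned regions are disjoint,
    sorted and maximal.
    """
    params = params or LcrParams()
    w = params.window
    if len(protein) < w:
        raise ValueError(
            f"{protein.id}: sequence shorter than entropy window ({len(protein)} < {w})"
        )
    ent = _window_entropies(protein.sequence, w)
    extendable = np.where(np.isnan(ent), False, ent <= params.entropy_extend)
    triggering = np.where(np.isnan(ent), False, ent <= params.entropy_trigger)

    mask = np.zeros(len(protein), dtype=bool)
    i = 0
    m = len(ent)
    while i < m:
        if not extendable[i]:
            i += 1
            continue
        j = i
        while j < m and extendable[j]:
            j += 1
        if triggering[i:j].any():
            mask[i : j - 1 + w] = True  # union of windows [i, j-1]
        i = j
    from .io import mask_to_regions

    return mask_to_regions(mask, protein.id, RegionKind.LCR)


def detect_homorepeats(
    protein: ProteinRecord, min_len: int = 5
) -> list[Region]:
    """Maximal runs of a single residue with length >= ``min_len``.

    Regions carry the repeated residue as ``label`` and the run length as
    ``score``-free metadata (length is recoverable from the interval).
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = protein.sequence
    regions: list[Region] = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = j - i
        if run >= min_len and seq[i] != "X":
            regions.append(
                Region(protein.id, i + 1, j, RegionKind.HOMOREPEAT,
                       score=None, label=seq[i])
            )
        i = j
    return regions


def overlap_stats(
    regions_a: list[Region],
    regions_b: list[Region],
    lengths: dict[str, int] | None = None,
) -> dict[str, float]:
    """Residue-set overlap between two region collections.

    Returns the Jaccard index of the covered residue sets and the two
    directional coverage fractions, pooled over the union of proteins.  If
    both sets are empty all three statistics are 0.
    """
    def residue_set(regions: list[Region]) -> set[tuple[str, int]]:
        out: set[tuple[str, int]] = set()
        for r in regions:
            out.update((r.protein_id, pos) for pos in r.residues())
        return out

    sa, sb = residue_set(regions_a), residue_set(regions_b)
    inter = len(sa & sb)
    union = len(sa | sb)
    return {
        "jaccard": inter / union if union else 0.0,
        "frac_a_in_b": inter / len(sa) if sa else 0.0,
        "frac_b_in_a": inter / len(sb) if sb else 0.0,
    }
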