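"""Disordered binding-region calling, conservation filtering, variant mapping.

The two-step procedure: (1) call candidate binding regions as maximal runs
of binding propensity >= 0.5 with a minimum length of 8 residues; (2) keep,
within each candidate, the maximal sub-runs whose sequence conservation is
at least 0.9 (and, by default, still at least 8 residues long).  Variants
given on protein coordinates are then mapped into the surviving regions.

The built-in binding-propensity predictor is a stand-in heuristic: the
windowed fraction of interaction-prone residues (aromatic/hydrophobic plus
charged anchors) multiplied by the local disorder score, squashed through a
logistic.  Externally computed tracks (e.g. ANCHOR output re-formatted as
TSV) slot in via :func:`idrpipe.io.read_score_tracks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conservation import ConservationTrack
from .disorder import DisorderProfile
from .io import (
    ProteinRecord,
    Region,
    RegionKind,
    ScoreTrack,
    VariantRecord,
    mask_to_regions,
)

DEFAULT_MIN_BINDING_LEN = 8
DEFAULT_SEQ_THRESHOLD = 0.9
#: Residues that commonly anchor induced-folding interactions.
INTERACTION_RESIDUES = frozenset("WFYLIVMR")


@dataclass
class BindingProfile:
    """Per-residue binding propensity in [0, 1] with calling threshold."""

    track: ScoreTrack
    threshold: float = 0.5

    def __post_init__(self) -> None:
        v = self.track.values
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{self.track.protein_id}: binding scores outside [0, 1]")

    @property
    def protein_id(self) -> str:
        return self.track.protein_id

    @property
    def values(self) -> np.ndarray:
        return self.track.values

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class ConservedBindingRegion:
    """A conserved sub-run of a candidate binding region."""

    region: Region
    parent_candidate: Region
    n_variants: int = 0
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (
            self.parent_candidate.start <= self.region.start
            and self.region.end <= self.parent_candidate.end
        ):
            raise ValueError("conserved region must lie within its candidate")


def predict_binding_standin(
    protein: ProteinRecord,
    disorder_profile: DisorderProfile,
    window: int = 9,
    logistic_midpoint: float = 0.15,
    logistic_slope: float = 12.0,
    threshold: float = 0.5,
) -> BindingProfile:
    """Heuristic binding-propensity stand-in.

    Propensity = logistic(windowed fraction of interaction-prone residues
    x local disorder score).  A disordered segment enriched in aromatic or
    hydrophobic anchors therefore scores high, mimicking the behaviour of
    energy-based binding-region predictors at the level needed here.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    n = len(protein)
    hot = np.array([aa in INTERACTION_RESIDUES for aa in protein.sequence], dtype=float)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(hot)))
    frac = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        frac[i] = (csum[hi] - csum[lo]) / (hi - lo)
    raw = frac * disorder_profile.values
    values = 1.0 / (1.0 + np.exp(-logistic_slope * (raw - logistic_midpoint)))
    return BindingProfile(
        ScoreTrack(protein.id, values, source="standin-binding"), threshold
    )


def candidate_binding_regions(
    binding_profile: BindingProfile, min_len: int = DEFAULT_MIN_BINDING_LEN
) -> list[Region]:
    """Maximal runs of binding score >= threshold, at least ``min_len`` long."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    mask = binding_profile.values >= binding_profile.threshold
    return mask_to_regions(
        mask, binding_profile.protein_id, RegionKind.BINDING_CANDIDATE, min_len=min_len
    )


def conserved_binding_regions(
    candidates: list[Region],
    conservation_track: ConservationTrack,
    seq_thr: float = DEFAULT_SEQ_THRESHOLD,
    min_conserved_run: int = DEFAULT_MIN_BINDING_LEN,
    whole_region: bool = False,
) -> list[ConservedBindingRegion]:
    """Intersect candidate binding regions with sequence conservation.

    Default (residue-level) mode: within each candidate, maximal sub-runs
    of residues with seq_cons >= ``seq_thr`` are kept when at least
    ``min_conserved_run`` residues long.  ``whole_region=True`` instead
    keeps or drops each candidate in full according to whether its mean
    seq_cons reaches the threshold.
    """
    out: list[ConservedBindingRegion] = []
    cons = conservation_track.seq_cons
    for cand in sorted(candidates, key=lambda r: (r.protein_id, r.start)):
        if cand.protein_id != conservation_track.protein_id:
            raise ValueError(
                f"candidate on {cand.protein_id!r} but track is for "
                f"{conservation_track.protein_id!r}"
            )
        if cand.end > len(cons):
            raise ValueError(
                f"candidate [{cand.start}, {cand.end}] outside conservation track"
            )
        if whole_region:
            if float(cons[cand.start - 1 : cand.end].mean()) >= seq_thr:
                region = Region(
                    cand.protein_id, cand.start, cand.end,
                    RegionKind.CONSERVED_BINDING, score=cand.score,
                )
                out.append(ConservedBindingRegion(region, cand))
            continue
        sub = cons[cand.start - 1 : cand.end] >= seq_thr
        for run in mask_to_regions(
            sub, cand.protein_id, RegionKind.CONSERVED_BINDING,
            min_len=min_conserved_run,
        ):
            region = Region(
                cand.protein_id,
                cand.start + run.start - 1,
                cand.start + run.end - 1,
                RegionKind.CONSERVED_BINDING,
            )
            out.append(ConservedBindingRegion(region, cand))
    return out


def map_variants(
    regions: list[Region] | list[ConservedBindingRegion],
    variants: list[VariantRecord],
) -> tuple[pd.DataFrame, list[VariantRecord]]:
    """Map variants into regions by interval membership.

    A variant maps to a region iff it lies on the same protein and
    ``start <= position <= end``.  Returns a per-region table (with counts
    and the mapped variant positions) and the list of variants that mapped
    nowhere.  ConservedBindingRegion inputs get their ``n_variants`` and
    ``variants`` fields filled in place.
    """
    rows = []
    mapped: set[int] = set()
    for item in regions:
        region = item.region if isinstance(item, ConservedBindingRegion) else item
        in_region = [
            v
            for v in variants
            if v.protein_id == region.protein_id
            and region.start <= v.position <= region.end
        ]
        mapped.update(id(v) for v in in_region)
        if isinstance(item, ConservedBindingRegion):
            item.n_variants = len(in_region)
            item.variants = in_region
        rows.append(
            {
                "protein_id": region.protein_id,
                "start": region.start,
                "end": region.end,
                "kind": region.kind.value,
                "n_variants": len(in_region),
                "variant_positions": [v.position for v in in_region],
            }
        )
    unmapped = [v for v in variants if id(v) not in mapped]
    return pd.DataFrame(rows), unmapped


def region_overlap(region_a: Region, region_b: Region) -> dict:
    """Overlap of two intervals on the same protein.

    ``shared = max(0, min(end_a, end_b) - max(start_a, start_b) + 1)``.
    """
    if region_a.protein_id != region_b.protein_id:
        raise ValueError(
            f"regions on different proteins: "
            f"{region_a.protein_id!r} vs {region_b.protein_id!r}"
        )
    shared = max(
        0, min(region_a.end, region_b.end) - max(region_a.start, region_b.start) + 1
    )
    return {"overlaps": shared > 0, "shared_residues": shared}
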