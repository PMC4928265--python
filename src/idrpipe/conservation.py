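"""Alignment-column conservation and constrained/flexible disorder classes.

Sequence conservation of an ortholog alignment column is scored as the
Jensen-Shannon divergence (base 2) between the column's residue
distribution and a background distribution, normalised by the divergence of
a single-residue column against that background so that a fully conserved
column scores 1 and a background-like column scores 0.  Columns with more
than 50% gaps score 0 (uninformative).  Per-column scores are smoothed with
a centred moving average of window 3 before being projected onto the
ungapped coordinates of the reference sequence.

Disorder conservation of a column is the fraction of non-gap orthologs
whose residue at that column is predicted disordered.  Reference residues
that are themselves disordered are then classed as

* CONSTRAINED_DISORDER — disorder and sequence both conserved,
* FLEXIBLE_DISORDER — only the disorder tendency is conserved,
* NOT_CONSERVED_DISORDER — neither.

Ordered reference residues are labelled ORDERED regardless of scores.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import AlignIO
from scipy.spatial.distance import jensenshannon

from .disorder import DisorderProfile
from .io import AMINO_ACIDS, Region

GAP = "-"
DEFAULT_WINDOW = 3
DEFAULT_SEQ_THRESHOLD = 0.9
DEFAULT_DIS_THRESHOLD = 0.75
MAX_GAP_FRACTION = 0.5


class DisorderConservationClass(Enum):
    CONSTRAINED_DISORDER = "CONSTRAINED_DISORDER"
    FLEXIBLE_DISORDER = "FLEXIBLE_DISORDER"
    NOT_CONSERVED_DISORDER = "NOT_CONSERVED_DISORDER"
    ORDERED = "ORDERED"


@dataclass
class OrthologAlignment:
    """A multiple alignment of orthologs with a designated reference row."""

    reference_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if self.reference_id not in self.rows:
            raise ValueError(f"reference {self.reference_id!r} absent from alignment")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def reference_row(self) -> str:
        return self.rows[self.reference_id]

    def column(self, j: int) -> list[str]:
        return [s[j] for s in self.rows.values()]

    def reference_columns(self) -> np.ndarray:
        """0-based alignment columns where the reference is ungapped."""
        ref = np.frombuffer(self.reference_row.encode(), dtype="S1")
        return np.flatnonzero(ref != GAP.encode())


def read_alignment(
    path: str | Path, reference_id: str, fmt: str | None = None
) -> OrthologAlignment:
    """Read an aligned FASTA or Clustal file into an OrthologAlignment."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal", ".clw"} else "fasta"
    msa = AlignIO.read(str(path), fmt)
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    if len(rows) != len(msa):
        raise ValueError("duplicate row ids in alignment")
    return OrthologAlignment(reference_id=reference_id, rows=rows)


def uniform_background() -> np.ndarray:
    """Uniform distribution over the 20 standard amino acids."""
    return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))


def _jsd_bits(p: np.ndarray, q: np.ndarray) -> float:
    # scipy returns the JS *distance* (sqrt of the divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


_MAX_DELTA_CACHE: dict[bytes, float] = {}


def _max_delta_jsd(background: np.ndarray) -> float:
    """Largest JSD any single-residue column can reach against background."""
    key = background.tobytes()
    cached = _MAX_DELTA_CACHE.get(key)
    if cached is not None:
        return cached
    best = 0.0
    for k in range(len(background)):
        delta = np.zeros_like(background)
        delta[k] = 1.0
        best = max(best, _jsd_bits(delta, background))
    _MAX_DELTA_CACHE[key] = best
    return best


def column_jsd(
    column_residues: Sequence[str],
    background: np.ndarray | None = None,
) -> float:
    """Normalised Jensen-Shannon conservation score of one column in [0, 1].

    0 means the column's residue distribution equals the background; 1 is a
    single invariant residue (the analytic maximum against the background).
    Columns that are mostly gaps (> 50%) score 0.  An all-gap column is an
    error.
    """
    background = uniform_background() if background is None else np.asarray(background)
    col = list(column_residues)
    n = len(col)
    gaps = sum(1 for c in col if c == GAP)
    if gaps == n:
        raise ValueError("all-gap column")
    if gaps / n > MAX_GAP_FRACTION:
        return 0.0
    counts = Counter(c for c in col if c in set(AMINO_ACIDS))
    total = sum(counts.values())
    if total < 2:
        return 0.0
    p = np.array([counts.get(a, 0) for a in AMINO_ACIDS], dtype=float) / total
    raw = _jsd_bits(p, background)
    return min(1.0, raw / _max_delta_jsd(background))


def smooth(values: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred moving average, window truncated at the ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


@dataclass
class ConservationTrack:
    """Per-reference-residue conservation scores (reference coordinates)."""

    protein_id: str
    seq_cons: np.ndarray     # smoothed, [0, 1], one per reference residue
    dis_cons: np.ndarray     # fraction of non-gap orthologs disordered
    column_index: np.ndarray  # 0-based alignment column of each residue

    def __post_init__(self) -> None:
        if not (len(self.seq_cons) == len(self.dis_cons) == len(self.column_index)):
            raise ValueError("conservation track arrays must align")

    def __len__(self) -> int:
        return len(self.seq_cons)


def conservation_track(
    alignment: OrthologAlignment,
    disorder_profiles: Mapping[str, DisorderProfile],
    window: int = DEFAULT_WINDOW,
    background: np.ndarray | None = None,
    disorder_threshold: float = 0.5,
) -> ConservationTrack:
    """Sequence- and disorder-conservation per reference residue.

    Every alignment row needs a disorder profile on its ungapped sequence
    (stand-in predictions are acceptable).  Column JSD scores are smoothed
    (window 3 by default) over all alignment columns, then both tracks are
    projected onto reference residues by dropping reference-gap columns.
    """
    for rid in alignment.rows:
        if rid not in disorder_profiles:
            raise ValueError(f"no disorder profile for alignment row {rid!r}")
    bg = uniform_background() if background is None else np.asarray(background)
    n_cols = alignment.n_columns
    row_ids = list(alignment.rows)
    row_seqs = [alignment.rows[rid] for rid in row_ids]
    # per-row mapping from alignment column to ungapped position
    disordered_at: list[np.ndarray] = []
    for rid, seq in zip(row_ids, row_seqs):
        prof = disorder_profiles[rid].values >= disorder_threshold
        flags = np.zeros(n_cols, dtype=bool)
        pos = 0
        for j, c in enumerate(seq):
            if c != GAP:
                flags[j] = prof[pos]
                pos += 1
        if pos != len(prof):
            raise ValueError(
                f"profile length mismatch for row {rid!r} "
                f"({len(prof)} scores, {pos} residues)"
            )
        disordered_at.append(flags)
    disordered_at_arr = np.array(disordered_at)
    gap_at = np.array(
        [[c == GAP for c in seq] for seq in row_seqs], dtype=bool
    )

    seq_raw = np.empty(n_cols)
    dis_raw = np.empty(n_cols)
    for j in range(n_cols):
        col = [seq[j] for seq in row_seqs]
        seq_raw[j] = 0.0 if all(c == GAP for c in col) else column_jsd(col, bg)
        nongap = ~gap_at[:, j]
        dis_raw[j] = (
            float(disordered_at_arr[nongap, j].mean()) if nongap.any() else 0.0
        )
    seq_smooth = smooth(seq_raw, window)
    ref_cols = alignment.reference_columns()
    return ConservationTrack(
        protein_id=alignment.reference_id,
        seq_cons=seq_smooth[ref_cols],
        dis_cons=dis_raw[ref_cols],
        column_index=ref_cols,
    )


def classify_disorder_conservation(
    track: ConservationTrack,
    reference_profile: DisorderProfile,
    dis_thr: float = DEFAULT_DIS_THRESHOLD,
    seq_thr: float = DEFAULT_SEQ_THRESHOLD,
) -> list[DisorderConservationClass]:
    """Constrained/flexible/not-conserved labels for reference residues."""
    if not (0.0 <= dis_thr <= 1.0 and 0.0 <= seq_thr <= 1.0):
        raise ValueError("thresholds must be in [0, 1]")
    if len(track) != len(reference_profile):
        raise ValueError("track and reference profile lengths differ")
    labels: list[DisorderConservationClass] = []
    disordered = reference_profile.values >= reference_profile.threshold
    for i in range(len(track)):
        if not disordered[i]:
            labels.append(DisorderConservationClass.ORDERED)
        elif track.dis_cons[i] >= dis_thr and track.seq_cons[i] >= seq_thr:
            labels.append(DisorderConservationClass.CONSTRAINED_DISORDER)
        elif track.dis_cons[i] >= dis_thr:
            labels.append(DisorderConservationClass.FLEXIBLE_DISORDER)
        else:
            labels.append(DisorderConservationClass.NOT_CONSERVED_DISORDER)
    return labels


def constrained_percent(
    classes: Sequence[DisorderConservationClass], region: Region
) -> float:
    """Percentage of a region's residues labelled constrained disorder."""
    if region.end > len(classes):
        raise ValueError(
            f"region end {region.end} beyond classified length {len(classes)}"
        )
    window = classes[region.start - 1 : region.end]
    n_con = sum(
        1 for c in window if c is DisorderConservationClass.CONSTRAINED_DISORDER
    )
    return 100.0 * n_con / len(window)
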