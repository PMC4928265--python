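"""Core sequence data model and file I/O.

Holds the protein record, region, variant and per-residue score-track types
that every analysis stage consumes, together with readers/writers for FASTA,
score-track TSV and BED6.

Coordinate convention: all residue intervals are 1-based and inclusive
(``aa 408-416`` means residues 408..416).  The only 0-based surface is BED
output, where ``chromStart = start - 1`` and ``chromEnd = end`` (half-open).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: Residues accepted in input sequences.  ``X`` (unknown) is tolerated but
#: excluded from composition-dependent computations (entropy, shuffling).
ALLOWED_RESIDUES = _AA_SET | {"X"}


class RegionKind(Enum):
    """Label for the biological interpretation of a residue interval."""

    IDR = "IDR"
    LCR = "LCR"
    HOMOREPEAT = "HOMOREPEAT"
    BINDING_CANDIDATE = "BINDING_CANDIDATE"
    CONSERVED_BINDING = "CONSERVED_BINDING"
    CUSTOM = "CUSTOM"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with optional family/taxon-group labels."""

    id: str
    sequence: str
    family: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must have length >= 1")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.id}: sequence must be uppercase")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in ALLOWED_RESIDUES:
                raise ValueError(
                    f"{self.id}: invalid residue {aa!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive residue interval on a named protein.

    ``label`` carries kind-specific annotation (e.g. the repeated residue of
    a homorepeat, or "helix" for torsion runs).
    """

    protein_id: str
    start: int
    end: int
    kind: RegionKind
    score: float | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] on {self.protein_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def residues(self) -> range:
        """1-based residue positions covered by the region."""
        return range(self.start, self.end + 1)

    def validate_against(self, protein: ProteinRecord) -> None:
        if self.protein_id != protein.id:
            raise ValueError(f"region on {self.protein_id}, protein is {protein.id}")
        if self.end > len(protein):
            raise ValueError(
                f"{self.protein_id}: region end {self.end} beyond length {len(protein)}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """A single-residue variant given on protein coordinates (1-based)."""

    protein_id: str
    position: int
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"variant position must be >= 1, got {self.position}")


@dataclass
class ScoreTrack:
    """Dense per-residue real-valued track (disorder, binding propensity...)."""

    protein_id: str
    values: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("score track must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0]) + 1
            raise ValueError(
                f"{self.protein_id}: non-finite score at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# FASTA

def _parse_description(description: str) -> tuple[str, dict[str, str]]:
    """Split a FASTA description into id and key=value tokens."""
    tokens = description.split()
    rec_id = tokens[0]
    kv: dict[str, str] = {}
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, value = tok.partition("=")
            kv[key] = value
    return rec_id, kv


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    The description line is parsed as ``id [family=..] [group=..]``.  Order
    is preserved.  Raises on an empty file, duplicate ids, or residues
    outside the 20-letter alphabet plus X.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rec_id, kv = _parse_description(rec.description)
        if rec_id in seen:
            raise ValueError(f"duplicate protein id in FASTA: {rec_id!r}")
        seen.add(rec_id)
        records.append(
            ProteinRecord(
                id=rec_id,
                sequence=str(rec.seq).upper() if str(rec.seq).isupper() else str(rec.seq),
                family=kv.get("family"),
                group=kv.get("group"),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, encoding family/group as key=value tokens."""
    out = []
    for rec in records:
        desc = []
        if rec.family is not None:
            desc.append(f"family={rec.family}")
        if rec.group is not None:
            desc.append(f"group={rec.group}")
        out.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=" ".join(desc))
        )
    SeqIO.write(out, str(path), "fasta")


# ---------------------------------------------------------------------------
# Score tracks

def read_score_tracks(
    path: str | Path,
    proteins: Sequence[ProteinRecord],
    source: str = "external",
) -> dict[str, ScoreTrack]:
    """Read a TSV of (protein_id, position, score) into dense tracks.

    Every residue of every listed protein must be covered exactly once;
    missing positions, unknown protein ids and non-finite scores are errors.
    """
    by_id = {p.id: p for p in proteins}
    values: dict[str, dict[int, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            pid, pos_s, score_s = row[0], row[1], row[2]
            if pid not in by_id:
                raise ValueError(f"unknown protein id in score track: {pid!r}")
            pos = int(pos_s)
            score = float(score_s)
            if not np.isfinite(score):
                raise ValueError(f"{pid}: non-finite score at position {pos}")
            if not (1 <= pos <= len(by_id[pid])):
                raise ValueError(f"{pid}: position {pos} outside sequence")
            slot = values.setdefault(pid, {})
            if pos in slot:
                raise ValueError(f"{pid}: duplicate score at position {pos}")
            slot[pos] = score
    tracks: dict[str, ScoreTrack] = {}
    for pid, scores in values.items():
        n = len(by_id[pid])
        gaps = [i for i in range(1, n + 1) if i not in scores]
        if gaps:
            raise ValueError(f"{pid}: missing score positions {gaps}")
        tracks[pid] = ScoreTrack(
            protein_id=pid,
            values=np.array([scores[i] for i in range(1, n + 1)]),
            source=source,
        )
    return tracks


def write_score_tracks(
    tracks: Mapping[str, ScoreTrack] | Iterable[ScoreTrack], path: str | Path
) -> None:
    if isinstance(tracks, Mapping):
        tracks = tracks.values()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_id", "position", "score"])
        for track in tracks:
            for i, v in enumerate(track.values, start=1):
                writer.writerow([track.protein_id, i, f"{v:.6g}"])


# ---------------------------------------------------------------------------
# Variants

def read_variants(
    path: str | Path, proteins: Sequence[ProteinRecord] | None = None
) -> list[VariantRecord]:
    """Read a variant TSV with columns protein_id, position[, annotation]."""
    by_id = {p.id: p for p in proteins} if proteins is not None else None
    variants: list[VariantRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            pid, pos = row[0], int(row[1])
            annotation = row[2] if len(row) > 2 else ""
            if by_id is not None:
                if pid not in by_id:
                    raise ValueError(f"unknown protein id in variants: {pid!r}")
                if not (1 <= pos <= len(by_id[pid])):
                    raise ValueError(f"{pid}: variant position {pos} outside sequence")
            variants.append(VariantRecord(pid, pos, annotation))
    return variants


# ---------------------------------------------------------------------------
# BED output

def write_regions_bed(regions: Iterable[Region], path: str | Path) -> None:
    """Write regions as BED6 (0-based half-open intervals).

    Scores assumed in [0, 1] are scaled to the BED 0-1000 range; missing
    scores map to 0.
    """
    with open(path, "w") as fh:
        for region in regions:
            if region.score is None:
                bed_score = 0
            else:
                bed_score = int(round(min(max(region.score, 0.0), 1.0) * 1000))
            fh.write(
                f"{region.protein_id}\t{region.start - 1}\t{region.end}\t"
                f"{region.kind.value}\t{bed_score}\t.\n"
            )


def write_regions_tsv(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_id", "start", "end", "kind", "score", "label"])
        for r in regions:
            writer.writerow(
                [r.protein_id, r.start, r.end, r.kind.value,
                 "" if r.score is None else f"{r.score:.6g}",
                 r.label or ""]
            )


# ---------------------------------------------------------------------------
# Shared region helpers

def regions_to_mask(regions: Iterable[Region], length: int) -> np.ndarray:
    """Boolean per-residue mask (index 0 = residue 1) covered by regions."""
    mask = np.zeros(length, dtype=bool)
    for r in regions:
        mask[r.start - 1 : r.end] = True
    return mask


def mask_to_regions(
    mask: np.ndarray,
    protein_id: str,
    kind: RegionKind,
    min_len: int = 1,
) -> list[Region]:
    """Maximal runs of True in a residue mask, as 1-based regions."""
    mask = np.asarray(mask, dtype=bool)
    regions: list[Region] = []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_len:
            regions.append(Region(protein_id, int(s) + 1, int(e), kind))
    return regions
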