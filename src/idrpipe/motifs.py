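"""Linear-motif scanning and enrichment against a shuffled-composition null.

Short linear motifs (ELM-style) are described as regular expressions over
the amino-acid alphabet.  Scanning is restricted to mostly disordered
proteins (disorder rate above 0.5), reports every match start (overlapping
occurrences included), and summarises counts as densities per 1000
residues.

The null model rebuilds the residue pool of the scanned disordered regions
into synthetic constructs of the same composition — by default 20
constructs of 10,000 residues, i.e. roughly 10x coverage of a typical
pooled disordered proteome slice — and compares the observed motif density
against the per-construct null densities with one- or two-sample t-tests
plus an always-reported empirical (rank) p-value.
"""

from __future__ import annotations

import csv
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .disorder import DisorderProfile
from .io import AMINO_ACIDS, ProteinRecord

DEFAULT_N_CONSTRUCTS = 20
DEFAULT_CONSTRUCT_LENGTH = 10_000


@dataclass(frozen=True)
class MotifClass:
    """A named motif pattern with functional tags (e.g. PPI, nuclear)."""

    id: str
    pattern: str
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("motif class id must be nonempty")
        re.compile(self.pattern)  # raises re.error on a bad pattern

    def compiled(self) -> re.Pattern[str]:
        # lookahead wrapper so overlapping occurrences are all found
        return re.compile(rf"(?=({self.pattern}))")


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    protein_id: str
    start: int   # 1-based inclusive
    end: int     # 1-based inclusive
    matched: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid hit span [{self.start}, {self.end}]")
        if len(self.matched) != self.end - self.start + 1:
            raise ValueError("matched string length disagrees with span")


@dataclass
class NullEnsemble:
    """Shuffled/resampled constructs with the pooled residue composition."""

    constructs: list[str]
    source_composition: Counter
    seed: int
    mode: str  # "permute" or "resample"

    @property
    def n_constructs(self) -> int:
        return len(self.constructs)

    @property
    def construct_length(self) -> int:
        return len(self.constructs[0]) if self.constructs else 0

    @property
    def total_residues(self) -> int:
        return sum(len(c) for c in self.constructs)


@dataclass(frozen=True)
class DensityStat:
    n_hits: int
    n_residues: int

    @property
    def density_per_kaa(self) -> float:
        return 1000.0 * self.n_hits / self.n_residues


def read_motif_classes(path: str | Path) -> list[MotifClass]:
    """Read a motif-class TSV with columns id, pattern, tags (comma-sep)."""
    classes: list[MotifClass] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "id":
                continue
            mid, pattern = row[0], row[1]
            tags = frozenset(t for t in row[2].split(",") if t) if len(row) > 2 else frozenset()
            if mid in seen:
                raise ValueError(f"duplicate motif class id: {mid!r}")
            seen.add(mid)
            classes.append(MotifClass(mid, pattern, tags))
    return classes


def scan_motifs(
    proteins: Sequence[ProteinRecord],
    profiles: Mapping[str, DisorderProfile],
    motif_classes: Sequence[MotifClass],
    require_disordered_fraction: float = 0.0,
    min_disorder_rate: float = 0.5,
) -> list[MotifHit]:
    """Scan mostly disordered proteins for all motif-class occurrences.

    Only proteins with disorder rate strictly above ``min_disorder_rate``
    are scanned (the selection is per protein, not per hit).  Overlapping
    matches at distinct start positions are all reported.  Optionally a hit
    is kept only when at least ``require_disordered_fraction`` of its
    residues score at or above the disorder threshold (default 0: hits are
    not filtered individually).  Output order is (protein, start, motif id).
    """
    if not (0.0 <= require_disordered_fraction <= 1.0):
        raise ValueError("require_disordered_fraction must be in [0, 1]")
    hits: list[MotifHit] = []
    for protein in proteins:
        profile = profiles.get(protein.id)
        if profile is None:
            raise ValueError(f"no disorder profile for protein {protein.id!r}")
        if profile.disorder_rate <= min_disorder_rate:
            continue
        disordered = profile.values >= profile.threshold
        for mc in motif_classes:
            for m in mc.compiled().finditer(protein.sequence):
                matched = m.group(1)
                if not matched:
                    continue
                start = m.start() + 1
                end = m.start() + len(matched)
                if require_disordered_fraction > 0:
                    frac = float(np.mean(disordered[start - 1 : end]))
                    if frac < require_disordered_fraction:
                        continue
                hits.append(MotifHit(mc.id, protein.id, start, end, matched))
    hits.sort(key=lambda h: (h.protein_id, h.start, h.motif_id))
    return hits


def disordered_residue_pool(
    proteins: Sequence[ProteinRecord],
    profiles: Mapping[str, DisorderProfile],
    min_disorder_rate: float = 0.5,
) -> str:
    """Concatenate the disordered residues of mostly disordered proteins.

    Collects every residue with disorder score >= threshold from proteins
    whose overall disorder rate exceeds ``min_disorder_rate``; X residues
    are dropped (excluded from composition-dependent computations).
    """
    parts: list[str] = []
    for protein in proteins:
        profile = profiles.get(protein.id)
        if profile is None:
            raise ValueError(f"no disorder profile for protein {protein.id!r}")
        if profile.disorder_rate <= min_disorder_rate:
            continue
        mask = profile.values >= profile.threshold
        parts.append(
            "".join(aa for aa, keep in zip(protein.sequence, mask) if keep and aa != "X")
        )
    return "".join(parts)


def build_null(
    disordered_residue_pool: str,
    n_constructs: int = DEFAULT_N_CONSTRUCTS,
    construct_length: int = DEFAULT_CONSTRUCT_LENGTH,
    seed: int = 0,
    mode: str | None = None,
) -> NullEnsemble:
    """Build composition-preserving null constructs from a residue pool.

    ``mode="permute"`` is an exact shuffle and requires the total construct
    length to equal the pool size (residue multisets are then conserved
    exactly).  ``mode="resample"`` draws residues i.i.d. from the pool
    composition and supports any coverage (the default 20 x 10,000 gives
    ~10x coverage of a ~20k-residue pool).  When ``mode`` is None, permute
    is chosen iff the lengths match exactly.
    """
    pool = disordered_residue_pool
    if not pool:
        raise ValueError("residue pool is empty")
    if n_constructs < 1 or construct_length < 1:
        raise ValueError("n_constructs and construct_length must be >= 1")
    if len(pool) < 20:
        warnings.warn(
            f"residue pool has only {len(pool)} residues; "
            "composition estimate is unstable"
        )
    total = n_constructs * construct_length
    if mode is None:
        mode = "permute" if total == len(pool) else "resample"
    rng = np.random.default_rng(seed)
    composition = Counter(pool)
    if mode == "permute":
        if total != len(pool):
            raise ValueError(
                f"permute mode needs total construct length == pool size "
                f"({total} != {len(pool)})"
            )
        shuffled = "".join(np.array(list(pool))[rng.permutation(len(pool))])
        constructs = [
            shuffled[i * construct_length : (i + 1) * construct_length]
            for i in range(n_constructs)
        ]
    elif mode == "resample":
        letters = sorted(composition)
        probs = np.array([composition[a] for a in letters], dtype=float)
        probs /= probs.sum()
        draws = rng.choice(len(letters), size=total, p=probs)
        alphabet = np.array(letters)
        flat = "".join(alphabet[draws])
        constructs = [
            flat[i * construct_length : (i + 1) * construct_length]
            for i in range(n_constructs)
        ]
    else:
        raise ValueError(f"unknown null mode {mode!r}")
    return NullEnsemble(constructs, composition, seed, mode)


def count_matches(sequence: str, motif_classes: Sequence[MotifClass]) -> int:
    """Number of motif occurrences (all starts, all classes) in a sequence."""
    return sum(
        1
        for mc in motif_classes
        for m in mc.compiled().finditer(sequence)
        if m.group(1)
    )


def density(n_hits: int | Sequence, n_residues: int) -> DensityStat:
    """Motif density per 1000 residues."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    if not isinstance(n_hits, (int, np.integer)):
        n_hits = len(n_hits)
    return DensityStat(n_hits=int(n_hits), n_residues=int(n_residues))


def null_densities(
    ensemble: NullEnsemble, motif_classes: Sequence[MotifClass]
) -> np.ndarray:
    """Per-construct motif densities (per 1000 aa) of a null ensemble."""
    return np.array(
        [
            density(count_matches(c, motif_classes), len(c)).density_per_kaa
            for c in ensemble.constructs
        ]
    )


def enrichment_test(
    observed_density: float,
    null_densities: Sequence[float],
    mode: str = "one_sample",
    observed_densities: Sequence[float] | None = None,
) -> dict:
    """Test whether the observed motif density exceeds the null.

    ``mode="one_sample"``: one-sample t of the per-construct null densities
    against the observed density treated as fixed.  ``mode="two_sample"``:
    Welch t between per-protein observed densities and per-construct null
    densities.  The empirical rank p-value
    ``(1 + #{null >= observed}) / (1 + #null)`` is always reported and is
    the recommended decision rule when the observed sample is small.
    """
    null = np.asarray(null_densities, dtype=float)
    empirical_p = float((1 + np.sum(null >= observed_density)) / (1 + len(null)))
    out = {"t": np.nan, "df": np.nan, "p": np.nan, "empirical_p": empirical_p}
    if mode == "one_sample":
        if len(null) < 2:
            raise ValueError("one-sample t needs >= 2 null densities")
        if np.ptp(null) == 0.0:
            warnings.warn("constant null densities; falling back to empirical p")
            return out
        res = stats.ttest_1samp(null, observed_density)
        out.update(t=float(res.statistic), df=float(len(null) - 1), p=float(res.pvalue))
    elif mode == "two_sample":
        if observed_densities is None:
            raise ValueError("two-sample mode needs per-protein observed densities")
        obs = np.asarray(observed_densities, dtype=float)
        if len(null) < 2 or len(obs) < 2:
            raise ValueError("two-sample t needs >= 2 values per side")
        if np.ptp(null) == 0.0 and np.ptp(obs) == 0.0:
            warnings.warn("constant samples; falling back to empirical p")
            return out
        res = stats.ttest_ind(obs, null, equal_var=False)
        out.update(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out


def filter_by_tag(
    items: Sequence[MotifClass] | Sequence[MotifHit],
    tag: str,
    motif_classes: Sequence[MotifClass] | None = None,
) -> list:
    """Subset of motif classes (or hits) whose class carries ``tag``.

    Hits do not carry tags themselves, so filtering hits requires the
    class table.  An unknown tag yields an empty subset with a warning.
    """
    if not tag:
        raise ValueError("tag must be nonempty")
    if not items:
        return []
    if isinstance(items[0], MotifClass):
        subset = [mc for mc in items if tag in mc.tags]
        known = set().union(*(mc.tags for mc in items))
    else:
        if motif_classes is None:
            raise ValueError("filtering hits by tag requires motif_classes")
        tagged = {mc.id for mc in motif_classes if tag in mc.tags}
        subset = [h for h in items if h.motif_id in tagged]
        known = set().union(*(mc.tags for mc in motif_classes))
    if tag not in known:
        warnings.warn(f"tag {tag!r} not carried by any motif class")
    return subset
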