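"""Synthetic protein families with known ground truth.

Every pipeline stage can be exercised without downloads: proteins are
assembled block-wise from ordered domains (order-promoting composition)
and disordered linkers (enriched in P, E, S, Q, K; depleted in W, C, F, I,
Y, V), with motif instances, binding regions and variants planted at
recorded coordinates.  Ortholog "alignments" are derived from the
reference by per-column substitution with class-specific probabilities
(star topology — no phylogeny is simulated), with small indels allowed
only outside planted features so coordinate truth stays exact.

Oracle score tracks (0.9 inside a planted region, 0.1 outside, optional
clipped Gaussian jitter) let downstream detectors be tested independently
of the built-in stand-in predictors.

The module also builds backbone coordinates from prescribed phi/psi
torsions (standard bond geometry, trans peptide), so multi-model structure
ensembles with known helix content can be written as PDB.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .conservation import OrthologAlignment
from .disorder import DisorderProfile
from .io import (
    AMINO_ACIDS,
    ProteinRecord,
    Region,
    RegionKind,
    ScoreTrack,
    VariantRecord,
)
from .motifs import MotifHit

# ---------------------------------------------------------------------------
# Compositions (frequencies are data, normalised at use)

#: Disorder-promoting composition: enriched P,E,S,Q,K; depleted W,C,F,I,Y,V.
DISORDER_COMPOSITION: dict[str, float] = {
    "P": 0.10, "E": 0.12, "S": 0.11, "Q": 0.10, "K": 0.10,
    "G": 0.08, "A": 0.07, "R": 0.06, "D": 0.06, "T": 0.05,
    "N": 0.04, "H": 0.03, "L": 0.03, "M": 0.015, "V": 0.015,
    "I": 0.01, "F": 0.01, "Y": 0.005, "C": 0.005, "W": 0.005,
}

#: Order-promoting composition: hydrophobic/aromatic enriched.
ORDER_COMPOSITION: dict[str, float] = {
    "L": 0.11, "V": 0.09, "I": 0.08, "A": 0.08, "F": 0.06,
    "G": 0.06, "T": 0.06, "Y": 0.05, "S": 0.05, "D": 0.04,
    "E": 0.04, "N": 0.04, "K": 0.04, "R": 0.04, "W": 0.03,
    "M": 0.03, "H": 0.03, "Q": 0.03, "C": 0.025, "P": 0.02,
}


def _freq_arrays(comp: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(sorted(comp))
    probs = np.array([comp[a] for a in sorted(comp)], dtype=float)
    return letters, probs / probs.sum()


def draw_sequence(length: int, composition: dict[str, float], rng: np.random.Generator) -> str:
    letters, probs = _freq_arrays(composition)
    return "".join(letters[rng.choice(len(letters), size=length, p=probs)])


# ---------------------------------------------------------------------------
# Configuration and truth containers

@dataclass(frozen=True)
class BlockSpec:
    kind: str      # "ordered" | "idr"
    length: int

    def __post_init__(self) -> None:
        if self.kind not in {"ordered", "idr"}:
            raise ValueError(f"unknown block kind {self.kind!r}")
        if self.length < 1:
            raise ValueError("block length must be >= 1")


@dataclass(frozen=True)
class MotifPlant:
    """A motif class to plant: concrete ``instance`` must match ``pattern``.

    Either ``count`` (exact number across the family) or
    ``density_per_kaa`` (expected plants per 1000 total residues; actual
    count is Poisson) must be given.
    """

    motif_id: str
    pattern: str
    instance: str
    count: int | None = None
    density_per_kaa: float | None = None

    def __post_init__(self) -> None:
        if (self.count is None) == (self.density_per_kaa is None):
            raise ValueError("give exactly one of count or density_per_kaa")
        if not re.fullmatch(self.pattern, self.instance):
            raise ValueError(
                f"instance {self.instance!r} does not match pattern {self.pattern!r}"
            )


@dataclass(frozen=True)
class BindingPlant:
    """A binding region planted inside a disordered linker.

    ``conservation`` names the column class its residues get in derived
    ortholog alignments ("invariant" plants survive the 0.9 sequence-
    conservation filter; "divergent" ones do not).
    """

    length: int = 12
    conservation: str = "invariant"

    def __post_init__(self) -> None:
        if self.length < 8:
            raise ValueError("binding plants must be >= 8 residues")


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_proteins: int = 6
    blocks: tuple[BlockSpec, ...] = (
        BlockSpec("ordered", 120),
        BlockSpec("idr", 220),
        BlockSpec("ordered", 120),
        BlockSpec("idr", 140),
    )
    motif_plants: tuple[MotifPlant, ...] = ()
    binding_plants: tuple[BindingPlant, ...] = (
        BindingPlant(12, "invariant"),
        BindingPlant(12, "divergent"),
    )
    #: region-relative 0-based offsets at which variants are planted into
    #: every conserved ("invariant") binding region
    variant_offsets: tuple[int, ...] = ()
    n_orthologs: int = 23
    column_classes: dict[str, float] = field(
        default_factory=lambda: {"invariant": 0.0, "conserved": 0.03, "divergent": 0.5}
    )
    ordered_class: str = "conserved"
    idr_class: str = "divergent"
    deletion_prob: float = 0.01
    insertion_prob: float = 0.005
    disorder_composition: dict[str, float] = field(
        default_factory=lambda: dict(DISORDER_COMPOSITION)
    )
    order_composition: dict[str, float] = field(
        default_factory=lambda: dict(ORDER_COMPOSITION)
    )

    def __post_init__(self) -> None:
        if self.n_orthologs < 2:
            raise ValueError("n_orthologs must be >= 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        for plant in self.binding_plants:
            if not any(
                b.kind == "idr" and b.length >= plant.length + 4 for b in self.blocks
            ):
                raise ValueError("binding plant does not fit in any disordered block")


@dataclass
class SyntheticTruth:
    """Planted features, keyed by protein id where applicable."""

    idrs: dict[str, list[Region]] = field(default_factory=dict)
    binding: dict[str, list[Region]] = field(default_factory=dict)
    conserved_binding: dict[str, list[Region]] = field(default_factory=dict)
    motif_hits: list[MotifHit] = field(default_factory=list)
    variants: list[VariantRecord] = field(default_factory=list)
    column_classes: dict[str, list[str]] = field(default_factory=dict)
    n_motif_plants: int = 0


# ---------------------------------------------------------------------------
# Family generation

def _rng_for(config: GeneratorConfig, label: str) -> np.random.Generator:
    """Deterministic per-purpose generator derived from the config seed."""
    return np.random.default_rng([config.seed & 0x7FFFFFFF, zlib.crc32(label.encode())])


def generate_family(config: GeneratorConfig) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate a protein family plus the ground truth of every plant.

    Deterministic per seed.  Planted motif instances never overlap each
    other or planted binding regions; every plant is re-verified against
    its pattern after splicing.
    """
    rng = _rng_for(config, "family")
    truth = SyntheticTruth()
    proteins: list[ProteinRecord] = []
    # per-protein free slots in disordered blocks for planting
    idr_blocks: list[tuple[str, int, int]] = []  # (pid, start, end) 1-based

    for k in range(config.n_proteins):
        pid = f"syn{k + 1}"
        seq_parts: list[str] = []
        classes: list[str] = []
        idrs: list[Region] = []
        pos = 1
        for block in config.blocks:
            comp = (
                config.disorder_composition
                if block.kind == "idr"
                else config.order_composition
            )
            seq_parts.append(draw_sequence(block.length, comp, rng))
            cls = config.idr_class if block.kind == "idr" else config.ordered_class
            classes.extend([cls] * block.length)
            if block.kind == "idr":
                idrs.append(Region(pid, pos, pos + block.length - 1, RegionKind.IDR))
                idr_blocks.append((pid, pos, pos + block.length - 1))
            pos += block.length
        sequence = list("".join(seq_parts))

        # binding plants: non-overlapping, inside disordered blocks, margin 2
        planted_binding: list[Region] = []
        conserved: list[Region] = []
        for plant in config.binding_plants:
            placed = False
            hosts = [r for r in idrs if r.length >= plant.length + 4]
            order = rng.permutation(len(hosts))
            for hi in order:
                host = hosts[hi]
                lo = host.start + 2
                hi_start = host.end - 2 - plant.length + 1
                candidates = [
                    s
                    for s in range(lo, hi_start + 1)
                    if all(
                        s + plant.length - 1 < r.start - 1 or s > r.end + 1
                        for r in planted_binding
                    )
                ]
                if not candidates:
                    continue
                s = int(candidates[rng.integers(len(candidates))])
                region = Region(
                    pid, s, s + plant.length - 1, RegionKind.BINDING_CANDIDATE,
                    label=plant.conservation,
                )
                planted_binding.append(region)
                for i in range(s - 1, s + plant.length - 1):
                    classes[i] = plant.conservation
                if plant.conservation == "invariant":
                    conserved.append(
                        Region(pid, s, s + plant.length - 1, RegionKind.CONSERVED_BINDING)
                    )
                placed = True
                break
            if not placed:
                raise ValueError(f"{pid}: no room for binding plant {plant}")

        truth.idrs[pid] = idrs
        truth.binding[pid] = sorted(planted_binding, key=lambda r: r.start)
        truth.conserved_binding[pid] = sorted(conserved, key=lambda r: r.start)
        truth.column_classes[pid] = classes
        proteins.append(ProteinRecord(pid, "".join(sequence)))

    # motif plants (across the family, inside disordered blocks)
    total_len = sum(len(p) for p in proteins)
    seqs = {p.id: list(p.sequence) for p in proteins}
    occupied: dict[str, list[tuple[int, int]]] = {p.id: [] for p in proteins}
    for pid, regions in truth.binding.items():
        occupied[pid].extend((r.start, r.end) for r in regions)

    for plant in config.motif_plants:
        if plant.count is not None:
            n_plant = plant.count
        else:
            n_plant = int(rng.poisson(plant.density_per_kaa * total_len / 1000.0))
        m = len(plant.instance)
        slots = [
            (pid, s)
            for (pid, b_start, b_end) in idr_blocks
            for s in range(b_start, b_end - m + 2)
        ]
        placed = 0
        attempts = 0
        while placed < n_plant:
            attempts += 1
            if attempts > 200 * max(n_plant, 1):
                raise ValueError(
                    f"could not place {n_plant} instances of {plant.motif_id}"
                )
            pid, s = slots[int(rng.integers(len(slots)))]
            e = s + m - 1
            if any(not (e < a - 1 or s > b + 1) for (a, b) in occupied[pid]):
                continue
            seqs[pid][s - 1 : e] = list(plant.instance)
            occupied[pid].append((s, e))
            truth.motif_hits.append(MotifHit(plant.motif_id, pid, s, e, plant.instance))
            placed += 1
        truth.n_motif_plants += placed

    proteins = [
        ProteinRecord(p.id, "".join(seqs[p.id]), p.family, p.group) for p in proteins
    ]
    by_id = {p.id: p for p in proteins}
    for hit in truth.motif_hits:  # consistency assertion for every plant
        segment = by_id[hit.protein_id].sequence[hit.start - 1 : hit.end]
        assert segment == hit.matched, "planted motif was clobbered"
    truth.motif_hits.sort(key=lambda h: (h.protein_id, h.start, h.motif_id))

    # variants planted into conserved binding regions
    for pid, regions in truth.conserved_binding.items():
        for region in regions:
            for off in config.variant_offsets:
                if 0 <= off < region.length:
                    truth.variants.append(
                        VariantRecord(pid, region.start + off, "planted")
                    )
    return proteins, truth


# ---------------------------------------------------------------------------
# Ortholog alignments

def generate_ortholog_alignment(
    protein: ProteinRecord,
    truth: SyntheticTruth,
    config: GeneratorConfig,
    substitution_override: float | None = None,
    replacement: str = "composition",
) -> OrthologAlignment:
    """Derive an ortholog alignment from a reference by column substitution.

    Each non-reference row substitutes residue ``i`` with the probability
    of its column class (0 for invariant columns); replacements are drawn
    from the composition of the residue's block kind (or uniformly when
    ``replacement="uniform"``).  Short indels are introduced only outside
    planted binding/motif features.  ``substitution_override`` forces one
    substitution probability everywhere — with 1.0 this produces the
    composition-preserving column scrambling used to emulate flexible
    (sequence-divergent but still disordered) regions.
    """
    rng = _rng_for(config, f"orthologs:{protein.id}")
    classes = truth.column_classes[protein.id]
    n = len(protein)
    idr_mask = np.zeros(n, dtype=bool)
    for r in truth.idrs.get(protein.id, []):
        idr_mask[r.start - 1 : r.end] = True
    protected = np.zeros(n, dtype=bool)
    for r in truth.binding.get(protein.id, []):
        protected[r.start - 1 : r.end] = True
    for h in truth.motif_hits:
        if h.protein_id == protein.id:
            protected[h.start - 1 : h.end] = True

    dis_letters, dis_probs = _freq_arrays(config.disorder_composition)
    ord_letters, ord_probs = _freq_arrays(config.order_composition)
    uni_letters = np.array(list(AMINO_ACIDS))

    def substitute(i: int) -> str:
        if replacement == "uniform":
            return str(uni_letters[rng.integers(20)])
        if idr_mask[i]:
            return str(dis_letters[rng.choice(len(dis_letters), p=dis_probs)])
        return str(ord_letters[rng.choice(len(ord_letters), p=ord_probs)])

    sub_prob = np.array(
        [
            substitution_override
            if substitution_override is not None
            else config.column_classes[c]
            for c in classes
        ]
    )

    rows: dict[str, list[str]] = {protein.id: list(protein.sequence)}
    insertions: dict[tuple[str, int], str] = {}  # (row_id, after_position0) -> residue
    for k in range(config.n_orthologs - 1):
        rid = f"{protein.id}_orth{k + 1}"
        row = []
        for i in range(n):
            if sub_prob[i] > 0 and rng.random() < sub_prob[i]:
                row.append(substitute(i))
            else:
                row.append(protein.sequence[i])
            if not protected[i] and rng.random() < config.deletion_prob:
                row[-1] = "-"
            if not protected[i] and rng.random() < config.insertion_prob:
                insertions[(rid, i)] = substitute(i)
        rows[rid] = row

    # expand insertion columns (gap everywhere except the inserting row)
    aligned: dict[str, list[str]] = {rid: [] for rid in rows}
    for i in range(n):
        for rid in rows:
            aligned[rid].append(rows[rid][i])
        for (ins_rid, pos), residue in insertions.items():
            if pos == i:
                for rid in rows:
                    aligned[rid].append(residue if rid == ins_rid else "-")
    return OrthologAlignment(
        reference_id=protein.id, rows={rid: "".join(s) for rid, s in aligned.items()}
    )


def truth_profiles_for_alignment(
    alignment: OrthologAlignment,
    reference_track: ScoreTrack,
    threshold: float = 0.5,
) -> dict[str, DisorderProfile]:
    """Oracle disorder profiles for every alignment row.

    Each row residue inherits the reference's truth-track value at its
    column (insertions relative to the reference inherit the preceding
    reference residue's value), so orthologs are disordered exactly where
    the reference is.
    """
    ref_row = alignment.reference_row
    col_value = np.empty(alignment.n_columns)
    pos = 0
    last = 0.1
    for j, c in enumerate(ref_row):
        if c != "-":
            last = reference_track.values[pos]
            pos += 1
        col_value[j] = last
    profiles: dict[str, DisorderProfile] = {}
    for rid, row in alignment.rows.items():
        values = np.array([col_value[j] for j, c in enumerate(row) if c != "-"])
        profiles[rid] = DisorderProfile(
            ScoreTrack(rid, values, source="truth"), threshold=threshold
        )
    return profiles


# ---------------------------------------------------------------------------
# Oracle score tracks

def generate_truth_tracks(
    truth: SyntheticTruth,
    proteins: list[ProteinRecord],
    kind: str = "disorder",
    jitter: float = 0.0,
    seed: int = 0,
    inside: float = 0.9,
    outside: float = 0.1,
) -> dict[str, ScoreTrack]:
    """Oracle tracks: ``inside`` within planted regions, ``outside`` elsewhere.

    ``kind`` selects which planted regions define the high level
    ("disorder" -> IDRs, "binding" -> binding regions).  Gaussian jitter of
    the given sigma (<= 0.05 recommended) is clipped to [0, 1].
    """
    if kind not in {"disorder", "binding"}:
        raise ValueError("kind must be 'disorder' or 'binding'")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    regions_by_pid = truth.idrs if kind == "disorder" else truth.binding
    rng = np.random.default_rng(seed)
    tracks: dict[str, ScoreTrack] = {}
    for protein in proteins:
        values = np.full(len(protein), outside)
        for r in regions_by_pid.get(protein.id, []):
            values[r.start - 1 : r.end] = inside
        if jitter > 0:
            values = np.clip(values + rng.normal(0.0, jitter, len(values)), 0.0, 1.0)
        tracks[protein.id] = ScoreTrack(protein.id, values, source=f"truth-{kind}")
    return tracks


# ---------------------------------------------------------------------------
# Backbone construction from torsions

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_OMEGA_TRANS = 180.0


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom D given A-B-C, bond |CD|, angle B-C-D and dihedral A-B-C-D."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m_hat = np.cross(n_hat, bc_hat)
    d_local = np.array(
        [-bond * np.cos(theta), bond * np.sin(theta) * np.cos(chi),
         bond * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> struc.AtomArray:
    """Backbone (N, CA, C) coordinates realising the given torsions.

    ``phi[0]`` and ``psi[-1]`` are geometrically undefined and ignored.
    Standard bond lengths/angles and trans peptide bonds are used, so
    recomputing torsions from the coordinates returns the inputs.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != psi.shape or phi.ndim != 1 or len(phi) < 2:
        raise ValueError("phi and psi must be equal-length 1-D arrays, n >= 2")
    n_res = len(phi)
    coords = np.empty((3 * n_res, 3))
    # first residue: N at origin, CA on +x, C in the xy-plane
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (_BOND_N_CA, 0.0, 0.0)
    alpha = np.radians(180.0 - _ANGLE_N_CA_C)
    coords[2] = coords[1] + _BOND_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[3 * i - 3], coords[3 * i - 2], coords[3 * i - 1]
        n_i = _place_atom(n_prev, ca_prev, c_prev, _BOND_C_N, _ANGLE_CA_C_N, psi[i - 1])
        ca_i = _place_atom(ca_prev, c_prev, n_i, _BOND_N_CA, _ANGLE_C_N_CA, _OMEGA_TRANS)
        c_i = _place_atom(c_prev, n_i, ca_i, _BOND_CA_C, _ANGLE_N_CA_C, phi[i])
        coords[3 * i : 3 * i + 3] = (n_i, ca_i, c_i)

    atoms = struc.AtomArray(3 * n_res)
    atoms.coord = coords
    atoms.chain_id = np.full(3 * n_res, "A")
    atoms.res_id = np.repeat(np.arange(1, n_res + 1), 3)
    atoms.res_name = np.full(3 * n_res, "ALA")
    atoms.atom_name = np.tile(["N", "CA", "C"], n_res)
    atoms.element = np.tile(["N", "C", "C"], n_res)
    atoms.hetero = np.zeros(3 * n_res, dtype=bool)
    return atoms


def write_torsion_ensemble(
    frames: list[tuple[np.ndarray, np.ndarray]], path: str | Path
) -> None:
    """Write a multi-model PDB whose model k realises frames[k] = (phi, psi)."""
    if not frames:
        raise ValueError("need at least one frame")
    stack = struc.stack([build_backbone(phi, psi) for phi, psi in frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
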