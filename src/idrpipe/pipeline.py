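"""End-to-end orchestration: disorder -> LCR -> motifs (+null) ->
conservation -> binding -> variant mapping, from one declarative config.

The run report is a plain JSON-serialisable dict (written with sorted keys,
so reruns under the same config and seed are byte-stable).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import binding as bindmod
from . import conservation as consmod
from . import disorder as dismod
from . import lcr as lcrmod
from . import motifs as motmod
from .io import (
    ProteinRecord,
    read_fasta,
    read_score_tracks,
    read_variants,
    write_regions_bed,
    write_regions_tsv,
)

logger = logging.getLogger("idrpipe")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with the standard defaults.

    ``predictor`` is "standin" (built-in composition predictors) or
    "external" (per-residue tracks read from TSV via ``disorder_tracks`` /
    ``binding_tracks``).  ``alignments`` maps protein id -> aligned FASTA
    path for the conservation stage.  A seed is mandatory whenever the
    shuffled null is enabled.
    """

    fasta: str
    out_dir: str
    predictor: str = "standin"
    disorder_tracks: str | None = None
    binding_tracks: str | None = None
    motif_classes: str | None = None
    variants: str | None = None
    alignments: dict[str, str] = field(default_factory=dict)

    disorder_threshold: float = 0.5
    min_disorder_rate: float = 0.5
    idr_length_cutoff: int = 80
    min_binding_len: int = 8
    seq_cons_threshold: float = 0.9
    dis_cons_threshold: float = 0.75
    conservation_window: int = 3
    alpha: float = 0.05

    null_enabled: bool = True
    n_constructs: int = 20
    construct_length: int = 10_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.predictor not in {"standin", "external"}:
            raise ValueError("predictor must be 'standin' or 'external'")
        if self.null_enabled and self.motif_classes and self.seed is None:
            raise ValueError("a seed is mandatory when the shuffled null is enabled")
        for name, value, lo, hi in [
            ("disorder_threshold", self.disorder_threshold, 0, 1),
            ("seq_cons_threshold", self.seq_cons_threshold, 0, 1),
            ("dis_cons_threshold", self.dis_cons_threshold, 0, 1),
            ("alpha", self.alpha, 0, 1),
        ]:
            if not (lo <= value <= hi):
                raise ValueError(f"{name} must be in [{lo}, {hi}]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _regions_json(regions) -> list[dict]:
    return [
        {"protein_id": r.protein_id, "start": r.start, "end": r.end,
         "kind": r.kind.value}
        for r in regions
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables, BED files and a JSON report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: v for k, v in dataclasses.asdict(config).items()}}

    proteins = read_fasta(config.fasta)
    logger.info("read %d proteins from %s", len(proteins), config.fasta)

    # --- disorder ---------------------------------------------------------
    if config.predictor == "external":
        if not config.disorder_tracks:
            raise ValueError("external predictor mode needs disorder_tracks")
        raw = read_score_tracks(config.disorder_tracks, proteins, source="external")
        profiles = {
            pid: dismod.DisorderProfile(track, config.disorder_threshold)
            for pid, track in raw.items()
        }
    else:
        profiles = {
            p.id: dismod.predict_disorder_standin(
                p, threshold=config.disorder_threshold
            )
            for p in proteins
        }
    missing = [p.id for p in proteins if p.id not in profiles]
    if missing:
        raise ValueError(f"disorder stage: no track for proteins {missing}")

    summaries = [
        dismod.summarize_disorder(profiles[p.id], cutoffs=(config.idr_length_cutoff,))
        for p in proteins
    ]
    all_idrs = [r for s in summaries for r in s.idr_regions]
    write_regions_bed(all_idrs, out / "idrs.bed")
    report["disorder"] = {
        s.protein_id: {
            "disorder_rate": s.disorder_rate,
            "longest_idr": s.longest_idr,
            "n_idrs": len(s.idr_regions),
            f"has_idr_gt_{config.idr_length_cutoff}": s.has_idr_gt[
                config.idr_length_cutoff
            ],
        }
        for s in summaries
    }
    if any(p.family for p in proteins):
        table = dismod.family_disorder_table(
            proteins, summaries, cutoffs=(config.idr_length_cutoff,)
        )
        table.to_csv(out / "family_disorder.tsv", sep="\t", index=False)
        report["family_disorder"] = table.to_dict(orient="records")

    # --- LCR / homorepeats ------------------------------------------------
    params = lcrmod.LcrParams()
    lcrs, repeats = [], []
    for p in proteins:
        if len(p) >= params.window:
            lcrs.extend(lcrmod.detect_lcr(p, params))
        repeats.extend(lcrmod.detect_homorepeats(p, params.min_homorepeat))
    write_regions_tsv(lcrs + repeats, out / "lcr.tsv")
    report["lcr"] = {
        "n_lcrs": len(lcrs),
        "n_homorepeats": len(repeats),
        "idr_overlap": lcrmod.overlap_stats(lcrs, all_idrs),
    }

    # --- motifs and null --------------------------------------------------
    if config.motif_classes:
        classes = motmod.read_motif_classes(config.motif_classes)
        hits = motmod.scan_motifs(
            proteins, profiles, classes, min_disorder_rate=config.min_disorder_rate
        )
        scanned = [
            p for p in proteins
            if profiles[p.id].disorder_rate > config.min_disorder_rate
        ]
        n_res = sum(len(p) for p in scanned)
        report["motifs"] = {
            "n_classes": len(classes),
            "n_scanned_proteins": len(scanned),
            "n_hits": len(hits),
        }
        if n_res:
            obs = motmod.density(len(hits), n_res)
            report["motifs"]["density_per_kaa"] = obs.density_per_kaa
            if config.null_enabled:
                pool = motmod.disordered_residue_pool(
                    proteins, profiles, config.min_disorder_rate
                )
                ensemble = motmod.build_null(
                    pool,
                    n_constructs=config.n_constructs,
                    construct_length=config.construct_length,
                    seed=config.seed,
                )
                nulls = motmod.null_densities(ensemble, classes)
                test = motmod.enrichment_test(obs.density_per_kaa, nulls)
                report["motifs"]["null"] = {
                    "mode": ensemble.mode,
                    "n_constructs": ensemble.n_constructs,
                    "construct_length": ensemble.construct_length,
                    "mean_density_per_kaa": float(np.mean(nulls)),
                    "test": {k: (None if np.isnan(v) else v) for k, v in test.items()},
                    "significant": bool(test["empirical_p"] <= config.alpha),
                }

    # --- conservation + binding ------------------------------------------
    if config.predictor == "external" and config.binding_tracks:
        raw = read_score_tracks(config.binding_tracks, proteins, source="external")
        binding_profiles = {
            pid: bindmod.BindingProfile(track, config.disorder_threshold)
            for pid, track in raw.items()
        }
    else:
        binding_profiles = {
            p.id: bindmod.predict_binding_standin(p, profiles[p.id]) for p in proteins
        }

    variants = (
        read_variants(config.variants, proteins) if config.variants else []
    )
    by_id = {p.id: p for p in proteins}
    binding_report: dict = {}
    all_conserved = []
    for pid, aln_path in sorted(config.alignments.items()):
        if pid not in by_id:
            raise ValueError(f"alignment given for unknown protein {pid!r}")
        alignment = consmod.read_alignment(aln_path, reference_id=pid)
        row_profiles = {
            rid: (
                profiles[rid]
                if rid in profiles
                else dismod.predict_disorder_standin(
                    ProteinRecord(rid, alignment.rows[rid].replace("-", "")),
                    threshold=config.disorder_threshold,
                )
            )
            for rid in alignment.rows
        }
        track = consmod.conservation_track(
            alignment, row_profiles, window=config.conservation_window
        )
        labels = consmod.classify_disorder_conservation(
            track, profiles[pid],
            dis_thr=config.dis_cons_threshold, seq_thr=config.seq_cons_threshold,
        )
        summary = next(s for s in summaries if s.protein_id == pid)
        idr_constrained = {
            f"{r.start}-{r.end}": consmod.constrained_percent(labels, r)
            for r in summary.idr_regions
        }
        candidates = bindmod.candidate_binding_regions(
            binding_profiles[pid], min_len=config.min_binding_len
        )
        conserved = bindmod.conserved_binding_regions(
            candidates, track,
            seq_thr=config.seq_cons_threshold,
            min_conserved_run=config.min_binding_len,
        )
        all_conserved.extend(conserved)
        binding_report[pid] = {
            "n_candidates": len(candidates),
            "n_conserved": len(conserved),
            "conserved_regions": _regions_json([c.region for c in conserved]),
            "idr_constrained_percent": idr_constrained,
        }
    if all_conserved:
        write_regions_bed([c.region for c in all_conserved], out / "conserved_binding.bed")
    if binding_report:
        report["binding"] = binding_report

    if variants:
        table, unmapped = bindmod.map_variants(all_conserved, variants)
        table.to_csv(out / "variant_map.tsv", sep="\t", index=False)
        report["variants"] = {
            "n_variants": len(variants),
            "n_mapped": len(variants) - len(unmapped),
            "n_unmapped": len(unmapped),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    logger.info("report written to %s", out / "report.json")
    return report
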