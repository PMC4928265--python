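"""Per-residue disorder profiling, IDR segmentation and family summaries.

The built-in predictor is a transparent stand-in for a full disorder
predictor: a per-residue composition propensity scale, smoothed by a
centred moving average and squashed through a logistic to [0, 1].  It is
adequate for sequences whose ordered and disordered segments differ in
composition (as the synthetic generator guarantees); externally computed
tracks (e.g. IUPred output re-formatted as TSV) can be supplied instead via
:func:`idrpipe.io.read_score_tracks`.

A residue is called disordered when its score is at least the profile
threshold (default 0.5); the disorder rate of a protein is the fraction of
such residues, and IDRs are the maximal runs of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import AMINO_ACIDS, ProteinRecord, Region, RegionKind, ScoreTrack

#: TOP-IDP-style disorder propensity scale (higher = more disorder-promoting).
#: Proline, glutamate, lysine, serine and glutamine promote disorder;
#: tryptophan, phenylalanine, isoleucine, tyrosine and valine promote order.
TOP_IDP_SCALE: dict[str, float] = {
    "W": -0.884, "F": -0.697, "Y": -0.510, "I": -0.486, "M": -0.397,
    "L": -0.326, "V": -0.121, "N": 0.007, "C": -0.020, "T": 0.059,
    "A": 0.060, "G": 0.166, "R": 0.180, "D": 0.192, "H": 0.303,
    "Q": 0.318, "K": 0.586, "S": 0.341, "E": 0.736, "P": 0.987,
}

DEFAULT_WINDOW = 21
DEFAULT_SLOPE = 4.0
DISORDER_THRESHOLD = 0.5


@dataclass
class DisorderProfile:
    """Per-residue disorder propensity in [0, 1] plus the calling threshold."""

    track: ScoreTrack
    threshold: float = DISORDER_THRESHOLD

    def __post_init__(self) -> None:
        v = self.track.values
        if np.any((v < 0) | (v > 1)):
            raise ValueError(f"{self.track.protein_id}: disorder scores outside [0, 1]")

    @property
    def protein_id(self) -> str:
        return self.track.protein_id

    @property
    def values(self) -> np.ndarray:
        return self.track.values

    @property
    def disorder_rate(self) -> float:
        """Fraction of residues with score >= threshold."""
        return float(np.mean(self.track.values >= self.threshold))

    def __len__(self) -> int:
        return len(self.track)


@dataclass
class DisorderSummary:
    protein_id: str
    disorder_rate: float
    idr_regions: list[Region]
    longest_idr: int
    has_idr_gt: dict[int, bool] = field(default_factory=dict)


def predict_disorder_standin(
    protein: ProteinRecord,
    scale_table: dict[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    logistic_midpoint: float | None = None,
    logistic_slope: float = DEFAULT_SLOPE,
    threshold: float = DISORDER_THRESHOLD,
) -> DisorderProfile:
    """Composition-scale disorder prediction.

    Each residue's propensity is the centred moving average (window
    truncated at the termini) of the scale values of the standard residues
    in its window, mapped through ``1 / (1 + exp(-slope * (avg - midpoint)))``.
    ``X`` residues contribute nothing to the averages.  The midpoint
    defaults to the unweighted mean of the scale, so an "average"
    composition scores 0.5.
    """
    scale = TOP_IDP_SCALE if scale_table is None else scale_table
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    missing = sorted({aa for aa in protein.sequence if aa != "X"} - set(scale))
    if missing:
        raise ValueError(f"{protein.id}: residues absent from scale table: {missing}")
    midpoint = float(np.mean(list(scale.values()))) if logistic_midpoint is None else logistic_midpoint

    n = len(protein)
    raw = np.array([scale.get(aa, np.nan) for aa in protein.sequence])
    known = np.isfinite(raw)
    half = window // 2
    # cumulative-sum moving average over standard residues only
    csum = np.concatenate(([0.0], np.cumsum(np.where(known, raw, 0.0))))
    ccnt = np.concatenate(([0], np.cumsum(known.astype(int))))
    avg = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        cnt = ccnt[hi] - ccnt[lo]
        avg[i] = (csum[hi] - csum[lo]) / cnt if cnt else midpoint
    values = 1.0 / (1.0 + np.exp(-logistic_slope * (avg - midpoint)))
    track = ScoreTrack(protein_id=protein.id, values=values, source="standin")
    return DisorderProfile(track=track, threshold=threshold)


def segment_idrs(profile: DisorderProfile) -> list[Region]:
    """Maximal runs of residues with score >= threshold, as IDR regions."""
    from .io import mask_to_regions

    mask = profile.values >= profile.threshold
    return mask_to_regions(mask, profile.protein_id, RegionKind.IDR)


def summarize_disorder(
    profile: DisorderProfile, cutoffs: tuple[int, ...] = (80,)
) -> DisorderSummary:
    idrs = segment_idrs(profile)
    longest = max((r.length for r in idrs), default=0)
    return DisorderSummary(
        protein_id=profile.protein_id,
        disorder_rate=profile.disorder_rate,
        idr_regions=idrs,
        longest_idr=longest,
        has_idr_gt={c: longest > c for c in cutoffs},
    )


def family_disorder_table(
    proteins: list[ProteinRecord],
    summaries: list[DisorderSummary],
    cutoffs: tuple[int, ...] = (80,),
) -> pd.DataFrame:
    """Per-family mean disorder rate and fraction of proteins with long IDRs.

    "Long" reads strictly: an IDR of exactly the cutoff length does not
    count.  Proteins without a family label are excluded with a warning.
    """
    fam = {p.id: p.family for p in proteins}
    rows = []
    for s in summaries:
        family = fam.get(s.protein_id)
        if family is None:
            warnings.warn(f"protein {s.protein_id} has no family label; excluded")
            continue
        row = {"family": family, "disorder_rate": s.disorder_rate}
        for c in cutoffs:
            row[f"idr_gt_{c}"] = s.longest_idr > c
        rows.append(row)
    if not rows:
        raise ValueError("no labelled proteins to summarise")
    df = pd.DataFrame(rows)
    agg = {"disorder_rate": "mean"}
    agg.update({f"idr_gt_{c}": "mean" for c in cutoffs})
    table = df.groupby("family").agg(**{
        "mean_disorder_rate": ("disorder_rate", "mean"),
        **{f"frac_idr_gt_{c}": (f"idr_gt_{c}", "mean") for c in cutoffs},
        "n": ("disorder_rate", "size"),
    })
    return table.reset_index()


def welch_t_test(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> dict:
    """Two-sample t-test with explicit handling of zero-variance cells.

    When both samples have zero variance the t statistic is undefined; if
    the means differ we report the difference as overwhelmingly significant
    (p recorded below 1e-12) rather than dividing by zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(len(a) + len(b) - 2), "p": 1.0,
                    "note": "zero variance, equal means"}
        return {"t": float("inf") if a.mean() > b.mean() else float("-inf"),
                "df": float(len(a) + len(b) - 2), "p": 1e-13,
                "note": "zero variance, means differ"}
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    df = getattr(res, "df", float(len(a) + len(b) - 2))
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue),
            "note": ""}


def compare_groups(
    length_table: pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = False,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Pairwise between-family t-tests of protein length within each group.

    ``length_table`` needs columns ``family``, ``group``, ``length``.  The
    default is Welch's unequal-variance test.  Cells with fewer than two
    observations are reported as untestable rather than silently dropped.
    Raw p-values are reported; optional Bonferroni correction multiplies by
    the number of comparisons within each group.
    """
    required = {"family", "group", "length"}
    if not required.issubset(length_table.columns):
        raise ValueError(f"length table must have columns {sorted(required)}")
    rows = []
    for group, sub in length_table.groupby("group"):
        fams = sorted(sub["family"].unique())
        pairs = [(fa, fb) for i, fa in enumerate(fams) for fb in fams[i + 1:]]
        for fa, fb in pairs:
            xa = sub.loc[sub["family"] == fa, "length"].to_numpy(dtype=float)
            xb = sub.loc[sub["family"] == fb, "length"].to_numpy(dtype=float)
            base = {
                "group": group, "family_a": fa, "family_b": fb,
                "mean_a": xa.mean() if len(xa) else np.nan,
                "mean_b": xb.mean() if len(xb) else np.nan,
                "sd_a": xa.std(ddof=1) if len(xa) > 1 else np.nan,
                "sd_b": xb.std(ddof=1) if len(xb) > 1 else np.nan,
                "n_a": len(xa), "n_b": len(xb),
            }
            if len(xa) < 2 or len(xb) < 2:
                rows.append({**base, "t": np.nan, "df": np.nan, "p": np.nan,
                             "significant": False, "untestable": True, "note": "n < 2"})
                continue
            res = welch_t_test(xa, xb, equal_var=equal_var)
            p = res["p"]
            if bonferroni:
                p = min(1.0, p * len(pairs))
            rows.append({**base, "t": res["t"], "df": res["df"], "p": p,
                         "significant": bool(p < alpha), "untestable": False,
                         "note": res["note"]})
    return pd.DataFrame(rows)
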