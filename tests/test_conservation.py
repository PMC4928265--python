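import math

import numpy as np
import pytest

from idrpipe.conservation import (
    DisorderConservationClass as C,
    OrthologAlignment,
    classify_disorder_conservation,
    column_jsd,
    conservation_track,
    constrained_percent,
    read_alignment,
    smooth,
    uniform_background,
)
from idrpipe.io import ProteinRecord, Region, RegionKind, ScoreTrack
from idrpipe.synthetic import (
    GeneratorConfig,
    generate_family,
    generate_ortholog_alignment,
    generate_truth_tracks,
    truth_profiles_for_alignment,
)

from conftest import profile_from


def manual_jsd_bits(p, q):
    """Independent evaluation of 0.5*KL(p||m) + 0.5*KL(q||m), base 2."""
    m = 0.5 * (np.asarray(p) + np.asarray(q))

    def kl(a, b):
        return sum(x * math.log2(x / y) for x, y in zip(a, b) if x > 0)

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


class TestColumnJsd:
    def test_background_like_column_scores_zero(self):
        # 20 residues, one of each: empirical distribution == uniform background
        assert column_jsd(list("ACDEFGHIKLMNPQRSTVWY")) == pytest.approx(0.0)

    def test_invariant_column_matches_formula(self):
        # oracle: JSD of a delta against uniform, normalised by itself -> 1
        bg = uniform_background()
        delta = np.zeros(20)
        delta[0] = 1.0
        raw = manual_jsd_bits(delta, bg)
        assert column_jsd(["A"] * 23) == pytest.approx(raw / raw) == 1.0

    def test_mixed_column_matches_formula(self):
        col = ["A"] * 12 + ["S"] * 11
        bg = uniform_background()
        p = np.zeros(20)
        p[0] = 12 / 23          # A
        p[15] = 11 / 23         # S
        delta = np.zeros(20)
        delta[0] = 1.0
        expected = manual_jsd_bits(p, bg) / manual_jsd_bits(delta, bg)
        assert column_jsd(col) == pytest.approx(expected)

    def test_majority_gap_column_scores_zero(self):
        assert column_jsd(["A", "A", "-", "-", "-"]) == 0.0

    def test_all_gap_column_errors(self):
        with pytest.raises(ValueError):
            column_jsd(["-", "-"])


class TestConservationTrack:
    def _identical_alignment(self, n_rows=5, seq="PEQSKPEQSK"):
        rows = {f"r{i}": seq for i in range(n_rows)}
        rows["ref"] = seq
        return OrthologAlignment("ref", rows)

    def _profiles(self, alignment, value=0.9):
        return {
            rid: profile_from([value] * len(row.replace("-", "")), rid)
            for rid, row in alignment.rows.items()
        }

    def test_identical_disordered_alignment_is_maximal(self):
        aln = self._identical_alignment()
        track = conservation_track(aln, self._profiles(aln))
        assert np.allclose(track.seq_cons, 1.0)
        assert np.allclose(track.dis_cons, 1.0)

    def test_reference_gap_columns_dropped(self):
        rows = {"ref": "PE-QS", "a": "PEKQS", "b": "PEKQS"}
        aln = OrthologAlignment("ref", rows)
        track = conservation_track(aln, self._profiles(aln))
        assert len(track) == 4  # ungapped reference length
        assert list(track.column_index) == [0, 1, 3, 4]

    def test_missing_reference_row_errors(self):
        with pytest.raises(ValueError, match="reference"):
            OrthologAlignment("nope", {"a": "PE", "b": "PE"})

    def test_row_reordering_invariance(self):
        rows = {"ref": "PEQSKA", "a": "PEQSKV", "b": "PAQSKA", "c": "PEQWKA"}
        aln1 = OrthologAlignment("ref", rows)
        aln2 = OrthologAlignment("ref", dict(reversed(list(rows.items()))))
        profs = self._profiles(aln1)
        t1 = conservation_track(aln1, profs)
        t2 = conservation_track(aln2, profs)
        assert np.allclose(t1.seq_cons, t2.seq_cons)
        assert np.allclose(t1.dis_cons, t2.dis_cons)

    def test_duplicate_row_never_decreases_seq_cons(self, rng):
        seq = "PEQSKADGRT"
        rows = {"ref": seq}
        for i in range(6):
            mutated = list(seq)
            for j in range(len(seq)):
                if rng.random() < 0.3:
                    mutated[j] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
            rows[f"r{i}"] = "".join(mutated)
        base = OrthologAlignment("ref", rows)
        dup = OrthologAlignment("ref", {**rows, "ref2": seq})
        profs_base = self._profiles(base)
        profs_dup = self._profiles(dup)
        t_base = conservation_track(base, profs_base)
        t_dup = conservation_track(dup, profs_dup)
        assert np.all(t_dup.seq_cons >= t_base.seq_cons - 1e-12)

    def test_planted_conserved_columns_outrank_divergent(self, small_family, truth_tracks):
        config, proteins, truth = small_family
        disorder_tracks, _ = truth_tracks
        p = proteins[0]
        aln = generate_ortholog_alignment(p, truth, config)
        profiles = truth_profiles_for_alignment(aln, disorder_tracks[p.id])
        track = conservation_track(aln, profiles)
        classes = truth.column_classes[p.id]
        invariant = [i for i, c in enumerate(classes) if c == "invariant"]
        divergent = [i for i, c in enumerate(classes) if c == "divergent"]
        assert track.seq_cons[invariant].mean() > track.seq_cons[divergent].mean()
        # high-conservation columns beat divergent ones almost everywhere
        frac = np.mean(
            track.seq_cons[invariant][:, None] > track.seq_cons[divergent][None, :]
        )
        assert frac >= 0.99


class TestClassification:
    def test_identical_fully_disordered_alignment_all_constrained(self):
        rows = {f"r{i}": "PEQSKPEQSK" for i in range(23)}
        rows["ref"] = "PEQSKPEQSK"
        aln = OrthologAlignment("ref", rows)
        profiles = {
            rid: profile_from([0.9] * 10, rid) for rid in rows
        }
        track = conservation_track(aln, profiles)
        labels = classify_disorder_conservation(track, profiles["ref"])
        assert all(l is C.CONSTRAINED_DISORDER for l in labels)

    def test_ordered_reference_residue_wins(self):
        rows = {f"r{i}": "PEQSK" for i in range(3)}
        rows["ref"] = "PEQSK"
        aln = OrthologAlignment("ref", rows)
        profiles = {rid: profile_from([0.9] * 5, rid) for rid in rows}
        track = conservation_track(aln, profiles)
        ref = profile_from([0.9, 0.9, 0.1, 0.9, 0.9], "ref")
        labels = classify_disorder_conservation(track, ref)
        assert labels[2] is C.ORDERED
        assert labels[0] is C.CONSTRAINED_DISORDER

    def test_scrambled_columns_read_flexible(self, small_family, truth_tracks):
        config, proteins, truth = small_family
        disorder_tracks, _ = truth_tracks
        p = proteins[0]
        aln = generate_ortholog_alignment(
            p, truth, config, substitution_override=1.0
        )
        profiles = truth_profiles_for_alignment(aln, disorder_tracks[p.id])
        track = conservation_track(aln, profiles)
        ref_profile = profile_from(disorder_tracks[p.id].values, p.id)
        labels = classify_disorder_conservation(track, ref_profile)
        disordered_idx = [
            i for i in range(len(p)) if disorder_tracks[p.id].values[i] >= 0.5
        ]
        flex = sum(
            1 for i in disordered_idx if labels[i] is C.FLEXIBLE_DISORDER
        )
        assert flex / len(disordered_idx) >= 0.95

    def test_constrained_percent_boundaries(self):
        labels = [C.CONSTRAINED_DISORDER] * 10
        region = Region("ref", 1, 10, RegionKind.IDR)
        assert constrained_percent(labels, region) == 100.0
        labels = [C.CONSTRAINED_DISORDER] * 5 + [C.FLEXIBLE_DISORDER] * 5
        assert constrained_percent(labels, region) == 50.0

    def test_monotone_in_both_thresholds(self, small_family, truth_tracks):
        config, proteins, truth = small_family
        disorder_tracks, _ = truth_tracks
        p = proteins[0]
        aln = generate_ortholog_alignment(p, truth, config)
        profiles = truth_profiles_for_alignment(aln, disorder_tracks[p.id])
        track = conservation_track(aln, profiles)
        ref_profile = profile_from(disorder_tracks[p.id].values, p.id)
        region = truth.idrs[p.id][0]
        percents_seq = []
        for seq_thr in (0.5, 0.7, 0.9, 0.99):
            labels = classify_disorder_conservation(track, ref_profile, seq_thr=seq_thr)
            percents_seq.append(constrained_percent(labels, region))
        assert percents_seq == sorted(percents_seq, reverse=True)
        percents_dis = []
        for dis_thr in (0.3, 0.6, 0.9):
            labels = classify_disorder_conservation(track, ref_profile, dis_thr=dis_thr)
            percents_dis.append(constrained_percent(labels, region))
        assert percents_dis == sorted(percents_dis, reverse=True)


class TestAlignmentIo:
    def test_read_aligned_fasta(self, tmp_path):
        f = tmp_path / "aln.afa"
        f.write_text(">ref\nPE-QS\n>a\nPEKQS\n")
        aln = read_alignment(f, "ref")
        assert aln.n_rows == 2 and aln.n_columns == 5

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            OrthologAlignment("a", {"a": "PEQ", "b": "PE"})


def test_smooth_is_centred_window_mean():
    values = np.array([0.0, 1.0, 0.0, 1.0, 1.0])
    out = smooth(values, 3)
    assert out == pytest.approx([0.5, 1 / 3, 2 / 3, 2 / 3, 1.0])
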