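import math
import re
from collections import Counter

import numpy as np
import pytest

from idrpipe.io import ProteinRecord, ScoreTrack
from idrpipe.disorder import DisorderProfile
from idrpipe.motifs import (
    MotifClass,
    build_null,
    count_matches,
    density,
    disordered_residue_pool,
    enrichment_test,
    filter_by_tag,
    null_densities,
    scan_motifs,
)

from conftest import profile_from, random_sequence


def brute_force_scan(sequence: str, pattern: str) -> list[tuple[int, int]]:
    """Try an anchored match at every start position (independent oracle)."""
    compiled = re.compile(pattern)
    hits = []
    for i in range(len(sequence)):
        m = compiled.match(sequence, i)
        if m and m.end() > m.start():
            hits.append((i + 1, m.end()))
    return hits


def all_disordered(protein: ProteinRecord) -> DisorderProfile:
    return profile_from([0.9] * len(protein), protein.id)


class TestScan:
    def test_overlapping_occurrences_both_reported(self):
        protein = ProteinRecord("p", "QAQAQ")
        hits = scan_motifs([protein], {"p": all_disordered(protein)},
                           [MotifClass("m", "Q.Q")])
        assert [(h.start, h.end) for h in hits] == [(1, 3), (3, 5)]
        assert all(h.matched == "QAQ" for h in hits)

    def test_mostly_ordered_protein_contributes_nothing(self):
        protein = ProteinRecord("p", "QAQAQQAQAQ")
        profile = profile_from([0.9] * 4 + [0.1] * 6, "p")  # rate 0.4
        hits = scan_motifs([protein], {"p": profile}, [MotifClass("m", "Q.Q")])
        assert hits == []

    def test_rate_exactly_half_is_excluded(self):
        # selection requires disorder rate strictly above 0.5
        protein = ProteinRecord("p", "QAQAQAQAQA")
        profile = profile_from([0.9] * 5 + [0.1] * 5, "p")
        assert scan_motifs([protein], {"p": profile}, [MotifClass("m", "Q.Q")]) == []

    def test_missing_profile_errors(self):
        with pytest.raises(ValueError, match="profile"):
            scan_motifs([ProteinRecord("p", "MK")], {}, [MotifClass("m", "M")])

    def test_matches_brute_force_on_random_sequences(self, rng):
        patterns = ["Q.Q", "K{2,3}", "[ED][ED]", "W.C"]
        for _ in range(60):
            seq = random_sequence(rng, 120)
            protein = ProteinRecord("p", seq)
            profiles = {"p": all_disordered(protein)}
            for pat in patterns:
                hits = scan_motifs([protein], profiles, [MotifClass("m", pat)])
                assert [(h.start, h.end) for h in hits] == brute_force_scan(seq, pat)

    def test_planted_density_recovered_exactly(self, small_family, truth_tracks):
        config, proteins, truth = small_family
        disorder_tracks, _ = truth_tracks
        profiles = {
            p.id: profile_from(disorder_tracks[p.id].values, p.id) for p in proteins
        }
        # planted instances use residues absent from the disordered background,
        # so every truth hit is found and no spurious ones appear
        hits = scan_motifs(proteins, profiles, [MotifClass("WIN_LIKE", "WCW[DE]W")],
                           min_disorder_rate=0.0)
        got = {(h.protein_id, h.start, h.end) for h in hits}
        expected = {(h.protein_id, h.start, h.end) for h in truth.motif_hits}
        assert got == expected
        n_res = sum(len(p) for p in proteins)
        stat = density(len(hits), n_res)
        assert stat.density_per_kaa == pytest.approx(1000 * len(expected) / n_res)


class TestNullEnsemble:
    def test_permute_mode_conserves_multiset(self):
        pool = "AACD"
        ens = build_null(pool, 1, 4, seed=3, mode="permute")
        assert ens.mode == "permute"
        assert Counter(ens.constructs[0]) == Counter(pool)

    def test_permute_multiset_at_scale(self, rng):
        pool = random_sequence(rng, 2000)
        ens = build_null(pool, 4, 500, seed=9, mode="permute")
        assert Counter("".join(ens.constructs)) == Counter(pool)

    def test_same_seed_is_bit_identical(self, rng):
        pool = random_sequence(rng, 3000)
        a = build_null(pool, 5, 1000, seed=11)
        b = build_null(pool, 5, 1000, seed=11)
        assert a.constructs == b.constructs
        assert build_null(pool, 5, 1000, seed=12).constructs != a.constructs

    def test_default_geometry(self, rng):
        pool = random_sequence(rng, 5000)
        ens = build_null(pool, seed=0)
        assert ens.n_constructs == 20
        assert ens.construct_length == 10_000
        assert ens.mode == "resample"

    def test_tiny_pool_warns(self):
        with pytest.warns(UserWarning, match="unstable"):
            build_null("ACDEFG", 1, 6, seed=0)

    def test_resample_composition_tracks_pool(self, rng):
        # biased pool; construct frequencies within 3 binomial SE per residue
        pool = "".join(
            np.array(list("AAAAAQQQKE"))[rng.integers(0, 10, size=4000)]
        )
        ens = build_null(pool, 5, 2000, seed=21, mode="resample")
        total = 10_000
        pool_freq = Counter(pool)
        got = Counter("".join(ens.constructs))
        for aa, count in pool_freq.items():
            p = count / len(pool)
            se = math.sqrt(p * (1 - p) * total)
            assert abs(got[aa] - p * total) <= 3 * se


class TestDensity:
    def test_paper_scale_arithmetic(self):
        assert density(50, 25_000).density_per_kaa == pytest.approx(2.0)

    def test_zero_hits(self):
        assert density(0, 1000).density_per_kaa == 0.0

    def test_closed_form(self, rng):
        for _ in range(20):
            h, n = int(rng.integers(0, 500)), int(rng.integers(1, 100_000))
            assert density(h, n).density_per_kaa == pytest.approx(1000 * h / n)

    def test_zero_residues_errors(self):
        with pytest.raises(ValueError):
            density(1, 0)


class TestEnrichmentTest:
    def test_observed_at_null_mean(self, rng):
        null = 1.0 + rng.normal(0, 0.05, size=40)
        res = enrichment_test(float(null.mean()), null)
        assert abs(res["t"]) < 1e-8 and res["p"] == pytest.approx(1.0)

    def test_empirical_counting_rule(self):
        res = enrichment_test(10.0, [0.5, 0.6, 0.7])
        assert res["empirical_p"] == pytest.approx(1 / 4)

    def test_one_sample_matches_closed_form(self, rng):
        null = rng.normal(0.645, 0.1, size=20)
        observed = 2.0
        res = enrichment_test(observed, null)
        t = (null.mean() - observed) / (null.std(ddof=1) / math.sqrt(len(null)))
        from scipy.stats import t as tdist

        assert res["t"] == pytest.approx(t)
        assert res["p"] == pytest.approx(2 * tdist.sf(abs(t), len(null) - 1))
        assert res["empirical_p"] == pytest.approx(1 / 21)

    def test_constant_null_falls_back_to_empirical(self):
        with pytest.warns(UserWarning, match="empirical"):
            res = enrichment_test(2.0, [1.0, 1.0, 1.0])
        assert math.isnan(res["t"]) and res["empirical_p"] == pytest.approx(1 / 4)

    def test_two_sample_requires_observed_densities(self):
        with pytest.raises(ValueError):
            enrichment_test(1.0, [0.5, 0.6], mode="two_sample")


class TestTagFilter:
    CLASSES = [
        MotifClass("a", "Q.Q", frozenset({"PPI"})),
        MotifClass("b", "K.K", frozenset({"PPI", "nuclear"})),
        MotifClass("c", "E.E", frozenset({"degron"})),
    ]

    def test_class_subset(self):
        assert {c.id for c in filter_by_tag(self.CLASSES, "PPI")} == {"a", "b"}

    def test_unknown_tag_warns_empty(self):
        with pytest.warns(UserWarning, match="membrane"):
            assert filter_by_tag(self.CLASSES, "membrane") == []

    def test_hit_filtering_via_classes(self):
        protein = ProteinRecord("p", "QAQKEKEAE")
        hits = scan_motifs([protein], {"p": all_disordered(protein)}, self.CLASSES)
        ppi = filter_by_tag(hits, "PPI", motif_classes=self.CLASSES)
        assert {h.motif_id for h in ppi} == {"a", "b"}
        assert len(ppi) < len(hits)
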