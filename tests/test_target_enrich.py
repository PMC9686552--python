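import itertools
import math
import random

import pytest
from statsmodels.stats.multitest import multipletests

from exomir import target_enrich as te
from exomir.io_formats import AnnotationRow, revcomp

LET7 = "TGAGGTAGTAGGTTGTATAGTT"


class TestScanSites:
    def test_8mer_site_derived_by_hand(self):
        # reverse complement of positions 2-8 (GAGGTAG) is CTACCTC; with an A
        # opposite position 1 the full site is CTACCTCA
        site = revcomp(LET7[1:8]) + "A"
        assert site == "CTACCTCA"
        utr = "GGGGGG" + site + "GGGGGG"
        sites = te.scan_sites(LET7, utr)
        assert sites == [(7, "8mer")]  # 6mer core starts after the m8 base

    def test_7mer_m8_without_a1(self):
        utr = "GGGGGG" + revcomp(LET7[1:8]) + "GGGGGGG"
        assert te.scan_sites(LET7, utr) == [(7, "7mer-m8")]

    def test_7mer_a1_without_m8(self):
        utr = "GGGGGG" + revcomp(LET7[1:7]) + "A" + "GGGGGG"
        assert te.scan_sites(LET7, utr) == [(6, "7mer-A1")]

    def test_6mer_only(self):
        utr = "GGGGGG" + revcomp(LET7[1:7]) + "GGGGGGG"
        assert te.scan_sites(LET7, utr) == [(6, "6mer")]

    def test_no_core_empty(self):
        assert te.scan_sites(LET7, "G" * 40) == []

    def test_short_inputs_rejected(self):
        with pytest.raises(te.TargetError):
            te.scan_sites("ACGTACG", "ACGTACGTACGT")

    def test_positions_match_bruteforce_oracle(self):
        rng = random.Random(5)
        core = revcomp(LET7[1:7])
        for _ in range(50):
            utr = "".join(rng.choice("ACGT") for _ in range(300))
            expected = [i for i in range(len(utr) - 5) if utr[i : i + 6] == core]
            assert [pos for pos, _ in te.scan_sites(LET7, utr)] == expected


class TestScoreSite:
    def _utr_with(self, site, flank_char):
        return flank_char * 30 + site + flank_char * 30

    def test_au_rich_beats_gc_rich(self):
        site = revcomp(LET7[1:8]) + "A"
        for flank_au, flank_gc in [("T", "G")]:
            utr_au = self._utr_with(site, flank_au)
            utr_gc = self._utr_with(site, flank_gc)
            (pos_au, type_au), = te.scan_sites(LET7, utr_au)
            (pos_gc, type_gc), = te.scan_sites(LET7, utr_gc)
            assert type_au == type_gc == "8mer"
            score_au, _ = te.score_site(LET7, utr_au, pos_au, "8mer")
            score_gc, _ = te.score_site(LET7, utr_gc, pos_gc, "8mer")
            assert score_au > score_gc

    def test_site_type_ranking_all_else_equal(self):
        # vary only the m8/A1 bases around a fixed core in a fixed G context
        core = revcomp(LET7[1:7])
        m8 = revcomp(LET7[7])
        cases = {
            "8mer": "G" * 29 + m8 + core + "A" + "G" * 30,
            "7mer-m8": "G" * 29 + m8 + core + "G" + "G" * 30,
            "7mer-A1": "G" * 29 + "G" + core + "A" + "G" * 30,
            "6mer": "G" * 29 + "G" + core + "G" + "G" * 30,
        }
        scores = {}
        for expected_type, utr in cases.items():
            (pos, site_type), = te.scan_sites(LET7, utr)
            assert site_type == expected_type
            scores[expected_type], _ = te.score_site(LET7, utr, pos, site_type)
        assert scores["8mer"] > scores["7mer-m8"] > scores["7mer-A1"] > scores["6mer"]

    def test_zero_pair_hypothetical_energy_is_zero(self, monkeypatch):
        monkeypatch.setattr(te, "_paired_positions", lambda *a: [])
        score, energy = te.score_site(LET7, "G" * 40, 10, "6mer")
        assert energy == 0.0 and score == 0.0

    def test_energy_negative_and_gc_stronger(self):
        gc_mirna = "TCCCGGGCCCGGGCCCGGGCCC"
        at_mirna = "TAATTAATTAATTAATTAATTA"
        for mirna in (gc_mirna, at_mirna):
            utr = "G" * 30 + revcomp(mirna[1:7]) + "G" * 30
            (pos, site_type), = te.scan_sites(mirna, utr)
            _, energy = te.score_site(mirna, utr, pos, site_type)
            assert energy < 0
        utr_gc = "G" * 30 + revcomp(gc_mirna[1:7]) + "G" * 30
        utr_at = "G" * 30 + revcomp(at_mirna[1:7]) + "G" * 30
        _, e_gc = te.score_site(gc_mirna, utr_gc, 30, "6mer")
        _, e_at = te.score_site(at_mirna, utr_at, 30, "6mer")
        assert e_gc < e_at


def _prediction(score, energy):
    return te.TargetPrediction("m", "t", 0, "8mer", score, energy)


class TestIntersectFilter:
    @pytest.mark.parametrize("score,energy,kept", [
        (55.0, -12.0, True),
        (45.0, -20.0, False),   # fails the score channel
        (80.0, -10.0, False),   # energy threshold is strict
        (50.0, -10.001, True),  # score threshold is inclusive
        (49.999, -30.0, False),
    ])
    def test_boundaries(self, score, energy, kept):
        result = te.intersect_filter([_prediction(score, energy)])
        assert (len(result) == 1) is kept

    def test_monotone_in_thresholds(self):
        rng = random.Random(6)
        predictions = [_prediction(rng.uniform(0, 100), rng.uniform(-30, 0))
                       for _ in range(200)]
        base = {id(p) for p in te.intersect_filter(list(predictions))}
        stricter_score = {id(p) for p in te.intersect_filter(list(predictions),
                                                             score_threshold=60)}
        stricter_energy = {id(p) for p in te.intersect_filter(list(predictions),
                                                              energy_threshold=-15)}
        assert stricter_score <= base and stricter_energy <= base


def hypergeom_oracle(N, K, n, k):
    """Independent combinatorial oracle: sum of tail terms via math.comb."""
    total = math.comb(N, n)
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / total


class TestHypergeomEnrich:
    def _setup(self, N, K, n):
        population = [f"g{i}" for i in range(N)]
        annotations = [AnnotationRow(f"g{i}", "GO:1", "term", "GO:BP")
                       for i in range(K)]
        study = population[:n]
        return study, population, annotations

    def test_flagship_case_by_enumeration(self):
        # N=20, K=5, n=5, k=3: enumerate all C(20,5) draws
        population = list(range(20))
        annotated = set(range(5))
        study = {0, 1, 2, 5, 6}  # k = 3
        hits = sum(1 for draw in itertools.combinations(population, 5)
                   if len(set(draw) & annotated) >= 3)
        assert hits / math.comb(20, 5) == pytest.approx(1126 / 15504)

        annotations = [AnnotationRow(f"g{i}", "GO:1", "t", "GO:BP") for i in range(5)]
        results = te.hypergeom_enrich(["g0", "g1", "g2", "g5", "g6"],
                                      [f"g{i}" for i in range(20)], annotations)
        assert results[0].p_value == pytest.approx(1126 / 15504, rel=1e-12)

    def test_certain_event_p_one(self):
        study, population, annotations = self._setup(6, 6, 6)
        results = te.hypergeom_enrich(study, population, annotations)
        assert results[0].p_value == pytest.approx(1.0)

    def test_matches_oracle_for_small_populations(self):
        rng = random.Random(7)
        for _ in range(30):
            N = rng.randint(5, 25)
            K = rng.randint(1, N)
            n = rng.randint(1, N)
            population = [f"g{i}" for i in range(N)]
            annotated = rng.sample(population, K)
            study = rng.sample(population, n)
            annotations = [AnnotationRow(g, "GO:1", "t", "GO:BP") for g in annotated]
            k = len(set(study) & set(annotated))
            results = te.hypergeom_enrich(study, population, annotations)
            if k == 0:
                assert results == []
            else:
                assert results[0].k == k
                assert results[0].p_value == pytest.approx(
                    hypergeom_oracle(N, K, n, k), rel=1e-10)

    def test_study_outside_population_raises(self):
        with pytest.raises(te.TargetError, match="gX"):
            te.hypergeom_enrich(["gX"], ["g0"], [])

    def test_invariant_to_order_and_duplicate_rows(self):
        study, population, annotations = self._setup(10, 4, 5)
        r1 = te.hypergeom_enrich(study, population, annotations)
        r2 = te.hypergeom_enrich(list(reversed(study)), list(reversed(population)),
                                 annotations + annotations)
        assert [(r.term_id, r.p_value) for r in r1] == \
            [(r.term_id, r.p_value) for r in r2]

    def test_bh_within_namespace(self):
        population = [f"g{i}" for i in range(30)]
        annotations = []
        for t in range(3):
            for g in range(10 + t * 5):
                annotations.append(AnnotationRow(f"g{g}", f"GO:{t}", "t", "GO:BP"))
        for t in range(2):
            for g in range(8 + t * 6):
                annotations.append(AnnotationRow(f"g{g}", f"ko{t}", "t", "KEGG"))
        results = te.hypergeom_enrich(population[:8], population, annotations)
        for namespace in {"GO:BP", "KEGG"}:
            group = sorted((r for r in results if r.namespace == namespace),
                           key=lambda r: r.p_value)
            fdrs = [r.bh_fdr for r in group]
            assert fdrs == sorted(fdrs)  # monotone in p rank


class TestBH:
    def test_hand_computed_step_up(self):
        assert te.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert te.bh_adjust([0.2]) == [0.2]

    def test_matches_statsmodels(self):
        rng = random.Random(8)
        for _ in range(20):
            p = [rng.random() for _ in range(rng.randint(1, 30))]
            expected = multipletests(p, method="fdr_bh")[1]
            assert te.bh_adjust(p) == pytest.approx(list(expected), rel=1e-12)


class TestPredictTargets:
    def test_end_to_end_with_planted_site(self):
        site = revcomp(LET7[1:8]) + "A"
        utr = "T" * 30 + site + "T" * 30
        predictions = te.predict_targets([("let7", LET7)], [("u1", utr)])
        assert len(predictions) == 1
        p = predictions[0]
        assert p.site_type == "8mer"
        assert p.passes  # AU-rich 8mer clears both thresholds
        assert te.top_terms([], 20) == []
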