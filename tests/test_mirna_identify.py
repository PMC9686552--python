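import random

from exomir import mirna_identify as mi
from exomir.io_formats import MatureAnnotation, SeqRecord, revcomp
from exomir.preprocess import run_preprocess, tags_for_identification
from exomir.synthetic_data import ReadSimDesign, generate_reads


def _precursor():
    # 5' arm (25) + loop (10) + 3' arm (25); mature on the 5' arm at [2, 24)
    random.seed(10)
    arm = "TGAGGTAGTAGGTTGTATAGTTACC"
    loop = "GAAAGAAGAT"
    seq = arm + loop + revcomp(arm)
    precursor = SeqRecord("pre-x", "", seq)
    mature = seq[2:24]
    ann = MatureAnnotation("pre-x", "mir-x-5p", "5p", 2, 24)
    return precursor, mature, ann


class TestMapToPrecursors:
    def test_exact_mature_is_known_with_zero_shifts(self):
        precursor, mature, ann = _precursor()
        hits, primary, unmapped = mi.map_to_precursors([mature], [precursor], [ann])
        assert primary[mature] == mi.CATEGORY_KNOWN
        hit = hits[0]
        assert hit.mismatches == 0 and (hit.end_shift_5p, hit.end_shift_3p) == (0, 0)

    def test_one_internal_substitution_still_known(self):
        precursor, mature, ann = _precursor()
        tag = mature[:10] + ("A" if mature[10] != "A" else "C") + mature[11:]
        hits, primary, _ = mi.map_to_precursors([tag], [precursor], [ann])
        assert primary[tag] == mi.CATEGORY_KNOWN
        assert hits[0].mismatches == 1

    def test_end_shift_within_bound(self):
        precursor, mature, ann = _precursor()
        tag = precursor.sequence[4:24]  # 5' shift +2
        hits, primary, _ = mi.map_to_precursors([tag], [precursor], [ann],
                                                max_end_shift=4)
        assert primary[tag] == mi.CATEGORY_KNOWN
        assert hits[0].end_shift_5p == 2

    def test_end_shift_beyond_bound_unmapped(self):
        precursor, mature, ann = _precursor()
        tag = precursor.sequence[8:28]  # 5' shift +6
        _, primary, unmapped = mi.map_to_precursors([tag], [precursor], [ann],
                                                    max_end_shift=4)
        assert tag in unmapped and tag not in primary

    def test_opposite_arm_is_novel_arm(self):
        precursor, mature, ann = _precursor()
        tag = precursor.sequence[37:57]  # inside the 3' arm
        _, primary, _ = mi.map_to_precursors([tag], [precursor], [ann])
        assert primary[tag] == mi.CATEGORY_NOVEL_3P

    def test_two_substitutions_unmapped_vs_oracle(self):
        precursor, mature, ann = _precursor()
        tag = list(mature)
        for pos in (3, 12):
            tag[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tag[pos]]
        tag = "".join(tag)
        # exhaustive window-scan oracle: no window within 1 substitution
        best = min(sum(a != b for a, b in zip(tag, precursor.sequence[i : i + len(tag)]))
                   for i in range(len(precursor.sequence) - len(tag) + 1))
        assert best == 2
        _, primary, unmapped = mi.map_to_precursors([tag], [precursor], [ann])
        assert tag in unmapped

    def test_unannotated_precursor_flagged(self):
        precursor, mature, _ = _precursor()
        _, primary, _ = mi.map_to_precursors([mature], [precursor], [])
        assert primary[mature] == mi.CATEGORY_UNANNOTATED


class TestMapToOtherSpecies:
    def test_retained_when_precursor_in_genome(self):
        precursor, mature, ann = _precursor()
        genome = [SeqRecord("chr1", "", "ACGT" * 30 + precursor.sequence + "TTTT" * 20)]
        hits, primary, unmapped = mi.map_to_other_species([mature], [precursor], genome)
        assert primary[mature] == mi.CATEGORY_OTHER and not unmapped

    def test_dropped_when_precursor_absent(self):
        precursor, mature, ann = _precursor()
        genome = [SeqRecord("chr1", "", "ACGT" * 100)]
        hits, primary, unmapped = mi.map_to_other_species([mature], [precursor], genome)
        assert not hits and unmapped == [mature]

    def test_no_references_is_identity(self):
        _, mature, _ = _precursor()
        hits, primary, unmapped = mi.map_to_other_species([mature], [], [])
        assert hits == [] and primary == {} and unmapped == [mature]


def _random_genome(length, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(length))


class TestGenomeScan:
    def test_planted_forward_hit(self):
        genome_seq = _random_genome(10_000, 1)
        tag = genome_seq[100:120]
        genome = [SeqRecord("chr1", "", genome_seq)]
        hits = [h for h in mi.genome_scan([tag], genome) if h.strand == "+"]
        assert any((h.start, h.end) == (100, 120) for h in hits)

    def test_planted_reverse_hit(self):
        genome_seq = _random_genome(5_000, 2)
        tag = revcomp(genome_seq[300:321])
        genome = [SeqRecord("chr1", "", genome_seq)]
        hits = mi.genome_scan([tag], genome)
        assert any(h.strand == "-" and (h.start, h.end) == (300, 321) for h in hits)

    def test_absent_tag_no_hit(self):
        genome = [SeqRecord("chr1", "", "A" * 500)]
        assert mi.genome_scan(["TGAGGTAGTAGGTTGTATAG"], genome) == []

    def test_equals_bruteforce_oracle(self):
        genome_seq = _random_genome(10_000, 3)
        genome = [SeqRecord("chr1", "", genome_seq)]
        rng = random.Random(4)
        tags = [genome_seq[i : i + rng.randint(18, 26)]
                for i in (rng.randrange(9000) for _ in range(10))]
        tags += [revcomp(genome_seq[i : i + 20]) for i in (55, 1234, 8000)]
        tags += ["".join(rng.choice("ACGT") for _ in range(20)) for _ in range(5)]
        expected = set()
        for tag in set(tags):
            for strand, query in (("+", tag), ("-", revcomp(tag))):
                if strand == "-" and query == tag:
                    continue
                for i in range(len(genome_seq) - len(query) + 1):
                    if genome_seq[i : i + len(query)] == query:
                        expected.add((tag, i, i + len(query), strand))
        observed = {(h.tag, h.start, h.end, h.strand)
                    for h in mi.genome_scan(sorted(set(tags)), genome)}
        assert observed == expected


class TestExtractWindows:
    def test_plain_arithmetic(self):
        genome = [SeqRecord("chr1", "", _random_genome(10_000, 5))]
        hit = mi.GenomeHit("x" * 20, "chr1", 100, 120, "+")
        windows = mi.extract_hairpin_windows(hit, genome, flank=80)
        assert (windows[0].window_start, windows[0].window_end) == (20, 120)
        assert (windows[1].window_start, windows[1].window_end) == (100, 200)
        assert (windows[0].mature_start, windows[0].mature_end) == (80, 100)
        assert (windows[1].mature_start, windows[1].mature_end) == (0, 20)

    def test_clipped_at_contig_start(self):
        genome = [SeqRecord("chr1", "", _random_genome(1_000, 6))]
        hit = mi.GenomeHit("x" * 20, "chr1", 10, 30, "+")
        windows = mi.extract_hairpin_windows(hit, genome, flank=80)
        assert (windows[0].window_start, windows[0].window_end) == (0, 30)
        assert (windows[0].mature_start, windows[0].mature_end) == (10, 30)

    def test_minus_strand_is_revcomp(self):
        genome_seq = _random_genome(2_000, 7)
        genome = [SeqRecord("chr1", "", genome_seq)]
        tag = revcomp(genome_seq[500:520])
        hit = mi.GenomeHit(tag, "chr1", 500, 520, "-")
        windows = mi.extract_hairpin_windows(hit, genome, flank=80)
        for window in windows:
            assert window.sequence == revcomp(
                genome_seq[window.window_start : window.window_end])
            assert window.sequence[window.mature_start : window.mature_end] == tag


class TestRunIdentifyPartition:
    def test_every_tag_gets_exactly_one_category(self, bundle, small_design):
        reads, truth = generate_reads(small_design, bundle)
        tags, _ = run_preprocess(reads, bundle.contaminants)
        tags = tags_for_identification(tags)
        result = mi.run_identify(tags, bundle.precursors, bundle.annotations,
                                 bundle.genome, bundle.other_precursors)
        assert set(result.categories) == {t.sequence for t in tags}
        allowed = {mi.CATEGORY_KNOWN, mi.CATEGORY_NOVEL_5P, mi.CATEGORY_NOVEL_3P,
                   mi.CATEGORY_OTHER, mi.CATEGORY_CANDIDATE, mi.CATEGORY_UNANNOTATED,
                   mi.CATEGORY_UNMAPPED}
        assert set(result.categories.values()) <= allowed

    def test_known_recall_is_one(self, bundle, small_design):
        reads, truth = generate_reads(small_design, bundle)
        tags, _ = run_preprocess(reads, bundle.contaminants)
        result = mi.run_identify(tags_for_identification(tags), bundle.precursors,
                                 bundle.annotations, bundle.genome)
        # every tag arising from a planted known read must be categorized known
        known_reads = truth[truth["category"] == "known"]
        mature_by_id = {m.id: m for m in bundle.matures}
        ann_by_mature = {a.mature_id: a for a in bundle.annotations}
        prec_by_id = {p.id: p for p in bundle.precursors}
        checked = 0
        for _, row in known_reads.iterrows():
            if row["mismatches"]:
                continue  # exact-shift variant reconstruction below needs 0 mm
            ann = ann_by_mature[row["source_id"]]
            seq = prec_by_id[ann.precursor_id].sequence
            tag = seq[ann.start + row["shift5"] : ann.end + row["shift3"]]
            assert result.categories.get(tag) == mi.CATEGORY_KNOWN
            checked += 1
        assert checked > 100

    def test_novel_reads_become_candidates(self, bundle, small_design):
        reads, truth = generate_reads(small_design, bundle)
        tags, _ = run_preprocess(reads, bundle.contaminants)
        result = mi.run_identify(tags_for_identification(tags), bundle.precursors,
                                 bundle.annotations, bundle.genome)
        novel = truth[truth["category"] == "novel"]
        loci = {l.locus_id: l for l in bundle.novel_loci}
        for _, row in novel.iterrows():
            locus = loci[row["source_id"]]
            m0 = locus.mature_start - locus.start
            m1 = locus.mature_end - locus.start
            tag = locus.sequence[m0 + row["shift5"] : m1 + row["shift3"]]
            assert result.categories.get(tag) == mi.CATEGORY_CANDIDATE
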