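"""Raw FASTQ -> "valid data": trimmed, junk-filtered, contaminant-filtered
unique tags with per-sample copy numbers.

Junk rules (applied post-trim, first match reported):

=====  ======================================================================
rule   rejects when
=====  ======================================================================
a      length < 18 nt
b      any single base accounts for >= 80% of the length (ties reject;
       denominator is the full post-trim length, N included)
c      N count >= 3 (not necessarily contiguous)
f      perfect dinucleotide repeat covering the whole sequence
       (trailing partial unit allowed)
g      perfect trinucleotide repeat covering the whole sequence
d      composed only of {A, C}
e      composed only of {G, T}
=====  ======================================================================

Periodicity rules (f, g) are checked before composition rules (d, e) so that
e.g. ``ACACAC...`` reports the dimer-repeat rule; the overall reject set is
unchanged by this ordering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .io_formats import FastqRead, SeqRecord, revcomp

#: Illumina TruSeq small-RNA 3' adapter (default; overridable by config).
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

MIN_TAG_LEN = 18
MAX_TAG_LEN = 26

JUNK_RULE_ORDER = ("a", "b", "c", "f", "g", "d", "e")

#: Contaminant classes in removal-priority order.
CONTAMINANT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA", "repeat", "mRNA")


class TrimResult(NamedTuple):
    insert: str
    adapter_found: bool
    is_dimer: bool


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_adapter(sequence: str, adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
                 min_overlap: int = 6, max_mismatch: int = 1) -> TrimResult:
    """Remove the 3' adapter from a read sequence.

    The suffix starting at the leftmost position where a prefix of the
    adapter (>= ``min_overlap`` long, <= ``max_mismatch`` substitutions in the
    matched region) aligns is removed.  A match at position 0 is an
    adapter-dimer (empty insert).  If no match is found the read is kept whole.
    """
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    if len(adapter) < min_overlap:
        raise ValueError("adapter shorter than min_overlap")
    n = len(sequence)
    for start in range(0, n - min_overlap + 1):
        matched = min(len(adapter), n - start)
        if _hamming(sequence[start : start + matched], adapter[:matched]) <= max_mismatch:
            if start == 0:
                return TrimResult("", True, True)
            return TrimResult(sequence[:start], True, False)
    return TrimResult(sequence, False, False)


def _is_periodic(sequence: str, period: int) -> bool:
    """True when the sequence is a repeat of its first ``period`` characters
    (with a trailing partial unit allowed) and uses more than one base."""
    if len(sequence) < 2 * period:
        return False
    unit = sequence[:period]
    if len(set(unit)) == 1:
        return False  # homopolymer handled by rule b
    return all(sequence[i] == sequence[i % period] for i in range(len(sequence)))


def junk_filter(sequence: str) -> str | None:
    """Return the id of the first junk rule that fires, or None to keep."""
    if not sequence:
        return "a"
    n = len(sequence)
    if n < MIN_TAG_LEN:
        return "a"
    counts = Counter(sequence)
    # integer arithmetic so an exact 80% tie rejects regardless of length
    if any(5 * counts[base] >= 4 * n for base in "ACGT"):
        return "b"
    if counts["N"] >= 3:
        return "c"
    if _is_periodic(sequence, 2):
        return "f"
    if _is_periodic(sequence, 3):
        return "g"
    bases = set(sequence)
    if bases <= {"A", "C"}:
        return "d"
    if bases <= {"G", "T"}:
        return "e"
    return None


@dataclass
class UniqueTag:
    """A deduplicated tag with per-sample copy numbers."""

    sequence: str
    copies: dict[str, int] = field(default_factory=dict)

    @property
    def total_copies(self) -> int:
        return sum(self.copies.values())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterStats:
    """Per-sample read accounting; ``raw == valid + all removed categories``."""

    samples: list[str] = field(default_factory=list)
    raw: Counter = field(default_factory=Counter)
    adapter_trimmed: Counter = field(default_factory=Counter)
    adapter_dimer: Counter = field(default_factory=Counter)
    junk_by_rule: dict[str, Counter] = field(
        default_factory=lambda: {rule: Counter() for rule in JUNK_RULE_ORDER}
    )
    contaminant_by_class: dict[str, Counter] = field(default_factory=dict)
    valid: Counter = field(default_factory=Counter)
    over_length: Counter = field(default_factory=Counter)  # informational; counted in valid

    def removed(self, sample: str) -> int:
        removed = self.adapter_dimer[sample]
        removed += sum(counter[sample] for counter in self.junk_by_rule.values())
        removed += sum(counter[sample] for counter in self.contaminant_by_class.values())
        return removed

    def check_conservation(self) -> None:
        for sample in self.samples:
            total = self.valid[sample] + self.removed(sample)
            if total != self.raw[sample]:
                raise AssertionError(
                    f"accounting violated for {sample}: raw={self.raw[sample]} "
                    f"!= valid+removed={total}"
                )


def collapse(reads_by_sample: Mapping[str, Iterable[str]]) -> list[UniqueTag]:
    """Collapse surviving read sequences into unique tags (sorted by sequence)."""
    table: dict[str, dict[str, int]] = {}
    for sample, sequences in reads_by_sample.items():
        for sequence in sequences:
            table.setdefault(sequence, {})[sample] = table.get(sequence, {}).get(sample, 0) + 1
    return [UniqueTag(sequence, dict(sorted(copies.items())))
            for sequence, copies in sorted(table.items())]


def _contaminant_class(record: SeqRecord) -> str:
    description = record.description.strip()
    return description.split()[0] if description else "unknown"


def _matches_window(tag: str, reference: str, max_mismatch: int = 1) -> bool:
    n, m = len(tag), len(reference)
    if n > m:
        return False
    if max_mismatch >= 1:
        for start in range(m - n + 1):
            if _hamming(tag, reference[start : start + n]) <= max_mismatch:
                return True
        return False
    return tag in reference


def match_contaminant(tag: str, contaminants: Sequence[SeqRecord],
                      max_mismatch: int = 1) -> str | None:
    """Return the class of the highest-priority contaminant the tag matches.

    A match is an exact substring on either strand, or a full-length
    alignment with <= ``max_mismatch`` substitutions.  Classes are scanned in
    :data:`CONTAMINANT_PRIORITY` order (unknown classes last, alphabetically),
    records within a class in input order.
    """
    by_class: dict[str, list[SeqRecord]] = {}
    for record in contaminants:
        by_class.setdefault(_contaminant_class(record), []).append(record)
    ordered = [cls for cls in CONTAMINANT_PRIORITY if cls in by_class]
    ordered += sorted(set(by_class) - set(CONTAMINANT_PRIORITY))
    tag_rc = revcomp(tag)
    for cls in ordered:
        for record in by_class[cls]:
            if _matches_window(tag, record.sequence, max_mismatch) or _matches_window(
                tag_rc, record.sequence, max_mismatch
            ):
                return cls
    return None


class ContaminantIndex:
    """Window-indexed contaminant matcher; equivalent to the exhaustive scan
    in :func:`match_contaminant` but linear in the number of tags."""

    def __init__(self, contaminants: Sequence[SeqRecord],
                 min_len: int = 1, max_len: int = 60):
        from .kmer_index import WindowIndex

        self._classes = {record.id: _contaminant_class(record) for record in contaminants}
        priority = {cls: rank for rank, cls in enumerate(CONTAMINANT_PRIORITY)}
        extra = sorted(set(self._classes.values()) - set(CONTAMINANT_PRIORITY))
        priority.update({cls: len(CONTAMINANT_PRIORITY) + i for i, cls in enumerate(extra)})
        self._priority = priority
        self._index = WindowIndex({r.id: r.sequence for r in contaminants}, min_len, max_len)

    def match(self, tag: str) -> str | None:
        hits = self._index.within_one(tag) + self._index.within_one(revcomp(tag))
        classes = {self._classes[ref_id] for ref_id, _, _ in hits}
        if not classes:
            return None
        return min(classes, key=lambda cls: self._priority[cls])


def contaminant_filter(tags: Sequence[UniqueTag], contaminants: Sequence[SeqRecord],
                       max_mismatch: int = 1):
    """Split tags into (kept, removed-with-class)."""
    kept: list[UniqueTag] = []
    removed: list[tuple[UniqueTag, str]] = []
    if max_mismatch == 1 and contaminants and tags:
        lengths = [len(tag.sequence) for tag in tags]
        index = ContaminantIndex(contaminants, min(lengths), max(lengths))
        matcher = index.match
    else:
        def matcher(sequence: str) -> str | None:
            return match_contaminant(sequence, contaminants, max_mismatch)
    for tag in tags:
        cls = matcher(tag.sequence)
        if cls is None:
            kept.append(tag)
        else:
            removed.append((tag, cls))
    return kept, removed


def run_preprocess(reads_by_sample: Mapping[str, Iterable[FastqRead]],
                   contaminants: Sequence[SeqRecord] = (),
                   adapter: str = TRUSEQ_SMALL_RNA_ADAPTER,
                   min_overlap: int = 6) -> tuple[list[UniqueTag], FilterStats]:
    """Full cleaning pass: trim -> junk filter -> collapse -> contaminant filter.

    Returns the surviving unique tags ("valid data") and per-sample
    :class:`FilterStats`.  Tags longer than :data:`MAX_TAG_LEN` survive into
    the tag table (flagged in ``over_length``) but are excluded from miRNA
    identification by :func:`tags_for_identification`.
    """
    stats = FilterStats(samples=sorted(reads_by_sample))
    survivors: dict[str, list[str]] = {sample: [] for sample in stats.samples}
    for sample in stats.samples:
        for read in reads_by_sample[sample]:
            stats.raw[sample] += 1
            insert, found, dimer = trim_adapter(read.sequence, adapter, min_overlap)
            if found:
                stats.adapter_trimmed[sample] += 1
            if dimer:
                stats.adapter_dimer[sample] += 1
                continue
            rule = junk_filter(insert)
            if rule is not None:
                stats.junk_by_rule[rule][sample] += 1
                continue
            survivors[sample].append(insert)

    tags = collapse(survivors)
    kept, removed = contaminant_filter(tags, contaminants)
    for tag, cls in removed:
        counter = stats.contaminant_by_class.setdefault(cls, Counter())
        for sample, copies in tag.copies.items():
            counter[sample] += copies
    for tag in kept:
        for sample, copies in tag.copies.items():
            stats.valid[sample] += copies
        if len(tag) > MAX_TAG_LEN:
            for sample, copies in tag.copies.items():
                stats.over_length[sample] += copies
    stats.check_conservation()
    return kept, stats


def tags_for_identification(tags: Sequence[UniqueTag]) -> list[UniqueTag]:
    """Tags in the 18-26 nt range admitted to miRNA identification."""
    return [tag for tag in tags if MIN_TAG_LEN <= len(tag) <= MAX_TAG_LEN]


def stats_rows(stats: FilterStats) -> list[dict]:
    """Flatten FilterStats for TSV export (one row per sample and category)."""
    rows = []
    for sample in stats.samples:
        rows.append({"sample": sample, "category": "raw", "reads": stats.raw[sample]})
        rows.append({"sample": sample, "category": "adapter_trimmed",
                     "reads": stats.adapter_trimmed[sample]})
        rows.append({"sample": sample, "category": "adapter_dimer",
                     "reads": stats.adapter_dimer[sample]})
        for rule in JUNK_RULE_ORDER:
            rows.append({"sample": sample, "category": f"junk_{rule}",
                         "reads": stats.junk_by_rule[rule][sample]})
        for cls in sorted(stats.contaminant_by_class):
            rows.append({"sample": sample, "category": f"contaminant_{cls}",
                         "reads": stats.contaminant_by_class[cls][sample]})
        rows.append({"sample": sample, "category": "valid", "reads": stats.valid[sample]})
        rows.append({"sample": sample, "category": "over_length",
                     "reads": stats.over_length[sample]})
    return rows
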