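"""Fold candidate windows and screen them with eleven secondary-structure
criteria.

Criteria (thresholds are defaults, all configurable):

1.  every single bulge/interior loop totals <= 12 unpaired nt
2.  stem base pairs >= 16
3.  free energy <= -15 kcal/mol
4.  hairpin span (up stem + terminal loop + down stem) >= 50 nt
5.  terminal loop <= 20 nt
6.  largest single bulge/interior loop in the mature pairing region <= 8 nt
7.  interior-loop asymmetry |5' side - 3' side| in the mature region <= 4
8.  number of one-sided bulges in the mature region <= 2
9.  unpaired mature positions <= 7
10. paired mature positions >= 12
11. fraction of mature positions inside the stem >= 0.80

A loop belongs to "the mature region" when any of its unpaired positions or
either flanking base pair touches the mature interval (so a bulge on the arm
opposite the mature, enclosed by mature pairs, counts).  Criterion 6 counts
the loop's total unpaired nucleotides on both sides; criterion 7 applies to
two-sided interior loops only; criterion 8 to one-sided bulges only.  These
readings are reconstructions of loosely specified published filters and are
isolated behind the predicates below so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io_formats import DotBracketRecord, FormatError

#: base pairs the built-in folder accepts (DNA letters; T stands for U)
_CANONICAL_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
_MIN_LOOP = 3  # minimum unpaired nucleotides in a hairpin loop


class FoldError(ValueError):
    pass


class NotSingleHairpin(ValueError):
    """Structure has zero or more than one terminal loop."""


def pair_table(dot_bracket: str) -> list[int | None]:
    """Partner index per position (None when unpaired); validates balance."""
    table: list[int | None] = [None] * len(dot_bracket)
    stack: list[int] = []
    for i, char in enumerate(dot_bracket):
        if char == "(":
            stack.append(i)
        elif char == ")":
            if not stack:
                raise FormatError("unbalanced dot-bracket string")
            j = stack.pop()
            table[i], table[j] = j, i
        elif char != ".":
            raise FormatError(f"illegal dot-bracket character {char!r}")
    if stack:
        raise FormatError("unbalanced dot-bracket string")
    return table


@dataclass
class Structure:
    sequence: str
    dot_bracket: str
    energy: float
    approximate_energy: bool = False
    pairs: list[int | None] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.dot_bracket) != len(self.sequence):
            raise FormatError("structure/sequence length mismatch")
        self.pairs = pair_table(self.dot_bracket)

    @property
    def n_pairs(self) -> int:
        return sum(1 for p in self.pairs if p is not None) // 2


@dataclass
class Loop:
    """A stem interruption between two consecutive stacked pairs."""

    side5: tuple[int, int]  # half-open unpaired interval on the 5' side
    side3: tuple[int, int]  # half-open unpaired interval on the 3' side
    flank_positions: tuple[int, int, int, int]  # outer pair (i, j), inner pair (i', j')

    @property
    def count5(self) -> int:
        return self.side5[1] - self.side5[0]

    @property
    def count3(self) -> int:
        return self.side3[1] - self.side3[0]

    @property
    def total(self) -> int:
        return self.count5 + self.count3

    @property
    def one_sided(self) -> bool:
        return (self.count5 == 0) != (self.count3 == 0)

    def positions(self) -> list[int]:
        return list(range(*self.side5)) + list(range(*self.side3))


@dataclass
class HairpinDecomposition:
    span: tuple[int, int]  # outermost pair, inclusive positions
    terminal_loop: tuple[int, int]  # half-open unpaired interval
    loops: list[Loop]
    n_pairs: int

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0] + 1

    @property
    def terminal_loop_length(self) -> int:
        return self.terminal_loop[1] - self.terminal_loop[0]


def decompose(structure: Structure) -> HairpinDecomposition:
    """Decompose a single-hairpin structure into stem, loops and terminal loop.

    Raises :class:`NotSingleHairpin` for structures with no pairs or with
    more than one helix branch (multiloops / multiple hairpins).
    """
    pairs = [(i, j) for i, j in enumerate(structure.pairs) if j is not None and i < j]
    if not pairs:
        raise NotSingleHairpin("no hairpin: structure contains no base pairs")
    pairs.sort()
    # single hairpin <=> pairs form one nested chain: i ascending, j descending
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 and j2 < j1):
            raise NotSingleHairpin("not a single hairpin: branched or multiple stems")
    loops: list[Loop] = []
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if i2 - i1 > 1 or j1 - j2 > 1:
            loops.append(Loop((i1 + 1, i2), (j2 + 1, j1), (i1, j1, i2, j2)))
    innermost = pairs[-1]
    return HairpinDecomposition(
        span=(pairs[0][0], pairs[0][1]),
        terminal_loop=(innermost[0] + 1, innermost[1]),
        loops=loops,
        n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# Folding backends
# ---------------------------------------------------------------------------


def _stack_energy(seq: str, i: int, j: int, k: int, l: int) -> float:
    """Crude stacking-energy estimate for pair (i,j) stacked on (k,l)."""

    def strength(a: str, b: str) -> float:
        if {a, b} == {"G", "C"}:
            return 3.0
        if {a, b} == {"A", "T"}:
            return 2.0
        return 1.0  # G:U wobble

    return -0.5 * (strength(seq[i], seq[j]) + strength(seq[k], seq[l]))


def estimate_energy(sequence: str, dot_bracket: str) -> float:
    """Sum of stacking estimates over stacked pairs (labelled approximate)."""
    table = pair_table(dot_bracket)
    energy = 0.0
    for i, j in ((i, j) for i, j in enumerate(table) if j is not None and i < j):
        k = i + 1
        if k < len(table) and table[k] == j - 1:
            energy += _stack_energy(sequence, i, j, k, j - 1)
    return energy


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL_PAIRS


def fold_builtin(sequence: str) -> Structure:
    """Maximum-pairing dynamic program (minimum loop 3, G:U allowed).

    The structure maximises the number of canonical pairs; the energy is a
    stacking estimate and is flagged approximate.  Traceback is deterministic
    (first optimal branch in a fixed scan order).
    """
    n = len(sequence)
    best = [[0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            value = best[i + 1][j] if i + 1 <= j else 0
            for k in range(i + _MIN_LOOP + 1, j + 1):
                if _can_pair(sequence[i], sequence[k]):
                    inner = best[i + 1][k - 1] if i + 1 <= k - 1 else 0
                    rest = best[k + 1][j] if k + 1 <= j else 0
                    value = max(value, 1 + inner + rest)
            best[i][j] = value

    brackets = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if best[i][j] == (best[i + 1][j] if i + 1 <= j else 0):
                candidate_unpaired = True
            else:
                candidate_unpaired = False
            if not candidate_unpaired:
                for k in range(i + _MIN_LOOP + 1, j + 1):
                    if _can_pair(sequence[i], sequence[k]):
                        inner = best[i + 1][k - 1] if i + 1 <= k - 1 else 0
                        rest = best[k + 1][j] if k + 1 <= j else 0
                        if best[i][j] == 1 + inner + rest:
                            brackets[i], brackets[k] = "(", ")"
                            if k + 1 <= j:
                                traceback(k + 1, j)
                            i, j = i + 1, k - 1
                            break
                else:
                    i += 1
            else:
                i += 1

    if n:
        traceback(0, n - 1)
    dot_bracket = "".join(brackets)
    return Structure(sequence, dot_bracket, estimate_energy(sequence, dot_bracket),
                     approximate_energy=True)


class BuiltinBackend:
    name = "builtin"

    def fold(self, sequence: str) -> Structure:
        if len(sequence) < 4:
            raise FoldError("sequence too short to fold")
        return fold_builtin(sequence)


class FileBackend:
    """Pass-through backend serving structures from a dot-bracket file."""

    name = "file"

    def __init__(self, records: Sequence[DotBracketRecord]):
        self._by_sequence = {record.sequence: record for record in records}

    def fold(self, sequence: str) -> Structure:
        record = self._by_sequence.get(sequence)
        if record is None:
            raise FoldError("no supplied structure for sequence")
        return Structure(record.sequence, record.structure, record.energy)


class ViennaBackend:
    """Adapter for the external ViennaRNA python bindings, when installed."""

    name = "vienna"

    def __init__(self):
        try:
            import RNA  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise FoldError("ViennaRNA python bindings are not installed") from exc
        self._rna = RNA

    def fold(self, sequence: str) -> Structure:  # pragma: no cover - optional
        dot_bracket, energy = self._rna.fold(sequence.replace("T", "U"))
        return Structure(sequence, dot_bracket, float(energy))


def get_backend(name: str, structures: Sequence[DotBracketRecord] | None = None):
    if name == "builtin":
        return BuiltinBackend()
    if name == "file":
        if structures is None:
            raise FoldError("file backend requires supplied structures")
        return FileBackend(structures)
    if name in ("vienna", "external"):
        return ViennaBackend()
    raise FoldError(f"unknown folding backend {name!r}")


# ---------------------------------------------------------------------------
# Criteria
# ---------------------------------------------------------------------------

DEFAULT_THRESHOLDS = {
    1: 12,     # max nt in any single bulge/interior loop
    2: 16,     # min stem base pairs
    3: -15.0,  # max free energy (kcal/mol)
    4: 50,     # min hairpin span (nt)
    5: 20,     # max terminal loop (nt)
    6: 8,      # max nt in a single bulge within the mature region
    7: 4,      # max interior-loop asymmetry within the mature region
    8: 2,      # max one-sided bulges within the mature region
    9: 7,      # max unpaired mature positions
    10: 12,    # min paired mature positions
    11: 0.80,  # min fraction of mature positions inside the stem
}

_CRITERION_OPS = {1: "<=", 2: ">=", 3: "<=", 4: ">=", 5: "<=",
                  6: "<=", 7: "<=", 8: "<=", 9: "<=", 10: ">=", 11: ">="}


@dataclass
class CriterionResult:
    criterion: int
    observed: float
    threshold: float
    op: str
    passed: bool


@dataclass
class CriteriaReport:
    results: list[CriterionResult]
    accepted: bool
    reason: str = ""
    approximate_energy: bool = False

    def result(self, criterion: int) -> CriterionResult:
        return next(r for r in self.results if r.criterion == criterion)

    def failing(self) -> list[int]:
        return [r.criterion for r in self.results if not r.passed]


def _loop_touches_interval(loop: Loop, start: int, end: int) -> bool:
    if any(start <= p < end for p in loop.positions()):
        return True
    return any(start <= p < end for p in loop.flank_positions)


def evaluate_criteria(structure: Structure, decomposition: HairpinDecomposition,
                      mature: tuple[int, int],
                      thresholds: dict[int, float] | None = None) -> CriteriaReport:
    """Evaluate the eleven structure criteria for one candidate window.

    ``mature`` is the 0-based half-open tag interval within the window.
    """
    mstart, mend = mature
    n = len(structure.sequence)
    if not (0 <= mstart < mend <= n):
        raise ValueError(f"mature interval [{mstart}, {mend}) outside window of length {n}")
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)

    mature_loops = [loop for loop in decomposition.loops
                    if _loop_touches_interval(loop, mstart, mend)]
    interior_mature = [loop for loop in mature_loops if loop.count5 > 0 and loop.count3 > 0]
    one_sided_mature = [loop for loop in mature_loops if loop.one_sided]

    span_start, span_end = decomposition.span
    tstart, tend = decomposition.terminal_loop
    paired_mature = sum(1 for p in range(mstart, mend) if structure.pairs[p] is not None)
    unpaired_mature = (mend - mstart) - paired_mature
    in_stem = sum(1 for p in range(mstart, mend)
                  if span_start <= p <= span_end and not (tstart <= p < tend))

    observed = {
        1: max((loop.total for loop in decomposition.loops), default=0),
        2: decomposition.n_pairs,
        3: structure.energy,
        4: decomposition.span_length,
        5: decomposition.terminal_loop_length,
        6: max((loop.total for loop in mature_loops), default=0),
        7: max((abs(loop.count5 - loop.count3) for loop in interior_mature), default=0),
        8: len(one_sided_mature),
        9: unpaired_mature,
        10: paired_mature,
        11: in_stem / (mend - mstart),
    }
    results = []
    for criterion in range(1, 12):
        op = _CRITERION_OPS[criterion]
        value, bound = observed[criterion], th[criterion]
        passed = value <= bound if op == "<=" else value >= bound
        results.append(CriterionResult(criterion, float(value), float(bound), op, passed))
    return CriteriaReport(results, all(r.passed for r in results),
                          approximate_energy=structure.approximate_energy)


def evaluate_window(sequence: str, mature: tuple[int, int], backend,
                    thresholds: dict[int, float] | None = None) -> CriteriaReport:
    """Fold one window and evaluate criteria; folding/shape failures become
    rejected reports with a reason rather than exceptions."""
    try:
        structure = backend.fold(sequence)
    except FoldError as exc:
        return CriteriaReport([], False, reason=str(exc))
    try:
        decomposition = decompose(structure)
    except NotSingleHairpin as exc:
        return CriteriaReport([], False, reason=str(exc))
    report = evaluate_criteria(structure, decomposition, mature, thresholds)
    report.energy = structure.energy  # type: ignore[attr-defined]
    return report


@dataclass
class ScreenResult:
    tag: str
    accepted: bool
    best_window: int | None  # index of the lowest-energy passing window
    reports: list[CriteriaReport]


def screen_candidates(candidates, backend,
                      thresholds: dict[int, float] | None = None) -> list[ScreenResult]:
    """Screen candidate tags.

    ``candidates`` is an iterable of ``(tag, windows)`` where each window is a
    ``(sequence, (mature_start, mature_end))`` pair.  A tag is accepted when
    at least one window yields a single hairpin passing all eleven criteria;
    the lowest-energy passing window is reported as best.
    """
    results = []
    for tag, windows in candidates:
        reports = [evaluate_window(seq, mature, backend, thresholds)
                   for seq, mature in windows]
        passing = [(getattr(report, "energy", 0.0), index)
                   for index, report in enumerate(reports) if report.accepted]
        best = min(passing)[1] if passing else None
        results.append(ScreenResult(tag, bool(passing), best, reports))
    return results


def report_rows(tag: str, report: CriteriaReport) -> list[dict]:
    """Flatten a report for TSV export."""
    if not report.results:
        return [{"tag": tag, "criterion": 0, "observed": float("nan"),
                 "threshold": float("nan"), "op": "", "passed": 0,
                 "note": report.reason}]
    rows = []
    for r in report.results:
        rows.append({"tag": tag, "criterion": r.criterion, "observed": r.observed,
                     "threshold": r.threshold, "op": r.op, "passed": int(r.passed),
                     "note": "approximate-energy" if (r.criterion == 3 and
                                                      report.approximate_energy) else ""})
    return rows
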