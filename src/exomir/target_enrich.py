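"""Seed-match target prediction with a dual-threshold filter, plus
hypergeometric GO/KEGG enrichment with Benjamini-Hochberg correction.

The two external target scorers are replaced by a transparent two-channel
scorer with the same dual-threshold intersection semantics: a prediction
passes only when ``context_like_score >= 50`` (inclusive) AND
``duplex_energy < -10`` (exclusive).

Scoring manual
--------------
``context_like_score`` (0-100) = site-type points (8mer 45, 7mer-m8 38,
7mer-A1 30, 6mer 20) + 35 x AU fraction of the 30-nt flanks + 5 points per
3'-supplementary pair (miRNA positions 13-16; capped at 20).

``duplex_energy`` (kcal/mol, lower = more stable) = +4 initiation penalty
plus, per Watson-Crick pair in the seed duplex and the 3'-supplementary
region, -3 (G:C) or -2 (A:T).  A hypothetical site with zero pairs scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io_formats import AnnotationRow, revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
SITE_TYPE_POINTS = {"8mer": 45.0, "7mer-m8": 38.0, "7mer-A1": 30.0, "6mer": 20.0}
SCORE_THRESHOLD = 50.0
ENERGY_THRESHOLD = -10.0
INITIATION_PENALTY = 4.0
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class TargetError(ValueError):
    pass


@dataclass
class TargetPrediction:
    mirna: str
    transcript: str
    position: int  # 0-based start of the 6mer seed core in the UTR
    site_type: str
    context_like_score: float = float("nan")
    duplex_energy: float = float("nan")
    passes: bool = False


def scan_sites(mirna: str, utr: str) -> list[tuple[int, str]]:
    """All seed-match sites of a miRNA in a UTR (positions of the 6mer core).

    The core is the reverse complement of miRNA positions 2-7.  Classification:
    8mer = positions 2-8 matched plus 'A' opposite position 1; 7mer-m8 =
    positions 2-8 matched; 7mer-A1 = 2-7 matched plus the A; 6mer otherwise.
    """
    if len(mirna) < 8 or len(utr) < 8:
        raise TargetError("miRNA and UTR must both be >= 8 nt")
    core = revcomp(mirna[1:7])
    sites = []
    pos = utr.find(core)
    while pos != -1:
        m8 = pos >= 1 and utr[pos - 1] == _COMPLEMENT[mirna[7]]
        a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
        if m8 and a1:
            site_type = "8mer"
        elif m8:
            site_type = "7mer-m8"
        elif a1:
            site_type = "7mer-A1"
        else:
            site_type = "6mer"
        sites.append((pos, site_type))
        pos = utr.find(core, pos + 1)
    return sites


def _paired_positions(mirna: str, utr: str, position: int) -> list[tuple[str, str]]:
    """(miRNA base, UTR base) for every Watson-Crick pair the site forms:
    seed positions 2-7, position 8 when matched, and 3'-supplementary 13-16."""
    pairs = []
    for m in range(1, 7):  # seed core (matched by construction of the site)
        pairs.append((mirna[m], utr[position + 6 - (m + 1)]))
    if position >= 1 and utr[position - 1] == _COMPLEMENT[mirna[7]]:
        pairs.append((mirna[7], utr[position - 1]))
    for m in range(12, 16):  # 3'-supplementary, positions 13-16 (1-based)
        if m >= len(mirna):
            break
        u = position + 6 - (m + 1)
        if 0 <= u < len(utr) and utr[u] == _COMPLEMENT[mirna[m]]:
            pairs.append((mirna[m], utr[u]))
    return pairs


def score_site(mirna: str, utr: str, position: int, site_type: str):
    """Deterministic ``(context_like_score, duplex_energy)`` per the manual."""
    flank5 = utr[max(0, position - 30) : position]
    flank3 = utr[position + 6 : position + 36]
    flanks = flank5 + flank3
    au = sum(1 for b in flanks if b in "AT") / len(flanks) if flanks else 0.0
    pairs = _paired_positions(mirna, utr, position)
    seed_pairs = 7 if site_type in ("8mer", "7mer-m8") else 6
    supp = max(0, len(pairs) - seed_pairs)
    score = SITE_TYPE_POINTS[site_type] + 35.0 * au + min(20.0, 5.0 * supp)
    if not pairs:
        return 0.0, 0.0
    energy = INITIATION_PENALTY
    for a, b in pairs:
        energy += -3.0 if {a, b} == {"G", "C"} else -2.0
    return float(score), float(energy)


def predict_targets(mirnas: Sequence[tuple[str, str]],
                    utrs: Sequence[tuple[str, str]]) -> list[TargetPrediction]:
    """Scan and score every (miRNA, UTR) pair; marks the dual-threshold flag."""
    predictions: list[TargetPrediction] = []
    for mirna_id, mirna_seq in mirnas:
        for utr_id, utr_seq in utrs:
            for position, site_type in scan_sites(mirna_seq, utr_seq):
                score, energy = score_site(mirna_seq, utr_seq, position, site_type)
                predictions.append(TargetPrediction(
                    mirna_id, utr_id, position, site_type, score, energy,
                    passes=(score >= SCORE_THRESHOLD and energy < ENERGY_THRESHOLD)))
    return predictions


def intersect_filter(predictions: Iterable[TargetPrediction],
                     score_threshold: float = SCORE_THRESHOLD,
                     energy_threshold: float = ENERGY_THRESHOLD) -> list[TargetPrediction]:
    """Keep predictions both scorers accept: score >= threshold (inclusive)
    AND energy < threshold (strict) -- the intersection semantics."""
    kept = []
    for p in predictions:
        p.passes = p.context_like_score >= score_threshold and \
            p.duplex_energy < energy_threshold
        if p.passes:
            kept.append(p)
    return kept


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int  # study hits
    K: int  # population hits
    n: int  # study size
    N: int  # population size
    p_value: float
    bh_fdr: float = float("nan")


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p, kind="stable")
    m = len(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted.tolist()


def hypergeom_enrich(study_genes: Sequence[str], population_genes: Sequence[str],
                     annotations: Sequence[AnnotationRow],
                     namespaces: Sequence[str] | None = None) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment per term, BH within namespace.

    ``p = P(X >= k)`` with population N, annotated K, study n, study hits k;
    terms with k = 0 are omitted.  Study genes must be a subset of the
    population.
    """
    study = set(study_genes)
    population = set(population_genes)
    offenders = sorted(study - population)
    if offenders:
        raise TargetError(f"study genes absent from population: {offenders}")

    by_term: dict[tuple[str, str, str], set[str]] = {}
    for row in annotations:
        if namespaces and row.namespace not in namespaces:
            continue
        key = (row.namespace, row.term_id, row.term_name)
        by_term.setdefault(key, set()).add(row.gene_id)

    N, n = len(population), len(study)
    results: list[EnrichmentResult] = []
    for (namespace, term_id, term_name), genes in sorted(by_term.items()):
        K = len(genes & population)
        k = len(genes & study)
        if k == 0 or K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, term_name, namespace, k, K, n, N, p))

    for namespace in sorted({r.namespace for r in results}):
        group = [r for r in results if r.namespace == namespace]
        adjusted = bh_adjust([r.p_value for r in group])
        for r, q in zip(group, adjusted):
            r.bh_fdr = float(q)
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def top_terms(results: Sequence[EnrichmentResult], top: int = 20) -> list[EnrichmentResult]:
    """Deterministic top-N report (sorted by p then term id)."""
    return sorted(results, key=lambda r: (r.p_value, r.term_id))[:top]


def prediction_rows(predictions: Sequence[TargetPrediction]) -> list[dict]:
    return [{"mirna": p.mirna, "transcript": p.transcript, "position": p.position,
             "site_type": p.site_type, "context_like_score": p.context_like_score,
             "duplex_energy": p.duplex_energy, "passes": int(p.passes)}
            for p in predictions]


def enrichment_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    return [{"term_id": r.term_id, "term_name": r.term_name, "namespace": r.namespace,
             "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p_value": r.p_value, "bh_fdr": r.bh_fdr}
            for r in results]
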