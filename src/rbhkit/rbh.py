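"""Reciprocal-best-hit inference.

Hits are filtered on e-value (<= 1e-6) and on coverage of the shorter protein
(>= 60%), both boundaries inclusive; per query the highest-bit-score hit is
selected (ties broken by lower e-value, higher identity, then smallest
subject id, and flagged); a pair is an RBH — and is inferred orthologous —
when each member is the other's best hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

from .align import Hit, HitTable, ScoringScheme, align_proteomes, self_scores


@dataclass(frozen=True)
class FilterConfig:
    """Hit acceptance thresholds (inclusive boundaries)."""

    max_evalue: float = 1e-6
    min_coverage: float = 0.60

    def __post_init__(self) -> None:
        if not (0.0 < self.min_coverage <= 1.0):
            raise ValueError("min_coverage must lie in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")

    def accepts(self, hit: Hit) -> bool:
        return hit.evalue <= self.max_evalue and coverage_of_shorter(hit) >= self.min_coverage


@dataclass(frozen=True)
class RBHPair:
    """A mutually-best protein pair, with both directional hits' statistics."""

    id_a: str
    id_b: str
    bits_ab: float
    bits_ba: float
    evalue_ab: float
    evalue_ba: float
    tie_flag: bool = False

    def unordered(self) -> frozenset:
        return frozenset((self.id_a, self.id_b))


def coverage_of_shorter(hit: Hit) -> float:
    """Fraction of the shorter protein spanned by the alignment.

    The span is measured on the side belonging to the shorter protein
    (query side when lengths are equal).
    """
    if hit.q_len <= hit.s_len:
        return (hit.q_end - hit.q_start + 1) / hit.q_len
    return (hit.s_end - hit.s_start + 1) / hit.s_len


def filter_hits(table: HitTable, cfg: Optional[FilterConfig] = None) -> HitTable:
    """Keep hits passing the e-value and coverage thresholds, order preserved."""
    cfg = cfg or FilterConfig()
    return HitTable(
        table.query_genome,
        table.target_genome,
        [h for h in table.hits if cfg.accepts(h)],
    )


def dedupe_hits(table: HitTable) -> HitTable:
    """Keep one row per (query, subject): the highest-scoring one.

    Some tools emit several HSP rows for the same pair; only the best
    (highest bits, then lowest e-value, then highest identity) is relevant
    for best-hit selection.
    """
    best: Dict[Tuple[str, str], Hit] = {}
    order: List[Tuple[str, str]] = []
    for h in table.hits:
        key = (h.query_id, h.subject_id)
        cur = best.get(key)
        if cur is None:
            best[key] = h
            order.append(key)
        elif _hit_rank(h) > _hit_rank(cur):
            best[key] = h
    return HitTable(table.query_genome, table.target_genome, [best[k] for k in order])


def _hit_rank(h: Hit) -> Tuple[float, float, float]:
    ident = h.identity_frac if h.identity_frac == h.identity_frac else -1.0
    return (h.bits, -h.evalue, ident)


def best_hits(table: HitTable) -> Dict[str, Hit]:
    """Best (highest-bits) hit per query id of an already-filtered table."""
    best, _ = _best_hits(table)
    return best


def _best_hits(table: HitTable) -> Tuple[Dict[str, Hit], Set[str]]:
    same_genome = table.query_genome == table.target_genome
    best: Dict[str, Hit] = {}
    tied: Set[str] = set()
    for h in dedupe_hits(table).hits:
        if same_genome and h.query_id == h.subject_id:
            continue  # a proteome searched against itself: self-hit is not a candidate
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
        elif h.bits > cur.bits:
            best[h.query_id] = h
            tied.discard(h.query_id)
        elif h.bits == cur.bits:
            tied.add(h.query_id)
            if _best_key(h) > _best_key(cur):
                best[h.query_id] = h
    return best, tied


def _best_key(h: Hit) -> Tuple[float, float, float, "_RevStr"]:
    ident = h.identity_frac if h.identity_frac == h.identity_frac else -1.0
    return (h.bits, -h.evalue, ident, _RevStr(h.subject_id))


class _RevStr(str):
    """Reverse-ordered string so max() prefers the lexicographically smallest."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def reciprocal_best_hits(
    table_ab: HitTable,
    table_ba: HitTable,
    cfg: Optional[FilterConfig] = None,
) -> List[RBHPair]:
    """Intersect the two directional best-hit maps into RBH pairs.

    Both tables are filtered with ``cfg`` first.  Output is ordered by the
    A-side protein id; each protein appears in at most one pair.
    """
    cfg = cfg or FilterConfig()
    _check_orientation(table_ab, table_ba)
    fab = filter_hits(table_ab, cfg)
    fba = filter_hits(table_ba, cfg)
    best_ab, tied_ab = _best_hits(fab)
    best_ba, tied_ba = _best_hits(fba)
    pairs: List[RBHPair] = []
    for a in sorted(best_ab):
        hit_ab = best_ab[a]
        b = hit_ab.subject_id
        hit_ba = best_ba.get(b)
        if hit_ba is None or hit_ba.subject_id != a:
            continue
        pairs.append(
            RBHPair(
                id_a=a,
                id_b=b,
                bits_ab=hit_ab.bits,
                bits_ba=hit_ba.bits,
                evalue_ab=hit_ab.evalue,
                evalue_ba=hit_ba.evalue,
                tie_flag=(a in tied_ab) or (b in tied_ba),
            )
        )
    return pairs


def _check_orientation(table_ab: HitTable, table_ba: HitTable) -> None:
    if table_ab.query_genome and table_ba.target_genome:
        if (
            table_ab.query_genome != table_ba.target_genome
            or table_ab.target_genome != table_ba.query_genome
        ):
            raise ValueError(
                "hit tables are not opposite directions of the same genome pair: "
                f"{table_ab.query_genome}->{table_ab.target_genome} vs "
                f"{table_ba.query_genome}->{table_ba.target_genome}"
            )
        return
    if table_ab.hits and table_ba.hits:
        subjects_ab = {h.subject_id for h in table_ab.hits}
        queries_ba = {h.query_id for h in table_ba.hits}
        if not subjects_ab & queries_ba:
            raise ValueError(
                "hit tables do not cross-match (no shared ids between the "
                "subjects of A->B and the queries of B->A); were they swapped?"
            )


# ---------------------------------------------------------------------------
# End-to-end convenience over the built-in aligner
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    """Everything the built-in RBH pipeline produces for one proteome pair."""

    rbh: List[RBHPair]
    table_ab: HitTable
    table_ba: HitTable
    filtered_ab: HitTable
    filtered_ba: HitTable
    self_bits_a: Dict[str, float]
    self_bits_b: Dict[str, float]

    @property
    def self_bits(self) -> Dict[str, float]:
        merged = dict(self.self_bits_a)
        merged.update(self.self_bits_b)
        return merged


def find_orthologs(
    proteome_a: Sequence,
    proteome_b: Sequence,
    scheme: Optional[ScoringScheme] = None,
    cfg: Optional[FilterConfig] = None,
    genome_a: str = "A",
    genome_b: str = "B",
    evalue_cap: Optional[float] = None,
) -> PipelineResult:
    """Run the whole built-in pipeline: align, filter, select, intersect."""
    scheme = scheme or ScoringScheme()
    cfg = cfg or FilterConfig()
    cap = evalue_cap if evalue_cap is not None else cfg.max_evalue
    table_ab, table_ba = align_proteomes(
        proteome_a, proteome_b, scheme, cap, genome_a, genome_b
    )
    fab = filter_hits(table_ab, cfg)
    fba = filter_hits(table_ba, cfg)
    pairs = reciprocal_best_hits(table_ab, table_ba, cfg)
    return PipelineResult(
        rbh=pairs,
        table_ab=table_ab,
        table_ba=table_ba,
        filtered_ab=fab,
        filtered_ba=fba,
        self_bits_a=self_scores(proteome_a, scheme),
        self_bits_b=self_scores(proteome_b, scheme),
    )


# ---------------------------------------------------------------------------
# RBH table serialization (the normal form consumed by evaluation)
# ---------------------------------------------------------------------------

RBH_COLUMNS = ("id_a", "id_b", "bits_ab", "bits_ba", "evalue_ab", "evalue_ba", "tie_flag")


def write_rbh_table(pairs: Iterable[RBHPair], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(RBH_COLUMNS) + "\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.bits_ab!r}\t{p.bits_ba!r}\t"
                f"{p.evalue_ab!r}\t{p.evalue_ba!r}\t{int(p.tie_flag)}\n"
            )


def read_rbh_table(path: Union[str, Path]) -> List[RBHPair]:
    pairs: List[RBHPair] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != RBH_COLUMNS:
            raise ValueError(f"{path}: not an RBH table (header {header})")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            pairs.append(
                RBHPair(
                    id_a=parts[0], id_b=parts[1],
                    bits_ab=float(parts[2]), bits_ba=float(parts[3]),
                    evalue_ab=float(parts[4]), evalue_ba=float(parts[5]),
                    tie_flag=bool(int(parts[6])),
                )
            )
    return pairs
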