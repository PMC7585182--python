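"""Evaluation statistics for RBH ortholog sets.

Three instruments:

* **Genomic Similarity Score (GSS)** — the sum of the bit scores of all RBH
  pairs in both directions (*compScore*) divided by the sum of the members'
  self-alignment bit scores (*selfScore*).  Near-identical proteome pairs
  score close to 1; the score decays with divergence.
* **Conserved-adjacency error rate** — gene-order based quality control.
  When genes *a*, *b* are neighbors in one genome and their homologs *a'*,
  *b'* are neighbors in the other, an orthologous *a*–*a'* pair predicts an
  orthologous *b*–*b'* pair.  Confirmations count toward *O*; a homologous
  but non-RBH (i.e. paralogous) pair found instead counts toward *P*; the
  error estimate is ``E = P / (P + O)``.
* **Cross-method intersections** — per-method RBH counts, proportions
  relative to a reference method, and UpSet-style subset counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple, Union

from .align import HitTable
from .io import GeneLocus
from .rbh import RBHPair


@dataclass(frozen=True)
class GSSResult:
    """Genomic Similarity Score for one proteome pair."""

    comp_score: float
    self_score: float
    n_pairs: int

    @property
    def gss(self) -> float:
        return self.comp_score / self.self_score


def gss(rbh: Sequence[RBHPair], self_bits: Mapping[str, float]) -> GSSResult:
    """GSS = compScore / selfScore over an RBH set.

    ``self_bits`` must cover every protein occurring in ``rbh``; both
    alignment directions enter the numerator and both members' self scores
    the denominator, making the statistic symmetric in the two genomes.
    """
    if not rbh:
        raise ValueError("GSS undefined for zero RBH")
    comp = 0.0
    self_score = 0.0
    # accumulate both sums in the same order so an identical proteome pair
    # (cross score == self score term by term) yields a GSS of exactly 1.0
    for p in rbh:
        comp += p.bits_ab
        comp += p.bits_ba
        for pid in (p.id_a, p.id_b):
            if pid not in self_bits:
                raise KeyError(f"no self score for protein {pid!r}")
            self_score += self_bits[pid]
    return GSSResult(comp_score=comp, self_score=self_score, n_pairs=len(rbh))


# ---------------------------------------------------------------------------
# Conserved-adjacency error rate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyCase:
    """One conserved-adjacency quadruple (a, b adjacent in A; a', b' in B)."""

    a: str
    b: str
    a_prime: str
    b_prime: str
    a_is_rbh: bool
    b_is_rbh: bool


@dataclass(frozen=True)
class ErrorEstimate:
    """Counts from the conserved-adjacency test and the ratio E = P/(P+O)."""

    O: int
    P: int
    n_adjacencies_tested: int

    @property
    def defined(self) -> bool:
        return (self.O + self.P) > 0

    @property
    def E(self) -> float:
        if not self.defined:
            return math.nan
        return self.P / (self.P + self.O)


def _homolog_pairs(filtered_ab: HitTable, filtered_ba: HitTable) -> Set[Tuple[str, str]]:
    """Unordered-as-(A,B) homolog pairs present in either filtered direction."""
    pairs = {(h.query_id, h.subject_id) for h in filtered_ab.hits}
    pairs |= {(h.subject_id, h.query_id) for h in filtered_ba.hits}
    return pairs


def _adjacent_pairs(loci: Sequence[GeneLocus], circular: bool = False):
    """Pairs of protein ids at consecutive ranks on the same replicon."""
    by_replicon: Dict[Tuple[str, str], List[GeneLocus]] = {}
    for l in loci:
        by_replicon.setdefault((l.genome_id, l.replicon_id), []).append(l)
    for key, group in sorted(by_replicon.items()):
        group = sorted(group, key=lambda l: l.index)
        for x, y in zip(group, group[1:]):
            yield x.protein_id, y.protein_id
        if circular and len(group) > 2:
            yield group[-1].protein_id, group[0].protein_id


def conserved_adjacencies(
    loci_a: Sequence[GeneLocus],
    loci_b: Sequence[GeneLocus],
    filtered_ab: HitTable,
    filtered_ba: HitTable,
    rbh: Sequence[RBHPair],
    circular: bool = False,
) -> List[AdjacencyCase]:
    """Enumerate testable conserved-adjacency quadruples.

    A quadruple (a, b, a', b') qualifies when a,b are rank-adjacent in genome
    A, a',b' rank-adjacent in genome B, a' is a filtered homolog of a, b' of
    b, and at least one of (a,a'), (b,b') is an RBH pair.  Each unordered
    quadruple is emitted once.  Replicon ends do not wrap unless ``circular``.
    """
    pids_a = {l.protein_id for l in loci_a}
    pids_b = {l.protein_id for l in loci_b}
    for h in filtered_ab.hits:
        if h.query_id not in pids_a:
            raise ValueError(f"protein {h.query_id!r} in hit table has no locus")
        if h.subject_id not in pids_b:
            raise ValueError(f"protein {h.subject_id!r} in hit table has no locus")
    for h in filtered_ba.hits:
        if h.query_id not in pids_b:
            raise ValueError(f"protein {h.query_id!r} in hit table has no locus")
        if h.subject_id not in pids_a:
            raise ValueError(f"protein {h.subject_id!r} in hit table has no locus")

    homologs = _homolog_pairs(filtered_ab, filtered_ba)
    homologs_of: Dict[str, Set[str]] = {}
    for a, b in homologs:
        homologs_of.setdefault(a, set()).add(b)
    rbh_set = {(p.id_a, p.id_b) for p in rbh}

    # B-side adjacency lookup: neighbor sets per protein
    neighbors_b: Dict[str, Set[str]] = {}
    for x, y in _adjacent_pairs(loci_b, circular):
        neighbors_b.setdefault(x, set()).add(y)
        neighbors_b.setdefault(y, set()).add(x)

    cases: List[AdjacencyCase] = []
    seen: Set[FrozenSet[Tuple[str, str]]] = set()
    for a, b in _adjacent_pairs(loci_a, circular):
        for a_prime in sorted(homologs_of.get(a, ())):
            for b_prime in sorted(neighbors_b.get(a_prime, ())):
                if b_prime not in homologs_of.get(b, ()):
                    continue
                a_rbh = (a, a_prime) in rbh_set
                b_rbh = (b, b_prime) in rbh_set
                if not (a_rbh or b_rbh):
                    continue
                key = frozenset(((a, a_prime), (b, b_prime)))
                if key in seen:
                    continue
                seen.add(key)
                cases.append(AdjacencyCase(a, b, a_prime, b_prime, a_rbh, b_rbh))
    return cases


def error_rate(cases: Sequence[AdjacencyCase], rbh: Sequence[RBHPair]) -> ErrorEstimate:
    """Count confirmations (O) and paralog substitutions (P) over the cases.

    Anchored on an RBH pair, the partner pair either confirms the inference
    (also RBH: O, counted once even when both sides are RBH) or reveals a
    paralogous assignment (homologous but not the RBH partner: P).
    """
    rbh_set = {(p.id_a, p.id_b) for p in rbh}
    O = 0
    P = 0
    for c in cases:
        a_rbh = (c.a, c.a_prime) in rbh_set
        b_rbh = (c.b, c.b_prime) in rbh_set
        if a_rbh and b_rbh:
            O += 1
        elif a_rbh or b_rbh:
            # the other pair is a filtered homolog by construction, yet not
            # the protein's RBH partner: a paralog pair where an orthologous
            # one was expected
            P += 1
    return ErrorEstimate(O=O, P=P, n_adjacencies_tested=len(cases))


# ---------------------------------------------------------------------------
# Cross-method intersections
# ---------------------------------------------------------------------------


@dataclass
class IntersectionReport:
    """Per-method counts, proportions vs a reference, and UpSet subset sizes."""

    method_names: List[str]
    reference: str
    counts: Dict[str, int]
    proportions: Dict[str, float]
    subset_counts: Dict[FrozenSet[str], int]

    @property
    def union_size(self) -> int:
        return sum(self.subset_counts.values())

    def rows(self) -> List[Tuple[Tuple[int, ...], int]]:
        """(membership vector over method_names, count) per non-empty subset."""
        out = []
        for subset, n in self.subset_counts.items():
            out.append((tuple(int(m in subset) for m in self.method_names), n))
        out.sort(key=lambda r: (-r[1], r[0]))
        return out


def _as_pair_set(pairs: Iterable) -> Set[FrozenSet[str]]:
    out: Set[FrozenSet[str]] = set()
    for p in pairs:
        if isinstance(p, RBHPair):
            out.add(p.unordered())
        else:
            a, b = p
            out.add(frozenset((a, b)))
    return out


def proportions_vs_reference(
    rbh_sets: Mapping[str, Iterable], reference: str
) -> IntersectionReport:
    """Compare several methods' RBH sets against a reference method.

    Membership is decided on unordered protein-id pairs.  Subset counts
    partition the union of all sets (every pair is assigned to the exact
    subset of methods that found it).
    """
    if reference not in rbh_sets:
        raise KeyError(f"reference method {reference!r} not among {sorted(rbh_sets)}")
    sets = {m: _as_pair_set(v) for m, v in rbh_sets.items()}
    if not sets[reference]:
        raise ValueError("reference RBH set is empty")
    methods = list(sets)
    counts = {m: len(s) for m, s in sets.items()}
    proportions = {m: counts[m] / counts[reference] for m in methods}
    union: Set[FrozenSet[str]] = set().union(*sets.values())
    subset_counts: Dict[FrozenSet[str], int] = {}
    for pair in union:
        subset = frozenset(m for m in methods if pair in sets[m])
        subset_counts[subset] = subset_counts.get(subset, 0) + 1
    return IntersectionReport(
        method_names=methods,
        reference=reference,
        counts=counts,
        proportions=proportions,
        subset_counts=subset_counts,
    )


def plot_intersections(report: IntersectionReport, path: Union[str, Path]) -> None:
    """Minimal UpSet-style figure: subset-size bars over a membership matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = report.rows()
    n_sub = len(rows)
    methods = report.method_names
    fig, (ax_bar, ax_mat) = plt.subplots(
        2, 1, figsize=(max(4, 0.8 * n_sub), 4 + 0.3 * len(methods)),
        sharex=True, height_ratios=[3, 1],
    )
    xs = range(n_sub)
    ax_bar.bar(xs, [n for _, n in rows], color="0.25")
    ax_bar.set_ylabel("RBH pairs")
    for x, (membership, _) in enumerate(rows):
        for y, bit in enumerate(membership):
            ax_mat.plot(x, y, "o", color="0.1" if bit else "0.85", markersize=8)
    ax_mat.set_yticks(range(len(methods)), methods)
    ax_mat.set_xticks([])
    ax_mat.set_ylim(-0.5, len(methods) - 0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# TSV writers
# ---------------------------------------------------------------------------


def write_gss_tsv(
    result: GSSResult, path: Union[str, Path], genome_a: str = "A", genome_b: str = "B"
) -> None:
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\tn_pairs\tcomp_score\tself_score\tgss\n")
        fh.write(
            f"{genome_a}\t{genome_b}\t{result.n_pairs}\t{result.comp_score!r}\t"
            f"{result.self_score!r}\t{result.gss!r}\n"
        )


def write_error_tsv(est: ErrorEstimate, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("O\tP\tE\tn_adjacencies_tested\tdefined\n")
        e = f"{est.E!r}" if est.defined else "NA"
        fh.write(f"{est.O}\t{est.P}\t{e}\t{est.n_adjacencies_tested}\t{int(est.defined)}\n")


def write_intersection_tsv(report: IntersectionReport, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(report.method_names) + "\tcount\n")
        for membership, n in report.rows():
            fh.write("\t".join(str(b) for b in membership) + f"\t{n}\n")
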