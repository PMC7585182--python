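"""Genome de-redundancy via oligonucleotide composition signatures.

A genome's signature is its vector of overlapping k-mer frequencies (k = 3 by
default) counted on both strands, so the vector is invariant under reverse
complementation.  The distance between two signatures is the total-variation
form::

    delta(x, y) = 1/2 * sum_i |x_i - y_i|        in [0, 1]

Genomes within a delta cutoff (default 0.04, roughly species level) are
single-linkage clustered, and each cluster is represented by its member with
the most annotated proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def kmer_alphabet(k: int = 3) -> List[str]:
    """All k-mers in lexicographic order over A,C,G,T (AAA..TTT for k=3)."""
    return ["".join(p) for p in product(_BASES, repeat=k)]


def _revcomp_permutation(k: int) -> np.ndarray:
    """perm[i] = index of the reverse complement of k-mer i."""
    n = 4**k
    perm = np.empty(n, dtype=np.int64)
    for code in range(n):
        digits = []
        c = code
        for _ in range(k):
            digits.append(c % 4)
            c //= 4
        # digits are last..first; complement (3-d) and keep this order to reverse
        rc = 0
        for d in digits:
            rc = rc * 4 + (3 - d)
        perm[code] = rc
    return perm


@dataclass(frozen=True)
class SignatureVector:
    """Both-strand k-mer frequency vector for one genome."""

    genome_id: str
    freqs: np.ndarray
    n_counted: int
    k: int = 3

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", f)
        if f.shape != (4**self.k,):
            raise ValueError(f"expected {4 ** self.k} frequencies, got {f.shape}")
        if self.n_counted > 0 and abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def signature(
    seqs: Union[str, Iterable[Union[str, Tuple[str, str]]]],
    genome_id: str = "",
    k: int = 3,
) -> SignatureVector:
    """Compute the both-strand k-mer signature of one genome.

    ``seqs`` may be a single sequence string or an iterable of sequences (or
    (id, sequence) pairs); multiple records are pooled into one vector.
    Windows containing characters outside A/C/G/T are skipped.
    """
    if isinstance(seqs, str):
        seqs = [seqs]
    counts = np.zeros(4**k, dtype=np.int64)
    for item in seqs:
        seq = item[1] if isinstance(item, tuple) else item
        counts += _count_kmers(seq.upper(), k)
    perm = _revcomp_permutation(k)
    both = counts + counts[perm]  # add the reverse-complement strand
    total = int(both.sum())
    if total == 0:
        raise ValueError(f"no countable {k}-mer window in genome {genome_id!r}")
    return SignatureVector(
        genome_id=genome_id, freqs=both / total, n_counted=total, k=k
    )


def _count_kmers(seq: str, k: int) -> np.ndarray:
    counts = np.zeros(4**k, dtype=np.int64)
    if len(seq) < k:
        return counts
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    vals = lut[codes]
    kcodes = np.zeros(len(seq) - k + 1, dtype=np.int64)
    valid = np.ones(len(seq) - k + 1, dtype=bool)
    for offset in range(k):
        window = vals[offset : offset + len(kcodes)]
        valid &= window >= 0
        kcodes = kcodes * 4 + np.where(window >= 0, window, 0)
    good = kcodes[valid]
    if good.size:
        counts += np.bincount(good, minlength=4**k)
    return counts


def delta_distance(x: SignatureVector, y: SignatureVector) -> float:
    """Total-variation distance between two signatures; in [0, 1]."""
    if x.k != y.k:
        raise ValueError("signatures have different k")
    return 0.5 * float(np.abs(x.freqs - y.freqs).sum())


@dataclass
class GenomeCluster:
    """One de-redundancy cluster and its representative genome."""

    member_ids: List[str]
    representative_id: str
    representative_protein_count: int


def cluster(
    genomes: Sequence[Tuple[SignatureVector, int]],
    cutoff: float = 0.04,
) -> List[GenomeCluster]:
    """Single-linkage clustering at a delta cutoff.

    Two genomes share a cluster iff they are connected by a chain of pairwise
    delta <= cutoff.  Each cluster's representative is the member with the
    largest protein count (ties: larger ``n_counted``, then lexicographically
    smallest id).  Output is ordered by smallest member id; clustering is
    invariant under input permutation.
    """
    ids = [sv.genome_id for sv, _ in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("genome ids must be unique")
    order = sorted(range(len(genomes)), key=lambda i: ids[i])
    n = len(order)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        svi = genomes[order[i]][0]
        for j in range(i + 1, n):
            if delta_distance(svi, genomes[order[j]][0]) <= cutoff:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(order[i])

    clusters: List[GenomeCluster] = []
    for root in sorted(groups, key=lambda r: ids[order[r]]):
        members = groups[root]
        rep = max(
            members,
            key=lambda m: (
                genomes[m][1],
                genomes[m][0].n_counted,
                _RevStr(ids[m]),
            ),
        )
        clusters.append(
            GenomeCluster(
                member_ids=sorted(ids[m] for m in members),
                representative_id=ids[rep],
                representative_protein_count=genomes[rep][1],
            )
        )
    return clusters


class _RevStr(str):
    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def delta_matrix(signatures: Sequence[SignatureVector]) -> np.ndarray:
    """Symmetric pairwise delta-distance matrix."""
    n = len(signatures)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = delta_distance(signatures[i], signatures[j])
    return out


def write_clusters_tsv(clusters: Sequence[GenomeCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember\tis_representative\n")
        for cid, cl in enumerate(clusters):
            for m in cl.member_ids:
                fh.write(f"{cid}\t{m}\t{int(m == cl.representative_id)}\n")
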