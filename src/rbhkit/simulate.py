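"""Synthetic genome pairs with planted ortholog/paralog ground truth.

The generative model: an ancestral proteome of random sequences becomes
genome A unchanged; genome B is the ancestor after (i) per-residue
substitution at probability ``divergence`` (replacement residues drawn from
BLOSUM62-conditional weights, so simulated drift interacts realistically
with the scorer), (ii) gene duplications with independent extra divergence,
(iii) gene losses, and (iv) random segment inversions of the gene order.
Genomic DNA is back-translated with a per-genome (clade-specific) synonymous
codon preference, which separates clades in trinucleotide-signature space.

Protein/gene ids encode ancestry (``anc0017_a``/``anc0017_b``,
``anc0017.dup1_b``), so ground-truth evaluation needs no join table.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .io import GeneLocus, ProteinRecord, write_fasta, write_loci

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: ungapped BLOSUM62 lambda, used only to weight substitution choices
_UNGAPPED_LAMBDA = 0.3176


def _substitution_weights() -> np.ndarray:
    """20x20 row-stochastic matrix of replacement probabilities (0 diagonal)."""
    mat = substitution_matrices.load("BLOSUM62")
    alph = str(mat.alphabet)
    idx = [alph.index(a) for a in AA20]
    S = np.asarray(mat, dtype=float)[np.ix_(idx, idx)]
    W = np.exp(_UNGAPPED_LAMBDA * S)
    np.fill_diagonal(W, 0.0)
    W /= W.sum(axis=1, keepdims=True)
    return W


_W = _substitution_weights()
_W_CUM = np.cumsum(_W, axis=1)

_CODONS_FOR: Dict[str, List[str]] = {}
for _codon, _aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated genome pair."""

    n_genes: int
    protein_length_range: Tuple[int, int] = (80, 400)
    divergence: float = 0.0
    p_dup: float = 0.0
    p_loss: float = 0.0
    n_inversions: int = 0
    codon_skew: float = 0.5
    indel_rate: float = 0.0
    uniform_substitutions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        for name in ("divergence", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("p_dup", "p_loss"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.codon_skew < 1.0):
            raise ValueError("codon_skew must lie in [0, 1)")
        lo, hi = self.protein_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid protein_length_range")


@dataclass
class SyntheticBundle:
    """A simulated proteome pair with loci, DNA and ground truth."""

    config: SimulationConfig
    proteome_a: List[ProteinRecord]
    proteome_b: List[ProteinRecord]
    loci_a: List[GeneLocus]
    loci_b: List[GeneLocus]
    dna_a: List[Tuple[str, str]]
    dna_b: List[Tuple[str, str]]
    truth_orthologs: Set[FrozenSet[str]]
    truth_paralogs: Dict[str, str]
    confused_genes: Set[str] = field(default_factory=set)

    def write(self, outdir: Union[str, Path]) -> List[Path]:
        """Write the bundle as FASTA/TSV files; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, records in (("proteome_a.faa", self.proteome_a), ("proteome_b.faa", self.proteome_b)):
            p = outdir / name
            write_fasta(records, p)
            paths.append(p)
        for name, loci in (("loci_a.tsv", self.loci_a), ("loci_b.tsv", self.loci_b)):
            p = outdir / name
            write_loci(loci, p)
            paths.append(p)
        for name, recs in (("dna_a.fna", self.dna_a), ("dna_b.fna", self.dna_b)):
            p = outdir / name
            with open(p, "w") as fh:
                for rid, seq in recs:
                    fh.write(f">{rid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i : i + 70] + "\n")
            paths.append(p)
        p = outdir / "truth.tsv"
        with open(p, "w") as fh:
            fh.write("id_a\tid_b\n")
            for pair in sorted(tuple(sorted(x)) for x in self.truth_orthologs):
                fh.write("\t".join(pair) + "\n")
        paths.append(p)
        return paths


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _random_proteome(cfg: SimulationConfig) -> List[str]:
    rng = _rng(cfg.seed, 0)
    lo, hi = cfg.protein_length_range
    seqs = []
    for _ in range(cfg.n_genes):
        length = int(rng.integers(lo, hi + 1))
        seqs.append("".join(AA20[i] for i in rng.integers(0, 20, length)))
    return seqs


def _substitute(seq: str, d: float, mask_rng, residue_rng, uniform: bool) -> str:
    """Substitute each residue with probability d.

    Replacement choices are drawn from a stream independent of the mask, so
    raising d on the same streams yields a superset of the same changes
    (divergence ladders are nested).
    """
    L = len(seq)
    u = mask_rng.random(L)
    r = residue_rng.random(L)
    out = list(seq)
    for p in np.nonzero(u < d)[0]:
        i = AA20.index(out[p])
        if uniform:
            j = int(r[p] * 19)
            j = j if j < i else j + 1
        else:
            j = int(np.searchsorted(_W_CUM[i], r[p], side="right"))
            j = min(j, 19)
        out[p] = AA20[j]
    return "".join(out)


def _apply_indels(seq: str, rate: float, rng) -> str:
    if rate <= 0.0:
        return seq
    out = []
    aa = None
    for ch in seq:
        u = rng.random()
        if u < rate / 2.0:
            continue  # deletion
        out.append(ch)
        if u > 1.0 - rate / 2.0:
            out.append(AA20[int(rng.integers(0, 20))])
    return "".join(out) or seq


def _codon_weights(rng, skew: float) -> Dict[str, np.ndarray]:
    """Per-amino-acid synonymous codon probabilities for one genome/clade.

    A mixture (1 - skew) * uniform + skew * point-mass on a randomly chosen
    preferred codon: skew 0 is uniform usage, skew near 1 is extreme bias.
    """
    weights = {}
    for aa, codons in _CODONS_FOR.items():
        n = len(codons)
        w = np.full(n, (1.0 - skew) / n)
        w[int(rng.integers(0, n))] += skew
        weights[aa] = w / w.sum()
    return weights


def _back_translate(seq: str, weights: Dict[str, np.ndarray], rng) -> str:
    parts = []
    for aa in seq:
        codons = _CODONS_FOR[aa]
        parts.append(codons[int(rng.choice(len(codons), p=weights[aa]))])
    return "".join(parts)


def _genome_dna(
    records: Sequence[ProteinRecord],
    loci: Sequence[GeneLocus],
    weights: Dict[str, np.ndarray],
    rng,
    replicon_prefix: str,
) -> List[Tuple[str, str]]:
    by_id = {r.protein_id: r for r in records}
    by_replicon: Dict[str, List[GeneLocus]] = {}
    for l in loci:
        by_replicon.setdefault(l.replicon_id, []).append(l)
    out = []
    for replicon in sorted(by_replicon):
        chunks = []
        for l in sorted(by_replicon[replicon], key=lambda x: x.index):
            cds = _back_translate(by_id[l.protein_id].sequence, weights, rng)
            if l.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            chunks.append(cds)
        out.append((f"{replicon_prefix}_{replicon}", "".join(chunks)))
    return out


def simulate_pair(cfg: SimulationConfig) -> SyntheticBundle:
    """Simulate one diverged genome pair with known ortholog/paralog truth."""
    ancestor = _random_proteome(cfg)
    gids = [f"anc{i:04d}" for i in range(cfg.n_genes)]

    strand_rng = _rng(cfg.seed, 1)
    proteome_a = [
        ProteinRecord(protein_id=f"{g}_a", sequence=s, gene_id=g)
        for g, s in zip(gids, ancestor)
    ]
    strands_a = ["+" if strand_rng.random() < 0.5 else "-" for _ in gids]
    loci_a = [
        GeneLocus("A", "chr1", i, strands_a[i], gids[i], f"{gids[i]}_a")
        for i in range(cfg.n_genes)
    ]

    # (i) substitutions: per-gene streams so divergence ladders are nested
    b_seqs = [
        _apply_indels(
            _substitute(
                ancestor[i], cfg.divergence,
                _rng(cfg.seed, 2, i), _rng(cfg.seed, 3, i),
                cfg.uniform_substitutions,
            ),
            cfg.indel_rate,
            _rng(cfg.seed, 4, i),
        )
        for i in range(cfg.n_genes)
    ]

    event_rng = _rng(cfg.seed, 5)
    entries: List[Tuple[str, str, str]] = [  # (gene_id, protein_id, sequence)
        (gids[i], f"{gids[i]}_b", b_seqs[i]) for i in range(cfg.n_genes)
    ]
    # (ii) duplications, inserted at random ranks with extra divergence
    dup_flags = event_rng.random(cfg.n_genes) < cfg.p_dup
    families: Dict[str, str] = {}
    for i in range(cfg.n_genes):
        if not dup_flags[i]:
            continue
        dup_seq = _substitute(
            b_seqs[i], max(cfg.divergence, 0.0),
            _rng(cfg.seed, 6, i), _rng(cfg.seed, 7, i),
            cfg.uniform_substitutions,
        )
        rank = int(event_rng.integers(0, len(entries) + 1))
        entries.insert(rank, (f"{gids[i]}.dup1", f"{gids[i]}.dup1_b", dup_seq))
    # (iii) losses remove the ortholog copy
    loss_flags = {gids[i]: bool(f) for i, f in enumerate(event_rng.random(cfg.n_genes) < cfg.p_loss)}
    entries = [e for e in entries if not loss_flags.get(e[0], False)]
    if not entries:
        raise ValueError("p_loss removed every gene; nothing survives in genome B")
    # (iv) segment inversions of gene order
    order = list(range(len(entries)))
    strands_b = ["+" if event_rng.random() < 0.5 else "-" for _ in entries]
    for _ in range(cfg.n_inversions):
        i = int(event_rng.integers(0, len(order)))
        j = int(event_rng.integers(0, len(order)))
        i, j = min(i, j), max(i, j)
        order[i : j + 1] = order[i : j + 1][::-1]
        for k in range(i, j + 1):
            strands_b[k] = "+" if strands_b[k] == "-" else "-"

    proteome_b = []
    loci_b = []
    for rank, k in enumerate(order):
        gene_id, protein_id, seq = entries[k]
        proteome_b.append(ProteinRecord(protein_id=protein_id, sequence=seq, gene_id=gene_id))
        loci_b.append(GeneLocus("B", "chr1", rank, strands_b[rank], gene_id, protein_id))

    truth = {
        frozenset((f"{g}_a", f"{g}_b"))
        for g in gids
        if not loss_flags.get(g, False)
    }
    paralogs: Dict[str, str] = {}
    for rec in proteome_a + proteome_b:
        paralogs[rec.protein_id] = rec.gene_id.split(".")[0]

    dna_rng_a = _rng(cfg.seed, 10)
    dna_rng_b = _rng(cfg.seed, 11)
    dna_a = _genome_dna(proteome_a, loci_a, _codon_weights(dna_rng_a, cfg.codon_skew), dna_rng_a, "A")
    dna_b = _genome_dna(proteome_b, loci_b, _codon_weights(dna_rng_b, cfg.codon_skew), dna_rng_b, "B")

    return SyntheticBundle(
        config=cfg,
        proteome_a=proteome_a,
        proteome_b=proteome_b,
        loci_a=loci_a,
        loci_b=loci_b,
        dna_a=dna_a,
        dna_b=dna_b,
        truth_orthologs=truth,
        truth_paralogs=paralogs,
    )


def divergence_ladder(
    base_cfg: SimulationConfig, d_values: Sequence[float]
) -> List[SyntheticBundle]:
    """One bundle per divergence level, sharing the seed-derived ancestor.

    ``d_values`` must be sorted ascending.  All non-divergence events
    (duplications, losses, inversions, ids) are identical across the ladder,
    and the substituted position sets are nested, so only divergence varies.
    """
    if list(d_values) != sorted(d_values):
        raise ValueError("d_values must be sorted ascending")
    return [simulate_pair(replace(base_cfg, divergence=float(d))) for d in d_values]


def plant_confusable_paralogs(
    bundle: SyntheticBundle, q: float, seed: int = 0
) -> SyntheticBundle:
    """Make a fraction q of duplicated genes ortholog-confusable.

    For each selected gene the B-side ortholog's sequence is replaced by a
    further-diverged copy of its paralog's sequence, so the paralog becomes
    the strictly higher-scoring partner of the A-side gene while the truth
    labels stay put.  The affected ancestral gene ids are recorded in
    ``confused_genes``.
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if q == 0.0:
        return replace(bundle, confused_genes=set())
    seqs_b = {r.protein_id: r.sequence for r in bundle.proteome_b}
    eligible = sorted(
        g for g in (r.gene_id for r in bundle.proteome_b if "." not in r.gene_id)
        if f"{g}.dup1_b" in seqs_b and f"{g}_b" in seqs_b
    )
    if not eligible:
        raise ValueError("no paralog families in the bundle; nothing to confuse")
    rng = _rng(seed, 100)
    n_confuse = int(round(q * len(eligible)))
    chosen = sorted(rng.choice(eligible, size=n_confuse, replace=False).tolist())
    extra_d = max(bundle.config.divergence, 0.1)
    new_proteome = []
    for i, rec in enumerate(bundle.proteome_b):
        if rec.gene_id in chosen and rec.protein_id == f"{rec.gene_id}_b":
            new_seq = _substitute(
                seqs_b[f"{rec.gene_id}.dup1_b"], extra_d,
                _rng(seed, 101, i), _rng(seed, 102, i), False,
            )
            rec = ProteinRecord(protein_id=rec.protein_id, sequence=new_seq, gene_id=rec.gene_id)
        new_proteome.append(rec)
    return replace(bundle, proteome_b=new_proteome, confused_genes=set(chosen))


# ---------------------------------------------------------------------------
# Clade DNA for signature clustering, and random hit tables for stress tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CladeGenome:
    """One simulated genome of a codon-usage clade (DNA + protein count)."""

    genome_id: str
    clade_id: int
    dna: List[Tuple[str, str]]
    protein_count: int


def simulate_clades(
    n_clades: int = 3,
    genomes_per_clade: int = 5,
    n_genes: int = 40,
    length_range: Tuple[int, int] = (80, 200),
    codon_skew: float = 0.7,
    seed: int = 0,
) -> List[CladeGenome]:
    """Genomes whose DNA composition separates by clade codon preference.

    Genomes of one clade share a synonymous codon-preference table; each
    genome carries its own random proteins, with protein counts varying
    within the clade so a unique cluster representative exists.
    """
    out = []
    for c in range(n_clades):
        weights = _codon_weights(_rng(seed, 200, c), codon_skew)
        for g in range(genomes_per_clade):
            rng = _rng(seed, 201, c, g)
            count = n_genes + g  # distinct within the clade
            chunks = []
            lo, hi = length_range
            for _ in range(count):
                L = int(rng.integers(lo, hi + 1))
                prot = "".join(AA20[i] for i in rng.integers(0, 20, L))
                chunks.append(_back_translate(prot, weights, rng))
            out.append(
                CladeGenome(
                    genome_id=f"clade{c}_g{g}",
                    clade_id=c,
                    dna=[(f"clade{c}_g{g}_chr1", "".join(chunks))],
                    protein_count=count,
                )
            )
    return out


def random_hit_tables(
    n_a: int,
    n_b: int,
    seed: int = 0,
    hit_prob: float = 0.4,
    genome_a: str = "A",
    genome_b: str = "B",
):
    """Random directional hit tables (for stress-testing RBH selection).

    Scores, e-values and spans are arbitrary but internally consistent
    (spans fit the lengths); the two directions are sampled independently.
    """
    from .align import Hit, HitTable

    rng = _rng(seed, 300)
    ids_a = [f"a{i:03d}" for i in range(n_a)]
    ids_b = [f"b{i:03d}" for i in range(n_b)]
    len_a = {i: int(rng.integers(50, 400)) for i in ids_a}
    len_b = {i: int(rng.integers(50, 400)) for i in ids_b}

    def draw(qids, sids, qlen, slen, qg, sg):
        hits = []
        for q in qids:
            for s in sids:
                if rng.random() > hit_prob:
                    continue
                ql, sl = qlen[q], slen[s]
                qs = int(rng.integers(1, ql + 1))
                qe = int(rng.integers(qs, ql + 1))
                ss = int(rng.integers(1, sl + 1))
                se = int(rng.integers(ss, sl + 1))
                bits = float(np.round(rng.uniform(25, 500), 1))
                hits.append(
                    Hit(
                        query_id=q, subject_id=s, bits=bits,
                        evalue=10.0 ** rng.uniform(-30, -3),
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        q_len=ql, s_len=sl,
                        identity_frac=float(rng.uniform(0.2, 1.0)),
                    )
                )
        rng.shuffle(hits)
        return HitTable(qg, sg, hits)

    return (
        draw(ids_a, ids_b, len_a, len_b, genome_a, genome_b),
        draw(ids_b, ids_a, len_b, len_a, genome_b, genome_a),
    )
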