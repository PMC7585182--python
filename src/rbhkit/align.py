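"""Protein alignment engine and hit records.

The built-in engine is an exact Smith-Waterman aligner with affine gap costs
(BLOSUM62, gap open 11, extend 1 by default).  Raw scores are converted to bit
scores with the standard gapped Karlin-Altschul parameters and to e-values
with a per-pair ``m * n`` search space::

    bits   = (lambda * raw - ln K) / ln 2
    evalue = q_len * s_len * 2 ** (-bits)

External search programs (blastp, lastal, diamond, mmseqs) are supported only
as command-line builders; the toolkit never invokes them itself.
"""

from __future__ import annotations

import math
import shlex
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from . import _kernels

#: Standard gapped Karlin-Altschul parameters for BLOSUM62 / open 11 / extend 1.
GAPPED_LAMBDA = 0.267
GAPPED_K = 0.041

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Hit:
    """One pairwise local-alignment record (one line of a tabular hit file)."""

    query_id: str
    subject_id: str
    bits: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    q_len: int
    s_len: int
    identity_frac: float = float("nan")
    raw_score: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end <= self.q_len):
            raise ValueError(
                f"invalid query span {self.q_start}..{self.q_end} (len {self.q_len}) "
                f"for {self.query_id}->{self.subject_id}"
            )
        if not (1 <= self.s_start <= self.s_end <= self.s_len):
            raise ValueError(
                f"invalid subject span {self.s_start}..{self.s_end} (len {self.s_len}) "
                f"for {self.query_id}->{self.subject_id}"
            )
        if self.bits <= 0:
            raise ValueError("bit score must be positive")
        if self.evalue < 0:
            raise ValueError("e-value must be non-negative")

    def mirrored(self) -> "Hit":
        """The same alignment viewed from the other genome's side."""
        return Hit(
            query_id=self.subject_id,
            subject_id=self.query_id,
            bits=self.bits,
            evalue=self.evalue,
            q_start=self.s_start,
            q_end=self.s_end,
            s_start=self.q_start,
            s_end=self.q_end,
            q_len=self.s_len,
            s_len=self.q_len,
            identity_frac=self.identity_frac,
            raw_score=self.raw_score,
        )


@dataclass
class HitTable:
    """An ordered collection of hits from one query proteome against one target."""

    query_genome: str = ""
    target_genome: str = ""
    hits: List[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def validate_against(self, query_ids: Iterable[str], target_ids: Iterable[str]) -> None:
        qset, tset = set(query_ids), set(target_ids)
        for h in self.hits:
            if h.query_id not in qset:
                raise ValueError(f"hit query {h.query_id!r} absent from query proteome")
            if h.subject_id not in tset:
                raise ValueError(f"hit subject {h.subject_id!r} absent from target proteome")


class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin-Altschul constants.

    Parameters
    ----------
    matrix_name:
        Name of a matrix shipped with biopython (default ``BLOSUM62``).
    gap_open, gap_extend:
        Positive penalties; a gap of length L costs ``gap_open + L * gap_extend``.
    lam, K:
        Karlin-Altschul parameters used to turn raw scores into bits.
    """

    def __init__(
        self,
        matrix_name: str = "BLOSUM62",
        gap_open: int = 11,
        gap_extend: int = 1,
        lam: float = GAPPED_LAMBDA,
        K: float = GAPPED_K,
    ) -> None:
        if gap_open <= 0 or gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if lam <= 0 or K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        self.matrix_name = matrix_name
        self.gap_open = int(gap_open)
        self.gap_extend = int(gap_extend)
        self.lam = float(lam)
        self.K = float(K)
        mat = substitution_matrices.load(matrix_name)
        self.alphabet = str(mat.alphabet)
        self.matrix = np.asarray(mat, dtype=np.int32)
        # '*' and '-' are not residues; everything else in the matrix is scorable
        self._index = {
            ch: i for i, ch in enumerate(self.alphabet) if ch not in ("*", "-")
        }

    def encode(self, sequence: str) -> np.ndarray:
        """Map residues to matrix row indices; unknown residues are an error."""
        idx = self._index
        try:
            return np.fromiter(
                (idx[c] for c in sequence), dtype=np.int8, count=len(sequence)
            )
        except KeyError:
            bad = sorted({c for c in sequence if c not in idx})
            raise ValueError(
                f"residue(s) {bad} not present in matrix {self.matrix_name}"
            ) from None

    def bits_from_raw(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / _LN2

    def evalue_from_bits(self, bits: float, q_len: int, s_len: int) -> float:
        return q_len * s_len * 2.0 ** (-bits)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ScoringScheme({self.matrix_name}, open={self.gap_open}, "
            f"extend={self.gap_extend}, lambda={self.lam}, K={self.K})"
        )


def _seq_of(record) -> str:
    return record.sequence if hasattr(record, "sequence") else str(record)


def _id_of(record, default: str) -> str:
    return record.protein_id if hasattr(record, "protein_id") else default


def smith_waterman(query, subject, scheme: Optional[ScoringScheme] = None) -> Optional[Hit]:
    """Best local alignment between two proteins, or None if nothing scores > 0.

    Accepts `ProteinRecord`-like objects (``.protein_id``/``.sequence``) or
    plain strings.  Only the single best alignment is reported (one HSP).
    """
    scheme = scheme or ScoringScheme()
    qseq, sseq = _seq_of(query), _seq_of(subject)
    if not qseq or not sseq:
        raise ValueError("cannot align empty sequences")
    a = scheme.encode(qseq)
    b = scheme.encode(sseq)
    raw, qs, qe, ss, se, ident, cols = _kernels.sw_traceback(
        a, b, scheme.matrix, scheme.gap_open, scheme.gap_extend
    )
    if raw <= 0:
        return None
    bits = scheme.bits_from_raw(float(raw))
    return Hit(
        query_id=_id_of(query, "query"),
        subject_id=_id_of(subject, "subject"),
        bits=bits,
        evalue=scheme.evalue_from_bits(bits, len(qseq), len(sseq)),
        q_start=int(qs),
        q_end=int(qe),
        s_start=int(ss),
        s_end=int(se),
        q_len=len(qseq),
        s_len=len(sseq),
        identity_frac=ident / cols if cols else 0.0,
        raw_score=int(raw),
    )


def _encode_proteome(records: Sequence, scheme: ScoringScheme):
    codes: List[np.ndarray] = [scheme.encode(_seq_of(r)) for r in records]
    offsets = np.zeros(len(codes) + 1, dtype=np.int64)
    for i, c in enumerate(codes):
        offsets[i + 1] = offsets[i] + len(c)
    flat = (
        np.concatenate(codes) if codes else np.zeros(0, dtype=np.int8)
    ).astype(np.int8)
    return flat, offsets, codes


def _sorted_hits(hits: List[Hit]) -> List[Hit]:
    return sorted(hits, key=lambda h: (h.query_id, -h.bits, h.subject_id))


def all_vs_all(
    queryome: Sequence,
    targetome: Sequence,
    scheme: Optional[ScoringScheme] = None,
    evalue_cap: float = 1e-6,
    query_genome: str = "",
    target_genome: str = "",
) -> HitTable:
    """Smith-Waterman hits for every ordered (query, target) pair under the cap.

    Hits are ordered by (query_id, descending bits, subject_id).
    """
    ab, _ = align_proteomes(
        queryome, targetome, scheme, evalue_cap, query_genome, target_genome
    )
    return ab


def align_proteomes(
    proteome_a: Sequence,
    proteome_b: Sequence,
    scheme: Optional[ScoringScheme] = None,
    evalue_cap: float = 1e-6,
    genome_a: str = "",
    genome_b: str = "",
) -> Tuple[HitTable, HitTable]:
    """Both directional hit tables (A->B and B->A) in one pass.

    The Smith-Waterman score is symmetric, so each unordered pair is aligned
    once and mirrored into the opposite direction.
    """
    scheme = scheme or ScoringScheme()
    flat_a, off_a, codes_a = _encode_proteome(proteome_a, scheme)
    flat_b, off_b, codes_b = _encode_proteome(proteome_b, scheme)
    na, nb = len(proteome_a), len(proteome_b)
    ids_a = [_id_of(r, f"q{i}") for i, r in enumerate(proteome_a)]
    ids_b = [_id_of(r, f"s{i}") for i, r in enumerate(proteome_b)]

    hits_ab: List[Hit] = []
    hits_ba: List[Hit] = []
    if na and nb:
        # single concatenated pool so one batch call scores all pairs
        codes = np.concatenate([flat_a, flat_b]) if len(flat_a) + len(flat_b) else flat_a
        offsets = np.concatenate([off_a, off_b[1:] + off_a[-1]])
        qi, si = np.meshgrid(np.arange(na), np.arange(nb) + na, indexing="ij")
        qi = qi.ravel().astype(np.int64)
        si = si.ravel().astype(np.int64)
        raw = _kernels.sw_score_batch(
            codes, offsets, qi, si, scheme.matrix, scheme.gap_open, scheme.gap_extend
        )
        for k in range(raw.shape[0]):
            r = int(raw[k])
            if r <= 0:
                continue
            i, j = int(qi[k]), int(si[k] - na)
            bits = scheme.bits_from_raw(r)
            ev = scheme.evalue_from_bits(bits, len(codes_a[i]), len(codes_b[j]))
            if ev > evalue_cap:
                continue
            _, qs, qe, ss, se, ident, cols = _kernels.sw_traceback(
                codes_a[i], codes_b[j], scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            hit = Hit(
                query_id=ids_a[i],
                subject_id=ids_b[j],
                bits=bits,
                evalue=ev,
                q_start=int(qs),
                q_end=int(qe),
                s_start=int(ss),
                s_end=int(se),
                q_len=len(codes_a[i]),
                s_len=len(codes_b[j]),
                identity_frac=ident / cols if cols else 0.0,
                raw_score=r,
            )
            hits_ab.append(hit)
            hits_ba.append(hit.mirrored())

    return (
        HitTable(genome_a, genome_b, _sorted_hits(hits_ab)),
        HitTable(genome_b, genome_a, _sorted_hits(hits_ba)),
    )


def self_scores(proteome: Sequence, scheme: Optional[ScoringScheme] = None) -> Dict[str, float]:
    """Bit score of each protein aligned against itself.

    When every residue has a positive diagonal matrix entry the self alignment
    is the ungapped full-length one, so the raw score is the diagonal sum; for
    sequences containing residues with non-positive self scores (e.g. X) the
    aligner is consulted.
    """
    scheme = scheme or ScoringScheme()
    diag = np.diag(scheme.matrix)
    out: Dict[str, float] = {}
    for i, rec in enumerate(proteome):
        codes = scheme.encode(_seq_of(rec))
        if codes.size and np.all(diag[codes] > 0):
            raw = int(diag[codes].sum())
        else:
            raw, _, _ = _kernels.sw_score(
                codes, codes, scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            raw = int(raw)
        out[_id_of(rec, f"p{i}")] = scheme.bits_from_raw(raw)
    return out


# ---------------------------------------------------------------------------
# Command builders for the four external search programs
# ---------------------------------------------------------------------------

DIAMOND_SENSITIVITIES = (
    "fast",
    "sensitive",
    "more-sensitive",
    "very-sensitive",
    "ultra-sensitive",
)

#: Tabular columns requested from tools that can report them (blast6ext form).
BLAST6EXT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore qlen slen"
)


@dataclass(frozen=True)
class CommandSpec:
    """Shell commands to build a target database and run one search."""

    program: str
    db_command: Tuple[str, ...]
    search_command: Tuple[str, ...]
    output_dialect: str

    def as_shell(self) -> str:
        return (
            shlex.join(self.db_command) + " && " + shlex.join(self.search_command)
        )


def build_external_command(
    program: str,
    query: str,
    subject: str,
    out: str,
    db_prefix: Optional[str] = None,
    sensitivity: Optional[object] = None,
    evalue: float = 1e-6,
    threads: int = 4,
) -> CommandSpec:
    """Argument vectors for one directional search with the standard options:

    e-value pre-filter 1e-6, tabular output with query/subject lengths where
    supported, soft-masking for blastp/lastal/mmseqs (diamond has no
    soft-masking and runs unmasked), and final Smith-Waterman alignment where
    the tool offers it.
    """
    programs = ("blastp", "lastal", "diamond", "mmseqs")
    if program not in programs:
        raise ValueError(f"unknown program {program!r}; expected one of {programs}")
    db = db_prefix or (subject + ".db")
    ev = f"{evalue:g}"
    th = str(threads)

    if program == "blastp":
        if sensitivity is not None:
            raise ValueError("blastp has no sensitivity option")
        dbc = ("makeblastdb", "-in", subject, "-dbtype", "prot", "-out", db)
        search = (
            "blastp", "-query", query, "-db", db, "-out", out,
            "-evalue", ev, "-num_threads", th,
            "-soft_masking", "true", "-seg", "yes", "-use_sw_tback",
            "-outfmt", "6 " + BLAST6EXT_COLUMNS,
        )
        return CommandSpec(program, dbc, search, "blast6ext")

    if program == "lastal":
        if sensitivity is not None:
            raise ValueError("lastal has no sensitivity option")
        # lastdb -c masks lowercase (soft-masking); -p = protein
        dbc = ("lastdb", "-p", "-c", db, subject)
        search = (
            "lastal", "-P", th, "-D", f"{1.0 / evalue:g}", "-f", "TAB", db, query,
        )
        return CommandSpec(program, dbc, search, "last_tab")

    if program == "diamond":
        sens = sensitivity or "very-sensitive"
        if sens not in DIAMOND_SENSITIVITIES:
            raise ValueError(
                f"unknown diamond sensitivity {sens!r}; expected one of "
                f"{DIAMOND_SENSITIVITIES}"
            )
        dbc = ("diamond", "makedb", "--in", subject, "-d", db)
        search = (
            "diamond", "blastp", "--query", query, "--db", db, "--out", out,
            "--evalue", ev, "--threads", th, "--masking", "0",
            f"--{sens}", "--outfmt", "6", *BLAST6EXT_COLUMNS.split(),
        )
        return CommandSpec(program, dbc, search, "blast6ext")

    # mmseqs
    sens = 5.7 if sensitivity is None else float(sensitivity)
    if not (1.0 <= sens <= 7.5):
        raise ValueError("mmseqs sensitivity must lie in [1.0, 7.5]")
    dbc = ("mmseqs", "createdb", subject, db)
    search = (
        "mmseqs", "easy-search", query, subject, out, out + ".tmp",
        "-s", f"{sens:g}", "-e", ev, "--threads", th,
        "--format-output",
        "query,target,fident,alnlen,mismatch,gapopen,"
        "qstart,qend,tstart,tend,evalue,bits,qlen,tlen",
    )
    return CommandSpec(program, dbc, search, "mmseqs_tab")
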