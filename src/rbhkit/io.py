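"""Readers and writers for proteome FASTA, gene-locus tables and hit tables.

Hit tables come in four tabular dialects, all normalized to :class:`~rbhkit.align.Hit`:

``blast6``
    the 12 standard BLAST ``-outfmt 6`` columns (qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore); sequence
    lengths must then be resolved from the proteomes.
``blast6ext``
    blast6 plus ``qlen slen`` (the toolkit's normal form).
``last_tab``
    LAST's tab format (raw score, 0-based starts, ``E=`` field); bit scores
    are derived from the raw score via the scoring scheme.
``mmseqs_tab``
    mmseqs2 ``easy-search`` default columns (identity as a fraction);
    ``qlen``/``tlen`` columns are used when present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

from Bio import SeqIO

from .align import Hit, HitTable, ScoringScheme

_AMINO = set("ACDEFGHIKLMNPQRSTVWY")
_TOLERATED = _AMINO | set("X*-")


@dataclass(frozen=True)
class ProteinRecord:
    """One annotated protein: id, owning gene, and amino-acid sequence."""

    protein_id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.protein_id!r}")
        if not self.gene_id:
            object.__setattr__(self, "gene_id", self.protein_id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """Position of a gene along its replicon (0-based consecutive rank)."""

    genome_id: str
    replicon_id: str
    index: int
    strand: str
    gene_id: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"unknown strand {self.strand!r} for gene {self.gene_id!r}"
            )
        if self.index < 0:
            raise ValueError("locus index must be >= 0")


def read_fasta(path: Union[str, Path]) -> List[ProteinRecord]:
    """Parse a protein FASTA file.

    The protein id is the first whitespace-delimited header token; a
    ``gene=`` tag in the description, if present, supplies the gene id.
    A trailing ``*`` (stop) is stripped silently; other characters outside
    the 20 standard amino acids plus ``X``/``*``/``-`` are an error, as are
    duplicate protein ids.
    """
    path = Path(path)
    records: List[ProteinRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        bad = set(seq) - _TOLERATED
        if bad:
            raise ValueError(
                f"non-amino-acid characters {sorted(bad)} in {pid!r} ({path})"
            )
        gene_id = ""
        for token in rec.description.split():
            if token.startswith("gene="):
                gene_id = token[5:]
                break
        records.append(ProteinRecord(protein_id=pid, sequence=seq, gene_id=gene_id))
    if not records:
        warnings.warn(f"no FASTA records found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for r in records:
            tag = f" gene={r.gene_id}" if r.gene_id != r.protein_id else ""
            fh.write(f">{r.protein_id}{tag}\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def read_dna_fasta(path: Union[str, Path]) -> List[Tuple[str, str]]:
    """DNA FASTA as (record id, uppercase sequence) pairs, order preserved."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def one_protein_per_gene(records: Sequence[ProteinRecord]) -> List[ProteinRecord]:
    """Collapse isoforms: keep one protein per gene.

    Eukaryotic annotation often carries several proteins per gene (splice
    isoforms); downstream orthology wants exactly one.  The longest isoform
    is kept, ties broken by lexicographically smallest protein id.  Input
    order of the retained genes is preserved.
    """
    best: Dict[str, ProteinRecord] = {}
    order: List[str] = []
    for rec in records:
        cur = best.get(rec.gene_id)
        if cur is None:
            best[rec.gene_id] = rec
            order.append(rec.gene_id)
        elif (rec.length, _neg_lex(rec.protein_id)) > (cur.length, _neg_lex(cur.protein_id)):
            best[rec.gene_id] = rec
    return [best[g] for g in order]


class _neg_lex(str):
    """Orders strings in reverse, so max() picks the lexicographically smallest."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Gene locus tables
# ---------------------------------------------------------------------------

LOCUS_COLUMNS = ("genome_id", "replicon_id", "index", "strand", "gene_id", "protein_id")


def read_loci(
    path: Union[str, Path],
    dialect: str = "tsv",
    genome_id: Optional[str] = None,
) -> List[GeneLocus]:
    """Read gene loci from a TSV table or a GFF3 file.

    Whatever the input coordinates, loci are re-ranked so that ``index`` is
    0-based and consecutive within each replicon, in coordinate order (GFF3
    start positions ascending; TSV by its ``index`` column).
    """
    if dialect == "tsv":
        raw = _read_loci_tsv(Path(path))
    elif dialect == "gff3":
        raw = _read_loci_gff3(Path(path), genome_id or Path(path).stem)
    else:
        raise ValueError(f"unknown locus dialect {dialect!r}")

    by_replicon: Dict[Tuple[str, str], List[Tuple[float, GeneLocus]]] = {}
    for sort_key, locus in raw:
        by_replicon.setdefault((locus.genome_id, locus.replicon_id), []).append(
            (sort_key, locus)
        )
    out: List[GeneLocus] = []
    seen_proteins: Dict[str, str] = {}
    for key in sorted(by_replicon):
        entries = sorted(by_replicon[key], key=lambda t: t[0])
        for rank, (_, locus) in enumerate(entries):
            if locus.protein_id in seen_proteins:
                raise ValueError(
                    f"protein {locus.protein_id!r} mapped to two loci in {path}"
                )
            seen_proteins[locus.protein_id] = locus.replicon_id
            out.append(
                GeneLocus(
                    genome_id=locus.genome_id,
                    replicon_id=locus.replicon_id,
                    index=rank,
                    strand=locus.strand,
                    gene_id=locus.gene_id,
                    protein_id=locus.protein_id,
                )
            )
    return out


def _read_loci_tsv(path: Path) -> List[Tuple[float, GeneLocus]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != LOCUS_COLUMNS:
            raise ValueError(
                f"{path}: expected header {LOCUS_COLUMNS}, got {tuple(header)}"
            )
        out = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(LOCUS_COLUMNS):
                raise ValueError(f"{path}:{lineno}: expected {len(LOCUS_COLUMNS)} columns")
            genome, replicon, index, strand, gene, protein = parts
            locus = GeneLocus(genome, replicon, int(index), strand, gene, protein)
            out.append((float(index), locus))
    return out


def _read_loci_gff3(path: Path, genome_id: str) -> List[Tuple[float, GeneLocus]]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feature_types = set(db.featuretypes())
    ftype = "CDS" if "CDS" in feature_types else "gene"
    out: List[Tuple[float, GeneLocus]] = []
    for feat in db.features_of_type(ftype):
        protein = _first_attr(feat, ("protein_id", "ID"))
        gene = _first_attr(feat, ("gene", "locus_tag", "Parent", "ID"))
        if protein is None:
            raise ValueError(f"{path}: {ftype} feature without protein_id/ID attribute")
        locus = GeneLocus(
            genome_id=genome_id,
            replicon_id=feat.seqid,
            index=0,
            strand=feat.strand,
            gene_id=gene or protein,
            protein_id=protein,
        )
        out.append((float(feat.start), locus))
    return out


def _first_attr(feat, names) -> Optional[str]:
    for name in names:
        if name in feat.attributes:
            return feat.attributes[name][0]
    return None


def write_loci(loci: Iterable[GeneLocus], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(LOCUS_COLUMNS) + "\n")
        for l in loci:
            fh.write(
                f"{l.genome_id}\t{l.replicon_id}\t{l.index}\t{l.strand}\t"
                f"{l.gene_id}\t{l.protein_id}\n"
            )


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

HIT_DIALECTS = ("blast6", "blast6ext", "last_tab", "mmseqs_tab")


def _length_map(proteome) -> Dict[str, int]:
    if isinstance(proteome, Mapping):
        return dict(proteome)
    return {r.protein_id: r.length for r in proteome}


def read_hit_table(
    path: Union[str, Path],
    dialect: str = "blast6ext",
    query_proteome=None,
    target_proteome=None,
    query_genome: str = "",
    target_genome: str = "",
    scheme: Optional[ScoringScheme] = None,
) -> HitTable:
    """Read a tabular alignment file and normalize it to :class:`HitTable`.

    ``query_proteome``/``target_proteome`` (records or ``{id: length}`` maps)
    are required for dialects that do not carry sequence lengths.
    """
    if dialect not in HIT_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {HIT_DIALECTS}")
    qlen = _length_map(query_proteome) if query_proteome is not None else None
    slen = _length_map(target_proteome) if target_proteome is not None else None
    hits: List[Hit] = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                hits.append(
                    _parse_hit_line(line, dialect, qlen, slen, scheme)
                )
            except _LengthsUnavailable:
                raise ValueError(
                    f"{path}:{lineno}: lengths unavailable — dialect {dialect!r} "
                    "carries no qlen/slen; supply the proteomes"
                ) from None
            except Exception as exc:
                raise ValueError(f"{path}:{lineno}: malformed line ({exc})") from exc
    return HitTable(query_genome, target_genome, hits)


class _LengthsUnavailable(Exception):
    pass


def _resolve_len(lengths: Optional[Dict[str, int]], key: str) -> int:
    if lengths is None:
        raise _LengthsUnavailable()
    if key not in lengths:
        raise _LengthsUnavailable()
    return lengths[key]


def _parse_hit_line(line, dialect, qlen, slen, scheme) -> Hit:
    parts = line.split("\t")
    if dialect in ("blast6", "blast6ext", "mmseqs_tab"):
        n_expected = {"blast6": 12, "blast6ext": 14}.get(dialect)
        if dialect == "mmseqs_tab":
            if len(parts) not in (12, 14):
                raise ValueError(f"expected 12 or 14 columns, got {len(parts)}")
        elif len(parts) != n_expected:
            raise ValueError(f"expected {n_expected} columns, got {len(parts)}")
        (q, s, ident, _length, _mm, _go, qs, qe, ss, se, ev, bits) = parts[:12]
        if len(parts) == 14:
            ql, sl = int(parts[12]), int(parts[13])
        else:
            ql = _resolve_len(qlen, q)
            sl = _resolve_len(slen, s)
        identity = float(ident)
        if dialect != "mmseqs_tab":
            identity /= 100.0
        return Hit(
            query_id=q, subject_id=s, bits=float(bits), evalue=float(ev),
            q_start=int(qs), q_end=int(qe), s_start=int(ss), s_end=int(se),
            q_len=ql, s_len=sl, identity_frac=identity,
        )

    # last_tab: score name1 start1 alnSize1 strand1 seqSize1
    #                 name2 start2 alnSize2 strand2 seqSize2 blocks [EG2= E=]
    if len(parts) < 12:
        raise ValueError(f"expected >= 12 columns, got {len(parts)}")
    score = int(parts[0])
    s, s0, s_aln, _s_strand, s_size = parts[1], int(parts[2]), int(parts[3]), parts[4], int(parts[5])
    q, q0, q_aln, _q_strand, q_size = parts[6], int(parts[7]), int(parts[8]), parts[9], int(parts[10])
    scheme = scheme or ScoringScheme()
    bits = scheme.bits_from_raw(score)
    evalue = None
    for extra in parts[12:]:
        if extra.startswith("E="):
            evalue = float(extra[2:])
    if evalue is None:
        evalue = scheme.evalue_from_bits(bits, q_size, s_size)
    return Hit(
        query_id=q, subject_id=s, bits=bits, evalue=evalue,
        q_start=q0 + 1, q_end=q0 + q_aln, s_start=s0 + 1, s_end=s0 + s_aln,
        q_len=q_size, s_len=s_size, raw_score=score,
    )


def write_hit_table(
    table: HitTable, path: Union[str, Path], dialect: str = "blast6ext"
) -> None:
    """Write a hit table; ``blast6ext`` (the 14-column form) is lossless."""
    if dialect not in ("blast6", "blast6ext"):
        raise ValueError("writing supports the blast6/blast6ext dialects only")
    with open(path, "w") as fh:
        for h in table.hits:
            ident = h.identity_frac * 100.0
            aln = max(h.q_end - h.q_start, h.s_end - h.s_start) + 1
            fields = [
                h.query_id, h.subject_id,
                repr(ident) if ident == ident else "nan",
                str(aln), "0", "0",
                str(h.q_start), str(h.q_end), str(h.s_start), str(h.s_end),
                repr(h.evalue), repr(h.bits),
            ]
            if dialect == "blast6ext":
                fields += [str(h.q_len), str(h.s_len)]
            fh.write("\t".join(fields) + "\n")
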