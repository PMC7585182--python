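# rbhkit

Reciprocal-best-hit ortholog inference and evaluation for pairs of
proteomes, with a built-in synthetic-genome simulator so every stage can be
tested against planted ground truth.

## What it does, and for whom

Comparative genomicists routinely infer orthologs between two genomes as
**reciprocal best hits (RBH)**: protein *a* of genome A and protein *b* of
genome B are called orthologs when each is the other's highest-scoring match
in an all-against-all protein comparison, after discarding weak alignments.
`rbhkit` implements that pipeline and the two statistics most used to judge
its output:

* **Filters.** A hit survives when its e-value ≤ 10⁻⁶ and the alignment
  covers ≥ 60% of the shorter protein (both boundaries inclusive).
* **Genomic Similarity Score.** For an RBH set,

  GSS = compScore / selfScore = Σ bits(a,b) / Σ bits(self)

  where the numerator sums the cross bit scores of all RBH pairs (both
  directions) and the denominator the members' self-alignment bit scores.
  GSS ≈ 1 for near-identical proteome pairs and decays with divergence.
* **Conserved-adjacency error rate.** If genes *a*, *b* are neighbors in
  genome A and homologs *a′*, *b′* are neighbors in genome B, an ortholog
  call for *a*–*a′* predicts one for *b*–*b′*. Confirmations count toward
  *O*; a homologous-but-not-RBH (paralogous) pair found instead counts
  toward *P*. The error estimate is **E = P / (P + O)**.

Around this core the package provides: a normalizing reader for the tabular
outputs of blastp / LAST / DIAMOND / MMseqs2 (and command builders with the
standard options: soft-masking and final Smith-Waterman where available, no
masking for DIAMOND, `-s 5.7` for MMseqs2, `--very-sensitive` for DIAMOND);
an exact Smith-Waterman engine (BLOSUM62, affine gaps 11/1, Karlin-Altschul
bits and e-values) so nothing external is ever required; one-protein-per-gene
proteome cleanup; genome de-redundancy by trinucleotide-signature
δ-distance clustering (cutoff 0.04 ≈ species level); UpSet-style
intersection reports across methods; and a simulator that plants ortholog /
paralog truth, tunable divergence, gene-order rearrangement and
clade-specific codon usage.

## Worked example

```python
import rbhkit as rk

cfg = rk.SimulationConfig(n_genes=50, divergence=0.1, seed=42)
bundle = rk.simulate_pair(cfg)                      # genome pair + truth
res = rk.find_orthologs(bundle.proteome_a, bundle.proteome_b)
print("RBH pairs:", len(res.rbh))

score = rk.gss(res.rbh, res.self_bits)
print("GSS:", round(score.gss, 4))

cases = rk.conserved_adjacencies(
    bundle.loci_a, bundle.loci_b, res.filtered_ab, res.filtered_ba, res.rbh
)
est = rk.error_rate(cases, res.rbh)
print(f"O={est.O} P={est.P} E={est.E}")
```

prints

```
RBH pairs: 50
GSS: 0.8942
O=49 P=0 E=0.0
```

All 50 planted orthologs are recovered despite 10% per-residue divergence;
the GSS of 0.894 quantifies that divergence; and all 49 testable gene-order
adjacencies confirm the calls, so the estimated error rate is zero.

The same pipeline is available from the shell:

```sh
rbhkit simulate --genes 50 --divergence 0.1 --seed 42 --out sim/
rbhkit rbh --a sim/proteome_a.faa --b sim/proteome_b.faa --out run/
rbhkit evaluate gss --rbh run/rbh.tsv \
    --proteome-a sim/proteome_a.faa --proteome-b sim/proteome_b.faa --out run/
rbhkit dedup genome1.fna genome2.fna --cutoff 0.04 --out clusters/
```

## Layout

| module | contents |
| --- | --- |
| `rbhkit.io` | FASTA / locus-table (TSV, GFF3) / hit-table dialects, isoform cleanup |
| `rbhkit.align` | Smith-Waterman engine, bit/e-value statistics, external command builders |
| `rbhkit.rbh` | filters, best-hit selection, reciprocal intersection |
| `rbhkit.evaluate` | GSS, conserved-adjacency error rate, intersection reports |
| `rbhkit.signature` | trinucleotide signatures, δ-distance, single-linkage clustering |
| `rbhkit.simulate` | genome-pair simulator with planted truth |
| `rbhkit.cli` | `rbhkit` console entry point |

See `docs/methods.md` for the model, parameter and design details.
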