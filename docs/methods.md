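# Methods

This note records the models, conventions and numerical choices behind
`rbhkit`, in the order the pipeline uses them, together with what the
synthetic data can and cannot demonstrate.

## Alignment engine and score statistics

The built-in engine computes the exact best local alignment of two proteins
(Smith-Waterman with affine gaps, Gotoh recurrences) under BLOSUM62 with gap
open 11 and extend 1; a gap of length L costs 11 + L, matching NCBI BLAST's
`-gapopen 11 -gapextend 1`. Only the single best alignment is reported per
pair — one HSP per hit, mirroring the one-line-per-pair tabular outputs the
pipeline consumes from external tools. Raw scores are converted with the
standard gapped Karlin-Altschul parameters for this scoring system,
λ = 0.267 and K = 0.041:

    bits   = (λ·S − ln K) / ln 2
    evalue = m·n · 2^(−bits)

The search space is the plain per-pair product m·n, not a database-wide
effective length: the 10⁻⁶ filter is defined relative to this e-value for
built-in hits, while hit tables imported from external tools keep the
e-values those tools printed. Consequences worth knowing: bit scores are
strictly increasing in raw score, e-values strictly decreasing in bits, and
for any two proteins the cross bit score cannot exceed either self score
(BLOSUM62 satisfies s(x,y) ≤ min(s(x,x), s(y,y))), which is what bounds the
GSS by 1 when scores come from the built-in engine.

Traceback ties prefer the diagonal move, then the vertical, then the
horizontal, and gap closure over gap extension; this affects only the
reported coordinates, never the score. When several cells attain the
maximal score the first one in row-major order is used. `X` is scored
through the matrix's own X row; `*` and `-` are rejected as non-residues.
Self scores are taken as the diagonal sum (exact whenever every residue has
a positive self score) with a fall-back to the full aligner otherwise, and
the two routes are asserted equal in the tests.

Because alignment scores are symmetric, the all-against-all step aligns
each unordered pair once and mirrors the hit into the opposite direction.
A score-only linear-memory pass (numba-compiled) scores all pairs; the full
traceback runs only for pairs that beat the e-value cap.

## Filters and RBH selection

A hit survives filtering when `evalue ≤ 1e-6` **and** the alignment spans
at least 60% of the shorter protein. Both boundaries are inclusive, chosen
to match blastp's `-evalue` semantics, since the thresholds themselves are
stated without strictness. Coverage is measured on the span belonging to
the shorter protein (query side on equal lengths), from the single HSP.

Per query the best hit maximizes bits, with a deterministic tie cascade:
lower e-value, then higher identity fraction, then lexicographically
smallest subject id. Ties at the top bit score are flagged on the resulting
pair (`tie_flag`) rather than discarding the query, keeping output stable
under row reordering while preserving an audit trail. Hit sources that emit
several rows per (query, subject) pair are deduplicated to the
highest-scoring row first. Self-hits are excluded only when a proteome is
compared against itself. An RBH pair requires mutual best-ness in the two
independently filtered directions; each protein appears in at most one
pair, and the output is sorted by the A-side id. Dialects that do not
report identities (LAST's tab format) rank below any real identity in the
tie cascade; their bit scores are derived from the raw score via the
scheme's λ and K.

## Genomic Similarity Score

GSS = compScore / selfScore, where compScore sums the bit scores of all RBH
pairs in **both** directions and selfScore the self-alignment bits of both
members. Using both directions makes the statistic symmetric in the two
genomes; using one direction would change nothing at the limit (identical
proteomes still give exactly 1) and little elsewhere, since the two
directional bit scores of one pair are equal under the built-in engine.
Both sums are accumulated in the same term order so that the identical-pair
limit is exact in floating point, not approximate. Self scores must come
from a single source (built-in scorer or a self-comparison hit table);
mixing sources inside one GSS is refused. GSS is undefined (an error) for
an empty RBH set.

## Conserved-adjacency error rate

Gene order provides an internal quality check: for genes *a*, *b* at
consecutive ranks on one replicon of genome A, and filtered homologs *a′*,
*b′* at consecutive ranks in genome B, an RBH call for one pair predicts an
RBH call for the other. The enumerator emits each unordered quadruple
(a, b, a′, b′) once, requiring at least one of the two pairs to be an RBH.
Scoring: both pairs RBH → one confirmation (O, counted once, not twice);
exactly one RBH → the other pair is homologous yet not the RBH partner,
i.e. a paralog found where an ortholog was expected → one mistake (P).
E = P/(P+O); when no quadruple is testable the estimate is returned flagged
as undefined rather than raising.

Adjacency means rank difference 1 on the same replicon, ignoring strand and
intergenic distance; replicon ends do not wrap by default (a `circular`
flag adds the wrap adjacency). "Paralog" is operationalized as *filtered
homolog that is not the RBH partner*, consistent with RBH being the
pipeline's orthology definition. Known bias, visible in simulations: a
duplicate inserted by chance next to a true ortholog can create a quadruple
whose non-anchor side is necessarily paralogous, so E slightly overestimates
the planted mis-assignment rate (by a few hundredths at the default
simulation sizes); and when *both* genes of a junction are mis-assigned
consistently, no anchor survives and the estimator never sees the junction.

## Genome signatures and de-redundancy

A genome's signature is the frequency vector of overlapping trinucleotides
(k configurable, default 3) counted on the sequence and its reverse
complement, so the vector is strand-invariant; windows containing non-ACGT
characters are skipped, multi-record FASTA files are pooled. The distance is
the total-variation form δ(x,y) = ½·Σ|xᵢ−yᵢ| ∈ [0,1] — symmetric, zero on
identity, triangle inequality (property-tested). The published cutoff scale
(0.04) was defined for a related but not fully specified normalization, so
the cutoff is an exposed parameter rather than a constant: users can
recalibrate if their signature variant differs. Clusters are single-linkage
components of the δ ≤ cutoff graph — the minimal assumption that turns a
pairwise cutoff into a partition — and each cluster is represented by its
member with the most annotated proteins (ties: more counted windows, then
smallest id).

## Synthetic data

The generator is the package's test bed, not an afterthought. An ancestral
proteome of `n_genes` random sequences (uniform over the 20 amino acids,
lengths uniform in 80–400 residues by default) becomes genome A unchanged.
Genome B applies, in order: (i) per-residue substitution with probability
`divergence`, the replacement drawn from BLOSUM62-conditional weights
(∝ exp(0.3176·s(r,r′)), the ungapped λ) so that simulated drift degrades
scores the way real divergence does — a uniform-replacement mode exists as
a flag; (ii) duplications with probability `p_dup` per gene, the copy
diverging independently by the same rate and inserted at a random rank;
(iii) losses with probability `p_loss`; (iv) `n_inversions` random
segment reversals of gene order with strand flips. Truth: surviving
ancestor–descendant pairs are orthologs; duplicates are paralogs and never
enter the truth set. Ids encode ancestry (`anc0017_a`, `anc0017_b`,
`anc0017.dup1_b`). Indels are available (`indel_rate`, default 0) but off
by default so the coverage filter is stressed only by substitutions.

Per-gene random streams are split so that divergence ladders are *nested*:
raising d adds substituted positions without changing earlier ones or any
duplication/loss/inversion events. That is what licenses the strict
monotonicity checks (GSS strictly decreasing in d) on a single seed rather
than on averages.

`plant_confusable_paralogs` creates the exact error mode the adjacency
estimator is meant to catch. For a fraction q of duplicated genes, the
B-side ortholog's sequence is replaced by a *further-diverged copy of its
paralog's* sequence, so the paralog becomes the strictly higher-scoring
partner of the A-side gene while truth labels stay put. (A verbatim copy
would only tie the two scores, because the duplicate's sequence derives
from the ortholog's; the extra divergence makes the displacement strict and
deterministic.) The planted gene set is recorded so estimator output can be
compared with the planted mis-assignment rate among testable junctions.

Back-translation uses the standard genetic code with a per-genome
synonymous codon preference: each amino acid's codon distribution is
(1−s)·uniform + s·point-mass on a preferred codon chosen per clade, with
`codon_skew` s ∈ [0,1) (default 0.5 — a visible but not extreme bias).
Clademates share the preference table, which separates clades in
trinucleotide space (at the default sizes, within-clade δ ≈ 0.03 versus
between-clade δ ≈ 0.1–0.16) while every genome keeps its own random gene
content.

What the simulator does **not** model: insertions/deletions by default,
multi-domain and low-complexity proteins, horizontal transfer, multi-replicon
genomes, gene conversion, or phylogenetically structured multi-lineage
divergence. Passing tests therefore demonstrate the correctness and internal
calibration of the pipeline's logic, not its behavior on the full complexity
of real proteomes — in particular, real eukaryotic paralogy is far messier
than the single-duplication families planted here.

## Problem sizes and numerics

The test and reproduction runs use 150–200 genes per genome (about
20,000–40,000 pairwise alignments per comparison), 80 genes for the
error-rate studies, and 3 clades × 5 genomes for clustering — sizes chosen
so the whole suite exercises every end-to-end path in about a minute on one
CPU while leaving no statistic at the mercy of a handful of events.
Alignment kernels are numba-compiled; scores are integers throughout the
DP, so no tolerance questions arise there. Float comparisons in tests use
exact equality only where the arithmetic is genuinely identical (the d = 0
GSS limit, score mirroring) and small absolute tolerances (1e-9 … 1e-12)
elsewhere. The error-estimator calibration tolerance (±0.1 against the
planted rate) reflects the duplicate-adjacency bias described above plus
counting noise at ~40 testable junctions.

## External tools

blastp, lastal, diamond and mmseqs are supported strictly as *command
builders* plus hit-table readers: the toolkit composes argument vectors
with the standard options (tabular output with lengths where supported,
e-value pre-filter 10⁻⁶, soft-masking for blastp/lastal/mmseqs, no masking
for diamond, Smith-Waterman final alignment where offered, `-s 5.7` default
for mmseqs, `--very-sensitive` default for diamond) and normalizes their
outputs, but never invokes a binary itself; no test depends on any of them
being installed. Runtimes of CLI commands are recorded in each run's
manifest for bookkeeping only.
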