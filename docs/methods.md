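# Methods

## Scope and model

`transcurate` curates the *output* of de novo transcriptome assembly; it
does not assemble reads, run external aligners, or query annotation
databases. Its inputs are the field's exchange formats: contig FASTA
(one file per assembly or caste), 12-column tabular local-alignment
hits, spliced alignments in the GFF3 `match`/`match_part` dialect, gene
models in GFF3, a subject-to-taxon table, and GO annotation tables. All
internal interval arithmetic is 0-based half-open; 1-based inclusive
coordinates exist only at the I/O boundary.

## Redundancy collapse

Two sequences are mergeable when their best overlap alignment satisfies
both thresholds (contigs: ≥ 100 aligned columns at ≥ 95% identity;
proteins: ≥ 90% identity over ≥ 90% of the shorter sequence). Identity
is matches / aligned columns, with internal gap columns in the
denominator and terminal overhangs excluded; this convention must be
fixed for threshold comparisons and is stated here so users can match
other tools. Nucleotide comparisons evaluate both orientations, since
de novo contigs have arbitrary strand. Clusters are the transitive
closure of mergeability (single linkage), which matches non-redundant
set semantics. The representative is the longest member (ties:
lexicographically smallest id). A column-wise consensus would require a
multiple alignment; since the step is redundancy removal, the longest
member is a deterministic and testable stand-in.

Two alignment routes exist: a seeded default (shared exact k-mers, k=15
nt / 5 aa, vote for a diagonal band of width 32; the implied overlap
window is then aligned with edlib, allowing gaps) and a full
dynamic-programming local-alignment oracle (match +1, mismatch −1, gap
open −2, extend −1). The oracle is the independent cross-check: tests
assert that both routes produce identical clusterings on random sets
with planted near-duplicates, reverse-complement copies and fragments.
The seeded route skips the reverse orientation when the forward
alignment already matches ≥ 95% of the shorter sequence, which cannot
change a merge decision. The protein-overlap fraction is measured
against the shorter sequence; whether a 90%-overlap rule should be
relative to the shorter or the longer sequence is genuinely open, so
"shorter" — the permissive reading — is the default and the fraction is
an exposed parameter.

## Evidence classification

A hit is evidence iff e-value ≤ 1e−3 AND identity ≥ 70% AND aligned
length ≥ 33 aa (100 bases); all minima are inclusive, the e-value
maximum is inclusive. For nucleotide-vs-nucleotide hit tables the 100-nt
figure applies (`units="nt"`). Classification precedence is
micro-organism > ant > other insect > unannotated, regardless of bit
score: exogenous material is screened out *first*, mirroring the
published workflow's database tiering; a best-hit-wins mode is available
behind a flag. Report percentages are computed over the length-passing
total and rounded half-up to one decimal, matching how such tables are
printed. Note that with the published counts the micro-organism class is
1.5% of the *length-filtered* total (120,212), not of the full merged
assembly; the length-filtered denominator is used throughout.

## Gene grouping and isoforms

Gene assignment scores a contig against a gene as the sum over alignment
blocks of identity-weighted bases overlapping the gene's exons, and
takes the argmax (ties: smallest gene id, logged). Identity weighting
prevents long, low-identity blocks from outvoting short exact ones.
Overlapping reference gene models are rejected at load — the argmax is
ill-defined otherwise. Alignments overlapping no model are reported as
unplaced, never invented as novel genes.

The consensus exon model is the interval union of the reference exons
and all assigned blocks, after snapping block boundaries within
`isoform_boundary_tol` (default 6 nt; 0 in clean-data tests) of a model
boundary. The default absorbs aligner jitter without merging genuine
alternative splice sites, which are rarely closer than 6 nt. A contig's
exon chain is the ordered set of consensus exons it overlaps. Two chains
conflict iff, restricted to their shared span of exon indices, one skips
an exon the other includes; disjoint spans are compatible, which is what
joins non-overlapping fragments of one transcript. Groups are built
longest-chain-first; a chain joins a group only if compatible with every
member, and when several groups qualify it attaches to the largest, then
the one with the smallest label chain — deterministic, and biased toward
fewer (conservative) isoforms. The unigene is the longest assigned
contig per gene (ties: smallest id). Isoform summary statistics
(mean/sd/range) are over multi-isoform genes only, with the sample
standard deviation; for an all-singlet input they are reported as
absent, not zero.

## Internal spliced mapper

`unigene.splice_map` is an exact-k-mer (k=21) chaining aligner over a
genome index: same-diagonal seed runs within 64 bp are bridged (block
identity recomputed by direct comparison), and a quadratic DP selects
the best colinear chain, allowing ≤ k overlap between consecutive blocks
(seed runs can overrun a splice junction by chance-matching bases) which
is trimmed afterwards. Both orientations are tried; minus-strand block
contig coordinates refer to the reverse-complemented contig. This mapper
is built for high-identity synthetic data and small fixtures; aligning
diverged transcripts across a deep species split is the job of a real
spliced aligner, whose GFF3 output the pipeline consumes directly.

## Caste and GO comparisons

The caste presence matrix marks a gene present in a caste when at least
one pre-collapse contig from that caste's assembly belongs to a cluster
whose representative was assigned to the gene — presence survives
redundancy collapse via the cluster map. Venn regions are enumerated
exhaustively (≤ 6 castes) and checked against per-gene brute force.

GO frequency tables count genes per term within each category; a gene
contributes to every term it carries, so percentages are of the
category's summed counts. Profiles are compared with a paired t-test
over the per-term percentage differences restricted to shared terms
(df = shared terms − 1, two-sided p). The pairing is an inference from
the degrees-of-freedom arithmetic of the published comparisons (df 11,
16, 9 match plausible shared-term counts minus one); an unpaired Welch
option exists behind a flag. Terms are compared as annotated, with no
ancestor propagation up the ontology graph.

## Synthetic data

The generator emulates the structure the pipeline assumes: multi-exon
genes separated by ≥ 200 bp spacers on one chromosome; isoforms by
internal-exon skipping only (every chain keeps the terminal exons, so
distinct chains always conflict and per-gene isoform counts are exactly
recoverable on clean data); per-transcript redundant copies with
per-base SNP (default 0.01) and single-base indel (default 0.002)
jitter, standing in for multi-k-mer re-assembly of genetically variable
pooled RNA; optional fragmentation of a transcript into two disjoint
exon-chain pieces (default probability 0.1); random contaminant
sequences labelled micro-organism; and a per-gene caste mask
(three castes, dropout 0.1, redrawn so every gene is expressed
somewhere). Hit tables are derived from the truth (identity = 1 −
observed mutation load, length in residues), so the evidence thresholds
are exercised without an external aligner. Default geometry — 3–6 exons
of 100–200 bp, introns 60–150 bp, 1–3 isoforms, 2–4 copies — is chosen
so a skipped exon always drops dovetail identity below the 95% merge
threshold; with larger exon-to-transcript ratios the collapse would
absorb true splice variants, the same caveat the real pipeline carries.

What the simulation does *not* model: sequencing reads and coverage,
expression levels, alternative 5′/3′ splice sites, chimeric contigs,
genuinely diverged orthologs, or taxonomically restricted genes. Passing
tests therefore demonstrate that the *logic* of each stage is exactly
invertible under its own assumptions and robust to point-mutation
jitter, not that the thresholds are optimal for any particular real
dataset.

## Problem sizes and numerical choices

End-to-end checks run at 200 genes (≈ 3,000–3,500 contigs): one clean
run asserting exact recovery of gene count, per-gene isoform counts and
caste-unique sets, and ten independent 1%-SNP replicates asserting
≥ 95% gene-count recovery; these sizes keep the whole suite and the
acceptance script to a few minutes on one CPU while leaving every
cluster, chain and Venn region non-trivial. Percent rounding is half-up
(decimal arithmetic, not banker's rounding). N50 returns the largest
qualifying length when several satisfy the definition. Reference-protein
coverage pools the subject-interval union across all passing contigs per
protein (the plural "represented by transcripts" reading); a
single-best-contig mode exists for sensitivity analysis, and the
≥ 90%-covered class uses a closed lower bound.

## Known limitations

The seeded overlap route estimates the overlap window from one diagonal
band; overlaps with very large internal indels may be under-aligned
(the oracle route has no such limit). `read_spliced_gff3` supports the
match/cDNA_match/EST_match + match_part dialects only. The compatibility
grouping can under-count isoforms when a fragment bridges two otherwise
conflicting chains, and over-counting is possible when true alternative
splice sites are closer than the snapping tolerance. Caste presence is
detection-based: a gene absent from one caste's assembly may simply be
lowly expressed there.
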