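# norvle

Tokenization-based assembly and positional analytics for megabase tandem
arrays of 45S rRNA genes — nucleolus organizer regions (NORs) — from
ultralong noisy reads.

## The problem

A NOR is hundreds of near-identical ~10-kbp rRNA gene repeats in tandem.
The transcribed parts (18S, 5.8S, 25S, the spacers) are essentially
invariant between copies, so ordinary assemblers collapse the locus.
What *does* differ between gene copies is a handful of variable-length
elements (VLEs): the 3'ETS repeat block, the Sal-repeat array of the
intergenic spacer, the spacer-promoter cluster and the 5'ETS repeats.
Each gene copy carries one variant of each VLE, and the permutation of
variants defines the copy's **subtype**.

norvle exploits this: it reduces each ultralong read to a short **token
string** — one subtype (or VLE-call tuple) per gene unit — so a 300-kbp
read becomes ~35 tokens. Token patterns that occur once per genome
(**landmarks**) anchor and order the reads; reads placed through their
landmark offsets vote on each array position's subtype; and a polished
DNA consensus is produced per unit with the positional register fixed by
the unit segmentation. Downstream modules map subtype composition,
local homogeneity (concerted-evolution signal), per-unit variants,
allele-specific expression, nucleolus association and 5mC methylation
onto array coordinates.

For a read *r* segmented into units *u₁…uₖ* at 25S anchors, the token of
unit *u* is

&nbsp;&nbsp;&nbsp;&nbsp;*t(u)* = ( argmin₍v∈V_R₎ d(u_R, v) )₍R ∈ variable regions₎

with *d* the Levenshtein distance and *u_R* the subsequence of *u*
between region *R*'s conserved flanks. A k-gram *p* of tokens is a
landmark when its read-set count *c(p)* satisfies
*c(p)/C_k ≈ 1* (within a tolerance band), where *C_k* is the read-set
coverage corrected for the probability that a read spans *k* consecutive
complete units.

## Worked example

Simulate a small 40-unit locus, tokenize its reads, assemble and
analyze — all from the shell:

```sh
norvle simulate --preset small --seed 3 --out sim/
# simulated 40 units, 235 reads (30.0x) -> sim

norvle tokenize --reads sim/reads.fastq --catalog sim/catalog \
    --model sim/model --out tokens.tsv
# tokenized 227 reads (1242 units) -> tokens.tsv

norvle assemble --tokens tokens.tsv --reads sim/reads.fastq \
    --model sim/model --catalog sim/catalog \
    --expected-genes 40 --no-filter --out asm/
# contig1: 40 units, 324915 bp, read-vs-assembly R^2 = 0.6771

norvle analyze --assembly asm/ --name contig1 --model sim/model --out tracks/
# 40 genes; unit lengths 7625-8844 bp; modal subtype fraction 0.2000 -> tracks
```

Reading the numbers: all 40 gene units were recovered (the count is the
number of 25S anchors in the consensus; lengths are I-PpoI-to-I-PpoI
distances), the most abundant subtype holds 20% of the array, and the
token-pattern frequencies of raw reads agree with the assembly (the R²
is computed through the origin; at 40 units nearly every pattern is
single-copy, which caps this statistic — at the 894-unit scale of a real
NOR it reaches ≥ 0.99, see `tests/test_assembly.py`). The first token
lines show each read unit's strand, 1-based interval and per-region VLE
calls:

```
#read_id   unit_index  strand  start   end     subtype_id  calls
sim000000  0           -       10416   16510   3   ETS3_R=v3;IGS_SAL=v4;IGS_SPP=v3;ETS5_C=v4
sim000000  1           -       2502    10415   17  ETS3_R=v4;IGS_SAL=v1;IGS_SPP=v1;ETS5_C=v4
```

`norvle expression`, `norvle enrich` and `norvle methylome` map RNA
allele frequencies, nucleolus-vs-nuclei VLE enrichment and binned 5mC
onto the assembly; `norvle simulate` also writes the matching input
tables. The same operations are available as library functions
(`norvle.tokenize_read`, `norvle.find_landmarks`,
`norvle.tagged_consensus`, …); see `docs/methods.md` for the model and
parameter choices.

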