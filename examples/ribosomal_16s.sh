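#!/usr/bin/env bash
# Batch workflow for comparing 16S ribosomal RNA structures under different
# inhibitors, using Bpseq files the user downloads themselves (e.g. from a
# secondary-structure database).  Not executed in CI: it only documents the
# intended shell usage on real data.
#
#   1. compare the pseudoknot skeletons (shadows) across molecules —
#      identical shadows mean the inhibitors act below the pseudoknot scale;
#   2. zoom into a nucleotide window and compare the cores there;
#   3. search a pattern in each core.
set -euo pipefail

MOLECULES="$@"   # e.g. ./ribosomal_16s.sh mol1.bpseq mol2.bpseq ...

for f in $MOLECULES; do
    echo "== $f shadow =="
    relmat matrix "$f" --level shadow --format tsv
done

# extract a subrange with standard tools first (positions 800-900), e.g.:
#   awk '$1 >= 800 && $1 <= 900' mol1.bpseq | awk '{print NR, $2, ($3>=800 && $3<=900 ? $3-799 : 0)}' > mol1_800_900.bpseq
# then:
# for f in *_800_900.bpseq; do
#     relmat matrix "$f" --level core --format tsv > "${f%.bpseq}.core.tsv"
#     relmat match --target "${f%.bpseq}.core.tsv" --pattern pattern.tsv
# done
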