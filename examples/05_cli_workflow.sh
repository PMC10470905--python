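#!/bin/sh
# Shell workflow: simulate paired data, train gene sets, estimate abundance.
# Each command is a thin wrapper over the library; outputs are plain text.
set -e
workdir=$(mktemp -d)

streak simulate --cells 400 --genes 300 --receptors 3 --seed 11 --out-dir "$workdir/sim"
streak train --rna "$workdir/sim/rna" --adt "$workdir/sim/adt" \
    --set-size 10 --seed 11 --out "$workdir/genesets.tsv"
streak estimate --rna "$workdir/sim/rna" --genesets "$workdir/genesets.tsv" \
    --seed 11 --out "$workdir/estimates.csv"

echo "--- learned gene sets (first lines) ---"
head -n 4 "$workdir/genesets.tsv"
echo "--- estimates (first lines) ---"
head -n 3 "$workdir/estimates.csv" | cut -c1-80
rm -rf "$workdir"
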