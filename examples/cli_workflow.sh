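#!/bin/sh
# Two-pass shell workflow: simulate a labelled benchmark, inspect the
# degree histogram, bin with thresholds, then score against the truth.
set -e

WORK=$(mktemp -d)
cat > "$WORK/community.json" <<'EOF'
{
  "genomes": [
    {"name": "gA", "length": 10000, "depth": 10.0},
    {"name": "gB", "length": 10000, "depth": 10.0}
  ],
  "read_length": {"mean": 200, "sd": 15},
  "error_rate": 0.0,
  "chimera_fraction": 0.0
}
EOF

readbin simulate --genomes "$WORK/community.json" --seed 7 -o "$WORK/bench"
readbin hist -i "$WORK/bench/benchmark.fasta" -b 70 \
    --truth "$WORK/bench/benchmark.truth.tsv" -o "$WORK/hist"
head -5 "$WORK/hist/histogram.tsv"
readbin bin -i "$WORK/bench/benchmark.fasta" -b 70 --min-bin-size 50 \
    --emit-excluded -o "$WORK/bins"
readbin eval --bins "$WORK/bins/reads_manifest.tsv" \
    --truth "$WORK/bench/benchmark.truth.tsv" -b 70 \
    --reads "$WORK/bench/benchmark.fasta" -o "$WORK/scores"
cat "$WORK/scores/recall.tsv"
echo "outputs in $WORK"
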