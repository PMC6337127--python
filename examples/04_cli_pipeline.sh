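#!/usr/bin/env bash
# Full pipeline from the shell: simulate a benchmark, embed the networks,
# train the cascade, rank per-gene label predictions, and cross-validate.
set -euo pipefail
work=$(mktemp -d)

difforest simulate --out-dir "$work/bench" --n-genes 120 --n-labels 6 --n-networks 2 --seed 0

cat > "$work/run.yaml" <<EOF
network_files: ["$work/bench/net0.tsv", "$work/bench/net1.tsv"]
gene_index: "$work/bench/genes.txt"
annotations: "$work/bench/annotations.tsv"
alpha: 0.5
d: 10
folds: 3
threshold: 0.5
seed: 0
out_dir: "$work/run"
cascade:
  n_forests: 2
  n_trees: 25
  early_stopping_rounds: 1
  max_levels: 2
  seed: 7
EOF

difforest embed    --config "$work/run.yaml"
difforest train    --config "$work/run.yaml"
difforest predict  --config "$work/run.yaml"
difforest evaluate --config "$work/run.yaml"

head -5 "$work/run/predictions.tsv"
echo "artifacts in $work/run"
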