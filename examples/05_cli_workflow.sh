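#!/usr/bin/env bash
# End-to-end command-line workflow: simulate -> fit -> predict -> evaluate
# -> select, all driven by one YAML config.  Run from anywhere; writes into
# a temporary directory.
set -euo pipefail
dir=$(mktemp -d)
trap 'rm -rf "$dir"' EXIT

cat > "$dir/config.yaml" <<'EOF'
model:
  copula: clayton
  margins: [poisson, poisson]
  responses: [y1, y2]
boost:
  mstop_max: 150
simulate:
  p: 6
  n_train: 1000
  n_val: 1500
  n_test: 1000
  intercepts: {0: 0.5, 1: 0.5, 2: 0.7}
  coefs:
    0: {1: 0.8}
    1: {2: -0.8}
    2: {3: 0.5}
select:
  copulas: [clayton, gaussian, frank, gumbel]
EOF

copulaboost simulate --config "$dir/config.yaml" --out-prefix "$dir/data" --seed 7
copulaboost fit      --config "$dir/config.yaml" --train "$dir/data_train.csv" \
                     --val "$dir/data_val.csv" --out "$dir/fit.json" --seed 7 2>/dev/null
copulaboost predict  --fit "$dir/fit.json" --data "$dir/data_test.csv" \
                     --what tau --out "$dir/tau.csv"
copulaboost evaluate --fit "$dir/fit.json" --data "$dir/data_test.csv" \
                     --n-samples 300 --out "$dir/metrics.json"
echo "--- held-out metrics ---"
cat "$dir/metrics.json"
echo
copulaboost select   --config "$dir/config.yaml" --train "$dir/data_train.csv" \
                     --val "$dir/data_val.csv" --test "$dir/data_test.csv" \
                     --out "$dir/ranking.csv" --seed 7 2>/dev/null
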