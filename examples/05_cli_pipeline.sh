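#!/usr/bin/env bash
# Full file-based pipeline via the CLI: every stage reads and writes CSV so
# each step can be audited or re-run in isolation.
set -euo pipefail
out=${1:-/tmp/cropcarbon_demo}

cropcarbon simulate --seed 1 --outdir "$out/inputs"
cropcarbon inventory --panel "$out/inputs/activity_panel.csv" \
    --areas "$out/inputs/province_areas.csv" --out "$out/records.csv"
cropcarbon screen --matrix "$out/inputs/indicator_matrix.csv" --seed 1 \
    --out "$out/importance.csv"
cropcarbon downscale --matrix "$out/inputs/indicator_matrix.csv" \
    --report "$out/importance.csv" \
    --counties "$out/inputs/county_covariates.csv" --seed 1 \
    --out "$out/raw_estimates.csv"
cropcarbon adjust --estimates "$out/raw_estimates.csv" \
    --provincial "$out/records.csv" --out "$out/county_estimates.csv"
cropcarbon validate --ours "$out/county_estimates.csv" \
    --reference "$out/inputs/reference.csv" --name synthetic \
    --out "$out/comparison.csv"

echo "artifacts in $out"
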