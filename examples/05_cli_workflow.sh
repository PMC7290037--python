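#!/usr/bin/env bash
# End-to-end command-line workflow: simulate a cohort, fit one subject's
# kernel, predict another subject with it, then cross-validate the cohort.
# Everything lands in a scratch directory printed at the end.
set -euo pipefail

work=$(mktemp -d)
echo "working in $work"

# 1. A 3-subject synthetic cohort at 5% vascular noise.
nvctf simulate --n-subjects 3 --noise-to 0.05 --seed 7 --out-dir "$work/cohort"

# 2. Fit subject 0's kernel (reduced protocol for speed; defaults are 50x3).
nvctf fit \
  --from "$work/cohort/sim-0_from.csv" \
  --to "$work/cohort/sim-0_to.csv" \
  --meta "$work/cohort/sim-0_meta.json" \
  --runs 6 --iterations 2 --seed 1 \
  --out "$work/tf0.json" \
  --log "$work/tf0_runs.csv"
echo "fitted kernel:"
cat "$work/tf0.json"

# 3. Predict subject 1's vascular trace with subject 0's kernel.
nvctf predict \
  --from "$work/cohort/sim-1_from.csv" \
  --to "$work/cohort/sim-1_to.csv" \
  --meta "$work/cohort/sim-1_meta.json" \
  --tf "$work/tf0.json" \
  --out "$work/pred1.csv"

# 4. Full leave-one-out cross-validation and standard-kernel selection.
nvctf crossval \
  --cohort "$work/cohort/manifest.json" \
  --runs 4 --iterations 1 --seed 2 \
  --out "$work/report.json"
echo "cohort report:"
cat "$work/report.json"

echo "artifacts kept in $work"
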