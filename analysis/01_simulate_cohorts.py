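#!/usr/bin/env python
"""Generate the four synthetic study cohorts and write them as TSV.

The four cohorts cross data inequality (2184 vs 320, or 260 vs 260 samples)
with distribution discrepancy (20 DE features + 74 discordant effect signs,
or none). Outputs go to results/cohorts/dataset_<k>/.
"""

import argparse
import dataclasses
from pathlib import Path

from equibench.io import save_cohort, write_manifest
from equibench.study import derive_seeds
from equibench.synth_cohort import generate_cohort, study_config


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1, help="master seed")
    ap.add_argument("--out", type=Path, default=Path("results/cohorts"))
    args = ap.parse_args()

    for dataset in (1, 2, 3, 4):
        cohort_seed, _ = derive_seeds(args.seed, dataset)
        cfg = study_config(dataset, seed=cohort_seed)
        cohort = generate_cohort(cfg)
        out_dir = args.out / f"dataset_{dataset}"
        save_cohort(cohort, out_dir)
        write_manifest(out_dir, "01_simulate_cohorts", dataclasses.asdict(cfg), args.seed)
        n1 = int((cohort.group == 1).sum())
        n2 = int((cohort.group == 2).sum())
        print(
            f"dataset {dataset}: {cohort.n_samples} samples "
            f"({n1} majority / {n2} minority), {cohort.n_features} features, "
            f"{len(cohort.truth['de_indices'])} DE features -> {out_dir}"
        )


if __name__ == "__main__":
    main()
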