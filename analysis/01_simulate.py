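#!/usr/bin/env python
"""Generate the synthetic study the downstream analyses run on.

Emulates the five-arm design (Control, Tenebrio, Buffalo, LPS, Tenebrio+LPS;
8 animals each; 89 variables in six blocks) and plants known discriminators:
four insect-responsive variables (up in both insect groups) and four
inflammation-responsive variables (down under LPS), all at d = 2 SD.  Also
writes a noisy qPCR Ct table for the expression analysis.

Outputs: results/data/{samples,annotations,ct}.csv and the planted truth.
"""

import json
from pathlib import Path

from dietsel import CtConfig, StudyConfig, generate_ct_table, generate_study, ground_truth
from dietsel.synthetic import plant_effects

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "data"

INSECT_PLANTED = (0, 12, 45, 60)   # indices into the 89-variable list
LPS_PLANTED = (5, 30, 52, 70)


def build_config(seed: int = SEED) -> StudyConfig:
    base = StudyConfig(master_seed=seed, missing_rate=0.02)
    names = base.variable_names()
    cfg = plant_effects(base, [names[i] for i in INSECT_PLANTED],
                        ("Tenebrio", "Buffalo"), d=2.0)
    return plant_effects(cfg, [names[i] for i in LPS_PLANTED],
                         ("LPS",), d=2.0, direction="down")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = build_config()
    table = generate_study(cfg)
    table.to_csv(OUT / "samples.csv", OUT / "annotations.csv")
    ct = generate_ct_table(
        CtConfig(noise_sd=0.4, group_shifts={"Tas1r1": {"Tenebrio": -0.8, "Buffalo": -1.0}}),
        seed=SEED,
    )
    ct.to_csv(OUT / "ct.csv")
    truth = [e.__dict__ | {"groups": list(e.groups)} for e in ground_truth(cfg)]
    (OUT / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    n_missing = int(table.data.isna().to_numpy().sum())
    print(f"wrote {table.data.shape[0]} samples x {table.data.shape[1]} variables "
          f"({n_missing} missing cells) and a Ct table with {len(ct.target_genes)} genes")
    print(f"planted {len(truth)} effects at d=2.0 (4 insect-up, 4 LPS-down)")


if __name__ == "__main__":
    main()
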