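#!/usr/bin/env python
"""Synthesize the study cohorts.

Writes a small recording-level cohort (full 19-electrode rsEEG, used by the
pipeline-level analyses) to scratch/, and a 200-subject feature-level cohort
(drawn from the published normative age curves) to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from qeegnorm.io import write_text_recording
from qeegnorm.synthetic import CohortSpec, generate_cohort, generate_feature_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-recordings", type=int, default=8)
    ap.add_argument("--duration", type=float, default=60.0)
    args = ap.parse_args()

    rec_dir = ROOT / "scratch" / "cohort"
    rec_dir.mkdir(parents=True, exist_ok=True)
    cs = CohortSpec(n=args.n_recordings, seed=args.seed, duration=args.duration)
    rows = []
    for i, (rec, truth) in enumerate(generate_cohort(cs)):
        name = f"subject{i:03d}.tsv"
        write_text_recording(rec, rec_dir / name, include_dummy_ecg=True)
        rows.append({"file": name, "age": truth["age"],
                     "pdr_freq_true": truth["pdr_freq"]})
    pd.DataFrame(rows).to_csv(rec_dir / "ages.csv", index=False)
    print(f"wrote {len(rows)} recordings ({args.duration:.0f} s each) "
          f"to {rec_dir}")

    feats = generate_feature_cohort(200, seed=args.seed)
    out = ROOT / "results" / "feature_cohort.csv"
    out.parent.mkdir(exist_ok=True)
    feats.to_csv(out, index=False)
    print(f"wrote 200-subject feature cohort to {out} "
          f"(ages {feats['age'].min():.1f}-{feats['age'].max():.1f})")


if __name__ == "__main__":
    main()
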