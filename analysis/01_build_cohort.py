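#!/usr/bin/env python
"""Sample the study cohort and report its demographics.

Generates 10 men + 10 women with sex-specific anatomy (jugular cross-section,
sternocleidomastoid thickness, vessel depth, relative hemoglobin, venous
attenuation gain) and writes the cohort table plus a demographics comparison
(two-sample t-tests by sex) to results/.
"""

import argparse
import json
from pathlib import Path

from chijva import io, stats
from chijva.cohort import make_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    cohort = make_cohort(10, 10, args.seed)
    df = io.cohort_to_frame(cohort)
    df.to_csv(args.out / "cohort.csv", index=False)

    demo = {}
    for col in ("age", "bsa", "bmi", "csa_baseline", "scm_thickness", "ijv_depth"):
        t, p = stats.demographics_ttest(df, col)
        m = df.loc[df.sex == "M", col]
        f = df.loc[df.sex == "F", col]
        demo[col] = {
            "women_mean": round(f.mean(), 3), "women_sd": round(f.std(ddof=1), 3),
            "men_mean": round(m.mean(), 3), "men_sd": round(m.std(ddof=1), 3),
            "t": round(t, 3), "p": round(p, 4),
        }
    (args.out / "demographics.json").write_text(json.dumps(demo, indent=2))

    print(f"cohort of {len(cohort)} written to {args.out/'cohort.csv'}")
    for col, row in demo.items():
        print(
            f"  {col:14s} women {row['women_mean']:6.3f} ± {row['women_sd']:.3f}"
            f"   men {row['men_mean']:6.3f} ± {row['men_sd']:.3f}   p={row['p']:.4f}"
        )


if __name__ == "__main__":
    main()
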