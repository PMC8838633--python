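#!/usr/bin/env python
"""Mixed-model analysis of CSA and JVA across challenge levels by sex.

Fits response ~ level x sex + (1 | participant) per condition for both
outcomes, with and without the baseline-CSA covariate, and reports
fixed-effect tests, estimated marginal means, and Tukey-adjusted per-level
sex contrasts.  Reads results/trials.csv and writes results/mixed_models.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chijva import stats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path, default=Path("results/trials.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    trials = pd.read_csv(args.trials)

    out = {}
    for cond in ("HDT", "LBNP"):
        sub = trials[trials.condition == cond]
        for response in ("csa", "jva"):
            for with_base in (False, True):
                key = f"{cond}_{response}" + ("_basecov" if with_base else "")
                try:
                    res = stats.fit_lmm(sub, response=response, include_baseline_csa=with_base)
                except ValueError as exc:
                    out[key] = {"error": str(exc)}
                    continue
                out[key] = {
                    "p_values": {k: round(v, 5) for k, v in res.p_values.items()},
                    "emm": res.emm.round(4).to_dict(orient="records"),
                    "sex_contrasts": res.contrasts.round(4).to_dict(orient="records"),
                    "df_method": res.df_method,
                }
                if not with_base:
                    p = res.p_values
                    print(f"{cond} {response.upper()}: level p={p['level']:.4g}, "
                          f"sex p={p['sex']:.4g}, interaction p={p['sex_x_level']:.4g}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "mixed_models.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
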