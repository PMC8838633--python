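#!/usr/bin/env python
"""JVA-versus-CSA association analyses on the extracted trial table.

Per condition and sex: repeated-measures correlation (common slope across
participants), per-participant regressions with median/IQR summaries, the
Wilcoxon rank-sum comparison of male vs female individual slopes, the
reliability stratification at a 0.15 cm**2 change in CSA, and pooled
correlations of baseline JVA with muscle thickness and vessel depth.
Reads results/trials.csv (from 02) and writes results/associations.json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from chijva import stats


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--trials", type=Path, default=Path("results/trials.csv"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    trials = pd.read_csv(args.trials)

    out = {"rmcorr": {}, "individual": {}, "slope_comparison": {}}
    fits_all = []
    for cond in ("HDT", "LBNP"):
        sub = trials[trials.condition == cond]
        for sex in ("M", "F"):
            try:
                r = stats.rmcorr(sub[sub.sex == sex])
            except ValueError:
                continue
            out["rmcorr"][f"{cond}_{sex}"] = {
                "r_rm": round(r.r_rm, 3), "ci": [round(r.ci_low, 3), round(r.ci_high, 3)],
                "p": round(r.p, 5), "common_slope": round(r.common_slope, 3), "df": r.df,
            }
            print(f"{cond} {sex}: r_rm={r.r_rm:.2f} (95% CI {r.ci_low:.2f},{r.ci_high:.2f}) "
                  f"p={r.p:.4f}, common slope {r.common_slope:.3f} a.u./cm^2, df={r.df}")
        fits = stats.individual_fits(sub)
        fits_all.extend(fits)
        out["individual"][cond] = stats.summarize_fits(fits).round(3).to_dict(orient="records")
        m = [f.slope for f in fits if f.sex == "M"]
        f_ = [f.slope for f in fits if f.sex == "F"]
        if m and f_:
            stat, p = stats.compare_slopes(m, f_)
            out["slope_comparison"][cond] = {
                "median_m": round(float(np.median(m)), 3),
                "median_f": round(float(np.median(f_)), 3),
                "statistic": stat, "p": round(p, 4),
            }
            print(f"{cond}: male median slope {np.median(m):.2f} vs female "
                  f"{np.median(f_):.2f} a.u./cm^2, rank-sum p={p:.4f}")

    rel = stats.stratify_reliability(fits_all)
    out["reliability"] = {k: v for k, v in rel.items()}
    print(f"individual r IQR: delta-CSA<{rel['threshold']} -> {rel['iqr_low']}, "
          f">= threshold -> {rel['iqr_high']}")

    if args.cohort.exists():
        cohort = pd.read_csv(args.cohort)
        base = trials[(trials.condition == "HDT") & (trials.level == 0.0)]
        merged = base.merge(cohort[["id", "scm_thickness", "ijv_depth"]],
                            left_on="participant", right_on="id")
        anth = stats.anthropometric_correlations(merged.rename(columns={"jva": "jva_baseline"}))
        out["anthropometric"] = anth
        print(f"baseline JVA vs muscle thickness r={anth['scm_thickness']['r']:.2f}; "
              f"vs vessel depth r={anth['ijv_depth']['r']:.2f}")

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "associations.json").write_text(json.dumps(out, indent=2, default=str))


if __name__ == "__main__":
    main()
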