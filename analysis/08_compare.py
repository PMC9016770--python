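#!/usr/bin/env python
"""Cross-framework model comparison table.

Collects the best model of each trait-free family (null, time-dependent,
temperature-dependent, episodic, diversity-dependent) for each analysis
unit from the per-family tables written by scripts 03-05 and ranks them by
AIC and Akaike weight, mirroring the published comparison-table layout.
Mk and SSE results are reported separately by scripts 06-07 and are never
merged into this table (their likelihoods condition on different data).
"""

import argparse
from pathlib import Path

import pandas as pd

from paleodiv.selection import ModelRow, akaike_table


def best_row(df, label_prefix, exclude=None, only=None):
    d = df
    if exclude is not None:
        d = d[~d["model"].isin(exclude)]
    if only is not None:
        d = d[d["model"].isin(only)]
    if d.empty:
        return None
    r = d.loc[d["AIC"].idxmin()]
    return ModelRow(f"{label_prefix}:{r['model']}", int(r["np"]),
                    float(r["logL"]), float(r["AIC"]))


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    ap.add_argument("--out", type=Path, default=Path("results/compare"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    for unit in ("whole_tree", "Clade_I", "Clade_II"):
        rows = []
        time_path = args.results / "time_env" / f"models_{unit}_time.csv"
        if time_path.exists():
            t = pd.read_csv(time_path)
            rows.append(best_row(t, "null", only=["BCST", "BCST_DCST"]))
            rows.append(best_row(t, "time", exclude=["BCST", "BCST_DCST"]))
        env_path = args.results / "time_env" / f"models_{unit}_env.csv"
        if env_path.exists():
            rows.append(best_row(pd.read_csv(env_path), "env"))
        ep_path = args.results / "episodic" / f"shifts_{unit}.csv"
        if ep_path.exists():
            e = pd.read_csv(ep_path)
            r = e.loc[e["AIC"].idxmin()]
            rows.append(ModelRow(f"episodic:BD-{int(r['s'])}shift",
                                 int(r["np"]), float(r["logL"]),
                                 float(r["AIC"])))
        dd_path = args.results / "dd" / f"dd_{unit}.csv"
        if dd_path.exists():
            d = pd.read_csv(dd_path)
            r = d.loc[d["AIC"].idxmin()]
            rows.append(ModelRow(f"dd:{r['model']}", int(r["np"]),
                                 float(r["logL"]), float(r["AIC"])))
        rows = [r for r in rows if r is not None]
        if not rows:
            continue
        table = akaike_table(rows)
        table.to_csv(args.out / f"cross_framework_{unit}.csv", index=False)
        best = table.iloc[0]
        print(f"{unit:12s} best: {best['model']:24s} "
              f"dAIC=0  wAIC={best['wAIC_pct']:.1f}%")


if __name__ == "__main__":
    main()
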