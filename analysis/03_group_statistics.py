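#!/usr/bin/env python
"""Group statistics on the per-mouse summary table.

Reads results/cohort/summary.csv (from 02_quantify_synapses.py) and runs the
two comparison families: a two-way genotype × age ANOVA (Type-II sums of
squares) for the normally distributed density statistics, and Kruskal–Wallis
rank tests across age groups for the colocalization percentages.  Also
reports the Shapiro–Wilk normality gate for each statistic so the branch
choice is auditable.  Writes results/stats/statistics.csv.

Run:  python analysis/03_group_statistics.py [--summary results/cohort/summary.csv]
"""

import argparse
from pathlib import Path

import pandas as pd

from synaptomo import group_stats
from synaptomo.errors import ConfigError
from synaptomo.pipeline import STATISTICS


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--summary", type=Path, default=Path("results/cohort/summary.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/stats"))
    args = ap.parse_args()

    summary = pd.read_csv(args.summary)
    summary["age_months"] = summary["age_months"].astype(str)
    rows = []
    for stat, (_, branch) in STATISTICS.items():
        if stat not in summary.columns:
            continue
        values = summary[stat].dropna()
        try:
            w, p_norm = group_stats.shapiro_normality(values.tolist())
            gate = f"Shapiro-Wilk W={w:.3f}, p={p_norm:.3g}"
        except ConfigError:
            gate = "Shapiro-Wilk undefined (constant values)"
        print(f"\n{stat}  [{gate}; branch: {branch}]")
        if branch == "anova":
            sub = summary.dropna(subset=[stat])
            res = group_stats.two_way_anova(
                sub[stat].tolist(), sub["genotype"].tolist(),
                sub["age_months"].tolist())
            for term in ("factor_a", "factor_b", "interaction"):
                tr = res.terms[term]
                label = {"factor_a": "genotype", "factor_b": "age",
                         "interaction": "genotype x age"}[term]
                print(f"  {label}: F({tr.df},{res.terms['residual'].df}) = "
                      f"{tr.statistic:.3f}, p = {tr.p_value:.4f}")
                rows.append(dict(statistic=stat, test="two_way_anova", term=label,
                                 value=tr.statistic, df=tr.df, p=tr.p_value))
        else:
            for genotype, sub in summary.groupby("genotype"):
                sub = sub.dropna(subset=[stat])
                groups = [g[stat].tolist()
                          for _, g in sub.groupby("age_months") if len(g)]
                if len(groups) < 2:
                    continue
                res = group_stats.kruskal_wallis(groups)
                print(f"  age within {genotype}: H({res.df}) = "
                      f"{res.statistic:.3f}, p = {res.p_value:.4f}")
                rows.append(dict(statistic=stat, test="kruskal_wallis",
                                 term=f"age within {genotype}",
                                 value=res.statistic, df=res.df, p=res.p_value))

    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "statistics.csv", index=False)
    print(f"\nWrote {args.out / 'statistics.csv'}")


if __name__ == "__main__":
    main()
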