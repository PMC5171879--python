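#!/usr/bin/env python
"""Allometric slopes and residual-variance selection indices.

Fits ln-ln regressions of each character on head width per population,
tabulates residual variances with across-population margins, tests slope
heterogeneity (ANCOVA-style F), compares among-population slope
variances between characters, and checks for a latitudinal cline in the
slopes. The expectation under the study design: tightly canalized
characters (HTL, then FTSL) show small residual variances and slope
dispersion; the weakly selected HTSL shows the largest of both.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from stasiscope import allometry as alm
from stasiscope import io

CHARACTERS = ["HTL", "FTSL", "HTSL"]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results/allometry")
    args = ap.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    table = alm.ln_transform(io.read_morph_tsv(Path(args.datadir) / "morphometry.tsv"))
    lat = pd.read_csv(Path(args.datadir) / "latitudes.tsv", sep="\t")
    latitudes = dict(zip(lat["population"], lat["latitude"]))

    fits = {ch: alm.fit_allometry(table, ch, group_by="population") for ch in CHARACTERS}
    resid = alm.residual_variance_by_population(fits, scale=1e5)
    resid.to_csv(out / "residual_variances.tsv", sep="\t")

    slopes = pd.DataFrame(
        {ch: {f.group: f.slope for f in fs} for ch, fs in fits.items()}
    )
    slopes.to_csv(out / "slopes.tsv", sep="\t")

    stats = {}
    for ch in CHARACTERS:
        f, dfp, p = alm.slope_homogeneity_test(table, ch)
        r, pr = alm.slope_latitude_correlation(fits[ch], latitudes)
        stats[ch] = {
            "slope_variance": alm.slope_variance_across_populations(fits[ch]),
            "slope_heterogeneity": {"F": f, "df": dfp, "p": p},
            "slope_latitude": {"r": r, "p": pr},
        }
    # pairwise F comparisons of the among-population slope variances
    comparisons = {}
    m = 3
    for a, b in (("HTSL", "FTSL"), ("HTSL", "HTL"), ("FTSL", "HTL")):
        f, p = alm.variance_ratio_test(
            stats[a]["slope_variance"], 7, stats[b]["slope_variance"], 7
        )
        comparisons[f"{a}_vs_{b}"] = {
            "F": f, "p": p, "p_bonferroni": alm.bonferroni(p, m),
        }
    (out / "allometry_stats.json").write_text(
        json.dumps({"per_character": stats, "slope_variance_F": comparisons}, indent=2)
    )

    print("Residual variances (x 1e-5, ln scale), across-population margins:")
    for ch in CHARACTERS:
        print(f"  {ch:5s} mean {resid.loc[ch,'mean']:6.1f}  sd {resid.loc[ch,'sd']:5.2f}")
    print("Among-population slope variance:")
    for ch in CHARACTERS:
        print(f"  {ch:5s} {stats[ch]['slope_variance']:.3e}")
    ordered = sorted(CHARACTERS, key=lambda c: resid.loc[c, "mean"])
    print(f"Selection-strength ranking by residual variance: "
          f"{' < '.join(ordered)} (strongest first)")


if __name__ == "__main__":
    main()
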