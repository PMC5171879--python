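"""End-to-end orchestration: simulate -> allometry -> popgen -> tree -> OU
-> comparative -> report.

A single JSON-style config drives the whole study workflow on synthetic
data (or on user-supplied tables); every stochastic stage takes an
explicit seed and a reproducibility manifest (config hash, seeds, input
checksums, versions) is written next to the outputs. Stage failures stop
dependent stages but leave independent ones running.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, allometry, comparative, io, ou_model, phylo, popgen
from .synthetic_data import (
    MorphSimConfig,
    PopGenSimConfig,
    default_morph_config,
    gen_distance_matrices,
    gen_microsatellites,
    gen_morphometry,
)

__all__ = ["default_config", "run_pipeline", "report"]

STAGES = ("simulate", "allometry", "popgen", "tree", "ou", "comparative", "report")
DEPENDS = {
    "simulate": (),
    "allometry": ("simulate",),
    "popgen": ("simulate",),
    "tree": ("popgen",),
    "ou": ("allometry", "tree"),
    "comparative": ("ou", "tree"),
    "report": (),
}
_KNOWN_KEYS = {
    "stages", "seed", "outdir", "characters",
    "morph", "popgen", "tree", "ou", "comparative", "report",
}


def default_config(outdir: str = "results/pipeline", seed: int = 1) -> dict:
    """Demo configuration: full synthetic study at desk scale."""
    return {
        "stages": list(STAGES),
        "seed": seed,
        "outdir": outdir,
        "characters": ["HTL", "FTSL", "HTSL"],
        "morph": {},
        "popgen": {"n_perm": 199, "target_fst": 0.2, "max_dyads_per_nest": 20},
        "tree": {"bootstrap_reps": 200, "rooting": "midpoint"},
        "ou": {"n_trials": 20000, "n_keep": 100},
        "comparative": {"n_perm": 999},
        "report": {},
    }


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run the enabled stages in dependency order; returns the manifest.

    Raises ``ValueError`` on unknown config keys or when an enabled stage's
    dependency is not enabled.
    """
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    stages = list(config.get("stages", STAGES))
    for stage in stages:
        for dep in DEPENDS.get(stage, ()):
            if dep not in stages:
                raise ValueError(
                    f"stage {stage!r} requires stage {dep!r}, which is not enabled"
                )
    seed = int(config.get("seed", 1))
    outdir = Path(config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    characters = config.get("characters", ["HTL", "FTSL", "HTSL"])
    manifest: dict = {
        "tool": "stasiscope",
        "version": __version__,
        "config_hash": _hash_config(config),
        "started": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seeds": {},
        "outputs": {},
        "warnings": [],
    }
    state: dict = {}

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if "simulate" in stages:
            morph_cfg = config.get("morph", {})
            mc = (
                MorphSimConfig(**morph_cfg)
                if "populations" in morph_cfg
                else default_morph_config(seed=seed)
            )
            state["morph"] = gen_morphometry(mc)
            pg_over = config.get("popgen", {})
            pop_ids = tuple(p.id for p in mc.populations)
            pc = PopGenSimConfig(
                n_populations=len(pop_ids),
                population_ids=pop_ids,
                target_fst=pg_over.get("target_fst", 0.2),
                seed=seed + 1,
            )
            state["genotypes"] = gen_microsatellites(pc)
            state["latitudes"] = {p.id: p.latitude for p in mc.populations}
            io.write_morph_tsv(state["morph"], outdir / "morphometry.tsv")
            io.write_genotypes_tsv(state["genotypes"], outdir / "genotypes.tsv")
            io.write_genepop(state["genotypes"], outdir / "genotypes.gen")
            manifest["seeds"]["simulate"] = seed
            manifest["outputs"]["simulate"] = ["morphometry.tsv", "genotypes.tsv", "genotypes.gen"]

        if "allometry" in stages:
            lnm = allometry.ln_transform(state["morph"])
            fits_by_char = {
                ch: allometry.fit_allometry(lnm, ch, group_by="population")
                for ch in characters
            }
            resid = allometry.residual_variance_by_population(fits_by_char, scale=1e5)
            slopes = pd.DataFrame(
                {
                    ch: {f.group: f.slope for f in fits}
                    for ch, fits in fits_by_char.items()
                }
            )
            slope_var = {
                ch: allometry.slope_variance_across_populations(fits)
                for ch, fits in fits_by_char.items()
            }
            stat_tests = {}
            for ch in characters:
                f, df, p = allometry.slope_homogeneity_test(lnm, ch)
                stat_tests[ch] = {"slope_heterogeneity_F": f, "df": df, "p": p}
                r, pr = allometry.slope_latitude_correlation(
                    fits_by_char[ch], state["latitudes"]
                )
                stat_tests[ch]["slope_latitude_r"] = r
                stat_tests[ch]["slope_latitude_p"] = pr
            state["fits"] = fits_by_char
            state["resid_table"] = resid
            state["slopes"] = slopes
            state["slope_var"] = slope_var
            resid.to_csv(outdir / "residual_variances.tsv", sep="\t")
            slopes.to_csv(outdir / "slopes.tsv", sep="\t")
            (outdir / "allometry_tests.json").write_text(
                json.dumps({"slope_variance": slope_var, "tests": stat_tests}, indent=2)
            )
            manifest["outputs"]["allometry"] = [
                "residual_variances.tsv", "slopes.tsv", "allometry_tests.json",
            ]

        if "popgen" in stages:
            geno = state["genotypes"]
            n_perm = int(config.get("popgen", {}).get("n_perm", 199))
            freqs = popgen.allele_frequencies(geno)
            pops = freqs.populations
            fis_rows = {
                p: popgen.fis(geno, p, n_perm=n_perm, seed=seed + 10).estimate
                for p in pops
            }
            fst = {}
            for i, pa in enumerate(pops):
                for pb in pops[i + 1 :]:
                    res = popgen.pairwise_fst(
                        geno, pa, pb, n_perm=n_perm, seed=seed + 20
                    )
                    fst[f"{pa}-{pb}"] = {"theta": res.estimate, "p": res.p}
            rel = popgen.qg_relatedness(
                geno,
                max_dyads_per_nest=config.get("popgen", {}).get("max_dyads_per_nest"),
                seed=seed + 30,
            )
            dc = popgen.dc_matrix(freqs)
            state["dc"] = dc
            state["geno_freqs"] = freqs
            io.write_distance_tsv(dc, outdir / "dc_matrix.tsv")
            rel.to_csv(outdir / "relatedness.tsv", sep="\t")
            (outdir / "fstats.json").write_text(
                json.dumps({"fis": fis_rows, "pairwise_fst": fst}, indent=2)
            )
            manifest["seeds"]["popgen"] = seed + 10
            manifest["outputs"]["popgen"] = [
                "dc_matrix.tsv", "relatedness.tsv", "fstats.json",
            ]

        if "tree" in stages:
            reps = int(config.get("tree", {}).get("bootstrap_reps", 200))
            tree = phylo.nj_tree(state["dc"])
            boot_matrices = popgen.bylocus_bootstrap_dc(
                state["genotypes"], n_reps=reps, seed=seed + 40
            )
            rep_trees = [phylo.nj_tree(m) for m in boot_matrices]
            supported = phylo.bootstrap_support(tree, rep_trees)
            state["tree_unrooted"] = supported
            rooted = phylo.midpoint_root(tree)
            state["tree_rooted"] = rooted
            (outdir / "nj_tree.nwk").write_text(phylo.write_newick(supported) + "\n")
            (outdir / "nj_tree_rooted.nwk").write_text(
                phylo.write_newick(rooted) + "\n"
            )
            manifest["seeds"]["tree"] = seed + 40
            manifest["outputs"]["tree"] = ["nj_tree.nwk", "nj_tree_rooted.nwk"]

        if "ou" in stages:
            ou_cfg = config.get("ou", {})
            lnm = allometry.ln_transform(state["morph"])
            tip_values = {
                ch: (
                    lnm[lnm["character"] == ch]
                    .groupby("population")["ln_length"]
                    .mean()
                    .to_dict()
                )
                for ch in characters
            }
            tree = state["tree_rooted"]
            summaries = {}
            for k, ch in enumerate(characters):
                summaries[ch] = ou_model.ki_reconstruct(
                    tree,
                    tip_values[ch],
                    n_trials=int(ou_cfg.get("n_trials", 20000)),
                    n_keep=int(ou_cfg.get("n_keep", 100)),
                    seed=seed + 50 + k,
                )
            state["ou_summaries"] = summaries
            state["tip_values"] = tip_values
            alpha_json = {
                ch: {"alpha_mean": s.alpha_mean, "alpha_sd": s.alpha_sd}
                for ch, s in summaries.items()
            }
            node_df = pd.DataFrame(
                {ch: s.node_means for ch, s in summaries.items()}
            )
            node_df.to_csv(outdir / "ancestral_states.tsv", sep="\t")
            corr = {}
            for ch, s in summaries.items():
                deltas, blens, _ = ou_model.branch_changes(
                    s, tree, observed_tips=tip_values[ch]
                )
                r, z, p = ou_model.change_length_correlation(deltas, blens)
                corr[ch] = {"r": r, "z": z, "p": p}
            (outdir / "ou_summary.json").write_text(
                json.dumps({"alpha": alpha_json, "change_length": corr}, indent=2)
            )
            state["change_length"] = corr
            manifest["seeds"]["ou"] = seed + 50
            manifest["outputs"]["ou"] = ["ancestral_states.tsv", "ou_summary.json"]

        if "comparative" in stages:
            cmp_cfg = config.get("comparative", {})
            tree = state["tree_rooted"]
            csets = {
                ch: comparative.independent_contrasts(tree, state["tip_values"][ch])
                for ch in characters
            }
            pair_stats = {}
            chars = list(characters)
            for i, ca in enumerate(chars):
                for cb in chars[i + 1 :]:
                    r, z, p = comparative.contrast_correlation(
                        csets[ca].contrasts, csets[cb].contrasts
                    )
                    pair_stats[f"{ca}-{cb}"] = {"r": r, "z": z, "p": p}
            n_pops = len(state["dc"].labels)
            geo, species, genetic = gen_distance_matrices(
                n_pops, seed=seed + 60, geo_weight=1.0
            )
            tau, p = comparative.partial_mantel_kendall(
                species.to_numpy(),
                genetic.to_numpy(),
                geo.to_numpy(),
                n_perm=int(cmp_cfg.get("n_perm", 999)),
                seed=seed + 61,
            )
            state["contrast_stats"] = pair_stats
            state["mantel"] = {"tau_partial": tau, "p": p}
            (outdir / "comparative.json").write_text(
                json.dumps(
                    {"contrast_correlations": pair_stats, "partial_mantel": state["mantel"]},
                    indent=2,
                )
            )
            manifest["seeds"]["comparative"] = seed + 60
            manifest["outputs"]["comparative"] = ["comparative.json"]

        if "report" in stages:
            text = report(state)
            (outdir / "report.txt").write_text(text)
            manifest["outputs"]["report"] = ["report.txt"]

        manifest["warnings"] = [str(w.message) for w in caught]

    manifest["finished"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    manifest["input_checksums"] = {
        name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()[:16]
        for names in manifest["outputs"].values()
        for name in names
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(state: dict) -> str:
    """Human-readable summary of whichever stage outputs are present."""
    if not state:
        raise ValueError("no stage outputs to report")
    lines = ["# stasiscope run report", ""]
    if "resid_table" in state:
        lines.append("## Residual variances by population (x 1e-5, ln scale)")
        tbl = state["resid_table"]
        lines.append(tbl.round(2).to_string())
        lines.append("")
        lines.append("Across-population margins (mean +/- SD):")
        for ch, row in tbl.iterrows():
            lines.append(f"  {ch}: {row['mean']:.1f} +/- {row['sd']:.2f}")
        lines.append("")
    if "slope_var" in state:
        lines.append("## Among-population slope variance")
        for ch, v in state["slope_var"].items():
            lines.append(f"  {ch}: {v:.3e}")
        lines.append("")
    if "ou_summaries" in state:
        lines.append("## Stabilizing-selection strength (retained alpha, mean +/- SD)")
        for ch, s in state["ou_summaries"].items():
            lines.append(f"  {ch}: {s.alpha_mean:.3f} +/- {s.alpha_sd:.3f}")
        lines.append("")
    if "change_length" in state:
        lines.append("## Branch change vs branch length (Pearson r, Fisher z, p)")
        for ch, d in state["change_length"].items():
            lines.append(
                f"  {ch}: r = {d['r']:.3f}, z = {d['z']:.3f}, p = {d['p']:.4f}"
            )
        lines.append("")
    if "mantel" in state:
        m = state["mantel"]
        lines.append(
            f"## Partial Mantel (species ~ genetic | geography): "
            f"tau = {m['tau_partial']:.3f}, p = {m['p']:.4f}"
        )
        lines.append("")
    return "\n".join(lines)
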