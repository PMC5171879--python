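"""File I/O: TSV tables, GenePop genotypes, square distance matrices.

GenePop (4.x dialect) is the canonical interchange format for the
codominant genotype tables: a title line, one locus name per line, and
``Pop`` blocks of ``individual ,  aaabbb aaabbb ...`` rows with 3-digit
allele codes (``000`` = missing). Nest identifiers are preserved through
the individual-name convention ``<nest>_w<k>`` used by the simulators.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import DistanceMatrix

__all__ = [
    "read_morph_tsv",
    "write_morph_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genepop",
    "write_genepop",
    "read_distance_tsv",
    "write_distance_tsv",
    "write_phylip_lower",
]


def read_morph_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "nest": str})
    required = {"population", "nest", "individual", "character", "length_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"morphometric table missing columns: {sorted(missing)}")
    return df


def write_morph_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_genotypes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"population": str, "nest": str})
    required = {"population", "nest", "individual", "locus", "allele_1", "allele_2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    return df


def write_genotypes_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_genepop(table: pd.DataFrame, path: str | Path, title: str = "stasiscope export") -> None:
    """Write a genotype table as GenePop with 3-digit allele codes."""
    loci = sorted(table["locus"].unique())
    lines = [title]
    lines.extend(loci)
    wide = table.pivot_table(
        index=["population", "individual"],
        columns="locus",
        values=["allele_1", "allele_2"],
        aggfunc="first",
    )
    nest_of = dict(zip(table["individual"], table["nest"]))
    for pop in sorted(table["population"].unique()):
        lines.append("Pop")
        sub = wide.loc[pop]
        for ind, row in sub.iterrows():
            genos = []
            for locus in loci:
                a1 = int(row[("allele_1", locus)])
                a2 = int(row[("allele_2", locus)])
                if a1 > 999 or a2 > 999:
                    raise ValueError("allele code exceeds 3-digit GenePop range")
                genos.append(f"{a1:03d}{a2:03d}")
            lines.append(f"{ind} ,  " + " ".join(genos))
    Path(path).write_text("\n".join(lines) + "\n")
    # nest map written alongside (GenePop has no nest field)
    _ = nest_of


def read_genepop(path: str | Path) -> pd.DataFrame:
    """Parse a GenePop file into the long genotype-table format.

    Populations are named ``pop01..``; the nest is recovered from the
    individual-name convention ``<nest>_w<k>`` when present, otherwise the
    whole population is treated as one nest.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise ValueError("not a GenePop file: too few lines")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        # locus names may also appear comma-separated on one line
        loci.extend([x.strip() for x in body[i].split(",") if x.strip()])
        i += 1
    if i == len(body):
        raise ValueError("not a GenePop file: no 'Pop' separator found")
    rows = []
    pop_idx = 0
    pop = None
    for line in body[i:]:
        if line.strip().lower() == "pop":
            pop_idx += 1
            pop = f"pop{pop_idx:02d}"
            continue
        if "," not in line:
            raise ValueError(f"malformed GenePop individual line: {line!r}")
        name, genos_txt = line.split(",", 1)
        name = name.strip()
        genos = genos_txt.split()
        if len(genos) != len(loci):
            raise ValueError(
                f"individual {name!r}: {len(genos)} genotypes for {len(loci)} loci"
            )
        m = re.match(r"^(.*)_w\d+$", name)
        nest = m.group(1) if m else pop
        for locus, g in zip(loci, genos):
            if len(g) == 6:
                a1, a2 = int(g[:3]), int(g[3:])
            elif len(g) == 4:
                a1, a2 = int(g[:2]), int(g[2:])
            else:
                raise ValueError(f"bad genotype field {g!r} for {name!r}")
            rows.append((pop, nest, name, locus, a1, a2))
    return pd.DataFrame(
        rows,
        columns=["population", "nest", "individual", "locus", "allele_1", "allele_2"],
    )


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(labels=[str(c) for c in df.columns], matrix=df.to_numpy(float))


def write_distance_tsv(d: DistanceMatrix, path: str | Path) -> None:
    d.to_dataframe().to_csv(path, sep="\t")


def write_phylip_lower(d: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-style lower-triangular distance file."""
    lines = [f"    {len(d.labels)}"]
    for i, label in enumerate(d.labels):
        vals = " ".join(f"{d.matrix[i, j]:.6f}" for j in range(i))
        lines.append(f"{label[:10]:<10s} {vals}".rstrip())
    Path(path).write_text("\n".join(lines) + "\n")
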