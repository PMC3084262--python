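"""Readers and writers for the tab-delimited, FASTA, and PWM formats used
throughout the pipeline.

All genomic coordinates are 0-based half-open.  Occupancy matrices are two
tab-delimited files (log2 ratios and binding p-values) sharing the leading
columns region_id, chrom, start, end, category.  PWMs use a plain-matrix
text format: a ``MOTIF <name>`` line, an optional ``BG`` line of four
background probabilities, then one line of four probabilities (A C G T)
per motif position.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .pwm import PWM
from .simulate import OccupancyMatrix, SyntheticTruth

COORD_COLS = ["region_id", "chrom", "start", "end", "category"]


def write_occupancy(occupancy: OccupancyMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    coords = occupancy.regions[COORD_COLS].reset_index(drop=True)
    for name, table in (("ratios", occupancy.ratios),
                        ("pvalues", occupancy.pvalues)):
        df = coords.merge(table.reset_index(names="region_id"),
                          on="region_id")
        df.to_csv(outdir / f"occupancy_{name}.tsv", sep="\t", index=False)
    meta = {"factors": list(occupancy.factors),
            "corepressor": occupancy.corepressor}
    (outdir / "occupancy_meta.yaml").write_text(yaml.safe_dump(meta))


def read_occupancy(outdir) -> OccupancyMatrix:
    outdir = Path(outdir)
    meta = yaml.safe_load((outdir / "occupancy_meta.yaml").read_text())
    ratios = pd.read_csv(outdir / "occupancy_ratios.tsv", sep="\t")
    pvalues = pd.read_csv(outdir / "occupancy_pvalues.tsv", sep="\t")
    regions = ratios[COORD_COLS].set_index("region_id", drop=False)
    return OccupancyMatrix(
        regions=regions,
        ratios=ratios.drop(columns=COORD_COLS[1:]).set_index("region_id"),
        pvalues=pvalues.drop(columns=COORD_COLS[1:]).set_index("region_id"),
        factors=list(meta["factors"]),
        corepressor=meta["corepressor"],
    )


def write_truth(truth: SyntheticTruth, path) -> None:
    data = {
        "planted_weights": {k: float(v)
                            for k, v in truth.planted_weights.items()},
        "planted_intercept": float(truth.planted_intercept),
        "noise_sd": float(truth.noise_sd),
        "planted_target_ids": sorted(truth.planted_target_ids),
        "redundancy": float(truth.redundancy),
        "derepression_slope": float(truth.derepression_slope),
        "seed": int(truth.seed),
    }
    Path(path).write_text(yaml.safe_dump(data))


def read_truth(path) -> SyntheticTruth:
    data = yaml.safe_load(Path(path).read_text())
    data["planted_target_ids"] = frozenset(data["planted_target_ids"])
    return SyntheticTruth(**data)


def write_fasta(records, path) -> None:
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by region_id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_pwms(pwms: Mapping[str, PWM], path) -> None:
    lines = []
    for pwm in pwms.values():
        lines.append(f"MOTIF {pwm.name}")
        lines.append("BG " + " ".join(f"{b:.6f}" for b in pwm.background))
        for row in pwm.matrix:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_pwms(path) -> dict[str, PWM]:
    pwms: dict[str, PWM] = {}
    name, bg, rows = None, None, []

    def flush():
        if name is not None:
            matrix = np.array(rows, dtype=float)
            # renormalize away text round-off so validation is exact
            matrix = matrix / matrix.sum(axis=1, keepdims=True)
            background = np.asarray(bg, dtype=float) if bg is not None \
                else np.full(4, 0.25)
            background = background / background.sum()
            pwms[name] = PWM(name, matrix, background)

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("MOTIF"):
            flush()
            name, bg, rows = line.split(maxsplit=1)[1], None, []
        elif line.startswith("BG"):
            bg = [float(x) for x in line.split()[1:]]
        else:
            rows.append([float(x) for x in line.split()])
    flush()
    return pwms


def write_bed(bed: pd.DataFrame, path) -> None:
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_profile(path) -> pd.DataFrame:
    """Per-replicate array profile: region_id, chrom, start, end, value."""
    return pd.read_csv(path, sep="\t")


def read_expression(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0],
                     name="log2_change")


def read_gene_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_config(config, path) -> None:
    from dataclasses import asdict
    data = asdict(config)
    data["weights"] = {k: float(v) for k, v in data["weights"].items()}
    Path(path).write_text(yaml.safe_dump(data))


def read_config(path):
    from .simulate import GeneratorConfig
    return GeneratorConfig(**yaml.safe_load(Path(path).read_text()))
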