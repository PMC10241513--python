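"""Plain-text readers and writers for the pipeline's file formats.

Genotypes travel as a wide TSV (marker_id, chrom, pos_bp, one column per
strain) with a PLINK-style ``.map`` sidecar for interoperability; abundance
and annotation are TSV; hotspots, planted truth and reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .architecture import HotspotCall
from .simdata import GenotypePanel, PlantedTruth

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_map",
    "write_abundance",
    "read_abundance",
    "write_annotation",
    "read_annotation",
    "write_truth",
    "read_truth",
    "write_hotspots",
    "read_hotspots",
    "write_json",
]


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.alleles.T, index=panel.marker_ids, columns=panel.strain_ids)
    df.insert(0, "chrom", panel.chrom)
    df.insert(1, "pos_bp", panel.pos_bp)
    df.index.name = "marker_id"
    df.to_csv(path, sep="\t")


def read_genotypes(path: str | Path) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", index_col="marker_id", dtype={"chrom": str})
    strains = [c for c in df.columns if c not in ("chrom", "pos_bp")]
    return GenotypePanel(
        strain_ids=strains,
        marker_ids=df.index.tolist(),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_bp=df["pos_bp"].to_numpy(dtype=np.int64),
        alleles=df[strains].to_numpy(dtype=np.int8).T,
    )


def write_map(panel: GenotypePanel, path: str | Path) -> None:
    """PLINK-style .map: chrom, marker_id, genetic position (0), bp position."""
    with open(path, "w") as fh:
        for mid, c, pos in zip(panel.marker_ids, panel.chrom, panel.pos_bp):
            fh.write(f"{c}\t{mid}\t0\t{pos}\n")


def write_abundance(abundance: pd.DataFrame, path: str | Path) -> None:
    abundance.rename_axis("feature_id").to_csv(path, sep="\t")


def read_abundance(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.rename_axis("feature_id").to_csv(path, sep="\t")


def read_annotation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id", dtype={"gene_chrom": str})


def write_truth(truth: PlantedTruth, path: str | Path) -> None:
    write_json(dataclasses.asdict(truth), path)


def read_truth(path: str | Path) -> PlantedTruth:
    with open(path) as fh:
        d = json.load(fh)
    return PlantedTruth(**d)


def write_hotspots(calls: list[HotspotCall], path: str | Path) -> None:
    write_json([h.to_dict() for h in calls], path)


def read_hotspots(path: str | Path) -> list[HotspotCall]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        HotspotCall(
            chrom=d["chrom"],
            window_start_bp=d["window_start_bp"],
            window_end_bp=d["window_end_bp"],
            peak_marker_id=d["peak_marker_id"],
            member_features=d["member_features"],
        )
        for d in data
    ]


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
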