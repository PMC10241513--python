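"""Cis/trans classification of QTL and trans-hotspot detection.

A pQTL is *cis* when the associated marker lies within a window (default
1 Mb) of the measured feature's encoding gene and passes the cis threshold
(default p < 1e-5); any other association passing the stricter trans
threshold (default p < 1e-6) is *trans*. Cis-eligibility takes precedence: a
sub-window association is never counted as trans however strong. A locus
whose window collects the trans peaks of many distinct features (default
>= 10) is a trans-hotspot — the signature of a shared local driver.

Coordinates are 1-based; windows are half-open [start, end).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import GENOMEWIDE_ALPHA, Kinship, NullFit, fit_null, scan_lmm
from .simdata import GenotypePanel

__all__ = [
    "HotspotCall",
    "classify_pqtl",
    "feature_peaks",
    "detect_hotspots",
    "map_eigengene",
    "link_table",
]

CIS_WINDOW_BP = 1_000_000
CIS_ALPHA = 1e-5
TRANS_ALPHA = 1e-6


@dataclass
class HotspotCall:
    chrom: str
    window_start_bp: int
    window_end_bp: int
    peak_marker_id: str
    member_features: list[str]

    @property
    def n_members(self) -> int:
        return len(self.member_features)

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "window_start_bp": int(self.window_start_bp),
            "window_end_bp": int(self.window_end_bp),
            "peak_marker_id": self.peak_marker_id,
            "n_members": self.n_members,
            "member_features": list(self.member_features),
        }


def classify_pqtl(
    records: pd.DataFrame,
    annotation: pd.DataFrame,
    cis_window: float = CIS_WINDOW_BP,
    cis_alpha: float = CIS_ALPHA,
    trans_alpha: float = TRANS_ALPHA,
) -> pd.DataFrame:
    """Label association records cis/trans; drop sub-threshold records.

    ``records`` needs columns feature_id, marker_id, chrom, pos_bp, p (plus
    any carried through); ``annotation`` is indexed by feature_id with
    gene_chrom and gene_pos_bp. Every feature must be annotated.
    """
    feats = records["feature_id"].unique()
    missing = [f for f in feats if f not in annotation.index]
    if missing:
        raise ValueError(f"unannotated features: {sorted(missing)[:20]}")
    ann = annotation.loc[records["feature_id"], ["gene_chrom", "gene_pos_bp"]].reset_index(drop=True)
    rec = records.reset_index(drop=True).copy()
    rec["gene_chrom"] = ann["gene_chrom"].astype(str).to_numpy()
    rec["gene_pos_bp"] = ann["gene_pos_bp"].to_numpy()

    same_chrom = rec["chrom"].astype(str).to_numpy() == rec["gene_chrom"].to_numpy()
    near = np.abs(rec["pos_bp"].to_numpy() - rec["gene_pos_bp"].to_numpy()) <= cis_window
    cis_eligible = same_chrom & near
    p = rec["p"].to_numpy()

    qtl_class = np.full(len(rec), "", dtype=object)
    qtl_class[cis_eligible & (p < cis_alpha)] = "cis"
    qtl_class[~cis_eligible & (p < trans_alpha)] = "trans"
    rec["qtl_class"] = qtl_class
    return rec[rec["qtl_class"] != ""].reset_index(drop=True)


def feature_peaks(classified: pd.DataFrame) -> pd.DataFrame:
    """Per-feature, per-class peak: the minimum-p record in each class."""
    if classified.empty:
        return classified
    idx = classified.groupby(["feature_id", "qtl_class"], sort=False)["p"].idxmin()
    return classified.loc[idx.to_numpy()].reset_index(drop=True)


def detect_hotspots(
    classified: pd.DataFrame,
    window_bp: float = 4e6,
    min_members: int = 10,
) -> list[HotspotCall]:
    """Sliding-window trans-hotspot caller.

    Windows of ``window_bp`` advance by half a window per chromosome; a window
    qualifies when the trans *peaks* (one per feature) of at least
    ``min_members`` distinct features fall inside. Overlapping qualifying
    windows are merged into a single call whose peak marker is the member peak
    with the smallest p in the merged interval.
    """
    peaks = feature_peaks(classified)
    peaks = peaks[peaks["qtl_class"] == "trans"]
    calls: list[HotspotCall] = []
    if peaks.empty:
        return calls
    step = int(window_bp // 2)
    for chrom, grp in peaks.groupby(peaks["chrom"].astype(str)):
        pos = grp["pos_bp"].to_numpy()
        lo, hi = int(pos.min()), int(pos.max())
        starts = np.arange(max(1, lo - step), hi + 1, step)
        qualifying = []
        for s in starts:
            inside = (pos >= s) & (pos < s + window_bp)
            if grp.loc[inside, "feature_id"].nunique() >= min_members:
                qualifying.append((int(s), int(s + window_bp)))
        # merge overlapping qualifying windows
        merged: list[list[int]] = []
        for s, e in qualifying:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in merged:
            inside = grp[(pos >= s) & (pos < e)]
            best = inside.loc[inside["p"].idxmin()]
            calls.append(
                HotspotCall(
                    chrom=str(chrom),
                    window_start_bp=s,
                    window_end_bp=e,
                    peak_marker_id=str(best["marker_id"]),
                    member_features=sorted(inside["feature_id"].unique().tolist()),
                )
            )
    calls.sort(key=lambda h: h.n_members, reverse=True)
    return calls


def map_eigengene(
    eigengene: np.ndarray | pd.Series,
    panel: GenotypePanel,
    K: Kinship,
    threshold: float = GENOMEWIDE_ALPHA,
    null: NullFit | None = None,
) -> tuple[pd.DataFrame, str | None]:
    """LMM scan of a module eigengene; the peak is the genome-wide minimum p
    if it clears the significance threshold, else None."""
    y = np.asarray(pd.Series(eigengene), dtype=float)
    if null is None:
        null = fit_null(y, K)
    rec = scan_lmm(y, panel, K, null)
    best = rec.loc[rec["p"].idxmin()]
    peak = str(best["marker_id"]) if best["p"] < threshold else None
    return rec, peak


def link_table(classified: pd.DataFrame) -> pd.DataFrame:
    """Circos-style link table: one feature -> peak-marker edge per class."""
    peaks = feature_peaks(classified)
    cols = ["feature_id", "gene_chrom", "gene_pos_bp", "chrom", "pos_bp", "marker_id", "qtl_class", "p"]
    return peaks[cols].rename(columns={"chrom": "marker_chrom", "pos_bp": "marker_pos_bp"})
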