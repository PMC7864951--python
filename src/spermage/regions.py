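"""Adjacent-site co-methylation clustering (A-clustering).

Neighbouring array probes whose methylation is correlated across subjects
are grouped into co-regulated regions by a greedy left-to-right scan per
chromosome: the current cluster is extended to the next probe iff the
genomic gap to the previous probe is at most `max_gap` base pairs AND the
linkage correlation between the candidate and the cluster reaches
`corr_threshold`.  Only clusters of >= 2 probes are emitted; clusters are
disjoint and the scan is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import MethylomeDataset

__all__ = ["MethylRegion", "find_clusters", "regions_to_bed"]


@dataclass(frozen=True)
class MethylRegion:
    """An ordered run of correlated probes on one chromosome.

    `start`/`end` are the 1-based positions of the first and last probe
    (inclusive); BED export converts to 0-based half-open.
    """

    region_id: str
    chrom: str
    probe_ids: tuple[str, ...]
    start: int
    end: int

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


def _corr_matrix(values: np.ndarray, corr_type: str) -> np.ndarray:
    if corr_type == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 1, values)
    elif corr_type == "pearson":
        ranked = values
    else:
        raise ValueError(f"unknown corr_type {corr_type!r}")
    with np.errstate(invalid="ignore"):
        return np.corrcoef(ranked)


def _link_corr(corr: np.ndarray, members: list[int], cand: int, linkage: str) -> float:
    if linkage == "single":
        # nearest member by genomic order is the most recently added probe
        return corr[members[-1], cand]
    if linkage == "average":
        return float(np.mean([corr[m, cand] for m in members]))
    raise ValueError(f"unknown linkage {linkage!r}")


def find_clusters(
    ds: MethylomeDataset,
    max_gap: int = 1000,
    corr_threshold: float = 0.5,
    corr_type: str = "spearman",
    linkage: str = "single",
) -> list[MethylRegion]:
    """Greedy adjacent-site clustering on M-values.

    Correlations are computed across subjects on M-values (Spearman by
    default).  Zero-variance probes never correlate and so never join a
    cluster.
    """
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must be in (0, 1)")
    man = ds.manifest.table
    M = ds.m_values()
    regions: list[MethylRegion] = []
    counter = 0
    for chrom, sub in man.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"manifest not position-sorted on {chrom}")
        corr = _corr_matrix(M[idx], corr_type)
        corr = np.nan_to_num(corr, nan=-1.0)  # zero-variance probes never link
        members = [0]
        for j in range(1, len(idx)):
            gap_ok = pos[j] - pos[j - 1] <= max_gap
            if gap_ok and _link_corr(corr, members, j, linkage) >= corr_threshold:
                members.append(j)
            else:
                if len(members) >= 2:
                    counter += 1
                    regions.append(_emit(counter, chrom, sub, members))
                members = [j]
        if len(members) >= 2:
            counter += 1
            regions.append(_emit(counter, chrom, sub, members))
    return regions


def _emit(counter: int, chrom: str, sub: pd.DataFrame, members: list[int]) -> MethylRegion:
    rows = sub.iloc[members]
    return MethylRegion(
        region_id=f"region_{counter:05d}",
        chrom=str(chrom),
        probe_ids=tuple(rows["probe_id"]),
        start=int(rows["pos"].iloc[0]),
        end=int(rows["pos"].iloc[-1]),
    )


def regions_to_bed(regions: list[MethylRegion], bed_path, membership_path=None) -> None:
    """Write regions as BED (0-based half-open) and optional membership TSV."""
    bed = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start - 1 for r in regions],
            "end": [r.end for r in regions],
            "name": [r.region_id for r in regions],
        }
    )
    bed.to_csv(bed_path, sep="\t", header=False, index=False)
    if membership_path is not None:
        rows = [
            {"region_id": r.region_id, "probe_id": p, "chrom": r.chrom}
            for r in regions
            for p in r.probe_ids
        ]
        pd.DataFrame(rows).to_csv(membership_path, sep="\t", index=False)
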