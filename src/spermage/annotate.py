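"""Genomic annotation of methylation regions and feature enrichment.

Regions are intersected with named interval tracks (CpG island / shore /
shelf / open sea context, genic features, sperm nucleosome retention, TFBS)
under BED semantics: 0-based half-open intervals, membership by any overlap
of at least one base.  DMR enrichment per feature is a two-sided Fisher
exact test of DMRs vs non-DMR regions (disjoint rows).  Each region can be
assigned the nearest gene whose TSS lies within a window (default 1500 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import MethylomeDataset
from .regions import MethylRegion

__all__ = [
    "AnnotationTrack",
    "EnrichmentResult",
    "assign_nearest_gene",
    "annotate_features",
    "fisher_enrichment",
    "direction_summary",
    "spearman_locus",
    "export_gene_list",
]


@dataclass
class AnnotationTrack:
    """A named set of genomic intervals with BED coordinate semantics."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end [, label]

    def __post_init__(self) -> None:
        t = self.intervals
        if (t["start"] >= t["end"]).any():
            bad = t[t["start"] >= t["end"]].iloc[0]
            raise ValueError(f"invalid interval {bad['chrom']}:{bad['start']}-{bad['end']}")
        self.intervals = t.sort_values(["chrom", "start"]).reset_index(drop=True)

    @classmethod
    def read_bed(cls, name: str, path) -> "AnnotationTrack":
        t = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        return cls(name, t)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, sub in self.intervals.groupby("chrom"):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(sub["start"].astype(int), sub["end"].astype(int))
            )
        return out


def _region_interval(r: MethylRegion) -> tuple[int, int]:
    """1-based inclusive probe span -> 0-based half-open interval."""
    return r.start - 1, r.end


def annotate_features(
    regions: list[MethylRegion], tracks: list[AnnotationTrack]
) -> pd.DataFrame:
    """Region x feature boolean membership by any-overlap; non-exclusive.

    Raises when a region chromosome appears in no track chromosome set, to
    surface naming mismatches ('chr1' vs '1') rather than silently reporting
    zero overlap.
    """
    track_chroms = set()
    trees = {}
    for tr in tracks:
        trees[tr.name] = tr.trees()
        track_chroms |= set(trees[tr.name])
    region_chroms = {r.chrom for r in regions}
    unmatched = sorted(region_chroms - track_chroms)
    if unmatched:
        raise ValueError(f"region chromosomes absent from every track: {unmatched}")
    out = {}
    for tr in tracks:
        col = []
        for r in regions:
            s, e = _region_interval(r)
            tree = trees[tr.name].get(r.chrom)
            col.append(bool(tree is not None and tree.overlap(s, e)))
        out[tr.name] = col
    return pd.DataFrame(out, index=[r.region_id for r in regions])


def assign_nearest_gene(
    regions: list[MethylRegion], tss_table: pd.DataFrame, window: int = 1500
) -> pd.DataFrame:
    """Assign each region the gene whose TSS is nearest, within `window` bp.

    `tss_table` columns: gene_id, chrom, strand, tss_pos (1-based).  Distance
    is 0 when the TSS falls inside the region span, otherwise the unsigned
    gap to the nearer region edge; strand is ignored.  Exact-distance ties
    break to the lexicographically smallest gene id and all tied genes are
    recorded in the `ambiguous` column.  Malformed TSS rows are skipped and
    counted in the frame's ``attrs['n_skipped_tss']``.
    """
    ok = tss_table["tss_pos"].apply(lambda v: isinstance(v, (int, np.integer)) or
                                    (isinstance(v, float) and float(v).is_integer()))
    ok &= tss_table["gene_id"].notna() & tss_table["chrom"].notna()
    skipped = int((~ok).sum())
    tss = tss_table[ok].copy()
    tss["tss_pos"] = tss["tss_pos"].astype(int)
    by_chrom = {str(c): sub.sort_values("tss_pos") for c, sub in tss.groupby("chrom")}
    rows = []
    for r in regions:
        sub = by_chrom.get(r.chrom)
        gene, dist, amb = None, None, ""
        if sub is not None:
            pos = sub["tss_pos"].to_numpy()
            d = np.where((pos >= r.start) & (pos <= r.end), 0,
                         np.minimum(np.abs(pos - r.start), np.abs(pos - r.end)))
            best = d.min() if len(d) else None
            if best is not None and best <= window:
                tied = sorted(sub["gene_id"].to_numpy()[d == best])
                gene, dist = tied[0], int(best)
                if len(tied) > 1:
                    amb = ";".join(tied)
        rows.append({"region_id": r.region_id, "gene_id": gene,
                     "distance": dist, "ambiguous": amb})
    out = pd.DataFrame(rows).set_index("region_id")
    out.attrs["n_skipped_tss"] = skipped
    return out


@dataclass
class EnrichmentResult:
    feature: str
    table: np.ndarray  # [[dmr_in, dmr_out], [non_in, non_out]]
    odds_ratio: float
    p: float
    direction: str  # enriched / depleted / none

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        return {"dmr_in": int(t[0, 0]), "dmr_out": int(t[0, 1]),
                "non_dmr_in": int(t[1, 0]), "non_dmr_out": int(t[1, 1])}


def fisher_enrichment(
    dmr_flags: pd.Series, membership: pd.DataFrame, feature: str
) -> EnrichmentResult:
    """Two-sided Fisher exact test of feature membership, DMRs vs non-DMRs.

    The contrast rows are disjoint (DMRs against the remaining regions of
    the full cluster set).  The sample odds ratio is reported, with a
    Haldane 0.5 continuity correction when any cell is zero.
    """
    dmr = dmr_flags.reindex(membership.index).fillna(False).astype(bool)
    if not dmr.any():
        raise ValueError("empty DMR set")
    mem = membership[feature].astype(bool)
    a = int((dmr & mem).sum())
    b = int((dmr & ~mem).sum())
    c = int((~dmr & mem).sum())
    d = int((~dmr & ~mem).sum())
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    direction = "enriched" if orr > 1 else ("depleted" if orr < 1 else "none")
    return EnrichmentResult(feature, table, float(orr), float(p), direction)


def direction_summary(dmr_table: pd.DataFrame, membership: pd.DataFrame) -> pd.DataFrame:
    """Per-feature percent of member DMRs that are hypermethylated.

    Features with no member DMRs report NaN (unknown), not 0 %.
    """
    dirs = dmr_table.set_index("region_id")["direction"]
    rows = []
    for feature in membership.columns:
        members = membership.index[membership[feature].astype(bool)]
        members = [m for m in members if m in dirs.index]
        n = len(members)
        if n == 0:
            rows.append({"feature": feature, "n_dmrs": 0, "pct_hyper": np.nan})
        else:
            hyper = sum(dirs[m] == "hyper" for m in members)
            rows.append({"feature": feature, "n_dmrs": n, "pct_hyper": 100.0 * hyper / n})
    return pd.DataFrame(rows).set_index("feature")


def spearman_locus(ds: MethylomeDataset, probe_ids, age: np.ndarray):
    """Spearman correlation of a probe's (or region-mean) beta with age."""
    idx = ds.probe_index(np.atleast_1d(probe_ids))
    values = ds.beta[idx].mean(axis=0)
    if len(values) < 5:
        raise ValueError("need >= 5 subjects")
    if np.ptp(values) == 0 or np.ptp(age) == 0:
        raise ValueError("zero variance in methylation or age")
    rho, p = stats.spearmanr(values, age)
    return float(rho), float(p)


def export_gene_list(gene_map: pd.DataFrame, region_subset, path=None) -> list[str]:
    """Deduplicated, sorted gene ids for the chosen regions; optional TXT."""
    sub = gene_map.loc[gene_map.index.intersection(list(region_subset))]
    genes = sorted(set(sub["gene_id"].dropna()))
    if path is not None:
        with open(path, "w") as fh:
            fh.write("gene_id\n")
            for g in genes:
                fh.write(f"{g}\n")
    return genes
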