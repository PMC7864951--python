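"""Core methylome data model: probe manifest, beta matrix, transforms, QC, I/O.

Beta-values are methylation proportions in (0, 1); M-values are their
log2-odds, ``M = log2(beta / (1 - beta))``, the scale preferred for linear
modelling because it is closer to homoscedastic.  Sperm samples are checked
for somatic-cell contamination through imprinted loci: maternally imprinted
loci must be essentially unmethylated in pure sperm (< 10 %) and paternally
imprinted loci essentially fully methylated (> 85 %).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProbeManifest",
    "MethylomeDataset",
    "QCReport",
    "FilterReport",
    "beta_to_m",
    "m_to_beta",
    "apply_probe_filters",
    "imprinting_qc",
]

DEFAULT_EPS = 1e-6


def beta_to_m(beta, eps: float = DEFAULT_EPS):
    """log2-odds transform of beta-values, clipped to (eps, 1 - eps).

    Strictly increasing on the clipped range; ``m_to_beta`` inverts it
    exactly for beta in (eps, 1 - eps).
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("non-finite beta values")
    b = np.clip(b, eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 1 / (1 + 2**(-M))."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("non-finite M values")
    out = 1.0 / (1.0 + np.exp2(-m))
    return out if out.ndim else float(out)


@dataclass
class ProbeManifest:
    """Probe annotation: id, chromosome and 1-based position.

    Positions are sorted ascending within chromosome on construction;
    `excluded`/`exclusion_reason` track probes dropped by filtering.
    """

    table: pd.DataFrame  # columns: probe_id, chrom, pos [, excluded, reason]

    def __post_init__(self) -> None:
        t = self.table
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(t.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if t["probe_id"].duplicated().any():
            dup = t.loc[t["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise ValueError(f"duplicate probe_id: {dup}")
        # stable sort keeps input order within (chrom, pos) ties
        self.table = t.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def read_tsv(cls, path) -> "ProbeManifest":
        t = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
        return cls(t[["probe_id", "chrom", "pos"]])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    counts_by_reason: dict[str, int]
    unknown_ids: dict[str, int]
    n_input: int
    n_kept: int


@dataclass
class MethylomeDataset:
    """Probe manifest plus a probes x subjects beta matrix in (0, 1)."""

    manifest: ProbeManifest
    beta: np.ndarray  # shape (n_probes, n_subjects)
    subject_ids: list[str]
    filter_report: FilterReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.manifest), len(self.subject_ids)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{len(self.manifest)} probes x {len(self.subject_ids)} subjects"
            )
        if np.isnan(self.beta).any():
            raise ValueError("missing beta values; impute or drop before constructing")
        if (self.beta <= 0).any() or (self.beta >= 1).any():
            raise ValueError("beta values must lie strictly in (0, 1)")

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.beta.shape[1]

    def m_values(self, eps: float = DEFAULT_EPS) -> np.ndarray:
        return beta_to_m(self.beta, eps)

    def probe_index(self, probe_ids: Iterable[str]) -> np.ndarray:
        lookup = pd.Index(self.manifest.table["probe_id"])
        idx = lookup.get_indexer(list(probe_ids))
        if (idx < 0).any():
            missing = [p for p, i in zip(probe_ids, idx) if i < 0]
            raise KeyError(f"probes not in manifest: {missing[:5]}")
        return idx

    # ---- I/O ----------------------------------------------------------

    @classmethod
    def read(cls, manifest_path, beta_path) -> "MethylomeDataset":
        manifest = ProbeManifest.read_tsv(manifest_path)
        sep = "\t" if str(beta_path).endswith((".tsv", ".txt")) else ","
        mat = pd.read_csv(beta_path, sep=sep, index_col=0)
        mat = mat.reindex(manifest.table["probe_id"])
        if mat.isna().any().any():
            raise ValueError("beta matrix missing probes present in manifest")
        return cls(manifest, mat.to_numpy(float), [str(c) for c in mat.columns])

    def write(self, manifest_path, beta_path) -> None:
        self.manifest.write_tsv(manifest_path)
        sep = "\t" if str(beta_path).endswith((".tsv", ".txt")) else ","
        pd.DataFrame(
            self.beta, index=self.manifest.table["probe_id"], columns=self.subject_ids
        ).to_csv(beta_path, sep=sep)


def read_exclusion_list(path) -> set[str]:
    """One probe id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def apply_probe_filters(
    ds: MethylomeDataset, exclusion_lists: Mapping[str, Iterable[str]]
) -> MethylomeDataset:
    """Drop probes named in any exclusion list (cross-reactive, sex-chromosome,
    near-SNP, user lists ...), preserving probe order.

    A probe in several lists is attributed to the first list (mapping order).
    Unknown ids are ignored but counted.  Raises if nothing survives.
    """
    ids = ds.manifest.table["probe_id"]
    known = set(ids)
    assigned: dict[str, str] = {}
    counts: dict[str, int] = {}
    unknown: dict[str, int] = {}
    for reason, probes in exclusion_lists.items():
        probes = set(probes)
        unknown[reason] = len(probes - known)
        hit = 0
        for p in probes & known:
            if p not in assigned:
                assigned[p] = reason
                hit += 1
        counts[reason] = hit
    keep = ~ids.isin(assigned.keys())
    if not keep.any():
        raise ValueError("all probes excluded; empty dataset after filtering")
    new_manifest = ProbeManifest(ds.manifest.table.loc[keep, ["probe_id", "chrom", "pos"]])
    report = FilterReport(counts, unknown, len(ds.manifest), int(keep.sum()))
    return MethylomeDataset(new_manifest, ds.beta[keep.to_numpy()], list(ds.subject_ids), report)


@dataclass
class QCReport:
    """Per-subject imprinting verdicts from maternal/paternal locus means."""

    maternal_max: float
    paternal_min: float
    locus_means: pd.DataFrame  # subjects x loci mean beta
    failures: dict[str, list[str]]  # subject -> offending loci

    @property
    def passed(self) -> bool:
        return not self.failures

    def to_json(self, path) -> None:
        payload = {
            "maternal_max": self.maternal_max,
            "paternal_min": self.paternal_min,
            "passed": self.passed,
            "failures": self.failures,
            "locus_means": self.locus_means.round(6).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def imprinting_qc(
    ds: MethylomeDataset,
    maternal_loci: Mapping[str, Sequence[str]],
    paternal_loci: Mapping[str, Sequence[str]],
    maternal_max: float = 0.10,
    paternal_min: float = 0.85,
) -> QCReport:
    """Somatic-contamination QC on imprinted loci.

    Each locus is a named set of probes; a subject passes iff every maternal
    locus mean beta is strictly below `maternal_max` and every paternal locus
    mean strictly above `paternal_min` (boundary values fail).
    """
    if not maternal_loci or not paternal_loci:
        raise ValueError("maternal and paternal locus sets must be non-empty")
    means: dict[str, np.ndarray] = {}
    for name, probes in {**maternal_loci, **paternal_loci}.items():
        idx = ds.probe_index(probes)  # raises if absent from manifest
        means[name] = ds.beta[idx].mean(axis=0)
    locus_means = pd.DataFrame(means, index=ds.subject_ids)
    failures: dict[str, list[str]] = {}
    for subj in ds.subject_ids:
        bad = [n for n in maternal_loci if locus_means.loc[subj, n] >= maternal_max]
        bad += [n for n in paternal_loci if locus_means.loc[subj, n] <= paternal_min]
        if bad:
            failures[subj] = bad
    return QCReport(maternal_max, paternal_min, locus_means, failures)
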