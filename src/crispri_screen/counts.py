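"""Spacer extraction from amplicon reads and count-matrix construction.

Amplicons carry the 20-nt spacer between two constant anchor sequences
(the amplification arms). Extraction is exact by default: both anchors
must match with the spacer exactly 20 nt between them, in either read
orientation. Reads that fail extraction, or whose spacer is not in the
library, are tallied per sample as ``unassigned`` so that
assigned + unassigned always equals the number of reads processed.

Normalization is by median-of-ratios size factors computed over guides
detected in every sample, the standard depth correction for count
screens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from crispri_screen.design import GuideLibrary, SPACER_LEN
from crispri_screen.genome import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AmpliconSchema:
    """Constant sequences flanking the spacer in the sequencing amplicon."""

    upstream_anchor: str
    downstream_anchor: str
    expected_amplicon_length: int = 219

    def __post_init__(self) -> None:
        for name in ("upstream_anchor", "downstream_anchor"):
            a = getattr(self, name)
            if len(a) < 8:
                raise ValueError(f"{name} must be >= 8 nt")
            if "N" in a.upper():
                raise ValueError(f"{name} must not contain N")


def _match_with_mismatches(read: str, pos: int, anchor: str, max_mm: int) -> bool:
    seg = read[pos : pos + len(anchor)]
    if len(seg) != len(anchor):
        return False
    if max_mm == 0:
        return seg == anchor
    return sum(a != b for a, b in zip(seg, anchor)) <= max_mm


def _extract_oriented(read: str, schema: AmpliconSchema, max_mm: int) -> Optional[str]:
    up, down = schema.upstream_anchor, schema.downstream_anchor
    if max_mm == 0:
        start = 0
        while True:
            i = read.find(up, start)
            if i < 0:
                return None
            j = i + len(up)
            if read[j + SPACER_LEN : j + SPACER_LEN + len(down)] == down and j + SPACER_LEN + len(down) <= len(read):
                return read[j : j + SPACER_LEN]
            start = i + 1
    for i in range(len(read) - len(up) - SPACER_LEN - len(down) + 1):
        if _match_with_mismatches(read, i, up, max_mm) and _match_with_mismatches(
            read, i + len(up) + SPACER_LEN, down, max_mm
        ):
            return read[i + len(up) : i + len(up) + SPACER_LEN]
    return None


def extract_spacer(read: str, schema: AmpliconSchema, max_anchor_mismatches: int = 0) -> Optional[str]:
    """Return the 20-nt spacer between the anchors, or None.

    Both read orientations are tried; anchors must match exactly unless
    ``max_anchor_mismatches`` allows up to that many mismatches per
    anchor.
    """
    read = read.upper()
    spacer = _extract_oriented(read, schema, max_anchor_mismatches)
    if spacer is None:
        spacer = _extract_oriented(revcomp(read), schema, max_anchor_mismatches)
    return spacer


@dataclass
class CountMatrix:
    """guide x sample raw counts with sample metadata and unassigned tallies."""

    counts: pd.DataFrame  # index: spacer, columns: sample ids, integer
    samples: pd.DataFrame  # index: sample ids; columns: condition, replicate
    unassigned: pd.Series  # per-sample reads not assigned to any library spacer

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.samples.index):
            raise ValueError("count columns and sample sheet rows disagree")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")

    def total_reads(self) -> pd.Series:
        return self.counts.sum(axis=0) + self.unassigned

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("spacer").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls, path: str | Path, samples: Optional[pd.DataFrame] = None
    ) -> "CountMatrix":
        counts = pd.read_csv(path, sep="\t", comment="#", index_col="spacer")
        if samples is not None:
            samples = samples.reindex(counts.columns)
            if samples.isna().any().any():
                raise ValueError("sample sheet does not cover all count columns")
        if samples is None:
            samples = pd.DataFrame(
                {"condition": list(counts.columns), "replicate": [1] * counts.shape[1]},
                index=counts.columns,
            )
        return cls(counts=counts, samples=samples, unassigned=pd.Series(0, index=counts.columns))


@dataclass
class NormalizedCounts:
    matrix: pd.DataFrame
    size_factors: pd.Series


def count_reads(
    fastq_by_sample: Mapping[str, Sequence[str | Path] | str | Path],
    library: GuideLibrary,
    schema: AmpliconSchema,
    sample_conditions: Optional[Mapping[str, str]] = None,
    sample_replicates: Optional[Mapping[str, int]] = None,
    max_anchor_mismatches: int = 0,
) -> CountMatrix:
    """Count library spacers in amplicon FASTQ files, one column per sample.

    Extracted spacers are matched exactly against the library; spacers
    absent from the library (and reads failing extraction) increment the
    sample's ``unassigned`` tally. Multi-target guides are counted here
    and flagged for exclusion in gene-level statistics downstream.
    """
    spacers = sorted(library.by_spacer)
    spacer_idx = {s: i for i, s in enumerate(spacers)}
    sample_ids = list(fastq_by_sample)
    mat = np.zeros((len(spacers), len(sample_ids)), dtype=np.int64)
    unassigned = np.zeros(len(sample_ids), dtype=np.int64)

    for j, sid in enumerate(sample_ids):
        paths = fastq_by_sample[sid]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        n_reads = 0
        for path in paths:
            with pysam.FastxFile(str(path)) as fh:
                for entry in fh:
                    n_reads += 1
                    spacer = extract_spacer(entry.sequence, schema, max_anchor_mismatches)
                    if spacer is not None and spacer in spacer_idx:
                        mat[spacer_idx[spacer], j] += 1
                    else:
                        unassigned[j] += 1
        if n_reads == 0:
            logger.warning("sample %s has no reads; all-zero column", sid)

    counts = pd.DataFrame(mat, index=pd.Index(spacers, name="spacer"), columns=sample_ids)
    samples = pd.DataFrame(
        {
            "condition": [
                (sample_conditions or {}).get(sid, sid) for sid in sample_ids
            ],
            "replicate": [(sample_replicates or {}).get(sid, 1) for sid in sample_ids],
        },
        index=pd.Index(sample_ids),
    )
    return CountMatrix(counts=counts, samples=samples, unassigned=pd.Series(unassigned, index=sample_ids))


def pool_replicates(m: CountMatrix, conditions: Optional[Iterable[str]] = None) -> CountMatrix:
    """Sum raw replicate counts per condition (done before normalization)."""
    known = list(dict.fromkeys(m.samples["condition"]))
    if conditions is not None:
        unknown = set(conditions) - set(known)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        known = [c for c in known if c in set(conditions)]
    cols = {}
    una = {}
    for cond in known:
        sids = m.samples.index[m.samples["condition"] == cond]
        cols[cond] = m.counts[sids].sum(axis=1)
        una[cond] = int(m.unassigned[sids].sum())
    counts = pd.DataFrame(cols)
    samples = pd.DataFrame(
        {"condition": known, "replicate": ["pooled"] * len(known)}, index=counts.columns
    )
    return CountMatrix(counts=counts, samples=samples, unassigned=pd.Series(una))


def median_ratio_normalize(m: CountMatrix | pd.DataFrame) -> NormalizedCounts:
    """Median-of-ratios size factors (computed over all-nonzero guides).

    size_factor_j = median_i(c_ij / g_i) with g_i the geometric mean of
    guide i across samples, restricted to guides nonzero in every
    sample; normalized counts are raw counts / size factor.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    if counts.shape[1] < 2:
        raise ValueError("normalization needs >= 2 samples")
    c = counts.to_numpy(dtype=float)
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no guide is nonzero in all samples; filter low-coverage guides first"
        )
    logc = np.log(c[all_nonzero])
    log_gmean = logc.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logc - log_gmean, axis=0))
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    return NormalizedCounts(matrix=counts / sf, size_factors=sf)
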