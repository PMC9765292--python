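"""Reporter-screen scoring: specific luciferase activity and gene summaries.

Each selected clone carries one gRNA and a promoter-luciferase fusion
whose output tracks promoter activity. Specific Lux activity is the sum
over the time course of RLU / OD600 (density-normalized light), and a
clone's effect is log2 of its specific activity over the no-gRNA
reference. Per gene, evidence combines the mean log2 fold change over
the distinct selected guides with the library-normalized guide count
(selected guides / library guides for that gene), the gene-size
correction for the higher chance of hitting large genes. Antagonist
calls require normalized count > 0.02 and mean log2FC > 0.5 (strict);
the mirrored agonist rule (mean log2FC < -0.5) is an extension flagged
as such.

Also includes the transformation-rate arithmetic of the spontaneous
transformation screen (selective vs total CFU with dilution factors).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from crispri_screen.design import GuideLibrary

logger = logging.getLogger(__name__)


@dataclass
class LuxTimeSeries:
    """Growth + luminescence time course for one clone."""

    clone_id: str
    spacer: Optional[str]
    timepoints: list[tuple[float, float, float]] = field(default_factory=list)  # (t_min, od600, rlu)

    def __post_init__(self) -> None:
        ts = [p[0] for p in self.timepoints]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("timepoints must be strictly increasing in t")
        if any(p[1] <= 0 for p in self.timepoints):
            raise ValueError("od600 must be positive")
        if any(p[2] < 0 for p in self.timepoints):
            raise ValueError("rlu must be non-negative")


def specific_lux(ts: LuxTimeSeries, od_floor: float = 0.01) -> float:
    """Sum of RLU/OD600 over timepoints with OD600 >= od_floor.

    The floor drops early near-blank wells where the ratio blows up.
    """
    included = [(od, rlu) for _, od, rlu in ts.timepoints if od >= od_floor]
    if not included:
        raise ValueError(f"clone {ts.clone_id}: no timepoint with od600 >= {od_floor}")
    if len(included) < len(ts.timepoints):
        logger.info(
            "clone %s: %d timepoints below OD floor excluded",
            ts.clone_id,
            len(ts.timepoints) - len(included),
        )
    return float(sum(rlu / od for od, rlu in included))


def clone_fold_change(
    clone: LuxTimeSeries, reference: LuxTimeSeries, od_floor: float = 0.01
) -> float:
    """log2 of clone specific Lux activity over the reference clone's."""
    ref = specific_lux(reference, od_floor)
    if ref <= 0:
        raise ValueError("reference specific Lux activity must be positive")
    val = specific_lux(clone, od_floor)
    if val <= 0:
        raise ValueError(f"clone {clone.clone_id}: specific Lux activity must be positive")
    return math.log2(val / ref)


def summarize_reporter_genes(
    clone_fold_changes: pd.DataFrame,
    library: GuideLibrary,
    count_cutoff: float = 0.02,
    lfc_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Aggregate selected-clone fold changes to per-gene reporter calls.

    ``clone_fold_changes`` needs columns ``clone_id``, ``spacer``,
    ``log2fc``. Distinct spacers are counted once per gene (re-isolated
    clones with the same spacer contribute one guide, their fold changes
    averaged); multi-target and unmapped spacers are excluded and
    reported in the ``unmapped`` attribute of the result. Classes:
    antagonist (count > count_cutoff and mean log2FC > lfc_cutoff),
    agonist (count > count_cutoff and mean log2FC < -lfc_cutoff, an
    extension of the published antagonist rule), else unclassified.
    """
    required = {"clone_id", "spacer", "log2fc"}
    if not required.issubset(clone_fold_changes.columns):
        raise ValueError(f"clone table needs columns {sorted(required)}")

    per_spacer = (
        clone_fold_changes.groupby("spacer")["log2fc"].mean().rename("log2fc").reset_index()
    )
    unmapped: list[str] = []
    rows: dict[str, list[tuple[str, float]]] = {}
    for spacer, lfc in per_spacer.itertuples(index=False):
        genes = library.gene_of_spacer(spacer)
        if not genes:
            unmapped.append(spacer)
            continue
        for gene in genes:
            rows.setdefault(gene, []).append((spacer, float(lfc)))
    if unmapped:
        logger.warning("%d selected spacers not mappable to a single gene", len(unmapped))

    out_rows = []
    for gene, hits in sorted(rows.items()):
        n_selected = len({s for s, _ in hits})
        n_library = len(library.by_gene.get(gene, []))
        norm_count = n_selected / n_library if n_library else float("nan")
        if n_library and n_selected > n_library:
            logger.warning("gene %s: more selected than library guides (library mismatch)", gene)
        mean_lfc = float(np.mean([l for _, l in hits]))
        if norm_count > count_cutoff and mean_lfc > lfc_cutoff:
            klass = "antagonist"
        elif norm_count > count_cutoff and mean_lfc < -lfc_cutoff:
            klass = "agonist"
        else:
            klass = "unclassified"
        out_rows.append(
            {
                "gene": gene,
                "n_selected_guides": n_selected,
                "n_library_guides": n_library,
                "normalized_count": norm_count,
                "mean_log2fc": mean_lfc,
                "class": klass,
            }
        )
    out = pd.DataFrame(
        out_rows,
        columns=[
            "gene",
            "n_selected_guides",
            "n_library_guides",
            "normalized_count",
            "mean_log2fc",
            "class",
        ],
    ).set_index("gene")
    out.attrs["unmapped"] = unmapped
    return out


@dataclass
class TransformationResult:
    cfu_selective: int
    cfu_total: int
    dilution_selective: float
    dilution_total: float
    rate: Optional[float]  # None encodes "not detected"

    @property
    def detected(self) -> bool:
        return self.rate is not None


def transformation_rate(
    cfu_selective: int,
    cfu_total: int,
    dilution_selective: float = 1.0,
    dilution_total: float = 1.0,
) -> TransformationResult:
    """Transformation rate from selective/total plate CFU counts.

    rate = (cfu_sel * dil_sel) / (cfu_tot * dil_tot); zero selective
    colonies encode as not detected (rate None).
    """
    if cfu_selective < 0 or cfu_total < 0:
        raise ValueError("CFU counts must be non-negative")
    if dilution_selective < 1 or dilution_total < 1:
        raise ValueError("dilution factors must be >= 1")
    if cfu_total == 0:
        raise ValueError("total CFU count is zero; rate undefined")
    rate = None
    if cfu_selective > 0:
        rate = (cfu_selective * dilution_selective) / (cfu_total * dilution_total)
    return TransformationResult(
        cfu_selective=cfu_selective,
        cfu_total=cfu_total,
        dilution_selective=dilution_selective,
        dilution_total=dilution_total,
        rate=rate,
    )


def read_timeseries(path) -> dict[str, LuxTimeSeries]:
    """Long-format TSV (clone_id, t_min, od600, rlu) -> per-clone series."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for clone_id, sub in df.groupby("clone_id"):
        sub = sub.sort_values("t_min")
        out[str(clone_id)] = LuxTimeSeries(
            clone_id=str(clone_id),
            spacer=None,
            timepoints=list(zip(sub["t_min"], sub["od600"], sub["rlu"])),
        )
    return out


def read_clone_sheet(path) -> pd.DataFrame:
    """Clone sheet TSV with columns clone_id, spacer, phenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"clone_id", "spacer"}
    if not required.issubset(df.columns):
        raise ValueError("clone sheet needs columns clone_id, spacer")
    return df
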