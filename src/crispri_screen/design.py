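"""Strand-aware gRNA library design for bacterial CRISPRi.

Every 20-nt window immediately followed by an NGG PAM on either strand is
a candidate protospacer. Within coding features the guide must base-pair
with the coding (nontemplate) strand to block elongation, which is
equivalent to requiring the protospacer (and PAM) to lie on the template
strand — i.e. the strand opposite the feature. Guides falling wholly in
intergenic regions are kept on both strands. Spacer sequences occurring
more than once among retained guides are flagged ``multi_target`` and are
excluded from gene-level statistics downstream.

``protospacer_start`` records the genomic coordinate (forward 0-based) of
the protospacer's 5'-most base *as read on its own strand*: for a ``+``
site this is the leftmost spacer base, for a ``-`` site the rightmost.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from crispri_screen.genome import AnnotatedGenome, Feature, derive_intergenic, revcomp

SPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = SPACER_LEN + PAM_LEN

CDS_LIKE_DEFAULT = ("CDS", "rRNA", "tRNA")


@dataclass(frozen=True)
class CandidateSite:
    """A 20-nt spacer + NGG PAM occurrence on one strand of the genome."""

    protospacer_strand: str
    protospacer_start: int
    spacer: str
    pam: str

    def spacer_interval(self) -> tuple[int, int]:
        """Raw forward-strand interval [a, b) of the 20-nt protospacer.

        May extend below 0 or beyond the genome length on circular
        genomes; normalize with :func:`normalize_interval`.
        """
        if self.protospacer_strand == "+":
            return (self.protospacer_start, self.protospacer_start + SPACER_LEN)
        return (self.protospacer_start - SPACER_LEN + 1, self.protospacer_start + 1)


def normalize_interval(a: int, b: int, L: int) -> list[tuple[int, int]]:
    """Split a possibly-wrapping forward interval into sub-intervals in [0, L)."""
    span = b - a
    if span > L:
        raise ValueError("interval longer than the genome")
    a2 = a % L
    b2 = a2 + span
    if b2 <= L:
        return [(a2, b2)]
    return [(a2, L), (0, b2 - L)]


@dataclass
class GuideRecord:
    """A retained (or rejected) candidate with its target assignment."""

    protospacer_strand: str
    protospacer_start: int
    spacer: str
    pam: str
    targets: list[tuple[str, int]] = field(default_factory=list)
    target_class: str = "rejected"  # cds_rule_pass | intergenic | rejected
    multi_target: bool = False
    copies: int = 1


@dataclass
class LibraryStats:
    n_guides: int
    median_guides_per_cds: float
    mean_spacing_bp: int
    coverage: pd.DataFrame  # per-feature guide counts


@dataclass
class GuideLibrary:
    """The retained guide set with spacer and gene indexes."""

    guides: list[GuideRecord]
    genome_id: str = ""
    genome_length: int = 0
    by_spacer: dict[str, list[int]] = field(default_factory=dict, repr=False)
    by_gene: dict[str, list[int]] = field(default_factory=dict, repr=False)
    stats: Optional[LibraryStats] = None

    def __post_init__(self) -> None:
        self.reindex()

    def reindex(self) -> None:
        self.by_spacer = {}
        self.by_gene = {}
        for i, g in enumerate(self.guides):
            self.by_spacer.setdefault(g.spacer, []).append(i)
            for locus, _ in g.targets:
                self.by_gene.setdefault(locus, []).append(i)

    def __len__(self) -> int:
        return len(self.guides)

    def gene_of_spacer(self, spacer: str) -> list[str]:
        """Locus tags targeted by a spacer (empty if absent or multi-target)."""
        idxs = self.by_spacer.get(spacer, [])
        genes: list[str] = []
        for i in idxs:
            g = self.guides[i]
            if g.multi_target:
                return []
            genes.extend(t for t, _ in g.targets)
        return genes


def enumerate_candidates(genome: AnnotatedGenome) -> list[CandidateSite]:
    """All 20-nt + NGG windows on both strands, circular-aware.

    Windows containing any non-ACGT base yield no candidate. A linear
    genome shorter than 23 nt yields an empty list.
    """
    L = genome.length
    if L < SITE_LEN:
        # a window cannot fit (a sub-23-nt circle would wrap onto itself)
        return []
    ext = genome.sequence + (genome.sequence[: SITE_LEN - 1] if genome.circular else "")
    arr = np.frombuffer(ext.encode("ascii"), dtype=np.uint8)
    is_acgt = (
        (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    )
    # window [i, i+23) is clean iff cumulative ACGT count advances by 23
    cum = np.concatenate([[0], np.cumsum(is_acgt)])
    n_windows = L if genome.circular else L - SITE_LEN + 1
    starts = np.arange(n_windows)
    clean = (cum[starts + SITE_LEN] - cum[starts]) == SITE_LEN

    G, C = ord("G"), ord("C")
    plus_mask = clean & (arr[starts + SPACER_LEN + 1] == G) & (arr[starts + SPACER_LEN + 2] == G)
    minus_mask = clean & (arr[starts] == C) & (arr[starts + 1] == C)

    sites: list[CandidateSite] = []
    for i in np.flatnonzero(plus_mask):
        i = int(i)
        sites.append(
            CandidateSite("+", i, ext[i : i + SPACER_LEN], ext[i + SPACER_LEN : i + SITE_LEN])
        )
    for s in np.flatnonzero(minus_mask):
        s = int(s)
        window = revcomp(ext[s : s + SITE_LEN])
        sites.append(
            CandidateSite("-", (s + SITE_LEN - 1) % L, window[:SPACER_LEN], window[SPACER_LEN:])
        )
    sites.sort(key=lambda c: (c.protospacer_strand, c.protospacer_start, c.spacer))
    return sites


def extract_site(genome: AnnotatedGenome, site: CandidateSite) -> str:
    """Re-extract the 23 nt (spacer+PAM) at a site's recorded locus/strand."""
    L = genome.length
    if site.protospacer_strand == "+":
        a = site.protospacer_start
        return genome.fetch(a, a + SITE_LEN, "+")
    a = (site.protospacer_start - SITE_LEN + 1) % L
    return genome.fetch(a, a + SITE_LEN, "-")


def _overlap_len(a1: int, b1: int, a2: int, b2: int) -> int:
    return max(0, min(b1, b2) - max(a1, a2))


def apply_retention_rules(
    sites: Sequence[CandidateSite],
    genome: AnnotatedGenome,
    intergenic: Optional[Sequence[Feature]] = None,
    cds_like: Iterable[str] = CDS_LIKE_DEFAULT,
) -> GuideLibrary:
    """Apply the coding-strand retention rule and build the library.

    A candidate overlapping (by >= 1 protospacer base) a coding-like
    feature on strand sigma is retained for that feature iff its
    protospacer lies on the opposite strand; candidates overlapping no
    coding-like feature are intergenic and retained on either strand;
    everything else is rejected. Duplicate spacers among retained guides
    get ``multi_target=True`` with ``copies`` set.
    """
    L = genome.length
    cds_like = set(cds_like)
    feats = [f for f in genome.features if f.kind in cds_like]
    if intergenic is None:
        intergenic = derive_intergenic(genome, min_length=1)

    # flattened sub-interval arrays for vectorized overlap queries
    f_start, f_end, f_idx = [], [], []
    for i, f in enumerate(feats):
        for s, e in f.intervals(L):
            f_start.append(s)
            f_end.append(e)
            f_idx.append(i)
    f_start_a = np.asarray(f_start, dtype=np.int64)
    f_end_a = np.asarray(f_end, dtype=np.int64)
    f_idx_a = np.asarray(f_idx, dtype=np.int64)

    ig_ivals: list[tuple[int, int, str]] = []
    for f in intergenic:
        for s, e in f.intervals(L):
            ig_ivals.append((s, e, f.locus_tag))

    retained: list[GuideRecord] = []
    rejected: list[GuideRecord] = []
    for site in sites:
        a, b = site.spacer_interval()
        subs = normalize_interval(a, b, L) if genome.circular else [(max(a, 0), min(b, L))]
        overlaps: dict[int, int] = {}
        if len(f_start_a):
            for s, e in subs:
                hit = np.flatnonzero((f_start_a < e) & (f_end_a > s))
                for h in hit:
                    i = int(f_idx_a[h])
                    overlaps[i] = overlaps.get(i, 0) + _overlap_len(s, e, int(f_start_a[h]), int(f_end_a[h]))
        rec = GuideRecord(
            protospacer_strand=site.protospacer_strand,
            protospacer_start=site.protospacer_start,
            spacer=site.spacer,
            pam=site.pam,
        )
        if overlaps:
            passing = [
                (feats[i].locus_tag, ov)
                for i, ov in sorted(overlaps.items())
                if feats[i].strand != site.protospacer_strand
            ]
            if passing:
                rec.targets = passing
                rec.target_class = "cds_rule_pass"
                retained.append(rec)
            else:
                rec.targets = [(feats[i].locus_tag, ov) for i, ov in sorted(overlaps.items())]
                rec.target_class = "rejected"
                rejected.append(rec)
        else:
            ig_hits: dict[str, int] = {}
            for s, e in subs:
                for gs, ge, tag in ig_ivals:
                    ov = _overlap_len(s, e, gs, ge)
                    if ov:
                        ig_hits[tag] = ig_hits.get(tag, 0) + ov
            rec.targets = sorted(ig_hits.items())
            rec.target_class = "intergenic"
            retained.append(rec)

    copies = Counter(g.spacer for g in retained)
    for g in retained:
        g.copies = copies[g.spacer]
        g.multi_target = g.copies > 1

    return GuideLibrary(guides=retained, genome_id=genome.id, genome_length=L)


def library_stats(lib: GuideLibrary, genome: AnnotatedGenome) -> LibraryStats:
    """Library density statistics: size, median guides per CDS, spacing.

    ``mean_spacing_bp`` is genome length / n_guides rounded to the
    nearest base. The per-CDS median includes CDSs with zero guides and
    uses the midpoint convention for even counts.
    """
    if len(lib) == 0:
        raise ValueError("empty library: spacing undefined (division by zero)")
    cds_feats = [f for f in genome.features if f.kind == "CDS"]
    per_feature = []
    for f in genome.features:
        if f.kind == "intergenic":
            continue
        per_feature.append(
            {
                "locus_tag": f.locus_tag,
                "kind": f.kind,
                "strand": f.strand,
                "length": f.length,
                "n_guides": len(lib.by_gene.get(f.locus_tag, [])),
            }
        )
    coverage = pd.DataFrame(per_feature, columns=["locus_tag", "kind", "strand", "length", "n_guides"])
    cds_counts = [len(lib.by_gene.get(f.locus_tag, [])) for f in cds_feats]
    median_cds = float(np.median(cds_counts)) if cds_counts else float("nan")
    return LibraryStats(
        n_guides=len(lib),
        median_guides_per_cds=median_cds,
        mean_spacing_bp=int(round(genome.length / len(lib))),
        coverage=coverage,
    )


def design_library(
    genome: AnnotatedGenome,
    min_intergenic: int = 1,
    cds_like: Iterable[str] = CDS_LIKE_DEFAULT,
    with_stats: bool = True,
) -> GuideLibrary:
    """Enumerate, filter and (optionally) summarize a guide library."""
    intergenic = derive_intergenic(genome, min_length=min_intergenic)
    sites = enumerate_candidates(genome)
    lib = apply_retention_rules(sites, genome, intergenic=intergenic, cds_like=cds_like)
    if with_stats and len(lib):
        lib.stats = library_stats(lib, genome)
    return lib


_LIB_COLUMNS = ["spacer", "pam", "strand", "start", "targets", "class", "multi_target", "copies"]


def write_library(lib: GuideLibrary, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
    """TSV of the retained library plus an optional BED6 protospacer track."""
    rows = []
    for g in lib.guides:
        tgt = ",".join(f"{t}:{ov}" for t, ov in g.targets) or "."
        rows.append(
            {
                "spacer": g.spacer,
                "pam": g.pam,
                "strand": g.protospacer_strand,
                "start": g.protospacer_start,
                "targets": tgt,
                "class": g.target_class,
                "multi_target": int(g.multi_target),
                "copies": g.copies,
            }
        )
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(tsv_path, sep="\t", index=False)
    if bed_path is not None:
        L = lib.genome_length
        with open(bed_path, "w") as fh:
            for g in lib.guides:
                a, b = CandidateSite(
                    g.protospacer_strand, g.protospacer_start, g.spacer, g.pam
                ).spacer_interval()
                subs = normalize_interval(a, b, L) if L else [(a, b)]
                for s, e in subs:
                    fh.write(
                        f"{lib.genome_id}\t{s}\t{e}\t{g.spacer}\t0\t{g.protospacer_strand}\n"
                    )


def read_library(tsv_path: str | Path) -> GuideLibrary:
    """Inverse of :func:`write_library` (TSV part)."""
    df = pd.read_csv(
        tsv_path, sep="\t", comment="#", dtype={"spacer": str, "pam": str, "strand": str}
    )
    if list(df.columns) != _LIB_COLUMNS:
        raise ValueError(f"unexpected library header: {list(df.columns)}")
    guides = []
    for spacer, pam, strand, start, targets_s, klass, multi, copies in df.itertuples(
        index=False, name=None
    ):
        targets: list[tuple[str, int]] = []
        if str(targets_s) != ".":
            for chunk in str(targets_s).split(","):
                locus, ov = chunk.rsplit(":", 1)
                targets.append((locus, int(ov)))
        guides.append(
            GuideRecord(
                protospacer_strand=strand,
                protospacer_start=int(start),
                spacer=spacer,
                pam=pam,
                targets=targets,
                target_class=klass,
                multi_target=bool(multi),
                copies=int(copies),
            )
        )
    return GuideLibrary(guides=guides)
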