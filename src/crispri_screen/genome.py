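"""Genome sequence + annotation container and coordinate conventions.

All internal coordinates are 0-based half-open on the forward strand.
GFF3 input/output converts to and from the 1-based inclusive convention.
Circular replicons are supported: a feature that wraps the origin is
stored with ``end > genome length`` and normalizes to two sub-intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
FEATURE_KINDS = ("CDS", "rRNA", "tRNA", "intergenic")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_RC)[::-1]


@dataclass
class Feature:
    """An annotated interval on the genome.

    ``start``/``end`` are 0-based half-open forward-strand coordinates.
    For circular genomes a feature wrapping the origin has
    ``end > genome_length``; :meth:`intervals` yields the normalized
    sub-intervals. ``strand`` is ``'+'``, ``'-'`` or ``'both'``
    (intergenic regions are strandless).
    """

    locus_tag: str
    kind: str
    strand: str
    start: int
    end: int
    gene_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.kind == "intergenic" and self.strand != "both":
            raise ValueError("intergenic features are strandless (strand='both')")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def intervals(self, genome_length: int) -> list[tuple[int, int]]:
        """Normalized sub-intervals within [0, genome_length)."""
        if self.end <= genome_length:
            return [(self.start, self.end)]
        return [(self.start, genome_length), (0, self.end - genome_length)]


@dataclass
class AnnotatedGenome:
    """Single-replicon genome with strand-aware features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
        seen: set[str] = set()
        for f in self.features:
            if f.locus_tag in seen:
                raise ValueError(f"duplicate feature identifier {f.locus_tag!r}")
            seen.add(f.locus_tag)
            limit = 2 * self.length if self.circular else self.length
            if f.end > limit or (not self.circular and f.end > self.length):
                raise ValueError(
                    f"feature {f.locus_tag} interval [{f.start}, {f.end}) "
                    f"exceeds genome length {self.length}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Sequence of [start, end); ``end`` may wrap past the origin on
        circular genomes. ``strand='-'`` returns the reverse complement."""
        if end <= self.length:
            s = self.sequence[start:end]
        elif self.circular:
            s = self.sequence[start:] + self.sequence[: end - self.length]
        else:
            raise ValueError("interval exceeds linear genome")
        return revcomp(s) if strand == "-" else s


def _parse_gff_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for chunk in col9.strip().split(";"):
        chunk = chunk.strip()
        if not chunk or "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_genome(fasta_path: str | Path, gff_path: str | Path, circular: bool = True) -> AnnotatedGenome:
    """Load a single-replicon FASTA + GFF3 into an :class:`AnnotatedGenome`.

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open. Feature kinds other than CDS/rRNA/tRNA are ignored with a
    logged warning. Lowercase bases are uppercased; characters outside
    {A,C,G,T,N} raise ``ValueError``.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()

    features: list[Feature] = []
    skipped: set[str] = set()
    with open(gff_path) as fh:
        for n_anon, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            kind = cols[2]
            if kind not in ("CDS", "rRNA", "tRNA"):
                skipped.add(kind)
                continue
            start1, end1 = int(cols[3]), int(cols[4])
            if start1 < 1 or end1 > len(seq):
                raise ValueError(
                    f"feature coordinates {start1}..{end1} outside genome of length {len(seq)}"
                )
            strand = cols[6]
            if strand not in ("+", "-"):
                raise ValueError(f"feature of kind {kind} requires an explicit strand")
            attrs = _parse_gff_attributes(cols[8])
            locus = attrs.get("locus_tag") or attrs.get("ID") or f"feature_{len(features)+1}"
            features.append(
                Feature(
                    locus_tag=locus,
                    gene_name=attrs.get("gene") or attrs.get("Name"),
                    kind=kind,
                    strand=strand,
                    start=start1 - 1,
                    end=end1,
                )
            )
    if skipped:
        logger.warning("ignored GFF3 feature kinds: %s", ", ".join(sorted(skipped)))
    return AnnotatedGenome(id=rec.id, sequence=seq, circular=circular, features=features)


def write_genome(genome: AnnotatedGenome, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write FASTA + GFF3 such that :func:`read_genome` round-trips."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            if f.kind == "intergenic":
                continue
            attrs = f"locus_tag={f.locus_tag}"
            if f.gene_name:
                attrs += f";gene={f.gene_name}"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "crispri_screen",
                        f.kind,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def _merged_intervals(features: Iterable[Feature], length: int) -> list[tuple[int, int]]:
    ivals: list[tuple[int, int]] = []
    for f in features:
        ivals.extend(f.intervals(length))
    if not ivals:
        return []
    ivals.sort()
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def derive_intergenic(genome: AnnotatedGenome, min_length: int = 1) -> list[Feature]:
    """Maximal gaps between annotated features, as strandless features.

    On circular genomes the gap spanning the origin is reported as a
    single wrapped feature. Gaps shorter than ``min_length`` are dropped.
    """
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    L = genome.length
    annotated = [f for f in genome.features if f.kind != "intergenic"]
    merged = _merged_intervals(annotated, L)

    gaps: list[tuple[int, int]] = []
    if not merged:
        gaps = [(0, L)]
    else:
        for (s1, e1), (s2, _) in zip(merged, merged[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        head = merged[0][0]
        tail = L - merged[-1][1]
        if genome.circular:
            if head and tail:
                gaps.append((merged[-1][1], L + head))  # wraps the origin
            elif tail:
                gaps.append((merged[-1][1], L))
            elif head:
                gaps.append((0, head))
        else:
            if head:
                gaps.insert(0, (0, head))
            if tail:
                gaps.append((merged[-1][1], L))

    out = []
    for i, (s, e) in enumerate(sorted(gaps)):
        if e - s >= min_length:
            out.append(
                Feature(
                    locus_tag=f"intergenic_{i+1:04d}",
                    kind="intergenic",
                    strand="both",
                    start=s,
                    end=e,
                )
            )
    return out
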