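"""Synthetic inputs with planted ground truth for the whole pipeline.

The generator emulates the statistical structure the analysis assumes:

* a circular annotated genome with non-overlapping CDSs on alternating
  strands separated by intergenic gaps;
* pooled-screen counts from exponential growth over G generations
  (default 12): guide i of gene g has expected relative abundance
  proportional to a_i * 2**(G * (1 + s_g(condition) + eps_i)), with
  log-normal initial abundances a_i, per-guide-per-condition efficacy
  noise eps_i ~ N(0, sigma_g), and negative-binomial sequencing noise
  around the multinomial expectation at the configured depth (dispersion
  0 degrades to multinomial). Selection is parameterized per generation,
  so a planted coefficient s maps onto an expected guide log2 fold
  change of G*s;
* amplicon FASTQ in which each spacer sits between the constant anchor
  sequences, in random read orientation;
* luciferase reporter time series: logistic growth from OD 0.05 with
  rlu(t) = A * reporter_factor * od(t) * (1 + eta),
  eta ~ N(0, sigma_lux), sampled every 10 minutes over 8 hours.

Gene classes: ``neutral`` (all s = 0), ``essential`` (equal cost in both
induced conditions), ``competence_costly`` (cost only when competence is
induced — the planted analog of a competence-antagonist gene), and
``competence_required`` (an activator that is nevertheless depleted
under competence induction, the fratricide-style penalty).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from crispri_screen.cog import CogTable
from crispri_screen.counts import AmpliconSchema, CountMatrix
from crispri_screen.design import GuideLibrary
from crispri_screen.genome import AnnotatedGenome, Feature, revcomp
from crispri_screen.reporter import LuxTimeSeries

CONDITIONS = ("mock", "Ci", "CiC")

# synthetic amplification arms; the downstream anchor is the start of the
# sgRNA scaffold so simulated amplicons resemble real constructs
DEFAULT_SCHEMA = AmpliconSchema(
    upstream_anchor="TTGACAGCTAGC",
    downstream_anchor="GTTTTAGAGCTA",
    expected_amplicon_length=219,
)


@dataclass
class SimConfig:
    """Study conditions of the simulated screen."""

    n_genes: int = 1000
    guides_per_gene_mean: float = 24.0  # Poisson mean; None-like fixed via guides_per_gene
    guides_per_gene: Optional[int] = None  # fixed count overrides the Poisson draw
    generations: float = 12.0
    depth: int = 5_000_000  # reads per condition (split over replicates)
    replicates: int = 4
    overdispersion: float = 0.01  # NB dispersion; 0 -> multinomial
    initial_sigma: float = 0.5  # log-normal sigma of initial guide abundance
    guide_effect_sigma: float = 0.02  # per-generation guide efficacy noise
    lux_sigma: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("generations", "depth", "replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("overdispersion", "initial_sigma", "guide_effect_sigma", "lux_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_genome(
    n_genes: int,
    mean_gene_length: int = 900,
    gene_length_spread: int = 500,
    mean_gap: int = 120,
    gc: float = 0.40,
    seed: int = 0,
    circular: bool = True,
) -> tuple[AnnotatedGenome, pd.DataFrame]:
    """Random circular genome with alternating-strand CDSs and gaps.

    Returns the genome and a ground-truth coordinate table
    (locus_tag, start, end, strand, length).
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    lengths = rng.integers(
        max(60, mean_gene_length - gene_length_spread),
        mean_gene_length + gene_length_spread + 1,
        size=n_genes,
    )
    gaps = rng.integers(max(20, mean_gap // 2), mean_gap * 2 + 1, size=n_genes + 1)
    total = int(lengths.sum() + gaps.sum())
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=total, p=p)])

    features = []
    truth_rows = []
    pos = int(gaps[0])
    for i in range(n_genes):
        start, end = pos, pos + int(lengths[i])
        strand = "+" if i % 2 == 0 else "-"
        tag = f"gene_{i+1:04d}"
        features.append(Feature(locus_tag=tag, kind="CDS", strand=strand, start=start, end=end))
        truth_rows.append(
            {"locus_tag": tag, "start": start, "end": end, "strand": strand, "length": end - start}
        )
        pos = end + int(gaps[i + 1])
    if pos > total:
        raise ValueError("genes cannot fit the generated sequence length")
    genome = AnnotatedGenome(id=f"synth_{seed}", sequence=seq, circular=circular, features=features)
    return genome, pd.DataFrame(truth_rows)


def plant_effects(
    gene_ids: list[str],
    n_costly: int = 50,
    n_essential: int = 100,
    n_required: int = 0,
    s_delta: float = -0.25,
    s_essential: float = -0.30,
    costly_reporter_factor: float = 2.0,
    required_reporter_factor: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign per-gene selection coefficients and reporter effects.

    ``competence_costly`` genes cost fitness only under competence
    induction (s_ci = 0, s_cic = s_delta); ``essential`` genes cost
    equally in both induced conditions; ``competence_required`` genes
    are activators carrying the fratricide-style penalty (s_cic =
    s_delta) with reduced reporter activity. Everything is neutral in
    the mock (no dCas9 induction).
    """
    if n_costly + n_essential + n_required > len(gene_ids):
        raise ValueError("more planted genes than genes available")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(gene_ids))
    classes = np.array(["neutral"] * len(gene_ids), dtype=object)
    classes[order[:n_costly]] = "competence_costly"
    classes[order[n_costly : n_costly + n_essential]] = "essential"
    classes[order[n_costly + n_essential : n_costly + n_essential + n_required]] = (
        "competence_required"
    )
    rows = []
    for gene, klass in zip(gene_ids, classes):
        s_ci, s_cic, factor = 0.0, 0.0, 1.0
        if klass == "competence_costly":
            s_cic, factor = s_delta, costly_reporter_factor
        elif klass == "essential":
            s_ci = s_cic = s_essential
        elif klass == "competence_required":
            s_cic, factor = s_delta, required_reporter_factor
        rows.append(
            {
                "gene": gene,
                "class": klass,
                "s_mock": 0.0,
                "s_ci": s_ci,
                "s_cic": s_cic,
                "reporter_factor": factor,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _guide_selection(library: GuideLibrary, truth: pd.DataFrame) -> pd.DataFrame:
    """Per retained guide: spacer and its per-condition selection coefficients
    (intergenic guides and guides of unlisted genes are neutral)."""
    rows = []
    for g in library.guides:
        s_ci = s_cic = 0.0
        if g.target_class == "cds_rule_pass" and g.targets:
            gene = max(g.targets, key=lambda t: (t[1], t[0]))[0]
            if gene in truth.index:
                s_ci = float(truth.loc[gene, "s_ci"])
                s_cic = float(truth.loc[gene, "s_cic"])
        rows.append({"spacer": g.spacer, "s_mock": 0.0, "s_Ci": s_ci, "s_CiC": s_cic})
    df = pd.DataFrame(rows)
    # identical spacers share one abundance slot
    return df.groupby("spacer", sort=True).first()


def simulate_library(gene_ids: list[str], cfg: SimConfig) -> GuideLibrary:
    """Fabricate a retained guide library directly (no genome scan).

    Gives each gene a fixed (``cfg.guides_per_gene``) or Poisson
    (``cfg.guides_per_gene_mean``, minimum 1) number of unique random
    spacers, all single-target coding-strand passes. Used for
    count-level simulations where the sequence context is irrelevant.
    """
    from crispri_screen.design import GuideRecord

    rng = np.random.default_rng(cfg.rng_seed + 2)
    if cfg.guides_per_gene is not None:
        per_gene = np.full(len(gene_ids), cfg.guides_per_gene, dtype=int)
    else:
        per_gene = np.maximum(rng.poisson(cfg.guides_per_gene_mean, size=len(gene_ids)), 1)
    total = int(per_gene.sum())
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    spacers: list[str] = []
    while len(spacers) < total:
        block = rng.choice(4, size=(total, 20))
        for row in block:
            s = "".join(bases[row])
            if s not in seen:
                seen.add(s)
                spacers.append(s)
                if len(spacers) == total:
                    break
    guides = []
    pos = 0
    for gene, k in zip(gene_ids, per_gene):
        for j in range(int(k)):
            guides.append(
                GuideRecord(
                    protospacer_strand="+",
                    protospacer_start=pos * 25,
                    spacer=spacers[pos],
                    pam="AGG",
                    targets=[(gene, 20)],
                    target_class="cds_rule_pass",
                )
            )
            pos += 1
    return GuideLibrary(guides=guides)


def simulate_screen_counts(
    library: GuideLibrary,
    truth: pd.DataFrame,
    cfg: SimConfig,
    fastq_dir: str | Path | None = None,
    schema: AmpliconSchema = DEFAULT_SCHEMA,
) -> CountMatrix:
    """Pooled-screen counts for mock / Ci / CiC with planted effects.

    Optionally writes per-sample amplicon FASTQ files embedding each
    spacer between the schema anchors.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    sel = _guide_selection(library, truth)
    spacers = list(sel.index)
    n = len(spacers)
    if n == 0:
        raise ValueError("empty library")
    a = np.exp(rng.normal(0.0, cfg.initial_sigma, size=n))  # initial abundances

    depth_per_rep = cfg.depth // cfg.replicates
    if depth_per_rep == 0:
        raise ValueError("depth too small for the replicate count")
    cols = {}
    cond_of: dict[str, str] = {}
    rep_of: dict[str, int] = {}
    s_col = {"mock": "s_mock", "Ci": "s_Ci", "CiC": "s_CiC"}
    for cond in CONDITIONS:
        s = sel[s_col[cond]].to_numpy(dtype=float)
        eps = rng.normal(0.0, cfg.guide_effect_sigma, size=n) if cfg.guide_effect_sigma else 0.0
        log2_w = np.log2(a) + cfg.generations * (1.0 + s + eps)
        w = np.exp2(log2_w - log2_w.max())
        p = w / w.sum()
        for r in range(1, cfg.replicates + 1):
            mu = depth_per_rep * p
            if cfg.overdispersion > 0:
                shape = 1.0 / cfg.overdispersion
                lam = rng.gamma(shape, mu / shape)
                counts = rng.poisson(lam)
            else:
                counts = rng.multinomial(depth_per_rep, p)
            sid = f"{cond}_r{r}"
            cols[sid] = counts
            cond_of[sid] = cond
            rep_of[sid] = r

    counts = pd.DataFrame(cols, index=pd.Index(spacers, name="spacer"))
    samples = pd.DataFrame(
        {"condition": [cond_of[s] for s in counts.columns], "replicate": [rep_of[s] for s in counts.columns]},
        index=counts.columns,
    )
    cm = CountMatrix(counts=counts, samples=samples, unassigned=pd.Series(0, index=counts.columns))
    if fastq_dir is not None:
        fastq_dir = Path(fastq_dir)
        fastq_dir.mkdir(parents=True, exist_ok=True)
        for sid in counts.columns:
            write_amplicon_fastq(
                counts[sid], schema, fastq_dir / f"{sid}.fastq", rng=rng
            )
    return cm


def write_amplicon_fastq(
    spacer_counts: pd.Series,
    schema: AmpliconSchema,
    path: str | Path,
    rng: np.random.Generator,
    shuffle: bool = True,
) -> int:
    """Write error-free amplicon reads (anchor+spacer+anchor), random
    orientation; returns the number of reads written."""
    reads = []
    for spacer, k in spacer_counts.items():
        insert = schema.upstream_anchor + spacer + schema.downstream_anchor
        reads.extend([insert] * int(k))
    if shuffle:
        order = rng.permutation(len(reads))
        reads = [reads[i] for i in order]
    flips = rng.random(len(reads)) < 0.5
    with open(path, "w") as fh:
        for i, (read, flip) in enumerate(zip(reads, flips)):
            seq = revcomp(read) if flip else read
            fh.write(f"@read_{i}\n{seq}\n+\n{'I' * len(seq)}\n")
    return len(reads)


def simulate_lux_series(
    clone_id: str,
    reporter_factor: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    spacer: Optional[str] = None,
    base_activity: float = 2000.0,
    duration_min: float = 480.0,
    interval_min: float = 10.0,
) -> LuxTimeSeries:
    """One clone's growth + luminescence curve.

    OD grows logistically from 0.05 to a plateau of 1.5 over the run;
    rlu(t) = base_activity * reporter_factor * od(t) * (1 + eta).
    """
    t = np.arange(0.0, duration_min + interval_min / 2, interval_min)
    od0, k_cap, rate = 0.05, 1.5, 0.025  # per-minute logistic growth rate
    od = k_cap / (1.0 + (k_cap / od0 - 1.0) * np.exp(-rate * t))
    eta = rng.normal(0.0, cfg.lux_sigma, size=len(t)) if cfg.lux_sigma else np.zeros(len(t))
    rlu = np.maximum(base_activity * reporter_factor * od * (1.0 + eta), 0.0)
    return LuxTimeSeries(
        clone_id=clone_id,
        spacer=spacer,
        timepoints=list(zip(t.tolist(), od.tolist(), rlu.tolist())),
    )


def simulate_reporter(
    truth: pd.DataFrame,
    library: GuideLibrary,
    cfg: SimConfig,
    clones_per_gene: int = 3,
) -> tuple[pd.DataFrame, dict[str, LuxTimeSeries]]:
    """Selected-clone sheet + time series for genes with a planted
    promoter effect, plus the no-gRNA reference clone."""
    rng = np.random.default_rng(cfg.rng_seed + 1)
    clone_rows = []
    series: dict[str, LuxTimeSeries] = {}
    series["reference"] = simulate_lux_series("reference", 1.0, cfg, rng)
    clone_rows.append({"clone_id": "reference", "spacer": ".", "phenotype": "reference"})

    affected = truth.index[truth["reporter_factor"] != 1.0]
    n_clone = 0
    for gene in affected:
        factor = float(truth.loc[gene, "reporter_factor"])
        idxs = [
            i
            for i in library.by_gene.get(gene, [])
            if not library.guides[i].multi_target
            and library.guides[i].target_class == "cds_rule_pass"
        ]
        if not idxs:
            continue
        chosen = rng.choice(idxs, size=min(clones_per_gene, len(idxs)), replace=False)
        for i in chosen:
            n_clone += 1
            cid = f"clone_{n_clone:04d}"
            spacer = library.guides[int(i)].spacer
            phenotype = "dark_blue" if factor > 1 else "white"
            clone_rows.append({"clone_id": cid, "spacer": spacer, "phenotype": phenotype})
            series[cid] = simulate_lux_series(cid, factor, cfg, rng, spacer=spacer)
    return pd.DataFrame(clone_rows), series


def simulate_cog(gene_ids: list[str], seed: int = 0) -> CogTable:
    """Random single-letter COG assignments with a bacterially plausible
    category frequency profile; ~10% of genes left unassigned."""
    rng = np.random.default_rng(seed)
    cats = list("JKLMNOCEFGHIPQDTUV")
    weights = np.array([8, 6, 6, 5, 2, 4, 6, 8, 4, 7, 4, 3, 5, 3, 2, 3, 2, 2], dtype=float)
    weights /= weights.sum()
    assignments = {}
    for gene in gene_ids:
        if rng.random() < 0.10:
            continue
        assignments[gene] = cats[int(rng.choice(len(cats), p=weights))]
    return CogTable(assignments=assignments)


def write_timeseries(series: dict[str, LuxTimeSeries], path: str | Path) -> None:
    rows = []
    for cid, ts in series.items():
        for t, od, rlu in ts.timepoints:
            rows.append({"clone_id": cid, "t_min": t, "od600": od, "rlu": rlu})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
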