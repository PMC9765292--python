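import numpy as np
import pytest

from crispri_screen.design import (
    CandidateSite,
    apply_retention_rules,
    design_library,
    enumerate_candidates,
    extract_site,
    library_stats,
    normalize_interval,
    read_library,
    write_library,
)
from crispri_screen.genome import AnnotatedGenome, Feature, revcomp

from conftest import random_genome


def oracle_candidates(seq: str, circular: bool) -> set[tuple]:
    """Brute-force scan: slide a 23-nt window over both explicit strand
    strings; independent of the vectorized implementation."""
    L = len(seq)
    out = set()
    fw = seq + (seq[:22] if circular else "")
    n = L if circular else max(L - 22, 0)
    for i in range(n):
        w = fw[i : i + 23]
        if len(w) == 23 and set(w) <= set("ACGT") and w[21:23] == "GG":
            out.add(("+", i, w[:20], w[20:23]))
    rv = revcomp(seq)
    rv_ext = rv + (rv[:22] if circular else "")
    for j in range(n):
        w = rv_ext[j : j + 23]
        if len(w) == 23 and set(w) <= set("ACGT") and w[21:23] == "GG":
            out.add(("-", (L - 1 - j) % L, w[:20], w[20:23]))
    return out


def oracle_retained(genome: AnnotatedGenome, cds_like=("CDS", "rRNA", "tRNA")) -> set[tuple]:
    """Per-base membership rule checker for the retention rules."""
    L = genome.length
    base_feats: dict[int, list[Feature]] = {}
    for f in genome.features:
        if f.kind not in cds_like:
            continue
        for s, e in f.intervals(L):
            for b in range(s, e):
                base_feats.setdefault(b, []).append(f)
    out = set()
    for strand, start, spacer, pam in oracle_candidates(genome.sequence, genome.circular):
        if strand == "+":
            bases = [(start + k) % L for k in range(20)]
        else:
            bases = [(start - k) % L for k in range(20)]
        touched = [f for b in bases for f in base_feats.get(b, [])]
        if touched:
            if any(f.strand != strand for f in touched):
                out.add((strand, start, spacer, pam, "cds_rule_pass"))
        else:
            out.add((strand, start, spacer, pam, "intergenic"))
    return out


def retained_set(lib) -> set[tuple]:
    return {
        (g.protospacer_strand, g.protospacer_start, g.spacer, g.pam, g.target_class)
        for g in lib.guides
    }


class TestEnumerate:
    def test_poly_a_has_no_candidates(self):
        g = AnnotatedGenome("g", "A" * 200, circular=True)
        assert enumerate_candidates(g) == []

    def test_linear_22nt_too_short(self):
        g = AnnotatedGenome("g", "ACGGGGACGGGGACGGGGACGG", circular=False)
        assert len(g.sequence) == 22
        assert enumerate_candidates(g) == []

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_window_scan_oracle(self, circular):
        rng = np.random.default_rng(17)
        for _ in range(25):
            g = random_genome(rng, int(rng.integers(30, 400)), 0, circular=circular)
            got = {
                (c.protospacer_strand, c.protospacer_start, c.spacer, c.pam)
                for c in enumerate_candidates(g)
            }
            assert got == oracle_candidates(g.sequence, circular)

    def test_window_with_n_skipped(self):
        seq = "ACGTACGTACGTACGTACGTAGGACGT"
        g = AnnotatedGenome("g", seq[:10] + "N" + seq[11:], circular=False)
        starts_clean = {c.protospacer_start for c in enumerate_candidates(AnnotatedGenome("g", seq, circular=False))}
        starts_n = {c.protospacer_start for c in enumerate_candidates(g)}
        assert 0 in starts_clean and 0 not in starts_n

    def test_spacer_pam_reextracts_from_locus(self, toy_genome):
        genome, _ = toy_genome
        for c in enumerate_candidates(genome):
            assert extract_site(genome, c) == c.spacer + c.pam


class TestRetention:
    def test_coding_strand_rule_by_explicit_base_pairing(self):
        # 100-bp toy CDS on the + strand; its coding (nontemplate) strand
        # is the + strand, so an effective guide must base-pair with it,
        # i.e. the protospacer must sit on the - strand.
        rng = np.random.default_rng(5)
        g = random_genome(rng, 150, 0)
        genome = AnnotatedGenome(
            "g", g.sequence, circular=False,
            features=[Feature("cds1", "CDS", "+", 20, 120)],
        )
        sites = enumerate_candidates(genome)
        lib = apply_retention_rules(sites, genome)
        retained = {(g.protospacer_strand, g.protospacer_start) for g in lib.guides}
        checked_plus = checked_minus = False
        for site in sites:
            a, b = site.spacer_interval()
            if not (a >= 20 and b <= 120):
                continue  # only sites wholly inside the CDS
            coding = genome.sequence[a:b]  # + strand is the coding strand here
            key = (site.protospacer_strand, site.protospacer_start)
            if site.protospacer_strand == "-":
                # spacer base-pairs with the coding strand: it IS its
                # reverse complement, hence the guide silences -> retained
                assert site.spacer == revcomp(coding)
                assert key in retained
                checked_minus = True
            else:
                # spacer matches the coding strand, pairs with the
                # template strand only -> rejected
                assert site.spacer == coding
                assert key not in retained
                checked_plus = True
        assert checked_plus and checked_minus

    def test_intergenic_candidates_kept_both_strands(self):
        rng = np.random.default_rng(6)
        genome = random_genome(rng, 300, 0, circular=False)
        lib = apply_retention_rules(enumerate_candidates(genome), genome)
        assert lib.guides and all(g.target_class == "intergenic" for g in lib.guides)
        assert {g.protospacer_strand for g in lib.guides} == {"+", "-"}

    @pytest.mark.parametrize("circular", [False, True])
    def test_matches_per_base_rule_oracle(self, circular):
        rng = np.random.default_rng(23)
        for _ in range(20):
            genome = random_genome(rng, int(rng.integers(100, 800)), int(rng.integers(0, 5)), circular=circular)
            lib = design_library(genome, with_stats=False)
            assert retained_set(lib) == oracle_retained(genome)

    def test_duplicate_spacers_flagged_multi_target(self):
        core = "ACGTACGTACGTACGTACGTAGG"  # 20-nt spacer + AGG PAM
        seq = core + "TTTTTTTTTT" + core + "TTTTTTTTTT"
        genome = AnnotatedGenome("g", seq, circular=False)
        lib = apply_retention_rules(enumerate_candidates(genome), genome)
        dups = [g for g in lib.guides if g.spacer == core[:20]]
        assert len(dups) == 2
        assert all(g.multi_target and g.copies == 2 for g in dups)


class TestReverseComplementSymmetry:
    def test_library_reflects_under_genome_reversal(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            genome = random_genome(rng, int(rng.integers(150, 600)), 3, circular=bool(rng.integers(0, 2)))
            L = genome.length
            flipped = AnnotatedGenome(
                genome.id,
                revcomp(genome.sequence),
                circular=genome.circular,
                features=[
                    Feature(f.locus_tag, f.kind, "-" if f.strand == "+" else "+", L - f.end, L - f.start)
                    for f in genome.features
                ],
            )
            lib = design_library(genome, with_stats=False)
            lib_f = design_library(flipped, with_stats=False)
            reflected = {
                ("-" if s == "+" else "+", (L - 1 - start) % L, spacer, pam, klass)
                for s, start, spacer, pam, klass in retained_set(lib)
            }
            assert reflected == retained_set(lib_f)


class TestLibraryStats:
    def test_single_guide_spacing(self):
        # exactly one NGG site in a 100-bp genome -> spacing 100
        genome = AnnotatedGenome("g", "A" * 20 + "AGG" + "A" * 77, circular=False)
        lib = design_library(genome, with_stats=False)
        assert len(lib) == 1
        stats = library_stats(lib, genome)
        assert stats.mean_spacing_bp == 100

    def test_median_midpoint_convention_and_zero_cds_included(self):
        # fabricate a library over 10 CDSs with guide counts 0..9
        from crispri_screen.design import GuideLibrary, GuideRecord

        feats = [Feature(f"c{i}", "CDS", "+", i * 10, i * 10 + 9) for i in range(10)]
        genome = AnnotatedGenome("g", "A" * 120, circular=False, features=feats)
        guides = []
        for i in range(10):
            for j in range(i):
                guides.append(
                    GuideRecord("-", i * 10 + j, f"S{i}_{j:02d}" + "A" * 13, "AGG",
                                targets=[(f"c{i}", 20)], target_class="cds_rule_pass")
                )
        lib = GuideLibrary(guides=guides, genome_id="g", genome_length=120)
        stats = library_stats(lib, genome)
        assert stats.median_guides_per_cds == 4.5  # midpoint of {0..9}
        assert stats.coverage.set_index("locus_tag").loc["c0", "n_guides"] == 0

    def test_empty_library_errors(self):
        genome = AnnotatedGenome("g", "A" * 100, circular=False)
        from crispri_screen.design import GuideLibrary

        with pytest.raises(ValueError):
            library_stats(GuideLibrary(guides=[]), genome)


class TestLibraryIO:
    def test_round_trip(self, tmp_path, toy_library):
        write_library(toy_library, tmp_path / "lib.tsv")
        lib2 = read_library(tmp_path / "lib.tsv")
        assert [vars(g) for g in lib2.guides] == [vars(g) for g in toy_library.guides]

    def test_empty_library_header_only(self, tmp_path):
        from crispri_screen.design import GuideLibrary

        write_library(GuideLibrary(guides=[]), tmp_path / "empty.tsv")
        lines = (tmp_path / "empty.tsv").read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("spacer\t")

    def test_bed_intervals_match_protospacer_coordinates(self, tmp_path, toy_genome, toy_library):
        genome, _ = toy_genome
        write_library(toy_library, tmp_path / "lib.tsv", bed_path=tmp_path / "lib.bed")
        for line in (tmp_path / "lib.bed").read_text().splitlines():
            chrom, s, e, spacer, _, strand = line.split("\t")
            s, e = int(s), int(e)
            seq = genome.sequence[s:e]
            # each BED block is a (possibly partial, if origin-wrapped)
            # forward-strand segment of the protospacer
            if strand == "+":
                assert seq in spacer or spacer in seq
            else:
                assert seq in revcomp(spacer) or revcomp(spacer) in seq


def test_normalize_interval_wraps():
    assert normalize_interval(90, 110, 100) == [(90, 100), (0, 10)]
    assert normalize_interval(-5, 15, 100) == [(95, 100), (0, 15)]
    assert normalize_interval(10, 30, 100) == [(10, 30)]
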