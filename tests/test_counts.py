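import numpy as np
import pandas as pd
import pytest

from crispri_screen import simulate as sim
from crispri_screen.counts import (
    AmpliconSchema,
    CountMatrix,
    count_reads,
    extract_spacer,
    median_ratio_normalize,
    pool_replicates,
)
from crispri_screen.genome import revcomp

SCHEMA = sim.DEFAULT_SCHEMA


class TestExtractSpacer:
    def test_constructed_read_recovers_spacer(self):
        spacer = "ACGTACGTACGTACGTACGT"
        read = SCHEMA.upstream_anchor + spacer + SCHEMA.downstream_anchor
        assert extract_spacer(read, SCHEMA) == spacer
        assert extract_spacer(revcomp(read), SCHEMA) == spacer

    def test_missing_anchor_returns_none(self):
        spacer = "ACGTACGTACGTACGTACGT"
        assert extract_spacer(spacer + SCHEMA.downstream_anchor, SCHEMA) is None
        assert extract_spacer(SCHEMA.upstream_anchor + spacer, SCHEMA) is None

    def test_wrong_gap_rejected(self):
        spacer21 = "ACGTACGTACGTACGTACGTA"
        read = SCHEMA.upstream_anchor + spacer21 + SCHEMA.downstream_anchor
        assert extract_spacer(read, SCHEMA) is None

    def test_one_mismatch_mode(self):
        spacer = "ACGTACGTACGTACGTACGT"
        up = SCHEMA.upstream_anchor
        mutated = "A" + up[1:] if up[0] != "A" else "C" + up[1:]
        read = mutated + spacer + SCHEMA.downstream_anchor
        assert extract_spacer(read, SCHEMA) is None
        assert extract_spacer(read, SCHEMA, max_anchor_mismatches=1) == spacer

    def test_short_anchor_rejected_by_schema(self):
        with pytest.raises(ValueError):
            AmpliconSchema("ACGTACG", "GTTTTAGAGCTA")


class TestCountReads:
    def test_zero_reads_all_zero(self, tmp_path, toy_library):
        f = tmp_path / "empty.fastq"
        f.write_text("")
        cm = count_reads({"s1": f}, toy_library, SCHEMA)
        assert cm.counts["s1"].sum() == 0 and cm.unassigned["s1"] == 0

    def test_known_mixture_exact_and_order_invariant(self, tmp_path, toy_library):
        rng = np.random.default_rng(8)
        spacers = sorted(toy_library.by_spacer)[:50]
        comp = pd.Series(rng.integers(1, 40, size=50), index=spacers)
        n = sim.write_amplicon_fastq(comp, SCHEMA, tmp_path / "a.fastq", rng, shuffle=False)
        sim.write_amplicon_fastq(comp, SCHEMA, tmp_path / "b.fastq", rng, shuffle=True)
        cm = count_reads({"a": tmp_path / "a.fastq", "b": tmp_path / "b.fastq"}, toy_library, SCHEMA)
        assert cm.unassigned.tolist() == [0, 0]
        got_a = cm.counts.loc[spacers, "a"]
        assert (got_a == comp).all()
        assert (cm.counts["a"] == cm.counts["b"]).all()  # read order irrelevant
        assert cm.total_reads()["a"] == n

    def test_foreign_spacer_counts_unassigned(self, tmp_path, toy_library):
        foreign = "TTTTTTTTTTTTTTTTTTTT"
        assert foreign not in toy_library.by_spacer
        read = SCHEMA.upstream_anchor + foreign + SCHEMA.downstream_anchor
        (tmp_path / "f.fastq").write_text(f"@r\n{read}\n+\n{'I'*len(read)}\n")
        cm = count_reads({"s": tmp_path / "f.fastq"}, toy_library, SCHEMA)
        assert cm.counts["s"].sum() == 0 and cm.unassigned["s"] == 1
        assert cm.total_reads()["s"] == 1


class TestPoolReplicates:
    def test_single_replicate_identity(self, small_screen):
        lib, truth, cm, cfg = small_screen
        one = CountMatrix(
            counts=cm.counts[["mock_r1"]],
            samples=cm.samples.loc[["mock_r1"]],
            unassigned=cm.unassigned[["mock_r1"]],
        )
        pooled = pool_replicates(one)
        assert (pooled.counts["mock"] == cm.counts["mock_r1"]).all()

    def test_sums_equal_oracle_addition(self, small_screen):
        lib, truth, cm, cfg = small_screen
        pooled = pool_replicates(cm)
        for cond in ("mock", "Ci", "CiC"):
            reps = [c for c in cm.counts.columns if c.startswith(cond + "_")]
            assert (pooled.counts[cond] == cm.counts[reps].sum(axis=1)).all()

    def test_unknown_condition_rejected(self, small_screen):
        _, _, cm, _ = small_screen
        with pytest.raises(ValueError):
            pool_replicates(cm, conditions=["mock", "nope"])


class TestMedianRatioNormalize:
    def test_identical_columns_unit_factors(self):
        df = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        nc = median_ratio_normalize(df)
        assert np.allclose(nc.size_factors, 1.0)

    def test_scaling_law(self):
        rng = np.random.default_rng(2)
        base = rng.integers(5, 500, size=50)
        df = pd.DataFrame({"a": base, "b": base * 3})
        nc = median_ratio_normalize(df)
        assert np.isclose(nc.size_factors["b"] / nc.size_factors["a"], 3.0)

    def test_hand_matrix_oracle(self):
        # 5 guides x 3 samples; size factors worked out by hand:
        # g_i = (c1*c2*c3)^(1/3); sf_j = median_i(c_ij/g_i)
        df = pd.DataFrame(
            {"s1": [10, 20, 40, 5, 100], "s2": [20, 40, 80, 10, 200], "s3": [10, 10, 40, 20, 100]},
            index=[f"g{i}" for i in range(5)],
        )
        g = (df.prod(axis=1)) ** (1 / 3)
        expect = (df.div(g, axis=0)).median(axis=0)
        nc = median_ratio_normalize(df)
        assert np.allclose(nc.size_factors, expect)

    def test_depth_invariance_of_fold_changes(self):
        # scaling one sample's depth must not move any between-sample
        # fold change; the normalized matrix is defined up to one global
        # factor (the geometric-mean reference shifts by k^(1/m))
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.integers(1, 1000, size=(100, 3)), columns=list("abc"))
        nc1 = median_ratio_normalize(df)
        df2 = df.copy()
        df2["b"] = df2["b"] * 7
        nc2 = median_ratio_normalize(df2)
        ratio = nc2.matrix.to_numpy() / nc1.matrix.to_numpy()
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-9)
        for s, t in [("a", "b"), ("b", "c"), ("a", "c")]:
            assert np.allclose(nc1.matrix[s] / nc1.matrix[t], nc2.matrix[s] / nc2.matrix[t], rtol=1e-9)

    def test_requires_common_nonzero_guide(self):
        df = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="nonzero"):
            median_ratio_normalize(df)


def test_count_matrix_round_trip(tmp_path, small_screen):
    _, _, cm, _ = small_screen
    cm.to_tsv(tmp_path / "c.tsv")
    back = CountMatrix.from_tsv(tmp_path / "c.tsv", samples=cm.samples)
    assert back.counts.equals(cm.counts)
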