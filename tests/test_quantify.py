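"""RPKM arithmetic, replicate QC and merging semantics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdseq.io import exonic_lengths_from_gtf, write_gtf
from cdseq.models import CountLibrary, TranscriptModel
from cdseq.quantify import (
    compute_rpkm,
    detected,
    merge_replicates,
    replicate_correlation,
    rpkm_matrix,
)
from cdseq.synthetic import SimulationConfig, simulate_counts


class TestComputeRpkm:
    @pytest.mark.parametrize(
        "c,l,n,expected",
        [
            (0, 2000, 5_000_000, 0.0),
            (500, 2000, 5_000_000, 50.0),
            (1000, 1000, 10**9, 1.0),
        ],
    )
    def test_worked_examples(self, c, l, n, expected):
        assert compute_rpkm(c, l, n) == pytest.approx(expected)

    @pytest.mark.parametrize("c,l,n", [(1, 0, 100), (1, 100, 0), (-1, 100, 100)])
    def test_domain_errors(self, c, l, n):
        with pytest.raises(ValueError):
            compute_rpkm(c, l, n)

    @given(
        c=st.integers(min_value=0, max_value=10**6),
        l=st.integers(min_value=1, max_value=10**5),
        n=st.integers(min_value=1, max_value=10**9),
        k=st.integers(min_value=1, max_value=1000),
    )
    def test_depth_scaling_invariance_and_linearity(self, c, l, n, k):
        base = compute_rpkm(c, l, n)
        assert compute_rpkm(k * c, l, k * n) == pytest.approx(base, rel=1e-9)
        assert compute_rpkm(k * c, l, n) == pytest.approx(k * base, rel=1e-9)


class TestReplicateCorrelation:
    def _models(self, n=5):
        return [TranscriptModel(f"T{i}", f"L{i}", 1000 + i) for i in range(n)]

    def test_self_correlation_is_one(self):
        models = self._models()
        lib = CountLibrary(
            "root", "0h", {m.transcript_id: 10 * (i + 1) for i, m in enumerate(models)}, 10_000
        )
        assert replicate_correlation(lib, lib, models) == pytest.approx(1.0)

    def test_invariant_to_sequencing_depth(self):
        models = self._models()
        counts = {m.transcript_id: 7 * (i + 1) for i, m in enumerate(models)}
        a = CountLibrary("root", "0h", counts, 10_000, replicate=1)
        b = CountLibrary(
            "root", "0h", {t: 2 * c for t, c in counts.items()}, 20_000, replicate=2
        )
        assert replicate_correlation(a, b, models) == pytest.approx(1.0)

    def test_independent_replicates_highly_correlated(self):
        cfg = SimulationConfig(
            n_transcripts=1000, n_replicates=2, de_fraction=0.0, dispersion=0.0, seed=5
        )
        libraries, models, _ = simulate_counts(cfg)
        a, b = [l for l in libraries if (l.tissue, l.condition) == ("root", "0h")]
        assert replicate_correlation(a, b, models) > 0.9

    def test_errors(self):
        models = self._models(2)
        lib = CountLibrary("root", "0h", {"T0": 5, "T1": 5}, 100)
        other = CountLibrary("shoot", "0h", {"T0": 5, "T1": 5}, 100)
        with pytest.raises(ValueError, match="matching tissue/condition"):
            replicate_correlation(lib, other, models)
        with pytest.raises(ValueError, match="at least 3"):
            replicate_correlation(lib, lib, models)


class TestMergeReplicates:
    def test_single_library_unchanged_up_to_replicate_field(self):
        lib = CountLibrary("root", "0h", {"T1": 3}, 100, replicate=1)
        merged = merge_replicates([lib])
        assert merged.counts == lib.counts and merged.n_total == 100
        assert merged.replicate is None

    def test_counts_and_totals_sum(self):
        a = CountLibrary("root", "0h", {"T1": 3}, 100, replicate=1)
        b = CountLibrary("root", "0h", {"T1": 5}, 200, replicate=2)
        merged = merge_replicates([a, b])
        assert merged.counts == {"T1": 8} and merged.n_total == 300

    def test_mixed_conditions_rejected(self):
        a = CountLibrary("root", "0h", {"T1": 3}, 100)
        b = CountLibrary("root", "1h", {"T1": 5}, 200)
        with pytest.raises(ValueError):
            merge_replicates([a, b])

    def test_merged_rpkm_is_pooled_not_averaged(self):
        # hand-built counterexample: two replicates of very different
        # depth; pooling weights the deep library, averaging does not
        models = [TranscriptModel("T1", "L1", 1000), TranscriptModel("T2", "L2", 1000)]
        a = CountLibrary("root", "0h", {"T1": 10, "T2": 90}, 100, replicate=1)
        b = CountLibrary("root", "0h", {"T1": 900, "T2": 100}, 1000, replicate=2)
        merged = merge_replicates([a, b])
        pooled = compute_rpkm(910, 1000, 1100)
        mean_of_rpkm = (compute_rpkm(10, 1000, 100) + compute_rpkm(900, 1000, 1000)) / 2
        got = rpkm_matrix([merged], models).loc["T1"].iloc[0]
        assert got == pytest.approx(pooled)
        assert got != pytest.approx(mean_of_rpkm)


class TestExpressionMatrix:
    def test_detection_rule_matches_positive_rpkm(self, small_dataset):
        libraries, models, _ = small_dataset
        mat = rpkm_matrix(libraries[:2], models)
        det = detected(mat)
        assert det.to_numpy().sum() == (mat.to_numpy() > 0).sum()
        assert (mat.to_numpy() >= 0).all()

    def test_absent_transcripts_are_zero(self):
        models = [TranscriptModel("T1", "L1", 500), TranscriptModel("T2", "L2", 500)]
        lib = CountLibrary("root", "0h", {"T1": 10}, 1000)
        mat = rpkm_matrix([lib], models)
        assert mat.loc["T2"].iloc[0] == 0.0


class TestGtfLengths:
    def test_union_of_overlapping_exons(self, tmp_path):
        gtf = tmp_path / "m.gtf"
        lines = [
            # T1: exons 101-200 and 151-300 overlap -> union 101-300 = 200 nt
            'chr1\tx\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "T1";',
            'chr1\tx\texon\t151\t300\t.\t+\t.\tgene_id "g1"; transcript_id "T1";',
            # T2: disjoint exons 1-100 and 201-250 -> 100 + 50 = 150 nt
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g2"; transcript_id "T2";',
            'chr1\tx\texon\t201\t250\t.\t+\t.\tgene_id "g2"; transcript_id "T2";',
        ]
        gtf.write_text("\n".join(lines) + "\n")
        lengths = exonic_lengths_from_gtf(gtf)
        assert lengths == {"T1": 200, "T2": 150}

    def test_roundtrip_with_writer(self, tmp_path):
        models = [TranscriptModel("T1", "L1", 777), TranscriptModel("T2", "L2", 1234)]
        path = tmp_path / "models.gtf"
        write_gtf(models, path)
        lengths = exonic_lengths_from_gtf(path)
        assert lengths == {"T1": 777, "T2": 1234}
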