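"""Batch engine: streaming, determinism, output formats."""

import io

import numpy as np
import pytest

from pseaac.batch import RunConfig, run_batch
from pseaac.errors import ArgumentError, ConfigurationError
from pseaac.output import read_matrix_csv, write_output
from pseaac.registry import default_resources, register_builtin_modes
from pseaac.synthetic import synth_fasta, synth_proteins


def _run(mode, fasta_text, **kwargs):
    out = io.StringIO()
    report = run_batch(
        RunConfig(mode=mode, fasta=io.StringIO(fasta_text), out=out, **kwargs)
    )
    return out.getvalue(), report


class TestRunBatch:
    def test_two_record_aac_csv(self):
        text, report = _run("aac", ">p1\nACDE\n>p2\nAAAA\n")
        lines = text.splitlines()
        assert len(lines) == 3
        assert lines[0].split(",")[0] == "id"
        assert len(lines[0].split(",")) == 21
        assert report.records_written == 2
        assert report.output_dim == 20

    def test_empty_fasta_header_only(self):
        text, report = _run("aac", "")
        assert text.splitlines() == [
            ",".join(["id"] + [f"AAC_{a}" for a in "ACDEFGHIKLMNPQRSTVWY"])
        ]
        assert report.records_read == 0

    def test_rows_preserve_fasta_order(self):
        fasta = synth_fasta(4, 20, (40, 60))
        text, _ = _run("dpc", fasta)
        ids = [ln.split(",")[0] for ln in text.splitlines()[1:]]
        expected = [r.id for r in synth_proteins(4, 20, (40, 60))]
        assert ids == expected

    def test_determinism_byte_identical(self):
        fasta = synth_fasta(8, 25, (50, 90))
        text1, _ = _run("pseaac1", fasta, params={"lam": 12})
        text2, _ = _run("pseaac1", fasta, params={"lam": 12})
        assert text1 == text2

    def test_skip_policy_counts_short_sequences(self):
        fasta = ">ok\n" + "ACDEFGHIKL" * 6 + "\n>short\nACD\n"
        text, report = _run(
            "pseaac1", fasta, params={"lam": 10}, on_error="skip"
        )
        assert report.records_read == 2
        assert report.records_written == 1
        assert report.records_skipped == 1
        assert "short" in report.skip_reasons[0]

    def test_abort_policy_raises_with_offender(self):
        fasta = ">short\nACD\n"
        with pytest.raises(Exception, match="short"):
            _run("pseaac1", fasta, params={"lam": 10})

    def test_missing_side_input_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="annotation"):
            _run("go", ">p1\nACDE\n")

    def test_streaming_one_record_at_a_time(self):
        """The engine must write row i before pulling record i+2: proof
        that it never accumulates records or vectors."""
        out = io.StringIO()
        records = synth_proteins(2, 50, (40, 60))
        pulled = 0

        def lazy_records():
            nonlocal pulled
            for rec in records:
                pulled += 1
                rows_so_far = out.getvalue().count("\n") - 1  # minus header
                assert rows_so_far >= pulled - 2
                yield rec

        report = run_batch(
            RunConfig(mode="aac", fasta=None, out=out),
            records=lazy_records(),
        )
        assert report.records_written == 50

    def test_moderate_batch_completes(self):
        """2,000 synthetic records through a correlation mode in one pass."""
        fasta = synth_fasta(3, 2000, (40, 80))
        text, report = _run("pseaac1", fasta, params={"lam": 8})
        assert report.records_written == 2000
        assert len(text.splitlines()) == 2001


class TestWriters:
    def test_csv_round_trip_12_sig_digits(self, tmp_path):
        rng = np.random.default_rng(0)
        rows = [(f"p{i}", rng.random(7)) for i in range(5)]
        names = [f"F{j}" for j in range(7)]
        path = tmp_path / "m.csv"
        with open(path, "w") as fh:
            write_output(iter(rows), names, fh, "csv")
        ids, cols, values = read_matrix_csv(path)
        assert ids == [r[0] for r in rows]
        assert cols == names
        original = np.stack([r[1] for r in rows])
        assert np.allclose(values, original, rtol=1e-11)

    def test_svmlight_sparse_and_parseable(self, tmp_path):
        from sklearn.datasets import load_svmlight_file

        fasta = ">p1\nACDACD\n>p2\nAAAA\n"
        out = io.StringIO()
        run_batch(
            RunConfig(mode="tpc", fasta=io.StringIO(fasta), out=out,
                      output_format="svmlight")
        )
        lines = out.getvalue().splitlines()
        # sparsity bound: at most L-2 nonzero tripeptides per row
        assert len(lines[0].split("#")[0].split()) - 1 <= 4
        assert lines[0].rstrip().endswith("# p1")
        path = tmp_path / "m.svml"
        path.write_text("\n".join(ln.split(" #")[0] for ln in lines) + "\n")
        X, y = load_svmlight_file(str(path), n_features=8000)
        assert X.shape == (2, 8000)
        assert X[1].toarray()[0][0] == 1.0  # TPC_AAA is feature 1

    def test_unknown_format_rejected(self):
        with pytest.raises(ArgumentError):
            write_output(iter([]), ["F"], io.StringIO(), "parquet")


class TestHeaderStability:
    def test_feature_names_stable_across_runs(self):
        registry = register_builtin_modes()
        res = default_resources()
        rec = synth_proteins(1, 1, (100, 100))[0]
        for mode in ("aac", "ctd", "qso", "pseaac2", "nmbroto"):
            v1 = registry.compute_checked(mode, rec, None, res)
            v2 = registry.compute_checked(mode, rec, None, res)
            assert v1.feature_names == v2.feature_names
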