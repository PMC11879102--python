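"""Readers/writers round-trips, validation errors and the pipeline runner."""

import json

import numpy as np
import pytest

from cmtarget.binding import BindingScore
from cmtarget.connectivity import ConnectivityResult
from cmtarget.fileio import (
    RunConfig,
    build_signature_library,
    read_compounds,
    read_fasta,
    read_gmt,
    read_profiles,
    read_results,
    read_rnk,
    read_scores,
    read_signature_library,
    run_pipeline,
    write_compounds,
    write_fasta,
    write_gmt,
    write_profiles,
    write_results,
    write_rnk,
    write_scores,
    write_signature_library,
)
from cmtarget.simulate import (
    SimulationConfig,
    generate_genesets,
    generate_query,
    generate_signature_library,
    generate_target_genesets,
)


class TestRnk:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "q.rnk"
        path.write_text("a\t3.0\nb\t1.5\nc\t-0.5\n")
        q = read_rnk(path)
        assert q.gene_ids == ["a", "b", "c"]
        np.testing.assert_allclose(q.metrics, [3.0, 1.5, -0.5])

    def test_unsorted_input_is_sorted_with_warning(self, tmp_path, caplog):
        path = tmp_path / "q.rnk"
        path.write_text("a\t1.0\nb\t5.0\nc\t3.0\n")
        with caplog.at_level("WARNING", logger="cmtarget.fileio"):
            q = read_rnk(path)
        assert q.gene_ids == ["b", "c", "a"]
        assert any("sort" in m for m in caplog.messages)

    def test_duplicate_gene_names_line_and_gene(self, tmp_path):
        path = tmp_path / "q.rnk"
        path.write_text("a\t1.0\nb\t0.5\na\t0.2\n")
        with pytest.raises(ValueError, match=r"3.*'a'|'a'.*3"):
            read_rnk(path)

    def test_non_numeric_metric_names_line(self, tmp_path):
        path = tmp_path / "q.rnk"
        path.write_text("a\t1.0\nb\thigh\n")
        with pytest.raises(ValueError, match="2"):
            read_rnk(path)

    def test_round_trip(self, tmp_path):
        _, truth = generate_signature_library(
            SimulationConfig(n_genes=100, n_targets=2, replicates_per_target=2,
                             signature_size=5, seed=1)
        )
        q = generate_query(truth, [("T1", +1)], seed=2)
        path = tmp_path / "q.rnk"
        write_rnk(q, path)
        back = read_rnk(path, label=q.label)
        assert back.gene_ids == q.gene_ids
        np.testing.assert_allclose(back.metrics, q.metrics, rtol=1e-5)


class TestGmtAndFasta:
    def test_gmt_round_trip(self, tmp_path):
        _, truth = generate_signature_library(
            SimulationConfig(n_genes=100, n_targets=2, replicates_per_target=2,
                             signature_size=5, seed=1)
        )
        collection, _ = generate_genesets(truth, n_sets=4, set_size=10, seed=3)
        path = tmp_path / "sets.gmt"
        write_gmt(collection, path)
        back = read_gmt(path)
        assert back.sets == collection.sets

    def test_gmt_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("ok\tdesc\tg1\tg2\nbad_line_without_members\n")
        with pytest.raises(ValueError, match="2"):
            read_gmt(path)

    def test_empty_gmt_rejected(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_gmt(path)

    def test_fasta_wrapped_lines_concatenate(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">p1\nMKVA\nHLW\n>p2\nACDE\n")
        proteins = read_fasta(path)
        assert proteins == {"p1": "MKVAHLW", "p2": "ACDE"}

    def test_fasta_round_trip(self, tmp_path):
        proteins = {"p1": "M" * 130, "p2": "ACDEFGHIKL"}
        path = tmp_path / "p.fasta"
        write_fasta(proteins, path)
        assert read_fasta(path) == proteins


class TestTables:
    def test_signature_library_round_trip(self, tmp_path):
        config = SimulationConfig(n_genes=100, n_targets=3,
                                  replicates_per_target=2, signature_size=5,
                                  seed=4)
        signatures, _ = generate_signature_library(config)
        library, _ = build_signature_library(signatures, 5)
        path = tmp_path / "siglib.tsv"
        write_signature_library(library, path)
        back = read_signature_library(path)
        assert {s.target_id: (s.t_up, s.t_down) for s in back} == {
            s.target_id: (s.t_up, s.t_down) for s in library
        }

    def test_profiles_round_trip(self, tmp_path):
        config = SimulationConfig(n_genes=50, n_targets=2,
                                  replicates_per_target=2, signature_size=5,
                                  seed=5)
        signatures, _ = generate_signature_library(config)
        write_profiles(signatures, tmp_path / "prof.tsv", tmp_path / "meta.tsv")
        back = read_profiles(tmp_path / "prof.tsv", tmp_path / "meta.tsv")
        assert [s.signature_id for s in back] == [s.signature_id for s in signatures]
        np.testing.assert_allclose(back[0].values, signatures[0].values, rtol=1e-5)

    def test_results_round_trip(self, tmp_path):
        results = [
            ConnectivityResult("t1", 0.5, 0.01, 3.2, 0.001, 10, 9),
            ConnectivityResult("t2", -0.25, 0.2, -1.1, 0.4, 8, 10),
        ]
        path = tmp_path / "res.tsv"
        write_results(results, path)
        back = read_results(path)
        assert [r.target_id for r in back] == ["t1", "t2"]
        assert back[0].nets == pytest.approx(3.2)
        assert back[1].n_genes_matched_down == 10

    def test_scores_and_compounds_round_trip(self, tmp_path):
        compounds = {"c1": "CCO", "c2": "c1ccccc1"}
        write_compounds(compounds, tmp_path / "c.tsv")
        assert read_compounds(tmp_path / "c.tsv") == compounds
        scores = [BindingScore("c1", "p1", 0.95), BindingScore("c2", "p2", 0.1)]
        write_scores(scores, tmp_path / "s.tsv")
        back = read_scores(tmp_path / "s.tsv")
        assert [(s.compound_id, s.protein_id) for s in back] == [
            ("c1", "p1"), ("c2", "p2")
        ]


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    """Simulated pipeline inputs: signature library, queries, binding, GMT."""
    outdir = tmp_path_factory.mktemp("inputs")
    config = SimulationConfig(
        n_genes=300, n_targets=5, replicates_per_target=3,
        signature_size=10, seed=6,
    )
    signatures, truth = generate_signature_library(config)
    library, _ = build_signature_library(signatures, 10)
    write_signature_library(library, outdir / "siglib.tsv")
    disease = generate_query(
        truth, [("T1", +1), ("T2", +1)], seed=6, label="disease"
    )
    write_rnk(disease, outdir / "disease.rnk")
    write_rnk(disease.negated(), outdir / "drug.rnk")
    scores = [BindingScore("c1", "T1", 0.99), BindingScore("c2", "T9", 0.95)]
    write_scores(scores, outdir / "binding.tsv")
    collection = generate_target_genesets(truth, ["T1", "T2"], seed=6)
    write_gmt(collection, outdir / "sets.gmt")
    return outdir


class TestPipeline:
    def run_config(self, fixture_dir, outdir, **kwargs):
        defaults = dict(
            siglib=str(fixture_dir / "siglib.tsv"),
            drug_rnk=str(fixture_dir / "drug.rnk"),
            disease_rnk=str(fixture_dir / "disease.rnk"),
            binding_scores=str(fixture_dir / "binding.tsv"),
            gmt=str(fixture_dir / "sets.gmt"),
            outdir=str(outdir),
            n_perm=100,
            seed=5,
        )
        defaults.update(kwargs)
        return RunConfig(**defaults)

    def test_end_to_end_outputs_and_manifest(self, fixture_dir, tmp_path):
        rundir = run_pipeline(self.run_config(fixture_dir, tmp_path / "run"))
        for name in (
            "drug_results.tsv", "disease_results.tsv", "target_calls.tsv",
            "component_network.tsv", "manifest.json",
        ):
            assert (rundir / name).exists(), name
        manifest = json.loads((rundir / "manifest.json").read_text())
        assert manifest["seed"] == 5
        assert manifest["counts"]["targets_scored"] == 5
        assert set(manifest["inputs"]) == {
            "siglib", "drug_rnk", "disease_rnk", "binding_scores", "gmt"
        }

    def test_rerun_is_byte_identical(self, fixture_dir, tmp_path):
        a = run_pipeline(self.run_config(fixture_dir, tmp_path / "a"))
        b = run_pipeline(self.run_config(fixture_dir, tmp_path / "b"))
        for name in ("drug_results.tsv", "disease_results.tsv",
                     "target_calls.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_missing_binding_degrades_to_all_indirect(self, fixture_dir,
                                                      tmp_path, caplog):
        with caplog.at_level("WARNING", logger="cmtarget.fileio"):
            rundir = run_pipeline(
                self.run_config(fixture_dir, tmp_path / "nb",
                                binding_scores=None)
            )
        assert any("indirect" in m for m in caplog.messages)
        calls = (rundir / "target_calls.tsv").read_text()
        assert "direct" not in calls.replace("indirect", "")

    def test_invalid_thresholds_rejected(self, fixture_dir, tmp_path):
        with pytest.raises(ValueError):
            self.run_config(fixture_dir, tmp_path / "x", fdr_threshold=1.5)
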