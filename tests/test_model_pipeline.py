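import json

import pytest
import yaml
from click.testing import CliRunner

from chipscan import cli as ccli
from chipscan import io as cio
from chipscan import simulate as sim
from chipscan.model import BindingModel
from chipscan.pipeline import run_pipeline


class TestModel:
    def test_fit_produces_consistent_results(self, small_array):
        _, probes, genes, _ = small_array
        res = BindingModel(probes, genes).fit(n_permutations=2, seed=1)
        assert res.n_regions == len(res.regions)
        assert res.n_significant_triplets >= res.n_regions
        assert res.fdr.observed_regions == res.n_regions
        assert (res.regions["n_probes"] >= 3).all()
        assert (res.regions["start"] < res.regions["end"]).all()
        # merged regions never overlap on a chromosome
        for _, grp in res.regions.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_report_and_summary(self, small_array):
        _, probes, genes, _ = small_array
        res = BindingModel(probes, genes).fit(n_permutations=2, seed=1)
        rep = res.report()
        for key in ("n_probes", "n_regions", "fdr", "targets", "config", "version"):
            assert key in rep
        assert rep["targets"]["fraction_of_array"] == pytest.approx(
            rep["targets"]["unique_gene_counts"].get("protein_coding", 0)
            / rep["targets"]["array_gene_total"]
        )
        text = res.summary()
        assert "bound regions" in text and "empirical FDR" in text

    def test_save_round_trips_regions(self, small_array, tmp_path):
        _, probes, genes, _ = small_array
        res = BindingModel(probes, genes).fit(n_permutations=0, seed=1)
        assert res.fdr is None
        res.save(tmp_path)
        back = cio.read_regions_bed(tmp_path / "regions.bed")
        assert back["region_id"].tolist() == res.regions["region_id"].tolist()
        assert back["start"].tolist() == res.regions["start"].tolist()

    def test_tss_profile_requires_genes(self, small_array):
        _, probes, _, _ = small_array
        res = BindingModel(probes).fit(n_permutations=0)
        with pytest.raises(ValueError, match="gene annotation"):
            res.tss_profile()


class TestPipeline:
    def _config(self, **extra):
        cfg = {
            "simulate": {"n_genes": 150},
            "caller": {"n_permutations": 2},
        }
        cfg.update(extra)
        return cfg

    def test_simulate_then_analyze_report_complete(self, tmp_path):
        report = run_pipeline(self._config(), tmp_path, seed=1)
        assert report["incomplete"] is False
        assert report["recovery_vs_truth"]["sensitivity"] >= 0.9
        assert (tmp_path / "regions.bed").exists()
        assert (tmp_path / "tss_profile.tsv").exists()
        on_disk = json.loads((tmp_path / "report.json").read_text())
        assert on_disk == report

    def test_no_motif_config_omits_motif_block(self, tmp_path):
        report = run_pipeline(self._config(), tmp_path, seed=1)
        assert "motif" not in report

    def test_same_seed_identical_reports(self, tmp_path):
        a = run_pipeline(self._config(), tmp_path / "a", seed=5)
        b = run_pipeline(self._config(), tmp_path / "b", seed=5)
        assert a == b

    def test_optional_stages_run_when_configured(self, tmp_path):
        seqs_dir = tmp_path / "seqs"
        sim.simulate_sequences(40, 200, 0.5, "CACCAGGG", 0.6, seed=2, outdir=seqs_dir)
        lib_path = tmp_path / "lib.pwm"
        cio.write_pwm_library(sim.decoy_pwm_library(3, seed=1), lib_path)
        probes, genes, _ = sim.simulate_array(sim.SimulationConfig(n_genes=150, seed=4))
        refs_dir = tmp_path / "refs"
        sim.simulate_reference_sets(genes, 30, 30, 15, seed=3, outdir=refs_dir)
        cfg = self._config(
            overlap={"reference_sets": [{"name": "refA", "path": str(refs_dir / "setA.txt")}]},
            motif={
                "fasta": str(seqs_dir / "sequences.fa"),
                "k": 8,
                "max_mismatches": 0,
                "pwm_library": str(lib_path),
                "n_null": 100,
            },
        )
        report = run_pipeline(cfg, tmp_path / "out", seed=1)
        assert report["incomplete"] is False
        assert "refA" in report["overlap"]
        assert report["motif"]["consensus"]
        assert report["motif"]["best_pwm_match"]["library_name"] == "REST_like_synthetic"

    def test_missing_input_named(self, tmp_path):
        cfg = {"inputs": {"probes": str(tmp_path / "nope.tsv")}}
        with pytest.raises(FileNotFoundError, match="nope.tsv"):
            run_pipeline(cfg, tmp_path / "out", seed=0)
        report = json.loads((tmp_path / "out" / "report.json").read_text())
        assert report["incomplete"] is True
        assert "nope.tsv" in report["error"]

    def test_bad_config_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown config"):
            run_pipeline({"simulate": {}, "bogus": 1}, tmp_path, seed=0)
        with pytest.raises(ValueError, match="exactly one"):
            run_pipeline({"caller": {}}, tmp_path, seed=0)


class TestCli:
    def test_simulate_call_round_trip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "simdir"
        r = runner.invoke(
            ccli.main,
            ["simulate", "array", "--n-genes", "80", "--outdir", str(out), "--seed", "2"],
        )
        assert r.exit_code == 0, r.output
        r = runner.invoke(
            ccli.main,
            [
                "call",
                "--probes", str(out / "probes.tsv"),
                "--genes", str(out / "genes.bed"),
                "--n-permutations", "2",
                "--outdir", str(tmp_path / "calls"),
                "--seed", "1",
            ],
        )
        assert r.exit_code == 0, r.output
        assert "bound regions" in r.output
        assert (tmp_path / "calls" / "regions.bed").exists()

    def test_run_subcommand(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(
            yaml.safe_dump({"simulate": {"n_genes": 100}, "caller": {"n_permutations": 2}})
        )
        runner = CliRunner()
        r = runner.invoke(
            ccli.main,
            ["run", "--config", str(cfg_path), "--outdir", str(tmp_path / "out"), "--seed", "3"],
        )
        assert r.exit_code == 0, r.output
        assert (tmp_path / "out" / "report.json").exists()

    def test_overlap_subcommand(self, tmp_path):
        (tmp_path / "u.txt").write_text("\n".join(f"g{i}" for i in range(100)) + "\n")
        (tmp_path / "a.txt").write_text("\n".join(f"g{i}" for i in range(20)) + "\n")
        (tmp_path / "b.txt").write_text("\n".join(f"g{i}" for i in range(10, 40)) + "\n")
        runner = CliRunner()
        r = runner.invoke(
            ccli.main,
            [
                "overlap",
                "--set-a", str(tmp_path / "a.txt"),
                "--set-b", str(tmp_path / "b.txt"),
                "--universe", str(tmp_path / "u.txt"),
            ],
        )
        assert r.exit_code == 0, r.output
        payload = json.loads(r.output)
        assert payload["n_overlap"] == 10
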