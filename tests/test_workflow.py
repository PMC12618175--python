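"""Experiment orchestration, IO round trips, fixtures and the CLI."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from fourdct.cli import main
from fourdct.errors import FourDCTError
from fourdct.io import read_phase4dct, read_trace_csv, write_phase4dct, write_trace_csv
from fourdct.phantom import PhantomSpec
from fourdct.respsignal import generate_sinusoid
from fourdct.workflow import (
    ExperimentConfig,
    cell_seed,
    evaluate_external,
    make_fixtures,
    run_phantom_experiment,
)

COARSE = dict(
    phantom=PhantomSpec(grid_shape=(48, 48, 44), spacing_mm=(2.0, 2.0, 2.0)),
    roi_diameter_px=6.0,
    roi_offset_px=12,
)


@pytest.fixture(scope="module")
def coarse_report():
    cfg = ExperimentConfig(replicates=1, base_seed=11, **COARSE)
    return run_phantom_experiment(cfg)


class TestExperiment:
    def test_seed_derivation_is_stable_and_bounded(self):
        s = cell_seed(3, "volume", "normal", 0)
        assert s == cell_seed(3, "volume", "normal", 0)
        assert s != cell_seed(3, "helical", "normal", 0)
        assert 0 <= s < 2**31

    def test_grid_is_complete(self, coarse_report):
        assert len(coarse_report.cells) == 6  # 2 modes x 3 patterns x 1 replicate
        for cell in coarse_report.cells.values():
            for block in ("cnr", "dimensional", "positional", "dose"):
                assert block in cell
            assert len(cell["positional"]["per_phase_abs_error_mm"]) == 10

    def test_report_is_deterministic(self, coarse_report):
        cfg = ExperimentConfig(replicates=1, base_seed=11, **COARSE)
        again = run_phantom_experiment(cfg)
        assert coarse_report.to_json() == again.to_json()

    def test_yaml_config_round_trip(self, tmp_path):
        doc = {
            "phantom": {"grid_shape": [48, 48, 44], "spacing_mm": [2.0, 2.0, 2.0]},
            "acquisition": {"noise_sd_hu": 5.0},
            "experiment": {"modes": ["volume"], "patterns": ["normal"], "base_seed": 4},
        }
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(doc))
        cfg = ExperimentConfig.from_yaml(p)
        assert cfg.phantom.grid_shape == (48, 48, 44)
        assert cfg.acquisition_overrides == {"noise_sd_hu": 5.0}
        assert cfg.modes == ("volume",) and cfg.base_seed == 4


class TestTraceCSV:
    def test_round_trip(self, tmp_path):
        trace = generate_sinusoid(10.0, 4.0, 20.0)
        p = tmp_path / "trace.csv"
        write_trace_csv(trace, p)
        back = read_trace_csv(p)
        np.testing.assert_allclose(back.amplitude, trace.amplitude, atol=1e-7)
        assert back.sample_rate == pytest.approx(trace.sample_rate)

    def test_crlf_tolerated(self, tmp_path):
        p = tmp_path / "trace.csv"
        rows = ["time_s,amplitude_mm"] + [f"{i*0.04:.3f},{i%5}" for i in range(100)]
        p.write_bytes(("\r\n".join(rows) + "\r\n").encode())
        assert read_trace_csv(p).times.size == 100

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,a\n0,1\n0.04,2\n")
        with pytest.raises(FourDCTError):
            read_trace_csv(p)


@pytest.fixture(scope="module")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    make_fixtures(out, seed=0)
    return out


class TestExternalEvaluation:

    def test_round_trip_matches_in_memory(self, fixture_dir, seg):
        """Simulator output pushed through the NIfTI writer and re-evaluated
        reproduces the in-memory metrics."""
        from fourdct.qametrics import dimensional_report, positional_report
        from fourdct.phantom import MotionModel

        phases = read_phase4dct(fixture_dir / "phases")
        trace = read_trace_csv(fixture_dir / "trace_normal.csv")
        frag = evaluate_external(
            fixture_dir / "phases",
            fixture_dir / "trace_normal.csv",
            roi_diameter_px=4.0,
            roi_offset_px=10,
        )
        motion = MotionModel(trace, axis="z")
        pos = positional_report(phases, motion, trace, seg)
        assert frag["positional"]["mean_abs_error_mm"] == pytest.approx(
            pos.mean_abs_error_mm, abs=1e-6
        )
        assert frag["positional"]["surrogate_correlation"] == pytest.approx(
            pos.surrogate_correlation, abs=1e-6
        )

    def test_missing_phase_file_is_named(self, fixture_dir, tmp_path):
        import shutil

        broken = tmp_path / "phases"
        shutil.copytree(fixture_dir / "phases", broken)
        (broken / "phase_40.nii.gz").unlink()
        with pytest.raises(FourDCTError, match="phase_40"):
            evaluate_external(broken, fixture_dir / "trace_normal.csv")

    def test_manifest_schema_and_seed_sensitivity(self, fixture_dir, tmp_path):
        manifest = json.loads((fixture_dir / "manifest.json").read_text())
        assert set(manifest) == {"seed", "files"}
        assert "trace_normal.csv" in manifest["files"]
        other = tmp_path / "fx2"
        m2 = make_fixtures(other, seed=1)
        assert set(m2) == {"seed", "files"}
        assert (
            m2["files"]["trace_irregular.csv"]
            != manifest["files"]["trace_irregular.csv"]
        )

    def test_dicom_phase_series_readable(self, tmp_path):
        """A per-phase DICOM series directory round-trips pixel data and
        spacing."""
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        from fourdct.phantom import render_volume

        spec = PhantomSpec(
            grid_shape=(24, 24, 8), spacing_mm=(2.0, 2.0, 2.0), target_diameter_mm=10.0
        )
        vol = render_volume(spec, 0.0)
        root = tmp_path / "series"
        for label in (0, 10):
            d = root / f"phase_{label:02d}"
            d.mkdir(parents=True)
            for k in range(vol.voxels.shape[2]):
                ds = Dataset()
                ds.file_meta = FileMetaDataset()
                ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
                ds.SOPInstanceUID = generate_uid()
                ds.SOPClassUID = pydicom.uid.CTImageStorage
                ds.file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
                ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
                ds.Rows, ds.Columns = vol.voxels.shape[1], vol.voxels.shape[0]
                ds.PixelSpacing = [2.0, 2.0]
                ds.SliceThickness = 2.0
                ds.ImagePositionPatient = [0.0, 0.0, float(k * 2.0)]
                ds.InstanceNumber = k + 1
                ds.BitsAllocated = 16
                ds.BitsStored = 16
                ds.HighBit = 15
                ds.PixelRepresentation = 1
                ds.SamplesPerPixel = 1
                ds.PhotometricInterpretation = "MONOCHROME2"
                ds.RescaleSlope = 1.0
                ds.RescaleIntercept = 0.0
                ds.PixelData = (
                    vol.voxels[:, :, k].T.astype(np.int16).tobytes()
                )
                ds.save_as(d / f"{k:03d}.dcm", enforce_file_format=True)
        phases = read_phase4dct(root)
        assert len(phases.phases) == 2
        np.testing.assert_allclose(phases.phases[0].voxels, np.round(vol.voxels))
        assert phases.phases[0].spacing_mm == (2.0, 2.0, 2.0)


class TestCLI:
    def test_simulate_report_and_fixture_verbs(self, tmp_path):
        runner = CliRunner()
        cfg = {
            "phantom": {"grid_shape": [40, 40, 44], "spacing_mm": [2.0, 2.0, 2.0]},
            "metrics": {"roi_diameter_px": 6, "roi_offset_px": 10},
            "experiment": {"modes": ["volume"], "patterns": ["normal"], "base_seed": 2},
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        out = tmp_path / "report.json"
        res = runner.invoke(
            main,
            ["simulate", "--config", str(cfg_path), "--out", str(out)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0, res.output
        data = json.loads(out.read_text())
        assert "volume:normal:0" in data["cells"]

        csv_out = tmp_path / "report.csv"
        res = runner.invoke(
            main, ["report", "--in", str(out), "--out-csv", str(csv_out)],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
        assert csv_out.read_text().count("\n") == 11  # header + 10 phases

        res = runner.invoke(
            main, ["fixtures", "--out", str(tmp_path / "fx"), "--seed", "0"],
            catch_exceptions=False,
        )
        assert res.exit_code == 0
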