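"""Shared fixtures: one default synthetic bundle and its pipeline runs.

The bundle is generated once per session at the generator defaults
(3+3 samples, 8 planted triads, 4-fold changes) and the full pipeline is
run twice on it, so determinism and recovery checks share the work.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pytest

from cernapipe.pipeline import run_all
from cernapipe.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """(bundle_dir, GeneratedBundle) at generator defaults, seed 0."""
    out = tmp_path_factory.mktemp("bundle")
    bundle = generate_dataset(GeneratorConfig(seed=0), out_dir=out)
    return out, bundle


@pytest.fixture(scope="session")
def pipeline_runs(default_bundle, tmp_path_factory):
    """Two full pipeline runs on the default bundle, with wall times."""
    bundle_dir, _ = default_bundle
    runs = []
    for name in ("run1", "run2"):
        out = tmp_path_factory.mktemp(name)
        start = time.perf_counter()
        manifest = run_all(bundle_dir, out)
        runs.append({"dir": out, "manifest": manifest,
                     "seconds": time.perf_counter() - start})
    return runs


@pytest.fixture(scope="session")
def recovery(pipeline_runs):
    report_path = Path(pipeline_runs[0]["dir"]) / "recovery_report.json"
    return json.loads(report_path.read_text())


@pytest.fixture(scope="session")
def tiny_config():
    """A small generator config for fast structural tests."""
    return GeneratorConfig(
        seed=7, n_mrna=16, n_lncrna=12, n_mirna=8, n_triads=2,
        n_de_extra_mrna=2, n_de_extra_lncrna=2, n_de_extra_mirna=2,
        n_antisense=1, n_neighbor=1, n_distal=1, n_control_distal=1,
        lnc_multi_isoform_fraction=0.0,
    )
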