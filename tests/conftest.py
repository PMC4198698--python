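import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from fedvar.genotyper import PileupColumn
from fedvar.registry import Registry
from fedvar.synthetic import Site, build_federation, simulate_cohort


def column(bases: str, qual: int = 30, chrom: str = "chr1",
           pos: int = 100, ref: str = "A") -> PileupColumn:
    return PileupColumn(chrom, pos, ref, list(bases), [qual] * len(bases))


@pytest.fixture
def registry() -> Registry:
    reg = Registry(salt="test-salt", clock=_ticker())
    reg.add_user("bootstrap", "sysadmin", "system_admin")
    reg.add_center("sysadmin", "C1", "Center One", ["admin1"])
    reg.add_center("sysadmin", "C2", "Center Two", ["admin2"])
    return reg


def _ticker():
    state = {"t": 0.0}

    def clock():
        state["t"] += 1.0
        return state["t"]

    return clock


def manifest_row(local_name="S-001", pi="PI_A", sample_type="Research",
                 build="hg19", data_path=""):
    return {
        "SampleLocalName": local_name,
        "PIName": pi,
        "SampleType": sample_type,
        "SampleReferenceVersion": build,
        "DataPath": data_path,
    }


@pytest.fixture
def small_federation(tmp_path):
    """2 centers x 6 samples, one planted het at the first site."""
    sites = [
        Site("chr9", 2115841, "G", "A", 0.0, "rs0000001"),
        Site("chr9", 2115900, "C", "T", 0.25),
    ]
    truth = simulate_cohort(6, sites, seed=11,
                            plant_overrides={("SMP-0002", 0): 1})
    deployment = build_federation(tmp_path / "fed", truth, n_centers=2,
                                  fixed_depth=20, seed=11)
    return truth, deployment
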