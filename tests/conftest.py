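import textwrap

import numpy as np
import pytest

from mrmpanel.proteome_io import Category, Proteome
from mrmpanel.simulate import SimConfig


@pytest.fixture
def write_fasta(tmp_path):
    """Write {accession: sequence} to a FASTA file and return its path."""

    def _write(records: dict[str, str], name: str = "test.fasta"):
        path = tmp_path / name
        lines = []
        for acc, seq in records.items():
            lines.append(f">{acc} some description")
            lines.extend(textwrap.wrap(seq, 60))
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_sim():
    """Small, noiseless, jitter-free simulation settings."""
    return SimConfig(seed=7, noise_scale=0.0, rt_jitter_sd_min=0.0, baseline=0.0)


def make_proteome(pid: str, category, sequences: list[str]) -> Proteome:
    return Proteome(
        id=pid,
        taxon_name=f"taxon {pid}",
        category=Category(category),
        proteins=[(f"{pid}_p{i}", s) for i, s in enumerate(sequences)],
    )
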