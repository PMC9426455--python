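import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def _pdb_atom(serial: int, name: str, resname: str, chain: str, seq: int,
              x: float, y: float, z: float, occ: float = 1.0,
              altloc: str = " ", icode: str = " ", record: str = "ATOM",
              element: str = "C") -> str:
    return (f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
            f"{seq:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


@pytest.fixture
def pdb_atom():
    return _pdb_atom


@pytest.fixture
def ten_ca_pdb(tmp_path) -> Path:
    """Synthetic single-chain PDB with 10 CA records numbered 1..10."""
    lines = [
        _pdb_atom(i + 1, "CA", "ALA", "A", i + 1, 3.8 * i, 0.0, 0.0)
        for i in range(10)
    ]
    lines.append("END")
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
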