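import numpy as np
import pytest

from tgfm import ModelConfig, SyntheticSpec, generate_synthetic, pack, preprocess


@pytest.fixture(scope="session")
def small_records():
    return generate_synthetic(SyntheticSpec(n_molecules=10, atom_range=(3, 9),
                                            seed=11))


@pytest.fixture(scope="session")
def small_ds(small_records):
    ds = pack(small_records)
    ds, _ = preprocess(ds)
    return ds


@pytest.fixture()
def tiny_config():
    """A desk-size model configuration exercising every component."""
    return ModelConfig(embed_dim=16, layers=2, hops=3, hop_hidden=24,
                       ffn_hidden=24, vn_hidden=24, attn_dim=16, seed=3)


METHANE_SDF = """methane
  synthetic fixture

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300    0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300   -0.6300    0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
   -0.6300    0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
    0.6300   -0.6300   -0.6300 H   0  0  0  0  0  0  0  0  0  0  0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
$$$$
"""

CORRUPT_SDF_BLOCK = """broken
  synthetic fixture

  2  1  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
  1  2  1  0
M  END
$$$$
"""


@pytest.fixture()
def methane_sdf(tmp_path):
    p = tmp_path / "methane.sdf"
    p.write_text(METHANE_SDF)
    return p


@pytest.fixture()
def mixed_sdf(tmp_path):
    p = tmp_path / "mixed.sdf"
    p.write_text(CORRUPT_SDF_BLOCK + METHANE_SDF)
    return p
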