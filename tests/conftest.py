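import pytest

from aminotp import Dataset, IsotopeSample, generate, paperlike_config


@pytest.fixture
def small_dataset() -> Dataset:
    """Three individuals, one per food-web cluster; two with AA values."""
    return Dataset(
        [
            IsotopeSample("pisc_1", "piscivore", -12.0, 20.0, d15n_glu=25.0, d15n_phe=6.0),
            IsotopeSample("sang_1", "sanguivore", -12.0, 9.0, d15n_glu=14.0, d15n_phe=8.0),
            IsotopeSample("frug_1", "frugivore", -25.0, 8.0),
        ]
    )


@pytest.fixture
def csv_factory(tmp_path):
    """Write CSV text to a temp file and return its path."""

    counter = {"n": 0}

    def _write(text: str):
        counter["n"] += 1
        path = tmp_path / f"table_{counter['n']}.csv"
        path.write_text(text)
        return path

    return _write


@pytest.fixture(scope="session")
def paperlike_community():
    """Deterministic nine-guild community plus its ground truth."""
    cfg = paperlike_config(seed=42)
    ds, truth = generate(cfg)
    return cfg, ds, truth
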