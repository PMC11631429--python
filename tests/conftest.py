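import numpy as np
import pytest

from specgmm import pipeline as pl
from specgmm import synthetic_data as syn


@pytest.fixture(scope="session")
def default_records():
    """Two-class fixture: period-3 vs period-7 motifs, 60 sequences each."""
    records, _ = syn.generate(syn.default_two_class_spec(seed=7))
    return records


@pytest.fixture(scope="session")
def end_to_end_reports(default_records):
    """Supervector and baseline evaluations with the linear discriminant.

    Computed once per session: the scaled window preset (63/9/64, K=5)
    keeps the run inside a few seconds.
    """
    cfg = pl.RunConfig(
        winlen=63, winshift=9, fft_order=64, K=5, classifier="ld", seed=7
    )
    spec_report, artifacts = pl.evaluate_dataset(default_records, cfg)
    cfg_base = pl.RunConfig(
        winlen=63, winshift=9, fft_order=64, K=5, classifier="ld", seed=7,
        feature_kind="baseline",
    )
    base_report, _ = pl.evaluate_dataset(default_records, cfg_base)
    return {"specgmm": spec_report, "baseline": base_report, "artifacts": artifacts}


@pytest.fixture(scope="session")
def region_ranking():
    """Region-localized fixture ranking: only V3 carries class signal."""
    from specgmm import hvr_analysis as hvr

    records, hvr_df = syn.generate(syn.region_localized_spec(seed=7))
    cfg = pl.RunConfig(
        winlen=63, winshift=9, fft_order=64, K=5, classifier="ld", seed=7
    )
    table, details = hvr.rank_regions(records, hvr_df, cfg)
    return {"table": table, "details": details, "n_sequences": len(records)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_fixture(tmp_path):
    """Small on-disk FASTA + manifest for I/O and CLI tests."""
    spec = syn.SyntheticSpec(
        classes=[("a", "ATT"), ("b", "AAATTTT")],
        n_per_class=8,
        length_range=(300, 420),
        motif_density=0.5,
        seed=3,
    )
    return syn.write_fixture(spec, tmp_path / "tiny")
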