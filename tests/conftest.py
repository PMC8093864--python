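import numpy as np
import pytest

from covnet import synth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cov_fixture():
    """Latent-factor covariance volume dataset (dataset, covariates, truth)."""
    return synth.gen_covariance_dataset(rng_seed=101)


@pytest.fixture(scope="session")
def volume_files(tmp_path_factory, cov_fixture):
    """The covariance fixture written out as per-subject NIfTIs + mask."""
    ds, table, truth = cov_fixture
    outdir = tmp_path_factory.mktemp("vols")
    manifest = synth.save_volume_dataset(ds, outdir)
    table.df.to_csv(outdir / "covariates.tsv", sep="\t", index=False)
    manifest["covariates"] = str(outdir / "covariates.tsv")
    return manifest
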