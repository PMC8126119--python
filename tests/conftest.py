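import numpy as np
import pandas as pd
import pytest

from riboshift import annotation_io as ai
from riboshift import synthetic_data as sd
from riboshift import uorf_discovery as ud

TINY_SEED = 7


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_fixture")
    sd.write_fixture("tiny", out, seed=TINY_SEED, force=True)
    return out


@pytest.fixture(scope="session")
def tiny_models(tiny_dir):
    return ai.parse_annotation(
        str(tiny_dir / "annotation.gff3"), str(tiny_dir / "genome.fa")
    )


@pytest.fixture(scope="session")
def tiny_uorfs(tiny_models):
    return ud.discover_uorfs(tiny_models)


@pytest.fixture(scope="session")
def tiny_truth(tiny_dir):
    return pd.read_csv(tiny_dir / "truth_genes.tsv", sep="\t", index_col=0)


@pytest.fixture(scope="session")
def tiny_meta(tiny_dir):
    return pd.read_csv(tiny_dir / "samples.tsv", sep="\t", index_col=0)


@pytest.fixture(scope="session")
def tiny_ledger(tiny_dir):
    return pd.read_csv(tiny_dir / "truth_ledger.tsv", sep="\t")


@pytest.fixture(scope="session")
def tiny_sam_paths(tiny_dir, tiny_meta):
    return {s: str(tiny_dir / f"{s}.sam") for s in tiny_meta.index}


def random_genome(rng: np.random.Generator, chroms: dict[str, int]) -> dict[str, str]:
    return {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in chroms.items()
    }
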