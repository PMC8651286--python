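import numpy as np
import pandas as pd
import pytest

from cfimmune.atlas import MethylationAtlas
from cfimmune.panel import AmpliconDef, Panel, default_panel


@pytest.fixture(scope="session")
def panel16() -> Panel:
    return default_panel()


@pytest.fixture()
def toy_amplicon() -> AmpliconDef:
    # one CpG (offset 1), one non-CpG C (offset 4)
    return AmpliconDef(name="TOY1", cell_type="t_cell", chrom="chr1",
                       start=0, end=6, ref_seq="ACGTCA")


@pytest.fixture()
def toy_panel(toy_amplicon) -> Panel:
    return Panel(amplicons=[toy_amplicon])


def make_atlas(betas: np.ndarray, columns, positions=None,
               chrom="chr1") -> MethylationAtlas:
    n = betas.shape[0]
    ids = [f"cg{i:05d}" for i in range(n)]
    if positions is None:
        positions = [1000 * (i + 1) for i in range(n)]
    return MethylationAtlas(
        betas=pd.DataFrame(betas, index=pd.Index(ids, name="cpg_id"),
                           columns=list(columns)),
        coords=pd.DataFrame({"chrom": chrom, "pos": positions},
                            index=pd.Index(ids, name="cpg_id")))


@pytest.fixture()
def atlas_32col():
    """One target column + 31 other tissues, 4 CpGs with graded signals."""
    rng = np.random.default_rng(7)
    columns = ["target_cell"] + [f"tissue_{i:02d}" for i in range(31)]
    betas = rng.uniform(0.85, 1.0, size=(4, 32))
    return make_atlas(betas, columns)
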