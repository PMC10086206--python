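import numpy as np
import pandas as pd
import pytest

from epilnc import io_annotation as ioa
from epilnc.synthetic import CohortConfig, generate_cohort

SMALL = CohortConfig(n_samples=120, n_lncrna=300, n_pcg=500, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """120-sample cohort with 15 planted ER lncRNAs (fast shared fixture)."""
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def small_promoters(small_cohort):
    """Promoter-level betas of the small cohort, plus the lncRNA subset."""
    mapping = ioa.map_probes_to_promoters(small_cohort.probes, small_cohort.genes)
    prom = ioa.promoter_beta(small_cohort.meth, mapping)
    lnc = prom.loc[[g for g in prom.index
                    if small_cohort.genes.loc[g, "biotype"] == "lncRNA"]]
    return prom, lnc


@pytest.fixture(scope="session")
def hot_labels(small_cohort):
    """Planted subtype labels as cluster 1 (Hot) / 2 (Cold)."""
    truth = small_cohort.truth.subtype_labels
    return pd.Series(np.where(truth == "Hot", 1, 2), index=truth.index)
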