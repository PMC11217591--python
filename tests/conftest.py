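import pandas as pd
import pytest

import paleomethyl as pm


@pytest.fixture(scope="session")
def small_bundle():
    return pm.simulate.build_reference(
        chrom_length=120_000, n_islands=3, island_length=600, n_genes=12, seed=1
    )


@pytest.fixture(scope="session")
def small_catalog(small_bundle):
    return small_bundle.catalog()


@pytest.fixture(scope="session")
def small_truth(small_bundle):
    return pm.simulate.draw_truth_methylome(small_bundle, dmg_fraction=0.25, seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_bundle, small_truth):
    meta, labs = pm.simulate.small_cohort_meta(6)
    cohort = pm.simulate.simulate_cohort(small_bundle, small_truth, meta, labs, seed=7)
    return meta, labs, cohort


@pytest.fixture(scope="session")
def small_counts(small_cohort, small_catalog):
    """Depth-filtered per-genome site counts for the 6-genome toy cohort."""
    _, _, cohort = small_cohort
    return {
        gid: pm.scoring.apply_depth_filter(
            pm.scoring.count_site_evidence_table(
                rs.reads, rs.ledger[rs.ledger["deaminated"]], small_catalog, rs.library
            ),
            4,
        )
        for gid, rs in cohort.items()
    }


@pytest.fixture()
def toy_meta():
    return pd.DataFrame(
        {
            "genome_id": [f"g{i}" for i in range(6)],
            "subsistence": ["HG", "NF", "HG", "NF", "HG", "NF"],
            "tissue": ["bone", "bone", "tooth", "bone", "tooth", "bone"],
            "sex": ["XY", "XX", "XX", "XY", "XY", "XX"],
            "laboratory": ["A", "A", "A", "B", "B", "B"],
            "library": ["ds"] * 6,
            "coverage": [10.0] * 6,
        }
    )
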