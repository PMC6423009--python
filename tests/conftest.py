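import pandas as pd
import pytest

from clonarch import arms as arms_mod
from clonarch import ccf as ccf_mod
from clonarch import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample default cohort shared across tests (read-only)."""
    return synthetic.generate_cohort(synthetic.default_config(n_samples=60, seed=11))


@pytest.fixture(scope="session")
def small_cohort_calls(small_cohort):
    """Per-mutation clonality calls on the shared cohort (post read filters)."""
    kept, _ = ccf_mod.filter_snvs(small_cohort.mutations)
    return ccf_mod.call_mutations(kept, small_cohort.purities, small_cohort.segments)


@pytest.fixture(scope="session")
def small_cohort_event_calls(small_cohort, small_cohort_calls):
    """Gene-level plus arm-level event calls for the shared cohort."""
    g = ccf_mod.gene_level_calls(ccf_mod.exclude_multihit_genes(small_cohort_calls))
    events = arms_mod.build_arm_events(
        small_cohort.segments, small_cohort.purities, small_cohort.arms
    )
    table = arms_mod.merge_chromosome_events(events, small_cohort.arms)
    called = table[table["clonality"].isin(["clonal", "subclonal"])]
    return pd.concat(
        [
            g[["sample_id", "event_id", "ccf", "clonality"]],
            called[["sample_id", "event_id", "ccf", "clonality"]],
        ],
        ignore_index=True,
    )
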