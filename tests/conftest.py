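import numpy as np
import pytest

from replimode import mfa, simdata


@pytest.fixture(scope="session")
def termination_sim():
    """Main chromosome (bidirectional) + chromid (unidirectional) under
    termination synchrony: the standard two-replicon study condition."""
    main = simdata.SimReplicon(
        id="chr1", length=3_000_000, mode="bidirectional", ori=0, C=1.0, seed=1
    )
    chromid = simdata.SimReplicon(
        id="chr2", length=800_000, mode="unidirectional", ori=100_000, C=0.5, seed=2
    )
    growth = simdata.GrowthModel(tau=1.0, synchrony="termination")
    cov = simdata.simulate_coverage([main, chromid], growth, mean_depth=200, seed=1)
    return main, chromid, growth, cov


def corrected_profile(cov, replicon_id, length, bin_size=1000):
    """bin -> correct -> mask, the standard preparation order."""
    p = mfa.bin_coverage(cov.exponential[replicon_id], bin_size, replicon_id)
    s = mfa.bin_coverage(
        cov.stationary[replicon_id], bin_size, replicon_id, phase="stationary"
    )
    return mfa.remove_outliers(mfa.correct_coverage(p, s))


@pytest.fixture(scope="session")
def termination_profiles(termination_sim):
    main, chromid, growth, cov = termination_sim
    return {
        r.id: corrected_profile(cov, r.id, r.length) for r in (main, chromid)
    }
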