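import numpy as np
import pytest

from lipscan import fixtures as fx
from lipscan import profiles

# amphipathic-ish sequence: polar face (E/K) against an apolar face
AMPHI_SEQ = "ALKELAEKLLEALHKALEDL"


@pytest.fixture(scope="session")
def helix20():
    return fx.make_helix(AMPHI_SEQ, protein_id="helix20")


@pytest.fixture(scope="session")
def helix20_profile(helix20):
    return profiles.scan_profiles(helix20)


@pytest.fixture(scope="session")
def lattice3():
    return fx.make_lattice(3, 2.0)


# three amphipathic helices with 10-residue graded polar blocks: profile
# features wider than the probe, the regime in which window-length
# robustness is expected to hold
WIDE_BUNDLE_SEQS = ["LALLALLASTKEDKSEEKTSALLALLAL",
                    "ALLALLALLSTKSEEKTDESALLALLAL",
                    "LLALLASTKEDKSEKTSLALLALLALLA"]


@pytest.fixture(scope="session")
def wide_bundle():
    return fx.make_bundle(WIDE_BUNDLE_SEQS, protein_id="wide_bundle")


@pytest.fixture(scope="session")
def wide_bundle_tracks(wide_bundle):
    """PR/rho tracks of the wide bundle at window lengths 7, 8 and 9."""
    return {L: profiles.scan_profiles(wide_bundle, L=L) for L in (7, 8, 9)}


@pytest.fixture(scope="session")
def bundle3():
    return fx.make_bundle(["ALKELAEKLLEALHKA", "LLEALKKLFEALEKLL",
                           "ASDLKELAEKLFEALK"])


def random_track(rng, n=40, p_peak=0.15, p_missing=0.05, p_inf=0.03):
    """Random synthetic PR/rho tracks exercising all sentinel cases."""
    pr = rng.uniform(0.2, 0.75, size=n)
    peaks = rng.random(n) < p_peak
    pr[peaks] = rng.uniform(0.8, 1.3, size=peaks.sum())
    pr[rng.random(n) < p_missing] = np.nan
    pr[rng.random(n) < p_inf] = np.inf
    rho = rng.uniform(0.6, 0.95, size=n)
    rho[rng.random(n) < p_missing] = np.nan
    nums = np.arange(4, 4 + n)
    return profiles.ProfilePair("rand", nums, [str(v) for v in nums],
                                ["ALA"] * n, pr, rho)
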