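import numpy as np
import pytest

from cgsea import RankedGeneList


@pytest.fixture
def toy_ranked() -> RankedGeneList:
    """Five genes with statistics [3, 2, 1, -1, -2], already in rank order."""
    return RankedGeneList(["G1", "G2", "G3", "G4", "G5"], [3, 2, 1, -1, -2])


def brute_force_es(stats, member_positions, w):
    """Independent running-sum enumeration of the enrichment score.

    Plain Python walk down the ranked statistics: add |L_i|^w / NR at
    member positions, subtract 1/(N - N_C) elsewhere, track the maximum
    over the first N-1 prefixes (the full walk returns to zero).
    """
    stats = list(stats)
    members = set(member_positions)
    n = len(stats)
    n_c = len(members)
    assert 1 <= n_c < n
    nr = 0.0
    for i in sorted(members):
        nr += abs(stats[i]) ** w
    running = 0.0
    best = None
    for i in range(n - 1):
        if i in members:
            running += abs(stats[i]) ** w / nr
        else:
            running -= 1.0 / (n - n_c)
        if best is None or running > best:
            best = running
    return best


def make_ranked(rng, n):
    """Random ranked list over n genes with normal statistics (signed sort)."""
    stats = np.sort(rng.standard_normal(n))[::-1]
    return RankedGeneList([f"G{i}" for i in range(n)], stats)
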