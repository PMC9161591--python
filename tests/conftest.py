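import numpy as np
import pandas as pd
import pytest

import ctlungvol as cv


@pytest.fixture(scope="session")
def compact_phantom():
    """Miniature noiseless phantom at 1-mm isotropic spacing."""
    spec = cv.PhantomSpec.compact()
    ct, labels, truth = cv.make_lung_phantom(spec)
    return spec, ct, labels, truth


@pytest.fixture(scope="session")
def km_fixture():
    """10-subject survival fixture with a hand-computed product-limit table.

    Subjects: events at 1, 3, 4, 4, 6, 8, 9; censored at 2, 5, 7.
    Product-limit: S(1)=9/10, S(3)=0.9*7/8, S(4)=...*5/7, S(6)=...*3/4,
    S(8)=...*1/2, S(9)=0.
    """
    df = pd.DataFrame(
        {
            "time": [1, 2, 3, 4, 4, 5, 6, 7, 8, 9],
            "event": [1, 0, 1, 1, 1, 0, 1, 0, 1, 1],
        }
    )
    expected = {
        1: 0.9,
        3: 0.7875,
        4: 0.5625,
        6: 0.421875,
        8: 0.2109375,
        9: 0.0,
    }
    return df, expected


def logrank_oracle(times, events, groups):
    """Direct observed-minus-expected summation over event-time 2xK tables."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    o_minus_e = np.zeros(len(labels))
    var = np.zeros((len(labels), len(labels)))
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        d = ((times == t) & (events == 1)).sum()
        for i, g in enumerate(labels):
            n_g = (at_risk & (groups == g)).sum()
            d_g = ((times == t) & (events == 1) & (groups == g)).sum()
            o_minus_e[i] += d_g - d * n_g / n
        if n > 1:
            for i, gi in enumerate(labels):
                n_i = (at_risk & (groups == gi)).sum()
                for j, gj in enumerate(labels):
                    n_j = (at_risk & (groups == gj)).sum()
                    delta = 1.0 if i == j else 0.0
                    var[i, j] += (
                        d * (n_i / n) * (delta - n_j / n) * (n - d) / (n - 1)
                    )
    # drop one group (statistic is on K-1 df)
    v = var[:-1, :-1]
    u = o_minus_e[:-1]
    return float(u @ np.linalg.solve(v, u))


def harrell_oracle(risk, times, events):
    """O(n^2) pairwise enumeration of Harrell's C."""
    n = len(risk)
    conc = disc = tied = 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # i must be the usable earlier event of the pair
            if events[i] != 1:
                continue
            if not (times[i] < times[j] or (times[i] == times[j] and events[j] == 0)):
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                tied += 1
    return conc, disc, tied
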