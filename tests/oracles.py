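"""Independent reference computations used to validate the implementation.

The brute-force marginal likelihood enumerates every hidden-template path
of the two-state switching chain explicitly, so it shares no code with the
recursive filter it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp


def brute_force_total_surprisal(
    obs: np.ndarray,
    lam_m: np.ndarray,
    lam_u: float,
    p_switch: float,
    initial_prior: float,
) -> float:
    """-log marginal likelihood by explicit enumeration of hidden paths.

    State 0 = metered (onset probability ``lam_m[t]``), state 1 = unmetered
    (constant ``lam_u``); the regime switches between observations with
    probability ``p_switch``.  Exponential in the stream length — intended
    for streams of a dozen steps or fewer.
    """
    obs = np.asarray(obs, dtype=int)
    T = obs.size
    assert T <= 16, "path enumeration is exponential in stream length"
    # all 2^T hidden-state paths as a bit matrix
    codes = np.arange(2 ** T)
    paths = (codes[:, None] >> np.arange(T)[None, :]) & 1
    onset_prob = np.where(paths == 0, lam_m[None, :], lam_u)
    emit = np.where(obs[None, :] == 1, onset_prob, 1.0 - onset_prob)
    log_emit = np.log(emit).sum(axis=1)
    pi = np.array([initial_prior, 1.0 - initial_prior])
    log_init = np.log(pi[paths[:, 0]])
    switches = paths[:, 1:] != paths[:, :-1]
    log_trans = np.where(switches, np.log(p_switch), np.log1p(-p_switch)).sum(axis=1)
    return float(-logsumexp(log_init + log_emit + log_trans))
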