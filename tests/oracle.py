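"""Independent analytic oracles for the stochastic copying simulator.

The forward recursion here is derived directly from the generative
model's parameters (extension probabilities, propensity matrix, boost),
never from the sampling code: a two-state Markov recursion over the
terminal-pair status gives the exact marginal per-position probabilities
of {complementary, mismatch, unextended}.
"""

from __future__ import annotations

import numpy as np

from nerpe.construct import CopyingModel


def _comp_index(model: CopyingModel) -> list[int]:
    alpha = model.system.alphabet
    return [alpha.index(model.system.complement[b]) for b in alpha]


def mismatch_prob_given_incorporation(model: CopyingModel, boosted: bool) -> float:
    """P(incorporated base mismatches | incorporation), averaged over templates."""
    comp = _comp_index(model)
    q = 0.0
    for t in range(4):
        w = model.propensity[t].astype(float).copy()
        if boosted:
            mask = np.full(4, model.post_mismatch_error_boost)
            mask[comp[t]] = 1.0
            w = w * mask
        q += model.template_dist[t] * (1.0 - w[comp[t]] / w.sum())
    return q


def marginal_frequencies(model: CopyingModel, template_len: int = 6) -> dict[str, np.ndarray]:
    """Exact P(complementary), P(mismatch), P(unextended) at each position.

    States: after position i the read is stopped, or active with a
    complementary terminal pair, or active with a mismatched one.
    """
    q0 = mismatch_prob_given_incorporation(model, boosted=False)
    qb = mismatch_prob_given_incorporation(model, boosted=True)
    p_init = model.p_ext_initial
    p_m, p_mm = model.p_ext_after_match, model.p_ext_after_mismatch

    comp = np.zeros(template_len)
    mis = np.zeros(template_len)
    a_c = p_init * (1.0 - q0)
    a_m = p_init * q0
    comp[0], mis[0] = a_c, a_m
    for i in range(1, template_len):
        a_c, a_m = (
            a_c * p_m * (1.0 - q0) + a_m * p_mm * (1.0 - qb),
            a_c * p_m * q0 + a_m * p_mm * qb,
        )
        comp[i], mis[i] = a_c, a_m
    return {"complementary": comp, "mismatch": mis, "unextended": 1.0 - comp - mis}


def extension_ratio(model: CopyingModel) -> float:
    """True extension-probability ratio past comp vs mismatch at any position."""
    return model.p_ext_after_match / model.p_ext_after_mismatch
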