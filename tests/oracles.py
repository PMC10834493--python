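"""Independent brute-force oracles used by the test suite.

These deliberately avoid numpy vectorisation and any dissolvekit code:
plain-Python loops transcribing the defining equations, so that the
implementation and the oracle can only agree if both are right.
"""

import math


def f1_bruteforce(ref, test):
    """Difference factor from the defining sums, term by term."""
    num = 0.0
    den = 0.0
    for r, t in zip(ref, test, strict=True):
        num += abs(r - t)
        den += r
    return num / den * 100.0


def f2_bruteforce(ref, test):
    """Similarity factor from the defining equation, term by term."""
    n = len(ref)
    ss = 0.0
    for r, t in zip(ref, test, strict=True):
        ss += (r - t) ** 2
    return 50.0 * math.log10((1.0 + ss / n) ** -0.5 * 100.0)


def cumulative_percent_massbalance(conc_by_time, medium_ml, withdraw_ml,
                                   label_mg, replaced):
    """Cumulative % released for one replicate, by explicit mass balance.

    At sampling i the vessel holds C_i * V_i mg; every earlier aliquot j
    carried C_j * w mg out of the vessel.  Cumulative dissolved drug is
    the sum of both.  Vessel volume stays at medium_ml when aliquots are
    replaced, otherwise shrinks by w per prior withdrawal.
    """
    out = []
    removed = 0.0
    volume = medium_ml
    for i, c in enumerate(conc_by_time):
        if not replaced:
            volume = medium_ml - i * withdraw_ml
        in_vessel = c * volume
        out.append(100.0 * (in_vessel + removed) / label_mg)
        removed += c * withdraw_ml
    return out
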