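"""Independent brute-force oracle for the diploid caller.

Deliberately written from the model definition, not from the package
implementation: per-genotype likelihoods come from a direct product of
per-read probabilities, and the call/PL/GQ logic is re-derived here from
first principles so the two routes stay independent.
"""

import math

GTS = ("0/0", "0/1", "1/1")


def brute_force_likelihoods(bases, quals, ref, alt):
    """Direct product over reads for each of the three genotypes."""
    likelihoods = []
    for a1, a2 in ((ref, ref), (ref, alt), (alt, alt)):
        product = 1.0
        for base, qual in zip(bases, quals):
            err = 10.0 ** (-qual / 10.0)
            p1 = (1.0 - err) if base == a1 else err / 3.0
            p2 = (1.0 - err) if base == a2 else err / 3.0
            product *= 0.5 * p1 + 0.5 * p2
        likelihoods.append(product)
    return likelihoods


def brute_force_call(bases, quals, ref, alt):
    """(gt, pl, gq) derived directly from the product likelihoods."""
    likelihoods = brute_force_likelihoods(bases, quals, ref, alt)
    lmax = max(likelihoods)
    pl = tuple(int(round(-10.0 * math.log10(lk / lmax)))
               for lk in likelihoods)
    # smallest PL wins; on ties the genotype with more reference alleles
    best = 0
    for i in (1, 2):
        if pl[i] < pl[best]:
            best = i
    gq = min(sorted(pl)[1] - min(pl), 99)
    return GTS[best], pl, gq
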