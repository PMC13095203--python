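"""Brute-force reference classifier, independent of the package internals.

Everything here is written with plain sorting and loops: the percentile is
computed by explicit sort + linear interpolation between order statistics,
and the four decision steps are applied literally, one sample at a time.
Used only to cross-check ``clearseq.classifier.classify_cohort``.
"""

import math


def sort_percentile(values, q):
    """The k-th of n sorted values sits at percent 100*(k-1)/(n-1)."""
    s = sorted(values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * q / 100.0
    lo, hi = math.floor(h), math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def oracle_classify(samples, p3_ratio=80, p3_c2=50, p3_cc=64, p3_te=75,
                    p2=50, p4=60):
    """Classify a list of 8-key score dicts; returns a list of labels.

    Steps, applied literally:
      1. ccrcc3 iff ccrcc3_up/ccrcc3_down > P80 (over all) and ccrcc2_up,
         cell_cycle, t_effector at or below their P50/P64/P75 (over all).
      2. among the rest: ccrcc2 iff ccrcc2_up/ccrcc1and4_up > P50 of that
         ratio over the rest.
      3. among the still-unlabeled: ccrcc4 iff ccrcc4_up/ccrcc1_up > P60 of
         that ratio over those samples.
      4. remainder: ccrcc1.
    """
    n = len(samples)
    r3 = [s["ccrcc3_up"] / s["ccrcc3_down"] for s in samples]
    c2up = [s["ccrcc2_up"] for s in samples]
    cc = [s["cell_cycle"] for s in samples]
    te = [s["t_effector"] for s in samples]

    t_r3 = sort_percentile(r3, p3_ratio)
    t_c2 = sort_percentile(c2up, p3_c2)
    t_cc = sort_percentile(cc, p3_cc)
    t_te = sort_percentile(te, p3_te)

    labels = [None] * n
    for i in range(n):
        if r3[i] > t_r3 and c2up[i] <= t_c2 and cc[i] <= t_cc and te[i] <= t_te:
            labels[i] = "ccrcc3"

    rest = [i for i in range(n) if labels[i] is None]
    r2 = {i: samples[i]["ccrcc2_up"] / samples[i]["ccrcc1and4_up"] for i in rest}
    t_r2 = sort_percentile([r2[i] for i in rest], p2)
    for i in rest:
        if r2[i] > t_r2:
            labels[i] = "ccrcc2"

    rest2 = [i for i in range(n) if labels[i] is None]
    r4 = {i: samples[i]["ccrcc4_up"] / samples[i]["ccrcc1_up"] for i in rest2}
    t_r4 = sort_percentile([r4[i] for i in rest2], p4)
    for i in rest2:
        labels[i] = "ccrcc4" if r4[i] > t_r4 else "ccrcc1"

    return labels
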