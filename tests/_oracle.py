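"""Independent brute-force reference implementations.

Explicit nested loops over degrees, thresholds, utterances and classes —
deliberately slow and transparent, with no shared code paths with the
package's vectorized implementations. Used to pin down every agent-level
computation, typically at 4x grid resolution.
"""

from __future__ import annotations

import math


def gaussian_masses(points, mean, sd):
    out = []
    for x in points:
        z = (x - mean) / sd
        out.append(math.exp(-0.5 * z * z))
    total = sum(out)
    return [w / total for w in out]


def semantics(polarity: str, x: float, theta: float) -> bool:
    if polarity == "positive":
        return x > theta
    if polarity == "negative":
        return x < theta
    return True  # silence is true everywhere


def oracle_literal_listener(polarity, prior_mass, points):
    """L0(x | u, c): joint over (x, theta) ~ [[u]] * P(x|c) * P(theta),
    normalized once, theta marginalized by explicit summation."""
    n = len(points)
    joint_sum = [0.0] * n
    total = 0.0
    for i, x in enumerate(points):
        for theta in points:
            if semantics(polarity, x, theta):
                w = prior_mass[i] * (1.0 / n)
                joint_sum[i] += w
                total += w
    if total <= 0:
        raise ZeroDivisionError("utterance true nowhere with prior mass")
    return [v / total for v in joint_sum]


def oracle_speaker_row(alpha, costs, class_mass, points, x_index):
    """S1(u | x, c) at one grid point; utterance order (pos, neg, silence)."""
    l0 = {}
    for pol in ("positive", "negative", "silence"):
        try:
            l0[pol] = oracle_literal_listener(pol, class_mass, points)[x_index]
        except ZeroDivisionError:
            l0[pol] = 0.0
    utils = []
    for pol, cost in zip(("positive", "negative", "silence"), costs):
        if alpha == 0:
            utils.append(0.0)
        elif l0[pol] > 0:
            utils.append(alpha * (math.log(l0[pol]) - cost))
        else:
            utils.append(-math.inf)
    m = max(utils)
    if m == -math.inf:
        raise ZeroDivisionError("degenerate speaker state")
    exps = [math.exp(u - m) for u in utils]
    z = sum(exps)
    return [e / z for e in exps]


def oracle_speaker_table(alpha, costs, class_mass, points):
    """S1(u | x, c) for every x; rows (pos, neg, silence), columns x."""
    # precompute the three L0 posteriors once (still via the nested-loop L0)
    l0 = {}
    for pol in ("positive", "negative", "silence"):
        try:
            l0[pol] = oracle_literal_listener(pol, class_mass, points)
        except ZeroDivisionError:
            l0[pol] = [0.0] * len(points)
    table = [[0.0] * len(points) for _ in range(3)]
    for j in range(len(points)):
        utils = []
        for r, (pol, cost) in enumerate(zip(("positive", "negative", "silence"), costs)):
            v = l0[pol][j]
            if alpha == 0:
                utils.append(0.0)
            elif v > 0:
                utils.append(alpha * (math.log(v) - cost))
            else:
                utils.append(-math.inf)
        m = max(utils)
        if m == -math.inf:
            continue
        exps = [math.exp(u - m) for u in utils]
        z = sum(exps)
        for r in range(3):
            table[r][j] = exps[r] / z
    return table


def oracle_pragmatic_class_posterior(
    polarity, alpha, costs, k_mass, sub_mass, super_mass, p_sub, points
):
    """P(c_sub | u, k) by full enumeration of the joint over (x, c)."""
    row = {"positive": 0, "negative": 1, "silence": 2}[polarity]
    s_sub = oracle_speaker_table(alpha, costs, sub_mass, points)[row]
    s_super = oracle_speaker_table(alpha, costs, super_mass, points)[row]
    num = 0.0
    den = 0.0
    for j in range(len(points)):
        num += s_sub[j] * k_mass[j] * p_sub
        den += s_sub[j] * k_mass[j] * p_sub + s_super[j] * k_mass[j] * (1 - p_sub)
    return num / den


def oracle_literal_class_posterior(polarity, sub_mass, super_mass, p_sub, points):
    """P(c_sub | u, k) for the non-pragmatic listener: joint over
    (x, theta, c) ~ [[u]] * P(x|c) * P(theta) * P(c|k)."""
    n = len(points)
    num = 0.0
    den = 0.0
    for c, (mass, pc) in enumerate(((sub_mass, p_sub), (super_mass, 1 - p_sub))):
        for i, x in enumerate(points):
            for theta in points:
                if semantics(polarity, x, theta):
                    w = mass[i] * (1.0 / n) * pc
                    den += w
                    if c == 0:
                        num += w
    return num / den


def oracle_endorsement(polarity, alpha2, costs, k_mass, class_mass, points):
    """sum_x P(x|k) * S1(u | x, explicit class; alpha2)."""
    row = {"positive": 0, "negative": 1, "silence": 2}[polarity]
    s = oracle_speaker_table(alpha2, costs, class_mass, points)[row]
    return sum(k_mass[j] * s[j] for j in range(len(points)))


def oracle_binomial_loglik(rows):
    """Straight-line re-summation: rows of (k, n, p)."""
    total = 0.0
    for k, n, p in rows:
        total += (
            math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
        )
        if 0 < p < 1:
            total += k * math.log(p) + (n - k) * math.log(1 - p)
        elif (p == 0 and k > 0) or (p == 1 and k < n):
            return -math.inf
        elif p in (0.0, 1.0):
            pass  # consistent degenerate cell contributes 0
        else:
            return -math.inf  # nan probability
    return total
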