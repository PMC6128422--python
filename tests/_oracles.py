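"""Independent oracles used by the test suite.

Everything here is deliberately written without reference to the package's
implementation: brute-force grid maximum likelihood for the logistic model,
a closed-form even-df chi-square survival function, a verbal-definition
transcription of the trajectory class mapping, a Hudson-style FST estimator,
and the single-locus post-selection frequency expectation summed explicitly
over the three genotypes.
"""

from __future__ import annotations

import math

import numpy as np


def grid_mle_logistic(dosage, y, span: float = 8.0, n_grid: int = 41,
                      n_refine: int = 30) -> tuple[float, float]:
    """Coarse-to-fine grid search for the logistic MLE (intercept, slope)."""
    dosage = np.asarray(dosage, float)
    y = np.asarray(y, float)

    def negll(b0, b1):
        eta = b0 + b1 * dosage
        # log(1 + exp(eta)) computed stably
        return float(np.sum(np.logaddexp(0.0, eta)) - np.sum(y * eta))

    c0, c1, s = 0.0, 0.0, span
    for _ in range(n_refine):
        b0s = np.linspace(c0 - s, c0 + s, n_grid)
        b1s = np.linspace(c1 - s, c1 + s, n_grid)
        vals = np.array([[negll(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        c0, c1 = float(b0s[i]), float(b1s[j])
        s *= 0.5
    return c0, c1


def chi2_sf_even_df(x: float, df: int) -> float:
    """Upper tail of a chi-square with even df via the Erlang closed form."""
    assert df % 2 == 0
    k = df // 2
    h = x / 2.0
    return math.exp(-h) * sum(h**i / math.factorial(i) for i in range(k))


def classify_oracle(s12, s13, s23, d12, d13, d23) -> str:
    """Trajectory class mapping transcribed directly from the verbal definitions.

    s_ij: bool significance flags; d_ij: direction signs in {-1, 0, 1}.
    """
    # A: G2 significantly above both G1 and G3; G1 and G3 similar.
    if d12 == 1 and s12 and d23 == -1 and s23 and not s13:
        return "A"
    # B: G2 significantly below both; G1 and G3 similar.
    if d12 == -1 and s12 and d23 == 1 and s23 and not s13:
        return "B"
    # C: significantly increased in G2 and in centenarians vs G1.
    if s12 and d12 == 1 and s13 and d13 == 1:
        return "C"
    # D: significantly decreased in G2 and in centenarians vs G1.
    if s12 and d12 == -1 and s13 and d13 == -1:
        return "D"
    # E: significantly decreased in centenarians only; G1 and G2 similar.
    if not s12 and s13 and d13 == -1 and s23 and d23 == -1:
        return "E"
    # F: significantly increased in centenarians only; G1 and G2 similar.
    if not s12 and s13 and d13 == 1 and s23 and d23 == 1:
        return "F"
    return "UNCLASSIFIED"


def hudson_fst(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Hudson-style FST (ratio of averages) from two dosage matrices."""
    def freq_and_n(d):
        obs = np.isfinite(d)
        n = 2.0 * obs.sum(axis=0)
        p = np.where(obs, d, 0.0).sum(axis=0) / n
        return p, n

    p1, n1 = freq_and_n(np.asarray(dos_a, float))
    p2, n2 = freq_and_n(np.asarray(dos_b, float))
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.mean() / den.mean())


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def post_selection_freq(p: float, beta: float, base_surv: float) -> float:
    """Expected allele frequency among survivors of one selection window.

    Explicit sum over the three genotypes g in {0, 1, 2} with HW weights:
    p' = sum_g P(g) s(g) g/2 / sum_g P(g) s(g), s(g) = sigmoid(logit(base)+beta*g).
    """
    a = math.log(base_surv / (1 - base_surv))
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    s = [float(sigmoid(a + beta * g)) for g in (0, 1, 2)]
    num = sum(hw[g] * s[g] * g / 2 for g in (0, 1, 2))
    den = sum(hw[g] * s[g] for g in (0, 1, 2))
    return num / den


def two_stage_freq(p: float, bm: float, bl: float, base_m: float, base_l: float) -> float:
    """Expected frequency after both windows (joint weighting over genotypes)."""
    am = math.log(base_m / (1 - base_m))
    al = math.log(base_l / (1 - base_l))
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    w = [
        float(sigmoid(am + bm * g)) * float(sigmoid(al + bl * g)) for g in (0, 1, 2)
    ]
    num = sum(hw[g] * w[g] * g / 2 for g in (0, 1, 2))
    den = sum(hw[g] * w[g] for g in (0, 1, 2))
    return num / den
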