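"""Independent exact-arithmetic oracle for the stationary master equation.

Solves the balance equations of an N-state cycle with ``fractions.Fraction``
(floats are exact rationals), so the stationary distribution and the
one-step net flux carry no floating-point error at all.  Kept deliberately
free of any dissipath internals beyond the scheme's raw rate constants.
"""

from fractions import Fraction


def exact_stationary(n_states, k):
    """Exact stationary probabilities of the cycle master equation."""
    k = [Fraction(x) for x in k]
    n = n_states
    rates = [[Fraction(0)] * n for _ in range(n)]  # rates[i][j]: i -> j
    for i in range(n):
        j = (i + 1) % n
        rates[i][j] += k[2 * i]
        rates[j][i] += k[2 * i + 1]
    # balance equation for each state j: sum_i p_i rates[i][j] = p_j outflow_j,
    # with the last row replaced by normalisation sum p_i = 1
    A = [
        [rates[i][j] - (sum(rates[j]) if i == j else Fraction(0)) for i in range(n)]
        for j in range(n)
    ]
    A[-1] = [Fraction(1)] * n
    b = [Fraction(0)] * (n - 1) + [Fraction(1)]
    M = [row[:] + [b[r]] for r, row in enumerate(A)]
    for c in range(n):
        pivot = next(r for r in range(c, n) if M[r][c] != 0)
        M[c], M[pivot] = M[pivot], M[c]
        for r in range(n):
            if r != c and M[r][c] != 0:
                f = M[r][c] / M[c][c]
                M[r] = [a - f * bb for a, bb in zip(M[r], M[c])]
    return [M[i][n] / M[i][i] for i in range(n)]


def exact_one_step_net_flux(scheme):
    """Exact p1*k1 - p2*k2 through the substrate-binding transition."""
    p = exact_stationary(scheme.n_states, scheme.k)
    return p[0] * Fraction(scheme.k[0]) - p[1] * Fraction(scheme.k[1]), p
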