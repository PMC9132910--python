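"""Independent dense brute-force training oracle.

Re-derives the training loop from the model definition with plain Python
loops over a full n x n list-of-lists matrix — no shared code with the
package's sparse or vectorized paths beyond stimulus construction.  Used to
verify the fast paths on tiny lattices.
"""

from hebbtone.stimuli import build_stimulus


def oracle_train(
    lattice,
    signature,
    base_order,
    eta=1.0,
    kappa=0.0,
    transfer="relative",
    floor=0.0,
):
    """Return (weights, self_coincidence) after presenting ``base_order``."""
    n = lattice.n_tones
    weights = [[0.0] * n for _ in range(n)]
    selfco = [0.0] * n
    wmax = 0.0
    for base in base_order:
        stim = build_stimulus(lattice, base, signature)
        total = [0.0] * n
        for i, a in stim.components:
            total[i] += a
        if kappa > 0.0 and wmax > 0.0:
            for i, a in stim.components:
                for j in range(n):
                    w = weights[i][j]
                    if j != i and w > floor:
                        if transfer == "relative":
                            carry = w / wmax
                        elif transfer == "gated":
                            carry = 1.0
                        else:
                            carry = w
                        total[j] += kappa * a * carry
        active = [i for i in range(n) if total[i] > 0.0]
        for x, i in enumerate(active):
            selfco[i] += eta * total[i] * total[i]
            for j in active[x + 1:]:
                inc = eta * total[i] * total[j]
                weights[i][j] += inc
                weights[j][i] += inc
                if weights[i][j] > wmax:
                    wmax = weights[i][j]
    return weights, selfco
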