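"""What the cloud server can and cannot see.

Encrypts fragment lengths under the order-preserving homomorphic index
scheme and demonstrates the two ciphertext capabilities the solver relies
on: keyless order comparison and additive homomorphism.  The printed
ciphertext vectors are what crosses the public channel — real numbers that
reveal order but not magnitude.
"""

import numpy as np

from ppddp.ophi import NoiseBudget, Order, add, compare, encrypt, keygen

rng = np.random.default_rng(11)
key = keygen(3, rng=rng)
budget = NoiseBudget(p_min=1.0, L_max=4).resolved(key)

c10 = encrypt(key, 10, budget, rng)
c7 = encrypt(key, 7, budget, rng)
c3 = encrypt(key, 3, budget, rng)

print("Enc(10) =", [f"{v:.3f}" for v in c10.c])
print("Enc(7)  =", [f"{v:.3f}" for v in c7.c])
print("Enc(3)  =", [f"{v:.3f}" for v in c3.c])

print("compare(Enc(10), Enc(7)):", compare(c10, c7).name)  # GREATER, no key needed

s = add(c7, c3)
print("Enc(7) + Enc(3) vs Enc(10):", compare(s, c10, tie_gap=min(key.k) / 2).name)
# INDISTINGUISHABLE: the homomorphic sum encrypts the same plaintext 10,
# differing from a fresh Enc(10) only by noise below the public tie scale.
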