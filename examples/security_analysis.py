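"""The framework's security arithmetic, computed exactly.

Prints the exhaustive-search (one-wayness) bounds for a single encrypted
fragment and for a whole instance, and the probability that a lazy server's
random guess passes the owner's verification.
"""

import math

from ppddp.security import SecurityParams, exhaustive_search_bounds, lazy_server_probability

params = SecurityParams(key_bound=2**10, message_space=2**7, m=2, n=2, k=3)
per, full = exhaustive_search_bounds(params)

print(f"ciphertext-space expansion: {params.key_bound} = 2^10")
print(f"plaintext space |M| >= {params.message_space} = 2^7")
print(f"per-fragment recovery probability: 2^{math.log2(per):.0f}")
print(f"whole-instance ({params.m + params.n + params.k} fragments): "
      f"2^{math.log2(full):.0f}  (below the 2^-110 target)")
print(f"lazy-server guess probability (p=q=2): {lazy_server_probability(2, 2)}")
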