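"""Solve a tiny double digest instance end to end, privately.

A molecule of length 5 is cut by enzyme alpha into fragments {1, 4}, by
enzyme beta into {2, 3}, and by both together into {1, 1, 3}.  The owner
encrypts the three multisets, the (simulated) cloud server finds orderings
of A and B whose merged cut sites reproduce C working only on ciphertexts,
and the owner verifies the returned mapping and reads off the physical map.
"""

from ppddp import DDPInstance, GAConfig
from ppddp.framework import run_session

inst = DDPInstance(A=[1, 4], B=[2, 3], C=[1, 1, 3])
report = run_session(inst, n=3, cfg=GAConfig(seed=7), crypto_seed=1)

print(f"success:      {report.success}")
print(f"generations:  {report.generations}")
print(f"fitness:      {report.fitness}")
print(f"mu (1-based): {[i + 1 for i in report.mapping.mu]}")
print(f"nu (1-based): {[i + 1 for i in report.mapping.nu]}")

# The mapping orders A as (1, 4) and B as (2, 3): cut sites {1} and {2}
# merge to gaps 1, 1, 3 — exactly the simultaneous digest C, so the
# owner accepts (fitness 1 means an exact spectrum match).
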