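# ppddp — privacy-preserving outsourcing of the double digest problem

Restriction mapping by double digestion cuts one DNA molecule three ways —
with enzyme α, with enzyme β, and with both — and gel electrophoresis
reports three multisets of fragment lengths *A*, *B*, *C* with
Σaᵢ = Σbⱼ = Σcₖ. The **double digest problem (DDP)** asks for orderings
(permutations μ of *A*'s indices and ν of *B*'s) whose merged cut sites
reproduce *C*; it is strongly NP-complete, and the fragment-length data is
expensive to produce and commercially sensitive. This package is for
researchers who want to hand the search to an untrusted compute server
without revealing the lengths.

It implements a complete, simulated two-party protocol:

* **OPHI — order-preserving homomorphic index scheme.** A symmetric,
  probabilistic, decryption-free encryption of integers: plaintext *m*
  becomes the vector cᵢ = kᵢ·m + rᵢ (i < n), cₙ = kₙ·Σrᵢ, with secret
  positive keys kᵢ ≤ 2¹⁰ and budgeted positive noise. Ciphertexts support
  componentwise addition (encrypting m₁+m₂) and keyless order comparison,
  which is exactly what cut-site arithmetic needs.
* **QIGA — quantum-inspired genetic algorithm.** Individuals are qubit
  amplitude chromosomes; measurement collapses them to random keys that
  decode into valid permutation pairs, and rotation/crossover/mutation
  operators evolve them against the fitness
  f(μ,ν) = 1 / (1 + |C′\_{μ,ν} ⊖ C|), the L1 distance between the implied
  and observed double-digest spectra — computed entirely on ciphertexts.
* **The five-stage protocol.** (1) owner encrypts, (2) publishes the
  ciphertexts, (3) server solves over ciphertexts, (4) server publishes
  the index permutations — which reveal nothing without the plaintexts —
  (5) owner verifies with one plaintext evaluation and extracts the
  physical map. A lazy server's random guess is caught at stage 5 with
  probability 1 − s/(p!·q!), s being the number of equivalent solutions.

## A worked example

```python
from ppddp import DDPInstance, GAConfig
from ppddp.framework import run_session

inst = DDPInstance(A=[1, 4], B=[2, 3], C=[1, 1, 3])
report = run_session(inst, n=3, cfg=GAConfig(seed=7), crypto_seed=1)
print(report.success, report.generations, report.fitness,
      [i + 1 for i in report.mapping.mu], [i + 1 for i in report.mapping.nu])
```

prints

```
True 1 1.0 [1, 2] [1, 2]
```

The server found μ = (1,2), ν = (1,2) in one generation: ordering *A* as
(1, 4) and *B* as (2, 3) puts the α cut at coordinate 1 and the β cut at 2,
whose merged gaps 1, 1, 3 equal *C* exactly (fitness 1). The owner's
stage-5 check accepted, so `report.success` is true. Throughout the run
the server saw only 7 ciphertext vectors and a public residual threshold.

More narrative scripts live in `examples/` (ciphertext capabilities,
success-rate experiments, one-wayness arithmetic, ciphertext-distribution
QQ checks), and the same functionality is scriptable through the `ppddp`
command line tool (`ppddp gen`, `ppddp encrypt`, `ppddp solve`,
`ppddp verify`, `ppddp run`, `ppddp security`, `ppddp bench`).

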