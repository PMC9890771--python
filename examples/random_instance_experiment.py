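"""Success-rate experiment on random double digest instances.

Generates instances with growing simultaneous-digest size |C|, runs the
full encrypted pipeline repeatedly with different GA seeds, and reports
per-group success rates — the protocol used to characterize how solver
performance scales.  Sizes and repeat counts are kept small here so the
script finishes in about a minute.
"""

from ppddp.generate import success_rate_experiment
from ppddp.qiga import GAConfig

df = success_rate_experiment([6, 8, 10], runs=10, cfg=GAConfig(), seed=42)
print(df.to_string(index=False))

# success_rate is the fraction of runs whose returned mapping passed the
# owner's plaintext verification; mean_generations shows how much longer
# the search works as |C| grows.
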